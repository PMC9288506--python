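"""Dose-series description and dose-label parsing.

A LiP-MS dose-response experiment treats aliquots of one native lysate with a
compound dilution series plus a vehicle (0 M) control.  The default series
reproduces the 10-point design used for target deconvolution: seven 10-fold
dilutions from a high of 2 mM, two intermediate points (1 mM and 100 uM)
added to anchor the sigmoid mid-range, and the vehicle.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import DoseParseError

#: multipliers for the unit suffixes accepted in dose labels
_UNIT_SCALE = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,  # micro sign
    "μM": 1e-6,  # greek mu
    "nM": 1e-9,
    "pM": 1e-12,
}

_VEHICLE_LABELS = {"vehicle", "dmso", "control", "ctrl", "veh", "0"}

_DOSE_RE = re.compile(
    r"^\s*([0-9]+(?:\.[0-9]+)?(?:[eE][+-]?[0-9]+)?)\s*"
    r"(pM|nM|uM|µM|μM|mM|M)\s*$"
)


def parse_dose_label(label: str | float | int) -> float:
    """Convert a dose label such as ``"2mM"``, ``"100uM"`` or ``"vehicle"``
    to a molar concentration.

    Numeric inputs are taken as molar already.  Raises
    :class:`~lipsite.errors.DoseParseError` for anything unrecognised.
    """
    if isinstance(label, (int, float)):
        value = float(label)
        if value < 0:
            raise DoseParseError(f"negative dose: {label!r}")
        return value
    text = str(label).strip()
    if text.lower() in _VEHICLE_LABELS:
        return 0.0
    m = _DOSE_RE.match(text)
    if m is None:
        try:
            value = float(text)
        except ValueError:
            raise DoseParseError(f"cannot parse dose label {label!r}") from None
        if value < 0:
            raise DoseParseError(f"negative dose: {label!r}")
        return value
    return float(m.group(1)) * _UNIT_SCALE[m.group(2)]


def format_dose(conc: float) -> str:
    """Human-readable label for a molar concentration (``0 -> "vehicle"``)."""
    if conc == 0:
        return "vehicle"
    for unit, scale in (("mM", 1e-3), ("uM", 1e-6), ("nM", 1e-9), ("pM", 1e-12)):
        if conc >= scale:
            value = conc / scale
            return f"{value:g}{unit}"
    return f"{conc:g}M"


@dataclass(frozen=True)
class DoseSeries:
    """An ordered compound dilution series including one vehicle point.

    Parameters
    ----------
    concentrations
        Molar concentrations, exactly one of which is 0 (the vehicle).  The
        non-vehicle entries must be strictly monotone.
    labels
        One label per concentration; unique.
    replicates_per_dose
        Number of independent replicates treated at every concentration.
    """

    concentrations: tuple[float, ...]
    labels: tuple[str, ...] = field(default=())
    replicates_per_dose: int = 3

    def __post_init__(self):
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(format_dose(c) for c in self.concentrations)
            )
        if len(self.labels) != len(self.concentrations):
            raise ValueError("labels and concentrations must have equal length")
        n_vehicle = sum(1 for c in self.concentrations if c == 0)
        if n_vehicle != 1:
            raise ValueError(f"exactly one vehicle (0 M) entry required, got {n_vehicle}")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("dose labels must be unique")
        positive = [c for c in self.concentrations if c > 0]
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be non-negative")
        increasing = all(a < b for a, b in zip(positive, positive[1:]))
        decreasing = all(a > b for a, b in zip(positive, positive[1:]))
        if positive and not (increasing or decreasing):
            raise ValueError("non-vehicle concentrations must be strictly monotone")
        if self.replicates_per_dose < 1:
            raise ValueError("replicates_per_dose must be positive")

    @property
    def vehicle(self) -> float:
        return 0.0

    @property
    def nonzero(self) -> tuple[float, ...]:
        return tuple(c for c in self.concentrations if c > 0)

    @property
    def max_dose(self) -> float:
        return max(self.nonzero)

    @property
    def min_dose(self) -> float:
        return min(self.nonzero)

    def __len__(self) -> int:
        return len(self.concentrations)


def default_dose_series(replicates_per_dose: int = 3) -> DoseSeries:
    """The 10-point series used throughout: 10-fold dilutions from 2 mM down
    to 2 nM, plus intermediates 1 mM and 100 uM, plus vehicle."""
    concs = (
        2e-3,   # 2 mM, top of the series
        1e-3,   # 1 mM, intermediate
        2e-4,
        1e-4,   # 100 uM, intermediate
        2e-5,
        2e-6,
        2e-7,
        2e-8,
        2e-9,
        0.0,    # vehicle
    )
    return DoseSeries(concentrations=concs, replicates_per_dose=replicates_per_dose)
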