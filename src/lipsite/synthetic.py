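"""Synthetic LiP-MS and competition-pulldown data with known ground truth.

Every downstream stage (differential screen, 4PL fitting, structure mapping,
site triangulation, competition ranking) can be exercised offline against
data whose generating parameters are known exactly.  The LiP generator
emulates the statistical structure of a 10-concentration dose-response
experiment: most peptides are dose-independent with multiplicative
log-normal measurement noise, a planted minority follows a 4-parameter
log-logistic mean curve, and the peptides of the planted set occur in the
sequence of a toy protein structure clustered around a designated pocket
center so that center-of-mass triangulation has a recoverable truth.

The generators do not emulate raw DIA spectra, retention times, fragment
interference, or missing values in the LiP table; see the methods note for
what that implies about test coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doses import DoseSeries, default_dose_series
from .dose_response import four_pl
from .quant_io import (
    ONE_TO_THREE,
    Atom,
    Residue,
    StructureModel,
    read_structure,
    write_structure,
)
import biotite.structure.info as struc_info

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: pocket geometry: responsive-peptide segments centred within this radius
#: of the pocket center; background segments pushed out to the far shell
POCKET_RADIUS = 6.0
BACKGROUND_RADIUS = 45.0

_BACKBONE = {
    # ideal-geometry offsets (Angstrom) from the C-alpha position, in the
    # local frame of each residue; good enough for mass-weighted centroids
    "N": np.array([-1.46, 0.0, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.52, 0.0, 0.0]),
    "O": np.array([2.15, 1.05, 0.0]),
    "CB": np.array([-0.52, 1.42, 0.0]),
}
_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment, for parameter-recovery tests."""

    responsive_peptides: tuple[str, ...] = ()
    true_ec50: dict = field(default_factory=dict)       # peptide -> molar
    true_direction: dict = field(default_factory=dict)  # peptide -> +1 / -1
    pocket_center: np.ndarray | None = None
    noise_cv: float = 0.0
    seed: int = 0
    target_protein: str = ""
    warnings: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------


def _mass(element: str) -> float:
    return float(struc_info.mass(element))


def _segment_coords(n_residues: int, geometry: str) -> np.ndarray:
    """C-alpha positions of an ideal segment: alpha-helix (100 deg turn,
    1.5 A rise, 2.3 A radius -> 3.8 A consecutive C-alpha distance) or an
    extended strand-like zig-zag with the same spacing."""
    i = np.arange(n_residues)
    if geometry == "helix":
        angle = np.deg2rad(100.0) * i
        return np.column_stack(
            [2.3 * np.cos(angle), 2.3 * np.sin(angle), 1.5 * i]
        )
    if geometry == "extended":
        # 3.72 A run + 0.8 A zig-zag -> 3.8 A consecutive C-alpha distance
        return np.column_stack([3.72 * i, 0.8 * (i % 2), np.zeros(n_residues)])
    raise ValueError(f"geometry must be 'helix' or 'extended', got {geometry!r}")


def _build_residues(
    sequence: str,
    ca_coords: np.ndarray,
    start_number: int,
) -> list[Residue]:
    residues = []
    for idx, letter in enumerate(sequence):
        if letter not in ONE_TO_THREE:
            raise ValueError(f"non-standard residue letter {letter!r}")
        res_name = ONE_TO_THREE[letter]
        atom_names = ["N", "CA", "C", "O"] + ([] if letter == "G" else ["CB"])
        atoms = []
        for name in atom_names:
            pos = ca_coords[idx] + _BACKBONE[name]
            element = _ELEMENT[name]
            atoms.append(
                Atom(name, element, _mass(element), float(pos[0]), float(pos[1]), float(pos[2]))
            )
        residues.append(
            Residue(name=res_name, number=start_number + idx, atoms=tuple(atoms))
        )
    return residues


def write_toy_structure(
    sequence: str, geometry: str = "helix", path=None, chain_id: str = "A"
) -> StructureModel:
    """Build (and optionally write as PDB) a minimal single-chain structure
    with ideal geometry: backbone N/CA/C/O plus C-beta for non-glycine.

    Consecutive C-alpha atoms are ~3.8 A apart in both geometries.  The
    emitted PDB round-trips losslessly through
    :func:`lipsite.quant_io.read_structure` (coordinates to PDB precision).
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    ca = _segment_coords(len(sequence), geometry)
    model = StructureModel()
    model.chains[chain_id] = _build_residues(sequence.upper(), ca, start_number=1)
    if path is not None:
        write_structure(model, path)
    return model


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def build_pocket_structure(
    pocket_peptides: list[str],
    background_peptides: list[str],
    pocket_center: np.ndarray,
    rng: np.random.Generator,
    chain_id: str = "A",
) -> StructureModel:
    """One chain whose sequence is the concatenation of all peptides, with
    the pocket peptides' segments geometrically clustered around
    ``pocket_center`` and the background segments pushed to a distant shell.

    Chain connectivity between segments is not physical (the chain jumps
    between segments); the construct exists to give mapping and
    center-of-mass triangulation a known geometric truth, not to be a
    plausible fold.
    """
    segments = [(seq, True) for seq in pocket_peptides] + [
        (seq, False) for seq in background_peptides
    ]
    order = rng.permutation(len(segments))
    model = StructureModel()
    residues: list[Residue] = []
    number = 1
    for idx in order:
        seq, in_pocket = segments[idx]
        ca = _segment_coords(len(seq), "helix")
        ca = ca - ca.mean(axis=0)
        ca = ca @ _random_rotation(rng).T
        if in_pocket:
            # centroid uniform in a ball of radius POCKET_RADIUS
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            radius = POCKET_RADIUS * rng.random() ** (1 / 3)
            centroid = np.asarray(pocket_center) + radius * direction
        else:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            centroid = np.asarray(pocket_center) + BACKGROUND_RADIUS * direction
        ca = ca + centroid
        residues.extend(_build_residues(seq, ca, start_number=number))
        number += len(seq)
    model.chains[chain_id] = residues
    return model


# ---------------------------------------------------------------------------
# LiP dose-response experiment
# ---------------------------------------------------------------------------


def _random_peptides(
    rng: np.random.Generator, n: int, min_len: int = 7, max_len: int = 14
) -> list[str]:
    """Unique random tryptic-looking peptides (C-terminal K/R)."""
    peptides: list[str] = []
    seen = set()
    while len(peptides) < n:
        length = int(rng.integers(min_len, max_len + 1))
        body = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length - 1))
        pep = body + ("K" if rng.random() < 0.5 else "R")
        if pep not in seen:
            seen.add(pep)
            peptides.append(pep)
    return peptides


def _log2_noise_sd(noise_cv: float) -> float:
    """log2-scale s.d. of multiplicative log-normal noise with the given CV."""
    if noise_cv == 0:
        return 0.0
    return math.sqrt(math.log1p(noise_cv**2)) / math.log(2.0)


def simulate_lip_experiment(
    n_peptides: int = 500,
    n_responsive: int = 10,
    dose_series: DoseSeries | None = None,
    ec50: float = 1e-6,
    effect_log2: float = 1.5,
    noise_cv: float = 0.05,
    seed: int = 0,
    slope: float = 1.0,
    n_background_in_chain: int = 10,
    pocket_center=(25.0, 25.0, 25.0),
) -> tuple[pd.DataFrame, StructureModel, SimTruth]:
    """Simulate a full LiP-MS dose-response experiment.

    Returns ``(quant_table, structure, truth)``: a long-format
    PeptideQuantTable over the dose series (3 replicates per dose by
    default), a toy structure whose chain A contains every responsive
    peptide near ``pocket_center`` (plus ``n_background_in_chain``
    non-responsive peptides far from it), and the ground truth.

    Non-responsive peptides are dose-independent log-normal; responsive
    peptides follow a 4PL mean curve in log2 intensity with asymptote
    separation ``effect_log2`` (direction random per peptide) and planted
    midpoint ``ec50``.  Noise is multiplicative log-normal with coefficient
    of variation ``noise_cv``.  Identical arguments and seed reproduce the
    outputs bit-for-bit.
    """
    if n_responsive > n_peptides:
        raise ValueError(
            f"n_responsive ({n_responsive}) cannot exceed n_peptides ({n_peptides})"
        )
    if n_peptides < 1:
        raise ValueError("n_peptides must be positive")
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    if dose_series is None:
        dose_series = default_dose_series()

    warnings = []
    if dose_series.nonzero and not (
        dose_series.min_dose <= ec50 <= dose_series.max_dose
    ):
        warnings.append(
            f"planted ec50 {ec50:g} M lies outside the dose range "
            f"[{dose_series.min_dose:g}, {dose_series.max_dose:g}] M"
        )

    rng = np.random.default_rng(seed)
    peptides = _random_peptides(rng, n_peptides)
    responsive = list(rng.choice(n_peptides, size=n_responsive, replace=False))
    responsive_set = [peptides[i] for i in sorted(responsive)]
    directions = {
        pep: (1 if rng.random() < 0.5 else -1) for pep in responsive_set
    }

    sd_log2 = _log2_noise_sd(noise_cv)
    baseline = rng.normal(17.0, 1.5, size=n_peptides)  # log2 intensity scale

    doses = np.array(dose_series.concentrations)
    n_rep = dose_series.replicates_per_dose
    records = []
    chain_peptides = set(responsive_set)
    # non-responsive chain occupants: background decoys mapped far from pocket
    background_pool = [p for p in peptides if p not in chain_peptides]
    background_in_chain = background_pool[:n_background_in_chain]
    chain_peptides |= set(background_in_chain)

    for pep_idx, pep in enumerate(peptides):
        base = baseline[pep_idx]
        if pep in directions:
            bottom = base
            top = base + directions[pep] * effect_log2
            mean_log2 = four_pl(doses, bottom, top, ec50, slope)
        else:
            mean_log2 = np.full(doses.shape, base)
        protein = "SIM_TARGET" if pep in chain_peptides else f"BG_{pep_idx:04d}"
        for d_idx, dose in enumerate(doses):
            noise = rng.normal(0.0, sd_log2, size=n_rep) if sd_log2 else np.zeros(n_rep)
            for rep in range(n_rep):
                records.append(
                    (
                        protein,
                        pep,
                        pep,
                        float(dose),
                        f"R{rep + 1}",
                        float(2.0 ** (mean_log2[d_idx] + noise[rep])),
                    )
                )
    quant = pd.DataFrame(
        records,
        columns=[
            "protein_id",
            "modified_sequence",
            "stripped_sequence",
            "dose",
            "replicate",
            "quantity",
        ],
    )

    pocket_center = np.asarray(pocket_center, dtype=float)
    structure = build_pocket_structure(
        responsive_set, background_in_chain, pocket_center, rng
    )
    # guarantee unique mapping: every chain peptide occurs exactly once
    chain_seq = structure.chain_sequence("A")
    for pep in chain_peptides:
        assert chain_seq.count(pep) == 1, f"peptide {pep} not unique in chain"

    truth = SimTruth(
        responsive_peptides=tuple(responsive_set),
        true_ec50={pep: ec50 for pep in responsive_set},
        true_direction=directions,
        pocket_center=pocket_center,
        noise_cv=noise_cv,
        seed=seed,
        target_protein="SIM_TARGET",
        warnings=tuple(warnings),
    )
    return quant, structure, truth


# ---------------------------------------------------------------------------
# competition pulldown
# ---------------------------------------------------------------------------


def simulate_competition_experiment(
    n_proteins: int = 300,
    target_log2fc: float = 3.0,
    n_replicates: int = 2,
    seed: int = 0,
    background_sd: float = 0.3,
    channel_bias_sd: float = 0.15,
    missing_fraction: float = 0.02,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate an iTRAQ competition pulldown (channels vehicle / 8 uM /
    80 uM / 800 uM, competed-positive log2 ratios).

    One planted target shows dose-increasing competition reaching
    ``target_log2fc`` at the highest dose in every replicate; background
    proteins are centered at 0 with s.d. ``background_sd`` plus a shared
    per-channel bias (which median normalization must remove); a small
    fraction of background measurements are missing so the complete-cases
    rule is exercised.  Seeded and deterministic.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    from .competition import DEFAULT_CHANNELS

    rng = np.random.default_rng(seed)
    proteins = [f"P{idx:04d}" for idx in range(n_proteins)]
    target = proteins[int(rng.integers(0, n_proteins))]
    channels = list(DEFAULT_CHANNELS.items())  # (label, dose)
    # monotone competition profile peaking at exactly target_log2fc
    profile = {"vehicle": 0.0, "low": 0.3, "mid": 0.75, "high": 1.0}

    channel_bias = {
        (label, rep): (rng.normal(0.0, channel_bias_sd) if label != "vehicle" else 0.0)
        for label, _ in channels
        for rep in range(1, n_replicates + 1)
    }

    records = []
    for prot in proteins:
        n_pep = int(rng.poisson(8)) + 1
        for rep in range(1, n_replicates + 1):
            for label, dose in channels:
                if label == "vehicle":
                    value = 0.0  # ratio to itself, by construction
                elif prot == target:
                    value = target_log2fc * profile[label] + rng.normal(0.0, 0.05)
                    if label == "high":
                        # the planted truth: full competition in every replicate
                        value = target_log2fc
                else:
                    value = rng.normal(0.0, background_sd) + channel_bias[(label, rep)]
                    if rng.random() < missing_fraction:
                        value = np.nan
                records.append((prot, f"R{rep}", label, dose, value, n_pep))
    table = pd.DataFrame(
        records,
        columns=["protein_id", "replicate", "channel", "dose", "log2_ratio", "unique_peptides"],
    )
    truth = SimTruth(
        responsive_peptides=(),
        true_ec50={},
        true_direction={},
        pocket_center=None,
        noise_cv=background_sd,
        seed=seed,
        target_protein=target,
    )
    return table, truth
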