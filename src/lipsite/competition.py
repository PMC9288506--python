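"""Competition-pulldown target ranking (isobaric-label chemoproteomics).

A reverse competition experiment pre-incubates lysate with free compound at
increasing doses before enrichment on compound-derivatised beads; proteins
genuinely bound by the compound are competed off the beads, so their
enrichment drops with free-compound dose.  Quantification is by iTRAQ 4-plex
(one channel per dose: vehicle, 8 uM, 80 uM, 800 uM), two replicates.

The sign convention here is competed-positive: ``log2_ratio`` is
log2(vehicle enrichment / this-dose enrichment), so a true target shows a
large positive value at the highest dose.  Proteins are median-normalized
per channel, then ranked by the minimum across replicates of the
highest-dose log2 fold-change; the significance call is log2FC > 2 in all
required replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: canonical columns of a CompetitionTable (long format)
COMPETITION_COLUMNS = [
    "protein_id",
    "replicate",
    "channel",
    "dose",
    "log2_ratio",
    "unique_peptides",
]

#: iTRAQ 4-plex channel -> free-compound dose (molar)
DEFAULT_CHANNELS = {
    "vehicle": 0.0,
    "low": 8e-6,
    "mid": 80e-6,
    "high": 800e-6,
}

DEFAULT_THRESHOLD = 2.0


def read_competition_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a CompetitionTable TSV (columns :data:`COMPETITION_COLUMNS`)."""
    table = pd.read_csv(path, sep=sep)
    missing = [c for c in COMPETITION_COLUMNS if c not in table.columns]
    if missing:
        from .errors import MissingColumnError

        raise MissingColumnError(missing[0], list(table.columns))
    if table.empty:
        from .errors import EmptyTableError

        raise EmptyTableError(f"{path} contains no data rows")
    return table


def median_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Median-normalize log2 fold-changes per (channel, replicate).

    Proteins not quantified in all channels of every replicate are dropped
    first (the complete-cases rule), then the per-channel median across
    proteins is subtracted, making every channel's median exactly 0.
    Idempotent.
    """
    out = table.dropna(subset=["log2_ratio"]).copy()
    n_samples = out[["channel", "replicate"]].drop_duplicates().shape[0]
    counts = out.groupby("protein_id")[["channel"]].size()
    complete = counts.index[counts == n_samples]
    out = out[out["protein_id"].isin(complete)].copy()
    out["log2_ratio"] = out["log2_ratio"] - out.groupby(["channel", "replicate"])[
        "log2_ratio"
    ].transform("median")
    return out.reset_index(drop=True)


def rank_targets(
    table: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    replicates_required: str = "all",
) -> pd.DataFrame:
    """Rank proteins by competition at the highest free-compound dose.

    Parameters
    ----------
    table
        A median-normalized CompetitionTable.
    threshold
        Significance cut on the highest-dose log2 fold-change (default 2).
    replicates_required
        ``"all"``: every replicate must exceed the threshold (default);
        ``"any"``: one suffices.

    Returns
    -------
    pandas.DataFrame
        One row per protein ordered by the minimum-across-replicates
        highest-dose log2FC, descending, with columns ``protein_id``,
        ``min_log2_fc``, ``max_log2_fc``, ``unique_peptides``,
        ``significant``.
    """
    if replicates_required not in {"all", "any"}:
        raise ValueError(
            f"replicates_required must be 'all' or 'any', got {replicates_required!r}"
        )
    high_dose = table["dose"].max()
    high = table[table["dose"] == high_dose]
    per_protein = high.groupby("protein_id").agg(
        min_log2_fc=("log2_ratio", "min"),
        max_log2_fc=("log2_ratio", "max"),
        unique_peptides=("unique_peptides", "max"),
    )
    if replicates_required == "all":
        per_protein["significant"] = per_protein["min_log2_fc"] > threshold
    else:
        per_protein["significant"] = per_protein["max_log2_fc"] > threshold
    out = (
        per_protein.sort_values(
            ["min_log2_fc", "protein_id"], ascending=[False, True]
        )
        .reset_index()
    )
    return out
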