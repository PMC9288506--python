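"""End-to-end orchestration: report -> candidates -> fits -> ranking -> site.

``run_site_prediction`` chains the differential screen, 4PL fitting/ranking
and structure mapping with the published default thresholds (q < 0.01,
|log2FC| > 0.46, R^2 > 0.9, top 3 peptides), writes every intermediate
table, and logs a machine-parseable count summary per stage.
``run_competition`` does the same for the pulldown ranking.  Both are
deterministic given identical inputs and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import pandas as pd

from . import competition as comp
from . import differential as diff
from . import dose_response as dr
from . import quant_io
from . import structure_mapping as smap
from .doses import DoseSeries
from .errors import ConfigError, StageError

log = logging.getLogger("lipsite")


@dataclass
class PipelineConfig:
    """All knobs of the site-prediction and competition pipelines.

    Defaults are the published analysis values: q < 0.01, |log2FC| > 0.46,
    R^2 > 0.9, top k = 3 peptides, competition threshold log2FC > 2.
    """

    quant_path: str | None = None
    structure_path: str | None = None
    competition_path: str | None = None
    out_prefix: str = "lipsite_out"
    chain_id: str | None = None           # None: first chain holding all top peptides
    q_threshold: float = 0.01
    fc_threshold: float = 0.46
    r2_threshold: float = 0.9
    k: int = 3
    neighbor_radius: float = 10.0
    weighting: str = "mass"
    comparison_doses: tuple[float, ...] = diff.DEFAULT_COMPARISON_DOSES
    vehicle_dose: float = 0.0
    candidate_rule: str = "any"           # any | all comparisons must pass
    fdr_scope: str = "per_comparison"     # per_comparison | global
    il_equivalent: bool = False
    deduplicate_atoms: bool = True
    competition_threshold: float = 2.0
    replicates_required: str = "all"
    seed: int = 0
    column_map: dict = field(default_factory=dict)

    def validate(self) -> "PipelineConfig":
        if self.k < 1:
            raise ConfigError(f"k must be >= 1, got {self.k}")
        for name in ("q_threshold", "fc_threshold", "r2_threshold",
                     "neighbor_radius", "competition_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.weighting not in {"mass", "geometric"}:
            raise ConfigError(f"weighting must be 'mass' or 'geometric'")
        return self


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat ``key = value`` config file ('#' starts a comment)."""
    known = {f.name: f for f in fields(PipelineConfig)}
    kwargs = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = (s.strip() for s in line.partition("="))
        if key not in known:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        kwargs[key] = _coerce(key, value)
    return PipelineConfig(**kwargs).validate()


def _coerce(key: str, value: str):
    if key in {"k", "seed"}:
        return int(value)
    if key in {"q_threshold", "fc_threshold", "r2_threshold", "neighbor_radius",
               "competition_threshold", "vehicle_dose"}:
        return float(value)
    if key in {"il_equivalent", "deduplicate_atoms"}:
        return value.lower() in {"1", "true", "yes"}
    if key == "comparison_doses":
        return tuple(float(v) for v in value.split(","))
    return value


def _stage(name: str, counts: dict):
    summary = " ".join(f"{k}={v}" for k, v in counts.items())
    log.info("stage=%s %s", name, summary)


@dataclass
class SiteRunResult:
    """Everything the site pipeline produced."""

    prediction: smap.BindingSitePrediction | None
    differential: pd.DataFrame
    candidates: set
    ranking_table: pd.DataFrame
    top: dr.TopSelection | None
    counts: dict
    outputs: dict


class NoCandidatesError(StageError):
    """The differential screen produced zero candidates; the differential
    table is still written before this is raised."""

    def __init__(self):
        Exception.__init__(self, "differential screen produced zero candidate peptides")
        self.stage = "differential"


def run_site_prediction(
    config: PipelineConfig,
    quant: pd.DataFrame | None = None,
    structure: quant_io.StructureModel | None = None,
    dose_series: DoseSeries | None = None,
    write_outputs: bool = True,
) -> SiteRunResult:
    """Run the full binding-site pipeline.

    ``quant``/``structure`` may be passed in memory (as from the synthetic
    generator); otherwise they are read from the configured paths.
    """
    config.validate()
    outputs: dict[str, Path] = {}
    prefix = Path(config.out_prefix)
    if write_outputs:
        prefix.parent.mkdir(parents=True, exist_ok=True)

    try:
        if quant is None:
            quant = quant_io.read_peptide_report(
                config.quant_path, column_map=config.column_map or None
            )
        if structure is None:
            structure = quant_io.read_structure(config.structure_path)
    except Exception as exc:
        raise StageError("input", exc) from exc

    counts = {"peptides_read": int(quant["modified_sequence"].nunique())}
    _stage("input", counts)

    # --- differential screen -------------------------------------------
    try:
        centered = diff.median_center(quant)
        differential = diff.differential_table(
            centered,
            comparison_doses=config.comparison_doses,
            vehicle=config.vehicle_dose,
            q_threshold=config.q_threshold,
            fc_threshold=config.fc_threshold,
            fdr_scope=config.fdr_scope,
        )
        candidates = diff.filter_candidates(
            differential,
            q_threshold=config.q_threshold,
            fc_threshold=config.fc_threshold,
            rule=config.candidate_rule,
        )
    except Exception as exc:
        raise StageError("differential", exc) from exc
    if write_outputs:
        p = prefix.with_name(prefix.name + "_differential.tsv")
        differential.to_csv(p, sep="\t", index=False)
        outputs["differential"] = p
    counts["candidates"] = len(candidates)
    _stage("differential", {"candidates": len(candidates)})
    if not candidates:
        raise NoCandidatesError()

    # --- dose-response fitting ------------------------------------------
    try:
        fits = dr.fit_all(centered, peptides=sorted(candidates))
        ranking = dr.rank_peptides(fits, r2_threshold=config.r2_threshold)
        ranking_table = dr.fits_to_frame(ranking)
        top = dr.select_top(ranking, k=config.k)
    except Exception as exc:
        raise StageError("dose_response", exc) from exc
    if write_outputs:
        p = prefix.with_name(prefix.name + "_fits.tsv")
        ranking_table.to_csv(p, sep="\t", index=False)
        outputs["fits"] = p
    counts["fits_converged"] = int(sum(f.converged for f in fits))
    counts["above_r2_threshold"] = int(sum(flag for _, flag in ranking))
    counts["top_k"] = len(top.fits)
    _stage(
        "dose_response",
        {
            "fits_converged": counts["fits_converged"],
            "above_r2_threshold": counts["above_r2_threshold"],
            "top_k": counts["top_k"],
        },
    )

    # --- structure mapping / site triangulation --------------------------
    try:
        chain_id = config.chain_id or _chain_holding_all(structure, top.peptides)
        mappings = []
        for fit in top.fits:
            m = smap.map_peptide_to_structure(
                fit.peptide, structure, chain_id, il_equivalent=config.il_equivalent
            )
            m = replace(m, r_squared=fit.r_squared, ec50=fit.ec50)
            mappings.append(m)
        prediction = smap.predict_binding_site(
            mappings,
            structure,
            weighting=config.weighting,
            neighbor_radius=config.neighbor_radius,
            deduplicate=config.deduplicate_atoms,
        )
    except Exception as exc:
        raise StageError("structure_mapping", exc) from exc
    counts["atoms_pooled"] = prediction.atom_count
    _stage("structure_mapping", {"atoms_pooled": prediction.atom_count})

    if write_outputs:
        tsv, pdb = quant_io.write_site_outputs(prediction, prefix, structure=structure)
        outputs["site_tsv"], outputs["site_pdb"] = tsv, pdb

    return SiteRunResult(
        prediction=prediction,
        differential=differential,
        candidates=candidates,
        ranking_table=ranking_table,
        top=top,
        counts=counts,
        outputs=outputs,
    )


def _chain_holding_all(structure: quant_io.StructureModel, peptides) -> str:
    """Default chain choice: the first chain whose sequence contains every
    top peptide exactly."""
    for chain_id in structure.chain_ids:
        seq = structure.chain_sequence(chain_id)
        if all(p in seq for p in peptides):
            return chain_id
    raise ValueError(
        f"no chain contains all top peptides {list(peptides)}; pass chain_id explicitly"
    )


@dataclass
class CompetitionRunResult:
    ranking: pd.DataFrame
    counts: dict
    outputs: dict


def run_competition(
    config: PipelineConfig, table: pd.DataFrame | None = None, write_outputs: bool = True
) -> CompetitionRunResult:
    """Median-normalize a competition table and rank candidate targets."""
    config.validate()
    outputs = {}
    try:
        if table is None:
            table = comp.read_competition_table(config.competition_path)
    except Exception as exc:
        raise StageError("input", exc) from exc
    try:
        normalized = comp.median_normalize(table)
        ranking = comp.rank_targets(
            normalized,
            threshold=config.competition_threshold,
            replicates_required=config.replicates_required,
        )
    except Exception as exc:
        raise StageError("competition", exc) from exc
    counts = {
        "proteins_in": int(table["protein_id"].nunique()),
        "proteins_complete": int(normalized["protein_id"].nunique()),
        "significant": int(ranking["significant"].sum()),
    }
    _stage("competition", counts)
    if write_outputs:
        prefix = Path(config.out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        p = prefix.with_name(prefix.name + "_targets.tsv")
        ranking.to_csv(p, sep="\t", index=False)
        outputs["targets"] = p
    return CompetitionRunResult(ranking=ranking, counts=counts, outputs=outputs)
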