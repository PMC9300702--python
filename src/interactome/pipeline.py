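"""End-to-end orchestration: configuration, the full interactome run, assays.

``run_pipeline`` executes the in-memory analysis chain
filter -> log2 -> impute -> ratios -> t-test -> BH -> call -> background-flag
-> classify -> partition -> category enrichment; ``run_interactome`` wraps
it with file I/O (TSV/GMT in, TSV + JSON report out).  All randomness flows
from the single config seed, and output tables are sorted by protein ID so
equal-seed runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, assays, lfq, simulate
from .matrix import CONTROL, ENDOSOMAL, SURFACE, IntensityMatrix, load_intensity_table

__all__ = ["RunConfig", "RunReport", "PipelineResult", "run_pipeline", "run_interactome",
           "estimate_frap_reduction", "estimate_internalization_reduction",
           "estimate_flux_reduction", "run_assays"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one interactome run."""

    matrix_path: str
    annotations_path: str | None = None
    background_path: str | None = None
    categories_path: str | None = None
    out_dir: str = "out"
    dialect: str = "plain"
    imputation: lfq.ImputationParams = field(default_factory=lfq.ImputationParams)
    calling: lfq.CallingParams = field(default_factory=lfq.CallingParams)
    enrichment_fdr: float = 0.05
    background_flag_threshold: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        imput = lfq.ImputationParams(**raw.pop("imputation", {}))
        calling = lfq.CallingParams(**raw.pop("calling", {}))
        return cls(imputation=imput, calling=calling, **raw)


@dataclass
class RunReport:
    counts: dict
    params: dict
    seed: int
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    matrix_filtered: IntensityMatrix
    matrix_imputed: IntensityMatrix
    enrichment: pd.DataFrame
    volcano: pd.DataFrame
    sets: annotate.InteractomeSets
    transmembrane: set[str]
    endosome_located: set[str]
    chord_table: pd.DataFrame
    category_enrichment: pd.DataFrame
    report: RunReport


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(
    matrix: IntensityMatrix,
    *,
    annotations: dict[str, annotate.AnnotationRecord] | None = None,
    background: lfq.BackgroundFrequencyTable | None = None,
    categories: dict[str, set[str]] | None = None,
    calling: lfq.CallingParams | None = None,
    imputation: lfq.ImputationParams | None = None,
    enrichment_fdr: float = 0.05,
    seed: int = 0,
) -> PipelineResult:
    """Run the full statistical + classification chain in memory."""
    calling = calling or lfq.CallingParams()
    imputation = imputation or dataclasses.replace(lfq.ImputationParams(), seed=seed)
    warnings: list[str] = []

    filtered = _stage("filter_by_valid_values")(lfq.filter_by_valid_values)(matrix, calling)
    logged = _stage("log2_transform")(lfq.log2_transform)(filtered)
    imputed = _stage("impute_downshifted_normal")(lfq.impute_downshifted_normal)(
        logged, imputation
    )
    table = _stage("enrichment_table")(lfq.build_enrichment_table)(imputed, calling)
    table = _stage("call_interactors")(lfq.call_interactors)(table, calling)
    if background is not None:
        table = _stage("flag_background")(lfq.flag_background)(table, background)
    table = table.sort_values(["compartment", "protein_id"], kind="stable").reset_index(drop=True)
    volcano = lfq.export_volcano(table)

    called = table[table["interactor"]]
    surface_ids = sorted(called.loc[called["compartment"] == SURFACE, "protein_id"])
    endo_ids = sorted(called.loc[called["compartment"] == ENDOSOMAL, "protein_id"])
    sets = _stage("partition_sets")(annotate.partition_sets)(surface_ids, endo_ids)

    transmembrane: set[str] = set()
    endosome_located: set[str] = set()
    chord = pd.DataFrame(columns=["protein_id", "group"])
    cat_result = pd.DataFrame(columns=["category", "category_size", "overlap", "p", "q",
                                       "significant"])
    if annotations is not None:
        union_records = [
            annotations.get(pid, annotate.AnnotationRecord(protein_id=pid))
            for pid in sorted(sets.union)
        ]
        n_unannotated = sum(1 for r in union_records if not r.topology and not r.locations)
        if n_unannotated:
            warnings.append(f"{n_unannotated} called interactors have no annotation record")
        transmembrane = _stage("classify_transmembrane")(annotate.classify_transmembrane)(
            union_records
        )
        endosome_located = _stage("classify_endosomal")(annotate.classify_endosomal)(
            union_records
        )
        tm_records = [r for r in union_records if r.protein_id in transmembrane]
        chord = _stage("group_membrane_locations")(annotate.group_membrane_locations)(tm_records)
        if categories:
            # KEGG-style enrichment of the interactors remaining after the
            # transmembrane and endosome-located branches are removed.
            remaining = sets.union - (transmembrane | endosome_located)
            universe = set(imputed.protein_ids)
            if remaining:
                cat_result = _stage("hypergeometric_enrichment")(
                    annotate.hypergeometric_enrichment
                )(remaining, categories, universe, fdr=enrichment_fdr)
            else:
                warnings.append("no interactors remain after excluding transmembrane/endosomal")

    degenerate = int(table["degenerate"].sum())
    if degenerate:
        warnings.append(f"{degenerate} protein/compartment tests had zero ratio SD")

    report = RunReport(
        counts={
            "proteins_input": int(len(matrix.protein_ids)),
            "proteins_after_filter": int(len(filtered.protein_ids)),
            "interactors_surface": len(sets.surface),
            "interactors_endosomal": len(sets.endosomal),
            "interactors_shared": len(sets.shared),
            "interactors_union": len(sets.union),
            "transmembrane": len(transmembrane),
            "endosome_located": len(endosome_located),
        },
        params={
            "calling": dataclasses.asdict(calling),
            "imputation": dataclasses.asdict(imputation),
            "enrichment_fdr": enrichment_fdr,
        },
        seed=seed,
        warnings=warnings,
    )
    return PipelineResult(
        matrix_filtered=filtered,
        matrix_imputed=imputed,
        enrichment=table,
        volcano=volcano,
        sets=sets,
        transmembrane=transmembrane,
        endosome_located=endosome_located,
        chord_table=chord,
        category_enrichment=cat_result,
        report=report,
    )


def run_interactome(config: RunConfig) -> RunReport:
    """File-based end-to-end run; writes all tables plus a JSON report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = load_intensity_table(config.matrix_path, dialect=config.dialect)
    annotations = (
        annotate.load_annotations(config.annotations_path) if config.annotations_path else None
    )
    background = (
        lfq.BackgroundFrequencyTable.from_tsv(
            config.background_path, flag_threshold=config.background_flag_threshold
        )
        if config.background_path
        else None
    )
    categories = annotate.read_gmt(config.categories_path) if config.categories_path else None
    imputation = dataclasses.replace(config.imputation, seed=config.seed)

    result = run_pipeline(
        matrix,
        annotations=annotations,
        background=background,
        categories=categories,
        calling=config.calling,
        imputation=imputation,
        enrichment_fdr=config.enrichment_fdr,
        seed=config.seed,
    )

    result.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False, na_rep="NA",
                             float_format="%.10g")
    result.volcano.to_csv(out / "volcano.tsv", sep="\t", index=False, na_rep="NA",
                          float_format="%.10g")
    for name, ids in (
        ("surface", result.sets.surface),
        ("endosomal", result.sets.endosomal),
        ("shared", result.sets.shared),
    ):
        (out / f"interactors_{name}.txt").write_text(
            "".join(f"{pid}\n" for pid in sorted(ids)), encoding="utf-8"
        )
    result.chord_table.sort_values(["protein_id", "group"]).to_csv(
        out / "chord_table.tsv", sep="\t", index=False
    )
    result.category_enrichment.to_csv(out / "category_enrichment.tsv", sep="\t", index=False,
                                      float_format="%.10g")
    result.report.to_json(out / "report.json")
    return result.report


# ---------------------------------------------------------------------------
# assay orchestration


def estimate_frap_reduction(
    ctrl: simulate.FrapScenario, treat: simulate.FrapScenario
) -> assays.PercentChange:
    """Simulate both FRAP conditions and estimate the mobile-fraction reduction.

    Per-cell mobile fractions are averaged per condition; the percent change
    carries a delta-method SE from the two across-cell SEMs.
    """
    estimates = []
    for scenario, cond in ((ctrl, "ctrl"), (treat, "treat")):
        traces = simulate.simulate_frap(scenario, condition=cond)
        mfs = np.array([assays.mobile_fraction(t).value for t in traces])
        estimates.append((mfs.mean(), mfs.std(ddof=1) / np.sqrt(len(mfs))))
    (m_c, se_c), (m_t, se_t) = estimates
    return assays.percent_change(m_c, m_t, ctrl_se=se_c, treat_se=se_t)


def estimate_internalization_reduction(
    scenario: simulate.AssayScenario,
) -> assays.PercentChange:
    """Simulate paired ELISA plates and estimate the internalization reduction."""
    (plate_ctrl, plate_treat), _ = simulate.simulate_assays(scenario)
    est_c = assays.internalization_percent(plate_ctrl)
    est_t = assays.internalization_percent(plate_treat)
    return assays.percent_change(est_c.value, est_t.value, ctrl_se=est_c.se, treat_se=est_t.se)


def estimate_flux_reduction(scenario: simulate.AssayScenario) -> assays.PercentChange:
    """Simulate paired permeability timecourses and compare through-origin slopes."""
    _, (tc_ctrl, tc_treat) = simulate.simulate_assays(scenario)
    slope_c = assays.permeability_flux(tc_ctrl).slope_per_h
    slope_t = assays.permeability_flux(tc_treat).slope_per_h
    return assays.percent_change(slope_c, slope_t)


def run_assays(name: str, seed: int = 0) -> dict[str, float]:
    """Dispatch a shipped paired scenario to its estimator; returns a summary."""
    pair = simulate.paired_scenarios(name, seed)
    if isinstance(pair, tuple) and isinstance(pair[0], simulate.FrapScenario):
        change = estimate_frap_reduction(*pair)
        kind = "frap_mobile_fraction"
    else:
        change = estimate_internalization_reduction(pair)
        kind = "internalization_percent"
    return {"scenario": name, "kind": kind, "percent_reduction": change.value,
            "se": change.se, "seed": seed}
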