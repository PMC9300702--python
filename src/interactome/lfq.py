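"""Label-free-quantification interactor calling against an unlabeled control.

Implements the Perseus-style AP-MS workflow: replicate-validity filtering,
log2 scaling, missing-not-at-random imputation from a downshifted normal,
per-replicate log2 ratios versus the control pull-down, a one-sample t-test
per protein, Benjamini–Hochberg q-values, threshold calling (fold change and
raw p), and contaminant-repository background flagging.

The enrichment table is a tidy DataFrame with one row per protein per
compartment and columns::

    protein_id  compartment  mean_log2_ratio  t  p  q  degenerate
    interactor  background_flag
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .matrix import CONTROL, ENDOSOMAL, SURFACE, IntensityMatrix

__all__ = [
    "ImputationParams",
    "CallingParams",
    "BackgroundFrequencyTable",
    "filter_by_valid_values",
    "log2_transform",
    "impute_downshifted_normal",
    "compute_ratios",
    "one_sample_ttest",
    "bh_fdr",
    "build_enrichment_table",
    "call_interactors",
    "flag_background",
    "export_volcano",
]

logger = logging.getLogger(__name__)

COMPARTMENTS = (SURFACE, ENDOSOMAL)


@dataclass(frozen=True)
class ImputationParams:
    """Downshifted-normal imputation settings.

    Missing values in a sample column are drawn from
    Normal(mu - downshift * sigma, (width * sigma)^2) where mu and sigma are
    the mean and SD of the column's *observed* values — the standard
    left-censored (MNAR) imputation for LFQ data.
    """

    width: float = 0.3
    downshift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("imputation width must be > 0")
        if self.downshift < 0:
            raise ValueError("imputation downshift must be >= 0")


@dataclass(frozen=True)
class CallingParams:
    """Interactor-calling thresholds.

    A protein is called an interactor in a compartment when its mean fold
    change over the control is at least ``fc_threshold`` (inclusive) and its
    raw one-sample-t p value is below ``p_threshold`` (strict).
    """

    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    min_valid: int = 3
    n_replicates: int = 4
    paired: bool = True
    use_q: bool = False

    def __post_init__(self) -> None:
        if not self.fc_threshold > 1:
            raise ValueError("fc_threshold must be > 1")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.min_valid > self.n_replicates:
            raise ValueError("min_valid cannot exceed n_replicates")

    @property
    def log2_fc_threshold(self) -> float:
        return float(np.log2(self.fc_threshold))


@dataclass
class BackgroundFrequencyTable:
    """Contaminant-repository detection frequencies (CRAPome-style).

    ``frequencies`` maps protein ID to the fraction of repository negative
    control runs in which the protein was detected.  Proteins at or above
    ``flag_threshold`` are flagged as probable background; the flag is an
    annotation only and never removes a called interactor.
    """

    frequencies: pd.Series
    flag_threshold: float = 0.5

    def __post_init__(self) -> None:
        freq = pd.Series(self.frequencies, dtype=float)
        if ((freq < 0) | (freq > 1)).any():
            raise ValueError("background frequencies must lie in [0, 1]")
        self.frequencies = freq

    @classmethod
    def from_tsv(cls, path: str | Path, flag_threshold: float = 0.5) -> "BackgroundFrequencyTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(frequencies=df.iloc[:, 0], flag_threshold=flag_threshold)


# ---------------------------------------------------------------------------
# matrix-level operations


def filter_by_valid_values(m: IntensityMatrix, params: CallingParams) -> IntensityMatrix:
    """Keep proteins quantified in >= ``min_valid`` replicates of >= 1 group."""
    if len(m.protein_ids) < 1:
        raise ValueError("matrix has no proteins")
    keep = np.zeros(len(m.protein_ids), dtype=bool)
    for group in m.groups:
        cols = m.columns_for(group)
        if params.min_valid > len(cols):
            raise ValueError(
                f"min_valid={params.min_valid} exceeds the {len(cols)} replicates of group {group!r}"
            )
        keep |= m.values[cols].notna().sum(axis=1).to_numpy() >= params.min_valid
    return m.copy_with(m.values.loc[keep])


def log2_transform(m: IntensityMatrix) -> IntensityMatrix:
    """Log2-scale a linear matrix; missingness is untouched."""
    if m.scale != "linear":
        raise ValueError("matrix is already on the log2 scale")
    vals = m.values.to_numpy(dtype=float)
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"nonpositive intensity for protein {m.protein_ids[i]!r} "
            f"in sample {m.values.columns[j]!r}"
        )
    return m.copy_with(pd.DataFrame(np.log2(vals), index=m.values.index, columns=m.values.columns),
                       scale="log2")


def impute_downshifted_normal(m: IntensityMatrix, p: ImputationParams) -> IntensityMatrix:
    """Replace missing values column-wise from the downshifted normal.

    Perseus-style: the imputation distribution is computed per sample column
    from that column's observed values.  Observed cells are unchanged.
    Deterministic for a fixed seed.
    """
    if m.scale != "log2":
        raise ValueError("imputation requires a log2-scaled matrix")
    rng = np.random.default_rng(p.seed)
    out = m.values.copy()
    for col in out.columns:
        observed = out[col].dropna()
        n_missing = int(out[col].isna().sum())
        if n_missing == 0:
            continue
        if len(observed) < 2:
            raise ValueError(f"column {col!r} has fewer than 2 observed values; SD undefined")
        mu = float(observed.mean())
        sigma = float(observed.std(ddof=1))
        if sigma == 0.0:
            logger.warning("column %s has zero observed SD; imputing the constant %g", col, mu)
            draws = np.full(n_missing, mu)
        else:
            draws = rng.normal(mu - p.downshift * sigma, p.width * sigma, size=n_missing)
        out.loc[out[col].isna(), col] = draws
    return m.copy_with(out)


def compute_ratios(m: IntensityMatrix, compartment: str, *, paired: bool = True) -> pd.DataFrame:
    """Per-protein log2 ratios of a compartment over the control.

    With ``paired=True`` (default) replicate i of the compartment is divided
    by replicate i of the control — the experiments are paired biological
    replicates.  On the log2 scale the ratio is the difference of the two
    log2 intensities.  ``paired=False`` subtracts the control mean from every
    compartment replicate instead.
    """
    if m.scale != "log2":
        raise ValueError("ratios are computed on the log2 scale")
    if compartment not in m.groups:
        raise ValueError(f"compartment {compartment!r} absent from matrix groups {m.groups}")
    comp_cols = m.columns_for(compartment)
    ctrl_cols = m.columns_for(CONTROL)
    comp = m.values[comp_cols].to_numpy(dtype=float)
    ctrl = m.values[ctrl_cols].to_numpy(dtype=float)
    if paired:
        if len(comp_cols) != len(ctrl_cols):
            raise ValueError(
                f"paired ratios need equal replicate counts; "
                f"{compartment} has {len(comp_cols)}, control has {len(ctrl_cols)}"
            )
        ratios = comp - ctrl
    else:
        ratios = comp - np.nanmean(ctrl, axis=1, keepdims=True)
    cols = [f"ratio_{i + 1}" for i in range(ratios.shape[1])]
    return pd.DataFrame(ratios, index=m.protein_ids, columns=cols)


# ---------------------------------------------------------------------------
# testing


def one_sample_ttest(ratios: pd.DataFrame) -> pd.DataFrame:
    """Two-sided one-sample t-test of the per-protein ratios against 0.

    Returns columns ``t``, ``p``, ``degenerate``.  Zero-SD rows are flagged
    degenerate: p = 0 when the mean differs from 0 (infinitely concentrated
    evidence), p = 1 when mean and SD are both 0.
    """
    x = ratios.to_numpy(dtype=float)
    n = x.shape[1]
    if n < 2:
        raise ValueError("one-sample t-test requires at least 2 ratios per protein")
    if np.isnan(x).any():
        raise ValueError("ratios contain missing values; impute before testing")
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    degenerate = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 1)
    degen_t = np.where(mean > 0, np.inf, np.where(mean < 0, -np.inf, 0.0))
    t = np.where(degenerate, degen_t, t)
    p = np.where(degenerate, np.where(mean == 0.0, 1.0, 0.0), p)
    return pd.DataFrame({"t": t, "p": p, "degenerate": degenerate}, index=ratios.index)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


# ---------------------------------------------------------------------------
# enrichment table


def build_enrichment_table(
    m: IntensityMatrix,
    params: CallingParams,
    compartments: tuple[str, ...] = COMPARTMENTS,
) -> pd.DataFrame:
    """Ratios + t-test + BH per compartment, stacked into one tidy table.

    BH correction is applied within each compartment across all tested
    proteins.  The ``interactor`` and ``background_flag`` columns are
    initialised False; use :func:`call_interactors` and
    :func:`flag_background`.
    """
    blocks = []
    for comp in compartments:
        ratios = compute_ratios(m, comp, paired=params.paired)
        stats = one_sample_ttest(ratios)
        block = pd.DataFrame(
            {
                "protein_id": ratios.index,
                "compartment": comp,
                "mean_log2_ratio": ratios.mean(axis=1).to_numpy(),
                "t": stats["t"].to_numpy(),
                "p": stats["p"].to_numpy(),
                "q": bh_fdr(stats["p"].to_numpy()),
                "degenerate": stats["degenerate"].to_numpy(),
            }
        )
        for i, col in enumerate(ratios.columns, start=1):
            block[f"ratio_{i}"] = ratios[col].to_numpy()
        blocks.append(block)
    table = pd.concat(blocks, ignore_index=True)
    table["interactor"] = False
    table["background_flag"] = False
    return table


def call_interactors(table: pd.DataFrame, params: CallingParams) -> pd.DataFrame:
    """Flag interactors: mean fold change >= threshold AND p below threshold.

    "At least" a 1.5-fold increase is inclusive; "p lower than" 0.05 is
    strict.  With ``params.use_q`` the BH q-value replaces the raw p in the
    significance condition.
    """
    out = table.copy()
    pcol = "q" if params.use_q else "p"
    out["interactor"] = (out["mean_log2_ratio"] >= params.log2_fc_threshold) & (
        out[pcol] < params.p_threshold
    )
    return out


def flag_background(table: pd.DataFrame, bg: BackgroundFrequencyTable) -> pd.DataFrame:
    """Annotate probable background binders; never changes the interactor flag.

    A protein is flagged when its repository detection frequency is at or
    above the table's threshold; proteins absent from the repository are
    unflagged.
    """
    out = table.copy()
    freq = out["protein_id"].map(bg.frequencies)
    out["background_flag"] = (freq >= bg.flag_threshold).fillna(False).to_numpy(dtype=bool)
    return out


def export_volcano(table: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot coordinates: x = mean log2 ratio, y = -log10 p, with flags."""
    with np.errstate(divide="ignore"):
        y = -np.log10(table["p"].to_numpy(dtype=float))
    return pd.DataFrame(
        {
            "protein_id": table["protein_id"],
            "compartment": table["compartment"],
            "log2_ratio": table["mean_log2_ratio"],
            "neg_log10_p": y,
            "interactor": table["interactor"],
            "background_flag": table["background_flag"],
        }
    )
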