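"""Protein-by-sample intensity matrix with group/replicate metadata.

The central container of the pipeline: rows are protein groups (one row per
protein identifier), columns are MS runs labeled ``<group>_<replicate>``
(e.g. ``surface_1`` ... ``control_4``).  Values are label-free quantification
(LFQ) intensities, either on the linear or the log2 scale; missing values
(proteins not quantified in a run) are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["IntensityMatrix", "load_intensity_table", "SURFACE", "ENDOSOMAL", "CONTROL"]

SURFACE = "surface"
ENDOSOMAL = "endosomal"
CONTROL = "control"

#: TSV dialect marker for missing values on disk.
NA_TOKEN = "NA"


def _parse_sample_name(name: str) -> tuple[str, int]:
    group, _, rep = name.rpartition("_")
    if not group:
        raise ValueError(f"sample column {name!r} is not of the form '<group>_<replicate>'")
    return group, int(rep)


@dataclass
class IntensityMatrix:
    """Proteins x samples intensities plus per-column (group, replicate) metadata.

    Parameters
    ----------
    values
        DataFrame indexed by unique protein IDs; columns are sample names.
        NaN encodes a missing (not quantified) intensity.
    sample_meta
        DataFrame indexed like ``values.columns`` with columns ``group`` and
        ``replicate``.  Built from the column names when omitted.
    scale
        ``"linear"`` or ``"log2"``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = None
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein IDs: {dups[:5]}")
        if self.sample_meta is None:
            parsed = [_parse_sample_name(c) for c in self.values.columns]
            self.sample_meta = pd.DataFrame(
                parsed, columns=["group", "replicate"], index=self.values.columns
            )
        else:
            self.sample_meta = self.sample_meta.loc[self.values.columns]
        for group, sub in self.sample_meta.groupby("group"):
            if sub["replicate"].duplicated().any():
                raise ValueError(f"duplicate replicate indices within group {group!r}")
        if self.scale == "log2":
            finite = np.isfinite(self.values.to_numpy(dtype=float))
            present = ~np.isnan(self.values.to_numpy(dtype=float))
            if not (finite | ~present).all():
                raise ValueError("log2 matrix contains non-finite present values")

    # -- metadata helpers ---------------------------------------------------

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.sample_meta["group"]:
            seen.setdefault(g, None)
        return list(seen)

    def columns_for(self, group: str) -> list[str]:
        """Column names of one group, ordered by replicate index."""
        sub = self.sample_meta[self.sample_meta["group"] == group]
        if sub.empty:
            raise KeyError(f"group {group!r} absent from sample metadata")
        return sub.sort_values("replicate").index.tolist()

    def n_replicates(self, group: str) -> int:
        return len(self.columns_for(group))

    def copy_with(self, values: pd.DataFrame, scale: str | None = None) -> "IntensityMatrix":
        return IntensityMatrix(
            values=values,
            sample_meta=self.sample_meta.loc[values.columns].copy(),
            scale=self.scale if scale is None else scale,
        )

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path: str | Path, *, id_column: str = "protein_id") -> None:
        """Write tab-separated, UTF-8, 'NA' for missing, first column protein ID."""
        out = self.values.copy()
        out.index.name = id_column
        out.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, *, scale: str = "linear") -> "IntensityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False)
        return cls(values=df.astype(float), scale=scale)


def load_intensity_table(
    path: str | Path,
    sample_map: Mapping[str, tuple[str, int]] | None = None,
    *,
    dialect: str = "plain",
    scale: str = "linear",
) -> IntensityMatrix:
    """Read an intensity TSV into an :class:`IntensityMatrix`.

    ``sample_map`` maps raw column names to (group, replicate); columns not in
    the map are dropped only if they carry no intensity data — an intensity
    column left unmapped is an error.  With ``sample_map=None`` columns must
    already be named ``<group>_<replicate>``.

    ``dialect="maxquant"`` treats 0 as missing, since MaxQuant writes LFQ
    intensity 0 for proteins not quantified in a run.
    """
    if dialect not in ("plain", "maxquant"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False)
    if sample_map is not None:
        missing = [c for c in df.columns if c not in sample_map]
        if missing:
            raise ValueError(f"intensity columns without a (group, replicate) mapping: {missing}")
        df = df.rename(columns={c: f"{g}_{r}" for c, (g, r) in sample_map.items()})
    df = df.astype(float)
    if dialect == "maxquant":
        df = df.replace(0.0, np.nan)
    return IntensityMatrix(values=df, scale=scale)
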