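"""Topology/location classification of interactors and category enrichment.

Classifies called interactors by UniProt-style membrane topology and
subcellular location, partitions the surface and endosomal interactor sets,
and tests gene-set (GMT) category enrichment with one-sided hypergeometric
tests and BH correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import scipy.stats

from .lfq import bh_fdr

__all__ = [
    "AnnotationRecord",
    "InteractomeSets",
    "load_annotations",
    "classify_transmembrane",
    "classify_endosomal",
    "group_membrane_locations",
    "partition_sets",
    "hypergeometric_enrichment",
    "read_gmt",
    "write_gmt",
]

logger = logging.getLogger(__name__)

#: UniProt topology terms defining the transmembrane class.
TRANSMEMBRANE_TERMS = (
    "single-pass type i membrane protein",
    "single-pass type ii membrane protein",
    "multi-pass membrane protein",
)

#: Subcellular-location categories defining the endosome-located class.
#: "cytoplasmic vesicle" matches both singular and plural annotation text.
ENDOSOMAL_TERMS = ("early endosome", "late endosome", "lysosome", "cytoplasmic vesicle")

#: Location groups used for the transmembrane chord export.  Order matters:
#: "cell membrane" and "cell junction" are matched before the bare
#: "membrane" term, which would otherwise swallow them as a substring.
MEMBRANE_GROUPS = ("Cell membrane", "Cell Junction", "Focal adhesion", "Membrane")


@dataclass(frozen=True)
class AnnotationRecord:
    """One protein's UniProt-style annotation.

    ``topology`` is the free-text Topology field; ``locations`` the set of
    subcellular-location strings.  All matching is case-insensitive substring
    matching after whitespace trimming, since UniProt free text varies
    ("Multi-pass membrane protein; Signal-anchor" etc.).
    """

    protein_id: str
    topology: str = ""
    locations: frozenset[str] = frozenset()

    def is_transmembrane(self) -> bool:
        topo = self.topology.strip().lower()
        if not topo:
            return False
        return any(term in topo for term in TRANSMEMBRANE_TERMS)

    def is_endosomal(self) -> bool:
        locs = [loc.strip().lower() for loc in self.locations]
        return any(term in loc for term in ENDOSOMAL_TERMS for loc in locs)


def load_annotations(path: str | Path) -> dict[str, AnnotationRecord]:
    """Read a TSV of (protein_id, topology, locations) with '|'-separated locations."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = {}
    for _, row in df.iterrows():
        locs = frozenset(s for s in str(row.iloc[2]).split("|") if s)
        records[row.iloc[0]] = AnnotationRecord(
            protein_id=row.iloc[0], topology=str(row.iloc[1]), locations=locs
        )
    return records


def classify_transmembrane(records: Iterable[AnnotationRecord]) -> set[str]:
    """Proteins whose topology names a single-pass (type I/II) or multi-pass TM protein."""
    out = set()
    for rec in records:
        if not rec.topology.strip():
            logger.warning("protein %s has no topology annotation; treated as non-transmembrane",
                           rec.protein_id)
            continue
        if rec.is_transmembrane():
            out.add(rec.protein_id)
    return out


def classify_endosomal(records: Iterable[AnnotationRecord]) -> set[str]:
    """Proteins located at early/late endosomes, lysosomes, or cytoplasmic vesicles."""
    out = set()
    for rec in records:
        if not rec.locations:
            logger.warning("protein %s has no subcellular-location annotation", rec.protein_id)
            continue
        if rec.is_endosomal():
            out.add(rec.protein_id)
    return out


def group_membrane_locations(records: Iterable[AnnotationRecord]) -> pd.DataFrame:
    """Long-format (protein, group) membership table for transmembrane proteins.

    A protein matching k of the membrane location groups yields k rows —
    multi-membership feeds the chord-diagram export.  Proteins matching no
    group are emitted once under "Other".
    """
    rows: list[tuple[str, str]] = []
    for rec in records:
        locs = [loc.strip().lower() for loc in rec.locations]
        matched = []
        for group in MEMBRANE_GROUPS:
            g = group.lower()
            if g == "membrane":
                # bare "Membrane" must not be satisfied by "cell membrane"
                hit = any(g in loc and "cell membrane" not in loc for loc in locs)
            else:
                hit = any(g in loc for loc in locs)
            if hit:
                matched.append(group)
        if not matched:
            logger.warning("transmembrane protein %s matches no membrane location group",
                           rec.protein_id)
            matched = ["Other"]
        rows.extend((rec.protein_id, g) for g in matched)
    return pd.DataFrame(rows, columns=["protein_id", "group"])


@dataclass(frozen=True)
class InteractomeSets:
    """Surface/endosomal interactor sets and their set algebra."""

    surface: frozenset[str]
    endosomal: frozenset[str]

    @property
    def shared(self) -> frozenset[str]:
        return self.surface & self.endosomal

    @property
    def union(self) -> frozenset[str]:
        return self.surface | self.endosomal

    def counts(self) -> dict[str, int]:
        return {
            "surface": len(self.surface),
            "endosomal": len(self.endosomal),
            "shared": len(self.shared),
            "union": len(self.union),
        }


def partition_sets(surface: Sequence[str], endosomal: Sequence[str]) -> InteractomeSets:
    """Exact set algebra over the two interactor lists (duplicates rejected)."""
    for name, ids in (("surface", surface), ("endosomal", endosomal)):
        ids = list(ids)
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate protein IDs in the {name} list")
    return InteractomeSets(surface=frozenset(surface), endosomal=frozenset(endosomal))


# ---------------------------------------------------------------------------
# category enrichment


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse GMT: one category per line, tab-separated name, description, members."""
    categories: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            categories[parts[0]] = {m for m in parts[2:] if m}
    return categories


def write_gmt(categories: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in categories.items():
            fh.write("\t".join([name, name, *sorted(members)]) + "\n")


def hypergeometric_enrichment(
    query: set[str],
    categories: Mapping[str, set[str]],
    universe: set[str],
    *,
    fdr: float = 0.05,
    min_category_size: int = 2,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per category.

    For a category with K members in the universe of size N and an overlap of
    k with the query of size n, p = P(X >= k) under Hypergeometric(N, K, n).
    Categories are intersected with the universe first; categories with fewer
    than ``min_category_size`` universe members are skipped as degenerate.
    BH correction is applied across the tested categories; ``significant``
    marks q < ``fdr``.
    """
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query set")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, members in categories.items():
        cat = members & universe
        K = len(cat)
        if K < min_category_size:
            continue
        k = len(cat & query)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"category": name, "category_size": K, "overlap": k, "p": min(p, 1.0)})
    result = pd.DataFrame(rows, columns=["category", "category_size", "overlap", "p"])
    if len(result):
        result["q"] = bh_fdr(result["p"].to_numpy())
        result["significant"] = result["q"] < fdr
        result = result.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        result["q"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result
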