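"""Reference-set enrichment and set-overlap utilities.

The background universe of every enrichment is the set of proteins detected
in the same screen — never a whole-proteome background — and the reference
set is intersected with it before testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .stats import fisher_exact_one_sided

__all__ = [
    "ReferenceSet",
    "read_reference_sets",
    "enrichment_against_reference",
    "venn_counts",
    "jaccard_index",
]


@dataclass(frozen=True)
class ReferenceSet:
    """A named set of protein ids, e.g. database interactors above a score
    cutoff (the published screens used score > 150)."""

    name: str
    members: frozenset[str]
    min_score: float | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"reference set {self.name!r} has no members")


def read_reference_sets(path: str | Path, min_score: float | None = None) -> dict[str, ReferenceSet]:
    """Load reference sets from a TSV with columns set_name, protein_id and
    optionally score; rows below ``min_score`` are dropped when given."""
    df = pd.read_csv(path, sep="\t")
    for col in ("set_name", "protein_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} is missing")
    if min_score is not None and "score" in df.columns:
        df = df[df["score"] > min_score]
    out = {}
    for name, sub in df.groupby("set_name"):
        out[str(name)] = ReferenceSet(
            str(name), frozenset(sub["protein_id"].astype(str)), min_score
        )
    return out


def enrichment_against_reference(
    hits: set[str], detected: set[str], reference: ReferenceSet
) -> tuple[tuple[int, int, int, int], float]:
    """One-sided Fisher enrichment of reference members among hits.

    The contingency table is built after intersecting the reference with the
    detected universe: a = |hits & ref|, b = |hits - ref|,
    c = |(detected - hits) & ref|, d = the remainder.
    """
    if not hits <= detected:
        raise ValueError("hits must be a subset of the detected universe")
    ref = set(reference.members) & detected
    a = len(hits & ref)
    b = len(hits - ref)
    c = len(ref - hits)
    d = len(detected) - a - b - c
    return (a, b, c, d), fisher_exact_one_sided(a, b, c, d)


def venn_counts(set_a: set, set_b: set) -> tuple[int, int, int]:
    """(only in A, shared, only in B) partition counts."""
    shared = len(set_a & set_b)
    return len(set_a) - shared, shared, len(set_b) - shared


def jaccard_index(set_a: set, set_b: set) -> float:
    """|A & B| / |A | B|; NaN (undefined) when both sets are empty."""
    union = set_a | set_b
    if not union:
        return math.nan
    return len(set_a & set_b) / len(union)
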