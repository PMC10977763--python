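"""Base composition and strand-asymmetry (skew) statistics.

Mitochondrial strands differ in their exposure to mutational pressure, which
leaves a compositional asymmetry commonly summarized by two statistics:

    AT-skew = (A - T) / (A + T)
    GC-skew = (G - C) / (G + C)

Both are dimensionless, lie in [-1, 1], are invariant to whether counts or
percentages are supplied, and change sign under reverse complementation.
This module computes per-region composition profiles (single genes, pooled
categories, or the whole genome) from an annotated sequence.  Per-gene
regions are sense-strand compositions: genes encoded on the L strand are
reverse-complemented before counting, and pooled categories concatenate
the sense sequences of their members.  The whole-genome region uses the
forward (H) strand as deposited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

from .annotation import MitogenomeAnnotation

Number = Union[int, float]


def at_skew(a: Number, t: Number) -> float:
    """(A - T) / (A + T); ``nan`` when A + T == 0 (flagged by the caller)."""
    if a < 0 or t < 0:
        raise ValueError("counts/percentages must be non-negative")
    if a + t == 0:
        return math.nan
    return (a - t) / (a + t)


def gc_skew(g: Number, c: Number) -> float:
    """(G - C) / (G + C); ``nan`` when G + C == 0."""
    if g < 0 or c < 0:
        raise ValueError("counts/percentages must be non-negative")
    if g + c == 0:
        return math.nan
    return (g - c) / (g + c)


@dataclass
class CompositionProfile:
    """Counts, percentages and skews for one named region."""

    region_name: str
    size: int                     # counted A+C+G+T (ambiguity codes excluded)
    counts: dict                  # base -> count for A, C, G, T
    ambiguous: int = 0            # N and other non-ACGT characters
    flags: list = field(default_factory=list)

    @property
    def percentages(self) -> dict:
        if self.size == 0:
            return {b: math.nan for b in "ACGT"}
        return {b: 100.0 * self.counts[b] / self.size for b in "ACGT"}

    @property
    def at_content(self) -> float:
        p = self.percentages
        return p["A"] + p["T"]

    @property
    def at_skew(self) -> float:
        return at_skew(self.counts["A"], self.counts["T"])

    @property
    def gc_skew(self) -> float:
        return gc_skew(self.counts["G"], self.counts["C"])

    def as_row(self) -> dict:
        """Report row with the conventional rounding: percentages to 2 d.p.,
        skews to 3 d.p.  Internal values stay at full precision."""
        p = self.percentages
        return {
            "region": self.region_name,
            "size": self.size,
            "a_pct": round(p["A"], 2), "t_pct": round(p["T"], 2),
            "g_pct": round(p["G"], 2), "c_pct": round(p["C"], 2),
            "at_pct": round(self.at_content, 2),
            "at_skew": round(self.at_skew, 3),
            "gc_skew": round(self.gc_skew, 3),
        }


def profile_sequence(seq: str, region_name: str = "sequence") -> CompositionProfile:
    """Count bases of a sequence; ambiguity codes are excluded from the four
    counts and reported separately."""
    s = seq.upper().replace("U", "T")
    counts = {b: s.count(b) for b in "ACGT"}
    size = sum(counts.values())
    ambiguous = len(s) - size
    flags = []
    if size == 0:
        flags.append("empty region: skews undefined")
    return CompositionProfile(region_name=region_name, size=size,
                              counts=counts, ambiguous=ambiguous, flags=flags)


def region_composition(annotation: MitogenomeAnnotation,
                       region_spec: str) -> CompositionProfile:
    """Composition profile for a gene, a pooled category or the whole genome.

    ``region_spec`` may be a normalized gene name (sense-strand composition),
    one of ``PCG``/``tRNA``/``rRNA`` (concatenated sense strands of all
    members) or ``genome`` (full forward strand).  Wrap-spanning genes are
    stitched across the origin, never truncated.
    """
    if annotation.sequence is None:
        raise ValueError("annotation carries no sequence")
    if region_spec == "genome":
        return profile_sequence(annotation.sequence, "genome")
    if region_spec in ("PCG", "tRNA", "rRNA"):
        members = annotation.genes_of(region_spec)
        if not members:
            raise KeyError(f"no genes of category {region_spec}")
        pooled = "".join(annotation.gene_sequence(g.name) for g in members)
        return profile_sequence(pooled, region_spec)
    names = [g.name for g in annotation.genes]
    if region_spec not in names:
        raise KeyError(f"unknown region {region_spec!r}")
    return profile_sequence(annotation.gene_sequence(region_spec), region_spec)


def composition_table(annotation: MitogenomeAnnotation,
                      per_gene: bool = True) -> "pandas.DataFrame":
    """Composition report in the conventional layout: whole genome first,
    then (optionally) each PCG, then pooled tRNAs, rRNAs and PCGs."""
    import pandas as pd

    rows = [region_composition(annotation, "genome").as_row()]
    if per_gene:
        for g in annotation.genes_of("PCG"):
            rows.append(region_composition(annotation, g.name).as_row())
    for cat in ("tRNA", "rRNA", "PCG"):
        if annotation.genes_of(cat):
            rows.append(region_composition(annotation, cat).as_row())
    return pd.DataFrame(rows)
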