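"""Codon usage statistics under the invertebrate mitochondrial genetic code.

Relative synonymous codon usage (RSCU) expresses how often a codon is used
relative to uniform usage within its synonymous family: for codon *i* in a
family *F* of codons encoding the same amino acid,

    RSCU_i = count_i * |F| / sum_{j in F} count_j

so RSCU averages to 1 within every family with observations.  Families are
defined by the genetic code; the invertebrate mitochondrial code (NCBI
translation table 5) is the default, with its characteristic 8-codon serine
family (UCN + AGN), UGA read as tryptophan, and UAA/UAG as the only
terminators — which are treated as one two-member family of their own so
stop-codon usage gets RSCU values too.  Codon counts are reported as RNA
codons (T read as U).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

from .annotation import MitogenomeAnnotation

_BASES = "UCAG"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


@dataclass(frozen=True)
class GeneticCode:
    """A translation table: codon->amino acid map plus synonymous families."""

    table_id: int
    codon_to_aa: Dict[str, str]        # RNA codons; '*' for terminators
    start_codons: tuple

    @classmethod
    def from_table(cls, table_id: int = 5) -> "GeneticCode":
        from Bio.Data import CodonTable

        tbl = CodonTable.unambiguous_rna_by_id[table_id]
        mapping = dict(tbl.forward_table)
        for stop in tbl.stop_codons:
            mapping[stop] = "*"
        starts = tuple(s.replace("T", "U") for s in tbl.start_codons)
        return cls(table_id=table_id, codon_to_aa=dict(mapping), start_codons=starts)

    @property
    def families(self) -> Dict[str, tuple]:
        """Partition of the 64 codons by encoded amino acid ('*' = stops)."""
        fams: Dict[str, list] = {}
        for codon in ALL_CODONS:
            fams.setdefault(self.codon_to_aa[codon], []).append(codon)
        return {aa: tuple(codons) for aa, codons in fams.items()}

    def family_of(self, codon: str) -> tuple:
        return self.families[self.codon_to_aa[as_rna(codon)]]

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[as_rna(codon)] == "*"


def as_rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


def as_dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# CDS extraction and codon counting
# ---------------------------------------------------------------------------

def extract_cds(annotation: MitogenomeAnnotation, gene: str) -> str:
    """In-frame sense-strand DNA of a protein-coding gene.

    L-strand genes are reverse-complemented; wrap-spanning genes are
    stitched across the origin.  A length not divisible by 3 drops the
    trailing remainder with a warning on the annotation.
    """
    rec = annotation.gene(gene)
    if rec.category != "PCG":
        raise ValueError(f"{gene} is not a protein-coding gene")
    seq = annotation.gene_sequence(gene)
    if len(seq) % 3:
        annotation.warn(f"{gene}: CDS length {len(seq)} not divisible by 3; "
                        f"dropping trailing {len(seq) % 3} nt")
        seq = seq[:len(seq) - len(seq) % 3]
    return seq.upper()


def start_stop_census(annotation: MitogenomeAnnotation,
                      code: Optional[GeneticCode] = None) -> List[dict]:
    """Per-PCG start/stop codon report.

    Codons are read from the sequence when the annotation carries one,
    otherwise the table's codon columns are trusted.  Non-canonical codons
    relative to the genetic code are flagged.
    """
    code = code or GeneticCode.from_table(5)
    pcgs = annotation.genes_of("PCG")
    if len(pcgs) < 13:
        annotation.warn(f"only {len(pcgs)} PCGs present (13 expected)")
    rows = []
    for g in pcgs:
        if annotation.sequence is not None:
            cds = extract_cds(annotation, g.name)
            start, stop = cds[:3], cds[-3:]
        else:
            start, stop = g.start_codon, g.stop_codon
        flags = []
        if start and as_rna(start) not in code.start_codons:
            flags.append("non-canonical start")
        if stop and not code.is_stop(stop):
            flags.append("non-canonical stop")
        rows.append({"gene": g.name, "start_codon": start, "stop_codon": stop,
                     "flags": flags})
    return rows


def count_codons(cds_set: Iterable[str]) -> Counter:
    """Codon counts (RNA alphabet) over a set of in-frame DNA/RNA strings,
    terminators included."""
    counts: Counter = Counter()
    for cds in cds_set:
        s = as_rna(cds)
        if len(s) % 3:
            raise ValueError("CDS length must be divisible by 3")
        for i in range(0, len(s), 3):
            counts[s[i:i + 3]] += 1
    return counts


# ---------------------------------------------------------------------------
# RSCU and codons-per-thousand
# ---------------------------------------------------------------------------

@dataclass
class CodonUsageTable:
    """Per-codon counts, RSCU and codons-per-thousand for one region."""

    counts: Dict[str, int]
    rscu: Dict[str, float]
    per_thousand: Dict[str, float]
    code: GeneticCode
    source: str = ""
    flags: list = field(default_factory=list)

    def as_dataframe(self) -> "pandas.DataFrame":
        import pandas as pd

        rows = [{"codon": c, "aa": self.code.codon_to_aa[c],
                 "count": float(self.counts.get(c, 0)),
                 "rscu": round(self.rscu[c], 2),
                 "per_thousand": round(self.per_thousand.get(c, 0.0), 2)}
                for c in ALL_CODONS]
        return pd.DataFrame(rows)


def rscu(counts: Dict[str, int],
         code: Optional[GeneticCode] = None,
         source: str = "") -> CodonUsageTable:
    """RSCU over any codon count map.

    Families with a zero total get RSCU 0 for every member and are flagged;
    uniform scaling of all counts leaves RSCU unchanged by construction.
    """
    code = code or GeneticCode.from_table(5)
    clean = {as_rna(c): n for c, n in counts.items()}
    for c, n in clean.items():
        if n < 0:
            raise ValueError(f"negative count for codon {c}")
        if c not in code.codon_to_aa:
            raise ValueError(f"not a codon: {c}")
    values: Dict[str, float] = {}
    flags = []
    for aa, family in code.families.items():
        total = sum(clean.get(c, 0) for c in family)
        if total == 0:
            for c in family:
                values[c] = 0.0
            flags.append(f"family {aa}: no observations, RSCU set to 0")
        else:
            for c in family:
                values[c] = clean.get(c, 0) * len(family) / total
    grand = sum(clean.values())
    per_thousand = ({c: 1000.0 * n / grand for c, n in clean.items()}
                    if grand else {})
    return CodonUsageTable(counts=clean, rscu=values, per_thousand=per_thousand,
                           code=code, source=source, flags=flags)


def codons_per_thousand(counts: Dict[str, int]) -> Dict[str, float]:
    """1000 * count / total for every codon in the map."""
    clean = {as_rna(c): n for c, n in counts.items()}
    total = sum(clean.values())
    if total <= 0:
        raise ValueError("empty codon counts")
    return {c: 1000.0 * n / total for c, n in clean.items()}


def codon_usage(annotation: MitogenomeAnnotation,
                code: Optional[GeneticCode] = None,
                source: str = "13 PCGs") -> CodonUsageTable:
    """Count codons over all PCGs of an annotated sequence and compute RSCU."""
    code = code or GeneticCode.from_table(5)
    cds_set = [extract_cds(annotation, g.name)
               for g in annotation.genes_of("PCG")]
    return rscu(count_codons(cds_set), code=code, source=source)


def plot_codon_usage(table: CodonUsageTable, path: str) -> None:
    """Bar-chart export of codons-per-thousand and RSCU (optional extra)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.as_dataframe().sort_values(["aa", "codon"])
    fig, axes = plt.subplots(2, 1, figsize=(14, 7), sharex=True)
    axes[0].bar(df["codon"], df["per_thousand"], color="#4878a8")
    axes[0].set_ylabel("codons per thousand")
    axes[1].bar(df["codon"], df["rscu"], color="#b85450")
    axes[1].set_ylabel("RSCU")
    axes[1].tick_params(axis="x", rotation=90, labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
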