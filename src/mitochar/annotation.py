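"""Reading, validation and accounting of circular mitogenome annotations.

A metazoan mitogenome is a closed-circular molecule of roughly 15-17 kb
carrying 37 canonical genes: 13 protein-coding genes (PCGs), 22 transfer
RNAs and 2 ribosomal RNAs.  This module parses annotations from either a
tab-separated gene table (columns: gene, strand, start, end, length,
start_codon, stop_codon, anticodon) or a GenBank flat file, normalizes the
notoriously inconsistent gene nomenclature (COI vs COX1, ND5 vs NAD5 ...)
to one canonical vocabulary, and computes the bookkeeping the downstream
statistics rely on: intergenic spacers, gene overlaps and the gene-content
census.

Coordinates are 1-based inclusive throughout, matching the convention of
published organization tables.  A gene whose ``end`` is smaller than its
``start`` wraps the origin of the circle.  Printed length columns are
cross-checked against the coordinates; the coordinates are authoritative
and any discrepancy is recorded as a warning on the annotation.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Canonical gene vocabulary
# ---------------------------------------------------------------------------

PCG_LABELS = (
    "COX1", "COX2", "COX3", "ATP6", "ATP8",
    "NAD1", "NAD2", "NAD3", "NAD4", "NAD4L", "NAD5", "NAD6", "CYTB",
)
RRNA_LABELS = ("rrnL", "rrnS")
TRNA_LABELS = tuple(
    "trn" + x
    for x in ("A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2",
              "M", "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y")
)
CANONICAL_LABELS = PCG_LABELS + RRNA_LABELS + TRNA_LABELS

#: three-letter to one-letter amino-acid codes used in tRNA names
_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# anticodons that disambiguate the duplicated Leu/Ser tRNAs
_LEU_SER_BY_ANTICODON = {
    ("L", "TAG"): "trnL1", ("L", "TAA"): "trnL2",
    ("S", "GCT"): "trnS1", ("S", "TGA"): "trnS2",
}

_PCG_SYNONYMS = {
    "COI": "COX1", "COII": "COX2", "COIII": "COX3",
    "CO1": "COX1", "CO2": "COX2", "CO3": "COX3",
    "COX1": "COX1", "COX2": "COX2", "COX3": "COX3",
    "ND1": "NAD1", "ND2": "NAD2", "ND3": "NAD3", "ND4": "NAD4",
    "ND4L": "NAD4L", "ND5": "NAD5", "ND6": "NAD6",
    "NAD1": "NAD1", "NAD2": "NAD2", "NAD3": "NAD3", "NAD4": "NAD4",
    "NAD4L": "NAD4L", "NAD5": "NAD5", "NAD6": "NAD6",
    "NADH1": "NAD1", "NADH2": "NAD2", "NADH3": "NAD3", "NADH4": "NAD4",
    "NADH4L": "NAD4L", "NADH5": "NAD5", "NADH6": "NAD6",
    "ATP6": "ATP6", "ATP8": "ATP8", "ATPASE6": "ATP6", "ATPASE8": "ATP8",
    "CYTB": "CYTB", "COB": "CYTB", "CYB": "CYTB", "CYTOCHROMEB": "CYTB",
}

_RRNA_SYNONYMS = {
    "RRNS": "rrnS", "RRNL": "rrnL",
    "12S": "rrnS", "16S": "rrnL",
    "12SRRNA": "rrnS", "16SRRNA": "rrnL",
    "12SRIBOSOMALRNA": "rrnS", "16SRIBOSOMALRNA": "rrnL",
    "SRRNA": "rrnS", "LRRNA": "rrnL",
    "SSU": "rrnS", "LSU": "rrnL",
}


def normalize_gene_name(raw: str, anticodon: Optional[str] = None) -> str:
    """Map a raw gene label to the canonical 37-label vocabulary.

    Handles the common synonym families (``COI``/``COX1``, ``ND5``/``NAD5``,
    ``NAD4l``/``ND4L``, ``12S rRNA``/``rrnS``, ``tRNA-Asp``/``trnD`` ...).
    For the duplicated leucine and serine tRNAs an explicit ``1``/``2``
    suffix is honoured; otherwise the ``anticodon`` (TAG/TAA for Leu,
    GCT/TGA for Ser) disambiguates.  Unknown labels pass through unchanged
    (callers flag them; normalization never fails).
    """
    label = raw.strip().strip("*")
    key = re.sub(r"[\s_\-^()\.]", "", label).upper()
    if key in _PCG_SYNONYMS:
        return _PCG_SYNONYMS[key]
    if key in _RRNA_SYNONYMS:
        return _RRNA_SYNONYMS[key]
    m = re.match(r"^TRNA?([A-Z]{1,3})([12]?)$", key)
    if m:
        aa, suffix = m.groups()
        one = _AA3_TO_1.get(aa, aa if len(aa) == 1 else None)
        if one is not None:
            if one in ("L", "S"):
                if suffix:
                    return f"trn{one}{suffix}"
                if anticodon:
                    hit = _LEU_SER_BY_ANTICODON.get(
                        (one, anticodon.upper().replace("U", "T")))
                    if hit:
                        return hit
                return f"trn{one}"  # ambiguous; caller flags
            if not suffix:
                return f"trn{one}"
    return label


def gene_category(label: str) -> str:
    """Category of a canonical label: ``PCG``, ``tRNA``, ``rRNA`` or ``other``."""
    if label in PCG_LABELS:
        return "PCG"
    if label in RRNA_LABELS:
        return "rRNA"
    if label in TRNA_LABELS or re.match(r"^trn[A-Z][12]?$", label):
        return "tRNA"
    return "other"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


def gene_span_length(start: int, end: int, genome_length: int) -> int:
    """Length of a 1-based inclusive span on a circle, wrap-aware."""
    if end >= start:
        return end - start + 1
    return (genome_length - start + 1) + end


@dataclass
class GeneRecord:
    """One annotated feature on the circular genome."""

    name: str
    category: str
    strand: str  # 'H' (forward/deposited strand) or 'L' (complement)
    start: int   # 1-based inclusive
    end: int     # 1-based inclusive; < start means the gene wraps the origin
    length: int
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    anticodon: Optional[str] = None
    flags: list = field(default_factory=list)

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def validate(self, genome_length: int) -> None:
        if self.strand not in ("H", "L"):
            raise AnnotationError(
                f"{self.name}: strand must be 'H' or 'L', got {self.strand!r}")
        if not (1 <= self.start <= genome_length and 1 <= self.end <= genome_length):
            raise AnnotationError(
                f"{self.name}: coordinates {self.start}..{self.end} exceed "
                f"genome length {genome_length}")
        expected = gene_span_length(self.start, self.end, genome_length)
        if self.length != expected:
            raise AnnotationError(
                f"{self.name}: stored length {self.length} does not match "
                f"coordinates {self.start}..{self.end} (expected {expected})")


@dataclass
class MitogenomeAnnotation:
    """A circular genome of stated length plus its ordered gene records."""

    genome_length: int
    genes: list  # of GeneRecord, sorted by (start, -length)
    circular: bool = True
    sequence: Optional[str] = None
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.genes = sorted(self.genes, key=lambda g: (g.start, -g.length))
        names = [g.name for g in self.genes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise AnnotationError(f"duplicate gene names: {sorted(dupes)}")
        for g in self.genes:
            g.validate(self.genome_length)
        if self.sequence is not None and len(self.sequence) != self.genome_length:
            raise AnnotationError(
                f"sequence length {len(self.sequence)} != genome length "
                f"{self.genome_length}")

    def gene(self, name: str) -> GeneRecord:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def genes_of(self, category: str) -> list:
        return [g for g in self.genes if g.category == category]

    def gene_sequence(self, name: str) -> str:
        """Sense-strand sequence of a gene (L-strand genes reverse-complemented),
        stitched across the origin for wrap-spanning genes."""
        if self.sequence is None:
            raise AnnotationError("annotation carries no sequence")
        g = self.gene(name)
        raw = slice_circular(self.sequence, g.start, g.end)
        return reverse_complement(raw) if g.strand == "L" else raw

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        logger.warning(message)


def slice_circular(sequence: str, start: int, end: int) -> str:
    """1-based inclusive slice of a circular sequence, wrap-aware, never truncated."""
    if end >= start:
        return sequence[start - 1:end]
    return sequence[start - 1:] + sequence[:end]


_COMPLEMENT = str.maketrans("ACGTacgtNnUu", "TGCAtgcaNnAa")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Gene table I/O
# ---------------------------------------------------------------------------

TABLE_COLUMNS = ("gene", "strand", "start", "end", "length",
                 "start_codon", "stop_codon", "anticodon")

_LENGTH_RE = re.compile(r"genome_length\s*=\s*(\d+)")


def parse_gene_table(table_text: str,
                     genome_length: Optional[int] = None) -> MitogenomeAnnotation:
    """Parse a tab-separated gene table into an annotation.

    The dialect has a required header row with the columns ``gene  strand
    start  end  length  start_codon  stop_codon  anticodon`` (the last four
    optional per row).  Lines starting with ``#`` are comments; a comment of
    the form ``genome_length=N`` supplies the circle length when the
    ``genome_length`` argument is omitted.  Gene names are normalized; the
    printed length column is cross-checked against the coordinates, which
    are authoritative.
    """
    header = None
    rows = []
    for lineno, line in enumerate(table_text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            if genome_length is None:
                m = _LENGTH_RE.search(stripped)
                if m:
                    genome_length = int(m.group(1))
            continue
        fields = [f.strip() for f in line.rstrip("\n").split("\t")]
        if header is None:
            header = [f.lower() for f in fields]
            if "gene" not in header or "start" not in header:
                raise AnnotationError(
                    "gene table must begin with a header row naming at least "
                    "'gene' and 'start' columns")
            continue
        rows.append((lineno, fields))
    if header is None or not rows:
        raise AnnotationError("empty gene table")
    if genome_length is None:
        raise AnnotationError(
            "genome_length not given and no 'genome_length=' comment found")

    idx = {name: header.index(name) for name in header}

    def cell(fields, col):
        i = idx.get(col)
        if i is None or i >= len(fields):
            return ""
        return fields[i]

    genes = []
    warnings: list = []
    for lineno, fields in rows:
        if len(fields) < 4:
            raise AnnotationError(f"row {lineno}: expected at least 4 columns, "
                                  f"got {len(fields)}: {fields!r}")
        raw_name = cell(fields, "gene")
        anticodon = cell(fields, "anticodon") or None
        name = normalize_gene_name(raw_name, anticodon=anticodon)
        try:
            start = int(cell(fields, "start"))
            end = int(cell(fields, "end"))
        except ValueError as exc:
            raise AnnotationError(f"row {lineno} ({raw_name}): bad coordinates") from exc
        if start < 1 or end < 1:
            raise AnnotationError(f"row {lineno} ({raw_name}): positions must be positive")
        if start > genome_length or end > genome_length:
            raise AnnotationError(
                f"row {lineno} ({raw_name}): coordinate exceeds genome length "
                f"{genome_length}")
        length = gene_span_length(start, end, genome_length)
        printed = cell(fields, "length")
        flags = []
        if printed:
            if int(printed) != length:
                warnings.append(
                    f"{name}: printed length {printed} != coordinate length "
                    f"{length}; using coordinates")
        if name not in CANONICAL_LABELS:
            flags.append("unrecognized gene name")
        category = gene_category(name)
        genes.append(GeneRecord(
            name=name, category=category,
            strand=cell(fields, "strand") or "H",
            start=start, end=end, length=length,
            start_codon=cell(fields, "start_codon") or None,
            stop_codon=cell(fields, "stop_codon") or None,
            anticodon=anticodon, flags=flags,
        ))

    ann = MitogenomeAnnotation(genome_length=genome_length, genes=genes)
    for w in warnings:
        ann.warn(w)
    return ann


def emit_gene_table(annotation: MitogenomeAnnotation) -> str:
    """Write an annotation back to the TSV gene-table dialect."""
    out = io.StringIO()
    out.write(f"# genome_length={annotation.genome_length}\n")
    out.write("\t".join(TABLE_COLUMNS) + "\n")
    for g in annotation.genes:
        out.write("\t".join([
            g.name, g.strand, str(g.start), str(g.end), str(g.length),
            g.start_codon or "", g.stop_codon or "", g.anticodon or "",
        ]) + "\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# GenBank I/O
# ---------------------------------------------------------------------------

def parse_genbank(source) -> MitogenomeAnnotation:
    """Read a GenBank flat file (path, file object or text) into an annotation.

    CDS features become PCG records (strand ``L`` for ``complement(...)``
    locations, the ``/anticodon`` and ``/codon_start`` qualifiers honoured),
    tRNA and rRNA features map to their categories, and any other feature
    type is ignored with a warning.  Start/stop codons are read from the
    record sequence when one is present.
    """
    from Bio import SeqIO

    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    record = SeqIO.read(source, "genbank")
    genome_length = len(record)
    if genome_length == 0:
        raise AnnotationError("GenBank record has no length (missing LOCUS length?)")
    seq = str(record.seq) if len(record.seq) else None
    has_seq = seq is not None and set(seq) <= set("ACGTNacgtn") and any(
        c in "ACGTacgt" for c in seq)

    genes = []
    warnings: list = []
    for feat in record.features:
        if feat.type in ("source", "gene", "D-loop", "misc_feature"):
            if feat.type in ("D-loop", "misc_feature"):
                warnings.append(f"ignoring non-gene feature of type {feat.type}")
            continue
        if feat.type not in ("CDS", "tRNA", "rRNA"):
            warnings.append(f"ignoring feature of unsupported type {feat.type}")
            continue
        quals = feat.qualifiers
        raw_name = (quals.get("gene") or quals.get("product") or ["?"])[0]
        anticodon = None
        if "anticodon" in quals:
            m = re.search(r"seq\s*:\s*([acgtu]{3})", quals["anticodon"][0], re.I)
            anticodon = (m.group(1) if m else quals["anticodon"][0])
            anticodon = anticodon.upper().replace("U", "T")
        name = normalize_gene_name(raw_name, anticodon=anticodon)

        parts = feat.location.parts
        strand = "L" if feat.location.strand == -1 else "H"
        if len(parts) == 1:
            start = int(parts[0].start) + 1
            end = int(parts[0].end)
        else:
            # join(a..N, 1..b): wrap-spanning gene
            ordered = sorted(parts, key=lambda p: int(p.start))
            start = int(ordered[-1].start) + 1
            end = int(ordered[0].end)
        length = gene_span_length(start, end, genome_length)

        start_codon = stop_codon = None
        category = gene_category(name)
        if feat.type == "CDS":
            category = "PCG" if category in ("PCG", "other") else category
            if has_seq:
                raw = slice_circular(seq, start, end)
                sense = reverse_complement(raw) if strand == "L" else raw
                offset = int(quals.get("codon_start", ["1"])[0]) - 1
                sense = sense[offset:]
                if len(sense) >= 3:
                    start_codon = sense[:3].upper()
                    tail = len(sense) - (len(sense) % 3 or 3)
                    stop_codon = sense[tail:tail + 3].upper() if len(sense) % 3 == 0 \
                        else sense[-3:].upper()
        elif feat.type == "tRNA":
            category = "tRNA"
        elif feat.type == "rRNA":
            category = "rRNA"

        genes.append(GeneRecord(
            name=name, category=category, strand=strand,
            start=start, end=end, length=length,
            start_codon=start_codon, stop_codon=stop_codon,
            anticodon=anticodon,
            flags=[] if name in CANONICAL_LABELS else ["unrecognized gene name"],
        ))

    if not genes:
        warnings.append("GenBank record contains no gene features")
    ann = MitogenomeAnnotation(
        genome_length=genome_length, genes=genes,
        sequence=seq if has_seq else None)
    for w in warnings:
        ann.warn(w)
    return ann


# ---------------------------------------------------------------------------
# Spacers, overlaps, census
# ---------------------------------------------------------------------------

@dataclass
class SpacerPair:
    upstream: str
    downstream: str
    gap: int  # >0 spacer, 0 abutment, <0 overlap of |gap| nt


@dataclass
class SpacerReport:
    """Gap accounting for consecutive genes on the circle.

    One pair per gene (the last gene closes back onto the first); ``gap``
    is ``next.start - prev.end - 1``, so positive gaps are intergenic
    spacers, zero is abutment and negative gaps are overlaps.
    """

    pairs: list  # of SpacerPair
    genome_length: int

    @property
    def overlaps(self) -> list:
        return [p for p in self.pairs if p.gap < 0]

    @property
    def spacers(self) -> list:
        return [p for p in self.pairs if p.gap > 0]

    @property
    def abutments(self) -> list:
        return [p for p in self.pairs if p.gap == 0]

    @property
    def max_spacer(self) -> Optional[SpacerPair]:
        return max(self.spacers, key=lambda p: p.gap, default=None)

    @property
    def total_spacer_length(self) -> int:
        return sum(p.gap for p in self.spacers)

    @property
    def total_overlap_length(self) -> int:
        return sum(-p.gap for p in self.overlaps)

    def summary(self) -> dict:
        return {
            "n_pairs": len(self.pairs),
            "n_overlaps": len(self.overlaps),
            "n_spacers": len(self.spacers),
            "n_abutments": len(self.abutments),
            "total_spacer_length": self.total_spacer_length,
            "total_overlap_length": self.total_overlap_length,
            "max_spacer": (
                {"between": [self.max_spacer.upstream, self.max_spacer.downstream],
                 "length": self.max_spacer.gap}
                if self.max_spacer else None),
        }


def spacers_and_overlaps(annotation: MitogenomeAnnotation) -> SpacerReport:
    """Compute the circular spacer/overlap report for an annotation."""
    genes = annotation.genes
    if len(genes) < 2:
        raise AnnotationError("spacer analysis needs at least two genes")
    L = annotation.genome_length
    pairs = []
    for prev, nxt in zip(genes, genes[1:]):
        pairs.append(SpacerPair(prev.name, nxt.name, nxt.start - prev.end - 1))
    last, first = genes[-1], genes[0]
    # circular closure: distance across the origin
    wrap_gap = (L - last.end) + (first.start - 1)
    pairs.append(SpacerPair(last.name, first.name, wrap_gap))
    return SpacerReport(pairs=pairs, genome_length=L)


def summarize(annotation: MitogenomeAnnotation) -> dict:
    """Gene-content census: counts, strand usage, extremes, summed lengths."""
    genes = annotation.genes
    if not genes:
        raise AnnotationError("cannot summarize an empty annotation")
    by_category: dict = {}
    length_by_category: dict = {}
    for g in genes:
        by_category[g.category] = by_category.get(g.category, 0) + 1
        length_by_category[g.category] = length_by_category.get(g.category, 0) + g.length
    longest = max(genes, key=lambda g: g.length)
    shortest = min(genes, key=lambda g: g.length)
    return {
        "genome_length": annotation.genome_length,
        "n_genes": len(genes),
        "counts_by_category": by_category,
        "counts_by_strand": {
            "H": sum(1 for g in genes if g.strand == "H"),
            "L": sum(1 for g in genes if g.strand == "L"),
        },
        "length_by_category": length_by_category,
        "longest_gene": {"name": longest.name, "length": longest.length},
        "shortest_gene": {"name": shortest.name, "length": shortest.length},
        "l_strand_genes": [g.name for g in genes if g.strand == "L"],
    }
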