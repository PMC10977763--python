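"""Concatenated 13-PCG supermatrix assembly for phylogenetic inference.

Mitogenome phylogenies are normally inferred from the concatenation of the
13 protein-coding genes across taxa.  This module takes per-gene nucleotide
alignments (already aligned — alignment itself is an input, not a step
performed here), concatenates them in a fixed canonical gene order, fills
missing taxa with gap characters, and emits the text artifacts an external
inference run needs: FASTA, relaxed PHYLIP, NEXUS with a sets block, a
plain-text partition file (GTR+F+R6 per partition, 1000 ultrafast
bootstrap replicates recorded for the ML run) and a MrBayes command block
(nst=6, rates=invgamma, 2,000,000 generations, sample frequency 1000,
burn-in fraction 0.25, two runs).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, List, Optional

CANONICAL_PCG_ORDER = (
    "COX1", "COX2", "COX3", "ATP6", "ATP8",
    "NAD1", "NAD2", "NAD3", "NAD4", "NAD4L", "NAD5", "NAD6", "CYTB",
)


class SupermatrixError(ValueError):
    pass


@dataclass
class Supermatrix:
    """Aligned per-gene blocks concatenated across taxa."""

    taxa: List[str]
    gene_order: List[str]
    partitions: List[tuple]          # (gene, start_col, end_col), 1-based inclusive
    rows: Dict[str, str]             # taxon -> concatenated sequence
    missing: Dict[str, List[str]]    # taxon -> genes gap-filled for it
    gap_char: str = "-"

    @property
    def n_columns(self) -> int:
        return self.partitions[-1][2] if self.partitions else 0

    def validate(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise SupermatrixError(f"ragged matrix rows: lengths {sorted(lengths)}")
        if lengths and lengths.pop() != self.n_columns:
            raise SupermatrixError("row length does not match partition spans")


def read_fasta_alignment(source) -> Dict[str, str]:
    """Read one aligned FASTA (path, handle or text) into taxon->sequence."""
    from Bio import SeqIO

    if isinstance(source, str) and source.lstrip().startswith(">"):
        source = io.StringIO(source)
    seqs = {}
    for rec in SeqIO.parse(source, "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def build_supermatrix(per_gene_alignments: Dict[str, Dict[str, str]],
                      gene_order: Optional[List[str]] = None,
                      gap_char: str = "-") -> Supermatrix:
    """Concatenate per-gene alignments into a supermatrix.

    ``per_gene_alignments`` maps gene name to a taxon->aligned-sequence
    map.  Genes are concatenated in the canonical PCG order (genes absent
    from the input are skipped; extra genes follow alphabetically).  A
    taxon missing from a gene gets a gap block and is flagged.
    """
    if not per_gene_alignments:
        raise SupermatrixError("no alignments given")
    if gene_order is None:
        known = [g for g in CANONICAL_PCG_ORDER if g in per_gene_alignments]
        extra = sorted(set(per_gene_alignments) - set(known))
        gene_order = known + extra

    lengths = {}
    for gene in gene_order:
        aln = per_gene_alignments[gene]
        if not aln:
            raise SupermatrixError(f"alignment for {gene} is empty")
        lens = {len(s) for s in aln.values()}
        if len(lens) != 1:
            raise SupermatrixError(
                f"ragged alignment for {gene}: sequence lengths {sorted(lens)}")
        lengths[gene] = lens.pop()

    taxa = sorted({t for aln in per_gene_alignments.values() for t in aln})
    if not taxa:
        raise SupermatrixError("zero taxa shared across alignments")

    rows = {t: [] for t in taxa}
    missing: Dict[str, List[str]] = {t: [] for t in taxa}
    partitions = []
    col = 0
    for gene in gene_order:
        aln = per_gene_alignments[gene]
        L = lengths[gene]
        partitions.append((gene, col + 1, col + L))
        col += L
        for t in taxa:
            if t in aln:
                rows[t].append(aln[t])
            else:
                rows[t].append(gap_char * L)
                missing[t].append(gene)

    matrix = Supermatrix(
        taxa=taxa, gene_order=list(gene_order), partitions=partitions,
        rows={t: "".join(parts) for t, parts in rows.items()},
        missing={t: m for t, m in missing.items() if m},
        gap_char=gap_char)
    matrix.validate()
    return matrix


# ---------------------------------------------------------------------------
# Writers (all deterministic: no timestamps)
# ---------------------------------------------------------------------------

def write_fasta(matrix: Supermatrix) -> str:
    out = io.StringIO()
    for t in matrix.taxa:
        out.write(f">{t}\n{matrix.rows[t]}\n")
    return out.getvalue()


def write_phylip(matrix: Supermatrix) -> str:
    """Relaxed PHYLIP: full taxon names, two-space separator."""
    out = io.StringIO()
    out.write(f" {len(matrix.taxa)} {matrix.n_columns}\n")
    width = max(len(t) for t in matrix.taxa) + 2
    for t in matrix.taxa:
        out.write(t.ljust(width) + matrix.rows[t] + "\n")
    return out.getvalue()


def write_nexus(matrix: Supermatrix) -> str:
    out = io.StringIO()
    out.write("#NEXUS\n\nbegin data;\n")
    out.write(f"  dimensions ntax={len(matrix.taxa)} nchar={matrix.n_columns};\n")
    out.write(f"  format datatype=dna missing=? gap={matrix.gap_char};\n")
    out.write("  matrix\n")
    width = max(len(t) for t in matrix.taxa) + 2
    for t in matrix.taxa:
        out.write("    " + t.ljust(width) + matrix.rows[t] + "\n")
    out.write("  ;\nend;\n\nbegin sets;\n")
    for gene, a, b in matrix.partitions:
        out.write(f"  charset {gene} = {a}-{b};\n")
    out.write("end;\n")
    return out.getvalue()


def read_phylip(text: str) -> Dict[str, str]:
    """Read relaxed PHYLIP back into taxon->sequence (round-trip check)."""
    lines = [l for l in text.splitlines() if l.strip()]
    header = lines[0].split()
    ntax, nchar = int(header[0]), int(header[1])
    rows = {}
    for line in lines[1:1 + ntax]:
        name, seq = line.split(None, 1)
        rows[name] = seq.replace(" ", "")
        if len(rows[name]) != nchar:
            raise SupermatrixError(f"row {name}: length != {nchar}")
    return rows


def read_nexus(text: str) -> Dict[str, str]:
    """Read the matrix block of a NEXUS file back into taxon->sequence."""
    rows: Dict[str, str] = {}
    in_matrix = False
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.lower() == "matrix":
            in_matrix = True
            continue
        if in_matrix:
            if stripped == ";":
                break
            if stripped:
                name, seq = stripped.split(None, 1)
                rows[name] = rows.get(name, "") + seq.replace(" ", "")
    return rows


def write_partition_file(matrix: Supermatrix,
                         model: str = "GTR+F+R6",
                         merge: bool = False) -> str:
    """RAxML/IQ-TREE-style partition file, one line per gene partition
    (or a single concatenated partition when ``merge`` is set), with the
    ML bootstrap setting recorded as a comment."""
    out = io.StringIO()
    out.write("# ML run setting: 1000 ultrafast likelihood bootstrap "
              "replicates (iqtree -bb 1000)\n")
    if merge:
        out.write(f"{model}, concatenated = 1-{matrix.n_columns}\n")
    else:
        for gene, a, b in matrix.partitions:
            out.write(f"{model}, {gene} = {a}-{b}\n")
    return out.getvalue()


def write_mrbayes_block(matrix: Supermatrix,
                        outgroup: Optional[str] = None,
                        ngen: int = 2_000_000,
                        samplefreq: int = 1000,
                        burninfrac: float = 0.25,
                        nruns: int = 2,
                        nchains: int = 4) -> str:
    """MrBayes command block (nst=6, rates=invgamma) as a literal artifact."""
    out = io.StringIO()
    out.write("begin mrbayes;\n")
    out.write("  set autoclose=yes nowarn=yes;\n")
    for i, (gene, a, b) in enumerate(matrix.partitions, start=1):
        out.write(f"  charset {gene} = {a}-{b};\n")
    names = " ".join(g for g, _, _ in matrix.partitions)
    out.write(f"  partition bygene = {len(matrix.partitions)}: {names};\n")
    out.write("  set partition=bygene;\n")
    if outgroup:
        out.write(f"  outgroup {outgroup};\n")
    out.write("  lset applyto=(all) nst=6 rates=invgamma;\n")
    out.write(f"  mcmc ngen={ngen} samplefreq={samplefreq} "
              f"nruns={nruns} nchains={nchains};\n")
    out.write(f"  sumt burninfrac={burninfrac};\n")
    out.write(f"  sump burninfrac={burninfrac};\n")
    out.write("end;\n")
    return out.getvalue()


def write_inference_configs(matrix: Supermatrix,
                            outgroup: Optional[str] = None,
                            merge: bool = False) -> Dict[str, str]:
    """All inference artifacts for one supermatrix, keyed by file name."""
    if not matrix.partitions:
        raise SupermatrixError("empty supermatrix")
    return {
        "supermatrix.fasta": write_fasta(matrix),
        "supermatrix.phy": write_phylip(matrix),
        "supermatrix.nex": write_nexus(matrix),
        "partitions.txt": write_partition_file(matrix, merge=merge),
        "mrbayes.nex": write_nexus(matrix) + "\n" +
                       write_mrbayes_block(matrix, outgroup=outgroup),
    }
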