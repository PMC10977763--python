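"""Seed-controlled synthetic mitogenomes, tRNAs and rearrangement scenarios.

The generator emulates the statistical structure the analyses assume — an
AT-rich (~70% A+T) circular genome of 15-17 kb carrying the 37 canonical
genes, protein-coding genes that are genuine open reading frames under the
invertebrate mitochondrial code, tRNA genes instantiated from cloverleaf
templates with configurable missing arms, and rearrangement events applied
to a base gene order with a ground-truth log — so every analysis stage is
testable without downloading any deposited sequence.

All randomness flows through one ``numpy.random.Generator`` per call;
identical (spec, seed) inputs give bit-identical outputs.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .annotation import (GeneRecord, MitogenomeAnnotation, gene_category,
                         reverse_complement)
from .gene_order import (GeneOrderError, SignedGeneOrder, invert_block,
                         move_block)

# ---------------------------------------------------------------------------
# Defaults: realistic per-gene parameters for a littorinimorph-like mitogenome
# ---------------------------------------------------------------------------

DEFAULT_PCG_LENGTHS = {
    "COX1": 1551, "COX2": 693, "COX3": 780, "ATP6": 696, "ATP8": 159,
    "NAD1": 945, "NAD2": 1089, "NAD3": 357, "NAD4": 1305, "NAD4L": 303,
    "NAD5": 1872, "NAD6": 504, "CYTB": 1140,
}
DEFAULT_RRNA_LENGTHS = {"rrnS": 896, "rrnL": 1364}
DEFAULT_ANTICODONS = {
    "trnA": "TGC", "trnC": "GCA", "trnD": "GTC", "trnE": "TTC",
    "trnF": "GAA", "trnG": "TCC", "trnH": "GTG", "trnI": "GAT",
    "trnK": "TTT", "trnL1": "TAG", "trnL2": "TAA", "trnM": "CAT",
    "trnN": "GTT", "trnP": "TGG", "trnQ": "TTG", "trnR": "TCG",
    "trnS1": "GCT", "trnS2": "TGA", "trnT": "TGT", "trnV": "TAC",
    "trnW": "TCA", "trnY": "GTA",
}
#: mirrors the degenerate tRNAs common in gastropod mitogenomes:
#: the two serine tRNAs lack the D arm, the alanine tRNA lacks the T arm
DEFAULT_TRNA_ARMS = {"trnS1": ("acceptor", "anticodon", "T"),
                     "trnS2": ("acceptor", "anticodon", "T"),
                     "trnA": ("acceptor", "D", "anticodon")}
ALL_ARMS = ("acceptor", "D", "anticodon", "T")

STOP_CODONS_DNA = ("TAA", "TAG")  # invertebrate mitochondrial code


class SpecError(ValueError):
    pass


@dataclass
class GenomeSpec:
    """Parameters of one synthetic mitogenome."""

    genome_length: int = 16000
    at_content: float = 0.70
    gene_order: Union[SignedGeneOrder, str, None] = None  # default: organism order
    pcg_lengths: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PCG_LENGTHS))
    rrna_lengths: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_RRNA_LENGTHS))
    anticodons: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ANTICODONS))
    trna_arms: Dict[str, tuple] = field(default_factory=lambda: dict(DEFAULT_TRNA_ARMS))
    start_codons: Union[str, Dict[str, str]] = "ATG"
    stop_codons: Union[str, Dict[str, str]] = "TAA"
    spacer_range: Tuple[int, int] = (3, 30)
    control_region_after: str = "trnF"
    overlaps: Dict[Tuple[str, str], int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.at_content < 1.0):
            raise SpecError("at_content must be in (0, 1)")
        for name, L in {**self.pcg_lengths, **self.rrna_lengths}.items():
            if L <= 0:
                raise SpecError(f"{name}: length must be positive")
        for name, L in self.pcg_lengths.items():
            if L % 3:
                raise SpecError(f"{name}: PCG length {L} not divisible by 3")


def _resolve_order(spec: GenomeSpec) -> SignedGeneOrder:
    from . import datasets

    if isinstance(spec.gene_order, SignedGeneOrder):
        return spec.gene_order
    if spec.gene_order in (None, "desmaulus"):
        from .gene_order import order_from_annotation
        return order_from_annotation(datasets.desmaulus_annotation())
    if spec.gene_order == "ancestral":
        return datasets.ancestral_gastropod_order()
    raise SpecError(f"unknown gene order {spec.gene_order!r}")


# ---------------------------------------------------------------------------
# Sequence building blocks
# ---------------------------------------------------------------------------

def _rand_bases(rng: np.random.Generator, n: int, at: float) -> str:
    bases = rng.choice(np.array(list("ATGC")), size=n,
                       p=[at / 2, at / 2, (1 - at) / 2, (1 - at) / 2])
    return "".join(bases)


def _rand_codon(rng: np.random.Generator, at: float) -> str:
    while True:
        codon = _rand_bases(rng, 3, at)
        if codon not in STOP_CODONS_DNA:
            return codon


def _policy(policy, gene: str, default: str) -> str:
    if isinstance(policy, dict):
        return policy.get(gene, default)
    return policy


def generate_pcg(rng: np.random.Generator, length: int, at: float,
                 start_codon: str, stop_codon: str) -> Tuple[str, Counter]:
    """An open reading frame of the given length (start + body + stop) with
    no internal terminators; returns the sequence and its codon counts."""
    if length % 3 or length < 9:
        raise SpecError(f"PCG length {length} infeasible")
    n_body = length // 3 - 2
    body = [_rand_codon(rng, at) for _ in range(n_body)]
    codons = [start_codon] + body + [stop_codon]
    counts = Counter(c.replace("T", "U") for c in codons)
    return "".join(codons), counts


@dataclass
class TrnaTemplate:
    """A generated tRNA with its ground-truth layout."""

    sequence: str
    arm_config: tuple            # arms constructed
    anticodon: str
    anticodon_span: Tuple[int, int]
    mismatch_positions: List[Tuple[int, int]]
    wobble_positions: List[Tuple[int, int]]


_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def generate_trna(arm_config=ALL_ARMS,
                  anticodon: str = "CAT",
                  rng: Optional[np.random.Generator] = None,
                  seed: Optional[int] = None,
                  at: float = 0.70,
                  n_mismatches: int = 0,
                  n_wobbles: int = 0) -> TrnaTemplate:
    """Template tRNA whose stems are built by reverse complementation.

    ``arm_config`` selects which arms are structured; the acceptor and
    anticodon arms are always required.  Omitted D/T arms are replaced by
    unstructured loops (the D-less serine and T-less alanine analogues).
    Optional wobble pairs and mismatches are introduced on the 3' side of
    the acceptor stem, with their positions returned as ground truth.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    if "acceptor" not in arm_config or "anticodon" not in arm_config:
        raise SpecError("acceptor and anticodon arms are always required")
    ac_dna = anticodon.upper().replace("U", "T")

    a5 = _rand_bases(rng, 7, at)
    s1 = _rand_bases(rng, 1, at)
    if "D" in arm_config:
        d5 = _rand_bases(rng, 4, at)
        d_region = d5 + _rand_bases(rng, 8, at) + _revcomp(d5)
    else:
        d_region = _rand_bases(rng, 6, at)
    s2 = _rand_bases(rng, 1, at)
    ac5 = _rand_bases(rng, 5, at)
    ac_loop = _rand_bases(rng, 2, at) + ac_dna + _rand_bases(rng, 2, at)
    ac_arm = ac5 + ac_loop + _revcomp(ac5)
    if "T" in arm_config:
        var = _rand_bases(rng, 4, at)
        t5 = _rand_bases(rng, 5, at)
        t_region = t5 + _rand_bases(rng, 7, at) + _revcomp(t5)
    else:
        var = _rand_bases(rng, 8, at)
        t_region = ""
    acc3 = _revcomp(a5)
    disc = _rand_bases(rng, 1, at)

    prefix = a5 + s1 + d_region + s2 + ac_arm + var + t_region
    seq = list(prefix + acc3 + disc)
    n = len(seq)
    ac_off = len(a5 + s1 + d_region + s2 + ac5) + 2

    # acceptor-stem pair (k): 5' pos k  <->  3' pos n-2-k  (one discriminator)
    mism, wob = [], []
    slots = list(rng.permutation(7))
    for _ in range(n_wobbles):
        k = slots.pop()
        i, j = k, n - 2 - k
        if seq[i] not in ("G", "T"):
            seq[i] = "G"
        seq[j] = "T" if seq[i] == "G" else "G"
        wob.append((i, j))
    for _ in range(n_mismatches):
        k = slots.pop()
        i, j = k, n - 2 - k
        bad = {"A": "C", "C": "A", "G": "A", "T": "C"}  # breaks WC and wobble
        seq[j] = bad[seq[i]]
        mism.append((i, j))

    return TrnaTemplate(sequence="".join(seq), arm_config=tuple(arm_config),
                        anticodon=ac_dna,
                        anticodon_span=(ac_off, ac_off + 3),
                        mismatch_positions=sorted(mism),
                        wobble_positions=sorted(wob))


# ---------------------------------------------------------------------------
# Whole-genome generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    sequence: str
    annotation: MitogenomeAnnotation
    truth: dict

    def __iter__(self):
        return iter((self.sequence, self.annotation))


def generate_mitogenome(spec: Optional[GenomeSpec] = None,
                        seed: Optional[int] = None) -> SyntheticGenome:
    """Build a circular annotated genome from a spec (see module docstring).

    Gene sequences are laid down in the spec's gene order starting at
    position 1; intergenic spacers are drawn from ``spacer_range`` and one
    larger control-region spacer absorbs the remainder so the realized
    length equals ``genome_length`` exactly.  An infeasible spec raises
    :class:`SpecError` before any sequence is generated.
    """
    spec = spec or GenomeSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)
    order = _resolve_order(spec)
    at = spec.at_content

    # --- plan lengths and check feasibility before generating ---------------
    planned: Dict[str, int] = {}
    for label, _sign in order:
        cat = gene_category(label)
        if cat == "PCG":
            planned[label] = spec.pcg_lengths[label]
        elif cat == "rRNA":
            planned[label] = spec.rrna_lengths[label]
        elif cat == "tRNA":
            arms = spec.trna_arms.get(label, ALL_ARMS)
            planned[label] = 71 if "T" in arms and "D" in arms else \
                (61 if "T" in arms else 58)
        else:
            raise SpecError(f"cannot generate gene of unknown category: {label}")
    total_genes = sum(planned.values())
    labels = [l for l, _ in order]
    n_gaps = len(labels)  # circular: one gap per gene
    overlap_total = sum(spec.overlaps.values())
    min_spacers = (n_gaps - 1) * spec.spacer_range[0]
    if total_genes - overlap_total + min_spacers >= spec.genome_length:
        raise SpecError(
            f"infeasible spec: {total_genes} nt of genes + minimum spacers "
            f"exceed genome_length {spec.genome_length}")

    # --- generate per-gene sense sequences ----------------------------------
    sense: Dict[str, str] = {}
    codon_truth: Counter = Counter()
    trna_truth: Dict[str, dict] = {}
    pcg_codons: Dict[str, Tuple[str, str]] = {}
    for label, _sign in order:
        cat = gene_category(label)
        if cat == "PCG":
            start = _policy(spec.start_codons, label, "ATG")
            stop = _policy(spec.stop_codons, label, "TAA")
            seq, counts = generate_pcg(rng, planned[label], at, start, stop)
            sense[label] = seq
            codon_truth += counts
            pcg_codons[label] = (start, stop)
        elif cat == "rRNA":
            sense[label] = _rand_bases(rng, planned[label], at)
        else:
            arms = spec.trna_arms.get(label, ALL_ARMS)
            tpl = generate_trna(arm_config=arms,
                                anticodon=spec.anticodons[label], rng=rng, at=at)
            sense[label] = tpl.sequence
            trna_truth[label] = {
                "arms": list(arms), "anticodon": tpl.anticodon,
                "anticodon_span": list(tpl.anticodon_span)}
            planned[label] = len(tpl.sequence)

    # --- spacers: fixed draws everywhere, control region absorbs the rest ---
    gap_after: Dict[str, int] = {}
    for up, down in zip(labels, labels[1:] + labels[:1]):
        k = spec.overlaps.get((up, down))
        gap_after[up] = -k if k else int(rng.integers(spec.spacer_range[0],
                                                      spec.spacer_range[1] + 1))
    cr_host = spec.control_region_after if spec.control_region_after in labels \
        else labels[-1]
    occupied = sum(planned.values()) + sum(g for g in gap_after.values()
                                           if gap_after and g) - gap_after[cr_host]
    cr_len = spec.genome_length - occupied
    if cr_len < spec.spacer_range[0]:
        raise SpecError("infeasible spec: no room for the control region; "
                        "reduce gene lengths or spacers")
    gap_after[cr_host] = cr_len

    # --- assemble sequence and annotation ------------------------------------
    chunks: List[str] = []
    genes: List[GeneRecord] = []
    pos = 1
    for label, sign in order:
        L = planned[label]
        gseq = sense[label] if sign > 0 else reverse_complement(sense[label])
        overlap = -gap_after.get(_prev_label(labels, label), 0) \
            if gap_after.get(_prev_label(labels, label), 0) < 0 else 0
        if overlap:
            # positional overlap: the upstream gene's tail is shared
            gseq = gseq[overlap:]
            start = pos - overlap
        else:
            start = pos
        chunks.append(gseq)
        end = start + L - 1
        cat = gene_category(label)
        rec = GeneRecord(
            name=label, category=cat, strand="H" if sign > 0 else "L",
            start=start, end=end, length=L,
            start_codon=pcg_codons[label][0] if cat == "PCG" else None,
            stop_codon=pcg_codons[label][1] if cat == "PCG" else None,
            anticodon=spec.anticodons.get(label) if cat == "tRNA" else None)
        genes.append(rec)
        pos = end + 1
        gap = gap_after[label]
        if gap > 0 and label != labels[-1]:
            chunks.append(_rand_bases(rng, gap, at))
            pos += gap
    # trailing gap closes the circle back to position 1
    tail = spec.genome_length - (pos - 1)
    if tail < 0:
        raise SpecError("internal layout error: genome overflow")
    if tail:
        chunks.append(_rand_bases(rng, tail, at))
    sequence = "".join(chunks)
    assert len(sequence) == spec.genome_length

    annotation = MitogenomeAnnotation(genome_length=spec.genome_length,
                                      genes=genes, sequence=sequence)
    truth = {
        "seed": spec.seed,
        "genome_length": spec.genome_length,
        "at_content_target": at,
        "codon_counts": {c: int(n) for c, n in sorted(codon_truth.items())},
        "trnas": trna_truth,
        "pcg_codons": {g: list(v) for g, v in pcg_codons.items()},
        "gene_order": [[l, "+" if s > 0 else "-"] for l, s in order],
    }
    return SyntheticGenome(sequence=sequence, annotation=annotation, truth=truth)


def _prev_label(labels: List[str], label: str) -> str:
    i = labels.index(label)
    return labels[i - 1]


# ---------------------------------------------------------------------------
# Rearrangement scenarios
# ---------------------------------------------------------------------------

@dataclass
class SimEvent:
    """One ground-truth rearrangement applied by the simulator."""

    type: str                 # shuffling | translocation | inversion | inverted_translocation
    block: Tuple[str, ...]    # labels of the moved/flipped block
    after: Optional[str] = None  # insertion anchor (None for in-place inversion)


def apply_rearrangements(order: SignedGeneOrder,
                         events: List[SimEvent],
                         allow_overlap: bool = False
                         ) -> Tuple[SignedGeneOrder, List[SimEvent]]:
    """Apply typed events in sequence; returns the result and the event log.

    Events reference genes by label so earlier events do not invalidate
    later ones.  Blocks of distinct events must be disjoint unless
    ``allow_overlap`` is set.
    """
    seen: set = set()
    for e in events:
        if not allow_overlap and seen & set(e.block):
            raise GeneOrderError(f"overlapping event blocks at {e.block}")
        seen.update(e.block)
    cur = order
    for e in events:
        labels = list(cur.labels)
        try:
            idxs = sorted(labels.index(g) for g in e.block)
        except ValueError as exc:
            raise GeneOrderError(f"unknown label in block {e.block}") from exc
        i, j = idxs[0], idxs[-1] + 1
        # the block is located by its label set, so a previously inverted
        # block is still addressable (inversion stays an involution)
        if idxs != list(range(i, j)):
            raise GeneOrderError(f"block {e.block} not contiguous")
        if e.type == "inversion":
            cur = invert_block(cur, i, j)
            continue
        if e.after is None:
            raise GeneOrderError(f"{e.type} event needs an insertion anchor")
        flip = e.type == "inverted_translocation"
        dest = labels.index(e.after) + 1
        if i <= dest <= j:
            raise GeneOrderError("insertion anchor inside the moved block")
        cur = move_block(cur, i, j, dest, flip=flip)
    return cur, list(events)


def sample_events(order: SignedGeneOrder, k: int,
                  rng: Optional[np.random.Generator] = None,
                  seed: Optional[int] = None) -> List[SimEvent]:
    """Draw k well-separated random events of the four types.

    Blocks are 1-3 genes, never touch the canonical anchor gene, and are
    kept at least one gene apart from each other and from each other's
    insertion points, so the scenario is unambiguous for recovery tests.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    labels = list(order.labels)
    n = len(labels)
    cats = {l: gene_category(l) for l in labels}
    types = ["inversion", "shuffling", "translocation", "inverted_translocation"]
    used: set = {0}  # protect the canonical anchor
    events: List[SimEvent] = []
    attempts = 0
    while len(events) < k and attempts < 500:
        attempts += 1
        etype = types[int(rng.integers(len(types)))]
        blen = int(rng.integers(1, 4))
        i = int(rng.integers(1, n - blen))
        span = set(range(i - 1, i + blen + 1))
        if span & used:
            continue
        block = tuple(labels[i:i + blen])
        if etype == "inversion":
            events.append(SimEvent("inversion", block))
            used |= span
            continue
        if etype == "shuffling":
            # an all-tRNA block hops past the single adjacent tRNA; with
            # only tRNAs involved the move reads as a shuffling no matter
            # which side of the swap is taken as the mover
            nxt = i + blen
            if any(cats[g] != "tRNA" for g in block):
                continue
            if nxt >= n - 1 or cats[labels[nxt]] != "tRNA":
                continue
            if {nxt, nxt + 1} & used:
                continue
            events.append(SimEvent("shuffling", block, after=labels[nxt]))
            used |= span | {nxt, nxt + 1}
            continue
        # translocation / inverted_translocation: cross 4-9 genes with >=1
        # PCG or rRNA among them
        reach = int(rng.integers(4, 10))
        dest = i + blen + reach
        if dest >= n - 1:
            continue
        crossed = labels[i + blen:dest]
        if not any(cats[g] in ("PCG", "rRNA") for g in crossed):
            continue
        if set(range(i + blen, dest + 2)) & used:
            continue
        events.append(SimEvent(etype, block, after=labels[dest - 1]))
        used |= span | set(range(i + blen, dest + 2))
    if len(events) < k:
        raise GeneOrderError(f"could not place {k} separated events")
    return events


# ---------------------------------------------------------------------------
# Emission of on-disk artifacts
# ---------------------------------------------------------------------------

def annotation_to_genbank(annotation: MitogenomeAnnotation,
                          name: str = "synthetic") -> str:
    """GenBank flat-file text for an annotated (sequence-bearing) genome."""
    import io as _io

    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    if annotation.sequence is None:
        raise ValueError("annotation carries no sequence")
    record = SeqRecord(Seq(annotation.sequence), id=name, name=name,
                       description="synthetic mitochondrial genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular"
    L = annotation.genome_length
    type_of = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
    for g in annotation.genes:
        strand = 1 if g.strand == "H" else -1
        if g.wraps:
            loc = CompoundLocation([FeatureLocation(g.start - 1, L, strand),
                                    FeatureLocation(0, g.end, strand)])
        else:
            loc = FeatureLocation(g.start - 1, g.end, strand)
        quals = {"gene": [g.name]}
        if g.category == "PCG":
            quals["codon_start"] = ["1"]
            quals["transl_table"] = ["5"]
        if g.anticodon:
            quals["anticodon"] = [f"(seq:{g.anticodon.lower()})"]
        record.features.append(
            SeqFeature(loc, type=type_of.get(g.category, "misc_feature"),
                       qualifiers=quals))
    buf = _io.StringIO()
    SeqIO.write(record, buf, "genbank")
    return buf.getvalue()


def annotation_to_fasta(annotation: MitogenomeAnnotation,
                        name: str = "synthetic") -> str:
    if annotation.sequence is None:
        raise ValueError("annotation carries no sequence")
    seq = annotation.sequence
    lines = [f">{name}"] + [seq[i:i + 70] for i in range(0, len(seq), 70)]
    return "\n".join(lines) + "\n"


def truth_to_json(genome: SyntheticGenome) -> str:
    return json.dumps(genome.truth, indent=2, sort_keys=True)
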