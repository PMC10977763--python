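"""Circular signed gene orders and rearrangement analysis.

A mitogenome's gene arrangement is modelled as a circular signed
permutation: each gene carries an orientation (+ = H strand, - = L strand),
and two orders are equivalent under rotation and under reading the circle
from the other strand (full reversal with all signs flipped).  Comparing a
query order to a reference yields:

* **breakpoints** — signed circular adjacencies of the query absent from
  the reference;
* **synteny blocks** — maximal runs of genes contiguous and co-oriented in
  both orders (a run matching the reference in reversed order with flipped
  signs counts as one *inverted* block);
* **events** — a heuristic scenario of typed rearrangements transforming
  the reference into the query.  Blocks are greedily anchored by a
  maximum-weight chain that keeps its circular order and orientation;
  every unanchored block is reported as one event:

  - *inversion*: orientation flipped, position otherwise unchanged;
  - *shuffling*: a local move on the same strand crossing only tRNAs;
  - *translocation*: a move crossing at least one protein-coding or rRNA
    gene (crossing measured on the reference);
  - *inverted_translocation*: moved and flipped.

The scenario is heuristic, not guaranteed minimal, and the report says so.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .annotation import MitogenomeAnnotation, gene_category

Signed = Tuple[str, int]  # (label, +1 | -1)


class GeneOrderError(ValueError):
    pass


@dataclass(frozen=True)
class SignedGeneOrder:
    """A circular signed permutation of gene labels."""

    genes: Tuple[Signed, ...]

    def __post_init__(self):
        labels = [g for g, _ in self.genes]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise GeneOrderError(f"duplicate labels in gene order: {dupes}")
        if any(s not in (1, -1) for _, s in self.genes):
            raise GeneOrderError("orientations must be +1 or -1")

    def __len__(self):
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    @property
    def labels(self) -> Tuple[str, ...]:
        return tuple(g for g, _ in self.genes)

    def sign_of(self, label: str) -> int:
        for g, s in self.genes:
            if g == label:
                return s
        raise KeyError(label)

    def rotate(self, k: int) -> "SignedGeneOrder":
        n = len(self.genes)
        k %= n
        return SignedGeneOrder(self.genes[k:] + self.genes[:k])

    def reflect(self) -> "SignedGeneOrder":
        """Read the circle from the complementary strand."""
        return SignedGeneOrder(tuple((g, -s) for g, s in reversed(self.genes)))

    def canonical(self, anchor: Optional[str] = None) -> "SignedGeneOrder":
        """Rotate so the anchor gene comes first with + orientation,
        reflecting the circle if needed.  Default anchor is COX1 when
        present, else the lexicographically smallest label."""
        if not self.genes:
            return self
        labels = self.labels
        if anchor is None:
            anchor = "COX1" if "COX1" in labels else min(labels)
        if anchor not in labels:
            raise GeneOrderError(f"anchor {anchor!r} not in order")
        order = self
        if order.sign_of(anchor) == -1:
            order = order.reflect()
        return order.rotate(order.labels.index(anchor))

    def equivalent(self, other: "SignedGeneOrder") -> bool:
        if set(self.labels) != set(other.labels):
            return False
        anchor = self.labels[0]
        return self.canonical(anchor).genes == other.canonical(anchor).genes

    # -- text round-trip ---------------------------------------------------

    def to_text(self) -> str:
        return "".join(f"{g}\t{'+' if s > 0 else '-'}\n" for g, s in self.genes)

    @classmethod
    def from_text(cls, text: str) -> "SignedGeneOrder":
        genes = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2 or parts[1] not in ("+", "-"):
                raise GeneOrderError(f"bad gene-order line: {line!r}")
            genes.append((parts[0], 1 if parts[1] == "+" else -1))
        return cls(tuple(genes))


def order_from_annotation(annotation: MitogenomeAnnotation) -> SignedGeneOrder:
    """Signed order of an annotation: genes by start, + for H strand,
    canonicalized to put COX1 first with + orientation."""
    if not annotation.genes:
        raise GeneOrderError("empty annotation")
    genes = tuple((g.name, 1 if g.strand == "H" else -1)
                  for g in annotation.genes)
    return SignedGeneOrder(genes).canonical()


# ---------------------------------------------------------------------------
# Breakpoints
# ---------------------------------------------------------------------------

def _adjacency(a: Signed, b: Signed):
    """Canonical form of the signed adjacency a->b, identical to the
    adjacency seen when traversing the circle in the other direction."""
    fwd = (a[0], a[1], b[0], b[1])
    rev = (b[0], -b[1], a[0], -a[1])
    return min(fwd, rev)


def _adjacency_set(order: SignedGeneOrder):
    n = len(order.genes)
    return {_adjacency(order.genes[i], order.genes[(i + 1) % n])
            for i in range(n)}


def _check_labels(query: SignedGeneOrder, ref: SignedGeneOrder) -> None:
    q, r = set(query.labels), set(ref.labels)
    if q != r:
        raise GeneOrderError(
            f"label sets differ: only in query {sorted(q - r)}, "
            f"only in reference {sorted(r - q)}")


def breakpoints(query: SignedGeneOrder,
                ref: SignedGeneOrder) -> Tuple[int, list]:
    """Number of signed circular adjacencies of the query absent from the
    reference, plus the list of shared adjacencies.  Symmetric."""
    _check_labels(query, ref)
    qa, ra = _adjacency_set(query), _adjacency_set(ref)
    shared = sorted(qa & ra)
    return len(qa - ra), shared


# ---------------------------------------------------------------------------
# Synteny blocks
# ---------------------------------------------------------------------------

@dataclass
class SyntenyBlock:
    genes: List[Signed]     # in query orientation
    inverted: bool          # True if it matches the reference reversed+flipped

    @property
    def labels(self) -> List[str]:
        return [g for g, _ in self.genes]

    @property
    def size(self) -> int:
        return len(self.genes)


def synteny_blocks(query: SignedGeneOrder,
                   ref: SignedGeneOrder) -> List[SyntenyBlock]:
    """Maximal runs of genes contiguous and co-oriented in both orders,
    given in query order; a partition of all genes."""
    _check_labels(query, ref)
    n = len(query)
    ra = _adjacency_set(ref)
    q = query.genes
    linked = [_adjacency(q[i], q[(i + 1) % n]) in ra for i in range(n)]
    cuts = [(i + 1) % n for i in range(n) if not linked[i]]
    rsign = {g: s for g, s in ref.genes}

    def orient(block):
        g, s = block[0]
        return s != rsign[g]

    if not cuts:
        return [SyntenyBlock(genes=list(q), inverted=orient(q))]
    blocks = []
    cuts.sort()
    for j, start in enumerate(cuts):
        end = cuts[(j + 1) % len(cuts)]
        idxs = range(start, end) if end > start else \
            list(range(start, n)) + list(range(end))
        genes = [q[i] for i in idxs]
        blocks.append(SyntenyBlock(genes=genes, inverted=orient(genes)))
    # report in query order starting from query position 0
    blocks.sort(key=lambda b: query.labels.index(b.labels[0]))
    return blocks


# ---------------------------------------------------------------------------
# Event classification
# ---------------------------------------------------------------------------

@dataclass
class RearrangementEvent:
    type: str               # shuffling | translocation | inversion | inverted_translocation
    genes: List[str]
    description: str


@dataclass
class RearrangementReport:
    breakpoint_count: int
    blocks: List[SyntenyBlock]
    events: List[RearrangementEvent]
    differing_genes: List[str]
    heuristic_note: str = ("event scenario is heuristic (greedy block "
                           "anchoring); it is not guaranteed to be minimal")

    @property
    def scenario_length(self) -> int:
        return len(self.events)

    def as_dict(self) -> dict:
        return {
            "breakpoint_count": self.breakpoint_count,
            "n_blocks": len(self.blocks),
            "blocks": [{"genes": b.labels, "inverted": b.inverted}
                       for b in self.blocks],
            "events": [{"type": e.type, "genes": e.genes,
                        "description": e.description} for e in self.events],
            "differing_genes": self.differing_genes,
            "scenario_length": self.scenario_length,
            "note": self.heuristic_note,
        }


def _weighted_lcs(a: Sequence, b: Sequence, weight) -> list:
    """Heaviest common subsequence of two sequences of hashable items."""
    la, lb = len(a), len(b)
    dp = [[0.0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la - 1, -1, -1):
        for j in range(lb - 1, -1, -1):
            if a[i] == b[j]:
                dp[i][j] = weight(a[i]) + dp[i + 1][j + 1]
            else:
                dp[i][j] = max(dp[i + 1][j], dp[i][j + 1])
    out, i, j = [], 0, 0
    while i < la and j < lb:
        if a[i] == b[j] and dp[i][j] == weight(a[i]) + dp[i + 1][j + 1]:
            out.append(a[i])
            i += 1
            j += 1
        elif dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    return out


def classify_events(query: SignedGeneOrder,
                    ref: SignedGeneOrder) -> RearrangementReport:
    """Greedy typed-event scenario transforming the reference into the query."""
    _check_labels(query, ref)
    anchor = "COX1" if "COX1" in query.labels else min(query.labels)
    qc = query.canonical(anchor)
    rc = ref.canonical(anchor)
    n = len(qc)
    bp, _shared = breakpoints(qc, rc)
    blocks = synteny_blocks(qc, rc)

    # differing genes: neighborhood or orientation differs from the reference
    ra = _adjacency_set(rc)
    rsign = {g: s for g, s in rc.genes}
    differing = set()
    for i in range(n):
        a, b = qc.genes[i], qc.genes[(i + 1) % n]
        if _adjacency(a, b) not in ra:
            differing.update((a[0], b[0]))
    for g, s in qc.genes:
        if s != rsign[g]:
            differing.add(g)

    if bp == 0:
        return RearrangementReport(0, blocks, [], [])

    # --- anchor chain: maximum-weight set of co-oriented blocks keeping
    # their circular order in both query and reference -----------------------
    co = [b for b in blocks if not b.inverted]
    frame = max(co, key=lambda b: (b.size, -rc.labels.index(b.labels[0]))) \
        if co else max(blocks, key=lambda b: b.size)
    rpos = {g: i for i, (g, _) in enumerate(rc.genes)}
    shift = rpos[frame.labels[0]]
    refpos = {g: (i - shift) % n for g, i in rpos.items()}

    qstart = {id(b): qc.labels.index(b.labels[0]) for b in blocks}
    fstart = qstart[id(frame)]
    # query order of blocks starting at the frame
    qorder = sorted(blocks, key=lambda b: (qstart[id(b)] - fstart) % n)
    eligible = [b for b in qorder if not b.inverted]
    seq_q = [id(b) for b in eligible]
    seq_r = [id(b) for b in sorted(eligible, key=lambda b: refpos[b.labels[0]])]
    wt = {id(b): b.size for b in eligible}
    chain_ids = set(_weighted_lcs(seq_q, seq_r, lambda x: wt[x]))
    chain_ids.add(id(frame))
    chain_genes = {g for b in blocks if id(b) in chain_ids for g in b.labels}

    event_blocks = [b for b in qorder if id(b) not in chain_ids]

    # --- group event blocks into inter-chain gaps and detect moves ----------
    def left_chain_gene(labels_seq, start_idx):
        i = (start_idx - 1) % n
        while labels_seq[i] not in chain_genes:
            i = (i - 1) % n
        return labels_seq[i]

    qlabels, rlabels = list(qc.labels), list(rc.labels)
    gaps_q: Dict[str, list] = {}
    gaps_r: Dict[str, list] = {}
    for b in event_blocks:
        pq = left_chain_gene(qlabels, qlabels.index(b.labels[0]))
        first_r = b.labels[0] if not b.inverted else b.labels[-1]
        pr = left_chain_gene(rlabels, rlabels.index(first_r))
        gaps_q.setdefault(pq, []).append(b)
        gaps_r.setdefault(pr, []).append(b)
    for p in gaps_r:
        gaps_r[p].sort(key=lambda b: refpos[b.labels[0] if not b.inverted
                                            else b.labels[-1]])

    unmoved = set()
    for p, qlist in gaps_q.items():
        rlist = gaps_r.get(p, [])
        keep = _weighted_lcs([id(b) for b in qlist], [id(b) for b in rlist],
                             lambda x: next(b.size for b in qlist if id(b) == x))
        unmoved.update(keep)

    # --- type each event ----------------------------------------------------
    events = []
    for b in event_blocks:
        pq = left_chain_gene(qlabels, qlabels.index(b.labels[0]))
        if id(b) in unmoved:
            if b.inverted:
                events.append(RearrangementEvent(
                    "inversion", b.labels,
                    f"block [{','.join(b.labels)}] inverted in place"))
            else:
                events.append(RearrangementEvent(
                    "shuffling", b.labels,
                    f"block [{','.join(b.labels)}] locally reordered"))
            continue
        # moved: crossing measured on the reference, shorter arc between the
        # block's reference location and its insertion point (after pq)
        idxs = sorted(refpos[g] for g in b.labels)
        lo, hi = idxs[0], idxs[-1]
        ip = refpos[pq]
        fwd = [rlabels[(shift + k) % n]
               for k in range(hi + 1, hi + 1 + ((ip - hi) % n))]
        bwd = [rlabels[(shift + k) % n]
               for k in range(ip + 1, ip + 1 + ((lo - ip - 1) % n))]
        traversed = fwd if len(fwd) <= len(bwd) else bwd
        traversed = [g for g in traversed if g not in b.labels]
        crossed_major = [g for g in traversed
                         if gene_category(g) in ("PCG", "rRNA")]
        where = f"downstream of {pq}"
        if b.inverted:
            etype = "inverted_translocation"
            desc = f"block [{','.join(b.labels)}] inverted and relocated {where}"
        elif crossed_major:
            etype = "translocation"
            desc = (f"block [{','.join(b.labels)}] relocated {where}, "
                    f"crossing {','.join(crossed_major)}")
        else:
            etype = "shuffling"
            desc = f"block [{','.join(b.labels)}] shuffled {where}"
        events.append(RearrangementEvent(etype, b.labels, desc))

    return RearrangementReport(bp, blocks, events, sorted(differing))


# ---------------------------------------------------------------------------
# Primitive rearrangement operations (used by the simulator)
# ---------------------------------------------------------------------------

def invert_block(order: SignedGeneOrder, i: int, j: int) -> SignedGeneOrder:
    """Reverse genes[i:j] in place with signs flipped (0-based, j exclusive)."""
    g = list(order.genes)
    g[i:j] = [(lab, -s) for lab, s in reversed(g[i:j])]
    return SignedGeneOrder(tuple(g))


def move_block(order: SignedGeneOrder, i: int, j: int, dest: int,
               flip: bool = False) -> SignedGeneOrder:
    """Excise genes[i:j] and reinsert before original index ``dest``
    (which must lie outside [i, j]); optionally reversed with signs flipped."""
    if i <= dest <= j:
        raise GeneOrderError("destination lies inside the moved block")
    g = list(order.genes)
    block = g[i:j]
    if flip:
        block = [(lab, -s) for lab, s in reversed(block)]
    rest = g[:i] + g[j:]
    at = dest - (j - i) if dest > j else dest
    return SignedGeneOrder(tuple(rest[:at] + block + rest[at:]))


def render_diff(query: SignedGeneOrder, ref: SignedGeneOrder) -> str:
    """Side-by-side text rendering of two circular orders (H on top, L below)."""
    def row(order):
        top, bot = [], []
        for g, s in order.genes:
            w = max(len(g), 4)
            top.append(g.center(w) if s > 0 else " " * w)
            bot.append(g.center(w) if s < 0 else " " * w)
        return " ".join(top), " ".join(bot)

    rt, rb = row(ref.canonical(ref.labels[0]))
    qt, qb = row(query.canonical(ref.labels[0] if ref.labels[0] in query.labels
                                 else None))
    return (f"reference (H):\n  {rt}\nreference (L):\n  {rb}\n"
            f"query (H):\n  {qt}\nquery (L):\n  {qb}\n")
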