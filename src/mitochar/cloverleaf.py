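"""Constrained cloverleaf folding of mitochondrial tRNA sequences.

Metazoan mitochondrial tRNAs are short (typically 51-75 nt) and frequently
degenerate: serine tRNAs often lack the dihydrouridine (D) arm and some
others lack the TΨC (T) arm.  Rather than thermodynamic folding, this
module performs an exhaustive search over the constrained cloverleaf
layout:

* acceptor stem of 7 bp with up to 2 unpaired discriminator nt at the 3'
  end and up to 2 leading nt at the 5' end;
* D arm: stem 3-4 bp, loop 4-12 nt (optionally absent, replaced by an
  unstructured stretch);
* anticodon arm: stem 4-5 bp, loop of exactly 7 nt with the anticodon at
  its centre;
* variable region of 3-23 nt;
* T arm: stem 4-5 bp, loop 3-9 nt (optionally absent).

Stems are scored +2 per Watson-Crick pair, +1 per G·U wobble and -2 per
mismatch; an arm is called present iff its best stem holds at least three
Watson-Crick-or-wobble pairs with a positive score.  The highest-scoring
layout wins, with deterministic tie-breaking (score, then total paired
count, then fewest mismatches, then leftmost acceptor, then shortest
variable loop).  When an expected anticodon is supplied, layouts that
place it centrally in the anticodon loop are preferred before score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Tuple

from .codons import GeneticCode

WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "T"), ("T", "G")}

PAIR_SCORE = {"WC": 2, "wobble": 1, "mismatch": -2}

# layout search ranges (config defaults)
ACCEPTOR_STEM = 7
MAX_LEAD = 2
MAX_DISCRIMINATOR = 2
MAX_ARM_SPACER = 2
D_STEM_RANGE = (3, 4)
D_LOOP_RANGE = (4, 12)
D_ABSENT_RANGE = (0, 14)
AC_STEM_RANGE = (4, 5)
AC_LOOP = 7
VAR_RANGE = (3, 23)
T_STEM_RANGE = (4, 5)
T_LOOP_RANGE = (3, 9)


def pair_class(x: str, y: str) -> str:
    if (x, y) in WC_PAIRS:
        return "WC"
    if (x, y) in WOBBLE_PAIRS:
        return "wobble"
    return "mismatch"


@dataclass
class Arm:
    name: str                   # acceptor | D | anticodon | T
    stem_len: int
    pairs: List[Tuple[int, int, str]]   # (5' pos, 3' pos, class), 0-based
    loop: Tuple[int, int]       # [start, end) of the loop / unpaired span
    present: bool

    @property
    def score(self) -> int:
        return sum(PAIR_SCORE[c] for _, _, c in self.pairs)

    @property
    def n_paired(self) -> int:
        return sum(1 for _, _, c in self.pairs if c != "mismatch")

    @property
    def n_mismatch(self) -> int:
        return sum(1 for _, _, c in self.pairs if c == "mismatch")


@dataclass
class CloverleafFold:
    sequence: str               # in the input alphabet
    arms: Dict[str, Arm]
    arm_present: Dict[str, bool]
    anticodon: Optional[str]
    anticodon_span: Optional[Tuple[int, int]]   # [start, end) 0-based
    variable_span: Tuple[int, int]
    total_score: int
    foldable: bool = True
    flags: list = field(default_factory=list)

    @property
    def all_pairs(self) -> List[Tuple[int, int, str]]:
        return [p for arm in self.arms.values() for p in arm.pairs]

    def dot_bracket(self) -> str:
        s = ["."] * len(self.sequence)
        for i, j, _ in self.all_pairs:
            s[i], s[j] = "(", ")"
        return "".join(s)

    def as_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "foldable": self.foldable,
            "total_score": self.total_score,
            "anticodon": self.anticodon,
            "arm_present": dict(self.arm_present),
            "dot_bracket": self.dot_bracket(),
            "arms": {
                name: {"stem_len": a.stem_len, "score": a.score,
                       "pairs": a.pairs, "loop": list(a.loop),
                       "present": a.present}
                for name, a in self.arms.items()},
            "mismatches": [list(p) for p in mismatch_report(self)],
            "wobbles": [[i, j] for i, j, c in self.all_pairs if c == "wobble"],
        }


class FoldInputError(ValueError):
    pass


def _normalize(seq: str) -> Tuple[str, bool]:
    s = seq.strip().upper()
    was_rna = "U" in s
    s = s.replace("U", "T")
    if not s or set(s) - set("ACGT"):
        raise FoldInputError(f"sequence contains invalid characters: "
                             f"{sorted(set(s) - set('ACGT'))}")
    return s, was_rna


def _stem(seq: str, i: int, j: int, n: int) -> Tuple[Tuple[int, int, str], ...]:
    """Pairs of a stem whose 5' side starts at i and 3' side starts at j,
    both of length n (position i+k pairs with j+n-1-k)."""
    return tuple((i + k, j + n - 1 - k, pair_class(seq[i + k], seq[j + n - 1 - k]))
                 for k in range(n))


def _stem_stats(pairs) -> Tuple[int, int, int]:
    score = sum(PAIR_SCORE[c] for _, _, c in pairs)
    paired = sum(1 for _, _, c in pairs if c != "mismatch")
    mism = len(pairs) - paired
    return score, paired, mism


def _arm_ok(pairs) -> bool:
    score, paired, _ = _stem_stats(pairs)
    return paired >= 3 and score > 0


def fold_cloverleaf(seq: str,
                    expected_anticodon: Optional[str] = None) -> CloverleafFold:
    """Best constrained cloverleaf layout of a tRNA sequence.

    Returns a fold-failure result (``foldable=False``, all arms absent)
    rather than raising when no feasible layout exists; raises
    :class:`FoldInputError` only for invalid characters.
    """
    dna, was_rna = _normalize(seq)
    N = len(dna)
    expected = (expected_anticodon.upper().replace("U", "T")
                if expected_anticodon else None)

    stem_cache: dict = {}

    def stem(i, j, n):
        key = (i, j, n)
        if key not in stem_cache:
            stem_cache[key] = _stem(dna, i, j, n)
        return stem_cache[key]

    best_key = None
    best = None

    for lead in range(min(MAX_LEAD, max(N - 14, 0)) + 1):
        for disc in range(MAX_DISCRIMINATOR + 1):
            acc3_start = N - disc - ACCEPTOR_STEM
            inner_start = lead + ACCEPTOR_STEM
            inner_len = acc3_start - inner_start
            if inner_len < 15:       # smallest possible AC arm + margins
                continue
            acc_pairs = stem(lead, acc3_start, ACCEPTOR_STEM)

            d_options = [("absent", 0, 0, u)
                         for u in range(D_ABSENT_RANGE[0], D_ABSENT_RANGE[1] + 1)]
            d_options += [("present", ds, dl, 2 * ds + dl)
                          for ds in range(D_STEM_RANGE[0], D_STEM_RANGE[1] + 1)
                          for dl in range(D_LOOP_RANGE[0], D_LOOP_RANGE[1] + 1)]
            t_options = [("absent", 0, 0, 0)]
            t_options += [("present", ts, tl, 2 * ts + tl)
                          for ts in range(T_STEM_RANGE[0], T_STEM_RANGE[1] + 1)
                          for tl in range(T_LOOP_RANGE[0], T_LOOP_RANGE[1] + 1)]

            for s1 in range(MAX_ARM_SPACER + 1):
                for dkind, dstem, dloop, dlen in d_options:
                    for s2 in range(MAX_ARM_SPACER + 1):
                        for astem in range(AC_STEM_RANGE[0], AC_STEM_RANGE[1] + 1):
                            aclen = 2 * astem + AC_LOOP
                            for tkind, tstem, tloop, tlen in t_options:
                                var = inner_len - s1 - dlen - s2 - aclen - tlen
                                if not (VAR_RANGE[0] <= var <= VAR_RANGE[1]):
                                    continue
                                d0 = inner_start + s1
                                ac0 = d0 + dlen + s2
                                acloop0 = ac0 + astem
                                t0 = ac0 + aclen + var

                                d_pairs = (stem(d0, d0 + dstem + dloop, dstem)
                                           if dkind == "present" else ())
                                ac_pairs = stem(ac0, acloop0 + AC_LOOP, astem)
                                t_pairs = (stem(t0, t0 + tstem + tloop, tstem)
                                           if tkind == "present" else ())
                                if dkind == "present" and not _arm_ok(d_pairs):
                                    continue
                                if tkind == "present" and not _arm_ok(t_pairs):
                                    continue

                                anticodon = dna[acloop0 + 2:acloop0 + 5]
                                ac_match = 1 if (expected and anticodon == expected) else 0

                                all_pairs = acc_pairs + d_pairs + ac_pairs + t_pairs
                                score, paired, mism = _stem_stats(all_pairs)
                                key = (ac_match, score, paired, -mism,
                                       -lead, -var)
                                if best_key is None or key > best_key:
                                    best_key = key
                                    best = (lead, disc, dkind, dstem, dloop,
                                            dlen, s1, s2, astem, tkind, tstem,
                                            tloop, var, d0, ac0, acloop0, t0,
                                            acc_pairs, d_pairs, ac_pairs,
                                            t_pairs, anticodon)

    out_seq = seq.strip().upper()
    if best is None:
        return CloverleafFold(
            sequence=out_seq, arms={},
            arm_present={"acceptor": False, "D": False,
                         "anticodon": False, "T": False},
            anticodon=None, anticodon_span=None, variable_span=(0, 0),
            total_score=0, foldable=False,
            flags=[f"no feasible cloverleaf layout for {N} nt sequence"])

    (lead, disc, dkind, dstem, dloop, dlen, s1, s2, astem, tkind, tstem,
     tloop, var, d0, ac0, acloop0, t0, acc_pairs, d_pairs, ac_pairs,
     t_pairs, anticodon) = best

    def back(p):  # report positions in the input alphabet (identity here)
        return list(p)

    arms = {
        "acceptor": Arm("acceptor", ACCEPTOR_STEM, back(acc_pairs),
                        (lead + ACCEPTOR_STEM, len(dna) - disc - ACCEPTOR_STEM),
                        _arm_ok(acc_pairs)),
        "anticodon": Arm("anticodon", astem, back(ac_pairs),
                         (acloop0, acloop0 + AC_LOOP), _arm_ok(ac_pairs)),
    }
    if dkind == "present":
        arms["D"] = Arm("D", dstem, back(d_pairs),
                        (d0 + dstem, d0 + dstem + dloop), _arm_ok(d_pairs))
    else:
        arms["D"] = Arm("D", 0, [], (d0, d0 + dlen), False)
    if tkind == "present":
        arms["T"] = Arm("T", tstem, back(t_pairs),
                        (t0 + tstem, t0 + tstem + tloop), _arm_ok(t_pairs))
    else:
        arms["T"] = Arm("T", 0, [], (t0, t0), False)

    if not (arms["acceptor"].present and arms["anticodon"].present):
        weak = [n for n in ("acceptor", "anticodon") if not arms[n].present]
        return CloverleafFold(
            sequence=out_seq, arms=arms,
            arm_present={"acceptor": False, "D": False,
                         "anticodon": False, "T": False},
            anticodon=None, anticodon_span=None, variable_span=(0, 0),
            total_score=sum(a.score for a in arms.values()), foldable=False,
            flags=[f"mandatory {n} stem cannot pair" for n in weak])

    display_anticodon = anticodon.replace("T", "U") if was_rna else anticodon
    flags = []
    if expected and anticodon != expected:
        flags.append(f"expected anticodon {expected_anticodon} not placeable "
                     f"centrally; best layout reads {display_anticodon}")
    fold = CloverleafFold(
        sequence=out_seq,
        arms=arms,
        arm_present={name: arms[name].present
                     for name in ("acceptor", "D", "anticodon", "T")},
        anticodon=display_anticodon,
        anticodon_span=(acloop0 + 2, acloop0 + 5),
        variable_span=(ac0 + 2 * astem + AC_LOOP, t0),
        total_score=sum(a.score for a in arms.values()),
        foldable=True, flags=flags)
    return fold


def mismatch_report(fold: CloverleafFold) -> List[Tuple[int, int, str]]:
    """All non-canonical pairs of a fold, with stem positions (0-based).
    G·U wobbles are classed separately and not reported as mismatches."""
    return [(i, j, "mismatch") for i, j, c in fold.all_pairs if c == "mismatch"]


# ---------------------------------------------------------------------------
# Anticodon validation
# ---------------------------------------------------------------------------

_AA1 = set("ACDEFGHIKLMNPQRSTVWY")
_AA3 = {"ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
        "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
        "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
        "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V"}

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def validate_anticodon(anticodon: str, amino_acid: str,
                       code: Optional[GeneticCode] = None) -> Tuple[bool, List[str]]:
    """Whether an anticodon decodes the given amino acid under a genetic code.

    The reverse complement of the anticodon, read 5'->3', is the primary
    codon; standard wobble at the codon third position is allowed
    (anticodon first base U pairs with A or G, G pairs with C or U).
    Returns (valid, matched codons as RNA strings).
    """
    code = code or GeneticCode.from_table(5)
    ac = anticodon.upper().replace("U", "T")
    if len(ac) != 3 or set(ac) - set("ACGT"):
        raise ValueError(f"not a valid anticodon: {anticodon!r}")
    aa = amino_acid.strip().upper()
    if len(aa) == 3 and aa in _AA3:
        aa = _AA3[aa]
    if aa not in _AA1:
        raise ValueError(f"unknown amino acid: {amino_acid!r}")

    primary = "".join(_COMP[b] for b in reversed(ac))
    third_options = {primary[2]}
    wobble_base = ac[0]
    if wobble_base == "T":
        third_options.update({"A", "G"})
    elif wobble_base == "G":
        third_options.update({"C", "T"})
    matched = []
    for third in sorted(third_options):
        codon = (primary[:2] + third).replace("T", "U")
        if code.codon_to_aa.get(codon) == aa:
            matched.append(codon)
    return bool(matched), matched


def fold_all_trnas(annotation) -> Dict[str, CloverleafFold]:
    """Batch fold every tRNA of an annotated sequence, passing each gene's
    annotated anticodon as the expected anticodon."""
    out = {}
    for g in annotation.genes_of("tRNA"):
        out[g.name] = fold_cloverleaf(annotation.gene_sequence(g.name),
                                      expected_anticodon=g.anticodon)
    return out
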