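# Methods

Definitions and conventions used by `mitochar`. All analyses operate on a
circular chromosome with 1-based inclusive coordinates; a gene whose end
coordinate is smaller than its start wraps through the origin.

## Annotation model

Genes carry a canonical label from the 37-gene metazoan vocabulary
(13 PCGs: COX1–3, ATP6/8, NAD1–6, NAD4L, CYTB; 2 rRNAs: rrnS, rrnL;
22 tRNAs: trnA…trnY with the duplicated leucine and serine tRNAs
distinguished as trnL1/trnL2 and trnS1/trnS2), a strand (H or L), a span,
and optional start/stop codons or anticodon. Raw names are normalized
through a synonym table (`COI`→`COX1`, `12S rRNA`→`rrnS`,
`tRNA-Ser2`→`trnS2`, …); the Leu/Ser copies are disambiguated by their
anticodons (TAG/TAA for Leu, GCT/TGA for Ser) when no explicit suffix is
given. Unknown labels pass through unchanged and are flagged by callers
rather than rejected. When a table prints a gene length that contradicts
its coordinates, the coordinates win and a warning is recorded.

For each adjacent pair on the circle (including the wrap-around pair) the
gap is `next.start − prev.end − 1`: positive values are intergenic
spacers, zero is an abutment, and negative values are overlaps. Gene
spans plus signed gaps always sum to the genome length (closure
invariant).

## Composition

Counts exclude ambiguity codes. AT-skew = (A−T)/(A+T) and
GC-skew = (G−C)/(G+C); a zero denominator yields NaN, negative inputs are
rejected. Whole-genome values are computed on the forward (H) strand.
Category pools (PCG, tRNA, rRNA) concatenate each gene's **sense**
strand: L-strand genes are reverse-complemented before pooling, so skews
describe the transcribed sequences. Both statistics are antisymmetric
under strand exchange, which the test suite checks as an identity.

## Codon usage

Coding sequences are extracted on the sense strand; trailing bases that
do not complete a codon are dropped with a warning. The genetic code is
taken from the NCBI tables (default table 5, invertebrate mitochondrial:
AGA/AGG = Ser giving an 8-codon serine family, UGA = Trp, stops
UAA/UAG). RSCU for codon *i* in synonymous family *F* is
`count_i × |F| / Σ_{j∈F} count_j`; families with no observations get
RSCU 0 and a flag. The two terminators are treated as their own 2-member
family so stop-codon usage is reported on the same scale. Codons per
thousand is `1000 × count / total`.

## Gene order

An arrangement is a circular signed permutation (+ = H strand). Orders
are compared after canonicalization: rotate COX1 first, reflecting the
circle (reverse order, flip all signs) if COX1 lies on the minus strand.
A signed adjacency is stored in an orientation-independent canonical
form; the breakpoint count is the number of query adjacencies absent
from the reference (symmetric). Synteny blocks are maximal runs of genes
contiguous in both orders; a run matching the reference in reversed
order with flipped signs is a single *inverted* block.

Event classification is a stated heuristic, not a minimal-scenario
solver. Co-oriented blocks that keep their circular order in both
arrangements form a maximum-weight anchor chain (weighted by gene
count); every remaining block is one event. An inverted block that sits
in its reference position is an **inversion**; a moved block is typed by
the genes its move crosses on the reference (shorter arc between origin
and insertion point): only tRNAs → **shuffling**, at least one PCG or
rRNA → **translocation**, and moved-plus-flipped blocks are
**inverted translocations**. The report carries a note that the scenario
is heuristic.

## tRNA cloverleaf

Folding is an exhaustive search over a constrained layout: 7 bp acceptor
stem with ≤2 leading bases and ≤2 discriminator bases, D arm (stem 3–4,
loop 4–12) or an unpaired region of ≤14 nt, anticodon stem 4–5 with a
loop of exactly 7 (anticodon = central triplet), variable region 3–23,
T arm (stem 4–5, loop 3–9) or absent, and ≤2 spacer bases between arms.
Pairs score +2 (Watson–Crick), +1 (G·U wobble) or −2 (mismatch); an arm
counts as present only with ≥3 non-mismatch pairs and a positive stem
score, and this same rule applies to the mandatory acceptor and
anticodon stems — a sequence whose best layout cannot pair them is
reported as unfoldable rather than given a degenerate "fold".
Candidates are ranked by (anticodon match if one is expected, total
score, pairs, fewer mismatches, less leading sequence, shorter variable
region). Stems are memoized so the search runs in well under a second
per tRNA.

## Supermatrix preparation

Per-gene nucleotide alignments (alignment itself is an input, not a step
performed here) are concatenated in a fixed canonical PCG order; taxa
missing a gene receive gap blocks and are flagged. Writers emit FASTA,
relaxed PHYLIP and NEXUS (with a `sets` block), a partition file
(default `GTR+F+R6` per gene, with the 1000-replicate ultrafast
bootstrap ML setting recorded as a comment) and a MrBayes block
(`nst=6 rates=invgamma`, 2,000,000 generations, sample frequency 1000,
two runs of four chains, 25% burn-in). All writers are deterministic and
round-trip through the bundled readers.

## Synthetic genomes

`generate_mitogenome` draws bases from a per-base categorical
distribution with P(A) = P(T) = AT/2. PCGs are built as start codon +
body codons (terminators rejected) + stop codon, so every generated PCG
is an open reading frame with no internal stops by construction. tRNAs
are instantiated from reverse-complement stem templates (71 nt with all
arms, 61 nt D-less, 58 nt T-less) with optional injected wobbles and
mismatches whose positions are returned as ground truth. Spacers are
drawn per adjacency, configured overlaps are honored, and a control
region absorbs the remainder so the realized circle length equals the
requested length exactly. Everything — codon counts, tRNA layouts, gene
order, seed — is returned in a truth bundle and emitted as GenBank,
FASTA, gene table and JSON. The rearrangement simulator applies typed
events to a signed order and returns the exact log; sampled shuffling
events use all-tRNA blocks so their type is well-defined no matter which
side of the swap a classifier treats as the mover. A single seeded
generator drives all randomness; no global random state is touched.
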