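import pytest
from hypothesis import given, strategies as st

import mitochar as m
from mitochar.annotation import AnnotationError


# ---------------------------------------------------------------------------
# Gene-name normalization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("raw,want", [
    ("COX1", "COX1"), ("cox1", "COX1"), ("COI", "COX1"), ("CO1", "COX1"),
    ("Cytb", "CYTB"), ("COB", "CYTB"), ("cytochrome b", "CYTB"),
    ("NAD4l", "NAD4L"), ("ND4L", "NAD4L"), ("nad4", "NAD4"),
    ("ATPase6", "ATP6"), ("ATP8", "ATP8"),
    ("12S rRNA", "rrnS"), ("16S rRNA", "rrnL"), ("srRNA", "rrnS"),
    ("rrnL", "rrnL"),
    ("tRNA-Met", "trnM"), ("trnM", "trnM"), ("tRNA-Ser2", "trnS2"),
    ("tRNA-Leu1", "trnL1"), ("trnW", "trnW"),
])
def test_normalize_gene_name(raw, want):
    assert m.normalize_gene_name(raw) == want


def test_normalize_leu_ser_by_anticodon():
    assert m.normalize_gene_name("tRNA-Leu", anticodon="TAG") == "trnL1"
    assert m.normalize_gene_name("tRNA-Leu", anticodon="TAA") == "trnL2"
    assert m.normalize_gene_name("tRNA-Ser", anticodon="GCT") == "trnS1"
    assert m.normalize_gene_name("tRNA-Ser", anticodon="TGA") == "trnS2"


def test_normalize_unknown_passes_through():
    # normalization never fails; unknown labels survive for callers to flag
    assert m.normalize_gene_name("NAD9") == "NAD9"
    assert m.gene_category("NAD9") == "other"


def test_gene_category():
    assert m.gene_category("COX1") == "PCG"
    assert m.gene_category("rrnS") == "rRNA"
    assert m.gene_category("trnS2") == "tRNA"


# ---------------------------------------------------------------------------
# Coordinates on the circle
# ---------------------------------------------------------------------------

def test_gene_span_length_linear():
    assert m.gene_span_length(1, 1551, 16608) == 1551


def test_gene_span_length_wrapping():
    # wraps the origin: tail of the circle plus the head
    assert m.gene_span_length(16500, 30, 16608) == 139


def test_slice_circular_wraps():
    seq = "ABCDEFGHIJ"
    assert m.slice_circular(seq, 9, 2) == "IJAB"
    assert m.slice_circular(seq, 3, 5) == "CDE"


def test_reverse_complement():
    assert m.reverse_complement("ATGC") == "GCAT"
    assert m.reverse_complement(m.reverse_complement("AATTGGCC")) == "AATTGGCC"


# ---------------------------------------------------------------------------
# Gene-table parsing
# ---------------------------------------------------------------------------

def test_parse_fixture_census(desmaulus):
    assert desmaulus.genome_length == 16608
    assert len(desmaulus.genes) == 37
    s = m.summarize(desmaulus)
    assert s["counts_by_category"] == {"PCG": 13, "tRNA": 22, "rRNA": 2}
    assert s["counts_by_strand"] == {"H": 29, "L": 8}


def test_fixture_names_normalized(desmaulus):
    names = {g.name for g in desmaulus.genes}
    assert "CYTB" in names and "NAD4L" in names
    assert "rrnS" in names and "rrnL" in names
    assert "trnS1" in names and "trnS2" in names


def test_parse_rejects_duplicates():
    text = ("gene\tstrand\tstart\tend\n"
            "COX1\tH\t1\t100\nCOI\tH\t200\t300\n")
    with pytest.raises(AnnotationError, match="duplicate"):
        m.parse_gene_table(text, genome_length=1000)


def test_parse_rejects_bad_coordinates():
    text = "gene\tstrand\tstart\tend\nCOX1\tH\t0\t100\n"
    with pytest.raises(AnnotationError):
        m.parse_gene_table(text, genome_length=1000)


def test_parse_rejects_out_of_range():
    text = "gene\tstrand\tstart\tend\nCOX1\tH\t1\t2000\n"
    with pytest.raises(AnnotationError):
        m.parse_gene_table(text, genome_length=1000)


def test_parse_empty_table():
    with pytest.raises(AnnotationError, match="empty"):
        m.parse_gene_table("gene\tstrand\tstart\tend\n", genome_length=100)


def test_printed_length_mismatch_warns_not_raises():
    # coordinates are authoritative; a contradictory printed length column
    # produces a warning, not an error
    text = ("gene\tstrand\tstart\tend\tlength\n"
            "COX1\tH\t1\t99\t1551\n")
    a = m.parse_gene_table(text, genome_length=1000)
    assert a.gene("COX1").length == 99
    assert any("length" in w for w in a.warnings)


def test_emit_parse_round_trip(desmaulus):
    text = m.emit_gene_table(desmaulus)
    again = m.parse_gene_table(text)
    assert again.genome_length == desmaulus.genome_length
    for g in desmaulus.genes:
        h = again.gene(g.name)
        assert (h.strand, h.start, h.end, h.anticodon) == \
               (g.strand, g.start, g.end, g.anticodon)


# ---------------------------------------------------------------------------
# Spacers and overlaps
# ---------------------------------------------------------------------------

def test_fixture_overlaps(desmaulus):
    rep = m.spacers_and_overlaps(desmaulus)
    overlaps = {(p.upstream, p.downstream): -p.gap for p in rep.overlaps}
    assert overlaps == {("trnW", "trnQ"): 2, ("trnG", "trnE"): 1,
                        ("rrnS", "trnV"): 1, ("trnV", "rrnL"): 10}


def test_fixture_max_spacer(desmaulus):
    rep = m.spacers_and_overlaps(desmaulus)
    p = rep.max_spacer
    assert (p.upstream, p.downstream, p.gap) == ("trnF", "trnT", 648)


def test_spacer_closure(desmaulus):
    # walking every adjacent pair around the circle accounts for every
    # position exactly once: gene spans plus signed gaps sum to the circle
    rep = m.spacers_and_overlaps(desmaulus)
    span = sum(g.length for g in desmaulus.genes)
    gaps = sum(p.gap for p in rep.pairs)
    assert span + gaps == desmaulus.genome_length
    assert len(rep.pairs) == len(desmaulus.genes)


def test_spacer_closure_synthetic(synthetic):
    a = synthetic.annotation
    rep = m.spacers_and_overlaps(a)
    assert sum(g.length for g in a.genes) + sum(p.gap for p in rep.pairs) \
        == a.genome_length


def test_spacers_need_two_genes():
    a = m.parse_gene_table("gene\tstrand\tstart\tend\nCOX1\tH\t1\t99\n",
                           genome_length=1000)
    with pytest.raises(AnnotationError):
        m.spacers_and_overlaps(a)


# ---------------------------------------------------------------------------
# Census numbers
# ---------------------------------------------------------------------------

def test_fixture_lengths(desmaulus):
    s = m.summarize(desmaulus)
    assert s["length_by_category"] == {"PCG": 11394, "tRNA": 1485,
                                       "rRNA": 2260}
    assert s["longest_gene"] == {"name": "NAD5", "length": 1872}
    assert s["shortest_gene"] == {"name": "trnA", "length": 51}


def test_gene_sequence_needs_sequence(desmaulus):
    with pytest.raises(AnnotationError):
        desmaulus.gene_sequence("COX1")


def test_gene_sequence_sense_strand(synthetic):
    a = synthetic.annotation
    for g in a.genes:
        seq = a.gene_sequence(g.name)
        assert len(seq) == g.length
        if g.strand == "H" and not g.wraps:
            assert seq == a.sequence[g.start - 1:g.end]


@given(start=st.integers(1, 300), length=st.integers(1, 300))
def test_span_length_wrap_consistency(start, length):
    # a span of `length` positions starting anywhere on a 300-circle
    # always measures `length`
    end = (start + length - 1 - 1) % 300 + 1
    assert m.gene_span_length(start, end, 300) == length
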