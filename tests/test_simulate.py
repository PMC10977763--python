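import json
from collections import Counter

import pytest

import mitochar as m
from mitochar.simulate import GenomeSpec, SpecError

from conftest import GENOME_SEED


# ---------------------------------------------------------------------------
# Spec validation
# ---------------------------------------------------------------------------

def test_bad_at_content():
    with pytest.raises(SpecError):
        GenomeSpec(at_content=1.5)


def test_pcg_length_not_codon_multiple():
    with pytest.raises(SpecError):
        GenomeSpec(pcg_lengths={"COX1": 1000})


def test_infeasible_genome_length():
    with pytest.raises(SpecError):
        m.generate_mitogenome(GenomeSpec(genome_length=5000))


# ---------------------------------------------------------------------------
# Whole-genome generation
# ---------------------------------------------------------------------------

def test_deterministic_under_seed(synthetic):
    again = m.generate_mitogenome(seed=GENOME_SEED)
    assert again.sequence == synthetic.sequence
    assert [(g.name, g.start, g.end, g.strand) for g in
            again.annotation.genes] == \
           [(g.name, g.start, g.end, g.strand) for g in
            synthetic.annotation.genes]


def test_different_seeds_differ():
    a = m.generate_mitogenome(seed=1)
    b = m.generate_mitogenome(seed=2)
    assert a.sequence != b.sequence


def test_realized_length_exact(synthetic):
    assert len(synthetic.sequence) == 16000
    assert synthetic.annotation.genome_length == 16000


def test_gene_census(synthetic):
    s = m.summarize(synthetic.annotation)
    assert s["counts_by_category"] == {"PCG": 13, "tRNA": 22, "rRNA": 2}


def test_at_content_within_two_points(synthetic):
    at = m.composition.profile_sequence(synthetic.sequence).at_content
    assert abs(at - 70.0) < 2.0


def test_pcgs_are_clean_orfs(synthetic, code5):
    for g in synthetic.annotation.genes_of("PCG"):
        cds = m.extract_cds(synthetic.annotation, g.name)
        assert len(cds) % 3 == 0
        inner = [cds[i:i + 3] for i in range(3, len(cds) - 3, 3)]
        assert not any(code5.is_stop(c) for c in inner), g.name
        assert code5.is_stop(cds[-3:])


def test_codon_truth(synthetic):
    counts = m.count_codons([m.extract_cds(synthetic.annotation, g.name)
                             for g in synthetic.annotation.genes_of("PCG")])
    assert counts == Counter(synthetic.truth["codon_counts"])


def test_gene_order_matches_default(synthetic, desmaulus):
    q = m.order_from_annotation(synthetic.annotation)
    assert q.equivalent(m.order_from_annotation(desmaulus))


def test_custom_order_respected(ancestral):
    g = m.generate_mitogenome(GenomeSpec(gene_order="ancestral", seed=5))
    assert m.order_from_annotation(g.annotation).equivalent(ancestral)


def test_configured_overlap_realized():
    spec = GenomeSpec(overlaps={("COX1", "COX2"): 4}, seed=6)
    g = m.generate_mitogenome(spec)
    rep = m.spacers_and_overlaps(g.annotation)
    pair = next(p for p in rep.pairs
                if (p.upstream, p.downstream) == ("COX1", "COX2"))
    assert pair.gap == -4


# ---------------------------------------------------------------------------
# tRNA templates
# ---------------------------------------------------------------------------

def test_template_lengths():
    assert len(m.generate_trna(seed=0).sequence) == 71
    assert len(m.generate_trna(arm_config=("acceptor", "anticodon", "T"),
                               seed=0).sequence) == 61
    assert len(m.generate_trna(arm_config=("acceptor", "D", "anticodon"),
                               seed=0).sequence) == 58


def test_template_requires_mandatory_arms():
    with pytest.raises(SpecError):
        m.generate_trna(arm_config=("acceptor",))


def test_template_anticodon_placed():
    t = m.generate_trna(seed=3, anticodon="GTT")
    i, j = t.anticodon_span
    assert t.sequence[i:j] == "GTT"


# ---------------------------------------------------------------------------
# Event application
# ---------------------------------------------------------------------------

def test_apply_empty_events(ancestral):
    out, log = m.apply_rearrangements(ancestral, [])
    assert out.genes == ancestral.genes and log == []


def test_apply_inversion_involution(ancestral):
    ev = [m.SimEvent("inversion", ("NAD4", "NAD4L"))]
    once, _ = m.apply_rearrangements(ancestral, ev)
    twice, _ = m.apply_rearrangements(once, ev)
    assert twice.genes == ancestral.genes


def test_apply_overlapping_blocks_rejected(ancestral):
    ev = [m.SimEvent("inversion", ("NAD4", "NAD4L")),
          m.SimEvent("inversion", ("NAD4L", "NAD4"))]
    with pytest.raises(m.GeneOrderError):
        m.apply_rearrangements(ancestral, ev)
    out, log = m.apply_rearrangements(ancestral, ev, allow_overlap=True)
    assert len(log) == 2


def test_apply_unknown_label(ancestral):
    with pytest.raises(m.GeneOrderError):
        m.apply_rearrangements(ancestral, [m.SimEvent("inversion",
                                                      ("NAD9",))])


def test_sample_events_reproducible(ancestral):
    a = m.sample_events(ancestral, k=3, seed=12)
    b = m.sample_events(ancestral, k=3, seed=12)
    assert a == b
    assert len(a) == 3


# ---------------------------------------------------------------------------
# Artifact round trips
# ---------------------------------------------------------------------------

def test_genbank_round_trip(synthetic):
    text = m.annotation_to_genbank(synthetic.annotation)
    again = m.parse_genbank(text)
    for g in synthetic.annotation.genes:
        h = again.gene(g.name)
        assert (h.start, h.end, h.strand) == (g.start, g.end, g.strand)
        if g.anticodon:
            assert h.anticodon == g.anticodon
    assert again.sequence == synthetic.annotation.sequence


def test_fasta_emission(synthetic):
    text = m.annotation_to_fasta(synthetic.annotation)
    body = "".join(text.splitlines()[1:])
    assert body == synthetic.annotation.sequence


def test_truth_json_parses(synthetic):
    d = json.loads(m.truth_to_json(synthetic))
    assert d["seed"] == synthetic.truth["seed"]
    assert "codon_counts" in d and "trnas" in d
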