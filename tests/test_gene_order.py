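from collections import Counter

import pytest
from hypothesis import given, strategies as st

import mitochar as m
from mitochar.gene_order import GeneOrderError, SignedGeneOrder

SMALL = SignedGeneOrder((("COX1", 1), ("trnA", 1), ("NAD1", 1),
                         ("trnB", -1), ("rrnS", 1), ("trnC", 1)))


# ---------------------------------------------------------------------------
# Signed circular orders
# ---------------------------------------------------------------------------

def test_duplicate_labels_rejected():
    with pytest.raises(GeneOrderError, match="duplicate"):
        SignedGeneOrder((("COX1", 1), ("COX1", -1)))


def test_canonical_puts_anchor_first_plus():
    rotated = SMALL.rotate(3)
    c = rotated.canonical()
    assert c.genes[0] == ("COX1", 1)
    assert c.genes == SMALL.genes


def test_canonical_reflects_when_anchor_on_minus():
    flipped = SMALL.reflect()
    assert flipped.sign_of("COX1") == -1
    assert flipped.canonical().genes == SMALL.genes


@given(k=st.integers(0, 11), refl=st.booleans())
def test_equivalence_under_rotation_and_reflection(k, refl):
    other = SMALL.rotate(k)
    if refl:
        other = other.reflect()
    assert SMALL.equivalent(other)
    assert other.equivalent(SMALL)


def test_text_round_trip(ancestral):
    assert SignedGeneOrder.from_text(ancestral.to_text()).genes \
        == ancestral.genes


def test_from_text_rejects_garbage():
    with pytest.raises(GeneOrderError):
        SignedGeneOrder.from_text("COX1 plus\n")


def test_order_from_annotation(desmaulus):
    order = m.order_from_annotation(desmaulus)
    assert order.genes[0] == ("COX1", 1)
    assert len(order) == 37
    assert order.sign_of("trnT") == -1


# ---------------------------------------------------------------------------
# Breakpoints
# ---------------------------------------------------------------------------

def test_breakpoints_identity(ancestral):
    n, shared = m.breakpoints(ancestral, ancestral)
    assert n == 0
    assert len(shared) == len(ancestral)


def test_breakpoints_rotation_invariant(ancestral):
    n, _ = m.breakpoints(ancestral.rotate(7), ancestral.reflect())
    assert n == 0


def test_breakpoints_single_inversion():
    # inverting an internal block breaks exactly the two flanking
    # adjacencies
    q = m.invert_block(SMALL, 2, 5)
    n, _ = m.breakpoints(q, SMALL)
    assert n == 2


def test_breakpoints_single_move():
    # excising one gene and reinserting it elsewhere breaks three
    # adjacencies
    q = m.move_block(SMALL, 1, 2, 4)
    n, _ = m.breakpoints(q, SMALL)
    assert n == 3


def test_breakpoints_symmetric(desmaulus, ancestral):
    q = m.order_from_annotation(desmaulus)
    assert m.breakpoints(q, ancestral)[0] == m.breakpoints(ancestral, q)[0]


def test_label_mismatch_raises(ancestral):
    with pytest.raises(GeneOrderError, match="label sets differ"):
        m.breakpoints(SMALL, ancestral)


# ---------------------------------------------------------------------------
# Synteny blocks
# ---------------------------------------------------------------------------

def test_blocks_partition_genes(desmaulus, ancestral):
    q = m.order_from_annotation(desmaulus)
    blocks = m.synteny_blocks(q.canonical(), ancestral.canonical())
    labels = [g for b in blocks for g in b.labels]
    assert sorted(labels) == sorted(q.labels)


def test_identical_orders_one_block(ancestral):
    blocks = m.synteny_blocks(ancestral, ancestral)
    assert len(blocks) == 1 and not blocks[0].inverted


def test_inverted_block_detected():
    q = m.invert_block(SMALL, 2, 5)
    blocks = m.synteny_blocks(q, SMALL)
    inv = [b for b in blocks if b.inverted]
    assert len(inv) == 1
    assert inv[0].labels == ["rrnS", "trnB", "NAD1"]


# ---------------------------------------------------------------------------
# Event classification on the packaged pair
# ---------------------------------------------------------------------------

def test_organism_vs_ancestral_events(desmaulus, ancestral):
    q = m.order_from_annotation(desmaulus)
    rep = m.classify_events(q, ancestral)
    assert rep.breakpoint_count == 6
    types = Counter(e.type for e in rep.events)
    assert types == Counter({"inverted_translocation": 3, "inversion": 1})

    cluster = next(e for e in rep.events
                   if e.genes == ["trnM", "trnY", "trnC", "trnW",
                                  "trnQ", "trnG", "trnE"])
    assert cluster.type == "inverted_translocation"
    assert "downstream of ATP6" in cluster.description

    moved = {g for e in rep.events for g in e.genes}
    assert {"NAD5", "NAD4", "NAD4L", "CYTB", "NAD6",
            "NAD1", "rrnL", "rrnS"} <= moved


def test_identical_orders_no_events(ancestral):
    rep = m.classify_events(ancestral, ancestral)
    assert rep.events == [] and rep.breakpoint_count == 0


def test_report_serializable(desmaulus, ancestral):
    import json
    rep = m.classify_events(m.order_from_annotation(desmaulus), ancestral)
    d = json.loads(json.dumps(rep.as_dict()))
    assert d["scenario_length"] == len(rep.events)
    assert "heuristic" in d["note"]


def test_render_diff_mentions_all_genes(desmaulus, ancestral):
    q = m.order_from_annotation(desmaulus)
    text = m.render_diff(q, ancestral)
    for label in q.labels:
        assert label in text


# ---------------------------------------------------------------------------
# Rearrangement primitives
# ---------------------------------------------------------------------------

def test_invert_block_involution(ancestral):
    assert m.invert_block(m.invert_block(ancestral, 3, 9), 3, 9).genes \
        == ancestral.genes


def test_move_block_rejects_inner_destination():
    with pytest.raises(GeneOrderError):
        m.move_block(SMALL, 1, 4, 2)


def test_move_block_preserves_content():
    q = m.move_block(SMALL, 1, 3, 5, flip=True)
    assert sorted(q.labels) == sorted(SMALL.labels)


# ---------------------------------------------------------------------------
# Seeded generator + classifier recovery (smoke; the full-rate check lives
# in the acceptance tests)
# ---------------------------------------------------------------------------

def test_sampled_events_recovered():
    ref = m.datasets.ancestral_gastropod_order()
    for seed in range(10):
        events = m.sample_events(ref, k=2, seed=seed)
        q, log = m.apply_rearrangements(ref, events)
        rep = m.classify_events(q, ref)
        assert Counter(e.type for e in rep.events) == \
            Counter(e.type for e in events), f"seed {seed}"
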