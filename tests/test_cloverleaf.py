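import pytest

import mitochar as m
from mitochar.cloverleaf import FoldInputError, pair_class


# ---------------------------------------------------------------------------
# Pair classification
# ---------------------------------------------------------------------------

def test_pair_classes():
    assert pair_class("A", "T") == "WC"
    assert pair_class("G", "C") == "WC"
    assert pair_class("G", "T") == "wobble"
    assert pair_class("T", "G") == "wobble"
    assert pair_class("A", "G") == "mismatch"


# ---------------------------------------------------------------------------
# Folding generated templates (construction oracle)
# ---------------------------------------------------------------------------

def test_all_arms_template_recovers_four_arms():
    t = m.generate_trna(seed=1, anticodon="CAT")
    f = m.fold_cloverleaf(t.sequence)
    assert f.foldable
    assert all(f.arm_present[a] for a in ("acceptor", "D", "anticodon", "T"))
    assert f.anticodon == t.anticodon


def test_d_less_template():
    t = m.generate_trna(arm_config=("acceptor", "anticodon", "T"),
                        seed=2, anticodon="TGA")
    f = m.fold_cloverleaf(t.sequence)
    assert f.foldable
    assert not f.arm_present["D"]
    assert f.arm_present["T"] and f.arm_present["anticodon"]


def test_t_less_template():
    t = m.generate_trna(arm_config=("acceptor", "D", "anticodon"),
                        seed=3, anticodon="TGC")
    f = m.fold_cloverleaf(t.sequence)
    assert f.foldable
    assert not f.arm_present["T"]
    assert f.arm_present["D"]


def test_configured_mismatch_found():
    t = m.generate_trna(seed=4, anticodon="GAT", n_mismatches=1)
    f = m.fold_cloverleaf(t.sequence, expected_anticodon="GAT")
    assert f.foldable
    found = {(i, j) for i, j, _ in m.mismatch_report(f)}
    assert set(t.mismatch_positions) <= found


def test_configured_wobble_found():
    t = m.generate_trna(seed=5, anticodon="GAA", n_wobbles=1)
    f = m.fold_cloverleaf(t.sequence, expected_anticodon="GAA")
    wobbles = {(i, j) for i, j, c in f.all_pairs if c == "wobble"}
    assert set(t.wobble_positions) <= wobbles


def test_anticodon_span_matches_template():
    t = m.generate_trna(seed=6, anticodon="TTC")
    f = m.fold_cloverleaf(t.sequence, expected_anticodon="TTC")
    assert f.anticodon_span == t.anticodon_span


# ---------------------------------------------------------------------------
# Fold behaviour
# ---------------------------------------------------------------------------

def test_deterministic():
    t = m.generate_trna(seed=7)
    f1 = m.fold_cloverleaf(t.sequence)
    f2 = m.fold_cloverleaf(t.sequence)
    assert f1.as_dict() == f2.as_dict()


def test_unfoldable_returns_failure_not_exception():
    f = m.fold_cloverleaf("A" * 70)
    assert not f.foldable
    assert all(not v for v in f.arm_present.values())


def test_invalid_characters_raise():
    with pytest.raises(FoldInputError):
        m.fold_cloverleaf("ACGTXACGT" * 8)


def test_rna_input_accepted():
    t = m.generate_trna(seed=8, anticodon="CAT")
    rna = t.sequence.replace("T", "U")
    f = m.fold_cloverleaf(rna)
    assert f.foldable
    assert f.anticodon == "CAU"   # reported in the input alphabet


def test_dot_bracket_balanced():
    t = m.generate_trna(seed=9)
    f = m.fold_cloverleaf(t.sequence)
    db = f.dot_bracket()
    assert len(db) == len(t.sequence)
    assert db.count("(") == db.count(")")


# ---------------------------------------------------------------------------
# Anticodon/amino-acid consistency
# ---------------------------------------------------------------------------

def test_validate_anticodon_met(code5):
    ok, codons = m.validate_anticodon("CAT", "M", code5)
    assert ok and "AUG" in codons


def test_validate_anticodon_trp_wobble(code5):
    # anticodon TCA reads both UGA and UGG as tryptophan under this code
    ok, codons = m.validate_anticodon("TCA", "W", code5)
    assert ok
    assert {"UGA", "UGG"} & set(codons)


def test_validate_anticodon_wrong_amino_acid(code5):
    ok, _ = m.validate_anticodon("CAT", "K", code5)
    assert not ok


# ---------------------------------------------------------------------------
# Batch folding of an annotated genome
# ---------------------------------------------------------------------------

def test_fold_all_trnas_synthetic(synthetic):
    folds = m.fold_all_trnas(synthetic.annotation)
    assert len(folds) == 22
    assert all(f.foldable for f in folds.values())
    for name, f in folds.items():
        assert f.anticodon == synthetic.annotation.gene(name).anticodon
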