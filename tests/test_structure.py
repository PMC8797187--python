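"""Folding DP vs exhaustive enumeration; dot-bracket I/O; dsRNA stretch logic."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from adarcall.structure import (
    SecondaryStructure,
    StructureConfig,
    StructureError,
    fold_builtin,
    helix_stretch,
    load_external_structure,
    parse_dot_bracket,
    site_pairing,
)

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def can_pair(a: str, b: str) -> bool:
    return (a.replace("T", "U"), b.replace("T", "U")) in _PAIRS


def exhaustive_max_pairs(seq: str, i: int, j: int, min_loop: int = 3) -> int:
    """Plain recursive enumeration over all nested structures (no memo)."""
    if j - i <= min_loop:
        return 0
    best = exhaustive_max_pairs(seq, i, j - 1, min_loop)
    for k in range(i, j - min_loop):
        if can_pair(seq[k], seq[j]):
            v = 1
            if k > i:
                v += exhaustive_max_pairs(seq, i, k - 1, min_loop)
            v += exhaustive_max_pairs(seq, k + 1, j - 1, min_loop)
            best = max(best, v)
    return best


def structure_from(db: str) -> SecondaryStructure:
    return SecondaryStructure(None, (0, len(db)), parse_dot_bracket(db))


class TestFoldBuiltin:
    def test_short_sequence_all_unpaired(self):
        assert fold_builtin("AAAA").dot_bracket == "...."

    def test_ggg_cccc_hairpin(self):
        st = fold_builtin("GGGAAAACCC")
        assert st.n_pairs == 3

    def test_rejects_non_nucleotides(self):
        with pytest.raises(StructureError):
            fold_builtin("ACGX")

    def test_pair_count_equals_exhaustive_enumeration_1000_seqs(self):
        rng = np.random.default_rng(31)
        for _ in range(1000):
            n = int(rng.integers(1, 13))
            seq = "".join(rng.choice(list("ACGU"), n))
            st = fold_builtin(seq)
            assert st.n_pairs == exhaustive_max_pairs(seq, 0, n - 1), seq

    def test_involution_on_random_folds(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGU"), int(rng.integers(20, 80))))
            st = fold_builtin(seq)
            p = st.partner
            paired = np.nonzero(p >= 0)[0]
            assert np.array_equal(p[p[paired]], paired)

    def test_loops_respect_min_loop(self):
        rng = np.random.default_rng(15)
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGU"), 40))
            p = fold_builtin(seq).partner
            for i, j in enumerate(p):
                if j > i:
                    assert j - i > 3  # min_loop unpaired bases between pair ends


class TestDotBracketIO:
    def test_nested_parse(self):
        p = parse_dot_bracket("(((...)))")
        assert p[0] == 8 and p[1] == 7 and p[2] == 6 and p[4] == -1

    def test_all_unpaired(self):
        assert (parse_dot_bracket(".........") == -1).all()

    @pytest.mark.parametrize("bad", ["(((", "))", "((.[).]"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(StructureError):
            parse_dot_bracket(bad)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGU"), int(rng.integers(15, 60))))
            db = fold_builtin(seq).dot_bracket
            assert structure_from(db).dot_bracket == db

    def test_load_vienna_file(self, tmp_path):
        f = tmp_path / "fold.db"
        f.write_text(">t1\nGGGAAAACCC\n(((....))) (-1.20)\n")
        st = load_external_structure(f)
        assert st.transcript_id == "t1"
        assert st.sequence == "GGGAAAACCC"
        assert st.n_pairs == 3

    def test_load_length_mismatch(self, tmp_path):
        f = tmp_path / "bad.db"
        f.write_text("GGGAAAACCC\n((...))\n")
        with pytest.raises(StructureError, match="length"):
            load_external_structure(f)

    def test_agrees_with_thermodynamic_folder(self, tmp_path):
        """An RNAfold-produced structure loads and annotates identically."""
        RNA = pytest.importorskip("RNA")
        seq = "GGGGAAAACCCCAUAUAUGCGCGC"
        db, _ = RNA.fold(seq)
        f = tmp_path / "rnafold.db"
        f.write_text(f"{seq}\n{db}\n")
        st = load_external_structure(f)
        assert st.dot_bracket == db
        for pos in range(len(seq)):
            paired, partner = site_pairing(st, pos)
            assert paired == (db[pos] != ".")


@st_.composite
def balanced_dot_bracket(draw, max_depth=4):
    """Arbitrary well-nested structure with >= 3 dots inside every pair."""
    def block(depth):
        kind = draw(st_.integers(0, 2 if depth < max_depth else 1))
        if kind == 0:
            return "." * draw(st_.integers(1, 4))
        if kind == 1:
            return "." * draw(st_.integers(0, 3)) + "." * 3
        inner = "".join(block(depth + 1) for _ in range(draw(st_.integers(1, 2))))
        return "(" + ("..." if len(inner) < 3 else inner) + ")"

    return "".join(block(0) for _ in range(draw(st_.integers(1, 4))))


@settings(derandomize=True, max_examples=100)
@given(balanced_dot_bracket())
def test_parse_round_trip_and_involution_on_arbitrary_structures(db):
    st = structure_from(db)
    assert st.dot_bracket == db
    p = st.partner
    for i in np.nonzero(p >= 0)[0]:
        assert p[p[i]] == i and p[i] != i


class TestSitePairing:
    def test_pairing_lookup(self):
        st = structure_from("(((...)))")
        assert site_pairing(st, 0) == (True, 8)
        assert site_pairing(st, 4) == (False, None)
        assert site_pairing(st, 8) == (True, 0)

    def test_out_of_window_raises(self):
        st = structure_from("(((...)))")
        with pytest.raises(StructureError):
            site_pairing(st, 9)

    def test_window_offset_coordinates(self):
        st = SecondaryStructure(None, (100, 109), parse_dot_bracket("(((...)))"))
        assert site_pairing(st, 100) == (True, 108)


def brute_force_stretch(partner: np.ndarray, pos: int, min_frac: float) -> int:
    """O(L^2) interval enumeration with per-interval recount (the slow oracle)."""
    if partner[pos] < 0:
        return 0
    n = len(partner)
    best = 1
    for a in range(pos + 1):
        if partner[a] < 0:
            continue
        for b in range(pos, n):
            if partner[b] < 0:
                continue
            paired = sum(1 for k in range(a, b + 1) if partner[k] >= 0)
            if paired / (b - a + 1) >= min_frac:
                best = max(best, b - a + 1)
    return best


class TestHelixStretch:
    def test_perfect_helix_arm(self):
        st = structure_from("((((...))))")
        assert helix_stretch(st, 1) == 4

    def test_unpaired_site_is_zero(self):
        st = structure_from("((((...))))")
        assert helix_stretch(st, 5) == 0

    def test_bulged_helix_spans_bulge_at_80_percent(self):
        st = structure_from("(((.(((...))).)))")
        assert helix_stretch(st, 5) >= 7  # [0,6] has 6/7 paired
        assert helix_stretch(st, 5) == brute_force_stretch(st.partner, 5, 0.8)

    def test_matches_brute_force_on_100_random_structures(self):
        rng = np.random.default_rng(47)
        cfg = StructureConfig()
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGU"), int(rng.integers(20, 61))))
            st = fold_builtin(seq, cfg)
            pos = int(rng.integers(0, len(seq)))
            assert helix_stretch(st, pos, cfg) == brute_force_stretch(
                st.partner, pos, cfg.min_paired_frac
            )

    def test_monotone_in_min_paired_frac(self):
        rng = np.random.default_rng(51)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGU"), 50))
            st = fold_builtin(seq)
            paired_pos = np.nonzero(st.partner >= 0)[0]
            if len(paired_pos) == 0:
                continue
            pos = int(paired_pos[0])
            prev = None
            for frac in (0.5, 0.7, 0.8, 0.9, 1.0):
                s = helix_stretch(st, pos, StructureConfig(min_paired_frac=frac))
                if prev is not None:
                    assert s <= prev
                prev = s
            assert prev >= 1  # paired site always has stretch >= 1
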