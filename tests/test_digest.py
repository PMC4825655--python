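"""Cut coordinates, fragment enumeration, and GBS selection rules."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igc_gbs.catalog import EnzymeSpec
from igc_gbs.digest import (
    CHROM_END,
    CutSite,
    Fragment,
    cut_positions,
    enumerate_fragments,
    fragments_to_bed,
    select_fragments,
)

from conftest import ORACLE_IUPAC, oracle_rc

TOY25 = "CCCATGCCCCCAATTCCCCCATGCC"


def oracle_fragments(sequence, enzyme_list, terminal_policy="include"):
    """Independent slicing oracle: per-position IUPAC matching + offset arithmetic."""
    labels = {}
    for enz in enzyme_list:
        pats = [(enz.recognition, enz.cut_offset)]
        rc = oracle_rc(enz.recognition)
        if rc != enz.recognition:
            pats.append((rc, enz.site_length - enz.cut_offset))
        for pat, off in pats:
            for p in range(len(sequence) - len(pat) + 1):
                if all(sequence[p + i] in ORACLE_IUPAC[c] for i, c in enumerate(pat)):
                    labels.setdefault(p + off, set()).add(enz.name)
    bounds = [(0, {CHROM_END})] + sorted(labels.items()) + [(len(sequence), {CHROM_END})]
    out = []
    for (s, left), (e, right) in zip(bounds, bounds[1:]):
        if e - s < 1:
            continue
        if terminal_policy == "exclude" and (CHROM_END in left or CHROM_END in right):
            continue
        out.append((s, e, frozenset(left), frozenset(right)))
    return out


class TestCutPositions:
    def test_single_enzyme_offsets(self, enzymes):
        cuts = cut_positions("CATGCATGCATG", enzymes["CviAII"])
        assert [(c.position, set(c.enzymes)) for c in cuts] == [
            (1, {"CviAII"}), (5, {"CviAII"}), (9, {"CviAII"}),
        ]

    def test_pair_on_toy25(self, enzymes):
        cuts = cut_positions(TOY25, [enzymes["CviAII"], enzymes["MluCI"]])
        assert [(c.position, set(c.enzymes)) for c in cuts] == [
            (3, {"CviAII"}), (11, {"MluCI"}), (20, {"CviAII"}),
        ]

    def test_shared_coordinate_carries_both_labels(self):
        a, b = EnzymeSpec("A", "AACG", 2), EnzymeSpec("B", "ACGT", 1)
        cuts = cut_positions("TAACGTT", [a, b], strands="forward")
        assert [(c.position, set(c.enzymes)) for c in cuts] == [(3, {"A", "B"})]
        # default both-strand scanning also sees the reverse-orientation
        # AACG site (CGTT at 3), adding a second A-labeled cut
        both = cut_positions("TAACGTT", [a, b])
        assert [(c.position, set(c.enzymes)) for c in both] == [
            (3, {"A", "B"}), (5, {"A"}),
        ]

    def test_site_start_mode(self, enzymes):
        cuts = cut_positions(TOY25, [enzymes["CviAII"], enzymes["MluCI"]],
                             boundary_mode="site_start")
        assert [c.position for c in cuts] == [2, 11, 19]

    def test_no_sites_is_empty(self, enzymes):
        assert cut_positions("TTTTTTTT", enzymes["CviAII"]) == []

    def test_pair_cuts_are_union_of_singles(self, enzymes):
        random.seed(5)
        seq = "".join(random.choice("ACGT") for _ in range(3000))
        a, b = enzymes["CviAII"], enzymes["MluCI"]
        pair = {c.position for c in cut_positions(seq, [a, b])}
        single = {c.position for c in cut_positions(seq, a)}
        single |= {c.position for c in cut_positions(seq, b)}
        assert pair == single
        assert len(pair) >= len({c.position for c in cut_positions(seq, a)})


class TestEnumerateFragments:
    def test_basic_tiling(self):
        cuts = [CutSite(p, frozenset({"E"})) for p in (1, 5, 9)]
        frags = enumerate_fragments(cuts, 12, "toy")
        assert [f.length for f in frags] == [1, 4, 4, 3]
        assert frags[0].left_end == frozenset({CHROM_END})
        assert frags[-1].right_end == frozenset({CHROM_END})

    def test_no_cuts(self):
        frags = enumerate_fragments([], 10, "r")
        assert len(frags) == 1 and frags[0].length == 10
        assert frags[0].left_end == frags[0].right_end == frozenset({CHROM_END})
        assert enumerate_fragments([], 10, "r", terminal_policy="exclude") == []

    def test_toy25_internal_fragments(self, enzymes):
        cuts = cut_positions(TOY25, [enzymes["CviAII"], enzymes["MluCI"]])
        frags = enumerate_fragments(cuts, 25, "toy25")
        assert len(frags) == 4
        internal = [f for f in frags if CHROM_END not in f.left_end | f.right_end]
        assert [(f.start, f.end, f.length) for f in internal] == [(3, 11, 8), (11, 20, 9)]
        assert internal[0].left_end == frozenset({"CviAII"})
        assert internal[0].right_end == frozenset({"MluCI"})

    def test_cut_beyond_record_rejected(self):
        with pytest.raises(ValueError):
            enumerate_fragments([CutSite(11, frozenset({"E"}))], 10, "r")

    def test_zero_length_terminals_suppressed(self):
        frags = enumerate_fragments(
            [CutSite(0, frozenset({"E"})), CutSite(10, frozenset({"E"}))], 10, "r")
        assert [(f.start, f.end) for f in frags] == [(0, 10)]

    @given(
        length=st.integers(1, 500),
        cut_fracs=st.lists(st.integers(0, 500), max_size=20),
    )
    @settings(max_examples=200, deadline=None)
    def test_length_conservation(self, length, cut_fracs):
        """With terminals included, fragment lengths tile the record exactly."""
        positions = sorted({min(c, length) for c in cut_fracs})
        cuts = [CutSite(p, frozenset({"E"})) for p in positions]
        frags = enumerate_fragments(cuts, length, "r")
        assert sum(f.length for f in frags) == length
        for f1, f2 in zip(frags, frags[1:]):
            assert f1.end == f2.start


class TestSelectFragments:
    def test_inclusive_window(self):
        frags = [Fragment("r", s, e, frozenset({"A"}), frozenset({"B"}))
                 for s, e in [(0, 99), (100, 200), (300, 900), (1000, 1601)]]
        kept = select_fragments(frags, 100, 600)
        assert [f.length for f in kept] == [100, 600]

    def test_any_rule_on_toy12(self, enzymes):
        cuts = cut_positions("CATGCATGCATG", enzymes["CviAII"])
        frags = enumerate_fragments(cuts, 12, "toy")
        kept = select_fragments(frags, 2, 4)
        assert len(kept) == 3 and sum(f.length for f in kept) == 11

    def test_different_ends_on_toy25(self, enzymes):
        cuts = cut_positions(TOY25, [enzymes["CviAII"], enzymes["MluCI"]])
        frags = enumerate_fragments(cuts, 25, "toy25")
        kept = select_fragments(frags, 5, 10, end_rule="different_enzymes")
        assert len(kept) == 2 and sum(f.length for f in kept) == 17

    def test_single_enzyme_has_no_different_ends(self, enzymes):
        cuts = cut_positions("CATGCATGCATGCATG", enzymes["CviAII"])
        frags = enumerate_fragments(cuts, 16, "r")
        assert select_fragments(frags, 1, 16, end_rule="different_enzymes") == []

    def test_chrom_end_never_qualifies(self):
        f = Fragment("r", 0, 150, frozenset({CHROM_END}), frozenset({"A"}))
        assert select_fragments([f], 100, 600, end_rule="different_enzymes") == []

    def test_shared_label_set_admits_distinct_assignment(self):
        f = Fragment("r", 0, 150, frozenset({"A"}), frozenset({"A", "B"}))
        assert select_fragments([f], 100, 600, end_rule="different_enzymes") == [f]
        g = Fragment("r", 0, 150, frozenset({"A"}), frozenset({"A"}))
        assert select_fragments([g], 100, 600, end_rule="different_enzymes") == []

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            select_fragments([], 600, 100)

    @given(
        lo1=st.integers(0, 50), hi1=st.integers(0, 50),
        widen=st.integers(0, 30), seed=st.integers(0, 10_000),
    )
    @settings(max_examples=100, deadline=None)
    def test_widening_window_is_monotone(self, lo1, hi1, widen, seed):
        rng = random.Random(seed)
        frags = [Fragment("r", i * 100, i * 100 + rng.randint(1, 80),
                          frozenset({"A"}), frozenset({"B"})) for i in range(20)]
        lo, hi = min(lo1, hi1), max(lo1, hi1) + 1
        narrow = select_fragments(frags, lo, hi)
        wide = select_fragments(frags, max(lo - widen, 0), hi + widen)
        assert set((f.start, f.end) for f in narrow) <= set((f.start, f.end) for f in wide)


class TestOracleEquivalence:
    def test_fragments_match_slicing_oracle(self, enzymes):
        """Full digest equals the independent per-position slicing oracle."""
        rng = random.Random(99)
        pairs = [
            [enzymes["CviAII"]], [enzymes["HinfI"]],
            [enzymes["CviAII"], enzymes["MluCI"]],
            [enzymes["HinfI"], enzymes["HpyCH4IV"]],
            [enzymes["PstI"], enzymes["MspI"]],
        ]
        for rep in range(30):
            seq = "".join(rng.choice("ACGTACGTN" if rep % 4 == 0 else "ACGT")
                          for _ in range(rng.randint(100, 2000)))
            for enz_list in pairs:
                for policy in ("include", "exclude"):
                    cuts = cut_positions(seq, enz_list)
                    got = enumerate_fragments(cuts, len(seq), "r", terminal_policy=policy)
                    expected = oracle_fragments(seq, enz_list, terminal_policy=policy)
                    assert [(f.start, f.end, f.left_end, f.right_end) for f in got] == expected


def test_bed_export(enzymes):
    cuts = cut_positions(TOY25, [enzymes["CviAII"], enzymes["MluCI"]])
    frags = enumerate_fragments(cuts, 25, "toy25")
    bed = fragments_to_bed(frags)
    lines = bed.strip().split("\n")
    assert len(lines) == 4
    assert lines[1].split("\t") == ["toy25", "3", "11", "CviAII|MluCI", "8", "."]
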