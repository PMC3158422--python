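"""Filter-builder tests: binning, ordering, fringe fill, soundness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from shapequad import (
    BinConfig,
    BinnedDescriptors,
    accumulate,
    bin_descriptors,
    build_filter_set,
    fill_map,
    order_pair,
    to_bin,
)
from shapequad.filters import RawDeltaMap


CFG = BinConfig()


def bd(v, qx=0, qy=0, qz=0):
    return BinnedDescriptors(v_bin=v, qx_bin=qx, qy_bin=qy, qz_bin=qz)


class TestToBin:
    @pytest.mark.parametrize(
        "value,binsize,expected",
        [
            (511.2, 5.0, 102),  # a typical mid-corpus monopole volume
            (0.0, 5.0, 0),
            (2.4999, 2.5, 0),
            (2.5, 2.5, 1),
        ],
    )
    def test_floor_convention(self, value, binsize, expected):
        assert to_bin(value, binsize) == expected

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            to_bin(-0.1, 5.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        mantissa=st.integers(min_value=0, max_value=10_000_000),
        exponent=st.integers(min_value=-3, max_value=5),
    )
    def test_shift_by_one_binsize_increments(self, mantissa, exponent):
        # power-of-two bin sizes keep the quotient arithmetic exact, so the
        # real-arithmetic invariant to_bin(v + b) = to_bin(v) + 1 is testable
        binsize = 2.0**exponent
        value = mantissa * binsize / 1024.0
        assert to_bin(value + binsize, binsize) == to_bin(value, binsize) + 1


class TestOrderPair:
    def test_smaller_volume_first(self):
        a, b = bd(110), bd(100)
        assert order_pair(a, b) == (b, a)

    def test_tie_cascades_through_quadrupoles(self):
        a, b = bd(100, qx=5), bd(100, qx=3)
        assert order_pair(a, b) == (b, a)
        a, b = bd(100, qx=3, qy=9), bd(100, qx=3, qy=2)
        assert order_pair(a, b) == (b, a)
        a, b = bd(100, qx=3, qy=2, qz=7), bd(100, qx=3, qy=2, qz=1)
        assert order_pair(a, b) == (b, a)

    def test_identical_bins_preserve_input_order(self):
        a, b = bd(100, 1, 2, 3), bd(100, 1, 2, 3)
        assert order_pair(a, b) == (a, b)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 50), st.integers(0, 20), st.integers(0, 50), st.integers(0, 20))
    def test_swap_invariance(self, v1, q1, v2, q2):
        a, b = bd(v1, qx=q1), bd(v2, qx=q2)
        m1, m2 = order_pair(a, b)
        n1, n2 = order_pair(b, a)
        assert (m1.sort_key, m2.sort_key) == (n1.sort_key, n2.sort_key)


class TestAccumulate:
    def test_single_pair_bookkeeping(self):
        raw = accumulate([(bd(10, qx=4), bd(12, qx=7))], "x", CFG)
        assert dict(raw.counts[(10, 12)]) == {3: 1}

    def test_ordering_canonicalizes_both_presentations(self):
        a, b = bd(12, qx=7), bd(10, qx=4)
        raw_fwd = accumulate([(a, b)], "x", CFG)
        raw_rev = accumulate([(b, a)], "x", CFG)
        assert raw_fwd.counts == raw_rev.counts

    def test_counts_conserved(self, rng):
        pairs = [
            (bd(int(rng.integers(5, 15)), qx=int(rng.integers(8))),
             bd(int(rng.integers(5, 15)), qx=int(rng.integers(8))))
            for _ in range(100)
        ]
        raw = accumulate(pairs, "x", CFG)
        assert raw.total == 100

    def test_invalid_key_rejected(self):
        raw = RawDeltaMap(component="x", cfg=CFG)
        with pytest.raises(ValueError, match="canonical"):
            raw.add(14, 12, 3)


class TestFillMap:
    def toy(self, entries):
        raw = RawDeltaMap(component="x", cfg=CFG)
        for (v1, v2), dqs in entries.items():
            for dq in dqs:
                raw.add(v1, v2, dq)
        return raw

    def test_row_gap_closed(self):
        # hand-execution: at level 2 the populated region {(10,10),(10,12)}
        # closes row-wise to include (10,11)
        f = fill_map(self.toy({(10, 10): [2], (10, 12): [2]}))
        assert f.lookup(10, 11) == (2, 2)
        assert f.lookup(10, 10) == (2, 2)

    def test_single_key_untouched(self):
        f = fill_map(self.toy({(7, 9): [-1, 0, 3]}))
        assert f.entries == {(7, 9): (-1, 3)}

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            fill_map(RawDeltaMap(component="x", cfg=CFG))

    def test_column_gap_closed(self):
        f = fill_map(self.toy({(8, 12): [1], (10, 12): [1]}))
        assert f.lookup(9, 12) == (1, 1)

    def test_branches_filled_independently(self):
        # negative branch has a different populated region than the positive
        f = fill_map(self.toy({(10, 10): [2], (10, 12): [2], (10, 14): [-1]}))
        assert f.lookup(10, 11) == (2, 2)
        assert f.lookup(10, 14)[0] == -1

    def _region(self, f):
        return {
            (k, dq)
            for k, (lo, hi) in f.entries.items()
            for dq in range(lo, hi + 1)
        }

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.data())
    def test_fill_superset_and_idempotent(self, data):
        n = data.draw(st.integers(1, 12))
        raw = RawDeltaMap(component="x", cfg=CFG)
        for _ in range(n):
            v1 = data.draw(st.integers(0, 6))
            v2 = data.draw(st.integers(v1, 6))
            raw.add(v1, v2, data.draw(st.integers(-4, 4)))
        f1 = fill_map(raw)
        # superset: every observed (key, dq) is admitted
        for key, counter in raw.counts.items():
            lo, hi = f1.entries[key]
            for dq in counter:
                assert lo <= dq <= hi
        # idempotent: refilling the filled ranges changes nothing
        raw2 = RawDeltaMap(component="x", cfg=CFG)
        for key, (lo, hi) in f1.entries.items():
            for dq in range(lo, hi + 1):
                raw2.add(*key, dq)
        f2 = fill_map(raw2)
        assert f2.entries == f1.entries


class TestBuildFilterSet:
    def _self_pair_corpus(self, small_corpus):
        ids = list(small_corpus.descriptors)[:30]
        return pd.DataFrame({"id1": ids, "id2": ids, "st": [1.0] * len(ids)})

    def test_self_pairs_give_zero_ranges(self, small_corpus):
        pairs = self._self_pair_corpus(small_corpus)
        fs = build_filter_set(pairs, small_corpus.descriptors, CFG)
        for comp in "xyz":
            for lo, hi in fs.member(comp).entries.values():
                assert (lo, hi) == (0, 0)

    def test_missing_descriptor_id_named(self, small_corpus):
        pairs = pd.DataFrame({"id1": ["ghost"], "id2": ["ghost"], "st": [1.0]})
        with pytest.raises(KeyError, match="ghost"):
            build_filter_set(pairs, small_corpus.descriptors, CFG)

    def test_zero_pairs_after_restriction_rejected(self, small_corpus):
        pairs = self._self_pair_corpus(small_corpus).assign(st=0.1)
        with pytest.raises(ValueError, match="threshold"):
            build_filter_set(pairs, small_corpus.descriptors, CFG)

    def test_threshold_nesting(self, small_corpus):
        """The allowed region at a stricter threshold nests inside the looser one."""
        pairs = small_corpus.train_pairs
        loose = build_filter_set(pairs, small_corpus.descriptors, BinConfig(st_threshold=0.80))
        strict_cfg = BinConfig(st_threshold=0.95)
        if (pairs["st"] >= 0.95).sum() == 0:
            pytest.skip("no strict-threshold pairs in this corpus draw")
        strict = build_filter_set(pairs, small_corpus.descriptors, strict_cfg)
        for comp in "xyz":
            for key, (lo, hi) in strict.member(comp).entries.items():
                llo, lhi = loose.member(comp).entries[key]
                assert llo <= lo and hi <= lhi

    def test_pair_input_order_irrelevant(self, small_corpus):
        pairs = small_corpus.train_pairs
        swapped = pairs.rename(columns={"id1": "id2", "id2": "id1"})
        fs1 = build_filter_set(pairs, small_corpus.descriptors, CFG)
        fs2 = build_filter_set(swapped, small_corpus.descriptors, CFG)
        for comp in "xyz":
            assert fs1.member(comp).entries == fs2.member(comp).entries
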