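from __future__ import annotations

import numpy as np
import pytest

from phage_ssr import (
    CompoundSSR,
    CssrParams,
    SequenceRecord,
    build_cssrs,
    ccssr_count,
    dmax_sweep,
    find_ssrs,
)
from tests.conftest import make_ssr


def components_oracle(ssrs, dmax):
    """Transitive closure on the pairwise gap <= dmax graph (independent
    of the greedy chaining): union-find over all SSR pairs."""
    n = len(ssrs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            gap = max(ssrs[j].start, ssrs[i].start) - min(ssrs[j].end, ssrs[i].end) - 1
            if gap <= dmax:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return sorted(sorted(c) for c in comps.values())


def random_layout(rng, n):
    """Random sorted SSR list with clustered and isolated tracts."""
    ssrs, pos = [], 1
    motifs = ["C", "CG", "GT", "AAG", "CGG"]
    for _ in range(n):
        pos += int(rng.integers(0, 80))
        motif = motifs[rng.integers(len(motifs))]
        iters = int(rng.integers(6 if len(motif) == 1 else 3, 9))
        ssrs.append(make_ssr(motif, iters, pos))
        pos = ssrs[-1].end + 1
    return sorted(ssrs, key=lambda s: (s.start, s.motif_len))


class TestBuildCssrs:
    def test_zero_gap_pair_chains(self):
        ssrs = [make_ssr("GT", 5, 1), make_ssr("CG", 3, 11)]
        cssrs, standalone = build_cssrs(ssrs, CssrParams(dmax=10))
        assert len(cssrs) == 1 and not standalone
        assert cssrs[0].n_members == 2
        assert cssrs[0].gaps == (0,)

    @pytest.mark.parametrize("gap,n_expected", [(10, 1), (11, 0)])
    def test_dmax_boundary(self, gap, n_expected):
        ssrs = [make_ssr("CG", 3, 1), make_ssr("GT", 3, 7 + gap)]
        cssrs, standalone = build_cssrs(ssrs, CssrParams(dmax=10))
        assert len(cssrs) == n_expected
        assert len(standalone) == 2 - 2 * n_expected

    def test_three_member_chain(self):
        ssrs = [make_ssr("CG", 3, 1), make_ssr("GC", 3, 14), make_ssr("CG", 3, 21)]
        cssrs, _ = build_cssrs(ssrs, CssrParams(dmax=10))
        assert len(cssrs) == 1
        assert cssrs[0].n_members == 3
        assert cssrs[0].gaps == (7, 1)

    def test_unsorted_input_rejected(self):
        ssrs = [make_ssr("CG", 3, 100), make_ssr("GT", 3, 1)]
        with pytest.raises(ValueError, match="sorted"):
            build_cssrs(ssrs)

    def test_dmax_range_enforced(self):
        with pytest.raises(ValueError):
            CssrParams(dmax=51)
        with pytest.raises(ValueError):
            CssrParams(dmax=-1)

    def test_partition_property_random_layouts(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            ssrs = random_layout(rng, int(rng.integers(2, 40)))
            for dmax in (0, 10, 25, 50):
                cssrs, standalone = build_cssrs(ssrs, CssrParams(dmax=dmax))
                assert len(standalone) + ccssr_count(cssrs) == len(ssrs)
                for c in cssrs:
                    assert all(g <= dmax for g in c.gaps)

    def test_matches_connected_components_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            ssrs = random_layout(rng, int(rng.integers(2, 30)))
            for dmax in (0, 5, 10, 30, 50):
                cssrs, standalone = build_cssrs(ssrs, CssrParams(dmax=dmax))
                got = sorted(
                    [sorted(ssrs.index(m) for m in c.members) for c in cssrs]
                    + [[ssrs.index(s)] for s in standalone]
                )
                assert got == components_oracle(ssrs, dmax)


class TestClassify:
    def test_interrupted_pure(self):
        c = CompoundSSR("g", (make_ssr("CA", 3, 1), make_ssr("CA", 3, 16)))
        assert c.cssr_class == "interrupted-pure"

    def test_compound_zero_gap(self):
        c = CompoundSSR("g", (make_ssr("GT", 5, 1), make_ssr("CG", 3, 11)))
        assert c.cssr_class == "compound"

    def test_interrupted_compound(self):
        c = CompoundSSR("g", (make_ssr("GA", 3, 1), make_ssr("AAG", 9, 15)))
        assert c.cssr_class == "interrupted-compound"

    def test_complex(self):
        c = CompoundSSR(
            "g", (make_ssr("CG", 3, 1), make_ssr("GC", 3, 14), make_ssr("CG", 3, 21))
        )
        assert c.cssr_class == "complex"

    def test_three_members_all_zero_gaps_is_compound(self):
        c = CompoundSSR(
            "g", (make_ssr("GT", 3, 1), make_ssr("CG", 3, 7), make_ssr("AAG", 3, 13))
        )
        assert c.cssr_class == "compound"

    def test_same_class_zero_gap_from_rotation_break(self):
        # ACACAC|CACACA: two maximal same-class tracts abutting at gap 0
        seq = SequenceRecord(id="g", seq="TTACACACCACACATT")
        ssrs = find_ssrs(seq)
        assert [s.motif for s in ssrs] == ["AC", "CA"]
        cssrs, _ = build_cssrs(ssrs, CssrParams(dmax=10))
        assert cssrs[0].cssr_class == "compound"

    def test_fewer_than_two_members_rejected(self):
        with pytest.raises(ValueError):
            CompoundSSR("g", (make_ssr("CG", 3, 1),))


class TestSweepAndCounts:
    def test_ccssr_count(self):
        one = CompoundSSR("g", (make_ssr("CG", 3, 1), make_ssr("GT", 3, 10)))
        assert ccssr_count([one]) == 2
        assert ccssr_count([]) == 0

    def test_m73_like_member_total(self):
        # 17 compound loci holding 36 member SSRs in total
        cssrs, pos = [], 1
        for i in range(17):
            size = 3 if i < 2 else 2
            members = []
            for _ in range(size):
                members.append(make_ssr("CG", 3, pos))
                pos = members[-1].end + 3
            cssrs.append(CompoundSSR("g", tuple(members)))
            pos += 100
        assert len(cssrs) == 17
        assert ccssr_count(cssrs) == 36

    def test_member_total_nondecreasing_in_dmax(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            ssrs = random_layout(rng, 25)
            totals = [
                ccssr_count(build_cssrs(ssrs, CssrParams(dmax=d))[0])
                for d in (0, 10, 20, 30, 40, 50)
            ]
            assert totals == sorted(totals)

    def test_clustered_layout_n_cssr_nondecreasing_with_plateau(self):
        # isolated clusters > 50 bp apart: chains only grow within a cluster
        ssrs = []
        pos = 1
        for gaps in [(4,), (12,), (25, 3), (45,)]:
            members = [make_ssr("CG", 3, pos)]
            for g in gaps:
                members.append(make_ssr("GT", 3, members[-1].end + 1 + g))
            ssrs.extend(members)
            pos = members[-1].end + 200
        df = dmax_sweep(ssrs, [0, 10, 20, 30, 40, 50])
        counts = list(df.n_cssr)
        assert counts == sorted(counts)
        assert counts[-1] == 4
        assert len(set(counts)) < len(counts)  # at least one plateau

    def test_dmax_zero_all_gaps_positive(self):
        ssrs = [make_ssr("CG", 3, 1), make_ssr("GT", 3, 10), make_ssr("C", 6, 30)]
        df = dmax_sweep(ssrs, [0])
        assert df.n_cssr.iloc[0] == 0

    def test_sweep_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            dmax_sweep([make_ssr("CG", 3, 1)], [60])
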