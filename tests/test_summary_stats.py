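from __future__ import annotations

import math

import numpy as np
import pytest

from phage_ssr import (
    GenomeSummary,
    SequenceRecord,
    build_cssrs,
    find_ssrs,
    regress,
    study_constants,
    summarize_genome,
    zscores,
)
from phage_ssr.errors import ComputationError


def summary(genome_id="g", genome_len=50_000, gc=0.6, n_ssr=100, n_cssr=5,
            ccssr=11, ssr_bp=800, cssr_bp=150):
    return GenomeSummary(
        genome_id=genome_id, genome_len=genome_len, gc_fraction=gc,
        n_ssr=n_ssr, n_cssr=n_cssr, ccssr=ccssr, ssr_bp=ssr_bp, cssr_bp=cssr_bp,
    )


class TestGenomeSummary:
    def test_relative_abundance_d29_like(self):
        # 78 SSRs in a 49,136 bp genome -> 1.59 per kb
        s = summary(genome_len=49_136, n_ssr=78)
        assert round(s.ra, 2) == 1.59

    @pytest.mark.parametrize(
        "n_ssr,n_cssr,expected", [(96, 8, 8.33), (93, 1, 1.08)]
    )
    def test_cssr_percent_extremes(self, n_ssr, n_cssr, expected):
        s = summary(n_ssr=n_ssr, n_cssr=n_cssr, ccssr=2 * n_cssr)
        assert round(s.cssr_percent, 2) == expected

    def test_member_percent_distinct_from_count_percent(self):
        # 93 SSRs with 2 of them inside 1 compound locus: 2.15% members, 1.08% loci
        s = summary(n_ssr=93, n_cssr=1, ccssr=2)
        assert round(s.ssr_in_cssr_percent, 2) == 2.15
        assert round(s.cssr_percent, 2) == 1.08
        assert s.cssr_percent <= s.ssr_in_cssr_percent

    def test_ra_rd_recover_counts(self):
        s = summary()
        kb = s.genome_len / 1000
        assert s.ra * kb == pytest.approx(s.n_ssr)
        assert s.rd * kb == pytest.approx(s.ssr_bp)
        assert s.cra * kb == pytest.approx(s.n_cssr)
        assert s.crd * kb == pytest.approx(s.cssr_bp)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            summary(genome_len=0)

    def test_zero_ssr_guarded(self):
        s = summary(n_ssr=0, n_cssr=0, ccssr=0, ssr_bp=0, cssr_bp=0)
        assert s.cssr_percent == 0.0 and s.ssr_in_cssr_percent == 0.0

    def test_summarize_from_detection(self, seqrec):
        seq = seqrec("TT" + "GT" * 5 + "CG" * 3 + "TA" * 2 + "A" * 60)
        ssrs = find_ssrs(seq)
        cssrs, _ = build_cssrs(ssrs)
        s = summarize_genome(seq, ssrs, cssrs)
        assert s.n_ssr == len(ssrs)
        assert s.ccssr >= 2 * s.n_cssr


class TestStudyConstants:
    def test_hand_arithmetic(self):
        a = summary(genome_id="a", n_cssr=2, ccssr=4)
        b = summary(genome_id="b", n_cssr=2, ccssr=6)
        const = study_constants([a, b])
        assert const.c_prime == pytest.approx(2.5)
        assert const.n_genomes == 2

    def test_constant_ratio_cohort(self):
        cohort = [summary(genome_id=f"g{i}", n_cssr=i + 1, ccssr=3 * (i + 1))
                  for i in range(5)]
        assert study_constants(cohort).c_prime == pytest.approx(3.0)

    def test_zero_cssr_genomes_excluded(self):
        a = summary(genome_id="a", n_cssr=2, ccssr=5)
        b = summary(genome_id="b", n_cssr=0, ccssr=0)
        const = study_constants([a, b])
        assert const.n_genomes == 1
        assert const.c_prime == pytest.approx(2.5)

    def test_all_zero_is_error(self):
        with pytest.raises(ComputationError):
            study_constants([summary(n_cssr=0, ccssr=0)])

    def test_brute_force_mean_large_cohort(self):
        rng = np.random.default_rng(9)
        cohort = []
        for i in range(147):
            n_cssr = int(rng.integers(1, 18))
            ccssr = n_cssr * 2 + int(rng.integers(0, 5))
            cohort.append(summary(genome_id=f"g{i}", n_cssr=n_cssr, ccssr=ccssr))
        expected = sum(s.ccssr / s.n_cssr for s in cohort) / len(cohort)
        assert study_constants(cohort).c_prime == pytest.approx(expected)


class TestZScores:
    def test_hand_arithmetic(self):
        a = summary(genome_id="a", n_cssr=2, ccssr=4)
        b = summary(genome_id="b", n_cssr=2, ccssr=6)
        const = study_constants([a, b])  # c' = 2.5
        zb = zscores([b], const)[0]
        assert zb.cssr_exp == pytest.approx(2.4)
        assert zb.z == pytest.approx((2 - 2.4) / math.sqrt(2.4), abs=1e-9)
        assert round(zb.z, 3) == -0.258

    def test_homogeneous_cohort_all_zero(self):
        cohort = [summary(genome_id=f"g{i}", n_cssr=i + 2, ccssr=3 * (i + 2))
                  for i in range(6)]
        const = study_constants(cohort)
        for z in zscores(cohort, const):
            assert z.z == pytest.approx(0.0, abs=1e-12)

    def test_sign_convention_and_flagging(self):
        a = summary(genome_id="a", n_cssr=4, ccssr=8)    # ratio 2
        b = summary(genome_id="b", n_cssr=2, ccssr=8)    # ratio 4
        c = summary(genome_id="c", n_cssr=0, ccssr=0)
        const = study_constants([a, b])                   # c' = 3
        za, zb, zc = zscores([a, b, c], const)
        assert za.z > 0 and zb.z < 0                      # O >/< E
        assert zc.z is None                               # flagged, not zero
        n_flagged = sum(1 for z in (za, zb, zc) if z.z is None)
        assert n_flagged + sum(1 for z in (za, zb, zc) if z.z is not None) == 3


class TestRegress:
    def test_perfect_fit(self):
        x = list(range(1, 11))
        y = [2 * v for v in x]
        r2, slope, p = regress(x, y)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)
        assert p < 1e-10

    def test_null_case(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        y = rng.normal(size=500)
        r2, _, _ = regress(x, y)
        assert r2 < 0.02

    def test_closed_form_fixture(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
        y = [2.1, 3.9, 6.2, 8.1, 9.8, 12.3, 13.9, 16.2, 18.1, 19.7]
        n = len(x)
        sx, sy = sum(x), sum(y)
        sxx = sum(v * v for v in x)
        sxy = sum(a * b for a, b in zip(x, y))
        slope_hand = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        mean_y = sy / n
        intercept = mean_y - slope_hand * sx / n
        ss_res = sum((b - (intercept + slope_hand * a)) ** 2 for a, b in zip(x, y))
        ss_tot = sum((b - mean_y) ** 2 for b in y)
        r2_hand = 1 - ss_res / ss_tot
        r2, slope, _ = regress(x, y)
        assert slope == pytest.approx(slope_hand, abs=1e-12)
        assert r2 == pytest.approx(r2_hand, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ComputationError):
            regress([1.0] * 5, [1, 2, 3, 4, 5])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            regress([1, 2], [1, 2])
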