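import itertools
import math

import numpy as np
import pytest

from conftest import make_ar
from selratio.selection_fdr import (
    FdrBinScheme,
    SelectionResult,
    UndefinedRatioError,
    assign_bins,
    classify,
    empirical_fdr,
    sample_ars,
    selection_ratio,
    theoretical_fdr,
)


class TestSelectionRatio:
    @pytest.mark.parametrize(
        "d_f,d_ln,expected",
        [(0.2, 0.2, 1.0), (0.9, 0.2, 4.5), (0.0, 0.3, 0.0)],
    )
    def test_quotient(self, d_f, d_ln, expected):
        assert selection_ratio(d_f, d_ln) == pytest.approx(expected)

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedRatioError):
            selection_ratio(0.1, 0.0)


class TestBinScheme:
    def test_bin_counts(self):
        scheme = FdrBinScheme.default()
        assert scheme.n_gc_bins == 9
        assert scheme.n_len_bins == 5
        assert scheme.n_sr_bins == 41

    @pytest.mark.parametrize(
        "gc,length,sr,expected",
        [
            (0.25, 100, 0.1, (0, 0, 0)),   # leading closed intervals
            (0.0, 1, 0.0, (0, 0, 0)),
            (0.26, 101, 0.11, (1, 1, 1)),  # just past the closed bins
            (0.30, 150, 0.2, (1, 1, 1)),   # right edges belong to their bin
            (0.61, 500, 4.0, (8, 4, 39)),
            (0.9, 350, 4.2, (8, 4, 40)),   # overflow SR bin (4.0, inf)
        ],
    )
    def test_boundary_membership(self, gc, length, sr, expected):
        scheme = FdrBinScheme.default()
        g, l, s, flags = assign_bins(gc, length, sr, scheme)
        assert (g, l, s) == expected
        assert not flags

    def test_length_overflow_flagged_into_last_bin(self):
        scheme = FdrBinScheme.default()
        g, l, s, flags = assign_bins(0.5, 620, 1.0, scheme)
        assert l == 4 and "len_overflow" in flags

    def test_sr_bins_partition(self):
        scheme = FdrBinScheme.default()
        rng = np.random.default_rng(0)
        for sr in rng.uniform(0, 6, size=200):
            _, _, s, _ = assign_bins(0.5, 100, sr, scheme)
            lo, hi = scheme.sr_edges[s], scheme.sr_edges[s + 1]
            assert (lo < sr <= hi) or (s == 0 and 0 <= sr <= hi)


def make_result(fid, sr, gc=0.4, length=120):
    return SelectionResult(
        feature_id=fid, d_f=sr * 0.4, d_ln=0.4, sr=sr, gc=gc,
        degapped_len=length, si=0.8,
    )


class TestEmpiricalFdr:
    def build_populations(self, n=1000, t=50, m=10000, s=100, sr_in=1.05, sr_out=0.35):
        feats = [make_result(f"f{i}", sr_in if i < t else sr_out) for i in range(n)]
        ars = [make_result(f"a{i}", sr_in if i < s else sr_out) for i in range(m)]
        return feats, ars

    def test_worked_example_is_one_fifth(self):
        # 1% of ARs and 5% of features in the SR bin -> FDR 0.2
        feats, ars = self.build_populations()
        empirical_fdr(feats, [ars])
        assert feats[0].fdr == pytest.approx(0.2)

    def test_capped_at_one(self):
        feats, ars = self.build_populations(t=10, s=1000)
        empirical_fdr(feats, [ars])
        assert feats[0].fdr == 1.0

    def test_zero_ar_hits_give_zero(self):
        feats, ars = self.build_populations(s=0)
        empirical_fdr(feats, [ars])
        assert feats[0].fdr == 0.0

    def test_mean_over_samplings(self):
        feats, ars1 = self.build_populations(s=100)
        _, ars2 = self.build_populations(s=300)
        empirical_fdr(feats, [ars1, ars2])
        assert feats[0].fdr == pytest.approx((0.2 + 0.6) / 2)

    def test_empty_null_cell_flags_sparse(self):
        feats, _ = self.build_populations(n=10, t=2)
        ars = [make_result("a0", 1.0, gc=0.9, length=450)]  # different cell
        empirical_fdr(feats, [ars])
        assert feats[0].fdr is None and "null_sparse" in feats[0].flags

    def test_invariant_to_feature_order(self):
        feats, ars = self.build_populations(n=40, t=7, m=200, s=11)
        empirical_fdr(feats, [ars])
        by_id = {f.feature_id: f.fdr for f in feats}
        feats2, ars2 = self.build_populations(n=40, t=7, m=200, s=11)
        rng = np.random.default_rng(1)
        perm = list(rng.permutation(len(feats2)))
        feats2 = [feats2[i] for i in perm]
        empirical_fdr(feats2, [ars2])
        for f in feats2:
            assert f.fdr == pytest.approx(by_id[f.feature_id])

    def test_fdr_within_unit_interval(self):
        rng = np.random.default_rng(2)
        feats = [make_result(f"f{i}", rng.uniform(0, 5)) for i in range(100)]
        ars = [make_result(f"a{i}", rng.uniform(0, 5)) for i in range(300)]
        empirical_fdr(feats, [ars])
        for f in feats:
            assert f.fdr is not None and 0 <= f.fdr <= 1


class TestSampleArs:
    def _pool(self, n=20):
        return [make_ar(f"ar{i}", "chrT", np.arange(i * 500, i * 500 + 200))
                for i in range(n)]

    def test_deterministic_given_seed(self):
        pool = self._pool()
        s1, _ = sample_ars(pool, n=10, seed=3)
        s2, _ = sample_ars(pool, n=10, seed=3)
        assert [a.ar_id for a in s1] == [a.ar_id for a in s2]

    def test_oversampling_requires_replacement(self):
        pool = self._pool(5)
        with pytest.raises(ValueError):
            sample_ars(pool, n=10, seed=0)
        sample, flags = sample_ars(pool, n=10, seed=0, with_replacement=True)
        assert len(sample) == 10 and "sampled_with_replacement" in flags

    def test_min_length_filter(self):
        short = [make_ar("s", "chrT", np.arange(0, 50))]
        with pytest.raises(ValueError):
            sample_ars(short, n=1, min_len=80, seed=0)


class TestClassify:
    @pytest.mark.parametrize(
        "sr,fdr,mode,expected",
        [
            (0.3, 0.05, "denovo", "negative"),
            (0.3, 0.25, "denovo", "unclassified"),
            (2.5, 0.5, "denovo", "unclassified"),
            (2.5, 0.2, "denovo", "rapid"),
            (1.7, 0.1, "rfam", "rapid"),
            (1.7, 0.1, "denovo", "unclassified"),
            (1.0, 0.0, "denovo", "unclassified"),
            (None, 0.1, "denovo", "unclassified"),
            (2.5, None, "denovo", "unclassified"),
        ],
    )
    def test_threshold_table(self, sr, fdr, mode, expected):
        assert classify(sr, fdr, mode) == expected


def enumerate_exceedance(p, len_f, len_n, threshold, mode):
    """Brute-force enumeration over all (k_F, k_LN) outcomes."""
    total = 0.0
    for kf, kn in itertools.product(range(len_f + 1), range(len_n + 1)):
        prob = (
            math.comb(len_f, kf) * p**kf * (1 - p) ** (len_f - kf)
            * math.comb(len_n, kn) * p**kn * (1 - p) ** (len_n - kn)
        )
        if kn == 0:
            continue  # null distance zero: SR undefined, never a discovery
        if mode == "count":
            df, dn = kf / len_f, kn / len_n
        else:
            pf, pn = kf / len_f, kn / len_n
            df = math.inf if pf >= 0.75 else -0.75 * math.log(1 - 4 * pf / 3)
            dn = math.inf if pn >= 0.75 else -0.75 * math.log(1 - 4 * pn / 3)
        if math.isinf(dn):
            continue
        if dn > 0 and df / dn > threshold:
            total += prob
    return total


class TestTheoreticalFdr:
    @pytest.mark.parametrize("mode", ["count", "jukes_cantor"])
    @pytest.mark.parametrize(
        "p,len_f,len_n,threshold",
        [
            (0.5, 1, 1, 2.0),
            (0.2, 5, 12, 2.0),
            (0.3, 12, 8, 1.5),
            (0.6, 10, 10, 2.0),
            (0.1, 3, 3, 0.5),
        ],
    )
    def test_matches_exhaustive_enumeration(self, p, len_f, len_n, threshold, mode):
        got, _ = theoretical_fdr(p, len_f, len_n, threshold, mode)
        want = enumerate_exceedance(p, len_f, len_n, threshold, mode)
        assert got == pytest.approx(want, abs=1e-12)

    def test_single_site_case_by_hand(self):
        # len 1 each, P=0.5: the only outcome with a defined SR that could
        # exceed 2 is (k_F=1, k_LN=1) giving SR=1; so exceedance is 0
        got, _ = theoretical_fdr(0.5, 1, 1, 2.0, "count")
        assert got == 0.0

    def test_vanishes_as_p_tends_to_zero(self):
        # exceedance requires both counts nonzero, so it is O(p^2) in the limit
        vals = [theoretical_fdr(p, 50, 200, 2.0, "count")[0]
                for p in (1e-3, 1e-4, 1e-5)]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-5

    def test_monotone_decreasing_in_lengths(self):
        by_null = [theoretical_fdr(0.2, 100, n, 2.0, "count")[0]
                   for n in (100, 300, 1000, 3000)]
        assert all(b <= a for a, b in zip(by_null, by_null[1:]))
        by_feat = [theoretical_fdr(0.2, n, 1000, 2.0, "count")[0]
                   for n in (50, 100, 200, 400)]
        assert all(b <= a for a, b in zip(by_feat, by_feat[1:]))

    def test_monte_carlo_agreement_small(self):
        p, len_f, len_n, thr = 0.2, 30, 100, 2.0
        exact, _ = theoretical_fdr(p, len_f, len_n, thr, "count")
        rng = np.random.default_rng(5)
        n = 200_000
        kf = rng.binomial(len_f, p, size=n)
        kn = rng.binomial(len_n, p, size=n)
        ok = kn > 0
        mc = np.mean(ok & ((kf / len_f) > thr * (kn / len_n)))
        se = math.sqrt(exact * (1 - exact) / n)
        assert abs(mc - exact) < 3 * se + 1e-12

    def test_implied_fdr_requires_explicit_prior(self):
        exceed, implied = theoretical_fdr(0.2, 100, 1000, 2.0, "count")
        assert implied is None
        _, implied = theoretical_fdr(
            0.2, 100, 1000, 2.0, "count", prior_null=0.9, alt_exceedance=0.5
        )
        assert 0 <= implied <= 1
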