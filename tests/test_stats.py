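"""Pointwise tests, run-length null, split-plot ANOVA, contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from hypercoh.stats import (
    StatSeries,
    agency_contrast,
    ar1_coefficient,
    gb_filter,
    gb_threshold,
    longest_run,
    mixed_anova,
    pointwise_paired_t,
)


class TestPointwisePairedT:
    def test_identical_inputs_give_null_result(self, rng):
        a = rng.standard_normal((5, 20))
        ss = pointwise_paired_t(a, a.copy())
        np.testing.assert_allclose(ss.t, 0.0)
        np.testing.assert_allclose(ss.p, 1.0)
        assert not ss.sig_raw.any()

    def test_closed_form_three_subjects(self):
        # differences {1, 2, 3}: mean 2, sd 1, t = 2*sqrt(3), df = 2
        a = np.array([[1.0], [2.0], [3.0]])
        b = np.zeros((3, 1))
        ss = pointwise_paired_t(a, b)
        assert ss.df == 2
        assert ss.t[0] == pytest.approx(2 * np.sqrt(3))
        assert ss.p[0] == pytest.approx(2 * sps.t.sf(2 * np.sqrt(3), 2))

    def test_constant_nonzero_difference_undefined(self, rng):
        a = rng.standard_normal((4, 10))
        b = a.copy()
        a[:, 3] = 1.0
        b[:, 3] = 0.0  # exactly constant non-zero difference
        with pytest.warns(UserWarning, match="zero-variance"):
            ss = pointwise_paired_t(a, b)
        assert np.isnan(ss.t[3]) and not ss.sig_raw[3]
        assert ss.undefined[3]

    def test_rejection_rate_matches_analytic_power(self):
        """Paired t with a 1-sd shift, n=15: empirical power over 2000
        replicates matches the noncentral-t closed form within 2 points."""
        rng = np.random.default_rng(8)
        n, reps = 15, 2000
        d = rng.standard_normal((n, reps)) + 1.0  # shift = 1 sd
        ss = pointwise_paired_t(d, np.zeros_like(d))
        emp = ss.sig_raw.mean()
        crit = sps.t.ppf(0.975, n - 1)
        ncp = np.sqrt(n) * 1.0
        power = sps.nct.sf(crit, n - 1, ncp) + sps.nct.cdf(-crit, n - 1, ncp)
        assert emp == pytest.approx(power, abs=0.02)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            pointwise_paired_t(np.ones((1, 5)), np.zeros((1, 5)))


class TestGBThreshold:
    def test_monotone_in_autocorrelation(self):
        lo = gb_threshold(0.0, 60, 15, n_sim=2000, seed=0)
        hi = gb_threshold(0.9, 60, 15, n_sim=2000, seed=0)
        assert lo < hi

    def test_monotone_in_run_alpha(self):
        # stricter run-level alpha demands longer (rarer) runs, with the
        # pointwise test level held fixed
        strict = gb_threshold(0.8, 60, 15, alpha=0.05, run_alpha=0.01,
                              n_sim=2000, seed=0)
        loose = gb_threshold(0.8, 60, 15, alpha=0.05, run_alpha=0.2,
                             n_sim=2000, seed=0)
        assert strict >= loose

    def test_single_sample_degenerate(self):
        assert gb_threshold(0.5, 1, 15, n_sim=1000, seed=0) == 1

    def test_deterministic_given_seed(self):
        a = gb_threshold(0.7, 50, 10, n_sim=1000, seed=3)
        b = gb_threshold(0.7, 50, 10, n_sim=1000, seed=3)
        assert a == b

    def test_rho_domain_checked(self):
        with pytest.raises(ValueError, match="rho"):
            gb_threshold(1.0, 50, 10, n_sim=1000)

    def test_exceedance_is_at_least_quantile(self):
        q = gb_threshold(0.8, 60, 15, n_sim=2000, seed=1)
        e = gb_threshold(0.8, 60, 15, n_sim=2000, seed=1, convention="exceedance")
        assert e >= q

    def test_familywise_error_controlled_with_exceedance_rule(self):
        """Pointwise t + run filter at the exceedance threshold keeps the
        probability of any surviving cluster near or below alpha on AR(1)
        null data."""
        rho, n_samples, n_sub, reps = 0.8, 60, 12, 500
        thr = gb_threshold(rho, n_samples, n_sub, n_sim=3000, seed=5,
                           convention="exceedance")
        rng = np.random.default_rng(6)
        fp = 0
        sd = np.sqrt(1 - rho**2)
        for _ in range(reps):
            x = np.empty((n_sub, n_samples))
            x[:, 0] = rng.standard_normal(n_sub)
            for k in range(1, n_samples):
                x[:, k] = rho * x[:, k - 1] + sd * rng.standard_normal(n_sub)
            ss = pointwise_paired_t(x, np.zeros_like(x))
            if gb_filter(ss, thr).sig_filtered.any():
                fp += 1
        mc_se = np.sqrt(0.05 * 0.95 / reps)
        assert fp / reps <= 0.05 + 2 * mc_se


class TestGBFilter:
    def _ss(self, mask):
        mask = np.asarray(mask, bool)
        n = len(mask)
        return StatSeries(
            t=np.ones(n), p=np.where(mask, 0.01, 0.5), df=9, sig_raw=mask
        )

    def test_short_run_cleared_long_run_kept(self):
        out = gb_filter(self._ss([1, 1, 1, 0, 1]), 3)
        np.testing.assert_array_equal(out.sig_filtered, [1, 1, 1, 0, 0])

    def test_threshold_one_is_identity(self):
        mask = [0, 1, 0, 1, 1]
        out = gb_filter(self._ss(mask), 1)
        np.testing.assert_array_equal(out.sig_filtered, mask)

    def test_saturated_mask_unchanged(self):
        out = gb_filter(self._ss([1] * 8), 5)
        assert out.sig_filtered.all()

    def test_run_exactly_at_threshold_kept(self):
        out = gb_filter(self._ss([0, 1, 1, 1, 0]), 3)
        np.testing.assert_array_equal(out.sig_filtered, [0, 1, 1, 1, 0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        mask=st.lists(st.booleans(), min_size=1, max_size=40),
        thr=st.integers(1, 10),
    )
    def test_filtered_mask_properties(self, mask, thr):
        out = gb_filter(self._ss(mask), thr)
        # subset of the raw mask
        assert not np.any(out.sig_filtered & ~out.sig_raw)
        # every surviving run is at least thr long; removed runs were shorter
        assert longest_run(out.sig_filtered) == 0 or longest_run(out.sig_filtered) >= thr
        if longest_run(np.asarray(mask, bool)) >= thr:
            assert out.sig_filtered.any()


def brute_force_splitplot(Y):
    """Independent oracle: sums of squares from explicit cell-mean loops.

    Y has shape (groups, subjects, a_levels, f_levels).
    """
    g, n, na, nf = Y.shape
    grand = Y.mean()
    ss = {}
    ss["total"] = ((Y - grand) ** 2).sum()
    # between stratum
    ss["B"] = sum(
        n * na * nf * (Y[gi].mean() - grand) ** 2 for gi in range(g)
    )
    ss["subj"] = sum(
        na * nf * (Y[gi, si].mean() - Y[gi].mean()) ** 2
        for gi in range(g) for si in range(n)
    )
    # within factor A
    ss["A"] = sum(g * n * nf * (Y[:, :, ai].mean() - grand) ** 2 for ai in range(na))
    ss["AB"] = sum(
        n * nf * (Y[gi, :, ai].mean() - Y[gi].mean() - Y[:, :, ai].mean() + grand) ** 2
        for gi in range(g) for ai in range(na)
    )
    ss["Asubj"] = sum(
        nf * (
            Y[gi, si, ai].mean() - Y[gi, si].mean() - Y[gi, :, ai].mean() + Y[gi].mean()
        ) ** 2
        for gi in range(g) for si in range(n) for ai in range(na)
    )
    # within factor F
    ss["F"] = sum(g * n * na * (Y[:, :, :, fi].mean() - grand) ** 2 for fi in range(nf))
    ss["FB"] = sum(
        n * na * (Y[gi, :, :, fi].mean() - Y[gi].mean() - Y[:, :, :, fi].mean() + grand) ** 2
        for gi in range(g) for fi in range(nf)
    )
    ss["Fsubj"] = sum(
        na * (
            Y[gi, si, :, fi].mean() - Y[gi, si].mean()
            - Y[gi, :, :, fi].mean() + Y[gi].mean()
        ) ** 2
        for gi in range(g) for si in range(n) for fi in range(nf)
    )
    # A x F
    ss["AF"] = sum(
        g * n * (
            Y[:, :, ai, fi].mean() - Y[:, :, ai].mean() - Y[:, :, :, fi].mean() + grand
        ) ** 2
        for ai in range(na) for fi in range(nf)
    )
    ss["ABF"] = sum(
        n * (
            Y[gi, :, ai, fi].mean()
            - Y[gi, :, ai].mean() - Y[gi, :, :, fi].mean() - Y[:, :, ai, fi].mean()
            + Y[gi].mean() + Y[:, :, ai].mean() + Y[:, :, :, fi].mean() - grand
        ) ** 2
        for gi in range(g) for ai in range(na) for fi in range(nf)
    )
    ss["AFsubj"] = ss["total"] - sum(
        ss[k] for k in ("B", "subj", "A", "AB", "Asubj", "F", "FB", "Fsubj", "AF", "ABF")
    )
    return ss


def _tidy(Y):
    g, n, na, nf = Y.shape
    rows = []
    for gi in range(g):
        for si in range(n):
            for ai in range(na):
                for fi in range(nf):
                    rows.append(
                        {
                            "subject": f"g{gi}s{si}",
                            "role": ["receiver", "observer"][gi],
                            "agency": ["agent", "pc"][ai],
                            "fairness": ["fair", "hyperunfair"][fi],
                            "amplitude_uv": Y[gi, si, ai, fi],
                        }
                    )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_f_values_match_brute_force_oracle(self, rng):
        Y = rng.standard_normal((2, 4, 2, 2))
        table = mixed_anova(_tidy(Y))
        ss = brute_force_splitplot(Y)
        g, n = 2, 4
        df_subj = g * (n - 1)
        expected = {
            "ROLE": (ss["B"] / 1) / (ss["subj"] / df_subj),
            "AGENCY": (ss["A"] / 1) / (ss["Asubj"] / df_subj),
            "AGENCY:ROLE": (ss["AB"] / 1) / (ss["Asubj"] / df_subj),
            "FAIRNESS": (ss["F"] / 1) / (ss["Fsubj"] / df_subj),
            "FAIRNESS:ROLE": (ss["FB"] / 1) / (ss["Fsubj"] / df_subj),
            "AGENCY:FAIRNESS": (ss["AF"] / 1) / (ss["AFsubj"] / df_subj),
            "AGENCY:FAIRNESS:ROLE": (ss["ABF"] / 1) / (ss["AFsubj"] / df_subj),
        }
        for effect, F in expected.items():
            assert table.effect(effect)["F"] == pytest.approx(F, abs=1e-9), effect

    def test_ss_partition_sums_to_total(self, rng):
        Y = rng.standard_normal((2, 5, 2, 2))
        table = mixed_anova(_tidy(Y))
        # partition identity is asserted internally; check table consistency
        assert table.ss_total == pytest.approx(((Y - Y.mean()) ** 2).sum(), abs=1e-9)

    def test_f_invariant_to_constant_shift(self, rng):
        Y = rng.standard_normal((2, 4, 2, 2))
        t1 = mixed_anova(_tidy(Y))
        t2 = mixed_anova(_tidy(Y + 100.0))
        np.testing.assert_allclose(t1.table["F"], t2.table["F"], atol=1e-8)

    def test_planted_fairness_effect_dominates(self, rng):
        Y = rng.standard_normal((2, 10, 2, 2))
        Y[:, :, :, 0] += 3.0  # large fairness main effect only
        table = mixed_anova(_tidy(Y))
        f_fair = table.effect("FAIRNESS")["F"]
        others = table.table[table.table["effect"] != "FAIRNESS"]["F"]
        assert f_fair > 10 * others.max()
        assert table.effect("FAIRNESS")["p"] < 1e-6

    def test_degrees_of_freedom_for_paper_sized_design(self, rng):
        # 14 receivers + 14 observers: between df (1, 26), within df (1, 26)
        Y = rng.standard_normal((2, 14, 2, 2))
        table = mixed_anova(_tidy(Y))
        row = table.effect("ROLE")
        assert (row["df1"], row["df2"]) == (1, 26)

    def test_unbalanced_missing_cell_rejected(self, rng):
        df = _tidy(rng.standard_normal((2, 4, 2, 2))).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_anova(df)

    def test_unequal_group_sizes_rejected(self, rng):
        df = _tidy(rng.standard_normal((2, 4, 2, 2)))
        df = df[~((df.role == "observer") & (df.subject == "g1s3"))]
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_anova(df)


class TestAgencyContrast:
    def _ss(self, t):
        t = np.asarray(t, float)
        return StatSeries(
            t=t, p=np.ones_like(t), df=9, sig_raw=np.zeros_like(t, bool)
        )

    def test_identical_series_give_zero(self):
        d = agency_contrast(self._ss([1, 2, 3]), self._ss([1, 2, 3]))
        np.testing.assert_allclose(d, 0.0)

    def test_constant_offset_recovered(self):
        d = agency_contrast(self._ss([3, 4, 5]), self._ss([1, 2, 3]))
        np.testing.assert_allclose(d, 2.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            agency_contrast(self._ss([1, 2]), self._ss([1, 2, 3]))


def test_ar1_coefficient_recovers_known_process(rng):
    rho = 0.7
    n = 20000
    x = np.empty(n)
    x[0] = rng.standard_normal()
    eps = rng.standard_normal(n - 1) * np.sqrt(1 - rho**2)
    for k in range(1, n):
        x[k] = rho * x[k - 1] + eps[k - 1]
    assert ar1_coefficient(x) == pytest.approx(rho, abs=0.02)
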