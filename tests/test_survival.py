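"""Kaplan-Meier, log-rank and the per-feature covariate scan."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from mirffl import (
    covariate_scan,
    generate_methylation,
    generate_survival,
    km_estimate,
    log_rank,
    median_split,
    methylation_heatmap_table,
)


def records(times, events, covariates=None):
    n = len(times)
    return pd.DataFrame(
        {
            "sample": [f"S{i}" for i in range(n)],
            "time": times,
            "event": events,
            "covariate": covariates if covariates is not None else np.zeros(n),
        }
    )


def oe_oracle(df, in_high):
    """Independent observed/expected/variance log-rank computation."""
    O1 = E1 = V = 0.0
    for s in sorted(df.loc[df.event == 1, "time"].unique()):
        at = df.time >= s
        n, n1 = at.sum(), (at & in_high).sum()
        dead = (df.time == s) & (df.event == 1)
        d, d1 = dead.sum(), (dead & in_high).sum()
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return O1, E1, V


class TestMedianSplit:
    def test_even_split(self):
        r = records([1, 2, 3, 4], [1, 1, 1, 1], [1.0, 2.0, 3.0, 4.0])
        g = median_split(r)
        assert list(g) == ["low", "low", "high", "high"]

    def test_ties_go_low(self):
        r = records([1] * 5, [1] * 5, [1.0, 2.0, 3.0, 3.0, 4.0])
        g = median_split(r)  # median 3: the tied 3s are low
        assert list(g) == ["low", "low", "low", "low", "high"]

    def test_degenerate_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_split(records([1, 2, 3, 4], [1, 1, 1, 1], [2.0, 2.0, 2.0, 2.0]))

    def test_group_size_gap_bounded_by_ties(self, rng):
        for _ in range(20):
            cov = np.round(rng.normal(size=21), 1)  # coarse grid forces ties
            if np.all(cov == cov[0]):
                continue
            r = records(rng.exponential(10, 21), rng.integers(0, 2, 21), cov)
            g = median_split(r)
            ties = (cov == np.median(cov)).sum()
            gap = abs((g == "high").sum() - (g == "low").sum())
            # at most 2t-1 with t ties at the (attained) median; 0 when the
            # even-n median falls between two distinct values
            assert gap <= 2 * ties if ties else gap <= 1


class TestKmEstimate:
    def test_empirical_survival_no_censoring(self):
        curve = km_estimate(records([1, 2, 3, 4], [1, 1, 1, 1]))
        assert curve.survival_at(2) == pytest.approx(0.5)
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])
        np.testing.assert_allclose(curve.at_risk, [4, 3, 2, 1])

    def test_hand_traced_product_limit_with_censoring(self):
        # deaths at 1 and 3, censored at 2: S(1)=2/3, S(3)=2/3 * (1-1/1)=0
        curve = km_estimate(records([1, 2, 3], [1, 0, 1]))
        np.testing.assert_allclose(curve.times, [1, 3])
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])

    def test_nonincreasing_on_random_data(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 50))
            r = records(rng.exponential(10, n), rng.integers(0, 2, n))
            if r["event"].sum() == 0:
                continue
            curve = km_estimate(r)
            assert (np.diff(curve.survival) <= 1e-12).all()
            assert (np.diff(curve.at_risk) <= 0).all()
            assert (curve.survival >= -1e-12).all() and (curve.survival <= 1).all()

    def test_equals_empirical_survival_when_uncensored(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 200))
            t = rng.exponential(20, n).round(1) + 0.1  # ties included
            curve = km_estimate(records(t, np.ones(n, dtype=int)))
            for s, surv in zip(curve.times, curve.survival):
                assert surv == pytest.approx((t > s).mean(), abs=1e-12)

    def test_zero_events_flat(self):
        curve = km_estimate(records([1, 2, 3], [0, 0, 0]))
        assert curve.times.size == 0
        assert curve.survival_at(99) == 1.0


class TestLogRank:
    def test_identical_groups_null(self):
        base = records([1, 2, 3, 4, 5], [1, 1, 0, 1, 1])
        both = pd.concat([base, base], ignore_index=True)
        groups = pd.Series(["high"] * 5 + ["low"] * 5)
        res = log_rank(both, groups)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.hr == pytest.approx(1.0)
        assert res.n_high == res.n_low == 5

    def test_matches_hand_oracle_small_datasets(self, rng):
        """O/E/V oracle agreement on enumerable datasets of <= 8 subjects."""
        from scipy.stats import chi2 as chi2_dist

        for _ in range(50):
            n = int(rng.integers(4, 9))
            r = records(
                rng.integers(1, 6, n).astype(float), rng.integers(0, 2, n),
                rng.normal(size=n),
            )
            in_high = pd.Series(rng.integers(0, 2, n).astype(bool))
            if in_high.all() or not in_high.any() or r["event"].sum() == 0:
                continue
            groups = pd.Series(np.where(in_high, "high", "low"))
            O1, E1, V = oe_oracle(r, in_high)
            res = log_rank(r, groups, invert_hr=False)
            if V > 0:
                assert res.chi2 == pytest.approx((O1 - E1) ** 2 / V, abs=1e-10)
                assert res.p_value == pytest.approx(chi2_dist.sf(res.chi2, 1), abs=1e-12)
            else:
                assert res.chi2 == 0.0

    def test_matches_lifelines(self, rng):
        for k in range(10):
            s = generate_survival(60, 0.02, 0.7, censor_rate=0.01, seed=1000 + k)
            groups = median_split(s)
            res = log_rank(s, groups, invert_hr=False)
            ref = logrank_test(
                s.loc[(groups == "high").to_numpy(), "time"],
                s.loc[(groups == "low").to_numpy(), "time"],
                s.loc[(groups == "high").to_numpy(), "event"],
                s.loc[(groups == "low").to_numpy(), "event"],
            )
            assert res.chi2 == pytest.approx(ref.test_statistic, rel=1e-6)
            assert res.p_value == pytest.approx(ref.p_value, rel=1e-6)

    def test_hr_inversion_involution(self):
        s = generate_survival(100, 0.02, -1.0, censor_rate=0.01, seed=5)
        groups = median_split(s)
        raw = log_rank(s, groups, invert_hr=False)
        inv = log_rank(s, groups, invert_hr=True)
        if raw.hr < 1:
            assert inv.inverted and inv.hr == pytest.approx(1 / raw.hr)
        else:
            assert not inv.inverted and inv.hr == pytest.approx(raw.hr)
        assert inv.hr >= 1

    def test_chi2_invariant_under_label_swap(self):
        s = generate_survival(80, 0.02, 0.8, censor_rate=0.01, seed=6)
        groups = median_split(s)
        swapped = groups.map({"high": "low", "low": "high"})
        a = log_rank(s, groups, invert_hr=False)
        b = log_rank(s, swapped, invert_hr=False)
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-10)
        assert a.hr == pytest.approx(1 / b.hr, rel=1e-10)

    def test_empty_group_error(self):
        s = generate_survival(20, 0.02, 0.0, seed=1)
        with pytest.raises(ValueError):
            log_rank(s, pd.Series(["high"] * 20))


class TestCovariateScan:
    def test_single_feature_matches_direct_call(self):
        s = generate_survival(60, 0.02, 1.0, censor_rate=0.01, seed=9)
        matrix = pd.DataFrame([s["covariate"].to_numpy()], index=["F1"],
                              columns=s["sample"].tolist())
        scan = covariate_scan(matrix, s)
        direct = log_rank(s, median_split(s))
        assert scan.loc[0, "chi2"] == pytest.approx(direct.chi2)
        assert scan.loc[0, "p_value"] == pytest.approx(direct.p_value)
        assert scan.loc[0, "hr"] == pytest.approx(direct.hr)

    def test_planted_prognostic_cpg_ranks_first(self):
        """One log_hr=1.2 CpG among 50 nulls ranks first by p in >=90% of seeds."""
        hits = 0
        for k in range(100):
            meth = generate_methylation(51, 100, seed=k)
            surv = generate_survival(
                100, 0.02, 1.2, covariate=meth.iloc[0].to_numpy(),
                censor_rate=0.01, seed=10_000 + k,
            )
            scan = covariate_scan(meth, surv)
            hits += scan.iloc[0]["feature_id"] == meth.index[0]
        assert hits >= 90

    def test_null_scan_calibration(self):
        meth = generate_methylation(500, 100, seed=3)
        surv = generate_survival(100, 0.02, 0.0, censor_rate=0.01, seed=4)
        scan = covariate_scan(meth, surv)
        frac = (scan["p_value"] < 0.05).mean()
        assert 0.02 <= frac <= 0.08

    def test_degenerate_feature_skipped(self):
        surv = generate_survival(50, 0.02, 0.0, seed=2)
        matrix = pd.DataFrame(
            [np.ones(50), np.linspace(0, 1, 50)], index=["FLAT", "OK"],
            columns=surv["sample"].tolist(),
        )
        scan = covariate_scan(matrix, surv)
        assert list(scan["feature_id"]) == ["OK"]


class TestHeatmapTable:
    def test_by_mean_order_and_shape(self):
        m = pd.DataFrame([[0.2, 0.2], [0.8, 0.8]], index=["low", "high"], columns=["a", "b"])
        ordered, ann = methylation_heatmap_table(m, "by_mean")
        assert list(ordered.index) == ["high", "low"]
        assert ordered.shape == m.shape
        pd.testing.assert_frame_equal(ordered.sort_index(), m.sort_index())

    def test_by_p_matches_scan(self):
        meth = generate_methylation(20, 60, seed=8)
        surv = generate_survival(60, 0.02, 1.0, covariate=meth.iloc[3].to_numpy(),
                                 censor_rate=0.01, seed=9)
        ordered, ann = methylation_heatmap_table(meth, "by_p", survival=surv)
        scan = covariate_scan(meth, surv)
        assert list(ordered.index)[: len(scan)] == list(scan["feature_id"])

    def test_unknown_order_key(self):
        with pytest.raises(ValueError, match="order"):
            methylation_heatmap_table(pd.DataFrame([[0.1]]), "by_rank")
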