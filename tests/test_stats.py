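import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from pulsegate import (
    build_comparison_table,
    sample_size_wilcoxon,
    shapiro_wilk,
    wilcoxon_signed_rank,
)


def _brute_force_exact_p(x, y):
    """Oracle: enumerate all 2^n sign assignments of the |difference| ranks
    and count assignments with min signed-rank sum <= the observed one."""
    diff = np.asarray(x, float) - np.asarray(y, float)
    diff = diff[diff != 0]
    ranks = sstats.rankdata(np.abs(diff))
    w_pos = ranks[diff > 0].sum()
    w_neg = ranks[diff < 0].sum()
    t_obs = min(w_pos, w_neg)
    n = diff.size
    hits = 0
    for signs in itertools.product((1, -1), repeat=n):
        w = ranks[np.array(signs) > 0].sum()
        if min(w, ranks.sum() - w) <= t_obs + 1e-9:
            hits += 1
    return hits / 2**n


class TestWilcoxon:
    def test_degenerate_all_zero_differences(self):
        x = np.arange(8.0)
        res = wilcoxon_signed_rank(x, x)
        assert res.degenerate and np.isnan(res.p_value)

    def test_one_signed_n21_floor(self):
        # n = 21, every difference positive: the uncorrected normal
        # approximation gives the p-value floor 6.0e-5
        x = np.arange(1.0, 22.0)
        res = wilcoxon_signed_rank(x, np.zeros(21))
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(6.0e-5, rel=0.01)

    def test_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.normal(size=21)
            y = rng.normal(size=21)
            ours = wilcoxon_signed_rank(x, y)
            ref = sstats.wilcoxon(
                x, y, correction=False, method="approx", zero_method="wilcox"
            )
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)
            assert ours.statistic == pytest.approx(ref.statistic)

    @pytest.mark.parametrize("n", [5, 8, 10])
    def test_exact_matches_brute_force(self, n):
        rng = np.random.default_rng(n)
        for _ in range(3):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            ours = wilcoxon_signed_rank(x, y, method="exact")
            assert ours.p_value == pytest.approx(_brute_force_exact_p(x, y))

    def test_exact_handles_ties_and_zeros(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 4.0])
        y = np.array([0.0, 0.0, 0.0, 3.0, 1.0, 1.0, 6.0])
        ours = wilcoxon_signed_rank(x, y, method="exact")
        assert ours.n_used == 6  # one zero difference dropped
        assert ours.p_value == pytest.approx(_brute_force_exact_p(x, y))

    def test_exact_close_to_normal_at_n21(self):
        # away from the floor the two methods agree within 10% relative
        rng = np.random.default_rng(1)
        checked = 0
        for _ in range(10):
            x = rng.normal(size=21)
            y = rng.normal(size=21)
            approx = wilcoxon_signed_rank(x, y).p_value
            exact = wilcoxon_signed_rank(x, y, method="exact").p_value
            if 0.01 < exact < 0.99:
                assert approx == pytest.approx(exact, rel=0.10)
                checked += 1
        assert checked >= 5

    def test_type_i_error_calibrated(self):
        # null: both samples from the same distribution, n = 21, alpha 0.05
        rng = np.random.default_rng(2)
        n_sets = 2000
        rejections = 0
        for _ in range(n_sets):
            x = rng.normal(size=21)
            y = rng.normal(size=21)
            if wilcoxon_signed_rank(x, y).p_value <= 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sets <= 0.07

    def test_input_validation(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2, 3], [0, 0, 0])  # n < 5 for approx


class TestShapiroWilk:
    def test_normal_sample_high_w(self):
        rng = np.random.default_rng(3)
        w, p = shapiro_wilk(rng.normal(size=50))
        assert w > 0.95

    def test_bimodal_sample_rejected(self):
        # two point masses plus jitter: grossly non-normal
        rng = np.random.default_rng(4)
        rejected = 0
        for _ in range(20):
            x = np.concatenate([
                rng.normal(0.0, 0.01, 25), rng.normal(10.0, 0.01, 25)
            ])
            _, p = shapiro_wilk(x)
            rejected += p < 0.05
        assert rejected >= 19

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            shapiro_wilk(np.ones(10))
        with pytest.raises(ValueError):
            shapiro_wilk(np.arange(2.0))


class TestSampleSize:
    def test_reference_planning_point(self):
        plan = sample_size_wilcoxon(0.86, alpha=0.05, power=0.95, tails=2)
        assert plan.n_required == 21
        assert plan.achieved_power >= 0.95

    def test_large_effect_hits_lower_bound(self):
        assert sample_size_wilcoxon(10.0).n_required == 5

    def test_are_one_matches_t_test_oracle(self):
        # with ARE = 1 the procedure is a paired t-test power computation;
        # statsmodels' one-sample noncentral-t solver is the oracle
        from statsmodels.stats.power import TTestPower

        plan = sample_size_wilcoxon(0.6, alpha=0.05, power=0.9, parent="none")
        oracle_n = TTestPower().solve_power(
            effect_size=0.6, alpha=0.05, power=0.9, alternative="two-sided"
        )
        assert plan.n_required == int(np.ceil(oracle_n))

    def test_monotone_in_effect_and_power(self):
        ns = [
            sample_size_wilcoxon(d).n_required for d in (0.4, 0.6, 0.86, 1.2)
        ]
        assert ns == sorted(ns, reverse=True)
        ps = [
            sample_size_wilcoxon(0.86, power=p).n_required
            for p in (0.8, 0.9, 0.95, 0.99)
        ]
        assert ps == sorted(ps)

    def test_invalid_arguments(self):
        for kwargs in (
            {"d": 0.0},
            {"d": 0.5, "alpha": 1.5},
            {"d": 0.5, "tails": 3},
            {"d": 0.5, "parent": "cauchy"},
        ):
            with pytest.raises(ValueError):
                sample_size_wilcoxon(**kwargs)


class TestComparisonTable:
    @staticmethod
    def _contrasts(n_subjects=8, delta2_shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subjects):
            for pulse in (1, 2):
                pre = 0.30 + rng.normal(0, 0.02)
                ext = 0.10 + rng.normal(0, 0.02) + (
                    delta2_shift if pulse == 2 else 0.0
                )
                rows.append({
                    "subject": f"s{s}", "electrode": "Fz",
                    "band_lo": 40, "band_hi": 42, "pulse": pulse,
                    "kind": "min", "pre_mean": pre, "extremum": ext,
                    "delta": ext - pre,
                })
        return pd.DataFrame(rows)

    def test_layout_and_significance(self):
        contrasts = self._contrasts()
        levels = pd.DataFrame({
            "subject": [f"s{s}" for s in range(8)],
            "electrode": "Fz", "band_lo": 40, "band_hi": 42,
            "baseline": np.random.default_rng(1).normal(0.09, 0.01, 8),
            "steady": np.random.default_rng(2).normal(0.33, 0.03, 8),
        })
        erp = pd.DataFrame({
            "subject": [f"s{s}" for s in range(8)],
            "electrode": "Fz",
            "first_amp": np.random.default_rng(3).normal(5.0, 0.5, 8),
            "second_amp": np.random.default_rng(4).normal(3.3, 0.5, 8),
            "pps_percent": 35.0,
        })
        tables = build_comparison_table(contrasts, levels, erp)
        osc = tables["oscillations"]
        assert len(osc) == 1
        row = osc.iloc[0]
        assert row["p_ext_vs_pre_1"] < 0.05  # clear dip
        assert row["ext1_mean"] == pytest.approx(0.10, abs=0.03)
        assert tables["steady_state"].iloc[0]["p_steady_vs_baseline"] < 0.05
        assert tables["erp"].iloc[0]["p_first_vs_second"] < 0.05

    def test_identical_deltas_degenerate(self):
        contrasts = self._contrasts()
        # make pulse-2 deltas exactly equal pulse-1 deltas per subject
        p1 = contrasts[contrasts["pulse"] == 1].copy()
        p2 = p1.copy()
        p2["pulse"] = 2
        tables = build_comparison_table(pd.concat([p1, p2], ignore_index=True))
        assert np.isnan(tables["oscillations"].iloc[0]["p_delta_1_vs_2"])

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            build_comparison_table(pd.DataFrame({"subject": []}))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            build_comparison_table(self._contrasts(n_subjects=3))
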