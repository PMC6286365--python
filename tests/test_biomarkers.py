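"""EV-count statistics, ddCt fold changes, ANOVA with Tukey post hoc."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from qhtskit.biomarkers import (
    GroupedCounts,
    anova_tukey,
    ddct_fold_change,
    ev_dose_response,
    percent_reduction,
)
from qhtskit.exceptions import InvalidParameterError
from qhtskit.synth import simulate_ev_study, simulate_qpcr


def qpcr_table(folds_by_group, noise=0.0, n=3, seed=0):
    return simulate_qpcr(folds_by_group, n=n, noise_sd=noise, seed=seed)


class TestDdct:
    def test_treatment_equal_control_fold_one(self):
        out = ddct_fold_change(qpcr_table({"t": {"g": 1.0}}), "control")
        assert out["fold_change"].iloc[0] == pytest.approx(1.0)

    def test_minus_one_ddct_is_twofold(self):
        out = ddct_fold_change(qpcr_table({"t": {"g": 2.0}}), "control")
        row = out[out["group"] == "t"].iloc[0]
        assert row["mean_ddct"] == pytest.approx(-1.0)
        assert row["fold_change"] == pytest.approx(2.0)

    @settings(max_examples=30, deadline=None)
    @given(offset=st.floats(-5.0, 5.0), seed=st.integers(0, 500))
    def test_plate_offset_invariance(self, offset, seed):
        """Adding a constant to both target and reference Ct of every
        sample leaves all fold-changes unchanged."""
        df = qpcr_table({"t": {"g": 3.0}}, noise=0.2, seed=seed)
        shifted = df.copy()
        shifted["ct_target"] += offset
        shifted["ct_reference"] += offset
        a = ddct_fold_change(df, "control")["fold_change"]
        b = ddct_fold_change(shifted, "control")["fold_change"]
        assert np.allclose(a, b)

    def test_missing_control_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            ddct_fold_change(qpcr_table({"t": {"g": 2.0}}), "no_such_group")

    def test_implausible_ct_rejected(self):
        df = qpcr_table({"t": {"g": 2.0}})
        df.loc[0, "ct_target"] = 60.0
        with pytest.raises(InvalidParameterError):
            ddct_fold_change(df, "control")


class TestPercentReduction:
    def test_equal_means_zero(self):
        assert percent_reduction([5.0, 5.0], [5.0, 5.0]).estimate_pct == 0.0

    def test_complete_suppression_hundred(self):
        assert percent_reduction([0.0, 0.0], [5.0, 6.0]).estimate_pct == 100.0

    def test_antisymmetry_transform(self):
        """Swapping roles maps p -> 100*(1 - 1/(1 - p/100))."""
        t, r = np.array([2.0, 2.4, 1.9]), np.array([4.1, 3.9, 4.0])
        p = percent_reduction(t, r).estimate_pct
        q = percent_reduction(r, t).estimate_pct
        assert q == pytest.approx(100.0 * (1.0 - 1.0 / (1.0 - p / 100.0)))

    def test_bootstrap_and_delta_se_comparable(self):
        rng = np.random.default_rng(0)
        t, r = rng.normal(5, 1, 8), rng.normal(10, 1, 8)
        d = percent_reduction(t, r, method="delta")
        b = percent_reduction(t, r, method="bootstrap", seed=1)
        assert b.se_pct == pytest.approx(d.se_pct, rel=0.5)

    def test_estimator_unbiased_against_generator(self):
        """A planted 51% in-vivo reduction (n=5 per arm, lognormal
        dispersion) is recovered without bias over many replicate studies."""
        estimates = []
        for s in range(1000):
            df = simulate_ev_study(
                group_means={"il1b": 1.0e9, "il1b_treated": 0.49e9},
                n_replicates=5,
                dispersion=0.25,
                seed=s,
            )
            counts = GroupedCounts.from_frame(df)
            estimates.append(
                percent_reduction(
                    counts, counts, "il1b_treated", "il1b"
                ).estimate_pct
            )
        # mean of 1000 estimates: Monte-Carlo SEM ~ 0.5 pct points
        assert np.mean(estimates) == pytest.approx(51.0, abs=1.5)


class TestAnovaTukey:
    def test_identical_groups_null_f(self):
        g = GroupedCounts({"a": [5.0, 5.0, 5.0], "b": [5.0, 5.0, 5.0]})
        res = anova_tukey(g)
        assert res.f_statistic == pytest.approx(0.0)
        assert res.p_value > 0.99

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(10, 2, 6), rng.normal(12, 2, 6)
        res = anova_tukey(GroupedCounts({"a": a, "b": b}))
        t_stat = stats.ttest_ind(a, b).statistic
        assert res.f_statistic == pytest.approx(t_stat**2, rel=1e-9)

    def test_matches_brute_force_oracle_to_ten_figures(self):
        """F from the module equals a brute-force sums-of-squares
        evaluation (and scipy's reference) to 10 significant figures."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            data = {
                f"g{i}": rng.uniform(1.0, 10.0, rng.integers(3, 8))
                for i in range(int(rng.integers(2, 5)))
            }
            res = anova_tukey(GroupedCounts(data))
            # brute force: explicit double loops over observations
            all_vals = [v for g in data.values() for v in g]
            grand = sum(all_vals) / len(all_vals)
            ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in data.values())
            ssw = sum(
                (v - sum(g) / len(g)) ** 2 for g in data.values() for v in g
            )
            dfb, dfw = len(data) - 1, len(all_vals) - len(data)
            f_oracle = (ssb / dfb) / (ssw / dfw)
            assert res.f_statistic == pytest.approx(f_oracle, rel=1e-10)
            assert res.f_statistic == pytest.approx(
                stats.f_oneway(*data.values()).statistic, rel=1e-9
            )

    def test_tukey_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(2)
        data = {c: rng.normal(m, 1.5, 6) for c, m in [("a", 5.0), ("b", 6.0), ("c", 9.0)]}
        res = anova_tukey(GroupedCounts(data))
        values = np.concatenate(list(data.values()))
        labels = np.repeat(list(data), [len(v) for v in data.values()])
        sm = pairwise_tukeyhsd(values, labels)
        assert np.allclose(
            sorted(res.tukey["p_adj"]), sorted(sm.pvalues), atol=1e-6
        )

    def test_shifted_group_flagged_in_all_comparisons(self):
        """A group shifted by 5 SD (n=5) is detected against every other
        group at alpha 0.05 in essentially every simulated study."""
        rng = np.random.default_rng(5)
        hits = 0
        n_sim = 300
        for _ in range(n_sim):
            data = {f"g{i}": rng.normal(50.0, 1.0, 5) for i in range(3)}
            data["shifted"] = rng.normal(55.0, 1.0, 5)
            res = anova_tukey(GroupedCounts(data))
            mask = (res.tukey["group_1"] == "shifted") | (
                res.tukey["group_2"] == "shifted"
            )
            if res.tukey.loc[mask, "reject"].all():
                hits += 1
        assert hits / n_sim >= 0.99

    def test_single_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            anova_tukey(GroupedCounts({"a": [1.0, 2.0]}))


class TestEvDoseResponse:
    DOSES = {"vehicle": 0.0, "d03": 0.3, "d1": 1.0, "d3": 3.0, "d10": 10.0}

    def _study(self, emax, seed=0, dispersion=0.0):
        return simulate_ev_study(
            group_means={
                "vehicle": 1e9,
                "d03": 1e9 * (1 - emax / 100 * 0.3 / 1.3),
                "d1": 1e9 * (1 - emax / 100 * 1.0 / 2.0),
                "d3": 1e9 * (1 - emax / 100 * 3.0 / 4.0),
                "d10": 1e9 * (1 - emax / 100 * 10.0 / 11.0),
            },
            n_replicates=4,
            dispersion=dispersion,
            seed=seed,
        )

    def test_planted_ec50_recovered_noise_free(self):
        counts = GroupedCounts.from_frame(self._study(emax=100.0))
        fit = ev_dose_response(counts, self.DOSES)
        assert fit.ic50_um == pytest.approx(1.0, rel=1e-4)

    def test_inactive_analog_flat(self):
        counts = GroupedCounts.from_frame(self._study(emax=0.0))
        fit = ev_dose_response(counts, self.DOSES)
        assert abs(fit.efficacy) < 5.0
        assert fit.crc_class == 4.0

    def test_single_dose_rejected(self):
        counts = GroupedCounts.from_frame(
            simulate_ev_study(group_means={"vehicle": 1e9, "d1": 5e8}, seed=0)
        )
        with pytest.raises(InvalidParameterError):
            ev_dose_response(counts, {"vehicle": 0.0, "d1": 1.0})
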