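"""Synthetic-data generators: assay forward model, plates, PK, EV, qPCR."""

import numpy as np
import pandas as pd
import pytest

from qhtskit.dose_response import fit_4pl
from qhtskit.exceptions import ConfigurationError, InvalidParameterError
from qhtskit.pk import nca
from qhtskit.plates import ROLE_NEG, ROLE_POS, ROLE_POS_DOSE, ROLE_TEST
from qhtskit.synth import (
    AssayModel,
    CompoundGroundTruth,
    PKParameters,
    make_library,
    simulate_counter_plate,
    simulate_ev_study,
    simulate_pk,
    simulate_plate,
    simulate_qpcr,
    simulate_rate,
)

DOSES_4 = (57.0, 11.4, 2.28, 0.456)


class TestAssayModel:
    def test_michaelis_menten_midpoint(self, clean_assay):
        """At S = Km with no inhibitor the rate is Vmax/2."""
        v = simulate_rate(clean_assay, substrate_um=clean_assay.km_sm)
        assert v == pytest.approx(clean_assay.vmax / 2.0)

    @pytest.mark.parametrize("substrate", [2.0, 20.0, 80.0])
    def test_noncompetitive_halving_at_ki(self, clean_assay, substrate):
        """Noncompetitive inhibition halves the rate at I = Ki at any S."""
        v0 = simulate_rate(clean_assay, substrate)
        v = simulate_rate(clean_assay, substrate, 0.03, 0.03, mode="noncompetitive")
        assert v == pytest.approx(0.5 * v0)

    def test_noncompetitive_round_trip_recovers_ic50(self, clean_assay):
        """A noise-free inhibitor sweep at fixed substrate refits to the
        planted Ki as its IC50 (noncompetitive: IC50 = Ki at any S)."""
        ki = 0.03
        doses = np.geomspace(1e-4, 100.0, 11)
        v0 = simulate_rate(clean_assay, 20.0)
        resp = [
            100.0 * (1.0 - simulate_rate(clean_assay, 20.0, i, ki, mode="noncompetitive") / v0)
            for i in doses
        ]
        fit = fit_4pl(doses, resp)
        assert fit.ic50_um == pytest.approx(ki, rel=1e-4)

    def test_signal_monotone_in_enzyme_substrate_and_time(self):
        """Expected RFU is nondecreasing in enzyme load, substrate and time."""
        base = dict(noise_cv=0.0)
        for field, values in [
            ("enzyme_conc", [0.03, 0.063, 0.1, 0.25, 0.5]),
            ("substrate_conc", [5.0, 10.0, 20.0, 40.0]),
            ("incubation_time", [15.0, 30.0, 60.0, 120.0, 150.0]),
        ]:
            rfu = [
                AssayModel(**{**base, field: v, "vmax": 0.2}).expected_rfu(
                    AssayModel(**{**base, field: v, "vmax": 0.2}).rate()
                )
                for v in values
            ]
            assert np.all(np.diff(rfu) >= 0), field

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            AssayModel(gain=-1.0)
        with pytest.raises(InvalidParameterError):
            AssayModel(km_sm=0.0)
        with pytest.raises(InvalidParameterError):
            simulate_rate(AssayModel(), substrate_um=-5.0)
        with pytest.raises(InvalidParameterError):
            simulate_rate(AssayModel(), 20.0, 1.0, true_ic50_um=-2.0, mode="noncompetitive")

    def test_substrate_depletion_guard(self):
        over = AssayModel(noise_cv=0.0, vmax=5.0, incubation_time=240.0)
        with pytest.raises(InvalidParameterError):
            over.expected_rfu(over.rate())


class TestGroundTruth:
    def test_counter_fp_requires_counter_ic50(self):
        with pytest.raises(InvalidParameterError):
            CompoundGroundTruth("X", "counter_false_positive")

    def test_library_composition_and_determinism(self):
        lib1 = make_library(n_inactive=20, n_true=3, n_counter_fp=2, n_promiscuous=1, seed=5)
        lib2 = make_library(n_inactive=20, n_true=3, n_counter_fp=2, n_promiscuous=1, seed=5)
        assert lib1 == lib2
        counts = pd.Series([c.class_label for c in lib1]).value_counts()
        assert counts["inactive"] == 20 and counts["true_inhibitor"] == 3
        assert all(c.promiscuity_flag == (c.class_label == "promiscuous") for c in lib1)


class TestPlates:
    def test_all_inactive_noise_free_equals_positive_mean(self, layout, clean_assay):
        lib = [CompoundGroundTruth(f"C{i}", "inactive") for i in range(10)]
        plate = simulate_plate(layout, clean_assay, lib, DOSES_4, seed=0)
        pos_mean = plate.loc[plate["role"] == ROLE_POS, "rfu"].mean()
        test = plate.loc[plate["role"] == ROLE_TEST, "rfu"]
        assert np.allclose(test, pos_mean)

    def test_positive_signal_near_2500_rfu(self, layout, noisy_assay):
        """Defaults are tuned to the validated ~2500 RFU uninhibited signal."""
        plate = simulate_plate(layout, noisy_assay, [], seed=1)
        pos = plate.loc[plate["role"] == ROLE_POS, "rfu"]
        assert abs(pos.mean() - 2500.0) < 2 * 0.05 * 2500.0

    def test_fixed_seed_bitwise_identical(self, layout, noisy_assay, small_library):
        p1 = simulate_plate(layout, noisy_assay, small_library, DOSES_4, seed=42)
        p2 = simulate_plate(layout, noisy_assay, small_library, DOSES_4, seed=42)
        pd.testing.assert_frame_equal(p1, p2)

    def test_control_column_roles_and_dose_series(self, layout, clean_assay):
        plate = simulate_plate(layout, clean_assay, [], seed=0)
        col1 = plate[plate["col"] == 1]
        assert set(col1["role"]) == {ROLE_POS_DOSE}
        doses = sorted(col1["conc_um"].unique(), reverse=True)
        assert len(doses) == 16 and doses[0] == pytest.approx(285.0)
        assert np.allclose(np.array(doses[:-1]) / np.array(doses[1:]), 2.0)
        assert set(plate.loc[plate["col"] == 2, "role"]) == {ROLE_NEG}
        assert set(plate.loc[plate["col"] == 3, "role"]) == {ROLE_POS}

    def test_empty_dose_scheme_rejected(self, layout, clean_assay, small_library):
        with pytest.raises(ConfigurationError):
            simulate_plate(layout, clean_assay, small_library, [], seed=0)

    def test_over_capacity_rejected(self, layout, clean_assay):
        lib = [CompoundGroundTruth(f"C{i}", "inactive") for i in range(400)]
        with pytest.raises(ConfigurationError):
            simulate_plate(layout, clean_assay, lib, DOSES_4, seed=0)


class TestCounterPlate:
    def _percent_inhibition(self, plate, cid):
        pos = plate.loc[plate["role"] == ROLE_POS, "rfu"].mean()
        neg = plate.loc[plate["role"] == ROLE_NEG, "rfu"].mean()
        sub = plate[plate["compound_id"] == cid]
        return 100.0 * (1.0 - (sub["rfu"].to_numpy() - neg) / (pos - neg)), sub[
            "conc_um"
        ].to_numpy()

    def test_true_inhibitor_shows_no_counter_inhibition(self, layout):
        lib = [CompoundGroundTruth("T", "true_inhibitor", true_ic50_um=0.03)]
        plate = simulate_counter_plate(
            layout, lib, [100.0, 10.0, 1.0, 0.1], seed=0, assay=AssayModel(noise_cv=0.0)
        )
        inh, _ = self._percent_inhibition(plate, "T")
        assert np.allclose(inh, 0.0, atol=1e-9)

    def test_counter_fp_midpoint(self, layout):
        lib = [CompoundGroundTruth("F", "counter_false_positive", counter_ic50_um=1.0)]
        plate = simulate_counter_plate(
            layout, lib, [1.0], seed=0, assay=AssayModel(noise_cv=0.0)
        )
        inh, _ = self._percent_inhibition(plate, "F")
        assert inh[0] == pytest.approx(50.0)

    def test_inactive_flat_everywhere(self, layout):
        lib = [CompoundGroundTruth("I", "inactive")]
        plate = simulate_counter_plate(
            layout, lib, list(DOSES_4), seed=0, assay=AssayModel(noise_cv=0.0)
        )
        inh, _ = self._percent_inhibition(plate, "I")
        assert np.allclose(inh, 0.0, atol=1e-9)


class TestPK:
    def test_fast_absorption_limit_recovers_ke(self):
        """With near-instant absorption the curve is monoexponential and the
        NCA terminal slope recovers the elimination constant."""
        params = PKParameters(ka=500.0, ke=0.7, amplitude_um=10.0)
        plasma, _ = simulate_pk(params, times_h=(0.25, 0.5, 1, 2, 4, 6), noise_cv=0.0, seed=0)
        res = nca(plasma)
        assert res.lambda_z == pytest.approx(0.7, rel=1e-3)

    def test_brain_partition_round_trip(self):
        plasma, brain = simulate_pk(brain_partition=0.26, noise_cv=0.0, seed=0)
        r_p, r_b = nca(plasma), nca(brain)
        assert r_b.auc_inf / r_p.auc_inf == pytest.approx(0.26, rel=1e-9)

    def test_per_time_mean_cv_scales_with_sqrt_n(self):
        """With n animals per time the per-time mean has CV ~ noise_cv/sqrt(n)."""
        cv, n_per_time, reps = 0.1, 3, 1000
        means = []
        for s in range(reps):
            plasma, _ = simulate_pk(noise_cv=cv, n_per_time=n_per_time, seed=s)
            means.append(plasma.mean[2])
        observed_cv = np.std(means, ddof=1) / np.mean(means)
        assert observed_cv == pytest.approx(cv / np.sqrt(n_per_time), rel=0.1)

    def test_default_analytic_auc_is_ten(self):
        assert PKParameters().auc_inf == pytest.approx(10.0)


class TestEVStudy:
    def test_zero_effect_groups_equal_in_expectation(self):
        df = simulate_ev_study(
            group_means={"a": 5e8, "b": 5e8}, n_replicates=4, dispersion=0.0, seed=0
        )
        means = df.groupby("condition")["value"].mean()
        assert means["a"] == pytest.approx(means["b"])

    def test_saturating_dose_hits_floor(self):
        from qhtskit.synth import EmaxModel

        df = simulate_ev_study(
            effect_model=EmaxModel(vehicle_mean=1e9, ec50_um=0.1, emax_pct=100.0),
            doses_um=[1000.0],
            dispersion=0.0,
            seed=0,
        )
        assert df.loc[df["condition"] == "dose_1000", "value"].mean() == pytest.approx(
            0.0, abs=1e9 * 1e-3
        )

    def test_requires_groups(self):
        with pytest.raises(ConfigurationError):
            simulate_ev_study(group_means={})


class TestQPCR:
    def test_fold_one_gives_zero_ddct(self):
        from qhtskit.biomarkers import ddct_fold_change

        df = simulate_qpcr({"treated": {"tnfa": 1.0}}, noise_sd=0.0, seed=0)
        out = ddct_fold_change(df, "control")
        row = out[(out["group"] == "treated") & (out["gene"] == "tnfa")].iloc[0]
        assert row["mean_ddct"] == pytest.approx(0.0, abs=1e-12)
        assert row["fold_change"] == pytest.approx(1.0)

    def test_fold_two_gives_minus_one_ddct_exactly(self):
        from qhtskit.biomarkers import ddct_fold_change

        df = simulate_qpcr({"treated": {"il6": 2.0}}, noise_sd=0.0, seed=0)
        out = ddct_fold_change(df, "control")
        row = out[(out["group"] == "treated") & (out["gene"] == "il6")].iloc[0]
        assert row["mean_ddct"] == pytest.approx(-1.0)

    def test_planted_fold_recovered_with_noise(self):
        """Across many simulated studies a planted 4-fold induction is
        recovered within 5% on average (0.1-cycle Ct noise, n=5)."""
        from qhtskit.biomarkers import ddct_fold_change

        folds = []
        for s in range(300):
            df = simulate_qpcr({"treated": {"ccl2": 4.0}}, n=5, noise_sd=0.1, seed=s)
            out = ddct_fold_change(df, "control")
            folds.append(
                out[(out["group"] == "treated") & (out["gene"] == "ccl2")][
                    "fold_change"
                ].iloc[0]
            )
        assert np.mean(folds) == pytest.approx(4.0, rel=0.05)
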