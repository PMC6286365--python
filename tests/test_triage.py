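"""Hit-triage cascade: stage rules, conservation, end-to-end recovery."""

import numpy as np
import pytest

from qhtskit.dose_response import DoseResponseResult
from qhtskit.triage import (
    TriageConfig,
    TriageReport,
    confirm,
    counter_screen_filter,
    finalize,
    run_triage,
    select_primary,
    triage_report,
)

DOSES_4 = (0.456, 2.28, 11.4, 57.0)
DOSES_7 = tuple(sorted(57.0 / 3.0**k for k in range(7)))


def result(cid="C", crc=-1.1, top_resp=90.0, ic50=1.0, efficacy=None, doses=DOSES_4):
    """Hand-built classified result; response at the top dose is the last."""
    resp = tuple(np.linspace(5.0, top_resp, len(doses)))
    return DoseResponseResult(
        compound_id=cid,
        assay_id="main",
        doses=tuple(doses),
        response=resp,
        bottom=0.0,
        top=top_resp,
        ic50_um=ic50,
        hill=1.0,
        r2=0.99,
        n_asymptotes=2,
        efficacy=efficacy if efficacy is not None else top_resp,
        converged=True,
        extrapolated=False,
        crc_class=crc,
    )


class TestSelectPrimary:
    def test_boundary_49_percent_excluded(self):
        v = select_primary({"C": result(top_resp=49.0)})["C"]
        assert not v.primary_selected
        assert "primary:top_dose_response" in v.reasons

    def test_robust_class_strong_response_selected(self):
        v = select_primary({"C": result(crc=-1.1, top_resp=90.0)}, {"C": False})["C"]
        assert v.primary_selected and not v.promiscuous_removed

    def test_class_three_excluded_despite_response(self):
        v = select_primary({"C": result(crc=-3.0, top_resp=80.0)})["C"]
        assert not v.primary_selected
        assert "primary:curve_class" in v.reasons

    def test_promiscuous_removed_after_selection(self):
        v = select_primary({"C": result()}, {"C": True})["C"]
        assert v.promiscuous_removed and not v.primary_selected
        assert "primary:promiscuous" in v.reasons

    @pytest.mark.parametrize("crc", [-1.1, -1.2, -2.1, -2.2])
    def test_all_selectable_classes_pass(self, crc):
        assert select_primary({"C": result(crc=crc)})["C"].primary_selected


class TestConfirm:
    def test_selectable_refit_confirms(self):
        verdicts = select_primary({"C": result()})
        verdicts = confirm(verdicts, {"C": result(crc=-1.1, doses=DOSES_7)})
        assert verdicts["C"].confirmed

    def test_inactive_refit_fails_confirmation(self):
        verdicts = select_primary({"C": result()})
        verdicts = confirm(verdicts, {"C": result(crc=4.0, doses=DOSES_7)})
        assert not verdicts["C"].confirmed
        assert "confirm:curve_class" in verdicts["C"].reasons

    def test_empty_input_empty_output(self):
        assert confirm({}, {}) == {}


class TestCounterScreenFilter:
    def test_flat_counter_is_bona_fide(self):
        main = result(crc=-1.1, ic50=0.5)
        counter = result(crc=4.0, top_resp=2.0, efficacy=1.0)
        assert counter_screen_filter(main, counter) == "bona_fide"

    def test_large_potency_gap_is_differential(self):
        main = result(crc=-1.1, ic50=0.1)
        counter = result(crc=-1.1, ic50=50.0)
        assert counter_screen_filter(main, counter) == "differential"

    def test_weak_counter_efficacy_is_differential(self):
        main = result(crc=-1.1, ic50=1.0)
        counter = result(crc=-1.2, ic50=1.0, efficacy=40.0)
        assert counter_screen_filter(main, counter) == "differential"

    def test_identical_curves_are_counter_active(self):
        main = result(crc=-1.1, ic50=1.0)
        assert counter_screen_filter(main, main) == "counter_active"

    def test_threshold_rule_variant(self):
        cfg = TriageConfig(counter_inactive_rule="threshold")
        main = result(crc=-1.1, ic50=0.5)
        counter = result(crc=-2.2, top_resp=20.0, efficacy=20.0)
        assert counter_screen_filter(main, counter, cfg) == "bona_fide"


class TestFinalize:
    def _verdicts(self, ic50, counter_active=False):
        verdicts = select_primary({"C": result()})
        verdicts = confirm(verdicts, {"C": result(doses=DOSES_7, ic50=ic50)})
        verdicts["C"].counter_active = counter_active
        return finalize(verdicts)

    def test_gate_boundary_inclusive(self):
        assert self._verdicts(10.0)["C"].final_hit

    def test_above_gate_excluded(self):
        v = self._verdicts(10.5)["C"]
        assert not v.final_hit and "final:potency_gate" in v.reasons

    def test_counter_active_never_final(self):
        assert not self._verdicts(9.0, counter_active=True)["C"].final_hit


class TestReport:
    def test_flowchart_identities_from_stage_counts(self):
        """The published flowchart arithmetic: 1990 selected, 1782 confirmed
        (90%), 1718 counter false positives (86%), 64 bona fide, +156
        differential = 220 advanced."""
        rep = TriageReport.from_stage_counts(
            selected=1990, confirmed=1782, counter_false_positives=1718,
            differential_rescued=156,
        )
        assert rep.n_bona_fide == 64
        assert rep.n_advanced == 220
        assert round(rep.confirmation_rate_pct) == 90
        assert round(rep.counter_false_positive_rate_pct) == 86
        assert rep.n_unconfirmed == 1990 - 1782

    def test_empty_screen_all_zero(self):
        rep = triage_report({})
        assert rep.n_tested == rep.n_primary_selected == rep.n_final == 0

    def test_counts_match_planted_composition(self, noise_free_config):
        from qhtskit.pipeline import run_pipeline

        s = run_pipeline(noise_free_config)
        t = s["triage"]
        syn = noise_free_config.synth
        # every true inhibitor and every counter fp is selected; promiscuous
        # compounds are removed at the primary stage; inactives never selected
        assert t["n_promiscuous_removed"] == syn.n_promiscuous
        assert t["n_primary_selected"] == syn.n_true + syn.n_counter_fp
        assert t["n_confirmed"] == t["n_primary_selected"]
        assert t["n_counter_active"] == syn.n_counter_fp
        assert t["n_bona_fide"] == syn.n_true
        assert t["n_final"] == syn.n_true


class TestCascadeProperties:
    def test_stage_monotonicity_and_conservation(self, small_config):
        """Each filter's survivors are a subset of its input; differential
        rescue only re-admits counter-removed compounds; every removed
        compound carries a reason."""
        # reuse the pipeline's plate simulation through a deterministic run
        import numpy as np

        from qhtskit.pipeline import screen_and_fit
        from qhtskit.plates import PlateLayout
        from qhtskit.synth import AssayModel, make_library

        cfg = small_config
        rng = np.random.default_rng(cfg.seed)
        seeds = rng.integers(0, 2**31 - 1, size=64)
        lib = make_library(
            n_inactive=cfg.synth.n_inactive,
            n_true=cfg.synth.n_true,
            n_counter_fp=cfg.synth.n_counter_fp,
            n_promiscuous=cfg.synth.n_promiscuous,
            seed=int(seeds[0]),
        )
        assay = AssayModel(noise_cv=cfg.synth.noise_cv)
        layout = PlateLayout()
        th = cfg.dose_response.thresholds()
        primary, _, _ = screen_and_fit(
            lib, assay, layout, cfg.synth.primary_doses_um, seeds[1:17], th
        )
        flags = {c.compound_id: c.promiscuity_flag for c in lib}
        selected_lib = [
            c for c in lib if select_primary(primary, flags)[c.compound_id].primary_selected
        ]
        confirmation, _, _ = screen_and_fit(
            selected_lib, assay, layout, cfg.synth.confirmation_doses_um,
            seeds[17:33], th, "main", "CONFIRM",
        )
        counter, _, _ = screen_and_fit(
            selected_lib, assay, layout, cfg.synth.confirmation_doses_um,
            seeds[33:49], th, "counter", "COUNTER",
        )
        verdicts = run_triage(primary, confirmation, counter, flags)

        sel = {c for c, v in verdicts.items() if v.primary_selected}
        conf = {c for c, v in verdicts.items() if v.confirmed}
        ca = {c for c, v in verdicts.items() if v.counter_active}
        diff = {c for c, v in verdicts.items() if v.differential_rescued}
        final = {c for c, v in verdicts.items() if v.final_hit}
        assert conf <= sel
        assert ca <= conf and diff <= conf
        assert not (ca & diff)
        assert final <= conf - ca
        # conservation at each stage
        rep = triage_report(verdicts)
        assert rep.n_primary_selected == rep.n_confirmed + rep.n_unconfirmed
        assert rep.n_advanced == rep.n_bona_fide + rep.n_differential
        # every compound that fell out somewhere has at least one reason
        for cid, v in verdicts.items():
            if not v.final_hit:
                assert v.reasons, cid

    def test_noise_free_screen_perfect_recovery(self, noise_free_config):
        """On a noise-free synthetic screen the cascade recovers exactly the
        planted inhibitors: sensitivity = specificity = 1."""
        from qhtskit.pipeline import run_pipeline

        summary = run_pipeline(noise_free_config)
        assert summary["recovery"]["sensitivity"] == 1.0
        assert summary["recovery"]["specificity"] == 1.0
        assert summary["recovery"]["false_positives"] == 0
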