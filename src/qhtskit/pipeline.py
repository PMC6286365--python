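"""End-to-end synthetic screening pipeline.

``run_pipeline`` generates a ground-truth compound library, simulates the
4-dose primary screen plate by plate, runs QC, fits and classifies every
compound, then simulates the 7-dose confirmation and counter screens for
the primary-selected set, applies the triage cascade, and writes stage
outputs plus a machine-readable summary into a run directory.  The whole
run is a pure function of (config, seed): rerunning with the same config
yields a byte-identical summary.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as qio
from .config import PipelineConfig, config_hash, save_config
from .dose_response import DoseResponseResult, fit_and_classify
from .plates import PlateLayout
from .qc import plate_qc
from .synth import AssayModel, CompoundGroundTruth, make_library, simulate_counter_plate, simulate_plate
from .triage import run_triage, triage_report, verdicts_frame

__all__ = ["run_pipeline", "screen_and_fit", "recovery_metrics"]


def _chunks(seq, size):
    for i in range(0, len(seq), size):
        yield seq[i : i + size]


def _fit_all(
    responses: pd.DataFrame, assay_id: str, thresholds
) -> dict[str, DoseResponseResult]:
    results = {}
    for cid, g in responses.groupby("compound_id", sort=False):
        results[cid] = fit_and_classify(
            g["conc_um"].to_numpy(),
            g["response"].to_numpy(),
            compound_id=cid,
            assay_id=assay_id,
            thresholds=thresholds,
        )
    return results


def screen_and_fit(
    library: list[CompoundGroundTruth],
    assay: AssayModel,
    layout: PlateLayout,
    doses_um: list[float],
    seeds: np.ndarray,
    thresholds,
    assay_kind: str = "main",
    plate_prefix: str = "MAIN",
    control_ic50_um: float = 27.0,
):
    """Simulate plates for a compound set and fit/classify every compound.

    Returns ``(results, plates, qc_list)``.
    """
    from .dose_response import plate_responses

    per_plate = layout.n_test_wells // len(doses_um)
    plates, qcs, frames = [], [], []
    for i, chunk in enumerate(_chunks(library, per_plate)):
        pid = f"{plate_prefix}-{i + 1:03d}"
        if assay_kind == "main":
            plate = simulate_plate(
                layout, assay, chunk, doses_um, int(seeds[i]), pid, control_ic50_um
            )
        else:
            plate = simulate_counter_plate(layout, chunk, doses_um, int(seeds[i]), pid, assay)
        plates.append(plate)
        qcs.append(plate_qc(plate))
        frames.append(plate_responses(plate))
    responses = pd.concat(frames, ignore_index=True)
    results = _fit_all(responses, assay_kind, thresholds)
    return results, plates, qcs


def recovery_metrics(
    library: list[CompoundGroundTruth],
    verdicts,
    potency_gate_um: float,
) -> dict:
    """Sensitivity/specificity of the final hit set against planted truth.

    A compound is an expected hit when it is a genuine inhibitor with a
    planted IC50 at or below the potency gate.
    """
    expected = {
        c.compound_id
        for c in library
        if c.class_label == "true_inhibitor" and c.true_ic50_um <= potency_gate_um
    }
    final = {cid for cid, v in verdicts.items() if v.final_hit}
    all_ids = {c.compound_id for c in library}
    tp = len(final & expected)
    fp = len(final - expected)
    fn = len(expected - final)
    tn = len(all_ids) - tp - fp - fn
    return {
        "n_expected_hits": len(expected),
        "true_positives": tp,
        "false_positives": fp,
        "false_negatives": fn,
        "sensitivity": tp / len(expected) if expected else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
    }


def run_pipeline(
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    write_plates: bool = True,
) -> dict:
    """Run the full synthetic screen and triage cascade.

    Returns the summary dict; when ``outdir`` is given, also writes the run
    directory (config echo, plate CSVs, QC table, per-stage results CSVs,
    verdicts, and ``summary.json``).
    """
    cfg = config or PipelineConfig()
    s = cfg.synth
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(0, 2**31 - 1, size=64)

    library = make_library(
        n_inactive=s.n_inactive,
        n_true=s.n_true,
        n_counter_fp=s.n_counter_fp,
        n_promiscuous=s.n_promiscuous,
        seed=int(seeds[0]),
        true_ic50_range_um=s.true_ic50_range_um,
        true_efficacy_range_pct=s.true_efficacy_range_pct,
        counter_ic50_range_um=s.counter_ic50_range_um,
        promiscuous_ic50_range_um=s.promiscuous_ic50_range_um,
    )
    assay = AssayModel(noise_cv=s.noise_cv)
    layout = PlateLayout(
        control_top_um=s.control_top_um, control_n_doses=s.control_n_doses
    )
    thresholds = cfg.dose_response.thresholds()
    tri_cfg = cfg.triage.triage_config()

    primary_results, main_plates, main_qc = screen_and_fit(
        library,
        assay,
        layout,
        s.primary_doses_um,
        seeds[1:17],
        thresholds,
        "main",
        "MAIN",
        s.control_ic50_um,
    )
    flags = {c.compound_id: c.promiscuity_flag for c in library}

    from .triage import select_primary

    stage1 = select_primary(primary_results, flags, tri_cfg)
    selected = [
        c for c in library if stage1[c.compound_id].primary_selected
    ]

    confirm_results, confirm_plates, confirm_qc = screen_and_fit(
        selected,
        assay,
        layout,
        s.confirmation_doses_um,
        seeds[17:33],
        thresholds,
        "main",
        "CONFIRM",
        s.control_ic50_um,
    )
    counter_results, counter_plates, counter_qc = screen_and_fit(
        selected,
        assay,
        layout,
        s.confirmation_doses_um,
        seeds[33:49],
        thresholds,
        "counter",
        "COUNTER",
        s.control_ic50_um,
    )

    verdicts = run_triage(primary_results, confirm_results, counter_results, flags, tri_cfg)
    report = triage_report(verdicts)
    recovery = recovery_metrics(library, verdicts, tri_cfg.potency_gate_um)

    final_hits = sorted(
        (
            {"compound_id": cid, "ic50_um": v.ic50_um}
            for cid, v in verdicts.items()
            if v.final_hit
        ),
        key=lambda r: r["ic50_um"],
    )
    summary = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "n_compounds": len(library),
        "qc": {
            "n_plates": len(main_qc),
            "z_prime_mean": float(np.mean([q.z_prime for q in main_qc])),
            "signal_to_background_mean": float(
                np.mean([q.signal_to_background for q in main_qc])
            ),
            "all_passed": bool(all(q.passed for q in main_qc)),
        },
        "triage": asdict(report),
        "recovery": recovery,
        "final_hits": final_hits,
    }

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        save_config(cfg, out / "config.yaml")
        if write_plates:
            pdir = out / "plates"
            pdir.mkdir(exist_ok=True)
            for plate in main_plates + confirm_plates + counter_plates:
                qio.write_plate_csv(plate, pdir / f"{plate['plate_id'].iloc[0]}.csv")
        qc_rows = [
            {
                "plate_id": q.plate_id,
                "pos_mean": q.pos_mean,
                "pos_sd": q.pos_sd,
                "neg_mean": q.neg_mean,
                "neg_sd": q.neg_sd,
                "z_prime": q.z_prime,
                "signal_to_background": q.signal_to_background,
                "positional_flag": q.positional_flag,
                "passed": q.passed,
            }
            for q in main_qc + confirm_qc + counter_qc
        ]
        pd.DataFrame(qc_rows).to_csv(out / "plate_qc.csv", index=False)
        qio.write_results_csv(primary_results, out / "primary_results.csv")
        qio.write_results_csv(confirm_results, out / "confirmation_results.csv")
        qio.write_results_csv(counter_results, out / "counter_results.csv")
        verdicts_frame(verdicts).to_csv(out / "verdicts.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
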