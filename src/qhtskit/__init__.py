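"""qhtskit: quantitative high-throughput screening analysis toolkit.

A reusable implementation of the analysis chain behind an enzyme-inhibitor
discovery campaign: synthetic 1536-well screen generation with planted
ground truth, plate quality control (Z', signal/background, positional
effects), four-parameter-logistic dose-response fitting with curve-response
class (CRC) scoring, the multi-stage hit-triage cascade with counter-screen
and differential rescue, Michaelis-Menten inhibition-mode kinetics,
non-compartmental pharmacokinetics, and extracellular-vesicle / cytokine
biomarker statistics.
"""

from . import biomarkers, config, dose_response, io, kinetics, pipeline, pk, plates, qc, synth, triage
from .config import PipelineConfig, load_config
from .dose_response import (
    CRCThresholds,
    DoseResponseResult,
    crc_classify,
    fit_4pl,
    fit_and_classify,
    ic50_with_ci,
    percent_inhibition,
)
from .kinetics import fit_inhibition_global, fit_mm, selectivity_summary
from .pipeline import run_pipeline
from .pk import auc_ratio, microsome_summary, nca, time_above
from .plates import PlateLayout
from .qc import plate_qc, positional_effect, signal_to_background, z_prime
from .synth import (
    AssayModel,
    CompoundGroundTruth,
    EmaxModel,
    PKParameters,
    make_library,
    simulate_counter_plate,
    simulate_ev_study,
    simulate_pk,
    simulate_plate,
    simulate_qpcr,
    simulate_rate,
)
from .triage import TriageConfig, TriageReport, run_triage, triage_report

__version__ = "0.1.0"
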