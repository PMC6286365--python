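"""Hit-triage cascade for a quantitative HTS campaign.

Stages mirror the screening flowchart: primary selection on the 4-dose
screen (top-dose response and robust curve class), removal of flagged
promiscuous compounds, 7-dose confirmation refit, counter-screen
elimination of detection-cascade false positives, differential rescue of
compounds far more potent in the main assay than in the counter assay, and
a final potency gate (IC50 <= 10 µM, inclusive).

Every stage records a reason code for each removed compound; stage counts
satisfy the conservation identities reproduced by :func:`triage_report`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import SELECTABLE_CLASSES, DoseResponseResult
from .exceptions import InvalidParameterError

__all__ = [
    "TriageConfig",
    "TriageVerdict",
    "TriageReport",
    "select_primary",
    "confirm",
    "counter_screen_filter",
    "finalize",
    "run_triage",
    "triage_report",
    "verdicts_frame",
]


@dataclass(frozen=True)
class TriageConfig:
    top_dose_response_min: float = 50.0  # percent, strict > at the top dose
    selectable_classes: tuple = SELECTABLE_CLASSES
    counter_inactive_rule: str = "class"  # or "threshold"
    counter_inactive_floor: float = 30.0  # percent response for rule="threshold"
    differential_pic50_gap: float = 1.0  # log units main vs counter potency
    differential_counter_efficacy: float = 50.0  # percent
    potency_gate_um: float = 10.0  # inclusive


@dataclass
class TriageVerdict:
    compound_id: str
    primary_selected: bool = False
    promiscuous_removed: bool = False
    confirmed: bool = False
    counter_active: bool = False
    differential_rescued: bool = False
    final_hit: bool = False
    ic50_um: float = math.nan
    reasons: list = field(default_factory=list)


def select_primary(
    results: dict[str, DoseResponseResult],
    promiscuity_flags: dict[str, bool] | None = None,
    config: TriageConfig | None = None,
) -> dict[str, TriageVerdict]:
    """Primary-screen selection on classified 4-dose results.

    A compound is selected when its response at the highest tested dose
    exceeds the activity floor *and* its curve class is one of the robust
    inhibition classes; flagged promiscuous compounds are then removed.
    Returns a verdict per compound (selected or not, with reasons).
    """
    cfg = config or TriageConfig()
    flags = promiscuity_flags or {}
    verdicts: dict[str, TriageVerdict] = {}
    for cid, res in results.items():
        v = TriageVerdict(compound_id=cid)
        if res.crc_class is None:
            raise InvalidParameterError(f"{cid}: result not classified")
        active = res.response_at_top_dose > cfg.top_dose_response_min
        robust = res.crc_class in cfg.selectable_classes
        if not active:
            v.reasons.append("primary:top_dose_response")
        if not robust:
            v.reasons.append("primary:curve_class")
        if active and robust:
            v.primary_selected = True
            if flags.get(cid, False):
                v.primary_selected = False
                v.promiscuous_removed = True
                v.reasons.append("primary:promiscuous")
        verdicts[cid] = v
    return verdicts


def confirm(
    verdicts: dict[str, TriageVerdict],
    confirmation_results: dict[str, DoseResponseResult],
    config: TriageConfig | None = None,
) -> dict[str, TriageVerdict]:
    """Confirmation stage: the 7-dose refit must retain a selectable class."""
    cfg = config or TriageConfig()
    for cid, v in verdicts.items():
        if not v.primary_selected:
            continue
        res = confirmation_results.get(cid)
        if res is None or res.crc_class is None:
            v.reasons.append("confirm:missing_refit")
            continue
        v.ic50_um = res.ic50_um
        if res.crc_class in cfg.selectable_classes:
            v.confirmed = True
        else:
            v.reasons.append("confirm:curve_class")
    return verdicts


def counter_screen_filter(
    main: DoseResponseResult,
    counter: DoseResponseResult,
    config: TriageConfig | None = None,
) -> str:
    """Classify one compound's counter-screen outcome.

    Returns ``"bona_fide"`` when the counter curve is inactive (class 4 by
    default, or below the response floor at the top counter dose under the
    threshold rule), ``"differential"`` when counter-active but much weaker
    than in the main assay (pIC50 gap >= 1 log, or counter efficacy < 50%),
    else ``"counter_active"``.
    """
    cfg = config or TriageConfig()
    if cfg.counter_inactive_rule == "class":
        inactive = counter.crc_class == 4.0
    elif cfg.counter_inactive_rule == "threshold":
        inactive = counter.response_at_top_dose < cfg.counter_inactive_floor
    else:
        raise InvalidParameterError(
            f"unknown counter_inactive_rule {cfg.counter_inactive_rule!r}"
        )
    if inactive:
        return "bona_fide"
    if (
        counter.converged
        and not math.isnan(counter.efficacy)
        and counter.efficacy < cfg.differential_counter_efficacy
    ):
        return "differential"
    if (
        main.converged
        and counter.converged
        and np.isfinite(main.ic50_um)
        and np.isfinite(counter.ic50_um)
        and math.log10(counter.ic50_um / main.ic50_um) >= cfg.differential_pic50_gap
    ):
        return "differential"
    return "counter_active"


def finalize(
    verdicts: dict[str, TriageVerdict],
    config: TriageConfig | None = None,
) -> dict[str, TriageVerdict]:
    """Final potency gate over confirmed, counter-clean compounds.

    ``final_hit`` requires confirmation, a clean (or rescued) counter
    outcome, and a confirmation IC50 at or below the potency gate.
    """
    cfg = config or TriageConfig()
    for v in verdicts.values():
        if not v.confirmed or v.counter_active:
            continue
        if not math.isnan(v.ic50_um) and v.ic50_um <= cfg.potency_gate_um:
            v.final_hit = True
        else:
            v.reasons.append("final:potency_gate")
    return verdicts


def run_triage(
    primary_results: dict[str, DoseResponseResult],
    confirmation_results: dict[str, DoseResponseResult],
    counter_results: dict[str, DoseResponseResult],
    promiscuity_flags: dict[str, bool] | None = None,
    config: TriageConfig | None = None,
) -> dict[str, TriageVerdict]:
    """Run the full cascade and return a verdict per screened compound."""
    cfg = config or TriageConfig()
    verdicts = select_primary(primary_results, promiscuity_flags, cfg)
    verdicts = confirm(verdicts, confirmation_results, cfg)
    for cid, v in verdicts.items():
        if not v.confirmed:
            continue
        counter = counter_results.get(cid)
        if counter is None:
            raise InvalidParameterError(f"{cid}: confirmed but no counter-screen result")
        outcome = counter_screen_filter(confirmation_results[cid], counter, cfg)
        if outcome == "counter_active":
            v.counter_active = True
            v.reasons.append("counter:active")
        elif outcome == "differential":
            v.differential_rescued = True
            v.reasons.append("counter:differential_rescue")
    return finalize(verdicts, cfg)


def verdicts_frame(verdicts: dict[str, TriageVerdict]) -> pd.DataFrame:
    rows = [
        {
            "compound_id": v.compound_id,
            "primary_selected": v.primary_selected,
            "promiscuous_removed": v.promiscuous_removed,
            "confirmed": v.confirmed,
            "counter_active": v.counter_active,
            "differential_rescued": v.differential_rescued,
            "final_hit": v.final_hit,
            "ic50_um": v.ic50_um,
            "reasons": ";".join(v.reasons),
        }
        for v in verdicts.values()
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TriageReport:
    """Stage counts of the cascade plus the flowchart arithmetic identities.

    ``n_advanced = n_bona_fide + n_differential`` is the follow-up set;
    ``n_bona_fide = n_confirmed - n_counter_active``; rates are relative to
    the primary-selected set, in percent.
    """

    n_tested: int
    n_primary_selected: int
    n_promiscuous_removed: int
    n_confirmed: int
    n_unconfirmed: int
    n_counter_active: int
    n_bona_fide: int
    n_differential: int
    n_advanced: int
    n_final: int

    @property
    def confirmation_rate_pct(self) -> float:
        if self.n_primary_selected == 0:
            return math.nan
        return 100.0 * self.n_confirmed / self.n_primary_selected

    @property
    def counter_false_positive_rate_pct(self) -> float:
        if self.n_primary_selected == 0:
            return math.nan
        return 100.0 * self.n_counter_active / self.n_primary_selected

    @classmethod
    def from_stage_counts(
        cls,
        selected: int,
        confirmed: int,
        counter_false_positives: int,
        differential_rescued: int,
        tested: int | None = None,
        promiscuous_removed: int = 0,
        final: int = 0,
    ) -> "TriageReport":
        """Reproduce the flowchart bookkeeping from stage totals alone."""
        bona_fide = confirmed - counter_false_positives
        return cls(
            n_tested=tested if tested is not None else selected,
            n_primary_selected=selected,
            n_promiscuous_removed=promiscuous_removed,
            n_confirmed=confirmed,
            n_unconfirmed=selected - confirmed,
            n_counter_active=counter_false_positives,
            n_bona_fide=bona_fide,
            n_differential=differential_rescued,
            n_advanced=bona_fide + differential_rescued,
            n_final=final,
        )


def triage_report(verdicts: dict[str, TriageVerdict]) -> TriageReport:
    """Stage-count summary of a set of verdicts (flowchart reproduction)."""
    vs = list(verdicts.values())
    selected = sum(v.primary_selected for v in vs)
    confirmed = sum(v.confirmed for v in vs)
    counter_active = sum(v.counter_active for v in vs)
    differential = sum(v.differential_rescued for v in vs)
    bona_fide = confirmed - counter_active - differential
    return TriageReport(
        n_tested=len(vs),
        n_primary_selected=selected,
        n_promiscuous_removed=sum(v.promiscuous_removed for v in vs),
        n_confirmed=confirmed,
        n_unconfirmed=selected - confirmed,
        n_counter_active=counter_active,
        n_bona_fide=bona_fide,
        n_differential=differential,
        n_advanced=bona_fide + differential,
        n_final=sum(v.final_hit for v in vs),
    )
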