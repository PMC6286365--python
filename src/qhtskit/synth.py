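"""Synthetic data generators for every stage of the screening pipeline.

All inputs the pipeline consumes can be generated here with known ground
truth: 1536-well screening plates (main assay and counter assay), enzyme
kinetic rate tables, plasma/brain concentration–time profiles, grouped
extracellular-vesicle (EV) particle counts, and qPCR Ct tables.

The forward model of the fluorescence assay: the enzyme hydrolyses
sphingomyelin at a Michaelis–Menten rate; the liberated phosphorylcholine is
converted stoichiometrically through a coupled enzymatic cascade to a
fluorophore, so RFU = background + gain × product.  Product accumulation is
linearised over the incubation (the reaction is run in its linear range and
substrate depletion is guarded to stay below 10%).  Well-level noise is
multiplicative lognormal with configurable CV, which keeps RFU positive.

Every generator is a pure function of its parameters and an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InvalidParameterError
from .pk import ConcentrationTimeProfile
from .plates import ROLE_NEG, ROLE_POS_DOSE, ROLE_TEST, PlateLayout, row_label

__all__ = [
    "AssayModel",
    "CompoundGroundTruth",
    "PKParameters",
    "EmaxModel",
    "simulate_rate",
    "simulate_plate",
    "simulate_counter_plate",
    "simulate_kinetic_table",
    "simulate_pk",
    "simulate_ev_study",
    "simulate_qpcr",
    "make_library",
    "fractional_activity",
    "crc_exemplar_curves",
    "CRC_EXEMPLAR_REGIONS",
    "PLATE_COLUMNS",
]

#: Documented column order of plate tables.
PLATE_COLUMNS = ["plate_id", "row", "col", "role", "compound_id", "conc_um", "rfu"]

CLASS_LABELS = ("inactive", "true_inhibitor", "counter_false_positive", "promiscuous")


# ---------------------------------------------------------------------------
# assay forward model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssayModel:
    """Forward model of the coupled-fluorescence enzyme activity assay.

    Parameters
    ----------
    enzyme_conc : float
        Enzyme preparation concentration, µg protein/µL.  The catalytic rate
        scales linearly with ``enzyme_conc / reference_enzyme_conc``.
    substrate_conc : float
        Sphingomyelin concentration, µM.
    incubation_time : float
        Incubation, minutes.
    gain : float
        RFU per µM of fluorogenic product.
    background_rfu : float
        Fluorescence of a no-enzyme well, RFU.
    noise_cv : float
        Well-level multiplicative lognormal coefficient of variation.
    km_sm : float
        Michaelis constant for sphingomyelin, µM.
    vmax : float
        Maximal rate at the reference enzyme concentration, µM product / h.

    The defaults reproduce the optimised screening conditions: 0.1 µg/µL
    enzyme, 20 µM substrate, 2 h incubation, yielding an uninhibited signal
    of 2500 RFU over a 119 RFU background (signal/background 21).
    """

    enzyme_conc: float = 0.1
    substrate_conc: float = 20.0
    incubation_time: float = 120.0
    gain: float = 2381.0
    background_rfu: float = 119.0
    noise_cv: float = 0.05
    km_sm: float = 20.0
    vmax: float = 1.0
    reference_enzyme_conc: float = 0.1

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise InvalidParameterError("gain must be > 0")
        if self.noise_cv < 0:
            raise InvalidParameterError("noise_cv must be >= 0")
        if self.km_sm <= 0 or self.vmax <= 0:
            raise InvalidParameterError("Km and Vmax must be > 0")
        if self.enzyme_conc < 0 or self.reference_enzyme_conc <= 0:
            raise InvalidParameterError("enzyme concentrations must be positive")
        if self.substrate_conc <= 0 or self.incubation_time < 0:
            raise InvalidParameterError("substrate and incubation must be positive")

    def rate(self, substrate: float | None = None) -> float:
        """Uninhibited catalytic rate (µM product / h) at this enzyme load."""
        s = self.substrate_conc if substrate is None else substrate
        scale = self.enzyme_conc / self.reference_enzyme_conc
        return scale * self.vmax * s / (self.km_sm + s)

    def product_um(self, rate_um_per_h: float) -> float:
        """Linearised product accumulated over the incubation, µM."""
        prod = rate_um_per_h * self.incubation_time / 60.0
        if prod > 0.1 * self.substrate_conc:
            raise InvalidParameterError(
                "linearised product exceeds 10% of substrate; "
                "shorten incubation or lower enzyme concentration"
            )
        return prod

    def expected_rfu(self, rate_um_per_h: float) -> float:
        return self.background_rfu + self.gain * self.product_um(rate_um_per_h)


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise factors."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def fractional_activity(
    inhibitor_um: float | np.ndarray,
    ic50_um: float,
    efficacy_pct: float = 100.0,
    hill: float = 1.0,
) -> float | np.ndarray:
    """Remaining fractional activity under a Hill-type inhibitor.

    ``1 - (efficacy/100) * I^h / (I^h + IC50^h)``; efficacy 100 and hill 1
    recover the simple Langmuir inhibition curve.
    """
    if ic50_um <= 0:
        raise InvalidParameterError("ic50 must be > 0")
    if not 0 <= efficacy_pct <= 100:
        raise InvalidParameterError("efficacy must lie in [0, 100]")
    i = np.asarray(inhibitor_um, dtype=float)
    frac = 1.0 - (efficacy_pct / 100.0) * i**hill / (i**hill + ic50_um**hill)
    return float(frac) if np.isscalar(inhibitor_um) else frac


def simulate_rate(
    assay: AssayModel,
    substrate_um: float,
    inhibitor_um: float = 0.0,
    true_ic50_um: float | None = None,
    efficacy_pct: float = 100.0,
    mode: str = "none",
) -> float:
    """Catalytic rate (µM/h) under a Michaelis–Menten + inhibition model.

    Modes
    -----
    ``none``
        Plain Michaelis–Menten.
    ``noncompetitive``
        ``v = Vmax*S / ((Km+S)*(1+I/Ki))`` with ``Ki = true_ic50``: the rate
        is halved at ``I = IC50`` regardless of substrate.  ``efficacy < 100``
        caps the attainable inhibition.
    ``competitive`` / ``uncompetitive``
        Textbook forms with ``Ki = true_ic50`` (for these modes the apparent
        IC50 depends on substrate; the supplied value is the Ki).
    """
    if substrate_um <= 0:
        raise InvalidParameterError("substrate must be > 0")
    if inhibitor_um < 0:
        raise InvalidParameterError("inhibitor must be >= 0")
    scale = assay.enzyme_conc / assay.reference_enzyme_conc
    vmax, km = scale * assay.vmax, assay.km_sm
    s, i = substrate_um, inhibitor_um
    if mode == "none" or i == 0 or true_ic50_um is None:
        return vmax * s / (km + s)
    ki = float(true_ic50_um)
    if ki <= 0:
        raise InvalidParameterError("true_ic50 must be > 0")
    if mode == "noncompetitive":
        v0 = vmax * s / (km + s)
        return v0 * fractional_activity(i, ki, efficacy_pct)
    if mode == "competitive":
        return vmax * s / (km * (1.0 + i / ki) + s)
    if mode == "uncompetitive":
        return vmax * s / (km + s * (1.0 + i / ki))
    raise InvalidParameterError(f"unknown inhibition mode {mode!r}")


# ---------------------------------------------------------------------------
# compound ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundGroundTruth:
    """Planted identity of a library compound.

    ``true_ic50_um``/``true_efficacy_pct`` describe activity against the
    target enzyme (or, for promiscuous compounds, their apparent activity).
    ``counter_ic50_um`` is the potency with which a detection-cascade
    inhibitor suppresses the coupled readout; such compounds look fully
    active in the main assay without touching the enzyme.
    """

    compound_id: str
    class_label: str
    true_ic50_um: float | None = None
    true_efficacy_pct: float = 100.0
    counter_ic50_um: float | None = None
    promiscuity_flag: bool = False

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise InvalidParameterError(f"unknown class label {self.class_label!r}")
        if self.true_ic50_um is not None and self.true_ic50_um <= 0:
            raise InvalidParameterError("true_ic50 must be > 0 when present")
        if not 0 <= self.true_efficacy_pct <= 100:
            raise InvalidParameterError("efficacy must lie in [0, 100]")
        if self.class_label == "counter_false_positive" and self.counter_ic50_um is None:
            raise InvalidParameterError("counter_false_positive requires counter_ic50")
        if self.counter_ic50_um is not None and self.counter_ic50_um <= 0:
            raise InvalidParameterError("counter_ic50 must be > 0 when present")


def make_library(
    n_inactive: int = 1387,
    n_true: int = 8,
    n_counter_fp: int = 30,
    n_promiscuous: int = 15,
    seed: int = 0,
    true_ic50_range_um: tuple[float, float] = (0.03, 3.0),
    true_efficacy_range_pct: tuple[float, float] = (85.0, 100.0),
    counter_ic50_range_um: tuple[float, float] = (0.1, 50.0),
    promiscuous_ic50_range_um: tuple[float, float] = (1.0, 30.0),
) -> list[CompoundGroundTruth]:
    """Build a ground-truth compound library.

    Potencies are drawn log-uniformly within the stated ranges.  The default
    composition mirrors a scaled-down screen: a rare population of genuine
    inhibitors, a larger pool of detection-cascade false positives, a handful
    of flagged promiscuous actives, and an inactive majority.
    """
    rng = np.random.default_rng(seed)

    def logu(lo: float, hi: float, n: int) -> np.ndarray:
        return np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))

    lib: list[CompoundGroundTruth] = []
    k = 0
    for ic50, eff in zip(
        logu(*true_ic50_range_um, n_true),
        rng.uniform(*true_efficacy_range_pct, size=n_true),
    ):
        lib.append(
            CompoundGroundTruth(f"CMPD-{k:05d}", "true_inhibitor", float(ic50), float(eff))
        )
        k += 1
    for cic50 in logu(*counter_ic50_range_um, n_counter_fp):
        lib.append(
            CompoundGroundTruth(
                f"CMPD-{k:05d}",
                "counter_false_positive",
                counter_ic50_um=float(cic50),
            )
        )
        k += 1
    for ic50 in logu(*promiscuous_ic50_range_um, n_promiscuous):
        lib.append(
            CompoundGroundTruth(
                f"CMPD-{k:05d}",
                "promiscuous",
                true_ic50_um=float(ic50),
                promiscuity_flag=True,
            )
        )
        k += 1
    for _ in range(n_inactive):
        lib.append(CompoundGroundTruth(f"CMPD-{k:05d}", "inactive"))
        k += 1
    # deterministic shuffle so classes are spread over plates
    order = rng.permutation(len(lib))
    return [lib[i] for i in order]


# ---------------------------------------------------------------------------
# plate simulation
# ---------------------------------------------------------------------------


def _main_assay_activity(c: CompoundGroundTruth, dose_um: float) -> float:
    """Fractional signal remaining in the main assay at one dose."""
    if c.class_label == "inactive":
        return 1.0
    if c.class_label == "counter_false_positive":
        # suppresses the detection cascade, hence the whole readout
        return fractional_activity(dose_um, c.counter_ic50_um)
    # true inhibitors and promiscuous actives inhibit the enzyme (apparently)
    return fractional_activity(dose_um, c.true_ic50_um, c.true_efficacy_pct)


def _counter_assay_activity(c: CompoundGroundTruth, dose_um: float) -> float:
    """Fractional signal remaining in the enzyme-free counter assay."""
    if c.class_label == "counter_false_positive":
        return fractional_activity(dose_um, c.counter_ic50_um)
    return 1.0


def _build_plate(
    layout: PlateLayout,
    assay: AssayModel,
    compounds: Sequence[CompoundGroundTruth],
    dose_scheme: Sequence[float],
    seed: int,
    plate_id: str,
    activity_fn,
    control_active: bool,
    control_ic50_um: float,
) -> pd.DataFrame:
    if not dose_scheme:
        raise ConfigurationError("dose_scheme must not be empty")
    if any(d <= 0 for d in dose_scheme):
        raise ConfigurationError("doses must be positive")
    n_wells_needed = len(compounds) * len(dose_scheme)
    if n_wells_needed > layout.n_test_wells:
        raise ConfigurationError(
            f"{len(compounds)} compounds x {len(dose_scheme)} doses "
            f"exceed {layout.n_test_wells} test wells"
        )
    rng = np.random.default_rng(seed)
    v0 = assay.rate()  # uninhibited rate under screening conditions
    signal0 = assay.gain * assay.product_um(v0)

    rows: list[tuple] = []
    # control columns
    ctrl_doses = layout.control_doses_um()
    per_dose = layout.n_rows // layout.control_n_doses
    for col in range(1, layout.n_cols + 1):
        role = layout.role_of(col)
        if role == ROLE_TEST:
            continue
        for r in range(layout.n_rows):
            if role == ROLE_POS_DOSE:
                dose = ctrl_doses[r // per_dose]
                frac = (
                    fractional_activity(dose, control_ic50_um) if control_active else 1.0
                )
                mu = assay.background_rfu + signal0 * frac
                cid, conc = "CONTROL-INHIBITOR", dose
            elif role == ROLE_NEG:
                mu = assay.background_rfu
                cid, conc = "", 0.0
            else:  # saturating positive control: full uninhibited signal
                mu = assay.background_rfu + signal0
                cid, conc = "", 0.0
            rows.append((plate_id, row_label(r), col, role, cid, conc, mu))

    # test field: each compound occupies len(dose_scheme) consecutive wells
    wells = [(r, c) for c in layout.test_columns for r in range(layout.n_rows)]
    i = 0
    for comp in compounds:
        for dose in dose_scheme:
            r, c = wells[i]
            mu = assay.background_rfu + signal0 * activity_fn(comp, dose)
            rows.append(
                (plate_id, row_label(r), c, ROLE_TEST, comp.compound_id, dose, mu)
            )
            i += 1
    # leftover test wells carry vehicle only (full signal)
    for r, c in wells[i:]:
        rows.append(
            (plate_id, row_label(r), c, ROLE_TEST, "", 0.0, assay.background_rfu + signal0)
        )

    df = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    df["rfu"] = df["rfu"].to_numpy() * _lognormal_factors(rng, assay.noise_cv, len(df))
    return df


def simulate_plate(
    layout: PlateLayout,
    assay: AssayModel,
    compounds: Sequence[CompoundGroundTruth],
    dose_scheme: Sequence[float] = (57.0, 11.4, 2.28, 0.456),
    seed: int = 0,
    plate_id: str = "MAIN-001",
    control_ic50_um: float = 27.0,
) -> pd.DataFrame:
    """Simulate one main-assay screening plate.

    The default dose scheme is the 4-dose primary design (57 µM top, 1:5
    dilutions).  Column 1 carries the positive-inhibitor dose series
    (IC50 ``control_ic50_um``, default 27 µM), column 2 the no-enzyme
    background, column 3 the saturating positive control.
    """
    return _build_plate(
        layout,
        assay,
        compounds,
        dose_scheme,
        seed,
        plate_id,
        _main_assay_activity,
        control_active=True,
        control_ic50_um=control_ic50_um,
    )


def simulate_counter_plate(
    layout: PlateLayout,
    compounds: Sequence[CompoundGroundTruth],
    dose_scheme: Sequence[float] = (57.0, 11.4, 2.28, 0.456),
    seed: int = 0,
    plate_id: str = "COUNTER-001",
    assay: AssayModel | None = None,
) -> pd.DataFrame:
    """Simulate one counter-assay plate (detection cascade only, no enzyme).

    The cascade is primed with its own substrate, so uninhibited wells give
    the full signal; genuine enzyme inhibitors produce no inhibition here,
    while detection-cascade inhibitors suppress signal with their
    ``counter_ic50``.  The column-1 inhibitor series is enzyme-directed and
    therefore inactive on this plate.
    """
    assay = assay or AssayModel()
    return _build_plate(
        layout,
        assay,
        compounds,
        dose_scheme,
        seed,
        plate_id,
        _counter_assay_activity,
        control_active=False,
        control_ic50_um=27.0,
    )


# ---------------------------------------------------------------------------
# kinetic tables
# ---------------------------------------------------------------------------


def simulate_kinetic_table(
    assay: AssayModel,
    substrate_um: Sequence[float] = (2.5, 5.0, 10.0, 20.0, 40.0, 80.0),
    inhibitor_um: Sequence[float] = (0.0, 0.01, 0.03, 0.1),
    true_ic50_um: float = 0.03,
    mode: str = "noncompetitive",
    noise_cv: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Rate table over a substrate × inhibitor grid.

    Columns: ``substrate_um, inhibitor_um, replicate, rate`` (µM/h).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i_conc in inhibitor_um:
        for s in substrate_um:
            v = simulate_rate(assay, s, i_conc, true_ic50_um, mode=mode)
            for rep in range(n_replicates):
                rows.append((s, i_conc, rep, v))
    df = pd.DataFrame(rows, columns=["substrate_um", "inhibitor_um", "replicate", "rate"])
    df["rate"] = df["rate"].to_numpy() * _lognormal_factors(rng, noise_cv, len(df))
    return df


# ---------------------------------------------------------------------------
# pharmacokinetic profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PKParameters:
    """One-compartment first-order absorption model, C(t) = A(e^-ke t - e^-ka t).

    Defaults give a plasma AUC(0-inf) of 10 µM·h with a sampled Tmax of 0.5 h
    under the standard 6-time-point design.
    """

    ka: float = 3.2  # 1/h
    ke: float = 0.8  # 1/h
    amplitude_um: float = 10.0 / (1 / 0.8 - 1 / 3.2)

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.ke <= 0 or self.amplitude_um <= 0:
            raise InvalidParameterError("PK parameters must be positive")
        if self.ka <= self.ke:
            raise InvalidParameterError("absorption must be faster than elimination")

    def conc(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.amplitude_um * (np.exp(-self.ke * t) - np.exp(-self.ka * t))

    @property
    def auc_inf(self) -> float:
        """Analytic AUC(0-inf), µM·h."""
        return self.amplitude_um * (1.0 / self.ke - 1.0 / self.ka)


def simulate_pk(
    dose_params: PKParameters | None = None,
    brain_partition: float = 0.26,
    times_h: Sequence[float] = (0.25, 0.5, 1.0, 2.0, 4.0, 6.0),
    n_per_time: int = 3,
    noise_cv: float = 0.1,
    seed: int = 0,
) -> tuple[ConcentrationTimeProfile, ConcentrationTimeProfile]:
    """Composite-design plasma and brain concentration–time profiles.

    Each animal contributes a single time point (destructive sampling); the
    brain profile is the plasma curve scaled by ``brain_partition``.
    Returns ``(plasma, brain)``.
    """
    if not 0 <= brain_partition:
        raise InvalidParameterError("brain_partition must be >= 0")
    if n_per_time < 1:
        raise InvalidParameterError("n_per_time must be >= 1")
    params = dose_params or PKParameters()
    rng = np.random.default_rng(seed)
    t = np.asarray(times_h, dtype=float)
    mu = params.conc(t)

    profiles = []
    for label, scale in (("plasma", 1.0), ("brain", brain_partition)):
        noise = _lognormal_factors(rng, noise_cv, t.size * n_per_time).reshape(
            t.size, n_per_time
        )
        conc = scale * mu[:, None] * noise
        ids = np.array(
            [
                [f"{label}-animal-{i * n_per_time + j + 1:02d}" for j in range(n_per_time)]
                for i in range(t.size)
            ]
        )
        profiles.append(
            ConcentrationTimeProfile(
                matrix_label=label, times=t, concentrations=conc, animal_ids=ids
            )
        )
    return profiles[0], profiles[1]


# ---------------------------------------------------------------------------
# EV and qPCR studies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmaxModel:
    """Inhibitory Emax dose–response for EV release: mean(d) = V*(1 - Emax/100 * d/(d+EC50))."""

    vehicle_mean: float
    ec50_um: float
    emax_pct: float

    def __post_init__(self) -> None:
        if self.vehicle_mean <= 0 or self.ec50_um <= 0:
            raise InvalidParameterError("vehicle mean and EC50 must be > 0")
        if not 0 <= self.emax_pct <= 100:
            raise InvalidParameterError("Emax must lie in [0, 100]")

    def mean_at(self, dose_um: float) -> float:
        return self.vehicle_mean * float(fractional_activity(dose_um, self.ec50_um, self.emax_pct))


def simulate_ev_study(
    group_means: Mapping[str, float] | None = None,
    effect_model: EmaxModel | None = None,
    doses_um: Sequence[float] | None = None,
    n_replicates: int = 4,
    dispersion: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Grouped EV particle concentrations (lognormal replicates per group).

    Either supply explicit ``group_means`` (condition -> EVs/mL) or an
    ``effect_model`` plus ``doses_um``, in which case groups ``vehicle`` and
    ``dose_<d>`` are generated from the Emax curve.  ``dispersion`` is the
    lognormal CV of replicate values.
    Columns: ``condition, replicate, value``.
    """
    if group_means is None:
        if effect_model is None or doses_um is None:
            raise ConfigurationError("supply group_means or (effect_model, doses_um)")
        group_means = {"vehicle": effect_model.vehicle_mean}
        for d in doses_um:
            group_means[f"dose_{d:g}"] = effect_model.mean_at(d)
    if not group_means:
        raise ConfigurationError("no groups to simulate")
    if n_replicates < 2:
        raise InvalidParameterError("need >= 2 replicates per group")
    rng = np.random.default_rng(seed)
    rows = []
    for cond, mean in group_means.items():
        if mean < 0:
            raise InvalidParameterError("group means must be >= 0")
        noise = _lognormal_factors(rng, dispersion, n_replicates)
        for rep, f in enumerate(noise):
            rows.append((cond, rep, mean * f))
    return pd.DataFrame(rows, columns=["condition", "replicate", "value"])


def simulate_qpcr(
    group_effects: Mapping[str, Mapping[str, float]],
    reference_ct: float = 18.0,
    n: int = 5,
    noise_sd: float = 0.1,
    seed: int = 0,
    control_group: str = "control",
    target_offset_ct: float = 5.0,
) -> pd.DataFrame:
    """Ct table for a relative-quantification (2^-ddCt) qPCR study.

    ``group_effects`` maps group -> {gene -> fold-change vs control}.  The
    control group is added automatically (fold 1 for every gene) if absent.
    A fold-change f shifts the target Ct by -log2(f); Gaussian noise of
    ``noise_sd`` cycles is added independently to target and reference Ct.
    Columns: ``sample_id, group, gene, ct_target, ct_reference``.
    """
    if not group_effects:
        raise ConfigurationError("group_effects must not be empty")
    if n < 2:
        raise InvalidParameterError("need n >= 2 samples per group")
    genes = sorted({g for eff in group_effects.values() for g in eff})
    if not genes:
        raise ConfigurationError("no genes specified")
    effects = {grp: dict(eff) for grp, eff in group_effects.items()}
    if control_group not in effects:
        effects[control_group] = {g: 1.0 for g in genes}
    rng = np.random.default_rng(seed)
    rows = []
    for grp, eff in effects.items():
        for k in range(n):
            sid = f"{grp}-{k + 1:02d}"
            for gene in genes:
                fold = eff.get(gene, 1.0)
                if fold <= 0:
                    raise InvalidParameterError("fold-changes must be > 0")
                ct_t = reference_ct + target_offset_ct - math.log2(fold)
                ct_r = reference_ct
                rows.append(
                    (
                        sid,
                        grp,
                        gene,
                        ct_t + rng.normal(0.0, noise_sd),
                        ct_r + rng.normal(0.0, noise_sd),
                    )
                )
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "gene", "ct_target", "ct_reference"]
    )


# ---------------------------------------------------------------------------
# curve-class exemplar curves (classifier regression population)
# ---------------------------------------------------------------------------

#: Parameter regions generating clear exemplars of each curve-response class
#: on the 7-dose confirmation design: (top range, IC50 range (µM), hill range).
#: Each region sits well inside its class so the planted label is unambiguous;
#: curves straddling class boundaries are excluded by construction.
CRC_EXEMPLAR_REGIONS = {
    -1.1: ((88.0, 98.0), (1.5, 3.0), (1.2, 1.8)),
    -1.2: ((45.0, 70.0), (1.5, 3.0), (1.2, 1.8)),
    -2.1: ((97.0, 100.0), (6.0, 9.0), (1.0, 1.2)),
    -2.2: ((85.0, 100.0), (32.0, 45.0), (1.2, 1.8)),
    4.0: None,  # inactive: no dose effect
}


def crc_exemplar_curves(
    n_per_class: int = 200,
    doses_um: Sequence[float] | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> list[dict]:
    """Dose-response curves with known curve-response-class labels.

    Draws 4PL parameters from :data:`CRC_EXEMPLAR_REGIONS` and returns one
    record per curve: ``{"crc_class", "doses_um", "response"}`` with percent
    inhibition on the 7-dose design (or the supplied doses).  ``noise_cv``
    applies the well-level multiplicative lognormal noise model to the
    remaining-activity fraction, as on a plate.
    """
    if doses_um is None:
        doses_um = [57.0 / 3.0**k for k in range(7)][::-1]
    d = np.asarray(doses_um, dtype=float)
    rng = np.random.default_rng(seed)
    records = []
    for cls, region in CRC_EXEMPLAR_REGIONS.items():
        for _ in range(n_per_class):
            if region is None:
                activity = np.ones(d.size)
            else:
                (t_lo, t_hi), (i_lo, i_hi), (h_lo, h_hi) = region
                top = rng.uniform(t_lo, t_hi)
                ic50 = math.exp(rng.uniform(math.log(i_lo), math.log(i_hi)))
                hill = rng.uniform(h_lo, h_hi)
                inhib = top / (1.0 + (ic50 / d) ** hill)
                activity = 1.0 - inhib / 100.0
            activity = activity * _lognormal_factors(rng, noise_cv, d.size)
            records.append(
                {
                    "crc_class": cls,
                    "doses_um": d.copy(),
                    "response": 100.0 * (1.0 - activity),
                }
            )
    return records
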