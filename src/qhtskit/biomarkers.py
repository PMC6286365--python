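"""Downstream effect statistics: EV counts, qPCR fold-changes, group comparisons.

Covers the endpoints measured after a hit is in hand: extracellular-vesicle
(EV) particle-count dose–response and group comparisons (one-way ANOVA with
Tukey's HSD), relative qPCR quantification by the 2^-ddCt method, and
percent-reduction estimates with delta-method (or bootstrap) uncertainty.

The ANOVA decomposition is computed from sums of squares directly and the
Tukey critical values from the studentized-range distribution, so the whole
module is self-contained given scipy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dose_response import DoseResponseResult, fit_and_classify
from .exceptions import InvalidParameterError

__all__ = [
    "GroupedCounts",
    "ddct_fold_change",
    "percent_reduction",
    "anova_tukey",
    "ev_dose_response",
    "AnovaResult",
    "PercentReduction",
]


@dataclass(frozen=True)
class GroupedCounts:
    """Replicate measurements per condition (EVs/mL, cell counts, intensities)."""

    groups: dict  # condition -> 1-D array of replicate values

    def __post_init__(self) -> None:
        clean = {}
        for cond, vals in self.groups.items():
            arr = np.asarray(vals, dtype=float)
            if arr.size < 2:
                raise InvalidParameterError(f"group {cond!r} needs >= 2 replicates")
            if np.any(arr < 0):
                raise InvalidParameterError(f"group {cond!r} has negative values")
            clean[cond] = arr
        object.__setattr__(self, "groups", clean)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, condition: str = "condition", value: str = "value"
    ) -> "GroupedCounts":
        return cls(
            {c: g[value].to_numpy(dtype=float) for c, g in frame.groupby(condition, sort=False)}
        )

    def mean(self, cond: str) -> float:
        return float(self.groups[cond].mean())

    def sem(self, cond: str) -> float:
        g = self.groups[cond]
        return float(g.std(ddof=1) / math.sqrt(g.size))


@dataclass(frozen=True)
class PercentReduction:
    estimate_pct: float
    se_pct: float
    method: str  # "delta" or "bootstrap"


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    tukey: pd.DataFrame  # pairwise comparisons with adjusted p-values


def ddct_fold_change(records: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Per-gene fold-changes by the 2^-ddCt method.

    ``records`` needs columns ``sample_id, group, gene, ct_target,
    ct_reference``.  Per sample, dCt = Ct_target - Ct_reference; ddCt is the
    sample dCt minus the control group's mean dCt for that gene; the fold
    change is ``2^-ddCt``.  Returns one row per (group, gene) with the
    geometric-mean fold and its log2 dispersion (SD of ddCt).
    """
    required = {"sample_id", "group", "gene", "ct_target", "ct_reference"}
    if not required.issubset(records.columns):
        raise InvalidParameterError(f"qPCR table needs columns {sorted(required)}")
    if control_group not in set(records["group"]):
        raise InvalidParameterError(f"control group {control_group!r} not in table")
    ct = records[["ct_target", "ct_reference"]].to_numpy(dtype=float)
    if np.any(ct < 0) or np.any(ct > 45):
        raise InvalidParameterError("Ct values outside the plausible 0-45 cycle range")
    df = records.copy()
    df["dct"] = df["ct_target"] - df["ct_reference"]
    control_dct = (
        df[df["group"] == control_group].groupby("gene")["dct"].mean().rename("control_dct")
    )
    df = df.join(control_dct, on="gene")
    missing = df["control_dct"].isna()
    if missing.any():
        genes = sorted(df.loc[missing, "gene"].unique())
        raise InvalidParameterError(f"genes missing from control group: {genes}")
    df["ddct"] = df["dct"] - df["control_dct"]
    out = (
        df.groupby(["group", "gene"])["ddct"]
        .agg(mean_ddct="mean", sd_ddct=lambda x: x.std(ddof=1), n="size")
        .reset_index()
    )
    out["fold_change"] = 2.0 ** (-out["mean_ddct"])
    return out[["group", "gene", "n", "mean_ddct", "sd_ddct", "fold_change"]]


def percent_reduction(
    treated: GroupedCounts | np.ndarray,
    reference: GroupedCounts | np.ndarray,
    treated_group: str | None = None,
    reference_group: str | None = None,
    method: str = "delta",
    n_boot: int = 2000,
    seed: int = 0,
) -> PercentReduction:
    """Percent reduction of the treated mean relative to the reference mean.

    ``100 * (1 - mean_treated / mean_reference)``.  Uncertainty is by
    first-order (delta-method) propagation of the two group SEMs by default;
    ``method="bootstrap"`` resamples replicates within each group instead.
    """

    def _values(obj, group):
        if isinstance(obj, GroupedCounts):
            if group is None:
                if len(obj.groups) != 1:
                    raise InvalidParameterError("specify which group to use")
                group = next(iter(obj.groups))
            return obj.groups[group]
        return np.asarray(obj, dtype=float)

    t = _values(treated, treated_group)
    r = _values(reference, reference_group)
    if t.size < 2 or r.size < 2:
        raise InvalidParameterError("need >= 2 replicates per group")
    mt, mr = t.mean(), r.mean()
    if mr <= 0:
        raise InvalidParameterError("reference mean must be > 0")
    est = 100.0 * (1.0 - mt / mr)
    if method == "delta":
        se_t = t.std(ddof=1) / math.sqrt(t.size)
        se_r = r.std(ddof=1) / math.sqrt(r.size)
        se = 100.0 * math.sqrt((se_t / mr) ** 2 + (mt * se_r / mr**2) ** 2)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = [
            100.0
            * (
                1.0
                - rng.choice(t, t.size).mean() / max(rng.choice(r, r.size).mean(), 1e-300)
            )
            for _ in range(n_boot)
        ]
        se = float(np.std(reps, ddof=1))
    else:
        raise InvalidParameterError(f"unknown uncertainty method {method!r}")
    return PercentReduction(float(est), float(se), method)


def anova_tukey(groups: GroupedCounts, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA from sums of squares, with Tukey's HSD post hoc.

    The F statistic is ``(SSB/dfB) / (SSW/dfW)``; pairwise comparisons use
    the studentized-range distribution with the pooled within-group variance
    (Tukey–Kramer for unequal group sizes).
    """
    names = list(groups.groups)
    if len(names) < 2:
        raise InvalidParameterError("need >= 2 groups for ANOVA")
    data = [groups.groups[c] for c in names]
    ns = np.array([g.size for g in data])
    means = np.array([g.mean() for g in data])
    grand = np.concatenate(data).mean()
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(np.sum((g - m) ** 2) for g, m in zip(data, means)))
    dfb = len(names) - 1
    dfw = int(ns.sum()) - len(names)
    if dfw <= 0:
        raise InvalidParameterError("no within-group degrees of freedom")
    msw = ssw / dfw
    if msw > 0:
        f = (ssb / dfb) / msw
    else:
        # degenerate within-group variance: identical constant groups are a
        # null result (F = 0), any between-group spread is infinitely strong
        f = 0.0 if ssb == 0 else math.inf
    p = float(stats.f.sf(f, dfb, dfw)) if math.isfinite(f) else 0.0

    rows = []
    k = len(names)
    for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
        diff = means[j] - means[i]
        se = math.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        q = abs(diff) / se if se > 0 else math.inf
        p_adj = float(stats.studentized_range.sf(q, k, dfw)) if math.isfinite(q) else 0.0
        rows.append(
            {
                "group_1": a,
                "group_2": b,
                "mean_diff": float(diff),
                "q": float(q),
                "p_adj": p_adj,
                "reject": p_adj < alpha,
            }
        )
    return AnovaResult(
        f_statistic=float(f),
        p_value=p,
        df_between=dfb,
        df_within=dfw,
        ss_between=ssb,
        ss_within=ssw,
        tukey=pd.DataFrame(rows),
    )


def ev_dose_response(
    counts: GroupedCounts,
    doses_um: dict,
    vehicle_group: str | None = None,
) -> DoseResponseResult:
    """Emax fit of EV-release inhibition versus dose.

    ``doses_um`` maps condition name -> dose (µM); conditions with dose 0
    (or the explicit ``vehicle_group``) define the 100%-release baseline.
    Per-group mean counts are converted to percent inhibition of the vehicle
    mean and fitted with the shared 4PL machinery, so EC50/Emax come back as
    ``ic50_um``/``efficacy``.
    """
    if not doses_um:
        raise InvalidParameterError("doses_um must not be empty")
    vehicle_conditions = [c for c, d in doses_um.items() if d == 0]
    if vehicle_group is not None:
        vehicle_conditions.append(vehicle_group)
    vehicle_conditions = [c for c in vehicle_conditions if c in counts.groups]
    if not vehicle_conditions:
        raise InvalidParameterError("no vehicle (dose 0) condition found")
    baseline = float(np.mean([counts.mean(c) for c in vehicle_conditions]))
    if baseline <= 0:
        raise InvalidParameterError("vehicle baseline must be > 0")
    doses, resp = [], []
    for cond, dose in doses_um.items():
        if dose == 0 or cond not in counts.groups:
            continue
        for v in counts.groups[cond]:
            doses.append(dose)
            resp.append(100.0 * (1.0 - v / baseline))
    return fit_and_classify(doses, resp, compound_id="", assay_id="ev_release")
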