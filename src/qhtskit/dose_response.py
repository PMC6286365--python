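"""Percent inhibition, four-parameter logistic fitting, and curve-class scoring.

Each compound × assay yields a dose–response record: percent inhibition at
each tested dose, a 4PL (Hill) fit on log10 dose::

    y = bottom + (top - bottom) / (1 + 10^(h * (log10 IC50 - log10 x)))

and a curve-response class (CRC) summarising curve completeness (number of
asymptotes), efficacy, and fit quality.  Classes follow the qHTS convention:
class 1 = both asymptotes, 2 = one asymptote, 3 = single-dose activity only,
4 = inactive; subclass .1 = high efficacy, .2 = partial efficacy; the sign is
negative for inhibition.  Numeric thresholds (high-efficacy floor, partial
floor, minimum r², asymptote tolerance) are configurable, not canonical.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import InvalidControlError, InvalidParameterError
from .plates import ROLE_NEG, ROLE_POS, ROLE_TEST

__all__ = [
    "CRCThresholds",
    "DoseResponseResult",
    "IC50Interval",
    "percent_inhibition",
    "plate_responses",
    "fit_4pl",
    "crc_classify",
    "fit_and_classify",
    "ic50_with_ci",
    "SELECTABLE_CLASSES",
]

#: CRC classes conventionally carried forward to confirmation.
SELECTABLE_CLASSES = (-1.1, -1.2, -2.1, -2.2)

REPORT_CLIP = (-10.0, 110.0)


@dataclass(frozen=True)
class CRCThresholds:
    """Tunable cut-offs of the curve-response-class assignment."""

    high_efficacy: float = 80.0  # percent; subclass .1 at or above
    partial_floor: float = 30.0  # percent; below this a curve is inactive
    r2_min: float = 0.9  # minimum r2 for a robust (class 1/2) curve
    asymptote_slope_tol: float = 10.0  # pts/decade; curve flat at a range end
    baseline_prox_tol: float = 10.0  # pts; flat low end must sit near the baseline
    single_dose_activity: float = 50.0  # percent; class-3 single-point criterion
    extrapolation_logs: float = 1.0  # IC50 beyond range+this is flagged/demoted


@dataclass(frozen=True)
class DoseResponseResult:
    """4PL fit and curve-class descriptors for one compound in one assay.

    ``efficacy`` is the signed inhibition reached within the tested range,
    relative to the fitted baseline (the qHTS "maximal response" convention:
    for complete curves it equals the fitted span; for incomplete curves it
    is the fitted response at the top dose, which stays well identified when
    the extrapolated plateau is not).  Activation curves come out negative
    and classify inactive.
    """

    compound_id: str
    assay_id: str
    doses: tuple
    response: tuple
    bottom: float
    top: float
    ic50_um: float
    hill: float
    r2: float
    n_asymptotes: int
    efficacy: float
    converged: bool
    extrapolated: bool
    crc_class: float | None = None

    @property
    def max_response(self) -> float:
        return float(np.max(self.response))

    @property
    def response_at_top_dose(self) -> float:
        i = int(np.argmax(self.doses))
        return float(self.response[i])

    def is_selectable(self) -> bool:
        return self.crc_class in SELECTABLE_CLASSES


@dataclass(frozen=True)
class IC50Interval:
    estimate_um: float
    lower_um: float | None
    upper_um: float | None
    n_boot: int
    level: float = 0.95


def percent_inhibition(
    rate_with_inhibitor: float, rate_without: float, clip: tuple = REPORT_CLIP
) -> float:
    """Percent inhibition from progress-curve slopes.

    ``100 * (1 - rate_I / rate_0)``, clipped to the reporting window so that
    noise-driven activation or super-maximal readings stay bounded.
    """
    if rate_without <= 0:
        raise InvalidControlError("uninhibited control rate must be > 0")
    value = 100.0 * (1.0 - rate_with_inhibitor / rate_without)
    return float(np.clip(value, *clip))


def plate_responses(plate: pd.DataFrame, clip: tuple = REPORT_CLIP) -> pd.DataFrame:
    """Per-well percent inhibition of every compound well on a plate.

    Normalises test-well RFU between the plate's negative (background) and
    saturating positive control means.  Returns a tidy frame with columns
    ``compound_id, conc_um, response`` (one row per compound well).
    """
    pos = plate.loc[plate["role"] == ROLE_POS, "rfu"].to_numpy()
    neg = plate.loc[plate["role"] == ROLE_NEG, "rfu"].to_numpy()
    if pos.size == 0 or neg.size == 0:
        raise InvalidControlError("plate lacks positive or negative control wells")
    mu_p, mu_n = float(pos.mean()), float(neg.mean())
    if mu_p <= mu_n:
        raise InvalidControlError("positive control does not exceed background")
    test = plate[(plate["role"] == ROLE_TEST) & (plate["compound_id"] != "")]
    activity = (test["rfu"].to_numpy() - mu_n) / (mu_p - mu_n)
    resp = np.clip(100.0 * (1.0 - activity), *clip)
    return pd.DataFrame(
        {
            "compound_id": test["compound_id"].to_numpy(),
            "conc_um": test["conc_um"].to_numpy(),
            "response": resp,
        }
    )


_LN10 = math.log(10.0)


def _model(logx: np.ndarray, bottom: float, top: float, log_ic50: float, hill: float):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ic50 - logx)))


def _model_jac(logx, bottom, top, log_ic50, hill):
    z = 10.0 ** (hill * (log_ic50 - logx))
    den = 1.0 + z
    span = top - bottom
    d_b = z / den
    d_t = 1.0 / den
    d_l = -span * z * _LN10 * hill / den**2
    d_h = -span * z * _LN10 * (log_ic50 - logx) / den**2
    return np.stack([d_b, d_t, d_l, d_h], axis=1)


def fit_4pl(
    doses,
    response,
    weights=None,
    compound_id: str = "",
    assay_id: str = "",
    constrained: bool | None = None,
    thresholds: CRCThresholds | None = None,
) -> DoseResponseResult:
    """Least-squares 4PL fit of percent inhibition on log10 dose.

    With exactly four distinct doses (the primary-screen design) the fit is
    constrained — bottom fixed at 0 and hill limited to [0.5, 3] — to avoid
    overfitting; richer designs fit all four parameters with soft bounds.
    Pass ``constrained`` to override the automatic choice.  ``weights`` are
    per-point standard deviations (as in :func:`scipy.optimize.curve_fit`).

    A non-converged fit is returned with ``converged=False`` and NaN
    parameters; classification then falls back to single-dose criteria.
    """
    th = thresholds or CRCThresholds()
    d = np.asarray(doses, dtype=float)
    y = np.asarray(response, dtype=float)
    if d.size != y.size or d.size == 0:
        raise InvalidParameterError("doses and response must match and be non-empty")
    if np.any(d <= 0):
        raise InvalidParameterError("doses must be positive")
    n_distinct = np.unique(d).size
    if n_distinct < 4:
        raise InvalidParameterError(
            f"need >= 4 distinct doses for a dose-response fit, got {n_distinct}"
        )
    if constrained is None:
        constrained = n_distinct <= 4
    logd = np.log10(d)
    lo_log, hi_log = logd.min() - 3.0, logd.max() + 3.0

    # midpoint start: dose whose response is closest to the half-range
    y_mid = (y.min() + y.max()) / 2.0
    crossing = float(logd[np.argmin(np.abs(y - y_mid))])
    starts = [crossing, float(np.median(logd)), lo_log + 1.0, hi_log - 1.0]

    def try_fit(p0, bounds, model, jac):
        try:
            popt, _ = curve_fit(
                model,
                logd,
                y,
                p0=p0,
                bounds=bounds,
                sigma=weights,
                jac=jac,
                method="dogbox",
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            return None, np.inf
        rss = float(np.sum((model(logd, *popt) - y) ** 2))
        return popt, rss

    best, best_rss = None, np.inf
    if constrained:
        model = lambda lx, top, lic50, h: _model(lx, 0.0, top, lic50, h)  # noqa: E731
        jac = lambda lx, top, lic50, h: _model_jac(lx, 0.0, top, lic50, h)[:, 1:]  # noqa: E731
        bounds = ([-20.0, lo_log, 0.5], [120.0, hi_log, 3.0])
        for s in starts:
            p0 = [float(np.clip(y.max(), -19, 119)), float(np.clip(s, lo_log, hi_log)), 1.0]
            popt, rss = try_fit(p0, bounds, model, jac)
            if popt is not None and rss < best_rss:
                best, best_rss = np.concatenate([[0.0], popt]), rss
            if best_rss <= 1e-10 * d.size:  # exact fit; further starts pointless
                break
    else:
        bounds = ([-30.0, -20.0, lo_log, 0.5], [60.0, 120.0, hi_log, 3.0])
        for s in starts:
            p0 = [
                float(np.clip(y.min(), -29, 59)),
                float(np.clip(y.max(), -19, 129)),
                float(np.clip(s, lo_log, hi_log)),
                1.0,
            ]
            popt, rss = try_fit(p0, bounds, _model, _model_jac)
            if popt is not None and rss < best_rss:
                best, best_rss = popt, rss
            if best_rss <= 1e-10 * d.size:
                break

    if best is None:
        return DoseResponseResult(
            compound_id=compound_id,
            assay_id=assay_id,
            doses=tuple(d),
            response=tuple(y),
            bottom=math.nan,
            top=math.nan,
            ic50_um=math.nan,
            hill=math.nan,
            r2=0.0,
            n_asymptotes=0,
            efficacy=0.0,
            converged=False,
            extrapolated=False,
        )

    bottom, top, log_ic50, hill = (float(v) for v in best)
    ic50 = 10.0**log_ic50
    fitted = _model(logd, bottom, top, log_ic50, hill)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 and best_rss < 1e-9 else 1.0 - best_rss / max(ss_tot, 1e-12)
    r2 = float(np.clip(r2, 0.0, 1.0))

    # An asymptote is reached when the fitted curve is flat at that end of
    # the tested range: |dy/dlog10(dose)| below tolerance at the extreme dose.
    # Fitted end-slopes and end-values are well identified even when the
    # plateau *parameters* of an incomplete curve are not, which keeps the
    # call (and the efficacy actually reached in-range) stable under noise.
    def _end_slope(lx):
        z = 10.0 ** (hill * (log_ic50 - lx))
        return abs((top - bottom) * _LN10 * hill * z / (1.0 + z) ** 2)

    pred_lo = float(_model(np.array([logd.min()]), *best)[0])
    pred_hi = float(_model(np.array([logd.max()]), *best)[0])
    top_asym = _end_slope(logd.max()) <= th.asymptote_slope_tol
    # a flat low end only counts as the *lower* plateau if it sits near the
    # fitted baseline (a saturated curve is flat-high at the lowest dose)
    bottom_asym = (
        _end_slope(logd.min()) <= th.asymptote_slope_tol
        and pred_lo - bottom <= th.baseline_prox_tol
    )
    n_asym = int(bottom_asym) + int(top_asym)
    efficacy = pred_hi - bottom
    extrapolated = (
        log_ic50 > logd.max() + th.extrapolation_logs
        or log_ic50 < logd.min() - th.extrapolation_logs
    )
    return DoseResponseResult(
        compound_id=compound_id,
        assay_id=assay_id,
        doses=tuple(d),
        response=tuple(y),
        bottom=bottom,
        top=top,
        ic50_um=float(ic50),
        hill=hill,
        r2=r2,
        n_asymptotes=n_asym,
        efficacy=efficacy,
        converged=True,
        extrapolated=extrapolated,
    )


def crc_classify(
    fit: DoseResponseResult, thresholds: CRCThresholds | None = None
) -> float:
    """Curve-response class of a fitted (or failed) dose–response.

    Always returns a class: non-converged or low-quality fits can only be
    -3 (single-dose activity) or 4 (inactive).  Fits whose IC50 lands more
    than one log unit outside the tested range are demoted .1 -> .2.
    """
    th = thresholds or CRCThresholds()
    max_resp = fit.max_response
    if not fit.converged or fit.r2 < th.r2_min:
        return -3.0 if max_resp >= th.single_dose_activity else 4.0
    if fit.efficacy < th.partial_floor:
        return 4.0
    if fit.n_asymptotes == 0:
        # a well-fit curve whose midpoint lies inside the tested range is an
        # incomplete curve, not single-point activity; only curves with no
        # asymptote AND an out-of-range midpoint degrade to class 3
        d = np.asarray(fit.doses, dtype=float)
        if not d.min() <= fit.ic50_um <= d.max():
            return -3.0 if max_resp >= th.single_dose_activity else 4.0
        major = 2
    else:
        major = 1 if fit.n_asymptotes == 2 else 2
    sub = 1 if fit.efficacy >= th.high_efficacy else 2
    if fit.extrapolated and sub == 1:
        sub = 2
    return -(major + sub / 10.0)


def fit_and_classify(
    doses,
    response,
    thresholds: CRCThresholds | None = None,
    **fit_kwargs,
) -> DoseResponseResult:
    """Convenience wrapper: 4PL fit followed by CRC assignment."""
    fit = fit_4pl(doses, response, thresholds=thresholds, **fit_kwargs)
    return dataclasses.replace(fit, crc_class=crc_classify(fit, thresholds))


def ic50_with_ci(
    fit: DoseResponseResult,
    n_boot: int = 500,
    seed: int = 0,
    level: float = 0.95,
) -> IC50Interval:
    """Residual-bootstrap percentile interval for the fitted IC50.

    Resamples fit residuals with replacement onto the fitted curve and
    refits; ``n_boot=0`` returns the point estimate only.
    """
    if not fit.converged:
        raise InvalidParameterError("cannot bootstrap a non-converged fit")
    if n_boot < 0:
        raise InvalidParameterError("n_boot must be >= 0")
    if n_boot == 0:
        return IC50Interval(fit.ic50_um, None, None, 0, level)
    d = np.asarray(fit.doses)
    y = np.asarray(fit.response)
    logd = np.log10(d)
    fitted = _model(logd, fit.bottom, fit.top, math.log10(fit.ic50_um), fit.hill)
    constrained = np.unique(d).size <= 4
    # inflate residuals by sqrt(n/(n-p)): raw residuals of a p-parameter fit
    # underestimate the noise scale and would shrink the interval
    n_par = 3 if constrained else 4
    dof = max(d.size - n_par, 1)
    resid = (y - fitted) * math.sqrt(d.size / dof)
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_boot):
        y_b = fitted + rng.choice(resid, size=resid.size, replace=True)
        try:
            b = fit_4pl(d, y_b, constrained=constrained)
        except InvalidParameterError:
            continue
        if b.converged:
            estimates.append(b.ic50_um)
    if not estimates:
        return IC50Interval(fit.ic50_um, None, None, 0, level)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(estimates, [alpha, 1.0 - alpha])
    return IC50Interval(fit.ic50_um, float(lo), float(hi), len(estimates), level)
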