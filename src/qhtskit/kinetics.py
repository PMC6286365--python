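"""Michaelis–Menten fitting and inhibition-mode diagnosis.

Per-inhibitor-level Michaelis–Menten fits expose the apparent Vmax(I) and
Km(I) trends; a global fit across all inhibitor levels selects the
inhibition mode (competitive, noncompetitive, uncompetitive, or mixed) by
small-sample-corrected AIC.  The noncompetitive signature — Vmax falls with
inhibitor while Km is unchanged, and IC50 = Ki at any substrate — is the
diagnostic this module exists to reproduce.

Rate units are carried through unchanged (µM/h if the table is in µM/h,
RFU/h otherwise); Vmax inherits them, Km and Ki are in the concentration
units of the input table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import InvalidParameterError

__all__ = [
    "MMFit",
    "InhibitionFit",
    "KineticSeries",
    "fit_mm",
    "fit_inhibition_global",
    "selectivity_summary",
]

MODES = ("competitive", "noncompetitive", "uncompetitive", "mixed")


@dataclass(frozen=True)
class MMFit:
    vmax: float
    km: float
    vmax_se: float
    km_se: float
    km_in_range: bool = True  # substrate design straddles the fitted Km

    @property
    def km_ill_determined(self) -> bool:
        """Km is untrustworthy: SE exceeds the estimate, or the design
        never reached it (only the Vmax/Km ratio is then identified)."""
        return (
            not np.isfinite(self.km_se) or self.km_se > self.km or not self.km_in_range
        )


@dataclass(frozen=True)
class InhibitionFit:
    mode: str
    vmax: float
    km: float
    ki: float
    alpha: float | None  # mixed-mode asymmetry; None for pure modes
    aicc_by_mode: dict
    per_level: dict  # inhibitor conc -> MMFit
    ambiguous: bool

    @property
    def mode_scores(self) -> dict:
        return self.aicc_by_mode


@dataclass(frozen=True)
class KineticSeries:
    """Complete rate table over a substrate × inhibitor grid."""

    substrate: np.ndarray
    inhibitor: np.ndarray
    rate: np.ndarray  # matrix, shape (n_inhibitor, n_substrate)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "KineticSeries":
        """Build from a tidy table with substrate_um, inhibitor_um, rate columns.

        Replicate rows (same substrate and inhibitor) are averaged.
        """
        required = {"substrate_um", "inhibitor_um", "rate"}
        if not required.issubset(table.columns):
            raise InvalidParameterError(f"kinetic table needs columns {sorted(required)}")
        grid = (
            table.groupby(["inhibitor_um", "substrate_um"])["rate"].mean().unstack()
        )
        if grid.isna().any().any():
            raise InvalidParameterError("rate matrix incomplete over substrate x inhibitor grid")
        return cls(
            substrate=grid.columns.to_numpy(dtype=float),
            inhibitor=grid.index.to_numpy(dtype=float),
            rate=grid.to_numpy(dtype=float),
        )


def fit_mm(substrate, rate) -> MMFit:
    """Least-squares fit of v = Vmax*S/(Km+S) with standard errors.

    Duplicate substrate values are averaged before fitting.  Warns when
    fewer than 4 levels are available or the design does not straddle the
    fitted Km (the Km is then poorly identified).
    """
    s = np.asarray(substrate, dtype=float)
    v = np.asarray(rate, dtype=float)
    if s.size != v.size or s.size < 2:
        raise InvalidParameterError("need matching substrate/rate with >= 2 points")
    if np.any(s <= 0):
        raise InvalidParameterError("substrate concentrations must be > 0")
    # idempotent averaging of duplicates
    uniq, inv = np.unique(s, return_inverse=True)
    if uniq.size < s.size:
        v = np.bincount(inv, weights=v) / np.bincount(inv)
        s = uniq
    if s.size < 4:
        warnings.warn("fewer than 4 substrate levels; MM fit may be unstable", stacklevel=2)

    def model(ss, vmax, km):
        return vmax * ss / (km + ss)

    p0 = [float(v.max()) or 1.0, float(np.median(s))]
    popt, pcov = curve_fit(
        model, s, v, p0=p0, bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000
    )
    se = np.sqrt(np.diag(pcov))
    in_range = popt[1] <= s.max()
    fit = MMFit(float(popt[0]), float(popt[1]), float(se[0]), float(se[1]), bool(in_range))
    if not in_range:
        warnings.warn(
            "substrate range does not straddle the fitted Km; Km ill-determined",
            stacklevel=2,
        )
    return fit


def _mode_model(mode: str):
    """Global rate law v(S, I) for each inhibition mode (log-parametrised Ki)."""

    def competitive(x, vmax, km, ki):
        s, i = x
        return vmax * s / (km * (1 + i / ki) + s)

    def noncompetitive(x, vmax, km, ki):
        s, i = x
        return vmax * s / ((km + s) * (1 + i / ki))

    def uncompetitive(x, vmax, km, ki):
        s, i = x
        return vmax * s / (km + s * (1 + i / ki))

    def mixed(x, vmax, km, ki, alpha):
        s, i = x
        return vmax * s / (km * (1 + i / ki) + s * (1 + i / (alpha * ki)))

    return {
        "competitive": competitive,
        "noncompetitive": noncompetitive,
        "uncompetitive": uncompetitive,
        "mixed": mixed,
    }[mode]


def _aicc(rss: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return math.inf
    return n * math.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_inhibition_global(
    series: KineticSeries | pd.DataFrame,
    ambiguity_delta: float = 2.0,
) -> InhibitionFit:
    """Global inhibition-mode fit and AICc model selection.

    Fits all four mode equations to the full (S, I) grid, selects the lowest
    small-sample-corrected AIC, and reports per-level Michaelis–Menten fits
    for the apparent Vmax(I)/Km(I) trends.  When the top two modes differ by
    less than ``ambiguity_delta`` AICc units the diagnosis is flagged
    ambiguous (reported mode "mixed" behaviour should then be interpreted
    with care, not asserted).
    """
    if isinstance(series, pd.DataFrame):
        series = KineticSeries.from_table(series)
    inhibitor_levels = series.inhibitor
    if inhibitor_levels.size < 2 or np.count_nonzero(inhibitor_levels > 0) < 1:
        raise InvalidParameterError(
            "need >= 2 inhibitor levels (at least one non-zero) to diagnose the mode"
        )
    s_grid, i_grid = np.meshgrid(series.substrate, series.inhibitor)
    x = (s_grid.ravel(), i_grid.ravel())
    y = series.rate.ravel()
    n = y.size

    v0_guess = float(series.rate[np.argmin(series.inhibitor)].max())
    km_guess = float(np.median(series.substrate))
    ki_guess = float(np.median(inhibitor_levels[inhibitor_levels > 0]))

    fits: dict[str, tuple] = {}
    scores: dict[str, float] = {}
    for mode in MODES:
        model = _mode_model(mode)
        k = 4 if mode == "mixed" else 3
        p0 = [v0_guess, km_guess, ki_guess] + ([1.0] if mode == "mixed" else [])
        lo = [1e-12] * k
        hi = [np.inf] * k
        try:
            popt, _ = curve_fit(model, x, y, p0=p0, bounds=(lo, hi), maxfev=50000)
            rss = float(np.sum((model(x, *popt) - y) ** 2))
        except (RuntimeError, ValueError):
            popt, rss = None, math.inf
        fits[mode] = popt
        # floor the RSS at numerical precision of the data scale so that on
        # noise-free inputs nested models tie on fit and the parameter
        # penalty (not rounding noise) decides the mode
        rss_floor = n * (1e-8 * float(np.max(np.abs(y)))) ** 2
        scores[mode] = _aicc(max(rss, rss_floor), n, k)

    order = sorted(scores, key=scores.get)
    best = order[0]
    ambiguous = len(order) > 1 and scores[order[1]] - scores[best] < ambiguity_delta
    popt = fits[best]
    if popt is None:
        raise InvalidParameterError("no inhibition model could be fitted")

    per_level = {
        float(i_conc): fit_mm(series.substrate, series.rate[j])
        for j, i_conc in enumerate(series.inhibitor)
    }
    return InhibitionFit(
        mode=best,
        vmax=float(popt[0]),
        km=float(popt[1]),
        ki=float(popt[2]),
        alpha=float(popt[3]) if best == "mixed" else None,
        aicc_by_mode=scores,
        per_level=per_level,
        ambiguous=ambiguous,
    )


def selectivity_summary(
    ic50_by_target: dict[str, float],
    primary_target: str | None = None,
    inactivity_threshold_um: float = 100.0,
) -> pd.DataFrame:
    """Fold-selectivity of the primary target versus off-targets.

    ``ic50_by_target`` maps target name -> IC50 (µM); values above the
    inactivity threshold are reported inactive with a lower-bound fold
    (">N-fold").  The primary target defaults to the most potently hit one.
    Returns a frame with columns target, ic50_um, status, fold_selectivity.
    """
    if not ic50_by_target:
        raise InvalidParameterError("no targets supplied")
    if any(v <= 0 for v in ic50_by_target.values()):
        raise InvalidParameterError("IC50 values must be > 0")
    if primary_target is None:
        primary_target = min(ic50_by_target, key=ic50_by_target.get)
    if primary_target not in ic50_by_target:
        raise InvalidParameterError(f"unknown primary target {primary_target!r}")
    primary_ic50 = ic50_by_target[primary_target]
    rows = []
    for target, ic50 in ic50_by_target.items():
        inactive = ic50 > inactivity_threshold_um
        # inactive targets report the threshold-based lower bound (">N-fold")
        fold = (inactivity_threshold_um if inactive else ic50) / primary_ic50
        rows.append(
            {
                "target": target,
                "ic50_um": ic50,
                "status": (
                    "primary"
                    if target == primary_target
                    else ("inactive" if inactive else "active")
                ),
                "fold_selectivity": fold,
                "fold_is_lower_bound": inactive,
            }
        )
    return pd.DataFrame(rows)
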