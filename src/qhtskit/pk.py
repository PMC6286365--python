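"""Non-compartmental pharmacokinetic analysis and microsomal-stability summaries.

Implements model-free NCA of plasma/brain concentration–time profiles from a
composite (destructive) sampling design: per-time means are computed by naive
pooling of the animals sampled at each time, Cmax/Tmax are read off the mean
profile, the terminal slope ``lambda_z`` comes from log-linear regression of
the last quantifiable points, and AUC uses either the linear or the
lin-up/log-down trapezoid dialect.  ``AUC(0-inf) = AUC(0-tlast) + Clast/lambda_z``.

Brain concentrations in pmol/g are treated as numerically equivalent to µM
(unit tissue density convention), so brain/plasma AUC ratios are dimensionless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .exceptions import InvalidParameterError

__all__ = [
    "ConcentrationTimeProfile",
    "NCAResult",
    "MicrosomeStability",
    "nca",
    "auc_ratio",
    "time_above",
    "microsome_summary",
    "trapezoid_auc",
]


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """Concentration–time data for one matrix (plasma or brain).

    ``concentrations`` is a 2-D array of shape ``(n_times, n_animals)``;
    with destructive sampling each column at a given row is a distinct animal.
    """

    matrix_label: str
    times: np.ndarray
    concentrations: np.ndarray
    animal_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.atleast_2d(np.asarray(self.concentrations, dtype=float))
        if c.shape[0] != t.size:
            c = c.T
        if c.shape[0] != t.size:
            raise InvalidParameterError("concentration matrix does not match times")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if t.size < 3:
            raise InvalidParameterError("need at least 3 time points")
        if np.any(np.diff(t) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if np.any(c < 0):
            raise InvalidParameterError("concentrations must be non-negative")

    @property
    def mean(self) -> np.ndarray:
        """Per-time mean concentration (naive pooling across animals)."""
        return self.concentrations.mean(axis=1)

    @property
    def sd(self) -> np.ndarray:
        if self.concentrations.shape[1] < 2:
            return np.zeros(self.times.size)
        return self.concentrations.std(axis=1, ddof=1)

    def to_frame(self):
        import pandas as pd

        n_t, n_a = self.concentrations.shape
        ids = (
            np.asarray(self.animal_ids)
            if self.animal_ids is not None
            else np.array(
                [f"{self.matrix_label}-t{i}-a{j}" for i in range(n_t) for j in range(n_a)]
            ).reshape(n_t, n_a)
        )
        return pd.DataFrame(
            {
                "matrix": self.matrix_label,
                "time_h": np.repeat(self.times, n_a),
                "conc": self.concentrations.ravel(),
                "animal_id": ids.ravel(),
            }
        )


@dataclass(frozen=True)
class NCAResult:
    matrix_label: str
    cmax: float
    tmax: float
    lambda_z: float | None
    auc_0t: float
    auc_inf: float | None
    n_lambda_points: int = 0
    lambda_r2: float | None = None

    def time_above(self, threshold: float) -> float:  # pragma: no cover - thin alias
        raise NotImplementedError("use qhtskit.pk.time_above on the profile")


@dataclass(frozen=True)
class MicrosomeStability:
    species: str
    times: np.ndarray
    percent_remaining: np.ndarray
    k: float
    half_life: float  # minutes; may be inf
    stable: bool
    flagged_increasing: bool = False


def trapezoid_auc(times: np.ndarray, conc: np.ndarray, method: str = "linuplogdown") -> float:
    """AUC of a sampled profile by the requested trapezoid dialect.

    ``linear`` applies the ordinary trapezoid everywhere.  ``linuplogdown``
    applies the log trapezoid ``(C1 - C2) * dt / ln(C1/C2)`` on strictly
    decreasing segments with both endpoints positive, and the linear rule
    otherwise (rising segments, ties, zeros).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if method not in ("linear", "linuplogdown"):
        raise InvalidParameterError(f"unknown trapezoid method {method!r}")
    auc = 0.0
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if method == "linuplogdown" and c1 > c2 > 0:
            auc += dt * (c1 - c2) / np.log(c1 / c2)
        else:
            auc += dt * (c1 + c2) / 2.0
    return float(auc)


def _terminal_slope(times: np.ndarray, conc: np.ndarray, n_points: int, select: str):
    """Log-linear regression over terminal points.

    ``select='last'`` uses the last ``n_points`` quantifiable (positive)
    concentrations; ``select='best_adj_r2'`` scans candidate windows of at
    least ``n_points`` terminal points and keeps the best adjusted r².
    Returns ``(lambda_z, r2, n_used)`` or ``(None, None, 0)``.
    """
    pos = conc > 0
    t, c = times[pos], conc[pos]
    # exclude points before (and including) Cmax from the terminal phase
    imax = int(np.argmax(c))
    t_term, c_term = t[imax + 1 :], c[imax + 1 :]
    if t_term.size < n_points:
        # fall back to including Cmax itself if the tail is short
        t_term, c_term = t[imax:], c[imax:]
    if t_term.size < max(n_points, 3):
        return None, None, 0

    def fit(tt, cc):
        res = stats.linregress(tt, np.log(cc))
        lam = -res.slope
        r2 = res.rvalue**2
        n = tt.size
        adj = 1 - (1 - r2) * (n - 1) / (n - 2) if n > 2 else r2
        return lam, r2, adj

    if select == "last":
        lam, r2, _ = fit(t_term[-n_points:], c_term[-n_points:])
        return (lam, r2, n_points) if lam > 0 else (None, None, 0)
    if select == "best_adj_r2":
        best = None
        for k in range(n_points, t_term.size + 1):
            lam, r2, adj = fit(t_term[-k:], c_term[-k:])
            if lam <= 0:
                continue
            if best is None or adj > best[3] + 1e-12:
                best = (lam, r2, k, adj)
        return (best[0], best[1], best[2]) if best else (None, None, 0)
    raise InvalidParameterError(f"unknown lambda_z selection {select!r}")


def nca(
    profile: ConcentrationTimeProfile,
    method: str = "linuplogdown",
    lambda_z_points: int = 3,
    lambda_z_select: str = "last",
    assume_zero_at_dose: bool = True,
) -> NCAResult:
    """Non-compartmental analysis of the pooled mean profile.

    Parameters
    ----------
    method : {'linuplogdown', 'linear'}
        Trapezoid dialect for AUC(0-tlast).
    lambda_z_points : int
        Minimum number of terminal points in the log-linear regression.
    lambda_z_select : {'last', 'best_adj_r2'}
        Terminal-window selection rule.
    assume_zero_at_dose : bool
        For extravascular dosing, prepend C=0 at t=0 when the first sample
        is after dose time, so the absorption-phase triangle is counted.
    """
    t = profile.times
    c = profile.mean
    if assume_zero_at_dose and t[0] > 0:
        t = np.concatenate([[0.0], t])
        c = np.concatenate([[0.0], c])
    imax = int(np.argmax(c))
    cmax, tmax = float(c[imax]), float(t[imax])
    auc_0t = trapezoid_auc(t, c, method=method)
    lam, r2, n_used = _terminal_slope(t, c, lambda_z_points, lambda_z_select)
    if lam is None:
        warnings.warn(
            f"{profile.matrix_label}: fewer than {lambda_z_points} usable terminal "
            "points; lambda_z and AUC(0-inf) unavailable",
            stacklevel=2,
        )
        auc_inf = None
    else:
        clast = float(c[c > 0][-1])
        auc_inf = auc_0t + clast / lam
    return NCAResult(
        matrix_label=profile.matrix_label,
        cmax=cmax,
        tmax=tmax,
        lambda_z=lam,
        auc_0t=auc_0t,
        auc_inf=auc_inf,
        n_lambda_points=n_used,
        lambda_r2=r2,
    )


def auc_ratio(brain: NCAResult | float, plasma: NCAResult | float) -> float:
    """Brain/plasma exposure ratio, ``AUC(0-inf) brain / AUC(0-inf) plasma``.

    Accepts either :class:`NCAResult` objects or bare AUC numbers so printed
    AUC values can be ratioed directly.
    """
    b = brain.auc_inf if isinstance(brain, NCAResult) else float(brain)
    p = plasma.auc_inf if isinstance(plasma, NCAResult) else float(plasma)
    if b is None or p is None:
        raise InvalidParameterError("AUC(0-inf) unavailable for ratio")
    if p <= 0:
        raise InvalidParameterError("plasma AUC must be positive")
    return b / p


def time_above(profile: ConcentrationTimeProfile, threshold: float) -> float:
    """Duration (h, from dose time) the interpolated mean profile exceeds a level.

    Returns the time of the last downward crossing of ``threshold`` by the
    linearly interpolated mean profile; 0 if the profile never exceeds it.
    If the profile is still above threshold at the last sample, the last
    sample time is returned.
    """
    if threshold <= 0:
        raise InvalidParameterError("threshold must be positive")
    t = profile.times
    c = profile.mean
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        c = np.concatenate([[0.0], c])
    above = c > threshold
    if not above.any():
        return 0.0
    if above[-1]:
        return float(t[-1])
    last = int(np.max(np.nonzero(above)))
    # linear interpolation of the crossing within segment [last, last+1]
    c1, c2 = c[last], c[last + 1]
    t1, t2 = t[last], t[last + 1]
    return float(t1 + (c1 - threshold) / (c1 - c2) * (t2 - t1))


def microsome_summary(
    times_min: np.ndarray, percent_remaining: np.ndarray, species: str = "mouse"
) -> MicrosomeStability:
    """First-order decay summary of a microsomal stability time course.

    ``percent_remaining`` is normalised so the t=0 point is 100%.  A decay
    constant whose 95% CI includes zero (or a non-positive fit) reports
    ``half_life = inf`` and ``stable = True``.  A significantly *increasing*
    trend is flagged and the rate clipped to zero.
    """
    t = np.asarray(times_min, dtype=float)
    p = np.asarray(percent_remaining, dtype=float)
    if t.size != p.size or t.size < 2:
        raise InvalidParameterError("need matching times and >= 2 points")
    if t[0] != 0:
        raise InvalidParameterError("time course must include t=0")
    p = 100.0 * p / p[0]

    def model(tt, k):
        return 100.0 * np.exp(-k * tt)

    with warnings.catch_warnings():
        # a perfectly stable time course has a singular covariance; the SE
        # is then treated as infinite, which the stability call handles
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        popt, pcov = optimize.curve_fit(model, t, p, p0=[1e-3], maxfev=10000)
    k = float(popt[0])
    k_se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
    flagged = False
    if k < 0:
        if k_se < np.inf and k < -1.96 * k_se:
            flagged = True
            warnings.warn(
                f"{species} microsomes: percent remaining increases with time; "
                "rate clipped to 0",
                stacklevel=2,
            )
        k = 0.0
    # "stable": decay not distinguishable from zero (or numerically nil)
    tol = max(1.96 * k_se, 1e-9) if np.isfinite(k_se) else 1e-9
    stable = k <= tol
    half_life = np.inf if stable else float(np.log(2) / k)
    return MicrosomeStability(
        species=species,
        times=t,
        percent_remaining=p,
        k=k,
        half_life=half_life,
        stable=stable,
        flagged_increasing=flagged,
    )
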