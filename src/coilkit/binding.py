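"""Quadratic ligand-binding fits and thermal-melt midpoints.

Fluorescence-anisotropy titrations at reporter concentrations comparable to
K_D require the exact (ligand-depletion) mass-action solution rather than a
hyperbolic approximation.  With L and P the total reporter and titrant
concentrations, the observed anisotropy is ::

    FA(P) = FA_min + (FA_max - FA_min) *
            (L + K_D + P - sqrt((L + K_D + P)^2 - 4 L P)) / (2 L)

The surd term over 2L is the bound fraction of the reporter, the smaller
root of the mass-action quadratic.  Fits are unweighted nonlinear least
squares with K_D log-parameterized (keeping it positive); 95% confidence
bounds come from the linearized covariance, with an optional seeded
bootstrap.

Thermal melts (ellipticity at 222 nm vs temperature) yield Tm as the
temperature of the maximum of the smoothed first derivative, refined by
3-point parabolic interpolation; a cooperativity score (peak derivative
over mean derivative magnitude) flags shallow, non-two-state curves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import FitError, UnitError

log = logging.getLogger(__name__)


@dataclass
class BindingModel:
    """Parameters of the quadratic binding model (concentrations unit-tagged)."""

    kd: float
    fa_min: float
    fa_max: float
    l_total: float
    unit: str = "nM"

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.l_total <= 0:
            raise ValueError("K_D and L must be positive")
        if self.fa_max < self.fa_min:
            raise ValueError("FA_max must be >= FA_min")


@dataclass
class TitrationSet:
    """Observed (P, FA) points at fixed reporter concentration L."""

    P: np.ndarray
    FA: np.ndarray
    l_total: float
    unit: str = "nM"

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, float)
        self.FA = np.asarray(self.FA, float)
        if self.P.size == 0:
            raise ValueError("titration has no points")
        if np.any(self.P < 0):
            raise ValueError("P must be >= 0")


def fa_model(m: BindingModel, P, unit: str | None = None) -> np.ndarray | float:
    """Evaluate the quadratic binding model at titrant concentration(s) P."""
    if unit is not None and unit != m.unit:
        raise UnitError(f"P given in {unit!r} but model is in {m.unit!r}")
    P = np.asarray(P, float)
    s = m.l_total + m.kd + P
    surd = np.sqrt(np.clip(s * s - 4.0 * m.l_total * P, 0.0, None))
    bound = (s - surd) / (2.0 * m.l_total)
    out = m.fa_min + (m.fa_max - m.fa_min) * bound
    return float(out) if out.ndim == 0 else out


@dataclass
class BindingFit:
    model: BindingModel
    ci95: dict[str, tuple[float, float]]
    stderr: dict[str, float]
    residual_ss: float
    n_points: int
    bootstrap_ci95: dict[str, tuple[float, float]] | None = None


def _initial_guess(t: TitrationSet) -> tuple[float, float, float]:
    fa_min = float(t.FA.min())
    fa_max = float(t.FA.max())
    half = fa_min + 0.5 * (fa_max - fa_min)
    above = t.P[t.FA >= half]
    kd0 = float(above.min()) if above.size else float(np.median(t.P[t.P > 0]))
    return max(kd0, 1e-6), fa_min, fa_max


def fit_binding(t: TitrationSet, init: BindingModel | None = None,
                bootstrap: int = 0, seed: int | None = None) -> BindingFit:
    """Least-squares fit of (K_D, FA_min, FA_max) to a titration.

    K_D is fit on a log scale; its 95% bounds are the exponentiated
    log-scale bounds.  ``bootstrap`` > 0 adds case-resampling bootstrap
    percentile intervals (requires ``seed``).
    """
    if np.ptp(t.FA) < 1e-12:
        raise FitError("FA is constant: K_D is unidentifiable")
    if len(t.P) < 4:
        raise FitError("need at least 4 titration points")
    if init is not None and init.unit != t.unit:
        raise UnitError(f"init model in {init.unit!r}, data in {t.unit!r}")

    if init is not None:
        kd0, fmin0, fmax0 = init.kd, init.fa_min, init.fa_max
    else:
        kd0, fmin0, fmax0 = _initial_guess(t)
    half = fmin0 + 0.5 * (fmax0 - fmin0)
    if not (np.any(t.FA < half) and np.any(t.FA > half)):
        log.warning("titration does not span the half-saturation point; "
                    "K_D may be poorly determined")

    def residuals(theta: np.ndarray) -> np.ndarray:
        kd, fa_min, fa_max = math.exp(theta[0]), theta[1], theta[2]
        m = BindingModel(kd=kd, fa_min=min(fa_min, fa_max),
                         fa_max=max(fa_min, fa_max), l_total=t.l_total, unit=t.unit)
        return fa_model(m, t.P) - t.FA

    theta0 = np.array([math.log(kd0), fmin0, fmax0])
    res = optimize.least_squares(residuals, theta0, method="lm", max_nfev=5000)
    if not res.success:
        raise FitError(f"binding fit did not converge: {res.message}")

    log_kd, fa_min, fa_max = res.x
    if fa_max < fa_min:
        fa_min, fa_max = fa_max, fa_min
    model = BindingModel(kd=math.exp(log_kd), fa_min=fa_min, fa_max=fa_max,
                         l_total=t.l_total, unit=t.unit)

    dof = max(len(t.P) - 3, 1)
    ss = float(np.sum(res.fun ** 2))
    s2 = ss / dof
    J = res.jac
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    tval = float(stats.t.ppf(0.975, dof))
    ci = {
        "kd": (math.exp(log_kd - tval * se[0]), math.exp(log_kd + tval * se[0])),
        "fa_min": (res.x[1] - tval * se[1], res.x[1] + tval * se[1]),
        "fa_max": (res.x[2] - tval * se[2], res.x[2] + tval * se[2]),
    }
    stderr = {"log_kd": float(se[0]), "fa_min": float(se[1]), "fa_max": float(se[2])}

    boot_ci = None
    if bootstrap > 0:
        if seed is None:
            raise FitError("bootstrap requires an explicit seed")
        rng = np.random.default_rng(seed)
        kds, fmins, fmaxs = [], [], []
        n = len(t.P)
        for _ in range(bootstrap):
            idx = rng.integers(0, n, n)
            try:
                sub = TitrationSet(P=t.P[idx], FA=t.FA[idx],
                                   l_total=t.l_total, unit=t.unit)
                fit = fit_binding(sub)
            except (FitError, ValueError):
                continue
            kds.append(fit.model.kd)
            fmins.append(fit.model.fa_min)
            fmaxs.append(fit.model.fa_max)
        if kds:
            boot_ci = {
                "kd": tuple(np.percentile(kds, [2.5, 97.5])),
                "fa_min": tuple(np.percentile(fmins, [2.5, 97.5])),
                "fa_max": tuple(np.percentile(fmaxs, [2.5, 97.5])),
            }
    return BindingFit(model=model, ci95=ci, stderr=stderr, residual_ss=ss,
                      n_points=len(t.P), bootstrap_ci95=boot_ci)


# ---------------------------------------------------------------------------
# thermal melts


@dataclass
class MeltingCurve:
    """Temperature (C, strictly increasing) vs ellipticity at 222 nm."""

    T: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, float)
        self.theta = np.asarray(self.theta, float)
        if np.any(np.diff(self.T) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass
class MeltResult:
    tm: float | None
    cooperativity: float
    has_transition: bool
    derivative: np.ndarray = field(repr=False, default=None)
    T_mid: np.ndarray = field(repr=False, default=None)


def tm_from_melt(c: MeltingCurve, smooth_window: int = 5,
                 min_cooperativity: float = 2.0,
                 min_amplitude: float = 1e-9) -> MeltResult:
    """Tm from the maximum of the first derivative of theta(T).

    The curve is moving-average smoothed (odd ``smooth_window``), centrally
    differenced, and the derivative maximum refined by parabolic
    interpolation; Tm is reported at 0.1 C resolution.  The cooperativity
    score is the peak |dtheta/dT| over the mean slope magnitude
    (range/span): ~1 for a linear ramp, large for a sharp two-state
    transition.  Curves with score below ``min_cooperativity`` or amplitude
    below ``min_amplitude`` carry no transition (Tm is ``None``).
    """
    if smooth_window % 2 != 1 or smooth_window < 1:
        raise ValueError("smooth_window must be odd and positive")
    if len(c.T) < 5:
        raise ValueError("need at least 5 melt points")
    half = smooth_window // 2
    theta_s = np.array([c.theta[max(0, i - half):i + half + 1].mean()
                        for i in range(len(c.theta))])
    dT = np.gradient(theta_s, c.T)
    amplitude = float(np.ptp(theta_s))
    span = float(c.T[-1] - c.T[0])
    if amplitude < min_amplitude:
        log.warning("flat melting curve: no transition")
        return MeltResult(tm=None, cooperativity=0.0, has_transition=False,
                          derivative=dT, T_mid=c.T)
    mean_slope = amplitude / span
    i = int(np.argmax(np.abs(dT)))
    cooperativity = float(np.abs(dT[i]) / mean_slope)
    # parabolic refinement around the discrete maximum of |dtheta/dT|
    if 0 < i < len(dT) - 1:
        y0, y1, y2 = np.abs(dT[i - 1:i + 2])
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-15 else 0.0
        delta = min(max(delta, -1.0), 1.0)
        step = 0.5 * (c.T[min(i + 1, len(c.T) - 1)] - c.T[max(i - 1, 0)])
        tm = float(c.T[i] + delta * step)
    else:
        tm = float(c.T[i])
    has_transition = cooperativity >= min_cooperativity
    if not has_transition:
        log.warning("shallow melting curve (cooperativity %.2f < %.2f): "
                    "no two-state transition", cooperativity, min_cooperativity)
        return MeltResult(tm=None, cooperativity=cooperativity,
                          has_transition=False, derivative=dT, T_mid=c.T)
    return MeltResult(tm=round(tm, 1), cooperativity=cooperativity,
                      has_transition=True, derivative=dT, T_mid=c.T)
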