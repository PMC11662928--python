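"""Condition-level model fits: isotherm, saturating rates, Bell law, oligomerization.

Takes tables of per-condition amplitudes and rates (one row per
concentration, force or incubation time) and fits the four compact
models used to summarize the kinetics:

* Langmuir isotherm           theta(c) = c / (c + K_half)
* saturating rate             k(c) = a c b / (a c + b)
* Bell force law              k(F) = k_0 exp(F dx / kBT)
* oligomerization time course k(t) = k_inf + (k_0 - k_inf) exp(-t / tau)

Fits are weighted least squares when per-point SEMs are available,
with covariance from the Jacobian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "IsothermFit",
    "SaturatingRateFit",
    "BellFit",
    "OligoTimeFit",
    "occupancy_from_extension",
    "fit_langmuir",
    "fit_saturating_rate",
    "bell_rate",
    "fit_bell",
    "fit_oligo_time",
]


def occupancy_from_extension(dx_f, dx_max: float, dx_min: float,
                             noise: float = 0.0):
    """De-compact occupancy from equilibrium extension reductions.

    ``theta_d = (dx_max - dx_f) / (dx_max - dx_min)`` where ``dx_max``
    is the per-nt reduction of the maximally compacted state and
    ``dx_min`` that of the fully de-compacted state.  Values outside
    [0, 1] are clipped; a warning is emitted if they exceed the bounds
    by more than ``noise``.
    """
    if dx_max <= dx_min:
        raise ValueError("require dx_max > dx_min")
    theta = (dx_max - np.asarray(dx_f, dtype=float)) / (dx_max - dx_min)
    if np.any(theta < -noise - 1e-12) or np.any(theta > 1 + noise + 1e-12):
        warnings.warn("occupancy outside [0, 1] beyond fit noise; clipping",
                      stacklevel=2)
    out = np.clip(theta, 0.0, 1.0)
    return float(out) if np.ndim(dx_f) == 0 else out


@dataclass
class IsothermFit:
    K_half: float                 # nM
    theta: np.ndarray             # fitted occupancies at the input concentrations
    concentrations: np.ndarray
    residual_rms: float
    covariance: np.ndarray = field(default_factory=lambda: np.zeros((1, 1)))


def fit_langmuir(points: Sequence[tuple[float, float]],
                 sems: Optional[Sequence[float]] = None) -> IsothermFit:
    """Least-squares Langmuir fit ``theta(c) = c / (c + K_half)``."""
    pts = np.asarray(points, dtype=float)
    c, th = pts[:, 0], pts[:, 1]
    if len(np.unique(c)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.ptp(th) == 0:
        raise ValueError("no information: all occupancies equal")

    def model(cc, K):
        return cc / (cc + K)

    sigma = np.asarray(sems, float) if sems is not None else None
    popt, pcov = curve_fit(model, c, th, p0=[np.median(c)], sigma=sigma,
                           bounds=(1e-12, np.inf), maxfev=10000)
    K = float(popt[0])
    pred = model(c, K)
    return IsothermFit(K_half=K, theta=pred, concentrations=c,
                       residual_rms=float(np.sqrt(np.mean((th - pred) ** 2))),
                       covariance=pcov)


@dataclass
class SaturatingRateFit:
    bimolecular: float            # a, nM^-1 s^-1
    asymptote: float              # b, s^-1
    covariance: np.ndarray
    applies_to: str = "compaction"
    residual_rms: float = 0.0

    def predict(self, c):
        a, b = self.bimolecular, self.asymptote
        return a * np.asarray(c, float) * b / (a * np.asarray(c, float) + b)


def fit_saturating_rate(
    points: Sequence[tuple[float, float]],
    sems: Optional[Sequence[float]] = None,
    applies_to: str = "compaction",
    recompaction_k0: Optional[float] = None,
    recompaction_Kr: Optional[float] = None,
) -> SaturatingRateFit:
    """Fit the linear-then-plateau rate law ``k(c) = a c b / (a c + b)``.

    ``a`` is the bimolecular constant (the low-concentration slope) and
    ``b`` the high-concentration asymptote.  For the de-compaction
    series the measured phase-2 relaxation rate additionally contains
    the concurrent facilitated re-compaction channel; passing
    ``recompaction_k0`` and ``recompaction_Kr`` adds the fixed, known
    term ``k0*Kr/(Kr + c)`` to the model before fitting, avoiding a
    degenerate four-parameter fit.
    """
    pts = np.asarray(points, dtype=float)
    c, k = pts[:, 0], pts[:, 1]
    if len(np.unique(c)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if (recompaction_k0 is None) != (recompaction_Kr is None):
        raise ValueError("recompaction_k0 and recompaction_Kr go together")

    def baseline(cc):
        if recompaction_k0 is None:
            return 0.0
        return recompaction_k0 * recompaction_Kr / (recompaction_Kr + cc)

    def model(cc, a, b):
        return a * cc * b / (a * cc + b) + baseline(cc)

    k_net = k - baseline(c)
    a0 = max(k_net[np.argmin(c)] / max(c.min(), 1e-9), 1e-6)
    b0 = max(k_net.max(), 1e-6)
    sigma = np.asarray(sems, float) if sems is not None else None
    popt, pcov = curve_fit(model, c, k, p0=[a0, b0], sigma=sigma,
                           bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                           maxfev=20000)
    pred = model(c, *popt)
    return SaturatingRateFit(
        bimolecular=float(popt[0]), asymptote=float(popt[1]),
        covariance=pcov, applies_to=applies_to,
        residual_rms=float(np.sqrt(np.mean((k - pred) ** 2))),
    )


@dataclass
class BellFit:
    k_0: float                    # s^-1, rate extrapolated to zero force
    delta_x: float                # nm, transition-state distance (may be < 0)
    covariance: np.ndarray
    kBT: float = 4.0615


def bell_rate(k_0: float, dx: float, force, kBT: float):
    """Bell-model rate ``k(F) = k_0 exp(F dx / kBT)``."""
    return k_0 * np.exp(np.asarray(force, float) * dx / kBT)


def fit_bell(points: Sequence[tuple[float, float]], kBT: float = 4.0615,
             sems: Optional[Sequence[float]] = None) -> BellFit:
    """Log-linear fit of the Bell force law; exact for two points."""
    pts = np.asarray(points, dtype=float)
    F, k = pts[:, 0], pts[:, 1]
    if len(F) < 2:
        raise ValueError("need at least 2 forces")
    if np.any(k <= 0):
        raise ValueError("non-positive rates in input")
    y = np.log(k)
    w = None
    if sems is not None:
        w = 1.0 / (np.asarray(sems, float) / k)  # delta-method log weights
    coeffs = np.polyfit(F, y, 1, w=w)
    if len(F) > 3:  # numpy needs n > order + 2 for a covariance estimate
        _, cov = np.polyfit(F, y, 1, w=w, cov=True)
    else:
        cov = np.zeros((2, 2))
    slope, intercept = float(coeffs[0]), float(coeffs[1])
    return BellFit(k_0=float(np.exp(intercept)), delta_x=slope * kBT,
                   covariance=np.asarray(cov), kBT=kBT)


@dataclass
class OligoTimeFit:
    k_0: float                    # s^-1, rate at zero incubation time
    k_inf: float                  # s^-1, long-incubation limit
    tau: float                    # s, oligomerization timescale
    covariance: np.ndarray

    def predict(self, t):
        return self.k_inf + (self.k_0 - self.k_inf) * np.exp(
            -np.asarray(t, float) / self.tau)


def fit_oligo_time(points: Sequence[tuple[float, float]],
                   sems: Optional[Sequence[float]] = None) -> OligoTimeFit:
    """Fit ``k(t) = k_inf + (k_0 - k_inf) exp(-t/tau)`` to re-compaction rates.

    Requires incubation times sampling both the fast limit (one point
    at or below tau/4) and the plateau (one at or beyond 3 tau), which
    the fitted tau itself is checked against.  Non-monotone input
    beyond noise triggers a warning but the fit is still returned.
    """
    pts = np.asarray(points, dtype=float)
    order = np.argsort(pts[:, 0])
    t, k = pts[order, 0], pts[order, 1]
    if len(t) < 4:
        raise ValueError("need at least 4 incubation times")
    rises = np.diff(k)
    tol = 0.05 * np.ptp(k) if np.ptp(k) else 0.0
    if np.any(rises > tol):
        warnings.warn("re-compaction rates not monotone non-increasing "
                      "beyond noise; fitting anyway", stacklevel=2)

    def model(tt, k0, kinf, tau):
        return kinf + (k0 - kinf) * np.exp(-tt / tau)

    p0 = [max(k[0], 1e-6), max(k[-1], 1e-8), max(np.median(t), 1e-3)]
    sigma = np.asarray(sems, float)[order] if sems is not None else None
    popt, pcov = curve_fit(model, t, k, p0=p0, sigma=sigma,
                           bounds=([1e-12, 1e-12, 1e-9], [np.inf] * 3),
                           maxfev=20000)
    k0, kinf, tau = (float(v) for v in popt)
    if not (t.min() <= tau / 4 + 1e-9 and t.max() >= 3 * tau - 1e-9):
        warnings.warn("incubation times poorly bracket the fitted timescale",
                      stacklevel=2)
    return OligoTimeFit(k_0=k0, k_inf=kinf, tau=tau, covariance=pcov)
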