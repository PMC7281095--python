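"""Quantitative property extraction.

Everything downstream of the raw traces lives here: exponential
time-constant fits of the interface transform beta(t), viscosity under
constant and varying flow, the Maxwell elasticity G = mu / lambda, the
RBC aggregation index (time-normalized integral of the post-stop
intensity rise), shear rate and equivalent diameter of the shallow
rectangular channel, the velocity-to-flow calibration, and power-law
(Ostwald-de Waele) shear-thinning summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .circuit import DEFAULT_CONSTANTS, ChannelGeometry, ModelConstants
from .errors import DegenerateFitError, EmptyResultError, FitError
from .traces import IntensityTrace
from .units import CP_TO_PAS, MLH_TO_M3S, UM_TO_M

__all__ = [
    "ExpFitResult",
    "AggregationResult",
    "PowerLawFit",
    "VelocityCalibration",
    "fit_time_constant",
    "viscosity_constant_flow",
    "viscosity_varying_flow",
    "shear_rate",
    "equivalent_diameter",
    "elasticity",
    "find_t0",
    "aggregation_index",
    "velocity_to_flow",
    "power_law_fit",
]


@dataclass(frozen=True)
class ExpFitResult:
    """Result of one transient fit beta(t) = beta0 + beta1 exp(-t/lam)."""

    beta0: float
    beta1: float
    lam: float
    rms_residual: float
    window: tuple[float, float]
    n_points: int


@dataclass(frozen=True)
class AggregationResult:
    """RBC aggregation index over one stop-flow window."""

    t0: float
    ts: float
    AI: float


@dataclass(frozen=True)
class PowerLawFit:
    """Ostwald-de Waele apparent-viscosity fit mu = mu0 * gdot^(n-1)."""

    mu0: float
    n: float
    r_squared: float


@dataclass(frozen=True)
class VelocityCalibration:
    """Linear ROI-velocity vs pump-flow calibration <U> = slope * Q."""

    slope_mm_s_per_mLh: float
    diluent: str = ""
    r_squared: float = float("nan")

    def __post_init__(self):
        if self.slope_mm_s_per_mLh <= 0:
            raise ValueError("calibration slope must be positive")


def fit_time_constant(
    t: np.ndarray,
    beta: np.ndarray,
    window_s: tuple[float, float] | None = None,
) -> ExpFitResult:
    """Fit a single first-order transient by damped nonlinear least
    squares.

    ``t`` should start at (or contain) a pump transition; the fit uses
    samples with ``window_s[0] <= t <= window_s[1]`` (the whole input
    when omitted) and re-zeroes time at the window start, so ``beta0``
    is the asymptote and ``beta0 + beta1`` the value at the transition.
    Initialization: beta0 = last sample, beta1 = first - last,
    lam = window/5; lam is bounded to (dt/10, 10*window].
    """
    t = np.asarray(t, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if window_s is not None:
        sel = (t >= window_s[0] - 1e-9) & (t <= window_s[1] + 1e-9)
        t, beta = t[sel], beta[sel]
    if t.size < 4:
        raise ValueError("need at least 4 samples in the fit window")
    t0, t1 = float(t[0]), float(t[-1])
    tt = t - t0
    span = tt[-1]
    dt = float(np.median(np.diff(tt)))
    b0_init = float(beta[-1])
    b1_init = float(beta[0] - beta[-1])
    if abs(b1_init) < 1e-3:
        raise DegenerateFitError(
            f"no transient: |beta1| initial estimate {abs(b1_init):.2e} < 1e-3"
        )
    lam_lo, lam_hi = dt / 10.0, 10.0 * span
    p0 = (b0_init, b1_init, span / 5.0)

    def model(x, b0, b1, lam):
        return b0 + b1 * np.exp(-x / lam)

    try:
        popt, _ = curve_fit(
            model,
            tt,
            beta,
            p0=p0,
            bounds=([-np.inf, -np.inf, lam_lo], [np.inf, np.inf, lam_hi]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    resid = beta - model(tt, *popt)
    return ExpFitResult(
        beta0=float(popt[0]),
        beta1=float(popt[1]),
        lam=float(popt[2]),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        window=(t0, t1),
        n_points=int(t.size),
    )


def viscosity_constant_flow(
    beta: float,
    mu_R_cP: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Test-fluid viscosity from the steady interface at matched flow
    rates (Q_T = Q_R): mu_B = mu_R (beta - 1) F2, in cP."""
    if beta < 1.0:
        raise ValueError("beta must be >= 1")
    if mu_R_cP <= 0:
        raise ValueError("mu_R must be positive")
    if beta == 1.0:
        warnings.warn("beta = 1 gives zero viscosity (empty test lane)")
    return mu_R_cP * (beta - 1.0) * constants.F2


def viscosity_varying_flow(
    beta_t: np.ndarray,
    mu_R_cP: float,
    Q_R_mLh: float,
    Q_B_mLh_t: np.ndarray,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    Q_min_mLh: float = 0.1,
) -> np.ndarray:
    """Pointwise flow-corrected viscosity
    mu_B(t) = mu_R (beta - 1) F2 (Q_R / Q_B), in cP.

    Samples with Q_B below ``Q_min_mLh`` (default 0.1 mL/h, where the
    correction blows up in the data this models) are returned as NaN.
    """
    beta_t = np.asarray(beta_t, dtype=float)
    Q_B = np.asarray(Q_B_mLh_t, dtype=float)
    if beta_t.shape != Q_B.shape:
        raise ValueError("beta and Q_B must have the same shape")
    if Q_R_mLh <= 0:
        raise ValueError("Q_R must be positive")
    valid = Q_B >= Q_min_mLh
    if not valid.any():
        raise EmptyResultError(f"all samples below Q_min = {Q_min_mLh} mL/h")
    mu = np.full_like(beta_t, np.nan)
    mu[valid] = mu_R_cP * (beta_t[valid] - 1.0) * constants.F2 * (Q_R_mLh / Q_B[valid])
    return mu


def shear_rate(Q_mLh: float, geom: ChannelGeometry) -> float:
    """Characteristic wall shear rate of a shallow rectangular channel,
    gdot = 6 Q / (W h^2), in 1/s."""
    if Q_mLh < 0:
        raise ValueError("Q must be non-negative")
    Q = Q_mLh * MLH_TO_M3S
    W = geom.W_um * UM_TO_M
    h = geom.h_um * UM_TO_M
    return 6.0 * Q / (W * h**2)


def equivalent_diameter(W_fill_um: float, h_um: float) -> float:
    """Equivalent circular diameter (um) of a filled rectangular cross
    section, d = sqrt(4 W h / pi) (area conservation)."""
    if W_fill_um <= 0 or h_um <= 0:
        raise ValueError("dimensions must be positive")
    return float(np.sqrt(4.0 * W_fill_um * h_um / np.pi))


def elasticity(mu_B_cP: float, lam_s: float) -> float:
    """Maxwell elastic modulus G = mu / lambda, returned in mPa.

    With mu in cP (1 cP = 1e-3 Pa s) and lambda in s the SI division
    lands numerically on mu_cP / lam_s when expressed in mPa.
    """
    if lam_s <= 0:
        raise ValueError("time constant must be positive")
    G_Pa = (mu_B_cP * CP_TO_PAS) / lam_s
    return G_Pa * 1.0e3


def _moving_average(I: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return I
    kernel = np.ones(n) / n
    # normalized 'same' convolution so window truncation at the edges
    # does not bias the level
    norm = np.convolve(np.ones_like(I), kernel, mode="same")
    return np.convolve(I, kernel, mode="same") / norm


def find_t0(
    intensity: IntensityTrace,
    off_window: tuple[float, float],
    smooth_s: float = 0.0,
) -> float:
    """Time of the post-stop intensity minimum within ``off_window``;
    ties break toward the earliest sample.

    With ``smooth_s`` > 0 the minimum is located in two stages: a
    coarse argmin on a centered moving average of that width (immune to
    the extreme-value bias a global argmin has on a noisy trace),
    refined by a raw-trace argmin restricted to one smoothing width
    around the coarse location (so an asymmetric minimum is not shifted
    by the averaging).  The returned time stays on the sampling grid.
    """
    t, I = intensity.t, intensity.I
    sel = (t >= off_window[0] - 1e-9) & (t <= off_window[1] + 1e-9)
    if not sel.any():
        raise ValueError("off_window contains no samples")
    t_w, I_w = t[sel], I[sel]
    if smooth_s > 0 and len(intensity) > 1:
        dt = float(np.median(np.diff(t)))
        I_sm = _moving_average(I, max(1, int(round(smooth_s / dt))))[sel]
        t_coarse = t_w[np.argmin(I_sm)]
        local = np.abs(t_w - t_coarse) <= smooth_s + 1e-9
        t_w, I_w = t_w[local], I_w[local]
    return float(t_w[np.argmin(I_w)])  # argmin returns the first minimum


def aggregation_index(
    intensity: IntensityTrace,
    t0: float,
    ts: float,
    baseline: float | None = None,
) -> AggregationResult:
    """RBC aggregation index: the trapezoid integral of
    <I(t)> - <I(t0)> over [t0, t0 + ts], divided by ts.

    Units follow the intensity trace (gray levels).  The integrand is
    signed; intensity dipping below its t0 value reduces the index.
    ``baseline`` overrides <I(t0)> (e.g. a smoothed estimate of the
    minimum level on a noisy trace).
    """
    if ts <= 0:
        raise ValueError("ts must be positive")
    t, I = intensity.t, intensity.I
    if t0 < t[0] - 1e-9 or t0 + ts > t[-1] + 1e-9:
        raise ValueError("[t0, t0 + ts] must lie within the trace")
    sel = (t >= t0 - 1e-9) & (t <= t0 + ts + 1e-9)
    t_w, I_w = t[sel], I[sel]
    i0 = float(np.interp(t0, t, I)) if baseline is None else float(baseline)
    ai = float(np.trapezoid(I_w - i0, t_w) / ts)
    return AggregationResult(t0=float(t0), ts=float(ts), AI=ai)


def velocity_to_flow(
    U_mm_s: np.ndarray,
    calib: VelocityCalibration,
) -> np.ndarray:
    """Invert the linear velocity calibration: Q_B = <U> / slope, mL/h."""
    U = np.asarray(U_mm_s, dtype=float)
    return U / calib.slope_mm_s_per_mLh


def power_law_fit(gamma_dot: np.ndarray, mu: np.ndarray) -> PowerLawFit:
    """Least-squares power-law fit mu(gdot) = mu0 * gdot^(n-1) in
    log-log space (standard apparent-viscosity convention)."""
    g = np.asarray(gamma_dot, dtype=float)
    m = np.asarray(mu, dtype=float)
    if g.shape != m.shape:
        raise ValueError("gamma_dot and mu must have the same shape")
    if g.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(g <= 0) or np.any(m <= 0):
        raise ValueError("gamma_dot and mu must be positive")
    x, y = np.log(g), np.log(m)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(mu0=float(np.exp(intercept)), n=float(1.0 + slope), r_squared=r2)
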