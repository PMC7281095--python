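"""Lumped fluidic-circuit model of two co-flowing streams.

A test fluid (typically a blood sample) and a reference fluid share a
wide, shallow rectangular channel.  Each stream is driven by its own
syringe pump; the interface between them sits where the pressure drops
of the two lanes balance, so its position encodes the flow-weighted
viscosity ratio.  An air cavity trapped in a driving syringe behaves as
a fluidic capacitance ``C_T`` in the circuit: it smooths pump pulsation
but delays every flow transient with a first-order time constant.

The interface fraction ``alpha`` (test-fluid lane width / channel width)
obeys the nonlinear balance

    C_T R_WT d/dt [ C_f(alpha) / (1 - alpha) ] + C_f(alpha) alpha / (1 - alpha)
        = (Q_T / Q_R) (mu_T / mu_R)

where ``R_WT = 12 mu_T L_cc / (W_lane h^3)`` is the hydraulic resistance
of the test-fluid lane and ``C_f`` is a quartic polynomial in ``alpha``
(fitted against full CFD over 0.1 < alpha < 0.9) that compensates the
virtual-wall idealization.  Substituting ``beta = 1/(1 - alpha)`` and
two closure coefficients ``F1, F2`` linearizes this to

    lambda d(beta)/dt + beta = 1 + (1/F2)(Q_T/Q_R)(mu_T/mu_R),
    lambda = F1 F2 C_T R_WT.

Both forms are integrated here under periodic on-off pump protocols;
the linear form is the workhorse (and what the estimators invert), the
nonlinear form serves as its accuracy check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import IntegrationDomainError, ValidityRangeError
from .traces import InterfaceTrace
from .units import CP_TO_PAS, ULPA_TO_M3PA, UM_TO_M

__all__ = [
    "ModelConstants",
    "DEFAULT_CONSTANTS",
    "ChannelGeometry",
    "FluidPair",
    "PumpProtocol",
    "CompliancePack",
    "correction_factor",
    "lane_resistance",
    "time_constant_from_compliance",
    "steady_state_beta",
    "steady_state_alpha",
    "steady_state_alpha_nonlinear",
    "simulate_linear",
    "simulate_nonlinear",
]


@dataclass(frozen=True)
class ModelConstants:
    """Closure constants of the circuit model.

    ``F1`` and ``F2`` come from the approximate linearization procedure;
    ``cf_coeffs`` are the quartic correction-factor coefficients in
    descending order (alpha^4 ... alpha^0), valid on ``cf_alpha_range``.
    """

    F1: float = 1.112
    F2: float = 1.129
    cf_coeffs: tuple[float, float, float, float, float] = (
        6.6908,
        -13.382,
        10.81,
        -4.1196,
        1.6206,
    )
    cf_alpha_range: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self):
        if self.F1 <= 0 or self.F2 <= 0:
            raise ValueError("F1 and F2 must be positive")
        lo, hi = self.cf_alpha_range
        if not (0.0 <= lo < hi < 1.0):
            raise ValueError("cf_alpha_range must be an interval inside [0, 1)")
        if len(self.cf_coeffs) != 5:
            raise ValueError("cf_coeffs must hold five coefficients")


DEFAULT_CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class ChannelGeometry:
    """Channel dimensions in micrometres.

    ``W_lane_um`` is the width entering the lane-resistance formula; by
    default the full channel width is used (the lane occupied by the
    test fluid is not resolved separately).
    """

    W_um: float = 1000.0
    h_um: float = 100.0
    L_cc_um: float = 5000.0
    W_lane_um: float | None = None

    def __post_init__(self):
        for name in ("W_um", "h_um", "L_cc_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.W_lane_um is not None:
            if self.W_lane_um <= 0:
                raise ValueError("W_lane_um must be positive")
            if self.W_lane_um > self.W_um:
                raise ValueError("W_lane_um cannot exceed W_um")

    @property
    def lane_width_um(self) -> float:
        return self.W_um if self.W_lane_um is None else self.W_lane_um


@dataclass(frozen=True)
class FluidPair:
    """Viscosities (cP) and labels of the reference / test fluids."""

    mu_R_cP: float = 1.0
    mu_T_cP: float = 2.95
    label_R: str = "1x PBS"
    label_T: str = "blood (Hct 50%, PBS)"

    def __post_init__(self):
        if self.mu_R_cP <= 0 or self.mu_T_cP <= 0:
            raise ValueError("viscosities must be positive")

    @property
    def viscosity_ratio(self) -> float:
        return self.mu_T_cP / self.mu_R_cP


@dataclass(frozen=True)
class PumpProtocol:
    """Periodic on-off schedule of the test-fluid syringe pump.

    The reference pump runs at constant ``Q_R_mLh`` throughout.  The
    test pump delivers ``Q_T_on_mLh`` during the first ``duty`` fraction
    of every period and ``Q_T_off_mLh`` (zero in the experiments this
    models) for the remainder.  Switching is instantaneous.
    """

    period_s: float = 240.0
    duty: float = 0.5
    Q_R_mLh: float = 0.5
    Q_T_on_mLh: float = 0.5
    Q_T_off_mLh: float = 0.0
    n_periods: int = 3
    dt_s: float = 0.5

    def __post_init__(self):
        if self.period_s <= 0:
            raise ValueError("period_s must be positive")
        if not (0 < self.duty < 1):
            raise ValueError("duty must lie in (0, 1)")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.Q_R_mLh <= 0:
            raise ValueError("Q_R_mLh must be positive")
        if self.Q_T_on_mLh < 0 or self.Q_T_off_mLh < 0:
            raise ValueError("test flow rates must be non-negative")
        if self.n_periods < 1:
            raise ValueError("n_periods must be >= 1")

    @property
    def duration_s(self) -> float:
        return self.period_s * self.n_periods

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration_s / self.dt_s)) + 1
        return np.arange(n) * self.dt_s

    def segments(self) -> list[tuple[float, float, bool]]:
        """(t_start, t_end, pump_on) tuples tiling the full run."""
        out = []
        for k in range(self.n_periods):
            t0 = k * self.period_s
            t_sw = t0 + self.duty * self.period_s
            t1 = t0 + self.period_s
            out.append((t0, t_sw, True))
            out.append((t_sw, t1, False))
        return out

    def q_t(self, t) -> np.ndarray:
        """Test-pump flow rate (mL/h) at time(s) t."""
        t = np.asarray(t, dtype=float)
        phase = np.mod(t, self.period_s)
        on = phase < self.duty * self.period_s - 1e-12
        # the terminal sample t == duration belongs to the last off segment
        return np.where(on, self.Q_T_on_mLh, self.Q_T_off_mLh)


@dataclass(frozen=True)
class CompliancePack:
    """First-order relaxation times of the interface after pump
    transitions.

    The primary parameterization is the pair (``lambda_on_s``,
    ``lambda_off_s``) fitted from data, because the compliance of an air
    cavity is rarely known numerically.  When a compliance ``C_T`` is
    available instead, use :func:`time_constant_from_compliance` or
    :meth:`from_compliance` (which yields a single lambda for both
    directions, as the model itself does not distinguish them).
    """

    lambda_on_s: float
    lambda_off_s: float
    C_T_uL_per_Pa: float | None = None

    def __post_init__(self):
        if self.lambda_on_s <= 0 or self.lambda_off_s <= 0:
            raise ValueError("time constants must be positive")

    @classmethod
    def from_compliance(
        cls,
        C_T_uL_per_Pa: float,
        geom: ChannelGeometry,
        fluids: FluidPair,
        constants: ModelConstants = DEFAULT_CONSTANTS,
    ) -> "CompliancePack":
        lam = time_constant_from_compliance(C_T_uL_per_Pa, geom, fluids.mu_T_cP, constants)
        return cls(lambda_on_s=lam, lambda_off_s=lam, C_T_uL_per_Pa=C_T_uL_per_Pa)


def correction_factor(
    alpha,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    mode: str = "strict",
):
    """Virtual-wall correction factor C_f(alpha).

    Quartic polynomial fitted against full CFD; only trustworthy on
    ``constants.cf_alpha_range``.  ``mode='strict'`` raises outside that
    interval, ``mode='clamp'`` evaluates at the nearest boundary with a
    warning.
    """
    alpha = np.asarray(alpha, dtype=float)
    lo, hi = constants.cf_alpha_range
    out_of_range = (alpha < lo) | (alpha > hi)
    if np.any(out_of_range):
        if mode == "strict":
            raise ValidityRangeError(
                f"alpha outside the C_f validity interval ({lo}, {hi}): "
                f"offending value(s) near {np.atleast_1d(alpha)[np.atleast_1d(out_of_range)][0]:.4g}"
            )
        elif mode == "clamp":
            warnings.warn(
                "alpha clamped to the C_f validity interval", stacklevel=2
            )
            alpha = np.clip(alpha, lo, hi)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    val = np.polyval(constants.cf_coeffs, alpha)
    return float(val) if val.ndim == 0 else val


def lane_resistance(geom: ChannelGeometry, mu_T_cP: float) -> float:
    """Hydraulic resistance of the test-fluid lane, Pa s / m^3.

    R_WT = 12 mu_T L_cc / (W_lane h^3), the shallow-rectangular-channel
    approximation.
    """
    if mu_T_cP <= 0:
        raise ValueError("viscosity must be positive")
    mu = mu_T_cP * CP_TO_PAS
    L = geom.L_cc_um * UM_TO_M
    w = geom.lane_width_um * UM_TO_M
    h = geom.h_um * UM_TO_M
    return 12.0 * mu * L / (w * h**3)


def time_constant_from_compliance(
    C_T_uL_per_Pa: float,
    geom: ChannelGeometry,
    mu_T_cP: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """lambda = F1 F2 C_T R_WT, in seconds."""
    if C_T_uL_per_Pa <= 0:
        raise ValueError("compliance must be positive")
    R = lane_resistance(geom, mu_T_cP)
    return constants.F1 * constants.F2 * C_T_uL_per_Pa * ULPA_TO_M3PA * R


def steady_state_beta(
    Q_T_mLh: float,
    Q_R_mLh: float,
    mu_T_cP: float,
    mu_R_cP: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Equilibrium beta of the linearized model:
    beta_ss = 1 + (1/F2)(Q_T/Q_R)(mu_T/mu_R)."""
    if Q_R_mLh <= 0:
        raise ValueError("Q_R must be positive")
    if mu_T_cP <= 0 or mu_R_cP <= 0:
        raise ValueError("viscosities must be positive")
    if Q_T_mLh < 0:
        raise ValueError("Q_T must be non-negative")
    return 1.0 + (Q_T_mLh / Q_R_mLh) * (mu_T_cP / mu_R_cP) / constants.F2


def steady_state_alpha(
    Q_T_mLh: float,
    Q_R_mLh: float,
    mu_T_cP: float,
    mu_R_cP: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """alpha_ss = 1 - 1/beta_ss of the linearized model."""
    return 1.0 - 1.0 / steady_state_beta(Q_T_mLh, Q_R_mLh, mu_T_cP, mu_R_cP, constants)


def _cf_over_one_minus_alpha(alpha: float, constants: ModelConstants) -> float:
    # state map y(alpha) = C_f(alpha)/(1 - alpha); monotone increasing on
    # the validity interval, which makes the inverse a bracketing solve
    return float(np.polyval(constants.cf_coeffs, alpha)) / (1.0 - alpha)


def steady_state_alpha_nonlinear(
    Q_T_mLh: float,
    Q_R_mLh: float,
    mu_T_cP: float,
    mu_R_cP: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Equilibrium alpha of the full nonlinear balance
    C_f(alpha) alpha / (1 - alpha) = (Q_T/Q_R)(mu_T/mu_R)."""
    if Q_R_mLh <= 0:
        raise ValueError("Q_R must be positive")
    r = (Q_T_mLh / Q_R_mLh) * (mu_T_cP / mu_R_cP)
    lo, hi = constants.cf_alpha_range

    def resid(a):
        return float(np.polyval(constants.cf_coeffs, a)) * a / (1.0 - a) - r

    if resid(lo) > 0 or resid(hi) < 0:
        raise ValidityRangeError(
            f"steady-state alpha for drive ratio {r:.4g} lies outside ({lo}, {hi})"
        )
    return brentq(resid, lo, hi, xtol=1e-12)


def simulate_linear(
    protocol: PumpProtocol,
    compliance: CompliancePack,
    fluids: FluidPair,
    beta_init: float = 1.0,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    W_um: float | None = None,
) -> InterfaceTrace:
    """Integrate the linearized interface ODE over the pump protocol.

    Each constant-flow segment obeys lambda d(beta)/dt = beta_ss - beta
    with lambda = lambda_on during on segments and lambda_off during off
    segments; switching steps Q_T instantaneously.  Integration is
    adaptive (rtol 1e-8) with the solution interpolated onto the
    protocol sampling grid.
    """
    if beta_init < 1.0:
        raise ValueError("beta_init must be >= 1 (alpha would be negative)")
    t = protocol.time_grid()
    beta = np.empty_like(t)
    beta[0] = beta_init
    state = beta_init
    for t0, t1, on in protocol.segments():
        q = protocol.Q_T_on_mLh if on else protocol.Q_T_off_mLh
        bss = steady_state_beta(q, protocol.Q_R_mLh, fluids.mu_T_cP, fluids.mu_R_cP, constants)
        lam = compliance.lambda_on_s if on else compliance.lambda_off_s
        sol = solve_ivp(
            lambda tt, y: (bss - y) / lam,
            (t0, t1),
            [state],
            method="LSODA",
            rtol=1e-8,
            atol=1e-12,
            dense_output=True,
        )
        if not sol.success:  # pragma: no cover - LSODA on a linear ODE
            raise RuntimeError(f"ODE integration failed on segment [{t0}, {t1}]: {sol.message}")
        mask = (t > t0 + 1e-9) & (t <= t1 + 1e-9)
        beta[mask] = sol.sol(t[mask])[0]
        state = float(sol.y[0, -1])
    # the integrator may undershoot the beta = 1 asymptote by ~atol
    beta = np.maximum(beta, 1.0)
    return InterfaceTrace.from_beta(
        t,
        beta,
        W_um=W_um,
        Q_T_mLh=protocol.q_t(t),
        Q_R_mLh=np.full_like(t, protocol.Q_R_mLh),
    )


def simulate_nonlinear(
    protocol: PumpProtocol,
    C_T_uL_per_Pa: float,
    geom: ChannelGeometry,
    fluids: FluidPair,
    alpha_init: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    mode: str = "strict",
) -> InterfaceTrace:
    """Integrate the full nonlinear interface ODE over the pump protocol.

    The state variable is y = C_f(alpha)/(1 - alpha), which is monotone
    in alpha on the validity interval, so alpha is recovered from y by
    bracketed root finding at every evaluation.  In ``strict`` mode the
    integration aborts with :class:`IntegrationDomainError` the moment
    alpha leaves the C_f validity interval; in ``clamp`` mode C_f is
    frozen at its boundary value and alpha may continue toward 0 or 1
    (with a warning), which is useful for protocols whose off segments
    drain the test lane below alpha = 0.1.
    """
    lo, hi = constants.cf_alpha_range
    if not (lo <= alpha_init <= hi):
        raise ValidityRangeError(
            f"alpha_init must lie within the C_f validity interval ({lo}, {hi})"
        )
    if mode not in ("strict", "clamp"):
        raise ValueError(f"unknown mode {mode!r}")
    tau = (
        C_T_uL_per_Pa
        * ULPA_TO_M3PA
        * lane_resistance(geom, fluids.mu_T_cP)
    )
    if tau <= 0:
        raise ValueError("compliance must be positive")

    cf_lo = float(np.polyval(constants.cf_coeffs, lo))
    cf_hi = float(np.polyval(constants.cf_coeffs, hi))
    alpha_floor = 1e-9 if mode == "clamp" else lo
    alpha_ceil = 1.0 - 1e-9 if mode == "clamp" else hi

    def y_of_alpha(a: float) -> float:
        # clamp mode extends the map by freezing C_f at the boundary value,
        # keeping y monotone on (0, 1)
        if a < lo:
            return cf_lo / (1.0 - a)
        if a > hi:
            return cf_hi / (1.0 - a)
        return _cf_over_one_minus_alpha(a, constants)

    y_floor = y_of_alpha(alpha_floor)
    y_ceil = y_of_alpha(alpha_ceil)

    def alpha_of_y(y: float) -> float:
        y = min(max(y, y_floor), y_ceil)
        return brentq(lambda a: y_of_alpha(a) - y, alpha_floor, alpha_ceil, xtol=1e-12)

    visc_ratio = fluids.viscosity_ratio

    def rhs(tt, yv, r):
        a = alpha_of_y(yv[0])
        cf = y_of_alpha(a) * (1.0 - a)  # C_f at (possibly clamped) alpha
        return [(r - cf * a / (1.0 - a)) / tau]

    t = protocol.time_grid()
    alpha = np.empty_like(t)
    alpha[0] = alpha_init
    state = y_of_alpha(alpha_init)

    if mode == "clamp":
        warnings.warn(
            "nonlinear simulation running in clamp mode: C_f frozen at its "
            "boundary value outside the fitted interval",
            stacklevel=2,
        )

    events = []
    if mode == "strict":
        ylo = _cf_over_one_minus_alpha(lo, constants)
        yhi = _cf_over_one_minus_alpha(hi, constants)

        def hit_lo(tt, yv, r):
            return yv[0] - ylo

        def hit_hi(tt, yv, r):
            return yv[0] - yhi

        hit_lo.terminal = True
        hit_lo.direction = -1
        hit_hi.terminal = True
        hit_hi.direction = 1
        events = [hit_lo, hit_hi]

    for t0, t1, on in protocol.segments():
        q = protocol.Q_T_on_mLh if on else protocol.Q_T_off_mLh
        r = (q / protocol.Q_R_mLh) * visc_ratio
        sol = solve_ivp(
            rhs,
            (t0, t1),
            [state],
            args=(r,),
            method="LSODA",
            rtol=1e-8,
            atol=1e-12,
            dense_output=True,
            events=events,
        )
        if sol.status == 1:  # terminated by a validity-interval event
            t_exit = float(np.concatenate([te for te in sol.t_events if te.size]).min())
            raise IntegrationDomainError(
                f"alpha left the C_f validity interval at t = {t_exit:.3f} s",
                time_s=t_exit,
            )
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"ODE integration failed on segment [{t0}, {t1}]: {sol.message}")
        mask = (t > t0 + 1e-9) & (t <= t1 + 1e-9)
        yvals = sol.sol(t[mask])[0]
        alpha[mask] = [alpha_of_y(v) for v in yvals]
        state = float(sol.y[0, -1])

    return InterfaceTrace(
        t,
        alpha,
        W_um=geom.W_um,
        Q_T_mLh=protocol.q_t(t),
        Q_R_mLh=np.full_like(t, protocol.Q_R_mLh),
    )
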