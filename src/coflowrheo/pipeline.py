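"""Per-period orchestration of the measurement chain.

One experimental period yields, in sequence: the blood viscosity from
the steady portion of the on segment, the turn-off and turn-on time
constants from exponential fits, the Maxwell elasticity from their
ratio, and the RBC aggregation index from the intensity trace after the
flow stops.  Periods whose steady sub-window has not converged (the
signature of a large air compliance in the blood-sample syringe) are
flagged and their viscosity withheld rather than reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit import DEFAULT_CONSTANTS, ModelConstants, PumpProtocol
from .errors import CoflowError, DegenerateFitError, EmptyResultError, FitError
from .estimators import (
    VelocityCalibration,
    aggregation_index,
    elasticity,
    find_t0,
    fit_time_constant,
    velocity_to_flow,
    viscosity_constant_flow,
    viscosity_varying_flow,
)
from .traces import IntensityTrace, InterfaceTrace, VelocityTrace

__all__ = [
    "PeriodWindows",
    "AnalysisConfig",
    "RheoSummary",
    "segment_periods",
    "check_convergence",
    "analyze_experiment",
    "recommend_half_period_extension",
    "recommend_period",
]


@dataclass(frozen=True)
class PeriodWindows:
    """Time windows (s) of one pump period."""

    index: int
    on: tuple[float, float]
    off: tuple[float, float]
    steady: tuple[float, float]  # tail of the on segment used for viscosity


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything the per-period analysis needs beyond the traces."""

    protocol: PumpProtocol
    mu_R_cP: float = 1.0
    constants: ModelConstants = DEFAULT_CONSTANTS
    window_off_s: float = 60.0
    window_on_s: float = 20.0
    steady_frac: float = 0.25
    conv_tol: float = 0.01
    ts_s: float = 60.0
    Q_min_mLh: float = 0.1
    smooth_I_s: float = 5.0  # moving-average width for locating the intensity minimum

    def __post_init__(self):
        if self.mu_R_cP <= 0:
            raise ValueError("mu_R_cP must be positive")
        if not (0 < self.steady_frac <= 1):
            raise ValueError("steady_frac must lie in (0, 1]")
        if self.window_off_s <= 0 or self.window_on_s <= 0:
            raise ValueError("fit windows must be positive")


@dataclass
class RheoSummary:
    """Per-period records plus mean +/- sample SD summaries."""

    per_period: pd.DataFrame
    notes: list[str] = field(default_factory=list)

    _COLUMNS = ("mu_B_cP", "lambda_off_s", "lambda_on_s", "G_B_mPa", "AI")

    def summary(self) -> dict[str, tuple[float, float]]:
        out = {}
        for col in self._COLUMNS:
            if col in self.per_period.columns:
                vals = self.per_period[col].dropna()
                if len(vals):
                    out[col] = (float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
        return out

    def to_csv(self, path) -> None:
        self.per_period.to_csv(path, index=False)


def segment_periods(
    protocol: PumpProtocol,
    duration_s: float,
    steady_frac: float = 0.25,
) -> list[PeriodWindows]:
    """Deterministic per-period windows from the protocol timing.

    The steady sub-window is the trailing ``steady_frac`` of each on
    segment, ending at the on-to-off transition.  A trailing partial
    period is dropped with a warning.
    """
    T = protocol.period_s
    if duration_s < T - 1e-9:
        raise ValueError(f"trace ({duration_s} s) shorter than one period ({T} s)")
    n_full = int((duration_s + 1e-9) // T)
    if duration_s - n_full * T > 1e-9:
        warnings.warn(
            f"trace covers {duration_s} s: using {n_full} full period(s), "
            "dropping the partial remainder"
        )
    out = []
    on_len = protocol.duty * T
    for k in range(n_full):
        t0 = k * T
        t_sw = t0 + on_len
        t1 = t0 + T
        out.append(
            PeriodWindows(
                index=k,
                on=(t0, t_sw),
                off=(t_sw, t1),
                steady=(t_sw - steady_frac * on_len, t_sw),
            )
        )
    return out


def check_convergence(t: np.ndarray, beta: np.ndarray, tol: float = 0.01) -> bool:
    """True when beta has plateaued over the window: relative drift
    |beta_end - beta_start| / beta_end <= tol."""
    beta = np.asarray(beta, dtype=float)
    if beta.size == 0:
        raise ValueError("empty segment")
    if tol >= 1.0:
        return True
    drift = abs(beta[-1] - beta[0]) / abs(beta[-1])
    return bool(drift <= tol)


def _window(t, *arrays, lo, hi):
    sel = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    return (t[sel],) + tuple(a[sel] for a in arrays)


def analyze_experiment(
    interface: InterfaceTrace,
    config: AnalysisConfig,
    intensity: IntensityTrace | None = None,
    velocity: VelocityTrace | None = None,
    calibration: VelocityCalibration | None = None,
) -> RheoSummary:
    """Run the full per-period analysis.

    Per period: mean beta over the steady sub-window -> viscosity (only
    if the window has converged); 60 s / 20 s exponential fits after the
    off / on transitions -> lambda_off, lambda_on; G_B = mu_B/lambda_off;
    intensity minimum + trapezoid integral -> aggregation index; and,
    when a velocity trace and calibration are supplied, the
    flow-corrected varying-flow viscosity.  Stage failures are recorded
    per period; the run raises only if every period fails everywhere.
    """
    p = config.protocol
    t = interface.t
    beta = interface.beta
    windows = segment_periods(p, float(t[-1]), config.steady_frac)
    notes: list[str] = []
    records = []
    q_ratio = p.Q_R_mLh / p.Q_T_on_mLh if p.Q_T_on_mLh > 0 else np.nan

    for w in windows:
        rec: dict = {"period": w.index}
        ok = False

        # --- viscosity from the steady on sub-window (constant flow) ---
        ts_w, beta_s = _window(t, beta, lo=w.steady[0], hi=w.steady[1])
        mu_B = np.nan
        if beta_s.size == 0:
            notes.append(f"period {w.index}: steady window empty")
        elif not check_convergence(ts_w, beta_s, config.conv_tol):
            notes.append(
                f"period {w.index}: steady sub-window not converged "
                f"(beta still drifting); viscosity withheld"
            )
        else:
            try:
                mu_B = viscosity_constant_flow(
                    float(beta_s.mean()), config.mu_R_cP, config.constants
                ) * q_ratio
                ok = True
            except ValueError as exc:
                notes.append(f"period {w.index}: viscosity failed ({exc})")
        rec["mu_B_cP"] = mu_B
        rec["steady_converged"] = not np.isnan(mu_B)

        # --- time constants ---
        for key, (lo, hi) in (
            ("lambda_off_s", (w.off[0], min(w.off[0] + config.window_off_s, w.off[1]))),
            ("lambda_on_s", (w.on[0], min(w.on[0] + config.window_on_s, w.on[1]))),
        ):
            try:
                fit = fit_time_constant(t, beta, (lo, hi))
                rec[key] = fit.lam
                ok = True
            except (DegenerateFitError, FitError, ValueError) as exc:
                rec[key] = np.nan
                notes.append(f"period {w.index}: {key} fit failed ({exc})")

        # --- Maxwell elasticity ---
        if not np.isnan(rec["mu_B_cP"]) and not np.isnan(rec.get("lambda_off_s", np.nan)):
            rec["G_B_mPa"] = elasticity(rec["mu_B_cP"], rec["lambda_off_s"])
        else:
            rec["G_B_mPa"] = np.nan

        # --- aggregation index ---
        rec["AI"] = np.nan
        if intensity is not None and len(intensity):
            try:
                # locate the minimum on a lightly smoothed trace so the
                # argmin is not an extreme-value statistic of the noise,
                # then baseline and integrate the raw trace at that time
                t0 = find_t0(intensity, w.off, smooth_s=config.smooth_I_s)
                if t0 + config.ts_s > intensity.t[-1] + 1e-9:
                    notes.append(
                        f"period {w.index}: AI span exceeds the trace; skipped"
                    )
                else:
                    rec["AI"] = aggregation_index(intensity, t0, config.ts_s).AI
                    rec["t0_s"] = t0
                    ok = True
            except ValueError as exc:
                notes.append(f"period {w.index}: AI failed ({exc})")

        # --- varying-flow viscosity (optional branch) ---
        if velocity is not None and calibration is not None:
            try:
                tv, Uv = _window(
                    velocity.t, velocity.U_mm_s, lo=w.on[0], hi=w.off[1]
                )
                tb, beta_v = _window(t, beta, lo=w.on[0], hi=w.off[1])
                if tv.shape != tb.shape or not np.allclose(tv, tb):
                    raise ValueError("velocity and interface traces not on one grid")
                Q_B = velocity_to_flow(Uv, calibration)
                mu_t = viscosity_varying_flow(
                    beta_v, config.mu_R_cP, p.Q_R_mLh, Q_B,
                    config.constants, config.Q_min_mLh,
                )
                rec["mu_B_varflow_cP"] = float(np.nanmean(mu_t))
                ok = True
            except (EmptyResultError, ValueError) as exc:
                rec["mu_B_varflow_cP"] = np.nan
                notes.append(f"period {w.index}: varying-flow viscosity failed ({exc})")

        rec["any_success"] = ok
        records.append(rec)

    if not any(r["any_success"] for r in records):
        raise CoflowError("every period failed every analysis stage")
    df = pd.DataFrame(records).drop(columns=["any_success"])
    return RheoSummary(per_period=df, notes=notes)


def recommend_half_period_extension(delta_lambda_off_s) -> float:
    """Minimum extra half-period needed so the slowest fluid still
    plateaus: the largest of the measured lambda_off increments."""
    arr = np.asarray(list(delta_lambda_off_s), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one increment")
    return float(arr.max())


def recommend_period(lambda_off_s: float, t_steady_s: float) -> float:
    """Planner helper: a period of at least 2 (t_steady + 2 lambda_off)
    leaves both a converged plateau and a clean transient per half
    period."""
    if lambda_off_s <= 0 or t_steady_s < 0:
        raise ValueError("invalid planner inputs")
    return 2.0 * (t_steady_s + 2.0 * lambda_off_s)
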