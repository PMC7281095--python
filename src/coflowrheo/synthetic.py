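"""Protocol-locked synthetic experiment generator.

Stands in for the microscope + syringe-pump experiment: it produces
interface, intensity, and velocity traces and two-phase channel image
stacks with the statistical structure the analysis assumes, alongside
the ground truth that produced them.  The generator's job is structure,
not literal reproduction of any particular blood sample: first-order
on/off interface transients with distinct time constants, a saturating
intensity rise once the flow has slowed enough for RBC aggregation to
proceed, a linear velocity-flow relation, and a sharp two-phase
interface plus additive Gaussian noise.

Default constants mimic the magnitudes of the measurements this package
models: per-diluent viscosities of 2.95 / 3.53 / 5.89 / 4.59 cP,
velocity-calibration slopes of 2.0732 (PBS) and 2.6287 (dextran)
mm/s per mL/h, and a 240 s period with duty 0.5 sampled at 0.5 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .circuit import (
    DEFAULT_CONSTANTS,
    CompliancePack,
    FluidPair,
    ModelConstants,
    PumpProtocol,
    simulate_linear,
    steady_state_beta,
)
from .estimators import aggregation_index, find_t0
from .imaging import ROI, ImageStack
from .traces import IntensityTrace, InterfaceTrace, VelocityTrace

__all__ = [
    "AggregationModel",
    "NoiseModel",
    "SyntheticScenario",
    "DILUENT_PRESETS",
    "scenario_for_diluent",
    "gen_beta_trace",
    "gen_intensity_trace",
    "gen_velocity_trace",
    "gen_coflow_stack",
]

#: slope of the empirical lambda_on vs lambda_off relation used to pick a
#: default turn-on time constant when only lambda_off is specified
_LAM_ON_SLOPE, _LAM_ON_INTERCEPT = 0.2815, 1.4967


@dataclass(frozen=True)
class AggregationModel:
    """Saturating-exponential aggregation kinetics with a velocity gate.

    Aggregation proceeds (intensity relaxing toward
    ``i_base + amplitude``) whenever the blood velocity is below
    ``gate_velocity_mm_s``, and disaggregates (relaxing back to
    ``i_base`` with ``tau_disagg_s``) whenever flow resumes.  A small
    flow-brightness term makes the intensity scale with velocity while
    flowing, which places the post-stop intensity minimum at the moment
    the gate opens.
    """

    amplitude_gray: float = 10.0
    tau_s: float = 20.0
    gate_velocity_mm_s: float = 0.05
    flow_brightness_gray_per_mm_s: float = 2.0
    i_base_gray: float = 80.0
    tau_disagg_s: float = 5.0

    def __post_init__(self):
        if self.amplitude_gray < 0:
            raise ValueError("amplitude must be >= 0")
        if self.tau_s <= 0 or self.tau_disagg_s <= 0:
            raise ValueError("time constants must be positive")
        if self.gate_velocity_mm_s < 0 or self.flow_brightness_gray_per_mm_s < 0:
            raise ValueError("gate velocity and flow brightness must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise levels, one per measurement channel.

    Defaults are ~1-2% of the respective signal amplitude: the same
    relative level for every channel (the intensity channel is an ROI
    mean over tens of thousands of pixels, so its absolute noise is
    small compared with the aggregation amplitude).
    """

    beta_rel: float = 0.01  # sd relative to the on-step beta amplitude
    intensity_gray: float = 0.1
    velocity_mm_s: float = 0.02

    def __post_init__(self):
        if min(self.beta_rel, self.intensity_gray, self.velocity_mm_s) < 0:
            raise ValueError("noise levels must be >= 0")


@dataclass(frozen=True)
class SyntheticScenario:
    """Complete parameterization of one synthetic experiment."""

    seed: int
    protocol: PumpProtocol = field(default_factory=PumpProtocol)
    compliance: CompliancePack = field(
        default_factory=lambda: CompliancePack(lambda_on_s=3.16, lambda_off_s=5.9)
    )
    fluids: FluidPair = field(default_factory=FluidPair)
    aggregation: AggregationModel = field(default_factory=AggregationModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    calibration_slope_mm_s_per_mLh: float = 2.0732
    constants: ModelConstants = DEFAULT_CONSTANTS

    def __post_init__(self):
        if self.calibration_slope_mm_s_per_mLh <= 0:
            raise ValueError("calibration slope must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator."""
        return np.random.default_rng([self.seed, stream])


def _lambda_on_default(lambda_off: float) -> float:
    return _LAM_ON_SLOPE * lambda_off + _LAM_ON_INTERCEPT


#: (mu_T cP, G_B mPa, calibration slope mm/s per mL/h) per diluent; the
#: time constant follows from the Maxwell relation lambda = mu / G
DILUENT_PRESETS: dict[str, dict] = {
    "pbs": {"mu_T_cP": 2.95, "G_B_mPa": 0.50, "slope": 2.0732},
    "dextran5": {"mu_T_cP": 3.53, "G_B_mPa": 0.62, "slope": 2.6287},
    "dextran10": {"mu_T_cP": 5.89, "G_B_mPa": 0.79, "slope": 2.6287},
    "plasma": {"mu_T_cP": 4.59, "G_B_mPa": 0.76, "slope": 2.0732},
}


def scenario_for_diluent(diluent: str, seed: int, **overrides) -> SyntheticScenario:
    """Build a scenario whose viscosity, time constant, and velocity
    calibration follow the per-diluent defaults."""
    preset = DILUENT_PRESETS[diluent]
    lam_off = preset["mu_T_cP"] / preset["G_B_mPa"]
    base = SyntheticScenario(
        seed=seed,
        fluids=FluidPair(mu_T_cP=preset["mu_T_cP"], label_T=f"blood (Hct 50%, {diluent})"),
        compliance=CompliancePack(
            lambda_on_s=_lambda_on_default(lam_off), lambda_off_s=lam_off
        ),
        calibration_slope_mm_s_per_mLh=preset["slope"],
    )
    return replace(base, **overrides) if overrides else base


def _beta_amplitude(scenario: SyntheticScenario) -> float:
    p, f, c = scenario.protocol, scenario.fluids, scenario.constants
    b_on = steady_state_beta(p.Q_T_on_mLh, p.Q_R_mLh, f.mu_T_cP, f.mu_R_cP, c)
    b_off = steady_state_beta(p.Q_T_off_mLh, p.Q_R_mLh, f.mu_T_cP, f.mu_R_cP, c)
    return abs(b_on - b_off)


def gen_beta_trace(scenario: SyntheticScenario) -> tuple[InterfaceTrace, dict]:
    """Noisy interface trace plus ground truth.

    The noiseless trajectory is the linear circuit simulation; Gaussian
    noise with sd ``noise.beta_rel`` times the on-step beta amplitude is
    added to beta (floored at 1 so alpha stays non-negative).
    """
    clean = simulate_linear(
        scenario.protocol, scenario.compliance, scenario.fluids,
        constants=scenario.constants,
    )
    beta_clean = clean.beta
    sigma = scenario.noise.beta_rel * _beta_amplitude(scenario)
    beta = beta_clean
    if sigma > 0:
        beta = np.maximum(
            1.0, beta_clean + scenario.rng(0).normal(0.0, sigma, beta_clean.shape)
        )
    trace = InterfaceTrace.from_beta(
        clean.t, beta, Q_T_mLh=clean.Q_T_mLh, Q_R_mLh=clean.Q_R_mLh
    )
    truth = {
        "lambda_on_s": scenario.compliance.lambda_on_s,
        "lambda_off_s": scenario.compliance.lambda_off_s,
        "mu_T_cP": scenario.fluids.mu_T_cP,
        "beta_clean": beta_clean,
        "noise_sigma_beta": sigma,
    }
    return trace, truth


def _velocity_clean(scenario: SyntheticScenario) -> np.ndarray:
    """Noiseless blood velocity: first-order relaxation of the effective
    flow toward each segment's pump setting, scaled by the calibration
    slope."""
    p = scenario.protocol
    slope = scenario.calibration_slope_mm_s_per_mLh
    t = p.time_grid()
    U = np.empty_like(t)
    state = slope * p.Q_T_off_mLh  # start from rest
    U[0] = state
    for t0, t1, on in p.segments():
        target = slope * (p.Q_T_on_mLh if on else p.Q_T_off_mLh)
        lam = scenario.compliance.lambda_on_s if on else scenario.compliance.lambda_off_s
        mask = (t > t0 + 1e-9) & (t <= t1 + 1e-9)
        U[mask] = target + (state - target) * np.exp(-(t[mask] - t0) / lam)
        state = target + (state - target) * np.exp(-(t1 - t0) / lam)
    return U


def gen_velocity_trace(scenario: SyntheticScenario) -> tuple[VelocityTrace, dict]:
    """Noisy micro-PIV-like velocity trace plus ground truth."""
    t = scenario.protocol.time_grid()
    U_clean = _velocity_clean(scenario)
    U = U_clean
    if scenario.noise.velocity_mm_s > 0:
        U = U_clean + scenario.rng(2).normal(
            0.0, scenario.noise.velocity_mm_s, U_clean.shape
        )
    truth = {
        "slope_mm_s_per_mLh": scenario.calibration_slope_mm_s_per_mLh,
        "U_clean": U_clean,
    }
    return VelocityTrace(t, U), truth


def _intensity_clean(scenario: SyntheticScenario) -> np.ndarray:
    """Noiseless intensity: base level + flow brightness + gated
    saturating aggregation component (exact per-sample exponential
    updates)."""
    agg = scenario.aggregation
    p = scenario.protocol
    t = p.time_grid()
    U = _velocity_clean(scenario)
    dt = p.dt_s
    a = np.empty_like(t)
    a[0] = 0.0
    for i in range(1, t.size):
        if U[i - 1] < agg.gate_velocity_mm_s:
            target, tau = agg.amplitude_gray, agg.tau_s
        else:
            target, tau = 0.0, agg.tau_disagg_s
        a[i] = target + (a[i - 1] - target) * np.exp(-dt / tau)
    return agg.i_base_gray + agg.flow_brightness_gray_per_mm_s * U + a


def gen_intensity_trace(
    scenario: SyntheticScenario,
    ts_s: float = 60.0,
) -> tuple[IntensityTrace, dict]:
    """Noisy ROI-intensity trace plus per-period ground-truth
    aggregation indices.

    Ground truth is the aggregation index of the *noiseless* trace
    computed with the same minimum-finding and trapezoid-integration
    rules the analysis applies, so an end-to-end run measures only the
    effect of noise.
    """
    p = scenario.protocol
    t = p.time_grid()
    I_clean = _intensity_clean(scenario)
    clean_trace = IntensityTrace(t, I_clean)
    truth_records = []
    for t0_seg, t1_seg, on in p.segments():
        if on:
            continue
        t0 = find_t0(clean_trace, (t0_seg, t1_seg))
        if t0 + ts_s > t[-1] + 1e-9:
            continue
        res = aggregation_index(clean_trace, t0, ts_s)
        truth_records.append({"off_start_s": t0_seg, "t0_s": t0, "AI": res.AI})
    I = I_clean
    if scenario.noise.intensity_gray > 0:
        I = I_clean + scenario.rng(1).normal(
            0.0, scenario.noise.intensity_gray, I_clean.shape
        )
    truth = {"ts_s": ts_s, "periods": truth_records, "I_clean": I_clean}
    return IntensityTrace(t, I), truth


def gen_coflow_stack(
    scenario: SyntheticScenario,
    n_frames: int = 50,
    height_px: int = 60,
    width_px: int = 200,
    blood_gray: float = 60.0,
    ref_gray: float = 200.0,
    edge_blur_px: float = 0.0,
    noise_gray: float = 0.0,
    pixel_size_um: float = 5.0,
    alpha: np.ndarray | None = None,
) -> tuple[ImageStack, np.ndarray]:
    """Two-phase co-flow channel image stack plus the true alpha(t).

    Each frame is split at column ``round(alpha * width_px)`` with the
    (darker) blood phase on the left; optional single-pixel edge blur
    and additive Gaussian pixel noise.  When ``alpha`` is omitted the
    linear circuit simulation supplies it (first ``n_frames`` samples).
    """
    if width_px < 100:
        raise ValueError("image width must be >= 100 px")
    if alpha is None:
        clean = simulate_linear(
            scenario.protocol, scenario.compliance, scenario.fluids,
            constants=scenario.constants,
        )
        alpha = clean.alpha[:n_frames]
    alpha = np.asarray(alpha, dtype=float)
    n_frames = alpha.size
    frames = np.full((n_frames, height_px, width_px), ref_gray, dtype=float)
    for k, a in enumerate(alpha):
        split = int(round(a * width_px))
        frames[k, :, :split] = blood_gray
    if edge_blur_px > 0:
        frames = gaussian_filter1d(frames, sigma=edge_blur_px, axis=2)
    if noise_gray > 0:
        frames = frames + scenario.rng(3).normal(0.0, noise_gray, frames.shape)
    frames = np.clip(np.round(frames), 0, 255).astype(np.uint8)
    stack = ImageStack(
        frames=frames,
        dt_s=scenario.protocol.dt_s,
        pixel_size_um=pixel_size_um,
        roi=ROI(0, 0, height_px, width_px),
    )
    return stack, alpha
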