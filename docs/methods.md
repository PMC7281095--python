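# Methods

## Physical model

Two immiscible-in-practice laminar streams — a test fluid (blood) and a
reference fluid — share one wide, shallow rectangular channel.  Because
the flow is Stokes flow, the interface settles where the pressure drops
of the two lanes balance, so the blood-filled width fraction α encodes
the flow-weighted viscosity ratio of the streams.  Each stream is
modelled as a discrete fluidic circuit: a flow source (the syringe
pump), lane resistances, and a single lumped compliance C_T on the
test-fluid side that aggregates the elasticity of any air cavity in the
driving syringe, the tubing, and the PDMS device.  Treating the
interface as a virtual wall and compensating the resulting boundary
error with a CFD-fitted quartic correction factor

    C_f(α) = 6.6908 α⁴ − 13.382 α³ + 10.81 α² − 4.1196 α + 1.6206,
    valid on 0.1 < α < 0.9,

gives the nonlinear balance

    C_T R_WT d/dt[C_f/(1−α)] + C_f α/(1−α) = (Q_T/Q_R)(μ_T/μ_R),

with the lane resistance R_WT = 12 μ_T L_cc/(W_lane h³).  Substituting
β = 1/(1−α) and the closure coefficients F₁ = 1.112, F₂ = 1.129
linearizes this to

    λ dβ/dt + β = 1 + (1/F₂)(Q_T/Q_R)(μ_T/μ_R),    λ = F₁F₂ C_T R_WT.

Assumptions worth stating: pump switching is instantaneous (syringe
ramps are not modelled); the two streams do not mix; channel
deformation under pressure is neglected in α = W_B/W (the imaging
module can measure it — it stays below 2% at the flow rates the model
targets); and a single λ per flow direction captures all compliance
effects, with λ_on and λ_off allowed to differ because the upstream
impedance seen by the interface differs between the pumping and
draining configurations.

## Parameters and units

User-facing units are the laboratory's: μm, cP, mL/h, s, gray levels.
All internal computation is SI.  Key defaults:

| parameter | default | why |
|---|---|---|
| W, h | 1000, 100 μm | the channel this chain was designed around |
| L_cc | 5000 μm | nominal co-flow channel length (only enters the C_T→λ map) |
| T, duty, dt | 240 s, 0.5, 0.5 s | the standard on-off protocol and sampling |
| Q_R = Q_T,on | 0.5 mL/h | low enough for aggregation after stop |
| μ_R (PBS) | 1.0 cP at 25 °C | mandatory config entry so it is always visible |
| F₁, F₂ | 1.112, 1.129 | linearization closure constants |
| fit windows | 60 s (off), 20 s (on) | transient lengths after each transition |
| steady sub-window | last 25% of the on segment | 30 s ≫ every λ_off seen without a blood-syringe cavity |
| convergence tol | 1% relative β drift | refuses viscosity from unconverged windows |
| t_s (AI span) | 60 s | integration span of the aggregation index |
| Q_min | 0.1 mL/h | below this the 1/Q_B flow correction is dominated by velocity noise |

The simulator's primary parameterization is (λ_on, λ_off) directly —
compliances of real air cavities are rarely known numerically — with
C_T accepted as an alternative through λ = F₁F₂ C_T R_WT.  Whether
R_WT should use the full width W or the blood-lane width α·W is not
settled; the package defaults to W and exposes `W_lane_um`.

## Numerical choices

- **ODE integration** is adaptive (LSODA, rtol 1e-8, atol 1e-12) with
  dense output interpolated onto the protocol grid.  Tests hold the
  linear simulation to ≤ 1e-6 relative error against the per-segment
  analytic exponential.  Tiny integrator undershoot below the β = 1
  asymptote is floored at 1.
- **The nonlinear form** integrates y = C_f(α)/(1−α), which is monotone
  on the validity interval, inverting y → α by bracketed root finding.
  In strict mode (default) integration aborts with the failure time
  the moment α leaves (0.1, 0.9); clamp mode freezes C_f at its
  boundary value so fully draining off segments can be simulated, at
  the cost of extrapolating beyond the polynomial's fitted range.
- **Exponential fits** use damped least squares with β₀ initialized at
  the window's last sample, β₁ at first − last, λ at window/5, and λ
  bounded to (dt/10, 10·window].  An initial amplitude below 1e-3 is a
  degenerate (no-transient) error, not a fit.
- **Otsu thresholding**: on a cleanly bimodal histogram the
  between-class variance is flat between the modes and the returned
  threshold sits at the plateau's lower edge, occasionally letting
  noise punch single-pixel holes in the blood mask.  The interface
  extractor therefore follows the threshold with a 3×3 opening and a
  3×3 closing on an edge-replicated pad (so regions touching the ROI
  border survive), then measures W_B as the row-mean contiguous
  blood-class run from the inlet wall.  A separability guard
  (between/within class variance ≥ 4) rejects unimodal ROIs.
- **Channel-width measurement** interpolates the wall crossings of the
  cross-channel profile at the midpoint of the two Otsu class means —
  the half-maximum of an ideal edge — which keeps sharp and
  symmetrically blurred walls unbiased to well under a pixel.
- **The aggregation index** integrates the raw trace by the trapezoid
  rule (lowest-order unbiased rule on a uniform grid).  The post-stop
  minimum t₀ is located in two stages: a coarse argmin on a 5 s moving
  average (a global argmin of a noisy trace is an extreme-value
  statistic biased low) refined by a raw argmin within one smoothing
  width (a plain smoothed argmin shifts the asymmetric V-shaped
  minimum toward its shallow side).  The integrand is signed.
- **Periods are summarized** as mean ± sample standard deviation; a
  trailing partial period is dropped with a warning.

## What the synthetic generator emulates — and what it does not

The generator produces protocol-locked traces and image stacks with
the structure the analysis assumes: first-order β transients with
distinct λ_on/λ_off plus Gaussian noise scaled to 1% of the on-step
amplitude; a velocity trace relaxing toward slope·Q with the segment's
time constant; an intensity trace with a small flow-brightness term
and a velocity-gated saturating aggregation component
A(1 − e^(−t/τ)); and two-level channel frames split at
round(α·W_px) with optional edge blur and pixel noise.  Per-diluent
presets (viscosity, λ_off via the Maxwell relation, calibration slope)
mirror the magnitudes typical of washed RBCs at Hct 50% in PBS,
dextran 5 and 10 mg/mL, and plasma.

It does **not** model RBC aggregation mechanistically (the kinetics are
a single gated exponential chosen for structure, not fidelity), PIV
correlation noise, camera shot noise, illumination drift, channel
deformation, or the non-monotone dependence of λ_off on a
reference-syringe air cavity seen experimentally — that effect is
outside the circuit model and the package does not claim to reproduce
it.  Passing tests therefore demonstrate that the chain recovers the
parameters of data obeying its own model assumptions at realistic
noise, not that it is robust to every artifact of real bright-field
microscopy.

## Design decisions on genuinely open points

- G_B is always reported in mPa (μ[Pa·s]/λ[s]); with μ in cP and λ in
  s the number equals μ_cP/λ_s.
- The power-law summary uses the apparent-viscosity convention
  μ(γ̇) = μ₀ γ̇^(n−1), fitted in log-log space.
- α = W_B/W uses the nominal width W by default; the measured
  (deformed) width can be substituted and differs by < 2% below
  2 mL/h.
- λ_off is the representative time constant for G_B; λ_on is used only
  in the varying-flow branch's turn-on analysis.
- The protocol planner recommends T ≥ 2(t_steady + 2 λ_off) and, given
  measured λ_off increments from added air cavities, a half-period
  extension equal to their maximum.  Recommendations are reported,
  never silently applied.
- Defaulted parameters are echoed into the run metadata so a result is
  reproducible from its metadata file alone.

## Problem sizes

The test suite and the acceptance script run entirely on generated
data: traces of 1–3 periods (481–1441 samples at 0.5 s), image stacks
of up to 100 frames at 60×200 px, and Monte-Carlo loops of 20 seeds
per condition — sizes chosen so the whole suite completes in seconds
while leaving every estimator's error well below its tolerance.

## Known limitations

- The C_f polynomial is a package constant; geometries far from the
  1000×100 μm channel need their own correction factor and closure
  coefficients.
- The linearized model deviates from the nonlinear one by up to ~6% in
  steady state mid-range (worst case inside 0.15 ≤ α ≤ 0.85 is ~10% in
  β during large-amplitude transients), which bounds the accuracy of
  viscosities inferred through F₂.
- The compliance→λ map needs L_cc, which is nominal; treat λ values
  derived from C_T as order-of-magnitude unless L_cc is measured.
- Interface extraction assumes the blood stream is the darker phase
  and touches the inlet-side wall of the ROI; multiple lanes or
  detached streams are out of scope.
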