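# coflowrheo

Blood rheometry from co-flowing-stream microfluidics: viscosity,
viscoelastic time constants and elasticity, and red-blood-cell (RBC)
aggregation, extracted from microscope images and time series of a
two-stream microchannel experiment — together with the lumped
fluidic-circuit model needed to interpret the air-compliance effects
that dominate such measurements.

## The measurement

A blood sample and a reference fluid are driven into a shared wide,
shallow channel (W = 1000 μm, h = 100 μm) by two syringe pumps.  The
reference pump runs continuously; the blood pump is switched on and off
periodically (T = 240 s, duty 0.5).  Two observables are recorded every
0.5 s:

- the **interface fraction** α = W_B/W (blood-filled width over channel
  width), obtained by Otsu-thresholding a region of interest spanning
  the channel, and its linearizing transform **β = 1/(1 − α)**;
- the **ROI-averaged image intensity** ⟨I⟩ of the blood stream, which
  rises when RBCs aggregate after the flow stops.

Modelling each stream as a lumped fluidic circuit (resistances R, a
compliance C_T contributed mainly by any air cavity trapped in a
syringe) gives a first-order equation for the interface,

```
λ dβ/dt + β = 1 + (1/F₂)(Q_T/Q_R)(μ_T/μ_R),    λ = F₁F₂ C_T R_WT,
```

with R_WT = 12 μ_T L_cc/(W h³) and closure constants F₁ = 1.112,
F₂ = 1.129.  From this, per pump period:

- **viscosity** μ_B = μ_R (β − 1) F₂ from the converged plateau of the
  on segment (flow-corrected by Q_R/Q_B when the flow varies);
- **time constants** λ_off, λ_on from exponential fits
  β = β₀ + β₁ exp(−t/λ) over 60 s / 20 s windows after each transition;
- **elasticity** G_B = μ_B/λ_off (linear Maxwell model);
- **aggregation index** AI = (1/t_s)∫[⟨I(t)⟩ − ⟨I(t₀)⟩]dt from the
  post-stop intensity minimum t₀ over a span t_s.

An air cavity in the *blood* syringe lengthens λ_off until β never
plateaus and the flow never slows enough for aggregation — the regime
the pipeline detects and refuses to report viscosity in, rather than
returning a biased number.

## Worked example

A fully synthetic experiment (the `synthetic` module stands in for the
microscope and pumps; the generating truth is μ_T = 2.95 cP,
λ_off = 5.9 s, three 240 s periods, 1%-of-amplitude noise):

```python
import coflowrheo as cf

sc = cf.scenario_for_diluent("pbs", seed=1)
beta, truth = cf.gen_beta_trace(sc)
inten, _ = cf.gen_intensity_trace(sc)
summary = cf.analyze_experiment(
    beta, cf.AnalysisConfig(protocol=sc.protocol, mu_R_cP=1.0),
    intensity=inten,
)
print(summary.per_period.round(3))
```

prints

```
 period  mu_B_cP  lambda_off_s  lambda_on_s  G_B_mPa    AI
      0    2.945         5.809        3.157    0.507 6.730
      1    2.943         5.795        3.136    0.508 6.810
      2    2.948         5.862        3.174    0.503 6.938
```

and `summary.summary()` reports the mean ± sample SD over periods:
μ_B = 2.945 ± 0.003 cP, λ_off = 5.822 ± 0.035 s,
G_B = 0.506 ± 0.003 mPa, AI = 6.83 ± 0.11 gray — each within a few
percent of the generating truth.

The same chain is available from a shell:

```
coflow synth    --scenario examples/scenario.yaml --out data/
coflow analyze  --config examples/run.yaml --traces data/ --out results/
coflow simulate --config examples/run.yaml --out sim/
```

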