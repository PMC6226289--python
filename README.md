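# cortexflow

Quantitative analysis of actomyosin cortical flow in *C. elegans*
zygotes — the kind of flow that polarizes the one-cell embryo during
the first minutes of development. Given time-lapse cortical
fluorescence movies (myosin II::GFP) and the corresponding PIV velocity
fields, `cortexflow` computes, per RNAi condition:

- mean anterior-directed flow velocity **v̄x** and chiral
  counter-rotation velocity **v̄c** (posterior minus anterior
  y-velocity),
- the pulsatile flow period **T_osc** from the first peak of the
  temporal autocorrelation of the posterior box velocity,
- myosin **foci size S** (first minimum of the radial spatial intensity
  autocorrelation) and **foci number density ρ** (four-step local-maxima
  detection),
- the cortex's **hydrodynamic length λ** and **chirality index c**, by
  fitting a thin-film active chiral fluid model to the binned
  intensity/velocity profiles,
- a 2-D **minimum curvilinear embedding (MCE)** of the per-condition
  feature vectors (ρ, v̄x, T_osc, λ, c) for cluster discovery,

together with Wilcoxon rank-sum / normal-CDF significance flags against
a negative-control condition. A synthetic-data generator produces
movies, velocity fields, pulsatile series and foci images with known
ground truth, so every stage is testable without real embryo data.

## The model

With active tension `T = α·I` and active torque density `τ = β·I`
proportional to the myosin fluorescence intensity `I(x)` along the
anterior-posterior (AP) axis, force and torque balance in a thin viscous
film with friction reduce to two boundary-value problems

    λ² v_x″ − v_x = (α/γ) ∂x I
    (λ²/2) v_y″ − v_y = (β/γ) ∂x I

where `λ = sqrt(η/γ)` is the hydrodynamic length (cortex viscosity η
over friction γ) and `c = τ/T = β/α` the chirality index. Only λ, α/γ
and β/γ are identifiable from flow profiles. The solver uses
second-order central differences (tridiagonal solve); the fit exploits
linearity in (α, β) and searches λ by a bounded 1-D minimization, with
standard errors from the finite-difference Hessian of the residual.

## A worked example

`examples/active_gel_fit.py` generates one binned profile obeying the
model (λ = 18 µm, c = 0.321, 5 % velocity noise) and fits it back:

```
truth:  lambda = 18.0 um, c = 0.321
fitted: lambda = 16.90 +/- 1.95 um, c = 0.319 +/- 0.014
residual sum of squares: 0.492 over 36 data points
```

The fitted λ agrees with the truth within one standard error; c is
recovered to 1 %. The other scripts in `examples/` demonstrate flow
statistics, period estimation, foci detection, the MCE map and a full
three-condition screen; `examples/full_screen.py` prints the
per-condition report and shows the λ-halved knockdown being flagged
significant against the control while an equal-λ slowed-flow knockdown
is not.

A thin CLI mirrors the library:

```bash
cortexflow simulate --out demo --preset screen --seed 1
cortexflow run-all --config screen.yaml
cortexflow fit --profiles profile.csv
```

## Layout

```
src/cortexflow/     io, geometry, flow, oscillation, foci, activegel,
                    mce, synthetic, pipeline, cli
examples/           one narrative script per capability
tests/              pytest suite incl. oracle-based acceptance tests
scripts/            acceptance.py
docs/methods.md     models, parameters, numerical choices, limitations
```
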