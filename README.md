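# ozotox

In-vitro ozone cytogenotoxicity analysis: a logistic growth model with
time-varying parameters for cultured-cell viability, Replication-Index-driven
simulation of exposed populations, the cytokinesis-block micronucleus (CBMN)
and alkaline comet-assay index calculus, the associated group statistics, and
a calibrated synthetic study generator.

## Who this is for

Toxicologists and modellers analysing controlled-atmosphere exposure
experiments on cell cultures — the motivating study exposed A549 alveolar
adenocarcinoma cells and Hs27 skin fibroblasts to 120 ppb ozone and read out
luminescent viability (RLU), CBMN slide scores, and per-cell comet
measurements. The package turns those three table types into effect sizes,
significance calls, and a mechanistic growth simulation, end to end.

## The model

Population growth follows the logistic ordinary differential equation

```
dN/dt = α(t) (1 − N/k(t)) N,    α(t) = α₀ e^{βt},    k(t) = k₀ e^{−γt}
```

with growth rate α and carrying capacity k. β = γ = 0 recovers the classic
constant-parameter logistic (its closed form is the solver's verification
oracle); β > 0, γ > 0 let the model reproduce the rise-then-fall viability
curves confluent cultures actually show. Parameters are estimated from
control means by bounded nonlinear least squares with the seeding density n₀
fixed. Exposure is simulated by scaling α(t) and γ with the fractional
Replication Index deficit measured in the CBMN assay, piecewise over time
windows.

The assay indices:

- **RI** = [(N₂ + 2·N₃₊)/N]ₜᵣₑₐₜₑ𝒹 ÷ [same]𝒸ₒₙₜᵣₒₗ × 100 — cytostasis,
- **CBPI** = (N₁ + 2N₂ + 3N₃₊)/N ∈ [1, 3] — cell cycles per cell,
- **MN frequency** — micronuclei per 1000 binucleated cells,
- **TM** = %tailDNA × tail length / 100, **OTM** = %tailDNA × centroid
  distance / 100 — comet damage moments,

with Student's pooled t-test (viability, MN) and Mann-Whitney (comet; exact
permutation distribution for combined n ≤ 10) at star thresholds
p < 0.05 / 0.005 / 0.0005.

## Worked example

`examples/` holds one narrative script per capability. Fitting both model
scenarios to a control curve that peaks at 48 h and halves by 72 h
(`examples/01_growth_model.py`):

```
constant-parameter fit:     RSS = 2.9255
time-varying-parameter fit: RSS = 7.69e-26
fitted: alpha0=0.0341 /h  beta=0.0000 /h  k0=119.91  gamma=0.0717 /h
model at 0/24/48/72 h: [1.0, 2.2, 3.6, 1.8]
```

The constant-parameter logistic is monotone and cannot follow the fall — its
residual sum of squares is orders of magnitude larger — while the
time-varying model passes through every mean. Simulating exposure with the
measured RI deficits (11% to 48 h, 6% after; `examples/02_treated_simulation.py`):

```
t=24 h  control=2.200  treated=2.027
t=48 h  control=3.600  treated=3.454
t=72 h  control=1.800  treated=2.514
doubling time: control 20.94 h, treated 23.53 h (+2.59 h)
```

The treated curve sits below the control through 48 h and doubles ~2.6 h
later — replication is slowed — then ends above it at 72 h because the
capacity of the treated culture's environment decays more slowly, the same
crossover the measured viability shows. The full pipeline
(`examples/04_full_pipeline.py`) closes the loop on a synthetic A549 bundle:
the exposure schedule is derived from the CBMN table it just analysed, never
hand-entered.

The command line mirrors the library:

```
ozotox synth --what all --cell-line A549 --seed 0 --out bundle/
ozotox run --viability bundle/viability.csv --cbmn bundle/cbmn.csv \
           --comet bundle/comet.csv --out results/
```

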