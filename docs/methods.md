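# Methods

## Growth model

The population model is the logistic ODE `dN/dt = α(t)(1 − N/k(t))N` with
`α(t) = α₀e^{βt}` and `k(t) = k₀e^{−γt}`. The time dependence encodes two
observations about confluent cultures: the apparent per-capita growth rate
of viable signal can drift upward during the exponential phase (β ≥ 0), and
the capacity of a closed growth environment is consumed as the culture ages
(γ ≥ 0), which is what lets the model produce the rise-then-fall viability
curves a constant-parameter logistic cannot (a monotone function of time).

Integration is scipy's adaptive Runge-Kutta 4(5) at rtol 1e−8 / atol 1e−10,
giving two decades of headroom below the 1e−6 relative agreement required
against the constant-parameter closed form
`N(t) = k₀ / (1 + (k₀/n₀ − 1)e^{−α₀t})`, which serves as the solver oracle
(an independent fixed-step RK4 covers the time-varying case in the tests).

### Fitting

Bounded nonlinear least squares (trust-region reflective) on control
viability means, restarted from 5 jittered initial guesses; best residual
sum of squares wins. n₀ is fixed from the known seeding density (the t=0
observation in normalised units), never fitted. The "constant" scenario
frees (α₀, k₀); "time_varying" frees (α₀, β, k₀, γ).

Default box bounds, chosen to be biologically plausible and fully
config-overridable since viability data alone constrain them weakly:

| parameter | bounds | rationale |
|---|---|---|
| α₀ | [1e−3, 0.2] h⁻¹ | doubling times ~3.5–700 h; A549 literature doubling ≈ 22 h |
| β | [0, 0.1] h⁻¹ | non-negative drift, bounded well below α₀'s scale |
| γ | [0, 0.1] h⁻¹ | capacity can only decay |
| k₀ | [max(obs), 100·max(obs)] | capacity at least the largest observation |

Viability is normalised to the 0 h control mean before fitting (n₀ = 1 in
normalised units) because absolute luminescence is instrument-dependent.

**Degenerate designs.** A 4-time-point design with the 4-parameter scenario
is exactly determined (the t=0 point is consistent by construction), leaving
a manifold of essentially zero-residual fits. When the best fit's RMS
residual falls below ~1e−7 of the RMS data, the fit is refined to the
manifold member with the smallest β, located by profiling β downward with
continuation bisection. Rationale: an exponentially self-accelerating growth
rate is the model's biologically strongest assumption, so among
indistinguishable fits the one assuming the least of it is preferred. The
tie-break never activates when the data identify the parameters, and it
places the fitted control in the rate-limited regime in which the simulated
exposure behaves like the measured one (below control through 48 h, longer
doubling time). The fit requires at least as many observations as free
parameters; a "+1" margin would reject the study's own 4-point design.

### Exposure simulation

A piecewise schedule of fractional reductions f (derived from measured RI
deficits, e.g. 0.11 on [0, 48) h and 0.06 on [48, 72] h) scales both the
instantaneous growth rate α(t) and the capacity decay rate γ by (1 − f)
within each half-open segment; population and capacity are carried
continuously across boundaries (the capacity accumulates its log-decay, so
k has no jumps). The reduction multiplies the whole of α(t) rather than α₀
alone — equivalent on the first segment and unambiguous across segments.
Segment reductions replace one another; they do not compound.

Two consequences worth noting. With all reductions zero the simulation is
the identical code path as the plain solver, so the null-exposure identity
is exact, not approximate. And because a reduction also slows capacity
*decay*, more damage can mean a *higher* population late in the experiment —
the treated curve crosses above the control after its peak. That crossover
is a genuine prediction matching the measured viability (treated above
control at 72 h), so "damage monotonically lowers the curve" holds only in
the γ = 0 case, and that is how the monotonicity property is tested.

Doubling time is the first t with N(t) ≥ 2n₀, bracketed on a 0.25 h grid and
refined by bisection to 0.01 h; a population seeded at capacity correctly
reports "no doubling" rather than a number.

## Assay indices and statistics

RI uses (binucleate + 2×multinucleate)/total with multinucleate = N₃ + N₄,
the same grouping the CBPI formula uses. The Tail Moment is
%tailDNA × tail length / 100; the Olive Tail Moment adopts the standard
definition %tailDNA × head–tail centroid distance / 100 (matching what
comet image-analysis software exports) since the moment needs the centroid
separation as an input column.

Comet group summaries average per-cell values within each replicate slide,
then report mean ± SE across replicates (≥3). Comparisons are two-sided
throughout: Student's pooled-variance t-test for viability and MN data, and
Mann-Whitney for the skewed per-cell comet measurements — exact permutation
enumeration of the rank sum for combined n ≤ 10 (midranks under ties;
two-sided p doubles the smaller tail, capped at 1), the tie- and
continuity-corrected normal approximation above. Stars are a pure strict
threshold function: * p < 0.05, ** p < 0.005, *** p < 0.0005; a p-value
exactly at a boundary earns no star.

MN induction is reported both as the ratio of pooled frequencies and as the
mean of per-replicate ratios, since either convention is defensible and they
differ at small replicate counts.

## Synthetic study generator

The generator emulates the study design — two cell lines, control vs ozone,
three biological replicates in technical triplicate, viability at
0/24/48/72 h, CBMN and comet at 48/72 h, 1000 binucleated cells scored per
CBMN slide, 300 cells per comet slide — with effect sizes calibrated to the
study's results:

- A549 viability: 21.5% treated deficit at 24 h, none at 48 h; 72-vs-48 h
  drop of 50% (control) and 26% (treated). The profile's 72 h treated mean
  derives from the treated drop applied to the 48 h treated mean (a single
  profile cannot simultaneously satisfy "no deficit at 72 h" and the two
  different drops; the drop is what the study quantifies, and the implied
  treated-above-control at 72 h matches the measured pattern).
- RI deficits 11% (48 h) and 6% (72 h) in A549 only, implemented by scaling
  the bi/multinucleate multinomial fractions by (1 − deficit).
- MN fold 2.0 at 48 h (A549) and at 72 h (Hs27), binomial counts on a
  spontaneous baseline of 12.5 MN per 1000 binucleated cells.
- Comet means: tail DNA 8.3 vs 2.88 (A549 48 h), 7.3 vs 3.7 (72 h), 5.9 vs
  3.3 (Hs27 72 h); OTM 4.1 vs 1.3, 4.4 vs 1.8, 2.2 vs 1.38.

Noise models: multiplicative log-normal on RLU with CV 5% (positive-valued,
CV-stable, mean-preserving so group means are unbiased for their targets);
Beta-distributed tail-DNA fractions (concentration 5, right-skewed at low
damage); log-normal lengths (CV 30%) with the centroid-distance mean set so
E[OTM] = E[%tail]·E[distance]/100 hits the OTM target. Values the study does
not print — replicate-level variances, the control nucleation split
(0.30/0.55/0.08/0.07, CBPI 1.85), the MN baseline, the Hs27 48 h comet means
(set equal to control), the control viability shape (1, 2.2, peak 3.6) — are
field-typical choices fixed once and exposed as profile fields.

What the generator does **not** emulate: plate-position and batch effects,
correlated technical replicates, inter-slide scoring drift, the discrete
saturation of heavily damaged comets, or any dose dependence (single
exposure level). Passing tests therefore demonstrate the pipeline's
arithmetic and statistical behaviour under the study's effect sizes and
idealised noise, not robustness to real-world assay artefacts.

## Pipeline

Per cell line: summarise viability (per-time t-tests, percent changes,
72-vs-48 drops) → CBMN indices and MN comparisons → comet summaries and
Mann-Whitney tests → fit the growth model to control means → convert
measured RI deficits (rounded to 3 decimals, clamped to [0, 1]; an RI above
100 clamps to zero with a logged warning) into the exposure schedule →
simulate the treated trajectory. The schedule is a pure function of the
CBMN input. Reports carry a provenance block (seed, config hash, version);
identical config + seed reproduces the report exactly. Missing optional
inputs yield a partial report with the section marked absent (CLI exit
code 3); a missing control series aborts.

## Problem sizes

The acceptance script averages 20 replicate studies for viability, pools
100 for CBMN counts (300 000 binucleated cells per group), and averages 8
for comet means (7 200 cells per group), sizes at which the calibrated
effect sizes dominate sampling noise. The test suite's noisy
parameter-recovery study uses 100 simulated curves at CV 5% on a 13-point
grid; the type-I-error study runs the statistical pipeline on 200 null
studies.

## Known limitations

- The time-varying logistic is descriptive: β and γ absorb confluence and
  medium-exhaustion effects without modelling them mechanistically.
- With 4 time points the growth-model parameters are not identified; only
  the fitted curve and the parsimony-selected representative are meaningful.
- RI-deficit scaling assumes the CBMN-measured replication slowdown maps
  linearly onto both rate parameters; no uptake kinetics or dose-response
  is modelled.
- The exact Mann-Whitney path enumerates up to C(10,5) = 252 assignments;
  beyond combined n = 10 the normal approximation's accuracy is that of its
  tie and continuity corrections.
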