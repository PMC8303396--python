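# Methods

## Model

A cell deciding among a finite fate set `{x_1, …, x_n}` is modelled as a
maximum-entropy decision-maker: its fate distribution maximizes the Shannon
entropy of internal states subject to the expected microenvironmental entropy
it senses, with an extra Poisson term for asymmetric divisions. The resulting
steady state is Boltzmann-like,

    P(x_i) = exp(−β S_i − μ N_i) / Z(β, μ),

with `S_i = S(y|x_i)` the sensed microenvironmental entropy conditioned on
fate i (nats), `N_i` the expected neighbour count, `β` the sensitivity to
microenvironmental order, and `μ ≥ 0` the asymmetric-division intensity.
All logarithms are natural and the Boltzmann constant is 1, so entropies,
divergences and entropy production are all in nats. The state set is discrete
and finite; the continuous-state generalization (an integral partition
function) is deliberately out of scope because every application here lives on
the five-cone set.

For a Gaussian sensed microenvironment, `S_i = ½ ln(2πe σ_i²)` with `σ_i` the
per-fate NND standard deviation, and with `μ = 0` the distribution collapses
to `P_i = σ_i^(−β)/Σ_j σ_j^(−β)`. `β = 2` reproduces minimum-variance sensor
fusion, and `β = 1` the Jeffreys-prior weighting. The receptor–ligand module
grounds the `β = 2` case mechanistically: steady-state complex formation under
fast decay is a weighted combination of ligand signals, the weight variance
`Σ w_i² σ_i²` is minimized exactly by the `σ^−2` weights, and a Poisson
(diffusing) ligand gives receptor occupancy ∝ σ_Y^(−2) — an exact log-log
slope of −2 that the test suite checks to 1e−10.

Identities used as internal cross-checks rather than assumptions:
`S(x) = β⟨S⟩ + μ⟨N⟩ + ln Z` (tested on random models to 1e−10), and the
decomposition `ΔS = ΔS_LEUP + ΔN − ln(Z1/Z2)` across a progenitor/
differentiated model pair.

## β inference

`fit_beta` minimizes `D_KL(P_exp ‖ Q(β)) = Σ_i P_i ln(P_i/Q_i)` — direction
fixed, experimental proportions first — by a grid scan (default step 1e−3 on
[0, 10]) followed by bounded Brent refinement (tolerance 1e−8). The curve is
smooth and, on the avian table, unimodal over the default bounds, so the
grid+refine scheme is an exact argmin to well below the reported precision; a
1e−4 exhaustive grid is kept as a test oracle. Proportions are renormalized on
load only when they sum to within [0.99, 1.01] (rounded published tables);
anything further off is rejected as malformed.

Because the data give no likelihood, the plausibility band around `β̂` is a
level set of the divergence: the connected interval where `D_KL ≤ threshold`,
endpoints by bisection to 1e−6. The threshold is a user parameter (default
0.01); at that default the band on the avian table is ≈ (1.38, 2.14). There is
no canonical threshold convention, so the band is interpretive, not inferential.

## Thermodynamic robustness

The transition from a pluripotent tissue (uniform fate prior over the n
states) to the differentiated one satisfies a Crooks-type bound: the maximal
forward/backward transition-probability ratio is
`exp(⟨β′ΔQ⟩ + ⟨ΔS⟩ − ⟨Δi⟩)`, and robustness (macroscopic irreversibility)
requires the exponent to be strictly positive. Equality is reported as
not-robust. `⟨Δi⟩` (pointwise-mutual-information change) defaults to 0,
appropriate for equilibrium end states, and remains settable.

The heat term combines anaerobic glycolysis (109.4 kJ/mol, the progenitor
pathway) and aerobic respiration (2820 kJ/mol) at 310 K. The dimensionless
convention is deliberate and literal: kJ/mol divided by kelvin with the
dimension dropped (2929.4/310 ≈ 9.450). A unit-consistent per-molecule
bookkeeping (dividing by R·T) is available behind `per_rt=True` and yields a
number ≈ 120× larger; it is clearly flagged as a different convention, and the
per-mole vs per-cell question is left open rather than silently reconciled.

## Entropy-production landscapes

With `σ_d² = V R^A` (hyperuniform differentiated mosaic, A < D) and
`σ_s² = U R^D` (Poisson progenitors), total entropy production is

    f(R) = C0 + C1(β_d − β_s) + ½ ln(V^β_d / U^β_s) + Γ ln R + Δμ̃ R^D,

`C1 = ½ ln(2πe)`, `Γ = (A β_d − D β_s)/2`. `C0` bundles the heat term, −⟨Δi⟩
and −ln(Z1/Z2) as one opaque constant; the reference landscapes fix it at −1
and the package exposes it without interpreting its magnitude. The stationary
point `R_c = (−Γ/(Δμ̃ D))^(1/D)` exists iff `Γ/Δμ̃ < 0`; the second derivative
`−ΓD/R_c²` makes it a minimum for `Γ < 0` and a maximum for `Γ > 0`. `Δμ̃ = 0`
or matching signs return a "none" result rather than an error, since f is then
monotone in R and the scan remains meaningful. Default dimension is D = 2
(planar retina); D = 3 is allowed. Radii carry the same length unit as the
input σ (μm for the avian table); f is treated as dimensionless (nats).

Feasibility scans evaluate f on inclusive rectangular (β_s, β_d[, Δμ̃]) grids,
at a fixed radius or at each point's own R_c, and emit a ternary
classification: `robust` (f > 0 and Γ < 0, an interior minimum above zero),
`positive_no_minimum`, `nonpositive`. CSV rasters are the contract; no
plotting code ships.

## Sensing geometry

The empirical variance model `σ²(R) = M1 R² + M2 R ln R + M3 R` is inverted
for R by bracketed root finding (Brent, default bracket 1e−6–100 μm, 512-point
log-spaced sign-change scan). The coefficients are an external published
table and are accepted only as user configuration — the package never bundles
them as data. When the model crosses the target variance more than once the
smallest radius is returned with a warning. The hyperuniformity exponent uses
the pure-power-law approximation with V fixed to 1: `A = 2 ln σ / ln R̄`
(undefined at R̄ = 1); a general (V, A) fit over a radius range is out of
scope. On the published (σ, R̄) pairs for the five chicken cones this
reproduces the published exponents within 0.005 — the residual comes from the
three-decimal rounding of the printed inputs. The published comparison of
sensing radii to the measured cone size (2.59 ± 1.05 μm via a ±3σ rule) needs
the underlying size distribution, which is not printed anywhere we ingest; it
is noted here and not reproduced.

## Synthetic mosaics

The generator emulates the two spatial regimes the theory assumes:

* **jittered_lattice** — per-type triangular lattices (spacing from that
  type's intensity `λ_i = λ p_i`, unit cell `a² √3/2`), independent Gaussian
  jitter, wrapped toroidally into the window so counts and stationarity are
  preserved. Small jitter gives sub-Poissonian (hyperuniform-like) count
  fluctuations; the tests assert a fitted exponent < 1.9 at jitter ≤ 0.1
  spacing.
* **poisson** — homogeneous Poisson with multinomial type labels (the
  progenitor assumption; count-variance exponent ≈ D = 2).
* **hard_core** — sequential inhibition with per-type exclusion radius and a
  bounded-attempt failure mode.

NND statistics use the nearest *same-type* Euclidean neighbour. The source
mosaic data were summarized via Delaunay triangulation instead; the difference
is real but immaterial here because the exponent and fit tests use internally
consistent statistics. Likewise the "local neighbourhood" over which σ should
be taken is ambiguous in the source; we compute the global per-type SD.
Edge handling is minus-sampling: reference points within one provisional NND
mean of the border are dropped (neighbours may lie in the buffer), mimicking
bounded retinal patches; a toroidal mode exists for exact lattice tests.
Count-variance estimation places disk centres at least R from every border
(rejection-free) and regresses log variance on log radius; at least three
radii are required. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`), never global state; identical seeds give
byte-identical CSV output.

The recovery harness draws multinomial fate samples of size n from
`Q(β_true)` and refits β per replicate. Study conditions used by the tests:
n = 1e5 cells × 100 replicates (mean β̂ within 0.05 of truth), the noiseless
limit (within 1e−3), and an end-to-end run where a jittered-lattice mosaic of
~1.2 cells/μm² in a 100×100 μm window (≥ 1e4 points) is generated from LEUP
proportions and β is refit from the *realized* NND SDs (recovered within
0.2). The end-to-end tolerance is loose on purpose: nearest-of-six-neighbour
statistics shrink the realized SD relative to the configured jitter by a
factor that is only approximately common across types, and the fit is
invariant only under a common rescaling of the σ vector.

What passing these tests does and does not show: the generator reproduces the
*statistical* structure the analysis assumes (proportions, NND spreads,
count-variance scaling), not the biological correlations of a real mosaic —
no cross-type interactions, no rods, no developmental gradients, no imaging
noise. Agreement on synthetic data validates the estimators and the fit
machinery, not the biological model itself; that case rests on the published
summary statistics in the packaged fixture.

## Numerical choices

* Log-sum-exp shifting everywhere an exponential family is normalized
  (β scans reach ±50 without overflow).
* `0 ln 0 ≡ 0` in entropies and divergences; infinite KL (p > 0 where q = 0)
  is an error, not a large number.
* Probability vectors are validated to sum to 1 within 1e−12 after
  normalization; published tables are renormalized within a ±1% tolerance.
* ODE relaxation uses LSODA at rtol 1e−10 with horizon 20/d (linear
  relaxation has converged to ~2e−9 relative by then); the contract is the
  1e−6 agreement with the closed form, not the solver choice.
* Reports serialize with sorted keys and full float precision; rounding is
  presentation-only.

## Limitations

* μ is fixed to 0 in the fitted application; no multi-parameter fits and no
  uncertainty quantification beyond the divergence-threshold band.
* Only the averaged end-state fluctuation bound is computed — no
  trajectory-level sampling of the underlying path relation, and no
  estimation of ⟨Δi⟩ from data.
* The double cone's σ < 1 μm makes its ln σ² negative; nothing in the theory
  requires special treatment, and all types are handled identically.
* The three-coefficient variance model is inverted, never re-derived from
  point patterns; the count-variance exponent estimator in the mosaic module
  is the independent route to A.
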