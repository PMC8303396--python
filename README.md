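# leup

Entropy-based analysis of photoreceptor mosaics: cone-fate prediction from
spatial fluctuations, thermodynamic robustness of differentiation, and the
sensing-radius limits that keep tissue development irreversible.

## The problem and the model

The avian retina contains five cone photoreceptor types (green, red, blue,
violet, and the double cone) arranged as interleaved, highly regular spatial
mosaics. This package treats each differentiating cell as a maximum-entropy
decision-maker: its fate distribution maximizes internal-state entropy subject
to the entropy of the microenvironment it senses (the least microenvironmental
uncertainty principle, LEUP), giving

```
P(x_i) ∝ exp(−β·S(y|x_i) − μ·N(y|x_i)) ,
```

where `S(y|x_i)` is the sensed microenvironmental entropy conditioned on fate
`x_i`, `N(y|x_i)` a neighbour count weighted by the asymmetric-division
intensity `μ`, and `β` the sensing sensitivity. For a Gaussian
microenvironment with per-fate nearest-neighbour-distance (NND) spread `σ_i`
and `μ = 0` this collapses to

```
P(x_i) = σ_i^(−β) / Σ_j σ_j^(−β) ,
```

the minimum-variance estimator of sensor fusion when `β = 2`. Three analyses
build on this:

* **β inference** — fit `β` to observed cone proportions by minimizing the
  Kullback–Leibler divergence `D(P_exp ‖ Q(β))`;
* **thermodynamic robustness** — a fluctuation-theorem bound
  `⟨β′ΔQ⟩ + ⟨ΔS⟩ > ⟨Δi⟩` on the differentiation transition, with the heat term
  from glycolysis + respiration;
* **entropy-production landscapes** — with `σ_d² = V·R^A` (hyperuniform cones)
  and `σ_s² = U·R^D` (Poisson progenitors), total entropy production
  `f(R) = C0 + C1(β_d−β_s) + ½ln(V^β_d/U^β_s) + Γ·lnR + Δμ̃·R^D` has a
  critical sensing radius `R_c = (−Γ/(Δμ̃·D))^(1/D)`, `Γ = (Aβ_d − Dβ_s)/2`,
  whose character (minimum/maximum) follows the sign of `Γ`.

A synthetic-mosaic module generates seeded point patterns (jittered
triangular lattices, Poisson, hard-core) and estimators (per-type NND
statistics, count-variance exponents, β-recovery harness) so the whole
pipeline is testable without external data.

## Worked example

```python
>>> from leup import load_fixture, fit_beta, gaussian_leup_weights, internal_entropy
>>> stats = load_fixture("kram2010_chicken")   # published chicken cone table
>>> fit = fit_beta(stats)
>>> round(fit.beta_hat, 3), round(fit.dkl_min, 4)
(1.756, 0.0041)
>>> gaussian_leup_weights(stats.nnd_sd, 2.0).round(3)
array([0.238, 0.155, 0.124, 0.071, 0.413])
>>> round(internal_entropy(stats.proportions), 3)
1.474
```

The fitted sensitivity `β̂ ≈ 1.76` lies close to 2, i.e. the observed cone
mosaic is consistent with near-optimal (minimum-variance) microenvironmental
sensing; the divergence at the optimum (≈ 0.004 nats) says the one-parameter
weights reproduce the five observed cone proportions almost exactly. The
Shannon entropy of the differentiated proportions (1.474 nats) sits just below
the uniform five-state value ln 5 ≈ 1.609, so differentiation costs only
≈ 0.136 nats of fate entropy — vastly outweighed by the metabolic heat term
≈ 9.45, which is why the differentiated mosaic is thermodynamically robust.

The same pipeline is scriptable from the shell:

```
leup run --out report.json                 # full pipeline on the fixture
leup fit-beta --stats my_counts.csv        # user-supplied table, same schema
leup entropy-production --params p.json --scan 0.1:5:0.01 --out raster.csv
leup simulate --config gen.json --out pattern.csv && leup nnd --pattern pattern.csv --out stats.csv
```

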