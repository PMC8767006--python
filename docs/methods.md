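# Methods

## Scope and assumptions

The package assesses chronic oral exposure to eight metals through
consumption of dried earthworm material. The exposure model is the standard
intake equation with a single deterministic transfer ratio `T = 0.10` from
raw material to decoction; absorption is implicitly 100%, which is
conservative. Only the ingestion route is modelled — no dermal or inhalation
pathways, no age or sex stratification, and no relative-bioavailability
adjustment. Within a Monte Carlo iteration, each metal's concentration and
the annual consumption are drawn independently; nothing in the available
summary data identifies a dependence structure, and summing HQ (and CRi)
across metals drawn independently is the conventional additive treatment.

## Exposure parameters

| parameter | symbol | default | units | note |
|---|---|---|---|---|
| body weight | BW | 63 | kg | Chinese adult average |
| transfer ratio | T | 0.10 | – | material → decoction |
| exposure duration | E_D | 20 (scenarios 20/40) | y | carcinogenic scenarios |
| lifetime | – | 70 | y | carcinogenic averaging horizon |
| averaging time | T_A | E_D·365 or 70·365 | d | endpoint-dependent |
| iterations | – | 10,000 | – | Monte Carlo driver |
| HQ/HI threshold | – | 1 | – | acceptability |
| CRi/CRT threshold | – | 1×10⁻⁴ | – | acceptability |

Reference doses (mg/(kg·d)): Cr 1.5, Mn 0.14, Co 0.0003, Ni 0.02, Cu 0.04,
Zn 0.3, Cd 0.001, As 0.0003, Pb 0.0085, Al 0.0004, Hg 0.0003. Oral slope
factors ((kg·d)/mg): Cr 0.5, Cd 0.38, Pb 0.0085, As 1.5.

Non-carcinogenic intake is independent of `E_D` because `E_D/T_A = 1/365`
cancels; carcinogenic intake is proportional to `E_D`. Percentiles are
computed by linear interpolation of order statistics (numpy's default,
"type 7"); this matters for P97.5 at 10,000 iterations and is therefore fixed
here as the package convention.

## Censoring rule

Values below the limit of detection are replaced by 0; values between the
LOD and LOQ by LOQ/2. The rule is idempotent and is applied at read time, so
a validated table only ever contains 0, LOQ/2, or detected raw values. The
surveyed material had every metal quantified in every sample, so this is a
rare path in practice, but it is fully implemented and tested. No default
LOD/LOQ values ship with the package — they are assay properties and must be
supplied whenever censored tokens appear in an input file.

## Synthetic data generators

The raw survey tables (98 concentration batches; ~29,000 consumption
records) are not public. The generators reproduce their *published summary
statistics*, which makes the pipeline testable but limits what passing tests
show about real data: marginal means, three quantiles, and limit-exceedance
fractions are honoured; any cross-metal correlation, within-individual
dependence between consumption amount and frequency, spatial (origin)
structure, and batch effects of the real data are not represented.

**Consumption.** Each marginal (annual consumption g/y, exposure frequency
d/y, daily intake g/d) is a shifted (3-parameter) lognormal pinned exactly to
its published P5/P50/P95 anchors — (60, 168, 1050), (7, 14, 98), (6, 9, 18).
Because the 5% and 95% normal deviates are symmetric, the shift γ solves
(q50−γ)² = (q5−γ)(q95−γ), a linear equation; then μ = ln(q50−γ) and
σ = (ln(q95−γ)−μ)/z₀.₉₅. For annual consumption this gives γ ≈ 44.93,
μ ≈ 4.813, σ ≈ 1.277 and a closed-form mean of 322.98 g/y, 1.3% above the
published 318.9 g/y — supporting the family choice. Anchors requiring a
negative shift (log-convex triples) are rejected as a calibration failure.
The three marginals are drawn independently; the AC ≈ EF×DI identity is
checked only as a warning (the published marginals themselves are only
approximately consistent: 318.9 vs 30.4×10.3 ≈ 313). Frequency draws are
clipped at 365 d/y (~0.5% of the calibrated model's mass lies above it).

**Concentrations.** Per-metal families follow what fit the real samples:
Weibull (As), inverse Gaussian (Mn), lognormal (the rest). Each model is
calibrated to two constraints — published mean, and published exceedance of
the 30 mg/kg pharmacopoeia limit — to 1e-6 (relative on the mean, absolute on
the tail probability). Numerical choices:

- *Lognormal*: eliminating μ gives σ²/2 − zσ − ln(m/L) = 0 with
  z = Φ⁻¹(1−p). When the mean is below the limit both roots are admissible
  and satisfy both constraints; the smaller σ is chosen (lighter tail, more
  plausible for fully-detected survey data). For Cr (mean 31.85 above the
  limit) only the larger root is positive: μ ≈ 3.082, σ ≈ 0.870.
- *Weibull*: with the mean fixed, the scale is λ(k) = m/Γ(1+1/k) and the
  tail constraint (L/λ(k))^k = −ln p is solved in k. The constraint is
  non-monotone (two roots for As: k ≈ 0.21 and k ≈ 1.58); the larger shape is
  chosen (finite mode, increasing hazard). Roots are bracketed by a
  sign-change scan over a geometric grid k ∈ [0.05, 100] and polished with
  Brent's method.
- *Inverse Gaussian*: parameterised by (mean, shape λ); the mean is fixed and
  λ is found by Brent's method on [10⁻³, 10⁶] using the closed-form CDF
  (Mn: λ ≈ 110.6).
- *Zero published exceedance* (Cd) leaves one constraint for two parameters;
  the second is closed by a default coefficient of variation of 0.5, a
  mid-range dispersion for trace-element surveys.
- *Infeasible pairs*: the published Hg pair (mean 1.58, exceedance 1.02%)
  is jointly unreachable by any lognormal — with the mean fixed the tail
  probability is maximised at σ = √(2·ln(L/m)), giving at most 0.76%.
  Calibration raises by default; the default model table uses the
  nearest-feasible model (mean exact, σ at the maximiser) for Hg so the
  8-metal pipeline remains runnable. Hg contributes negligibly to total risk
  either way.

Metals are independent across and within samples (no copula), matching how
the simulation treats them downstream.

## Distribution fitting and selection

Candidate families: lognormal, Weibull, inverse Gaussian, gamma, normal —
the three observed in the survey plus two controls, since selection is only
meaningful against alternatives. MLEs are closed-form where they exist
(normal; lognormal via log-moments; inverse Gaussian via μ̂ = x̄,
λ̂ = n/Σ(1/xᵢ − 1/x̄)) and numerical otherwise (Weibull, gamma, location
pinned at 0, method-of-moments starts via scipy). Selection minimises AIC =
2k − 2ℓ; ties break by fewest parameters, then a fixed family order, so
selection is fully deterministic. Zeros arising from the censoring rule are
excluded from positive-support fits with a logged count; a shifted-fit
alternative is deliberately not implemented because fully-censored data are
outside the intended use. Goodness-of-fit hypothesis tests and censored
likelihoods are out of scope.

At the survey's own scale (n = 98) AIC selection is noisy — close families
(lognormal vs inverse Gaussian) can swap, as the worked example shows for Cu.
Parameter-recovery and selection-consistency tests therefore run at
n = 10,000, where the criterion is reliable.

## Monte Carlo driver

Per iteration: one concentration per metal from its model/fit (negative
draws — possible only for the normal control — are rejected and redrawn),
one annual-consumption value per user class (random: resampled with
replacement from records or drawn from the model; average: fixed at the
mean; high: fixed at the empirical/model P95), then the four risk equations.
All randomness flows through one `numpy.random.Generator` seeded from the
configuration, so identical configurations are bit-identical. The
deterministic comparison pairs mean concentration with mean consumption
(average user) and P95 concentration with P95 consumption (high user) — the
conservative reading of a "high" point assessment.

## Safe-frequency inversion

`EDI_max = Risk_l·SF/CSF_As` caps the intake at the acceptable lifetime
cancer risk (1×10⁻⁴) scaled by the share of the dietary risk budget
allocated to traditional-medicine use (SF = 13.3%), using arsenic — the
highest-risk metal — as the driver. Solving the intake equation for the
number of dosing days per year at the maximum daily intake (10 g/d) and a
concentration at the limit `C_l` gives
`EF = EDI_max·T_A·BW·1000/(C_l·RDI·T·E_D)` with `T_A = 70·365` d.

SF is applied exactly once. A literal reading of the two equations in
sequence would divide by SF again in the EF step, cancelling it — the safe
frequency would then not depend on the budget share at all, and the
defaults would give EF ≈ 179 d/y rather than the ~24 d/y a 13.3% budget
share implies. The once-applied composition is the default; the cancelling
variant is available behind `FrequencyPolicy(sf_in_frequency=True)` for
comparison rather than silently discarded. `E_D = 20` y (the shorter of the
two carcinogenic scenarios) is the default for the EF curve. EF is reported
both as a real number and rounded *up* to whole days, since the
recommendation is an upper bound ("fewer than N days"). The inversion is
exact: feeding EF back through the intake and cancer-risk equations returns
`Risk_l·SF` to machine precision, and EF·C_l·E_D is constant across limits
and durations.

## Known limitations

- Calibration targets are summary statistics, not raw data: tail behaviour
  beyond the constrained quantities is a modelling assumption, so the
  survey's exact Monte Carlo exceedance percentages (which depended on the
  raw 98-sample fits) are not reproduced, only their order of magnitude.
- Independence across metals likely understates the variance of HI and CRT
  if metal burdens are correlated across batches (plausible for
  soil-derived contamination).
- The consumption marginals ignore within-person dependence; the "random
  user" class is therefore marginally, not jointly, realistic.
- The default problem sizes (10,000 iterations; 50,000–100,000 calibration
  check draws) keep every computation in the seconds range while holding
  Monte Carlo error well inside the calibration tolerances.
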