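# Methods

## Model structure and assumptions

The model is a discrete-time cohort state-transition (Markov) model with
three states: stable (progression-free, on treatment), progressive, and
dead. The entire cohort starts stable. Transitions allowed per cycle:
stable→stable, stable→progressive, stable→dead, progressive→progressive,
progressive→dead; death is absorbing and recovery to the stable state is
excluded. The cycle length is 28 days; the default horizon is five years,
implemented as ⌈5·365.25/28⌉ = 65 cycles. Costs and QALYs are discounted at
an annual rate r (default 3%) with per-cycle factor
(1+r)^(−c·28/365.25). Accrual uses start-of-cycle occupancy; a half-cycle
correction (average of start- and end-of-cycle occupancy) is available
behind a flag but off by default, since the timing convention of the
original spreadsheet-style implementations of such models is rarely stated.
Death accrues zero cost and zero utility.

## Survival extrapolation

Inputs are digitized KM coordinates — survival proportions on a time grid —
without at-risk counts, so maximum likelihood is unavailable. Each of the
five standard families is fitted by bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective) on the survival
proportions:

| family       | parameters        | S(t) |
|--------------|-------------------|------|
| exponential  | rate λ            | exp(−λt) |
| Weibull      | shape k, scale λ  | exp(−(t/λ)^k) |
| Gompertz     | shape η, rate b   | exp(−(b/η)(e^{ηt}−1)) |
| log-logistic | shape β, scale α  | 1/(1+(t/α)^β) |
| log-normal   | meanlog μ, sdlog σ| 1 − Φ((ln t − μ)/σ) |

Multi-start initial values are data-driven (scale anchored at the first
grid time where survival falls to 0.5; shapes in {0.5, 1, 2}; several small
positive Gompertz shapes), because the Gompertz and log-logistic objectives
are initialization-sensitive; the best final SSR is kept. Ranking uses the
least-squares information criteria AIC = n·ln(SSR/n) + 2k and
BIC = n·ln(SSR/n) + k·ln(n). Selection takes the lowest AIC; AIC differences
below 0.01 are treated as ties and broken by BIC, then SSR, then fewer
parameters, then the declared family order — the full ranking table is
always emitted so a reviewer can overrule the automatic choice on clinical
plausibility grounds. A curve with no decline is flagged non-informative
rather than fitted. PFS and OS are fitted independently per arm (four
selections per analysis).

## Transition-probability construction

On the cycle grid t_c = c·28/30.4375 months the construction enforces two
targets simultaneously: stable occupancy equals S_PFS(t_c) and the alive
fraction equals S_OS(t_c). Where the fitted curves cross, S_OS is clipped up
to S_PFS and the event is counted and logged. Per cycle, with
stable = S_PFS(t_c), prog = S_OS(t_c) − S_PFS(t_c):

- total stable exits are fixed by the PFS decline,
  E = 1 − S_PFS(t_{c+1})/S_PFS(t_c);
- required deaths are fixed by the OS decline,
  D = S_OS(t_c) − S_OS(t_{c+1});
- deaths are drawn from the progressive compartment first
  (p_pd = (D − stable·p_sd)/prog, capped at 1); any overflow — always the
  case at cycle 0, when the progressive compartment is still empty but the
  published OS curve already declines — is assigned to the stable state,
  displacing progression (p_sp = E − p_sd), so both targets remain exact;
- background mortality (from the life table at the attained age, converted
  by 1 − (1−q_annual)^{28/365.25}) is a floor on the stable-state death
  probability. It is not added in the progressive state, where the
  OS-matching death probability already embeds all-cause mortality.

This allocation is the unique one that reproduces both curves exactly under
the no-recovery structure (verified to ~1e-16 in the tests for bg = 0);
published OS curves mix pre- and post-progression deaths, so any
reconstruction of the split is a modelling choice, and this one
deliberately errs toward the reading that some mortality occurs in the
progression-free state. The survivor-fraction conversion utility uses
P = 1 − y^{1/t}; the commonly printed variant with a negated exponent is
negative for y < 1 and is treated as a typographical artifact.

All emitted probabilities are clipped to [0,1]; clip events are counted on
the schedule object and logged at INFO.

## Economic inputs

All euro amounts are per 28-day cycle and accrue in the stable state only
(treatment-emergent costing; treatment continues until progression):

- MIRV drug cost 18,231.66 € (the tabulated value; 18,281.66 € also
  circulates for the same quantity and can be configured instead). An
  optional dose-based calculator (6 mg/kg adjusted ideal body weight at
  30.39 €/mg, every 3 weeks re-expressed per 28 days, AIBW = IBW +
  0.4·(actual − IBW), female Devine IBW) is provided because the protocol's
  exact adjustment formula is unpublished.
- Standard-arm drug cost: `blended` mode returns the single average
  1,276.83 € per treatment interval (the base case); `weighted` mode
  returns the proportion-weighted sum of the per-drug monthly costs
  (0.41·519.77 + 0.23·299.43 + 0.36·457.63 ≈ 446.72 €). The two disagree by
  roughly a factor of 2.9 in the published inputs; both are exposed and no
  reconciliation is guessed.
- Monitoring 96.96 €; imaging 141.12 € through 1-based cycle 9 and 70.56 €
  from cycle 10 (the switch boundary is stated ambiguously in the source
  material; the "cycles 1 to 9" reading is implemented).
- Premedication 82.06 € (MIRV) / 27.93 € (standard).
- Adverse events (grade ≥3 anemia and neutropenia): per-episode inpatient
  cost × cumulative incidence ÷ 60, treating the 60-month amortization
  window as 60 four-week cycles (a ≈2% month/cycle approximation inherited
  from the framing of the inputs). The per-episode costs are not printed
  directly and are inferred from the intervention-arm per-cycle cells
  (e.g., anemia: 0.50 €·60/0.0088 ≈ 3,409 €); applying them to the
  comparator incidences reproduces the comparator cells within 1%. An event
  enters the cost stack only if the 2×2 Pearson chi-square (no continuity
  correction, counts = incidence × arm sizes 227/226) gives p < 0.05;
  zero-margin tables are excluded with a warning.
- Utilities 0.61 (stable) / 0.50 (progressive), shared across arms in the
  base case; per-arm overrides implement the bivariate scenarios, and
  per-cycle linear decline scenarios (0.005 "slow", 0.01 "fast") subtract
  decline·cycle, floored at 0.

## Sensitivity analyses

**Deterministic.** One-way variation with the conventional ranges: drug
prices ±50%, adverse-event, monitoring (including imaging) and
premedication costs ±25%, utilities ±20% (each state's utility one at a
time, shared across arms). The tornado table reports ICUR at the low and
high value and the absolute bar width, sorted descending. Scenario reruns
cover horizons {5, 10} years and discount rates {0%, 3%, 5%}. The price
threshold solves ICUR(price) = WTP by bracketing (`brentq`) — incremental
cost is affine in the per-cycle price and ΔQALY is unaffected, so the root
is unique; the round-trip |ICUR(p*) − WTP|/WTP stays below 1e-4.

**Probabilistic.** First-order Monte Carlo, default 10,000 iterations.
Costs are gamma (shape = mean²/sd², scale = sd²/mean), utilities beta
(moment-matched, sd = CI half-width / 1.96), and two lognormal(meanlog 0,
sdlog 0.10) multipliers — one for mortality-type (stable→dead,
progressive→dead) and one for progression-type (stable→progressive)
probabilities — are each drawn once per iteration and shared across cycles
and arms, with products re-clipped to [0,1]. The published analysis states
these distribution families but not their spreads; by default the DSA
ranges are re-expressed as sds by treating ±range as a 95% interval
(sd = multiplier·mean/1.96). Summaries: mean of per-iteration ICURs with a
normal-approximation 95% CI of that mean (matching the "average ICUR with
CI" framing), plus the ratio of means (the economically standard summary);
iterations with ΔQALY ≤ 0 are excluded from the ratio mean but counted and
retained in the CEAC, which is the fraction of iterations with
WTP·ΔQALY − ΔCost > 0 per WTP on the grid {151,833; 155,499; 310,998;
466,497} € (taken verbatim from the source's threshold grid). Per-parameter
RNG substreams are derived from the master seed and a stable hash of the
parameter name, so adding a parameter does not reshuffle the others and
identical seeds give byte-identical outputs.

## Synthetic data

The generator emulates what a plot digitizer extracts from published
two-arm KM figures: survival proportions on a monthly grid over 24 months
(matching the trial's follow-up and a typical digitization density),
perturbed by additive Gaussian noise (default sd 0.02, a plausible
digitization error on a proportion scale) and projected back to a valid
curve by least-squares isotonic (non-increasing) regression with clipping
to [0,1] and S(0) = 1. Ground truth defaults: intervention arm log-logistic
(shape 1.8), comparator arm Weibull (shape 1.3) — the family each arm's
published fit selected — with PFS medians 5.62 vs 3.98 months and OS
medians 16.46 vs 12.75 months; sharing one shape per arm guarantees
OS ≥ PFS by construction, and specs violating that ordering are rejected.
The life-table generator produces a geometric (Gompertz-like) annual death
risk, default 1.2% at age 64 growing 9.5% per year of age, approximating a
contemporary German female period table.

What the synthetic world does **not** emulate: censoring marks and at-risk
tables, step-function KM geometry, correlated digitization error, informative
dropout, or the real trial's covariate structure. A green pipeline test
therefore establishes the correctness of the machinery — fitting,
construction, accrual, inversion, sampling — on curves of realistic shape
and noise, not agreement with the published trial's numbers, which depend on
fitted parameters available only in unpublished supplementary material.

One consequence measured honestly: at noise sd 0.02 on 25 monthly points
the log-logistic and log-normal families are near-indistinguishable, so the
generating log-logistic is top-ranked in only ~72% of 200 seeded replicates
(the log-normal takes the rest; the Weibull comparator curve is recovered
in ~88%). The multi-start fits reach the global optimum in the losing
replicates — the limit is statistical identifiability, not optimization.

## Numerical conventions and degenerate inputs

Months per cycle 28/30.4375; years per cycle 28/365.25; cycle c covers
[t_c, t_{c+1}) with occupancy read at cycle start. Currency is kept at full
float precision internally and rounded to cents only for display; CSVs are
dot-decimal UTF-8 without currency symbols. Dominance configurations
(cheaper-and-better or costlier-and-worse) are flagged instead of reporting
a signed ratio; ΔQALY = 0 leaves the ICUR undefined rather than infinite.
Beta moment-matching rejects infeasible variances (sd² ≥ mean(1−mean));
gamma and lognormal samplers require strictly positive spreads. Flat KM
curves (no observed events) are flagged non-informative rather than fitted.

## Known limitations

- Post-progression treatment costs, dose reductions and discontinuations
  are not modelled (no usable source data), which biases costs in the
  intervention's favor by construction.
- The OS-matching death split between states is identifiable only up to the
  allocation rule described above.
- Tornado orderings and PSA probabilities computed on synthetic fixtures
  are properties of the synthetic world, not estimates of the published
  model's values.
- No half-cycle correction by default; switching it on changes all accruals
  by roughly half a cycle's worth of each quantity.
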