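# Methods

## Model

For dose combination `(i, j)` of a two-drug grid (drug A level `i = 1..I`,
drug B level `j = 1..J`) the DLT count at each combination is binomial,

    m_ij ~ Binomial(n_ij, π_ij),
    π_ij = 1 − C(1 − p_i^exp(α), 1 − q_j^exp(β); γ),

with `C` a one-parameter copula, `p_i`, `q_j` prespecified strictly
increasing skeleton probabilities in (0, 1), and γ the interaction
parameter.  Writing the marginal exponents as `exp(α)`, `exp(β)` keeps the
intercepts unconstrained so standard-normal priors apply directly.
Patients' outcomes are independent, so the likelihood is the product of
binomial pmfs over the grid; untreated combinations contribute nothing.

Seven families are implemented (module `families`).  Their formulas at
transformed margins `x = p^α`, `y = q^β`:

| family  | π(x, y; γ) | original γ space |
|---------|------------|------------------|
| Clayton | 1 − ((1−x)^−γ + (1−y)^−γ − 1)^(−1/γ) | [−1, ∞) \ {0} |
| GUMM    | 1 − (1−x)(1−y)(1 + xy·tanh(γ/2)) | (−∞, ∞) |
| GUMH    | 1 − exp(−[(−log(1−x))^γ + (−log(1−y))^γ]^(1/γ)) | [1, ∞) |
| Frank   | 1 + (1/γ)·log[1 + (e^(−γ(1−x))−1)(e^(−γ(1−y))−1)/(e^(−γ)−1)] | (−∞, ∞) \ {0} |
| AMH     | 1 − (1−x)(1−y)/(1 − γxy) | [−1, 1) |
| Joe     | (x^γ + y^γ − x^γ y^γ)^(1/γ) | [1, ∞) |
| FGM     | 1 − (1−x)(1−y)(1 + γxy) | [−1, 1) |

The GUMM interaction factor is `(e^γ − 1)/(e^γ + 1) = tanh(γ/2)`; this
rendering is confirmed by reproducing the attainable range [0.26, 0.29] at
margins 0.15.  All seven families satisfy the boundary properties π(0,0)=0,
π(x,0)=x, π(0,y)=y, π(·)=1 when either margin is 1, and each has a unique
independence point γ₀ at which π = 1 − (1−x)(1−y) (γ→0 as an analytic
limit for Clayton and Frank, whose γ = 0 is a removable singularity; the
evaluator routes γ = 0 to that limit so samplers never trip over it, while
`gamma_space` still reports the exclusion).

The Clayton interval is stated as closed at −1 although the family was
introduced with γ > 0 and is sometimes quoted as −1 < γ < ∞; we expose the
closed bound, at which the surface attains the upper Fréchet–Hoeffding
bound exactly (via the standard `max(S, 0)` clamp of the Clayton
generator, needed for γ ∈ (−1, 0)).

## Extended parameter spaces

A proper copula requires both `0 ≤ F ≤ 1` and a nonnegative density
`∂²F/∂p∂q ≥ 0`.  Dropping only the density condition, while keeping
`0 ≤ π ≤ 1` for all margins, enlarges the γ space of three families:

| family | original | extended | π range at margins 0.15 |
|--------|----------|----------|--------------------------|
| AMH    | [−1, 1)  | (−∞, 1)  | [0.26, 0.29] → [0.26, 1.00] |
| GUMH   | [1, ∞)   | (0, ∞)   | [0.15, 0.28] → [0.15, 1.00] |
| Joe    | [1, ∞)   | (0, ∞)   | [0.15, 0.28] → [0.15, 1.00] |

The function is then no longer a joint distribution function — the AMH
copula density `c(u,v) = (1 − γ + 2γC(u,v))/D(u,v)²`,
`D = 1 − γ(1−u)(1−v)`, goes negative somewhere on (0,1)² whenever γ < −1
(`amh_density_sign` demonstrates this on a grid) — but as a regression
function inside a binomial likelihood it is perfectly proper, and it
retains the boundary properties above.  The payoff is the release of the
upper Fréchet–Hoeffding bound: with γ → −∞ the extended AMH surface
approaches 1 at any margins, so extreme synergistic toxicity becomes
expressible.  FGM is *not* extended because its admissible range depends
on the margins (γ ≥ −(xy)^−1), and monotonicity of the extended surfaces
in dose is checked empirically rather than assumed.

`pi_range` computes attainable-range endpoints by a dense scan over the
space (linear grid on [−20, 20], log-spaced tails to 10^8 standing in for
the ±∞ limits, open finite endpoints approached to 10^−9); every family is
monotone in γ so the scan is exact to well below the 2-decimal reporting
precision, and a 10^5-point brute-force scan agrees to 10^−3 (tested).

## Priors, posterior, sampler

Priors (module `model`): α, β intercepts ~ N(0, 1); γ by design —

- AMH original: Uniform(−1, 1)
- GUMH / Joe original: N(1, 3²) truncated to [1, ∞)
- AMH extended: N(0, 1500²) truncated to (−∞, 1)
- GUMH / Joe extended: Gamma(shape 0.5, rate 0.5)

The very flat SD = 1500 prior deliberately allows strong synergy; the
prior SD is configurable (`design_config(..., gamma_prior_sd=...)`) for
sensitivity sweeps over {50, 100, 500, 1000, 1500, 3000}.  Truncated
normals are normal densities renormalised on the stated interval;
Gamma(0.5, 0.5) uses the rate parameterisation (mean 1, matching the
original-space independence anchor γ = 1 of GUMH/Joe).

Sampling is adaptive random-walk Metropolis on the unconstrained triple
`(α, β, link(γ))`, with the link chosen by the space: identity on ℝ,
`log(γ − lo)` / `log(hi − γ)` on half-lines, logit on bounded intervals.
All three components are updated jointly with a diagonal Gaussian
proposal; the proposal scale (initial 0.5) is multiplied by
`exp(rate − 0.3)` every 50 iterations during burn-in (targeting ~30%
acceptance, observed 25–35%) and frozen afterwards.  Chains start at the
prior medians (α = β = 0, γ at its prior median) with randomised restarts
if the posterior is non-finite there.  The default effort is 10 000 kept
draws after 1000 burn-in iterations with thinning interval 3 — read as
30 000 post-burn-in iterations keeping every third — in one chain.  Two
reduced profiles ship: `desk` (2000 kept, 500 burn-in, thin 1), used by
the simulation benchmarks, and `smoke` (400/200/1) for unit tests.

The sampler's inner loop is a numba-compiled kernel fed pre-generated
normal increments and log-uniforms from a seeded numpy Generator, so runs
are bit-reproducible, independent of numba internals, and fast enough
(~1 ms per desk-profile fit on one core) that a full 30-patient simulated
trial costs ~20 ms.  The numpy-side log-posterior is the reference
implementation and the kernel is unit-tested to agree with it up to an
additive constant.  Numerical guards: all family formulas are evaluated in
log space where overflow is possible (|γ| up to ~10⁴ occurs under the
SD = 1500 prior), exponents are clipped at ±700, and π is clipped to
[10⁻¹⁵, 1 − 10⁻¹⁵] inside the kernel likelihood only.

Correctness is checked against an independent oracle: on a 1×1 grid,
`Pr(π < φ | D)` from the sampler matches brute-force 3-D quadrature of the
posterior within 0.02 for several data configurations.

## Trial design

Defaults: target φ = 0.3, N = 30 patients in cohorts of 3, escalation /
de-escalation thresholds c_e = 0.75, c_d = 0.55 (c_e + c_d > 1 enforced),
MTDC interval half-width δ = 0.1, no early stopping.

**Stage 1 (rule-based).**  The first cohort is treated at (1, 1).  Cohorts
then walk the diagonal dose groups (constant `i + j`), drawing uniformly
without replacement inside a group and advancing when it is exhausted;
were the top group exhausted without any DLT the cells would be re-treated
round-robin (unreachable at N = 30 on the packaged grids).  Stage 1 ends
with the first cohort containing at least one DLT.  Outcomes are generated
per cohort, so a per-patient DLT trigger would be indistinguishable at
this granularity and no separate option is provided.

**Stage 2 (model-based).**  After each cohort the posterior is refreshed.
At current combination (i, j):

- if `Pr(π_ij < φ | D) > c_e`, move to the member of
  {(i+1,j), (i,j+1), (i+1,j−1), (i−1,j+1)} ∩ grid whose *posterior-mean*
  toxicity is closest to φ (retain (I, J) if already at the top);
- if `Pr(π_ij > φ | D) > c_d`, move analogously within
  {(i−1,j), (i,j−1), (i+1,j−1), (i−1,j+1)} (retain (1, 1) at the bottom);
- otherwise retain the current combination.

The "closest to φ" estimator is the posterior mean of π (the design family
is silent on the estimator; the mean is standard in this class).  Ties
break toward the lower total dose `i + j`, then the lower drug-A level —
which is already unique, so no random tie-break is needed.  With
c_e + c_d > 1 the two conditions are provably exclusive; this is also
asserted at runtime.

**MTDC determination.**  At the end of the trial the MTDC is the
combination *actually used to treat patients* maximising
`Pr(π_ij ∈ [φ−δ, φ+δ] | D)`, same tie-break.

**Stopping (optional).**  When enabled, the trial stops for safety before
any model-based cohort if `Pr(π_11 > φ | D) > λ`; λ defaults to 0.95 ("a
threshold close to 1") and is configurable.  The benchmark simulations run
with stopping disabled.

## Scenario library and simulator

Eighteen benchmark matrices of true DLT probabilities ship with the
package (3×3, 4×4, 4×2 and 5×3 grids), each with its designated MTDC set
(all true MTDC probabilities lie in [0.28, 0.34]); combinations with true
π ≥ 0.35 are overdose combinations.  A scenario is *extremely synergistic*
when at some interior MTDC (i, j)

    Pr(i,j) > [Pr(i−1,j) − Pr(i−1,j−1)] + [Pr(i,j−1) − Pr(i−1,j−1)] + Pr(i−1,j−1),

i.e. the joint toxicity exceeds the additive marginal increments.  Edge
MTDCs (i = 1 or j = 1) skip the test because the reference cell is
undefined.  The strict rule flags scenarios 4–8, 14–16 — the labelled
extreme set — and additionally scenario 11 (0.28 > 0.20 at its (2, 2)
MTDC); scenario objects carry both the strict classification and the
conventional label, and reporting uses the label.

Skeletons are assigned by grid dimension: (0.1, 0.3) for 2 levels,
(0.1, 0.2, 0.3) for 3, (0.075, 0.15, 0.225, 0.3) for 4,
(0.06, 0.12, 0.18, 0.24, 0.30) for 5 — identical for both drugs.

The simulator draws each cohort's DLT count as
Binomial(3, true π at the allocated cell).  Per-trial seeds are spawned
from a master `SeedSequence`, so batches are reproducible and
order-independent.  Operating characteristics aggregate over all simulated
trials; early-stopped trials count as "no selection" in the selection
percentages (the selection distribution then sums below 1) while the
accuracy index renormalises over selecting trials only — a convention
choice that is moot in the benchmark runs, which never stop.

What the generator does *not* emulate: patient-level heterogeneity,
late-onset or graded toxicities, accrual timing, and attribution of DLTs
to a single agent — all trials are exchangeable binomial draws from a
static truth.  Passing benchmarks therefore demonstrate correctness of the
decision algorithm and estimator under the stated sampling model, not
robustness to those real-data features.

## Benchmark problem sizes

The packaged benchmark reproduction runs 250 simulated trials per scenario
with the `desk` MCMC profile (2000 kept / 500 burn-in / thin 1).  At that
size the Monte-Carlo standard error of a per-scenario selection percentage
is ≈ 2–3 points and of an 18-scenario average ≈ 0.7 points, comfortably
inside the comparison tolerances (±6 points for a single scenario, ±4 for
averages); the corresponding suite runtime is a few minutes on one core.
Observed values (seeds as in the tests): AMH-O / AMH-E / GUMH-E average
correct-MTDC selection 33.6 / 42.2 / 37.4% against published 34 / 44 / 41,
AMH-E average overdose selection 27.6% against 28, and AMH-E on scenario
S02 80.4% against 84.

## Known limitations

- Single-chain sampling with acceptance-rate diagnostics only; no R-hat or
  effective-sample-size machinery (draws export to CSV for external
  tools).
- The extended-space posterior of γ under the SD = 1500 prior is strongly
  prior-influenced (posterior means far from 0 even without synergy);
  this is intrinsic to the flat-prior strategy, and marginal-probability
  estimation suffers accordingly — the design targets *dose selection*,
  not parameter interpretation.
- Monotonicity of extended-space surfaces in dose is an empirical
  observation on the packaged grids, not a theorem.
- The FGM margin-dependent extension and d > 2 drug combinations are out
  of scope.
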