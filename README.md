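# copulafind

Copula-type dose-toxicity models and Bayesian dose-finding designs for
two-drug phase I combination trials.

## The problem

Phase I oncology trials of two combined agents must find the **maximum
tolerated dose combination (MTDC)** — the dose pair whose probability of a
dose-limiting toxicity (DLT) is closest to a target φ (here 0.3).
Copula-type models express the joint DLT probability of combination
`(i, j)` as

```
π_ij = 1 − C(1 − p_i^exp(α), 1 − q_j^exp(β); γ)
```

where `C` is a one-parameter bivariate copula, `p_i`, `q_j` are working
("skeleton") toxicity probabilities of each drug alone, and γ captures the
drug–drug toxicity interaction.  These models are attractive because they
behave correctly when one drug contributes no toxicity, but a *proper*
copula is pinned by the Fréchet–Hoeffding bounds

```
max(p_i^α, q_j^β)  ≤  π_ij  ≤  min(p_i^α + q_j^β, 1)
```

so when a combination is **extremely synergistic** — far more toxic than
its margins suggest — the model cannot reach the truth and the design
mis-targets doses.

`copulafind` implements both the classical (original-space) models and
their **extended-parameter-space** variants: for the Ali-Mikhail-Haq (AMH),
Gumbel-Hougaard (GUMH) and Joe families the admissible range of γ can be
enlarged (to `(−∞, 1)`, `(0, ∞)` and `(0, ∞)` respectively) by dropping the
density-nonnegativity requirement while keeping `0 ≤ π ≤ 1`.  The extension
releases the upper Fréchet–Hoeffding bound (π can go to 1 at any margins),
which markedly improves MTDC identification under synergistic toxicity.

The package covers:

- **`families`** — closed-form surfaces for Clayton, Gumbel-Murtaugh,
  Gumbel-Hougaard, Frank, AMH, Joe and Farlie-Gumbel-Morgenstern copulas;
  γ-spaces, Fréchet–Hoeffding bounds, attainable π ranges, AMH density
  sign diagnostics.
- **`model`** — statsmodels-style `CombinationToxicityModel` /
  `CombinationToxicityResults`: binomial likelihood over the dose grid,
  standard-normal priors on the marginal intercepts, the published γ
  priors, adaptive random-walk Metropolis sampling, posterior summaries.
- **`design`** — the two-stage escalation algorithm (rule-based diagonal
  walk, then posterior-guided moves with thresholds c_e = 0.75,
  c_d = 0.55), early stopping, and MTDC determination by the maximal
  posterior probability of `π ∈ [φ−δ, φ+δ]`.
- **`scenarios`** — 18 packaged benchmark true-toxicity matrices with MTDC
  labels, overdose sets (true π ≥ 0.35) and an extreme-synergy classifier.
- **`simulate` / `metrics`** — a Monte-Carlo engine producing the six
  operating characteristics (correct-MTDC %, overdose-selection %,
  accuracy index, observed-toxicity %, patient-allocation %).
- **`cli`** — a `copulafind` command with `ranges`, `scenarios`,
  `simulate` and `summarize` subcommands.

## Worked example

```python
import numpy as np
import copulafind as cf

# attainable joint-toxicity ranges at margins p^a = q^b = 0.15
for variant in ("original", "extended"):
    lo, hi = cf.pi_range(cf.gamma_space("AMH", variant), 0.15, 0.15)
    print(f"AMH {variant:9s} range: [{lo:.2f}, {hi:.2f}]")

# fit the extended AMH model to a small trial snapshot
config = cf.design_config("AMH-E", (3, 3))
n = np.array([[3, 3, 0], [3, 0, 0], [0, 0, 0]])   # patients per (i, j)
m = np.array([[0, 1, 0], [2, 0, 0], [0, 0, 0]])   # DLTs per (i, j)
model = cf.CombinationToxicityModel(cf.TrialData(n, m), config.spec,
                                    config.skeleton, config.prior)
res = model.fit(cf.mcmc_profile("desk"), seed=3)
print(np.round(res.summaries(phi=0.3).mean_pi, 3))

# operating characteristics of AMH-E on benchmark scenario S02
s2 = cf.get_scenario("S02")
oc = cf.run_operating_characteristics(
    s2, cf.design_config("AMH-E", s2.shape, profile="desk"),
    n_sims=250, master_seed=1)
print(f"MTDC {oc.pct_mtdc_selected:.1f}%  OC {oc.pct_oc_selected:.1f}%  "
      f"AI {oc.accuracy_index:.1f}")
```

prints

```
AMH original  range: [0.26, 0.29]
AMH extended  range: [0.26, 1.00]
[[0.251 0.413 0.549]
 [0.451 0.628 0.74 ]
 [0.616 0.762 0.841]]
MTDC 80.4%  OC 15.2%  AI 83.4
```

The first two lines show the Fréchet–Hoeffding release: at margins 0.15 the
original AMH surface cannot exceed 0.29, the extended one reaches 1.  The
matrix is the posterior-mean toxicity surface after 9 patients (3 DLTs at
the lower-left combinations pull the whole surface up).  The last line is
the scenario-S02 benchmark: about 80% of 250 simulated 30-patient trials
select a true MTDC, roughly 15% select an overdose combination, and the
accuracy index (max 100) is ~83.

Equivalent from the shell:

```bash
copulafind ranges --all
copulafind simulate --design AMH-E --scenario S02 --n-sims 250 \
    --seed 1 --profile desk --out results/
```

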