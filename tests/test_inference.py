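"""Likelihood, priors, posterior sampling and summaries."""

import math

import numpy as np
import pytest
from scipy import stats

import copulafind as cf
from copulafind import _mcmc
from copulafind.model import _forward_t


def one_cell_skeleton(p=0.5):
    return cf.MarginalSkeleton(np.array([p]), np.array([p]))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def test_single_cell_binomial_loglike():
    # Clayton at gamma=-1 gives pi = x + y exactly; choose exponents so
    # that 0.5**alpha = 0.15, making pi = 0.30.
    spec = cf.gamma_space("Clayton")
    alpha = math.log(0.15) / math.log(0.5)
    params = cf.ModelParams(math.log(alpha), math.log(alpha), -1.0)
    data = cf.TrialData(np.array([[3]]), np.array([[1]]))
    ll = cf.log_likelihood(spec, params, data, one_cell_skeleton())
    assert ll == pytest.approx(math.log(0.441), abs=1e-9)  # C(3,1)*0.3*0.7^2


def test_loglike_matches_scipy_binomial_oracle():
    spec = cf.gamma_space("AMH")
    sk = cf.default_skeleton((3, 3))
    rng = np.random.default_rng(5)
    n = rng.integers(0, 7, size=(3, 3))
    m = np.array([rng.integers(0, k + 1) for k in n.ravel()]).reshape(3, 3)
    data = cf.TrialData(n, m)
    params = cf.ModelParams(0.3, -0.2, 0.5)
    model = cf.CombinationToxicityModel(data, spec, sk)
    pi = model.pi_surface(params)
    expect = stats.binom.logpmf(m, n, pi).sum()
    assert model.loglike(params) == pytest.approx(expect, abs=1e-9)


def test_loglike_empty_grid_and_untreated_cells():
    spec = cf.gamma_space("AMH")
    sk = cf.default_skeleton((3, 3))
    params = cf.ModelParams(0.0, 0.0, 0.0)
    empty = cf.TrialData.empty((3, 3))
    assert cf.log_likelihood(spec, params, empty, sk) == 0.0
    # adding untreated cells does not change the likelihood
    small = cf.TrialData(np.array([[3]]), np.array([[1]]))
    sk1 = cf.MarginalSkeleton(np.array([0.1]), np.array([0.1]))
    big_n = np.zeros((3, 3), dtype=int)
    big_m = np.zeros((3, 3), dtype=int)
    big_n[0, 0], big_m[0, 0] = 3, 1
    sk3 = cf.MarginalSkeleton(np.array([0.1, 0.2, 0.3]), np.array([0.1, 0.2, 0.3]))
    assert cf.log_likelihood(spec, params, small, sk1) == pytest.approx(
        cf.log_likelihood(spec, params, cf.TrialData(big_n, big_m), sk3)
    )


def test_loglike_invariant_to_cell_permutation():
    spec = cf.gamma_space("AMH")
    sk = cf.default_skeleton((3, 3))
    params = cf.ModelParams(0.1, 0.2, -0.4)
    n = np.array([[3, 0, 0], [6, 3, 0], [0, 0, 3]])
    m = np.array([[1, 0, 0], [2, 0, 0], [0, 0, 2]])
    base = cf.log_likelihood(spec, params, cf.TrialData(n, m), sk)
    # transposing data AND skeleton relabels the grid cells
    swapped = cf.log_likelihood(
        spec,
        cf.ModelParams(params.b, params.a, params.gamma),
        cf.TrialData(n.T, m.T),
        sk,
    )
    assert base == pytest.approx(swapped)


def test_trial_data_validation():
    with pytest.raises(ValueError):
        cf.TrialData(np.array([[1]]), np.array([[2]]))
    with pytest.raises(ValueError):
        cf.TrialData(np.array([[-1]]), np.array([[0]]))


# ---------------------------------------------------------------------------
# priors and posterior density
# ---------------------------------------------------------------------------


def test_published_default_priors():
    assert cf.default_gamma_prior(cf.gamma_space("AMH")) == cf.UniformInteractionPrior(-1, 1)
    p = cf.default_gamma_prior(cf.gamma_space("GUMH"))
    assert p == cf.TruncatedNormalInteractionPrior(1.0, 3.0, lo=1.0)
    p = cf.default_gamma_prior(cf.gamma_space("AMH", "extended"))
    assert p == cf.TruncatedNormalInteractionPrior(0.0, 1500.0, hi=1.0)
    assert cf.default_gamma_prior(cf.gamma_space("Joe", "extended")) == cf.GammaInteractionPrior(0.5, 0.5)


def test_prior_support_must_fit_space():
    with pytest.raises(ValueError):
        cf.PriorSpec(cf.UniformInteractionPrior(-2, 1)).validate_against(
            cf.gamma_space("AMH")
        )


def test_logpost_outside_support_is_minus_inf():
    spec = cf.gamma_space("AMH")
    sk = cf.default_skeleton((3, 3))
    model = cf.CombinationToxicityModel(cf.TrialData.empty((3, 3)), spec, sk)
    assert model.logpost(cf.ModelParams(0, 0, 1.5)) == -math.inf
    assert math.isfinite(model.logpost(cf.ModelParams(0, 0, 0.2)))


def test_zero_data_logpost_equals_log_prior():
    spec = cf.gamma_space("AMH")
    sk = cf.default_skeleton((3, 3))
    model = cf.CombinationToxicityModel(cf.TrialData.empty((3, 3)), spec, sk)
    params = cf.ModelParams(0.3, -0.2, 0.1)
    assert model.logpost(params) == pytest.approx(model.logprior(params))


def test_kernel_logpost_matches_reference_up_to_constant():
    """numba kernel == numpy log-posterior + gamma-link Jacobian + const."""
    for label in ["AMH-O", "AMH-E", "GUMH-E", "Joe-O"]:
        config = cf.design_config(label, (3, 3))
        n = np.array([[3, 3, 0], [3, 0, 0], [0, 0, 0]])
        m = np.array([[0, 1, 0], [2, 0, 0], [0, 0, 0]])
        model = cf.CombinationToxicityModel(
            cf.TrialData(n, m), config.spec, config.skeleton, config.prior
        )
        fam, link, prior_code, pp1, pp2, logp, logq, nc, mc = model._kernel_args()
        lo, hi = config.spec.gamma_lo, config.spec.gamma_hi
        rng = np.random.default_rng(0)
        diffs = []
        while len(diffs) < 30:
            a, b = rng.normal(size=2)
            # stay clear of the space edges where pi saturates at 1 and the
            # kernel's numerical clipping legitimately departs from -inf
            g = rng.uniform(max(lo, -50) + 0.05, min(hi, 50) - 0.05)
            if not config.spec.contains(g, allow_excluded=True):
                continue
            t = _forward_t(g, link, lo, hi)
            k = _mcmc._logpost(a, b, t, fam, link, lo, hi, prior_code, pp1, pp2,
                               logp, logq, nc, mc)
            _, lj, _ = _mcmc._gamma_from_t(t, link, lo, hi)
            ref = model.logpost(cf.ModelParams(a, b, g))
            diffs.append(k - lj - ref)
        assert np.ptp(diffs) < 1e-8, label


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def test_sampler_deterministic_under_seed(desk):
    spec = cf.gamma_space("AMH", "extended")
    sk = cf.default_skeleton((3, 3))
    n = np.zeros((3, 3), dtype=int)
    m = np.zeros((3, 3), dtype=int)
    n[0, 0], m[0, 0] = 6, 2
    model = cf.CombinationToxicityModel(cf.TrialData(n, m), spec, sk)
    r1 = model.fit(desk, seed=42)
    r2 = model.fit(desk, seed=42)
    assert np.array_equal(r1.draws, r2.draws)
    r3 = model.fit(desk, seed=43)
    assert not np.array_equal(r1.draws, r3.draws)


def test_zero_data_posterior_recovers_prior():
    """With no data the gamma margin must match its Uniform(-1,1) prior."""
    spec = cf.gamma_space("AMH")
    sk = cf.default_skeleton((3, 3))
    model = cf.CombinationToxicityModel(cf.TrialData.empty((3, 3)), spec, sk)
    res = model.fit(cf.McmcSettings(n_keep=4000, burn_in=500, thin=2), seed=11)
    g = res.draws[:, 2]
    # batch-means MC standard error (accounts for autocorrelation)
    bm = g[: 40 * (len(g) // 40)].reshape(40, -1).mean(axis=1)
    se = bm.std(ddof=1) / math.sqrt(len(bm))
    assert abs(g.mean() - 0.0) < 3 * se + 0.02
    a = res.draws[:, 0]
    assert abs(a.mean()) < 0.15 and abs(a.std() - 1.0) < 0.15


def test_dlts_raise_posterior_toxicity(desk):
    spec = cf.gamma_space("AMH")
    sk = cf.default_skeleton((3, 3))
    empty = cf.CombinationToxicityModel(cf.TrialData.empty((3, 3)), spec, sk)
    n = np.zeros((3, 3), dtype=int)
    m = np.zeros((3, 3), dtype=int)
    n[0, 0], m[0, 0] = 3, 3
    toxic = cf.CombinationToxicityModel(cf.TrialData(n, m), spec, sk)
    base = empty.fit(desk, seed=1).summaries().mean_pi[0, 0]
    bumped = toxic.fit(desk, seed=1).summaries().mean_pi[0, 0]
    assert bumped > base


def test_parameter_recovery_with_large_counts(desk):
    """AMH-E truth, 200 patients per cell: mean surface within 0.05."""
    spec = cf.gamma_space("AMH", "extended")
    sk = cf.default_skeleton((3, 3))
    truth = cf.ModelParams(0.0, 0.0, -20.0)
    P, Q = np.meshgrid(sk.p, sk.q, indexing="ij")
    pi_true = cf.joint_tox_prob(spec, truth, P, Q)
    rng = np.random.default_rng(3)
    n = np.full((3, 3), 200)
    m = rng.binomial(n, pi_true)
    model = cf.CombinationToxicityModel(cf.TrialData(n, m), spec, sk)
    res = model.fit(desk, seed=4)
    assert np.max(np.abs(res.summaries().mean_pi - pi_true)) < 0.05


def test_summaries_from_given_surface_draws():
    spec = cf.gamma_space("AMH")
    sk = cf.MarginalSkeleton(np.array([0.2]), np.array([0.2]))
    model = cf.CombinationToxicityModel(cf.TrialData.empty((1, 1)), spec, sk)
    res = cf.CombinationToxicityResults(model, np.zeros((3, 3)), 0.3,
                                        cf.McmcSettings())
    res._pi_draws = np.array([0.25, 0.35, 0.50]).reshape(3, 1, 1)
    s = res.summaries(phi=0.3, delta=0.1)
    assert s.pr_interval[0, 0] == pytest.approx(2 / 3)
    assert s.pr_below[0, 0] == pytest.approx(1 / 3)
    assert s.pr_above[0, 0] == pytest.approx(2 / 3)
    assert s.mean_pi[0, 0] == pytest.approx(np.mean([0.25, 0.35, 0.50]))
    assert np.all(s.pr_below + s.pr_above <= 1 + 1e-12)


def test_results_summary_and_export(tmp_path, desk):
    config = cf.design_config("AMH-O", (3, 3))
    n = np.zeros((3, 3), dtype=int)
    m = np.zeros((3, 3), dtype=int)
    n[0, 0], m[0, 0] = 3, 1
    model = cf.CombinationToxicityModel(cf.TrialData(n, m), config.spec,
                                        config.skeleton, config.prior)
    res = model.fit(cf.mcmc_profile("smoke"), seed=0)
    text = res.summary()
    assert "AMH" in text and "gamma" in text
    out = tmp_path / "draws.csv"
    res.to_csv(out)
    import pandas as pd

    back = pd.read_csv(out)
    assert list(back.columns) == ["a", "b", "gamma"]
    assert len(back) == res.draws.shape[0]


def test_mcmc_settings_validation_and_profiles():
    with pytest.raises(ValueError):
        cf.McmcSettings(n_keep=0)
    assert cf.mcmc_profile("full") == cf.McmcSettings()
    assert cf.mcmc_profile("desk").n_keep == 2000
    with pytest.raises(ValueError):
        cf.mcmc_profile("bogus")
    # thinning convention: burn_in + n_keep * thin total iterations
    assert cf.McmcSettings().n_iter == 1000 + 10000 * 3
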