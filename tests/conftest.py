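import numpy as np
import pytest

import copulafind as cf


@pytest.fixture(scope="session")
def scenarios():
    return cf.load_scenarios()


@pytest.fixture(scope="session")
def all_specs():
    """Every family/space pair that exists."""
    out = []
    for fam in cf.CopulaFamily:
        out.append(cf.gamma_space(fam, "original"))
        try:
            out.append(cf.gamma_space(fam, "extended"))
        except cf.UnsupportedExtensionError:
            pass
    return out


def gamma_samples(spec, n=9):
    """Admissible gamma values spanning the space (incl. near-endpoints)."""
    lo = max(spec.gamma_lo, -1e4)
    hi = min(spec.gamma_hi, 1e4)
    vals = list(np.linspace(lo, hi, n))
    vals += [lo + 1e-6, hi - 1e-6]
    return [g for g in vals if spec.contains(g, allow_excluded=True)]


@pytest.fixture(scope="session")
def flat_scenario():
    """Uniform low-toxicity 3x3 scenario (no cell near the target)."""
    return cf.ToxicityScenario(
        name="flat", probs=np.full((3, 3), 0.1), mtdc_set=frozenset()
    )


@pytest.fixture(scope="session")
def zero_tox_scenario():
    """All true probabilities zero: no DLT can ever occur."""
    return cf.ToxicityScenario(
        name="zero", probs=np.zeros((3, 3)), mtdc_set=frozenset()
    )


@pytest.fixture(scope="session")
def certain_tox_scenario():
    """All true probabilities one: every patient has a DLT."""
    return cf.ToxicityScenario(
        name="one", probs=np.ones((3, 3)), mtdc_set=frozenset()
    )


@pytest.fixture(scope="session")
def smoke():
    return cf.mcmc_profile("smoke")


@pytest.fixture(scope="session")
def desk():
    return cf.mcmc_profile("desk")
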