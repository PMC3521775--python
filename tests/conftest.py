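import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

import flamexp as fx


@pytest.fixture(scope="session")
def tiny_sim():
    """Tiny simulated dataset + matching spec, shared across tests."""
    return fx.make_fixture("tiny", seed=3)


@pytest.fixture()
def toy_spec():
    """Four-occasion single-cell toy: detection only at the age-3 occasion."""
    return fx.ModelSpec(K=2, n_occasions=4, a_pool=3, p_occasions=(3,))


def random_toy(rng, T=None, K=None):
    """Random small spec + natural parameter values for oracle checks."""
    T = T or int(rng.integers(4, 7))
    K = K or int(rng.integers(2, 4))
    cold = int(rng.integers(0, T - 1)) if rng.random() < 0.5 else None
    spec = fx.ModelSpec(K=K, n_occasions=T, a_pool=T - 1, cold_spell_step=cold)
    values = {}
    for cell in spec.cell_names():
        values[cell] = float(rng.uniform(0.05, 0.95))
    return spec, values


def enumeration_loglik(spec, values, history):
    """Independent oracle: sum over all latent state paths.

    States are (experience, breeding) pairs plus None for dead, with step
    probabilities written out from first principles (survive, then breed
    with the destination-season rate, then emit), without using the
    package's matrix builders.
    """
    K = spec.K
    T = spec.n_occasions
    c = history.cohort_index

    def phi(age, t, e):
        cls = "first" if age == 0 else "adult"
        regime = "cold" if t == spec.cold_spell_step else "normal"
        base = values[f"phi[{cls},{regime}]"]
        if spec.experience_on_survival == "additive" and cls == "adult" and e > 0:
            from scipy.special import expit, logit
            base = float(expit(logit(base) + values[f"phi_exp[{e}]"]))
        return base

    def beta(age, e):
        if age < spec.a_min:
            return 0.0
        a = min(age, spec.a_pool_eff)
        return values.get(f"beta[{a},{e}]", 0.0)

    def pdet(t):
        return values.get(f"p[{t}]", 0.0)

    total = 0.0

    def walk(t, e, breeding, prob):
        nonlocal total
        if prob == 0.0:
            return
        if t == T - 1:
            total += prob
            return
        age_t = t - c
        code = history.events[t + 1 - c]
        ph = phi(age_t, t, e)
        # death branch: the rest of the history must be all zeros
        if code == 0 and all(x == 0 for x in history.events[t + 1 - c:]):
            total += prob * (1.0 - ph)
        e2 = min(e + 1, K - 1) if breeding else e
        b = beta(t + 1 - c, e2)
        p = pdet(t + 1)
        # breed next season
        emit = p if code == 1 else 1.0 - p
        walk(t + 1, e2, True, prob * ph * b * emit)
        # skip next season (emits 0 surely)
        if code == 0:
            walk(t + 1, e2, False, prob * ph * (1.0 - b))

    walk(c, 0, False, 1.0)
    return np.log(total) if total > 0 else -np.inf
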