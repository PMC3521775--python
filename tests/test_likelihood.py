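import numpy as np
import pytest

import flamexp as fx
from flamexp.design import ParameterMap, materialize_rates
from flamexp.likelihood import FastLikelihood, batch_loglik, split_cohorts

from conftest import enumeration_loglik, random_toy

VALS = {"phi[first,normal]": 0.9, "phi[adult,normal]": 1.0,
        "beta[3,0]": 0.5, "p[3]": 0.8}


class TestMaterializeRates:
    def test_first_year_fixed_value(self, toy_spec):
        spec = toy_spec.with_fixed(**{"phi[first,normal]": 0.763})
        pm = ParameterMap(spec)
        vals = pm.natural_values(np.zeros(pm.n_free))
        r = materialize_rates(spec, vals, 0, 0)
        assert r.phi == pytest.approx(0.763)

    def test_beta_zero_below_maturity(self, toy_spec):
        r = materialize_rates(toy_spec, VALS, 0, 1)  # destination age 2
        assert np.all(r.beta_by_level == 0.0)

    def test_logit_zero_is_half(self, toy_spec):
        pm = ParameterMap(toy_spec)
        vals = pm.natural_values(np.zeros(pm.n_free))
        assert vals["beta[3,0]"] == pytest.approx(0.5)


class TestHistoryLoglik:
    def test_single_detection_probability(self, toy_spec):
        h = fx.EncounterHistory("x", 0, (0, 0, 0, 1))
        # survive the risky first year (0.9), then breed (0.5) and be seen (0.8)
        assert np.exp(fx.history_loglik(toy_spec, VALS, h)) == pytest.approx(0.36)

    def test_no_detection_probability(self, toy_spec):
        h = fx.EncounterHistory("x", 0, (0, 0, 0, 0))
        # die (0.1) + survive and skip (0.9*0.5) + survive, breed, missed (0.9*0.5*0.2)
        assert np.exp(fx.history_loglik(toy_spec, VALS, h)) == pytest.approx(0.64)

    def test_impossible_history(self, toy_spec):
        sure = {"phi[first,normal]": 1.0, "phi[adult,normal]": 1.0,
                "beta[3,0]": 1.0, "p[3]": 1.0}
        h = fx.EncounterHistory("x", 0, (0, 0, 0, 0))
        assert fx.history_loglik(toy_spec, sure, h) == -np.inf

    def test_matches_enumeration_on_random_toys(self):
        rng = np.random.default_rng(2024)
        for _ in range(40):
            spec, values = random_toy(rng)
            T = spec.n_occasions
            ev = [0] * T
            for t in range(3, T):
                ev[t] = int(rng.random() < 0.4)
            h = fx.EncounterHistory("x", 0, tuple(ev))
            a = fx.history_loglik(spec, values, h)
            b = enumeration_loglik(spec, values, h)
            assert a == pytest.approx(b, abs=1e-10)


class TestDeviance:
    def test_matches_hand_arithmetic(self, toy_spec):
        h1 = fx.EncounterHistory("a", 0, (0, 0, 0, 1))
        h0 = fx.EncounterHistory("b", 0, (0, 0, 0, 0))
        hs = fx.HistorySet(("1977", "1978", "1979", "1980"), [h1, h0])
        dev = fx.deviance(toy_spec, VALS, hs)
        assert dev == pytest.approx(-2 * (np.log(0.36) + np.log(0.64)))

    def test_duplication_doubles_contribution(self, toy_spec):
        years = ("1977", "1978", "1979", "1980")
        h = fx.EncounterHistory("a", 0, (0, 0, 0, 1))
        one = fx.HistorySet(years, [h])
        two = fx.HistorySet(
            years, [fx.EncounterHistory("a", 0, (0, 0, 0, 1), 2)]
        )
        assert fx.deviance(toy_spec, VALS, two) == pytest.approx(
            2 * fx.deviance(toy_spec, VALS, one)
        )

    def test_aggregation_invariance(self, toy_spec):
        years = ("1977", "1978", "1979", "1980")
        parts = [fx.EncounterHistory(f"i{k}", 0, (0, 0, 0, 1)) for k in range(3)]
        split = fx.HistorySet(years, parts)
        merged = split.aggregate()
        assert len(merged) == 1
        assert fx.deviance(toy_spec, VALS, merged) == pytest.approx(
            fx.deviance(toy_spec, VALS, split)
        )

    def test_total_probability_is_one(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            spec, values = random_toy(rng)
            _, probs = fx.event_string_probs(spec, values, 0)
            assert probs.sum() == pytest.approx(1.0, abs=1e-10)


class TestFastEngine:
    def test_matches_reference_path(self):
        sim, spec = fx.make_fixture("tiny", seed=9)
        pm = ParameterMap(spec)
        eng = FastLikelihood(spec)
        rng = np.random.default_rng(1)
        for _ in range(3):
            x = pm.random_start(rng)
            vec, vals = pm.natural_vector(x), pm.natural_values(x)
            for batch in split_cohorts(sim.histories):
                fast = eng.batch_loglik(vec, batch, beta_shift=0.4)
                ref = batch_loglik(spec, vals, batch, beta_shift=0.4)
                nodes = eng.batch_loglik_nodes(vec, batch, np.array([0.0, 0.4]))
                assert np.allclose(fast, ref, atol=1e-12)
                assert np.allclose(nodes[1], ref, atol=1e-12)

    def test_additive_survival_variant(self):
        spec = fx.ModelSpec(K=2, n_occasions=6, a_pool=5,
                            experience_on_survival="additive")
        pm = ParameterMap(spec)
        x = pm.random_start(np.random.default_rng(3))
        vec, vals = pm.natural_vector(x), pm.natural_values(x)
        h = fx.EncounterHistory("x", 0, (0, 0, 0, 1, 0, 1))
        eng = FastLikelihood(spec)
        from flamexp.likelihood import CohortBatch
        b = CohortBatch(0, np.array([h.events], dtype=np.int8), np.ones(1))
        assert eng.batch_loglik(vec, b)[0] == pytest.approx(
            fx.history_loglik(spec, vals, h), abs=1e-12
        )
        # oracle cross-check with experience-dependent survival
        assert fx.history_loglik(spec, vals, h) == pytest.approx(
            enumeration_loglik(spec, vals, h), abs=1e-10
        )
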