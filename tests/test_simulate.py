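import numpy as np
import pandas as pd
import pytest
from scipy import stats

import flamexp as fx


def small_cfg(**kw):
    beta = kw.pop("beta", fx.default_breeding_profile(range(3, 7), 2))
    base = dict(first_year=2000, final_year=2007, cohort_sizes=(200, 200),
                cold_spell_year=2002, beta=beta, seed=1)
    base.update(kw)
    return fx.SimulationConfig(**base)


class TestSimulate:
    def test_no_breeding_means_all_zero(self):
        beta = pd.DataFrame({0: [0.0] * 4, 1: [0.0] * 4}, index=range(3, 7))
        sim = fx.simulate(small_cfg(beta=beta))
        assert all(sum(h.events) == 0 for h in sim.histories.histories)

    def test_sure_breeding_and_detection(self):
        beta = pd.DataFrame({0: [1.0] * 4, 1: [1.0] * 4}, index=range(3, 7))
        cfg = small_cfg(
            beta=beta, cohort_sizes=(30,), cold_spell_year=None,
            phi_first_normal=1.0, phi_adult_normal=1.0,
            p_by_year={y: 1.0 for y in range(2000, 2008)},
        )
        sim = fx.simulate(cfg)
        for h in sim.histories.histories:
            ages = np.arange(len(h.events))
            assert all(h.events[a] == (1 if a >= 3 else 0) for a in ages)

    def test_no_detection_before_maturity_or_after_death(self):
        sim = fx.simulate(small_cfg())
        lat = sim.latent
        assert (lat.loc[lat.age < 3, "event"] == 0).all()
        assert (lat.loc[lat.state == "DEAD", "event"] == 0).all()
        # experience counts never decrease within an individual
        for _, grp in lat[lat.state != "DEAD"].groupby("id"):
            e = grp.sort_values("occasion")["experience"].to_numpy()
            assert (np.diff(e) >= 0).all()

    def test_events_consistent_with_latent_states(self):
        sim = fx.simulate(small_cfg())
        lat = sim.latent
        seen = lat[lat.event == 1]
        assert seen.state.str.startswith("B").all()

    def test_breeding_fractions_within_binomial_envelope(self):
        beta = fx.default_breeding_profile(range(3, 8), 2)
        cfg = small_cfg(beta=beta, cohort_sizes=(2500, 2500),
                        first_year=2000, final_year=2009, seed=7)
        sim = fx.simulate(cfg)
        lat = sim.latent
        alive = lat[(lat.state != "DEAD") & (lat.age >= 3)]
        checked = 0
        for (age, e), grp in alive.groupby(["age", "experience"]):
            n = len(grp)
            if n < 200:
                continue
            k = grp.state.str.startswith("B").sum()
            b = cfg.beta_at(int(age), int(e))
            lo, hi = stats.binom.ppf([0.005, 0.995], n, b)
            assert lo <= k <= hi, (age, e, k, n, b)
            checked += 1
        assert checked >= 5

    def test_cold_spell_depresses_survival(self):
        cfg = small_cfg(phi_adult_cold=0.6, phi_adult_normal=0.95,
                        cohort_sizes=(3000,), seed=3)
        sim = fx.simulate(cfg)
        lat = sim.latent
        step = cfg.cold_spell_step

        def surv(t):
            now = lat[(lat.occasion == t) & (lat.state != "DEAD") & (lat.age >= 1)]
            nxt = lat[(lat.occasion == t + 1) & (lat.state != "DEAD")]
            return len(nxt[nxt.id.isin(now.id)]) / len(now)

        assert surv(step) < surv(step + 1)
        assert surv(step) < surv(step - 1)


class TestDeterminism:
    def test_same_seed_identical(self):
        a = fx.simulate(small_cfg())
        b = fx.simulate(small_cfg())
        assert a.histories == b.histories
        assert a.latent.equals(b.latent)

    def test_substreams_stable_under_cohort_resizing(self):
        a = fx.simulate(small_cfg(cohort_sizes=(50, 50)))
        b = fx.simulate(small_cfg(cohort_sizes=(50, 120)))
        first = lambda s: sorted(
            (h.individual_id, h.events) for h in s.histories.histories
            if h.cohort_index == 0
        )
        assert first(a) == first(b)

    def test_fixture_files_byte_identical(self, tmp_path, tiny_sim):
        sim, _ = tiny_sim
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        fx.write_histories(sim.histories, p1, "csv")
        fx.write_histories(sim.histories, p2, "csv")
        assert p1.read_bytes() == p2.read_bytes()


class TestTruth:
    def test_truth_profile_round_trip(self):
        cfg = small_cfg()
        beta, params = fx.truth_profile(cfg)
        assert beta.equals(cfg.beta)
        assert params["phi_first_normal"] == cfg.phi_first_normal

    def test_default_shape_orders_experience(self):
        beta = fx.default_breeding_profile(range(3, 16), 3)
        assert beta.loc[8, 1] > beta.loc[8, 0]
        assert ((beta >= 0) & (beta <= 1)).all().all()
        # most-experienced birds approach systematic breeding by age 15
        assert beta.loc[15, 2] > 0.9
        # peak near age 8 for the less experienced levels
        assert beta.loc[8, 0] == beta[0].max()

    def test_truth_values_align_with_spec_cells(self):
        sim, spec = fx.make_fixture("tiny", seed=0)
        tv = fx.truth_values(sim.config, spec)
        for cell in fx.ParameterMap(spec).free_names:
            assert cell in tv

    def test_exposure_counts_total(self, tiny_sim):
        sim, spec = tiny_sim
        expo = fx.exposure_counts(sim, spec)
        lat = sim.latent
        n_breeder_seasons = (lat.state.str.startswith("B")).sum()
        assert expo[[c for c in expo.index if c.startswith("p[")]].sum() == \
            n_breeder_seasons


class TestClosure:
    def test_simulate_fit_simulate_closes(self):
        """Refitting data simulated at fitted parameters recovers those
        parameters within 3 SE (well-exposed cells)."""
        sim, spec = fx.make_fixture("small", seed=31)
        m = fx.BreedingExperienceModel(spec, sim.histories)
        res = m.fit(n_starts=1, seed=0, jac="2-point")
        est = res.probabilities
        # rebuild a generator at the fitted parameter values
        cfg0 = sim.config
        beta = cfg0.beta.copy()
        for a in beta.index:
            for e in beta.columns:
                cell = f"beta[{a},{e}]"
                if cell in est:
                    beta.loc[a, e] = est[cell]
        p_by_year = dict(cfg0.p_by_year)
        for t in spec.p_occasions:
            p_by_year[cfg0.years[t]] = float(est[f"p[{t}]"])
        cfg1 = fx.SimulationConfig(
            first_year=cfg0.first_year, final_year=cfg0.final_year,
            cohort_sizes=cfg0.cohort_sizes,
            phi_first_normal=est["phi[first,normal]"],
            phi_first_cold=est["phi[first,cold]"],
            phi_adult_normal=est["phi[adult,normal]"],
            phi_adult_cold=est["phi[adult,cold]"],
            cold_spell_year=cfg0.cold_spell_year,
            beta=beta, p_by_year=p_by_year, seed=77,
        )
        sim1 = fx.simulate(cfg1)
        m1 = fx.BreedingExperienceModel(spec, sim1.histories)
        res1 = m1.fit(n_starts=1, seed=1, jac="2-point")
        expo = fx.exposure_counts(sim1, spec)
        truth1 = fx.truth_values(cfg1, spec)
        checked = hits = 0
        for cell in m1.map.free_names:
            se = res1.bse_natural[cell]
            if expo.get(cell, 0) < 100 or se == 0.0:
                continue
            checked += 1
            hits += abs(res1.probabilities[cell] - truth1[cell]) <= 3 * se
        assert checked >= 10
        assert hits / checked >= 0.9


class TestMakeFixture:
    def test_tiny_parses_validates_and_fits_quickly(self, tmp_path, tiny_sim):
        import time

        sim, spec = tiny_sim
        path = tmp_path / "tiny.csv"
        fx.write_histories(sim.histories, path, "csv")
        hs = fx.read_histories(path, "csv")
        t0 = time.time()
        res = fx.BreedingExperienceModel(spec, hs).fit(n_starts=1, seed=0)
        assert time.time() - t0 < 60
        assert np.isfinite(res.deviance)

    def test_unknown_scale(self):
        with pytest.raises(ValueError):
            fx.make_fixture("huge")
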