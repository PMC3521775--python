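"""Synthetic encounter-history generator with full latent truth.

Emulates the study design the model targets: chicks ringed over 21 annual
cohorts (1977-1997) and resighted through 2001, detection of breeders only,
sexual maturity at age 3, a one-step survival shock (the February 1985 cold
spell) between the 1984 and 1985 seasons, breeding probability driven by an
age x experience table, and optionally a static logit-normal individual
effect on breeding probability.  Scaled-down fixtures keep the same
structure at a fraction of the size.

The default breeding-probability table encodes only the qualitative shape
reported for this population: curves for the inexperienced and
once-experienced groups rise to a peak near age 8 and then decline, while
the most-experienced group keeps rising toward systematic breeding (near 1)
around age 15.  No numeric value is treated as a published estimate.

Every simulation is reproducible from one master seed; per-individual
random substreams are derived from (seed, cohort, index), so changing one
cohort's size does not perturb the draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .design import MIN_BREEDING_AGE, ModelSpec, RandomEffectSpec
from .histories import EncounterHistory, HistorySet

__all__ = [
    "SimulationConfig",
    "SimulatedData",
    "default_breeding_profile",
    "default_detection",
    "simulate",
    "truth_profile",
    "truth_values",
    "exposure_counts",
    "make_fixture",
]


def default_breeding_profile(ages, n_levels: int = 3) -> pd.DataFrame:
    """Age x experience breeding-probability table with the field-typical
    shape: right-skewed peak at age 8 for the less experienced levels,
    monotone rise toward ~1 by age 15 for the pooled top level."""
    ages = np.asarray(list(ages), dtype=float)
    peaks = np.linspace(0.30, 0.55, max(n_levels - 1, 1))
    cols = {}
    for e in range(n_levels - 1):
        width = np.where(ages <= 8.0, 2.5, 4.5)
        cols[e] = peaks[e] * np.exp(-((ages - 8.0) ** 2) / (2 * width ** 2))
    cols[n_levels - 1] = 0.97 * expit((ages - 9.0) / 1.8)
    df = pd.DataFrame(cols, index=ages.astype(int))
    df.index.name = "age"
    return df


def default_detection(years) -> dict[int, float]:
    """Year-varying detection of breeders (cycling 0.6 / 0.75 / 0.9)."""
    cycle = [0.6, 0.75, 0.9]
    return {int(y): cycle[i % 3] for i, y in enumerate(years)}


@dataclass
class SimulationConfig:
    """Generator parameters (defaults emulate the full study design)."""

    first_year: int = 1977
    final_year: int = 2001
    cohort_sizes: tuple[int, ...] = (700,) * 21
    phi_first_normal: float = 0.763
    phi_first_cold: float = 0.589
    phi_adult_normal: float = 0.96
    phi_adult_cold: float = 0.88
    cold_spell_year: int | None = 1984  # shock over the 1984 -> 1985 step
    beta: pd.DataFrame | None = None    # index: age classes, columns: 0..K-1
    p_by_year: Mapping[int, float] | None = None
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.final_year <= self.first_year:
            raise ValueError("final_year must exceed first_year")
        if self.first_year + len(self.cohort_sizes) - 1 > self.final_year:
            raise ValueError("cohorts extend past the final year")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.beta is None:
            self.beta = default_breeding_profile(
                range(MIN_BREEDING_AGE, min(17, self.n_occasions - 1) + 1)
            )
        if ((self.beta.to_numpy() < 0) | (self.beta.to_numpy() > 1)).any():
            raise ValueError("beta outside [0, 1]")
        if int(self.beta.index.min()) < MIN_BREEDING_AGE:
            raise ValueError(f"beta table starts below age {MIN_BREEDING_AGE}")
        if self.p_by_year is None:
            self.p_by_year = default_detection(self.years)
        bad = [v for v in self.p_by_year.values() if not 0 <= v <= 1]
        if bad:
            raise ValueError(f"detection outside [0, 1]: {bad}")
        for name in ("phi_first_normal", "phi_first_cold",
                     "phi_adult_normal", "phi_adult_cold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} outside [0, 1]: {v}")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(self.first_year, self.final_year + 1))

    @property
    def n_occasions(self) -> int:
        return self.final_year - self.first_year + 1

    @property
    def K(self) -> int:
        return self.beta.shape[1]

    @property
    def a_pool(self) -> int:
        return int(self.beta.index.max())

    @property
    def cold_spell_step(self) -> int | None:
        if self.cold_spell_year is None:
            return None
        return self.cold_spell_year - self.first_year

    def phi(self, age: int, t: int) -> float:
        cold = self.cold_spell_step is not None and t == self.cold_spell_step
        if age == 0:
            return self.phi_first_cold if cold else self.phi_first_normal
        return self.phi_adult_cold if cold else self.phi_adult_normal

    def beta_at(self, age: int, e: int) -> float:
        if age < MIN_BREEDING_AGE:
            return 0.0
        a = min(age, self.a_pool)
        return float(self.beta.loc[a, e])


@dataclass
class SimulatedData:
    """Simulated histories plus the latent truth used to generate them."""

    histories: HistorySet
    latent: pd.DataFrame   # long: id, cohort, occasion, age, state, experience, event
    u: pd.Series           # individual effect per id
    config: SimulationConfig


def simulate(cfg: SimulationConfig) -> SimulatedData:
    """Draw one dataset under the generator.

    Per individual and step: survive (age- and regime-specific), increment
    experience on leaving a breeding season, breed at the destination season
    with beta(age, e) shifted by the individual's u_i on the logit scale,
    and emit code 1 with the year's detection probability only while
    breeding.
    """
    T = cfg.n_occasions
    years = cfg.years
    histories: list[EncounterHistory] = []
    rows: list[tuple] = []
    u_index: list[str] = []
    u_vals: list[float] = []
    for c, size in enumerate(cfg.cohort_sizes):
        for i in range(size):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(cfg.seed), c, i])
            )
            iid = f"c{years[c]}i{i}"
            u = float(cfg.sigma * rng.standard_normal()) if cfg.sigma > 0 else 0.0
            u_index.append(iid)
            u_vals.append(u)
            events = [0]
            exp = 0
            breeding = False
            alive = True
            rows.append((iid, c, c, 0, "N0", 0, 0))
            for t in range(c, T - 1):
                age_t = t - c
                if alive:
                    alive = rng.random() < cfg.phi(age_t, t)
                if not alive:
                    events.append(0)
                    rows.append((iid, c, t + 1, t + 1 - c, "DEAD", -1, 0))
                    continue
                if breeding:
                    exp = min(exp + 1, cfg.K - 1)
                age_d = t + 1 - c
                b = cfg.beta_at(age_d, exp)
                if u != 0.0 and 0.0 < b < 1.0:
                    b = float(expit(logit(b) + u))
                breeding = rng.random() < b
                code = 0
                if breeding and rng.random() < cfg.p_by_year[years[t + 1]]:
                    code = 1
                events.append(code)
                state = f"{'B' if breeding else 'N'}{exp}"
                rows.append((iid, c, t + 1, age_d, state, exp, code))
            histories.append(EncounterHistory(iid, c, tuple(events)))
    hs = HistorySet(
        tuple(str(y) for y in years), histories,
        provenance=f"simulated (seed={cfg.seed}, sigma={cfg.sigma})",
    )
    latent = pd.DataFrame(
        rows,
        columns=["id", "cohort", "occasion", "age", "state", "experience", "event"],
    )
    return SimulatedData(hs, latent, pd.Series(u_vals, index=u_index, name="u"), cfg)


def truth_profile(cfg: SimulationConfig) -> tuple[pd.DataFrame, dict[str, float]]:
    """The generating truth in fit-report shape: the beta table plus the
    scalar parameters (survival, detection per year, sigma)."""
    params: dict[str, float] = {
        "phi_first_normal": cfg.phi_first_normal,
        "phi_adult_normal": cfg.phi_adult_normal,
        "sigma": cfg.sigma,
    }
    if cfg.cold_spell_step is not None:
        params["phi_first_cold"] = cfg.phi_first_cold
        params["phi_adult_cold"] = cfg.phi_adult_cold
    for y in cfg.years:
        params[f"p_{y}"] = float(cfg.p_by_year[y])
    return cfg.beta.copy(), params


def truth_values(cfg: SimulationConfig, spec: ModelSpec) -> dict[str, float]:
    """Generating truth keyed by the spec's structural cell names."""
    if spec.n_occasions != cfg.n_occasions:
        raise ValueError("spec and config disagree on the occasion axis")
    vals: dict[str, float] = {
        "phi[first,normal]": cfg.phi_first_normal,
        "phi[adult,normal]": cfg.phi_adult_normal,
    }
    if spec.cold_spell_step is not None:
        if spec.cold_spell_step != cfg.cold_spell_step:
            raise ValueError("spec and config disagree on the cold-spell step")
        vals["phi[first,cold]"] = cfg.phi_first_cold
        vals["phi[adult,cold]"] = cfg.phi_adult_cold
    for cell in spec.beta_cells():
        a, e = map(int, cell[len("beta["):-1].split(","))
        vals[cell] = cfg.beta_at(a, e)
    for t in spec.p_occasions:
        vals[f"p[{t}]"] = float(cfg.p_by_year[cfg.years[t]])
    if spec.random_effect is not None:
        vals["sigma"] = cfg.sigma
    return vals


def exposure_counts(sim: SimulatedData, spec: ModelSpec) -> pd.Series:
    """Effective exposures per structural cell, from the latent truth.

    beta cells count live bird-seasons at that age class x experience;
    p cells count breeder-seasons at that occasion; phi cells count at-risk
    between-season transitions in that age class x regime.
    """
    lat = sim.latent
    cfg = sim.config
    counts: dict[str, int] = {c: 0 for c in spec.cell_names() if c != "sigma"}
    alive = lat[lat["state"] != "DEAD"]
    # beta exposures: live seasons at or past maturity
    mature = alive[alive["age"] >= spec.a_min]
    for (age, e), n in mature.groupby(["age", "experience"]).size().items():
        cell = f"beta[{min(int(age), spec.a_pool_eff)},{int(e)}]"
        if cell in counts:
            counts[cell] += int(n)
    # detection exposures: breeder-seasons per occasion
    breeders = alive[alive["state"].str.startswith("B")]
    for t, n in breeders.groupby("occasion").size().items():
        cell = f"p[{int(t)}]"
        if cell in counts:
            counts[cell] += int(n)
    # survival exposures: at-risk transitions (alive at t, t < T-1)
    at_risk = alive[alive["occasion"] < spec.n_occasions - 1]
    for (occ, age), n in at_risk.groupby(["occasion", "age"]).size().items():
        cls = "first" if age == 0 else "adult"
        regime = "cold" if int(occ) == spec.cold_spell_step else "normal"
        cell = f"phi[{cls},{regime}]"
        if cell in counts:
            counts[cell] += int(n)
    return pd.Series(counts, name="exposures")


_FIXTURES = {
    # scale: (n_cohorts, cohort_size, n_occasions, K, a_pool, cold_step)
    "tiny": (3, 50, 6, 2, 5, None),
    "small": (10, 300, 12, 3, 8, 4),
    "study": (21, 700, 25, 3, 17, 7),
}


def make_fixture(
    scale: str, seed: int = 0, sigma: float = 0.0
) -> tuple[SimulatedData, ModelSpec]:
    """Simulated dataset plus the matching ModelSpec at a named scale.

    tiny  = 3 cohorts x 50 ind. x 6 occasions (unit tests);
    small = 10 x 300 x 12 (recovery studies);
    study = 21 x 700 x 25 (the full study design).

    First-year normal survival is fixed at 0.763 in the returned spec (it
    is confounded with the inexperienced breeding probabilities when free).
    """
    if scale not in _FIXTURES:
        raise ValueError(f"unknown scale {scale!r}; use {sorted(_FIXTURES)}")
    n_cohorts, size, T, K, a_pool, cold_step = _FIXTURES[scale]
    first_year = 1977
    beta = default_breeding_profile(range(MIN_BREEDING_AGE, a_pool + 1), K)
    cfg = SimulationConfig(
        first_year=first_year,
        final_year=first_year + T - 1,
        cohort_sizes=(size,) * n_cohorts,
        cold_spell_year=None if cold_step is None else first_year + cold_step,
        beta=beta,
        sigma=sigma,
        seed=seed,
    )
    spec = ModelSpec(
        K=K,
        n_occasions=T,
        a_pool=a_pool,
        cold_spell_step=cold_step,
        fixed={"phi[first,normal]": cfg.phi_first_normal},
        random_effect=(RandomEffectSpec(sigma=0.5, n_nodes=15, sigma_free=True)
                       if sigma > 0 else None),
    )
    return simulate(cfg), spec
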