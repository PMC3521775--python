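"""Declarative model structure and its mapping to per-step rates.

A :class:`ModelSpec` names every structural parameter cell of a model:

* survival ``phi[age_class,regime]`` with age classes ``first`` (the year
  after ringing) and ``adult``, and regimes ``normal`` / ``cold`` (the
  one-step survival shock of a severe winter cold spell);
* optional additive experience offsets on adult survival ``phi_exp[e]``
  (logit-scale, baseline e=0);
* breeding probability ``beta[a,e]`` for each categorical age class
  ``a = a_min .. a_pool`` (the last pooled "a_pool or older") crossed with
  experience level ``e`` — only attainable combinations (``e <= a - a_min``)
  exist, and beta is structurally 0 below the age at maturity ``a_min``;
* detection ``p[t]`` per occasion (breeders only; a pre-breeder is
  unobservable, which realizes "detection fixed to 0 in the first years of
  life" structurally);
* optionally the standard deviation ``sigma`` of an individual random
  effect on the logit of beta.

Free cells are estimated on the logit scale; cells listed in ``fixed`` are
held exactly at the given probability.  ``chat`` is the variance-inflation
factor used for QAIC and quasi-likelihood standard errors; it is an input
(estimated externally from a goodness-of-fit test), not a fitted quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy.special import expit, logit

from .states import StepRates

__all__ = ["ModelSpec", "RandomEffectSpec", "ParameterMap", "materialize_rates"]

MIN_BREEDING_AGE = 3


@dataclass(frozen=True)
class RandomEffectSpec:
    """Additive individual effect u_i ~ N(0, sigma^2) on logit(beta).

    The effect is drawn once per individual and shared by every breeding
    probability cell of that individual; survival and detection are
    unaffected.  The marginal likelihood integrates u out by Gauss-Hermite
    quadrature with ``n_nodes`` nodes (odd counts include the mode).
    """

    sigma: float = 0.0
    n_nodes: int = 15
    sigma_free: bool = True

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one candidate model.

    Parameters
    ----------
    K : int
        Number of experience levels (2, 3 or 4); the top level is pooled.
    n_occasions : int
        Number of breeding seasons on the occasion axis.
    a_min : int
        Age at sexual maturity; beta is structurally 0 below it.
    a_pool : int
        Oldest distinct age class; older ages share the "a_pool+" cell.
        Clipped to the oldest attainable age, ``n_occasions - 1``.
    cold_spell_step : int or None
        Occasion index t such that survival over the step t -> t+1 uses the
        "cold" regime (the between-season mortality shock).
    experience_on_survival : {"off", "additive"}
        If "additive", adult survival gains K-1 additive logit offsets.
    p_occasions : tuple of int or None
        Occasions with a free detection cell; default: every occasion at
        which a bird ringed at occasion 0 could have reached maturity.
    fixed : mapping cell name -> value
        Cells held exactly at the given value (probability scale; offset
        cells on the logit scale).
    chat : float
        Variance inflation factor for QAIC and quasi-SEs.
    random_effect : RandomEffectSpec or None
    """

    K: int = 3
    n_occasions: int = 25
    a_min: int = MIN_BREEDING_AGE
    a_pool: int = 17
    cold_spell_step: int | None = None
    experience_on_survival: str = "off"
    p_occasions: tuple[int, ...] | None = None
    fixed: Mapping[str, float] = field(default_factory=dict)
    chat: float = 1.0
    random_effect: RandomEffectSpec | None = None

    def __post_init__(self) -> None:
        if self.K < 2 or self.K > 4:
            raise ValueError("K must be 2, 3 or 4")
        if self.a_min < MIN_BREEDING_AGE:
            raise ValueError(f"a_min must be >= {MIN_BREEDING_AGE}")
        if self.chat <= 0:
            raise ValueError("chat must be > 0")
        if self.experience_on_survival not in ("off", "additive"):
            raise ValueError("experience_on_survival must be 'off' or 'additive'")
        if self.p_occasions is None:
            object.__setattr__(
                self, "p_occasions",
                tuple(range(self.a_min, self.n_occasions)),
            )
        else:
            object.__setattr__(self, "p_occasions", tuple(self.p_occasions))
        object.__setattr__(self, "fixed", dict(self.fixed))
        for name in self.fixed:
            if name not in self.cell_names():
                raise ValueError(f"fixed parameter {name!r} names no cell")

    # -- cell enumeration ---------------------------------------------------

    @property
    def a_pool_eff(self) -> int:
        return min(self.a_pool, self.n_occasions - 1)

    @property
    def ages(self) -> tuple[int, ...]:
        return tuple(range(self.a_min, self.a_pool_eff + 1))

    def beta_cells(self) -> list[str]:
        return [
            f"beta[{a},{e}]"
            for a in self.ages
            for e in range(self.K)
            if e <= a - self.a_min  # experience cannot exceed seasons since maturity
        ]

    def phi_cells(self) -> list[str]:
        regimes = ["normal"] + (["cold"] if self.cold_spell_step is not None else [])
        cells = [f"phi[{c},{r}]" for c in ("first", "adult") for r in regimes]
        if self.experience_on_survival == "additive":
            cells += [f"phi_exp[{e}]" for e in range(1, self.K)]
        return cells

    def p_cells(self) -> list[str]:
        return [f"p[{t}]" for t in self.p_occasions]

    def cell_names(self) -> list[str]:
        cells = self.phi_cells() + self.beta_cells() + self.p_cells()
        if self.random_effect is not None:
            cells.append("sigma")
        return cells

    def with_fixed(self, **fixed: float) -> "ModelSpec":
        new = dict(self.fixed)
        new.update(fixed)
        return replace(self, fixed=new)

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "K": self.K,
            "n_occasions": self.n_occasions,
            "a_min": self.a_min,
            "a_pool": self.a_pool,
            "cold_spell_step": self.cold_spell_step,
            "experience_on_survival": self.experience_on_survival,
            "p_occasions": list(self.p_occasions),
            "fixed": dict(self.fixed),
            "chat": self.chat,
        }
        if self.random_effect is not None:
            d["random_effect"] = {
                "sigma": self.random_effect.sigma,
                "n_nodes": self.random_effect.n_nodes,
                "sigma_free": self.random_effect.sigma_free,
            }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelSpec":
        d = yaml.safe_load(Path(path).read_text())
        re_d = d.pop("random_effect", None)
        if re_d is not None:
            d["random_effect"] = RandomEffectSpec(**re_d)
        if d.get("p_occasions") is not None:
            d["p_occasions"] = tuple(d["p_occasions"])
        return cls(**d)


class ParameterMap:
    """Ordered registry of free coefficients for a ModelSpec.

    Free probability cells live on the logit scale; ``phi_exp`` offsets and
    ``sigma`` are taken at face value (sigma bounded below by 0 at fit
    time).  Fixed cells are held exactly on their natural scale.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.all_cells = spec.cell_names()
        self.fixed = dict(spec.fixed)
        if spec.random_effect is not None and not spec.random_effect.sigma_free:
            self.fixed.setdefault("sigma", spec.random_effect.sigma)
        self.free_names = [c for c in self.all_cells if c not in self.fixed]

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def kind(self, name: str) -> str:
        if name.startswith("phi_exp") or name == "sigma":
            return "raw"
        return "prob"

    def natural_vector(self, x: np.ndarray) -> np.ndarray:
        """Natural-scale values aligned with ``spec.cell_names()`` (fast path)."""
        x = np.asarray(x, dtype=float)
        if not hasattr(self, "_fixed_vec"):
            names = self.all_cells
            self._free_pos = np.array(
                [names.index(n) for n in self.free_names], dtype=int
            )
            self._free_is_prob = np.array(
                [self.kind(n) == "prob" for n in self.free_names]
            )
            self._fixed_vec = np.zeros(len(names))
            for n, v in self.fixed.items():
                self._fixed_vec[names.index(n)] = v
        vec = self._fixed_vec.copy()
        vec[self._free_pos] = np.where(self._free_is_prob, expit(x), x)
        return vec

    def natural_values(self, x: np.ndarray) -> dict[str, float]:
        """Map a free-coefficient vector to {cell name: natural value}."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_free,):
            raise ValueError(
                f"expected {self.n_free} free coefficients, got {x.shape}"
            )
        vals: dict[str, float] = {}
        for name, xi in zip(self.free_names, x):
            vals[name] = float(xi) if self.kind(name) == "raw" else float(expit(xi))
        vals.update(self.fixed)
        return vals

    def link_values(self, natural: Mapping[str, float]) -> np.ndarray:
        """Inverse of :meth:`natural_values` restricted to free cells."""
        out = np.empty(self.n_free)
        for i, name in enumerate(self.free_names):
            v = natural[name]
            out[i] = v if self.kind(name) == "raw" else logit(v)
        return out

    def random_start(self, rng: np.random.Generator) -> np.ndarray:
        """Multi-start draw: logit coefficients ~ U(-2, 2), sigma ~ U(0.1, 1.5)."""
        x = rng.uniform(-2.0, 2.0, size=self.n_free)
        for i, name in enumerate(self.free_names):
            if name == "sigma":
                x[i] = rng.uniform(0.1, 1.5)
        return x

    def bounds(self) -> list[tuple[float | None, float | None]]:
        return [
            (0.0, None) if name == "sigma" else (None, None)
            for name in self.free_names
        ]


def _shifted(b: float, u: float) -> float:
    """Apply a logit-scale shift to a probability; structural 0/1 stay put."""
    if u == 0.0 or b <= 0.0 or b >= 1.0:
        return b
    return float(expit(logit(b) + u))


def materialize_rates(
    spec: ModelSpec,
    values: Mapping[str, float],
    cohort_index: int,
    t: int,
    beta_shift: float = 0.0,
) -> StepRates:
    """Rates for the step from occasion ``t`` to ``t+1`` of an individual
    ringed at ``cohort_index``.

    Survival uses the age at the start of the step (age 0 -> first-year) and
    the normal/cold regime of the step; beta uses the age reached at the
    destination season (0 below ``a_min``, pooled above ``a_pool``);
    detection uses the destination occasion.  ``beta_shift`` adds an
    individual effect on the logit of every (non-degenerate) beta cell.
    """
    if t < cohort_index:
        raise ValueError("step starts before ringing")
    age_t = t - cohort_index
    age_class = "first" if age_t == 0 else "adult"
    regime = "cold" if t == spec.cold_spell_step else "normal"
    base = values[f"phi[{age_class},{regime}]"]
    if spec.experience_on_survival == "additive" and age_class == "adult":
        lo = logit(base)
        phi = np.array([
            float(expit(lo + (values[f"phi_exp[{e}]"] if e > 0 else 0.0)))
            for e in range(spec.K)
        ])
    else:
        phi = float(base)

    age_dest = t + 1 - cohort_index
    beta = np.zeros(spec.K)
    if age_dest >= spec.a_min:
        a = min(age_dest, spec.a_pool_eff)
        for e in range(spec.K):
            cell = f"beta[{a},{e}]"
            if cell in values:
                beta[e] = _shifted(values[cell], beta_shift)

    p_cell = f"p[{t + 1}]"
    p = values.get(p_cell, 0.0)
    return StepRates(phi=phi, beta_by_level=beta, p=float(p))
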