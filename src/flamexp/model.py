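"""Model and Results objects for fitting the experience model to data.

Usage parallels other likelihood-based modelling packages: build a
:class:`BreedingExperienceModel` from a :class:`~flamexp.design.ModelSpec`
and a :class:`~flamexp.histories.HistorySet`, call :meth:`fit`, and read the
estimates, standard errors, deviance and QAIC off the returned
:class:`BreedingExperienceResults`.

The deviance is minimized by quasi-Newton (L-BFGS-B) iteration from several
random starts (multievent likelihoods are multimodal); standard errors come
from the numerically differentiated Hessian at the optimum, inflated by the
variance inflation factor c-hat (quasi-likelihood convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.tools import numdiff

from scipy.special import logsumexp

from .design import ModelSpec, ParameterMap
from .histories import HistorySet
from .likelihood import CohortBatch, FastLikelihood, split_cohorts
from .random_effect import gauss_hermite_rule
from .random_effect import average_individual_profile
from .selection import qaic as _qaic
from .states import build_state_space

__all__ = ["BreedingExperienceModel", "BreedingExperienceResults", "FitError"]

#: |logit coefficient| beyond which an estimate is flagged as on the boundary
BOUNDARY_LOGIT = 15.0


class FitError(RuntimeError):
    """All optimization starts failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list[dict]):
        super().__init__(message)
        self.diagnostics = diagnostics


class BreedingExperienceModel:
    """Hidden-Markov model of breeding probability by age and experience.

    Parameters
    ----------
    spec : ModelSpec
        Declarative structure (experience levels, age classes, survival
        regimes, detection cells, fixed values, c-hat, random effect).
    data : HistorySet
        Encounter histories on the same occasion axis as the spec.
    """

    def __init__(self, spec: ModelSpec, data: HistorySet):
        if data.n_occasions != spec.n_occasions:
            raise ValueError(
                f"data has {data.n_occasions} occasions, spec expects "
                f"{spec.n_occasions}"
            )
        self.spec = spec
        self.data = data.aggregate()
        self.map = ParameterMap(spec)
        self.state_space = build_state_space(spec.K)
        self.batches: list[CohortBatch] = split_cohorts(self.data)
        self._engine = FastLikelihood(spec)
        if spec.random_effect is not None:
            self._gh = gauss_hermite_rule(spec.random_effect.n_nodes)
            self._sigma_idx = self.map.all_cells.index("sigma")
        self._check_detectable()

    @classmethod
    def from_files(cls, spec_path, data_path, dialect: str = "csv"):
        """Build from a YAML model config and an encounter-history file."""
        from .histories import read_histories

        spec = ModelSpec.from_yaml(spec_path)
        return cls(spec, read_histories(data_path, dialect))

    def _check_detectable(self) -> None:
        p_occ = set(self.spec.p_occasions)
        for h in self.data.histories:
            for off, code in enumerate(h.events):
                t = h.cohort_index + off
                if code == 1 and t not in p_occ:
                    raise ValueError(
                        f"{h.individual_id}: detection at occasion {t} but the "
                        "spec has no detection cell there (p fixed to 0)"
                    )

    # -- likelihood ---------------------------------------------------------

    def loglike(self, x: np.ndarray) -> float:
        """Multiplicity-weighted log-likelihood at free coefficients ``x``."""
        vec = self.map.natural_vector(x)
        re = self.spec.random_effect
        total = 0.0
        for batch in self.batches:
            if re is not None:
                sigma = vec[self._sigma_idx]
                if sigma == 0.0:
                    lp = self._engine.batch_loglik(vec, batch)
                else:
                    z, logw = self._gh
                    per_node = self._engine.batch_loglik_nodes(vec, batch, sigma * z)
                    lp = logsumexp(per_node + logw[:, None], axis=0)
            else:
                lp = self._engine.batch_loglik(vec, batch)
            if np.any(np.isneginf(lp)):
                return -np.inf
            total += float(np.dot(batch.multiplicity, lp))
        return total

    def deviance(self, x: np.ndarray) -> float:
        return -2.0 * self.loglike(x)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        n_starts: int = 5,
        seed: int | None = None,
        start: np.ndarray | Mapping[str, float] | None = None,
        compute_se: bool = True,
        maxiter: int = 2000,
        jac: str = "3-point",
    ) -> "BreedingExperienceResults":
        """Minimize the deviance from ``n_starts`` random starts.

        ``start``, if given, replaces the first random start (natural-scale
        mapping or link-scale vector).  ``jac`` selects the finite-difference
        scheme ("3-point" central, or the cheaper "2-point").  Returns the
        best local optimum; all per-start diagnostics are kept on the result.
        """
        rng = np.random.default_rng(seed)
        if isinstance(start, Mapping):
            start = self.map.link_values(start)
        diagnostics: list[dict] = []
        best = None
        for s in range(n_starts):
            x0 = (np.asarray(start, dtype=float)
                  if (s == 0 and start is not None)
                  else self.map.random_start(rng))
            try:
                res = optimize.minimize(
                    self.deviance, x0, method="L-BFGS-B", jac=jac,
                    bounds=self.map.bounds(),
                    options={"maxiter": maxiter, "maxfun": 10 * maxiter,
                             "ftol": 1e-12, "gtol": 1e-7},
                )
            except Exception as exc:  # numerical failure in one start
                diagnostics.append({"start": s, "error": str(exc)})
                continue
            if not res.success:
                # a cold restart recovers from line-search breakdown at the
                # finite-difference noise floor
                res2 = optimize.minimize(
                    self.deviance, res.x, method="L-BFGS-B", jac="3-point",
                    bounds=self.map.bounds(),  # polish always uses central diffs
                    options={"maxiter": maxiter, "maxfun": 10 * maxiter,
                             "ftol": 1e-11, "gtol": 1e-7},
                )
                if res2.fun <= res.fun:
                    res = res2
            grad_max = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
            diagnostics.append({
                "start": s, "deviance": float(res.fun), "success": bool(res.success),
                "grad_max": grad_max, "nit": int(res.nit),
            })
            if np.isfinite(res.fun) and (best is None or res.fun < best[1].fun):
                best = (s, res, grad_max)
        if best is None:
            raise FitError("no optimization start converged", diagnostics)
        s_best, res, grad_max = best

        cov_link = None
        se_flag = ""
        if compute_se:
            cov_link, se_flag = self._cov_link(res.x)
        # the deviance is evaluated to ~1e-10 relative accuracy, so the
        # gradient criterion scales with its magnitude
        converged = bool(res.success) or grad_max <= 1e-6 * (1.0 + abs(res.fun))
        return BreedingExperienceResults(
            model=self, x=np.asarray(res.x, dtype=float),
            deviance_=float(res.fun), converged=converged,
            grad_max=grad_max, n_starts=n_starts, best_start=s_best,
            start_diagnostics=diagnostics, cov_link=cov_link, se_note=se_flag,
        )

    def _cov_link(self, x: np.ndarray) -> tuple[np.ndarray, str]:
        """Quasi-likelihood covariance 2 * c-hat * H_deviance^{-1}."""
        H = numdiff.approx_hess(np.asarray(x, dtype=float), self.deviance)
        H = (H + H.T) / 2.0
        note = ""
        try:
            cov = 2.0 * self.spec.chat * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = 2.0 * self.spec.chat * np.linalg.pinv(H)
            note = "singular Hessian: pseudo-inverse covariance"
        if np.any(np.diag(cov) < 0):
            note = (note + "; " if note else "") + "non-PSD Hessian at optimum"
        return cov, note


@dataclass
class BreedingExperienceResults:
    """Estimates, uncertainties and information criteria of one fit."""

    model: BreedingExperienceModel
    x: np.ndarray
    deviance_: float
    converged: bool
    grad_max: float
    n_starts: int
    best_start: int
    start_diagnostics: list[dict]
    cov_link: np.ndarray | None = None
    se_note: str = ""
    rank_deficiency: int = 0

    # -- parameters ----------------------------------------------------------

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def params(self) -> pd.Series:
        """Free coefficients on the link (logit) scale."""
        return pd.Series(self.x, index=self.model.map.free_names, name="coef")

    @property
    def probabilities(self) -> pd.Series:
        """All structural cells on the natural scale (fixed cells included)."""
        vals = self.model.map.natural_values(self.x)
        return pd.Series(vals, name="estimate")

    @property
    def bse(self) -> pd.Series:
        """Link-scale standard errors of the free coefficients."""
        if self.cov_link is None:
            raise ValueError("fit was run with compute_se=False")
        se = np.sqrt(np.clip(np.diag(self.cov_link), 0.0, np.inf))
        return pd.Series(se, index=self.model.map.free_names, name="se")

    @property
    def bse_natural(self) -> pd.Series:
        """Delta-method standard errors on the probability scale."""
        se = self.bse.copy()
        vals = self.model.map.natural_values(self.x)
        for name in se.index:
            if self.model.map.kind(name) == "prob":
                b = vals[name]
                se[name] = se[name] * b * (1.0 - b)
        return se.rename("se")

    @property
    def boundary_cells(self) -> list[str]:
        """Free cells estimated at the boundary (|logit coef| > 15)."""
        return [
            n for n, v in self.params.items()
            if self.model.map.kind(n) == "prob" and abs(v) > BOUNDARY_LOGIT
        ]

    # -- information criteria ------------------------------------------------

    @property
    def deviance(self) -> float:
        return self.deviance_

    @property
    def k(self) -> int:
        """Model rank: free cells minus detected rank deficiency."""
        return self.model.map.n_free - self.rank_deficiency

    @property
    def qaic(self) -> float:
        return _qaic(self.deviance_, self.k, self.spec.chat)

    def with_rank_deficiency(self, deficiency: int) -> "BreedingExperienceResults":
        """Copy of the results with k reduced by a diagnosed redundancy."""
        import copy

        out = copy.copy(self)
        out.rank_deficiency = int(deficiency)
        return out

    # -- presentation ---------------------------------------------------------

    def beta_table(self) -> pd.DataFrame:
        """Breeding probability by age class (rows) and experience level
        (columns); under a random-effect model this is the average
        individual's (u = 0) profile."""
        return average_individual_profile(self.spec, self.model.map.natural_values(self.x))

    def summary(self) -> str:
        est = self.probabilities
        free = self.model.map.free_names
        tab = pd.DataFrame({
            "estimate": [est[n] for n in free],
            "link_coef": self.x,
        }, index=free)
        if self.cov_link is not None:
            tab["se"] = self.bse_natural
        fixed = {n: v for n, v in self.model.map.fixed.items()}
        lines = [
            "Breeding-experience multievent model",
            "=" * 52,
            f"experience levels (K):     {self.spec.K}",
            f"occasions:                 {self.spec.n_occasions}",
            f"individuals:               {self.model.data.n_individuals}",
            f"deviance:                  {self.deviance_:.2f}",
            f"rank k:                    {self.k}",
            f"c-hat:                     {self.spec.chat}",
            f"QAIC:                      {self.qaic:.2f}",
            f"converged:                 {self.converged}"
            f" (max |grad| {self.grad_max:.2e}, start {self.best_start}/{self.n_starts})",
        ]
        if fixed:
            lines.append("fixed cells:               "
                         + ", ".join(f"{n}={v}" for n, v in fixed.items()))
        if self.boundary_cells:
            lines.append("boundary estimates:        " + ", ".join(self.boundary_cells))
        if self.se_note:
            lines.append(f"SE note:                   {self.se_note}")
        lines += ["-" * 52, tab.to_string(float_format=lambda v: f"{v:.4f}"),
                  "-" * 52,
                  "breeding probability by age x experience:",
                  self.beta_table().to_string(float_format=lambda v: f"{v:.3f}")]
        return "\n".join(lines)

    def plot_breeding_profile(self, ax=None):
        """Plot beta against age, one line per experience level."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tab = self.beta_table()
        ages = [int(str(a).rstrip("+")) for a in tab.index]
        for col in tab.columns:
            ax.plot(ages, tab[col], marker="o", label=col)
        ax.set_xlabel("age (years)")
        ax.set_ylabel("breeding probability")
        ax.set_ylim(0, 1)
        ax.legend(title="previous experiences")
        return ax
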