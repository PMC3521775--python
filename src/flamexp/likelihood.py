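"""Exact hidden-Markov likelihood of encounter histories.

The probability of a history, conditional on release as a chick (state N_0
at the ringing occasion), is computed with the scaled forward recursion:
propagate the state distribution through the step transition matrix, weight
by the emission probability of the observed code, renormalize and
accumulate the log of the normalizer.  This equals the sum over all latent
state sequences of the product of step probabilities, without underflow on
long histories.

Histories are processed in per-cohort batches: every history of a cohort
shares the same sequence of transition and emission matrices (for a common
individual effect), so one matrix product per step serves the whole batch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .design import ModelSpec, ParameterMap, materialize_rates
from .histories import EncounterHistory, HistorySet
from .states import StateSpace, build_state_space, event_matrix, initial_vector, transition_matrix

__all__ = [
    "CohortBatch",
    "batch_loglik",
    "history_loglik",
    "deviance",
    "event_string_probs",
    "as_values",
]


def as_values(spec: ModelSpec, params) -> Mapping[str, float]:
    """Accept either a natural-scale {cell: value} mapping or a vector of
    free link-scale coefficients."""
    if isinstance(params, Mapping):
        return params
    return ParameterMap(spec).natural_values(np.asarray(params, dtype=float))


@dataclass
class CohortBatch:
    """Unique histories of one cohort, stacked for vectorized recursion."""

    cohort_index: int
    events: np.ndarray       # (H, L) codes over occasions cohort..T-1
    multiplicity: np.ndarray  # (H,)

    @classmethod
    def from_histories(
        cls, histories: Sequence[EncounterHistory], cohort_index: int
    ) -> "CohortBatch":
        hs = [h for h in histories if h.cohort_index == cohort_index]
        ev = np.array([h.events for h in hs], dtype=np.int8)
        mult = np.array([h.multiplicity for h in hs], dtype=float)
        return cls(cohort_index, ev, mult)


def split_cohorts(hs: HistorySet) -> list[CohortBatch]:
    agg = hs.aggregate()
    cohorts = sorted({h.cohort_index for h in agg.histories})
    return [CohortBatch.from_histories(agg.histories, c) for c in cohorts]


def batch_loglik(
    spec: ModelSpec,
    values: Mapping[str, float],
    batch: CohortBatch,
    ss: StateSpace | None = None,
    beta_shift: float = 0.0,
) -> np.ndarray:
    """Log-probability of every history in a cohort batch (-inf where the
    history is impossible under the parameters)."""
    ss = ss or build_state_space(spec.K)
    H, L = batch.events.shape
    c = batch.cohort_index
    T = spec.n_occasions
    if c + L != T:
        raise ValueError("batch events do not reach the final occasion")
    alpha = np.tile(initial_vector(ss), (H, 1))
    logp = np.zeros(H)
    alive = np.ones(H, dtype=bool)
    for t in range(c, T - 1):
        r = materialize_rates(spec, values, c, t, beta_shift=beta_shift)
        M = transition_matrix(ss, r)
        E = event_matrix(ss, r.p)
        alpha = alpha @ M
        codes = batch.events[:, t + 1 - c]
        alpha = alpha * E[:, codes].T
        s = alpha.sum(axis=1)
        dead = s <= 0.0
        alive &= ~dead
        s_safe = np.where(s > 0.0, s, 1.0)
        logp += np.where(alive, np.log(s_safe), 0.0)
        alpha = alpha / s_safe[:, None]
    logp[~alive] = -np.inf
    return logp


def history_loglik(
    spec: ModelSpec,
    params,
    h: EncounterHistory,
    ss: StateSpace | None = None,
    beta_shift: float = 0.0,
) -> float:
    """log P(events | release as N_0 at the ringing occasion).

    Returns -inf for a history that is impossible under the parameters
    (e.g. a detection where breeding has probability 0).
    """
    values = as_values(spec, params)
    batch = CohortBatch(
        h.cohort_index,
        np.array([h.events], dtype=np.int8),
        np.array([h.multiplicity], dtype=float),
    )
    return float(batch_loglik(spec, values, batch, ss, beta_shift)[0])


def deviance(spec: ModelSpec, params, hs: HistorySet) -> float:
    """-2 * sum of multiplicity-weighted history log-likelihoods.

    Additive over histories and invariant to aggregation; any impossible
    history makes the deviance +inf.
    """
    values = as_values(spec, params)
    ss = build_state_space(spec.K)
    total = 0.0
    for batch in split_cohorts(hs):
        lp = batch_loglik(spec, values, batch, ss)
        if np.any(np.isneginf(lp)):
            return float("inf")
        total += float(np.dot(batch.multiplicity, lp))
    return -2.0 * total


class FastLikelihood:
    """Index-precomputed forward recursion for repeated evaluation.

    Resolves every per-step cell lookup (survival class/regime, breeding
    age x experience, detection occasion) into integer indices over the
    spec's cell vector once, so each likelihood evaluation is pure array
    arithmetic.  Numerically identical to :func:`batch_loglik`.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.K = spec.K
        self.S = 2 * spec.K + 1
        names = spec.cell_names()
        idx = {n: i for i, n in enumerate(names)}
        self._plans: dict[int, list[tuple]] = {}
        for c in range(spec.n_occasions):
            steps = []
            for t in range(c, spec.n_occasions - 1):
                age_t = t - c
                cls = "first" if age_t == 0 else "adult"
                regime = "cold" if t == spec.cold_spell_step else "normal"
                phi_idx = idx[f"phi[{cls},{regime}]"]
                if spec.experience_on_survival == "additive" and cls == "adult":
                    off_idx = np.array(
                        [-1] + [idx[f"phi_exp[{e}]"] for e in range(1, spec.K)]
                    )
                else:
                    off_idx = None
                age_d = t + 1 - c
                beta_idx = np.full(spec.K, -1, dtype=int)
                if age_d >= spec.a_min:
                    a = min(age_d, spec.a_pool_eff)
                    for e in range(spec.K):
                        cell = f"beta[{a},{e}]"
                        if cell in idx:
                            beta_idx[e] = idx[cell]
                p_idx = idx.get(f"p[{t + 1}]", -1)
                steps.append((phi_idx, off_idx, beta_idx, p_idx))
            self._plans[c] = steps

    def batch_loglik(
        self, vec: np.ndarray, batch: CohortBatch, beta_shift: float = 0.0
    ) -> np.ndarray:
        from scipy.special import expit, logit

        K, S = self.K, self.S
        H = batch.events.shape[0]
        alpha = np.zeros((H, S))
        alpha[:, 0] = 1.0
        logp = np.zeros(H)
        alive = np.ones(H, dtype=bool)
        M = np.zeros((S, S))
        M[S - 1, S - 1] = 1.0
        e1 = np.zeros(S)
        for off, (phi_idx, off_idx, beta_idx, p_idx) in enumerate(self._plans[batch.cohort_index]):
            beta = np.where(beta_idx >= 0, vec[beta_idx], 0.0)
            if beta_shift != 0.0:
                inner = (beta > 0.0) & (beta < 1.0)
                beta[inner] = expit(logit(beta[inner]) + beta_shift)
            base = vec[phi_idx]
            if off_idx is None:
                phi_lv = None
            else:
                lo = logit(base)
                phi_lv = expit(lo + np.where(off_idx >= 0, vec[off_idx], 0.0))
            for e in range(K):
                ph = base if phi_lv is None else phi_lv[e]
                e2 = min(e + 1, K - 1)
                M[2 * e, 2 * e + 1] = ph * beta[e]
                M[2 * e, 2 * e] = ph * (1.0 - beta[e])
                M[2 * e, S - 1] = 1.0 - ph
                M[2 * e + 1, 2 * e2 + 1] = ph * beta[e2]
                M[2 * e + 1, 2 * e2] = ph * (1.0 - beta[e2])
                # breeder rows: zero the stale destinations before writing
                for j in range(K):
                    if j != e2:
                        M[2 * e + 1, 2 * j] = 0.0
                        M[2 * e + 1, 2 * j + 1] = 0.0
                M[2 * e + 1, S - 1] = 1.0 - ph
            p = vec[p_idx] if p_idx >= 0 else 0.0
            e1[1:S - 1:2] = p
            codes = batch.events[:, off + 1]
            alpha = alpha @ M
            w = np.where(codes[:, None] == 1, e1[None, :], 1.0 - e1[None, :])
            alpha *= w
            s = alpha.sum(axis=1)
            alive &= s > 0.0
            s_safe = np.where(s > 0.0, s, 1.0)
            logp += np.where(alive, np.log(s_safe), 0.0)
            alpha /= s_safe[:, None]
        logp[~alive] = -np.inf
        return logp

    def batch_loglik_nodes(
        self, vec: np.ndarray, batch: CohortBatch, shifts: np.ndarray
    ) -> np.ndarray:
        """Forward recursion for several beta shifts at once.

        Returns an (n_shifts, H) array; one quadrature node per row.  The
        per-step matrices differ across nodes only through the shifted
        breeding probabilities, so all nodes advance in a single batched
        matrix product.
        """
        from scipy.special import expit, logit

        K, S = self.K, self.S
        shifts = np.asarray(shifts, dtype=float)
        n = shifts.size
        H = batch.events.shape[0]
        alpha = np.zeros((n, H, S))
        alpha[:, :, 0] = 1.0
        logp = np.zeros((n, H))
        alive = np.ones((n, H), dtype=bool)
        M = np.zeros((n, S, S))
        M[:, S - 1, S - 1] = 1.0
        e1 = np.zeros((n, S))
        for off, (phi_idx, off_idx, beta_idx, p_idx) in enumerate(self._plans[batch.cohort_index]):
            base_beta = np.where(beta_idx >= 0, vec[beta_idx], 0.0)
            beta = np.tile(base_beta, (n, 1))
            inner = (base_beta > 0.0) & (base_beta < 1.0)
            if inner.any():
                beta[:, inner] = expit(
                    logit(base_beta[inner])[None, :] + shifts[:, None]
                )
            base = vec[phi_idx]
            if off_idx is None:
                phi_lv = np.full(K, base)
            else:
                phi_lv = expit(logit(base) + np.where(off_idx >= 0, vec[off_idx], 0.0))
            for e in range(K):
                ph = phi_lv[e]
                e2 = min(e + 1, K - 1)
                M[:, 2 * e, 2 * e + 1] = ph * beta[:, e]
                M[:, 2 * e, 2 * e] = ph * (1.0 - beta[:, e])
                M[:, 2 * e, S - 1] = 1.0 - ph
                M[:, 2 * e + 1, 2 * e2 + 1] = ph * beta[:, e2]
                M[:, 2 * e + 1, 2 * e2] = ph * (1.0 - beta[:, e2])
                M[:, 2 * e + 1, S - 1] = 1.0 - ph
            p = vec[p_idx] if p_idx >= 0 else 0.0
            e1[:, 1:S - 1:2] = p
            codes = batch.events[:, off + 1]
            alpha = np.matmul(alpha, M)
            w = np.where(codes[None, :, None] == 1, e1[:, None, :],
                         1.0 - e1[:, None, :])
            alpha *= w
            s = alpha.sum(axis=2)
            alive &= s > 0.0
            s_safe = np.where(s > 0.0, s, 1.0)
            logp += np.where(alive, np.log(s_safe), 0.0)
            alpha /= s_safe[:, :, None]
        logp[~alive] = -np.inf
        return logp


def event_string_probs(
    spec: ModelSpec,
    params,
    cohort_index: int,
    beta_shift: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Probability of every possible event string for one cohort.

    Enumerates all 2**(T - cohort - 1) post-release code strings (the
    release record itself is code 0) and evaluates each with the forward
    recursion.  Intended for small T: exhaustive totals and identifiability
    Jacobians.
    """
    values = as_values(spec, params)
    n_free = spec.n_occasions - cohort_index - 1
    if n_free > 20:
        raise ValueError("event-string enumeration needs a short occasion axis")
    n = 2 ** n_free
    strings = ((np.arange(n)[:, None] >> np.arange(n_free - 1, -1, -1)) & 1).astype(np.int8)
    events = np.concatenate([np.zeros((n, 1), dtype=np.int8), strings], axis=1)
    batch = CohortBatch(cohort_index, events, np.ones(n))
    lp = batch_loglik(spec, values, batch, beta_shift=beta_shift)
    return events, np.exp(lp)
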