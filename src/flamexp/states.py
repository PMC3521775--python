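"""Hidden-state space and per-step matrices of the experience model.

Biological states track current breeding status and the count of previous
breeding episodes ("local experience"): ``N_e`` = alive, not breeding this
season, with ``e`` previous experiences; ``B_e`` = currently breeding with
``e`` previous experiences; ``DEAD`` absorbs both mortality and permanent
emigration (apparent survival).  The top experience class is pooled
("e or more"): a breeder in ``B_{K-1}`` gains no further experience.

Between two seasons an individual first survives (probability phi), then —
conditional on survival — breeds with probability beta indexed by its
experience count *entering* the destination season.  Leaving a breeding
season increments experience (capped at the pooled level), so ``B_e`` is a
transitory state.  At each occasion a breeder is seen (event code 1) with
probability p; non-breeders are off-colony and never observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "StateSpace",
    "StepRates",
    "build_state_space",
    "transition_matrix",
    "event_matrix",
    "initial_vector",
]


@dataclass(frozen=True)
class StateSpace:
    """Ordered hidden states [N_0, B_0, ..., N_{K-1}, B_{K-1}, DEAD]."""

    max_levels: int
    states: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.max_levels < 2:
            raise ValueError(f"need at least 2 experience levels, got {self.max_levels}")
        labels = []
        for e in range(self.max_levels):
            labels += [f"N{e}", f"B{e}"]
        labels.append("DEAD")
        object.__setattr__(self, "states", tuple(labels))

    @property
    def n_states(self) -> int:
        return 2 * self.max_levels + 1

    def index(self, label: str) -> int:
        return self.states.index(label)

    def N(self, e: int) -> int:
        return 2 * e

    def B(self, e: int) -> int:
        return 2 * e + 1

    @property
    def dead(self) -> int:
        return self.n_states - 1

    def experience_of(self, idx: int) -> int | None:
        """Experience count of a live state index, None for DEAD."""
        return None if idx == self.dead else idx // 2

    def is_breeding(self, idx: int) -> bool:
        return idx != self.dead and idx % 2 == 1


@dataclass
class StepRates:
    """Rates governing one individual-step (one between-season transition
    plus the observation at the destination occasion).

    phi may be a scalar (shared by all live states) or a length-K array of
    per-experience-level survival probabilities (the additive
    experience-on-survival variant).
    """

    phi: float | np.ndarray
    beta_by_level: np.ndarray
    p: float

    def __post_init__(self) -> None:
        self.beta_by_level = np.asarray(self.beta_by_level, dtype=float)
        phi = np.asarray(self.phi, dtype=float)
        for name, val in [("phi", phi), ("beta", self.beta_by_level),
                          ("p", np.asarray(self.p, dtype=float))]:
            if np.any(val < 0) or np.any(val > 1):
                raise ValueError(f"{name} outside [0, 1]: {val}")

    def phi_for_level(self, e: int, K: int) -> float:
        phi = np.asarray(self.phi, dtype=float)
        if phi.ndim == 0:
            return float(phi)
        if phi.shape != (K,):
            raise ValueError(f"phi must be scalar or length-{K}, got {phi.shape}")
        return float(phi[e])


def build_state_space(K: int) -> StateSpace:
    """State space with K experience classes (top one pooled), 2K+1 states."""
    return StateSpace(K)


def transition_matrix(ss: StateSpace, r: StepRates) -> np.ndarray:
    """Row-stochastic one-step transition matrix.

    From ``N_e``: stay alive with phi, then breed (-> ``B_e``) with
    beta_e or skip (-> ``N_e``).  From ``B_e``: experience increments to
    ``e' = min(e+1, K-1)``; breed (-> ``B_e'``) with beta_e' or skip
    (-> ``N_e'``).  Death/emigration with 1-phi; DEAD is absorbing.
    """
    K = ss.max_levels
    beta = r.beta_by_level
    if beta.shape != (K,):
        raise ValueError(f"beta_by_level must have length {K}, got {beta.shape}")
    M = np.zeros((ss.n_states, ss.n_states))
    for e in range(K):
        phi = r.phi_for_level(e, K)
        # non-breeder keeps its experience count
        M[ss.N(e), ss.B(e)] = phi * beta[e]
        M[ss.N(e), ss.N(e)] = phi * (1.0 - beta[e])
        M[ss.N(e), ss.dead] = 1.0 - phi
        # breeder gains one experience (capped at the pooled top level)
        e2 = min(e + 1, K - 1)
        M[ss.B(e), ss.B(e2)] = phi * beta[e2]
        M[ss.B(e), ss.N(e2)] = phi * (1.0 - beta[e2])
        M[ss.B(e), ss.dead] = 1.0 - phi
    M[ss.dead, ss.dead] = 1.0
    return M


def event_matrix(ss: StateSpace, p: float) -> np.ndarray:
    """States x {code 0, code 1} emission matrix.

    A breeder is seen breeding (code 1) with probability p; non-breeders
    are off-colony and DEAD birds are gone, so both emit code 0 surely.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p outside [0, 1]: {p}")
    E = np.zeros((ss.n_states, 2))
    for idx in range(ss.n_states):
        if ss.is_breeding(idx):
            E[idx, 0] = 1.0 - p
            E[idx, 1] = p
        else:
            E[idx, 0] = 1.0
    return E


def initial_vector(ss: StateSpace) -> np.ndarray:
    """Release distribution: a ringed chick starts in N_0 with certainty."""
    v = np.zeros(ss.n_states)
    v[ss.N(0)] = 1.0
    return v
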