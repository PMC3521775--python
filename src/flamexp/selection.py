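"""QAIC model selection, identifiability diagnostics and small utilities.

QAIC corrects AIC for overdispersion by dividing the deviance by a variance
inflation factor c-hat estimated externally from a goodness-of-fit test of
a general reference model:

    QAIC = deviance / c-hat + 2 k,

with k the model rank (number of separately estimable parameters).
Parameter redundancy — e.g. first-year survival confounded with the
breeding probabilities of inexperienced birds — is diagnosed numerically:
the rank of the Jacobian of all encounter-history-class probabilities with
respect to the free coefficients, with near-null-space loadings naming the
confounded cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import ModelSpec, ParameterMap
from .likelihood import event_string_probs

__all__ = [
    "qaic",
    "delta_qaic",
    "comparison_table",
    "RankDiagnostic",
    "numeric_rank",
    "emigration_adjust",
    "emigration_fraction",
    "true_survival_from_apparent",
]


def qaic(deviance: float, k: int, chat: float) -> float:
    """QAIC = deviance / c-hat + 2k."""
    if chat <= 0:
        raise ValueError("chat must be > 0")
    return deviance / chat + 2.0 * k


def delta_qaic(
    candidate: tuple[float, int], reference: tuple[float, int], chat: float
) -> float:
    """QAIC(candidate) - QAIC(reference), each given as (deviance, k)."""
    return qaic(*candidate, chat) - qaic(*reference, chat)


def comparison_table(
    models: Iterable[tuple[str, float, int]],
    reference: str,
    chat: float,
) -> pd.DataFrame:
    """Model-comparison table: rows (name, deviance, k) -> QAIC and
    Delta-QAIC against the named reference model, sorted ascending by QAIC
    (ties broken by smaller k)."""
    rows = [
        {"model": name, "deviance": dev, "k": k, "qaic": qaic(dev, k, chat)}
        for name, dev, k in models
    ]
    df = pd.DataFrame(rows)
    if reference not in set(df["model"]):
        raise ValueError(f"reference model {reference!r} not among the rows")
    ref_qaic = float(df.loc[df["model"] == reference, "qaic"].iloc[0])
    df["delta_qaic"] = df["qaic"] - ref_qaic
    return df.sort_values(["qaic", "k"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# identifiability

@dataclass
class RankDiagnostic:
    """Numeric-rank identifiability report.

    ``rank`` is the median numerical rank of the (column-equilibrated)
    probability Jacobian over the evaluation points; ``deficiency`` is
    ``n_free - rank``.  ``loadings`` holds, per free cell, the factor by
    which the smallest singular value recovers when that cell is removed
    from the model ("repair ratio"): cells that take part in the redundancy
    repair it by orders of magnitude, uninvolved cells leave it unchanged.
    """

    n_free: int
    rank: int
    ranks: list[int]
    loadings: pd.Series
    repair_threshold: float = 100.0

    @property
    def deficiency(self) -> int:
        return self.n_free - self.rank

    @property
    def full_rank(self) -> bool:
        return self.deficiency == 0

    @property
    def confounded(self) -> list[str]:
        if self.full_rank:
            return []
        return list(self.loadings.index[self.loadings > self.repair_threshold])

    def __str__(self) -> str:
        head = (f"numeric rank {self.rank} of {self.n_free} free cells "
                f"(deficiency {self.deficiency})")
        if self.full_rank:
            return head + ": all cells separately estimable"
        return head + "; confounded cells: " + ", ".join(self.confounded)


def numeric_rank(
    spec: ModelSpec,
    cohort_indices: Sequence[int],
    x0: np.ndarray | None = None,
    n_points: int = 3,
    seed: int = 0,
    rtol: float = 1e-6,
    step: float = 1e-5,
) -> RankDiagnostic:
    """Numeric replacement of the hybrid symbolic-numeric redundancy check.

    Stacks the probabilities of every possible encounter-history class for
    the given cohorts, differentiates them (central differences) with
    respect to the free link-scale coefficients, column-equilibrates the
    Jacobian (rank is scale-invariant; equilibration separates exact
    redundancies from merely weak cells), and takes the numerical rank
    (singular values above ``rtol`` times the largest) at ``n_points``
    random interior points.

    When a deficiency is found, each cell is scored by how much the
    smallest singular value recovers once that cell's column is removed:
    a cell involved in the redundancy repairs it by orders of magnitude.

    Exhaustive history-class enumeration restricts this to short occasion
    axes (the diagnostic is about model *structure*, not data size).
    """
    if spec.random_effect is not None:
        raise ValueError("numeric_rank applies to fixed-effect structures")
    pm = ParameterMap(spec)
    if pm.n_free == 0:
        raise ValueError("no free cells")
    if x0 is not None and np.max(np.abs(x0)) > 10.0:
        raise ValueError("evaluation point is on the boundary (|coef| > 10)")
    rng = np.random.default_rng(seed)

    def prob_vector(x: np.ndarray) -> np.ndarray:
        values = pm.natural_values(x)
        return np.concatenate([
            event_string_probs(spec, values, c)[1] for c in cohort_indices
        ])

    ranks: list[int] = []
    repair = np.ones(pm.n_free)
    for j in range(n_points):
        if x0 is not None and j == 0:
            x = np.asarray(x0, dtype=float)
        else:
            x = rng.uniform(-1.0, 1.0, size=pm.n_free)
        J = np.empty((prob_vector(x).size, pm.n_free))
        for i in range(pm.n_free):
            xp, xm = x.copy(), x.copy()
            xp[i] += step
            xm[i] -= step
            J[:, i] = (prob_vector(xp) - prob_vector(xm)) / (2 * step)
        norms = np.linalg.norm(J, axis=0)
        if np.any(norms == 0.0):
            dead = [pm.free_names[i] for i in np.nonzero(norms == 0.0)[0]]
            raise ValueError(f"cells without influence on any history: {dead}")
        Jn = J / norms
        s = np.linalg.svd(Jn, compute_uv=False)
        r = int(np.sum(s > rtol * s[0]))
        ranks.append(r)
        if r < pm.n_free:
            s_min = s[-1]
            for i in range(pm.n_free):
                s_i = np.linalg.svd(np.delete(Jn, i, axis=1), compute_uv=False)
                repair[i] = max(repair[i], s_i[-1] / s_min)
    rank = int(np.median(ranks))
    loadings = pd.Series(repair, index=pm.free_names, name="repair_ratio")
    return RankDiagnostic(pm.n_free, rank, ranks, loadings)


# ---------------------------------------------------------------------------
# emigration arithmetic

def emigration_adjust(true_survival: float, emigration_fraction: float) -> float:
    """Apparent survival = true survival x (1 - permanent-emigration share)."""
    _check01(true_survival, "true_survival")
    _check01(emigration_fraction, "emigration_fraction")
    return true_survival * (1.0 - emigration_fraction)


def emigration_fraction(apparent: float, true_survival: float) -> float:
    """Share of apparent losses due to permanent emigration."""
    _check01(apparent, "apparent")
    _check01(true_survival, "true_survival")
    if true_survival == 0:
        raise ZeroDivisionError("true survival of 0 leaves emigration undefined")
    return 1.0 - apparent / true_survival

def true_survival_from_apparent(apparent: float, emigration_fraction: float) -> float:
    """True survival implied by apparent survival and an emigration share."""
    _check01(apparent, "apparent")
    _check01(emigration_fraction, "emigration_fraction")
    if emigration_fraction == 1:
        raise ZeroDivisionError("emigration of 1 leaves true survival undefined")
    return apparent / (1.0 - emigration_fraction)


def _check01(x: float, name: str) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {x}")
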