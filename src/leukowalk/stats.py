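"""Statistical primitives: two-sample KS, Spearman rank correlation, Pareto
dominance machinery and the Λ centre-of-front score.

All objectives are minimised.  A candidate's objective vector holds the KS
distances between simulated and target motility distributions (translation,
turn, meandering index) — or, in the MSD variant, the absolute difference of
log-log MSD regression slopes as the third entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ObjectiveVector",
    "ParetoMember",
    "ParetoFront",
    "ks_two_sample",
    "spearman_rho",
    "dominates",
    "pareto_filter",
    "nondominated_proportion",
    "lambda_score",
]


@dataclass(frozen=True)
class ObjectiveVector:
    """Ordered objective scores (translation, turn, third).

    ``ks_based`` is False in MSD mode, where the third entry is an
    unbounded |slope difference| and Λ is meaningless.
    """

    values: tuple[float, float, float]
    ks_based: bool = True

    def __post_init__(self):
        v = tuple(float(x) for x in self.values)
        if len(v) != 3:
            raise ValueError("objective vector must have exactly 3 entries")
        if not all(np.isfinite(v)) or any(x < 0 for x in v):
            raise ValueError(f"objectives must be finite and >= 0, got {v}")
        if self.ks_based and any(x > 1 + 1e-12 for x in v):
            raise ValueError(f"KS objectives must lie in [0, 1], got {v}")
        object.__setattr__(self, "values", v)

    def __iter__(self):
        return iter(self.values)


@dataclass(frozen=True)
class ParetoMember:
    """A candidate parameter vector with its objective scores."""

    params: object
    objectives: ObjectiveVector
    origin: str = "training"
    uid: int = -1


class ParetoFront:
    """A set of mutually non-dominated members (checked on construction).

    Exactly-equal objective vectors do not dominate each other, so
    duplicates may coexist (front sizes are reported downstream, so they
    are never silently deduplicated).
    """

    def __init__(self, members: Iterable[ParetoMember]):
        members = list(members)
        if not members:
            raise ValueError("a Pareto front cannot be empty")
        for i, a in enumerate(members):
            for j, b in enumerate(members):
                if i != j and dominates(a.objectives, b.objectives):
                    raise ValueError("front contains dominated members")
        self.members = members

    def __len__(self):
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def objective_array(self) -> np.ndarray:
        return np.array([m.objectives.values for m in self.members])


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov D and asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS statistic requires two non-empty samples")
    res = _sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with tie correction (mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length sequences of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p = _sps.spearmanr(x, y)
    return float(rho), float(p)


def dominates(a: ObjectiveVector, b: ObjectiveVector) -> bool:
    """True iff a is at least as good on all objectives and strictly better
    on at least one (minimisation)."""
    av, bv = a.values, b.values
    return all(x <= y for x, y in zip(av, bv)) and any(x < y for x, y in zip(av, bv))


def pareto_filter(members: Sequence[ParetoMember]) -> ParetoFront:
    """Extract exactly the non-dominated members."""
    members = list(members)
    objs = np.array([m.objectives.values for m in members])
    keep = _nondominated_mask(objs)
    return ParetoFront([m for m, k in zip(members, keep) if k])


def _nondominated_mask(objs: np.ndarray) -> np.ndarray:
    """Vectorised non-domination scan: keep[i] unless some j dominates i."""
    n = objs.shape[0]
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        le = (objs <= objs[i]).all(axis=1)
        lt = (objs < objs[i]).any(axis=1)
        dominated_by = le & lt
        dominated_by[i] = False
        if dominated_by.any():
            keep[i] = False
    return keep


def nondominated_proportion(f1: ParetoFront, f2: ParetoFront) -> float:
    """Percentage of f1's members not dominated by any member of f2."""
    o1, o2 = f1.objective_array(), f2.objective_array()
    count = 0
    for row in o1:
        le = (o2 <= row).all(axis=1)
        lt = (o2 < row).any(axis=1)
        if not (le & lt).any():
            count += 1
    return 100.0 * count / len(f1)


def lambda_score(m: ParetoMember, alpha: float = 1.0) -> float:
    """Λ = α·mean(KS)² + Σ_o (KS_o − mean(KS))².

    Low for solutions with low mean objective KS and small spread — the
    balanced centre of the front.  Only defined for KS-based objectives;
    mixing a KS distance with an unbounded slope difference is nonsensical.
    Λ values are comparable only for a common α.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not m.objectives.ks_based:
        raise ValueError("lambda_score requires KS-based objectives (not MSD mode)")
    ks = np.asarray(m.objectives.values)
    mean = ks.mean()
    return float(alpha * mean**2 + np.sum((ks - mean) ** 2))
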