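"""Non-domination logic, constrained NSGA-II over the surrogates, and
exact hypervolume for up to three objectives.

Convention: every objective is maximized (Tm, kD, retained monomer all
"higher is better").  Constraint handling follows a strict
discard-and-retry rule: a crossover/mutation move that produces an
infeasible child is thrown away and re-attempted, so the evolving
population never contains infeasible points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ParetoCandidate",
    "SearchError",
    "dominates",
    "non_dominated_filter",
    "non_dominated_mask",
    "hypervolume",
    "point_hypervolume",
    "nsga2_front",
]


class SearchError(RuntimeError):
    """Feasible-region sampling exhausted its retry budget."""


@dataclass(frozen=True)
class ParetoCandidate:
    """A feasible design-space point with surrogate-predicted objectives."""

    point: np.ndarray
    predicted: np.ndarray
    feasible: bool = True


def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff a >= b in every objective and > in at least one."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return bool(np.all(a >= b) and np.any(a > b))


def non_dominated_mask(Y: np.ndarray) -> np.ndarray:
    """Boolean mask of rows of Y dominated by no other row."""
    Y = np.asarray(Y, dtype=float)
    n = len(Y)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        if not mask[i]:
            continue
        ge = np.all(Y >= Y[i], axis=1)
        gt = np.any(Y > Y[i], axis=1)
        dominators = ge & gt
        dominators[i] = False
        if dominators.any():
            mask[i] = False
    return mask


def non_dominated_filter(Y: np.ndarray) -> np.ndarray:
    """Rows of Y not dominated by any other row, original order kept."""
    Y = np.asarray(Y, dtype=float)
    if len(Y) == 0:
        return Y
    return Y[non_dominated_mask(Y)]


def point_hypervolume(y: np.ndarray, ref: np.ndarray) -> float:
    """Volume of the single box [ref, y]: prod(max(0, y_i - ref_i))."""
    y = np.asarray(y, dtype=float)
    ref = np.asarray(ref, dtype=float)
    return float(np.prod(np.maximum(0.0, y - ref)))


def _hv2d(Y: np.ndarray, ref: np.ndarray) -> float:
    keep = np.all(Y > ref, axis=1)
    Y = Y[keep]
    if len(Y) == 0:
        return 0.0
    Y = Y[non_dominated_mask(Y)]
    order = np.argsort(-Y[:, 0], kind="stable")
    Y = Y[order]
    area = 0.0
    prev_y2 = ref[1]
    for y1, y2 in Y:
        if y2 > prev_y2:
            area += (y1 - ref[0]) * (y2 - prev_y2)
            prev_y2 = y2
    return area


def hypervolume(Y: np.ndarray, ref: np.ndarray) -> float:
    """Lebesgue measure of the union of boxes [ref, y] over y in Y.

    Exact for 1-3 objectives (maximization).  Points that do not strictly
    dominate the reference contribute nothing.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    ref = np.asarray(ref, dtype=float)
    if Y.size == 0:
        return 0.0
    m = Y.shape[1]
    keep = np.all(Y > ref, axis=1)
    Y = Y[keep]
    if len(Y) == 0:
        return 0.0
    if m == 1:
        return float(Y.max() - ref[0])
    if m == 2:
        return float(_hv2d(Y, ref))
    if m == 3:
        # sweep the third coordinate: between consecutive z-levels the
        # dominated region's cross-section is the 2-D hypervolume of all
        # points at or above the upper level
        z = np.unique(Y[:, 2])[::-1]
        levels = np.concatenate([z, [ref[2]]])
        vol = 0.0
        for upper, lower in zip(levels[:-1], levels[1:]):
            slab = Y[Y[:, 2] >= upper][:, :2]
            vol += _hv2d(slab, ref[:2]) * (upper - lower)
        return float(vol)
    raise NotImplementedError("exact hypervolume implemented for <= 3 objectives")


# ---------------------------------------------------------------------------
# NSGA-II
# ---------------------------------------------------------------------------


def _fast_non_dominated_ranks(Y: np.ndarray) -> np.ndarray:
    """Pareto rank (0 = best front) of each row, maximization."""
    n = len(Y)
    ranks = np.full(n, -1, dtype=int)
    remaining = np.arange(n)
    r = 0
    while len(remaining):
        sub = Y[remaining]
        front = non_dominated_mask(sub)
        ranks[remaining[front]] = r
        remaining = remaining[~front]
        r += 1
    return ranks


def _crowding_distance(Y: np.ndarray) -> np.ndarray:
    n, m = Y.shape
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for j in range(m):
        order = np.argsort(Y[:, j], kind="stable")
        span = Y[order[-1], j] - Y[order[0], j]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span <= 0:
            continue
        dist[order[1:-1]] += (Y[order[2:], j] - Y[order[:-2], j]) / span
    return dist


def _sbx_crossover(p1: np.ndarray, p2: np.ndarray, rng, eta: float, prob: float):
    """Simulated binary crossover, per-gene, clipped to the unit cube."""
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() >= prob:
        return c1, c2
    for j in range(len(p1)):
        if rng.random() > 0.5 or abs(p1[j] - p2[j]) < 1e-14:
            continue
        u = rng.random()
        if u <= 0.5:
            beta = (2 * u) ** (1 / (eta + 1))
        else:
            beta = (1 / (2 * (1 - u))) ** (1 / (eta + 1))
        c1[j] = 0.5 * ((1 + beta) * p1[j] + (1 - beta) * p2[j])
        c2[j] = 0.5 * ((1 - beta) * p1[j] + (1 + beta) * p2[j])
    return np.clip(c1, 0, 1), np.clip(c2, 0, 1)


def _polynomial_mutation(x: np.ndarray, rng, eta: float, prob: float) -> np.ndarray:
    y = x.copy()
    for j in range(len(x)):
        if rng.random() >= prob:
            continue
        u = rng.random()
        if u < 0.5:
            delta = (2 * u) ** (1 / (eta + 1)) - 1
        else:
            delta = 1 - (2 * (1 - u)) ** (1 / (eta + 1))
        y[j] = x[j] + delta
    return np.clip(y, 0, 1)


def _sample_feasible(feasibility: Callable, n: int, dim: int, rng, retry_cap: int) -> np.ndarray:
    points = []
    attempts = 0
    while len(points) < n:
        u = rng.random(dim)
        attempts += 1
        if feasibility(u):
            points.append(u)
            attempts = 0
        elif attempts > retry_cap:
            raise SearchError(
                f"could not draw a feasible point in {retry_cap} attempts"
            )
    return np.array(points)


def nsga2_front(
    models: Sequence,
    feasibility: Callable[[np.ndarray], bool],
    pop: int = 100,
    gens: int = 100,
    rng: np.random.Generator | int | None = None,
    dim: int = 6,
    retry_cap: int = 1000,
    eta_crossover: float = 15.0,
    p_crossover: float = 0.9,
    eta_mutation: float = 20.0,
    p_mutation: float | None = None,
) -> list[ParetoCandidate]:
    """Evolve a feasible Pareto-front approximation of the surrogate means.

    ``models`` is a sequence of fitted surrogates (one per objective, all
    maximized); ``feasibility`` is a predicate on unit-cube points.
    Genetic moves whose children violate a constraint are discarded and
    re-attempted (up to ``retry_cap`` per slot).  Returns the mutually
    non-dominated, de-duplicated members of the final population.
    """
    rng = np.random.default_rng(rng)
    if p_mutation is None:
        p_mutation = 1.0 / dim

    def evaluate(X: np.ndarray) -> np.ndarray:
        return np.column_stack([m.predict(X) for m in models])

    X = _sample_feasible(feasibility, pop, dim, rng, retry_cap)
    Y = evaluate(X)

    for _ in range(gens):
        ranks = _fast_non_dominated_ranks(Y)
        crowd = np.zeros(len(Y))
        for r in np.unique(ranks):
            idx = np.where(ranks == r)[0]
            crowd[idx] = _crowding_distance(Y[idx])

        def tournament() -> int:
            i, j = rng.integers(0, len(Y), size=2)
            if ranks[i] != ranks[j]:
                return i if ranks[i] < ranks[j] else j
            return i if crowd[i] >= crowd[j] else j

        children: list[np.ndarray] = []
        while len(children) < pop:
            p1, p2 = X[tournament()], X[tournament()]
            for _attempt in range(retry_cap):
                c1, c2 = _sbx_crossover(p1, p2, rng, eta_crossover, p_crossover)
                c1 = _polynomial_mutation(c1, rng, eta_mutation, p_mutation)
                c2 = _polynomial_mutation(c2, rng, eta_mutation, p_mutation)
                accepted = [c for c in (c1, c2) if feasibility(c)]
                if accepted:
                    children.extend(accepted)
                    break
            else:
                raise SearchError("genetic move retry budget exhausted")
        children = children[:pop]
        Xc = np.array(children)
        Yc = evaluate(Xc)

        X_all = np.vstack([X, Xc])
        Y_all = np.vstack([Y, Yc])
        ranks_all = _fast_non_dominated_ranks(Y_all)
        selected: list[int] = []
        for r in np.unique(ranks_all):
            idx = np.where(ranks_all == r)[0]
            if len(selected) + len(idx) <= pop:
                selected.extend(idx.tolist())
            else:
                d = _crowding_distance(Y_all[idx])
                order = np.argsort(-d, kind="stable")
                selected.extend(idx[order[: pop - len(selected)]].tolist())
                break
        X, Y = X_all[selected], Y_all[selected]

    mask = non_dominated_mask(Y)
    Xf, Yf = X[mask], Y[mask]
    _, unique_idx = np.unique(np.round(Xf, 12), axis=0, return_index=True)
    unique_idx = np.sort(unique_idx)
    return [
        ParetoCandidate(point=Xf[i].copy(), predicted=Yf[i].copy())
        for i in unique_idx
    ]
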