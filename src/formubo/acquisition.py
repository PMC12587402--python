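"""Acquisition: exploit/explore route choice, Pareto-point selection by
combined distance to prior observations, Steinerberger-sum space-filling
exploration, and greedy Kriging-believer batching.

Each suggestion draws a route: with probability ``p_exploit`` (default
0.75) the next experiment is the Pareto-front candidate farthest from
what is already known (a max-min distance rule combining variable space
and standardized objective space); otherwise a space-filling point is
found by minimizing the Steinerberger proximity sum over the feasible
region.  Batches are assembled greedily: after each pick, every
objective surrogate is refit with the pick's posterior mean treated as a
real observation (Kriging believer).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .pareto import ParetoCandidate, SearchError, nsga2_front

__all__ = [
    "AcquisitionConfig",
    "Suggestion",
    "choose_route",
    "exploit_candidate",
    "steinerberger_sum",
    "explore_candidate",
    "propose_batch",
]

#: score assigned where the Steinerberger kernel is singular or a point
#: is infeasible; large enough to dominate any regular score.
SENTINEL = 1e12


@dataclass(frozen=True)
class AcquisitionConfig:
    """Batch-acquisition settings.

    p_exploit : probability of the exploitation route per suggestion.
    batch_size : suggestions per iteration (Kriging-believer greedy).
    explore_starts : random restarts of the exploration minimizer.
    distance_weight : weight w on the objective-space distance in the
        exploit score w*d_obj + (1-w)*d_var (both max-normalized).
    retry_cap : feasible-sampling retry budget.
    pop, gens : NSGA-II population size and generation count.
    """

    p_exploit: float = 0.75
    batch_size: int = 5
    explore_starts: int = 20
    distance_weight: float = 0.5
    retry_cap: int = 1000
    pop: int = 100
    gens: int = 100
    explore_maxiter: int = 200

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_exploit <= 1.0:
            raise ValueError("p_exploit must lie in [0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class Suggestion:
    """One proposed experiment: unit-cube point, route label, and the
    surrogates' fantasy predictions at selection time."""

    point: np.ndarray
    route: str
    predicted: np.ndarray | None = None


def choose_route(rng: np.random.Generator, p_exploit: float = 0.75) -> str:
    """Bernoulli route draw: 'exploit' with probability p_exploit."""
    return "exploit" if rng.random() < p_exploit else "explore"


def exploit_candidate(
    front: Sequence[ParetoCandidate],
    X_hist: np.ndarray,
    Y_hist_std: np.ndarray,
    standardize: Callable[[np.ndarray], np.ndarray],
    w: float = 0.5,
) -> ParetoCandidate:
    """Pick the front member farthest from prior observations.

    For each candidate, d_var is its minimum Euclidean distance to the
    observed unit-cube points and d_obj the minimum distance of its
    predicted objectives to observed objectives, both in standardized
    objective space; each is divided by its maximum over the front and the
    candidate maximizing w*d_obj + (1-w)*d_var is returned (ties to the
    lowest index).
    """
    if len(front) == 0:
        raise SearchError("empty Pareto front; fall back to exploration")
    X_hist = np.atleast_2d(X_hist)
    Y_hist_std = np.atleast_2d(Y_hist_std)
    pts = np.array([c.point for c in front])
    preds = standardize(np.array([c.predicted for c in front]))
    d_var = np.min(np.linalg.norm(pts[:, None, :] - X_hist[None, :, :], axis=2), axis=1)
    d_obj = np.min(np.linalg.norm(preds[:, None, :] - Y_hist_std[None, :, :], axis=2), axis=1)
    if d_var.max() > 0:
        d_var = d_var / d_var.max()
    if d_obj.max() > 0:
        d_obj = d_obj / d_obj.max()
    score = w * d_obj + (1.0 - w) * d_var
    return front[int(np.argmax(score))]


def steinerberger_sum(x: np.ndarray, history_points: np.ndarray) -> float:
    """Proximity of x to the explored points.

    S(x) = sum over history p of prod over dims d of
    (1 - log(2 sin(pi |x_d - p_d|))); larger means closer.  At a
    coordinate coincidence the log diverges; a large sentinel is returned
    instead of +inf.
    """
    x = np.asarray(x, dtype=float)
    P = np.atleast_2d(np.asarray(history_points, dtype=float))
    diff = np.abs(x[None, :] - P)
    s = np.sin(np.pi * diff)
    if np.any(s <= 0):
        return SENTINEL
    terms = 1.0 - np.log(2.0 * s)
    return float(np.sum(np.prod(terms, axis=1)))


def explore_candidate(
    history_points: np.ndarray,
    feasibility: Callable[[np.ndarray], bool],
    rng: np.random.Generator | int | None = None,
    n_starts: int = 20,
    retry_cap: int = 1000,
    maxiter: int = 200,
) -> np.ndarray:
    """Space-filling point: minimize the Steinerberger sum over the
    feasible region from ``n_starts`` random feasible starts.

    The minimizer is a bounded derivative-free simplex search; infeasible
    or out-of-cube iterates receive the sentinel score (rejection).  The
    best feasible point ever evaluated is returned.
    """
    rng = np.random.default_rng(rng)
    P = np.atleast_2d(np.asarray(history_points, dtype=float))
    dim = P.shape[1]

    best = {"x": None, "score": np.inf}

    def objective(x: np.ndarray) -> float:
        if np.any(x < 0) or np.any(x > 1) or not feasibility(x):
            return SENTINEL
        s = steinerberger_sum(x, P)
        if s < best["score"]:
            best["score"], best["x"] = s, x.copy()
        return s

    starts = []
    attempts = 0
    while len(starts) < n_starts:
        u = rng.random(dim)
        attempts += 1
        if feasibility(u):
            starts.append(u)
            attempts = 0
        elif attempts > retry_cap:
            raise SearchError("no feasible exploration start found")
    for x0 in starts:
        objective(x0)
        minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-8},
        )
    if best["x"] is None:
        raise SearchError("exploration found no feasible point")
    return best["x"]


def propose_batch(
    models: Sequence,
    X_hist: np.ndarray,
    Y_hist: np.ndarray,
    feasibility: Callable[[np.ndarray], bool],
    config: AcquisitionConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[Suggestion]:
    """Greedy Kriging-believer batch of ``config.batch_size`` suggestions.

    For each slot: draw the route; exploitation builds an NSGA-II front on
    the current (fantasy-augmented) surrogates and applies the combined
    distance rule, exploration minimizes the Steinerberger sum over the
    fantasy history.  After each pick every surrogate is refit with its
    posterior mean at the pick as a believed observation.  A duplicate
    pick is perturbed and re-checked once, then raises.
    """
    config = AcquisitionConfig() if config is None else config
    rng = np.random.default_rng(rng)
    models = list(models)
    X_f = np.atleast_2d(np.asarray(X_hist, dtype=float)).copy()
    Y_f = np.atleast_2d(np.asarray(Y_hist, dtype=float)).copy()

    def standardize(Y: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [(Y[:, j] - m.y_mean_) / m.y_sd_ for j, m in enumerate(models)]
        )

    suggestions: list[Suggestion] = []
    for _ in range(config.batch_size):
        route = choose_route(rng, config.p_exploit)
        if route == "exploit":
            front = nsga2_front(
                models,
                feasibility,
                pop=config.pop,
                gens=config.gens,
                rng=rng,
                dim=X_f.shape[1],
                retry_cap=config.retry_cap,
            )
            try:
                cand = exploit_candidate(
                    front, X_f, standardize(Y_f), standardize, config.distance_weight
                )
                point = cand.point
            except SearchError:
                route = "explore"
                point = explore_candidate(
                    X_f, feasibility, rng, config.explore_starts,
                    config.retry_cap, config.explore_maxiter,
                )
        else:
            point = explore_candidate(
                X_f, feasibility, rng, config.explore_starts,
                config.retry_cap, config.explore_maxiter,
            )

        if len(suggestions) and np.min(
            np.linalg.norm(np.array([s.point for s in suggestions]) - point, axis=1)
        ) < 1e-9:
            point = np.clip(point + rng.normal(0.0, 1e-3, size=len(point)), 0, 1)
            if not feasibility(point):
                raise SearchError("duplicate suggestion; perturbation infeasible")

        fantasy = np.array([float(m.predict(point.reshape(1, -1))[0]) for m in models])
        models = [m.fantasize(point) for m in models]
        X_f = np.vstack([X_f, point])
        Y_f = np.vstack([Y_f, fantasy])
        suggestions.append(Suggestion(point=point, route=route, predicted=fantasy))
    return suggestions
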