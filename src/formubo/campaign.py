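"""Campaign orchestration: uniform feasible initialization, sequential
batch iterations against a measurement source, an append-only ledger, and
the convergence/correlation diagnostics (hypervolume trace, prediction
MAE trace, Spearman correlations, per-formulation hypervolume).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import chemistry
from .acquisition import AcquisitionConfig, propose_batch
from .chemistry import (
    FORMULATION_COLUMNS,
    OBJECTIVE_COLUMNS,
    DesignSpace,
    decode_point,
    feasible_predicate,
)
from .pareto import hypervolume, non_dominated_mask, point_hypervolume
from .surrogate import ObjectiveGP
from .virtual_lab import Observation

__all__ = [
    "CampaignConfig",
    "CampaignState",
    "initialize_campaign",
    "run_iteration",
    "run_campaign",
    "hypervolume_trace",
    "prediction_mae_trace",
    "per_formulation_hypervolume",
    "spearman",
    "fit_surrogates",
]

LEDGER_COLUMNS = ("iteration", "route", "u0", "u1", "u2", "u3", "u4", "u5") + tuple(
    FORMULATION_COLUMNS
) + tuple(OBJECTIVE_COLUMNS)

OBJECTIVE_NAMES = ("Tm", "kD", "RM")


@dataclass(frozen=True)
class CampaignConfig:
    """Full declarative configuration of a campaign."""

    space: DesignSpace = field(default_factory=DesignSpace)
    n_init: int = 13
    batch_size: int = 5
    n_iterations: int = 4
    p_exploit: float = 0.75
    pop: int = 100
    gens: int = 100
    explore_starts: int = 20
    distance_weight: float = 0.5
    retry_cap: int = 1000
    gp_restarts: int = 9
    seed: int = 0

    def acquisition(self) -> AcquisitionConfig:
        return AcquisitionConfig(
            p_exploit=self.p_exploit,
            batch_size=self.batch_size,
            explore_starts=self.explore_starts,
            distance_weight=self.distance_weight,
            retry_cap=self.retry_cap,
            pop=self.pop,
            gens=self.gens,
        )


@dataclass
class CampaignState:
    """Append-only campaign ledger plus RNG state and model cache."""

    config: CampaignConfig
    rng: np.random.Generator
    observations: list[Observation] = field(default_factory=list)
    points: list[np.ndarray] = field(default_factory=list)
    models: dict | None = None

    @property
    def n_iterations_done(self) -> int:
        if not self.observations:
            return 0
        return max(o.iteration for o in self.observations)

    def X(self) -> np.ndarray:
        return np.array(self.points)

    def Y(self) -> np.ndarray:
        return np.array([o.objectives for o in self.observations])

    def ledger(self) -> pd.DataFrame:
        rows = []
        for u, obs in zip(self.points, self.observations):
            row = {"iteration": obs.iteration, "route": obs.route}
            row.update({f"u{i}": u[i] for i in range(len(u))})
            row.update(obs.formulation.to_row())
            row.update(dict(zip(OBJECTIVE_COLUMNS, obs.objectives)))
            rows.append(row)
        return pd.DataFrame(rows, columns=list(LEDGER_COLUMNS))


def fit_surrogates(
    X: np.ndarray, Y: np.ndarray, n_restarts: int = 9, seeds=(0, 1, 2)
) -> list[ObjectiveGP]:
    """One independent GP per objective column of Y."""
    return [
        ObjectiveGP(name=name, n_restarts=n_restarts, random_state=int(seed)).fit(X, Y[:, j])
        for j, (name, seed) in enumerate(zip(OBJECTIVE_NAMES, seeds))
    ]


def sample_initial_points(
    config: CampaignConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    """Uniform unit-cube draws rejection-sampled to feasibility."""
    is_feasible = feasible_predicate(config.space)
    points: list[np.ndarray] = []
    attempts = 0
    while len(points) < config.n_init:
        u = rng.random(6)
        attempts += 1
        if is_feasible(u):
            points.append(u)
            attempts = 0
        elif attempts > config.retry_cap:
            raise ValueError(
                "initialization rejection cap exceeded; constraint window too tight"
            )
    return points


def initialize_campaign(config: CampaignConfig, lab, rng=None) -> CampaignState:
    """Draw ``n_init`` feasible uniform points, measure them, and record
    them as iteration 0 with route label 'init'."""
    rng = np.random.default_rng(config.seed if rng is None else rng)
    state = CampaignState(config=config, rng=rng)
    for u in sample_initial_points(config, rng):
        form = decode_point(u, config.space)
        obs = lab.measure(form)
        obs.iteration = 0
        obs.route = "init"
        state.points.append(u)
        state.observations.append(obs)
    return state


def run_iteration(state: CampaignState, lab) -> CampaignState:
    """Fit the surrogates on the ledger, propose a Kriging-believer batch,
    measure it, and append the results under the next iteration index."""
    if len(state.observations) < 2:
        raise ValueError("need at least 2 observations before iterating")
    cfg = state.config
    seeds = state.rng.integers(0, 2**31 - 1, size=3)
    models = fit_surrogates(state.X(), state.Y(), cfg.gp_restarts, seeds)
    state.models = dict(zip(OBJECTIVE_NAMES, models))
    suggestions = propose_batch(
        models,
        state.X(),
        state.Y(),
        feasible_predicate(cfg.space),
        cfg.acquisition(),
        state.rng,
    )
    it = state.n_iterations_done + 1
    for s in suggestions:
        form = decode_point(s.point, cfg.space)
        obs = lab.measure(form)
        obs.iteration = it
        obs.route = s.route
        state.points.append(s.point)
        state.observations.append(obs)
    return state


def run_campaign(config: CampaignConfig, lab, rng=None) -> CampaignState:
    """Closed loop: initialization plus ``n_iterations`` batch iterations."""
    state = initialize_campaign(config, lab, rng)
    for _ in range(config.n_iterations):
        run_iteration(state, lab)
    return state


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def _standardized(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize objectives over the full ledger; reference point is the
    per-objective minimum minus 0.5, fixed for the whole trace."""
    mu = Y.mean(axis=0)
    sd = Y.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Y - mu) / sd
    ref = Z.min(axis=0) - 0.5
    return Z, ref


def hypervolume_trace(state: CampaignState) -> pd.DataFrame:
    """Hypervolume of all observations up to and including each iteration,
    on standardized objectives with a trace-fixed reference point."""
    Y = state.Y()
    iters = np.array([o.iteration for o in state.observations])
    Z, ref = _standardized(Y)
    rows = [
        {"iteration": int(t), "hypervolume": hypervolume(Z[iters <= t], ref)}
        for t in np.unique(iters)
    ]
    return pd.DataFrame(rows)


def per_formulation_hypervolume(state: CampaignState) -> np.ndarray:
    """Individual dominated volume of each observation (standardized
    objectives, same reference as the trace)."""
    Z, ref = _standardized(state.Y())
    return np.array([point_hypervolume(z, ref) for z in Z])


def prediction_mae_trace(state: CampaignState, n_restarts: int = 3) -> pd.DataFrame:
    """Per-objective mean absolute error of surrogates trained on
    iterations < t predicting iteration t, in raw units."""
    Y = state.Y()
    X = state.X()
    iters = np.array([o.iteration for o in state.observations])
    rows = []
    for t in sorted(set(iters)):
        if t == 0:
            continue
        train = iters < t
        test = iters == t
        models = fit_surrogates(X[train], Y[train], n_restarts, seeds=(0, 1, 2))
        row = {"iteration": int(t)}
        for j, name in enumerate(OBJECTIVE_NAMES):
            pred = models[j].predict(X[test])
            row[f"mae_{name}"] = float(np.mean(np.abs(pred - Y[test, j])))
        rows.append(row)
    return pd.DataFrame(rows)


def spearman(x, y) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with at least 3 values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero rank variance; Spearman correlation undefined")
    return float(stats.spearmanr(x, y).statistic)


def spearman_table(state: CampaignState) -> pd.DataFrame:
    """Spearman correlation of each design variable with each objective."""
    df = state.ledger()
    variables = ("pH", "sorbitol_mM", "arginine_mM", "f_asp", "f_glu", "f_hcl", "f_acetic")
    rows = []
    for var in variables:
        row = {"variable": var}
        for col, name in zip(OBJECTIVE_COLUMNS, OBJECTIVE_NAMES):
            x = df[var].to_numpy()
            try:
                row[name] = spearman(x, df[col].to_numpy())
            except ValueError:
                row[name] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ledger serialization
# ---------------------------------------------------------------------------


def write_ledger(state: CampaignState, path) -> None:
    state.ledger().to_csv(path, index=False)


def read_ledger(path, config: CampaignConfig | None = None) -> CampaignState:
    """Rebuild a campaign state from a ledger CSV (models not refit)."""
    config = CampaignConfig() if config is None else config
    df = pd.read_csv(path)
    state = CampaignState(config=config, rng=np.random.default_rng(config.seed))
    for _, row in df.iterrows():
        u = row[[f"u{i}" for i in range(6)]].to_numpy(dtype=float)
        form = decode_point(u, config.space)
        obs = Observation(
            formulation=form,
            tm=float(row["Tm_C"]),
            kd=float(row["kD_mL_per_g"]),
            rm=float(row["RM_pct"]),
            iteration=int(row["iteration"]),
            route=str(row["route"]),
        )
        state.points.append(u)
        state.observations.append(obs)
    return state
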