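"""Ant-colony-optimization feature selection over deep-feature tables.

The selector maintains a per-feature pheromone vector delta (initialized
uniformly at delta0) and a static per-feature visibility heuristic v.
Each iteration, every ant builds a feature subset with the
pseudo-random-proportional rule: with probability q0 it greedily takes
the feature maximizing delta_j^alpha * v_j^beta among those not yet
chosen, otherwise it samples proportionally to that product. Subset
quality is the held-out accuracy of a 1-nearest-neighbor classifier on
the subset's columns. The iteration-best subset deposits pheromone on
its member features,

    delta_j <- (1 - mu) * delta_j + mu * fitness,

and a global evaporation step pulls every feature back toward the
initial level,

    delta_j <- (1 - theta) * delta_j + theta * delta0.

After a fixed iteration budget (100 by default) the elitist best subset
is kept and 15-20% of it is pruned by greedy maximum-absolute-correlation
redundancy removal.

The colony-sizing rule Kn = V x d (V samples, d features) is preserved
as a formal cap: with deep-feature tables it is astronomically large, so
the default colony is min(V x d, 32) ants.

Two visibility modes exist. ``fisher`` (default) scores each feature by
the Fisher class-separability ratio — variance of the class means over
the mean within-class variance. ``paper_literal`` ties visibility to the
pheromone vector itself (v = delta, recomputed each call); this mode is
degenerate as a heuristic and is retained only for fidelity experiments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .features import FeatureTable

__all__ = [
    "ACOConfig",
    "PheromoneState",
    "ColonySpec",
    "SelectionResult",
    "init_state",
    "fisher_visibility",
    "transition_probabilities",
    "construct_subset",
    "subset_fitness",
    "local_update",
    "global_update",
    "run_aco",
    "prune_redundant",
]

ANTS_CAP = 32
SUBSET_SIZE_CAP = 512


@dataclass
class ACOConfig:
    n_iterations: int = 100
    n_ants: int | str = "auto"  # "auto" = min(V*d, ANTS_CAP); "literal" = V*d
    subset_size: int | None = None  # None = round(0.5*d), capped at SUBSET_SIZE_CAP
    alpha_pheromone_exponent: float = 1.0
    beta_visibility_exponent: float = 1.0
    exploit_prob_q0: float = 0.3
    mu_local_rate: float = 0.1
    theta_global_rate: float = 0.05
    delta0_init: float = 1.0
    prune_fraction: float = 0.20
    seed: int = 0
    heuristic_mode: str = "fisher"  # fisher | paper_literal
    fitness_holdout_fraction: float = 0.25
    allow_prune_override: bool = False

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0.0 < self.mu_local_rate < 1.0):
            raise ValueError("mu_local_rate must satisfy 0 < mu < 1")
        if not (0.0 < self.theta_global_rate < 1.0):
            raise ValueError("theta_global_rate must satisfy 0 < theta < 1")
        if self.delta0_init <= 0:
            raise ValueError("delta0_init must be > 0")
        if not (0.0 <= self.exploit_prob_q0 <= 1.0):
            raise ValueError("exploit_prob_q0 must be in [0, 1]")
        if not self.allow_prune_override and not (0.15 <= self.prune_fraction <= 0.20):
            raise ValueError(
                "prune_fraction must be in [0.15, 0.20] "
                "(set allow_prune_override=True to bypass)"
            )
        if self.heuristic_mode not in ("fisher", "paper_literal"):
            raise ValueError("heuristic_mode must be 'fisher' or 'paper_literal'")

    def resolved_subset_size(self, d: int) -> int:
        if self.subset_size is not None:
            if self.subset_size > d:
                raise ValueError(f"subset_size {self.subset_size} exceeds d={d}")
            if self.subset_size < 1:
                raise ValueError("subset_size must be >= 1")
            return self.subset_size
        return max(1, min(round(0.5 * d), SUBSET_SIZE_CAP, d))


@dataclass
class PheromoneState:
    pheromone: np.ndarray  # delta, length d, strictly positive
    visibility: np.ndarray  # v, length d, nonnegative
    iteration: int = 0


@dataclass(frozen=True)
class ColonySpec:
    n_ants: int  # Kn
    n_samples: int  # V
    n_features: int  # d


@dataclass
class SelectionResult:
    kept_indices: np.ndarray
    pruned_indices: np.ndarray
    final_pheromone: np.ndarray
    best_fitness_per_iteration: np.ndarray
    best_subset: np.ndarray  # elitist subset before pruning
    best_fitness: float
    config: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        payload = {
            "kept_indices": self.kept_indices.tolist(),
            "pruned_indices": self.pruned_indices.tolist(),
            "final_pheromone": self.final_pheromone.tolist(),
            "best_fitness_per_iteration": self.best_fitness_per_iteration.tolist(),
            "best_subset": self.best_subset.tolist(),
            "best_fitness": self.best_fitness,
            "config": self.config,
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "SelectionResult":
        p = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            np.array(p["kept_indices"], dtype=np.int64),
            np.array(p["pruned_indices"], dtype=np.int64),
            np.array(p["final_pheromone"], dtype=np.float64),
            np.array(p["best_fitness_per_iteration"], dtype=np.float64),
            np.array(p["best_subset"], dtype=np.int64),
            float(p["best_fitness"]),
            p.get("config", {}),
        )


def fisher_visibility(table: FeatureTable) -> np.ndarray:
    """Per-feature Fisher class-separability ratio.

    ratio_j = Var_c(mean of feature j in class c) / mean_c(within-class
    variance of feature j). Features with zero between-class variance get
    visibility 0; features that separate classes with zero within-class
    variance get twice the largest finite ratio.
    """
    classes = np.unique(table.labels)
    if len(classes) < 2:
        raise ValueError("fisher visibility requires at least 2 classes")
    X, y = table.matrix, table.labels
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    withins = np.stack([X[y == c].var(axis=0) for c in classes])
    between = means.var(axis=0)
    within = withins.mean(axis=0)

    vis = np.zeros(table.feature_dim)
    regular = (between > 0) & (within > 0)
    vis[regular] = between[regular] / within[regular]
    degenerate = (between > 0) & (within == 0)
    if degenerate.any():
        finite_max = vis[regular].max() if regular.any() else 1.0
        vis[degenerate] = 2.0 * max(finite_max, 1e-12)
    return vis


def init_state(table: FeatureTable, cfg: ACOConfig) -> tuple[PheromoneState, ColonySpec]:
    """Uniform pheromone at delta0; visibility per heuristic mode; colony size."""
    if table.feature_dim < 2:
        raise ValueError("need at least 2 features")
    if not np.all(np.isfinite(table.matrix)):
        raise ValueError("feature table contains non-finite values")
    d = table.feature_dim
    v_count = table.n_samples
    pheromone = np.full(d, cfg.delta0_init, dtype=np.float64)
    if cfg.heuristic_mode == "fisher":
        visibility = fisher_visibility(table)
    else:  # paper_literal: v = delta
        visibility = pheromone.copy()
    literal = v_count * d
    if cfg.n_ants == "literal":
        n_ants = literal
    elif cfg.n_ants == "auto":
        n_ants = min(literal, ANTS_CAP)
    else:
        n_ants = int(cfg.n_ants)
        if n_ants < 1:
            raise ValueError("n_ants must be >= 1")
    return PheromoneState(pheromone, visibility), ColonySpec(n_ants, v_count, d)


def _weights(state: PheromoneState, cfg: ACOConfig) -> np.ndarray:
    v = state.pheromone if cfg.heuristic_mode == "paper_literal" else state.visibility
    return (
        np.power(state.pheromone, cfg.alpha_pheromone_exponent)
        * np.power(v, cfg.beta_visibility_exponent)
    )


def transition_probabilities(state: PheromoneState, cfg: ACOConfig,
                             excluded) -> np.ndarray:
    """p_j proportional to delta_j^alpha * v_j^beta over non-excluded features."""
    d = len(state.pheromone)
    excluded = set(int(i) for i in excluded)
    if len(excluded) >= d:
        raise ValueError("all features excluded; nothing to transition to")
    w = _weights(state, cfg)
    mask = np.ones(d, dtype=bool)
    mask[list(excluded)] = False
    w = np.where(mask, w, 0.0)
    total = w.sum()
    if total <= 0:  # all remaining weights zero: fall back to uniform
        w = mask.astype(np.float64)
        total = w.sum()
    return w / total


def construct_subset(state: PheromoneState, cfg: ACOConfig,
                     rng: np.random.Generator, subset_size: int | None = None) -> np.ndarray:
    """Build one ant's subset with the pseudo-random-proportional rule."""
    d = len(state.pheromone)
    k = subset_size if subset_size is not None else cfg.resolved_subset_size(d)
    if k > d:
        raise ValueError(f"subset_size {k} exceeds number of features {d}")
    chosen: list[int] = []
    base = _weights(state, cfg)
    remaining = np.ones(d, dtype=bool)
    for _ in range(k):
        if cfg.exploit_prob_q0 > 0 and rng.random() < cfg.exploit_prob_q0:
            w = np.where(remaining, base, -np.inf)
            j = int(np.argmax(w))  # ties -> lowest index
        else:
            p = np.where(remaining, base, 0.0)
            total = p.sum()
            if total <= 0:
                p = remaining.astype(np.float64)
                total = p.sum()
            j = int(rng.choice(d, p=p / total))
        chosen.append(j)
        remaining[j] = False
    return np.array(sorted(chosen), dtype=np.int64)


def _fitness_split(labels: np.ndarray, holdout_fraction: float,
                   seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified holdout split (indices), >=1 test sample per class."""
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        n_test = max(1, int(round(holdout_fraction * len(idx))))
        n_test = min(n_test, len(idx) - 1)
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


class _FitnessEvaluator:
    """Seeded 1-NN holdout accuracy on feature subsets, with caching.

    The split and the per-feature standardization (train statistics) are
    fixed once per run, so fitness is a pure function of the subset.
    """

    def __init__(self, table: FeatureTable, cfg: ACOConfig):
        self.train_idx, self.test_idx = _fitness_split(
            table.labels, cfg.fitness_holdout_fraction, cfg.seed
        )
        X = table.matrix
        mu = X[self.train_idx].mean(axis=0)
        sd = X[self.train_idx].std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        self.Ztr, self.Zte = Z[self.train_idx], Z[self.test_idx]
        self.ytr = table.labels[self.train_idx]
        self.yte = table.labels[self.test_idx]
        self._cache: dict[tuple, float] = {}

    def __call__(self, subset: np.ndarray) -> float:
        key = tuple(int(i) for i in subset)
        if key in self._cache:
            return self._cache[key]
        cols = np.asarray(key, dtype=np.int64)
        dist = cdist(self.Zte[:, cols], self.Ztr[:, cols])
        pred = self.ytr[np.argmin(dist, axis=1)]
        acc = float(np.mean(pred == self.yte))
        self._cache[key] = acc
        return acc


def subset_fitness(table: FeatureTable, subset, cfg: ACOConfig,
                   rng=None) -> float:
    """Held-out 1-NN accuracy of the subset's columns; deterministic per cfg.seed."""
    subset = np.asarray(list(subset), dtype=np.int64)
    if subset.size == 0:
        raise ValueError("subset must be nonempty")
    if subset.min() < 0 or subset.max() >= table.feature_dim:
        raise ValueError("subset references out-of-range feature index")
    return _FitnessEvaluator(table, cfg)(subset)


def local_update(state: PheromoneState, best_subset, best_fitness: float,
                 cfg: ACOConfig) -> PheromoneState:
    """Deposit the iteration-best fitness on its member features.

    delta_j <- (1 - mu) delta_j + mu * best_fitness for j in best_subset.
    """
    mu = cfg.mu_local_rate
    idx = np.asarray(list(best_subset), dtype=np.int64)
    state.pheromone[idx] = (1.0 - mu) * state.pheromone[idx] + mu * best_fitness
    return state


def global_update(state: PheromoneState, cfg: ACOConfig) -> PheromoneState:
    """Evaporate every feature toward delta0: delta <- (1-theta) delta + theta delta0."""
    th = cfg.theta_global_rate
    state.pheromone = (1.0 - th) * state.pheromone + th * cfg.delta0_init
    state.iteration += 1
    return state


def prune_redundant(table: FeatureTable, subset, prune_fraction: float,
                    visibility: np.ndarray | None = None,
                    allow_override: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Drop ``floor(prune_fraction * |subset|)`` most-redundant features.

    Iteratively removes the feature whose maximum absolute Pearson
    correlation to the other kept features is largest; ties break toward
    lower visibility, then lower feature index.
    """
    if not allow_override and not (0.15 <= prune_fraction <= 0.20):
        raise ValueError("prune_fraction must be in [0.15, 0.20] without override")
    subset = np.array(sorted(int(i) for i in subset), dtype=np.int64)
    if subset.size <= 1:
        return subset, np.array([], dtype=np.int64)
    n_remove = math.floor(prune_fraction * subset.size)
    if n_remove == 0:
        return subset, np.array([], dtype=np.int64)
    if visibility is None:
        try:
            visibility = fisher_visibility(table)
        except ValueError:
            visibility = np.zeros(table.feature_dim)

    X = table.matrix[:, subset]
    sd = X.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(X)
    Z[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    corr = np.abs(Z.T @ Z / X.shape[0])  # zero-variance columns -> corr 0
    np.fill_diagonal(corr, 0.0)

    alive = list(range(subset.size))
    pruned_local: list[int] = []
    for _ in range(n_remove):
        sub = corr[np.ix_(alive, alive)]
        maxcorr = sub.max(axis=1) if len(alive) > 1 else np.zeros(1)
        # lexicographic: highest max-correlation, then lowest visibility,
        # then lowest feature index
        best_pos, best_key = None, None
        for pos, loc in enumerate(alive):
            key = (-maxcorr[pos], visibility[subset[loc]], subset[loc])
            if best_key is None or key < best_key:
                best_pos, best_key = pos, key
        pruned_local.append(alive.pop(best_pos))
    kept = subset[sorted(alive)]
    pruned = subset[sorted(pruned_local)]
    return kept, pruned


def run_aco(table: FeatureTable, cfg: ACOConfig) -> SelectionResult:
    """Full selection run: colony loop, elitist tracking, final pruning."""
    state, colony = init_state(table, cfg)
    subset_size = cfg.resolved_subset_size(colony.n_features)
    rng = np.random.default_rng(cfg.seed)
    fitness = _FitnessEvaluator(table, cfg)

    best_subset: np.ndarray | None = None
    best_fit = -np.inf
    trace = np.empty(cfg.n_iterations)
    for it in range(cfg.n_iterations):
        iter_best_subset, iter_best_fit = None, -np.inf
        for _ in range(colony.n_ants):
            s = construct_subset(state, cfg, rng, subset_size)
            f = fitness(s)
            if f > iter_best_fit or (
                f == iter_best_fit and tuple(s) < tuple(iter_best_subset)
            ):
                iter_best_subset, iter_best_fit = s, f
        local_update(state, iter_best_subset, iter_best_fit, cfg)
        global_update(state, cfg)
        if iter_best_fit > best_fit:
            best_subset, best_fit = iter_best_subset, iter_best_fit
        trace[it] = best_fit

    kept, pruned = prune_redundant(
        table, best_subset, cfg.prune_fraction,
        visibility=state.visibility if cfg.heuristic_mode == "fisher" else None,
        allow_override=True,
    )
    cfg_echo = {
        "n_iterations": cfg.n_iterations,
        "n_ants": colony.n_ants,
        "subset_size": subset_size,
        "alpha": cfg.alpha_pheromone_exponent,
        "beta": cfg.beta_visibility_exponent,
        "q0": cfg.exploit_prob_q0,
        "mu": cfg.mu_local_rate,
        "theta": cfg.theta_global_rate,
        "delta0": cfg.delta0_init,
        "prune_fraction": cfg.prune_fraction,
        "seed": cfg.seed,
        "heuristic_mode": cfg.heuristic_mode,
    }
    return SelectionResult(
        kept_indices=kept,
        pruned_indices=pruned,
        final_pheromone=state.pheromone.copy(),
        best_fitness_per_iteration=trace,
        best_subset=np.asarray(best_subset),
        best_fitness=float(best_fit),
        config=cfg_echo,
    )
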