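"""Query strategies: which stimulation parameter set to administer next.

Nine active-learning strategies plus the random-sampling baseline, each a
map from the current labeled/unlabeled partition of the pool to the index
of the next sample:

* ``rs`` — uniform random draw from the unlabeled pool.
* ``qbc`` — query by committee: maximize the population variance of a
  bootstrap committee's predictions (disagreement sampling).
* ``emcm`` — expected model change maximization: maximize the mean, over
  committee members, of |member prediction - main-model prediction| times
  the norm of the candidate's (standardized) feature vector, i.e. the
  expected gradient-magnitude change a new label would induce.
* ``gs`` — greedy sampling: maximize the candidate's minimum Euclidean
  distance to already-labeled samples (max-min; the literal max-max
  variant is available via ``gs_variant``).
* ``rd`` — representativeness & diversity: k-means with k = S0 + 1 over
  the whole pool, restrict to the largest cluster containing no labeled
  sample, pick the member nearest its centroid.
* ``rd_qbc`` / ``rd_emcm`` / ``rd_gs`` — RD cluster restriction, then the
  base criterion inside the chosen cluster.
* ``eqbc`` / ``eemcm`` — "enhanced" variants: identical per-query
  behaviour to qbc/emcm, but the episode's initial samples are chosen by
  k-means representative initialization (each cluster's member nearest
  its centroid) instead of at random, so initial samples cannot be
  outliers.

Ties are always broken toward the lowest pool index; every strategy is
deterministic given the state's seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .regressors import RegressorSpec, bootstrap_committee, fit, predict

__all__ = [
    "QueryState",
    "StrategyConfig",
    "STRATEGY_NAMES",
    "AL_STRATEGY_NAMES",
    "ENHANCED_STRATEGIES",
    "qbc_scores",
    "emcm_scores",
    "gs_scores",
    "select_random",
    "select_qbc",
    "select_emcm",
    "select_gs",
    "select_rd",
    "select_next",
    "representative_init",
]

#: random-sampling baseline plus the nine active-learning strategies
STRATEGY_NAMES = ("rs", "qbc", "emcm", "gs", "rd", "rd_qbc", "rd_emcm", "rd_gs", "eqbc", "eemcm")
AL_STRATEGY_NAMES = STRATEGY_NAMES[1:]
ENHANCED_STRATEGIES = {"eqbc": "qbc", "eemcm": "emcm"}
_RD_BASES = {"rd": None, "rd_qbc": "qbc", "rd_emcm": "emcm", "rd_gs": "gs"}


@dataclass
class QueryState:
    """Labeled/unlabeled pool partition as seen by a strategy.

    Indices are pool-local (0 .. N_pool-1) into ``pool_features``, which
    must already be standardized so distances and feature norms are
    scale-free.
    """

    pool_features: np.ndarray
    labeled: list[int]
    unlabeled: list[int]
    labeled_targets: np.ndarray
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.pool_features = np.atleast_2d(np.asarray(self.pool_features, dtype=float))
        self.labeled = [int(i) for i in self.labeled]
        self.unlabeled = sorted(int(i) for i in self.unlabeled)
        self.labeled_targets = np.asarray(self.labeled_targets, dtype=float).ravel()
        if set(self.labeled) & set(self.unlabeled):
            raise ValueError("labeled and unlabeled sets overlap")
        if set(self.labeled) | set(self.unlabeled) != set(range(self.pool_features.shape[0])):
            raise ValueError("labeled + unlabeled must cover the pool exactly")
        if len(self.labeled) != self.labeled_targets.size:
            raise ValueError("one target per labeled index required")


@dataclass(frozen=True)
class StrategyConfig:
    """Strategy name plus the knobs shared across strategies."""

    name: str = "qbc"
    committee_size: int = 10
    kmeans_restarts: int = 10
    gs_variant: str = "max_min"

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_NAMES:
            raise ValueError(f"unknown strategy {self.name!r}; choose from {STRATEGY_NAMES}")
        if self.name in ("qbc", "emcm", "rd_qbc", "rd_emcm", "eqbc", "eemcm") and self.committee_size < 2:
            raise ValueError("committee strategies need committee_size >= 2")
        if self.gs_variant not in ("max_min", "max_max"):
            raise ValueError("gs_variant must be 'max_min' or 'max_max'")


def _argbest(candidates: Sequence[int], scores: np.ndarray) -> int:
    """Highest score wins; ties go to the lowest pool index.

    ``candidates`` must be sorted ascending (QueryState guarantees it),
    so the first argmax is the lowest-index winner.
    """
    return int(candidates[int(np.argmax(scores))])


# ---------------------------------------------------------------------------
# pure scoring functions (the defining formulas, exposed for direct testing)


def qbc_scores(committee_predictions: np.ndarray) -> np.ndarray:
    """Committee disagreement: population variance across members.

    ``committee_predictions`` has shape ``(n_candidates, P)``; returns
    sigma_n = (1/P) sum_p (y_n^p - mean_p y_n^p)^2 for each candidate.
    """
    preds = np.atleast_2d(np.asarray(committee_predictions, dtype=float))
    return preds.var(axis=1)


def emcm_scores(
    committee_predictions: np.ndarray, main_predictions: np.ndarray, features: np.ndarray
) -> np.ndarray:
    """Expected model change: g_n = (1/P) sum_p |y_n^p - yhat_n| * ||u_n||."""
    preds = np.atleast_2d(np.asarray(committee_predictions, dtype=float))
    yhat = np.asarray(main_predictions, dtype=float).ravel()
    norms = np.linalg.norm(np.atleast_2d(features), axis=1)
    return np.abs(preds - yhat[:, None]).mean(axis=1) * norms


def gs_scores(
    candidate_features: np.ndarray, labeled_features: np.ndarray, variant: str = "max_min"
) -> np.ndarray:
    """Distance of each candidate from the labeled set.

    ``max_min`` (default) scores by the minimum Euclidean distance to any
    labeled sample (greedy max-min coverage); ``max_max`` scores by the
    maximum distance.
    """
    U = np.atleast_2d(candidate_features)
    L = np.atleast_2d(labeled_features)
    if L.shape[0] == 0:
        raise ValueError("greedy sampling needs at least one labeled sample")
    dists = np.linalg.norm(U[:, None, :] - L[None, :, :], axis=2)
    return dists.min(axis=1) if variant == "max_min" else dists.max(axis=1)


# ---------------------------------------------------------------------------
# selection


def select_random(state: QueryState) -> int:
    """Uniform random draw from the unlabeled pool (the RS baseline)."""
    if not state.unlabeled:
        raise ValueError("no unlabeled candidates left")
    rng = np.random.default_rng(state.rng_seed)
    return int(rng.choice(state.unlabeled))


def _committee_for(state: QueryState, spec: RegressorSpec, config: StrategyConfig):
    X_lab = state.pool_features[state.labeled]
    return bootstrap_committee(
        spec, X_lab, state.labeled_targets, config.committee_size, seed=state.rng_seed
    )


def select_qbc(
    state: QueryState, spec: RegressorSpec, config: StrategyConfig, candidates: list[int] | None = None
) -> int:
    """Query by committee over ``candidates`` (default: all unlabeled)."""
    candidates = state.unlabeled if candidates is None else candidates
    if not candidates:
        raise ValueError("no unlabeled candidates left")
    committee = _committee_for(state, spec, config)
    preds = committee.predict_matrix(state.pool_features[candidates])
    return _argbest(candidates, qbc_scores(preds))


def select_emcm(
    state: QueryState, spec: RegressorSpec, config: StrategyConfig, candidates: list[int] | None = None
) -> int:
    """Expected model change maximization over ``candidates``."""
    candidates = state.unlabeled if candidates is None else candidates
    if not candidates:
        raise ValueError("no unlabeled candidates left")
    X_cand = state.pool_features[candidates]
    main = fit(spec, state.pool_features[state.labeled], state.labeled_targets)
    yhat = predict(main, X_cand)
    committee = _committee_for(state, spec, config)
    preds = committee.predict_matrix(X_cand)
    return _argbest(candidates, emcm_scores(preds, yhat, X_cand))


def select_gs(
    state: QueryState, config: StrategyConfig = StrategyConfig(name="gs"), candidates: list[int] | None = None
) -> int:
    """Greedy sampling: the candidate farthest from the labeled set."""
    candidates = state.unlabeled if candidates is None else candidates
    if not candidates:
        raise ValueError("no unlabeled candidates left")
    scores = gs_scores(
        state.pool_features[candidates], state.pool_features[state.labeled], config.gs_variant
    )
    return _argbest(candidates, scores)


def _relabel_clusters(labels: np.ndarray, k: int) -> tuple[np.ndarray, list[np.ndarray]]:
    """Renumber clusters by ascending first-member index (deterministic)."""
    order = sorted(range(k), key=lambda c: int(np.argmax(labels == c)) if (labels == c).any() else len(labels))
    members = [np.flatnonzero(labels == c) for c in order]
    return order, members


def _rd_cluster(state: QueryState, config: StrategyConfig) -> np.ndarray:
    """Members of the largest labeled-free k-means cluster (k = S0 + 1)."""
    X = state.pool_features
    k = min(len(state.labeled) + 1, X.shape[0])
    km = KMeans(
        n_clusters=k,
        n_init=config.kmeans_restarts,
        max_iter=300,
        random_state=state.rng_seed % (2**31),
    ).fit(X)
    _, members = _relabel_clusters(km.labels_, k)
    labeled_set = set(state.labeled)
    free = [m for m in members if m.size and not (set(m.tolist()) & labeled_set)]
    if not free:
        # degenerate clustering (duplicated points); fall back to the whole unlabeled set
        return np.asarray(state.unlabeled, dtype=int)
    # largest by member count; ties resolved by relabeled order (lowest first-member index)
    sizes = [m.size for m in free]
    return free[int(np.argmax(sizes))]


def select_rd(
    state: QueryState,
    base: str | None = None,
    spec: RegressorSpec | None = None,
    config: StrategyConfig = StrategyConfig(name="rd"),
) -> int:
    """Representativeness & diversity, naive or integrated with a base.

    Naive (``base=None``): return the chosen cluster's member nearest its
    centroid.  Integrated: apply the base criterion (qbc/emcm/gs)
    restricted to the cluster's unlabeled members.
    """
    if not state.unlabeled:
        raise ValueError("no unlabeled candidates left")
    cluster = _rd_cluster(state, config)
    candidates = sorted(set(cluster.tolist()) & set(state.unlabeled))
    if not candidates:
        candidates = state.unlabeled
    if base is None:
        X_c = state.pool_features[candidates]
        centroid = state.pool_features[cluster].mean(axis=0)
        dist = np.linalg.norm(X_c - centroid, axis=1)
        return int(candidates[int(np.argmin(dist))])
    if base == "gs":
        return select_gs(state, config, candidates=candidates)
    if base == "qbc":
        return select_qbc(state, spec, config, candidates=candidates)
    if base == "emcm":
        return select_emcm(state, spec, config, candidates=candidates)
    raise ValueError(f"unknown RD base {base!r}")


def representative_init(
    pool_features: np.ndarray, n_init: int, seed: int, restarts: int = 10
) -> list[int]:
    """Outlier-safe initial samples: k-means representatives of the pool.

    Clusters the pool and returns, for each of the ``n_init`` largest
    clusters, the member nearest its centroid.  A singleton cluster is a
    suspected outlier, so k grows until the ``n_init`` largest clusters
    all hold at least two members (or k reaches the pool size) — a lone
    extreme point can then never be an initial sample.  Used by the
    enhanced (eqbc, eemcm) strategies in place of random initialization.
    """
    X = np.atleast_2d(np.asarray(pool_features, dtype=float))
    n = X.shape[0]
    if n_init < 1 or n_init > n:
        raise ValueError(f"n_init={n_init} outside 1..{n}")
    k = n_init
    while True:
        km = KMeans(n_clusters=k, n_init=restarts, max_iter=300, random_state=seed % (2**31)).fit(X)
        _, members = _relabel_clusters(km.labels_, k)
        members = [m for m in members if m.size]
        # n_init largest clusters; ties keep relabeled (first-member) order
        largest = sorted(members, key=lambda m: -m.size)[:n_init]
        if all(m.size >= 2 for m in largest) or k >= min(n, 2 * n_init + 5):
            break
        k += 1
    chosen = []
    for m in sorted(largest, key=lambda m: int(m[0])):
        dist = np.linalg.norm(X[m] - X[m].mean(axis=0), axis=1)
        chosen.append(int(m[int(np.argmin(dist))]))
    return chosen


def select_next(state: QueryState, config: StrategyConfig, spec: RegressorSpec) -> int:
    """Dispatch on strategy name; enhanced names defer to their base."""
    name = ENHANCED_STRATEGIES.get(config.name, config.name)
    if name == "rs":
        return select_random(state)
    if name == "qbc":
        return select_qbc(state, spec, config)
    if name == "emcm":
        return select_emcm(state, spec, config)
    if name == "gs":
        return select_gs(state, config)
    if name in _RD_BASES:
        return select_rd(state, base=_RD_BASES[name], spec=spec, config=config)
    raise ValueError(f"unknown strategy {config.name!r}")
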