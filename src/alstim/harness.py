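"""Three-phase episode runner and the repeated AL-vs-RS benchmark.

An *episode* is one pass of the in-silico experimental-design loop:

1. **Initial sampling** — draw a few samples (default: one per input
   feature) from the training pool and fit an initial model.
2. **Model improvement** — repeatedly let the query strategy pick one
   unlabeled pool sample, reveal its response, and refit.
3. **Validation** — after every addition, measure RMSE on the held-out
   test set, yielding an RMSE-vs-training-size curve whose trapezoidal
   area (AUC_RMSE) summarizes sample efficiency: lower means a better
   model was reached with fewer administered stimulations.

A *benchmark* repeats the episode many times with fresh pool/test splits,
pairing strategies within a repeat (same split, same initial samples and
seed path) so per-repeat AUC_RMSE differences support a paired t-test.

Modes: ``static`` learns response = f(amplitude, frequency, pulse_width);
``state_dynamic`` appends the pre-stimulation brain state as a fourth
input; ``stochastic_response`` treats each queried response as a uniform
draw from the m recorded sessions of that parameter set, emulating
trial-to-trial variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .query import (
    ENHANCED_STRATEGIES,
    QueryState,
    StrategyConfig,
    representative_init,
    select_next,
)
from .regressors import RegressorSpec, fit, predict
from .sweep_data import ParameterSweepTable, SplitIndices, StandardizationStats, partition, standardize
from . import synthetic

__all__ = [
    "EpisodeConfig",
    "RMSECurve",
    "BenchmarkResult",
    "BenchmarkError",
    "EPISODE_PRESETS",
    "run_episode",
    "auc_rmse",
    "run_benchmark",
]

MODES = ("static", "state_dynamic", "stochastic_response")

#: per-dataset episode defaults: pool/test geometry mirrors each protocol
EPISODE_PRESETS: dict[str, dict] = {
    "pd_sweep": {"n_init": 3, "n_final": 20, "test_fraction": 0.20},
    "nhp_grid": {"n_init": 3, "n_final": 20, "test_fraction": 0.20},
    "opto_sweep": {"n_init": 3, "n_final": 20, "test_fraction": 20 / 72},
    # closed-loop replication: 3 initial + 72 queried, 25 unseen of 1080
    "invivo_loop": {"n_init": 3, "n_final": 75, "test_fraction": 25 / 1080},
}


@dataclass(frozen=True)
class EpisodeConfig:
    """Everything one episode needs besides the data and the split."""

    strategy: StrategyConfig = StrategyConfig(name="qbc")
    regressor: RegressorSpec = RegressorSpec(family="ridge")
    n_init: int | None = None  # default: number of input features
    n_final: int = 20
    mode: str = "static"
    test_fraction: float = 0.2
    seed: int = 0
    session: int = 0  # response column used in static/state_dynamic modes
    test_target: str = "session_mean"  # or "random_session" (stochastic mode)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.n_init is not None and self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        if self.n_init is not None and self.n_final <= self.n_init:
            raise ValueError("n_final must exceed n_init")
        if self.test_target not in ("session_mean", "random_session"):
            raise ValueError("test_target must be 'session_mean' or 'random_session'")


@dataclass
class RMSECurve:
    """Test RMSE after each model-improvement addition of one episode."""

    training_sizes: np.ndarray
    rmse: np.ndarray
    seed: int
    config: EpisodeConfig | None = None

    def __post_init__(self) -> None:
        self.training_sizes = np.asarray(self.training_sizes, dtype=int)
        self.rmse = np.asarray(self.rmse, dtype=float)
        if self.training_sizes.shape != self.rmse.shape:
            raise ValueError("training_sizes and rmse must have equal length")
        if self.training_sizes.size > 1 and np.any(np.diff(self.training_sizes) <= 0):
            raise ValueError("training_sizes must be strictly increasing")


def auc_rmse(curve: RMSECurve | np.ndarray) -> float:
    """Trapezoidal area of the RMSE curve over the iteration index.

    Unit spacing on the abscissa; a single-point curve has area 0.
    """
    values = curve.rmse if isinstance(curve, RMSECurve) else np.asarray(curve, dtype=float)
    if values.size == 0:
        raise ValueError("empty curve")
    return float(np.trapezoid(values))


def _episode_features(table: ParameterSweepTable, mode: str) -> np.ndarray:
    if mode == "state_dynamic":
        if table.pre_stim_state is None:
            raise ValueError("state_dynamic mode requires a pre_stim_state column")
        return np.column_stack([table.parameters, table.pre_stim_state])
    return table.parameters


def run_episode(table: ParameterSweepTable, split: SplitIndices, config: EpisodeConfig) -> RMSECurve:
    """Run one three-phase episode and return its RMSE curve.

    Deterministic for a fixed (table, split, config): the seed drives two
    independent streams, one for initialization/strategy randomness and
    one for stochastic-mode session draws, so static and
    stochastic-response episodes consume the main stream identically.
    """
    if config.mode == "stochastic_response" and table.m < 2:
        raise ValueError("stochastic_response mode needs m >= 2 response sessions")
    features = _episode_features(table, config.mode)
    pool, test = split.pool, split.test
    n_pool = pool.size
    n_init = config.n_init if config.n_init is not None else features.shape[1]
    if config.n_final > n_pool:
        raise ValueError(f"n_final={config.n_final} exceeds pool size {n_pool}")
    if config.n_final <= n_init:
        raise ValueError("n_final must exceed n_init")

    stats = StandardizationStats.from_pool(features[pool])
    X_pool = standardize(features[pool], stats)
    X_test = standardize(features[test], stats)

    ss = np.random.SeedSequence(config.seed)
    main_ss, session_ss = ss.spawn(2)
    main_rng = np.random.default_rng(main_ss)
    session_rng = np.random.default_rng(session_ss)

    def draw_label(pool_local: int) -> float:
        row = pool[pool_local]
        if config.mode == "stochastic_response":
            return float(table.responses[row, session_rng.integers(table.m)])
        return float(table.responses[row, config.session])

    if config.mode == "stochastic_response":
        if config.test_target == "session_mean":
            y_test = table.responses[test].mean(axis=1)
        else:
            cols = session_rng.integers(table.m, size=test.size)
            y_test = table.responses[test, cols]
    else:
        y_test = table.responses[test, config.session]

    init_seed = int(main_rng.integers(2**31))
    if config.strategy.name in ENHANCED_STRATEGIES:
        labeled = representative_init(X_pool, n_init, seed=init_seed)
    else:
        init_rng = np.random.default_rng(init_seed)
        labeled = sorted(int(i) for i in init_rng.choice(n_pool, size=n_init, replace=False))
    targets = [draw_label(i) for i in labeled]
    unlabeled = sorted(set(range(n_pool)) - set(labeled))

    sizes, errors = [], []
    while len(labeled) < config.n_final:
        state = QueryState(
            pool_features=X_pool,
            labeled=labeled,
            unlabeled=unlabeled,
            labeled_targets=np.asarray(targets),
            rng_seed=int(main_rng.integers(2**31)),
        )
        chosen = select_next(state, config.strategy, config.regressor)
        unlabeled.remove(chosen)
        labeled.append(chosen)
        targets.append(draw_label(chosen))
        model = fit(config.regressor, X_pool[labeled], np.asarray(targets))
        resid = y_test - predict(model, X_test)
        sizes.append(len(labeled))
        errors.append(math.sqrt(float(np.mean(resid**2))))

    return RMSECurve(training_sizes=np.asarray(sizes), rmse=np.asarray(errors), seed=config.seed, config=config)


# ---------------------------------------------------------------------------
# repeated paired benchmark


class BenchmarkError(RuntimeError):
    """Raised when too many benchmark repeats fail."""


@dataclass
class BenchmarkResult:
    """AUC_RMSE of every (repeat, strategy) pair plus full provenance."""

    auc: np.ndarray
    strategies: list[str]
    split_seeds: list[int]
    episode_seeds: list[int]
    config: dict
    log: list[str] = field(default_factory=list)

    @property
    def repeats(self) -> int:
        return self.auc.shape[0]

    def column(self, strategy: str) -> np.ndarray:
        return self.auc[:, self.strategies.index(strategy)]

    def to_dir(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        frame = pd.DataFrame(self.auc, columns=self.strategies)
        frame.insert(0, "repeat", np.arange(self.repeats))
        frame.to_csv(path / "auc.csv", index=False, float_format="%.15g")
        meta = dict(self.config)
        meta["strategies"] = list(self.strategies)
        meta["split_seeds"] = [int(s) for s in self.split_seeds]
        meta["episode_seeds"] = [int(s) for s in self.episode_seeds]
        (path / "config.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
        (path / "log.txt").write_text("\n".join(self.log) + ("\n" if self.log else ""))
        return path

    @classmethod
    def from_dir(cls, path: str | Path) -> "BenchmarkResult":
        path = Path(path)
        auc_file = path / "auc.csv"
        if not auc_file.exists():
            raise FileNotFoundError(f"{path}: missing auc.csv")
        frame = pd.read_csv(auc_file)
        if "repeat" not in frame.columns or frame.shape[1] < 3:
            raise ValueError(f"{auc_file}: expected a repeat column plus >= 2 strategy columns")
        if frame.isna().any().any():
            raise ValueError(f"{auc_file}: missing cells")
        strategies = [c for c in frame.columns if c != "repeat"]
        meta_file = path / "config.yaml"
        meta = yaml.safe_load(meta_file.read_text()) if meta_file.exists() else {}
        return cls(
            auc=frame[strategies].to_numpy(dtype=float),
            strategies=strategies,
            split_seeds=meta.get("split_seeds", []),
            episode_seeds=meta.get("episode_seeds", []),
            config=meta,
        )


def _resolve_table(table_or_preset, seed: int) -> tuple[ParameterSweepTable, dict]:
    if isinstance(table_or_preset, ParameterSweepTable):
        return table_or_preset, {"dataset": table_or_preset.metadata.get("preset", "user table")}
    table = synthetic.make_preset(str(table_or_preset), seed=seed)
    return table, {"dataset": str(table_or_preset), "dataset_seed": seed}


def run_benchmark(
    table_or_preset,
    configs: list[EpisodeConfig],
    repeats: int,
    base_seed: int,
    max_abort_fraction: float = 0.05,
) -> BenchmarkResult:
    """Repeat paired episodes and collect one AUC_RMSE per (repeat, strategy).

    Repeat ``r`` uses split seed ``base_seed + r`` and an episode seed
    shared by all strategies, so each repeat's strategies see the same
    test set, initial samples, and seed path (the paired design).  A
    failing episode aborts its repeat; more than ``max_abort_fraction``
    aborted repeats fails the whole run.
    """
    if repeats < 2:
        raise ValueError("repeats must be >= 2")
    if len(configs) < 2:
        raise ValueError("need at least two strategies to compare")
    table, provenance = _resolve_table(table_or_preset, base_seed)
    strategies = [c.strategy.name for c in configs]
    rows, kept_split, kept_episode, log = [], [], [], []
    aborted = 0
    for r in range(repeats):
        split_seed = base_seed + r
        episode_seed = int(np.random.SeedSequence([base_seed & 0x7FFFFFFF, r]).generate_state(1)[0] % (2**31))
        split = partition(table, configs[0].test_fraction, seed=split_seed)
        try:
            row = []
            for cfg in configs:
                curve = run_episode(table, split, replace(cfg, seed=episode_seed))
                row.append(auc_rmse(curve))
        except Exception as exc:  # noqa: BLE001 - repeat-level containment by design
            aborted += 1
            log.append(f"repeat={r} strategy={cfg.strategy.name} aborted: {exc}")
            continue
        rows.append(row)
        kept_split.append(split_seed)
        kept_episode.append(episode_seed)
        log.append(f"repeat={r} split_seed={split_seed} episode_seed={episode_seed} ok")

    if aborted / repeats > max_abort_fraction:
        raise BenchmarkError(f"{aborted}/{repeats} repeats aborted (> {max_abort_fraction:.0%})")

    snapshot = {
        **provenance,
        "repeats": repeats,
        "base_seed": base_seed,
        "aborted": aborted,
        "mode": configs[0].mode,
        "test_fraction": configs[0].test_fraction,
        "n_init": configs[0].n_init,
        "n_final": configs[0].n_final,
        "test_target": configs[0].test_target,
        "regressor": {k: v for k, v in vars(configs[0].regressor).items()},
        "committee_size": configs[0].strategy.committee_size,
    }
    return BenchmarkResult(
        auc=np.asarray(rows, dtype=float),
        strategies=strategies,
        split_seeds=kept_split,
        episode_seeds=kept_episode,
        config=snapshot,
        log=log,
    )
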