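"""Parameter-sweep tables: the core data container and its plumbing.

A parameter-sweep experiment administers ``n`` stimulation parameter sets
(amplitude, frequency, pulse width) and records ``m >= 1`` brain-response
measurements per set — one column per experimental session — plus an
optional pre-stimulation brain-state value used by state-dependent
modeling.  This module owns the on-disk CSV format, the pool/test split,
and feature standardization (computed from pool rows only, so the unseen
test set never leaks into the feature scaling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParameterSweepTable",
    "SplitIndices",
    "StandardizationStats",
    "SweepFormatError",
    "read_sweep_table",
    "write_sweep_table",
    "partition",
    "standardize",
]

#: canonical internal parameter order
PARAM_NAMES = ("amplitude", "frequency", "pulse_width")


class SweepFormatError(ValueError):
    """Raised when a sweep file or dialect is malformed."""


@dataclass
class ParameterSweepTable:
    """n stimulation parameter sets with m response measurements each.

    Parameters
    ----------
    parameters
        Array of shape ``(n, d)`` with ``d >= 3``; columns follow the
        canonical order (amplitude, frequency, pulse_width, ...).
    responses
        Array of shape ``(n, m)``, one column per session.
    pre_stim_state
        Optional length-``n`` vector of pre-stimulation biomarker values.
    metadata
        Free-form provenance: units, response band, parameter bounds.
    """

    parameters: np.ndarray
    responses: np.ndarray
    pre_stim_state: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.parameters = np.asarray(self.parameters, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim == 1:
            self.responses = self.responses[:, None]
        if self.parameters.ndim != 2:
            raise SweepFormatError("parameters must be a 2-D array")
        n = self.parameters.shape[0]
        if n < 2:
            raise SweepFormatError(f"need at least 2 rows, got {n}")
        if self.responses.shape[0] != n:
            raise SweepFormatError(
                f"responses have {self.responses.shape[0]} rows, parameters {n}"
            )
        if self.pre_stim_state is not None:
            self.pre_stim_state = np.asarray(self.pre_stim_state, dtype=float)
            if self.pre_stim_state.shape != (n,):
                raise SweepFormatError("pre_stim_state must be a length-n vector")
        for name, arr in (("parameters", self.parameters), ("responses", self.responses)):
            if not np.all(np.isfinite(arr)):
                raise SweepFormatError(f"{name} contain non-finite entries")

    @property
    def n(self) -> int:
        return self.parameters.shape[0]

    @property
    def d(self) -> int:
        return self.parameters.shape[1]

    @property
    def m(self) -> int:
        """Number of response sessions per parameter set."""
        return self.responses.shape[1]


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint pool/test row-index partition of a sweep table."""

    pool: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pool", np.asarray(self.pool, dtype=int))
        object.__setattr__(self, "test", np.asarray(self.test, dtype=int))
        both = np.concatenate([self.pool, self.test])
        n = both.size
        if not np.array_equal(np.sort(both), np.arange(n)):
            raise ValueError("pool and test must partition 0..n-1")


def partition(table: ParameterSweepTable, test_fraction: float, seed: int) -> SplitIndices:
    """Randomly split table rows into a training pool and unseen test set.

    ``|test| = round(n * test_fraction)`` with round-half-away-from-zero;
    sampling is uniform without replacement and reproducible under ``seed``.
    """
    if not 0.0 <= test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in [0, 1), got {test_fraction}")
    n = table.n
    n_test = int(math.floor(n * test_fraction + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return SplitIndices(pool=np.sort(perm[n_test:]), test=np.sort(perm[:n_test]))


@dataclass(frozen=True)
class StandardizationStats:
    """Per-feature affine standardization fitted on pool rows only.

    Constant features are flagged and passed through with scale 1 so the
    map is always invertible.
    """

    location: np.ndarray
    scale: np.ndarray
    constant: np.ndarray

    @classmethod
    def from_pool(cls, features: np.ndarray) -> "StandardizationStats":
        X = np.asarray(features, dtype=float)
        loc = X.mean(axis=0)
        sd = X.std(axis=0)
        constant = sd == 0.0
        scale = np.where(constant, 1.0, sd)
        return cls(location=loc, scale=scale, constant=constant)

    @property
    def d(self) -> int:
        return self.location.size

    def inverse(self, standardized: np.ndarray) -> np.ndarray:
        Z = np.asarray(standardized, dtype=float)
        return Z * self.scale + self.location


def standardize(features: np.ndarray, stats: StandardizationStats) -> np.ndarray:
    """Apply a fitted per-feature (x - location) / scale map."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != stats.d:
        raise ValueError(f"features have {X.shape[1]} columns, stats expect {stats.d}")
    return (X - stats.location) / stats.scale


# ---------------------------------------------------------------------------
# CSV I/O


def _default_dialect(columns: Sequence[str]) -> dict:
    """Infer a column mapping from canonical header names."""
    cols = list(columns)
    dialect: dict = {}
    for name in PARAM_NAMES:
        if name in cols:
            dialect[name] = name
    responses = [c for c in cols if c.startswith("response_")]
    if responses:
        dialect["responses"] = sorted(responses, key=lambda c: int(c.split("_")[-1]))
    if "pre_stim_state" in cols:
        dialect["pre_stim_state"] = "pre_stim_state"
    return dialect


def read_sweep_table(path: str | Path, dialect: dict | None = None) -> ParameterSweepTable:
    """Read a sweep CSV into a validated :class:`ParameterSweepTable`.

    Parameters
    ----------
    path
        CSV file with a header row.
    dialect
        Column mapping with keys ``amplitude``, ``frequency``,
        ``pulse_width`` (column names), ``responses`` (list of column
        names, session order), and optionally ``pre_stim_state``.  When
        omitted, canonical names (``amplitude``, ``frequency``,
        ``pulse_width``, ``response_1..response_m``) are expected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SweepFormatError(f"{path}: empty file") from exc
    if frame.empty:
        raise SweepFormatError(f"{path}: no data rows")

    dialect = dict(dialect) if dialect else _default_dialect(frame.columns)
    missing = [k for k in PARAM_NAMES if k not in dialect]
    if missing or "responses" not in dialect:
        raise SweepFormatError(
            f"{path}: dialect missing mappings for {missing + (['responses'] if 'responses' not in dialect else [])}"
        )
    wanted = [dialect[k] for k in PARAM_NAMES] + list(dialect["responses"])
    if "pre_stim_state" in dialect:
        wanted.append(dialect["pre_stim_state"])
    absent = [c for c in wanted if c not in frame.columns]
    if absent:
        raise SweepFormatError(f"{path}: missing columns {absent}")

    sub = frame[wanted]
    numeric = sub.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna()
        row = int(bad.any(axis=1).idxmax())
        col = bad.columns[bad.loc[row].to_numpy().argmax()]
        raise SweepFormatError(f"{path}: non-numeric cell at row {row}, column {col!r}")

    params = numeric[[dialect[k] for k in PARAM_NAMES]].to_numpy(dtype=float)
    responses = numeric[list(dialect["responses"])].to_numpy(dtype=float)
    state = None
    if "pre_stim_state" in dialect:
        state = numeric[dialect["pre_stim_state"]].to_numpy(dtype=float)
    return ParameterSweepTable(
        parameters=params,
        responses=responses,
        pre_stim_state=state,
        metadata={"source": str(path)},
    )


def write_sweep_table(table: ParameterSweepTable, path: str | Path) -> Path:
    """Write a table as canonical CSV (>= 12 significant digits)."""
    path = Path(path)
    data: dict[str, np.ndarray] = {}
    names = list(PARAM_NAMES) + [f"param_{j}" for j in range(3, table.d)]
    for j, name in enumerate(names):
        data[name] = table.parameters[:, j]
    for s in range(table.m):
        data[f"response_{s + 1}"] = table.responses[:, s]
    if table.pre_stim_state is not None:
        data["pre_stim_state"] = table.pre_stim_state
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.15g")
    return path
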