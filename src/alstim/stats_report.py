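"""Paired AL-vs-RS comparison statistics and summary matrices.

Because every strategy within a benchmark repeat shares its pool/test
split and initial samples, per-repeat AUC_RMSE values are naturally
paired and compared with a two-sided paired t-test.  With nine
active-learning strategies tested against the random-sampling baseline,
the Bonferroni-corrected significance threshold is 0.05/9 ~= 0.0056, and
a cell is flagged significant only when it is both below threshold and
in the beneficial direction (AL mean AUC_RMSE lower than RS).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "paired_compare",
    "bonferroni_threshold",
    "ComparisonMatrix",
    "summary_matrix",
    "render_heatmap",
]


def paired_compare(auc_al: np.ndarray, auc_rs: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test on per-repeat AUC_RMSE differences.

    Returns ``(mean_diff, p)`` with ``mean_diff = mean(AL - RS)``; a
    zero-variance difference vector yields p = 1 by convention.
    """
    al = np.asarray(auc_al, dtype=float).ravel()
    rs = np.asarray(auc_rs, dtype=float).ravel()
    if al.size != rs.size:
        raise ValueError(f"length mismatch: {al.size} vs {rs.size}")
    if al.size < 2:
        raise ValueError("need at least two paired repeats")
    diff = al - rs
    mean_diff = float(diff.mean())
    if np.allclose(diff.std(ddof=1), 0.0):
        return mean_diff, 1.0
    t = sstats.ttest_rel(al, rs)
    return mean_diff, float(t.pvalue)


def bonferroni_threshold(alpha: float, n_comparisons: int) -> float:
    """Per-comparison threshold alpha / n (0.05/9 ~= 0.0056)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return alpha / n_comparisons


@dataclass
class ComparisonMatrix:
    """Strategy x condition grid of (mean ΔAUC_RMSE, p, significant).

    ``significant`` is True iff p < threshold and the mean difference is
    negative (the AL model reached lower error with the same samples).
    """

    strategies: list[str]
    conditions: list[str]
    mean_diff: np.ndarray
    pvalue: np.ndarray
    significant: np.ndarray
    n_repeats: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        shape = (len(self.strategies), len(self.conditions))
        for name in ("mean_diff", "pvalue", "significant", "n_repeats"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
            setattr(self, name, arr)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for i, s in enumerate(self.strategies):
            for j, c in enumerate(self.conditions):
                records.append(
                    {
                        "strategy": s,
                        "condition": c,
                        "mean_diff": float(self.mean_diff[i, j]),
                        "pvalue": float(self.pvalue[i, j]),
                        "significant": bool(self.significant[i, j]),
                        "n_repeats": int(self.n_repeats[i, j]),
                    }
                )
        return pd.DataFrame.from_records(records)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.15g")
        return path

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "strategies": self.strategies,
            "conditions": self.conditions,
            "threshold": self.threshold,
            "mean_diff": self.mean_diff.tolist(),
            "pvalue": self.pvalue.tolist(),
            "significant": self.significant.astype(bool).tolist(),
            "n_repeats": self.n_repeats.astype(int).tolist(),
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ComparisonMatrix":
        payload = json.loads(Path(path).read_text())
        return cls(
            strategies=list(payload["strategies"]),
            conditions=list(payload["conditions"]),
            mean_diff=np.asarray(payload["mean_diff"], dtype=float),
            pvalue=np.asarray(payload["pvalue"], dtype=float),
            significant=np.asarray(payload["significant"], dtype=bool),
            n_repeats=np.asarray(payload["n_repeats"], dtype=int),
            threshold=float(payload["threshold"]),
        )


def summary_matrix(results: list, corrected_alpha: float, rs_name: str = "rs",
                   condition_names: list[str] | None = None) -> ComparisonMatrix:
    """One comparison cell per (AL strategy, benchmark condition).

    Each element of ``results`` is a BenchmarkResult containing an
    ``rs_name`` column and one or more AL columns with paired repeats.
    """
    if not results:
        raise ValueError("no benchmark results supplied")
    if condition_names is None:
        condition_names = [
            str(res.config.get("dataset", f"condition_{j}")) + f"#{j}" if len(results) > 1
            else str(res.config.get("dataset", "condition_0"))
            for j, res in enumerate(results)
        ]
    strategies: list[str] = []
    for res in results:
        if rs_name not in res.strategies:
            raise ValueError(f"benchmark lacks an {rs_name!r} column: {res.strategies}")
        for s in res.strategies:
            if s != rs_name and s not in strategies:
                strategies.append(s)
    shape = (len(strategies), len(results))
    mean_diff = np.full(shape, np.nan)
    pvalue = np.full(shape, np.nan)
    significant = np.zeros(shape, dtype=bool)
    n_repeats = np.zeros(shape, dtype=int)
    for j, res in enumerate(results):
        rs_col = res.column(rs_name)
        for i, s in enumerate(strategies):
            if s not in res.strategies:
                continue
            md, p = paired_compare(res.column(s), rs_col)
            mean_diff[i, j] = md
            pvalue[i, j] = p
            significant[i, j] = (p < corrected_alpha) and (md < 0)
            n_repeats[i, j] = rs_col.size
    return ComparisonMatrix(
        strategies=strategies,
        conditions=condition_names,
        mean_diff=mean_diff,
        pvalue=pvalue,
        significant=significant,
        n_repeats=n_repeats,
        threshold=corrected_alpha,
    )


def render_heatmap(matrix: ComparisonMatrix, path: str | Path) -> Path:
    """Render the ΔAUC_RMSE grid as a PNG/SVG heatmap (asterisks mark
    cells significant after correction)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(2 + len(matrix.conditions), 1 + 0.5 * len(matrix.strategies)))
    data = matrix.mean_diff
    vmax = np.nanmax(np.abs(data)) or 1.0
    im = ax.imshow(data, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(matrix.conditions)), matrix.conditions, rotation=30, ha="right")
    ax.set_yticks(range(len(matrix.strategies)), matrix.strategies)
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            if matrix.significant[i, j]:
                ax.text(j, i, "*", ha="center", va="center", fontsize=14)
    fig.colorbar(im, ax=ax, label="mean ΔAUC_RMSE (AL - RS)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
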