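"""Trajectory verification utilities.

The headline check is the per-species area-under-curve (AUC) comparison
used to prove the modular (hybrid, mean mode) and integrated formulations
equivalent: each quantity's trapezoidal integral over the horizon is
compared between the two runs, relatively where the signal is appreciable
and absolutely where it is pinned near zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .hybrid_engine import Trajectory

__all__ = [
    "ComparisonRecord",
    "ComparisonReport",
    "auc",
    "compare_auc",
    "ensemble_stats",
    "EnsembleStats",
    "plot_auc_scatter",
]

DEFAULT_TOLERANCE = 1e-3  # splitting error at dt = 30 s dominates solver error


def auc(traj: Trajectory) -> dict[str, float]:
    """Trapezoidal area under each quantity over the recorded horizon.

    Units are nM*s for concentration columns and molecule*s for count
    columns.
    """
    if len(traj.times) < 2:
        raise ValueError("AUC needs at least 2 time points")
    if traj.states.shape[0] != traj.times.shape[0]:
        raise ValueError("trajectory grid and state matrix lengths differ")
    areas = np.trapezoid(traj.states, traj.times, axis=0)
    return dict(zip(traj.labels, (float(a) for a in areas)))


@dataclass(frozen=True)
class ComparisonRecord:
    label: str
    auc_a: float
    auc_b: float
    abs_diff: float
    rel_diff: float | None  # None when both areas are near zero


@dataclass(frozen=True)
class ComparisonReport:
    records: tuple[ComparisonRecord, ...]
    tolerance: float
    near_zero_floor: float
    passed: bool

    @property
    def max_rel_diff(self) -> float:
        diffs = [r.rel_diff for r in self.records if r.rel_diff is not None]
        return max(diffs, default=0.0)

    @property
    def n_near_zero(self) -> int:
        return sum(1 for r in self.records if r.rel_diff is None)

    def worst(self) -> ComparisonRecord | None:
        comparable = [r for r in self.records if r.rel_diff is not None]
        return max(comparable, key=lambda r: r.rel_diff, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": r.label,
                    "auc_a": r.auc_a,
                    "auc_b": r.auc_b,
                    "abs_diff": r.abs_diff,
                    "rel_diff": math.nan if r.rel_diff is None else r.rel_diff,
                }
                for r in self.records
            ]
        ).sort_values("abs_diff", ascending=False, kind="stable").reset_index(drop=True)

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
        return path


def compare_auc(
    traj_a: Trajectory,
    traj_b: Trajectory,
    tolerance: float = DEFAULT_TOLERANCE,
    abs_tol: float = 1e-12,
) -> ComparisonReport:
    """Per-quantity AUC comparison between two trajectories.

    Quantities whose areas both fall below ``abs_tol * duration`` are
    compared absolutely against that floor; all others relatively, with
    denominator ``max(|auc_a|, |auc_b|)`` (symmetric in the arguments).
    """
    if traj_a.labels != traj_b.labels:
        only_a = sorted(set(traj_a.labels) - set(traj_b.labels))
        only_b = sorted(set(traj_b.labels) - set(traj_a.labels))
        raise ValueError(
            f"label sets differ (only in a: {only_a}; only in b: {only_b})"
            if only_a or only_b
            else "label order differs between trajectories"
        )
    if traj_a.times.shape != traj_b.times.shape or not np.allclose(
        traj_a.times, traj_b.times
    ):
        raise ValueError("trajectories are not on identical time grids")
    duration = float(traj_a.times[-1] - traj_a.times[0])
    floor = abs_tol * duration
    a_map, b_map = auc(traj_a), auc(traj_b)
    records: list[ComparisonRecord] = []
    passed = True
    for label in traj_a.labels:
        va, vb = a_map[label], b_map[label]
        diff = abs(va - vb)
        denom = max(abs(va), abs(vb))
        if denom > floor:
            rel = diff / denom
            records.append(ComparisonRecord(label, va, vb, diff, rel))
            passed &= rel <= tolerance
        else:
            records.append(ComparisonRecord(label, va, vb, diff, None))
            passed &= diff <= floor
    return ComparisonReport(
        records=tuple(records), tolerance=tolerance,
        near_zero_floor=floor, passed=passed,
    )


@dataclass(frozen=True)
class EnsembleStats:
    times: np.ndarray
    mean: np.ndarray  # [n_recorded, n_quantities]
    se: np.ndarray  # standard error of the mean, same shape
    labels: list[str]
    n_cells: int

    def mean_trajectory(self) -> Trajectory:
        return Trajectory(
            times=self.times, states=self.mean, labels=list(self.labels),
            mode="ensemble_mean",
        )


def ensemble_stats(trajs: list[Trajectory]) -> EnsembleStats:
    """Pointwise mean and standard error over an ensemble of trajectories."""
    if len(trajs) < 2:
        raise ValueError("ensemble_stats needs at least 2 trajectories")
    first = trajs[0]
    for t in trajs[1:]:
        if t.labels != first.labels or t.times.shape != first.times.shape or not np.allclose(
            t.times, first.times
        ):
            raise ValueError("ensemble trajectories must share grid and labels")
    stack = np.stack([t.states for t in trajs])  # [n_cells, n_t, n_q]
    mean = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) / math.sqrt(len(trajs))
    return EnsembleStats(
        times=first.times.copy(), mean=mean, se=se,
        labels=list(first.labels), n_cells=len(trajs),
    )


def plot_auc_scatter(report: ComparisonReport, path: str | Path) -> Path:
    """Log-log scatter of per-quantity AUCs of the two runs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [abs(r.auc_a) for r in report.records]
    ys = [abs(r.auc_b) for r in report.records]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    lo = max(min(x for x in xs + ys if x > 0), report.near_zero_floor) * 0.5
    hi = max(xs + ys) * 2 if xs else 1.0
    ax.loglog([lo, hi], [lo, hi], "-", color="0.7", lw=1)
    ax.loglog(xs, ys, "o", ms=4, mfc="none")
    ax.set_xlabel("AUC, modular formulation")
    ax.set_ylabel("AUC, integrated formulation")
    ax.set_title(f"max rel. diff = {report.max_rel_diff:.2e}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
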