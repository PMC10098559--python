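"""Repeat-run orchestration, aggregate statistics and comparison reports.

The study protocol runs each metaheuristic ten times, reports holdout
accuracy and selected feature-vector size (F.V.S.) as mean ± sample
standard deviation, compares against the full 180-feature baseline, and
tests pairwise differences with a two-sample t-test at p < 0.01. This
module reproduces that machinery for any feature table: per-algorithm
repeated runs with consecutive seeds, a full-feature baseline on the same
split machinery, Welch t-tests (pooled-variance optional), and a
table-shaped report that serializes to JSON/TSV.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError
from .features import FeatureTable
from .objective import CostEvaluator, CostSpec, FeatureMask, make_split
from .optimizers import RunResult, SearchConfig, run

__all__ = [
    "RepeatedRunSummary",
    "ComparisonReport",
    "repeat_runs",
    "full_feature_baseline",
    "welch_ttest",
    "build_report",
    "compare_algorithms",
]


@dataclass
class RepeatedRunSummary:
    """Aggregate of n repeated seeded runs of one algorithm."""

    algorithm: str
    runs: list[RunResult]
    wall_time_mean: float = float("nan")  # informational only

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def accuracies_pct(self) -> np.ndarray:
        return np.array([100.0 * r.best_accuracy for r in self.runs])

    @property
    def feature_counts(self) -> np.ndarray:
        return np.array([float(r.n_selected) for r in self.runs])

    @property
    def acc_mean(self) -> float:
        return float(self.accuracies_pct.mean())

    @property
    def acc_sd(self) -> float:
        return float(self.accuracies_pct.std(ddof=1))

    @property
    def fvs_mean(self) -> float:
        return float(self.feature_counts.mean())

    @property
    def fvs_sd(self) -> float:
        return float(self.feature_counts.std(ddof=1))


def repeat_runs(
    table: FeatureTable,
    config: SearchConfig,
    cost_spec: CostSpec = CostSpec(),
    n_runs: int = 10,
) -> RepeatedRunSummary:
    """Run one algorithm ``n_runs`` times with seeds base+1 ... base+n_runs."""
    if n_runs < 2:
        raise ParameterError("n_runs must be >= 2 for a standard deviation")
    runs: list[RunResult] = []
    times: list[float] = []
    for r in range(1, n_runs + 1):
        cfg = SearchConfig(
            algorithm=config.algorithm,
            t_max=config.t_max,
            pop_size=config.pop_size,
            seed=config.seed + r,
            params=config.params,
        )
        t0 = time.perf_counter()
        runs.append(run(table, cfg, cost_spec))
        times.append(time.perf_counter() - t0)
    return RepeatedRunSummary(
        algorithm=config.algorithm,
        runs=runs,
        wall_time_mean=float(np.mean(times)),
    )


def full_feature_baseline(table: FeatureTable,
                          cost_spec: CostSpec = CostSpec()) -> float:
    """Holdout accuracy (%) of the all-ones mask on the spec's fixed split."""
    split = make_split(table, cost_spec)
    evaluator = CostEvaluator(table, split, cost_spec)
    return 100.0 * evaluator.accuracy(FeatureMask.all_ones(table.n_features))


def welch_ttest(sample_a, sample_b, pooled: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test; unequal-variance (Welch) by default.

    Degenerate case: both samples constant with equal means returns
    (0.0, 1.0) by convention instead of NaN.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each sample needs >= 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ParameterError("samples must be finite")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    with warnings.catch_warnings():
        # near-identical samples trigger scipy's precision-loss warning;
        # the degenerate exact-tie case is already handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=pooled)
    return float(t), float(p)


@dataclass
class ComparisonReport:
    """Per-algorithm summaries plus the full-feature baseline and t-tests."""

    summaries: list[RepeatedRunSummary]
    full_feature_accuracy: float
    pairwise_tests: list[tuple[str, str, float, float]] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.summaries:
            rows.append({
                "algorithm": s.algorithm,
                "n_runs": s.n_runs,
                "fvs_mean": s.fvs_mean,
                "fvs_sd": s.fvs_sd,
                "acc_mean": s.acc_mean,
                "acc_sd": s.acc_sd,
                "wall_time_mean_s": s.wall_time_mean,
            })
        rows.append({
            "algorithm": "full_features",
            "n_runs": 1,
            "fvs_mean": float(self.summaries[0].runs[0].best_mask.d)
            if self.summaries else float("nan"),
            "fvs_sd": 0.0,
            "acc_mean": self.full_feature_accuracy,
            "acc_sd": 0.0,
            "wall_time_mean_s": float("nan"),
        })
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps({
            "full_feature_accuracy": self.full_feature_accuracy,
            "pairwise_tests": [
                {"a": a, "b": b, "t": t, "p": p}
                for a, b, t, p in self.pairwise_tests
            ],
            "summaries": [
                {
                    "algorithm": s.algorithm,
                    "wall_time_mean": s.wall_time_mean,
                    "runs": [json.loads(r.to_json()) for r in s.runs],
                }
                for s in self.summaries
            ],
        }, indent=2)

    @classmethod
    def from_json(cls, s: str | Path) -> "ComparisonReport":
        obj = json.loads(s if isinstance(s, str) else s.read_text())
        summaries = [
            RepeatedRunSummary(
                algorithm=item["algorithm"],
                runs=[RunResult.from_json(json.dumps(r)) for r in item["runs"]],
                wall_time_mean=item["wall_time_mean"],
            )
            for item in obj["summaries"]
        ]
        return cls(
            summaries=summaries,
            full_feature_accuracy=obj["full_feature_accuracy"],
            pairwise_tests=[(d["a"], d["b"], d["t"], d["p"])
                            for d in obj["pairwise_tests"]],
        )

    def plot(self, ax=None):
        """Bar chart of mean ± sd accuracy per algorithm vs the baseline."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        names = [s.algorithm.upper() for s in self.summaries] + ["Full"]
        means = [s.acc_mean for s in self.summaries] + [self.full_feature_accuracy]
        sds = [s.acc_sd for s in self.summaries] + [0.0]
        ax.bar(names, means, yerr=sds, capsize=3)
        ax.set_ylabel("Holdout accuracy (%)")
        ax.set_ylim(0, 105)
        return ax


def build_report(
    summaries: list[RepeatedRunSummary],
    baseline: float,
    tests: list[tuple[str, str, float, float]] | None = None,
) -> ComparisonReport:
    """Assemble the comparison report from precomputed pieces."""
    if not summaries:
        raise ParameterError("at least one summary required")
    return ComparisonReport(
        summaries=summaries,
        full_feature_accuracy=baseline,
        pairwise_tests=tests if tests is not None else [],
    )


def compare_algorithms(
    table: FeatureTable,
    algorithms: tuple[str, ...] | list[str] = None,
    cost_spec: CostSpec = CostSpec(),
    t_max: int = 100,
    pop_size: int = 10,
    n_runs: int = 10,
    base_seed: int = 0,
) -> ComparisonReport:
    """Full study-protocol comparison: each algorithm x n_runs, baseline,
    and pairwise Welch t-tests on the per-run accuracies."""
    from .optimizers import ALGORITHMS

    if algorithms is None:
        algorithms = ALGORITHMS
    summaries = [
        repeat_runs(
            table,
            SearchConfig(algorithm=alg, t_max=t_max, pop_size=pop_size,
                         seed=base_seed),
            cost_spec,
            n_runs=n_runs,
        )
        for alg in algorithms
    ]
    tests = []
    for i in range(len(summaries)):
        for j in range(i + 1, len(summaries)):
            t, p = welch_ttest(summaries[i].accuracies_pct,
                               summaries[j].accuracies_pct)
            tests.append((summaries[i].algorithm, summaries[j].algorithm, t, p))
    baseline = full_feature_baseline(table, cost_spec)
    return build_report(summaries, baseline, tests)
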