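"""Model/Results interface to wrapper feature selection.

``MetaheuristicSelector`` binds a feature table to a search configuration
and a wrapper cost, the way a statistical model binds data to a likelihood;
``fit()`` runs one seeded metaheuristic search and returns a
:class:`SelectionResults` carrying the selected mask, its holdout accuracy,
the convergence curve and a ``summary()`` table. ``fit_repeated()`` runs
the study protocol (ten seeded runs) and aggregates mean ± sd accuracy and
feature-vector size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import RepeatedRunSummary, full_feature_baseline, repeat_runs
from .features import FeatureTable, STATISTIC_NAMES
from .objective import CostSpec
from .optimizers import RunResult, SearchConfig, run

__all__ = ["MetaheuristicSelector", "SelectionResults", "RepeatedSelectionResults"]


class MetaheuristicSelector:
    """Wrapper feature-selection problem bound to one feature table.

    Parameters
    ----------
    table : FeatureTable
        Trials x features matrix with class labels.
    algorithm : str
        One of "pso", "cso", "fa", "ba", "fpo", "woa", "gwo".
    t_max, pop_size : int
        Iteration and population budget (study settings: 100 and 10).
    cost_spec : CostSpec
        Wrapper cost parameters (alpha=0.99, beta=0.01, k=5, 0.2 holdout).
    params : per-algorithm parameter record, optional.
    """

    def __init__(
        self,
        table: FeatureTable,
        algorithm: str = "gwo",
        t_max: int = 100,
        pop_size: int = 10,
        cost_spec: CostSpec = CostSpec(),
        params=None,
    ):
        self.table = table
        self.algorithm = algorithm
        self.t_max = t_max
        self.pop_size = pop_size
        self.cost_spec = cost_spec
        self.params = params

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "label",
        **kwargs,
    ) -> "MetaheuristicSelector":
        """Build from a flat DataFrame whose feature columns are named
        ``channel:statistic`` (or anything containing one colon)."""
        labels = df[label_col].astype(str).tolist()
        feat_cols = [c for c in df.columns if c != label_col]
        names = []
        for c in feat_cols:
            if ":" in str(c):
                ch, st = str(c).split(":", 1)
            else:
                ch, st = str(c), ""
            names.append((ch, st))
        table = FeatureTable(
            values=df[feat_cols].to_numpy(dtype=float),
            labels=labels,
            column_names=names,
        )
        return cls(table, **kwargs)

    def _config(self, seed: int) -> SearchConfig:
        return SearchConfig(
            algorithm=self.algorithm,
            t_max=self.t_max,
            pop_size=self.pop_size,
            seed=seed,
            params=self.params,
        )

    def fit(self, seed: int = 0) -> "SelectionResults":
        """One seeded search run."""
        return SelectionResults(self, run(self.table, self._config(seed),
                                          self.cost_spec))

    def fit_repeated(self, n_runs: int = 10,
                     base_seed: int = 0) -> "RepeatedSelectionResults":
        """Study protocol: runs with seeds base_seed+1 ... base_seed+n_runs."""
        summary = repeat_runs(self.table, self._config(base_seed),
                              self.cost_spec, n_runs=n_runs)
        return RepeatedSelectionResults(self, summary)


class SelectionResults:
    """Result of one metaheuristic run: mask, cost, accuracy, curve."""

    def __init__(self, model: MetaheuristicSelector, result: RunResult):
        self.model = model
        self.result = result

    @property
    def mask(self):
        return self.result.best_mask

    @property
    def cost(self) -> float:
        return self.result.best_cost

    @property
    def accuracy(self) -> float:
        return self.result.best_accuracy

    @property
    def n_selected(self) -> int:
        return self.result.n_selected

    @property
    def curve(self) -> list[float]:
        return self.result.curve

    @property
    def selected_columns(self) -> list[tuple[str, str]]:
        cols = self.model.table.column_names
        return [cols[i] for i, b in enumerate(self.mask.bits) if b]

    def selected_channel_counts(self) -> pd.Series:
        """How many of each channel's five statistics were selected."""
        chans = [c for c, _ in self.selected_columns]
        return pd.Series(chans, dtype=object).value_counts()

    def summary(self) -> str:
        r = self.result
        lines = [
            "Wrapper feature selection results",
            "=" * 44,
            f"algorithm:         {r.algorithm}",
            f"seed:              {r.seed}",
            f"iterations:        {len(r.curve)}",
            f"cost evaluations:  {r.evaluations}",
            f"best cost J:       {r.best_cost:.6f}",
            f"holdout accuracy:  {100 * r.best_accuracy:.2f} %",
            f"selected features: {r.n_selected} / {r.best_mask.d}",
        ]
        return "\n".join(lines)

    def plot_convergence(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(1, len(self.curve) + 1), self.curve)
        ax.set_xlabel("iteration")
        ax.set_ylabel("best cost J")
        ax.set_title(f"{self.result.algorithm.upper()} convergence")
        return ax


class RepeatedSelectionResults:
    """Aggregate of repeated seeded runs, with the study's summary metrics."""

    def __init__(self, model: MetaheuristicSelector, summary: RepeatedRunSummary):
        self.model = model
        self._summary = summary

    @property
    def runs(self) -> list[RunResult]:
        return self._summary.runs

    @property
    def acc_mean(self) -> float:
        return self._summary.acc_mean

    @property
    def acc_sd(self) -> float:
        return self._summary.acc_sd

    @property
    def fvs_mean(self) -> float:
        return self._summary.fvs_mean

    @property
    def fvs_sd(self) -> float:
        return self._summary.fvs_sd

    def baseline(self) -> float:
        """Full-feature holdout accuracy (%) on the fixed split."""
        return full_feature_baseline(self.model.table, self.model.cost_spec)

    def summary(self) -> str:
        s = self._summary
        lines = [
            "Repeated wrapper feature selection",
            "=" * 44,
            f"algorithm:      {s.algorithm}",
            f"runs:           {s.n_runs}",
            f"accuracy:       {s.acc_mean:.2f} ± {s.acc_sd:.2f} %",
            f"feature count:  {s.fvs_mean:.1f} ± {s.fvs_sd:.1f}"
            f" of {self.model.table.n_features}",
            f"mean wall time: {s.wall_time_mean:.2f} s/run",
        ]
        return "\n".join(lines)
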