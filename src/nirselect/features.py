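"""Temporal statistical features of windowed ΔHbO signals.

Five statistics per channel per trial: the window mean, the peak (maximum),
the fitted slope of a least-squares line (units per second), and the
skewness and kurtosis as population standardized moments,

    S = E[(X - mu)^3] / sigma^3,      K = E[(X - mu)^4] / sigma^4,

with sigma the population (divide-by-N) standard deviation and K on the
non-excess convention (a Gaussian signal has K = 3). For the study layout
of 36 channels this yields the 180-dimensional (36 x 5) feature vector the
wrapper search operates on. Columns are channel-major: all five statistics
of channel 1, then channel 2, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError, DegenerateSignalError, ParameterError
from .preprocess import TrialTensor

__all__ = [
    "STATISTIC_NAMES",
    "ChannelFeatureVector",
    "FeatureTable",
    "channel_statistics",
    "extract_features",
    "save_feature_table",
    "load_feature_table",
]

STATISTIC_NAMES: tuple[str, ...] = ("mean", "peak", "slope", "skewness", "kurtosis")


@dataclass(frozen=True)
class ChannelFeatureVector:
    """The five temporal statistics of one channel over one trial window."""

    mean: float
    peak: float
    slope: float
    skewness: float
    kurtosis: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mean, self.peak, self.slope,
                         self.skewness, self.kurtosis])


def channel_statistics(x: np.ndarray, fs: float) -> ChannelFeatureVector:
    """Compute the five statistics of a windowed signal.

    The slope's time axis is in seconds, so its value reads as a
    concentration change rate. Raises :class:`DegenerateSignalError` for a
    constant window, where the standardized moments are undefined.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ParameterError("x must be a 1-D vector of length >= 3")
    if not np.all(np.isfinite(x)):
        raise DataError("x contains non-finite values")
    if fs <= 0:
        raise ParameterError("fs must be > 0")

    mu = x.mean()
    centered = x - mu
    sigma = np.sqrt(np.mean(centered**2))
    if sigma == 0.0:
        raise DegenerateSignalError("constant signal: moments undefined")

    t = np.arange(x.size) / fs
    slope = np.polyfit(t, x, 1)[0]
    z = centered / sigma
    return ChannelFeatureVector(
        mean=float(mu),
        peak=float(x.max()),
        slope=float(slope),
        skewness=float(np.mean(z**3)),
        kurtosis=float(np.mean(z**4)),
    )


@dataclass
class FeatureTable:
    """Trial-by-feature matrix with class labels and named columns.

    ``column_names`` are (channel_label, statistic) pairs in channel-major
    order, so masks are portable across runs of the same montage.
    """

    values: np.ndarray
    labels: list[str]
    column_names: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be 2-D (trials x features)")
        if len(self.labels) != self.values.shape[0]:
            raise DataError("labels length must equal trial count")
        if len(self.column_names) != self.values.shape[1]:
            raise DataError("column_names length must equal feature count")
        if not np.all(np.isfinite(self.values)):
            raise DataError("feature table contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def to_dataframe(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(self.column_names,
                                         names=["channel", "statistic"])
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, ("label", ""), self.labels)
        return df

    @classmethod
    def from_arrays(cls, values: np.ndarray, labels: list[str],
                    channel_labels: list[str]) -> "FeatureTable":
        cols = [(ch, st) for ch in channel_labels for st in STATISTIC_NAMES]
        return cls(values=values, labels=list(labels), column_names=cols)


def extract_features(trials: TrialTensor,
                     channel_labels: list[str] | None = None) -> FeatureTable:
    """Assemble the (trials x 5*channels) feature table from a trial tensor."""
    if trials.n_trials == 0:
        raise DataError("empty trial tensor")
    if channel_labels is None:
        channel_labels = [f"CH{c + 1}" for c in range(trials.n_channels)]
    values = np.empty((trials.n_trials, trials.n_channels * len(STATISTIC_NAMES)))
    for ti in range(trials.n_trials):
        for ci in range(trials.n_channels):
            try:
                fv = channel_statistics(trials.data[ti, ci], trials.fs)
            except DegenerateSignalError as err:
                raise DegenerateSignalError(
                    f"trial {ti}, channel {ci}: {err}"
                ) from err
            values[ti, ci * 5 : ci * 5 + 5] = fv.as_array()
    return FeatureTable(
        values=values,
        labels=list(trials.labels),
        column_names=[(ch, st) for ch in channel_labels for st in STATISTIC_NAMES],
    )


def save_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Delimited text with a two-row header (channel, statistic) + label column."""
    path = Path(path)
    chan_row = "label\t" + "\t".join(c for c, _ in table.column_names)
    stat_row = "\t" + "\t".join(s for _, s in table.column_names)
    lines = [chan_row, stat_row]
    for lab, row in zip(table.labels, table.values):
        lines.append(lab + "\t" + "\t".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")


def load_feature_table(path: str | Path) -> FeatureTable:
    """Inverse of :func:`save_feature_table`; round-trips losslessly."""
    lines = Path(path).read_text().splitlines()
    channels = lines[0].split("\t")[1:]
    stats = lines[1].split("\t")[1:]
    labels: list[str] = []
    rows: list[list[float]] = []
    for line in lines[2:]:
        parts = line.split("\t")
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    return FeatureTable(
        values=np.array(rows),
        labels=labels,
        column_names=list(zip(channels, stats)),
    )
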