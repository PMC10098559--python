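"""Shared fixtures: synthetic sessions and small constructed feature tables."""

from __future__ import annotations

import numpy as np
import pytest

import nirselect as ns


def make_separable_table(n_per_class: int = 20, d: int = 8,
                         seed: int = 0) -> ns.FeatureTable:
    """One strongly separating feature (column 0) plus d-1 pure-noise columns.

    Class gap (3.0) is 30x the within-class sd, so any mask containing
    column 0 classifies the holdout perfectly and the exhaustive optimum is
    that single column.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    values = rng.standard_normal((n, d))
    values[:n_per_class, 0] = rng.normal(0.0, 0.1, n_per_class)
    values[n_per_class:, 0] = rng.normal(3.0, 0.1, n_per_class)
    labels = ["A"] * n_per_class + ["B"] * n_per_class
    return ns.FeatureTable(values, labels,
                           [(f"F{i}", "x") for i in range(d)])


def make_session_table(amplitude: float = 0.3, seed: int = 11,
                       n_informative: int = 4):
    """Full pipeline on one study-paradigm session: simulate at 12.5 Hz,
    down-sample to 10 Hz, band-pass 0.01-0.1 Hz, epoch the 10-s task
    windows, extract the 36 x 5 feature table. Returns (table, activation).
    """
    paradigm = ns.ParadigmConfig()
    activation = ns.default_activation(paradigm, n_informative=n_informative,
                                       amplitude=amplitude, seed=seed)
    rec = ns.generate_session(paradigm, activation)
    rec = ns.bandpass(ns.resample(rec, paradigm.fs_target))
    tensor = ns.epoch(rec, (0.0, 10.0))
    table = ns.extract_features(tensor, channel_labels=rec.channel_labels)
    return table, activation


@pytest.fixture(scope="session")
def separable_table() -> ns.FeatureTable:
    return make_separable_table()


@pytest.fixture(scope="session")
def session_table():
    return make_session_table()


@pytest.fixture(scope="session")
def default_session():
    """One defaults session (2 classes, 10 trials each) at acquisition rate."""
    paradigm = ns.ParadigmConfig()
    activation = ns.default_activation(paradigm, seed=3)
    return paradigm, activation, ns.generate_session(paradigm, activation)
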