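"""Synthetic fNIRS session generator.

Emulates a block-design motor-imagery / mental-arithmetic paradigm: a
multichannel ΔHbO recording acquired at 12.5 Hz with 36 channels, 20 trials
per session (10 per class), each trial a 2-s cue, a 10-s task phase and a
15-17 s rest, bracketed by 60-s pre/post rest. Class-dependent hemodynamic
activation (a task boxcar convolved with a gamma-shaped hemodynamic response
function) is confined to a configurable subset of "informative" channels,
and every channel carries slow drift, oscillatory physiological noise
(Mayer waves ~0.1 Hz, respiration ~0.25 Hz, cardiac ~1 Hz) and white noise.

Because the informative channels are known by construction, every downstream
stage — filtering, epoching, feature extraction and wrapper selection — can
be tested against ground truth without any external dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .exceptions import DataError, ParameterError

__all__ = [
    "ParadigmConfig",
    "NoiseSpec",
    "ActivationSpec",
    "Recording",
    "generate_hrf_kernel",
    "generate_session",
    "default_activation",
    "save_recording",
    "load_recording",
]


@dataclass(frozen=True)
class ParadigmConfig:
    """Timing and layout of one recording session.

    Defaults reproduce the study paradigm: 36 channels at 12.5 Hz
    (down-sampled later to 10 Hz), 10 trials per class, 2-s cue, 10-s task,
    15-17 s inter-trial rest and one minute of rest at either end.
    """

    n_channels: int = 36
    fs_acquire: float = 12.5
    fs_target: float = 10.0
    n_trials_per_class: int = 10
    classes: tuple[str, ...] = ("MA", "baseline")
    cue_s: float = 2.0
    task_s: float = 10.0
    rest_s_range: tuple[float, float] = (15.0, 17.0)
    pre_rest_s: float = 60.0
    post_rest_s: float = 60.0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ParameterError("n_channels must be >= 1")
        if self.fs_acquire <= 0 or self.fs_target <= 0:
            raise ParameterError("sampling rates must be positive")
        if self.fs_acquire < self.fs_target:
            raise ParameterError("fs_acquire must be >= fs_target")
        if self.n_trials_per_class < 1:
            raise ParameterError("n_trials_per_class must be >= 1")
        if len(self.classes) < 2:
            raise ParameterError("at least two classes required")
        if min(self.cue_s, self.task_s, self.pre_rest_s, self.post_rest_s) < 0:
            raise ParameterError("durations must be non-negative")
        lo, hi = self.rest_s_range
        if lo <= 0 or hi < lo:
            raise ParameterError("rest_s_range must be a positive interval")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model shared by all channels.

    Amplitudes are in the same arbitrary ΔHbO concentration units as the
    activation amplitude. Defaults are chosen so the 0.01-0.1 Hz band-pass
    stage visibly suppresses the cardiac and respiratory components.
    """

    drift_per_min: float = 0.01
    mayer_freq: float = 0.1
    mayer_amp: float = 0.2
    resp_freq: float = 0.25
    resp_amp: float = 0.1
    cardiac_freq: float = 1.0
    cardiac_amp: float = 0.1
    white_sd: float = 0.2

    def __post_init__(self) -> None:
        amps = (self.mayer_amp, self.resp_amp, self.cardiac_amp, self.white_sd)
        if any(a < 0 for a in amps):
            raise ParameterError("noise amplitudes must be >= 0")

    @classmethod
    def silent(cls) -> "NoiseSpec":
        """A zero-noise spec, useful for oracle comparisons."""
        return cls(drift_per_min=0.0, mayer_amp=0.0, resp_amp=0.0,
                   cardiac_amp=0.0, white_sd=0.0)


@dataclass(frozen=True)
class ActivationSpec:
    """Ground-truth activation model for a synthetic session."""

    informative_channels: Mapping[str, tuple[int, ...]]
    amplitude: float = 1.0
    hrf_peak_s: float = 6.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")
        if self.hrf_peak_s <= 0:
            raise ParameterError("hrf_peak_s must be > 0")


@dataclass
class Recording:
    """Continuous multichannel ΔHbO recording with trigger annotations.

    ``data`` is (n_channels, n_samples); ``triggers`` is a list of
    ``(onset_sample, class_label)`` pairs sorted by onset, with onsets
    marking task phase starts.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    triggers: list[tuple[int, str]]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError("data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise DataError("recording contains non-finite values")
        if len(self.channel_labels) != self.data.shape[0]:
            raise DataError("channel_labels length must match channel count")
        onsets = [t[0] for t in self.triggers]
        if onsets != sorted(onsets):
            raise DataError("triggers must be sorted by onset")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def generate_hrf_kernel(fs: float, duration_s: float, peak_s: float) -> np.ndarray:
    """Gamma-family hemodynamic impulse response, normalized to unit maximum.

    The kernel is ``(t/p)^a exp(-a(t/p - 1))`` with shape exponent a = 6,
    a non-negative unimodal bump peaking at ``peak_s`` — a conventional
    stand-in for the sluggish blood-oxygenation response to a neural event.

    Parameters
    ----------
    fs : sampling rate in Hz.
    duration_s : kernel support in seconds; must exceed ``peak_s``.
    peak_s : time-to-peak in seconds (canonically ~6 s).
    """
    if fs <= 0:
        raise ParameterError("fs must be > 0")
    if not (duration_s > peak_s > 0):
        raise ParameterError("require duration_s > peak_s > 0")
    a = 6.0  # shape exponent: wider than cardiac, narrower than the task block
    t = np.arange(int(round(duration_s * fs))) / fs
    with np.errstate(divide="ignore", invalid="ignore"):
        h = (t / peak_s) ** a * np.exp(-a * (t / peak_s - 1.0))
    h[0] = 0.0
    return h / h.max()


def default_activation(
    paradigm: ParadigmConfig,
    n_informative: int = 4,
    amplitude: float = 1.0,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> ActivationSpec:
    """Assign ``n_informative`` distinct channels to the first class.

    A two-class discrimination only needs class-dependent activation; giving
    one class an activated channel block and the other none mirrors a
    task-vs-baseline contrast. With more classes, consecutive disjoint
    blocks of channels are assigned to every class except the last (which
    acts as the baseline condition).
    """
    needed = n_informative * (len(paradigm.classes) - 1)
    if needed > paradigm.n_channels:
        raise ParameterError("not enough channels for the requested layout")
    mapping: dict[str, tuple[int, ...]] = {}
    for i, label in enumerate(paradigm.classes[:-1]):
        lo = i * n_informative
        mapping[label] = tuple(range(lo, lo + n_informative))
    mapping[paradigm.classes[-1]] = ()
    return ActivationSpec(
        informative_channels=mapping,
        amplitude=amplitude,
        noise=noise if noise is not None else NoiseSpec(),
        seed=seed,
    )


def _trial_layout(
    paradigm: ParadigmConfig, rng: np.random.Generator
) -> tuple[list[str], np.ndarray]:
    """Seeded label order and per-trial rest durations."""
    labels = [c for c in paradigm.classes for _ in range(paradigm.n_trials_per_class)]
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]
    rests = rng.uniform(*paradigm.rest_s_range, size=len(labels))
    return labels, rests


def generate_session(
    paradigm: ParadigmConfig, activation: ActivationSpec
) -> Recording:
    """Simulate one session at the acquisition rate.

    Timeline: pre-rest, then for each trial a cue, the task phase (trigger
    onset) and a seeded 15-17 s rest, then post-rest. Informative channels
    of a class receive ``amplitude x (task boxcar ⊗ HRF)`` time-locked to
    that class's triggers; all channels receive the configured drift,
    sinusoidal and white noise. Identical ``ActivationSpec.seed`` gives a
    bit-identical recording.
    """
    for label, chans in activation.informative_channels.items():
        if label not in paradigm.classes:
            raise ParameterError(f"unknown class in activation spec: {label!r}")
        for c in chans:
            if not (0 <= c < paradigm.n_channels):
                raise ParameterError(
                    f"informative channel {c} out of range for "
                    f"{paradigm.n_channels} channels"
                )

    rng = np.random.default_rng(activation.seed)
    fs = paradigm.fs_acquire
    labels, rests = _trial_layout(paradigm, rng)

    total_s = (
        paradigm.pre_rest_s
        + sum(paradigm.cue_s + paradigm.task_s + r for r in rests)
        + paradigm.post_rest_s
    )
    n = int(np.ceil(total_s * fs))
    t = np.arange(n) / fs

    triggers: list[tuple[int, str]] = []
    cursor = paradigm.pre_rest_s
    for label, rest in zip(labels, rests):
        cursor += paradigm.cue_s
        triggers.append((int(round(cursor * fs)), label))
        cursor += paradigm.task_s + rest

    # class-wise neural boxcars convolved with the HRF; scaled so a single
    # task block peaks at exactly `amplitude` concentration units
    task_len = int(round(paradigm.task_s * fs))
    hrf = generate_hrf_kernel(fs, duration_s=25.0, peak_s=activation.hrf_peak_s)
    single_block_peak = np.convolve(np.ones(task_len), hrf).max()
    responses: dict[str, np.ndarray] = {}
    for cls in paradigm.classes:
        box = np.zeros(n)
        for onset, label in triggers:
            if label == cls:
                box[onset : onset + task_len] = 1.0
        responses[cls] = (
            activation.amplitude * np.convolve(box, hrf)[:n] / single_block_peak
        )

    data = np.zeros((paradigm.n_channels, n))
    for cls, chans in activation.informative_channels.items():
        for c in chans:
            data[c] += responses[cls]

    noise = activation.noise
    for c in range(paradigm.n_channels):
        slope = rng.uniform(-noise.drift_per_min, noise.drift_per_min)
        drift = slope * t / 60.0
        osc = np.zeros(n)
        for freq, amp in (
            (noise.mayer_freq, noise.mayer_amp),
            (noise.resp_freq, noise.resp_amp),
            (noise.cardiac_freq, noise.cardiac_amp),
        ):
            phase = rng.uniform(0.0, 2.0 * np.pi)
            osc += amp * np.sin(2.0 * np.pi * freq * t + phase)
        white = rng.normal(0.0, noise.white_sd, size=n) if noise.white_sd else 0.0
        data[c] += drift + osc + white

    channel_labels = [f"CH{c + 1}" for c in range(paradigm.n_channels)]
    return Recording(data=data, fs=fs, channel_labels=channel_labels, triggers=triggers)


# -- delimited-text I/O -------------------------------------------------------

def save_recording(rec: Recording, out_dir: str | Path) -> None:
    """Write ``data.tsv`` (channels as columns) plus ``recording.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = "\t".join(rec.channel_labels)
    np.savetxt(out / "data.tsv", rec.data.T, delimiter="\t",
               header=header, comments="")
    sidecar = {
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "triggers": [{"onset_sample": int(o), "label": l} for o, l in rec.triggers],
    }
    (out / "recording.json").write_text(json.dumps(sidecar, indent=2))


def load_recording(in_dir: str | Path) -> Recording:
    """Inverse of :func:`save_recording`."""
    src = Path(in_dir)
    sidecar = json.loads((src / "recording.json").read_text())
    data = np.loadtxt(src / "data.tsv", delimiter="\t", skiprows=1).T
    if data.ndim == 1:
        data = data[np.newaxis, :]
    return Recording(
        data=data,
        fs=float(sidecar["fs"]),
        channel_labels=list(sidecar["channel_labels"]),
        triggers=[(int(t["onset_sample"]), str(t["label"]))
                  for t in sidecar["triggers"]],
    )
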