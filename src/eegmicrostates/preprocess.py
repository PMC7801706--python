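"""Loading and preprocessing of multichannel EEG recordings.

The preprocessing chain follows standard microstate practice: a 2-20 Hz
zero-phase band-pass, common-average re-referencing, segmentation into
non-overlapping 2-s epochs, and threshold-based artifact rejection
(max |amplitude| > 100 uV or per-channel variance > 500 uV^2).  The chain
order is fixed: filter -> re-reference -> epoch -> reject; filtering is
applied to the continuous recording so epoch edges carry no filter
transients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

from .montage import CHANNELS_1020

__all__ = [
    "Recording",
    "Epoch",
    "ChannelMismatchError",
    "load_recording",
    "save_recording",
    "bandpass_filter",
    "rereference_average",
    "segment_epochs",
    "reject_artifacts",
    "preprocess_recording",
]


class ChannelMismatchError(ValueError):
    """A file's channel labels do not cover the expected montage."""


@dataclass
class Recording:
    """A continuous multichannel EEG recording in microvolts.

    ``data`` is (n_channels, n_samples); channel order follows
    ``channel_labels``.  ``condition`` is ``"rest"`` or ``"task"``;
    ``group`` is ``"good"`` or ``"poor"`` (arithmetic-performance groups).
    """

    data: np.ndarray
    channel_labels: tuple[str, ...]
    rate_hz: float
    subject_id: str | None = None
    condition: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass
class Epoch:
    """One fixed-length window cut from a recording (channels x samples)."""

    data: np.ndarray
    rate_hz: float
    subject_id: str | None = None
    condition: str | None = None
    group: str | None = None
    epoch_index: int = 0
    rejected: bool = False
    reject_reason: str | None = None

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _canonical_order(
    data: np.ndarray, labels: Sequence[str], montage: Sequence[str]
) -> tuple[np.ndarray, tuple[str, ...]]:
    labels = list(labels)
    missing = [c for c in montage if c not in labels]
    if missing:
        raise ChannelMismatchError(f"recording is missing channel(s): {missing}")
    idx = [labels.index(c) for c in montage]
    return data[idx], tuple(montage)


def load_recording(
    path: str | Path,
    metadata: dict | None = None,
    montage: Sequence[str] = CHANNELS_1020,
) -> Recording:
    """Load a recording from EDF or from a numeric matrix + JSON sidecar.

    Matrix files (``.tsv``/``.txt``/``.csv``) hold samples as rows and
    channels as columns, with a sidecar ``<stem>.json`` carrying channel
    labels, sampling rate and subject metadata.  EDF files are read through
    :mod:`mne` (optional dependency).  Channels are re-ordered to the
    canonical 19-name montage; a missing montage channel raises
    :class:`ChannelMismatchError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = dict(metadata or {})
    if path.suffix.lower() == ".edf":
        import mne  # deferred: heavy optional dependency

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne returns volts
        labels = list(raw.ch_names)
        rate = float(raw.info["sfreq"])
    else:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"sidecar not found: {sidecar}")
        side = json.loads(sidecar.read_text())
        data = np.loadtxt(path, ndmin=2).T  # rows=samples on disk
        labels = list(side["channel_labels"])
        rate = float(side["rate_hz"])
        for k in ("subject_id", "condition", "group"):
            meta.setdefault(k, side.get(k))
    data, labels = _canonical_order(data, labels, montage)
    return Recording(
        data=data,
        channel_labels=labels,
        rate_hz=rate,
        subject_id=meta.get("subject_id"),
        condition=meta.get("condition"),
        group=meta.get("group"),
    )


def save_recording(rec: Recording, path: str | Path, fmt: str = "%.6f") -> Path:
    """Write a recording as a TSV matrix (samples x channels) + JSON sidecar."""
    path = Path(path)
    np.savetxt(path, rec.data.T, fmt=fmt, delimiter="\t")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "channel_labels": list(rec.channel_labels),
                "rate_hz": rec.rate_hz,
                "subject_id": rec.subject_id,
                "condition": rec.condition,
                "group": rec.group,
                "units": "uV",
            },
            indent=1,
        )
    )
    return path


def bandpass_filter(
    rec: Recording, low_hz: float = 2.0, high_hz: float = 20.0, order: int = 4
) -> Recording:
    """Zero-phase Butterworth band-pass of the continuous recording.

    A 4th-order Butterworth applied forward and backward (``sosfiltfilt``)
    gives zero phase distortion, which preserves the timing of topographic
    transitions that microstate segmentation depends on.
    """
    if not (0 < low_hz < high_hz < rec.rate_hz / 2):
        raise ValueError(
            f"invalid band ({low_hz}, {high_hz}) Hz for rate {rec.rate_hz} Hz"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.rate_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=filtered)


def rereference_average(rec: Recording) -> Recording:
    """Re-reference to the common average: subtract the per-sample channel mean."""
    if rec.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    return replace(rec, data=rec.data - rec.data.mean(axis=0, keepdims=True))


def segment_epochs(rec: Recording, length_s: float = 2.0) -> list[Epoch]:
    """Cut consecutive non-overlapping epochs of ``length_s`` seconds.

    Epoch boundaries are half-open sample intervals; a trailing remainder
    shorter than one epoch is discarded.  Returns an empty list when the
    recording is shorter than one epoch.
    """
    n_per = int(round(length_s * rec.rate_hz))
    if n_per < 1:
        raise ValueError("epoch length must cover at least one sample")
    n_epochs = rec.n_samples // n_per
    return [
        Epoch(
            data=rec.data[:, i * n_per : (i + 1) * n_per].copy(),
            rate_hz=rec.rate_hz,
            subject_id=rec.subject_id,
            condition=rec.condition,
            group=rec.group,
            epoch_index=i,
        )
        for i in range(n_epochs)
    ]


def reject_artifacts(
    epochs: Iterable[Epoch],
    amp_threshold_uv: float = 100.0,
    var_threshold: float = 500.0,
    manual_exclusions: set[tuple[str | None, int]] | None = None,
) -> tuple[list[Epoch], list[dict]]:
    """Flag artifact epochs; return (kept epochs, rejection log).

    An epoch is rejected iff any channel's max |value| exceeds
    ``amp_threshold_uv`` (uV), any channel's variance exceeds
    ``var_threshold`` (uV^2), or its (subject_id, epoch_index) pair appears
    in ``manual_exclusions`` (the deterministic stand-in for visual
    inspection).  The log records one row per rejected epoch with the
    offending channel and value.
    """
    manual = manual_exclusions or set()
    kept: list[Epoch] = []
    log: list[dict] = []
    for ep in epochs:
        reason = None
        channel: int | None = None
        value = np.nan
        if (ep.subject_id, ep.epoch_index) in manual:
            reason = "manual"
        else:
            absmax = np.abs(ep.data).max(axis=1)
            if absmax.max() > amp_threshold_uv:
                i = int(absmax.argmax())
                reason, channel, value = "amplitude", i, float(absmax[i])
            else:
                var = ep.data.var(axis=1)
                if var.max() > var_threshold:
                    i = int(var.argmax())
                    reason, channel, value = "variance", i, float(var[i])
        if reason is None:
            kept.append(ep)
        else:
            ep.rejected = True
            ep.reject_reason = reason
            log.append(
                {
                    "subject_id": ep.subject_id,
                    "condition": ep.condition,
                    "epoch_index": ep.epoch_index,
                    "reason": reason,
                    "channel": channel,
                    "value": value,
                }
            )
    return kept, log


def preprocess_recording(
    rec: Recording,
    low_hz: float = 2.0,
    high_hz: float = 20.0,
    bandpass: bool = True,
    epoch_length_s: float = 2.0,
    amp_threshold_uv: float = 100.0,
    var_threshold: float = 500.0,
    manual_exclusions: set[tuple[str | None, int]] | None = None,
) -> tuple[list[Epoch], list[dict]]:
    """Full chain: band-pass (optional), average reference, epoch, reject."""
    if bandpass:
        rec = bandpass_filter(rec, low_hz, high_hz)
    rec = rereference_average(rec)
    epochs = segment_epochs(rec, epoch_length_s)
    return reject_artifacts(epochs, amp_threshold_uv, var_threshold, manual_exclusions)
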