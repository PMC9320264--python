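"""Continuous-recording preprocessing: resampling, band filtering, epoching.

The processing chain mirrors a standard resting-state EEG pipeline:
downsample to a working rate, zero-phase Butterworth band-pass over the
broadband analysis range, optional artifact-removal hook, segmentation into
overlapping fixed-length epochs, and per-rhythm band decomposition.

Filtering is always applied to the *continuous* signal; epochs are then cut
from every filtered stream at identical offsets.  Short windows (4 s) are
comparable to the theta-band filter transient, so filtering per epoch would
corrupt the band estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import signal

from .montage import BANDS, BROADBAND, CHANNELS

#: Default filter order passed to the Butterworth designer.
FILTER_ORDER = 4


@dataclass
class Recording:
    """A continuous multichannel recording.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal matrix (microvolt-scale for real EEG; arbitrary units for
        synthetic input).
    fs : float
        Sampling rate in samples/second.
    channels : tuple of str
        Ordered channel names, one per row of ``data``.
    subject_id : str
        Subject identifier.
    group : str
        Cohort label (e.g. ``"GAD"`` or ``"HC"``).
    """

    data: np.ndarray
    fs: float
    channels: tuple[str, ...] = CHANNELS
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} rows"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains NaN or Inf samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Segmented epochs with broadband and per-rhythm versions.

    ``broadband`` has shape (n_epochs, n_channels, n_window_samples); each
    entry of ``bands`` has the same shape.  ``subject_ids`` and ``groups``
    carry per-epoch provenance.  ``source`` retains the continuous broadband
    recording so that rhythm extraction can filter the continuous signal and
    cut windows at the stored ``offsets``.
    """

    broadband: np.ndarray
    subject_ids: list[str]
    groups: list[str]
    fs: float
    window_s: float
    overlap_frac: float
    channels: tuple[str, ...]
    offsets: np.ndarray
    bands: dict[str, np.ndarray] = field(default_factory=dict)
    source: Recording | None = None

    @property
    def n_epochs(self) -> int:
        return self.broadband.shape[0]

    @property
    def n_window_samples(self) -> int:
        return self.broadband.shape[2]

    def __len__(self) -> int:
        return self.n_epochs


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased polyphase resampling of a recording to ``target_fs``.

    Output length is ``floor(n_samples * target_fs / fs)``.  Upsampling is
    not supported.
    """
    if target_fs >= rec.fs:
        raise ValueError("target_fs must be below the recording rate")
    from fractions import Fraction

    ratio = Fraction(target_fs / rec.fs).limit_denominator(1000)
    up, down = ratio.numerator, ratio.denominator
    out = signal.resample_poly(rec.data, up, down, axis=1)
    n_out = int(np.floor(rec.n_samples * target_fs / rec.fs))
    out = out[:, :n_out]
    return replace(rec, data=out, fs=float(target_fs))


def _band_sos(lo: float, hi: float, fs: float, order: int = FILTER_ORDER):
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band ({lo}, {hi}) Hz invalid for fs={fs}")
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass(rec: Recording, lo: float, hi: float, order: int = FILTER_ORDER) -> Recording:
    """Zero-phase Butterworth band-pass of the continuous recording.

    The filter is applied forward and backward (``sosfiltfilt``) so that
    phase estimates downstream are undistorted; the effective magnitude
    response is the design response squared.
    """
    sos = _band_sos(lo, hi, rec.fs, order)
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=out)


def identity_artifact_hook(rec: Recording) -> Recording:
    """Default artifact-removal hook: pass-through.

    Synthetic cohorts carry no ocular or muscle artifacts; an ICA-based
    cleaner may be substituted here when processing real recordings.
    """
    return rec


def segment(rec: Recording, window_s: float = 4.0, overlap_frac: float = 0.5) -> EpochSet:
    """Cut the recording into fixed-length windows with fractional overlap.

    Windows start every ``window_s * (1 - overlap_frac)`` seconds; a trailing
    partial window is dropped.  The epoch count is
    ``floor((T - window_s) / (window_s * (1 - overlap_frac))) + 1``.
    """
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must lie in [0, 1)")
    win = int(round(window_s * rec.fs))
    if rec.n_samples < win:
        raise ValueError(
            f"recording of {rec.n_samples} samples shorter than one "
            f"{win}-sample window"
        )
    step = int(round(window_s * (1 - overlap_frac) * rec.fs))
    offsets = np.arange(0, rec.n_samples - win + 1, step)
    windows = np.stack([rec.data[:, o : o + win] for o in offsets])
    return EpochSet(
        broadband=windows,
        subject_ids=[rec.subject_id] * len(offsets),
        groups=[rec.group] * len(offsets),
        fs=rec.fs,
        window_s=window_s,
        overlap_frac=overlap_frac,
        channels=rec.channels,
        offsets=offsets,
        source=rec,
    )


def extract_rhythms(
    epochs: EpochSet,
    bands: dict[str, tuple[float, float]] | None = None,
    order: int = FILTER_ORDER,
) -> EpochSet:
    """Add per-rhythm band-filtered versions of every epoch.

    Each rhythm is obtained by zero-phase Butterworth filtering of the
    *continuous* source recording, after which windows are cut at the same
    offsets as the broadband epochs.
    """
    if epochs.source is None:
        raise ValueError("EpochSet has no continuous source recording")
    bands = dict(BANDS) if bands is None else bands
    win = epochs.n_window_samples
    out: dict[str, np.ndarray] = {}
    for name, (lo, hi) in bands.items():
        filtered = bandpass(epochs.source, lo, hi, order=order)
        out[name] = np.stack([filtered.data[:, o : o + win] for o in epochs.offsets])
    return replace(epochs, bands=out)


def preprocess_recording(
    rec: Recording,
    target_fs: float = 100.0,
    broadband: tuple[float, float] = BROADBAND,
    window_s: float = 4.0,
    overlap_frac: float = 0.5,
    bands: dict[str, tuple[float, float]] | None = None,
    artifact_hook: Callable[[Recording], Recording] = identity_artifact_hook,
) -> EpochSet:
    """Full preprocessing chain for one recording.

    Downsample -> broadband zero-phase band-pass -> artifact hook ->
    overlapping segmentation -> per-rhythm decomposition.
    """
    if rec.fs > target_fs:
        rec = downsample(rec, target_fs)
    elif rec.fs < target_fs:
        raise ValueError("recording rate below the requested working rate")
    rec = bandpass(rec, *broadband)
    rec = artifact_hook(rec)
    epochs = segment(rec, window_s=window_s, overlap_frac=overlap_frac)
    return extract_rhythms(epochs, bands=bands)


def concat_epochs(epoch_sets: Sequence[EpochSet] | Iterable[EpochSet]) -> EpochSet:
    """Concatenate per-subject epoch sets into a single cohort-level set."""
    epoch_sets = list(epoch_sets)
    if not epoch_sets:
        raise ValueError("no epoch sets to concatenate")
    first = epoch_sets[0]
    for es in epoch_sets[1:]:
        if es.channels != first.channels or es.fs != first.fs:
            raise ValueError("epoch sets differ in montage or sampling rate")
        if set(es.bands) != set(first.bands):
            raise ValueError("epoch sets differ in extracted rhythms")
    return EpochSet(
        broadband=np.concatenate([es.broadband for es in epoch_sets]),
        subject_ids=[s for es in epoch_sets for s in es.subject_ids],
        groups=[g for es in epoch_sets for g in es.groups],
        fs=first.fs,
        window_s=first.window_s,
        overlap_frac=first.overlap_frac,
        channels=first.channels,
        offsets=np.concatenate([es.offsets for es in epoch_sets]),
        bands={
            b: np.concatenate([es.bands[b] for es in epoch_sets]) for b in first.bands
        },
        source=None,
    )
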