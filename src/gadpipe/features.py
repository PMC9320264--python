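"""Epoch-level feature families: relative band power, fuzzy entropy, PLI.

Three families, each decoding a different dimension of the signal:

* **PSD** — relative band power from a one-sided periodogram of the
  broadband window, normalised by the bandwidth ratio so a flat spectrum
  scores 1 in every band.
* **FE** — fuzzy entropy, a signal-complexity measure comparing the
  similarity of embedded vector pairs at dimensions m and m+1 under a
  Gaussian-family kernel ``exp(-ln 2 (d/r)^2)`` with tolerance
  ``r = k * sd(window)``.
* **PLI** — phase lag index, the absolute time-average of the sign of the
  wrapped instantaneous phase difference between two channels, computed on
  analytic-signal phases of the band-filtered windows.

`build_feature_table` assembles one row per epoch with a deterministic
column order: the PSD block, then FE, then PLI; within each block
band-major (theta, alpha1, alpha2, beta), then channel (montage order) or
channel pair (upper-triangle order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.spatial.distance import pdist

from .montage import BAND_NAMES, BANDS, BROADBAND
from .preprocess import EpochSet

FAMILIES = ("PSD", "FE", "PLI")

#: Fraction of phase samples discarded at each window edge before PLI, to
#: suppress analytic-signal boundary distortion.
PLI_EDGE_TRIM = 0.05


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


@dataclass
class Spectrum:
    """One-sided periodogram of a real window.

    ``power`` is normalised so that ``power.sum()`` equals the mean squared
    signal (non-DC, non-Nyquist bins carry the standard factor-2 doubling).
    """

    freqs: np.ndarray
    power: np.ndarray
    n: int


def periodogram(window: np.ndarray, fs: float) -> Spectrum:
    """Raw (boxcar) one-sided periodogram on the FFT bin grid."""
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("window must be a 1-D vector of length >= 2")
    n = x.size
    spec = np.fft.rfft(x)
    power = np.abs(spec) ** 2 / n**2
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return Spectrum(freqs=freqs, power=power, n=n)


def band_power(spec: Spectrum, lo: float, hi: float) -> float:
    """Summed power over FFT bins in the half-open interval [lo, hi) Hz."""
    mask = (spec.freqs >= lo) & (spec.freqs < hi)
    return float(spec.power[mask].sum())


def relative_power(
    spec: Spectrum,
    band: tuple[float, float],
    total: tuple[float, float] = BROADBAND,
) -> float:
    """Bandwidth-normalised relative power of one rhythm band.

    Returns ``(P_band / P_total) * (f_m - f_n) / (f_h - f_l)`` where the
    integrals are discrete sums over half-open [lo, hi) bin intervals, so
    shared band edges are never double-counted.  A flat spectrum yields
    exactly 1 for every band.
    """
    f_l, f_h = band
    f_n, f_m = total
    if not (f_n <= f_l < f_h <= f_m):
        raise ValueError("band must lie within the total range")
    denom = band_power(spec, f_n, f_m)
    if denom <= 0:
        raise ValueError("zero total-band power: degenerate window")
    num = band_power(spec, f_l, f_h)
    return (num / denom) * (f_m - f_n) / (f_h - f_l)


# ---------------------------------------------------------------------------
# fuzzy entropy
# ---------------------------------------------------------------------------


@dataclass
class FuzzyParams:
    """Fuzzy-entropy parameters.

    m is the embedding dimension; the tolerance is ``r = k * sd(window)``
    with k conventionally in [0.10, 0.25].  The similarity kernel is
    ``exp(-ln 2 * (d / r)^2)`` (exponent fixed at 2), which equals 1/2 at
    ``d = r``.
    """

    m: int = 2
    k: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if not 0.0 < self.k:
            raise ValueError("tolerance coefficient k must be positive")


def _embed(x: np.ndarray, p: int, n_vec: int) -> np.ndarray:
    """First ``n_vec`` sliding windows of length p, each window mean-removed."""
    idx = np.arange(n_vec)[:, None] + np.arange(p)[None, :]
    v = x[idx]
    return v - v.mean(axis=1, keepdims=True)


def _mean_similarity(vectors: np.ndarray, r: float) -> float:
    """Average pairwise similarity exp(-ln2 (d/r)^2), d = Chebyshev distance.

    The distance matrix is symmetric with zero diagonal, so only the
    condensed upper triangle is evaluated.
    """
    n = vectors.shape[0]
    d = pdist(vectors, "chebyshev")
    sim_sum = np.exp(-np.log(2.0) * (d / r) ** 2).sum()
    return float(2.0 * sim_sum / (n * (n - 1)))


def fuzzy_entropy(window: np.ndarray, params: FuzzyParams = FuzzyParams()) -> float:
    """Fuzzy entropy FE(m, r, N) = ln O^m(r) - ln O^{m+1}(r).

    Embedded vectors of length m and m+1 (both N - m of them) are compared
    after removing each vector's own mean; similarity uses the Gaussian
    kernel above with ``r = k * sd``.  A constant window returns 0 by
    convention (all distances vanish, all similarities are 1).  The value is
    invariant to positive rescaling of the window because r scales with it.
    """
    x = np.asarray(window, dtype=float)
    m = params.m
    if x.ndim != 1 or x.size <= m + 1:
        raise ValueError(f"window length must exceed m + 1 = {m + 1}")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = params.k * sd
    n_vec = x.size - m
    o_m = _mean_similarity(_embed(x, m, n_vec), r)
    o_m1 = _mean_similarity(_embed(x, m + 1, n_vec), r)
    return float(np.log(o_m) - np.log(o_m1))


def fuzzy_entropy_many(
    windows: np.ndarray, params: FuzzyParams = FuzzyParams()
) -> np.ndarray:
    """Fuzzy entropy of each row of a 2-D array of windows."""
    w = np.asarray(windows, dtype=float)
    if w.ndim != 2:
        raise ValueError("windows must be 2-D (n_windows x n_samples)")
    return np.array([fuzzy_entropy(row, params) for row in w])


# ---------------------------------------------------------------------------
# phase lag index
# ---------------------------------------------------------------------------


def hilbert_phase(window: np.ndarray) -> np.ndarray:
    """Instantaneous phase of the analytic signal, values in (-pi, pi].

    Operates along the last axis; intended for band-limited windows.
    """
    x = np.asarray(window, dtype=float)
    if not np.any(x):
        raise ValueError("phase undefined for an all-zero window")
    return np.angle(signal.hilbert(x, axis=-1))


def wrap_phase(d: np.ndarray) -> np.ndarray:
    """Wrap phase differences to the interval (-pi, pi]."""
    out = np.mod(d + np.pi, 2.0 * np.pi) - np.pi
    return np.where(out == -np.pi, np.pi, out)


def pli(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Phase lag index |<sign(wrap(phi_a - phi_b))>| in [0, 1].

    0 means no consistent lead/lag relation (including identical phases,
    where sign(0) = 0); 1 means a perfectly consistent nonzero lag.
    """
    a = np.asarray(phase_a, dtype=float)
    b = np.asarray(phase_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("phase vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 phase samples")
    return float(np.abs(np.mean(np.sign(wrap_phase(a - b)))))


def _pli_matrix(phases: np.ndarray, iu: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """PLI of every channel pair; ``phases`` is (n_channels, n_samples)."""
    d = wrap_phase(phases[iu[0]] - phases[iu[1]])
    return np.abs(np.sign(d).mean(axis=1))


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureColumn:
    """Column descriptor: family kind, rhythm band, channel or channel pair."""

    kind: str
    band: str
    channels: tuple[str, ...]

    @property
    def name(self) -> str:
        return f"{self.kind}:{self.band}:{'-'.join(self.channels)}"


@dataclass
class FeatureTable:
    """Epochs x features matrix with column and row metadata."""

    values: np.ndarray
    columns: list[FeatureColumn]
    row_meta: pd.DataFrame  # columns: subject_id, group

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.row_meta), len(self.columns)):
            raise ValueError("values shape inconsistent with metadata")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains NaN or Inf")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column_mask(
        self,
        kind: str | None = None,
        band: str | None = None,
    ) -> np.ndarray:
        return np.array(
            [
                (kind is None or c.kind == kind) and (band is None or c.band == band)
                for c in self.columns
            ]
        )

    def column_index(self, kind: str, band: str, channels) -> int:
        """Index of the column matching kind, band and channel (set)."""
        want = {channels} if isinstance(channels, str) else set(channels)
        for i, c in enumerate(self.columns):
            if c.kind == kind and c.band == band and set(c.channels) == want:
                return i
        raise KeyError(f"no column {kind}:{band}:{sorted(want)}")

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask, dtype=bool)
        return FeatureTable(
            values=self.values[:, mask],
            columns=[c for c, keep in zip(self.columns, mask) if keep],
            row_meta=self.row_meta,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[c.name for c in self.columns])
        return pd.concat([self.row_meta.reset_index(drop=True), df], axis=1)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        meta = df[["subject_id", "group"]]
        feat = df.drop(columns=["subject_id", "group"])
        cols = []
        for name in feat.columns:
            kind, band, chans = name.split(":")
            cols.append(FeatureColumn(kind, band, tuple(chans.split("-"))))
        return cls(values=feat.to_numpy(float), columns=cols, row_meta=meta)


def feature_columns(
    channels: Sequence[str],
    families: Iterable[str] = FAMILIES,
    bands: Sequence[str] = BAND_NAMES,
) -> list[FeatureColumn]:
    """The deterministic column layout for a montage and family selection."""
    families = [f for f in FAMILIES if f in set(families)]
    cols: list[FeatureColumn] = []
    for fam in families:
        for band in bands:
            if fam in ("PSD", "FE"):
                cols.extend(FeatureColumn(fam, band, (ch,)) for ch in channels)
            else:
                cols.extend(
                    FeatureColumn(fam, band, pair)
                    for pair in combinations(channels, 2)
                )
    return cols


def build_feature_table(
    epochs: EpochSet,
    families: Iterable[str] = FAMILIES,
    fe_params: FuzzyParams = FuzzyParams(),
    edge_trim: float = PLI_EDGE_TRIM,
) -> FeatureTable:
    """Compute all requested feature families for every epoch.

    PSD features come from one periodogram per (epoch, channel) on the
    broadband window; FE and PLI are computed on the band-filtered windows,
    PLI on analytic-signal phases with ``edge_trim`` of the samples dropped
    at each end.
    """
    fams = set(families)
    unknown = fams - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown feature families: {sorted(unknown)}")
    if epochs.n_epochs == 0:
        raise ValueError("no epochs")
    if fams - {"PSD"} and not epochs.bands:
        raise ValueError("FE/PLI need band-filtered windows; run extract_rhythms")

    n_ep = epochs.n_epochs
    n_ch = len(epochs.channels)
    blocks: list[np.ndarray] = []

    if "PSD" in fams:
        psd = np.empty((n_ep, len(BAND_NAMES) * n_ch))
        for e in range(n_ep):
            specs = [periodogram(epochs.broadband[e, c], epochs.fs) for c in range(n_ch)]
            col = 0
            for band in BAND_NAMES:
                for c in range(n_ch):
                    psd[e, col] = relative_power(specs[c], BANDS[band])
                    col += 1
        blocks.append(psd)

    if "FE" in fams:
        fe = np.empty((n_ep, len(BAND_NAMES) * n_ch))
        for bi, band in enumerate(BAND_NAMES):
            w = epochs.bands[band]  # (n_ep, n_ch, L)
            flat = w.reshape(n_ep * n_ch, -1)
            vals = fuzzy_entropy_many(flat, fe_params).reshape(n_ep, n_ch)
            fe[:, bi * n_ch : (bi + 1) * n_ch] = vals
        blocks.append(fe)

    if "PLI" in fams:
        iu = np.triu_indices(n_ch, k=1)
        n_pairs = len(iu[0])
        L = epochs.n_window_samples
        t0 = int(np.floor(edge_trim * L))
        t1 = L - t0
        pli_block = np.empty((n_ep, len(BAND_NAMES) * n_pairs))
        for bi, band in enumerate(BAND_NAMES):
            w = epochs.bands[band]
            for e in range(n_ep):
                phases = hilbert_phase(w[e])[:, t0:t1]
                pli_block[e, bi * n_pairs : (bi + 1) * n_pairs] = _pli_matrix(
                    phases, iu
                )
        blocks.append(pli_block)

    values = np.concatenate(blocks, axis=1)
    cols = feature_columns(epochs.channels, fams)
    meta = pd.DataFrame(
        {"subject_id": epochs.subject_ids, "group": epochs.groups}
    )
    return FeatureTable(values=values, columns=cols, row_meta=meta)
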