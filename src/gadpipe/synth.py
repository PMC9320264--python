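"""Synthetic two-cohort resting-EEG generator.

Each subject's channel signal is a sum of four band-limited stochastic
oscillations (white noise filtered into the rhythm band, so instantaneous
phase is non-degenerate), plus 1/f^slope background noise.  Group effects
are injected in two ways:

* **Band power** — per-group oscillation amplitudes (e.g. a patient group
  with beta amplitude scaled up and alpha1 scaled down).
* **Lagged coupling** — a coupled channel pair shares one latent
  band-limited source; the second channel receives it rotated by a constant
  phase lag (a rotation of the analytic signal).  The coupled band component
  is a *normalised* convex mixture ``[(1-w)·intrinsic + w·source] /
  sqrt((1-w)^2 + w^2)`` with a per-group mixing weight ``w``, so coupling
  strength moves phase synchronisation without moving band power.  A weight
  of 1 yields near-perfect phase locking; 0 removes the coupling.

Generation is deterministic given the cohort seed: per-subject streams are
derived with ``numpy.random.SeedSequence(seed, group index, subject index)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal

from .montage import BANDS, CHANNELS, channel_index
from .preprocess import FILTER_ORDER, Recording

GROUPS = ("GAD", "HC")


@dataclass
class CouplingSpec:
    """A lagged coupling between two channels in one rhythm band.

    ``strength`` maps group label to the mixing weight in [0, 1].  A zero
    ``lag_rad`` is legal but invisible to the phase lag index by
    construction (zero-lag synchrony has no consistent lead/lag).
    """

    chan_a: str
    chan_b: str
    band: str
    lag_rad: float
    strength: dict[str, float]

    def __post_init__(self) -> None:
        if self.chan_a == self.chan_b:
            raise ValueError("coupled channels must differ")
        channel_index(self.chan_a)
        channel_index(self.chan_b)
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")
        for g, w in self.strength.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"strength[{g!r}]={w} outside [0, 1]")


@dataclass
class CohortSpec:
    """Parameters of a two-cohort synthetic resting-EEG study.

    Attributes
    ----------
    n_per_group : int
        Subjects per cohort (>= 2).
    duration_s : float
        Continuous recording length per subject in seconds.
    fs : float
        Sampling rate in samples/second.
    band_amp : dict
        ``group -> band -> oscillation amplitude`` (standard-deviation
        units of the band-limited oscillation).
    couplings : list of CouplingSpec
        Lagged channel couplings; at most one per (channel, band).
    noise_sigma : float
        Standard deviation of the 1/f^slope background noise.
    noise_slope : float
        Spectral exponent of the background (power ~ 1/f^slope).
    amp_jitter : float
        Half-width of the uniform per-subject, per-band relative amplitude
        jitter (0.1 = +/-10 %), so epochs from different subjects are not
        exchangeable.
    seed : int
        Master seed of the cohort.
    """

    n_per_group: int
    duration_s: float = 600.0
    fs: float = 250.0
    band_amp: dict[str, dict[str, float]] = field(default_factory=dict)
    couplings: list[CouplingSpec] = field(default_factory=list)
    noise_sigma: float = 1.0
    noise_slope: float = 1.0
    amp_jitter: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.duration_s * self.fs < 1:
            raise ValueError("recording must contain at least one sample")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for g, amps in self.band_amp.items():
            for b, a in amps.items():
                if b not in BANDS:
                    raise ValueError(f"unknown band {b!r} in band_amp[{g!r}]")
                if a < 0:
                    raise ValueError("band amplitudes must be >= 0")
        seen: set[tuple[str, str]] = set()
        for c in self.couplings:
            for ch in (c.chan_a, c.chan_b):
                key = (ch, c.band)
                if key in seen:
                    raise ValueError(
                        f"channel {ch} has more than one coupling in band {c.band}"
                    )
                seen.add(key)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["couplings"] = [
            c if isinstance(c, CouplingSpec) else CouplingSpec(**c)
            for c in d.get("couplings", [])
        ]
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _band_noise(rng: np.random.Generator, n: int, band: tuple[float, float], fs: float) -> np.ndarray:
    """Unit-variance band-limited noise (zero-phase Butterworth of white noise)."""
    x = rng.standard_normal(n)
    sos = signal.butter(FILTER_ORDER, list(band), btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def _pink_noise(rng: np.random.Generator, n: int, slope: float, sigma: float, fs: float) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^slope, scaled to sd ``sigma``."""
    if sigma == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    scale = np.zeros(len(freqs))
    scale[1:] = freqs[1:] ** (-slope / 2.0)
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return sigma * x / sd if sd > 0 else x


def _rotate_phase(x: np.ndarray, lag_rad: float) -> np.ndarray:
    """Delay a band-limited signal by ``lag_rad`` via analytic-signal rotation."""
    return np.real(signal.hilbert(x) * np.exp(-1j * lag_rad))


def generate_subject(spec: CohortSpec, group: str, subject_index: int) -> Recording:
    """Generate one subject's 16-channel recording.

    Deterministic given ``(spec.seed, group, subject_index)``.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    if not 0 <= subject_index < spec.n_per_group:
        raise ValueError("subject_index out of range")
    n = spec.n_samples
    rng = np.random.default_rng(
        np.random.SeedSequence((spec.seed, GROUPS.index(group), subject_index))
    )
    amps = spec.band_amp.get(group, {})

    # per-subject, per-band amplitude jitter
    jitter = {
        b: 1.0 + rng.uniform(-spec.amp_jitter, spec.amp_jitter) for b in BANDS
    }

    # latent coupled sources, one per coupling
    sources = {id(c): _band_noise(rng, n, BANDS[c.band], spec.fs) for c in spec.couplings}
    coupled: dict[tuple[str, str], tuple[np.ndarray, float]] = {}
    for c in spec.couplings:
        w = c.strength.get(group, 0.0)
        if not 0.0 <= w <= 1.0:
            raise ValueError("coupling strength outside [0, 1]")
        src = sources[id(c)]
        coupled[(c.chan_a, c.band)] = (src, w)
        coupled[(c.chan_b, c.band)] = (_rotate_phase(src, c.lag_rad), w)

    data = np.zeros((len(CHANNELS), n))
    for ci, ch in enumerate(CHANNELS):
        for b, edges in BANDS.items():
            amp = amps.get(b, 0.0) * jitter[b]
            if amp == 0.0 and (ch, b) not in coupled:
                continue
            intrinsic = _band_noise(rng, n, edges, spec.fs)
            if (ch, b) in coupled:
                src, w = coupled[(ch, b)]
                norm = np.hypot(1.0 - w, w)
                comp = ((1.0 - w) * intrinsic + w * src) / norm
            else:
                comp = intrinsic
            data[ci] += amp * comp
        data[ci] += _pink_noise(rng, n, spec.noise_slope, spec.noise_sigma, spec.fs)

    return Recording(
        data=data,
        fs=spec.fs,
        channels=CHANNELS,
        subject_id=f"{group}{subject_index + 1:02d}",
        group=group,
    )


def generate_cohort(spec: CohortSpec) -> list[Recording]:
    """Generate the full two-cohort study: ``2 * n_per_group`` recordings."""
    return [
        generate_subject(spec, group, i)
        for group in GROUPS
        for i in range(spec.n_per_group)
    ]


def flat_band_amps(value: float = 1.0) -> dict[str, dict[str, float]]:
    """Identical oscillation amplitudes for both groups in every band."""
    return {g: {b: value for b in BANDS} for g in GROUPS}


def null_cohort_spec(
    n_per_group: int = 10, duration_s: float = 60.0, seed: int = 0
) -> CohortSpec:
    """A cohort with no implanted group effects (type-I calibration runs)."""
    return CohortSpec(
        n_per_group=n_per_group,
        duration_s=duration_s,
        band_amp=flat_band_amps(),
        couplings=[],
        seed=seed,
    )


#: Frontal-to-other channel pairs carrying the implanted coupling effect,
#: two per rhythm band.
DEFAULT_COUPLED_PAIRS: dict[str, list[tuple[str, str]]] = {
    "theta": [("Fp1", "C3"), ("F4", "P4")],
    "alpha1": [("F3", "P3"), ("Fp2", "C4")],
    "alpha2": [("F7", "T7"), ("F8", "T8")],
    "beta": [("F3", "P4"), ("F7", "C3")],
}


def effect_cohort_spec(
    n_per_group: int = 10,
    duration_s: float = 60.0,
    seed: int = 0,
    beta_scale: float = 1.3,
    alpha1_scale: float = 0.75,
    strength_hc: float = 0.8,
    strength_gad: float = 0.3,
    lag_rad: float = np.pi / 4,
) -> CohortSpec:
    """The default group-effect preset.

    The patient group ("GAD") has beta oscillation amplitude scaled by
    ``beta_scale`` and alpha1 by ``alpha1_scale`` relative to controls, and
    the mixing weight of every frontal-to-other coupling drops from
    ``strength_hc`` to ``strength_gad``.
    """
    band_amp = flat_band_amps()
    band_amp["GAD"]["beta"] *= beta_scale
    band_amp["GAD"]["alpha1"] *= alpha1_scale
    couplings = [
        CouplingSpec(a, b, band, lag_rad, {"HC": strength_hc, "GAD": strength_gad})
        for band, pairs in DEFAULT_COUPLED_PAIRS.items()
        for a, b in pairs
    ]
    return CohortSpec(
        n_per_group=n_per_group,
        duration_s=duration_s,
        band_amp=band_amp,
        couplings=couplings,
        seed=seed,
    )


def implanted_effects(spec: CohortSpec) -> list[dict]:
    """Enumerate the features a spec implants, with expected difference signs.

    Returns dicts with keys ``kind`` ("PSD" or "PLI"), ``band``, ``channels``
    (a name or an unordered pair) and ``sign`` (+1 if the patient-group mean
    should exceed controls, -1 otherwise).  Band-amplitude effects translate
    to relative-power signs; coupling-strength effects to PLI signs.
    """
    out: list[dict] = []
    gad = spec.band_amp.get("GAD", {})
    hc = spec.band_amp.get("HC", {})
    for b in BANDS:
        a_g, a_h = gad.get(b, 0.0), hc.get(b, 0.0)
        if a_g != a_h:
            sign = 1 if a_g > a_h else -1
            out.extend(
                {"kind": "PSD", "band": b, "channels": ch, "sign": sign}
                for ch in CHANNELS
            )
    for c in spec.couplings:
        w_g = c.strength.get("GAD", 0.0)
        w_h = c.strength.get("HC", 0.0)
        if w_g != w_h and c.lag_rad != 0.0:
            out.append(
                {
                    "kind": "PLI",
                    "band": c.band,
                    "channels": frozenset((c.chan_a, c.chan_b)),
                    "sign": 1 if w_g > w_h else -1,
                }
            )
    return out
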