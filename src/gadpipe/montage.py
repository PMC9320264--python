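"""Channel montage and rhythm band definitions.

Sixteen scalp electrodes of the international 10-20 system and the four
canonical analysis rhythms used throughout the pipeline.
"""

from __future__ import annotations

CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4",
    "O1", "O2", "F7", "F8", "T7", "T8", "P7", "P8",
)

#: Frontal electrode subset used for the frontal-edge connectivity summary.
FRONTAL_CHANNELS: frozenset[str] = frozenset({"Fp1", "Fp2", "F3", "F4", "F7", "F8"})

#: Rhythm name -> (low, high) corner frequencies in Hz.
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha1": (8.0, 10.0),
    "alpha2": (10.0, 13.0),
    "beta": (13.0, 30.0),
}

BAND_NAMES: tuple[str, ...] = tuple(BANDS)

#: Broadband analysis range in Hz (also the total band of the relative-power
#: normalisation).
BROADBAND: tuple[float, float] = (4.0, 30.0)


def channel_index(name: str) -> int:
    """Return the row index of a channel name, raising ``KeyError`` if unknown."""
    try:
        return CHANNELS.index(name)
    except ValueError:
        raise KeyError(f"unknown channel name: {name!r}") from None
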