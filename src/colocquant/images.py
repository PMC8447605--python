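"""Core in-memory containers: fluorescence channels and ROI masks.

A :class:`ChannelImage` holds one normalized channel of a multi-marker
confocal scene on a fixed pixel grid; a :class:`ROIMask` is the binary
region over which every statistic is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChannelImage", "ROIMask", "as_channel"]

#: marker tags used throughout: red, green, far-red, nuclear stain
CHANNEL_LABELS = ("R", "G", "F", "nuclei", "other")


@dataclass(frozen=True)
class ChannelImage:
    """One fluorescence channel, normalized to [0, 1].

    Parameters
    ----------
    pixels : ndarray of float, shape (H, W)
        Intensities in [0, 1] (raw counts divided by the bit-depth maximum).
    label : str
        Marker tag: ``"R"``, ``"G"``, ``"F"``, ``"nuclei"`` or ``"other"``.
    source_bit_depth : int
        Bit depth of the acquisition (8 or 16); fixes the intensity quantum.
    """

    pixels: np.ndarray
    label: str = "other"
    source_bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"channel must be 2D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("channel contains non-finite pixels")
        if px.size and (px.min() < 0.0 or px.max() > 1.0):
            raise ValueError("channel intensities must lie in [0, 1]")
        if self.label not in CHANNEL_LABELS:
            raise ValueError(f"unknown channel label {self.label!r}")
        if self.source_bit_depth not in (8, 16):
            raise ValueError("source_bit_depth must be 8 or 16")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "ChannelImage":
        """Same label/bit depth, new pixel grid."""
        return ChannelImage(pixels, label=self.label,
                            source_bit_depth=self.source_bit_depth)


@dataclass(frozen=True)
class ROIMask:
    """Binary analysis region; ``n_pixels`` is the N of every fraction."""

    mask: np.ndarray
    _n: int = field(init=False, repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask).astype(bool)
        if m.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {m.shape}")
        n = int(m.sum())
        if n < 1:
            raise ValueError("ROI mask is empty")
        object.__setattr__(self, "mask", m)
        object.__setattr__(self, "_n", n)

    @property
    def n_pixels(self) -> int:
        return self._n

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @classmethod
    def full(cls, shape: tuple[int, int]) -> "ROIMask":
        """Whole-frame ROI."""
        return cls(np.ones(shape, dtype=bool))


def as_channel(image, label: str = "other", bit_depth: int = 8) -> ChannelImage:
    """Coerce an array or ChannelImage to a ChannelImage."""
    if isinstance(image, ChannelImage):
        return image
    return ChannelImage(np.asarray(image, dtype=np.float64), label=label,
                        source_bit_depth=bit_depth)
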