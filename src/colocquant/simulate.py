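"""Synthetic confocal-like scenes with known co-localization ground truth.

Emulates the imaging data the pipeline quantifies: DAPI-style nuclei
(anti-aliased discs), optional plasma-membrane rings, and punctate
endosomal marker channels rendered as isotropic Gaussian spots. A
controllable fraction ``coloc_fraction`` of puncta is shared — placed at
identical centers across the marker channels — while the remaining puncta
keep at least ``min_separation`` pixels from every spot of the other
channels, so the planted fraction is the scene's true co-localization.
Gaussian read noise and single-pixel speckle (the noise class the wavelet
band-pass filter targets) are added before 8-bit quantization, mirroring
8-bit acquisition.

A second generator simulates the receptor recycling assay: fields of cells
whose per-compartment positivity is drawn from a scheduled fraction at each
chase time, rendered as nuclei plus a receptor marker (membrane ring for
surface signal, cytoplasmic puncta for internalized signal), with the true
counts returned alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .images import ChannelImage

__all__ = [
    "SceneParams",
    "SceneGroundTruth",
    "PackingError",
    "generate_scene",
    "generate_cell_field",
    "generate_recycling_series",
    "RecyclingScenePoint",
]


class PackingError(RuntimeError):
    """Could not place the requested objects at the required separation."""


@dataclass
class SceneParams:
    """Generative parameters of a synthetic multi-marker scene."""

    shape: tuple[int, int] = (256, 256)
    channels: tuple[str, ...] = ("R", "G")   # marker channels to render
    n_spots: int = 25                        # puncta per marker channel
    coloc_fraction: float = 0.5              # fraction of shared puncta
    spot_sigma: float = 2.0                  # px
    spot_amplitude: float = 0.9              # peak intensity, [0, 1]
    min_separation: float = 16.0             # px between non-shared spots
    n_nuclei: int = 3
    nucleus_radius: float = 15.0             # px
    nucleus_intensity: float = 0.8
    membrane_channel: Optional[str] = None   # render rings on this channel
    gaussian_sigma: float = 0.0              # read-noise SD
    speckle_density: float = 0.0             # fraction of speckled pixels
    speckle_amplitude: float = 3.0 / 255.0   # a few gray levels (shot noise)
    quantize: bool = True                    # 8-bit quantization
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must be in [0, 1]")
        if self.n_spots < 0 or self.n_nuclei < 0:
            raise ValueError("object counts must be >= 0")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel labels")


@dataclass
class SceneGroundTruth:
    """Realized generative state of one scene."""

    image_shape: tuple[int, int]
    nuclei: list[tuple[float, float, float]]  # (row, col, radius)
    spots_per_channel: dict[str, list[tuple[float, float, float, float]]]
    # per channel: (row, col, amplitude, sigma)
    shared_spots: list[tuple[float, float]]
    coloc_fraction: float
    noise: tuple[float, float, float]  # (gaussian_sigma, density, amplitude)
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "image_shape": list(self.image_shape),
            "nuclei": [list(n) for n in self.nuclei],
            "spots_per_channel": {
                k: [list(s) for s in v]
                for k, v in self.spots_per_channel.items()},
            "shared_spots": [list(s) for s in self.shared_spots],
            "coloc_fraction": self.coloc_fraction,
            "noise": list(self.noise),
            "seed": self.seed,
        }


# ---------------------------------------------------------------- placement

def _place_points(rng: np.random.Generator, n: int, shape, margin: float,
                  min_dist: float, existing: Sequence[tuple[float, float]],
                  max_tries: int = 400) -> list[tuple[float, float]]:
    """Uniform points >= min_dist from ``existing`` and from each other."""
    pts: list[tuple[float, float]] = []
    all_pts = list(existing)
    lo_r, hi_r = margin, shape[0] - margin
    lo_c, hi_c = margin, shape[1] - margin
    if hi_r <= lo_r or hi_c <= lo_c:
        raise PackingError("image too small for the requested margin")
    for _ in range(n):
        for _try in range(max_tries):
            r = rng.uniform(lo_r, hi_r)
            c = rng.uniform(lo_c, hi_c)
            if all((r - pr) ** 2 + (c - pc) ** 2 >= min_dist ** 2
                   for pr, pc in all_pts):
                pts.append((r, c))
                all_pts.append((r, c))
                break
        else:
            raise PackingError(
                f"could not place point {len(pts) + 1} of {n} at "
                f"separation {min_dist}")
    return pts


# ---------------------------------------------------------------- rendering

def _paint_gaussian(img: np.ndarray, row: float, col: float,
                    amplitude: float, sigma: float) -> None:
    rad = int(math.ceil(4.0 * sigma))
    r0 = max(int(row) - rad, 0)
    r1 = min(int(row) + rad + 1, img.shape[0])
    c0 = max(int(col) - rad, 0)
    c1 = min(int(col) + rad + 1, img.shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d2 = (rr - row) ** 2 + (cc - col) ** 2
    img[r0:r1, c0:c1] += amplitude * np.exp(-d2 / (2.0 * sigma ** 2))


def _paint_disc(img: np.ndarray, row: float, col: float, radius: float,
                intensity: float) -> None:
    rad = int(math.ceil(radius)) + 1
    r0 = max(int(row) - rad, 0)
    r1 = min(int(row) + rad + 1, img.shape[0])
    c0 = max(int(col) - rad, 0)
    c1 = min(int(col) + rad + 1, img.shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = np.sqrt((rr - row) ** 2 + (cc - col) ** 2)
    img[r0:r1, c0:c1] += intensity * np.clip(radius + 0.5 - d, 0.0, 1.0)


def _paint_ring(img: np.ndarray, row: float, col: float, radius: float,
                width: float, intensity: float) -> None:
    rad = int(math.ceil(radius + width)) + 1
    r0 = max(int(row) - rad, 0)
    r1 = min(int(row) + rad + 1, img.shape[0])
    c0 = max(int(col) - rad, 0)
    c1 = min(int(col) + rad + 1, img.shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = np.sqrt((rr - row) ** 2 + (cc - col) ** 2)
    img[r0:r1, c0:c1] += intensity * np.clip(
        width / 2.0 + 0.5 - np.abs(d - radius), 0.0, 1.0)


def _finalize(img: np.ndarray, rng: np.random.Generator,
              params: SceneParams) -> np.ndarray:
    if params.gaussian_sigma > 0.0:
        img = img + rng.normal(0.0, params.gaussian_sigma, img.shape)
    if params.speckle_density > 0.0:
        n_speck = int(round(params.speckle_density * img.size))
        idx = rng.choice(img.size, size=n_speck, replace=False)
        flat = img.ravel()
        flat[idx] += params.speckle_amplitude
    img = np.clip(img, 0.0, 1.0)
    if params.quantize:
        img = np.round(img * 255.0) / 255.0
    return img


def generate_scene(params: SceneParams
                   ) -> tuple[list[ChannelImage], SceneGroundTruth]:
    """Render one multi-channel scene; deterministic per seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape = params.shape
    margin = 4.0 * params.spot_sigma + 2.0

    n_shared = int(round(params.coloc_fraction * params.n_spots))
    shared = _place_points(rng, n_shared, shape, margin,
                           params.min_separation, existing=[])
    spots: dict[str, list[tuple[float, float, float, float]]] = {}
    occupied = list(shared)
    for ch in params.channels:
        unique = _place_points(rng, params.n_spots - n_shared, shape, margin,
                               params.min_separation, existing=occupied)
        occupied.extend(unique)
        spots[ch] = [(r, c, params.spot_amplitude, params.spot_sigma)
                     for r, c in shared + unique]

    nuclei_pts = _place_points(
        rng, params.n_nuclei, shape,
        margin=params.nucleus_radius + 2.0,
        min_dist=2.5 * params.nucleus_radius, existing=[]
    ) if params.n_nuclei else []
    nuclei = [(r, c, params.nucleus_radius) for r, c in nuclei_pts]

    channels: list[ChannelImage] = []
    for ch in params.channels:
        img = np.zeros(shape, dtype=np.float64)
        for r, c, amp, sig in spots[ch]:
            _paint_gaussian(img, r, c, amp, sig)
        if params.membrane_channel == ch:
            for r, c, rad in nuclei:
                _paint_ring(img, r, c, rad + 6.0, 3.0, 0.7)
        channels.append(ChannelImage(_finalize(img, rng, params), label=ch))

    if params.n_nuclei:
        img = np.zeros(shape, dtype=np.float64)
        for r, c, rad in nuclei:
            _paint_disc(img, r, c, rad, params.nucleus_intensity)
        channels.append(ChannelImage(_finalize(img, rng, params),
                                     label="nuclei"))

    truth = SceneGroundTruth(
        image_shape=shape, nuclei=nuclei, spots_per_channel=spots,
        shared_spots=shared, coloc_fraction=params.coloc_fraction,
        noise=(params.gaussian_sigma, params.speckle_density,
               params.speckle_amplitude),
        seed=params.seed)
    return channels, truth


# ------------------------------------------------------- recycling assay

@dataclass(frozen=True)
class RecyclingScenePoint:
    """One rendered field of the simulated recycling assay."""

    time_point_min: float
    compartment: str
    nuclei: ChannelImage
    marker: ChannelImage
    n_cells: int
    n_positive: int


def generate_cell_field(n_cells: int, positive: Sequence[bool],
                        rng: np.random.Generator,
                        compartment: str = "cell_surface",
                        cell_spacing: int = 48, nucleus_radius: float = 9.0,
                        marker_intensity: float = 0.6,
                        gaussian_sigma: float = 0.01,
                        ) -> tuple[ChannelImage, ChannelImage]:
    """Render a field of cells on a jittered grid.

    Positive cells carry receptor signal: a membrane ring for the
    ``cell_surface`` compartment, cytoplasmic puncta for ``internalized``,
    and both for ``total``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if len(positive) != n_cells:
        raise ValueError("positive flags must match n_cells")
    n_cols = int(math.ceil(math.sqrt(n_cells)))
    n_rows = int(math.ceil(n_cells / n_cols))
    shape = (n_rows * cell_spacing, n_cols * cell_spacing)
    nuc = np.zeros(shape, dtype=np.float64)
    mk = np.zeros(shape, dtype=np.float64)

    for i in range(n_cells):
        gr, gc = divmod(i, n_cols)
        row = gr * cell_spacing + cell_spacing / 2.0 + rng.uniform(-3, 3)
        col = gc * cell_spacing + cell_spacing / 2.0 + rng.uniform(-3, 3)
        _paint_disc(nuc, row, col, nucleus_radius, 0.8)
        if not positive[i]:
            continue
        if compartment in ("cell_surface", "total"):
            _paint_ring(mk, row, col, nucleus_radius + 6.0, 3.0,
                        marker_intensity)
        if compartment in ("internalized", "total"):
            for _ in range(6):
                ang = rng.uniform(0, 2 * math.pi)
                rad = rng.uniform(nucleus_radius + 1, nucleus_radius + 5)
                _paint_gaussian(mk, row + rad * math.sin(ang),
                                col + rad * math.cos(ang),
                                marker_intensity, 1.5)

    if gaussian_sigma > 0:
        nuc = nuc + rng.normal(0.0, gaussian_sigma, shape)
        mk = mk + rng.normal(0.0, gaussian_sigma, shape)
    nuc = np.round(np.clip(nuc, 0, 1) * 255) / 255
    mk = np.round(np.clip(mk, 0, 1) * 255) / 255
    return (ChannelImage(nuc, label="nuclei"), ChannelImage(mk, label="G"))


def generate_recycling_series(schedule: dict[float, tuple[float, float]],
                              n_cells: int = 100, seed: int = 0,
                              render: bool = True,
                              ) -> list[RecyclingScenePoint]:
    """Simulate a surface/internalized receptor time course.

    ``schedule`` maps chase time (minutes) to ``(surface_fraction,
    internal_fraction)``. At each time point and compartment, each cell's
    positivity is an independent Bernoulli draw from the scheduled fraction
    (the ``total`` compartment uses the receptor-present probability,
    capped at 1). Scenes are rendered unless ``render`` is False (truth
    counts only); the true counts always accompany each point.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    points: list[RecyclingScenePoint] = []
    for t in sorted(schedule):
        surf, internal = schedule[t]
        if not (0.0 <= surf <= 1.0 and 0.0 <= internal <= 1.0):
            raise ValueError(f"fractions at t={t} must be in [0, 1]")
        fractions = {"cell_surface": surf, "internalized": internal,
                     "total": min(surf + internal, 1.0)}
        for comp in ("total", "cell_surface", "internalized"):
            flags = rng.random(n_cells) < fractions[comp]
            if render:
                nuc, mk = generate_cell_field(n_cells, flags.tolist(), rng,
                                              compartment=comp)
            else:
                empty = ChannelImage(np.zeros((1, 1)))
                nuc = mk = empty
            points.append(RecyclingScenePoint(
                time_point_min=float(t), compartment=comp, nuclei=nuc,
                marker=mk, n_cells=n_cells,
                n_positive=int(flags.sum())))
    return points
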