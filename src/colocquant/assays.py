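"""Image-derived assay quantifiers.

Two assays are covered:

* **Recycling assay** — at each chase time point, the percentage of cells
  that are receptor-positive (in a given compartment: total, cell surface
  or internalized) over total cells counted from the nuclear stain, then
  referred to the time-zero value. The original scoring was visual; here
  nuclei are segmented automatically (Otsu threshold, connected components
  with a minimum-area filter and a watershed split of touching nuclei),
  each nucleus is dilated by a fixed radius to approximate its cell, and a
  cell is scored positive when the mean marker intensity over that region
  exceeds a configurable threshold. Manually scored count tables can be fed
  directly to :func:`recycling_timecourse`, bypassing segmentation.

* **Invasion assay** — cells invade a collagen plug imaged in serial
  confocal sections (20 µm spacing); the invading proportion is the total
  fluorescence beyond a depth threshold (default 40 µm, strictly greater)
  over the total across all sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import expand_labels, watershed

from .config import AssayConfig
from .images import ChannelImage, as_channel

__all__ = [
    "AssayCount",
    "RecyclingTimecourse",
    "InvasionProfile",
    "count_positive_cells",
    "recycling_timecourse",
    "invasion_fraction",
    "segment_nuclei",
]

COMPARTMENTS = ("total", "cell_surface", "internalized")


@dataclass(frozen=True)
class AssayCount:
    """Per-scene cell counts for one condition/time point/compartment."""

    scene_id: str
    condition: str
    time_point_min: float
    compartment: str
    n_nuclei: int
    n_positive: int
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.n_nuclei < 0 or not 0 <= self.n_positive <= max(self.n_nuclei, 0):
            raise ValueError(
                f"invalid counts: {self.n_positive}/{self.n_nuclei}")


@dataclass(frozen=True)
class RecyclingTimecourse:
    """Receptor-positive percentages referred to time zero (= 100)."""

    condition: str
    compartment: str
    series: tuple[tuple[float, float], ...]  # (time_point_min, percent_of_t0)

    def percent_at(self, t: float) -> float:
        for tp, pct in self.series:
            if tp == t:
                return pct
        raise KeyError(f"no time point {t}")


@dataclass(frozen=True)
class InvasionProfile:
    """Depth-resolved total fluorescence for one Transwell insert."""

    insert_id: str
    condition: str
    sections: tuple[tuple[float, float], ...]  # (depth_um, total_intensity)
    depth_threshold_um: float = 40.0

    def __post_init__(self) -> None:
        depths = [d for d, _ in self.sections]
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValueError("section depths must be strictly increasing")
        if len(depths) >= 3:
            spacings = np.diff(depths)
            if not np.allclose(spacings, spacings[0]):
                raise ValueError("section spacing must be constant")
        if any(i < 0 for _, i in self.sections):
            raise ValueError("section intensities must be nonnegative")


def segment_nuclei(nuclei, params: Optional[AssayConfig] = None) -> np.ndarray:
    """Label nuclei: Otsu + connected components + watershed split.

    Returns an integer label image (0 = background). An all-background
    channel yields an all-zero label image rather than an error.
    """
    params = params or AssayConfig()
    px = as_channel(nuclei, label="nuclei").pixels
    if px.max() <= 0.0:
        return np.zeros(px.shape, dtype=np.int32)
    try:
        thr = threshold_otsu(px)
    except ValueError:  # constant image
        return np.zeros(px.shape, dtype=np.int32)
    fg = px > thr
    fg = _drop_small(cc_label(fg), params.min_nucleus_area) > 0
    if not fg.any():
        return np.zeros(px.shape, dtype=np.int32)
    # split touching nuclei on the smoothed distance transform
    dist = ndi.distance_transform_edt(fg)
    dist = ndi.gaussian_filter(dist, sigma=2.0)
    peaks = (dist == ndi.maximum_filter(dist, size=9)) & fg & (dist > 1.0)
    markers = cc_label(peaks)
    if markers.max() == 0:
        markers = cc_label(fg)
    labels = watershed(-dist, markers, mask=fg)
    labels = _drop_small(labels, params.min_nucleus_area)
    return labels.astype(np.int32)


def _drop_small(labels: np.ndarray, min_area: int) -> np.ndarray:
    """Zero out labelled components smaller than ``min_area``, then
    relabel consecutively."""
    if labels.max() == 0:
        return labels
    areas = np.bincount(labels.ravel())
    keep = np.flatnonzero(areas >= min_area)
    keep = keep[keep > 0]
    remap = np.zeros(areas.size, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    return remap[labels]


def count_positive_cells(nuclei, marker, params: Optional[AssayConfig] = None,
                         scene_id: str = "", condition: str = "",
                         time_point_min: float = 0.0,
                         compartment: str = "total") -> AssayCount:
    """Count nuclei and marker-positive cells in one field.

    Each segmented nucleus is dilated by ``params.dilation_radius`` to
    approximate the cell region; a cell is positive when the mean marker
    intensity inside its region exceeds ``params.positivity_threshold``.
    A field with no detectable nuclei returns counts (0, 0) with a
    ``no_nuclei`` flag rather than raising.
    """
    params = params or AssayConfig()
    nuc = as_channel(nuclei, label="nuclei")
    mk = as_channel(marker)
    if nuc.shape != mk.shape:
        raise ValueError(
            f"nuclei shape {nuc.shape} != marker shape {mk.shape}")

    labels = segment_nuclei(nuc, params)
    n_nuclei = int(labels.max())
    if n_nuclei == 0:
        return AssayCount(scene_id=scene_id, condition=condition,
                          time_point_min=time_point_min,
                          compartment=compartment, n_nuclei=0, n_positive=0,
                          flags=("no_nuclei",))
    cells = expand_labels(labels, distance=params.dilation_radius)
    means = ndi.mean(mk.pixels, labels=cells,
                     index=np.arange(1, n_nuclei + 1))
    n_positive = int(np.count_nonzero(means > params.positivity_threshold))
    return AssayCount(scene_id=scene_id, condition=condition,
                      time_point_min=time_point_min, compartment=compartment,
                      n_nuclei=n_nuclei, n_positive=n_positive)


def recycling_timecourse(counts: Sequence[AssayCount]
                         ) -> list[RecyclingTimecourse]:
    """Per condition x compartment, percent of time-zero positivity.

    Counts at the same (condition, compartment, time) are pooled before the
    percentage ``100 * n_positive / n_nuclei`` is formed; every series is
    then referred to its time-zero value (so t0 maps to 100).
    """
    groups: dict[tuple[str, str], dict[float, list[AssayCount]]] = {}
    for c in counts:
        groups.setdefault((c.condition, c.compartment), {}) \
              .setdefault(float(c.time_point_min), []).append(c)

    out: list[RecyclingTimecourse] = []
    for (condition, compartment), by_time in sorted(groups.items()):
        if 0.0 not in by_time:
            raise ValueError(
                f"no time-zero counts for {condition!r}/{compartment!r}")
        pct: dict[float, float] = {}
        for t, items in by_time.items():
            nn = sum(c.n_nuclei for c in items)
            npos = sum(c.n_positive for c in items)
            if nn == 0:
                raise ValueError(
                    f"zero total nuclei at t={t} for {condition!r}")
            pct[t] = 100.0 * npos / nn
        if pct[0.0] == 0.0:
            raise ValueError(
                f"time-zero positivity is zero for {condition!r}/"
                f"{compartment!r}; percent-of-t0 undefined")
        series = tuple((t, 100.0 * pct[t] / pct[0.0])
                       for t in sorted(pct))
        out.append(RecyclingTimecourse(condition=condition,
                                       compartment=compartment,
                                       series=series))
    return out


def invasion_fraction(profile: InvasionProfile) -> float:
    """Fraction of total fluorescence strictly beyond the depth threshold."""
    if len(profile.sections) < 2:
        raise ValueError("need at least 2 sections")
    total = sum(i for _, i in profile.sections)
    if total <= 0.0:
        raise ValueError("total intensity is zero; ratio undefined")
    beyond = sum(i for d, i in profile.sections
                 if d > profile.depth_threshold_um)
    return beyond / total
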