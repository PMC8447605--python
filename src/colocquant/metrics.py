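"""Pixel co-localization statistics for multi-marker fluorescence scenes.

Implements the full metric set used to quantify receptor/endosome marker
co-incidence on a region of interest (ROI) of N pixels:

* **Expression fractions** ``F_R = N_R / N`` — fraction of ROI pixels where
  a channel is strictly positive.
* **Overlap images** ``I_RG = I_R * I_G`` (and ``I_RFG = I_R * I_F * I_G``)
  — elementwise products of normalized channels; intensity approaches 1
  where markers strongly overlap.
* **Overlap fractions** ``OF_RG = N_RG / N`` — strictly-positive fraction
  of the overlap image.
* **Manders coefficients** M1/M2 with lower-bound thresholds chosen by the
  Costes procedure (orthogonal regression between the two channels, then
  descent along the regression line until sub-threshold pixels are
  uncorrelated).
* **Triple-marker MCC**: the overlap image ``I_FR = I_F * I_R`` is scored
  against the third channel G with Costes thresholds ``T_FR`` and ``T_G``.

All statistics are restricted to the ROI, including the Costes regression
and threshold scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .images import ChannelImage, ROIMask, as_channel
from .wavelet import bandpass_filter

__all__ = [
    "POSITIVITY_EPS",
    "CostesResult",
    "MandersResult",
    "ColocMetrics",
    "DegenerateChannelError",
    "expression_fraction",
    "overlap_image",
    "overlap_fraction",
    "costes_thresholds",
    "manders_coefficients",
    "triple_manders",
    "compute_all_metrics",
    "METRIC_COLUMNS",
]

#: guard against float dust when counting "strictly positive" pixels
POSITIVITY_EPS = 1e-12

#: default Costes threshold quantum: one 8-bit gray level on the [0,1] scale
DEFAULT_COSTES_STEP = 1.0 / 255.0


class DegenerateChannelError(ValueError):
    """Channel is constant within the ROI; regression is undefined."""


@dataclass(frozen=True)
class CostesResult:
    """Automatic Manders thresholds for a channel pair.

    ``t_a``/``t_b`` are the lower-bound thresholds for the first and second
    channel. ``r_below`` is the Pearson correlation of the sub-threshold
    pixels at termination (<= 0 unless the scan hit the grid floor).
    ``anti_correlated`` flags a negative orthogonal-regression slope, in
    which case the thresholds sit at the search ceiling.
    """

    t_a: float
    t_b: float
    slope: float
    intercept: float
    r_below: float
    anti_correlated: bool = False
    at_floor: bool = False


class MandersResult(NamedTuple):
    m1: float
    m2: float
    zero_denom_a: bool = False
    zero_denom_b: bool = False


def _roi_values(channel: ChannelImage, roi: ROIMask) -> np.ndarray:
    if channel.shape != roi.shape:
        raise ValueError(
            f"channel shape {channel.shape} != ROI shape {roi.shape}")
    return channel.pixels[roi.mask]


def expression_fraction(channel, roi: ROIMask,
                        eps: float = POSITIVITY_EPS) -> float:
    """Fraction of ROI pixels with strictly positive intensity (N_x / N)."""
    vals = _roi_values(as_channel(channel), roi)
    return float(np.count_nonzero(vals > eps)) / roi.n_pixels


def overlap_image(channels: Sequence) -> ChannelImage:
    """Elementwise product of two or more normalized channels.

    The product image lives in [0, 1]: it tends to 1 where every marker is
    bright and vanishes wherever any marker is absent.
    """
    chans = [as_channel(c) for c in channels]
    if len(chans) < 2:
        raise ValueError("overlap_image needs at least 2 channels")
    shape = chans[0].shape
    for c in chans[1:]:
        if c.shape != shape:
            raise ValueError(
                f"channel shapes differ: {c.shape} vs {shape}")
    prod = chans[0].pixels.copy()
    for c in chans[1:]:
        prod *= c.pixels
    return ChannelImage(prod, label="other",
                        source_bit_depth=chans[0].source_bit_depth)


def overlap_fraction(channels: Sequence, roi: ROIMask,
                     eps: float = POSITIVITY_EPS) -> float:
    """Strictly-positive fraction of the overlap image over the ROI
    (OF_RG = N_RG / N, OF_RFG = N_RFG / N)."""
    return expression_fraction(overlap_image(channels), roi, eps=eps)


def _tls_fit(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Orthogonal (total-least-squares) regression b ~ slope*a + intercept.

    Slope is the major axis of the centered scatter; its sign follows the
    covariance of the two channels.
    """
    am, bm = a.mean(), b.mean()
    s_aa = float(np.mean((a - am) ** 2))
    s_bb = float(np.mean((b - bm) ** 2))
    s_ab = float(np.mean((a - am) * (b - bm)))
    if s_aa <= 0.0:
        raise DegenerateChannelError("first channel constant within ROI")
    if s_bb <= 0.0:
        raise DegenerateChannelError("second channel constant within ROI")
    if s_ab == 0.0:
        # uncorrelated: major axis aligns with the higher-variance channel
        slope = 0.0 if s_aa >= s_bb else np.inf
    else:
        d = s_bb - s_aa
        slope = (d + np.hypot(d, 2.0 * s_ab)) / (2.0 * s_ab)
    intercept = bm - slope * am
    return float(slope), float(intercept)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r, or nan when undefined (n < 2 or zero variance)."""
    if x.size < 2:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if den == 0.0:
        return float("nan")
    return float((xc * yc).sum() / den)


def costes_thresholds(chan_a, chan_b, roi: ROIMask,
                      step: float = DEFAULT_COSTES_STEP) -> CostesResult:
    """Automatic lower-bound thresholds by the Costes descent.

    Fits an orthogonal regression ``I_b = slope * I_a + intercept`` over the
    ROI pixels, then scans the candidate threshold ``t_a`` downward from
    ``max(I_a)`` in decrements of ``step`` with the paired
    ``t_b = slope * t_a + intercept``. The scan stops at the first candidate
    for which the Pearson correlation of the pixels below both thresholds is
    <= 0; if no candidate achieves that, the thresholds stop at the grid
    floor (one ``step``) with ``at_floor`` set.

    An anti-correlated pair (negative slope) cannot be thresholded along the
    regression line; the search ceiling is returned with ``anti_correlated``
    set.
    """
    if step <= 0.0:
        raise ValueError("step must be positive")
    ca, cb = as_channel(chan_a), as_channel(chan_b)
    a = _roi_values(ca, roi)
    b = _roi_values(cb, roi)
    slope, intercept = _tls_fit(a, b)

    a_max = float(a.max())
    if slope < 0.0:
        t_a = min(max(a_max, 0.0), 1.0)
        t_b = min(max(slope * t_a + intercept, 0.0), 1.0)
        return CostesResult(t_a=t_a, t_b=t_b, slope=slope,
                            intercept=intercept, r_below=float("nan"),
                            anti_correlated=True)

    # descending grid from max(I_a); floor at one step above zero
    n_steps = int(np.floor(a_max / step))
    candidates = a_max - step * np.arange(0, max(n_steps, 0) + 1)
    candidates = candidates[candidates > 0.0]
    if candidates.size == 0:
        candidates = np.array([step])

    r = float("nan")
    t_a = float(candidates[-1])
    at_floor = True
    for cand in candidates:
        t_b_cand = slope * cand + intercept
        below = (a < cand) & (b < t_b_cand)
        r_cand = _pearson(a[below], b[below])
        if not np.isnan(r_cand):
            r = r_cand
        if not np.isnan(r_cand) and r_cand <= 0.0:
            t_a = float(cand)
            at_floor = False
            break
    t_b = slope * t_a + intercept
    return CostesResult(
        t_a=float(min(max(t_a, 0.0), 1.0)),
        t_b=float(min(max(t_b, 0.0), 1.0)),
        slope=slope, intercept=intercept, r_below=r, at_floor=at_floor)


def manders_coefficients(chan_a, chan_b, roi: ROIMask,
                         thresholds) -> MandersResult:
    """Manders co-localization coefficients with lower-bound thresholds.

    ``m1`` is the fraction of the first channel's intensity found where the
    second channel exceeds its threshold; ``m2`` the converse::

        m1 = sum(I_a where I_b > t_b) / sum(I_a over ROI)
        m2 = sum(I_b where I_a > t_a) / sum(I_b over ROI)

    A channel summing to zero yields coefficient 0 with its zero-denominator
    flag set.

    ``thresholds`` may be a :class:`CostesResult` or a ``(t_a, t_b)`` pair.
    """
    if isinstance(thresholds, CostesResult):
        t_a, t_b = thresholds.t_a, thresholds.t_b
    else:
        t_a, t_b = thresholds
    if not (0.0 <= t_a <= 1.0 and 0.0 <= t_b <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    a = _roi_values(as_channel(chan_a), roi)
    b = _roi_values(as_channel(chan_b), roi)

    sum_a = float(a.sum())
    sum_b = float(b.sum())
    zero_a = sum_a == 0.0
    zero_b = sum_b == 0.0
    m1 = 0.0 if zero_a else float(a[b > t_b].sum()) / sum_a
    m2 = 0.0 if zero_b else float(b[a > t_a].sum()) / sum_b
    return MandersResult(m1=m1, m2=m2, zero_denom_a=zero_a,
                         zero_denom_b=zero_b)


def triple_manders(chan_r, chan_f, chan_g, roi: ROIMask,
                   step: float = DEFAULT_COSTES_STEP,
                   ) -> tuple[float, float, CostesResult]:
    """Three-marker MCC: the F x R overlap image scored against G.

    Builds ``I_FR = I_F * I_R``, determines Costes thresholds ``T_FR`` and
    ``T_G`` for the (I_FR, G) pair, and returns their Manders coefficients
    together with the thresholds. If either side is constant within the ROI
    (e.g. fully saturated markers), the regression is undefined and zero
    thresholds are forced instead.
    """
    i_fr = overlap_image([as_channel(chan_f), as_channel(chan_r)])
    g = as_channel(chan_g)
    try:
        costes = costes_thresholds(i_fr, g, roi, step=step)
    except DegenerateChannelError:
        costes = CostesResult(t_a=0.0, t_b=0.0, slope=float("nan"),
                              intercept=float("nan"), r_below=float("nan"))
    m1, m2, _, _ = manders_coefficients(i_fr, g, roi, costes)
    return m1, m2, costes


# CSV column order for per-scene metric rows (deterministic)
METRIC_COLUMNS = [
    "scene_id", "roi_id", "condition", "time_point_min",
    "f_r", "f_g", "f_f",
    "of_rg", "of_rf", "of_rfg",
    "m1", "m2", "t_a", "t_b",
    "of_fg", "triple_m1", "triple_m2", "t_fr", "t_g3",
    "flags",
]


@dataclass
class ColocMetrics:
    """Full metric vector for one scene/ROI, plus metadata and flags.

    Metrics that do not apply (e.g. triple statistics of a two-channel
    scene) are ``None`` and serialize to empty CSV fields.
    """

    scene_id: str = ""
    roi_id: str = ""
    condition: str = ""
    time_point_min: Optional[float] = None
    f_r: Optional[float] = None
    f_g: Optional[float] = None
    f_f: Optional[float] = None
    of_rg: Optional[float] = None
    of_rf: Optional[float] = None
    of_fg: Optional[float] = None
    of_rfg: Optional[float] = None
    m1: Optional[float] = None
    m2: Optional[float] = None
    costes: Optional[CostesResult] = None
    triple_m1: Optional[float] = None
    triple_m2: Optional[float] = None
    triple_costes: Optional[CostesResult] = None
    flags: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        """Flat dict in :data:`METRIC_COLUMNS` order (empty for absent)."""
        row = {
            "scene_id": self.scene_id,
            "roi_id": self.roi_id,
            "condition": self.condition,
            "time_point_min": self.time_point_min,
            "f_r": self.f_r, "f_g": self.f_g, "f_f": self.f_f,
            "of_rg": self.of_rg, "of_rf": self.of_rf, "of_rfg": self.of_rfg,
            "m1": self.m1, "m2": self.m2,
            "t_a": self.costes.t_a if self.costes else None,
            "t_b": self.costes.t_b if self.costes else None,
            "of_fg": self.of_fg,
            "triple_m1": self.triple_m1, "triple_m2": self.triple_m2,
            "t_fr": self.triple_costes.t_a if self.triple_costes else None,
            "t_g3": self.triple_costes.t_b if self.triple_costes else None,
            "flags": ";".join(self.flags),
        }
        return {k: row[k] for k in METRIC_COLUMNS}


def _pair_costes_or_flag(a, b, roi, step, flags, tag) -> CostesResult:
    try:
        return costes_thresholds(a, b, roi, step=step)
    except DegenerateChannelError:
        flags.append(f"degenerate_costes_{tag}")
        return CostesResult(t_a=0.0, t_b=0.0, slope=float("nan"),
                            intercept=float("nan"), r_below=float("nan"))


def compute_all_metrics(scene: Sequence[ChannelImage], roi: ROIMask,
                        config=None, **meta) -> ColocMetrics:
    """Run the complete metric set on one scene.

    Channels are matched by label (R, G required; F optional; a nuclei
    channel is ignored here). Each marker channel is band-pass filtered
    first unless the configuration disables it. Metrics whose channels are
    missing stay absent — never fabricated.

    Parameters
    ----------
    scene : sequence of ChannelImage
        2 or 3 marker channels, optionally plus a nuclei channel.
    roi : ROIMask
    config : PipelineConfig, optional
        Wavelet and Costes settings; defaults used when omitted.
    meta : scene_id, roi_id, condition, time_point_min
    """
    from .config import PipelineConfig
    cfg = config if config is not None else PipelineConfig()

    by_label: dict[str, ChannelImage] = {}
    for ch in scene:
        ch = as_channel(ch)
        if ch.label in ("R", "G", "F"):
            if ch.label in by_label:
                raise ValueError(f"duplicate channel label {ch.label!r}")
            by_label[ch.label] = ch
    if len(by_label) < 2:
        raise ValueError("need at least 2 marker channels (R/G/F labels)")

    if cfg.wavelet.enabled:
        by_label = {
            lab: bandpass_filter(ch, n_scales=cfg.wavelet.n_scales,
                                 drop_finest=cfg.wavelet.drop_finest,
                                 drop_residual=cfg.wavelet.drop_residual)
            for lab, ch in by_label.items()
        }

    r = by_label.get("R")
    g = by_label.get("G")
    f = by_label.get("F")
    eps = cfg.positivity_epsilon
    step = cfg.costes.step
    out = ColocMetrics(**meta)

    if r is not None:
        out.f_r = expression_fraction(r, roi, eps=eps)
    if g is not None:
        out.f_g = expression_fraction(g, roi, eps=eps)
    if f is not None:
        out.f_f = expression_fraction(f, roi, eps=eps)

    if r is not None and g is not None:
        out.of_rg = overlap_fraction([r, g], roi, eps=eps)
        out.costes = _pair_costes_or_flag(r, g, roi, step, out.flags, "rg")
        m = manders_coefficients(r, g, roi, out.costes)
        out.m1, out.m2 = m.m1, m.m2
        if m.zero_denom_a or m.zero_denom_b:
            out.flags.append("zero_denominator_manders")
    if r is not None and f is not None:
        out.of_rf = overlap_fraction([r, f], roi, eps=eps)
    if f is not None and g is not None:
        out.of_fg = overlap_fraction([f, g], roi, eps=eps)
    if r is not None and f is not None and g is not None:
        out.of_rfg = overlap_fraction([r, f, g], roi, eps=eps)
        out.triple_m1, out.triple_m2, out.triple_costes = triple_manders(
            r, f, g, roi, step=step)
    return out
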