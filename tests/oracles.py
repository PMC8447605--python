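"""Independent brute-force oracles used by the test suite.

Everything here is written naively (explicit loops, eigendecomposition,
direct convolution) and never calls the package's own vectorized paths.
"""

from __future__ import annotations

import numpy as np

B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def mirror_index(i: int, n: int) -> int:
    """scipy 'mirror' boundary: reflect about edge samples (period 2n-2)."""
    if n == 1:
        return 0
    period = 2 * n - 2
    i = i % period
    if i < 0:
        i += period
    return i if i < n else period - i


def atrous_smooth_naive(img: np.ndarray, scale: int) -> np.ndarray:
    """Direct separable convolution with the dilated B3 kernel."""
    holes = 2 ** (scale - 1) - 1
    taps = np.zeros(4 * (holes + 1) + 1)
    taps[:: holes + 1] = B3
    half = len(taps) // 2
    h, w = img.shape
    tmp = np.zeros_like(img)
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for j, t in enumerate(taps):
                if t:
                    acc += t * img[mirror_index(r + j - half, h), c]
            tmp[r, c] = acc
    out = np.zeros_like(img)
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for j, t in enumerate(taps):
                if t:
                    acc += t * tmp[r, mirror_index(c + j - half, w)]
            out[r, c] = acc
    return out


def atrous_planes_naive(img: np.ndarray, n_scales: int):
    planes = []
    c_prev = img.astype(float).copy()
    for k in range(1, n_scales + 1):
        c_k = atrous_smooth_naive(c_prev, k)
        planes.append(c_prev - c_k)
        c_prev = c_k
    return planes, c_prev


def positive_count_naive(pixels: np.ndarray, mask: np.ndarray,
                         eps: float = 1e-12) -> int:
    n = 0
    h, w = pixels.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and pixels[r, c] > eps:
                n += 1
    return n


def product_naive(channels) -> np.ndarray:
    h, w = channels[0].shape
    out = np.ones((h, w))
    for r in range(h):
        for c in range(w):
            v = 1.0
            for ch in channels:
                v *= ch[r, c]
            out[r, c] = v
    return out


def manders_naive(a: np.ndarray, b: np.ndarray, mask: np.ndarray,
                  t_a: float, t_b: float) -> tuple[float, float]:
    num1 = den1 = num2 = den2 = 0.0
    h, w = a.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            den1 += a[r, c]
            den2 += b[r, c]
            if b[r, c] > t_b:
                num1 += a[r, c]
            if a[r, c] > t_a:
                num2 += b[r, c]
    m1 = num1 / den1 if den1 > 0 else 0.0
    m2 = num2 / den2 if den2 > 0 else 0.0
    return m1, m2


def tls_naive(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Orthogonal regression via eigendecomposition of the covariance."""
    x = np.stack([a, b])
    cov = np.cov(x, ddof=0)
    vals, vecs = np.linalg.eigh(cov)
    major = vecs[:, int(np.argmax(vals))]
    if major[0] == 0.0:
        slope = np.inf
    else:
        slope = major[1] / major[0]
    # orient along the covariance sign (eigenvector sign is arbitrary)
    if cov[0, 1] != 0 and np.sign(slope) != np.sign(cov[0, 1]):
        slope = -slope  # pragma: no cover - defensive
    return float(slope), float(b.mean() - slope * a.mean())


def pearson_naive(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2:
        return float("nan")
    xm, ym = x.mean(), y.mean()
    sxy = float(((x - xm) * (y - ym)).sum())
    sxx = float(((x - xm) ** 2).sum())
    syy = float(((y - ym) ** 2).sum())
    if sxx == 0 or syy == 0:
        return float("nan")
    return sxy / np.sqrt(sxx * syy)


def costes_scan_naive(a: np.ndarray, b: np.ndarray, mask: np.ndarray,
                      step: float) -> tuple[float, float]:
    """Exhaustive descent over the same threshold grid."""
    av = a[mask]
    bv = b[mask]
    slope, intercept = tls_naive(av, bv)
    if slope < 0:
        # anti-correlated pair: no descent possible, search ceiling returned
        t_a = float(av.max())
        return t_a, slope * t_a + intercept
    cand = float(av.max())
    last = None
    while cand > 0.0:
        t_b = slope * cand + intercept
        sel = (av < cand) & (bv < t_b)
        r = pearson_naive(av[sel], bv[sel])
        last = cand
        if not np.isnan(r) and r <= 0.0:
            return cand, t_b
        cand -= step
    if last is None:
        last = step
    return last, slope * last + intercept


def pooled_t_naive(a, b) -> tuple[float, float]:
    """Textbook pooled two-sample t and two-tailed p."""
    from scipy.stats import t as tdist
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) \
        / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return float(t), float(p)
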