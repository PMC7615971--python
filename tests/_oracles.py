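"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive and slow: profiled 1-D search for the
decay lifetime, O(N*M) exact Euclidean distances for ring banding, and
sliding-window min/max morphology for the top-hat.  None of it shares code
with the package's implementation paths.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar


def grid_search_tau(hist, tau_lo: float = 0.2, tau_hi: float = 10.0, n_grid: int = 197) -> float:
    """Profiled 1-D grid search for the decay lifetime.

    For each candidate tau the baseline and amplitude enter linearly, so
    they are profiled out by linear least squares; the residual sum of
    squares is minimised over a coarse tau grid and then refined by bounded
    scalar minimisation.
    """
    t = hist.bin_centers
    y = np.asarray(hist.counts, dtype=float)
    start = int(np.argmax(y))
    t, y = t[start:], y[start:]

    def rss(tau: float) -> float:
        design = np.column_stack([np.ones_like(t), np.exp(-t / tau)])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        return float(resid @ resid)

    taus = np.linspace(tau_lo, tau_hi, n_grid)
    values = [rss(x) for x in taus]
    i = int(np.argmin(values))
    lo = taus[max(i - 1, 0)]
    hi = taus[min(i + 1, n_grid - 1)]
    res = minimize_scalar(rss, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10})
    return float(res.x)


def exact_ring_bands(mask: np.ndarray, n_contours: int) -> np.ndarray:
    """Exact Euclidean distance banding by brute force.

    For every outside pixel, the distance to the mask is the minimum over
    all mask pixels of the Euclidean pixel-center distance; band k collects
    distances in (k-1, k].  Returns the same labelling convention as the
    implementation: 0 inside the mask, -1 beyond the last band.
    """
    mask = np.asarray(mask, dtype=bool)
    fg = np.argwhere(mask).astype(float)
    labels = np.full(mask.shape, -1, dtype=np.int32)
    labels[mask] = 0
    outside = np.argwhere(~mask).astype(float)
    if fg.size == 0:
        raise ValueError("empty mask")
    # chunk to keep the (outside x mask) distance matrix small
    for block in np.array_split(outside, max(1, len(outside) // 2048)):
        d2 = ((block[:, None, :] - fg[None, :, :]) ** 2).sum(axis=2)
        dist = np.sqrt(d2.min(axis=1))
        band = np.ceil(dist).astype(np.int32)
        band[band > n_contours] = -1
        labels[block[:, 0].astype(int), block[:, 1].astype(int)] = band
    return labels


def _sliding_window(img: np.ndarray, footprint: np.ndarray, reducer) -> np.ndarray:
    """Apply min/max over a boolean footprint at every pixel (edge-padded)."""
    r = footprint.shape[0] // 2
    pad_min = reducer is np.min
    padded = np.pad(img, r, mode="constant", constant_values=np.inf if pad_min else -np.inf)
    out = np.empty_like(img, dtype=float)
    offs = np.argwhere(footprint) - r
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            vals = [padded[i + r + di, j + r + dj] for di, dj in offs]
            out[i, j] = reducer(vals)
    return out


def brute_force_white_tophat(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """White top-hat as input minus (min-then-max) sliding-window opening.

    Uses edge padding conventions matching grey-scale morphology on a
    bounded domain (erosion pads +inf, dilation -inf).
    """
    img = np.asarray(img, dtype=float)
    eroded = _sliding_window(img, footprint, np.min)
    opened = _sliding_window(eroded, footprint, np.max)
    return img - opened


def pooled_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Closed-form Student pooled t statistic and degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return float(t), float(na + nb - 2)
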