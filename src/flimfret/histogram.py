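"""Photon arrival-time histograms and TCSPC images.

Time-correlated single photon counting (TCSPC) records, for every detected
photon, its arrival time relative to the preceding excitation pulse.  The raw
object of lifetime analysis is therefore a histogram of photon counts over
uniform time bins spanning one laser repetition period (12.5 ns at 80 MHz),
either for a single spatial bin (:class:`PhotonHistogram`) or per pixel of an
image (:class:`TCSPCImage`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["PhotonHistogram", "TCSPCImage"]


@dataclass(frozen=True)
class PhotonHistogram:
    """Photon counts over uniform arrival-time bins.

    Parameters
    ----------
    bin_edges : ndarray, shape (n_bins + 1,)
        Strictly increasing, uniformly spaced bin edges in nanoseconds.
    counts : ndarray, shape (n_bins,)
        Non-negative integer photon counts per bin.
    """

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("bin_edges must be 1-D with at least 2 entries")
        widths = np.diff(edges)
        if np.any(widths <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if not np.allclose(widths, widths[0], rtol=1e-9, atol=0.0):
            raise ValueError("bin_edges must be uniformly spaced")
        if counts.ndim != 1 or counts.size != edges.size - 1:
            raise ValueError("counts must be 1-D with length n_bins")
        if not np.all(np.isfinite(counts)) or np.any(counts < 0):
            raise ValueError("counts must be non-negative and finite")
        object.__setattr__(self, "bin_edges", edges)
        # measured histograms are integer counts; exact model evaluations
        # (noiseless fixtures) may carry float values
        if np.issubdtype(counts.dtype, np.integer):
            counts = counts.astype(np.int64)
        object.__setattr__(self, "counts", counts)

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def window(self) -> float:
        """Total span of the histogram in ns (the repetition period)."""
        return float(self.bin_edges[-1] - self.bin_edges[0])

    @property
    def total_counts(self) -> int:
        return int(round(float(self.counts.sum())))

    def __add__(self, other: "PhotonHistogram") -> "PhotonHistogram":
        if not np.array_equal(self.bin_edges, other.bin_edges):
            raise ValueError("cannot pool histograms with different bin edges")
        return PhotonHistogram(self.bin_edges, self.counts + other.counts)


@dataclass
class TCSPCImage:
    """Per-pixel photon arrival-time histograms sharing one time axis.

    Attributes
    ----------
    counts : ndarray, shape (height, width, n_bins)
        Photon counts per pixel and time bin.
    bin_edges : ndarray, shape (n_bins + 1,)
        Shared time-bin edges (ns).
    metadata : dict
        Free-form acquisition metadata (e.g. acquisition seconds, excitation
        wavelength in nm, emission filter).
    """

    counts: np.ndarray
    bin_edges: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        edges = np.asarray(self.bin_edges, dtype=float)
        if counts.ndim != 3:
            raise ValueError("counts must have shape (height, width, n_bins)")
        if counts.shape[0] < 1 or counts.shape[1] < 1:
            raise ValueError("image dimensions must be >= 1")
        if edges.ndim != 1 or edges.size != counts.shape[2] + 1:
            raise ValueError("bin_edges length must equal n_bins + 1")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64, copy=False)
        self.bin_edges = edges

    @property
    def height(self) -> int:
        return self.counts.shape[0]

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    def intensity(self) -> np.ndarray:
        """Total photons per pixel (sum over time bins)."""
        return self.counts.sum(axis=2)

    def pixel_histogram(self, row: int, col: int) -> PhotonHistogram:
        return PhotonHistogram(self.bin_edges, self.counts[row, col])

    def pooled_histogram(self, mask: np.ndarray | None = None) -> PhotonHistogram:
        """Pool histograms over ``mask`` (all pixels when mask is None)."""
        if mask is None:
            pooled = self.counts.sum(axis=(0, 1))
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.counts.shape[:2]:
                raise ValueError("mask shape must match image dimensions")
            pooled = self.counts[mask].sum(axis=0)
        return PhotonHistogram(self.bin_edges, pooled)
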