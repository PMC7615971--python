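"""Spatial binning, photon gating and lifetime maps.

The pixel-fitting workflow pools an image into square spatial bins (35x35
pixels by default), requires a minimum pooled photon count per bin (10,000
by default) for a reliable fit, fits each valid bin's pooled decay, and
renders the per-bin lifetimes as a heatmap.  Incomplete edge bins are
discarded rather than padded; invalid bins carry NaN, never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .decay import fit_monoexponential
from .histogram import PhotonHistogram, TCSPCImage

__all__ = [
    "SpatialBin",
    "LifetimeMap",
    "spatial_bin",
    "photon_gate",
    "lifetime_map",
    "mean_lifetime",
]

DEFAULT_BIN_SIZE = 35
DEFAULT_PHOTON_THRESHOLD = 10_000


@dataclass(frozen=True)
class SpatialBin:
    """One pooled spatial bin: grid location and pooled histogram."""

    row: int
    col: int
    histogram: PhotonHistogram


def spatial_bin(image: TCSPCImage, bin_size: int = DEFAULT_BIN_SIZE) -> list[SpatialBin]:
    """Pool an image into complete ``bin_size`` x ``bin_size`` spatial bins.

    Each bin's histogram is the elementwise sum of its pixels' histograms.
    Edge remainders that do not fill a complete bin are discarded.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    n_rows = image.height // bin_size
    n_cols = image.width // bin_size
    if n_rows == 0 or n_cols == 0:
        warnings.warn("bin_size exceeds image dimensions; no complete bins", stacklevel=2)
        return []
    cropped = image.counts[: n_rows * bin_size, : n_cols * bin_size]
    pooled = cropped.reshape(n_rows, bin_size, n_cols, bin_size, image.n_bins).sum(axis=(1, 3))
    return [
        SpatialBin(r, c, PhotonHistogram(image.bin_edges, pooled[r, c]))
        for r in range(n_rows)
        for c in range(n_cols)
    ]


def photon_gate(bins: list[SpatialBin], threshold: int = DEFAULT_PHOTON_THRESHOLD) -> list[bool]:
    """Validity flags per bin: valid iff total counts >= threshold (inclusive)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return [b.histogram.total_counts >= threshold for b in bins]


@dataclass
class LifetimeMap:
    """Grid of per-spatial-bin lifetimes.

    ``tau`` holds the fitted lifetime (ns) per bin, NaN where the bin is
    invalid (photon gate failed or fit did not converge); ``n_photons`` the
    pooled counts per bin; ``valid`` the boolean validity grid.
    """

    tau: np.ndarray
    n_photons: np.ndarray
    valid: np.ndarray
    bin_size: int
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.tau.shape

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.indices(self.shape)
        return pd.DataFrame(
            {
                "bin_row": rows.ravel(),
                "bin_col": cols.ravel(),
                "tau_ns": self.tau.ravel(),
                "n_photons": self.n_photons.ravel(),
                "valid": self.valid.ravel(),
            }
        )


def lifetime_map(
    image: TCSPCImage,
    bin_size: int = DEFAULT_BIN_SIZE,
    threshold: int = DEFAULT_PHOTON_THRESHOLD,
    weights: str = "poisson",
) -> LifetimeMap:
    """Fit the mono-exponential lifetime in every valid spatial bin.

    Bins below the photon gate, or whose fit fails to converge, are marked
    invalid (NaN lifetime).
    """
    bins = spatial_bin(image, bin_size)
    n_rows = image.height // bin_size
    n_cols = image.width // bin_size
    tau = np.full((n_rows, n_cols), np.nan)
    photons = np.zeros((n_rows, n_cols), dtype=np.int64)
    valid = np.zeros((n_rows, n_cols), dtype=bool)
    gate = photon_gate(bins, threshold)
    for b, ok in zip(bins, gate):
        photons[b.row, b.col] = b.histogram.total_counts
        if not ok:
            continue
        try:
            res = fit_monoexponential(b.histogram, weights=weights)
        except ValueError:
            continue
        if res.converged:
            tau[b.row, b.col] = res.tau
            valid[b.row, b.col] = True
    if bins and not valid.any():
        warnings.warn("no valid bins above the photon gate", stacklevel=2)
    return LifetimeMap(
        tau=tau,
        n_photons=photons,
        valid=valid,
        bin_size=bin_size,
        metadata={"threshold": threshold, **image.metadata},
    )


def mean_lifetime(lifetimes: LifetimeMap) -> float:
    """Unweighted arithmetic mean of the valid bin lifetimes (ns)."""
    if lifetimes.n_valid == 0:
        raise ValueError("no valid bins to average")
    return float(np.nanmean(lifetimes.tau[lifetimes.valid]))
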