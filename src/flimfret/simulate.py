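"""Synthetic TCSPC data with known ground truth.

Emulates the acquisition conditions of the FLIM experiments: 80 MHz pulsed
excitation (12.5 ns repetition window), mono-exponential decays with a
constant background, Poisson photon statistics, dark-cell-in-bright-hydrogel
scenes, and cleaved/uncleaved two-lifetime mixtures parameterised by the
cleaved fraction of the FRET sensor.

Photon-level sampling (single decays and mixtures): the total count is
Poisson, each photon is uniform background with probability
``background_fraction`` and otherwise an exponential arrival time truncated
to ``[0, window)``.  No instrument response function is convolved — decays
are delta-excitation, matching the pure ``Z + A exp(-t/tau)`` analysis
model.

Scene sampling: per-pixel, per-time-bin counts are independent Poisson
variates whose means follow the local true lifetime and photon rate (the
exact thinning of the photon-level process), drawn in one pass from a single
seeded generator so scenes are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.ndimage import distance_transform_edt

from .histogram import PhotonHistogram, TCSPCImage

__all__ = [
    "DecaySpec",
    "MixtureSpec",
    "SceneSpec",
    "SceneTruth",
    "simulate_decay_histogram",
    "simulate_mixture_histogram",
    "simulate_scene",
    "cleaved_fraction_timecourse",
    "expected_decay_histogram",
    "linear_tau_field",
]

#: Repetition period of an 80 MHz pulsed laser, ns.
DEFAULT_WINDOW_NS = 12.5
#: Conventional TCSPC time resolution (power-of-two bins).
DEFAULT_N_BINS = 256


@dataclass(frozen=True)
class DecaySpec:
    """A single mono-exponential decay measurement.

    Parameters
    ----------
    tau : float
        Fluorescence lifetime, ns.
    n_photons : float
        Expected total photon count (realised count is Poisson).
    background_fraction : float
        Fraction of photons drawn uniformly over the window (0-1); this is
        the generative counterpart of the fitted baseline Z.
    window : float
        Repetition period, ns (12.5 for 80 MHz).
    n_bins : int
        Number of time bins (>= 8).
    seed : int or None
        RNG seed; identical spec + seed gives bit-identical histograms.
    """

    tau: float
    n_photons: float = 10_000.0
    background_fraction: float = 0.0
    window: float = DEFAULT_WINDOW_NS
    n_bins: int = DEFAULT_N_BINS
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must lie in [0, 1]")
        if self.n_photons < 0:
            raise ValueError("n_photons must be >= 0")
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if self.n_bins < 8:
            raise ValueError("n_bins must be >= 8")

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.window, self.n_bins + 1)


@dataclass(frozen=True)
class MixtureSpec(DecaySpec):
    """A two-lifetime mixture of uncleaved (FRET-quenched, tau_DA) and
    cleaved (donor-unquenched, tau_D) sensor populations.

    ``tau`` is interpreted as the uncleaved lifetime; ``tau_cleaved`` must be
    at least as long (cleavage abolishes FRET quenching).
    """

    tau_cleaved: float = 2.35
    cleaved_fraction: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if not 0.0 <= self.cleaved_fraction <= 1.0:
            raise ValueError("cleaved_fraction must lie in [0, 1]")
        if self.tau_cleaved < self.tau:
            raise ValueError("tau_cleaved must be >= tau_uncleaved")

    @property
    def tau_uncleaved(self) -> float:
        return self.tau


def _truncated_exp_times(u: np.ndarray, tau: np.ndarray | float, window: float) -> np.ndarray:
    """Inverse-CDF sample of an exponential conditioned on [0, window)."""
    scale = -np.expm1(-window / np.asarray(tau, dtype=float))
    return -tau * np.log1p(-u * scale)


def truncated_exp_mean(tau: float, window: float) -> float:
    """Closed-form mean of an exponential truncated to [0, window)."""
    t_over = window / tau
    return tau - window * np.exp(-t_over) / -np.expm1(-t_over)


def _sample_histogram(
    rng: np.random.Generator,
    tau_a: float,
    tau_b: float,
    frac_b: float,
    spec: DecaySpec,
) -> PhotonHistogram:
    """Shared photon-level sampler.

    Always consumes three uniform streams (background flag, component flag,
    arrival time) so that the mixture with ``frac_b`` at 0 or 1 is
    bit-identical to the corresponding single-lifetime simulation.
    """
    n = int(rng.poisson(spec.n_photons))
    edges = spec.bin_edges
    if n == 0:
        return PhotonHistogram(edges, np.zeros(spec.n_bins, dtype=np.int64))
    u_bg = rng.random(n)
    u_comp = rng.random(n)
    u_time = rng.random(n)
    tau_ph = np.where(u_comp < frac_b, tau_b, tau_a)
    t_signal = _truncated_exp_times(u_time, tau_ph, spec.window)
    times = np.where(u_bg < spec.background_fraction, u_time * spec.window, t_signal)
    counts, _ = np.histogram(times, bins=edges)
    return PhotonHistogram(edges, counts)


def expected_decay_histogram(spec: DecaySpec) -> np.ndarray:
    """Expected (noise-free) counts per bin under a decay spec.

    Useful for Poisson-thinned batch simulation: drawing independent Poisson
    counts around these means is distributionally identical to photon-level
    sampling at the same expected total.
    """
    p = _bin_probabilities(np.array([spec.tau]), spec.bin_edges, spec.background_fraction)[0]
    return spec.n_photons * p


def simulate_decay_histogram(spec: DecaySpec) -> PhotonHistogram:
    """Simulate one mono-exponential decay histogram.

    Photon counts are Poisson with mean ``spec.n_photons``; arrival times are
    a mixture of a uniform background (probability ``background_fraction``)
    and an exponential with lifetime ``spec.tau`` truncated to the window.
    """
    rng = np.random.default_rng(spec.seed)
    return _sample_histogram(rng, spec.tau, spec.tau, 0.0, spec)


def simulate_mixture_histogram(spec: MixtureSpec) -> PhotonHistogram:
    """Simulate a cleaved/uncleaved two-lifetime mixture decay.

    Each signal photon is drawn from the cleaved lifetime with probability
    ``cleaved_fraction`` and the uncleaved lifetime otherwise.  The endpoints
    (fraction 0 or 1) reduce exactly to the single-lifetime simulation.
    """
    rng = np.random.default_rng(spec.seed)
    return _sample_histogram(
        rng, spec.tau_uncleaved, spec.tau_cleaved, spec.cleaved_fraction, spec
    )


def cleaved_fraction_timecourse(rate_constant: float, times: np.ndarray) -> np.ndarray:
    """First-order cleavage surrogate: f(t) = 1 - exp(-rate * t).

    Parameters
    ----------
    rate_constant : float
        Cleavage rate, 1/min (>= 0).
    times : array-like
        Times in minutes (>= 0).
    """
    times = np.asarray(times, dtype=float)
    if rate_constant < 0:
        raise ValueError("rate_constant must be >= 0")
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    return -np.expm1(-rate_constant * times)


# ---------------------------------------------------------------------------
# cell-in-hydrogel scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneSpec:
    """A dark-cell-in-bright-hydrogel FLIM scene.

    The cell is an ellipse (``center`` (row, col), ``semi_axes`` (a, b) in
    pixels along the rotated axes, ``orientation`` in radians).  The hydrogel
    lifetime is either constant (``tau_field`` a float) or a radial function
    ``tau_field(d)`` of the Euclidean distance ``d`` (pixels) from the cell
    boundary.  Photon rates are expectations per pixel; realised counts are
    Poisson.  The cell interior must be dimmer than the hydrogel, as in
    two-photon images where the gel fluoresces and cells appear dark.
    """

    width: int = 120
    height: int = 120
    center: tuple[float, float] = (60.0, 60.0)
    semi_axes: tuple[float, float] = (12.0, 9.0)
    orientation: float = 0.0
    tau_field: float | Callable[[np.ndarray], np.ndarray] = 2.0
    hydrogel_rate: float = 250.0
    interior_rate: float = 12.5
    background_fraction: float = 0.0
    window: float = DEFAULT_WINDOW_NS
    n_bins: int = DEFAULT_N_BINS
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be >= 1")
        if self.hydrogel_rate < 0 or self.interior_rate < 0:
            raise ValueError("photon rates must be >= 0")
        if self.interior_rate >= self.hydrogel_rate:
            raise ValueError("interior rate must be below the hydrogel rate (dark cell)")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must lie in [0, 1]")
        if self.window <= 0 or self.n_bins < 8:
            raise ValueError("invalid timing fields")
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("semi-axes must be > 0")
        cy, cx = self.center
        r = max(a, b)
        if cy - r < 0 or cx - r < 0 or cy + r > self.height - 1 or cx + r > self.width - 1:
            raise ValueError("cell ellipse must lie fully inside the image")

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.window, self.n_bins + 1)

    def cell_mask(self) -> np.ndarray:
        yy, xx = np.mgrid[0 : self.height, 0 : self.width]
        cy, cx = self.center
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        u = (yy - cy) * c + (xx - cx) * s
        v = -(yy - cy) * s + (xx - cx) * c
        a, b = self.semi_axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


@dataclass
class SceneTruth:
    """Ground truth of a simulated scene: per-pixel true lifetime (ns),
    binary cell mask, per-pixel expected photon count, and the seed."""

    tau_map: np.ndarray
    cell_mask: np.ndarray
    expected_counts: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.tau_map.shape == self.cell_mask.shape == self.expected_counts.shape):
            raise ValueError("truth fields must share the image dimensions")
        if np.any(self.tau_map[~self.cell_mask] <= 0):
            raise ValueError("lifetimes outside the mask must be > 0")


def _bin_probabilities(tau: np.ndarray, edges: np.ndarray, background_fraction: float) -> np.ndarray:
    """P(photon lands in bin b | lifetime tau), truncated-exponential signal
    plus uniform background.  tau may be any shape; output appends a bin axis."""
    tau = np.asarray(tau, dtype=float)[..., None]
    window = edges[-1] - edges[0]
    cdf = -np.expm1(-edges / tau) / -np.expm1(-window / tau)
    p_signal = np.diff(cdf, axis=-1)
    p_bg = np.diff(edges) / window
    return background_fraction * p_bg + (1.0 - background_fraction) * p_signal


def simulate_scene(spec: SceneSpec) -> tuple[TCSPCImage, SceneTruth]:
    """Simulate a cell-in-hydrogel TCSPC image with ground truth.

    Per-pixel expected counts are ``hydrogel_rate`` outside the cell mask and
    ``interior_rate`` inside; the true lifetime at each pixel follows
    ``tau_field`` evaluated at the distance from the cell boundary (interior
    pixels take the boundary value, d = 0).
    """
    mask = spec.cell_mask()
    distance = distance_transform_edt(~mask)
    if callable(spec.tau_field):
        tau_map = np.asarray(spec.tau_field(distance), dtype=float)
        if tau_map.shape != distance.shape:
            raise ValueError("tau_field must map distances to an equal-shaped array")
    else:
        tau_map = np.full(distance.shape, float(spec.tau_field))
    if np.any(tau_map <= 0):
        raise ValueError("tau_field must be positive everywhere")

    rate = np.where(mask, spec.interior_rate, spec.hydrogel_rate).astype(float)
    edges = spec.bin_edges
    lam = rate[..., None] * _bin_probabilities(tau_map, edges, spec.background_fraction)
    rng = np.random.default_rng(spec.seed)
    counts = rng.poisson(lam)
    image = TCSPCImage(
        counts,
        edges,
        metadata={
            "seed": spec.seed,
            "window_ns": spec.window,
            "hydrogel_rate": spec.hydrogel_rate,
            "interior_rate": spec.interior_rate,
        },
    )
    truth = SceneTruth(tau_map=tau_map, cell_mask=mask, expected_counts=rate, seed=spec.seed)
    return image, truth


def linear_tau_field(tau0: float, slope: float) -> Callable[[np.ndarray], np.ndarray]:
    """Radial lifetime field tau(d) = tau0 + slope * d (ns, ns/px)."""

    def field(d: np.ndarray) -> np.ndarray:
        return tau0 + slope * np.asarray(d, dtype=float)

    return field
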