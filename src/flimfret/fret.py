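"""FRET efficiency and intensity-ratio measurements.

FRET efficiency from donor lifetimes: E = 1 - tau_DA / tau_D, where tau_D is
the lifetime of the donor-only protein and tau_DA the donor lifetime in the
presence of the acceptor.  The intensity route compares acceptor-to-donor
mean fluorescence after background subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FRETPair", "fret_efficiency", "intensity_ratio"]


def fret_efficiency(tau_DA: float, tau_D: float) -> float:
    """FRET efficiency E = 1 - tau_DA / tau_D (fraction).

    Parameters
    ----------
    tau_DA : float
        Donor lifetime in the presence of the acceptor, ns.
    tau_D : float
        Donor-only lifetime, ns (> 0).
    """
    if tau_D <= 0:
        raise ValueError("tau_D must be > 0")
    return 1.0 - tau_DA / tau_D


@dataclass(frozen=True)
class FRETPair:
    """Donor-only and donor-acceptor lifetimes with the derived efficiency."""

    tau_D: float
    tau_DA: float

    def __post_init__(self) -> None:
        if self.tau_D <= 0:
            raise ValueError("tau_D must be > 0")
        if self.tau_DA < 0:
            raise ValueError("tau_DA must be >= 0")

    @property
    def efficiency(self) -> float:
        return fret_efficiency(self.tau_DA, self.tau_D)


def intensity_ratio(
    acceptor_image: np.ndarray,
    donor_image: np.ndarray,
    background_offsets: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Acceptor-to-donor mean intensity ratio after background subtraction.

    Returns ``mean(acceptor - offset_a) / mean(donor - offset_d)``.
    """
    acceptor = np.asarray(acceptor_image, dtype=float)
    donor = np.asarray(donor_image, dtype=float)
    if acceptor.shape != donor.shape:
        raise ValueError("acceptor and donor images must share a shape")
    off_a, off_d = background_offsets
    donor_mean = float(np.mean(donor) - off_d)
    if donor_mean <= 0:
        raise ValueError("donor mean must be positive after background subtraction")
    return float(np.mean(acceptor) - off_a) / donor_mean
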