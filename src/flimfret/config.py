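"""Run configuration.

All pipeline tunables in one validated, YAML-loadable object.  Defaults
mirror the published analysis where stated (35x35-pixel spatial bins,
10,000-photon gate, contour groups of 4, alpha 0.05); the image-processing
defaults (Canny, top-hat, closing) are this package's own choices since no
values are published for them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # spatial binning and photon gating
    bin_size: int = 35              # pixels per spatial-bin side
    min_photons: int = 10_000       # photon gate (inclusive), counts
    # decay fit
    fit_xtol: float = 1e-8
    fit_max_iter: int = 500
    fit_weights: str = "poisson"    # "poisson" (IRLS) | "none"
    # TCSPC timing
    window_ns: float = 12.5         # 80 MHz repetition period
    n_time_bins: int = 256
    # contour pipeline
    tophat_radius: int = 15         # px
    canny_sigma: float = 3.0
    canny_low: float = 0.15         # fraction of max gradient
    canny_high: float = 0.3
    closing_radius: int = 2         # px
    n_contours: int = 40
    contour_group: int = 4          # contours per ring bin (~4.7 px spot)
    # statistics
    alpha: float = 0.05
    equal_variance: bool = True
    # randomness
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.min_photons < 0:
            raise ValueError("min_photons must be >= 0")
        if self.fit_xtol <= 0 or self.fit_max_iter < 1:
            raise ValueError("invalid fit tolerances")
        if self.fit_weights not in ("none", "poisson"):
            raise ValueError("fit_weights must be 'none' or 'poisson'")
        if self.window_ns <= 0 or self.n_time_bins < 8:
            raise ValueError("invalid TCSPC timing fields")
        if self.tophat_radius < 1 or self.closing_radius < 0:
            raise ValueError("invalid morphology radii")
        if not 0 < self.canny_low < self.canny_high <= 1:
            raise ValueError("need 0 < canny_low < canny_high <= 1")
        if self.n_contours < 1 or self.contour_group < 1:
            raise ValueError("invalid contour counts")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load from YAML, rejecting unknown keys."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Short stable digest of the configuration, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
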