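"""Deterministic wet-lab calculators.

Small, pure helpers for the biochemical characterisation around the FLIM
measurements: chromophore-corrected protein masses, PEG-protein conjugate
mass enumeration, size-exclusion chromatography (SEC) calibration,
Beer-Lambert concentrations, substrate fold-excess, and rheology plateau
moduli.  Masses are handled in Da internally with kDa convenience I/O;
rounding happens only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ProteinMassSpec",
    "SECCalibration",
    "ConjugateSpec",
    "BeerLambertSpec",
    "RheologyTrace",
    "corrected_mass",
    "conjugate_mass_series",
    "sec_calibrate",
    "predict_elution",
    "beer_lambert_concentration",
    "fold_excess",
    "plateau_modulus",
    "protein_average_mass",
]

#: Mass lost per fluorescent-protein chromophore on autocatalytic
#: cyclisation (one oxygen plus 4-5 hydrogens), Da.
CHROMOPHORE_MASS_SHIFT_DA = 20.77


@dataclass(frozen=True)
class ProteinMassSpec:
    """Theoretical protein mass and number of maturing chromophores."""

    theoretical_mass: float  # Da
    n_chromophores: int
    shift_per_chromophore: float = CHROMOPHORE_MASS_SHIFT_DA

    def __post_init__(self) -> None:
        if self.theoretical_mass <= 0:
            raise ValueError("theoretical_mass must be > 0")
        if self.n_chromophores < 0:
            raise ValueError("n_chromophores must be >= 0")


def corrected_mass(spec: ProteinMassSpec) -> float:
    """Chromophore-corrected theoretical mass (Da):
    theoretical mass minus n_chromophores x shift."""
    return spec.theoretical_mass - spec.n_chromophores * spec.shift_per_chromophore


@dataclass(frozen=True)
class ConjugateSpec:
    """Multi-arm PEG scaffold decorated with 1..n_arms proteins (kDa)."""

    scaffold_mass: float = 20.0
    protein_mass: float = 58.0
    n_arms: int = 8

    def __post_init__(self) -> None:
        if self.n_arms < 1:
            raise ValueError("n_arms must be >= 1")
        if self.scaffold_mass <= 0 or self.protein_mass <= 0:
            raise ValueError("masses must be > 0")


def conjugate_mass_series(spec: ConjugateSpec) -> list[float]:
    """Possible conjugate masses (kDa), ascending:
    scaffold + n x protein for n = 1..n_arms."""
    return [spec.scaffold_mass + n * spec.protein_mass for n in range(1, spec.n_arms + 1)]


@dataclass(frozen=True)
class SECCalibration:
    """Linear SEC calibration: elution volume = slope * log10(MW) + intercept.

    Fitted from standards of known molecular weight; larger proteins elute
    earlier, so the slope is negative for a well-behaved column.
    """

    slope: float
    intercept: float
    markers: tuple[tuple[float, float], ...]


def sec_calibrate(markers) -> SECCalibration:
    """Least-squares calibration line from (MW kDa, elution mL) markers."""
    markers = [(float(mw), float(v)) for mw, v in markers]
    if len(markers) < 2:
        raise ValueError("need at least 2 markers")
    mw = np.array([m for m, _ in markers])
    if np.unique(mw).size < 2:
        raise ValueError("markers must span distinct molecular weights")
    if np.any(mw <= 0):
        raise ValueError("molecular weights must be > 0")
    vol = np.array([v for _, v in markers])
    slope, intercept = np.polyfit(np.log10(mw), vol, 1)
    return SECCalibration(float(slope), float(intercept), tuple(markers))


def predict_elution(cal: SECCalibration, mw_kda: float) -> float:
    """Predicted elution volume (mL) for a protein of given MW (kDa)."""
    if mw_kda <= 0:
        raise ValueError("MW must be > 0")
    return cal.slope * np.log10(mw_kda) + cal.intercept


@dataclass(frozen=True)
class BeerLambertSpec:
    """Beer-Lambert inputs: absorbance, path length (cm) and molar
    extinction coefficient (M^-1 cm^-1; 45000 for SFGFP at 490 nm)."""

    absorbance: float
    path_length_cm: float = 1.0
    extinction: float = 45_000.0

    def __post_init__(self) -> None:
        if self.absorbance < 0:
            raise ValueError("absorbance must be >= 0")
        if self.path_length_cm <= 0 or self.extinction <= 0:
            raise ValueError("path length and extinction must be > 0")


def beer_lambert_concentration(spec: BeerLambertSpec) -> float:
    """Molar concentration c = A / (l * epsilon)."""
    return spec.absorbance / (spec.path_length_cm * spec.extinction)


def fold_excess(
    substrate_conc_um: float, sensor_conc_um: float, sites_per_sensor: int = 4
) -> tuple[float, int]:
    """Fold excess of competing substrate over sensor cleavage sites.

    Returns ``(exact, rounded)`` where exact =
    substrate / (sensor x sites_per_sensor); e.g. a hydrogel carrying
    1211.4 uM degradable peptide against 1 uM sensor bearing ~4 cleavable
    sites is a ~303-fold excess.
    """
    if sensor_conc_um <= 0 or sites_per_sensor < 1:
        raise ValueError("sensor concentration and site count must be positive")
    exact = substrate_conc_um / (sensor_conc_um * sites_per_sensor)
    return exact, int(round(exact))


@dataclass(frozen=True)
class RheologyTrace:
    """Oscillatory rheology time sweep: t (min), storage modulus G' (Pa)
    and loss modulus G'' (Pa)."""

    time_min: np.ndarray
    g_prime: np.ndarray
    g_double_prime: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        g = np.asarray(self.g_prime, dtype=float)
        if t.size != g.size:
            raise ValueError("time and G' must align")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "g_prime", g)
        if self.g_double_prime is not None:
            g2 = np.asarray(self.g_double_prime, dtype=float)
            if g2.size != t.size:
                raise ValueError("G'' must align with time")
            object.__setattr__(self, "g_double_prime", g2)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RheologyTrace":
        g2 = frame["g_double_prime_pa"].to_numpy() if "g_double_prime_pa" in frame else None
        return cls(frame["time_min"].to_numpy(), frame["g_prime_pa"].to_numpy(), g2)


def plateau_modulus(trace: RheologyTrace, window: tuple[float, float] = (30.0, 40.0)) -> float:
    """Plateau modulus: mean G' (Pa) over samples with t in [window] min."""
    lo, hi = window
    inside = (trace.time_min >= lo) & (trace.time_min <= hi)
    if not inside.any():
        raise ValueError("no samples inside the plateau window")
    return float(np.mean(trace.g_prime[inside]))


# average masses of amino-acid residues (Da); free termini add one water
_RESIDUE_AVG_DA = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_WATER_DA = 18.01528


def protein_average_mass(sequence: str) -> float:
    """Average isotopic mass (Da) of an unmodified protein sequence.

    Convenience utility for sanity-checking theoretical masses from coding
    sequences; mass-scale conventions (average vs monoisotopic, termini
    modifications) vary, so this is not an analysis surface.
    """
    seq = sequence.strip().upper()
    try:
        return sum(_RESIDUE_AVG_DA[a] for a in seq) + _WATER_DA
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None
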