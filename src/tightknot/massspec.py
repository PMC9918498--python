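"""Neutral-mass computation from ESI charge-state envelopes and MALDI adducts.

An electrospray envelope is a run of consecutively charged ions of one
molecule; each peak at m/z with charge z and adduct mass m_a implies the
same neutral mass M = z*(m/z) - z*m_a. Deconvolution searches all
assignments of consecutive descending charges to the ascending peak list
and keeps the one whose implied masses agree best.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EnvelopeError, ValidationError

PROTON_MASS = 1.007276
SODIUM_MASS = 22.989218

#: Common singly-charged adducts for MALDI interpretation.
COMMON_ADDUCTS = [("H+", PROTON_MASS), ("Na+", SODIUM_MASS)]


@dataclass(frozen=True)
class IonEnvelope:
    """A centroided peak list (m/z ascending, optional intensities)."""

    mz: np.ndarray
    intensity: np.ndarray | None = None

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        if mz.ndim != 1 or len(mz) == 0:
            raise ValidationError("mz: at least one peak required")
        if np.any(mz <= 0):
            raise ValidationError("mz: values must be positive")
        order = np.argsort(mz)
        mz = mz[order]
        inten = self.intensity
        if inten is not None:
            inten = np.asarray(inten, dtype=float)[order]
            if inten.shape != mz.shape:
                raise ValidationError("intensity: must align with mz")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    def __len__(self):
        return len(self.mz)

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path)
        return cls(df["mz"].to_numpy(float),
                   df["intensity"].to_numpy(float) if "intensity" in df else None)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"mz": self.mz})
        if self.intensity is not None:
            df["intensity"] = self.intensity
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class ChargeAssignment:
    charges: np.ndarray          # aligned with ascending peaks
    adduct_mass: float
    per_peak_mass: np.ndarray
    variance: float              # sample variance of implied masses (Da^2)


@dataclass(frozen=True)
class DeconvolutionResult:
    mass: float                  # mean of per-peak neutral masses (Da)
    spread: float                # sample SD across peaks (Da)
    assignment: ChargeAssignment

    def summary(self) -> str:
        z = ", ".join(str(int(z)) for z in self.assignment.charges)
        return (f"Envelope deconvolution: M = {self.mass:.4f} Da "
                f"(spread {self.spread:.4f} Da across {len(self.assignment.charges)} "
                f"peaks, charges {z})")


def neutral_mass(mz: float, z: int, adduct_mass: float = PROTON_MASS) -> float:
    """Neutral mass implied by one peak: M = z*(m/z) - z*m_adduct."""
    if z < 1:
        raise ValidationError("z: charge must be >= 1")
    if mz <= adduct_mass:
        raise ValidationError("mz: must exceed the adduct mass")
    return z * mz - z * adduct_mass


def assign_charges(env: IonEnvelope, z_min: int = 1, z_max: int = 30,
                   adduct_mass: float = PROTON_MASS,
                   max_rel_spread: float = 0.01) -> ChargeAssignment:
    """Best consecutive-charge assignment for an envelope.

    Ascending m/z peaks receive consecutive descending charges
    z_top, z_top-1, ...; all placements with charges inside
    [z_min, z_max] are scored by the variance of the implied neutral
    masses and the minimizer is returned. A single-peak envelope is
    unambiguous only when ``z_min == z_max``.
    """
    n = len(env)
    if n == 1:
        if z_min != z_max:
            raise EnvelopeError("single peak: charge is ambiguous unless z_min == z_max")
        m = neutral_mass(env.mz[0], z_min, adduct_mass)
        return ChargeAssignment(np.array([z_min]), adduct_mass, np.array([m]), 0.0)
    if z_max - z_min + 1 < n:
        raise EnvelopeError(f"charge window [{z_min}, {z_max}] cannot hold {n} consecutive charges")

    best = None
    for z_top in range(z_min + n - 1, z_max + 1):
        charges = np.arange(z_top, z_top - n, -1)
        masses = env.mz * charges - charges * adduct_mass
        var = float(np.var(masses, ddof=1))
        if best is None or var < best[0]:
            best = (var, charges, masses)
    var, charges, masses = best
    mean = float(np.mean(masses))
    if mean <= 0 or np.sqrt(var) / mean > max_rel_spread:
        raise EnvelopeError(
            "no consistent envelope: best consecutive assignment has relative "
            f"mass spread {np.sqrt(var) / mean:.4f} > {max_rel_spread}")
    return ChargeAssignment(charges, adduct_mass, masses, var)


def deconvolve(env: IonEnvelope, z_min: int = 1, z_max: int = 30,
               adduct_mass: float = PROTON_MASS,
               intensity_weighted: bool = False,
               max_rel_spread: float = 0.01) -> DeconvolutionResult:
    """Neutral mass of an envelope: mean of per-peak implied masses.

    The mean is unweighted by default; ``intensity_weighted=True`` weights
    peaks by their intensities when present.
    """
    assignment = assign_charges(env, z_min, z_max, adduct_mass, max_rel_spread)
    masses = assignment.per_peak_mass
    if intensity_weighted and env.intensity is not None:
        mass = float(np.average(masses, weights=env.intensity))
    else:
        mass = float(np.mean(masses))
    spread = float(np.std(masses, ddof=1)) if len(masses) > 1 else 0.0
    return DeconvolutionResult(mass=mass, spread=spread, assignment=assignment)


def adduct_candidates(observed_mz: float,
                      adducts: list[tuple[str, float]] = COMMON_ADDUCTS
                      ) -> list[tuple[str, float]]:
    """Neutral-mass candidates for a singly charged peak, one per adduct."""
    if observed_mz <= 0:
        raise ValidationError("observed_mz: must be positive")
    return [(label, observed_mz - mass) for label, mass in adducts]
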