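"""Geometric dilution ladders for fatty-acid threshold testing.

Stimulus concentrations in detection-threshold work are spaced evenly on a
decimal-log scale (here 0.25 log-unit steps), so a ladder is fully defined by
its bottom concentration, the number of levels and the log step.  Two unit
conventions coexist in the literature: millimolar (mM) and mass-per-volume
percent (%w/v, grams per 100 mL).  They are related through the molar mass:

    mM = %w/v * 10000 / MW

Oleic acid (MW 282.46 g/mol) is the default solute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Molar mass of oleic acid (C18H34O2), g/mol.
OLEIC_ACID_MOLAR_MASS = 282.46

__all__ = [
    "OLEIC_ACID_MOLAR_MASS",
    "Concentration",
    "DilutionSeries",
    "pct_to_mM",
    "mM_to_pct",
    "build_series",
    "study1_series",
    "study2_series",
]


def pct_to_mM(pct_wv: float, molar_mass: float = OLEIC_ACID_MOLAR_MASS) -> float:
    """Convert mass-per-volume percent (g/100 mL) to millimolar.

    Parameters
    ----------
    pct_wv
        Concentration in %w/v; must be positive.
    molar_mass
        Solute molar mass in g/mol; must be positive.
    """
    if pct_wv <= 0:
        raise ValueError(f"pct_wv must be positive, got {pct_wv}")
    if molar_mass <= 0:
        raise ValueError(f"molar_mass must be positive, got {molar_mass}")
    return pct_wv * 10000.0 / molar_mass


def mM_to_pct(mM: float, molar_mass: float = OLEIC_ACID_MOLAR_MASS) -> float:
    """Convert millimolar to mass-per-volume percent (g/100 mL)."""
    if mM <= 0:
        raise ValueError(f"mM must be positive, got {mM}")
    if molar_mass <= 0:
        raise ValueError(f"molar_mass must be positive, got {molar_mass}")
    return mM * molar_mass / 10000.0


@dataclass(frozen=True)
class Concentration:
    """A single concentration carrying both unit representations."""

    mM: float
    pct_wv: float

    def __post_init__(self) -> None:
        if self.mM <= 0 or self.pct_wv <= 0:
            raise ValueError("Concentration values must be positive")

    @classmethod
    def from_pct(cls, pct_wv: float, molar_mass: float = OLEIC_ACID_MOLAR_MASS) -> "Concentration":
        return cls(mM=pct_to_mM(pct_wv, molar_mass), pct_wv=pct_wv)

    @classmethod
    def from_mM(cls, mM: float, molar_mass: float = OLEIC_ACID_MOLAR_MASS) -> "Concentration":
        return cls(mM=mM, pct_wv=mM_to_pct(mM, molar_mass))


@dataclass(frozen=True)
class DilutionSeries:
    """An ascending geometric ladder of concentrations.

    Level ``i`` has ``mM[i] = mM[0] * 10**(i * log_step)``.  Indices are
    0-based internally; reports display 1-based level numbers.
    """

    mM: np.ndarray
    log_step: float
    molar_mass: float = OLEIC_ACID_MOLAR_MASS

    def __post_init__(self) -> None:
        object.__setattr__(self, "mM", np.asarray(self.mM, dtype=float))
        if self.mM.size < 2:
            raise ValueError("a dilution series needs at least 2 levels")
        if np.any(self.mM <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(self.mM) <= 0):
            raise ValueError("series must be strictly increasing")
        ratios = np.diff(np.log10(self.mM))
        if not np.allclose(ratios, self.log_step, atol=1e-6):
            raise ValueError("adjacent levels must differ by exactly log_step decades")

    @property
    def n_levels(self) -> int:
        return int(self.mM.size)

    @property
    def pct_wv(self) -> np.ndarray:
        return self.mM * self.molar_mass / 10000.0

    @property
    def log10_mM(self) -> np.ndarray:
        return np.log10(self.mM)

    @property
    def bottom(self) -> Concentration:
        return Concentration(mM=float(self.mM[0]), pct_wv=float(self.pct_wv[0]))

    @property
    def top(self) -> Concentration:
        return Concentration(mM=float(self.mM[-1]), pct_wv=float(self.pct_wv[-1]))

    @property
    def span_decades(self) -> float:
        """Decimal-log span of the ladder from bottom to top."""
        return float(np.log10(self.mM[-1] / self.mM[0]))

    def level(self, index: int) -> Concentration:
        return Concentration(mM=float(self.mM[index]), pct_wv=float(self.pct_wv[index]))

    def to_frame(self) -> pd.DataFrame:
        """Ladder as a table with columns level_index, mM, pct_wv."""
        return pd.DataFrame(
            {
                "level_index": np.arange(self.n_levels),
                "mM": self.mM,
                "pct_wv": self.pct_wv,
            }
        )


def build_series(
    bottom: Concentration | float,
    n_levels: int,
    log_step: float = 0.25,
    molar_mass: float = OLEIC_ACID_MOLAR_MASS,
    *,
    bottom_unit: str = "pct_wv",
) -> DilutionSeries:
    """Construct a dilution ladder from its bottom level.

    ``bottom`` may be a :class:`Concentration` or a bare number interpreted in
    ``bottom_unit`` ('pct_wv' or 'mM').  The ladder is canonical in the unit
    the bottom was given in; the other unit is derived via ``molar_mass``.
    """
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    if log_step <= 0:
        raise ValueError(f"log_step must be positive, got {log_step}")
    if isinstance(bottom, Concentration):
        bottom_mM = bottom.mM
    elif bottom_unit == "pct_wv":
        bottom_mM = pct_to_mM(float(bottom), molar_mass)
    elif bottom_unit == "mM":
        if bottom <= 0:
            raise ValueError("bottom concentration must be positive")
        bottom_mM = float(bottom)
    else:
        raise ValueError(f"unknown bottom_unit {bottom_unit!r}")
    levels = bottom_mM * 10.0 ** (log_step * np.arange(n_levels))
    return DilutionSeries(mM=levels, log_step=log_step, molar_mass=molar_mass)


def study1_series() -> DilutionSeries:
    """Nine-level oleic-acid ladder, 0.0088 %w/v (0.31 mM) bottom, 0.25 log steps.

    Spans two full decades up to 0.88 %w/v (~31 mM).
    """
    return build_series(0.0088, n_levels=9, log_step=0.25)


def study2_series() -> DilutionSeries:
    """Twelve-level oleic-acid ladder, 0.0028 %w/v (0.098 mM) bottom, 0.25 log steps.

    Extends the nine-level ladder two steps lower and one step higher,
    spanning 2.75 decades up to ~1.58 %w/v (~56 mM).
    """
    return build_series(0.0028, n_levels=12, log_step=0.25)
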