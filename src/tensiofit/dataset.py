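"""Equilibrium surface-tension datasets.

A :class:`TensionDataset` is the experimental unit of the whole pipeline: a
set of (bulk concentration, equilibrium surface tension) pairs measured at a
fixed temperature against a solvent of known clean-interface tension.

Units
-----
Concentrations are stored in mol/m^3 (numerically equal to mmol/L), tensions
in mN/m, temperature in K. Conversion from user units happens at I/O time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TensionDataset", "MEASUREMENT_TOLERANCE"]

#: Fractional tolerance by which a measured tension may exceed the solvent
#: tension (run-to-run reproducibility of the tensiometry is <= 3 %).
MEASUREMENT_TOLERANCE = 0.03


@dataclass(frozen=True)
class TensionDataset:
    """Equilibrium surface tension vs. bulk surfactant concentration.

    Parameters
    ----------
    concentrations : array-like
        Bulk surfactant concentrations C in mol/m^3, strictly positive.
        Stored sorted ascending.
    tensions : array-like
        Equilibrium surface tensions gamma^e in mN/m, one per concentration.
    temperature : float
        Absolute temperature T in K.
    gamma0 : float
        Surface tension of the clean solvent (buffer) in mN/m.
    label : str
        Free-text surfactant name.
    """

    concentrations: np.ndarray
    tensions: np.ndarray
    temperature: float
    gamma0: float
    label: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        g = np.asarray(self.tensions, dtype=float)
        if c.ndim != 1 or g.ndim != 1 or c.size != g.size:
            raise ValueError(
                "concentrations and tensions must be 1-D arrays of equal length"
            )
        order = np.argsort(c)
        c, g = c[order], g[order]
        if not np.all(c > 0):
            raise ValueError("all concentrations must be > 0")
        if not np.all(g > 0):
            raise ValueError("all surface tensions must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.gamma0 <= 0:
            raise ValueError("gamma0 must be > 0 mN/m")
        if np.any(g > self.gamma0 * (1.0 + MEASUREMENT_TOLERANCE)):
            raise ValueError(
                "surface tensions exceed the solvent tension beyond the "
                f"{MEASUREMENT_TOLERANCE:.0%} measurement tolerance"
            )
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "tensions", g)

    def __len__(self) -> int:
        return self.concentrations.size

    @property
    def log_concentrations(self) -> np.ndarray:
        """Natural log of the concentrations (mol/m^3)."""
        return np.log(self.concentrations)

    def subset(self, indices) -> "TensionDataset":
        """New dataset restricted to the given indices."""
        idx = np.asarray(indices, dtype=int)
        return TensionDataset(
            self.concentrations[idx],
            self.tensions[idx],
            self.temperature,
            self.gamma0,
            self.label,
        )
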