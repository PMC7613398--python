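"""Declarative sampling design for the canopy/atmosphere state lookup table.

The training universe for the retrieval models is a lookup table (LUT) of
coupled canopy–atmosphere states.  Each state variable is described by a
:class:`VariableSpec` (distribution family plus bounds); a :class:`LUTSpec`
is an ordered collection of those.  The default specs encode the leaf,
canopy, soil and geometry variables of the surface simulation and the
atmospheric variables of the coupling step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VariableSpec",
    "LUTSpec",
    "default_canopy_spec",
    "default_atmosphere_spec",
    "default_state_spec",
    "sample_lut",
]


@dataclass(frozen=True)
class VariableSpec:
    """Sampling description for one scalar state variable.

    Parameters
    ----------
    name : str
        Variable identifier (e.g. ``"LAI"``).
    distribution : {"uniform", "gaussian_truncated", "constant"}
        Sampling family.  Truncated Gaussians are sampled by rejection so
        the bounds carry no probability atoms.
    min, max : float
        Hard bounds in the variable's physical units.
    mean, sd : float, optional
        Required for ``gaussian_truncated``.
    """

    name: str
    distribution: str
    min: float
    max: float
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.distribution not in ("uniform", "gaussian_truncated", "constant"):
            raise ValueError(
                f"{self.name}: unknown distribution {self.distribution!r}"
            )
        if self.min > self.max:
            raise ValueError(f"{self.name}: min {self.min} > max {self.max}")
        if self.distribution == "gaussian_truncated":
            if self.mean is None or self.sd is None:
                raise ValueError(f"{self.name}: gaussian_truncated requires mean and sd")
            if self.sd <= 0:
                raise ValueError(f"{self.name}: sd must be > 0, got {self.sd}")
        if self.distribution == "constant" and self.min != self.max:
            raise ValueError(f"{self.name}: constant requires min == max")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.distribution == "uniform":
            return rng.uniform(self.min, self.max, size=n)
        if self.distribution == "constant":
            return np.full(n, self.min)
        # truncated Gaussian by rejection: redraw out-of-bounds values until
        # all fall inside [min, max]
        out = rng.normal(self.mean, self.sd, size=n)
        bad = (out < self.min) | (out > self.max)
        while bad.any():
            out[bad] = rng.normal(self.mean, self.sd, size=int(bad.sum()))
            bad = (out < self.min) | (out > self.max)
        return out


@dataclass
class LUTSpec:
    """Ordered collection of :class:`VariableSpec` defining the LUT design."""

    variables: list[VariableSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in LUTSpec")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def __getitem__(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __add__(self, other: "LUTSpec") -> "LUTSpec":
        return LUTSpec(self.variables + other.variables)

    @classmethod
    def from_dict(cls, d: dict) -> "LUTSpec":
        """Build from a mapping ``{name: {distribution, min, max[, mean, sd]}}``."""
        return cls([VariableSpec(name=k, **v) for k, v in d.items()])

    @classmethod
    def from_file(cls, path) -> "LUTSpec":
        """Load a sampling design from a JSON config file."""
        import json

        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_file(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_dict(self) -> dict:
        out = {}
        for v in self.variables:
            row = {"distribution": v.distribution, "min": v.min, "max": v.max}
            if v.mean is not None:
                row["mean"] = v.mean
            if v.sd is not None:
                row["sd"] = v.sd
            out[v.name] = row
        return out


def default_canopy_spec() -> LUTSpec:
    """Leaf, canopy, soil and geometry sampling design.

    Units: LCC and Cxc in µg/cm², Cdm in g/cm², Cw in cm, LAI in m²/m²,
    LIDF in rad, SMC in %, angles in degrees.
    """
    return LUTSpec([
        VariableSpec("N", "gaussian_truncated", 1.0, 2.7, 1.5, 0.5),
        VariableSpec("LCC", "uniform", 0.0, 95.6),
        VariableSpec("Cxc", "gaussian_truncated", 0.0, 20.0, 10.0, 10.0),
        VariableSpec("Cdm", "gaussian_truncated", 0.002, 0.02, 0.005, 0.003),
        VariableSpec("Cw", "gaussian_truncated", 0.005, 0.035, 0.012, 0.006),
        VariableSpec("LAI", "uniform", 0.0, 7.0),
        VariableSpec("LIDF", "uniform", -1.0, 1.0),
        VariableSpec("SMC", "gaussian_truncated", 5.0, 55.0, 25.0, 12.5),
        VariableSpec("BSM_brightness", "gaussian_truncated", 0.0, 0.9, 0.5, 0.25),
        VariableSpec("BSM_lat", "gaussian_truncated", 20.0, 40.0, 25.0, 12.5),
        VariableSpec("BSM_long", "gaussian_truncated", 45.0, 65.0, 50.0, 10.0),
        VariableSpec("SZA", "uniform", 20.0, 40.0),
        VariableSpec("OZA", "uniform", -10.0, 10.0),
        VariableSpec("RAA", "constant", 180.0, 180.0),
    ])


def default_atmosphere_spec() -> LUTSpec:
    """Atmospheric sampling design: O3 in amt-cm, CWV in g·cm⁻²; AOT at
    550 nm, Ångström exponent and Henyey–Greenstein asymmetry unitless."""
    return LUTSpec([
        VariableSpec("O3", "uniform", 0.25, 0.35),
        VariableSpec("CWV", "uniform", 0.4, 4.5),
        VariableSpec("AOT", "uniform", 0.05, 0.5),
        VariableSpec("angstrom", "uniform", 0.05, 2.0),
        VariableSpec("hg_g", "uniform", 0.6, 1.0),
    ])


def default_state_spec() -> LUTSpec:
    """Full coupled canopy + atmosphere design (19 variables)."""
    return default_canopy_spec() + default_atmosphere_spec()


def sample_lut(spec: LUTSpec, n: int, seed: int | np.random.Generator) -> pd.DataFrame:
    """Draw ``n`` coupled states from the LUT design.

    Returns a DataFrame with one row per state and one column per variable,
    in spec order.  Seeded draws are bitwise reproducible.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return pd.DataFrame({v.name: v.sample(n, rng) for v in spec.variables})
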