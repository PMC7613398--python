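"""Synthetic scenes and seasonal trait trajectories for end-to-end tests.

Real acquisitions are replaced by fully synthetic ones: per-pixel trait
fields pushed through the forward model into 21-band radiance cubes with a
bitfield quality band (bit 0 = bright/cloud, bit 1 = inland water), and
double-logistic seasonal trait trajectories with optional noise and cloud
gaps.  Everything is seeded and deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import forward
from .mapping import BRIGHT_BIT, DEFAULT_GEOTRANSFORM, WATER_BIT, Scene
from .sampling import LUTSpec, default_state_spec, sample_lut
from .spectral import BandSet, band_convolve, olci_band_set

__all__ = ["make_scene", "double_logistic", "make_series"]


def make_scene(
    trait_fields: dict[str, np.ndarray],
    spec: LUTSpec | None = None,
    timestamp=None,
    cloud_fraction: float = 0.0,
    seed: int = 0,
    bands: BandSet | None = None,
    water_mask: np.ndarray | None = None,
    geotransform: tuple = DEFAULT_GEOTRANSFORM,
) -> Scene:
    """Forward-simulate a scene from per-pixel trait fields.

    ``trait_fields`` maps state-variable names (at least ``"LAI"``; typically
    also ``"LCC"``) to H×W grids.  Variables not given as fields are drawn
    once per scene from the LUT design and held spatially constant, so a
    scene's heterogeneity comes only from the supplied fields.  Exactly
    ⌈cloud_fraction·H·W⌉ random pixels get the bright bit; pixels under
    ``water_mask`` get the inland-water bit.
    """
    if not trait_fields:
        raise ValueError("trait_fields must contain at least one field")
    if not 0.0 <= cloud_fraction <= 1.0:
        raise ValueError("cloud_fraction must be in [0, 1]")
    shapes = {np.asarray(v).shape for v in trait_fields.values()}
    if len(shapes) != 1:
        raise ValueError(f"trait fields have mismatched shapes: {shapes}")
    (h, w) = shapes.pop()
    if spec is None:
        spec = default_state_spec()
    if bands is None:
        bands = olci_band_set()
    rng = np.random.default_rng(seed)

    base = sample_lut(spec, 1, rng).iloc[0]
    states = pd.DataFrame({name: np.full(h * w, val) for name, val in base.items()})
    for name, grid_vals in trait_fields.items():
        states[name] = np.asarray(grid_vals, float).ravel()

    rho_c = forward.simulate_toc_reflectance(states, bands.grid)
    tf = forward.simulate_atmo_functions(states, bands.grid)
    toa = forward.toc_to_toa(rho_c, tf, states["SZA"].to_numpy(float))
    radiance = band_convolve(toa, bands).T.reshape(bands.n_bands, h, w)

    flags = np.zeros((h, w), np.uint8)
    n_cloud = int(np.ceil(cloud_fraction * h * w))
    if n_cloud:
        pick = rng.choice(h * w, size=n_cloud, replace=False)
        flags.ravel()[pick] |= 1 << BRIGHT_BIT
    if water_mask is not None:
        flags[np.asarray(water_mask, bool)] |= 1 << WATER_BIT

    return Scene(
        radiance=radiance,
        flags=flags,
        timestamp=timestamp,
        geotransform=geotransform,
        band_ids=bands.band_ids,
    )


def double_logistic(
    t: np.ndarray,
    base: float,
    amplitude: float,
    m1: float,
    s1: float,
    m2: float,
    s2: float,
) -> np.ndarray:
    """Seasonal trajectory: green-up and senescence sigmoids.

    trait(t) = base + amplitude·[1/(1+exp(−m1(t−s1))) − 1/(1+exp(−m2(t−s2)))]

    with t in days; s1/s2 are the inflection days and m1/m2 the slopes.
    """
    t = np.asarray(t, float)
    up = 1.0 / (1.0 + np.exp(-m1 * (t - s1)))
    down = 1.0 / (1.0 + np.exp(-m2 * (t - s2)))
    return base + amplitude * (up - down)


def make_series(
    phenology: dict[str, dict],
    dates: np.ndarray,
    gap_pattern=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-date trait values on a double-logistic phenology, with gaps.

    ``phenology`` maps trait name to double-logistic parameters
    {base, amplitude, m1, s1, m2, s2}; ``dates`` are ordered day numbers (or
    datetimes convertible to day numbers).  ``gap_pattern`` is a boolean
    keep-mask or an index array of dates to drop (cloud gaps).  Returns a
    DataFrame indexed by the surviving dates, one column per trait.
    """
    t = np.asarray(dates)
    if np.issubdtype(t.dtype, np.datetime64):
        tdays = (t - t[0]) / np.timedelta64(1, "D")
    else:
        tdays = t.astype(float)
    if (np.diff(tdays) <= 0).any():
        raise ValueError("dates must be strictly increasing")
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(index=pd.Index(t, name="date"))
    for trait, p in phenology.items():
        vals = double_logistic(tdays, **p)
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, size=vals.size)
        out[trait] = vals
    if gap_pattern is not None:
        gap = np.asarray(gap_pattern)
        keep = gap if gap.dtype == bool else ~np.isin(np.arange(len(t)), gap)
        out = out.iloc[keep]
    return out
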