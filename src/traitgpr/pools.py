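"""Training-pool assembly: simulated samples plus synthetic mixed-scene spectra.

A pool is a tidy DataFrame with one row per labeled sample: the state
variables, the four trait labels (LCC, LAI, FAPAR, FVC), the 21 band
radiances and an ``origin`` column ({"simulated", "scene_mixed"}).

The default composition follows the hybrid-retrieval recipe: 1000 samples
simulated directly from the LUT design, mixed with 1000 synthetic
heterogeneous-pixel spectra (convex vegetated/bare-soil mixtures standing in
for spectra extracted from real scenes), 2000 samples in total.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import forward
from .sampling import LUTSpec, default_state_spec, sample_lut
from .spectral import BandSet, band_convolve, olci_band_set

__all__ = [
    "TRAITS",
    "build_simulated_pool",
    "build_scene_mixed_pool",
    "build_training_pool",
    "pool_to_cube",
    "write_pool",
    "read_pool",
]

TRAITS = ["LCC", "LAI", "FAPAR", "FVC"]


def _forward_to_bands(states: pd.DataFrame, bands: BandSet) -> np.ndarray:
    """Full forward chain for a table of states: TOC -> TOA -> band radiances."""
    grid = bands.grid
    rho_c = forward.simulate_toc_reflectance(states, grid)
    tf = forward.simulate_atmo_functions(states, grid)
    toa = forward.toc_to_toa(rho_c, tf, states["SZA"].to_numpy(float))
    return band_convolve(toa, bands)


def _assemble(states: pd.DataFrame, radiance: np.ndarray, bands: BandSet,
              origin: str) -> pd.DataFrame:
    pool = states.reset_index(drop=True).copy()
    pool["FAPAR"] = forward.compute_fapar(states, bands.grid)
    pool["FVC"] = forward.fvc_from_lai(states["LAI"].to_numpy(float))
    for j, bid in enumerate(bands.band_ids):
        pool[bid] = radiance[:, j]
    pool["origin"] = origin
    return pool


def build_simulated_pool(
    spec: LUTSpec | None = None,
    n: int = 1000,
    seed: int = 0,
    bands: BandSet | None = None,
) -> pd.DataFrame:
    """Simulate ``n`` labeled samples straight from the LUT design.

    Chains state sampling → canopy reflectance → trait labels → atmospheric
    transfer functions → Lambertian TOA coupling → RSR band convolution.
    """
    if spec is None:
        spec = default_state_spec()
    if bands is None:
        bands = olci_band_set()
    states = sample_lut(spec, n, seed)
    radiance = _forward_to_bands(states, bands)
    return _assemble(states, radiance, bands, "simulated")


def build_scene_mixed_pool(
    sim_pool: pd.DataFrame,
    n: int = 1000,
    seed: int = 0,
    spec: LUTSpec | None = None,
    bands: BandSet | None = None,
) -> pd.DataFrame:
    """Synthetic heterogeneous-pixel samples: vegetated/bare-soil mixtures.

    Each sample is a convex mixture f·(vegetated TOA spectrum) +
    (1−f)·(bare-soil TOA spectrum) with f ~ Uniform(0,1); trait labels are
    the same convex mixture of the endmember labels (the area-fraction
    interpretation of a mixed 300 m pixel).  Bare-soil endmembers are fresh
    LUT draws with LAI and LCC forced to zero.
    """
    if len(sim_pool) == 0:
        raise ValueError("sim_pool must be nonempty")
    if spec is None:
        spec = default_state_spec()
    if bands is None:
        bands = olci_band_set()
    rng = np.random.default_rng(seed)

    # vegetated endmembers: resample rows of the simulated pool
    veg_idx = rng.integers(0, len(sim_pool), size=n)
    veg = sim_pool.iloc[veg_idx].reset_index(drop=True)

    # bare-soil endmembers: fresh states with no canopy
    soil_states = sample_lut(spec, n, rng)
    soil_states["LAI"] = 0.0
    soil_states["LCC"] = 0.0
    soil_rad = _forward_to_bands(soil_states, bands)
    soil = _assemble(soil_states, soil_rad, bands, "scene_mixed")

    f = rng.uniform(0.0, 1.0, size=n)[:, None]
    cols = [c for c in sim_pool.columns if c != "origin"]
    mixed = pd.DataFrame(
        f * veg[cols].to_numpy(float) + (1.0 - f) * soil[cols].to_numpy(float),
        columns=cols,
    )
    mixed["origin"] = "scene_mixed"
    return mixed


def build_training_pool(
    spec: LUTSpec | None = None,
    n_simulated: int = 1000,
    n_mixed: int = 1000,
    seed: int = 0,
    bands: BandSet | None = None,
) -> pd.DataFrame:
    """Default combined pool: simulated + mixed-scene samples (1000 + 1000)."""
    sim = build_simulated_pool(spec, n_simulated, seed, bands)
    mixed = build_scene_mixed_pool(sim, n_mixed, seed + 1, spec, bands)
    return pd.concat([sim, mixed], ignore_index=True)


def pool_to_cube(pool: pd.DataFrame):
    """Pool as an xarray Dataset (sample × band cube plus per-sample labels)."""
    import xarray as xr

    band_cols = [c for c in pool.columns if c.startswith("band_")]
    other = [c for c in pool.columns if c not in band_cols]
    ds = xr.Dataset(
        {
            "toa_radiance": (
                ("sample", "band"),
                pool[band_cols].to_numpy(float),
            )
        },
        coords={"sample": np.arange(len(pool)), "band": band_cols},
    )
    for c in other:
        ds[c] = ("sample", pool[c].to_numpy())
    return ds


def write_pool(pool: pd.DataFrame, path) -> None:
    """Write a pool as CSV or as a NetCDF-style cube (by extension)."""
    path = str(path)
    if path.endswith(".nc"):
        ds = pool_to_cube(pool)
        # NETCDF3 via the scipy backend has no string-dtype support
        ds["origin"] = ("sample", pool["origin"].map({"simulated": 0, "scene_mixed": 1}).to_numpy())
        ds.to_netcdf(path, engine="scipy")
    else:
        pool.to_csv(path, index=False)


def read_pool(path) -> pd.DataFrame:
    path = str(path)
    if path.endswith(".nc"):
        import xarray as xr

        ds = xr.open_dataset(path, engine="scipy")
        band_cols = [str(b) for b in ds["band"].values]
        pool = pd.DataFrame(ds["toa_radiance"].values, columns=band_cols)
        for name, var in ds.data_vars.items():
            if name == "toa_radiance":
                continue
            pool[name] = var.values
        pool["origin"] = pool["origin"].map({0: "simulated", 1: "scene_mixed"})
        # restore canonical column order: states/traits first, bands, origin
        front = [c for c in pool.columns if c not in band_cols and c != "origin"]
        return pool[front + band_cols + ["origin"]]
    return pd.read_csv(path)
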