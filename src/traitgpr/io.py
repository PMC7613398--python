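"""File I/O: GeoTIFF-style rasters for scenes and trait maps, delimited
text for time series.

Scenes are written as uncompressed multi-band TIFFs (bands 1..B radiance,
last band the quality bitfield) with a JSON sidecar carrying the
geotransform, timestamp and band list; trait maps as 3-band TIFFs
(mean, sigma, cv) plus sidecar.  NaN no-data is mapped to a configurable
sentinel on write and restored on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .mapping import Scene, TraitMap
from .timeseries import TraitSeries

__all__ = [
    "write_scene",
    "read_scene",
    "write_trait_map",
    "read_trait_map",
    "write_series",
    "read_series",
]

NODATA = -9999.0


def _sidecar(path) -> Path:
    return Path(str(path) + ".json")


def _parse_timestamp(ts):
    """Timestamps may be day numbers (floats) or ISO dates."""
    if not ts:
        return None
    try:
        return float(ts)
    except ValueError:
        return np.datetime64(ts)


def write_scene(scene: Scene, path) -> None:
    stack = np.concatenate(
        [scene.radiance.astype(np.float32), scene.flags[None].astype(np.float32)]
    )
    tifffile.imwrite(path, stack, photometric="minisblack")
    meta = {
        "kind": "scene",
        "geotransform": list(scene.geotransform),
        "timestamp": str(scene.timestamp) if scene.timestamp is not None else None,
        "band_ids": scene.band_ids,
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_scene(path) -> Scene:
    stack = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    if meta.get("kind") != "scene":
        raise ValueError(f"{path} is not a scene raster")
    return Scene(
        radiance=stack[:-1],
        flags=stack[-1].astype(np.uint8),
        timestamp=_parse_timestamp(meta["timestamp"]),
        geotransform=tuple(meta["geotransform"]),
        band_ids=meta["band_ids"],
    )


def write_trait_map(tmap: TraitMap, path, nodata: float = NODATA) -> None:
    def fill(a):
        out = a.astype(np.float32).copy()
        out[~np.isfinite(out)] = nodata
        return out

    stack = np.stack([fill(tmap.mean), fill(tmap.sigma), fill(tmap.cv)])
    tifffile.imwrite(path, stack, photometric="minisblack")
    meta = {
        "kind": "trait_map",
        "trait": tmap.trait,
        "nodata": nodata,
        "geotransform": list(tmap.geotransform),
        "timestamp": str(tmap.timestamp) if tmap.timestamp is not None else None,
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_trait_map(path) -> TraitMap:
    stack = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    if meta.get("kind") != "trait_map":
        raise ValueError(f"{path} is not a trait-map raster")
    nodata = meta["nodata"]
    stack[stack == nodata] = np.nan
    return TraitMap(
        mean=stack[0],
        sigma=stack[1],
        cv=stack[2],
        valid_mask=np.isfinite(stack[0]),
        trait=meta["trait"],
        timestamp=_parse_timestamp(meta["timestamp"]),
        geotransform=tuple(meta["geotransform"]),
    )


def scene_to_dataset(scene: Scene):
    """Scene as an xarray Dataset (NetCDF-style cube)."""
    import xarray as xr

    ds = xr.Dataset(
        {
            "radiance": (("band", "y", "x"), scene.radiance),
            "flags": (("y", "x"), scene.flags.astype(np.int32)),
        },
        coords={"band": scene.band_ids},
        attrs={
            "geotransform": list(scene.geotransform),
            "timestamp": str(scene.timestamp) if scene.timestamp is not None else "",
        },
    )
    return ds


def write_scene_netcdf(scene: Scene, path) -> None:
    scene_to_dataset(scene).to_netcdf(path, engine="scipy")


def read_scene_netcdf(path) -> Scene:
    import xarray as xr

    ds = xr.open_dataset(path, engine="scipy")
    return Scene(
        radiance=ds["radiance"].values,
        flags=ds["flags"].values.astype(np.uint8),
        timestamp=_parse_timestamp(str(ds.attrs.get("timestamp", ""))),
        geotransform=tuple(ds.attrs["geotransform"]),
        band_ids=[str(b) for b in ds["band"].values],
    )


def write_series(series: TraitSeries, path) -> None:
    df = pd.DataFrame({"date_days": series.dates, "value": series.values})
    if series.sigma is not None:
        df["sigma"] = series.sigma
    df.to_csv(path, index=False)


def read_series(path, trait: str = "", region: str = "") -> TraitSeries:
    df = pd.read_csv(path)
    return TraitSeries(
        df["date_days"].to_numpy(float),
        df["value"].to_numpy(float),
        df["sigma"].to_numpy(float) if "sigma" in df else None,
        trait=trait,
        region=region,
    )
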