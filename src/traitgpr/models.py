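"""Trait retrieval models: pool split, per-trait training, evaluation and
the reduced-band foreign-sensor variant.

The operational recipe: assemble the 2000-sample pool, draw one random
250-sample training subset (shared across traits), fit four independent GP
models (LCC, LAI, FAPAR, FVC) on the same 21-band radiance matrix, and score
each against the 1750 held-out samples with R², RMSE and range-normalized
NRMSE.  The 250-sample cap mirrors the memory constraint of the deployment
platform and the cubic training cost of exact GPs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gpr import ARDGaussianProcessRegressor
from .metrics import goodness_of_fit
from .pools import TRAITS
from .spectral import BandSet

__all__ = [
    "split_pool",
    "fit_trait_models",
    "evaluate_models",
    "EvaluationReport",
    "band_subset_variant",
    "resample_foreign_sensor",
    "band_columns",
]

DEFAULT_N_TRAIN = 250


def band_columns(pool: pd.DataFrame) -> list[str]:
    return [c for c in pool.columns if c.startswith("band_")]


def split_pool(
    pool: pd.DataFrame, n_train: int = DEFAULT_N_TRAIN, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniform random train/validation partition without replacement.

    The validation set is the leftover (default 250 of 2000 → 1750 held
    out).  One split is shared by all four trait models.
    """
    if n_train >= len(pool):
        raise ValueError(f"n_train={n_train} must be < pool size {len(pool)}")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(pool))
    train = pool.iloc[idx[:n_train]].reset_index(drop=True)
    val = pool.iloc[idx[n_train:]].reset_index(drop=True)
    return train, val


def fit_trait_models(
    train: pd.DataFrame,
    traits: list[str] | None = None,
    bands: list[str] | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    sigma_variant: str = "latent",
) -> dict[str, ARDGaussianProcessRegressor]:
    """Fit one GP per trait on the shared radiance matrix.

    Returns {trait: fitted model}; each model carries its trait name and
    band list for serialization.
    """
    if traits is None:
        traits = TRAITS
    if bands is None:
        bands = band_columns(train)
    if len(train) == 0:
        raise ValueError("empty training set")
    X = train[bands].to_numpy(float)
    models = {}
    for trait in traits:
        y = train[trait].to_numpy(float)
        if not np.isfinite(y).all():
            raise ValueError(f"non-finite labels for trait {trait}")
        gp = ARDGaussianProcessRegressor(
            n_restarts=n_restarts, random_state=seed, sigma_variant=sigma_variant
        ).fit(X, y)
        gp.trait_ = trait
        gp.band_ids_ = list(bands)
        models[trait] = gp
    return models


@dataclass
class EvaluationReport:
    """Per-trait goodness-of-fit over the validation set."""

    metrics: dict[str, dict]  # trait -> {R2, RMSE, NRMSE}
    n_validation: int
    nrmse_norm: str = "range"

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_validation": self.n_validation,
                "nrmse_norm": self.nrmse_norm,
                "metrics": self.metrics,
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = [f"{'trait':<8}{'R2':>8}{'RMSE':>10}{'NRMSE%':>10}   (n={self.n_validation}, norm={self.nrmse_norm})"]
        for trait, m in self.metrics.items():
            lines.append(
                f"{trait:<8}{m['R2']:>8.3f}{m['RMSE']:>10.4f}{m['NRMSE']:>10.2f}"
            )
        return "\n".join(lines)


def evaluate_models(
    models: dict[str, ARDGaussianProcessRegressor],
    validation: pd.DataFrame,
    nrmse_norm: str = "range",
) -> EvaluationReport:
    """Score each trait model on the held-out samples."""
    if len(validation) == 0:
        raise ValueError("empty validation set")
    out = {}
    for trait, model in models.items():
        bands = getattr(model, "band_ids_", band_columns(validation))
        est = model.predict(validation[bands].to_numpy(float))
        out[trait] = goodness_of_fit(
            est, validation[trait].to_numpy(float), nrmse_norm=nrmse_norm
        )
    return EvaluationReport(out, len(validation), nrmse_norm)


def band_subset_variant(
    train: pd.DataFrame,
    kept_bands: list[int] | None = None,
    traits: list[str] | None = None,
    **fit_kwargs,
) -> dict[str, ARDGaussianProcessRegressor]:
    """Retrain on a reduced band set (foreign-sensor substitute models).

    ``kept_bands`` are 0-based indices into the pool's band columns; the
    default drops the three shortest-wavelength (blue) bands, leaving 18 —
    the bands reconstructable from a Landsat-class sensor.
    """
    all_bands = band_columns(train)
    if kept_bands is None:
        kept_bands = list(range(3, len(all_bands)))
    if len(kept_bands) == 0:
        raise ValueError("band subset must be nonempty")
    bad = [i for i in kept_bands if not 0 <= i < len(all_bands)]
    if bad:
        raise ValueError(f"invalid band indices {bad}")
    bands = [all_bands[i] for i in kept_bands]
    return fit_trait_models(train, traits=traits, bands=bands, **fit_kwargs)


def resample_foreign_sensor(
    foreign_values: np.ndarray,
    foreign_bands: BandSet,
    target_bands: BandSet,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate target-sensor bands from a foreign sensor's band values.

    The foreign band values are linearly interpolated (by band center) onto
    the fine spectral grid, then convolved with the target RSRs.  Target
    bands whose centers fall outside the foreign sensor's covered range are
    flagged unreconstructable (mask False, value NaN) — extrapolation is
    never attempted.
    """
    foreign_values = np.asarray(foreign_values, float)
    fc = foreign_bands.centers
    lo, hi = fc.min(), fc.max()
    grid = target_bands.grid
    if hi < grid.min() or lo > grid.max():
        raise ValueError("foreign sensor does not overlap the target grid")
    order = np.argsort(fc)
    fine = np.interp(grid, fc[order], foreign_values[order])
    values = (fine[None, :] * target_bands.rsr).sum(axis=1) * float(
        np.diff(grid).mean()
    )
    mask = (target_bands.centers >= lo) & (target_bands.centers <= hi)
    values = np.where(mask, values, np.nan)
    return values, mask
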