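"""Trait time series: spatial averaging, GP gap-filling, monthly chunking.

Gap-filling runs the same ARD-SE Gaussian process used for retrieval, but in
one dimension (time, fractional days) and with *fixed* global
hyperparameters — no per-series marginal-likelihood optimization.  Pooled
hyperparameters are obtained once from an ensemble of series
(:func:`fit_global_hyperparams`, median of per-series log-optima), which
makes filling a new series two triangular solves instead of an optimizer
run.  The accuracy cost of this shortcut is measured by
:func:`gapfill_degradation_ensemble`.

Long records are processed in overlapping monthly chunks
(:func:`chunked_gapfill`) to bound memory; with an overlap of three length
scales the stitched result is numerically indistinguishable from filling the
whole series at once.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import solve_triangular

from .gpr import ARDGaussianProcessRegressor, Hyperparams, _kernel_matrix, factorize
from .synth import double_logistic

__all__ = [
    "TraitSeries",
    "GlobalHyperparams",
    "spatial_average",
    "fit_global_hyperparams",
    "gapfill_series",
    "gapfill_uncertainty",
    "chunked_gapfill",
    "gapfill_degradation_ensemble",
]

_EPOCH = np.datetime64("2000-01-01")


def _to_days(dates) -> np.ndarray:
    """Dates to float days since the fixed epoch (floats pass through)."""
    arr = np.asarray(dates)
    if np.issubdtype(arr.dtype, np.datetime64):
        return (arr - _EPOCH) / np.timedelta64(1, "D")
    return arr.astype(float)


@dataclass
class TraitSeries:
    """Spatially averaged trait record: ordered dates, values, optional σ."""

    dates: np.ndarray
    values: np.ndarray
    sigma: np.ndarray | None = None
    trait: str = ""
    region: str = ""

    def __post_init__(self) -> None:
        self.dates = _to_days(self.dates)
        self.values = np.asarray(self.values, float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, float)
            if self.sigma.size != self.dates.size:
                raise ValueError("sigma must align with dates")
        if self.values.size != self.dates.size:
            raise ValueError("values must align with dates")
        if (np.diff(self.dates) <= 0).any():
            raise ValueError("dates must be strictly increasing")

    def __len__(self) -> int:
        return self.dates.size


@dataclass(frozen=True)
class GlobalHyperparams:
    """Fixed gap-filling hyperparameters: temporal length scale (days),
    signal variance and noise variance (trait units²)."""

    length_scale: float
    variance: float
    noise: float

    def __post_init__(self) -> None:
        if self.length_scale <= 0 or self.variance <= 0 or self.noise <= 0:
            raise ValueError("all global hyperparameters must be > 0")

    def to_theta(self) -> Hyperparams:
        return Hyperparams(self.variance, np.array([self.length_scale]), self.noise)


def default_global_hyperparams(trait_range: float, length_scale: float = 60.0) -> GlobalHyperparams:
    """Declared default when no fitted values are available: length scale
    60 days, variance (range/4)², noise 5% of variance."""
    var = (trait_range / 4.0) ** 2
    return GlobalHyperparams(length_scale, var, 0.05 * var)


def spatial_average(maps: list, region_mask: np.ndarray, trait: str = "",
                    region: str = "") -> TraitSeries:
    """Average valid in-region pixels of each map into one value per date.

    Dates with no valid in-region pixel are dropped; the σ series is the
    mean of the per-pixel σ over the same pixels.
    """
    region_mask = np.asarray(region_mask, bool)
    if not region_mask.any():
        raise ValueError("region mask selects no pixels")
    dates, vals, sigs = [], [], []
    for m in maps:
        if m.mean.shape != region_mask.shape:
            raise ValueError("region mask does not align with map grid")
        ok = m.valid_mask & region_mask & np.isfinite(m.mean)
        if not ok.any():
            continue
        dates.append(m.timestamp)
        vals.append(float(m.mean[ok].mean()))
        sigs.append(float(np.nanmean(m.sigma[ok])))
    if not dates:
        raise ValueError("no date has a valid in-region pixel")
    order = np.argsort(_to_days(np.asarray(dates)))
    return TraitSeries(
        np.asarray(dates)[order],
        np.asarray(vals)[order],
        np.asarray(sigs)[order],
        trait=trait or getattr(maps[0], "trait", ""),
        region=region,
    )


def fit_global_hyperparams(series_collection: list[TraitSeries], seed: int = 0) -> GlobalHyperparams:
    """Pooled hyperparameters: per-series LML optimization, then the median
    of the log-hyperparameters across series (robust to outlier series).

    Series with fewer than 4 points are skipped; if none remain, raises.
    """
    logs = []
    for s in series_collection:
        if len(s) < 4:
            continue
        gp = ARDGaussianProcessRegressor(
            n_restarts=2, normalize_x=False, center_y=True, random_state=seed
        ).fit(s.dates[:, None], s.values)
        logs.append(
            [
                np.log(gp.theta_.length_scales[0]),
                np.log(gp.theta_.sigma_s2),
                np.log(max(gp.theta_.sigma_n2, 1e-12)),
            ]
        )
    if not logs:
        raise ValueError("no series with >= 4 observations")
    med = np.median(np.asarray(logs), axis=0)
    return GlobalHyperparams(*np.exp(med))


def _gp_posterior(t_obs, y_obs, t_out, hp: GlobalHyperparams, offset: float | None = None):
    theta = hp.to_theta()
    if offset is None:
        offset = float(np.mean(y_obs))
    L, alpha = factorize(t_obs[:, None], y_obs - offset, theta)
    Ks = _kernel_matrix(t_out[:, None], t_obs[:, None], theta)
    mean = Ks @ alpha + offset
    v = solve_triangular(L, Ks.T, lower=True)
    var = np.clip(theta.sigma_s2 - (v ** 2).sum(axis=0), 0.0, None)
    return mean, np.sqrt(var)


def gapfill_series(series: TraitSeries, hp: GlobalHyperparams, output_dates) -> TraitSeries:
    """GP posterior of the series at ``output_dates`` with fixed
    hyperparameters — no retraining.

    Observed dates are reproduced within the noise level; the posterior σ
    grows with distance from observations and saturates at √variance far
    outside the record.
    """
    if len(series) < 2:
        raise ValueError("gap-filling needs at least 2 observations")
    t_out = _to_days(output_dates)
    mean, sig = _gp_posterior(series.dates, series.values, t_out, hp)
    return TraitSeries(t_out, mean, sig, trait=series.trait, region=series.region)


def gapfill_uncertainty(series: TraitSeries, hp: GlobalHyperparams, output_dates) -> TraitSeries:
    """Interpolate the σ series itself with the same GP mechanics.

    The filled values are a posterior over σ, clipped at zero (a σ series is
    nonnegative by definition).
    """
    if series.sigma is None:
        raise ValueError("series has no sigma to interpolate")
    if len(series) < 2:
        raise ValueError("gap-filling needs at least 2 observations")
    t_out = _to_days(output_dates)
    mean, sig = _gp_posterior(series.dates, series.sigma, t_out, hp)
    return TraitSeries(
        t_out, np.clip(mean, 0.0, None), sig, trait=series.trait, region=series.region
    )


def chunked_gapfill(
    series: TraitSeries,
    hp: GlobalHyperparams,
    output_dates=None,
    window_days: float = 30.0,
    overlap_scales: float = 3.0,
) -> TraitSeries:
    """Monthly chunked gap-filling for long records.

    Each chunk predicts its own central window using observations within
    ``overlap_scales`` length scales on either side; chunks are stitched by
    keeping each window's own output dates, so no date is duplicated.  With
    an overlap of 3 length scales the stitched series matches the
    whole-series posterior to numerical precision; chunks too sparse to fill
    are widened until they hold 2 observations.
    """
    if len(series) < 2:
        raise ValueError("gap-filling needs at least 2 observations")
    t_out = _to_days(output_dates) if output_dates is not None else series.dates.copy()
    span = series.dates[-1] - series.dates[0]
    if span <= window_days:
        return gapfill_series(series, hp, t_out)

    overlap = overlap_scales * hp.length_scale
    edges = np.arange(series.dates[0], series.dates[-1] + window_days, window_days)
    means, sigs, dates = [], [], []
    for i, (w0, w1) in enumerate(zip(edges[:-1], edges[1:])):
        # first/last chunks also own output dates beyond the observed span
        lo = -np.inf if i == 0 else w0
        hi = np.inf if w1 >= edges[-1] else w1
        sel_out = (t_out >= lo) & (t_out < hi)
        if not sel_out.any():
            continue
        ov = overlap
        obs = (series.dates >= w0 - ov) & (series.dates <= w1 + ov)
        while obs.sum() < 2:  # widen until the chunk is viable
            ov *= 2.0
            obs = (series.dates >= w0 - ov) & (series.dates <= w1 + ov)
        # all chunks share the whole-series offset so they agree with the
        # unchunked posterior away from chunk boundaries
        m, s = _gp_posterior(
            series.dates[obs],
            series.values[obs],
            t_out[sel_out],
            hp,
            offset=float(series.values.mean()),
        )
        means.append(m)
        sigs.append(s)
        dates.append(t_out[sel_out])
    out_t = np.concatenate(dates)
    order = np.argsort(out_t)
    return TraitSeries(
        out_t[order],
        np.concatenate(means)[order],
        np.concatenate(sigs)[order],
        trait=series.trait,
        region=series.region,
    )


def gapfill_degradation_ensemble(
    n_series: int = 50,
    gap_fraction: float = 0.3,
    seed: int = 0,
    n_dates: int = 73,
    noise_sd: float = 0.1,
) -> dict:
    """Cost of fixed global hyperparameters, measured on a seeded ensemble.

    Simulates ``n_series`` double-logistic seasonal trajectories sampled
    every ~5 days over a year, withholds ``gap_fraction`` of the dates at
    random, and reconstructs the withheld values two ways: (a) per-series
    optimized hyperparameters, (b) the pooled global hyperparameters fitted
    on the same ensemble.  Returns the ensemble-mean relative RMSE increase
    of (b) over (a), in percent, plus the per-series values.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 360.0, n_dates)
    rows = []
    for _ in range(n_series):
        p = dict(
            base=rng.uniform(0.2, 0.8),
            amplitude=rng.uniform(1.0, 5.0),
            m1=rng.uniform(0.05, 0.15),
            s1=rng.uniform(100.0, 160.0),
            m2=rng.uniform(0.05, 0.15),
            s2=rng.uniform(230.0, 290.0),
        )
        truth = double_logistic(t, **p)
        obs = truth + rng.normal(0.0, noise_sd, size=t.size)
        n_gap = int(round(gap_fraction * t.size))
        gap_idx = np.sort(rng.choice(t.size, size=n_gap, replace=False))
        keep = np.setdiff1d(np.arange(t.size), gap_idx)
        rows.append((t[keep], obs[keep], t[gap_idx], truth[gap_idx]))

    observed = [TraitSeries(tk, yk) for tk, yk, _, _ in rows]
    global_hp = fit_global_hyperparams(observed, seed=seed)

    degradations = []
    for s, (tk, yk, tg, truth_g) in zip(observed, rows):
        gp = ARDGaussianProcessRegressor(
            n_restarts=2, normalize_x=False, center_y=True, random_state=seed
        ).fit(s.dates[:, None], s.values)
        own_hp = GlobalHyperparams(
            gp.theta_.length_scales[0],
            gp.theta_.sigma_s2,
            max(gp.theta_.sigma_n2, 1e-10),
        )
        rmse_own = _reconstruction_rmse(s, own_hp, tg, truth_g)
        rmse_global = _reconstruction_rmse(s, global_hp, tg, truth_g)
        degradations.append(100.0 * (rmse_global - rmse_own) / rmse_own)
    degradations = np.asarray(degradations)
    return {
        "mean_degradation_pct": float(degradations.mean()),
        "max_degradation_pct": float(degradations.max()),
        "per_series_pct": degradations,
        "global_hyperparams": global_hp,
    }


def _reconstruction_rmse(series, hp, t_target, truth) -> float:
    filled = gapfill_series(series, hp, t_target)
    return float(np.sqrt(np.mean((filled.values - truth) ** 2)))
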