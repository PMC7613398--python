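"""Validation statistics: goodness-of-fit, ΔX% series comparison,
percentage-difference maps and grid matching."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "goodness_of_fit",
    "ComparisonResult",
    "delta_x_percent",
    "difference_map",
    "regrid",
]


def goodness_of_fit(estimates, references, nrmse_norm: str = "range") -> dict:
    """R², RMSE and NRMSE (percent) of estimates against references.

    R² = 1 − SS_res/SS_tot; NRMSE = 100·RMSE / denominator with the
    denominator the reference range (default) or mean.
    """
    est = np.asarray(estimates, float).ravel()
    ref = np.asarray(references, float).ravel()
    if est.size != ref.size:
        raise ValueError(f"length mismatch: {est.size} vs {ref.size}")
    if est.size < 2:
        raise ValueError("need at least 2 pairs")
    if not (np.isfinite(est).all() and np.isfinite(ref).all()):
        raise ValueError("non-finite values")
    resid = est - ref
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(((ref - ref.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else np.nan
    if nrmse_norm == "range":
        denom = float(ref.max() - ref.min())
    elif nrmse_norm == "mean":
        denom = float(ref.mean())
    else:
        raise ValueError(f"unknown nrmse_norm {nrmse_norm!r}")
    if denom == 0:
        raise ValueError("NRMSE undefined: zero-variance reference")
    return {"R2": r2, "RMSE": rmse, "NRMSE": 100.0 * rmse / denom}


@dataclass
class ComparisonResult:
    """Summary comparison of two trait time series over a common window."""

    delta_x: float  # percent
    mean_gpr: float
    mean_ref: float
    sd_gpr: float
    sd_ref: float
    max_gpr: float
    max_ref: float
    n_dates: int


def delta_x_percent(series_gpr, series_ref) -> ComparisonResult:
    """Percentage difference of time-series means.

    ΔX% = 100·|X̄_gpr − X̄_ref| / X̄_gpr — the retrieved series' mean is the
    denominator.  Inputs are aligned series (gap-fill beforehand); accepts
    TraitSeries or plain arrays.
    """
    g = np.asarray(getattr(series_gpr, "values", series_gpr), float).ravel()
    r = np.asarray(getattr(series_ref, "values", series_ref), float).ravel()
    if g.size == 0 or r.size == 0:
        raise ValueError("empty series")
    mg, mr = float(g.mean()), float(r.mean())
    if mg == 0:
        raise ValueError("delta-X undefined: retrieved series mean is zero")
    return ComparisonResult(
        delta_x=100.0 * abs(mg - mr) / abs(mg),
        mean_gpr=mg,
        mean_ref=mr,
        sd_gpr=float(g.std(ddof=0)),
        sd_ref=float(r.std(ddof=0)),
        max_gpr=float(g.max()),
        max_ref=float(r.max()),
        n_dates=int(min(g.size, r.size)),
    )


def difference_map(
    map_gpr, map_ref, epsilon: float = 1e-6, signed: bool = True
) -> np.ndarray:
    """Per-pixel percentage difference 100·(gpr − ref)/gpr.

    Signed by default (negative = retrieval lower than reference); NaN where
    either input is invalid or the retrieval is below ``epsilon``.  Accepts
    TraitMap or plain arrays; grids must already match (regrid first).
    """
    def _values(obj):
        # TraitMap-like objects carry a valid_mask; otherwise a plain grid
        return obj.mean if hasattr(obj, "valid_mask") else obj

    g = np.asarray(_values(map_gpr), float)
    r = np.asarray(_values(map_ref), float)
    if g.shape != r.shape:
        raise ValueError(
            f"grid mismatch {g.shape} vs {r.shape}: regrid the reference first"
        )
    out = np.full(g.shape, np.nan)
    ok = np.isfinite(g) & np.isfinite(r) & (np.abs(g) > epsilon)
    for m in (map_gpr, map_ref):
        vm = getattr(m, "valid_mask", None)
        if vm is not None:
            ok &= vm
    out[ok] = 100.0 * (g[ok] - r[ok]) / g[ok]
    if not signed:
        out = np.abs(out)
    return out


def regrid(
    values: np.ndarray,
    target_shape: tuple,
    method: str = "nearest",
    valid: np.ndarray | None = None,
    min_valid_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Match a grid to a target shape by nearest-neighbour or block mean.

    ``nearest`` serves upsampling; ``mean_aggregate`` averages the valid
    source pixels inside each target cell and marks the cell invalid when
    fewer than ``min_valid_fraction`` of its contributors are valid.
    Returns (regridded values, validity mask).  Shapes must be related by
    integer factors (same-extent, north-up grids).
    """
    values = np.asarray(values, float)
    if valid is None:
        valid = np.isfinite(values)
    sh, sw = values.shape
    th, tw = target_shape
    if (sh, sw) == (th, tw):
        return values.copy(), valid.copy()
    if method == "nearest":
        rows = np.minimum((np.arange(th) * sh) // th, sh - 1)
        cols = np.minimum((np.arange(tw) * sw) // tw, sw - 1)
        out = values[np.ix_(rows, cols)]
        return out, valid[np.ix_(rows, cols)]
    if method != "mean_aggregate":
        raise ValueError(f"unknown regrid method {method!r}")
    if sh % th or sw % tw:
        raise ValueError("mean_aggregate needs integer aggregation factors")
    fh, fw = sh // th, sw // tw
    blocks = values.reshape(th, fh, tw, fw)
    vblocks = valid.reshape(th, fh, tw, fw)
    count = vblocks.sum(axis=(1, 3))
    total = np.where(vblocks, blocks, 0.0).sum(axis=(1, 3))
    with np.errstate(invalid="ignore"):
        out = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    ok = count >= min_valid_fraction * fh * fw
    out[~ok] = np.nan
    return out, ok
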