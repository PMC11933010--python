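"""2-D Gaussian receptive-field fits to 11 x 11 sparse-noise maps.

The model is an elliptical Gaussian with rotation,

    f(x, y) = A exp(-u^2 / 2B^2 - v^2 / 2C^2) + G,
    u = (x - E) cos D - (y - F) sin D,
    v = (x - E) sin D + (y - F) cos D,

fit by least squares with multi-start initialization (the map's top peaks
plus random perturbations).  RF size is the area of the half-maximum
ellipse, pi * 2 ln 2 * B * C; a fit is "clear" when its coefficient of
determination reaches 0.5.  Cluster summaries report the clear fraction,
size statistics, and RF coverage — the area of the union of half-maximum
ellipses — with clusters split into compact (< 900 deg^2) and full-field
coverage groups.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .config import (
    MONITOR_CENTER_DEG,
    RfConfig,
    SPARSE_GRID_N,
    SPARSE_SQUARE_DEG,
)

TWO_LN2 = 2.0 * np.log(2.0)
#: smallest permitted Gaussian width: keeps the half-maximum area at or
#: above one grid square (25 deg^2) for degenerate single-hot-square maps
MIN_WIDTH_DEG = float(np.sqrt(25.0 / (np.pi * TWO_LN2)))


@dataclass
class RfFit:
    A: float
    B: float
    C: float
    D: float
    E: float
    F: float
    G: float
    r2: float
    rfs: float
    clear: bool
    converged: bool = True


def grid_coordinates() -> tuple[np.ndarray, np.ndarray]:
    """Azimuth/elevation (deg) of the 11 x 11 square centers; index (0, 0)
    is the lower-nasal corner."""
    cx, cy = MONITOR_CENTER_DEG
    offs = (np.arange(SPARSE_GRID_N) - SPARSE_GRID_N // 2) * SPARSE_SQUARE_DEG
    az, el = np.meshgrid(cx + offs, cy + offs, indexing="ij")
    return az, el


def gauss2d(az: np.ndarray, el: np.ndarray, A: float, B: float, C: float,
            D: float, E: float, F: float, G: float) -> np.ndarray:
    u = (az - E) * np.cos(D) - (el - F) * np.sin(D)
    v = (az - E) * np.sin(D) + (el - F) * np.cos(D)
    return A * np.exp(-(u**2) / (2 * B**2) - (v**2) / (2 * C**2)) + G


def rf_size(fit: RfFit | None = None, B: float | None = None,
            C: float | None = None) -> float:
    """Half-maximum ellipse area: pi * 2 ln 2 * B * C (deg^2)."""
    if fit is not None:
        B, C = fit.B, fit.C
    if B is None or C is None or B <= 0 or C <= 0:
        raise ValueError("B and C must be positive")
    return float(np.pi * TWO_LN2 * B * C)


def fit_rf(map_grid: np.ndarray, config: RfConfig | None = None,
           seed: int = 0) -> RfFit:
    """Least-squares 2-D Gaussian fit of an 11 x 11 response map.

    Multi-start: the map's top-3 peaks plus randomly perturbed restarts;
    center bounded within 10 degrees of the grid, widths bounded below so
    the half-maximum area never collapses under one grid square.  If no
    start converges the fit is flagged (clear = False, NaN parameters).
    """
    if config is None:
        config = RfConfig()
    m = np.asarray(map_grid, dtype=float)
    if m.shape != (SPARSE_GRID_N, SPARSE_GRID_N) or not np.all(np.isfinite(m)):
        raise ValueError("map must be a finite 11 x 11 array")
    az, el = grid_coordinates()
    rng = np.random.default_rng(seed)
    flat = m.ravel()
    order = np.argsort(flat)[::-1]
    span = SPARSE_GRID_N // 2 * SPARSE_SQUARE_DEG
    lo = [0.0, MIN_WIDTH_DEG, MIN_WIDTH_DEG, -np.pi,
          MONITOR_CENTER_DEG[0] - span - 10.0,
          MONITOR_CENTER_DEG[1] - span - 10.0, -np.inf]
    hi = [np.inf, 12 * SPARSE_SQUARE_DEG, 12 * SPARSE_SQUARE_DEG, np.pi,
          MONITOR_CENTER_DEG[0] + span + 10.0,
          MONITOR_CENTER_DEG[1] + span + 10.0, np.inf]

    def residuals(p: np.ndarray) -> np.ndarray:
        return gauss2d(az, el, *p).ravel() - flat

    starts = []
    amp0 = max(flat.max() - flat.min(), 1e-6)
    for k in range(min(3, len(order))):
        i, j = np.unravel_index(order[k], m.shape)
        starts.append([amp0, 6.0, 6.0, 0.0, az[i, j], el[i, j], flat.min()])
    while len(starts) < config.n_starts:
        base = starts[len(starts) % 3].copy()
        base[1] = rng.uniform(MIN_WIDTH_DEG + 0.5, 15.0)
        base[2] = rng.uniform(MIN_WIDTH_DEG + 0.5, 15.0)
        base[3] = rng.uniform(-np.pi / 2, np.pi / 2)
        base[4] += rng.normal(0, 5.0)
        base[5] += rng.normal(0, 5.0)
        starts.append(base)

    ss_tot = float(((flat - flat.mean()) ** 2).sum())
    best = None
    for p0 in starts:
        p0 = np.clip(p0, lo, hi)
        try:
            sol = least_squares(residuals, p0, bounds=(lo, hi),
                                max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        # an excellent fit cannot be improved enough to change any
        # downstream decision; skip the remaining restarts
        if ss_tot > 0 and 1.0 - 2.0 * best.cost / ss_tot >= 0.995:
            break
    if best is None:
        return RfFit(*([np.nan] * 7), r2=np.nan, rfs=np.nan, clear=False,
                     converged=False)
    A, B, C, D, E, F, G = best.x
    ss_res = float((best.fun**2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return RfFit(A=float(A), B=float(B), C=float(C), D=float(D), E=float(E),
                 F=float(F), G=float(G), r2=float(r2),
                 rfs=rf_size(B=B, C=C), clear=bool(r2 >= config.clear_r2))


def sparse_noise_maps(dff_sparse: np.ndarray, schedule: dict) -> np.ndarray:
    """(n_neuron, 11, 11) response maps from the sparse-noise block.

    The block's time axis is the presentation sequence (baseline samples,
    then 121 black squares, then 121 white squares); ON and OFF sub-maps
    are combined by per-square maximum of the trial means before fitting.
    """
    tm = np.asarray(dff_sparse, dtype=float).mean(axis=2)
    pre = int(schedule.get("pre_samples", 0))
    n_sq = int(schedule.get("n_squares", SPARSE_GRID_N**2))
    black = tm[:, pre:pre + n_sq]
    white = tm[:, pre + n_sq:pre + 2 * n_sq]
    combined = np.maximum(black, white)
    return combined.reshape(-1, SPARSE_GRID_N, SPARSE_GRID_N)


def fit_population(maps: np.ndarray, config: RfConfig | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Fit every neuron's map; one row per neuron."""
    rows = []
    for i in range(maps.shape[0]):
        fit = fit_rf(maps[i], config=config, seed=seed + i)
        rows.append({
            "roi_id": i, "A": fit.A, "B": fit.B, "C": fit.C, "D": fit.D,
            "E": fit.E, "F": fit.F, "G": fit.G, "r2": fit.r2,
            "rfs": fit.rfs, "clear": fit.clear,
        })
    return pd.DataFrame(rows)


def coverage_area(fits: pd.DataFrame,
                  resolution: float = 0.5) -> float:
    """Area (deg^2) of the union of half-maximum ellipses of clear fits,
    by rasterization at ``resolution`` degrees."""
    clear = fits[fits.clear]
    if clear.empty:
        return np.nan
    span = SPARSE_GRID_N // 2 * SPARSE_SQUARE_DEG + 20.0
    cx, cy = MONITOR_CENTER_DEG
    xs = np.arange(cx - span, cx + span, resolution)
    ys = np.arange(cy - span, cy + span, resolution)
    gx, gy = np.meshgrid(xs, ys)
    mask = np.zeros(gx.shape, dtype=bool)
    for row in clear.itertuples():
        u = (gx - row.E) * np.cos(row.D) - (gy - row.F) * np.sin(row.D)
        v = (gx - row.E) * np.sin(row.D) + (gy - row.F) * np.cos(row.D)
        mask |= (u**2 / (2 * row.B**2) + v**2 / (2 * row.C**2)) <= np.log(2.0)
    return float(mask.sum() * resolution**2)


def cluster_rf_summary(fits: pd.DataFrame, labels: np.ndarray,
                       config: RfConfig | None = None) -> pd.DataFrame:
    """Per-cluster clear fraction, size statistics, RF coverage and
    coverage group (compact vs full-field at the 900 deg^2 split)."""
    if config is None:
        config = RfConfig()
    labels = np.asarray(labels)
    if len(labels) != len(fits):
        raise ValueError("labels must align with fits")
    rows = []
    for c in np.unique(labels):
        sub = fits[labels == c]
        clear = sub[sub.clear]
        cov = coverage_area(sub, config.raster_resolution_deg) \
            if not clear.empty else np.nan
        rows.append({
            "cluster": int(c),
            "n": len(sub),
            "clear_fraction": float(sub.clear.mean()) if len(sub) else np.nan,
            "rfs_mean": float(clear.rfs.mean()) if not clear.empty else np.nan,
            "rfs_sd": float(clear.rfs.std(ddof=0)) if not clear.empty else np.nan,
            "coverage_deg2": cov,
            "coverage_group": (
                "undefined" if not np.isfinite(cov)
                else "compact" if cov < config.coverage_threshold_deg2
                else "full_field"
            ),
        })
    return pd.DataFrame(rows)
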