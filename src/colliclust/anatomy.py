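"""Anatomical patchiness: density recovery profile (DRP), half-peak
radius, and depth/genotype group breakdowns.

The DRP is the probability of finding a same-cluster cell per unit area as
a function of distance from a reference cell of that cluster:

    rho(r) = N(r) / A(r)

where N(r) dr is the mean same-cluster neighbor count per annulus over
reference cells and A(r) dr is the mean annulus area clipped to the field
of view, taken as the convex hull of all recorded neurons.  Annulus-hull
intersection areas are estimated by seeded Monte-Carlo sampling.  Only
fields with more than 5 neurons are analyzed.

The half-peak radius summarizes patch size: the smallest radius at or
beyond the profile's peak where density falls below half the peak density
(for a compact patch this is the radius at which the patch density has
decayed to half).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from scipy.spatial import ConvexHull, QhullError

from .config import AnatomyConfig


@dataclass
class DrpProfile:
    radii: np.ndarray  # bin edges (um)
    rho: np.ndarray  # density per annulus (cells / um^2)
    n_per_annulus: np.ndarray  # mean neighbor count N(r) dr
    area_per_annulus: np.ndarray  # mean clipped annulus area A(r) dr
    n_reference_cells: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.radii[:-1] + self.radii[1:])


def _hull_path(positions: np.ndarray) -> tuple[MplPath, ConvexHull]:
    try:
        hull = ConvexHull(positions)
    except QhullError as err:
        raise ValueError("degenerate field: convex hull undefined "
                         "(collinear positions?)") from err
    return MplPath(positions[hull.vertices]), hull


def drp(positions: np.ndarray, labels: np.ndarray, cluster_id: int,
        bin_width: float = 20.0, max_radius: float = 300.0,
        n_mc: int = 10_000, seed: int = 0) -> DrpProfile:
    """Density recovery profile of one cluster within the recorded field.

    ``positions`` (n, 2) in um covers *all* neurons in the field (the
    convex hull is built from everyone); reference cells are the members
    of ``cluster_id``.  Requires > 5 neurons in the field.
    """
    positions = np.asarray(positions, dtype=float)
    labels = np.asarray(labels)
    if positions.shape[0] <= 5:
        raise ValueError("DRP requires more than 5 neurons in the field")
    hull_path, _ = _hull_path(positions)
    members = positions[labels == cluster_id]
    n_ref = len(members)
    edges = np.arange(0.0, max_radius + bin_width, bin_width)
    n_bins = len(edges) - 1
    counts = np.zeros(n_bins)
    if n_ref >= 1:
        diff = members[:, None, :] - members[None, :, :]
        dist = np.hypot(diff[..., 0], diff[..., 1])
        iu = ~np.eye(n_ref, dtype=bool)
        d = dist[iu]
        counts, _ = np.histogram(d, bins=edges)
        counts = counts / n_ref  # mean neighbor count per reference cell
    # Monte-Carlo annulus area clipped to the hull, averaged over reference
    # cells: sample points uniformly by area within each annulus around
    # randomly chosen reference cells
    rng = np.random.default_rng(seed)
    areas = np.zeros(n_bins)
    for b in range(n_bins):
        r0, r1 = edges[b], edges[b + 1]
        full_area = np.pi * (r1**2 - r0**2)
        if n_ref == 0:
            areas[b] = full_area
            continue
        refs = members[rng.integers(0, n_ref, n_mc)]
        rr = np.sqrt(rng.uniform(r0**2, r1**2, n_mc))
        th = rng.uniform(0.0, 2 * np.pi, n_mc)
        pts = refs + np.column_stack([rr * np.cos(th), rr * np.sin(th)])
        frac = hull_path.contains_points(pts).mean()
        areas[b] = full_area * frac
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(areas > 0, counts / np.where(areas > 0, areas, 1.0),
                       np.nan)
    return DrpProfile(radii=edges, rho=rho, n_per_annulus=counts,
                      area_per_annulus=areas, n_reference_cells=n_ref)


def half_peak_radius(profile: DrpProfile | None = None,
                     rho: np.ndarray | None = None,
                     bin_centers: np.ndarray | None = None) -> float:
    """Smallest radius at or beyond the density peak where the density
    falls below half the peak density (NaN-flagged for flat or empty
    profiles).

    For a compact patch (monotonically decaying profile) this is the
    radius at which the patch density halves; a profile that never decays
    below half its peak within range is flagged.
    """
    if profile is not None:
        rho = profile.rho
        bin_centers = profile.bin_centers
    rho = np.asarray(rho, dtype=float)
    finite = np.isfinite(rho)
    if not finite.any() or np.nanmax(rho) <= 0:
        return np.nan
    peak_idx = int(np.nanargmax(rho))
    half = rho[peak_idx] / 2.0
    for i in range(peak_idx, len(rho)):
        if np.isfinite(rho[i]) and rho[i] < half:
            return float(bin_centers[i])
    return np.nan


def drp_all_clusters(positions: np.ndarray, labels: np.ndarray,
                     config: AnatomyConfig | None = None) -> pd.DataFrame:
    """DRP summary table (one row per cluster); clusters with a single
    member get NaN half-peak radii."""
    if config is None:
        config = AnatomyConfig()
    rows = []
    for c in np.unique(labels):
        n_ref = int(np.count_nonzero(labels == c))
        if n_ref < 2:
            rows.append({"cluster": int(c), "n": n_ref,
                         "half_peak_radius_um": np.nan,
                         "peak_density": np.nan})
            continue
        prof = drp(positions, labels, c, bin_width=config.bin_width_um,
                   max_radius=config.max_radius_um, n_mc=config.n_mc,
                   seed=config.seed)
        rows.append({
            "cluster": int(c), "n": n_ref,
            "half_peak_radius_um": half_peak_radius(prof),
            "peak_density": float(np.nanmax(prof.rho)),
        })
    return pd.DataFrame(rows)


def group_breakdown(labels: np.ndarray, depth: np.ndarray,
                    genotype: np.ndarray, traces: np.ndarray,
                    depth_edges: tuple[float, ...] = (0.0, 100.0, 400.0)
                    ) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Mean population trace and cluster percentages per depth bin and
    genotype.

    Returns ``(mean_traces, percentages)``: mean trace per group label,
    and a table whose rows (one per group) give the percentage of each
    cluster within that group (rows sum to 100).  Empty groups are
    omitted with a warning.
    """
    labels = np.asarray(labels)
    depth = np.asarray(depth, dtype=float)
    genotype = np.asarray(genotype)
    clusters = np.unique(labels)
    groups: dict[str, np.ndarray] = {}
    for i in range(len(depth_edges) - 1):
        lo, hi = depth_edges[i], depth_edges[i + 1]
        groups[f"depth_{lo:g}-{hi:g}um"] = (depth >= lo) & (depth < hi)
    for g in np.unique(genotype):
        groups[f"genotype_{g}"] = genotype == g
    mean_traces: dict[str, np.ndarray] = {}
    rows = []
    for name, mask in groups.items():
        if not mask.any():
            import warnings

            warnings.warn(f"empty group {name!r} omitted")
            continue
        mean_traces[name] = traces[mask].mean(axis=0)
        frac = np.array([
            np.count_nonzero(labels[mask] == c) for c in clusters
        ], dtype=float)
        frac = 100.0 * frac / frac.sum()
        rows.append({"group": name,
                     **{f"cluster_{int(c)}": f for c, f in zip(clusters, frac)}})
    return mean_traces, pd.DataFrame(rows)
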