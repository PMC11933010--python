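"""Synthetic two-photon session generator with planted ground truth.

Emulates a superficial-superior-colliculus population recording: four
natural-movie stimuli with ~1/f^2 spatial statistics, a six-protocol
artificial battery (moving bar, looming, sparse noise, chirp, color, size
tuning), GCaMP-like single-exponential calcium kinetics at 4.8 Hz, neuropil
contamination, and spatially patchy anatomy in a 600 x 600 um field.

Every neuron carries its generating parameters (cluster identity, RF,
tuning indices, kinetics, position) so each analysis stage downstream can
be checked against planted truth.

Movie-response cluster structure is planted at the cluster level: each
cluster owns a template trace built from an RF-weighted, kernel-convolved
movie drive, and member neurons are template + smooth jitter whose scale is
set by ``cluster_separation``.  Per-neuron RF geometry drives the
sparse-noise map and battery responses.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, map_coordinates

from .config import (
    FIELD_SIZE_UM,
    MONITOR_CENTER_DEG,
    MONITOR_SPAN_DEG,
    N_BAR_DIRECTIONS,
    SIZE_DIAMETERS_DEG,
    SPARSE_GRID_N,
    SPARSE_SQUARE_DEG,
    SessionConfig,
)

MOVIE_NAMES = ("baby_owl", "running_cat", "foraging", "optical_flow")


@dataclass
class MovieStimulus:
    """A natural-movie stimulus: luminance frames in [0, 1]."""

    frames: np.ndarray  # (height, width, time)
    frame_rate: float
    name: str
    degrees_per_pixel: float

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[2] < 2:
            raise ValueError("movie frames must be (h, w, t) with t >= 2")
        if self.frames.min() < -1e-12 or self.frames.max() > 1 + 1e-12:
            raise ValueError("luminance values must lie in [0, 1]")


@dataclass
class GroundTruthNeuron:
    cluster_id: int
    rf_center: tuple[float, float]  # (azimuth, elevation) deg
    rf_sigma: tuple[float, float]  # (B, C) deg
    rf_angle: float  # rad
    pref_direction: float  # rad
    dsi_true: float
    osi_true: float
    size_pref: float  # deg
    kinetics_tau: float  # s
    transientness: float
    position: tuple[float, float]  # (x, y) um
    depth: float  # um
    genotype: str
    # extended truth used by the battery simulator and recovery tests
    amplitude: float = 1.0
    diameter: float = 15.0
    functional_type: int = 0
    hi_true: float = 0.0
    lsi_true: float = 0.0
    csi_true: float = 0.0
    bgi_true: float = 0.0
    fsi_true: float = 0.0
    rafm_true: float = 0.0
    raam_true: float = 0.0


@dataclass
class StimulusBlock:
    """Raw traces for one stimulus: (n_roi, n_time, n_rep), plus timing."""

    name: str
    traces: np.ndarray
    neuropil: np.ndarray
    frame_rate: float
    schedule: dict = field(default_factory=dict)


@dataclass
class Session:
    blocks: dict[str, StimulusBlock]
    ground_truth: pd.DataFrame
    config: SessionConfig
    movies: list[MovieStimulus] = field(default_factory=list)

    @property
    def n_rois(self) -> int:
        return len(self.ground_truth)

    def block_names(self) -> list[str]:
        return list(self.blocks)


# ---------------------------------------------------------------------------
# movies

def _pink_texture(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random texture whose power spectrum falls as 1/f^2."""
    fx = np.fft.fftfreq(n)
    radius = np.hypot(fx[None, :], fx[:, None])
    radius[0, 0] = 1.0
    amplitude = 1.0 / radius  # power ~ amplitude^2 ~ 1/f^2
    amplitude[0, 0] = 0.0
    phase = rng.uniform(0.0, 2.0 * np.pi, size=(n, n))
    spectrum = amplitude * np.exp(1j * phase)
    tex = np.real(np.fft.ifft2(spectrum))
    return tex


def _crop(tex: np.ndarray, y0: float, x0: float, h: int, w: int) -> np.ndarray:
    n = tex.shape[0]
    ys = (np.arange(h) + int(round(y0))) % n
    xs = (np.arange(w) + int(round(x0))) % n
    return tex[np.ix_(ys, xs)]


def generate_movies(config: SessionConfig) -> list[MovieStimulus]:
    """Four natural-movie surrogates with distinct spatiotemporal content.

    All are windows into large 1/f^2 textures: a slow drift with luminance
    modulation ("baby_owl"), a fast horizontal translation ("running_cat"),
    a jittery random walk ("foraging"), and an expanding zoom
    ("optical_flow").  Deterministic under ``config.seed``.
    """
    if config.movie_height_px < 8 or config.movie_width_px < 8:
        raise ValueError("movie dimensions too small")
    rng = np.random.default_rng(config.seed)
    h, w = config.movie_height_px, config.movie_width_px
    n_frames = int(round(config.movie_duration_s * config.frame_rate))
    if n_frames < 2:
        raise ValueError("movie must have at least 2 frames")
    tex_n = 4 * max(h, w)
    deg_per_px = MONITOR_SPAN_DEG[0] / w
    movies = []
    for name in MOVIE_NAMES:
        tex = _pink_texture(rng, tex_n)
        frames = np.empty((h, w, n_frames))
        if name == "baby_owl":
            lum = 1.0 + 0.3 * np.sin(2 * np.pi * np.arange(n_frames) / n_frames)
            for t in range(n_frames):
                frames[:, :, t] = _crop(tex, 0.7 * t, 0.7 * t, h, w) * lum[t]
        elif name == "running_cat":
            for t in range(n_frames):
                frames[:, :, t] = _crop(tex, 0.0, 3.2 * t, h, w)
        elif name == "foraging":
            walk = np.cumsum(rng.integers(-3, 4, size=(n_frames, 2)), axis=0)
            for t in range(n_frames):
                frames[:, :, t] = _crop(tex, walk[t, 0], walk[t, 1], h, w)
        else:  # optical_flow: expanding zoom about the texture center
            yy, xx = np.mgrid[0:h, 0:w].astype(float)
            cy, cx = tex_n / 2.0, tex_n / 2.0
            for t in range(n_frames):
                # expanding flow: gentle zoom cycle so the magnification
                # stays near 1 and the 1/f^2 spatial spectrum is preserved
                scale = 0.85 + 0.45 * (t % (n_frames // 2)) / (n_frames // 2)
                coords = np.array(
                    [cy + (yy - h / 2.0) / scale, cx + (xx - w / 2.0) / scale]
                )
                frames[:, :, t] = map_coordinates(tex, coords, order=0, mode="wrap")
        lo, hi = frames.min(), frames.max()
        frames = (frames - lo) / (hi - lo)
        movies.append(
            MovieStimulus(frames=frames, frame_rate=config.frame_rate,
                          name=name, degrees_per_pixel=deg_per_px)
        )
    return movies


def movie_stats(movie: MovieStimulus) -> pd.DataFrame:
    """Per-frame brightness, RMS contrast and motion energy.

    Brightness is the spatial mean luminance; RMS contrast is spatial
    SD / spatial mean (NaN-flagged where the mean is zero); motion energy
    is the mean squared inter-frame luminance difference (length T-1,
    padded with NaN at the first frame so the table has one row per frame).
    """
    frames = movie.frames
    if frames.shape[2] < 2:
        raise ValueError("movie_stats needs >= 2 frames")
    mean = frames.mean(axis=(0, 1))
    sd = frames.std(axis=(0, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        contrast = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
    if np.any(mean == 0):
        warnings.warn("uniform zero frame: RMS contrast undefined, flagged NaN")
    diff = np.diff(frames, axis=2)
    motion = (diff**2).mean(axis=(0, 1))
    return pd.DataFrame(
        {
            "frame": np.arange(frames.shape[2]),
            "brightness": mean,
            "rms_contrast": contrast,
            "motion_energy": np.concatenate([[np.nan], motion]),
        }
    )


# ---------------------------------------------------------------------------
# population

_GENOTYPES = ("wild-type", "Vglut2", "Vgat", "Tac1", "Rorb", "Ntsr1")


def _monitor_bounds() -> tuple[float, float, float, float]:
    cx, cy = MONITOR_CENTER_DEG
    sx, sy = MONITOR_SPAN_DEG
    return cx - sx / 2, cx + sx / 2, cy - sy / 2, cy + sy / 2


def sparse_grid_centers() -> np.ndarray:
    """(121, 2) az/el centers of the 11 x 11 sparse-noise squares."""
    cx, cy = MONITOR_CENTER_DEG
    offs = (np.arange(SPARSE_GRID_N) - SPARSE_GRID_N // 2) * SPARSE_SQUARE_DEG
    az, el = np.meshgrid(cx + offs, cy + offs, indexing="ij")
    return np.column_stack([az.ravel(), el.ravel()])


def generate_population(config: SessionConfig) -> list[GroundTruthNeuron]:
    """Plant a clustered population with ground-truth tuning and anatomy.

    The first ``n_compact_clusters`` clusters have compact RF coverage
    (centers within an 8-degree disc, area << 900 deg^2) and compact
    anatomical patches whose same-cluster density halves at
    ``patch_radius_um``; the remaining clusters span the monitor and the
    field.  ``n_unresponsive`` extra ROIs (cluster_id = -1, zero response
    gain) and a small fraction of out-of-size ROIs exercise the gating
    stage.
    """
    rng = np.random.default_rng(config.seed + 1)
    K = config.n_clusters
    az_lo, az_hi, el_lo, el_hi = _monitor_bounds()
    grid_half = SPARSE_GRID_N // 2 * SPARSE_SQUARE_DEG  # sparse grid half-span
    cx, cy = MONITOR_CENTER_DEG
    patch_sigma = config.patch_radius_um / (2.0 * np.sqrt(np.log(2.0)))

    neurons: list[GroundTruthNeuron] = []
    # cluster-level draws
    cl_rf_center = np.column_stack(
        [rng.uniform(cx - grid_half + 8, cx + grid_half - 8, K),
         rng.uniform(cy - grid_half + 8, cy + grid_half - 8, K)]
    )
    cl_patch_center = rng.uniform(120.0, FIELD_SIZE_UM - 120.0, (K, 2))
    cl_dsi = rng.uniform(0.05, 0.40, K)
    cl_osi = rng.uniform(0.05, 0.40, K)
    cl_dir = rng.uniform(0, 2 * np.pi, K)
    cl_size = rng.choice(SIZE_DIAMETERS_DEG, K)
    cl_tau = rng.uniform(0.3, 1.2, K)
    cl_trans = rng.uniform(0.0, 1.0, K)
    cl_geno_p = rng.dirichlet(np.full(len(_GENOTYPES), 0.8), size=K)
    type_a = rng.integers(0, config.n_functional_types, K)
    type_b = (type_a + 1 + rng.integers(0, config.n_functional_types - 1, K)) % \
        config.n_functional_types

    for c in range(K):
        compact = c < config.n_compact_clusters
        n = config.neurons_per_cluster
        for _ in range(n):
            if compact:
                while True:
                    off = rng.normal(0.0, 3.0, 2)
                    if np.hypot(*off) < 8.0:
                        break
                center = cl_rf_center[c] + off
                pos = cl_patch_center[c] + rng.normal(0.0, patch_sigma, 2)
                pos = np.clip(pos, 0.0, FIELD_SIZE_UM)
                depth = rng.uniform(20.0, 100.0)
            else:
                center = np.array(
                    [rng.uniform(cx - grid_half, cx + grid_half),
                     rng.uniform(cy - grid_half, cy + grid_half)]
                )
                pos = rng.uniform(0.0, FIELD_SIZE_UM, 2)
                depth = rng.uniform(20.0, 300.0)
            dsi = float(np.clip(rng.normal(cl_dsi[c], 0.06), 0.01, 0.49))
            osi = float(np.clip(rng.normal(cl_osi[c], 0.06), 0.01, 0.99 - dsi))
            # keep dsi + osi <= 0.5 so the cosine tuning curve is nonnegative
            if dsi + osi > 0.5:
                osi = 0.5 - dsi
            u = rng.uniform()
            if u < config.out_of_bounds_fraction:
                diameter = rng.uniform(21.0, 26.0)
            else:
                diameter = float(np.clip(rng.normal(15.0, 2.0), 10.5, 19.5))
            t_u = rng.uniform()
            ftype = int(type_a[c] if t_u < 0.55 else
                        type_b[c] if t_u < 0.80 else
                        rng.integers(0, config.n_functional_types))
            neurons.append(GroundTruthNeuron(
                cluster_id=c,
                rf_center=(float(center[0]), float(center[1])),
                rf_sigma=(float(rng.uniform(3.0, 6.0)),
                          float(rng.uniform(3.0, 6.0))),
                rf_angle=float(rng.uniform(0.0, np.pi)),
                pref_direction=float((cl_dir[c] + rng.normal(0, 0.3)) % (2 * np.pi)),
                dsi_true=dsi,
                osi_true=osi,
                size_pref=float(cl_size[c]),
                kinetics_tau=float(np.clip(rng.normal(cl_tau[c], 0.05), 0.1, 2.0)),
                transientness=float(np.clip(rng.normal(cl_trans[c], 0.1), 0.0, 1.0)),
                position=(float(pos[0]), float(pos[1])),
                depth=float(depth),
                genotype=str(rng.choice(_GENOTYPES, p=cl_geno_p[c])),
                amplitude=float(np.clip(rng.lognormal(0.0, 0.3), 0.5, 2.5)),
                diameter=diameter,
                functional_type=ftype,
                hi_true=float(rng.uniform(0.0, 0.6)),
                lsi_true=float(rng.uniform(-0.3, 0.8)),
                csi_true=float(rng.uniform(-0.8, 0.8)),
                bgi_true=float(rng.uniform(-0.6, 0.6)),
                fsi_true=float(rng.uniform(-0.6, 0.6)),
                rafm_true=float(rng.uniform(0.0, 0.4)),
                raam_true=float(rng.uniform(0.0, 0.4)),
            ))
    for _ in range(config.n_unresponsive):
        neurons.append(GroundTruthNeuron(
            cluster_id=-1,
            rf_center=(float(rng.uniform(az_lo, az_hi)),
                       float(rng.uniform(el_lo, el_hi))),
            rf_sigma=(4.0, 4.0), rf_angle=0.0,
            pref_direction=0.0, dsi_true=0.0, osi_true=0.0,
            size_pref=8.0, kinetics_tau=0.5, transientness=0.5,
            position=(float(rng.uniform(0, FIELD_SIZE_UM)),
                      float(rng.uniform(0, FIELD_SIZE_UM))),
            depth=float(rng.uniform(20, 300)),
            genotype=str(rng.choice(_GENOTYPES)),
            amplitude=0.0,
            diameter=float(np.clip(rng.normal(15.0, 2.0), 10.5, 19.5)),
            functional_type=int(rng.integers(0, config.n_functional_types)),
        ))
    return neurons


def population_frame(neurons: Sequence[GroundTruthNeuron]) -> pd.DataFrame:
    rows = []
    for i, nrn in enumerate(neurons):
        rows.append({
            "roi_id": i, "cluster_id": nrn.cluster_id,
            "rf_az": nrn.rf_center[0], "rf_el": nrn.rf_center[1],
            "rf_b": nrn.rf_sigma[0], "rf_c": nrn.rf_sigma[1],
            "rf_angle": nrn.rf_angle, "pref_direction": nrn.pref_direction,
            "dsi_true": nrn.dsi_true, "osi_true": nrn.osi_true,
            "size_pref": nrn.size_pref, "kinetics_tau": nrn.kinetics_tau,
            "transientness": nrn.transientness,
            "x_um": nrn.position[0], "y_um": nrn.position[1],
            "depth_um": nrn.depth, "genotype": nrn.genotype,
            "amplitude": nrn.amplitude, "diameter_um": nrn.diameter,
            "functional_type": nrn.functional_type,
            "hi_true": nrn.hi_true, "lsi_true": nrn.lsi_true,
            "csi_true": nrn.csi_true, "bgi_true": nrn.bgi_true,
            "fsi_true": nrn.fsi_true, "rafm_true": nrn.rafm_true,
            "raam_true": nrn.raam_true,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# battery schedule

def default_battery(frame_rate: float) -> dict:
    """Timing metadata for the six artificial protocols (seconds).

    Every block starts with a 2-s gray baseline used downstream for F0.
    """
    pre = 2.0
    bar_segs = []
    t = pre
    for k in range(N_BAR_DIRECTIONS):
        bar_segs.append({"name": f"dir_{k}", "t0": t, "t1": t + 2.5,
                         "direction": 2 * np.pi * k / N_BAR_DIRECTIONS})
        t += 4.0  # 2.5-s sweep + 1.5-s gray gap (lets calcium decay)
    bar = {"kind": "bar", "pre": (0.0, pre), "segments": bar_segs, "duration": t}

    loom_segs = [
        {"name": "expand", "t0": pre, "t1": pre + 1.22},
        {"name": "gray", "t0": pre + 1.22, "t1": pre + 3.22},
        {"name": "recede", "t0": pre + 3.22, "t1": pre + 4.19},
    ]
    loom = {"kind": "looming", "pre": (0.0, pre), "segments": loom_segs,
            "duration": pre + 4.19 + 1.0}

    chirp_layout = [("black1", 3), ("white", 3), ("black2", 3), ("gray1", 3),
                    ("fm", 8), ("gray2", 3), ("am", 8), ("gray3", 3),
                    ("black3", 3)]
    t = pre
    chirp_segs = []
    for name, dur in chirp_layout:
        chirp_segs.append({"name": name, "t0": t, "t1": t + dur})
        t += dur
    chirp = {"kind": "chirp", "pre": (0.0, pre), "segments": chirp_segs,
             "duration": t}

    color_layout = [("black1", 1), ("blue", 3), ("black2", 4), ("green", 3),
                    ("black3", 3)]
    t = pre
    color_segs = []
    for name, dur in color_layout:
        color_segs.append({"name": name, "t0": t, "t1": t + dur})
        t += dur
    color = {"kind": "color", "pre": (0.0, pre), "segments": color_segs,
             "duration": t}

    t = pre
    size_segs = []
    for diam in SIZE_DIAMETERS_DEG:
        size_segs.append({"name": f"size_{diam:g}", "t0": t, "t1": t + 2.0,
                          "diameter": diam})
        size_segs.append({"name": f"gray_{diam:g}", "t0": t + 2.0, "t1": t + 4.0})
        t += 4.0
    size = {"kind": "size", "pre": (0.0, pre), "segments": size_segs,
            "duration": t}

    sparse = {"kind": "sparse_noise", "pre_samples": 5,
              "n_squares": SPARSE_GRID_N**2, "polarities": ["black", "white"],
              "grid_n": SPARSE_GRID_N, "square_deg": SPARSE_SQUARE_DEG}
    return {"bar": bar, "looming": loom, "chirp": chirp, "color": color,
            "size": size, "sparse_noise": sparse}


# ---------------------------------------------------------------------------
# simulation helpers

def calcium_kernel(tau: float, frame_rate: float) -> np.ndarray:
    """Single-exponential decay kernel, unit peak."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    n = max(2, int(round(5.0 * tau * frame_rate)))
    return np.exp(-np.arange(n) / (tau * frame_rate))


def _convolve(drive: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return np.convolve(drive, kernel)[: drive.shape[0]]


def _convolve_population(drive: np.ndarray, taus: np.ndarray,
                         frame_rate: float, n_bins: int = 8) -> np.ndarray:
    """Convolve each row with a calcium kernel; neurons are binned into
    ``n_bins`` tau groups so the convolution stays vectorized."""
    from scipy.signal import fftconvolve

    out = np.empty_like(drive)
    order = np.argsort(taus)
    edges = np.linspace(0, len(order), n_bins + 1).astype(int)
    for b in range(n_bins):
        idx = order[edges[b]:edges[b + 1]]
        if len(idx) == 0:
            continue
        kernel = calcium_kernel(float(np.mean(taus[idx])), frame_rate)
        out[idx] = fftconvolve(drive[idx], kernel[None, :], axes=1)[
            :, : drive.shape[1]]
    return out


def direction_tuning(dsi: float, osi: float, pref: float,
                     directions: np.ndarray) -> np.ndarray:
    """Nonnegative tuning curve whose vector-sum DSI/OSI equal the planted
    values exactly on an even direction grid.

    Uses 1 + 2*dsi*cos(th - pref) + 2*osi*cos(2(th - pref)) (exact for
    dsi + osi <= 1/2); a fully selective neuron (dsi ~ 1) degenerates to a
    single response at the grid direction closest to ``pref``.
    """
    if dsi >= 0.95:
        resp = np.zeros_like(directions)
        resp[np.argmin(np.abs(np.angle(np.exp(1j * (directions - pref)))))] = 1.0
        return resp
    resp = 1.0 + 2 * dsi * np.cos(directions - pref) \
        + 2 * osi * np.cos(2 * (directions - pref))
    return np.clip(resp, 0.0, None) / 2.0


def size_tuning(size_pref: float, diameters: np.ndarray) -> np.ndarray:
    return np.exp(-((np.log2(diameters) - np.log2(size_pref)) ** 2) / 2.0)


def rf_weight(az: np.ndarray, el: np.ndarray, center: tuple[float, float],
              sigma: tuple[float, float], angle: float) -> np.ndarray:
    """Elliptical Gaussian RF profile (unit peak) at query points."""
    dx, dy = az - center[0], el - center[1]
    u = dx * np.cos(angle) - dy * np.sin(angle)
    v = dx * np.sin(angle) + dy * np.cos(angle)
    return np.exp(-(u**2) / (2 * sigma[0] ** 2) - (v**2) / (2 * sigma[1] ** 2))


def _bump(n_t: int, t0: int, t1: int, frame_rate: float) -> np.ndarray:
    """Unit-peak Gaussian bump centered in [t0, t1) (sample indices)."""
    t = np.arange(n_t)
    mid = 0.5 * (t0 + t1)
    width = max(1.0, 0.15 * (t1 - t0))
    return np.exp(-((t - mid) ** 2) / (2 * width**2))


def _seg_samples(seg: dict, frame_rate: float) -> tuple[int, int]:
    return int(round(seg["t0"] * frame_rate)), int(round(seg["t1"] * frame_rate))


# ---------------------------------------------------------------------------
# cluster movie templates

def cluster_movie_templates(population: Sequence[GroundTruthNeuron],
                            movies: list[MovieStimulus],
                            config: SessionConfig) -> np.ndarray:
    """(K, T_total) templates: RF-weighted movie drive per planted cluster,
    rectified, transientness-mixed, kernel-convolved and gain-modulated.
    """
    rng = np.random.default_rng(config.seed + 2)
    K = config.n_clusters
    df = population_frame(list(population))
    h, w, _ = movies[0].frames.shape
    dpp = movies[0].degrees_per_pixel
    az0 = MONITOR_CENTER_DEG[0] - MONITOR_SPAN_DEG[0] / 2
    el0 = MONITOR_CENTER_DEG[1] - MONITOR_SPAN_DEG[1] / 2
    az = az0 + (np.arange(w) + 0.5) * dpp
    el = el0 + (np.arange(h) + 0.5) * (MONITOR_SPAN_DEG[1] / h)
    azg, elg = np.meshgrid(az, el)

    gains = rng.uniform(0.2, 1.0, size=(K, len(movies)))
    # a few clusters strongly prefer one movie (movie-selective clusters)
    for c in range(min(4, K)):
        gains[c] = 0.15
        gains[c, c % len(movies)] = 1.0

    # gain- and transientness-independent convolved drive components:
    # the calcium convolution is linear, so the sustained and transient
    # parts can be mixed after convolving each once per cluster
    conv_s, conv_d = [], []
    trans_mix = np.empty(K)
    for c in range(K):
        sub = df[df.cluster_id == c]
        center = (sub.rf_az.mean(), sub.rf_el.mean())
        sigma = (max(sub.rf_b.mean(), 4.0), max(sub.rf_c.mean(), 4.0))
        wmap = rf_weight(azg, elg, center, sigma, 0.0)
        wmap /= wmap.sum()
        kernel = calcium_kernel(sub.kinetics_tau.mean(), config.frame_rate)
        trans_mix[c] = sub.transientness.mean()
        ss, dd = [], []
        for movie in movies:
            s = np.einsum("hw,hwt->t", wmap, movie.frames)
            s = np.clip(s - np.median(s), 0.0, None)
            d = np.clip(np.diff(s, prepend=s[0]), 0.0, None)
            for arr in (s, d):
                peak = arr.max()
                if peak > 0:
                    arr /= peak
            ss.append(_convolve(s, kernel))
            dd.append(_convolve(d, kernel))
        conv_s.append(ss)
        conv_d.append(dd)

    def build(c: int) -> np.ndarray:
        tpl = np.concatenate([
            gains[c, m] * ((1.0 - trans_mix[c]) * conv_s[c][m]
                           + trans_mix[c] * conv_d[c][m])
            for m in range(len(movies))
        ])
        peak = tpl.max()
        return tpl / peak if peak > 0 else tpl

    templates = np.asarray([build(c) for c in range(K)])
    # diversify: the planted clusters must be pairwise distinct, or the
    # advertised separation is not actually delivered; redraw the movie
    # gains and temporal character of any cluster whose template nearly
    # duplicates another's, keeping the best redraw
    for _ in range(60):
        dist = np.linalg.norm(templates[:, None, :] - templates[None, :, :],
                              axis=2)
        np.fill_diagonal(dist, np.inf)
        dbar = dist[np.isfinite(dist)].mean()
        i, j = np.unravel_index(np.argmin(dist), dist.shape)
        if dist[i, j] >= 0.7 * dbar:
            break
        c = max(i, j)  # keep the earlier cluster (movie-selective ones stay)
        best_tpl, best_sep = templates[c], dist[c].min()
        best_state = (gains[c].copy(), trans_mix[c])
        others = np.delete(np.arange(K), c)
        for _try in range(12):
            gains[c] = rng.uniform(0.2, 1.0, len(movies))
            gains[c, rng.integers(0, len(movies))] = 1.0
            trans_mix[c] = rng.uniform(0.0, 1.0)
            cand = build(c)
            sep = np.linalg.norm(templates[others] - cand, axis=1).min()
            if sep > best_sep:
                best_tpl, best_sep = cand, sep
                best_state = (gains[c].copy(), trans_mix[c])
        gains[c], trans_mix[c] = best_state
        templates[c] = best_tpl
    return templates


def _jitter_shape(templates: np.ndarray,
                  separation: float) -> tuple[np.ndarray, np.ndarray]:
    """Within-cluster jitter profile and per-cluster scale.

    The jitter amplitude follows the template (no variability where the
    template is silent) and vanishes near the template's peak so that the
    min-max anchors used by the analysis normalization are stable within a
    cluster.  The per-cluster scale makes the mean between-template
    distance equal ``separation`` within-cluster SDs.
    """
    K = templates.shape[0]
    shape = np.stack([
        np.minimum(tpl, np.clip((0.9 - tpl) / 0.4, 0.0, 1.0))
        for tpl in templates
    ])
    d = [np.linalg.norm(templates[i] - templates[j])
         for i in range(K) for j in range(i + 1, K)]
    dbar = float(np.mean(d))
    norms = np.linalg.norm(shape, axis=1)
    norms[norms == 0] = 1.0
    return shape, dbar / (separation * norms)


# ---------------------------------------------------------------------------
# session simulation

def simulate_session(population: Sequence[GroundTruthNeuron],
                     movies: list[MovieStimulus],
                     battery_spec: dict | None = None,
                     config: SessionConfig | None = None) -> Session:
    """Simulate raw fluorescence for the four movies and the six-protocol
    battery: baseline + kernel-convolved stimulus drive + iid Gaussian noise
    per repetition, plus a paired neuropil trace (0.7 x field-mean drive +
    noise) so neuropil correction at r = 0.7 is exactly invertible in the
    noiseless limit.
    """
    if config is None:
        raise ValueError("config is required")
    if battery_spec is None:
        battery_spec = default_battery(config.frame_rate)
    if movies and abs(movies[0].frame_rate - config.frame_rate) > 1e-9:
        raise ValueError("movie frame rate inconsistent with session config")
    rng = np.random.default_rng(config.seed + 3)
    df = population_frame(list(population))
    n = len(df)
    fr = config.frame_rate
    n_rep = config.n_repetitions
    b = config.baseline_f
    b_np = 0.3
    r_np = config.neuropil_r
    amp = df.amplitude.to_numpy()

    blocks: dict[str, StimulusBlock] = {}
    taus = df.kinetics_tau.to_numpy()

    def assemble(name: str, drive: np.ndarray, schedule: dict,
                 rep_scale: np.ndarray | None = None,
                 convolve: bool = False) -> None:
        """drive: (n, t) noiseless somatic drive in dF/F units.

        ``rep_scale`` is an optional (n_rep, n) gain (used for looming
        habituation); ``convolve`` applies the per-neuron calcium kernel.
        """
        if convolve:
            drive = _convolve_population(drive, taus, fr)
        n_t = drive.shape[1]
        field_drive = drive.mean(axis=0)
        npil = np.empty((n, n_t, n_rep), dtype=np.float32)
        raw = np.empty((n, n_t, n_rep), dtype=np.float32)
        drift = config.drift_amp * np.sin(
            2 * np.pi * np.arange(n_t) / (fr * 40.0)
            + rng.uniform(0, 2 * np.pi, n)[:, None]
        ) if config.drift_amp > 0 else np.zeros((n, n_t))
        for rep in range(n_rep):
            scale = 1.0 if rep_scale is None else rep_scale[rep][:, None]
            np_noise = rng.normal(0.0, config.noise_sd * 0.5, (n, n_t)) \
                if config.noise_sd > 0 else 0.0
            npil_rep = b_np + field_drive[None, :] + np_noise
            som_noise = rng.normal(0.0, config.noise_sd, (n, n_t)) \
                if config.noise_sd > 0 else 0.0
            raw_rep = b + b * drive * scale + b * drift \
                + r_np * npil_rep + som_noise
            npil[:, :, rep] = npil_rep
            raw[:, :, rep] = raw_rep
        blocks[name] = StimulusBlock(name=name, traces=raw, neuropil=npil,
                                     frame_rate=fr, schedule=schedule)

    # --- movies: cluster template + template-shaped smooth jitter ---------
    templates = cluster_movie_templates(population, movies, config)
    jit_shape, jit_scale = _jitter_shape(templates, config.cluster_separation)
    T_movie = templates.shape[1] // len(movies)
    pre_n = int(round(2.0 * fr))
    cluster_ids = df.cluster_id.to_numpy()
    jitter = gaussian_filter1d(
        rng.normal(0.0, 1.0, (n, templates.shape[1])), sigma=2.0, axis=1)
    jitter /= jitter.std(axis=1, keepdims=True)
    full = np.zeros((n, templates.shape[1]))
    responsive = cluster_ids >= 0
    cid = cluster_ids[responsive]
    full[responsive] = templates[cid] + jitter[responsive] \
        * (jit_shape[cid] * jit_scale[cid][:, None])
    full *= amp[:, None]
    for m, movie in enumerate(movies):
        seg = full[:, m * T_movie:(m + 1) * T_movie]
        drive = np.concatenate([np.zeros((n, pre_n)), seg], axis=1)
        schedule = {"kind": "movie", "pre": (0.0, 2.0),
                    "segments": [{"name": movie.name, "t0": 2.0,
                                  "t1": 2.0 + T_movie / fr}],
                    "duration": 2.0 + T_movie / fr}
        assemble(f"movie_{movie.name}", drive, schedule)

    # --- bar --------------------------------------------------------------
    sched = battery_spec["bar"]
    n_t = int(round(sched["duration"] * fr))
    directions = np.array([s["direction"] for s in sched["segments"]])
    drive = np.zeros((n, n_t))
    tune = np.stack([
        direction_tuning(row.dsi_true, row.osi_true, row.pref_direction,
                         directions)
        for row in df.itertuples()
    ])
    for k, seg in enumerate(sched["segments"]):
        s0, _ = _seg_samples(seg, fr)
        # bump early in the sweep so the calcium tail decays within the gap
        bump = _bump(n_t, s0, s0 + int(round(1.2 * fr)), fr)
        drive += (amp * tune[:, k])[:, None] * bump[None, :]
    drive[~responsive] = 0.0
    assemble("bar", drive, sched, convolve=True)

    # --- looming (habituation across the 10 repetitions) ------------------
    sched = battery_spec["looming"]
    n_t = int(round(sched["duration"] * fr))
    segs = {s["name"]: s for s in sched["segments"]}
    e0, e1 = _seg_samples(segs["expand"], fr)
    r0, r1 = _seg_samples(segs["recede"], fr)
    bump_e = _bump(n_t, e0, e1, fr)
    bump_r = _bump(n_t, r0, r1, fr)
    lsi = df.lsi_true.to_numpy()
    rw_gain = (1.0 - lsi) / (1.0 + lsi)
    hi = df.hi_true.to_numpy()
    hab_end = (1.0 - hi) / (1.0 + hi)
    # geometric habituation from 1 to (1-HI)/(1+HI) across repetitions; the
    # per-rep scale is applied to the whole block (receding bump included,
    # which leaves LSI from trial means unbiased)
    drive = (amp * 1.0)[:, None] * bump_e[None, :] \
        + (amp * rw_gain)[:, None] * bump_r[None, :]
    drive[~responsive] = 0.0
    rep_scale = np.stack([
        hab_end ** (rep / max(1, n_rep - 1)) for rep in range(n_rep)
    ])  # (n_rep, n)
    assemble("looming", drive, sched, rep_scale=rep_scale, convolve=True)

    # --- chirp ------------------------------------------------------------
    sched = battery_spec["chirp"]
    n_t = int(round(sched["duration"] * fr))
    segs = {s["name"]: s for s in sched["segments"]}
    csi = df.csi_true.to_numpy()
    on_g = np.clip((1.0 + csi) / 2.0, 0.0, None)
    off_g = np.clip((1.0 - csi) / 2.0, 0.0, None)
    sus = (1.0 - df.transientness.to_numpy() * 0.9)  # sustained fraction
    fsi = df.fsi_true.to_numpy()
    low_g = np.clip((1.0 + fsi) / 2.0, 0.0, None)
    high_g = np.clip((1.0 - fsi) / 2.0, 0.0, None)
    drive = np.zeros((n, n_t))
    t_ax = np.arange(n_t) / fr

    def flash_shape(t0: float, t1: float) -> np.ndarray:
        inside = (t_ax >= t0) & (t_ax < t1)
        shape = np.zeros(n_t)
        shape[inside] = 1.0
        dt = t_ax[inside] - t0
        return inside, dt

    for name, gain in [("white", on_g), ("black2", off_g), ("black3", off_g)]:
        seg = segs[name]
        inside, dt = flash_shape(seg["t0"], seg["t1"])
        drive[:, inside] += gain[:, None] * (
            sus[:, None] + (1 - sus[:, None]) * np.exp(-dt / 0.5)[None, :]
        )
    # frequency-modulation envelope: low gain over first 3 s ramping to high
    # gain over the last 2 s
    seg = segs["fm"]
    inside = (t_ax >= seg["t0"]) & (t_ax < seg["t1"])
    dt = t_ax[inside] - seg["t0"]
    dur = seg["t1"] - seg["t0"]
    ramp = np.clip((dt - 3.0) / (dur - 5.0), 0.0, 1.0)
    drive[:, inside] += (low_g[:, None] * (1 - ramp)[None, :]
                         + high_g[:, None] * ramp[None, :]) * 0.9
    # rebound responses 1.6 s after each modulation ends
    for seg_name, amp_col in [("fm", df.rafm_true), ("am", df.raam_true)]:
        t_end = segs[seg_name]["t1"]
        s0 = int(round((t_end + 1.2) * fr))
        s1 = int(round((t_end + 2.0) * fr))
        bump = _bump(n_t, s0, s1, fr)
        drive += amp_col.to_numpy()[:, None] * bump[None, :]
    # amplitude-modulation envelope
    seg = segs["am"]
    inside = (t_ax >= seg["t0"]) & (t_ax < seg["t1"])
    dt = t_ax[inside] - seg["t0"]
    drive[:, inside] += 0.4 * (dt / (seg["t1"] - seg["t0"]))[None, :]
    drive *= amp[:, None]
    drive[~responsive] = 0.0
    assemble("chirp", drive, sched, convolve=True)

    # --- color ------------------------------------------------------------
    sched = battery_spec["color"]
    n_t = int(round(sched["duration"] * fr))
    segs = {s["name"]: s for s in sched["segments"]}
    bgi = df.bgi_true.to_numpy()
    drive = np.zeros((n, n_t))
    for name, gain in [("blue", np.clip((1 + bgi) / 2, 0, None)),
                       ("green", np.clip((1 - bgi) / 2, 0, None))]:
        s0, s1 = _seg_samples(segs[name], fr)
        bump = _bump(n_t, s0, s1, fr)
        drive += (amp * gain)[:, None] * bump[None, :]
    drive[~responsive] = 0.0
    assemble("color", drive, sched, convolve=True)

    # --- size tuning ------------------------------------------------------
    sched = battery_spec["size"]
    n_t = int(round(sched["duration"] * fr))
    diam = np.asarray(SIZE_DIAMETERS_DEG)
    stune = np.stack([size_tuning(p, diam) for p in df.size_pref])
    drive = np.zeros((n, n_t))
    k = 0
    for seg in sched["segments"]:
        if not seg["name"].startswith("size_"):
            continue
        s0, s1 = _seg_samples(seg, fr)
        bump = _bump(n_t, s0, s1, fr)
        drive += (amp * stune[:, k])[:, None] * bump[None, :]
        k += 1
    drive[~responsive] = 0.0
    assemble("size", drive, sched, convolve=True)

    # --- sparse noise: per-presentation peak amplitudes -------------------
    sched = dict(battery_spec["sparse_noise"])
    centers = sparse_grid_centers()
    pre_samples = sched["pre_samples"]
    rfw = np.stack([
        rf_weight(centers[:, 0], centers[:, 1],
                  (row.rf_az, row.rf_el), (row.rf_b, row.rf_c), row.rf_angle)
        for row in df.itertuples()
    ])  # (n, 121)
    vals = np.concatenate([rfw, 0.9 * rfw], axis=1)  # black then white
    drive = np.concatenate(
        [np.zeros((n, pre_samples)), amp[:, None] * vals], axis=1)
    drive[~responsive] = 0.0
    sched["pre"] = (0.0, pre_samples / fr)
    sched["duration"] = drive.shape[1] / fr
    assemble("sparse_noise", drive, sched)

    return Session(blocks=blocks, ground_truth=df, config=config,
                   movies=movies)


def generate_session(config: SessionConfig) -> Session:
    """Movies + population + simulated traces in one call."""
    movies = generate_movies(config)
    pop = generate_population(config)
    return simulate_session(pop, movies, default_battery(config.frame_rate),
                            config)
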