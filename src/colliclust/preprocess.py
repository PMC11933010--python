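"""Raw fluorescence -> dF/F: neuropil correction, percentile detrending,
response SNR and ROI gating.

The processing chain per ROI and stimulus block is

    F_true = F_raw - r * F_neuropil          (neuropil correction, r ~ 0.7)
    F_b(t) = F_true(t) - P8[window(t)]       (slow-baseline removal; the 8th
                                              percentile of a 15-s window
                                              centered on each frame,
                                              truncated at the edges)
    R(t)   = F_b(t) / F0                     (dF/F; F0 = mean F_true during
                                              the pre-stimulus gray period)

Repeat reliability is SNR = Var_t[<C>_r] / <Var_r[C]>_t, where C is the
time x repetition response matrix; ROIs are kept when their diameter looks
neuronal (10-20 um) and SNR exceeds 0.35 for at least one stimulus.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PreprocessConfig
from .synthgen import Session


@dataclass
class Trace:
    values: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")


@dataclass
class DffSession:
    """dF/F responses (all ROIs) plus the gating audit."""

    dff: dict[str, np.ndarray]  # block -> (n_roi, n_t, n_rep)
    snr: pd.DataFrame  # per roi x block SNR values
    audit: pd.DataFrame  # roi_id, diameter, snr, kept, reason
    kept: np.ndarray  # indices of ROIs passing the gate
    schedules: dict[str, dict] = field(default_factory=dict)
    frame_rate: float = 4.8


# ---------------------------------------------------------------------------
# elementary operations

def neuropil_correct(raw: Trace, neuropil: Trace, r: float) -> Trace:
    """F_true = F_raw - r * F_neuropil (elementwise)."""
    if raw.values.shape != neuropil.values.shape:
        raise ValueError("raw and neuropil traces must have equal length")
    return Trace(raw.values - r * neuropil.values, raw.sample_rate)


def detrend_baseline(trace: Trace, percentile: float = 8.0,
                     window_s: float = 15.0) -> Trace:
    """Subtract the running low-percentile baseline.

    The window is centered on each sample and truncated (never padded) at
    the trace edges; a trace shorter than the window degrades gracefully to
    a whole-trace percentile.
    """
    values = trace.values
    if values.size == 0:
        raise ValueError("empty trace")
    half = max(1, int(round(window_s * trace.sample_rate / 2.0)))
    baseline = _running_percentile(values[None, :], percentile, half)[0]
    return Trace(values - baseline, trace.sample_rate)


def _running_percentile(arr: np.ndarray, percentile: float,
                        half: int) -> np.ndarray:
    """Truncated centered running percentile along the last axis.

    ``arr`` is (..., n_t); returns the per-sample baseline.
    """
    n_t = arr.shape[-1]
    out = np.empty_like(arr, dtype=float)
    for t in range(n_t):
        lo, hi = max(0, t - half), min(n_t, t + half + 1)
        out[..., t] = np.percentile(arr[..., lo:hi], percentile, axis=-1)
    return out


def dff(trace: Trace, f0: float) -> Trace:
    """(F - F0) / F0; F0 must be positive."""
    if f0 <= 0:
        raise ValueError("f0 must be > 0")
    return Trace((trace.values - f0) / f0, trace.sample_rate)


def compute_snr(C: np.ndarray) -> float:
    """Repeat reliability of a time x repetition response matrix.

    Degenerate conventions (documented): a constant matrix returns 0.0 and
    identical nonconstant repetitions (zero noise) return +inf, so the
    downstream gate behaves monotonically in both limits.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] < 2 or C.shape[1] < 2:
        raise ValueError("C must be N_t x N_r with N_t, N_r >= 2")
    signal = np.var(C.mean(axis=1))
    noise = np.mean(np.var(C, axis=1, ddof=0))
    if noise == 0.0:
        if signal == 0.0:
            return 0.0
        warnings.warn("identical repetitions: SNR is +inf")
        return np.inf
    return float(signal / noise)


def snr_block(arr: np.ndarray) -> np.ndarray:
    """Vectorized SNR over a (n_roi, n_t, n_rep) block."""
    signal = arr.mean(axis=2).var(axis=1)
    noise = arr.var(axis=2).mean(axis=1)
    out = np.full(arr.shape[0], 0.0)
    nz = noise > 0
    out[nz] = signal[nz] / noise[nz]
    out[~nz & (signal > 0)] = np.inf
    return out


def gate_rois(records: pd.DataFrame, config: PreprocessConfig) -> pd.DataFrame:
    """Audit table from per-ROI diameter and SNR.

    ``records`` needs columns roi_id, diameter, snr.  Keeps ROIs with
    diameter inside ``roi_diameter_bounds`` AND snr > snr_threshold; the
    audit lists which criterion failed.
    """
    lo, hi = config.roi_diameter_bounds
    rows = []
    for row in records.itertuples():
        size_ok = lo <= row.diameter <= hi
        snr_ok = row.snr > config.snr_threshold
        reason = []
        if not size_ok:
            reason.append("diameter")
        if not snr_ok:
            reason.append("snr")
        rows.append({
            "roi_id": row.roi_id, "diameter": row.diameter, "snr": row.snr,
            "kept": size_ok and snr_ok,
            "reason": "" if size_ok and snr_ok else "+".join(reason),
        })
    cols = ["roi_id", "diameter", "snr", "kept", "reason"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# session-level driver

def preprocess_session(session: Session,
                       config: PreprocessConfig | None = None) -> DffSession:
    """Run the full chain on every stimulus block of a synthetic session."""
    if config is None:
        config = PreprocessConfig()
    fr = session.blocks[next(iter(session.blocks))].frame_rate
    half = max(1, int(round(config.window_s * fr / 2.0)))
    dff_blocks: dict[str, np.ndarray] = {}
    snr_cols: dict[str, np.ndarray] = {}
    schedules = {}
    for name, block in session.blocks.items():
        corrected = block.traces.astype(float) \
            - config.r * block.neuropil.astype(float)
        pre0, pre1 = block.schedule.get("pre", (0.0, 2.0))
        p0, p1 = int(round(pre0 * fr)), max(1, int(round(pre1 * fr)))
        f0 = corrected[:, p0:p1, :].mean(axis=(1, 2))
        f0 = np.where(f0 > 0, f0, np.nan)
        if np.any(~np.isfinite(f0)):
            warnings.warn("non-positive F0 for some ROIs; dF/F flagged NaN")
        # running-percentile baseline on the repetition-collapsed trace is
        # not equivalent to per-rep detrending; drift is per-rep here, so
        # detrend each repetition
        arr = np.moveaxis(corrected, 2, 1)  # (n, rep, t)
        base = _running_percentile(arr, config.percentile, half)
        detrended = np.moveaxis(arr - base, 1, 2)
        dff_blocks[name] = (detrended / f0[:, None, None]).astype(np.float32)
        snr_cols[name] = snr_block(dff_blocks[name])
        schedules[name] = block.schedule
    snr_df = pd.DataFrame(snr_cols)
    snr_df.insert(0, "roi_id", np.arange(session.n_rois))
    if config.snr_pooling == "max":
        pooled = snr_df.drop(columns="roi_id").max(axis=1).to_numpy()
    else:
        pooled = snr_df[config.snr_pooling].to_numpy()
    records = pd.DataFrame({
        "roi_id": np.arange(session.n_rois),
        "diameter": session.ground_truth.diameter_um.to_numpy(),
        "snr": pooled,
    })
    audit = gate_rois(records, config)
    kept = audit.loc[audit.kept, "roi_id"].to_numpy()
    return DffSession(dff=dff_blocks, snr=snr_df, audit=audit, kept=kept,
                      schedules=schedules, frame_rate=fr)
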