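"""Battery-derived functional indices and cluster-level summaries.

Implements the standard selectivity measures used for superficial-SC
neurons: direction/orientation selectivity from the response-weighted
circular vector sum over 12 bar directions,

    DSI = |sum_k R_k exp(i rho_k)| / sum_k R_k
    OSI = |sum_k R_k exp(2 i theta_k)| / sum_k R_k,

the family of paired contrast indices (a - b)/(a + b) — habituation (HI),
looming (LSI), motion (MSI), contrast (CSI), peak-final (PFSI), frequency
(FSI), surround suppression (SSI), blue-green (BGI) — best stimulus size
(BSS), signed response to motion (RtM), rebound amplitudes after frequency
and amplitude modulation (RaFM/RaAM), the per-index relative selectivity
(RSI = value - reference), the cluster x index SI table with one-sample
t-tests, and the cluster-by-functional-type composition analysis with a
permutation null.

Peak responses are maxima of the trial-averaged dF/F inside the stimulus
windows given by each block's schedule; negative peaks are rectified to
zero before the paired indices (RtM alone keeps its sign).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import SIZE_DIAMETERS_DEG
from .preprocess import DffSession

INDEX_NAMES = ("RtM", "DSI", "OSI", "HI", "LSI", "MSI", "CSI", "PFSI",
               "FSI", "RaFM", "RaAM", "BSS", "SSI", "BGI", "RFS")

#: Reference values subtracted to form the relative selectivity index.
RSI_REFERENCES: dict[str, float] = {
    "RtM": 0.0, "DSI": 0.15, "OSI": 0.15, "HI": 0.0, "LSI": 0.0, "MSI": 0.0,
    "CSI": 0.0, "PFSI": 0.5, "FSI": 0.0, "RaFM": 0.0, "RaAM": 0.0,
    "BSS": 8.0, "SSI": 0.0, "BGI": 0.0, "RFS": 90.0,
}


def dsi_osi(bar_responses: np.ndarray,
            directions: np.ndarray | None = None) -> tuple[float, float]:
    """Direction and orientation selectivity from 12 peak responses.

    Negative responses are rectified to zero with a warning; an all-zero
    response vector leaves both indices undefined (NaN).
    """
    R = np.asarray(bar_responses, dtype=float)
    if directions is None:
        directions = np.arange(len(R)) * 2 * np.pi / len(R)
    if np.any(R < 0):
        warnings.warn("negative bar responses rectified to 0")
        R = np.clip(R, 0.0, None)
    total = R.sum()
    if total == 0:
        return np.nan, np.nan
    dsi = np.abs(np.sum(R * np.exp(1j * directions))) / total
    osi = np.abs(np.sum(R * np.exp(2j * directions))) / total
    return float(dsi), float(osi)


def paired_index(a: float, b: float) -> float:
    """(a - b) / (a + b); NaN-flagged when a + b = 0."""
    if not (np.isfinite(a) and np.isfinite(b)):
        return np.nan
    if a + b == 0:
        return np.nan
    return float((a - b) / (a + b))


def rsi(profile: dict[str, float],
        refs: dict[str, float] | None = None) -> dict[str, float]:
    """Relative selectivity: index value minus its reference; missing
    indices propagate as NaN."""
    if refs is None:
        refs = RSI_REFERENCES
    return {k: profile.get(k, np.nan) - ref for k, ref in refs.items()}


# ---------------------------------------------------------------------------
# window helpers

def _trial_mean(arr: np.ndarray) -> np.ndarray:
    return np.asarray(arr, dtype=float).mean(axis=-1)


def _win(schedule_seg: dict, fr: float, n_t: int) -> slice:
    s0 = int(round(schedule_seg["t0"] * fr))
    s1 = min(n_t, int(round(schedule_seg["t1"] * fr)))
    return slice(s0, max(s1, s0 + 1))


def _peak(trace: np.ndarray, window: slice) -> float:
    return float(trace[window].max())


# ---------------------------------------------------------------------------
# per-protocol extraction (vectorized over neurons)

def bar_peaks(dff: np.ndarray, schedule: dict, fr: float) -> np.ndarray:
    """(n_neuron, 12) peak responses per direction from trial means."""
    tm = _trial_mean(dff)
    out = np.stack([
        tm[:, _win(seg, fr, tm.shape[1])].max(axis=1)
        for seg in schedule["segments"]
    ], axis=1)
    return out


def bar_rtm(dff: np.ndarray, schedule: dict, fr: float) -> np.ndarray:
    """Signed response to motion: the value of largest magnitude in the
    trial-mean trace during bar motion (negative for motion-suppressed
    neurons)."""
    tm = _trial_mean(dff)
    t0 = _win(schedule["segments"][0], fr, tm.shape[1]).start
    sweep = tm[:, t0:]
    idx = np.argmax(np.abs(sweep), axis=1)
    return sweep[np.arange(sweep.shape[0]), idx]


def looming_quantities(dff: np.ndarray, schedule: dict,
                       fr: float) -> dict[str, np.ndarray]:
    """R1/R10 (first/last repetition peaks during expansion), and the
    trial-mean expansion and recession peaks feeding LSI."""
    arr = np.asarray(dff, dtype=float)
    n_t = arr.shape[1]
    segs = {s["name"]: s for s in schedule["segments"]}
    w_exp = _win(segs["expand"], fr, n_t)
    w_rec = _win(segs["recede"], fr, n_t)
    tm = arr.mean(axis=2)
    return {
        "R1": arr[:, w_exp, 0].max(axis=1),
        "R10": arr[:, w_exp, -1].max(axis=1),
        "Rk": tm[:, w_exp].max(axis=1),
        "Rw": tm[:, w_rec].max(axis=1),
    }


def chirp_derived(chirp_tm: np.ndarray, schedule: dict,
                  fr: float) -> dict[str, np.ndarray]:
    """Chirp-trace quantities (vectorized over neurons).

    R_On/R_Off: peaks during the white flash and the black flash after it;
    R_peak/R_final: peak and final value of the preferred flash segment;
    R_low/R_high: peaks in the first 3 s and last 2 s of the frequency
    modulation; RaFM/RaAM: amplitude 1.6 s after each modulation ends minus
    the mean of the gray segment preceding that modulation.
    """
    tm = np.atleast_2d(np.asarray(chirp_tm, dtype=float))
    n_t = tm.shape[1]
    segs = {s["name"]: s for s in schedule["segments"]}
    w_on = _win(segs["white"], fr, n_t)
    w_off = _win(segs["black2"], fr, n_t)
    r_on = tm[:, w_on].max(axis=1)
    r_off = tm[:, w_off].max(axis=1)
    # preferred flash segment: white or black, whichever peaks higher
    prefer_on = r_on >= r_off
    r_peak = np.where(prefer_on, r_on, r_off)
    final_on = tm[:, w_on.stop - 1]
    final_off = tm[:, w_off.stop - 1]
    r_final = np.where(prefer_on, final_on, final_off)
    fm = segs["fm"]
    w_low = _win({"t0": fm["t0"], "t1": fm["t0"] + 3.0}, fr, n_t)
    w_high = _win({"t0": fm["t1"] - 2.0, "t1": fm["t1"]}, fr, n_t)
    r_low = tm[:, w_low].max(axis=1)
    r_high = tm[:, w_high].max(axis=1)

    def rebound(mod: str, gray_before: str) -> np.ndarray:
        t_probe = segs[mod]["t1"] + 1.6
        i_probe = min(n_t - 1, int(round(t_probe * fr)))
        base = tm[:, _win(segs[gray_before], fr, n_t)].mean(axis=1)
        return tm[:, i_probe] - base

    return {
        "R_On": r_on, "R_Off": r_off, "R_peak": r_peak, "R_final": r_final,
        "R_low": r_low, "R_high": r_high,
        "RaFM": rebound("fm", "gray1"), "RaAM": rebound("am", "gray2"),
        "R_flash": np.maximum(r_on, r_off),
    }


def bss_rtm(size_peaks: np.ndarray, rtm: np.ndarray,
            diameters: tuple[float, ...] = SIZE_DIAMETERS_DEG
            ) -> dict[str, np.ndarray]:
    """Best stimulus size (argmax diameter, ties to the smallest) plus the
    small/large peaks feeding SSI."""
    peaks = np.asarray(size_peaks, dtype=float)
    diam = np.asarray(diameters)
    best = diam[np.argmax(peaks, axis=1)]  # argmax takes first (smallest) tie
    return {
        "BSS": best, "RtM": np.asarray(rtm, dtype=float),
        "R_small": peaks[:, 0], "R_large": peaks[:, -1],
    }


def size_peaks_from_block(dff: np.ndarray, schedule: dict,
                          fr: float) -> np.ndarray:
    tm = _trial_mean(dff)
    segs = [s for s in schedule["segments"] if s["name"].startswith("size_")]
    return np.stack([
        tm[:, _win(seg, fr, tm.shape[1])].max(axis=1) for seg in segs
    ], axis=1)


def color_peaks(dff: np.ndarray, schedule: dict,
                fr: float) -> tuple[np.ndarray, np.ndarray]:
    tm = _trial_mean(dff)
    segs = {s["name"]: s for s in schedule["segments"]}
    rb = tm[:, _win(segs["blue"], fr, tm.shape[1])].max(axis=1)
    rg = tm[:, _win(segs["green"], fr, tm.shape[1])].max(axis=1)
    return rb, rg


def _rect(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, None)


def _paired(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a, b = _rect(a), _rect(b)
    s = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(s > 0, (a - b) / np.where(s > 0, s, 1.0), np.nan)


def compute_profiles(dffs: DffSession,
                     rfs: np.ndarray | None = None) -> pd.DataFrame:
    """Per-neuron TuningProfile table from a preprocessed session.

    ``rfs`` optionally supplies per-neuron RF sizes (deg^2) from the RF
    stage so the profile table carries the complete index set.
    """
    fr = dffs.frame_rate
    out: dict[str, np.ndarray] = {}
    bar = dffs.dff["bar"]
    sched = dffs.schedules["bar"]
    peaks = bar_peaks(bar, sched, fr)
    directions = np.array([s["direction"] for s in sched["segments"]])
    rect = _rect(peaks)
    total = rect.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dsi = np.abs((rect * np.exp(1j * directions)).sum(axis=1)) / total
        osi = np.abs((rect * np.exp(2j * directions)).sum(axis=1)) / total
    dsi[total == 0] = np.nan
    osi[total == 0] = np.nan
    out["DSI"], out["OSI"] = dsi, osi
    rtm = bar_rtm(bar, sched, fr)
    r_m = rect.max(axis=1)

    loom = looming_quantities(dffs.dff["looming"], dffs.schedules["looming"], fr)
    out["HI"] = _paired(loom["R1"], loom["R10"])
    out["LSI"] = _paired(loom["Rk"], loom["Rw"])

    chirp = chirp_derived(_trial_mean(dffs.dff["chirp"]),
                          dffs.schedules["chirp"], fr)
    out["CSI"] = _paired(chirp["R_On"], chirp["R_Off"])
    out["PFSI"] = _paired(chirp["R_peak"], chirp["R_final"])
    out["FSI"] = _paired(chirp["R_low"], chirp["R_high"])
    out["RaFM"] = chirp["RaFM"]
    out["RaAM"] = chirp["RaAM"]
    out["MSI"] = _paired(r_m, chirp["R_flash"])

    speaks = size_peaks_from_block(dffs.dff["size"], dffs.schedules["size"], fr)
    bq = bss_rtm(speaks, rtm)
    out["BSS"] = bq["BSS"]
    out["RtM"] = bq["RtM"]
    out["SSI"] = _paired(bq["R_small"], bq["R_large"])

    rb, rg = color_peaks(dffs.dff["color"], dffs.schedules["color"], fr)
    out["BGI"] = _paired(rb, rg)

    out["RFS"] = rfs if rfs is not None else np.full(bar.shape[0], np.nan)
    df = pd.DataFrame(out)
    df.insert(0, "roi_id", np.arange(bar.shape[0]))
    return df[["roi_id", *INDEX_NAMES]]


# ---------------------------------------------------------------------------
# cluster-level summaries

def cluster_si_table(profiles: pd.DataFrame, labels: np.ndarray,
                     refs: dict[str, float] | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cluster x index mean relative-selectivity table.

    Returns ``(mean_rsi, normalized, mask)``: the raw per-cluster mean RSI,
    the columnwise max-|value| normalized table, and a boolean mask that is
    True where the one-sample t-test against 0 is not significant
    (p >= .05) or degenerate (zero variance / < 2 neurons).
    """
    if refs is None:
        refs = RSI_REFERENCES
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    idx_cols = [c for c in profiles.columns if c in refs]
    means = pd.DataFrame(index=clusters, columns=idx_cols, dtype=float)
    mask = pd.DataFrame(False, index=clusters, columns=idx_cols)
    for c in clusters:
        sub = profiles.loc[labels == c, idx_cols]
        for col in idx_cols:
            vals = (sub[col] - refs[col]).dropna().to_numpy()
            if len(vals) < 2:
                means.loc[c, col] = np.nan
                mask.loc[c, col] = True
                continue
            means.loc[c, col] = vals.mean()
            if np.allclose(vals, vals[0]):
                mask.loc[c, col] = True  # degenerate: test undefined
                continue
            _, p = stats.ttest_1samp(vals, 0.0)
            mask.loc[c, col] = bool(p >= 0.05)
    col_max = means.abs().max(axis=0).replace(0.0, 1.0)
    normalized = means / col_max
    return means, normalized, mask


def composition_analysis(cluster_labels: np.ndarray, type_labels: np.ndarray,
                         n_perm: int = 1000, seed: int = 0
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cluster-by-functional-type composition with a permutation null.

    Returns the row-normalized contribution matrix (fraction of each
    cluster contributed by each type), the per-cluster sorted cumulative
    contribution curves, and a per-cluster table of chi-square distances
    from the global type distribution with permutation p-values (type
    labels shuffled ``n_perm`` times).
    """
    cluster_labels = np.asarray(cluster_labels)
    type_labels = np.asarray(type_labels)
    if cluster_labels.shape != type_labels.shape:
        raise ValueError("labelings must cover the same neurons")
    ct = pd.crosstab(pd.Series(cluster_labels, name="cluster"),
                     pd.Series(type_labels, name="type"))
    contrib = ct.div(ct.sum(axis=1), axis=0)
    cum = pd.DataFrame(
        np.cumsum(np.sort(contrib.to_numpy(), axis=1)[:, ::-1], axis=1) * 100,
        index=contrib.index,
        columns=[f"top_{i + 1}" for i in range(contrib.shape[1])],
    )
    global_p = ct.sum(axis=0) / ct.to_numpy().sum()

    def chi2_distance(table: pd.DataFrame) -> np.ndarray:
        frac = table.div(table.sum(axis=1), axis=0)
        diff = frac - global_p.to_numpy()[None, :]
        return np.nansum(diff.to_numpy() ** 2
                         / global_p.to_numpy()[None, :], axis=1)

    observed = chi2_distance(ct)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(ct.index))
    for _ in range(n_perm):
        perm = rng.permutation(type_labels)
        pct = pd.crosstab(pd.Series(cluster_labels), pd.Series(perm))
        pct = pct.reindex(index=ct.index, columns=ct.columns, fill_value=0)
        exceed += chi2_distance(pct) >= observed
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    ptable = pd.DataFrame({
        "cluster": ct.index, "chi2_distance": observed, "p_perm": pvals,
    })
    return contrib, cum, ptable
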