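"""End-to-end orchestration: synthesis -> preprocessing -> clustering ->
stability -> tuning -> RF -> anatomy, with CSV/JSON outputs, SVG figures
and a markdown report.

Every numeric output table carries the config hash and seed in a comment
header.  A stage failure is logged and its dependents are skipped; the
run exits nonzero (raises) only if the session itself cannot be built.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import anatomy as an  # noqa: E402
from . import featcluster as fc  # noqa: E402
from . import preprocess as pp  # noqa: E402
from . import rf as rfmod  # noqa: E402
from . import stability as st  # noqa: E402
from . import synthgen as sg  # noqa: E402
from . import tuning as tn  # noqa: E402
from .config import PipelineConfig  # noqa: E402
from .io import save_session  # noqa: E402

log = logging.getLogger("colliclust")


@dataclass
class PipelineResult:
    config: PipelineConfig
    output_dir: Path
    session: sg.Session = None
    dffs: pp.DffSession = None
    features: fc.FeatureDecomposition = None
    clustering: fc.GmmClustering = None
    stability: st.StabilityReport = None
    profiles: pd.DataFrame = None
    rf_fits: pd.DataFrame = None
    rf_summary: pd.DataFrame = None
    drp_table: pd.DataFrame = None
    stages_failed: dict[str, str] = field(default_factory=dict)

    @property
    def best_k(self) -> int | None:
        return self.clustering.K if self.clustering is not None else None


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config={cfg.hash()} seed={cfg.seed}\n")
        df.to_csv(fh, index=False)


def run(config: PipelineConfig, save_store: bool = False) -> PipelineResult:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(config=config, output_dir=out)
    t_start = time.time()

    # --- synthesis (fatal on failure) ------------------------------------
    log.info("stage synthgen: generating session (seed=%d)", config.session.seed)
    session = sg.generate_session(config.session)
    result.session = session
    if save_store:
        save_session(session, out / f"{config.run_id}_session.h5")

    movie_rows = []
    for movie in session.movies:
        stats = sg.movie_stats(movie)
        stats.insert(0, "movie", movie.name)
        movie_rows.append(stats)
    _write_csv(pd.concat(movie_rows), out / "movie_stats.csv", config)

    # --- preprocess -------------------------------------------------------
    try:
        log.info("stage preprocess")
        dffs = pp.preprocess_session(session, config.preprocess)
        result.dffs = dffs
        _write_csv(dffs.audit, out / "roi_audit.csv", config)
    except Exception as err:  # noqa: BLE001
        log.error("stage preprocess failed: %s; downstream stages skipped", err)
        result.stages_failed["preprocess"] = str(err)
        return result

    kept = dffs.kept
    gt = session.ground_truth.iloc[kept].reset_index(drop=True)

    # --- features + clustering -------------------------------------------
    labels = None
    try:
        log.info("stage featcluster")
        order = [f"movie_{n}" for n in sg.MOVIE_NAMES]
        missing = [n for n in order if n not in dffs.dff]
        if missing:
            raise KeyError(f"missing movie blocks: {missing}")
        pre_n = int(round(2.0 * dffs.frame_rate))
        tm = {n: dffs.dff[n][kept, pre_n:, :].mean(axis=2) for n in order}
        D = fc.normalize_movie_responses(tm, order)
        feats = fc.extract_features(
            D, target_variance=config.cluster.target_variance,
            n_features=config.cluster.n_features)
        clustering = fc.scan_components(feats.X, config=config.cluster)
        result.features = feats
        result.clustering = clustering
        labels = clustering.labels
        bic_df = pd.DataFrame({
            "K": list(clustering.bic_curve),
            "bic": list(clustering.bic_curve.values()),
        })
        _write_csv(bic_df, out / "bic_curve.csv", config)
        lab_df = pd.DataFrame({"roi_id": gt.roi_id, "cluster": labels})
        _write_csv(lab_df, out / "cluster_labels.csv", config)
        model = {
            "K": clustering.K,
            "phi": clustering.phi.tolist(),
            "mu": clustering.mu.tolist(),
            "n_features": feats.n_features,
            "variance_explained": feats.variance_explained,
        }
        (out / "gmm_model.json").write_text(json.dumps(model))
    except Exception as err:  # noqa: BLE001
        log.error("stage featcluster failed: %s", err)
        result.stages_failed["featcluster"] = str(err)

    # --- stability --------------------------------------------------------
    if labels is not None:
        try:
            log.info("stage stability (%d subsets)", config.stability.n_subsets)
            rep = st.stability_report(
                result.features.X, result.clustering, D=result.features.D,
                fraction=config.stability.fraction,
                n_subsets=config.stability.n_subsets,
                seed=config.stability.seed, n_init=config.stability.n_init)
            result.stability = rep
            _write_csv(rep.jsc_per_cluster, out / "stability_jsc.csv", config)
            _write_csv(rep.distance_table, out / "stability_distance.csv",
                       config)
            _write_csv(rep.correlation_hist,
                       out / "stability_correlation.csv", config)
            np.save(out / "coassociation.npy", rep.cam)
        except Exception as err:  # noqa: BLE001
            log.error("stage stability failed: %s", err)
            result.stages_failed["stability"] = str(err)
    else:
        log.warning("stage stability skipped: no clustering available")

    # --- receptive fields -------------------------------------------------
    rfs_vec = None
    try:
        log.info("stage rf")
        if "sparse_noise" not in dffs.dff:
            raise KeyError("sparse_noise block missing; rf stage skipped")
        maps = rfmod.sparse_noise_maps(dffs.dff["sparse_noise"][kept],
                                       dffs.schedules["sparse_noise"])
        fits = rfmod.fit_population(maps, config.rf,
                                    seed=config.session.seed + 11)
        fits["roi_id"] = gt.roi_id.to_numpy()
        result.rf_fits = fits
        rfs_vec = np.where(fits.clear, fits.rfs, np.nan)
        _write_csv(fits, out / "rf_fits.csv", config)
        if labels is not None:
            summary = rfmod.cluster_rf_summary(fits, labels, config.rf)
            result.rf_summary = summary
            _write_csv(summary, out / "rf_cluster_summary.csv", config)
    except Exception as err:  # noqa: BLE001
        log.error("stage rf failed: %s", err)
        result.stages_failed["rf"] = str(err)

    # --- tuning -----------------------------------------------------------
    try:
        log.info("stage tuning")
        battery = ("bar", "looming", "chirp", "color", "size")
        missing = [b for b in battery if b not in dffs.dff]
        if missing:
            raise KeyError(f"battery stimuli missing from store: {missing}; "
                           "tuning stage skipped")
        sub = pp.DffSession(
            dff={k: v[kept] for k, v in dffs.dff.items()},
            snr=dffs.snr, audit=dffs.audit, kept=np.arange(len(kept)),
            schedules=dffs.schedules, frame_rate=dffs.frame_rate)
        profiles = tn.compute_profiles(sub, rfs=rfs_vec)
        profiles["roi_id"] = gt.roi_id.to_numpy()
        result.profiles = profiles
        _write_csv(profiles, out / "tuning_profiles.csv", config)
        if labels is not None:
            means, norm, mask = tn.cluster_si_table(profiles, labels)
            si = norm.copy()
            si[mask] = np.nan
            si.insert(0, "cluster", si.index)
            _write_csv(si.reset_index(drop=True), out / "cluster_si.csv",
                       config)
            contrib, cum, ptab = tn.composition_analysis(
                labels, gt.functional_type.to_numpy(),
                n_perm=config.tuning.n_perm, seed=config.tuning.seed)
            _write_csv(contrib.reset_index(), out / "composition.csv", config)
            _write_csv(ptab, out / "composition_pvalues.csv", config)
    except Exception as err:  # noqa: BLE001
        log.error("stage tuning failed: %s", err)
        result.stages_failed["tuning"] = str(err)

    # --- anatomy ----------------------------------------------------------
    try:
        log.info("stage anatomy")
        if labels is None:
            raise RuntimeError("no clustering; anatomy stage skipped")
        positions = gt[["x_um", "y_um"]].to_numpy()
        result.drp_table = an.drp_all_clusters(positions, labels,
                                               config.anatomy)
        _write_csv(result.drp_table, out / "drp_summary.csv", config)
        pre_n = int(round(2.0 * dffs.frame_rate))
        order = [f"movie_{n}" for n in sg.MOVIE_NAMES]
        traces = np.concatenate(
            [dffs.dff[n][kept, pre_n:, :].mean(axis=2) for n in order], axis=1)
        _, pct = an.group_breakdown(
            labels, gt.depth_um.to_numpy(), gt.genotype.to_numpy(), traces,
            depth_edges=config.anatomy.depth_edges)
        _write_csv(pct, out / "group_breakdown.csv", config)
    except Exception as err:  # noqa: BLE001
        log.error("stage anatomy failed: %s", err)
        result.stages_failed["anatomy"] = str(err)

    _figures(result)
    _report(result, time.time() - t_start)
    return result


# ---------------------------------------------------------------------------
# report

def _figures(result: PipelineResult) -> None:
    out = result.output_dir
    if result.clustering is not None:
        fig, ax = plt.subplots(figsize=(4, 3))
        ks = list(result.clustering.bic_curve)
        ax.plot(ks, [result.clustering.bic_curve[k] for k in ks], "o-")
        ax.axvline(result.clustering.K, color="r", ls="--")
        ax.set_xlabel("number of components K")
        ax.set_ylabel("BIC")
        fig.tight_layout()
        fig.savefig(out / "bic_curve.svg")
        plt.close(fig)
    if result.stability is not None:
        fig, ax = plt.subplots(figsize=(4, 3))
        jsc = result.stability.jsc_per_cluster
        ax.errorbar(jsc.cluster, jsc.jsc_mean, yerr=jsc.jsc_sd, fmt="o")
        ax.axhline(0.5, color="r", ls="--")
        ax.set_xlabel("cluster")
        ax.set_ylabel("Jaccard similarity")
        ax.set_ylim(0, 1.05)
        fig.tight_layout()
        fig.savefig(out / "stability_jsc.svg")
        plt.close(fig)
        fig, ax = plt.subplots(figsize=(4, 3.5))
        im = ax.imshow(result.stability.between_cluster_rate, cmap="viridis",
                       vmin=0, vmax=1)
        fig.colorbar(im, ax=ax, label="co-clustering rate")
        ax.set_xlabel("cluster")
        ax.set_ylabel("cluster")
        fig.tight_layout()
        fig.savefig(out / "between_cluster_rate.svg")
        plt.close(fig)
    if result.clustering is not None and result.features is not None:
        means = np.stack([
            result.features.D[result.clustering.labels == c].mean(axis=0)
            for c in range(result.clustering.K)
        ])
        fig, ax = plt.subplots(figsize=(6, 5))
        for i, tr in enumerate(means):
            ax.plot(tr + i * 1.2, lw=0.8)
        ax.set_xlabel("time (samples, movies concatenated)")
        ax.set_yticks([])
        ax.set_title("cluster mean temporal profiles")
        fig.tight_layout()
        fig.savefig(out / "cluster_profiles.svg")
        plt.close(fig)
    if result.rf_summary is not None:
        fig, axes = plt.subplots(1, 2, figsize=(7, 3))
        rs = result.rf_summary
        axes[0].bar(rs.cluster, 100 * rs.clear_fraction)
        axes[0].axhline(80, color="b", ls="--")
        axes[0].set_xlabel("cluster")
        axes[0].set_ylabel("% clear RFs")
        srt = rs.sort_values("coverage_deg2")
        axes[1].plot(range(len(srt)), srt.coverage_deg2, "o-")
        axes[1].axhline(900, color="b", ls="--")
        axes[1].set_xlabel("cluster (sorted)")
        axes[1].set_ylabel("RF coverage (deg$^2$)")
        fig.tight_layout()
        fig.savefig(out / "rf_summary.svg")
        plt.close(fig)


def _report(result: PipelineResult, elapsed: float) -> None:
    cfg = result.config
    lines = [
        f"# colliclust report — run `{cfg.run_id}`",
        "",
        f"- config hash: `{cfg.hash()}`, seed: {cfg.seed}",
        f"- elapsed: {elapsed:.0f} s",
        f"- ROIs kept: {len(result.dffs.kept) if result.dffs else 0}"
        f" / {result.session.n_rois if result.session else 0}",
        "",
    ]
    if result.clustering is not None:
        lines += [
            f"## Clustering",
            f"- best K by BIC: **{result.clustering.K}** "
            f"(scan {min(result.clustering.bic_curve)}-"
            f"{max(result.clustering.bic_curve)})",
            f"- features: {result.features.n_features} "
            f"({100 * result.features.variance_explained:.1f}% variance)",
            "",
            "![BIC](bic_curve.svg)",
            "![profiles](cluster_profiles.svg)",
            "",
        ]
    if result.stability is not None:
        jsc = result.stability.jsc_per_cluster
        lines += [
            "## Stability",
            f"- min cluster JSC: {jsc.jsc_mean.min():.3f} "
            f"({'all stable' if jsc.stable.all() else 'UNSTABLE clusters'})",
            "",
            "![JSC](stability_jsc.svg)",
            "![between-cluster rate](between_cluster_rate.svg)",
            "",
        ]
    if result.rf_summary is not None:
        compact = (result.rf_summary.coverage_group == "compact").sum()
        lines += [
            "## Receptive fields",
            f"- clusters with compact (<900 deg²) coverage: {compact}",
            "",
            "![RF summary](rf_summary.svg)",
            "",
        ]
    if result.stages_failed:
        lines += ["## Stage failures", ""]
        lines += [f"- {k}: {v}" for k, v in result.stages_failed.items()]
    (result.output_dir / "report.md").write_text("\n".join(lines))
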