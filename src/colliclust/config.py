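"""Configuration objects for every pipeline stage.

All configs are plain dataclasses so they serialize losslessly to/from YAML
(`PipelineConfig.load` / `.save`). A single global seed is fanned out to
per-stage child seeds by fixed offsets so stages are independently
reproducible.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

# Stimulus geometry shared across modules.  The monitor subtends 106 x 79
# degrees centered at (95 az, 25 el); the sparse-noise grid is 11 x 11
# squares of 5 degrees centered on the monitor center.
MONITOR_SPAN_DEG = (106.0, 79.0)
MONITOR_CENTER_DEG = (95.0, 25.0)
SPARSE_GRID_N = 11
SPARSE_SQUARE_DEG = 5.0
FIELD_SIZE_UM = 600.0
SIZE_DIAMETERS_DEG = (2.0, 4.0, 8.0, 16.0, 32.0)
N_BAR_DIRECTIONS = 12


@dataclass
class SessionConfig:
    """Ground-truth session layout for the synthetic generator.

    ``cluster_separation`` is the mean between-cluster distance of the
    planted movie-response templates expressed in units of the
    within-cluster SD; 5.0 gives cleanly separable clusters comparable to
    the structure the clustering stage is designed to recover.
    """

    n_clusters: int = 16
    neurons_per_cluster: int = 200
    n_repetitions: int = 10
    frame_rate: float = 4.8
    noise_sd: float = 0.1
    cluster_separation: float = 5.0
    seed: int = 0
    movie_duration_s: float = 20.0
    movie_height_px: int = 48
    movie_width_px: int = 64
    n_compact_clusters: int = -1  # -1 -> half of n_clusters
    patch_radius_um: float = 100.0  # radius at which patch density halves
    n_unresponsive: int = 30
    out_of_bounds_fraction: float = 0.02  # ROIs with non-neuronal diameter
    drift_amp: float = 0.05
    neuropil_r: float = 0.7
    baseline_f: float = 1.0
    kinetics_tau_default: float = 0.5
    n_functional_types: int = 24

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.cluster_separation <= 0:
            raise ValueError("cluster_separation must be > 0")
        if self.n_repetitions < 2:
            raise ValueError("n_repetitions must be >= 2")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.n_compact_clusters < 0:
            self.n_compact_clusters = self.n_clusters // 2
        if self.n_compact_clusters > self.n_clusters:
            raise ValueError("n_compact_clusters cannot exceed n_clusters")


@dataclass
class PreprocessConfig:
    r: float = 0.7
    percentile: float = 8.0
    window_s: float = 15.0
    snr_threshold: float = 0.35
    roi_diameter_bounds: tuple[float, float] = (10.0, 20.0)
    snr_pooling: str = "max"  # max across stimuli, or a stimulus name

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("neuropil factor r must be in [0, 1]")
        if not 0.0 < self.percentile < 100.0:
            raise ValueError("percentile must be in (0, 100)")
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")


@dataclass
class ClusterConfig:
    kmin: int = 2
    kmax: int = 30
    n_init: int = 50
    covariance: str = "full"
    target_variance: float = 0.70
    n_features: int | None = None
    reg_covar: float = 1e-6
    max_iter: int = 200
    seed: int = 0


@dataclass
class StabilityConfig:
    n_subsets: int = 100
    fraction: float = 0.9
    n_init: int = 3
    seed: int = 0


@dataclass
class TuningConfig:
    n_perm: int = 1000
    seed: int = 0


@dataclass
class RfConfig:
    clear_r2: float = 0.5
    coverage_threshold_deg2: float = 900.0
    raster_resolution_deg: float = 0.5
    n_starts: int = 10


@dataclass
class AnatomyConfig:
    bin_width_um: float = 20.0
    max_radius_um: float = 300.0
    n_mc: int = 10_000
    min_neurons: int = 6  # DRP needs > 5 neurons in the field
    depth_edges: tuple[float, ...] = (0.0, 100.0, 400.0)
    seed: int = 0


@dataclass
class PipelineConfig:
    session: SessionConfig = field(default_factory=SessionConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    tuning: TuningConfig = field(default_factory=TuningConfig)
    rf: RfConfig = field(default_factory=RfConfig)
    anatomy: AnatomyConfig = field(default_factory=AnatomyConfig)
    run_id: str = "run"
    output_dir: str = "colliclust_out"
    seed: int = 0

    def __post_init__(self) -> None:
        self.apply_seed(self.seed)

    def apply_seed(self, seed: int) -> None:
        """Fan the global seed out to per-stage child seeds (fixed offsets)."""
        self.seed = int(seed)
        base = int(seed) % (2**31 - 1000)
        self.session.seed = base
        self.cluster.seed = base + 1
        self.stability.seed = base + 2
        self.tuning.seed = base + 3
        self.anatomy.seed = base + 4

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for key, sub in [
            ("session", SessionConfig), ("preprocess", PreprocessConfig),
            ("cluster", ClusterConfig), ("stability", StabilityConfig),
            ("tuning", TuningConfig), ("rf", RfConfig), ("anatomy", AnatomyConfig),
        ]:
            if key in kwargs and isinstance(kwargs[key], dict):
                sub_kwargs = dict(kwargs[key])
                for tup_field in ("roi_diameter_bounds", "depth_edges"):
                    if tup_field in sub_kwargs and isinstance(sub_kwargs[tup_field], list):
                        sub_kwargs[tup_field] = tuple(sub_kwargs[tup_field])
                kwargs[key] = sub(**sub_kwargs)
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        """Hash of the scientific configuration (bookkeeping fields like
        the output directory and run id are excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        d.pop("run_id", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
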