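"""Shared fixtures: small synthetic sessions generated at test time."""
from __future__ import annotations

import numpy as np
import pytest

from colliclust.config import PipelineConfig, PreprocessConfig, SessionConfig
from colliclust import preprocess as pp
from colliclust import synthgen as sg


@pytest.fixture(scope="session")
def tiny_config() -> SessionConfig:
    """3 planted clusters x 30 neurons, short movies; fast everywhere."""
    return SessionConfig(n_clusters=3, neurons_per_cluster=30, seed=7,
                         movie_duration_s=10.0, n_unresponsive=5)


@pytest.fixture(scope="session")
def tiny_session(tiny_config) -> sg.Session:
    return sg.generate_session(tiny_config)


@pytest.fixture(scope="session")
def tiny_dffs(tiny_session) -> pp.DffSession:
    return pp.preprocess_session(tiny_session, PreprocessConfig())


@pytest.fixture(scope="session")
def noiseless_session() -> sg.Session:
    """Zero-noise, zero-drift session for exact-recovery checks."""
    cfg = SessionConfig(n_clusters=3, neurons_per_cluster=20, seed=4,
                        noise_sd=0.0, drift_amp=0.0, movie_duration_s=10.0,
                        n_unresponsive=0, out_of_bounds_fraction=0.0)
    return sg.generate_session(cfg)


@pytest.fixture(scope="session")
def noiseless_dffs(noiseless_session) -> pp.DffSession:
    return pp.preprocess_session(noiseless_session, PreprocessConfig())


def kept_dffs(dffs: pp.DffSession) -> pp.DffSession:
    """Restrict a DffSession to its gated ROIs."""
    return pp.DffSession(
        dff={k: v[dffs.kept] for k, v in dffs.dff.items()},
        snr=dffs.snr, audit=dffs.audit,
        kept=np.arange(len(dffs.kept)),
        schedules=dffs.schedules, frame_rate=dffs.frame_rate)
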