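"""Shared fixtures: small synthetic subjects and session-scoped study runs.

The heavy study fixtures (calibration, recovery, oscillation) are session
scoped so the acceptance tests and module-level recovery tests share one
computation each.
"""

from __future__ import annotations

import numpy as np
import pytest

from syncnet import pipeline, studies
from syncnet.sim import CouplingEdge, SimConfig, generate_cohort, generate_subject


@pytest.fixture(scope="session")
def tiny_subject():
    """One no-effect subject with a retrieval period (fast)."""
    cfg = SimConfig(
        rois=studies.ROIS6[:3], n_subjects=1, n_lists=2, words_per_list=12,
        include_retrieval=True, seed=5,
    )
    return cfg, generate_subject(cfg, 0)


@pytest.fixture(scope="session")
def coupled_subject():
    """One subject with a strongly theta-coupled ROI pair (fast)."""
    cfg = SimConfig(
        rois=studies.ROIS6[:3], n_subjects=1, n_lists=4, words_per_list=12,
        p_recall=0.5,
        coupling_graph=(
            CouplingEdge("L-hippocampus", "L-middle-frontal", kappa_rem=8.0,
                         kappa_nrem=0.5, freq=6.0, amplitude=3.0),
        ),
        include_retrieval=False, seed=6,
    )
    return cfg, generate_subject(cfg, 0)


@pytest.fixture(scope="session")
def calibration_results():
    """Null-calibration study on the no-effect cohort (8 subjects)."""
    return studies.calibration_study(seed=11)


@pytest.fixture(scope="session")
def theta_recovery_bundle():
    """Encoding run on the single-injected-theta-pair cohort."""
    cfg = pipeline.RunConfig(
        sim=studies.theta_pair_config(seed=21), n_perm=500, min_subjects=7,
        seed=21,
    )
    return pipeline.run_encoding(cfg)


@pytest.fixture(scope="session")
def crossband_bundle():
    """Encoding run on the co-located HG-power/HG-decoupling/theta cohort."""
    cfg = pipeline.RunConfig(
        sim=studies.crossband_config(seed=31), n_perm=500, min_subjects=7,
        seed=31,
    )
    return pipeline.run_encoding(cfg)


@pytest.fixture(scope="session")
def burst_subnet_bundle():
    """Oscillation-subnetwork run on the phase-locked 52 Hz burst cohort."""
    cfg = pipeline.RunConfig(
        sim=studies.burst_config(seed=41), n_perm=500, min_subjects=7, seed=41,
    )
    return pipeline.run_oscillation_subnet(cfg)


@pytest.fixture(scope="session")
def retrieval_bundle():
    """Retrieval-contrast run on the theta-coupled retrieval cohort."""
    cfg = pipeline.RunConfig(
        sim=studies.retrieval_config(seed=51), contrast="retrieval",
        n_perm=500, min_subjects=7, seed=51,
    )
    return pipeline.run_retrieval(cfg)
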