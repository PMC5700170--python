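"""Canned study configurations and summary runners.

These functions define the synthetic study conditions under which the
package's statistical properties are established — null calibration of the
edge z-test, recovery of injected coupling and power effects, and
oscillation detection — and are shared by the test-suite and the
reproduction script so both exercise identical conditions.

Design notes
------------
The no-effect calibration cohort follows the exchangeable-by-construction
design: coupled ROI pairs carry *equal* phase-locking concentration in both
conditions (kappa_rem = kappa_nrem = 8), so trial labels are exchangeable
while the phase-difference distributions are concentrated.  Concentration
matters for tail calibration: with uniform phase differences the D
statistic's null is visibly short-tailed (|z| > 1.96 under ~3.3% instead of
5%), whereas with a common von Mises concentration its tails are close to
normal.  Both regimes are conservative; the coupled pairs provide the
calibration measurement and the uncoupled pairs a conservativeness check.
"""

from __future__ import annotations

import numpy as np

from .preprocess import (
    ENCODING_SPAN_MS,
    bipolar_montage,
    epoch_encoding,
    notch_filter,
    resample_to_analysis_rate,
)
from .sim import BurstSpec, CouplingEdge, PowerEffect, SimConfig, generate_subject
from .spectral import THETA_FREQS, morlet_decompose, window_starts_ms
from .synchrony import compute_pair_stats, make_label_perms, zscore_stat
from .network import pool_across_subjects, pool_to_roi_pair

ROIS6 = (
    "L-hippocampus",
    "L-middle-frontal",
    "R-superior-temporal",
    "L-precuneus",
    "R-cingulate",
    "L-fusiform",
)

ROIS12 = (
    "L-hippocampus",
    "L-middle-frontal",
    "L-inferior-frontal",
    "L-superior-temporal",
    "L-fusiform",
    "L-inferior-parietal",
    "R-hippocampus",
    "R-middle-frontal",
    "R-superior-temporal",
    "R-precuneus",
    "R-cingulate",
    "R-middle-occipital",
)

#: "memory network" members of ROIS12, deliberately non-contiguous in the
#: sorted ROI order so cyclic shifts of the flattened vectors cannot re-align
#: active blocks
MEMORY_ROIS = (
    "L-hippocampus",
    "L-middle-frontal",
    "L-superior-temporal",
    "R-hippocampus",
    "R-superior-temporal",
    "R-cingulate",
)


def no_effect_config(seed: int = 11, n_subjects: int = 8, n_lists: int = 17) -> SimConfig:
    """No-condition-effect cohort: equal kappas on three disjoint ROI pairs.

    Each coupled pair carries stationary common coupling (equal moderate
    kappa in both conditions) at 4, 6, and 8 Hz across the whole epoch, so
    every theta cell of a coupled pair sees a moderately concentrated,
    condition-independent phase-difference distribution.
    """
    edges = tuple(
        CouplingEdge(ROIS6[2 * i], ROIS6[2 * i + 1], kappa_rem=1.5, kappa_nrem=1.5,
                     freq=f, amplitude=3.0, time_range_ms=(0.0, 2400.0))
        for i in range(3)
        for f in (4.0, 6.0, 8.0)
    )
    return SimConfig(
        rois=ROIS6, n_subjects=n_subjects, n_lists=n_lists, words_per_list=12,
        coupling_graph=edges, include_retrieval=False, seed=seed,
    )


def theta_pair_config(seed: int = 21, n_subjects: int = 8) -> SimConfig:
    """One injected theta-coupled ROI pair (kappa 8 remembered vs 0.5)."""
    edge = CouplingEdge(
        "L-hippocampus", "L-middle-frontal", kappa_rem=8.0, kappa_nrem=0.5,
        freq=6.0, amplitude=3.0,
    )
    return SimConfig(
        rois=ROIS6, n_subjects=n_subjects, n_lists=8, words_per_list=12,
        coupling_graph=(edge,), include_retrieval=False, seed=seed,
    )


def crossband_config(seed: int = 31, n_subjects: int = 8) -> SimConfig:
    """HG power gains co-located with HG decoupling and theta coupling.

    Six "memory" ROIs receive (i) high-gamma band-power gains of varying
    size (remembered > not-remembered), (ii) high-gamma *de*coupling on a
    ring of edges among them (kappa_rem 0.5 vs kappa_nrem 8 at 70 Hz), and
    (iii) theta coupling on the same ring (kappa_rem 8 vs 0.5 at 6 Hz).
    Gains vary across ROIs so the power-synchrony correlation has a unique
    spatial alignment.
    """
    mem = MEMORY_ROIS
    gains = (1.8, 2.0, 2.2, 2.4, 2.6, 2.8)
    power = tuple(
        PowerEffect(roi, band=(65.0, 95.0), gain_rem=g, gain_nrem=1.0, amplitude=2.0)
        for roi, g in zip(mem, gains)
    )
    ring = [(mem[i], mem[(i + 1) % len(mem)]) for i in range(len(mem))]
    hg_edges = tuple(
        CouplingEdge(a, b, kappa_rem=0.5, kappa_nrem=8.0, freq=70.0,
                     phase_lag=0.0, amplitude=4.0)
        for a, b in ring
    )
    theta_edges = tuple(
        CouplingEdge(a, b, kappa_rem=8.0, kappa_nrem=0.5, freq=6.0, amplitude=3.0)
        for a, b in ring
    )
    return SimConfig(
        rois=ROIS12, n_subjects=n_subjects, n_lists=8, words_per_list=12,
        coupling_graph=hg_edges + theta_edges, power_effects=power,
        include_retrieval=False, seed=seed,
    )


def burst_config(seed: int = 41, n_subjects: int = 4) -> SimConfig:
    """Phase-locked 52 Hz bursts between two ROIs (p 0.6 vs 0.1), riding on
    broadband high-gamma decoupling between the same ROIs.

    The burst onset window (350-650 ms) centers bursts on the 400-600 ms
    analysis window where the oscillatory subsequent-memory effect is
    measured.  The co-injected decoupling (kappa 0.5 remembered vs 6
    not-remembered at 85 Hz) emulates the broadband asynchronous
    high-frequency component that coexists with rare narrowband
    oscillations; it also offsets the partial phase-locking a detectable
    52 Hz burst necessarily leaks into 65-85 Hz wavelets at wave number 5.
    """
    burst = BurstSpec(
        center_freq=52.0, n_cycles=16.0, p_burst_rem=0.6, p_burst_nrem=0.1,
        amplitude=2.5, rois=("L-hippocampus", "L-middle-frontal"),
        phase_locked=True, kappa=30.0, time_range_ms=(350.0, 650.0),
    )
    decouple = CouplingEdge(
        "L-hippocampus", "L-middle-frontal", kappa_rem=0.5, kappa_nrem=6.0,
        freq=85.0, amplitude=1.0, time_range_ms=(0.0, 1600.0),
    )
    return SimConfig(
        rois=ROIS6[:4], n_subjects=n_subjects, n_lists=10, words_per_list=12,
        burst_spec=(burst,), coupling_graph=(decouple,),
        include_retrieval=False, seed=seed,
    )


def retrieval_config(seed: int = 51, n_subjects: int = 8) -> SimConfig:
    """Theta-coupled cohort with recall periods, for the retrieval contrast."""
    edge = CouplingEdge(
        "L-hippocampus", "L-middle-frontal", kappa_rem=8.0, kappa_nrem=0.5,
        freq=6.0, amplitude=3.0,
    )
    return SimConfig(
        rois=ROIS6[:4], n_subjects=n_subjects, n_lists=6, words_per_list=12,
        p_recall=0.4, coupling_graph=(edge,), include_retrieval=True, seed=seed,
    )


def calibration_study(seed: int = 11, n_subjects: int = 8, n_lists: int = 17) -> dict:
    """Null-calibration measurements on the no-effect cohort.

    Returns electrode-level z-cells for coupled and uncoupled pairs (theta
    grid, all 18 windows) and the pooled theta ROI network for the
    summed-weight/hub calibration.
    """
    cfg = no_effect_config(seed=seed, n_subjects=n_subjects, n_lists=n_lists)
    roi_sorted = sorted(cfg.rois)
    coupled_keys = {
        tuple(sorted((ROIS6[2 * i], ROIS6[2 * i + 1]))) for i in range(3)
    }
    z_coupled, z_uncoupled, pools = [], [], []
    for s in range(cfg.n_subjects):
        sub = generate_subject(cfg, s)
        bip = resample_to_analysis_rate(notch_filter(bipolar_montage(sub.raw, sub.electrodes)))
        ep = epoch_encoding(bip, sub.events)
        tensor = morlet_decompose(ep, THETA_FREQS)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1000 + s]))
        perms = make_label_perms(ep.condition, 500, rng)
        roi_of = list(ep.pairs["roi"])
        idx_pairs = [
            (i, j) for i in range(len(roi_of)) for j in range(i + 1, len(roi_of))
        ]
        meta = [(f"{i}-{j}", roi_of[i], roi_of[j]) for i, j in idx_pairs]
        stats = compute_pair_stats(tensor, idx_pairs, 200.0, perms, meta)
        for st in stats:
            z, _ = zscore_stat(st.d_true, st.d_null)
            key = tuple(sorted((st.roi_a, st.roi_b)))
            (z_coupled if key in coupled_keys else z_uncoupled).append(z.ravel())
        pools.append(pool_to_roi_pair(stats))
    net = pool_across_subjects(
        pools, roi_sorted, THETA_FREQS, window_starts_ms(ENCODING_SPAN_MS, 200.0)
    )
    return {
        "cfg": cfg,
        "z_coupled": np.concatenate(z_coupled),
        "z_uncoupled": np.concatenate(z_uncoupled),
        "net": net,
    }
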