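"""ROI-level network construction, summed-weight, hub, and timecourse tests.

Electrode-pair D statistics are pooled hierarchically: averaged across
electrode pairs spanning an ROI pair within a subject, then across subjects
(true values and null distributions averaged replicate-by-replicate).  The
z-score of the pooled true D against the pooled null is the connection
weight.  ROI pairs sampled by fewer than ``min_subjects`` subjects are
zeroed (coverage mask).  Every functional applied to the true network is
applied identically to each of the null networks, whose weights are the
z-scored null replicates; P-values use the plus-one rule
P = (1 + #{null beats true}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import rois as roilib
from .spectral import band_indices
from .synchrony import PairSyncStat, zscore_stat

DEFAULT_MIN_SUBJECTS = 7

PairKey = tuple[str, str]


def _pair_key(roi_a: str, roi_b: str) -> PairKey:
    return (roi_a, roi_b) if roi_a <= roi_b else (roi_b, roi_a)


def pool_to_roi_pair(
    stats: list[PairSyncStat],
) -> dict[PairKey, tuple[np.ndarray, np.ndarray]]:
    """Within-subject pooling: mean D_true and replicate-wise mean null
    across all electrode pairs spanning each ROI pair (self-pairs dropped)."""
    groups: dict[PairKey, list[PairSyncStat]] = {}
    for st in stats:
        if st.roi_a == st.roi_b:
            continue
        groups.setdefault(_pair_key(st.roi_a, st.roi_b), []).append(st)
    return {
        key: (
            np.mean([s.d_true for s in grp], axis=0),
            np.mean([s.d_null for s in grp], axis=0),
        )
        for key, grp in groups.items()
    }


@dataclass
class RoiNetwork:
    """Symmetric ROI-pair network with pooled true/null statistics.

    Stored in condensed form: ``pairs[e]`` names the e-th sampled ROI pair,
    ``d_true`` is (E, F, W) and ``d_null`` (E, P, F, W).  ``covered`` marks
    pairs passing the coverage mask; uncovered pairs contribute zero weight
    everywhere.
    """

    rois: list[str]
    pairs: list[PairKey]
    d_true: np.ndarray
    d_null: np.ndarray
    subject_count: np.ndarray
    freqs: np.ndarray
    window_starts_ms: np.ndarray
    covered: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.covered is None:
            self.covered = np.ones(len(self.pairs), dtype=bool)

    @property
    def n_perm(self) -> int:
        return self.d_null.shape[1]

    def zscores(self) -> tuple[np.ndarray, np.ndarray]:
        """(z_true (E,F,W), z_null (E,P,F,W)); uncovered pairs zeroed."""
        mu = self.d_null.mean(axis=1)
        sd = self.d_null.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z_true = np.where(sd > 0, (self.d_true - mu) / sd, 0.0)
            z_null = np.where(
                sd[:, None] > 0, (self.d_null - mu[:, None]) / sd[:, None], 0.0
            )
        z_true[~self.covered] = 0.0
        z_null[~self.covered] = 0.0
        return z_true, z_null

    def pair_indices(self) -> np.ndarray:
        index = {r: i for i, r in enumerate(self.rois)}
        return np.array([(index[a], index[b]) for a, b in self.pairs])

    def to_matrix(self, f_idx: int = 0, w_idx: int = 0) -> np.ndarray:
        """Dense symmetric z matrix at one (frequency, window) cell."""
        z_true, _ = self.zscores()
        m = np.zeros((len(self.rois), len(self.rois)))
        for e, (ia, ib) in enumerate(self.pair_indices()):
            m[ia, ib] = m[ib, ia] = z_true[e, f_idx, w_idx]
        return m


def pool_across_subjects(
    subject_pools: list[dict[PairKey, tuple[np.ndarray, np.ndarray]]],
    rois: list[str],
    freqs: np.ndarray,
    window_starts_ms: np.ndarray,
) -> RoiNetwork:
    """Across-subject pooling of per-subject ROI-pair statistics."""
    keys = sorted({k for pool in subject_pools for k in pool})
    if not keys:
        raise ValueError("no ROI pairs sampled in any subject")
    d_true, d_null, counts = [], [], []
    for key in keys:
        trues = [pool[key][0] for pool in subject_pools if key in pool]
        nulls = [pool[key][1] for pool in subject_pools if key in pool]
        d_true.append(np.mean(trues, axis=0))
        d_null.append(np.mean(nulls, axis=0))
        counts.append(len(trues))
    return RoiNetwork(
        rois=list(rois),
        pairs=keys,
        d_true=np.asarray(d_true, dtype=np.float32),
        d_null=np.asarray(d_null, dtype=np.float32),
        subject_count=np.asarray(counts),
        freqs=np.asarray(freqs, dtype=float),
        window_starts_ms=np.asarray(window_starts_ms, dtype=float),
    )


def apply_coverage_mask(
    net: RoiNetwork, min_subjects: int = DEFAULT_MIN_SUBJECTS
) -> RoiNetwork:
    """Zero out ROI pairs represented by fewer than ``min_subjects`` subjects."""
    covered = net.subject_count >= min_subjects
    return replace(net, covered=covered)


def exclusion_report(net: RoiNetwork) -> dict:
    """Accounting of masked pairs (interhemispheric share, totals)."""
    excluded = [p for p, c in zip(net.pairs, net.covered) if not c]
    inter = [p for p in excluded if roilib.is_interhemispheric(*p)]
    n_possible = roilib.n_roi_pairs(len(net.rois))
    return {
        "n_possible_pairs": n_possible,
        "n_sampled": len(net.pairs),
        "n_excluded": len(excluded),
        "n_excluded_interhemispheric": len(inter),
        "interhemispheric_fraction_pct": (
            100.0 * len(inter) / len(excluded) if excluded else 0.0
        ),
    }


def band_time_average(
    net: RoiNetwork,
    band: str | tuple[float, float] | None = None,
    window_idx: np.ndarray | None = None,
) -> RoiNetwork:
    """Average true and null D over band frequencies and selected windows.

    The z-score of the averaged statistic is computed against the averaged
    null; returns a network with a single (frequency, window) cell.
    """
    f_idx = (
        band_indices(net.freqs, band) if band is not None
        else np.arange(net.freqs.size)
    )
    w_idx = (
        np.asarray(window_idx) if window_idx is not None
        else np.arange(net.window_starts_ms.size)
    )
    d_true = net.d_true[:, f_idx][:, :, w_idx].mean(axis=(1, 2), keepdims=True)
    d_null = net.d_null[:, :, f_idx][:, :, :, w_idx].mean(axis=(2, 3), keepdims=True)
    return replace(
        net,
        d_true=d_true,
        d_null=d_null,
        freqs=np.array([net.freqs[f_idx].mean()]),
        window_starts_ms=np.array([net.window_starts_ms[w_idx][0]]),
    )


def _rank_p(true: float, null: np.ndarray, tail: str) -> float:
    if tail == "+":
        beats = np.sum(null >= true)
    else:
        beats = np.sum(null <= true)
    return (1.0 + beats) / (1.0 + null.size)


def summed_weight_test(net: RoiNetwork, sign: str = "+") -> dict:
    """Network-wide summed positive (or negative) connection weights vs. null.

    Expects a banded network (single frequency/window cell).
    """
    z_true, z_null = net.zscores()
    zt = z_true[:, 0, 0]
    zn = z_null[:, :, 0, 0]
    if sign == "+":
        s_true = zt[zt > 0].sum()
        s_null = np.where(zn > 0, zn, 0.0).sum(axis=0)
    elif sign == "-":
        s_true = zt[zt < 0].sum()
        s_null = np.where(zn < 0, zn, 0.0).sum(axis=0)
    else:
        raise ValueError("sign must be '+' or '-'")
    sd = s_null.std(ddof=1)
    z = (s_true - s_null.mean()) / sd if sd > 0 else 0.0
    return {
        "sum": float(s_true),
        "z": float(z),
        "p": _rank_p(s_true, s_null, sign),
        "null_mean": float(s_null.mean()),
        "null_sd": float(s_null.std(ddof=1)),
    }


def _strengths(
    net: RoiNetwork, sign: str | None, f_idx: int = 0, w_idx: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Node strengths (R,) and null strengths (P, R) at one cell."""
    z_true, z_null = net.zscores()
    zt = z_true[:, f_idx, w_idx]
    zn = z_null[:, :, f_idx, w_idx]  # (E, P)
    if sign == "+":
        zt = np.where(zt > 0, zt, 0.0)
        zn = np.where(zn > 0, zn, 0.0)
    elif sign == "-":
        zt = np.where(zt < 0, zt, 0.0)
        zn = np.where(zn < 0, zn, 0.0)
    n_rois = len(net.rois)
    k_true = np.zeros(n_rois)
    k_null = np.zeros((net.n_perm, n_rois))
    for e, (ia, ib) in enumerate(net.pair_indices()):
        k_true[ia] += zt[e]
        k_true[ib] += zt[e]
        k_null[:, ia] += zn[e]
        k_null[:, ib] += zn[e]
    return k_true, k_null


def node_strength(net: RoiNetwork, sign: str | None = None) -> pd.Series:
    """Node strength k_i = sum_j w_ij over the chosen sign (banded network)."""
    k_true, _ = _strengths(net, sign)
    return pd.Series(k_true, index=net.rois, name="strength")


def hub_test(net: RoiNetwork, sign: str = "+", alpha: float = 0.05) -> pd.DataFrame:
    """Per-ROI node-strength permutation test, BH-corrected across ROIs.

    ``sign='+'`` tests for synchronous hubs (strength above chance in the
    upper tail); ``sign='-'`` for asynchronous hubs (lower tail).
    """
    k_true, k_null = _strengths(net, sign)
    tail = "+" if sign == "+" else "-"
    p = np.array([_rank_p(k_true[i], k_null[:, i], tail) for i in range(len(net.rois))])
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    null_mu, null_sd = k_null.mean(axis=0), k_null.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(null_sd > 0, (k_true - null_mu) / null_sd, 0.0)
    return pd.DataFrame(
        {
            "roi": net.rois,
            "strength": k_true,
            "z": z,
            "p": p,
            "p_fdr": p_adj,
            "hub": reject,
        }
    )


def strength_timecourse(
    net: RoiNetwork,
    band: str | tuple[float, float] | None = None,
    sign: str = "+",
    roi_subset: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Frequency-averaged node strength per time window vs. its null.

    Returns one row per (ROI, window) with z, P, and significance flag;
    statistics are never smoothed (smoothing is a plotting concern only).
    """
    f_idx = (
        band_indices(net.freqs, band) if band is not None
        else np.arange(net.freqs.size)
    )
    d_true = net.d_true[:, f_idx].mean(axis=1, keepdims=True)
    d_null = net.d_null[:, :, f_idx].mean(axis=2, keepdims=True)
    banded = replace(net, d_true=d_true, d_null=d_null, freqs=np.array([0.0]))
    rows = []
    rois_wanted = set(roi_subset) if roi_subset is not None else None
    tail = "+" if sign == "+" else "-"
    for w in range(net.window_starts_ms.size):
        k_true, k_null = _strengths(banded, sign, f_idx=0, w_idx=w)
        for i, roi in enumerate(net.rois):
            if rois_wanted is not None and roi not in rois_wanted:
                continue
            p = _rank_p(k_true[i], k_null[:, i], tail)
            sd = k_null[:, i].std(ddof=1)
            z = (k_true[i] - k_null[:, i].mean()) / sd if sd > 0 else 0.0
            rows.append(
                {
                    "roi": roi,
                    "region": roilib.hemisphere(roi) + "-" + roilib.lobe(roi),
                    "window_start_ms": net.window_starts_ms[w],
                    "strength": k_true[i],
                    "z": z,
                    "p": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


def strength_zmap(net: RoiNetwork, sign: str | None = None) -> np.ndarray:
    """Z-scored node strength per (ROI, frequency, window) against its null."""
    z_true, z_null = net.zscores()  # (E, F, W), (E, P, F, W)
    if sign == "+":
        z_true = np.where(z_true > 0, z_true, 0.0)
        z_null = np.where(z_null > 0, z_null, 0.0)
    elif sign == "-":
        z_true = np.where(z_true < 0, z_true, 0.0)
        z_null = np.where(z_null < 0, z_null, 0.0)
    n_rois = len(net.rois)
    k_true = np.zeros((n_rois,) + z_true.shape[1:])
    k_null = np.zeros((n_rois,) + z_null.shape[1:])
    for e, (ia, ib) in enumerate(net.pair_indices()):
        k_true[ia] += z_true[e]
        k_true[ib] += z_true[e]
        k_null[ia] += z_null[e]
        k_null[ib] += z_null[e]
    mu = k_null.mean(axis=1)
    sd = k_null.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sd > 0, (k_true - mu) / sd, 0.0)


def network_to_edge_list(net: RoiNetwork, band_tag: str = "") -> pd.DataFrame:
    """Long-form edge list (roi_a, roi_b, freq, window, z, n_subjects)."""
    z_true, _ = net.zscores()
    rows = []
    for e, (a, b) in enumerate(net.pairs):
        for fi, f in enumerate(net.freqs):
            for wi, w0 in enumerate(net.window_starts_ms):
                rows.append(
                    {
                        "roi_a": a, "roi_b": b, "band": band_tag, "freq": f,
                        "window_start_ms": w0, "z": z_true[e, fi, wi],
                        "n_subjects": net.subject_count[e],
                        "covered": bool(net.covered[e]),
                    }
                )
    return pd.DataFrame(rows)
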