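"""Narrowband-oscillation detection (BOSC / P_episode) and oscillatory SME.

An oscillation at frequency f is declared when wavelet power exceeds a
power threshold *and* stays above it for at least three cycles (3/f s).
The threshold is the 95th percentile of the chi-square(2) distribution of
wavelet power scaled to a background estimate, itself a robust linear fit
of log power vs. log frequency (so narrowband peaks do not inflate the
background).  The fraction of each 200 ms window occupied by oscillations
(P_episode) feeds a remembered vs. not-remembered Welch-t contrast per
time-frequency pixel, BH-corrected per electrode; the electrodes that carry
an oscillatory SME define a sparse synchronization subnetwork.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .power_sme import welch_t

#: duration criterion, in cycles
MIN_CYCLES = 3.0
#: percentile of the chi-square(2) power distribution used as threshold
THRESHOLD_PCT = 0.95


@dataclass
class BoscBackground:
    """Robust log-log background fit for one channel."""

    slope: float
    intercept: float
    freq_range: tuple[float, float]

    def mean_power(self, freq: float | np.ndarray) -> np.ndarray:
        """Estimated background mean power at a frequency."""
        return np.exp(self.intercept + self.slope * np.log(freq))

    def power_threshold(self, freq: float | np.ndarray) -> np.ndarray:
        """95th percentile of chi2(2) scaled to the background mean power."""
        return stats.chi2.ppf(THRESHOLD_PCT, 2) * self.mean_power(freq) / 2.0


def bosc_background_fit(
    freqs: np.ndarray, log_mean_power: np.ndarray
) -> BoscBackground:
    """Robust (IRLS, bisquare) linear fit of log mean power vs. log frequency."""
    freqs = np.asarray(freqs, float)
    y = np.asarray(log_mean_power, float)
    if freqs.size < 5:
        raise ValueError("background fit needs at least 5 frequencies")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in mean log power spectrum")
    X = sm.add_constant(np.log(freqs))
    fit = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight()).fit()
    return BoscBackground(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        freq_range=(float(freqs.min()), float(freqs.max())),
    )


def _enforce_min_run(mask: np.ndarray, min_len: int) -> np.ndarray:
    """Keep only runs of True along the last axis with length >= min_len."""
    shape = mask.shape
    flat = mask.reshape(-1, shape[-1])
    out = np.zeros_like(flat)
    n = shape[-1]
    for row in range(flat.shape[0]):
        m = flat[row]
        if not m.any():
            continue
        padded = np.concatenate([[False], m, [False]])
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for s, e in zip(starts, ends):
            if e - s >= min_len:
                out[row, s:e] = True
    return out.reshape(shape)


def bosc_detect(
    power: np.ndarray, freq: float, background: BoscBackground, fs: float
) -> np.ndarray:
    """Boolean oscillation mask for power timeseries at one frequency.

    ``power``: wavelet power (linear units), time on the last axis.  A
    sample is flagged iff it exceeds the power threshold and belongs to a
    supra-threshold run lasting at least three cycles.
    """
    lo, hi = background.freq_range
    if not (lo <= freq <= hi):
        raise ValueError(f"frequency {freq} Hz outside fitted range [{lo}, {hi}]")
    above = np.asarray(power) > background.power_threshold(freq)
    min_len = int(np.ceil(MIN_CYCLES * fs / freq))
    return _enforce_min_run(above, min_len)


def detect_trials(
    power: np.ndarray, freqs: np.ndarray, background: BoscBackground, fs: float
) -> np.ndarray:
    """Oscillation mask for (trial, freq, sample) power at grid frequencies."""
    out = np.zeros(power.shape, dtype=bool)
    for fi, f in enumerate(np.asarray(freqs, float)):
        out[:, fi] = bosc_detect(power[:, fi], f, background, fs)
    return out


def pepisode_fraction(
    mask: np.ndarray, fs: float, window_ms: float = 200.0
) -> np.ndarray:
    """Fraction of each non-overlapping window occupied by oscillation.

    ``mask``: (..., sample); returns (..., window) fractions in [0, 1].
    """
    k = int(round(window_ms * fs / 1000.0))
    n = mask.shape[-1]
    nw = n // k
    m = mask[..., : nw * k].reshape(mask.shape[:-1] + (nw, k))
    return m.mean(axis=-1)


def oscillatory_sme(
    fractions: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.1,
) -> dict:
    """Welch-t oscillatory SME per pixel, BH across the pixel family.

    ``fractions``: (trial, freq, window) P_episode values.  Returns t map,
    parametric two-sided P, BH-adjusted P, the significant-pixel mask, and
    whether the electrode is flagged (any surviving pixel).
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("each condition needs at least two trials")
    x, y = fractions[labels], fractions[~labels]
    t = welch_t(x, y)
    nx, ny = x.shape[0], y.shape[0]
    vx = x.var(axis=0, ddof=1) / nx
    vy = y.var(axis=0, ddof=1) / ny
    with np.errstate(invalid="ignore", divide="ignore"):
        df = (vx + vy) ** 2 / (vx**2 / (nx - 1) + vy**2 / (ny - 1))
    df = np.where(np.isfinite(df) & (df > 0), df, 1.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(vx + vy > 0, p, 1.0)  # constant pixels carry no evidence
    reject, p_adj, _, _ = multipletests(p.ravel(), alpha=alpha, method="fdr_bh")
    sig = reject.reshape(p.shape)
    return {
        "t": t,
        "p": p,
        "p_fdr": p_adj.reshape(p.shape),
        "significant": sig,
        "flagged": bool(sig.any()),
    }


def subnetwork_edge_counts(
    net,
    alpha: float = 0.05,
) -> dict:
    """Significant synchronous/asynchronous edge counts vs. chance.

    ``net`` is a (banded) RoiNetwork built from the oscillatory-electrode
    subset with no minimum-subject mask.  Edge significance at P < alpha
    (uncorrected, tail by sign); the same counting functional is applied to
    every null network to obtain the chance level.
    """
    d_true = net.d_true[:, 0, 0]
    d_null = net.d_null[:, :, 0, 0]  # (E, P)
    n_perm = d_null.shape[1]
    # true-edge P by null rank (plus-one), each tail
    ge = (1.0 + np.sum(d_null >= d_true[:, None], axis=1)) / (1.0 + n_perm)
    le = (1.0 + np.sum(d_null <= d_true[:, None], axis=1)) / (1.0 + n_perm)
    count_sync = int(np.sum(ge < alpha))
    count_async = int(np.sum(le < alpha))
    # same functional on each null network (rank within the null sample)
    order = np.argsort(np.argsort(d_null, axis=1), axis=1)  # ascending ranks
    ge_null = (n_perm - order) / n_perm  # fraction of nulls >= this replicate
    le_null = (order + 1.0) / n_perm
    sync_null = (ge_null < alpha).sum(axis=0)
    async_null = (le_null < alpha).sum(axis=0)

    def _summ(count: int, null_counts: np.ndarray, tail: str) -> dict:
        sd = null_counts.std(ddof=1)
        z = (count - null_counts.mean()) / sd if sd > 0 else 0.0
        beats = (
            np.sum(null_counts >= count) if tail == "+" else np.sum(null_counts <= count)
        )
        return {
            "count": count,
            "chance_mean": float(null_counts.mean()),
            "chance_sd": float(null_counts.std(ddof=1)),
            "z": float(z),
            "p": float((1.0 + beats) / (1.0 + n_perm)),
        }

    return {
        "synchronous": _summ(count_sync, sync_null, "+"),
        "asynchronous": _summ(count_async, async_null, "+"),
        "n_edges": int(d_true.size),
    }


def subnetwork_mean_z_by_freq(net) -> pd.DataFrame:
    """Z-scored mean subnetwork connection weight per frequency.

    Averages true and null D over edges and windows at each frequency, then
    z-scores the true mean against the null means.
    """
    d_true = net.d_true.mean(axis=(0, 2))  # (F,)
    d_null = net.d_null.mean(axis=(0, 3))  # (P, F)
    mu, sd = d_null.mean(axis=0), d_null.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (d_true - mu) / sd, 0.0)
    return pd.DataFrame({"freq": net.freqs, "mean_z": z})
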