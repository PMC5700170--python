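"""Correlations between spectral-power SME maps and node-strength maps.

Two correlation families:

* per-ROI: Pearson r between a region's z-scored power map and z-scored
  node-strength map across high-gamma time-frequency pixels, BH-corrected
  across ROIs;
* cross-band: band-averaged power and strength, flattened over
  (ROI x time window) with a fixed ROI-major order, correlated with
  significance from a cyclic-shift/mirror permutation that preserves the
  spatial and temporal dependence of the two maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .spectral import band_indices


@dataclass
class CorrelationResult:
    family: str  # 'per_roi' | 'cross_band'
    label: str  # ROI name or ROI-subset tag
    band_x: str
    band_y: str
    r: float
    p: float
    n: int


def roi_power_synchrony_corr(
    power_z: np.ndarray,
    strength_z: np.ndarray,
    rois: list[str],
    sampled: np.ndarray | None = None,
    pixel_mask: tuple[np.ndarray, np.ndarray] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-ROI Pearson correlation across time-frequency pixels.

    ``power_z`` and ``strength_z`` are (R, F, W) on matching grids;
    ``pixel_mask`` optionally restricts to (freq_idx, window_idx) (e.g. the
    high-gamma rows and item-presentation windows).  P-values are
    BH-corrected across ROIs.
    """
    if power_z.shape != strength_z.shape:
        raise ValueError("power and strength grids do not match")
    if pixel_mask is not None:
        f_idx, w_idx = pixel_mask
        power_z = power_z[:, f_idx][:, :, w_idx]
        strength_z = strength_z[:, f_idx][:, :, w_idx]
    if sampled is None:
        sampled = np.ones(len(rois), dtype=bool)
    rows = []
    for i, roi in enumerate(rois):
        if not sampled[i]:
            continue
        x = power_z[i].ravel()
        y = strength_z[i].ravel()
        if np.all(np.isfinite(x)) and x.std() > 0 and y.std() > 0:
            r, p = stats.pearsonr(x, y)
        else:
            r, p = np.nan, 1.0
        rows.append({"roi": roi, "r": r, "p": p, "n": x.size})
    df = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(df["p"], alpha=alpha, method="fdr_bh")
    df["p_fdr"] = p_adj
    df["significant"] = reject
    return df


def flatten_band_vectors(
    zmap: np.ndarray,
    freqs: np.ndarray,
    band: str | tuple[float, float],
    window_idx: np.ndarray,
    roi_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Band-average a (R, F, W) map and flatten over (ROI x window).

    Ordering contract: element index = roi_index * n_windows + window_index
    (ROI-major, window-minor).
    """
    f_idx = band_indices(freqs, band)
    v = zmap[:, f_idx].mean(axis=1)[:, np.asarray(window_idx)]
    if roi_idx is not None:
        v = v[np.asarray(roi_idx)]
    return v.reshape(-1)


def circular_shift_pvalue(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """True Pearson r of x, y with a cyclic-shift/mirror permutation P.

    The null pool holds corr(x, rotate(y, s)) for s = 1..N-1 together with
    corr(x, rotate(reverse(y), s)) for s = 0..N-1 (2N-1 replicates);
    P = (1 + #{|r_null| >= |r_true|}) / 2N.  Computed via FFT circular
    cross-correlation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 8:
        raise ValueError("vectors too short for the shift null (need N >= 8)")
    xc = x - x.mean()
    yc = y - y.mean()
    sx, sy = xc.std(), yc.std()
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant vector")

    def _all_shift_corrs(yv: np.ndarray) -> np.ndarray:
        # c[s] = sum_i xc[i] * yv[(i - s) mod n]
        c = np.fft.irfft(np.fft.rfft(xc) * np.conj(np.fft.rfft(yv)), n)
        return c / (n * sx * sy)

    fwd = _all_shift_corrs(yc)
    rev = _all_shift_corrs(yc[::-1])
    r_true = float(fwd[0])
    null = np.concatenate([fwd[1:], rev])
    p = (1.0 + np.sum(np.abs(null) >= abs(r_true))) / (2.0 * n)
    return r_true, float(p), null


def cross_band_correlations(
    power_zmap: np.ndarray,
    strength_zmap: np.ndarray,
    freqs: np.ndarray,
    window_idx: np.ndarray,
    rois: list[str],
    band_pairs: tuple[tuple[str, str], ...] = (
        ("high_gamma", "high_gamma"),
        ("high_gamma", "theta"),
        ("theta", "theta"),
        ("theta", "high_gamma"),
    ),
    roi_subset: list[str] | None = None,
    subset_tag: str = "all",
) -> list[CorrelationResult]:
    """Power-band vs. synchrony-band correlations with the shift null.

    Each pair is (power band, strength band); the strength vector is the one
    rotated against the fixed power vector.
    """
    if roi_subset is not None:
        if len(roi_subset) < 2:
            raise ValueError("ROI subset must contain at least two ROIs")
        index = {r: i for i, r in enumerate(rois)}
        roi_idx = np.array([index[r] for r in roi_subset])
    else:
        roi_idx = None
    results = []
    for band_pow, band_syn in band_pairs:
        x = flatten_band_vectors(power_zmap, freqs, band_pow, window_idx, roi_idx)
        y = flatten_band_vectors(strength_zmap, freqs, band_syn, window_idx, roi_idx)
        good = np.isfinite(x) & np.isfinite(y)
        r, p, _ = circular_shift_pvalue(x[good], y[good])
        results.append(
            CorrelationResult(
                family="cross_band",
                label=subset_tag,
                band_x=f"{band_pow}-power",
                band_y=f"{band_syn}-synchrony",
                r=r,
                p=p,
                n=int(good.sum()),
            )
        )
    return results


def correlations_to_table(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family": c.family, "subset": c.label, "band_x": c.band_x,
                "band_y": c.band_y, "r": c.r, "p": c.p, "n": c.n,
            }
            for c in results
        ]
    )
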