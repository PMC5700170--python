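"""Spectral-power subsequent-memory effect (SME) with permutation pooling.

Per electrode, z-scored log power in each (frequency, window) cell is
contrasted between remembered and not-remembered trials with Welch's
unequal-variance t-test; 500 label-shuffle null t-statistics accompany each
cell.  True statistics and nulls are pooled exactly like the synchrony
networks (electrode mean within ROI, then subject mean), yielding a z-scored
power-SME map per ROI.  The "core memory network" split partitions ROIs by
the significance/size of their band-averaged high-gamma SME.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import band_indices


def welch_t(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Welch t statistic (x mean minus y mean), trials on axis 0."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = x.shape[0], y.shape[0]
    if nx < 2 or ny < 2:
        raise ValueError("each condition needs at least two trials")
    num = x.mean(axis=0) - y.mean(axis=0)
    den = np.sqrt(x.var(axis=0, ddof=1) / nx + y.var(axis=0, ddof=1) / ny)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(den > 0, num / den, 0.0)
    return t


def electrode_power_sme(power_w: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Welch t (remembered minus not-remembered) per (frequency, window).

    ``power_w``: windowed z-scored log power, (trial, freq, window).
    """
    labels = np.asarray(labels, dtype=bool)
    return welch_t(power_w[labels], power_w[~labels])


def electrode_power_sme_null(
    power_w: np.ndarray, perms: np.ndarray
) -> np.ndarray:
    """Null Welch t per label shuffle: (n_perm, freq, window).

    Vectorized over shuffles via group sums/sums-of-squares.
    """
    x = np.asarray(power_w, dtype=np.float64)
    t_shape = x.shape[1:]
    flat = x.reshape(x.shape[0], -1)
    sq = flat**2
    out = []
    for member in (perms, ~perms):
        n = member.sum(axis=1)[:, None]
        s1 = member.astype(float) @ flat
        s2 = member.astype(float) @ sq
        mean = s1 / n
        var = (s2 - n * mean**2) / (n - 1)
        out.append((mean, var / n))
    num = out[0][0] - out[1][0]
    den = np.sqrt(out[0][1] + out[1][1])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(den > 0, num / den, 0.0)
    return t.reshape((perms.shape[0],) + t_shape)


@dataclass
class PowerSmeMap:
    """Pooled power-SME statistics per ROI.

    ``t_true`` is (R, F, W); ``t_null`` (R, P, F, W); ROIs with no
    electrodes carry NaN and are excluded from downstream correlations.
    """

    rois: list[str]
    t_true: np.ndarray
    t_null: np.ndarray
    subject_count: np.ndarray
    freqs: np.ndarray
    window_starts_ms: np.ndarray

    def zscores(self) -> np.ndarray:
        mu = self.t_null.mean(axis=1)
        sd = self.t_null.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sd > 0, (self.t_true - mu) / sd, 0.0)

    def band_time_z(
        self,
        band: str | tuple[float, float],
        window_idx: np.ndarray | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Band/time-averaged z and its two-tailed permutation P per ROI."""
        f_idx = band_indices(self.freqs, band)
        w_idx = (
            np.asarray(window_idx) if window_idx is not None
            else np.arange(self.window_starts_ms.size)
        )
        t = self.t_true[:, f_idx][:, :, w_idx].mean(axis=(1, 2))
        null = self.t_null[:, :, f_idx][:, :, :, w_idx].mean(axis=(2, 3))
        mu, sd = null.mean(axis=1), null.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (t - mu) / sd, 0.0)
        centered = np.abs(null - mu[:, None])
        p = (1.0 + np.sum(centered >= np.abs(t - mu)[:, None], axis=1)) / (
            1.0 + null.shape[1]
        )
        return z, p


def pool_power_sme(
    subject_maps: list[dict[str, tuple[np.ndarray, np.ndarray]]],
    rois: list[str],
    freqs: np.ndarray,
    window_starts_ms: np.ndarray,
) -> PowerSmeMap:
    """Pool per-electrode t maps: electrode mean within ROI, subject mean.

    ``subject_maps[s]`` maps roi -> (t_true (F, W), t_null (P, F, W)),
    already electrode-averaged within the subject.
    """
    sampled = sorted({r for m in subject_maps for r in m})
    if not sampled:
        raise ValueError("no ROIs sampled")
    shape = next(iter(subject_maps[0].values()))[0].shape if subject_maps[0] else None
    for m in subject_maps:
        if m:
            shape = next(iter(m.values()))[0].shape
            n_perm = next(iter(m.values()))[1].shape[0]
            break
    t_true = np.full((len(rois),) + shape, np.nan, dtype=np.float32)
    t_null = np.full((len(rois), n_perm) + shape, np.nan, dtype=np.float32)
    counts = np.zeros(len(rois), dtype=int)
    for i, roi in enumerate(rois):
        trues = [m[roi][0] for m in subject_maps if roi in m]
        if not trues:
            continue
        nulls = [m[roi][1] for m in subject_maps if roi in m]
        t_true[i] = np.mean(trues, axis=0)
        t_null[i] = np.mean(nulls, axis=0)
        counts[i] = len(trues)
    return PowerSmeMap(
        rois=list(rois),
        t_true=t_true,
        t_null=t_null,
        subject_count=counts,
        freqs=np.asarray(freqs, float),
        window_starts_ms=np.asarray(window_starts_ms, float),
    )


def average_electrodes_by_roi(
    roi_of_channel: list[str],
    t_true: np.ndarray,
    t_null: np.ndarray,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Within-subject electrode averaging: roi -> (t (F,W), null (P,F,W))."""
    out: dict[str, tuple[list, list]] = {}
    for ch, roi in enumerate(roi_of_channel):
        out.setdefault(roi, ([], []))
        out[roi][0].append(t_true[ch])
        out[roi][1].append(t_null[:, ch])
    return {
        roi: (np.mean(ts, axis=0), np.mean(ns, axis=0))
        for roi, (ts, ns) in out.items()
    }


def core_network_split(
    sme: PowerSmeMap,
    band: str | tuple[float, float] = "high_gamma",
    window_idx: np.ndarray | None = None,
    alpha: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Partition ROIs into core memory network vs. out-of-network sets.

    Out-of-network: sampled ROIs whose band/time-averaged power SME is not
    significant (two-tailed permutation P >= alpha).  Core: the equally many
    significant ROIs with the largest |z| (ties broken by ROI label).
    """
    import logging

    z, p = sme.band_time_z(band, window_idx)
    sampled = np.flatnonzero(sme.subject_count > 0)
    nonsig = sorted(
        ((abs(z[i]), sme.rois[i]) for i in sampled if p[i] >= alpha),
        key=lambda t: (t[0], t[1]),
    )
    sig = sorted(
        ((abs(z[i]), sme.rois[i]) for i in sampled if p[i] < alpha),
        key=lambda t: (-t[0], t[1]),
    )
    n = min(len(nonsig), len(sig))
    if n < max(len(nonsig), len(sig)):
        logging.getLogger(__name__).info(
            "core_network_split: truncating to %d ROIs per set "
            "(%d significant, %d non-significant)", n, len(sig), len(nonsig)
        )
    core = sorted(r for _, r in sig[:n])
    out_set = sorted(r for _, r in nonsig[:n])
    return core, out_set


def sme_to_table(sme: PowerSmeMap) -> pd.DataFrame:
    z = sme.zscores()
    rows = []
    for i, roi in enumerate(sme.rois):
        if sme.subject_count[i] == 0:
            continue
        for fi, f in enumerate(sme.freqs):
            for wi, w0 in enumerate(sme.window_starts_ms):
                rows.append(
                    {
                        "roi": roi, "freq": f, "window_start_ms": w0,
                        "z": z[i, fi, wi], "n_subjects": sme.subject_count[i],
                    }
                )
    return pd.DataFrame(rows)
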