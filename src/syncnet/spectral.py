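"""Morlet wavelet decomposition, power normalization, window averaging.

Signals are convolved with complex Morlet wavelets (wave number 5).  Band
grids: theta 3-8 Hz (6 wavelets, 1 Hz spacing), low gamma 30-60 Hz (5 Hz
spacing), high gamma 45-100 Hz (11 wavelets, 5 Hz spacing except 90-100),
and a 35-wavelet log-spaced 3-120 Hz sweep.  Log power is z-scored within
session; phase differences are averaged within non-overlapping windows
(200 ms for encoding, 250 ms for retrieval) by the circular mean before
phase-locking values are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from mne.time_frequency import tfr_array_morlet

from .preprocess import EpochSet

logger = logging.getLogger(__name__)

THETA_FREQS = np.arange(3.0, 9.0)  # 3..8 Hz, 1 Hz spacing (6 wavelets)
LOW_GAMMA_FREQS = np.arange(30.0, 61.0, 5.0)  # 30..60 Hz (7 wavelets)
HIGH_GAMMA_FREQS = np.array(
    [45.0, 50.0, 55.0, 60.0, 65.0, 70.0, 75.0, 80.0, 85.0, 90.0, 100.0]
)  # 11 wavelets, 5 Hz spaced except between 90 and 100 Hz
FULL_FREQS = np.logspace(np.log10(3.0), np.log10(120.0), 35)
OSC_FREQS = np.logspace(np.log10(30.0), np.log10(58.0), 18)

BANDS: dict[str, tuple[float, float]] = {
    "theta": (3.0, 8.0),
    "low_gamma": (30.0, 60.0),
    "high_gamma": (45.0, 100.0),
    "full": (3.0, 120.0),
}

#: default window widths (ms)
ENCODING_WINDOW_MS = 200.0
RETRIEVAL_WINDOW_MS = 250.0

_POWER_FLOOR = 1e-30  # guard for log(0) on silent synthetic input


def band_indices(freqs: np.ndarray, band: str | tuple[float, float]) -> np.ndarray:
    """Indices of grid frequencies falling inside a band (inclusive)."""
    lo, hi = BANDS[band] if isinstance(band, str) else band
    idx = np.flatnonzero((np.asarray(freqs) >= lo) & (np.asarray(freqs) <= hi))
    if idx.size == 0:
        raise ValueError(f"band {band!r} contains no grid frequencies")
    return idx


@dataclass
class SpectralTensor:
    """Phase (unit phasors) and log power per (channel, trial, freq, sample).

    Phasors ``e^{i phase}`` are stored instead of raw angles so circular
    means are direct sums; the buffer samples have been clipped.
    """

    phasor: np.ndarray  # complex64 (ch, trial, freq, sample)
    log_power: np.ndarray  # float32, same shape
    freqs: np.ndarray
    fs: float
    t_start_ms: float
    condition: np.ndarray  # bool per trial
    power_zscored: bool = False

    @property
    def n_samples(self) -> int:
        return self.phasor.shape[-1]

    @property
    def n_trials(self) -> int:
        return self.phasor.shape[1]


def morlet_decompose(
    epochs: EpochSet, freqs: np.ndarray, wave_number: float = 5.0
) -> SpectralTensor:
    """Complex Morlet decomposition; buffers clipped after convolution."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.max() > epochs.fs / 2:
        raise ValueError("requested frequency exceeds Nyquist")
    nb = int(round(epochs.buffer_ms * epochs.fs / 1000.0))
    n_ch, n_tr, n_samp = epochs.data.shape
    n_keep = n_samp - 2 * nb
    phasor = np.empty((n_ch, n_tr, freqs.size, n_keep), dtype=np.complex64)
    log_power = np.empty((n_ch, n_tr, freqs.size, n_keep), dtype=np.float32)
    for ch in range(n_ch):  # per channel to bound memory
        if n_tr == 0:
            continue
        coef = tfr_array_morlet(
            epochs.data[ch][:, None, :], sfreq=epochs.fs, freqs=freqs,
            n_cycles=wave_number, output="complex", zero_mean=True,
            verbose="error",
        )[:, 0]  # (trial, freq, time)
        coef = coef[..., nb : n_samp - nb]
        mag = np.abs(coef)
        with np.errstate(invalid="ignore"):
            unit = np.where(mag > 0, coef / mag, 1.0 + 0.0j)
        phasor[ch] = unit.astype(np.complex64)
        log_power[ch] = np.log(np.maximum(mag**2, _POWER_FLOOR)).astype(np.float32)
    return SpectralTensor(
        phasor=phasor,
        log_power=log_power,
        freqs=freqs,
        fs=epochs.fs,
        t_start_ms=epochs.t_start_ms + epochs.buffer_ms,
        condition=np.asarray(epochs.condition, dtype=bool),
    )


def zscore_power_within_session(
    tensor: SpectralTensor, sessions: np.ndarray | None = None
) -> SpectralTensor:
    """Z-score log power per (channel, frequency) across a session's samples."""
    lp = tensor.log_power.astype(np.float64)
    out = np.empty_like(lp)
    if sessions is None:
        sessions = np.zeros(tensor.n_trials, dtype=int)
    sessions = np.asarray(sessions)
    for s in np.unique(sessions):
        sel = sessions == s
        x = lp[:, sel]  # (ch, trial_s, freq, samp)
        mu = x.mean(axis=(1, 3), keepdims=True)
        sd = x.std(axis=(1, 3), ddof=0, keepdims=True)
        bad = np.argwhere(sd[:, 0, :, 0] == 0)
        if bad.size:
            ch, fr = bad[0]
            raise ValueError(
                f"zero-variance power in session {s}: channel {ch}, "
                f"frequency {tensor.freqs[fr]:g} Hz"
            )
        out[:, sel] = (x - mu) / sd
    return SpectralTensor(
        phasor=tensor.phasor,
        log_power=out.astype(np.float32),
        freqs=tensor.freqs,
        fs=tensor.fs,
        t_start_ms=tensor.t_start_ms,
        condition=tensor.condition,
        power_zscored=True,
    )


def n_windows(span_ms: tuple[float, float], window_ms: float) -> int:
    """Number of whole non-overlapping windows tiling a span."""
    return int((span_ms[1] - span_ms[0]) // window_ms)


def window_starts_ms(span_ms: tuple[float, float], window_ms: float) -> np.ndarray:
    return span_ms[0] + window_ms * np.arange(n_windows(span_ms, window_ms))


def samples_per_window(fs: float, window_ms: float) -> int:
    return int(round(window_ms * fs / 1000.0))


def window_average(
    values: np.ndarray, fs: float, window_ms: float, circular: bool = False
) -> np.ndarray:
    """Average the last axis into non-overlapping windows.

    ``circular=True`` treats values as angles (radians) and returns the angle
    of the mean unit phasor per window.  A trailing remainder that does not
    fill a whole window is dropped (and logged).
    """
    k = samples_per_window(fs, window_ms)
    n = values.shape[-1]
    if k > n:
        raise ValueError("window longer than epoch")
    nw = n // k
    if n % k:
        logger.info("window_average: dropping %d remainder samples", n % k)
    v = values[..., : nw * k].reshape(values.shape[:-1] + (nw, k))
    if circular:
        s = np.exp(1j * v).mean(axis=-1)
        return np.angle(s)
    return v.mean(axis=-1)


def window_sum_phasor(phasor_values: np.ndarray, k: int) -> np.ndarray:
    """Sum complex values over non-overlapping blocks of k along last axis."""
    n = phasor_values.shape[-1]
    nw = n // k
    v = phasor_values[..., : nw * k].reshape(phasor_values.shape[:-1] + (nw, k))
    return v.sum(axis=-1)
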