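"""Phase-locking difference statistic D with trial-shuffle permutation null.

For an electrode pair, frequency, and time window, the mean resultant vector
length (phase-locking value) R of the across-trial phase-difference
distribution is computed separately for remembered and not-remembered
trials; the statistic is their difference D = R_rem - R_nrem.  Because R is
biased by sample size, significance comes from a label-shuffle permutation
null that preserves the group sizes: z = (D_true - mean(null)) / sd(null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import SpectralTensor, samples_per_window, window_sum_phasor

DEFAULT_N_PERM = 500


def resultant_length(angles: np.ndarray, axis: int = 0) -> np.ndarray:
    """Mean resultant vector length (phase-locking value), in [0, 1]."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("resultant_length of an empty sample")
    return np.abs(np.exp(1j * angles).mean(axis=axis))


def pair_D(phase_diff: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """D = R over remembered minus R over not-remembered trials.

    ``phase_diff``: windowed phase-difference angles, trials on axis 0
    (any trailing (frequency, window) axes).  ``labels``: bool per trial.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("each condition needs at least two trials")
    return resultant_length(phase_diff[labels]) - resultant_length(phase_diff[~labels])


def make_label_perms(
    labels: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (n_perm, n_trials) matrix of label shuffles (group sizes kept)."""
    labels = np.asarray(labels, dtype=bool)
    perms = np.empty((n_perm, labels.size), dtype=bool)
    for r in range(n_perm):
        perms[r] = rng.permutation(labels)
    return perms


def _cond_means(unit: np.ndarray, member: np.ndarray) -> np.ndarray:
    """|mean phasor| per row of ``member`` (bool (..., T)) against unit (T, M)."""
    counts = member.sum(axis=-1, keepdims=True)
    sums = member.astype(np.float64) @ unit
    return np.abs(sums) / counts


def null_D_from_phasors(unit: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Null D sample from unit phasors (T, ...) and label shuffles (P, T)."""
    shape = unit.shape
    u = unit.reshape(shape[0], -1).astype(np.complex128)
    d = _cond_means(u, perms) - _cond_means(u, ~perms)
    return d.reshape((perms.shape[0],) + shape[1:])


def permutation_null(
    phase_diff: np.ndarray,
    labels: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Label-shuffle null sample of D (shape (n_perm, ...))."""
    import warnings

    if n_perm < 100:
        warnings.warn("n_perm < 100: z-scores will be unstable", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("each condition needs at least two trials")
    perms = make_label_perms(labels, n_perm, rng)
    return null_D_from_phasors(np.exp(1j * np.asarray(phase_diff, float)), perms)


def zscore_stat(
    d_true: np.ndarray, null: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """z = (D_true - mean(null)) / sd(null); degenerate sd=0 cells get z=0.

    Returns (z, degenerate_mask).  Positive z means greater phase locking for
    the remembered (or retrieval) condition.
    """
    null = np.asarray(null, dtype=float)
    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (np.asarray(d_true, float) - mu) / sd
    z = np.where(degenerate, 0.0, z)
    return z, degenerate


@dataclass
class PairSyncStat:
    """D_true and its permutation null for one electrode pair.

    Arrays are indexed (frequency, window) and (perm, frequency, window).
    """

    pair: str
    roi_a: str
    roi_b: str
    d_true: np.ndarray
    d_null: np.ndarray

    @property
    def z(self) -> np.ndarray:
        return zscore_stat(self.d_true, self.d_null)[0]


def pair_windowed_phasors(
    tensor: SpectralTensor, i: int, j: int, window_ms: float
) -> np.ndarray:
    """Unit phasors of the within-window circular-mean phase difference.

    Returns complex (trial, freq, window): the direction of the summed
    phasor of (phase_i - phase_j) over each window's samples.
    """
    k = samples_per_window(tensor.fs, window_ms)
    prod = tensor.phasor[i] * np.conj(tensor.phasor[j])  # (trial, freq, samp)
    s = window_sum_phasor(prod, k)
    mag = np.abs(s)
    return np.where(mag > 0, s / mag, 1.0 + 0.0j)


def compute_pair_stats(
    tensor: SpectralTensor,
    pairs: list[tuple[int, int]],
    window_ms: float,
    perms: np.ndarray,
    pair_meta: list[tuple[str, str, str]] | None = None,
) -> list[PairSyncStat]:
    """D_true and null for every electrode pair, sharing one shuffle set.

    ``perms`` is the (n_perm, n_trials) label-shuffle matrix for this
    subject (shared across pairs so null replicate r forms a coherent null
    network); the true labels are ``tensor.condition``.
    """
    labels = tensor.condition
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("each condition needs at least two trials")
    out = []
    for n, (i, j) in enumerate(pairs):
        unit = pair_windowed_phasors(tensor, i, j, window_ms)
        u = unit.reshape(unit.shape[0], -1).astype(np.complex128)
        d_true = (
            np.abs(u[labels].mean(axis=0)) - np.abs(u[~labels].mean(axis=0))
        ).reshape(unit.shape[1:])
        d_null = null_D_from_phasors(unit, perms).astype(np.float32)
        name, ra, rb = (
            pair_meta[n] if pair_meta is not None else (f"{i}-{j}", "", "")
        )
        out.append(
            PairSyncStat(
                pair=name, roi_a=ra, roi_b=rb,
                d_true=d_true.astype(np.float32), d_null=d_null,
            )
        )
    return out
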