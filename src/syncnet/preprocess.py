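"""Bipolar montage, 60 Hz notch, resampling, and epoch extraction.

The analysis operates on bipolar derivations (differences of adjacent
contacts on one strip/grid/depth lead), notch-filtered at 60 Hz and
resampled to a common 500 samples/s rate.  Two epoch families are produced:

* encoding epochs, -1000..+2600 ms around word onset (plus 1000 ms wavelet
  buffers on each side), labelled by whether the word was later recalled;
* retrieval epochs, the 500 ms immediately before a correct vocalization
  ("retrieval") vs. 500 ms windows followed by >= 2 s without any
  vocalization ("unsuccessful memory search").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: sampling rates accepted for raw recordings (samples/s)
ACCEPTED_FS = (500.0, 512.0, 1000.0, 1024.0, 2000.0)

#: encoding epoch geometry (ms relative to word onset)
ENCODING_SPAN_MS = (-1000.0, 2600.0)
#: retrieval epoch geometry (ms relative to anchor = vocalization onset or
#: search-window end)
RETRIEVAL_SPAN_MS = (-500.0, 0.0)
#: wavelet buffer retained on each side of an epoch, clipped after convolution
BUFFER_MS = 1000.0


@dataclass
class RawRecording:
    """Continuous multichannel recording (microvolt scale)."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    channels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("RawRecording.data must be 2-D (channels, samples)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel list length does not match data")
        if float(self.fs) not in ACCEPTED_FS:
            raise ValueError(
                f"sampling rate {self.fs} not in accepted set {ACCEPTED_FS}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class BipolarRecording:
    """Difference signals of adjacent contacts, with per-pair metadata.

    ``pairs`` has columns: pair, anode, cathode, lead, roi, hemisphere.
    """

    data: np.ndarray  # (n_pairs, n_samples)
    fs: float
    pairs: pd.DataFrame

    @property
    def channels(self) -> list[str]:
        return list(self.pairs["pair"])

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Epoched data, (channel, trial, sample), with condition labels.

    ``t_start_ms`` is the time of the first sample relative to the anchor
    (word onset or vocalization), including the wavelet buffer; ``span_ms``
    is the analysis span that remains after buffers are clipped.
    """

    data: np.ndarray  # (n_channels, n_trials, n_samples)
    fs: float
    t_start_ms: float
    span_ms: tuple[float, float]
    buffer_ms: float
    condition: np.ndarray  # bool per trial (True = remembered / retrieval)
    pairs: pd.DataFrame
    anchors_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_dropped: int = 0

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


def bipolar_montage(raw: RawRecording, electrodes: pd.DataFrame) -> BipolarRecording:
    """Form difference signals between adjacent contacts on each lead.

    ``electrodes`` columns: channel, lead, contact, roi (and optionally
    hemisphere).  Pairs are formed between contacts with consecutive order on
    the same lead; pairs whose two contacts carry different ROI labels are
    dropped (and logged), since a bipolar pair inherits a single label.
    """
    required = {"channel", "lead", "contact", "roi"}
    missing = required - set(electrodes.columns)
    if missing:
        raise ValueError(f"electrode table missing columns: {sorted(missing)}")
    index_of = {ch: i for i, ch in enumerate(raw.channels)}
    unknown = [ch for ch in electrodes["channel"] if ch not in index_of]
    if unknown:
        raise ValueError(f"electrode table channels absent from recording: {unknown}")

    rows = []
    signals = []
    n_conflict = 0
    for lead, grp in electrodes.groupby("lead", sort=True):
        grp = grp.sort_values("contact")
        if len(grp) < 2:
            raise ValueError(f"lead {lead!r} has fewer than two contacts")
        recs = grp.to_dict("records")
        for a, b in zip(recs[:-1], recs[1:]):
            if a["roi"] != b["roi"]:
                n_conflict += 1
                continue
            ia, ib = index_of[a["channel"]], index_of[b["channel"]]
            signals.append(raw.data[ia] - raw.data[ib])
            rows.append(
                {
                    "pair": f"{a['channel']}-{b['channel']}",
                    "anode": a["channel"],
                    "cathode": b["channel"],
                    "lead": lead,
                    "roi": a["roi"],
                    "hemisphere": a.get("hemisphere", str(a["roi"]).partition("-")[0]),
                }
            )
    if n_conflict:
        logger.info("bipolar_montage: dropped %d cross-ROI pairs", n_conflict)
    if not rows:
        raise ValueError("no bipolar pairs could be formed")
    return BipolarRecording(
        data=np.asarray(signals), fs=raw.fs, pairs=pd.DataFrame(rows)
    )


def notch_filter(
    sig: BipolarRecording, freq: float = 60.0, stop_halfwidth: float = 1.0
) -> BipolarRecording:
    """Butterworth band-stop (order 4, 59-61 Hz), applied forward-backward."""
    if sig.fs <= 2 * (freq + stop_halfwidth):
        raise ValueError(f"sampling rate {sig.fs} too low to notch at {freq} Hz")
    sos = sps.butter(
        2, [freq - stop_halfwidth, freq + stop_halfwidth], btype="bandstop",
        fs=sig.fs, output="sos",
    )
    out = sps.sosfiltfilt(sos, sig.data, axis=-1)
    return BipolarRecording(data=out, fs=sig.fs, pairs=sig.pairs)


def resample_to_analysis_rate(
    sig: BipolarRecording, target_fs: float = 500.0
) -> BipolarRecording:
    """Anti-aliased resampling to the analysis rate (no upsampling)."""
    if sig.fs < target_fs:
        raise ValueError("upsampling is not supported")
    if sig.fs == target_fs:
        return sig
    frac = Fraction(int(round(target_fs)), int(round(sig.fs)))
    out = sps.resample_poly(sig.data, frac.numerator, frac.denominator, axis=-1)
    return BipolarRecording(data=out, fs=float(target_fs), pairs=sig.pairs)


def _extract_epochs(
    sig: BipolarRecording,
    anchors_ms: np.ndarray,
    labels: np.ndarray,
    span_ms: tuple[float, float],
    buffer_ms: float,
) -> EpochSet:
    fs = sig.fs
    start_ms = span_ms[0] - buffer_ms
    stop_ms = span_ms[1] + buffer_ms
    n_per = int(round((stop_ms - start_ms) * fs / 1000.0))
    keep, starts = [], []
    for k, onset in enumerate(np.asarray(anchors_ms, dtype=float)):
        i0 = int(round((onset + start_ms) * fs / 1000.0))
        if i0 < 0 or i0 + n_per > sig.n_samples:
            continue
        keep.append(k)
        starts.append(i0)
    n_dropped = len(anchors_ms) - len(keep)
    if n_dropped:
        logger.info("epoching: dropped %d events near recording edges", n_dropped)
    if keep:
        data = np.stack([sig.data[:, i0 : i0 + n_per] for i0 in starts], axis=1)
        cond = np.asarray(labels, dtype=bool)[keep]
        anchors = np.asarray(anchors_ms, dtype=float)[keep]
    else:
        data = np.empty((sig.data.shape[0], 0, n_per))
        cond = np.empty(0, dtype=bool)
        anchors = np.empty(0)
    return EpochSet(
        data=data,
        fs=fs,
        t_start_ms=start_ms,
        span_ms=span_ms,
        buffer_ms=buffer_ms,
        condition=cond,
        pairs=sig.pairs,
        anchors_ms=anchors,
        n_dropped=n_dropped,
    )


def epoch_encoding(
    sig: BipolarRecording, events: pd.DataFrame, buffer_ms: float = BUFFER_MS
) -> EpochSet:
    """One epoch per word presentation; condition = later recalled.

    ``events`` must contain word rows with columns onset_ms and recalled
    (an ``event_type`` column, if present, selects rows equal to 'word').
    """
    words = events
    if "event_type" in events.columns:
        words = events[events["event_type"] == "word"]
    onsets = words["onset_ms"].to_numpy(dtype=float)
    labels = words["recalled"].to_numpy(dtype=bool)
    return _extract_epochs(sig, onsets, labels, ENCODING_SPAN_MS, buffer_ms)


def search_window_starts(
    voc_onsets_ms: np.ndarray,
    recall_start_ms: float,
    recall_end_ms: float,
    window_ms: float = 500.0,
    quiet_ms: float = 2000.0,
    voc_duration_ms: float = 1000.0,
) -> np.ndarray:
    """Start times of qualifying 'unsuccessful memory search' windows.

    Windows of ``window_ms`` are tiled non-overlapping from the start of each
    silent stretch (a stretch begins after the vocal activity of the previous
    vocalization and ends at the next vocalization onset or recall end).  A
    window qualifies if no vocalization onset occurs within ``quiet_ms``
    after the window ends.  This tiling is shared with the synthetic
    generator, so injected "search" effects line up with extracted windows.
    """
    vocs = np.sort(np.asarray(voc_onsets_ms, dtype=float))
    vocs = vocs[(vocs >= recall_start_ms) & (vocs <= recall_end_ms)]
    bounds_lo = np.concatenate([[recall_start_ms], vocs + voc_duration_ms])
    bounds_hi = np.concatenate([vocs, [recall_end_ms]])
    starts: list[float] = []
    for lo, hi in zip(bounds_lo, bounds_hi):
        s = lo
        while s + window_ms <= hi:
            t_end = s + window_ms
            if not np.any((vocs >= s) & (vocs < t_end + quiet_ms)):
                starts.append(s)
            s += window_ms
    return np.asarray(starts)


def epoch_retrieval(
    sig: BipolarRecording,
    events: pd.DataFrame,
    buffer_ms: float = BUFFER_MS,
    quiet_ms: float = 2000.0,
    voc_duration_ms: float = 1000.0,
) -> EpochSet:
    """Retrieval ([-500, 0) ms before vocalization) vs. search epochs.

    ``events`` must carry 'vocalization' rows (onset_ms) and recall-period
    boundaries as 'recall_start'/'recall_end' rows.
    """
    if "event_type" not in events.columns:
        raise ValueError("retrieval epoching needs an event_type column")
    vocs = events.loc[events["event_type"] == "vocalization", "onset_ms"].to_numpy(
        dtype=float
    )
    rec_start = events.loc[events["event_type"] == "recall_start", "onset_ms"]
    rec_end = events.loc[events["event_type"] == "recall_end", "onset_ms"]
    if rec_start.empty or rec_end.empty:
        raise ValueError("no recall-period boundaries in event table")

    anchors: list[float] = []
    labels: list[bool] = []
    window_ms = RETRIEVAL_SPAN_MS[1] - RETRIEVAL_SPAN_MS[0]
    for lo, hi in zip(rec_start.to_numpy(float), rec_end.to_numpy(float)):
        in_period = vocs[(vocs >= lo) & (vocs <= hi)]
        for v in in_period:
            if v - lo >= window_ms:  # need a clean pre-vocalization window
                anchors.append(v)
                labels.append(True)
        starts = search_window_starts(
            in_period, lo, hi, window_ms=window_ms, quiet_ms=quiet_ms,
            voc_duration_ms=voc_duration_ms,
        )
        for s in starts:
            anchors.append(s + window_ms)  # anchor at window end
            labels.append(False)
    if not any(not l for l in labels):
        raise ValueError("no qualifying unsuccessful-search windows found")
    return _extract_epochs(
        sig, np.asarray(anchors), np.asarray(labels), RETRIEVAL_SPAN_MS, buffer_ms
    )
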