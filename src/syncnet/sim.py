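"""Synthetic iEEG cohort generator with known ground truth.

Generates trial-structured multichannel recordings that emulate the
statistical structure the downstream analysis assumes: 1/f background,
60 Hz line noise, condition-dependent pairwise theta/gamma phase coupling
(shared sinusoidal driver per edge plus von Mises phase jitter per trial),
condition-dependent band-limited power effects during item presentation,
and rare narrowband gamma bursts.  Every injected effect is recorded in a
:class:`GroundTruth` object so recovery can be tested.

Each lead carries two contacts; condition-dependent components are injected
into the first contact only, so the bipolar derivation (contact0 - contact1)
formed by :func:`syncnet.preprocess.bipolar_montage` retains them while
common-mode noise is suppressed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import rois as roilib
from .preprocess import RawRecording, search_window_starts

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class CouplingEdge:
    """Condition-dependent phase coupling between two ROIs.

    A shared sinusoid at ``freq`` Hz is added to the injection contacts of
    both ROIs during each trial; the phase offset between the two ROIs is
    drawn per trial from von Mises(``phase_lag``, kappa_cond), so kappa
    controls how concentrated the trial-to-trial phase-difference
    distribution is (kappa 0 = uniform = no locking).
    """

    roi_a: str
    roi_b: str
    kappa_rem: float
    kappa_nrem: float
    freq: float = 6.0
    phase_lag: float = 0.0
    amplitude: float = 3.0
    #: injection window relative to word onset (ms); the default covers the
    #: item-presentation interval
    time_range_ms: tuple[float, float] = (0.0, 1600.0)


@dataclass(frozen=True)
class PowerEffect:
    """Condition-dependent band-limited amplitude gain in one ROI.

    Band-limited Gaussian noise of RMS ``amplitude * gain_cond`` is added
    during the item-presentation interval, so the remembered/not-remembered
    band-power ratio of the injected component is gain_rem^2/gain_nrem^2.
    """

    roi: str
    band: tuple[float, float]
    gain_rem: float
    gain_nrem: float = 1.0
    amplitude: float = 2.0


@dataclass(frozen=True)
class BurstSpec:
    """Rare narrowband oscillatory bursts (Hann-windowed sinusoids).

    Placement: either on the injection contacts of ``rois`` (optionally
    phase-locked across ROIs through a shared per-trial phase), or on the
    first ``ceil(channel_fraction * n_leads)`` leads.
    """

    center_freq: float = 52.0
    n_cycles: float = 16.0
    p_burst_rem: float = 0.6
    p_burst_nrem: float = 0.1
    amplitude: float = 6.0
    channel_fraction: float | None = None
    rois: tuple[str, ...] | None = None
    phase_locked: bool = False
    phase_lag: float = 0.0
    kappa: float = 30.0
    time_range_ms: tuple[float, float] = (0.0, 1600.0)


@dataclass
class SimConfig:
    """Cohort-level simulation configuration.

    One lead (``contacts_per_lead`` contacts) per (ROI, lead index); the
    number of bipolar channels per subject is
    ``len(rois) * leads_per_roi * (contacts_per_lead - 1)``.
    """

    rois: tuple[str, ...]
    n_subjects: int = 8
    leads_per_roi: int = 1
    contacts_per_lead: int = 2
    fs: float = 500.0
    n_lists: int = 8
    words_per_list: int = 12
    p_recall: float = 0.35
    coupling_graph: tuple[CouplingEdge, ...] = ()
    power_effects: tuple[PowerEffect, ...] = ()
    burst_spec: tuple[BurstSpec, ...] = ()
    noise_exponent: float = 2.0
    noise_amplitude: float = 1.0
    #: white measurement-noise floor (RMS), keeps high-frequency background
    #: from vanishing under the 1/f spectrum
    noise_floor_amp: float = 0.3
    line_noise_amp: float = 0.5
    word_duration_ms: float = 1600.0
    isi_range_ms: tuple[float, float] = (750.0, 1000.0)
    recall_period_s: float = 30.0
    include_retrieval: bool = True
    vocabulary: tuple[str, ...] = field(
        default_factory=lambda: tuple(roilib.default_vocabulary())
    )
    seed: int = 0

    @property
    def n_trials(self) -> int:
        return self.n_lists * self.words_per_list

    def validate(self) -> None:
        unknown = [r for r in self.rois if r not in self.vocabulary]
        if unknown:
            raise ValueError(f"ROI labels absent from the vocabulary: {unknown}")
        if len(set(self.rois)) != len(self.rois):
            raise ValueError("duplicate ROI labels in config")
        if self.contacts_per_lead < 2:
            raise ValueError("need at least two contacts per lead")
        if not (0.0 <= self.p_recall <= 1.0):
            raise ValueError("p_recall must be in [0, 1]")
        max_f = 60.0
        for e in self.coupling_graph:
            if e.kappa_rem < 0 or e.kappa_nrem < 0:
                raise ValueError("coupling kappa must be >= 0")
            for r in (e.roi_a, e.roi_b):
                if r not in self.rois:
                    raise ValueError(f"coupling edge references absent ROI {r!r}")
            max_f = max(max_f, e.freq)
        for p in self.power_effects:
            if p.roi not in self.rois:
                raise ValueError(f"power effect references absent ROI {p.roi!r}")
            max_f = max(max_f, p.band[1])
        for b in self.burst_spec:
            if b.n_cycles < 3:
                raise ValueError("burst n_cycles must be >= 3")
            if not (0 <= b.p_burst_rem <= 1 and 0 <= b.p_burst_nrem <= 1):
                raise ValueError("burst probabilities must be in [0, 1]")
            if b.rois is not None:
                for r in b.rois:
                    if r not in self.rois:
                        raise ValueError(f"burst spec references absent ROI {r!r}")
            max_f = max(max_f, b.center_freq)
        if self.fs <= 2 * max_f:
            raise ValueError(
                f"fs={self.fs} too low for requested frequencies (max {max_f} Hz)"
            )


@dataclass
class GroundTruth:
    """Realized injections for one subject (everything recovery tests need)."""

    recalled: np.ndarray  # bool per word trial
    word_onsets_ms: np.ndarray
    voc_onsets_ms: np.ndarray
    coupling_deltas: dict[str, np.ndarray]  # edge key -> phase offset per trial
    power_effects: list[PowerEffect]
    burst_channels: list[str]
    burst_events: pd.DataFrame  # channel, trial, onset_ms, freq

    def to_json(self) -> str:
        obj = {
            "recalled": self.recalled.astype(int).tolist(),
            "word_onsets_ms": self.word_onsets_ms.tolist(),
            "voc_onsets_ms": self.voc_onsets_ms.tolist(),
            "coupling_deltas": {k: v.tolist() for k, v in self.coupling_deltas.items()},
            "power_effects": [asdict(p) for p in self.power_effects],
            "burst_channels": self.burst_channels,
            "burst_events": self.burst_events.to_dict("list"),
        }
        return json.dumps(obj, indent=1)


@dataclass
class SubjectData:
    subject: str
    raw: RawRecording
    events: pd.DataFrame
    electrodes: pd.DataFrame
    truth: GroundTruth


@dataclass
class CohortBundle:
    cfg: SimConfig
    subjects: list[SubjectData]


# ----------------------------------------------------------------- helpers

def _one_over_f_noise(
    rng: np.random.Generator, n: int, fs: float, exponent: float, amplitude: float
) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x * (amplitude / sd) if sd > 0 else x


def _band_noise(rng: np.random.Generator, n: int, fs: float, band: tuple) -> np.ndarray:
    """Unit-RMS Gaussian noise restricted to a frequency band."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _ramped_cos(n: int, fs: float, freq: float, phase: float, ramp_ms: float = 25.0):
    t = np.arange(n) / fs
    w = np.cos(_TWO_PI * freq * t + phase)
    nr = min(int(round(ramp_ms * fs / 1000.0)), n // 2)
    if nr > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        w[:nr] *= ramp
        w[-nr:] *= ramp[::-1]
    return w


def _edge_key(edge: CouplingEdge) -> str:
    return f"{edge.roi_a}|{edge.roi_b}|{edge.freq:g}Hz"


# ------------------------------------------------------------- generation

def generate_subject(cfg: SimConfig, subject_index: int) -> SubjectData:
    """Generate one subject's recording, event table, electrodes, and truth."""
    cfg.validate()
    if not (0 <= subject_index < cfg.n_subjects):
        raise ValueError("subject_index out of range")
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), subject_index]))
    fs = cfg.fs
    subject = f"S{subject_index:03d}"

    # --- electrode layout -------------------------------------------------
    elec_rows = []
    for roi in cfg.rois:
        for k in range(cfg.leads_per_roi):
            for c in range(cfg.contacts_per_lead):
                elec_rows.append(
                    {
                        "channel": f"{roi}:{k}:{c}",
                        "lead": f"{roi}:{k}",
                        "contact": c,
                        "roi": roi,
                        "hemisphere": roilib.hemisphere(roi),
                    }
                )
    electrodes = pd.DataFrame(elec_rows)
    channels = list(electrodes["channel"])
    ch_index = {ch: i for i, ch in enumerate(channels)}
    # injection targets: first contact of each lead
    anodes_of_roi: dict[str, list[int]] = {roi: [] for roi in cfg.rois}
    lead_anodes: list[int] = []
    for roi in cfg.rois:
        for k in range(cfg.leads_per_roi):
            i = ch_index[f"{roi}:{k}:0"]
            anodes_of_roi[roi].append(i)
            lead_anodes.append(i)

    # --- timeline ---------------------------------------------------------
    lead_in_ms, gap_ms, tail_ms = 3000.0, 2000.0, 3000.0
    cursor = lead_in_ms
    word_rows, rec_bounds = [], []
    for lst in range(cfg.n_lists):
        for w in range(cfg.words_per_list):
            onset = cursor
            word_rows.append((lst, onset))
            cursor = onset + cfg.word_duration_ms + rng.uniform(*cfg.isi_range_ms)
        if cfg.include_retrieval:
            rec_start = cursor + gap_ms
            rec_end = rec_start + cfg.recall_period_s * 1000.0
            rec_bounds.append((lst, rec_start, rec_end))
            cursor = rec_end + gap_ms
        else:
            cursor += gap_ms
    total_ms = cursor + tail_ms
    n_samples = int(round(total_ms * fs / 1000.0))

    word_onsets = np.array([o for _, o in word_rows])
    n_trials = len(word_onsets)
    recalled = rng.random(n_trials) < cfg.p_recall

    # vocalization onsets: recalled words of each list, spaced 3 s apart,
    # leaving >= 2.5 s of silence at the end of the recall period
    voc_rows = []
    if cfg.include_retrieval:
        for lst, rec_start, rec_end in rec_bounds:
            idx = [
                t for t, (l, _) in enumerate(word_rows) if l == lst and recalled[t]
            ]
            v = rec_start + 2000.0
            for t in idx:
                if v + 3000.0 > rec_end - 2600.0:
                    break
                voc_rows.append((lst, t, v))
                v += 3000.0
    voc_onsets = np.array([v for _, _, v in voc_rows])

    # --- background -------------------------------------------------------
    data = np.empty((len(channels), n_samples))
    for i in range(len(channels)):
        data[i] = _one_over_f_noise(
            rng, n_samples, fs, cfg.noise_exponent, cfg.noise_amplitude
        )
        if cfg.noise_floor_amp > 0:
            data[i] += cfg.noise_floor_amp * rng.standard_normal(n_samples)
        if cfg.line_noise_amp > 0:
            phase = rng.uniform(0, _TWO_PI)
            t = np.arange(n_samples) / fs
            data[i] += cfg.line_noise_amp * np.sin(_TWO_PI * 60.0 * t + phase)

    def _add(chan: int, t0_ms: float, wave: np.ndarray) -> None:
        i0 = int(round(t0_ms * fs / 1000.0))
        i1 = min(i0 + wave.size, n_samples)
        if 0 <= i0 < n_samples:
            data[chan, i0:i1] += wave[: i1 - i0]

    n_word = int(round(cfg.word_duration_ms * fs / 1000.0))
    ret_win_ms = 500.0
    n_ret = int(round(ret_win_ms * fs / 1000.0))

    # search-window tiles per recall period (same rule the preprocessor uses)
    search_tiles: list[float] = []
    for lst, rec_start, rec_end in rec_bounds:
        in_period = voc_onsets[(voc_onsets >= rec_start) & (voc_onsets <= rec_end)]
        search_tiles.extend(
            search_window_starts(in_period, rec_start, rec_end, ret_win_ms)
        )

    # --- coupling ---------------------------------------------------------
    coupling_deltas: dict[str, np.ndarray] = {}
    for edge in cfg.coupling_graph:
        t_lo, t_hi = edge.time_range_ms
        n_seg = int(round((t_hi - t_lo) * fs / 1000.0))
        deltas = np.empty(n_trials)
        for t in range(n_trials):
            kappa = edge.kappa_rem if recalled[t] else edge.kappa_nrem
            phi = rng.uniform(0, _TWO_PI)
            delta = rng.vonmises(edge.phase_lag, kappa) if kappa > 0 else rng.uniform(
                -np.pi, np.pi
            )
            deltas[t] = delta
            wa = edge.amplitude * _ramped_cos(n_seg, fs, edge.freq, phi)
            wb = edge.amplitude * _ramped_cos(n_seg, fs, edge.freq, phi + delta)
            for i in anodes_of_roi[edge.roi_a]:
                _add(i, word_onsets[t] + t_lo, wa)
            for i in anodes_of_roi[edge.roi_b]:
                _add(i, word_onsets[t] + t_lo, wb)
        coupling_deltas[_edge_key(edge)] = deltas
        # retrieval contrast: kappa_rem before vocalizations, kappa_nrem in
        # unsuccessful-search tiles
        for v in voc_onsets:
            phi = rng.uniform(0, _TWO_PI)
            d = rng.vonmises(edge.phase_lag, edge.kappa_rem) if edge.kappa_rem > 0 \
                else rng.uniform(-np.pi, np.pi)
            wa = edge.amplitude * _ramped_cos(n_ret, fs, edge.freq, phi)
            wb = edge.amplitude * _ramped_cos(n_ret, fs, edge.freq, phi + d)
            for i in anodes_of_roi[edge.roi_a]:
                _add(i, v - ret_win_ms, wa)
            for i in anodes_of_roi[edge.roi_b]:
                _add(i, v - ret_win_ms, wb)
        for s in search_tiles:
            phi = rng.uniform(0, _TWO_PI)
            d = rng.vonmises(edge.phase_lag, edge.kappa_nrem) if edge.kappa_nrem > 0 \
                else rng.uniform(-np.pi, np.pi)
            wa = edge.amplitude * _ramped_cos(n_ret, fs, edge.freq, phi)
            wb = edge.amplitude * _ramped_cos(n_ret, fs, edge.freq, phi + d)
            for i in anodes_of_roi[edge.roi_a]:
                _add(i, s, wa)
            for i in anodes_of_roi[edge.roi_b]:
                _add(i, s, wb)

    # --- power effects ----------------------------------------------------
    for eff in cfg.power_effects:
        for t in range(n_trials):
            gain = eff.gain_rem if recalled[t] else eff.gain_nrem
            for i in anodes_of_roi[eff.roi]:
                seg = eff.amplitude * gain * _band_noise(rng, n_word, fs, eff.band)
                _add(i, word_onsets[t], seg)
        for v in voc_onsets:
            for i in anodes_of_roi[eff.roi]:
                seg = eff.amplitude * eff.gain_rem * _band_noise(rng, n_ret, fs, eff.band)
                _add(i, v - ret_win_ms, seg)
        for s in search_tiles:
            for i in anodes_of_roi[eff.roi]:
                seg = eff.amplitude * eff.gain_nrem * _band_noise(rng, n_ret, fs, eff.band)
                _add(i, s, seg)

    # --- bursts -----------------------------------------------------------
    burst_channels: set[str] = set()
    burst_rows = []
    for spec in cfg.burst_spec:
        n_burst = int(round(spec.n_cycles / spec.center_freq * fs))
        lo = spec.time_range_ms[0]
        hi = max(lo, spec.time_range_ms[1] - n_burst * 1000.0 / fs)

        def _burst(phase: float) -> np.ndarray:
            t = np.arange(n_burst) / fs
            return (
                spec.amplitude
                * np.hanning(n_burst)
                * np.cos(_TWO_PI * spec.center_freq * t + phase)
            )

        if spec.rois is not None and spec.phase_locked:
            groups = [anodes_of_roi[r] for r in spec.rois]
            for g in groups:
                burst_channels.update(channels[i] for i in g)
            for t in range(n_trials):
                p = spec.p_burst_rem if recalled[t] else spec.p_burst_nrem
                if rng.random() >= p:
                    continue
                onset = word_onsets[t] + rng.uniform(lo, hi)
                phi = rng.uniform(0, _TWO_PI)
                for gi, g in enumerate(groups):
                    ph = phi if gi == 0 else phi + rng.vonmises(spec.phase_lag, spec.kappa)
                    for i in g:
                        _add(i, onset, _burst(ph))
                        burst_rows.append(
                            (channels[i], t, onset - word_onsets[t], spec.center_freq)
                        )
        else:
            if spec.rois is not None:
                targets = [i for r in spec.rois for i in anodes_of_roi[r]]
            else:
                frac = spec.channel_fraction if spec.channel_fraction else 0.0
                n_sel = int(np.ceil(frac * len(lead_anodes)))
                targets = lead_anodes[:n_sel]
            burst_channels.update(channels[i] for i in targets)
            for i in targets:
                for t in range(n_trials):
                    p = spec.p_burst_rem if recalled[t] else spec.p_burst_nrem
                    if rng.random() >= p:
                        continue
                    onset = word_onsets[t] + rng.uniform(lo, hi)
                    _add(i, onset, _burst(rng.uniform(0, _TWO_PI)))
                    burst_rows.append(
                        (channels[i], t, onset - word_onsets[t], spec.center_freq)
                    )

    # --- event table --------------------------------------------------------
    ev_rows = []
    for t, (lst, onset) in enumerate(word_rows):
        ev_rows.append(
            {
                "subject": subject, "list": lst, "trial": t, "event_type": "word",
                "onset_ms": onset, "offset_ms": onset + cfg.word_duration_ms,
                "recalled": bool(recalled[t]),
            }
        )
    for lst, rec_start, rec_end in rec_bounds:
        ev_rows.append(
            {
                "subject": subject, "list": lst, "trial": -1,
                "event_type": "recall_start", "onset_ms": rec_start,
                "offset_ms": rec_start, "recalled": False,
            }
        )
        ev_rows.append(
            {
                "subject": subject, "list": lst, "trial": -1,
                "event_type": "recall_end", "onset_ms": rec_end,
                "offset_ms": rec_end, "recalled": False,
            }
        )
    for lst, t, v in voc_rows:
        ev_rows.append(
            {
                "subject": subject, "list": lst, "trial": t,
                "event_type": "vocalization", "onset_ms": v, "offset_ms": v,
                "recalled": True,
            }
        )
    events = pd.DataFrame(ev_rows).sort_values("onset_ms").reset_index(drop=True)

    truth = GroundTruth(
        recalled=recalled,
        word_onsets_ms=word_onsets,
        voc_onsets_ms=voc_onsets,
        coupling_deltas=coupling_deltas,
        power_effects=list(cfg.power_effects),
        burst_channels=sorted(burst_channels),
        burst_events=pd.DataFrame(
            burst_rows, columns=["channel", "trial", "onset_in_trial_ms", "freq"]
        ),
    )
    raw = RawRecording(data=data, fs=fs, channels=channels)
    return SubjectData(subject, raw, events, electrodes, truth)


def generate_cohort(cfg: SimConfig) -> CohortBundle:
    """Generate all subjects (deterministic per-subject seeds from cfg.seed)."""
    cfg.validate()
    deficient = [
        (e.roi_a, e.roi_b)
        for e in cfg.coupling_graph
        if e.roi_a not in cfg.rois or e.roi_b not in cfg.rois
    ]
    if deficient:
        raise ValueError(f"coupling graph references uncovered ROI pairs: {deficient}")
    subjects = [generate_subject(cfg, i) for i in range(cfg.n_subjects)]
    return CohortBundle(cfg=cfg, subjects=subjects)


# ------------------------------------------------------------------ export

def write_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False, float_format="%.3f")


def write_electrodes_tsv(electrodes: pd.DataFrame, path: str | Path) -> None:
    electrodes.to_csv(path, sep="\t", index=False)


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())


def save_recording(raw: RawRecording, path: str | Path) -> None:
    np.savez_compressed(
        path, data=raw.data.astype(np.float32), fs=raw.fs,
        channels=np.asarray(raw.channels),
    )


def load_recording(path: str | Path) -> RawRecording:
    with np.load(path, allow_pickle=False) as z:
        return RawRecording(
            data=z["data"].astype(np.float64),
            fs=float(z["fs"]),
            channels=[str(c) for c in z["channels"]],
        )
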