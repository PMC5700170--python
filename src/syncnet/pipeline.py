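"""End-to-end orchestration: encoding, retrieval, and oscillation-subnetwork
runs over a (synthetic or loaded) cohort, with deterministic seeding and
TSV/JSON export.

Encoding analysis: bipolar montage -> 60 Hz notch -> 500 Hz -> encoding
epochs -> Morlet phase/power -> pair D statistics with 500 shared label
shuffles -> ROI/subject pooling -> coverage-masked networks -> band
summed-weight tests, hub tables, strength timecourses, power-SME maps, and
power-synchrony correlations.  Retrieval runs the identical machinery on
500 ms pre-vocalization vs. unsuccessful-search epochs with two 250 ms
windows.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .oscillations import (
    bosc_background_fit,
    detect_trials,
    oscillatory_sme,
    pepisode_fraction,
    subnetwork_edge_counts,
    subnetwork_mean_z_by_freq,
)
from .network import (
    RoiNetwork,
    apply_coverage_mask,
    band_time_average,
    exclusion_report,
    hub_test,
    network_to_edge_list,
    pool_across_subjects,
    pool_to_roi_pair,
    strength_timecourse,
    strength_zmap,
    summed_weight_test,
)
from .power_sme import (
    PowerSmeMap,
    average_electrodes_by_roi,
    core_network_split,
    electrode_power_sme,
    electrode_power_sme_null,
    pool_power_sme,
    sme_to_table,
)
from .power_synchrony import (
    correlations_to_table,
    cross_band_correlations,
    roi_power_synchrony_corr,
)
from .preprocess import (
    ENCODING_SPAN_MS,
    RETRIEVAL_SPAN_MS,
    bipolar_montage,
    epoch_encoding,
    epoch_retrieval,
    notch_filter,
    resample_to_analysis_rate,
)
from .sim import CohortBundle, SimConfig, SubjectData, generate_cohort
from .spectral import (
    ENCODING_WINDOW_MS,
    HIGH_GAMMA_FREQS,
    OSC_FREQS,
    RETRIEVAL_WINDOW_MS,
    THETA_FREQS,
    morlet_decompose,
    n_windows,
    window_average,
    window_starts_ms,
    zscore_power_within_session,
)
from .synchrony import compute_pair_stats, make_label_perms

logger = logging.getLogger(__name__)

#: encoding window indices (of the 18-window grid) covering 0-1600 ms
ITEM_WINDOW_IDX = np.arange(5, 13)
#: window indices covering -200 to 1800 ms (the 10-timepoint correlation grid)
CORR_WINDOW_IDX = np.arange(4, 14)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    sim: SimConfig
    contrast: str = "encoding"  # 'encoding' | 'retrieval'
    bands: tuple[str, ...] = ("theta", "high_gamma")
    n_perm: int = 500
    min_subjects: int = 7
    alpha: float = 0.05
    seed: int = 0
    out_dir: str | Path | None = None

    def validate(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")
        if self.contrast not in ("encoding", "retrieval"):
            raise ValueError(f"unknown contrast {self.contrast!r}")
        self.sim.validate()


@dataclass
class AnalysisBundle:
    """Outputs of an encoding or retrieval run."""

    net: RoiNetwork  # coverage-masked, full (freq, window) grid
    sme: PowerSmeMap
    banded: dict[str, RoiNetwork]
    summed: pd.DataFrame
    hubs: dict[tuple[str, str], pd.DataFrame]
    timecourses: pd.DataFrame
    power_zmap: np.ndarray  # (R, F, W)
    strength_map: np.ndarray  # (R, F, W) z-scored node strength
    corr_per_roi: pd.DataFrame
    corr_cross_band: pd.DataFrame
    core_rois: list[str]
    out_rois: list[str]
    exclusion: dict
    manifest: dict


def _preprocess_subject(sub: SubjectData, contrast: str):
    bip = bipolar_montage(sub.raw, sub.electrodes)
    bip = notch_filter(bip)
    bip = resample_to_analysis_rate(bip, 500.0)
    if contrast == "encoding":
        return epoch_encoding(bip, sub.events)
    # retrieval epochs span only 500 ms; a 1500 ms buffer keeps the slowest
    # (3 Hz, 5-cycle) wavelet shorter than the buffered epoch
    return epoch_retrieval(bip, sub.events, buffer_ms=1500.0)


def _subject_stats(
    sub: SubjectData,
    contrast: str,
    freqs: np.ndarray,
    window_ms: float,
    n_perm: int,
    master_seed: int,
    subject_index: int,
):
    """Per-subject synchrony and power-SME statistics, pooled to ROI level."""
    epochs = _preprocess_subject(sub, contrast)
    labels = epochs.condition
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError(
            f"{sub.subject}: need >= 2 trials per condition "
            f"(got {int(labels.sum())}/{int((~labels).sum())})"
        )
    tensor = morlet_decompose(epochs, freqs)
    tensor = zscore_power_within_session(tensor)
    power_w = window_average(tensor.log_power, tensor.fs, window_ms)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(master_seed), 1000 + subject_index])
    )
    perms = make_label_perms(labels, n_perm, rng)

    roi_of = list(epochs.pairs["roi"])
    names = list(epochs.pairs["pair"])
    idx_pairs = [
        (i, j) for i in range(len(roi_of)) for j in range(i + 1, len(roi_of))
    ]
    meta = [(f"{names[i]}|{names[j]}", roi_of[i], roi_of[j]) for i, j in idx_pairs]
    stats = compute_pair_stats(tensor, idx_pairs, window_ms, perms, meta)
    sync_pool = pool_to_roi_pair(stats)

    t_true = np.stack(
        [electrode_power_sme(power_w[ch], labels) for ch in range(len(roi_of))]
    )
    t_null = np.stack(
        [electrode_power_sme_null(power_w[ch], perms) for ch in range(len(roi_of))],
        axis=1,
    )  # (P, ch, F, W)
    power_pool = average_electrodes_by_roi(roi_of, t_true, t_null)
    return sync_pool, power_pool


def _config_hash(cfg: RunConfig) -> str:
    obj = dataclasses.asdict(cfg)
    obj.pop("out_dir", None)  # output location does not define the run
    blob = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _run_contrast(cfg: RunConfig, cohort: CohortBundle | None) -> AnalysisBundle:
    cfg.validate()
    if cohort is None:
        cohort = generate_cohort(cfg.sim)
    contrast = cfg.contrast
    if contrast == "retrieval" and not cfg.sim.include_retrieval:
        raise ValueError("retrieval contrast requested but cohort has no recall data")
    window_ms = ENCODING_WINDOW_MS if contrast == "encoding" else RETRIEVAL_WINDOW_MS
    span = ENCODING_SPAN_MS if contrast == "encoding" else RETRIEVAL_SPAN_MS
    freqs = np.concatenate([THETA_FREQS, HIGH_GAMMA_FREQS])
    w_starts = window_starts_ms(span, window_ms)
    n_win = n_windows(span, window_ms)
    item_idx = ITEM_WINDOW_IDX if contrast == "encoding" else np.arange(n_win)
    corr_idx = CORR_WINDOW_IDX if contrast == "encoding" else np.arange(n_win)

    sync_pools, power_pools = [], []
    for s, sub in enumerate(cohort.subjects):
        logger.info("stage synchrony/power: subject %s", sub.subject)
        sync_pool, power_pool = _subject_stats(
            sub, contrast, freqs, window_ms, cfg.n_perm, cfg.seed, s
        )
        sync_pools.append(sync_pool)
        power_pools.append(power_pool)

    rois = sorted(cfg.sim.rois)
    net = pool_across_subjects(sync_pools, rois, freqs, w_starts)
    net = apply_coverage_mask(net, cfg.min_subjects)
    sme = pool_power_sme(power_pools, rois, freqs, w_starts)

    banded, summed_rows, hubs = {}, [], {}
    for band in cfg.bands:
        bnet = band_time_average(net, band, item_idx)
        banded[band] = bnet
        for sign in ("+", "-"):
            res = summed_weight_test(bnet, sign)
            summed_rows.append({"band": band, "sign": sign, **res})
            hubs[(band, sign)] = hub_test(bnet, sign, cfg.alpha)
    summed = pd.DataFrame(summed_rows)

    tc_frames = []
    for band in cfg.bands:
        for sign in ("+", "-"):
            tc = strength_timecourse(net, band, sign, alpha=cfg.alpha)
            tc.insert(0, "band", band)
            tc.insert(1, "sign", sign)
            tc_frames.append(tc)
    timecourses = pd.concat(tc_frames, ignore_index=True)

    power_zmap = sme.zscores()
    strength_map = strength_zmap(net, sign=None)
    sampled = sme.subject_count > 0
    hg_idx = np.flatnonzero((freqs >= 45) & (freqs <= 100))
    corr_per_roi = roi_power_synchrony_corr(
        power_zmap, strength_map, rois, sampled,
        pixel_mask=(hg_idx, item_idx), alpha=cfg.alpha,
    )

    core, out_rois = core_network_split(sme, "high_gamma", item_idx, cfg.alpha)
    cross = cross_band_correlations(
        power_zmap, strength_map, freqs, corr_idx, rois, subset_tag="all",
        roi_subset=[r for i, r in enumerate(rois) if sampled[i]],
    )
    for tag, subset in (("core", core), ("out", out_rois)):
        if len(subset) >= 2:
            cross += cross_band_correlations(
                power_zmap, strength_map, freqs, corr_idx, rois,
                roi_subset=subset, subset_tag=tag,
            )
    corr_cross = correlations_to_table(cross)

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "contrast": contrast,
        "n_perm": cfg.n_perm,
        "n_subjects": len(cohort.subjects),
        "window_ms": window_ms,
        "n_windows": n_win,
    }
    bundle = AnalysisBundle(
        net=net, sme=sme, banded=banded, summed=summed, hubs=hubs,
        timecourses=timecourses, power_zmap=power_zmap,
        strength_map=strength_map, corr_per_roi=corr_per_roi,
        corr_cross_band=corr_cross, core_rois=core, out_rois=out_rois,
        exclusion=exclusion_report(net), manifest=manifest,
    )
    if cfg.out_dir is not None:
        export_bundle(bundle, cfg.out_dir)
    return bundle


def run_encoding(cfg: RunConfig, cohort: CohortBundle | None = None) -> AnalysisBundle:
    """Encoding (remembered vs. not-remembered) contrast, 200 ms windows."""
    if cfg.contrast != "encoding":
        raise ValueError("cfg.contrast must be 'encoding'")
    return _run_contrast(cfg, cohort)


def run_retrieval(cfg: RunConfig, cohort: CohortBundle | None = None) -> AnalysisBundle:
    """Retrieval (pre-vocalization vs. unsuccessful search), 250 ms windows."""
    if cfg.contrast != "retrieval":
        raise ValueError("cfg.contrast must be 'retrieval'")
    return _run_contrast(cfg, cohort)


@dataclass
class SubnetBundle:
    """Outputs of the oscillatory-subnetwork run."""

    n_flagged_electrodes: int
    flagged: pd.DataFrame  # subject, channel, peak_freq, peak_window_start_ms
    net: RoiNetwork | None
    counts: dict  # band tag -> edge-count summary
    mean_z_by_freq: pd.DataFrame | None
    manifest: dict


#: frequency grids for the oscillatory subnetwork contrast
SUBNET_FREQS = np.array([50.0, 55.0, 65.0, 70.0, 75.0, 80.0, 85.0])
SUBNET_BANDS = {"50-55": (50.0, 55.0), "65-85": (65.0, 85.0)}
#: analysis window of maximal oscillatory SME (ms from word onset)
SUBNET_WINDOW_MS = (400.0, 600.0)


def run_oscillation_subnet(
    cfg: RunConfig,
    cohort: CohortBundle | None = None,
    sme_alpha: float = 0.1,
    allow_empty: bool = False,
) -> SubnetBundle:
    """BOSC oscillatory-SME electrode selection and subnetwork statistics."""
    cfg.validate()
    if cohort is None:
        cohort = generate_cohort(cfg.sim)
    window_ms = ENCODING_WINDOW_MS
    w_starts = window_starts_ms(ENCODING_SPAN_MS, window_ms)
    subnet_w = int(
        np.flatnonzero(np.isclose(w_starts, SUBNET_WINDOW_MS[0]))[0]
    )

    flagged_rows = []
    sync_pools = []
    for s, sub in enumerate(cohort.subjects):
        epochs = _preprocess_subject(sub, "encoding")
        labels = epochs.condition
        tensor = morlet_decompose(epochs, OSC_FREQS)
        fs = tensor.fs
        i0 = int(round((0.0 - tensor.t_start_ms) * fs / 1000.0))
        i1 = i0 + int(round(1600.0 * fs / 1000.0))
        flagged_ch = []
        for ch in range(tensor.phasor.shape[0]):
            power = np.exp(tensor.log_power[ch].astype(np.float64))
            bg = bosc_background_fit(
                OSC_FREQS, np.log(power.mean(axis=(0, 2)))
            )
            mask = detect_trials(power, OSC_FREQS, bg, fs)
            fractions = pepisode_fraction(mask[..., i0:i1], fs, window_ms)
            res = oscillatory_sme(fractions, labels, alpha=sme_alpha)
            if res["flagged"]:
                flagged_ch.append(ch)
                tz = np.where(res["significant"], res["t"], -np.inf)
                fi, wi = np.unravel_index(np.argmax(tz), tz.shape)
                flagged_rows.append(
                    {
                        "subject": sub.subject,
                        "channel": epochs.pairs["pair"].iloc[ch],
                        "roi": epochs.pairs["roi"].iloc[ch],
                        "peak_freq": OSC_FREQS[fi],
                        "peak_window_start_ms": wi * window_ms,
                    }
                )
        del tensor
        if len(flagged_ch) < 2:
            continue
        roi_of = [epochs.pairs["roi"].iloc[ch] for ch in flagged_ch]
        if len(set(roi_of)) < 2:
            continue
        sub_epochs = dataclasses.replace(
            epochs, data=epochs.data[flagged_ch],
            pairs=epochs.pairs.iloc[flagged_ch].reset_index(drop=True),
        )
        t_hg = morlet_decompose(sub_epochs, SUBNET_FREQS)
        rng = np.random.default_rng(
            np.random.SeedSequence([int(cfg.seed), 2000 + s])
        )
        perms = make_label_perms(labels, cfg.n_perm, rng)
        names = list(sub_epochs.pairs["pair"])
        idx_pairs = [
            (i, j) for i in range(len(roi_of)) for j in range(i + 1, len(roi_of))
        ]
        meta = [(f"{names[i]}|{names[j]}", roi_of[i], roi_of[j]) for i, j in idx_pairs]
        stats = compute_pair_stats(t_hg, idx_pairs, window_ms, perms, meta)
        for st in stats:  # keep only the 400-600 ms window
            st.d_true = st.d_true[:, [subnet_w]]
            st.d_null = st.d_null[:, :, [subnet_w]]
        sync_pools.append(pool_to_roi_pair(stats))

    flagged = pd.DataFrame(
        flagged_rows,
        columns=["subject", "channel", "roi", "peak_freq", "peak_window_start_ms"],
    )
    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "n_flagged": len(flagged),
    }
    if not sync_pools:
        if not allow_empty:
            raise ValueError(
                "oscillatory subnetwork is empty: "
                f"{len(flagged)} flagged electrodes, no subject contributes "
                "two flagged electrodes spanning distinct ROIs"
            )
        return SubnetBundle(
            n_flagged_electrodes=len(flagged), flagged=flagged, net=None,
            counts={}, mean_z_by_freq=None, manifest=manifest,
        )
    rois = sorted(cfg.sim.rois)
    net = pool_across_subjects(
        sync_pools, rois, SUBNET_FREQS, np.array([SUBNET_WINDOW_MS[0]])
    )  # no minimum-subject mask for the sparse subnetwork
    counts = {}
    for tag, band in SUBNET_BANDS.items():
        bnet = band_time_average(net, band)
        counts[tag] = subnetwork_edge_counts(bnet, alpha=0.05)
    return SubnetBundle(
        n_flagged_electrodes=len(flagged),
        flagged=flagged,
        net=net,
        counts=counts,
        mean_z_by_freq=subnetwork_mean_z_by_freq(net),
        manifest=manifest,
    )


def export_bundle(bundle: AnalysisBundle, out_dir: str | Path) -> None:
    """Write all bundle tables as TSV plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = {"sep": "\t", "index": False, "float_format": "%.6g"}
    for band, bnet in bundle.banded.items():
        network_to_edge_list(bnet, band).to_csv(out / f"network_{band}.tsv", **fmt)
    bundle.summed.to_csv(out / "summed_weights.tsv", **fmt)
    for (band, sign), table in bundle.hubs.items():
        tag = "pos" if sign == "+" else "neg"
        table.to_csv(out / f"hubs_{band}_{tag}.tsv", **fmt)
    bundle.timecourses.to_csv(out / "strength_timecourses.tsv", **fmt)
    sme_to_table(bundle.sme).to_csv(out / "power_sme.tsv", **fmt)
    bundle.corr_per_roi.to_csv(out / "corr_per_roi.tsv", **fmt)
    bundle.corr_cross_band.to_csv(out / "corr_cross_band.tsv", **fmt)
    pd.DataFrame(
        {"core": pd.Series(bundle.core_rois), "out": pd.Series(bundle.out_rois)}
    ).to_csv(out / "core_network_split.tsv", **fmt)
    (out / "manifest.json").write_text(
        json.dumps({**bundle.manifest, "exclusion": bundle.exclusion}, indent=1)
    )
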