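"""End-to-end pipelines: the follow-up study and the two classification tasks.

Each runner consumes a validated :class:`~mirebound.config.PipelineConfig`,
derives all randomness from its single seed, writes every artifact (CSV
tables, JSON report, the resolved config) into the output directory and
returns the in-memory results.  Re-running with the same config reproduces
the outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .containers import EpochSet
from .erders import (
    band_power_timecourse,
    condition_difference,
    erders_timecourse,
    single_trial_erders,
)
from .features import assemble_features
from .io import load_epochs, save_epochs, write_summary_csv
from .model import ClassificationReport, cross_validate, select_then_classify
from .rebound import (
    FollowUpOutcome,
    FollowUpSummary,
    difference_map,
    follow_up_present,
    summarize_follow_up,
)
from .slr import SLRFit
from .synthetic import default_profiles, generate_epochs

__all__ = ["concat_epochs", "run_followup_study", "run_classification"]

logger = logging.getLogger(__name__)


def concat_epochs(parts: list[EpochSet]) -> EpochSet:
    """Stack epoch sets sharing fs, channels and time axis."""
    first = parts[0]
    for p in parts[1:]:
        if p.channel_labels != first.channel_labels or p.fs != first.fs:
            raise ValueError("epoch sets are incompatible")
        if not np.allclose(p.time_axis, first.time_axis):
            raise ValueError("epoch time axes differ")
    return EpochSet(
        data=np.concatenate([p.data for p in parts]),
        fs=first.fs,
        channel_labels=list(first.channel_labels),
        time_axis=first.time_axis.copy(),
        labels=pd.concat([p.labels for p in parts], ignore_index=True),
    )


def _erds_trace(epochs: EpochSet, cfg: PipelineConfig):
    bp = band_power_timecourse(epochs, cfg.band, cfg.smooth_window)
    return erders_timecourse(bp, cfg.reference_interval)


def _synthetic_pair(cfg: PipelineConfig, seed_me: int, seed_mi: int, subject, motion,
                    profiles=None):
    profiles = profiles or default_profiles()
    me, _ = generate_epochs(
        profiles["ME"], cfg.n_trials, cfg.channels, cfg.fs, cfg.epoch_window,
        seed_me, condition="ME", motion=motion, subject=subject,
    )
    mi, _ = generate_epochs(
        profiles["MI"], cfg.n_trials, cfg.channels, cfg.fs, cfg.epoch_window,
        seed_mi, condition="MI", motion=motion, subject=subject,
    )
    return me, mi


def _paired_epochs(cfg: PipelineConfig, profiles=None):
    """Yield (subject, motion, me_epochs, mi_epochs) pairs."""
    if cfg.input_path is not None:
        epochs = load_epochs(cfg.input_path)
        groups = epochs.labels.groupby(["subject", "motion"])
        missing = []
        pairs = []
        for (subject, motion), idx in groups.groups.items():
            sub = epochs.labels.loc[idx, "condition"]
            conditions = set(sub)
            if not {"ME", "MI"} <= conditions:
                missing.append(f"{subject}/{motion}")
                continue
            rows = np.asarray(idx)
            me_rows = rows[(epochs.labels.loc[idx, "condition"] == "ME").to_numpy()]
            mi_rows = rows[(epochs.labels.loc[idx, "condition"] == "MI").to_numpy()]
            me = EpochSet(
                epochs.data[me_rows], epochs.fs, list(epochs.channel_labels),
                epochs.time_axis, epochs.labels.iloc[me_rows].reset_index(drop=True),
            )
            mi = EpochSet(
                epochs.data[mi_rows], epochs.fs, list(epochs.channel_labels),
                epochs.time_axis, epochs.labels.iloc[mi_rows].reset_index(drop=True),
            )
            pairs.append((str(subject), str(motion), me, mi))
        if missing:
            raise ValueError(f"unpaired conditions for: {', '.join(sorted(missing))}")
        return pairs
    rng = np.random.default_rng(cfg.seed)
    pairs = []
    for s in range(cfg.n_subjects):
        for m in range(cfg.n_motions):
            seed_me = int(rng.integers(0, 2**31))
            seed_mi = int(rng.integers(0, 2**31))
            subject, motion = f"S{s + 1:02d}", f"M{m + 1}"
            me, mi = _synthetic_pair(cfg, seed_me, seed_mi, subject, motion, profiles)
            pairs.append((subject, motion, me, mi))
    return pairs


def run_followup_study(
    cfg: PipelineConfig,
    output_dir: str | Path | None = None,
    profiles: dict | None = None,
) -> tuple[FollowUpSummary, FollowUpSummary, list[FollowUpOutcome]]:
    """Paired ME/MI cohort -> ERD/ERS -> follow-up decisions -> summaries.

    Writes subject- and motion-level percentage tables, a time-by-subject
    difference-map CSV for the first motion, and the resolved config.
    ``profiles`` overrides the default synthetic condition profiles (must
    contain keys ``ME`` and ``MI``); ignored when reading epochs from disk.
    """
    t_start = time.perf_counter()
    out = Path(output_dir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outcomes = []
    first_motion_diffs: dict[str, object] = {}
    for subject, motion, me, mi in _paired_epochs(cfg, profiles):
        tr_me, tr_mi = _erds_trace(me, cfg), _erds_trace(mi, cfg)
        outcome = follow_up_present(
            tr_me,
            tr_mi,
            cfg.followup_channel,
            cfg.search_window,
            cfg.min_magnitude,
            subject=subject,
            motion=motion,
            min_amplitude=cfg.min_amplitude,
        )
        outcomes.append(outcome)
        if motion == outcomes[0].motion:
            first_motion_diffs[subject] = condition_difference(tr_me, tr_mi)
    by_subject = summarize_follow_up(outcomes, by="subject")
    by_motion = summarize_follow_up(outcomes, by="motion")
    write_summary_csv(by_subject, out / "followup_by_subject.csv")
    write_summary_csv(by_motion, out / "followup_by_motion.csv")
    difference_map(first_motion_diffs, cfg.followup_channel).to_csv(
        out / "difference_map.csv", float_format="%.4f"
    )
    (out / "resolved_config.json").write_text(cfg.resolved_json())
    logger.info(
        "follow-up study: %d pairs in %.1f s", len(outcomes), time.perf_counter() - t_start
    )
    return by_subject, by_motion, outcomes


def _classification_cohort(cfg: PipelineConfig) -> EpochSet:
    if cfg.input_path is not None:
        return load_epochs(cfg.input_path)
    rng = np.random.default_rng(cfg.seed)
    profiles = default_profiles()
    if cfg.task == "me_vs_mi":
        spec = [("ME", "ME", "none"), ("MI", "MI", "none")]
    else:
        spec = [("left", "MI", "left"), ("right", "MI", "right")]
    parts = []
    for name, condition, hand in spec:
        seed = int(rng.integers(0, 2**31))
        ep, _ = generate_epochs(
            profiles[name], cfg.n_trials, cfg.channels, cfg.fs, cfg.epoch_window,
            seed, condition=condition, hand=hand,
        )
        parts.append(ep)
    return concat_epochs(parts)


def run_classification(
    cfg: PipelineConfig, output_dir: str | Path | None = None
) -> tuple[ClassificationReport, SLRFit | None]:
    """Feature extraction -> optional SLR selection -> SVM cross-validation.

    Features are computed on the post-stimulus reactive window
    (``cfg.feature_window``); the per-trial ERD/ERS series feeding sample
    entropy is normalized against the pre-stimulus reference of the full
    epoch before cropping.
    """
    t_start = time.perf_counter()
    if cfg.task not in ("me_vs_mi", "left_vs_right"):
        raise ValueError("classification task must be me_vs_mi or left_vs_right")
    out = Path(output_dir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    epochs = _classification_cohort(cfg)

    erds_series = None
    if cfg.task == "left_vs_right":
        erds_series = single_trial_erders(epochs, cfg.band, cfg.reference_interval,
                                          cfg.smooth_window)
        mask = (epochs.time_axis >= cfg.feature_window[0] - 1e-9) & (
            epochs.time_axis <= cfg.feature_window[1] + 1e-9
        )
        erds_series = erds_series[:, :, mask]
    cropped = epochs.crop(*cfg.feature_window)
    fm = assemble_features(cropped, cfg.task, band=cfg.band, erds_series=erds_series)
    fm.to_frame().to_csv(out / "features.csv", index=False, float_format="%.10g")

    slr_fit = None
    if cfg.slr_variant != "none":
        slr_fit, report = select_then_classify(
            fm, variant=cfg.slr_variant, k=cfg.cv_folds, seed=cfg.seed,
            optimize=cfg.optimize_svm,
        )
    else:
        report = cross_validate(fm, k=cfg.cv_folds, seed=cfg.seed, optimize=cfg.optimize_svm)
    (out / "report.json").write_text(
        json.dumps(report.to_dict(), sort_keys=True, indent=1)
    )
    (out / "resolved_config.json").write_text(cfg.resolved_json())
    logger.info(
        "classification %s: %.2f%% mean accuracy in %.1f s",
        cfg.task, report.mean_accuracy, time.perf_counter() - t_start,
    )
    return report, slr_fit


def simulate_to_sidecar(cfg: PipelineConfig, path: str | Path) -> Path:
    """Generate the synthetic cohort a config describes and save it."""
    if cfg.task == "followup":
        parts = []
        for subject, motion, me, mi in _paired_epochs(cfg):
            parts += [me, mi]
        epochs = concat_epochs(parts)
    else:
        epochs = _classification_cohort(cfg)
    return save_epochs(epochs, path)
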