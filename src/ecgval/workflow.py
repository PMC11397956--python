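"""End-to-end evaluation: read → truncate → detect → sync → match → report.

These drivers bind the library modules into the validation workflow: the
criterion record is beat-detected, each device stream is aligned onto the
criterion timeline via RR-tachogram correlation, device beats are matched
one-to-one against criterion beats, and per-stratum tables plus RR′
agreement statistics are assembled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import DetectorConfig, PeakList, detect_r_peaks
from .io import RRSeries, StreamBundle
from .sync import AlignmentResult, coarse_align, refine_by_rr_correlation
from .validation import (
    MatchResult,
    bland_altman,
    match_peaks,
    paired_rr_differences,
    stratified_report,
)

__all__ = ["BundleEvaluation", "evaluate_bundle", "study_report"]


@dataclass
class BundleEvaluation:
    bundle: StreamBundle
    criterion_peaks: PeakList
    chest_match: MatchResult | None = None
    chest_alignment: AlignmentResult | None = None
    chest_peaks_ms: np.ndarray | None = None
    rr_match: MatchResult | None = None
    rr_alignment: AlignmentResult | None = None
    rr_beats_ms: np.ndarray | None = None


def _align_and_match(
    criterion_times: np.ndarray,
    device_times: np.ndarray,
    threshold_ms: float,
    search_ms: float,
    step_ms: float,
) -> tuple[MatchResult, AlignmentResult | None, np.ndarray]:
    """Offset-correct device beats against criterion beats, then match."""
    alignment = None
    if criterion_times.size >= 12 and device_times.size >= 12:
        ref = RRSeries.from_beat_times(criterion_times)
        dev = RRSeries.from_beat_times(device_times)
        center = coarse_align(ref, dev)
        if abs(center) > search_ms:
            center = float(np.clip(center, -search_ms, search_ms))
        alignment = refine_by_rr_correlation(
            ref,
            dev,
            search_ms=search_ms,
            step_ms=step_ms,
            center_ms=0.0 if abs(center) < step_ms else center,
            min_overlap_beats=10,
        )
        if alignment.verified:
            device_times = device_times + alignment.offset_ms
    # compare only over the mutual span: a beat outside the other stream's
    # recording window is unobservable, not a detection error
    if criterion_times.size and device_times.size:
        device_times = device_times[
            (device_times >= criterion_times[0] - threshold_ms)
            & (device_times <= criterion_times[-1] + threshold_ms)
        ]
    if criterion_times.size and device_times.size:
        criterion_times = criterion_times[
            (criterion_times >= device_times[0] - threshold_ms)
            & (criterion_times <= device_times[-1] + threshold_ms)
        ]
    match = match_peaks(criterion_times, device_times, threshold_ms=threshold_ms)
    return match, alignment, device_times


def evaluate_bundle(
    bundle: StreamBundle,
    detector_config: DetectorConfig | None = None,
    threshold_ms: float = 100.0,
    sync_search_ms: float = 8000.0,
    sync_step_ms: float = 50.0,
) -> BundleEvaluation:
    """Detect, synchronise and match every device stream of one bundle."""
    detector_config = detector_config or DetectorConfig()
    crit_peaks, _ = detect_r_peaks(bundle.criterion, detector_config)
    out = BundleEvaluation(bundle=bundle, criterion_peaks=crit_peaks)
    ct = crit_peaks.peak_epoch_ms

    if bundle.device_ecg is not None:
        dev_peaks, _ = detect_r_peaks(bundle.device_ecg, detector_config)
        out.chest_match, out.chest_alignment, out.chest_peaks_ms = _align_and_match(
            ct, dev_peaks.peak_epoch_ms, threshold_ms, sync_search_ms, sync_step_ms
        )
    if bundle.device_rr is not None:
        out.rr_match, out.rr_alignment, out.rr_beats_ms = _align_and_match(
            ct, bundle.device_rr.beat_times_full(), threshold_ms, sync_search_ms, sync_step_ms
        )
    return out


def study_report(
    bundles: list[StreamBundle],
    detector_config: DetectorConfig | None = None,
    threshold_ms: float = 100.0,
    sync_search_ms: float = 8000.0,
    sync_step_ms: float = 50.0,
) -> dict:
    """Stratified sensitivity/precision tables and RR′ agreement per device.

    Counts are summed per (activity, exercise-mode) stratum over subjects
    and rates computed from the pooled counts; RR′ Bland–Altman statistics
    pool matched-pair differences per activity.
    """
    evals = [
        evaluate_bundle(b, detector_config, threshold_ms, sync_search_ms, sync_step_ms)
        for b in bundles
    ]
    report: dict = {"evaluations": evals, "tables": {}, "agreement": {}}
    for device in ("chest", "rr"):
        rows: dict[tuple[str, str], dict] = {}
        diffs_by_activity: dict[str, list[pd.DataFrame]] = {}
        for ev in evals:
            match = ev.chest_match if device == "chest" else ev.rr_match
            if match is None:
                continue
            key = (ev.bundle.activity_label, ev.bundle.mode)
            row = rows.setdefault(
                key,
                {
                    "activity": key[0],
                    "exercise": key[1],
                    "participants": 0,
                    "tp": 0,
                    "fn": 0,
                    "fp": 0,
                },
            )
            row["participants"] += 1
            row["tp"] += match.tp
            row["fn"] += match.fn
            row["fp"] += match.fp
            diffs_by_activity.setdefault(key[0], []).append(paired_rr_differences(match))
        if not rows:
            continue
        report["tables"][device] = stratified_report(list(rows.values()))
        agreement = {}
        for activity, frames in diffs_by_activity.items():
            frames = [f for f in frames if len(f)]
            if not frames:
                continue
            diffs = pd.concat(frames, ignore_index=True)
            if len(diffs) >= 2:
                agreement[activity] = bland_altman(diffs["diff_ms"])
        pooled = [f for frames in diffs_by_activity.values() for f in frames if len(f)]
        if pooled:
            all_diffs = pd.concat(pooled, ignore_index=True)
            if len(all_diffs) >= 2:
                agreement["overall"] = bland_altman(all_diffs["diff_ms"])
        report["agreement"][device] = agreement
    return report
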