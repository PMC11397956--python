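"""Exercise-robust R-peak detection.

The detector is built for chest-strap and laboratory ECG recorded during
incremental exercise to exhaustion, where heart rate spans roughly
60–200 bpm within one recording and electrode motion perturbs amplitude.
It works as follows:

1. the record is segmented into short intervals so the voltage statistics
   used for thresholding track slow amplitude drift;
2. each interval is scanned twice — once for upright R apices and once on
   the inverted signal for dominant S deflections, so lead polarity and
   electrode placement do not matter;
3. per interval and branch, a threshold is chosen by descending through the
   sorted voltage tail until the implied beat count is physiologically
   plausible (30–240 bpm) and no two supra-threshold local maxima violate
   the ~200 ms QRS refractory period;
4. the two branches merge into one beat list (the dominant deflection wins
   when both branches see the same beat);
5. RR intervals are screened against a rolling robust baseline; anomalous
   gaps trigger a local re-search around the expected beat time with a
   relaxed threshold, and suspected spurious beats are pruned;
6. steps 4–5 iterate, lowering thresholds in intervals with dense
   anomalies, until no repair changes the beat list.

Detection is fully deterministic: same record and configuration, same
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences

from .io import ECGRecord

__all__ = [
    "DetectorConfig",
    "PeakList",
    "DetectionDiagnostics",
    "IntervalRange",
    "segment_intervals",
    "detect_in_interval",
    "merge_branches",
    "flag_abnormal_rr",
    "local_repeak_search",
    "detect_r_peaks",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable detector parameters (times in s/ms as named).

    ``threshold_quantile_start`` is the percentile of window voltage at
    which the threshold search begins; it is lowered one percentile at a
    time (never below ``threshold_quantile_floor``) until the candidate set
    is plausible.
    """

    interval_s: float = 10.0
    refractory_ms: float = 200.0
    threshold_quantile_start: float = 99.0
    threshold_quantile_floor: float = 70.0
    bpm_min: float = 30.0
    bpm_max: float = 240.0
    anomaly_window: int = 11
    anomaly_k: float = 4.0
    anomaly_floor_frac: float = 0.05
    anomaly_floor_ms: float = 20.0
    high_ratio: float = 1.8
    low_ratio: float = 0.55
    cluster_span_frac: float = 0.5
    search_halfwidth_ms: float = 300.0
    repair_gate: float = 0.5
    max_iterations: int = 5
    redetect_anomaly_frac: float = 0.3
    redetect_quantile_step: float = 5.0

    def __post_init__(self) -> None:
        if self.interval_s <= 0 or self.refractory_ms < 0 or self.max_iterations < 1:
            raise ValueError("invalid detector configuration")


@dataclass
class PeakList:
    """Detected (or ground-truth) beat events on a record's sample grid."""

    peak_epoch_ms: np.ndarray
    sample_index: np.ndarray
    branch: np.ndarray  # 'R' | 'S' | 'repaired'
    source_label: str = ""

    def __post_init__(self) -> None:
        self.peak_epoch_ms = np.asarray(self.peak_epoch_ms, dtype=float)
        self.sample_index = np.asarray(self.sample_index, dtype=int)
        self.branch = np.asarray(self.branch, dtype=object)
        if not (self.peak_epoch_ms.size == self.sample_index.size == self.branch.size):
            raise ValueError("peak arrays must align")
        if self.peak_epoch_ms.size and np.any(np.diff(self.peak_epoch_ms) <= 0):
            raise ValueError("peak times must be strictly increasing")

    @property
    def n_peaks(self) -> int:
        return int(self.peak_epoch_ms.size)

    def rr_ms(self) -> np.ndarray:
        return np.diff(self.peak_epoch_ms)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peak_epoch_ms": self.peak_epoch_ms,
                "sample_index": self.sample_index,
                "branch": self.branch,
            }
        )


@dataclass
class DetectionDiagnostics:
    interval_thresholds: list[float] = field(default_factory=list)
    n_r_only: int = 0
    n_s_only: int = 0
    n_both: int = 0
    anomalies_flagged: int = 0
    repairs_made: int = 0
    removals_made: int = 0
    iterations: int = 0
    last_iteration_repairs: int = 0
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "interval_thresholds": [float(t) for t in self.interval_thresholds],
            "n_r_only": self.n_r_only,
            "n_s_only": self.n_s_only,
            "n_both": self.n_both,
            "anomalies_flagged": self.anomalies_flagged,
            "repairs_made": self.repairs_made,
            "removals_made": self.removals_made,
            "iterations": self.iterations,
            "last_iteration_repairs": self.last_iteration_repairs,
            "notes": self.notes,
        }


@dataclass(frozen=True)
class IntervalRange:
    start: int  # inclusive sample index
    stop: int  # exclusive
    fs: float


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_intervals(record: ECGRecord, interval_s: float) -> list[IntervalRange]:
    """Partition a record into contiguous half-open index ranges.

    Ranges are ``interval_s`` long except possibly a short final one; their
    union is the full index set. The rate measured from the record's
    timestamps is attached to each range.
    """
    if interval_s <= 0:
        raise ValueError("interval_s must be positive")
    n = record.n_samples
    if n < 1:
        raise ValueError("record has no samples")
    step = max(1, int(round(interval_s * record.fs)))
    ranges = []
    for start in range(0, n, step):
        ranges.append(IntervalRange(start=start, stop=min(start + step, n), fs=record.fs))
    return ranges


# ---------------------------------------------------------------------------
# per-interval thresholded detection
# ---------------------------------------------------------------------------


def _plausible_count(n_peaks: int, duration_s: float, config: DetectorConfig) -> bool:
    lo = max(1, int(np.floor(config.bpm_min * duration_s / 60.0)))
    hi = int(np.ceil(config.bpm_max * duration_s / 60.0))
    return lo <= n_peaks <= hi


def detect_in_interval(
    window: np.ndarray,
    polarity: Literal["R", "S"],
    config: DetectorConfig,
    fs: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Candidate peaks in one window for one branch.

    Returns ``(indices, voltages, threshold)`` with indices local to the
    window and voltages in the original (non-inverted) sign.

    The threshold search descends through the sorted voltage tail one
    percentile at a time. At each level, supra-threshold local maxima
    closer than the refractory period are clustered onto their dominant
    sample (micro-maxima from noise riding one apex collapse; wide chains
    betray noise and disqualify the level). The accepted threshold is the
    highest one whose candidate set is plausible (30–240 bpm for the
    window length), refractory-consistent, and *stable* — the next
    percentile step adds no new beat — so the search keeps descending
    while genuinely smaller apices are still being uncovered, but stops
    before repolarisation waves or noise enter. A window where no level
    qualifies (flat line, pure noise) yields no candidates.
    """
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    if polarity == "S":
        x = -x
    if np.ptp(x) == 0:
        return np.zeros(0, dtype=int), np.zeros(0), np.nan
    duration_s = x.size / fs
    refractory_samples = config.refractory_ms * fs / 1000.0
    max_span = config.cluster_span_frac * refractory_samples
    xs = np.sort(x)

    def _threshold(q: float) -> float:
        return float(xs[min(int(q / 100.0 * (xs.size - 1)), xs.size - 1)])

    def _candidates(q: float) -> tuple[np.ndarray, np.ndarray, float]:
        thr = _threshold(q)
        raw, _ = find_peaks(x, height=thr)
        reps, spans = _cluster_maxima(x, raw, refractory_samples)
        return reps, spans, thr

    q = config.threshold_quantile_start
    prev: tuple[np.ndarray, np.ndarray, float] | None = None
    while q >= config.threshold_quantile_floor:
        reps, spans, thr = _candidates(q)
        ok = (
            reps.size > 0
            and _plausible_count(reps.size, duration_s, config)
            and (spans.size == 0 or spans.max() <= max_span)
        )
        if ok and prev is not None and np.array_equal(reps, prev[0]):
            # stable across one percentile step: accept the higher level
            return prev[0], np.asarray(window[prev[0]], dtype=float), prev[2]
        prev = (reps, spans, thr) if ok else None
        q -= 1.0
    return np.zeros(0, dtype=int), np.zeros(0), np.nan


def _cluster_maxima(
    x: np.ndarray, raw_peaks: np.ndarray, refractory_samples: float
) -> tuple[np.ndarray, np.ndarray]:
    """Chain supra-threshold maxima closer than the refractory period.

    Each chain is represented by its largest sample (tie → earliest), so
    representatives of adjacent chains are automatically separated by at
    least the refractory period. Returns ``(representatives, spans)`` with
    spans in samples.
    """
    if raw_peaks.size == 0:
        return raw_peaks, np.zeros(0)
    breaks = np.nonzero(np.diff(raw_peaks) >= refractory_samples)[0] + 1
    reps, spans = [], []
    for grp in np.split(raw_peaks, breaks):
        reps.append(grp[int(np.argmax(x[grp]))])
        spans.append(grp[-1] - grp[0])
    return np.asarray(reps, dtype=int), np.asarray(spans, dtype=float)


# ---------------------------------------------------------------------------
# branch merging
# ---------------------------------------------------------------------------


def merge_branches(
    r_peaks: tuple[np.ndarray, np.ndarray],
    s_peaks: tuple[np.ndarray, np.ndarray],
    refractory_ms: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Combine R- and S-branch candidates into one refractory-consistent list.

    Inputs are ``(times_ms, voltages)`` per branch. Candidates from both
    branches closer than the refractory period describe the same beat and
    collapse to a single event; the deflection with the larger |voltage|
    keeps its time (tie → R branch, then the earlier event). The survivors
    are strictly sorted and pairwise separated by at least the refractory
    period. Returns ``(times, voltages, branches)``.
    """
    rt, rv = (np.asarray(a, dtype=float) for a in r_peaks)
    st, sv = (np.asarray(a, dtype=float) for a in s_peaks)
    times = np.concatenate([rt, st])
    volts = np.concatenate([rv, sv])
    branches = np.concatenate([np.full(rt.size, "R", dtype=object), np.full(st.size, "S", dtype=object)])
    if times.size == 0:
        return times, volts, branches
    # stable sort keeps R before S at equal times, giving the tie-break
    order = np.argsort(times, kind="stable")
    times, volts, branches = times[order], volts[order], branches[order]

    keep_t: list[float] = []
    keep_v: list[float] = []
    keep_b: list[str] = []
    for t, v, b in zip(times, volts, branches):
        if keep_t and t - keep_t[-1] < refractory_ms:
            # same beat: keep the dominant deflection
            better = abs(v) > abs(keep_v[-1]) or (
                abs(v) == abs(keep_v[-1]) and b == "R" and keep_b[-1] != "R"
            )
            if better:
                keep_t[-1], keep_v[-1], keep_b[-1] = t, v, b
        else:
            keep_t.append(float(t))
            keep_v.append(float(v))
            keep_b.append(str(b))
    return (
        np.asarray(keep_t),
        np.asarray(keep_v),
        np.asarray(keep_b, dtype=object),
    )


# ---------------------------------------------------------------------------
# RR anomaly screening
# ---------------------------------------------------------------------------


def flag_abnormal_rr(peak_times_ms: np.ndarray, config: DetectorConfig) -> pd.DataFrame:
    """Screen RR intervals against a rolling robust baseline.

    An interval is anomalous when it deviates from the rolling median
    (window of ``anomaly_window`` intervals) by more than
    ``anomaly_k``·MAD — with an absolute floor so near-constant series are
    not over-flagged — or breaches the ratio gates ``high_ratio`` /
    ``low_ratio``. The gates tolerate the gradual RR drift of an
    incremental test while catching single missed or spurious beats.

    Returns a frame with columns ``gap_index`` (interval i spans peaks i,
    i+1), ``rr_ms``, ``local_median_ms`` and ``kind``
    ('missed' for long gaps, 'extra' for short ones).
    """
    t = np.asarray(peak_times_ms, dtype=float)
    empty = pd.DataFrame(columns=["gap_index", "rr_ms", "local_median_ms", "kind"])
    if t.size < 3:
        return empty
    rr = pd.Series(np.diff(t))
    med = rr.rolling(config.anomaly_window, center=True, min_periods=1).median()
    absdev = (rr - med).abs()
    mad = absdev.rolling(config.anomaly_window, center=True, min_periods=1).median()
    floor = np.maximum(config.anomaly_floor_frac * med, config.anomaly_floor_ms)
    dev_gate = np.maximum(config.anomaly_k * mad, floor)
    anomalous = (absdev > dev_gate) | (rr > config.high_ratio * med) | (rr < config.low_ratio * med)
    idx = np.nonzero(anomalous.to_numpy())[0]
    if idx.size == 0:
        return empty
    return pd.DataFrame(
        {
            "gap_index": idx,
            "rr_ms": rr.to_numpy()[idx],
            "local_median_ms": med.to_numpy()[idx],
            "kind": np.where(rr.to_numpy()[idx] > med.to_numpy()[idx], "missed", "extra"),
        }
    )


# ---------------------------------------------------------------------------
# local re-search
# ---------------------------------------------------------------------------


def local_repeak_search(
    record: ECGRecord,
    target_epoch_ms: float,
    halfwidth_ms: float,
    threshold_uv: float,
    config: DetectorConfig | None = None,
) -> tuple[int, float, float] | None:
    """Look for a beat near an expected time with a relaxed threshold.

    Scans ``±halfwidth_ms`` around the target on both branches, ranks local
    extrema by prominence, and accepts the most prominent one if its
    |voltage| exceeds ``repair_gate`` × the enclosing interval's detection
    threshold. Returns ``(sample_index, epoch_ms, voltage)`` or ``None``.
    """
    config = config or DetectorConfig()
    if not (record.start_epoch_ms <= target_epoch_ms < record.end_epoch_ms):
        return None
    i0 = record.index_at(target_epoch_ms - halfwidth_ms)
    i1 = record.index_at(target_epoch_ms + halfwidth_ms) + 1
    seg = record.samples[i0:i1]
    if seg.size < 3 or np.ptp(seg) == 0:
        return None
    gate = config.repair_gate * threshold_uv
    best: tuple[float, int, float] | None = None  # (prominence, local idx, voltage)
    for sign in (1.0, -1.0):
        x = sign * seg
        peaks, _ = find_peaks(x)
        if peaks.size == 0:
            continue
        prom = peak_prominences(x, peaks)[0]
        for p, pr in zip(peaks, prom):
            v = float(seg[p])
            if abs(v) < gate:
                continue
            cand = (float(pr), int(p), v)
            if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                best = cand
    if best is None:
        return None
    idx = i0 + best[1]
    return idx, float(record.sample_time_ms(idx)), best[2]


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def _run_branch_detection(
    record: ECGRecord,
    intervals: list[IntervalRange],
    quantiles: np.ndarray,
    config: DetectorConfig,
) -> tuple:
    """Dual-branch detection over all intervals.

    Each interval is padded on both sides so apices at interval edges are
    still local maxima; only candidates whose index falls in the interval's
    half-open core are kept. Returns merged ``(times, indices, voltages,
    branches)`` plus per-interval thresholds via the diagnostics the caller
    maintains.
    """
    pad = int(round(0.5 * record.fs))  # 0.5 s of context on each side
    all_rt, all_rv, all_ri = [], [], []
    all_st, all_sv, all_si = [], [], []
    thresholds = np.full(len(intervals), np.nan)
    for k, rng in enumerate(intervals):
        cfg_k = replace(config, threshold_quantile_start=float(quantiles[k]))
        lo = max(0, rng.start - pad)
        hi = min(record.n_samples, rng.stop + pad)
        window = record.samples[lo:hi]
        r_idx, r_v, r_thr = detect_in_interval(window, "R", cfg_k, rng.fs)
        s_idx, s_v, s_thr = detect_in_interval(window, "S", cfg_k, rng.fs)
        thresholds[k] = np.nanmax([r_thr, s_thr]) if not (np.isnan(r_thr) and np.isnan(s_thr)) else np.nan
        for idx, v, acc_t, acc_v, acc_i in (
            (r_idx, r_v, all_rt, all_rv, all_ri),
            (s_idx, s_v, all_st, all_sv, all_si),
        ):
            g = idx + lo
            core = (g >= rng.start) & (g < rng.stop)
            acc_i.extend(g[core].tolist())
            acc_t.extend(record.sample_time_ms(g[core]).tolist())
            acc_v.extend(np.asarray(v)[core].tolist())
    # de-duplicate candidates found in two padded windows
    def _dedup(times, volts, idxs):
        if not times:
            return np.zeros(0), np.zeros(0), np.zeros(0, dtype=int)
        arr = sorted(set(zip(idxs, times, volts)))
        i, t, v = zip(*[(a, b, c) for a, b, c in arr])
        return np.asarray(t), np.asarray(v), np.asarray(i, dtype=int)

    rt, rv, ri = _dedup(all_rt, all_rv, all_ri)
    st, sv, si = _dedup(all_st, all_sv, all_si)

    # merge branches on times, then recover indices from the time grid
    mt, mv, mb = merge_branches((rt, rv), (st, sv), config.refractory_ms)
    idx_map = {}
    for t, i in zip(rt, ri):
        idx_map[(round(t, 6), "R")] = i
    for t, i in zip(st, si):
        idx_map[(round(t, 6), "S")] = i
    mi = np.array([idx_map[(round(t, 6), b)] for t, b in zip(mt, mb)], dtype=int)
    return mt, mi, mv, mb, thresholds, int(rt.size), int(st.size)


def _interval_of(intervals: list[IntervalRange], sample_index: int) -> int:
    step = intervals[0].stop - intervals[0].start
    return min(int(sample_index // step), len(intervals) - 1)


def detect_r_peaks(
    record: ECGRecord, config: DetectorConfig | None = None
) -> tuple[PeakList, DetectionDiagnostics]:
    """Run the full detection pipeline on one record.

    Segment → dual-branch thresholded detection → merge → RR anomaly
    screening → local re-search/pruning, iterated (with per-interval
    threshold relaxation where anomalies cluster) until the beat list stops
    changing or ``max_iterations`` is reached.
    """
    config = config or DetectorConfig()
    diag = DetectionDiagnostics()
    if record.duration_s < 2.0:
        raise ValueError("record shorter than 2 s")
    if np.ptp(record.samples) == 0:
        diag.notes.append("record is flat throughout; nothing detectable")
        return (
            PeakList(np.zeros(0), np.zeros(0, dtype=int), np.zeros(0, dtype=object), record.source_label),
            diag,
        )

    intervals = segment_intervals(record, config.interval_s)
    quantiles = np.full(len(intervals), config.threshold_quantile_start)

    times, idxs, volts, branches, thresholds, n_r_cand, n_s_cand = _run_branch_detection(
        record, intervals, quantiles, config
    )
    diag.n_both = n_r_cand + n_s_cand - int(times.size)
    diag.n_r_only = int(np.sum(branches == "R"))
    diag.n_s_only = int(np.sum(branches == "S"))

    for iteration in range(1, config.max_iterations + 1):
        diag.iterations = iteration
        changed = False
        anomalies = flag_abnormal_rr(times, config)
        diag.anomalies_flagged += len(anomalies)
        iteration_repairs = 0

        # --- repair long gaps by local re-search -------------------------
        for _, row in anomalies[anomalies["kind"] == "missed"].iterrows():
            gi = int(row["gap_index"])
            t_lo, t_hi = times[gi], times[gi + 1]
            med = float(row["local_median_ms"])
            n_missing = max(1, int(round((t_hi - t_lo) / max(med, 1.0))) - 1)
            step = (t_hi - t_lo) / (n_missing + 1)
            for j in range(1, n_missing + 1):
                target = t_lo + j * step
                k = _interval_of(intervals, record.index_at(target))
                thr = thresholds[k]
                if np.isnan(thr):
                    thr = float(np.nanmedian(thresholds)) if np.any(~np.isnan(thresholds)) else 0.0
                found = local_repeak_search(
                    record, target, config.search_halfwidth_ms, thr, config
                )
                if found is None:
                    continue
                fi, ft, fv = found
                pos = np.searchsorted(times, ft)
                left_ok = pos == 0 or ft - times[pos - 1] >= config.refractory_ms
                right_ok = pos == times.size or times[pos] - ft >= config.refractory_ms
                if left_ok and right_ok:
                    times = np.insert(times, pos, ft)
                    idxs = np.insert(idxs, pos, fi)
                    volts = np.insert(volts, pos, fv)
                    branches = np.insert(branches, pos, "repaired")
                    diag.repairs_made += 1
                    iteration_repairs += 1
                    changed = True

        # --- extend beyond the first/last detection ----------------------
        # gap screening cannot see beats outside the detected range, so
        # probe one local-median RR beyond each end while beats keep
        # turning up
        while times.size >= 3:
            med_rr = float(np.median(np.diff(times[: min(12, times.size)])))
            target = times[0] - med_rr
            if target < record.start_epoch_ms:
                break
            k = _interval_of(intervals, record.index_at(target))
            thr = thresholds[k] if not np.isnan(thresholds[k]) else float(np.nanmedian(thresholds))
            found = local_repeak_search(record, target, config.search_halfwidth_ms, thr, config)
            if found is None or times[0] - found[1] < config.refractory_ms or found[1] >= times[0]:
                break
            times = np.insert(times, 0, found[1])
            idxs = np.insert(idxs, 0, found[0])
            volts = np.insert(volts, 0, found[2])
            branches = np.insert(branches, 0, "repaired")
            diag.repairs_made += 1
            iteration_repairs += 1
            changed = True
        while times.size >= 3:
            med_rr = float(np.median(np.diff(times[-min(12, times.size) :])))
            target = times[-1] + med_rr
            if target >= record.end_epoch_ms:
                break
            k = _interval_of(intervals, record.index_at(target))
            thr = thresholds[k] if not np.isnan(thresholds[k]) else float(np.nanmedian(thresholds))
            found = local_repeak_search(record, target, config.search_halfwidth_ms, thr, config)
            if found is None or found[1] - times[-1] < config.refractory_ms or found[1] <= times[-1]:
                break
            times = np.append(times, found[1])
            idxs = np.append(idxs, found[0])
            volts = np.append(volts, found[2])
            branches = np.append(branches, "repaired")
            diag.repairs_made += 1
            iteration_repairs += 1
            changed = True

        # --- prune spurious beats in short gaps --------------------------
        anomalies = flag_abnormal_rr(times, config)
        drop: set[int] = set()
        for _, row in anomalies[anomalies["kind"] == "extra"].iterrows():
            gi = int(row["gap_index"])
            # only ratio-gated short gaps justify removing a beat
            if row["rr_ms"] >= config.low_ratio * row["local_median_ms"]:
                continue
            a, b = gi, gi + 1
            if a in drop or b in drop:
                continue
            victim = a if abs(volts[a]) < abs(volts[b]) else b
            if branches[victim] == "repaired":
                victim = b if victim == a else a
            drop.add(victim)
        if drop:
            keep = np.setdiff1d(np.arange(times.size), np.array(sorted(drop)))
            times, idxs, volts, branches = times[keep], idxs[keep], volts[keep], branches[keep]
            diag.removals_made += len(drop)
            changed = True

        # --- relax thresholds where anomalies cluster --------------------
        redetect = np.zeros(len(intervals), dtype=bool)
        anomalies = flag_abnormal_rr(times, config)
        if len(anomalies) and times.size > 2:
            per_interval = np.zeros(len(intervals))
            counts = np.zeros(len(intervals))
            for gi in range(times.size - 1):
                counts[_interval_of(intervals, idxs[gi])] += 1
            for _, row in anomalies.iterrows():
                per_interval[_interval_of(intervals, idxs[int(row["gap_index"])])] += 1
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(counts > 0, per_interval / counts, 0.0)
            redetect = (frac > config.redetect_anomaly_frac) & (
                quantiles - config.redetect_quantile_step >= config.threshold_quantile_floor
            )
        if np.any(redetect):
            quantiles = np.where(redetect, quantiles - config.redetect_quantile_step, quantiles)
            times, idxs, volts, branches, thresholds, n_r_cand, n_s_cand = _run_branch_detection(
                record, intervals, quantiles, config
            )
            changed = True

        diag.last_iteration_repairs = iteration_repairs
        if not changed:
            break

    diag.interval_thresholds = thresholds.tolist()
    peaks = PeakList(
        peak_epoch_ms=times,
        sample_index=idxs,
        branch=branches,
        source_label=record.source_label,
    )
    return peaks, diag
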