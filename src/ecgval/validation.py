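"""Beat-level and RR′-level device-validation statistics.

Device beats are matched one-to-one to criterion beats within a time
window (default 100 ms, chosen against the ~200 ms QRS refractory period
so a device beat can only ever claim one true beat). Matched/unmatched
counts give sensitivity, precision and — with sample-level true negatives
at the criterion sampling rate — specificity, accuracy and a detection
error rate. Agreement of the RR′ intervals themselves is quantified by
Bland–Altman statistics, Pearson correlation of instantaneous heart rate,
and ICC(3,1) (two-way mixed, single measure, consistency) for per-subject
average heart rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MatchResult",
    "ConfusionSummary",
    "AgreementReport",
    "match_peaks",
    "confusion_summary",
    "sensitivity",
    "precision",
    "specificity",
    "accuracy",
    "detection_error_rate",
    "paired_rr_differences",
    "bland_altman",
    "instantaneous_hr",
    "icc3_single",
    "rr_sd",
    "percent_of_mean",
    "stratified_report",
    "STRATUM_COLUMNS",
]

DEFAULT_MATCH_THRESHOLD_MS = 100.0


def _times_of(obj) -> np.ndarray:
    if hasattr(obj, "peak_epoch_ms"):
        return np.asarray(obj.peak_epoch_ms, dtype=float)
    return np.asarray(obj, dtype=float)


@dataclass
class MatchResult:
    """One-to-one correspondence between criterion and device beats."""

    tp: int
    fn: int
    fp: int
    pairs: np.ndarray  # shape (tp, 2): criterion time, device time
    pair_indices: np.ndarray  # shape (tp, 2): criterion idx, device idx
    unmatched_criterion: np.ndarray
    unmatched_device: np.ndarray
    threshold_ms: float

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=float).reshape(-1, 2)
        self.pair_indices = np.asarray(self.pair_indices, dtype=int).reshape(-1, 2)
        if self.pairs.size and self.tp != self.pairs.shape[0]:
            raise ValueError("tp must equal the number of matched pairs")
        if self.pairs.size and np.any(np.abs(self.pairs[:, 1] - self.pairs[:, 0]) > self.threshold_ms):
            raise ValueError("matched pair exceeds the threshold window")

    @property
    def n_criterion(self) -> int:
        return self.tp + self.fn

    @property
    def n_device(self) -> int:
        return self.tp + self.fp

    @classmethod
    def from_counts(
        cls, tp: int, fn: int, fp: int, threshold_ms: float = DEFAULT_MATCH_THRESHOLD_MS
    ) -> "MatchResult":
        """Counts-only result (e.g. from a published table) without pair lists."""
        return cls(
            tp=tp,
            fn=fn,
            fp=fp,
            pairs=np.zeros((0, 2)),
            pair_indices=np.zeros((0, 2), dtype=int),
            unmatched_criterion=np.zeros(0),
            unmatched_device=np.zeros(0),
            threshold_ms=threshold_ms,
        )


@dataclass
class ConfusionSummary:
    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: float
    precision: float
    specificity: float
    accuracy: float
    der: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class AgreementReport:
    mean_diff_ms: float
    sd_diff_ms: float
    loa_low_ms: float
    loa_high_ms: float
    pearson_r: float = math.nan
    icc3: float = math.nan
    n_pairs: int = 0
    percent_of_mean: float = math.nan


# ---------------------------------------------------------------------------
# beat matching
# ---------------------------------------------------------------------------


def match_peaks(
    criterion,
    device,
    threshold_ms: float = DEFAULT_MATCH_THRESHOLD_MS,
) -> MatchResult:
    """Greedy one-to-one nearest-neighbour beat matching.

    Criterion beats are visited in time order; each claims the closest
    unconsumed device beat within ``threshold_ms`` (inclusive; ties go to
    the earlier device beat). Leftover criterion beats are false negatives,
    leftover device beats false positives. With both streams respecting the
    refractory period and a window of half that period, the pairing is
    essentially unique, so the greedy result coincides with the optimal
    assignment.
    """
    c = _times_of(criterion)
    d = _times_of(device)
    used = np.zeros(d.size, dtype=bool)
    pairs, pair_idx = [], []
    for i, t in enumerate(c):
        lo = np.searchsorted(d, t - threshold_ms, side="left")
        hi = np.searchsorted(d, t + threshold_ms, side="right")
        best_j, best_dist = -1, np.inf
        for j in range(lo, hi):
            if used[j]:
                continue
            dist = abs(d[j] - t)
            if dist < best_dist:
                best_j, best_dist = j, dist
        if best_j >= 0:
            used[best_j] = True
            pairs.append((t, d[best_j]))
            pair_idx.append((i, best_j))
    tp = len(pairs)
    matched_c = {i for i, _ in pair_idx}
    return MatchResult(
        tp=tp,
        fn=int(c.size - tp),
        fp=int(d.size - tp),
        pairs=np.asarray(pairs, dtype=float).reshape(-1, 2),
        pair_indices=np.asarray(pair_idx, dtype=int).reshape(-1, 2),
        unmatched_criterion=np.asarray([t for i, t in enumerate(c) if i not in matched_c]),
        unmatched_device=d[~used],
        threshold_ms=threshold_ms,
    )


# ---------------------------------------------------------------------------
# confusion-derived rates (all returned as percentages)
# ---------------------------------------------------------------------------


def sensitivity(tp: int, fn: int) -> float:
    """TP / (TP + FN) · 100; NaN when there are no positives."""
    return math.nan if tp + fn == 0 else 100.0 * tp / (tp + fn)


def precision(tp: int, fp: int) -> float:
    """TP / (TP + FP) · 100; NaN when nothing was detected."""
    return math.nan if tp + fp == 0 else 100.0 * tp / (tp + fp)


def specificity(tn: int, fp: int) -> float:
    return math.nan if tn + fp == 0 else 100.0 * tn / (tn + fp)


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    total = tp + tn + fp + fn
    return math.nan if total == 0 else 100.0 * (tp + tn) / total


def detection_error_rate(tp: int, tn: int, fp: int, fn: int) -> float:
    """(FP + FN) / (TP + TN + FP + FN) · 100."""
    total = tp + tn + fp + fn
    return math.nan if total == 0 else 100.0 * (fp + fn) / total


def confusion_summary(match: MatchResult, total_samples: int) -> ConfusionSummary:
    """All five rates, with sample-level TN = samples − TP − FN − FP.

    Event detection on a continuous signal has no natural negative class;
    counting every criterion-rate sample not involved in a beat decision as
    a true negative makes specificity/accuracy computable.
    """
    if total_samples < match.tp + match.fn + match.fp:
        raise ValueError("total_samples smaller than the classified events")
    tn = int(total_samples - match.tp - match.fn - match.fp)
    return ConfusionSummary(
        tp=match.tp,
        fn=match.fn,
        fp=match.fp,
        tn=tn,
        sensitivity=sensitivity(match.tp, match.fn),
        precision=precision(match.tp, match.fp),
        specificity=specificity(tn, match.fp),
        accuracy=accuracy(match.tp, tn, match.fp, match.fn),
        der=detection_error_rate(match.tp, tn, match.fp, match.fn),
    )


# ---------------------------------------------------------------------------
# RR′ agreement
# ---------------------------------------------------------------------------


def paired_rr_differences(match: MatchResult) -> pd.DataFrame:
    """Per-pair RR′ differences (device − criterion) for Bland–Altman.

    An RR′ pair exists only where two *consecutive* criterion beats are
    both matched; intervals spanning a missed beat are excluded rather than
    compared against a summed device interval. Returns columns
    ``mean_rr_ms`` (two-device mean) and ``diff_ms``.
    """
    if match.tp < 2:
        return pd.DataFrame(columns=["mean_rr_ms", "diff_ms"])
    ci = match.pair_indices[:, 0]
    ct = match.pairs[:, 0]
    dt = match.pairs[:, 1]
    consecutive = np.diff(ci) == 1
    rr_c = np.diff(ct)[consecutive]
    rr_d = np.diff(dt)[consecutive]
    return pd.DataFrame({"mean_rr_ms": (rr_c + rr_d) / 2.0, "diff_ms": rr_d - rr_c})


def bland_altman(diffs: Sequence[float]) -> AgreementReport:
    """Mean difference, sample SD (n−1) and ±1.96·SD limits of agreement."""
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two differences")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementReport(
        mean_diff_ms=mean,
        sd_diff_ms=sd,
        loa_low_ms=mean - 1.96 * sd,
        loa_high_ms=mean + 1.96 * sd,
        n_pairs=int(d.size),
    )


def instantaneous_hr(rr_ms):
    """60000 / RR′ (bpm)."""
    rr = np.asarray(rr_ms, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("RR intervals must be positive")
    out = 60000.0 / rr
    return float(out) if np.isscalar(rr_ms) else out


def icc3_single(ratings: np.ndarray) -> float:
    """ICC(3,1): two-way mixed, single measure, consistency.

    ``ratings`` is an n_subjects × k matrix with no missing cells
    (k = 2 raters here: device and criterion). Computed from the two-way
    ANOVA mean squares as (MS_rows − MS_error) / (MS_rows + (k−1)·MS_error).
    The consistency form ignores a fixed offset between raters. NaN when
    between-subject variance is zero (undefined reliability).
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise ValueError("need an n>=3 by k>=2 ratings matrix")
    if np.any(~np.isfinite(m)):
        raise ValueError("ratings must not contain missing cells")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_total = float(((m - grand) ** 2).sum())
    ss_rows = float(k * ((row_means - grand) ** 2).sum())
    ss_cols = float(n * ((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err
    if ms_rows <= 0 or denom == 0:
        return math.nan
    return (ms_rows - ms_err) / denom


def rr_sd(rr_ms: Sequence[float]) -> float:
    """Sample standard deviation (n−1) of an RR′ series — SDNN."""
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < 2:
        raise ValueError("need at least two intervals")
    return float(np.std(rr, ddof=1))


def percent_of_mean(mean_diff: float, reference_mean: float) -> float:
    """Mean difference as a percentage of the reference mean."""
    if reference_mean == 0:
        raise ValueError("reference mean is zero")
    return 100.0 * mean_diff / reference_mean


# ---------------------------------------------------------------------------
# stratified tables
# ---------------------------------------------------------------------------

STRATUM_COLUMNS = ["activity", "exercise", "participants", "tp", "fn", "sensitivity", "fp", "precision"]


def stratified_report(rows: pd.DataFrame | Sequence[dict]) -> pd.DataFrame:
    """Per-stratum and pooled sensitivity/precision table.

    ``rows`` carries one entry per (activity, exercise) stratum with raw
    ``tp``, ``fn``, ``fp`` counts (and optionally ``participants``). The
    pooled row sums counts first and then computes rates — never a mean of
    rates — which is how an overall figure must be derived from a
    per-stratum table. Strata with no beats are dropped.
    """
    df = pd.DataFrame(rows).copy()
    for col in ("tp", "fn", "fp"):
        if col not in df.columns:
            raise ValueError(f"missing count column {col!r}")
    if "participants" not in df.columns:
        df["participants"] = np.nan
    empty = (df["tp"] + df["fn"] + df["fp"]) == 0
    if empty.any():
        df = df[~empty]
    df["sensitivity"] = [sensitivity(tp, fn) for tp, fn in zip(df["tp"], df["fn"])]
    df["precision"] = [precision(tp, fp) for tp, fp in zip(df["tp"], df["fp"])]
    pooled = {
        "activity": "Overall",
        "exercise": "All",
        "participants": df["participants"].sum(min_count=1),
        "tp": int(df["tp"].sum()),
        "fn": int(df["fn"].sum()),
        "fp": int(df["fp"].sum()),
    }
    pooled["sensitivity"] = sensitivity(pooled["tp"], pooled["fn"])
    pooled["precision"] = precision(pooled["tp"], pooled["fp"])
    out = pd.concat([df, pd.DataFrame([pooled])], ignore_index=True)
    cols = [c for c in STRATUM_COLUMNS if c in out.columns]
    return out[cols + [c for c in out.columns if c not in cols]]
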