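"""Multi-stream alignment on a common Unix-epoch timeline.

Global start timestamps put every stream on the same epoch, but
independent device clocks typically disagree by up to a few seconds. The
residual offset is recovered from the beat pattern itself: both RR′
sequences are resampled as tachograms (RR value held between beats on a
fixed grid), and the offset that maximizes their normalized
cross-correlation over the overlap is taken, with parabolic sub-step
interpolation. Correlating tachograms rather than index-paired RR values
makes the estimate robust to missed beats, which would de-phase any
index-wise comparison.

A single constant offset per stream is estimated; clock drift over a
recording is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RRSeries, StreamBundle

__all__ = ["AlignmentResult", "coarse_align", "refine_by_rr_correlation", "apply_alignment"]


@dataclass
class AlignmentResult:
    """Offset (ms) to add to device time to land on criterion time."""

    offset_ms: float
    score: float
    search_ms: float
    step_ms: float
    verified: bool

    def __post_init__(self) -> None:
        if np.isfinite(self.score) and not (-1.0 - 1e-9 <= self.score <= 1.0 + 1e-9):
            raise ValueError("correlation score outside [-1, 1]")


def coarse_align(a: RRSeries, b: RRSeries) -> float:
    """Residual start-time discrepancy between two epoch-stamped series.

    Both series already share the Unix epoch, so the baseline offset is
    zero; the returned value ``a_start − b_start`` bounds the refinement
    search. Raises when the spans do not overlap at all.
    """
    if a.n_beats == 0 or b.n_beats == 0:
        raise ValueError("empty RR series")
    a0, a1 = a.beat_epoch_ms[0], a.beat_epoch_ms[-1]
    b0, b1 = b.beat_epoch_ms[0], b.beat_epoch_ms[-1]
    if a1 < b0 or b1 < a0:
        raise ValueError("no overlap between stream spans")
    return float(a0 - b0)


def _tachogram_at(series: RRSeries, grid_ms: np.ndarray) -> np.ndarray:
    """RR value of the interval containing each grid time (step-hold)."""
    idx = np.searchsorted(series.beat_epoch_ms, grid_ms, side="left")
    idx = np.clip(idx, 0, series.rr_ms.size - 1)
    return series.rr_ms[idx]


def refine_by_rr_correlation(
    reference: RRSeries,
    device: RRSeries,
    search_ms: float = 30_000.0,
    step_ms: float = 50.0,
    grid_ms: float = 250.0,
    center_ms: float = 0.0,
    min_score: float = 0.5,
    min_overlap_beats: int = 30,
) -> AlignmentResult:
    """Recover the device clock offset from tachogram cross-correlation.

    Scans offsets ``center_ms ± search_ms`` on a ``step_ms`` grid; at each
    candidate the device tachogram is sampled on the reference grid over
    the mutual overlap and Pearson-correlated with the reference tachogram.
    The best offset is refined by fitting a parabola through the
    correlation at the optimum and its two neighbours. A peak correlation
    below ``min_score`` (or a degenerate, constant tachogram) leaves the
    result unverified.
    """
    if reference.n_beats < min_overlap_beats or device.n_beats < min_overlap_beats:
        raise ValueError(f"need at least {min_overlap_beats} beats per stream")
    offsets = center_ms + np.arange(-search_ms, search_ms + step_ms / 2, step_ms)
    ref_t0, ref_t1 = reference.beat_epoch_ms[0], reference.beat_epoch_ms[-1]
    grid = np.arange(ref_t0, ref_t1, grid_ms)
    ref_tach_full = _tachogram_at(reference, grid)

    scores = np.full(offsets.size, -np.inf)
    for i, delta in enumerate(offsets):
        d0 = device.beat_epoch_ms[0] + delta
        d1 = device.beat_epoch_ms[-1] + delta
        mask = (grid >= max(ref_t0, d0)) & (grid <= min(ref_t1, d1))
        if mask.sum() < max(8, min_overlap_beats // 2):
            continue
        ref_vals = ref_tach_full[mask]
        dev_vals = _tachogram_at(device.shifted(delta), grid[mask])
        if np.ptp(ref_vals) == 0 or np.ptp(dev_vals) == 0:
            continue
        scores[i] = float(np.corrcoef(ref_vals, dev_vals)[0, 1])

    if not np.any(np.isfinite(scores)):
        return AlignmentResult(0.0, float("nan"), search_ms, step_ms, verified=False)
    best = int(np.argmax(scores))
    offset = float(offsets[best])
    score = float(scores[best])

    # parabolic sub-step interpolation of the optimum (skipped when the
    # peak is already exact; vertex clamped to half a step)
    if (
        score < 1.0 - 1e-9
        and 0 < best < offsets.size - 1
        and np.isfinite(scores[best - 1])
        and np.isfinite(scores[best + 1])
    ):
        y0, y1, y2 = scores[best - 1], scores[best], scores[best + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            shift = 0.5 * step_ms * (y0 - y2) / denom
            offset += float(np.clip(shift, -step_ms / 2, step_ms / 2))

    verified = np.isfinite(score) and score >= min_score
    return AlignmentResult(
        offset_ms=offset,
        score=min(max(score, -1.0), 1.0),
        search_ms=search_ms,
        step_ms=step_ms,
        verified=verified,
    )


def apply_alignment(
    bundle: StreamBundle,
    device_ecg_result: AlignmentResult | None = None,
    device_rr_result: AlignmentResult | None = None,
    override: bool = False,
) -> StreamBundle:
    """Shift device streams onto the criterion timeline.

    Only event/sample times move; RR′ values are untouched. Unverified
    alignments are refused unless ``override`` is set.
    """
    for res in (device_ecg_result, device_rr_result):
        if res is not None and not res.verified and not override:
            raise ValueError("refusing to apply an unverified alignment (pass override=True)")
    device_ecg = bundle.device_ecg
    if device_ecg is not None and device_ecg_result is not None:
        device_ecg = device_ecg.shifted(device_ecg_result.offset_ms)
    device_rr = bundle.device_rr
    if device_rr is not None and device_rr_result is not None:
        device_rr = device_rr.shifted(device_rr_result.offset_ms)
    return StreamBundle(
        criterion=bundle.criterion,
        device_ecg=device_ecg,
        device_rr=device_rr,
        activity_label=bundle.activity_label,
        subject=bundle.subject,
        mode=bundle.mode,
    )
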