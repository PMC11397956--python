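"""Ground-truthed synthetic data emulating an exercise validation study.

The generator emulates the three stream types a chest-strap validation
session produces — a 1000 Hz laboratory criterion ECG, a 500 Hz packetized
chest-sensor ECG, and an RR-interval export from a sports watch — all
derived from one known beat-time sequence, so every downstream statistic
can be checked against exact ground truth.

The default protocol profile follows the study shape: 5 min seated rest,
6 min warm-up, a ramp to exhaustion, 6 min cool-down, and 5 min final
rest, with heart rate spanning roughly 65–200 bpm and short-term RR
variability (SDNN) of ~95 ms at initial rest, lower during exercise and
early recovery. Beats are drawn by an integrate-and-fire walk along the
instantaneous heart-rate trajectory with white Gaussian RR jitter; QRS
complexes are rendered as analytic two-lobe templates (controllable apex
time, width and R:S dominance) rather than by a full dynamical ECG model,
because detector testing needs exact fiducial control, not PQRST realism.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import (
    ECGRecord,
    RRSeries,
    StreamBundle,
    write_criterion_ecg,
    write_packet_ecg,
    write_rr_stream,
)

__all__ = [
    "Segment",
    "ProtocolProfile",
    "MorphologyConfig",
    "DegradationConfig",
    "generate_beat_times",
    "synthesize_ecg",
    "simulate_packet_stream",
    "simulate_rr_device",
    "make_study_fixture",
    "write_study_fixture",
]

#: Activity labels used throughout; warm-up, ramp and cool-down all belong
#: to the incremental-test activity.
REST_PRE, INCREMENTAL, REST_POST = "rest_pre", "incremental", "rest_post"


@dataclass(frozen=True)
class Segment:
    duration_s: float
    hr_start_bpm: float
    hr_end_bpm: float
    activity: str
    sdnn_ms: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("segment duration must be positive")
        for hr in (self.hr_start_bpm, self.hr_end_bpm):
            if not 30.0 <= hr <= 240.0:
                raise ValueError("heart rate outside the physiological 30-240 bpm band")


@dataclass(frozen=True)
class ProtocolProfile:
    segments: tuple[Segment, ...]
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0, scale: float = 1.0, hr_max: float = 200.0) -> "ProtocolProfile":
        """Study-shaped protocol; ``scale`` shrinks durations uniformly."""
        return cls(
            segments=(
                Segment(300 * scale, 65, 65, REST_PRE, 95.0),
                Segment(360 * scale, 100, 120, INCREMENTAL, 55.0),
                Segment(600 * scale, 120, hr_max, INCREMENTAL, 40.0),
                Segment(360 * scale, hr_max, 120, INCREMENTAL, 40.0),
                Segment(300 * scale, 108, 100, REST_POST, 25.0),
            ),
            seed=seed,
        )

    @property
    def total_s(self) -> float:
        return sum(s.duration_s for s in self.segments)

    def _locate(self, t_s: float) -> tuple[Segment, float]:
        acc = 0.0
        for seg in self.segments:
            if t_s < acc + seg.duration_s or seg is self.segments[-1]:
                return seg, (t_s - acc) / seg.duration_s
            acc += seg.duration_s
        raise AssertionError("unreachable")

    def hr_at(self, t_s: float) -> float:
        seg, frac = self._locate(t_s)
        frac = min(max(frac, 0.0), 1.0)
        return seg.hr_start_bpm + frac * (seg.hr_end_bpm - seg.hr_start_bpm)

    def sdnn_at(self, t_s: float) -> float:
        return self._locate(t_s)[0].sdnn_ms

    def activity_at(self, t_s: float) -> str:
        return self._locate(t_s)[0].activity


@dataclass(frozen=True)
class MorphologyConfig:
    """Analytic QRS template parameters.

    ``rs_ratio`` is the main:secondary lobe amplitude ratio; its sign
    selects the dominant deflection (positive → upright R dominant,
    negative → inverted, S dominant). The ground-truth beat time always
    coincides with the dominant apex.
    """

    qrs_amplitude_uv: float = 1000.0
    qrs_width_ms: float = 80.0
    rs_ratio: float = 3.0
    t_amplitude_uv: float = 150.0
    wander_amplitude_uv: float = 80.0
    wander_freq_hz: float = 0.3
    noise_sd_uv: float = 0.0

    def __post_init__(self) -> None:
        if self.qrs_width_ms <= 0 or self.rs_ratio == 0:
            raise ValueError("invalid morphology")


@dataclass(frozen=True)
class DegradationConfig:
    """Failure modes of a consumer RR-interval device.

    ``periodic_miss_k`` drops every k-th beat (halving apparent heart rate
    at k = 2, the characteristic diagonal a watch shows when it only keeps
    up with alternate beats at high intensity); ``miss_above_bpm`` /
    ``miss_prob_high`` add extra misses only when instantaneous HR exceeds
    a threshold. After a detection gap of at least ``sentinel_after_gap_s``
    the device emits 5000 ms sentinel codes.
    """

    miss_prob: float = 0.0
    periodic_miss_k: int | None = None
    extra_prob: float = 0.0
    jitter_sd_ms: float = 0.0
    sentinel_after_gap_s: float = 5.0
    miss_above_bpm: float | None = None
    miss_prob_high: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.miss_prob, self.extra_prob, self.miss_prob_high):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.periodic_miss_k is not None and self.periodic_miss_k < 2:
            raise ValueError("periodic_miss_k must be >= 2")


# ---------------------------------------------------------------------------
# beat times
# ---------------------------------------------------------------------------


def generate_beat_times(profile: ProtocolProfile) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth beat times (ms from protocol start) and activity labels.

    Integrate-and-fire on the profile's instantaneous heart rate: each RR
    is the current 60000/HR plus zero-mean Gaussian jitter targeting the
    segment's SDNN, floored at 280 ms so no nonphysiological interval can
    be generated. Reproducible under the profile seed.
    """
    rng = np.random.default_rng(profile.seed)
    total_ms = profile.total_s * 1000.0
    times = [0.0]
    labels = [profile.activity_at(0.0)]
    t = 0.0
    while True:
        hr = profile.hr_at(t / 1000.0)
        sdnn = profile.sdnn_at(t / 1000.0)
        rr = 60000.0 / hr
        if sdnn > 0:
            rr += rng.normal(0.0, sdnn)
        rr = max(rr, 280.0)
        if t + rr > total_ms:
            break
        t += rr
        times.append(t)
        labels.append(profile.activity_at(t / 1000.0))
    return np.asarray(times), np.asarray(labels, dtype=object)


# ---------------------------------------------------------------------------
# waveform rendering
# ---------------------------------------------------------------------------


def synthesize_ecg(
    beat_times_ms: np.ndarray,
    fs: float,
    morphology: MorphologyConfig | None = None,
    start_epoch_ms: float | None = None,
    pad_ms: float = 500.0,
    seed: int = 0,
    source_label: str = "synthetic",
) -> ECGRecord:
    """Render beats as a sampled voltage trace.

    Each beat contributes a dominant Gaussian lobe centred exactly on its
    ground-truth time, an opposite-sign secondary lobe offset by ~60% of
    the QRS width, and a broad T wave placed adaptively at 35% of the next
    RR (so repolarisation never collides with the next QRS at high heart
    rate). Baseline wander and white Gaussian noise are added per the
    morphology. The record spans the beats plus ``pad_ms`` on both sides.
    """
    morphology = morphology or MorphologyConfig()
    beats = np.asarray(beat_times_ms, dtype=float)
    if beats.size == 0:
        raise ValueError("no beats to render")
    if beats.size > 1 and np.min(np.diff(beats)) < morphology.qrs_width_ms:
        raise ValueError("beats closer than the QRS width are nonphysiological")
    rng = np.random.default_rng(seed)
    period = 1000.0 / fs
    t0 = beats[0] - pad_ms if start_epoch_ms is None else start_epoch_ms
    n = int(round((beats[-1] + pad_ms - t0) / period)) + 1
    grid = t0 + np.arange(n) * period
    x = np.zeros(n)

    main_amp = morphology.qrs_amplitude_uv * np.sign(morphology.rs_ratio)
    sec_amp = -main_amp / abs(morphology.rs_ratio)
    sigma = morphology.qrs_width_ms / 6.0
    sec_offset = 0.6 * morphology.qrs_width_ms
    rr_next = np.diff(beats, append=beats[-1] + (np.median(np.diff(beats)) if beats.size > 1 else 800.0))

    half_support = 4 * sigma + sec_offset
    for tb, rrn in zip(beats, rr_next):
        t_off = 0.35 * rrn
        t_sigma = 0.08 * rrn
        lo = np.searchsorted(grid, tb - half_support)
        hi = np.searchsorted(grid, tb + t_off + 4 * t_sigma)
        g = grid[lo:hi]
        x[lo:hi] += main_amp * np.exp(-0.5 * ((g - tb) / sigma) ** 2)
        x[lo:hi] += sec_amp * np.exp(-0.5 * ((g - tb - sec_offset) / sigma) ** 2)
        x[lo:hi] += morphology.t_amplitude_uv * np.exp(-0.5 * ((g - tb - t_off) / t_sigma) ** 2)

    if morphology.wander_amplitude_uv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += morphology.wander_amplitude_uv * np.sin(
            2 * np.pi * morphology.wander_freq_hz * (grid - grid[0]) / 1000.0 + phase
        )
    if morphology.noise_sd_uv > 0:
        x += rng.normal(0.0, morphology.noise_sd_uv, size=n)

    return ECGRecord(samples=x, fs=fs, start_epoch_ms=float(t0), source_label=source_label)


# ---------------------------------------------------------------------------
# device-stream simulation
# ---------------------------------------------------------------------------


def simulate_packet_stream(
    record: ECGRecord,
    path: str | Path,
    drop_packet_prob: float = 0.0,
    seed: int = 0,
) -> dict:
    """Write a record as a chest-sensor packet CSV with random packet loss."""
    if not np.isclose(record.fs, 500.0):
        raise ValueError("chest-sensor streams are 500 Hz")
    rng = np.random.default_rng(seed)
    n_packets = record.n_samples // 16
    keep = rng.random(n_packets) >= drop_packet_prob
    if not keep.any():
        raise ValueError("all packets dropped; nothing to write")
    write_packet_ecg(record, path, keep_packet=keep)
    return {"n_packets": int(n_packets), "n_dropped": int((~keep).sum())}


def simulate_rr_device(
    beat_times_ms: np.ndarray,
    degradation: DegradationConfig | None = None,
    clock_offset_ms: float = 0.0,
    seed: int = 0,
) -> tuple[RRSeries, dict]:
    """Degrade a ground-truth beat sequence into an RR-device stream.

    Misses (random, periodic, and HR-gated), spurious beats and Gaussian
    timing jitter are applied to the event times; RR′ is recomputed from
    the surviving events, so a missed beat doubles the local interval
    exactly as a real device export shows it. Sentinel bookkeeping marks
    detection gaps of at least ``sentinel_after_gap_s``.

    Returns the series plus a truth dict with the full device beat-time
    array (including the first beat, which carries no RR′ row) and miss /
    extra bookkeeping.
    """
    degradation = degradation or DegradationConfig()
    rng = np.random.default_rng(seed)
    t = np.asarray(beat_times_ms, dtype=float)
    n = t.size
    keep = np.ones(n, dtype=bool)
    # the HR gate scopes both the periodic and the extra random misses
    gated = np.ones(n, dtype=bool)
    if degradation.miss_above_bpm is not None and n > 1:
        rr_local = np.diff(t, prepend=t[0] - (t[1] - t[0]))
        hr_local = 60000.0 / np.maximum(rr_local, 1.0)
        gated = hr_local >= degradation.miss_above_bpm
    if degradation.periodic_miss_k:
        periodic = np.zeros(n, dtype=bool)
        periodic[1 :: degradation.periodic_miss_k] = True
        keep &= ~(periodic & gated)
    if degradation.miss_prob > 0:
        keep &= rng.random(n) >= degradation.miss_prob
    if degradation.miss_prob_high > 0:
        keep &= ~(gated & (rng.random(n) < degradation.miss_prob_high))
    keep[0] = True  # a stream always opens with a first detection
    survivors = t[keep]
    if degradation.jitter_sd_ms > 0:
        survivors = survivors + rng.normal(0.0, degradation.jitter_sd_ms, survivors.size)
    extras = np.zeros(0)
    if degradation.extra_prob > 0 and survivors.size > 1:
        gaps = np.diff(survivors)
        spur = rng.random(gaps.size) < degradation.extra_prob
        extras = survivors[:-1][spur] + gaps[spur] * rng.uniform(0.3, 0.7, int(spur.sum()))
    events = np.sort(np.concatenate([survivors, extras]))
    events = events[np.concatenate([[True], np.diff(events) > 1.0])]
    events = events + clock_offset_ms

    rr = np.diff(events)
    gap_ms = degradation.sentinel_after_gap_s * 1000.0
    sentinel_epochs = []
    for i, g in enumerate(rr):
        n_sent = int(g // gap_ms)
        for j in range(1, n_sent + 1):
            sentinel_epochs.append(events[i] + j * gap_ms)
    flags = np.zeros(rr.size + len(sentinel_epochs), dtype=bool)
    flags[: len(sentinel_epochs)] = True  # count only; row order is the writer's concern
    series = RRSeries(
        beat_epoch_ms=events[1:],
        rr_ms=rr,
        sentinel_flags=flags,
        source_label="rr_device_synthetic",
    )
    truth = {
        "beat_times_ms": events,
        "n_input_beats": int(n),
        "n_missed": int(n - keep.sum()),
        "n_extras": int(extras.size),
        "clock_offset_ms": float(clock_offset_ms),
        "sentinel_epochs_ms": np.asarray(sentinel_epochs),
    }
    return series, truth


# ---------------------------------------------------------------------------
# full study fixture
# ---------------------------------------------------------------------------


def make_study_fixture(
    n_subjects: int = 5,
    modes: tuple[str, ...] = ("running", "cycling"),
    seed: int = 0,
    scale: float = 1.0,
    degradation: DegradationConfig | None = None,
    device_ecg_offset_ms: float = 1500.0,
    device_rr_offset_ms: float = -2300.0,
    chest_morphology: MorphologyConfig | None = None,
    criterion_morphology: MorphologyConfig | None = None,
) -> dict:
    """Per-subject criterion + chest-sensor + RR-device streams with truth.

    Each subject gets one protocol-shaped beat sequence; the criterion
    record (1000 Hz), the chest record (500 Hz, shifted by a device clock
    offset), and the RR-device stream (degraded per ``degradation``,
    shifted by its own offset) all derive from it. Streams are sliced into
    the three activities at inter-beat midpoints so no QRS straddles a
    slice edge. Returns ``{"bundles": [...], "truth": {...}}`` where truth
    maps (subject, activity) to ground-truth beat times and records the
    injected offsets.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    criterion_morphology = criterion_morphology or MorphologyConfig(noise_sd_uv=5.0)
    chest_morphology = chest_morphology or MorphologyConfig(
        qrs_amplitude_uv=800.0, noise_sd_uv=5.0
    )
    bundles: list[StreamBundle] = []
    truth: dict = {
        "device_ecg_offset_ms": device_ecg_offset_ms,
        "device_rr_offset_ms": device_rr_offset_ms,
        "beats": {},
        "rr_device": {},
    }
    base_epoch = 1_700_000_000_000.0
    for s in range(n_subjects):
        mode = modes[s % len(modes)]
        hr_max = 200.0 if mode == "running" else 192.0
        profile = ProtocolProfile.default(seed=seed * 1000 + s, scale=scale, hr_max=hr_max)
        rel_beats, labels = generate_beat_times(profile)
        t0 = base_epoch + s * 36_000_000.0
        beats = rel_beats + t0

        criterion = synthesize_ecg(
            beats, fs=1000.0, morphology=criterion_morphology, seed=seed * 1000 + s,
            source_label="criterion",
        )
        chest_true = synthesize_ecg(
            beats, fs=500.0, morphology=chest_morphology, seed=seed * 1000 + s + 500,
            source_label="chest_sensor",
        )
        chest = chest_true.shifted(device_ecg_offset_ms)
        rr_series, rr_truth = simulate_rr_device(
            beats,
            degradation=degradation,
            clock_offset_ms=device_rr_offset_ms,
            seed=seed * 1000 + s + 900,
        )

        subject = f"S{s:02d}"
        for activity in (REST_PRE, INCREMENTAL, REST_POST):
            in_act = labels == activity
            act_beats = beats[in_act]
            if act_beats.size < 3:
                continue
            first, last = np.nonzero(in_act)[0][[0, -1]]
            lo = beats[first] - 400.0 if first == 0 else (beats[first - 1] + beats[first]) / 2.0
            hi = beats[last] + 400.0 if last == beats.size - 1 else (beats[last] + beats[last + 1]) / 2.0
            rr_mask = (rr_series.beat_epoch_ms >= lo + device_rr_offset_ms) & (
                rr_series.beat_epoch_ms < hi + device_rr_offset_ms
            )
            device_rr = (
                RRSeries(
                    beat_epoch_ms=rr_series.beat_epoch_ms[rr_mask],
                    rr_ms=rr_series.rr_ms[rr_mask],
                    source_label=rr_series.source_label,
                )
                if rr_mask.sum() >= 2
                else None
            )
            bundles.append(
                StreamBundle(
                    criterion=criterion.slice_time(lo, hi),
                    device_ecg=chest.slice_time(lo + device_ecg_offset_ms, hi + device_ecg_offset_ms),
                    device_rr=device_rr,
                    activity_label=activity,
                    subject=subject,
                    mode=mode,
                )
            )
            truth["beats"][(subject, activity)] = act_beats
        truth["rr_device"][subject] = rr_truth
    return {"bundles": bundles, "truth": truth}


def write_study_fixture(fixture: dict, outdir: str | Path) -> list[Path]:
    """Write every bundle in the three stream dialects plus a truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    truth_rows = []
    for bundle in fixture["bundles"]:
        stem = f"{bundle.subject}_{bundle.activity_label}"
        written.append(write_criterion_ecg(bundle.criterion, outdir / f"{stem}_criterion.txt"))
        if bundle.device_ecg is not None:
            written.append(write_packet_ecg(bundle.device_ecg, outdir / f"{stem}_chest.csv"))
        if bundle.device_rr is not None:
            written.append(write_rr_stream(bundle.device_rr, outdir / f"{stem}_rr.csv"))
        for t in fixture["truth"]["beats"].get((bundle.subject, bundle.activity_label), []):
            truth_rows.append(
                {
                    "beat_epoch_ms": t,
                    "subject": bundle.subject,
                    "activity": bundle.activity_label,
                    "mode": bundle.mode,
                }
            )
    import pandas as pd

    truth_path = outdir / "ground_truth.csv"
    pd.DataFrame(truth_rows).to_csv(truth_path, index=False, float_format="%.3f")
    written.append(truth_path)
    return written
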