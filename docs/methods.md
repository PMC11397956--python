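# Methods

This note documents the models, algorithms and numerical choices behind
`ecgval`, and what the synthetic benchmarks do and do not establish.

## Data model

All streams are normalised to Unix epoch milliseconds on load. An
`ECGRecord` is strictly uniform: sample *i* sits at
`start_epoch_ms + i·1000/fs`; no resampling or filtering is applied, so
each stream keeps its native rate (1000 Hz criterion, 500 Hz chest
sensor). Packet loss in the chest stream is zero-filled to preserve the
uniform grid, with the lost spans recorded as dropout segments (a gap
counts as a dropout when consecutive packet timestamps differ by more
than 1.5 packet durations).

Watch exports are timestamped in seconds since the FIT epoch (midnight
31 December 1989 UTC); conversion adds 631,065,600 s — twenty calendar
years including five leap days, minus one day. An `RRSeries` stores one
row per detected beat: the beat epoch and the RR′ interval ending there.
Rows equal to the 5000 ms sentinel (no beat detected in the preceding
5 s) are flagged and excluded from the interval arrays rather than
treated as intervals; this is why the series does not force the strict
`beats = cumsum(rr)` relation, which only holds for sentinel-free data.

Disconnections show as almost-absent voltage: the record is truncated at
the first sliding window (default 2 s, hop 1 s) whose peak-to-peak range
falls below 50 µV, and only the data before the cut are used. Both
constants are configurable; the defaults are an operationalisation of a
qualitative rule and sit far below any attached-electrode QRS amplitude
(hundreds to thousands of µV) yet above baseline noise.

## R-peak detection

The detector targets recordings whose heart rate spans roughly 60–200
bpm within minutes and whose QRS amplitude drifts with electrode motion.

**Segmentation.** The record is cut into contiguous intervals (default
10 s — long enough for ≥5 beats at 30 bpm, short enough that amplitude
and rate are near-stationary during a ramp). Each interval is processed
with 0.5 s of context on both sides so an apex at an interval edge is
still a local maximum; only candidates inside the half-open core are
kept.

**Dual branches.** Every interval is scanned for upright R apices and,
on the negated signal, for dominant S deflections. This makes detection
invariant to lead polarity: negating the whole record exactly swaps the
branches.

**Threshold search.** Within a branch, candidate thresholds descend from
the 99th voltage percentile in one-percentile steps (floor: 70th).
At each level the supra-threshold local maxima are clustered: maxima
closer than the 200 ms refractory period chain together and are
represented by their largest sample (ties to the earliest). Noise riding
an apex therefore collapses onto the apex, while genuine noise produces
long chains. A level is *admissible* when the cluster count is plausible
for the window length (30–240 bpm), and every cluster is tight (span ≤
half the refractory period). The accepted threshold is the highest
admissible level whose candidate set is unchanged at the next level —
descending further is uncovering no smaller apices. This stop rule is
what lets the search pass below low-amplitude beats in baseline-wander
troughs without descending far enough to pick up T waves: T waves double
the cluster count or break stability first. A window where no level
qualifies (flat line, pure noise) yields no candidates.

**Merging.** Candidates from both branches are merged; events closer
than the refractory period are the same beat, and the deflection with
the larger |voltage| keeps its time (tie → R branch, then the earlier
event). Dominance-based preference — rather than always preferring the
R branch — is what keeps the fiducial on the main deflection for
S-dominant (inverted) morphologies, and it is symmetric, which the
polarity-invariance property requires.

**RR screening and repair.** Detected RR intervals are compared with a
centred rolling median (11 intervals) and MAD. An interval is anomalous
when it deviates from the local median by more than `k·MAD` (k = 4,
with an absolute floor of max(5% of median, 20 ms), since the MAD of a
near-constant series collapses to zero), or breaches the ratio gates
1.8×/0.55× of the local median. The window and gates tolerate the
per-beat RR drift of an incremental test (~2–3 ms/beat) while flagging
any single missed or spurious beat. Long gaps trigger a local re-search:
±300 ms around each expected beat position, both branches, ranked by
prominence, accepted at 0.5× the enclosing interval's threshold — a
relaxed gate that is safe because it applies only inside flagged gaps.
The same search probes beyond the first and last detections, which gap
screening cannot see. Short gaps below the 0.55× gate remove the
lower-|voltage| endpoint. Intervals where more than 30% of RRs are
anomalous get their starting percentile lowered by 5 and are
re-detected. The loop runs until an iteration changes nothing (hard cap
5 iterations); on clean signals it converges in one pass.

Detection is deterministic: no randomness anywhere, ties broken to the
earliest sample, peak time always exactly a sample time.

## Synchronization

Global start timestamps already place every stream on the epoch;
what remains is a constant per-device clock offset (drift within a
session is out of scope). Both RR sequences are rendered as step-held
tachograms on a 250 ms grid — fine enough to resolve beats at 240 bpm —
and the offset grid (default ±30 s in 50 ms steps, centred on the
coarse start-time discrepancy) is scanned for the maximum Pearson
correlation over the mutual overlap, followed by parabolic interpolation
of the optimum (clamped to ±half a step, skipped when the peak is
exact). Correlating value-against-time rather than index-paired RR
values keeps the estimate robust to missed beats, which would de-phase
any index-wise pairing. A peak correlation below 0.5, or a degenerate
constant tachogram (e.g. jitter-free steady rhythm), leaves the result
unverified, and unverified alignments are refused unless explicitly
overridden — the automated counterpart of a visual alignment check.

## Validation statistics

**Matching.** Criterion beats, in time order, each claim the closest
unconsumed device beat within ±100 ms (inclusive). The window is set
against the ~200 ms QRS refractory period: since no two true beats can
be closer than 200 ms, a window of half that makes the one-to-one
pairing essentially unique, and the greedy result coincides with the
optimal assignment (property-tested against a `linear_sum_assignment`
oracle). Unclaimed criterion beats are FN, unclaimed device beats FP.

**Rates.** Sensitivity = TP/(TP+FN)·100, precision = TP/(TP+FP)·100.
Event detection on a continuous signal has no natural negative class, so
TN is defined at the criterion sampling rate: every sample not involved
in a beat decision, TN = total samples − TP − FN − FP. That convention
makes specificity TN/(TN+FP), accuracy (TP+TN)/total and the detection
error rate (FP+FN)/total computable, and it reproduces the aggregate
figures printed in validation studies that use it. Undefined rates
(zero denominators) are reported as NaN, never as 0. Stratified tables
pool by summing counts and then computing rates — a mean of per-stratum
rates would weight a 5-minute rest equal to a 20-minute ramp.

**Agreement.** An RR′ difference pair exists only where two
*consecutive* criterion beats are both matched; intervals spanning a
missed beat are excluded rather than compared to a doubled device
interval, which would contaminate the limits of agreement with
detection failures that the confusion counts already describe.
Bland–Altman uses the sample SD (n−1) and mean ± 1.96·SD. ICC(3,1) is
the two-way mixed, single-measure, consistency form
`(MS_rows − MS_err)/(MS_rows + (k−1)·MS_err)` — consistency rather than
absolute agreement because the raters (devices) are fixed, so a constant
device offset is not a reliability failure; the implementation is
cross-checked against `pingouin`'s ICC(C,1) in the tests.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of an exercise validation
session. Beat times follow a protocol profile — by default 5 min rest
(65 bpm, SDNN 95 ms), 6 min warm-up, a 10 min ramp to ~200 bpm, 6 min
cool-down (SDNN 40–55 ms during exercise), 5 min final rest (~100 bpm,
SDNN 25 ms) — via integrate-and-fire on the instantaneous HR with white
Gaussian RR jitter, floored at 280 ms. The rest/exercise HR and SDNN
levels mirror the physiological ranges such protocols produce. QRS
complexes are analytic two-lobe Gaussian templates with an adaptive
T wave (placed at 35% of the next RR so repolarisation never collides
with the next beat at high HR), baseline wander and white noise; the
dominant apex coincides with the ground-truth beat time by construction.
Device failure modes are modelled as Bernoulli and periodic beat misses
(optionally gated to high HR), spurious beats, Gaussian beat-time
jitter, clock offsets, packet loss and 5000 ms sentinels.

Deliberately *not* modelled: realistic P/QRS/T morphology variation,
respiration coupling, ectopic beats, coloured (autonomic) HRV spectra,
electrode-impedance transients, and clock drift. Consequently the
benchmarks establish that the pipeline recovers known ground truth under
controlled amplitude inversion, noise, dropout, jitter and offset — they
do not certify performance on pathological rhythms or real motion
artifact, which only real recordings can.

Activity slices are cut at inter-beat midpoints so no QRS straddles a
slice boundary, and matching is restricted to the mutual span of the two
streams being compared: a beat outside the other stream's recording
window is unobservable, not a detection error.

## Problem sizes and tolerances

The test suite and the acceptance script shrink protocol durations by a
scale factor (0.2–0.5 for signal-level work; beat-level simulations use
the full-length profile, ~4000 beats per subject, pooling two subjects
where ≥5000 beats are needed). The clean end-to-end benchmark uses five
subjects × three activities × both exercise modes at scale 0.25, where
detection, synchronization and matching are exact: 100.00% sensitivity
and precision, Bland–Altman mean ≈ 0 with SD at the 500 Hz
quantization floor (~1.7 ms). Statistical recovery checks use the 95%
binomial CI at the pooled n (miss rates), ±10% (jitter → SD of
differences, against the closed form σ√2), ±100 ms (offset recovery
under 5% dropout, against a 50 ms search step), and ±0.05 (halved-HR
ratio). Seeds are fixed in tests; the acceptance script derives every
seed from its `--seed` argument.

## Known limitations

* A constant offset per stream; clock drift over very long sessions
  would need a piecewise or linear-skew extension.
* The 30–240 bpm plausibility band is an assumption; severe bradycardia
  below 30 bpm in a 10 s window would defeat the threshold search
  (shorten `interval_s` in that case).
* Tachogram correlation needs RR variability; a perfectly metronomic
  rhythm cannot be aligned (flagged as unverified rather than guessed).
* The repair stage can only recover beats whose deflection still exceeds
  half the local threshold; beats fully buried in artifact stay missed,
  which is the honest behaviour for a validation tool.
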