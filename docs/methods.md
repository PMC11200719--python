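# Methods

## Signal model

The pipeline assumes a ruminating cow filmed at a fixed frame rate
(nominally 30 fps) by a static camera, with a pose detector emitting one
nose and one mouth keypoint per frame in image pixels. One chew is one
jaw cycle — mouth closing, opening, closing again — and appears as one
unimodal pulse in the nose–mouth Euclidean distance `d_i`. The curve is
only *quasi*-periodic: amplitude and period vary cycle to cycle, so chews
are counted individually rather than inferred from a dominant frequency.

Everything downstream needs only the distance series, which is invariant
to camera translation and equivariant under pixel scale; the chew
decision itself is scale-invariant because the median threshold scales
with the data.

## Gap policy

Undetected frames (head turns, occlusion) are handled before filtering:
runs of at most `max_gap_frames` (default 10 frames ≈ 0.33 s) are filled
by linear interpolation of the distance; longer runs split the series
into segments that are filtered and scanned independently, and the
peak-spacing counter never crosses a segment boundary. The default is a
compromise: interpolating across a 2-frame flicker is harmless, while
interpolating across a multi-second dropout would fabricate motion.

## Denoising

The default filter is a zero-phase (forward–backward) Butterworth
low-pass, order 4, cutoff 3 Hz at 30 fps. The chew fundamental sits near
1.2–1.5 Hz (a jaw cycle of ~20 frames plus a brief closed-mouth dwell),
so 3 Hz preserves the chewing band with a wide margin while attenuating
detector jitter; zero-phase filtering is essential because the counter
keys on peak positions, and the forward–backward pass moves them by at
most one frame on band-limited input. A sliding-window median filter
(window 5, shrinking at edges) is provided for comparison. Median
filtering tends to produce flat-topped plateaus (overlapping windows
share a median), which interacts with the strict peak rule — see below.

## Chew decision

Within each segment, scanning left to right, index `i` is a chew iff

* `d_i − d_{i−1} > 0` and `d_i − d_{i+1} > 0` (strict local maximum;
  endpoints are never peaks),
* `d_i > threshold`,
* `i − i_last > min_spacing_frames` (no constraint on the first
  acceptance in a segment).

Acceptance is greedy: once a peak is accepted, any candidate inside the
spacing window is rejected even if taller. This resolution order is a
design choice (the constraint alone does not dictate one); greedy
left-to-right matches streaming evaluation and is deterministic.

**Threshold.** The default is the median of the full filtered series.
The rationale is empirical: during brief rest bouts the mouth wobble
stays below the median while genuine crests exceed it, and the median is
robust to outliers. Computing it on the filtered series (the series the
detector scans) is the default; a `threshold_on_raw` switch uses the raw
series instead, and `fixed` / `rolling_median` modes exist for
heterogeneous recordings whose camera distance drifts.

**Spacing.** `min_spacing_frames` defaults to 20 and is defined at
30 fps; at other rates it is rescaled by `fps/30`, since the constant
encodes a physical chew duration, not a frame count.

**Plateaus.** Strict inequalities mean exact ties are not peaks. Filtered
real signals essentially never plateau, but median-filtered or
integer-valued signals do; `plateau_policy="midpoint"` counts a maximal
flat run flanked by strict ascent and descent as one peak at its centre.

## Session indicators

Chew events are the peak times. Consecutive chews with gap ≤ 3 s belong
to one bout; a bout contributes last-minus-first chew time to rumination
duration, and longer gaps accumulate as excluded rest (the identity
`duration + excluded = last − first` holds exactly). The rest rule is a
strict `>` — a gap of exactly 3 s still counts as rumination. The rule
operates on inter-chew gaps because peaks are the only timestamps the
method produces; there is no separate quiescence detector. Chewing
frequency is count/duration (NaN for a zero-duration session), and a
sliding-window variant (default 10 s window) provides the real-time
display series.

## Keypoint evaluation

OKS is the mean over visible keypoints of `exp(−d²/(2·s·σ²))` with `s`
the bounding-box area and σ the per-keypoint spread constant (default
0.025, the tight-landmark range of the COCO face keypoints). A
`strict_as_printed` switch squares the area in the denominator for
compatibility with formulations that write the scale as `s²`. AP at
threshold T is, by default, the fraction of instances with OKS > T
(`indicator` mode); `as_printed` mode instead averages the OKS values
themselves with sub-threshold values zeroed. Both are monotone
non-increasing in T. mAP\@0.5:0.95 averages AP over thresholds 0.50 to
0.95 in steps of 0.05. Predictions are matched to ground truth per image,
greedily by descending OKS; a matched prediction with OKS above the
threshold is a true positive, other predictions are false positives, and
unmatched ground truths are false negatives. Precision is TP/(TP+FP),
recall TP/(TP+FN).

## Count validation

The chew-count error rate for one video is
`100·|assessed − measured| / reference` where *assessed* is the
pipeline's count and *measured* the manual tally. The default reference
is the assessed count — the convention under which the bundled ten-video
validation table is internally consistent — with `denominator="measured"`
available for the alternative convention of normalising by the human
tally. Across videos the summary is the arithmetic mean and the
*population* standard deviation (divisor n), with rounding applied only
at reporting time. Two rows of the bundled table carry a one-unit
inconsistency in their printed last digit relative to the exact ratios;
the package always reports the exact ratios.

## Synthetic generator

The generator scripts the distance signal first and then places
keypoints to realise it: the nose is anchored, the mouth sits directly
below at the scripted distance, and both receive independent Gaussian
coordinate noise. Each chew is a raised half-sine pulse over the
closed-mouth baseline (any unimodal pulse would do; the half-sine is
analytically convenient and matches the close–open–close description).
Cycles are separated by a short closed-mouth dwell (default 5 frames):
without it, back-to-back ~20-frame cycles would place true peaks exactly
20 frames apart, which the strict >20-frame spacing rule would reject —
the dwell is both physically real and what makes the ~20-frame chew
duration and the spacing rule mutually consistent. A +0.25-sample phase
offset in the pulse guarantees a unique strict maximum per cycle for any
integer period.

Defaults, chosen as plausible for a cow filmed at 30 fps and fixed
thereafter: baseline 30 px, amplitude 15 px (±10% per cycle), period
20 frames (±10%), keypoint noise 1 px, no dropout. These place the series
median roughly halfway between rest wobble and chew crests, the regime
the median threshold is designed for. Rest bouts replace the dwell before
a given chew index with a slow 0.5 Hz wobble at 20% of the chew
amplitude, guaranteed below the series median in all default regimes;
because the rest replaces only the dwell, the measurable inter-peak gap
exceeds the scripted rest duration by about one chew period (the flanking
half-cycles), which is the tolerance used when checking rest exclusion.
Randomness is split into four independent sub-streams (period, amplitude,
noise, dropout), so toggling dropout does not change the noise draws.

What the generator does **not** emulate: pose-detector error structure
beyond isotropic Gaussian jitter and Bernoulli dropout (no correlated
drift, no identity switches, no confidence degradation near occlusion),
camera motion, perspective change, or multiple animals. Passing the
synthetic suite therefore demonstrates correctness of the *computation*
on the stated signal model, not detector robustness on real video.

## Numerical choices and degenerate inputs

* Even-length medians are the midpoint of the two central order
  statistics (numpy convention).
* Zero detected frames, empty series and empty metric lists raise a
  validation error; a zero-duration session yields frequency NaN rather
  than an exception; empty-prediction precision is NaN, recall 0.
* Segments shorter than the zero-phase filter's padding requirement
  (3·(order+1)+1 samples) raise an error naming the segments.
* Problem sizes in the test and acceptance runs — sessions up to 200
  chews, 500 random series for the oracle comparison, 10 replicates per
  noise level — are the package's own choice of a grid dense enough to
  exercise every code path while keeping the suite fast.

## Known limitations

* Chew counting presumes the animal is ruminating; the package does not
  classify rumination vs. feeding vs. idle, so feeding jaw motion would
  be counted as chews.
* The median threshold assumes roughly stationary camera distance within
  a video; slow zoom or approach shifts the median (the rolling-median
  mode is a partial remedy).
* Rumination duration is measured between chew peaks, so the half-cycle
  before the first and after the last chew of each bout is not counted.
* The rest-exclusion rule cannot distinguish a genuine rest from a long
  detection dropout that splits a segment; both appear as long inter-chew
  gaps.
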