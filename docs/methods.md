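# Methods

## Detection model

Let `au6[i]`, `au12[i]` be continuous AU intensities (0–5 FACS scale) and
`au25[i]` the dichotomous lips-apart flag for frame `i` of a session sampled
at `fps` frames per second. Frame timestamps are frame *start* times; a
frame spans `[t, t + 1/fps)` and all interval arithmetic is half-open in
time, while frame spans are inclusive in indices.

A frame is a smile frame iff

```
au6[i] > Th1  and  au12[i] > Th2  and  tracked[i]
```

Strict inequalities fix the boundary behaviour, which the 0.05-step grid
search needs to be well defined: with `Th = 5` the classifier is
all-negative. Frames where face tracking failed are retained (the time base
stays intact) but can never be smile frames; they accumulate gap time like
any other non-smile frame. Treating lost tracking as "not smiling" is the
conservative policy; it will shorten episodes spanning tracking dropouts.

**Segmentation.** Maximal runs of smile frames are merged iff the gap
between them is strictly shorter than the stand-by time (default 2 s):
`gap_frames / fps < standby`. A gap of exactly the stand-by splits. The
rule's two natural phrasings — "episode ends after sub-threshold activity
longer than 2 s" and "episodes separated by less than 2 s merge" —
contradict each other only at exactly 2 s; we follow the merge phrasing
with a strict comparison. Merged gap frames belong to the episode: they
count toward duration and sit in the denominators of mean AU6, mean AU12
and tooth show ("across the entire episode"). Episodes truncated by an
analysis window are kept; there is no minimum-duration filter, so
single-frame noise spikes are reported as episodes and are expected to be
dealt with at calibration, not by post-hoc pruning.

**Session metrics.** episodes/minute = n / (length/60); relative smile
time = 100 × Σ durations / length; episode means are unweighted. With zero
episodes the means are reported absent (`None`), not zero.

## Calibration

Calibration is frame-wise and precedes episode logic (no stand-by merging):
the reference is the manual coders' frame labelling, expanded from
inclusive onset/offset frame intervals. Both thresholds sweep the inclusive
lattice {0, 0.05, …, 5}²; frames from all sessions are pooled into one
confusion table per lattice point (the validation sample is reported as a
single Se/Sp/AUC, and pooling is the reading that reproduces single
numbers; per-session tables are available by calling `threshold_grid` on
single sessions).

The grid is computed by binning each frame's (AU6, AU12) pair against the
lattice once and recovering every point's counts with a reverse 2-D
cumulative sum — O(frames + lattice) instead of O(frames × lattice); a test
verifies equality with naive per-point classification. Untracked frames are
pushed to −∞ before binning so they classify negative at every threshold.

A two-threshold classifier has no ROC *curve*; we use the Pareto
upper-left envelope of the (FPR, TPR) cloud, anchored at (0,0) and (1,1),
and the trapezoidal area under it as AUC. The operating point maximises
Youden's J = Se + Sp − 1, ties broken toward higher specificity, then
higher Th1, then higher Th2 (the most conservative tied point). Undefined
rates (no positive or no negative reference frames) propagate as NaN and
such points are excluded from the frontier and the argmax.

## Episode-level validation

Detected and reference episodes are matched one-to-one, greedily in
decreasing frame-overlap order (ties: earlier reference, then earlier
detection); any overlap ≥ 1 frame is matchable, with an optional minimum
overlap fraction of the shorter span (default 0). The episode-level true
positive rate is 100 × matched reference / total reference. Greedy rather
than optimal assignment: the two differ only in pathological overlap
patterns, and greedy is reproducible and easy to reason about.

For the confounder analysis, a task is flagged iff any detected episode's
time span `[onset, onset + duration)` intersects the task window
`[start, end)`; posed-smiling tasks are excluded from the denominator
(a smile detected there is correct).

## Synthetic sessions

The generator emulates the validation setup: a 264 s stimulus viewing at
30 fps, optionally followed by the scripted task block (speaking 10 s, all
other tasks 6 s, 6 s inter-task intervals; posed smiling three times;
13 events).

* **Episode count** ~ Poisson(rate × length/60), default rate 1.6/min.
* **Durations** ~ log-normal matched by moments to mean 11.3 s, SD 5.6 s,
  floored at 2·ramp + 2 frames so a plateau always exists.
* **Placement** uses a spacing construction: the duration set is drawn
  (re-drawn up to 100 times if it cannot fit), the mandatory ≥ 2 s + 2
  frame separations are reserved, and the remaining slack is split
  uniformly over the n + 1 gaps. A configuration whose expected occupancy
  rate × (mean duration + separation) exceeds the session is rejected as
  infeasible; an individual count draw that cannot fit is truncated — a
  saturated session holds as many episodes as physically fit, which
  slightly shortens realised durations in tightly packed sessions.
* **Trajectories** are trapezoids: linear 0.5 s ramps from a constant
  per-session baseline (uniform in [0, 0.6 × boundary]) to the apex
  (defaults 1.3 for AU6, 2.2 for AU12), with each AU's ramp shifted in
  time so that *both AUs cross their boundaries (0.5, 1.5) exactly at the
  episode's onset and offset*. Ground truth is defined as the frames where
  both noise-free trajectories strictly exceed their boundaries, so a
  noise-free detection at the generative boundaries reproduces the truth
  identically, and truth intervals inherit the ≥ 2 s separation of the
  placement.
* **Partial activations** (default 3/min, alternating kinds) populate the
  near-boundary region of the non-smile intensity distributions:
  non-Duchenne events drive AU12 to its apex while AU6 rises only *to* its
  boundary (a triangle with the same slope as the smile ramp at its
  crossing, peak exactly at the boundary, never above), and
  cheek-raise-only events are the mirror image. They generate no ground
  truth. Without them the joint rule makes each threshold unidentifiable
  from below — the other AU's threshold gates every false positive — and
  the Youden optimum drifts several grid steps low under noise; with them
  the false-positive and false-negative pressures around each boundary have
  matched densities by construction and the grid search recovers both
  boundaries to within one 0.05 step. These events are stylised
  identifiability devices, not claims about facial physiology.
* **Noise** is additive i.i.d. Gaussian (default SD 0.1), clipped to
  [0, 5]. **Tooth show**: AU25 is Bernoulli(0.472) on ground-truth smile
  frames, false elsewhere. Confounder-task signatures: yawning and mouth
  covering raise AU12 (not AU6) above boundary inside the task window;
  posed smiling raises both; all other tasks perturb AU12 sub-boundary
  only — likewise stylised.

Everything is a deterministic function of the configuration including the
seed; batches derive per-session seeds from a `SeedSequence`.

**What the generator does not emulate:** AU estimation error structure of
real landmark trackers (autocorrelated, heteroscedastic, head-pose
dependent), smooth or asymmetric onset/offset dynamics, apex variability
within an episode, tracking dropouts, or inter-individual baseline
differences within one session. Passing tests therefore demonstrate the
correctness of the algorithms under the stated generative model, not field
performance on real video; the published validation numbers (AUC 0.94,
Se 82.9 %, Sp 89.7 % on 30 participants) require the original recordings
and are out of desk-scale reach.

## Numerical choices

* Threshold lattice values are rounded to 10 decimals so they print as the
  exact decimals they represent.
* CSV round trips are exact: floats are written with 17 significant digits
  and parsed with pandas' `round_trip` parser.
* Frame rate is inferred as the reciprocal of the *median* inter-frame
  interval (robust to isolated dropped frames) and is invariant under time
  shifts.
* AU25 continuous columns, if present, are ignored; the dichotomous
  `AU25_c` is authoritative (≥ 0.5 → true).
* Degenerate inputs: empty reference (all-negative) sessions leave Se/J as
  NaN rather than raising inside the grid; writing a zero-frame series is
  refused; a single-frame series cannot infer fps and must be given one.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
the segmentation oracle uses 1000 random vectors of ≤ 50 frames; threshold
recovery pools 20 one-minute sessions at 30 fps (36 000 frames) over the
10 201-point grid; noise-free consistency covers 20 seeded 264 s sessions.
These sizes make every check complete in seconds while keeping the
statistical checks (3-SE bands on rates, durations and tooth show over 50
sessions) meaningfully powered.
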