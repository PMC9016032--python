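# Methods

`tapjump` re-creates, end to end, the analysis of how vigorously an
ongoing interception movement is corrected when its target jumps
sideways. Because the original motion-capture recordings are not part
of this package, a synthetic-experiment generator with a fully known
generative law stands in for them; every downstream stage is tested
against that law.

## The task being modelled

A participant rests a finger on a start point at the bottom of a
screen. A disk (3 cm or 1.5 cm diameter) appears 48 cm above the start
point and moves straight down at 10 cm/s; it must be tapped before its
leading edge reaches a horizontal line 800 ms later (hence the line
sits 9.5 cm / 8.75 cm below the appearance point). The moment the
finger lifts more than 5 mm off the screen, the target jumps 2.6 cm
left or right. In alternating 20-trial blocks the target either stays
on the displaced path or jumps back 150 ms later. Two 12-block
sessions are run per participant (one target size each, order
counterbalanced); the first two blocks of each session are warm-up.
Within a block, 10 leftward and 10 rightward jumps occur in random
order. A tap is registered online when the finger's acceleration away
from the screen exceeds 50 m/s²; recording stops 500 ms after movement
onset if no tap occurred.

## Analysis chain

1. **Filtered kinematics.** Acceleration (and, where needed, velocity)
   comes from a second-order Savitzky–Golay filter over ±20 ms
   (21 samples at 500 Hz): twice the quadratic coefficient of the
   least-squares parabola per window, in physical m/s². Windows
   containing any invalid sample are invalid — no curvature is invented
   across marker dropouts — so the first and last 10 samples of every
   valid run carry no estimate.
2. **Events.** Onset = first valid sample with z > 5 mm (the jump is
   simultaneous by design). Tap = the peak of the first
   above-threshold (50 m/s²) away-from-screen acceleration excursion
   after onset. We use the excursion *peak*, not the first threshold
   crossing, because any smoothing filter crosses the threshold a few
   milliseconds before impact while the peak coincides with the contact
   kink; on noise-free data this recovers the true contact time to one
   sample. When no excursion exists the tap time is estimated: first
   from the moment the finger stops moving toward the screen (filtered
   z-velocity ≥ −0.01 m/s, a tolerance ≈ 3× the velocity noise, after
   descending below a 10 mm gate), else by a least-squares line through
   the last 10 valid samples extrapolated to z = 0, accepted only when
   the extrapolated contact is ≤ 50 ms past the last valid sample.
   Trials with no acceptable estimate carry a +inf sentinel for their
   time measures; the sentinel is legal only inside medians, and a
   median that lands on it aborts the run.
3. **Pairing and response measures.** The i-th leftward jump of a block
   is paired with its i-th rightward jump. The right-minus-left lateral
   acceleration difference (each trial aligned at its own jump time)
   cancels jump-independent curvature; **vigour** is its signed peak
   over the response window, with ties broken to the earliest peak.
   For stay pairs the window runs from the jump to the earlier of the
   two taps. For jump-back pairs it is additionally capped at 250 ms
   after the jump (150 ms jump-back delay + ~100 ms visuomotor
   latency): the return correction's deceleration lobe points in the
   first-jump direction and would otherwise masquerade as
   first-response vigour, and only the first response is analysed.
   The lateral-position half-difference re-indexes each trial by time
   before its own tap (linear interpolation at the native sample
   period) and halves the right-minus-left difference so the scale
   corresponds to a single 2.6 cm jump; it requires *detected* taps.
   A pair's remaining time (tap − jump), reaction time (appearance →
   jump) and main-direction peak acceleration are the means of its two
   members' values (+inf propagates).
4. **Aggregation.** Medians across the 5 replications of each block
   type per participant (cells: condition × size × pair index; even
   counts take the mean of the central pair; the vigour median uses
   only replications usable for acceleration, with the count recorded),
   then unweighted means ± standard errors (sample SD/√n) across
   participants. Hit fractions count every analysed trial (no-move
   trials are misses).
5. **Vigour fit.** Vigour and remaining time are both noisy, so the
   relation is summarised by orthogonal (total least squares)
   regression after standardizing each variable by its mean and sample
   SD (ddof = 1) — the distance metric is then unit-free. On
   standardized data the orthogonal slope is sign(r)·1, so the raw
   slope is sign(r)·SDy/SDx through the point of means; the
   implementation takes the principal axis via SVD so this closed form
   is a tested consequence, not an assumption. Residuals are reported
   as rms perpendicular distance in SD units, making pooled, by-size
   and by-participant fits comparable. The pooled fit uses the 40
   group-level cells; the by-participant fit uses each participant's
   overall mean; points are unweighted. The same machinery fits vigour
   against reaction time and against main-direction peak acceleration
   for the residual comparison.

## The synthetic generator

Phenomenological, not biomechanical: no arm model, no muscles, no
feedback controller. Each trial composes three smooth parts on the
500 Hz grid:

* **z (perpendicular):** minimum-jerk rise to 5 cm, placed so the 5 mm
  crossing lands on the drawn onset time; then a constant-velocity
  final descent (1.3 m/s) ending in a contact kink whose filtered
  deceleration (~65 m/s²) is what the 50 m/s² tap criterion sees.
  "Gentle" taps land with a minimum-jerk profile (zero contact
  velocity) and are invisible to that criterion.
* **y (main direction):** minimum-jerk transport to the target's
  interception height, time-warped by a lognormal exponent
  (σ = 0.2) so peak transport acceleration varies across repetitions
  independently of the correction law, as repeated reaches do.
* **x (lateral):** flat until one visuomotor latency (100 ms) after
  the jump, then a minimum-jerk correction of amplitude gain × 2.6 cm
  completing at the *planned* tap time; in jump-back trials an equal
  and opposite correction starts one latency after the jump back and
  completes at the actual tap. The peak acceleration of a minimum-jerk
  displacement is (10/√3)·amplitude/duration², so vigour is by
  construction a function of the (planned) remaining time.

Behavioural distributions the study did not print are fixed once at
values consistent with its reported tap times (~0.55–0.75 s after
appearance) and ~400 ms movement times: onset N(0.25, 0.04) s; planned
movement time N(0.38, 0.03) s for the large target and N(0.42, 0.03) s
for the small one. Two further features mirror the reported
phenomenology: a within-block linear trend of ±30 ms in planned
movement time (stay blocks start slow and speed up; jump-back blocks
the reverse), and a movement prolongation of N(0.04, 0.02) s (clipped
at 0) in jump-back trials — the return response lengthens the
movement, while the first response's vigour is set by the *expected*
(planned) remaining time. Default first-response gains are 1.0 (stay)
and 0.8 (jump-back). Measurement imperfections are applied last:
0.2 mm additive marker noise, contiguous dropout runs (geometric run
length, mean 8 samples, 0.5% marginal rate), 4% gentle taps, and
0.125% no-move trials (5 in 4000). Endpoint aim error is N(0, 5 mm)
per axis; a trial is a hit when the noise-free fingertip lies within
the target disk at contact.

Randomness: one master seed; each trial draws from a substream keyed
by (seed, participant, session, block, trial), so single trials can be
regenerated without replaying the experiment, and identical seeds give
byte-identical outputs.

### What the generator does not emulate

Real recordings contain skin-motion artefacts, marker rotation away
from the cameras (modelled only coarsely as dropout), curved
idiosyncratic lateral paths beyond a smooth drift, trial-to-trial
learning within blocks beyond the movement-time trend, and any genuine
dependence of vigour on anything but remaining time. A green test
therefore establishes that the *pipeline* measures what the generative
law put in — not that the law is true of people.

## Numerical choices

* Sentinel: +inf, never serialized (tables blank it and record a
  boolean; writers refuse to emit it).
* The stop-moment velocity tolerance (0.01 m/s) exists because
  overlapping filter windows make the post-contact velocity estimate
  one long correlated draw that can sit slightly below zero.
* Interpolation for the time-before-tap grid is linear and marks
  points bridging dropout gaps (> 2.5 samples) invalid.
* Vigour tie-break: earliest peak. Degenerate corrections (window
  shorter than two samples) are emitted without a correction and
  flagged.
* The orthogonal-fit angle-scan oracle (brute-force scan over line
  angles) ships in the test suite only.

## Known limitations

* Vigour is an extremum statistic, so measurement noise biases it
  upward (~1 m/s² at the default noise level); the bias is intrinsic
  to the statistic and present in any empirical use of it. The null
  calibration is therefore stated at the difference-trace level.
* The by-participant fit recovers the sign and rough magnitude of the
  generative slope but is steeper than the pooled fit, because
  across-participant scatter in mean vigour is dominated by the
  curvature of the underlying 1/(t−λ)² law over each participant's own
  operating range.
* Tap-time estimates for gentle taps are biased late by up to ~20 ms
  (half a filter window); this only affects time measures of trials
  without a detected tap.
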