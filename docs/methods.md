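# Methods

This note records the models, parameter choices and numerical decisions
behind `cathstab`, in the order data flows through the package.

## Synthetic trajectories (`cathstab.simulate`)

A session trajectory is assembled additively:

```
pos(t) = baseline + respiration(t) + movements(t) + jitter(t)
```

sampled uniformly at 60 Hz (typical electroanatomic-mapping location rate;
sub-50 ms resolution is needed to resolve the 2 s dwell and 3 s grace
windows).  All randomness comes from two child streams of one session seed
(respiration timing and localisation jitter), so ground truth is exactly
separable: subtracting the stored respiration channel from a simulated
trajectory reproduces the respiration-free simulation bit-for-bit.

**Respiration.**  Cycle lengths are drawn per cycle as
`T·(1 + jitter·N(0,1))`, clipped to ±50%, with `jitter = 0.02` by default
and the rate defaulting to 10 breaths/min (the clinical ventilation range
here is 10–12; studies vary the rate explicitly).  Within a cycle the
waveform is either a sinusoid or, by default, an *asymmetric plateau*:
raised-cosine inhale/exhale with an end-expiration plateau occupying 40% of
the cycle, making end-expiration a well-defined long dwell, as it is
clinically.  Phase 0 is the plateau centre; ground-truth end-expiration
instants are the cycle boundaries.  The default peak-to-peak excursion is
(2, 3, 6) mm — a few millimetres more along one (roughly cranio-caudal)
axis, in the range reported for left-atrial catheter tips.

**Movements.**  A `MovementEvent` displaces the tip by a fixed vector with
200 ms half-cosine ramps (no unphysical velocity steps).  The entire
excursion, including the return ramp, lives inside
`[t_start, t_start + duration]`, so a "3 s excursion" occupies exactly 3 s
of trajectory.  Non-returning events hold their displacement to the end of
the session.  Overlapping events are rejected at configuration time.

**Jitter.**  Localisation noise is white Gaussian (default SD 0.15 mm)
smoothed over 0.1 s, emulating the low-pass filtering of mapping-system
location streams.  Unfiltered white noise at 60 Hz would imply centimetre
per-second apparent tip speeds that no filtered clinical stream shows.

**Timeline.**  `training` (default two nominal respiratory cycles, so the
estimator always has a full training window) → `pre_ablation` irrigation
(2 s) → RF-on (3–4 s QMODE+, AI-guided or explicit for QMODE) → a short
tail.  The RF-on flag is half-open: a sample exactly at RF onset is on.

## Respiration estimation (`cathstab.respiration`)

Estimation is deliberately two-stage.

1. **Oscillation split.**  A moving average of window length one period —
   always a *full-length* window, shifted rather than shortened at the
   edges, so a periodic component cancels everywhere — yields a slow trend;
   the residual is the oscillatory channel used for period estimation and
   event detection.  The first full period is flagged as warm-up
   (`valid = False`): automatic training in progress.

2. **Phase-locked template.**  The respiration estimate proper is a
   synchronous average: the oscillatory channel is binned by respiratory
   phase (24 bins, circular interpolation) over the quiescent training
   window, and the resulting per-phase mean displacement vector is evaluated
   at the continuously tracked phase.  `compensated = raw − template(phase)`
   exactly, per sample.  The moving average itself is *not* used as the
   compensated channel: it would smear a 3 s catheter excursion over a full
   respiratory cycle, which both blunts the velocity signal and stretches
   brief excursions past the thermal-latency grace window.  With the
   template, aperiodic movements pass to the compensated channel unsmoothed.

**Period.**  Principal-axis projection (first right singular vector of the
demeaned positions), linear detrend, lag-unbiased autocorrelation, earliest
peak within 85% of the band maximum in the physiologic 2–12 s band
(earliest, so period multiples are not mistaken for the fundamental),
parabolic sub-sample refinement.  Because short-window autocorrelation
carries an O(period/span) lag bias, the final value is the median spacing of
hysteresis zero crossings of the projected signal when that agrees with the
autocorrelation estimate to 25%.  Signals with RMS below 0.1 mm or peak
autocorrelation below 0.2 raise the *no-respiration* flag (not an error):
compensation becomes a pass-through and the gated algorithm has no events.

**End-expiration events.**  The oscillatory channel is projected on the
principal respiratory axis with the sign chosen so the long-dwell extremum
(more samples within 15% of one extreme than the other) is positive; events
are centres of runs above `max − 0.15·range`, with run fragments merged
below a quarter-period gap, boundary-clipped runs dropped (their centres are
biased), and only the largest period-grid-consistent subset kept (tolerance
0.2 cycle) so that movement artefacts cannot fake a breath.  Ties between
equal extrema resolve to the earlier.  Detection thresholds and axis come
from the training window only.

**Phase tracking.**  Phase is 0 at each detected event, linear in between,
extrapolated at the nominal period outside the detected range.

## Gated algorithm (`cathstab.gated`)

Only positions at end-expiration instants are examined, a deliberate
contract: the verdict is provably invariant to any motion between events.
A tag appears at the first instant with `min_ee_events` (default 2)
consecutive end-expiration positions — counted from RF onset, an event
exactly at onset included — whose spread is within 3 mm.  "Spread" is the
Euclidean distance for two events and the SD of consecutive-pair distances
for longer windows (the two-point reading generalised).  Fewer events than
required, e.g. because a 3–4 s application ends before a full cycle, yields
no indication.  `monte_carlo_time_to_tag` runs the same detector on
analytically constructed event grids with uniform onset phase; its mean for
a stationary catheter is `1.5 × period` (9 s at 10 breaths/min).

## Stability+ (`cathstab.stability_plus`)

Per-sample classification of the compensated stream, causal, strict
inequalities exactly as printed: distance to the site centre < 3 mm AND
speed < 2.5 cm/s.  Speed is a centred finite difference smoothed as a
*vector* over 0.2 s (vector smoothing lets zero-mean noise cancel; smoothing
the scalar speed would rectify it into a positive bias).

**Site centre.**  The centre of mass accumulates only samples classified
stable — it freezes during an excursion.  The alternative (all samples)
lets the centre chase the excursion, ending unstable runs before the
catheter has actually returned and defeating the return test.

**Thermal latency.**  A maximal unstable run is *forgiven* — reclassified
stable — iff it lasts at most 3 s and ends within `return_radius` (default
`d_max`) of the frozen pre-excursion centre.  A run that outlives the grace
window breaks the site on the spot: classification restarts there with a
fresh centre, so a catheter that settles at a new position simply opens a
new site (and can earn a new tag).  The filter is idempotent.

**Tags.**  A tag displays after 2 s of continuous stability, with the dwell
clock never starting before RF onset — a catheter stable from the start of
ablation tags at exactly 2.0 s, independent of respiratory rate.  The dwell
clock runs on *raw* stability: a forgiven excursion keeps the site (and the
session classification) stable but still postpones the tag, so 1 s of
initial movement pushes the tag to ~3 s.  The tag position is the centre of
mass of the stable compensated samples of its dwell.  The first tag of a
session carries `first_site`; a site ended by an unforgiven excursion during
RF carries `halo`.  Pre-ablation stability demands raw stability over the
full 2 s irrigation look-back: thermal latency is an RF-heating argument and
forgives nothing before energy delivery.

**Warm-up.**  While the respiration estimate is invalid the raw positions
stand in for compensated ones, and classification restarts with a fresh site
at the warm-up boundary so the channel switch cannot fake an excursion.

**A caveat on threshold monotonicity.**  Within a fixed site segmentation,
enlarging `d_max` or `v_max` can only enlarge the stable set.  Across an
entire session the site *breaks* may move by a few samples when thresholds
change, flipping isolated samples at break boundaries; the property is
asserted in the tests on break-free trajectories.

## Metrics (`cathstab.metrics`)

**AI surrogate.**  The proprietary ablation index is replaced by
`AI(t) = k·(F^α · P^β · t_rf)^γ` with F contact force (g), P power (W) and
`t_rf` accumulated RF-on seconds.  Defaults: α = 0.68, β = 1.63,
γ = ln(500/350)/ln(20/8) ≈ 0.389, and k calibrated so 50 W / 10 g reaches
AI 350 at 8 s and AI 500 at 20 s — placing most simulated QMODE target times
below the 9 s gated latency, and 90 W reaching 350 in ≈ 3 s, consistent with
3–4 s QMODE+ applications.  The constants live in configuration, not code;
no identifiability with the commercial index is claimed.

**Overshoot.**  The fraction of applications whose AI-350 time falls within
a reference latency (the gated mean): those would have delivered the target
lesion before the gated tag even displayed.  "Within" is inclusive by
default, with a strict-comparison switch.

**Time-to-tag statistics.**  Mean and sample SD over tagged sessions only;
no-tag sessions are counted separately, never imputed.  A single tagged
session reports SD = NaN.

**Study summary.**  Counts with percentages at mixed printed precision —
application shares to one decimal, stability shares to the integer —
recomputed from raw counts, never stored.

## What the simulator does and does not show

The generator reproduces the *mechanisms* the detectors react to: periodic
tip displacement with a dominant axis and an expiratory dwell, cycle-length
jitter, filtered localisation noise, ramped sustained and move-and-return
excursions, and the session timeline (training, irrigation, RF).  It does
not model tissue contact force dynamics, lesion formation, catheter bending,
ectopy or cough, ventilation changes mid-session, or mapping-system
drop-outs.  Passing tests therefore demonstrate algorithmic correctness
under the stated motion model — not clinical performance; the clinical
means (e.g. the 2.5 ± 1 s observed Stability+ latency, which includes
operator settling) are not reproducible from first principles and are not
simulation targets.

## Problem sizes

Default test and acceptance runs use 10,000 Monte-Carlo draws for the gated
latency (event-grid sessions; sub-second), single 18–35 s sessions at 60 Hz
for pipeline checks, and cohorts of ~50 applications for the study command —
sizes chosen so the full suite runs in seconds while Monte-Carlo error stays
well inside the asserted tolerances.
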