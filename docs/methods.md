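# Methods

## Sensing model and conventions

The detector consumes streams of 32×32 absolute-temperature frames (°C) at
a nominal f_s = 5 Hz, one ambient-temperature reading per frame, and a raw
binary PIR level.  Pixel coordinates are one-based; row r grows downward,
column c rightward, so a falling person's centroid moves toward larger r.
The ambient channel is carried through the data model but plays no role in
detection (the rules operate on the pixel grid alone).

## Low-pass filter

Continuous prototype H(s) = ω_l/(s + ω_l); discretized by the bilinear
substitution s = 2 f_s (z − 1)/(z + 1) without pre-warping (at 0.16 Hz
against 5 Hz the warping error is below 0.1 %):

    y[k] = b0 x[k] + b1 x[k−1] − a1 y[k−1],
    b0 = b1 = ω_l/(ω_l + 2 f_s),  a1 = (ω_l − 2 f_s)/(ω_l + 2 f_s).

Defaults: ω_l = 1 rad/s (cut-off ω_l/2π ≈ 0.16 Hz — temperature scenes
change slowly), f_s = 5 Hz, giving b0 = b1 = 1/11, a1 = −9/11.  Filter
state initializes to the first frame (x_prev = y_prev = x[0]); a
zero-initialized filter would suppress a warm body for several seconds and
starve segmentation on short streams.  DC gain is exactly 1 and |a1| < 1
for every valid design.

## Segmentation

Pixels outside [0, 40] °C are deleted before any statistics (hot shower
water above 40 °C is removed here).  The threshold is the midpoint
T_th = (T_min + T_max)/2 of the surviving extremes, and the candidate band
[T_th, T_max] is inclusive at both ends — an exclusive upper bound would
discard the hottest body pixel.  When all valid pixels are equal the
degenerate threshold selects everything rather than failing.

Labeling is the two-pass double boundary scan over a 34×34 zero-bordered
label grid: the first raster pass assigns provisional block numbers from
the 8-neighborhood (fresh number on an empty neighbor set, otherwise the
minimum) and appends multi-label neighbor sets to a relationship table; the
second pass unions intersecting relation sets and relabels to each set's
minimum.  The pairwise union pass is iterated to a fixpoint because a
single pass can miss chains such as {1,2},{3,4},{2,3}; the literal single
pass remains available (`to_fixpoint=False`).  Only the largest block
survives; ties break to the smallest block number (deterministic).  The
suite proves equivalence with an independent flood-fill oracle
(scipy.ndimage, 8-connectivity) exhaustively on all 4×4 masks and on seeded
random 6×6 and 32×32 masks.

## Streaming detector

Per frame, the locked region's centroid enters a five-sample (1 s) rolling
buffer; stability requires stdX_c < 1, stdY_c < 1, |dX_c| < 2, |dY_c| < 2
(strict; population standard deviations, configurable via `std_ddof`).
Stable snapshots record the stable center (the buffer means), the full
temperature grid, the locked-area mean temperature T_c, pixel count N_c and
row span LY.  Three design choices harden the snapshot bookkeeping against
the filter's one-second memory:

* **One-second means for T_c and N_c.**  Matching the mean-based stable
  center, the snapshot's T_c and N_c are means over the last five frames,
  so a single smeared frame at the edge of a stability window cannot
  corrupt the reference values.
* **Thermal-stability gate.**  A snapshot is only taken when the 1 s
  standard deviation of T_c is below 1 °C.  When a body leaves its
  position, the filter keeps a *cooling afterimage* there whose centroid
  does not move; it passes the center-stability test while its temperature
  collapses, and without this gate it would refresh the reference snapshot
  and break the |dT_c| < 2 °C comparison of the fall rule.
* **New-moment threshold of 2 px.**  A stable frame opens a *new* stable
  moment (pushing the previous snapshot into the comparison slot) only when
  the stable center moved by more than 2 px — the same granularity as the
  |dX_c|, |dY_c| < 2 motion bound.  Sub-pixel drift while a settled body's
  filtered image finishes converging refreshes the current moment in place.

The fall-action rule is the nine-way conjunction over adjacent stable
moments: |dT_c| < 2 °C, 0.5 < RN_c < 1, 20 < N_c < 200, |dSX_c| < LY/3,
|dSY_c| > LY/2, SPIR = 1, 1 < SX_c < 30, ED > 10, flag_sta = 1, where
RN_c = N_c(new)/N_c(old), LY is the previous snapshot's row span and ED is
the root of summed squared temperature differences over the new locked
region between the two snapshot grids.  Difference terms use absolute
values (a `signed_deltas` option keeps the literal one-sided forms).  The
conjunction is re-evaluated at **every** stable frame, not only when a new
stable moment opens: the filtered temperatures of a freshly occupied area
keep settling for a couple of seconds, so a comparison that fails at the
first stable moment can legitimately pass a few frames later while the PIR
hold is still active.  On the 0→1 transition T_c0/N_c0 are latched and the
duration timer t_d starts.

The reset rule clears the flag (and t_d) when any of |dX_c| > 2,
|dY_c| > 2, t_d > 120 s, T_c − T_c0 > 2 °C, or N_c − N_c0 > N_c0/3 holds;
the temperature and area clauses are one-sided growth checks (drift onto a
heat source), the center clauses absolute.  A transient set-reset-set cycle
can occur while a landed body's image finishes warming (the area-growth
guard fires once); t_d is nondecreasing within each episode.

SPIR extends raw PIR activity by a 2 s hold (a raw pulse yields 11 active
frames at 5 Hz); t_bm accumulates SPIR-active seconds over a trailing 60 s
window (hence 0 ≤ t_bm ≤ 60).  When segmentation returns nothing, the
rolling buffers clear and the flags decay to 0; stable snapshots are
retained so a re-acquired lock can still compare.  On a static degenerate
scene (all pixels equal, the whole grid selected) flag_sta can legitimately
be 1; the fall flag still cannot fire because N_c ≥ 200.

Per-test summary: each stream collapses to the feature vector of the frame
with maximal t_d (the most developed fall evidence), or the final frame if
the flag never rose — one 8-element row plus one label per test, which is
what the classifier trains and predicts on.  In deployment the features
mature over the 60 s movement window, so the practical response time is on
the order of a minute.

## Classifier

8 inputs, 20 tansig hidden units (tansig ≡ tanh), 1 relu output; training
minimizes ERR = Σ(EY − Tg)²/2 on {0,1} targets.  Levenberg–Marquardt is
the default (damped Gauss–Newton on the output Jacobian; steps accepted
only when ERR decreases, λ adapted by factors of 10), with plain batch
steepest descent selectable (`learning_rate` applies to the summed
gradient; default 1e-3).  Stopping: training MSE ≤ `target_mse` (default
1e-3) or `max_epochs` (default 1000).  `final_error` is the training MSE
(= 2·ERR/N).

Initialization draws all weights and thresholds uniformly from
[−0.5, 0.5] (seeded), then shifts the output threshold so the mean output
pre-activation over the training batch equals the target mean 0.5: the
hidden tanh layer can saturate to nearly sample-independent outputs, and an
uncalibrated start then lands in the relu's dead region — zero gradient —
with even odds.  If a fit still stalls, training restarts from the next
seeded initialization (up to `restarts` = 5) and keeps the best run;
everything is deterministic given the seed.  Inputs are min–max scaled to
[0, 1] by default, fitted on training data only, because the raw features
mix binary flags with durations up to 120 s; `none` and `zscore` are
available.  The decision threshold on the relu output is 0.5, inclusive.
Models persist as flat JSON (shapes, weights, config, scaling) and
round-trip bit-exactly.

## Scene simulator

The generator renders the factorial study design: 5 ambient levels × 2⁶
binary factor combinations × {fall, non-fall} = 640 scenarios, 128 per
ambient level, 64 falls per level.  Per-scenario seeds derive
deterministically from the base seed; streams are bit-reproducible.

Rendering choices (the sensor deposits no public radiometry, so these are
modeling decisions): background = ambient + illumination term (LED: −0.3 °C
corner vignette; sunlight: +2 °C horizontal ramp) + i.i.d. Gaussian noise,
default σ = 0.3 °C (typical thermopile noise-equivalent scale).  The body
is an elliptical blob, 33 °C rim to 36 °C core, composited by `max`;
pre-fall semi-axes (6, 4) px for the 1.6 m subject and (8, 5) px for the
1.8 m subject place the locked count inside the rule's (20, 200) band.
Falls drop the centroid 12 rows (beyond LY/2 for both builds) with a 1 px
sideways drift and shrink the area to ×0.85 (sitting) or ×0.6 (lying),
over 0.5 s (fast) or a sustained constant-rate 2.5 s (slow).  Falls are
preceded by a 1.2 s sideways stagger (the slip) — real falls are preceded
by motion, and the stagger breaks centroid stability so the pre-fall
reference snapshot freezes while the body is still settled — and followed
by 2 s of sub-pixel settling jitter that keeps the PIR channel active
through the thermal transient without breaking stability.

Non-falls rotate through four archetypes keyed to the factor levels:
squat-and-rise (4-row centroid dip, deliberately below the LY/2
displacement bound, with a stable pause at the bottom that exercises the
stable-moment machinery without alarming), a horizontal walk-through with a
mid-room pause, a normal shower (person present with continuous bounded
jitter), and shower-only with no person.  Shower scenes add a static warm
water patch — 35 °C (inside the body band, confusable) or 43 °C (removed by
abnormal-pixel rejection), chosen by seed — plus residual warm floor
pixels.  Raw PIR fires on frames where the rendered body centroid moved at
least 0.5 px and on appearance; the static patch never drives it.

What the simulator does **not** model: real radiometric mixing at body
edges, sensor fixed-pattern noise and drift, occlusion, multiple people,
steam, or the optics of the real enclosure.  Synthetic accuracy therefore
measures the internal consistency of the pipeline against the geometry the
method assumes, not field performance on real recordings.

## Evaluation

RE = TP/(TP+FN), PR = TP/(TP+FP), ACC = (TP+TN)/total,
F1 = 2·RE·PR/(RE+PR); undefined ratios surface as NaN with a warning.
Cross-validation is five-fold by ambient temperature: fold i validates on
the i-th level (18 … 30 °C) and trains on the other four, with a
fold-specific training seed derived from the run seed.  Fold averages are
means of per-fold metrics — the convention that reproduces the reference
trial's printed averages; pooled-count metrics differ (pooled precision
94.48 % vs 94.45 %) and are available separately, clearly labeled.
Percentages display with half-up rounding to two decimals.

Problem sizes: the evaluation harness and the acceptance script run the
factorial at 30 s per stream (enough for every scripted activity to
complete and the fall rule to mature) and σ = 0.3 °C; the generator default
remains 120 s.  Dataset-write checks use 2 s streams since the counted
design is duration-independent.

## Known limitations

* A slow fall that pauses *stably* (≥ 1 s) half-way down defeats the
  adjacent-stable-moment comparison: each hop spans less than LY/2 and no
  single comparison sees the full drop.  The rendered slow fall is
  therefore a continuous descent; the stable mid-pause case is a genuine
  blind spot of the rule set.
* The |dT_c| < 2 °C check depends on the reference snapshot staying clean
  through the fall transient; the thermal-stability gate handles the
  cooling-afterimage pathology, but extreme contrast combined with an
  utterly motionless pre-fall subject remains the hardest corner.
* A warm object larger than the person (e.g., an extended hot-water area)
  would capture the largest-block lock; the method tracks exactly one
  block by design.
* Classification quality on real recordings cannot be assessed here; no
  raw data from the original sensor pair is publicly available.
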