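# Methods

`cardiosync` quantifies cardiac synchrony among small groups of
spectators from beat-to-beat (RR) interval data, using cross-recurrence
quantification analysis (CRQA), and relates it to how strongly the
group converges in its explicit emotional ratings.  This note documents
the model, the numerical choices, and what the synthetic data can and
cannot show.

## Pipeline

1. **Tachogram → RR series.**  R-peak times are differenced into RR
   intervals; each interval is anchored at its *second* peak (the
   common heart-rate-variability convention).  A natural cubic spline
   through the (anchor time, RR) pairs is evaluated at 4 Hz inside each
   analysis window.  The seven windows per participant are the
   two-minute baseline, the first and last two minutes of each of the
   two monologues (T1/T2), and the two post-monologue rests.
2. **Series length.**  A two-minute window at 4 Hz yields a 480-point
   grid, but every analyzed series is trimmed symmetrically to the
   central 430 samples.  430 is the fixed series length the analysis is
   defined on; the trimming also discards the window edges, where
   spline support is weakest.  `n_target` is configurable.
3. **Embedding.**  Series are z-scored per segment, then delay-embedded
   with delay τ = 1 sample and dimension m = 11 by default.  When
   `m=None`, the dimension is chosen per series by the
   false-nearest-neighbor (FNN) test and the study-level dimension is
   the maximum over all series.  The FNN test is Kennel's, with both
   criteria: distance-ratio tolerance 10, and attractor-size tolerance
   2 (criterion II is what keeps the FNN fraction high for noise — with
   criterion I alone, 430 samples of white noise "embed" at m ≈ 3).
   "Consistently below the 0.1 cutoff" is operationalized as: below the
   cutoff at the candidate m and at every larger tested m up to
   `m_max` = 15.
4. **Cross-recurrence.**  For an ordered pair of embedded trajectories,
   cell (i, j) is recurrent when the per-dimension RMS distance
   (Euclidean / √m; `euclidean` and `max` norms are available) is at
   most ε.  The default threshold is an *absolute* radius ε = 0.2 in
   z-scored units, i.e. 0.2 standard deviations of signal amplitude —
   one fixed cut for every pair and segment, because a cross-condition
   comparison is only meaningful against a common yardstick.  Two
   relative modes exist: `global_frac` (fraction of the dataset-level
   mean phase-space radius of the segment) and `max_frac` (fraction of
   the pair's own maximal distance).  `max_frac` should not be used for
   group contrasts: a coupled pair is smoother, has smaller extremes,
   hence a smaller cut — the adaptive threshold absorbs, and can
   reverse, the very effect under study.
5. **CRQA metrics.**  Four statistics per plot: recurrence rate `rec`
   (fraction in [0, 1]); diagonal line-length entropy `ent` (Shannon,
   natural log, over maximal diagonal runs ≥ l_min = 2); laminarity
   `lam` (fraction of recurrent points on vertical runs ≥ v_min = 2);
   and `lmax`, the longest diagonal run.  Entropy is *raw* by default.
   The normalized variant (ent / ln #distinct lengths) is available but
   off: its normalizer grows with line diversity, which on strongly
   coupled plots outpaces the entropy itself and inverts the
   coupling-entropy relation; a per-plot data-dependent normalizer is
   not scale-invariant across groups.  No Theiler window is applied —
   these are cross-recurrence plots between distinct participants, so
   there is no self-matching line of identity to exclude.
   Determinism (DET) is provided as a convenience but is not part of
   the pipeline's four metrics.
6. **Threshold selection.**  A data-driven alternative to the fixed ε:
   per pair, the grid candidate maximizing the standard deviation of
   the diagonal line-length distribution ("recurrence states" read as
   the line-length distribution; an SD-of-matrix-entries variant is
   behind `threshold_mode`), ties to the smallest candidate; the
   study-level threshold is the mean of the per-pair selections.
7. **Group contrast.**  Each participant is paired with their three
   quartet-mates (in-group) and with three spectators drawn uniformly
   without replacement from other quartets (out-group), once per run
   from a seed and reused across segments and for convergence scoring.
   Out-group pairs are compared on the *same* segment label.  Metrics
   of the three ordered pairs are averaged per participant × segment ×
   group type.  `rec`, `ent` and `lmax` are orientation-invariant; for
   `lam` the participant is always the row axis.  The group summary is
   descriptive (mean, SE over participants); inferential multivariate
   tests are out of scope.
8. **Behavioral convergence.**  For the performance emotional-intensity
   item (configurable), a participant's convergence score is
   Σ |own − partner| over the three partners, computed per monologue
   and averaged over the two monologues; range [0, 12] for 1-5 ratings.
   Scores (and, separately, the raw intensity ratings averaged over
   monologues) are Pearson-correlated, two-tailed, with the
   participant's mean CRQA metrics over the four monologue windows;
   the significance threshold is Bonferroni-corrected for the four
   metrics (0.05 / 4 = 0.0125).  Zero-variance correlations are
   reported as missing, not zero.

## Synthetic sessions

The generator emulates the study design: `n_quartets` (default 11)
quartets of four spectators; two-minute rests; performance durations
drawn Normal(5.41 min, 1.26 min) truncated at 4 min.  Instantaneous RR
for participant p of quartet q is

    RR_p(t) = μ + σ²_slow/μ + rr_sd · (c_q s_q(t) + c_out g(t) + b u_p(t)) + ε

with μ = `rr_mean` = 0.85 s, `rr_sd` = 0.05 s, s_q a band-limited
(0.04-0.15 Hz) unit-variance driver shared by the quartet, g a global
driver linking quartets (gain 0 by default — out-group spectators
attended different sessions), u_p an individual process, and ε white
per-beat noise.  R-peak times follow by cumulative summation of
instantaneous RR (integral-pulse scheme); the σ²_slow/μ term
compensates the renewal bias of beat-sampling (beats oversample
fast-heart-rate stretches), so the tachogram mean matches `rr_mean`.

Parameter choices that matter:

- **Individual band = driver band.**  If the idiosyncratic component
  had a different (wider) band than the shared driver, the coupling
  gain would change each series' marginal spectrum, and recurrence with
  *anyone* — including out-group partners — would track coupling
  through smoothness alone.  Matching the bands makes coupling act on
  cross-correlation only.
- **Per-beat noise as a fixed fraction (`noise_frac` = 0.04) of the
  modelled slow-signal SD** (~2 ms at default amplitudes, the order of
  R-peak jitter at 1 kHz ECG sampling).  An *absolute* jitter would
  make the noise share — and hence each series' smoothness — depend on
  the coupling gain, and recurrence with anyone would track coupling.
- **`individual_gain` b = 0.35**: at c = 1 the shared driver carries
  ≈ 89% of the modelled variance — strong but not degenerate coupling.

Ratings: per (quartet, monologue, item), a quartet-level mean
~ Uniform(2, 4.5); member ratings ~ Normal(mean, 2.0·(1 − a) + 0.05),
rounded and clipped to 1-5, where a is the quartet's rating agreement.
At a = 1 members receive identical ratings (the dispersion is exactly
zero, not merely small).  With `link_ratings_to_coupling`, a latent
quartet "collective engagement" e ~ Uniform(0, 1) fixes *both* sides:
the rating agreement a = e, and the shared-variance share of the
cardiac signal, ρ(e) = 1 − 0.4·0.02^e (the residual idiosyncratic
share shrinks geometrically from 40% to 0.8%, because the recurrence
rate responds roughly linearly to the *log* of the residual share —
a linear map would leave half the quartets on the flat part of the
response curve).  The coupling gain realizing that share is
c_q = b·√(ρ/(1 − ρ)).  This is the mechanism by which physiological
synchrony and rating convergence become negatively associated.

The strength of this built-in dependence is a design requirement of
the generator, not a free nuisance parameter: the module exists to
produce *recoverable* coupling, and its recovery ceiling is set by the
integer-rating convergence score (a participant-level correlation with
the latent engagement of at best ≈ −0.73 given rounding to five levels
and three comparison partners) times the finite-window recurrence
estimate (≈ 0.8-0.85).

What the generator does **not** emulate: ECG morphology and R-peak
detection; respiratory sinus arrhythmia and other structured HRV
rhythms beyond band-limited Gaussian drivers; nonstationarity within
windows (arousal trends); phase-locking (coupling is additive only — an
open modelling question); actor physiology.  Passing recovery tests
therefore shows the *pipeline* detects additive shared drive at
realistic amplitudes, not that real audiences couple this way.

## Replicated recovery studies

`cardiosync.experiments` runs the generator through the full analysis:

- **Contrast study** (100 replicates, 11 quartets, coupling 1.0):
  mean in-group − out-group recurrence difference per replicate,
  evaluated on one monologue window (m1_T1) per replicate to keep a
  replicate's cost at a few hundred recurrence plots; the effect is
  window-exchangeable by construction.  Without coupling, the observed
  difference is compared against a 200-draw sign-flip permutation null
  (95% band) per replicate.
- **Correlation study** (100 replicates, link mode): the full
  four-monologue-window synchrony analysis, convergence scoring, and
  Bonferroni-corrected correlations, recording in-group recovery and
  out-group specificity.

## Numerical notes and edge cases

- Line-length extraction shears the binary matrix so diagonals become
  columns, then run-length-encodes all columns in one pass; it matches
  a naive per-diagonal scan exactly (tested to 1e-12 on random plots).
- Empty plots score zero on all four metrics; entropy is zero whenever
  the diagonal histogram has at most one distinct length.
- A constant series z-scores to zeros and reports FNN dimension 1.
- Resampling requires the trimmed grid to lie inside the tachogram's
  anchor-time support; violations name the participant and segment.
  A participant missing any segment is excluded from pairwise analysis
  (mirroring the study's exclusion of an incomplete quartet).
- Performances shorter than 4 min make T1 and T2 overlap; this is
  logged and analyzed anyway.
- Floats round-trip through CSV at 12 significant digits; all
  randomness flows through explicit integer seeds, and the full
  pipeline is byte-deterministic given (data, config).

## Known limitations

- The recurrence-rate scale depends on the threshold convention; with
  the default absolute ε = 0.2 SD the plots are sparse (rec of order
  10⁻²), which sharpens group contrasts but means absolute metric
  values are not comparable to analyses using adaptive thresholds.
- With τ = 1 at 4 Hz the embedded cloud of a slow RR series is strongly
  anisotropic (near the main diagonal of the embedding space); m = 11
  is then largely redundant but retained as the pipeline's fixed
  dimension.
- The permutation null treats participants as exchangeable units,
  ignoring the quartet clustering of in-group values; at 11 quartets
  the band is mildly conservative.
- Out-group partner draws are uniform, unbalanced for sex or session
  order (neither exists in the generator).
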