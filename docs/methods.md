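# Methods

This note documents the models, conventions and numerical choices behind
swimmetrics, in the order data flows through the pipeline.

## Coordinates, files and binning

All geometry lives in an arena-local frame: millimetres, origin at the
arena centre, y increasing upward. Tracking files are self-describing CSVs
with `#` metadata lines (format, units, subject roster); `cm`/`m` and
`ms`/`min` declarations are converted on read, unknown units are rejected.
Per subject, time must be strictly increasing and the sampling period
constant up to a relative tolerance of 1e-3 (dropout gaps that are
near-integer multiples of the base period are allowed). Gaps up to 0.2 s
are linearly interpolated; longer gaps start a new trajectory segment and
are logged, and step-based quantities never bridge segments.

Binning attributes each step's full length to the half-open bin
`[t_start, t_start + dt)` containing the step's *start* time. This is
deterministic and conserves total path length exactly for any bin width.
The same start-point rule attributes steps and inter-sample intervals to
zones, so per-zone times sum to the observed duration and per-zone
distances to the path length (to float round-off); the price is a one-step
attribution error at zone crossings, which vanishes at 25 Hz sampling.

## Arenas and zones

- **Circular well** (larval assays; default radius 8 mm for a 24-well
  plate): inner circle of radius R/√2 gives center/outer zones of exactly
  equal area — the unique analytic solution to the equal-area split.
- **Open tank** (adult open field, default 300 × 300 mm): a peripheral wall
  band of thickness `band_fraction × min(width, height)`. The default
  band_fraction `(1 − 1/√2)/2 ≈ 0.1464` makes the peripheral and center
  areas equal, mirroring the larval convention; it is configurable because
  the band used in adult studies is rarely reported.
- **Three-chamber tank** (default 210 × 110 mm, chambers at thirds): the
  subject's domain is the middle chamber. Each divider has an abutting
  sector of depth `sector_fraction ×` middle-chamber length; the default
  0.5 bisects the chamber into two sectors with no neutral strip, matching
  two-sector scoring in which the SPI denominator is "both sectors".
  Smaller fractions insert a neutral zone.

Points outside an arena by at most 0.5 mm (tracker jitter) are clamped to
the boundary; anything further is a data error naming the sample.

## Protocols and stimulus windows

Protocols are contiguous phases (illumination, sound, drug) plus stimulus
onsets that must coincide with phase starts. Presets encode the assay
schedules: larval light/dark (45 min habituation, 5 min light L0 / dark D1 /
light L1), ASR and VMR (60 min adaptation, then three cycles of 5 min
conditioning + 15 s stimulus), and the PTZ challenge (5 min acclimation +
45 min spontaneous under light, then 5 min light / 5 min dark). The
light-to-dark VMR variant leaves the dark-phase duration configurable
(default 300 s) since only the first 15 s enter the response. Builders take
explicit durations throughout rather than hard-coding a total test length.

Stimulus-locked analysis uses `mean(post) − mean(pre)` on 1-s bins with a
60 s pre window and 15 s post window (ASR, VMR) or symmetric 60 s windows
(PTZ). Pre windows are clipped at the recording start and flagged when
shortened. The habituation index `(r₁ − r_last)/r₁` is this package's
scalar summary of response decline; the per-stimulus paired pre/post tests
are also produced, and the index is undefined (NaN) when the first response
is not positive. All undefined metrics propagate as NaN, never as 0.

## Stereotypy detectors

The source studies scored "small circling" and "walling" by a blinded human
rater from trajectory plots; swimmetrics replaces the rater with explicit,
configurable rules, which is a deliberate divergence in exchange for
reproducibility.

- **Small circling**: per-step headings (steps below a 0.05 mm noise floor
  inherit the previous heading) give a signed cumulative turn. A segment
  qualifies when its *net* turn reaches 330° within at most 3 s while its
  points fit in a bounding circle of diameter ≤ one sixth of the tank's
  smaller side; the shortest qualifying segment from each start is tested
  so brief loops flanked by fast swimming are found. Net (signed) turn is
  used rather than summed absolute turn because heading jitter otherwise
  accumulates without real rotation. Overlapping detections merge into
  episodes; an episode with total turn T yields `1 + floor((T − 330°)/360°)`
  events (one per full revolution, absorbing the ~2 steps of turn lost to
  discretization at the episode edges). The bounding diameter is estimated
  as twice the maximum distance from the segment centroid — exact for
  circles and cheap.
- **Walling**: a maximal interval ≥ 2 s spent within the walling band while
  moving at ≥ 5 mm/s, with sub-0.5 s interruptions bridged. The walling
  band defaults to 12 mm (about one adult body depth) rather than the full
  thigmotaxis band: ordinary peripheral swimming occupies the wall *zone*
  without pressing against the wall, and using the full band lets it
  swamp the count. Speeds are centred two-step estimates, making both
  detectors invariant under time reversal.

## Group statistics

Unpaired comparisons use the classical pooled-variance Student statistic
(the studies say "Student's t test", not Welch; Welch is an option), paired
comparisons the difference-based paired t, and ordinal comparisons the
Mann–Whitney U with midranks. The Mann–Whitney p is exact (scipy's
enumeration) when n_x + n_y ≤ 16 without ties, otherwise the normal
approximation with tie and continuity correction. One-tailed directions are
never inferred from the data — each hypothesis declares its direction, and
results carry both one- and two-sided p-values plus the observed effect
direction. Zero-variance inputs return a degenerate flag rather than a
statistic. The tests delegate the numerics to scipy.stats; the test suite
checks them against closed forms and full enumeration independently.

`delta_ct` implements relative expression `2^(−ΔCt)` with an optional
calibrator for `2^(−ΔΔCt)`.

## The simulator

Each subject is an independent discrete-time agent at 25 Hz (the acquisition
rate of the emulated trackers). Per step:

1. heading gains a wrapped-normal increment (`turning_sd`, default 14°/step,
   making swim paths persistent over ~1 s yet diffusive at arena scale);
2. steering: outside the wall band the heading relaxes toward the nearest
   wall at rate `wall_attraction` (1/s, decaying with distance over a
   quarter of the arena half-size); inside the band it aligns with the
   nearer wall tangent, and below a 20 mm standoff it steers away — fish
   follow walls, they do not grind into them. In the three-chamber tank a
   constant relaxation `social_attraction` pulls toward the stimulus-side
   divider;
3. speed is `base_speed × gain(t)` with mean-corrected lognormal jitter
   (`speed_cv`), so the realized mean speed equals `base_speed` when gains
   are 1; positions advance and reflect off boundaries (mirror reflection,
   heading following the realized displacement).

Two transient states interrupt the walk at Poisson rates: **circling**
(150°/s at 0.6 × base speed for 3.5 s — a tight loop the circle detector
sees) and **walling** (6 s riding an 8 mm rail along the wall at base
speed). Stimulus kernels multiply speed by `light_onset_gain` (τ = 10 s) or
`dark_onset_gain` (τ = 30 s) after illumination transitions, and add a
startle burst `startle_gain × base_speed × habituation_factor^(k−1)`
(τ = 3 s) at the k-th noise onset. PTZ at concentration c (mM) suppresses
the dark-onset gain by `exp(−0.3 c)` while adding a seizure-like drive
`ptz_sensitivity × c` plus burst noise — a purely phenomenological model of
the drug's behavioral signature.

Determinism: one global seed; each subject's stream comes from
`SeedSequence([seed, sha256(subject_id) mod 2³¹])`, so a subject's
trajectory is independent of cohort size and ordering, and identical specs
reproduce bit-identical datasets.

### Genotype presets

`default_presets()` encodes the wild-type vs mutant contrasts of the adult
and sensory assays: the mutant is faster (58 vs 45 mm/s), less
wall-attracted (0.25 vs 0.9 /s), socially indifferent (0 vs 0.8 /s),
circles and walls more (1.5 vs 0.2 and 1.5 vs 0.3 episodes/min), lacks
light-onset hypoactivity (gain 1.15 vs 0.2), startles harder with weaker
habituation (gain 6 vs 3, h = 0.9 vs 0.45) and is far more PTZ-sensitive
(0.25 vs 0.02 /mM). Magnitudes are tuned for detectability at n = 20 per
group, not fitted to the source data — the studies report only p-values and
group sizes, so real effect sizes are unrecoverable.

Larval and adult thigmotaxis run in opposite directions in the emulated
phenotype (mutant larvae hug the wall more; mutant adults less). A single
`wall_attraction` cannot express both, so the larval light/dark assay uses
`larval_ld_presets()`, which swaps the wall-attraction ordering and keeps
everything else; larval assays also scale speeds by 0.1.

### What the generator does and does not emulate

It reproduces the structure the metrics consume: bounded 2-D paths at
25 Hz, zone occupancy biases, stimulus-locked speed changes, habituating
startles and drug-modulated transition responses, with subject-level
variability from independent random streams. It does not emulate burst/glide
micro-kinematics, tail-beat structure, inter-individual trait correlations
across assays, tracking noise or dropouts (clean trajectories), 3-D motion
or any neural/pharmacological mechanism. Passing tests therefore certify
the *analysis* — geometry, windowing, statistics, detectors — on data with
the assumed structure; they do not certify that real mutants behave like
the presets.

## Problem sizes

The analysis windows are what carry signal, so tests, examples and the
acceptance script keep every analyzed phase at protocol duration but
shorten the signal-free habituation/adaptation periods to 60–120 s and trim
the 30 min open-field/social recordings to ~10 min, with n = 20 per group
for the effect-direction harness. These desk-scale sizes are the package's
demo defaults (`DESK_SCALE_ASSAYS`); the full schedules remain the preset
defaults.

## Known limitations

- Stereotypy thresholds are heuristic stand-ins for human scoring; absolute
  counts include wall-adjacent false positives and are only meaningful
  within a fixed parameterization (group contrasts, not rates).
- The equal-area adult wall band and the bisected three-chamber sectors are
  conventions chosen here; studies vary and both are configurable.
- The Mann–Whitney "exact" path requires tie-free data; tied small samples
  fall back to the corrected normal approximation.
- Multiple-testing correction is out of scope by design (the emulated
  analyses apply none); interpret the per-comparison p-values accordingly.
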