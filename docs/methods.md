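# Methods

This note documents the models, estimators and numerical choices behind
`unwindkit`, in the spirit of a methods section: what is assumed, what the
defaults mean, and where the procedures reach their limits.

## The ensemble kinetic model

Single-turnover bulk unwinding is modelled as `m` sequential
rate-limiting steps, each exponential with observed rate constant
`k_obs`, giving an Erlang(m, k_obs) completion-time law and an unwound
fraction `f_ss(t) = P(m, k_obs·t)` (regularised lower incomplete gamma
function — numerically stable for any `m`, unlike the explicit partial
sum). `m` is always fixed by the caller, never fitted: an integer step
count is not identifiable from a single noisy curve, and residuals of
fits with different `m` are not comparable (use AIC across a family of
fits if model selection is genuinely needed). The default `m = 2`
reproduces the lag phase seen in single-turnover curves.

**Normalisation.** Raw fluorescence curves are mapped to the model's 0–1
scale by fitting `signal = B + A·f_ss(t; k_obs, m)` with amplitude `A`,
baseline `B` and `k_obs` free (Levenberg–Marquardt via lmfit; `k_obs`
initialised from the half-rise time, `A` from the signal span). Min–max
scaling was rejected because it inherits the bias of noise extremes.
Degenerate (flat) curves raise an error rather than fit silently. The
loss is ordinary least squares — no error model is assumed for the plate
reader — with an optional Huber loss flag for outlier-prone data.

**Delay.** The slow-down caused by a barrier is the difference of t50
values (linearly interpolated first upward crossing of 0.5 on the
normalized curves). This definition is model-light, recovers a pure time
shift exactly, and is antisymmetric by construction. The alternative —
difference of fitted `m/k_obs` means — is not the default because a
barrier distorts the curve *shape*, and forcing the m-step model onto a
distorted curve propagates specification error into the delay. For the
same reason the bootstrap resamples residuals about a 5-point
running-median smooth of each curve rather than about the fitted model.
When handing pre-normalized curves to `estimate_delay` (or the CLI with
`--normalized`), the model fit is skipped entirely; feeding *raw*
barrier-distorted curves through model-based normalisation can bias t50
by a few percent of the time axis, which is the main caveat of the
estimator.

## The simulator

The generator reproduces the statistical structure of a surface-tethered
single-molecule unwinding assay: a 2.7-kb substrate, 10-s frame interval,
40-min acquisition, read-out proportional to unwound base pairs
(fluorescent ssDNA-binding protein on both exposed strands), a
multiplicative intensity drop at completion (release of the strand not
coupled to the surface; depth `drop_factor` = 0.5 by default — the true
depth is not constrained by data, only its existence), and additive
per-frame Gaussian noise of SD 2% of full scale.

* **Rates.** Per-molecule rates are drawn once per molecule from a
  truncated normal (floor 0.5 bp/s) whose parent parameters are solved so
  the *realised* distribution has the configured mean and SD
  (8.2 ± 4.2 bp/s by default) — the simplest law matching the first two
  moments. Within a molecule the rate is constant; between frames the
  helicase advances deterministically (`stepping="continuous"`). At 10-s
  framing a molecule moves ~80 bp per frame, so single-bp stochasticity
  is unresolvable; a `stepping="gillespie"` mode (exponential per-bp
  waiting times) exists to verify that the continuous approximation is
  immaterial, and a property test does exactly that.
* **Barriers.** A `BarrierSpec` is an arrest (leading strand: permanent
  halt), a pause (lagging strand, duplex-stabilising: exponential dwell,
  then resumption at the pre-pause rate — post-block rates are
  experimentally indistinguishable from unadducted ones), or transparent
  (lagging strand: no effect). `occupancy` is the fraction of molecules
  actually carrying the block (crosslinking is incomplete; 0.8 is the
  default for the leading-strand block). During a pause the rate is
  exactly zero.
* **Pausing probability.** The observed discernible-pausing fraction
  (26%) counts only pauses longer than the 30-s detection threshold, so
  the generator's latent pausing probability is
  `0.26 / exp(−30 s / 4.63 min) ≈ 0.29`. Whether the observed fraction
  reflects occupancy, pause penetrance, or both is not experimentally
  resolved; the generator exposes `occupancy` and `pause_probability`
  separately (defaults 1.0 and 0.29) without claiming to resolve it.
* **Reproducibility.** All randomness derives from one seed;
  per-molecule sub-streams are split per purpose (rate / barrier /
  noise), which makes a transparent-barrier trace bit-identical to its
  no-barrier counterpart and keeps batches reproducible byte for byte.
* **Ensembles.** Ensemble curves draw completion times from the
  Erlang(m, k_obs) law (plus pause dwells for pausing molecules; infinity
  for arrested ones) and report the completed fraction per frame. With no
  barrier and no noise the expectation is exactly `f_ss`, which the DKW
  property test checks at n = 10,000 for m ∈ {1, 2, 3, 5}.

What the generator does **not** emulate: photobleaching and intensity
drift, stage drift, spot-detection errors, RPA-binding kinetics, helicase
loading kinetics, and heterogeneous within-molecule rates. Passing the
recovery tests therefore shows the pipelines are correct under the
modelled noise structure, not that they are immune to every artefact of
real movies.

## Single-molecule pipeline

**Calibration.** Intensities are median-filtered (3 frames) and mapped to
base pairs with one intensity-per-bp scale per imaging batch. Because the
completion drop fires the moment unwinding finishes, there is no pre-drop
plateau to average; the full-substrate intensity is instead obtained by
fitting a short line through the last pre-drop frames (excluding the
final one, whose median-filter window already mixes in the drop) and
evaluating it half a frame before the drop. The batch scale is the median
over completed molecules, which places stalled molecules — which never
reach full length — correctly on the bp axis. Self-calibration of a
single trace works the same way but carries up to half a frame of advance
(~1.5% of substrate length) of quantisation error, since completion is
only localised to one frame.

**Completion.** The drop is called at the earliest post-peak frame where
the filtered intensity has fallen by ≥ 30% of the plateau and stays there
for 3 frames; single-frame spikes are ignored, and absence of a drop is a
censored value, not an error.

**Pause calling.** A pause is a dwell: rate below 1 bp/s sustained for
more than 30 s. The 1 bp/s floor (~12% of the mean rate) separates pauses
from slow molecules given the 8.2 ± 4.2 bp/s population. The caller is a
three-stage threshold segmentation:

1. *Seed* — frames whose 3-frame central-difference rate is below the
   floor (maximally sensitive, deliberately unspecific).
2. *Refine* — around each seed run, the pause level (median bp of the
   seeds) is expanded frame-by-frame while the trajectory stays within a
   noise-scaled band of the level; overlapping intervals merge. The
   reported span uses a half-step membership band plus the midpoint
   convention (half a frame per side), so a clean flat segment of
   duration d is reported as d.
3. *Validate* — the interval must (a) exceed the 30-s threshold,
   (b) be followed by ≥ 100 bp of further advance (terminal plateaus of
   stalled or completed traces are never pauses), (c) have a robust
   (Theil–Sen, interior-trimmed) dwell slope below twice the floor, and
   (d) pass a flank-offset test: lines fitted to the trajectory just
   before and after the candidate must be vertically offset by at least
   the advance a half-dwell pause would have cost, plus 1.64 (2.0 for
   short candidates) prediction SDs. A genuine pause delays everything
   downstream by its duration; a noise excursion leaves the flanks
   collinear. This is the step that rejects slowly translocating
   molecules, whose dwell time in any position band is long but whose
   flanks carry no time offset.

At 2%-of-full-scale noise one frame of position is uncertain by ~54 bp ≈
50 s of sub-floor drift, so pauses of 30–60 s in slow molecules sit at
the measurement floor. The measured operating point on simulated blocked
batches (n = 420) is: recall ≥ 0.9 for pauses over one minute, ~0.85
over all pauses above the 30-s threshold, precision ≥ 0.9, about 1% of
unadducted traces acquiring a spurious call, and mean position within a
few bp of the block. Detection completeness is therefore
duration-dependent; the suite pins the ≥ 1-min recall and treats the
30–60-s band as best-effort.

**Rates.** Fork rates are least-squares slopes over the advancing region
(2–98% of substrate length). Pause intervals are excised by default, and
each inter-pause segment is fitted separately with slopes combined by
span weights — a single line through the surviving frames would be biased
low because the pause time-shifts the downstream segment. A flag reverts
to averaging straight through the pause.

**Pause durations.** Detected durations are left-truncated at the 30-s
threshold. For an exponential law the excess over the threshold is again
exponential (memorylessness), so the maximum-likelihood mean is the
sample mean minus the threshold, with SE = mean/√n; the correction
vanishes as the threshold goes to zero.

**Classification.** Completion ⇒ `completed` (or `paused_then_completed`);
censored completion with a terminal plateau (rate below the floor over
the last 300 s) inside the ±150-bp barrier window ⇒ `stalled`; anything
else — still advancing at acquisition end, or a plateau away from the
barrier — ⇒ `ambiguous`, counted and reported, never dropped. The 300-s
terminal window is long enough to make floor excursions by correlated
noise negligible while every arrested molecule (barrier hit by 1600 s at
the slowest admissible rate) plateaus at least that long.

## Densitometry

Band tables, not gel images, are the interface (image linearisation and
ROI extraction happen upstream in gel software). Percent unwound is
`100·Σ(numerator − bg)/Σ(denominator − bg)`; background is a scalar per
lane unless a per-band column is supplied — the scalar default is an
assumption, recorded in the output. Negative corrected intensities clip
to zero with a warning. The arithmetic is scale-invariant, and
complementary fractions partition to 100%.

## Recovery experiments and problem sizes

`scripts/acceptance.py` and the mirror tests run six experiments, sized
for tight statistics at interactive runtimes (each completes in seconds
on one core):

* mean fork rate from 500 unadducted traces, observed for 5600 s so that
  even a floor-rate molecule completes — censoring would otherwise
  select against slow molecules and bias the mean upward by several
  percent;
* truncation-corrected exponential fit of 109 simulated pause durations
  (the published event count; SE is ~10% of the mean at that n, which is
  the dominant uncertainty of this quantity);
* discernible-pausing fraction among 420 blocked molecules and stalled
  fraction among 100 leading-strand-block molecules at the default
  40-min acquisition;
* t50 recovery of a 4.09-min shift injected into a noiseless m = 2 curve
  (0–60 min, 5-s sampling);
* mean near-barrier pause position over 100 molecules simulated with
  pause probability 1 (the experiment conditions on pausing molecules).

## Known limitations

* Pauses shorter than ~1 min in molecules slower than ~2.5 bp/s are not
  reliably separable from noise at the default noise level; the caller
  prefers precision over recall there.
* Two pauses closer than the refinement band merge into one event; the
  single-barrier design makes this immaterial here.
* Curve normalisation assumes the m-step shape; heavily distorted curves
  should be normalised externally and passed with `normalized=True`.
* The completion drop depth is a free parameter of the generator; the
  detector only assumes the drop exceeds 30% of the plateau.
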