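# Methods

This note documents the models and scoring rules synapseflux implements, the
design decisions behind them, what the synthetic generators do and do not
emulate, and the numerical conventions that matter when reproducing results.

## ΔF/F normalisation

A trace is normalised per ROI as ΔF/F = (F_t − F0)/F0 with F0 the minimum
fluorescence recorded in that trace. This convention is simple and
monotone-invariant (detection is unchanged by any positive gain applied to
the raw signal), but F0 is an extreme-value statistic: with i.i.d. Gaussian
frame noise of standard deviation σ (in ΔF/F units), the expected depth of
the minimum over n frames is ≈ σ√(2 ln n), so every ΔF/F value is inflated
by a pedestal of roughly σ√(2 ln n)/(1 − σ√(2 ln n)). At σ = 0.02 this is
≈ 5% of baseline for 25-frame epochs and ≈ 11–15% for 150–200-frame traces.
Two practical consequences, both quantified by the recovery studies:

* scored amplitudes are biased upward relative to the *clean* transient
  amplitude by the pedestal (not by detector error — recovery tests therefore
  compare scored amplitudes with ground truth re-expressed through the same
  observed F0, isolating detection error, which is ≲ 0.5%);
* the effective detection threshold above the noise floor is
  0.1 − pedestal, so long traces progressively lose specificity. Analyses
  should use short recording epochs (the generator default is 25 frames,
  ≈ 27 s at 0.92 frames/s) or a per-epoch F0.

Traces containing samples ≤ 0 are rejected (`NonPositiveBaselineError`):
they indicate background-subtracted or clipped input for which a minimum
normalisation is meaningless.

## Event and burst detection

All rules operate on discrete frames; plateaus of exactly equal values
collapse to their first frame. With threshold θ = 0.1 and offset band
β = 0.2 (both ΔF/F, both from the published scoring procedure):

1. candidate peaks are local maxima with ΔF/F > θ;
2. a transient's onset is the first frame of the maximal monotone
   non-decreasing run ending at its first peak (ties extend the walk to the
   earliest frame);
3. scanning forward from a peak, the transient offsets at the first
   falling-phase frame whose ΔF/F is within β of the onset value, or at the
   final frame;
4. peaks with no qualifying offset between them belong to one burst;
5. the scored amplitude is the highest peak of the transient.

A transient still rising at the final frame is closed there and flagged
`truncated`; truncated transients count toward event rates but are excluded
from amplitude means (their peak is unobserved). Adjacent transients may
share the single trough frame that closes one and opens the next; the suite
verifies the detector against an independent frame-by-frame transcription of
these rules on every sequence up to length 8 over a six-value ΔF/F grid.

No smoothing or detrending precedes detection by default (an optional moving
average, `DetectionParams.smooth_window`, is provided but off). Whether
amplitude means pool single events with burst maxima is configurable
(`amplitude_source="all" | "bursts"`); pooling is the default.

## Synthetic traces

`simulate_trace` builds F_t = F0·exp(−λt)·(1 + Σ transients) + F0·ε_t with
ε_t ~ N(0, noise_sd) i.i.d.; bleaching λ defaults to 0. Each transient rises
linearly over `rise_frames` (default 2) to its amplitude and decays
exponentially with `decay_tau_s` (default 0.5 s — fast, matching the
sub-second off-kinetics of the glutamate indicator at ~1 Hz sampling).
Bursts are ≥ 2 overlapping kernels with peaks 2 frames apart and sub-peak
amplitudes floored at 0.45 ΔF/F so the composed inter-peak troughs stay
above the burst-continuity band with several noise standard deviations of
margin; ground truth records the local maxima of each event's noiseless
composed waveform, so truth labels align with detector semantics by
construction. Event counts are Poisson at `event_rate_per_min` (default
6/min) with onsets placed non-overlapping (one transient support plus a
3-frame gap); at high rates the realised count falls below the Poisson draw.
Defaults — short 25-frame epochs, fast decay, amplitude 0.5 ± 0.1, noise
0.02 — were chosen in a design pilot so the detector operates in the regime
the ΔF/F definition supports (see the pedestal analysis above); under these
conditions onset recall ≈ 0.96–0.98 and precision ≈ 0.90–0.94 at a ±2-frame
tolerance across seeds.

Not emulated: photon (shot) noise and 1/f drift, motion artefacts,
indicator saturation, propagating activity waves, and overlapping events —
so a pass on synthetic data demonstrates correctness of the scoring rules,
not robustness to every pathology of real recordings.

## Survival model and tests

`simulate_survival` draws death days from a proportional-hazards Weibull
family: T = scale·(E/HR)^(1/shape), E ~ Exp(1), with shape 4 by default
(sigmoidal, fly-like survivorship; `family="exponential"` available) and
scale 60 days. Hazard ratios act multiplicatively per 2×2 design cell
(genotype, induction, and their interaction; reference levels are the first
labels listed). Days are continuous — real death scoring is discrete
(checks a few times per week) and tied; the log-rank implementation handles
ties with the hypergeometric variance and is exercised on tied toy data, but
calibration studies use the continuous model. Right-censoring is supported
(`censor_day`) and off by default.

The two-group log-rank statistic is (Σ(O−E))²/ΣV with V the hypergeometric
variance at each distinct event time, and p from the χ²(1) upper tail. At
n = 50/group with no censoring its measured type-I error at α = 0.05 is
≈ 0.056 (40 000-replicate estimate) — the known mild liberality of the
χ² approximation at modest samples, shared by standard implementations
(the suite cross-checks statistic and p against lifelines to 1e-9).

The genotype × induction interaction is tested by permutation rather than a
Cox model fit: the observed statistic is s_A − s_B where s_g is the
induced-vs-uninduced log-rank χ² within genotype g, signed positive when
induction is harmful; permuting genotype labels within induction strata
preserves induction main effects while breaking genotype-specific responses.
p = (1 + #{|T_perm| ≥ |T_obs|})/(1 + n_perm) — two-sided, never exactly
zero, exactly calibrated by exchangeability (attainable size 10/201 ≈ 0.0498
at the default study's 200 permutations; the library default is 10 000).
A Cox model with an interaction term is retained in the test suite as an
independent cross-check of direction and significance, not as the
implementation.

## Climbing

PI = 0.5·(N_top + N_mid + N_bot + N_top − N_bot)/N_total, bounded in [0, 1]
and invariant to scaling all bins. Trials are trinomial draws of `n_flies`
(default 50, one trial per timepoint). Genotype comparisons use a
permutation test on mean PI differences at matched timepoints, reshuffling
flies between genotypes within each timepoint by multivariate hypergeometric
draws on the pooled bins — replacing an ordinal regression with a test whose
null is exact under exchangeability.

## Image quantification

Stacks are (slice, row, column), 0-based, non-negative. Registration is
integer-shift only: each slice is aligned to the first by exhaustive search
over |dy|,|dx| ≤ max_shift maximising raw cross-correlation, ties broken
toward the smallest displacement, vacated pixels zero-filled; sub-pixel
registration is out of scope. Background harmonisation subtracts each
image's low-percentile intensity (default 5th, as the nearest-below order
statistic so the operation is exactly idempotent) and clips at 0, giving all
samples background level 0. ROI quantification applies a 2-D mask to every
slice, reporting per-slice masked means and their average (averaging, not
summing, across slices). Masks are inputs; no segmentation is performed.

## Pipeline and reproducibility

Experiment runs derive every unit's seed deterministically from the master
seed via `numpy.random.SeedSequence` spawn keys, write all intermediates as
CSV/JSON to the run directory, and record a provenance block (config, seed,
package version, SHA-256 over the written tables). No timestamps enter run
outputs, so identical config + seed reproduces every file bit for bit. Fewer
than 3 animals per condition triggers an underpowered-design warning.

## Validation study sizes

The shipped studies use: exhaustive detector-rule equivalence on all ΔF/F
sequences of length ≤ 8 over a six-value grid (≈ 2.0 × 10⁶ cases);
200-trace detector recovery; 2000-replicate log-rank null calibration at
n = 50/group; 1000-replicate interaction null and power studies at
n = 150/cell with 200 permutations each; 20-stack registration recovery.
These sizes give Monte-Carlo standard errors comfortably inside the asserted
bands while keeping the default suite runnable on a laptop in minutes.

## Known limitations

* The ΔF/F pedestal makes absolute amplitudes epoch-length dependent;
  compare amplitudes only across traces of equal length.
* Event detection has no deconvolution or spike inference; closely spaced
  events merge per the burst rule rather than being resolved.
* The log-rank χ² approximation is mildly liberal below ~50 events/group;
  for small cohorts prefer the permutation machinery.
* Registration assumes rigid integer translation and a dominant static
  structure; it is not a replacement for dedicated motion-correction tools
  on real movies.
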