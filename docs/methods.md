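# Methods

This note documents the models and procedures implemented in `aukcalls`, the
defaults and why they were chosen, what the synthetic data do and do not
emulate, and the package's known limitations.

## The scientific setting

Little auk chicks produce one call type in two behavioural contexts:
*begging* (in the nest, interacting with a parent) and *handling* (held by a
human; a distress context). The analysis chain asks (i) whether the acoustic
structure of a call predicts its context once repeated measures of the same
individuals are controlled for, (ii) which of seven standard acoustic
parameters carry the context effect and in which direction, and (iii) how
much individual-identity information each context's calls carry. The study
design is strongly unbalanced: 9 nest chicks contributed 1229 calls (26–293
each), 21 handled chicks contributed 206 (many exactly one). Each individual
occurs in exactly one context (a nested design), which dictates most of the
statistical choices below.

## Acoustic feature extraction

Calls are analysed frame-wise: 1024-sample (≈21.3 ms) Hann windows on a 5 ms
hop at 48 kHz. Frames whose RMS falls more than 60 dB below the loudest
frame are excluded from all spectral averaging (the "dynamic range" gate).
Per retained frame:

- **mean f0** — normalised autocorrelation (bias-corrected by `N/(N−lag)`)
  searched at lags corresponding to 800–3500 Hz; local maxima are refined by
  parabolic interpolation (at a non-integer period the integer-lag sample
  underestimates the peak); a frame is voiced when the best peak reaches the
  voicing threshold (default 0.45). Two standard disambiguation steps guard
  against octave errors: a candidate must have spectral energy at its own
  fundamental (default ≥ 5% of the frame's strongest bin within ±2 bins),
  and near-threshold candidates are ranked by harmonic summation (total
  spectral energy at the candidate's first five multiples). The call value
  is the mean over voiced frames; a call with no voiced frame carries a
  missing f0 and is excluded from the statistical tables (with a logged
  count).
- **Q25/Q50/Q75** — frequencies at which the cumulative spectral power
  crosses 25/50/75% of the frame total, linearly interpolated between bins.
- **Wiener entropy** — geometric/arithmetic mean ratio of the power
  spectrum, in [0, 1] (0 = pure tone, 1 = white noise). The spectrum is
  first smoothed with a 9-bin moving average: without it, single-bin
  periodogram fluctuations (exponentially distributed) bias the geometric
  mean down so far that even white noise scores ≈0.56; with a 9-bin average
  the white-noise expectation is ≈0.95.
- **spectral slope** — OLS slope of the max-normalised magnitude spectrum
  against frequency in kHz; more negative = steeper roll-off.

Call values are per-frame means (a pooled-spectrum mode exists behind
`AnalysisSettings.pooled_spectrum`). All features are level-normalised, so
the extractor is gain-invariant by construction. The window length and the
voicing threshold are not dictated by the recording protocol; 1024 samples
resolves ≥2 periods at the 800 Hz pitch floor while keeping ~60 frames on a
0.3 s call, and 0.45 is a conventional autocorrelation voicing bar. Both
are configurable.

## Synthetic data

### Feature tier

The generator draws each of the seven parameters from the same model the
downstream statistics assume:

    value = intercept_handling + offset_begging·[context = begging]
            + b_individual + e_call,
    b ~ N(0, σ²_ind),  e ~ N(0, σ²_res),

with the published per-context means as fixed effects and per-individual
call counts resampled from the published design (options: the exact design,
a fixed count, or counts pooled across contexts — the latter makes
individuals fully exchangeable and is the right null design for
permutation-calibration experiments). Draws are repaired to physical
invariants — the quartile triple is sorted, entropy clipped to [0.01, 0.95]
(a real call never has literally zero or unit entropy), f0 clipped to the
analysis pitch window, duration floored at one analysis window — and every
repair is counted and logged.

The variance components are not published (the study reports fixed-effect
estimates and standard errors only), so defaults were chosen once to give a
plausible individual-signature regime — between-individual SD slightly
below within-individual SD for every parameter (e.g. mean f0: 120 Hz
between, 150 Hz within) — in which the pDFA is clearly but not trivially
separable and Hs sits in the single-digit-bits range. A per-context
multiplier on σ_ind (`sigma_individual_scale`) emulates the published
pattern of handling calls carrying less identity information. All of this
is configurable; none of it is fitted to data.

### Audio tier

Each call is rendered so that the *analyser's own output* approximates the
drawn parameters. The renderer plans a target cumulative-energy curve
through the three quartile targets, with dense "straddle" mass around each
crossing so the analyser's per-frame crossing estimate is stable; density
between the knots is concentrated near harmonics of the target f0
(harmonic sidebands, as in rough/deterministic-chaos vocalisations), and
each harmonic absorbs the density in its neighbourhood, which both
strengthens voicing and pins nearby quartile crossings. Noise components
are rendered as deterministic-magnitude random-phase combs on the
analysis-bin grid: every analysis frame then sees the same magnitude
spectrum, removing the chi-square bin fluctuations of true filtered noise
that otherwise make per-frame quartile crossings bimodal. Entropy is
controlled by a wideband noise floor whose mix fraction is solved by
bisection against the analyser's own entropy computation, and the quartile
plan is iterated against the analyser's own quartile measurement, with each
candidate plan scored by its predicted pitch-period autocorrelation
(computable in closed form from the planned spectrum) so that chasing the
quartiles never silently destroys voicing. Mild vibrato (1%) and 10 ms
cosine edge ramps finish the call; peaks are normalised to 0.9.

**A physical cap on round-trip fidelity.** The feature tier draws the seven
parameters independently, so a drawn combination can demand a spectrum no
voiced call possesses: whenever the quartile targets put a substantial
share (≳25%) of spectral energy in bands near odd half-multiples of f0 —
common for handling-like draws whose Q50 lands near 0.5·f0 — the attainable
normalised autocorrelation at the pitch period is capped below the voicing
threshold, and the analyser (correctly) reports the call as unvoiced. On
the default design mix this caps all-parameter round-trip recovery at
roughly 70–80% of calls (begging ≈85–90%, handling ≈10–20%), with duration
and entropy essentially always recovered and f0/quartiles carrying the
failures. `analysis/02_roundtrip_validation.py` tabulates this per call.
Consequences for interpretation: audio-tier datasets are a faithful
test-bed for the extractor on *acoustically coherent* calls, but the
unvoiced tail means audio-tier statistics see a censored version of the
latent model; the statistical validation therefore runs on the feature
tier, where the generating model is exact.

What the synthetic data do not emulate: call ontogeny (real begging calls
change as chicks grow), frequency-modulation contours beyond mild vibrato,
microphone/burrow transfer functions, background colony noise, and any
correlation structure among the seven parameters beyond what the shared
individual intercepts induce. Passing tests on these data show the
*statistics* are correct under the assumed model, not that the model
captures every property of field recordings.

## Nested permuted DFA

For each (real or permuted) labelling, the same number of calls per
individual (default: the minimum count across individuals, so nobody is
excluded) enters the derivation set of a two-class linear discriminant
(pooled covariance, priors proportional to derivation class sizes); the
remaining calls form the validation set. The observed statistics —
% correctly classified (derivation) and % correctly cross-classified
(validation) — are averaged over 100 random balanced selections. The null
distribution reassigns context labels to whole individuals uniformly among
assignments preserving the per-context individual counts (1000 permutations
by default); chance levels are the null means, and
p = (1 + #{null ≥ observed}) / (n_perm + 1), so p is never zero and the
identity permutation is a legal tie.

Two calibration-relevant choices, both verified by simulation:

- **Permutations use the same number of selections as the observed
  statistic.** Averaging the observed statistic over 100 selections while
  giving null draws a single selection makes the null distribution strictly
  wider than the observed one and the test severely conservative (measured
  null rejection rate 0 at α = 0.05). With matched statistics the test is
  calibrated (measured 0.03–0.05 across 100 null datasets). The closed-form
  LDA fit (~0.2 ms) makes the matched default cheap.
- **Calibration checks need an exchangeable null.** If call counts are
  resampled per context (begging individuals get begging-scale counts), the
  count pattern itself carries the label even when the features are null,
  exchangeability fails, and the permutation test is conservative
  regardless of the statistic. The pooled count model exists for exactly
  this purpose.

The priors-from-class-sizes choice is what makes the chance level sit far
above 50% on unbalanced designs, matching how such analyses report chance.
Crossed designs (individuals in both contexts) are rejected explicitly.

## Mixed models

One model per parameter: context fixed (handling is the reference level, so
the intercept is the handling mean), individual random intercept, Gaussian
residual. Because each individual appears in one context, a random context
slope is inestimable, so only intercepts are fitted. Mean entropy is the
one transformed response, `log(x + 1 − min x)` over the dataset (minimum
maps to 0, order preserved); the other parameters are modelled raw.

The fitter profiles the likelihood to a one-dimensional bounded search over
the variance ratio σ²_ind/σ²_res (per-group Woodbury identities; REML for
reported estimates, ML for likelihood ratios). It matches statsmodels
`MixedLM` to ~0.1% on estimates and to 4 decimals on ML log-likelihood
(asserted in the tests), and a fit costs well under a millisecond — which
is what makes the parametric bootstrap practical: the context p-value is
obtained by simulating responses from the fitted null model (random
intercepts and residuals included), refitting both models, and counting
bootstrap LRTs at least as large as the observed one, with the +1
convention (default 1000 bootstraps; measured null rejection rate 0.075
with a binomial 95% interval of [0.020, 0.080] at 200 replicates × 200
bootstraps). Bootstrap refit failures are dropped and counted; more than
10% failures aborts. Q-Q diagnostics (ordered residuals vs normal
quantiles, summary correlation) are descriptive only.

## Individuality

Per context, individuals with at least five calls contribute five randomly
selected calls (seeded). KMO sampling adequacy is computed from the
anti-image partial correlations (the two-variable case equals 0.5 exactly,
a useful unit check); a correlation-matrix PCA retains all components; each
component's one-way ANOVA across individuals yields F, and the information
content is `½·log₂ F` bits, floored at zero when F < 1 — information cannot
be negative, and the significant-only variant (components with ANOVA
p < 0.05) already handles weak components. `Hs(all)` sums all components,
`Hs(significant)` the significant ones, and `floor(2^Hs)` (minimum 1) is
the approximate number of distinguishable individuals — 5.26 bits ↦ 38
individuals, 1.11 bits ↦ 2. A raw-feature mode (ANOVAs on standardised
features instead of components) exists for sensitivity analysis. `Hs` is
verified against a brute-force sums-of-squares ANOVA to 1e-9 and is
monotone in the generator's between-individual SD.

The seven extracted parameters yield seven components; reports of this
statistic sometimes involve larger descriptor sets, so absolute Hs values
are comparable only for matching variable counts.

## Pipeline, seeds, problem sizes

`run_full_analysis` chains simulate/ingest → extract → pDFA → mixed models
→ per-context individuality, writing a feature CSV, three result tables and
a schema-validated JSON report. One master seed derives every stage seed
via `SeedSequence(master, stage_index)` (values kept below 2³¹), so a
config file reproduces a run bit-for-bit; log verbosity never affects
numbers. Stage failures halt with the stage name and leave a MANIFEST of
completed stages.

Simulation experiments in the test suite use desk-scale sizes chosen for
stable pass/fail behaviour at minute-scale runtimes: 100 null datasets ×
200 permutations for pDFA calibration, 20 datasets for power, 200
replicates × 200 bootstraps for the mixed-model null, 50 replicates for
coverage, ~250 rendered calls for the round trip. The acceptance script
runs the full simulated analysis at the published design size (~1400–1900
calls) with 1000 permutations and 500 bootstraps.

## Known limitations

- The audio tier's round-trip fidelity is capped by the independence of the
  latent draws (see above); handling-like geometries are frequently
  unvoiceable, and those calls lose f0.
- The pDFA implements the nested design only; crossed designs and more than
  two contexts are rejected or untested.
- Spectral slope units follow the max-normalised-magnitude definition here;
  published slope values from other analysers are not directly comparable,
  and the audio tier treats slope as emergent (it is not a synthesis
  target).
- The permutation test's validity argument conditions on the observed call
  counts; when counts are informative about the label (as in the real
  design), the test is conservative rather than exact.
- No call detection/segmentation: annotations are required input; stereo
  audio is collapsed by channel selection.
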