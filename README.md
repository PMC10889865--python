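# aukcalls

Do the calls of little auk (*Alle alle*) chicks encode the behavioural
context in which they are produced — begging in the nest with a parent
(putatively positive valence) versus being handled by a human (distress)?
And do the two contexts carry different amounts of individual identity
information?

`aukcalls` is a tested, reusable implementation of the full analysis chain
for this kind of two-context, individual-structured bioacoustic dataset,
aimed at behavioural ecologists and bioacousticians:

- **acoustic feature extraction** of the seven standard affect parameters —
  duration, mean fundamental frequency (autocorrelation pitch tracking in a
  800–3500 Hz window), energy quartiles Q25/Q50/Q75, spectral slope, and
  Wiener entropy — from WAV audio with Raven-style selection tables
  (48 kHz, 60 dB dynamic range, 5 ms step);
- **nested permuted discriminant function analysis (pDFA)**: a linear
  discriminant of context on the call features whose significance comes from
  permuting context labels across *whole individuals* (each individual
  occurs in one context), with balanced call selections per individual —
  robust to repeated measures and the severely unbalanced design;
- **per-parameter linear mixed models** (context fixed, chick identity
  random, entropy log-transformed as `log(x + 1 − min x)`) with
  parametric-bootstrap likelihood-ratio p-values;
- **individuality quantification**: Kaiser–Meyer–Olkin sampling adequacy,
  correlation-matrix PCA, and Beecher's information statistic
  `Hs = Σ_j max(0, ½·log₂ F_j)` over the orthogonalised components, where
  `F_j` is the one-way ANOVA F ratio across individuals; `2^Hs` approximates
  the number of individuals the signal can distinguish;
- a **two-tier synthetic call generator** that emulates the study design
  (9 begging / 21 handling individuals, per-individual call counts resampled
  from the published table, published per-context feature means): tier
  *feature* draws the parameters directly from the assumed mixed-effects
  model, tier *audio* renders each call as a waveform whose re-extracted
  features recover the drawn parameters — an end-to-end oracle for the
  extractor.

## Worked example

The numbered scripts under `analysis/` run the whole study shape on
synthetic data (synthetic because the original recordings are not public):

```bash
python analysis/01_simulate_dataset.py   # design + features (+ audio demo)
python analysis/03_context_pdfa.py       # nested pDFA
python analysis/04_context_lmms.py       # mixed models
python analysis/05_individuality.py      # KMO + PCA + Hs per context
```

On the default dataset (seed 1, 1728 calls from 30 individuals) this prints:

```
Correctly cross-classified (%)         99.89
Chance level for cross-classified (%)  69.21
P value for cross-classified           0.0010
```

— calls are assigned to their context far above the permutation chance
level, and the mixed models recover the generating effect pattern:

```
Parameter                  begging  handling   SE(b)   SE(h)  p(boot)  Interpretation
duration_s                  -0.024     0.335   0.028   0.018   0.4056  no effect
mean_f0_hz                -339.134  1856.797  51.969  32.813   0.0010  increase during handling
q25_hz                     869.628   576.609  76.532  48.196   0.0010  decrease during handling
q50_hz                     646.354  1530.455 118.421  72.521   0.0010  decrease during handling
q75_hz                     -74.319  3546.396 159.735 100.788   0.6523  no effect
spectral_slope_per_khz      -1.740    -1.251   0.127   0.077   0.0010  less steep during handling
mean_entropy*               -0.118     0.162   0.013   0.008   0.0010  increase during handling
```

Handling calls have higher pitch and entropy, lower spectral quartiles and a
shallower slope, while duration and Q75 show no effect — the same five-of-
seven significance pattern the generator was parameterised to produce.
`analysis/05_individuality.py` then reports per-context KMO, Hs in bits and
the implied number of distinguishable individuals; lowering the
between-individual variance for one context
(`SimConfig(sigma_individual_scale={"handling": 0.3})`) reproduces the
"distress calls lose identity information" pattern.

Everything is also scriptable through the CLI (`aukcalls simulate|extract|
pdfa|lmm|individuality|run`) or the `run_full_analysis` pipeline, which
writes a versioned JSON report plus the three result tables from one config
and one master seed.

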