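# Methods

`nldeeg` implements an EEG biomarker-discovery pipeline for predicting a
binary developmental outcome (positive = later diagnosis) from infant EEG
recorded during a passive phoneme-oddball task, together with a synthetic
cohort generator that reproduces the data structure end to end. This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic results do and do not establish.

## Pipeline overview

1. **Segmentation.** Only EEG during the frequent "standard" phoneme is
   analyzed. The longest run of consecutive standard trials is located from
   the event annotations (runs ranked by trial count, ties to the earliest;
   a run's span ends at its last onset + 0.3 s stimulus + the realized ISI,
   falling back to the maximum ISI of 1.2 s when per-trial ISIs are
   unknown). The centered 20-s window — start `t0 + (span − 20)/2`, rounded
   to the nearest sample, half-open sample interval of exactly
   `round(20·fs)` samples — is sliced identically from all channels.
   Subjects whose longest run is shorter than the window are excluded and
   logged, not errored.
2. **Decomposition.** Each channel is decomposed with a 6-level orthogonal
   DWT (Daubechies-4, symmetric extension; both config-exposed). Each
   detail level is inverted on its own to a full-length band signal; the
   <2 Hz approximation is discarded. Nominal dyadic edges at 250 Hz are
   125–62.5, …, 3.9–1.95 Hz; printed labels follow the acquisition filters
   (1 Hz high-pass, 100 Hz low-pass), so the outer bands read 62.5–100 and
   1–3.9 Hz. Coarse-graining (non-overlapping block means, trailing
   remainder dropped) is applied to the *broadband* segment at scales 2–6
   with factors 2^(s−1) — the only factor map consistent with labels such
   as "1–31.2 Hz (scale 3)" and "1–15.6 Hz (scale 4)" at 250 Hz.
3. **Measures.** Twelve per-band measures — relative power plus 11
   nonlinear measures — and sample entropy of the coarse-grained series at
   scales 2–6 (MSE), giving 12·6 + 5 = 77 features per channel and
   18 × 77 = 1386 for the full montage.
4. **Evaluation.** Nested leave-one-out cross-validation: inside every
   training fold, features are z-scored with training-fold statistics and
   the selector picks k = 20 features; the classifier is fit and the
   held-out subject predicted. Metrics: accuracy, sensitivity, specificity,
   PPV, NPV (0/0 ratios reported missing, never 0). Significance by
   permutation: labels shuffled per iteration, each fold's feature set
   frozen to its true-label selection, classifiers refit; z-score of the
   observed accuracy against the null plus the +1-corrected empirical p.
5. **Characterization.** Fold selections collated by channel, measure and
   band: average count per iteration (total / n_iterations — per axis these
   sum to exactly k) and percentage of iterations with ≥1 selection; the 20
   most frequently selected features are compared between groups with
   independent pooled-variance t tests at the Bonferroni threshold
   0.05/20 = 0.0025.

## Synthetic cohort model

Each channel of a subject's recording is an independent sum of

- six band-limited Gaussian noises: white noise filtered with an order-4
  zero-phase Butterworth at the band edges, standardized, scaled by
  amplitude `a_b · s_b(group) · exp(ε)`, where `a_b` falls off with
  frequency (1.0 → 0.25 from the 1–3.9 to the 62.5–100 Hz band), `s_b` is
  the injected multiplicative group shift (1 for the negative group) and
  `ε ~ N(0, 0.2²)` is per-subject log-amplitude jitter — the dominant
  between-subject variance;
- a 1/f^β background (spectrally shaped white noise, standardized,
  amplitude 0.5, β = 1 plus the group's slope shift);
- optionally a chaotic component: the logistic map `x → 4x(1−x)`
  (Lyapunov exponent ln 2), standardized and low-passed at 30 Hz, mixed
  with a per-group weight — this is how "complexity" differences are
  injected deliberately;
- white observation noise (SD 0.2).

Events: 0.3-s stimuli with ISIs uniform on [1.0, 1.2] s, deviant
probability 0.2, and a guaranteed ≥25-s standard run (a contiguous block is
relabeled at a random admissible position when needed — without it a 0.2
deviant rate would leave many subjects without a 20-s window, mirroring the
original design's selection of usable subjects rather than their
exclusion). Determinism: subject seeds fan out as
`SeedSequence([cohort_seed, subject_index])`; identical specs give
byte-identical serialized cohorts.

**Effect-size targeting.** For a band-amplitude shift the expected
relative-power difference has a closed first-order form: with per-band
variance fractions `q_b = v_b / v_total`, the delta method propagates the
log-amplitude jitter and the finite-window estimation noise
(2·bandwidth·duration degrees of freedom) into

`Var(rp_b) ≈ 4σ_j² [ q_b²(1−rp_b)² + rp_b² Σ_{k≠b} q_k² ] + (rp_b(1−rp_b))²·2/n_eff`,

from which a targeted Cohen's d follows. Monte-Carlo d over many simulated
subjects agrees with this target to within ±0.2 (the residual gap comes
from DWT band leakage, which the analytic form ignores).

**What the generator does not emulate:** ERP morphology and evoked
responses, artifacts (blinks, line noise, movement), inter-channel
correlation and volume conduction, non-stationarity within a recording,
and any calibration to the original cohort's amplitudes (the source study
deposits no raw data). Passing tests therefore establish that the
*pipeline* recovers injected effects and is calibrated under the null —
not that real infant EEG carries such effects.

## Measure battery: definitions and defaults

All entropies use base-2 logarithms (consistent with permutation-entropy
values printed near the log2(3!) = 2.585 ceiling). All parameters are
config-exposed on `MeasureConfig`; none were printed in the source
analysis, so defaults follow the conventions of the packages it cites.

| Measure | Definition / estimator | Defaults |
|---|---|---|
| Power | var(band) / var(broadband segment) — relative power; printed power values of 0.01–0.11 are dimensionless fractions (absolute variance by flag) | — |
| SampE | −log2(A/B), templates m and m+1, Chebyshev matches ≤ r, self-matches excluded | m = 2, r = 0.2·SD |
| AppE | Pincus Φ_m − Φ_{m+1}, self-matches included | m = 2, r = 0.2·SD |
| PermE | Shannon entropy of ordinal patterns, unnormalized; ties by stable argsort (order of appearance) | order 3, delay 1 |
| SpecE | entropy of the Welch PSD / log2(#bins), in [0, 1] | nperseg 256 |
| SVDE | entropy of normalized singular values of the delay-embedding matrix | dim 10, delay 1 |
| HFD | Higuchi curve-length regression | kmax = 8 |
| KFD | log10 n / (log10 n + log10 d/L), amplitude path length | — |
| LZC | LZ76 phrase count c(n)·log2(n)/n on the median-binarized series | — |
| DFA | slope of log F(s) vs log s, integrated profile, linear detrend | 16 log-spaced sizes in [4, N/4] |
| HurstE | rescaled range with Anis–Lloyd–Peters small-sample correction | 12 sizes in [16, N/4] |
| LyapE | Rosenstein: delay embedding, Theiler window = one mean period, slope of mean log divergence (nats/sample) | dim 5, lag = 1/e ACF decay |
| MSE | SampE of the coarse-grained broadband series, factor 2^(s−1) | scales 2–6 |

Numerical choices worth recording:

- **Template matching** uses KD-trees (Chebyshev metric) and the first
  N−m windows at both template lengths; brute-force O(n²) oracles in the
  test suite agree to 1e−9. Degenerate cases: constant input → 0 with a
  warning (a flat sub-band must not abort a cohort run); B = 0 → 0;
  A = 0 → capped at log2 B.
- **Lyapunov.** Embedding dimension 5 and a 1/e-decorrelation lag. On the
  r = 4 logistic map — the analytic benchmark, λ = ln 2 — dimension 10
  over-embeds the one-dimensional map: nearest-neighbor distances grow to
  within ~3 e-foldings of the attractor diameter and the pre-saturation
  scaling region becomes too short (slope ≈ 0.61). A zero-crossing lag
  rule returns lag 2 on delta-correlated series and breaks step parity.
  With dim 5 / lag 1 the estimate is 0.667–0.686 across initial
  conditions. The fit excludes t = 0 (a biased minimum by construction of
  nearest-neighbor selection) and stops two e-foldings below the attractor
  scale (mean log distance of random embedded pairs); divergence is
  averaged over ≤1500 anchor points, which bounds the neighbor-query cost
  on long low-frequency series without changing the statistic.
- **LZ76** phrase parsing is the longest-reproducible-prefix formulation
  (overlapping sources allowed), verified identical to the
  Kaspar–Schuster index-walking algorithm on random sequences. With the
  c(n)log2(n)/n normalization a random binary sequence → 1.0; printed LZC
  values near 1.55 suggest the original used a different normalization,
  which remains unresolved — the convention here is internally consistent
  and is what the tests pin down.
- **Hurst** without the Anis–Lloyd correction overestimates H on short
  blocks; with it, white noise gives 0.5 ± 0.02 at n = 10⁴.
- **F-test selector:** 0/0 (constant feature) ranks last, x/0 (perfect
  separation) first; for two groups F = t², so its ranking provably equals
  the |Pearson| ranking (tested). **RFE** eliminates 10% of features per
  step with a linear SVM and picks the retained size ≤ k by inner
  stratified 3-fold CV; ties prefer the larger size, keeping the full
  selection budget rather than collapsing to one feature.
- **kNN** uses k = floor(√N_total) fixed from the full sample size before
  cross-validation (7 at N = 54, 8 at N = 67), not the training-fold size.
- **Permutation scheme:** the frozen-selection design is the default; a
  fully re-selected variant (selection repeated on shuffled labels) is
  available behind `refit_selection=True` for methodological comparison.
- **t tests** on top features are independent pooled-variance Student's t
  (the two outcome groups are independent and of unequal size; a paired
  design is incoherent here), Welch by flag.

## Problem sizes used by tests, drivers and the acceptance script

The full design (18 channels, ~700-s recordings, 54 or 67 subjects,
1386 features) costs hours of CPU for the measure battery alone, so the
shipped runs use demonstration conditions that preserve the study's
subject counts and class imbalance while trimming the montage and
recording length — a problem-size choice of this package:

- **Strong-effect recovery:** 14 vs 40 subjects, channels F7 + C3, 90-s
  recordings, full 154-feature battery; Pearson(k=20)+RBF-SVM nested LOOCV
  reaches accuracy 0.96–1.0 with permutation z ≈ 14–20 at 200 shuffles.
- **Null calibration:** 20 cohorts of 5 vs 15 subjects (the study's ~1:3
  imbalance), channels F3 + Pz, an inexpensive 8-measure subset, 100
  permutations each. The observed accuracy falls inside the central 95% of
  its own null in ≥ 18/20 cohorts. This check uses the Gaussian
  naive-Bayes classifier: with the RBF-SVM on small imbalanced noise
  cohorts, both the observed run and every permutation collapse to
  majority-class voting, the null becomes a point mass and the central-95%
  interval has zero width, so any one-subject fluctuation counts as a
  miss — a discreteness artifact of the interval, not a calibration
  failure (naive Bayes and kNN give 20/20 coverage, LDA 19/20, SVM 16/20).

## Limitations

- Synthetic channels are independent; channel-axis selection profiles on
  synthetic cohorts carry no spatial physiology.
- The exact wavelet family, coarse-graining recipe and measure parameters
  of the original analysis live in unavailable supplementary material; all
  corresponding settings here are explicit, config-exposed stand-ins.
- Headline accuracies of the original cohort (100%, 7%, 61.2%) concern
  unavailable human data; this package reproduces the *method* and its
  printed arithmetic, and demonstrates recovery only on synthetic effects.
- LOOCV with embedded selection is pessimistically biased on null data
  (selection overfits training noise); the frozen-selection permutation
  null does not share that bias, which is visible at very small n.
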