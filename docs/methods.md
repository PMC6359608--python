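# Methods

## Problem and model

`eegstate` classifies single-channel EEG segments into three clinical
states — healthy (code −1, the {O,Z} scalp recordings), interictal
(code 0, the {F,N} seizure-free intracranial recordings) and ictal
(code 1, the {S} seizure recordings) — from sub-band statistics of a
discrete wavelet decomposition, using a gradient boosting machine built
from first principles.

The processing chain is:

1. **Band-limiting.** A zero-phase Butterworth filter (order 4, default
   edges 0.5–50 Hz) restricts each segment to the 0–50 Hz range in which
   the five conventional EEG rhythms live. Forward–backward application
   removes group delay, so transients stay aligned. A pure low-pass mode
   (`low_cut = 0`) is available, since a band edge at exactly 0 Hz makes
   a band-pass design degenerate. The published workflow also removed
   artifacts with an interactive GUI toolbox; that step is not
   algorithmically specified anywhere, so this package deliberately
   replaces it with the documented band-pass + normalisation stage.
2. **Per-segment normalisation.** z-scoring with the *population* (1/n)
   standard deviation. The population convention is used everywhere in
   the package (features, PCA) — stated once here, applied consistently.
3. **Symlet-4 decomposition.** Four cascaded analysis levels with the
   8-tap Symlet-4 orthogonal filter bank split the band dyadically:
   d1 → γ (25–50 Hz), d2 → β (12.5–25), d3 → α (6.25–12.5),
   d4 → θ (3.125–6.25), a4 → δ (0–3.125). The literature usually rounds
   these edges (12–25, 6–12, 3–6, 0–3); the exact dyadic values are used
   internally. Statistics are computed on the *coefficient sequences*,
   not on reconstructed band signals.
4. **Features.** Per band: mean of |coefficients| and population std of
   raw coefficients → a 10-vector ordered γ,β,α,θ,δ. Means of raw
   zero-mean detail coefficients carry almost no information, hence the
   absolute value; the std is kept on raw values so it measures
   dispersion, not folded magnitude. Both conventions are switchable
   (`abs_mode`) because published summary tables in this literature are
   ambiguous on the point (they report negative means alongside an
   absolute-value statement). Optional PCA (eigendecomposition of the
   feature covariance, `variance_keep = 0.95` default) reduces the
   10-vector; at this dimensionality the reduction is cosmetic, and PCA
   is always refitted inside each training fold to avoid leakage.
5. **Classifier.** Multiclass gradient boosting with multinomial
   deviance (the loss is never named in the source literature; softmax
   deviance is the standard choice for K-class boosting and matches the
   negative-gradient framing). Scores initialise at log class
   proportions. Each stage fits one exact greedy CART regression tree
   per class to the residual Y − softmax(F); leaf values are one-step
   Newton estimates, γ = (K−1)/K · Σr / Σ|r|(1−|r|), clipped to ±10 for
   numerical safety, scaled by the learning rate ν. A per-leaf Newton
   step is the standard resolution of "find the best step size" for
   deviance, where a global scalar line search has no closed form.
   There is no subsampling, so fitting is deterministic given input
   order; the config's `seed` exists only for interface symmetry.
6. **Tuning.** Coarse grid (stages 50..500 step 50 × ν ∈
   {0.05, 0.1, 0.15, 0.2}) then a fine grid centred on the winner
   (ν step 0.01, stage step 10, bounded by the coarse neighbours),
   scored by 10-fold cross-validated misclassification rate. Ties
   resolve to the smaller (stages, ν). Folds are seeded and stratified
   by default. Because an m-stage model is a prefix of an M-stage model,
   all stage counts sharing a learning rate are evaluated from one fit
   per fold via staged scores; a test pins this fast path to the naive
   one-fit-per-config path exactly.
7. **Evaluation.** 3×3 confusion matrix in fixed order [OZ, FN, S];
   SEN_i = A_ii/A_i; SPE_i = Σ_{j≠i,k≠i} A_jk / Σ_{j≠i} A_j;
   ACC = trace/total; one-vs-rest ROC with trapezoidal AUC (equal to the
   Mann–Whitney pairwise probability, ties counting half), macro
   averaging; precision–recall curves. Undefined rates (empty
   denominator) are reported as NaN, never as 0. Note the three-class
   "2×2-block" specificity is algebraically identical to the
   conventional one-vs-rest TN/(TN+FP): excluding row i and column i of
   the matrix leaves exactly the true negatives, and the non-i row total
   is TN+FP. The `spec_mode` flag is kept for interface clarity and a
   test asserts the equivalence.

## Wavelet implementation notes

The DWT/IDWT are written from first principles (padding, convolution,
dyadic down/upsampling), with the 8 Symlet-4 low-pass taps hard-coded at
full double precision and the high-pass branch derived as
`dec_hi[k] = (−1)^(k+1) dec_lo[L−1−k]`. Two boundary policies:

* `symmetric` (production): half-sample symmetric extension, output
  length floor((n + taps − 1)/2) per branch — the standard choice for
  EEG because it avoids the artificial edge discontinuities of a
  periodic wrap. Inversion trims the synthesis output to the recorded
  per-level input lengths, giving exact reconstruction (~1e-12 observed,
  tested at 1e-8).
* `periodization`: circular extension, length ceil(n/2), an orthogonal
  transform under which Parseval's identity holds to ~1e-10; used by the
  energy-conservation tests. Odd-length inputs repeat the final sample
  once, which (as in any periodized DWT) sacrifices strict orthogonality
  for those lengths; energy tests use even lengths.

Vanishing moments: detail output annihilates polynomials up to degree 3.
This is exact only up to the taps' own precision, so it is a *relative*
property: a cubic sampled with O(1) values leaves interior details at
~1e-15, but scaling the polynomial by 1e6 scales the residual the same
way. Tests therefore use unit-scale polynomials, and the degree-4
counter-check compares magnitudes on the same grid rather than against
an absolute bar.

## Tree and tie-break details

Splits scan every feature and every midpoint of consecutive distinct
sorted values, maximising squared-error reduction via prefix sums (exact,
not quantile-approximate). Ties — which occur systematically, e.g. any
two features that induce the same partition of a two-sample leaf give
identical gain — resolve to the lowest feature index, then the lowest
threshold, making fits independent of sample order but, by construction,
*not* invariant to feature reordering in the tied case. Gains within
1e-9 (relative) are treated as ties so the resolution does not depend on
floating-point summation order. Recursion stops at `max_depth`
(default 3), `min_samples_leaf` (default 1), or zero gain.

Class prediction is the argmax of softmax probabilities with ties broken
toward the smaller class code (so an uninformative model predicts the
most benign label deterministically).

## Synthetic EEG generator

Real archives of clinical EEG cannot be bundled, so the generator
emulates the three states' gross structure:

* per class, a **band-power profile** over the five dyadic bands,
  realised as a weighted sum of Butterworth-filtered white-noise
  processes (deliberately *not* inverse-DWT synthesis, so the generator
  is independent of the wavelet code it helps validate);
* a **target amplitude dispersion** per class — 4.6 (healthy), 13.1
  (interictal), 38.6 (ictal) µV — mirroring the ordering and magnitude
  of per-class standard deviations reported for the public Bonn
  recordings;
* **spike–wave transients** (70 ms biphasic spike + one 3 Hz half-wave
  at 3× background amplitude, Poisson-placed) at 0 / 0.2 / 2 events per
  second for the three classes, a documented stand-in for ictal
  morphology rather than a physiological model.

The final signal (noise *plus* spikes) is rescaled to the target std.
Rescaling before adding spikes would inflate the ictal class's realised
dispersion by roughly half again, breaking the generator's own contract
that empirical std tracks `target_std`; the post-spike rescale keeps the
dispersion ordering exact by construction. Default dataset shape is
200/200/100 segments of 4097 samples at 173.61 Hz, matching the public
archive's layout. Child seeds are spawned per segment from the master
seed.

What the generator does **not** emulate: 1/f background spectra,
non-stationarity within a segment, electrode artifacts, inter-subject
variability, or any spatial structure. Synthetic classes are far more
separable than real recordings — cross-validated accuracy near 100% here
demonstrates that the pipeline's plumbing and the classifier's
optimisation work end to end, not that real ictal EEG is this easy.

## Problem sizes and numerical tolerances

The bundled verification suite runs the full pipeline at the archive's
own shape (500 segments × 4097 samples, 10-fold CV, M = 60, ν = 0.1,
depth 3 — a fixed configuration; the grid search itself is validated
separately on a 60–90-sample subsample with compact grids). Transform
exactness is asserted at 1e-8 (observed ~1e-12), the filter taps against
an independent wavelet library at 1e-10, the deviance gradient against
central finite differences at 1e-6 (observed ~1e-10), AUC against the
brute-force pairwise probability at 1e-10.

## Known limitations

* Single-channel only; no EDF/BDF readers, no montage handling.
* No artifact rejection beyond the band-pass.
* The comparison SVM / random-forest back-ends are not bundled;
  `cv_error` accepts any `fit_predict` callable for plugging one in.
* Cross-validated scores are reported as CV means, not held-out-set
  estimates; no nested CV, so tuned scores are mildly optimistic.
* The generator's classes are calibrated for separability ordering, not
  physiological realism (see above).
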