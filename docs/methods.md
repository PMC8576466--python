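# Methods

This note documents the models, procedures and design choices behind
`ramanfp`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open choices were made.

## The analysis problem

Surface-enhanced Raman spectra of dried saliva drops carry a broadband
biochemical fingerprint (protein, lipid, nucleic-acid and saccharide
bands between 400 and 1600 cm⁻¹). The pipeline asks three questions of
a three-group cohort (healthy controls, Parkinson's disease,
Alzheimer's disease): *which bands differ between groups*, *how well
can a spectrum or a patient be assigned to a group*, and *do the
discriminative spectral components track clinical severity*.

## Preprocessing

Two canonical chains are provided; both start from raw spectra on the
acquisition grid (400–1600 cm⁻¹, 0.8 cm⁻¹/step).

* **MVA chain** (feeds PCA–LDA): QC → baseline(5) → despike →
  substrate subtraction → alignment to 1001 cm⁻¹ → unit-vector
  normalization.
* **ML chain** (feeds the classifiers): QC → resample to 900 points →
  substrate subtraction → baseline(6) → despike → normalization
  (unit-vector default; SNV/max/min–max available).

Orders were chosen so baseline removal precedes normalization and QC
precedes everything; within that constraint the steps commute only
approximately, and the chain order is fixed for reproducibility.

**Despiking.** Whitaker–Hayes style: modified z-scores
z_i = 0.6745·(Δ_i − median Δ)/MAD(Δ) of the first differences
Δ_i = I_i − I_{i−1}; |z| > 3.5 marks a spike; replacement is the mean
of non-spike points in a centered 11-point window, widened
symmetrically if all neighbors are flagged. Two boundary rules are
fixed: MAD = 0 (flat or quantized signal) means *no spikes*, since a
zero scale estimate would flag everything; and a spike at point k
flags both k and k+1 (both adjacent differences are large) — the
window-mean replacement restores the clean neighbor to within the
noise. Two caveats are inherent to the method and accepted: with
~1500 points the expected maximum of pure-noise z-scores sits near the
3.5 threshold, so occasional false flags occur (harmless — replacement
is a local mean); and steep flanks of sharp bands can exceed the
threshold (the replacement again changes them by less than the noise
scale).

**Baseline.** Plain least-squares polynomials (degree 5 in the MVA
chain, 6 in the ML chain), fitted on an axis internally mapped to
[−1, 1] for conditioning. No anchor points or asymmetric weighting are
used: the vendor software's exact scheme is unpublished, and plain
least squares is the reproducible default. Consequence: residuals
contain no polynomial component of the fitted degree (asserted to
1e-8 in tests), but strong peaks bias the fit slightly downward —
acceptable because every downstream consumer sees the same transform.

**Substrate.** The aluminum-substrate contribution is removed as
spectrum − ĉ·substrate with ĉ = max(0, ⟨s, sub⟩/⟨sub, sub⟩), the
non-negative least-squares scalar. A fitted scalar (rather than raw
subtraction) absorbs drop-to-drop variation in substrate exposure.

**QC.** Saturation = ≥5% of points within 0.5% of the spectrum
maximum AND that maximum at the 99th percentile of cohort maxima;
no-signal = total baseline-subtracted intensity below 10% of the
cohort median, or correlation with the cohort median spectrum below
0.5. These thresholds are not published anywhere; they are exposed in
`PreprocessParams` and validated against the generator (well-formed
synthetic spectra pass at 100%).

**Alignment.** The intensity maximum within ±10 cm⁻¹ of 1001 cm⁻¹
(phenylalanine ring breathing — the strongest, most stable salivary
band) is shifted onto the target; a window with no interior maximum
leaves the spectrum unchanged with a warning. Edge samples exposed by
the shift are filled by edge replication.

## Synthetic cohort generator

The generator is the package's test bed and defines the study
conditions:

* **Spectral model.** I(ν) = Σ_k a_k·Lorentzian(ν; μ_k, 8 cm⁻¹ FWHM)
  over the 20 canonical salivary bands (1001 cm⁻¹ dominant), plus a
  random positive-trend cubic fluorescence background, a scaled
  substrate profile, Gaussian noise (σ = 0.01 relative to a unit
  1001-band), and Poisson-count cosmic spikes (amplitude 20–100× noise,
  width 1 point).
* **Effects.** a_k = base_k · group factor · subject effect ·
  (1 + 0.15·severity on 1001/1346/1444 for PD). Group factors default
  to ±15–35% changes at the bands where the group difference spectra
  diverge; their magnitudes are order-of-magnitude placeholders (the
  real effect sizes are published only graphically) and are meant to
  be overridden per experiment. Subject effects are lognormal, global
  and per-peak, with CTRL spread (σ = 0.10) configured above PD/AD
  (σ = 0.05), reproducing the larger control-group SD bands.
* **Cohort.** 33/23/10 subjects with 20–30 spectra each; ages
  63.5±8 / 69.9±8.8 / 78.6±7.9 and male fractions 66.6/74/80%
  (CTRL/PD/AD). PD clinical scores derive from a latent severity
  s ~ N(0,1): UPDRS III = 31.7 + 14.5·(ρs + √(1−ρ²)ε) truncated ≥ 0,
  H&Y analogous (2.19 ± 0.7, clipped to [1,5], kept continuous), LEDD
  466 ± 220 truncated ≥ 0, with ρ = 0.7 by default.

What it deliberately does **not** model: physical SERS enhancement,
drying-ring spatial heterogeneity, instrument drift, and
non-Lorentzian band shapes. Passing tests therefore demonstrate that
the *analysis machinery* recovers known structure under realistic
noise — not that real saliva spectra behave this simply.

## Difference analysis

ΔI = mean_A − mean_B on unit-vector-normalized spectra; the
propagated error is √(SEM_A² + SEM_B²) (standard error of a
difference of independent means — the exact error formula is not
published, this is the standard choice). Significant positions are
local extrema of |ΔI| passing |ΔI| ≥ 0.01 AND |ΔI| > error;
peak-mode (extrema) rather than every super-threshold grid point keeps
the output comparable to published peak lists, and a pointwise mode is
available. Attribution maps each position to the nearest of the 20
canonical bands within ±8 cm⁻¹ (ties to the lower wavenumber).

Note a structural limit: a configured effect whose expected normalized
|ΔI| lies below the 0.01 floor (e.g. a 15% change of a band whose
normalized amplitude is ~0.06) is undetectable *by the rule itself*,
at any sample size. The recovery tests therefore assert recall = 1
only over bands whose analytic noiseless difference clears 1.5× the
threshold. A second observation from the generator: per-spectrum
alignment to 1001 cm⁻¹ introduces sub-step relative shifts between
groups, so difference features take a dipole (derivative-like) shape
around each affected band — exactly as seen in real subtraction
spectra — which is why significant extrema sit a few cm⁻¹ off the band
centers.

## PCA–LDA

PCA retains 15 components by default (a 10-component variant is one
keyword away), with a fixed sign convention (largest-magnitude loading
element positive). LDA solves B v = λ W v with B the between-class and
W the pooled within-class covariance on the PC scores; axes are
normalized so the canonical-space within-class covariance is the
identity. Classification assigns argmin_c ½‖x − μ_c‖² − log π_c in
that whitened space — the Gaussian-posterior rule; with equal priors
it reduces to the nearest class centroid. The prior term matters only
in the no-signal regime, where it drives predictions toward the
majority class (the behavior expected of a null classifier); under
real separation both rules agree. A singular W (too many PCs for the
sample) raises with the advice to reduce the component count.

LOOCV refits PCA and LDA in every fold (no peeking at the held-out
spectrum; fold bookkeeping is asserted). Note that spectrum-level
LOOCV retains the held-out *subject's other spectra* in training, so
its metrics measure spectrum assignment, not generalization to new
patients — that is what the patient-level model is for. The ROC score
is the posterior-like PD probability in canonical space (softmax over
−½d_c² + log π_c); AUC is the Mann–Whitney probability with ties
counted ½.

## Patient-level learning

Class-rebalancing augmentation derives per-class multipliers
m_c = round(base · max_count/count_c) (base 10), so the largest class
is augmented base-fold and smaller classes proportionally more;
distortions are additive Gaussian noise (σ = 0.003 on normalized
intensities), integer Raman-shift offsets (±3 points, edge-replicated)
and a random linear slope (±0.01 across the window) — each smaller
than the configured group effects, so labels survive distortion.

Classifiers: SVM (RBF) and random forest via scikit-learn; FCNN and 1D
CNN on an in-package numpy engine (im2col convolutions, ReLU,
max-pooling, dense head with inverted dropout 0.5/0.3, softmax
cross-entropy, Adam, early stopping on a 10% stratified validation
split, plus a convergence exit once validation cross-entropy falls
below 0.02). The default CNN — conv blocks (8,7,2)/(16,7,2)/(32,7,2),
dense 64/32, batch 128, lr 2e-3, ≤30 epochs — is sized so a full
leave-one-patient-out experiment runs in minutes on one CPU core;
every element is exposed in `NetworkSpec`.

Hyper-parameter search is a propose/evaluate loop: a short random
phase, then a random-forest surrogate ranking random proposals by
predicted error; every candidate is scored by 10-fold grouped
(by-patient) CV classification error computed on the training
partition only.

LOPOCV holds out all spectra of one patient per fold; augmentation and
tuning run strictly inside the fold's training partition (augmenting
before splitting would leak distorted copies of test patients into
training), and a programmatic check asserts in every fold that the
held-out subject contributed no training or augmented example. The
patient label is the majority vote over the predicted spectrum labels;
ties break by summed class probability, then by the fixed class order
CTRL < PD < AD.

## Clinical correlation

Per-subject component scores are the mean over that subject's spectra
(the aggregation is not otherwise specified; the mean is the natural
choice for i.i.d. replicates). Partial Pearson r is the correlation of
the least-squares residuals of both variables on [1, age, sex] (sex
coded M=1/F=0); p is two-sided from t = r√((n−2−k)/(1−r²)) on n−2−k
degrees of freedom. An independent precision-matrix route
(r = −P₀₁/√(P₀₀P₁₁)) is exposed and agrees to 1e-10. p-values are
reported raw (significance stars at 0.05/0.01/0.001), with
Benjamini–Hochberg available but off by default — fidelity to common
practice first, rigor one flag away. Only age and sex are supported as
covariates; no other behavioral covariates are defined anywhere, and
the panel metadata records which covariates were used.

## Statistical-testing conventions in the test suite

Two conventions deserve a note. First, where a null-model accuracy is
compared to the majority-class rate, the binomial confidence interval
uses the number of *patients*, not spectra: spectra of one subject are
strongly correlated (they share the subject's latent spectral
effects), so patients are the independent units. Second, recovery
assertions on the difference rule are restricted to effects above the
rule's own detection floor, computed analytically from the noiseless
generator (see Difference analysis).

## Problem sizes

Test and reproduction runs use the full 66-subject cohort at 20
spectra/subject for the PCA–LDA LOOCV (1320 folds, ~2 minutes on one
core) and a scaled 15-patient cohort (6/5/4 × 8 spectra) for the CNN
LOPOCV (~2–3 minutes) — sizes chosen so the complete suite runs on a
laptop while keeping every statistical property testable. Monte-Carlo
checks (spike counts, clinical-link recovery, type-I error rates) use
200–10,000 replicates as noted in the individual tests.

## Known limitations

* The numpy CNN is single-threaded and CPU-bound; it is a faithful,
  reproducible reference, not a performance implementation.
* Spectrum-level LOOCV inherits the subject-leakage optimism discussed
  above; compare patient-level LOPOCV for deployment-relevant numbers.
* The generator's group effect sizes are placeholders; absolute
  classification metrics on synthetic cohorts characterize the
  machinery under the configured separation, not clinical performance.
* Despiking on sharp bands and the ΔI ≥ 0.01 floor behave as described
  above; both are properties of the published procedures, reproduced
  deliberately.
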