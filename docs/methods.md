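# Methods

This note documents the models, parameter choices and numerical decisions
behind `pfasrisk`, and what the synthetic-data tests do and do not
demonstrate about real acquisitions.

## Mass chemistry

Formulas are element-count maps over {C, H, N, O, F, S, Cl} — the elements
that occur in drinking-water PFAS and their fragments. Monoisotopic masses
use fixed CODATA/IUPAC lightest-isotope values (H 1.0078250, C 12 exactly,
N 14.0030740, O 15.9949146, F 18.9984032, S 31.9720707, Cl 34.9688527),
stored in a single table so tests can pin them. Anion m/z adds one electron
mass (0.0005486 Da) per charge; neutral-loss masses do not. This convention
reproduces both the carboxylate CO₂ loss at 43.98983 Da and the sulfonate
[SO₃]⁻ ion at m/z 79.95736.

Homologue rules map (class, carbon count) to a neutral-acid formula for all
eleven classes (e.g. PFCA(n) = CnHF₂ₙ₋₁O₂, PFSA(n) = CnHF₂ₙ₊₁SO₃; FTSA is
counted in total carbons, so 6:2 FTSA is n = 8). Each
registry compound's packaged formula is reproduced exactly by its class
rule, and consecutive homologues differ by one CF₂ (49.99681 Da) — both are
property-tested.

Isotope envelopes (M, M+1, M+2) are computed by per-atom convolution of
isotope-abundance patterns aggregated at nominal-mass offsets, which is
accurate at the two-isotopologue depth feature tables report; fine mass
structure within an isotopologue is not modelled.

## The packaged registry

`data/registry.tsv` lists the 30 identified compounds (acronym, class,
carbon count, formula, identification confidence, detection frequency,
maximum concentration ng/L, legacy flag). Detection frequencies are stored
as printed percentages and converted to fractions at parse time. The n = 6
hydrogenated carboxylate's maximum prints as 0.00 ng/L (below
quantification) and is stored as 0.0, not missing — it anchors the
Magnitude minimum in the risk equations. Legacy means the PFCA and PFSA
homologue series (16 compounds); the other nine classes (14 compounds) are
novel/emerging chemistries.

## Screening cascade

Filters run in order: blank, exact mass, isotope pattern, retention time,
fragments, confidence assignment. All thresholds are strict inequalities
("> 5x", "< 5 ppm", "> 70%") taken literally. Defaults: blank factor 5,
MS1 5 ppm, MS2 10 ppm, RT 1.5 min, isotope fit > 70% with per-isotopologue
intensity deviation < 30% and mass deviation < 5 ppm.

Decisions where practice leaves room:

* **Isotope fit score** = 100 × (1 − Σ|obs − theo| / Σ theo) over relative
  intensities with M ≡ 1 — a sum-of-absolute-deviation similarity, since
  vendor software names a threshold without defining its score.
  Isotopologues below 1% relative abundance carry too little signal and are
  excluded from the per-isotopologue deviation check (they still enter the
  score). Feature tables usually lack per-isotopologue m/z, so the mass
  deviation term defaults to zero unless supplied.
* **Missing RT predictions**: candidates pass flagged "unfiltered"
  (filtering only applies where predictions exist); a hard-fail policy is
  available in `ScreenConfig`.
* **Deduplication** keeps the lowest-|ppm| candidate per compound within a
  0.2 min RT cluster. Peak-shape screening is a pass-through: features
  arrive pre-picked, and shape quality is a property of raw chromatograms
  this package never sees.
* **Confidence levels**: level 1 needs authentic-standard RT + MS2 +
  isotope agreement; level 2 needs ≥ 2 diagnostic fragments with
  isomer-discriminating evidence, split 2a/2b by retention-time support;
  level 3a needs ≥ 1 fragment. Chain-length-parameterized fragments and
  precursor-anchored neutral losses count as isomer-discriminating because
  they pin the homologue; fixed ions like [SO₃]⁻ do not. Under these rules
  the hydrogenated carboxylates — whose only diagnostic is the combined
  CO₂ + HF loss — land at 3a, matching their registry assignment.

## Synthetic data

Generators are pure functions of (parameters, seed) and plant ground truth
for every stage:

* **Feature tables**: planted features at theoretical anion m/z with
  Normal(0, σ_ppm) relative jitter (default σ = 1 ppm, well inside the
  5 ppm gate), RT jitter 0.2 min, lognormal intensity noise (CV 0.2;
  multiplicative noise matches ESI response behaviour), blank contamination
  at 5% of mean signal (inside the 5x rule). Noise peaks are uniform in
  m/z and RT and redrawn until > 5 ppm from every suspect, so any noise
  peak surviving the cascade would be a genuine code defect.
* **MS2 spectra**: every diagnostic fragment of the planted class with
  2 ppm jitter plus lognormal-intensity distractors; noise features get
  distractor-only spectra.
* **Descriptors**: iid standard-normal matrix (default 200 columns — a
  desk-scale stand-in for the thousands a full 2-D descriptor suite
  yields; pass more for fidelity runs) with responses affine in
  k = 5 informative columns. Coefficient vectors are unit-norm, so the
  noise SD parameter reads directly as a fraction of signal SD. RF offset
  5 keeps response factors positive.
* **Attribute tables**: 19 hazard attributes drawn from plausible QSAR and
  docking ranges with a planted chain-length trend (longer chains more
  persistent and bioaccumulative), mirroring the field's observation.
* **Profile matrices**: per-group mean log₁₀ composition with lognormal
  within-group scatter.

What passing synthetic tests does **not** show: real acquisitions have
correlated noise, in-source fragmentation, co-elution, matrix effects and
descriptor collinearity that iid generators cannot emulate. Recovery of
20/20 planted compounds with 0 false positives demonstrates the cascade's
logic and threshold arithmetic, not field-sample performance.

## RT/RF regression

The split protocol is 8:2 (train = round(0.8 n); n = 68 gives 54/14),
seed-reproducible. Model selection is a budgeted seeded random search over
a declared space — ridge, lasso, relaxed lasso (lasso support + OLS refit),
elastic net, and one/two-layer MLPs — each scored by 3-fold CV RMSE on the
training split only; the minimum-RMSE configuration is refit on all
training data. Four fixed baseline configurations are always evaluated
first (within the budget) so the search never misses the obvious
candidates. The relaxed lasso matters on sparse linear signals at p ≫ n:
plain lasso's shrinkage bias caps accuracy near 1% of response SD, while
the OLS refit on the recovered support is essentially exact in the
noiseless limit. Zero-variance and duplicate descriptors are dropped and
the rest standardized before fitting. An optional floor keeps predicted
response factors positive.

## Quantification

Calibration is ordinary least squares over ≥ 5 strictly increasing levels
with the QC rule r² > 0.99; when detection limits are not supplied they
default to the residual-SD rule (LOD 3.3 s/slope, LOQ 10 s/slope).
Responses are internal-standard-normalized upstream (the IS mapping is
configuration, not code). Semi-quantification divides response by the
predicted RF with zero intercept — standard-free compounds have no
calibration line to supply one. Censored (< LOQ) values report as "<LOQ"
and contribute 0 to detection frequencies and summaries; no substitution
rule (LOQ/2 etc.) is applied.

## ToxPi scoring

The 19 attributes (3 persistence, 2 bioaccumulation, 3 ecotoxicity,
5 human-health, 6 receptor-docking) carry the published transforms and
weights. Transform direction makes "larger = more hazardous": Biowin
probabilities are negated (faster biodegradation is less hazardous),
LC50/EC50/LD50 take −log₁₀ (lower dose is more toxic), BAF takes log₁₀.
Normalization is per-attribute min-max across the scored compound set —
scores are therefore relative to the set, and adding a compound can shift
others' scores only through the min/max constants (documented coupling);
this also makes scores invariant to affine rescaling of any raw attribute.

The printed weights sum to 46/45 (persistence 1/3, bioaccumulation 1/3,
ecotox 1/9, human-health 1/9, docking 2/15), not 1. The default
renormalizes by the total so an all-extreme compound scores exactly 1.0 and
totals stay in [0, 1] — the conventional ToxPi range, and the one the
reported score range (0.09–0.85) sits inside; `audit_weights` surfaces the
discrepancy, and both modes are available. Slice scores P, B, T are
weight-weighted means within their groups. Whether the original scores
used renormalized weights cannot be verified without the underlying
attribute values; tests exercise both modes.

## Risk Index

C_i in the Magnitude equation is the per-compound maximum concentration
across samples — the summary that reproduces the reported worked value
RI(PFOA) ≈ 0.47 vs the printed 0.46 (the gap is input rounding of the
two-decimal ToxPi score). Reference pseudo-compounds sit at the 4 ng/L MCL
with DF = 1 and are excluded from the min/max normalization constants, so
they measure where a regulatory-limit compound would fall in the observed
set. High-concern requires RI strictly above both references; ties break by
ToxPi then alphabetically, making the ranking permutation-invariant. A
quantile-binning mode (5 ordered categories for concentration and DF,
damping outliers) implements the discretized reading of the exposure
variables; the continuous equations are the default since they reproduce
the worked example.

## Profile PCA

Preprocessing: zeros and censored cells are replaced by half the smallest
positive value of their compound (all-zero compounds are dropped), then
log₁₀, column centering and Pareto scaling (divide by √SD) — the standard
chemometrics pairing that tames order-of-magnitude concentration ranges
without amplifying near-constant compounds; unit-variance and
centering-only scalings are config switches.

PCA is iterative NIPALS with deflation (tolerance 1e-14, restart from the
largest-SS column), sign-fixed so each component's largest-magnitude
loading is positive. R²X per component is the explained fraction of total
SS and agrees with an SVD to 1e-8 on test matrices. Q² uses element-wise
deletion cross-validation (7 scattered folds by default, seeded): held-out
entries are EM-imputed (30 refit/impute rounds from a zero start, the
column mean of a centered matrix), squared prediction errors accumulate
into PRESS, and Q² = 1 − PRESS/SS. Element-wise (rather than row-wise)
deletion is the chemometrics convention for PCA cross-validation. Q² > 0.5
is flagged as good predictive stability; pure-noise matrices give Q² ≤ 0.

## Problem sizes

Tests and the worked example run at desk scale: 20 planted compounds + 500
noise peaks for screening, 68 compounds x 200 descriptors with a 50-model
search budget for regression, 10x6 to 16x10 matrices for PCA/Q². These
sizes exercise every code path; the generators accept larger values
(e.g. thousands of descriptors, full 5000-model budgets) for fidelity runs.

## Known limitations

* Screening starts from picked peaks; no raw-profile (scan-level) data,
  vendor readers, or peak-shape modelling.
* QSAR/docking attribute values are inputs; the package never runs the
  external predictors that produce them.
* Formulas only — no structures, SMILES or 3-D geometry, so isomers within
  a homologue are distinguishable only through fragment/RT evidence.
* No matrix-effect or recovery correction in quantification.
* ToxPi and RI are set-relative by construction; scores from different
  compound sets are not comparable.
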