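# Methods

## Model

`parkmlr` classifies parkinsonian syndromes from FDG-PET volumes in a
single level. The generative assumption is the scaled-subprofile model: a
subject's metabolic image is a group mean profile, multiplied by a
subject-specific global scaling factor (GSF — overall tracer uptake,
scanner calibration, injected dose), modulated by region-specific
covariance, with multiplicative voxel noise. Taking logarithms makes every
one of these effects additive; subtracting each subject's row mean removes
the GSF exactly, and subtracting the column means removes the shared
profile, leaving the subject residual profile (SRP) that PCA decomposes.

The eigendecomposition is performed in subject space (`S_sub = SRP·SRPᵀ`,
M×M with M ≤ ~100) rather than voxel space (N×N with N in the thousands);
the two share their nonzero spectrum, and the voxel-space components (GIS)
follow as `SRPᵀ·E·Λ^(−1/2)`. Double centering removes one dimension, so at
most M−1 components are retained; eigenvalues below 1e-10 of the largest
are treated as numerical rank deficiency and dropped.

The reference category of the multinomial logistic regression is an
artificial "undetermined" (UD) class: voxel-wise averages of disjoint
(PD, MSA, PSP) triplets, built in native intensity space before the log
transform. This removes the dependence on healthy-control databases. The
triplet pairing is a seeded uniform shuffle per class — any disjoint
pairing satisfies the independence requirement, and on synthetic cohorts
the downstream results are insensitive to the pairing seed.

## Fitting and model selection

The multinomial likelihood (UD linear predictor fixed at 0) is maximized
by full Newton iterations with step-halving; with at most a handful of
components the exact Hessian (3(P+1) × 3(P+1)) is cheap. The gradient
tolerance is run to 1e-10 so algebraic identities (shift invariance,
agreement with reference fitters) hold to their stated tolerances. A ridge
of 1e-8 on the slope coefficients (intercepts unpenalized) keeps the
optimum finite under complete separation, which clean cohorts genuinely
produce; a fit whose in-sample log-likelihood is within 0.01 of its
supremum 0 is flagged as separated. The reported log-likelihood and AIC
are unpenalized. AIC counts k = 3(P+1) parameters — three intercepts plus
three slopes per selected component; only AIC differences matter for
selection.

The selection grid crosses mask thresholds 15–45% in steps of 5 with all
component subsets of size ≥ 3 drawn from a pool capped at 50% cumulative
variance accounted for (floored at 3). The SSM/PCA state is recomputed per
threshold, since the mask changes the voxel set; the UD triplet plan is
drawn once per run so AIC differences isolate threshold and subset
effects. Cells that fail to fit record +inf AIC with a warning. AIC ties
break toward smaller subsets, then lower thresholds (parsimony). The
winning threshold, SSM state and regression fit are frozen into a single
model archive; validation subjects are always masked with the training
mask and centered with the training voxel-mean profile (their own row
mean is still subtracted, as that is the subject's GSF).

Masking reads the percentage-of-maximum per image and intersects across
subjects, so every matrix entry is above threshold in every subject;
reported diagnostic performance is insensitive to the exact threshold in
this band, which the AIC surface also shows. Eigenvector signs are fixed
by making the dominant entry of each GIS column positive, making
topographies bit-reproducible; the paired flip of E leaves all products
unchanged.

## Evaluation

ROC curves are one-vs-rest on the predicted class probability. The
operating point is the classical cost-slope construction: the vertex
maximizing TPR − S·FPR with S = (Cost(P|N) − Cost(N|N)) / (Cost(N|P) −
Cost(P|P)) · N/P, equal unit costs by default (S = N/P), ties toward lower
FPR. Sensitivity/specificity come from the vertex rates, PPV/NPV from the
implied counts. Classification rules are argmax over the four classes, or
a reject option (best disease class only if its probability exceeds 90% or
99%, else undetermined); validation cohorts contain no true UD subjects,
so confusion matrices are 3×4.

## Synthetic cohorts

The generator emulates exactly the structure the model assumes:
`image = GSF · base(x) · (1 + pattern_class(x)) · exp(ε)`, ε ~ N(0, σ²)
i.i.d. per voxel, GSF uniform on its range. The base profile is a brain
ellipsoid whose intensity falls from the center (100, arbitrary units) to
25% of peak at the rim — so percentage-of-maximum thresholds in the 15–45%
band trim the rim progressively — over a small positive background (1% of
peak), which keeps the log transform defined and gives the mask something
to exclude.

Defaults are the conditions exercised throughout the tests: 20 subjects
per class for identification (17 for validation), pattern amplitude 0.15
(15% regional deviation), noise σ = 0.05 in log-intensity units, GSF range
0.8–1.2 (a realistic ±20% global-uptake spread), grid 20×24×20. Patterns
live in ellipsoidal pseudo-anatomical regions sized like the real
topographies' spatial extents (hundreds of voxels — whole cortical
territories and the cerebellum, not isolated nuclei): PD raises striatum
and cerebellum and lowers parieto-temporal cortex; MSA lowers putamen and
cerebellum; PSP lowers caudate and mediofrontal cortex with a relatively
raised cerebellum. The shared cerebellar region with opposite PD/MSA signs
reproduces the characteristic anti-correlation of the PD/UD and MSA/UD
topographies. With these extents the eigen-spectrum looks like real
SSM/PCA spectra: two dominant group components plus a noise tail, with the
50%-VAF pool landing around 4–8 components.

What the generator does *not* emulate — anatomy, MNI registration, scanner
point-spread, partial-volume effects, age/sex covariates, disease
heterogeneity — bounds what passing tests show: they demonstrate that the
pipeline recovers planted multiplicative group structure and that its
algebra is correct, not that clinical accuracy transfers to real cohorts.

Two structural facts about the synthetic study are worth recording. First,
because the UD reference is the average of the three class means, the
double-centered class-mean geometry spans two strong directions (the third
is only the small log-of-mean vs mean-of-log curvature); group signal
therefore concentrates in the first two principal components. Second, at
amplitude 0.15 against σ = 0.05 the four classes separate completely in
score space, so all minimum-size subsets containing those two components
tie at the separation-limited AIC of 2k and the winner is resolved by
parsimony. Both are properties of the study design, not defects of the
selection machinery; at smaller amplitudes or higher noise the AIC surface
becomes informative in the usual way.

## Numerical choices and limitations

- Tolerances: double-centering residuals < 1e-10; eigen-identities and
  reconstruction < 1e-8; probability normalization < 1e-10.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical inputs and seeds give
  bit-identical cohorts, grids and reports.
- Problem sizes in tests and the acceptance script (20×24×20 grids, ~2–3k
  masked voxels, 80-subject analyses, 20-seed recovery studies) are chosen
  so the whole suite runs in well under a minute while exercising every
  stage at realistic subject counts.
- The package assumes spatially normalized, smoothed volumes; raw DICOM
  handling, normalization and smoothing belong to upstream preprocessing.
- AIC values are comparable within one run's grid; they change with the
  voxel count and are not comparable across cohorts.
- PPV/NPV at the operating point depend on the validation class mix and
  are not population-prevalence adjusted.
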