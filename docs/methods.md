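# Methods

This note documents the models, the synthetic cohort, the numerical choices
and the known limitations of `gradefuse`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Pipeline overview

A patient contributes three co-registered modality volumes (CT/MRI/PET
surrogates), a binary tumor mask and a structured clinical record. The
processing order is: imaging preprocessing (trilinear resampling to a target
spacing, in-mask intensity standardisation, ROI masking) and clinical
preprocessing (imputation, standardisation, one-hot encoding, boxplot
outlier handling, mutual-information feature selection), temporal alignment
of imaging and clinical records within a configurable window (default 30
days); four branch encoders; grade-conditioned gated attention fusion; the
collaborative head (shared 3D encoder, dictionary reconstruction, gated
assembly, grading head, prototype subtype head); training under the joint
loss; evaluation and subtype-sensitive maps.

## Numerics core

No external deep-learning framework is used: `gradefuse.autodiff` is a
small reverse-mode automatic-differentiation engine over float64 numpy
arrays (dense ops, softmax/log-softmax, im2col-based 2D/3D convolution, max
pooling, single-head attention), with layers and an Adam optimiser in
`gradefuse.nn`. Gradients of every primitive are tested against central
finite differences. Everything is CPU-only and deterministic given the run
seed; batch normalisation treats its batch statistics as constants in the
backward pass (the stop-gradient variant), which is stable at the problem
sizes used here.

## Synthetic phantom cohort

The generator (`gradefuse.phantom`) emulates a solid-tumor cohort with two
grade strata and two planted treatment-response subtypes:

* **Cohort composition** follows the reference cohort description: grade
  prevalence 0.42/0.58, responder fraction 0.49, tumor-type mix NSCLC 0.53 /
  HCC 0.47, age 62.4 ± 11.5, male fraction 0.624, and subtype-dependent PFS
  medians of 14.2 (low-risk) and 5.8 months (high-risk) under exponential
  hazards with independent exponential censoring calibrated to a 25%
  censoring rate.
* **Geometry.** The tumor is a randomly placed ellipsoid with a smooth
  boundary perturbation; the necrotic core is a concentric inner region
  whose volume fraction has grade-dependent mean (0.05 GI–II, 0.30 GIII).
* **Modalities.** CT carries rim texture with grade-dependent SD and a dark
  core; MRI is smoother with a bright core; PET adds focal Gaussian hotspots
  whose amplitude and count scale with grade and subtype.
* **Subtype effect sizes.** The paper-scale cohort is private and no effect
  sizes are published, so the planted high-risk subtype is a generator
  design choice, made for testability: it is planted as a *dominant
  within-grade mode of variation* — extra necrotic fraction +0.30, texture
  SD ×2, PET hotspot amplitude +1.5 with two extra foci, and a strongly
  bimodal PD-L1-like marker (shift 3.0 at within-class SD 0.45, mirroring
  the clinical bimodality of PD-L1 tumor proportion scores). The rationale
  is quantitative: an unsupervised clusterer can only recover a planted
  binary structure whose separation exceeds the high-dimensional
  detectability threshold at the cohort sizes used (n ≈ 300, 64-dim pooled
  representations); these settings give an ideal-observer separation of
  roughly 3.5–4σ on the clinical side and ~1σ on the imaging side after
  encoding — recoverable, but far from trivial, and weak enough that wrong
  grade conditioning visibly degrades recovery.
* **Response model.** Responder labels follow a logistic model on centred
  planted covariates: intercept at the configured base rate, subtype main
  effect (−2.0 log-odds by default), grade effect (+1.2), a grade×subtype
  interaction (−0.5 × the subtype effect, so a null subtype effect removes
  all subtype dependence), and texture/biomarker latent terms (−0.4, +0.3).
  Coefficients and per-patient Bayes probabilities are recorded in the truth
  manifest; `bayes_optimal_auc` gives the cohort's performance ceiling.

What the phantom does **not** emulate: scanner physics, registration error,
partial-volume effects, realistic organ context, longitudinal imaging, or
label noise in grade/response adjudication. Passing recovery tests on the
phantom therefore demonstrates that the implementation is mechanically
correct and that grade guidance carries usable information in the intended
regime — not that the method reaches any particular performance on real
cohorts.

## Design choices in the model

* **2D/3D reconciliation.** The fusion branches operate on 2D material
  extracted from the ROI volumes (central CT slice for the residual branch,
  central MRI slice for the direct branch, a central 7-slice 20×20 PET block
  for the unit branch), while the collaborative head's shared encoder sees
  the stacked 3D volumes. All printed widths (512/16/32/64 → 624; D = 128;
  d_g = 32; u_fus 560; C_e = 64; gate hidden 32; heads 64→32→G) are
  respected and asserted structurally. The imaging residual u_fus is the
  560-wide concatenation exactly; z_fus is carried alongside rather than
  folded into it (the two printed statements about its width are
  inconsistent; the printed 560 wins).
* **Residual-branch depth** is configurable (18 or 34; both end at 512
  channels); the desk default is 18 with a configurable input size (224 for
  the width contract, 56 in the training runs for problem-size reasons).
* **Clinical encoder.** Per-variable embeddings are refined by a
  graph-convolution step over a thresholded-correlation adjacency and pooled
  by *concatenation* (not averaging): mean pooling across V variable nodes
  attenuates a single informative biomarker by √V, which at desk scale
  destroys the subtype signal the downstream clustering depends on.
* **Feature selection** (greedy mRMR with 16-bin histogram mutual
  information against both grade and response labels, lowest-index
  tie-break) is applied to the encoded clinical table during featurisation
  (default k = 3), fitted on the training split only.
* **Conditional clustering.** "Clustering under grading conditions" is
  realised literally: the prototype head operates on
  `u_cond = (u − μ̂_grade(ŷ)) / s`, where μ̂_grade are grade-conditional
  means of u estimated on the training split and indexed by the *guidance*
  grade (true labels in oracle mode, predicted in two-pass mode, permuted in
  the shuffling experiment, the global mean with no guidance), and s is a
  single scalar residual scale so that κ_proto = 1 is scale-meaningful
  without distorting the variance structure. Correct guidance removes the
  grade-explained variance exactly; shuffled guidance mis-centres every
  patient.
* **Prototype initialisation.** After a short warm-up, the two centers are
  initialised from the response-class means of u_cond on the training split
  — the follow-up response signal orients the subtype axis — with the mean
  difference denoised by projection onto the leading 16-dim principal
  subspace, then refined by two k-means sweeps before joint optimisation.
  A pure k-means++ initialisation was measured to fail here: at n ≈ 300 and
  64 dimensions, a ~2σ planted axis sits below the Marchenko–Pastur
  detectability edge, so unsupervised seeding finds dominant-variance
  directions unrelated to the subtype. Longer unsupervised refinement
  drifts the same way, hence the two-sweep cap.
* **Specific projector.** The conditional affine modulation is generated
  from the context c = projection of [h_cli; z_fus] (clinical source
  weighted dominant, RMS-normalised); the scale head starts at exactly 1 and
  the shift head at a pinned RMS ratio (2.0) to the content projection, so
  the context-to-content mixing is set by design rather than by
  initialisation chance. A zero context reproduces the unmodulated
  projection exactly. Gates start mildly open (σ(1) ≈ 0.73).
* **Read-outs.** Reported grading predictions come from a regularised
  logistic read-out on the residual pathway [u_fus; z_fus] (the grading
  branch predicts from u_fus; the collaborative head's cross-entropy remains
  the L_grade term of the joint loss). Reported response metrics come from a
  logistic read-out on [π, grade-context one-hot, π×grade] — response
  prediction from the discovered subtype structure under the grading
  context — fit on the training split only. This keeps the joint loss
  literal (no supervised response term) while still producing the AUC /
  precision / recall numbers the evaluation reports.
* **Risk orientation.** The C-index risk score is π for whichever cluster
  has the shorter median observed PFS on the training split.

## Training schedule

Adam (β₁ = 0.9, β₂ = 0.999, weight decay 1e-5) at initial learning rate
1e-4; plateau-triggered decay (×0.5 when validation grading accuracy fails
to improve by 1e-3 for 5 epochs); if grading plateaus while clustering
consistency (epoch-to-epoch ARI of validation assignments) has not
stabilised, the grading head is frozen and fine-tuning continues at 0.1× the
current rate; early stopping requires both signals stable. A statistics
pre-pass sets the conditional centering before the first step. λ = 0.1,
β = 0.05, γ = 0.01. All loss terms are logged per epoch as their weighted
contributions. At the default desk scale the 2D branch backbones and the 3D
shared encoder act as fixed random-feature extractors (config flags
`freeze_backbones` / `freeze_shared_encoder`); end-to-end optimisation of
all convolutional backbones is supported by the same code path and is simply
slower. With ≤ 20 epochs at the printed learning rate, parameters move
little, so the recovery behaviour rests mainly on the architectural
mechanisms above; this is a deliberate desk-scale design.

## Problem sizes

The recovery experiments in the test suite and the acceptance script use
cohorts of 300 patients with 16³ volumes, 10 training epochs, a 70/15/15
patient-level split (grade×response stratified) and five experiment seeds;
per seed, two model seeds are trained per guidance mode, their pairwise
assignment ARI is the clustering-consistency statistic, and the per-seed
subtype ARI is the mean of the two runs. Subtype ARI is scored over the full
cohort (subtype discovery is unsupervised); supervised read-outs are scored
on the held-out test split.

## Numerical conventions

Population (not sample) standard deviations in intensity and clinical
standardisation. Voxel indices are 0-based; world coordinate = index ×
spacing; resampling samples output-voxel centers (half-pixel convention)
with edge clamping. Artifact suppression is a frequency-domain Gaussian
low-pass followed by a 3³ median filter. IQR multiplier 1.5; temporal window
30 days; SMOTE λ ~ U(0,1) with k = 5 neighbours within grade×response cells,
training split only. AUC is the normalised Mann–Whitney statistic with
half-credit ties; the C-index uses comparable pairs (t_i < t_j, event_i = 1)
with half-credit ties; clustering consistency is mean pairwise adjusted Rand
index; 0·log 0 ≡ 0 in the entropy penalty. Dictionary temperature τ and
prototype temperature κ_proto default to 1.0. Kaplan–Meier estimation and
log-rank tests delegate to lifelines; ARI to scikit-learn; both are
cross-checked against brute-force implementations in the tests.

## Known limitations

* The phantom's subtype is deliberately recoverable; real response subtypes
  will rarely present a 3–4σ axis, and nothing here estimates how the method
  degrades toward the detectability threshold.
* The "clinical interpretability score" mentioned alongside the evaluation
  metrics is never defined and is not implemented.
* The consistency statistic is computed from two model seeds per condition;
  its direction (true guidance more stable than shuffled) holds on the test
  seeds but is noisy at this number of replicates.
* The learned segmentation producing tumor masks is out of scope — masks
  are inputs, supplied by the generator.
* Visualisation decoding (64→48→32→16 upsampling) is forward-only plumbing
  for map export; the reconstruction term of the loss targets the encoder
  features F, as printed.
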