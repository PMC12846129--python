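# gradefuse

Grade-guided multimodal collaborative modeling of tumor grading and
treatment-response subtypes, exercised end-to-end on synthetic phantom
cohorts.

## The problem

Pathological grade (here the binary strata GI–II vs GIII) and treatment
response (responder CR/PR vs non-responder SD/PD under RECIST-style
adjudication) are usually modeled separately, although grade conditions how
imaging and clinical phenotypes relate to response. `gradefuse` implements a
framework in which the grade label acts as a weakly supervised structural
prior on multimodal fusion and on response-subtype discovery:

* **Branches.** Three imaging streams — a residual CNN on 224×224 tiles
  (h_res ∈ R⁵¹²), a small direct CNN on 50×50 tiles (h_dir ∈ R¹⁶), a
  unit-level encoder on 20×20×7 blocks (h_enc ∈ R³²) — plus a relational
  clinical encoder (h_cli ∈ R⁶⁴); the concatenation h ∈ R⁶²⁴.
* **Grade-conditioned gated attention.** Each branch is aligned to D = 128,
  the grade label is embedded (d_g = 32, combined with the response-status
  embedding during training), and modality weights are scored as
  `s_m = vᵀ tanh(A h̃_m + B g + c)`, `α = softmax(s)`,
  `z = Σ_m α_m h̃_m`, `z_fus = ReLU(W_f z + b_f)`, with a residual imaging
  pathway u_fus ∈ R⁵⁶⁰ and an entropy regulariser
  `L_gate = γ E[−Σ α_m log α_m]`. Since α is convex,
  `Var(Σ α_m ε_m) = Σ α_m² Var(ε_m) ≤ Σ α_m Var(ε_m)`.
* **Collaborative head.** A shared four-stage 3D residual encoder (channels
  32→64→96→128, /16 spatial) yields F; generic/specific position-wise
  projectors map to C_e = 64, a learnable dictionary E ∈ R^{K×64}
  reconstructs `x̃_i = softmax(q_i Eᵀ/τ) E`, a gate
  `g_i = σ(W₂ φ(W₁ X_d(i)))` assembles
  `y_i = x̃_i + g_i ⊙ (X_d(i) − x̃_i)`, pooled to u ∈ R⁶⁴ with a 64→32→G
  grading head and Gaussian-kernel prototype clustering
  `π_m ∝ exp(−‖u − μ_m‖²/κ)`. The joint objective is
  `L = L_grade + λ Σ_m π_m ‖u − μ_m‖² + β ‖F − F̂‖₁` (λ = 0.1, β = 0.05).
* **Interpretation.** Subtype-sensitive maps `S_m(p) = E[g_p π_m]` localise
  positions whose gates co-activate with a subtype.

Because clinical imaging cohorts of this kind are not publicly shareable,
the package ships a first-class phantom generator that plants the structure
the framework assumes — grade-dependent necrosis and texture heterogeneity,
grade-correlated biomarkers, grade-conditioned response subtypes, and
subtype-dependent progression-free survival — together with the ground truth
needed to score recovery. All neural components run on a compact
reverse-mode autodiff core over numpy included in the package.

## Worked example

```bash
cat > example.yaml <<'YAML'
seed: 7
phantom:
  n_patients: 200
train:
  epochs: 10
YAML
gradefuse simulate --config example.yaml --out run/
gradefuse train    --config example.yaml --out run/
gradefuse evaluate --config example.yaml --out run/
gradefuse interpret --config example.yaml --out run/
```

prints (abbreviated):

```
trained 10 epochs; checkpoint at run/checkpoints/model.npz
{
  "grading_accuracy": 0.8,
  "grading_kappa": 0.5871559633027524,
  "response_auc": 0.7888888888888889,
  "response_precision": 0.875,
  "response_recall": 0.4666666666666667,
  "subtype_ari": 0.6221135324941818,
  "c_index": 0.5359281437125748
}
wrote 2 subtype maps to run/maps (test ARI 0.622)
```

Reading the numbers: on the held-out test split the model grades 80% of
patients correctly (Cohen's κ 0.59 beyond chance) and ranks responders above
non-responders with AUC 0.79; the unsupervised subtype assignment recovers
the planted response subtype with adjusted Rand index 0.62 over the whole
cohort; the C-index measures how well the subtype-derived risk score orders
progression-free survival. `run/maps/` holds the subtype-sensitive maps as
NIfTI volumes on the encoder grid; `run/history.jsonl` logs every loss term
and schedule event per epoch. `gradefuse ablate` and `gradefuse permtest`
run the module-ablation grid (imaging-only → early fusion → deep fusion →
grade-guided) and the label-shuffling permutation experiment on the same
splits.

The same pipeline is available as a library:

```python
from gradefuse.phantom import PhantomConfig, generate_cohort
from gradefuse.train import TrainConfig, train_model, evaluate_model

cohort = generate_cohort(PhantomConfig(n_patients=200, seed=7))
result = train_model(TrainConfig(epochs=10, seed=7), cohort)
metrics = evaluate_model(result)
```

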