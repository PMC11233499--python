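# Methods

This note documents the models and procedures implemented in `tpd_qspr`,
the parameters that matter, what the synthetic study does and does not
emulate, and the numerical conventions chosen where a design was open.

## Problem setting

Quantitative structure–property relationship (QSPR) models predict
ADME and physicochemical endpoints from molecular structure. The package
targets the setting where those models must serve targeted protein
degraders (TPDs) — molecular glues and, especially, heterobifunctional
degraders (warhead–linker–E3-ligand chains, typically 700–1000 Da and
beyond the rule of five) — even though such compounds are a small
fraction of the training data. Because industrial assay databases of this
kind are proprietary, the package ships a synthetic-study generator with
known ground truth; every pipeline stage is exercised, and every headline
number recomputed, on generated data.

## Task registry

Twenty-five assay endpoints are grouped into four multi-task models:
permeability (5 tasks), microsomal clearance (6), binding/lipophilicity
(10), and CYP inhibition (4). Each task carries:

- a raw quantity with units — P_app (10⁻⁶ cm/s), CL_int (µL·min⁻¹·mg⁻¹),
  F_u (fraction unbound), k_obs (min⁻¹), IC₅₀ (µM), LogP/LogD, efflux
  ratio;
- a model-scale transform — log₁₀ for P_app, CL_int, F_u, k_obs and the
  efflux ratio; pIC₅₀ = −log₁₀(IC₅₀ in mol/L), so 1 µM ↦ 6; identity for
  LogP/LogD. %bound PPB readouts are first converted to F_u = 1 − %/100;
- optional low/high risk thresholds on the raw scale. Five tasks carry
  them: P_app > 5 low, ≤ 1.5 high; rat and human CL_int ≤ 100 low,
  > 300 high; k_obs < 0.01 low, > 0.025 high; CYP3A4 IC₅₀ ≥ 10 µM low,
  < 1 µM high. Boundary semantics are exactly as written (CL_int = 100 is
  low risk; k_obs = 0.01 is medium).

The registry ships as YAML (`tpd_qspr/data/tasks.yaml`) and is validated
on load (disjoint risk rules, known groups/quantities/transforms).

## Data ingestion

Censored readouts ('<'/'>') are discarded — mandatorily for permeability,
PPB, LogP and LogD tasks, and by default (configurable) everywhere else —
with per-task audit counts. Replicates are aggregated with the geometric
mean of the raw values; since LogP/LogD are stored as log quantities
(possibly ≤ 0), aggregation is implemented as the arithmetic mean on the
model scale, which coincides with the raw-scale geometric mean for every
log-family task and is the natural convention for the identity-transform
tasks. Per-task dynamic-range limits can be configured; values outside
are excluded. Aggregated values become a sparse compound × task matrix
(rows sorted by compound id, columns by task id) with a boolean
observation mask.

The temporal split assigns compounds registered on or before the cutoff
(default 2021-12-31) to training and later registrations to test, with
per-modality counts reported.

## Model

The regressor is an ensemble of directed-bond message-passing networks
(D-MPNN) with a feed-forward multi-output head, implemented in numpy with
hand-written backpropagation (forward, adjoint, Adam; gradients are
verified against finite differences in the test suite).

- Messages live on directed bonds. Initial state: ReLU(W_i·[x_atom‖x_bond])
  for the bond's source atom features and bond features. Update at each of
  `message_passing_depth` rounds: m_uv = Σ messages entering u excluding
  the reverse bond; h_uv = ReLU(h⁰_uv + W_h·m_uv). Readout: per-atom sum of
  incoming messages, ReLU(W_o·[x_atom‖·]), then the **arithmetic mean over
  atoms** forms the molecular vector (mean aggregation).
- Atom features: one-hot element (C, N, O, F, P, S, Cl, Br, I, B, Si),
  degree, formal charge, attached-H count, aromaticity and ring flags,
  atomic mass/100. Bond features: one-hot order, conjugation, ring flag.
  Unsupported elements raise, naming the element.
- Head: `ffn_layers` ReLU layers of width `hidden_width`, then one linear
  output per task.
- Loss: masked mean squared error over observed cells only; unobserved
  cells contribute neither loss nor gradient, and an all-masked batch has
  loss exactly 0. Labels are standardized per task (zero mean, unit
  variance on the training portion) and the standardization inverted at
  prediction.
- Optimization: Adam, batch size 50, learning rate warmed up linearly from
  1e-4 to 1e-3 over `warmup_epochs` (default 2) and decayed exponentially
  to 1e-4 at `max_epochs`, the decay rate solved in closed form. Early
  stopping monitors the masked loss on a 10% validation set held out by
  whole Bemis–Murcko scaffold groups (no framework on both sides) and is
  armed only after `min_epochs` (default 12), so a validation plateau
  during warm-up cannot abort training; the best-epoch weights are
  restored.
- Ensembles: members share architecture, task ordering, and the scaffold
  split; they differ by seeded initialization and minibatch order. The
  prediction is the arithmetic mean of member outputs; the member standard
  deviation is reported as spread.

Package defaults (width 300, depth 3, 2 FFN layers, ensemble 5) are
config-exposed. The canned studies in `tpd_qspr.studies` use width 64,
depth 2, one member, and ≤ 45 epochs — sized so a 5000-compound study
trains in about a minute on one core while reaching ~1.1× the analytic
noise floor, which is the regime the study conclusions need.

## Decision layer and metrics

Numeric predictions (or measurements) are categorized per task into low
risk / inconclusive (medium) / high risk by the raw-scale thresholds;
model-scale inputs are back-transformed first. Tasks without thresholds
return "not applicable". Reported metrics:

- MAE on model scale (Σ|y−ŷ|/n);
- opposite-extreme misclassification: error_low = % of predicted-low
  compounds whose measured class is high (and symmetrically error_high);
  measured-medium compounds sit in the denominator but never in the
  numerator. A flag switches to denominators that exclude measured-medium
  compounds entirely;
- precision per class, with any non-matching measured class (including
  medium) counted as a false positive;
- the inconclusive fraction: % of predictions in the medium band.

Empty denominators (no predictions in a class) report 0 alongside an
explicit n_pred = 0 flag rather than NaN.

Evaluation is stratified by modality (glues, heterobifunctionals, other,
and pooled); strata with fewer than five labeled test compounds are
skipped and listed in the report's audit. Each scored stratum carries a
bootstrap distribution of the MAE — compounds (prediction/label pairs)
resampled with replacement, n = 1000, seeded — summarized by quartiles
and 1.5·IQR whiskers, plus the constant baseline that predicts each
task's training-set mean.

## Refinement and distillation

Fine-tuning warm-starts every member from the original weights and
continues training on a refinement subset with all layers trainable, the
learning-rate schedule scaled down 10× with a 1-epoch warm-up, and a
fresh scaffold validation split drawn inside the subset. Label
standardization statistics are reused from the original model so the
warm-started weights keep seeing labels on their training scale. The
original checkpoint is never mutated. Two subset strategies: all
compounds registered in the window after the original cutoff, or
heterobifunctionals registered through the refinement cutoff. Retraining
runs the ordinary pipeline from fresh initialization on all data through
the new cutoff and is labelled as such in the audit.

Distillation standardizes and deduplicates a structure list, annotates
each unique structure with dense teacher predictions for all tasks
(unparsable entries go to a rejects file and the run continues), trains a
student with the teacher's architecture on the dense pseudo-labels, and
reports per-task Pearson/Spearman correlation between student and teacher
on held-out structures; constant prediction vectors are flagged rather
than propagated as NaN correlations.

## Synthetic study generator

The generator emulates the *structure* of an industrial ADME data set,
not its values:

- **Library.** Heterobifunctionals are assembled by SMILES concatenation
  of curated warhead + one-or-two linker + E3-ligand fragments (~650–900
  Da, all beyond Ro5 by molecular weight); glues are medium-size
  imide-style cores with 1–3 decorations (~250–500 Da); "other" compounds
  are generic drug-like cores with decorations. Fragment pools ship in
  the package; every assembly position is validated for free valences and
  all combinations parse (tested). Registration dates are uniform over
  2020-01-01 to 2023-07-13, spanning the 2021-12-31 temporal cutoff.
- **Ground truth.** Each task's noiseless value is a deterministic
  function of the z-scored Ro5 descriptor block: a model-group latent
  factor (tasks within a group share it, which is what multi-task
  learning exploits), a small task-specific linear term, a tanh
  nonlinearity, and additive modality offsets. Offsets encode the
  systematic heterobifunctional behaviour (lower permeability, higher
  clearance, CYP engagement, and LogD). The six standard-study tasks use
  fixed parameters placing class occupancy across all three risk bands;
  other tasks draw seeded parameters.
- **Readouts.** Gaussian noise (sd 0.3 by default) is added on model
  scale and back-transformed; cells are observed with per-task
  probability (0.5–0.9 across the standard tasks); 10% of observations
  get a second replicate; 5% of records are censored into '<'/'>'
  qualifiers; measurement dates trail registration by 0–120 days. All
  randomness flows from a single seed through numpy's PCG64.

Because noise lives on the model scale, the expected held-out MAE of an
oracle that returns the planted truth is exactly E|N(0,σ)| = σ√(2/π)
≈ 0.2394 for σ = 0.3 — an analytic floor for judging trained models.
Replicate aggregation shrinks the effective noise for the ~10% of
replicated observations by 1/√2, so the oracle's pooled estimate sits
~2.9% below the floor; this is a property of aggregation, not a defect.

What the generator does **not** emulate: realistic absolute ADME values
or assay-specific error structure (heteroscedastic, non-Gaussian noise),
correlated missingness (real panels are requested per project, not at
random), activity cliffs, or chemistry outside its fragment pools.
Passing studies therefore demonstrate that the pipeline's machinery —
masked multi-task learning, the decision layer, temporal evaluation,
fine-tuning, distillation — behaves correctly and in the directions the
underlying science predicts, not that any particular accuracy will be
achieved on real assay data.

## Study designs

- **Standard study**: 5000 compounds (30% heterobifunctional, 35% glue,
  35% other), the six standard tasks (the five thresholded endpoints plus
  LogD, spanning all four model groups), σ = 0.3. Checks: oracle within
  5% of the analytic floor; trained model between the floor and twice the
  floor; model strictly below the training-mean baseline on every task.
- **Fine-tuning study**: heterobifunctionals down-weighted to 2% of a
  4000-compound library; original model trained pre-cutoff; strategy-2
  fine-tuning on heterobifunctionals through 2022-06-30; compared on
  later heterobifunctionals over three seeds (direction: fine-tuning
  reduces MAE on at least 5 of 6 tasks).
- **Distillation study**: 20 000 unique surrogate structures (the
  generator is oversampled and deduplicated), student of identical
  architecture trained on dense teacher labels, fidelity measured on
  2000 disjoint held-out structures (expected per-task Pearson r ≥ 0.9;
  observed ~0.97–0.996).

## Numerical conventions and edge cases

- Tanimoto distance of two all-zero fingerprints is defined as 0
  (maximally similar) with a warning, avoiding 0/0.
- MACCS keys are exposed as 166 bits (RDKit's never-set bit 0 dropped).
- Acyclic molecules map to a designated empty-scaffold key and form one
  scaffold group in splits.
- Standardization order is fixed: explicit-H removal, metal
  disconnection, normalization, reionization, optional largest-fragment
  desalting (off by default), stereochemistry assignment,
  canonicalization; the cascade is idempotent.
- Beyond-Ro5 defaults to Lipinski's "more than one violation" of
  MW ≤ 500, cLogP ≤ 5, HBD ≤ 5, HBA ≤ 10; a single-violation variant is
  configurable.
- UMAP embeds deduplicated fingerprints under a precomputed Tanimoto
  distance matrix (duplicates then share coordinates exactly);
  n_neighbors/min_dist are config-exposed and n_neighbors is clipped for
  small inputs.
- The pipeline derives per-stage seeds from the global seed via named
  `SeedSequence` keys; stage manifests record config and artifact hashes,
  and an unchanged config reuses cached artifacts.

## Known limitations

- The numpy implementation is single-core and sized for studies of
  10³–10⁴ molecules; it is not a GPU-scale training stack.
- Ensemble spread is the only uncertainty signal; no calibration is
  attempted.
- The surrogate/distillation path annotates generated structures, not an
  actual public-database extract.
- Hyperparameters are fixed at sensible defaults; no search framework is
  included.
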