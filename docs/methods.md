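# Methods

This note describes the models and procedures implemented in `planxai`, the
assumptions behind them, the tunable parameters that matter, and the design
choices made where the design was genuinely open.

## The planning environment

### Inverse-planning objective

The environment emulates a treatment planning system (TPS) for
intensity-modulated radiotherapy at desk scale.  A planning case consists of
a 2-D voxel grid with three structures — one planning target volume (PTV)
and two organs at risk (OARs), a bladder and a rectum — a non-negative
dose-deposition matrix `M` (Gy per unit fluence), and a prescription dose
`d_p` (default 79.2 Gy).  Given a beamlet fluence vector `x >= 0`, the dose
is `d = M x` and the fluence-map objective is

```
F(x) = λ_PTV [ Σ_{v∈PTV} (d_v − d_p)_−²  +  Σ_{v∈S_PTV} (d_v − t_PTV d_p)_+² ]
     + Σ_{i∈{BLA,REC}} λ_i Σ_{v∈S_i} (d_v − t_i d_p)_+²
```

with `(a)_− = min(a, 0)`, `(a)_+ = max(a, 0)`.  The nine treatment planning
parameters (TPPs) are the weights `λ_PTV, λ_BLA, λ_REC`, the upper dose
thresholds `t_PTV, t_BLA, t_REC` (stored as fractions of `d_p`, so cases
with different prescriptions share TPP semantics), and the allowed volume
fractions `V_PTV, V_BLA, V_REC`.  Raw sums (not per-voxel averages) are
used; only relative objective values matter to the optimizer, and the
λ-rescaling invariance test pins this down.

### Dose-volume constraint handling

The volume parameters enter through voxel selection `S_i`: among the voxels
of structure `i` whose dose exceeds `t_i·d_p`, the highest-dose fraction
`V_i` of the structure's volume is allowed to remain above the threshold
un-penalized; the remaining (lowest-dose) violators are selected for
penalization.  This is the standard DVH-constraint heuristic: the voxels
closest to the threshold are the cheapest to pull below it.  Selection is
refreshed on every outer round.  The selection makes the problem piecewise
(and non-convex across selections); ties and the `V_i`-fraction allowance
mean the minimizer is not always unique, which matters for oracle tests
(see *Numerical choices*).

### Solver

Fluence optimization alternates voxel re-selection (20 outer rounds) with
projected Barzilai–Borwein gradient descent on the fixed-selection
subproblem (50 inner steps, monotone backtracking safeguard, `x >= 0` by
clipping).  The initial step size comes from a Lipschitz estimate
`2 λ_tot ||M||_F²`, which makes the iterates invariant under a common
rescaling of the three weights.  Stopping: relative objective change below
`1e-6` with an unchanged selection.  The `converged` flag additionally
requires a small projected-gradient norm.  Everything is deterministic
given the case, the TPPs and the (optional) warm start; episode loops
warm-start each re-optimization from the previous plan.

### Synthetic cases

`generate_case(seed, overlap_level, size)` builds a 20×20 grid (400 voxels,
30 beamlets; `medium` is 30×30 / 48) with a jittered central PTV disk and
OAR voxel sets sampled above/below it.  `overlap_level` sets the fraction
of each OAR's voxels lying within one voxel (Chebyshev) of the PTV,
emulating the anatomical PTV–OAR overlap spread of a prostate cohort.  The
dose matrix uses straight pencil beams from 5 equispaced gantry angles × 6
lateral offsets aimed through the PTV, with a Gaussian lateral profile
(σ = 1.2 voxels) and exponential depth attenuation (μ = 0.035 per voxel).
Every PTV voxel is irradiable by construction.  What this phantom does
*not* emulate: 3-D scatter, heterogeneity corrections, realistic organ
shapes, couch/beam geometry, or clinical dose engines — only DVH-level
behavior is meaningful, which is all the downstream analysis consumes.
Full plan score is attainable for favorable (low-overlap) geometries and
becomes progressively harder as overlap grows; tests passing on this
phantom demonstrate the *pipeline's* correctness and the qualitative
training trends, not clinical planning performance.

## Plan evaluation

DVH curves are sampled at 100 uniform points on relative dose `[0, 1.2]`;
the network input is the concatenation `[PTV, bladder, rectum]` (300
values in `[0, 1]`).  Plans are scored against a criterion table in the
style of criterion-based plan-quality systems, with a maximum of 9 points:

| Structure | Criterion | Points |
|---|---|---|
| PTV | V(0.95 d_p) ≥ 0.95 | 2 |
| PTV | V(1.07 d_p) ≤ 0.10 | 1 |
| Bladder | V(0.6 d_p) ≤ 0.50, V(0.8 d_p) ≤ 0.30, V(0.9 d_p) ≤ 0.15 | 1 each |
| Rectum | V(0.6 d_p) ≤ 0.45, V(0.8 d_p) ≤ 0.25, V(0.9 d_p) ≤ 0.10 | 1 each |

The exact clinical criteria of the commercial scoring system are not
public; this table mirrors its structure (graded OAR dose-volume limits,
target coverage plus hot-spot control, total 9) and is fully overridable
through `scoring.criteria` in the run configuration.  Criterion evaluation
interpolates the DVH linearly.  The per-criterion *dose violation* is the
volume-fraction excess beyond the limit (`max(0, observed − limit)` for
upper limits, mirrored for coverage); organ violation is the sum over that
organ's criteria, so a violation is zero exactly when the criterion passes.

## The tuning agent

The policy space has 18 discrete actions: increase or decrease each TPP by
a fixed step (λ: 0.15 on [0.05, 5]; t: 0.05 on [0.5, 1.2]; V: 0.05 on
[0.05, 0.95]); values clip at the bounds.  Initial TPPs default to
mid-range.  These grids are package defaults chosen to give a planning
problem that is genuinely unsolved at initialization yet solvable within a
few tens of steps.

The network is `dvh(300) → dense tanh(64) → LSTM(32) → {policy softmax(18),
Q(18)}`, implemented directly in numpy with exact analytic forward and
backward passes.  The agent observes only the DVH, so tuning is a
partially observed decision process and the LSTM memory (c, h) carries
state across steps.  The backward pass doubles as the gradient oracle for
attribution (below); finite-difference tests pin both input and parameter
gradients to ~1e-7.

Training is on-policy advantage actor-critic with entropy regularization —
a deliberate simplification of the actor-critic-with-experience-replay
algorithm that produced the original agents.  Per step: immediate reward =
Δ(total score) − 0.05 step penalty, +1 terminal bonus at the full score;
TD(0) target `y = r + γ V(s')` with `V(s) = Σ_j p_j q_j`; advantage
`y − V(s)` drives the policy head, `(q_a − y)²` the Q head; Adam
(lr 1e-3), entropy bonus β = 0.01, γ = 0.95, gradient-norm clip 5.
Backpropagation treats each step's incoming memory as a constant
(truncation horizon 1) — adequate at this scale and keeps the trainer
simple and exactly reproducible.  Checkpoints are snapshots of all
parameters every `checkpoint_every` environment steps; an optional
untrained step-0 snapshot anchors learning-progress comparisons.

Greedy rollouts are deterministic end-to-end; stochastic rollouts draw
from a dedicated per-episode substream, so traces are bit-reproducible.
Checkpoint evaluation can jitter the initial TPPs by up to ±2 lattice
steps per parameter (seeded) so that greedy rollouts probe distinct
starting conditions.

## Integrated-gradients attribution

For `F_j` = post-softmax probability of action `j` (the probability, not
the logit, is the quantity the policy acts on), the attribution of input
feature `i` against baseline `x'` is

```
IG_ij = (x_i − x'_i) ∫₀¹ ∂F_j(x' + α(x − x')) / ∂x_i dα
```

All three inputs (DVH, c, h) are scaled along one joint straight path from
their baselines, so completeness — `Σ_i IG_ij = F_j(x) − F_j(x')` over the
concatenated inputs — holds for a single path.  The integral uses
trapezoid quadrature (default 256 intervals; all path points evaluated in
one batched backward pass).  The completeness residual is stored on every
record, making quadrature adequacy observable rather than assumed: at 1024
intervals residuals sit well below 1e-4 on random networks; 2-interval
quadrature demonstrably fails tight tolerances.  Baselines default to all
zeros ("complete absence of planning signal").  The offset-sensitivity
analysis shifts only the OAR baseline entries (0.005, 0.01; PTV entries
stay zero so the baseline never violates target coverage) and compares
300-value DVH heatmaps against the zero-baseline ones by cosine
similarity, grouped by the step's leading action.  Cosine with a zero
vector is defined as 0; cosine values are clipped to [−1, 1] so identical
heatmaps report exactly 1.

Heatmaps are summarized in 30 segments of 10 consecutive DVH points
(segments 0–9 PTV, 10–19 bladder, 20–29 rectum); segment sums conserve the
total exactly.  The *leading action* for an input source is the action
with the highest total attribution from that source, ties broken toward
the lowest action index.

## Interpretation metrics

* **Organ-wise similarity.**  Per step `i` and action `j`, the attribution
  vector `A_ij` holds the three organ-block sums of the DVH attribution and
  the reward vector `R_ij` the counterfactual organ-wise immediate reward:
  mode 1 = per-organ score change, mode 2 = per-organ violation *reduction*
  (before − after, so mitigation is positive).  Each counterfactual applies
  action `j` to the step's pre-action TPPs, re-optimizes (warm-started) and
  rescores; a bound-clipped action leaves the TPPs unchanged and scores an
  exact zero vector.  The per-plan index is
  `Similarity = (1/N) Σ_i Σ_j p_ij cos(A_ij, R_ij)`, in [−1, 1].
* **Entropy.**  `−(1/N) Σ_i Σ_j p_ij ln p_ij`, in [0, ln 18 ≈ 2.8904];
  lower entropy = more decisive policies.
* **Ideal planning steps.**  `Σ_p round(|final_p − initial_p| / δ_p)` — the
  minimal monotonic one-directional adjustment count, which equals the
  shortest path on the 18-action lattice (verified against breadth-first
  search).  Actual steps may exceed it (back-and-forth tuning) or, near
  bounds, undershoot via clipping, so no inequality is asserted.
* **Memory probe.**  Eight scenarios set each organ's DVH block to all ones
  ("violation") or zeros ("conserved"); memory is reset per scenario and
  the same input processed ten times so the memory evolves, yielding 80 c
  and 80 h vectors (unit-normalized) with scenario labels, embedded by
  t-SNE (perplexity 8, cosine metric, PCA initialization, learning rate
  50).  A within- versus between-scenario cosine-distance summary
  quantifies clustering without relying on the stochastic embedding.
* **Cohort report.**  Per checkpoint: initial/final score mean ± std,
  full-score plan count, actual and ideal steps over full-score plans,
  similarity and entropy distributions, and the TPP-space summary
  (multisets of final TPP values over full-score plans).  Across
  checkpoints, the correlation between mean mode-2 similarity and mean
  planning steps is reported as both Pearson and Spearman (a strong
  negative correlation is the expected signature of efficient agents).
  Statistical significance testing of step counts (linear mixed model) is
  delegated to `statsmodels` behind the optional hook
  `planning_steps_mixed_model`; no bespoke statistics are implemented.

## Numerical choices and degenerate inputs

* Solver tolerances: `rel_tol 1e-6`, 20×50 iterations by default; oracle
  and invariance tests tighten to `1e-12…1e-14` because the piecewise
  objective has nearly flat directions — the objective converges orders of
  magnitude faster than the argmin.
* The DVH-selection allowance makes some optima non-unique (an "allowed"
  violator feels no gradient).  Counterfactual-reward oracle tests
  therefore use a toy case with crossfire coupling and all penalties
  active, where the minimizer is strictly unique; on the full phantom,
  rewards are defined by the deterministic warm-started procedure itself.
* `0 · ln 0 = 0` in the entropy; probability rows are validated to sum to
  1 within 1e-6.
* Off-lattice final TPPs (beyond 1e-3 step units) raise an error rather
  than silently rounding.
* Attribution of the Q head is out of scope; only the policy head is
  attributed.

## Scaled-down study conditions

The reference protocol interprets agents trained for 1e5–2e5 steps on a
single designated clinical case.  At desk scale this package mirrors
that: the trend study (`planxai.studies.run_trend_study`) trains on one
*designated* synthetic case — a fixed study input
(`generate_case(1, overlap_level=0.2)`, mid-cohort difficulty) — for
24 000 environment steps with checkpoints every 6 000 steps plus the
untrained snapshot.  Sizes were chosen once so that (a) score improvement
saturates within the budget and (b) the attribution–violation alignment,
which emerges later in training than raw score gains, is measurable at
every trained checkpoint.  The alignment strength varies across random
phantom geometries (some geometries yield near-zero similarity even for
well-trained toy agents), which is why the study pins the case and the
seed argument drives only training and evaluation randomness.
Evaluation uses 20 jittered greedy episodes per checkpoint and stochastic
episodes for the similarity/entropy analyses.  The "best" checkpoint is
the highest-scoring one, with scores within half a point of the maximum
treated as ties and resolved toward the most-trained checkpoint (score
plus maturity, as in the reference agent selection).  The end-to-end
trend assertions are deliberately modest — mean final score not
decreasing from the untrained to the last checkpoint across 3 training
seeds, positive mode-2 similarity of the best checkpoint, and a
*reported* (not asserted) sign for the similarity-versus-steps
correlation — because individual training runs at this scale are noisy;
at the step cap most toy episodes do not terminate early, so the
correlation can be undefined (constant step counts) and is then reported
neutrally.

## Known limitations

* The phantom's 2-D pencil-beam physics cannot reproduce clinical DVH
  shapes quantitatively; all quantitative results are properties of the
  synthetic environment.
* The simplified actor-critic trainer (no experience replay correction,
  no trust region, truncation horizon 1) learns far more slowly than the
  original agent; it produces the graded checkpoint progression the
  analysis needs, not clinical-quality planners.
* The criterion table stands in for an unpublished clinical scoring
  system; absolute score values are not comparable to the clinical ones.
* t-SNE embeddings are for visualization; assertions about memory
  clustering use direct cosine-distance statistics instead.
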