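# planxai

Explainable deep reinforcement learning for automatic radiotherapy
treatment planning, at desk scale.

## The problem

In inverse planning for intensity-modulated radiotherapy (IMRT), a
treatment planning system (TPS) optimizes beamlet fluences `x ≥ 0`
(dose `d = M x`) against clinician goals — target coverage and organ-at-
risk (OAR) sparing — encoded as weighted penalty terms.  How those goals
trade off is controlled by *treatment planning parameters* (TPPs):
per-structure weights `λ`, dose thresholds `t`, and allowed volume
fractions `V`.  Human planners adjust TPPs by trial and error; a
reinforcement-learning agent can automate that loop, observing the
dose-volume histogram (DVH) of an intermediate plan and issuing discrete
TPP-tuning actions until the plan satisfies criterion-based quality
scoring (maximum 9 points here).  But such agents are black boxes.

`planxai` is a self-contained pipeline for *interpreting* such an agent:

* **`planxai.phantom`** — a synthetic 2-D IMRT environment: phantom cases
  (PTV, bladder, rectum with controllable PTV–OAR overlap), a pencil-beam
  dose matrix, and a deterministic DVH-constrained fluence-map optimizer.
* **`planxai.dvh`** — DVH extraction (100 relative-dose points per
  structure; 300-value network input) and criterion-table plan scoring
  with per-organ dose-violation magnitudes.
* **`planxai.agent`** — an 18-action tuning agent (±fixed step per TPP)
  built on a numpy LSTM policy/value network, episode rollout, and
  simplified actor-critic training with parameter checkpoints.
* **`planxai.ig`** — integrated-gradients attribution from the three
  inputs (DVH, LSTM memory c and h) to any action's policy probability,

  `IG_ij = (x_i − x'_i) ∫₀¹ ∂F_j(x' + α(x − x'))/∂x_i dα`,

  with completeness auditing (`Σ_i IG_ij = F_j(x) − F_j(x')`), policy
  decomposition, 30-segment heatmaps, and baseline-offset sensitivity.
* **`planxai.metrics`** — the interpretation suite: organ-wise
  attribution–reward cosine similarity
  `(1/N) Σ_i Σ_j p_ij cos(A_ij, R_ij)`, normalized policy entropy
  `−(1/N) Σ_ij p_ij ln p_ij`, ideal planning-step counts, the LSTM memory
  probe (8 violation scenarios × 10 repeats → t-SNE), and cohort reports
  with the similarity-versus-steps correlation.
* **`planxai.io` / `planxai.cli`** — JSON-lines trace and attribution
  archives, YAML configuration, archive validation, and the `planxai`
  command-line tool (`train`, `plan`, `attribute`, `simulate-cohort`,
  `analyze`, `probe-memory`, `validate`).

See `docs/methods.md` for the models, assumptions and design choices.

## Worked example

```python
import numpy as np
from planxai import (generate_case, train_checkpoints, evaluate_checkpoint,
                     run_episode, CriteriaTable)
from planxai.metrics import analyze_trace

case = generate_case(seed=1, overlap_level=0.2, size="small")
ckpts = train_checkpoints([case], steps=12000, checkpoint_every=3000,
                          seed=1, include_initial=True)

for ck in ckpts:
    traces = evaluate_checkpoint(ck, case, n_episodes=10, mode="greedy",
                                 seed=7, jitter_init=2)
    print(ck.step, np.mean([t.final_score for t in traces]))

net = ckpts[-1].net()
trace = run_episode(case, net, max_steps=20, mode="stochastic", seed=3)
pa = analyze_trace(trace, case, net, CriteriaTable.default(), path_steps=32)
print(f"final score {trace.final_score}, steps {trace.n_steps}, "
      f"similarity(mode 2) {pa.similarity_mode2:.3f}, "
      f"entropy {pa.entropy:.3f}")
```

prints (exact numbers vary with the seed):

```
0 5.0
3000 6.3
6000 6.3
9000 6.3
12000 6.3
final score 6.0, steps 20, similarity(mode 2) 0.158, entropy 2.436
```

Reading: the untrained snapshot plans at a mean score of 5.0/9; training
raises the mean greedy score by about one point at this toy scale.  For
the most-trained checkpoint, the positive mode-2 similarity says that,
averaged over its policy, the organ-wise DVH attributions of its actions
point in the same direction as the organ-wise dose-violation *reductions*
those actions actually achieve — the agent promotes actions because of
the violations they mitigate.  The entropy (≤ ln 18 ≈ 2.89) quantifies
how concentrated its policy has become.

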