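"""Quantitative interpretation suite for tuning agents.

Connects attribution to planning behavior:

* organ-wise attribution vectors (PTV, bladder, rectum sums of the DVH
  attributions) versus organ-wise immediate reward vectors, combined into a
  probability-weighted cosine-similarity index per plan,

      Similarity = (1/N) sum_i sum_j p_ij cos(A_ij, R_ij)

  with reward mode 1 = per-organ score change and mode 2 = per-organ dose-
  violation reduction;

* the per-plan normalized policy entropy

      Entropy = -(1/N) sum_i sum_j p_ij ln p_ij   in [0, ln 18];

* the 'ideal' number of planning steps: the minimal count of monotonic
  one-directional fixed-step TPP adjustments from the initial to the final
  TPP vector;

* an LSTM memory probe over the eight organ-violation scenarios, producing
  80 c and 80 h vectors for t-SNE clustering;

* cohort-level reports with the similarity-versus-steps correlation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from . import dvh as dvh_mod
from .agent import (EpisodeStep, EpisodeTrace, apply_action,
                    build_action_space)
from .ig import (AttributionRecord, BaselineSpec, ORGAN_SLICES, cosine,
                 integrated_gradients)
from .network import N_ACTIONS, PolicyValueNet
from .phantom import (OptimizerConfig, PhantomCase, TPPVector,
                      optimize_fluence, STRUCTURES)

MAX_ENTROPY = float(np.log(N_ACTIONS))


def organ_attribution(record: AttributionRecord) -> np.ndarray:
    """Sum the 300 DVH attributions per organ -> (PTV, BLA, REC)."""
    if record.ig_dvh.shape != (300,):
        raise ValueError("record must hold 300 DVH attributions")
    return np.array([record.ig_dvh[ORGAN_SLICES[s]].sum() for s in STRUCTURES])


def reward_vectors(step: EpisodeStep, case: PhantomCase,
                   criteria: dvh_mod.CriteriaTable, mode: int,
                   opt_config: OptimizerConfig = OptimizerConfig()
                   ) -> np.ndarray:
    """Counterfactual organ-wise immediate rewards, shape (18, 3).

    For every action, the step's pre-action TPPs are perturbed, the plan is
    re-optimized (warm-started from the pre-action plan) and rescored.
    Mode 1: organ score after minus before.  Mode 2: organ dose violation
    before minus after, so that a violation *reduction* is positive.  An
    action clipped at a parameter bound leaves the TPPs unchanged and gets
    an exactly zero vector.
    """
    if mode not in (1, 2):
        raise ValueError("reward mode must be 1 or 2")
    actions = build_action_space(step.tpps_before)
    before_curves = dvh_mod.plan_dvhs(case, step.plan_before)
    before = dvh_mod.score_plan(before_curves, criteria)
    out = np.zeros((N_ACTIONS, 3))
    for j, act in enumerate(actions):
        tpps_j = apply_action(step.tpps_before, act)
        if np.array_equal(tpps_j.values, step.tpps_before.values):
            continue  # clipped: re-optimization is idempotent
        plan_j = optimize_fluence(case, tpps_j, warm_start=step.plan_before,
                                  config=opt_config)
        after = dvh_mod.score_plan(dvh_mod.plan_dvhs(case, plan_j), criteria)
        if mode == 1:
            out[j] = after.scores_vector - before.scores_vector
        else:
            out[j] = before.violations_vector - after.violations_vector
    return out


def similarity(probs: np.ndarray, attributions: np.ndarray,
               rewards: np.ndarray) -> float:
    """Probability-weighted mean cosine similarity between per-step
    per-action attribution and reward vectors.

    ``probs`` (N, 18), ``attributions`` and ``rewards`` (N, 18, 3).  The
    cosine with a zero vector is defined as 0.
    """
    probs = np.asarray(probs, float)
    A = np.asarray(attributions, float)
    R = np.asarray(rewards, float)
    n = probs.shape[0]
    if A.shape[:2] != probs.shape or R.shape[:2] != probs.shape:
        raise ValueError("shape mismatch between probs and vectors")
    if n == 0:
        raise ValueError("empty plan")
    na = np.linalg.norm(A, axis=2)
    nr = np.linalg.norm(R, axis=2)
    dot = (A * R).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where((na > 0) & (nr > 0), dot / (na * nr), 0.0)
    cos = np.clip(cos, -1.0, 1.0)
    return float((probs * cos).sum() / n)


def entropy(probs: np.ndarray, tol: float = 1e-6) -> float:
    """Normalized policy entropy -(1/N) sum_ij p_ij ln p_ij, with
    0 ln 0 = 0.  Rows must be probability distributions."""
    probs = np.asarray(probs, float)
    if probs.ndim != 2 or probs.shape[0] == 0:
        raise ValueError("expected a nonempty (N, 18) probability matrix")
    if np.any(np.abs(probs.sum(axis=1) - 1.0) > tol) or np.any(probs < -tol):
        raise ValueError("rows are not probability distributions")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log(probs), 0.0)
    return float(-plogp.sum() / probs.shape[0])


def ideal_steps(initial: TPPVector, final: TPPVector,
                lattice_tol: float = 1e-3) -> int:
    """Minimal number of monotonic one-directional fixed-step adjustments
    from the initial to the final TPP vector."""
    diff = np.abs(final.values - initial.values)
    k = diff / initial.delta
    if np.any(np.abs(k - np.round(k)) > lattice_tol):
        raise ValueError("final TPPs are off the tuning lattice")
    return int(np.round(k).sum())


# ---------------------------------------------------------------------------
# Memory probe
# ---------------------------------------------------------------------------

PROBE_SCENARIOS = ("none", "PTV", "BLA", "REC", "PTV+BLA", "PTV+REC",
                   "BLA+REC", "all")


def memory_probe(net: PolicyValueNet, repeats: int = 10
                 ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Probe the LSTM memory with the eight organ-violation scenarios.

    Each scenario sets each organ's 100-value DVH block to all ones
    ('violation') or all zeros ('conserved').  Memory is reset per scenario
    and the same input is processed ``repeats`` times so the memory evolves;
    the c and h vectors after each application are collected and normalized
    to unit length.  Returns (C, H, labels) with 8 * repeats rows each.
    """
    organs = ("PTV", "BLA", "REC")
    C, H, labels = [], [], []
    for name in PROBE_SCENARIOS:
        active = set() if name == "none" else set(organs) if name == "all" \
            else set(name.split("+"))
        x = np.zeros(300)
        for organ in active:
            x[ORGAN_SLICES[organ]] = 1.0
        memory = net.zero_memory()
        for _ in range(repeats):
            out = net.forward(x, memory)
            memory = out.new_memory
            C.append(_unit(memory.c))
            H.append(_unit(memory.h))
            labels.append(name)
    return np.array(C), np.array(H), labels


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    return v / n if n > 0 else v.copy()


def tsne_embed(vectors: np.ndarray, seed: int = 0) -> np.ndarray:
    """2-D t-SNE embedding with perplexity 8, cosine metric, PCA
    initialization and learning rate 50."""
    from sklearn.manifold import TSNE
    return TSNE(n_components=2, perplexity=8, metric="cosine", init="pca",
                learning_rate=50, random_state=seed).fit_transform(vectors)


def probe_separation(vectors: np.ndarray, labels: list[str]) -> dict[str, float]:
    """Mean within- versus between-scenario cosine distance."""
    labels_arr = np.asarray(labels)
    sim = vectors @ vectors.T
    norm = np.linalg.norm(vectors, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = sim / np.outer(norm, norm)
    dist = 1.0 - np.nan_to_num(sim)
    same = labels_arr[:, None] == labels_arr[None, :]
    off_diag = ~np.eye(len(labels_arr), dtype=bool)
    return {"within": float(dist[same & off_diag].mean()),
            "between": float(dist[~same].mean())}


# ---------------------------------------------------------------------------
# Per-plan and cohort analysis
# ---------------------------------------------------------------------------

@dataclass
class PlanAnalysis:
    case_id: str
    checkpoint: str
    initial_score: float
    final_score: float
    n_steps: int
    full_score: bool
    ideal_steps: int
    entropy: float
    similarity_mode1: float
    similarity_mode2: float


def analyze_trace(trace: EpisodeTrace, case: PhantomCase,
                  net: PolicyValueNet, criteria: dvh_mod.CriteriaTable,
                  checkpoint: str = "", path_steps: int = 64,
                  opt_config: OptimizerConfig = OptimizerConfig(),
                  baseline: BaselineSpec | None = None) -> PlanAnalysis:
    """Full interpretation of one planning episode: per-step attributions
    for all actions, counterfactual rewards under both modes, and the
    similarity/entropy indices."""
    max_points = criteria.total_points
    if trace.n_steps == 0:
        return PlanAnalysis(trace.case_id, checkpoint,
                            trace.initial_score.total, trace.final_score,
                            0, trace.final_score >= max_points, 0,
                            float("nan"), float("nan"), float("nan"))
    baseline = baseline or BaselineSpec.zero(hidden=net.hidden)
    probs = trace.probs_matrix()
    A = np.zeros((trace.n_steps, N_ACTIONS, 3))
    R1 = np.zeros_like(A)
    R2 = np.zeros_like(A)
    for i, step in enumerate(trace.steps):
        for j in range(N_ACTIONS):
            rec = integrated_gradients(net, step.dvh_input,
                                       step.memory_in.c, step.memory_in.h,
                                       baseline, j, path_steps)
            A[i, j] = organ_attribution(rec)
        R1[i] = reward_vectors(step, case, criteria, 1, opt_config)
        R2[i] = reward_vectors(step, case, criteria, 2, opt_config)
    return PlanAnalysis(
        case_id=trace.case_id, checkpoint=checkpoint,
        initial_score=trace.initial_score.total,
        final_score=trace.final_score,
        n_steps=trace.n_steps,
        full_score=trace.final_score >= max_points,
        ideal_steps=ideal_steps(trace.initial_tpps, trace.final_tpps),
        entropy=entropy(probs),
        similarity_mode1=similarity(probs, A, R1),
        similarity_mode2=similarity(probs, A, R2),
    )


@dataclass
class TPPSpaceSummary:
    initial: np.ndarray
    final_values: list[Counter] = field(default_factory=list)  # one per TPP
    ideal_steps: list[int] = field(default_factory=list)


def tpp_space_summary(traces: list[EpisodeTrace],
                      max_points: float = 9.0) -> TPPSpaceSummary:
    """Final TPP configurations of the full-score plans, as per-parameter
    value multisets, plus their ideal step counts."""
    full = [t for t in traces if t.final_score >= max_points]
    if not traces:
        raise ValueError("empty cohort")
    initial = traces[0].initial_tpps.values
    counters = [Counter() for _ in range(9)]
    ideals = []
    for t in full:
        for k, v in enumerate(t.final_tpps.values):
            counters[k][round(float(v), 6)] += 1
        ideals.append(ideal_steps(t.initial_tpps, t.final_tpps))
    return TPPSpaceSummary(initial=initial, final_values=counters,
                           ideal_steps=ideals)


@dataclass
class CheckpointSummary:
    checkpoint: str
    n_plans: int
    initial_score_mean: float
    initial_score_std: float
    final_score_mean: float
    final_score_std: float
    n_full_score: int
    steps_mean: float          # over full-score plans; nan if none
    steps_std: float
    ideal_steps_mean: float
    ideal_steps_std: float
    similarity_mode1_mean: float
    similarity_mode2_mean: float
    entropy_mean: float


@dataclass
class AnalysisReport:
    summaries: list[CheckpointSummary]
    pearson_r: float
    pearson_p: float
    spearman_r: float
    spearman_p: float


def cohort_report(analyses: list[PlanAnalysis]) -> AnalysisReport:
    """Aggregate per-plan analyses per checkpoint and correlate the
    checkpoint-level mean mode-2 similarity with the mean step count."""
    if not analyses:
        raise ValueError("empty cohort")
    by_ckpt: dict[str, list[PlanAnalysis]] = {}
    for a in analyses:
        by_ckpt.setdefault(a.checkpoint, []).append(a)
    summaries = []
    for name, group in sorted(by_ckpt.items()):
        full = [a for a in group if a.full_score]
        def ms(vals):
            vals = [v for v in vals if np.isfinite(v)]
            return (float(np.mean(vals)), float(np.std(vals))) if vals \
                else (float("nan"), float("nan"))
        sm, ss = ms([a.n_steps for a in full])
        im, istd = ms([a.ideal_steps for a in full])
        summaries.append(CheckpointSummary(
            checkpoint=name, n_plans=len(group),
            initial_score_mean=ms([a.initial_score for a in group])[0],
            initial_score_std=ms([a.initial_score for a in group])[1],
            final_score_mean=ms([a.final_score for a in group])[0],
            final_score_std=ms([a.final_score for a in group])[1],
            n_full_score=len(full),
            steps_mean=sm, steps_std=ss,
            ideal_steps_mean=im, ideal_steps_std=istd,
            similarity_mode1_mean=ms([a.similarity_mode1 for a in group])[0],
            similarity_mode2_mean=ms([a.similarity_mode2 for a in group])[0],
            entropy_mean=ms([a.entropy for a in group])[0],
        ))
    sims = [s.similarity_mode2_mean for s in summaries]
    steps = [np.nanmean([a.n_steps for a in by_ckpt[s.checkpoint]])
             for s in summaries]
    mask = np.isfinite(sims) & np.isfinite(steps)
    if mask.sum() >= 2 and len(set(np.asarray(sims)[mask])) > 1:
        pr = sps.pearsonr(np.asarray(sims)[mask], np.asarray(steps)[mask])
        sr = sps.spearmanr(np.asarray(sims)[mask], np.asarray(steps)[mask])
        pearson_r, pearson_p = float(pr.statistic), float(pr.pvalue)
        spearman_r, spearman_p = float(sr.statistic), float(sr.pvalue)
    else:
        pearson_r = pearson_p = spearman_r = spearman_p = float("nan")
    return AnalysisReport(summaries=summaries, pearson_r=pearson_r,
                          pearson_p=pearson_p, spearman_r=spearman_r,
                          spearman_p=spearman_p)


def analyses_frame(analyses: list[PlanAnalysis]):
    """Per-plan report rows (one row per plan) as a DataFrame."""
    import pandas as pd
    return pd.DataFrame([vars(a) for a in analyses])


def summary_frame(report: AnalysisReport):
    """One summary row per checkpoint as a DataFrame."""
    import pandas as pd
    return pd.DataFrame([vars(s) for s in report.summaries])


def write_report(analyses: list[PlanAnalysis], report: AnalysisReport,
                 directory) -> None:
    """Write the cohort report: per-plan CSV, per-checkpoint summary CSV,
    and a JSON summary with the correlations."""
    import json
    from pathlib import Path
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    analyses_frame(analyses).to_csv(d / "plans.csv", index=False)
    summary_frame(report).to_csv(d / "checkpoints.csv", index=False)
    payload = {"pearson_r": report.pearson_r, "pearson_p": report.pearson_p,
               "spearman_r": report.spearman_r,
               "spearman_p": report.spearman_p}
    (d / "summary.json").write_text(json.dumps(payload, indent=1))


def planning_steps_mixed_model(df):
    """Optional hook: linear mixed model of planning steps by checkpoint
    with a per-case random intercept, via statsmodels.  Requires columns
    ``n_steps``, ``checkpoint``, ``case_id``."""
    import statsmodels.formula.api as smf
    model = smf.mixedlm("n_steps ~ C(checkpoint)", df, groups=df["case_id"])
    return model.fit()
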