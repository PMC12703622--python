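"""Scaled-down end-to-end interpretation study.

Reproduces, at desk scale, the study design used to interpret checkpoint
agents: train on one case, snapshot checkpoints across training, evaluate
each checkpoint's planning effectiveness, and compute the
attribution-reward similarity of the best checkpoint together with the
checkpoint-level similarity-versus-steps correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from . import agent as agent_mod
from . import dvh as dvh_mod
from . import metrics as metrics_mod
from .phantom import generate_case


@dataclass
class TrendStudy:
    """Results of one scaled-down training-trend study."""

    seeds: list[int]
    checkpoint_steps: list[int]
    #: mean greedy final score per checkpoint, one row per training seed
    scores: np.ndarray
    mean_first_score: float
    mean_last_score: float
    #: index of the best checkpoint per seed
    best_index: list[int]
    #: mean mode-2 similarity of the best checkpoint per seed
    best_similarity: list[float]
    #: (similarity, steps) per (seed, checkpoint) for the correlation
    ckpt_rows: list[tuple[float, float]] = field(default_factory=list)
    correlation: float = float("nan")


def select_best_checkpoint(scores: list[float], tie_band: float = 0.5) -> int:
    """Best checkpoint by mean final score; checkpoints within
    ``tie_band`` points of the maximum count as ties, resolved toward the
    most-trained one (later agents attribute more coherently, so maturity
    is the tie-break)."""
    smax = max(scores)
    return max(i for i, s in enumerate(scores) if s >= smax - tie_band)


def run_trend_study(seed: int, train_steps: int = 24000,
                    checkpoint_every: int = 6000,
                    n_train_seeds: int = 3,
                    n_eval_episodes: int = 20,
                    n_similarity_episodes: int = 4,
                    n_corr_episodes: int = 2,
                    case_seed: int = 1,
                    case_overlap: float = 0.2,
                    episode_max_steps: int = 20,
                    path_steps: int = 32,
                    progress=None) -> TrendStudy:
    """Train ``n_train_seeds`` agents on one small case, evaluate every
    checkpoint with jittered greedy episodes, and analyze similarity.

    The training case is a fixed study input (the original protocol also
    trains on a single designated case); ``seed`` drives the per-seed
    training streams and all evaluation episodes.
    """
    root = np.random.SeedSequence([int(seed), 0x57D1])
    case = generate_case(case_seed, case_overlap, "small")
    criteria = dvh_mod.CriteriaTable.default()

    seeds = [int(s.generate_state(1)[0]) % (2**31)
             for s in root.spawn(n_train_seeds)]
    all_scores, best_idx, best_sims, ckpt_rows = [], [], [], []
    ckpt_steps: list[int] = []
    for si, train_seed in enumerate(seeds):
        ckpts = agent_mod.train_checkpoints(
            [case], steps=train_steps, checkpoint_every=checkpoint_every,
            seed=train_seed, include_initial=True)
        ckpt_steps = [c.step for c in ckpts]
        scores = []
        for ck in ckpts:
            traces = agent_mod.evaluate_checkpoint(
                ck, case, n_episodes=n_eval_episodes, mode="greedy",
                seed=train_seed + 17, jitter_init=2,
                max_steps=episode_max_steps + 10)
            scores.append(float(np.mean([t.final_score for t in traces])))
        all_scores.append(scores)
        bi = select_best_checkpoint(scores)
        best_idx.append(bi)

        def _similarities(ck, base_seed, n_episodes):
            net = ck.net()
            sims, steps = [], []
            for e in range(n_episodes):
                tr = agent_mod.run_episode(
                    case, net, max_steps=episode_max_steps,
                    mode="stochastic", seed=base_seed + e)
                if tr.n_steps:
                    pa = metrics_mod.analyze_trace(tr, case, net, criteria,
                                                   path_steps=path_steps)
                    sims.append(pa.similarity_mode2)
                    steps.append(tr.n_steps)
            return sims, steps

        sims, _ = _similarities(ckpts[bi], 1000 * (si + 1),
                                n_similarity_episodes)
        best_sims.append(float(np.mean(sims)))
        for ci, ck in enumerate(ckpts):
            s_i, n_i = _similarities(ck, 7000 + 1000 * si + 100 * ci,
                                     n_corr_episodes)
            if s_i:
                ckpt_rows.append((float(np.mean(s_i)), float(np.mean(n_i))))
        if progress is not None:
            progress(f"seed {train_seed}: scores={np.round(scores, 2)} "
                     f"best={bi} sim2={best_sims[-1]:.3f}")

    sims = np.array([r[0] for r in ckpt_rows])
    steps = np.array([r[1] for r in ckpt_rows])
    corr = float("nan")
    if len(sims) >= 2 and sims.std() > 0 and steps.std() > 0:
        corr = float(sps.pearsonr(sims, steps).statistic)
    scores_arr = np.array(all_scores)
    return TrendStudy(
        seeds=seeds, checkpoint_steps=ckpt_steps, scores=scores_arr,
        mean_first_score=float(scores_arr[:, 0].mean()),
        mean_last_score=float(scores_arr[:, -1].mean()),
        best_index=best_idx, best_similarity=best_sims,
        ckpt_rows=ckpt_rows, correlation=corr)
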