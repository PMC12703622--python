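"""TPP-tuning agent: action space, episode rollout, and training.

The policy space has 18 actions: each of the 9 treatment planning
parameters can be increased or decreased by its fixed step size (values are
clipped at the parameter bounds).  An episode alternates fluence-map
re-optimization, DVH observation, a network forward pass, and one tuning
action, until the plan reaches the maximum score or a step budget.

Training uses on-policy advantage actor-critic with entropy regularization
— a deliberate simplification of the full actor-critic-with-experience-
replay algorithm that produced the original agents — with immediate reward
equal to the per-step change in plan score minus a small step penalty and a
terminal bonus for a full-score plan.  Backpropagation treats the incoming
LSTM memory of each step as a constant (truncation horizon of one step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dvh as dvh_mod
from .network import MemoryState, N_ACTIONS, PolicyValueNet
from .phantom import (OptimizerConfig, PhantomCase, PlanState, TPPVector,
                      TPP_NAMES, optimize_fluence)


@dataclass(frozen=True)
class ActionSpec:
    index: int
    parameter: str        # one of TPP_NAMES
    direction: int        # +1 or -1
    delta: float


def build_action_space(tpps: TPPVector) -> tuple[ActionSpec, ...]:
    """18 actions: (increase, decrease) for each TPP, in TPP order."""
    actions = []
    for k, name in enumerate(TPP_NAMES):
        for direction in (+1, -1):
            actions.append(ActionSpec(index=len(actions), parameter=name,
                                      direction=direction,
                                      delta=float(tpps.delta[k])))
    return tuple(actions)


def action_label(action: ActionSpec) -> str:
    return f"{'increase' if action.direction > 0 else 'decrease'} {action.parameter}"


def apply_action(tpps: TPPVector, action: ActionSpec) -> TPPVector:
    """Move the target parameter by +/- its step, clipped to its bounds."""
    k = TPP_NAMES.index(action.parameter)
    values = tpps.values.copy()
    values[k] = np.clip(values[k] + action.direction * action.delta,
                        tpps.lo[k], tpps.hi[k])
    return tpps.with_values(values)


@dataclass
class EpisodeStep:
    dvh_input: np.ndarray            # 300-value observation before the action
    memory_in: MemoryState
    probs: np.ndarray                # 18
    q_values: np.ndarray             # 18
    action: int
    tpps_before: TPPVector
    tpps_after: TPPVector
    score_after: dvh_mod.ScoreCard
    plan_before: PlanState
    plan_after: PlanState


@dataclass
class EpisodeTrace:
    case_id: str
    initial_tpps: TPPVector
    initial_score: dvh_mod.ScoreCard
    steps: list[EpisodeStep] = field(default_factory=list)
    termination: str = "max_steps"

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def final_score(self) -> float:
        return self.steps[-1].score_after.total if self.steps \
            else self.initial_score.total

    @property
    def final_tpps(self) -> TPPVector:
        return self.steps[-1].tpps_after if self.steps else self.initial_tpps

    def probs_matrix(self) -> np.ndarray:
        return np.array([s.probs for s in self.steps]).reshape(-1, N_ACTIONS)


def run_episode(case: PhantomCase, net: PolicyValueNet,
                initial_tpps: TPPVector | None = None,
                max_steps: int = 30, mode: str = "greedy",
                seed: int | None = None,
                criteria: dvh_mod.CriteriaTable | None = None,
                opt_config: OptimizerConfig = OptimizerConfig()) -> EpisodeTrace:
    """Run one automatic-planning episode.

    ``mode='stochastic'`` samples actions from the policy using a dedicated
    per-episode random stream seeded by ``seed``; ``mode='greedy'`` takes
    the argmax and is deterministic end-to-end.  Each re-optimization is
    warm-started from the previous plan.
    """
    if mode not in ("greedy", "stochastic"):
        raise ValueError(f"mode must be greedy or stochastic, got {mode!r}")
    if mode == "stochastic" and seed is None:
        raise ValueError("stochastic mode requires a seed")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xAC7])) \
        if seed is not None else None
    criteria = criteria or dvh_mod.CriteriaTable.default()
    tpps = initial_tpps or TPPVector.default()
    actions = build_action_space(tpps)

    plan = optimize_fluence(case, tpps, config=opt_config)
    curves = dvh_mod.plan_dvhs(case, plan)
    score = dvh_mod.score_plan(curves, criteria)
    trace = EpisodeTrace(case_id=case.case_id, initial_tpps=tpps,
                         initial_score=score)
    memory = net.zero_memory()
    max_points = criteria.total_points
    if score.total >= max_points:
        trace.termination = "initial_full_score"
        return trace

    for _step in range(max_steps):
        x = dvh_mod.dvh_input_vector(curves)
        out = net.forward(x, memory)
        if mode == "greedy":
            a = int(np.argmax(out.probs))
        else:
            a = int(rng.choice(N_ACTIONS, p=out.probs / out.probs.sum()))
        new_tpps = apply_action(tpps, actions[a])
        new_plan = optimize_fluence(case, new_tpps, warm_start=plan,
                                    config=opt_config)
        new_curves = dvh_mod.plan_dvhs(case, new_plan)
        new_score = dvh_mod.score_plan(new_curves, criteria)
        trace.steps.append(EpisodeStep(
            dvh_input=x, memory_in=memory, probs=out.probs,
            q_values=out.q_values, action=a, tpps_before=tpps,
            tpps_after=new_tpps, score_after=new_score,
            plan_before=plan, plan_after=new_plan))
        tpps, plan, curves, score = new_tpps, new_plan, new_curves, new_score
        memory = out.new_memory
        if score.total >= max_points:
            trace.termination = "full_score"
            break
    else:
        trace.termination = "max_steps"
    return trace


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    max_steps_per_episode: int = 30
    gamma: float = 0.95
    learning_rate: float = 1e-3
    entropy_beta: float = 0.03
    critic_weight: float = 0.5
    step_penalty: float = 0.05
    terminal_bonus: float = 1.0
    grad_clip: float = 5.0
    dense: int = 64
    hidden: int = 32


@dataclass
class Checkpoint:
    step: int
    params: dict[str, np.ndarray]
    seed: int

    def net(self) -> PolicyValueNet:
        return PolicyValueNet({k: v.copy() for k, v in self.params.items()})


class _Adam:
    def __init__(self, params, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def update(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)


def train_checkpoints(cases: list[PhantomCase], steps: int,
                      checkpoint_every: int, seed: int,
                      config: TrainConfig = TrainConfig(),
                      initial_tpps: TPPVector | None = None,
                      criteria: dvh_mod.CriteriaTable | None = None,
                      opt_config: OptimizerConfig = OptimizerConfig(),
                      include_initial: bool = False) -> list[Checkpoint]:
    """Train the agent and snapshot parameters every ``checkpoint_every``
    environment steps; the checkpoint count is floor(steps / every)
    (plus an optional untrained step-0 snapshot)."""
    if steps < checkpoint_every:
        raise ValueError("steps must be >= checkpoint_every")
    criteria = criteria or dvh_mod.CriteriaTable.default()
    tpps0 = initial_tpps or TPPVector.default()
    actions = build_action_space(tpps0)
    ss = np.random.SeedSequence([int(seed), 0x7217])
    init_seed, samp_seed, case_seed = [int(s.generate_state(1)[0]) % (2**31)
                                       for s in ss.spawn(3)]
    net = PolicyValueNet.init(init_seed, dense=config.dense,
                              hidden=config.hidden)
    opt = _Adam(net.params, config.learning_rate)
    rng = np.random.default_rng(samp_seed)
    case_rng = np.random.default_rng(case_seed)
    max_points = criteria.total_points

    checkpoints: list[Checkpoint] = []
    if include_initial:
        checkpoints.append(Checkpoint(
            0, {k: v.copy() for k, v in net.params.items()}, seed))
    env_steps = 0
    next_ckpt = checkpoint_every
    n_wanted = steps // checkpoint_every

    while len(checkpoints) < n_wanted + (1 if include_initial else 0):
        case = cases[int(case_rng.integers(len(cases)))]
        tpps = tpps0
        plan = optimize_fluence(case, tpps, config=opt_config)
        curves = dvh_mod.plan_dvhs(case, plan)
        score = dvh_mod.score_plan(curves, criteria)
        memory = net.zero_memory()
        for _t in range(config.max_steps_per_episode):
            x = dvh_mod.dvh_input_vector(curves)
            cache = net.forward_cache(x[None, :], memory.c[None, :],
                                      memory.h[None, :])
            probs, q = cache["p"][0], cache["q"][0]
            a = int(rng.choice(N_ACTIONS, p=probs / probs.sum()))
            new_tpps = apply_action(tpps, actions[a])
            new_plan = optimize_fluence(case, new_tpps, warm_start=plan,
                                        config=opt_config)
            new_curves = dvh_mod.plan_dvhs(case, new_plan)
            new_score = dvh_mod.score_plan(new_curves, criteria)
            done = new_score.total >= max_points
            reward = (new_score.total - score.total) - config.step_penalty
            if done:
                reward += config.terminal_bonus

            new_memory = MemoryState(c=cache["c_t"][0], h=cache["h_t"][0])
            if done:
                v_next = 0.0
            else:
                x_next = dvh_mod.dvh_input_vector(new_curves)
                nxt = net.forward_cache(x_next[None, :],
                                        new_memory.c[None, :],
                                        new_memory.h[None, :])
                v_next = float((nxt["p"][0] * nxt["q"][0]).sum())
            target = reward + config.gamma * v_next
            v_now = float((probs * q).sum())
            advantage = target - v_now

            # policy loss -A log pi(a) - beta H, critic loss cw (q_a - y)^2
            logp = np.log(np.clip(probs, 1e-12, None))
            entropy = -float((probs * logp).sum())
            onehot = np.zeros(N_ACTIONS)
            onehot[a] = 1.0
            dlogits = -advantage * (onehot - probs) \
                + config.entropy_beta * probs * (logp + entropy)
            dq_vec = np.zeros(N_ACTIONS)
            dq_vec[a] = 2.0 * config.critic_weight * (q[a] - target)
            _, grads = net.backward(cache, dlogits[None, :],
                                    dq_vec[None, :], want_params=True)
            gnorm = np.sqrt(sum(float((gr * gr).sum())
                                for gr in grads.values()))
            if not np.isfinite(gnorm):
                raise FloatingPointError("divergent training gradient")
            if gnorm > config.grad_clip:
                grads = {k: gr * (config.grad_clip / gnorm)
                         for k, gr in grads.items()}
            opt.update(net.params, grads)

            tpps, plan, curves, score = new_tpps, new_plan, new_curves, new_score
            memory = new_memory
            env_steps += 1
            if env_steps >= next_ckpt:
                checkpoints.append(Checkpoint(
                    env_steps, {k: v.copy() for k, v in net.params.items()},
                    seed))
                next_ckpt += checkpoint_every
                if len(checkpoints) >= n_wanted + (1 if include_initial else 0):
                    break
            if done:
                break
    return checkpoints


def evaluate_checkpoint(ckpt: Checkpoint, case: PhantomCase,
                        n_episodes: int = 20, mode: str = "greedy",
                        seed: int = 0, max_steps: int = 30,
                        initial_tpps: TPPVector | None = None,
                        criteria: dvh_mod.CriteriaTable | None = None,
                        opt_config: OptimizerConfig = OptimizerConfig(),
                        jitter_init: int = 0) -> list[EpisodeTrace]:
    """Roll out evaluation episodes for one checkpoint.

    ``jitter_init`` > 0 perturbs the initial TPPs by up to that many lattice
    steps per parameter (uniform, seeded per episode), so that greedy
    rollouts probe distinct starting conditions.
    """
    net = ckpt.net()
    base = initial_tpps or TPPVector.default()
    ss = np.random.SeedSequence([int(seed), 0xE7A1])
    ep_seeds = [int(s.generate_state(1)[0]) % (2**31) for s in ss.spawn(n_episodes)]
    traces = []
    for k in range(n_episodes):
        tpps = base
        if jitter_init > 0:
            jr = np.random.default_rng(np.random.SeedSequence(
                [ep_seeds[k], 0x71]))
            shift = jr.integers(-jitter_init, jitter_init + 1, size=9)
            tpps = base.with_values(np.clip(
                base.values + shift * base.delta, base.lo, base.hi))
        traces.append(run_episode(case, net, initial_tpps=tpps,
                                  max_steps=max_steps, mode=mode,
                                  seed=ep_seeds[k], criteria=criteria,
                                  opt_config=opt_config))
    return traces
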