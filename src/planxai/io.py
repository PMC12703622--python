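"""File formats, configuration and the end-to-end cohort driver.

Traces and attributions are stored as JSON-lines (one header line, then one
line per step or per (step, action)); tabular reports as CSV; configuration
as a single YAML file.  All randomness flows from one root seed through
named substreams (case generation, training, episode action sampling) so
each component is independently reproducible, and payloads carry no
timestamps, making reruns byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import dvh as dvh_mod
from .agent import (Checkpoint, EpisodeStep, EpisodeTrace, apply_action,
                    build_action_space, run_episode)
from .ig import BaselineSpec, attribute_all_actions
from .network import MemoryState, N_ACTIONS, PolicyValueNet
from .phantom import (OptimizerConfig, PhantomCase, PlanState, TPPVector,
                      generate_case, optimize_fluence)

log = logging.getLogger("planxai")

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """Default run configuration; a run is reproducible from this + seed."""
    return {
        "seed": 0,
        "phantom": {
            "size": "small",
            "n_cases": 39,
            "overlap_range": [0.0, 0.5],
            "prescription_dose": 79.2,
        },
        "scoring": {"criteria": dvh_mod.CriteriaTable.default().to_config()},
        "network": {"dense": 64, "hidden": 32},
        "training": {
            "steps": 24000,
            "checkpoint_every": 6000,
            "max_steps_per_episode": 30,
            "learning_rate": 1e-3,
            "entropy_beta": 0.03,
            "gamma": 0.95,
        },
        "episode": {"max_steps": 30, "repeats": 5},
        "attribution": {"path_steps": 64, "tolerance": 1e-3,
                        "baseline_offset": 0.0},
        "analysis": {"reward_mode": 2, "offsets": [0.005, 0.01]},
    }


def load_config(path: str | Path) -> dict:
    cfg = default_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Case serialization
# ---------------------------------------------------------------------------

def save_case(case: PhantomCase, directory: str | Path) -> None:
    """One directory per case: JSON header plus whitespace-delimited text
    matrices for the dose matrix and structure masks."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    header = {"case_id": case.case_id, "grid_shape": list(case.grid_shape),
              "seed": case.seed, "prescription_dose": case.prescription_dose,
              "voxel_count": case.voxel_count,
              "beamlet_count": case.beamlet_count}
    (d / "case.json").write_text(json.dumps(header, indent=1))
    np.savetxt(d / "dose_matrix.txt", case.dose_matrix)
    for name, idx in case.structure_masks.items():
        np.savetxt(d / f"mask_{name}.txt", idx, fmt="%d")


def load_case(directory: str | Path) -> PhantomCase:
    d = Path(directory)
    header = json.loads((d / "case.json").read_text())
    masks = {name: np.loadtxt(d / f"mask_{name}.txt", dtype=int).reshape(-1)
             for name in ("PTV", "BLA", "REC")}
    case = PhantomCase(
        case_id=header["case_id"], grid_shape=tuple(header["grid_shape"]),
        structure_masks=masks,
        dose_matrix=np.loadtxt(d / "dose_matrix.txt").reshape(
            header["voxel_count"], header["beamlet_count"]),
        prescription_dose=header["prescription_dose"], seed=header["seed"])
    case.validate()
    return case


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(ckpt: Checkpoint, directory: str | Path) -> None:
    """Flat parameter archive (.npz) with a JSON manifest of shapes."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savez(d / "params.npz", **ckpt.params)
    manifest = {"step": ckpt.step, "seed": ckpt.seed,
                "shapes": {k: list(v.shape) for k, v in ckpt.params.items()}}
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_checkpoint(directory: str | Path) -> Checkpoint:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    with np.load(d / "params.npz") as data:
        params = {k: data[k].copy() for k in data.files}
    for k, shape in manifest["shapes"].items():
        if list(params[k].shape) != shape:
            raise ValueError(f"checkpoint shape mismatch for {k}")
    return Checkpoint(step=manifest["step"], params=params,
                      seed=manifest["seed"])


# ---------------------------------------------------------------------------
# Trace archives (JSON lines)
# ---------------------------------------------------------------------------

def _score_dict(sc: dvh_mod.ScoreCard) -> dict:
    return {"total": sc.total, "passed": list(sc.passed),
            "awarded": list(sc.awarded),
            "organ_scores": dict(sc.organ_scores),
            "organ_violations": dict(sc.organ_violations)}


def _score_from_dict(d: dict) -> dvh_mod.ScoreCard:
    return dvh_mod.ScoreCard(
        passed=tuple(bool(p) for p in d["passed"]),
        awarded=tuple(float(a) for a in d["awarded"]),
        organ_scores=d["organ_scores"], total=float(d["total"]),
        organ_violations=d["organ_violations"])


def save_trace(trace: EpisodeTrace, path: str | Path) -> None:
    tp = trace.initial_tpps
    header = {
        "type": "trace", "case_id": trace.case_id,
        "termination": trace.termination,
        "tpp_grid": {"lo": tp.lo.tolist(), "hi": tp.hi.tolist(),
                     "delta": tp.delta.tolist()},
        "initial_tpps": tp.values.tolist(),
        "initial_score": _score_dict(trace.initial_score),
        "n_steps": trace.n_steps,
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        for s in trace.steps:
            fh.write(json.dumps({
                "dvh_input": s.dvh_input.tolist(),
                "c_in": s.memory_in.c.tolist(),
                "h_in": s.memory_in.h.tolist(),
                "probs": s.probs.tolist(),
                "q_values": s.q_values.tolist(),
                "action": s.action,
                "tpps_before": s.tpps_before.values.tolist(),
                "tpps_after": s.tpps_after.values.tolist(),
                "fluence_after": s.plan_after.fluence.tolist(),
                "score_after": _score_dict(s.score_after),
            }) + "\n")


def load_trace(path: str | Path,
               case: PhantomCase | None = None) -> EpisodeTrace:
    """Load a trace archive.  If ``case`` is given, per-step plan states
    are rebuilt from the stored fluences (dose = M @ fluence)."""
    with open(path) as fh:
        lines = [json.loads(line) for line in fh if line.strip()]
    header, step_rows = lines[0], lines[1:]
    if header.get("type") != "trace":
        raise ValueError(f"{path} is not a trace archive")
    grid = header["tpp_grid"]
    mk_tpps = lambda v: TPPVector(np.asarray(v, float),
                                  lo=np.asarray(grid["lo"]),
                                  hi=np.asarray(grid["hi"]),
                                  delta=np.asarray(grid["delta"]))
    trace = EpisodeTrace(case_id=header["case_id"],
                         initial_tpps=mk_tpps(header["initial_tpps"]),
                         initial_score=_score_from_dict(header["initial_score"]),
                         termination=header["termination"])
    prev_plan: PlanState | None = None
    if case is not None:
        prev_plan = optimize_fluence(case, trace.initial_tpps)
    for row in step_rows:
        fluence = np.asarray(row["fluence_after"], float)
        plan_after = None
        if case is not None:
            plan_after = PlanState(fluence=fluence,
                                   dose=case.dose_matrix @ fluence,
                                   objective_value=float("nan"),
                                   converged=True)
        trace.steps.append(EpisodeStep(
            dvh_input=np.asarray(row["dvh_input"], float),
            memory_in=MemoryState(c=np.asarray(row["c_in"], float),
                                  h=np.asarray(row["h_in"], float)),
            probs=np.asarray(row["probs"], float),
            q_values=np.asarray(row["q_values"], float),
            action=int(row["action"]),
            tpps_before=mk_tpps(row["tpps_before"]),
            tpps_after=mk_tpps(row["tpps_after"]),
            score_after=_score_from_dict(row["score_after"]),
            plan_before=prev_plan, plan_after=plan_after))
        prev_plan = plan_after
    return trace


def save_attributions(records_per_step: list[list], path: str | Path,
                      case_id: str, baseline_key: str,
                      path_steps: int, tolerance: float) -> None:
    """One JSON line per (step, action) with the arrays and residual."""
    header = {"type": "attribution", "case_id": case_id,
              "baseline": baseline_key, "path_steps": path_steps,
              "tolerance": tolerance}
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        for i, records in enumerate(records_per_step):
            for rec in records:
                fh.write(json.dumps({
                    "step": i, "action": rec.action,
                    "ig_dvh": rec.ig_dvh.tolist(),
                    "ig_c": rec.ig_c.tolist(), "ig_h": rec.ig_h.tolist(),
                    "baseline_output": rec.baseline_output,
                    "actual_output": rec.actual_output,
                    "residual": rec.completeness_residual,
                }) + "\n")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_archive(path: str | Path) -> list[str]:
    """Check the declared invariants of a trace or attribution archive;
    return a list of human-readable violations (empty = clean)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        lines = [json.loads(line) for line in fh if line.strip()]
    if not lines:
        return ["empty archive"]
    header, rows = lines[0], lines[1:]
    problems: list[str] = []
    if header.get("type") == "trace":
        grid = header["tpp_grid"]
        lo = np.asarray(grid["lo"]); hi = np.asarray(grid["hi"])
        delta = np.asarray(grid["delta"])
        tpps = TPPVector(np.asarray(header["initial_tpps"]),
                         lo=lo, hi=hi, delta=delta)
        actions = build_action_space(tpps)
        total_pts = 9.0
        prev = np.asarray(header["initial_tpps"], float)
        for k, row in enumerate(rows):
            p = np.asarray(row["probs"], float)
            if abs(p.sum() - 1.0) > 1e-6 or np.any(p < 0) or np.any(p > 1):
                problems.append(f"step {k}: probs not a distribution")
            sc = row["score_after"]["total"]
            if not 0.0 <= sc <= total_pts:
                problems.append(f"step {k}: score {sc} outside [0, {total_pts}]")
            before = np.asarray(row["tpps_before"], float)
            after = np.asarray(row["tpps_after"], float)
            if not np.allclose(before, prev, atol=1e-9):
                problems.append(f"step {k}: TPP chain broken")
            expect = apply_action(TPPVector(before, lo=lo, hi=hi, delta=delta),
                                  actions[int(row["action"])])
            if not np.allclose(after, expect.values, atol=1e-9):
                problems.append(f"step {k}: TPPs inconsistent with action")
            if np.any(after < lo - 1e-9) or np.any(after > hi + 1e-9):
                problems.append(f"step {k}: TPPs out of bounds")
            prev = after
    elif header.get("type") == "attribution":
        tol = float(header.get("tolerance", 1e-3))
        for k, row in enumerate(rows):
            if len(row["ig_dvh"]) != 300:
                problems.append(f"line {k}: ig_dvh length != 300")
            if row["residual"] > tol:
                problems.append(
                    f"line {k}: completeness residual {row['residual']:g} "
                    f"above tolerance {tol:g}")
    else:
        problems.append(f"unknown archive type {header.get('type')!r}")
    return problems


# ---------------------------------------------------------------------------
# Cohort driver
# ---------------------------------------------------------------------------

def cohort_cases(cfg: dict, seed: int) -> list[PhantomCase]:
    """Generate the synthetic cohort: per-case geometry seeds and overlap
    levels drawn from a dedicated substream of the root seed."""
    ph = cfg["phantom"]
    ss = np.random.SeedSequence([int(seed), 0xCA5E])
    rng = np.random.default_rng(ss)
    lo, hi = ph["overlap_range"]
    cases = []
    for _ in range(int(ph["n_cases"])):
        cseed = int(rng.integers(2**31))
        overlap = float(rng.uniform(lo, hi))
        cases.append(generate_case(cseed, overlap, ph["size"],
                                   ph["prescription_dose"]))
    return cases


def simulate_cohort(cfg: dict, checkpoints: list[Checkpoint],
                    out_dir: str | Path, attribute: bool = True,
                    n_cases: int | None = None,
                    repeats: int | None = None) -> dict[str, list[Path]]:
    """Run the full evaluation cohort: for every checkpoint, every case is
    planned ``repeats`` times with stochastic action sampling; traces (and
    optionally per-step attributions for all actions) are written as
    JSON-lines archives.  Deterministic per config seed."""
    cfg = dict(cfg)
    if n_cases is not None:
        cfg["phantom"] = {**cfg["phantom"], "n_cases": n_cases}
    repeats = repeats if repeats is not None else cfg["episode"]["repeats"]
    seed = int(cfg["seed"])
    out = Path(out_dir)
    criteria = dvh_mod.CriteriaTable.from_config(cfg["scoring"]["criteria"])
    cases = cohort_cases(cfg, seed)
    written: dict[str, list[Path]] = {}
    att = cfg["attribution"]
    for ci, ckpt in enumerate(checkpoints):
        name = f"ckpt{ckpt.step}"
        net = ckpt.net()
        tdir = out / "traces" / name
        adir = out / "attributions" / name
        tdir.mkdir(parents=True, exist_ok=True)
        if attribute:
            adir.mkdir(parents=True, exist_ok=True)
        paths = []
        baseline = BaselineSpec.zero(hidden=net.hidden,
                                     offset=att["baseline_offset"])
        for k, case in enumerate(cases):
            for r in range(repeats):
                ep_seed = int(np.random.SeedSequence(
                    [seed, 0xE9, ci, k, r]).generate_state(1)[0]) % (2**31)
                trace = run_episode(case, net,
                                    max_steps=cfg["episode"]["max_steps"],
                                    mode="stochastic", seed=ep_seed,
                                    criteria=criteria)
                tpath = tdir / f"{case.case_id}_r{r}.jsonl"
                save_trace(trace, tpath)
                paths.append(tpath)
                log.info("trace ckpt=%s case=%s rep=%d steps=%d score=%g",
                         name, case.case_id, r, trace.n_steps,
                         trace.final_score)
                if attribute and trace.n_steps:
                    recs = [attribute_all_actions(
                        net, s.dvh_input, s.memory_in.c, s.memory_in.h,
                        baseline, att["path_steps"]) for s in trace.steps]
                    save_attributions(recs,
                                      adir / f"{case.case_id}_r{r}.jsonl",
                                      case.case_id, baseline.key(),
                                      att["path_steps"], att["tolerance"])
        written[name] = paths
    return written
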