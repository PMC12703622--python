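"""Integrated-gradients attribution for the tuning policy.

For a network output ``F_j`` (here the post-softmax probability of tuning
action ``j``) and an input ``x`` with baseline ``x'``, the integrated
gradient of input feature ``i`` is

    IG_ij = (x_i - x'_i) * Integral_0^1 dF_j(x' + a (x - x')) / dx_i da

computed along the straight path from baseline to input.  The agent has
three inputs per step — the 300-value DVH vector and the two 32-value LSTM
memory states c and h — and a single joint path scales all three from their
baselines simultaneously, so the completeness identity

    sum_i IG_ij = F_j(x) - F_j(x')

holds for the concatenated attribution vector.  The integral is
approximated by trapezoid quadrature; the completeness residual is recorded
on every attribution so quadrature adequacy is auditable.

Baselines are zero by default.  The baseline-offset sensitivity analysis
shifts only the OAR entries of the DVH baseline (PTV entries stay zero) and
compares the resulting DVH heatmaps with the zero-baseline ones by cosine
similarity, grouped by leading action.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import DVH_DIM, N_ACTIONS, PolicyValueNet

#: DVH index blocks per organ, ordered PTV, bladder, rectum.
ORGAN_SLICES = {"PTV": slice(0, 100), "BLA": slice(100, 200),
                "REC": slice(200, 300)}


@dataclass(frozen=True)
class BaselineSpec:
    """Baseline inputs for the attribution path.

    The default is all zeros.  A nonzero ``offset`` is applied to the OAR
    DVH entries only (indices 100-299); PTV entries are kept at zero so the
    baseline never violates a target-coverage criterion.
    """

    dvh: np.ndarray
    c: np.ndarray
    h: np.ndarray
    offset: float = 0.0

    @classmethod
    def zero(cls, hidden: int = 32, offset: float = 0.0,
             dvh_dim: int = DVH_DIM) -> "BaselineSpec":
        dvh = np.zeros(dvh_dim)
        dvh[100:] = offset
        return cls(dvh=dvh, c=np.zeros(hidden), h=np.zeros(hidden),
                   offset=float(offset))

    def key(self) -> str:
        return "zero" if self.offset == 0.0 else f"offset:{self.offset:g}"


@dataclass
class AttributionRecord:
    """Per-action IG arrays over the three inputs plus completeness audit."""

    action: int
    ig_dvh: np.ndarray
    ig_c: np.ndarray
    ig_h: np.ndarray
    baseline_output: float
    actual_output: float
    path_steps: int
    baseline_key: str = "zero"

    @property
    def total(self) -> float:
        return float(self.ig_dvh.sum() + self.ig_c.sum() + self.ig_h.sum())

    @property
    def completeness_residual(self) -> float:
        return abs(self.total - (self.actual_output - self.baseline_output))


def integrated_gradients(net: PolicyValueNet, dvh: np.ndarray,
                         c: np.ndarray, h: np.ndarray,
                         baseline: BaselineSpec, action: int,
                         path_steps: int = 256) -> AttributionRecord:
    """Attribute action ``action``'s policy probability to the three inputs.

    ``path_steps`` is the number of trapezoid intervals (>= 2); the path
    endpoints contribute with half weight.  All path points are evaluated
    in one batched forward/backward pass.
    """
    if path_steps < 2:
        raise ValueError("path_steps must be >= 2")
    dvh = np.asarray(dvh, float)
    c = np.asarray(c, float)
    h = np.asarray(h, float)
    alphas = np.linspace(0.0, 1.0, path_steps + 1)
    X = baseline.dvh[None, :] + alphas[:, None] * (dvh - baseline.dvh)[None, :]
    Cm = baseline.c[None, :] + alphas[:, None] * (c - baseline.c)[None, :]
    Hm = baseline.h[None, :] + alphas[:, None] * (h - baseline.h)[None, :]
    probs, dX, dC, dH = net.prob_input_gradients(X, Cm, Hm, action)
    if not (np.all(np.isfinite(dX)) and np.all(np.isfinite(dC))
            and np.all(np.isfinite(dH))):
        raise FloatingPointError("non-finite path gradients")
    w = np.full(path_steps + 1, 1.0 / path_steps)
    w[0] = w[-1] = 0.5 / path_steps
    rec = AttributionRecord(
        action=int(action),
        ig_dvh=(dvh - baseline.dvh) * (w @ dX),
        ig_c=(c - baseline.c) * (w @ dC),
        ig_h=(h - baseline.h) * (w @ dH),
        baseline_output=float(probs[0, action]),
        actual_output=float(probs[-1, action]),
        path_steps=int(path_steps),
        baseline_key=baseline.key(),
    )
    return rec


def attribute_all_actions(net: PolicyValueNet, dvh, c, h,
                          baseline: BaselineSpec,
                          path_steps: int = 256) -> list[AttributionRecord]:
    return [integrated_gradients(net, dvh, c, h, baseline, j, path_steps)
            for j in range(N_ACTIONS)]


def completeness_check(record: AttributionRecord, tol: float = 1e-4) -> bool:
    """Completeness axiom: attributions must sum to F_j(x) - F_j(x')."""
    return record.completeness_residual <= tol


def decompose_policy(records: list[AttributionRecord],
                     baseline_probs: np.ndarray,
                     tol: float = 1e-3) -> dict[str, np.ndarray]:
    """Stack, per action, the baseline probability and the summed DVH, c
    and h attributions; the four contributions sum to the actual policy
    probability (within quadrature tolerance)."""
    if len(records) != N_ACTIONS:
        raise ValueError("need one record per action")
    keys = {r.baseline_key for r in records}
    if len(keys) != 1:
        raise ValueError(f"records mix baselines: {sorted(keys)}")
    by_action = sorted(records, key=lambda r: r.action)
    out = {
        "baseline": np.asarray(baseline_probs, float),
        "dvh": np.array([r.ig_dvh.sum() for r in by_action]),
        "c": np.array([r.ig_c.sum() for r in by_action]),
        "h": np.array([r.ig_h.sum() for r in by_action]),
        "actual": np.array([r.actual_output for r in by_action]),
    }
    resid = np.abs(out["baseline"] + out["dvh"] + out["c"] + out["h"]
                   - out["actual"])
    if np.any(resid > tol):
        raise ValueError(f"decomposition residual {resid.max():g} above {tol:g}")
    return out


def leading_action(records: list[AttributionRecord],
                   input_type: str = "dvh") -> int:
    """Action with the highest total attribution from one input source;
    ties break toward the lowest action index."""
    attr = {"dvh": lambda r: r.ig_dvh, "c": lambda r: r.ig_c,
            "h": lambda r: r.ig_h}[input_type]
    totals = np.full(N_ACTIONS, -np.inf)
    for r in records:
        totals[r.action] = float(attr(r).sum())
    return int(np.argmax(totals))


def heatmap_segments(ig_dvh: np.ndarray) -> np.ndarray:
    """Group the 300 DVH attributions into 30 segments of 10 consecutive
    points (segments 0-9 PTV, 10-19 bladder, 20-29 rectum)."""
    a = np.asarray(ig_dvh, float)
    if a.shape != (DVH_DIM,):
        raise ValueError("expected a 300-value DVH attribution")
    return a.reshape(30, 10).sum(axis=1)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity; defined as 0 when either vector has zero norm.
    Identical nonzero vectors give exactly 1 (no rounding residue)."""
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    if np.array_equal(u, v):
        return 1.0
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


@dataclass
class SensitivityGroup:
    action: int
    mean: float
    std: float
    n: int
    values: np.ndarray = field(repr=False, default=None)  # type: ignore


def baseline_sensitivity(net: PolicyValueNet,
                         steps: list[tuple[np.ndarray, np.ndarray, np.ndarray, int]],
                         offsets: list[float],
                         path_steps: int = 256) -> dict[float, list[SensitivityGroup]]:
    """Cosine similarity of DVH heatmaps under offset baselines.

    ``steps`` holds (dvh, c, h, leading_action) per planning step.  For each
    offset, each step's leading action is re-attributed under the shifted
    baseline (PTV baseline entries stay zero) and the 300-value DVH heatmap
    is compared against the zero-baseline heatmap; results are grouped by
    action and summarized as mean +/- std.
    """
    hidden = net.hidden
    zero = BaselineSpec.zero(hidden=hidden)
    ref = {}
    for k, (x, c, h, a) in enumerate(steps):
        ref[k] = integrated_gradients(net, x, c, h, zero, a, path_steps).ig_dvh
    out: dict[float, list[SensitivityGroup]] = {}
    for off in offsets:
        base = BaselineSpec.zero(hidden=hidden, offset=off)
        by_action: dict[int, list[float]] = {}
        for k, (x, c, h, a) in enumerate(steps):
            rec = integrated_gradients(net, x, c, h, base, a, path_steps)
            by_action.setdefault(a, []).append(cosine(rec.ig_dvh, ref[k]))
        out[off] = [SensitivityGroup(action=a, mean=float(np.mean(v)),
                                     std=float(np.std(v)), n=len(v),
                                     values=np.asarray(v))
                    for a, v in sorted(by_action.items())]
    return out
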