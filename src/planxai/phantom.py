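"""Synthetic IMRT planning environment.

Stands in for a clinical treatment planning system and patient cohort: it
generates 2-D phantom cases (one planning target volume, a bladder and a
rectum on a voxel grid, with a pencil-beam dose-deposition matrix) and solves
the DVH-constrained fluence-map optimization for a given vector of treatment
planning parameters (TPPs).

The inverse-planning objective minimized over the non-negative beamlet
vector ``x`` (dose ``d = M x``) is

    F(x) = lam_PTV * [ sum_{v in PTV}   (d_v - d_p)_-^2
                     + sum_{v in S_PTV} (d_v - t_PTV d_p)_+^2 ]
         + sum_{i in {BLA, REC}} lam_i * sum_{v in S_i} (d_v - t_i d_p)_+^2

where ``(a)_- = min(a, 0)``, ``(a)_+ = max(a, 0)``, ``d_p`` is the
prescription dose and ``S_i`` is the dose-volume-constraint voxel selection:
among voxels exceeding the threshold ``t_i d_p``, the allowed volume fraction
``V_i`` of the structure may stay above it un-penalized; the lowest-dose
excess violators are penalized until the un-penalized violator fraction
equals ``V_i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

STRUCTURES = ("PTV", "BLA", "REC")

#: TPP order used everywhere: three weights, three dose thresholds
#: (fractions of d_p), three allowed volume fractions.
TPP_NAMES = (
    "lam_PTV", "lam_BLA", "lam_REC",
    "t_PTV", "t_BLA", "t_REC",
    "V_PTV", "V_BLA", "V_REC",
)


@dataclass(frozen=True)
class TPPVector:
    """The 9 tunable treatment planning parameters with bounds and steps.

    ``values`` follows :data:`TPP_NAMES`.  Thresholds ``t_*`` are stored as
    fractions of the prescription dose so that cases with different ``d_p``
    share TPP semantics.
    """

    values: np.ndarray
    lo: np.ndarray = field(default=None)  # type: ignore[assignment]
    hi: np.ndarray = field(default=None)  # type: ignore[assignment]
    delta: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        lo, hi, delta = _default_grid() if self.lo is None else (
            np.asarray(self.lo, float), np.asarray(self.hi, float),
            np.asarray(self.delta, float))
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        object.__setattr__(self, "delta", delta)
        if v.shape != (9,):
            raise ValueError(f"expected 9 TPPs, got shape {v.shape}")
        if np.any(v < self.lo - 1e-12) or np.any(v > self.hi + 1e-12):
            raise ValueError("TPP values outside bounds")
        if np.any(v[3:6] <= 0):
            raise ValueError("dose thresholds must be positive")

    @classmethod
    def default(cls) -> "TPPVector":
        """Mid-range initial TPPs on the default tuning grid."""
        lo, hi, delta = _default_grid()
        return cls(values=(lo + hi) / 2.0, lo=lo, hi=hi, delta=delta)

    def __getattr__(self, name: str):
        if name in TPP_NAMES:
            return self.values[TPP_NAMES.index(name)]
        raise AttributeError(name)

    def with_values(self, values: np.ndarray) -> "TPPVector":
        return replace(self, values=np.asarray(values, float))

    @property
    def lambdas(self) -> np.ndarray:
        return self.values[0:3]

    @property
    def thresholds(self) -> np.ndarray:
        return self.values[3:6]

    @property
    def volumes(self) -> np.ndarray:
        return self.values[6:9]


def _default_grid():
    lo = np.array([0.05] * 3 + [0.5] * 3 + [0.05] * 3)
    hi = np.array([5.0] * 3 + [1.2] * 3 + [0.95] * 3)
    delta = np.array([0.15] * 3 + [0.05] * 3 + [0.05] * 3)
    return lo, hi, delta


@dataclass(frozen=True)
class PhantomCase:
    """One synthetic planning case.

    ``structure_masks`` maps structure name to a sorted array of voxel
    indices; masks are disjoint (PTV has priority where geometries overlap).
    ``dose_matrix`` has shape (voxel_count, beamlet_count) in Gy per unit
    fluence.
    """

    case_id: str
    grid_shape: tuple[int, int]
    structure_masks: dict[str, np.ndarray]
    dose_matrix: np.ndarray
    prescription_dose: float
    seed: int

    @property
    def voxel_count(self) -> int:
        return self.dose_matrix.shape[0]

    @property
    def beamlet_count(self) -> int:
        return self.dose_matrix.shape[1]

    def validate(self) -> None:
        if self.prescription_dose <= 0:
            raise ValueError("prescription dose must be positive")
        seen: set[int] = set()
        for name in STRUCTURES:
            idx = set(self.structure_masks[name].tolist())
            if idx & seen:
                raise ValueError("structure masks overlap")
            seen |= idx
        ptv = self.structure_masks["PTV"]
        if np.any(self.dose_matrix[ptv].sum(axis=1) == 0):
            raise ValueError("PTV contains an un-irradiable voxel")
        if np.any(self.dose_matrix < 0):
            raise ValueError("dose matrix must be non-negative")


@dataclass
class PlanState:
    """Result of one fluence-map optimization."""

    fluence: np.ndarray
    dose: np.ndarray
    objective_value: float
    converged: bool


# ---------------------------------------------------------------------------
# Case generation
# ---------------------------------------------------------------------------

_SIZES = {"small": (20, 20, 5, 6), "medium": (30, 30, 6, 8)}


def generate_case(seed: int, overlap_level: float = 0.0,
                  size: str = "small",
                  prescription_dose: float = 79.2) -> PhantomCase:
    """Generate a deterministic synthetic planning case.

    Parameters
    ----------
    seed
        Seeds all geometry jitter and voxel sampling; identical seeds give
        bit-identical cases.
    overlap_level
        Target fraction of each OAR's voxels lying within one voxel
        (Chebyshev distance) of the PTV, emulating the anatomical
        PTV–OAR overlap variation of a prostate cohort.
    size
        ``small`` is a 20x20 grid with 30 beamlets; ``medium`` 30x30 / 48.
    """
    if not 0.0 <= overlap_level <= 1.0:
        raise ValueError(f"overlap_level must be in [0, 1], got {overlap_level}")
    if size not in _SIZES:
        raise ValueError(f"size must be one of {sorted(_SIZES)}")
    nr, nc, n_angles, n_off = _SIZES[size]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9A17]))

    rows, cols = np.indices((nr, nc))
    center = np.array([nr / 2 - 0.5, nc / 2 - 0.5])
    center = center + rng.uniform(-1.0, 1.0, size=2)
    r_ptv = rng.uniform(2.4, 3.2) * (nr / 20.0)

    dist2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    ptv_mask = dist2 <= r_ptv ** 2

    # Chebyshev distance of every voxel to the PTV set.
    cheb = _chebyshev_distance(ptv_mask)

    n_oar = max(12, int(0.05 * nr * nc))
    bla = _sample_oar(rng, cheb, rows < center[0], ptv_mask, overlap_level, n_oar)
    rec = _sample_oar(rng, cheb, rows > center[0], ptv_mask, overlap_level, n_oar)

    flat = lambda m: np.flatnonzero(m.ravel())
    ptv_idx = flat(ptv_mask)
    bla_idx = np.setdiff1d(bla, ptv_idx)
    rec_idx = np.setdiff1d(rec, np.concatenate([ptv_idx, bla_idx]))

    M = _pencil_beam_matrix(nr, nc, center, r_ptv, n_angles, n_off)

    case = PhantomCase(
        case_id=f"case-{size}-s{seed}-o{overlap_level:g}",
        grid_shape=(nr, nc),
        structure_masks={"PTV": ptv_idx, "BLA": bla_idx, "REC": rec_idx},
        dose_matrix=M,
        prescription_dose=float(prescription_dose),
        seed=int(seed),
    )
    case.validate()
    return case


def _chebyshev_distance(mask: np.ndarray) -> np.ndarray:
    """Chebyshev distance to the True set, by breadth-first dilation."""
    dist = np.full(mask.shape, np.inf)
    dist[mask] = 0
    frontier = mask.copy()
    d = 0
    while not frontier.all() and np.isfinite(dist).any():
        grown = _dilate(np.isfinite(dist))
        newly = grown & ~np.isfinite(dist)
        if not newly.any():
            break
        d += 1
        dist[newly] = d
        frontier = grown
    return dist


def _dilate(m: np.ndarray) -> np.ndarray:
    out = m.copy()
    out[1:, :] |= m[:-1, :]
    out[:-1, :] |= m[1:, :]
    out[:, 1:] |= m[:, :-1]
    out[:, :-1] |= m[:, 1:]
    out[1:, 1:] |= m[:-1, :-1]
    out[1:, :-1] |= m[:-1, 1:]
    out[:-1, 1:] |= m[1:, :-1]
    out[:-1, :-1] |= m[1:, 1:]
    return out


def _sample_oar(rng, cheb, side_mask, ptv_mask, overlap_level, n_oar):
    """Sample OAR voxel indices with a target adjacency fraction to the PTV."""
    near_band = (cheb == 1)
    far_band = (cheb >= 2) & side_mask
    near_side = near_band & side_mask
    n_near = int(round(overlap_level * n_oar))
    near_pool = np.flatnonzero(near_side.ravel())
    if near_pool.size < n_near:  # widen to the full ring if one side is short
        near_pool = np.flatnonzero(near_band.ravel())
    n_near = min(n_near, near_pool.size)
    far_pool = np.flatnonzero(far_band.ravel())
    # prefer far voxels close to the PTV so the OAR stays compact
    order = np.argsort(cheb.ravel()[far_pool] + rng.uniform(0, 0.5, far_pool.size))
    far_pool = far_pool[order]
    near = rng.choice(near_pool, size=n_near, replace=False)
    far = far_pool[: n_oar - n_near]
    return np.sort(np.concatenate([near, far]))


def _pencil_beam_matrix(nr, nc, center, r_ptv, n_angles, n_off,
                        sigma=1.2, mu=0.035):
    """Dense pencil-beam dose matrix: Gaussian lateral profile with
    exponential depth attenuation, beamlets aimed through the PTV."""
    rows, cols = np.indices((nr, nc))
    pos = np.stack([rows.ravel(), cols.ravel()], axis=1).astype(float)
    angles = np.pi * np.arange(n_angles) / n_angles
    offsets = np.linspace(-r_ptv, r_ptv, n_off)
    columns = []
    diag = float(np.hypot(nr, nc))
    for th in angles:
        direction = np.array([np.sin(th), np.cos(th)])
        normal = np.array([-direction[1], direction[0]])
        for off in offsets:
            origin = center + off * normal - (diag / 2) * direction
            rel = pos - origin
            depth = rel @ direction
            lateral = rel @ normal
            dose = np.exp(-lateral ** 2 / (2 * sigma ** 2)) * np.exp(-mu * np.clip(depth, 0, None))
            dose[depth < 0] = 0.0
            columns.append(dose)
    M = np.stack(columns, axis=1)
    # normalize so unit fluence on all beamlets gives ~1 Gy at the center
    M /= M.sum(axis=1).max()
    return M


# ---------------------------------------------------------------------------
# Fluence-map optimization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OptimizerConfig:
    max_outer: int = 20       # DVH voxel re-selection rounds
    max_inner: int = 50       # projected-gradient steps per round
    rel_tol: float = 1e-6     # relative objective-change stopping tolerance
    grad_tol: float = 1e-4    # projected-gradient norm for the converged flag


def select_voxels(dose: np.ndarray, case: PhantomCase,
                  tpps: TPPVector) -> dict[str, np.ndarray]:
    """Dose-volume-constraint voxel selection.

    For each structure, among the voxels whose dose exceeds the structure's
    threshold, the highest-dose fraction ``V`` of the structure's volume is
    allowed to remain above it; the remaining (lowest-dose) violators are
    selected for penalization.  Returns voxel index arrays keyed by
    structure; the PTV selection applies to its over-dose term only.
    """
    d_p = case.prescription_dose
    out: dict[str, np.ndarray] = {}
    for k, name in enumerate(STRUCTURES):
        idx = case.structure_masks[name]
        thr = tpps.thresholds[k] * d_p
        v_allowed = tpps.volumes[k]
        viol = idx[dose[idx] > thr]
        n_allowed = int(np.floor(v_allowed * idx.size))
        n_pen = max(0, viol.size - n_allowed)
        if n_pen == 0:
            out[name] = np.empty(0, dtype=idx.dtype)
            continue
        order = np.argsort(dose[viol], kind="stable")
        out[name] = np.sort(viol[order[:n_pen]])
    return out


def objective(x, case, tpps, selection):
    """Fixed-selection planning objective F(x)."""
    return _objective_from_dose(case.dose_matrix @ x, case, tpps, selection)


def _objective_from_dose(dose, case, tpps, selection):
    d_p = case.prescription_dose
    lam = tpps.lambdas
    thr = tpps.thresholds * d_p
    ptv = case.structure_masks["PTV"]
    under = np.minimum(dose[ptv] - d_p, 0.0)
    val = lam[0] * float(under @ under)
    for k, name in enumerate(STRUCTURES):
        sel = selection[name]
        if sel.size:
            over = np.maximum(dose[sel] - thr[k], 0.0)
            val += lam[k] * float(over @ over)
    return val


def _gradient_from_dose(dose, case, tpps, selection):
    """Gradient of F with respect to dose (chain through M^T outside)."""
    d_p = case.prescription_dose
    lam = tpps.lambdas
    thr = tpps.thresholds * d_p
    g = np.zeros_like(dose)
    ptv = case.structure_masks["PTV"]
    g[ptv] += 2.0 * lam[0] * np.minimum(dose[ptv] - d_p, 0.0)
    for k, name in enumerate(STRUCTURES):
        sel = selection[name]
        if sel.size:
            g[sel] += 2.0 * lam[k] * np.maximum(dose[sel] - thr[k], 0.0)
    return g


def solve_fixed_selection(case: PhantomCase, tpps: TPPVector,
                          selection: dict[str, np.ndarray],
                          x0: np.ndarray,
                          max_inner: int = 50,
                          rel_tol: float = 1e-6) -> tuple[np.ndarray, float]:
    """Projected-gradient descent with backtracking on the fixed-selection
    subproblem.  The objective is convex piecewise-quadratic; the step size
    is initialized from a Lipschitz estimate so iterates are invariant to a
    common rescaling of the weights."""
    M = case.dose_matrix
    lam_tot = float(tpps.lambdas.sum())
    # crude Lipschitz bound: 2 * lam_tot * ||M||_F^2 (scale-aware so the
    # iterates are invariant to a common rescaling of the weights)
    L = 2.0 * max(lam_tot, 1e-12) * float((M * M).sum())
    t = 1.0 / L
    x = np.clip(np.asarray(x0, float), 0.0, None)
    dose = M @ x
    f = _objective_from_dose(dose, case, tpps, selection)
    g = M.T @ _gradient_from_dose(dose, case, tpps, selection)
    for _ in range(max_inner):
        # monotone backtracking from the current (Barzilai-Borwein) step
        t_try = t
        for _bt in range(60):
            x_new = np.maximum(x - t_try * g, 0.0)
            dose_new = M @ x_new
            f_new = _objective_from_dose(dose_new, case, tpps, selection)
            if f_new <= f:
                break
            t_try *= 0.5
        if f_new > f or not np.isfinite(f_new):
            break
        g_new = M.T @ _gradient_from_dose(dose_new, case, tpps, selection)
        s = x_new - x
        y = g_new - g
        sy = float(s @ y)
        t = float(s @ s) / sy if sy > 1e-30 else t_try * 2.0
        moved = f - f_new
        x, dose, f, g = x_new, dose_new, f_new, g_new
        if f == 0.0 or moved <= rel_tol * max(f, 1e-30):
            break
    return x, f


def optimize_fluence(case: PhantomCase, tpps: TPPVector,
                     warm_start: PlanState | None = None,
                     config: OptimizerConfig = OptimizerConfig()) -> PlanState:
    """Solve the DVH-constrained fluence-map optimization.

    Alternates dose-volume voxel re-selection with projected-gradient
    descent on the resulting fixed-selection subproblem.  Deterministic
    given ``case``, ``tpps`` and ``warm_start``.
    """
    M = case.dose_matrix
    if warm_start is not None:
        x = np.asarray(warm_start.fluence, float).copy()
        if x.shape != (case.beamlet_count,):
            raise ValueError("warm start fluence has wrong length")
    else:
        x = np.ones(case.beamlet_count)
        ptv = case.structure_masks["PTV"]
        mean_ptv = float((M @ x)[ptv].mean())
        x *= case.prescription_dose / max(mean_ptv, 1e-12)

    f_prev = np.inf
    f = np.inf
    rel_change = np.inf
    selection = select_voxels(M @ x, case, tpps)
    for _outer in range(config.max_outer):
        x, f = solve_fixed_selection(case, tpps, selection, x,
                                     max_inner=config.max_inner,
                                     rel_tol=config.rel_tol)
        if not np.isfinite(f):
            raise FloatingPointError("non-finite planning objective")
        new_sel = select_voxels(M @ x, case, tpps)
        same = all(np.array_equal(new_sel[s], selection[s]) for s in STRUCTURES)
        rel_change = abs(f_prev - f) / max(f, 1e-30)
        selection, f_prev = new_sel, f
        if same and rel_change <= config.rel_tol:
            break

    dose = M @ x
    g = M.T @ _gradient_from_dose(dose, case, tpps, selection)
    proj_grad = x - np.maximum(x - g, 0.0)
    scale = max(1.0, float(np.abs(g).max()))
    converged = float(np.linalg.norm(proj_grad)) / scale <= config.grad_tol \
        or rel_change <= config.rel_tol
    return PlanState(fluence=x, dose=dose, objective_value=f,
                     converged=bool(converged))
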