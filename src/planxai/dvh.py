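"""DVH extraction and criterion-based plan scoring.

The cumulative dose-volume histogram (DVH) of a structure gives, for each
dose level, the fraction of the structure's volume receiving at least that
dose.  Curves are sampled at 100 points uniformly spaced along the relative
dose axis (dose / prescription dose), and the three structure curves
concatenated as [PTV, bladder, rectum] form the 300-value network input.

Plans are scored against a criterion table in the style of the ProKnow
plan-quality system: each dose-volume criterion that is satisfied awards
points, with a maximum total of 9 for the default table.  The per-criterion
*dose violation* is the volume-fraction excess of the observed DVH point
beyond the criterion's limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import STRUCTURES, PhantomCase, PlanState

#: 100 relative-dose sample points, uniform on [0, 1.2] x prescription.
DEFAULT_GRID = np.linspace(0.0, 1.2, 100)


@dataclass(frozen=True)
class DVHCurve:
    structure: str
    rel_dose_grid: np.ndarray
    volume_fraction: np.ndarray

    def at(self, rel_dose: float) -> float:
        """Volume fraction at a relative dose, linearly interpolated."""
        return float(np.interp(rel_dose, self.rel_dose_grid, self.volume_fraction))


def compute_dvh(dose: np.ndarray, mask: np.ndarray, d_p: float,
                grid: np.ndarray = DEFAULT_GRID,
                structure: str = "") -> DVHCurve:
    """Cumulative DVH: fraction of ``mask`` voxels with dose >= grid * d_p."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty structure mask")
    d = np.asarray(dose, float)[mask]
    vf = (d[:, None] >= grid[None, :] * d_p).mean(axis=0)
    return DVHCurve(structure=structure, rel_dose_grid=grid, volume_fraction=vf)


def plan_dvhs(case: PhantomCase, plan: PlanState,
              grid: np.ndarray = DEFAULT_GRID) -> dict[str, DVHCurve]:
    return {s: compute_dvh(plan.dose, case.structure_masks[s],
                           case.prescription_dose, grid, structure=s)
            for s in STRUCTURES}


def dvh_input_vector(curves: dict[str, DVHCurve]) -> np.ndarray:
    """Concatenate the three 100-point curves into the 300-value input,
    ordered PTV, bladder, rectum."""
    missing = [s for s in STRUCTURES if s not in curves]
    if missing:
        raise ValueError(f"missing structures: {missing}")
    return np.concatenate([curves[s].volume_fraction for s in STRUCTURES])


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Criterion:
    structure: str
    rel_dose: float          # fraction of the prescription dose
    bound_type: str          # "at_most" | "at_least"
    volume_limit: float      # volume fraction in [0, 1]
    points: float

    def evaluate(self, curve: DVHCurve) -> tuple[bool, float]:
        """Return (passed, violation).  Violation is the volume-fraction
        excess beyond the limit; zero iff the criterion passes."""
        observed = curve.at(self.rel_dose)
        if self.bound_type == "at_most":
            violation = max(0.0, observed - self.volume_limit)
        elif self.bound_type == "at_least":
            violation = max(0.0, self.volume_limit - observed)
        else:
            raise ValueError(f"unknown bound type {self.bound_type!r}")
        return violation == 0.0, violation


@dataclass(frozen=True)
class CriteriaTable:
    criteria: tuple[Criterion, ...]

    @property
    def total_points(self) -> float:
        return float(sum(c.points for c in self.criteria))

    def for_structure(self, structure: str) -> list[Criterion]:
        return [c for c in self.criteria if c.structure == structure]

    @classmethod
    def default(cls) -> "CriteriaTable":
        """Default 9-point table: PTV coverage/hot-spot plus graded
        bladder and rectum dose-volume limits."""
        mk = Criterion
        return cls(criteria=(
            mk("PTV", 0.95, "at_least", 0.95, 2.0),
            mk("PTV", 1.07, "at_most", 0.10, 1.0),
            mk("BLA", 0.60, "at_most", 0.50, 1.0),
            mk("BLA", 0.80, "at_most", 0.30, 1.0),
            mk("BLA", 0.90, "at_most", 0.15, 1.0),
            mk("REC", 0.60, "at_most", 0.45, 1.0),
            mk("REC", 0.80, "at_most", 0.25, 1.0),
            mk("REC", 0.90, "at_most", 0.10, 1.0),
        ))

    @classmethod
    def from_config(cls, rows: list[dict]) -> "CriteriaTable":
        return cls(criteria=tuple(
            Criterion(r["structure"], float(r["rel_dose"]), r["bound_type"],
                      float(r["volume_limit"]), float(r["points"]))
            for r in rows))

    def to_config(self) -> list[dict]:
        return [{"structure": c.structure, "rel_dose": c.rel_dose,
                 "bound_type": c.bound_type, "volume_limit": c.volume_limit,
                 "points": c.points} for c in self.criteria]


@dataclass(frozen=True)
class ScoreCard:
    passed: tuple[bool, ...]
    awarded: tuple[float, ...]
    organ_scores: dict[str, float]
    total: float
    organ_violations: dict[str, float]

    @property
    def violations_vector(self) -> np.ndarray:
        """Organ violations ordered PTV, bladder, rectum."""
        return np.array([self.organ_violations[s] for s in STRUCTURES])

    @property
    def scores_vector(self) -> np.ndarray:
        return np.array([self.organ_scores[s] for s in STRUCTURES])


def score_plan(curves: dict[str, DVHCurve],
               criteria: CriteriaTable) -> ScoreCard:
    passed: list[bool] = []
    awarded: list[float] = []
    organ_scores = {s: 0.0 for s in STRUCTURES}
    organ_viol = {s: 0.0 for s in STRUCTURES}
    for crit in criteria.criteria:
        ok, violation = crit.evaluate(curves[crit.structure])
        passed.append(ok)
        pts = crit.points if ok else 0.0
        awarded.append(pts)
        organ_scores[crit.structure] += pts
        organ_viol[crit.structure] += violation
    return ScoreCard(passed=tuple(passed), awarded=tuple(awarded),
                     organ_scores=organ_scores,
                     total=float(sum(awarded)),
                     organ_violations=organ_viol)
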