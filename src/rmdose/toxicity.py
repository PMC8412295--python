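"""Normalized total toxicity profile (nTTP) scoring.

Phase I trials traditionally reduce a patient's adverse events in a cycle to
a single binary dose-limiting-toxicity (DLT) indicator, discarding the
information carried by moderate, non-dose-limiting events.  The total
toxicity profile (TTP) instead condenses the maximum observed grade of each
monitored toxicity type into a quasi-continuous score using
clinician-elicited severity weights: with weight ``w[l, h]`` for type ``l``
at grade ``h`` and observed grades ``G[l]``,

    nTTP = sqrt( sum_l w[l, G[l]]**2 ) / toxmax

where ``toxmax`` is a normalization constant chosen at design time so that
the score lies in [0, 1].  The DLT definition remains available alongside
the score via a per-type minimal DLT grade (e.g. grade >= 3 renal or
neurological toxicity, grade 4 hematological toxicity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError

N_GRADES = 5  # CTCAE grades 0-4


@dataclass(frozen=True)
class WeightMatrix:
    """Elicited severity weights plus the DLT rule for the monitored toxicity types.

    Parameters
    ----------
    type_names
        Labels of the L monitored toxicity types.
    weights
        L x 5 array of non-negative severity weights, columns indexed by
        grade 0-4.  Grade-0 weights must be zero and weights must be
        non-decreasing in grade within each type.
    toxmax
        Normalization constant; must be at least the Euclidean norm of the
        per-type maximal weights so that nTTP stays within [0, 1].
    dlt_min_grade
        Per-type minimal grade whose occurrence constitutes a DLT, or
        ``None`` if no grade of that type alone is dose limiting.
    """

    type_names: tuple[str, ...]
    weights: np.ndarray
    toxmax: float
    dlt_min_grade: tuple[int | None, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "type_names", tuple(self.type_names))
        object.__setattr__(self, "dlt_min_grade", tuple(self.dlt_min_grade))
        if w.ndim != 2 or w.shape[1] != N_GRADES:
            raise ValidationError(f"weights must be L x {N_GRADES}, got shape {w.shape}")
        L = w.shape[0]
        if len(self.type_names) != L or len(self.dlt_min_grade) != L:
            raise ValidationError("type_names, weights and dlt_min_grade disagree on L")
        if np.any(w < 0):
            raise ValidationError("severity weights must be non-negative")
        if np.any(w[:, 0] != 0):
            raise ValidationError("grade-0 weights must all be zero")
        if np.any(np.diff(w, axis=1) < 0):
            raise ValidationError("weights must be non-decreasing in grade within each type")
        if self.toxmax <= 0:
            raise ValidationError("toxmax must be positive")
        wmax = math.sqrt(float(np.sum(w[:, -1] ** 2)))
        if self.toxmax < wmax - 1e-12:
            raise ValidationError(
                f"toxmax={self.toxmax} < sqrt(sum of squared maximal weights)={wmax:.5g}; "
                "nTTP would exceed 1"
            )
        for g in self.dlt_min_grade:
            if g is not None and g not in (1, 2, 3, 4):
                raise ValidationError("dlt_min_grade entries must be in 1..4 or None")

    @property
    def n_types(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def default(cls) -> "WeightMatrix":
        """Renal / neurological / hematological weights of the worked example.

        Grades 1-4 of renal and neurological toxicity weigh
        (0.5, 0.75, 1, 1.5); hematological toxicity only weighs in at grades
        3-4 (0.5, 1).  DLT rule: grade >= 3 renal or neurological, grade 4
        hematological.  toxmax = 2.5.
        """
        return cls(
            type_names=("renal", "neurological", "hematological"),
            weights=np.array(
                [
                    [0.0, 0.5, 0.75, 1.0, 1.5],
                    [0.0, 0.5, 0.75, 1.0, 1.5],
                    [0.0, 0.0, 0.0, 0.5, 1.0],
                ]
            ),
            toxmax=2.5,
            dlt_min_grade=(3, 3, 4),
        )

    def to_dict(self) -> dict:
        return {
            "toxmax": float(self.toxmax),
            "types": [
                {
                    "name": name,
                    "weights": [float(v) for v in row],
                    "dlt_min_grade": g,
                }
                for name, row, g in zip(self.type_names, self.weights, self.dlt_min_grade)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WeightMatrix":
        try:
            types = d["types"]
            return cls(
                type_names=tuple(t["name"] for t in types),
                weights=np.array([t["weights"] for t in types], dtype=float),
                toxmax=float(d["toxmax"]),
                dlt_min_grade=tuple(t.get("dlt_min_grade") for t in types),
            )
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"malformed weight-matrix config: {exc}") from exc


def validate_grades(grades: Sequence[int], wm: WeightMatrix) -> np.ndarray:
    g = np.asarray(grades)
    if g.shape != (wm.n_types,):
        raise ValidationError(
            f"expected {wm.n_types} grades (one per toxicity type), got {g.shape}"
        )
    if not np.issubdtype(g.dtype, np.integer):
        if np.any(g != np.floor(g)):
            raise ValidationError("grades must be integers")
        g = g.astype(int)
    if np.any((g < 0) | (g > 4)):
        raise ValidationError("grades must lie in 0..4")
    return g


def compute_nttp(grades: Sequence[int], wm: WeightMatrix) -> float:
    """Normalized total toxicity profile for one patient-cycle.

    ``grades[l]`` is the maximum observed grade of toxicity type ``l`` in
    the cycle.  Returns sqrt(sum of squared realized weights) / toxmax,
    which is 0 for an all-grade-0 profile and at most 1 by the toxmax
    invariant.
    """
    g = validate_grades(grades, wm)
    w = wm.weights[np.arange(wm.n_types), g]
    return float(math.sqrt(float(np.sum(w**2))) / wm.toxmax)


def is_dlt(grades: Sequence[int], wm: WeightMatrix) -> bool:
    """True iff any type reached its per-type minimal DLT grade."""
    g = validate_grades(grades, wm)
    for grade, min_grade in zip(g, wm.dlt_min_grade):
        if min_grade is not None and grade >= min_grade:
            return True
    return False
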