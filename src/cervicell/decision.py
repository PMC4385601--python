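"""Rule-based abnormality detection and LSIL/HSIL/SCC grading.

Five criteria flag a cell as abnormal:

1. enlarged nucleus or N/C ratio relative to the normal reference;
2. low circularity or low compactness;
3. too many peaks/valleys in the radial boundary signature;
4. cytoplasm mean color inside the jacinth (hyperkeratosis) bands;
5. nucleus mean color below the dark-stain (hyperchromasia) bounds.

Criteria are evaluated in the order 1, 4, 5, 2, 3 for the purpose of
recording which one triggered first; all five are always computed so the
per-cell report is complete.  All inequalities are strict: values exactly
at a threshold do not trigger.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ValidationError
from .features import FeatureVector, NormalReference

__all__ = [
    "Grade",
    "GradingRules",
    "CriterionOutcome",
    "GradingEvaluation",
    "criterion1",
    "criterion2",
    "criterion3",
    "criterion4",
    "criterion5",
    "detect_abnormal",
    "grade_cell",
    "evaluate_grading",
]


class Grade(enum.Enum):
    """Cell grade; severity increases NORMAL < LSIL < HSIL < SCC."""

    NORMAL = "NORMAL"
    LSIL = "LSIL"
    HSIL = "HSIL"
    SCC = "SCC"

    @property
    def severity(self) -> int:
        return _SEVERITY[self]


_SEVERITY = {Grade.NORMAL: 0, Grade.LSIL: 1, Grade.HSIL: 2, Grade.SCC: 3}

#: Evaluation order for ``first_triggered``.
CRITERION_ORDER = (1, 4, 5, 2, 3)


@dataclass(frozen=True)
class GradingRules:
    """Thresholds of the three-way grading rules applied to abnormal cells.

    SCC: nucleus RGB strictly below ``scc_nucleus_rgb_max`` channel-wise and
    ``grad_A > scc_area_ratio_min`` and ``grad_P > scc_nc_ratio_min``.
    LSIL: ``C < lsil_circularity_max and E < lsil_compactness_max``, or
    ``grad_P < lsil_nc_ratio_max`` with nucleus RGB strictly below
    ``lsil_nucleus_rgb_max``.  Anything else abnormal grades HSIL.  SCC is
    checked before LSIL (the rules are not mutually exclusive).

    Note the SCC blue bound defaults to 200 even though detection
    Criterion 5 uses 190: the two rules are printed with different bounds
    and are kept independently configurable.
    """

    scc_nucleus_rgb_max: tuple[float, float, float] = (120.0, 120.0, 200.0)
    scc_area_ratio_min: float = 2.0
    scc_nc_ratio_min: float = 10.0
    lsil_circularity_max: float = 0.8
    lsil_compactness_max: float = 0.7
    lsil_nc_ratio_max: float = 5.0
    lsil_nucleus_rgb_max: tuple[float, float, float] = (170.0, 120.0, 200.0)


@dataclass
class CriterionOutcome:
    """Per-criterion booleans plus the first criterion that triggered."""

    c1: bool
    c2: bool
    c3: bool
    c4: bool
    c5: bool
    first_triggered: int | None
    abnormal: bool


@dataclass
class GradingEvaluation:
    """Confusion matrix and accuracy of predicted vs actual grades."""

    confusion: pd.DataFrame  # rows = detected grade, cols = actual grade
    n_correct: int
    n_total: int
    accuracy: float
    tolerated_misclassifications: list  # predicted less severe than actual
    overcalled_misclassifications: list  # predicted more severe than actual


def criterion1(grad_A: float, grad_P: float, ref: NormalReference) -> bool:
    """Size criterion: enlarged nucleus area ratio or N/C ratio."""
    return grad_P > ref.nc_ratio_max or grad_A > ref.area_ratio_max


def criterion2(C: float, E: float, ref: NormalReference) -> bool:
    """Shape criterion: circularity or compactness below normal."""
    return C < ref.circularity_min or E < ref.compactness_min


def criterion3(N: int, ref: NormalReference) -> bool:
    """Boundary-irregularity criterion: too many signature extrema."""
    return N > ref.extrema_max


def criterion4(cytoplasm_rgb: Sequence[float], ref: NormalReference) -> bool:
    """Hyperkeratosis criterion: cytoplasm mean color inside all jacinth bands."""
    r, g, b = cytoplasm_rgb
    return (
        ref.jacinth_r[0] < r < ref.jacinth_r[1]
        and ref.jacinth_g[0] < g < ref.jacinth_g[1]
        and ref.jacinth_b[0] < b < ref.jacinth_b[1]
    )


def criterion5(nucleus_rgb: Sequence[float], ref: NormalReference) -> bool:
    """Hyperchromasia criterion: nucleus mean color below the dark-stain bounds."""
    r, g, b = nucleus_rgb
    return r < ref.dark_r and g < ref.dark_g and b < ref.dark_b


def detect_abnormal(fv: FeatureVector, ref: NormalReference) -> CriterionOutcome:
    """Evaluate all five criteria; abnormal iff any triggers."""
    for name in ("grad_A", "grad_P", "C", "E", "N", "nucleus_rgb", "cytoplasm_rgb"):
        if getattr(fv, name, None) is None:
            raise ValidationError(f"feature vector is missing {name}")
    results = {
        1: criterion1(fv.grad_A, fv.grad_P, ref),
        2: criterion2(fv.C, fv.E, ref),
        3: criterion3(fv.N, ref),
        4: criterion4(fv.cytoplasm_rgb, ref),
        5: criterion5(fv.nucleus_rgb, ref),
    }
    first = next((k for k in CRITERION_ORDER if results[k]), None)
    return CriterionOutcome(
        c1=results[1],
        c2=results[2],
        c3=results[3],
        c4=results[4],
        c5=results[5],
        first_triggered=first,
        abnormal=any(results.values()),
    )


def grade_cell(
    fv: FeatureVector,
    outcome: CriterionOutcome,
    rules: GradingRules | None = None,
) -> Grade:
    """Grade a cell: NORMAL if not abnormal, else SCC, LSIL, or HSIL.

    The SCC rule is tested first, then LSIL; remaining abnormal cells are
    HSIL.  All comparisons are strict.
    """
    rules = rules or GradingRules()
    if not outcome.abnormal:
        return Grade.NORMAL
    nr, ng, nb = fv.nucleus_rgb
    sr, sg, sb = rules.scc_nucleus_rgb_max
    if (
        nr < sr
        and ng < sg
        and nb < sb
        and fv.grad_A > rules.scc_area_ratio_min
        and fv.grad_P > rules.scc_nc_ratio_min
    ):
        return Grade.SCC
    lr, lg, lb = rules.lsil_nucleus_rgb_max
    if (fv.C < rules.lsil_circularity_max and fv.E < rules.lsil_compactness_max) or (
        fv.grad_P < rules.lsil_nc_ratio_max and nr < lr and ng < lg and nb < lb
    ):
        return Grade.LSIL
    return Grade.HSIL


_GRADE_ORDER = [Grade.LSIL, Grade.HSIL, Grade.SCC]


def evaluate_grading(
    predicted: Mapping, actual: Mapping, severity_tolerant: bool = False
) -> GradingEvaluation:
    """Compare predicted against actual grades over matched sample ids.

    Both mappings must share exactly the same keys and contain only
    LSIL/HSIL/SCC grades.  With ``severity_tolerant=True`` the
    misclassifications are additionally split into tolerated (predicted
    less severe than actual) and overcalled (predicted more severe).
    """
    if set(predicted) != set(actual):
        raise ValidationError(
            "predicted and actual grade maps must cover the same sample ids; "
            f"difference: {set(predicted) ^ set(actual)}"
        )
    if not predicted:
        raise ValidationError("empty grade maps")
    names = [g.value for g in _GRADE_ORDER]
    conf = pd.DataFrame(
        np.zeros((3, 3), dtype=int), index=names, columns=names
    )
    conf.index.name = "detected"
    conf.columns.name = "actual"
    tolerated, overcalled = [], []
    n_correct = 0
    for sid in sorted(predicted, key=str):
        p, a = predicted[sid], actual[sid]
        if p not in _GRADE_ORDER or a not in _GRADE_ORDER:
            raise ValidationError(
                f"sample {sid}: grades must be LSIL/HSIL/SCC, got {p} vs {a}"
            )
        conf.loc[p.value, a.value] += 1
        if p is a:
            n_correct += 1
        elif severity_tolerant:
            (tolerated if p.severity < a.severity else overcalled).append(sid)
    n_total = len(predicted)
    return GradingEvaluation(
        confusion=conf,
        n_correct=n_correct,
        n_total=n_total,
        accuracy=n_correct / n_total,
        tolerated_misclassifications=tolerated,
        overcalled_misclassifications=overcalled,
    )
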