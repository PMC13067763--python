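"""Base Editor Performance Index (BEPI) formulas and their evaluation framework.

A cytosine base editor is characterised by two headline percentages: the
C-to-T conversion rate it achieves at its target window, and the frequency
of unwanted indels it leaves behind. A composite score that trades the two
off against each other lets variants be ranked on a single axis. The
selected formulation divides a linearly indel-penalised activity by an
exponential indel penalty:

    BEPI = (C-to-T - Indel) / exp(Indel / 10)

Its precursor omits the linear term (C-to-T / exp(Indel/10)) and is kept
for comparison; it discriminates poorly between zero and low indel levels.

Candidate formulations are screened on a 7 x 8 grid of simulated scenarios
(seven C-to-T levels spanning 2.5-100 %, eight indel levels spanning
0-10 %, 56 cells) against three behavioural criteria: monotone response to
activity, monotone penalty for indels, and correct ordering of
high-efficiency/high-indel versus mid-efficiency/mid-indel editors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EditingOutcome",
    "BepiFormula",
    "EvaluationGrid",
    "CriteriaReport",
    "bepi_formula14",
    "bepi_formula11",
    "FORMULA_REGISTRY",
    "register_formula",
    "get_formula",
    "evaluate_grid",
    "sensitivity_profile",
    "criteria_check",
    "rank_variants",
    "DEFAULT_C_LEVELS",
    "DEFAULT_INDEL_LEVELS",
]

#: Seven C-to-T conversion levels (percent). Count and endpoints are fixed
#: by the screening design; interior points are configurable.
DEFAULT_C_LEVELS: tuple[float, ...] = (2.5, 5.0, 10.0, 25.0, 50.0, 75.0, 100.0)

#: Eight indel frequency levels (percent), spanning 0-10.
DEFAULT_INDEL_LEVELS: tuple[float, ...] = (0.0, 0.5, 1.0, 2.5, 5.0, 7.5, 9.0, 10.0)


@dataclass(frozen=True)
class EditingOutcome:
    """A (C-to-T %, indel %) pair — the argument of every BEPI formula.

    Both fields are percentages in [0, 100].
    """

    c_to_t: float
    indel: float

    def __post_init__(self) -> None:
        for name in ("c_to_t", "indel"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
            if not 0.0 <= value <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {value!r}")


@dataclass(frozen=True)
class BepiFormula:
    """A registered BEPI formulation.

    ``evaluator`` maps an :class:`EditingOutcome` to a real score. The four
    families mirror the screened design space: arithmetic operations,
    rational functions, logarithmic scaling and exponential-decay penalties.
    """

    id: int
    family: str
    evaluator: Callable[[EditingOutcome], float]
    description: str = ""

    _FAMILIES = frozenset(
        {"arithmetic", "rational", "logarithmic", "exponential-decay"}
    )

    def __post_init__(self) -> None:
        if not 1 <= self.id <= 15:
            raise ValueError(f"formula id must be 1-15, got {self.id}")
        if self.family not in self._FAMILIES:
            raise ValueError(f"unknown formula family {self.family!r}")

    def __call__(self, outcome: EditingOutcome | tuple[float, float]) -> float:
        if not isinstance(outcome, EditingOutcome):
            outcome = EditingOutcome(*outcome)
        score = float(self.evaluator(outcome))
        if not math.isfinite(score):
            raise ValueError(
                f"formula {self.id} produced non-finite score for {outcome}"
            )
        return score


def bepi_formula14(outcome: EditingOutcome | tuple[float, float]) -> float:
    """Selected BEPI: ``(c_to_t - indel) / exp(indel / 10)``.

    May be negative when the indel rate exceeds the conversion rate; the
    value is returned as-is (clamping would hide that pathology).
    """
    if not isinstance(outcome, EditingOutcome):
        outcome = EditingOutcome(*outcome)
    return (outcome.c_to_t - outcome.indel) / math.exp(outcome.indel / 10.0)


def bepi_formula11(outcome: EditingOutcome | tuple[float, float]) -> float:
    """Precursor BEPI: ``c_to_t / exp(indel / 10)``; always >= 0.

    Shares the exponential penalty with the selected form but lacks its
    linear numerator term, so discrimination between 0 % and low indel
    levels is weak.
    """
    if not isinstance(outcome, EditingOutcome):
        outcome = EditingOutcome(*outcome)
    return outcome.c_to_t / math.exp(outcome.indel / 10.0)


#: Registry of the fifteen screened formulations. Only formulas 11 and 14
#: have published algebra; the remaining slots are deliberate placeholders
#: (value ``None``) that users can fill via :func:`register_formula` — the
#: package never invents their algebra.
FORMULA_REGISTRY: dict[int, BepiFormula | None] = {i: None for i in range(1, 16)}
FORMULA_REGISTRY[11] = BepiFormula(
    11, "exponential-decay", bepi_formula11, "C-to-T / exp(Indel/10)"
)
FORMULA_REGISTRY[14] = BepiFormula(
    14, "exponential-decay", bepi_formula14, "(C-to-T - Indel) / exp(Indel/10)"
)


def register_formula(formula: BepiFormula, overwrite: bool = False) -> None:
    """Install a user-supplied formulation into the registry."""
    existing = FORMULA_REGISTRY.get(formula.id)
    if existing is not None and not overwrite:
        raise ValueError(f"formula {formula.id} already registered")
    FORMULA_REGISTRY[formula.id] = formula


def get_formula(formula_id: int) -> BepiFormula:
    formula = FORMULA_REGISTRY.get(formula_id)
    if formula is None:
        raise KeyError(
            f"formula {formula_id} has no registered algebra "
            "(only 11 and 14 are published; use register_formula)"
        )
    return formula


@dataclass(frozen=True)
class EvaluationGrid:
    """The 7 x 8 scenario grid a formulation is screened on (56 cells)."""

    c_levels: tuple[float, ...]
    indel_levels: tuple[float, ...]
    scores: np.ndarray  # shape (7, 8): rows = c levels, cols = indel levels

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.c_levels), len(self.indel_levels)):
            raise ValueError("score matrix shape mismatch")

    @property
    def n_cells(self) -> int:
        return self.scores.size

    def as_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with columns c_to_t, indel, score."""
        rows = [
            (c, d, self.scores[i, j])
            for i, c in enumerate(self.c_levels)
            for j, d in enumerate(self.indel_levels)
        ]
        return pd.DataFrame(rows, columns=["c_to_t", "indel", "score"])


def _validate_levels(
    levels: Sequence[float], n: int, lo: float, hi: float, what: str
) -> tuple[float, ...]:
    levels = tuple(float(x) for x in levels)
    if len(levels) != n:
        raise ValueError(f"expected {n} {what} levels, got {len(levels)}")
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError(f"{what} levels must be strictly increasing")
    if levels[0] < lo or levels[-1] > hi:
        raise ValueError(f"{what} levels must lie within [{lo}, {hi}]")
    return levels


def evaluate_grid(
    formula: BepiFormula | Callable[[EditingOutcome], float],
    c_levels: Sequence[float] = DEFAULT_C_LEVELS,
    indel_levels: Sequence[float] = DEFAULT_INDEL_LEVELS,
) -> EvaluationGrid:
    """Evaluate a formulation on the 7 C-to-T x 8 indel scenario grid."""
    c_levels = _validate_levels(c_levels, 7, 2.5, 100.0, "C-to-T")
    indel_levels = _validate_levels(indel_levels, 8, 0.0, 10.0, "indel")
    scores = np.empty((7, 8))
    for i, c in enumerate(c_levels):
        for j, d in enumerate(indel_levels):
            scores[i, j] = formula(EditingOutcome(c, d))
    if not np.all(np.isfinite(scores)):
        raise ValueError("formula produced non-finite grid values")
    return EvaluationGrid(c_levels, indel_levels, scores)


def sensitivity_profile(
    formula: BepiFormula | Callable[[EditingOutcome], float],
    c_fixed: Sequence[float] = (10.0, 25.0, 50.0, 75.0),
    indel_range: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Score-versus-indel curves at fixed C-to-T levels (for plotting).

    Returns a long-format DataFrame with columns ``c_to_t``, ``indel``,
    ``score``: one curve per fixed conversion level across the 0-10 %
    indel range.
    """
    if len(c_fixed) == 0:
        raise ValueError("c_fixed must be non-empty")
    if indel_range is None:
        indel_range = np.linspace(0.0, 10.0, 41)
    indel_range = np.asarray(indel_range, dtype=float)
    if indel_range.size == 0:
        raise ValueError("indel_range must be non-empty")
    rows = [
        (c, d, formula(EditingOutcome(c, d)))
        for c in c_fixed
        for d in indel_range
    ]
    return pd.DataFrame(rows, columns=["c_to_t", "indel", "score"])


@dataclass(frozen=True)
class CriteriaReport:
    """Outcome of the behavioural screen applied to one formulation.

    ``high_efficiency_ordering`` asks whether an editor at 75 % conversion
    with 7.5 % indels outscores one at 50 % conversion with 5 % indels —
    the trade-off a useful composite must reward.
    ``low_indel_discrimination`` is score(c, 0) - score(c, 1) at a
    reference conversion level; larger means better separation of
    zero-indel from low-indel conditions.
    """

    monotone_in_activity: bool
    monotone_in_indel: bool
    high_efficiency_ordering: bool
    low_indel_discrimination: float
    notes: str = ""

    @property
    def passes_all(self) -> bool:
        return (
            self.monotone_in_activity
            and self.monotone_in_indel
            and self.high_efficiency_ordering
        )


def criteria_check(
    formula: BepiFormula | Callable[[EditingOutcome], float],
    c_levels: Sequence[float] = DEFAULT_C_LEVELS,
    indel_levels: Sequence[float] = DEFAULT_INDEL_LEVELS,
    reference_c: float = 50.0,
) -> CriteriaReport:
    """Screen a formulation against the three selection criteria.

    All flags derive solely from grid evaluations: activity monotonicity is
    checked down every indel column, indel monotonicity (strictly
    decreasing, so an indel-blind formula fails) along every C-to-T row.
    """
    grid = evaluate_grid(formula, c_levels, indel_levels)
    s = grid.scores
    monotone_in_activity = bool(np.all(np.diff(s, axis=0) > 0))
    monotone_in_indel = bool(np.all(np.diff(s, axis=1) < 0))
    high = formula(EditingOutcome(75.0, 7.5))
    mid = formula(EditingOutcome(50.0, 5.0))
    discrimination = float(
        formula(EditingOutcome(reference_c, 0.0))
        - formula(EditingOutcome(reference_c, 1.0))
    )
    return CriteriaReport(
        monotone_in_activity=monotone_in_activity,
        monotone_in_indel=monotone_in_indel,
        high_efficiency_ordering=bool(high > mid),
        low_indel_discrimination=discrimination,
        notes=f"score(75,7.5)={high:.3f} vs score(50,5)={mid:.3f}",
    )


def rank_variants(
    outcomes: Mapping[str, EditingOutcome | tuple[float, float]],
    formula: BepiFormula | Callable[[EditingOutcome], float] = bepi_formula14,
) -> pd.DataFrame:
    """Rank named variants by descending score; ties break lexicographically.

    Returns a DataFrame with columns ``variant``, ``c_to_t``, ``indel``,
    ``score``, ``rank`` (1 = best). Duplicate names are rejected.
    """
    names = list(outcomes)
    if len(names) != len(set(names)):
        raise ValueError("variant names must be unique")
    rows = []
    for name in names:
        outcome = outcomes[name]
        if not isinstance(outcome, EditingOutcome):
            outcome = EditingOutcome(*outcome)
        rows.append((name, outcome.c_to_t, outcome.indel, formula(outcome)))
    frame = pd.DataFrame(rows, columns=["variant", "c_to_t", "indel", "score"])
    frame = frame.sort_values(
        ["score", "variant"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame
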