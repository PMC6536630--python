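"""Condition grid, class-level sampling and missingness patterns.

The simulation varies three factors: students per class (n2), number of
classes (n3) and a missingness pattern applied to the drawn sample:

* ``COM`` — complete data, nothing removed.
* ``MCAR`` — records missing completely at random.  By default 20% of all
  occasion-level rows are deleted uniformly; a student-level variant
  (20% of students each losing a random subset of occasions) is available
  via ``MissingnessPattern(student_level=True)``.
* ``DrOP2`` / ``DrOP3`` — 20% of students drop out and lose their last
  two / three occasions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "MissingnessPattern",
    "PATTERNS",
    "enumerate_conditions",
    "draw_sample",
    "impose_missingness",
]

DEFAULT_N2_LEVELS = (5, 15, 35)
DEFAULT_N3_LEVELS = (15, 35, 55)
DEFAULT_PATTERN_NAMES = ("COM", "MCAR", "DrOP2", "DrOP3")


@dataclass(frozen=True)
class MissingnessPattern:
    """Definition of one missing-value mechanism.

    ``student_fraction`` is the proportion of students affected (0 for
    complete data).  ``dropped_occasions`` lists the occasion indices a
    dropped-out student loses; it is empty for MCAR, where deletion is
    record-level (or per-student random subsets when ``student_level``).
    """

    name: str
    student_fraction: float = 0.0
    dropped_occasions: tuple[int, ...] = ()
    record_fraction: float = 0.0
    student_level: bool = False

    def __post_init__(self) -> None:
        for frac in (self.student_fraction, self.record_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("missingness fractions must lie in [0, 1]")
        occ = tuple(int(i) for i in self.dropped_occasions)
        if any(i < 0 for i in occ):
            raise ValueError("dropped_occasions must be valid indices")
        object.__setattr__(self, "dropped_occasions", occ)


PATTERNS: dict[str, MissingnessPattern] = {
    "COM": MissingnessPattern("COM"),
    "MCAR": MissingnessPattern("MCAR", student_fraction=0.20, record_fraction=0.20),
    "DrOP2": MissingnessPattern("DrOP2", student_fraction=0.20, dropped_occasions=(3, 4)),
    "DrOP3": MissingnessPattern("DrOP3", student_fraction=0.20, dropped_occasions=(2, 3, 4)),
}


@dataclass(frozen=True)
class Condition:
    """One cell of the n2 x n3 x pattern design."""

    n2: int
    n3: int
    pattern: str
    replicates: int = 1000

    def __post_init__(self) -> None:
        if self.n2 < 1 or self.n3 < 1 or self.replicates < 1:
            raise ValueError("n2, n3 and replicates must be positive")
        if self.pattern not in PATTERNS:
            raise ValueError(
                f"unknown pattern {self.pattern!r}; known: {sorted(PATTERNS)}"
            )

    @property
    def label(self) -> str:
        return f"{self.n2}/{self.n3}/{self.pattern}"


def enumerate_conditions(
    n2_levels: Sequence[int] = DEFAULT_N2_LEVELS,
    n3_levels: Sequence[int] = DEFAULT_N3_LEVELS,
    patterns: Sequence[str] = DEFAULT_PATTERN_NAMES,
    replicates: int = 1000,
) -> list[Condition]:
    """Cartesian product of the design factors in deterministic order.

    n2 varies slowest, then n3, then pattern; the default grid yields the
    36 study conditions.
    """
    if not n2_levels or not n3_levels or not patterns:
        raise ValueError("each design factor needs at least one level")
    return [
        Condition(n2=n2, n3=n3, pattern=p, replicates=replicates)
        for n2, n3, p in product(n2_levels, n3_levels, patterns)
    ]


def draw_sample(
    population: pd.DataFrame,
    condition: Condition,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw ``condition.n3`` classes without replacement from the matching
    class-size stratum and return all their rows.
    """
    stratum = population.loc[population["stratum"] == condition.n2]
    class_ids = stratum["class_id"].unique()
    if class_ids.size < condition.n3:
        raise ValueError(
            f"stratum n2={condition.n2} holds {class_ids.size} classes; "
            f"cannot draw {condition.n3} without replacement"
        )
    chosen = rng.choice(class_ids, size=condition.n3, replace=False)
    return stratum.loc[stratum["class_id"].isin(chosen)].reset_index(drop=True)


def _round_half_even(x: float) -> int:
    return int(round(x))  # Python round: banker's rounding


def impose_missingness(
    sample: pd.DataFrame,
    pattern: MissingnessPattern | str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Return a copy of ``sample`` with rows deleted per the pattern.

    Rows are only ever removed; surviving rows are byte-identical to the
    input.  A student may lose all occasions under MCAR.
    """
    if isinstance(pattern, str):
        pattern = PATTERNS[pattern]

    if pattern.name == "COM" or (
        pattern.student_fraction == 0 and pattern.record_fraction == 0
    ):
        return sample.copy()

    if pattern.dropped_occasions:  # dropout: students lose late occasions
        students = (
            sample[["class_id", "student_id"]].drop_duplicates().to_numpy()
        )
        n_drop = _round_half_even(pattern.student_fraction * len(students))
        idx = rng.choice(len(students), size=n_drop, replace=False)
        dropped = {tuple(row) for row in students[idx]}
        keys = list(zip(sample["class_id"], sample["student_id"]))
        is_dropped = np.fromiter(
            (k in dropped for k in keys), dtype=bool, count=len(keys)
        )
        lost = is_dropped & sample["occasion_index"].isin(
            pattern.dropped_occasions
        ).to_numpy()
        return sample.loc[~lost].reset_index(drop=True)

    if not pattern.student_level:  # record-level MCAR (default)
        n_rows = len(sample)
        n_del = _round_half_even(pattern.record_fraction * n_rows)
        kill = rng.choice(n_rows, size=n_del, replace=False)
        mask = np.ones(n_rows, dtype=bool)
        mask[kill] = False
        return sample.loc[mask].reset_index(drop=True)

    # student-level MCAR variant: affected students each lose a uniformly
    # chosen non-empty subset of their occasions
    students = sample[["class_id", "student_id"]].drop_duplicates().to_numpy()
    n_aff = _round_half_even(pattern.student_fraction * len(students))
    idx = rng.choice(len(students), size=n_aff, replace=False)
    affected = {tuple(row) for row in students[idx]}
    occ_values = np.sort(sample["occasion_index"].unique())
    lose: dict[tuple, set[int]] = {}
    for key in sorted(affected):
        k = int(rng.integers(1, occ_values.size + 1))
        lose[key] = set(rng.choice(occ_values, size=k, replace=False).tolist())
    drop_mask = np.fromiter(
        (
            (cid, sid) in lose and occ in lose[(cid, sid)]
            for cid, sid, occ in zip(
                sample["class_id"], sample["student_id"], sample["occasion_index"]
            )
        ),
        dtype=bool,
        count=len(sample),
    )
    return sample.loc[~drop_mask].reset_index(drop=True)
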