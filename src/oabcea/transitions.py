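"""Month-indexed symptom-severity transition matrices.

A :class:`TransitionModel` holds, for one drug, a row-stochastic L x L
matrix per symptom dimension (micturition frequency, incontinence) and
per month 1-3 of treatment.  Months beyond 3 reuse the month-3 matrix:
the treatment effect of antimuscarinics observed at 3 months is assumed
sustained, so the month 2 -> 3 transition matrix applies for the rest of
the time on that drug.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

DIMENSIONS = ("micturition", "incontinence")
MONTHS = (1, 2, 3)

#: tolerance for row-stochasticity checks
ROW_TOL = 1e-9


@dataclass(eq=False)
class TransitionModel:
    """Per-drug monthly symptom transition matrices.

    Parameters
    ----------
    drug : str
        Drug label the matrices belong to.
    matrices : dict
        ``matrices[dimension][month]`` is an (L, L) row-stochastic array of
        P(level_month = j | level_{month-1} = i) with levels 1..L mapped to
        rows/columns 0..L-1.  Months are 1, 2, 3.
    """

    drug: str
    matrices: dict[str, dict[int, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for dim in self.matrices:
            for m in self.matrices[dim]:
                self.matrices[dim][m] = np.asarray(self.matrices[dim][m], dtype=float)

    # -- access ---------------------------------------------------------
    @property
    def n_levels(self) -> int:
        dim = next(iter(self.matrices))
        return self.matrices[dim][1].shape[0]

    def matrix(self, dimension: str, month: int) -> np.ndarray:
        """Matrix for a given month on treatment; months > 3 reuse month 3."""
        if month < 1:
            raise ValueError(f"month must be >= 1, got {month}")
        return self.matrices[dimension][min(int(month), 3)]

    # -- validation -----------------------------------------------------
    def validate(self) -> list[str]:
        problems: list[str] = []
        for dim in DIMENSIONS:
            if dim not in self.matrices:
                problems.append(f"{self.drug}: missing dimension '{dim}'")
                continue
            for m in MONTHS:
                if m not in self.matrices[dim]:
                    problems.append(f"{self.drug}/{dim}: missing month {m}")
                    continue
                mat = self.matrices[dim][m]
                if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
                    problems.append(f"{self.drug}/{dim}/m{m}: not square")
                    continue
                if np.any(mat < -ROW_TOL) or np.any(mat > 1 + ROW_TOL):
                    problems.append(f"{self.drug}/{dim}/m{m}: entries outside [0,1]")
                if np.any(np.abs(mat.sum(axis=1) - 1.0) > ROW_TOL):
                    problems.append(f"{self.drug}/{dim}/m{m}: rows do not sum to 1")
        return problems

    def is_valid(self) -> bool:
        return not self.validate()

    # -- identity / copies ---------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TransitionModel):
            return NotImplemented
        if self.drug != other.drug:
            return False
        if set(self.matrices) != set(other.matrices):
            return False
        for dim in self.matrices:
            if set(self.matrices[dim]) != set(other.matrices[dim]):
                return False
            for m in self.matrices[dim]:
                if not np.array_equal(self.matrices[dim][m], other.matrices[dim][m]):
                    return False
        return True

    def copy(self) -> "TransitionModel":
        return TransitionModel(
            drug=self.drug,
            matrices={
                dim: {m: mat.copy() for m, mat in months.items()}
                for dim, months in self.matrices.items()
            },
        )

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            dim: {int(m): mat.tolist() for m, mat in months.items()}
            for dim, months in self.matrices.items()
        }

    @classmethod
    def from_dict(cls, drug: str, data: dict) -> "TransitionModel":
        matrices = {
            dim: {int(m): np.asarray(mat, dtype=float) for m, mat in months.items()}
            for dim, months in data.items()
        }
        return cls(drug=drug, matrices=matrices)

    def write_csv(self, directory: str) -> list[str]:
        """Write one CSV per (dimension, month), 5x5 with level header row/column."""
        os.makedirs(directory, exist_ok=True)
        written = []
        levels = [str(i + 1) for i in range(self.n_levels)]
        for dim, months in self.matrices.items():
            for m, mat in months.items():
                path = os.path.join(directory, f"{self.drug}_{dim}_month{m}.csv")
                with open(path, "w", encoding="utf-8") as fh:
                    fh.write("level," + ",".join(levels) + "\n")
                    for i, row in enumerate(mat):
                        fh.write(levels[i] + "," + ",".join(repr(float(x)) for x in row) + "\n")
                written.append(path)
        return written

    @classmethod
    def read_csv(cls, drug: str, directory: str) -> "TransitionModel":
        matrices: dict[str, dict[int, np.ndarray]] = {}
        for dim in DIMENSIONS:
            matrices[dim] = {}
            for m in MONTHS:
                path = os.path.join(directory, f"{drug}_{dim}_month{m}.csv")
                rows = []
                with open(path, encoding="utf-8") as fh:
                    next(fh)  # header
                    for line in fh:
                        rows.append([float(x) for x in line.strip().split(",")[1:]])
                matrices[dim][m] = np.asarray(rows, dtype=float)
        return cls(drug=drug, matrices=matrices)


def identity_model(drug: str, n_levels: int) -> TransitionModel:
    """Transition model with frozen symptom dynamics (identity matrices)."""
    eye = np.eye(n_levels)
    return TransitionModel(
        drug=drug,
        matrices={dim: {m: eye.copy() for m in MONTHS} for dim in DIMENSIONS},
    )
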