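"""Fleiss's kappa for multi-rater categorical assessments.

In the anisotropy workflow, several raters classify 2D-FFT images (e.g. as
healthy "arc" vs pathological "scatter"); Fleiss's kappa measures their
chance-corrected agreement.  For N subjects each rated by n raters into K
categories, with n_ij raters assigning subject i to category j:

    P_j = (1/(N·n)) Σ_i n_ij              (category proportions)
    P_i = Σ_j n_ij(n_ij − 1) / (n(n−1))   (per-subject pairwise agreement)
    P_o = (1/N) Σ_i P_i                   (observed agreement)
    P_e = Σ_j P_j²                        (chance agreement)
    κ   = (P_o − P_e) / (1 − P_e)

P_i is exactly the fraction of the n(n−1)/2 rater pairs that agree on
subject i.  κ is interpreted on the Landis–Koch scale (slight / fair /
moderate / substantial / almost perfect).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateKappaError, RatingValidationError

__all__ = [
    "RatingTable",
    "KappaResult",
    "category_proportions",
    "subject_agreement",
    "fleiss_kappa",
    "interpret_kappa",
]


@dataclass(frozen=True)
class RatingTable:
    """Subjects × categories count matrix with a fixed number of raters."""

    counts: np.ndarray
    subject_ids: tuple = ()
    category_labels: tuple = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise RatingValidationError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.round(counts)):
                raise RatingValidationError("counts must be integers")
            counts = counts.astype(int)
        if np.any(counts < 0):
            raise RatingValidationError("counts must be nonnegative")
        n_subj, n_cat = counts.shape
        if n_subj < 2 or n_cat < 2:
            raise RatingValidationError("need at least 2 subjects and 2 categories")
        row_sums = counts.sum(axis=1)
        if not np.all(row_sums == row_sums[0]):
            raise RatingValidationError("every subject must be rated by the same number of raters")
        if row_sums[0] < 2:
            raise RatingValidationError("need at least 2 raters per subject")
        object.__setattr__(self, "counts", counts)
        if not self.subject_ids:
            object.__setattr__(self, "subject_ids", tuple(range(n_subj)))
        if not self.category_labels:
            object.__setattr__(self, "category_labels", tuple(range(n_cat)))
        if len(self.subject_ids) != n_subj or len(self.category_labels) != n_cat:
            raise RatingValidationError("id/label lengths do not match the count matrix")

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[0]

    @property
    def n_categories(self) -> int:
        return self.counts.shape[1]

    @property
    def n_raters(self) -> int:
        return int(self.counts[0].sum())

    @classmethod
    def from_long(cls, records: pd.DataFrame | Iterable[tuple]) -> "RatingTable":
        """Aggregate long-format (subject_id, rater_id, category) records."""
        if not isinstance(records, pd.DataFrame):
            records = pd.DataFrame(records, columns=["subject_id", "rater_id", "category"])
        required = {"subject_id", "rater_id", "category"}
        if not required.issubset(records.columns):
            raise RatingValidationError(f"long format needs columns {sorted(required)}")
        if records.duplicated(["subject_id", "rater_id"]).any():
            raise RatingValidationError("a rater rated the same subject twice")
        table = pd.crosstab(records["subject_id"], records["category"])
        return cls(
            counts=table.to_numpy(),
            subject_ids=tuple(table.index),
            category_labels=tuple(table.columns),
        )


@dataclass(frozen=True)
class KappaResult:
    P_j: np.ndarray
    P_i: np.ndarray
    P_o: float
    P_e: float
    kappa: float
    label: str
    n_subjects: int
    n_raters: int
    n_categories: int


def category_proportions(table: RatingTable) -> np.ndarray:
    """P_j: fraction of all assignments falling in each category (sums to 1)."""
    return table.counts.sum(axis=0) / float(table.n_subjects * table.n_raters)


def subject_agreement(table: RatingTable) -> np.ndarray:
    """P_i: fraction of agreeing rater pairs for each subject."""
    n = table.n_raters
    if n < 2:
        raise RatingValidationError("pairwise agreement undefined for < 2 raters")
    c = table.counts
    return (c * (c - 1)).sum(axis=1) / float(n * (n - 1))


def fleiss_kappa(table: RatingTable) -> KappaResult:
    """The full Fleiss chain: P_j, P_i, P_o, P_e, kappa and its verbal band."""
    p_j = category_proportions(table)
    p_i = subject_agreement(table)
    p_o = float(p_i.mean())
    p_e = float(np.sum(p_j**2))
    if p_e >= 1.0:
        raise DegenerateKappaError("all ratings in one category: chance agreement is 1")
    kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(
        P_j=p_j,
        P_i=p_i,
        P_o=p_o,
        P_e=p_e,
        kappa=kappa,
        label=interpret_kappa(kappa),
        n_subjects=table.n_subjects,
        n_raters=table.n_raters,
        n_categories=table.n_categories,
    )


#: Landis–Koch bands; edges at two-decimal midpoints so that the printed
#: two-decimal band endpoints (0.20 slight / 0.21 fair, ...) round correctly.
_BAND_EDGES = (0.205, 0.405, 0.605, 0.805)
_BAND_LABELS = ("slight", "fair", "moderate", "substantial", "almost perfect")


def interpret_kappa(kappa: float) -> str:
    """Verbal Landis–Koch interpretation of a kappa value (kappa <= 1)."""
    if kappa > 1.0 + 1e-12:
        raise RatingValidationError(f"kappa {kappa} exceeds 1")
    if kappa < 0.0:
        return "poor (below chance)"
    for edge, label in zip(_BAND_EDGES, _BAND_LABELS):
        if kappa < edge:
            return label
    return _BAND_LABELS[-1]
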