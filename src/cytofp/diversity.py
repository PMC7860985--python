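"""Hill-number alpha-diversity and Bray-Curtis beta-diversity.

Diversity is computed on relative-abundance vectors regardless of what the
units are: strains of a known composition, mixture components, or grid bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import AlignmentError, UndefinedStatisticError
from .tables import CountTable


@dataclass
class Composition:
    """A unit-sum relative-abundance vector over S named units."""

    labels: list[str]
    p: np.ndarray

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 1 or len(self.p) != len(self.labels):
            raise ValueError("p must be 1-D and match labels")
        if np.any(self.p < 0):
            raise ValueError("abundances must be nonnegative")
        total = self.p.sum()
        if total == 0:
            raise UndefinedStatisticError("all-zero composition")
        if abs(total - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1 (renormalize first)")

    @classmethod
    def from_counts(cls, labels, counts) -> "Composition":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total == 0:
            raise UndefinedStatisticError("all-zero composition")
        return cls(list(labels), counts / total)


@dataclass(frozen=True)
class DiversityResult:
    sample_id: str
    q: float
    value: float


def hill_number(comp: Composition, q: float) -> float:
    """Effective number of units of order q.

    q=0 counts units with positive abundance (richness); q=1 is the
    exponential Shannon entropy (with 0 ln 0 := 0); q=2 the inverse Simpson
    concentration. Other nonnegative orders use the power-mean form.
    """
    if q < 0:
        raise ValueError("q must be nonnegative")
    p = comp.p[comp.p > 0]
    if q == 0:
        return float(len(p))
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def bray_curtis(a: Composition, b: Composition) -> float:
    """Sum of absolute abundance differences over the summed abundances."""
    if a.labels != b.labels:
        raise AlignmentError("compositions must share the same ordered labels")
    return float(np.sum(np.abs(a.p - b.p)) / np.sum(a.p + b.p))


def diversity_table(ct: CountTable, qs=(0, 1, 2)) -> pd.DataFrame:
    """One Hill number per sample and order; tidy (sample_id, q, value)."""
    if not ct.relative:
        ct = ct.to_relative()
    rows = []
    for sid, counts in zip(ct.sample_ids, ct.counts):
        comp = Composition.from_counts(ct.component_ids, counts)
        for q in qs:
            rows.append(
                {"sample_id": sid, "q": q, "value": hill_number(comp, q)}
            )
    return pd.DataFrame(rows, columns=["sample_id", "q", "value"])


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise Bray-Curtis matrix with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be n x n")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (off-diagonal) entries in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_csv(self, path: str) -> None:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)
        df.index.name = "sample_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls([str(s) for s in df.index], df.to_numpy(dtype=float))


def dissimilarity_matrix(ct: CountTable) -> DissimilarityMatrix:
    """All pairwise Bray-Curtis dissimilarities between table rows."""
    if not ct.relative:
        ct = ct.to_relative()
    if ct.n_samples < 2:
        raise ValueError("need at least 2 samples")
    condensed = pdist(ct.counts, metric="braycurtis")
    return DissimilarityMatrix(list(ct.sample_ids), squareform(condensed))
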