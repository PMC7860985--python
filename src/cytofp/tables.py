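"""Samples x components count tables (the cytometric fingerprints)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, EmptySampleError


@dataclass
class CountTable:
    """Relative (or raw) cell counts per fingerprint component and sample.

    When ``relative`` is true every row sums to 1 (within 1e-9); zero-cell
    rows are disallowed. Columns cover all template components, including
    ones no cell was assigned to.
    """

    sample_ids: list[str]
    component_ids: list[str]
    counts: np.ndarray
    relative: bool = True

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.sample_ids), len(self.component_ids)):
            raise ValueError("counts shape does not match id lists")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.relative:
            sums = self.counts.sum(axis=1)
            if np.any(sums == 0):
                bad = [s for s, t in zip(self.sample_ids, sums) if t == 0]
                raise EmptySampleError(f"zero-count rows: {bad}")
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("relative rows must sum to 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_components(self) -> int:
        return len(self.component_ids)

    def row(self, sample_id: str) -> np.ndarray:
        try:
            i = self.sample_ids.index(sample_id)
        except ValueError:
            raise AlignmentError(f"unknown sample {sample_id!r}") from None
        return self.counts[i]

    def to_relative(self) -> "CountTable":
        if self.relative:
            return self
        sums = self.counts.sum(axis=1, keepdims=True)
        return CountTable(
            self.sample_ids, self.component_ids, self.counts / sums, relative=True
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts, index=self.sample_ids, columns=self.component_ids
        )
        df.index.name = "sample_id"
        return df

    def to_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path: str, relative: bool = True) -> "CountTable":
        df = pd.read_csv(path, index_col=0)
        return cls(
            sample_ids=[str(s) for s in df.index],
            component_ids=[str(c) for c in df.columns],
            counts=df.to_numpy(dtype=float),
            relative=relative,
        )

    @classmethod
    def from_raw_counts(
        cls, sample_ids, component_ids, raw: np.ndarray
    ) -> "CountTable":
        """Build a relative table by row-normalizing raw assignment counts."""
        return cls(list(sample_ids), list(component_ids), raw, relative=False).to_relative()
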