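"""Fixed-grid binning fingerprints (the comparator workflow).

An L x L equal-width grid is laid over every bivariate channel combination
of the training data; per sample the 2-D histograms are flattened,
concatenated and globally normalized into a unit-sum fingerprint vector of
length C(D, 2) * L^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import (
    DegenerateChannelError,
    EmptySampleError,
    MissingChannelError,
    TransformStateError,
)
from .events import EventMatrix, ExperimentSet
from .gmm import _pool_sample
from .tables import CountTable


@dataclass
class GridTemplate:
    """Bin edges for every unordered channel pair of the training data."""

    channel_pairs: list[tuple[str, str]]
    L: int
    edges: dict[str, np.ndarray]  # per channel: L+1 strictly increasing edges

    @property
    def n_features(self) -> int:
        return len(self.channel_pairs) * self.L**2

    @property
    def component_ids(self) -> list[str]:
        ids = []
        for cx, cy in self.channel_pairs:
            ids.extend(
                f"{cx}|{cy}|{i:03d}x{j:03d}"
                for i in range(self.L)
                for j in range(self.L)
            )
        return ids

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "channel_pairs": [list(p) for p in self.channel_pairs],
                    "L": self.L,
                    "edges": {c: e.tolist() for c, e in self.edges.items()},
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: str) -> "GridTemplate":
        with open(path) as fh:
            b = json.load(fh)
        return cls(
            channel_pairs=[tuple(p) for p in b["channel_pairs"]],
            L=int(b["L"]),
            edges={c: np.asarray(e) for c, e in b["edges"].items()},
        )


def build_grid_template(train: EventMatrix, L: int = 128) -> GridTemplate:
    """Equal-width L-bin edges spanning the training range of each channel."""
    if not train.transformed:
        raise TransformStateError("grid template must be built on transformed data")
    if train.n_channels < 2:
        raise ValueError("grid fingerprinting needs at least 2 channels")
    if L < 1:
        raise ValueError("L must be positive")
    edges = {}
    for c in train.channels:
        col = train.column(c)
        lo, hi = float(col.min()), float(col.max())
        if lo == hi:
            raise DegenerateChannelError(f"channel {c!r} is constant at {lo}")
        edges[c] = np.linspace(lo, hi, L + 1)
    pairs = list(combinations(train.channels, 2))
    return GridTemplate(channel_pairs=pairs, L=L, edges=edges)


def _pair_histogram(
    template: GridTemplate, em: EventMatrix, cx: str, cy: str
) -> np.ndarray:
    ex, ey = template.edges[cx], template.edges[cy]
    # out-of-range events are clipped into the terminal bins
    x = np.clip(em.column(cx), ex[0], ex[-1])
    y = np.clip(em.column(cy), ey[0], ey[-1])
    h, _, _ = np.histogram2d(x, y, bins=[ex, ey])
    return h.ravel()


def grid_fingerprint_samples(
    template: GridTemplate,
    exp: ExperimentSet,
    n_cells_rep: int | None = None,
    seed: int = 0,
    policy: str = "error",
) -> CountTable:
    """Unit-sum concatenated-histogram fingerprint per sample."""
    for cx, cy in template.channel_pairs:
        for c in (cx, cy):
            if c not in exp.members[0].channels:
                raise MissingChannelError([c], exp.members[0].channels)
    rows = []
    for sid in exp.sample_ids:
        pooled = _pool_sample(exp.replicates(sid), n_cells_rep, seed, policy)
        if pooled.n_events == 0:
            raise EmptySampleError(f"sample {sid!r} empty after subsampling")
        vec = np.concatenate(
            [_pair_histogram(template, pooled, cx, cy) for cx, cy in template.channel_pairs]
        )
        rows.append(vec)
    return CountTable.from_raw_counts(
        exp.sample_ids, template.component_ids, np.vstack(rows)
    )
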