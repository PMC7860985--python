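"""In-silico synthetic community assembly.

Community compositions are drawn from a symmetric Dirichlet distribution
over a random strain subset; event data of individually measured strains
are then aggregated according to those compositions, giving communities
with exactly known ground-truth diversity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import rng_from
from .diversity import Composition, hill_number
from .errors import ConfigurationError, InsufficientEventsError
from .events import EventMatrix, subsample_events


@dataclass
class CompositionTable:
    """Ground-truth relative abundances: communities x strains."""

    community_ids: list[str]
    strain_ids: list[str]
    p: np.ndarray
    a: float | None = None
    split: str | None = None

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(self.community_ids), len(self.strain_ids)):
            raise ValueError("p shape must be communities x strains")
        if np.any(self.p < 0):
            raise ValueError("abundances must be nonnegative")
        if not np.allclose(self.p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows must sum to 1")

    @property
    def n_communities(self) -> int:
        return len(self.community_ids)

    def composition(self, i: int) -> Composition:
        return Composition(list(self.strain_ids), self.p[i])

    def to_csv(self, path: str) -> None:
        df = pd.DataFrame(self.p, index=self.community_ids, columns=self.strain_ids)
        df.index.name = "community_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str, a=None, split=None) -> "CompositionTable":
        df = pd.read_csv(path, index_col=0)
        return cls(
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            df.to_numpy(dtype=float),
            a=a,
            split=split,
        )


def simulate_compositions(
    n_communities: int,
    strain_pool: list[str],
    a: float,
    s_min: int = 2,
    s_max: int | None = None,
    seed: int = 0,
    split: str | None = None,
    id_prefix: str = "community",
) -> CompositionTable:
    """Draw community compositions from a symmetric Dirichlet.

    Per community: the number of member strains is uniform on
    {s_min, ..., s_max}; that many strains are drawn without replacement;
    their abundances come from Dirichlet(a, ..., a); non-members get zero.
    Small ``a`` yields dominance of a few strains, large ``a`` evenness.
    """
    s_max = len(strain_pool) if s_max is None else s_max
    if not (2 <= s_min <= s_max <= len(strain_pool)):
        raise ConfigurationError(
            f"need 2 <= s_min <= s_max <= {len(strain_pool)}, "
            f"got s_min={s_min}, s_max={s_max}"
        )
    if a <= 0:
        raise ConfigurationError("concentration parameter a must be positive")
    rng = rng_from(seed, "compositions", split or "")
    p = np.zeros((n_communities, len(strain_pool)))
    for i in range(n_communities):
        s_i = int(rng.integers(s_min, s_max + 1))
        members = rng.choice(len(strain_pool), size=s_i, replace=False)
        p[i, members] = rng.dirichlet(np.full(s_i, a))
    ids = [f"{id_prefix}{i:04d}" for i in range(n_communities)]
    return CompositionTable(ids, list(strain_pool), p, a=a, split=split)


def largest_remainder_counts(p: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` into integer counts proportional to ``p``.

    Floor each target, then hand the remaining units to the largest
    fractional parts (ties broken by lowest index). The counts sum to
    ``total`` exactly and differ from p * total by less than 1 each.
    """
    target = np.asarray(p, dtype=float) * total
    base = np.floor(target).astype(int)
    short = total - base.sum()
    if short > 0:
        frac = target - base
        order = np.lexsort((np.arange(len(p)), -frac))
        base[order[:short]] += 1
    return base


def assemble_community(
    comp: Composition,
    strain_events: dict[str, EventMatrix],
    total_cells: int,
    seed: int = 0,
    community_id: str = "assembled",
) -> EventMatrix:
    """Aggregate per-strain events according to a target composition.

    Each member strain contributes its largest-remainder share of
    ``total_cells`` events, subsampled without replacement from that
    strain's pool; row provenance records the source strain.
    """
    counts = largest_remainder_counts(comp.p, total_cells)
    parts, prov = [], []
    channels = None
    for strain, n in zip(comp.labels, counts):
        if n == 0:
            continue
        if strain not in strain_events:
            raise InsufficientEventsError(f"no events provided for strain {strain!r}")
        em = strain_events[strain]
        if channels is None:
            channels = em.channels
        if em.n_events < n:
            raise InsufficientEventsError(
                f"strain {strain!r}: need {n} events, have {em.n_events}"
            )
        sub = subsample_events(em, int(n), rng_from(seed, "assemble", strain).integers(2**31))
        parts.append(sub.events)
        prov.extend([strain] * int(n))
    return EventMatrix(
        sample_id=community_id,
        replicate_id="0",
        channels=list(channels),
        events=np.vstack(parts),
        transformed=next(iter(strain_events.values())).transformed,
        row_provenance=np.array(prov, dtype=object),
    )


def true_diversity(ct: CompositionTable, qs=(0, 1, 2)) -> pd.DataFrame:
    """Hill numbers of the predefined compositions (the ground truth)."""
    rows = []
    for i, cid in enumerate(ct.community_ids):
        comp = ct.composition(i)
        for q in qs:
            rows.append({"sample_id": cid, "q": q, "value": hill_number(comp, q)})
    return pd.DataFrame(rows, columns=["sample_id", "q", "value"])
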