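"""Event-level data structures and I/O.

An :class:`EventMatrix` holds the N x D intensity matrix of one cytometry
acquisition (one file: one sample/replicate). An :class:`ExperimentSet`
groups replicate acquisitions by sample and is defined on disk by a manifest
CSV with columns ``path, sample_id, replicate_id``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _fcs
from ._rng import rng_from
from .errors import (
    ChannelMismatchError,
    EmptyInputError,
    InsufficientEventsError,
    MissingChannelError,
)


@dataclass
class EventMatrix:
    """N cells x D channels of detector intensities for one acquisition.

    Parameters
    ----------
    sample_id, replicate_id
        Identifiers used for grouping replicates into samples.
    channels
        Ordered channel names, one per column of ``events``.
    events
        ``(N, D)`` float array. Raw intensities are nonnegative; transformed
        values may be any finite real.
    transformed
        Whether the asinh transform has been applied.
    row_provenance
        Optional length-N array of string labels recording where each row
        came from (source sample or strain); carried through subsampling and
        concatenation for diagnostics and ground-truth bookkeeping.
    """

    sample_id: str
    replicate_id: str
    channels: list[str]
    events: np.ndarray
    transformed: bool = False
    row_provenance: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 2:
            raise ValueError("events must be a 2-D array")
        if self.events.shape[0] < 1:
            raise EmptyInputError(f"{self.sample_id}: no events")
        if self.events.shape[1] != len(self.channels):
            raise ValueError("events width does not match channel list")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError(f"duplicate channel names: {self.channels}")
        if not np.all(np.isfinite(self.events)):
            raise ValueError("events contain non-finite values")
        if self.row_provenance is not None:
            self.row_provenance = np.asarray(self.row_provenance, dtype=object)
            if self.row_provenance.shape[0] != self.events.shape[0]:
                raise ValueError("row_provenance length mismatch")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    @property
    def n_channels(self) -> int:
        return self.events.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise MissingChannelError([name], self.channels) from None

    def column(self, name: str) -> np.ndarray:
        return self.events[:, self.channel_index(name)]

    def select_channels(self, subset: list[str]) -> "EventMatrix":
        missing = [c for c in subset if c not in self.channels]
        if missing:
            raise MissingChannelError(missing, self.channels)
        idx = [self.channels.index(c) for c in subset]
        return replace(self, channels=list(subset), events=self.events[:, idx])

    def take_rows(self, idx: np.ndarray) -> "EventMatrix":
        prov = None if self.row_provenance is None else self.row_provenance[idx]
        return replace(self, events=self.events[idx], row_provenance=prov)

    def to_csv(self, path: str) -> None:
        # %.17g + round_trip parsing makes the CSV round-trip bit-exact
        pd.DataFrame(self.events, columns=self.channels).to_csv(
            path, index=False, float_format="%.17g"
        )


def read_events(
    path: str,
    channel_subset: list[str] | None = None,
    format: str | None = None,
    sample_id: str | None = None,
    replicate_id: str = "0",
) -> EventMatrix:
    """Read one acquisition from a CSV or FCS file.

    ``format`` is inferred from the extension when omitted. The returned
    matrix is restricted to ``channel_subset`` (all channels when ``None``),
    marked untransformed, row order preserved.
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = "fcs" if ext == ".fcs" else "csv"
    if format not in ("csv", "fcs"):
        raise ValueError(f"unknown format {format!r}")
    if channel_subset is not None and len(channel_subset) == 0:
        raise ValueError("channel_subset must be nonempty when given")

    if format == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        if df.shape[0] == 0:
            raise EmptyInputError(f"{path}: no events")
        channels = [str(c) for c in df.columns]
        data = df.to_numpy(dtype=float)
    else:
        channels, data = _fcs.read_fcs(path)
        if data.shape[0] == 0:
            raise EmptyInputError(f"{path}: no events")

    em = EventMatrix(
        sample_id=sample_id or os.path.splitext(os.path.basename(path))[0],
        replicate_id=str(replicate_id),
        channels=channels,
        events=data,
    )
    if channel_subset is not None:
        em = em.select_channels(channel_subset)
    return em


def subsample_events(
    em: EventMatrix, n_cells: int, seed: int, policy: str = "error"
) -> EventMatrix:
    """Draw ``n_cells`` rows uniformly without replacement.

    ``policy`` controls behaviour when the matrix is short: ``"error"``
    raises; ``"take-all"`` returns every row (in randomized order).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be positive")
    rng = rng_from(seed, "subsample", em.sample_id, em.replicate_id)
    if n_cells > em.n_events:
        if policy == "error":
            raise InsufficientEventsError(
                f"{em.sample_id}/{em.replicate_id}: requested {n_cells} of "
                f"{em.n_events} events"
            )
        if policy != "take-all":
            raise ValueError(f"unknown policy {policy!r}")
        n_cells = em.n_events
    idx = rng.choice(em.n_events, size=n_cells, replace=False)
    return em.take_rows(idx)


@dataclass
class ExperimentSet:
    """A collection of acquisitions grouped into samples by ``sample_id``."""

    members: list[EventMatrix]
    metadata: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.members:
            raise EmptyInputError("experiment set has no members")

    @property
    def sample_ids(self) -> list[str]:
        seen: list[str] = []
        for em in self.members:
            if em.sample_id not in seen:
                seen.append(em.sample_id)
        return seen

    def replicates(self, sample_id: str) -> list[EventMatrix]:
        reps = [em for em in self.members if em.sample_id == sample_id]
        if not reps:
            raise KeyError(sample_id)
        return reps

    def n_replicates(self, sample_id: str) -> int:
        return len(self.replicates(sample_id))

    def map(self, fn) -> "ExperimentSet":
        return ExperimentSet([fn(em) for em in self.members], self.metadata)

    @classmethod
    def from_manifest(
        cls,
        manifest_path: str,
        channel_subset: list[str] | None = None,
        format: str | None = None,
    ) -> "ExperimentSet":
        """Build a set from a manifest CSV (path, sample_id, replicate_id)."""
        mf = pd.read_csv(manifest_path)
        required = {"path", "sample_id", "replicate_id"}
        if not required.issubset(mf.columns):
            raise ValueError(f"manifest needs columns {sorted(required)}")
        base = os.path.dirname(os.path.abspath(manifest_path))
        members = []
        for row in mf.itertuples(index=False):
            p = row.path
            if not os.path.isabs(p):
                p = os.path.join(base, p)
            members.append(
                read_events(
                    p,
                    channel_subset=channel_subset,
                    format=format,
                    sample_id=str(row.sample_id),
                    replicate_id=str(row.replicate_id),
                )
            )
        return cls(members, metadata=mf)


def concatenate_training(
    exp: ExperimentSet, n_cells_min: int, seed: int, policy: str = "error"
) -> EventMatrix:
    """Subsample every acquisition to ``n_cells_min`` cells and stack them.

    The result is the template-fitting training matrix; its row count is
    ``n_samples * n_replicates * n_cells_min`` when no file is short. Row
    provenance records the source sample of every row.
    """
    ref = exp.members[0].channels
    for em in exp.members[1:]:
        if em.channels != ref:
            raise ChannelMismatchError(
                f"channel lists differ: {ref} vs {em.channels}"
            )
    parts, prov = [], []
    for em in exp.members:
        sub = subsample_events(em, n_cells_min, seed, policy=policy)
        parts.append(sub.events)
        prov.extend([em.sample_id] * sub.n_events)
    return EventMatrix(
        sample_id="__training__",
        replicate_id="0",
        channels=list(ref),
        events=np.vstack(parts),
        transformed=exp.members[0].transformed,
        row_provenance=np.array(prov, dtype=object),
    )
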