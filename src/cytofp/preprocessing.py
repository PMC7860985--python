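"""Intensity transformation and fixed digital gating.

Two preprocessing steps are applied to every acquisition before
fingerprinting: an inverse-hyperbolic-sine transform of all channels, and a
single fixed 2-D polygon gate separating cells from debris/background. The
gate is defined in transformed coordinates and is shared by all samples of
an experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import json

import numpy as np
import shapely
import yaml

from .errors import TransformStateError
from .events import EventMatrix


def asinh_transform(em: EventMatrix, cofactor: float = 1.0) -> EventMatrix:
    """Replace every intensity v by asinh(v / cofactor).

    The default cofactor of 1 applies the plain asinh; other instruments may
    need a larger divisor. Applying the transform twice is a state error.
    """
    if em.transformed:
        raise TransformStateError(f"{em.sample_id}: already transformed")
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return replace(em, events=np.arcsinh(em.events / cofactor), transformed=True)


@dataclass(frozen=True)
class Gate:
    """A 2-D polygon gate in transformed coordinates.

    Events strictly inside or on the boundary of the polygon count as
    "inside"; ``keep_inside`` selects which side is retained.
    """

    channel_x: str
    channel_y: str
    vertices: tuple[tuple[float, float], ...]
    keep_inside: bool = True

    def __post_init__(self):
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise ValueError("gate polygon needs at least 3 vertices")
        if not np.all(np.isfinite(np.asarray(verts))):
            raise ValueError("gate vertices must be finite")
        if not self._polygon().is_simple:
            raise ValueError("gate polygon is self-intersecting")

    def _polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership for each (x, y) point."""
        return shapely.intersects_xy(self._polygon(), x, y)

    @classmethod
    def from_file(cls, path: str) -> "Gate":
        with open(path) as fh:
            spec = (json.load if path.endswith(".json") else yaml.safe_load)(fh)
        return cls(
            channel_x=spec["channel_x"],
            channel_y=spec["channel_y"],
            vertices=tuple(tuple(v) for v in spec["vertices"]),
            keep_inside=bool(spec.get("keep_inside", True)),
        )

    def to_file(self, path: str) -> None:
        spec = {
            "channel_x": self.channel_x,
            "channel_y": self.channel_y,
            "vertices": [list(v) for v in self.vertices],
            "keep_inside": self.keep_inside,
        }
        with open(path, "w") as fh:
            if path.endswith(".json"):
                json.dump(spec, fh, indent=2)
            else:
                yaml.safe_dump(spec, fh)


def apply_gate(em: EventMatrix, gate: Gate) -> EventMatrix:
    """Retain the events on the selected side of the gate polygon."""
    if not em.transformed:
        raise TransformStateError(
            f"{em.sample_id}: gate is defined in transformed coordinates"
        )
    inside = gate.contains(em.column(gate.channel_x), em.column(gate.channel_y))
    mask = inside if gate.keep_inside else ~inside
    return em.take_rows(np.flatnonzero(mask))
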