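"""Synthetic per-strain event clouds.

Stand-in for real single-strain cytometry acquisitions: each strain is a
small Gaussian mixture in transformed channel space with a tunable degree
of inter-strain overlap, plus per-replicate mean jitter emulating technical
replicates. With overlap near 0 strains are nearly separable; near 1 they
overlap heavily, which is the regime natural microbial data live in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ._rng import rng_from
from .errors import ConfigurationError
from .events import EventMatrix

_CENTER_OFFSET = 5.0  # typical asinh-transformed intensity scale
_SEP_AT_ZERO = 6.5  # minimum pairwise separation (pooled SDs) at overlap=0
_SEP_AT_ONE = 0.8  # maximum pairwise separation at overlap=1


@dataclass
class StrainModel:
    """A strain's event-cloud model: a 1-3 component Gaussian mixture."""

    strain_id: str
    component_weights: np.ndarray
    component_means: np.ndarray  # n_components x D
    component_covariances: np.ndarray  # n_components x D x D
    replicate_shift_sd: float = 0.05
    t_tails: bool = False

    def __post_init__(self):
        self.component_weights = np.asarray(self.component_weights, dtype=float)
        self.component_means = np.asarray(self.component_means, dtype=float)
        self.component_covariances = np.asarray(
            self.component_covariances, dtype=float
        )
        if abs(self.component_weights.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        for cov in self.component_covariances:
            np.linalg.cholesky(cov)  # raises if not positive definite

    @property
    def n_channels(self) -> int:
        return self.component_means.shape[1]

    @property
    def mean(self) -> np.ndarray:
        return self.component_weights @ self.component_means

    def to_dict(self) -> dict:
        return {
            "strain_id": self.strain_id,
            "component_weights": self.component_weights.tolist(),
            "component_means": self.component_means.tolist(),
            "component_covariances": self.component_covariances.tolist(),
            "replicate_shift_sd": self.replicate_shift_sd,
            "t_tails": self.t_tails,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StrainModel":
        return cls(
            strain_id=d["strain_id"],
            component_weights=np.asarray(d["component_weights"]),
            component_means=np.asarray(d["component_means"]),
            component_covariances=np.asarray(d["component_covariances"]),
            replicate_shift_sd=float(d.get("replicate_shift_sd", 0.05)),
            t_tails=bool(d.get("t_tails", False)),
        )


def save_strain_pool(pool: list[StrainModel], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([m.to_dict() for m in pool], fh)


def load_strain_pool(path: str) -> list[StrainModel]:
    with open(path) as fh:
        return [StrainModel.from_dict(d) for d in json.load(fh)]


def _random_covariance(rng: np.random.Generator, D: int) -> np.ndarray:
    """A mildly anisotropic, mildly correlated SPD matrix, unit-ish scale."""
    scales = rng.uniform(0.6, 1.4, size=D)
    A = rng.normal(0, 0.25, size=(D, D))
    corr_noise = (A + A.T) / 2
    np.fill_diagonal(corr_noise, 0.0)
    cov = np.outer(scales, scales) * (np.eye(D) + np.clip(corr_noise, -0.4, 0.4))
    # symmetrize and nudge to PD
    cov = (cov + cov.T) / 2 + 1e-6 * np.eye(D)
    return cov


def generate_strain_pool(
    n_strains: int = 20,
    D: int = 3,
    overlap: float = 0.5,
    seed: int = 0,
    replicate_shift_sd: float = 0.05,
    t_tails: bool = False,
) -> list[StrainModel]:
    """Build a seeded pool of strain models with controlled overlap.

    Strain centers are placed at random and rescaled so that at overlap=0
    every pairwise center distance exceeds ~6 pooled SDs (near-separable)
    while at overlap=1 every distance is below ~1 pooled SD; intermediate
    values interpolate geometrically, so mean separation decreases
    monotonically in ``overlap``. ``t_tails`` flags heavier-than-Gaussian
    tails at sampling time (model misspecification testing).
    """
    if n_strains < 2 or D < 2:
        raise ConfigurationError("need n_strains >= 2 and D >= 2")
    if not 0.0 <= overlap <= 1.0:
        raise ConfigurationError("overlap must be in [0, 1]")
    rng = rng_from(seed, "strain-pool")
    raw_centers = rng.normal(0.0, 1.0, size=(n_strains, D))
    dists = np.linalg.norm(
        raw_centers[:, None, :] - raw_centers[None, :, :], axis=-1
    )
    iu = np.triu_indices(n_strains, k=1)
    min_d, max_d = dists[iu].min(), dists[iu].max()
    # geometric interpolation between "min distance = wide" and
    # "max distance = narrow" scalings
    scale = (_SEP_AT_ZERO / min_d) ** (1.0 - overlap) * (_SEP_AT_ONE / max_d) ** overlap
    centers = raw_centers * scale + _CENTER_OFFSET

    pool = []
    for i in range(n_strains):
        n_comp = int(rng.integers(1, 4))
        weights = rng.dirichlet(np.full(n_comp, 4.0))
        jitter = rng.normal(0.0, 0.7, size=(n_comp, D))
        # recenter so the strain's mixture mean sits exactly on its center,
        # keeping the pairwise-separation contract exact
        means = centers[i] + (jitter - weights @ jitter)
        covs = np.stack([_random_covariance(rng, D) for _ in range(n_comp)])
        pool.append(
            StrainModel(
                strain_id=f"strain{i:02d}",
                component_weights=weights,
                component_means=means,
                component_covariances=covs,
                replicate_shift_sd=replicate_shift_sd,
                t_tails=t_tails,
            )
        )
    return pool


def sample_strain_events(
    model: StrainModel,
    n_cells: int,
    replicate: int = 0,
    seed: int = 0,
    channels: list[str] | None = None,
) -> EventMatrix:
    """Draw events from a strain's mixture with replicate-specific jitter.

    The replicate shift is a per-channel mean offset drawn once per
    (seed, strain, replicate), so two replicates of the same strain differ
    by ~``replicate_shift_sd``. Events are in transformed space (negative
    values allowed).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be positive")
    D = model.n_channels
    if channels is None:
        channels = ["FSC-H", "SSC-H", "FL1-H", "FL2-H", "FL3-H", "FL4-H"][:D]
        if len(channels) < D:
            channels = [f"CH{i}" for i in range(D)]
    shift_rng = rng_from(seed, "replicate-shift", model.strain_id, replicate)
    shift = shift_rng.normal(0.0, model.replicate_shift_sd, size=D)
    rng = rng_from(seed, "strain-events", model.strain_id, replicate)
    comp = rng.choice(
        len(model.component_weights), size=n_cells, p=model.component_weights
    )
    events = np.empty((n_cells, D))
    heavy = model.t_tails
    for k in range(len(model.component_weights)):
        mask = comp == k
        n_k = int(mask.sum())
        if n_k == 0:
            continue
        draws = rng.multivariate_normal(
            model.component_means[k], model.component_covariances[k], size=n_k
        )
        if heavy:
            # scale-mixture construction of multivariate-t-like tails (df=5)
            g = rng.chisquare(5, size=n_k) / 5.0
            draws = model.component_means[k] + (
                draws - model.component_means[k]
            ) / np.sqrt(g)[:, None]
        events[mask] = draws
    return EventMatrix(
        sample_id=model.strain_id,
        replicate_id=str(replicate),
        channels=list(channels),
        events=events + shift,
        transformed=True,
    )
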