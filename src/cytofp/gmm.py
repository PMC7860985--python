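"""Gaussian-mixture fingerprint templates.

A template is a K-component mixture fitted by EM to a concatenated training
matrix; K is deliberately chosen far above the number of biological
populations (overclustering) so the mixture approximates the density. Cells
of each sample are then assigned to the component with the highest posterior
responsibility, and the per-component relative counts form the sample's
fingerprint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from ._rng import child_seed
from .errors import (
    ChannelMismatchError,
    EmptySampleError,
    InfeasibleModelError,
    TransformStateError,
)
from .events import EventMatrix, ExperimentSet, subsample_events
from .tables import CountTable

COVARIANCE_TYPES = ("diag", "full", "spherical", "tied")


class _RecordingGaussianMixture(GaussianMixture):
    """GaussianMixture that records the lower bound at every EM iteration."""

    def __init__(self, **kwargs):
        super().__init__(**kwargs)
        self.ll_histories_: list[list[float]] = []

    def _initialize_parameters(self, X, random_state, **kwargs):
        self.ll_histories_.append([])
        super()._initialize_parameters(X, random_state, **kwargs)

    def _compute_lower_bound(self, _log_resp, log_prob_norm):
        lb = super()._compute_lower_bound(_log_resp, log_prob_norm)
        self.ll_histories_[-1].append(float(lb))
        return lb


@dataclass
class GMMTemplate:
    """A fitted K-component Gaussian mixture fingerprint template."""

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    covariance_type: str
    channels: list[str]
    fit_log: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariance_type not in COVARIANCE_TYPES:
            raise ValueError(f"covariance_type must be one of {COVARIANCE_TYPES}")
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("mixture weights must sum to 1")
        if self.means.shape != (self.K, len(self.channels)):
            raise ValueError("means shape does not match K x D")

    @property
    def K(self) -> int:
        return len(self.weights)

    @property
    def component_ids(self) -> list[str]:
        return [f"mix{k:03d}" for k in range(self.K)]

    def full_covariances(self) -> np.ndarray:
        """Expand the stored covariances to a (K, D, D) array."""
        K, D = self.means.shape
        ct, cov = self.covariance_type, self.covariances
        if ct == "full":
            return cov
        if ct == "tied":
            return np.broadcast_to(cov, (K, D, D)).copy()
        if ct == "diag":
            return np.stack([np.diag(c) for c in cov])
        # spherical: one variance per component
        return np.stack([np.eye(D) * v for v in cov])

    def log_responsibility_numerators(self, X: np.ndarray) -> np.ndarray:
        """log(pi_k) + log N(x | mu_k, Sigma_k) for every event and component.

        The posterior responsibility shares its denominator across
        components, so argmax over these numerators is the
        maximum-posterior assignment.
        """
        from scipy.linalg import solve_triangular

        X = np.asarray(X, dtype=float)
        K, D = self.means.shape
        out = np.empty((X.shape[0], K))
        for k, cov in enumerate(self.full_covariances()):
            chol = np.linalg.cholesky(cov)
            dev = X - self.means[k]
            z = solve_triangular(chol, dev.T, lower=True).T
            logdet = 2.0 * np.sum(np.log(np.diag(chol)))
            out[:, k] = (
                np.log(self.weights[k])
                - 0.5 * (D * np.log(2 * np.pi) + logdet + np.sum(z * z, axis=1))
            )
        return out

    def to_json(self, path: str) -> None:
        bundle = {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "covariance_type": self.covariance_type,
            "channels": self.channels,
            "fit_log": self.fit_log,
        }
        with open(path, "w") as fh:
            json.dump(bundle, fh)

    @classmethod
    def from_json(cls, path: str) -> "GMMTemplate":
        with open(path) as fh:
            bundle = json.load(fh)
        return cls(
            weights=np.asarray(bundle["weights"]),
            means=np.asarray(bundle["means"]),
            covariances=np.asarray(bundle["covariances"]),
            covariance_type=bundle["covariance_type"],
            channels=list(bundle["channels"]),
            fit_log=bundle.get("fit_log", {}),
        )


def fit_gmm_template(
    train: EventMatrix,
    K: int,
    covariance_type: str = "full",
    seed: int = 0,
    tol: float = 1e-3,
    max_iter: int = 200,
    reg_covar: float = 1e-6,
    n_init: int = 3,
) -> GMMTemplate:
    """EM-fit a K-component mixture to the training concatenation.

    Initialization is k-means based with ``n_init`` seeded restarts; the
    restart with the best final likelihood wins. Non-convergence within
    ``max_iter`` is recorded in ``fit_log`` rather than raised.
    """
    if not train.transformed:
        raise TransformStateError("template must be fitted on transformed data")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > train.n_events:
        raise InfeasibleModelError(f"K={K} exceeds N={train.n_events} events")
    gm = _RecordingGaussianMixture(
        n_components=K,
        covariance_type=covariance_type,
        tol=tol,
        max_iter=max_iter,
        reg_covar=reg_covar,
        n_init=n_init,
        init_params="kmeans",
        random_state=child_seed(seed, "gmm-fit") % (2**32),
    )
    gm.fit(train.events)
    fit_log = {
        "converged": bool(gm.converged_),
        "n_iter": int(gm.n_iter_),
        "final_log_likelihood_per_event": float(gm.lower_bound_),
        "ll_histories": gm.ll_histories_,
        "K": int(K),
        "covariance_type": covariance_type,
        "n_train_events": int(train.n_events),
        "seed": int(seed),
    }
    return GMMTemplate(
        weights=gm.weights_,
        means=gm.means_,
        covariances=gm.covariances_,
        covariance_type=covariance_type,
        channels=list(train.channels),
        fit_log=fit_log,
    )


def assign_cells(template: GMMTemplate, em: EventMatrix) -> np.ndarray:
    """Maximum-posterior component label per event (ties -> lowest index)."""
    if em.channels != template.channels:
        raise ChannelMismatchError(
            f"template channels {template.channels} vs {em.channels}"
        )
    if not em.transformed:
        raise TransformStateError("events must be transformed before assignment")
    return np.argmax(template.log_responsibility_numerators(em.events), axis=1)


def _pool_sample(
    reps: list[EventMatrix], n_cells_rep: int | None, seed: int, policy: str
) -> EventMatrix:
    """Subsample each replicate to a common depth, then pool."""
    depth = n_cells_rep
    if depth is None:
        depth = min(r.n_events for r in reps)
    parts = [subsample_events(r, depth, seed, policy=policy) for r in reps]
    pooled = parts[0]
    if len(parts) > 1:
        pooled = EventMatrix(
            sample_id=reps[0].sample_id,
            replicate_id="pooled",
            channels=list(reps[0].channels),
            events=np.vstack([p.events for p in parts]),
            transformed=reps[0].transformed,
        )
    return pooled


def fingerprint_samples(
    template: GMMTemplate,
    exp: ExperimentSet,
    n_cells_rep: int | None = None,
    seed: int = 0,
    policy: str = "error",
) -> CountTable:
    """Relative cells-per-component table, one row per sample.

    Replicates are subsampled to ``n_cells_rep`` each (or to the smallest
    replicate when ``None``) and pooled before assignment; counts are then
    row-normalized. All K template columns are present, zeros allowed.
    """
    rows = []
    for sid in exp.sample_ids:
        pooled = _pool_sample(exp.replicates(sid), n_cells_rep, seed, policy)
        if pooled.n_events == 0:
            raise EmptySampleError(f"sample {sid!r} empty after subsampling")
        labels = assign_cells(template, pooled)
        rows.append(np.bincount(labels, minlength=template.K).astype(float))
    return CountTable.from_raw_counts(
        exp.sample_ids, template.component_ids, np.vstack(rows)
    )
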