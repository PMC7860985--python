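"""End-to-end in-silico benchmark harness.

One benchmark run: simulate train/test community compositions, assemble
event data from a strain pool, fit a fingerprint template on the training
communities only, fingerprint everything, and score the diversity estimates
against the ground truth (rank correlation per Hill order, optional
supervised predictions, and a Mantel test on the Bray-Curtis matrices).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import child_seed
from .diversity import dissimilarity_matrix
from .diversity import diversity_table as fingerprint_diversity_table
from .diversity import DissimilarityMatrix
from .errors import ConfigurationError, UndefinedStatisticError
from .events import EventMatrix, ExperimentSet, concatenate_training
from .evaluation import kendall_tau_b, mantel_test, r_squared
from .gmm import fingerprint_samples, fit_gmm_template
from .grid import build_grid_template, grid_fingerprint_samples
from .insilico import (
    CompositionTable,
    assemble_community,
    simulate_compositions,
    true_diversity,
)
from .predict import RFSearchSpec, fit_diversity_regressor, predict_diversity
from .synthetic import generate_strain_pool, sample_strain_events
from .tables import CountTable


@dataclass
class BenchmarkConfig:
    """Parameters of one in-silico benchmark scenario."""

    method: str = "gmm"  # "gmm" or "grid"
    n_strains: int = 20
    D: int = 3
    overlap: float = 0.5
    a: float = 1.0
    n_train: int = 300
    n_test: int = 100
    total_cells: int = 1000  # events per assembled community
    n_cells_min: int = 250  # per community into the template training set
    n_cells_rep: int = 1000  # per community when deriving fingerprints
    K: int = 128
    covariance_type: str = "full"
    n_init: int = 1
    L: int = 128
    qs: tuple = (0, 1, 2)
    rf_qs: tuple = ()  # Hill orders to run the supervised layer for
    rf_candidates: int = 100
    rf_folds: int = 5
    rf_trees: int = 200
    mantel_permutations: int = 1000

    def __post_init__(self):
        if self.method not in ("gmm", "grid"):
            raise ConfigurationError(f"unknown method {self.method!r}")
        if self.a <= 0:
            raise ConfigurationError("a must be positive")
        if self.n_cells_rep > self.total_cells:
            raise ConfigurationError("n_cells_rep cannot exceed total_cells")


@dataclass
class RunResult:
    """Artifacts and scores of a single benchmark run."""

    run: int
    config: BenchmarkConfig
    compositions_train: CompositionTable
    compositions_test: CompositionTable
    fingerprints_train: CountTable
    fingerprints_test: CountTable
    truth_test: pd.DataFrame  # tidy (sample_id, q, value)
    estimates_test: pd.DataFrame
    scores: pd.DataFrame  # tidy (method, a, q, run, metric, value)
    mantel_statistic: float
    mantel_p: float
    bc_fingerprints: DissimilarityMatrix
    bc_truth: DissimilarityMatrix
    rf_predictions: dict = field(default_factory=dict)  # q -> DataFrame


def _strain_event_pools(pool, config: BenchmarkConfig, seed: int):
    return {
        m.strain_id: sample_strain_events(
            m, config.total_cells, replicate=0, seed=child_seed(seed, "pool-events")
        )
        for m in pool
    }


def _assemble_set(
    comps: CompositionTable, strain_events, config: BenchmarkConfig, seed: int
) -> ExperimentSet:
    members = []
    for i, cid in enumerate(comps.community_ids):
        members.append(
            assemble_community(
                comps.composition(i),
                strain_events,
                total_cells=config.total_cells,
                seed=child_seed(seed, "assemble", cid),
                community_id=cid,
            )
        )
    return ExperimentSet(members)


def _fit_template(train: EventMatrix, config: BenchmarkConfig, seed: int):
    if config.method == "gmm":
        return fit_gmm_template(
            train,
            K=config.K,
            covariance_type=config.covariance_type,
            seed=child_seed(seed, "template"),
            n_init=config.n_init,
        )
    return build_grid_template(train, L=config.L)


def _fingerprint(template, exp: ExperimentSet, config: BenchmarkConfig, seed: int):
    fp = fingerprint_samples if config.method == "gmm" else grid_fingerprint_samples
    return fp(template, exp, n_cells_rep=config.n_cells_rep, seed=child_seed(seed, "fp"))


def _tidy_values(df: pd.DataFrame, q: float) -> np.ndarray:
    return df.loc[df["q"] == q].set_index("sample_id")["value"]


def run_benchmark_once(config: BenchmarkConfig, seed: int, run: int = 0) -> RunResult:
    """Execute one seeded benchmark run and score it."""
    pool = generate_strain_pool(
        config.n_strains, config.D, config.overlap, seed=child_seed(seed, "strains")
    )
    run_seed = child_seed(seed, "run", run)
    strain_ids = [m.strain_id for m in pool]
    comp_train = simulate_compositions(
        config.n_train, strain_ids, config.a, seed=run_seed, split="train",
        id_prefix="train",
    )
    comp_test = simulate_compositions(
        config.n_test, strain_ids, config.a, seed=run_seed, split="test",
        id_prefix="test",
    )
    strain_events = _strain_event_pools(pool, config, run_seed)
    train_set = _assemble_set(comp_train, strain_events, config, run_seed)
    test_set = _assemble_set(comp_test, strain_events, config, run_seed)

    train_concat = concatenate_training(
        train_set, config.n_cells_min, seed=child_seed(run_seed, "concat")
    )
    template = _fit_template(train_concat, config, run_seed)
    fp_train = _fingerprint(template, train_set, config, run_seed)
    fp_test = _fingerprint(template, test_set, config, run_seed)

    truth_test = true_diversity(comp_test, qs=config.qs)
    truth_train = true_diversity(comp_train, qs=config.qs)
    est_test = fingerprint_diversity_table(fp_test, qs=config.qs)

    rows = []
    base = {"method": config.method, "a": config.a, "run": run}
    for q in config.qs:
        t = _tidy_values(truth_test, q)
        e = _tidy_values(est_test, q).loc[t.index]
        try:
            res = kendall_tau_b(t.to_numpy(), e.to_numpy())
            tau, p = res.tau_b, res.p_value
        except UndefinedStatisticError:
            # e.g. richness saturated at K for every test sample
            tau, p = np.nan, np.nan
        rows.append({**base, "q": q, "metric": "tau_direct", "value": tau})
        rows.append({**base, "q": q, "metric": "tau_direct_p", "value": p})

    rf_predictions = {}
    for q in config.rf_qs:
        spec = RFSearchSpec(
            n_candidates=config.rf_candidates,
            cv_folds=config.rf_folds,
            n_trees=config.rf_trees,
            seed=child_seed(run_seed, "rf", q),
        )
        bundle = fit_diversity_regressor(
            fp_train, truth_train.loc[truth_train["q"] == q], spec
        )
        preds = predict_diversity(bundle, fp_test)
        rf_predictions[q] = preds
        t = _tidy_values(truth_test, q)
        p = preds.set_index("sample_id")["value"].loc[t.index]
        res = kendall_tau_b(t.to_numpy(), p.to_numpy())
        rows.append({**base, "q": q, "metric": "tau_rf", "value": res.tau_b})
        rows.append({**base, "q": q, "metric": "tau_rf_p", "value": res.p_value})
        rows.append(
            {
                **base,
                "q": q,
                "metric": "r2_rf",
                "value": r_squared(t.to_numpy(), p.to_numpy()),
            }
        )

    bc_fp = dissimilarity_matrix(fp_test)
    bc_truth = dissimilarity_matrix(
        CountTable(
            list(comp_test.community_ids),
            list(comp_test.strain_ids),
            comp_test.p,
            relative=True,
        )
    )
    mantel = mantel_test(
        bc_fp,
        bc_truth,
        n_permutations=config.mantel_permutations,
        seed=child_seed(run_seed, "mantel"),
    )
    rows.append({**base, "q": None, "metric": "mantel_r", "value": mantel.statistic})
    rows.append({**base, "q": None, "metric": "mantel_p", "value": mantel.p_value})

    return RunResult(
        run=run,
        config=config,
        compositions_train=comp_train,
        compositions_test=comp_test,
        fingerprints_train=fp_train,
        fingerprints_test=fp_test,
        truth_test=truth_test,
        estimates_test=est_test,
        scores=pd.DataFrame(rows),
        mantel_statistic=mantel.statistic,
        mantel_p=mantel.p_value,
        bc_fingerprints=bc_fp,
        bc_truth=bc_truth,
        rf_predictions=rf_predictions,
    )


def run_benchmark(
    config: BenchmarkConfig,
    seed: int,
    n_runs: int = 1,
    a_values: tuple | None = None,
) -> pd.DataFrame:
    """Repeated runs, optionally over several Dirichlet concentrations.

    Returns the concatenated tidy score table keyed by
    (method, a, q, run, metric).
    """
    if a_values is not None and len(a_values) == 0:
        raise ConfigurationError("a_values must be nonempty when given")
    scenarios = a_values if a_values is not None else (config.a,)
    frames = []
    for a in scenarios:
        cfg = replace(config, a=a)
        for r in range(n_runs):
            frames.append(run_benchmark_once(cfg, seed, run=r).scores)
    return pd.concat(frames, ignore_index=True)


# Sweepable parameter names -> BenchmarkConfig fields.
SWEEP_PARAMS = {
    "D": "D",
    "K": "K",
    "N_CELLS_MIN": "n_cells_min",
    "N_CELLS_REP": "n_cells_rep",
    "N_SAMPLES": "n_train",
    "TYPE": "covariance_type",
}


def run_sweep(
    config: BenchmarkConfig,
    sweep: dict,
    seed: int,
    metric_q: int = 1,
) -> pd.DataFrame:
    """One-at-a-time parameter variation.

    For each named parameter and each value, rerun the benchmark (with the
    supervised layer enabled for order ``metric_q``) and report the test-set
    R^2 of the predictions alongside the direct rank correlation.
    """
    unknown = [k for k in sweep if k not in SWEEP_PARAMS]
    if unknown:
        raise ConfigurationError(
            f"unknown sweep parameter(s) {unknown}; known: {sorted(SWEEP_PARAMS)}"
        )
    rows = []
    for name, values in sweep.items():
        for v in values:
            cfg = replace(
                config, **{SWEEP_PARAMS[name]: v}, rf_qs=(metric_q,), qs=(metric_q,)
            )
            result = run_benchmark_once(cfg, seed)
            s = result.scores
            r2 = s.loc[(s["metric"] == "r2_rf") & (s["q"] == metric_q), "value"]
            tau = s.loc[(s["metric"] == "tau_rf") & (s["q"] == metric_q), "value"]
            rows.append(
                {
                    "parameter": name,
                    "value": v,
                    "metric_q": metric_q,
                    "r2_rf": float(r2.iloc[0]),
                    "tau_rf": float(tau.iloc[0]),
                }
            )
    return pd.DataFrame(rows)
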