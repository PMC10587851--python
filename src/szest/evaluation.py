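"""Outcome metrics and the strategy-comparison experiment.

Accuracy is measured by the mean absolute error (MAE) of the estimated
pointwise sensitivities against the true field, and by the absolute error of
mean sensitivity (MS-AE); speed by the number of stimulus presentations
(NP).  Metrics are aggregated per eye across repeated simulations and then
across the cohort, mirroring how clinical simulation studies report them:
the cohort SD of per-eye means reflects between-eye variation, while the
pooled pointwise SD reflects single-measurement spread.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .field_model import Field, Grid, build_neighbor_graph, make_grid
from .observer import ObserverConfig
from .priors import (
    PriorTable,
    agnostic_priors,
    lookup_structural_prior,
    DEFAULT_MIN_COUNT,
)
from .strategy import (
    StrategyConfig,
    TestResult,
    prune_edges_by_prediction,
    run_single_test,
)
from .synthetic_cohort import SyntheticEye

__all__ = [
    "EyeSummary",
    "ComparisonResult",
    "pointwise_errors",
    "mean_sensitivity",
    "summarize_eye",
    "evaluate_eye",
    "compare_strategies",
]


def pointwise_errors(estimated: Field, true_field: Field) -> pd.DataFrame:
    """Per-location absolute and signed errors (estimate minus truth, dB)."""
    if set(estimated.values) != set(true_field.values):
        raise ValueError("estimated and true fields cover different locations")
    ids = sorted(true_field.values)
    signed = np.array([estimated.values[i] - true_field.values[i] for i in ids])
    return pd.DataFrame(
        {"location_id": ids, "ae": np.abs(signed), "signed": signed}
    )


def mean_sensitivity(f: Field) -> float:
    """Mean sensitivity (MS): unweighted mean over the field's locations."""
    return float(np.mean(list(f.values.values())))


@dataclass
class EyeSummary:
    """Per-eye metrics averaged over repeated simulated tests."""

    eye_id: str
    mae: float
    signed_error: float
    ms_ae: float
    mean_total_presentations: float
    n_simulations: int
    # pooled pointwise moments (for the single-measurement SD convention)
    pooled_ae_sq: float = float("nan")
    pooled_signed_sq: float = float("nan")


def summarize_eye(results: Sequence[TestResult], true_field: Field) -> EyeSummary:
    """Aggregate repeated simulated tests of one eye."""
    if not results:
        raise ValueError("need at least one result")
    ids = sorted(true_field.values)
    truth = np.array([true_field.values[i] for i in ids])
    ms_true = float(truth.mean())
    signed = np.array(
        [[r.estimates.values[i] - true_field.values[i] for i in ids] for r in results]
    )
    ms_err = np.array(
        [abs(mean_sensitivity(r.estimates) - ms_true) for r in results]
    )
    npres = np.array([r.total_presentations for r in results], dtype=float)
    return EyeSummary(
        eye_id="",
        mae=float(np.abs(signed).mean()),
        signed_error=float(signed.mean()),
        ms_ae=float(ms_err.mean()),
        mean_total_presentations=float(npres.mean()),
        n_simulations=len(results),
        pooled_ae_sq=float((np.abs(signed) ** 2).mean()),
        pooled_signed_sq=float((signed**2).mean()),
    )


def _structural_priors_for_scan(
    predicted: Field, table: PriorTable, min_count: int
) -> dict:
    return {
        lid: lookup_structural_prior(table, pv, min_count)
        for lid, pv in predicted.values.items()
    }


def evaluate_eye(
    eye: SyntheticEye,
    cfg: StrategyConfig,
    observer: ObserverConfig,
    n_sim: int,
    seed: int,
    grid: Grid | None = None,
    table: PriorTable | None = None,
    min_count: int = DEFAULT_MIN_COUNT,
    config_label: str = "",
) -> EyeSummary:
    """Run ``n_sim`` simulated tests of one eye under one configuration.

    For the structural strategy a predicted field (one emulated OCT scan) is
    drawn at random for every test; its values choose the per-location priors
    and, with spatial enhancement on, prune the neighbour graph at predicted
    scotoma edges.  Simulation seeds depend only on (seed, eye, simulation
    index), so different configurations see the same random streams.
    """
    grid = grid or make_grid()
    structural = cfg.prior_mode == "structural"
    if structural and table is None:
        raise ValueError("structural strategy needs a prior table")
    base_graph = (
        build_neighbor_graph(grid, cfg.effective_spatial_weight, cfg.neighbor_rule)
        if cfg.spatial
        else None
    )
    if not structural:
        fixed_priors = agnostic_priors(grid, cfg.domain())
    obs = observer.with_gve(eye.gve_sigma)
    results = []
    for s in range(n_sim):
        eye_key = zlib.crc32(eye.eye_id.encode()) % 2**31  # stable across processes
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(eye_key, s))
        rng = np.random.default_rng(ss)
        if structural:
            scan = eye.predicted_fields[int(rng.integers(len(eye.predicted_fields)))]
            priors = _structural_priors_for_scan(scan, table, min_count)
            graph = (
                prune_edges_by_prediction(base_graph, scan, cfg.disconnect_threshold)
                if base_graph is not None
                else None
            )
        else:
            priors = fixed_priors
            graph = base_graph
        results.append(
            run_single_test(
                eye.true_field, priors, graph, cfg, obs, rng, log_trials=False
            )
        )
    summary = summarize_eye(results, eye.true_field)
    summary.eye_id = eye.eye_id
    return summary


@dataclass
class ComparisonResult:
    """Cohort-level comparison across strategy configurations."""

    eye_summaries: pd.DataFrame
    table: pd.DataFrame

    def render(self) -> str:
        cols = [
            "mae_mean", "mae_sd", "signed_mean",
            "ms_ae_mean", "ms_ae_sd", "np_mean", "np_sd",
        ]
        return self.table[cols].round(2).to_string()


def compare_strategies(
    cohort: Sequence[SyntheticEye],
    configs: Mapping[str, tuple[StrategyConfig, ObserverConfig]],
    n_sim: int,
    rng_seed: int = 0,
    grid: Grid | None = None,
    tables: Mapping[str, PriorTable] | None = None,
    min_count: int = DEFAULT_MIN_COUNT,
) -> ComparisonResult:
    """Run the strategy-comparison experiment on a cohort.

    ``configs`` maps a label to a (strategy, observer) pair.  For structural
    strategies, ``tables`` maps each subject id to the prior table built with
    that subject excluded (leave-one-subject-out); a single table under the
    key ``"*"`` is applied to every subject instead.

    Returns long-format per-eye summaries and a cohort table with, per
    configuration: cohort mean and between-eye SD of per-eye MAE, MS-AE and
    total presentations, plus the pooled pointwise SD convention for MAE and
    signed error.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    grid = grid or make_grid()
    rows = []
    for label, (cfg, obs) in configs.items():
        for eye in cohort:
            table = None
            if cfg.prior_mode == "structural":
                if tables is None:
                    raise ValueError(f"config {label!r} needs structural prior tables")
                table = tables.get(eye.subject_id, tables.get("*"))
                if table is None:
                    raise ValueError(f"no prior table for subject {eye.subject_id}")
            s = evaluate_eye(
                eye, cfg, obs, n_sim, rng_seed, grid, table, min_count, label
            )
            rows.append(
                {
                    "config": label,
                    "eye_id": s.eye_id,
                    "mae": s.mae,
                    "signed_error": s.signed_error,
                    "ms_ae": s.ms_ae,
                    "total_presentations": s.mean_total_presentations,
                    "n_simulations": s.n_simulations,
                    "pooled_ae_sq": s.pooled_ae_sq,
                    "pooled_signed_sq": s.pooled_signed_sq,
                }
            )
    eye_df = pd.DataFrame(rows)
    agg = []
    for label, g in eye_df.groupby("config", sort=False):
        agg.append(
            {
                "config": label,
                "mae_mean": g["mae"].mean(),
                "mae_sd": g["mae"].std(ddof=1),
                "signed_mean": g["signed_error"].mean(),
                "ms_ae_mean": g["ms_ae"].mean(),
                "ms_ae_sd": g["ms_ae"].std(ddof=1),
                "np_mean": g["total_presentations"].mean(),
                "np_sd": g["total_presentations"].std(ddof=1),
                # pooled single-measurement SDs
                "mae_sd_pooled": float(
                    np.sqrt(max(g["pooled_ae_sq"].mean() - g["mae"].mean() ** 2, 0.0))
                ),
                "signed_sd_pooled": float(
                    np.sqrt(
                        max(g["pooled_signed_sq"].mean() - g["signed_error"].mean() ** 2, 0.0)
                    )
                ),
            }
        )
    return ComparisonResult(
        eye_summaries=eye_df, table=pd.DataFrame(agg).set_index("config")
    )
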