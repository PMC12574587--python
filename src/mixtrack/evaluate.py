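"""Evaluation metrics (MAE, JSD, PCC) and benchmark sweeps.

Metrics compare the estimated proportion vector — unknown source first,
then the K observed sources, matching the truth convention — against the
simulated ground truth.  JSD uses base-2 logarithms, so it lies in [0, 1];
PCC is undefined (and excluded from averages, with a count) when either
vector is constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .direction import infer_directionality
from .exceptions import MixtrackError
from .gls import MixingEstimate, estimate_proportions
from .io import UnlabeledSampleSet
from .simulate import SimulationConfig, SimulationTruth, simulate_scenario1

logger = logging.getLogger("mixtrack")

__all__ = [
    "EvalMetrics",
    "BenchmarkReport",
    "mae",
    "jsd",
    "pcc",
    "evaluate_estimate",
    "run_proportion_benchmark",
    "run_directionality_benchmark",
]


def mae(estimated: np.ndarray, true: np.ndarray,
        indices: Optional[Sequence[int]] = None) -> float:
    """Mean absolute error over an index subset (default: all entries)."""
    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(true, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("estimated and true vectors must have equal length")
    if indices is not None:
        indices = np.asarray(indices, dtype=int)
        if indices.size == 0:
            raise ValueError("index subset must be non-empty")
        est, tru = est[indices], tru[indices]
    return float(np.mean(np.abs(est - tru)))


def _kl_bits(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence with base-2 logs: range [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("vectors must have equal length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("proportion vectors must be non-negative")
    for name, v in (("p", p.sum()), ("q", q.sum())):
        if abs(v - 1.0) > 1e-6:
            raise ValueError(f"{name} sums to {v:.8g}; not a proportion vector")
    p, q = p / p.sum(), q / q.sum()
    m = 0.5 * (p + q)
    return 0.5 * _kl_bits(p, m) + 0.5 * _kl_bits(q, m)


def pcc(p: np.ndarray, q: np.ndarray) -> Optional[float]:
    """Pearson correlation; ``None`` when a vector is constant."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("vectors must have equal length")
    if p.size < 2:
        raise ValueError("need at least 2 entries")
    if np.ptp(p) == 0 or np.ptp(q) == 0:
        return None
    return float(np.corrcoef(p, q)[0, 1])


@dataclass
class EvalMetrics:
    """Per-replicate accuracy metrics against simulation truth."""

    mae_observed: float
    mae_major: float
    mae_unobserved: float
    jsd: float
    pcc: Optional[float]


def evaluate_estimate(
    estimate: MixingEstimate,
    truth: SimulationTruth,
    observed_only: bool = False,
) -> EvalMetrics:
    """Align the estimate with the truth (unknown first) and score it.

    JSD/PCC are computed over observed sources plus the unknown entry by
    default; ``observed_only`` restricts them to the observed sources.
    """
    est = estimate.proportions
    tru = np.asarray(truth.alpha_true, dtype=float)
    if est.shape != tru.shape:
        raise ValueError(
            f"estimate has {est.size - 1} sources but truth has {tru.size - 1}"
        )
    k = tru.size - 1
    observed_idx = np.arange(1, k + 1)
    metrics_est, metrics_tru = (est[1:], tru[1:]) if observed_only else (est, tru)
    return EvalMetrics(
        mae_observed=mae(est, tru, observed_idx),
        mae_major=mae(est, tru, truth.major_indices),
        mae_unobserved=abs(est[0] - tru[0]),
        jsd=jsd(metrics_est / metrics_est.sum(), metrics_tru / metrics_tru.sum()),
        pcc=pcc(metrics_est, metrics_tru),
    )


@dataclass
class BenchmarkReport:
    """One row per (K, n_major) grid cell, plus the configuration used."""

    table: pd.DataFrame
    config: dict
    base_seed: int
    exclusions: dict = field(default_factory=dict)


def _cell_configs(K: int, n_major: int, n_replicates: int, base_seed: int,
                  **config_kwargs) -> list[SimulationConfig]:
    return [
        SimulationConfig(K=K, n_major=n_major, seed=base_seed + r, **config_kwargs)
        for r in range(n_replicates)
    ]


def run_proportion_benchmark(
    grid: Sequence[tuple[int, int]],
    n_replicates: int,
    base_seed: int,
    **config_kwargs,
) -> BenchmarkReport:
    """Simulate, estimate and evaluate over a (K, n_major) grid.

    Replicate r of every cell uses seed ``base_seed + r``.  Replicates
    whose estimation fails are excluded and counted (never imputed).
    """
    rows = []
    exclusions: dict = {}
    for K, n_major in grid:
        per_rep: list[EvalMetrics] = []
        excluded = 0
        for cfg in _cell_configs(K, n_major, n_replicates, base_seed,
                                 **config_kwargs):
            truth = simulate_scenario1(cfg)
            try:
                estimate = estimate_proportions(truth.community)
            except MixtrackError as exc:
                logger.warning("replicate seed=%d excluded: %s", cfg.seed, exc)
                excluded += 1
                continue
            per_rep.append(evaluate_estimate(estimate, truth))
        pccs = [m.pcc for m in per_rep if m.pcc is not None]
        rows.append({
            "K": K,
            "n_major": n_major,
            "n_replicates": len(per_rep),
            "mae_observed": np.mean([m.mae_observed for m in per_rep]),
            "mae_major": np.mean([m.mae_major for m in per_rep]),
            "mae_unobserved": np.mean([m.mae_unobserved for m in per_rep]),
            "jsd": np.mean([m.jsd for m in per_rep]),
            "pcc": np.mean(pccs) if pccs else np.nan,
            "pcc_undefined": len(per_rep) - len(pccs),
        })
        exclusions[(K, n_major)] = excluded
    return BenchmarkReport(
        table=pd.DataFrame(rows),
        config={"mode": "proportion", "n_replicates": n_replicates,
                **config_kwargs},
        base_seed=base_seed,
        exclusions=exclusions,
    )


def run_directionality_benchmark(
    grid: Sequence[tuple[int, int]],
    n_replicates: int,
    base_seed: int,
    **config_kwargs,
) -> BenchmarkReport:
    """Directionality accuracy sweep over a (K, n_major) grid.

    Each replicate simulates K observed sources plus the sink, strips the
    role labels (the true sink is placed last among the K+1 samples), runs
    the joint-likelihood inference, and scores a correct-sink indicator.
    """
    rows = []
    exclusions: dict = {}
    for K, n_major in grid:
        correct = 0
        n_done = 0
        excluded = 0
        for cfg in _cell_configs(K, n_major, n_replicates, base_seed,
                                 **config_kwargs):
            truth = simulate_scenario1(cfg)
            community = truth.community
            samples = UnlabeledSampleSet(
                taxon_ids=community.taxon_ids,
                counts=np.vstack([community.source_counts,
                                  community.sink_counts]),
                sample_ids=community.source_ids + [community.sink_id],
            )
            try:
                result = infer_directionality(samples)
            except MixtrackError as exc:
                logger.warning("replicate seed=%d excluded: %s", cfg.seed, exc)
                excluded += 1
                continue
            n_done += 1
            correct += int(result.selected_sink == samples.n_samples - 1)
        rows.append({
            "K": K,
            "n_major": n_major,
            "n_replicates": n_done,
            "directionality_accuracy": correct / n_done if n_done else np.nan,
        })
        exclusions[(K, n_major)] = excluded
    return BenchmarkReport(
        table=pd.DataFrame(rows),
        config={"mode": "direction", "n_replicates": n_replicates,
                **config_kwargs},
        base_seed=base_seed,
        exclusions=exclusions,
    )
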