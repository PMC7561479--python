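"""Count-accuracy statistics and the synthetic accuracy benchmark.

Automated counts are scored against reference (manual or ground-truth)
counts with the mean absolute error (MAE), the mean absolute percentage
error (MAPE, reference in the denominator) and Pearson's product-moment
correlation R; error-free counting gives MAE = MAPE = 0 and R = 1.
Group comparisons across imaging conditions use the Kruskal-Wallis
rank test (chi-square approximation, tie-corrected).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateGroups, DegenerateVariance, EmptyInput, JoinFailure, ZeroReference


@dataclass(frozen=True)
class CountPair:
    """One scored image: reference count, estimated count, condition tags."""

    reference: int
    estimate: int
    tags: dict = field(default_factory=dict)


def _split(pairs: Sequence) -> tuple[np.ndarray, np.ndarray]:
    if len(pairs) == 0:
        raise EmptyInput("no count pairs")
    ref = np.array([p.reference if isinstance(p, CountPair) else p[0] for p in pairs], dtype=float)
    est = np.array([p.estimate if isinstance(p, CountPair) else p[1] for p in pairs], dtype=float)
    return ref, est


def mae(pairs: Sequence) -> float:
    """Mean absolute error, (1/n) sum |estimate - reference|."""
    ref, est = _split(pairs)
    return float(np.mean(np.abs(est - ref)))


def mape(pairs: Sequence) -> float:
    """Mean absolute percentage error, (100/n) sum |est - ref| / ref."""
    ref, est = _split(pairs)
    if np.any(ref <= 0):
        raise ZeroReference("MAPE needs strictly positive reference counts")
    return float(100.0 * np.mean(np.abs(est - ref) / ref))


def pearson_r(pairs: Sequence) -> tuple[float, float]:
    """Pearson product-moment R and its two-sided p-value (t, n-2 df)."""
    ref, est = _split(pairs)
    if len(ref) < 3:
        raise EmptyInput("Pearson correlation needs at least 3 pairs")
    if np.std(ref) == 0 or np.std(est) == 0:
        raise DegenerateVariance("constant vector: correlation undefined")
    res = stats.pearsonr(ref, est)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p with k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise EmptyInput("need at least two non-empty groups")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise EmptyInput("need at least 3 values in total")
    if np.all(pooled == pooled[0]):
        raise DegenerateGroups("all values identical: ranks carry no information")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# joining truth/estimate tables (the `evaluate` subcommand)


def join_counts(
    truth: dict[str, int], estimates: dict[str, int], tags: dict[str, dict] | None = None
) -> list[CountPair]:
    """Inner-join two id -> count maps into scored pairs."""
    shared = sorted(set(truth) & set(estimates))
    if not shared:
        raise JoinFailure("truth and estimate tables share no ids")
    tags = tags or {}
    return [CountPair(int(truth[i]), int(estimates[i]), tags.get(i, {})) for i in shared]


@dataclass(frozen=True)
class EvaluationReport:
    mae: float
    mape: float
    pearson_r: float
    pearson_p: float
    n: int
    groups: dict[str, tuple[float, float]] = field(default_factory=dict)  # tag -> (H, p)


def evaluate_pairs(pairs: Sequence[CountPair], group_by: str | None = None) -> EvaluationReport:
    """All accuracy statistics on one pair set, optionally grouped."""
    groups: dict[str, tuple[float, float]] = {}
    if group_by is not None:
        by_level: dict[str, list[int]] = {}
        for p in pairs:
            by_level.setdefault(str(p.tags.get(group_by, "")), []).append(p.estimate)
        if len(by_level) >= 2:
            groups[group_by] = kruskal_wallis(list(by_level.values()))
    r, pv = pearson_r(pairs)
    return EvaluationReport(
        mae=mae(pairs), mape=mape(pairs), pearson_r=r, pearson_p=pv, n=len(pairs), groups=groups
    )


# ---------------------------------------------------------------------------
# synthetic accuracy benchmark


def run_benchmark(
    n_scenes: int = 20,
    seed: int = 0,
    count_range: tuple[int, int] = (8, 325),
    cluster_fly_fraction: float = 0.02,
    **scene_overrides,
) -> tuple[list[CountPair], EvaluationReport]:
    """Score the full pipeline on seeded synthetic A4 scenes.

    Per-scene fly counts are drawn uniformly from ``count_range``; a small
    fraction of flies sit in 2-3-fly touching clusters (contacts are
    minimised, matching the imaging protocol the generator emulates).
    Returns the per-scene pairs and the accuracy report.
    """
    from .report import count_image
    from .scene import benchmark_spec, generate_scene

    rng = np.random.default_rng(seed)
    pairs: list[CountPair] = []
    for i in range(n_scenes):
        n_flies = int(rng.integers(count_range[0], count_range[1] + 1))
        scene_seed = int(rng.integers(0, 2**31 - 1))
        spec = benchmark_spec(
            n_flies, scene_seed, cluster_fly_fraction=cluster_fly_fraction, **scene_overrides
        )
        image, truth = generate_scene(spec)
        result = count_image(image, spec.sheet)
        pairs.append(
            CountPair(truth.true_fly_count, result.report.total_estimate, {"scene": str(i)})
        )
    return pairs, evaluate_pairs(pairs)
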