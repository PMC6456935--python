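"""Per-sample richness and diversity estimation and group comparisons.

Implements observed richness, the Chao1 nonparametric richness estimator,
Shannon entropy (nats) and the Gini-Simpson index, plus cumulative dominance
curves (fraction of reads captured by the top-k OTUs) and rank-sum
comparisons of any metric between cohort groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .table import OtuTable, SampleMetadata, samples_in_group

__all__ = [
    "DiversityProfile",
    "GroupComparison",
    "observed_richness",
    "chao1",
    "shannon",
    "simpson",
    "diversity_table",
    "profiles_to_dataframe",
    "compare_groups",
    "dominance_curve",
]


@dataclass
class DiversityProfile:
    """Richness and diversity estimates for one sample."""

    sample_id: str
    observed_otus: int
    chao1: float
    shannon: float
    simpson: float


@dataclass
class GroupComparison:
    """Two-sided rank-sum comparison of one metric between two groups."""

    metric: str
    group_a: str
    group_b: str
    statistic: float
    p_value: float


def _as_counts(counts) -> np.ndarray:
    c = np.asarray(counts)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    return c


def _positive(counts) -> np.ndarray:
    c = _as_counts(counts)
    pos = c[c > 0]
    if pos.size == 0:
        raise ValueError("empty community: no positive counts")
    return pos


def observed_richness(counts) -> int:
    """Number of features with a positive count."""
    return int(np.count_nonzero(_as_counts(counts) > 0))


def chao1(counts) -> float:
    """Chao1 richness estimate.

    ``S_obs + F1^2 / (2 F2)`` where F1/F2 are the singleton/doubleton counts;
    when there are no doubletons the bias-corrected fallback
    ``S_obs + F1 (F1 - 1) / 2`` avoids the division by zero.
    """
    pos = _positive(counts)
    s_obs = pos.size
    f1 = int(np.sum(pos == 1))
    f2 = int(np.sum(pos == 2))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def shannon(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i, natural logarithm."""
    pos = _positive(counts)
    p = pos / pos.sum()
    return float(-np.sum(p * np.log(p)))


def simpson(counts) -> float:
    """Gini-Simpson diversity 1 - sum p_i^2."""
    pos = _positive(counts)
    p = pos / pos.sum()
    return float(1.0 - np.sum(p * p))


def simpson_dominance(counts) -> float:
    """Simpson dominance D = sum p_i^2 (alternative convention)."""
    return 1.0 - simpson(counts)


def inverse_simpson(counts) -> float:
    """Inverse Simpson 1 / sum p_i^2 (alternative convention)."""
    return 1.0 / (1.0 - simpson(counts))


def diversity_table(table: OtuTable) -> list[DiversityProfile]:
    """One :class:`DiversityProfile` per sample, computed on the table's
    counts as given (rarefy first for depth-comparable estimates)."""
    profiles = []
    for sid in table.sample_ids:
        col = table.sample_counts(sid)
        profiles.append(
            DiversityProfile(
                sample_id=sid,
                observed_otus=observed_richness(col),
                chao1=chao1(col),
                shannon=shannon(col),
                simpson=simpson(col),
            )
        )
    return profiles


def profiles_to_dataframe(profiles: list[DiversityProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": p.sample_id,
                "observed_otus": p.observed_otus,
                "chao1": p.chao1,
                "shannon": p.shannon,
                "simpson": p.simpson,
            }
            for p in profiles
        ]
    )


def compare_groups(
    profiles: list[DiversityProfile],
    metadata: list[SampleMetadata],
    metric: str,
    group_a: str,
    group_b: str,
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of ``metric`` between groups."""
    from .differential import wilcoxon_rank_sum

    by_id = {p.sample_id: p for p in profiles}
    values = {}
    for g in (group_a, group_b):
        ids = [s for s in samples_in_group(metadata, g) if s in by_id]
        if not ids:
            raise ValueError(f"group {g!r} has no samples with profiles")
        values[g] = np.array([getattr(by_id[s], metric) for s in ids], dtype=float)
    if min(len(values[group_a]), len(values[group_b])) < 2:
        warnings.warn(
            f"group with < 2 samples in {metric} {group_a} vs {group_b}; "
            "comparison inconclusive (p = 1)",
            stacklevel=2,
        )
        return GroupComparison(metric, group_a, group_b, float("nan"), 1.0)
    stat, p = wilcoxon_rank_sum(values[group_a], values[group_b])
    return GroupComparison(metric, group_a, group_b, stat, p)


def comparisons_to_dataframe(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metric": c.metric,
                "group_a": c.group_a,
                "group_b": c.group_b,
                "statistic": c.statistic,
                "p_value": c.p_value,
            }
            for c in comparisons
        ]
    )


def dominance_curve(counts, k_max: int) -> np.ndarray:
    """Cumulative fraction of reads in the top-k features, k = 1..k_max.

    Entry k is (sum of the k largest counts) / (total reads); once k exceeds
    the observed richness the curve is padded at 1.0.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    pos = _positive(counts)
    ordered = np.sort(pos)[::-1]
    frac = np.cumsum(ordered) / ordered.sum()
    if frac.size >= k_max:
        return frac[:k_max]
    return np.concatenate([frac, np.ones(k_max - frac.size)])


def write_diversity(profiles: list[DiversityProfile], path: str | Path) -> None:
    profiles_to_dataframe(profiles).to_csv(path, sep="\t", index=False)
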