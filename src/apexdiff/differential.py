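"""Multi-criterion differential abundance between cohort groups.

A feature is called significant only when three criteria hold together:
Storey q-value <= 0.05 from a two-sided Wilcoxon test, fold change of group
means >= 2, and a Q3 abundance floor — the 75th percentile of the enriched
group's normalized counts must reach 10 (OTU level) or 100 (genus level).
Counts are normalized by rarefaction to the cohort-minimum depth and
low-prevalence features (< 10% of samples) are removed before testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .table import (
    OtuTable,
    SampleMetadata,
    prevalence_filter,
    rarefy,
    samples_in_group,
)

__all__ = [
    "DiffConfig",
    "DiffRecord",
    "Pi0Estimate",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "storey_qvalues",
    "q3_quantile",
    "differential_analysis",
    "records_to_dataframe",
]

#: Sample-size bound below which rank tests use exact enumeration (no ties).
EXACT_N_MAX = 12


@dataclass
class DiffConfig:
    """Thresholds and options for one differential analysis."""

    q_threshold: float = 0.05
    fc_threshold: float = 2.0
    q3_min_otu: float = 10.0
    q3_min_genus: float = 100.0
    prevalence_min: float = 0.10
    pseudocount: float = 1.0
    paired: bool = False
    level: str = "otu"  # {"otu", "genus"}
    storey_lambda: float = 0.5

    def __post_init__(self) -> None:
        for name in ("q_threshold", "fc_threshold", "q3_min_otu", "q3_min_genus",
                     "prevalence_min", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if self.level not in ("otu", "genus"):
            raise ValueError("level must be 'otu' or 'genus'")
        if not 0 < self.storey_lambda < 1:
            raise ValueError("storey_lambda must be in (0, 1)")

    @property
    def q3_min(self) -> float:
        return self.q3_min_otu if self.level == "otu" else self.q3_min_genus


@dataclass
class DiffRecord:
    """Differential result for a single feature."""

    feature_id: str
    level: str
    mean_a: float
    mean_b: float
    fold_change: float
    direction: str  # {"up_in_a", "up_in_b"}
    p_value: float
    q_value: float
    q3_value: float
    passes_q3: bool
    significant: bool


@dataclass
class Pi0Estimate:
    """Storey estimate of the null proportion at a fixed lambda."""

    pi0: float
    lam: float


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test.

    Exact p by enumeration when ``len(x) + len(y) <= 12`` and the pooled
    values carry no ties; otherwise the normal approximation with midrank
    tie correction and continuity correction.
    Returns ``(U statistic for x, p value)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if pooled.size <= EXACT_N_MAX and no_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def wilcoxon_signed_rank(diffs) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped first; the test is exact for n <= 12
    without tied absolute differences, else normal approximation with
    continuity correction.  All-zero input yields p = 1 with a warning.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("no differences supplied")
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    no_ties = np.unique(np.abs(d)).size == d.size
    if d.size <= EXACT_N_MAX and no_ties:
        res = stats.wilcoxon(d, alternative="two-sided", method="exact")
    else:
        res = stats.wilcoxon(
            d, alternative="two-sided", method="approx", correction=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------


def storey_qvalues(
    p_values, lam: float = 0.5, pi0: float | None = None
) -> tuple[Pi0Estimate, np.ndarray]:
    """Storey q-values with the null proportion estimated at a single lambda.

    ``pi0 = min(1, #{p > lam} / (m (1 - lam)))``; passing ``pi0=1`` reduces
    the procedure to Benjamini-Hochberg.  q-values are monotone in p and
    returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < lam < 1:
        raise ValueError("lambda must be in (0, 1)")
    m = p.size
    if pi0 is None:
        pi0 = min(1.0, np.sum(p > lam) / (m * (1.0 - lam)))
        if pi0 <= 0:
            # every p below lambda: fall back to the smallest admissible value
            pi0 = 1.0 / m
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must be in (0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return Pi0Estimate(pi0=float(pi0), lam=lam), q


def q3_quantile(values) -> float:
    """75th percentile with linear interpolation between order statistics."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty vector")
    return float(np.quantile(v, 0.75))


# ---------------------------------------------------------------------------
# The full procedure
# ---------------------------------------------------------------------------


def differential_analysis(
    table: OtuTable,
    metadata: list[SampleMetadata],
    group_a: str,
    group_b: str,
    config: DiffConfig | None = None,
    *,
    seed: int = 0,
) -> list[DiffRecord]:
    """Run the multi-criterion differential pipeline between two groups.

    The table (already at the requested level) is rarefied to its minimum
    sample depth, prevalence-filtered over *all* its samples, then each
    feature is tested between the groups (rank-sum, or signed-rank on
    subject-paired samples when ``config.paired``).  Storey q-values are
    computed over the tested features; fold change uses group means with a
    pseudocount, oriented enriched/depleted; the Q3 filter requires the
    enriched group's 75th-percentile normalized count to reach the
    level-specific floor.  Records are sorted by (q, p).
    """
    config = config or DiffConfig()
    ids_a = samples_in_group(metadata, group_a)
    ids_b = samples_in_group(metadata, group_b)
    ids_a = [s for s in ids_a if s in table.sample_ids]
    ids_b = [s for s in ids_b if s in table.sample_ids]
    if not ids_a or not ids_b:
        raise ValueError(f"no samples for contrast {group_a} vs {group_b}")
    if min(len(ids_a), len(ids_b)) < 3:
        warnings.warn(
            f"group with < 3 samples in {group_a} vs {group_b}; "
            "results will be underpowered",
            stacklevel=2,
        )

    depth = int(table.sample_depths().min())
    normalized = rarefy(table, depth, seed=seed)
    normalized = prevalence_filter(normalized, config.prevalence_min)
    if normalized.n_features == 0:
        return []

    idx_a = [normalized.sample_index(s) for s in ids_a]
    idx_b = [normalized.sample_index(s) for s in ids_b]
    mat_a = normalized.counts[:, idx_a].astype(float)
    mat_b = normalized.counts[:, idx_b].astype(float)

    if config.paired:
        pair_a, pair_b = _paired_columns(metadata, ids_a, ids_b)
        mat_a = normalized.counts[:, [normalized.sample_index(s) for s in pair_a]].astype(float)
        mat_b = normalized.counts[:, [normalized.sample_index(s) for s in pair_b]].astype(float)

    p_values = np.empty(normalized.n_features)
    for i in range(normalized.n_features):
        if config.paired:
            _, p_values[i] = wilcoxon_signed_rank(mat_a[i] - mat_b[i])
        else:
            _, p_values[i] = wilcoxon_rank_sum(mat_a[i], mat_b[i])

    _, q_values = storey_qvalues(p_values, lam=config.storey_lambda)

    records = []
    for i, fid in enumerate(normalized.feature_ids):
        mean_a = float(mat_a[i].mean())
        mean_b = float(mat_b[i].mean())
        if mean_a >= mean_b:
            high, low, direction = mat_a[i], mean_b, "up_in_a"
            mean_high = mean_a
        else:
            high, low, direction = mat_b[i], mean_a, "up_in_b"
            mean_high = mean_b
        fc = (mean_high + config.pseudocount) / (low + config.pseudocount)
        q3 = q3_quantile(high)
        passes_q3 = q3 >= config.q3_min
        significant = (
            q_values[i] <= config.q_threshold
            and fc >= config.fc_threshold
            and passes_q3
        )
        records.append(
            DiffRecord(
                feature_id=fid,
                level=config.level,
                mean_a=mean_a,
                mean_b=mean_b,
                fold_change=float(fc),
                direction=direction,
                p_value=float(p_values[i]),
                q_value=float(q_values[i]),
                q3_value=float(q3),
                passes_q3=bool(passes_q3),
                significant=bool(significant),
            )
        )
    records.sort(key=lambda r: (r.q_value, r.p_value, r.feature_id))
    return records


def _paired_columns(
    metadata: list[SampleMetadata], ids_a: list[str], ids_b: list[str]
) -> tuple[list[str], list[str]]:
    """Match samples across groups by subject; subjects lacking a sample in
    either group are dropped; a subject's first sample per group (table
    order) is used."""
    subject = {m.sample_id: m.subject_id for m in metadata}
    first_a: dict[str, str] = {}
    for s in ids_a:
        first_a.setdefault(subject[s], s)
    first_b: dict[str, str] = {}
    for s in ids_b:
        first_b.setdefault(subject[s], s)
    shared = [subj for subj in first_a if subj in first_b]
    if not shared:
        raise ValueError("no subjects present in both groups for paired analysis")
    return [first_a[s] for s in shared], [first_b[s] for s in shared]


def records_to_dataframe(records: list[DiffRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "level": r.level,
                "mean_a": r.mean_a,
                "mean_b": r.mean_b,
                "fold_change": r.fold_change,
                "direction": r.direction,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "q3_value": r.q3_value,
                "passes_q3": r.passes_q3,
                "significant": r.significant,
            }
            for r in records
        ]
    )


def write_records(records: list[DiffRecord], path: str | Path) -> None:
    records_to_dataframe(records).to_csv(path, sep="\t", index=False)
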