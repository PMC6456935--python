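"""Pairwise shared/unique richness and abundance between samples.

For every unordered sample pair the present-feature sets are split into
shared and sample-unique parts; richness fractions are taken over the union
of present features (the shared fraction is the Jaccard index) and abundance
fractions over the two samples' pooled reads, so each decomposition is a
partition summing to 1.  Pairs are categorized by body site: O2O (oral-oral),
T2T (tooth-tooth) and O2T (oral-tooth).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .table import GROUPS, OtuTable, SampleMetadata

__all__ = ["OverlapRecord", "pairwise_overlap", "overlap_summary",
           "records_to_dataframe"]

#: Body-site code per group: HO is oral, all tooth-derived groups are T.
SITE = {"HO": "O", "HT": "T", "NRCT": "T", "RCT": "T"}


@dataclass
class OverlapRecord:
    """Shared/unique decomposition for one sample pair."""

    sample_x: str
    sample_y: str
    com_richness: float
    x_uni_richness: float
    y_uni_richness: float
    com_abundance: float
    x_uni_abundance: float
    y_uni_abundance: float
    category: str  # {"O2O", "T2T", "O2T"}


def _category(group_x: str, group_y: str) -> str:
    sites = sorted((SITE[group_x], SITE[group_y]))
    return f"{sites[0]}2{sites[1]}"


def pairwise_overlap(
    table: OtuTable,
    metadata: list[SampleMetadata],
    samples: list[str] | None = None,
    mode: str = "pooled",
) -> list[OverlapRecord]:
    """One :class:`OverlapRecord` per unordered pair of ``samples``.

    ``samples`` defaults to all HO and HT samples present in the table.
    ``mode`` controls the abundance decomposition: ``"pooled"`` (default)
    splits the two samples' pooled reads by feature subset; ``"min"`` uses
    the shared min-relative-abundance (Bray-Curtis-like) similarity, with
    the three slices renormalized to a partition.
    """
    if mode not in ("pooled", "min"):
        raise ValueError("mode must be 'pooled' or 'min'")
    group = {m.sample_id: m.group for m in metadata}
    if samples is None:
        samples = [s for s in table.sample_ids if group.get(s) in ("HO", "HT")]
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    for s in samples:
        if s not in table.sample_ids:
            raise ValueError(f"sample {s!r} not in table")
        if s not in group:
            raise ValueError(f"sample {s!r} not in metadata")

    records = []
    for sx, sy in combinations(samples, 2):
        cx = table.sample_counts(sx)
        cy = table.sample_counts(sy)
        px, py = cx > 0, cy > 0
        union = int(np.sum(px | py))
        if union == 0:
            raise ValueError(f"samples {sx!r} and {sy!r} are both empty")
        shared = px & py
        x_only = px & ~py
        y_only = py & ~px

        com_r = float(np.sum(shared)) / union
        x_uni_r = float(np.sum(x_only)) / union
        y_uni_r = float(np.sum(y_only)) / union

        if mode == "pooled":
            total = float(cx.sum() + cy.sum())
            com_a = float(cx[shared].sum() + cy[shared].sum()) / total
            x_uni_a = float(cx[x_only].sum()) / total
            y_uni_a = float(cy[y_only].sum()) / total
        else:
            fx = cx / cx.sum()
            fy = cy / cy.sum()
            shared_min = float(np.minimum(fx, fy).sum())
            raw = np.array([shared_min, 1.0 - shared_min, 1.0 - shared_min])
            raw /= raw.sum()
            com_a, x_uni_a, y_uni_a = (float(v) for v in raw)

        records.append(
            OverlapRecord(
                sample_x=sx,
                sample_y=sy,
                com_richness=com_r,
                x_uni_richness=x_uni_r,
                y_uni_richness=y_uni_r,
                com_abundance=com_a,
                x_uni_abundance=x_uni_a,
                y_uni_abundance=y_uni_a,
                category=_category(group[sx], group[sy]),
            )
        )
    return records


def overlap_summary(
    records: list[OverlapRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-category distribution summaries and pairwise category tests.

    Returns ``(summary, tests)``: quartile summaries of the shared richness
    and abundance fractions per category, and two-sided rank-sum p-values
    between every pair of categories for both metrics.
    """
    from .differential import wilcoxon_rank_sum

    df = records_to_dataframe(records)
    categories = sorted(df["category"].unique())
    if len(categories) < 2:
        raise ValueError("need records from at least 2 categories")

    rows = []
    for cat in categories:
        sub = df[df["category"] == cat]
        for metric in ("com_richness", "com_abundance"):
            v = sub[metric].to_numpy()
            rows.append(
                {
                    "category": cat,
                    "metric": metric,
                    "n_pairs": len(v),
                    "mean": v.mean(),
                    "q1": np.quantile(v, 0.25),
                    "median": np.median(v),
                    "q3": np.quantile(v, 0.75),
                }
            )
    summary = pd.DataFrame(rows)

    test_rows = []
    for ca, cb in combinations(categories, 2):
        for metric in ("com_richness", "com_abundance"):
            va = df.loc[df["category"] == ca, metric].to_numpy()
            vb = df.loc[df["category"] == cb, metric].to_numpy()
            stat, p = wilcoxon_rank_sum(va, vb)
            test_rows.append(
                {
                    "category_a": ca,
                    "category_b": cb,
                    "metric": metric,
                    "statistic": stat,
                    "p_value": p,
                }
            )
    return summary, pd.DataFrame(test_rows)


def records_to_dataframe(records: list[OverlapRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_x": r.sample_x,
                "sample_y": r.sample_y,
                "com_richness": r.com_richness,
                "x_uni_richness": r.x_uni_richness,
                "y_uni_richness": r.y_uni_richness,
                "com_abundance": r.com_abundance,
                "x_uni_abundance": r.x_uni_abundance,
                "y_uni_abundance": r.y_uni_abundance,
                "category": r.category,
            }
            for r in records
        ]
    )


def write_records(records: list[OverlapRecord], path: str | Path) -> None:
    records_to_dataframe(records).to_csv(path, sep="\t", index=False)
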