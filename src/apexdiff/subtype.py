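"""Lesion-size classification and genus-level subtype clustering.

Diseased teeth carry a radiographic lesion dimension string ("4×5 mm");
the maximum diameter classifies the lesion as LSA (>= 5 mm) or SSA (< 5 mm).
Diseased samples are partitioned into subtypes by agglomerative clustering
of genus-level relative abundances (Bray-Curtis dissimilarity, complete
linkage by default), and cluster-clinical concordance is scored as the
best-mapping accuracy with a label-permutation p-value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .table import OtuTable, relative_abundance

__all__ = [
    "LesionAnnotation",
    "SubtypeResult",
    "parse_lesion",
    "hierarchical_subtypes",
    "concordance",
]

#: Maximum-diameter cut (mm) between large (LSA) and small (SSA) lesion area.
LSA_MIN_MM = 5.0

_LESION_RE = re.compile(
    r"^\s*(\d+(?:\.\d+)?)\s*[×xX*]\s*(\d+(?:\.\d+)?)\s*(?:mm)?\s*$"
)


@dataclass
class LesionAnnotation:
    """Parsed lesion dimensions and the LSA/SSA classification."""

    raw: str
    dims_mm: tuple[float, float]
    max_mm: float
    label: str  # {"LSA", "SSA"}


@dataclass
class SubtypeResult:
    """Cluster assignment with concordance against clinical lesion labels."""

    assignment: dict[str, str]
    accuracy: float
    p_value: float


def parse_lesion(raw: str) -> LesionAnnotation:
    """Parse an "a×b mm" dimension string (mixed ×/x delimiters tolerated)
    and classify by the >= 5 mm maximum-diameter rule."""
    match = _LESION_RE.match(raw)
    if not match:
        raise ValueError(f"cannot parse lesion string {raw!r}")
    dims = (float(match.group(1)), float(match.group(2)))
    max_mm = max(dims)
    label = "LSA" if max_mm >= LSA_MIN_MM else "SSA"
    return LesionAnnotation(raw=raw, dims_mm=dims, max_mm=max_mm, label=label)


_CLUSTER_LETTERS = "ABCDEFGH"


def hierarchical_subtypes(
    table: OtuTable,
    samples: list[str],
    k: int = 2,
    metric: str = "braycurtis",
    method: str = "complete",
) -> dict[str, str]:
    """Agglomerative clustering of samples on relative-abundance profiles.

    ``table`` is expected at genus level (any table works).  Samples are
    ordered lexicographically before clustering so the result is
    deterministic; cluster labels A, B, ... are assigned by first occurrence
    in that order.  Returns sample -> cluster letter.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(samples) < k:
        raise ValueError(f"need at least {k} samples for {k} clusters")
    ordered = sorted(samples)
    sub = table.select_samples(ordered)
    profiles = relative_abundance(sub).T  # samples x features
    if len(ordered) == k:
        return {s: _CLUSTER_LETTERS[i] for i, s in enumerate(ordered)}
    dist = pdist(profiles, metric=metric)
    tree = linkage(dist, method=method)
    raw_labels = fcluster(tree, t=k, criterion="maxclust")
    letter: dict[int, str] = {}
    assignment: dict[str, str] = {}
    for sample, cluster in zip(ordered, raw_labels):
        if cluster not in letter:
            letter[cluster] = _CLUSTER_LETTERS[len(letter)]
        assignment[sample] = letter[cluster]
    return assignment


def concordance(
    assignment: dict[str, str],
    labels: dict[str, str],
    n_perm: int = 100_000,
    seed: int = 0,
    method: str = "permutation",
) -> SubtypeResult:
    """Best-mapping concordance between a 2-cluster assignment and binary
    clinical labels.

    Accuracy is the maximum over the two cluster->label mappings of the
    matching fraction (hence >= 0.5).  ``method="permutation"`` shuffles the
    labels uniformly and reports ``(1 + #{accuracy >= observed}) /
    (n_perm + 1)``; ``method="fisher"`` substitutes Fisher's exact test on
    the 2x2 cluster-by-label table.
    """
    if set(assignment) != set(labels):
        raise ValueError("assignment and labels must cover the same samples")
    samples = sorted(assignment)
    clusters = np.array([assignment[s] for s in samples])
    labs = np.array([labels[s] for s in samples])
    cluster_names = sorted(set(clusters))
    label_names = sorted(set(labs))
    if len(cluster_names) > 2 or len(label_names) > 2:
        raise ValueError("concordance is defined for two clusters and two labels")
    n = len(samples)
    is_a = clusters == cluster_names[0]
    is_first = labs == label_names[0]
    n_a = int(is_a.sum())
    n_first = int(is_first.sum())
    x_obs = int(np.sum(is_a & is_first))
    accuracy = _best_accuracy(x_obs, n_a, n_first, n)

    if method == "fisher":
        contingency = np.array(
            [[x_obs, n_a - x_obs], [n_first - x_obs, n - n_a - n_first + x_obs]]
        )
        _, p = stats.fisher_exact(contingency, alternative="two-sided")
    elif method == "permutation":
        # Under a uniform label shuffle the accuracy depends only on how many
        # of the first-label samples land in cluster A — hypergeometric.
        rng = np.random.default_rng(seed)
        x_perm = rng.hypergeometric(n_first, n - n_first, n_a, size=n_perm)
        acc_perm = _best_accuracy(x_perm, n_a, n_first, n)
        p = (1 + int(np.sum(acc_perm >= accuracy - 1e-12))) / (n_perm + 1)
    else:
        raise ValueError("method must be 'permutation' or 'fisher'")
    return SubtypeResult(assignment=dict(assignment), accuracy=float(accuracy),
                         p_value=float(p))


def _best_accuracy(x, n_a: int, n_first: int, n: int):
    """Accuracy maximized over the two cluster->label mappings, where ``x``
    is the count of cluster-A samples carrying the first label."""
    x = np.asarray(x)
    matches_1 = x + (n - n_a) - (n_first - x)  # A -> first label
    matches_2 = (n_a - x) + (n_first - x)      # A -> second label
    return np.maximum(matches_1, matches_2) / n


def assignment_to_dataframe(
    assignment: dict[str, str], labels: dict[str, str]
) -> pd.DataFrame:
    rows = []
    for s in sorted(assignment):
        rows.append(
            {
                "sample_id": s,
                "cluster": assignment[s],
                "lesion_label": labels.get(s, ""),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "cluster", "lesion_label"])
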