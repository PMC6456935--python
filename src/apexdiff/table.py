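"""OTU count tables and sample metadata.

Data model for feature (OTU) count matrices with Greengenes-style taxonomy
lineages, plus the table-level operations every downstream stage builds on:
classic tab-separated I/O, taxonomic aggregation, rarefaction (down-sampling
without replacement to a common depth), relative abundance and prevalence
filtering.
"""

from __future__ import annotations

import enum
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "GROUPS",
    "TaxLevel",
    "OtuTable",
    "SampleMetadata",
    "ParseError",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "aggregate_taxa",
    "rarefy",
    "relative_abundance",
    "prevalence_filter",
    "samples_in_group",
]

#: Taxonomic ranks in order, kingdom -> species.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Single-letter Greengenes rank prefixes, aligned with RANKS.
RANK_PREFIXES = ("k", "p", "c", "o", "f", "g", "s")

#: The four cohort groups: healthy oral, healthy tooth, apical periodontitis
#: without root canal treatment, and failed root canal treatment.
GROUPS = ("HO", "HT", "NRCT", "RCT")


class ParseError(ValueError):
    """Raised when an input file violates the expected dialect."""


class TaxLevel(enum.Enum):
    """Aggregation levels for taxon summarization (phylum through genus)."""

    PHYLUM = "phylum"
    CLASS = "class"
    ORDER = "order"
    FAMILY = "family"
    GENUS = "genus"

    @property
    def rank_index(self) -> int:
        return RANKS.index(self.value)


@dataclass
class OtuTable:
    """A features x samples integer count matrix with taxonomy lineages.

    Parameters
    ----------
    feature_ids
        Unique feature (OTU) identifiers, one per row of ``counts``.
    taxonomy
        Per-feature lineage of ranked names ordered kingdom -> species;
        lineages may be truncated and individual names may be empty.
    sample_ids
        Unique sample identifiers, one per column of ``counts``.
    counts
        Non-negative integer matrix, shape ``(n_features, n_samples)``.
    """

    feature_ids: list[str]
    taxonomy: list[tuple[str, ...]]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(self.taxonomy) != len(self.feature_ids):
            raise ValueError("taxonomy length must equal number of features")
        self.taxonomy = [tuple(lineage) for lineage in self.taxonomy]
        if self.n_features > 0:
            empty = [s for s, d in zip(self.sample_ids, self.sample_depths()) if d == 0]
            if empty:
                warnings.warn(f"samples with zero depth: {empty}", stacklevel=2)

    # -- basic introspection -------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_depths(self) -> np.ndarray:
        """Per-sample read totals (column sums)."""
        return self.counts.sum(axis=0)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in table") from None

    def sample_counts(self, sample_id: str) -> np.ndarray:
        """Count vector (over features) for one sample."""
        return self.counts[:, self.sample_index(sample_id)]

    # -- subsetting ----------------------------------------------------------

    def select_samples(self, sample_ids: list[str]) -> "OtuTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return OtuTable(
            feature_ids=list(self.feature_ids),
            taxonomy=list(self.taxonomy),
            sample_ids=list(sample_ids),
            counts=self.counts[:, idx],
        )

    def select_features(self, mask: np.ndarray) -> "OtuTable":
        mask = np.asarray(mask, dtype=bool)
        return OtuTable(
            feature_ids=[f for f, m in zip(self.feature_ids, mask) if m],
            taxonomy=[t for t, m in zip(self.taxonomy, mask) if m],
            sample_ids=list(self.sample_ids),
            counts=self.counts[mask, :],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and self.taxonomy == other.taxonomy
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class SampleMetadata:
    """Clinical annotation for one sample.

    ``group`` is one of HO/HT/NRCT/RCT; ``subject_id`` links a subject's
    paired oral (HO) and tooth (HT) samples; ``lesion`` is the radiographic
    lesion dimension string (diseased teeth only), e.g. ``"4×5 mm"``.
    """

    sample_id: str
    group: str
    subject_id: str
    lesion: str | None = None
    subtype: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.lesion is not None and self.group not in ("NRCT", "RCT"):
            raise ValueError("lesion annotation only allowed for diseased samples")


def samples_in_group(metadata: list[SampleMetadata], group: str) -> list[str]:
    """Sample ids belonging to ``group``, in metadata order."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    return [m.sample_id for m in metadata if m.group == group]


# ---------------------------------------------------------------------------
# Lineage string handling (Greengenes "k__Bacteria; p__Firmicutes; ..." style)
# ---------------------------------------------------------------------------

_PREFIX_RE = re.compile(r"^[a-zA-Z]__")


def parse_lineage(text: str) -> tuple[str, ...]:
    """Split a lineage string on ';' and strip rank prefixes of the form 'x__'."""
    if not text.strip():
        return ()
    names = []
    for part in text.split(";"):
        part = part.strip()
        names.append(_PREFIX_RE.sub("", part))
    return tuple(names)


def format_lineage(lineage: tuple[str, ...]) -> str:
    """Regenerate the prefixed form; unknown ranks become empty names."""
    parts = []
    for i, name in enumerate(lineage[: len(RANKS)]):
        prefix = RANK_PREFIXES[i] if i < len(RANK_PREFIXES) else "x"
        parts.append(f"{prefix}__{name}")
    return "; ".join(parts)


# ---------------------------------------------------------------------------
# File I/O — classic QIIME tab-separated dialect
# ---------------------------------------------------------------------------


def read_otu_table(path: str | Path) -> OtuTable:
    """Read a tab-separated OTU table.

    The first column holds feature ids (a leading ``#OTU ID`` header marker is
    tolerated), the remaining columns integer counts per sample, and an
    optional last column named ``taxonomy`` holds lineage strings.
    """
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 1:
        raise ParseError(f"{path}: malformed header")
    has_tax = len(header) >= 2 and header[-1].strip().lower() == "taxonomy"
    sample_ids = header[1 : len(header) - 1 if has_tax else len(header)]
    n_cols = len(header)

    feature_ids: list[str] = []
    taxonomy: list[tuple[str, ...]] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise ParseError(
                f"{path}:{lineno}: expected {n_cols} columns, got {len(fields)}"
            )
        feature_ids.append(fields[0])
        raw_counts = fields[1 : n_cols - 1 if has_tax else n_cols]
        row = []
        for value in raw_counts:
            try:
                x = float(value)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric count {value!r}") from None
            if x != math.floor(x):
                raise ParseError(f"{path}:{lineno}: non-integer count {value!r}")
            if x < 0:
                raise ParseError(f"{path}:{lineno}: negative count {value!r}")
            row.append(int(x))
        rows.append(row)
        taxonomy.append(parse_lineage(fields[-1]) if has_tax else ())

    counts = (
        np.array(rows, dtype=np.int64)
        if rows
        else np.zeros((0, len(sample_ids)), dtype=np.int64)
    )
    try:
        return OtuTable(feature_ids, taxonomy, sample_ids, counts)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write ``table`` in the dialect accepted by :func:`read_otu_table`.

    The taxonomy column is omitted when every lineage is empty, so that
    ``read(write(t)) == t`` holds in both cases.
    """
    path = Path(path)
    has_tax = any(len(lin) > 0 for lin in table.taxonomy)
    with path.open("w") as fh:
        header = ["#OTU ID", *table.sample_ids]
        if has_tax:
            header.append("taxonomy")
        fh.write("\t".join(header) + "\n")
        for i, fid in enumerate(table.feature_ids):
            row = [fid, *(str(int(c)) for c in table.counts[i])]
            if has_tax:
                row.append(format_lineage(table.taxonomy[i]))
            fh.write("\t".join(row) + "\n")


_META_COLUMNS = ("sample_id", "group", "subject_id", "lesion", "subtype")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read tab-separated sample metadata (sample_id, group, subject_id,
    optional lesion and subtype columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for required in ("sample_id", "group", "subject_id"):
        if required not in df.columns:
            raise ParseError(f"{path}: missing required column {required!r}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SampleMetadata(
                sample_id=row["sample_id"],
                group=row["group"],
                subject_id=row["subject_id"],
                lesion=row.get("lesion") or None,
                subtype=row.get("subtype") or None,
            )
        )
    return records


def write_metadata(metadata: list[SampleMetadata], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "group": m.group,
                "subject_id": m.subject_id,
                "lesion": m.lesion or "",
                "subtype": m.subtype or "",
            }
            for m in metadata
        ],
        columns=list(_META_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Table transformations
# ---------------------------------------------------------------------------


def aggregate_taxa(table: OtuTable, level: TaxLevel | str) -> OtuTable:
    """Sum features sharing the same lineage prefix down to ``level``.

    The aggregation key is the full lineage prefix (kingdom down to the
    requested rank), not the bare name, so homonymous genera in different
    families stay separate.  Features lacking a name at ``level`` are pooled
    into a single "unassigned" feature whose lineage is the element-wise
    common prefix of its members.  Per-sample depths are conserved.
    """
    level = TaxLevel(level)
    idx = level.rank_index

    keys: list[tuple[str, ...] | None] = []
    for lineage in table.taxonomy:
        if len(lineage) > idx and lineage[idx]:
            keys.append(tuple(lineage[: idx + 1]))
        else:
            keys.append(None)

    order: list[tuple[str, ...] | None] = []
    groups: dict[tuple[str, ...] | None, list[int]] = {}
    for i, key in enumerate(keys):
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(i)
    # unassigned bucket goes last
    if None in groups:
        order = [k for k in order if k is not None] + [None]

    feature_ids: list[str] = []
    taxonomy: list[tuple[str, ...]] = []
    rows = np.zeros((len(order), table.n_samples), dtype=np.int64)
    for j, key in enumerate(order):
        members = groups[key]
        rows[j] = table.counts[members].sum(axis=0)
        if key is None:
            feature_ids.append("unassigned")
            taxonomy.append(_common_prefix([table.taxonomy[i] for i in members], idx))
        else:
            feature_ids.append(";".join(key))
            taxonomy.append(key)
    return OtuTable(feature_ids, taxonomy, list(table.sample_ids), rows)


def _common_prefix(lineages: list[tuple[str, ...]], max_len: int) -> tuple[str, ...]:
    """Element-wise common prefix of lineages, truncated at ``max_len`` ranks."""
    if not lineages:
        return ()
    prefix: list[str] = []
    for rank in range(min(max_len, min(len(l) for l in lineages))):
        names = {l[rank] for l in lineages}
        if len(names) != 1 or not names.pop():
            break
        prefix.append(lineages[0][rank])
    return tuple(prefix)


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Down-sample every sample to exactly ``depth`` reads without replacement.

    Each retained column becomes a single multivariate-hypergeometric draw of
    size ``depth`` from its reads; samples whose total falls below ``depth``
    are dropped with a warning.  Reproducible given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    columns: list[np.ndarray] = []
    dropped: list[str] = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        total = int(col.sum())
        if total < depth:
            dropped.append(sid)
            continue
        keep.append(j)
        if total == depth:
            columns.append(col.copy())
        else:
            columns.append(rng.multivariate_hypergeometric(col, depth))
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} sample(s) below depth {depth}: {dropped}",
            stacklevel=2,
        )
    counts = (
        np.column_stack(columns)
        if columns
        else np.zeros((table.n_features, 0), dtype=np.int64)
    )
    return OtuTable(
        feature_ids=list(table.feature_ids),
        taxonomy=list(table.taxonomy),
        sample_ids=[table.sample_ids[j] for j in keep],
        counts=counts,
    )


def relative_abundance(table: OtuTable) -> np.ndarray:
    """Column-normalized fractions; every column sums to 1."""
    depths = table.sample_depths()
    if np.any(depths == 0):
        bad = [s for s, d in zip(table.sample_ids, depths) if d == 0]
        raise ValueError(f"zero-depth samples: {bad}")
    return table.counts / depths.astype(float)


def prevalence_filter(table: OtuTable, min_fraction: float = 0.10) -> OtuTable:
    """Retain features present (count > 0) in at least
    ``ceil(min_fraction * n_samples)`` samples."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    threshold = math.ceil(min_fraction * table.n_samples)
    presence = (table.counts > 0).sum(axis=1)
    return table.select_features(presence >= threshold)
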