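"""Synthetic apical-periodontitis cohort generator.

Emulates the study design every downstream stage is exercised on: four
groups (9 HO oral controls, 10 HT healthy-tooth apices from 9 subjects,
23 NRCT untreated diseased teeth, 8 RCT failed-treatment teeth), per-sample
read depths uniform on [29,604, 68,088], a heavy-tailed log-normal
rank-abundance with group-specific dominance (diseased communities are more
dominated), Dirichlet-multinomial sampling noise, paired subject effects
between a subject's oral and tooth samples, and three disjoint planted
feature sets: 49 features high in healthy and suppressed in disease, 40
features elevated in diseased teeth (NRCT and RCT) and near-zero in healthy
samples, and 51 features separating the lesion subtypes (present in
subtype B and the healthy groups, suppressed in A).
NRCT samples carry lesion-dimension strings aligned with their subtype
(A with large, B with small lesion area) up to a controllable mislabel rate.

The dominance tilt is drawn mostly per sample (``individuality``), with a
small cohort-shared component, mirroring the strong inter-individual
variability of these communities; consequently non-planted features are
close to exchangeable between groups at the single-feature level even
though per-sample dominance and richness differ sharply by group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .table import GROUPS, OtuTable, SampleMetadata

__all__ = ["CohortDesign", "PlantedTruth", "default_design", "simulate_cohort"]


def _default_group_sizes() -> dict[str, int]:
    return {"HO": 9, "HT": 10, "NRCT": 23, "RCT": 8}


def _default_sigmas() -> dict[str, float]:
    # Dominance parameter of the log-normal rank-abundance per group;
    # larger sigma concentrates reads in fewer features.  Calibrated so the
    # group-mean top-100 cumulative fractions fall near 85/83/75/72% for
    # RCT/NRCT/HT/HO at the default depths.
    return {"HO": 2.25, "HT": 2.40, "NRCT": 2.75, "RCT": 2.83}


@dataclass
class CohortDesign:
    """All knobs of the cohort simulator (defaults are the study design)."""

    group_sizes: dict[str, int] = field(default_factory=_default_group_sizes)
    depth_range: tuple[int, int] = (29_604, 68_088)
    n_features: int = 5_000
    lognormal_sigma_by_group: dict[str, float] = field(default_factory=_default_sigmas)
    overdispersion: float = 300.0
    n_down: int = 49
    n_up: int = 40
    n_subtype: int = 51
    subtype_split: tuple[int, int] = (9, 14)  # NRCT samples in subtype A, B
    lesion_mislabel_rate: float = 4 / 23
    individuality: float = 0.9
    paired_subject_effect: float = 0.3
    planted_high_share: float = 2e-3
    planted_share_sigma: float = 0.5
    planted_suppression: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if set(self.group_sizes) != set(GROUPS):
            raise ValueError(f"group_sizes must cover exactly {GROUPS}")
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("all group sizes must be positive")
        lo, hi = self.depth_range
        if not 0 < lo <= hi:
            raise ValueError("depth_range must satisfy 0 < low <= high")
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if min(self.n_down, self.n_up, self.n_subtype) < 0:
            raise ValueError("planted set sizes must be non-negative")
        if self.n_down + self.n_up + self.n_subtype > self.n_features:
            raise ValueError("planted sets cannot exceed the feature pool")
        if set(self.lognormal_sigma_by_group) != set(GROUPS):
            raise ValueError("lognormal_sigma_by_group must cover all groups")
        if sum(self.subtype_split) != self.group_sizes["NRCT"]:
            raise ValueError("subtype_split must sum to the NRCT group size")
        if any(n <= 0 for n in self.subtype_split):
            raise ValueError("both subtypes need at least one sample")
        if not 0 <= self.lesion_mislabel_rate <= 1:
            raise ValueError("lesion_mislabel_rate must be in [0, 1]")
        if not self.overdispersion > 0:
            raise ValueError("overdispersion must be positive (may be inf)")
        n_planted = self.n_down + self.n_up + self.n_subtype
        if self.planted_high_share <= 0 or self.planted_high_share * n_planted >= 0.5:
            # keep the planted pool well below half the community
            raise ValueError("planted_high_share too large for the planted pool")
        if not 0 < self.planted_suppression < 1:
            raise ValueError("planted_suppression must be in (0, 1)")
        if not 0 <= self.individuality <= 1:
            raise ValueError("individuality must be in [0, 1]")
        if not 0 <= self.paired_subject_effect <= 1:
            raise ValueError("paired_subject_effect must be in [0, 1]")


@dataclass
class PlantedTruth:
    """Ground truth of the planted effects, for recovery tests."""

    down_ids: list[str]
    up_ids: list[str]
    subtype_ids: list[str]
    subtype_assignment: dict[str, str]  # NRCT sample -> {"A", "B"}
    lesion_labels: dict[str, str]  # NRCT sample -> {"LSA", "SSA"}


def default_design(seed: int = 0) -> CohortDesign:
    """The study-design defaults with a caller-chosen seed."""
    return replace(CohortDesign(), seed=seed)


# -- taxonomy flavor --------------------------------------------------------

_PHYLA = (
    "Firmicutes",
    "Bacteroidetes",
    "Proteobacteria",
    "Actinobacteria",
    "Fusobacteria",
    "Spirochaetes",
    "Synergistetes",
    "TM7",
)

# Genera reserved for the planted sets, echoing taxa typical of healthy
# apices (down set), periodontal lesions (up set) and lactic-acid bacteria
# (subtype set).
_DOWN_GENERA = (
    "Streptococcus", "Haemophilus", "Actinomyces", "Granulicatella",
    "Leptotrichia", "Neisseria", "Veillonella", "Rothia",
)
_UP_GENERA = (
    "Treponema", "Sphaerochaeta", "Burkholderia", "Schwartzia", "Dialister",
    "Pseudoramibacter_Eubacterium", "Slackia", "Bifidobacterium", "TG5",
    "Prevotella",
)
_SUBTYPE_GENERA = (
    "Lactococcus", "Enterococcus", "Lactobacillus", "Mogibacterium",
    "Atopobium", "Olsenella", "Selenomonas", "Capnocytophaga",
)


def _lineage(genus: str, phylum: str, truncate: bool = False) -> tuple[str, ...]:
    base = ("Bacteria", phylum, phylum + "_c", phylum + "_o", genus + "_f")
    return base if truncate else base + (genus,)


def simulate_cohort(
    design: CohortDesign,
) -> tuple[OtuTable, list[SampleMetadata], PlantedTruth]:
    """Draw one synthetic cohort; deterministic given ``design.seed``."""
    design.validate()
    rng = np.random.default_rng(design.seed)
    nf = design.n_features

    feature_ids = [f"OTU_{i + 1:05d}" for i in range(nf)]
    z = rng.standard_normal(nf)

    n_planted = design.n_down + design.n_up + design.n_subtype
    planted = rng.choice(nf, size=n_planted, replace=False)
    down_idx = planted[: design.n_down]
    up_idx = planted[design.n_down : design.n_down + design.n_up]
    sub_idx = planted[design.n_down + design.n_up :]

    taxonomy = _draw_taxonomy(rng, nf, down_idx, up_idx, sub_idx)

    # target relative share of each planted feature in the groups where it
    # is "high"; suppressed groups get share * planted_suppression
    high_share = design.planted_high_share * np.exp(
        design.planted_share_sigma * rng.standard_normal(n_planted)
    )
    share_of = dict(zip(planted.tolist(), high_share.tolist()))

    unplanted_mask = np.ones(nf, dtype=bool)
    unplanted_mask[planted] = False

    def expected_profile(group: str, subtype: str | None, tilt: np.ndarray) -> np.ndarray:
        """Expected relative-abundance vector for one sample, given its
        dominance tilt."""
        sigma = design.lognormal_sigma_by_group[group]
        p = np.zeros(nf)
        healthy = group in ("HO", "HT")
        for i in down_idx:
            p[i] = share_of[i] * (1.0 if healthy else design.planted_suppression)
        for i in up_idx:
            p[i] = share_of[i] * (design.planted_suppression if healthy else 1.0)
        for i in sub_idx:
            high = healthy or subtype == "B"
            p[i] = share_of[i] * (1.0 if high else design.planted_suppression)
        planted_total = p[planted].sum()
        w = np.exp(sigma * tilt[unplanted_mask])
        p[unplanted_mask] = (1.0 - planted_total) * w / w.sum()
        return p

    # -- cohort layout -------------------------------------------------------
    n_ho, n_ht = design.group_sizes["HO"], design.group_sizes["HT"]
    n_nrct, n_rct = design.group_sizes["NRCT"], design.group_sizes["RCT"]
    healthy_subjects = [f"H{i + 1:02d}" for i in range(max(n_ho, n_ht - 1))]

    layout: list[tuple[str, str, str]] = []  # (sample_id, group, subject_id)
    for i in range(n_ho):
        layout.append((f"HO.{i + 1:02d}", "HO", healthy_subjects[i % len(healthy_subjects)]))
    for i in range(n_ht):
        # one healthy subject contributes two teeth when HT exceeds the
        # subject pool (the default: 10 teeth from 9 subjects)
        subject = healthy_subjects[i % len(healthy_subjects)]
        layout.append((f"HT.{i + 1:02d}", "HT", subject))
    for i in range(n_nrct):
        layout.append((f"NRCT.{i + 1:02d}", "NRCT", f"P{i + 1:02d}"))
    for i in range(n_rct):
        layout.append((f"RCT.{i + 1:02d}", "RCT", f"R{i + 1:02d}"))

    n_a = design.subtype_split[0]
    nrct_ids = [s for s, g, _ in layout if g == "NRCT"]
    subtype_assignment = {
        s: ("A" if i < n_a else "B") for i, s in enumerate(nrct_ids)
    }
    # RCT teeth also carry a latent lesion subtype, in the same proportion,
    # so the subtype features stay balanced between the diseased groups
    rct_ids = [s for s, g, _ in layout if g == "RCT"]
    n_a_rct = round(n_rct * n_a / n_nrct)
    latent_subtype = dict(subtype_assignment)
    latent_subtype.update(
        {s: ("A" if i < n_a_rct else "B") for i, s in enumerate(rct_ids)}
    )

    # the dominance tilt of the two samples of one healthy subject shares a
    # common component with weight paired_subject_effect
    subject_tilt: dict[str, np.ndarray] = {
        subj: rng.standard_normal(nf) for subj in healthy_subjects
    }

    # -- draw samples --------------------------------------------------------
    lo, hi = design.depth_range
    ind = design.individuality
    rho = design.paired_subject_effect
    columns = []
    metadata: list[SampleMetadata] = []
    lesion_labels: dict[str, str] = {}
    for sample_id, group, subject in layout:
        subtype = latent_subtype.get(sample_id)
        if group in ("HO", "HT"):
            eta = math.sqrt(rho) * subject_tilt[subject] + math.sqrt(
                1.0 - rho
            ) * rng.standard_normal(nf)
        else:
            eta = rng.standard_normal(nf)
        tilt = math.sqrt(1.0 - ind) * z + math.sqrt(ind) * eta
        p = expected_profile(group, subtype, tilt)
        if math.isinf(design.overdispersion):
            ps = p
        else:
            gamma = rng.gamma(design.overdispersion * p)
            total = gamma.sum()
            ps = gamma / total if total > 0 else p
        depth = int(rng.integers(lo, hi + 1))
        columns.append(rng.multinomial(depth, ps))

        lesion = None
        if group in ("NRCT", "RCT"):
            label = "LSA" if subtype == "A" else "SSA"
            if rng.random() < design.lesion_mislabel_rate:
                label = "SSA" if label == "LSA" else "LSA"
            lesion = _lesion_string(rng, label)
            if group == "NRCT":
                lesion_labels[sample_id] = label
        metadata.append(
            SampleMetadata(
                sample_id=sample_id, group=group, subject_id=subject, lesion=lesion
            )
        )

    table = OtuTable(
        feature_ids=feature_ids,
        taxonomy=taxonomy,
        sample_ids=[s for s, _, _ in layout],
        counts=np.column_stack(columns),
    )
    truth = PlantedTruth(
        down_ids=[feature_ids[i] for i in down_idx],
        up_ids=[feature_ids[i] for i in up_idx],
        subtype_ids=[feature_ids[i] for i in sub_idx],
        subtype_assignment=subtype_assignment,
        lesion_labels=lesion_labels,
    )
    return table, metadata, truth


def _draw_taxonomy(
    rng: np.random.Generator,
    n_features: int,
    down_idx: np.ndarray,
    up_idx: np.ndarray,
    sub_idx: np.ndarray,
) -> list[tuple[str, ...]]:
    """Assign lineages: planted sets draw from dedicated genus pools so
    genus-level signal survives aggregation; a few percent of background
    features carry family-truncated lineages."""
    n_regular_genera = 300
    regular = [f"Taxon{i + 1:03d}" for i in range(n_regular_genera)]
    phylum_of: dict[str, str] = {}
    for pool in (regular, _DOWN_GENERA, _UP_GENERA, _SUBTYPE_GENERA):
        for genus in pool:
            phylum_of[genus] = str(_PHYLA[rng.integers(len(_PHYLA))])

    taxonomy: list[tuple[str, ...] | None] = [None] * n_features
    for idx_set, pool in (
        (down_idx, _DOWN_GENERA),
        (up_idx, _UP_GENERA),
        (sub_idx, _SUBTYPE_GENERA),
    ):
        for i in idx_set:
            genus = pool[int(rng.integers(len(pool)))]
            taxonomy[int(i)] = _lineage(genus, phylum_of[genus])
    for i in range(n_features):
        if taxonomy[i] is None:
            genus = regular[int(rng.integers(n_regular_genera))]
            truncate = rng.random() < 0.04
            taxonomy[i] = _lineage(genus, phylum_of[genus], truncate=truncate)
    return taxonomy  # type: ignore[return-value]


def _lesion_string(rng: np.random.Generator, label: str) -> str:
    """Emit an "a×b mm" dimension string matching the LSA/SSA label, with
    the mixed ×/x delimiter and spacing styles seen in clinical tables."""
    if label == "LSA":
        a = int(rng.integers(5, 9))
        b = int(rng.integers(2, 8))
    else:
        a = int(rng.integers(2, 5))
        b = int(rng.integers(2, 5))
    if rng.random() < 0.5:
        a, b = b, a
    sep = "×" if rng.random() < 0.8 else "x"
    suffix = " mm" if rng.random() < 0.8 else "mm"
    return f"{a}{sep}{b}{suffix}"
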