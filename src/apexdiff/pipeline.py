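"""End-to-end orchestration: simulate -> diversity -> differential ->
overlap -> network -> subtype, with one root seed, flat-file outputs and a
JSON run manifest.

Every stage derives its own random substream from the root seed by hashing
the stage name, so stages can be re-run independently yet reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .differential import (
    DiffConfig,
    differential_analysis,
    records_to_dataframe,
)
from .diversity import (
    compare_groups,
    comparisons_to_dataframe,
    diversity_table,
    profiles_to_dataframe,
)
from .network import (
    adjust_pvalue_matrix,
    build_network,
    correlation_matrix,
    edges_to_dataframe,
    nodes_to_dataframe,
)
from .overlap import overlap_summary, pairwise_overlap
from .overlap import records_to_dataframe as overlap_to_dataframe
from .simulate import CohortDesign, default_design, simulate_cohort
from .subtype import (
    assignment_to_dataframe,
    concordance,
    hierarchical_subtypes,
    parse_lesion,
)
from .table import (
    TaxLevel,
    aggregate_taxa,
    prevalence_filter,
    rarefy,
    read_metadata,
    read_otu_table,
    samples_in_group,
    write_metadata,
    write_otu_table,
)

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "ALL_STAGES"]

logger = logging.getLogger("apexdiff")

ALL_STAGES = ("simulate", "diversity", "diff", "overlap", "network", "subtype")

#: Fig-1-style diversity contrasts run by the diversity stage.
DIVERSITY_CONTRASTS = (("NRCT", "HT"), ("RCT", "HT"), ("NRCT", "RCT"), ("HT", "HO"))


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the root seed."""
    ss = np.random.SeedSequence([root_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    out_dir: str
    seed: int = 0
    steps: tuple[str, ...] = ALL_STAGES
    table_path: str | None = None
    metadata_path: str | None = None
    diff: DiffConfig = field(default_factory=DiffConfig)
    network_r_min: float = 0.6
    network_alpha: float = 0.05
    network_adjust: str = "holm"
    overlap_mode: str = "pooled"
    subtype_metric: str = "braycurtis"
    subtype_linkage: str = "complete"
    subtype_k: int = 2
    subtype_n_perm: int = 100_000
    design: CohortDesign | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "diff" in raw:
            raw["diff"] = DiffConfig(**raw["diff"])
        if "design" in raw and raw["design"] is not None:
            raw["design"] = CohortDesign(**raw["design"])
        if "steps" in raw:
            raw["steps"] = tuple(raw["steps"])
        return cls(**raw)

    def validate(self) -> None:
        unknown = [s for s in self.steps if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown pipeline steps: {unknown}")
        needs_input = [s for s in self.steps if s != "simulate"]
        if needs_input and "simulate" not in self.steps:
            for name, p in (("table", self.table_path), ("metadata", self.metadata_path)):
                if p is None:
                    raise ValueError(f"{name}_path required when not simulating")
                if not Path(p).exists():
                    raise ValueError(f"{name} path does not exist: {p}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; returns the run
    manifest (also written to ``manifest.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "apexdiff",
        "version": __version__,
        "seed": config.seed,
        "steps": list(config.steps),
        "parameters": _config_dict(config),
        "stages": {},
    }

    table = metadata = truth = None
    if "simulate" in config.steps:
        logger.info("stage simulate")
        design = config.design or default_design()
        design = dataclasses.replace(design, seed=stage_seed(config.seed, "simulate"))
        table, metadata, truth = simulate_cohort(design)
        write_otu_table(table, out / "table.tsv")
        write_metadata(metadata, out / "metadata.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(
                {
                    "down_ids": truth.down_ids,
                    "up_ids": truth.up_ids,
                    "subtype_ids": truth.subtype_ids,
                    "subtype_assignment": truth.subtype_assignment,
                    "lesion_labels": truth.lesion_labels,
                },
                fh,
                indent=1,
            )
        manifest["stages"]["simulate"] = {
            "n_features": table.n_features,
            "n_samples": table.n_samples,
        }
    else:
        table = read_otu_table(config.table_path)
        metadata = read_metadata(config.metadata_path)

    min_depth = int(table.sample_depths().min())

    if "diversity" in config.steps:
        logger.info("stage diversity")
        rarefied = rarefy(table, min_depth, seed=stage_seed(config.seed, "diversity"))
        profiles = diversity_table(rarefied)
        profiles_to_dataframe(profiles).to_csv(out / "diversity.tsv", sep="\t", index=False)
        groups_present = {m.group for m in metadata}
        comparisons = []
        for a, b in DIVERSITY_CONTRASTS:
            if a in groups_present and b in groups_present:
                for metric in ("observed_otus", "chao1", "shannon", "simpson"):
                    comparisons.append(compare_groups(profiles, metadata, metric, a, b))
        comparisons_to_dataframe(comparisons).to_csv(
            out / "diversity_comparisons.tsv", sep="\t", index=False
        )
        manifest["stages"]["diversity"] = {
            "n_profiles": len(profiles),
            "n_comparisons": len(comparisons),
        }

    diff_records_otu = None
    if "diff" in config.steps:
        logger.info("stage diff")
        diff_seed = stage_seed(config.seed, "diff")
        cfg_otu = dataclasses.replace(config.diff, level="otu")
        diff_records_otu = differential_analysis(
            table, metadata, "NRCT", "HT", cfg_otu, seed=diff_seed
        )
        records_to_dataframe(diff_records_otu).to_csv(
            out / "diff_otu.tsv", sep="\t", index=False
        )
        genus_table = aggregate_taxa(table, TaxLevel.GENUS)
        cfg_gen = dataclasses.replace(config.diff, level="genus")
        diff_records_genus = differential_analysis(
            genus_table, metadata, "NRCT", "HT", cfg_gen, seed=diff_seed
        )
        records_to_dataframe(diff_records_genus).to_csv(
            out / "diff_genus.tsv", sep="\t", index=False
        )
        manifest["stages"]["diff"] = {
            "n_tested_otu": len(diff_records_otu),
            "n_significant_otu": sum(r.significant for r in diff_records_otu),
            "n_tested_genus": len(diff_records_genus),
            "n_significant_genus": sum(r.significant for r in diff_records_genus),
        }

    if "overlap" in config.steps:
        logger.info("stage overlap")
        records = pairwise_overlap(table, metadata, mode=config.overlap_mode)
        overlap_to_dataframe(records).to_csv(out / "overlap_pairs.tsv", sep="\t", index=False)
        summary, tests = overlap_summary(records)
        summary.to_csv(out / "overlap_summary.tsv", sep="\t", index=False)
        tests.to_csv(out / "overlap_tests.tsv", sep="\t", index=False)
        manifest["stages"]["overlap"] = {"n_pairs": len(records)}

    if "network" in config.steps:
        logger.info("stage network")
        if diff_records_otu is None:
            cfg_otu = dataclasses.replace(config.diff, level="otu")
            diff_records_otu = differential_analysis(
                table, metadata, "NRCT", "HT", cfg_otu,
                seed=stage_seed(config.seed, "diff"),
            )
        significant = [r for r in diff_records_otu if r.significant]
        if len(significant) >= 2:
            rarefied = rarefy(table, min_depth, seed=stage_seed(config.seed, "network"))
            ids = [r.feature_id for r in significant]
            idx = [rarefied.feature_ids.index(f) for f in ids]
            abundance = rarefied.counts[idx, :].astype(float)
            r_mat, p_mat, kept = correlation_matrix(abundance, ids)
            p_adj = adjust_pvalue_matrix(p_mat, method=config.network_adjust)
            directions = {
                r.feature_id: ("up" if r.direction == "up_in_a" else "down")
                for r in significant
            }
            net = build_network(
                r_mat, p_adj, kept,
                r_min=config.network_r_min, alpha=config.network_alpha,
                directions=directions,
            )
            edges_to_dataframe(net).to_csv(out / "network_edges.tsv", sep="\t", index=False)
            nodes_to_dataframe(net).to_csv(out / "network_nodes.tsv", sep="\t", index=False)
            manifest["stages"]["network"] = {
                "n_nodes": net.graph.number_of_nodes(),
                "n_edges": net.graph.number_of_edges(),
                "n_components": len(set(net.component_id.values())),
                "max_k_core": max(net.core_index.values(), default=0),
            }
        else:
            logger.warning("fewer than 2 significant features; skipping network")
            manifest["stages"]["network"] = {"n_nodes": 0, "n_edges": 0}

    if "subtype" in config.steps:
        logger.info("stage subtype")
        genus_table = aggregate_taxa(table, TaxLevel.GENUS)
        nrct = [s for s in samples_in_group(metadata, "NRCT") if s in table.sample_ids]
        assignment = hierarchical_subtypes(
            genus_table, nrct, k=config.subtype_k,
            metric=config.subtype_metric, method=config.subtype_linkage,
        )
        labels = {
            m.sample_id: parse_lesion(m.lesion).label
            for m in metadata
            if m.sample_id in assignment and m.lesion
        }
        df = assignment_to_dataframe(assignment, labels)
        result = None
        if set(labels) == set(assignment) and len(set(labels.values())) == 2:
            result = concordance(
                assignment, labels,
                n_perm=config.subtype_n_perm,
                seed=stage_seed(config.seed, "subtype"),
            )
            df["agreement"] = [
                ((assignment[s] == "A") == (labels[s] == "LSA")) for s in df["sample_id"]
            ]
        df.to_csv(out / "subtype.tsv", sep="\t", index=False)
        manifest["stages"]["subtype"] = {
            "n_samples": len(assignment),
            "accuracy": result.accuracy if result else None,
            "p_value": result.p_value if result else None,
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("design") is not None:
        d["design"]["depth_range"] = list(d["design"]["depth_range"])
        d["design"]["subtype_split"] = list(d["design"]["subtype_split"])
    d["steps"] = list(d["steps"])
    return d
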