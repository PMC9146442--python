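"""End-to-end pipeline: load (or simulate) cohorts, run every analysis
stage, and write TSV/JSON/GraphML artifacts plus a run manifest.

Stage order: collapse to analysis ranks -> relative abundance -> alpha
diversity, Bray-Curtis/PCoA/ANOSIM -> per-taxon rank-sum tests, the
compositional W screen, F/B ratio -> association grid (+ adjusted partial
correlations) and block CCA with Wilks' lambda -> cooccurrence networks
with the random-graph clustering null.  The manifest records every seed,
threshold, and filtering count so a rerun is fully determined.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_tables import (
    AbundanceTable,
    CohortStudy,
    collapse_taxa,
    derive_clinical,
    filter_rare,
    read_feature_table,
    read_metadata,
    to_relative,
    write_feature_table,
    write_metadata,
)
from .diversity import alpha_diversity, anosim, bray_curtis_matrix, pcoa
from .composition import ancom, fb_ratio, per_taxon_group_test
from .association import association_grid, cca
from .cooccurrence import build_network, intra_phylum_comparison, null_network_test
from .synthetic import default_spec, generate_paired_study

log = logging.getLogger("microcohort")

__all__ = ["PipelineConfig", "run_pipeline"]

#: default CCA variable groups screened against the phylum block
DEFAULT_CCA_GROUPS: dict[str, list[str]] = {
    "dietary": ["energy_kcal_d", "fiber_g_per_1000kcal", "fat_energy_pct"],
    "lifestyle": [
        "screen_weekday_h", "screen_weekend_h", "sedentary_h", "exercise_min_wk",
    ],
    "body_composition": [
        "fmi_kg_m2", "ffmi_kg_m2", "body_fat_pct", "trunk_fmi_kg_m2", "vfa_cm2",
    ],
    "metabolic": ["fpg_mg_dl", "tg_mg_dl", "hdl_c_mg_dl", "ldl_c_mg_dl", "alt_u_l"],
}

DEFAULT_ASSOCIATION_VARIABLES = [
    "age_yr", "sex", "weight_kg", "bmi_z", "waist_cm", "sbp_mmhg", "acanthosis",
    "fm_kg", "fmi_kg_m2", "ffmi_kg_m2", "body_fat_pct", "trunk_fmi_kg_m2",
    "vfa_cm2", "energy_kcal_d", "fiber_g_per_1000kcal", "fat_energy_pct",
    "screen_weekday_h", "screen_weekend_h", "sedentary_h", "exercise_min_wk",
    "tc_mg_dl", "ldl_c_mg_dl", "hdl_c_mg_dl", "tg_mg_dl", "alt_u_l",
    "fpg_mg_dl", "fi_mu_l", "homa_ir",
]


@dataclass
class PipelineConfig:
    """Everything a run needs; seeds and thresholds land in the manifest."""

    out_dir: str = "microcohort_out"
    seed: int = 0
    simulate: bool = False
    table_path: str | None = None
    metadata_path: str | None = None
    reference_table_path: str | None = None
    ranks: tuple[str, ...] = ("phylum", "genus")
    rare_threshold: float = 0.001
    alpha: float = 0.05
    fdr: float = 0.05
    spearman_permutations: int = 5000
    anosim_permutations: int = 999
    null_networks: int = 10_000
    adjust_covariates: tuple[str, ...] = ("age_yr", "sex", "bmi_kg_m2")
    association_variables: list[str] = field(
        default_factory=lambda: list(DEFAULT_ASSOCIATION_VARIABLES)
    )
    cca_groups: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CCA_GROUPS.items()}
    )
    #: which analysis stages to run
    stages: tuple[str, ...] = ("diversity", "compare", "associate", "cooccur")

    def validate(self) -> None:
        if not (0 <= self.rare_threshold < 1):
            raise ValueError("rare_threshold must be in [0, 1)")
        for name in ("alpha", "fdr"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.spearman_permutations < 1 or self.anosim_permutations < 1:
            raise ValueError("permutation counts must be >= 1")
        unknown = set(self.stages) - {"diversity", "compare", "associate", "cooccur"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.null_networks < 100:
            raise ValueError("null_networks must be >= 100")
        if not self.simulate and self.table_path is None:
            raise ValueError("need a feature table path unless simulate=True")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        cfg = cls(**payload)
        if isinstance(cfg.ranks, list):
            cfg.ranks = tuple(cfg.ranks)
        if isinstance(cfg.adjust_covariates, list):
            cfg.adjust_covariates = tuple(cfg.adjust_covariates)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapper
    return decorator


@_stage("load")
def _load_cohorts(config: PipelineConfig, out: Path, rng: np.random.Generator):
    if config.simulate:
        spec = default_spec()
        seed = int(rng.integers(0, 2**31 - 1))
        (obese, truth_o), (nonobese, truth_n) = generate_paired_study(spec, seed)
        write_feature_table(obese.table, out / "simulated_obese_counts.tsv")
        write_feature_table(nonobese.table, out / "simulated_nonobese_counts.tsv")
        if obese.metadata is not None:
            write_metadata(obese.metadata, out / "simulated_obese_metadata.tsv")
        (out / "simulated_obese_truth.json").write_text(truth_o.to_json())
        (out / "simulated_nonobese_truth.json").write_text(truth_n.to_json())
        return obese, nonobese
    table = read_feature_table(config.table_path)
    metadata = (
        read_metadata(config.metadata_path) if config.metadata_path else None
    )
    primary = CohortStudy(label="primary", table=table, metadata=metadata)
    reference = None
    if config.reference_table_path:
        reference = CohortStudy(
            label="reference", table=read_feature_table(config.reference_table_path)
        )
    return primary, reference


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest (also written to
    ``manifest.json`` in the output directory)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: v for k, v in asdict(config).items() if not isinstance(v, dict)
        },
        "stages": {},
    }

    primary, reference = _load_cohorts(config, out, rng)
    if primary.metadata is not None:
        primary = CohortStudy(
            label=primary.label,
            table=primary.table,
            metadata=derive_clinical(primary.metadata),
        )

    # --- diversity + composition per rank ---------------------------------
    if {"diversity", "compare"} & set(config.stages):
        for rank in config.ranks:
            _run_rank(config, out, rng, manifest, primary, reference, rank)

    # --- associations (genus level, primary cohort) ------------------------
    if "associate" in config.stages and primary.metadata is not None:
        _run_associations(config, out, rng, manifest, primary)

    # --- cooccurrence networks ---------------------------------------------
    if "cooccur" in config.stages:
        _run_cooccurrence(config, out, rng, manifest, primary, reference)

    checks = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file() and p.name != "manifest.json"
    }
    manifest["artifact_sha256"] = checks
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


@_stage("diversity")
def _run_rank(config, out: Path, rng, manifest, primary, reference, rank: str) -> None:
    do_diversity = "diversity" in config.stages
    do_compare = "compare" in config.stages
    collapsed = collapse_taxa(primary.table, rank)
    write_feature_table(collapsed, out / f"{rank}_counts_primary.tsv")
    info: dict = {"n_taxa_primary": collapsed.n_taxa}
    if do_diversity:
        alpha = alpha_diversity(collapsed)
        alpha.to_csv(out / f"{rank}_alpha_primary.tsv", sep="\t")

    if reference is not None:
        collapsed_ref = collapse_taxa(reference.table, rank)
        if do_diversity:
            alpha_diversity(collapsed_ref).to_csv(
                out / f"{rank}_alpha_reference.tsv", sep="\t"
            )
        # union taxon set, zero-filled, for joint beta diversity and tests
        union = sorted(set(collapsed.taxon_ids) | set(collapsed_ref.taxon_ids))
        joint = pd.concat(
            [
                collapsed.data.reindex(columns=union, fill_value=0),
                collapsed_ref.data.reindex(columns=union, fill_value=0),
            ]
        )
        lineages = {**collapsed_ref.lineages, **collapsed.lineages}
        joint_table = AbundanceTable(
            data=joint, lineages={t: lineages[t] for t in union}, mode="counts"
        )
        labels = np.array(
            [primary.label] * collapsed.n_samples
            + [reference.label] * collapsed_ref.n_samples
        )
        if do_diversity:
            dm = bray_curtis_matrix(to_relative(joint_table))
            dm.to_frame().to_csv(out / f"{rank}_braycurtis.tsv", sep="\t")
            ordination = pcoa(dm)
            ordination.coordinates.to_csv(out / f"{rank}_pcoa.tsv", sep="\t")
            anosim_seed = int(rng.integers(0, 2**31 - 1))
            res = anosim(
                dm, labels, permutations=config.anosim_permutations, seed=anosim_seed
            )
            info["anosim"] = {
                "r": res.r, "p": res.p_value, "permutations": res.permutations,
                "method": res.method, "seed": anosim_seed,
            }
        if not do_compare:
            manifest["stages"][f"rank_{rank}"] = info
            return
        rel_a = to_relative(
            AbundanceTable(
                joint.iloc[: collapsed.n_samples],
                {t: lineages[t] for t in union},
                "counts",
            )
        )
        rel_b = to_relative(
            AbundanceTable(
                joint.iloc[collapsed.n_samples:],
                {t: lineages[t] for t in union},
                "counts",
            )
        )
        tests = per_taxon_group_test(rel_a, rel_b, adjust="bh")
        tests.to_csv(out / f"{rank}_group_tests.tsv", sep="\t")
        w = ancom(joint_table, labels)
        w.table.to_csv(out / f"{rank}_ancom.tsv", sep="\t")
        info["ancom_rejected"] = int(w.table["reject"].sum())
        if rank == "phylum" and {"Firmicutes", "Bacteroidetes"} <= set(union):
            fb = fb_ratio(joint_table)
            fb.to_csv(out / "fb_ratio.tsv", sep="\t")
    manifest["stages"][f"rank_{rank}"] = info


@_stage("associations")
def _run_associations(config, out: Path, rng, manifest, primary) -> None:
    genus = filter_rare(collapse_taxa(primary.table, "genus"), config.rare_threshold)
    rel = to_relative(genus)
    variables = [
        v for v in config.association_variables if v in primary.metadata.data.columns
    ]
    grid_seed = int(rng.integers(0, 2**31 - 1))
    grid = association_grid(
        rel, primary.metadata, variables,
        b=config.spearman_permutations, fdr=config.fdr, seed=grid_seed,
    )
    grid.to_long().to_csv(out / "association_grid.tsv", sep="\t", index=False)
    covs = [
        c for c in config.adjust_covariates if c in primary.metadata.data.columns
    ]
    info = {
        "seed": grid_seed,
        "significant_cells": int(grid.significant.to_numpy().sum()),
        "tested_cells": int(np.isfinite(grid.p.to_numpy()).sum()),
    }
    if covs:
        adjusted = association_grid(
            rel, primary.metadata, [v for v in variables if v not in covs],
            b=config.spearman_permutations, fdr=config.fdr,
            adjust_for=covs, seed=grid_seed,
        )
        adjusted.to_long().to_csv(
            out / "association_grid_adjusted.tsv", sep="\t", index=False
        )
        info["adjusted_for"] = covs

    # block CCA: phylum relative abundances vs each clinical variable group
    phylum_rel = to_relative(collapse_taxa(primary.table, "phylum"))
    x = phylum_rel.data.to_numpy()
    cca_results = {}
    for group, cols in config.cca_groups.items():
        cols = [c for c in cols if c in primary.metadata.data.columns]
        if len(cols) < 1:
            continue
        y = primary.metadata.data.loc[phylum_rel.sample_ids, cols].to_numpy(float)
        ok = np.isfinite(y).all(axis=1)
        try:
            res = cca(x[ok], y[ok])
        except ValueError as exc:
            cca_results[group] = {"error": str(exc)}
            continue
        cca_results[group] = {
            "variables": cols,
            "correlations": [float(r) for r in res.correlations],
            "wilks": res.wilks.reset_index().to_dict(orient="records"),
            "n": res.n,
        }
    (out / "cca_results.json").write_text(
        json.dumps(cca_results, indent=2, sort_keys=True)
    )
    info["cca_groups"] = sorted(cca_results)
    manifest["stages"]["associations"] = info


@_stage("cooccurrence")
def _run_cooccurrence(config, out: Path, rng, manifest, primary, reference) -> None:
    info: dict = {}
    networks = {}
    for study in filter(None, (primary, reference)):
        genus = collapse_taxa(study.table, "genus")
        net = build_network(
            genus, min_mean_rel=config.rare_threshold, alpha=config.alpha
        )
        networks[study.label] = net
        net.pair_stats.to_csv(
            out / f"cooccurrence_pairs_{study.label}.tsv", sep="\t", index=False
        )
        net.to_edge_list().to_csv(
            out / f"cooccurrence_edges_{study.label}.tsv", sep="\t", index=False
        )
        nx.write_graphml(net.graph, out / f"cooccurrence_{study.label}.graphml")
        entry = {
            "genera_before_filter": genus.n_taxa,
            "genera_tested": net.n_genera_tested,
            "edges": int(net.pair_stats["retained"].sum()),
            "nodes": net.graph.number_of_nodes(),
            "clustering": net.clustering,
        }
        if net.graph.number_of_nodes() >= 3 and net.graph.number_of_edges() >= 1:
            null_seed = int(rng.integers(0, 2**31 - 1))
            null = null_network_test(net, r=config.null_networks, seed=null_seed)
            (out / f"cooccurrence_null_{study.label}.json").write_text(
                json.dumps(null.summary(), indent=2)
            )
            entry["null_p"] = null.p_value
            entry["null_seed"] = null_seed
        info[study.label] = entry

    if len(networks) == 2:
        labels = list(networks)
        for phylum in ("Firmicutes", "Bacteroidetes"):
            try:
                stat, p = intra_phylum_comparison(
                    networks[labels[0]], networks[labels[1]], phylum
                )
            except ValueError:
                continue
            info[f"intra_phylum_{phylum}"] = {"statistic": stat, "p": p}
    manifest["stages"]["cooccurrence"] = info
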