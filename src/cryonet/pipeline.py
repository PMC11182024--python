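"""Config-driven orchestration of the full microcosm analysis.

``run_pipeline`` executes, in order: table preparation -> diversity /
ordination / factorial PERMANOVA -> NST community assembly -> co-occurrence
network (modules, Zi-Pi, robustness, connectedness, P/N, per-treatment
subnetworks) -> soil quality index, treatment contrast and random-forest
feature importance. Every artifact is written to the output directory as a
tab-separated table or JSON document and listed, with a SHA-256 digest, in
``manifest.json``; identical config + seed reproduces byte-identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import assembly, community, network, soilquality, tables
from .synthetic import (
    DEFAULT_RR_EFFECTS,
    CommunityParams,
    DesignSpec,
    generate_community,
    generate_design,
    generate_soil_properties,
    module_mediator,
)

__all__ = ["ConfigError", "PipelineConfig", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid pipeline configuration (maps to CLI exit code 2)."""


@dataclass
class PipelineConfig:
    """All knobs of a run; defaults are the emulated study's printed thresholds."""

    outdir: Path = Path("cryonet_run")
    seed: int = 0
    synthetic: bool = True
    # input paths (required when synthetic=False)
    asv_table: Path | None = None
    metadata: Path | None = None
    soil_table: Path | None = None
    trait_map: Path | None = None
    # synthetic generator knobs
    design: DesignSpec = field(default_factory=DesignSpec)
    community_params: CommunityParams = field(default_factory=CommunityParams)
    soil_noise_sd: float = 0.12
    # preprocessing / network thresholds
    rarefaction_depth: int | None = None
    prevalence: float = 0.5
    r_min: float = 0.6
    p_max: float = 0.01
    zi_threshold: float = 2.5
    pi_threshold: float = 0.625
    # tests / null models
    n_perm: int = 999
    nst_draws: int = 1000
    nst_group_by: str = "residue"  # or "cell" for residue x ft x cycle cells
    robustness_fraction: float = 0.5
    robustness_trials: int = 100
    # random forest
    n_trees: int = 1000
    rf_null: int = 50

    def validate(self) -> None:
        if not 0 <= self.prevalence < 1:
            raise ConfigError("prevalence must lie in [0, 1)")
        if not 0 < self.r_min <= 1:
            raise ConfigError("r_min must lie in (0, 1]")
        if not 0 < self.p_max <= 1:
            raise ConfigError("p_max must lie in (0, 1]")
        if not 0 < self.robustness_fraction < 1:
            raise ConfigError("robustness_fraction must lie in (0, 1)")
        if self.nst_group_by not in {"residue", "cell"}:
            raise ConfigError("nst_group_by must be 'residue' or 'cell'")
        if not self.synthetic:
            for name in ("asv_table", "metadata", "soil_table"):
                path = getattr(self, name)
                if path is None:
                    raise ConfigError(f"{name} is required when synthetic=False")
                if not Path(path).exists():
                    raise ConfigError(f"{name} not found: {path}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "design" in doc and isinstance(doc["design"], dict):
            doc["design"] = DesignSpec(**doc["design"])
        if "community_params" in doc and isinstance(doc["community_params"], dict):
            doc["community_params"] = CommunityParams(**doc["community_params"])
        return cls(**doc)


def _write_json(doc, path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True, default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.synthetic:
        design = generate_design(config.design)
        table, truth = generate_community(design, config.community_params, config.seed)
        soil = generate_soil_properties(
            design,
            noise_sd=config.soil_noise_sd,
            seed=config.seed + 1,
            mediator=module_mediator(table, truth, design),
        )
        truth = dataclasses.replace(truth, true_effects=dict(DEFAULT_RR_EFFECTS))
        tables.write_sample_table(design, outdir / "metadata.tsv")
        tables.write_asv_table(table, outdir / "asv_table.tsv")
        tables.write_sample_table(soil.round(10), outdir / "soil_properties.tsv")
        truth.to_json(outdir / "ground_truth.json")
        return table, design, soil, truth
    table = tables.read_asv_table(config.asv_table)
    design = tables.read_sample_table(config.metadata)
    soil = tables.read_sample_table(config.soil_table)
    return table, design.loc[table.index], soil.loc[table.index], None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run report (also written as manifest.json)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"seed": config.seed, "stages": [], "outputs": {}}

    def record(name: str, path: Path):
        report["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    table, design, soil, truth = _load_inputs(config, outdir)
    if config.rarefaction_depth is not None:
        table = tables.rarefy(table, config.rarefaction_depth, seed=config.seed)
        design = design.loc[table.index]
        soil = soil.loc[table.index]
    report["n_samples"], report["n_taxa"] = map(int, table.shape)
    report["stages"].append("tables")

    # --- diversity / ordination / factorial permutation tests -------------
    rich = community.richness(table)
    rich.to_frame().to_csv(outdir / "richness.tsv", sep="\t", float_format="%.10g")
    dist = community.bray_curtis(table)
    community.write_distance_matrix(dist.round(12), outdir / "braycurtis.tsv")
    ordination = community.pcoa(dist, n_axes=4)
    ordination.coordinates.round(12).to_csv(outdir / "pcoa_coordinates.tsv", sep="\t")
    terms = [c for c in ("residue", "ft_intensity", "cycle") if c in design.columns]
    perm = community.permanova_factorial(
        dist, design, terms, n_perm=config.n_perm, seed=config.seed
    )
    perm.round(10).to_csv(outdir / "permanova.tsv", sep="\t")
    for name in ("richness.tsv", "braycurtis.tsv", "pcoa_coordinates.tsv", "permanova.tsv"):
        record(name.split(".")[0], outdir / name)
    report["stages"].append("community")

    # --- community assembly (NST) -----------------------------------------
    if config.nst_group_by == "residue":
        grouping = design["residue"].astype(str)
    else:
        grouping = (
            design["residue"].astype(str)
            + "_" + design["ft_intensity"].astype(str)
            + "_C" + design["cycle"].astype(str)
        )
    spec = assembly.NullModelSpec(n_draws=config.nst_draws, seed=config.seed)
    nst_results = assembly.pairwise_nst(table, grouping, spec)
    nst_summary = {}
    for label, result in sorted(nst_results.items()):
        path = outdir / f"nst_pairwise_{label}.tsv"
        result.to_files(path)
        record(f"nst_pairwise_{label}", path)
        nst_summary[label] = {
            "group_nst_percent": result.group_nst,
            "n_pairs": int(result.pairwise.shape[0]),
        }
    labels = sorted(nst_results)
    if len(labels) == 2:
        contrast = assembly.nst_compare(nst_results[labels[0]], nst_results[labels[1]])
        nst_summary["comparison"] = {
            "groups": labels,
            "t_statistic": contrast.statistic,
            "p_value": contrast.p_value,
        }
    nst_summary["null_spec"] = dataclasses.asdict(spec)
    _write_json(nst_summary, outdir / "nst_summary.json")
    record("nst_summary", outdir / "nst_summary.json")
    report["stages"].append("assembly")

    # --- co-occurrence network --------------------------------------------
    filtered = tables.prevalence_filter(table, config.prevalence)
    graph = network.build_cooccurrence_network(filtered, r_min=config.r_min, p_max=config.p_max)
    network.write_edge_list(graph, outdir / "network_edges.tsv")
    partition = network.detect_modules(graph, seed=config.seed)
    partition.to_frame().to_csv(outdir / "modules.tsv", sep="\t", index=False)
    topology = network.zipi(
        graph, partition, zi_threshold=config.zi_threshold, pi_threshold=config.pi_threshold
    )
    topology.round(10).to_csv(outdir / "node_topology.tsv", sep="\t")

    def graph_metrics(g, seed_offset=0):
        ratio = network.pn_ratio(g)
        return {
            "nodes": g.number_of_nodes(),
            "edges": g.number_of_edges(),
            "positive_edges": ratio.n_positive,
            "negative_edges": ratio.n_negative,
            "pn_ratio": ratio.ratio if ratio.defined else None,
            "connectedness": network.connectedness(g) if g.number_of_nodes() > 1 else None,
            "robustness": (
                network.robustness(
                    g,
                    removal_fraction=config.robustness_fraction,
                    trials=config.robustness_trials,
                    seed=config.seed + seed_offset,
                )
                if g.number_of_nodes() > 1
                else None
            ),
        }

    metrics = {"full": graph_metrics(graph), "modularity": partition.modularity}
    treatment_rows = {}
    for offset, level in enumerate(sorted(design["residue"].astype(str).unique()), start=1):
        subset = design.index[design["residue"] == level]
        sub = network.subnetwork(graph, table, subset)
        metrics[level] = graph_metrics(sub, seed_offset=offset)
        treatment_rows[level] = {
            "pn_ratio": metrics[level]["pn_ratio"],
            "robustness": metrics[level]["robustness"],
            "connectedness": metrics[level]["connectedness"],
        }
    _write_json(metrics, outdir / "network_metrics.json")
    top_modules = [m for m, size in sorted(partition.sizes.items()) if size >= 3][:4]
    if not top_modules:
        top_modules = [1]
    module_z = network.module_abundance(table, partition, modules=top_modules)
    module_z.round(10).to_csv(outdir / "module_abundance_z.tsv", sep="\t")
    for name in ("network_edges.tsv", "modules.tsv", "node_topology.tsv",
                 "network_metrics.json", "module_abundance_z.tsv"):
        record(name.split(".")[0], outdir / name)
    report["stages"].append("network")

    # --- soil quality and feature importance ------------------------------
    quality = soilquality.quality_index(soil)
    quality.index.round(12).to_frame().to_csv(outdir / "quality_index.tsv", sep="\t")
    contrast = soilquality.group_compare(quality.index, design["residue"])
    quality_doc = {
        "variables": list(quality.variables),
        "mean_by_residue": {
            level: float(quality.index[design["residue"] == level].mean())
            for level in sorted(design["residue"].astype(str).unique())
        },
        "t_statistic": contrast.statistic,
        "p_value": contrast.p_value,
    }
    _write_json(quality_doc, outdir / "quality_summary.json")

    treatment_metrics = pd.DataFrame(treatment_rows).T.astype(float)
    for col, fallback in (
        ("pn_ratio", metrics["full"]["pn_ratio"]),
        ("robustness", metrics["full"]["robustness"]),
        ("connectedness", metrics["full"]["connectedness"]),
    ):
        treatment_metrics[col] = treatment_metrics[col].fillna(
            fallback if fallback is not None else 0.0
        )
    features = soilquality.feature_matrix(
        design,
        richness={"community": rich},
        module_z=module_z.fillna(0.0),
        treatment_metrics=treatment_metrics,
    )
    features.round(12).to_csv(outdir / "feature_matrix.tsv", sep="\t")
    rf = soilquality.importance(
        features, quality.index, n_trees=config.n_trees, seed=config.seed, n_null=config.rf_null
    )
    rf.table.round(10).to_csv(outdir / "importance.tsv", sep="\t")
    _write_json(
        {
            "variance_explained": rf.variance_explained,
            "n_trees": rf.n_trees,
            "n_null": rf.n_null,
            "top_feature": rf.table.index[0],
        },
        outdir / "rf_summary.json",
    )
    for name in ("quality_index.tsv", "quality_summary.json", "feature_matrix.tsv",
                 "importance.tsv", "rf_summary.json"):
        record(name.split(".")[0], outdir / name)
    report["stages"].append("soilquality")

    if truth is not None:
        record("ground_truth", outdir / "ground_truth.json")
    report["config"] = {
        k: v
        for k, v in dataclasses.asdict(config).items()
        if not isinstance(v, dict)
    }
    report["exit_code"] = 0
    _write_json(report, outdir / "manifest.json")
    return report
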