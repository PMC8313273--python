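"""End-to-end orchestration of the two study designs.

``run_cycle_analysis`` reproduces the heat-cycle workflow: diversity-regime
filtering, alpha/beta diversity, PCoA, multi-factor PERMANOVA, then per-stage
network-regime filtering, SparCC, thresholded network, topology statistics and
MCODE modules, plus stage-enriched features by the LDA effect-size screen.

``run_puberty_analysis`` reproduces the failed-puberty workflow: network-regime
filtering, SparCC, CAG construction + permutational validation + Wilcoxon
group comparison, LDA effect-size screening at OTU/genus/family levels, and
(optionally) pathway-taxon Spearman correlation.

Every stage draws its seed from the master seed by a fixed counter scheme
(seed_k = (master * 1000 + k) mod 2^31) so stages can be rerun in isolation;
all numeric tables are written with a fixed float format, so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cag import (build_cags, compare_cag_groups, validate_cags,
                  write_cag_abundance, write_cag_assignment)
from .differential import lda_effect_size, spearman_correlation
from .diversity import alpha_diversity, bray_curtis, pcoa, permanova, unweighted_unifrac
from .network import (build_network, mcode, topology, write_edgelist,
                      write_graphml, write_modules)
from .simulate import SimulationConfig, simulate_dataset
from .sparcc import sparcc_correlations, write_correlation_matrix
from .tables_io import (aggregate_taxonomy, filter_otus, read_metadata,
                        read_otu_table, read_taxonomy, read_tree,
                        relative_abundance, write_metadata, write_otu_table,
                        write_taxonomy, write_tree)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Flat configuration for the pipeline; loadable from YAML."""

    # inputs (paths); all None => simulate with `simulation`
    otu_table: str | None = None
    metadata: str | None = None
    tree: str | None = None
    taxonomy: str | None = None
    pathways: str | None = None
    simulation: SimulationConfig | None = None

    output_dir: str = "gutlinks_output"
    rarefaction_depth: int | None = None      # None = input already rarefied

    # the two filter regimes (fractions)
    diversity_min_abund: float = 0.0001       # 0.01 %
    diversity_min_prevalence: float = 0.10
    network_min_abund: float = 0.0005         # 0.05 %
    network_min_prevalence: float = 0.20

    network_threshold: float = 0.65
    sparcc_resamples: int = 20
    sparcc_exclusion_threshold: float = 0.1

    cag_corr_threshold: float = 0.5
    cag_n_cags: int | str = "auto"
    cag_max_auto: int = 40
    cag_permutations: int = 999

    lda_alpha: float = 0.05
    lda_threshold: float = 2.0
    lda_boots: int = 30

    permanova_permutations: int = 999
    permanova_factors: tuple = ("batch", "stage", "farm", "genetics")
    stage_column: str = "stage"
    group_column: str = "group"

    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def stage_seed(self, k: int) -> int:
        return (self.seed * 1000 + k) % (2 ** 31)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)   # hash identifies the analysis, not its location
        blob = json.dumps(payload, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class _Manifest:
    def __init__(self, config: PipelineConfig, outdir: Path, analysis: str):
        self.data = {
            "analysis": analysis,
            "tool_version": __version__,
            "config_hash": config.config_hash(),
            "master_seed": config.seed,
            "stage_seeds": {},
            "outputs": [],
            "notes": [],
        }
        self.outdir = outdir

    def add(self, path: Path) -> None:
        self.data["outputs"].append(str(path.relative_to(self.outdir)))

    def note(self, msg: str) -> None:
        self.data["notes"].append(msg)
        logger.info(msg)

    def seed(self, name: str, value: int) -> None:
        self.data["stage_seeds"][name] = value

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
        return path


def _load_inputs(config: PipelineConfig, outdir: Path, manifest: _Manifest):
    if config.otu_table is not None:
        table = read_otu_table(config.otu_table)
        meta = read_metadata(config.metadata) if config.metadata else None
        tree = read_tree(config.tree) if config.tree else None
        tax = read_taxonomy(config.taxonomy) if config.taxonomy else None
        manifest.note(f"loaded OTU table {config.otu_table}: "
                      f"{table.n_samples} samples x {table.n_otus} OTUs")
    else:
        sim = config.simulation or SimulationConfig(seed=config.stage_seed(1))
        table, meta, tree, tax, _ = simulate_dataset(sim)
        manifest.seed("simulate", sim.seed)
        manifest.note(f"simulated dataset: {table.n_samples} samples x "
                      f"{table.n_otus} OTUs at depth {sim.depth}")
        simdir = outdir / "inputs"
        simdir.mkdir(exist_ok=True)
        write_otu_table(table, simdir / "otu_table.tsv")
        write_metadata(meta, simdir / "metadata.tsv")
        write_tree(tree, simdir / "tree.nwk")
        write_taxonomy(tax, simdir / "taxonomy.tsv")
        for f in ("otu_table.tsv", "metadata.tsv", "tree.nwk", "taxonomy.tsv"):
            manifest.add(simdir / f)
    if config.rarefaction_depth:
        from .tables_io import rarefy
        before = table.n_samples
        table = rarefy(table, config.rarefaction_depth,
                       seed=config.stage_seed(2))
        manifest.seed("rarefy", config.stage_seed(2))
        manifest.note(f"rarefied to {config.rarefaction_depth}; kept "
                      f"{table.n_samples}/{before} samples")
    return table, meta, tree, tax


def _write_df(df: pd.DataFrame, path: Path, manifest: _Manifest,
              index_name: str | None = None) -> None:
    out = df.copy()
    if index_name:
        out.index.name = index_name
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)
    manifest.add(path)


def _diversity_block(table, meta, tree, config, outdir, manifest):
    div_table = filter_otus(table, config.diversity_min_abund,
                            config.diversity_min_prevalence)
    manifest.note(f"diversity filter kept {div_table.n_otus}/{table.n_otus} OTUs")
    alpha = alpha_diversity(div_table, tree=tree)
    _write_df(alpha, outdir / "alpha_diversity.tsv", manifest, "sample_id")
    if tree is not None:
        dist = unweighted_unifrac(div_table, tree)
        beta_name = "unweighted_unifrac"
    else:
        dist = bray_curtis(div_table)
        beta_name = "bray_curtis"
        manifest.note("no tree supplied; beta diversity fell back to Bray-Curtis")
    _write_df(dist.to_data_frame(), outdir / f"beta_{beta_name}.tsv",
              manifest, "sample_id")
    ord_res = pcoa(dist, n_axes=min(10, len(dist.ids) - 1))
    _write_df(ord_res.coordinates, outdir / "pcoa_coordinates.tsv",
              manifest, "sample_id")
    eig = pd.DataFrame({
        "eigenvalue": ord_res.eigenvalues[: len(ord_res.proportion_explained)],
        "proportion_explained": ord_res.proportion_explained,
    }, index=[f"PCo{k+1}" for k in range(len(ord_res.proportion_explained))])
    _write_df(eig, outdir / "pcoa_eigenvalues.tsv", manifest, "axis")
    if meta is not None:
        factors = [f for f in config.permanova_factors
                   if f in meta.columns and meta.loc[list(dist.ids), f].nunique() > 1]
        if factors:
            perma = permanova(dist, meta, factors,
                              n_perm=config.permanova_permutations,
                              seed=config.stage_seed(3))
            manifest.seed("permanova", config.stage_seed(3))
            _write_df(perma, outdir / "permanova.tsv", manifest, "factor")
        else:
            manifest.note("no usable PERMANOVA factors in metadata")
    return div_table


def run_cycle_analysis(config: PipelineConfig) -> dict:
    """Per-stage networks + modules, diversity, PERMANOVA, stage biomarkers."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config, outdir, "cycle")
    table, meta, tree, tax = _load_inputs(config, outdir, manifest)
    if meta is None or config.stage_column not in meta.columns:
        raise ValueError("cycle analysis requires stage labels in metadata")
    stages = meta.loc[meta.index.intersection(table.sample_ids),
                      config.stage_column].dropna()
    missing = [s for s in table.sample_ids if s not in stages.index]
    if missing:
        raise ValueError(f"samples without stage labels: {missing}")
    levels = sorted(stages.unique())
    if len(levels) < 2:
        raise ValueError(f"need >= 2 stages, got {levels}")

    _diversity_block(table, meta, tree, config, outdir, manifest)

    topo_rows = {}
    for k, stage in enumerate(levels):
        sub = table.subset_samples(stages.index[stages == stage])
        net_table = filter_otus(sub, config.network_min_abund,
                                config.network_min_prevalence)
        manifest.note(f"stage {stage}: network filter kept "
                      f"{net_table.n_otus}/{sub.n_otus} OTUs over {sub.n_samples} samples")
        seed = config.stage_seed(10 + k)
        manifest.seed(f"sparcc_{stage}", seed)
        corr = sparcc_correlations(
            net_table, n_fraction_resamples=config.sparcc_resamples,
            exclusion_threshold=config.sparcc_exclusion_threshold, seed=seed)
        write_correlation_matrix(corr, outdir / f"sparcc_{stage}.tsv")
        manifest.add(outdir / f"sparcc_{stage}.tsv")
        mean_ab = relative_abundance(net_table).df.mean(axis=0)
        net = build_network(corr, threshold=config.network_threshold,
                            node_abundance=mean_ab)
        write_edgelist(net, outdir / f"network_{stage}_edges.tsv")
        manifest.add(outdir / f"network_{stage}_edges.tsv")
        write_graphml(net, outdir / f"network_{stage}.graphml")
        manifest.add(outdir / f"network_{stage}.graphml")
        topo_rows[stage] = dataclasses.asdict(topology(net))
        modules = mcode(net)
        write_modules(modules, outdir / f"modules_{stage}.tsv")
        manifest.add(outdir / f"modules_{stage}.tsv")
    _write_df(pd.DataFrame.from_dict(topo_rows, orient="index"),
              outdir / "topology_by_stage.tsv", manifest, "stage")

    # stage-enriched features at the OTU level
    div_table = filter_otus(table, config.diversity_min_abund,
                            config.diversity_min_prevalence)
    rel = relative_abundance(div_table)
    lefse = lda_effect_size(rel, stages.loc[div_table.sample_ids],
                            alpha=config.lda_alpha,
                            lda_threshold=config.lda_threshold,
                            n_boot=config.lda_boots,
                            seed=config.stage_seed(20))
    manifest.seed("lefse_stage", config.stage_seed(20))
    _write_df(lefse, outdir / "stage_effect_sizes.tsv", manifest)

    path = manifest.write()
    logger.info("cycle analysis complete; manifest at %s", path)
    return manifest.data


def run_puberty_analysis(config: PipelineConfig) -> dict:
    """CAGs + validation + NA/NO comparison, biomarkers, pathway correlation."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config, outdir, "puberty")
    table, meta, tree, tax = _load_inputs(config, outdir, manifest)
    if meta is None or config.group_column not in meta.columns:
        raise ValueError("puberty analysis requires a group column in metadata")
    groups = meta.loc[meta.index.intersection(table.sample_ids),
                      config.group_column].dropna()
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"group factor must have two levels, got {levels}")

    net_table = filter_otus(table, config.network_min_abund,
                            config.network_min_prevalence)
    manifest.note(f"network filter kept {net_table.n_otus}/{table.n_otus} OTUs")
    seed = config.stage_seed(30)
    manifest.seed("sparcc", seed)
    corr = sparcc_correlations(
        net_table, n_fraction_resamples=config.sparcc_resamples,
        exclusion_threshold=config.sparcc_exclusion_threshold, seed=seed)
    write_correlation_matrix(corr, outdir / "sparcc.tsv")
    manifest.add(outdir / "sparcc.tsv")

    cag_seed = config.stage_seed(31)
    manifest.seed("cag_validation", cag_seed)
    cags = build_cags(net_table, corr,
                      corr_keep_threshold=config.cag_corr_threshold,
                      n_cags=config.cag_n_cags, max_auto_cags=config.cag_max_auto,
                      n_perm=config.cag_permutations, seed=cag_seed)
    if not cags.pvalues:
        cags = validate_cags(cags, net_table, n_perm=config.cag_permutations,
                             seed=cag_seed)
    manifest.note(f"built {cags.n_cags} CAGs over {len(cags.assignment)} OTUs")
    write_cag_assignment(cags, outdir / "cag_assignment.tsv")
    manifest.add(outdir / "cag_assignment.tsv")
    write_cag_abundance(cags, outdir / "cag_abundance.tsv")
    manifest.add(outdir / "cag_abundance.tsv")
    comparison = compare_cag_groups(cags, meta, group_factor=config.group_column)
    _write_df(comparison, outdir / "cag_group_comparison.tsv", manifest)

    # LDA effect-size screening at OTU / genus / family levels
    div_table = filter_otus(table, config.diversity_min_abund,
                            config.diversity_min_prevalence)
    rel = relative_abundance(div_table)
    tables = {"otu": rel}
    if tax is not None:
        tables["genus"] = aggregate_taxonomy(rel, tax, "genus")
        tables["family"] = aggregate_taxonomy(rel, tax, "family")
    else:
        manifest.note("no taxonomy supplied; genus/family screens skipped")
    for k, (rank, feat) in enumerate(tables.items()):
        lefse = lda_effect_size(feat, groups.loc[div_table.sample_ids],
                                alpha=config.lda_alpha,
                                lda_threshold=config.lda_threshold,
                                n_boot=config.lda_boots,
                                seed=config.stage_seed(40 + k))
        manifest.seed(f"lefse_{rank}", config.stage_seed(40 + k))
        _write_df(lefse, outdir / f"effect_sizes_{rank}.tsv", manifest)

    if config.pathways is not None:
        pw = pd.read_csv(config.pathways, sep="\t", index_col=0)
        pw.index = pw.index.astype(str)
        corr_table = spearman_correlation(pw, rel.df)
        corr_table.to_csv(outdir / "pathway_correlations.tsv", sep="\t",
                          index=False, float_format=FLOAT_FMT)
        manifest.add(outdir / "pathway_correlations.tsv")
    else:
        manifest.note("no pathway table supplied; correlation stage skipped")

    path = manifest.write()
    logger.info("puberty analysis complete; manifest at %s", path)
    return manifest.data
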