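"""Synthetic OTU-table generator with planted structure and ground truth.

Emulates a gilt gut-microbiota study layout: samples arranged in oestrus-stage
(E1..E4) by group (NA = normal cycle, NO = no oestrus) cells, compositional
counts at a fixed sequencing depth, blocks of co-varying OTUs (for correlation
and co-abundance-group recovery), stage-periodic taxa, group-differential taxa,
a random coalescent phylogeny and a nested-clade taxonomy.

The generative model per sample s and OTU j:

1. latent log abundance  y[s,j] = b[j] + latent_sd * e[s,j] + stage + group
   where b[j] ~ N(0, base_logmean_sd) is a fixed baseline, e is unit-variance
   noise that is equi-correlated at ``block_correlation`` inside each planted
   block and independent elsewhere, the stage term is a one-period sinusoid
   over the four ordered stages and the group term is ±group_log2fc·ln 2 for
   NO samples on the planted group OTUs;
2. composition p[s] = softmax(y[s]);
3. counts ~ Dirichlet-multinomial at ``depth`` with Dirichlet concentration
   c = (1 - overdispersion)/overdispersion (plain multinomial when
   overdispersion = 0), so every row sums to ``depth`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster
from skbio import TreeNode

from .tables_io import RANKS, AbundanceTable, OtuTable

STAGES = ("E1", "E2", "E3", "E4")
GROUPS = ("NA", "NO")


@dataclass
class SimulationConfig:
    """Study-design parameters for :func:`simulate_dataset`.

    Defaults follow the emulated study scale: 22 samples per stage cell,
    rarefied depth 34,949 reads, a few hundred OTUs of which small planted
    subsets carry block, stage or group structure.
    """

    n_samples_per_cell: int = 22          # per stage x group cell
    n_otus: int = 300
    depth: int = 34949                    # reads per sample
    n_blocks: int = 3
    block_size: int = 8
    block_correlation: float = 0.8
    n_stage_otus: int = 10                # taxa with stage-periodic abundance
    stage_amplitude: float = 1.0          # ln-scale sinusoid amplitude
    n_group_otus: int = 10                # NA/NO differential taxa
    group_log2fc: float = 1.0
    base_logmean_sd: float = 1.5          # spread of fixed baselines (ln units)
    latent_sd: float = 2.0                # per-sample latent fluctuation (ln units)
    overdispersion: float = 1e-4          # residual technical DM theta; 0 = multinomial
    group_effect_block: int | None = None  # block that is also depleted in NO gilts
    seed: int = 0

    def validate(self) -> None:
        planted = self.n_blocks * self.block_size + self.n_stage_otus + self.n_group_otus
        if planted > self.n_otus:
            raise ValueError(
                f"planted OTUs ({planted}) exceed n_otus ({self.n_otus})")
        for name in ("n_samples_per_cell", "n_otus", "depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.block_correlation < 1:
            raise ValueError("block_correlation must be in (0, 1)")
        if not 0 <= self.overdispersion < 1:
            raise ValueError("overdispersion must be in [0, 1)")
        if self.latent_sd <= 0 or self.base_logmean_sd < 0:
            raise ValueError("scales must be positive")
        if self.group_effect_block is not None and not (
                0 <= self.group_effect_block < self.n_blocks):
            raise ValueError("group_effect_block must index an existing block")


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset."""

    block_membership: dict        # otu_id -> block index (absent = no block)
    stage_otus: dict              # otu_id -> phase (radians)
    group_otus: dict              # otu_id -> +1 (up in NO) / -1 (down in NO)
    true_correlations: pd.DataFrame  # latent basis correlation matrix


def _sample_layout(config: SimulationConfig):
    sample_ids, stage_col, group_col, batch, farm, genet, animal = [], [], [], [], [], [], []
    i = 0
    for g in GROUPS:
        for a in range(config.n_samples_per_cell):
            for s_idx, s in enumerate(STAGES):
                sample_ids.append(f"S{i:04d}")
                stage_col.append(s)
                group_col.append(g)
                batch.append(f"B{(a + s_idx) % 3 + 1}")
                farm.append(f"F{a % 2 + 1}")
                genet.append(f"L{(a // 2) % 2 + 1}")
                animal.append(f"{g}_A{a:03d}")
                i += 1
    meta = pd.DataFrame(
        {"stage": stage_col, "group": group_col, "batch": batch,
         "farm": farm, "genetics": genet, "animal_id": animal},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return meta


def _coalescent_tree(otu_ids, rng):
    """Random coalescent over the OTUs; returns (TreeNode, linkage matrix)."""
    n = len(otu_ids)
    nodes = [TreeNode(name=o) for o in otu_ids]
    heights = [0.0] * n
    active = list(range(n))          # indices into the linkage numbering
    node_of = {i: nodes[i] for i in range(n)}
    height_of = {i: 0.0 for i in range(n)}
    linkage = []
    t = 0.0
    next_id = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        a, b = rng.choice(k, size=2, replace=False)
        ia, ib = active[a], active[b]
        ca, cb = node_of.pop(ia), node_of.pop(ib)
        ca.length = t - height_of.pop(ia)
        cb.length = t - height_of.pop(ib)
        parent = TreeNode(children=[ca, cb])
        node_of[next_id] = parent
        height_of[next_id] = t
        size = _linkage_size(linkage, ia, n) + _linkage_size(linkage, ib, n)
        linkage.append([ia, ib, t, size])
        active = [x for x in active if x not in (ia, ib)] + [next_id]
        next_id += 1
    root = node_of[active[0]]
    root.length = None
    return root, np.asarray(linkage, dtype=float)


def _linkage_size(linkage, idx, n):
    return 1 if idx < n else int(linkage[idx - n][3])


def _taxonomy_from_tree(otu_ids, linkage, rng) -> pd.DataFrame:
    """Assign nested monophyletic labels by cutting the coalescent history."""
    n = len(otu_ids)
    targets = {
        "phylum": max(2, n // 60),
        "class": max(3, n // 40),
        "order": max(4, n // 25),
        "family": max(5, n // 15),
        "genus": max(6, n // 6),
    }
    tax = pd.DataFrame("", index=pd.Index(otu_ids, name="otu_id"),
                       columns=list(RANKS))
    tax["kingdom"] = "Bacteria"
    prefix = {"phylum": "p", "class": "c", "order": "o", "family": "f", "genus": "g"}
    for rank, k in targets.items():
        labels = fcluster(linkage, t=min(k, n), criterion="maxclust")
        tax[rank] = [f"{prefix[rank]}{lab}" for lab in labels]
    tax["species"] = [f"s_{o}" for o in otu_ids]
    return tax


def simulate_dataset(config: SimulationConfig):
    """Generate (OtuTable, metadata, tree, taxonomy, GroundTruth).

    Deterministic for a given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta = _sample_layout(config)
    n_samples = len(meta)
    m = config.n_otus
    otu_ids = [f"OTU{j:04d}" for j in range(m)]

    # planted roles
    block_of = {}
    pos = 0
    for b in range(config.n_blocks):
        for _ in range(config.block_size):
            block_of[otu_ids[pos]] = b
            pos += 1
    stage_otus = {otu_ids[pos + j]: rng.uniform(0, 2 * np.pi)
                  for j in range(config.n_stage_otus)}
    pos += config.n_stage_otus
    group_otus = {otu_ids[pos + j]: (1 if j % 2 == 0 else -1)
                  for j in range(config.n_group_otus)}

    baseline = rng.normal(0.0, config.base_logmean_sd, size=m)
    # Planted taxa take upper-half baselines so the planted structure is
    # observable at the configured depth (rare taxa carry no usable signal
    # and would be removed by the standard abundance filters anyway).
    n_planted = (config.n_blocks * config.block_size
                 + config.n_stage_otus + config.n_group_otus)
    baseline[:n_planted] = np.abs(baseline[:n_planted])

    # unit-variance latent noise, equi-correlated within blocks
    e = rng.standard_normal((n_samples, m))
    rho = config.block_correlation
    for b in range(config.n_blocks):
        members = [j for j, o in enumerate(otu_ids) if block_of.get(o) == b]
        f = rng.standard_normal(n_samples)
        e[:, members] = (np.sqrt(rho) * f[:, None]
                         + np.sqrt(1 - rho) * e[:, members])

    y = baseline[None, :] + config.latent_sd * e

    stage_idx = meta["stage"].map({s: i for i, s in enumerate(STAGES)}).to_numpy()
    for o, phase in stage_otus.items():
        j = otu_ids.index(o)
        y[:, j] += config.stage_amplitude * np.sin(
            2 * np.pi * stage_idx / len(STAGES) + phase)

    is_no = (meta["group"] == "NO").to_numpy()
    for o, sign in group_otus.items():
        j = otu_ids.index(o)
        y[is_no, j] += sign * config.group_log2fc * np.log(2)
    if config.group_effect_block is not None:
        for j, o in enumerate(otu_ids):
            if block_of.get(o) == config.group_effect_block:
                y[is_no, j] -= config.group_log2fc * np.log(2)
                group_otus[o] = -1

    # composition and Dirichlet-multinomial counts
    p = np.exp(y - y.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    counts = np.empty((n_samples, m), dtype=np.int64)
    theta = config.overdispersion
    for s in range(n_samples):
        q = p[s]
        if theta > 0:
            conc = (1.0 - theta) / theta
            q = rng.dirichlet(np.maximum(q * conc, 1e-12))
        counts[s] = rng.multinomial(config.depth, q)

    table = OtuTable(pd.DataFrame(counts, index=meta.index.copy(),
                                  columns=otu_ids))
    tree, linkage = _coalescent_tree(otu_ids, rng)
    tax = _taxonomy_from_tree(otu_ids, linkage, rng)

    true_corr = np.eye(m)
    for b in range(config.n_blocks):
        members = [j for j, o in enumerate(otu_ids) if block_of.get(o) == b]
        for a in members:
            for c in members:
                if a != c:
                    true_corr[a, c] = rho
    truth = GroundTruth(
        block_membership=dict(block_of),
        stage_otus=dict(stage_otus),
        group_otus=dict(group_otus),
        true_correlations=pd.DataFrame(true_corr, index=otu_ids, columns=otu_ids),
    )
    return table, meta, tree, tax, truth


def simulate_pathway_table(otu_table: OtuTable, linked_otus, weights,
                           noise_sd: float = 0.0, seed: int = 0,
                           n_null_pathways: int = 0,
                           name: str = "pathway_1") -> AbundanceTable:
    """Pathway intensities as weighted sums of linked OTU relative abundances.

    One named pathway is a weighted sum of the relative abundances of
    ``linked_otus`` plus Gaussian noise (clipped at zero); optional extra
    pathways are pure noise, for null calibration.
    """
    linked_otus = list(linked_otus)
    weights = np.asarray(list(weights), dtype=float)
    missing = [o for o in linked_otus if o not in otu_table.df.columns]
    if missing:
        raise ValueError(f"unknown OTUs in linked set: {missing}")
    if len(weights) != len(linked_otus):
        raise ValueError("weights must match linked_otus in length")
    rng = np.random.default_rng(seed)
    rel = otu_table.df.div(otu_table.df.sum(axis=1), axis=0)
    base = rel[linked_otus].to_numpy() @ weights
    cols = {name: np.clip(base + rng.normal(0, noise_sd, size=len(base)), 0, None)}
    for k in range(n_null_pathways):
        cols[f"null_pathway_{k + 1}"] = np.clip(
            rng.normal(0, max(noise_sd, 1e-12), size=len(base)), 0, None)
    df = pd.DataFrame(cols, index=otu_table.df.index)
    return AbundanceTable(df, normalized=False)
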