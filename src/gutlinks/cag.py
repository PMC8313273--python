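"""Co-abundance groups: Ward clustering of OTUs on SparCC correlation distance.

OTUs with at least one partner above a correlation threshold (0.5 by default)
are retained, the full 1 - rho matrix over the retained set is clustered with
Ward linkage, and the tree is cut into a requested number of CAGs.  Each CAG
is validated by a permutational MANOVA of its membership label on Bray-Curtis
distances among OTU abundance profiles (OTUs as observations, their profiles
across samples as coordinates) and deemed acceptable at p < 0.005.  Per-sample
CAG abundances (summed member relative abundances) support downstream group
comparisons by Wilcoxon rank-sum.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .sparcc import CorrelationMatrix
from .tables_io import OtuTable, relative_abundance

logger = logging.getLogger(__name__)

ACCEPTANCE_P = 0.005


@dataclass
class CagSet:
    """A partition of retained OTUs into co-abundance groups."""

    assignment: pd.Series              # otu_id -> CAG label (int, 1-based)
    abundance: pd.DataFrame            # samples x CAG (summed rel. abundances)
    pvalues: dict = field(default_factory=dict)      # CAG -> validation p
    acceptable: dict = field(default_factory=dict)   # CAG -> bool

    @property
    def n_cags(self) -> int:
        return int(self.assignment.nunique())

    @property
    def members(self) -> dict:
        return {int(c): sorted(idx)
                for c, idx in self.assignment.groupby(self.assignment).groups.items()}


def _retained_otus(corr: CorrelationMatrix, threshold: float) -> list:
    rho = corr.rho.to_numpy().copy()
    np.fill_diagonal(rho, -np.inf)
    keep = (rho > threshold).any(axis=1)
    return [o for o, k in zip(corr.otu_ids, keep) if k]


def build_cags(table: OtuTable, corr: CorrelationMatrix,
               corr_keep_threshold: float = 0.5,
               n_cags: int | str = "auto", max_auto_cags: int = 40,
               sub_threshold_to_one: bool = False,
               n_perm: int = 999, seed: int = 0) -> CagSet:
    """Cluster retained OTUs into CAGs by Ward linkage on 1 - rho.

    Retention keeps OTUs having at least one partner with rho >
    ``corr_keep_threshold`` (the full distance matrix over the retained set,
    including sub-threshold entries, is then clustered; pass
    ``sub_threshold_to_one=True`` for the alternative reading that saturates
    sub-threshold distances at 1).  With ``n_cags='auto'`` the largest cut (up
    to ``max_auto_cags``) for which every multi-member CAG is validated at
    p < 0.005 is selected.
    """
    retained = _retained_otus(corr, corr_keep_threshold)
    if not retained:
        raise ValueError(
            f"no OTU has a partner with rho > {corr_keep_threshold}")
    missing = [o for o in retained if o not in table.df.columns]
    if missing:
        raise ValueError(f"correlation matrix covers OTUs absent from table: {missing}")
    rho = corr.rho.loc[retained, retained].to_numpy()
    dist = 1.0 - rho
    if sub_threshold_to_one:
        dist[rho <= corr_keep_threshold] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    z = linkage(squareform(dist, checks=False), method="ward")

    if n_cags == "auto":
        upper = min(max_auto_cags, len(retained))
        for k in range(upper, 1, -1):
            cags = _cut(z, retained, k, table)
            cags = validate_cags(cags, table, n_perm=n_perm, seed=seed)
            multi = [c for c, mem in cags.members.items() if len(mem) >= 2]
            if multi and all(cags.acceptable.get(c, False) for c in multi):
                return cags
        raise ValueError("no cut up to max_auto_cags validates; supply n_cags explicitly")

    n_cags = int(n_cags)
    if n_cags > len(retained):
        raise ValueError(
            f"n_cags={n_cags} exceeds the {len(retained)} retained OTUs")
    if n_cags < 1:
        raise ValueError("n_cags must be >= 1")
    return _cut(z, retained, n_cags, table)


def _cut(z, retained, k, table: OtuTable) -> CagSet:
    labels = fcluster(z, t=k, criterion="maxclust")
    # relabel deterministically by first retained-OTU appearance
    seen, relabel = {}, {}
    for lab in labels:
        if lab not in seen:
            seen[lab] = len(seen) + 1
    labels = np.array([seen[lab] for lab in labels])
    assignment = pd.Series(labels, index=pd.Index(retained, name="otu_id"),
                           name="cag")
    rel = relative_abundance(table).df
    abund = pd.DataFrame(
        {c: rel[mem].sum(axis=1)
         for c, mem in assignment.groupby(assignment).groups.items()})
    abund.columns = [int(c) for c in abund.columns]
    return CagSet(assignment=assignment, abundance=abund)


def _two_group_permanova_p(dist: np.ndarray, in_group: np.ndarray,
                           n_perm: int, rng) -> float:
    """Two-group PERMANOVA pseudo-F permutation p, vectorised over permutations.

    With the Gower-centred matrix G (zero row sums) the model sum of squares
    for membership indicator m reduces to (1/n1 + 1/n2) m'Gm, so all permuted
    F statistics come from one matrix product.  When every distinct label
    configuration can be enumerated within the permutation budget the exact
    permutation distribution is used instead of Monte-Carlo sampling.
    """
    n = dist.shape[0]
    a = -0.5 * dist ** 2
    g = a - a.mean(axis=1, keepdims=True) - a.mean(axis=0, keepdims=True) + a.mean()
    ss_total = np.trace(g)
    n1 = int(in_group.sum())
    n2 = n - n1
    scale = 1.0 / n1 + 1.0 / n2

    def f_from_masks(masks: np.ndarray) -> np.ndarray:
        quad = np.einsum("ib,ib->b", masks, g @ masks)
        ss_between = scale * quad
        ss_within = ss_total - ss_between
        return ss_between / (ss_within / (n - 2))

    f_obs = f_from_masks(in_group.astype(float)[:, None])[0]
    n_exact = comb(n, n1, exact=True)
    if n_exact <= n_perm:
        masks = np.zeros((n, n_exact))
        for b, subset in enumerate(itertools.combinations(range(n), n1)):
            masks[list(subset), b] = 1.0
        f_all = f_from_masks(masks)
        return float(np.sum(f_all >= f_obs - 1e-12) / n_exact)
    order = np.argsort(rng.random((n, n_perm)), axis=0)
    masks = (order < n1).astype(float)
    exceed = int(np.sum(f_from_masks(masks) >= f_obs))
    return (1.0 + exceed) / (1.0 + n_perm)


def validate_cags(cags: CagSet, table: OtuTable, n_perm: int = 999,
                  seed: int = 0) -> CagSet:
    """Permutational MANOVA validation of each CAG's coherence.

    For every CAG with >= 2 members: Bray-Curtis distances are computed among
    the retained OTUs (profiles across samples as coordinates) and the
    membership label (this CAG vs. the rest) is tested with ``n_perm``
    permutations; the CAG is acceptable iff p < 0.005.  Single-member CAGs are
    skipped with a warning.
    """
    if n_perm < 199:
        raise ValueError("n_perm < 199 cannot resolve p < 0.005")
    retained = list(cags.assignment.index)
    rel = relative_abundance(table).df[retained]
    profiles = rel.T.to_numpy()            # OTUs x samples
    d = squareform(pdist(profiles, metric="braycurtis"))
    rng = np.random.default_rng(seed)
    pvalues, acceptable = {}, {}
    singletons = []
    for c, mem in cags.members.items():
        if len(mem) < 2:
            singletons.append(c)
            continue
        if len(mem) == len(retained):
            logger.warning("CAG %s contains every retained OTU; validation skipped", c)
            continue
        in_group = cags.assignment.to_numpy() == c
        p = _two_group_permanova_p(d, in_group, n_perm, rng)
        pvalues[c] = p
        acceptable[c] = p < ACCEPTANCE_P
    if singletons:
        logger.info("skipped validation for %d single-member CAGs: %s",
                    len(singletons), singletons)
    return CagSet(assignment=cags.assignment, abundance=cags.abundance,
                  pvalues=pvalues, acceptable=acceptable)


def compare_cag_groups(cags: CagSet, meta: pd.DataFrame,
                       group_factor: str = "group",
                       fdr: bool = False) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum of per-sample CAG abundance between the two
    levels of ``group_factor``.

    Direction reports the level with the larger median.  No multiplicity
    correction by default; ``fdr=True`` adds a Benjamini-Hochberg column.
    """
    samples = [s for s in cags.abundance.index if s in meta.index]
    groups = meta.loc[samples, group_factor].dropna()
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"{group_factor!r} must have exactly two levels, "
                         f"got {levels}")
    for lev in levels:
        if (groups == lev).sum() < 3:
            raise ValueError(f"level {lev!r} has fewer than 3 samples")
    rows = {}
    for c in sorted(cags.abundance.columns):
        x = cags.abundance.loc[groups.index[groups == levels[0]], c]
        y = cags.abundance.loc[groups.index[groups == levels[1]], c]
        w, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        direction = levels[0] if x.median() >= y.median() else levels[1]
        rows[c] = {"W": float(w), "p": float(p), "direction": direction}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "cag"
    if fdr:
        out["p_bh"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def write_cag_assignment(cags: CagSet, path) -> None:
    df = cags.assignment.to_frame()
    df["p_validation"] = [cags.pvalues.get(int(c), np.nan)
                          for c in cags.assignment]
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_cag_abundance(cags: CagSet, path) -> None:
    out = cags.abundance.copy()
    out.index.name = "sample_id"
    out.columns = [f"CAG{c}" for c in out.columns]
    out.to_csv(path, sep="\t", float_format="%.10g")
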