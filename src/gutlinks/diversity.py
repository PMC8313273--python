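"""Alpha/beta diversity, ordination and multi-factor PERMANOVA.

Alpha metrics (bias-corrected Chao1, Shannon in nats, Faith's PD) and
unweighted UniFrac are computed through scikit-bio; Bray-Curtis through scipy.
PCoA and the sequential (adonis-style) PERMANOVA with per-factor R^2 are
implemented here because the conventions the pipeline fixes (sign convention,
negative-eigenvalue handling, Type-I partitioning with permutation p-values)
are not all available from a single library call.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats
from skbio import TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import chao1 as _chao1
from skbio.diversity.alpha import shannon as _shannon
from skbio.stats.distance import DistanceMatrix

from .tables_io import OtuTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def _branch_spans(tree: TreeNode, otu_ids) -> list:
    """(length, subtended-OTU mask) for every non-root branch of the tree."""
    idx = {o: k for k, o in enumerate(otu_ids)}
    masks: dict[int, np.ndarray] = {}
    spans = []
    for node in tree.postorder(include_self=True):
        mask = np.zeros(len(otu_ids), dtype=bool)
        if node.is_tip():
            if node.name in idx:
                mask[idx[node.name]] = True
        else:
            for child in node.children:
                mask |= masks[id(child)]
        masks[id(node)] = mask
        if node.parent is not None and node.length:
            spans.append((float(node.length), mask))
    return spans


def faith_pd(counts_row: np.ndarray, otu_ids, tree: TreeNode) -> float:
    """Faith's phylogenetic diversity: total branch length of the minimal
    subtree spanning the observed leaves and the root."""
    present = np.asarray(counts_row) > 0
    return sum(length for length, mask in _branch_spans(tree, otu_ids)
               if (mask & present).any())


def alpha_diversity(table: OtuTable, tree: TreeNode | None = None,
                    bias_corrected: bool = True,
                    shannon_base: float = math.e) -> pd.DataFrame:
    """Per-sample Chao1, Shannon and (if a tree is given) Faith's PD.

    Chao1 uses the bias-corrected form S_obs + F1(F1-1)/(2(F2+1)) by default
    (defined even when no doubletons are observed); pass
    ``bias_corrected=False`` for the classic estimator.  Shannon is reported
    in nats by default, matching mothur.
    """
    counts = table.counts
    spans = None
    if tree is not None:
        leaves = {n.name for n in tree.tips()}
        missing = [o for o in table.otu_ids if o not in leaves]
        if missing:
            raise ValueError(f"OTUs missing from tree: {missing}")
        spans = _branch_spans(tree, table.otu_ids)
    rows = {}
    for i, sid in enumerate(table.sample_ids):
        c = counts[i]
        row = {
            "chao1": _chao1(c, bias_corrected=bias_corrected),
            "shannon": _shannon(c, base=shannon_base),
        }
        if spans is not None:
            present = c > 0
            row["pd"] = sum(length for length, mask in spans
                            if (mask & present).any())
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------

def unweighted_unifrac(table: OtuTable, tree: TreeNode) -> DistanceMatrix:
    """Presence/absence UniFrac: unique branch length / spanned branch length."""
    present = table.counts.sum(axis=1)
    if (present == 0).any():
        bad = [s for s, t in zip(table.sample_ids, present) if t == 0]
        raise ValueError(f"samples with no observed OTUs: {bad}")
    return beta_diversity("unweighted_unifrac", table.counts,
                          ids=table.sample_ids, taxa=table.otu_ids, tree=tree)


def bray_curtis(table: OtuTable, on: str = "relative") -> DistanceMatrix:
    """Bray-Curtis dissimilarity on relative abundances (default) or counts."""
    if on not in ("relative", "counts"):
        raise ValueError("on must be 'relative' or 'counts'")
    x = table.counts.astype(float)
    totals = x.sum(axis=1)
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"samples with zero total: {bad}")
    if on == "relative":
        x = x / totals[:, None]
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(d, ids=table.sample_ids)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class Ordination:
    """Principal-coordinates result."""

    coordinates: pd.DataFrame          # samples x axes
    eigenvalues: np.ndarray            # all eigenvalues, descending
    proportion_explained: np.ndarray   # over positive eigenvalues only

    @property
    def negative_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues < 0]


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dist: DistanceMatrix, n_axes: int | None = None) -> Ordination:
    """Classical scaling of a distance matrix.

    Eigendecomposition of the Gower-centred -D^2/2 matrix; coordinates are
    eigenvectors scaled by the square root of their (positive) eigenvalues.
    Negative eigenvalues are reported but excluded from the
    proportion-explained denominator.  For reproducibility the first nonzero
    loading of every axis is made positive.
    """
    d = dist.data.astype(float)
    n = d.shape[0]
    g = _gower_center(d)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-12
    pos = eigval > tol
    n_pos = int(pos.sum())
    if n_axes is None:
        n_axes = n_pos
    if n_axes > n_pos:
        logger.warning("requested %d axes but only %d positive eigenvalues",
                       n_axes, n_pos)
        n_axes = n_pos
    coords = eigvec[:, :n_axes] * np.sqrt(eigval[:n_axes])
    for k in range(coords.shape[1]):
        nz = np.nonzero(np.abs(coords[:, k]) > tol)[0]
        if nz.size and coords[nz[0], k] < 0:
            coords[:, k] = -coords[:, k]
    prop = eigval[:n_pos] / eigval[:n_pos].sum() if n_pos else np.array([])
    cols = [f"PCo{k + 1}" for k in range(n_axes)]
    return Ordination(
        coordinates=pd.DataFrame(coords, index=list(dist.ids), columns=cols),
        eigenvalues=eigval,
        proportion_explained=prop[:n_axes],
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _design_matrix(series: pd.Series) -> np.ndarray:
    dummies = pd.get_dummies(series.astype(str), drop_first=True)
    return dummies.to_numpy(dtype=float)


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def permanova(dist: DistanceMatrix, meta: pd.DataFrame, factors,
              n_perm: int = 999, seed: int = 0,
              mode: str = "sequential") -> pd.DataFrame:
    """Permutational multivariate ANOVA with per-factor R^2.

    Sequential (Type I) partitioning of the Gower-centred total sum of squares
    in the order the factors are given (the adonis default); ``mode
    = 'marginal'`` instead fits each factor alone.  P-values come from free
    permutation of sample labels: p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).

    Returns a DataFrame indexed by factor (plus a ``Residual`` row) with
    columns df, SS, R2, F and p.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if mode not in ("sequential", "marginal"):
        raise ValueError("mode must be 'sequential' or 'marginal'")
    factors = list(factors)
    ids = list(dist.ids)
    missing = [s for s in ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    sub = meta.loc[ids, factors]
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)].tolist()
        raise ValueError(f"samples with missing factor values: {bad}")
    for f in factors:
        if sub[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level")

    n = len(ids)
    g = _gower_center(dist.data.astype(float))
    ss_total = np.trace(g)

    if mode == "marginal":
        out = {}
        for f in factors:
            out[f] = permanova(dist, meta, [f], n_perm=n_perm, seed=seed).loc[f]
        return pd.DataFrame(out).T

    # sequential hat-matrix differences
    ones = np.ones((n, 1))
    blocks = [ones]
    h_prev = _hat(ones)
    rank_prev = 1
    deltas, dfs = [], []
    for f in factors:
        blocks.append(_design_matrix(sub[f]))
        x = np.hstack(blocks)
        h = _hat(x)
        rank = int(round(np.trace(h)))
        if rank == rank_prev:
            raise ValueError(f"factor {f!r} is aliased with preceding factors")
        deltas.append(h - h_prev)
        dfs.append(rank - rank_prev)
        h_prev, rank_prev = h, rank
    df_res = n - rank_prev
    if df_res <= 0:
        raise ValueError("model saturates the data; no residual df")
    h_full = h_prev

    def f_stats(gmat: np.ndarray) -> np.ndarray:
        ss = np.array([np.sum(dh * gmat.T) for dh in deltas])
        ss_res = np.trace(gmat) - np.sum(h_full * gmat.T)
        return (ss / np.asarray(dfs)) / (ss_res / df_res), ss, ss_res

    f_obs, ss_obs, ss_res = f_stats(g)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(factors))
    for _ in range(n_perm):
        p = rng.permutation(n)
        f_perm, _, _ = f_stats(g[np.ix_(p, p)])
        exceed += f_perm >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = {}
    for i, f in enumerate(factors):
        rows[f] = {"df": dfs[i], "SS": ss_obs[i],
                   "R2": ss_obs[i] / ss_total, "F": f_obs[i], "p": pvals[i]}
    rows["Residual"] = {"df": df_res, "SS": ss_res,
                        "R2": ss_res / ss_total, "F": np.nan, "p": np.nan}
    return pd.DataFrame.from_dict(rows, orient="index")


def kruskal_wallis_by_group(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Returns (0.0, 1.0) when all values are identical (the tie-correction
    degenerate case).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == lev] for lev in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)
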