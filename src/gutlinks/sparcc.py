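"""SparCC: basis correlations of OTUs from compositional count data.

Sequencing yields only relative abundances, so naive correlations between
taxa are distorted by the closure to a fixed total.  SparCC (sparse
compositional correlation) estimates the correlations of the unobserved
absolute ("basis") abundances from log-ratio variances under the assumption
that most pairs are uncorrelated:

    T_ij = Var_s[ ln(x_si / x_sj) ] = w_i + w_j - 2 rho_ij sqrt(w_i w_j)

Summing over j and assuming the correlation terms roughly cancel gives a
linear system for the basis variances w:

    sum_j T_ij = (m - 2) w_i + sum_j w_j

from which rho_ij = (w_i + w_j - T_ij) / (2 sqrt(w_i w_j)).  Strongly
correlated pairs violate the sparsity assumption, so the strongest pair above
an exclusion threshold is iteratively removed from the system and w re-solved.
Zeros are handled by drawing fractions from a per-sample Dirichlet with a
uniform pseudocount (counts + 1); the final estimate is the median over such
resamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import OtuTable

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric SparCC estimates with optional pseudo-p-values."""

    rho: pd.DataFrame                     # OTU x OTU, unit diagonal
    p: pd.DataFrame | None = None         # same shape; p(i,i) = 1 by convention
    excluded_pairs: set = field(default_factory=set)
    n_clipped: int = 0                    # raw estimates clipped into [-1, 1]

    @property
    def otu_ids(self) -> list:
        return list(self.rho.index)


def _variation_matrix(fracs: np.ndarray) -> np.ndarray:
    """T_ij = Var over samples of ln(x_i / x_j), via the log covariance."""
    logf = np.log(fracs)
    cov = np.cov(logf, rowvar=False)
    v = np.diag(cov)
    return v[:, None] + v[None, :] - 2.0 * cov


def _basis_correlations(t_mat: np.ndarray, exclusion_threshold: float,
                        max_rounds: int) -> tuple[np.ndarray, set, int]:
    """Solve for basis variances and correlations with iterative exclusion."""
    m = t_mat.shape[0]
    mact = np.ones((m, m)) + (m - 2) * np.eye(m)
    t_act = t_mat.copy()
    excluded: set = set()

    def solve() -> np.ndarray:
        w = np.linalg.solve(mact, t_act.sum(axis=1))
        w = np.maximum(w, 1e-12)       # variances; numerically guard
        denom = 2.0 * np.sqrt(np.outer(w, w))
        rho = (w[:, None] + w[None, :] - t_mat) / denom
        np.fill_diagonal(rho, 1.0)
        return rho

    rho = solve()
    for _ in range(max_rounds):
        masked = np.abs(np.triu(rho, k=1))
        for i, j in excluded:
            masked[i, j] = 0.0
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        excluded.add((i, j))
        mact[i, i] -= 1
        mact[j, j] -= 1
        mact[i, j] -= 1
        mact[j, i] -= 1
        t_act[i, j] = 0.0
        t_act[j, i] = 0.0
        if np.linalg.cond(mact) > 1e12:
            logger.warning("exclusion made the basis system ill-conditioned; stopping")
            break
        rho = solve()

    n_clipped = int(np.sum(np.abs(rho) > 1.0) // 2)
    rho = np.clip(rho, -1.0, 1.0)
    return rho, excluded, n_clipped


def _sparcc_once(counts: np.ndarray, rng, exclusion_threshold: float,
                 max_rounds: int):
    fracs = np.empty_like(counts, dtype=float)
    for s in range(counts.shape[0]):
        fracs[s] = rng.dirichlet(counts[s] + 1.0)
    t_mat = _variation_matrix(fracs)
    return _basis_correlations(t_mat, exclusion_threshold, max_rounds)


def sparcc_correlations(table: OtuTable, n_fraction_resamples: int = 20,
                        exclusion_threshold: float = 0.1,
                        max_exclusion_rounds: int | None = None,
                        seed: int = 0) -> CorrelationMatrix:
    """Estimate the SparCC correlation matrix of an OTU table.

    Defaults follow the reference implementation: 20 Dirichlet fraction
    resamples with a counts+1 prior, exclusion threshold 0.1, at most
    floor(m/3) exclusion rounds; the reported rho is the per-entry median
    across resamples, clipped into [-1, 1].
    """
    m = table.n_otus
    if m < 4:
        raise ValueError("SparCC needs at least 4 OTUs (basis system underdetermined)")
    counts = table.counts
    zero_otus = [o for o, c in zip(table.otu_ids, counts.sum(axis=0)) if c == 0]
    if zero_otus:
        raise ValueError(
            f"OTUs with zero counts in every sample (filter the table first): {zero_otus}")
    if np.all(np.ptp(counts / counts.sum(axis=1, keepdims=True), axis=0) < 1e-12):
        raise ValueError("all samples have identical composition; log-ratio "
                         "variances are zero and correlations are undefined")
    if max_exclusion_rounds is None:
        max_exclusion_rounds = m // 3
    rng = np.random.default_rng(seed)
    rhos = np.empty((n_fraction_resamples, m, m))
    excluded_union: set = set()
    n_clipped = 0
    for r in range(n_fraction_resamples):
        rho, excluded, clipped = _sparcc_once(
            counts, rng, exclusion_threshold, max_exclusion_rounds)
        rhos[r] = rho
        excluded_union |= excluded
        n_clipped += clipped
    med = np.median(rhos, axis=0)
    med = (med + med.T) / 2.0
    np.fill_diagonal(med, 1.0)
    if n_clipped:
        logger.info("clipped %d raw correlation estimates into [-1, 1]", n_clipped)
    ids = table.otu_ids
    return CorrelationMatrix(
        rho=pd.DataFrame(med, index=ids, columns=ids),
        excluded_pairs={(ids[i], ids[j]) for i, j in excluded_union},
        n_clipped=n_clipped,
    )


def sparcc_pvalues(table: OtuTable, observed: CorrelationMatrix,
                   n_bootstrap: int = 99, seed: int = 0,
                   n_fraction_resamples: int = 20,
                   exclusion_threshold: float = 0.1,
                   max_exclusion_rounds: int | None = None) -> CorrelationMatrix:
    """Two-sided pseudo-p-values by column-permutation bootstrap.

    Each bootstrap independently permutes every OTU's counts across samples
    (destroying all between-OTU association while keeping marginals), re-runs
    the full SparCC estimate and tallies |rho_boot| >= |rho_obs|;
    p = (1 + tally) / (1 + n_bootstrap).  Diagonal p is 1 by convention.
    """
    if n_bootstrap < 99:
        raise ValueError("n_bootstrap must be >= 99 to resolve alpha = 0.05")
    rng = np.random.default_rng(seed)
    counts = table.counts
    n, m = counts.shape
    obs = np.abs(observed.rho.to_numpy())
    exceed = np.zeros((m, m))
    for b in range(n_bootstrap):
        perm = np.empty_like(counts)
        for j in range(m):
            perm[:, j] = counts[rng.permutation(n), j]
        boot_table = OtuTable(pd.DataFrame(perm, index=table.sample_ids,
                                           columns=table.otu_ids))
        boot = sparcc_correlations(
            boot_table, n_fraction_resamples=n_fraction_resamples,
            exclusion_threshold=exclusion_threshold,
            max_exclusion_rounds=max_exclusion_rounds,
            seed=int(rng.integers(2 ** 31)))
        exceed += np.abs(boot.rho.to_numpy()) >= obs
    p = (1.0 + exceed) / (1.0 + n_bootstrap)
    p = (p + p.T) / 2.0
    np.fill_diagonal(p, 1.0)
    ids = table.otu_ids
    return CorrelationMatrix(
        rho=observed.rho.copy(),
        p=pd.DataFrame(p, index=ids, columns=ids),
        excluded_pairs=set(observed.excluded_pairs),
        n_clipped=observed.n_clipped,
    )


def write_correlation_matrix(corr: CorrelationMatrix, path, what: str = "rho") -> None:
    mat = corr.rho if what == "rho" else corr.p
    if mat is None:
        raise ValueError("no p-values present")
    out = mat.copy()
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_correlation_matrix(path) -> CorrelationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CorrelationMatrix(rho=df)
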