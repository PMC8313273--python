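"""LDA effect-size biomarker screening and pathway-taxon correlation.

The screening mirrors the LEfSe procedure: features are scaled per sample to a
total of 1e6, a Kruskal-Wallis test gates features at ``alpha``, and surviving
features receive an effect size from bootstrapped regularized linear
discriminant analysis — per bootstrap the effect of a feature is the
arithmetic mean of (a) the magnitude of the between-class mean difference the
LDA axis attributes to it and (b) the raw between-class mean difference; the
reported score is log10 of the bootstrap-mean effect, floored at 1 (so scores
are >= 0).  A feature is a biomarker iff its gate p < alpha and score >
``lda_threshold`` (2.0 for taxa in the conventional usage; 1.0 is typical for
pathway tables).

The original tool's subclass (pairwise Wilcoxon) stage is omitted: the designs
this package targets are one-factor comparisons with no subclass structure.
Exact numeric parity with the online tool is not promised; the estimator is
validated by null calibration and planted-effect recovery.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import AbundanceTable

logger = logging.getLogger(__name__)

LEFSE_SCALE = 1e6


def _as_frame(features) -> pd.DataFrame:
    if isinstance(features, AbundanceTable):
        return features.df
    return features


def lda_effect_size(features, classes, alpha: float = 0.05,
                    lda_threshold: float = 2.0, n_boot: int = 30,
                    boot_fraction: float = 2 / 3, seed: int = 0) -> pd.DataFrame:
    """Kruskal-Wallis screen plus bootstrapped LDA effect size per feature.

    ``features`` is samples x features (AbundanceTable or DataFrame);
    ``classes`` a per-sample label series/array with >= 2 levels and >= 3
    samples per level.  Returns a DataFrame indexed by feature with columns
    kw_p, lda_score, enriched_class and significant.
    """
    x = _as_frame(features)
    classes = pd.Series(np.asarray(classes), index=x.index)
    levels = sorted(classes.unique())
    if len(levels) < 2:
        raise ValueError("need at least two classes")
    for lev in levels:
        if (classes == lev).sum() < 3:
            raise ValueError(f"class {lev!r} has fewer than 3 samples")
    if n_boot < 10:
        warnings.warn("n_boot < 10 gives unstable effect sizes", stacklevel=2)

    # per-sample scaling to the conventional 1e6 total
    totals = x.sum(axis=1).replace(0, np.nan)
    xs = (x.div(totals, axis=0) * LEFSE_SCALE).fillna(0.0)
    feats = list(xs.columns)
    mat = xs.to_numpy(dtype=float)
    labels = classes.to_numpy()

    kw_p = np.ones(len(feats))
    for j in range(len(feats)):
        col = mat[:, j]
        # constant on the scaled axis (tolerant to per-sample division jitter)
        if np.allclose(col, col[0], rtol=1e-9, atol=0.0):
            kw_p[j] = 1.0
            continue
        groups = [col[labels == lev] for lev in levels]
        kw_p[j] = stats.kruskal(*groups)[1]
    surviving = np.where(kw_p < alpha)[0]

    scores = np.zeros(len(feats))
    if surviving.size:
        rng = np.random.default_rng(seed)
        effects = np.zeros((n_boot, surviving.size))
        sub = mat[:, surviving]
        for b in range(n_boot):
            idx = []
            for lev in levels:
                members = np.where(labels == lev)[0]
                k = max(3, int(np.ceil(boot_fraction * members.size)))
                idx.extend(rng.choice(members, size=min(k, members.size),
                                      replace=False))
            idx = np.asarray(idx)
            effects[b] = _lda_effect(sub[idx], labels[idx], levels, rng)
        scores[surviving] = np.log10(np.maximum(effects.mean(axis=0), 1.0))

    class_means = {lev: mat[labels == lev].mean(axis=0) for lev in levels}
    enriched = [max(levels, key=lambda lev: class_means[lev][j])
                for j in range(len(feats))]
    out = pd.DataFrame({
        "kw_p": kw_p,
        "lda_score": scores,
        "enriched_class": enriched,
        "significant": (kw_p < alpha) & (scores > lda_threshold),
    }, index=pd.Index(feats, name="feature"))
    return out


def _lda_effect(x: np.ndarray, labels: np.ndarray, levels, rng) -> np.ndarray:
    """Per-feature effect for one bootstrap: mean of |w_j (w . mdiff)| and
    |mdiff_j| where w is the (unit) regularized LDA direction and mdiff the
    extreme spread of class means (a plain difference for two classes)."""
    means = np.array([x[labels == lev].mean(axis=0) for lev in levels])
    # pooled within-class covariance with a small ridge
    n, m = x.shape
    sw = np.zeros((m, m))
    for i, lev in enumerate(levels):
        xc = x[labels == lev] - means[i]
        sw += xc.T @ xc
    sw /= max(n - len(levels), 1)
    ridge = max(np.trace(sw) / m, 1.0) * 1e-6
    sw[np.diag_indices(m)] += ridge
    # extreme class-mean spread per feature
    hi = means.max(axis=0)
    lo = means.min(axis=0)
    mdiff = hi - lo
    try:
        w = np.linalg.solve(sw, mdiff)
    except np.linalg.LinAlgError:
        w = mdiff.copy()
    norm = np.linalg.norm(w)
    if norm == 0:
        return np.abs(mdiff)
    w = w / norm
    projected = np.abs(w * (w @ mdiff))
    return (projected + np.abs(mdiff)) / 2.0


def spearman_correlation(pathways, features, feature_subset=None,
                         fdr: bool = False) -> pd.DataFrame:
    """Tie-corrected Spearman rho for every (pathway, feature) pair.

    Both tables are samples x columns over the same sample set.  Pairs with a
    constant vector get rho = NaN and are reported as missing.  ``fdr=True``
    adds a Benjamini-Hochberg column over the tested pairs.
    """
    pw = _as_frame(pathways)
    ft = _as_frame(features)
    if feature_subset is not None:
        ft = ft[[f for f in ft.columns if f in set(feature_subset)]]
    common = [s for s in pw.index if s in ft.index]
    if len(common) != len(pw.index) or len(common) != len(ft.index):
        raise ValueError("pathway and feature tables must share the same samples")
    pw, ft = pw.loc[common], ft.loc[common]
    rows = []
    for p in pw.columns:
        pv = pw[p].to_numpy(dtype=float)
        for f in ft.columns:
            fv = ft[f].to_numpy(dtype=float)
            if np.all(pv == pv[0]) or np.all(fv == fv[0]):
                rows.append({"pathway": p, "feature": f,
                             "rho": np.nan, "p": np.nan})
                continue
            rho, pval = stats.spearmanr(pv, fv)
            rows.append({"pathway": p, "feature": f,
                         "rho": float(rho), "p": float(pval)})
    out = pd.DataFrame(rows)
    if fdr:
        mask = out["p"].notna()
        out["p_bh"] = np.nan
        if mask.any():
            from .cag import _benjamini_hochberg
            out.loc[mask, "p_bh"] = _benjamini_hochberg(
                out.loc[mask, "p"].to_numpy())
    return out
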