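"""Reading, writing and basic manipulation of OTU tables and companion inputs.

The universal in-memory containers are :class:`OtuTable` (integer counts,
samples x OTUs) and :class:`AbundanceTable` (per-sample relative abundances).
Taxonomy maps and sample metadata are plain :class:`pandas.DataFrame` objects;
phylogenies are :class:`skbio.TreeNode` instances read from newick.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

#: Canonical rank order for 7-rank lineages.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Greengenes-style rank prefixes accepted (and stripped) in lineage strings.
_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


class TableParseError(ValueError):
    """Raised when an input file cannot be parsed into a valid table."""


class EmptyResultError(ValueError):
    """Raised when a filtering operation removes every feature."""


def _check_ids(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} IDs: {dupes}")


@dataclass(frozen=True)
class OtuTable:
    """Integer OTU count matrix, samples as rows, OTUs as columns."""

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df
        _check_ids(df.index, "sample")
        _check_ids(df.columns, "OTU")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or not np.all(values == np.floor(values)):
                bad = np.argwhere(~np.isfinite(values) | (values != np.floor(values)))
                i, j = bad[0]
                raise ValueError(
                    f"non-integer count at sample {df.index[i]!r}, OTU {df.columns[j]!r}"
                )
            object.__setattr__(self, "df", df.astype(np.int64))
            values = self.df.to_numpy()
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at sample {df.index[i]!r}, OTU {df.columns[j]!r}"
            )
        # axis labels are presentation-only; normalise so that written and
        # re-read tables compare equal
        if self.df.index.name is not None or self.df.columns.name is not None:
            object.__setattr__(self, "df",
                               self.df.rename_axis(index=None, columns=None))

    @property
    def sample_ids(self) -> list:
        return list(self.df.index)

    @property
    def otu_ids(self) -> list:
        return list(self.df.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.df.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.df.shape[0]

    @property
    def n_otus(self) -> int:
        return self.df.shape[1]

    def subset_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(self.df.loc[list(sample_ids)])

    def __eq__(self, other):
        return isinstance(other, OtuTable) and self.df.equals(other.df)


@dataclass(frozen=True)
class AbundanceTable:
    """Relative abundances, each row summing to one."""

    df: pd.DataFrame
    #: rows are allowed not to sum to 1 (e.g. simulated pathway intensities)
    normalized: bool = True

    def __post_init__(self):
        _check_ids(self.df.index, "sample")
        _check_ids(self.df.columns, "feature")
        values = self.df.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValueError("relative abundances must be non-negative")
        if self.normalized:
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.df.index[np.argmax(np.abs(sums - 1.0))]
                raise ValueError(f"row for sample {bad!r} does not sum to 1")

    @property
    def sample_ids(self) -> list:
        return list(self.df.index)

    @property
    def feature_ids(self) -> list:
        return list(self.df.columns)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_otu_table(path, transposed: bool = False) -> OtuTable:
    """Read a TSV OTU table (first column sample IDs, header OTU IDs).

    With ``transposed=True`` the file is OTUs x samples and is flipped on read.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except pd.errors.ParserError as exc:
        raise TableParseError(f"malformed OTU table {path}: {exc}") from exc
    if df.columns.size == 0:
        raise TableParseError(f"OTU table {path} has no data columns")
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise TableParseError(f"missing/ragged value in row {row!r} of {path}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            cell = bad[0] if len(bad) else "?"
            raise TableParseError(
                f"non-numeric cell at row {cell!r}, column {col!r} of {path}"
            )
    if transposed:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        return OtuTable(df)
    except ValueError as exc:
        raise TableParseError(f"invalid OTU table {path}: {exc}") from exc


def write_otu_table(table: OtuTable, path) -> None:
    df = table.df.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_taxonomy(path) -> pd.DataFrame:
    """Read a two-column TSV (otu_id, semicolon-delimited lineage).

    Greengenes-style ``k__``/``p__``/... prefixes are stripped.  Returns a
    DataFrame indexed by otu_id with the 7 rank columns; missing ranks are
    empty strings.
    """
    raw = pd.read_csv(path, sep="\t", header=None, names=["otu_id", "lineage"],
                      dtype=str, skiprows=_header_rows(path))
    rows = {}
    for otu, lineage in zip(raw["otu_id"], raw["lineage"].fillna("")):
        parts = [p.strip() for p in lineage.split(";")]
        if len(parts) > len(RANKS):
            raise TableParseError(f"lineage for {otu!r} has more than 7 ranks")
        clean = []
        for p in parts:
            for pref in _RANK_PREFIXES:
                if p.startswith(pref):
                    p = p[len(pref):]
                    break
            clean.append(p)
        clean += [""] * (len(RANKS) - len(clean))
        rows[str(otu)] = clean
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    df.index.name = "otu_id"
    return df


def _header_rows(path) -> int:
    with open(path) as fh:
        first = fh.readline()
    return 1 if first.lower().startswith(("otu_id", "#otu")) else 0


def write_taxonomy(tax: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\tlineage\n")
        for otu, row in tax.iterrows():
            lineage = ";".join(str(row[r]) for r in RANKS)
            fh.write(f"{otu}\t{lineage}\n")


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV keyed by sample_id; all columns kept as strings.

    Default NA-sniffing is disabled so that a literal group label ``NA`` (a
    perfectly ordinary category name) survives the round trip; only empty
    cells are treated as missing.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False, na_values=[""])
    df.index = df.index.astype(str)
    _check_ids(df.index, "sample")
    return df


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_tree(path) -> TreeNode:
    tree = TreeNode.read(str(path))
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path))


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a warning.
    Sampling is multivariate hypergeometric, so rows of the result sum to
    ``depth`` exactly and the procedure is reproducible for a given seed.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.df.sum(axis=1)
    kept = totals.index[totals >= depth]
    dropped = totals.index[totals < depth].tolist()
    if dropped:
        logger.warning("dropping %d samples below depth %d: %s",
                       len(dropped), depth, dropped)
    if len(kept) == 0:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    out = np.empty((len(kept), table.n_otus), dtype=np.int64)
    for i, sid in enumerate(kept):
        counts = table.df.loc[sid].to_numpy()
        if counts.sum() == depth:
            out[i] = counts
        else:
            out[i] = rng.multivariate_hypergeometric(counts, depth)
    return OtuTable(pd.DataFrame(out, index=list(kept), columns=table.otu_ids))


def relative_abundance(table: OtuTable) -> AbundanceTable:
    """Convert counts to per-sample fractions (rows sum to one)."""
    totals = table.df.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    return AbundanceTable(table.df.div(totals, axis=0))


def filter_otus(table: OtuTable, min_mean_rel_abund: float,
                min_prevalence: float, abundance_stat: str = "mean") -> OtuTable:
    """Keep OTUs passing both an abundance and a prevalence threshold.

    An OTU is kept iff its mean (or max, per ``abundance_stat``) relative
    abundance across samples is >= ``min_mean_rel_abund`` and it is present
    (count > 0) in at least a ``min_prevalence`` fraction of samples.  The
    sample set is unchanged.
    """
    for name, t in (("min_mean_rel_abund", min_mean_rel_abund),
                    ("min_prevalence", min_prevalence)):
        if not 0 <= t <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {t}")
    if abundance_stat not in ("mean", "max"):
        raise ValueError("abundance_stat must be 'mean' or 'max'")
    rel = relative_abundance(table).df
    stat = rel.mean(axis=0) if abundance_stat == "mean" else rel.max(axis=0)
    prevalence = (table.df > 0).mean(axis=0)
    keep = (stat >= min_mean_rel_abund) & (prevalence >= min_prevalence)
    if not keep.any():
        raise EmptyResultError("filtering removed every OTU")
    return OtuTable(table.df.loc[:, keep[keep].index])


def aggregate_taxonomy(table: AbundanceTable, tax: pd.DataFrame,
                       rank: str) -> AbundanceTable:
    """Sum feature abundances into lineages truncated at ``rank``.

    Features lacking an annotation at ``rank`` are pooled into an
    ``unclassified_<parent>`` column (parent = nearest annotated ancestor
    rank).  Total abundance per sample is conserved.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; must be one of {RANKS}")
    depth = RANKS.index(rank)
    labels = {}
    for otu in table.df.columns:
        if otu not in tax.index:
            labels[otu] = "unclassified_unknown"
            continue
        lineage = [str(tax.loc[otu, r]) for r in RANKS[: depth + 1]]
        lineage = ["" if v in ("nan", "None") else v for v in lineage]
        if lineage[depth]:
            labels[otu] = ";".join(lineage)
        else:
            parents = [v for v in lineage[:depth] if v]
            parent = parents[-1] if parents else "root"
            labels[otu] = f"unclassified_{parent}"
    grouped = table.df.T.groupby(pd.Series(labels)).sum().T
    return AbundanceTable(grouped, normalized=table.normalized)
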