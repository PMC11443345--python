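"""ASV table / taxonomy / metadata I-O and normalization.

The normalization chain mirrors standard amplicon practice: remove
off-target lineages (chloroplast, mitochondria, archaea), rarefy every
sample without replacement to a common depth, zero any cell with fewer
than 10 reads, then convert to relative abundance.  Grouping of swabs by
darkness (decile percentiles, and a Low/Mid/High "extremes" trio of size
k) also lives here, since group labels are part of the sample metadata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SAMPLE_TYPES = ("swab", "rumen_liquid", "rumen_solid")

#: Default off-target removal rules: (rank, label) pairs.
DEFAULT_REMOVE_RULES = (
    ("Order", "Chloroplast"),
    ("Family", "Mitochondria"),
    ("Kingdom", "Archaea"),
)

#: Decile group labels, lightest to darkest.
PERCENTILE_LABELS = ("Tenth", "Twentieth", "Thirtieth", "Fortieth", "Fiftieth",
                     "Sixtieth", "Seventieth", "Eightieth", "Ninetieth",
                     "Hundredth")


@dataclass
class CommunityTable:
    """Samples x ASVs abundance matrix.

    ``mode`` is ``"counts"`` (non-negative, typically integer) or
    ``"proportions"`` (each row sums to 1).  ``provenance`` accumulates a
    human-readable trace of the normalization steps applied.
    """

    df: pd.DataFrame
    mode: str = "counts"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "proportions"):
            raise ValueError(f"mode must be counts|proportions; got {self.mode!r}")
        vals = self.df.to_numpy()
        if vals.size and vals.min() < 0:
            raise ValueError("abundances must be non-negative")
        if self.df.index.has_duplicates:
            dup = self.df.index[self.df.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if self.df.columns.has_duplicates:
            dup = self.df.columns[self.df.columns.duplicated()][0]
            raise ValueError(f"duplicate ASV id {dup!r}")
        if self.mode == "proportions":
            sums = vals.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.df.index[np.argmax(np.abs(sums - 1.0))]
                raise ValueError(f"proportion rows must sum to 1 (sample {bad!r})")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.df.columns)

    def subset(self, sample_ids) -> "CommunityTable":
        return CommunityTable(self.df.loc[list(sample_ids)], self.mode,
                              dict(self.provenance))


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path: str, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{kind}: duplicate id {dup!r} in {path}")
    return df


def read_count_table(path: str) -> CommunityTable:
    """Read a samples x ASVs TSV of counts (first column = sample id)."""
    df = _read_tsv(path, "count table")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"count table {path}: non-numeric cell ({exc})") from exc
    if (df.to_numpy() < 0).any():
        r, c = np.argwhere(df.to_numpy() < 0)[0]
        raise ValueError(
            f"count table {path}: negative count at sample {df.index[r]!r}, "
            f"ASV {df.columns[c]!r}"
        )
    if np.allclose(df.to_numpy() % 1, 0):
        df = df.astype(int)
    return CommunityTable(df, mode="counts")


def read_metadata(path: str) -> pd.DataFrame:
    """Read sample metadata TSV (sample_id, sample_type, darkness?...)."""
    df = _read_tsv(path, "metadata")
    if "sample_type" not in df.columns:
        raise ValueError(f"metadata {path}: missing 'sample_type' column")
    bad = set(df["sample_type"]) - set(SAMPLE_TYPES)
    if bad:
        raise ValueError(f"metadata {path}: unknown sample_type(s) {sorted(bad)}")
    if "darkness" in df.columns:
        df["darkness"] = pd.to_numeric(df["darkness"], errors="coerce")
    return df


def read_taxonomy(path: str) -> pd.DataFrame:
    """Read taxonomy TSV (asv_id, Kingdom..Species)."""
    return _read_tsv(path, "taxonomy")


def write_table(table: CommunityTable, path: str) -> None:
    table.df.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# normalization


def remove_taxa(table: CommunityTable, taxonomy: pd.DataFrame,
                rules=DEFAULT_REMOVE_RULES) -> CommunityTable:
    """Drop ASV columns whose taxonomy matches any (rank, label) rule."""
    drop: set[str] = set()
    for rank, label in rules:
        if rank not in taxonomy.columns:
            continue
        hits = taxonomy.index[taxonomy[rank] == label]
        drop.update(a for a in hits if a in table.df.columns)
    if not drop:
        return table
    kept = table.df.drop(columns=sorted(drop))
    prov = dict(table.provenance)
    prov["removed_taxa"] = sorted(drop)
    logger.info("remove_taxa: dropped %d off-target ASVs", len(drop))
    return CommunityTable(kept, table.mode, prov)


def rarefy(table: CommunityTable, depth: int, seed: int = 0) -> CommunityTable:
    """Subsample each sample WITHOUT replacement to exactly *depth* reads.

    Samples whose total is below *depth* are dropped and recorded in
    ``provenance['rarefaction_dropped']``.  Deterministic under *seed*
    (multivariate hypergeometric draw per sample).
    """
    if table.mode != "counts":
        raise ValueError("rarefy requires a counts table")
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1; got {depth}")
    rng = np.random.default_rng(seed)
    counts = table.df.to_numpy().astype(np.int64)
    totals = counts.sum(axis=1)
    keep = totals >= depth
    dropped = [s for s, k in zip(table.df.index, keep) if not k]
    if not keep.any():
        raise ValueError(f"no samples survive rarefaction at depth {depth}")
    if dropped:
        logger.info("rarefy: dropped %d samples below depth %d", len(dropped), depth)
    rows = []
    for i in np.flatnonzero(keep):
        if totals[i] == depth:
            rows.append(counts[i])
        else:
            rows.append(rng.multivariate_hypergeometric(counts[i], depth))
    out = pd.DataFrame(np.array(rows, dtype=int), index=table.df.index[keep],
                       columns=table.df.columns)
    if out.empty:
        raise ValueError(f"no samples survive rarefaction at depth {depth}")
    prov = dict(table.provenance)
    prov["rarefaction_depth"] = depth
    prov["rarefaction_seed"] = seed
    prov["rarefaction_dropped"] = dropped
    return CommunityTable(out, "counts", prov)


def min_count_filter(table: CommunityTable, min_count: int = 10) -> CommunityTable:
    """Zero every cell with fewer than *min_count* reads (cell-wise rule).

    An ASV is "removed" for a sample if that sample holds 1..min_count-1
    reads of it; a cell with exactly *min_count* reads survives.  ASV
    columns that become all-zero are dropped.
    """
    if table.mode != "counts":
        raise ValueError("min_count_filter requires a counts table")
    vals = table.df.to_numpy().copy()
    vals[(vals > 0) & (vals < min_count)] = 0
    out = pd.DataFrame(vals, index=table.df.index, columns=table.df.columns)
    out = out.loc[:, out.sum(axis=0) > 0]
    prov = dict(table.provenance)
    prov["min_count"] = min_count
    return CommunityTable(out, "counts", prov)


def relative_abundance(table: CommunityTable) -> CommunityTable:
    """Row-normalize counts to proportions."""
    if table.mode != "counts":
        raise ValueError("relative_abundance expects a counts table")
    sums = table.df.sum(axis=1)
    if (sums == 0).any():
        bad = sums.index[sums == 0][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    out = table.df.div(sums, axis=0)
    return CommunityTable(out, "proportions", dict(table.provenance))


def aggregate_rank(table: CommunityTable, taxonomy: pd.DataFrame,
                   rank: str) -> CommunityTable:
    """Sum ASV columns sharing the same taxonomy label at *rank*."""
    if rank not in taxonomy.columns:
        raise ValueError(f"rank {rank!r} not in taxonomy columns "
                         f"{list(taxonomy.columns)}")
    labels = taxonomy[rank].reindex(table.df.columns).fillna("unclassified")
    agg = table.df.T.groupby(labels.values).sum().T
    return CommunityTable(agg, table.mode, dict(table.provenance))


def top_taxa(agg_table: CommunityTable, n: int = 10,
             groups: pd.Series | None = None) -> pd.DataFrame:
    """Group-mean relative abundance of the top-*n* taxa, remainder as "Other".

    *groups* maps sample id -> group label; when omitted each sample is its
    own group.  Taxa are ranked by grand mean across samples.
    """
    df = agg_table.df
    if agg_table.mode == "counts":
        df = df.div(df.sum(axis=1), axis=0)
    order = df.mean(axis=0).sort_values(ascending=False)
    top = list(order.index[:n])
    if groups is not None:
        df = df.groupby(groups.reindex(df.index)).mean()
    out = df[top].copy()
    out["Other"] = 1.0 - out.sum(axis=1)
    out["Other"] = out["Other"].clip(lower=0.0)
    return out


# ---------------------------------------------------------------------------
# darkness grouping


def _ranked_swabs(metadata: pd.DataFrame) -> pd.Index:
    """Swab ids sorted by (darkness, sample_id); the id breaks ties."""
    swabs = metadata[(metadata["sample_type"] == "swab")
                     & metadata["darkness"].notna()]
    order = swabs.sort_index().sort_values("darkness", kind="stable")
    return order.index


def assign_percentile_groups(metadata: pd.DataFrame) -> pd.DataFrame:
    """Split swabs into 10 decile groups by darkness rank.

    Ranks are partitioned into 10 contiguous blocks as equal as possible;
    the first ``n mod 10`` blocks receive the extra member.  Group 1
    ("Tenth") holds the lightest swabs, group 10 ("Hundredth") the darkest.
    """
    ranked = _ranked_swabs(metadata)
    n = len(ranked)
    if n < 10:
        raise ValueError(f"need >= 10 swabs with darkness; got {n}")
    base, extra = divmod(n, 10)
    sizes = [base + 1] * extra + [base] * (10 - extra)
    out = metadata.copy()
    out["percentile_group"] = pd.Series(pd.NA, index=out.index, dtype="Int64")
    out["percentile_label"] = pd.Series(pd.NA, index=out.index, dtype="string")
    start = 0
    for g, size in enumerate(sizes, start=1):
        ids = ranked[start : start + size]
        out.loc[ids, "percentile_group"] = g
        out.loc[ids, "percentile_label"] = PERCENTILE_LABELS[g - 1]
        start += size
    if metadata.loc[ranked, "darkness"].nunique() == 1:
        logger.warning("all darkness scores equal: decile groups follow the "
                       "sample-id tie-break only")
    return out


def assign_extremes_groups(metadata: pd.DataFrame, k: int = 13) -> pd.DataFrame:
    """Assign Low/Mid/High extremes groups of size *k* by darkness rank.

    Low = k lightest, High = k darkest, Mid = the k swabs whose ranks are
    centred on the median rank (ranks ``floor((n-k)/2)+1 .. +k``).  The
    default k = 13 matches the number of rumen reference animals, keeping
    group sizes even across swab and rumen groups.
    """
    ranked = _ranked_swabs(metadata)
    n = len(ranked)
    if n < 3 * k:
        raise ValueError(f"need >= 3k = {3 * k} swabs with darkness; got {n}")
    out = metadata.copy()
    out["extremes_group"] = pd.Series(pd.NA, index=out.index, dtype="string")
    out.loc[ranked[:k], "extremes_group"] = "Low"
    out.loc[ranked[-k:], "extremes_group"] = "High"
    start = (n - k) // 2  # 0-based; Mid covers ranks start+1 .. start+k
    out.loc[ranked[start : start + k], "extremes_group"] = "Mid"
    return out
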