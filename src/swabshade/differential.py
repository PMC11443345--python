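"""SIMPER decomposition, differential ASVs, prevalence and capture.

SIMPER decomposes the mean between-group Bray-Curtis dissimilarity into
per-ASV contributions.  ASVs contributing more than 1% (strictly) are
then tested for abundance differences between the two groups by
Kruskal-Wallis with Benjamini-Hochberg correction.  "Highly prevalent"
ASV sets are built from the rumen solid/liquid reference samples
(prevalence strictly above a threshold), and each swab's *capture
percentage* — the share of that set it contains — is correlated with its
darkness score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CommunityTable
from .ordination import TestResult, bh_adjust, kruskal_wallis, spearman


def simper(table: CommunityTable, group_a, group_b) -> pd.DataFrame:
    """Per-ASV contributions to the mean between-group Bray-Curtis dissimilarity.

    For each between-group sample pair (j, k) the per-ASV term is
    ``delta_i = |x_ij - x_ik| / sum_i (x_ij + x_ik)`` (so the terms sum to
    that pair's Bray-Curtis dissimilarity).  The reported
    ``mean_contribution`` of ASV i is ``mean_pairs(delta_i) / mean BC``,
    normalised to sum to 1 across ASVs.  Rows are sorted descending with a
    running ``cumulative`` column.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    xa = table.df.loc[group_a].to_numpy(dtype=float)
    xb = table.df.loc[group_b].to_numpy(dtype=float)
    # pairwise |x-y| per ASV and pair totals, vectorised over all pairs
    diff = np.abs(xa[:, None, :] - xb[None, :, :])  # a x b x asv
    tot = (xa[:, None, :] + xb[None, :, :]).sum(axis=2)  # a x b
    if (tot == 0).any():
        j, k = np.argwhere(tot == 0)[0]
        raise ValueError(
            f"pair ({group_a[j]!r}, {group_b[k]!r}) is all-zero: "
            "dissimilarity undefined"
        )
    delta = diff / tot[:, :, None]  # per-pair per-ASV contribution
    mean_delta = delta.mean(axis=(0, 1))  # per ASV
    mean_bc = mean_delta.sum()
    if mean_bc == 0:
        raise ValueError("groups are identical: zero dissimilarity to decompose")
    contrib = mean_delta / mean_bc
    out = pd.DataFrame(
        {"mean_contribution": contrib}, index=table.df.columns
    ).sort_values("mean_contribution", ascending=False)
    out["cumulative"] = out["mean_contribution"].cumsum()
    out["mean_bray_curtis"] = mean_bc
    out.index.name = "asv_id"
    return out


def differential_asvs(
    table: CommunityTable,
    group_a,
    group_b,
    simper_threshold: float = 0.01,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ASVs driving the difference between two groups.

    SIMPER contributions are gated at strictly > *simper_threshold*; each
    surviving ASV is tested by Kruskal-Wallis on its relative abundance
    across the two groups, with BH adjustment over the surviving set only.
    ``direction`` names the group with the higher median abundance.
    Returns an empty frame (not an error) when nothing passes the gate.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need >= 2 members for testing")
    sim = simper(table, group_a, group_b)
    surv = sim.index[sim["mean_contribution"] > simper_threshold]
    cols = ["simper_contribution", "kw_p", "q_value", "direction", "significant"]
    if len(surv) == 0:
        return pd.DataFrame(columns=cols)
    values = table.df.loc[group_a + group_b, surv]
    labels = np.array(["A"] * len(group_a) + ["B"] * len(group_b))
    rows = []
    for asv in surv:
        v = values[asv].to_numpy(dtype=float)
        res = kruskal_wallis(v, labels)
        med_a = float(np.median(v[labels == "A"]))
        med_b = float(np.median(v[labels == "B"]))
        direction = "A" if med_a > med_b else ("B" if med_b > med_a else "tie")
        rows.append((asv, sim.loc[asv, "mean_contribution"], res.p_value,
                     direction))
    out = pd.DataFrame(rows, columns=["asv_id", "simper_contribution", "kw_p",
                                      "direction"]).set_index("asv_id")
    out["q_value"] = bh_adjust(out["kw_p"].to_numpy())
    out["significant"] = out["q_value"] < alpha
    return out[cols]


@dataclass
class PrevalentSet:
    """Highly prevalent ASVs of one rumen fraction."""

    fraction: str  # "rumen_solid" | "rumen_liquid"
    asv_ids: list[str]
    threshold: float
    prevalence: pd.Series = field(repr=False, default=None)
    unique_ids: list[str] | None = None  # members absent from the other set

    @property
    def n_total(self) -> int:
        return len(self.asv_ids)

    @property
    def n_unique(self) -> int:
        return len(self.unique_ids) if self.unique_ids is not None else 0


def prevalent_set(
    table: CommunityTable,
    fraction_ids,
    threshold: float = 0.8,
    fraction: str = "",
    other_set: "PrevalentSet | None" = None,
) -> PrevalentSet:
    """ASVs strictly above *threshold* prevalence within one rumen fraction.

    Prevalence is the fraction of the group's samples with nonzero
    abundance.  Pass the other fraction's set as *other_set* to also
    record the members unique to this fraction.
    """
    fraction_ids = list(fraction_ids)
    if not fraction_ids:
        raise ValueError("fraction has no samples")
    sub = table.df.loc[fraction_ids]
    prev = (sub > 0).mean(axis=0)
    members = sorted(prev.index[prev > threshold])
    unique = None
    if other_set is not None:
        unique = sorted(set(members) - set(other_set.asv_ids))
    return PrevalentSet(fraction or "fraction", members, threshold, prev, unique)


def capture_fraction(table: CommunityTable, swab_ids,
                     pset: PrevalentSet) -> pd.DataFrame:
    """Per-swab capture of a prevalent ASV set.

    Presence is nonzero abundance in the (already rarefied and
    min-count-filtered) table.  Returns columns ``captured`` and
    ``capture_pct`` (0-100).
    """
    if pset.n_total == 0:
        raise ValueError("prevalent set is empty")
    present_cols = [a for a in pset.asv_ids if a in table.df.columns]
    sub = table.df.loc[list(swab_ids), present_cols] if present_cols else None
    captured = (sub > 0).sum(axis=1) if sub is not None else pd.Series(
        0, index=list(swab_ids))
    out = pd.DataFrame({"captured": captured.astype(int)})
    out["capture_pct"] = 100.0 * out["captured"] / pset.n_total
    out.index.name = "sample_id"
    return out


def capture_darkness_correlation(records: pd.DataFrame,
                                 darkness: pd.Series) -> TestResult:
    """Spearman correlation of capture percentage against darkness."""
    common = records.index.intersection(darkness.dropna().index)
    return spearman(darkness.loc[common].to_numpy(),
                    records.loc[common, "capture_pct"].to_numpy())
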