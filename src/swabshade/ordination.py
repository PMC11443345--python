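"""PCoA, PERMANOVA and the nonparametric test battery.

PCoA is the classical Gower double-centering eigendecomposition of
``-D^2/2``; negative eigenvalues are reported but excluded from the
variance-explained denominator, and each axis sign is fixed so the
largest-magnitude coordinate is positive.  PERMANOVA uses the one-way
pseudo-F on squared distances with seeded label permutations and the
add-one p-value rule (p is never exactly 0).  The battery wraps
Kruskal-Wallis, pairwise Wilcoxon rank-sum with Benjamini-Hochberg
adjustment, and Spearman rank correlation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from skbio import DistanceMatrix


@dataclass
class OrdinationResult:
    """PCoA embedding: coordinates, eigenvalues, variance explained."""

    coordinates: pd.DataFrame  # samples x axes ("PC1", "PC2", ...)
    eigenvalues: np.ndarray  # all eigenvalues, descending (may be negative)
    proportion_explained: np.ndarray  # per retained axis

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coordinates.index)


@dataclass
class TestResult:
    """Generic hypothesis-test outcome."""

    statistic: float
    p_value: float
    method: str
    q_value: float | None = None
    df: float | None = None
    n: int | None = None
    extras: dict = field(default_factory=dict)


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis of a distance matrix.

    Axes are eigenvectors of the Gower-centred matrix scaled by the square
    root of their (positive) eigenvalues.  ``n_axes`` defaults to all axes
    with positive eigenvalue.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if n_axes is not None and n_axes > n - 1:
        raise ValueError(f"n_axes must be <= n-1 = {n - 1}")
    a = -0.5 * d**2
    centre = np.eye(n) - np.ones((n, n)) / n
    b = centre @ a @ centre
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12
    k = int(pos.sum()) if n_axes is None else min(n_axes, int(pos.sum()))
    coords = evecs[:, :k] * np.sqrt(np.clip(evals[:k], 0, None))
    # orient each axis: the sample with the largest |coordinate| is positive
    for j in range(k):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    denom = evals[evals > 0].sum()
    prop = (evals[:k] / denom) if denom > 0 else np.zeros(k)
    frame = pd.DataFrame(coords, index=list(dm.ids),
                         columns=[f"PC{j + 1}" for j in range(k)])
    return OrdinationResult(frame, evals, prop)


# ---------------------------------------------------------------------------
# PERMANOVA


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    """(SS_total, SS_within) from squared distances and integer labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int, n: int) -> float:
    ss_total, ss_within = _permanova_ss(d2, codes, n_groups)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return math.inf if ss_between > 0 else 0.0
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(dm: DistanceMatrix, grouping, n_perm: int = 999,
              seed: int | None = None, exact: bool = False) -> TestResult:
    """One-way PERMANOVA on a distance matrix.

    ``grouping`` maps each sample (by position or via a pandas Series
    indexed by sample id) to its group.  With ``exact=True`` every distinct
    label permutation is enumerated and p is the exact tail fraction;
    otherwise p follows the add-one Monte-Carlo rule
    ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    ids = list(dm.ids)
    if isinstance(grouping, pd.Series):
        labels = grouping.reindex(ids).to_numpy()
    else:
        labels = np.asarray(grouping)
    if len(labels) != len(ids):
        raise ValueError("grouping length must match the distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        small = uniq[int(np.argmin(sizes))]
        raise ValueError(f"group {small!r} has fewer than 2 members")
    n = len(ids)
    d2 = np.asarray(dm.data, dtype=float) ** 2
    f_obs = _pseudo_f(d2, codes, len(uniq), n)
    if f_obs == 0.0 and d2.max() == 0:
        # all samples identical: no structure to test
        return TestResult(0.0, 1.0, "PERMANOVA", n=n,
                          extras={"degenerate": True, "n_perm": 0})
    if exact:
        perms = itertools.permutations(codes)
        seen = set()
        count = total = 0
        for p in perms:
            if p in seen:
                continue
            seen.add(p)
            total += 1
            if _pseudo_f(d2, np.asarray(p), len(uniq), n) >= f_obs - 1e-12:
                count += 1
        p_val = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        perm_codes = codes.copy()
        for _ in range(n_perm):
            rng.shuffle(perm_codes)
            if _pseudo_f(d2, perm_codes, len(uniq), n) >= f_obs - 1e-12:
                count += 1
        p_val = (1 + count) / (1 + n_perm)
        n_used = n_perm
    return TestResult(float(f_obs), float(p_val), "PERMANOVA", n=n,
                      df=len(uniq) - 1,
                      extras={"n_perm": n_used, "seed": seed, "exact": exact})


# ---------------------------------------------------------------------------
# regression of darkness on ordination axes


@dataclass
class AxisRegressionResult:
    """OLS of darkness on the first ordination axes."""

    params: pd.Series
    p_values: pd.Series
    t_values: pd.Series
    r_squared: float
    n: int
    model: object  # underlying statsmodels results


def regress_on_axes(darkness: pd.Series, ordination: OrdinationResult,
                    n_axes: int = 2) -> AxisRegressionResult:
    """Fit ``darkness ~ PC1 + ... + PCk`` by ordinary least squares."""
    coords = ordination.coordinates.iloc[:, :n_axes]
    common = coords.index.intersection(darkness.dropna().index)
    if len(common) < n_axes + 1:
        raise ValueError("need more swabs than axes for the regression")
    y = darkness.loc[common].astype(float)
    if y.nunique() == 1:
        raise ValueError("darkness is constant: regression undefined")
    x = sm.add_constant(coords.loc[common])
    res = sm.OLS(y, x).fit()
    return AxisRegressionResult(res.params, res.pvalues, res.tvalues,
                                float(res.rsquared), len(common), res)


def mean_distance_to_reference(ordination: OrdinationResult, swab_ids,
                               reference_ids, n_axes: int = 2) -> pd.Series:
    """Mean Euclidean distance of each swab to all reference samples.

    Measured in the first *n_axes* ordination axes (the plotted plane by
    default); pass ``n_axes=None`` to use every retained axis.
    """
    reference_ids = list(reference_ids)
    if not reference_ids:
        raise ValueError("reference set is empty")
    coords = ordination.coordinates if n_axes is None \
        else ordination.coordinates.iloc[:, :n_axes]
    refs = coords.loc[reference_ids].to_numpy()
    out = {}
    for sid in swab_ids:
        p = coords.loc[sid].to_numpy()
        out[sid] = float(np.linalg.norm(refs - p, axis=1).mean())
    return pd.Series(out, name="mean_distance")


# ---------------------------------------------------------------------------
# nonparametric battery


def kruskal_wallis(values, groups) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square p)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("Kruskal-Wallis needs >= 2 groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    if np.all(values == values[0]):
        return TestResult(0.0, 1.0, "Kruskal-Wallis", df=len(samples) - 1,
                          n=len(values))
    h, p = stats.kruskal(*samples)
    return TestResult(float(h), float(p), "Kruskal-Wallis",
                      df=len(samples) - 1, n=len(values))


def pairwise_wilcoxon_fdr(values, groups) -> pd.DataFrame:
    """Wilcoxon rank-sum for every group pair, BH-adjusted.

    Uses the normal approximation with tie and continuity corrections (the
    group sizes in this pipeline are always >= 13).  Returns a frame with
    columns ``group_a``, ``group_b``, ``statistic``, ``p``, ``q``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    rows = []
    for a, b in itertools.combinations(labels, 2):
        xa, xb = values[groups == a], values[groups == b]
        if len(xa) == 0 or len(xb) == 0:
            raise ValueError("empty group")
        stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                     method="asymptotic")
        rows.append((a, b, float(stat), float(p)))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def spearman(x, y) -> TestResult:
    """Spearman rank correlation; p via the t approximation with n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("Spearman needs >= 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman undefined for a constant input")
    rho, p = stats.spearmanr(x, y)
    return TestResult(float(rho), float(p), "Spearman", df=len(x) - 2, n=len(x))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` on the sorted p-values, capped
    at 1 and mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
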