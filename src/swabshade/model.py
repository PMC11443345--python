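"""Study-level model: darkness vs rumen-community capture.

:class:`SwabColorStudy` bundles an ASV count table, sample metadata
(with per-swab darkness scores) and optional taxonomy/phylogeny, and its
:meth:`~SwabColorStudy.fit` runs the full analysis chain:

1. normalization — off-target removal, rarefaction, >=10-read cell filter;
2. darkness grouping — decile percentiles and the Low/Mid/High extremes;
3. alpha diversity (Chao1 / Shannon / inverse Simpson) with
   Kruskal-Wallis, pairwise Wilcoxon (BH) and Spearman vs darkness;
4. beta diversity, PCoA, PERMANOVA over color/rumen groups;
5. OLS of darkness on the first two ordination axes; mean ordination
   distance of each swab to the rumen solid and liquid samples, with
   Spearman correlations against darkness;
6. SIMPER (>1% gate) + Kruskal-Wallis differential ASVs between the
   lightest and darkest groups;
7. highly prevalent rumen ASV sets and per-swab capture percentages,
   correlated with darkness.

The returned :class:`StudyResults` carries every intermediate product,
prints a summary table, and can write all stage outputs to disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, io, ordination
from .differential import (
    PrevalentSet,
    capture_darkness_correlation,
    capture_fraction,
    differential_asvs,
    prevalent_set,
)
from .io import CommunityTable
from .ordination import OrdinationResult, TestResult


@dataclass
class StudyConfig:
    """Tunable parameters of one study run (defaults: bacterial 16S run)."""

    rarefaction_depth: int = 7_000
    min_count: int = 10
    extremes_k: int = 13
    simper_threshold: float = 0.01
    prevalence_threshold: float = 0.8
    n_perm: int = 999
    alpha: float = 0.05
    beta_metric: str = "braycurtis"
    jaccard_binary: bool = False
    reference_distance_axes: int | None = 2
    seed: int = 0

    def validate(self) -> list[str]:
        errs = []
        if self.rarefaction_depth < 1:
            errs.append("rarefaction_depth must be >= 1")
        if self.min_count < 1:
            errs.append("min_count must be >= 1")
        if self.extremes_k < 1:
            errs.append("extremes_k must be >= 1")
        if not 0.0 <= self.simper_threshold < 1.0:
            errs.append("simper_threshold must lie in [0, 1)")
        if not 0.0 < self.prevalence_threshold < 1.0:
            errs.append("prevalence_threshold must lie in (0, 1)")
        if self.n_perm < 1:
            errs.append("n_perm must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            errs.append("alpha must lie in (0, 1)")
        return errs


class SwabColorStudy:
    """Model linking swab darkness to rumen-microbiome recapitulation.

    Parameters
    ----------
    counts : CommunityTable
        Raw ASV counts, samples x ASVs.
    metadata : DataFrame
        Indexed by sample id with ``sample_type`` in
        {swab, rumen_liquid, rumen_solid} and per-swab ``darkness``.
    taxonomy : DataFrame, optional
        ASV -> Kingdom..Species; enables off-target removal.
    tree : skbio.TreeNode, optional
        Rooted phylogeny over the ASVs; enables UniFrac.
    config : StudyConfig, optional
    """

    def __init__(self, counts: CommunityTable, metadata: pd.DataFrame,
                 taxonomy: pd.DataFrame | None = None, tree=None,
                 config: StudyConfig | None = None):
        self.counts = counts
        self.metadata = metadata.copy()
        self.taxonomy = taxonomy
        self.tree = tree
        self.config = config or StudyConfig()
        errs = self.config.validate()
        if errs:
            raise ValueError("invalid study config: " + "; ".join(errs))
        missing = set(counts.sample_ids) - set(metadata.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)[:3]}")

    @classmethod
    def from_tsv(cls, counts_path: str, metadata_path: str,
                 taxonomy_path: str | None = None, tree_path: str | None = None,
                 config: StudyConfig | None = None) -> "SwabColorStudy":
        from skbio import TreeNode

        counts = io.read_count_table(counts_path)
        metadata = io.read_metadata(metadata_path)
        taxonomy = io.read_taxonomy(taxonomy_path) if taxonomy_path else None
        tree = TreeNode.read(tree_path) if tree_path else None
        return cls(counts, metadata, taxonomy, tree, config)

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "StudyResults":
        cfg = self.config
        # 1. normalization
        table = self.counts
        if self.taxonomy is not None:
            table = io.remove_taxa(table, self.taxonomy)
        table = io.rarefy(table, cfg.rarefaction_depth, seed=cfg.seed)
        table = io.min_count_filter(table, cfg.min_count)
        meta = self.metadata.loc[table.sample_ids].copy()
        rel = io.relative_abundance(table)

        # 2. darkness grouping
        meta = io.assign_percentile_groups(meta)
        meta = io.assign_extremes_groups(meta, k=cfg.extremes_k)
        swabs = meta.index[(meta["sample_type"] == "swab")
                           & meta["darkness"].notna()]
        solids = list(meta.index[meta["sample_type"] == "rumen_solid"])
        liquids = list(meta.index[meta["sample_type"] == "rumen_liquid"])

        # 3. alpha diversity + tests
        alpha = diversity.alpha_table(table)
        alpha_tests = self._alpha_tests(alpha, meta, swabs)

        # 4. beta diversity / ordination / PERMANOVA over extremes + rumen
        dm = diversity.distance_matrix(table, cfg.beta_metric, tree=self.tree)
        ord_res = ordination.pcoa(dm)
        group = meta["extremes_group"].astype("object").copy()
        group[meta["sample_type"] == "rumen_solid"] = "rumen_solid"
        group[meta["sample_type"] == "rumen_liquid"] = "rumen_liquid"
        tested = group.dropna().index
        perm = ordination.permanova(
            dm.filter(tested), group.loc[tested],
            n_perm=cfg.n_perm, seed=cfg.seed,
        )

        # 5. axes regression + mean distance to rumen references
        darkness = meta.loc[swabs, "darkness"].astype(float)
        axis_reg = ordination.regress_on_axes(darkness, ord_res)
        ref_dist = pd.DataFrame({
            "dist_to_solid": ordination.mean_distance_to_reference(
                ord_res, swabs, solids, n_axes=cfg.reference_distance_axes),
            "dist_to_liquid": ordination.mean_distance_to_reference(
                ord_res, swabs, liquids, n_axes=cfg.reference_distance_axes),
        })
        dist_corr = {
            "rumen_solid": ordination.spearman(darkness, ref_dist["dist_to_solid"]),
            "rumen_liquid": ordination.spearman(darkness, ref_dist["dist_to_liquid"]),
        }

        # 6. SIMPER + KW differential ASVs between lightest and darkest
        low = list(meta.index[meta["extremes_group"] == "Low"])
        high = list(meta.index[meta["extremes_group"] == "High"])
        differential = differential_asvs(
            rel, low, high, simper_threshold=cfg.simper_threshold,
            alpha=cfg.alpha,
        )

        # 7. prevalent rumen sets + per-swab capture vs darkness
        pset_liquid = prevalent_set(table, liquids, cfg.prevalence_threshold,
                                    "rumen_liquid")
        pset_solid = prevalent_set(table, solids, cfg.prevalence_threshold,
                                   "rumen_solid", other_set=pset_liquid)
        pset_liquid.unique_ids = sorted(
            set(pset_liquid.asv_ids) - set(pset_solid.asv_ids))
        capture, capture_corr = {}, {}
        for label, pset in (("rumen_solid", pset_solid),
                            ("rumen_liquid", pset_liquid)):
            if pset.n_total:
                recs = capture_fraction(table, swabs, pset)
                capture[label] = recs
                capture_corr[label] = capture_darkness_correlation(recs, darkness)

        return StudyResults(
            config=cfg, table=table, rel_table=rel, metadata=meta,
            alpha=alpha, alpha_tests=alpha_tests, distance_matrix=dm,
            ordination=ord_res, permanova=perm, axis_regression=axis_reg,
            reference_distances=ref_dist, distance_correlations=dist_corr,
            differential=differential,
            prevalent_sets={"rumen_solid": pset_solid,
                            "rumen_liquid": pset_liquid},
            capture=capture, capture_correlations=capture_corr,
        )

    def _alpha_tests(self, alpha: pd.DataFrame, meta: pd.DataFrame,
                     swabs) -> dict:
        """KW across extremes+rumen groups, pairwise Wilcoxon, Spearman."""
        group = meta["extremes_group"].astype("object").copy()
        group[meta["sample_type"] == "rumen_solid"] = "rumen_solid"
        group[meta["sample_type"] == "rumen_liquid"] = "rumen_liquid"
        tested = group.dropna().index
        darkness = meta.loc[swabs, "darkness"].astype(float)
        out = {}
        for metric in alpha.columns:
            res = {
                "kruskal": ordination.kruskal_wallis(
                    alpha.loc[tested, metric].to_numpy(),
                    group.loc[tested].to_numpy()),
                "spearman_darkness": ordination.spearman(
                    darkness, alpha.loc[swabs, metric]),
            }
            if res["kruskal"].p_value < self.config.alpha:
                res["pairwise"] = ordination.pairwise_wilcoxon_fdr(
                    alpha.loc[tested, metric].to_numpy(),
                    group.loc[tested].to_numpy())
            out[metric] = res
        return out


@dataclass
class StudyResults:
    """Everything :meth:`SwabColorStudy.fit` computed."""

    config: StudyConfig
    table: CommunityTable  # rarefied + filtered counts
    rel_table: CommunityTable
    metadata: pd.DataFrame  # with group assignments
    alpha: pd.DataFrame
    alpha_tests: dict
    distance_matrix: object
    ordination: OrdinationResult
    permanova: TestResult
    axis_regression: ordination.AxisRegressionResult
    reference_distances: pd.DataFrame
    distance_correlations: dict[str, TestResult]
    differential: pd.DataFrame
    prevalent_sets: dict[str, PrevalentSet]
    capture: dict[str, pd.DataFrame]
    capture_correlations: dict[str, TestResult]

    # -- reporting ----------------------------------------------------------

    def headline(self) -> dict:
        """Machine-readable headline statistics."""
        dark = self.metadata.loc[self.metadata["sample_type"] == "swab",
                                 "darkness"].dropna()
        out = {
            "n_samples_analyzed": len(self.table.sample_ids),
            "n_samples_dropped_rarefaction": len(
                self.table.provenance.get("rarefaction_dropped", [])),
            "n_asvs": len(self.table.asv_ids),
            "darkness_min": float(dark.min()),
            "darkness_median": float(dark.median()),
            "darkness_max": float(dark.max()),
            "permanova_F": self.permanova.statistic,
            "permanova_p": self.permanova.p_value,
            "axis_regression_r2": self.axis_regression.r_squared,
            "n_differential_asvs": int(self.differential["significant"].sum())
            if len(self.differential) else 0,
        }
        for label, res in self.distance_correlations.items():
            out[f"spearman_darkness_dist_{label}"] = res.statistic
            out[f"spearman_darkness_dist_{label}_p"] = res.p_value
        for label, pset in self.prevalent_sets.items():
            out[f"n_prevalent_{label}"] = pset.n_total
            out[f"n_prevalent_{label}_unique"] = pset.n_unique
        for label, res in self.capture_correlations.items():
            out[f"spearman_darkness_capture_{label}"] = res.statistic
            out[f"spearman_darkness_capture_{label}_p"] = res.p_value
        for metric, tests in self.alpha_tests.items():
            out[f"spearman_darkness_{metric}"] = \
                tests["spearman_darkness"].statistic
        return out

    def summary(self) -> str:
        """Human-readable study summary."""
        h = self.headline()
        cfg = self.config
        lines = [
            "Swab darkness vs rumen community capture",
            "=" * 56,
            f"samples analysed            {h['n_samples_analyzed']:>8d}  "
            f"(rarefaction dropped {h['n_samples_dropped_rarefaction']})",
            f"ASVs after filtering        {h['n_asvs']:>8d}",
            f"rarefaction depth           {cfg.rarefaction_depth:>8d}  "
            f"min count/cell {cfg.min_count}",
            f"darkness range              {h['darkness_min']:.4f} - "
            f"{h['darkness_max']:.4f}  (median {h['darkness_median']:.4f})",
            "-" * 56,
            f"PERMANOVA (groups)          F = {h['permanova_F']:.3f}, "
            f"p = {h['permanova_p']:.4g}",
            f"darkness ~ PC1 + PC2        R^2 = {h['axis_regression_r2']:.3f}",
        ]
        for metric in self.alpha.columns:
            rho = h[f"spearman_darkness_{metric}"]
            lines.append(f"Spearman darkness vs {metric:<12s} rho = {rho:+.3f}")
        for label in self.distance_correlations:
            lines.append(
                f"Spearman darkness vs dist({label}): "
                f"rho = {h[f'spearman_darkness_dist_{label}']:+.3f} "
                f"(p = {h[f'spearman_darkness_dist_{label}_p']:.3g})")
        for label, pset in self.prevalent_sets.items():
            lines.append(
                f"prevalent {label}: {pset.n_total} total, "
                f"{pset.n_unique} unique (> {pset.threshold:.0%} prevalence)")
        for label in self.capture_correlations:
            lines.append(
                f"Spearman darkness vs capture({label}): "
                f"rho = {h[f'spearman_darkness_capture_{label}']:+.3f} "
                f"(p = {h[f'spearman_darkness_capture_{label}_p']:.3g})")
        lines.append(
            f"differential ASVs (Low vs High, SIMPER > "
            f"{cfg.simper_threshold:.0%}, q < {cfg.alpha}): "
            f"{h['n_differential_asvs']}")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, str]:
        """Write every stage output (TSV/JSON) under *outdir*."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}

        def tsv(name, df, **kw):
            p = out / f"{name}.tsv"
            df.to_csv(p, sep="\t", **kw)
            paths[name] = str(p)

        tsv("filtered_counts", self.table.df, index_label="sample_id")
        tsv("metadata_grouped", self.metadata, index_label="sample_id")
        tsv("alpha_diversity", self.alpha, index_label="sample_id")
        tsv("ordination_coordinates", self.ordination.coordinates,
            index_label="sample_id")
        tsv("reference_distances", self.reference_distances,
            index_label="sample_id")
        if len(self.differential):
            tsv("differential_asvs", self.differential)
        for label, recs in self.capture.items():
            tsv(f"capture_{label}", recs)
        for label, pset in self.prevalent_sets.items():
            tsv(f"prevalent_{label}",
                pd.DataFrame({"asv_id": pset.asv_ids}), index=False)
        report = {
            "config": asdict(self.config),
            "headline": self.headline(),
            "rarefaction_dropped": self.table.provenance.get(
                "rarefaction_dropped", []),
        }
        p = out / "report.json"
        p.write_text(json.dumps(report, indent=1, default=float))
        paths["report"] = str(p)
        (out / "summary.txt").write_text(self.summary() + "\n")
        paths["summary"] = str(out / "summary.txt")
        return paths
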