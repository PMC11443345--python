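"""Synthetic study generator: darkness-linked swab communities.

Emulates an oral-swab study of the rumen microbiome in which each swab
community is a mixture of rumen (solid + liquid) and oral/environmental
reference pools, with the rumen mixing fraction ``alpha`` linked
monotonically to the photographed darkness of the swab::

    p_swab     = alpha * (w_s * solid + w_l * liquid)
               + (1 - alpha) * (w_o * oral + w_e * environmental)
    counts     ~ DirichletMultinomial(p_swab * concentration, depth)
    darkness   = clip(d0 + d1 * alpha + Normal(0, sigma_d), 0, 1)

The generator also renders matching flat-plus-noise swab images, draws a
random rooted phylogeny over the ASVs, and records the planted truth
(per-swab alpha, per-ASV source pool, and the set of ASVs that truly
differ between light and dark swabs) for recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .colorimetry import DarknessScore, SwabImage
from .io import CommunityTable

POOL_LABELS = ("rumen_solid", "rumen_liquid", "oral", "environmental")

# Genus pools used to fabricate taxonomy strings.  Rumen genera follow the
# classic fibre/VFA community; oral/environmental genera are the taxa known
# to dominate bovine mouths and farm environments.
_RUMEN_GENERA = [
    "Prevotella", "Succiniclasticum", "Succinivibrionaceae_UCG-001",
    "Ruminococcus", "Fibrobacter", "Butyrivibrio", "Treponema",
    "Christensenellaceae_R-7", "NK4A214_group", "Rikenellaceae_RC9",
]
_ORAL_ENV_GENERA = [
    "Moraxella", "Bibersteinia", "Streptococcus", "Rothia", "Alysiella",
    "Neisseriaceae_unclassified", "Pasteurellaceae_unclassified",
    "Acinetobacter", "Psychrobacter", "Sphingomonas",
]
_PHYLA = {
    "rumen": ["Bacteroidota", "Firmicutes", "Fibrobacterota", "Spirochaetota"],
    "oral": ["Proteobacteria", "Actinobacteriota", "Firmicutes"],
}


@dataclass
class ReferenceCommunity:
    """One source pool: a fixed composition plus Dirichlet overdispersion."""

    label: str
    base_proportions: pd.Series  # indexed by ASV id, sums to 1
    overdispersion: float = 200.0  # Dirichlet concentration (sum of alphas)

    def __post_init__(self) -> None:
        if self.label not in POOL_LABELS:
            raise ValueError(f"unknown pool label {self.label!r}")
        p = self.base_proportions.to_numpy(dtype=float)
        if (p < 0).any():
            raise ValueError("proportions must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("proportions must sum to 1 within 1e-12")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be > 0")


@dataclass
class MixtureDesign:
    """Shape and parameters of one simulated study.

    Defaults reproduce the study design emulated throughout the package:
    402 swabs plus 13 rumen-liquid and 12 rumen-solid reference samples;
    rumen fraction ``alpha ~ Beta(2, 2)`` per swab; darkness linked as
    ``0.35 + 0.39 * alpha + N(0, 0.02)`` so scores span roughly 0.35-0.74;
    per-sample sequencing depth log-normal around ~30k reads with a heavy
    spread so that a realistic minority of swabs fall below a 7,000-read
    rarefaction depth.
    """

    n_swabs: int = 402
    n_liquid: int = 13
    n_solid: int = 12
    alpha_beta: tuple[float, float] = (2.0, 2.0)
    d0: float = 0.35
    d1: float = 0.39
    sigma_d: float = 0.02
    depth_meanlog: float = math.log(25_000.0)
    depth_sdlog: float = 0.9
    min_depth: int = 1_000
    # mixture weights inside the rumen and non-rumen halves
    w_solid: float = 0.6
    w_liquid: float = 0.4
    w_oral: float = 0.7
    w_env: float = 0.3
    concentration: float = 200.0
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_swabs, self.n_liquid, self.n_solid) < 1:
            raise ValueError("all sample counts must be >= 1")
        if not (0.0 <= self.d0 <= 1.0 and 0.0 <= self.d0 + self.d1 <= 1.0):
            raise ValueError("darkness link must keep d0 and d0+d1 in [0, 1]")
        for pair in ((self.w_solid, self.w_liquid), (self.w_oral, self.w_env)):
            if abs(sum(pair) - 1.0) > 1e-9:
                raise ValueError("mixture weight pairs must each sum to 1")


@dataclass
class PlantedTruth:
    """Ground truth recorded by the generator for recovery tests.

    ``differential_asvs`` are the ASVs constructed to differ between light
    and dark swabs strongly enough to be targets of the gated differential
    analysis; ``borderline_asvs`` also truly differ but sit just under the
    gate (an indeterminate zone), so recovery evaluations count them
    neither as hits nor as false positives.
    """

    alpha: pd.Series  # per-swab rumen fraction
    asv_source: pd.Series  # per-ASV source pool label
    differential_asvs: list[str]  # ASVs truly differing between light/dark
    borderline_asvs: list[str] = field(default_factory=list)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        obj = {
            "seed": self.seed,
            "alpha": {k: float(v) for k, v in self.alpha.items()},
            "asv_source": dict(self.asv_source),
            "differential_asvs": list(self.differential_asvs),
            "borderline_asvs": list(self.borderline_asvs),
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    def recovery(self, detected) -> dict[str, float]:
        """Sensitivity and false-discovery proportion of a detected ASV set.

        Borderline ASVs are indeterminate: excluded from the truth set and
        from the false-positive count.
        """
        det = set(detected)
        truth = set(self.differential_asvs)
        border = set(self.borderline_asvs)
        scored = det - border
        fp = scored - truth
        return {
            "sensitivity": len(det & truth) / len(truth) if truth else float("nan"),
            "fdr": len(fp) / len(scored) if scored else 0.0,
            "n_detected": len(det),
            "n_truth": len(truth),
        }


def simulate_references(
    n_asvs_per_pool: int = 160,
    overlap: float = 0.25,
    concentration: float = 200.0,
    seed: int = 0,
) -> list[ReferenceCommunity]:
    """Draw the four source pools with log-normal-ranked compositions.

    ``rumen_solid`` and ``rumen_liquid`` share exactly
    ``round(overlap * n_asvs_per_pool)`` ASV ids (the two rumen fractions
    overlap but remain distinct); the oral and environmental pools use
    fresh ids.
    """
    if n_asvs_per_pool < 5:
        raise ValueError("need at least 5 ASVs per pool")
    if not 0.0 <= overlap < 1.0:
        raise ValueError(f"overlap must lie in [0, 1); got {overlap}")
    rng = np.random.default_rng(seed)
    n_shared = round(overlap * n_asvs_per_pool)
    counter = 0

    def fresh(n: int) -> list[str]:
        nonlocal counter
        ids = [f"ASV{counter + i + 1:04d}" for i in range(n)]
        counter += n
        return ids

    solid_ids = fresh(n_asvs_per_pool)
    shared = solid_ids[:n_shared]
    liquid_ids = shared + fresh(n_asvs_per_pool - n_shared)
    pools = {
        "rumen_solid": solid_ids,
        "rumen_liquid": liquid_ids,
        "oral": fresh(n_asvs_per_pool),
        "environmental": fresh(n_asvs_per_pool),
    }
    refs = []
    for label, ids in pools.items():
        weights = rng.lognormal(mean=0.0, sigma=1.2, size=len(ids))
        props = pd.Series(weights / weights.sum(), index=ids)
        refs.append(ReferenceCommunity(label, props, concentration))
    return refs


def _union_proportions(refs: list[ReferenceCommunity]) -> pd.DataFrame:
    """Pool compositions aligned on the union ASV index (absent -> 0)."""
    frames = {r.label: r.base_proportions for r in refs}
    df = pd.DataFrame(frames).fillna(0.0)
    # deterministic ASV order
    return df.sort_index()


def expected_swab_proportions(alpha: float, refs: list[ReferenceCommunity],
                              design: MixtureDesign) -> pd.Series:
    """Noise-free expected composition of a swab with rumen fraction *alpha*."""
    pools = _union_proportions(refs)
    rumen = design.w_solid * pools["rumen_solid"] + design.w_liquid * pools["rumen_liquid"]
    other = design.w_oral * pools["oral"] + design.w_env * pools["environmental"]
    return alpha * rumen + (1.0 - alpha) * other


def _dirichlet_multinomial(p: np.ndarray, concentration: float, depth: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Draw counts ~ DM(p * concentration, depth); infinite concentration
    degenerates to a plain multinomial."""
    if depth <= 0:
        raise ValueError(f"depth must be positive; got {depth}")
    if np.isinf(concentration):
        return rng.multinomial(depth, p)
    support = p > 0
    theta = np.zeros_like(p)
    theta[support] = rng.dirichlet(p[support] * concentration)
    return rng.multinomial(depth, theta)


def simulate_swab(
    alpha: float,
    refs: list[ReferenceCommunity],
    depth: int,
    rng: np.random.Generator,
    design: MixtureDesign | None = None,
) -> tuple[pd.Series, DarknessScore]:
    """Draw one swab's ASV counts and its linked darkness score."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1]; got {alpha}")
    design = design or MixtureDesign()
    p = expected_swab_proportions(alpha, refs, design)
    counts = _dirichlet_multinomial(
        p.to_numpy(), design.concentration, depth, rng
    )
    d = design.d0 + design.d1 * alpha
    if design.sigma_d > 0:
        d += rng.normal(0.0, design.sigma_d)
    score = DarknessScore(float(np.clip(d, 0.0, 1.0)))
    return pd.Series(counts, index=p.index), score


def _planted_differential(
    alpha_draws: np.ndarray,
    refs: list[ReferenceCommunity],
    design: MixtureDesign,
    k: int = 13,
    threshold: float = 0.01,
) -> tuple[list[str], list[str]]:
    """(planted, borderline) ASVs differing between lightest/darkest swabs.

    The expected compositions at the mean alpha of the k lowest and k
    highest draws are compared; an ASV is planted-differential when its
    share of the light/dark L1 difference exceeds *threshold* — the same
    >1% contribution gate the downstream decomposition applies.  ASVs in
    ``(threshold/2, threshold]`` also truly differ but are not analysis
    targets; they are returned separately as the indeterminate zone.
    """
    srt = np.sort(alpha_draws)
    a_light = float(srt[:k].mean())
    a_dark = float(srt[-k:].mean())
    p_light = expected_swab_proportions(a_light, refs, design)
    p_dark = expected_swab_proportions(a_dark, refs, design)
    diff = (p_light - p_dark).abs()
    contrib = diff / diff.sum()
    planted = sorted(contrib.index[contrib > threshold])
    borderline = sorted(
        contrib.index[(contrib > threshold / 2) & (contrib <= threshold)])
    return planted, borderline


def simulate_dataset(
    design: MixtureDesign | None = None,
    refs: list[ReferenceCommunity] | None = None,
) -> tuple[CommunityTable, pd.DataFrame, PlantedTruth]:
    """Generate one full synthetic study.

    Returns the counts table (samples x ASVs), the sample metadata
    (``sample_type``, ``darkness``), and the planted truth.  Rumen
    reference samples are drawn from their own pool; swabs per
    :func:`simulate_swab`.  Fully reproducible under ``design.seed``.
    """
    design = design or MixtureDesign()
    rng = np.random.default_rng(design.seed)
    if refs is None:
        refs = simulate_references(seed=int(rng.integers(2**31)))
    pools = _union_proportions(refs)
    n_total = design.n_swabs + design.n_liquid + design.n_solid
    depths = np.maximum(
        rng.lognormal(design.depth_meanlog, design.depth_sdlog, n_total).astype(int),
        design.min_depth,
    )

    alpha_draws = rng.beta(*design.alpha_beta, size=design.n_swabs)
    rows, meta = [], []
    for i in range(design.n_swabs):
        sid = f"Swab{i + 1:03d}"
        counts, score = simulate_swab(alpha_draws[i], refs, int(depths[i]), rng, design)
        counts.name = sid
        rows.append(counts)
        meta.append((sid, "swab", score.value))
    for j, (stype, label, n) in enumerate(
        [("rumen_liquid", "rumen_liquid", design.n_liquid),
         ("rumen_solid", "rumen_solid", design.n_solid)]
    ):
        for i in range(n):
            sid = f"{'Liq' if stype == 'rumen_liquid' else 'Sol'}{i + 1:02d}"
            depth = int(depths[design.n_swabs + (j * design.n_liquid) + i])
            counts = pd.Series(
                _dirichlet_multinomial(
                    pools[label].to_numpy(), design.concentration, depth, rng
                ),
                index=pools.index, name=sid,
            )
            rows.append(counts)
            meta.append((sid, stype, np.nan))

    counts_df = pd.DataFrame(rows).astype(int)
    metadata = pd.DataFrame(meta, columns=["sample_id", "sample_type", "darkness"])
    metadata = metadata.set_index("sample_id")
    planted, borderline = _planted_differential(
        alpha_draws, refs, design, k=min(13, design.n_swabs // 3))
    truth = PlantedTruth(
        alpha=pd.Series(alpha_draws, index=counts_df.index[: design.n_swabs],
                        name="alpha"),
        asv_source=_source_labels(refs),
        differential_asvs=planted,
        borderline_asvs=borderline,
        seed=design.seed,
    )
    return CommunityTable(counts_df, mode="counts"), metadata, truth


def _source_labels(refs: list[ReferenceCommunity]) -> pd.Series:
    """One source label per ASV; ids shared by both rumen pools are tagged
    ``rumen_shared`` so every ASV carries exactly one label."""
    owner: dict[str, str] = {}
    for r in refs:
        for asv in r.base_proportions.index:
            if asv in owner:
                owner[asv] = "rumen_shared"
            else:
                owner[asv] = r.label
    return pd.Series(owner, name="source").sort_index()


def simulate_taxonomy(asv_source: pd.Series, seed: int = 0) -> pd.DataFrame:
    """Fabricate a Kingdom..Species taxonomy table consistent with source pools."""
    rng = np.random.default_rng(seed)
    rows = []
    for asv, src in asv_source.items():
        rumen = src in ("rumen_solid", "rumen_liquid", "rumen_shared")
        genus = rng.choice(_RUMEN_GENERA if rumen else _ORAL_ENV_GENERA)
        phylum = rng.choice(_PHYLA["rumen" if rumen else "oral"])
        rows.append((asv, "Bacteria", phylum, f"{phylum}_class",
                     f"{genus}_order", f"{genus}aceae", genus, "unclassified"))
    return pd.DataFrame(
        rows,
        columns=["asv_id", "Kingdom", "Phylum", "Class", "Order", "Family",
                 "Genus", "Species"],
    ).set_index("asv_id")


def render_swab_image(
    darkness: float | DarknessScore,
    size: int = 100,
    texture_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    sample_id: str = "",
) -> SwabImage:
    """Render a flat grayscale swab image whose mean intensity encodes *darkness*.

    Pixel values are ``255 * (1 - darkness)`` plus optional Gaussian texture
    noise, clipped to [0, 255] and kept as floats so that
    ``darkness_score(render(d))`` recovers ``d`` exactly when
    ``texture_sd == 0``.
    """
    d = darkness.value if isinstance(darkness, DarknessScore) else float(darkness)
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"darkness must lie in [0, 1]; got {d}")
    if size < 100:
        raise ValueError(f"image size must be >= 100 px for scoring; got {size}")
    base = np.full((size, size), 255.0 * (1.0 - d))
    if texture_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        base = base + rng.normal(0.0, texture_sd, base.shape)
    return SwabImage(np.clip(base, 0.0, 255.0), sample_id)


def simulate_tree(asv_ids: list[str], seed: int = 0) -> TreeNode:
    """Random rooted binary tree over *asv_ids* with exponential branch lengths."""
    ids = list(asv_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 ASVs for a tree")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ASV ids in tree leaf set")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=i, length=float(rng.exponential(1.0))) for i in ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(1.0)), children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def write_dataset(
    outdir: str | Path,
    table: CommunityTable,
    metadata: pd.DataFrame,
    truth: PlantedTruth,
    taxonomy: pd.DataFrame | None = None,
    tree: TreeNode | None = None,
    images: bool = False,
    image_texture_sd: float = 10.0,
) -> dict[str, str]:
    """Write the synthetic study to TSV/Newick/JSON (and optional PNGs).

    Every TSV carries the generator seed in a ``#`` header comment.
    Returns a name -> path map of everything written.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# seed={truth.seed}\n"
    paths: dict[str, str] = {}

    def _tsv(name: str, df: pd.DataFrame, index_label: str) -> None:
        p = out / name
        with open(p, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index_label=index_label)
        paths[name.removesuffix(".tsv")] = str(p)

    _tsv("counts.tsv", table.df, "sample_id")
    _tsv("metadata.tsv", metadata, "sample_id")
    if taxonomy is not None:
        _tsv("taxonomy.tsv", taxonomy, "asv_id")
    if tree is not None:
        p = out / "tree.nwk"
        tree.write(str(p))
        paths["tree"] = str(p)
    truth.to_json(out / "truth.json")
    paths["truth"] = str(out / "truth.json")
    if images:
        from PIL import Image

        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        rng = np.random.default_rng(truth.seed + 1)
        manifest_rows = []
        for sid, d in metadata["darkness"].dropna().items():
            img = render_swab_image(float(d), 100, image_texture_sd, rng, sid)
            arr = np.clip(np.rint(img.pixels), 0, 255).astype(np.uint8)
            p = img_dir / f"{sid}.png"
            Image.fromarray(arr, mode="L").save(p)
            manifest_rows.append((sid, str(p)))
        manifest = pd.DataFrame(manifest_rows, columns=["sample_id", "image_path"])
        mp = out / "image_manifest.tsv"
        with open(mp, "w") as fh:
            fh.write(header)
            manifest.to_csv(fh, sep="\t", index=False)
        paths["image_manifest"] = str(mp)
    return paths
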