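# swabshade

**Colorimetric swab scoring and darkness-stratified rumen microbiome
analysis.**

Oral swabs are an attractive non-invasive proxy for sampling the rumen
microbiome of dairy cattle: they pick up regurgitated rumen contents
during rumination. But swab quality varies widely, and one visible
correlate of quality is the swab's color — cows fed a total mixed ration
produce swabs ranging from near-white to dark brown depending on how much
rumen material was collected. `swabshade` implements the full analysis
chain for asking *how well does swab darkness predict a swab's ability to
recapitulate the rumen microbial community?*

The package provides:

- **Colorimetry** — reduce a swab photograph to a darkness score
  `d = 1 − mean(gray)/255 ∈ [0, 1]` (0 = white, 1 = black) via a centred
  100 × 100 px crop and BT.601 grayscale conversion.
- **Community analysis** — rarefaction, a ≥10-reads-per-cell abundance
  filter, alpha diversity (bias-corrected Chao1, Shannon, inverse
  Simpson), Bray-Curtis / Jaccard / unweighted UniFrac beta diversity,
  PCoA, one-way PERMANOVA, OLS of darkness on ordination axes, SIMPER
  decomposition with a strict >1 % contribution gate followed by
  Kruskal-Wallis + Benjamini-Hochberg, prevalence-based "core" rumen ASV
  sets (> 80 % prevalence) and per-swab capture percentages.
- **A synthetic study generator** — each swab community is a
  Dirichlet-multinomial draw from a mixture
  `p = α·(rumen solid/liquid) + (1 − α)·(oral/environmental)` whose rumen
  fraction `α ~ Beta(2, 2)` is linked to darkness by
  `d = 0.35 + 0.39·α + N(0, 0.02)`, plus matching rendered swab images, a
  random rooted phylogeny, and the planted ground truth for recovery
  tests.

## Worked example

```python
import swabshade as ss
from swabshade.model import SwabColorStudy, StudyConfig

# default synthetic study: 402 swabs + 13 rumen liquid + 12 rumen solid
table, metadata, truth = ss.simulate_dataset(ss.MixtureDesign(seed=42))
results = SwabColorStudy(table, metadata, config=StudyConfig(seed=1)).fit()
print(results.summary())
```

```
Swab darkness vs rumen community capture
========================================================
samples analysed                 396  (rarefaction dropped 31)
ASVs after filtering             600
rarefaction depth               7000  min count/cell 10
darkness range              0.3423 - 0.7473  (median 0.5454)
--------------------------------------------------------
PERMANOVA (groups)          F = 18.344, p = 0.001
darkness ~ PC1 + PC2        R^2 = 0.927
Spearman darkness vs chao1        rho = +0.043
Spearman darkness vs shannon      rho = +0.209
Spearman darkness vs inv_simpson  rho = +0.342
Spearman darkness vs dist(rumen_solid): rho = -0.951 (p = 5.58e-193)
Spearman darkness vs dist(rumen_liquid): rho = -0.922 (p = 4.59e-156)
prevalent rumen_solid: 56 total, 52 unique (> 80% prevalence)
prevalent rumen_liquid: 50 total, 46 unique (> 80% prevalence)
Spearman darkness vs capture(rumen_solid): rho = +0.914 (p = 4.92e-148)
Spearman darkness vs capture(rumen_liquid): rho = +0.916 (p = 1.14e-149)
differential ASVs (Low vs High, SIMPER > 1%, q < 0.05): 10
```

Reading the output: of 427 simulated samples, 396 had at least 7,000
reads and survived rarefaction. The darkness-stratified groups (Low /
Mid / High swab extremes plus the two rumen fractions) differ strongly
in community structure (PERMANOVA pseudo-F = 18.3, permutation p at the
floor of 999 permutations). Darkness is almost entirely explained by the
first two PCoA axes (R² = 0.93), darker swabs sit closer to the rumen
reference samples in ordination space (ρ ≈ −0.95), and darker swabs
capture a larger share of the highly prevalent rumen ASV set
(ρ ≈ +0.91) — the monotone link the generator planted, recovered by the
analysis.

`results` also exposes every intermediate object (`alpha`,
`distance_matrix`, `ordination`, `differential`, `prevalent_sets`,
`capture`, ...) and `results.save(outdir)` writes each stage as TSV/JSON.

## Command line

```sh
swabshade simulate --out sim/ --seed 42 --images   # synthetic study
swabshade darkness --manifest m.tsv --out scores.tsv
swabshade run --config cfg.yaml                    # full pipeline
```

The pipeline config is YAML (`counts`, `metadata`, optional `taxonomy`,
`tree`, `image_manifest`, plus any `StudyConfig` field); defaults are
rarefaction depth 7,000, min count 10, extremes k = 13, SIMPER gate 1 %,
prevalence 80 %, 999 permutations. A fungal ITS-style run is the same
pipeline with a different config (e.g. depth 2,800, prevalence 0.5).

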