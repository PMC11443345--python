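# Methods

## Problem and model

A swab wiped across the cheek of a ruminating cow collects a mixture of
regurgitated rumen contents and resident oral (plus environmental)
microbes. The working model throughout this package is that each swab's
amplicon community is a convex combination of four source pools —
rumen solids, rumen liquids, oral, environmental — with a single rumen
fraction `α ∈ [0, 1]` per swab:

```
p_swab = α (w_s · solid + w_l · liquid) + (1 − α)(w_o · oral + w_e · env)
```

and that the photographed darkness of the swab is a noisy monotone
readout of `α`:

```
darkness = clip(d0 + d1 α + ε, 0, 1),   ε ~ N(0, σ_d)
```

Observed counts are Dirichlet-multinomial: a sample-specific composition
is drawn from `Dirichlet(p_swab · c)` and reads are multinomial at the
sample's sequencing depth. The analysis side never sees `α`; it sees
counts, darkness scores, and sample types, and asks whether darkness
predicts rumen-community recapitulation.

## Colorimetry

A swab image is scored as `1 − mean(pixels)/255` over the grayscale
100 × 100 block at the image centre. Grayscale uses ITU-R BT.601 luma
weights (0.299, 0.587, 0.114) kept in floating point — no 8-bit rounding
before averaging — so a flat image of intensity `v` scores exactly
`1 − v/255`. The crop anchor for odd dimensions is
`floor(dim/2) − size/2`, fixed so results are deterministic. Images are
assumed pre-masked (the 100 × 100 centre block is swab material);
segmentation of the swab from its background is out of scope. Rounding
luma to 8 bits first would shift scores by < 0.002; PNG export of
rendered synthetic images quantizes to 8 bits and stays inside the same
bound.

## Synthetic-study generator

Defaults define the emulated study: **402 swabs, 13 rumen-liquid and
12 rumen-solid reference samples**; `α ~ Beta(2, 2)` (populates the full
range with mass in the middle); darkness link `d0 = 0.35`, `d1 = 0.39`,
`σ_d = 0.02`, spanning roughly 0.35–0.74 — the realistic range for
TMR-fed cows; per-sample depth log-normal (`μ = ln 25 000`, `σ = 0.9`,
floor 1 000), giving a heavy-tailed spread around ~30 k reads under
which roughly 5–10 % of samples fall below the 7 000-read rarefaction
depth, as happens in practice. Four pools of 160 ASVs each with
log-normal (σ = 1.2) rank-abundance; solid and liquid share 25 % of
their ASVs (overlapping but distinct fractions); oral/environmental
pools are disjoint from rumen pools; total 600 ASVs. Dirichlet
concentration `c = 200` gives realistic sample-to-sample compositional
noise (CV ≈ 0.7 at 1 % abundance). Within-pool mixture weights default
to 0.6/0.4 solid/liquid (darker swabs resemble solids more) and 0.7/0.3
oral/environmental; no quantitative oral:environmental ratio is
established in the field, so this is a configurable convention.

**Planted truth.** The generator records per-swab `α`, each ASV's source
pool, and the set of ASVs constructed to differ between light and dark
swabs: comparing expected compositions at the mean `α` of the 13 lowest
vs 13 highest draws, an ASV is *planted-differential* when its share of
the light/dark L1 difference exceeds the same strict 1 % gate the
analysis applies. Because that share is a continuous quantity, ASVs just
below the gate also genuinely differ; those in `(0.5 %, 1 %]` are
recorded as *borderline* and treated as indeterminate by recovery
scoring (neither hits nor false positives) — the standard effect-size
buffer used when benchmarking differential-abundance callers against a
thresholded truth.

What the generator does **not** emulate: read-level errors and chimeras,
taxonomy misassignment, phylogenetic signal in abundances (the tree is
random, so UniFrac analyses exercise correctness, not realism),
covariance between depth and sample type, and feed-darkened swabs that
carry no extra rumen material. Passing recovery tests therefore show the
statistical machinery recovers a planted monotone darkness-capture link
under realistic compositional noise — not that real swabs behave this
way.

## Normalization

Order follows standard amplicon practice: off-target removal
(Order = Chloroplast, Family = Mitochondria, Kingdom = Archaea), then
rarefaction, then the abundance cutoff. Rarefaction subsamples without
replacement (multivariate hypergeometric) to exactly the target depth,
dropping and logging shallower samples. The ≥10-read cutoff is
**cell-wise**: a cell with 1–9 reads is zeroed (that ASV is treated as
absent from that sample); a table-wide reading was considered and
rejected since the cutoff's purpose is to drop per-sample noise
detections. Presence in all prevalence/capture statistics is therefore
"≥ 10 reads after rarefaction".

## Darkness grouping

Two stratifications of swabs by darkness rank (ties broken by sample id,
deterministic and auditable):

- **Percentiles** — 10 contiguous decile blocks, sizes as equal as
  possible (first `n mod 10` blocks get the extra member), labelled
  Tenth (lightest) … Hundredth (darkest).
- **Extremes** — Low = k lightest, High = k darkest, Mid = the k swabs
  whose ranks are centred on the median rank
  (`floor((n−k)/2)+1 … +k`). Default `k = 13` matches the number of
  rumen reference animals so group sizes stay comparable. Mid is
  rank-centred rather than centred on the midpoint of the darkness
  range; the rank convention is deterministic under ties and
  independent of the score distribution's shape.

## Statistics

- **Alpha diversity**: bias-corrected Chao1
  `S_obs + F1(F1−1)/(2(F2+1))`, Shannon in nats, inverse Simpson.
  Computed on the rarefied, min-count-filtered table (the same table all
  other analyses see). Groups compared by Kruskal-Wallis; pairwise
  Wilcoxon rank-sum (normal approximation with tie and continuity
  corrections — group sizes here are ≥ 13) with BH adjustment; Spearman
  vs darkness. The nonparametric branch is used unconditionally.
- **Beta diversity**: Bray-Curtis `Σ|x−y| / Σ(x+y)`; Jaccard in the
  quantitative dialect `2B/(1+B)` by default (binary available — the
  field uses both and reports rarely say which); unweighted UniFrac via
  per-branch incidence (unique/union branch length over the rooted
  tree).
- **PCoA**: Gower double-centering of `−D²/2`, symmetric
  eigendecomposition, axes scaled by √eigenvalue. Negative eigenvalues
  are reported but excluded from the variance-explained denominator;
  each axis is oriented so its largest-magnitude coordinate is positive.
- **PERMANOVA**: one-way pseudo-F on squared distances
  (`SS_total = Σ_{i<j} d²/n`; within-group analogue per group), p by
  seeded label permutation with the add-one rule (p is never 0; default
  999 permutations). An exact-enumeration mode exists for small n. An
  all-identical-samples matrix returns F = 0, p = 1, flagged degenerate.
- **Darkness vs ordination**: OLS `darkness ~ PC1 + PC2` (multiple
  regression, per-axis t tests, R²). Distance-to-rumen is each swab's
  arithmetic-mean Euclidean distance to every rumen solid (or liquid)
  sample in the first two axes — the plotted plane; a flag switches to
  all retained axes.
- **SIMPER**: per between-group pair the per-ASV term
  `|x_ij − x_ik| / Σ_i(x_ij + x_ik)` (terms sum to that pair's
  Bray-Curtis); contributions averaged over pairs and normalized to
  sum to 1. Run on relative abundances of the filtered table (input
  scale configurable). ASVs with contribution strictly > 1 % proceed to
  per-ASV Kruskal-Wallis with BH over the surviving set only
  (per-comparison correction; a global flag exists); direction from
  group medians.
- **Prevalence/capture**: an ASV is highly prevalent in a rumen fraction
  when strictly more than 80 % (bacterial default; 50 % suits noisier
  fungal data) of that fraction's samples contain it. A swab's capture
  percentage is the share of that set present in the swab; Spearman
  correlates capture with darkness.

## Numerical choices

- All randomness flows through `numpy.random.default_rng` seeds carried
  in configs; rarefaction, PERMANOVA and the generator each log their
  seed.
- BH q-values: step-up `q_(i) = min_{j≥i} p_(j)·m/j`, capped at 1;
  verified against statsmodels.
- Degenerate inputs fail loudly and specifically: all-zero samples,
  empty groups/references, constant darkness (regression), constant
  input (Spearman), sub-minimum image sizes, duplicate ids.
- Strict inequalities at every published threshold (SIMPER > 1 %,
  prevalence > 80 %, cell filter "at least 10" keeps exactly 10).

## Test-problem sizes

The suite runs the headline recovery on the full default study
(427 samples × 600 ASVs — a few seconds). Oracle-equivalence checks use
1 000 random tables (≤ 10 × ≤ 12) and 100 random 8-leaf trees;
PERMANOVA calibration uses 1 000 null data sets at 199 permutations
(n = 10); FDR calibration 500 replicates at m = 40. These sizes give
binomial standard errors comfortably inside the asserted bands while
keeping the whole suite around twenty seconds.

## Known limitations

- The Model/Results API runs one marker at a time; a bacterial + fungal
  study is two runs with different configs.
- UniFrac is unweighted only; NMDS, betadisper-style dispersion tests
  and compositional differential-abundance methods (ALDEx2/ANCOM
  family) are out of scope.
- The generator mixes at the proportion level, not the read level; no
  FASTQ-level simulation.
- Recovery of the planted differential set is evaluated against a
  thresholded truth; the indeterminate buffer makes the evaluation
  honest near the gate but means sensitivity/FDR are statements about
  clearly-above-gate effects.
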