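# Methods

`seqrunqc` implements run-level quality diagnostics for multi-laboratory
marker-gene (16S rRNA amplicon) studies of soil microbiomes, together with
a synthetic multi-lab study generator that provides ground truth for
testing every diagnostic. This note records the models, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
studies do and do not tell you about real data.

## The setting

A multi-lab ring trial sequences the same two field soils in several
laboratories. Each laboratory performs one flow-cell run containing three
pooled libraries of increasing *workflow autonomy*:

* **Seq** — the primary lab extracted DNA, amplified and barcoded; the
  secondary lab only sequenced.
* **PCR/Seq** — the secondary lab amplified and sequenced a provided
  extract.
* **Ext/PCR/Seq** — the secondary lab did everything from soil.

Soil is subsampled in replicate per plot; every run also carries an
8-species genomic-DNA mock community and extraction/PCR negative
controls. The diagnostics ask: which runs (and which libraries within a
run) are *aberrant*, and at which workflow stage did the problem enter?

## Synthetic study generator

### Community and sampling model

* Base community: species abundances are drawn log-normally
  (`exp(N(mu, sigma))`, default `sigma = 2.0`) over a balanced synthetic
  taxonomy (default 8 phyla x 3 classes x 5 genera x 4 species = 480 soil
  species, plus the 8 mock species), then normalised. `sigma = 2` gives
  the steep, long-tailed rank-abundance profile typical of soil.
* Site effect: a fraction (default 0.2) of species get a true Log2FC drawn
  from `N(0, 1.0)` between the two sites.
* Counts: for each sample, `p ~ Dirichlet(theta * proportions)` then
  `counts ~ Multinomial(depth, p)`. The Dirichlet-multinomial models the
  patchy, overdispersed replicate-to-replicate variation of soil
  communities. The concentration `theta = 3000` was calibrated so that
  replicate soil subsamples show genus-level Bray-Curtis (Hellinger)
  similarities with medians near 0.90, the level reported for replicate
  soil amplicon libraries; it is the single most consequential default.
* Library autonomy noise: multiplicative per-taxon log-normal noise with
  sigma 0 (Seq), 0.10 (PCR/Seq), 0.20 (Ext/PCR/Seq), drawn once per
  (run, library). This encodes "more self-performed steps, more handling
  variability" as a systematic per-lab effect, not per-sample noise.
* Aberrant run: a designated run receives a phylum-wide bias — every genus
  in the (default 2 of 8) biased phyla is multiplied by `2^b`,
  `b ~ N(0, 1.5)` — in the libraries whose autonomy includes the bias
  *entry stage*. A PCR-stage bias hits PCR/Seq and Ext/PCR/Seq but leaves
  Seq untouched; an extraction-stage bias hits only Ext/PCR/Seq; a
  sequencing-stage bias hits all three. This is what makes stage
  attribution testable.
* Depths: per-run mean soil-sample depth (defaults 8k-110k across six
  runs, with one low-depth and one high-depth run) jittered log-normally
  (sigma 0.15) per sample. The default 12,000-read rarefaction therefore
  excludes most of the low-depth run's samples, deliberately exercising
  that code path.
* Read-accounting funnels are built backwards from the realised sample
  totals using each run's configured removal fractions (defaults: 42%
  demultiplex, 3% quality, 0.5% length; the low-quality run uses 30%
  quality removal).
* Mocks: one per (run, library), drawn from the theoretical 8-species
  profile with a small contaminant mass (default 0.1%). Negative controls
  get `Poisson(50)` reads of contaminant taxa only, keeping them below the
  0.4% control-read rule.

All randomness flows from the single config seed through named
substreams (CRC-keyed `SeedSequence` children), so every artefact is
byte-reproducible.

### What the generator does not emulate

Classification error and database effects, chimeras, read-length and
quality structure, primer bias, true taxonomies, and the real deviation
of sequenced mocks from their theoretical profile (simulated mocks score
~0.98 similarity; real ones score ~0.89 because extraction and PCR bias
also act on them). Passing diagnostics on synthetic studies therefore
demonstrates that the *statistics and rules* behave as intended under a
controlled data-generating process — not that any particular real run is
clean.

## Diagnostics

### Read-accounting funnel

Per run, removal fractions at demultiplexing, quality filtering and
length filtering. The quality step is flagged when outside the 2-5% band
(inclusive endpoints; the band is a published rule of thumb for this
pipeline order). Control reads are summed per run and flagged above 0.4%
of the run's total table reads (a per-sample variant is available since
the summed convention is a design choice).

### Richness saturation

Observed richness still rises with the original per-sample read count, so
the relationship is modelled as `S = Smax*R/(K+R)` (rectangular
hyperbola). `Smax` (asymptotic richness, species) and `K` (half-saturation
read count) are fitted per site by nonlinear least squares, initialised
from the Lineweaver-Burk (LB) linearisation `1/S = 1/Smax + (K/Smax)/R`.
The LB transform is also fitted per run by OLS, and each run's slope and
intercept are contrasted against the pooled remaining runs via an
indicator-interaction model with two-sided t tests (BH-adjusted versions
are emitted alongside raw p-values). LB regression is unweighted, as in
the diagnostic plots it mirrors; its heteroscedasticity is the reason the
MM fit is the primary estimator and LB only the outlier test. Richness
ANOVA uses type-II sums of squares on site + library + run-within-library
with partial eta^2 = SS_effect/(SS_effect+SS_residual).

"Original number of sequence reads" means the per-sample demultiplexed
read count throughout.

### Distances and ordination

Bray-Curtis on Hellinger-transformed genus abundances is the primary
metric; classical Morisita on raw integer genus counts is the
depth-robust alternative (Morisita-Horn is provided for non-integer
input). Morisita similarity can exceed 1 for small counts; the distance
is clamped to [0, 1] with raw values kept in a side channel. PCoA is
classical double-centering with negative eigenvalues reported but
excluded from the explained-variance denominator. perMANOVA uses the
squared-distance within/between decomposition with free, seeded label
permutations (999 by default) and `p = (1+m)/(1+n_perm)`. Variance
partitioning regresses the positive PCoA axes on each factor's dummies
(db-RDA) and reports marginal Ezekiel-adjusted R^2 per factor; marginal
(not joint) fractions match the additive way such results are usually
quoted, and a joint decomposition is out of scope.

### Similarity diagnostics and the flag rule

Within-run: similarities between replicate soil subsamples of each
(site, plot), pooled per (run, library). Between-run: each evaluated soil
sample is compared to the matching (site, plot, library) samples of each
designated reference (primary-lab) run, contributing one similarity per
reference run (the mean over that run's matching replicates, not further
averaged across reference runs). Summaries are boxplot-style: type-7
linear-interpolation quartiles, whiskers at the most extreme points
within 1.5 x IQR — stated explicitly because quartile conventions differ.

A (run, library) is flagged when its median similarity falls below the
reference pool's median minus one pool IQR. Flagging is one-sided (low
similarity is the failure mode) and the full-IQR band is used; both the
factor and the pool are configurable. The pipeline pools all evaluated
runs by default, accepting that a single bad run slightly inflates the
pool IQR — the median/IQR band is robust to one outlier among many
(run, library) groups.

The stage-attribution logic reads the flags jointly: PCR/Seq and
Ext/PCR/Seq flagged with Seq clean points at PCR; only Ext/PCR/Seq points
at extraction; all three depressed under Bray-Curtis but not under
Morisita points at sequencing depth rather than community bias.

### Mock evaluation

Bray-Curtis similarity of relative abundances between the observed mock
(at the table's rank; the expected profile is aggregated to match) and
the theoretical profile on the union of taxa, pass threshold 0.860, plus
the relative-abundance mass outside the expected genera as the
contaminant fraction.

### Abundance variability

CPM-normalised abundances per (run, library) are compared to the averaged
primary-lab baseline (mean of per-reference-run means, so each primary
lab weighs equally) as `log2((x+pc)/(ref+pc))` with pseudocount
`pc = 0.5` CPM (exposed and reported, since zero handling is a
convention). The per-taxon range (max - min) of Log2FC across runs, per
library, is the variability statistic; ranges are compared across the
three libraries by one-way repeated-measures ANOVA with taxon as subject,
Greenhouse-Geisser correction by default (uncorrected p also emitted),
BH-adjusted pairwise paired t-tests, and t-based 95% CIs on mean ranges.

Site contrasts use median-of-ratios (RLE) size factors within each
(run, library), Log2FC of site means with the same pseudocount, and a
two-sided label-permutation test (default 1000 permutations, seeded),
BH-adjusted across taxa. A permutation test replaces a parametric
negative-binomial model deliberately: it is assumption-light and its
type-I behaviour is verified by the calibration tests.

## Numerical conventions and degenerate inputs

* Exact-fit guard: when an LB model fits with essentially zero residual,
  deviation p-values are reported as exactly 1 (zero contrast) or 0
  (nonzero contrast) instead of an ill-conditioned t ratio.
* Constant-response ANOVA reports all partial eta^2 as 0.
* Constant-richness MM fits return `Smax = S`, `K = 0`, flagged
  degenerate; negative parameter estimates are flagged, not hidden.
* Zero-sum samples: relative abundance keeps them as zeros with a warning
  record; CPM refuses them by name; all-zero distance pairs get d = 0
  with a warning.
* Rarefaction is a single seeded multivariate-hypergeometric draw per
  sample; samples below depth are excluded with a record, never silently.
  Runs left with fewer than 3 usable points are skipped by the per-run LB
  fit, with the skip recorded in the report.
* Aggregation uses integer arithmetic and conserves row sums exactly.

## Problem sizes used by the test suite and acceptance script

Simulation-based checks use a compact study (2 sites x 2 plots x 2
replicates x 3 libraries x 6 runs, 8 phyla / 96 soil genera) except the
aberrant-run detection experiment, which uses the full default design
(4 plots, 288 soil samples, 120 genera) with depth-balanced runs
(20k-30k) so that flags reflect the injected PCR-stage bias rather than
depth artefacts; at that design the reference-soil diagnostic flags the
biased libraries while sparing the Seq library and the clean runs.
Replicate counts per experiment (60-200 simulations, 199-1000
permutations) are the package's chosen balance between statistical
resolution and runtime; the acceptance script prints the `n` it used next
to every value.

## Known limitations

* Classical Morisita requires integer counts; tables that have been
  normalised must use Morisita-Horn instead.
* The LB deviation test contrasts one run against the pool including
  heteroscedastic transformed noise; it is a screening tool, and the MM
  fit should be quoted for parameter values.
* Marginal variance partitioning double-counts shared variance between
  confounded factors; a crude confounding screen warns on fully aliased
  pairs only.
* The flag rule's pool choice matters when many runs are bad at once; the
  band assumes a majority of clean runs.
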