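# Methods

This note documents the statistical models implemented in `vulvasig`, the
defaults and why they were chosen, what the synthetic cohort generator does
and does not emulate, and the numerical conventions that matter when
comparing output against other tools.

## Input model and pre-processing

The package consumes three TSV tables: a taxonomic profile (MetaPhlAn-style
merged table with pipe-delimited clade strings on the 0–100 scale, or a
plain samples × species count matrix), an enzyme table keyed by EC number
(HUMAnN-style), and per-sample metadata (`sample_id age cohort status
read_count`). From a merged taxonomic table only species-level rows
(`s__` terminal clades) are read; values are rescaled to fractions, and the
genus of each species is the first token of its name.

Pre-processing filters, all boundary-inclusive:

* **Read depth** — samples with `read_count ≤ 20,000` are excluded. The
  threshold is the conventional floor below which shotgun profiles of
  low-biomass skin-adjacent sites become unreliable.
* **Species abundance** — a species is kept iff its summed abundance across
  the cohort divided by the table's grand total is ≥ 0.05%
  (`cum_threshold = 5e-4`). The share is computed cohort-wide, not
  per-sample, and rows are *not* renormalized afterwards: retained
  fractions stay interpretable against the original profile, and the CLR
  stage is insensitive to closure anyway. Both choices are configurable.
* **Enzymes** — duplicate EC identifiers are collapsed by summation, then
  features detected (value > 0) in fewer than 10% of samples are dropped,
  then features whose value vector exactly duplicates another's are reduced
  to one representative (lexicographically first). "Redundancy" has no
  canonical definition in HUMAnN post-processing; exact duplication is the
  conservative reading and every removal is reportable.
* **Age quartiles** — samples are sorted by age; quartiles are filled in
  order, each taking an even share of the samples still unassigned (earlier
  quartiles absorb the remainder), and a tie group of identical ages that
  would straddle a boundary joins the younger quartile wholesale, with the
  remaining quartiles rebalancing over what is left. A boundary therefore
  never splits an age value, and labels are monotone in age.

## Ecological signatures

Per sample, the skin fraction is the summed abundance of species whose genus
is in the skin panel divided by the sample's total retained abundance, and
analogously for the vaginal panel. The label is *skin* if the skin fraction
is ≥ 0.5, *vagina* if the vaginal fraction is ≥ 0.5, otherwise *mixture*;
the measure-zero double tie (0.5, 0.5) resolves to *mixture*. Fractions use
the retained-species denominator (the rule is stated over profiled microbes,
not raw reads), are computed after the abundance filter by default, and the
panels are configurable because panel genera are typical of — not exclusive
to — their niche.

## Diversity

Shannon index H = −Σ pᵢ ln pᵢ on each sample's relative abundances, zeros
excluded. Natural log is the default (the convention of the vegan ecology
stack); the base is a parameter. Group comparisons: Kruskal–Wallis with tie
correction (scipy), then Dunn's pairwise z on pooled mid-ranks,

z = (R̄_A − R̄_B) / sqrt[(N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_A + 1/n_B)],

two-sided normal p-values, Benjamini–Hochberg across pairs (Bonferroni
optional). If all observations are identical every z is 0 and p is 1.

## Ordination and PERMANOVA

CLR transform per sample: y = ln(x + pc) − mean(ln(x + pc)); rows sum to 0.
Zero replacement is a pseudocount of 1 on count tables (mirroring the count
pseudocount used in differential abundance) and half the minimum positive
value on relative-abundance tables. PCA is an SVD of the column-centered CLR
matrix; variance-explained fractions are eigenvalue shares over the full
rank; the sign convention makes each component's largest-magnitude loading
positive; a loading display multiplier can be recorded for biplots but never
affects scores.

PERMANOVA uses squared Euclidean distances on CLR coordinates (Aitchison
geometry). SS_total = Σ_{i<j} d²/n, SS_within sums the analogous per-group
terms, pseudo-F = (SS_B/(g−1))/(SS_W/(n−g)). Two null modes:

* **Monte-Carlo** (default 9,999 permutations, seed mandatory):
  p = (1 + #{F* ≥ F}) / (1 + n_perm).
* **Exhaustive** for small n: every distinct assignment of the label multiset
  is enumerated and p is the exact tail fraction including the observed
  labeling. If SS_within is 0 the statistic is +∞ and ties at +∞ count as
  extreme.

Pairwise mode reruns the test per group pair with BH across pairs (the
multiple-testing method is unspecified in the motivating analysis; BH
matches the adjusted-p convention used everywhere else). The implementation
agrees with scikit-bio's pseudo-F to machine precision (test-verified);
scikit-bio is used only as a cross-check because it lacks the exhaustive
mode.

## Species differential abundance (NB Wald)

A deliberately simplified DESeq2-style pipeline for two-group contrasts
(older Q3+Q4 vs younger Q1+Q2, HSIL vs healthy, LS vs healthy, or any
user-defined pair):

1. add pseudocount 1 to raw counts (applied before everything else);
2. median-of-ratios size factors s_j = median_i(c_ij / gm_i) over features
   with positive geometric mean, rescaled to geometric mean 1 (the median is
   taken on the ratio scale, as the estimator defines);
3. per-feature NB dispersion by method of moments on normalized counts,
   α = (var − mean)/mean², computed **within** each group and pooled with
   (n_g − 1)/(n − 2) weights so a real group effect is not absorbed into
   dispersion, floored at 1e-8;
4. log2FC = log2(μ̂_contrast / μ̂_ref) of normalized group means (means are
   strictly positive because of the pseudocount, so no extra offset is
   added and swapping the contrast negates the estimate exactly);
5. delta-method SE from the NB variance, Var(ln μ̂) ≈ (1/μ + α)/n; Wald
   z = log2FC/SE, two-sided normal p, BH across features.

Features that are all-zero in both groups are skipped and reported.
Relative-abundance input is converted to pseudo-counts (× library size,
default 100,000) with a warning, since the test is defined on counts. The
full DESeq2 machinery (Cox–Reid dispersion fitting, dispersion-trend and LFC
shrinkage, independent filtering, outlier replacement) is intentionally not
reproduced, so results on identical input will differ from DESeq2's;
simulation tests show sensitivity 1.0 for log2FC = 2 effects at n = 50 per
group and a null BH-rejection fraction far below 0.05. As in any
normalization-based method, when a nontrivial fraction of features truly
changes, size factors absorb part of the shift and unchanged features
acquire a small opposite-signed bias.

`rank_top` returns the top-k significant features by |log2FC| in a chosen
direction, the form used for "top 10 depleted/enriched" tables.

## Enzyme differential abundance (moderated t)

Enzyme abundances are log2-transformed with a half-minimum-positive offset
(the moderated t assumes approximately Gaussian responses; the offset is
configurable). For each EC feature, the two-group mean difference and pooled
residual variance s² (d = n_A + n_B − 2 df) feed the empirical-Bayes
hierarchy: sample variances are modeled as s² ~ s₀²·F(d, d₀), and (d₀, s₀²)
are estimated by matching the mean and excess variance of log s² through
digamma/trigamma identities, with a Newton trigamma inverse. Posterior
variances s²_post = (d₀s₀² + d·s²)/(d₀ + d) rescale the t statistic,

t_mod = Δ / sqrt(s²_post (1/n_A + 1/n_B)),  df = d + d₀,

with BH across features. d₀ = ∞ (no excess spread) collapses every posterior
to s₀²; the degenerate all-identical-variance input returns the common value
unchanged, so shrinkage is a no-op there. Forcing d₀ = 0 recovers the
ordinary pooled t exactly (test-verified to 1e-10). On dispersed inputs the
estimates and t statistics match the reference empirical-Bayes
implementation (limma 3.58.1) to ~1e-6 on a frozen fixture. Precision
weights and the mean-variance trend are not implemented; only two-group
designs are supported, matching the study contrasts. The HSIL functional
contrast is not configured by default — three subjects cannot support a
meaningful functional comparison — but the engine accepts any two-group
contrast.

## Synthetic cohort generator

No generative model is given for real vulvar communities, so the simulator
uses the standard overdispersed-composition model:

* **Species panel** — 22 species spanning the skin panel, the vaginal
  panel, and niche-nonspecific taxa, including all marker species the
  analysis discusses (S. epidermidis, F. magna, P. harei, P. timonensis,
  C. acnes, G. vaginalis, L. iners/crispatus/gasseri, S. hominis,
  M. luteus, C. amycolatum, C. simulans, M. osloensis).
* **Archetypes** — skin-dominant (66% base mass on skin genera),
  vagina-dominant (66% on vaginal genera), mixture (30%/35%), drawn with
  weights 0.24/0.22/0.54 by default — the proportions observed in the
  motivating cohort, as parameters rather than claims.
* **Per-sample counts** — Dirichlet(concentration × expected composition)
  then Multinomial at a depth uniform on [50,000, 500,000]. Concentration
  defaults to 50, giving visible inter-sample variability; an optional
  low-depth fraction plants samples under the 20,000-read filter.
* **Covariates** — age uniform on 22–82 years (the cohort's printed range;
  no menopause covariate, as none is recorded), status drawn at 58/67
  healthy, 6/67 LS, 3/67 HSIL.
* **Effects** — multiplicative 2^(log2-effect × units) on target species
  before renormalization; age effects are per decade above the cohort
  minimum, disease effects per affected sample. Defaults: −0.5/decade on
  three Lactobacillus species and −2.0 on four disease-depleted marker
  species. True effect magnitudes are not known for real cohorts; these are
  placeholders for power studies, not estimates.
* **Enzyme tables** — relative abundances × a sparse species-by-EC weight
  matrix with i.i.d. multiplicative lognormal noise (σ = 0.1 of log). Five
  real EC numbers relevant to the niche (aspartate and L-histidine pathway
  enzymes) head the default feature list; the rest are synthetic
  placeholders.

`CohortTruth` records per-sample archetypes and per-contrast planted log2
fold changes (an age effect per decade maps to the expected three-decade gap
between the older and younger halves of a uniform 22–82 distribution).

What the generator does **not** emulate: strain-level variation, inter-taxon
correlation beyond the Dirichlet, read-level error, virome/mycobiome
fractions, batch/cohort effects, or realistic enzyme-to-genome maps. Tests
passing on these simulations therefore demonstrate correctness of the
statistics under their own assumptions — not that real vulvar cohorts
satisfy those assumptions.

## Numerical conventions and problem sizes

* BH adjustment everywhere via statsmodels `multipletests`; significance at
  adjusted p < 0.05.
* Permutation p-values can never be 0 (Monte-Carlo mode adds 1 to both
  tail count and denominator).
* Tie handling: mid-ranks in all rank statistics; quartile ties to the
  younger quartile; the signature double tie to mixture.
* Dispersion floor 1e-8 prevents degenerate under-dispersed NB fits.
* Simulation-based tests use fixed seeds with sizes chosen for stable
  statistics at interactive runtimes: 1,000 datasets for permutation
  type-I error, 200 replicates for null FDR control, n = 4,000 for
  signature-proportion recovery, 5,000 features for variance-prior
  recovery.
* The pipeline writes eleven TSV reports plus `manifest.json` (package
  version, config hash, input SHA-256 checksums, per-stage counts,
  timestamps); reruns with identical config and seed are byte-identical
  except timestamps.

## Known limitations

* The NB Wald test is a documented simplification of DESeq2; no shrinkage
  of dispersions or fold changes, so small-n contrasts (e.g. 3 HSIL
  subjects) are noisy and should be read as exploratory.
* PERMANOVA assumes exchangeability under the null; heteroscedastic group
  dispersions can inflate significance, and no dispersion test is included.
* Cohort-specific published numbers (signature split of a particular study,
  PC percentages, species lists) depend on the underlying sequence archive
  and profiler database versions and are outside what desk-scale synthetic
  data can reproduce; the acceptance script instead reports recovery of
  known planted truth.
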