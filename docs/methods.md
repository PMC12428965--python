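# Methods

## Data model and preprocessing

Input is a pair of gene × sample integer count matrices — one per
sequencing fraction (`total`, `polysome`) — plus a sample sheet assigning
each library a condition (Control, Hardening, Stress, Combo), fraction,
biological replicate and technical replicate. Technical repeats are
resequencing runs of one library, so they are collapsed by **summation**
before any modelling; treating them as replicates would understate
biological dispersion.

Low-expression filtering keeps genes with ≥ `min_count` (default 10) reads
in ≥ `min_samples` (default 2) libraries in at least one fraction; the two
fractions are then restricted to the shared surviving gene universe so
translational ratios are defined everywhere.

Normalisation is counts-per-million (CPM). When externally computed TPM
tables are available they are accepted as a `NormalizedMatrix` with
`scale="tpm"`; with raw counts only, CPM stands in for TPM since transcript
lengths are out of scope, and the `scale` tag records which was used. The
PCA overview operates on log2(CPM + 1), gene-centred, without per-gene
scaling — the conventional transcriptome PCA.

## Differential expression

Counts follow NB2: `Var = μ + φ μ²`. Per-gene dispersion is estimated by
the method of moments on counts rescaled to a common library size,
`φ̂ = (s² − m̄) / m̄²`, pooled across groups with residual-df weights, and
shrunk toward the across-gene mean with `prior_weight` (default 10)
pseudo-degrees of freedom:

    φ_g = (w · φ_common + d · φ̂_g) / (w + d),  clipped at 0.

Groups with a single sample contribute nothing and set a fallback flag.

The two-group test is a **likelihood-ratio test of equal NB rates** with
library-size offsets (raw column totals — no TMM, since no
composition-bias model is part of the design): the alternative fits one
rate per group, the null a common rate, each by Fisher scoring on the log
rate; `2ΔlogL ~ χ²(1)`. `logFC` is the log2 ratio of offset-corrected
group means with a 0.5 pseudo-count added to each mean so fold changes
stay finite. FDR is Benjamini–Hochberg, but **classification uses the raw
p-value**, matching the stated thresholds:

* `Up`: logFC > 1 and p < 0.05
* `Down`: logFC < −1 and p < 0.05
* `Stable`: |logFC| ≤ 1 (no p condition)
* `Unclassified`: |logFC| > 1 but p ≥ 0.05

The Stable rule is threshold-only by choice: the source thresholds attach
one p-cutoff to all three classes without saying what it means for Stable,
and a threshold-only Stable with an explicit Unclassified gap is the
interpretation that partitions all genes without silently dropping any.

Calibration note: with 3 vs 3 replicates and moment+shrinkage dispersions
the test is mildly anti-conservative — measured type-I error ≈ 6 % at the
nominal 5 % on a 2 000-gene null (φ = 0.1) — which we consider acceptable
for an analysis whose calls additionally require a 2-fold change.

## Translational ratio and differential translation

For each unit (condition by default, paired biological replicate
optionally):

    TR = log2((poly_CPM + c) / (total_CPM + c)),   c = 0.5
    ΔTR(i, j) = TR_i − TR_j

The pseudocount keeps TR finite at zero counts; TR is antisymmetric under
swapping the fractions, ΔTR under swapping the units.

The model-based test fits, per gene, the NB regression with log-mean
`intercept + fraction + condition + fraction:condition` and library-size
offsets. In the 2 × 2 design the alternative is the saturated four-cell
model (each cell rate fitted by the same scalar Fisher scoring as the DE
test) and the null the additive three-parameter model (fitted by
vectorised IRLS); the likelihood ratio has 1 df. The interaction
coefficient, converted to log2, **is** the model estimate of ΔTR; a small
rate floor (0.5 / mean library size) keeps it finite for empty cells.
Classification reuses the Up/Down/Stable rule with |ΔTR| > 1 and p < 0.05 —
a deliberate symmetry with the expression thresholds, since no separate
ΔTR cutoff is specified anywhere.

**Pairing and what the test assumes.** Polysome profiling splits one
homogenate into the total and polysome aliquots, so plant-level biological
variability is shared by the fraction pair while sequencing noise is
aliquot-level. The interaction LRT, however, treats all libraries as
independent NB draws. Two consequences, both verified by simulation:

* under the test's own model (independent columns) the interaction p-value
  is calibrated (type-I ≈ 5 %);
* on paired data from the generator below the test is *conservative*
  (shared biology cancels in the double difference, so the model
  overstates the contrast's variance). Power is nevertheless excellent
  because the ΔTR estimator itself benefits from the pairing: planted
  translation-only effects of ΔTR = 2 are recovered at ≈ 99 % while ≈ 98 %
  of those genes are simultaneously called Stable in total-fraction DE,
  and transcription-only genes show median |ΔTR| ≈ 0.03.

Before translational co-expression analysis the TR matrix is mapped to the
linear scale (`2^TR`) and each column rescaled to sum to one million.
Log-ratios are signed and cannot meaningfully sum to a per-million total,
so the renormalisation is defined on the linear ratio scale — flagged here
because it is a modelling convention, not a mathematical necessity.

## Set comparison

UpSet-style decomposition counts elements belonging to *exactly* each
combination of sets; the exclusive regions partition the union. Jaccard
matrices use `J = |A∩B| / |A∪B|`, with J of two empty sets defined as 0
(warned). The stable core is the intersection of Stable sets across all
comparisons; with both fractions' Stable sets intersected, planted
invariant genes are recovered with ≈ 99 % precision in simulation.
Comparison names follow the `X_vs_Y` convention with a `_T` suffix for
transcriptional (total-fraction) sets.

## Co-expression networks

A deterministic, self-contained WGCNA-style stack:

* **Soft threshold.** For each power β in 1..20, connectivities
  `k_i = Σ_j a_ij` are binned (10 equal-width bins) and log10(frequency) is
  regressed on log10(mean k); the signed fit is R² negated when the slope
  is positive. When mean connectivity drops below 1 the network is
  essentially empty and any degree distribution looks heavy-tailed, so the
  fit is reported as 0 for that power. The smallest β with fit ≥ 0.8 is
  chosen; otherwise the best-fit β with a low-fit warning.
* **Adjacency.** Unsigned `|cor|^β` by default (signed `((1+cor)/2)^β`
  available); unit diagonal; zero-variance genes must be filtered first.
* **TOM.** `TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
  `l_ij = Σ_{u≠i,j} a_iu a_uj`; verified against a triple-loop oracle to
  1e-12.
* **Modules.** Average-linkage clustering of `1 − TOM`, cut statically at
  0.99 × the maximum merge height; clusters below `min_module_size`
  (default 30) become `grey`. This simplified cut replaces the hybrid
  dynamic tree cut: it is fully specified, deterministic, and recovers
  planted blocks exactly (ARI = 1.0 on 2- and 4-block simulations with
  orthogonal latent factors). Labels come from a fixed colour list ordered
  by module size; names carry no meaning.
* **Eigengenes.** First principal component of the standardised module
  expression, unit norm, sign aligned with the module's mean standardised
  profile.
* **Module–trait.** Pearson r of eigengene vs one-hot condition
  indicators; two-sided p from `t = r √(n−2) / √(1−r²)`, df = n − 2. At
  n = 4 this reduces to `p = 1 − |r|`, which reproduces reported
  module–trait pairs such as r = −0.98 → p = 0.02 and r = −0.97 → p = 0.030
  at rounding precision. Whether published correlations of this kind use
  condition-level (n = 4) or sample-level observations is usually
  unstated; the closed form above matches the printed values only under
  n = 4, which we record as an observation.
* **Hub genes.** Top 10 per module by kME (correlation with the
  eigengene), ties broken by gene id.

The transcriptional network runs on log2 CPM of the total fraction; the
translational network on log2 of the per-million-renormalised 2^TR per
replicate. The two runs share no state.

## Cross-level module overlap

Every non-grey module pair across the two levels is scored on the common
gene universe by Jaccard and by a one-sided hypergeometric overlap test
(the standard choice for module overlap; the criterion that pairs must
also be "statistically significant" names no test, so hypergeometric + BH
is adopted and documented as such). A pair is *related* when J ≥ 0.05 and
BH-FDR < 0.05. Balanced random partitions of 1 000 genes into 10 modules
have expected pairwise J ≈ 0.053 — above the 5 % bar — so the significance
filter, not the Jaccard threshold, is what suppresses false positives
(≥ 95 % of null runs yield no related pair; a planted 80-gene shared
program is detected with J = 0.67 and FDR ≪ 0.05).

## Enrichment

Hypergeometric over-representation (upper tail) and under-representation
(lower tail) of a query list in each annotation term, after intersecting
terms with the analysis universe. Terms with more than `term_size_max`
(250) annotated genes or fewer than `intersection_min` (10) query genes in
the term are excluded *before* testing; BH runs per direction across
surviving terms. `term_size` is interpreted as the number of annotated
genes in the term — the conventional meaning. The analysis is fully
offline against a user GMT; no web service is queried.

## Synthetic experiments

The generator emulates the 4-condition, 2-fraction, replicated design with
planted ground truth:

* Baseline log2 abundances ~ N(6, 2) (CPM-scale realism); per-gene
  baseline translational efficiency log2 ~ N(0, 0.5).
* A **transcriptional program** (150 up + 150 down genes, effect ±2 log2)
  tied to Hardening and shared by Combo, acting on both fractions —
  hardening has had time to reshape the transcriptome and everything
  downstream of it.
* A **translational program** (150 + 150, ±2 log2) tied to Stress and
  shared by Combo, acting on the polysome fraction only — acute stress
  regulates selective translation without prior transcriptional change.
* A **stable core** (150 genes) with no effect anywhere.
* **Co-expression modules** (4 × 50 genes, latent factor strength 1.0 on
  the log2 scale): transcriptional modules shift both fractions (and hence
  cancel in TR), translational modules shift the polysome fraction only
  and surface at the translational level.
* Library sizes log-normal around 5 × 10⁶ (log-sd 0.15); NB dispersion
  φ = 0.1. The gamma (biological) multiplier is drawn **once per
  biological sample and shared by its two fractions** (one homogenate,
  two aliquots); sequencing noise is aliquot-level Poisson. Marginally
  every library is NB(μ, φ) — verified against the moment identity
  `Var = μ + φμ²` — while the fraction pair is positively correlated, as
  in real paired designs.
* Technical repeats are binomial halves of one latent library
  (resequencing, not independent biology).
* Annotations: random terms (sizes 10–100) plus one term per planted
  program with 80 % of members drawn from the program.

Everything is deterministic given the seed.

**What the generator does not emulate:** transcript-length effects (hence
CPM, not TPM), compositional library artefacts beyond those induced by the
planted programs themselves, isoform structure, batch effects, and
condition-dependent dispersion. Passing tests therefore demonstrate
correctness of the statistical machinery under a faithful NB model of the
design, not robustness to every artefact of real libraries. Two visible
consequences of per-million normalisation on generator data are documented
rather than hidden: planted 4-fold translational effects appear slightly
attenuated (≈ 3.6×) because the shifted polysome pool changes the CPM
denominator, and a small fraction of strongly transcription-regulated
genes can leak into nominally significant ΔTR calls at low counts.

## Numerical choices

* NB fits floor dispersion at 1e-6 (quasi-Poisson limit); Fisher-scoring
  steps are clipped at ±4 on the log-rate scale; LRT statistics are
  clipped at 0.
* All-zero genes get p = 1, logFC/ΔTR = 0 and an `all_zero` flag.
* BH ties receive equal adjusted p; gene order never affects values.
* Tables are written with `%.6g` floats so reruns are byte-identical.
* Module detection, eigengenes and hub ranking contain no randomness; the
  only RNG in the package is the simulator's, seeded explicitly.

## Problem sizes

Simulation-based checks use 2 000 genes with 3 biological replicates per
condition (the design's own scale); block-model recovery uses 50-gene
blocks over 16 samples; exact oracles run on instances of ≤ 20 elements
where exhaustive enumeration is feasible. These sizes were chosen so the
full test suite and the acceptance script each complete in about a minute
while keeping every Monte-Carlo band comfortably away from its threshold.

## Known limitations

* The interaction test ignores the total/polysome pairing (see above); a
  paired or mixed-effects formulation would gain calibration on paired
  data at the cost of the simple GLM structure.
* The static tree cut does not split nested modules the way dynamic tree
  cut can; module merging by eigengene similarity is not implemented.
* Offsets are raw library totals; strongly asymmetric regulation biases
  fold changes toward zero for unregulated genes (no TMM-style
  composition correction).
* Enrichment ignores annotation hierarchy (no GO DAG propagation).
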