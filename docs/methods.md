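# Methods

This note documents the models behind `mthet`, the defaults and why they were
chosen, what the synthetic cohort generator does and does not emulate, and the
numerical choices that matter when interpreting results.

## Coordinate system and reference model

All positions are 1-based rCRS coordinates (`m.` positions) on the 16,569 bp
circular molecule; BED interchange converts to 0-based half-open at the I/O
boundary only. Position arithmetic wraps modulo the length, so trinucleotide
contexts and the D-loop (16024–16569 ∪ 1–576) span the origin naturally.
Position 3107 is the historical placeholder `N` and is excluded from callable
positions.

The locus map is the standard mtDNA annotation: 13 protein genes, 22 tRNAs,
2 rRNAs and the D-loop, plus an *intergenic aggregate* of exactly the 89
positions that fall between annotations — 39 region sets in total. Two gene
pairs overlap (ATP8/ATP6, ND4L/ND4); a variant there is evaluated in each
frame and counted non-synonymous if non-synonymous in *any* overlapping gene,
the conservative choice for burden analyses.

**Synthetic reference sequence.** The true rCRS nucleotide string is not
redistributable inside this package, so `synthetic_reference()` builds a
deterministic stand-in: mtDNA L-strand base composition (A .309 / C .313 /
G .131 / T .247), open reading frames in every protein gene's annotated frame
and strand (internal stop codons rewritten; incomplete terminal codons
completed by the poly-A convention), the poly-C tract structure at 303–315,
and fixed anchor bases at m.263 (A), m.7028 (C, in a TAC codon) and m.11719
(G, in a GCG codon) so the canonical transitions at those sites keep their
known consequences (in the vertebrate mitochondrial code any third-position
C>T or G>A is synonymous). Analyses that depend only on coordinates, classes,
frames, strand and arc behave identically to the real reference; analyses of
*specific* codons elsewhere do not, and the sequence is labelled synthetic
for that reason.

**Consequence calling** uses the vertebrate mitochondrial genetic code
(translation table 2). Genes annotated on the opposite strand (ND6 and eight
tRNAs) are read reverse-complemented. Non-protein loci label variants by
locus class (tRNA, rRNA, D-loop, intergenic).

**Replication arcs.** OriH is taken at m.191 and OriL at m.5799; the minor
arc is [191, 5799) and the major arc the remainder. The delimiting positions
are conventions (sources give delimiters, not inclusivity); m.191 is assigned
to the minor arc and m.5799 to the major arc.

**Homopolymer mask.** Default: all positions inside runs of ≥ 5 identical
bases (circular; runs may span the origin), plus an explicit, configurable
extra-exclusion list. Published pipelines exclude curated homopolymeric
regions without always listing them; the run-length default is documented
here rather than inferred, and the extra list is the hook for a curated set.

## Heteroplasmy classes and burden

HF classes partition [0.05, 1] half-open upward: low = [0.05, 0.10),
intermediate = [0.10, 0.95), homoplasmy = [0.95, 1]. Interval notation like
"5–10 %" is ambiguous at shared endpoints; assigning each boundary upward
keeps the classes a partition and matches the use of "HF ≥ 95 %" for
homoplasmy in haplogroup assignment. Burden tables count calls per sample ×
class × functional category; sharing spectra classify variants as singleton,
2–10 or >10 carriers (boundaries inclusive on the left, ">10" strict);
per-locus frequencies count *distinct variant sites* of each class per locus,
divided by locus length (whether occurrences or sites are counted is an open
presentational choice; distinct sites is the one implemented and tested).

## QC cascade

Stage order: sample coverage → basic call support → homopolymer →
within-group prevalence → panel concordance → optional CV filter. Choices
worth noting:

* *Basic call filter*: depth ≥ 500×, total alt reads ≥ 25 **and** ≥ 1 alt
  read on each strand (the two conditions are stated jointly), HF ≥ 5 %.
* *Prevalence filter*: a site heteroplasmic (0.05 ≤ HF ≤ 0.95) in **more
  than** 2 % of a group's individuals has its heteroplasmic calls removed
  *within that group*; homoplasmic calls at the site survive. Cohort-wide
  removal is available via `prevalence_scope="cohort"`.
* *Panel concordance*: homoplasmic variants (HF > 0.95) are removed when the
  cohort allele frequency differs from **either** reference panel by > 0.9;
  alleles absent from a panel count as panel AF 0. "Either panel" is the
  conservative combination rule.
* *CV filter* (off by default; the robustness re-analysis): per (pos, alt),
  the coefficient of variation of HF across heteroplasmic carriers is
  computed for sites with ≥ 3 carriers; sites at or below the 25th percentile
  of the CV distribution are removed entirely. NUMT pseudo-heteroplasmies —
  co-amplified nuclear copies — produce near-constant HF across carriers and
  therefore the lowest CVs. The carrier floor prevents single-carrier sites
  (CV undefined) from entering the distribution; both the percentile and the
  floor are configurable because the exact historical rule is not
  recoverable.

Every stage is a pure subset operation, so the cascade is idempotent and
stage counts are additive; the tests assert both.

## Negative-binomial burden regression

The response is the per-individual count of variants in one HF class
(optionally one functional category); predictors are a case indicator plus
age (years), sex (treatment-coded, reference F), mean read depth and
mitochondrial ancestry (treatment-coded, reference European). The model is
NB2 (variance = μ + αμ²) with log link, fitted by full maximum likelihood
(statsmodels `NegativeBinomial`); Wald z p-values per coefficient. When the
estimated dispersion collapses toward zero or the NB likelihood fails to
converge, the fit falls back to a Poisson GLM and the result is flagged —
this is the correct equidispersion limit, not an error. Rank-deficient
designs raise instead of silently dropping columns. Missing optional
covariates (blood pressure, smoking) are handled by complete-case analysis
per model. Bonferroni thresholds are exact internally (0.05/m) and echoed at
one significant figure only in human-readable reports (0.008, 0.01, 0.001,
3×10⁻⁵).

## SKAT-O region tests

For a region's variant set, carriers are coded 0/1 (HF dosage via a flag)
and weighted Beta(carrier frequency; 1, 25) — the de facto rare-variant
default, since no weighting scheme is prescribed for this analysis. Against
a covariate-only logistic null, the score family is

    Q_ρ = (1 − ρ) Σ_j (w_j S_j)² + ρ (Σ_j w_j S_j)²,

over ρ ∈ {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}. Per-ρ p-values use the
Liu–Tang–Zhang moment-matched chi-square approximation to the weighted
chi-square mixture (skewness/kurtosis matched); the combined p-value is the
minimum-p statistic evaluated by the standard one-dimensional integration
over the shared burden χ²₁ component, computed with a dense fixed
Gauss–Legendre rule (512 nodes on [0, 40]) — the integrand is bounded and
piecewise smooth, and the fixed rule is both accurate and fast enough for
thousands of null simulations. Exact eigenvalue (Davies) p-values are a
non-goal; instead the approximation error is *bounded by test* against a
residual-permutation oracle (|Δp| ≤ 0.02 on the reference instance at 10⁵
permutations) and by null calibration (empirical type-I error at 0.05 within
[0.03, 0.07] over 1,000 simulations). Regions with no qualifying variants
are reported as untested rather than p = 1. p_SKATO is clamped below by the
minimum per-ρ p (a mathematical lower bound); note p_SKATO ≤
max(p_SKAT, p_burden) is *not* guaranteed by the construction.

Tiles follow `bedtools makewindows` semantics: a window starts at every
multiple of the step below the genome length and is truncated at the end,
giving floor((L−1)/step) + 1 windows — 1,657 for 100 bp windows sliding by
10 bp on the mtDNA.

## Mutational signatures

Substitutions collapse to the six pyrimidine changes with explicit strand
attribution: the reference string is the L strand, so pyrimidine-reference
changes stay on L and purine-reference changes are complemented onto H.
Contexts are reported 5'→3' on the strand carrying the pyrimidine (H-strand
contexts are reverse-complemented), making the 96-context vectors comparable
across strands. Arc asymmetry uses a pooled two-proportions Z test, one-tailed
for "greater in the major arc" (the strand-asymmetric replication
hypothesis: the major arc spends more time single-stranded); x is the count
of the substitution on a strand in an arc and n the total same-strand
substitutions in that arc. The multiplicity denominator for the asymmetry
family defaults to the number of tests actually run, and is user-configurable
because no universal family size exists for this layout.

## Synthetic cohort generator

The generator emulates the *statistical structure* of a case–control deep
mtDNA sequencing study at the variant-call level (no reads are simulated —
the pipeline's entry point is the call table):

* **Inherited homoplasmies**: 150 haplogroup-like haplotypes with Dirichlet
  frequencies; 4 near-fixed backbone sites (carrier fraction 0.93–1), 3
  anchor sites at haplogroup-tagging frequencies (0.55–0.9), and private
  sites per haplotype calibrated so the per-individual mean is 9
  (HF drawn in [0.95, 1]).
* **Shared inherited heteroplasmies**: 30 recurrent sites carrying 15 % of
  the intermediate mean, HF drawn independently per carrier from the
  intermediate Beta — these give the sharing spectrum its 2–10-carrier class
  and give the CV filter a realistic high-CV background to rank NUMTs
  against.
* **Somatic heteroplasmies**: per-individual counts follow log-linear NB
  models — intermediate: mean 1.3 overall, case effect 0.27 (0.28 on the
  non-synonymous channel), age slope 0.001; low: mean 0.3, age slope 0.02
  per year, dispersions derived from the reported standard deviations via
  var = μ + αμ² (α ≈ 0.75 intermediate, ≈ 3.8 low). Class intercepts are
  calibrated against the realized covariates so the grand means are exact in
  expectation. Substitution types are 99.8 % transitions; among transitions
  80 % of the mass sits on the favored pair (C>T-on-H, T>C-on-L), and favored
  draws are placed in the major arc with an odds enrichment of 2.5. The bias
  and enrichment are the package's own defaults — no source states them —
  sized to produce a clearly detectable asymmetry at realistic call counts
  (power ≥ 0.8 from ~500 somatic calls) without saturating the spectrum.
  Positions are drawn uniformly within (substitution, arc) pools of matching
  reference base, excluding masked and placeholder positions.
* **NUMT pseudo-heteroplasmies**: 6 fixed sites, 1 % carrier rate, site-level
  HF in [0.06, 0.30] with 0.01 jitter — near-constant HF across carriers,
  the signature the CV filter keys on.
* **Artifacts**: homopolymer-region calls (0.15 per sample) and one-strand
  calls (0.05 per sample), which the mask and strand filters remove.
* **Covariates and depth**: ages uniform on [30, 90], mean depth ~N(1088,
  90²), per-site depth dispersion 18 %, 2 % of samples below the coverage
  threshold, ancestry 95/3/2 % European/African/Asian; blood pressure and
  smoking only for cases.
* **Panels and scores**: panel AFs are binomial resamples (n = 6,593 and
  498) of multiplicatively jittered cohort homoplasmy frequencies, with a
  configurable fraction of injected discordant sites (panel AF forced to 0)
  to exercise the concordance filter; the conservation surrogate draws
  D-loop sites lowest; the pathogenicity surrogate assigns a configurable
  fraction of non-synonymous variants to the ≥ 0.7 band with probability
  tilted toward low-HF variants (emulating purifying selection), which is
  what the HF-distribution comparisons detect.

One seed drives a single `SeedSequence`; stage substreams are spawned
deterministically, so identical configs yield identical cohorts.

**What passing tests do and do not show.** The generator reproduces the
study's *moments and mechanisms* (means, dispersions, effect sizes, signature
and sharing structure), not real linkage disequilibrium among mtDNA sites,
realistic haplogroup phylogeny, site-specific mutation-rate heterogeneity
(beyond arc/strand structure), or read-level error processes. Truth-
conditional results (e.g. "QC removes ≥ 95 % of artifacts") certify the
pipeline's behaviour under these generative assumptions, not its sensitivity
on any real dataset.

## Measurement conventions in the acceptance script

`scripts/acceptance.py` recomputes everything from scratch: 40 replicate
cohorts of the hypertension preset (700 cases / 360 controls) for the
case-effect recovery, 40 replicates of n = 2,000 for the age-slope recovery,
and the first 5 of those for the per-individual class means. All measurements
run the full QC cascade *with the CV filter enabled*: NUMT
pseudo-heteroplasmies carry no case or age effect, so leaving them in
dilutes the fitted coefficients — the same robustness consideration that
motivates the CV re-analysis in the first place. Forty replicates (the
criterion allows "≥ 20") halve the Monte-Carlo error of the replicate mean;
per-replicate estimates scatter with sd ≈ 0.08 around the preset. Problem
sizes were chosen so the whole script completes in well under a minute on
one CPU.

## Known limitations

* The synthetic reference preserves coordinates, frames and composition but
  not the true rCRS sequence; context-specific results are internally
  consistent, not literally transferable to real rCRS positions.
* The moment-matching SKAT-O p-value degrades in the far tail and at very
  small n; the permutation oracle is the arbiter there.
* The NB fallback cannot distinguish "truly Poisson" from "too little data
  to estimate α"; the flag reports which model produced the numbers.
* The prevalence and concordance filters assume group labels and panels are
  trustworthy; miscalibrated panels would remove genuine common variants
  (the injected discordant backbone site in the worked example shows the
  magnitude such removals can take).
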