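# Methods

This note documents the statistical model behind `hlakit`, the default
parameters and why they were chosen, what the synthetic-cohort generator does
and does not emulate, the numerical conventions, and known limitations. No
empirical claims are made beyond what the package computes.

## Nomenclature

Class I alleles are represented as `(gene, field1, field2)` with `gene ∈ {A, B,
C}`. Parsing accepts colon-delimited modern names with or without the `HLA-`
prefix, and legacy pre-2010 concatenated forms (`A0201`, `B4402`, `Cw0702`,
including 2-digit forms such as `A02`). Higher fields (`A*02:01:01:02`) and
expression suffixes (`N`, `L`, `Q`, …) are stripped: all analyses operate at
protein (4-digit) or allele-group (2-digit) resolution. Class II names are
rejected explicitly. Supertype assignment uses a packaged table of
functional-supertype memberships for HLA-A and HLA-B allele groups and
selected 4-digit alleles, including dual-membership labels; HLA-C has no
accepted supertype scheme, so lookups either raise or return a sentinel
depending on the caller's choice.

## Consensus decision tree

Each model contributes up to three ranked genotype solutions per source
(`wgs`, `rna`) plus an optional single high-resolution call. Reconciliation
applies the first matching rule:

1. **high_resolution** — a gold-standard call exists; report it.
2. **single_result** — only one source has calls; report its solution 0.
3. **match** — both sources' solution 0 agree at 4-digit resolution at all
   loci (allele pairs compared unordered via maximum bipartite matching).
4. **ASE pattern** — at loci where RNA is homozygous for an allele contained
   in the heterozygous WGS pair, the WGS pair is kept and the locus is treated
   as concordant; the result carries the `potential_ase_loss` flag and the
   affected genes. If all other loci agree at 4-digit resolution the result
   type remains `match`.
5. **curation** — per locus, candidate pairs are ranked by support level
   (present in all six solutions > present in both sources > WGS solution 0),
   with deterministic tie-breaking by source, solution rank and allele name;
   ambiguity is recorded in notes. The result is `partial_match` if the
   curated genotype agrees with both sources at 2-digit resolution and
   `manual_curation` otherwise.

A `force_undetermined` override yields `undetermined` with no genotype (the
only result type without one). An `all_homozygous` flag marks genotypes
homozygous at every locus.

## Accuracy metrics

Typing accuracy is per-allele: at each locus the predicted pair is aligned to
the truth pair by the orientation (straight or crossed) that maximizes
matches, at 4-digit or truncated 2-digit resolution; the denominator is always
two alleles per locus. Zygosity accuracy scores each locus 1 if the
predicted homozygous/heterozygous status matches the truth, regardless of
which alleles were called. Cohort headline numbers are means over models;
pooled (allele- or locus-weighted) versions are reported alongside as
diagnostics. Derived/isogenic models are excluded before evaluation so
clonally related lines are not double-counted. Percentages are displayed with
half-up rounding to one decimal.

## ASE loss

At a heterozygous locus with allele read counts `c1, c2`, the minor allele
frequency is `MAF = min(c1, c2) / (c1 + c2) ∈ [0, 0.5]`. A locus is an
ASE loss iff `MAF < 0.25` (strict). MAF is undefined for homozygous loci and
for total depth `< 10` reads (guards against zero-depth artifacts). The
0.25 threshold sits halfway between balanced expression (0.5) and complete
silencing (0), tolerating moderate allelic imbalance while catching
suppression. Per-sample summaries use the minimum MAF across the three genes.
Under an independent per-gene loss probability `p`, the expected fraction of
fully heterozygous samples with at least one loss is `1 − (1 − p)³`; this
closed form is used as a recovery oracle in tests. Case–control comparisons
use the two-sided Wilcoxon rank-sum test on per-sample minimum MAF and
Fisher's exact test on loss indicators.

## Neoepitope prioritization

Candidates carry three binding-affinity predictions (IC50, nM) and two
elution-likelihood percentile ranks. Aggregation takes the best (minimum)
score per row — the "lowest wins" convention of consensus predictors. Tier
thresholds, all strict: weak binder IC50 < 500 nM, strong binder < 50 nM,
elution percentile < 2% and < 0.5%. Baseline evidence gates: tumor DNA
coverage > 10 reads, variant allele frequency > 0.25, gene expression
> 1 TPM, transcript support level ≤ 1 (candidates without a TSL —
fusion/splice-derived — pass that gate). Within each variant only the top
epitope is kept (ordered by best IC50, then best elution percentile, then
peptide length, then lexicographically, making selection deterministic).
Recurrence counts a gene once per model. Cross-referencing matches mutant
peptides against a packaged table of experimentally validated epitopes at two
levels: peptide + HLA restriction, or peptide only with a
`restriction_mismatch` marker.

## Expression statistics

TPM values are transformed as `log2(TPM + 1)` with technical replicates
averaged on the TPM scale before transformation. Group comparisons use
Student's t or the Wilcoxon rank-sum test ("auto" chooses by Shapiro–Wilk
normality at α = 0.05); fold changes are reported only when both group means
are positive, with the mean difference always reported. Multiple testing uses
Benjamini–Hochberg step-up adjustment (via `statsmodels`). Correlations are
Pearson's r, with zero-variance inputs flagged rather than producing NaN
silently.

## Synthetic-cohort generator

All inputs can be simulated with known injected truth, driven by a single
`numpy.random.Generator`; a fixed seed yields bit-identical cohorts.
Defaults are the study conditions, fixed before any analysis and never tuned:

- `n_models = 200`; cancer-class mixture spanning ten classes including a
  control class; `n_derived = 2` isogenic derivatives.
- Genotypes: Hardy–Weinberg draws from a packaged illustrative
  allele-frequency table, with extra genomic homozygosity (LOH) injected at
  `p_loh = 0.10` per gene, so the per-gene homozygosity rate is
  `Σf² + p_loh(1 − Σf²)`.
- Source availability: 10% high-resolution, 72% both WGS and RNA, 6% WGS
  only, 12% RNA only.
- ASE: each heterozygous gene suffers loss with `p_ase = 0.15`; the
  suppressed allele is expressed at ratio `ase_suppression = 0.10`, giving
  expected MAF `s/(1+s) ≈ 0.09`. Read depth is negative binomial with mean
  100 (dispersion 10); allele counts are binomial given depth.
- Caller error: a per-allele 4-digit miscall rate of 0.05 that preserves the
  2-digit allele group, so 2-digit accuracy stays at 1 while 4-digit accuracy
  is 1 − 0.05 in expectation. RNA callers deterministically collapse a
  heterozygous gene to homozygous for the expressed allele when the simulated
  MAF falls below 0.10, producing the ASE discordance pattern.
- Candidates: ~12 per model; variant-class mixture dominated by SNVs with a
  substantial fusion fraction; log10 IC50 draws share a latent per-candidate
  binding factor (correlation 0.8 between algorithms) to which elution
  percentiles are coupled (0.5), emulating correlated predictors. A small
  number of validated driver-mutation epitopes (5) are spiked in with
  gate-passing evidence, emulating the public neoantigens real catalogs
  contain.
- Expression: class I genes at log2 TPM ≈ 8.2, class II near 0.15, matching
  the high-class-I/low-class-II profile the analysis expects.

The generator emulates the statistical structure the analysis consumes — it
does not emulate read-level sequencing, linkage disequilibrium between HLA
loci, haplotype-frequency structure, peptide–MHC binding chemistry, or
clonal architecture of variants.

## Numerical conventions

- Percentages: `decimal.Decimal` half-up rounding to one decimal place
  (banker's rounding would flip displayed values such as 96.2).
- All sorting of persisted tables uses stable mergesort and explicit key
  columns, so outputs are byte-identical across runs for a fixed seed.
- Derived seeds are kept below 2³¹.
- MAF, accuracy and tier computations use exact integer arithmetic where
  possible (counts, matches) and only convert to float at the final division.

## Limitations

- Only the classical class I genes (HLA-A/B/C) are handled; class II typing,
  non-classical class I, and field-3/4 resolution are out of scope.
- The supertype table covers the common functional assignments, not every
  described allele; unlisted alleles are reported as unclassified.
- The packaged allele-frequency table is an illustrative fixture, not a
  population estimate; absolute homozygosity rates from the simulator should
  not be interpreted biologically.
- ASE-loss calling from a single MAF threshold cannot distinguish
  transcriptional silencing from copy-number loss, imprinting or mapping bias.
- The curation heuristic is a deterministic operationalization of a manual
  review process; genuinely ambiguous loci are flagged in notes rather than
  resolved.
- IC50 and elution predictions are treated as given inputs; no binding
  prediction is performed.
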