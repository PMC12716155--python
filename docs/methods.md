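# Methods

`peagene` re-implements, as a tested library, a targeted-gene SNP analysis of
seed composition in pea (*Pisum sativum*): a capture panel over storage-protein
and starch-pathway genes is sequenced in a diversity panel of accessions, the
resulting variants are filtered to a high-quality biallelic SNP set, population
structure is summarized (PCA, neighbor joining, PC-score dendrograms), each SNP
is tested against protein and starch content with structure covariates, and
per-SNP effects are aggregated to gene-level effects with inverse-variance
weights. A simulator with known ground truth provides the data on which every
one of these steps is validated.

## The two-stage gene-to-phenotype model

Stage 1 fits, separately for each SNP *j*,

    y_i = mu + beta_j * g_ij + gamma_1 PC1_i + gamma_2 PC2_i + eps_i,
    eps_i ~ N(0, sigma^2)

where `g_ij` in {0, 1, 2} counts minor alleles (0 = homozygous major) and
PC1/PC2 are the leading principal components of the centered, mean-imputed
dosage matrix. Estimation is ordinary least squares over complete cases; the
dosage coefficient's standard error comes from the design inverse and the
two-sided p-value from a t distribution on `n - 4` degrees of freedom. The
displayed model contains no random terms, so OLS is the faithful estimator
even though mixed-model software can fit it.

SNPs with raw `p < 0.05` (strict, no multiple-testing correction — a
Benjamini-Hochberg option exists but is off by default, matching the raw
threshold this analysis style uses) are mapped to their genes. Stage 2
aggregates each gene g's significant SNPs S_g with weights `w_j = 1/SE_j^2`:

    E_g  = sum_{j in S_g} w_j beta_j / sum w_j
    SD_g = sqrt( sum w_j (beta_j - E_g)^2 / sum w_j )

`SD_g` is the weighted root-mean-square deviation about `E_g`. A first-moment
version of this formula (without the square) is identically zero for any
weights, so the RMS form is the only one consistent with reporting a
per-gene "± SD" that is 0 exactly when a gene has one significant SNP.
Zero standard errors (perfect fits) would give infinite weight; they are
capped at `w_max = 1e12`. Flanking-region SNPs inherit their assigned gene
for aggregation but carry a `region_category` so they can be excluded.

Pleiotropy is operationalized as the intersection of the two traits'
significant SNP sets, together with the genes that intersection maps to.

## Filtering and encoding

* Markers retained when `MAF > 0.05` and `missing fraction < 0.20`, both
  strict; the missingness rule is applied per marker (yielding a fixed marker
  panel), with an optional per-accession filter available separately.
* Multi-allelic VCF records are split per ALT allele; non-SNP alleles go to
  the InDel tally and never enter the dosage matrix.
* After `recode_major_minor`, dosage 2 always counts the minor allele; an
  exact 0.5 frequency keeps REF as major (deterministic, order-independent).
* Gene intervals are BED-like (0-based half-open); a 1-based VCF position is
  in the body iff `start < pos <= end`. Outside all bodies, a position within
  `flank_bp` of exactly one gene is `flanking`; within several flanks it is
  ambiguous and stays unassigned. Nested-gene ties go to the smallest
  interval, then lexicographic gene id.
* SnpEff-style `ANN` fields collapse to one impact class per marker, most
  severe first (HIGH > MODERATE > LOW > MODIFIER); absent or unrecognized
  annotations are UNANNOTATED.

## Population structure

* PCA is the SVD of the centered dosage matrix after per-marker mean
  imputation; explained fractions are `sigma_k^2 / sum sigma^2`. The sign of
  each component is fixed by making its largest-magnitude loading positive so
  score files are reproducible across SVD implementations.
* Pairwise distance is 1 minus mean identity-by-state over markers observed
  in both accessions (`1 - |d_i - d_j|/2` per marker). IBS distance is not
  guaranteed metric; no triangle inequality is asserted. A pair sharing zero
  markers is a hard error rather than a silent NaN.
* Neighbor joining is the Saitou-Nei agglomeration with the Studier-Keppler
  Q criterion, written here rather than delegated so the negative-branch
  policy is explicit: a negative branch is clamped to zero and the deficit
  moved to its sister, preserving path lengths and valid Newick. On additive
  inputs the reconstruction is exact (verified to 1e-9 against random
  additive trees, and cross-checked against scikit-bio's implementation).
* PC-score dendrograms use Ward linkage on Euclidean distances over the first
  two PCs (scipy). The linkage choice is a declared default — the analysis
  style this mirrors says only "hierarchical clustering" — picked because
  Ward yields the compact, trait-alignable clusters the dendrogram-vs-trait
  comparison needs.

## Mixed-type trait correlations

Cell dispatch depends only on the unordered pair of declared column types:
Pearson (continuous-continuous), point-biserial = Pearson on a 0/1 coding
(continuous-binary), sqrt(eta-squared) from one-way ANOVA with the F-test
p-value (continuous-multicategory), and Cramér's V from an uncorrected
chi-square (categorical-categorical). Because point-biserial signs depend on
the 0/1 coding, the coding is fixed and recorded: wrinkled = 1, patterned = 1,
non-round = 1; other binaries default to the lexicographically larger level.
Missing phenotypes are handled by pairwise-complete deletion. The output
carries a method matrix and significance codes (*** < 0.001, ** < 0.01,
* < 0.05, NS) because the coefficients are not mutually comparable.

## The simulator

`synthetic_data` generates the study conditions end to end: 100 accessions;
58 genes over 7 chromosomes (per-chromosome counts 14, 2, 12, 3, 14, 12, 1 —
the per-chromosome breakdown, which sums to 58; gene names follow the
storage-protein and starch-enzyme vocabulary of the domain); gene bodies of
2-5 kb with 1 kb flanking windows; roughly 100 body SNPs and 24 flanking SNPs
per gene; 3% missing calls; protein and starch intercepts 25.54 / 40.09 (%
dry weight) with residual SDs 2 and 3.

Key modelling choices:

* **Allele frequencies.** Ancestral minor-allele frequencies come from a
  rare-skewed two-component mixture: with probability `rare_fraction` (0.7)
  uniform on [0.025, 0.05), else uniform on [0.05, 0.495]. Sequencing panels
  are dominated by rare variants, and this mixture is what makes the MAF
  filter discard a realistic share of the panel (about 6.5k raw SNPs down to
  roughly 2.5-3k retained at n = 100).
* **Structure.** Balding-Nichols drift: each subpopulation's frequency is a
  Beta draw with mean p and variance `fst_like * p(1-p)` (defaults: 3
  subpopulations, `fst_like = 0.12`). Genotypes are binomial(2, p_subpop);
  missingness is completely at random.
* **Causal effects.** A causal gene's effect E (trait % per minor-allele
  dosage unit) is split equally over its m body markers (E/m each), acting on
  minor-allele dosage where "minor" is decided by the realized sample
  frequency — the only coding the analysis itself can reconstruct. Causal
  contributions are mean-centered so trait means stay at their intercepts,
  and causal-gene body markers are drawn from the common frequency band: an
  effect placed on a marker destined to fail the MAF filter would be
  invisible by construction. Because markers are mutually independent (no
  LD), each marker's marginal slope is E/m and the aggregated E_g estimates
  E/m; recovery experiments therefore use single-marker causal genes, for
  which gene-level and marker-level truth coincide. Pleiotropy is simulated
  by listing the same gene under both traits.
* **Morphology.** Binary wrinkling is a threshold on a latent
  `rho * z(starch) + sqrt(1-rho^2) * noise`. For a threshold at quantile q the
  attainable point-biserial is `rho * phi(z_q)/sqrt(q(1-q))` (at most 0.798
  |rho| for a median split), so `rho` is solved analytically from the target
  correlation (default -0.71 at q = 0.5); targets needing |rho| > 1 raise.
  Shape, seed size (mm^2), color, and patterning follow the latent chain with
  configurable cross-correlations.

What the generator does **not** emulate: linkage disequilibrium and
recombination maps, dominance/epistasis, informative missingness, assay-level
replicate noise, genotyping error, and the particular MAF spectrum of any
real panel. Tests passing on these simulations therefore certify the
*pipeline arithmetic and its statistical calibration* under an additive,
LD-free world — not discovery performance on real capture data.

## Numerical and degenerate-input conventions

* All randomness flows from one seed through `numpy.random.SeedSequence`
  spawning; a fixed configuration reproduces bit-identical datasets and
  byte-identical serialized files.
* Markers monomorphic over complete cases or producing a rank-deficient
  design are skipped with a log entry, not silently dropped.
* All-missing markers: MAF undefined and flagged; dropped by the filter and
  by PCA imputation (with a warning).
* p-values are floored at the smallest positive double to keep them in (0, 1].
* Stage-1 fits need at least 6 complete cases and more cases than parameters.

## Experiment sizes used by the validation suite

The calibration experiments run at: 10,000 null markers x 100 accessions
(type-I error, expected rejection in [0.043, 0.057] at alpha = 0.05); 100
replicates of n = 300 with a single-marker causal gene of effect 3.0 and
noise SD 2 (mean recovered E_g within 0.3 of truth); 6,000 null markers x
200 accessions in two drifted subpopulations with a +-2 trait shift
(rejection inflated without PCs, within [0.04, 0.06] with PC1-PC2); and
n = 2,000 for the wrinkling-starch target of -0.71 +- 0.05. These sizes give
binomial/Monte-Carlo standard errors several times smaller than the bands
they are checked against.

## Reference-data check

One check recomputes published per-accession phenotype summaries (mean
protein 25.54%, mean starch 40.09%, wrinkling-starch point-biserial -0.7065,
protein-starch Pearson -0.5119) through `trait_stats`. The per-accession
table behind those numbers is distributed only as external supplementary
material in an unnamed online repository, so the test fails with an
explanatory message when `tests/data/sm1_per_accession_phenotypes.csv` is
absent; supplying that table (columns `accession_id, protein_pct,
starch_pct, seed_wrinkling`) activates the comparison. No synthetic stand-in
is passed off as the reference data.

## Known limitations

* E_g estimates per-marker truth (E/m), not total gene effect, whenever a
  causal gene carries several independent markers; with real LD the marginal
  slopes would instead approach the full tagged effect.
* The raw p < 0.05 selection is intentionally anti-conservative (it mirrors
  the analysis style being reproduced); with ~3,000 markers it admits ~150
  false positives per trait, and gene lists built from it should be read
  accordingly. Use `bh_correction=True` for an FDR-controlled variant.
* Ward-on-PC-scores and 1-IBS NJ are declared defaults, not inferences about
  any particular published pipeline's internals.
* The per-marker missingness rule is one reading of an ambiguous
  "per accession" phrase; the per-accession variant is provided but off by
  default.
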