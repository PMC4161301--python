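# Methods

## Model and assumptions

The pipeline assumes biallelic SNPs coded as minor-allele counts 0/1/2,
cohort-relative (the minor allele is re-derived after sample intersection),
and per-gene expression that is already normalized to an approximately
Gaussian scale — no normalization is performed here. All genetic effects are
modeled as additive per allele copy; dominance, epistasis, covariates and
population-structure corrections are out of scope, matching the design the
method reimplements (a plain PLINK-`--assoc`-style scan).

Genotype quality filters — MAF > 0.05 (strict), per-SNP missingness < 0.1,
per-sample missingness < 0.1 — interact (dropping a sample changes per-SNP
MAF and missingness), so they are iterated to a fixed point; the result is
independent of application order. Missing genotypes are handled
pairwise-complete per regression. Coordinates are 1-based inclusive
internally (the VCF convention); BED inputs are converted on read. MAF is
recomputed after sample intersection; on subsets where the cohort minor
allele flips, counts are re-oriented.

## Statistical machinery

* **Marginal association**: OLS slope of expression on allele count with
  intercept; t = r√(n−2)/√(1−r²) referred to t(n−2), two-sided. No normal
  approximation — the intended cohort scale is ~50 samples. A numerically
  perfect fit reports the smallest positive normal double as p and a
  `perfect_fit` flag.
* **Conditioning**: the SNP coefficient's t-test in the joint model
  `target ~ intercept + snp + covariate` with exact df (n−3), solved by
  normal equations with a rank check. Collinear designs and saturated fits
  raise a degenerate-model error and the candidate is skipped with a log
  message. "Nominally significant" is α = 0.05, two-sided, throughout.
* **Triplet classification** is exhaustive and mutually exclusive: both
  conditional signals survive → mutual; exactly one → directional (the
  surviving side names `directional_target`); neither → the candidate is
  discarded, never stored.
* **Cooperating filter**: all four SNP coefficients (b₁, b₂ in both target
  models) significant at α. Perfectly collinear sources (r² = 1) fail with a
  `collinear` flag since the coefficients are not identifiable.
* **Intermediate-SNP filter**: a candidate s₃ must share a chromosome with a
  source (an intermediate explanation via linkage requires co-localization),
  must itself form a triplet with the two genes, and must win a
  conditional-significance exchange test against that source on *both*
  genes: p(source | s₃) ≥ α while p(s₃ | source) < α. This test is a
  reconstruction from a qualitative description; the package documents it as
  its own design and the LD simulations in the test suite show it removes
  tag-SNP quartets while keeping the causal ones.
* **Unique-targets deduplication** keeps, per gene pair, the quartet
  minimizing the maximum of its four marginal p-values (ties broken by SNP
  IDs). The worse marginal p is also the ranking key when tightening the
  association threshold to match the mean permuted triplet count — it is the
  binding constraint that defines a triplet.
* **Permutation null**: genotype sample labels are shuffled (equivalently,
  profiles are reassigned to samples); expression is untouched. Either side
  could be permuted; permuting one block preserves within-block correlation
  exactly. Per-permutation seeds derive from one master seed via a seed
  sequence. Empirical p is reported in both the add-one convention
  (1 + #{perm ≥ real})/(1 + N), which cannot return 0, and the raw
  proportion; add-one is primary. Empirical FDR = mean permuted count / real
  count, capped at 1, undefined at real count 0.
* **Sign algebra**: edges are oriented by the sign of the marginal slope.
  Consistency ⇔ even number of up edges ⇔ sign product +1 (8 of 16
  configurations). The consistent set splits into 4 two-member categories by
  the genes axis (do the sources act on g₂ as they do on g₁?) and the snps
  axis (does s₂ act on the targets as s₁ does?). The two members of a
  category are global sign flips of one another; negating a single source's
  two edges flips the snps axis (this follows directly from the axis
  definitions and is asserted by enumeration).
* **Fisher's exact tests** are two-sided (scipy), cross-checked in the tests
  against a from-scratch hypergeometric enumeration on every
  symmetry-distinct 2×2 table with total ≤ 40. The co-expression
  real-vs-permuted comparison uses a two-sample rank test (Mann–Whitney) on
  |r| for robustness. Functional-annotation and GWAS-overlap tests run
  against user-supplied tables (gene → term; gene list) — no live database
  queries.

## Synthetic data

The generator emulates exactly the structure the analysis assumes: genotypes
are Binomial(2, MAF) draws in Hardy–Weinberg proportions with MAF uniform in
`maf_range` (default 0.1–0.5, always above the quality filter); expression is
additive planted effects plus N(0, noise_sd²) with noise_sd = 1 by default;
non-planted genes are pure noise. Planted bi-fans take a 2×2 slope matrix and
four chromosomes (sources default to chr1/chr2, targets chr3/chr4 — a trans
motif); mediation chains are SNP → g₁ → g₂ on one chromosome. LD pairs are
generated by a Gaussian copula: a latent bivariate normal is thresholded at
Hardy–Weinberg quantiles, and the latent correlation is solved by bisection
on the exact rectangle probabilities so the realized count correlation lands
within ±0.05 of the target; infeasible targets (beyond what the two margins
allow) raise an error naming the bound. Default n_samples = 50 mirrors a
small sequencing cohort; the recovery and stability suites use n = 200,
MAF 0.3 and unit slopes, where single-edge power at p < 10⁻⁴ is ≈ 1.

What the generator does **not** emulate: realistic haplotype/coalescent LD
beyond explicit pairs, population structure, non-Gaussian expression,
batch effects, or polygenic background. Passing tests therefore demonstrate
correctness of the machinery and calibration under the assumed model, not
robustness to real-data violations of it.

## Problem sizes and numerical choices

The calibration experiments run at deliberately small scale chosen as the
smallest sizes at which each property is statistically crisp: null
calibration uses 50 samples × 200 SNPs × 100 genes (20,000 tests, exact
binomial 99% band at α = 0.05) with a 50-permutation band at threshold 10⁻³
(where null counts are non-trivially positive); planted recovery uses 10
bi-fans among 33 noise genes (528 null gene pairs) over 10 seeds. The
"within the permutation band" check uses the empirical [min, max] of the
permutation counts. Oracle-equivalence suites use 1000 random instances at
n ≤ 30 with tolerance 1e-9; the regression path is closed-form/normal
equations, the oracles are statsmodels and an independently written
normal-equations solver.

Ties in ranking and deduplication are always broken lexicographically by
identifiers, making every pipeline stage deterministic given the inputs and
the master seed. Degenerate inputs (constant genotype, constant expression,
collinear designs) follow explicit contracts rather than producing NaNs:
errors where the quantity is undefined, null results (β = 0, p = 1) where a
constant response makes "no evidence" the right answer.

## Known limitations

* The intermediate-SNP exchange test is the package's own reconstruction of
  a qualitatively described filter; other operationalizations ("better"
  as likelihood or R² comparison) are defensible and would change borderline
  cases.
* The unique-targets representative (min of max marginal p) is one
  reasonable choice among several; merging annotations across the discarded
  quartets is not implemented.
* Orientation auto-detection of the expression TSV requires the genotype
  sample IDs; with none supplied, rows are assumed to be genes.
* At cohort sizes near the minimum (10 shared samples) the conditional
  regressions have very few residual degrees of freedom; results there are
  exact but fragile, and the documented intended regime is n ≳ 50.
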