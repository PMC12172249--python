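# Methods

## The analysis

`l1burden` reimplements, end to end, a genome-wide association analysis of
polymorphic LINE-1 (L1) retrotransposon insertions in an ALS case-control
cohort. The unit of data is the insertion-Present ("P") allele count per
individual per locus: reference L1s (in the genome assembly, genotyped as
deletions when absent) and non-reference L1s (novel insertions, genotyped
MELT-style) are both recoded onto this common scale, so a genotype is 0, 1
or 2 Present alleles regardless of calling dialect.

The pipeline has four analytical stages over the QC'd genotypes:

1. **QC ledger.** Non-reference calls must carry ≥ 2 supporting split reads,
   an assessment score ≥ 3 and a PASS caller filter. The analysis cohort is
   restricted to individuals with > 90% European ancestry fraction and a
   diagnosis of ALS, ALS with another neurological disorder (ALSND), or
   non-neurological control (NNC). Loci out of Hardy-Weinberg equilibrium
   in controls (exact test p < 1e-6, strict) are removed. Two subsets
   branch off: loci with minor allele frequency strictly above 0.01 (the
   per-locus scan set) and the burden set — retrotransposition-competent
   (RC) loci from a curated catalog, autosomal, with ≤ 5% missing
   genotypes, further restricted to individuals genotyped at every
   retained locus. Every filter emits a ledger row
   (step, n_in, n_removed, n_out, criterion) and ledgers chain, so the
   locus accounting is fully auditable.

2. **RC burden.** Each individual's burden is the plain sum of Present
   alleles over the retained RC loci (no weights). Association with disease
   is a linear model `count ~ status + sex + age + seq_prep`, so the status
   coefficient β is in allele units (cases minus controls). A companion
   threshold scan fits, for each cut-point k in {43..48}, the logistic
   model `status ~ I(count ≥ k) + sex + age + seq_prep`, with Bonferroni
   correction over the thresholds actually fitted. Burden is also tested
   against age at onset (linear) and survival (Cox), both expected null.

3. **Per-locus scans.** Additive allele coding (0/1/2) throughout:
   case-control logistic regression (covariates sex, age, sequencing
   preparation), age-at-onset linear regression in cases (sex, sequencing
   preparation, site of onset), and Cox proportional hazards on survival in
   cases (sex, sequencing preparation, age at onset, site of onset), each
   Bonferroni-corrected over the number of loci fitted. "Age" follows the
   cohort convention: collection age for controls, onset age for cases;
   individuals missing it are dropped (complete case). Carrier-group onset
   means (Present-carrier vs homozygous-absent) are reported alongside the
   additive estimate; for rare loci without homozygous-Present genotypes
   the two codings coincide exactly.

4. **eQTL scan and RC enrichment.** Every (locus, transcript) pair within
   each of two motor-cortex tissues is tested with
   `expression ~ genotype + age + sex`; no cis-window restriction.
   Benjamini-Hochberg FDR is applied within tissue; a locus counts as an
   eQTL once if significant for ≥ 1 transcript in ≥ 1 tissue. Enrichment
   of RC loci among eQTL loci is a two-sided Fisher's exact test on the
   (RC vs non-RC) × (eQTL vs not) table over all tested loci, reported with
   both proportions and their explicit denominators.

## Statistical kernels

- **Exact HWE test** (own implementation): conditional on allele counts,
  the probability of every heterozygote configuration is built by the
  stable ratio recurrence, and the two-sided p is the summed mass of
  configurations no more probable than the observed one (no mid-p). Tests
  sweep every table with n ≤ 50 against an independent closed-form
  enumeration oracle.
- **Linear models**: ordinary least squares via statsmodels, classical
  standard errors; Student-t Wald p-values.
- **Logistic regression** (own implementation): Newton/IRLS with step
  halving; convergence when the score's max absolute entry < 1e-8 or the
  relative log-likelihood change < 1e-10, capped at 100 iterations.
  Separation (non-convergence or any |coefficient| > 15) triggers a Firth
  penalized refit, flagged `firth_fallback`, instead of dropping the locus.
  These tolerances are fixed, not configurable, for reproducibility.
- **Cox proportional hazards** (own implementation): Newton maximization
  of the Breslow-ties partial likelihood on internally standardized
  covariates; censored individuals contribute to risk sets only; monotone
  likelihoods are flagged. lifelines (Efron ties) is the cross-check oracle
  on tie-free data, where the two tie conventions coincide. The study we
  emulate cites a mixed-effects survival package but lists only fixed
  covariates; this package deliberately fits fixed effects only.
- **Fisher's exact test**: two-sided by summing hypergeometric
  probabilities ≤ the observed table's (relative tie guard 1e-12),
  normalized over the support. Odds ratios use the cross-product with a
  Woolf CI; the Haldane-Anscombe 0.5 correction is applied, and flagged,
  only when a cell is zero.
- **Multiple testing**: Bonferroni `min(1, p·m)` with the family size
  always the number of tests actually fitted (printed in the log);
  Benjamini-Hochberg step-up via statsmodels.
- All 95% intervals are Wald (estimate ± 1.96·SE, exponentiated for
  OR/HR), matching the reporting convention of the standard tools in this
  field (PLINK-style scans).

## The synthetic cohort generator

Access to the real consortium genomes is controlled, so the package ships a
generator whose defaults are the study conditions; all tests and the
acceptance script run on it.

| parameter | default | rationale |
|---|---|---|
| cohort | 320 NNC / 2,653 ALS+ALSND | analysis-cohort sizes |
| locus registry | 205 reference + 2,598 non-reference (+10 caller-evidence failures, +5 HWE violators) | post-QC registry size; decoys exercise the filters |
| IAF spectrum | 89.3% of reference and 5.7% of non-reference loci common (IAF ≥ 0.1, uniform to 0.98); the rest power-law p^-1.75 on [2e-4, 0.1) | bimodal reference/non-reference spectrum; the exponent sets the MAF > 0.01 scan set to ~501 loci |
| RC structure | 93 in-cohort RC loci (30 reference), of which 3 on chrX and 1 with 8% missing calls | reproduces the 93 → 89 burden-locus accounting |
| burden loci | 8 near fixation (IAF 0.95-0.99) + 81 at IAF 0.08-0.27 | gives per-genome counts centred near 44 with SD ≈ 4.9, i.e. control range ≈ [32, 56] and case range ≈ [30, 63] |
| burden shift | 0.40 alleles (cases − controls) | implemented by tilting each burden locus's case IAF by 0.40/(2·89), so HWE holds within each group — the mechanism a liability-style model would produce, and one of several consistent with the data |
| onset modifier | one locus, IAF 0.017, carrier (dominant) effect −6.55 y on a 59.2 y baseline, noise SD 12 y | rare onset-modifier conditions; ~84 carriers among cases |
| genotype missingness | 0.00105 per call (8% at the designated high-missingness locus) | leaves ~91% of individuals complete over 89 loci, matching the complete-case cohort of ~2,708 |
| survival | exponential, median 36 months post onset; uniform censoring at 6–120 months follow-up | 2–5 y life expectancy; censoring at last follow-up |
| ages | controls N(57.4, 13) on [17, 90], 13.4% missing; cases = onset, 6% missing | demographic table conventions |
| sex | 49.1% male in controls, 60.1% in cases | demographic counts (157/320 and 1,594/2,653), kept as counts so the printed percentages are reproducible arithmetic |
| expression | 2 tissues × 150 transcripts × 300 case samples; 30 planted eQTLs, slope 1.0 per allele, noise SD 1 | enough planted signal to exercise FDR and the enrichment table |

Randomness flows from one seed through named substreams (loci, genotypes,
phenotypes, expression), so outputs are byte-identical per seed and partial
regeneration is stable. An infeasible burden shift (case IAFs would exceed
0.999) raises with the maximum achievable shift. `simulate_null` zeroes
every planted effect and feeds all type-I-error suites. `focused_config`
keeps the cohort sizes and the full RC/burden structure but shrinks the
decoy registry, for repeated-seed experiments where the ~2,700 non-RC loci
are irrelevant.

### What the generator does and does not emulate

It emulates the marginal structure the analyses rely on: the bimodal
frequency spectrum, HWE within groups, the burden shift, censored
proportional-hazards survival, covariate conventions and missingness. It
does **not** emulate linkage disequilibrium between loci (loci are
independent), population substructure within the European subset,
covariate-burden dependence (covariates are generated independently of
burden; stated in the truth metadata), genotyping-error correlation with
coverage, or the heavy right tail the real burden distribution may have.
Consequently, passing tests demonstrate that the statistical machinery is
correct and calibrated under the stated model — not that the biological
findings would replicate. In particular, a 0.40-allele mean shift on a
burden SD of ~4.9 moves the ≥ 46-allele tail by only ~3 percentage points,
so tail percentages and the threshold-scan OR implied by this generator are
mild (OR ≈ 1.1–1.2 at k = 46); a real cohort could reach larger tail
separations only through distributional features this generator does not
model.

## Numerical and design choices

- Coordinates: VCF positions stay 1-based in records; interval arithmetic
  (genomic context, gene overlap) is 0-based half-open internally, with
  exon > utr5 > utr3 > intron > intergenic precedence.
- Missing genotypes: any GT with a missing allele (`./.`, `0/.`) is
  missing; nothing else is. Missing-evidence non-reference loci fail the
  caller filter and are counted in their own ledger step.
- MAF for the scan set is computed on the analysis cohort (the subset
  entering association); a full-cohort alternative is selectable
  (`maf_cohort="full"`). Missingness denominators are the analysis cohort
  after cohort selection, before complete-case restriction.
- chrY is handled like chrX in the burden filter (defensive; none are
  generated).
- Boundary semantics follow the filters' definitions exactly: HWE removal
  is strict `<` threshold, MAF keep is strict `>` 0.01, missingness
  removal is strict `>` 5%, ancestry keep is strict `>` 0.9; split reads
  and assessment score are inclusive `≥`.
- The threshold-scan cut-points default to {43, 44, 45, 46, 47, 48}: six
  categories centred on the reported significant window, overridable in
  config since the study never printed its exact six.
- The burden model direction is `count ~ status` so β is in allele units;
  the logistic reverse (`status ~ count`) is available via the threshold
  scan machinery if wanted.
- eQTL per-pair fits are computed by Frisch-Waugh residualization per
  locus (vectorized over transcripts), which is exactly equal to the
  stand-alone OLS for every pair (asserted in tests); per-locus
  complete-case handles missing genotypes without imputation.
- Degenerate cases are skipped and labelled, never silently dropped:
  monomorphic loci in scans, thresholds outside the observed burden range,
  zero-variance transcripts, loci with no genotyped controls (HWE p
  defaults to 1: no evidence against equilibrium).

## Problem sizes used by the test suite and acceptance script

Simulation-based checks run at the full cohort size (320/2,653). The
type-I suite pools 20 null cohorts for the per-locus scan, 50 for the
threshold scan and 20 for the eQTL scan; recovery experiments average 100–300
seeds (burden β), 100 (onset effect, planted OR). Exhaustive oracle sweeps
cover every HWE table with n ≤ 50 and every 2×2 table with margins ≤ 30.
These sizes were chosen so each experiment's Monte-Carlo error is small
relative to the tolerance it is checked against.

## Known limitations

- Fixed-effects Cox only; no frailty/kinship random effects.
- No LD, no ancestry structure, no SKAT-style weighted burden (the
  statistic of interest is the unweighted count).
- Firth fallback changes the estimand slightly at separated loci (penalized
  vs ML estimates); such loci are flagged so downstream consumers can
  filter on it.
- The eQTL stage assumes expression is already normalized; no batch
  correction is applied upstream of the scan.
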