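# Methods

This note documents the generative model behind the synthetic cohorts, the
statistical models the package fits, the decomposition logic, the defaults
and the numerical choices, and what the simulation-based checks do and do
not establish about real data.

## Scientific setting

Verbal ability (a PVT-style standardized vocabulary score measured at two
survey waves) is jointly shaped by a person's own genome and by the
socioeconomic environment their parents provide. Parental SES is itself
partly a product of the parents' genomes, and a child inherits half of each
parent's alleles. Consequently:

* a regression of ability on parental SES alone overstates the
  *environmental* SES effect (part of the SES coefficient is carried by
  alleles the child shares with its parents), and
* a regression on the child's polygenic score (PGS) alone overstates the
  *direct* genetic effect (the score proxies for the genomic component of
  the rearing environment — "genetic nurture").

The package quantifies both biases with sibling-clustered multilevel models
and corrects them with a coefficient-reduction argument: when the offspring
PGS is added to an SES model, the SES coefficient sheds (approximately) the
half of its genomic component shared with the child, so the full genomic
component is about twice the observed reduction:

```
enviSES = ParentalSES − 2 · (ParentalSES_without_PGS − ParentalSES_with_PGS)
```

On the variance scale, the incremental R² of SES over a PGS model is split
into an environmental part and a genomic-in-SES part, the latter bounded
above by the net-PGS incremental R² (the transmitted-allele effect is the
larger of the two, so the bound is conservative in the intended direction).
The bound is surfaced as its own ledger field so users can substitute a
different one.

## Generative model of the synthetic cohort

`simcohort` draws families of MZ twins, DZ twins, full siblings and
singletons. For each family:

1. **Genomes.** K biallelic SNPs with frequencies uniform on a configured
   range; optional population substructure via Balding–Nichols Beta
   perturbation of the base frequencies with divergence `fst`. Parents carry
   two phased haplotypes per SNP; each child receives one haplotype pick per
   SNP per parent with probability 1/2, independently across SNPs (no
   linkage: the decomposition algebra operates on aggregate scores, so LD
   adds realism without changing any estimand here). MZ co-twins copy the
   first twin's transmission outcome. The transmitted (T) and non-transmitted
   (NT) weighted allele sums are stored per child.
2. **True score.** Per-SNP weights are N(0, τ²/K), making the score variance
   K-invariant: Var(U) = Σ w²·2pq ≈ τ²·E[2pq]. The analyst-visible weight
   files are the true weights plus independent N(0, σ_noise) per SNP — two
   files, an "education-like" one (smaller noise) and a "cognition-like"
   one (larger noise), mirroring a strong and a weak GWAS.
3. **Parental SES.** A latent `S* = γ(U_mother + U_father) + ε`,
   ε ~ N(0, var_ses_env). All parental alleles act on SES while only half
   reach the child — this single asymmetry generates the entire
   genetic-nurture confounding structure.
4. **Indicators.** Parental education (3 levels), 16-code occupations mapped
   to an 11-level prestige scale, income quintiles, sibship size, a
   two-biological-parent flag, and six tract proportions (poverty,
   unemployment, female-headed households, no-HS-diploma, college degree,
   managerial jobs) are noisy monotone transforms of S*, per wave for the
   tract measures. They exercise the full SES design without modelling each
   indicator causally. MCAR missingness at a configured rate is injected
   into the indicator cells (never into phenotype or ids).
5. **Phenotype.** For waves t ∈ {1, 3}:

   ```
   Y_tij = β₀ + b_child·Z(U_o) + c_env·Z(S*) + gxe·Z(U_o)Z(S*)
           + demographic terms + μ_j + ν_ij + e_tij
   ```

   with independent Normal random intercepts at the family (σ²_u), person
   (σ²_v) and wave (σ²_e) levels.

### Model-implied slopes (the analytic oracle)

With V = Var(U_o) = Var(NT) = Σ w²·2pq, transmission independence gives
Cov(U_o, S*) = γV and Var(S*) = 2γ²V + var_ses_env, hence
ρ = Corr(U_o, S*) = γV / (√V·σ_S). For standardized single-predictor
regressions the population slopes are:

```
SES-only slope = c_env + b_child·ρ        PGS-only slope = b_child + c_env·ρ
```

`model_implied_slopes` evaluates these from the realized weights and
frequencies; large simulated cohorts must reproduce them within Monte-Carlo
error. The closed form assumes a single stratum (with substructure plus a
stratum phenotype effect, extra confounding terms appear), so the function
refuses multi-stratum configs.

Population-level consequences used as directional checks: the SES-only
slope exceeds the joint-model SES slope, which exceeds the corrected
enviSES value whenever b_child, c_env, γ > 0; with γ = 0 all reductions
vanish. Note that when the analyst PGS is *noiseless* the joint model
recovers c_env exactly and the ×2 correction overshoots by exactly the
original bias; with a noisy PGS (the realistic and default regime) the
joint SES coefficient retains part of the confounding and the corrected
value lands strictly closer to c_env. The correction is an approximation
tied to measured-score attenuation, not an identity.

## Defaults and why

| parameter | default | rationale |
|---|---|---|
| n_families | 3,000 (≈5,100 persons) | sibling-cluster cohort on the scale of the motivating study |
| sibship mix | 5% MZ, 5% DZ, 60% full sib, 30% singleton | enough twin pairs for the twin descriptive and within-family designs |
| n_snps, τ | 200, 1.0 | score variance is K-invariant; 200 loci keep PCs and scoring fast |
| allele freq range | (0.2, 0.8) | common variants, E[2pq] ≈ 0.44 |
| n_strata, fst, weights | 2, 0.01, (0.8, 0.2) | mild two-population admixture so ancestry-PC control is testable |
| γ, var_ses_env | 0.5, 1.0 | genomic share of SES variance ≈ 18%, ρ ≈ 0.30 |
| b_child, c_env | 2.5, 4.2 | on the PVT point scale; put SES-only R² near 0.20 and PGS-only R² near 0.07–0.13 |
| σ²_u, σ²_v, σ²_e | 38, 28, 25 | PVT-scale variances; strong family clustering, sizable person stability |
| weight-file noise | 0.065 (edu), 0.12 (cog) per SNP | analyst PGS reliabilities ≈ 0.55 and ≈ 0.25, attenuating the net-PGS incremental R² into the small-percentage regime typical of measured scores |
| missing_rate | 0.05 | a few percent missing per indicator, as in survey SES blocks |
| demographic effects | age 0.4, female −1.1, stratum −4.4, US-born 2.0, English-home 4.6, in-school 1.5 | realistic PVT-scale covariate structure; stratum effect makes admixture confounding real |

These defaults are the package's reference study conditions; the validation
suite runs against them (larger or structurally special cohorts are used
only where an asymptotic or balanced design is the point, and the sizes are
stated in each check).

## Estimation

* **Three-level model** (wave rows ⊂ persons ⊂ families): statsmodels
  `MixedLM` with the family intercept as the random-effect group, the person
  intercept as a variance component, and the residual as the wave-level
  variance. Sibship types are not distinguished in the covariance structure.
* **Conditional wave-3 model**: persons contributing both waves, wave-3
  score regressed on the wave-1 score plus the same design; two levels
  (family intercept + person residual).
* **ML vs REML**: REML by default; ML whenever fits feed a likelihood-ratio
  test. The LRT refuses REML fits with differing fixed effects.
* **Convergence**: L-BFGS with up to 200 iterations, falling back to BFGS
  and Powell restarts; boundary fits that stall without formally converging
  are returned (flagged) rather than discarded.
* **Companion OLS R²**: every multilevel fit also reports the R² of a
  single-level least-squares fit of the same fixed-effect design over the
  person-wave rows; all ledger arithmetic runs on these R²s so that
  incremental comparisons are well defined.
* **G×E**: PGSs and the SES summary score are mean-centered before products
  are formed; the interaction model is compared to the main-effects model by
  ML LRT with one df per product.
* **Sibling fixed effects**: MZ pairs are excluded (no within-pair genotype
  variance), response and predictors are family-demeaned, and standard
  errors are clustered by family.
* **Twin descriptive**: scores standardized within wave, averaged per
  person; within-pair Pearson correlations with double-entry pairing;
  h² = 2(r_MZ − r_DZ) truncated to [0, 1]. In the simulated cohorts the PGS
  pathway is the only genetic pathway, so simulated h² is small by design —
  the estimator, not the population value, is what the suite checks.
* **PCAs** (ancestry, neighborhood, SES summary): column-standardized SVD
  with a deterministic sign rule (largest-magnitude loading positive for
  genotype PCs; poverty loads positively for the neighborhood index;
  education loads positively for the SES summary). The neighborhood index is
  computed separately per wave. Missing values entering the SES summary are
  mean-substituted within stratum (a continuous composite cannot carry a
  missing category); the categorical design instead codes an explicit,
  always-emitted "missing" level per block, with reference levels
  "less than high school", "manual/blue collar", bottom income quintile and
  "no sibling".

## Numerical and degenerate-input choices

* Z-standardization uses the sample sd (n−1); strata with fewer than two
  distinct scores are an error.
* Dosage files: when the counted allele differs from the effect allele the
  dosage is reflected (d → 2−d); A/T and C/G flips are strand-ambiguous and
  raise a warning rather than a silent guess. Missing dosages are imputed to
  2p of the observed frequency.
* Percent vs proportion scale of the ledger is inferred (any R² above 1 ⇒
  percent); genuinely mixed inputs are rejected rather than guessed.
* A three-level fit where every family holds one person is unidentified
  (person component collinear with the family intercept) and raises with a
  pointer to the two-level configuration.
* Ledger identities (environmental + bounded genomic = SES incremental;
  totals additive) are asserted to 1e-12 after assembly.

## What the synthetic checks do and do not show

The generator reproduces the *causal skeleton* the decomposition relies on:
Mendelian transmission, a genome-driven SES latent, sibling clustering with
MZ/DZ structure, two-wave phenotypes, admixture, and missingness. Passing
the suite therefore shows the estimators and the correction behave correctly
*under that model*. Real data differ in ways the generator deliberately
omits: linkage disequilibrium, assortative mating (which breaks the
equal-subcomponents assumption behind the ×2 rule), dominance/epistasis,
direct NT pathways other than SES, non-Gaussian outcomes, informative
missingness, and survey design. The ledger's genomic-in-SES entry is an
upper bound by argument, not an estimate; on real data it inherits every one
of those caveats.

## Validation problem sizes

Chosen as the package's reference checks: the analytic slope oracle runs on
a ≈51,000-person single-stratum cohort (2% agreement, about two Monte-Carlo
standard errors at that size); variance-component recovery on 2,000
families × 2 siblings × 2 waves (10% relative); the γ = 0
vanishing-reduction check on 50 replicates of 250 families; the Mendelian
suite and the correction-recovery check on the default ≈5,100-person
cohort, the latter comparing the ledger's environmental-SES R² to a
truth-oracle semi-partial R² within ±30% relative — the correction is a
deliberately rough estimator.
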