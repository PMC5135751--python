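# Methods

`tnfigrs` implements a pharmacogenetic analysis of response to tumor
necrosis factor inhibitors (TNFi) in rheumatoid arthritis (RA), built
around weighted genetic risk scores, and a synthetic register-style cohort
generator that reproduces the statistical structure such an analysis
assumes. This note records the models, the parameters that matter, the
numerical conventions, and what the synthetic data do and do not show.

## Risk scores

Three scores are computed from published log odds ratios (lnOR):

* **SNP score** — over the candidate RA risk SNPs (default 76),
  `GRS = Σ_i lnOR_i × dosage_i`, with allele dosages in [0, 2].
* **Amino-acid position scores** — at HLA-DRB1 positions 11, 13, 71 and 74,
  `GRS_pos = Σ_residues lnOR(residue) × dosage(residue)`; each person
  carries two residues per position, so residue dosages sum to 2.
* **Haplotype score** — the sum of the lnOR of the two carried 4-position
  haplotype strings (e.g. `VHKA`).

Shared-epitope (SE) status counts classical DRB1 alleles *01 (except
*01:03), *04:01/*04:04/*04:08, and *10; because the generator emits
amino-acid haplotypes rather than classical alleles, a configurable
haplotype→SE lookup is also provided, defaulting to the SE-like haplotypes
{VHKA, VHRA, LFRA} (≈ *04:01, *04:04/*04:08, *01:01).

Continuous scores are categorized into quartiles using cutpoints fitted
**among controls only** (25th/50th/75th percentiles, linear-interpolation
convention) and applied to cases and controls alike. Intervals are
right-closed: a score equal to a cutpoint falls in the lower category, so
with degenerate cutpoints every tied score is Q1. Missing dosages are
refused by default; an explicit mean-imputation helper (per-SNP control
mean) is available and logs what it fills.

## Outcomes

The 4-variable DAS28-ESR is used,

    DAS28 = 0.56·√TJC28 + 0.28·√SJC28 + 0.70·ln(ESR) + 0.014·GH,

because ESR is recorded at every register visit and is the Swedish
standard; CRP is kept as a separate delta outcome. The baseline visit is
the one within ±7 days of treatment start (ties: smallest |day|, then
earliest). The evaluation visit is the follow-up within 2–8 months
(60–240 days, 1 month = 30 days throughout) with complete DAS28 components,
closest to 5 months (day 150); when two visits are equidistant the earlier
one is chosen — the equidistant tie rule is a documented convention.
Subjects lacking either visit are excluded and logged, not errored.

EULAR response uses the published grid with improvement Δ = baseline −
attained: *good* iff Δ > 1.2 (strict) and attained ≤ 3.2 (inclusive);
*none* iff Δ ≤ 0.6 or (Δ ≤ 1.2 and attained > 5.1, strict); *moderate*
otherwise. The boundary conventions are frozen in tests against an
independently coded grid oracle. The primary binary contrast is
good/moderate vs none; good vs none is retained as a sensitivity contrast.
Delta outcomes are evaluation − baseline for DAS28, CRP, ESR, SJC, TJC,
VAS-global, VAS-pain and HAQ, so improvement is negative.

## Association analyses

Logistic regression relates binary outcomes (response; case/control status)
to exposures — continuous scores (per-SD by default; per-unit is a scaling
choice only), quartile categories against Q1, any-SE, and individual
markers in 0/1/2-copy form. Wald 95% CIs and p-values are reported;
likelihood-based flags are unnecessary at these sample sizes. Models adjust
for age, sex and five genotype principal components (top right-singular
directions of the column-standardized dosage matrix; zero-variance markers
dropped; the largest-magnitude loading of each component is made positive so
scores are reproducible). Missing covariates are handled by listwise
deletion with the per-model n reported.

Separation, empty strata and empty cells yield NA-flagged result rows
rather than exceptions, matching how sparse register-scale tables are
reported. Individual-haplotype response contrasts put all non-reference
haplotype copy counts in one joint model against the most prevalent
non-risk haplotype (default PRAA); haplotypes with fewer than 10 carriers
in a stratum are NA-flagged as sparse cells.

Variance explained in the continuous deltas is the **block R²**: the
increase in R² when the exposure block (the SNP score alone, or SNP +
amino-acid scores + SE) is added to the covariate-only linear model, with
the F-test p-value for the block. With no covariates and one exposure this
is the squared Pearson correlation; under the null its expectation is
≈ 1/(n−1). Collinear block columns are dropped and logged.

Per-family multiple testing uses Benjamini–Hochberg FDR (76 SNPs; 21
residues; haplotypes; 8 delta outcomes per score), and each scan is
summarized against the central 95% Binomial(n_tests, 0.05) band — the
quantitative skeleton of a "no more significant than chance" conclusion.

Sensitivity analyses re-estimate the main response contrasts (i) excluding
etanercept, (ii) restricting the evaluation window to 2–5 months (60–150
days), (iii) among patients with baseline DAS28 > 5.1, and (iv) contrasting
good vs none.

## Polygenic threshold scan

Per-SNP disease associations are estimated in the full case-control sample
(additive logistic fits, adjusted for the same age/sex/PC set by default —
adjustment is toggleable), and scores are built from the SNPs passing each
threshold in the nested series 5e-8, 5e-4, 5e-3, 5e-2, 1.0, weighted by the
scan lnORs. Weights come from the disease scan only, never from the
response data — permuting response labels changes no score. Estimating
weights in-sample mirrors the original design; it overfits the disease R²
(which therefore rises mechanically with the threshold) but not the
response R². The profile of block R² per (threshold, outcome) is
serialized and plotted. Monomorphic or non-convergent SNPs are NA-flagged
and excluded from every score.

## Synthetic cohort generator

The generator defines the study conditions. Defaults: 867 treated cases
(75% ACPA-positive), 1941 controls, 76 candidate SNPs with MAF ~ U(0.05,
0.5), a 2000-SNP genome-wide stand-in panel, and **zero genetic effect on
response** — the null the analysis is calibrated against.

**Disease model.** Case status follows a logistic liability on the summed
lnOR-weighted SNP dosages plus haplotype weights, with the intercept solved
numerically so the population prevalence is 1%. Genetic effects act on
ACPA-positive disease only; ACPA-negative cases and controls are drawn from
base frequencies, so the expected contrast (strong ACPA-positive
association, null ACPA-negative) holds by construction. Case genotypes are
drawn *exactly* from this model by exponential tilting of the per-SNP
binomial and per-haplotype categorical proposals followed by an accept step
with probability 1/(1+exp(α+s)); at 1% prevalence essentially every
proposal is accepted, which keeps replicated simulation cheap. Default SNP
lnORs are |N(0.13, 0.04)| draws — a scale at which the per-SD SNP-GRS
disease OR comes out near 2, as observed for RA risk scores. Haplotype
frequencies default to the observed prevalence table of the 18 haplotypes
over positions 11/13/71/74; the per-haplotype and derived per-residue
weights shipped as defaults are *synthetic stand-ins* (no public
per-haplotype lnOR table accompanies the frequency data), with SE-like
haplotypes most at risk. Optional latent-ancestry axes (default 2, small
frequency shifts) are mixed into allele frequencies so PC adjustment is
exercised.

**Clinical model.** Every case starts a TNFi (drug label drawn with
realistic market shares) and gets one baseline visit within ±3 days and
one follow-up at a uniform day in [60, 240], plus a second visit with
probability 0.3 in [30, 270]. Baseline measures are anchored to the
observed treated-cohort means (DAS28 5.0, TJC/SJC 7.8, ESR 27.9, CRP 21,
VAS ~54, HAQ 1.0); dispersions are plausible register-scale choices, since
the source tables report means only. Changes from baseline are drawn from
a 7-component multivariate normal on (ΔTJC, ΔSJC, Δln ESR, ΔVAS-global,
Δln CRP, ΔVAS-pain, ΔHAQ) with exchangeable correlation 0.3 (configurable;
the true correlation structure is not published). Log-scale means for
ESR/CRP are derived from the arithmetic baseline and delta means via the
lognormal mean identity. Follow-up counts are rounded and clamped to
[0, 28], VAS to [0, 100], HAQ to the 1/8 grid, ESR kept ≥ 1 — so the DAS28
change *emerges* from components; its cohort mean is ≈ −1.5, matching the
anchor. Because of the floor at zero, realized component deltas are
slightly attenuated relative to their draw means (e.g. ΔTJC ≈ −3 rather
than −4.3); the DAS28 anchor is unaffected.

**Response effect.** When `response_lnor_per_sd = β ≠ 0`, the responder
indicator is drawn from expit(c + β·z), with z the standardized driving
score (the SNP GRS, or the true causal panel score for polygenic positive
controls) and c solved so the marginal good/moderate rate stays at 0.748.
The evaluation-visit deltas are then drawn from the improvement model
*conditioned* on the implied EULAR binary (rejection against the realized
classification). This injects the effect exactly on the logit scale — the
natural "response scale" for an odds-ratio estimand — so the recovery
simulations test the estimator, not an approximation; a linear shift of
deltas would only induce an approximate logistic effect. Conditioning
preserves the class-conditional delta distribution exactly.

**What the synthetic data do not show.** No linkage disequilibrium beyond
the optional ancestry mixing, no genotype imputation error, no informative
missingness (a missing-follow-up probability hook exists, default 0), no
secular trends in visit timing, and no correlation between clinical
baselines and genetics. Passing tests therefore demonstrate the
correctness and calibration of the *analysis machinery* under the assumed
structure, not properties of any real registry population.

## Simulation sizes and numerical choices

The calibration suites run 1000 null treated cohorts at n = 867 (type-I
error, CI coverage, scan-count band), 500 replicates for effect recovery,
40 case-control replicates (900/1000) for the disease quartile pattern, and
20 null + 3 positive-control polygenic replicates — sizes chosen so
Monte-Carlo error is small relative to each acceptance band while the whole
suite stays desk-scale. Both polygenic arms share a disease architecture
with 10% of a 600-SNP panel causal (lnOR ≈ 0.3) at n = 1000/1000: a
disease-informative scan is required for every threshold to select a
non-degenerate SNP set (with a disease-null panel the genome-wide
thresholds are empty and the profile's left edge is structurally zero,
which would register as a spurious increasing trend), and it keeps the
in-sample scan weights informative enough for the positive-control profile
to plateau rather than dilute at the all-marker threshold. The null arm
sets only the response effect to zero, mirroring a score series that
validly predicts disease but not response.

Coverage note: a replicate's three quartile ORs share the Q1 reference
cell, so the *joint* coverage of their three nominal 95% CIs is ~88% even
for an exactly calibrated estimator; the disease-pattern suite therefore
reports per-CI coverage (expected ~95%) alongside the joint fraction.

Batched per-marker logistic fits use Newton–Raphson with shared covariate
blocks (convergence tolerance 1e-10, coefficient cap 30 for separation
flagging); they are verified against statsmodels to 1e-6 in the test suite.
All randomness flows from one root seed through named substreams, so
changing e.g. the panel size never perturbs the clinical draws, and every
artifact is byte-reproducible under a fixed seed.
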