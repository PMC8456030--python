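# Methods

## The analysis model

`snpcc` implements the standard candidate-SNP case-control screen. Each SNP
is biallelic with a registry-fixed major/minor allele orientation; the minor
allele is defined from the control allele frequency (if data contradict the
registry the labels are swapped with a warning). Genotypes enter the models
through five encodings of the minor-allele count g ∈ {0, 1, 2}:

| model          | predictor                | reference            |
|----------------|--------------------------|----------------------|
| codominant het | 1{g = 1} (g = 2 dropped) | major homozygotes    |
| codominant hom | 1{g = 2} (g = 1 dropped) | major homozygotes    |
| additive       | g                        | per-allele trend     |
| dominant       | 1{g ≥ 1}                 | major homozygotes    |
| recessive      | 1{g = 2}                 | carriers of ≤1 minor |

Disease risk is modeled as logistic:
logit P(case) = β₀ + β₁·enc(g) + γ·covariates, so exp(β₁) is the model's
odds ratio. Because the design is retrospective, only β₁ (not β₀) is
interpretable, and case genotype frequencies are proportional to the control
frequencies times OR^enc(g) — the identity the simulator exploits.

### Estimation

* Crude ORs for 2-level contrasts: closed-form cross-product with Wald 95%
  CI on the log scale (SE = √Σ1/cell, z = 1.959964) and a two-sided Wald p.
  The crude logistic fit coincides with this closed form on a binary
  predictor (verified to 1e-6 in the tests), so the cheap route is used.
* Additive crude OR and all adjusted ORs: maximum-likelihood logistic
  regression (Newton/IRLS, convergence tolerance 1e-8, ≤100 iterations;
  statsmodels `Logit` supplies the optimizer). Separation, non-convergence
  or a singular information matrix set `estimable=False` with a diagnostic —
  degenerate entries like OR "999" are never printed.
* Default covariates are continuous age (years) and binary sex; a banded
  age covariate (`age_band`, <10 vs ≥10 years) substitutes when only banded
  age exists. Covariates that are constant on an analysis subset (sex inside
  a sex stratum, the band inside an age band) are dropped automatically and
  the result records the covariates actually used.

### Chi-square tests

Hardy–Weinberg equilibrium is tested in controls only, by the 1-df
goodness-of-fit χ² against expectations formed from the observed allele
frequency. Genotype/demographic distributions use the plain Pearson χ²;
no test applies a Yates continuity correction — the uncorrected statistic
is what reproduces reference demographic p-values (0.494, 0.107) exactly.
For 2-level model contrasts the "distribution p" is the Pearson χ² of the
collapsed 2×2 table; the scan also reports the overall 2×3 genotype-table
Pearson χ². No distribution p is attached to the additive trend (its Wald p
is the trend test).

### Missing data

Analysis is per-SNP complete-case: a missing genotype removes the subject
from that SNP's cells (tallied in `n_missing`) but not from other SNPs or
from demographics. No imputation. Missing stratum values exclude a subject
from that stratum only.

### Stratification

Variables measured on both groups (age band, sex) use the `within_stratum`
design (both groups filtered). Case-only clinical attributes use the
subtype design: subtype cases vs the full control group, so control cells
repeat across the rows of one variable. The default stratified contrast is
dominant. Laboratory strata consume pre-categorized Lower/Normal/Higher
labels; a categorizer applying pediatric reference ranges
(WBC 5–12 ×10⁹/L, platelets 140–440 ×10⁹/L) is provided for raw values.
No heterogeneity-of-OR or interaction tests are computed, and no
multiple-testing correction is applied across strata — the FPRP analysis is
the false-positive control.

### FPRP

FPRP(α, power, π) = α(1−π) / (α(1−π) + power·π), with α the finding's
observed two-sided p-value (the "observed-p" variant of the procedure).
Power is the Wald normal approximation of detecting OR₀ at level α given
the finding's log-OR standard error; the SE comes from the 2×2 cells when
available and from the CI width otherwise (both are exposed). OR₀ defaults
to 0.67 for protective findings and is reciprocated to 1/0.67 for risk
findings. The prior grid defaults to {0.25, 0.1, 0.01, 0.001, 0.0001} with
headline prior 0.1 and noteworthiness threshold FPRP < 0.2; all are
configurable. Output tables round to 3 decimals. Note that power reported
for reference findings may differ from published values by up to ~0.02:
recomputation from printed (rounded) OR/CI/p cannot recover unrounded
intermediates, so tests hold power to a ±0.02 band while FPRP from given
(α, power) pairs is exact.

## Synthetic cohorts

`simulate_cohort` emulates the study structure the analysis assumes:

* control genotypes i.i.d. from HWE at the configured MAF;
* case genotypes from the exact reweighting P(g|case) ∝ P(g)·OR^enc(g) —
  cheap and exact in distribution for a retrospective design, instead of
  simulating a population and thresholding;
* age truncated-normal (default mean 5.2, sd 2.9, range 0.5–18 years —
  a pediatric ALL age profile), sex Bernoulli (default 60% male), both
  independent of genotype by default; nonzero `covariate_effects` tilt the
  case distributions (exponential tilting via importance resampling for age);
* a case-only immunophenotype mixture (defaults matching the bundled
  study's subtype proportions);
* genotype masking at `missing_rate` (default 0.015), independent of status;
* one `numpy` Generator stream from a single seed: same seed, byte-identical
  cohort.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, population stratification, genotyping error or HWE violation in
controls, confounding between genotype and covariates (unless the tilt is
switched on), and any dependence among clinical attributes — each attribute
is drawn independently. Passing tests on simulated data therefore certify
the estimators under the stated sampling model, not robustness to those
real-data complications.

## The bundled count dataset

`snpcc.datasets` carries the published summary counts of a childhood-ALL
case-control study of three *MYBL2* SNPs, and
`load_all_study_cohort()` expands them into a pseudo-individual cohort via
`cohort_from_counts`. Expansion is positional within the anchor SNP's
genotype blocks (reference homozygotes, carriers, untyped), so every
per-SNP genotype margin and every stratum-by-carrier margin equals the
published cells exactly, while the joint distribution across variables is
arbitrary (and degenerate) — only margin-level analyses are meaningful on
this cohort. The three subjects untyped at the anchor SNP are placed as
male, age <10 — the unique assignment consistent with the whole-group
demographic margins. Continuous ages were never published, so the pseudo
cohort carries banded age only; adjusted models on it use `age_band` + sex.
The dataset's published control-HWE p for rs285162 (0.7301) is inconsistent
with its own printed counts (which give 0.93 under the stated test); it is
kept as metadata (`PUBLISHED_HWE_CONTROLS`) and never asserted.

## Numerical and design choices

* z = 1.959964 everywhere a 95% normal quantile is needed, matching the
  convention of the source tables.
* Zero-cell policy: `estimable=False` with a reason string; the optional
  Haldane–Anscombe +0.5 is off by default. Honest flagging is preferred to
  reproducing degenerate "0.001 (0.001–999)"-style output.
* Separation guard: a fit whose Wald SE exceeds 50 on the log-odds scale is
  treated as separated and flagged, not reported.
* MAF boundary: frequency exactly 0.5 keeps the registry orientation
  (no swap); monomorphic SNPs have MAF 0 after swap and an undefined HWE
  test (error, not NaN).
* Human-readable tables round to the conventional precisions (OR/CI 2
  decimals, p 3, HWE 4, FPRP 3); `results.txt` keeps full precision.
* Simulation-based test sizes were chosen to give tight Monte-Carlo error at
  desk scale: 500 replicates at n = 2000/2000 for bias/coverage (SE of the
  mean log-OR ≈ 0.005), 2000 replicates at n = 500 for type-I calibration,
  10⁵ draws for the Monte-Carlo power oracle.

## Known limitations

* No exact tests (Fisher, exact HWE), no Cochran–Armitage variant beyond
  the additive logistic trend, no haplotype/LD analysis, no BFDP or
  multiplicity-adjusted FPRP variants.
* The VCF reader handles biallelic single-nucleotide records with GT calls
  only.
* Covariate-adjusted estimates on the bundled pseudo cohort use banded age;
  exact reproduction of covariate-adjusted published values would require
  individual-level ages that were never released.
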