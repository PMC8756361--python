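# Methods

This note documents the models, estimators and design choices behind
`casediff` — what is computed, under which assumptions, and what the
synthetic validation does and does not demonstrate.

## The case-case difference statistic

Two case-control GWASs are compared: study 1 (TRS cases vs control set 1)
and study 2 (non-TRS cases vs control set 2). For each shared SNV, after
aligning study 2 to study 1's effect allele,

d = log(OR₁) − log(OR₂),  SE(d) = √(SE₁² + SE₂²),  z = d/SE(d),
P = 2(1 − Φ(|z|)).

SE here is the standard error of the *log* odds ratio — the only scale on
which d/SE(d) is standard normal — and P values come from the normal, not a
t, distribution, since the source GWASs are large-sample Wald tests. P is
floored at the smallest positive double rather than reported as zero.
The construction assumes the two studies share no samples (their control
sets are independent); it deliberately does not model between-study
heterogeneity, so z conflates genuine TRS/non-TRS differences with any
residual technical differences between the two source studies. Positive z
always means a stronger association in the TRS study.

### Harmonization

Allele alignment uses the standard action lattice: identity, allele swap
(β → −β, EAF → 1 − EAF), strand flip (complement both alleles), and
swap+flip. Rows whose alleles cannot be reconciled are excluded
(`allele_mismatch`). Palindromic SNVs (A/T, C/G) whose minor-allele
frequency lies in [0.4, 0.5] in *both* studies are strand-unidentifiable
and excluded (`palindromic_ambiguous`); palindromic SNVs outside that window
are aligned by the allele patterns alone, without frequency-based
disambiguation — a declared convention. Finally, SNVs whose post-alignment
allele-frequency difference exceeds 20% (configurable) are excluded
(`maf_diff`), mirroring pre-imputation-style quality control. Exclusions
are counted per reason and the input always partitions into
retained + excluded.

## Inflation diagnostics

λ is the median association χ² divided by the χ²₁ median (0.45494);
λ₁₀₀₀ = 1 + (λ − 1)(1/n₁ + 1/n₂)/(2/1000) rescales it to an equivalent
1000-vs-1000 study (Freedman-style convention). For the case-case statistic
n₁ and n₂ are the TRS and non-TRS case counts. The convention is declared:
published λ₁₀₀₀ values depend on an effective-N definition that is rarely
printed, so numerical agreement with any particular published pair is not a
goal. Note that at desk scale λ is a noisy statistic: with 5,000 SNVs in
LD blocks of 10 at r² = 0.2 (≈500 independent blocks) its per-scan sampling
sd is ≈0.06, which is why calibration checks pool scans across seeds.

## LD-score regression

Under a polygenic model, E[χ²ⱼ] = 1 + a + N·h²·lⱼ/M with lⱼ the LD score
(sum of r² with the SNVs of j's LD block, including itself) and M the panel
SNV count. The estimator:

1. an OLS pass of χ² on x = N·l/M seeds the weights;
2. one weight update to the standard heteroskedasticity/overcounting form
   w = 1/(max(l,1)·(â + ĥ·x)²), with the modelled variance floored at 0.05;
3. a weighted least-squares fit gives the intercept and slope (h²_obs);
4. standard errors come from a delete-a-block jackknife over contiguous SNV
   blocks (default 200, auto-reduced to ⌊n/10⌋ for small panels) in which
   the **entire two-pass procedure** is re-run per deleted block.

Numerical choices worth recording: the seed estimates are clipped only far
outside their sampling range (intercept to [0.1, 10], slope to [−1, 1]) so
that the weights remain a smooth functional of the data — a clip kink at
h = 0 would sit exactly on the null hypothesis and degrade jackknife
coverage there. Weights are not iterated further; one update is
deterministic and sufficient at these scales. Constant LD scores are
rejected as degenerate (slope and intercept are then collinear). The
jackknife remains mildly anti-conservative in small panels (≈92% coverage
of 2-SE intervals at 1,000 SNVs, ≈94% at 4,000); Monte-Carlo tests use
panel sizes where coverage is near nominal.

For two traits, z₁ⱼz₂ⱼ is regressed on √(N₁N₂)·lⱼ/M with weights
√(w₁w₂) (each trait's actual fitted weights); the slope is the genetic
covariance and rg = gencov/√(h²₁h²₂). No sample-overlap term is added to
the cross-trait intercept because the simulated design uses disjoint
control sets. If either h² estimate is non-positive, rg is reported as
undefined with a flag rather than a number. rg standard errors jackknife
the full ratio (all three regressions re-run per deleted block).

A desk-scale caveat established empirically during development: with only
~500 independent LD blocks, single-trait h² of a realistic case-control
chain carries a jackknife SE comparable to the estimate itself, so the rg
*ratio* from a fully simulated chain is not usefully identifiable. The
genetic-correlation validation therefore draws z scores directly from the
bivariate LD-score model (shared architecture component plus independent
noise), where the estimator faces the same inferential problem at a sample
size that actually identifies the ratio.

The observed↔liability conversions use the standard transforms:
h²_liab = h²_obs·K²(1−K)²/(φ(t)²P(1−P)) for heritability, and the Lee et al.
ascertainment-corrected transform for PRS R² (C = K(1−K)/φ(t)² · K(1−K)/(P(1−P)),
θ correction for case enrichment). K is always a user-supplied prevalence —
for TRS-among-cases phenotypes the TRS fraction (default 0.25 from the
reported 20–30% range) — never a hard-coded constant.

## Case-control GWAS at desk scale

Per-SNV association uses the allelic 2×2 table: OR = ad/bc on effect-allele
counts, Woolf SE = √(1/a+1/b+1/c+1/d), Haldane–Anscombe +0.5 on all cells
when any cell is zero. This replaces per-SNV logistic regression with
covariates: without covariates the two are asymptotically equivalent (the
test suite checks Woolf against an IRLS logistic fit), and the 2×2 form is
orders of magnitude faster. EAF is reported from the control group
(convention; affects only harmonization bookkeeping in simulations).
Monomorphic SNVs are dropped with a logged count.

## Polygenic scores

Clumping is greedy PRSice-style C+T: visit SNVs by ascending P (ties by
chromosome, position), keep a SNV unless r² > 0.1 with an already-kept SNV
within 250 kb (defaults; both configurable). Scores are Σⱼ βⱼgᵢⱼ over SNVs
with training P ≤ threshold, with per-SNV mean imputation of missing
dosages, returned raw and z-standardized. Association is a statsmodels
logistic regression (IRLS) of phenotype on the standardized PRS plus
covariates (sex and top-k dosage principal components in the synthetic
validation); perfect separation raises an error rather than returning a
spurious estimate. The threshold grid is a conventional 8-point grid
{5e-8, 1e-5, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0}; thresholds passing no SNV
are skipped with a log note, and P < 1 reproduces the
"all LD-independent SNVs" profile. FDR q values (Benjamini–Hochberg
step-up, implemented directly and cross-checked against statsmodels and a
brute-force definition oracle) are computed across each scan. Fixed-effect
meta-analysis pools effect estimates by inverse variance. Group profiles
residualize the PRS on covariates, z-standardize on the whole sample and
report per-group means ± 1.96·sd/√n.

## The synthetic-data generator

The generator emulates the study design, not human genomes:

* **Genotypes.** SNVs in consecutive LD blocks (default 10 SNVs per block)
  on one chromosome at 5 kb spacing, MAF ~ U(0.05, 0.5). Dosages are
  drawn through a Gaussian copula: a per-block latent factor plus
  independent noise, thresholded into {0,1,2} at the Hardy–Weinberg
  quantiles, so margins are HWE-exact. The latent loading is calibrated so
  the *dosage* r² within a block matches the target (default 0.2) by
  solving the bivariate-normal orthant equations (Brent's method) at the
  block's mean MAF.
* **Phenotypes.** Two-layer liability threshold model. L₁ = Σxⱼb_shared,ⱼ + e₁
  (x standardized dosages, b ~ N(0, h²_shared/m_causal), Var(L₁)=1);
  case ⇔ L₁ > Φ⁻¹(1−K). Among cases, an independent specific liability L₂
  labels TRS ⇔ L₂ > Φ⁻¹(1−trs_fraction). Because b_shared ⊥ b_specific,
  selection on L₁ leaves L₂ ≈ N(0,1) among cases, so the theoretical
  threshold yields the target TRS share (checked by Monte-Carlo). Effect
  vectors are drawn once per seed and stored with the cohort so liabilities
  can be replayed exactly. Sex is pure noise.
* **Sampling.** Individuals are drawn in batches and assigned to group
  quotas (TRS cases, non-TRS cases, two *disjoint* control sets, and a
  held-out validation set of cases at the natural TRS mix) until all quotas
  fill; a hard cap on total draws turns pathological configurations into a
  clear error. Defaults: K = 0.01 for realism; the test suite and
  acceptance script use K = 0.05, which preserves the liability structure
  while keeping rejection sampling to minutes.
* **Direct draws.** For estimator tests, z scores can be drawn straight
  from the (bivariate) LD-score model: zⱼ ~ N(0, 1 + N·h²·lⱼ/M), with a
  shared architecture component scaled by rg for trait pairs.

What the generator does **not** emulate: realistic human LD maps,
MAF-dependent architectures (an infinitesimal model within a configurable
causal set is used), ancestry structure or admixture, genotyping or
imputation error, sample overlap between studies. Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery
under the design's own assumptions — not robustness to the confounders of
real data.

## Problem sizes in the validation suite

Monte-Carlo checks run at sizes chosen to make each inference identifiable
at desk scale: null-calibration chains use 5,000 SNVs with 2,000
individuals per group over 10 seeds; the PRS directionality check uses
2,000 SNVs, 2,000 per discovery group and 800 held-out cases over 20 seeds
(frozen after a small power pilot at h²_specific = 0.1); genetic-correlation
checks use 5,000-SNV direct draws at N = 10⁴. The acceptance script scales
the same computations to a few minutes of runtime.

## Known limitations

* The Woolf 2×2 stage cannot adjust for covariates; population structure
  in real data would require the logistic/mixed-model GWAS it stands in for.
* The LD-score estimator implements the basic model only — no partitioned
  heritability, no annotation stratification, and not the LDAK/SumHer
  MAF-coupled estimator (whose point estimates would differ, as alternative
  model assumptions generally do).
* rg between two *simulated cohort* GWASs at desk scale is dominated by
  h² estimation noise; treat chain-level rg output as descriptive.
* λ₁₀₀₀ depends on a declared effective-N convention.
* PRS-CS-style Bayesian shrinkage scoring is out of scope; only C+T is
  implemented.
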