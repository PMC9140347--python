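# Methods

## The model

`tftrans` asks, for each gene in one tissue, whether variability in its
transcription factors (TFs) explains expression variance that a local
(*cis*) genetic model does not. Gene expression is decomposed in five
stages:

1. **Covariate residualization.** For each gene, ordinary least squares of
   observed expression on an intercept plus all supplied covariates (sex,
   sequencing platform, genotype principal components, PEER-style latent
   factors — consumed as pre-encoded numeric columns, never estimated
   here). The residuals are the *normalized expression* used everywhere
   downstream; they are orthogonal to every covariate column by
   construction (checked to |r| < 1e-8).

2. **Cis baseline.** An elastic net (mixing parameter 0.5, variants within
   ±1 Mb of the gene body, penalty chosen by 10-fold cross-validation on a
   30-point log-spaced path) predicting normalized expression from variant
   dosages. This is a trainable stand-in for externally trained
   transcriptome-imputation weights; a reader for external predictions
   (samples × genes table) is provided as an alternative entry point.
   Baseline quality `r2_cis` is the squared Pearson correlation between
   *out-of-fold* predictions and normalized expression, floored at 0; the
   in-sample value is also emitted. Genes with no cis variant in the window
   keep a zero prediction and `r2_cis = 0` — they are retained, not
   excluded. Cross-validated rather than in-sample predictions are used for
   the subtraction as well, which guards the baseline against optimism;
   whether the original protocol used in-sample or held-out predictions is
   not decidable from its description, so both estimates are reported.

3. **TF models.** The post-cis residual (normalized expression minus the
   cis prediction) is modeled by L1-penalized (LASSO) regression under two
   mechanisms:
   * *TF-expression*: predictors are the normalized expression values of
     the TFs annotated as regulating the gene;
   * *TF-binding*: predictors are dosages of nonsynonymous variants with a
     SIFT score strictly below 0.05 (the standard deleteriousness call)
     located within the gene's TFs. Synonymous variants, variants without
     a SIFT score, and variants of TFs lacking genomic bounds never enter.
   Predictors are standardized to unit variance, so reported weights are
   comparable across predictors; the penalty is selected at minimum 10-fold
   CV error (ties broken toward the sparser fit), and `r2_tf` uses the same
   floored out-of-fold estimator as the cis baseline so the two are
   directly comparable. Genes with no TF, or an empty predictor set after
   filtering, are *skipped* (recorded with a reason), never counted as
   negative results. A single predictor is allowed.

4. **Background nulls + FDR.** Each fitted gene must survive two
   permutation backgrounds, each with `n_null` (default 100) full
   refits including penalty re-selection — freezing the penalty would
   favor the observed fit:
   * *shuffled residuals*: the response permuted across samples;
   * *random TF sets*: TF sets of the same cardinality as the gene's true
     set, sampled without replacement from the non-associated TF pool, with
     the mechanism's predictor matrix rebuilt each draw. A draw whose
     matrix is empty (random TFs with no deleterious nsSNP) scores R² = 0;
     a gene whose non-associated pool is smaller than its true set is
     flagged untestable and cannot pass.
   Empirical p-values use the add-one estimator
   `(1 + #{null R² ≥ observed}) / (n_null + 1)` — never zero, with ties
   counting against the observed model (conservative). p-values are
   Benjamini–Hochberg adjusted within each (mechanism, null-kind) family
   across all candidate genes of the run; a gene passes only if both
   adjusted p-values are strictly below α = 0.05. Because empirical
   p-values live on a grid with floor `1/(n_null+1)`, the BH pass threshold
   is only reachable when `n_null` is large enough relative to the family —
   at the default 100 nulls the floor is ≈ 0.0099.

5. **Robustness.** Model fitting plus both backgrounds are re-run on
   `n_runs` (default 10) independent subsamples each retaining ⌈0.9·n⌉
   samples (a sample may be dropped in several runs). A gene is a **hit**
   if it passed the stage-4 filters and was discovered in at least
   ⌈n_runs/2⌉ runs (five of ten at the defaults). Robustness re-runs
   stages 3–4 on the precomputed residuals; re-running normalization and
   the cis fit inside each subsample is available via the library but not
   the default, trading a small optimism in the residuals for a large cost
   saving. When no gene passes stage 4 the robustness stage is skipped —
   the hit set is empty either way.

**Reporting.** A hit is an *explanatory trans association* when
`r2_tf ≥ r2_cis` (ties count; the strictly-greater tally is logged
alongside). Cross-study overlaps use the exact hypergeometric upper tail,
with the universe defaulting to the genes tested in the run. An audit table
lists variants shared between each gene's cis model and its TF-binding
model.

## Synthetic data and ground truth

Real donor-level genotype/expression data of this kind is access-controlled,
so the generator produces statistically matched stand-ins:

* **Genotypes** — dosages ~ Binomial(2, MAF), MAF uniform on [0.05, 0.5],
  variants independent (no linkage disequilibrium — a known simplification;
  none of the tested properties depend on LD). Genes and TFs are laid out
  on synthetic chromosomes 3 Mb apart so ±1 Mb cis windows never overlap;
  cis variants fall in their gene's window, nsSNPs inside their TF's body.
* **Regulatory map** — about 52% of genes get at least one TF; TFs-per-gene
  follows a zero-truncated negative binomial with mean 10.8 and SD 8.4,
  matching the bulk-tissue TF-target compendia the pipeline consumes.
* **Annotations** — nsSNPs per TF from a negative binomial with mean 1.55 /
  SD 1.77 (Poisson fallback when SD² ≤ mean); a configurable fraction
  (default 0.35) is deleterious with SIFT ~ U(0, 0.05), the rest
  U(0.05, 1); one synonymous decoy per TF.
* **Expression** — each gene is a weighted sum of standardized components:
  its cis-variant signal, TF-expression trans signal (β on `n_causal_tfs`
  of its TFs), TF-binding trans signal (γ on deleterious nsSNP dosages),
  covariate effects, and Gaussian noise. Components are Gram–Schmidt
  orthogonalized in order (cis → trans-expression → trans-binding →
  covariates → noise) before scaling, so the realized in-sample variance
  fraction of each component equals its configured target *exactly* per
  gene; each named component is the part of its raw signal orthogonal to
  what precedes it. Without this, O(1/√n) cross-correlations between
  independently drawn components blur the planted fractions by ~±0.03 at
  n = 1000. TF expression carries cis effects and noise only; covariate
  effects are planted on target genes, keeping every planted fraction
  identifiable by a direct regression oracle. With `noise_sd = 0` a gene is
  an exact linear combination of its planted inputs. Effect sizes are
  N(0, 1) draws rescaled jointly per gene, so individual predictor weights
  vary while the component variance hits its target.

Every planted quantity (TF sets, causal TFs and their β, causal nsSNPs and
their γ, cis weights, realized fractions, null flags, MAFs) is written to a
ground-truth ledger; a gene is recorded trans-null when no trans component
was actually realized (designated null, no TFs, zero configured fraction,
or no deleterious nsSNP available to carry a binding effect).

What the generator does **not** emulate: linkage disequilibrium, population
structure, realistic eQTL effect-size spectra, count-level (RNA-seq)
noise, or shared trans hubs across genes. Passing tests therefore
demonstrate correctness and calibration of the *procedure* under the
declared generative assumptions, not performance on real tissue data.

## Numerical choices

* One coordinate-descent path engine serves all penalized fits. The path
  has 30 points (25 for the TF models) from `alpha_max` (all-zero fit) down
  to `1e-3 · alpha_max`; fold splits, centered fold matrices and Gram
  matrices are cached per predictor matrix, which matters because the
  backgrounds refit the same matrix against hundreds of permuted responses.
* CV-error ties select the larger penalty (sparser model).
* Constant predictors are dropped before standardization; an all-constant
  set yields an all-zero fit with R² = 0 rather than an error.
* The floored R² returns 0 whenever predictions are constant (the selected
  penalty zeroed every coefficient) or the correlation is undefined.
* All randomness flows through `seed_derivation(master, stage, unit)`
  (SHA-256, 31-bit), so per-gene and per-run streams are independent of
  iteration order and worker count; serial and parallel runs are
  byte-identical, and `n_jobs` is excluded from the run manifest's
  configuration hash for that reason.
* Sample alignment is always the sorted intersection of the tables' sample
  ids.

## Validation studies and problem sizes

`scripts/acceptance.py` (and the mirrored acceptance tests) validate the
pipeline at desk scale:

* elementary statistics (BH, add-one empirical p, hypergeometric tail)
  against brute-force references, 1000 random instances each;
* type-I control: 50 candidate genes, n = 500, zero trans effects, 20 nulls
  per background, 10 robustness runs — the end-to-end hit fraction must
  stay at or below 0.05 (the dual-null + BH + robustness stack leaves it
  near zero);
* power: 100 genes with planted TF-expression effects at trans R² = 0.3
  (and 50 genes for TF-binding), n = 500 — at least 90% recovered as hits,
  with the top-|weight| predictor matching a planted causal TF/variant in
  at least 95% of hits. Power studies use 20 nulls per background; with an
  all-signal family the BH floor `1/21 ≈ 0.048` still clears α = 0.05,
  which is what makes this reduction sound;
* generator calibration at n = 1000 (per-gene worst error ≤ 0.05, using
  adjusted R² to correct the p/n inflation of the 20-column covariate
  block);
* exactness checks for the SIFT filter and the robustness rule on
  constructed fixtures, and a three-run byte-identity determinism check
  (two serial, one with two workers).

These sizes are the package's validation conditions; the pipeline itself
has no scale assumptions beyond ≥ 10 samples and ≥ 1 predictor per fitted
gene.

## Known limitations

* The cis baseline is trained on the same cohort it is evaluated on
  (cross-validated), unlike pretrained imputation models applied to an
  independent cohort; external predictions can be supplied instead.
* Empirical p-value resolution is `1/(n_null+1)`; small `n_null` makes the
  BH filter unreachable for small mixed families (a warning is emitted
  below 20 nulls).
* The random-TF-set null for TF-binding scores empty draws as R² = 0,
  which makes that null easier to beat for genes whose TF pool is
  nsSNP-poor; the shuffled-residual null is unaffected and both must pass.
* Multi-allelic variants and missing genotypes are dropped (with a
  warning) by the VCF converter rather than imputed; how the original
  protocol handled them is unstated, so dropping was chosen as the
  conservative policy.
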