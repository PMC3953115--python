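# Methods

## Scope

`nsclcmir` re-implements, as a tested pipeline, the integrative analysis
used to discriminate the two major NSCLC histological subtypes — squamous
cell carcinoma (SCC) and adenocarcinoma (AD) — from paired mRNA and miRNA
expression profiles: differential expression, a sparse discriminant
signature, qPCR relative quantification, miRNA–target network integration,
anti-correlation screening, and a composite diagnostic test.  Because the
original patient-level data are not distributed with the package, every
stage is exercised on synthetic cohorts with planted structure, plus the
one fully in-package worked example: the curated prediction table for the
nine subtype-discriminating miRNAs (`nsclcmir/data/mirna_targets_nsclc.tsv`).

## Differential expression

**mRNA (arrays).**  Expression is a genes × samples matrix of log10 ratios
of each tumour against a pooled lung-cancer reference.  Each gene is tested
within each subtype with a one-sample t-test against 0 (i.e. against the
pool); p-values are adjusted with the single-step Bonferroni procedure,
`p_adj = min(1, m·p)`, with one family spanning **all** tests performed
(both subtypes jointly, m = 2 × genes tested) so the screen's family-wise
error is controlled at α overall.  Survivors must additionally clear a
fold-change filter `|mean log10 ratio| > 0.3`, a *strict* inequality; the
constant is the base-10 log of a 2-fold change (log10 2 ≈ 0.301).  A gene
is called DE for a subtype only when both filters pass.  A Welch
two-sample subtype contrast (Welch–Satterthwaite df) is available behind
`contrast="two-sample"` for designs without a common reference.

**miRNA (qPCR).**  Assays detected in fewer than 80% of samples are
excluded before any testing (assessed per cohort).  Surviving assays are
compared between subtypes with a Welch t-test on the ΔCt scale — ΔCt is
approximately Gaussian, unlike 2^−ΔCt — with Benjamini–Hochberg FDR control
at q ≤ 0.05.  The source study names FDR control but not the procedure;
Benjamini–Hochberg is the standard choice and is documented as ours.
Direction is reported as the subtype with higher expression (lower ΔCt).

## Nearest-shrunken-centroid signature

The discriminant analysis is the standard nearest-shrunken-centroid (PAM)
formulation: standardized centroid differences
`d_ik = (x̄_ik − x̄_i) / (m_k (s_i + s0))` with `m_k = sqrt(1/n_k − 1/n)`,
soft-thresholded at Δ, and the shrunken centroids reassembled from the
thresholded `d'_ik`.  `s_i` is the pooled within-class sd and `s0` the
median of the `s_i`.  Classification minimises the standardized squared
distance to each shrunken centroid minus `2 log π_k`; exact ties go to the
lexicographically first class.  Published variants disagree on the
normaliser (`1/n_k − 1/n` vs `1/n_k + 1/n`); the former is the default and
the latter is available via `mk="plus"` because the signature size depends
on it.  Δ is chosen by stratified k-fold cross-validation (default 5
folds, seeded fold assignment) with a parsimony tie-break: the **largest**
Δ attaining the minimal CV error.  The signature is the set of genes with
any nonzero shrunken difference, ordered by `max_k |d'_ik|`.

## Relative quantification

Replicate Ct values are aggregated by the median of the non-missing
replicates.  The median commutes with the monotone map `x ↦ 2^−x`, so
aggregating Ct or expression gives identical results; Ct is used.
`ΔCt = Ct(target) − Ct(reference)`, relative expression `2^−ΔCt`; for
paired designs `ΔΔCt = ΔCt(tumour) − ΔCt(normal)` and `2^−ΔΔCt`, which
cancels any patient-wide Ct offset (tested as a translation invariance).
The miRNA reference is fixed to RNU48; the mRNA reference is selected from
B2M/ACTB/GAPDH as the candidate with the smallest across-sample sd of
aggregated Ct (ties go to the lexicographically first name, with a
warning).  `Undetermined` observations are missing data: they are never
imputed to a sentinel cycle number, and an assay with all replicates
missing is undetected for that patient.

## Network integration

Predicted miRNA→gene edges (miRanda / TargetScan / miRWalk, consumed as a
table) are kept only under repression consistency: the miRNA must be DE-up
in some subtype S and the gene DE-down in the same S.  With two subtypes
and a pooled-reference screen, "down in S" is implied either by a
down-vs-pool call in S or an up-vs-pool call in the other subtype;
conflicting implications drop the gene.  Program agreement is *not*
required (single-program predictions are legitimate edges in the published
table); an optional `min_programs` filter exists.  The result is a
directed bipartite graph; genes with in-degree ≥ 2 are reported as
multi-miRNA targets.

## Pair statistics and diagnostics

**Spearman.**  Mid-rank ties; for untied data the classic
`1 − 6Σd²/(n(n²−1))` formula is used because it is exact (perfect monotone
data gives ρ = ±1 exactly); with ties, Pearson on mid-ranks.  The
two-sided p-value uses the t approximation
`t = ρ sqrt((n−2)/(1−ρ²))` (standard for n > 10); an exact permutation
p-value is available for n ≤ 9.  Correlations are computed on the paired
2^−ΔΔCt scale; because Spearman is invariant under strictly increasing
transforms (tested), the scale choice only fixes the sign convention.

**Composite test.**  Within the analysed cohort, each measure is
binarized at its median: *high* iff strictly above the median, so ties at
the median — and constant vectors — are *low* (the direction is our
documented choice; the source is silent).  A patient is test-positive when
the miRNA is high **and** the target gene is low; condition-positive when
their subtype matches the pair's direction.  From the 2×2 table:
sensitivity tp/(tp+fn), specificity tn/(tn+fp), PPV tp/(tp+fp),
NPV tn/(tn+fn); zero denominators yield missing metrics.  Exact 95%
Clopper–Pearson intervals are computed from F quantiles (the equivalent
beta-quantile form is the test oracle); exact intervals are conservative,
so empirical coverage ≥ 95% (verified by simulation).

## Synthetic cohorts

The generator emulates the two study designs: a training cohort of 25 SCC
+ 19 AD tumours (arrays + miRNA cards) and a validation cohort of 17 SCC +
24 AD with paired adjacent-normal tissue (qPCR for miRNAs and the selected
genes).  The default planted configuration, chosen once as a realistic
calibration (the source reports no effect-size or variance estimates):

| parameter | default | meaning |
|---|---|---|
| DE genes | 50 of 2000 at 0.5 log10 | array subtype effects (≈3.2-fold) |
| array noise σ | 0.1 log10 | per-sample log-ratio sd |
| DE miRNAs | 9 of 100 at 2 Ct | 8 up in SCC, 1 up in AD, as reported |
| miRNA biological sd | 1.0 Ct | patient-level latent variation |
| true pairs | 19, slope 0.4 | published in-degree profile (4/3/3/2/1…) |
| replicate noise σ_ct | 0.3 Ct | qPCR technical noise |
| patient-level mRNA noise | 3 × σ_ct | see below |
| decoy predictions | 10 | predicted edges to genes with no signal |
| technical replicates | 3 | per qPCR assay |

Arrays: non-planted genes ~ Normal(0, σ²); planted genes shift by +effect
in their subtype.  qPCR: each miRNA has a latent per-patient expression
deviation (subtype effect, tumour tissue only, plus biological noise);
observed Ct = base − latent + replicate noise.  A true pair makes the
gene's Ct increase linearly (slope, Ct per Ct-unit) with the miRNA's
latent expression — such genes receive their subtype difference *only*
through this coupling, so their DE is mediated by the miRNA, which is the
causal structure the analysis is meant to detect.  Decoy predictions point
at genes with no planted signal at all, so the diagnostic comparison
true-vs-decoy is a genuine signal-vs-noise contrast.  Patient-level mRNA
noise scales as a fixed 3× multiple of σ_ct, and housekeeping patient-level
sds are fixed multiples of σ_ct (B2M the smallest, so the stability rule
selects it on faithful data); consequently σ_ct = 0 makes a coupled gene an
exact deterministic function of its miRNA and Spearman ρ = −1 exactly — the
degenerate case the property tests pin down.  The slope default 0.4 with
miRNA biological sd 1.0 was set analytically so that validation-cohort
Spearman ρ for true pairs lands near −0.5, matching the magnitude of the
reported correlations (−0.3 to −0.5).  Undetermined observations are
emitted as the literal instrument token for a deterministic count
(`round(fraction × n samples)`) of randomly chosen samples, which makes
detection-rule tests exact.

What the generator does **not** emulate: probe-level array intensities,
dye-swap/scanner artefacts, amplification-efficiency differences between
assays, RNA-quality covariates, or confounding between subtype and
clinical variables.  Passing tests therefore demonstrate correctness of
the statistical machinery under the assumed generative model, not
robustness to real-data artefacts.

## Numerical and design choices

- Log base 10 for array ratios (0.3 ≈ log10 2); Ct effects convert via
  log2(10) where needed.
- Fold-change boundary is strict: 0.3 exactly fails, 0.301 passes.
- The truth file is JSON (floats round-trip exactly through `repr`).
- Seeds: every generator takes an explicit seed; the validation cohort
  derives seed+1; CV fold assignment is seeded separately.
- Degenerate inputs raise typed errors (`UndefinedStatisticError` for
  zero-variance t-tests and constant-vector correlations,
  `ConfigurationError` for inconsistent designs) rather than returning
  NaN silently.
- Problem sizes used by the test suite and the acceptance script: the
  default study (2000 genes × 44 samples; 100 miRNA assays; 41 paired
  validation patients), 200 null replicates of 500 genes × 20 samples for
  the family-wise-error simulation, and 2000 binomial draws (p = 0.7,
  n = 17) for interval coverage — sizes chosen so the whole analysis
  re-runs in seconds while estimates remain stable.

## Known limitations

- Cohort-dependent published numbers (727 DE genes, the 61-gene signature,
  specific r and sensitivity/specificity values) require the original
  patient data and are not reproduction targets; the package reproduces
  the *structure* (the 19-edge network, the funnel logic) and verifies the
  machinery against planted truth instead.
- The one-sample screen treats the pooled reference as noise-free; the
  pool is emulated, not modelled as a second channel.
- The miRNA screen assumes ΔCt is comparable across patients after
  housekeeping normalization; no mixed-effects modelling of replicates.
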