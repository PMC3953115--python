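# nsclcmir

Integrative miRNA–mRNA expression analysis for discriminating the two
major histological subtypes of non-small-cell lung cancer — squamous cell
carcinoma (SCC) and adenocarcinoma (AD) — implemented as a reusable,
tested Python pipeline.  It is aimed at computational biologists who want
the full statistical machinery of a two-cohort biomarker study in one
place, runnable end to end on synthetic cohorts with known ground truth.

## What it computes

1. **Differential expression.**  For array log10 ratios x_gj of gene g vs
   a pooled reference: a one-sample t-test of H0: E[x_g] = 0 per subtype,
   single-step Bonferroni adjustment p_adj = min(1, m·p) over all tests,
   then a fold-change filter |mean log10 ratio| > 0.3 (0.301 = 2-fold).
   For miRNA qPCR: an 80% detection rule, Welch t on ΔCt between
   subtypes, Benjamini–Hochberg FDR.
2. **Sparse subtype signature** by nearest shrunken centroids (PAM):
   d_ik = (x̄_ik − x̄_i)/(m_k(s_i+s0)) soft-thresholded at Δ, with Δ chosen
   by stratified cross-validation; classification by minimal standardized
   distance to the shrunken centroids minus 2·log π_k.
3. **Relative quantification**: replicate-median Ct, stability-based
   housekeeping selection, ΔCt = Ct(target) − Ct(reference), relative
   expression 2^−ΔCt, and paired-tissue ΔΔCt with 2^−ΔΔCt.
4. **Network integration**: predicted miRNA→gene edges (miRanda /
   TargetScan / miRWalk) kept only when the miRNA is up- and the gene
   down-regulated in the *same* subtype (repression consistency); the
   package ships the curated 19-edge prediction table for the nine
   subtype-discriminating miRNAs as its in-package worked example.
5. **Pair statistics**: Spearman anti-correlation on the 2^−ΔΔCt scale,
   and a composite diagnostic test — patient positive iff miRNA above its
   cohort median AND target gene below its median — scored as
   sensitivity/specificity/PPV/NPV with exact Clopper–Pearson 95% CIs
   computed from F quantiles.
6. **Synthetic cohorts** mirroring the study designs (25 SCC + 19 AD
   training; 17 SCC + 24 AD validation with paired normals) with planted
   subtype effects, planted miRNA→target repression and decoy
   predictions, so every stage is scored against ground truth.

See `docs/methods.md` for formulas, defaults and the generator's model.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort; each is a thin driver over the library:

```bash
python analysis/01_simulate_cohorts.py --seed 1
python analysis/02_differential_expression.py
python analysis/03_nsc_signature.py --seed 1
python analysis/04_network_integration.py
python analysis/05_pair_diagnostics.py
```

which prints (seed 1):

```
mRNA screen: 2000 genes tested per subtype -> 50 DE (25 in SCC, 25 in AD)
miRNA screen: 100 assays past the detection rule -> 9 DE (8 up in SCC, 1 up in AD)
delta* = 4 (CV error 0.000); signature: 50 genes; 50 also DE
published table: 9 miRNAs (8 up in SCC), 11 genes, 19 edges; multi-miRNA targets: CEACAM6, MLPH, TMEM45B, ACSL5
synthetic study: 9 miRNAs, 11 genes, 19 edges kept of 29 predictions
19 true pairs: 19 anti-correlated, median rho -0.511, mean sensitivity 63.3%
10 decoy pairs: median rho -0.036, mean sensitivity 40.7%
```

Reading: all 50 planted DE genes and all 9 planted DE miRNAs were
recovered with zero false positives; integration kept exactly the 19
planted repression edges (and, for the curated published table, the
9-miRNA / 11-gene network); every true miRNA–target pair is
anti-correlated in the validation cohort (median Spearman ρ ≈ −0.5) while
decoy predictions hover near ρ ≈ 0; and the composite diagnostic ranks
true pairs well above decoys.  The same pipeline is available as one call
(`nsclcmir run-all --seed 1 --outdir results/pipeline`) or per stage via
the `nsclcmir` CLI (`simulate`, `de-mrna`, `de-mirna`, `nsc`, `quantify`,
`integrate`, `pairs`).

A library-level example:

```python
from nsclcmir import load_published_targets, integrate
from nsclcmir.network import gene_directions_from_targets

targets = load_published_targets()
net = integrate(targets.mirna_directions(),
                gene_directions_from_targets(targets), targets)
print(len(net.mirnas), len(net.genes), net.n_edges)   # 9 11 19
```

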