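#!/usr/bin/env python
"""Simulate the two study cohorts and write their raw data tables.

Training cohort: 25 SCC + 19 AD tumours with array log10 ratios (2000
genes, 50 planted at 0.5 log10) and miRNA qPCR cards (100 assays + RNU48,
9 planted at 2 Ct).  Validation cohort: 17 SCC + 24 AD with paired
tumour/normal qPCR for miRNAs and for the planted/decoy target genes.
Everything lands under results/data/ together with the planted truth.
"""

import argparse
from pathlib import Path

from nsclcmir import cohort as ch
from nsclcmir.io import write_ct, write_expression, write_targets

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results/data"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

training = ch.CohortDesign(n_scc=25, n_ad=19, seed=args.seed, cohort="training")
validation = ch.CohortDesign(n_scc=17, n_ad=24, paired_normals=True,
                             seed=args.seed + 1, cohort="validation")
truth = ch.default_truth(training)
ch.write_truth(truth, args.outdir / "truth.json")
write_targets(ch.truth_target_table(truth), args.outdir / "targets.tsv")

arrays = ch.generate_mrna_arrays(training, truth)
write_expression(arrays, args.outdir / "expression.tsv",
                 args.outdir / "sample_sheet.tsv")
mirna_tr, _ = ch.generate_ct_tables(training, truth)
write_ct(mirna_tr, args.outdir / "mirna_ct_training.tsv")
mirna_val, mrna_val = ch.generate_ct_tables(validation, truth)
write_ct(mirna_val, args.outdir / "mirna_ct_validation.tsv")
write_ct(mrna_val, args.outdir / "mrna_ct_validation.tsv")

print(f"seed {args.seed}: training {training.n_patients} tumours x "
      f"{training.n_genes} genes / {training.n_mirnas} miRNAs; "
      f"validation {validation.n_patients} patients (paired normals)")
print(f"planted: {len(truth.de_genes)} DE genes, {len(truth.de_mirnas)} DE "
      f"miRNAs, {len(truth.true_pairs)} repression pairs, "
      f"{len(truth.decoy_pairs)} decoy predictions -> {args.outdir}")
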