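#!/usr/bin/env python
"""Shrunken-centroid subtype signature and its overlap with the DE list.

Cross-validates the shrinkage threshold on the training arrays (parsimony
rule: largest delta at minimal CV error), extracts the surviving-gene
signature, and intersects it with the differential-expression hits.
Writes results/tables/nsc_signature.tsv and nsc_cv_curve.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from nsclcmir.io import read_expression
from nsclcmir.nsc import cv_select_delta, fit_nsc, signature_genes
from nsclcmir.pipeline import intersect_signature

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--datadir", type=Path, default=Path("results/data"))
parser.add_argument("--outdir", type=Path, default=Path("results/tables"))
args = parser.parse_args()

x = read_expression(args.datadir / "expression.tsv",
                    args.datadir / "sample_sheet.tsv")
delta_star, curve = cv_select_delta(x, folds=5, seed=args.seed)
curve.to_csv(args.outdir / "nsc_cv_curve.tsv", sep="\t", index=False)
model = fit_nsc(x, delta=delta_star)
signature = signature_genes(model)
pd.DataFrame({"gene": signature}).to_csv(
    args.outdir / "nsc_signature.tsv", sep="\t", index=False)

de = pd.read_csv(args.outdir / "de_mrna.tsv", sep="\t")
matched = intersect_signature(de[de["de"]]["feature"], signature)
print(f"delta* = {delta_star:g} (CV error "
      f"{curve.loc[curve['delta'] == delta_star, 'cv_error'].iloc[0]:.3f}); "
      f"signature: {len(signature)} genes; {len(matched)} also DE")
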