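#!/usr/bin/env python
"""Repression-consistent miRNA-target networks.

Two integrations: (a) the packaged published prediction table for the nine
subtype-discriminating miRNAs with their reported directions, reproducing
the 9-miRNA / 11-gene / 19-edge network; (b) the synthetic study's own DE
lists against the simulated prediction table.  Writes
results/tables/published_network.tsv and network.tsv (plus GraphML).
"""

import argparse
from pathlib import Path

import pandas as pd

from nsclcmir.io import load_published_targets, read_targets
from nsclcmir.network import (export_network, gene_directions_from_targets,
                              integrate, multi_mirna_targets)
from nsclcmir.pipeline import gene_down_map

parser = argparse.ArgumentParser()
parser.add_argument("--datadir", type=Path, default=Path("results/data"))
parser.add_argument("--outdir", type=Path, default=Path("results/tables"))
args = parser.parse_args()

published = load_published_targets()
pub_net = integrate(published.mirna_directions(),
                    gene_directions_from_targets(published), published)
export_network(pub_net, args.outdir / "published_network.tsv",
               args.outdir / "published_network.graphml")
print(f"published table: {len(pub_net.mirnas)} miRNAs "
      f"({len(pub_net.mirnas_up_in('SCC'))} up in SCC), "
      f"{len(pub_net.genes)} genes, {pub_net.n_edges} edges; "
      f"multi-miRNA targets: {', '.join(multi_mirna_targets(pub_net))}")

targets = read_targets(args.datadir / "targets.tsv")
de_mirna = pd.read_csv(args.outdir / "de_mirna.tsv", sep="\t")
de_mirna = de_mirna[de_mirna["de"]]
de_mrna = pd.read_csv(args.outdir / "de_mrna.tsv", sep="\t")
net = integrate(dict(zip(de_mirna["feature"], de_mirna["group"])),
                gene_down_map(de_mrna[de_mrna["de"]]), targets)
export_network(net, args.outdir / "network.tsv",
               args.outdir / "network.graphml")
print(f"synthetic study: {len(net.mirnas)} miRNAs, {len(net.genes)} genes, "
      f"{net.n_edges} edges kept of {targets.n_edges} predictions")
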