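"""End-to-end orchestration of the integrative analysis.

``run_all`` sequences the stages in study order:

1. simulate (or load) a training cohort (arrays + miRNA qPCR) and a paired
   validation cohort,
2. the two-stage mRNA screen (one-sample t + Bonferroni, then fold change),
3. the shrunken-centroid signature with cross-validated threshold,
4. the signature/DE intersection,
5. the miRNA screen (detection rule, Welch t on dCt, BH FDR),
6. repression-consistent network integration against a prediction table,
7. per-edge validation on the paired cohort: Spearman anti-correlation on
   the 2^-ddCt scale and the composite median-binarized diagnostic test.

Each stage's table is written under the output directory, and a JSON
summary records the counts entering and leaving every stage plus the seeds
used, so the funnel is auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as ch
from . import de as de_mod
from . import network as net_mod
from . import nsc as nsc_mod
from . import pairstats as ps
from . import quant
from .errors import ConfigurationError
from .io import (ExpressionMatrix, CtTable, TargetTable, read_expression,
                 read_ct, read_targets, write_expression, write_ct)

__all__ = ["PipelineConfig", "run_all", "intersect_signature", "load_config"]

log = logging.getLogger("nsclcmir")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Exactly one of ``synthetic`` (use the generator) or explicit input paths
    may be active.  Defaults carry the study constants: Bonferroni and FDR
    level 0.05, log10-ratio threshold 0.3 (2-fold), detection fraction 0.8.
    """

    synthetic: bool = True
    seed: int = 1
    # input paths (used when synthetic is False)
    expression_path: str | None = None
    sample_sheet_path: str | None = None
    mirna_ct_path: str | None = None
    validation_mirna_ct_path: str | None = None
    validation_mrna_ct_path: str | None = None
    targets_path: str | None = None
    # thresholds
    alpha_mrna: float = 0.05
    alpha_mirna: float = 0.05
    alpha_correlation: float = 0.05
    log_ratio_threshold: float = 0.3
    detection_fraction: float = 0.8
    # NSC settings
    nsc_folds: int = 5
    nsc_delta_grid: tuple[float, ...] = tuple(
        float(v) for v in np.linspace(0.0, 4.0, 17))
    # output
    outdir: str = "results/pipeline"

    def __post_init__(self) -> None:
        for name in ("alpha_mrna", "alpha_mirna", "alpha_correlation",
                     "detection_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigurationError(f"{name} = {v} outside (0, 1]")
        if self.log_ratio_threshold < 0:
            raise ConfigurationError("log_ratio_threshold must be >= 0")
        paths = [self.expression_path, self.mirna_ct_path, self.targets_path]
        if self.synthetic and any(p is not None for p in paths):
            raise ConfigurationError(
                "synthetic mode and explicit input paths are exclusive")
        if not self.synthetic and any(p is None for p in paths):
            raise ConfigurationError(
                "non-synthetic mode requires expression, miRNA Ct and "
                "target paths")


def load_config(path) -> PipelineConfig:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if "nsc_delta_grid" in payload:
        payload["nsc_delta_grid"] = tuple(payload["nsc_delta_grid"])
    return PipelineConfig(**payload)


def intersect_signature(de_genes, signature: list[str]) -> list[str]:
    """Genes present in both lists, in the signature's order."""
    de_set = set(de_genes)
    return [g for g in signature if g in de_set]


def _simulate_inputs(config: PipelineConfig):
    training = ch.CohortDesign(n_scc=25, n_ad=19, paired_normals=False,
                               seed=config.seed, cohort="training")
    validation = ch.CohortDesign(n_scc=17, n_ad=24, paired_normals=True,
                                 n_genes=training.n_genes,
                                 n_mirnas=training.n_mirnas,
                                 seed=config.seed + 1, cohort="validation")
    truth = ch.default_truth(training)
    arrays = ch.generate_mrna_arrays(training, truth)
    mirna_ct_train, _ = ch.generate_ct_tables(training, truth)
    mirna_ct_val, mrna_ct_val = ch.generate_ct_tables(validation, truth)
    targets = ch.truth_target_table(truth)
    return truth, arrays, mirna_ct_train, mirna_ct_val, mrna_ct_val, targets


def _load_inputs(config: PipelineConfig):
    arrays = read_expression(config.expression_path, config.sample_sheet_path)
    mirna_ct_train = read_ct(config.mirna_ct_path)
    mirna_ct_val = (read_ct(config.validation_mirna_ct_path)
                    if config.validation_mirna_ct_path else None)
    mrna_ct_val = (read_ct(config.validation_mrna_ct_path)
                   if config.validation_mrna_ct_path else None)
    targets = read_targets(config.targets_path)
    return None, arrays, mirna_ct_train, mirna_ct_val, mrna_ct_val, targets


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the summary dict (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}

    if config.synthetic:
        (truth, arrays, mirna_ct_train, mirna_ct_val, mrna_ct_val,
         targets) = _simulate_inputs(config)
        ch.write_truth(truth, outdir / "truth.json")
        write_expression(arrays, outdir / "expression.tsv",
                         outdir / "sample_sheet.tsv")
        write_ct(mirna_ct_train, outdir / "mirna_ct_training.tsv")
        write_ct(mirna_ct_val, outdir / "mirna_ct_validation.tsv")
        write_ct(mrna_ct_val, outdir / "mrna_ct_validation.tsv")
    else:
        (truth, arrays, mirna_ct_train, mirna_ct_val, mrna_ct_val,
         targets) = _load_inputs(config)
    summary["stages"]["inputs"] = {
        "genes": len(arrays.genes), "samples": len(arrays.samples),
        "mirna_assays": len(mirna_ct_train.assays),
        "predicted_pairs": targets.n_edges,
    }
    log.info("inputs: %s", summary["stages"]["inputs"])

    # ---- stage: mRNA DE screen -------------------------------------------
    de_genes = de_mod.mrna_de_screen(arrays, alpha=config.alpha_mrna,
                                     threshold=config.log_ratio_threshold)
    de_genes.to_csv(outdir / "de_mrna.tsv", sep="\t", index=False)
    de_gene_hits = de_genes[de_genes["de"]]
    summary["stages"]["mrna_de"] = {
        "tested": int(de_genes["feature"].nunique()),
        "de_rows": int(de_gene_hits.shape[0]),
        "de_genes": int(de_gene_hits["feature"].nunique()),
    }
    log.info("mRNA DE: %s", summary["stages"]["mrna_de"])

    # ---- stage: NSC signature --------------------------------------------
    delta_star, curve = nsc_mod.cv_select_delta(
        arrays, folds=config.nsc_folds,
        delta_grid=np.asarray(config.nsc_delta_grid), seed=config.seed)
    model = nsc_mod.fit_nsc(arrays, delta=delta_star)
    signature = nsc_mod.signature_genes(model)
    curve.to_csv(outdir / "nsc_cv_curve.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": signature}).to_csv(
        outdir / "nsc_signature.tsv", sep="\t", index=False)
    summary["stages"]["nsc"] = {"delta_star": delta_star,
                                "signature_genes": len(signature)}
    log.info("NSC: %s", summary["stages"]["nsc"])

    # ---- stage: signature / DE intersection ------------------------------
    matched = intersect_signature(de_gene_hits["feature"], signature)
    summary["stages"]["intersection"] = {"matched_genes": len(matched)}
    log.info("intersection: %s", summary["stages"]["intersection"])

    # ---- stage: miRNA DE screen ------------------------------------------
    rq_train = quant.relative_quantify(mirna_ct_train, ch.MIRNA_REFERENCE)
    subtype_of = _patient_subtypes(mirna_ct_train, arrays, config)
    de_mirnas = de_mod.mirna_de_screen(
        rq_train, subtype_of, alpha=config.alpha_mirna,
        detection_fraction=config.detection_fraction)
    de_mirnas.to_csv(outdir / "de_mirna.tsv", sep="\t", index=False)
    de_mirna_hits = de_mirnas[de_mirnas["de"]] if len(de_mirnas) else de_mirnas
    summary["stages"]["mirna_de"] = {
        "tested": int(len(de_mirnas)),
        "de_mirnas": int(len(de_mirna_hits)),
    }
    log.info("miRNA DE: %s", summary["stages"]["mirna_de"])

    # ---- stage: network integration --------------------------------------
    mirna_up = dict(zip(de_mirna_hits["feature"], de_mirna_hits["group"]))
    gene_down = gene_down_map(de_gene_hits)
    # restrict to the signature-matched funnel when it is non-trivial
    if matched:
        gene_down = {g: s for g, s in gene_down.items() if g in matched}
    net = net_mod.integrate(mirna_up, gene_down, targets)
    net_mod.export_network(net, outdir / "network.tsv",
                           outdir / "network.graphml")
    summary["stages"]["network"] = {
        "mirnas": len(net.mirnas), "genes": len(net.genes),
        "edges": net.n_edges,
        "multi_mirna_targets": len(net_mod.multi_mirna_targets(net)),
    }
    log.info("network: %s", summary["stages"]["network"])

    # ---- stage: paired-cohort validation + pair statistics ----------------
    if mirna_ct_val is not None and mrna_ct_val is not None:
        pair_table = validate_pairs(
            net, mirna_ct_val, mrna_ct_val, config=config)
        pair_table.to_csv(outdir / "pair_report.tsv", sep="\t", index=False)
        n_neg = int((pair_table["rho"] < 0).sum()) if len(pair_table) else 0
        summary["stages"]["pairs"] = {
            "pairs_tested": int(len(pair_table)),
            "negative_rho": n_neg,
            "significant_inverse": int(
                ((pair_table["rho"] < 0)
                 & (pair_table["p"] <= config.alpha_correlation)).sum())
            if len(pair_table) else 0,
        }
        log.info("pairs: %s", summary["stages"]["pairs"])

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8")
    cfg = asdict(config)
    cfg["nsc_delta_grid"] = list(cfg["nsc_delta_grid"])
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg), encoding="utf-8")
    return summary


_OTHER_SUBTYPE = {"SCC": "AD", "AD": "SCC"}


def gene_down_map(de_gene_hits: pd.DataFrame) -> dict[str, str]:
    """Subtype in which each DE gene is down-regulated.

    The one-sample screen reports per-subtype up/down vs the pooled
    reference; in the two-subtype contrast a gene down-vs-pool in S is down
    in S, and a gene up-vs-pool in T is down in the other subtype.
    Conflicting implications drop the gene.
    """
    out: dict[str, str] = {}
    conflicted: set[str] = set()
    for _, row in de_gene_hits.iterrows():
        down_in = (row["group"] if row["direction"] == "down"
                   else _OTHER_SUBTYPE[row["group"]])
        if row["feature"] in out and out[row["feature"]] != down_in:
            conflicted.add(row["feature"])
        out[row["feature"]] = down_in
    for g in conflicted:
        del out[g]
    return out


def _patient_subtypes(ct: CtTable, arrays: ExpressionMatrix,
                      config: PipelineConfig) -> dict[str, str]:
    """Subtype per patient for the miRNA screen.

    Synthetic cohorts encode the subtype in the patient id; otherwise the
    array sample sheet is consulted by patient_id.
    """
    patients = ct.data["patient_id"].unique()
    by_sheet = dict(zip(arrays.metadata["patient_id"], arrays.metadata["subtype"]))
    out = {}
    for p in patients:
        if p in by_sheet:
            out[p] = by_sheet[p]
        elif "-SCC-" in p:
            out[p] = "SCC"
        elif "-AD-" in p:
            out[p] = "AD"
        else:
            raise ConfigurationError(f"cannot determine subtype of patient {p!r}")
    return out


def validate_pairs(net: net_mod.RegulatoryNetwork,
                   mirna_ct: CtTable, mrna_ct: CtTable,
                   config: PipelineConfig,
                   extra_pairs: list[tuple[str, str, str]] | None = None
                   ) -> pd.DataFrame:
    """Spearman + composite diagnostics for every network edge on a paired
    cohort, computed on the 2^-ddCt scale.

    ``extra_pairs`` may append (mirna, gene, condition_subtype) triples that
    are not in the network (e.g. decoy predictions, for benchmarking).
    """
    ref_gene, _ = quant.select_housekeeping(
        mrna_ct, list(ch.MRNA_REFERENCES),
        min_detection=config.detection_fraction)
    rq_mirna = quant.relative_quantify(mirna_ct, ch.MIRNA_REFERENCE, paired=True)
    rq_mrna = quant.relative_quantify(mrna_ct, ref_gene, paired=True)
    expr_m = rq_mirna.pivot(index="patient_id", columns="assay",
                            values="rel_expr_paired")
    expr_g = rq_mrna.pivot(index="patient_id", columns="assay",
                           values="rel_expr_paired")
    patients = expr_m.index
    subtype = np.array(["SCC" if "-SCC-" in p else "AD" for p in patients])

    todo = [(m, g, net.graph.edges[m, g]["subtype"]) for m, g in net.edges()]
    todo += list(extra_pairs or [])
    results = []
    for mirna, gene, cond in todo:
        if mirna not in expr_m.columns or gene not in expr_g.columns:
            continue
        mv = expr_m[mirna].to_numpy()
        gv = expr_g.loc[patients, gene].to_numpy()
        keep = ~(np.isnan(mv) | np.isnan(gv))
        rho, p = ps.spearman(mv[keep], gv[keep])
        assoc = ps.PairAssociation(mirna=mirna, gene=gene,
                                   n=int(keep.sum()), rho=rho, p_value=p)
        diag = ps.composite_test(mv[keep], gv[keep], subtype[keep],
                                 condition_subtype=cond,
                                 mirna=mirna, gene=gene)
        results.append((assoc, diag))
    return ps.pair_report(results)
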