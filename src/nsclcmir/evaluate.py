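"""Scoring the pipeline against planted ground truth.

These helpers run the full synthetic study at a given seed and measure how
well each stage recovers what was planted: differential-expression recovery
and false-positive rates, anti-correlation of true repression pairs, and
the composite diagnostic's ability to rank true pairs above decoy
predictions.  They also provide the two error-control simulations (null
family-wise error of the mRNA screen, empirical coverage of the exact
binomial interval).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cohort as ch
from . import de as de_mod
from . import network as net_mod
from . import pairstats as ps
from . import quant
from .io import ExpressionMatrix
from .pipeline import PipelineConfig, gene_down_map, validate_pairs

__all__ = ["evaluate_synthetic_study", "null_screen_fwer",
           "clopper_pearson_coverage"]


def evaluate_synthetic_study(seed: int = 1) -> dict:
    """Run the default-size synthetic study and score it against truth.

    Designs mirror the two cohorts (25+19 training, 17+24 paired
    validation); the planted configuration is :func:`cohort.default_truth`
    (50 genes at 0.5 log10, 9 miRNAs at 2 Ct, 19 repression pairs, 10 decoy
    predictions).  Returns a flat dict of recovery metrics.
    """
    training = ch.CohortDesign(n_scc=25, n_ad=19, seed=seed, cohort="training")
    validation = ch.CohortDesign(n_scc=17, n_ad=24, paired_normals=True,
                                 seed=seed + 1, cohort="validation")
    truth = ch.default_truth(training)
    config = PipelineConfig(seed=seed, outdir="unused")

    # --- mRNA screen on arrays -------------------------------------------
    arrays = ch.generate_mrna_arrays(training, truth)
    de_genes = de_mod.mrna_de_screen(arrays, alpha=config.alpha_mrna,
                                     threshold=config.log_ratio_threshold)
    hits = de_genes[de_genes["de"]]
    flagged = set(zip(hits["feature"], hits["group"], hits["direction"]))
    planted_gene_hits = sum(
        (g, s, "up") in flagged for g, s, _ in truth.de_genes)
    planted_names = {g for g, _, _ in truth.de_genes}
    null_flagged = hits[~hits["feature"].isin(planted_names)]["feature"].nunique()
    n_null = training.n_genes - len(planted_names)

    # --- miRNA screen on training qPCR -----------------------------------
    mirna_ct, _ = ch.generate_ct_tables(training, truth)
    rq = quant.relative_quantify(mirna_ct, ch.MIRNA_REFERENCE)
    subtype_of = {p: ("SCC" if "-SCC-" in p else "AD")
                  for p in rq["patient_id"].unique()}
    de_mirnas = de_mod.mirna_de_screen(rq, subtype_of,
                                       alpha=config.alpha_mirna,
                                       detection_fraction=config.detection_fraction)
    mhits = de_mirnas[de_mirnas["de"]]
    mflagged = set(zip(mhits["feature"], mhits["group"]))
    planted_mirna_hits = sum((m, s) in mflagged for m, s, _ in truth.de_mirnas)

    # --- network integration ---------------------------------------------
    targets = ch.truth_target_table(truth)
    mirna_up = dict(zip(mhits["feature"], mhits["group"]))
    net = net_mod.integrate(mirna_up, gene_down_map(hits), targets)

    # --- paired-cohort pair statistics, true pairs and decoys -------------
    mirna_ct_val, mrna_ct_val = ch.generate_ct_tables(validation, truth)
    mirna_dir = truth.mirna_directions()
    decoy_triples = [(m, g, mirna_dir[m]) for m, g in truth.decoy_pairs]
    report = validate_pairs(net, mirna_ct_val, mrna_ct_val, config=config,
                            extra_pairs=decoy_triples)
    true_keys = {(m, g) for m, g, _ in truth.true_pairs}
    keys = list(zip(report["mirna"], report["gene"]))
    is_true = pd.Series([k in true_keys for k in keys], index=report.index)
    is_decoy = pd.Series([k in set(truth.decoy_pairs) for k in keys],
                         index=report.index)
    true_rows = report[is_true]
    decoy_rows = report[is_decoy]

    return {
        "n_planted_genes": len(truth.de_genes),
        "planted_gene_hits": int(planted_gene_hits),
        "null_genes": int(n_null),
        "null_gene_flags": int(null_flagged),
        "n_planted_mirnas": len(truth.de_mirnas),
        "planted_mirna_hits": int(planted_mirna_hits),
        "network_mirnas": len(net.mirnas),
        "network_genes": len(net.genes),
        "network_edges": net.n_edges,
        "n_true_pairs": int(len(true_rows)),
        "true_pairs_negative_rho": int((true_rows["rho"] < 0).sum()),
        "median_true_pair_rho": float(true_rows["rho"].median()),
        "true_pair_mean_sensitivity": float(true_rows["sens"].mean()),
        "n_decoy_pairs": int(len(decoy_rows)),
        "decoy_pair_mean_sensitivity": float(decoy_rows["sens"].mean()),
    }


def null_screen_fwer(n_replicates: int = 200, n_genes: int = 500,
                     n_scc: int = 10, n_ad: int = 10, sigma: float = 0.1,
                     alpha: float = 0.05, seed: int = 0) -> dict:
    """Family-wise error of the mRNA screen on pure-noise cohorts.

    Each replicate is a null expression matrix (no planted effects); a
    family-wise error occurs when any gene is flagged DE.  Also reports the
    FWER of the t+Bonferroni stage alone (before the fold-change filter),
    which is the quantity Bonferroni controls at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    samples = [f"S{i:03d}" for i in range(n_scc + n_ad)]
    meta = pd.DataFrame({
        "subtype": ["SCC"] * n_scc + ["AD"] * n_ad,
        "cohort": "sim", "tissue": "tumor", "patient_id": samples,
    }, index=pd.Index(samples, name="sample_id"))
    any_de = 0
    any_t = 0
    for _ in range(n_replicates):
        values = rng.normal(0.0, sigma, size=(n_genes, len(samples)))
        x = ExpressionMatrix(
            values=pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                                columns=samples),
            metadata=meta)
        res = de_mod.mrna_de_screen(x, alpha=alpha)
        any_de += int(res["de"].any())
        any_t += int(res["passes_t"].any())
    return {
        "n_replicates": n_replicates,
        "fwer_screen": any_de / n_replicates,
        "fwer_t_stage": any_t / n_replicates,
    }


def clopper_pearson_coverage(n_draws: int = 2000, p: float = 0.7,
                             n: int = 17, alpha: float = 0.05,
                             seed: int = 0) -> dict:
    """Empirical coverage of the exact binomial interval.

    Exact intervals are conservative, so coverage should be >= 1 - alpha.
    """
    rng = np.random.default_rng(seed)
    ks = rng.binomial(n, p, size=n_draws)
    covered = 0
    cache: dict[int, tuple[float, float]] = {}
    for k in ks:
        lo, hi = cache.setdefault(int(k), ps.clopper_pearson(int(k), n, alpha))
        covered += int(lo <= p <= hi)
    return {"n_draws": n_draws, "coverage": covered / n_draws}
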