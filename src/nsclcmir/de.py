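"""Differential-expression screens.

mRNA (arrays): each gene is tested per subtype with a one-sample t-test of
its log10 ratios against 0 (i.e. against the pooled reference), p-values are
adjusted with the single-step Bonferroni procedure over all genes tested,
and survivors must additionally clear a fold-change filter
|mean log10 ratio| > 0.3 (strictly; 0.301 = exactly 2-fold).  A gene is
differentially expressed for a subtype only if both filters pass.  A Welch
two-sample subtype-contrast mode is available behind a flag.

miRNA (qPCR): assays detected in fewer than 80% of samples are excluded
up front; surviving assays are compared between subtypes with a Welch
t-test on the dCt scale (approximately Gaussian, unlike 2^-dCt), with
Benjamini-Hochberg FDR control.  Direction is reported as the subtype with
the *higher* expression, i.e. the lower mean dCt.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, UndefinedStatisticError
from .io import ExpressionMatrix

__all__ = [
    "one_sample_t",
    "welch_t",
    "bonferroni",
    "fold_change_filter",
    "mrna_de_screen",
    "mirna_de_screen",
]

FOLD_CHANGE_THRESHOLD = 0.3  # log10 units; 10**0.3 ~ 2-fold

DE_COLUMNS = ["feature", "group", "effect", "t", "p_raw", "p_adj",
              "direction", "passes_t", "passes_fc", "de"]


def one_sample_t(values) -> tuple[float, float]:
    """Two-sided one-sample t-test of ``values`` against zero.

    Missing entries are dropped; requires >= 2 observations with nonzero
    variance.  Returns ``(t, p)`` with p from the t distribution on n-1 df.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    n = v.size
    if n < 2:
        raise UndefinedStatisticError("one-sample t needs >= 2 non-missing values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise UndefinedStatisticError("one-sample t undefined for zero variance")
    t = v.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def welch_t(a, b) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test with Welch-Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise UndefinedStatisticError("Welch t needs >= 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise UndefinedStatisticError("Welch t undefined: both groups constant")
    se2 = va / a.size + vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return float(t), float(p)


def bonferroni(p_raw, m: int | None = None) -> np.ndarray:
    """Single-step Bonferroni: adjusted p = min(1, m * p).

    ``m`` defaults to the number of p-values and must be at least that.
    """
    p = np.asarray(p_raw, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m = {m} smaller than the {p.size} tests considered")
    return np.minimum(1.0, m * p)


def fold_change_filter(mean_log_ratio: float,
                       threshold: float = FOLD_CHANGE_THRESHOLD) -> bool:
    """Pass iff |mean log10 ratio| strictly exceeds the threshold."""
    if not np.isfinite(mean_log_ratio):
        raise ValueError("fold-change filter requires a finite mean log ratio")
    return abs(mean_log_ratio) > threshold


def mrna_de_screen(x: ExpressionMatrix, alpha: float = 0.05,
                   threshold: float = FOLD_CHANGE_THRESHOLD,
                   contrast: str = "one-sample") -> pd.DataFrame:
    """Two-stage mRNA screen: t-test + Bonferroni, then fold-change filter.

    ``contrast='one-sample'`` (default) tests each gene's log ratios against
    the pooled reference separately within each subtype; the Bonferroni
    family is all genes tested within that subtype.  ``contrast='two-sample'``
    runs a Welch subtype contrast per gene instead (group label
    ``'SCC_vs_AD'``; effect = mean(SCC) - mean(AD)).

    Returns one row per (gene, group) with columns
    feature/group/effect/t/p_raw/p_adj/direction/passes_t/passes_fc/de.
    """
    subtype = x.subtypes().to_numpy()
    groups = sorted(set(subtype))
    if len(groups) < 2:
        raise ConfigurationError("both subtypes must be present for the screen")
    values = x.values.to_numpy(dtype=float)
    frames = []
    if contrast == "one-sample":
        stats_by_group = {}
        for sub in groups:
            cols = subtype == sub
            stats_by_group[sub] = _vector_one_sample(values[:, cols])
        # one Bonferroni family over every test performed (both subtypes),
        # so the screen's family-wise error is controlled at alpha overall
        m_total = int(sum(np.sum(~np.isnan(p)) for _, p, _ in
                          stats_by_group.values()))
        for sub in groups:
            t, p, effect = stats_by_group[sub]
            frames.append(_assemble(x.genes, sub, effect, t, p, alpha,
                                    threshold, m=m_total))
    elif contrast == "two-sample":
        a = values[:, subtype == groups[1]]  # SCC when groups = [AD, SCC]
        b = values[:, subtype == groups[0]]
        rows = [welch_t(a[i], b[i]) for i in range(values.shape[0])]
        t = np.array([r[0] for r in rows])
        p = np.array([r[1] for r in rows])
        effect = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
        frames.append(_assemble(x.genes, f"{groups[1]}_vs_{groups[0]}",
                                effect, t, p, alpha, threshold))
    else:
        raise ConfigurationError(f"unknown contrast {contrast!r}")
    out = pd.concat(frames, ignore_index=True)
    return out[DE_COLUMNS]


def _vector_one_sample(v: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise one-sample t vs 0 with NaN handling (vectorised)."""
    n = np.sum(~np.isnan(v), axis=1)
    mean = np.nanmean(v, axis=1)
    sd = np.nanstd(v, axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    bad = (n < 2) | (sd == 0)
    t[bad] = np.nan
    p[bad] = np.nan
    return t, p, mean


def _assemble(genes, group, effect, t, p, alpha, threshold,
              m: int | None = None) -> pd.DataFrame:
    tested = ~np.isnan(p)
    p_adj = np.full_like(p, np.nan)
    p_adj[tested] = bonferroni(p[tested], m=m if m is not None
                               else int(tested.sum()))
    passes_t = tested & (p_adj <= alpha)
    passes_fc = np.abs(effect) > threshold
    return pd.DataFrame({
        "feature": genes,
        "group": group,
        "effect": effect,
        "t": t,
        "p_raw": p,
        "p_adj": p_adj,
        "direction": np.where(effect >= 0, "up", "down"),
        "passes_t": passes_t,
        "passes_fc": passes_fc,
        "de": passes_t & passes_fc,
    })


def mirna_de_screen(rq: pd.DataFrame, subtypes: pd.Series | dict,
                    alpha: float = 0.05,
                    detection_fraction: float = 0.8) -> pd.DataFrame:
    """miRNA screen on relative-quantification output.

    ``rq`` must carry columns assay/patient_id/delta_ct/detected (as
    produced by :func:`nsclcmir.quant.relative_quantify`); ``subtypes`` maps
    patient_id -> subtype.  Assays detected in fewer than
    ``detection_fraction`` of patients are excluded before testing.  For the
    rest, a Welch t-test compares dCt between subtypes and
    Benjamini-Hochberg FDR is applied; an assay is DE iff q <= alpha, with
    direction the subtype of higher expression (lower dCt).

    Returns one row per tested assay: feature/group/effect/t/p_raw/p_adj/
    direction/passes_t/passes_fc/de, where ``effect`` is
    mean dCt(AD) - mean dCt(SCC) ... i.e. positive when expression is higher
    in SCC, ``group`` is the higher-expression subtype, and passes_fc is
    always True (no fold-change stage for miRNAs).
    """
    sub_map = dict(subtypes) if not isinstance(subtypes, dict) else subtypes
    rq = rq.copy()
    rq["subtype"] = rq["patient_id"].map(sub_map)
    if rq["subtype"].isna().any():
        missing = rq.loc[rq["subtype"].isna(), "patient_id"].unique()
        raise ConfigurationError(f"patients without subtype label: {missing[:5]}")
    rows = []
    for assay, grp in rq.groupby("assay", sort=True):
        det_frac = grp["detected"].mean()
        if det_frac < detection_fraction:
            continue
        scc = grp.loc[grp["subtype"] == "SCC", "delta_ct"].to_numpy()
        ad = grp.loc[grp["subtype"] == "AD", "delta_ct"].to_numpy()
        try:
            t, p = welch_t(ad, scc)  # positive t => higher dCt in AD => up in SCC
        except UndefinedStatisticError:
            continue
        effect = float(np.nanmean(ad) - np.nanmean(scc))
        rows.append({"feature": assay, "effect": effect, "t": t, "p_raw": p,
                     "group": "SCC" if effect > 0 else "AD"})
    if not rows:
        warnings.warn("no miRNA survives the detection rule", stacklevel=2)
        return pd.DataFrame(columns=DE_COLUMNS)
    out = pd.DataFrame(rows)
    reject, q, _, _ = multipletests(out["p_raw"], alpha=alpha, method="fdr_bh")
    out["p_adj"] = q
    out["passes_t"] = out["p_adj"] <= alpha
    out["passes_fc"] = True
    out["de"] = out["passes_t"]
    out["direction"] = "up"  # direction is expressed through `group`
    return out[DE_COLUMNS]
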