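"""Per-pair statistics: Spearman anti-correlation and the composite
median-binarized diagnostic test with exact binomial confidence intervals.

The composite test calls a patient *positive* when the miRNA is above its
cohort median AND the target gene is below its cohort median; the condition
is the patient's histological subtype.  Sensitivity, specificity, PPV and
NPV are reported with exact (Clopper-Pearson) 95% intervals computed from F
quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedStatisticError

__all__ = ["PairAssociation", "DiagnosticResult", "spearman",
           "binarize_at_median", "composite_test", "clopper_pearson"]


@dataclass(frozen=True)
class PairAssociation:
    mirna: str
    gene: str
    n: int
    rho: float
    p_value: float


@dataclass(frozen=True)
class DiagnosticResult:
    """2x2 diagnostic summary for one miRNA/gene pair.

    Metrics are proportions in [0, 1] (NaN when the denominator is zero, in
    which case the CI is (NaN, NaN) too).
    """

    mirna: str
    gene: str
    condition_subtype: str
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int, tn: int,
                    mirna: str = "", gene: str = "",
                    condition_subtype: str = "",
                    alpha: float = 0.05) -> "DiagnosticResult":
        """Metrics + exact CIs from a 2x2 table."""
        if min(tp, fp, fn, tn) < 0:
            raise ValueError("2x2 counts must be non-negative")

        def metric(k, n):
            if n == 0:
                return float("nan"), (float("nan"), float("nan"))
            return k / n, clopper_pearson(k, n, alpha)

        sens, sens_ci = metric(tp, tp + fn)
        spec, spec_ci = metric(tn, tn + fp)
        ppv, ppv_ci = metric(tp, tp + fp)
        npv, npv_ci = metric(tn, tn + fn)
        return cls(mirna=mirna, gene=gene, condition_subtype=condition_subtype,
                   tp=tp, fp=fp, fn=fn, tn=tn,
                   sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
                   sensitivity_ci=sens_ci, specificity_ci=spec_ci,
                   ppv_ci=ppv_ci, npv_ci=npv_ci)


def spearman(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties; two-sided p.

    Pairs with a missing value are dropped; needs >= 3 complete pairs and a
    non-constant x and y.  The p-value uses the t approximation
    ``t = rho * sqrt((n-2) / (1-rho^2))``; with ``exact=True`` (n <= 9) it
    enumerates all rank permutations instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise UndefinedStatisticError("Spearman needs >= 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("Spearman undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.unique(rx).size == n and np.unique(ry).size == n:
        # classic untied formula is exact (integer d^2), so perfect
        # monotone data yields rho = +/-1 exactly
        d2 = np.sum((rx - ry) ** 2)
        rho = float(1.0 - 6.0 * d2 / (n * (n * n - 1.0)))
    else:
        rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact:
        if n > 9:
            raise UndefinedStatisticError(
                "exact permutation p limited to n <= 9")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
                count += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def binarize_at_median(values) -> np.ndarray:
    """High/low flags: True (high) iff value > median of the non-missing
    values; ties at the median are low, so a constant vector is all-low.
    Missing values stay missing (returned as a masked False with NaN input
    positions propagated by the caller if needed)."""
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() < 2:
        raise UndefinedStatisticError("median binarization needs >= 2 values")
    med = np.median(v[ok])
    return v > med  # NaN > med is False; callers drop incomplete patients


def composite_test(mirna_expr, gene_expr, subtypes, condition_subtype: str,
                   mirna: str = "", gene: str = "",
                   alpha: float = 0.05) -> DiagnosticResult:
    """Composite median-binarized diagnostic test for one pair.

    Patients are test-positive when the miRNA is high (above the cohort
    median) and the gene low (at or below its median); condition-positive
    when their subtype equals ``condition_subtype``.  Patients with a
    missing measurement are dropped before the medians are taken.
    """
    mv = np.asarray(mirna_expr, dtype=float)
    gv = np.asarray(gene_expr, dtype=float)
    sub = np.asarray(subtypes)
    if not (mv.size == gv.size == sub.size):
        raise ValueError("mirna_expr, gene_expr and subtypes must align")
    keep = ~(np.isnan(mv) | np.isnan(gv))
    mv, gv, sub = mv[keep], gv[keep], sub[keep]
    mirna_high = binarize_at_median(mv)
    gene_high = binarize_at_median(gv)
    test_pos = mirna_high & ~gene_high
    cond_pos = sub == condition_subtype
    tp = int(np.sum(test_pos & cond_pos))
    fp = int(np.sum(test_pos & ~cond_pos))
    fn = int(np.sum(~test_pos & cond_pos))
    tn = int(np.sum(~test_pos & ~cond_pos))
    return DiagnosticResult.from_counts(
        tp, fp, fn, tn, mirna=mirna, gene=gene,
        condition_subtype=condition_subtype, alpha=alpha)


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial CI for k successes in n trials, via F quantiles.

    lower = [1 + (n-k+1) / (k * F(alpha/2; 2k, 2(n-k+1)))]^-1   (0 if k=0)
    upper = [1 + (n-k) / ((k+1) * F(1-alpha/2; 2(k+1), 2(n-k)))]^-1  (1 if k=n)
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k = {k} outside [0, {n}]")
    if k == 0:
        lower = 0.0
    else:
        f = stats.f.ppf(alpha / 2.0, 2 * k, 2 * (n - k + 1))
        lower = 1.0 / (1.0 + (n - k + 1) / (k * f))
    if k == n:
        upper = 1.0
    else:
        f = stats.f.ppf(1.0 - alpha / 2.0, 2 * (k + 1), 2 * (n - k))
        upper = 1.0 / (1.0 + (n - k) / ((k + 1) * f))
    return float(lower), float(upper)


def pair_report(results: list[tuple[PairAssociation, DiagnosticResult]]) -> pd.DataFrame:
    """Flatten association + diagnostic results into the report table."""
    rows = []
    for assoc, diag in results:
        rows.append({
            "mirna": assoc.mirna, "gene": assoc.gene, "n": assoc.n,
            "rho": assoc.rho, "p": assoc.p_value,
            "tp": diag.tp, "fp": diag.fp, "fn": diag.fn, "tn": diag.tn,
            "sens": diag.sensitivity,
            "sens_lo": diag.sensitivity_ci[0], "sens_hi": diag.sensitivity_ci[1],
            "spec": diag.specificity,
            "spec_lo": diag.specificity_ci[0], "spec_hi": diag.specificity_ci[1],
            "ppv": diag.ppv, "ppv_lo": diag.ppv_ci[0], "ppv_hi": diag.ppv_ci[1],
            "npv": diag.npv, "npv_lo": diag.npv_ci[0], "npv_hi": diag.npv_ci[1],
        })
    return pd.DataFrame(rows)
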