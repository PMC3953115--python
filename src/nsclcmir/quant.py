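"""Relative quantification of qPCR data: 2^-dCt and 2^-ddCt.

Replicate Ct values are aggregated by the median of the non-missing
replicates (the median commutes with the monotone 2^-x map, so aggregating
on the Ct scale and on the expression scale agree).  Undetermined
observations stay missing -- they are never imputed to a sentinel cycle
number -- and an assay whose replicates are all missing for a patient is
flagged undetected there.

dCt = Ct(target) - Ct(reference housekeeping assay); relative expression is
2^-dCt.  For paired tumour/normal designs, ddCt = dCt(tumour) - dCt(normal)
and relative expression is 2^-ddCt, which cancels any patient-wide Ct offset.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import CtTable

__all__ = [
    "aggregate_replicates",
    "select_housekeeping",
    "delta_ct",
    "delta_delta_ct",
    "relative_quantify",
]

RELQUANT_COLUMNS = ["assay", "patient_id", "delta_ct", "rel_expr",
                    "ddct", "rel_expr_paired", "detected"]


def aggregate_replicates(ct: CtTable) -> pd.DataFrame:
    """Median Ct over non-missing replicates per (assay, patient, tissue).

    Returns a frame with columns assay/patient_id/tissue/ct/detected, where
    ``detected`` is False (and ct is NaN) when every replicate is missing.
    """
    grouped = ct.data.groupby(["assay", "patient_id", "tissue"], sort=True)
    agg = grouped["ct"].agg(ct="median", detected=lambda s: s.notna().any())
    return agg.reset_index()


def select_housekeeping(ct: CtTable, candidates: list[str],
                        min_detection: float = 0.8) -> tuple[str, pd.DataFrame]:
    """Pick the most stable housekeeping assay.

    Stability is the standard deviation of the replicate-aggregated Ct
    across samples; the candidate with the smallest sd wins.  Candidates
    detected in fewer than ``min_detection`` of samples are disqualified.
    Ties resolve to the lexicographically first candidate with a warning.
    """
    if not candidates:
        raise ConfigurationError("no housekeeping candidates supplied")
    agg = aggregate_replicates(ct)
    rows = []
    for cand in sorted(candidates):
        sub = agg[agg["assay"] == cand]
        if sub.empty:
            raise ConfigurationError(f"candidate assay {cand!r} absent from Ct table")
        frac = sub["detected"].mean()
        sd = float(sub["ct"].std(ddof=1))
        rows.append({"assay": cand, "sd": sd, "detection": frac,
                     "eligible": frac >= min_detection})
    report = pd.DataFrame(rows)
    eligible = report[report["eligible"]]
    if eligible.empty:
        raise ConfigurationError(
            f"no housekeeping candidate detected in >= {min_detection:.0%} of samples")
    best_sd = eligible["sd"].min()
    winners = eligible[eligible["sd"] == best_sd]["assay"].tolist()
    if len(winners) > 1:
        warnings.warn(
            f"housekeeping stability tie between {winners}; "
            f"choosing {winners[0]!r}", stacklevel=2)
    return winners[0], report


def delta_ct(ct_target, ct_reference):
    """dCt = Ct(target) - Ct(reference) and 2^-dCt; missing propagates.

    Accepts scalars or numpy arrays; returns ``(delta_ct, rel_expr)``.
    """
    dct = np.asarray(ct_target, dtype=float) - np.asarray(ct_reference, dtype=float)
    rel = np.exp2(-dct)
    if np.ndim(dct) == 0:
        return float(dct), float(rel)
    return dct, rel


def delta_delta_ct(dct_tumor, dct_normal):
    """ddCt = dCt(tumour) - dCt(normal) and 2^-ddCt; missing propagates."""
    ddct = np.asarray(dct_tumor, dtype=float) - np.asarray(dct_normal, dtype=float)
    rel = np.exp2(-ddct)
    if np.ndim(ddct) == 0:
        return float(ddct), float(rel)
    return ddct, rel


def relative_quantify(ct: CtTable, reference_assay: str,
                      paired: bool = False) -> pd.DataFrame:
    """Full relative-quantification table for every non-reference assay.

    Aggregates replicates, subtracts the housekeeping Ct per
    (patient, tissue), and reports per (assay, patient): ``delta_ct`` and
    ``rel_expr`` (tumour tissue), plus ``ddct`` and ``rel_expr_paired`` when
    ``paired`` (tumour dCt additionally normalised to the patient's adjacent
    normal tissue).  ``detected`` refers to the tumour measurement.
    Patients lacking the normal measurement get a missing ddCt with a
    warning.
    """
    agg = aggregate_replicates(ct)
    ref = agg[agg["assay"] == reference_assay]
    if ref.empty:
        raise ConfigurationError(
            f"reference assay {reference_assay!r} absent from Ct table")
    ref = ref.set_index(["patient_id", "tissue"])["ct"]
    targets = agg[agg["assay"] != reference_assay].copy()
    keys = list(zip(targets["patient_id"], targets["tissue"]))
    targets["ref_ct"] = [ref.get(k, np.nan) for k in keys]
    targets["dct"] = targets["ct"] - targets["ref_ct"]

    tumor = targets[targets["tissue"] == "tumor"].set_index(["assay", "patient_id"])
    out = pd.DataFrame(index=tumor.index)
    out["delta_ct"] = tumor["dct"]
    out["rel_expr"] = np.exp2(-tumor["dct"])
    out["detected"] = tumor["detected"]
    if paired:
        normal = targets[targets["tissue"] == "normal"].set_index(
            ["assay", "patient_id"])["dct"]
        missing_normals = out.index.difference(normal.index)
        if len(missing_normals) > 0:
            warnings.warn(
                f"{len(missing_normals)} (assay, patient) pairs lack a normal"
                " tissue measurement; ddCt set to missing", stacklevel=2)
        aligned = normal.reindex(out.index)
        out["ddct"] = out["delta_ct"] - aligned
        out["rel_expr_paired"] = np.exp2(-out["ddct"])
    else:
        out["ddct"] = np.nan
        out["rel_expr_paired"] = np.nan
    return out.reset_index()[RELQUANT_COLUMNS]
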