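"""Nearest-shrunken-centroid (PAM-style) discriminant analysis.

For gene i and class k with n_k samples out of n total:

    d_ik  = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),   m_k = sqrt(1/n_k - 1/n)
    d'_ik = sign(d_ik) * max(|d_ik| - delta, 0)        (soft thresholding)
    xbar'_ik = xbar_i + m_k * (s_i + s0) * d'_ik       (shrunken centroid)

where s_i is the pooled within-class standard deviation and s0 is the median
of the s_i (a variance-stabilising offset).  A sample x is assigned to the
class minimising the discriminant

    delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2  -  2 log pi_k

with ties broken towards the lexicographically first class name.  Genes with
a nonzero shrunken difference for any class form the signature; the
surviving set shrinks monotonically as delta grows.

Published formulations disagree on the normaliser m_k: ``sqrt(1/n_k - 1/n)``
is used here by default, with ``mk="plus"`` switching to
``sqrt(1/n_k + 1/n)`` (the signature size depends on the choice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import ExpressionMatrix

__all__ = ["NSCModel", "fit_nsc", "predict_nsc", "cv_select_delta",
           "signature_genes"]


@dataclass
class NSCModel:
    genes: list[str]
    classes: list[str]
    overall_centroid: np.ndarray          # (genes,)
    class_centroids: np.ndarray           # (genes, classes), unshrunken
    shrunken_centroids: np.ndarray        # (genes, classes)
    s: np.ndarray                         # pooled within-class sd, (genes,)
    s0: float
    mk: np.ndarray                        # (classes,)
    dik: np.ndarray                       # (genes, classes)
    dik_shrunk: np.ndarray                # (genes, classes)
    delta: float
    priors: np.ndarray                    # (classes,)

    def survivors(self) -> np.ndarray:
        """Boolean mask of genes with any nonzero shrunken difference."""
        return np.any(self.dik_shrunk != 0, axis=1)


def _resolve_xy(x, labels):
    if isinstance(x, ExpressionMatrix):
        values = x.values.to_numpy(dtype=float)
        genes = x.genes
        if labels is None:
            labels = x.subtypes().to_numpy()
    else:
        values = np.asarray(x, dtype=float)
        genes = [f"g{i}" for i in range(values.shape[0])]
    return values, genes, np.asarray(labels)


def fit_nsc(x, labels=None, delta: float = 0.0, priors=None,
            mk: str = "minus") -> NSCModel:
    """Fit the shrunken-centroid model at threshold ``delta``.

    ``x`` is an :class:`ExpressionMatrix` (labels default to its subtype
    column) or a genes x samples array with explicit ``labels``.  ``priors``
    defaults to the class proportions.
    """
    values, genes, y = _resolve_xy(x, labels)
    if delta < 0:
        raise ConfigurationError("delta must be >= 0")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ConfigurationError("need at least two classes")
    n = values.shape[1]
    counts = np.array([(y == c).sum() for c in classes])
    if (counts < 2).any():
        few = [c for c, k in zip(classes, counts) if k < 2]
        raise ConfigurationError(f"class(es) with < 2 samples: {few}")

    overall = values.mean(axis=1)
    centroids = np.column_stack([values[:, y == c].mean(axis=1) for c in classes])
    ss = np.zeros(values.shape[0])
    for j, c in enumerate(classes):
        resid = values[:, y == c] - centroids[:, [j]]
        ss += (resid ** 2).sum(axis=1)
    s = np.sqrt(ss / (n - len(classes)))
    s0 = float(np.median(s))

    if mk == "minus":
        mks = np.sqrt(1.0 / counts - 1.0 / n)
    elif mk == "plus":
        mks = np.sqrt(1.0 / counts + 1.0 / n)
    else:
        raise ConfigurationError("mk must be 'minus' or 'plus'")

    denom = np.outer(s + s0, mks)
    dik = (centroids - overall[:, None]) / denom
    dik_shrunk = np.sign(dik) * np.maximum(np.abs(dik) - delta, 0.0)
    shrunken = overall[:, None] + denom * dik_shrunk

    if priors is None:
        priors = counts / n
    priors = np.asarray(priors, dtype=float)
    if not np.isclose(priors.sum(), 1.0):
        raise ConfigurationError("class priors must sum to 1")

    return NSCModel(genes=genes, classes=classes, overall_centroid=overall,
                    class_centroids=centroids, shrunken_centroids=shrunken,
                    s=s, s0=s0, mk=mks, dik=dik, dik_shrunk=dik_shrunk,
                    delta=float(delta), priors=priors)


def predict_nsc(model: NSCModel, profile) -> tuple[str, dict[str, float]]:
    """Classify one sample profile; returns (class, {class: score}).

    ``profile`` is a mapping/Series keyed by gene, or an array aligned to
    ``model.genes``.  Lower discriminant score wins; exact ties go to the
    lexicographically first class.
    """
    if isinstance(profile, (dict, pd.Series)):
        missing = [g for g in model.genes if g not in profile]
        if missing:
            raise ConfigurationError(
                f"profile lacks value(s) for gene(s): {missing[:5]}")
        xv = np.array([float(profile[g]) for g in model.genes])
    else:
        xv = np.asarray(profile, dtype=float)
        if xv.shape[0] != len(model.genes):
            raise ConfigurationError(
                f"profile length {xv.shape[0]} != {len(model.genes)} genes")
    if np.isnan(xv).any():
        bad = [g for g, v in zip(model.genes, xv) if np.isnan(v)]
        raise ConfigurationError(f"missing profile values for gene(s): {bad[:5]}")
    denom2 = (model.s + model.s0) ** 2
    scores = {}
    for j, c in enumerate(model.classes):
        resid2 = (xv - model.shrunken_centroids[:, j]) ** 2
        scores[c] = float(np.sum(resid2 / denom2) - 2.0 * np.log(model.priors[j]))
    # model.classes is sorted, so min() on (score, position) is the
    # lexicographically-first tie-break
    best = min(model.classes, key=lambda c: (scores[c], c))
    return best, scores


def predict_matrix(model: NSCModel, values: np.ndarray) -> list[str]:
    """Vectorised prediction over a genes x samples array."""
    denom2 = (model.s + model.s0) ** 2
    scores = np.empty((len(model.classes), values.shape[1]))
    for j in range(len(model.classes)):
        resid2 = (values - model.shrunken_centroids[:, [j]]) ** 2
        scores[j] = (resid2 / denom2[:, None]).sum(axis=0) \
            - 2.0 * np.log(model.priors[j])
    return [model.classes[j] for j in scores.argmin(axis=0)]


def cv_select_delta(x, labels=None, folds: int = 5, delta_grid=None,
                    seed: int = 0, mk: str = "minus"):
    """Stratified k-fold cross-validation over a delta grid.

    Returns ``(delta_star, curve)`` where ``curve`` is a DataFrame with
    columns delta/cv_error/n_genes and delta_star is the *largest* delta
    attaining the minimal CV error (parsimony tie-break).  Fold assignment
    is drawn from ``seed`` and stratified by class.
    """
    values, genes, y = _resolve_xy(x, labels)
    if folds < 2:
        raise ConfigurationError("folds must be >= 2")
    if delta_grid is None:
        delta_grid = np.linspace(0.0, 4.0, 17)
    rng = np.random.default_rng(seed)
    classes = sorted(set(y))
    fold_of = np.empty(len(y), dtype=int)
    for c in classes:
        idx = np.where(y == c)[0]
        if len(idx) < folds:
            raise ConfigurationError(
                f"class {c!r} has {len(idx)} samples < {folds} folds")
        perm = rng.permutation(idx)
        fold_of[perm] = np.arange(len(perm)) % folds

    errors = np.zeros(len(delta_grid))
    for f in range(folds):
        test = fold_of == f
        train_v, test_v = values[:, ~test], values[:, test]
        train_y, test_y = y[~test], y[test]
        for di, delta in enumerate(delta_grid):
            model = fit_nsc(train_v, train_y, delta=delta, mk=mk)
            pred = predict_matrix(model, test_v)
            errors[di] += int(np.sum(np.asarray(pred) != test_y))
    cv_error = errors / len(y)
    n_genes = []
    for delta in delta_grid:
        full = fit_nsc(values, y, delta=delta, mk=mk)
        n_genes.append(int(full.survivors().sum()))
    curve = pd.DataFrame({"delta": delta_grid, "cv_error": cv_error,
                          "n_genes": n_genes})
    best = cv_error.min()
    delta_star = float(np.max(np.asarray(delta_grid)[cv_error == best]))
    return delta_star, curve


def signature_genes(model: NSCModel) -> list[str]:
    """Surviving genes ordered by max |shrunken difference| descending
    (alphabetical within ties)."""
    score = np.max(np.abs(model.dik_shrunk), axis=1)
    keep = [(g, s) for g, s in zip(model.genes, score) if s > 0]
    keep.sort(key=lambda t: (-t[1], t[0]))
    return [g for g, _ in keep]
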