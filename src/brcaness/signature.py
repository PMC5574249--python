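"""Gene-signature derivation by DLDA under leave-one-out cross-validation.

The search mirrors a standard supervised microarray workflow: genes are first
reduced to the most variable ones (sample variance > 1), ranked by a
univariate two-group ANOVA against the copy-number reference label, and
nested gene sets of size 1..100 are evaluated with diagonal linear
discriminant analysis (equal priors) under leave-one-out cross-validation.
Gene ranking is refit inside every fold so the reported AUC validates the
whole selection procedure, not just the final fit. The signature size is the
smallest set attaining the maximum cross-validated AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .matrix import ExpressionMatrix, LabeledCohort, ValidationError

__all__ = [
    "variance_filter",
    "rank_genes_anova",
    "fit_dlda",
    "dlda_posterior",
    "loocv_search",
    "roc_auc",
    "DldaModel",
    "CvSearchResult",
]

VAR_FLOOR_REL = 1e-8  # pooled-variance floor, relative to the median pooled variance


@dataclass
class DldaModel:
    """Diagonal LDA: per-gene class means, shared per-gene pooled variance,
    equal class priors."""

    genes: list
    mean_pos: np.ndarray
    mean_neg: np.ndarray
    pooled_var: np.ndarray
    priors: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if np.any(self.pooled_var <= 0):
            raise ValidationError("pooled variances must be strictly positive")
        if abs(sum(self.priors) - 1.0) > 1e-12:
            raise ValidationError("priors must sum to 1")


@dataclass
class CvSearchResult:
    sizes: np.ndarray
    auc_per_size: np.ndarray
    selected_size: int
    selected_genes: list
    posterior_matrix: np.ndarray | None = None  # samples x sizes LOOCV posteriors


def variance_filter(expr: ExpressionMatrix, min_var: float = 1.0) -> list:
    """Genes whose unbiased sample variance across samples is strictly greater
    than ``min_var``, in input order."""
    if expr.n_samples < 2:
        raise ValidationError("variance filter needs at least 2 samples")
    var = expr.values.var(axis=1, ddof=1)
    return list(expr.gene_ids[var > min_var])


def _anova_order(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Rank order (best first) of gene rows by two-group ANOVA p-value.

    Ties broken by descending |standardized mean difference|, then input
    order. Degenerate genes (zero between- and within-group variance) get
    p = 1; zero within- with nonzero between-group variance gets p = 0.
    """
    pos = y == 1
    neg = ~pos
    n1, n0 = pos.sum(), neg.sum()
    n = n1 + n0
    m1 = x[:, pos].mean(axis=1)
    m0 = x[:, neg].mean(axis=1)
    grand = x.mean(axis=1)
    ssb = n1 * (m1 - grand) ** 2 + n0 * (m0 - grand) ** 2
    ssw = ((x[:, pos] - m1[:, None]) ** 2).sum(axis=1) + (
        (x[:, neg] - m0[:, None]) ** 2
    ).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / 1.0) / (ssw / (n - 2))
    p = np.where(
        ssw > 0,
        stats.f.sf(np.where(ssw > 0, f, 0.0), 1, n - 2),
        np.where(ssb > 0, 0.0, 1.0),
    )
    pooled = ssw / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        smd = np.where(pooled > 0, np.abs(m1 - m0) / np.sqrt(np.where(pooled > 0, pooled, 1.0)), 0.0)
    # lexsort: last key is primary
    return np.lexsort((np.arange(x.shape[0]), -smd, p))


def rank_genes_anova(cohort: LabeledCohort, genes: list) -> list:
    """Genes ordered by ascending two-group one-way ANOVA p-value against the
    reference label (ties: descending |standardized mean difference|, then
    input order)."""
    y = cohort.label.to_numpy()
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValidationError("both classes need at least 2 samples")
    x = cohort.expr.values.loc[genes].to_numpy()
    order = _anova_order(x, y)
    return [genes[i] for i in order]


def _fit_dlda_arrays(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pos = y == 1
    neg = ~pos
    n1, n0 = int(pos.sum()), int(neg.sum())
    if n1 < 2 or n0 < 2:
        raise ValidationError("DLDA needs at least 2 samples per class")
    m1 = x[:, pos].mean(axis=1)
    m0 = x[:, neg].mean(axis=1)
    s1 = x[:, pos].var(axis=1, ddof=1)
    s0 = x[:, neg].var(axis=1, ddof=1)
    pooled = ((n1 - 1) * s1 + (n0 - 1) * s0) / (n1 + n0 - 2)
    med = np.median(pooled)
    floor = VAR_FLOOR_REL * (med if med > 0 else 1.0)
    pooled = np.maximum(pooled, floor)
    return m1, m0, pooled


def fit_dlda(cohort: LabeledCohort, genes: list) -> DldaModel:
    """Fit diagonal LDA with equal priors on the given genes.

    The pooled within-class variance per gene is
    ((n+ - 1) s+^2 + (n- - 1) s-^2) / (n+ + n- - 2), floored at a small
    multiple of the median pooled variance to keep degenerate fixtures
    well-defined.
    """
    x = cohort.expr.values.loc[genes].to_numpy()
    m1, m0, pooled = _fit_dlda_arrays(x, cohort.label.to_numpy())
    return DldaModel(genes=list(genes), mean_pos=m1, mean_neg=m0, pooled_var=pooled)


def dlda_posterior(model: DldaModel, sample: pd.Series | dict) -> tuple[float, float]:
    """Posterior class probabilities (positive, negative) for one sample.

    p_k is proportional to prior_k * exp(-1/2 sum_g (x_g - mean_gk)^2 / var_g),
    evaluated in the log domain and normalized to sum to 1.
    """
    sample = pd.Series(sample)
    missing = [g for g in model.genes if g not in sample.index]
    if missing:
        raise ValidationError(f"sample is missing gene {missing[0]!r}")
    x = sample.loc[model.genes].to_numpy(dtype=float)
    log_pos = np.log(model.priors[0]) - 0.5 * np.sum((x - model.mean_pos) ** 2 / model.pooled_var)
    log_neg = np.log(model.priors[1]) - 0.5 * np.sum((x - model.mean_neg) ** 2 / model.pooled_var)
    m = max(log_pos, log_neg)
    w_pos, w_neg = np.exp(log_pos - m), np.exp(log_neg - m)
    total = w_pos + w_neg
    return float(w_pos / total), float(w_neg / total)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: probability a positive outranks a negative, ties
    counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC needs both classes")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def loocv_search(
    cohort: LabeledCohort,
    max_size: int = 100,
    min_var: float = 1.0,
    rank_once: bool = False,
) -> CvSearchResult:
    """Nested gene-set-size search under leave-one-out cross-validation.

    For each left-out sample, genes are re-ranked by ANOVA on the remaining
    samples (unless ``rank_once``, which ranks on the full cohort — the
    optimistic variant), DLDA is fit on the top-N genes for every N in
    1..max_size, and the left-out sample's posterior probability of the
    positive class is recorded. Per size, the AUC of those held-out
    posteriors against the reference labels is computed; the selected size is
    the smallest one attaining the maximum AUC, and the signature genes are
    the top genes at that size ranked on the full cohort.
    """
    genes = variance_filter(cohort.expr, min_var=min_var)
    if len(genes) == 0:
        raise ValidationError("no genes pass the variance filter")
    if len(genes) < max_size:
        warnings.warn(
            f"only {len(genes)} genes pass the variance filter; capping max_size",
            stacklevel=2,
        )
        max_size = len(genes)
    y = cohort.label.to_numpy()
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValidationError("both classes need at least 2 samples for LOOCV")
    x = cohort.expr.values.loc[genes].to_numpy()
    n = x.shape[1]

    full_order = _anova_order(x, y)
    posteriors = np.empty((n, max_size))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        x_tr, y_tr = x[:, mask], y[mask]
        order = full_order if rank_once else _anova_order(x_tr, y_tr)
        top = order[:max_size]
        m1, m0, pooled = _fit_dlda_arrays(x_tr[top], y_tr)
        xi = x[top, i]
        # per-gene log-likelihood-ratio contributions; equal priors cancel
        contrib = 0.5 * ((xi - m0) ** 2 - (xi - m1) ** 2) / pooled
        llr = np.cumsum(contrib)
        posteriors[i] = special.expit(llr)

    aucs = np.array([roc_auc(posteriors[:, j], y) for j in range(max_size)])
    best = aucs.max()
    selected_size = int(np.flatnonzero(aucs >= best - 1e-12)[0]) + 1
    selected_genes = [genes[i] for i in full_order[:selected_size]]
    return CvSearchResult(
        sizes=np.arange(1, max_size + 1),
        auc_per_size=aucs,
        selected_size=selected_size,
        selected_genes=selected_genes,
        posterior_matrix=posteriors,
    )
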