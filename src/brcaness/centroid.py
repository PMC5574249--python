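"""Nearest-centroid diagnostic over the signature genes.

The portable form of the classifier is a pair of per-class templates
(per-gene medians of the training classes) and a fixed decision threshold.
A new sample is scored by the difference of its Pearson correlations with
the two templates — score = r_pos - r_neg, in [-2, 2] — and called positive
when the score reaches the threshold (default -0.3; equality counts as
positive, the sensitivity-first convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import LabeledCohort, ValidationError

__all__ = [
    "SignatureModel",
    "ClassificationResult",
    "fit_centroids",
    "score_sample",
    "score_matrix",
    "calibrate_threshold",
]

DEFAULT_THRESHOLD = -0.3


@dataclass
class SignatureModel:
    """Per-class median centroids over the signature genes plus the decision
    threshold on the correlation-difference score."""

    genes: list
    centroid_pos: np.ndarray
    centroid_neg: np.ndarray
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        self.centroid_pos = np.asarray(self.centroid_pos, dtype=float)
        self.centroid_neg = np.asarray(self.centroid_neg, dtype=float)
        if len(self.genes) < 2:
            raise ValidationError("a signature needs at least 2 genes")
        if not (np.isfinite(self.centroid_pos).all() and np.isfinite(self.centroid_neg).all()):
            raise ValidationError("centroids must be finite")
        if not (-2.0 < self.threshold < 2.0):
            raise ValidationError("threshold must lie in (-2, 2)")

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "centroid_pos": self.centroid_pos.tolist(),
            "centroid_neg": self.centroid_neg.tolist(),
            "threshold": self.threshold,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureModel":
        for key in ("genes", "centroid_pos", "centroid_neg", "threshold"):
            if key not in d:
                raise ValidationError(f"signature model is missing field {key!r}")
        return cls(
            genes=list(d["genes"]),
            centroid_pos=np.asarray(d["centroid_pos"], dtype=float),
            centroid_neg=np.asarray(d["centroid_neg"], dtype=float),
            threshold=float(d["threshold"]),
        )

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ClassificationResult:
    sample_id: object
    r_pos: float
    r_neg: float
    score: float = field(init=False)
    call: bool = field(init=False)
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        self.score = self.r_pos - self.r_neg
        self.call = self.score >= self.threshold


def fit_centroids(
    cohort: LabeledCohort, genes: list, threshold: float = DEFAULT_THRESHOLD
) -> SignatureModel:
    """Per-gene medians of the positive and negative training classes.

    Even-count medians are the midpoint of the two central values (the
    ordinary sample median).
    """
    missing = [g for g in genes if g not in cohort.expr.gene_ids]
    if missing:
        raise ValidationError(f"gene {missing[0]!r} absent from cohort")
    x = cohort.expr.values.loc[genes]
    pos = cohort.positive_samples
    neg = cohort.negative_samples
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both classes must be non-empty")
    return SignatureModel(
        genes=list(genes),
        centroid_pos=x[pos].median(axis=1).to_numpy(),
        centroid_neg=x[neg].median(axis=1).to_numpy(),
        threshold=threshold,
    )


def _pearson(a: np.ndarray, b: np.ndarray, name: str) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.sqrt(a @ a), np.sqrt(b @ b)
    if na == 0 or nb == 0:
        which = name if na == 0 else "centroid"
        raise ValidationError(f"{which} has zero variance; correlation undefined")
    return float((a @ b) / (na * nb))


def score_sample(model: SignatureModel, sample: pd.Series | dict) -> ClassificationResult:
    """Correlation-difference score and dichotomous call for one sample."""
    sample = pd.Series(sample)
    missing = [g for g in model.genes if g not in sample.index]
    if missing:
        raise ValidationError(f"sample is missing gene {missing[0]!r}")
    x = sample.loc[model.genes].to_numpy(dtype=float)
    sid = getattr(sample, "name", None)
    r_pos = _pearson(x, model.centroid_pos, "sample")
    r_neg = _pearson(x, model.centroid_neg, "sample")
    return ClassificationResult(sample_id=sid, r_pos=r_pos, r_neg=r_neg, threshold=model.threshold)


def score_matrix(model: SignatureModel, expr) -> pd.DataFrame:
    """Score every sample of a genes-x-samples matrix.

    Returns a DataFrame indexed by sample with columns r_pos, r_neg, score,
    call.
    """
    values = expr.values if hasattr(expr, "gene_ids") else expr
    missing = [g for g in model.genes if g not in values.index]
    if missing:
        raise ValidationError(f"expression matrix is missing gene {missing[0]!r}")
    rows = []
    for sid in values.columns:
        res = score_sample(model, values[sid].loc[model.genes])
        rows.append((sid, res.r_pos, res.r_neg, res.score, res.call))
    return pd.DataFrame(
        rows, columns=["sample_id", "r_pos", "r_neg", "score", "call"]
    ).set_index("sample_id")


def calibrate_threshold(
    scores: np.ndarray, labels: np.ndarray, target_specificity: float = 0.75
) -> float:
    """Threshold maximizing sensitivity subject to specificity >= target.

    Candidate cutoffs are the midpoints between adjacent distinct observed
    scores plus sentinels below the minimum and above the maximum; a sample
    is called positive when its score is >= the cutoff. If no cutoff attains
    the target specificity, the one with maximal specificity is returned
    (ties resolved toward higher sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("calibration needs both label classes")
    uniq = np.unique(scores)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    best = None
    for t in candidates:
        call = scores >= t
        sens = (call & (labels == 1)).sum() / n_pos
        spec = (~call & (labels == 0)).sum() / n_neg
        key_feasible = spec >= target_specificity
        cand = (key_feasible, sens if key_feasible else spec, spec if key_feasible else sens, t)
        if best is None:
            best = cand
        else:
            # feasible beats infeasible; then primary criterion, then secondary
            if (cand[0], cand[1], cand[2]) > (best[0], best[1], best[2]):
                best = cand
    return float(best[3])
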