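"""Microarray preprocessing chain for the discovery expression data.

The stages, applied in this fixed order, are:

1. :func:`background_log_transform` — offset-10 background handling and log2,
2. :func:`quantile_normalize` — force a common per-sample distribution,
3. :func:`flag_low_signal` — treat post-normalization intensities < 1 as missing,
4. :func:`knn_impute` — 10-nearest-gene imputation of missing entries,
5. :func:`adjust_batch` — per-gene location/scale matching across biobank batches,
6. :func:`summarize_probes` — first-PC summarization of multi-probe genes.

Each function takes and returns an :class:`~brcaness.matrix.ExpressionMatrix`
and never mutates its input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ValidationError

__all__ = [
    "background_log_transform",
    "quantile_normalize",
    "flag_low_signal",
    "knn_impute",
    "adjust_batch",
    "summarize_probes",
    "preprocess_chain",
]


def background_log_transform(raw: ExpressionMatrix, offset: float = 10.0) -> ExpressionMatrix:
    """log2(max(v, 0) + offset) on background-subtracted linear intensities.

    Over-subtracted (negative) intensities are floored at zero before the
    offset is added, so the output is always finite. NaN entries (missing
    measurements) pass through as missing.
    """
    if offset <= 0:
        raise ValidationError("offset must be positive")
    x = raw.values.to_numpy()
    if np.isinf(x).any():
        raise ValidationError("non-finite (infinite) intensities in input")
    out = np.log2(np.maximum(x, 0.0) + offset)
    return raw.copy_with(pd.DataFrame(out, index=raw.gene_ids, columns=raw.sample_ids))


def _reference_distribution(x: np.ndarray) -> np.ndarray:
    """Row means of per-column sorted values, stretching incomplete columns
    onto the full-length grid by linear interpolation."""
    n_genes, n_samples = x.shape
    grid = np.arange(n_genes, dtype=float)
    stretched = np.empty_like(x)
    for j in range(n_samples):
        col = x[:, j]
        obs = np.sort(col[~np.isnan(col)])
        if obs.size == 0:
            raise ValidationError(f"sample at column {j} is entirely missing")
        if obs.size == n_genes:
            stretched[:, j] = obs
        else:
            stretched[:, j] = np.interp(grid, np.linspace(0, n_genes - 1, obs.size), obs)
    return stretched.mean(axis=1)


def _assign_reference(col: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Replace the observed values of one column by reference values at their
    ranks; tied values receive the mean of the reference values over the tied
    rank span."""
    out = col.copy()
    obs_idx = np.flatnonzero(~np.isnan(col))
    n_obs = obs_idx.size
    n = ref.size
    if n_obs == n:
        ref_sub = ref
    else:
        ref_sub = np.interp(np.linspace(0, n - 1, n_obs), np.arange(n), ref)
    vals = col[obs_idx]
    order = np.argsort(vals, kind="mergesort")
    sorted_vals = vals[order]
    assigned = ref_sub.copy()
    # average the reference over each tied group
    start = 0
    while start < n_obs:
        stop = start + 1
        while stop < n_obs and sorted_vals[stop] == sorted_vals[start]:
            stop += 1
        if stop - start > 1:
            assigned[start:stop] = assigned[start:stop].mean()
        start = stop
    out[obs_idx[order]] = assigned
    return out


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile normalization across samples.

    Missing values are excluded from the per-sample rank computation and stay
    missing; incomplete columns are matched to the reference distribution by
    linear interpolation on the rank grid. After normalization every complete
    column has the identical sorted value vector (the across-sample mean of
    the per-column sorted values).
    """
    if m.n_samples < 2:
        raise ValidationError("quantile normalization needs at least 2 samples")
    x = m.values.to_numpy()
    for j, sid in enumerate(m.sample_ids):
        if np.isnan(x[:, j]).all():
            raise ValidationError(f"sample {sid!r} is entirely missing")
    ref = _reference_distribution(x)
    out = np.column_stack([_assign_reference(x[:, j], ref) for j in range(m.n_samples)])
    return m.copy_with(pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids))


def flag_low_signal(m: ExpressionMatrix, threshold: float = 1.0) -> ExpressionMatrix:
    """Mark entries with intensity strictly below *threshold* as missing.

    The convention is strict '<': a value exactly at the threshold is kept.
    """
    values = m.values.where(~(m.values < threshold))
    return m.copy_with(values)


def knn_impute(m: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Impute missing entries from the k nearest gene rows.

    Distance between gene rows is the Euclidean distance over co-observed
    samples scaled by the number of co-observed positions (root mean squared
    difference), so rows with different missingness patterns are comparable.
    A missing entry (g, s) becomes the mean of the values at sample s over
    the k nearest rows that are observed at s; if no candidate row exists the
    row mean of g is used. Observed entries are never altered.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    x = m.values.to_numpy().copy()
    nan_mask = np.isnan(x)
    if not nan_mask.any():
        return m.copy_with(m.values.copy())
    empty_rows = np.flatnonzero(nan_mask.all(axis=1))
    if empty_rows.size:
        raise ValidationError(
            f"gene {m.gene_ids[empty_rows[0]]!r} has no observed values"
        )

    obs = (~nan_mask).astype(float)
    filled = np.where(nan_mask, 0.0, x)
    sq = filled * filled
    # pairwise sums over co-observed positions via matrix products
    counts = obs @ obs.T
    cross = filled @ filled.T
    s_a = sq @ obs.T  # sum_g a^2 over co-observed with h
    d2 = s_a + s_a.T - 2.0 * cross
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = np.sqrt(np.maximum(d2, 0.0) / counts)
    dist[counts == 0] = np.inf
    np.fill_diagonal(dist, np.inf)

    row_means = np.nansum(x, axis=1) / (~nan_mask).sum(axis=1)
    out = x.copy()
    for g in np.flatnonzero(nan_mask.any(axis=1)):
        d_g = dist[g]
        for s in np.flatnonzero(nan_mask[g]):
            candidates = np.flatnonzero(~nan_mask[:, s] & np.isfinite(d_g))
            if candidates.size == 0:
                out[g, s] = row_means[g]
                continue
            kk = min(k, candidates.size)
            nearest = candidates[np.argsort(d_g[candidates], kind="mergesort")[:kk]]
            out[g, s] = x[nearest, s].mean()
    return m.copy_with(pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids))


def adjust_batch(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene, per-batch location/scale matching to the pooled values.

    For each gene, every batch is centered on the grand mean and rescaled so
    its within-batch standard deviation equals the pooled within-batch
    standard deviation. The grand mean per gene is preserved and applying the
    adjustment twice equals applying it once. Batches of size 1 are rejected
    (their variance is undefined).
    """
    if m.batch is None:
        raise ValidationError("batch labels are required for batch adjustment")
    batches = m.batch.unique()
    if len(batches) < 2:
        return m.copy_with(m.values.copy())
    x = m.values.to_numpy()
    out = x.copy()
    grand_mean = np.nanmean(x, axis=1)

    cols_by_batch = {b: np.flatnonzero((m.batch == b).to_numpy()) for b in batches}
    for b, cols in cols_by_batch.items():
        if cols.size < 2:
            raise ValidationError(f"batch {b!r} has fewer than 2 samples")

    # pooled within-batch variance per gene
    pooled_num = np.zeros(m.n_genes)
    pooled_den = np.zeros(m.n_genes)
    stats = {}
    for b, cols in cols_by_batch.items():
        xb = x[:, cols]
        mb = np.nanmean(xb, axis=1)
        vb = np.nanvar(xb, axis=1, ddof=1)
        nb = (~np.isnan(xb)).sum(axis=1)
        stats[b] = (cols, mb, vb)
        pooled_num += np.where(nb > 1, (nb - 1) * vb, 0.0)
        pooled_den += np.maximum(nb - 1, 0)
    pooled_sd = np.sqrt(pooled_num / np.maximum(pooled_den, 1))

    for b, (cols, mb, vb) in stats.items():
        sb = np.sqrt(vb)
        scale = np.where(sb > 0, pooled_sd / np.where(sb > 0, sb, 1.0), 0.0)
        out[:, cols] = (x[:, cols] - mb[:, None]) * scale[:, None] + grand_mean[:, None]
    return m.copy_with(pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids))


def summarize_probes(
    m: ExpressionMatrix, probe_map: dict | pd.Series, min_corr: float = 0.5
) -> ExpressionMatrix:
    """Collapse probe-level rows to gene level.

    Single-probe genes pass through unchanged. For multi-probe genes, probes
    whose Pearson correlation with the per-sample mean probe profile is
    >= ``min_corr`` are retained (if none qualify, the single probe most
    correlated with the mean profile is kept), and the gene value is the
    first principal-component score of the retained probes across samples,
    rescaled to the mean per-probe standard deviation, sign-aligned with the
    mean probe profile, and re-centered on the mean probe location.
    """
    probe_map = pd.Series(probe_map)
    missing = m.gene_ids.difference(probe_map.index)
    if len(missing):
        raise ValidationError(f"probe {missing[0]!r} absent from probe map")
    x = m.values
    if x.isna().to_numpy().any():
        raise ValidationError("probe summarization requires a complete (imputed) matrix")

    genes: list = []
    rows: list[np.ndarray] = []
    for gene, probes in probe_map.loc[m.gene_ids].groupby(probe_map.loc[m.gene_ids]).groups.items():
        sub = x.loc[probes].to_numpy()
        if sub.shape[0] == 1:
            genes.append(gene)
            rows.append(sub[0])
            continue
        mean_profile = sub.mean(axis=0)
        corrs = np.array([_pearson(row, mean_profile) for row in sub])
        keep = np.flatnonzero(corrs >= min_corr)
        if keep.size == 0:
            keep = np.array([int(np.argmax(corrs))])
        sel = sub[keep]
        if sel.shape[0] == 1:
            genes.append(gene)
            rows.append(sel[0])
            continue
        centered = sel - sel.mean(axis=1, keepdims=True)
        # first right singular vector = PC scores across samples
        _, svals, vt = np.linalg.svd(centered, full_matrices=False)
        score = vt[0] * svals[0] / np.sqrt(max(sel.shape[0] - 1, 1))
        sd_target = sel.std(axis=1, ddof=1).mean()
        ssd = score.std(ddof=1)
        if ssd > 0:
            score = score / ssd * sd_target
        if _pearson(score, mean_profile) < 0:
            score = -score
        genes.append(gene)
        rows.append(score + sel.mean())
    values = pd.DataFrame(np.vstack(rows), index=pd.Index(genes, name="gene"), columns=m.sample_ids)
    return m.copy_with(values)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float((a @ b) / denom)


def preprocess_chain(
    raw: ExpressionMatrix,
    probe_map: pd.Series | dict | None = None,
    offset: float = 10.0,
    low_signal_threshold: float = 1.0,
    k: int = 10,
    min_corr: float = 0.5,
) -> ExpressionMatrix:
    """Run the full preprocessing pipeline in the canonical order."""
    m = background_log_transform(raw, offset=offset)
    m = quantile_normalize(m)
    m = flag_low_signal(m, threshold=low_signal_threshold)
    m = knn_impute(m, k=k)
    if m.batch is not None and m.batch.nunique() > 1:
        m = adjust_batch(m)
    if probe_map is not None:
        m = summarize_probes(m, probe_map, min_corr=min_corr)
    return m
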