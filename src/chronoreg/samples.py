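"""Sample-level transcriptome comparisons: distance matrices and 1-D embeddings.

Distances between samples of two genotypes are mean squared differences in
expression across orthologue pairs, optionally after genewise scaling.
:func:`registered_distance` additionally maps each registered gene's query
profile onto the reference time axis through its own optimal transformation
before comparing, which is what exposes shared developmental progression
between desynchronised transcriptomes.

:func:`embed_1d` projects samples to one dimension with t-SNE on Euclidean
distances of scaled expression — a compact readout of developmental
progression per sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expression import ExpressionSet, OrthologuePairSet, scale_genewise
from .registration import impute_linear, transform_times

__all__ = ["cross_distance", "registered_distance", "embed_1d"]


def _usable_pairs(expr_a, expr_b, pairs, scaled):
    mask = pairs.pairs["gene_a"].isin(expr_a.genes) & pairs.pairs["gene_b"].isin(expr_b.genes)
    sub = pairs.pairs[mask]
    if scaled:
        drop = sub["gene_a"].isin(expr_a.zero_variance_genes) | \
            sub["gene_b"].isin(expr_b.zero_variance_genes)
        sub = sub[~drop]
    if len(sub) == 0:
        raise ValueError("no usable orthologue pairs (missing or zero-variance genes)")
    return sub


def cross_distance(expr_a: ExpressionSet, expr_b: ExpressionSet,
                   pairs: OrthologuePairSet, scaled: bool = True) -> pd.DataFrame:
    """Mean squared expression difference between every A sample and every B
    sample over orthologue pairs.

    With ``scaled=True`` genewise scaling is applied within each genotype
    first (zero-variance genes are excluded). Entry (i, j) is
    ``mean_g (xA[g, i] - xB[g, j])^2``.
    """
    if scaled:
        expr_a = expr_a if expr_a.units == "scaled" else scale_genewise(expr_a)
        expr_b = expr_b if expr_b.units == "scaled" else scale_genewise(expr_b)
    sub = _usable_pairs(expr_a, expr_b, pairs, scaled)
    xa = expr_a.values.loc[sub["gene_a"]].to_numpy(dtype=float)
    xb = expr_b.values.loc[sub["gene_b"]].to_numpy(dtype=float)
    g = xa.shape[0]
    # (a - b)^2 expanded: avoids materialising genes x nA x nB
    d = (
        (xa ** 2).sum(axis=0)[:, None] + (xb ** 2).sum(axis=0)[None, :]
        - 2.0 * xa.T @ xb
    ) / g
    return pd.DataFrame(np.maximum(d, 0.0), index=expr_a.values.columns,
                        columns=expr_b.values.columns)


def registered_distance(expr_a: ExpressionSet, expr_b: ExpressionSet,
                        registrations, comparisons) -> pd.DataFrame:
    """Cross distance on scaled values after per-gene registration.

    Genes with verdict ``separate`` are excluded. Each remaining gene's
    scaled query (A) replicate-mean profile is mapped onto the reference time
    axis via its own optimal (stretch, shift) and linearly imputed at the
    reference timepoints inside its overlap window. Rows are reference
    timepoints (registered A pseudo-samples), columns are B samples; each
    entry averages over the genes whose overlap covers that timepoint.
    """
    verdicts = {(c.gene_a, c.gene_b): c.verdict for c in comparisons}
    keep = [r for r in registrations
            if r.flag == "ok" and verdicts.get((r.gene_a, r.gene_b)) == "registered"]
    if not keep:
        raise ValueError("no registered genes to compare")
    sa = expr_a if expr_a.units == "scaled" else scale_genewise(expr_a)
    sb = expr_b if expr_b.units == "scaled" else scale_genewise(expr_b)
    ref_tp = sb.timepoints
    means_a = sa.replicate_means()
    days_a = means_a.columns.to_numpy(dtype=float)

    imputed = np.full((len(keep), ref_tp.size), np.nan)
    b_rows = np.empty((len(keep), sb.values.shape[1]))
    for i, r in enumerate(keep):
        lo, hi = r.overlap
        ta = transform_times(days_a, r.stretch, r.shift)
        inside = (ref_tp >= lo - 1e-9) & (ref_tp <= hi + 1e-9)
        imputed[i, inside] = impute_linear(ta, means_a.loc[r.gene_a].to_numpy(dtype=float),
                                           ref_tp[inside])
        b_rows[i] = sb.values.loc[r.gene_b].to_numpy(dtype=float)

    d = np.full((ref_tp.size, sb.values.shape[1]), np.nan)
    for t in range(ref_tp.size):
        col = imputed[:, t]
        ok = ~np.isnan(col)
        if ok.any():
            d[t] = np.mean((col[ok, None] - b_rows[ok]) ** 2, axis=0)
    return pd.DataFrame(d, index=[f"registered_day{t:g}" for t in ref_tp],
                        columns=sb.values.columns)


def embed_1d(expr, perplexity: float = 20.0, max_iter: int = 16000,
             seed: int = 0) -> pd.Series:
    """1-D t-SNE embedding of samples on Euclidean distances of scaled
    expression.

    Deterministic under a fixed seed. The sign of the axis is arbitrary; the
    convention here is that the earliest sample gets the smaller coordinate.
    """
    from sklearn.manifold import TSNE

    if isinstance(expr, ExpressionSet):
        scaled = expr if expr.units == "scaled" else scale_genewise(expr)
        x = scaled.values.T.to_numpy(dtype=float)
        index = scaled.values.columns
        days = scaled.days
    else:
        x = np.asarray(expr, dtype=float)
        index = pd.RangeIndex(x.shape[0])
        days = None
    n = x.shape[0]
    if perplexity >= n:
        raise ValueError(f"perplexity ({perplexity}) must be < n_samples ({n})")
    tsne = TSNE(n_components=1, perplexity=perplexity, max_iter=max_iter,
                random_state=seed, init="pca", method="exact")
    coords = tsne.fit_transform(x)[:, 0]
    if days is not None and len(days):
        first = int(np.argmin(days))
        if coords[first] > np.median(coords):
            coords = -coords
    return pd.Series(coords, index=index, name="embedding_1d")
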