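"""Assortative mixing of registration parameters on a gene interaction network.

Tests whether genes that are directly linked in a cofunctional interaction
network share similar registration (desynchronisation) parameters. Following
Newman's scalar assortativity, the coefficient is the Pearson correlation of
the shift (translation) parameter across the endpoints of edges whose two
endpoints have the same stretch category, computed on the symmetrised
endpoint list (each edge contributes both orientations). Significance is
assessed by jointly reallocating (stretch, shift) pairs to genes at random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GeneNetwork", "AssortativityResult", "assortativity",
           "assortativity_permutation"]


@dataclass
class GeneNetwork:
    """Undirected edge list over gene ids; no self-loops, no duplicates."""

    edges: pd.DataFrame  # columns gene_a, gene_b

    def __post_init__(self) -> None:
        e = self.edges[["gene_a", "gene_b"]].reset_index(drop=True)
        if (e["gene_a"] == e["gene_b"]).any():
            raise ValueError("self-loops are not allowed")
        key = e.apply(lambda r: tuple(sorted((r["gene_a"], r["gene_b"]))), axis=1)
        if key.duplicated().any():
            raise ValueError("duplicate edges are not allowed")
        self.edges = e

    @classmethod
    def from_edges(cls, edge_iter) -> "GeneNetwork":
        return cls(pd.DataFrame(list(edge_iter), columns=["gene_a", "gene_b"]))

    @classmethod
    def from_tsv(cls, path) -> "GeneNetwork":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


@dataclass
class AssortativityResult:
    coefficient: float
    n_edges_used: int
    defined: bool
    p: float | None = None
    n_permutations: int = 0
    n_undefined_permutations: int = 0


def _symmetrised_pearson(shift_u: np.ndarray, shift_v: np.ndarray) -> float:
    """Pearson correlation over the symmetrised endpoint list: each edge
    contributes (s_u, s_v) and (s_v, s_u). NaN when undefined."""
    k = shift_u.size
    if k < 2:
        return np.nan
    n2 = 2.0 * k
    sx = np.sum(shift_u + shift_v)
    sxx = np.sum(shift_u ** 2 + shift_v ** 2)
    sxy = 2.0 * np.sum(shift_u * shift_v)
    mean = sx / n2
    den = sxx / n2 - mean ** 2
    if den <= 0:
        return np.nan
    return float((sxy / n2 - mean ** 2) / den)


def _edge_arrays(network: GeneNetwork, params: dict):
    """Index edges into the parameter table; returns (genes, stretch array,
    shift array, edge index u, edge index v) over edges with both endpoints
    parameterised."""
    genes = list(params.keys())
    pos = {g: i for i, g in enumerate(genes)}
    stretch = np.array([params[g][0] for g in genes], dtype=float)
    shift = np.array([params[g][1] for g in genes], dtype=float)
    mask = network.edges["gene_a"].isin(pos) & network.edges["gene_b"].isin(pos)
    sub = network.edges[mask]
    u = sub["gene_a"].map(pos).to_numpy(dtype=int)
    v = sub["gene_b"].map(pos).to_numpy(dtype=int)
    return genes, stretch, shift, u, v


def assortativity(network: GeneNetwork, params: dict) -> AssortativityResult:
    """Assortativity of the shift parameter among same-stretch linked genes.

    ``params`` maps gene id -> (stretch, shift); only genes present in it
    enter the computation (callers typically restrict to genes with a
    "registered" verdict). Edges whose endpoints differ in stretch are
    discarded. Flagged undefined when fewer than 2 qualifying edges remain
    or the shifts on the edge list have zero variance.
    """
    _, stretch, shift, u, v = _edge_arrays(network, params)
    same = stretch[u] == stretch[v]
    su, sv = shift[u[same]], shift[v[same]]
    coeff = _symmetrised_pearson(su, sv)
    return AssortativityResult(coefficient=float(coeff), n_edges_used=int(same.sum()),
                               defined=bool(np.isfinite(coeff)))


def assortativity_permutation(network: GeneNetwork, params: dict,
                              n_permutations: int = 100_000, seed: int = 0,
                              chunk: int = 2000) -> AssortativityResult:
    """Permutation test: (stretch, shift) pairs are jointly reallocated to
    genes and the coefficient recomputed ``n_permutations`` times.

    One-sided empirical p = (r + 1) / (N + 1) with r the number of defined
    permutations whose coefficient is at least the observed one; permutations
    with an undefined coefficient are excluded from N and recorded.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    observed = assortativity(network, params)
    if not observed.defined:
        raise ValueError("assortativity undefined on the observed data")
    genes, stretch, shift, u, v = _edge_arrays(network, params)
    rng = np.random.default_rng(seed)
    n_genes = len(genes)

    r = 0
    n_defined = 0
    n_undef = 0
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        perms = rng.permuted(np.tile(np.arange(n_genes), (m, 1)), axis=1)
        st = stretch[perms]
        sh = shift[perms]
        su, sv = st[:, u], st[:, v]
        eq = su == sv
        hu, hv = sh[:, u], sh[:, v]
        k = eq.sum(axis=1)
        n2 = 2.0 * k
        sx = ((hu + hv) * eq).sum(axis=1)
        sxx = ((hu ** 2 + hv ** 2) * eq).sum(axis=1)
        sxy = (2.0 * hu * hv * eq).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = sx / n2
            den = sxx / n2 - mean ** 2
            coeff = (sxy / n2 - mean ** 2) / den
        ok = (k >= 2) & np.isfinite(coeff) & (den > 0)
        n_defined += int(ok.sum())
        n_undef += int(m - ok.sum())
        r += int(np.sum(coeff[ok] >= observed.coefficient))
        done += m

    p = (r + 1) / (n_defined + 1)
    return AssortativityResult(coefficient=observed.coefficient,
                               n_edges_used=observed.n_edges_used, defined=True,
                               p=float(p), n_permutations=n_defined,
                               n_undefined_permutations=n_undef)
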