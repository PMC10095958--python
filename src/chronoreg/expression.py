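"""Expression data containers, I/O and preprocessing.

The central container is :class:`ExpressionSet`: a genes x samples matrix for
one genotype/tissue time course, with per-sample metadata (genotype, tissue,
day, replicate) and a units tag distinguishing raw counts, TMM-normalised
counts (TMMC) and genewise-scaled expression.

Preprocessing operations mirror a standard comparative time-course workflow:

* :func:`tmm_normalise` — trimmed mean of M-values library normalisation,
* :func:`scale_genewise` — per-gene centring/scaling over the time course,
* :func:`variance_explained_by_time` — one-way ANOVA R-squared by timepoint,
* :func:`filter_comparable_genes` — keep orthologue pairs reproducibly
  variable over time in both genotypes,
* :func:`aggregate_paralogues` — sum duplicated copies into one series.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ExpressionSet",
    "OrthologuePairSet",
    "read_expression",
    "tmm_normalise",
    "scale_genewise",
    "variance_explained_by_time",
    "filter_comparable_genes",
    "aggregate_paralogues",
]

_SAMPLE_RE = re.compile(r"^(?P<genotype>[^_]+)_(?P<tissue>[^_]+)_day(?P<day>\d+(?:\.\d+)?)_rep(?P<rep>\d+)$")

VALID_UNITS = ("counts", "TMMC", "scaled")


@dataclass
class ExpressionSet:
    """Genes x samples expression matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample.
    samples
        DataFrame indexed like ``values.columns`` with columns
        ``genotype``, ``tissue``, ``day`` (float, days since germination)
        and ``replicate`` (int).
    units
        One of ``"counts"``, ``"TMMC"`` or ``"scaled"``.
    zero_variance_genes
        Genes flagged during scaling because their series was constant;
        their scaled values are 0 and they are excluded from distances
        and registration.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    units: str = "counts"
    zero_variance_genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.units not in VALID_UNITS:
            raise ValueError(f"units must be one of {VALID_UNITS}, got {self.units!r}")
        self.values = self.values.rename_axis(index=None, columns=None)
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample metadata rows must correspond 1:1 with value columns")
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("expression values must be finite")
        if self.units in ("counts", "TMMC") and (vals < 0).any():
            raise ValueError(f"negative values not allowed for units={self.units!r}")

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def days(self) -> np.ndarray:
        """Day of each sample (aligned with columns)."""
        return self.samples["day"].to_numpy(dtype=float)

    @property
    def timepoints(self) -> np.ndarray:
        """Sorted unique sampling days."""
        return np.unique(self.days)

    def gene_series(self, gene: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (observation days, values) for one gene, day-sorted."""
        v = self.values.loc[gene].to_numpy(dtype=float)
        t = self.days
        order = np.argsort(t, kind="stable")
        return t[order], v[order]

    def replicate_means(self) -> pd.DataFrame:
        """Genes x timepoints matrix of replicate means."""
        groups = self.values.T.groupby(self.samples["day"].values)
        return groups.mean().T

    def subset_genes(self, genes) -> "ExpressionSet":
        return ExpressionSet(
            self.values.loc[list(genes)], self.samples, self.units,
            self.zero_variance_genes & set(genes),
        )

    # -- I/O -------------------------------------------------------------------

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, units: str = "counts", genotypes=None) -> "ExpressionSet":
        return read_expression(path, units=units, genotypes=genotypes)


def _parse_sample_names(columns, genotypes=None) -> pd.DataFrame:
    rows = []
    for col in columns:
        m = _SAMPLE_RE.match(str(col))
        if m is None:
            raise ValueError(
                f"sample column {col!r} does not match 'genotype_tissue_dayD_repR'"
            )
        if genotypes is not None and m["genotype"] not in set(genotypes):
            raise ValueError(f"sample column {col!r} has unknown genotype label {m['genotype']!r}")
        rows.append((col, m["genotype"], m["tissue"], float(m["day"]), int(m["rep"])))
    meta = pd.DataFrame(rows, columns=["sample", "genotype", "tissue", "day", "replicate"])
    return meta.set_index("sample")


def read_expression(path, units: str = "counts", genotypes=None) -> ExpressionSet:
    """Read a genes x samples TSV/CSV into an :class:`ExpressionSet`.

    The first column holds gene ids; sample columns are named
    ``genotype_tissue_dayD_repR`` (e.g. ``Col0_apex_day7_rep1``). Pass
    ``genotypes`` to restrict accepted genotype labels.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep, index_col=0)
    table.index.name = None
    meta = _parse_sample_names(table.columns, genotypes=genotypes)
    return ExpressionSet(table.astype(float), meta, units=units)


@dataclass
class OrthologuePairSet:
    """Orthologue mapping between two genotypes, supporting 1-to-many relations.

    ``pairs`` is a DataFrame with columns ``gene_a`` and ``gene_b``; the same
    gene may appear on either side more than once (paralogy). Optional
    ``paralogue_groups`` maps a group id to the B-side copies it aggregates.
    """

    pairs: pd.DataFrame
    paralogue_groups: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pairs = self.pairs[["gene_a", "gene_b"]].reset_index(drop=True)
        if self.pairs.duplicated().any():
            raise ValueError("duplicate (gene_a, gene_b) pairs")

    def __len__(self) -> int:
        return len(self.pairs)

    def subset(self, mask) -> "OrthologuePairSet":
        return OrthologuePairSet(self.pairs[mask].reset_index(drop=True), self.paralogue_groups)

    def to_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "OrthologuePairSet":
        return cls(pd.read_csv(path, sep="\t"))


# -----------------------------------------------------------------------------
# TMM normalisation
# -----------------------------------------------------------------------------

def _tmm_factor_vs_reference(obs, ref, lib_obs, lib_ref, trim_m, trim_a):
    """Weighted trimmed mean of log2 ratios of one library against a reference.

    Genes with a zero count in either library are excluded; the top/bottom
    ``trim_m`` fraction by M-value and ``trim_a`` fraction by A-value are
    trimmed; remaining M-values are averaged with inverse-variance
    (delta-method binomial) weights.
    """
    keep = (obs > 0) & (ref > 0)
    o = obs[keep] / lib_obs
    r = ref[keep] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # delta-method (binomial) variance of M; genes are weighted by 1/v
    v = (lib_obs - obs[keep]) / (lib_obs * obs[keep]) + (lib_ref - ref[keep]) / (lib_ref * ref[keep])
    n = m.size
    if n == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not sel.any() or not np.isfinite(v[sel]).all():
        return 1.0
    f = np.mean(m[sel] / v[sel]) / np.mean(1.0 / v[sel])
    return float(2.0 ** f) if np.isfinite(f) else 1.0


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05,
                reference="auto") -> pd.Series:
    """Per-sample TMM scaling factors, geometric mean 1.

    ``reference="auto"`` selects the sample whose upper-quartile count
    (relative to library size) is closest to the mean upper quartile.
    """
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"samples with all-zero counts: {bad}")
    if reference == "auto":
        f75 = np.array([np.quantile(mat[:, j], 0.75) / lib[j] for j in range(mat.shape[1])])
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.columns.get_loc(reference)
    ref = mat[:, ref_idx]
    factors = np.array([
        _tmm_factor_vs_reference(mat[:, j], ref, lib[j], lib[ref_idx], trim_m, trim_a)
        for j in range(mat.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def tmm_normalise(expr: ExpressionSet, trim_m: float = 0.30, trim_a: float = 0.05,
                  reference="auto") -> ExpressionSet:
    """TMM-normalise a counts ExpressionSet to TMMC units.

    Each count is divided by (library size x TMM factor) and scaled to a
    counts-per-million-like magnitude on the effective library size.
    """
    if expr.units != "counts":
        raise ValueError(f"tmm_normalise requires units='counts', got {expr.units!r}")
    factors = tmm_factors(expr.values, trim_m=trim_m, trim_a=trim_a, reference=reference)
    lib = expr.values.sum(axis=0)
    normalised = expr.values / (lib * factors) * 1e6
    return ExpressionSet(normalised, expr.samples, units="TMMC")


# -----------------------------------------------------------------------------
# Scaling, variance filtering, paralogues
# -----------------------------------------------------------------------------

def scale_genewise(expr: ExpressionSet) -> ExpressionSet:
    """Centre and scale each gene over the time course: (x - mean) / sd.

    Uses the sample (n-1) standard deviation. Genes with zero variance are
    flagged in ``zero_variance_genes`` and their scaled values set to 0.
    """
    vals = expr.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    scaled = (vals - mean) / sd
    scaled[flat] = 0.0
    flagged = frozenset(expr.genes[flat]) | expr.zero_variance_genes
    return ExpressionSet(
        pd.DataFrame(scaled, index=expr.genes, columns=expr.values.columns),
        expr.samples, units="scaled", zero_variance_genes=flagged,
    )


def variance_explained_by_time(days: np.ndarray, values: np.ndarray) -> float:
    """One-way ANOVA R-squared of a gene series grouped by timepoint.

    Returns ``1 - SS_within / SS_total``, the fraction of expression variance
    explained by time relative to replicate variation. NaN when the series is
    constant (SS_total = 0).
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    uniq = np.unique(days)
    if uniq.size < 2:
        raise ValueError("variance_explained_by_time requires >= 2 timepoints")
    ss_total = np.sum((values - values.mean()) ** 2)
    if ss_total == 0:
        return float("nan")
    ss_within = 0.0
    for t in uniq:
        group = values[days == t]
        ss_within += np.sum((group - group.mean()) ** 2)
    return float(1.0 - ss_within / ss_total)


def variance_explained_table(expr: ExpressionSet) -> pd.Series:
    """Variance explained by time for every gene in an ExpressionSet."""
    days = expr.days
    vals = expr.values.to_numpy(dtype=float)
    uniq = np.unique(days)
    if uniq.size < 2:
        raise ValueError("need >= 2 timepoints")
    mean = vals.mean(axis=1, keepdims=True)
    ss_total = np.sum((vals - mean) ** 2, axis=1)
    ss_within = np.zeros_like(ss_total)
    for t in uniq:
        cols = days == t
        grp = vals[:, cols]
        ss_within += np.sum((grp - grp.mean(axis=1, keepdims=True)) ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_total > 0, 1.0 - ss_within / ss_total, np.nan)
    return pd.Series(r2, index=expr.genes, name="variance_explained")


def filter_comparable_genes(expr_a: ExpressionSet, expr_b: ExpressionSet,
                            pairs: OrthologuePairSet, threshold: float = 0.7) -> OrthologuePairSet:
    """Retain orthologue pairs whose variance explained by time is at least
    ``threshold`` in both genotypes. Genes with undefined R-squared (constant
    series) never pass."""
    r2_a = variance_explained_table(expr_a)
    r2_b = variance_explained_table(expr_b)
    ga = pairs.pairs["gene_a"].map(r2_a)
    gb = pairs.pairs["gene_b"].map(r2_b)
    mask = (ga >= threshold) & (gb >= threshold)
    kept = pairs.subset(mask.to_numpy())
    if len(kept) == 0:
        import warnings
        warnings.warn("no orthologue pairs pass the variance-explained filter", stacklevel=2)
    return kept


def aggregate_paralogues(expr: ExpressionSet, groups: dict) -> ExpressionSet:
    """Sum paralogue copies into one series per group.

    ``groups`` maps group id -> list of member genes; members are removed and
    replaced by a single summed series named by the group id. Groups must not
    overlap, and members must exist.
    """
    seen: set = set()
    for gid, members in groups.items():
        member_set = set(members)
        if member_set & seen:
            raise ValueError(f"paralogue group {gid!r} overlaps another group")
        missing = member_set - set(expr.genes)
        if missing:
            raise ValueError(f"paralogue group {gid!r} references unknown genes {sorted(missing)}")
        seen |= member_set
    summed = {gid: expr.values.loc[list(members)].sum(axis=0) for gid, members in groups.items()}
    rest = expr.values.drop(index=[g for ms in groups.values() for g in ms])
    out = pd.concat([rest, pd.DataFrame(summed).T])
    return ExpressionSet(out, expr.samples, units=expr.units)
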