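"""Stretch-and-translate registration of expression time courses.

For each orthologue pair, the query genotype's time axis is transformed by
``t' = stretch * t + shift`` over a discrete grid of candidates (stretches
1x / 1.5x / 2x, shifts -4..+4 days by default). For every candidate the two
profiles are centred and scaled using the mean and standard deviation over
the overlapping registered timepoints, the query profile is linearly imputed
at the reference's observed timepoints inside the overlap, and the candidate
is scored by the mean squared difference between the reference replicate
means and the imputed query values. The best candidate minimises this score.

The model family is strictly stretch-and-translate: no subsection warping
and no continuous optimisation, which keeps the search exhaustive and the
fit hard to overfit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionSet, OrthologuePairSet

__all__ = [
    "RegistrationGrid",
    "RegistrationResult",
    "transform_times",
    "impute_linear",
    "score_candidate",
    "register_pair",
    "register_cohort",
]

_EPS = 1e-9


@dataclass(frozen=True)
class RegistrationGrid:
    """Discrete search grid of stretch factors and shifts (days)."""

    stretches: tuple = (1.0, 1.5, 2.0)
    shift_min: float = -4.0
    shift_max: float = 4.0
    shift_step: float = 1.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.stretches) or not self.stretches:
            raise ValueError("stretches must be positive and non-empty")
        if self.shift_min > self.shift_max:
            raise ValueError("shift_min must be <= shift_max")
        if self.shift_step <= 0:
            raise ValueError("shift_step must be > 0")

    @property
    def shifts(self) -> np.ndarray:
        n = int(np.floor((self.shift_max - self.shift_min) / self.shift_step + _EPS))
        return self.shift_min + self.shift_step * np.arange(n + 1)

    def candidates(self):
        """All (stretch, shift) pairs, in grid order."""
        return list(itertools.product(self.stretches, self.shifts.tolist()))


@dataclass
class RegistrationResult:
    """Optimal registration of one gene pair.

    ``score`` is the mean squared scaled-expression difference over the
    ``n_overlap`` reference timepoints inside the overlap window (on the
    reference time axis). ``flag`` is ``"ok"`` or ``"unregistrable"`` when
    every grid candidate was rejected."""

    gene_a: str
    gene_b: str
    stretch: float = np.nan
    shift: float = np.nan
    overlap: tuple = (np.nan, np.nan)
    overlap_timepoints: np.ndarray = field(default_factory=lambda: np.array([]))
    score: float = np.nan
    n_overlap: int = 0
    flag: str = "ok"


def transform_times(times, stretch: float, shift: float) -> np.ndarray:
    """Map query times onto the reference axis: ``t' = stretch * t + shift``."""
    return stretch * np.asarray(times, dtype=float) + shift


def impute_linear(times, values, at) -> np.ndarray:
    """Piecewise-linear interpolation through (time, mean value) points.

    Raises on any query outside the observed range — the overlap logic is
    responsible for never extrapolating.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    at = np.asarray(at, dtype=float)
    if at.size and (at.min() < times.min() - _EPS or at.max() > times.max() + _EPS):
        raise ValueError("imputation request outside the observed time range")
    return np.interp(at, times, values)


class _GeneSeries:
    """Replicate-level series of one gene with cached per-timepoint means."""

    __slots__ = ("obs_times", "obs_values", "unique_times", "means")

    def __init__(self, obs_times, obs_values):
        t = np.asarray(obs_times, dtype=float)
        v = np.asarray(obs_values, dtype=float)
        order = np.argsort(t, kind="stable")
        self.obs_times = t[order]
        self.obs_values = v[order]
        self.unique_times, inverse = np.unique(self.obs_times, return_inverse=True)
        sums = np.bincount(inverse, weights=self.obs_values)
        counts = np.bincount(inverse)
        self.means = sums / counts

    @classmethod
    def from_expression(cls, expr: ExpressionSet, gene: str) -> "_GeneSeries":
        return cls(expr.days, expr.values.loc[gene].to_numpy(dtype=float))


def _overlap_scaling(series_a: _GeneSeries, series_b: _GeneSeries, stretch: float,
                     shift: float, min_overlap: int, scale_level: str):
    """Overlap window, imputed query profile and per-genotype scaling stats.

    Both genotypes are centred and scaled on the *same* overlapping
    registered timepoints (the reference's observed days inside the overlap
    window, with the query linearly imputed there), so that under a perfect
    registration the two scaled profiles coincide up to interpolation error.
    Returns None when the candidate is rejected.
    """
    ta_obs = transform_times(series_a.obs_times, stretch, shift)
    lo = max(ta_obs[0], series_b.unique_times[0])
    hi = min(ta_obs[-1], series_b.unique_times[-1])
    if hi - lo < -_EPS:
        return None
    b_tp = series_b.unique_times
    b_in = (b_tp >= lo - _EPS) & (b_tp <= hi + _EPS)
    overlap_tp = b_tp[b_in]
    if overlap_tp.size < min_overlap:
        return None
    a_tp = transform_times(series_a.unique_times, stretch, shift)
    a_imp = impute_linear(a_tp, series_a.means, overlap_tp)
    a_mean, a_sd = a_imp.mean(), a_imp.std()
    if scale_level == "replicate":
        b_obs_in = (series_b.obs_times >= lo - _EPS) & (series_b.obs_times <= hi + _EPS)
        b_vals = series_b.obs_values[b_obs_in]
    else:
        b_vals = series_b.means[b_in]
    b_mean, b_sd = b_vals.mean(), b_vals.std()
    if a_sd <= _EPS or b_sd <= _EPS:
        return None
    return (float(lo), float(hi)), overlap_tp, b_in, a_imp, (a_mean, a_sd), (b_mean, b_sd)


def score_candidate(series_a: _GeneSeries, series_b: _GeneSeries, stretch: float,
                    shift: float, min_overlap: int = 4, scale_level: str = "replicate"):
    """Score one (stretch, shift) candidate for a gene pair.

    The score is the mean squared difference between the reference's scaled
    replicate means and the scaled imputed query values over the overlapping
    reference timepoints. Returns ``(score, (lo, hi), overlap_timepoints)``
    or ``None`` when the candidate is rejected (too few overlapping
    reference timepoints, or zero variance on the overlap for either
    genotype).
    """
    out = _overlap_scaling(series_a, series_b, stretch, shift, min_overlap, scale_level)
    if out is None:
        return None
    window, overlap_tp, b_in, a_imp, (a_mean, a_sd), (b_mean, b_sd) = out
    a_scaled = (a_imp - a_mean) / a_sd
    b_scaled = (series_b.means[b_in] - b_mean) / b_sd
    score = float(np.mean((b_scaled - a_scaled) ** 2))
    return score, window, overlap_tp


def registered_observations(series_a: _GeneSeries, series_b: _GeneSeries,
                            stretch: float, shift: float, lo: float, hi: float,
                            min_overlap: int = 1, scale_level: str = "replicate"):
    """Replicate-level scaled observations of both genotypes on the common
    registered time axis, restricted to the overlap window.

    Scaling statistics are those of the candidate's overlap (see
    :func:`score_candidate`). Returns ``(times_a, values_a, times_b,
    values_b)`` — inputs to the shared-vs-separate spline model comparison.
    """
    out = _overlap_scaling(series_a, series_b, stretch, shift, min_overlap, scale_level)
    if out is None:
        raise ValueError("candidate rejected on this overlap window")
    _, _, _, _, (a_mean, a_sd), (b_mean, b_sd) = out
    ta_obs = transform_times(series_a.obs_times, stretch, shift)
    a_mask = (ta_obs >= lo - _EPS) & (ta_obs <= hi + _EPS)
    b_mask = (series_b.obs_times >= lo - _EPS) & (series_b.obs_times <= hi + _EPS)
    a_scaled = (series_a.obs_values[a_mask] - a_mean) / a_sd
    b_scaled = (series_b.obs_values[b_mask] - b_mean) / b_sd
    return ta_obs[a_mask], a_scaled, series_b.obs_times[b_mask], b_scaled


def register_pair(series_a, series_b, grid: RegistrationGrid = RegistrationGrid(),
                  min_overlap: int = 4, scale_level: str = "replicate",
                  gene_a: str = "gene_a", gene_b: str = "gene_b") -> RegistrationResult:
    """Exhaustively search the grid and return the minimising registration.

    Ties are broken towards stretch closest to 1, then smallest ``|shift|``,
    then the smaller shift. If every candidate is rejected the pair is
    flagged ``unregistrable``.
    """
    if not isinstance(series_a, _GeneSeries):
        series_a = _GeneSeries(*series_a)
    if not isinstance(series_b, _GeneSeries):
        series_b = _GeneSeries(*series_b)
    best = None
    best_key = None
    for stretch, shift in grid.candidates():
        out = score_candidate(series_a, series_b, stretch, shift,
                              min_overlap=min_overlap, scale_level=scale_level)
        if out is None:
            continue
        score, window, overlap_tp = out
        key = (score, abs(stretch - 1.0), abs(shift), shift)
        if best_key is None or key < best_key:
            best_key = key
            best = (stretch, shift, window, overlap_tp, score)
    if best is None:
        return RegistrationResult(gene_a, gene_b, flag="unregistrable")
    stretch, shift, window, overlap_tp, score = best
    return RegistrationResult(gene_a, gene_b, stretch=stretch, shift=shift,
                              overlap=window, overlap_timepoints=overlap_tp,
                              score=score, n_overlap=len(overlap_tp))


def register_cohort(expr_a: ExpressionSet, expr_b: ExpressionSet,
                    pairs: OrthologuePairSet, grid: RegistrationGrid = RegistrationGrid(),
                    min_overlap: int = 4, scale_level: str = "replicate") -> list:
    """Register every orthologue pair; returns a list of RegistrationResult."""
    cache_a = {g: _GeneSeries.from_expression(expr_a, g)
               for g in pairs.pairs["gene_a"].unique()}
    cache_b = {g: _GeneSeries.from_expression(expr_b, g)
               for g in pairs.pairs["gene_b"].unique()}
    results = []
    for ga, gb in pairs.pairs.itertuples(index=False):
        results.append(register_pair(cache_a[ga], cache_b[gb], grid=grid,
                                     min_overlap=min_overlap, scale_level=scale_level,
                                     gene_a=ga, gene_b=gb))
    return results


def results_table(results) -> pd.DataFrame:
    """Tabulate registration results (gene_a, gene_b, stretch, shift, score,
    n_overlap, flag)."""
    return pd.DataFrame(
        [(r.gene_a, r.gene_b, r.stretch, r.shift, r.score, r.n_overlap, r.flag)
         for r in results],
        columns=["gene_a", "gene_b", "stretch", "shift", "score", "n_overlap", "flag"],
    )
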