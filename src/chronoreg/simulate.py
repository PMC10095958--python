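"""Synthetic two-genotype developmental time courses with planted ground truth.

The generator emulates the statistical structure of a comparative floral
transition experiment: two genotypes sampled over overlapping developmental
windows with replicates; groups of genes sharing a temporal shape but
desynchronised between genotypes by a group-specific stretch and shift of the
time axis; count-like magnitudes; 1-to-many orthologue relations; and a
contamination set of genes whose shapes genuinely differ between genotypes.

For a registered gene in a group with parameters ``(a, s)``, genotype B's
mean profile is ``f(t)`` on B's sampling days and genotype A's mean profile
is ``f(a*t + s)`` on A's days, so applying the time transformation
``t -> a*t + s`` to genotype A superimposes the two profiles exactly.

:func:`simulate_network_dynamics` generates time courses driven by a known
regulatory network, where each target at ``t+1`` is a smooth random function
(a Gaussian-process draw) of its parents at ``t`` — the benchmark substrate
for causal structure identification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionSet, OrthologuePairSet

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate_expression_pair",
    "simulate_network_dynamics",
]

# Sampling windows mirroring the real designs: genotype A daily over days
# 7-16 (Arabidopsis apex cadence), genotype B 17 timepoints over days 8-33.
DEFAULT_TIMEPOINTS_A = tuple(float(d) for d in range(7, 17))
DEFAULT_TIMEPOINTS_B = (8.0, 9.0, 10.0, 11.0, 12.0, 13.0, 14.0, 15.0, 16.0,
                        17.0, 18.0, 19.0, 21.0, 23.0, 25.0, 29.0, 33.0)

# Planted desynchronisation parameters, one per gene group, spanning the
# registration search grid.
DEFAULT_GROUP_PARAMS = ((1.0, 2.0), (1.5, -2.0), (2.0, 0.0), (1.5, 3.0))

SHAPE_FAMILIES = ("logistic", "gaussian", "ramp", "pulse")


@dataclass
class SyntheticConfig:
    """Parameters of the two-genotype simulation.

    ``group_params`` holds one (stretch >= 1, shift in days) pair per group.
    ``noise_sd`` is the replicate noise on the scaled (unit-variance) level;
    ``count_dispersion`` adds negative-binomial jitter on the count level
    (0 disables it). ``contamination_fraction`` of genes get independent
    shapes per genotype (truly different profiles, registered_flag False);
    ``paralogue_fraction`` of B genes are split into 2-3 copies summing to
    the parent profile.
    """

    n_genes: int = 500
    n_groups: int = len(DEFAULT_GROUP_PARAMS)
    timepoints_a: tuple = DEFAULT_TIMEPOINTS_A
    timepoints_b: tuple = DEFAULT_TIMEPOINTS_B
    n_replicates: int = 3
    group_params: tuple = DEFAULT_GROUP_PARAMS
    noise_sd: float = 0.2
    count_dispersion: float = 0.01
    contamination_fraction: float = 0.35
    paralogue_fraction: float = 0.0
    genotype_a: str = "genoA"
    genotype_b: str = "genoB"
    tissue: str = "apex"
    seed: int = 0

    def validate(self) -> None:
        ta = np.asarray(self.timepoints_a, dtype=float)
        tb = np.asarray(self.timepoints_b, dtype=float)
        if not (np.diff(ta) > 0).all() or not (np.diff(tb) > 0).all():
            raise ValueError("timepoint lists must be strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if len(self.group_params) != self.n_groups:
            raise ValueError("group_params length must equal n_groups")
        if not 0 <= self.paralogue_fraction <= 1:
            raise ValueError("paralogue_fraction must be in [0, 1]")
        if not 0 <= self.contamination_fraction <= 1:
            raise ValueError("contamination_fraction must be in [0, 1]")
        if self.count_dispersion < 0:
            raise ValueError("count_dispersion must be >= 0")
        for stretch, shift in self.group_params:
            lo, hi = stretch * ta[0] + shift, stretch * ta[-1] + shift
            if hi < tb[0] or lo > tb[-1]:
                raise ValueError(
                    f"group ({stretch}, {shift}): transformed A window "
                    f"[{lo}, {hi}] does not overlap B window [{tb[0]}, {tb[-1]}]"
                )


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-gene group/stretch/shift/shape and the
    registered flag (False exactly for contamination genes), plus the
    regulatory network for dynamics simulations."""

    genes: pd.DataFrame  # index gene_b; columns group, stretch, shift, shape_id, registered
    network: pd.DataFrame | None = None
    paralogue_groups: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes.reset_index().to_dict(orient="records"),
            "network": None if self.network is None else self.network.to_dict(orient="records"),
            "paralogue_groups": {k: list(v) for k, v in self.paralogue_groups.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# -----------------------------------------------------------------------------
# Temporal shape library
# -----------------------------------------------------------------------------

def _draw_shape(rng: np.random.Generator, window: tuple[float, float],
                family: str | None = None):
    """Draw a random temporal shape whose features lie inside ``window``.

    Families span the monotone and peaked profiles of developmental series:
    logistic switches, Gaussian pulses, saturating ramps and double-logistic
    transients (a rise followed by a partial fall). All are bounded, as
    expression is. Feature locations are anchored inside the window the
    analysis can observe for the gene's group — the timing of features
    outside the sampled overlap is unrecoverable in principle, for any
    method.
    """
    lo, hi = window
    span = hi - lo
    if family is None:
        family = SHAPE_FAMILIES[rng.integers(len(SHAPE_FAMILIES))]
    sign = 1.0 if rng.random() < 0.5 else -1.0
    core_lo, core_hi = lo + 0.3 * span, hi - 0.3 * span
    if family == "logistic":
        mid = rng.uniform(core_lo, core_hi)
        rate = rng.uniform(0.6, 1.2)
        params = (mid, rate, sign)

        def f(t, mid=mid, rate=rate, sign=sign):
            return sign / (1.0 + np.exp(-rate * (np.asarray(t, float) - mid)))
    elif family == "gaussian":
        centre = rng.uniform(core_lo, core_hi)
        width = rng.uniform(1.5, min(3.5, max(1.6, 0.25 * span)))
        params = (centre, width, sign)

        def f(t, c=centre, w=width, sign=sign):
            return sign * np.exp(-0.5 * ((np.asarray(t, float) - c) / w) ** 2)
    elif family == "ramp":
        length = rng.uniform(3.0, min(6.0, max(3.2, 0.5 * span)))
        start = rng.uniform(lo + 0.15 * span, hi - 0.15 * span - length)
        params = (start, length, sign)

        def f(t, s=start, L=length, sign=sign):
            return sign * np.clip((np.asarray(t, float) - s) / L, 0.0, 1.0)
    else:  # pulse: rise at t1 and partial fall at t2; the distance between
        # the two edges makes the stretch directly observable
        gap = rng.uniform(0.3 * span, 0.5 * span)
        t1 = rng.uniform(lo + 0.15 * span, hi - 0.15 * span - gap)
        t2 = t1 + gap
        rate = rng.uniform(0.8, 1.5)
        depth = rng.uniform(0.5, 0.9)
        params = (t1, t2, rate, depth, sign)

        def f(t, t1=t1, t2=t2, r=rate, d=depth, sign=sign):
            t = np.asarray(t, float)
            rise = 1.0 / (1.0 + np.exp(-r * (t - t1)))
            fall = 1.0 / (1.0 + np.exp(-r * (t - t2)))
            return sign * (rise - d * fall)
    return family, params, f


def _standardise(profile: np.ndarray) -> np.ndarray:
    sd = profile.std()
    if sd < 1e-12:
        return profile - profile.mean()
    return (profile - profile.mean()) / sd


def _to_counts(z: np.ndarray, z_lo: float, z_hi: float, base: float,
               dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Monotone positive count-like mapping of scaled expression.

    The scaled value is affinely mapped into [0.1, 1.9] x base using the
    gene pair's shared profile range [z_lo, z_hi] (so the gene-wise mean is
    about ``base``), floored at a small positive level against noise
    excursions, then optionally given negative-binomial jitter
    (var = mu + dispersion * mu^2; 0 disables sampling).
    """
    span = max(z_hi - z_lo, 1e-12)
    mu = base * (0.1 + 1.8 * (z - z_lo) / span)
    mu = np.maximum(mu, 0.01 * base)
    if dispersion <= 0:
        return mu
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(float)


def _sample_frame(genotype: str, tissue: str, timepoints, n_replicates: int) -> pd.DataFrame:
    rows = []
    for day in timepoints:
        for rep in range(1, n_replicates + 1):
            name = f"{genotype}_{tissue}_day{day:g}_rep{rep}"
            rows.append((name, genotype, tissue, float(day), rep))
    return pd.DataFrame(
        rows, columns=["sample", "genotype", "tissue", "day", "replicate"]
    ).set_index("sample")


def simulate_expression_pair(config: SyntheticConfig):
    """Simulate paired two-genotype time courses with planted registration.

    Returns ``(expr_a, expr_b, pairs, truth)``. Registered genes share a
    group shape desynchronised by the group's (stretch, shift); contamination
    genes get independent shapes per genotype. Replicate noise is Gaussian on
    the scaled level; values are then mapped through a gene-pair-specific
    monotone positive transform with optional negative-binomial jitter.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ta = np.asarray(config.timepoints_a, dtype=float)
    tb = np.asarray(config.timepoints_b, dtype=float)
    n = config.n_genes

    group_windows = [
        (max(stretch * ta[0] + shift, tb[0]), min(stretch * ta[-1] + shift, tb[-1]))
        for stretch, shift in config.group_params
    ]
    shapes = [
        _draw_shape(rng, w, family=SHAPE_FAMILIES[g % len(SHAPE_FAMILIES)])
        for g, w in enumerate(group_windows)
    ]
    group_of = rng.integers(config.n_groups, size=n)
    n_contam = int(round(config.contamination_fraction * n))
    contam = np.zeros(n, dtype=bool)
    contam[rng.choice(n, size=n_contam, replace=False)] = True

    genes_a = [f"gA{i:04d}" for i in range(n)]
    genes_b = [f"gB{i:04d}" for i in range(n)]
    meta_a = _sample_frame(config.genotype_a, config.tissue, ta, config.n_replicates)
    meta_b = _sample_frame(config.genotype_b, config.tissue, tb, config.n_replicates)
    days_a = meta_a["day"].to_numpy()
    days_b = meta_b["day"].to_numpy()

    vals_a = np.empty((n, len(meta_a)))
    vals_b = np.empty((n, len(meta_b)))
    truth_rows = []
    for i in range(n):
        g = int(group_of[i])
        stretch, shift = config.group_params[g]
        family, _, f = shapes[g]
        if contam[i]:
            fam_a, _, f_a = _draw_shape(rng, (ta[0], ta[-1]))
            fam_b, _, f_b = _draw_shape(rng, (tb[0], tb[-1]))
            mean_a = _standardise(f_a(ta))
            mean_b = _standardise(f_b(tb))
            shape_id = f"{fam_a}|{fam_b}"
        else:
            # one standardisation, anchored on the reference window, shared by
            # both genotypes: the count mapping is nonlinear, so per-genotype
            # scaling constants would break exact superimposability
            ref = f(tb)
            mu, sd = ref.mean(), max(ref.std(), 1e-12)
            mean_a = (f(stretch * ta + shift) - mu) / sd
            mean_b = (ref - mu) / sd
            shape_id = family
        za = np.repeat(mean_a, config.n_replicates)
        zb = np.repeat(mean_b, config.n_replicates)
        if config.noise_sd > 0:
            # replicate noise is relative to each genotype's own signal sd:
            # noise_sd is "on the scaled level" of that genotype's profile
            sd_a = max(float(np.std(mean_a)), 1e-12)
            sd_b = max(float(np.std(mean_b)), 1e-12)
            za = za + rng.normal(0.0, config.noise_sd * sd_a, size=za.shape)
            zb = zb + rng.normal(0.0, config.noise_sd * sd_b, size=zb.shape)
        base = float(np.exp(rng.uniform(np.log(1.0), np.log(1e4))))
        z_lo = float(min(mean_a.min(), mean_b.min()))
        z_hi = float(max(mean_a.max(), mean_b.max()))
        vals_a[i] = _to_counts(za, z_lo, z_hi, base, config.count_dispersion, rng)
        vals_b[i] = _to_counts(zb, z_lo, z_hi, base, config.count_dispersion, rng)
        truth_rows.append((genes_b[i], g, stretch, shift, shape_id, not contam[i]))

    vals_a_df = pd.DataFrame(vals_a, index=genes_a, columns=meta_a.index)
    truth = pd.DataFrame(
        truth_rows, columns=["gene_b", "group", "stretch", "shift", "shape_id", "registered"]
    ).set_index("gene_b")

    # paralogue duplication on the B side: copies sum to the parent profile
    pair_rows = list(zip(genes_a, genes_b))
    paralogue_groups: dict = {}
    n_para = int(round(config.paralogue_fraction * n))
    if n_para > 0:
        para_idx = rng.choice(n, size=n_para, replace=False)
        b_frames = {genes_b[i]: vals_b[i] for i in range(n)}
        for i in para_idx:
            parent = genes_b[i]
            n_copies = int(rng.integers(2, 4))
            weights = rng.dirichlet(np.ones(n_copies) * 5.0)
            copies = [f"{parent}_c{k + 1}" for k in range(n_copies)]
            del b_frames[parent]
            for name, w in zip(copies, weights):
                b_frames[name] = vals_b[i] * w
            paralogue_groups[parent] = copies
            pair_rows = [(a, b) for a, b in pair_rows if b != parent]
            pair_rows.extend((genes_a[i], c) for c in copies)
        vals_b_df = pd.DataFrame.from_dict(b_frames, orient="index")
        vals_b_df.columns = meta_b.index
    else:
        vals_b_df = pd.DataFrame(vals_b, index=genes_b, columns=meta_b.index)

    expr_a = ExpressionSet(vals_a_df, meta_a, units="counts")
    expr_b = ExpressionSet(vals_b_df, meta_b, units="counts")
    pairs = OrthologuePairSet(
        pd.DataFrame(pair_rows, columns=["gene_a", "gene_b"]),
        paralogue_groups=paralogue_groups,
    )
    return expr_a, expr_b, pairs, SyntheticTruth(truth, paralogue_groups=paralogue_groups)


# -----------------------------------------------------------------------------
# Network-driven dynamics for the CSI benchmark
# -----------------------------------------------------------------------------

def _gp_draw(rng: np.random.Generator, x: np.ndarray, lengthscale: float) -> np.ndarray:
    """One draw from a zero-mean unit-variance squared-exponential GP at x."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1:
        x = x.T
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
    cov = np.exp(-0.5 * d2 / lengthscale ** 2) + 1e-9 * np.eye(x.shape[0])
    return np.linalg.cholesky(cov) @ rng.standard_normal(x.shape[0])


def simulate_network_dynamics(n_genes: int, n_timepoints: int, noise_sd: float,
                              parent_correlation: float, gp_lengthscale: float,
                              seed: int, interaction: str = "gp",
                              max_parents: int = 2):
    """Time course driven by a known feedforward regulatory network.

    Root genes follow smooth random trajectories; each downstream target's
    value at ``t+1`` is a function of its parents' values at ``t`` (a GP draw
    with the given lengthscale, or linear) plus Gaussian noise. A quarter of
    the genes are non-parent "decoy" regulators constructed with the given
    Pearson correlation to a true parent series. Returns the expression set
    and the true directed edge list.
    """
    if n_timepoints < 5:
        raise ValueError("n_timepoints must be >= 5")
    if not 0.0 <= parent_correlation < 1.0:
        raise ValueError("parent_correlation must be in [0, 1)")
    if interaction not in ("gp", "linear"):
        raise ValueError("interaction must be 'gp' or 'linear'")
    rng = np.random.default_rng(seed)
    n_decoys = n_genes // 4
    n_core = n_genes - n_decoys
    n_roots = max(2, min(n_core - 1, n_core // 3))
    T = n_timepoints

    series = np.empty((n_genes, T))
    time_ls = max(T / 5.0, 2.0)
    for i in range(n_roots):
        series[i] = _gp_draw(rng, np.arange(T, dtype=float), time_ls)

    edges = []
    for i in range(n_roots, n_core):
        k = int(rng.integers(1, max_parents + 1))
        parents = rng.choice(i, size=min(k, i), replace=False)
        u = series[parents].T[:-1]  # (T-1, P): parents at t
        if interaction == "linear":
            w = rng.standard_normal(len(parents))
            w /= np.linalg.norm(w)
            g = u @ w
            fn_id = "linear"
        else:
            g = _gp_draw(rng, u, gp_lengthscale)
            fn_id = "gp"
        series[i, 0] = rng.standard_normal()
        series[i, 1:] = g + (noise_sd * rng.standard_normal(T - 1) if noise_sd > 0 else 0.0)
        edges.extend((f"g{p:03d}", f"g{i:03d}", fn_id) for p in parents)

    parent_pool = sorted({int(e[0][1:]) for e in edges}) or list(range(n_roots))
    rho = parent_correlation
    for j in range(n_decoys):
        i = n_core + j
        src = series[parent_pool[int(rng.integers(len(parent_pool)))]]
        src_std = (src - src.mean()) / max(src.std(), 1e-12)
        indep = _gp_draw(rng, np.arange(T, dtype=float), time_ls)
        indep = (indep - indep.mean()) / max(indep.std(), 1e-12)
        series[i] = rho * src_std + np.sqrt(1.0 - rho ** 2) * indep

    genes = [f"g{i:03d}" for i in range(n_genes)]
    meta = _sample_frame("sim", "net", np.arange(T, dtype=float), 1)
    expr = ExpressionSet(
        pd.DataFrame(series, index=genes, columns=meta.index), meta, units="scaled"
    )
    network = pd.DataFrame(edges, columns=["parent", "child", "interaction"])
    return expr, network
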