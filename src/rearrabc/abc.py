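"""Rejection-ABC inference of rearrangement rates from gene-order data.

The engine simulates ``s_abc`` datasets along the input tree with
parameters drawn from the prior (the proposal equals the prior), computes
the summary vector of each, and retains the ``m`` simulations closest to
the observed summaries under a standardized Euclidean distance — each
dimension divided by its standard deviation across the pool.  Retaining a
fixed ``m`` realizes a uniform kernel with a dynamic threshold (the
largest retained distance).  The point estimate per parameter is the mean
of the retained draws; the 90% credible interval is their 5th–95th
percentile range.

For the multi-chromosome model the parameter vector splits: the rates
inherited from the single-chromosome model (inversion, translocation,
block-size exponent) are inferred from the gene-order statistics alone,
and the chromosome-number parameters (root chromosome count, fusion and
fission rates) from the chromosome-level statistics alone — each group of
statistics carries little information about the other group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .block_stats import DEFAULT_S_BL, M0_STAT_NAMES, m0_summary
from .chromo_stats import M1_STAT_NAMES, m1_summary
from .genomes import GenomeSet, PhyloTree
from .simulator import ModelParams, simulate_tree

__all__ = [
    "Prior",
    "PriorSpec",
    "ReferencePool",
    "PosteriorSample",
    "Estimate",
    "default_prior",
    "sample_prior",
    "summary_vector",
    "summary_names",
    "build_pool",
    "distance",
    "retain_closest",
    "infer",
    "M0_PARAMS",
    "M1_ONLY_PARAMS",
]

M0_PARAMS = ("r_inv", "r_trans", "a")
M1_ONLY_PARAMS = ("ch_root", "r_fus", "r_fis")


@dataclass(frozen=True)
class Prior:
    """One parameter's prior: a named family plus hyperparameters.

    Families: ``uniform(lo, hi)``, ``int_uniform(lo, hi)`` (inclusive
    integers), ``lognormal(mu, sigma)``, ``gamma(shape, scale)``,
    ``poisson(lam)`` (discrete, shifted to be >= ``minimum``).
    """

    family: str
    args: tuple[float, ...]
    minimum: float | None = None  # clip/shift floor (validity region)

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "uniform":
            lo, hi = self.args
            x = rng.uniform(lo, hi)
        elif self.family == "int_uniform":
            lo, hi = self.args
            x = float(rng.integers(int(lo), int(hi) + 1))
        elif self.family == "lognormal":
            mu, sigma = self.args
            x = rng.lognormal(mu, sigma)
        elif self.family == "gamma":
            shape, scale = self.args
            x = rng.gamma(shape, scale)
        elif self.family == "poisson":
            (lam,) = self.args
            x = float(rng.poisson(lam))
        else:
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.minimum is not None and x < self.minimum:
            x = self.minimum
        return x

    def mean(self) -> float:
        if self.family in ("uniform",):
            return (self.args[0] + self.args[1]) / 2
        if self.family == "int_uniform":
            return (self.args[0] + self.args[1]) / 2
        if self.family == "lognormal":
            mu, sigma = self.args
            return float(np.exp(mu + sigma**2 / 2))
        if self.family == "gamma":
            return self.args[0] * self.args[1]
        if self.family == "poisson":
            return self.args[0]
        raise ValueError(self.family)


PriorSpec = dict[str, Prior]


def default_prior(model: str = "M0") -> PriorSpec:
    """The default uniform priors over the rate parameters."""
    spec: PriorSpec = {
        "a": Prior("uniform", (1.001, 2.0)),
        "r_inv": Prior("uniform", (0.0, 1.5)),
        "r_trans": Prior("uniform", (0.0, 1.5)),
    }
    if model == "M1":
        spec.update(
            ch_root=Prior("int_uniform", (4, 18)),
            r_fus=Prior("uniform", (0.0, 0.8)),
            r_fis=Prior("uniform", (0.0, 0.03)),
        )
    return spec


def sample_prior(
    spec: PriorSpec, rng: np.random.Generator, model: str = "M0",
    m_zip: int = 50,
) -> ModelParams:
    """Draw one parameter vector, each component independent."""
    draw = {name: p.sample(rng) for name, p in spec.items()}
    kwargs = dict(
        model=model,
        r_inv=draw.get("r_inv", 0.0),
        r_trans=draw.get("r_trans", 0.0),
        a=max(draw.get("a", 1.5), 1.001),
        m_zip=m_zip,
    )
    if model == "M1":
        kwargs.update(
            ch_root=max(int(round(draw.get("ch_root", 1))), 1),
            r_fus=draw.get("r_fus", 0.0),
            r_fis=draw.get("r_fis", 0.0),
        )
    return ModelParams(**kwargs)


def summary_names(model: str, s_bl: int = DEFAULT_S_BL) -> list[str]:
    names = M0_STAT_NAMES(s_bl)
    if model == "M1":
        names += M1_STAT_NAMES
    return names


def summary_vector(
    gs: GenomeSet, tree: PhyloTree | None, model: str, s_bl: int = DEFAULT_S_BL
) -> np.ndarray:
    """Full summary vector: 2*s_bl+2 gene-order statistics, plus the 8
    chromosome statistics under M1."""
    s = m0_summary(gs, s_bl).astype(float)
    if model == "M1":
        if tree is None:
            raise ValueError("M1 summaries require the tree")
        s = np.concatenate([s, m1_summary(gs, tree)])
    return s


@dataclass
class ReferencePool:
    """s_abc simulated (theta, summary) pairs plus per-dimension stds."""

    params: pd.DataFrame  # s_abc x n_params
    summaries: np.ndarray  # s_abc x n_dims
    model: str
    s_bl: int = DEFAULT_S_BL

    @property
    def stds(self) -> np.ndarray:
        return self.summaries.std(axis=0)

    @property
    def s_abc(self) -> int:
        return len(self.params)


def _one_row(tree, spec, n_root, model, s_bl, m_zip, seed):
    rng = np.random.default_rng(seed)
    theta = sample_prior(spec, rng, model=model, m_zip=m_zip)
    gs, _ = simulate_tree(tree, theta, n_root, rng)
    return theta.as_dict(), summary_vector(gs, tree, model, s_bl)


def build_pool(
    tree: PhyloTree,
    spec: PriorSpec,
    s_abc: int,
    n_root: int,
    model: str = "M0",
    rng: np.random.Generator | None = None,
    s_bl: int = DEFAULT_S_BL,
    m_zip: int = 50,
    n_jobs: int = 1,
) -> ReferencePool:
    """Simulate the reference pool: theta ~ prior, data ~ model, summaries.

    Reproducible for a fixed generator state at any worker count: each row
    gets its own child seed spawned from the generator's seed sequence.
    """
    if s_abc < 1:
        raise ValueError("s_abc must be >= 1")
    rng = rng or np.random.default_rng()
    seeds = rng.bit_generator.seed_seq.spawn(s_abc)
    if n_jobs == 1:
        rows = [_one_row(tree, spec, n_root, model, s_bl, m_zip, s) for s in seeds]
    else:
        rows = Parallel(n_jobs=n_jobs)(
            delayed(_one_row)(tree, spec, n_root, model, s_bl, m_zip, s)
            for s in seeds
        )
    params = pd.DataFrame([r[0] for r in rows])
    summaries = np.vstack([r[1] for r in rows])
    return ReferencePool(params=params, summaries=summaries, model=model, s_bl=s_bl)


def distance(
    s_obs: np.ndarray, s_sim: np.ndarray, stds: np.ndarray
) -> np.ndarray | float:
    """Standardized Euclidean distance; zero-variance dimensions are skipped.

    ``s_sim`` may be one vector or a (rows, dims) matrix; returns a scalar
    or one distance per row accordingly.
    """
    s_obs = np.asarray(s_obs, dtype=float)
    s_sim = np.asarray(s_sim, dtype=float)
    stds = np.asarray(stds, dtype=float)
    if s_obs.shape[-1] != stds.shape[-1] or s_sim.shape[-1] != stds.shape[-1]:
        raise ValueError("summary-vector length mismatch")
    ok = stds > 0
    diff = (s_sim[..., ok] - s_obs[ok]) / stds[ok]
    d = np.sqrt((diff**2).sum(axis=-1))
    return float(d) if d.ndim == 0 else d


@dataclass
class PosteriorSample:
    """The m retained parameter draws, their distances, and the realized
    dynamic threshold (largest retained distance)."""

    params: pd.DataFrame
    distances: np.ndarray
    max_distance: float


def retain_closest(
    pool: ReferencePool,
    s_obs: np.ndarray,
    m: int,
    dims: np.ndarray | list[int] | None = None,
    weight_mode: str = "divide",
) -> PosteriorSample:
    """Keep the m pool rows closest to ``s_obs``.

    ``dims`` restricts the distance to a subset of summary dimensions.
    ``weight_mode='divide'`` standardizes each dimension by its pool std
    (the default); ``'multiply'`` applies the literal multiply-by-std
    weighting for comparison.  Ties at the threshold break by row order.
    """
    if m > pool.s_abc:
        raise ValueError(f"m={m} exceeds pool size {pool.s_abc}")
    s_obs = np.asarray(s_obs, dtype=float)
    dims = np.arange(pool.summaries.shape[1]) if dims is None else np.asarray(dims)
    sub = pool.summaries[:, dims]
    stds = sub.std(axis=0)
    if weight_mode == "divide":
        d = distance(s_obs[dims], sub, stds)
    elif weight_mode == "multiply":
        ok = stds > 0
        diff = (sub[:, ok] - s_obs[dims][ok]) * stds[ok]
        d = np.sqrt((diff**2).sum(axis=1))
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    order = np.argsort(d, kind="stable")[:m]
    order = order[np.argsort(d[order], kind="stable")]
    return PosteriorSample(
        params=pool.params.iloc[order].reset_index(drop=True),
        distances=d[order],
        max_distance=float(d[order[-1]]) if m else float("nan"),
    )


@dataclass
class Estimate:
    """Posterior means and 90% credible intervals per parameter."""

    mean: dict[str, float]
    ci90: dict[str, tuple[float, float]]
    retained: dict[str, PosteriorSample] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"parameter": k, "mean": v, "ci5": self.ci90[k][0], "ci95": self.ci90[k][1]}
            for k, v in self.mean.items()
        ]
        return pd.DataFrame(rows)


def _summarize(sample: PosteriorSample, names) -> tuple[dict, dict]:
    mean, ci = {}, {}
    for name in names:
        vals = sample.params[name].to_numpy(dtype=float)
        mean[name] = float(vals.mean())
        ci[name] = (float(np.percentile(vals, 5)), float(np.percentile(vals, 95)))
    return mean, ci


def infer(
    gs: GenomeSet,
    tree: PhyloTree,
    spec: PriorSpec | None = None,
    s_abc: int = 200_000,
    m: int = 50,
    model: str = "M0",
    rng: np.random.Generator | None = None,
    pool: ReferencePool | None = None,
    s_bl: int = DEFAULT_S_BL,
    m_zip: int = 50,
    m0_dims: np.ndarray | None = None,
    n_jobs: int = 1,
) -> Estimate:
    """Full rejection-ABC pass on one observed dataset.

    A prebuilt ``pool`` may be supplied (and shared across datasets); its
    model and bin count must match.  ``m0_dims`` optionally restricts the
    gene-order statistics used for the inherited parameters (feature
    selection); the chromosome parameters always use the 8 chromosome
    statistics.
    """
    spec = spec or default_prior(model)
    tree.check_leaves(gs.names())
    s_obs = summary_vector(gs, tree, model, s_bl)
    if pool is None:
        pool = build_pool(
            tree, spec, s_abc, gs.n_root, model, rng, s_bl, m_zip, n_jobs
        )
    elif pool.model != model or pool.s_bl != s_bl:
        raise ValueError("pool configuration does not match the request")

    n_m0 = 2 * s_bl + 2
    dims_m0 = np.arange(n_m0) if m0_dims is None else np.asarray(m0_dims)
    sample_m0 = retain_closest(pool, s_obs, m, dims=dims_m0)
    mean, ci = _summarize(sample_m0, M0_PARAMS)
    retained = {"m0": sample_m0}
    if model == "M1":
        dims_m1 = np.arange(n_m0, n_m0 + 8)
        sample_m1 = retain_closest(pool, s_obs, m, dims=dims_m1)
        mean1, ci1 = _summarize(sample_m1, M1_ONLY_PARAMS)
        mean.update(mean1)
        ci.update(ci1)
        retained["m1"] = sample_m1
    return Estimate(mean=mean, ci90=ci, retained=retained)
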