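"""Validation harness: parameter-recovery accuracy, tuning and diagnostics.

Every experiment follows the same scheme: draw test parameter vectors from
the prior, simulate an "observed" dataset for each along a tree, run the
rejection-ABC inference, and compare inferred to true values with r^2 (the
square of Pearson's r) and mean squared error.  One reference pool is
shared across the test datasets of a configuration — at realistic pool
sizes the retained neighborhoods of distinct datasets barely overlap, and
rebuilding the pool per dataset would multiply the cost by the number of
test datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import dendropy

from .abc import (
    M0_PARAMS,
    M1_ONLY_PARAMS,
    PriorSpec,
    ReferencePool,
    build_pool,
    default_prior,
    retain_closest,
    sample_prior,
    summary_vector,
)
from .block_stats import DEFAULT_S_BL
from .genomes import PhyloTree
from .simulator import simulate_tree

__all__ = [
    "AccuracyReport",
    "r_squared",
    "mse",
    "random_tree",
    "make_test_sets",
    "accuracy_experiment",
    "size_and_length_sweeps",
    "coverage_experiment",
    "optimize_m",
    "leave_one_out_selection",
    "single_feature_baseline",
]


def r_squared(true: np.ndarray, est: np.ndarray) -> float:
    """Squared Pearson correlation; 0.0 when either side is constant."""
    true = np.asarray(true, dtype=float)
    est = np.asarray(est, dtype=float)
    if np.std(true) == 0 or np.std(est) == 0:
        return 0.0
    return float(np.corrcoef(true, est)[0, 1] ** 2)


def mse(true: np.ndarray, est: np.ndarray) -> float:
    true = np.asarray(true, dtype=float)
    est = np.asarray(est, dtype=float)
    return float(np.mean((est - true) ** 2))


def random_tree(
    n_leaves: int, total_length: float, rng: np.random.Generator
) -> PhyloTree:
    """Random rooted bifurcating tree with the requested total branch length.

    Topology by uniform random sequential joining of lineages; branch
    lengths i.i.d. exponential, rescaled so they sum to ``total_length``.
    Leaves are labelled t1..tN.
    """
    if n_leaves < 2:
        raise ValueError("need at least two leaves")
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(1, n_leaves + 1)])
    nodes = []
    for i in range(n_leaves):
        leaf = dendropy.Node(taxon=taxa[i])
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        nodes = [n for k, n in enumerate(nodes) if k not in (int(i), int(j))]
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[0]
    edges = [
        nd for nd in tree.preorder_node_iter() if nd.parent_node is not None
    ]
    lens = rng.exponential(1.0, size=len(edges))
    lens *= total_length / lens.sum()
    for nd, ln in zip(edges, lens):
        nd.edge.length = float(ln)
    return PhyloTree(tree)


@dataclass
class AccuracyReport:
    """Per-parameter r^2 and MSE over a batch of test datasets."""

    r2: dict[str, float]
    mse: dict[str, float]
    true: pd.DataFrame
    est: pd.DataFrame
    meta: dict

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.r2),
                "r2": list(self.r2.values()),
                "mse": [self.mse[k] for k in self.r2],
            }
        )


def make_test_sets(
    tree: PhyloTree,
    spec: PriorSpec,
    n_test: int,
    n_root: int,
    model: str,
    rng: np.random.Generator,
    s_bl: int = DEFAULT_S_BL,
    m_zip: int = 50,
):
    """Draw n_test (theta, observed-summary) pairs for evaluation."""
    thetas, obs = [], []
    for _ in range(n_test):
        theta = sample_prior(spec, rng, model=model, m_zip=m_zip)
        gs, _ = simulate_tree(tree, theta, n_root, rng)
        thetas.append(theta.as_dict())
        obs.append(summary_vector(gs, tree, model, s_bl))
    return pd.DataFrame(thetas), np.vstack(obs)


def _param_names(model: str) -> tuple[str, ...]:
    return M0_PARAMS + (M1_ONLY_PARAMS if model == "M1" else ())


def _estimates_from_pool(
    pool: ReferencePool,
    obs: np.ndarray,
    m: int,
    model: str,
    s_bl: int,
    m0_dims=None,
) -> pd.DataFrame:
    """Posterior means for a batch of observed summary vectors."""
    n_m0 = 2 * s_bl + 2
    dims_m0 = np.arange(n_m0) if m0_dims is None else np.asarray(m0_dims)
    rows = []
    for s_obs in obs:
        sample = retain_closest(pool, s_obs, m, dims=dims_m0)
        row = {k: float(sample.params[k].mean()) for k in M0_PARAMS}
        if model == "M1":
            s1 = retain_closest(pool, s_obs, m, dims=np.arange(n_m0, n_m0 + 8))
            row.update({k: float(s1.params[k].mean()) for k in M1_ONLY_PARAMS})
        rows.append(row)
    return pd.DataFrame(rows)


def accuracy_experiment(
    tree: PhyloTree,
    n_root: int,
    spec: PriorSpec | None = None,
    model: str = "M0",
    n_test: int = 200,
    s_abc: int = 200_000,
    m: int = 50,
    rng: np.random.Generator | None = None,
    s_bl: int = DEFAULT_S_BL,
    pool: ReferencePool | None = None,
    n_jobs: int = 1,
) -> AccuracyReport:
    """r^2 and MSE of posterior-mean estimates over n_test prior draws."""
    rng = rng or np.random.default_rng()
    spec = spec or default_prior(model)
    if pool is None:
        pool = build_pool(tree, spec, s_abc, n_root, model, rng, s_bl, n_jobs=n_jobs)
    true, obs = make_test_sets(tree, spec, n_test, n_root, model, rng, s_bl)
    est = _estimates_from_pool(pool, obs, m, model, s_bl)
    names = _param_names(model)
    return AccuracyReport(
        r2={k: r_squared(true[k], est[k]) for k in names},
        mse={k: mse(true[k], est[k]) for k in names},
        true=true,
        est=est,
        meta={"n_root": n_root, "s_abc": pool.s_abc, "m": m, "n_test": n_test,
              "model": model},
    )


def size_and_length_sweeps(
    tree: PhyloTree,
    n_root_grid: list[int],
    length_factor_grid: list[float],
    spec: PriorSpec | None = None,
    model: str = "M0",
    n_test: int = 200,
    s_abc: int = 200_000,
    m: int = 50,
    rng: np.random.Generator | None = None,
    base_n_root: int = 5000,
    s_bl: int = DEFAULT_S_BL,
) -> pd.DataFrame:
    """Accuracy grids over genome size and tree-divergence scaling.

    The genome-size sweep runs on the unscaled tree; the branch-length
    sweep multiplies every branch by the factor and uses ``base_n_root``
    genes.  Returns one tidy row per (grid key, parameter).
    """
    rng = rng or np.random.default_rng()
    spec = spec or default_prior(model)
    rows = []
    for n_root in n_root_grid:
        rep = accuracy_experiment(
            tree, n_root, spec, model, n_test, s_abc, m, rng, s_bl
        )
        for k in rep.r2:
            rows.append({"sweep": "n_root", "value": n_root, "parameter": k,
                         "r2": rep.r2[k], "mse": rep.mse[k]})
    for factor in length_factor_grid:
        scaled = tree.scale_branch_lengths(factor)
        rep = accuracy_experiment(
            scaled, base_n_root, spec, model, n_test, s_abc, m, rng, s_bl
        )
        for k in rep.r2:
            rows.append({"sweep": "length_factor", "value": factor, "parameter": k,
                         "r2": rep.r2[k], "mse": rep.mse[k]})
    return pd.DataFrame(rows)


def coverage_experiment(
    tree: PhyloTree,
    n_root: int,
    spec: PriorSpec | None = None,
    model: str = "M0",
    n_test: int = 200,
    s_abc: int = 200_000,
    m: int = 50,
    rng: np.random.Generator | None = None,
    s_bl: int = DEFAULT_S_BL,
    pool: ReferencePool | None = None,
) -> dict[str, float]:
    """Fraction of test datasets whose true parameter lies in the 90%
    credible interval (5th–95th percentile of the retained draws)."""
    rng = rng or np.random.default_rng()
    spec = spec or default_prior(model)
    if pool is None:
        pool = build_pool(tree, spec, s_abc, n_root, model, rng, s_bl)
    true, obs = make_test_sets(tree, spec, n_test, n_root, model, rng, s_bl)
    names = _param_names(model)
    hits = {k: 0 for k in names}
    n_m0 = 2 * s_bl + 2
    for i, s_obs in enumerate(obs):
        sample0 = retain_closest(pool, s_obs, m, dims=np.arange(n_m0))
        samples = {k: sample0.params[k] for k in M0_PARAMS}
        if model == "M1":
            s1 = retain_closest(pool, s_obs, m, dims=np.arange(n_m0, n_m0 + 8))
            samples.update({k: s1.params[k] for k in M1_ONLY_PARAMS})
        for k in names:
            vals = samples[k].to_numpy(dtype=float)
            lo, hi = np.percentile(vals, 5), np.percentile(vals, 95)
            if lo <= float(true[k][i]) <= hi:
                hits[k] += 1
    return {k: hits[k] / n_test for k in names}


def optimize_m(
    tree: PhyloTree,
    n_root: int,
    spec: PriorSpec | None = None,
    model: str = "M0",
    candidates: list[int] | None = None,
    n_test: int = 200,
    s_abc: int = 200_000,
    rng: np.random.Generator | None = None,
    s_bl: int = DEFAULT_S_BL,
    pool: ReferencePool | None = None,
) -> tuple[int, pd.DataFrame]:
    """Pick the retention size m maximizing the worst per-parameter r^2.

    One pool and one test set are reused for every candidate; ties go to
    the smallest m.  Returns (best m, per-candidate score table).
    """
    if not candidates:
        raise ValueError("no m candidates supplied")
    rng = rng or np.random.default_rng()
    spec = spec or default_prior(model)
    if pool is None:
        pool = build_pool(tree, spec, s_abc, n_root, model, rng, s_bl)
    true, obs = make_test_sets(tree, spec, n_test, n_root, model, rng, s_bl)
    names = _param_names(model)
    rows = []
    for m in sorted(candidates):
        est = _estimates_from_pool(pool, obs, m, model, s_bl)
        r2s = {k: r_squared(true[k], est[k]) for k in names}
        rows.append({"m": m, **r2s, "min_r2": min(r2s.values())})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["min_r2"].idxmax(), "m"])
    return best, table


def leave_one_out_selection(
    tree: PhyloTree,
    n_root: int,
    target: str,
    spec: PriorSpec | None = None,
    model: str = "M0",
    n_test: int = 200,
    s_abc: int = 200_000,
    m: int = 200,
    rng: np.random.Generator | None = None,
    s_bl: int = DEFAULT_S_BL,
    pool: ReferencePool | None = None,
    min_gain: float = 0.01,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Greedy backward elimination of gene-order summary dimensions.

    At each round the dimension whose removal most increases r^2 for
    ``target`` is dropped; stops when the best gain falls below
    ``min_gain``.  Returns (selected dimension indices, round log).
    """
    rng = rng or np.random.default_rng()
    spec = spec or default_prior(model)
    if pool is None:
        pool = build_pool(tree, spec, s_abc, n_root, model, rng, s_bl)
    true, obs = make_test_sets(tree, spec, n_test, n_root, model, rng, s_bl)
    n_m0 = 2 * s_bl + 2

    def score(dims) -> float:
        est = _estimates_from_pool(pool, obs, m, model, s_bl, m0_dims=dims)
        return r_squared(true[target], est[target])

    dims = list(range(n_m0))
    current = score(dims)
    log = [{"round": 0, "removed": None, "r2": current, "n_dims": len(dims)}]
    rnd = 0
    while len(dims) > 1:
        rnd += 1
        best_gain, best_dim, best_r2 = -np.inf, None, None
        for d in dims:
            trial = [x for x in dims if x != d]
            r2 = score(trial)
            if r2 - current > best_gain:
                best_gain, best_dim, best_r2 = r2 - current, d, r2
        if best_gain < min_gain:
            break
        dims.remove(best_dim)
        current = best_r2
        log.append({"round": rnd, "removed": best_dim, "r2": current,
                    "n_dims": len(dims)})
    return np.asarray(dims), pd.DataFrame(log)


def single_feature_baseline(
    tree: PhyloTree,
    n_root: int,
    spec: PriorSpec | None = None,
    model: str = "M0",
    n_test: int = 200,
    s_abc: int = 200_000,
    m: int = 50,
    rng: np.random.Generator | None = None,
    s_bl: int = DEFAULT_S_BL,
    pool: ReferencePool | None = None,
) -> pd.DataFrame:
    """MSE (and r^2) of inference restricted to each single gene-order
    statistic, one row per (dimension, parameter), plus full-set rows
    (dimension = -1) for comparison."""
    rng = rng or np.random.default_rng()
    spec = spec or default_prior(model)
    if pool is None:
        pool = build_pool(tree, spec, s_abc, n_root, model, rng, s_bl)
    true, obs = make_test_sets(tree, spec, n_test, n_root, model, rng, s_bl)
    n_m0 = 2 * s_bl + 2
    rows = []

    def add(dims, dim_label):
        est = _estimates_from_pool(pool, obs, m, model, s_bl, m0_dims=dims)
        for k in M0_PARAMS:
            rows.append({"dimension": dim_label, "parameter": k,
                         "mse": mse(true[k], est[k]),
                         "r2": r_squared(true[k], est[k])})

    add(None, -1)
    for d in range(n_m0):
        add([d], d)
    return pd.DataFrame(rows)
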