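"""Module- and basin-level assembly statistics, regressions and null models.

Two analyses are supported.

**Basin analysis.** Every basin holding at least two species gets the mean
pairwise phylogenetic distance <PD> and mean pairwise cosine distance <CD>
over its resident species. Within each basin cluster (module of the basin
network), <CD> is regressed on <PD>; random basin clusters of matching
sizes calibrate how much structure the clustering itself contributes.

**Species-module analysis.** Every module of a nearest-neighbour species
network gets <CD>, <PD> and NBS — the number of basins in which at least
two of the module's species co-occur. Two null hypotheses are examined per
network metric: H1, that NBS is unrelated to trait similarity (<CD>), and
H2, that NBS is unrelated to phylogenetic closeness (<PD>). The NN sweep
repeats module detection over a range of out-degrees and many seeded runs;
the random-module null redraws modules of matched sizes from the species
pool, which should destroy any module-level relationship.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError, InvalidDataError
from .networks import ModulePartition, build_nn_graph, detect_modules
from .seeding import derive_seed

__all__ = [
    "RegressionResult",
    "ols",
    "basin_means",
    "cluster_regressions",
    "random_basin_clusters",
    "module_stats",
    "nn_sweep",
    "random_module_null",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least squares summary for a y ~ x fit."""

    y_name: str
    x_name: str
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int
    estimable: bool = True


def _not_estimable(y_name: str, x_name: str, n: int) -> RegressionResult:
    return RegressionResult(y_name, x_name, np.nan, np.nan, np.nan, np.nan, n, False)


def ols(y, x, y_name: str = "y", x_name: str = "x") -> RegressionResult:
    """Simple linear regression with a two-sided t-test on the slope."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise InvalidArgumentError("y and x must have equal length")
    if y.size < 3:
        raise InvalidArgumentError("regression needs at least 3 points")
    if np.ptp(x) == 0.0:
        return _not_estimable(y_name, x_name, y.size)
    if np.ptp(y) == 0.0:
        # constant response: nothing to explain, not an error
        return RegressionResult(y_name, x_name, 0.0, float(y[0]), 0.0, 1.0, y.size)
    fit = stats.linregress(x, y)
    return RegressionResult(
        y_name=y_name,
        x_name=x_name,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=int(y.size),
    )


def _check_species(occ: pd.DataFrame, cd: pd.DataFrame, pd_: pd.DataFrame) -> None:
    for name, mat in (("cd", cd), ("pd", pd_)):
        missing = set(occ.index) - set(mat.index)
        if missing:
            raise InvalidDataError(
                f"species absent from {name} matrix: {sorted(missing)[:5]}"
            )


def _mean_pairwise(dist: np.ndarray, idx: np.ndarray) -> float:
    """Mean of the distance over all unordered pairs among ``idx``."""
    k = idx.size
    if k < 2:
        return np.nan
    sub = dist[np.ix_(idx, idx)]
    return float(sub.sum() / (k * (k - 1)))


def basin_means(occ: pd.DataFrame, cd: pd.DataFrame, pd_: pd.DataFrame) -> pd.DataFrame:
    """Per-basin species count, <CD> and <PD> over resident species pairs.

    Basins with fewer than two species get NaN means; they are excluded
    from downstream regressions.
    """
    _check_species(occ, cd, pd_)
    cd_arr = cd.loc[occ.index, occ.index].to_numpy(float)
    pd_arr = pd_.loc[occ.index, occ.index].to_numpy(float)
    arr = occ.to_numpy()
    rows = []
    for b, basin in enumerate(occ.columns):
        idx = np.nonzero(arr[:, b])[0]
        rows.append(
            {
                "basin": basin,
                "n_species": int(idx.size),
                "mean_cd": _mean_pairwise(cd_arr, idx),
                "mean_pd": _mean_pairwise(pd_arr, idx),
            }
        )
    return pd.DataFrame(rows).set_index("basin")


def cluster_regressions(
    basin_stats: pd.DataFrame, partition: ModulePartition | dict
) -> pd.DataFrame:
    """Per-cluster OLS of basin <CD> on basin <PD>.

    ``basin_stats`` is the output of :func:`basin_means`; ``partition``
    assigns each basin to a cluster. Clusters with fewer than three basins
    with defined means are flagged not estimable.
    """
    membership = partition.membership if isinstance(partition, ModulePartition) else partition
    stats_ = basin_stats.copy()
    stats_["cluster"] = [membership[b] for b in stats_.index]
    rows = []
    for cluster, grp in stats_.groupby("cluster"):
        usable = grp.dropna(subset=["mean_cd", "mean_pd"])
        if len(usable) < 3:
            res = _not_estimable("mean_cd", "mean_pd", len(usable))
        else:
            res = ols(usable["mean_cd"], usable["mean_pd"], "mean_cd", "mean_pd")
        rows.append(
            {
                "cluster": cluster,
                "n_basins": int(len(grp)),
                "n_used": res.n,
                "slope": res.slope,
                "intercept": res.intercept,
                "r2": res.r2,
                "p_value": res.p_value,
                "estimable": res.estimable,
            }
        )
    return pd.DataFrame(rows)


def random_basin_clusters(
    all_basins, cluster_sizes, n_reps: int, seed: int
) -> list[list[list]]:
    """Replicated random, disjoint pseudo-clusters of basins.

    Each replicate samples clusters without replacement from the basin pool
    with sizes matching ``cluster_sizes``.
    """
    pool = list(all_basins)
    sizes = [int(s) for s in cluster_sizes]
    if sum(sizes) > len(pool):
        raise InvalidArgumentError("cluster sizes exceed the basin pool")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_reps):
        perm = rng.permutation(len(pool))
        clusters, start = [], 0
        for s in sizes:
            clusters.append([pool[i] for i in perm[start : start + s]])
            start += s
        reps.append(clusters)
    return reps


def module_stats(
    partition: ModulePartition | dict,
    occ: pd.DataFrame,
    cd: pd.DataFrame,
    pd_: pd.DataFrame,
    min_cooccur: int = 2,
) -> pd.DataFrame:
    """Per-module species count, <CD>, <PD> and NBS.

    NBS counts the basins where at least ``min_cooccur`` of the module's
    species are present (default 2: the weakest notion of module
    co-occurrence that is not trivially satisfied by a single species).
    Modules with fewer than two species have undefined means and NBS = 0.
    """
    membership = partition.membership if isinstance(partition, ModulePartition) else partition
    _check_species(occ, cd, pd_)
    unknown = set(membership) - set(occ.index)
    if unknown:
        raise InvalidDataError(f"partition names unknown species {sorted(unknown)[:5]}")
    cd_arr = cd.loc[occ.index, occ.index].to_numpy(float)
    pd_arr = pd_.loc[occ.index, occ.index].to_numpy(float)
    occ_arr = occ.to_numpy()
    pos = {s: i for i, s in enumerate(occ.index)}
    modules: dict[int, list[int]] = {}
    for sp, m in membership.items():
        modules.setdefault(m, []).append(pos[sp])
    rows = []
    for m in sorted(modules):
        idx = np.asarray(sorted(modules[m]))
        nbs = int((occ_arr[idx].sum(axis=0) >= min_cooccur).sum()) if idx.size else 0
        rows.append(
            {
                "module": m,
                "n_species": int(idx.size),
                "mean_cd": _mean_pairwise(cd_arr, idx),
                "mean_pd": _mean_pairwise(pd_arr, idx),
                "nbs": nbs,
            }
        )
    return pd.DataFrame(rows)


_OTHER = {"cd": "pd", "pd": "cd"}


def _module_regressions(stats_df: pd.DataFrame, metric: str) -> list[RegressionResult]:
    """The two regressions of one network type: NBS ~ <metric> and
    <other metric> ~ <metric>, over modules with defined means."""
    x_name = f"mean_{metric}"
    usable = stats_df.dropna(subset=["mean_cd", "mean_pd"])
    out = []
    for y_name in ("nbs", f"mean_{_OTHER[metric]}"):
        if len(usable) < 3:
            out.append(_not_estimable(y_name, x_name, len(usable)))
        else:
            out.append(ols(usable[y_name], usable[x_name], y_name, x_name))
    return out


def _aggregate(per_run: pd.DataFrame, group_cols: list[str], alpha: float) -> pd.DataFrame:
    """Mean R^2, median p and slope over runs; flag = median p < alpha."""
    rows = []
    for keys, grp in per_run.groupby(group_cols):
        est = grp[grp["estimable"]]
        row = dict(zip(group_cols, keys if isinstance(keys, tuple) else (keys,)))
        row["n_runs"] = len(grp)
        row["n_estimable"] = len(est)
        if len(est) == 0:
            row.update(mean_r2=np.nan, median_p=np.nan, median_slope=np.nan,
                       significant=False, estimable=False)
        else:
            median_p = float(est["p_value"].median())
            row.update(
                mean_r2=float(est["r2"].mean()),
                median_p=median_p,
                median_slope=float(est["slope"].median()),
                significant=bool(median_p < alpha),
                estimable=True,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def nn_sweep(
    d_build: pd.DataFrame,
    occ: pd.DataFrame,
    cd: pd.DataFrame,
    pd_: pd.DataFrame,
    nn_values,
    metric: str,
    n_runs: int = 100,
    seed: int = 0,
    alpha: float = ALPHA,
    min_cooccur: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sweep of module detection and regressions over NN choices.

    For every ``NN`` the directed nearest-neighbour graph is built from
    ``d_build`` (the matrix of the named ``metric``), modules are detected
    ``n_runs`` times with derived seeds, and per run the module statistics
    feed two regressions: NBS on <metric>, and <other metric> on <metric>.

    Returns ``(per_run, aggregated)``; the aggregate reports mean R^2,
    median p-value and a significance flag (median p < alpha) per
    (NN, response).
    """
    if metric not in _OTHER:
        raise InvalidArgumentError("metric must be 'cd' or 'pd'")
    if n_runs < 1:
        raise InvalidArgumentError("n_runs must be >= 1")
    n = d_build.shape[0]
    records = []
    for nn in nn_values:
        if not 1 <= int(nn) <= n - 1:
            raise InvalidArgumentError(f"NN={nn} outside [1, {n - 1}]")
        g = build_nn_graph(d_build, int(nn))
        for run in range(n_runs):
            run_seed = derive_seed(seed, f"sweep-{metric}-nn{nn}", run)
            part = detect_modules(g, seed=run_seed)
            stats_df = module_stats(part, occ, cd, pd_, min_cooccur=min_cooccur)
            for res in _module_regressions(stats_df, metric):
                records.append(
                    {
                        "metric": metric,
                        "nn": int(nn),
                        "run": run,
                        "seed": run_seed,
                        "q": part.q,
                        "n_modules": part.n_modules,
                        "y": res.y_name,
                        "x": res.x_name,
                        "slope": res.slope,
                        "r2": res.r2,
                        "p_value": res.p_value,
                        "estimable": res.estimable,
                    }
                )
    per_run = pd.DataFrame(records)
    aggregated = _aggregate(per_run, ["metric", "nn", "y"], alpha)
    return per_run, aggregated


def random_module_null(
    partition_sizes,
    species_pool,
    occ: pd.DataFrame,
    cd: pd.DataFrame,
    pd_: pd.DataFrame,
    n_reps: int = 100,
    seed: int = 0,
    alpha: float = ALPHA,
    min_cooccur: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random-module null: redraw disjoint modules of matched sizes.

    Each replicate partitions a random sample of the species pool into
    modules whose size multiset equals ``partition_sizes`` and recomputes
    the four module regressions (NBS and cross-metric, for both metrics).
    Genuine module-level structure should vanish under this null.
    """
    pool = list(species_pool)
    sizes = [int(s) for s in partition_sizes]
    if sum(sizes) > len(pool):
        raise InvalidArgumentError("module sizes exceed the species pool")
    rng = np.random.default_rng(seed)
    records = []
    for rep in range(n_reps):
        perm = rng.permutation(len(pool))
        membership, start = {}, 0
        for m, s in enumerate(sizes):
            for i in perm[start : start + s]:
                membership[pool[i]] = m
            start += s
        stats_df = module_stats(membership, occ, cd, pd_, min_cooccur=min_cooccur)
        for metric in ("cd", "pd"):
            for res in _module_regressions(stats_df, metric):
                records.append(
                    {
                        "metric": metric,
                        "rep": rep,
                        "y": res.y_name,
                        "x": res.x_name,
                        "slope": res.slope,
                        "r2": res.r2,
                        "p_value": res.p_value,
                        "estimable": res.estimable,
                    }
                )
    per_rep = pd.DataFrame(records)
    aggregated = _aggregate(per_rep, ["metric", "y"], alpha)
    return per_rep, aggregated
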