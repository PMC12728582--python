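"""Inference layer linking diversity, composition, network complexity,
multifunctionality and productivity.

Provides pairwise correlation matrices, simple OLS regressions, the Mantel
permutation test between distance matrices, random-forest permutation
importance (%IncMSE, out-of-bag), and a piecewise path model whose overall
fit is judged with Fisher's C over the model's d-separation independence
claims (C = -2 sum ln p_i, chi-square with 2k degrees of freedom)."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

logger = logging.getLogger(__name__)

__all__ = [
    "correlation_matrix", "ols_fit", "mantel_test", "MantelResult",
    "rf_importance", "fit_path_model", "PathModel",
]


def correlation_matrix(data: pd.DataFrame, method: str = "pearson"):
    """Pairwise correlations with two-sided p-values (t approximation, n-2 df).

    Returns ``(r, p)`` DataFrames. Constant columns are flagged with NaN (and
    a warning) rather than silently zeroed.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    n = len(data)
    if n < 4:
        raise ValueError("need at least 4 samples")
    cols = list(data.columns)
    constant = [c for c in cols if data[c].nunique() <= 1]
    if constant:
        logger.warning("constant column(s) %s: correlations undefined (NaN)", constant)
    x = data.to_numpy(dtype=float)
    if method == "spearman":
        x = stats.rankdata(x, axis=0)
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.atleast_2d(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
        p = 2 * stats.t.sf(np.abs(t), n - 2)
    np.fill_diagonal(p, 0.0)
    p[np.abs(r) >= 1.0] = np.where(np.isnan(r[np.abs(r) >= 1.0]), np.nan, 0.0)
    for c in constant:
        k = cols.index(c)
        r[k, :] = r[:, k] = np.nan
        p[k, :] = p[:, k] = np.nan
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def ols_fit(x, y) -> dict:
    """Simple least-squares line fit: slope, intercept, R^2 and the two-sided
    t-test p-value of the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired points")
    if np.var(y) == 0:
        raise ValueError("response is constant; regression degenerate")
    if np.var(x) == 0:
        raise ValueError("predictor is constant; slope undefined")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p_slope": float(res.pvalue),
    }


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int


def mantel_test(d1, d2, n_perm: int = 999, seed: int | None = None) -> MantelResult:
    """Mantel test: Pearson correlation of the vectorised upper triangles,
    one-sided permutation p (rows+columns of the second matrix permuted
    jointly), ``p = (#{r_perm >= r_obs} + 1)/(n_perm + 1)``."""
    a = d1.to_numpy() if isinstance(d1, pd.DataFrame) else np.asarray(d1, dtype=float)
    b = d2.to_numpy() if isinstance(d2, pd.DataFrame) else np.asarray(d2, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("distance matrices must be square and the same size")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    va = a[iu]
    r_obs = float(np.corrcoef(va, b[iu])[0, 1])
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vb = b[np.ix_(perm, perm)][iu]
        if np.corrcoef(va, vb)[0, 1] >= r_obs:
            count_ge += 1
    return MantelResult(r=r_obs, p=(count_ge + 1) / (n_perm + 1), n_perm=n_perm)


def rf_importance(
    features: pd.DataFrame,
    response,
    n_trees: int = 500,
    seed: int | None = None,
) -> pd.Series:
    """Random-forest %IncMSE variable importance.

    For each tree, the out-of-bag MSE is compared with the MSE after
    permuting one predictor among the OOB rows; importance is the mean
    percent increase over trees. Deterministic given the seed.
    """
    y = np.asarray(response, dtype=float)
    x = features.to_numpy(dtype=float)
    n, p = x.shape
    if p < 2:
        raise ValueError("need >= 2 predictors")
    if n < 8:
        raise ValueError("need >= 8 samples")
    if np.var(y) == 0:
        raise ValueError("response is constant")
    rng = np.random.default_rng(seed)
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        bootstrap=True,
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=1,
    )
    forest.fit(x, y)
    inc = np.zeros(p)
    counts = np.zeros(p)
    for tree, bag in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), bag)
        if len(oob) < 2:
            continue
        x_oob = x[oob]
        base = np.mean((y[oob] - tree.predict(x_oob)) ** 2)
        if base == 0:
            continue
        for j in range(p):
            x_perm = x_oob.copy()
            x_perm[:, j] = x_perm[rng.permutation(len(oob)), j]
            mse = np.mean((y[oob] - tree.predict(x_perm)) ** 2)
            inc[j] += (mse - base) / base
            counts[j] += 1
    with np.errstate(invalid="ignore"):
        imp = 100.0 * inc / np.maximum(counts, 1)
    return pd.Series(imp, index=features.columns, name="pct_inc_mse")


@dataclass
class PathModel:
    """Fitted piecewise path model."""

    dag: nx.DiGraph
    coefficients: pd.DataFrame          # parent, child, estimate, p
    fisher_c: dict                      # C, df, p
    effects: pd.DataFrame               # source, target, direct, indirect, total
    independence_claims: list = field(default_factory=list)

    def coefficient(self, parent: str, child: str) -> float:
        row = self.coefficients[
            (self.coefficients["parent"] == parent) & (self.coefficients["child"] == child)
        ]
        if row.empty:
            raise KeyError(f"no path {parent} -> {child}")
        return float(row["estimate"].iloc[0])


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant variable(s): {list(sd.index[sd == 0])}")
    return (df - df.mean()) / sd


def _ols_coef_p(y: np.ndarray, x: np.ndarray):
    """Least-squares with intercept; returns per-column coefficients and
    two-sided t-test p-values."""
    n, k = x.shape
    design = np.column_stack([np.ones(n), x])
    cond = np.linalg.cond(design)
    if cond > 1e8:
        raise ValueError(f"collinear predictors (condition number {cond:.3g})")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    dof = n - k - 1
    if dof <= 0:
        raise ValueError("not enough samples for the parent-set size")
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    return beta[1:], pvals[1:]


def _basis_set(dag: nx.DiGraph):
    """Shipley d-separation basis: each non-adjacent ordered pair (u before v
    topologically), claimed independent given the union of both parents."""
    order = list(nx.topological_sort(dag))
    pos = {v: i for i, v in enumerate(order)}
    claims = []
    for u, v in itertools.combinations(order, 2):
        if dag.has_edge(u, v) or dag.has_edge(v, u):
            continue
        a, b = (u, v) if pos[u] < pos[v] else (v, u)
        cond = (set(dag.predecessors(a)) | set(dag.predecessors(b))) - {a, b}
        claims.append((a, b, tuple(sorted(cond))))
    return claims


def fit_path_model(dag, data: pd.DataFrame) -> PathModel:
    """Fit a piecewise path model on z-scored data.

    Each endogenous variable is regressed on its parents (standardised
    coefficients); the model-wide fit is Fisher's C over the d-separation
    basis claims, each tested as the partial-regression p-value of the
    claimed-independent pair given the union of their parents. Direct,
    indirect (sum over directed paths of coefficient products) and total
    effects are tabulated for every ordered variable pair connected by a
    directed path.
    """
    if not isinstance(dag, nx.DiGraph):
        dag = nx.DiGraph(list(dag))
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("graph has a cycle; path model requires a DAG")
    missing = [v for v in dag.nodes if v not in data.columns]
    if missing:
        raise KeyError(f"variable(s) not in data: {missing}")
    z = _zscore(data[list(dag.nodes)].astype(float))
    n = len(z)
    max_parents = max((dag.in_degree(v) for v in dag.nodes), default=0)
    if n <= max_parents + 2:
        raise ValueError("too few samples for the largest parent set")

    rows = []
    for child in dag.nodes:
        parents = list(dag.predecessors(child))
        if not parents:
            continue
        coefs, pvals = _ols_coef_p(z[child].to_numpy(), z[parents].to_numpy())
        for parent, c, p in zip(parents, coefs, pvals):
            rows.append({"parent": parent, "child": child,
                         "estimate": float(c), "p": float(p)})
    coefficients = pd.DataFrame(rows, columns=["parent", "child", "estimate", "p"])

    claims = _basis_set(dag)
    claim_ps = []
    for a, b, cond in claims:
        predictors = [a, *cond]
        _, pvals = _ols_coef_p(z[b].to_numpy(), z[predictors].to_numpy())
        claim_ps.append(float(pvals[0]))
    k = len(claims)
    if k:
        c_stat = -2.0 * float(np.sum(np.log(np.clip(claim_ps, 1e-300, None))))
        fisher_p = float(stats.chi2.sf(c_stat, 2 * k))
    else:
        c_stat, fisher_p = 0.0, 1.0
    fisher_c = {"C": c_stat, "df": 2 * k, "p": fisher_p}

    coef_of = {(r["parent"], r["child"]): r["estimate"] for r in rows}
    effect_rows = []
    for src in dag.nodes:
        for dst in dag.nodes:
            if src == dst or not nx.has_path(dag, src, dst):
                continue
            direct = coef_of.get((src, dst), 0.0)
            indirect = 0.0
            for path in nx.all_simple_paths(dag, src, dst):
                if len(path) <= 2:
                    continue
                prod = 1.0
                for u, v in zip(path, path[1:]):
                    prod *= coef_of[(u, v)]
                indirect += prod
            effect_rows.append({
                "source": src, "target": dst,
                "direct": direct, "indirect": indirect,
                "total": direct + indirect,
            })
    effects = pd.DataFrame(
        effect_rows, columns=["source", "target", "direct", "indirect", "total"]
    )
    return PathModel(
        dag=dag,
        coefficients=coefficients,
        fisher_c=fisher_c,
        effects=effects,
        independence_claims=[
            {"pair": (a, b), "conditioning": list(cond), "p": p}
            for (a, b, cond), p in zip(claims, claim_ps)
        ],
    )
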