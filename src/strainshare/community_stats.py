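"""Community-level statistics: Bray-Curtis, PERMANOVA, rank tests, ordination.

PERMANOVA follows the adonis2 convention: the squared distance matrix is
Gower-centered, terms are partitioned sequentially (Type I) via projection
(hat) matrices of the cumulative design, pseudo-F per term uses the residual
mean square, and significance comes from unrestricted permutation of sample
labels with the Monte Carlo correction p = (1 + #{F* >= F}) / (1 + n_perm).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu, spearmanr

__all__ = [
    "bray_curtis",
    "permanova",
    "wilcoxon_rank_sum",
    "spearman",
    "composition_axis",
]


def bray_curtis(abundance: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples (columns).

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i); a semimetric in [0, 1].
    Abundances must be non-negative with positive per-sample totals.
    """
    if (abundance.values < 0).any():
        raise ValueError("abundances must be non-negative")
    totals = abundance.sum(axis=0)
    if (totals <= 0).any():
        dead = totals.index[totals <= 0]
        raise ValueError(f"zero-total sample(s): {', '.join(map(str, dead))}")
    mat = squareform(pdist(abundance.values.T, metric="braycurtis"))
    return pd.DataFrame(mat, index=abundance.columns, columns=abundance.columns)


def _gower_center(distances: np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix G = J (-D^2 / 2) J."""
    a = -0.5 * distances**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _design_columns(metadata: pd.DataFrame, term: str) -> np.ndarray:
    """Model-matrix columns for one term: treatment dummies for categorical
    columns, the centered values for numeric ones."""
    col = metadata[term]
    if pd.api.types.is_numeric_dtype(col):
        v = col.to_numpy(float)
        return (v - v.mean())[:, None]
    levels = pd.unique(col)
    if len(levels) < 2:
        raise ValueError(f"term {term!r} has a single level")
    return np.column_stack([(col == lv).to_numpy(float) for lv in levels[1:]])


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T


def permanova(
    distances: pd.DataFrame,
    metadata: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sequential (Type I) PERMANOVA on a distance matrix.

    Parameters
    ----------
    distances
        Symmetric sample x sample distance matrix; rows of ``metadata`` are
        matched to its index via a ``sample_id`` column (or its own index).
    terms
        Metadata columns, partitioned in the given order.
    n_perm
        Number of unrestricted label permutations (999 by default).
    seed
        Seed for the permutation stream; fixing it fixes the p-values.

    Returns one row per term plus a ``Residual`` row, with df,
    sum-of-squares, pseudo-F, R2 and the Monte Carlo p-value
    (1 + #{F* >= F}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    md = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    md = md.loc[distances.index]
    n = len(md)

    g = _gower_center(distances.to_numpy(float))
    ss_total = np.trace(g)

    hats = [np.ones((n, n)) / n]  # intercept-only projection
    dfs = []
    x = np.ones((n, 1))
    for term in terms:
        x = np.hstack([x, _design_columns(md, term)])
        h = _hat(x)
        dfs.append(int(round(np.trace(h) - np.trace(hats[-1]))))
        hats.append(h)
    h_full = hats[-1]
    df_res = n - int(round(np.trace(h_full)))
    if df_res <= 0:
        raise ValueError("model saturates the samples; no residual df")

    term_proj = [hats[k + 1] - hats[k] for k in range(len(terms))]
    resid_proj = np.eye(n) - h_full

    def f_stats(gm: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float(np.sum(p * gm)) for p in term_proj])
        ss_res = float(np.sum(resid_proj * gm))
        return ss, ss_res

    ss_obs, ss_res_obs = f_stats(g)
    f_obs = (ss_obs / np.array(dfs)) / (ss_res_obs / df_res)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_res_p = f_stats(gp)
        f_p = (ss_p / np.array(dfs)) / (ss_res_p / df_res)
        exceed += f_p >= f_obs
    p_values = (1.0 + exceed) / (1.0 + n_perm)

    rows = [
        {
            "term": term,
            "df": dfs[k],
            "sum_of_squares": ss_obs[k],
            "pseudo_F": f_obs[k],
            "R2": ss_obs[k] / ss_total,
            "p_value": p_values[k],
            "n_permutations": n_perm,
        }
        for k, term in enumerate(terms)
    ]
    rows.append(
        {
            "term": "Residual",
            "df": df_res,
            "sum_of_squares": ss_res_obs,
            "pseudo_F": np.nan,
            "R2": ss_res_obs / ss_total,
            "p_value": np.nan,
            "n_permutations": n_perm,
        }
    )
    return pd.DataFrame(rows)


def wilcoxon_rank_sum(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses the exact null distribution when both groups have <= 8 observations
    and there are no ties; otherwise the normal approximation with tie and
    continuity corrections.  Returns (U of the first group, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return a.size * b.size / 2.0, 1.0
    no_ties = len(np.unique(combined)) == combined.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and no_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson on midranks).

    NaN when either vector is constant (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("inputs must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho, _ = spearmanr(x, y)
    return float(rho)


def composition_axis(distances: pd.DataFrame) -> pd.Series:
    """First principal-coordinate axis of a distance matrix.

    Classical metric scaling: the leading eigenvector of the Gower-centered
    matrix scaled by the square root of its eigenvalue.  The sign is fixed so
    the first sample with a nonzero coordinate is positive.  Serves as a
    one-dimensional summary of community composition.
    """
    if len(distances) < 3:
        raise ValueError("need at least 3 samples")
    g = _gower_center(distances.to_numpy(float))
    eigvals, eigvecs = np.linalg.eigh(g)
    lead = np.argmax(eigvals)
    lam = max(eigvals[lead], 0.0)
    coords = eigvecs[:, lead] * np.sqrt(lam)
    nz = np.nonzero(np.abs(coords) > 1e-12)[0]
    if nz.size and coords[nz[0]] < 0:
        coords = -coords
    return pd.Series(coords, index=distances.index, name="pcoa1")
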