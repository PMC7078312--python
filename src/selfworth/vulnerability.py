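"""Canonical correlation between symptoms and model parameters.

The "interpersonal vulnerability" dimension is the first canonical
dimension of a CCA between a subjects x symptoms block and a subjects x
fitted-parameters block.  Columns are standardized, the solution comes
from the QR + SVD formulation of the generalized eigenproblem, and
significance uses Rao's F approximation to Wilks' lambda (with a seeded
permutation alternative).  Scores are signed so that higher values mean
greater vulnerability (the global self-esteem coefficient is constrained
to be non-positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = ["CCAResult", "cca_fit", "wilks_test", "sequential_dimension_tests",
           "permutation_test", "vulnerability_scores"]

VULNERABILITY_ANCHOR = "global_self_esteem"


@dataclass
class CCAResult:
    """Fitted canonical correlation analysis.

    ``x_coef``/``y_coef`` are standardized canonical coefficients (columns
    = dimensions, rows = input variables); ``x_scores``/``y_scores`` are
    unit-variance canonical variates.  ``wilks_lambda``, ``f_stat``,
    ``df`` and ``p_value`` test the joint null of no association across
    all dimensions.
    """

    canonical_correlations: np.ndarray
    x_coef: np.ndarray
    y_coef: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    x_names: list
    y_names: list
    n: int
    wilks_lambda: float = np.nan
    f_stat: float = np.nan
    df: tuple = (np.nan, np.nan)
    p_value: float = np.nan
    p_value_permutation: float | None = None

    @property
    def first_correlation(self) -> float:
        return float(self.canonical_correlations[0])


def _standardize(M: np.ndarray, names: list) -> np.ndarray:
    sd = M.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if len(zero):
        bad = [names[i] for i in zero]
        raise ValueError(f"columns with zero variance: {bad}")
    return (M - M.mean(axis=0)) / sd


def _as_matrix(data, default_prefix: str) -> tuple[np.ndarray, list]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.columns)
    M = np.asarray(data, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    return M, [f"{default_prefix}{i}" for i in range(M.shape[1])]


def cca_fit(symptoms, params, anchor: str | None = VULNERABILITY_ANCHOR) -> CCAResult:
    """Fit a CCA between two subject-aligned variable blocks.

    Both blocks are standardized column-wise; the canonical directions
    come from the SVD of Qx' Qy where Qx, Qy are orthonormal bases of the
    centered blocks.  Requires n > p + q + 1 and full column rank (the
    collinear columns are named in the error otherwise).  If ``anchor``
    names a symptom-side column, each dimension is sign-flipped (both
    sides together) so that column's coefficient is <= 0, making higher
    first-dimension scores mean greater vulnerability.
    """
    X, x_names = _as_matrix(symptoms, "x")
    Y, y_names = _as_matrix(params, "y")
    n, p = X.shape
    q = Y.shape[1]
    if Y.shape[0] != n:
        raise ValueError("blocks must have the same number of subjects")
    if n <= p + q + 1:
        raise ValueError(f"need n > p + q + 1 subjects (n={n}, p={p}, q={q})")
    Xz = _standardize(X, x_names)
    Yz = _standardize(Y, y_names)

    for M, names in ((Xz, x_names), (Yz, y_names)):
        r = np.linalg.matrix_rank(M)
        if r < M.shape[1]:
            # name the columns whose pivots vanish in a rank-revealing QR
            _, R, piv = linalg.qr(M, mode="economic", pivoting=True)
            d = np.abs(np.diag(R))
            bad = [names[j] for j in piv[d < d[0] * 1e-10]]
            raise ValueError(f"rank-deficient block; collinear columns: {bad}")

    Qx, Rx = np.linalg.qr(Xz)
    Qy, Ry = np.linalg.qr(Yz)
    U, s, Vt = np.linalg.svd(Qx.T @ Qy)
    d = min(p, q)
    s = np.clip(s[:d], 0.0, 1.0)
    # scale so canonical variates have unit sample variance
    A = np.linalg.solve(Rx, U[:, :d]) * np.sqrt(n - 1)
    B = np.linalg.solve(Ry, Vt.T[:, :d]) * np.sqrt(n - 1)

    if anchor is not None and anchor in x_names:
        j = x_names.index(anchor)
        flip = np.where(A[j] > 0, -1.0, 1.0)
        A *= flip
        B *= flip

    result = CCAResult(
        canonical_correlations=s,
        x_coef=A, y_coef=B,
        x_scores=Xz @ A, y_scores=Yz @ B,
        x_names=x_names, y_names=y_names, n=n,
    )
    lam, f, df1, df2, pval = wilks_test(s, n, p, q)
    result.wilks_lambda, result.f_stat, result.df, result.p_value = lam, f, (df1, df2), pval
    return result


def wilks_test(canonical_correlations, n: int, p: int, q: int, start_dim: int = 0):
    """Rao's F approximation to Wilks' lambda.

    Tests the null that canonical correlations from ``start_dim`` onward
    are all zero.  lambda = prod(1 - r_i^2) over the tested dimensions;
    for the all-dimensions test df1 = p * q.  With p = q = 1 the statistic
    reduces to the usual F test of a squared correlation.
    """
    r = np.asarray(canonical_correlations, dtype=float)[start_dim:]
    pp = p - start_dim
    qq = q - start_dim
    nn = n - start_dim
    lam = float(np.prod(1.0 - r**2))
    df1 = pp * qq
    if lam <= 0.0:
        return 0.0, np.inf, df1, np.inf, 0.0
    num = pp**2 * qq**2 - 4
    den = pp**2 + qq**2 - 5
    t = np.sqrt(num / den) if den > 0 and num > 0 else 1.0
    w = nn - (pp + qq + 3) / 2.0
    df2 = w * t - df1 / 2.0 + 1.0
    lam_t = lam ** (1.0 / t)
    f = (1.0 - lam_t) / lam_t * df2 / df1
    pval = float(stats.f.sf(f, df1, df2)) if df2 > 0 else np.nan
    return lam, float(f), df1, float(df2), pval


def sequential_dimension_tests(result: CCAResult, p: int | None = None, q: int | None = None) -> pd.DataFrame:
    """Test dimensions 1..d sequentially (each row: dims k..d jointly zero)."""
    p = p or len(result.x_names)
    q = q or len(result.y_names)
    rows = []
    for k in range(len(result.canonical_correlations)):
        lam, f, df1, df2, pval = wilks_test(result.canonical_correlations, result.n, p, q, start_dim=k)
        rows.append({"dimension": k + 1, "wilks_lambda": lam, "F": f,
                     "df1": df1, "df2": df2, "p_value": pval})
    return pd.DataFrame(rows)


def permutation_test(symptoms, params, n_permutations: int = 1000, seed: int = 0) -> float:
    """Permutation p-value for the first canonical correlation.

    Rows of the parameter block are permuted, breaking the subject link
    while preserving within-block structure; small-sample F approximations
    can be liberal, so this is the conservative alternative.
    """
    X, _ = _as_matrix(symptoms, "x")
    Y, _ = _as_matrix(params, "y")
    obs = cca_fit(X, Y, anchor=None).first_correlation
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(Y))
        r = cca_fit(X, Y[perm], anchor=None).first_correlation
        if r >= obs:
            n_ge += 1
    return (1.0 + n_ge) / (1.0 + n_permutations)


def vulnerability_scores(
    result: CCAResult,
    groups: pd.Series | np.ndarray | None = None,
    min_group_size: int = 3,
) -> dict:
    """First-dimension score pairs and optional within-group correlations.

    The symptom-side and parameter-side scores are the standardized-block
    projections on the first canonical dimension; their full-sample
    correlation equals the first canonical correlation by construction.
    Groups smaller than ``min_group_size`` are skipped with a warning
    entry rather than an error.
    """
    sx = result.x_scores[:, 0]
    sy = result.y_scores[:, 0]
    out: dict = {
        "symptom_scores": sx,
        "parameter_scores": sy,
        "correlation": float(np.corrcoef(sx, sy)[0, 1]),
    }
    if groups is not None:
        groups = np.asarray(groups)
        within = {}
        skipped = []
        for g in pd.unique(groups):
            sel = groups == g
            if sel.sum() < min_group_size:
                skipped.append(str(g))
                continue
            within[str(g)] = float(np.corrcoef(sx[sel], sy[sel])[0, 1])
        out["within_group_correlation"] = within
        if skipped:
            out["skipped_groups"] = skipped
    return out
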