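"""Canonical correlation analysis via SVD, with cross-modality explained variance.

Given two sample-aligned feature tables X (n x p) and Y (n x q), both
column-centered, take thin SVDs X = U1 S1 V1', Y = U2 S2 V2'; the singular
values of U1'U2 = U S V' are the canonical correlations.  The fraction of
X's variance recoverable through the canonical directions of Y is

    Var(X <- Y) = || diag(S1) (U o rho) ||_F^2 / || S1 ||_F^2

(rows weighted by X's singular values, columns by the squared canonical
correlations; ``o`` is the element-wise product broadcast over columns).
Significance of the full canonical structure uses Wilks' Lambda
``prod(1 - rho_j^2)`` with Rao's F approximation.

Covariates (e.g. age, sex, genetic PCs, scanner position) can be
residualized out of both sides before the CCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CCAResult", "residualize", "cca_svd", "explained_variance", "cca_f_test", "cca"]

_SV_TRUNC = 1e-10  # relative cutoff for near-zero singular values


@dataclass
class CCAResult:
    rho: np.ndarray
    var_x_from_y: float
    var_y_from_x: float
    n: int
    p: int
    q: int
    f_stat: float
    df1: float
    df2: float
    p_value: float

    def summary(self) -> dict:
        return {
            "rho": [float(r) for r in self.rho],
            "var_x_from_y": self.var_x_from_y,
            "var_y_from_x": self.var_y_from_x,
            "n": self.n,
            "p": self.p,
            "q": self.q,
            "f_stat": self.f_stat,
            "df1": self.df1,
            "df2": self.df2,
            "p_value": self.p_value,
        }


def _as2d(M) -> np.ndarray:
    arr = M.to_numpy() if isinstance(M, pd.DataFrame) else np.asarray(M, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a 2D sample x feature table")
    return arr.astype(np.float64)


def residualize(M, C) -> np.ndarray:
    """Replace each column of M by its least-squares residual on [1 | C].

    Residual columns are orthogonal to the intercept and to every covariate
    column.  Raises on rank-deficient covariates, naming the columns.
    """
    M = _as2d(M)
    C = _as2d(C)
    if M.shape[0] != C.shape[0]:
        raise ValueError("M and C have different sample counts")
    design = np.column_stack([np.ones(C.shape[0]), C])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name collinear columns by greedy QR-style elimination
        bad = []
        cols = [np.ones(C.shape[0])]
        for j in range(C.shape[1]):
            trial = np.column_stack(cols + [C[:, j]])
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(j)
            else:
                cols.append(C[:, j])
        raise ValueError(f"covariate columns {bad} are collinear with the rest")
    beta, *_ = np.linalg.lstsq(design, M, rcond=None)
    return M - design @ beta


def cca_svd(X, Y) -> tuple[np.ndarray, dict]:
    """Canonical correlations of X and Y plus the SVD parts.

    Returns ``(rho, parts)`` with ``parts`` holding U1,S1,V1,U2,S2,V2 and
    the inner-product SVD U,S,V.  Columns are centered internally;
    near-zero singular values are truncated before forming U1'U2 so the
    correlations stay in [0, 1] numerically.
    """
    X = _as2d(X)
    Y = _as2d(Y)
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("X and Y have different sample counts")
    p, q = X.shape[1], Y.shape[1]
    if n <= max(p, q):
        raise ValueError(f"need n > max(p, q); got n={n}, p={p}, q={q}")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    for name, Mc in (("X", Xc), ("Y", Yc)):
        zero = np.where(Mc.std(axis=0) == 0)[0]
        if zero.size:
            raise ValueError(f"{name} has zero-variance columns {zero.tolist()}")

    U1, S1, V1t = np.linalg.svd(Xc, full_matrices=False)
    U2, S2, V2t = np.linalg.svd(Yc, full_matrices=False)
    k1 = int((S1 > _SV_TRUNC * S1[0]).sum())
    k2 = int((S2 > _SV_TRUNC * S2[0]).sum())
    U1, S1, V1t = U1[:, :k1], S1[:k1], V1t[:k1]
    U2, S2, V2t = U2[:, :k2], S2[:k2], V2t[:k2]

    U, S, Vt = np.linalg.svd(U1.T @ U2, full_matrices=False)
    rho = np.clip(S, 0.0, 1.0)
    parts = {"U1": U1, "S1": S1, "V1": V1t.T, "U2": U2, "S2": S2, "V2": V2t.T, "U": U, "S": S, "V": Vt.T}
    return rho, parts


def explained_variance(S1: np.ndarray, U: np.ndarray, rho: np.ndarray) -> float:
    """Var(X <- Y): Frobenius ratio of diag(S1) @ (U * rho) to S1."""
    S1 = np.asarray(S1, dtype=np.float64)
    if not (S1 > 0).any():
        raise ValueError("all-zero singular values")
    weighted = (S1[:, None] * U) * rho[None, :]
    return float(np.sum(weighted**2) / np.sum(S1**2))


def cca_f_test(rho: np.ndarray, n: int, p: int, q: int) -> tuple[float, float, float, float]:
    """Rao's F approximation to Wilks' Lambda for all canonical correlations.

    Reduces to the usual F = (n-2) r^2 / (1-r^2) with df (1, n-2) when
    p = q = 1.
    """
    if n <= p + q + 1:
        raise ValueError(f"need n > p + q + 1; got n={n}, p={p}, q={q}")
    rho = np.asarray(rho, dtype=np.float64)
    lam = float(np.prod(1.0 - rho**2))
    df1 = p * q
    denom = p**2 + q**2 - 5
    s = np.sqrt((p**2 * q**2 - 4) / denom) if denom > 0 else 1.0
    df2 = (n - (p + q + 3) / 2.0) * s - p * q / 2.0 + 1.0
    lam_s = lam ** (1.0 / s) if lam > 0 else 0.0
    if lam_s == 0.0:
        return float("inf"), float(df1), float(df2), 0.0
    f = (1.0 - lam_s) / lam_s * (df2 / df1)
    p_value = float(stats.f.sf(f, df1, df2))
    return float(f), float(df1), float(df2), p_value


def cca(X, Y, covariates=None) -> CCAResult:
    """End-to-end CCA: optional symmetric covariate adjustment, SVD CCA,
    explained variance both ways, and the Wilks/Rao F-test."""
    Xa = _as2d(X)
    Ya = _as2d(Y)
    if covariates is not None:
        Xa = residualize(Xa, covariates)
        Ya = residualize(Ya, covariates)
    rho, parts = cca_svd(Xa, Ya)
    var_xy = explained_variance(parts["S1"], parts["U"], rho)
    var_yx = explained_variance(parts["S2"], parts["V"], rho)
    f, df1, df2, pval = cca_f_test(rho, Xa.shape[0], Xa.shape[1], Ya.shape[1])
    return CCAResult(
        rho=rho,
        var_x_from_y=var_xy,
        var_y_from_x=var_yx,
        n=Xa.shape[0],
        p=Xa.shape[1],
        q=Ya.shape[1],
        f_stat=f,
        df1=df1,
        df2=df2,
        p_value=pval,
    )
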