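"""Robust-regression decomposition of a deletion LFC profile.

The deletion profile is modelled as a linear combination of
single-perturbation LFC profiles, fitted by Huber M-estimation (IRLS,
tuning constant 1.345, MAD scale re-estimated each iteration), and the
fit is scored by distance correlation between observed and predicted
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "DecompositionResult",
    "huber_rlm",
    "distance_correlation",
    "decompose_deletion",
]


@dataclass
class DecompositionResult:
    coefficients: pd.Series  # per perturbation
    intercept: float
    dcor: float
    genes: pd.Index
    predicted: pd.Series  # predicted LFC per gene
    observed: pd.Series
    top_table: pd.DataFrame  # top-k by |predicted LFC|


def huber_rlm(
    y: np.ndarray,
    X: np.ndarray,
    tuning: float = 1.345,
    fit_intercept: bool = True,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, float]:
    """Huber M-estimator by iteratively reweighted least squares.

    Residual scale is the median absolute deviation (consistency factor
    1/0.6745), re-estimated every iteration. Converges when the largest
    coefficient change drops below ``tol`` or after ``max_iter``
    iterations. Returns (coefficients, intercept).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(y) != len(X):
        raise ValueError("y and X must have the same number of rows")
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values in regression inputs")
    A = np.column_stack([np.ones(len(y)), X]) if fit_intercept else X
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # name the offending columns for the caller
        _, r = np.linalg.qr(A)
        dep = np.flatnonzero(np.abs(np.diag(r)) < 1e-10 * np.abs(r).max())
        raise ValueError(f"rank-deficient design; collinear columns: {dep.tolist()}")

    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    for _ in range(max_iter):
        resid = y - A @ beta
        mad = np.median(np.abs(resid - np.median(resid)))
        scale = mad / 0.6745
        if scale < 1e-12:
            break  # (near-)exact fit
        u = resid / scale
        w = np.where(np.abs(u) <= tuning, 1.0, tuning / np.abs(u))
        wa = A * w[:, None]
        new_beta = np.linalg.solve(wa.T @ A, wa.T @ y)
        if np.max(np.abs(new_beta - beta)) < tol:
            beta = new_beta
            break
        beta = new_beta
    if fit_intercept:
        return beta[1:], float(beta[0])
    return beta, 0.0


def _center_distance_matrix(v: np.ndarray) -> np.ndarray:
    d = cdist(v, v, metric="euclidean")
    return d - d.mean(axis=0) - d.mean(axis=1)[:, None] + d.mean()


def distance_correlation(
    x: np.ndarray, y: np.ndarray, unbiased: bool = False
) -> float:
    """Distance correlation (V-statistic by default) between two samples.

    Returns 0 when either input has zero distance variance (constant
    input). With ``unbiased=True`` the U-statistic estimator is used
    (can be negative; returned clipped at 0 after the sign check).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if y.ndim == 1:
        y = y[:, None]
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if n < 4:
        raise ValueError("need n >= 4 observations")
    if not unbiased:
        a = _center_distance_matrix(x)
        b = _center_distance_matrix(y)
        dcov2 = (a * b).mean()
        dvarx = (a * a).mean()
        dvary = (b * b).mean()
    else:
        a = cdist(x, x)
        b = cdist(y, y)

        def ucenter(d):
            out = (
                d
                - d.sum(axis=0) / (n - 2)
                - d.sum(axis=1)[:, None] / (n - 2)
                + d.sum() / ((n - 1) * (n - 2))
            )
            np.fill_diagonal(out, 0.0)
            return out

        a, b = ucenter(a), ucenter(b)
        denom = n * (n - 3)
        dcov2 = (a * b).sum() / denom
        dvarx = (a * a).sum() / denom
        dvary = (b * b).sum() / denom
    if dvarx <= 0 or dvary <= 0:
        return 0.0
    r2 = dcov2 / np.sqrt(dvarx * dvary)
    return float(np.sqrt(max(r2, 0.0)))


def decompose_deletion(
    deletion_de: pd.DataFrame,
    perturbation_des: dict[str, pd.DataFrame],
    gene_rule=None,
    min_mean: float = 0.25,
    tuning: float = 1.345,
    fit_intercept: bool = True,
    top_k: int = 100,
) -> DecompositionResult:
    """Fit deletion LFCs as a Huber-robust linear combination of
    perturbation LFC profiles and score the fit by distance correlation.

    The gene set defaults to the intersection of all tables' tested
    genes with deletion-control mean expression above ``min_mean``; pass
    an explicit gene list via ``gene_rule`` to override.
    """
    if not perturbation_des:
        raise ValueError("need at least one perturbation DE table")
    shared = set(deletion_de["gene"])
    for de in perturbation_des.values():
        shared &= set(de["gene"])
    if gene_rule is not None:
        genes = pd.Index([g for g in gene_rule if g in shared])
    else:
        expressed = deletion_de.loc[
            deletion_de["baseMean_control"] > min_mean, "gene"
        ]
        genes = pd.Index(sorted(shared & set(expressed)))
    if len(genes) == 0:
        raise ValueError("empty shared gene universe")

    y = deletion_de.set_index("gene")["lfc_log2"].reindex(genes).to_numpy()
    names = list(perturbation_des)
    X = np.column_stack(
        [
            perturbation_des[n]
            .set_index("gene")["lfc_log2"]
            .reindex(genes)
            .to_numpy()
            for n in names
        ]
    )
    coef, intercept = huber_rlm(y, X, tuning=tuning, fit_intercept=fit_intercept)
    predicted = intercept + X @ coef
    d = distance_correlation(y, predicted)

    top_idx = np.argsort(-np.abs(predicted))[:top_k]
    top = pd.DataFrame(
        {
            "gene": genes[top_idx],
            "observed_lfc": y[top_idx],
            "predicted_lfc": predicted[top_idx],
        }
    )
    for j, n in enumerate(names):
        top[f"lfc_{n}"] = X[top_idx, j]
    return DecompositionResult(
        coefficients=pd.Series(coef, index=names, name="coefficient"),
        intercept=float(intercept),
        dcor=d,
        genes=genes,
        predicted=pd.Series(predicted, index=genes),
        observed=pd.Series(y, index=genes),
        top_table=top.reset_index(drop=True),
    )
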