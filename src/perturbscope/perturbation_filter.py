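"""Perturbation-strength calls, LDA mosaic filtering and Hotelling's T2.

A perturbation is relevant in a cell type when its pseudobulk contrast
yields at least ``min_degs`` genes at the FDR threshold. For relevant
perturbations, a two-class linear discriminant trained on the
perturbation-specific DEGs (control vs perturbation nuclei,
resubstitution prediction) removes guide-carrying nuclei whose
transcriptome looks like control — the unedited mosaic fraction.
Hotelling's T2 on PCA scores ranks perturbation separability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .matrix import AnnotatedCountMatrix
from .pseudobulk_de import NormalizedMatrix, run_contrast

__all__ = [
    "StrengthCall",
    "LdaFilterResult",
    "HotellingResult",
    "classify_perturbation_strength",
    "lda_filter_nuclei",
    "refit_de_after_filter",
    "hotelling_t2",
]


@dataclass
class StrengthCall:
    perturbation: str
    cell_type: str | None
    n_degs: int
    relevant: bool


@dataclass
class LdaFilterResult:
    predicted: pd.Series  # per-nucleus predicted label, indexed by barcode
    retained_barcodes: pd.Index
    perturbed_fraction: float
    deg_genes: list


@dataclass
class HotellingResult:
    t2: float
    f_stat: float
    pvalue: float
    n_pcs: int
    n_group: int
    n_control: int


def classify_perturbation_strength(
    de: pd.DataFrame,
    min_degs: int = 5,
    fdr: float = 0.05,
    perturbation: str = "",
    cell_type: str | None = None,
) -> StrengthCall:
    """Relevant iff the DE table has >= ``min_degs`` genes at FDR < ``fdr``."""
    n = int((de["fdr"] < fdr).sum())
    return StrengthCall(
        perturbation=perturbation,
        cell_type=cell_type,
        n_degs=n,
        relevant=n >= min_degs,
    )


def lda_filter_nuclei(
    norm: NormalizedMatrix,
    control_barcodes,
    perturbation_barcodes,
    deg_genes,
    shrinkage: float = 0.1,
    control_label: str = "control",
    perturbation_label: str = "perturbation",
) -> LdaFilterResult:
    """Remove perturbation nuclei predicted as control by a two-class LDA
    trained (and resubstitution-predicted) on log-normalized expression
    of the perturbation-specific DEGs. Control nuclei are always kept.
    """
    deg_genes = list(dict.fromkeys(deg_genes))  # dedup, order-stable
    if len(deg_genes) < 1:
        raise ValueError("need at least one DEG feature")
    gene_idx = norm.genes.get_indexer(pd.Index(deg_genes))
    if (gene_idx < 0).any():
        missing = [g for g, i in zip(deg_genes, gene_idx) if i < 0]
        raise KeyError(f"DEG features absent from matrix: {missing[:5]}")

    ctrl_idx = norm.barcodes.get_indexer(pd.Index(control_barcodes))
    pert_idx = norm.barcodes.get_indexer(pd.Index(perturbation_barcodes))
    if (ctrl_idx < 0).any() or (pert_idx < 0).any():
        raise KeyError("barcodes absent from normalized matrix")
    if len(ctrl_idx) < 2 or len(pert_idx) < 2:
        raise ValueError("need >= 2 nuclei per class")

    feats = norm.values[np.ix_(gene_idx, np.concatenate([ctrl_idx, pert_idx]))].T
    const = feats.std(axis=0) == 0
    if const.all():
        raise ValueError(
            f"all features constant: {[deg_genes[i] for i in np.flatnonzero(const)[:5]]}"
        )
    if const.any():
        warnings.warn(
            f"{const.sum()} constant LDA features dropped", stacklevel=2
        )
        feats = feats[:, ~const]
    n0 = len(ctrl_idx)
    w, thr = _fit_threshold(feats[:n0], feats[n0:], shrinkage)
    scores = feats @ w
    pred = np.where(scores > thr, perturbation_label, control_label)

    barcodes = np.concatenate(
        [np.asarray(control_barcodes), np.asarray(perturbation_barcodes)]
    )
    predicted = pd.Series(pred, index=pd.Index(barcodes, name="barcode"))
    pert_pred = pred[n0:]
    retained = pd.Index(
        np.concatenate(
            [np.asarray(control_barcodes), np.asarray(perturbation_barcodes)[pert_pred == perturbation_label]]
        ),
        name="barcode",
    )
    return LdaFilterResult(
        predicted=predicted,
        retained_barcodes=retained,
        perturbed_fraction=float((pert_pred == perturbation_label).mean()),
        deg_genes=deg_genes,
    )


def _fit_threshold(
    x_ctrl: np.ndarray, x_pert: np.ndarray, shrinkage: float
) -> tuple[np.ndarray, float]:
    """LDA direction and decision threshold with empirical priors."""
    n0, n1 = len(x_ctrl), len(x_pert)
    m0, m1 = x_ctrl.mean(axis=0), x_pert.mean(axis=0)
    d0 = x_ctrl - m0
    d1 = x_pert - m1
    pooled = (d0.T @ d0 + d1.T @ d1) / (n0 + n1 - 2)
    pooled = np.atleast_2d(pooled)
    p = pooled.shape[0]
    target = (np.trace(pooled) / p) * np.eye(p)
    reg = (1 - shrinkage) * pooled + shrinkage * target
    w = np.linalg.solve(reg, m1 - m0)
    # Gaussian two-class rule: predict class 1 when
    # w.(x - (m0+m1)/2) > log(prior0/prior1)
    thr = float(0.5 * (m0 + m1) @ w + np.log(n0 / n1))
    return w, thr


def refit_de_after_filter(
    counts: AnnotatedCountMatrix,
    filter_result: LdaFilterResult,
    group: str,
    control: str,
    fdr: float = 0.05,
    **contrast_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Re-run pseudobulk DE on retained nuclei only.

    Returns the new DE table plus a comparison record against the
    unfiltered contrast: DEG-count change and pre/post LFC correlation.
    """
    pre = run_contrast(counts, group, control, **contrast_kwargs)
    retained = counts.barcodes.isin(filter_result.retained_barcodes)
    # nuclei outside the contrast (other perturbations) stay as-is
    in_contrast = counts.metadata["perturbation"].isin([group, control]).to_numpy()
    keep = ~in_contrast | retained
    post = run_contrast(counts.subset_nuclei(keep), group, control, **contrast_kwargs)

    merged = pre.merge(post, on="gene", suffixes=("_pre", "_post"))
    comparison = {
        "n_degs_pre": int((pre["fdr"] < fdr).sum()),
        "n_degs_post": int((post["fdr"] < fdr).sum()),
        "lfc_correlation": float(
            np.corrcoef(merged["lfc_log2_pre"], merged["lfc_log2_post"])[0, 1]
        )
        if len(merged) > 2
        else np.nan,
    }
    comparison["delta_degs"] = comparison["n_degs_post"] - comparison["n_degs_pre"]
    return post, comparison


def hotelling_t2(
    norm: NormalizedMatrix,
    group_barcodes,
    control_barcodes,
    n_pcs: int = 20,
    scores: np.ndarray | None = None,
) -> HotellingResult:
    """Two-sample Hotelling's T2 on the first ``n_pcs`` PCA scores.

    PCA is computed once on the standardized expressed-gene matrix over
    all nuclei in ``norm`` (one shared basis per cell type); pass
    ``scores`` to reuse a precomputed nuclei x PC matrix.
    """
    if scores is None:
        scores = pca_scores(norm, n_pcs)
    n_pcs = min(n_pcs, scores.shape[1])
    gi = norm.barcodes.get_indexer(pd.Index(group_barcodes))
    ci = norm.barcodes.get_indexer(pd.Index(control_barcodes))
    if (gi < 0).any() or (ci < 0).any():
        raise KeyError("barcodes absent from normalized matrix")
    x, y = scores[gi, :n_pcs], scores[ci, :n_pcs]
    n1, n2 = len(x), len(y)
    if n1 + n2 <= n_pcs + 2:
        raise ValueError("combined group size must exceed n_pcs + 2")
    while n_pcs >= 1:
        xs, ys = x[:, :n_pcs], y[:, :n_pcs]
        d0 = xs - xs.mean(axis=0)
        d1 = ys - ys.mean(axis=0)
        pooled = (d0.T @ d0 + d1.T @ d1) / (n1 + n2 - 2)
        pooled = np.atleast_2d(pooled)
        try:
            sol = np.linalg.solve(pooled, xs.mean(axis=0) - ys.mean(axis=0))
            break
        except np.linalg.LinAlgError:
            warnings.warn(
                f"singular pooled covariance at {n_pcs} PCs; reducing",
                stacklevel=2,
            )
            n_pcs -= 1
    diff = xs.mean(axis=0) - ys.mean(axis=0)
    t2 = float(n1 * n2 / (n1 + n2) * diff @ sol)
    p = n_pcs
    df2 = n1 + n2 - p - 1
    f_stat = t2 * df2 / ((n1 + n2 - 2) * p)
    pvalue = float(f_dist.sf(f_stat, p, df2))
    return HotellingResult(
        t2=t2, f_stat=float(f_stat), pvalue=pvalue, n_pcs=n_pcs,
        n_group=n1, n_control=n2,
    )


def pca_scores(norm: NormalizedMatrix, n_pcs: int = 20) -> np.ndarray:
    """PCA scores (nuclei x components) of the z-scored expression matrix."""
    x = norm.values.T  # nuclei x genes
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = x / sd
    n_pcs = min(n_pcs, min(x.shape) - 1)
    # economical SVD: use covariance in the smaller dimension
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    return u[:, :n_pcs] * s[:n_pcs]
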