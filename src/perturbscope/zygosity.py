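"""Zygosity dissection: diffusion-map embedding and DC1 clustering.

Control plus one perturbation's nuclei are embedded with a Gaussian
kernel diffusion map (median-distance bandwidth, anisotropic alpha=1
normalization); the first diffusion component is clustered with 1-D
k-means (k=3) to separate control-like, intermediate (heterozygous-like)
and strong (homozygous-like) expression states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .matrix import AnnotatedCountMatrix
from .pseudobulk_de import NormalizedMatrix, run_contrast

__all__ = [
    "DiffusionEmbedding",
    "ZygosityLabels",
    "diffusion_map",
    "cluster_dc1",
    "zygosity_expression_contrast",
]

CLUSTER_NAMES = ("control-like", "intermediate", "strong")


@dataclass
class DiffusionEmbedding:
    coordinates: pd.DataFrame  # columns DC1, DC2, ... indexed by barcode
    eigenvalues: np.ndarray
    bandwidth: float
    is_control: pd.Series  # bool per barcode


@dataclass
class ZygosityLabels:
    labels: pd.Series  # per-barcode cluster name
    cluster_means: pd.Series  # cluster name -> mean DC1
    k: int


def diffusion_map(
    norm: NormalizedMatrix,
    is_control: np.ndarray,
    n_components: int = 2,
    bandwidth: float | None = None,
) -> DiffusionEmbedding:
    """Diffusion-map embedding of nuclei in normalized expression space.

    Gaussian kernel on Euclidean distances with the global
    median-pairwise-distance bandwidth (overridable), anisotropic
    normalization with alpha=1, then the row-normalized transition
    operator; the trivial constant eigenvector is dropped and components
    are ordered by descending eigenvalue. Sign convention: each
    component is oriented so the control-nuclei mean is <= the overall
    mean.
    """
    x = norm.values.T  # nuclei x genes
    n = x.shape[0]
    if n < 10:
        raise ValueError("need >= 10 nuclei for a diffusion map")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in expression matrix")
    is_control = np.asarray(is_control, dtype=bool)
    if len(is_control) != n:
        raise ValueError("is_control length mismatch")

    dist = pdist(x)
    if np.any(dist == 0):
        warnings.warn(
            "duplicate identical nuclei detected; kernel may be degenerate "
            "(consider jittering)",
            stacklevel=2,
        )
    sigma = float(np.median(dist)) if bandwidth is None else float(bandwidth)
    if sigma <= 0:
        raise ValueError("degenerate kernel: zero bandwidth")
    d2 = squareform(dist) ** 2
    k = np.exp(-d2 / (2.0 * sigma**2))

    # anisotropic (alpha = 1) normalization removes density effects
    q = k.sum(axis=1)
    k1 = k / np.outer(q, q)
    d = k1.sum(axis=1)
    # symmetric conjugate of the row-normalized transition operator
    dinv = 1.0 / np.sqrt(d)
    s = dinv[:, None] * k1 * dinv[None, :]
    s = 0.5 * (s + s.T)
    evals, evecs = np.linalg.eigh(s)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # right eigenvectors of the transition operator; drop the constant one
    phi = dinv[:, None] * evecs
    comps = phi[:, 1 : n_components + 1]
    comps = comps / np.linalg.norm(comps, axis=0)
    comps = comps * evals[1 : n_components + 1][None, :]

    # orientation: control mean below overall mean on every component
    for j in range(comps.shape[1]):
        if is_control.any() and comps[is_control, j].mean() > comps[:, j].mean():
            comps[:, j] = -comps[:, j]

    coords = pd.DataFrame(
        comps,
        index=norm.barcodes,
        columns=[f"DC{j + 1}" for j in range(comps.shape[1])],
    )
    return DiffusionEmbedding(
        coordinates=coords,
        eigenvalues=evals[1 : n_components + 1],
        bandwidth=sigma,
        is_control=pd.Series(is_control, index=norm.barcodes),
    )


def cluster_dc1(
    embedding: DiffusionEmbedding, k: int = 3, seed: int = 0, n_init: int = 50
) -> ZygosityLabels:
    """1-D k-means on DC1; clusters named by ascending distance of their
    mean from the control-nuclei mean (control-like -> strong)."""
    dc1 = embedding.coordinates["DC1"].to_numpy()
    if not np.isfinite(dc1).all():
        raise ValueError("non-finite DC1 values")
    if len(np.unique(dc1)) < k:
        raise ValueError(f"k={k} exceeds number of distinct DC1 values")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(dc1[:, None])
    centers = km.cluster_centers_.ravel()
    ctrl = embedding.is_control.to_numpy()
    ctrl_mean = dc1[ctrl].mean() if ctrl.any() else dc1.mean()
    order = np.argsort(np.abs(centers - ctrl_mean))
    if k == 3:
        names = list(CLUSTER_NAMES)
    else:
        names = [f"cluster{j + 1}" for j in range(k)]
    rename = {int(old): names[rank] for rank, old in enumerate(order)}
    labels = pd.Series(
        [rename[int(c)] for c in raw], index=embedding.coordinates.index,
        name="zygosity_cluster",
    )
    means = pd.Series(
        {names[rank]: float(centers[old]) for rank, old in enumerate(order)},
        name="mean_dc1",
    )
    return ZygosityLabels(labels=labels, cluster_means=means, k=k)


def zygosity_expression_contrast(
    counts: AnnotatedCountMatrix,
    labels: ZygosityLabels,
    control_label: str,
    fdr: float = 0.05,
    min_nuclei_per_cluster: int = 20,
    **contrast_kwargs,
) -> dict:
    """Per-cluster DE against control; reports DEG-identity overlap
    (Jaccard) between the intermediate and strong clusters and the ratio
    of their median |LFC| over the union of DEGs."""
    md = counts.metadata.copy()
    cluster = labels.labels.reindex(counts.barcodes)
    group_col = np.where(
        md["perturbation"] == control_label, control_label, cluster.fillna("")
    )
    md["zygosity_group"] = group_col
    acm = AnnotatedCountMatrix(counts.counts, counts.genes, counts.barcodes, md)

    tables: dict[str, pd.DataFrame] = {}
    skipped: list[str] = []
    for name in labels.cluster_means.index:
        n_in = int((md["zygosity_group"] == name).sum())
        if n_in < min_nuclei_per_cluster:
            skipped.append(name)
            continue
        tables[name] = run_contrast(
            acm, name, control_label, group_key="zygosity_group",
            **contrast_kwargs,
        )
    report: dict = {"tables": tables, "skipped": skipped}
    if {"intermediate", "strong"} <= set(tables):
        ti, ts = tables["intermediate"], tables["strong"]
        degs_i = set(ti.loc[ti["fdr"] < fdr, "gene"])
        degs_s = set(ts.loc[ts["fdr"] < fdr, "gene"])
        union = degs_i | degs_s
        report["jaccard"] = (
            len(degs_i & degs_s) / len(union) if union else np.nan
        )
        if union:
            gi = ti.set_index("gene")["lfc_log2"].reindex(sorted(union))
            gs = ts.set_index("gene")["lfc_log2"].reindex(sorted(union))
            med_i = float(np.nanmedian(np.abs(gi)))
            report["lfc_ratio_strong_over_intermediate"] = (
                float(np.nanmedian(np.abs(gs))) / med_i if med_i > 0 else np.nan
            )
    return report
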