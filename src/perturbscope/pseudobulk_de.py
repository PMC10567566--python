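"""Pseudobulk differential expression via negative-binomial GLM LRT.

Nuclei are summed into pseudobulk replicates (per lane for the screen,
per animal for cohorts), per-gene NB dispersions are estimated by
Cox-Reid adjusted profile likelihood with empirical-Bayes shrinkage
toward a common value, and each contrast is tested with a
likelihood-ratio test of the group coefficient against chi-square(1).
Effective library sizes use TMM normalization factors by default.

A single-cell comparator (per-gene logistic regression of group label on
log-normalized expression) is provided alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import gammaln
from scipy.stats import chi2

from .matrix import AnnotatedCountMatrix

__all__ = [
    "PseudobulkMatrix",
    "DispersionModel",
    "NormalizedMatrix",
    "filter_expressed_genes",
    "make_pseudobulk",
    "tmm_factors",
    "estimate_dispersions",
    "nb_glm_lrt",
    "single_cell_logreg_de",
    "normalize_log1p",
    "bh_adjust",
    "run_contrast",
]

DE_COLUMNS = ["gene", "baseMean_control", "lfc_log2", "lr_stat", "pvalue", "fdr"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PseudobulkMatrix:
    """Genes x samples summed counts with per-sample keys."""

    counts: np.ndarray  # dense, genes x samples, integer
    genes: pd.Index
    samples: pd.DataFrame  # columns: group, replicate, cell_type, n_nuclei
    norm_factors: np.ndarray | None = None  # TMM factors, geometric mean 1

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def effective_library_sizes(self) -> np.ndarray:
        libs = self.library_sizes.astype(float)
        if self.norm_factors is not None:
            libs = libs * self.norm_factors
        return libs

    def subset_groups(self, groups) -> "PseudobulkMatrix":
        mask = self.samples["group"].isin(groups).to_numpy()
        nf = self.norm_factors[mask] if self.norm_factors is not None else None
        return PseudobulkMatrix(
            counts=self.counts[:, mask],
            genes=self.genes,
            samples=self.samples.loc[mask].reset_index(drop=True),
            norm_factors=nf,
        )


@dataclass
class DispersionModel:
    """Raw, common and empirical-Bayes shrunken NB dispersions."""

    raw: np.ndarray
    common: float
    tagwise: np.ndarray
    prior_df: float = 10.0


@dataclass
class NormalizedMatrix:
    """log1p(CP10K) expression, genes x nuclei, dense."""

    values: np.ndarray
    genes: pd.Index
    barcodes: pd.Index
    dropped_barcodes: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# expression filter / pseudobulk construction
# ---------------------------------------------------------------------------


def filter_expressed_genes(
    counts: AnnotatedCountMatrix,
    control_label: str,
    min_mean: float = 0.25,
    group_col: str = "perturbation",
) -> pd.Index:
    """Genes whose mean raw UMI across control nuclei is strictly above
    ``min_mean`` (default 0.25 UMI per nucleus)."""
    mask = (counts.metadata[group_col] == control_label).to_numpy()
    if not mask.any():
        raise ValueError(f"no control nuclei labelled {control_label!r}")
    means = np.asarray(counts.counts[:, np.flatnonzero(mask)].mean(axis=1)).ravel()
    return counts.genes[means > min_mean]


def make_pseudobulk(
    counts: AnnotatedCountMatrix,
    replicate_key: str = "lane",
    group_key: str = "perturbation",
    cell_type: str | None = None,
    min_nuclei: int = 3,
) -> PseudobulkMatrix:
    """Sum raw UMI counts into one column per (group x replicate unit).

    Columns with fewer than ``min_nuclei`` member nuclei are dropped with
    a warning; a group losing all its columns raises.
    """
    md = counts.metadata
    for key in (replicate_key, group_key):
        if key not in md.columns:
            raise ValueError(f"metadata lacks column {key!r}")
    acm = counts
    if cell_type is not None:
        acm = counts.subset_nuclei((md["cell_type"] == cell_type).to_numpy())
        md = acm.metadata
        if acm.n_nuclei == 0:
            raise ValueError(f"no nuclei of cell type {cell_type!r}")

    groups = md[group_key].to_numpy()
    reps = md[replicate_key].to_numpy()
    keys = pd.DataFrame({"group": groups, "replicate": reps})
    uniq = keys.drop_duplicates().reset_index(drop=True)

    cols, meta_rows = [], []
    csc = acm.counts.tocsc()
    for _, row in uniq.iterrows():
        member = np.flatnonzero((groups == row["group"]) & (reps == row["replicate"]))
        if len(member) < min_nuclei:
            warnings.warn(
                f"pseudobulk column ({row['group']}, {row['replicate']}) has "
                f"{len(member)} nuclei < {min_nuclei}; dropped",
                stacklevel=2,
            )
            continue
        cols.append(np.asarray(csc[:, member].sum(axis=1)).ravel())
        meta_rows.append(
            (row["group"], row["replicate"], cell_type, len(member))
        )
    requested_groups = pd.unique(groups)
    kept_groups = {r[0] for r in meta_rows}
    for g in requested_groups:
        if g not in kept_groups:
            raise ValueError(
                f"group {g!r} has no pseudobulk column with >= {min_nuclei} nuclei"
            )
    mat = np.column_stack(cols).astype(np.int64)
    samples = pd.DataFrame(
        meta_rows, columns=["group", "replicate", "cell_type", "n_nuclei"]
    )
    return PseudobulkMatrix(counts=mat, genes=acm.genes, samples=samples)


def tmm_factors(
    counts: np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors (geometric mean 1).

    The reference column is the sample whose 75th-percentile expression
    fraction is closest to the mean across samples.
    """
    counts = np.asarray(counts, dtype=float)
    libs = counts.sum(axis=0)
    if (libs <= 0).any():
        raise ValueError("zero library size in pseudobulk matrix")
    q75 = np.array([np.quantile(counts[:, k] / libs[k], 0.75) for k in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.ones(counts.shape[1])
    yr, nr = counts[:, ref], libs[ref]
    for k in range(counts.shape[1]):
        if k == ref:
            continue
        yk, nk = counts[:, k], libs[k]
        ok = (yk > 0) & (yr > 0)
        if ok.sum() < 10:
            continue
        m = np.log2((yk[ok] / nk) / (yr[ok] / nr))
        a = 0.5 * np.log2((yk[ok] / nk) * (yr[ok] / nr))
        w = (nk - yk[ok]) / (nk * yk[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() == 0 or w[keep].sum() == 0:
            continue
        factors[k] = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    return factors / np.exp(np.mean(np.log(factors)))


# ---------------------------------------------------------------------------
# NB GLM machinery (vectorized across genes)
# ---------------------------------------------------------------------------


def _nb_loglik(y: np.ndarray, mu: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Rowwise NB log-likelihood; ``disp`` per gene (0 -> Poisson limit)."""
    mu = np.maximum(mu, 1e-300)
    d = np.asarray(disp, dtype=float)
    if d.ndim == 0:
        d = np.full(y.shape[0], float(d))
    out = np.empty(y.shape[0])
    pois = d < 1e-10
    if pois.any():
        out[pois] = np.sum(
            y[pois] * np.log(mu[pois]) - mu[pois] - gammaln(y[pois] + 1), axis=1
        )
    nb = ~pois
    if nb.any():
        r = (1.0 / d[nb])[:, None]
        yb, mb = y[nb], mu[nb]
        out[nb] = np.sum(
            gammaln(yb + r)
            - gammaln(r)
            - gammaln(yb + 1)
            + yb * np.log(mb)
            - yb * np.log(mb + r)
            + r * np.log(r)
            - r * np.log(mb + r),
            axis=1,
        )
    return out


def _fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    disp: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched IRLS fit of NB GLMs with log link and offsets.

    Parameters: ``y`` genes x samples counts, ``X`` samples x p design,
    ``offset`` per sample, ``disp`` per gene. Returns (beta genes x p,
    mu genes x samples). Steps are damped when the likelihood worsens.
    """
    g, s = y.shape
    p = X.shape[1]
    d = np.asarray(disp, dtype=float)
    if d.ndim == 0:
        d = np.full(g, float(d))

    # init: regress log pseudo-rates on X
    z0 = np.log((y + 0.5)) - offset[None, :]
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # genes x p
    eta = beta @ X.T + offset[None, :]
    eta = np.clip(eta, -30, 30)
    mu = np.exp(eta)
    ll = _nb_loglik(y, mu, d)

    for _ in range(max_iter):
        w = mu / (1.0 + d[:, None] * mu)  # working weights
        z = (eta - offset[None, :]) + (y - mu) / np.maximum(mu, 1e-12)
        xtwx = np.einsum("sp,gs,sq->gpq", X, w, X)
        xtwz = np.einsum("sp,gs,gs->gp", X, w, z)
        xtwx += 1e-10 * np.eye(p)[None, :, :]
        new_beta = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        step = new_beta - beta
        # damped update: halve the step while the likelihood decreases
        lam = np.ones(g)
        for _half in range(8):
            cand = beta + lam[:, None] * step
            eta_c = np.clip(cand @ X.T + offset[None, :], -30, 30)
            ll_c = _nb_loglik(y, np.exp(eta_c), d)
            bad = ll_c < ll - 1e-12
            if not bad.any():
                break
            lam[bad] *= 0.5
        beta = beta + lam[:, None] * step
        eta = np.clip(beta @ X.T + offset[None, :], -30, 30)
        mu = np.exp(eta)
        new_ll = _nb_loglik(y, mu, d)
        if np.max(np.abs(lam[:, None] * step)) < tol:
            ll = new_ll
            break
        ll = new_ll
    return beta, mu


def _cox_reid_adjustment(
    mu: np.ndarray, X: np.ndarray, disp: np.ndarray
) -> np.ndarray:
    """0.5 * logdet(X' W X) per gene (Cox-Reid profile adjustment)."""
    d = np.asarray(disp, dtype=float)
    if d.ndim == 0:
        d = np.full(mu.shape[0], float(d))
    w = mu / (1.0 + d[:, None] * mu)
    xtwx = np.einsum("sp,gs,sq->gpq", X, w, X)
    xtwx += 1e-10 * np.eye(X.shape[1])[None, :, :]
    sign, logdet = np.linalg.slogdet(xtwx)
    return 0.5 * logdet


_DISPERSION_GRID = np.concatenate([[0.0], np.logspace(-5, 1.5, 27)])


def estimate_dispersions(
    pb: PseudobulkMatrix,
    design: np.ndarray | None = None,
    prior_df: float = 10.0,
    grid: np.ndarray = _DISPERSION_GRID,
) -> DispersionModel:
    """Per-gene NB dispersion by maximum Cox-Reid adjusted profile
    likelihood over a dispersion grid, a common (pooled) dispersion, and
    tagwise empirical-Bayes shrinkage toward the common value.

    The shrunken estimate is a convex combination of raw and common with
    weight ``df_residual / (df_residual + prior_df)`` on the raw value,
    so it always lies between the two.
    """
    y = pb.counts.astype(float)
    if design is None:
        groups = pd.get_dummies(pb.samples["group"], dtype=float).to_numpy()
        design = groups
    X = np.asarray(design, dtype=float)
    s, p = X.shape
    if s - p < 1:
        raise ValueError(
            "design leaves no residual degrees of freedom; use a common "
            "dispersion (need >= 2 replicates per group)"
        )
    offset = np.log(pb.effective_library_sizes())
    apl = np.empty((y.shape[0], len(grid)))
    for j, d in enumerate(grid):
        _, mu = _fit_nb_glm(y, X, offset, d, max_iter=25)
        apl[:, j] = _nb_loglik(y, mu, d) - _cox_reid_adjustment(mu, X, d)
    raw = grid[np.argmax(apl, axis=1)]
    common = float(grid[np.argmax(apl.sum(axis=0))])
    df_res = s - p
    w_raw = df_res / (df_res + prior_df)
    tagwise = w_raw * raw + (1 - w_raw) * common
    return DispersionModel(raw=raw, common=common, tagwise=tagwise, prior_df=prior_df)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-aware)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    n = pv.size
    if n == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(n)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def nb_glm_lrt(
    pb: PseudobulkMatrix,
    disp: DispersionModel | np.ndarray | float,
    contrast: tuple[str, str],
) -> pd.DataFrame:
    """Likelihood-ratio test of group vs control on pseudobulk counts.

    Fits, per gene, an NB GLM with intercept + group indicator and
    log-effective-library-size offsets; the LR statistic is referred to
    chi-square with 1 df; LFC is the group coefficient in log2 units.
    """
    group, control = contrast
    sub = pb.subset_groups([group, control])
    labels = sub.samples["group"].to_numpy()
    if (labels == group).sum() < 2 or (labels == control).sum() < 2:
        raise ValueError("each contrast group needs >= 2 pseudobulk columns")
    d = disp.tagwise if isinstance(disp, DispersionModel) else disp

    y = sub.counts.astype(float)
    nonzero = y.sum(axis=1) > 0
    y = y[nonzero]
    genes = sub.genes[nonzero]
    d_arr = np.asarray(d, dtype=float)
    if d_arr.ndim == 1:
        d_arr = d_arr[nonzero]

    offset = np.log(sub.effective_library_sizes())
    X_full = np.column_stack(
        [np.ones(len(labels)), (labels == group).astype(float)]
    )
    X_null = X_full[:, :1]
    beta_f, mu_f = _fit_nb_glm(y, X_full, offset, d_arr)
    _, mu_n = _fit_nb_glm(y, X_null, offset, d_arr)
    ll_f = _nb_loglik(y, mu_f, d_arr)
    ll_n = _nb_loglik(y, mu_n, d_arr)
    stat = np.maximum(2.0 * (ll_f - ll_n), 0.0)
    pval = chi2.sf(stat, df=1)
    lfc = beta_f[:, 1] / np.log(2.0)

    ctrl_cols = labels == control
    base_mean = y[:, ctrl_cols].sum(axis=1) / sub.samples.loc[
        ctrl_cols, "n_nuclei"
    ].sum()
    table = pd.DataFrame(
        {
            "gene": genes,
            "baseMean_control": base_mean,
            "lfc_log2": lfc,
            "lr_stat": stat,
            "pvalue": pval,
            "fdr": bh_adjust(pval),
        }
    )
    table.attrs["contrast"] = {"group": group, "control": control}
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# single-cell comparator + normalization
# ---------------------------------------------------------------------------


def normalize_log1p(
    counts: AnnotatedCountMatrix | sp.spmatrix | np.ndarray,
    scale: float = 1e4,
) -> NormalizedMatrix:
    """CP10K log-normalization: x -> ln(1 + scale * x / column_total).

    Columns with zero total are dropped (and recorded) rather than
    producing NaNs.
    """
    if isinstance(counts, AnnotatedCountMatrix):
        mat, genes, barcodes = counts.counts, counts.genes, counts.barcodes
    else:
        mat = sp.csr_matrix(counts)
        genes = pd.Index(range(mat.shape[0]))
        barcodes = pd.Index(range(mat.shape[1]))
    totals = np.asarray(mat.sum(axis=0)).ravel().astype(float)
    keep = totals > 0
    dropped = list(barcodes[~keep])
    if dropped:
        warnings.warn(f"{len(dropped)} zero-total nuclei dropped", stacklevel=2)
    dense = np.asarray(mat[:, np.flatnonzero(keep)].todense(), dtype=float)
    dense = np.log1p(scale * dense / totals[keep][None, :])
    return NormalizedMatrix(
        values=dense, genes=genes, barcodes=barcodes[keep], dropped_barcodes=dropped
    )


def single_cell_logreg_de(
    norm: NormalizedMatrix,
    labels: np.ndarray,
    contrast: tuple[str, str],
    max_iter: int = 50,
) -> pd.DataFrame:
    """Per-gene logistic regression of group membership on normalized
    expression, LRT against the intercept-only model (chi-square, 1 df).

    Genes at a perfect-separation bound are flagged in the ``flagged``
    column; their p-values come from the likelihood at the iteration cap.
    """
    group, control = contrast
    mask = np.isin(labels, [group, control])
    yb = (labels[mask] == group).astype(float)  # samples
    Xg = norm.values[:, mask]  # genes x samples
    g, s = Xg.shape
    if s < 4:
        raise ValueError("need >= 4 nuclei in the contrast")

    pbar = yb.mean()
    ll_null = s * (pbar * np.log(max(pbar, 1e-12)) + (1 - pbar) * np.log(max(1 - pbar, 1e-12)))

    b0 = np.full(g, np.log(pbar / (1 - pbar)))
    b1 = np.zeros(g)
    flagged = np.zeros(g, dtype=bool)
    for _ in range(max_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * Xg, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        z = eta + (yb[None, :] - mu) / w
        sw = w.sum(axis=1)
        swx = (w * Xg).sum(axis=1)
        swxx = (w * Xg * Xg).sum(axis=1)
        swz = (w * z).sum(axis=1)
        swxz = (w * Xg * z).sum(axis=1)
        det = sw * swxx - swx**2
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        nb0 = (swxx * swz - swx * swxz) / det
        nb1 = (sw * swxz - swx * swz) / det
        bad = ~np.isfinite(nb0) | ~np.isfinite(nb1)
        nb0[bad], nb1[bad] = b0[bad], b1[bad]
        moved = np.max(np.abs(np.column_stack([nb0 - b0, nb1 - b1])), axis=1)
        b0, b1 = nb0, nb1
        if np.all(moved < 1e-9):
            break
    else:
        flagged |= moved >= 1e-9
    flagged |= np.abs(b1) > 25  # separation bound

    eta = np.clip(b0[:, None] + b1[:, None] * Xg, -30, 30)
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    ll_full = np.sum(yb[None, :] * np.log(mu) + (1 - yb[None, :]) * np.log(1 - mu), axis=1)
    stat = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    pval = chi2.sf(stat, df=1)
    ctrl_mean_expr = Xg[:, yb == 0].mean(axis=1)
    table = pd.DataFrame(
        {
            "gene": norm.genes,
            "baseMean_control": ctrl_mean_expr,
            "lfc_log2": (Xg[:, yb == 1].mean(axis=1) - ctrl_mean_expr) / np.log(2.0),
            "lr_stat": stat,
            "pvalue": pval,
            "fdr": bh_adjust(pval),
            "flagged": flagged,
        }
    )
    table.attrs["contrast"] = {"group": group, "control": control}
    return table


# ---------------------------------------------------------------------------
# high-level contrast runner
# ---------------------------------------------------------------------------


def run_contrast(
    counts: AnnotatedCountMatrix,
    group: str,
    control: str,
    cell_type: str | None = None,
    replicate_key: str = "lane",
    group_key: str = "perturbation",
    min_mean: float = 0.25,
    min_nuclei: int = 3,
    prior_df: float = 10.0,
    use_tmm: bool = True,
) -> pd.DataFrame:
    """Expression filter -> pseudobulk -> dispersion -> NB-GLM LRT,
    for one (group vs control, cell type) contrast."""
    sub = counts
    if cell_type is not None:
        sub = counts.subset_nuclei(
            (counts.metadata["cell_type"] == cell_type).to_numpy()
        )
    kept = filter_expressed_genes(sub, control, min_mean=min_mean, group_col=group_key)
    if len(kept) == 0:
        raise ValueError("no genes pass the expression filter")
    sub = sub.subset_genes(kept)
    keep_mask = sub.metadata[group_key].isin([group, control]).to_numpy()
    sub = sub.subset_nuclei(keep_mask)
    pb = make_pseudobulk(
        sub, replicate_key=replicate_key, group_key=group_key,
        min_nuclei=min_nuclei,
    )
    if use_tmm:
        pb.norm_factors = tmm_factors(pb.counts)
    disp = estimate_dispersions(pb, prior_df=prior_df)
    return nb_glm_lrt(pb, disp, contrast=(group, control))
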