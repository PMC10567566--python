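"""Gene programs, per-nucleus program scores and signature similarity.

Programs are the up/down DEG sets of a perturbation (|log2FC| > 0.5,
FDR < 0.01 by default). Program scores average z-scaled log-normalized
expression of program genes per nucleus. LFC profiles are compared by
Pearson correlation or cosine similarity over the union of DEGs, and
gene-set overlaps are tested with the upper-tail hypergeometric test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from .pseudobulk_de import NormalizedMatrix, bh_adjust

__all__ = [
    "GeneProgram",
    "OverlapTestResult",
    "define_gene_programs",
    "top_upregulated",
    "gene_program_score",
    "lfc_similarity",
    "hypergeometric_overlap",
]


@dataclass
class GeneProgram:
    perturbation: str
    direction: str  # "up" | "down"
    genes: list
    lfc_thresh: float = 0.5
    fdr_thresh: float = 0.01
    source: str = "screen"
    empty: bool = field(init=False)

    def __post_init__(self) -> None:
        self.genes = list(dict.fromkeys(self.genes))
        self.empty = len(self.genes) == 0


@dataclass
class OverlapTestResult:
    set_a: frozenset
    set_b: frozenset
    universe_size: int
    overlap: int
    pvalue: float
    fdr: float | None = None


def define_gene_programs(
    de: pd.DataFrame,
    perturbation: str = "",
    lfc_thresh: float = 0.5,
    fdr_thresh: float = 0.01,
    source: str = "screen",
) -> tuple[GeneProgram, GeneProgram]:
    """Split the post-filter DE table into up (LFC > t) and down
    (LFC < -t) programs at FDR < ``fdr_thresh`` (both strict)."""
    sig = de[de["fdr"] < fdr_thresh]
    up = sig.loc[sig["lfc_log2"] > lfc_thresh, "gene"].tolist()
    down = sig.loc[sig["lfc_log2"] < -lfc_thresh, "gene"].tolist()
    mk = lambda d, g: GeneProgram(  # noqa: E731
        perturbation, d, g, lfc_thresh, fdr_thresh, source
    )
    up_p, down_p = mk("up", up), mk("down", down)
    for prog in (up_p, down_p):
        if prog.empty:
            warnings.warn(
                f"{perturbation or 'perturbation'} {prog.direction} program "
                "is empty",
                stacklevel=2,
            )
    return up_p, down_p


def top_upregulated(de: pd.DataFrame, k: int = 20, fdr_thresh: float = 0.01) -> list:
    """Top-k upregulated genes ranked by LFC among FDR-significant genes;
    ties broken by smaller FDR then gene id."""
    sig = de[de["fdr"] < fdr_thresh].copy()
    sig = sig.sort_values(
        ["lfc_log2", "fdr", "gene"], ascending=[False, True, True]
    )
    return sig["gene"].head(k).tolist()


def gene_program_score(
    norm: NormalizedMatrix, program: GeneProgram
) -> pd.Series:
    """Per-nucleus mean of z-scaled (over all nuclei) normalized
    expression of the program genes."""
    genes = list(dict.fromkeys(program.genes))
    if not genes:
        raise ValueError("cannot score an empty program")
    idx = norm.genes.get_indexer(pd.Index(genes))
    present = idx >= 0
    if not present.any():
        raise ValueError("no program genes present in the matrix")
    if not present.all():
        warnings.warn(
            f"{(~present).sum()} program genes absent from matrix; dropped",
            stacklevel=2,
        )
    x = norm.values[idx[present]]
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    return pd.Series(z.mean(axis=0), index=norm.barcodes, name="program_score")


def _select_genes(de_tables: dict[str, pd.DataFrame], gene_rule) -> pd.Index:
    if isinstance(gene_rule, (list, tuple, pd.Index)):
        return pd.Index(gene_rule)
    if gene_rule == "union-of-degs":
        selected: set = set()
        for de in de_tables.values():
            sig = de[(de["fdr"] < 0.01) & (de["lfc_log2"].abs() > 0.5)]
            selected |= set(sig["gene"])
        return pd.Index(sorted(selected))
    raise ValueError(f"unknown gene rule {gene_rule!r}")


def lfc_similarity(
    de_tables: dict[str, pd.DataFrame],
    gene_rule="union-of-degs",
    metric: str = "pearson",
) -> pd.DataFrame:
    """Pairwise similarity of LFC vectors over a shared gene selection.

    ``gene_rule`` is ``"union-of-degs"`` (|LFC| > 0.5, FDR < 0.01 in at
    least one table) or an explicit gene list. The result carries the
    average-linkage leaf order in ``.attrs['leaf_order']`` and the gene
    set in ``.attrs['genes']``.
    """
    if len(de_tables) < 2:
        raise ValueError("need >= 2 DE tables")
    shared = None
    for de in de_tables.values():
        shared = set(de["gene"]) if shared is None else shared & set(de["gene"])
    genes = _select_genes(de_tables, gene_rule)
    genes = pd.Index([g for g in genes if g in shared])
    if len(genes) == 0:
        raise ValueError("empty gene selection for similarity")

    names = list(de_tables)
    mat = np.column_stack(
        [
            de_tables[n].set_index("gene")["lfc_log2"].reindex(genes).to_numpy()
            for n in names
        ]
    )
    if metric == "pearson":
        sim = np.corrcoef(mat.T)
        np.fill_diagonal(sim, 1.0)
    elif metric == "cosine":
        norms = np.linalg.norm(mat, axis=0)
        norms[norms == 0] = 1.0
        sim = (mat.T @ mat) / np.outer(norms, norms)
        sim = np.clip(sim, -1.0, 1.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    out = pd.DataFrame(sim, index=names, columns=names)
    if len(names) > 2:
        dist = squareform(np.maximum(1.0 - sim, 0.0), checks=False)
        link = average(dist)
        out.attrs["leaf_order"] = [names[i] for i in leaves_list(link)]
        out.attrs["linkage"] = link
    else:
        out.attrs["leaf_order"] = names
    out.attrs["genes"] = list(genes)
    return out


def hypergeometric_overlap(
    set_a, set_b, universe, n_lists_for_bh: int | None = None
) -> OverlapTestResult:
    """Upper-tail hypergeometric p-value for observing at least the given
    overlap between two gene sets drawn from ``universe``."""
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    a = frozenset(set_a) & universe
    b = frozenset(set_b) & universe
    if frozenset(set_a) - universe or frozenset(set_b) - universe:
        raise ValueError("sets must be subsets of the universe")
    k = len(a & b)
    n = len(universe)
    # P(X >= k) with X ~ Hypergeom(N=n, K=|a|, n=|b|)
    p = float(hypergeom.sf(k - 1, n, len(a), len(b)))
    return OverlapTestResult(
        set_a=a, set_b=b, universe_size=n, overlap=k, pvalue=min(p, 1.0)
    )


def adjust_overlap_family(results: list[OverlapTestResult]) -> list[OverlapTestResult]:
    """BH adjustment across a family of overlap tests (in place)."""
    fdrs = bh_adjust(np.array([r.pvalue for r in results]))
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
    return results
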