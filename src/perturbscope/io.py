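"""Readers and writers for the on-disk conventions.

Counts travel as Matrix Market (.mtx) with 10x-style ``features.tsv``
and ``barcodes.tsv`` sidecars plus a ``metadata.tsv`` nucleus table;
guide tables and truth tables are TSV; DE tables are CSV with a fixed
column order and a provenance header comment.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import __version__
from .matrix import AnnotatedCountMatrix
from .pseudobulk_de import DE_COLUMNS
from .synthetic_data import SyntheticDataset

log = logging.getLogger("perturbscope")

__all__ = [
    "load_count_matrix",
    "write_count_matrix",
    "write_dataset",
    "read_guide_table",
    "write_de_table",
    "read_de_table",
]


def write_count_matrix(acm: AnnotatedCountMatrix, outdir: str | Path) -> Path:
    """Write matrix.mtx + features.tsv + barcodes.tsv + metadata.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", sp.coo_matrix(acm.counts))
    pd.Series(acm.genes).to_csv(
        outdir / "features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(acm.barcodes).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    acm.metadata.to_csv(outdir / "metadata.tsv", sep="\t")
    return outdir


def load_count_matrix(indir: str | Path) -> AnnotatedCountMatrix:
    """Load the matrix.mtx / features / barcodes / metadata convention.

    Barcodes missing from the metadata table are excluded (counted in
    the log); a dimension mismatch between the mtx header and the
    sidecar files raises.
    """
    indir = Path(indir)
    for name in ("matrix.mtx", "features.tsv", "barcodes.tsv", "metadata.tsv"):
        if not (indir / name).exists():
            raise FileNotFoundError(indir / name)
    try:
        mat = scipy.io.mmread(indir / "matrix.mtx").tocsr()
    except ValueError as exc:
        raise ValueError(f"malformed Matrix Market file: {exc}") from exc
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    if mat.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"mtx header {mat.shape} does not match sidecars "
            f"({len(genes)} features, {len(barcodes)} barcodes)"
        )
    metadata = pd.read_csv(indir / "metadata.tsv", sep="\t", index_col=0)
    known = barcodes.isin(metadata.index)
    n_missing = int((~known).sum())
    if n_missing:
        log.warning("%d barcodes missing from metadata; excluded", n_missing)
        keep = np.flatnonzero(known.to_numpy())
        mat = mat[:, keep]
        barcodes = barcodes[known]
    return AnnotatedCountMatrix(
        counts=mat.astype(np.int64),
        genes=pd.Index(genes),
        barcodes=pd.Index(barcodes),
        metadata=metadata.loc[barcodes],
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> Path:
    """Write a synthetic dataset: counts convention + guide/truth TSVs."""
    outdir = Path(outdir)
    write_count_matrix(ds.counts, outdir)
    ds.guide_table.to_csv(outdir / "guide_table.tsv", sep="\t", index=False)
    ds.truth.nuclei.to_csv(outdir / "truth_nuclei.tsv", sep="\t")
    rows = [
        (target, gene, lfc)
        for target, prog in ds.truth.programs.items()
        for gene, lfc in prog.items()
    ]
    pd.DataFrame(rows, columns=["target", "gene", "true_lfc_log2"]).to_csv(
        outdir / "truth_programs.tsv", sep="\t", index=False
    )
    return outdir


def read_guide_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    return table


def _provenance_header(seed: int | None, config_hash: str | None) -> str:
    parts = [f"perturbscope v{__version__}"]
    if config_hash:
        parts.append(f"config={config_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return "# " + " ".join(parts) + "\n"


def config_hash(obj) -> str:
    return hashlib.sha256(repr(sorted(str(obj).split())).encode()).hexdigest()[:12]


def write_de_table(
    de: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config_digest: str | None = None,
) -> Path:
    """Write a DE table as CSV with the fixed column order and a
    provenance header comment."""
    path = Path(path)
    cols = [c for c in DE_COLUMNS if c in de.columns] + [
        c for c in de.columns if c not in DE_COLUMNS
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_provenance_header(seed, config_digest))
        de[cols].to_csv(fh, index=False)
    return path


def read_de_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
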