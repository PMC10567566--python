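"""End-to-end pipeline: configuration, staged execution and run log."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as psio
from .guide_assignment import GuideLibrary, assign_guides, filter_guide_records
from .matrix import AnnotatedCountMatrix
from .perturbation_filter import (
    classify_perturbation_strength,
    hotelling_t2,
    lda_filter_nuclei,
    pca_scores,
)
from .pseudobulk_de import normalize_log1p, run_contrast
from .signatures import define_gene_programs, lfc_similarity
from .synthetic_data import CONTROL_LABEL

log = logging.getLogger("perturbscope")

__all__ = ["PipelineConfig", "RunLog", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All paths and thresholds of the end-to-end run."""

    counts_dir: str = ""
    guide_table: str = ""
    guide_library: str = ""
    out_dir: str = "perturbscope_out"
    control_label: str = CONTROL_LABEL
    min_coverage: float = 60.0
    min_umi: int = 2
    min_fraction: float = 0.10
    min_mean: float = 0.25
    deg_lfc: float = 0.5
    deg_fdr: float = 0.01
    strength_fdr: float = 0.05
    min_degs: int = 5
    n_pcs: int = 20
    k_zygosity: int = 3
    lda_shrinkage: float = 0.1
    replicate_key: str = "lane"
    min_nuclei: int = 3
    cell_types: list[str] = field(default_factory=list)
    seed: int = 0

    def validate(self, check_paths: bool = True) -> None:
        for name in (
            "min_coverage",
            "min_umi",
            "min_fraction",
            "min_mean",
            "deg_lfc",
            "deg_fdr",
            "strength_fdr",
            "min_degs",
            "n_pcs",
            "k_zygosity",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if check_paths:
            for name in ("counts_dir", "guide_table", "guide_library"):
                p = getattr(self, name)
                if p and not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


class RunLog:
    """Structured begin/end events per stage, serializable to JSON."""

    def __init__(self) -> None:
        self.events: list[dict] = []

    def stage(self, name: str):
        outer = self

        class _Stage:
            def __enter__(self):
                self.t0 = time.time()
                outer.events.append({"stage": name, "event": "begin"})
                return self

            def note(self, **kw):
                outer.events.append({"stage": name, "event": "note", **kw})

            def __exit__(self, exc_type, exc, tb):
                outer.events.append(
                    {
                        "stage": name,
                        "event": "end" if exc_type is None else "error",
                        "wall_s": round(time.time() - self.t0, 3),
                        **({"error": str(exc)} if exc else {}),
                    }
                )
                return False

        return _Stage()

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.events, fh, indent=1)


def run_pipeline(
    config: PipelineConfig,
    counts: AnnotatedCountMatrix | None = None,
    guide_table: pd.DataFrame | None = None,
    library: GuideLibrary | None = None,
    deletion_de: pd.DataFrame | None = None,
) -> dict:
    """Run guide assignment -> DE -> strength calls -> LDA filter ->
    refit -> programs/similarity (-> decomposition when a deletion DE
    table is supplied). Objects may be passed directly or loaded from
    the configured paths. Returns a dict of artifacts; everything is
    also written under ``config.out_dir``.
    """
    config.validate(check_paths=counts is None)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runlog = RunLog()
    # digest covers analysis parameters only, not paths, so identical
    # analyses in different directories produce identical outputs
    params = {
        k: v
        for k, v in asdict(config).items()
        if k not in ("counts_dir", "guide_table", "guide_library", "out_dir")
    }
    digest = psio.config_hash(params)
    artifacts: dict = {}

    with runlog.stage("load"):
        if counts is None:
            counts = psio.load_count_matrix(config.counts_dir)
        if guide_table is None:
            guide_table = psio.read_guide_table(config.guide_table)
        if library is None:
            library = GuideLibrary.from_tsv(config.guide_library)

    with runlog.stage("assign_guides") as st:
        filtered = filter_guide_records(
            guide_table,
            min_coverage=config.min_coverage,
            min_umi=config.min_umi,
            min_fraction=config.min_fraction,
        )
        assignments = assign_guides(filtered, library, all_barcodes=counts.barcodes)
        st.note(
            n_records_in=len(guide_table),
            n_records_kept=len(filtered),
            n_unique=int((assignments["status"] == "unique").sum()),
        )
        assignments.to_csv(out / "guide_assignments.tsv", sep="\t", index=False)
        artifacts["assignments"] = assignments

    # restrict to uniquely assigned nuclei; label with the guide's target
    unique = assignments[assignments["status"] == "unique"]
    keep = counts.barcodes.isin(unique["barcode"])
    analysed = counts.subset_nuclei(keep.to_numpy() if hasattr(keep, "to_numpy") else keep)
    target_of = unique.set_index("barcode")["target"]
    md = analysed.metadata.copy()
    md["perturbation"] = target_of.reindex(analysed.barcodes).to_numpy()
    analysed = AnnotatedCountMatrix(
        analysed.counts, analysed.genes, analysed.barcodes, md
    )

    cell_types = config.cell_types or sorted(md["cell_type"].unique())
    perturbations = sorted(set(md["perturbation"]) - {config.control_label})

    de_tables: dict[tuple[str, str], pd.DataFrame] = {}
    strength: list = []
    filters: dict = {}
    refit_tables: dict = {}
    programs: dict = {}

    for ct in cell_types:
        ct_counts = analysed.subset_nuclei(
            (analysed.metadata["cell_type"] == ct).to_numpy()
        )
        if ct_counts.n_nuclei == 0:
            continue
        norm = normalize_log1p(ct_counts)
        ctrl_bc = ct_counts.barcodes[
            (ct_counts.metadata["perturbation"] == config.control_label).to_numpy()
        ]
        scores = None
        for pert in perturbations:
            pert_bc = ct_counts.barcodes[
                (ct_counts.metadata["perturbation"] == pert).to_numpy()
            ]
            if len(pert_bc) < 2 * config.min_nuclei:
                continue
            with runlog.stage(f"de:{ct}:{pert}") as st:
                try:
                    de = run_contrast(
                        analysed,
                        pert,
                        config.control_label,
                        cell_type=ct,
                        replicate_key=config.replicate_key,
                        min_mean=config.min_mean,
                        min_nuclei=config.min_nuclei,
                    )
                except ValueError as exc:
                    st.note(skipped=str(exc))
                    continue
                de_tables[(ct, pert)] = de
                psio.write_de_table(
                    de, out / f"de_{ct}_{pert}.csv", seed=config.seed,
                    config_digest=digest,
                )
            call = classify_perturbation_strength(
                de, min_degs=config.min_degs, fdr=config.strength_fdr,
                perturbation=pert, cell_type=ct,
            )
            strength.append(call)
            if not call.relevant:
                continue
            with runlog.stage(f"filter:{ct}:{pert}") as st:
                degs = de.loc[de["fdr"] < config.strength_fdr, "gene"].tolist()
                try:
                    res = lda_filter_nuclei(
                        norm, ctrl_bc, pert_bc, degs,
                        shrinkage=config.lda_shrinkage,
                        control_label=config.control_label,
                        perturbation_label=pert,
                    )
                except (ValueError, KeyError) as exc:
                    st.note(skipped=str(exc))
                    continue
                filters[(ct, pert)] = res
                st.note(perturbed_fraction=res.perturbed_fraction)
            with runlog.stage(f"refit:{ct}:{pert}") as st:
                retained = analysed.barcodes.isin(res.retained_barcodes) | ~analysed.barcodes.isin(
                    np.concatenate([ctrl_bc, pert_bc])
                )
                try:
                    refit = run_contrast(
                        analysed.subset_nuclei(retained.to_numpy() if hasattr(retained, "to_numpy") else retained),
                        pert,
                        config.control_label,
                        cell_type=ct,
                        replicate_key=config.replicate_key,
                        min_mean=config.min_mean,
                        min_nuclei=config.min_nuclei,
                    )
                except ValueError as exc:
                    st.note(skipped=str(exc))
                    continue
                refit_tables[(ct, pert)] = refit
                psio.write_de_table(
                    refit, out / f"de_refit_{ct}_{pert}.csv", seed=config.seed,
                    config_digest=digest,
                )
                up, down = define_gene_programs(
                    refit, perturbation=pert, lfc_thresh=config.deg_lfc,
                    fdr_thresh=config.deg_fdr,
                )
                programs[(ct, pert)] = (up, down)
            with runlog.stage(f"hotelling:{ct}:{pert}") as st:
                if scores is None:
                    scores = pca_scores(norm, config.n_pcs)
                try:
                    ht = hotelling_t2(
                        norm, pert_bc, ctrl_bc, n_pcs=config.n_pcs, scores=scores
                    )
                    st.note(t2=ht.t2, p=ht.pvalue)
                    artifacts.setdefault("hotelling", {})[(ct, pert)] = ht
                except ValueError as exc:
                    st.note(skipped=str(exc))

    summary = pd.DataFrame(
        [
            {
                "cell_type": s.cell_type,
                "perturbation": s.perturbation,
                "n_degs": s.n_degs,
                "relevant": s.relevant,
                "perturbed_fraction": (
                    filters[(s.cell_type, s.perturbation)].perturbed_fraction
                    if (s.cell_type, s.perturbation) in filters
                    else np.nan
                ),
            }
            for s in strength
        ]
    )
    summary.to_csv(out / "perturbation_summary.csv", index=False)

    with runlog.stage("similarity") as st:
        sims = {}
        for ct in cell_types:
            named = {
                pert: t for (c, pert), t in refit_tables.items() if c == ct
            }
            if len(named) >= 2:
                try:
                    sims[ct] = lfc_similarity(named)
                    sims[ct].to_csv(out / f"similarity_{ct}.csv")
                except ValueError as exc:
                    st.note(cell_type=ct, skipped=str(exc))
        artifacts["similarity"] = sims

    if deletion_de is not None:
        from .decomposition import decompose_deletion

        with runlog.stage("decomposition"):
            per_pert = {}
            for (ct, pert), t in refit_tables.items():
                per_pert.setdefault(pert, t)  # first cell type wins
            if per_pert:
                dec = decompose_deletion(deletion_de, per_pert)
                artifacts["decomposition"] = dec
                with open(out / "decomposition.json", "w") as fh:
                    json.dump(
                        {
                            "coefficients": dec.coefficients.to_dict(),
                            "intercept": dec.intercept,
                            "dcor": dec.dcor,
                        },
                        fh,
                        indent=1,
                    )
                dec.top_table.to_csv(out / "decomposition_top.csv", index=False)
    else:
        runlog.events.append(
            {"stage": "decomposition", "event": "skipped", "reason": "no deletion DE"}
        )

    runlog.write(out / "run_log.json")
    artifacts.update(
        de_tables=de_tables,
        refit_tables=refit_tables,
        strength=strength,
        filters=filters,
        programs=programs,
        summary=summary,
        runlog=runlog,
    )
    return artifacts
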