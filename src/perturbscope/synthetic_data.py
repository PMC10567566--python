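"""Synthetic pooled-screen and deletion-cohort generator with ground truth.

Generates gene x nucleus UMI count matrices, per-nucleus guide capture
tables and truth bookkeeping with the statistical structure the
downstream analysis assumes:

* negative-binomial (gamma-Poisson) counts with per-gene dispersion and
  lognormal per-nucleus library sizes;
* a guide library of target guides plus safe-harbour controls;
* editing mosaicism — a guide-carrying nucleus is loss-of-function with
  probability ``mosaic_fraction``, and perturbed nuclei are homozygous
  or heterozygous (heterozygous effects scaled by ``het_effect_scale``);
* per-perturbation up/down gene programs acting multiplicatively on
  expression rates;
* ambient guide contamination with low UMI counts and low read coverage;
* a deletion cohort whose deleted genes run at half dosage and whose
  remaining transcriptome is a weighted combination of single-gene
  perturbation programs.

Randomness comes from one seed; independent substreams are spawned in a
fixed, documented order (programs, baselines, nuclei, counts, guides) so
each component regenerates reproducibly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix import AnnotatedCountMatrix

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SyntheticDataset",
    "default_guide_library",
    "simulate_screen",
    "simulate_guide_capture",
    "simulate_deletion_cohort",
]

CONTROL_LABEL = "SH-control"

#: fixed substream order spawned from the config seed
_SUBSTREAMS = ("programs", "baselines", "nuclei", "counts", "guides")


def default_guide_library(
    n_targets: int = 29, guides_per_target: int = 2, n_controls: int = 5
) -> pd.DataFrame:
    """Guide library mirroring the screen design: ``n_targets`` genes with
    ``guides_per_target`` guides each plus ``n_controls`` safe-harbour guides.

    Returns a table with columns ``guide_id``, ``target``, ``is_control``.
    """
    rows = []
    for t in range(n_targets):
        target = f"Tgt{t:02d}"
        for g in range(guides_per_target):
            rows.append((f"{target}_g{g + 1}", target, False))
    for c in range(n_controls):
        rows.append((f"SH_g{c + 1}", CONTROL_LABEL, True))
    return pd.DataFrame(rows, columns=["guide_id", "target", "is_control"])


@dataclass
class SimulationConfig:
    """Parameters of the synthetic screen generator."""

    n_genes: int = 2000
    cell_types: dict[str, float] = field(
        default_factory=lambda: {
            "excitatory_L23": 0.25,
            "excitatory_L5": 0.20,
            "excitatory_L6": 0.15,
            "interneuron": 0.20,
            "astrocyte": 0.12,
            "oligodendrocyte": 0.08,
        }
    )
    n_nuclei: int = 5000
    n_lanes: int = 9
    guide_library: pd.DataFrame = field(default_factory=default_guide_library)
    mosaic_fraction: float = 0.5
    zygosity_split: float = 0.5
    het_effect_scale: float = 0.5
    program_size: int = 50
    effect_lfc: float = 1.0
    nb_dispersion: float = 0.05
    library_size_lognormal: tuple[float, float] = (8.0, 0.35)
    ambient_rate: float = 0.2
    guide_dropout: float = 0.0
    guide_mean_umi: float = 25.0
    coverage_factor: float = 100.0
    #: program genes are drawn from baselines above this expression
    #: quantile — differential expression is only observable on genes
    #: that are actually expressed
    program_expression_quantile: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("mosaic_fraction", "zygosity_split", "guide_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_genes", "n_nuclei", "n_lanes", "program_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.effect_lfc < 0:
            raise ValueError("effect_lfc must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.ambient_rate < 0:
            raise ValueError("ambient_rate must be >= 0")
        if self.het_effect_scale < 0:
            raise ValueError("het_effect_scale must be >= 0")
        lib = self.guide_library
        if not isinstance(lib, pd.DataFrame) or not {
            "guide_id",
            "target",
            "is_control",
        } <= set(lib.columns):
            raise ValueError(
                "guide_library must have columns guide_id, target, is_control"
            )
        if not lib["is_control"].any():
            raise ValueError("guide_library must contain >= 1 control guide")
        if lib["guide_id"].duplicated().any():
            raise ValueError("guide ids must be unique")
        freqs = np.asarray(list(self.cell_types.values()), dtype=float)
        if len(freqs) == 0 or (freqs < 0).any() or freqs.sum() <= 0:
            raise ValueError("cell_types must give non-negative frequencies")

    def targets(self) -> list[str]:
        """Non-control target genes, in library order."""
        lib = self.guide_library
        return list(dict.fromkeys(lib.loc[~lib["is_control"], "target"]))

    def rngs(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_SUBSTREAMS))
        return {
            name: np.random.default_rng(seq)
            for name, seq in zip(_SUBSTREAMS, children)
        }


@dataclass
class SimulationTruth:
    """Ground truth: per-nucleus states and per-perturbation programs.

    ``nuclei`` is indexed by barcode with columns ``guide_id``, ``target``,
    ``perturbed``, ``zygosity`` (control/het/hom), ``lane``, ``animal``,
    ``cell_type``. ``programs`` maps target -> {gene -> signed true log2FC}
    (positive = up program, negative = down program).
    """

    nuclei: pd.DataFrame
    programs: dict[str, dict[str, float]]

    def program_lfc_vector(self, target: str, genes: pd.Index) -> np.ndarray:
        vec = np.zeros(len(genes))
        prog = self.programs.get(target, {})
        if prog:
            idx = genes.get_indexer(pd.Index(list(prog)))
            vec[idx] = np.fromiter(prog.values(), dtype=float)
        return vec


@dataclass
class SyntheticDataset:
    counts: AnnotatedCountMatrix
    guide_table: pd.DataFrame
    truth: SimulationTruth


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _gene_index(n_genes: int) -> pd.Index:
    return pd.Index([f"Gene{i:05d}" for i in range(n_genes)], name="gene")


def _assign_programs(
    config: SimulationConfig,
    rng: np.random.Generator,
    base_weights: np.ndarray | None = None,
) -> dict[str, dict[str, float]]:
    """Disjoint up/down program gene sets per target, constant |log2FC|.

    Candidate genes come from baselines above
    ``program_expression_quantile`` when base weights are supplied.
    """
    targets = config.targets()
    genes = _gene_index(config.n_genes)
    if base_weights is not None:
        cutoff = np.quantile(base_weights, config.program_expression_quantile)
        candidates = np.flatnonzero(base_weights >= cutoff)
    else:
        candidates = np.arange(config.n_genes)
    needed = 2 * config.program_size * len(targets)
    if needed > len(candidates):
        raise ValueError(
            f"program assignment needs {needed} genes but only "
            f"{len(candidates)} candidate genes are available "
            f"({config.n_genes} simulated)"
        )
    order = candidates[rng.permutation(len(candidates))]
    programs: dict[str, dict[str, float]] = {}
    pos = 0
    for target in targets:
        up = order[pos : pos + config.program_size]
        pos += config.program_size
        down = order[pos : pos + config.program_size]
        pos += config.program_size
        prog = {genes[i]: float(config.effect_lfc) for i in up}
        prog.update({genes[i]: -float(config.effect_lfc) for i in down})
        programs[target] = prog
    return programs


def _baseline_rates(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Shared base expression plus per-cell-type relative weights
    (weights sum to 1 per type)."""
    base = rng.lognormal(mean=0.0, sigma=1.2, size=config.n_genes)
    weights = {}
    for ct in config.cell_types:
        jitter = rng.lognormal(mean=0.0, sigma=0.25, size=config.n_genes)
        w = base * jitter
        weights[ct] = w / w.sum()
    return base, weights


def _sample_counts(
    mu: np.ndarray, dispersion: float | np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Gamma-Poisson draw, elementwise mean ``mu``; dispersion 0 -> Poisson."""
    disp = np.asarray(dispersion, dtype=float)
    if np.all(disp == 0):
        return rng.poisson(mu)
    if disp.ndim == 1:  # per-gene, mu is genes x nuclei
        disp = disp[:, None]
    shape = np.where(disp > 0, 1.0 / np.maximum(disp, 1e-12), np.inf)
    lam = np.where(
        disp > 0, rng.gamma(np.minimum(shape, 1e12), 1.0) * mu * disp, mu
    )
    return rng.poisson(lam)


def _simulate_counts_for_nuclei(
    config: SimulationConfig,
    nuclei: pd.DataFrame,
    programs: dict[str, dict[str, float]],
    weights: dict[str, np.ndarray],
    rng: np.random.Generator,
    extra_lfc: dict[str, np.ndarray] | None = None,
    chunk: int = 512,
) -> sp.csr_matrix:
    """NB counts for each nucleus; rate = cell-type baseline x library size
    x 2^(zygosity-scaled program LFC) [x 2^extra condition LFC]."""
    genes = _gene_index(config.n_genes)
    n = len(nuclei)
    mu_log, sd_log = config.library_size_lognormal
    lib = rng.lognormal(mean=mu_log, sigma=sd_log, size=n)

    # per-nucleus signed LFC scale: 0 control, het_effect_scale het, 1 hom
    scale = np.zeros(n)
    scale[nuclei["zygosity"].to_numpy() == "het"] = config.het_effect_scale
    scale[nuclei["zygosity"].to_numpy() == "hom"] = 1.0

    prog_vectors = {
        t: SimulationTruth(nuclei, programs).program_lfc_vector(t, genes)
        for t in programs
    }
    ct_arr = nuclei["cell_type"].to_numpy()
    tg_arr = nuclei["target"].to_numpy()
    cond_arr = (
        nuclei["condition"].to_numpy()
        if "condition" in nuclei.columns
        else np.array([""] * n)
    )

    blocks = []
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        mu = np.empty((config.n_genes, stop - start))
        for j in range(start, stop):
            lfc = np.zeros(config.n_genes)
            if scale[j] > 0 and tg_arr[j] in prog_vectors:
                lfc = scale[j] * prog_vectors[tg_arr[j]]
            if extra_lfc is not None and cond_arr[j] in extra_lfc:
                lfc = lfc + extra_lfc[cond_arr[j]]
            mu[:, j - start] = lib[j] * weights[ct_arr[j]] * np.exp2(lfc)
        counts = _sample_counts(mu, config.nb_dispersion, rng)
        blocks.append(sp.csr_matrix(counts.astype(np.int64)))
    return sp.hstack(blocks, format="csr") if blocks else sp.csr_matrix(
        (config.n_genes, 0), dtype=np.int64
    )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def planned_programs(config: SimulationConfig) -> dict[str, dict[str, float]]:
    """The program assignment a simulation with this config will use,
    without generating counts."""
    rngs = config.rngs()
    base, _ = _baseline_rates(config, rngs["baselines"])
    return _assign_programs(config, rngs["programs"], base)


def baseline_expression(config: SimulationConfig) -> pd.Series:
    """Expected per-gene relative expression (shared base, pre-jitter)."""
    base, _ = _baseline_rates(config, config.rngs()["baselines"])
    return pd.Series(base / base.sum(), index=_gene_index(config.n_genes))


def simulate_screen(config: SimulationConfig) -> SyntheticDataset:
    """Simulate a pooled screen: nuclei with guides, mosaicism and programs.

    Control-guide nuclei are always unperturbed; a non-control-guide
    nucleus is loss-of-function with probability ``mosaic_fraction`` and,
    if perturbed, homozygous with probability ``zygosity_split``.
    """
    config.validate()
    rngs = config.rngs()
    base, weights = _baseline_rates(config, rngs["baselines"])
    programs = _assign_programs(config, rngs["programs"], base)

    rng = rngs["nuclei"]
    n = config.n_nuclei
    ct_names = list(config.cell_types)
    ct_freqs = np.asarray(list(config.cell_types.values()), dtype=float)
    ct_freqs = ct_freqs / ct_freqs.sum()
    cell_type = rng.choice(ct_names, size=n, p=ct_freqs)
    for ct in ct_names:
        if not (cell_type == ct).any():
            warnings.warn(f"no nuclei drawn for cell type {ct!r}", stacklevel=2)
    lane = rng.integers(1, config.n_lanes + 1, size=n)

    lib = config.guide_library.reset_index(drop=True)
    gidx = rng.integers(0, len(lib), size=n)
    guide_id = lib["guide_id"].to_numpy()[gidx]
    target = lib["target"].to_numpy()[gidx]
    is_control = lib["is_control"].to_numpy()[gidx]

    perturbed = (~is_control) & (rng.random(n) < config.mosaic_fraction)
    zygosity = np.where(
        perturbed,
        np.where(rng.random(n) < config.zygosity_split, "hom", "het"),
        "control",
    )

    barcodes = pd.Index([f"BC{i:06d}" for i in range(n)], name="barcode")
    nuclei = pd.DataFrame(
        {
            "guide_id": guide_id,
            "target": target,
            "perturbed": perturbed,
            "zygosity": zygosity,
            "lane": lane,
            "animal": [f"A{l}" for l in lane],
            "cell_type": cell_type,
        },
        index=barcodes,
    )
    truth = SimulationTruth(nuclei=nuclei, programs=programs)

    counts = _simulate_counts_for_nuclei(
        config, nuclei, programs, weights, rngs["counts"]
    )
    metadata = nuclei[["lane", "animal", "cell_type"]].copy()
    metadata["perturbation"] = np.where(is_control, CONTROL_LABEL, target)
    acm = AnnotatedCountMatrix(
        counts=counts, genes=_gene_index(config.n_genes), barcodes=barcodes,
        metadata=metadata,
    )
    guide_table = simulate_guide_capture(truth, config)
    return SyntheticDataset(counts=acm, guide_table=guide_table, truth=truth)


def simulate_guide_capture(
    truth: SimulationTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Per-nucleus guide capture: the true guide at ~``guide_mean_umi`` UMIs
    and high coverage, plus low-UMI low-coverage ambient records.

    Returns a table with columns ``barcode``, ``guide_id``, ``umi_count``,
    ``read_count``.
    """
    config.validate()
    rng = config.rngs()["guides"]
    barcodes = truth.nuclei.index.to_numpy()
    guides = truth.nuclei["guide_id"].to_numpy()
    n = len(barcodes)
    all_guides = config.guide_library["guide_id"].to_numpy()

    rows: list[tuple[str, str, int, int]] = []
    captured = rng.random(n) >= config.guide_dropout
    umi = np.maximum(rng.poisson(config.guide_mean_umi, size=n), 1)
    # per-run coverage factor with mild multiplicative noise
    cov = config.coverage_factor * rng.lognormal(0.0, 0.05, size=n)
    reads = np.maximum(np.round(umi * cov).astype(int), umi)
    for i in range(n):
        if captured[i]:
            rows.append((barcodes[i], guides[i], int(umi[i]), int(reads[i])))
    n_ambient = rng.poisson(config.ambient_rate, size=n)
    for i in range(n):
        for _ in range(n_ambient[i]):
            g = all_guides[rng.integers(0, len(all_guides))]
            a_umi = int(rng.integers(1, 3))
            a_reads = a_umi * int(rng.integers(5, 41))
            rows.append((barcodes[i], g, a_umi, a_reads))
    table = pd.DataFrame(
        rows, columns=["barcode", "guide_id", "umi_count", "read_count"]
    )
    # enforce (barcode, guide) uniqueness: ambient duplicate of a captured
    # guide merges into that record
    table = (
        table.groupby(["barcode", "guide_id"], as_index=False, sort=False)
        .agg(umi_count=("umi_count", "sum"), read_count=("read_count", "sum"))
    )
    return table


def simulate_deletion_cohort(
    config: SimulationConfig,
    weights: dict[str, float],
    deleted_genes: list[str],
    n_animals_per_arm: int = 3,
    lfc_noise_sd: float = 0.3,
) -> SyntheticDataset:
    """Simulate a WT-vs-deletion cohort with animal-level replicates.

    Deletion nuclei express ``deleted_genes`` at half the wild-type rate;
    every other gene carries a true log2FC equal to the weighted sum of
    the named perturbation programs plus iid Gaussian gene-level noise.
    """
    config.validate()
    if n_animals_per_arm < 2:
        raise ValueError(
            "n_animals_per_arm must be >= 2 (differential expression "
            "requires replicates)"
        )
    rngs = config.rngs()
    base, base_weights = _baseline_rates(config, rngs["baselines"])
    programs = _assign_programs(config, rngs["programs"], base)
    for t in weights:
        if t not in programs:
            raise ValueError(f"weights reference unknown perturbation {t!r}")
    genes = _gene_index(config.n_genes)

    rng = rngs["nuclei"]
    combo = np.zeros(config.n_genes)
    truth_probe = SimulationTruth(pd.DataFrame(), programs)
    for t, w in weights.items():
        combo += w * truth_probe.program_lfc_vector(t, genes)
    if lfc_noise_sd > 0:
        combo = combo + rng.normal(0.0, lfc_noise_sd, size=config.n_genes)
    del_idx = genes.get_indexer(pd.Index(deleted_genes))
    if (del_idx < 0).any():
        raise ValueError("deleted_genes contains genes not simulated")
    combo[del_idx] = -1.0  # rate x 0.5, exactly

    n = config.n_nuclei
    animals = [
        f"{arm}{a + 1}"
        for arm in ("WT", "DEL")
        for a in range(n_animals_per_arm)
    ]
    conditions = {a: ("DEL" if a.startswith("DEL") else "WT") for a in animals}
    animal = np.asarray(animals)[rng.integers(0, len(animals), size=n)]
    condition = np.asarray([conditions[a] for a in animal])

    ct_names = list(config.cell_types)
    ct_freqs = np.asarray(list(config.cell_types.values()), dtype=float)
    cell_type = rng.choice(ct_names, size=n, p=ct_freqs / ct_freqs.sum())

    barcodes = pd.Index([f"BC{i:06d}" for i in range(n)], name="barcode")
    nuclei = pd.DataFrame(
        {
            "guide_id": "",
            "target": "",
            "perturbed": condition == "DEL",
            "zygosity": "control",
            "lane": animal,
            "animal": animal,
            "cell_type": cell_type,
            "condition": condition,
        },
        index=barcodes,
    )
    counts = _simulate_counts_for_nuclei(
        config,
        nuclei,
        programs,
        base_weights,
        rngs["counts"],
        extra_lfc={"DEL": combo},
    )
    metadata = nuclei[["lane", "animal", "cell_type"]].copy()
    metadata["perturbation"] = condition
    acm = AnnotatedCountMatrix(
        counts=counts, genes=genes, barcodes=barcodes, metadata=metadata
    )
    truth = SimulationTruth(nuclei=nuclei, programs=programs)
    truth.deletion_lfc = pd.Series(combo, index=genes)  # type: ignore[attr-defined]
    return SyntheticDataset(counts=acm, guide_table=pd.DataFrame(
        columns=["barcode", "guide_id", "umi_count", "read_count"]
    ), truth=truth)
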