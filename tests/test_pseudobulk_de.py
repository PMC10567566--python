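"""Tests for pseudobulk construction and NB-GLM differential expression."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import optimize, stats

from perturbscope.matrix import AnnotatedCountMatrix
from perturbscope.pseudobulk_de import (
    PseudobulkMatrix,
    bh_adjust,
    estimate_dispersions,
    filter_expressed_genes,
    make_pseudobulk,
    nb_glm_lrt,
    normalize_log1p,
    run_contrast,
    single_cell_logreg_de,
    tmm_factors,
)


def acm_from_dense(dense, metadata, genes=None):
    dense = np.asarray(dense)
    genes = genes or [f"g{i}" for i in range(dense.shape[0])]
    barcodes = [f"bc{i}" for i in range(dense.shape[1])]
    md = pd.DataFrame(metadata, index=pd.Index(barcodes, name="barcode"))
    return AnnotatedCountMatrix(
        counts=sp.csr_matrix(dense), genes=pd.Index(genes),
        barcodes=pd.Index(barcodes), metadata=md,
    )


def pb_from_dense(dense, groups, n_nuclei=10):
    dense = np.asarray(dense, dtype=np.int64)
    samples = pd.DataFrame(
        {
            "group": groups,
            "replicate": range(len(groups)),
            "cell_type": None,
            "n_nuclei": n_nuclei,
        }
    )
    return PseudobulkMatrix(
        counts=dense,
        genes=pd.Index([f"g{i}" for i in range(dense.shape[0])]),
        samples=samples,
    )


class TestExpressionFilter:
    def test_strict_boundary(self):
        # means: 0.30 kept, 0.25 dropped (strictly greater)
        dense = np.array([[1, 0, 1, 0, 1, 0, 0, 0, 1, 2],  # mean 0.6
                          [1, 1, 0, 0, 0, 0, 0, 0, 0, 0],  # mean 0.2
                          [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]])  # mean 0.3
        md = {"perturbation": ["ctrl"] * 10}
        acm = acm_from_dense(dense, md)
        kept = filter_expressed_genes(acm, "ctrl", min_mean=0.25)
        assert list(kept) == ["g0", "g2"]
        # exact boundary: mean == 0.25 dropped
        dense2 = np.zeros((1, 4)); dense2[0, 0] = 1  # mean 0.25
        acm2 = acm_from_dense(dense2, {"perturbation": ["ctrl"] * 4})
        assert len(filter_expressed_genes(acm2, "ctrl")) == 0

    def test_all_zero_dropped(self):
        acm = acm_from_dense(np.zeros((2, 5)), {"perturbation": ["ctrl"] * 5})
        assert len(filter_expressed_genes(acm, "ctrl")) == 0

    def test_no_control_errors(self):
        acm = acm_from_dense(np.ones((2, 3)), {"perturbation": ["x"] * 3})
        with pytest.raises(ValueError, match="control"):
            filter_expressed_genes(acm, "ctrl")

    def test_matches_bruteforce_mean(self, screen, control_label):
        kept = filter_expressed_genes(screen.counts, control_label)
        dense = screen.counts.dense()
        ctrl = (screen.counts.metadata["perturbation"] == control_label).to_numpy()
        brute = screen.counts.genes[dense[:, ctrl].mean(axis=1) > 0.25]
        assert list(kept) == list(brute)


class TestMakePseudobulk:
    def test_toy_sum(self):
        dense = np.array([[3, 2], [0, 5]])
        md = {"perturbation": ["a", "a"], "lane": [1, 1], "cell_type": ["n"] * 2}
        pb = make_pseudobulk(acm_from_dense(dense, md), min_nuclei=2)
        np.testing.assert_array_equal(pb.counts.ravel(), [5, 5])

    def test_conservation(self, screen):
        pb = make_pseudobulk(screen.counts, min_nuclei=1)
        total_in = 0
        md = screen.counts.metadata
        for _, row in pb.samples.iterrows():
            members = (md["perturbation"] == row["group"]) & (
                md["lane"] == row["replicate"]
            )
            total_in += int(
                screen.counts.counts[:, np.flatnonzero(members)].sum()
            )
        assert pb.counts.sum() == total_in

    def test_nine_lane_columns(self):
        from conftest import small_config
        from perturbscope.synthetic_data import simulate_screen

        cfg = small_config(
            n_nuclei=4000, seed=19,
            guide_library=pd.DataFrame(
                {
                    "guide_id": ["g1", "gSH"],
                    "target": ["T1", "SH-control"],
                    "is_control": [False, True],
                }
            ),
        )
        ds = simulate_screen(cfg)
        pb = make_pseudobulk(ds.counts)
        for group in ("T1", "SH-control"):
            assert (pb.samples["group"] == group).sum() == 9

    def test_small_columns_dropped_with_warning(self):
        dense = np.ones((2, 4))
        md = {
            "perturbation": ["a", "a", "a", "b"],
            "lane": [1, 1, 1, 1],
            "cell_type": ["n"] * 4,
        }
        with pytest.warns(UserWarning, match="dropped"):
            with pytest.raises(ValueError, match="'b'"):
                make_pseudobulk(acm_from_dense(dense, md), min_nuclei=3)

    def test_every_nucleus_at_most_one_column(self, screen):
        pb = make_pseudobulk(screen.counts, min_nuclei=1)
        assert not pb.samples.duplicated(["group", "replicate"]).any()


class TestNormalizeLog1p:
    def test_zero_entry_maps_to_zero(self):
        acm = acm_from_dense([[0, 3], [5, 1]], {"perturbation": ["a", "a"]})
        norm = normalize_log1p(acm)
        assert norm.values[0, 0] == 0.0

    def test_formula(self):
        # nucleus total 10,000 with entry 10 -> ln(11)
        dense = np.zeros((2, 1)); dense[0, 0] = 10; dense[1, 0] = 9990
        acm = acm_from_dense(dense, {"perturbation": ["a"]})
        norm = normalize_log1p(acm)
        assert norm.values[0, 0] == pytest.approx(np.log(11))

    def test_scaled_totals_constant(self, screen):
        norm = normalize_log1p(screen.counts)
        pre_log = np.expm1(norm.values)
        np.testing.assert_allclose(pre_log.sum(axis=0), 1e4, rtol=1e-8)

    def test_zero_column_dropped(self):
        acm = acm_from_dense([[1, 0], [1, 0]], {"perturbation": ["a", "a"]})
        with pytest.warns(UserWarning, match="zero-total"):
            norm = normalize_log1p(acm)
        assert norm.values.shape[1] == 1
        assert norm.dropped_barcodes == ["bc1"]


class TestBH:
    def test_fdr_at_least_p_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.random(200)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.random(500) ** 2
        q = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, ref, atol=1e-12)


def poisson_lrt_oracle(y, groups, offsets):
    """Direct numeric maximization of the Poisson GLM likelihoods."""

    def negll(beta, X):
        eta = X @ beta + np.log(offsets)
        return -(y * eta - np.exp(eta)).sum()

    X_full = np.column_stack([np.ones(len(y)), groups])
    X_null = X_full[:, :1]
    full = optimize.minimize(negll, [0.0, 0.0], args=(X_full,), method="BFGS",
                             options={"gtol": 1e-10})
    null = optimize.minimize(negll, [0.0], args=(X_null,), method="BFGS",
                             options={"gtol": 1e-10})
    return 2.0 * (null.fun - full.fun)


class TestNbGlmLrt:
    def test_identical_groups_null(self):
        counts = np.tile([[40], [7], [100]], (1, 6))
        pb = pb_from_dense(counts, ["a"] * 3 + ["b"] * 3)
        de = nb_glm_lrt(pb, 0.1, contrast=("a", "b"))
        np.testing.assert_allclose(de["lfc_log2"], 0.0, atol=1e-6)
        assert (de["pvalue"] > 0.99).all()

    def test_poisson_oracle_at_zero_dispersion(self):
        """NB-LRT with dispersion 0 equals the direct-maximization Poisson
        LRT on a 5-gene toy (tolerance 1e-6)."""
        rng = np.random.default_rng(5)
        counts = rng.poisson(20, size=(5, 8))
        groups = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        pb = pb_from_dense(counts, ["ctrl"] * 4 + ["trt"] * 4)
        de = nb_glm_lrt(pb, 0.0, contrast=("trt", "ctrl"))
        libs = counts.sum(axis=0).astype(float)
        for i, row in de.iterrows():
            g = int(row["gene"][1:])
            oracle = poisson_lrt_oracle(counts[g].astype(float), groups, libs)
            assert row["lr_stat"] == pytest.approx(oracle, abs=1e-6)

    def test_lfc_sign_matches_mean_difference(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(30, size=(50, 8))
        counts[:25, 4:] = rng.poisson(60, size=(25, 4))
        # equalize library sizes
        pb = pb_from_dense(counts, ["a"] * 4 + ["b"] * 4)
        pb.norm_factors = pb.library_sizes.mean() / pb.library_sizes
        de = nb_glm_lrt(pb, 0.05, contrast=("b", "a")).set_index("gene")
        mean_diff = counts[:, 4:].mean(axis=1) - counts[:, :4].mean(axis=1)
        for i in range(50):
            if abs(mean_diff[i]) > 5:
                assert np.sign(de.loc[f"g{i}", "lfc_log2"]) == np.sign(
                    mean_diff[i]
                )

    def test_type_i_error_calibration(self):
        """Null NB data: empirical type-I error in [0.03, 0.07] at 5%."""
        rng = np.random.default_rng(11)
        n_genes = 2000
        mu = rng.lognormal(3, 1, size=n_genes)
        disp = 0.05
        lam = rng.gamma(1 / disp, disp, size=(n_genes, 18)) * mu[:, None]
        counts = rng.poisson(lam)
        pb = pb_from_dense(counts, ["a"] * 9 + ["b"] * 9)
        dm = estimate_dispersions(pb)
        de = nb_glm_lrt(pb, dm, contrast=("b", "a"))
        rate = (de["pvalue"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_lfc_parameter_recovery(self):
        """Genes at true log2FC=1 recover mean LFC in [0.9, 1.1]."""
        rng = np.random.default_rng(13)
        n_genes = 300
        mu = rng.lognormal(3, 1, size=n_genes)
        disp = 0.05
        mu_mat = np.tile(mu[:, None], (1, 18)).astype(float)
        mu_mat[:, 9:] *= 2.0  # log2FC = 1 for every gene
        counts = rng.poisson(rng.gamma(1 / disp, disp, size=mu_mat.shape) * mu_mat)
        pb = pb_from_dense(counts, ["a"] * 9 + ["b"] * 9)
        # library sizes are inflated in group b by the global doubling;
        # use equal effective sizes to isolate the coefficient
        pb.norm_factors = pb.library_sizes.mean() / pb.library_sizes
        dm = estimate_dispersions(pb)
        de = nb_glm_lrt(pb, dm, contrast=("b", "a"))
        assert 0.9 <= de["lfc_log2"].mean() <= 1.1

    def test_needs_two_columns_per_group(self):
        pb = pb_from_dense(np.ones((3, 3), dtype=int), ["a", "b", "b"])
        with pytest.raises(ValueError, match=">= 2"):
            nb_glm_lrt(pb, 0.1, contrast=("a", "b"))


class TestDispersions:
    def test_constant_gene_zero_dispersion(self):
        counts = np.tile([[50], [20]], (1, 6))
        pb = pb_from_dense(counts, ["a"] * 3 + ["b"] * 3)
        dm = estimate_dispersions(pb)
        assert dm.raw[0] == 0.0

    def test_poisson_shrinks_toward_zero_with_replicates(self):
        rng = np.random.default_rng(3)
        meds = []
        for reps in (4, 16):
            counts = rng.poisson(40, size=(300, reps))
            pb = pb_from_dense(counts, ["a"] * (reps // 2) + ["b"] * (reps // 2))
            dm = estimate_dispersions(pb)
            meds.append(np.median(dm.tagwise))
        assert meds[1] <= meds[0]
        assert meds[1] < 0.01

    def test_nb_dispersion_recovery(self):
        rng = np.random.default_rng(4)
        disp = 0.1
        mu = rng.lognormal(4, 0.5, size=500)
        lam = rng.gamma(1 / disp, disp, size=(500, 18)) * mu[:, None]
        counts = rng.poisson(lam)
        pb = pb_from_dense(counts, ["a"] * 9 + ["b"] * 9)
        dm = estimate_dispersions(pb)
        assert 0.05 <= np.median(dm.tagwise) <= 0.2

    def test_shrunken_between_raw_and_common(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(rng.lognormal(3, 1, size=(100, 1)) * np.ones((100, 8)))
        pb = pb_from_dense(counts, ["a"] * 4 + ["b"] * 4)
        dm = estimate_dispersions(pb)
        lo = np.minimum(dm.raw, dm.common)
        hi = np.maximum(dm.raw, dm.common)
        assert ((dm.tagwise >= lo - 1e-12) & (dm.tagwise <= hi + 1e-12)).all()

    def test_single_replicate_errors(self):
        pb = pb_from_dense(np.ones((3, 2), dtype=int), ["a", "b"])
        with pytest.raises(ValueError, match="common"):
            estimate_dispersions(pb)


class TestTmm:
    def test_identical_columns_unit_factors(self):
        counts = np.tile(np.arange(1, 101)[:, None], (1, 4))
        np.testing.assert_allclose(tmm_factors(counts), 1.0, atol=1e-12)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(rng.lognormal(2, 1, size=(400, 1)) * np.ones((400, 6)))
        f = tmm_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-10)


class TestSingleCellLogreg:
    def _norm(self, values):
        from perturbscope.pseudobulk_de import NormalizedMatrix

        g, n = values.shape
        return NormalizedMatrix(
            values=values,
            genes=pd.Index([f"g{i}" for i in range(g)]),
            barcodes=pd.Index([f"bc{i}" for i in range(n)]),
        )

    def test_identical_gene_null(self):
        # both groups hold the same value multiset -> beta = 0, p = 1
        half = np.linspace(0, 1, 20)
        vals = np.tile(np.concatenate([half, half]), (3, 1))
        labels = np.array(["a"] * 20 + ["b"] * 20)
        de = single_cell_logreg_de(self._norm(vals), labels, ("b", "a"))
        assert (de["pvalue"] > 0.99).all()

    def test_separated_gene_tiny_p(self):
        rng = np.random.default_rng(9)
        vals = np.zeros((1, 200))
        vals[0, 100:] = rng.uniform(1, 2, 100)  # expressed only in group b
        labels = np.array(["a"] * 100 + ["b"] * 100)
        de = single_cell_logreg_de(self._norm(vals), labels, ("b", "a"))
        assert de.loc[0, "pvalue"] < 1e-10

    def test_null_calibration_ks(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(size=(400, 300))
        labels = np.array(["a"] * 150 + ["b"] * 150)
        de = single_cell_logreg_de(self._norm(vals), labels, ("b", "a"))
        ks = stats.kstest(de["pvalue"], "uniform")
        assert ks.pvalue > 0.01


class TestRunContrast:
    def test_recovers_program_degs(self, screen, control_label):
        de = run_contrast(screen.counts, "Tgt00", control_label)
        prog = screen.truth.programs["Tgt00"]
        tested = de.set_index("gene")
        prog_tested = [g for g in prog if g in tested.index]
        sig = tested.loc[prog_tested, "fdr"] < 0.05
        assert sig.mean() > 0.6
        # effect direction recovered
        signs = np.sign(tested.loc[prog_tested, "lfc_log2"])
        expected = np.sign([prog[g] for g in prog_tested])
        assert (signs == expected).mean() > 0.95

    def test_fdr_invariants(self, screen, control_label):
        de = run_contrast(screen.counts, "Tgt00", control_label)
        assert ((de["fdr"] >= de["pvalue"] - 1e-12) & (de["fdr"] <= 1)).all()
        assert np.isfinite(de["lfc_log2"]).all()
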