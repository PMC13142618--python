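"""QC layer contracts: fixed thresholds, polynomial outliers, consensus
voting, and the Gaussian-mixture heterotypic filter."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from glioprog.qc import (
    QCThresholds,
    basic_filters,
    consensus_doublet_filter,
    drop_blacklist_cells,
    gmm_heterotypic_filter,
    lognormalize,
    marker_score,
    polynomial_outlier_filter,
)
from glioprog.synthetic import CountMatrix, generate_cohort, inject_doublets
from tests.conftest import small_config


def _matrix_from_dense(dense, mito_genes=0):
    dense = np.asarray(dense)
    n, g = dense.shape
    flags = np.zeros(g, dtype=bool)
    flags[:mito_genes] = True
    return CountMatrix(
        counts=sp.csr_matrix(dense),
        cell_ids=[f"C{i}" for i in range(n)],
        gene_ids=[f"G{j}" for j in range(g)],
        gene_flags=flags,
    )


class TestBasicFilters:
    def test_umi_boundary_inclusive(self):
        # two cells at 499 and 500 total UMIs, no mito content
        dense = np.zeros((2, 600), dtype=int)
        dense[0, 10:509] = 1      # 499 UMIs, 499 genes
        dense[1, 10:510] = 1      # 500 UMIs, 500 genes
        m = _matrix_from_dense(dense, mito_genes=5)
        thr = QCThresholds(min_umi=500, min_genes=400)
        keep = basic_filters(m, thr)
        assert keep.tolist() == [False, True]

    def test_mito_fraction_strictly_above_removed(self):
        dense = np.zeros((2, 600), dtype=int)
        # cell 0: 11% mito; cell 1: exactly 10% (kept: bound inclusive)
        dense[0, 0] = 66
        dense[0, 10:544] = 1
        dense[1, 0] = 60
        dense[1, 10:550] = 1
        m = _matrix_from_dense(dense, mito_genes=1)
        thr = QCThresholds(min_umi=100, min_genes=100)
        keep = basic_filters(m, thr)
        assert keep.tolist() == [False, True]

    def test_empty_matrix(self):
        m = _matrix_from_dense(np.zeros((0, 10), dtype=int))
        assert basic_filters(m).shape == (0,)


class TestPolynomialFilter:
    def test_exact_fit_all_kept(self):
        umi = np.logspace(3, 5, 50)
        genes = 100 + 300 * np.log10(umi) + 20 * np.log10(umi) ** 2
        keep, coef = polynomial_outlier_filter(umi, genes)
        assert keep.all()
        # coefficients recover the generating polynomial
        np.testing.assert_allclose(coef, [20, 300, 100], rtol=1e-8)

    def test_displaced_point_removed(self):
        """Only the +3000-gene outlier is removed; verified against an
        independent least-squares solve."""
        umi = np.logspace(3, 5, 200)
        genes = 100 + 300 * np.log10(umi) + 20 * np.log10(umi) ** 2
        genes[37] += 3000
        keep, coef = polynomial_outlier_filter(umi, genes)
        assert not keep[37]
        assert keep.sum() == 199
        # independent oracle: design-matrix least squares
        A = np.vander(np.log10(umi), 3)
        coef_oracle = np.linalg.lstsq(A, genes, rcond=None)[0]
        resid = np.abs(genes - A @ coef_oracle)
        np.testing.assert_array_equal(keep, resid <= 2000)

    def test_zero_threshold_boundary(self):
        """At threshold ~0 only exact-fit points survive: all of them when
        the data are exactly polynomial, none once a perturbation shifts
        the fitted curve away from every point."""
        umi = np.logspace(3, 4, 30)
        genes = 50 + 100 * np.log10(umi) + 5 * np.log10(umi) ** 2
        thr = QCThresholds(poly_residual_max=1e-6)
        keep, _ = polynomial_outlier_filter(umi, genes, thr)
        assert keep.all()
        genes[3] += 1.0
        keep, _ = polynomial_outlier_filter(umi, genes, thr)
        assert not keep.any()

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            polynomial_outlier_filter(np.array([1000.0, 2000.0]), np.array([1.0, 2.0]))


class TestConsensusFilter:
    def test_forced_flagging(self, small_cohort):
        _, matrix, _, _ = small_cohort
        n = matrix.n_cells

        def always_flag_x(m, seed):
            out = np.zeros(n, dtype=bool)
            out[5] = True
            return out

        keep, frac = consensus_doublet_filter(matrix, always_flag_x, seed=0)
        assert not keep[5]
        assert frac[5] == 1.0
        assert keep.sum() == n - 1

    def test_never_flag(self, small_cohort):
        _, matrix, _, _ = small_cohort
        keep, _ = consensus_doublet_filter(
            matrix, lambda m, s: np.zeros(matrix.n_cells, dtype=bool), seed=0
        )
        assert keep.all()

    def test_deterministic_scorer_seed_invariant(self, small_cohort):
        """With a deterministic scorer the consensus mask is the same for
        any driver seed."""
        _, matrix, _, _ = small_cohort
        n = matrix.n_cells

        def deterministic(m, seed):
            return np.arange(n) % 7 == 0

        k1, _ = consensus_doublet_filter(matrix, deterministic, seed=1)
        k2, _ = consensus_doublet_filter(matrix, deterministic, seed=999)
        np.testing.assert_array_equal(k1, k2)

    def test_wrong_length_scorer(self, small_cohort):
        _, matrix, _, _ = small_cohort
        with pytest.raises(ValueError, match="scorer returned"):
            consensus_doublet_filter(matrix, lambda m, s: np.zeros(3, dtype=bool), seed=0)


class TestMarkerScore:
    def test_all_zero_expression(self):
        m = _matrix_from_dense(np.zeros((5, 10), dtype=int))
        lognorm = lognormalize(m)
        scores = marker_score(lognorm, m.gene_ids, {"A": ["G0", "G1"], "B": ["G2"]})
        assert (scores.to_numpy() == 0).all()

    def test_single_gene_identity(self, rng):
        dense = rng.poisson(5, size=(20, 10))
        m = _matrix_from_dense(dense)
        lognorm = lognormalize(m)
        scores = marker_score(lognorm, m.gene_ids, {"A": ["G3"], "B": ["G4"]})
        np.testing.assert_allclose(
            scores["A"].to_numpy(), np.asarray(lognorm[:, 3].todense()).ravel()
        )

    def test_missing_class_errors(self, small_cohort):
        _, matrix, _, _ = small_cohort
        lognorm = lognormalize(matrix)
        with pytest.raises(ValueError, match="no marker genes"):
            marker_score(lognorm, matrix.gene_ids, {"A": ["NOPE"], "B": ["ALSO_NOPE"]})

    def test_class_scores_bimodal(self, small_cohort):
        """Cells of a class score well above cells of other classes."""
        _, matrix, ann, _ = small_cohort
        lognorm = lognormalize(matrix)
        scores = marker_score(lognorm, matrix.gene_ids, matrix.marker_sets("cell_class"))
        cls = ann["cell_class"].to_numpy()
        own = scores["Astrocyte"][cls == "Astrocyte"]
        other = scores["Astrocyte"][cls != "Astrocyte"]
        assert own.min() > other.max() - 0.5
        assert own.mean() - other.mean() > 1.0


class TestGMMFilter:
    def test_threshold_recovery_known_mixture(self, rng):
        """N(0,1) w=.9 + N(10,1) w=.1: threshold = mu_low + 4*sd_low lands
        in [3.5, 4.5]."""
        x = np.concatenate([rng.normal(0, 1, 1800), rng.normal(10, 1, 200)])
        y = np.concatenate([rng.normal(10, 1, 200), rng.normal(0, 1, 1800)])
        scores = pd.DataFrame({"A": x, "B": y})
        _, cuts, _ = gmm_heterotypic_filter(scores, seed=0)
        assert 3.5 < cuts["A"] < 4.5
        assert 3.5 < cuts["B"] < 4.5

    def test_single_class_exceedance_kept(self, rng):
        x = np.concatenate([rng.normal(0, 1, 900), rng.normal(10, 1, 100)])
        y = np.concatenate([rng.normal(10, 1, 100), rng.normal(0, 1, 900)])
        scores = pd.DataFrame({"A": x, "B": y})
        keep, _, _ = gmm_heterotypic_filter(scores, seed=0)
        # every cell is high for at most one class: all kept
        assert keep.all()

    def test_planted_heterotypic_doublets_flagged(self):
        """>=90% of planted heterotypic doublets removed, few singlets lost."""
        cfg = small_config(seed=6, n_cells_per_donor=600,
                           n_donors_per_group={"UPR": 1, "Reactive": 1, "Homeostatic": 1})
        matrix, ann, _ = generate_cohort(cfg)
        matrix, ann = inject_doublets(matrix, ann, rate=0.05, seed=2, heterotypic_only=True)
        lognorm = lognormalize(matrix)
        scores = marker_score(lognorm, matrix.gene_ids, matrix.marker_sets("cell_class"))
        keep, _, _ = gmm_heterotypic_filter(scores, seed=0)
        dbl = ann["is_doublet_truth"].to_numpy()
        assert (~keep)[dbl].mean() >= 0.9
        assert (~keep)[~dbl].mean() <= 0.02

    def test_doublet_free_false_positive_bound(self, small_cohort):
        """On doublet-free data the GMM layer removes at most 2% of cells."""
        _, matrix, _, _ = small_cohort
        lognorm = lognormalize(matrix)
        scores = marker_score(lognorm, matrix.gene_ids, matrix.marker_sets("cell_class"))
        keep, _, _ = gmm_heterotypic_filter(scores, seed=0)
        assert (~keep).mean() <= 0.02

    def test_needs_two_classes(self, rng):
        with pytest.raises(ValueError):
            gmm_heterotypic_filter(pd.DataFrame({"A": rng.normal(size=100)}))


def test_blacklist_gene_filter():
    dense = np.array([[0, 5, 1], [0, 0, 3], [2, 0, 0]])
    m = _matrix_from_dense(dense)
    keep = drop_blacklist_cells(m, ["G0"], min_count=1)
    assert keep.tolist() == [True, True, False]
    # unknown genes leave everything untouched
    assert drop_blacklist_cells(m, ["NOPE"]).all()
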