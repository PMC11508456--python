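"""PLS-DA decomposition, variance explained, CV component choice, RFE."""

import numpy as np
import pytest

from proteomark import (
    SyntheticConfig,
    fit_splsda,
    generate_abundance,
    rfe,
    select_n_components,
    variance_explained,
)
from proteomark.errors import DegenerateFitError, ParameterError

from conftest import make_matrix


def random_matrix(n_proteins, n_cases, n_controls, seed=0, separation=0.0, n_sep=0):
    rng = np.random.default_rng(seed)
    vals = rng.lognormal(mean=3, sigma=0.5, size=(n_proteins, n_cases + n_controls))
    vals[:n_sep, :n_cases] *= 2.0 ** separation
    return make_matrix(vals, [f"c{i}" for i in range(n_cases)],
                       [f"h{i}" for i in range(n_controls)])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

class TestFit:
    def test_score_equation_identity(self):
        # S_j = sum_i u_i1 r_ij on the centered/scaled matrix, to 1e-8
        m = random_matrix(40, 5, 7, seed=2)
        model = fit_splsda(m, n_components=3)
        expected = model.fitted_matrix @ model.loadings[:, 0]
        assert np.max(np.abs(model.scores[:, 0] - expected)) < 1e-8

    def test_loading_columns_are_unit_norm(self):
        m = random_matrix(30, 4, 6, seed=3)
        model = fit_splsda(m, n_components=3)
        np.testing.assert_allclose(np.linalg.norm(model.loadings, axis=0), 1.0, atol=1e-12)

    def test_dense_loading_matches_eigendecomposition_oracle(self):
        # component-1 direction = leading eigenvector of X'y y'X (6 x 4 case)
        m = random_matrix(4, 3, 3, seed=4)
        model = fit_splsda(m, n_components=1)
        Xs = model.fitted_matrix
        yc = model.y_centered
        Z = np.outer(Xs.T @ yc, Xs.T @ yc)
        eigvals, eigvecs = np.linalg.eigh(Z)
        lead = eigvecs[:, np.argmax(eigvals)]
        cos = abs(float(lead @ model.loadings[:, 0]))
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_sparsity_keeps_only_the_separating_protein(self):
        # one perfectly separating protein, one pure-noise protein, keep=1
        rng = np.random.default_rng(5)
        sep = np.array([10, 11, 10, 1, 2, 1, 2, 1], dtype=float)
        noise = rng.normal(5, 1, size=8)
        m = make_matrix(np.vstack([sep, noise]), [f"c{i}" for i in range(3)],
                        [f"h{i}" for i in range(5)])
        model = fit_splsda(m, n_components=1, keep_per_component=1)
        u = model.loadings[:, 0]
        assert u[0] != 0.0 and u[1] == 0.0

    def test_too_many_components_rejected(self):
        m = random_matrix(10, 3, 3, seed=6)
        with pytest.raises(ParameterError):
            fit_splsda(m, n_components=6)  # > n_samples - 1

    def test_constant_matrix_is_degenerate(self):
        m = make_matrix(np.full((5, 6), 3.0), ["a", "b", "c"], ["d", "e", "f"])
        with pytest.raises(DegenerateFitError):
            fit_splsda(m, n_components=1)


# ---------------------------------------------------------------------------
# variance explained
# ---------------------------------------------------------------------------

class TestVarianceExplained:
    def test_rank_one_matrix_fully_explained(self):
        t = np.array([1.0, -2.0, 0.5, 3.0, -1.0, 0.0])
        p = np.array([2.0, -1.0, 0.5, 1.5])
        X = np.outer(t - t.mean(), p)  # columns already centered
        m = make_matrix(X.T + 100.0, ["a", "b", "c"], ["d", "e", "f"])
        model = fit_splsda(m, n_components=1, scale=False)
        assert variance_explained(model)[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_residual_sum_of_squares_oracle(self):
        m = random_matrix(8, 5, 5, seed=7)
        model = fit_splsda(m, n_components=3)
        X0 = model.fitted_matrix
        total = (X0 ** 2).sum()
        for k in range(3):
            t = model.scores[:, k]
            resid = X0 - np.outer(t, X0.T @ t / (t @ t))
            expected = 1.0 - (resid ** 2).sum() / total
            assert variance_explained(model)[k] == pytest.approx(expected, abs=1e-10)

    def test_fractions_additive_for_orthogonal_scores(self):
        m = random_matrix(12, 5, 6, seed=8)
        model = fit_splsda(m, n_components=4)
        # NIPALS scores are mutually orthogonal, so fractions add
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))
        ve = variance_explained(model)
        assert 0 < ve.sum() <= 1 + 1e-10
        assert np.all((ve >= 0) & (ve <= 1))


# ---------------------------------------------------------------------------
# component-count selection
# ---------------------------------------------------------------------------

class TestSelectNComponents:
    def test_pure_noise_returns_one_by_parsimony(self):
        m = random_matrix(30, 8, 8, seed=9)
        assert select_n_components(m, max_components=4, n_repeats=3, seed=0) == 1

    def test_single_planted_direction_stays_small(self):
        m = random_matrix(30, 10, 10, seed=10, separation=3.0, n_sep=8)
        k = select_n_components(m, max_components=4, n_repeats=3, seed=0)
        assert k in (1, 2)

    def test_oversized_fold_count_rejected(self):
        m = random_matrix(10, 3, 8, seed=11)
        with pytest.raises(ParameterError):
            select_n_components(m, n_folds=5)


# ---------------------------------------------------------------------------
# recursive feature elimination
# ---------------------------------------------------------------------------

class TestRfe:
    def test_ceil_stopping_rule(self):
        m = random_matrix(100, 4, 6, seed=12)
        trace = rfe(m, n_components=1, target_fraction=0.05)
        assert trace.n_retained == 5  # ceil(0.05 * 100)
        assert len(trace.eliminated) + trace.n_retained == 100

    def test_no_protein_appears_twice(self):
        m = random_matrix(60, 4, 6, seed=13)
        trace = rfe(m, n_components=1, target_fraction=0.1)
        ids = [acc for _, acc, _ in trace.eliminated] + trace.retained
        assert len(ids) == len(set(ids)) == 60

    def test_elimination_is_monotone_nested(self):
        m = random_matrix(40, 4, 6, seed=14)
        trace = rfe(m, n_components=1, target_fraction=0.1)
        alive = set(m.accessions)
        for _, acc, _ in trace.eliminated:
            assert acc in alive  # each removal strictly shrinks the set
            alive.remove(acc)
        assert alive == set(trace.retained)

    def test_dominant_protein_survives_across_seeds(self):
        for seed in range(20):
            m = random_matrix(30, 5, 7, seed=100 + seed, separation=4.0, n_sep=1)
            trace = rfe(m, n_components=1, target_fraction=0.1)
            assert m.accessions[0] in trace.retained

    def test_chunked_elimination_reaches_same_target(self):
        m = random_matrix(80, 4, 6, seed=15)
        assert rfe(m, target_fraction=0.1, chunk=7).n_retained == 8

    def test_permuted_labels_retain_markers_at_chance_rate(self):
        # with labels permuted, planted markers survive no more than chance
        cfg = SyntheticConfig(n_proteins=200, n_markers=20, effect_log2fc=2.0,
                              noise_sd=0.5, isoform_fraction=0.0, seed=16)
        matrix, truth = generate_abundance(cfg)
        import pandas as pd

        from proteomark import AbundanceMatrix

        rng = np.random.default_rng(16)
        fractions = []
        for _ in range(60):
            perm_groups = pd.Series(rng.permutation(matrix.groups.to_numpy()),
                                    index=matrix.sample_ids)
            m_perm = AbundanceMatrix(matrix.values, perm_groups)
            trace = rfe(m_perm, n_components=1, target_fraction=0.05)
            fractions.append(len(set(trace.retained) & truth.marker_ids) / 20)
        mean_frac = np.mean(fractions)
        # fractions are dependent across markers within one permutation, so
        # the Monte-Carlo error comes from the per-permutation spread
        se = np.std(fractions, ddof=1) / np.sqrt(len(fractions))
        assert mean_frac <= 0.05 + 3 * se

    def test_bad_target_fraction_rejected(self):
        m = random_matrix(10, 3, 3, seed=17)
        with pytest.raises(ParameterError):
            rfe(m, target_fraction=1.5)
        with pytest.raises(ParameterError):
            rfe(m, target_fraction=0.0)
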