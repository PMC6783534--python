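"""NMF extraction, rank selection, NNLS refitting and spectra utilities."""

import numpy as np
import pytest

from fluorosig import synthetic_data as syn
from fluorosig import signatures as sig


def nonincreasing(trace, slack=1e-8):
    trace = np.asarray(trace)
    return bool(np.all(np.diff(trace) <= slack * np.maximum(1.0, np.abs(trace[:-1]))))


class TestNmf:
    def test_exact_rank_one_matrix_recovered(self):
        rng = np.random.default_rng(0)
        w = rng.random(96)
        h = rng.random(12) * 50
        V = np.outer(w, h)
        res = sig.nmf_factorize(V, rank=1, seed=1)
        rel_err = np.linalg.norm(V - res.W @ res.H) / np.linalg.norm(V)
        assert rel_err < 1e-6

    @pytest.mark.parametrize("objective", ["kl", "frobenius"])
    def test_objective_nonincreasing(self, objective):
        rng = np.random.default_rng(5)
        V = rng.poisson(20.0, size=(96, 10)).astype(float)
        res = sig.nmf_factorize(V, rank=3, seed=6, objective=objective,
                                max_iter=500)
        assert nonincreasing(res.objective_trace)
        assert (res.W >= 0).all() and (res.H >= 0).all()

    def test_basis_is_column_stochastic_and_reconstruction_preserved(self):
        rng = np.random.default_rng(7)
        V = rng.poisson(10.0, size=(96, 8)).astype(float)
        res = sig.nmf_factorize(V, rank=2, seed=8, max_iter=300)
        assert np.allclose(res.W.sum(axis=0), 1.0, atol=1e-9)

    def test_planted_signatures_recovered(self, signature_set, planted_catalog):
        catalog, _ = planted_catalog
        res = sig.nmf_factorize(catalog, rank=3, seed=21)
        for k in range(3):
            best = max(sig.cosine_sim(signature_set.probs[:, k], res.W[:, j])
                       for j in range(3))
            assert best >= 0.95

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sig.nmf_factorize(np.zeros((96, 4)), rank=2)
        with pytest.raises(ValueError):
            sig.nmf_factorize(np.ones((96, 4)), rank=5)

    def test_agrees_with_independent_mu_solver(self, planted_catalog):
        """Cross-check the multiplicative-update implementation against
        scikit-learn's KL-NMF on the same planted catalog."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        catalog, _ = planted_catalog
        V = catalog.counts.astype(float)
        ours = sig.nmf_factorize(V, rank=3, seed=4)
        model = sklearn.NMF(n_components=3, solver="mu",
                            beta_loss="kullback-leibler", init="random",
                            random_state=4, max_iter=2000, tol=1e-6)
        W_ref = model.fit_transform(V)
        W_ref = W_ref / W_ref.sum(axis=0)
        for j in range(3):
            best = max(sig.cosine_sim(W_ref[:, j], ours.W[:, k])
                       for k in range(3))
            assert best >= 0.95


class TestConsensus:
    def test_requires_multiple_runs(self, planted_catalog):
        with pytest.raises(ValueError):
            sig.consensus_cophenetic(planted_catalog[0], 2, n_runs=1)

    def test_diagonal_is_one_and_symmetric(self, signature_set):
        rng = np.random.default_rng(2)
        E = rng.dirichlet(np.ones(3), 12).T * 1000
        cat = syn.sample_catalog(signature_set, E, seed=3)
        res = sig.consensus_cophenetic(cat, 2, n_runs=4, seed=4, max_iter=300)
        assert np.allclose(np.diag(res.consensus), 1.0)
        assert np.allclose(res.consensus, res.consensus.T)

    def test_separable_blocks_give_high_cophenetic(self, signature_set):
        E = np.zeros((3, 20))
        E[0, :10] = 2000.0
        E[1, 10:] = 2000.0
        cat = syn.sample_catalog(signature_set, E, seed=13)
        res = sig.consensus_cophenetic(cat, 2, n_runs=10, seed=3)
        assert res.cophenetic >= 0.99


class TestRankSelection:
    def test_planted_rank_recovered(self, signature_set):
        """Noisy 30-sample cohort with three dominant-signature blocks:
        the cophenetic profile suggests the planted rank 3."""
        rng = np.random.default_rng(42)
        E = np.full((3, 30), 125.0)
        for s in range(30):
            E[s % 3, s] = 250.0
        E *= rng.uniform(0.7, 1.3, size=E.shape)
        cat = syn.sample_catalog(signature_set, E, seed=43)
        table, suggested = sig.select_rank(cat, range(2, 6), n_runs=10,
                                           seed=44, max_iter=600)
        assert list(table["rank"]) == [2, 3, 4, 5]
        assert suggested == 3

    def test_single_rank_range(self, signature_set):
        rng = np.random.default_rng(1)
        E = rng.dirichlet(np.ones(3), 8).T * 500
        cat = syn.sample_catalog(signature_set, E, seed=2)
        table, suggested = sig.select_rank(cat, [2], n_runs=3, max_iter=200)
        assert suggested == 2 and len(table) == 1


class TestCosine:
    def test_identical_is_one(self):
        v = np.arange(1, 97, dtype=float)
        assert sig.cosine_sim(v, v) == pytest.approx(1.0)

    def test_disjoint_support_is_zero(self):
        a = np.zeros(96)
        b = np.zeros(96)
        a[:10], b[10:20] = 1, 1
        assert sig.cosine_sim(a, b) == 0.0

    def test_hand_computed_value(self):
        a = np.zeros(96)
        b = np.zeros(96)
        a[:3] = [1, 2, 2]
        b[:3] = [2, 1, 2]
        assert sig.cosine_sim(a, b) == pytest.approx(8 / 9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(96), rng.random(96)
        assert sig.cosine_sim(3.7 * a, b) == pytest.approx(sig.cosine_sim(a, 0.2 * b))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            sig.cosine_sim(np.zeros(96), np.ones(96))


class TestMatching:
    def test_self_match_is_identity(self, signature_set):
        matches, scores = sig.match_to_reference(signature_set, signature_set)
        assert list(matches["best_match"]) == signature_set.signature_ids
        assert np.allclose(matches["cosine"], 1.0)
        assert np.allclose(np.diag(scores.to_numpy()), 1.0)

    def test_single_column_reference(self, signature_set):
        ref = sig.SignatureMatrix(signature_set.probs[:, :1], ["only"])
        matches, _ = sig.match_to_reference(signature_set, ref)
        assert set(matches["best_match"]) == {"only"}

    def test_recovered_planted_signature_matches_truth(self, signature_set,
                                                       planted_catalog):
        catalog, _ = planted_catalog
        res = sig.nmf_factorize(catalog, rank=3, seed=9)
        matches, _ = sig.match_to_reference(res.signature_matrix(),
                                            signature_set)
        assert set(matches["best_match"]) == set(signature_set.signature_ids)


def grid_search_nnls(counts, probs, step=0.01, max_exposure=None):
    """Brute-force two-signature exposure search (independent oracle)."""
    total = counts.sum()
    hi = max_exposure or 2 * total
    grid = np.arange(0.0, hi + step, step * total)
    best, best_obj = None, np.inf
    for e1 in grid:
        resid = counts - probs[:, 0] * e1
        for e2 in grid:
            obj = np.sum((resid - probs[:, 1] * e2) ** 2)
            if obj < best_obj:
                best_obj, best = obj, (e1, e2)
    return np.array(best), best_obj


class TestRefit:
    def test_exact_mixture_recovery(self, signature_set):
        E = np.array([[100.0, 0.0], [50.0, 400.0], [0.0, 30.0]])
        V = signature_set.probs @ E
        exposures = sig.refit_nnls(V, signature_set)
        assert np.allclose(exposures.values, E, atol=1e-6)

    def test_zero_sample_gives_zero_exposure(self, signature_set):
        exposures = sig.refit_nnls(np.zeros((96, 1)), signature_set)
        assert not exposures.values.any()

    def test_matches_grid_oracle_on_two_signature_toy(self, signature_set):
        two = sig.SignatureMatrix(
            signature_set.probs[:, :2] /
            signature_set.probs[:, :2].sum(axis=0),
            ["a", "b"])
        rng = np.random.default_rng(17)
        counts = rng.poisson(two.probs @ np.array([60.0, 40.0]))
        exposures = sig.refit_nnls(counts[:, None].astype(float), two)
        nnls_obj = np.sum((counts - two.probs @ exposures.values[:, 0]) ** 2)
        _, grid_obj = grid_search_nnls(counts.astype(float), two.probs)
        assert nnls_obj <= grid_obj + 1e-9

    def test_kkt_conditions(self, signature_set, planted_catalog):
        catalog, _ = planted_catalog
        P = signature_set.probs
        exposures = sig.refit_nnls(catalog, signature_set)
        for s in range(0, catalog.n_samples, 10):
            e = exposures.values[:, s]
            grad = P.T @ (P @ e - catalog.counts[:, s])
            assert np.all(grad[e > 1e-9] <= 1e-6 * max(1, np.abs(grad).max()))
            assert np.all(grad[e <= 1e-9] >= -1e-6)

    def test_planted_proportions_recovered(self, signature_set,
                                           planted_catalog):
        catalog, E = planted_catalog
        rel = sig.relative_contribution(
            sig.refit_nnls(catalog, signature_set)).to_numpy()
        truth = E / E.sum(axis=0)
        r = np.corrcoef(rel.ravel(), truth.ravel())[0, 1]
        assert r >= 0.95
        assert np.abs(rel - truth).mean() <= 0.03


class TestRelativeContribution:
    def test_proportions(self):
        exp = sig.ExposureMatrix(np.array([[300.0], [700.0]]), ["a", "b"], ["s"])
        rel = sig.relative_contribution(exp)
        assert rel["s"].tolist() == pytest.approx([0.3, 0.7])

    def test_single_active_signature(self):
        exp = sig.ExposureMatrix(np.array([[42.0], [0.0]]), ["a", "b"], ["s"])
        assert sig.relative_contribution(exp)["s"].tolist() == [1.0, 0.0]

    def test_zero_total_is_missing(self):
        exp = sig.ExposureMatrix(np.zeros((2, 1)), ["a", "b"], ["s"])
        assert sig.relative_contribution(exp)["s"].isna().all()


class TestDifferenceSpectrum:
    def test_identical_spectra(self):
        p = np.full(96, 1 / 96)
        assert np.allclose(sig.difference_spectrum(p, p), 0.0)

    def test_antisymmetry_and_zero_sum(self):
        rng = np.random.default_rng(9)
        p = rng.dirichlet(np.ones(96))
        q = rng.dirichlet(np.ones(96))
        d = sig.difference_spectrum(p, q)
        assert np.allclose(d, -sig.difference_spectrum(q, p))
        assert abs(d.sum()) < 1e-9

    def test_hand_toy(self):
        p = np.zeros(96)
        q = np.zeros(96)
        p[:3] = [0.5, 0.3, 0.2]
        q[:3] = [0.2, 0.3, 0.5]
        d = sig.difference_spectrum(p, q)
        assert d[:3] == pytest.approx([0.3, 0.0, -0.3])

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            sig.difference_spectrum(np.full(96, 0.02), np.full(96, 1 / 96))


class TestCohortContrast:
    def test_identical_groups(self):
        res = sig.cohort_contrast([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["p_value"] == pytest.approx(1.0)

    def test_exact_small_sample_enumeration(self):
        # all 20 rank assignments: only the 2 extreme splits are as extreme
        res = sig.cohort_contrast([1, 2, 3], [4, 5, 6])
        assert res["method"] == "exact"
        assert res["p_value"] == pytest.approx(0.1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            sig.cohort_contrast([], [1.0])

    def test_power_on_shifted_groups(self):
        rng = np.random.default_rng(23)
        hits = 0
        for _ in range(100):
            a = rng.normal(0, 1, 50)
            b = rng.normal(1, 1, 50)
            hits += sig.cohort_contrast(a, b)["p_value"] < 0.05
        assert hits >= 90
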