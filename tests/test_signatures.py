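"""Cosine similarity, NNLS refitting, NMF extraction and clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import mutpatterns as mp
from mutpatterns.signatures import (
    cluster_samples,
    cos_sim,
    cos_sim_matrix,
    extract_signatures,
    fit_to_signatures,
    match_signatures,
    nnls_fit,
    rank_survey,
)


def random_signature_frame(k, seed, n_channels=96):
    rng = np.random.default_rng(seed)
    sigs = rng.dirichlet([0.1] * n_channels, size=k).T
    return pd.DataFrame(sigs, index=list(mp.CHANNELS_96)[:n_channels], columns=[f"S{i}" for i in range(k)])


class TestCosSim:
    def test_direct_evaluation(self):
        assert cos_sim([1, 2, 2], [2, 1, 2]) == pytest.approx(8 / 9)

    def test_identity_and_orthogonality(self):
        assert cos_sim([0.3, 0.7], [0.3, 0.7]) == pytest.approx(1)
        assert cos_sim([1, 0], [0, 1]) == pytest.approx(0)

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            cos_sim([0, 0], [1, 1])

    @given(
        hnp.arrays(np.float64, 8, elements=st.floats(0, 100)),
        hnp.arrays(np.float64, 8, elements=st.floats(0, 100)),
        st.floats(0.01, 50),
    )
    def test_bounds_symmetry_scale_invariance(self, a, b, c):
        if a.sum() == 0 or b.sum() == 0:
            return
        s = cos_sim(a, b)
        assert 0 <= s <= 1
        assert cos_sim(b, a) == pytest.approx(s)
        assert cos_sim(a, c * a) == pytest.approx(1)
        assert cos_sim(c * a, b) == pytest.approx(s)


class TestCosSimMatrix:
    def test_unit_diagonal_and_elementwise(self):
        A = random_signature_frame(3, 1)
        sim = cos_sim_matrix(A, A)
        assert np.allclose(np.diag(sim), 1)
        B = random_signature_frame(2, 2)
        sim2 = cos_sim_matrix(A, B)
        for i in A.columns:
            for j in B.columns:
                assert sim2.loc[i, j] == pytest.approx(cos_sim(A[i], B[j]))

    def test_column_permutation(self):
        A = random_signature_frame(3, 1)
        B = random_signature_frame(3, 2)
        perm = ["S2", "S0", "S1"]
        assert (cos_sim_matrix(A, B[perm]) == cos_sim_matrix(A, B)[perm]).all().all()

    def test_channel_mismatch_errors(self):
        A = random_signature_frame(2, 1)
        B = A.iloc[::-1]
        with pytest.raises(ValueError, match="channel order"):
            cos_sim_matrix(A, B)


def kkt_violation(S, d, x):
    """Max violation of the NNLS optimality conditions."""
    grad = S.T @ (S @ x - d)
    active = np.where(x > 0, np.abs(grad), 0.0)
    inactive = np.where(x <= 0, np.maximum(-grad, 0.0), 0.0)
    return max(active.max(), inactive.max())


class TestNnls:
    def test_exact_two_component_mixture(self):
        S = np.zeros((96, 2))
        S[0, 0] = 1
        S[1, 1] = 1
        d = S @ np.array([0.3, 0.7])
        assert nnls_fit(S, d) == pytest.approx([0.3, 0.7])

    def test_orthogonal_target(self):
        S = np.array([[1.0], [0.0]])
        x = nnls_fit(S, np.array([0.0, 1.0]))
        assert x == pytest.approx([0.0])

    def test_recovers_planted_weights(self):
        S = random_signature_frame(5, 3).to_numpy()
        x_true = np.array([5.0, 0.0, 2.5, 0.0, 1.0])
        x = nnls_fit(S, S @ x_true)
        assert np.abs(x - x_true).max() < 1e-6

    def test_matches_simplex_grid_oracle_k2(self):
        """Brute-force search over the weight simplex agrees at grid resolution."""
        rng = np.random.default_rng(4)
        S = random_signature_frame(2, 5).to_numpy()
        w = rng.dirichlet([1, 1])
        d = S @ w
        grid = np.linspace(0, 1, 10_001)  # step 1e-4
        X = np.stack([grid, 1 - grid])
        best = grid[np.argmin(((S @ X - d[:, None]) ** 2).sum(axis=0))]
        x = nnls_fit(S, d)
        assert abs(x[0] - best) < 1e-4 + 1e-8

    def test_kkt_conditions(self):
        rng = np.random.default_rng(9)
        for k in (2, 3, 5):
            S = random_signature_frame(k, int(rng.integers(1000))).to_numpy()
            d = rng.random(96)
            x = nnls_fit(S, d)
            assert kkt_violation(S, d, x) < 1e-8 * max(1.0, np.linalg.norm(d))

    def test_shape_and_negativity_errors(self):
        with pytest.raises(ValueError, match="shape"):
            nnls_fit(np.ones((4, 2)), np.ones(3))
        with pytest.raises(ValueError, match="negative"):
            nnls_fit(np.ones((2, 1)), np.array([-1.0, 0.0]))


class TestFitToSignatures:
    def test_exact_mixtures_reconstruct_perfectly(self):
        S = random_signature_frame(4, 11)
        W = np.random.default_rng(12).random((4, 6)) * 100
        M = pd.DataFrame(S.to_numpy() @ W, index=S.index, columns=[f"m{i}" for i in range(6)])
        fit = fit_to_signatures(M, S)
        assert (fit.diagnostics["cosine"] >= 1 - 1e-9).all()
        assert (fit.diagnostics["rss"] < 1e-9).all()
        assert not fit.diagnostics["flagged"].any()

    def test_single_signature_scaling(self):
        S = random_signature_frame(3, 13)
        M = pd.DataFrame({"m": 500 * S["S1"]})
        fit = fit_to_signatures(M, S)
        x = fit.contributions["m"]
        assert x["S1"] == pytest.approx(500, abs=1e-6)
        assert x.drop("S1").abs().max() < 1e-6

    def test_per_sample_independence(self, separated_signatures):
        rng = np.random.default_rng(14)
        W = rng.dirichlet([1] * 3, size=4)
        M = mp.simulate_mut_matrix(separated_signatures, W, 1000, seed=15)
        whole = fit_to_signatures(M, separated_signatures)
        alone = fit_to_signatures(M[["sample_2"]], separated_signatures)
        assert np.allclose(whole.contributions["sample_2"], alone.contributions["sample_2"])

    def test_simulated_contribution_correlation(self, separated_signatures):
        """Refitted weights track the generating mixture weights."""
        rng = np.random.default_rng(16)
        W = rng.dirichlet([0.8] * 3, size=8)
        M = mp.simulate_mut_matrix(separated_signatures, W, 5000, seed=17)
        fit = fit_to_signatures(M, separated_signatures)
        est = fit.relative_contributions().to_numpy().T.ravel()
        r = np.corrcoef(W.ravel(), est)[0, 1]
        assert r >= 0.95

    def test_absolute_contributions_sum_to_mutation_count(self, separated_signatures):
        W = np.array([[0.5, 0.25, 0.25]])
        d = separated_signatures.to_numpy() @ (W[0] * 800)
        M = pd.DataFrame({"m": d}, index=separated_signatures.index)
        fit = fit_to_signatures(M, separated_signatures)
        assert fit.contributions["m"].sum() == pytest.approx(800, rel=1e-9)


class TestExtractSignatures:
    def test_rank1_exact(self):
        rng = np.random.default_rng(21)
        w = rng.random(96) + 0.05
        h = rng.random(5) * 100 + 10
        M = pd.DataFrame(np.outer(w, h), index=list(mp.CHANNELS_96), columns=[f"s{i}" for i in range(5)])
        res = extract_signatures(M, rank=1, nrun=2, seed=1)
        assert cos_sim(res.signatures.iloc[:, 0], w) >= 0.999
        recon = res.reconstructed().to_numpy()
        assert np.abs(recon - M.to_numpy()).max() / M.to_numpy().max() < 1e-3

    def test_determinism(self, separated_signatures):
        M = mp.simulate_mut_matrix(separated_signatures, np.eye(3)[[0, 1, 2, 0]], 400, seed=2)
        a = extract_signatures(M, rank=2, nrun=3, seed=5)
        b = extract_signatures(M, rank=2, nrun=3, seed=5)
        assert (a.signatures == b.signatures).all().all()
        assert (a.contributions == b.contributions).all().all()
        assert a.best_run == b.best_run

    def test_objective_monotone_non_increasing(self, separated_signatures):
        M = mp.simulate_mut_matrix(separated_signatures, np.eye(3)[[0, 1, 2, 1]], 500, seed=3)
        res = extract_signatures(M, rank=2, nrun=1, seed=9)
        h = np.array(res.history)
        assert (np.diff(h) <= 1e-8 * np.maximum(np.abs(h[:-1]), 1)).all()

    def test_signatures_column_stochastic_and_product_preserved(self, separated_signatures):
        M = mp.simulate_mut_matrix(separated_signatures, np.eye(3)[[0, 1, 2, 2]], 600, seed=4)
        res = extract_signatures(M, rank=2, nrun=2, seed=6)
        assert np.allclose(res.signatures.sum(axis=0), 1)
        assert (res.contributions.to_numpy() >= 0).all()

    def test_input_validation(self, separated_signatures):
        M = mp.simulate_mut_matrix(separated_signatures, np.eye(3), 100, seed=5)
        with pytest.raises(ValueError, match="rank"):
            extract_signatures(M, rank=3, nrun=1, seed=1)
        M2 = M.copy()
        M2["sample_1"] = 0
        with pytest.raises(ValueError, match="all-zero"):
            extract_signatures(M2, rank=2, nrun=1, seed=1)

    def test_cross_check_against_sklearn(self, separated_signatures):
        """Independent NMF implementation finds the same signatures."""
        sklearn_nmf = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(31)
        W = rng.dirichlet([0.5] * 3, size=12)
        M = mp.simulate_mut_matrix(separated_signatures, W, 2000, seed=32)
        ours = extract_signatures(M, rank=3, nrun=5, seed=33)
        model = sklearn_nmf.NMF(
            n_components=3, solver="mu", beta_loss="kullback-leibler", init="random",
            random_state=0, max_iter=2000, tol=1e-8,
        )
        Wsk = model.fit_transform(M.to_numpy())
        theirs = pd.DataFrame(
            Wsk / Wsk.sum(axis=0), index=M.index, columns=[f"sk{i}" for i in range(3)]
        )
        matched = match_signatures(ours.signatures, theirs)
        assert (matched["cosine"] >= 0.98).all()


class TestRankSurvey:
    def test_returns_ranks_in_order(self, separated_signatures):
        M = mp.simulate_mut_matrix(
            separated_signatures, np.random.default_rng(41).dirichlet([1] * 3, 8), 800, seed=42
        )
        survey = rank_survey(M, [2, 3], nrun=2, seed=43)
        assert list(survey["rank"]) == [2, 3]
        assert {"best_objective", "mean_reconstruction_cosine", "stability"} <= set(survey.columns)

    def test_elbow_at_true_rank(self, separated_signatures):
        rng = np.random.default_rng(44)
        M = mp.simulate_mut_matrix(separated_signatures, rng.dirichlet([0.5] * 3, 20), 2000, seed=45)
        survey = rank_survey(M, [2, 3, 4], nrun=4, seed=46).set_index("rank")
        cos = survey["mean_reconstruction_cosine"]
        assert cos[4] - cos[3] < cos[3] - cos[2]
        assert survey["stability"][3] >= survey["stability"][4]


class TestClusterSamples:
    def test_identical_rows_merge_first(self):
        X = pd.DataFrame([[1.0, 0.0], [1.0, 0.0], [0.0, 5.0]], index=["a", "b", "c"])
        res = cluster_samples(X)
        assert res.linkage[0, 2] == pytest.approx(0.0)
        first_pair = {res.labels[int(res.linkage[0, 0])], res.labels[int(res.linkage[0, 1])]}
        assert first_pair == {"a", "b"}

    def test_outlier_merges_last(self):
        X = pd.DataFrame([[0.0, 0.0], [1.0, 0.0], [10.0, 10.0]], index=["a", "b", "far"])
        res = cluster_samples(X)
        assert res.leaf_order.index("far") in (0, 2)
        last = res.linkage[-1]
        assert last[2] > res.linkage[0][2]

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(51)
        X = pd.DataFrame(rng.random((6, 4)), index=list("abcdef"))
        r1 = cluster_samples(X)
        r2 = cluster_samples(X.iloc[[3, 1, 5, 0, 2, 4]])
        def merges(res):
            out = []
            n = len(res.labels)
            clusters = {i: frozenset([res.labels[i]]) for i in range(n)}
            for k, (i, j, _, _) in enumerate(res.linkage):
                merged = clusters[int(i)] | clusters[int(j)]
                clusters[n + k] = merged
                out.append(merged)
            return set(out)
        assert merges(r1) == merges(r2)

    def test_newick_export(self):
        X = pd.DataFrame([[0.0], [1.0], [5.0]], index=["a", "b", "c"])
        nwk = cluster_samples(X).to_newick()
        assert nwk.endswith(";") and all(s in nwk for s in "abc")

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="at least 2"):
            cluster_samples(pd.DataFrame([[1.0]], index=["a"]))
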