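"""sPLS against a dense SVD oracle; sparsity, similarity, and networks."""

import numpy as np
import pandas as pd
import pytest

import panelomics as po
from panelomics.spls import _soft_keep


def _random_blocks(rng, n=12, p=8, q=5):
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)],
                     index=[f"G{i}" for i in range(n)])
    Y = pd.DataFrame(rng.normal(size=(n, q)), columns=[f"y{j}" for j in range(q)],
                     index=X.index)
    return po.autoscale(X), po.autoscale(Y)


def _factor_blocks(rng, n=12, p=12, q=6, k=4, noise=0.15):
    f = rng.normal(size=n)
    X = rng.normal(size=(n, p)) * noise
    X[:, :k] += f[:, None]
    Y = rng.normal(size=(n, q)) * noise + f[:, None]
    idx = [f"G{i}" for i in range(n)]
    X = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)], index=idx)
    Y = pd.DataFrame(Y, columns=[f"y{j}" for j in range(q)], index=idx)
    return po.autoscale(X), po.autoscale(Y)


class TestSoftKeep:
    def test_retains_largest_magnitudes(self):
        w = np.array([0.1, -3.0, 2.0, 0.5])
        out = _soft_keep(w, 2)
        assert (out != 0).sum() == 2
        assert out[1] < 0 < out[2]

    def test_keep_all_is_identity(self):
        w = np.array([1.0, -2.0])
        assert np.allclose(_soft_keep(w, 5), w)


class TestSPLSFit:
    @pytest.mark.parametrize("seed", range(5))
    def test_dense_first_component_equals_svd(self, seed):
        X, Y = _random_blocks(np.random.default_rng(seed))
        m = po.spls_fit(X, Y, n_components=1, keep_x=X.shape[1], keep_y=Y.shape[1])
        u, s, vt = np.linalg.svd(X.to_numpy().T @ Y.to_numpy())
        assert abs(float(m.x_weights.iloc[:, 0] @ u[:, 0])) > 0.999
        assert abs(float(m.y_weights.iloc[:, 0] @ vt[0])) > 0.999
        # and the variate pair attains the leading singular value (max cov)
        t = m.x_variates.iloc[:, 0].to_numpy()
        sv = m.y_variates.iloc[:, 0].to_numpy()
        assert abs(t @ Y.to_numpy() @ m.y_weights.iloc[:, 0].to_numpy()) == pytest.approx(s[0], rel=1e-6)

    def test_noiseless_copy_column_selected(self):
        rng = np.random.default_rng(10)
        X, _ = _random_blocks(rng)
        Y = X[["x2"]].rename(columns={"x2": "y0"})
        m = po.spls_fit(X, Y, n_components=1, keep_x=1, keep_y=1)
        w = m.x_weights.iloc[:, 0]
        assert abs(w["x2"]) == pytest.approx(1.0)
        r = np.corrcoef(m.x_variates.iloc[:, 0], m.y_variates.iloc[:, 0])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_planted_support_recovery(self):
        hits = 0
        for seed in range(50):
            X, Y = _factor_blocks(np.random.default_rng(100 + seed))
            m = po.spls_fit(X, Y, n_components=1, keep_x=4, keep_y=Y.shape[1])
            sel = set(m.x_weights.index[m.x_weights.iloc[:, 0] != 0])
            hits += sel == {"x0", "x1", "x2", "x3"}
        assert hits >= 45  # >= 90% of seeds

    def test_sparsity_budget_respected(self):
        X, Y = _random_blocks(np.random.default_rng(1))
        m = po.spls_fit(X, Y, n_components=2, keep_x=3, keep_y=2)
        for h in range(2):
            assert (m.x_weights.iloc[:, h] != 0).sum() <= 3
            assert (m.y_weights.iloc[:, h] != 0).sum() <= 2
            assert np.linalg.norm(m.x_weights.iloc[:, h]) == pytest.approx(1.0)

    def test_sign_convention_and_reproducibility(self):
        X, Y = _random_blocks(np.random.default_rng(2))
        m1 = po.spls_fit(X, Y, n_components=2)
        m2 = po.spls_fit(X.copy(), Y.copy(), n_components=2)
        pd.testing.assert_frame_equal(m1.x_weights, m2.x_weights, check_exact=True)
        for h in range(2):
            w = m1.x_weights.iloc[:, h].to_numpy()
            assert w[np.abs(w).argmax()] > 0

    def test_joint_row_permutation_invariance(self):
        X, Y = _factor_blocks(np.random.default_rng(3))
        perm = np.random.default_rng(4).permutation(len(X))
        Xp, Yp = X.iloc[perm], Y.iloc[perm]
        m1 = po.spls_fit(X, Y, n_components=1)
        m2 = po.spls_fit(Xp, Yp, n_components=1)
        M1 = po.similarity_matrix(m1, X, Y)
        M2 = po.similarity_matrix(m2, Xp, Yp)
        assert np.allclose(M1.to_numpy(), M2.to_numpy(), atol=1e-8)

    def test_x_only_permutation_destroys_signal(self):
        X, Y = _factor_blocks(np.random.default_rng(5))
        Xp = pd.DataFrame(X.to_numpy()[np.random.default_rng(6).permutation(len(X))],
                          index=X.index, columns=X.columns)
        m = po.spls_fit(Xp, Y, n_components=1)
        M = po.similarity_matrix(m, Xp, Y)
        assert np.abs(M.to_numpy()[:4]).max() < 0.7  # planted block edges gone

    def test_mismatched_rows_rejected(self):
        X, Y = _random_blocks(np.random.default_rng(7))
        with pytest.raises(po.PanelError, match="row"):
            po.spls_fit(X.iloc[:10], Y, n_components=1)


class TestSimilarityMatrix:
    def test_identical_aligned_column_scores_one(self):
        rng = np.random.default_rng(20)
        n = 12
        f = rng.normal(size=n)
        X = po.autoscale(pd.DataFrame({"x0": f, "x1": rng.normal(size=n)}))
        Y = po.autoscale(pd.DataFrame({"y0": f}))
        m = po.spls_fit(X, Y, n_components=1, keep_x=1, keep_y=1)
        M = po.similarity_matrix(m, X, Y)
        assert M.loc["x0", "y0"] == pytest.approx(1.0, abs=1e-9)
        assert M.to_numpy().min() >= -1.0 - 1e-9 and M.to_numpy().max() <= 1.0 + 1e-9

    def test_uncorrelated_row_near_zero(self):
        vals = []
        for seed in range(30):
            X, Y = _factor_blocks(np.random.default_rng(seed), p=8, k=3)
            m = po.spls_fit(X, Y, n_components=1, keep_x=3)
            M = po.similarity_matrix(m, X, Y)
            vals.append(np.abs(M.loc["x7"].to_numpy()).max())  # noise column
        assert np.mean(vals) < 0.4

    def test_approximates_correlation_under_one_factor_model(self):
        # strict one-factor data: every column loads (+/-) on a shared latent
        rng = np.random.default_rng(21)
        n, p, q, noise = 12, 8, 5, 0.05
        f = rng.normal(size=n)
        sx = np.where(rng.random(p) < 0.5, 1.0, -1.0)
        sy = np.where(rng.random(q) < 0.5, 1.0, -1.0)
        X = po.autoscale(pd.DataFrame(
            f[:, None] * sx + noise * rng.normal(size=(n, p)),
            columns=[f"x{j}" for j in range(p)], index=[f"G{i}" for i in range(n)]))
        Y = po.autoscale(pd.DataFrame(
            f[:, None] * sy + noise * rng.normal(size=(n, q)),
            columns=[f"y{j}" for j in range(q)], index=X.index))
        m = po.spls_fit(X, Y, n_components=1, keep_x=p, keep_y=q)
        M = po.similarity_matrix(m, X, Y)
        corr = np.corrcoef(X.to_numpy().T, Y.to_numpy().T)[:p, p:]
        assert np.abs(M.to_numpy() - corr).max() < 0.1


class TestBuildNetwork:
    def test_threshold_extremes(self):
        M = pd.DataFrame([[0.9, -0.8], [0.2, 0.5]], index=["x0", "x1"], columns=["y0", "y1"])
        assert po.build_network(M, threshold=1.01).n_edges == 0
        full = po.build_network(M, threshold=0.0)
        assert full.n_edges == 4  # complete bipartite
        net = po.build_network(M, threshold=0.7)
        assert net.edge_keys() == {("x0", "y0"), ("x0", "y1")}
        signs = {e.key(): np.sign(e.weight) for e in net.edges}
        assert signs[("x0", "y1")] == -1

    def test_isolated_nodes_dropped(self):
        M = pd.DataFrame([[0.9], [0.1]], index=["x0", "x1"], columns=["y0"])
        net = po.build_network(M, threshold=0.7)
        assert net.node_set() == {"x0", "y0"}

    def test_planted_block_edges_recovered_with_precision(self):
        precisions = []
        for seed in range(20):
            X, Y = _factor_blocks(np.random.default_rng(500 + seed), noise=0.1)
            m = po.spls_fit(X, Y, n_components=1, keep_x=4)
            M = po.similarity_matrix(m, X, Y)
            net = po.build_network(M, threshold=0.7)
            if net.n_edges == 0:
                continue
            true_edges = {(f"x{i}", f"y{j}") for i in range(4) for j in range(Y.shape[1])}
            found = {tuple(sorted(k)) for k in net.edge_keys()}
            true_sorted = {tuple(sorted(e)) for e in true_edges}
            precisions.append(len(found & true_sorted) / len(found))
        assert np.mean(precisions) >= 0.8


class TestLaggedNetwork:
    def test_same_stage_equals_within_stage_pipeline(self, small_panel):
        table, _, _ = small_panel
        _, M1, n1 = po.spls_network(table, "CE", n_components=2)
        _, M2, n2 = po.lagged_network(table, "CE", "CE", n_components=2)
        pd.testing.assert_frame_equal(M1, M2, check_exact=True)
        assert n1.edge_keys() == n2.edge_keys()

    def test_planted_lagged_dependency_recovered(self):
        # Y at the later stage built from the X factor of the earlier stage
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(700 + seed)
            n, p, k = 12, 10, 3
            idx = pd.MultiIndex.from_product(
                [[f"G{i}" for i in range(n)], ["CE", "OR"], [1]],
                names=("genotype", "stage", "replicate"))
            f = rng.normal(size=n)
            spots = rng.normal(size=(n, p)) * 0.1
            spots[:, :k] += f[:, None]
            met_or = f[:, None] + rng.normal(size=(n, 2)) * 0.1
            rows = []
            for gi, g in enumerate([f"G{i}" for i in range(n)]):
                for s in ("CE", "OR"):
                    rows.append(np.concatenate([
                        spots[gi] if s == "CE" else rng.normal(size=p),
                        met_or[gi] if s == "OR" else rng.normal(size=2)]))
            cols = [f"spot{j}" for j in range(p)] + ["metA", "metB"]
            vals = pd.DataFrame(rows, index=idx, columns=cols)
            meta = po.make_trait_meta(cols, ["protein_spot"] * p + ["metabolite"] * 2)
            table = po.TraitTable(vals, meta)
            _, M, net = po.lagged_network(table, "CE", "OR", n_components=1,
                                          keep_x=k, threshold=0.7)
            want = {(f"spot{j}", m) for j in range(k) for m in ("metA", "metB")}
            hits += want <= {tuple(sorted(e, key=lambda x: (not x.startswith("spot"), x)))
                             for e in net.edge_keys()}
        assert hits >= 8

    def test_empty_y_errors(self, small_panel):
        table, _, _ = small_panel
        with pytest.raises(po.PanelError, match="empty"):
            po.lagged_network(table, "CE", "OR", y_traits=[])
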