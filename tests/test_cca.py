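"""Regularized CCA, cross-validated penalty selection, relevance networks."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

import bigsea as bg

from conftest import make_groups


def _centered_pair(seed=42, n=20, p=4, q=3):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, p))
    y = rng.standard_normal((n, q))
    return x - x.mean(0), y - y.mean(0)


def _classical_cca_oracle(x, y):
    """Whitening-based classical CCA: correlations via SVD of whitened cross-cov."""
    n = x.shape[0]
    sxx = x.T @ x / (n - 1)
    syy = y.T @ y / (n - 1)
    sxy = x.T @ y / (n - 1)
    wx = np.real(linalg.sqrtm(linalg.inv(sxx)))
    wy = np.real(linalg.sqrtm(linalg.inv(syy)))
    return linalg.svd(wx @ sxy @ wy, compute_uv=False)


class TestZscoreWithinGroup:
    def test_per_group_moments(self):
        ids, groups = make_groups(7, 7)
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(5, 3, size=(14, 6)), index=ids)
        z = bg.zscore_within_group(m, groups)
        for label in ("A", "B"):
            block = z.loc[groups.mask(ids, label)]
            assert np.abs(block.mean()).max() < 1e-12
            assert np.abs(block.var(ddof=1) - 1).max() < 1e-12

    def test_group_shift_removed(self):
        # variable = pure group shift + noise -> near-zero correlation with group
        ids, groups = make_groups(7, 7)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            v = rng.normal(0, 1, 14)
            v[7:] += 5.0
            z = bg.zscore_within_group(pd.DataFrame({"v": v}, index=ids), groups)
            r = np.corrcoef(z["v"], np.r_[np.zeros(7), np.ones(7)])[0, 1]
            hits += abs(r) < 0.2
        assert hits == 20

    def test_two_by_two_hand_calculation(self):
        ids, groups = make_groups(2, 2)
        m = pd.DataFrame({"v": [0.0, 1.0, 5.0, 9.0]}, index=ids)
        z = bg.zscore_within_group(m, groups)
        expected = [-np.sqrt(0.5), np.sqrt(0.5), -np.sqrt(0.5), np.sqrt(0.5)]
        np.testing.assert_allclose(z["v"], expected, atol=1e-12)

    def test_constant_within_group_named(self):
        ids, groups = make_groups(3, 3)
        m = pd.DataFrame({"flat": [1, 1, 1, 2, 3, 4]}, index=ids, dtype=float)
        with pytest.raises(ValueError, match="flat.*A"):
            bg.zscore_within_group(m, groups)


class TestRcc:
    def test_duplicated_column_gives_perfect_correlation(self):
        x, _ = _centered_pair()
        y = x[:, [0]].copy()
        model = bg.rcc(x, y, 0.0, 0.0)
        assert model.can_cor[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_classical_cca_oracle_at_zero_penalty(self):
        x, y = _centered_pair()
        model = bg.rcc(x, y, 0.0, 0.0)
        rho = _classical_cca_oracle(x, y)
        assert np.abs(model.can_cor - rho[: model.n_dims]).max() < 1e-8

    def test_variates_reproduce_canonical_correlations(self):
        # at lambda = 0 the plain Pearson correlation of paired variates is rho
        # (with ridge, rho is the correlation under the regularized metric)
        x, y = _centered_pair(seed=3)
        model = bg.rcc(x, y, 0.0, 0.0)
        for l in range(model.n_dims):
            r = stats.pearsonr(model.x_variates[:, l], model.y_variates[:, l])[0]
            assert r == pytest.approx(model.can_cor[l], abs=1e-8)

    def test_heavy_penalty_limit_is_cross_covariance_svd(self):
        x, y = _centered_pair(seed=5)
        lam = 1e8
        model = bg.rcc(x, y, lam, lam)
        n = x.shape[0]
        u, _, vt = linalg.svd(x.T @ y / (n - 1), full_matrices=False)
        a = model.x_weights[:, 0] / np.linalg.norm(model.x_weights[:, 0])
        assert abs(abs(a @ u[:, 0])) == pytest.approx(1.0, abs=1e-4)

    def test_role_symmetry(self):
        x, y = _centered_pair(seed=7)
        fwd = bg.rcc(x, y, 0.2, 0.4)
        rev = bg.rcc(y, x, 0.4, 0.2)
        assert np.abs(fwd.can_cor - rev.can_cor).max() < 1e-10

    def test_rotation_invariance_of_correlations(self):
        x, y = _centered_pair(seed=8)
        q, _ = np.linalg.qr(np.random.default_rng(9).standard_normal((4, 4)))
        rotated = bg.rcc(x @ q, y, 0.0, 0.0)
        base = bg.rcc(x, y, 0.0, 0.0)
        assert np.abs(base.can_cor - rotated.can_cor).max() < 1e-10

    def test_collinear_columns_without_penalty_rejected(self):
        x, y = _centered_pair()
        x_bad = np.hstack([x, x[:, [0]]])
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            bg.rcc(x_bad, y, 0.0, 0.0)

    def test_uncentered_input_rejected(self):
        x, y = _centered_pair()
        with pytest.raises(ValueError, match="centered"):
            bg.rcc(x + 5.0, y, 0.1, 0.1)


class TestEstimateRegularization:
    def test_single_point_grid_returned(self):
        x, y = _centered_pair(seed=11, n=10)
        lx, ly, surface = bg.estimate_regularization(x, y, [0.3], [0.7])
        assert (lx, ly) == (0.3, 0.7)
        assert surface.shape == (1, 1)

    def test_surface_matches_explicit_loo_loop(self):
        x, y = _centered_pair(seed=12, n=12, p=5, q=3)
        grid = [0.05, 0.5]
        _, _, surface = bg.estimate_regularization(x, y, grid, grid)
        for lx in grid:
            for ly in grid:
                u = np.empty(12)
                v = np.empty(12)
                for i in range(12):
                    keep = np.arange(12) != i
                    xt = x[keep] - x[keep].mean(0)
                    yt = y[keep] - y[keep].mean(0)
                    model = bg.rcc(xt, yt, lx, ly)
                    u[i] = (x[i] - x[keep].mean(0)) @ model.x_weights[:, 0]
                    v[i] = (y[i] - y[keep].mean(0)) @ model.y_weights[:, 0]
                expected = np.corrcoef(u, v)[0, 1]
                assert surface.at[lx, ly] == pytest.approx(expected, abs=1e-10)

    def test_shared_latent_factor_beats_extreme_corners(self):
        rng = np.random.default_rng(13)
        n, p, q = 14, 60, 8
        latent = rng.standard_normal(n)
        x = 0.8 * np.outer(latent, rng.standard_normal(p) / 3) + rng.standard_normal((n, p))
        y = 0.8 * np.outer(latent, np.ones(q)) + rng.standard_normal((n, q))
        x -= x.mean(0)
        y -= y.mean(0)
        grid = [1e-4, 0.01, 0.1, 1.0, 100.0]
        lx, ly, surface = bg.estimate_regularization(x, y, grid, grid)
        best = surface.at[lx, ly]
        assert best >= surface.at[1e-4, 1e-4] - 1e-12
        assert best >= surface.at[100.0, 100.0] - 1e-12


class TestSimilarityNetwork:
    def test_single_dimension_product(self):
        # engineer variates, then check s = corr(x_j, Z) * corr(y_k, Z)
        x, y = _centered_pair(seed=14, n=30, p=3, q=2)
        model = bg.rcc(x, y, 0.1, 0.1)
        net = bg.similarity_network(model, x, y, d=1, tau=0.0)
        z = (model.x_variates[:, 0] + model.y_variates[:, 0]) / 2
        for j in range(3):
            for k in range(2):
                expected = (
                    stats.pearsonr(x[:, j], z)[0] * stats.pearsonr(y[:, k], z)[0]
                )
                assert net.similarity.iat[j, k] == pytest.approx(expected, abs=1e-12)

    def test_matrix_product_equals_double_loop(self):
        x, y = _centered_pair(seed=15, n=20, p=6, q=4)
        model = bg.rcc(x, y, 0.2, 0.2)
        d = 3
        net = bg.similarity_network(model, x, y, d=d, tau=0.0)
        z = (model.x_variates[:, :d] + model.y_variates[:, :d]) / 2
        for j in range(6):
            for k in range(4):
                s = sum(
                    stats.pearsonr(x[:, j], z[:, l])[0]
                    * stats.pearsonr(y[:, k], z[:, l])[0]
                    for l in range(d)
                )
                assert abs(net.similarity.iat[j, k] - s) < 1e-12

    def test_threshold_rule(self):
        sim = pd.DataFrame(
            [[0.7, 0.64], [-0.66, 0.0]], index=["g1", "g2"], columns=["m1", "m2"]
        )
        net = bg.SimilarityNetwork.from_similarity(sim, dims_used=2, threshold=0.65)
        assert [(e[0], e[1], e[3]) for e in net.edges] == [
            ("g1", "m1", "positive"),
            ("g2", "m1", "negative"),
        ]

    def test_increasing_threshold_never_adds_edges(self):
        x, y = _centered_pair(seed=16, n=15, p=8, q=5)
        model = bg.rcc(x, y, 0.1, 0.1)
        counts = [
            len(bg.similarity_network(model, x, y, d=3, tau=tau).edges)
            for tau in (0.0, 0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_similarity_bounded_by_dimension_count(self):
        x, y = _centered_pair(seed=17, n=15, p=8, q=5)
        model = bg.rcc(x, y, 0.1, 0.1)
        d = 4
        net = bg.similarity_network(model, x, y, d=d, tau=0.0)
        assert np.abs(net.similarity.to_numpy()).max() <= d

    def test_dimension_overflow_rejected(self):
        x, y = _centered_pair()
        model = bg.rcc(x, y, 0.1, 0.1)
        with pytest.raises(ValueError, match="d must be"):
            bg.similarity_network(model, x, y, d=10)


class TestSelectMarkerAssociatedGenes:
    def _setup(self):
        sim = pd.DataFrame(
            [[0.8, 0.1], [0.1, 0.0], [0.9, 0.2]],
            index=["g1", "g2", "g3"],
            columns=["m1", "m2"],
        )
        net = bg.SimilarityNetwork.from_similarity(sim, 2, 0.65)
        de = bg.DiffExpResult(
            gene_ids=["g1", "g2", "g3"],
            log_fc=np.array([1.0, 2.0, 0.1]),
            t_stat=np.array([5.0, 6.0, 0.5]),
            df_residual=np.array([12.0] * 3),
            residual_variance=np.array([1.0] * 3),
            p_raw=np.array([0.001, 0.001, 0.5]),
            p_adj=np.array([0.01, 0.01, 0.2]),
            moderated=False,
            reference_group="A",
        )
        return net, de

    def test_conjunction_rule(self):
        net, de = self._setup()
        # g1: edge + significant -> in; g2: significant, no edge -> out;
        # g3: edge, not significant -> out
        assert bg.select_marker_associated_genes(net, de, 0.05) == ["g1"]

    def test_raw_p_gate_option(self):
        net, de = self._setup()
        de.p_raw[2] = 0.01
        assert bg.select_marker_associated_genes(net, de, 0.05, use_adjusted=False) == [
            "g1",
            "g3",
        ]

    def test_disjoint_universes_rejected(self):
        net, de = self._setup()
        de.gene_ids = ["other1", "other2", "other3"]
        with pytest.raises(ValueError, match="disjoint"):
            bg.select_marker_associated_genes(net, de)


class TestMixOmicsCrossCheck:
    """Independent implementation check against mixOmics rcc/network in R."""

    def test_canonical_correlations_and_similarity(self, tmp_path):
        rng = np.random.default_rng(77)
        n, p, q = 14, 10, 4
        x = rng.standard_normal((n, p))
        y = rng.standard_normal((n, q))
        x -= x.mean(0)
        y -= y.mean(0)
        np.savetxt(tmp_path / "x.tsv", x, delimiter="\t")
        np.savetxt(tmp_path / "y.tsv", y, delimiter="\t")
        script = tmp_path / "check.R"
        script.write_text(
            'suppressMessages(library(mixOmics))\n'
            'x <- as.matrix(read.table("x.tsv")); colnames(x) <- paste0("g", 1:ncol(x))\n'
            'y <- as.matrix(read.table("y.tsv")); colnames(y) <- paste0("m", 1:ncol(y))\n'
            'fit <- rcc(x, y, method="ridge", lambda1=0.1, lambda2=0.2)\n'
            'write.table(fit$cor, "rho.tsv", col.names=FALSE, row.names=FALSE)\n'
            'pdf(NULL)\n'
            'net <- network(fit, comp=1:2, cutoff=0)\n'
            'write.table(net$M, "simM.tsv", sep="\\t", quote=FALSE)\n'
        )
        proc = subprocess.run(
            ["Rscript", "check.R"], cwd=tmp_path, capture_output=True, text=True
        )
        assert proc.returncode == 0, proc.stderr
        model = bg.rcc(x, y, 0.1, 0.2)
        rho_r = np.loadtxt(tmp_path / "rho.tsv")
        np.testing.assert_allclose(model.can_cor, rho_r, atol=1e-6)
        sim_r = pd.read_csv(tmp_path / "simM.tsv", sep="\t").to_numpy()
        net = bg.similarity_network(model, x, y, d=2, tau=0.0)
        np.testing.assert_allclose(net.similarity.to_numpy(), sim_r, atol=1e-6)
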