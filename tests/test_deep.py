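"""Cholesky feature encoding, network accounting, training and grid search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mtgp.genotypes import GRM, CholeskyFactor, cholesky_factor
from mtgp.gblup import build_design_matrices
from mtgp.deep import (
    EncodedInputs,
    HyperGrid,
    NetworkSpec,
    count_grid,
    encode_features,
    grid_search,
    network_depth,
    network_size,
    network_width,
    predict_network,
    train_network,
)

from conftest import random_psd


def _design(J, I, n_cells, rng):
    lines = [f"L{j}" for j in range(J)]
    envs = [f"E{i}" for i in range(I)]
    cells = [(l, e) for e in envs for l in lines]
    idx = rng.permutation(len(cells))[:n_cells]
    chosen = [cells[k] for k in sorted(idx)]
    pheno = pd.DataFrame({"line": [c[0] for c in chosen],
                          "environment": [c[1] for c in chosen],
                          "value": rng.normal(size=len(chosen))})
    return pheno, lines, envs


class TestEncoding:
    def test_identity_factor_leaves_design_unchanged(self, rng):
        pheno, lines, envs = _design(4, 2, 6, rng)
        Z_E, Z_G, Z_GE = build_design_matrices(pheno, line_ids=lines, env_ids=envs)
        fac = CholeskyFactor(np.eye(4), lines)
        enc = encode_features(Z_E, Z_G, Z_GE, fac, include_interaction=False)
        start, stop = enc.column_blocks["genotype"]
        np.testing.assert_array_equal(enc.X[:, start:stop], Z_G.toarray())

    def test_genotype_covariance_identity(self, rng):
        G = random_psd(5, rng)
        pheno, lines, envs = _design(5, 2, 8, rng)
        Z_E, Z_G, Z_GE = build_design_matrices(pheno, line_ids=lines, env_ids=envs)
        fac = cholesky_factor(GRM(G, lines))
        enc = encode_features(Z_E, Z_G, Z_GE, fac, include_interaction=False)
        a, b = enc.column_blocks["genotype"]
        Xg = enc.X[:, a:b]
        lhs = Xg @ Xg.T
        rhs = (Z_G @ (G + fac.jitter * np.eye(5)) @ Z_G.T)
        np.testing.assert_allclose(lhs, np.asarray(rhs), atol=1e-8)

    def test_interaction_kronecker_identity(self, rng):
        # dense Kronecker oracle on a complete 2-env x 3-line design
        G = random_psd(3, rng)
        lines = [f"L{j}" for j in range(3)]
        envs = ["E0", "E1"]
        pheno = pd.DataFrame({"line": lines * 2,
                              "environment": ["E0"] * 3 + ["E1"] * 3,
                              "value": np.arange(6.0)})
        Z_E, Z_G, Z_GE = build_design_matrices(pheno, line_ids=lines, env_ids=envs)
        fac = cholesky_factor(GRM(G, lines))
        enc = encode_features(Z_E, Z_G, Z_GE, fac, include_interaction=True)
        a, b = enc.column_blocks["interaction"]
        Xge = enc.X[:, a:b]
        Gj = G + fac.jitter * np.eye(3)
        rhs = Z_GE @ np.kron(np.eye(2), Gj) @ Z_GE.T
        np.testing.assert_allclose(Xge @ Xge.T, np.asarray(rhs), atol=1e-8)

    def test_ordering_mismatch_rejected(self, rng):
        pheno, lines, envs = _design(4, 2, 6, rng)
        Z_E, Z_G, Z_GE = build_design_matrices(pheno, line_ids=lines, env_ids=envs)
        fac = CholeskyFactor(np.eye(3), lines[:3])
        with pytest.raises(ValueError, match="factor"):
            encode_features(Z_E, Z_G, Z_GE, fac)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(min_value=2, max_value=12), st.integers(min_value=1, max_value=4),
           st.integers(min_value=0, max_value=9999))
    def test_covariance_identity_property(self, J, I, seed):
        rng = np.random.default_rng(seed)
        G = random_psd(J, rng)
        n = min(J * I, 15)
        pheno, lines, envs = _design(J, I, n, rng)
        Z_E, Z_G, Z_GE = build_design_matrices(pheno, line_ids=lines, env_ids=envs)
        fac = cholesky_factor(GRM(G, lines))
        enc = encode_features(Z_E, Z_G, Z_GE, fac, include_interaction=True)
        a, b = enc.column_blocks["genotype"]
        Xg = enc.X[:, a:b]
        Gj = G + fac.jitter * np.eye(J)
        np.testing.assert_allclose(Xg @ Xg.T, np.asarray(Z_G @ Gj @ Z_G.T), atol=1e-8)


class TestAccounting:
    @pytest.mark.parametrize("sizes,depth,size,width", [
        ((8, 4, 4, 4, 3), 4, 27, 9),  # the worked example
        ((1, 1), 1, 3, 2),
        ((5, 3, 2), 2, 12, 6),  # width = max(6, 4, 2)
        ((3, 10, 2), 2, 17, 11),
    ])
    def test_depth_size_width(self, sizes, depth, size, width):
        assert network_depth(sizes) == depth
        assert network_size(sizes) == size
        assert network_width(sizes) == width

    def test_too_few_layers_rejected(self):
        with pytest.raises(ValueError):
            network_depth((5,))

    def test_count_grid(self):
        assert count_grid(HyperGrid()) == 6000
        assert count_grid(HyperGrid((20,), (1,), (1,))) == 1
        assert count_grid(HyperGrid((20, 40), (1, 2, 3), (1, 2))) == 12


def _linear_problem(rng, n=120, d=8, outputs=1):
    X = rng.normal(size=(n, d))
    W = np.abs(rng.normal(size=(d, outputs)))
    Y = 5.0 + X @ W  # positive-leaning linear map
    return X, Y


class TestTraining:
    def test_seeded_init_and_training_deterministic(self, rng):
        X, Y = _linear_problem(rng)
        spec = NetworkSpec(n_hidden_layers=1, units_per_layer=10, max_epochs=5, seed=3)
        m1 = train_network(X, Y, spec)
        m2 = train_network(X, Y, spec)
        for w1, w2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(w1, w2)
        assert m1.train_loss == m2.train_loss

    def test_fits_realizable_positive_linear_map(self, rng):
        X = rng.normal(size=(200, 8))
        Y = 10.0 + X @ np.abs(rng.normal(size=(8, 1)))  # strictly positive
        spec = NetworkSpec(n_hidden_layers=1, units_per_layer=40, dropout_rate=0.0,
                           max_epochs=600, learning_rate=0.05, batch_size=200, seed=0)
        model = train_network(X, Y, spec)
        assert model.train_loss[-1] <= 1e-3 * Y.var()

    def test_constant_target_learned_via_bias(self, rng):
        X = rng.normal(size=(60, 5))
        Y = np.full((60, 1), 7.0)
        spec = NetworkSpec(n_hidden_layers=1, units_per_layer=8, dropout_rate=0.0,
                           max_epochs=50, seed=1)
        model = train_network(X, Y, spec)
        pred = predict_network(model, X)
        np.testing.assert_allclose(pred, 7.0, atol=0.2)

    def test_missing_targets_dropped_listwise(self, rng):
        X, Y = _linear_problem(rng, n=50, outputs=2)
        Y2 = Y.copy(); Y2[::5, 0] = np.nan
        spec = NetworkSpec(n_hidden_layers=1, units_per_layer=5, n_outputs=2,
                           max_epochs=2, seed=0)
        model = train_network(X, Y2, spec)  # must not propagate NaN
        assert np.isfinite(model.train_loss[-1])

    def test_udl_is_mtdl_restricted_to_one_trait(self, rng):
        X, Y = _linear_problem(rng, outputs=1)
        spec = NetworkSpec(n_hidden_layers=2, units_per_layer=12, n_outputs=1,
                           max_epochs=10, seed=5)
        m_udl = train_network(X, Y[:, 0], spec)
        m_mtdl = train_network(X, Y, spec)
        assert m_udl.train_loss == m_mtdl.train_loss


class TestPredict:
    def test_zero_weights_relu_gives_zero(self, rng):
        X = rng.normal(size=(4, 3))
        spec = NetworkSpec(n_hidden_layers=1, units_per_layer=2, seed=0)
        model = train_network(X, np.ones((4, 1)), NetworkSpec(
            n_hidden_layers=1, units_per_layer=2, max_epochs=1, seed=0))
        for w in model.weights:
            w[:] = 0.0
        for b in model.biases:
            b[:] = 0.0
        np.testing.assert_array_equal(predict_network(model, X), 0.0)

    def test_inference_deterministic_despite_dropout(self, rng):
        X, Y = _linear_problem(rng)
        spec = NetworkSpec(n_hidden_layers=2, units_per_layer=10,
                           dropout_rate=0.5, max_epochs=3, seed=2)
        model = train_network(X, Y, spec)
        np.testing.assert_array_equal(predict_network(model, X), predict_network(model, X))

    def test_hand_computed_forward_pass(self):
        # one hidden unit: y = relu(w2 * relu(w1*x + b1) + b2)
        spec = NetworkSpec(n_hidden_layers=1, units_per_layer=1, max_epochs=1, seed=0)
        model = train_network(np.array([[1.0], [2.0]]), np.array([[1.0], [1.0]]), spec)
        model.weights[0][:] = 2.0; model.biases[0][:] = -1.0
        model.weights[1][:] = 3.0; model.biases[1][:] = 0.5
        model.x_mean[:] = 0.0; model.x_scale[:] = 1.0
        # x=1: relu(2*1-1)=1 -> relu(3*1+0.5)=3.5
        out = predict_network(model, np.array([[1.0]]))
        assert out[0, 0] == pytest.approx(3.5)

    def test_dimension_mismatch_rejected(self, rng):
        X, Y = _linear_problem(rng)
        model = train_network(X, Y, NetworkSpec(n_hidden_layers=1, units_per_layer=4,
                                                max_epochs=1, seed=0))
        with pytest.raises(ValueError, match="feature dimension"):
            predict_network(model, X[:, :3])


class TestGridSearch:
    def test_single_combination_returned(self, rng):
        X, Y = _linear_problem(rng)
        grid = HyperGrid((8,), (3,), (1,))
        spec, table = grid_search(X, Y, grid, NetworkSpec(seed=0))
        assert (spec.units_per_layer, spec.max_epochs, spec.n_hidden_layers) == (8, 3, 1)
        assert len(table) == 1

    def test_score_table_covers_full_grid(self, rng):
        X, Y = _linear_problem(rng, n=60)
        grid = HyperGrid((4, 8), (1, 2, 3, 4), (1, 2))
        _, table = grid_search(X, Y, grid, NetworkSpec(max_epochs=4, seed=0))
        assert len(table) == count_grid(grid) == 16

    def test_tie_break_prefers_smaller_architecture(self, rng, monkeypatch):
        # force identical scores: constant validation loss regardless of config
        X, Y = _linear_problem(rng, n=40)
        import mtgp.deep as deep

        real_train = deep.train_network

        def fake_train(Xt, Yt, spec, validation=None):
            model = real_train(Xt, Yt, spec, validation=validation)
            model.val_loss = [1.0] * spec.max_epochs
            return model

        monkeypatch.setattr(deep, "train_network", fake_train)
        grid = HyperGrid((4, 8), (2, 3), (1, 2))
        spec, _ = deep.grid_search(X, Y, grid, NetworkSpec(seed=0))
        assert (spec.n_hidden_layers, spec.units_per_layer, spec.max_epochs) == (1, 4, 2)

    def test_tiny_validation_split_rejected(self, rng):
        X, Y = _linear_problem(rng, n=3)
        with pytest.raises(ValueError, match="validation split"):
            grid_search(X, Y, HyperGrid((4,), (1,), (1,)), NetworkSpec(seed=0),
                        validation_fraction=0.01)


def test_multi_trait_borrowing_helps_on_correlated_traits():
    """With highly correlated traits and no interaction, the multi-trait net
    is on average no worse than its univariate counterpart: joint training
    lets each trait borrow the others' records.  Tested as a tendency over
    replicates, not per run."""
    from mtgp.evaluation import cv1_partition, maape
    from mtgp.genotypes import cholesky_factor, compute_grm, impute_missing, qc_markers
    from mtgp.gblup import build_design_matrices
    from mtgp.simulate import (
        SimulationConfig, make_incomplete_design, simulate_markers, simulate_phenotypes,
    )
    import pandas as pd

    R = ((1.0, 0.9, 0.85), (0.9, 1.0, 0.8), (0.85, 0.8, 1.0))
    mt_scores, udl_scores = [], []
    for seed in range(10):
        cfg = SimulationConfig(
            n_lines=30, n_markers=300, n_envs=4, lines_per_env_range=(12, 18),
            sigma2_ge=(0.0, 0.0, 0.0), sigma2_e=(8.0, 0.25, 40.0),
            trait_genetic_correlation=R, seed=seed,
        )
        grm = compute_grm(impute_missing(qc_markers(simulate_markers(cfg))))
        fac = cholesky_factor(grm)
        pheno, _ = simulate_phenotypes(make_incomplete_design(cfg), grm, cfg)
        part = cv1_partition(pheno, seed=seed, n_partitions=1)[0]
        wide = pheno.pivot_table(index=["line", "environment"], columns="trait",
                                 values="value")
        tr = wide.reindex(pd.MultiIndex.from_tuples(
            part.train_cells, names=["line", "environment"])).reset_index()
        te = wide.reindex(pd.MultiIndex.from_tuples(
            part.test_cells, names=["line", "environment"])).reset_index()
        both = pd.concat([tr, te], ignore_index=True)
        Z = build_design_matrices(both, line_ids=grm.line_ids,
                                  env_ids=sorted(pheno["environment"].unique()))
        enc = encode_features(*Z, fac, include_interaction=False)
        Xtr, Xte = enc.X[:len(tr)], enc.X[len(tr):]
        traits = cfg.trait_names
        Ytr, Yte = tr[traits].to_numpy(), te[traits].to_numpy()
        spec = NetworkSpec(n_hidden_layers=1, units_per_layer=32, n_outputs=3,
                           max_epochs=60, seed=seed)
        pred = predict_network(train_network(Xtr, Ytr, spec), Xte)
        mt_scores.append(np.mean([maape(Yte[:, t], pred[:, t]) for t in range(3)]))
        per_trait = []
        for t in range(3):
            spec_u = NetworkSpec(n_hidden_layers=1, units_per_layer=32, n_outputs=1,
                                 max_epochs=60, seed=seed)
            pred_u = predict_network(train_network(Xtr, Ytr[:, t], spec_u), Xte)[:, 0]
            per_trait.append(maape(Yte[:, t], pred_u))
        udl_scores.append(np.mean(per_trait))
    assert np.mean(mt_scores) <= np.mean(udl_scores)
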