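"""Network forward/backward passes, training, merging, pruning, extensions."""
import itertools
import math

import numpy as np
import pytest

from xgakit import nnmodel
from xgakit.nnmodel import (
    NetworkParams,
    ThreeLayerParams,
    TrainConfig,
    build_three_layer,
    extend_always_present_factor,
    flag_lambda_before_jump,
    make_params,
    merge_runs,
    nonzero_support,
    predicted_activity_ratio,
    prune_weights,
    train,
    train_runs,
)


def scalar_sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


class TestForward:
    def test_all_knockout_genotype_gates_activities_to_zero(self):
        p = make_params(4, 2, rng=np.random.default_rng(1), lam=0.0)
        p.drug_bias[:] = [0.3, -0.7]
        A, R = p.forward(np.zeros(4))
        assert np.all(A == 0.0)
        assert np.allclose(R[0], [scalar_sigmoid(0.3), scalar_sigmoid(-0.7)], atol=1e-15)

    def test_neutral_network_gives_half_activity(self):
        p = make_params(6, 1, lam=0.0)  # zero weights
        A, _ = p.forward(np.ones(6))
        assert np.allclose(A, 0.5)

    def test_two_locus_hand_oracle(self):
        """Forward pass reproduces independent scalar arithmetic to 1e-12."""
        p = make_params(2, 1, lam=0.0)
        p.influence[0, 1] = -0.69
        E1, E2 = 1.5, 1.8
        p.efflux[:, 0] = [E1, E2]
        for g1, g2 in itertools.product((0, 1), repeat=2):
            a1 = scalar_sigmoid(0.0) * g1
            a2 = scalar_sigmoid(-0.69 * g1) * g2
            r = scalar_sigmoid(a1 * E1 + a2 * E2)
            A, R = p.forward(np.array([g1, g2], dtype=float))
            assert abs(A[0, 0] - a1) < 1e-12 and abs(A[0, 1] - a2) < 1e-12
            assert abs(R[0, 0] - r) < 1e-12

    def test_gating_exactness_property(self, rng):
        for _ in range(20):
            p = make_params(8, 3, rng=rng, lam=0.0)
            G = rng.integers(0, 2, size=(5, 8)).astype(float)
            A, R = p.forward(G)
            assert np.all(A[G == 0] == 0.0)
            # knocked-out loci contribute exactly nothing to any prediction
            p2 = p.copy()
            for j in range(8):
                p2.efflux[j, :] = np.where(G[0, j] == 0, 123.0, p2.efflux[j, :])
            assert np.allclose(p2.predict(G[:1]), R[:1], atol=1e-15)

    def test_dimension_mismatch_rejected(self):
        p = make_params(4, 1)
        with pytest.raises(ValueError):
            p.forward(np.ones(7))

    def test_gradients_match_finite_differences(self, rng):
        p = make_params(5, 2, rng=rng, lam=1e-3)
        G = rng.integers(0, 2, size=(30, 5)).astype(float)
        r = rng.uniform(0.2, 0.9, size=(30, 2))
        _, grads = p.loss_grads(G, r)
        h = 1e-7

        def total_loss(params):
            mse = float(np.mean((params.predict(G) - r) ** 2))
            return mse + params.lam * (
                np.abs(params.influence).sum() + np.abs(params.activity_bias).sum()
            )

        for name, idx in [("influence", (0, 2)), ("efflux", (1, 0)), ("activity_bias", (3,)), ("drug_bias", (1,))]:
            plus, minus = p.copy(), p.copy()
            np.atleast_1d(plus.arrays()[name])[idx] += h
            np.atleast_1d(minus.arrays()[name])[idx] -= h
            fd = (total_loss(plus) - total_loss(minus)) / (2 * h)
            assert grads[name][idx] == pytest.approx(fd, abs=1e-5)


class TestThreeLayerForward:
    def test_matches_scalar_oracle_on_all_genotypes(self):
        p = build_three_layer(5, focal=0, n_drugs=1, lam=0.0)
        p.direct[:] = [0.0, -0.4, 0.2, 0.0, -0.7]
        p.indirect[:] = [0.0, -1.1, -0.9, -1.3, -0.5]
        p.mediator_bias = 0.8
        p.mediator_weight = 2.0
        p.activity_bias = -0.3
        p.efflux[:] = 3.5
        p.drug_bias[:] = -1.2
        for G in itertools.product((0, 1), repeat=5):
            ap = scalar_sigmoid(sum(i * g for i, g in zip(p.indirect, G)) + 0.8)
            z = sum(i * g for i, g in zip(p.direct, G)) + 2.0 * ap - 0.3
            a = scalar_sigmoid(z) * G[0]
            r = scalar_sigmoid(a * 3.5 - 1.2)
            A, R = p.forward(np.array(G, dtype=float))
            assert abs(A[0] - a) < 1e-12 and abs(R[0, 0] - r) < 1e-12

    def test_zero_mediator_reduces_to_two_layer(self):
        p = build_three_layer(5, focal=2, n_drugs=1, lam=0.0)
        p.direct[:] = [0.3, -0.2, 0.0, 0.1, 0.4]
        p.efflux[:] = 2.0
        G = np.array([[1, 1, 1, 0, 1]], dtype=float)
        z = float(G[0] @ p.direct) + 0.5 * p.mediator_weight  # w = 0 here
        assert p.mediator_weight == 0.0
        a_expected = scalar_sigmoid(float(G[0] @ p.direct))
        A, _ = p.forward(G)
        assert A[0] == pytest.approx(a_expected, abs=1e-12)

    def test_canonicalization_preserves_function(self, rng):
        p = build_three_layer(5, focal=1, n_drugs=2, rng=rng, lam=0.0)
        p.mediator_weight = -1.7
        G = rng.integers(0, 2, size=(20, 5)).astype(float)
        before = p.predict(G)
        q = p.copy()
        q.canonicalize()
        assert q.mediator_weight >= 0
        assert np.allclose(q.predict(G), before, atol=1e-12)


class TestTraining:
    def test_zero_epochs_returns_init(self, rng):
        init = make_params(4, 2, rng=rng, lam=0.0)
        cfg = TrainConfig(epochs=0, seed=1)
        out, _ = train(np.ones((10, 4)), np.full((10, 2), 0.5), init, cfg)
        assert np.allclose(out.influence, init.influence)
        assert np.allclose(out.efflux, init.efflux)

    def test_training_reaches_noise_floor(self, rng):
        truth = make_params(6, 2, rng=rng, lam=0.0)
        truth.efflux[0, 0] = 2.0
        truth.drug_bias[:] = [-0.5, 0.5]
        G = rng.integers(0, 2, size=(500, 6)).astype(float)
        noise_sd = 0.02
        r = np.clip(truth.predict(G) + rng.normal(0, noise_sd, (500, 2)), 1e-10, 1.0)
        cfg = TrainConfig(epochs=800, seed=3)
        fitted, hist = train(G, r, make_params(6, 2, rng=rng, lam=0.0), cfg)
        assert hist[-1]["train_mse"] <= noise_sd**2 * 1.2

    def test_huge_lambda_silences_influences_and_offsets(self, rng):
        G = rng.integers(0, 2, size=(200, 5)).astype(float)
        r = rng.uniform(0.2, 0.8, size=(200, 1))
        cfg = TrainConfig(epochs=300, seed=4)
        fitted, _ = train(G, r, make_params(5, 1, rng=rng, lam=1.0), cfg)
        assert np.all(np.abs(fitted.influence) < 1e-3)
        assert np.all(np.abs(fitted.activity_bias) < 1e-3)

    def test_efflux_nonnegative_throughout(self, rng):
        G = rng.integers(0, 2, size=(100, 4)).astype(float)
        r = rng.uniform(0.1, 0.9, size=(100, 2))
        fitted, _ = train(
            G, r, make_params(4, 2, rng=rng, lam=1e-4), TrainConfig(epochs=200, seed=5)
        )
        assert np.all(fitted.efflux >= 0.0)

    def test_same_seed_reproducible(self, rng):
        G = rng.integers(0, 2, size=(80, 4)).astype(float)
        r = rng.uniform(0.1, 0.9, size=(80, 1))
        cfg = TrainConfig(epochs=50, n_runs=2, seed=9)
        runs1 = train_runs(G, r, cfg, lambda rg: make_params(4, 1, rng=rg, lam=0.0))
        runs2 = train_runs(G, r, cfg, lambda rg: make_params(4, 1, rng=rg, lam=0.0))
        assert np.array_equal(runs1[0].influence, runs2[0].influence)
        assert not np.array_equal(runs1[0].influence, runs1[1].influence)


class TestMergeRuns:
    def _runs(self, values):
        runs = []
        for v in values:
            p = make_params(3, 1, lam=0.0)
            p.efflux[0, 0] = abs(v)
            p.influence[0, 1] = v
            runs.append(p)
        return runs

    def test_identical_runs_kept_despite_zero_sd(self):
        merged, z = merge_runs(self._runs([0.7] * 10))
        assert merged.influence[0, 1] == pytest.approx(0.7)
        assert np.isinf(z["influence"][0, 1])

    def test_sign_alternating_runs_zeroed(self):
        merged, _ = merge_runs(self._runs([0.5, -0.5] * 5))
        assert merged.influence[0, 1] == 0.0

    def test_tight_cluster_passes_z_filter(self):
        vals = [1.0, 1.1, 0.9, 1.05, 0.95, 1.0, 1.02, 0.98, 1.07, 0.93]
        merged, z = merge_runs(self._runs(vals))
        assert z["influence"][0, 1] > 4
        assert merged.influence[0, 1] == pytest.approx(np.mean(vals))

    def test_median_mode_skips_z_filter(self):
        merged, z = merge_runs(self._runs([0.5, -0.5, 0.5, -0.5]), mode="median_no_z")
        assert z == {}
        assert merged.influence[0, 1] == 0.0  # median of symmetric values

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            merge_runs([make_params(3, 1), make_params(4, 1)])


class TestPruning:
    def test_weight_with_no_predictive_effect_pruned(self, rng):
        p = make_params(4, 1, lam=0.0)
        p.efflux[2, 0] = 5.0  # transporter 2 active in no strain below
        p.drug_bias[:] = 0.3
        G = np.ones((50, 4))
        G[:, 2] = 0.0
        r = p.predict(G)
        pruned, report = prune_weights(p, G, r)
        assert pruned.efflux[2, 0] == 0.0

    def test_strong_weight_retained(self, rng):
        p = make_params(4, 1, lam=0.0)
        p.efflux[1, 0] = 3.0
        p.drug_bias[:] = -1.0
        G = rng.integers(0, 2, size=(2000, 4)).astype(float)
        r = np.clip(p.predict(G) + rng.normal(0, 0.02, (2000, 1)), 1e-10, 1.0)
        pruned, report = prune_weights(p, G, r)
        assert pruned.efflux[1, 0] == 3.0

    def test_single_weight_bonferroni_is_just_alpha(self, rng):
        p = make_params(3, 1, lam=0.0)
        p.efflux[0, 0] = 2.0
        G = rng.integers(0, 2, size=(500, 3)).astype(float)
        r = np.clip(p.predict(G) + rng.normal(0, 0.01, (500, 1)), 1e-10, 1.0)
        p.drug_bias[:] = 0.0  # ensure exactly one non-zero weight
        pruned, report = prune_weights(p, G, r)
        assert len(report) == 1
        assert pruned.efflux[0, 0] == 2.0

    def test_pruning_never_removes_high_impact_weight(self, rng):
        """Post-hoc sanity: no pruned weight raises total squared error > 10%."""
        truth = make_params(6, 2, rng=rng, lam=0.0)
        G = rng.integers(0, 2, size=(800, 6)).astype(float)
        r = np.clip(truth.predict(G) + rng.normal(0, 0.02, (800, 2)), 1e-10, 1.0)
        pruned, report = prune_weights(truth, G, r)
        base_sse = np.sum((truth.predict(G) - r) ** 2)
        for rec in report.itertuples(index=False):
            if rec.kept:
                continue
            trial = truth.copy()
            arr = np.atleast_1d(trial.arrays()[rec.name])
            arr[rec.index] = 0.0
            sse = np.sum((trial.predict(G) - r) ** 2)
            assert sse <= base_sse * 1.10


class TestLambdaSearch:
    def test_single_point_grid(self, rng):
        G = rng.integers(0, 2, size=(100, 3)).astype(float)
        r = rng.uniform(0.2, 0.8, size=(100, 1))
        cfg = TrainConfig(epochs=30, n_runs=2, seed=1)
        tab = nnmodel.lambda_search(
            G, r, [1e-4], cfg, lambda lam: (lambda rg: make_params(3, 1, rng=rg, lam=lam))
        )
        assert len(tab) == 1 and set(tab.columns) == {"lam", "mse", "n_nonzero"}

    def test_penalty_limit_reduces_support(self, rng):
        truth = make_params(4, 2, rng=rng, lam=0.0)
        G = rng.integers(0, 2, size=(400, 4)).astype(float)
        r = np.clip(truth.predict(G) + rng.normal(0, 0.01, (400, 2)), 1e-10, 1.0)
        cfg = TrainConfig(epochs=150, n_runs=3, seed=2)
        tab = nnmodel.lambda_search(
            G, r, [0.0, 1.0], cfg, lambda lam: (lambda rg: make_params(4, 2, rng=rg, lam=lam))
        )
        nz = dict(zip(tab["lam"], tab["n_nonzero"]))
        assert nz[0.0] > nz[1.0]

    def test_jump_flagging(self):
        import pandas as pd

        tab = pd.DataFrame(
            {"lam": [1e-5, 1e-4, 1e-3], "mse": [0.001, 0.0011, 0.01], "n_nonzero": [30, 20, 5]}
        )
        assert flag_lambda_before_jump(tab, factor=2.0) == 1e-4


class TestAlwaysPresentFactor:
    def test_zero_extra_weights_leave_predictions_unchanged(self, rng):
        base = make_params(5, 2, rng=rng, lam=0.0)
        ext = extend_always_present_factor(base)
        G = rng.integers(0, 2, size=(30, 5)).astype(float)
        assert np.allclose(ext.predict(G), base.predict(G), atol=1e-12)

    def test_factor_gate_never_zeroed(self, rng):
        ext = extend_always_present_factor(make_params(5, 1, rng=rng, lam=0.0))
        ext.influence[0, 5] = -2.0
        G = np.zeros((1, 6))  # even passing an explicit zero for the factor slot
        A, _ = ext.forward(G)
        assert A[0, 5] != 0.0

    def test_factor_influence_recovery(self):
        """Always-present factor inhibited by 4 genes, with graded effects:
        each additional knockout of an inhibitor visibly raises the factor's
        activity (the factor's baseline offset keeps its sigmoid in the
        responsive range), mirroring resistance that grows with every
        combination of the four deletions."""
        rng = np.random.default_rng(42)
        L, D, n = 16, 2, 3000
        truth = make_params(L, D, always_present=1, lam=0.0)
        for i in (1, 2, 3, 4):
            truth.influence[i, L] = -1.2
        truth.activity_bias[L] = 2.0
        truth.efflux[L, 0] = 3.0
        truth.efflux[5, 1] = 2.5
        truth.drug_bias[:] = [-1.0, -1.5]
        G = rng.integers(0, 2, size=(n, L)).astype(float)
        R = truth.predict(G)
        r_obs = np.clip(R * np.exp(rng.normal(0, 0.03, R.shape)), 1e-10, 1.0)
        cfg = TrainConfig(epochs=1000, n_runs=6, seed=7, learning_rate=0.01)
        fit = nnmodel.fit_network(
            G, r_obs, cfg, lambda rg: make_params(L, D, rng=rg, lam=1e-5, always_present=1)
        )
        recovered = sum(1 for i in (1, 2, 3, 4) if fit.pruned.influence[i, L] < 0)
        assert recovered >= 3
        assert fit.pruned.efflux[L, 0] > 0


class TestThreeLayerTraining:
    def _truth(self):
        t = build_three_layer(5, focal=0, n_drugs=1)
        t.indirect[:] = [0, -2.5, -2.5, -2.5, -2.5]
        t.mediator_bias = 2.0
        t.mediator_weight = 3.0
        t.direct[:] = [0, -0.4, 0, 0, -0.4]
        t.activity_bias = -1.0
        t.efflux[:] = 4.0
        t.drug_bias[:] = -1.5
        return t

    def test_mediator_model_beats_restricted_two_layer_held_out(self):
        rng = np.random.default_rng(11)
        truth = self._truth()
        n = 2000
        G = rng.integers(0, 2, size=(n, 5)).astype(float)
        G[:, 0] = rng.random(n) < 0.8
        R = truth.predict(G)
        r_obs = np.clip(R * np.exp(rng.normal(0, 0.03, R.shape)), 1e-10, 1.0)
        idx = rng.permutation(n)
        tr, te = idx[:1600], idx[1600:]
        cfg = TrainConfig(
            epochs=1500, n_runs=6, seed=5, learning_rate=0.01, merge_mode="median_no_z"
        )

        class NoMediator(ThreeLayerParams):
            def apply_constraints(self):
                super().apply_constraints()
                self.mediator_weight = 0.0
                self.indirect[...] = 0.0

        def mk3(rg):
            return build_three_layer(5, focal=0, n_drugs=1, rng=rg, lam=1e-5)

        def mk2(rg):
            b = build_three_layer(5, focal=0, n_drugs=1, rng=rg, lam=1e-5)
            return NoMediator(
                direct=b.direct,
                indirect=b.indirect,
                mediator_bias=0.0,
                mediator_weight=0.0,
                activity_bias=b.activity_bias,
                efflux=b.efflux,
                drug_bias=b.drug_bias,
                lam=b.lam,
                focal=0,
            )

        fit3 = nnmodel.fit_network(G[tr], r_obs[tr], cfg, mk3)
        fit2 = nnmodel.fit_network(G[tr], r_obs[tr], cfg, mk2)
        mse3 = np.mean((fit3.pruned.predict(G[te]) - r_obs[te]) ** 2)
        mse2 = np.mean((fit2.pruned.predict(G[te]) - r_obs[te]) ** 2)
        assert mse3 < mse2
        # indirect influences recovered with correct (negative) sign
        assert sum(fit3.pruned.indirect[1:] < 0) >= 3


class TestActivityRatio:
    def _model(self):
        p = build_three_layer(5, focal=0, n_drugs=1)
        p.direct[:] = [0, -0.5, -0.5, 0, 0]
        p.indirect[:] = [0, -1.0, -1.0, -1.0, -1.0]
        p.mediator_bias = 1.0
        p.mediator_weight = 2.0
        p.activity_bias = -0.5
        return p

    def test_wild_type_ratio_is_one(self):
        p = self._model()
        wt = np.ones(5)
        assert predicted_activity_ratio(p, wt) == pytest.approx(1.0)
        assert predicted_activity_ratio(p, wt, "indirect_only") == pytest.approx(1.0)

    def test_direct_only_model_has_unit_indirect_ratio(self):
        p = self._model()
        p.indirect[:] = 0.0
        p.mediator_weight = 0.0
        quad = np.array([1, 0, 0, 0, 0], dtype=float)
        assert predicted_activity_ratio(p, quad, "indirect_only") == pytest.approx(1.0)

    def test_quadruple_knockout_exceeds_doubles(self):
        p = self._model()
        quad = np.array([1, 0, 0, 0, 0], dtype=float)
        ratio_quad = predicted_activity_ratio(p, quad)
        assert ratio_quad > 1.0
        for pair in itertools.combinations(range(1, 5), 2):
            dbl = np.ones(5)
            dbl[list(pair)] = 0.0
            assert ratio_quad > predicted_activity_ratio(p, dbl)


def test_params_json_round_trip(tmp_path, rng):
    p = make_params(4, 2, rng=rng, lam=5e-4, always_present=0)
    nnmodel.params_to_json(p, tmp_path / "m.json", manifest={"note": "test"})
    q = nnmodel.params_from_json(tmp_path / "m.json")
    assert np.allclose(p.influence, q.influence)
    assert np.allclose(p.efflux, q.efflux)
    assert q.lam == 5e-4


def test_nonzero_support_excludes_structural_zeros():
    p = make_params(3, 1, lam=0.0)
    p.influence[0, 1] = 0.5
    support = nonzero_support(p)
    assert ("influence", (0, 1)) in support
    diag = [idx for name, idx in support if name == "influence" and idx[0] == idx[1]]
    assert diag == []
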