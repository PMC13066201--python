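"""Ensemble scoring: detectability, random-forest discriminability, joint
functionality, tuning correlations and the trade-off fits."""

import numpy as np
import pandas as pd
import pytest

from hostscent import ensemble as ens
from hostscent import olfactory as olf


@pytest.fixture(scope="module")
def toy_model():
    universe = pd.Index([f"c{i}" for i in range(30)])
    return olf.sample_model(4, 8, universe, np.random.default_rng(2))


class TestDetectability:
    def test_single_sample_equals_eag_response(self, toy_model):
        dose = pd.DataFrame(
            [np.where(np.random.default_rng(0).random(30) < 0.5, 2.5,
                      np.nan)], columns=toy_model.universe)
        d = ens.detectability_index(toy_model, dose)
        row = {c: v for c, v in dose.iloc[0].items() if not np.isnan(v)}
        assert d == pytest.approx(olf.eag_response(toy_model, row))

    def test_additive_over_sample_lists(self, toy_model):
        rng = np.random.default_rng(1)
        mk = lambda n: pd.DataFrame(
            np.where(rng.random((n, 30)) < 0.4, rng.random((n, 30)) * 5,
                     np.nan), columns=toy_model.universe)
        a, b = mk(5), mk(7)
        both = pd.concat([a, b], ignore_index=True)
        assert ens.detectability_index(toy_model, both) == pytest.approx(
            ens.detectability_index(toy_model, a)
            + ens.detectability_index(toy_model, b))

    def test_model_detecting_nothing_scores_zero(self, toy_model):
        dose = pd.DataFrame(np.full((4, 30), np.nan),
                            columns=toy_model.universe)
        assert ens.detectability_index(toy_model, dose) == 0.0


class TestDiscriminability:
    def _separable(self, n_species=28, reps=5):
        # each species drives its own feature deterministically
        y = np.repeat([f"sp{i}" for i in range(n_species)], reps)
        X = np.repeat(np.eye(n_species), reps, axis=0)
        return X, y

    def test_separable_fixture_is_classified(self):
        X, y = self._separable()
        score, degen = ens.discriminability_index(X, y, rf_trees=200, seed=0)
        assert not degen
        assert score >= 0.95

    def test_permuted_labels_fall_to_chance(self):
        X, y = self._separable(n_species=5, reps=12)
        rng = np.random.default_rng(3)
        scores = []
        for i in range(5):
            yp = rng.permutation(y)
            s, _ = ens.discriminability_index(X, yp, rf_trees=200, seed=i)
            scores.append(s)
        assert abs(np.mean(scores) - 1 / 5) < 0.12

    def test_constant_features_flagged_at_chance(self):
        X = np.zeros((20, 4))
        y = np.repeat(["a", "b", "c", "d"], 5)
        score, degen = ens.discriminability_index(X, y, rf_trees=50)
        assert degen
        assert score == pytest.approx(0.25)

    def test_label_requirements(self):
        with pytest.raises(ValueError):
            ens.discriminability_index(np.zeros((3, 2)),
                                       np.array(["a", "a", "b"]))

    def test_ranger_and_sklearn_backends_agree(self):
        """Same OOB statistic from both random-forest engines."""
        rng = np.random.default_rng(8)
        y = np.repeat([f"sp{i}" for i in range(6)], 10)
        X = (np.repeat(np.eye(6), 10, axis=0)
             + rng.normal(0, 0.6, size=(60, 6)))
        stack = X[None, :, :]
        seeds = np.array([123])
        s_r, _ = ens.oob_scores_batch(stack, y, 300, seeds,
                                      backend="ranger")
        s_k, _ = ens.oob_scores_batch(stack, y, 300, seeds,
                                      backend="sklearn")
        assert abs(s_r[0] - s_k[0]) < 0.12


class TestJointFunctionality:
    def test_rescaled_range_and_mean_model(self):
        d = np.array([1.0, 2.0, 3.0, 4.0, 5.0])  # model 2 sits at the mean
        disc = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        j, rd, rdisc = ens.joint_functionality(d, disc)
        assert ((rd >= 0) & (rd <= 1)).all()
        assert ((rdisc >= 0) & (rdisc <= 1)).all()
        assert rd.mean() == pytest.approx(0.5)
        assert j[2] == pytest.approx(0.25)  # 0.5 * 0.5 at the joint mean

    def test_jointly_top_model_has_maximal_j(self):
        d = np.array([1.0, 5.0, 3.0, 2.0, 4.0])
        disc = np.array([0.2, 0.9, 0.5, 0.3, 0.6])
        j, _, _ = ens.joint_functionality(d, disc)
        assert np.argmax(j) == 1

    def test_constant_index_rejected(self):
        with pytest.raises(ValueError, match="discriminability"):
            ens.joint_functionality(np.arange(5.0), np.ones(5))


class TestTuningCorrelations:
    def _model_detecting(self, universe, detected_positions):
        k = len(detected_positions)
        idx = np.array(detected_positions).reshape(1, k)
        t = np.full((1, k), 1.0)
        w = np.full((1, k), 2.0)
        return olf.OlfactoryModel(0, pd.Index(universe), idx, t, w)

    def test_detecting_most_shared_gives_positive_r_prob(self, shared28):
        order = np.argsort(shared28.to_numpy())
        top = self._model_detecting(shared28.index, order[-50:])
        bottom = self._model_detecting(shared28.index, order[:50])
        assert ens.detection_sharedness_corr(top, shared28) > 0
        assert ens.detection_sharedness_corr(bottom, shared28) < 0

    def test_random_detection_has_zero_mean_r_prob(self, shared28):
        rng = np.random.default_rng(0)
        rs = []
        for _ in range(40):
            pos = rng.choice(len(shared28), size=60, replace=False)
            m = self._model_detecting(shared28.index, pos)
            rs.append(ens.detection_sharedness_corr(m, shared28))
        assert abs(np.mean(rs)) < 0.02

    def test_threshold_sharedness_coupling_sets_r_amp_sign(self, shared28):
        # low thresholds assigned to low-sharedness compounds -> at an
        # intermediate dose they respond more -> negative correlation
        order = np.argsort(shared28.to_numpy())
        universe = shared28.index
        k = 100
        chosen = np.concatenate([order[:50], order[-50:]])
        t = np.where(np.isin(chosen, order[:50]), 0.5, 4.0)
        m = olf.OlfactoryModel(0, universe, chosen.reshape(1, k),
                               t.reshape(1, k), np.full((1, k), 1.0))
        assert ens.amplitude_sharedness_corr(m, shared28, 2.0) < 0

    def test_saturated_responses_are_undefined(self, shared28):
        m = self._model_detecting(shared28.index, [0, 1, 2, 3])
        # dose 5 saturates every ramp (t=1, w=2): zero variance
        assert np.isnan(ens.amplitude_sharedness_corr(m, shared28, 5.0))


class TestRunEnsemble:
    def test_deterministic_given_master_seed(self, processed,
                                             species_labels, shared28):
        cfg = ens.EnsembleConfig(n_models=5, master_seed=21,
                                 compute_discriminability=False)
        a = ens.run_ensemble(cfg, processed.dose, species_labels, shared28)
        b = ens.run_ensemble(cfg, processed.dose, species_labels, shared28)
        pd.testing.assert_frame_equal(a, b)

    def test_zscores_standardized_within_cell(self, processed,
                                              species_labels, shared28):
        cfg = ens.EnsembleConfig(n_models=40, master_seed=5,
                                 compute_discriminability=False)
        m = ens.run_ensemble(cfg, processed.dose, species_labels, shared28)
        assert m["z_detectability"].mean() == pytest.approx(0.0, abs=1e-10)
        assert m["z_detectability"].std(ddof=0) == pytest.approx(1.0,
                                                                 abs=1e-10)

    def test_grid_manifest_arithmetic(self):
        configs = ens.grid_configs(n_models=10_000)
        man = ens.manifest(configs)
        assert man["n_cells"] == 12
        assert man["n_models_total"] == 120_000
        cells = {(c["n_ors"], c["level"], c["dataset_id"])
                 for c in man["cells"]}
        assert len(cells) == 12
        assert {c["n_ors"] for c in man["cells"]} == {10, 20}

    def test_level_mapping_is_fixed(self):
        assert ens.EnsembleConfig(n_ors=10, level="high").compounds_per_or \
            == 60
        assert ens.EnsembleConfig(n_ors=20, level="high").compounds_per_or \
            == 30
        with pytest.raises(ValueError):
            ens.EnsembleConfig(n_ors=15)


class TestTradeoffFit:
    def _metrics(self, n, rng, effect=0.0):
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = effect * (x1 - x2) + rng.normal(size=n)
        df = pd.DataFrame({"detectability": y, "r_prob": x1,
                           "r_amp_2.5": x2})
        return ens.zscore_cell(df)

    def test_coefficients_match_least_squares_oracle(self):
        rng = np.random.default_rng(0)
        m = self._metrics(10, rng, effect=0.5)
        rep = ens.tradeoff_fit(m, indices=("detectability",), min_models=5)
        x1 = m["z_r_prob"].to_numpy()
        x2 = m["z_r_amp_2.5"].to_numpy()
        X = np.column_stack([np.ones(10), x1, x2, x1 * x2])
        beta = np.linalg.solve(X.T @ X, X.T @ m["z_detectability"])
        got = rep["fits"]["detectability"]["coef"]
        np.testing.assert_allclose(
            [got["intercept"], got["r_prob"], got["r_amp"],
             got["interaction"]], beta, atol=1e-10)

    def test_null_ensemble_has_near_zero_effects(self):
        rng = np.random.default_rng(1)
        m = self._metrics(3000, rng, effect=0.0)
        rep = ens.tradeoff_fit(m, indices=("detectability",))
        coefs = rep["fits"]["detectability"]["coef"]
        assert abs(coefs["r_prob"]) < 0.06
        assert abs(coefs["r_amp"]) < 0.06

    def test_joint_index_peaks_at_opposite_signs(self):
        # fixture where J is high only when r_prob and r_amp disagree in
        # sign: the interaction term must come out negative
        rng = np.random.default_rng(2)
        x1 = rng.normal(size=2000)
        x2 = rng.normal(size=2000)
        j = -x1 * x2 + 0.1 * rng.normal(size=2000)
        m = ens.zscore_cell(pd.DataFrame({"joint": j, "r_prob": x1,
                                          "r_amp_2.5": x2}))
        rep = ens.tradeoff_fit(m, indices=("joint",))
        assert rep["fits"]["joint"]["coef"]["interaction"] < -0.5
        assert rep["fits"]["joint"]["p"]["interaction"] < 1e-6

    def test_too_few_models_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            ens.tradeoff_fit(self._metrics(50, rng))
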