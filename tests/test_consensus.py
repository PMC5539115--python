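import numpy as np
import pytest

from flexens import (
    ConsensusModel,
    FlexibilityProfile,
    encode_features,
    inverse_logistic,
    logistic_target,
    make_cv_folds,
    predict,
    spearman_rs,
    train,
)
from flexens.consensus import (
    N_FEATURES,
    PER_POSITION,
    FeatureNormalizer,
    TrainingTarget,
    _forward,
)
from flexens.synthetic import make_sequence, make_ss_profile, make_training_set, smooth_profile


def chain_inputs(length=30, seed=0):
    rng = np.random.default_rng(seed)
    ids = tuple(range(1, length + 1))
    ff = FlexibilityProfile(ids, rng.uniform(0, 3, size=length), units="angstrom")
    dyn = FlexibilityProfile(ids, rng.uniform(0, 1, size=length))
    seq = make_sequence(length, rng)
    ss = make_ss_profile("".join(rng.choice(list("HEC"), size=length)), ids)
    return ff, dyn, seq, ss


class TestEncodeFeatures:
    def test_vector_length_is_246(self):
        x = encode_features(*chain_inputs())
        assert x.shape[1] == 246 == N_FEATURES

    def test_terminal_positions_carry_missing_flags_only(self):
        x = encode_features(*chain_inputs())
        first = x[0]
        for w in range(4):  # window offsets -4..-1 fall off the N-terminus
            block = first[w * PER_POSITION : (w + 1) * PER_POSITION]
            assert block[-1] == 1.0
            assert np.all(block[:-1] == 0.0)
        # the centre position is real
        centre = first[4 * PER_POSITION : 5 * PER_POSITION]
        assert centre[-1] == 0.0

    def test_interior_residue_slots_are_consistent(self):
        x = encode_features(*chain_inputs())
        mid = x[15]
        for w in range(9):
            block = mid[w * PER_POSITION : (w + 1) * PER_POSITION]
            assert block[-1] == 0.0  # nothing missing
            assert block[2:23].sum() == pytest.approx(1.0)  # one-hot
            assert block[23:26].sum() == pytest.approx(1.0, abs=1e-3)  # ss probs

    def test_global_features(self):
        length = 30
        x = encode_features(*chain_inputs(length))
        assert np.allclose(x[:, -3], np.log(length))
        i = np.arange(length)
        assert np.allclose(x[:, -2], i / length)
        assert np.allclose(x[:, -1], (length - 1 - i) / length)

    def test_inconsistent_coverage_rejected(self):
        ff, dyn, seq, ss = chain_inputs()
        with pytest.raises(ValueError):
            encode_features(ff, dyn, seq[:-1], ss)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            encode_features(*chain_inputs(), window=8)


class TestLogisticTransform:
    def test_midpoint_maps_to_half(self):
        assert logistic_target(1.7, m=1.7, s=0.4) == pytest.approx(0.5)

    def test_inverse_identity_on_grid(self):
        grid = np.linspace(0.05, 8.0, 50)
        back = inverse_logistic(logistic_target(grid, 1.5, 0.6), 1.5, 0.6)
        assert np.abs(back - grid).max() < 1e-9

    def test_strictly_increasing(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b = np.sort(rng.uniform(0, 10, size=2))
            if a == b:
                continue
            assert logistic_target(a, 2.0, 0.5) < logistic_target(b, 2.0, 0.5)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            logistic_target(1.0, 1.0, 0.0)


class TestMakeCvFolds:
    def test_singletons_are_pooled(self):
        plan = make_cv_folds({"t1": "a", "t2": "a", "t3": "b", "t4": "c"})
        assert plan.n_splits == 2
        groups = set(plan.group_of.values())
        assert "a" in groups and len(groups) == 2

    def test_each_target_held_out_exactly_once(self):
        labels = {f"t{i}": f"g{i % 5}" for i in range(15)}
        plan = make_cv_folds(labels)
        assert plan.n_splits == 5
        held = [t for g in plan.heldout_groups for t in plan.split_targets(g)[1]]
        assert sorted(held) == sorted(labels)

    def test_33_groups_give_33_splits(self):
        labels = {f"t{i}": f"g{i % 33}" for i in range(66)}
        assert make_cv_folds(labels).n_splits == 33

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            make_cv_folds({"t1": "a", "t2": "a"})


def constant_model(w1=None, w2=None, hidden=10, window=9):
    n_feat = window * PER_POSITION + 3
    return ConsensusModel(
        w1=np.zeros((n_feat + 1, hidden)) if w1 is None else w1,
        w2=np.zeros((hidden + 1, 1)) if w2 is None else w2,
        hidden_units=hidden,
        logistic_m=1.0,
        logistic_s=0.5,
        normalizer=FeatureNormalizer(0, 1, 0, 1),
    )


class TestPredict:
    def test_zero_weights_give_half_everywhere(self):
        model = constant_model()
        x = np.random.default_rng(0).uniform(size=(7, N_FEATURES))
        assert np.allclose(predict(model, x), 0.5)

    def test_forward_pass_matches_manual_recomputation(self):
        rng = np.random.default_rng(1)
        model = constant_model(
            w1=rng.normal(size=(N_FEATURES + 1, 10)), w2=rng.normal(size=(11, 1))
        )
        x = rng.uniform(size=(10, N_FEATURES))
        sig = lambda v: 1.0 / (1.0 + np.exp(-v))
        for row in x:
            h = sig(model.w1[0] + row @ model.w1[1:])
            y = sig(model.w2[0, 0] + h @ model.w2[1:, 0])
            assert predict(model, row[None])[0] == pytest.approx(y, abs=1e-12)

    def test_masked_slots_do_not_leak_when_weights_zeroed(self):
        rng = np.random.default_rng(2)
        w1 = rng.normal(size=(N_FEATURES + 1, 10))
        # zero the weights of every slot in window position 0 except its flag
        w1[1 : PER_POSITION, :] = 0.0
        model = constant_model(w1=w1, w2=rng.normal(size=(11, 1)))
        x = rng.uniform(size=(3, N_FEATURES))
        y0 = predict(model, x)
        x2 = x.copy()
        x2[:, 0 : PER_POSITION - 1] = rng.uniform(size=(3, PER_POSITION - 1))
        assert np.allclose(predict(model, x2), y0)

    def test_wrong_feature_count_rejected(self):
        with pytest.raises(ValueError):
            predict(constant_model(), np.zeros((2, 100)))


class TestTrain:
    def test_architecture_shapes(self):
        targets, groups = make_training_set(6, 3, length=30, mode="planted_linear", seed=0)
        res = train(targets, make_cv_folds(groups), hidden=10, seed=0, max_epochs=5)
        model = next(iter(res.models.values()))
        assert model.w1.shape == (247, 10)
        assert model.w2.shape == (11, 1)

    def test_deterministic_given_seed(self):
        targets, groups = make_training_set(6, 3, length=30, mode="planted_linear", seed=0)
        plan = make_cv_folds(groups)
        a = train(targets, plan, seed=5, max_epochs=60)
        b = train(targets, plan, seed=5, max_epochs=60)
        for g in a.models:
            assert np.array_equal(a.models[g].w1, b.models[g].w1)
            assert np.array_equal(a.models[g].w2, b.models[g].w2)

    def test_outputs_stay_in_unit_interval(self):
        targets, groups = make_training_set(6, 3, length=30, mode="planted_linear", seed=1)
        res = train(targets, make_cv_folds(groups), seed=1, max_epochs=100)
        for prof in res.oof_scores.values():
            assert np.all(prof.values > 0) and np.all(prof.values < 1)

    def test_planted_function_is_recovered_out_of_fold(self):
        targets, groups = make_training_set(16, 4, length=60, mode="planted_linear", seed=7)
        res = train(targets, make_cv_folds(groups), seed=3, patience=100, tol=1e-6)
        rs = [
            spearman_rs(res.oof_scores[t.target_id], t.rmsd_profile) for t in targets
        ]
        assert np.median(rs) >= 0.9

    def test_noise_predictor_does_not_drag_consensus_down(self):
        """With one informative predictor and one pure-noise predictor, the
        consensus tracks the informative one: it beats the noise input and
        stays within 0.05 of the informative input's correlation."""
        rng = np.random.default_rng(11)
        targets = []
        groups = {}
        for n in range(16):
            tid = f"T{n:03d}"
            groups[tid] = f"G{n % 4}"
            ids = tuple(range(1, 61))
            p1 = smooth_profile(60, rng, 0.0, 1.0)
            rmsd = 0.3 + 2.0 * p1  # truth is a monotone map of predictor 1
            targets.append(
                TrainingTarget(
                    target_id=tid,
                    group=groups[tid],
                    seq=make_sequence(60, rng),
                    ss=make_ss_profile("C" * 60, ids),
                    ff_profile=FlexibilityProfile(ids, p1),
                    dyn_profile=FlexibilityProfile(ids, rng.normal(size=60)),
                    rmsd_profile=FlexibilityProfile(ids, rmsd, units="angstrom"),
                )
            )
        res = train(targets, make_cv_folds(groups), seed=2, patience=100, tol=1e-6)

        def median_rs(profiles):
            out = []
            for t in targets:
                try:
                    out.append(spearman_rs(profiles(t), t.rmsd_profile))
                except ValueError:
                    out.append(0.0)
            return float(np.median(out))

        cons = median_rs(lambda t: res.oof_scores[t.target_id])
        informative = median_rs(lambda t: t.ff_profile)
        noisy = median_rs(lambda t: t.dyn_profile)
        assert cons >= noisy
        assert cons >= informative - 0.05

    def test_angstrom_back_transform_preserves_ranking(self):
        targets, groups = make_training_set(6, 3, length=30, mode="planted_linear", seed=2)
        res = train(targets, make_cv_folds(groups), seed=0, max_epochs=200)
        for tid in res.oof_scores:
            assert spearman_rs(res.oof_scores[tid], res.oof_angstrom[tid]) == pytest.approx(1.0)


class TestModelSerialization:
    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        model = constant_model(
            w1=rng.normal(size=(N_FEATURES + 1, 10)), w2=rng.normal(size=(11, 1))
        )
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ConsensusModel.from_json(path)
        assert np.allclose(back.w1, model.w1)
        assert np.allclose(back.w2, model.w2)
        assert back.logistic_m == model.logistic_m
        assert back.normalizer == model.normalizer
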