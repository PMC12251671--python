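import numpy as np
import pytest

from cogpose.camera import CameraIntrinsics, project
from cogpose.losses import LossWeights, loss_total
from cogpose.network import (LiftingModel, ModelConfig, TrainConfig,
                             desk_model_config, desk_train_config, evaluate,
                             fit, load_checkpoint, save_checkpoint,
                             select_hypothesis)
from cogpose.skeleton import Pose2D, Pose3D
from cogpose.synth import SynthConfig, make_dataset


@pytest.fixture(scope="module")
def tiny_data():
    cfg = SynthConfig(seed=21)
    rng = np.random.default_rng(21)
    train = make_dataset(cfg, 64, rng)
    val = make_dataset(cfg, 32, rng, skeleton_id_start=100)
    return train, val


@pytest.fixture(scope="module")
def tiny_model():
    return LiftingModel(desk_model_config(), rng=np.random.default_rng(3))


def analytic_param_count(cfg: ModelConfig) -> int:
    """Closed-form parameter count of the lifting architecture."""
    d = cfg.hidden
    embed = 2 * (3 * d + d)                      # joint + bone projections
    pos = (133 + 132) * d
    attn = 4 * (d * d + d)                       # q, k, v, o
    ffn = d * (d * cfg.ffn_mult) + d * cfg.ffn_mult \
        + (d * cfg.ffn_mult) * d + d
    lns = 3 * 2 * d                              # ln1, ln_kv, ln2
    block = attn + ffn + lns
    n_blocks = 2 * cfg.cross_layers + cfg.depth
    head = 2 * d + (d * 3 + 3)                   # ln_out + linear head
    total = embed + pos + n_blocks * block + head
    if cfg.multi_hypothesis:
        total += 2 * (2 * d + d * 3 + 3)
    return total


class TestForward:
    def test_output_shape_and_determinism(self, tiny_model, tiny_data):
        train, _ = tiny_data
        fj, fb = tiny_model.prepare_inputs(train["kp2d"][:4], train["conf"][:4],
                                           train["valid"][:4])
        a = tiny_model.forward(fj, fb)
        b = tiny_model.forward(fj, fb)
        assert a.data.shape == (4, 133, 3)
        np.testing.assert_array_equal(a.data, b.data)

    def test_duplicated_sample_gives_identical_rows(self, tiny_model,
                                                    tiny_data):
        train, _ = tiny_data
        kp2d = np.repeat(train["kp2d"][:1], 2, axis=0)
        conf = np.repeat(train["conf"][:1], 2, axis=0)
        valid = np.repeat(train["valid"][:1], 2, axis=0)
        out = tiny_model.predict_batch(kp2d, conf, valid)
        np.testing.assert_allclose(out[0], out[1], atol=1e-5)

    def test_untrained_output_finite_and_root_relative(self, tiny_model,
                                                       tiny_data):
        train, _ = tiny_data
        out = tiny_model.predict_batch(train["kp2d"][:8], train["conf"][:8],
                                       train["valid"][:8])
        assert np.all(np.isfinite(out))
        root = 0.5 * (out[:, 11] + out[:, 12])
        np.testing.assert_allclose(root, 0.0, atol=1e-3)

    def test_predict_single_pose(self, tiny_model, tiny_data):
        train, _ = tiny_data
        pose = Pose2D(coords=train["kp2d"][0], confidence=train["conf"][0],
                      valid=train["valid"][0])
        out = tiny_model.predict(pose)
        assert isinstance(out, Pose3D) and out.frame == "root_relative"

    def test_parameter_count_matches_analytic_formula(self):
        for cfg in (desk_model_config(),
                    desk_model_config(hidden=16, heads=2, depth=2,
                                      cross_layers=2),
                    desk_model_config(multi_hypothesis=True)):
            model = LiftingModel(cfg, rng=np.random.default_rng(0))
            assert model.n_parameters() == analytic_param_count(cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(hidden=30, heads=4)
        with pytest.raises(ValueError):
            ModelConfig(depth=0)
        with pytest.raises(ValueError):
            TrainConfig(epochs=100, lr_drop_epochs=(170, 200))


class TestFit:
    def test_two_epoch_smoke(self, tiny_data):
        train, val = tiny_data
        model, hist = fit(train, val, desk_model_config(),
                          desk_train_config(epochs=2, seed=9))
        assert len(hist) == 2
        assert {"epoch", "lr", "train_loss", "val_loss",
                "val_mpjpe_mm"} <= set(hist[0])

    def test_loss_descends_over_training(self, tiny_data):
        train, val = tiny_data
        mcfg = desk_model_config()
        model, hist = fit(train, val, mcfg,
                          desk_train_config(epochs=10, seed=9, augment=False))
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]
        assert hist[-1]["val_mpjpe_mm"] <= hist[0]["val_mpjpe_mm"]

    def test_position_only_weights_zero_other_terms(self, tiny_data):
        train, val = tiny_data
        _, hist = fit(train, val, desk_model_config(),
                      desk_train_config(epochs=1, seed=9,
                                        loss_weights=LossWeights(1, 0, 0)))
        assert hist[0]["train_cog"] == 0.0
        assert hist[0]["train_bone"] == 0.0

    def test_checkpoint_round_trip(self, tiny_data, tmp_path):
        train, val = tiny_data
        tcfg = desk_train_config(epochs=1, seed=9)
        model, hist = fit(train, val, desk_model_config(), tcfg)
        before = evaluate(model, val)["whole_body"]
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, tcfg, extra={"epoch": 0})
        reloaded, meta = load_checkpoint(path)
        after = evaluate(reloaded, val)["whole_body"]
        assert after == pytest.approx(before, abs=1e-6)
        assert meta["train_config"].seed == 9


class TestHypothesisSelection:
    @pytest.fixture()
    def scene(self, rng):
        cfg = SynthConfig(seed=4, noise_sigma_px=0.0, occlusion_prob=0.0)
        data = make_dataset(cfg, 1, np.random.default_rng(4))
        gt = data["kp3d"][0]
        pose2d = Pose2D(coords=data["kp2d"][0], confidence=data["conf"][0],
                        valid=data["valid"][0])
        cam = CameraIntrinsics(*data["camera"][0])
        return gt, pose2d, cam, data["root"][0]

    def test_single_candidate_returned(self, scene):
        gt, pose2d, cam, root = scene
        cand = Pose3D(coords=gt, frame="root_relative")
        assert select_hypothesis([cand], pose2d, cam) is cand

    def test_ground_truth_beats_corrupted(self, scene, rng):
        gt, pose2d, cam, root = scene
        good = Pose3D(coords=gt, frame="root_relative")
        bad = Pose3D(coords=gt + rng.normal(0, 120, gt.shape),
                     frame="root_relative")
        picked = select_hypothesis([bad, good], pose2d, cam,
                                   root_position=root)
        assert picked is good
        picked = select_hypothesis([bad, good], pose2d, cam)  # unknown root
        assert picked is good

    def test_tie_breaks_to_lowest_index(self, scene):
        gt, pose2d, cam, root = scene
        a = Pose3D(coords=gt, frame="root_relative")
        b = Pose3D(coords=gt.copy(), frame="root_relative")
        assert select_hypothesis([a, b], pose2d, cam,
                                 root_position=root) is a

    def test_empty_candidates_rejected(self, scene):
        _, pose2d, cam, _ = scene
        with pytest.raises(ValueError):
            select_hypothesis([], pose2d, cam)

    def test_multi_hypothesis_forward(self, tiny_data):
        train, _ = tiny_data
        model = LiftingModel(desk_model_config(multi_hypothesis=True),
                             rng=np.random.default_rng(1))
        fj, fb = model.prepare_inputs(train["kp2d"][:2], train["conf"][:2],
                                      train["valid"][:2])
        hyps = model.forward_hypotheses(fj, fb)
        assert len(hyps) == 3
        for h in hyps:
            assert h.data.shape == (2, 133, 3)
            assert np.all(np.isfinite(h.data))
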