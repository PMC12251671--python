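import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cogpose.anthropometry import body_cog, cog_weight_vector
from cogpose.autodiff import Tensor
from cogpose.losses import (LossWeights, cog_distances, loss_bone, loss_cog,
                            loss_position, loss_total, mpjpe, percent_change)
from cogpose.skeleton import BoneTree, Pose3D


@pytest.fixture()
def w_cog(table_m, layout):
    return cog_weight_vector(table_m, layout)


@pytest.fixture()
def pose_pair(rng):
    gt = rng.normal(0, 400, (133, 3))
    pred = gt + rng.normal(0, 30, (133, 3))
    return pred, gt


class TestPositionLoss:
    def test_zero_at_ground_truth(self, pose_pair):
        _, gt = pose_pair
        assert loss_position(gt, gt) == 0.0

    def test_three_four_five(self):
        gt = np.zeros((1, 3))
        pred = np.array([[3.0, 4.0, 0.0]])
        assert loss_position(pred, gt) == pytest.approx(5.0)

    def test_mean_over_joints(self):
        gt = np.zeros((2, 3))
        pred = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        assert loss_position(pred, gt) == pytest.approx(5.0)

    def test_no_valid_joints_raises(self, pose_pair):
        pred, gt = pose_pair
        with pytest.raises(ValueError):
            loss_position(pred, gt, valid=np.zeros(133, bool))

    def test_equals_whole_body_mpjpe(self, pose_pair, layout):
        pred, gt = pose_pair
        assert loss_position(pred, gt) == pytest.approx(
            mpjpe(pred, gt, group=layout.part_groups["whole_body"]))


class TestCogLoss:
    def test_zero_at_ground_truth(self, pose_pair, w_cog):
        _, gt = pose_pair
        assert loss_cog(gt, gt, w_cog) == pytest.approx(0.0, abs=1e-18)

    def test_rigid_motion_invariance(self, pose_pair, w_cog, rng):
        pred, gt = pose_pair
        base = loss_cog(pred, gt, w_cog)
        R = Rotation.random(random_state=3).as_matrix()
        t = rng.normal(0, 800, 3)
        moved = loss_cog(pred @ R.T + t, gt @ R.T + t, w_cog)
        assert moved == pytest.approx(base, rel=1e-9)

    def test_translating_one_pose_keeps_own_distances(self, pose_pair, w_cog):
        pred, gt = pose_pair
        assert loss_cog(gt + np.array([500.0, 0, 0]), gt, w_cog) == \
            pytest.approx(0.0, abs=1e-15)

    def test_matches_independent_recomputation(self, pose_pair, table_m,
                                               layout, w_cog):
        pred, gt = pose_pair
        gp = np.linalg.norm(
            pred - body_cog(Pose3D(coords=pred), table_m).coords, axis=1)
        gg = np.linalg.norm(
            gt - body_cog(Pose3D(coords=gt), table_m).coords, axis=1)
        expect = np.mean((gp - gg) ** 2)
        assert loss_cog(pred, gt, w_cog, layout=layout) == \
            pytest.approx(expect, rel=1e-9)

    def test_cog_distances_shape_and_sign(self, pose_pair, w_cog):
        pred, _ = pose_pair
        g = cog_distances(pred, w_cog)
        assert g.shape == (133,) and np.all(g >= 0)


class TestBoneLoss:
    @pytest.fixture()
    def toy_tree(self):
        return BoneTree(parent=np.array([-1, 0, 1]),
                        edges=np.array([[0, 1], [1, 2]]))

    def test_zero_at_ground_truth(self, toy_tree, rng):
        gt = rng.normal(0, 1, (3, 3))
        assert loss_bone(gt, gt, toy_tree) == pytest.approx(0.0, abs=1e-12)

    def test_right_angle_rotation_costs_one(self):
        tree = BoneTree(parent=np.array([-1, 0]), edges=np.array([[0, 1]]))
        gt = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        pred = np.array([[0.0, 0, 0], [0.0, 1.0, 0]])
        # equal length, 90 degrees: cosine term 1; length term lambda*|b-b^|
        assert loss_bone(pred, gt, tree, lambda_bone=0.0) == pytest.approx(1.0)

    def test_doubled_bone_costs_lambda_times_length(self):
        tree = BoneTree(parent=np.array([-1, 0]), edges=np.array([[0, 1]]))
        gt = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        pred = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert loss_bone(pred, gt, tree, lambda_bone=1.0) == pytest.approx(1.0)

    def test_translation_invariance(self, tree, pose_pair, rng):
        pred, gt = pose_pair
        t = rng.normal(0, 500, 3)
        assert loss_bone(pred + t, gt + t, tree) == pytest.approx(
            loss_bone(pred, gt, tree), rel=1e-9)

    def test_zero_length_gt_bones_masked(self, toy_tree, rng):
        gt = np.zeros((3, 3))
        gt[2] = [1.0, 0, 0]          # first bone degenerate, second fine
        pred = rng.normal(0, 1, (3, 3))
        val = loss_bone(pred, gt, toy_tree)
        assert np.isfinite(val)
        with pytest.raises(ValueError):
            loss_bone(pred, np.zeros((3, 3)), toy_tree)


class TestTotalLoss:
    def test_reduces_to_position_loss(self, pose_pair, w_cog, tree):
        pred, gt = pose_pair
        total, breakdown = loss_total(pred, gt, w_cog, tree,
                                      weights=LossWeights(1, 0, 0))
        assert total == loss_position(pred, gt)
        assert breakdown["cog"] == 0.0 and breakdown["bone"] == 0.0

    def test_zero_at_ground_truth(self, pose_pair, w_cog, tree):
        _, gt = pose_pair
        total, breakdown = loss_total(gt, gt, w_cog, tree)
        assert total == pytest.approx(0.0, abs=1e-12)
        assert all(v == pytest.approx(0.0, abs=1e-12)
                   for v in breakdown.values())

    def test_additivity(self, pose_pair, w_cog, tree, layout):
        pred, gt = pose_pair
        total, _ = loss_total(pred, gt, w_cog, tree,
                              weights=LossWeights(1, 1, 1), layout=layout)
        parts = (loss_position(pred, gt) + loss_cog(pred, gt, w_cog)
                 + loss_bone(pred, gt, tree))
        assert total == pytest.approx(parts, abs=1e-12)

    def test_weights_scale_terms(self, pose_pair, w_cog, tree):
        pred, gt = pose_pair
        t1, _ = loss_total(pred, gt, w_cog, tree, weights=LossWeights(2, 3, 0.5))
        expect = (2 * loss_position(pred, gt) + 3 * loss_cog(pred, gt, w_cog)
                  + 0.5 * loss_bone(pred, gt, tree))
        assert t1 == pytest.approx(expect, rel=1e-12)


class TestGradients:
    """Analytic loss gradients agree with central finite differences."""

    @staticmethod
    def _check(fn, pred, rel=1e-4):
        t = Tensor(pred, requires_grad=True)
        fn(t).backward()
        eps = 1e-6
        num = np.zeros_like(pred)
        it = np.nditer(pred, flags=["multi_index"])
        while not it.finished:
            i = it.multi_index
            up, dn = pred.copy(), pred.copy()
            up[i] += eps
            dn[i] -= eps
            num[i] = (float(fn(Tensor(up, requires_grad=True)).data)
                      - float(fn(Tensor(dn, requires_grad=True)).data)) \
                / (2 * eps)
            it.iternext()
        scale = np.abs(num).max()
        np.testing.assert_allclose(t.grad, num, atol=rel * max(scale, 1e-8),
                                   rtol=rel)

    def test_position_loss_gradient(self, rng):
        gt = rng.normal(0, 1, (8, 3))
        pred = gt + rng.normal(0, 0.3, (8, 3))
        self._check(lambda t: loss_position(t, gt), pred)

    def test_cog_loss_gradient(self, rng):
        w = rng.dirichlet(np.ones(8))
        gt = rng.normal(0, 1, (8, 3))
        pred = gt + rng.normal(0, 0.3, (8, 3))
        self._check(lambda t: loss_cog(t, gt, w), pred)

    def test_bone_loss_gradient(self, rng):
        tree = BoneTree(parent=np.array([-1, 0, 1, 1, 3]),
                        edges=np.array([[0, 1], [1, 2], [1, 3], [3, 4]]))
        gt = rng.normal(0, 1, (5, 3))
        pred = gt + rng.normal(0, 0.3, (5, 3))
        self._check(lambda t: loss_bone(t, gt, tree), pred)

    def test_total_loss_gradient(self, rng):
        tree = BoneTree(parent=np.array([-1, 0, 1, 1]),
                        edges=np.array([[0, 1], [1, 2], [1, 3]]))
        w = rng.dirichlet(np.ones(4))
        gt = rng.normal(0, 1, (4, 3))
        pred = gt + rng.normal(0, 0.3, (4, 3))
        self._check(lambda t: loss_total(t, gt, w, tree)[0], pred)


class TestMpjpe:
    def test_constant_offset(self, rng, layout):
        gt = rng.normal(0, 300, (133, 3))
        pred = gt + np.array([0.0, 0.0, 44.49])
        for group in layout.part_groups.values():
            assert mpjpe(pred, gt, group=group) == pytest.approx(44.49)

    def test_group_decomposition(self, rng, layout):
        gt = rng.normal(0, 300, (133, 3))
        pred = gt + rng.normal(0, 20, (133, 3))
        parts = [(len(layout.part_groups[g]),
                  mpjpe(pred, gt, group=layout.part_groups[g]))
                 for g in ("body", "face", "hands")]
        combined = sum(n * v for n, v in parts) / 133
        assert mpjpe(pred, gt) == pytest.approx(combined, rel=1e-12)

    def test_masked_brute_force(self, rng):
        gt = rng.normal(0, 300, (133, 3))
        pred = gt + rng.normal(0, 20, (133, 3))
        mask = rng.random(133) > 0.4
        brute = np.mean([np.linalg.norm(pred[i] - gt[i])
                         for i in range(133) if mask[i]])
        assert mpjpe(pred, gt, valid=mask) == pytest.approx(brute)

    def test_empty_group_raises(self, rng):
        gt = rng.normal(0, 1, (133, 3))
        with pytest.raises(ValueError):
            mpjpe(gt, gt, group=np.array([], dtype=int))


class TestPercentChange:
    def test_no_change(self):
        assert percent_change(100.0, 100.0) == 0.0

    def test_improvement_reported_positive(self):
        assert percent_change(112.3, 44.49, decimals=1) == 60.4

    def test_two_decimal_rounding(self):
        assert percent_change(67.50, 44.49) == pytest.approx(34.0889, abs=1e-4)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 10.0)
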