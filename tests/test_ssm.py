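"""SSM/PCA identities: double centering, eigendecomposition, projection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parkmlr import (
    BrainVolume,
    build_mask,
    double_center,
    eigendecompose,
    fit_ssm,
    project_subjects,
    stack,
)
from parkmlr.image_io import VoxelMask, VoxelMatrix
from parkmlr.ssm import SubjectScores


def random_matrix(rng, m=6, n=50):
    return rng.uniform(0.5, 2.0, (m, n))


def toy_voxel_matrix(values):
    m, n = values.shape
    mask = VoxelMask(np.ones((1, 1, n), bool), 25.0)
    return VoxelMatrix(values, mask, [f"s{i}" for i in range(m)], ["PD"] * m)


class TestDoubleCenter:
    def test_all_ones_gives_zero_srp(self):
        srp, vmp = double_center(np.ones((4, 10)))
        assert not srp.any()
        assert not vmp.any()

    def test_hand_example(self):
        # log P = [[0, 2], [0, 0]]; row-center -> [[-1, 1], [0, 0]];
        # column-center -> [[-0.5, 0.5], [0.5, -0.5]]
        p = np.array([[1.0, np.e ** 2], [1.0, 1.0]])
        srp, vmp = double_center(p)
        np.testing.assert_allclose(srp, [[-0.5, 0.5], [0.5, -0.5]], atol=1e-12)
        np.testing.assert_allclose(vmp, [-0.5, 0.5], atol=1e-12)

    def test_global_scaling_of_one_subject_absorbed(self, rng):
        p = random_matrix(rng)
        srp, _ = double_center(p)
        p2 = p.copy()
        p2[2] *= 37.5
        srp2, _ = double_center(p2)
        np.testing.assert_allclose(srp, srp2, atol=1e-12)

    def test_nonpositive_entry_cites_indices(self, rng):
        p = random_matrix(rng)
        p[3, 7] = 0.0
        with pytest.raises(ValueError, match=r"row 3.*column 7"):
            double_center(p)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1), st.integers(3, 10), st.integers(4, 40))
    def test_row_and_column_means_vanish(self, seed, m, n):
        p = np.random.default_rng(seed).uniform(0.1, 10.0, (m, n))
        srp, _ = double_center(p)
        np.testing.assert_allclose(srp.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(srp.mean(axis=1), 0, atol=1e-10)


@pytest.fixture(scope="module")
def model_and_srp():
    p = random_matrix(np.random.default_rng(5), m=6, n=50)
    srp, vmp = double_center(p)
    mask = VoxelMask(np.ones((1, 1, 50), bool), 25.0)
    model = eigendecompose(srp, vmp, mask, [f"s{i}" for i in range(6)], ["PD"] * 6)
    return model, srp


class TestEigendecompose:

    def test_subject_and_voxel_covariances_share_spectrum(self, model_and_srp):
        model, srp = model_and_srp
        vox_eigs = np.linalg.eigvalsh(srp.T @ srp)[::-1][: model.n_components]
        np.testing.assert_allclose(model.eigenvalues, vox_eigs, rtol=1e-8)

    def test_reconstruction(self, model_and_srp):
        model, srp = model_and_srp
        np.testing.assert_allclose(model.ssf @ model.gis.T, srp, atol=1e-8)

    def test_gis_orthonormal(self, model_and_srp):
        model, _ = model_and_srp
        k = model.n_components
        np.testing.assert_allclose(model.gis.T @ model.gis, np.eye(k), atol=1e-8)

    def test_rank_at_most_m_minus_one(self, rng):
        for _ in range(5):
            p = random_matrix(rng, m=7, n=30)
            srp, vmp = double_center(p)
            mask = VoxelMask(np.ones((1, 1, 30), bool), 25.0)
            model = eigendecompose(srp, vmp, mask, [str(i) for i in range(7)], ["PD"] * 7)
            assert model.n_components <= 6

    def test_vaf_sums_to_one(self, model_and_srp):
        model, _ = model_and_srp
        assert model.vaf.sum() == pytest.approx(1.0)
        assert (np.diff(model.eigenvalues) <= 0).all()

    def test_zero_srp_rejected(self):
        mask = VoxelMask(np.ones((1, 1, 10), bool), 25.0)
        with pytest.raises(ValueError, match="degenerate"):
            eigendecompose(np.zeros((4, 10)), np.zeros(10), mask, list("abcd"), ["PD"] * 4)

    def test_sign_convention_reproducible(self):
        p = random_matrix(np.random.default_rng(9), m=5, n=40)
        mask = VoxelMask(np.ones((1, 1, 40), bool), 25.0)
        runs = []
        for _ in range(2):
            srp, vmp = double_center(p)
            model = eigendecompose(srp, vmp, mask, list("abcde"), ["PD"] * 5)
            runs.append(model.gis)
        np.testing.assert_array_equal(runs[0], runs[1])
        # dominant entry of each column is positive
        dom = np.abs(runs[0]).argmax(axis=0)
        assert (runs[0][dom, np.arange(runs[0].shape[1])] > 0).all()


class TestProjection:
    def test_training_cohort_reproduces_ssf(self, small_ssm, small_cohort):
        from parkmlr import augment_with_ud

        augmented, _ = augment_with_ud(small_cohort.images, seed=11)
        scores = project_subjects(augmented, small_ssm)
        np.testing.assert_allclose(scores.scores, small_ssm.ssf, atol=1e-8)

    def test_gsf_invariance(self, small_ssm, small_cohort):
        vol = small_cohort.images[0]
        scaled = BrainVolume(data=3.0 * vol.data, subject_id="x", label=vol.label)
        s1 = project_subjects([vol], small_ssm).scores
        s2 = project_subjects([scaled], small_ssm).scores
        np.testing.assert_allclose(s1, s2, atol=1e-10)

    def test_log_space_mean_projects_to_zero(self, small_ssm, small_cohort):
        from parkmlr import augment_with_ud

        augmented, _ = augment_with_ud(small_cohort.images, seed=11)
        matrix = stack(augmented, small_ssm.mask)
        mean_row = np.exp(np.log(matrix.values).mean(axis=0))
        mean_vol = BrainVolume.__new__(BrainVolume)
        mean_vol.data = np.ones(small_ssm.mask.grid_shape)
        mean_vol.data[small_ssm.mask.included] = mean_row
        mean_vol.affine, mean_vol.subject_id, mean_vol.label = np.eye(4), "mean", "unknown"
        scores = project_subjects([mean_vol], small_ssm).scores
        np.testing.assert_allclose(scores, 0, atol=1e-8)

    def test_component_out_of_range_rejected(self, small_ssm, small_cohort):
        with pytest.raises(ValueError, match="component"):
            project_subjects(small_cohort.images[:1], small_ssm, (1, 2, 999))

    def test_wrong_mask_rejected(self, small_ssm, rng):
        other_mask = VoxelMask(np.ones(small_ssm.mask.grid_shape, bool), 25.0)
        values = rng.uniform(1, 2, (2, other_mask.n_voxels))
        matrix = VoxelMatrix(values, other_mask, ["a", "b"], ["PD", "PD"])
        with pytest.raises(ValueError, match="mask"):
            project_subjects(matrix, small_ssm)

    def test_scores_column_order(self):
        with pytest.raises(ValueError, match="ascending"):
            SubjectScores(np.zeros((2, 2)), (3, 1), ["a", "b"], ["PD", "PD"])


def test_model_archive_round_trip(tmp_path, small_ssm):
    small_ssm.save(tmp_path / "ssm.npz")
    from parkmlr import SSMModel

    back = SSMModel.load(tmp_path / "ssm.npz")
    np.testing.assert_array_equal(back.gis, small_ssm.gis)
    np.testing.assert_array_equal(back.mask.included, small_ssm.mask.included)
    assert back.labels == small_ssm.labels
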