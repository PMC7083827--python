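"""GPA, semilandmark sliding, PCA and Sum-of-Variances behaviour."""

import numpy as np
import pytest

from tarsomorph import (
    LandmarkConfiguration,
    LandmarkDataset,
    LandmarkScheme,
    centroid_size,
    gpa_align,
    optimal_rotation,
    pca,
    slide_semilandmarks,
    sum_of_variances,
)
from tarsomorph.superimposition import AlignedDataset

from conftest import make_dataset


def rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


class TestCentroidSize:
    def test_unit_square(self):
        assert centroid_size(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)) == pytest.approx(
            np.sqrt(2), abs=1e-12
        )

    def test_homogeneous_in_scale_and_translation_invariant(self, rng):
        x = rng.normal(size=(7, 2))
        cs = centroid_size(x)
        assert centroid_size(3.7 * x) == pytest.approx(3.7 * cs, rel=1e-12)
        assert centroid_size(x + [11.0, -4.0]) == pytest.approx(cs, rel=1e-12)

    def test_coincident_points_are_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            centroid_size(np.ones((5, 2)))


class TestOptimalRotation:
    def test_recovers_quarter_turn(self):
        A = np.array([[1.0, 0.0], [-1.0, 0.0]])
        B = A @ rot(np.pi / 2).T
        R = optimal_rotation(A, B)
        np.testing.assert_allclose(R, rot(np.pi / 2), atol=1e-12)
        np.testing.assert_allclose(A @ R.T, B, atol=1e-12)

    def test_identity_for_equal_sets(self, rng):
        A = rng.normal(size=(5, 2))
        A -= A.mean(0)
        np.testing.assert_allclose(optimal_rotation(A, A), np.eye(2), atol=1e-12)

    def test_never_returns_a_reflection(self, rng):
        A = rng.normal(size=(6, 2))
        A -= A.mean(0)
        B = A * [-1.0, 1.0]  # reflected copy
        R = optimal_rotation(A, B)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            optimal_rotation(np.zeros((3, 2)), np.zeros((4, 2)))


class TestGpaAlign:
    def test_copies_of_one_shape_align_exactly(self, quad_scheme, rng):
        base = np.array([[0.0, 0.0], [2.0, 0.3], [1.8, 1.5], [0.2, 1.2]])
        shapes = {}
        for i in range(6):
            x = base @ rot(rng.uniform(0, 2 * np.pi)).T
            shapes[f"s{i}"] = rng.uniform(0.5, 3.0) * x + rng.normal(size=2) * 10
        ds = make_dataset(shapes, quad_scheme)
        aligned = gpa_align(ds, slide=False)
        spread = np.abs(aligned.aligned - aligned.aligned.mean(axis=0)).max()
        assert spread < 1e-8
        assert sum_of_variances(aligned) < 1e-16

    def test_unit_mode_frame_invariants(self, quad_dataset):
        aligned = gpa_align(quad_dataset, slide=False)
        for x in aligned.aligned:
            assert np.abs(x.mean(axis=0)).max() < 1e-10
            assert np.sqrt((x**2).sum()) == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(
            aligned.consensus, aligned.aligned.mean(axis=0), atol=1e-10
        )

    def test_output_invariant_to_rigid_motion_of_inputs(self, quad_dataset, rng):
        ref = gpa_align(quad_dataset, slide=False)
        moved = {
            c.specimen_id: c.coords @ rot(rng.uniform(0, 2 * np.pi)).T
            + rng.normal(size=2) * 5
            for c in quad_dataset.configurations
        }
        other = gpa_align(make_dataset(moved, quad_dataset.scheme), slide=False)
        np.testing.assert_allclose(other.aligned, ref.aligned, atol=1e-8)

    def test_consensus_matches_rotation_grid_oracle(self, quad_dataset):
        """Independent GPA: per-shape rotation by explicit angle-grid search
        (1e-4 rad, parabolic refinement on the grid) instead of the SVD."""
        aligned = gpa_align(quad_dataset, slide=False)

        shapes = []
        for c in quad_dataset.configurations:
            x = c.coords - c.coords.mean(0)
            shapes.append(x / np.sqrt((x**2).sum()))
        thetas = np.arange(0.0, 2 * np.pi, 1e-4)
        consensus = shapes[0]
        for _ in range(200):
            rotated = []
            for x in shapes:
                # sum sq dist(theta) = const - 2*(A cos + B sin)
                A = float((x * consensus).sum())
                B = float(np.sum(x[:, 0] * consensus[:, 1] - x[:, 1] * consensus[:, 0]))
                vals = A * np.cos(thetas) + B * np.sin(thetas)
                j = int(np.argmax(vals))
                t0 = thetas[j]
                # parabolic refinement around the best grid angle
                tm, tp = t0 - 1e-4, t0 + 1e-4
                fm, f0, fp = (A * np.cos(t) + B * np.sin(t) for t in (tm, t0, tp))
                denom = fm - 2 * f0 + fp
                shift = 0.0 if denom == 0 else 0.5e-4 * (fm - fp) / denom
                rotated.append(x @ rot(t0 + shift).T)
            new_consensus = np.mean(rotated, axis=0)
            new_consensus /= np.sqrt((new_consensus**2).sum())
            if np.abs(new_consensus - consensus).max() < 1e-12:
                consensus = new_consensus
                break
            consensus = new_consensus

        # compare shapes up to rotation
        A = float((consensus * aligned.consensus).sum())
        B = float(
            np.sum(
                consensus[:, 0] * aligned.consensus[:, 1]
                - consensus[:, 1] * aligned.consensus[:, 0]
            )
        )
        best = consensus @ rot(np.arctan2(B, A)).T
        cn = aligned.consensus / np.sqrt((aligned.consensus**2).sum())
        assert np.abs(best - cn).max() < 1e-6

    def test_single_configuration_rejected(self, quad_scheme):
        ds = make_dataset({"a": np.arange(8.0).reshape(4, 2)}, quad_scheme)
        with pytest.raises(ValueError, match="at least 2"):
            gpa_align(ds)

    def test_mm_mode_keeps_physical_scale(self, quad_dataset):
        aligned = gpa_align(quad_dataset, slide=False, scale_mode="mm")
        sizes = [np.sqrt((x**2).sum()) for x in aligned.aligned]
        assert not np.allclose(sizes, 1.0)
        np.testing.assert_allclose(sizes, aligned.centroid_sizes, rtol=1e-9)


@pytest.fixture
def slid_setup():
    """Two specimens with one semilandmark on a horizontal chord."""
    scheme = LandmarkScheme(
        n_landmarks=2, n_semilandmarks=1, semilandmark_neighbours=((0, 1),)
    )
    coords = np.array(
        [
            [[0.0, 0.0], [2.0, 0.0], [1.3, 0.0]],
            [[0.0, 0.0], [2.0, 0.0], [0.4, 0.0]],
        ]
    )
    consensus = np.array([[0.0, 0.0], [2.0, 0.0], [0.8, 0.5]])
    return AlignedDataset(
        scheme=scheme,
        specimen_ids=["a", "b"],
        aligned=coords,
        consensus=consensus,
        centroid_sizes=np.ones(2),
        scale_mode="mm",
    )


class TestSliding:
    def test_projects_to_perpendicular_foot(self, slid_setup):
        out = slide_semilandmarks(slid_setup)
        np.testing.assert_allclose(out.aligned[0][2], [0.8, 0.0], atol=1e-12)

    def test_reaches_consensus_point_on_the_tangent_line(self, slid_setup):
        slid_setup.consensus[2] = [0.9, 0.0]  # already on the chord line
        out = slide_semilandmarks(slid_setup)
        np.testing.assert_allclose(out.aligned[0][2], [0.9, 0.0], atol=1e-12)
        np.testing.assert_allclose(out.aligned[1][2], [0.9, 0.0], atol=1e-12)

    def test_never_increases_distance_to_consensus(self, rng):
        scheme = LandmarkScheme(
            n_landmarks=3, n_semilandmarks=2, semilandmark_neighbours=((0, 1), (1, 2))
        )
        coords = rng.normal(size=(5, 5, 2))
        consensus = rng.normal(size=(5, 2))
        ds = AlignedDataset(
            scheme=scheme,
            specimen_ids=[f"s{i}" for i in range(5)],
            aligned=coords,
            consensus=consensus,
            centroid_sizes=np.ones(5),
            scale_mode="mm",
        )
        out = slide_semilandmarks(ds)
        for before, after in zip(coords, out.aligned):
            assert ((after - consensus) ** 2).sum() <= ((before - consensus) ** 2).sum() + 1e-12

    def test_fixed_landmarks_never_move(self, slid_setup):
        out = slide_semilandmarks(slid_setup)
        np.testing.assert_array_equal(out.aligned[:, :2], slid_setup.aligned[:, :2])

    def test_coincident_neighbours_warn_and_stay(self, slid_setup):
        slid_setup.aligned[0][1] = slid_setup.aligned[0][0]  # zero chord
        with pytest.warns(UserWarning, match="coincident"):
            out = slide_semilandmarks(slid_setup)
        np.testing.assert_array_equal(out.aligned[0][2], slid_setup.aligned[0][2])

    def test_gpa_objective_is_monotone_with_sliding(self, rng, tarsus_scheme):
        base = np.array(
            [[8, 5], [-8, 4], [10, 0], [7, -5], [0, -6], [-9, 0], [0, 6], [9, -3],
             [-7, -4], [-8.8, 2], [-8.5, -2]],
            float,
        )
        shapes = {f"s{i}": base + rng.normal(scale=0.4, size=base.shape) for i in range(6)}
        ds = make_dataset(shapes, tarsus_scheme)
        aligned = gpa_align(ds, slide=True)
        traj = np.array(aligned.provenance["objective_trajectory"])
        assert np.all(np.diff(traj) <= 1e-10)


class TestMorphospace:
    def test_identical_specimens_have_zero_eigenvalues(self, quad_scheme):
        x = np.arange(8.0).reshape(4, 2)
        ds = make_dataset({f"s{i}": x for i in range(4)}, quad_scheme)
        summary = pca(gpa_align(ds, slide=False))
        assert np.abs(summary.eigenvalues).max() < 1e-20

    def test_single_deformation_axis_gives_rank_one(self, quad_scheme):
        base = np.array([[0.0, 0.0], [2.0, 0.1], [1.9, 1.4], [0.1, 1.3]])
        direction = np.array([[0.3, -0.1], [0.0, 0.2], [-0.3, 0.0], [0.0, -0.1]])
        aligned = AlignedDataset(
            scheme=quad_scheme,
            specimen_ids=[f"s{i}" for i in range(5)],
            aligned=np.stack([base + t * direction for t in np.linspace(-1, 1, 5)]),
            consensus=base,
            centroid_sizes=np.ones(5),
            scale_mode="mm",
        )
        summary = pca(aligned)
        assert summary.eigenvalues[0] > 1e-4
        assert np.abs(summary.eigenvalues[1:]).max() < 1e-10

    def test_eigenvalue_sum_equals_sum_of_variances(self, quad_dataset):
        aligned = gpa_align(quad_dataset, slide=False)
        summary = pca(aligned)
        assert summary.eigenvalues.sum() == pytest.approx(
            sum_of_variances(aligned), abs=1e-10
        )
        assert np.all(np.diff(summary.eigenvalues) <= 1e-15)
        assert np.all(summary.eigenvalues >= -1e-15)

    def test_minimum_specimen_counts(self, quad_scheme):
        x = np.arange(8.0).reshape(4, 2)
        two = AlignedDataset(
            scheme=quad_scheme,
            specimen_ids=["a", "b"],
            aligned=np.stack([x, x + 0.1]),
            consensus=x,
            centroid_sizes=np.ones(2),
            scale_mode="mm",
        )
        with pytest.raises(ValueError):
            pca(two)
        one = AlignedDataset(
            scheme=quad_scheme,
            specimen_ids=["a"],
            aligned=x[None],
            consensus=x,
            centroid_sizes=np.ones(1),
            scale_mode="mm",
        )
        with pytest.raises(ValueError):
            sum_of_variances(one)

    def test_sov_single_coordinate_difference(self, quad_scheme):
        x = np.arange(8.0).reshape(4, 2)
        y = x.copy()
        y[2, 1] += 2.0
        aligned = AlignedDataset(
            scheme=quad_scheme,
            specimen_ids=["a", "b"],
            aligned=np.stack([x, y]),
            consensus=x,
            centroid_sizes=np.ones(2),
            scale_mode="mm",
        )
        assert sum_of_variances(aligned) == pytest.approx(2.0, abs=1e-12)
        assert sum_of_variances(aligned, ddof=0) == pytest.approx(1.0, abs=1e-12)


class TestFixedPoint:
    def test_converged_alignment_is_a_fixed_point(self, quad_dataset):
        aligned = gpa_align(quad_dataset, slide=False)
        assert aligned.provenance["converged"]
        rerun_ds = make_dataset(
            {sid: aligned.aligned[i] for i, sid in enumerate(aligned.specimen_ids)},
            quad_dataset.scheme,
        )
        rerun = gpa_align(rerun_ds, slide=False)
        np.testing.assert_allclose(rerun.aligned, aligned.aligned, atol=1e-8)
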