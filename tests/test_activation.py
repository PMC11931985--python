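"""Activation metrics: distances, the A100 index, classification, RMSD/RMSF."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from statescan.activation import (
    DEFAULT_A100_SPEC,
    a100_score_from_distances,
    a100_series,
    ca_distance_series,
    classify_state,
    rmsd_series,
    rmsf,
)
from statescan.errors import (
    InsufficientFramesError,
    InvalidParameterError,
    MissingAtomError,
)
from statescan.structure_io import Selection, Structure, Trajectory


def _structure_from_points(residue_ids, points):
    n = len(residue_ids)
    return Structure(
        residue_ids=np.asarray(residue_ids),
        atom_names=np.array(["CA"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        masses=np.full(n, 12.011),
        coords=np.asarray(points, dtype=float),
    )


def _static_traj(structure, n_frames=3):
    coords = np.repeat(structure.coords[None], n_frames, axis=0)
    return Trajectory(structure, coords, np.arange(n_frames, dtype=float))


@pytest.fixture
def a100_zero_structure():
    """All five index pairs coincident → every pair distance is zero."""
    pairs = DEFAULT_A100_SPEC.pairs
    rids, pts = [], []
    for i, (a, b) in enumerate(pairs):
        p = [10.0 * i, 0.0, 0.0]
        rids += [a, b]
        pts += [p, p]
    order = np.argsort(rids)
    return _structure_from_points(np.asarray(rids)[order], np.asarray(pts)[order])


class TestDistanceSeries:
    def test_static_pair_distance(self):
        s = _structure_from_points([1, 2, 3], [[0, 0, 0], [8, 0, 0], [0, 3, 0]])
        series = ca_distance_series(_static_traj(s), 1, 2)
        np.testing.assert_allclose(series.values, 8.0)

    def test_open_minus_closed_equals_shift(self, reference_pair):
        closed, open_ = reference_pair
        coords = np.stack([open_.coords, closed.coords])
        traj = Trajectory(closed, coords, np.array([0.0, 1.0]))
        series = ca_distance_series(traj, 173, 318)
        assert series.values[0] - series.values[1] == pytest.approx(8.0, abs=1e-9)

    def test_same_residue_gives_zero(self):
        s = _structure_from_points([1, 2, 3], [[0, 0, 0], [8, 0, 0], [0, 3, 0]])
        series = ca_distance_series(_static_traj(s), 2, 2)
        np.testing.assert_allclose(series.values, 0.0)

    def test_missing_residue_named_in_error(self, clean_collapse_traj):
        with pytest.raises(MissingAtomError, match="999"):
            ca_distance_series(clean_collapse_traj, 173, 999)


class TestA100:
    def test_zero_distances_give_intercept(self, a100_zero_structure):
        states = a100_series(_static_traj(a100_zero_structure))
        np.testing.assert_allclose(states.scores, 278.88)

    def test_all_distances_ten_angstrom(self):
        assert a100_score_from_distances([10.0] * 5) == pytest.approx(34.08)

    def test_linearity_by_geometric_finite_differences(self, a100_zero_structure):
        """Moving one pair's partner by h Å changes the score by c_i·h."""
        base = _static_traj(a100_zero_structure, n_frames=1)
        s0 = a100_series(base).scores[0]
        for i, (a, b) in enumerate(DEFAULT_A100_SPEC.pairs):
            for h in (1.0, 2.5):
                pert = a100_zero_structure.coords.copy()
                j = a100_zero_structure.atom_index(b)
                pert[j] += np.array([0.0, h, 0.0])  # distance goes 0 → h
                traj = Trajectory(
                    a100_zero_structure, pert[None], np.array([0.0])
                )
                s = a100_series(traj).scores[0]
                expected = DEFAULT_A100_SPEC.coefficients[i] * h
                assert s - s0 == pytest.approx(expected, abs=1e-9)

    def test_doubling_distances_doubles_excess(self):
        d = np.array([3.0, 4.0, 5.0, 6.0, 7.0])
        s1 = a100_score_from_distances(d) - 278.88
        s2 = a100_score_from_distances(2 * d) - 278.88
        assert s2 == pytest.approx(2 * s1)


class TestClassification:
    @pytest.mark.parametrize(
        "score,three,two",
        [
            (-5.0, "inactive", "inactive"),
            (-1e-9, "inactive", "inactive"),
            (0.0, "intermediate", "inactive"),
            (24.999, "intermediate", "inactive"),
            (25.0, "intermediate", "active"),
            (30.0, "intermediate", "active"),
            (54.999, "intermediate", "active"),
            (55.0, "active", "active"),
            (100.0, "active", "active"),
        ],
    )
    def test_thresholds_and_boundaries(self, score, three, two):
        assert classify_state(score, "three_state") == three
        assert classify_state(score, "two_state") == two

    def test_nan_rejected(self):
        with pytest.raises(InvalidParameterError):
            classify_state(float("nan"))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.floats(-200, 200, allow_nan=False),
        st.floats(0, 50, allow_nan=False),
        st.sampled_from(["two_state", "three_state"]),
    )
    def test_monotone_in_score(self, score, bump, model):
        order = {"inactive": 0, "intermediate": 1, "active": 2}
        lo = order[classify_state(score, model)]
        hi = order[classify_state(score + bump, model)]
        assert hi >= lo


class TestRMSD:
    def test_copies_of_reference_are_zero(self, reference_pair):
        closed, _ = reference_pair
        traj = _static_traj(closed, n_frames=4)
        out = rmsd_series(traj, closed, Selection(mode="ca"))
        np.testing.assert_allclose(out["rmsd_A"], 0.0, atol=1e-10)

    def test_rigid_rotation_gives_zero(self, reference_pair):
        from scipy.spatial.transform import Rotation

        closed, _ = reference_pair
        rot = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        coords = np.stack([closed.coords, closed.coords @ rot.T + 7.0])
        traj = Trajectory(closed, coords, np.array([0.0, 1.0]))
        out = rmsd_series(traj, closed, Selection(mode="ca"))
        np.testing.assert_allclose(out["rmsd_A"], 0.0, atol=1e-8)

    def test_single_displaced_atom_closed_form(self):
        """Without re-superposition, RMSD = d·sqrt(w/Σw) for one moved atom."""
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(25, 3)) * 6
        ref = _structure_from_points(np.arange(1, 26), pts)
        moved = pts.copy()
        d = 3.0
        moved[7] += [0, 0, d]
        traj = Trajectory(ref, moved[None], np.array([0.0]))
        out = rmsd_series(traj, ref, Selection(mode="ca"), superpose=False)
        w = ref.masses
        expected = d * np.sqrt(w[7] / w.sum())
        assert out["rmsd_A"][0] == pytest.approx(expected, rel=1e-12)

    def test_subsampling_leaves_values_unchanged(self, clean_collapse_traj, reference_pair):
        closed, _ = reference_pair
        full = rmsd_series(clean_collapse_traj, closed, Selection(mode="ca"))
        sub = rmsd_series(clean_collapse_traj[::4], closed, Selection(mode="ca"))
        np.testing.assert_allclose(sub["rmsd_A"], full["rmsd_A"][::4], atol=1e-12)


class TestRMSF:
    def test_static_trajectory_is_zero(self, reference_pair):
        closed, _ = reference_pair
        out = rmsf(_static_traj(closed, 5), Selection(mode="ca"))
        np.testing.assert_allclose(out.to_numpy(), 0.0, atol=1e-10)

    def test_square_wave_oscillation_amplitude(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(20, 3)) * 5
        s = _structure_from_points(np.arange(1, 21), pts)
        a = 1.5
        frames = []
        for f in range(6):
            c = pts.copy()
            c[4, 0] += a if f % 2 == 0 else -a
            frames.append(c)
        traj = Trajectory(s, np.stack(frames), np.arange(6, dtype=float))
        out = rmsf(traj, Selection(mode="ca"), align=False)
        assert out.loc[5] == pytest.approx(a, rel=1e-12)
        others = out.drop(index=5)
        np.testing.assert_allclose(others.to_numpy(), 0.0, atol=1e-12)

    def test_invariant_to_global_translation_when_aligned(self, clean_collapse_traj):
        base = rmsf(clean_collapse_traj, Selection(mode="ca"), align=True)
        shifted = Trajectory(
            clean_collapse_traj.topology,
            clean_collapse_traj.coords + np.array([5.0, -2.0, 9.0]),
            clean_collapse_traj.times,
        )
        out = rmsf(shifted, Selection(mode="ca"), align=True)
        np.testing.assert_allclose(out.to_numpy(), base.to_numpy(), atol=1e-8)

    def test_single_frame_rejected(self, reference_pair):
        closed, _ = reference_pair
        with pytest.raises(InsufficientFramesError):
            rmsf(_static_traj(closed, 1), Selection(mode="ca"))


def test_ionic_lock_series_monotone_through_collapse(clean_collapse_traj):
    """Noise-free collapse: the R173–E318 distance never increases."""
    series = ca_distance_series(clean_collapse_traj, 173, 318)
    assert np.all(np.diff(series.values) <= 1e-9)
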