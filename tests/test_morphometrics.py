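"""Angle measurement, rank statistics, tissue phenotype, boundary detection."""

import numpy as np
import pytest
import scipy.stats

from pitchersim.errors import ConfigurationError
from pitchersim.mesh import (IDENTITY_ADAXIAL, TissueMesh, classify_layers)
from pitchersim.morphometrics import (IntensityProfile, circular_summary,
                                      compare_angle_distributions,
                                      division_angle_from_line,
                                      expression_boundary, fold_angle_deg,
                                      make_step_profile, mann_whitney_exact,
                                      protrusion_index)
from conftest import make_onion_mesh, states_for


def _strip_mesh(angle_deg: float = 0.0, n: int = 8):
    """A single row of unit squares, optionally rotated; flat boundary."""
    verts, cells = [], []
    for i in range(n + 1):
        verts += [(float(i), 0.0), (float(i), 1.0)]
    for i in range(n):
        cells.append([2 * i, 2 * i + 2, 2 * i + 3, 2 * i + 1])
    v = np.array(verts)
    t = np.radians(angle_deg)
    R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    return TissueMesh(v @ R.T, cells)


class TestDivisionAngle:
    def test_parallel_line_is_periclinal(self):
        mesh = _strip_mesh(0.0)
        a = division_angle_from_line(mesh, np.array([3.0, 0.5]),
                                     np.array([4.0, 0.5]))
        assert a == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_line_is_longitudinal(self):
        mesh = _strip_mesh(0.0)
        a = division_angle_from_line(mesh, np.array([3.5, 0.1]),
                                     np.array([3.5, 0.9]))
        assert a == pytest.approx(90.0, abs=1e-9)

    def test_rotated_boundary_vertical_line(self):
        """Boundary at 30 degrees, vertical division line: angle = 60."""
        mesh = _strip_mesh(30.0)
        centre = mesh.vertices[[8, 9, 10, 11]].mean(axis=0)
        p1 = centre - [0.0, 0.3]
        p2 = centre + [0.0, 0.3]
        a = division_angle_from_line(mesh, p1, p2)
        assert a == pytest.approx(60.0, abs=1e-6)

    def test_fold_convention(self):
        assert fold_angle_deg(120.0) == pytest.approx(60.0)
        assert fold_angle_deg(-30.0) == pytest.approx(30.0)
        assert fold_angle_deg(270.0) == pytest.approx(90.0)


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        u, p = mann_whitney_exact([10., 20., 30.], [10., 20., 30.])
        assert p == pytest.approx(1.0)

    def test_disjoint_groups_u_zero(self):
        u, p = mann_whitney_exact([1., 2., 3.], [80., 85., 88.])
        assert u == 0.0
        assert p == pytest.approx(2 / 20)  # 2 of C(6,3)=20 assignments

    def test_exact_matches_scipy_enumeration(self):
        """Cross-check the enumeration against scipy's exact method on
        tie-free data."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            a = rng.uniform(0, 90, 6)
            b = rng.uniform(10, 80, 7)
            u, p = mann_whitney_exact(a, b)
            ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                           method="exact")
            assert u == pytest.approx(float(ref.statistic))
            assert p == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_asymptotic_close_to_exact_at_n8(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 90, 8)
        b = rng.uniform(20, 90, 8)
        _, p_exact = mann_whitney_exact(a, b)
        res = compare_angle_distributions(a, b, exact_max_n=0)
        assert res.method == "asymptotic"
        assert abs(res.p - p_exact) < 0.015

    def test_bonferroni_adjustment(self):
        r = compare_angle_distributions([1., 2., 3.], [80., 85., 88.],
                                        n_family=5)
        assert r.p_adjusted == pytest.approx(min(1.0, r.p * 5))

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_angle_distributions([1.0, 2.0], [3.0, 4.0, 5.0])


def test_circular_summary_axial():
    s = circular_summary([10.0, 10.0, 10.0])
    assert s["mean_deg"] == pytest.approx(10.0)
    assert s["resultant_length"] == pytest.approx(1.0)
    # perpendicular axes cancel
    s2 = circular_summary([0.0, 90.0])
    assert s2["resultant_length"] == pytest.approx(0.0, abs=1e-12)


class TestProtrusionIndex:
    def _disc_tissue(self, finger: bool = False):
        """Onion disc with adaxial identity at the bottom; optionally a
        finger of adaxial cells appended below."""
        mesh = make_onion_mesh(n_rings=5, n_sectors=12)
        states = states_for(mesh)
        l1 = np.flatnonzero(states.layer == 1)
        centres = mesh.cell_centres()[l1]
        # adaxial = boundary cells nearest the bottom (-y)
        order = np.argsort(centres[:, 1])
        ada = l1[order[:3]]
        states.identity[ada] = IDENTITY_ADAXIAL
        if finger:
            # drag the adaxial boundary far down: a tongue ~5 cell
            # diameters long sticking out of the disc
            bottom = mesh.vertices[:, 1] < -4.0
            mesh.vertices[bottom, 1] -= 12.0
        classify_layers(mesh, states)
        return mesh, states

    def test_disc_classified_bifacial(self):
        """A plain disc has no adaxial outgrowth beyond the mild convexity
        of its circular boundary."""
        mesh, states = self._disc_tissue()
        pi = protrusion_index(mesh, states)
        assert pi.height < 2.0
        assert pi.classification == "bifacial"

    def test_finger_classified_protrusion(self):
        mesh, states = self._disc_tissue(finger=True)
        pi = protrusion_index(mesh, states)
        assert pi.height > 2.0
        assert pi.classification == "protrusion"

    def test_rigid_motion_invariance(self):
        mesh, states = self._disc_tissue(finger=True)
        pi1 = protrusion_index(mesh, states)
        t = 0.7
        R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        mesh2 = TissueMesh(mesh.vertices @ R.T + np.array([13.0, -4.0]),
                           [c.copy() for c in mesh.cells])
        pi2 = protrusion_index(mesh2, states.copy())
        assert pi2.height == pytest.approx(pi1.height, rel=1e-9)
        assert pi2.classification == pi1.classification

    def test_missing_identity_raises(self):
        mesh = make_onion_mesh()
        states = states_for(mesh)  # abaxial only
        with pytest.raises(ConfigurationError):
            protrusion_index(mesh, states)


class TestExpressionBoundary:
    def test_single_step_recovered(self):
        prof = make_step_profile([100.0, 10.0], [10, 10])
        out = expression_boundary(prof)
        falls = out[out["kind"] == "fall"]
        assert len(falls) == 1
        assert abs(falls["position"].iloc[0] - 10.0) <= 1.0

    def test_constant_profile_empty(self):
        prof = IntensityProfile(np.arange(20.0), np.full(20, 7.0))
        assert expression_boundary(prof).empty

    def test_two_step_staircase_ordered(self):
        prof = make_step_profile([10.0, 60.0, 120.0], [8, 8, 8])
        out = expression_boundary(prof)
        rises = out[out["kind"] == "rise"]["position"].to_numpy()
        assert len(rises) == 2
        assert abs(rises[0] - 8.0) <= 1.0 and abs(rises[1] - 16.0) <= 1.0
        assert (out["position"].is_monotonic_increasing)

    def test_noisy_step_recovery_at_snr_5(self):
        """Planted boundary recovered within +-1 cell at SNR >= 5 in every
        one of 100 seeded replicates."""
        height, snr = 90.0, 5.0
        sd = height / snr
        failures = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            prof = make_step_profile([100.0, 10.0], [10, 10],
                                     noise_sd=sd, rng=rng)
            out = expression_boundary(prof)
            falls = out[out["kind"] == "fall"]
            ok = (not falls.empty and
                  np.min(np.abs(falls["position"].to_numpy() - 10.0)) <= 1.0)
            if not ok:
                failures += 1
        assert failures == 0

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            IntensityProfile(np.arange(4.0), np.ones(4))
        with pytest.raises(ValueError):
            IntensityProfile(np.array([0.0, 1, 1, 2, 3]), np.ones(5))
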