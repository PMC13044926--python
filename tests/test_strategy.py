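"""Characterization, polyhedron orientations, mounting fit and native strategies."""

import dataclasses
import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mxstrat.geometry import GoniostatModel
from mxstrat.sample import random_crystal
from mxstrat.strategy import (
    DEFAULT_BATCH_DEG,
    StrategyPlan,
    Sweep,
    accessible_fraction,
    advanced_strategy,
    assign_lengths,
    basic_strategy,
    characterization_strategy,
    fit_to_mounting,
    predicted_multiplicity,
    target_orientations,
)

# point group -> (sweep count, total length deg, maximum multiplicity), the
# published advanced-strategy table (lengths = one 360 + (n-1) x 192)
ADVANCED_TABLE = {
    "1": (4, 936, 10), "2": (4, 936, 20), "3": (3, 744, 24), "222": (3, 744, 32),
    "4": (3, 744, 32), "32": (2, 552, 36), "6": (2, 552, 36), "422": (2, 552, 48),
    "622": (2, 552, 72), "23": (1, 360, 48), "432": (1, 360, 96),
}


class TestCharacterization:
    def test_default_wedges(self):
        plan = characterization_strategy()
        assert len(plan.sweeps) == 5
        assert [s.omega_start_deg for s in plan.sweeps] == [0, 45, 90, 135, 180]
        assert all(s.width_deg == pytest.approx(1.2) for s in plan.sweeps)
        assert sum(s.n_images for s in plan.sweeps) == 60

    def test_single_wedge(self):
        plan = characterization_strategy(n_wedges=1)
        assert len(plan.sweeps) == 1
        assert plan.sweeps[0].omega_start_deg == 0.0


class TestTargetOrientations:
    @pytest.mark.parametrize("pg,count", [(k, v[0]) for k, v in ADVANCED_TABLE.items()])
    def test_orientation_counts_match_sweep_counts(self, pg, count):
        vecs, scheme = target_orientations(pg)
        assert len(vecs) == count
        for v in vecs:
            assert np.linalg.norm(v) == pytest.approx(1.0)

    def test_trigonal_four_sweep_variant(self):
        vecs, scheme = target_orientations("3x4")
        assert len(vecs) == 4 and "square" in scheme

    def test_triangle_triplet_geometry(self):
        """The 222/4 triplet is an equilateral polyhedron triangle."""
        vecs, _ = target_orientations("222")
        dots = [vecs[i] @ vecs[j] for i, j in ((0, 1), (0, 2), (1, 2))]
        assert dots == pytest.approx([dots[0]] * 3, abs=1e-12)

    def test_unsupported_group_rejected(self):
        with pytest.raises(ValueError):
            target_orientations("m-3")


class TestFitToMounting:
    def test_reachable_targets_realized_isometrically(self, mini_kappa):
        """When no fallback occurs, pairwise target angles are preserved."""
        targets, _ = target_orientations("222")
        centre = sum(targets) / 3.0
        centre /= np.linalg.norm(centre)
        # orient the crystal so the triangle centre sits on the mounted axis
        rot = _rotation_taking(centre, np.array([1.0, 0.0, 0.0]))
        fit = fit_to_mounting(targets, rot, mini_kappa)
        assert not fit.fallback
        achieved = [np.asarray(s.axis_direction_crystal) for s in fit.sweeps]
        for i in range(3):
            for j in range(i + 1, 3):
                assert achieved[i] @ achieved[j] == pytest.approx(
                    targets[i] @ targets[j], abs=1e-9)

    def test_aligned_target_realized_at_chi_zero(self, mini_kappa):
        u = np.eye(3)
        fit = fit_to_mounting([np.array([1.0, 0.0, 0.0])], u, mini_kappa)
        assert fit.sweeps[0].kappa_deg == pytest.approx(0.0, abs=1e-9)
        assert fit.sweeps[0].chi_deg == pytest.approx(0.0, abs=1e-9)

    def test_unreachable_targets_fall_back_inside_chi_limit(self, mini_kappa):
        u = np.eye(3)
        with pytest.warns(UserWarning, match="accessible"):
            fit = fit_to_mounting([np.array([0.0, 0.0, 1.0])], u, mini_kappa)
        assert fit.fallback
        assert fit.sweeps[0].chi_deg <= mini_kappa.chi_max_mech_deg + 1e-6


def _rotation_taking(a, b):
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    ang = np.arctan2(s, a @ b)
    return Rotation.from_rotvec(v / s * ang).as_matrix()


class TestAssignLengths:
    def test_first_sweep_full_turn_later_shadowed_get_192(self, pilatus6m,
                                                          mini_kappa):
        sweeps = [
            Sweep(chi_deg=40.0, kappa_deg=150.0, goniostat=mini_kappa),
            Sweep(chi_deg=5.0, kappa_deg=15.0, goniostat=mini_kappa),
        ]
        out = assign_lengths(sweeps, pilatus6m, 200.0, mini_kappa)
        assert [s.chi_deg for s in out] == [5.0, 40.0]  # ordered by chi
        assert out[0].width_deg == 360.0
        assert out[1].width_deg == pytest.approx(192.0)
        for s in out:
            assert (s.width_deg / DEFAULT_BATCH_DEG) == pytest.approx(
                round(s.width_deg / DEFAULT_BATCH_DEG))

    def test_low_chi_sweeps_all_full_turn_when_shadow_free(self, pilatus6m,
                                                           mini_kappa):
        sweeps = [Sweep(chi_deg=c, kappa_deg=10.0, goniostat=mini_kappa)
                  for c in (2.0, 4.0)]
        out = assign_lengths(sweeps, pilatus6m, 2000.0, mini_kappa)
        assert all(s.width_deg == 360.0 for s in out)


@pytest.mark.parametrize("pg,row", list(ADVANCED_TABLE.items()))
def test_predicted_multiplicity_reproduces_published_table(pg, row):
    n_sweeps, length, mult = row
    sweeps = [Sweep(width_deg=360.0)] + [Sweep(width_deg=192.0)] * (n_sweeps - 1)
    plan = StrategyPlan(sweeps)
    assert plan.total_length_deg == length
    assert predicted_multiplicity(plan, pg) == pytest.approx(mult)


def test_predicted_multiplicity_trigonal_four_sweep_row():
    plan = StrategyPlan([Sweep(width_deg=360.0)] + [Sweep(width_deg=192.0)] * 3)
    assert predicted_multiplicity(plan, "3") == pytest.approx(30.0)


def test_accessible_fraction_converges_to_analytic_value():
    frac = accessible_fraction(48.0, n_samples=100_000, seed=7)
    assert frac == pytest.approx(1.0 - np.cos(np.radians(48.0)), abs=0.01)
    assert round(100 * frac) == 33


class TestBasicStrategy:
    def test_monoclinic_single_sweep_no_recentring(self):
        crystal = random_crystal("monoclinic", seed=2, target_resolution_A=2.0)
        plan = basic_strategy(crystal)
        assert len(plan.sweeps) == 1
        assert plan.sweeps[0].width_deg == 360.0
        assert plan.recentring_count == 0

    def test_triclinic_needs_two_sweeps(self):
        crystal = random_crystal("triclinic", seed=2, target_resolution_A=2.0)
        plan = basic_strategy(crystal)
        assert len(plan.sweeps) == 2

    def test_symmetry_aligned_mount_triggers_reorientation(self, sim_stats):
        """4-fold along the mounted axis: reorient by >= theta_max, after which
        the simulator confirms full completeness."""
        crystal = random_crystal("tetragonal", seed=3, point_group="4",
                                 target_resolution_A=2.0, cell_edge_range=(40, 50))
        # orient the crystal 4-fold (c axis) along the mounted omega/phi axis
        u = _rotation_taking(np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))
        aligned = dataclasses.replace(crystal, orientation=u)
        plan = basic_strategy(aligned)
        assert plan.notes and "reoriented" in plan.notes[0]
        axis = np.asarray(plan.sweeps[0].axis_direction_crystal)
        tilt = np.degrees(np.arccos(abs(axis @ [0.0, 0.0, 1.0])))
        theta_max = np.degrees(np.arcsin(1.0 / (2 * 2.0)))
        assert tilt >= theta_max
        stats = sim_stats(aligned, plan.sweeps, d_min=2.5)
        assert stats.completeness_pct == pytest.approx(100.0, abs=0.01)


class TestAdvancedStrategy:
    @pytest.mark.parametrize("system,pg", [
        ("hexagonal", "622"), ("tetragonal", "4"), ("monoclinic", "2"),
        ("cubic", "432"),
    ])
    def test_sweep_counts_and_first_sweep(self, system, pg, pilatus6m):
        crystal = random_crystal(system, seed=4, point_group=pg,
                                 target_resolution_A=2.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plan = advanced_strategy(crystal, pilatus6m, 250.0)
        assert len(plan.sweeps) == ADVANCED_TABLE[pg][0]
        assert plan.sweeps[0].width_deg == 360.0
        assert plan.sweeps[0].chi_deg == min(s.chi_deg for s in plan.sweeps)
        for s in plan.sweeps:
            assert s.chi_deg <= 48.0 + 1e-6
            assert (s.width_deg / DEFAULT_BATCH_DEG) == pytest.approx(
                round(s.width_deg / DEFAULT_BATCH_DEG))

    def test_hexagonal_total_length_matches_table(self, pilatus6m):
        crystal = random_crystal("hexagonal", seed=4, point_group="622",
                                 target_resolution_A=2.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plan = advanced_strategy(crystal, pilatus6m, 250.0)
        assert plan.total_length_deg == pytest.approx(552.0)

    def test_chi0_variant_saves_a_recentring(self, pilatus6m):
        crystal = random_crystal("tetragonal", seed=6, point_group="4",
                                 target_resolution_A=2.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plan = advanced_strategy(crystal, pilatus6m, 250.0,
                                     first_sweep_chi0=True)
        assert min(s.chi_deg for s in plan.sweeps) == pytest.approx(0.0, abs=1e-9)


def test_redundancy_distribution_more_uniform_for_advanced(sim_stats, pilatus6m):
    """Multi-sweep averaging reduces the spread of per-reflection redundancy
    (length-normalized) relative to a single sweep, with gaps and cusps on."""
    crystal = random_crystal("monoclinic", seed=22, target_resolution_A=2.0,
                             cell_edge_range=(45, 55))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        basic = basic_strategy(crystal)
        advanced = advanced_strategy(crystal, pilatus6m, 300.0)
    sb = sim_stats(crystal, basic.sweeps, 2.5, pilatus6m, 300.0)
    sa = sim_stats(crystal, advanced.sweeps, 2.5, pilatus6m, 300.0)
    rel_spread = lambda stats, plan: float(
        (stats.table.multiplicity / plan.total_length_deg).std()
        / (stats.table.multiplicity / plan.total_length_deg).mean())
    assert rel_spread(sa, advanced) < rel_spread(sb, basic)
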