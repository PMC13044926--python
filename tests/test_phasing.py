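"""Dauter minimum sweeps, cusp filling, interleaving and sweep splitting."""

import dataclasses

import numpy as np
import pytest

from mxstrat.geometry import two_theta_for_resolution
from mxstrat.phasing import (
    cusp_fill,
    interleave_schedule,
    min_anomalous_sweep,
    split_sweep_for_completeness,
)
from mxstrat.sample import random_crystal
from mxstrat.strategy import Sweep


class TestMinAnomalousSweep:
    @pytest.mark.parametrize("pg,alignment,tth,expected", [
        ("1", "aligned", 15.0, 195.0),
        ("1", "orthogonal", 30.0, 210.0),
        ("2", "aligned", 15.0, 180.0),
        ("3", "aligned", 15.0, 120.0),
        ("4", "aligned", 15.0, 90.0),
        ("6", "aligned", 15.0, 60.0),
        ("2", "orthogonal", 15.0, 97.5),      # 90 + theta_max
        ("222", "aligned", 15.0, 90.0),       # 360 / (2 x 2)
        ("422", "aligned", 15.0, 45.0),       # 360 / (2 x 4)
        ("622", "aligned", 15.0, 30.0),
        ("622", "orthogonal", 15.0, 90.0),
        ("32", "orthogonal", 15.0, 90.0),
    ])
    def test_rule_table(self, pg, alignment, tth, expected):
        assert min_anomalous_sweep(pg, alignment, tth) == pytest.approx(expected)

    def test_even_axis_override_for_trigonal_multi_axis(self):
        # 32 has an odd principal axis; aligning on its twofold is allowed
        assert min_anomalous_sweep("32", "aligned", 15.0, axis_order=2) == 90.0
        with pytest.raises(ValueError, match="even"):
            min_anomalous_sweep("32", "aligned", 15.0)

    def test_disputed_monoclinic_orthogonal_value_behind_flag(self):
        assert min_anomalous_sweep("2", "orthogonal", 15.0,
                                   dauter_monoclinic=True) == pytest.approx(195.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            min_anomalous_sweep("2", "aligned", -1.0)


class TestCuspFill:
    MAIN = Sweep(width_deg=180.0)

    def test_pair_mode_two_short_sweeps_half_turn_apart(self):
        fills = cusp_fill(self.MAIN, 15.0, mode="pair")
        assert len(fills) == 2
        assert all(f.width_deg == pytest.approx(15.0) for f in fills)
        assert abs(fills[1].omega_start_deg - fills[0].omega_start_deg) == 180.0

    def test_basic_and_extended_lengths(self):
        (basic,) = cusp_fill(self.MAIN, 15.0, mode="basic")
        assert basic.width_deg == pytest.approx(195.0)
        (ext,) = cusp_fill(self.MAIN, 15.0, mode="extended")
        assert ext.width_deg == pytest.approx(210.0)  # 180 + 4 theta_max

    def test_fill_axis_away_from_main_axis(self, mini_kappa):
        u = np.eye(3)
        fills = cusp_fill(Sweep(width_deg=180.0,
                                axis_direction_crystal=(1.0, 0.0, 0.0)),
                          15.0, mode="pair", gonio=mini_kappa, orientation=u)
        axis = np.asarray(fills[0].axis_direction_crystal)
        sep = np.degrees(np.arccos(abs(axis @ [1.0, 0.0, 0.0])))
        assert sep == pytest.approx(mini_kappa.chi_max_mech_deg, abs=1e-6)

    def test_fill_recovers_aligned_cusp_in_simulation(self, sim_stats):
        """Evenfold-aligned main sweep plus a fill pair: the anomalous
        completeness lost to the uncompensated cusp is recovered."""
        crystal = random_crystal("monoclinic", seed=22, target_resolution_A=2.0,
                                 cell_edge_range=(45, 55))
        u = np.array([[0.0, 1, 0], [-1, 0, 0], [0, 0, 1]])  # b (2-fold) -> omega
        aligned = dataclasses.replace(crystal, orientation=u)
        tth = two_theta_for_resolution(2.0, 1.0)
        main = [Sweep(width_deg=180.0)]
        fills = cusp_fill(main[0], tth, mode="pair", orientation=u)
        alone = sim_stats(aligned, main, 2.0).anomalous_completeness_pct
        filled = sim_stats(aligned, main + fills, 2.0).anomalous_completeness_pct
        assert filled > alone
        assert filled == pytest.approx(100.0, abs=0.2)


class TestInterleave:
    def test_half_turn_in_ten_degree_wedges(self):
        segs = interleave_schedule(Sweep(width_deg=180.0), 10.0)
        assert len(segs) == 36
        offsets = {s.offset_deg for s in segs}
        assert offsets == {0.0, 180.0}

    def test_partitions_sweep_exactly(self):
        sweep = Sweep(omega_start_deg=30.0, width_deg=120.0)
        segs = interleave_schedule(sweep, 15.0)
        base = sorted(s.omega_start_deg for s in segs if s.offset_deg == 0.0)
        assert base == pytest.approx(list(np.arange(30.0, 150.0, 15.0)))
        starts_plus_widths = [(s, s + 15.0) for s in base]
        for (a0, a1), (b0, b1) in zip(starts_plus_widths, starts_plus_widths[1:]):
            assert a1 == pytest.approx(b0)  # no gap, no overlap

    def test_wedge_equal_to_width(self):
        segs = interleave_schedule(Sweep(width_deg=90.0), 90.0)
        assert len(segs) == 2

    def test_wavelength_interleaving_doubles_segments(self):
        one = interleave_schedule(Sweep(width_deg=90.0), 30.0)
        two = interleave_schedule(Sweep(width_deg=90.0), 30.0,
                                  wavelengths=["peak", "remote"])
        assert len(two) == 2 * len(one)
        assert {s.wavelength for s in two} == {"peak", "remote"}

    def test_non_dividing_wedge_rejected(self):
        with pytest.raises(ValueError):
            interleave_schedule(Sweep(width_deg=100.0), 13.0)


class TestSplitSweep:
    def test_default_midpoint_split_preserves_union(self):
        sweep = Sweep(omega_start_deg=10.0, width_deg=180.0)
        parts = split_sweep_for_completeness(sweep)
        assert len(parts) == 2
        assert sum(p.width_deg for p in parts) == pytest.approx(180.0)
        covered = sorted((p.omega_start_deg, p.omega_start_deg + p.width_deg)
                         for p in parts)
        assert covered[0][1] == pytest.approx(covered[1][0])
        assert covered[0][0] == 10.0 and covered[1][1] == pytest.approx(190.0)

    def test_anchor_inside_reorders_halves(self):
        sweep = Sweep(omega_start_deg=0.0, width_deg=180.0)
        parts = split_sweep_for_completeness(sweep, anchor_omega_deg=120.0)
        assert parts[0].omega_start_deg == pytest.approx(120.0)  # anchored part first
        assert sum(p.width_deg for p in parts) == pytest.approx(180.0)

    def test_anchor_outside_returns_unsplit_with_warning(self):
        sweep = Sweep(omega_start_deg=0.0, width_deg=90.0)
        with pytest.warns(UserWarning):
            parts = split_sweep_for_completeness(sweep, anchor_omega_deg=200.0)
        assert parts == [sweep]


class TestAnomalousMinimaInSimulation:
    """The minimum-length rules deliver near-complete anomalous data, and
    completeness degrades when the sweep is shortened.  Exact 100% holds only
    outside a volume somewhat larger than the cusps, so the thresholds here
    are a little below 100."""

    def test_p1_minimum(self, sim_stats):
        crystal = random_crystal("triclinic", seed=21, target_resolution_A=2.0,
                                 cell_edge_range=(45, 55))
        tth = two_theta_for_resolution(2.0, 1.0)
        w_min = min_anomalous_sweep("1", "aligned", tth)
        at_min = sim_stats(crystal, [Sweep(width_deg=w_min)], 2.0)
        short = sim_stats(crystal, [Sweep(width_deg=w_min - 10.0)], 2.0)
        assert at_min.anomalous_completeness_outside_blind_pct > 97.5
        assert short.anomalous_completeness_outside_blind_pct < \
            at_min.anomalous_completeness_outside_blind_pct - 1.0

    def test_evenfold_aligned_monoclinic_minimum(self, sim_stats):
        crystal = random_crystal("monoclinic", seed=22, target_resolution_A=2.0,
                                 cell_edge_range=(45, 55))
        u = np.array([[0.0, 1, 0], [-1, 0, 0], [0, 0, 1]])
        aligned = dataclasses.replace(crystal, orientation=u)
        w_min = min_anomalous_sweep("2", "aligned", 30.0)  # 360/2
        stats = sim_stats(aligned, [Sweep(width_deg=w_min)], 2.0)
        assert stats.anomalous_completeness_outside_blind_pct == pytest.approx(100.0)

    def test_orthogonal_monoclinic_minimum_needs_matched_start(self, sim_stats):
        crystal = random_crystal("monoclinic", seed=22, target_resolution_A=2.0,
                                 cell_edge_range=(45, 55))
        ortho = dataclasses.replace(crystal, orientation=np.eye(3))
        tth = two_theta_for_resolution(2.0, 1.0)
        w_min = min_anomalous_sweep("2", "orthogonal", tth)
        best = max(
            sim_stats(ortho, [Sweep(width_deg=w_min, omega_start_deg=s)], 2.0
                      ).anomalous_completeness_outside_blind_pct
            for s in np.arange(0.0, 180.0, 15.0)
        )
        short = max(
            sim_stats(ortho, [Sweep(width_deg=w_min - 10.0, omega_start_deg=s)],
                      2.0).anomalous_completeness_outside_blind_pct
            for s in np.arange(0.0, 180.0, 15.0)
        )
        assert best > 97.5
        assert short < best - 1.0

    def test_aligned_evenfold_mates_cross_on_same_image(self):
        """With an evenfold axis on the rotation axis, each reflection and its
        Bijvoet comparison partner cross at the same omega."""
        from mxstrat.simulate import ewald_crossings, generate_hkl

        crystal = random_crystal("monoclinic", seed=22, target_resolution_A=2.5,
                                 cell_edge_range=(45, 55))
        u = np.array([[0.0, 1, 0], [-1, 0, 0], [0, 0, 1]])
        aligned = dataclasses.replace(crystal, orientation=u)
        sweep = Sweep(width_deg=360.0)
        two_fold = np.array([[-1, 0, 0], [0, 1, 0], [0, 0, -1]])  # 2 along b
        rng = np.random.default_rng(5)
        hkls = generate_hkl(aligned, 3.5)
        for hkl in hkls[rng.choice(len(hkls), size=20, replace=False)]:
            partner = two_fold @ (-hkl)
            a = sorted(w % 360 for w in ewald_crossings(hkl, aligned, sweep))
            b = sorted(w % 360 for w in ewald_crossings(partner, aligned, sweep))
            assert a == pytest.approx(b, abs=1e-6)
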