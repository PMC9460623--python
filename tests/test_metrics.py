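"""Energy-share metrics: Omega, dominant hotspot, Psi, P_av."""

import numpy as np
import pytest

from conftest import homogeneous_phantom
from mhfocus import Excitation, TargetSpec, evaluate, scale_to_total_power
from mhfocus.dataset import build_mask
from mhfocus.errors import DegenerateExcitationError, MetricError
from mhfocus.excitation import HPMap, expand_free_phases, superpose
from mhfocus.metrics import find_dominant_hotspot, omega_region, p_av, psi
from mhfocus.phantom import GridSpec

# Printed (Omega_target, Omega_hotspot, Psi) triples: linear table rows and
# the circular cases reported in the running text.
PSI_TRIPLES = [
    (8.42, 10.78, 1.28), (10.20, 9.04, 0.89),
    (8.69, 16.64, 1.91), (10.56, 12.71, 1.20),
    (12.63, 11.44, 0.91), (15.20, 10.08, 0.66),
    (13.67, 16.05, 1.17), (15.10, 10.24, 0.68),
    (14.31, 7.81, 0.55), (15.42, 7.79, 0.51),
    (12.42, 7.95, 0.64), (15.07, 4.87, 0.32),
    (12.31, 7.47, 0.61), (19.47, 10.51, 0.54),
]


class TestOmegaRegion:
    def test_whole_breast_is_100_percent(self, small_phantom):
        rng = np.random.default_rng(0)
        q0 = rng.uniform(size=small_phantom.grid.shape) * small_phantom.breast_mask
        hp = HPMap(grid=small_phantom.grid, q0=q0)
        assert omega_region(hp, small_phantom, small_phantom.breast_mask) == pytest.approx(100.0)

    def test_hand_computed_share(self):
        grid = GridSpec(8, 8, 1.0)
        phantom = homogeneous_phantom(grid)
        q0 = np.zeros((8, 8))
        q0[0, :3] = [10, 15, 5]  # region sums to 30
        q0[4, :4] = [40, 20, 10, 20]  # remainder sums to 90; breast total 120
        region = np.zeros((8, 8), dtype=bool)
        region[0, :3] = True
        hp = HPMap(grid=grid, q0=q0)
        assert omega_region(hp, phantom, region) == pytest.approx(25.0)

    def test_outside_breast_pixels_excluded_from_both_sums(self):
        grid = GridSpec(8, 8, 1.0)
        phantom = homogeneous_phantom(grid)
        mask = phantom.breast_mask.copy()
        mask[0, :] = False
        phantom = type(phantom)(grid=grid, eps_r=phantom.eps_r,
                                sigma=phantom.sigma * mask, breast_mask=mask)
        q0 = np.ones((8, 8))
        region = np.zeros((8, 8), dtype=bool)
        region[0, :] = True  # entirely outside the breast
        region[1, 0] = True
        hp = HPMap(grid=grid, q0=q0)
        assert omega_region(hp, phantom, region) == pytest.approx(100.0 / 56.0)

    def test_zero_total_energy_raises(self, small_phantom):
        hp = HPMap(grid=small_phantom.grid, q0=np.zeros(small_phantom.grid.shape))
        with pytest.raises(MetricError):
            omega_region(hp, small_phantom, small_phantom.breast_mask)


class TestDominantHotspot:
    # Note: the target must sit off-center, else no 10 mm window on a toy
    # grid can be disjoint from it (a GeometryError by design).

    def test_energy_only_in_target_gives_zero_hotspot(self):
        grid = GridSpec(20, 20, 1.0)
        phantom = homogeneous_phantom(grid)
        target = TargetSpec(center=(-4.5, 5.0))  # upper-left corner square
        q0 = build_mask(target, grid).astype(float)
        _, om_h = find_dominant_hotspot(HPMap(grid=grid, q0=q0), phantom, target)
        assert om_h == 0.0

    def test_matches_exhaustive_window_scan(self):
        grid = GridSpec(20, 20, 1.0)
        phantom = homogeneous_phantom(grid)
        target = TargetSpec(center=(-4.5, 5.0))
        rng = np.random.default_rng(7)
        q0 = rng.uniform(size=(20, 20))
        hp = HPMap(grid=grid, q0=q0)
        window, om_h = find_dominant_hotspot(hp, phantom, target)
        # oracle: test every 10x10 placement disjoint from the target square
        tmask = build_mask(target, grid).astype(bool)
        rows, cols = np.nonzero(tmask)
        rt, ct = rows.min(), cols.min()
        best = -1.0
        for r in range(11):
            for c in range(11):
                if abs(r - rt) < 10 and abs(c - ct) < 10:
                    continue
                best = max(best, q0[r : r + 10, c : c + 10].sum())
        assert q0[window].sum() == pytest.approx(best)
        assert om_h == pytest.approx(100.0 * best / q0.sum())
        assert not (window & tmask).any()

    def test_centered_target_on_tiny_grid_raises(self):
        grid = GridSpec(20, 20, 1.0)
        phantom = homogeneous_phantom(grid)
        target = TargetSpec(center=(0.0, 0.0))
        q0 = np.ones((20, 20))
        from mhfocus.errors import GeometryError

        with pytest.raises(GeometryError):
            find_dominant_hotspot(HPMap(grid=grid, q0=q0), phantom, target)

    def test_tie_breaks_toward_smallest_row_then_column(self):
        grid = GridSpec(32, 32, 1.0)
        phantom = homogeneous_phantom(grid)
        target = TargetSpec(center=(0.0, 0.0))
        q0 = np.zeros((32, 32))
        q0[0, 0] = q0[31, 31] = 5.0  # two identical off-target peaks
        window, om_h = find_dominant_hotspot(HPMap(grid=grid, q0=q0), phantom, target)
        assert window[0, 0]
        assert om_h == pytest.approx(50.0)


class TestPsi:
    @pytest.mark.parametrize("om_t,om_h,expected", PSI_TRIPLES)
    def test_reproduces_published_ratios(self, om_t, om_h, expected):
        assert psi(om_h, om_t) == pytest.approx(expected, abs=0.01)

    def test_zero_hotspot_gives_zero(self):
        assert psi(0.0, 8.0) == 0.0

    def test_zero_target_raises(self):
        with pytest.raises(MetricError):
            psi(5.0, 0.0)


class TestPav:
    def test_uniform_hp_over_target_equals_that_level(self):
        grid = GridSpec(20, 20, 1.0)
        phantom = homogeneous_phantom(grid, sigma=2.0)
        target = TargetSpec(center=(0.0, 0.0))
        e = np.zeros((1, 20, 20), dtype=complex)
        tmask = build_mask(target, grid).astype(bool)
        e[0][tmask] = 1.0  # q0 = 0.5 * 2 * 1 = 1 W/m^3 on the target
        assert p_av(e, phantom, target) == pytest.approx(1.0 / 1000.0)
        # printed-formula variant without the 1/2
        assert p_av(e, phantom, target, include_half=False) == pytest.approx(2.0 / 1000.0)

    def test_doubling_field_quadruples_pav(self):
        grid = GridSpec(20, 20, 1.0)
        phantom = homogeneous_phantom(grid)
        target = TargetSpec(center=(2.0, -3.0))
        rng = np.random.default_rng(3)
        e = rng.normal(size=(2, 20, 20)) + 1j * rng.normal(size=(2, 20, 20))
        assert p_av(2 * e, phantom, target) == pytest.approx(4 * p_av(e, phantom, target))

    def test_hand_written_patch_equals_direct_mean(self):
        grid = GridSpec(20, 20, 1.0)
        phantom = homogeneous_phantom(grid, sigma=1.3)
        target = TargetSpec(center=(0.0, 0.0))
        rng = np.random.default_rng(5)
        e = rng.normal(size=(2, 20, 20)) + 1j * rng.normal(size=(2, 20, 20))
        tmask = build_mask(target, grid).astype(bool)
        direct = (0.5 * 1.3 * (np.abs(e) ** 2).sum(axis=0))[tmask].mean() / 1000.0
        assert p_av(e, phantom, target) == pytest.approx(direct, rel=1e-12)


class TestEvaluate:
    def test_report_is_internally_consistent(self, small_linear_fieldset, small_phantom):
        exc = Excitation(scheme="linear", voltages=[1, 2, 0.5, 1.5],
                         phases=expand_free_phases("linear", [40.0, 250.0]))
        report = evaluate(exc, small_linear_fieldset, small_phantom,
                          TargetSpec(center=(15.0, 9.0)))
        assert report.psi == pytest.approx(report.omega_hotspot / report.omega_target)
        assert 0 <= report.omega_target <= 100
        assert 0 <= report.omega_hotspot <= 100
        assert report.excitation.total_antenna_power_w() == pytest.approx(6.0)

    def test_omega_invariant_under_power_scaling_but_pav_not(
        self, small_linear_fieldset, small_phantom
    ):
        target = TargetSpec(center=(15.0, 9.0))
        exc = Excitation(scheme="linear", voltages=[1, 2, 0.5, 1.5],
                         phases=expand_free_phases("linear", [40.0, 250.0]))
        r6 = evaluate(exc, small_linear_fieldset, small_phantom, target, total_w=6.0)
        r12 = evaluate(exc, small_linear_fieldset, small_phantom, target, total_w=12.0)
        assert r12.omega_target == pytest.approx(r6.omega_target, rel=1e-10)
        assert r12.omega_hotspot == pytest.approx(r6.omega_hotspot, rel=1e-10)
        assert r12.p_av_kw_m3 == pytest.approx(2 * r6.p_av_kw_m3, rel=1e-9)

    def test_zero_excitation_raises(self, small_linear_fieldset, small_phantom):
        exc = Excitation(scheme="linear", voltages=np.zeros(4), phases=np.zeros(4))
        with pytest.raises((DegenerateExcitationError, MetricError)):
            evaluate(exc, small_linear_fieldset, small_phantom,
                     TargetSpec(center=(15.0, 9.0)))

    def test_end_to_end_matches_stepwise_oracle(self, small_linear_fieldset, small_phantom):
        target = TargetSpec(center=(15.0, 9.0))
        exc = scale_to_total_power(
            Excitation(scheme="linear", voltages=[1.0, 0.5, 2.0, 1.0],
                       phases=expand_free_phases("linear", [100.0, 290.0]))
        )
        report = evaluate(exc, small_linear_fieldset, small_phantom, target, total_w=None)
        # independent stepwise computation
        e_tot = superpose(small_linear_fieldset, exc)
        q0 = 0.5 * small_phantom.sigma * (np.abs(e_tot) ** 2).sum(axis=0)
        tmask = build_mask(target, small_phantom.grid).astype(bool)
        breast = small_phantom.breast_mask
        om_t = 100.0 * q0[tmask & breast].sum() / q0[breast].sum()
        assert report.omega_target == pytest.approx(om_t, rel=1e-12)
        assert report.p_av_kw_m3 == pytest.approx(q0[tmask].mean() / 1000.0, rel=1e-12)
        assert report.psi == pytest.approx(report.omega_hotspot / om_t, rel=1e-12)
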