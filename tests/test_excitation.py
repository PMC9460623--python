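"""Phase constraints, superposition, heating potential, power accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhfocus import (
    Excitation,
    heating_potential,
    normalize_hp,
    port_power,
    scale_to_total_power,
    superpose,
    wrap_phase,
)
from mhfocus.errors import ContractError, DegenerateExcitationError, MetricError
from mhfocus.excitation import (
    HPMap,
    circular_phase_vector,
    linear_phase_vector,
    load_excitation,
    save_excitation,
    superpose_coefficients,
)
from conftest import homogeneous_phantom
from mhfocus.phantom import GridSpec

# Published per-antenna phase rows (linear: 4 channels; circular: 12 antennas)
LINEAR_ROWS = [
    [0.00, -48.46, -178.10, 133.44],
    [0.00, -100.00, 138.00, 38.00],
    [0.00, -43.10, 135.73, 92.63],
    [0.00, -100.00, 140.00, 40.00],
]
CIRCULAR_ROWS = [
    [0.00, 98.57, -15.76, -114.3, 170.8, -74.84, -40.73, 34.11, -62.28, -96.39, -108.0, -11.60],
    [0.00, 126.03, -61.00, 172.97, 97.59, -75.38, -94.68, -19.31, -59.18, -39.88, 96.33, 136.21],
    [0.00, -31.33, 138.53, 169.86, 52.28, -117.6, 0.42, 118.0, 29.80, -88.19, -157.3, -69.07],
]


class TestWrapPhase:
    @pytest.mark.parametrize(
        "deg,expected",
        [(0.0, 0.0), (-226.56, 133.44), (540.0, 180.0), (-180.0, 180.0),
         (180.0, 180.0), (360.0, 0.0), (-90.0, -90.0)],
    )
    def test_worked_values(self, deg, expected):
        assert wrap_phase(deg) == pytest.approx(expected, abs=1e-9)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.floats(min_value=-1e6, max_value=1e6))
    def test_range_and_congruence(self, deg):
        w = wrap_phase(deg)
        assert -180.0 < w <= 180.0
        assert (w - deg) % 360.0 == pytest.approx(0.0, abs=1e-6) or (
            (w - deg) % 360.0 == pytest.approx(360.0, abs=1e-6)
        )


class TestPhaseVectors:
    @pytest.mark.parametrize(
        "phi2,phi3,phi4",
        [(-48.46, -178.10, 133.44), (-100.00, 138.00, 38.00), (0.0, 0.0, 0.0)],
    )
    def test_linear_tied_fourth_phase(self, phi2, phi3, phi4):
        vec = linear_phase_vector(phi2, phi3)
        assert vec[0] == 0.0
        assert vec[3] == pytest.approx(phi4, abs=1e-9)

    def test_circular_odd_antennas_are_neighbour_sums(self):
        evens = [98.57, -114.3, -74.84, 34.11, -96.39, -11.60]
        vec = circular_phase_vector(evens)
        assert vec[0] == 0.0
        assert vec[6] == pytest.approx(-40.73, abs=1e-9)  # antenna 7 = 6 + 8
        evens_c = [-31.33, 169.86, -117.6, 118.0, -88.19, -69.07]
        assert circular_phase_vector(evens_c)[2] == pytest.approx(138.53, abs=0.01)
        assert np.array_equal(circular_phase_vector([0.0] * 6), np.zeros(12))

    @pytest.mark.parametrize("row", LINEAR_ROWS)
    def test_published_linear_rows_satisfy_constraint(self, row):
        Excitation(scheme="linear", voltages=np.ones(4), phases=row)

    @pytest.mark.parametrize("row", CIRCULAR_ROWS)
    def test_published_circular_rows_satisfy_constraint(self, row):
        # values are printed with 1-2 decimals, so residuals reach 0.06 deg
        exc = Excitation.__new__(Excitation)
        object.__setattr__(exc, "scheme", "circular")
        object.__setattr__(exc, "voltages", np.ones(12))
        object.__setattr__(exc, "phases", np.asarray(row, dtype=float))
        exc.validate_phases(tol_deg=0.1)

    def test_constraint_violation_raises(self):
        with pytest.raises(ValueError):
            Excitation(scheme="linear", voltages=np.ones(4), phases=[0, 10, 20, 90])
        with pytest.raises(ValueError):
            Excitation(scheme="linear", voltages=np.ones(4), phases=[5, 10, 20, 30])


class TestSuperpose:
    def test_single_channel_selects_that_field(self, small_linear_fieldset):
        exc = Excitation(scheme="linear", voltages=[1, 0, 0, 0], phases=[0, 0, 0, 0])
        assert np.array_equal(superpose(small_linear_fieldset, exc),
                              small_linear_fieldset.fields[0])

    def test_all_zero_voltages_give_zero_field(self, small_linear_fieldset):
        exc = Excitation(scheme="linear", voltages=[0, 0, 0, 0], phases=[0, 0, 0, 0])
        assert not superpose(small_linear_fieldset, exc).any()

    def test_two_field_hand_computation(self):
        f0 = np.array([[[1 + 1j, 2], [0, 1j]]])  # (C=1, 2, 2)
        f1 = np.array([[[2, -1j], [1, 1 + 0j]]])
        fields = np.stack([f0, f1])
        out = superpose_coefficients(fields, [1.0, 2.0 * np.exp(1j * np.pi / 2)])
        assert np.allclose(out, f0 + 2j * f1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_linearity_against_per_pixel_oracle(self, seed):
        rng = np.random.default_rng(seed)
        fields = rng.normal(size=(3, 2, 4, 4)) + 1j * rng.normal(size=(3, 2, 4, 4))
        c1 = rng.normal(size=3) + 1j * rng.normal(size=3)
        c2 = rng.normal(size=3) + 1j * rng.normal(size=3)
        combined = superpose_coefficients(fields, c1 + c2)
        # brute-force oracle: explicit per-pixel loop
        oracle = np.zeros((2, 4, 4), dtype=complex)
        for comp in range(2):
            for r in range(4):
                for c in range(4):
                    oracle[comp, r, c] = sum(
                        (c1[i] + c2[i]) * fields[i, comp, r, c] for i in range(3)
                    )
        assert np.allclose(combined, oracle, rtol=1e-12)
        assert np.allclose(
            combined,
            superpose_coefficients(fields, c1) + superpose_coefficients(fields, c2),
            rtol=1e-12,
        )

    def test_channel_count_mismatch_raises(self, small_linear_fieldset):
        with pytest.raises(ContractError):
            superpose_coefficients(small_linear_fieldset.fields, np.ones(3))


class TestHeatingPotential:
    def test_arithmetic(self):
        grid = GridSpec(8, 8, 1.0)
        p = homogeneous_phantom(grid, eps_r=30.0, sigma=2.0)
        e = np.zeros((1, 8, 8), dtype=complex)
        e[0, 4, 4] = 1 + 0j
        hp = heating_potential(e, p)
        assert hp.q0[4, 4] == pytest.approx(1.0)  # 0.5 * 2.0 * 1
        p144 = homogeneous_phantom(grid, sigma=1.44)
        e2 = np.zeros((2, 8, 8), dtype=complex)
        e2[0, 2, 2] = 3 + 4j
        assert heating_potential(e2, p144).q0[2, 2] == pytest.approx(18.0)

    def test_zero_conductivity_pixel_has_zero_hp(self):
        from conftest import lossless_phantom

        grid = GridSpec(8, 8, 1.0)
        e = np.ones((2, 8, 8), dtype=complex)
        assert not heating_potential(e, lossless_phantom(grid)).q0.any()

    def test_global_phase_shift_leaves_hp_unchanged(self, small_linear_fieldset,
                                                    small_phantom):
        coeff = np.exp(1j * np.deg2rad([0.0, 40.0, -60.0, -20.0]))
        base = heating_potential(
            superpose_coefficients(small_linear_fieldset.fields, coeff), small_phantom
        ).q0
        for shift in (30.0, 123.4, -270.0):
            rotated = coeff * np.exp(1j * np.deg2rad(shift))
            q0 = heating_potential(
                superpose_coefficients(small_linear_fieldset.fields, rotated),
                small_phantom,
            ).q0
            assert np.allclose(q0, base, rtol=1e-10)


class TestPower:
    def test_port_power_worked_values(self):
        assert port_power(1.0) == pytest.approx(0.02)
        assert port_power(0.0) == 0.0
        assert port_power(5.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            port_power(-1.0)

    def test_scaling_reaches_6w_for_any_vector(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            exc = Excitation(scheme="circular", voltages=rng.uniform(0.1, 9, 12),
                             phases=circular_phase_vector(rng.uniform(-180, 180, 6)))
            scaled = scale_to_total_power(exc)
            assert scaled.total_antenna_power_w() == pytest.approx(6.0, abs=1e-12)
            assert np.array_equal(scaled.phases, exc.phases)

    def test_linear_unit_voltages_scale_by_five(self):
        exc = Excitation(scheme="linear", voltages=np.ones(4), phases=np.zeros(4))
        assert exc.total_antenna_power_w() == pytest.approx(0.24)  # 12 x 0.02 W
        scaled = scale_to_total_power(exc, 6.0)
        assert np.allclose(scaled.voltages, 5.0)

    def test_already_scaled_unchanged(self):
        exc = Excitation(scheme="linear", voltages=np.ones(4) * 5.0, phases=np.zeros(4))
        scaled = scale_to_total_power(exc, 6.0)
        assert np.allclose(scaled.voltages, exc.voltages)

    def test_all_zero_raises(self):
        exc = Excitation(scheme="linear", voltages=np.zeros(4), phases=np.zeros(4))
        with pytest.raises(DegenerateExcitationError):
            scale_to_total_power(exc)


class TestNormalizeHP:
    def test_min_max_arithmetic(self):
        grid = GridSpec(8, 8, 1.0)
        q0 = np.ones((8, 8))
        q0[0, :4] = [1, 2, 3, 5]
        out = normalize_hp(HPMap(grid=grid, q0=q0))
        assert np.allclose(out.q0[0, :4], [0.0, 0.25, 0.5, 1.0])
        assert out.q0.min() == 0.0 and out.q0.max() == 1.0

    def test_already_normalized_unchanged(self):
        grid = GridSpec(8, 8, 1.0)
        q0 = np.linspace(0, 1, 64).reshape(8, 8)
        assert np.allclose(normalize_hp(HPMap(grid=grid, q0=q0)).q0, q0)

    def test_constant_map_raises(self):
        grid = GridSpec(8, 8, 1.0)
        with pytest.raises(MetricError):
            normalize_hp(HPMap(grid=grid, q0=np.ones((8, 8))))


def test_yaml_round_trip(tmp_path):
    exc = Excitation(scheme="linear", voltages=[1.25, 0.0, 3.5, 0.125],
                     phases=linear_phase_vector(-48.46, -178.10))
    path = tmp_path / "exc.yaml"
    save_excitation(exc, path)
    back = load_excitation(path)
    assert np.allclose(back.voltages, exc.voltages, atol=1e-9)
    assert np.allclose(back.phases, exc.phases, atol=1e-9)
    assert back.scheme == exc.scheme
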