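import numpy as np
import pytest

from demonsreg import (
    DisplacementField,
    Image,
    RegistrationConfig,
    check_convergence,
    energy,
    jacobian_determinant,
    make_checkerboard,
    make_pair,
    ncc,
    register,
    register_level,
    warp,
)
from demonsreg import WarpKind, WarpSpec, make_phantom
from demonsreg.exceptions import ConfigurationError, DimensionError

from oracles import energy_loop


class TestEnergy:
    def test_identical_images_have_zero_energy(self, phantom64):
        assert energy(phantom64, phantom64) == 0.0

    def test_two_by_two_arithmetic(self):
        # single differing value 2 vs 0 on a 2x2 grid: sum diff^2 = 4, /(2*4) = 0.5
        fixed = Image([[2.0, 1.0], [1.0, 1.0]])
        moving = Image([[0.0, 1.0], [1.0, 1.0]])
        assert energy(fixed, moving) == pytest.approx(0.5)

    def test_matches_loop_oracle(self, random_image):
        a, b = random_image((3, 3)), random_image((3, 3))
        assert energy(a, b) == pytest.approx(energy_loop(a.data, b.data), rel=1e-14)

    def test_shape_mismatch_raises(self):
        with pytest.raises(DimensionError):
            energy(Image(np.ones((3, 3))), Image(np.ones((4, 4))))


class TestCheckConvergence:
    def test_improvement_above_threshold_continues(self):
        assert check_convergence(99.4, 100.0, 0.005) is False  # improvement 0.6 >= 0.5

    def test_improvement_below_threshold_stops(self):
        assert check_convergence(99.6, 100.0, 0.005) is True  # improvement 0.4 < 0.5

    def test_zero_improvement_stops(self):
        assert check_convergence(50.0, 50.0, 0.005) is True

    def test_non_positive_previous_energy_treated_as_converged(self):
        assert check_convergence(0.0, 0.0, 0.005) is True

    def test_literal_form_fires_on_any_decrease(self):
        assert check_convergence(99.4, 100.0, 0.005, literal=True) is True


class TestRegisterLevel:
    def test_identical_images_converge_immediately(self, phantom64):
        v, trace = register_level(phantom64, phantom64, None, RegistrationConfig(levels=1))
        assert len(trace) <= 2
        assert trace[-1] == pytest.approx(0.0, abs=1e-12)
        assert np.abs(v.vectors).max() < 1e-6

    def test_shifted_checkerboard_recovery(self):
        fixed = make_checkerboard((64, 64), square_size=8)
        shift = DisplacementField(np.stack([np.full((64, 64), 2.0), np.zeros((64, 64))]))
        moving = warp(fixed, shift)
        result = register(fixed, moving)
        e0 = energy(fixed, moving)
        ef = energy(fixed, result.warped)
        assert ef < 0.05 * e0
        assert ncc(fixed, result.warped) > ncc(fixed, moving)

    def test_trace_non_increasing_within_tolerance(self, phantom64):
        _, moving, _ = make_pair(phantom64, WarpSpec(strength=0.4))
        _, trace = register_level(phantom64, moving, None, RegistrationConfig())
        t = np.asarray(trace)
        if len(t) > 1:
            assert np.diff(t).max() <= 0.01 * energy(phantom64, moving)
            assert t[-1] <= t[0]


class TestRegister:
    def test_single_level_matches_register_level(self, phantom64):
        _, moving, _ = make_pair(phantom64, WarpSpec(strength=0.3))
        config = RegistrationConfig(levels=1)
        result = register(phantom64, moving, config)
        v, trace = register_level(phantom64, moving, None, config)
        assert result.trace == [trace]
        np.testing.assert_array_equal(result.velocity.vectors, v.vectors)

    def test_recovery_improves_ncc_at_strength_30(self, phantom64):
        fixed, moving, _ = make_pair(phantom64, WarpSpec(strength=0.3))
        result = register(fixed, moving)
        assert result.metrics["ncc"] > ncc(fixed, moving)

    def test_final_field_is_diffeomorphic(self, phantom64):
        fixed, moving, _ = make_pair(
            phantom64, WarpSpec(kind=WarpKind.EXTRUSION, strength=0.5)
        )
        result = register(fixed, moving)
        det = jacobian_determinant(result.field)
        assert det[1:-1, 1:-1].min() > 0

    def test_adaptive_stopping_invariant(self, phantom64):
        fixed, moving, _ = make_pair(phantom64, WarpSpec(strength=0.5))
        config = RegistrationConfig()
        result = register(fixed, moving, config)
        for trace in result.trace:
            assert len(trace) <= config.max_iterations
            if len(trace) < config.max_iterations and len(trace) >= 2:
                assert check_convergence(trace[-1], trace[-2], config.stop_criterium)

    def test_deterministic_bit_identical(self, phantom64):
        fixed, moving, _ = make_pair(phantom64, WarpSpec(strength=0.5))
        r1 = register(fixed, moving)
        r2 = register(fixed, moving)
        np.testing.assert_array_equal(r1.field.vectors, r2.field.vectors)
        assert r1.trace == r2.trace

    def test_multiresolution_beats_single_level_on_large_deformation(self):
        base = make_phantom((96, 96))
        fixed, moving, _ = make_pair(base, WarpSpec(strength=0.7))
        budget = dict(max_iterations=60)
        e3 = register(fixed, moving, RegistrationConfig(levels=3, **budget)).trace[-1][-1]
        e1 = register(fixed, moving, RegistrationConfig(levels=1, **budget)).trace[-1][-1]
        assert e3 <= e1

    def test_warped_shape_matches_fixed(self, phantom64):
        fixed, moving, _ = make_pair(phantom64, WarpSpec(strength=0.3))
        result = register(fixed, moving)
        assert result.warped.shape == fixed.shape

    def test_shape_mismatch_raises(self, phantom64):
        with pytest.raises(DimensionError):
            register(phantom64, make_phantom((32, 32)))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"gaussian_sigma": 0.0},
            {"sigma_x": -1.0},
            {"levels": 0},
            {"stop_criterium": 1.5},
            {"max_iterations": 0},
            {"smooth": "nothing"},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            RegistrationConfig(**kwargs)

    def test_force_accepts_string_aliases(self):
        assert RegistrationConfig(force="thirion").force.value == "thirion"
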