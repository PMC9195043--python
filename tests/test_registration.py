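import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vertetrack.frames import FrameKind, ProjectionImage
from vertetrack.geometry import DetectorSpec, ROITemplate, Shift2D, iso_to_detector_px
from vertetrack.registration import (
    RegistrationConfig,
    brute_force_register,
    downhill_simplex_2d,
    ncc_objective,
    penalized_objective,
    register,
    translate_image,
)

from conftest import smooth_image


def _frame(pixels, kind=FrameKind.CBCT, **kw):
    return ProjectionImage(pixels=pixels, gantry_deg=180.0, kind=kind, **kw)


class TestTranslateImage:
    def test_zero_shift_is_identity(self, rng, tiny_spec):
        img = smooth_image(rng, (tiny_spec.n_rows, tiny_spec.n_cols))
        assert np.array_equal(translate_image(img, Shift2D(0, 0), tiny_spec), img)

    def test_integer_pixel_shift_is_exact_relabeling(self, rng, tiny_spec):
        img = smooth_image(rng, (tiny_spec.n_rows, tiny_spec.n_cols))
        # an iso shift equal to exactly 3 detector pixels
        from vertetrack.geometry import detector_shift_to_iso

        s = detector_shift_to_iso((3.0, 0.0), tiny_spec)
        out = translate_image(img, s, tiny_spec)
        assert np.allclose(out[:, 3:], img[:, :-3], atol=1e-9)

    def test_round_trip_within_interpolation_tolerance(self, rng, tiny_spec):
        img = smooth_image(rng, (tiny_spec.n_rows, tiny_spec.n_cols), sigma=4.0)
        d = Shift2D(1.7, -2.3)
        back = translate_image(translate_image(img, d, tiny_spec), Shift2D(-d.x, -d.y), tiny_spec)
        dynamic = img.max() - img.min()
        interior = np.abs(back - img)[4:-4, 4:-4]
        assert interior.max() < 0.01 * dynamic


class TestNCCObjective:
    def test_self_match_is_one(self, smooth_pair, tiny_spec):
        ref, roi = smooth_pair
        val = ncc_objective(ref, ref, roi, Shift2D(0, 0), tiny_spec)
        assert val == pytest.approx(1.0, abs=1e-12)

    def test_matches_double_loop_oracle_on_small_arrays(self, tiny_spec):
        rng = np.random.default_rng(5)
        a8 = rng.random((8, 8)) * 100 + 1
        b8 = rng.random((8, 8)) * 100 + 1
        ref_px = np.zeros((tiny_spec.n_rows, tiny_spec.n_cols))
        live_px = np.zeros((tiny_spec.n_rows, tiny_spec.n_cols))
        ref_px[20:28, 30:38] = a8
        live_px[20:28, 30:38] = b8
        mask = np.zeros_like(ref_px, dtype=bool)
        mask[20:28, 30:38] = True
        roi = ROITemplate(mask=mask)

        num = den_a = den_b = 0.0
        for i in range(8):
            for j in range(8):
                num += a8[i, j] * b8[i, j]
                den_a += a8[i, j] ** 2
                den_b += b8[i, j] ** 2
        expected = num / np.sqrt(den_a * den_b)

        got = ncc_objective(_frame(ref_px), _frame(live_px), roi, Shift2D(0, 0), tiny_spec)
        assert got == pytest.approx(expected, abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    def test_bounded_on_nonnegative_images(self, seed, tiny_spec):
        rng = np.random.default_rng(seed)
        shape = (tiny_spec.n_rows, tiny_spec.n_cols)
        ref = _frame(rng.random(shape) * rng.uniform(1, 1e4))
        live = _frame(rng.random(shape) * rng.uniform(1, 1e4))
        mask = np.zeros(shape, dtype=bool)
        mask[10:30, 20:50] = True
        roi = ROITemplate(mask=mask)
        shift = Shift2D(rng.uniform(-10, 10), rng.uniform(-10, 10))
        val = ncc_objective(ref, live, roi, shift, tiny_spec)
        assert 0.0 <= val <= 1.0

    def test_zero_denominator_scores_zero(self, tiny_spec):
        shape = (tiny_spec.n_rows, tiny_spec.n_cols)
        blank = _frame(np.zeros(shape))
        mask = np.zeros(shape, dtype=bool)
        mask[5:10, 5:10] = True
        assert ncc_objective(blank, blank, ROITemplate(mask=mask), Shift2D(0, 0), tiny_spec) == 0.0

    def test_agrees_with_full_frame_translation(self, smooth_pair, tiny_spec):
        """The cropped evaluation equals the literal translate-then-mask form."""
        ref, roi = smooth_pair
        live = _frame(np.roll(ref.pixels, (1, -2), axis=(0, 1)))
        for shift in (Shift2D(1.3, -0.8), Shift2D(-4.0, 2.5), Shift2D(0.0, 6.1)):
            moved = translate_image(ref.pixels, shift, tiny_spec)
            a = moved[roi.mask]
            b = live.pixels[roi.mask]
            expected = float(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            got = ncc_objective(ref, live, roi, shift, tiny_spec)
            assert got == pytest.approx(expected, abs=1e-12)


class TestPenalizedObjective:
    def test_outside_capture_range_scores_worst(self, smooth_pair, tiny_spec):
        ref, roi = smooth_pair
        cfg = RegistrationConfig(capture_range=20.0)
        assert penalized_objective(ref, ref, roi, Shift2D(25.0, 0.0), tiny_spec, cfg) == 0.0
        assert penalized_objective(ref, ref, roi, Shift2D(0.0, -20.001), tiny_spec, cfg) == 0.0

    def test_boundary_is_inside(self, smooth_pair, tiny_spec):
        ref, roi = smooth_pair
        cfg = RegistrationConfig(capture_range=20.0)
        val = penalized_objective(ref, ref, roi, Shift2D(20.0, 20.0), tiny_spec, cfg)
        assert val > 0.0

    def test_identical_images_at_zero_shift(self, smooth_pair, tiny_spec):
        ref, roi = smooth_pair
        assert penalized_objective(
            ref, ref, roi, Shift2D(0, 0), tiny_spec, RegistrationConfig()
        ) == pytest.approx(1.0, abs=1e-12)


class TestDownhillSimplex:
    def test_recovers_paraboloid_maximum(self):
        a, b = 3.7, -1.2

        def obj(s: Shift2D) -> float:
            return -((s.x - a) ** 2 + (s.y - b) ** 2)

        # the relative-spread rule cannot fire on values approaching zero,
        # so give the simplex one long uninterrupted run (no rebuilds, which
        # would reset the simplex to the initial edge length)
        best, value, converged, rebuilds = downhill_simplex_2d(
            obj, Shift2D(0, 0), RegistrationConfig(max_iter=200, max_rebuilds=0)
        )
        assert best.x == pytest.approx(a, abs=1e-3)
        assert best.y == pytest.approx(b, abs=1e-3)

    def test_paraboloid_with_default_budget_lands_close(self):
        a, b = 3.7, -1.2

        def obj(s: Shift2D) -> float:
            return -((s.x - a) ** 2 + (s.y - b) ** 2)

        best, _, _, _ = downhill_simplex_2d(obj, Shift2D(0, 0), RegistrationConfig())
        assert best.x == pytest.approx(a, abs=5e-3)
        assert best.y == pytest.approx(b, abs=5e-3)

    def test_constant_objective_stops_immediately_at_start(self):
        calls = []

        def obj(s: Shift2D) -> float:
            calls.append(s)
            return 0.5

        best, value, converged, rebuilds = downhill_simplex_2d(
            obj, Shift2D(1.0, 2.0), RegistrationConfig()
        )
        assert converged
        assert rebuilds == 0
        assert (best.x, best.y) == (1.0, 2.0)
        assert len(calls) == 3  # only the initial simplex was evaluated

    def test_monotone_improvement_over_start(self, smooth_pair, tiny_spec):
        ref, roi = smooth_pair
        live = _frame(translate_image(ref.pixels, Shift2D(2.5, -1.5), tiny_spec))
        cfg = RegistrationConfig()

        def obj(s: Shift2D) -> float:
            return penalized_objective(ref, live, roi, s, tiny_spec, cfg)

        start = Shift2D(0.0, 0.0)
        best, value, _, _ = downhill_simplex_2d(obj, start, cfg)
        assert value >= obj(start)


class TestRegister:
    def test_self_registration(self, smooth_pair, tiny_spec):
        ref, roi = smooth_pair
        res = register(ref, ref, roi, tiny_spec)
        assert abs(res.shift.x) < 1e-3
        assert abs(res.shift.y) < 1e-3
        assert res.objective == pytest.approx(1.0, abs=1e-9)

    def test_recovers_synthetic_translation(self, smooth_pair, tiny_spec):
        ref, roi = smooth_pair
        truth = Shift2D(3.0, -2.0)
        live = _frame(translate_image(ref.pixels, truth, tiny_spec), kind=FrameKind.IMR)
        res = register(ref, live, roi, tiny_spec)
        assert res.shift.x == pytest.approx(truth.x, abs=0.1)
        assert res.shift.y == pytest.approx(truth.y, abs=0.1)

    def test_deterministic_bit_identical(self, smooth_pair, tiny_spec):
        ref, roi = smooth_pair
        live = _frame(translate_image(ref.pixels, Shift2D(1.1, 0.7), tiny_spec))
        r1 = register(ref, live, roi, tiny_spec)
        r2 = register(ref, live, roi, tiny_spec)
        assert r1 == r2

    def test_warm_start_chain_is_static_under_identical_frames(self, smooth_pair, tiny_spec):
        ref, roi = smooth_pair
        live = _frame(translate_image(ref.pixels, Shift2D(2.0, 1.0), tiny_spec))
        warm = None
        shifts = []
        for _ in range(4):
            res = register(ref, live, roi, tiny_spec, warm_start=warm)
            warm = res.shift
            shifts.append((res.shift.x, res.shift.y))
        xs = [s[0] for s in shifts]
        ys = [s[1] for s in shifts]
        assert np.std(xs[1:], ddof=0) == 0.0
        assert np.std(ys[1:], ddof=0) == 0.0

    def test_result_never_exceeds_capture_range(self, smooth_pair, tiny_spec):
        ref, roi = smooth_pair
        cfg = RegistrationConfig(capture_range=5.0)
        live = _frame(translate_image(ref.pixels, Shift2D(12.0, -9.0), tiny_spec))
        res = register(ref, live, roi, tiny_spec, cfg)
        assert abs(res.shift.x) <= cfg.capture_range
        assert abs(res.shift.y) <= cfg.capture_range

    def test_objective_in_unit_interval(self, smooth_pair, tiny_spec):
        ref, roi = smooth_pair
        live = _frame(np.full_like(ref.pixels, 7.0))
        res = register(ref, live, roi, tiny_spec)
        assert 0.0 <= res.objective <= 1.0


class TestBruteForceOracle:
    def test_identical_images_argmax_at_zero(self, smooth_pair, tiny_spec):
        ref, roi = smooth_pair
        shift, _ = brute_force_register(ref, ref, roi, tiny_spec, grid_step=1.0, search_range=3.0)
        assert (shift.x, shift.y) == (0.0, 0.0)

    def test_exact_recovery_of_pixel_shift(self, smooth_pair, tiny_spec):
        from vertetrack.geometry import detector_shift_to_iso

        ref, roi = smooth_pair
        iso = detector_shift_to_iso((2.0, 0.0), tiny_spec)  # exactly 2 px
        live = _frame(translate_image(ref.pixels, iso, tiny_spec))
        step = iso.x / 2.0  # one-pixel grid step
        shift, _ = brute_force_register(
            ref, live, roi, tiny_spec, grid_step=step, search_range=4 * step
        )
        assert shift.x == pytest.approx(iso.x, abs=1e-9)
        assert shift.y == pytest.approx(0.0, abs=1e-9)

    def test_simplex_matches_grid_oracle_on_random_instances(self, tiny_spec):
        """On >=20 random smooth pairs the simplex lands within one grid step
        of the exhaustive argmax and never scores below it."""
        cfg = RegistrationConfig()
        step = 0.5
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            ref_px = smooth_image(rng, (tiny_spec.n_rows, tiny_spec.n_cols))
            truth = Shift2D(rng.uniform(-3, 3), rng.uniform(-3, 3))
            live = _frame(translate_image(ref_px, truth, tiny_spec), kind=FrameKind.IMR)
            ref = _frame(ref_px)
            mask = np.zeros_like(ref_px, dtype=bool)
            mask[12:36, 18:46] = True
            roi = ROITemplate(mask=mask)

            grid_shift, grid_val = brute_force_register(
                ref, live, roi, tiny_spec, grid_step=step, search_range=4.0
            )
            res = register(ref, live, roi, tiny_spec, cfg)
            assert res.objective >= grid_val - 1e-5
            assert abs(res.shift.x - grid_shift.x) <= step
            assert abs(res.shift.y - grid_shift.y) <= step

    def test_rejects_non_positive_step(self, smooth_pair, tiny_spec):
        ref, roi = smooth_pair
        with pytest.raises(ValueError):
            brute_force_register(ref, ref, roi, tiny_spec, grid_step=0.0)


class TestRegistrationConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"step_init": 0.0},
            {"tol": 0.0},
            {"tol": 1.5},
            {"max_iter": 0},
            {"max_rebuilds": -1},
            {"capture_range": -1.0},
            {"interpolation": "cubic"},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            RegistrationConfig(**kw)

    def test_zero_mean_variant_still_finds_translation(self, smooth_pair, tiny_spec):
        ref, roi = smooth_pair
        cfg = RegistrationConfig(zero_mean=True)
        truth = Shift2D(2.0, -1.0)
        live = _frame(translate_image(ref.pixels, truth, tiny_spec))
        res = register(ref, live, roi, tiny_spec, cfg)
        assert res.shift.x == pytest.approx(truth.x, abs=0.2)
        assert res.shift.y == pytest.approx(truth.y, abs=0.2)
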