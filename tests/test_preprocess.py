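import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mangonir.data import WavelengthGrid
from mangonir.preprocess import (
    DegenerateSpectrumError,
    OperatorSpec,
    PipelineError,
    PipelineSpec,
    enumerate_pipelines,
    fit_apply_pipeline,
    op_baseline,
    op_clip,
    op_detrend,
    op_emsc,
    op_lsnv,
    op_msc,
    op_norml,
    op_resample,
    op_rnv,
    op_savgol,
    op_smooth,
    op_snv,
    search_best,
)

finite_spectra = hnp.arrays(
    np.float64,
    st.integers(16, 64),
    elements=st.floats(-5, 5, allow_nan=False, width=32),
)


class TestScatterCorrections:
    def test_snv_hand_example(self):
        np.testing.assert_allclose(op_snv([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_snv_constant_is_degenerate(self):
        with pytest.raises(DegenerateSpectrumError):
            op_snv([5.0, 5.0, 5.0])

    @settings(deadline=None, derandomize=True)
    @given(finite_spectra)
    def test_snv_standardizes(self, x):
        if np.std(x, ddof=1) <= 1e-12:
            return
        out = op_snv(x)
        assert abs(out.mean()) < 1e-8
        assert abs(np.std(out, ddof=1) - 1) < 1e-8

    def test_rnv_hand_example(self):
        # linear-interpolated percentiles of [1,2,3]: P75=2.5, P25=1.5
        np.testing.assert_allclose(op_rnv([1.0, 2.0, 3.0], (75, 25)), [-1.0, 0.0, 1.0])

    def test_rnv_constant_is_degenerate(self):
        with pytest.raises(DegenerateSpectrumError):
            op_rnv([2.0, 2.0, 2.0])

    def test_lsnv_full_window_reduces_to_snv(self):
        x = np.sin(np.linspace(0, 3, 17))
        np.testing.assert_allclose(op_lsnv(x, window=17), op_snv(x))

    def test_lsnv_standardizes_each_window(self):
        x = np.concatenate([np.linspace(0, 1, 5), np.linspace(10, 30, 5)])
        out = op_lsnv(x, window=5)
        np.testing.assert_allclose(out[:5], op_snv(x[:5]))
        np.testing.assert_allclose(out[5:], op_snv(x[5:]))

    def test_lsnv_merges_remainder_into_last_window(self):
        x = np.random.default_rng(1).normal(size=12)
        out = op_lsnv(x, window=5)
        np.testing.assert_allclose(out[5:], op_snv(x[5:]))  # last window has 7 pts

    def test_msc_recovers_reference_from_affine_distortion(self):
        ref = np.sin(np.linspace(0, 4, 50)) + 2
        np.testing.assert_allclose(op_msc(2 * ref + 3, ref), ref, atol=1e-10)
        np.testing.assert_allclose(op_msc(ref, ref), ref, atol=1e-10)

    def test_msc_orthogonal_spectrum_is_degenerate(self):
        ref = np.array([1.0, -1.0, 1.0, -1.0])
        with pytest.raises(DegenerateSpectrumError):
            op_msc(np.ones(4), ref)

    def test_emsc_removes_quadratic_wavelength_term(self):
        wl = np.linspace(1350, 2500, 60)
        lam = 2 * (wl - wl[0]) / (wl[-1] - wl[0]) - 1
        ref = np.exp(-0.5 * ((wl - 1900) / 120) ** 2)
        x = ref + 0.1 * lam**2
        np.testing.assert_allclose(op_emsc(x, ref, wl), ref, atol=1e-9)

    def test_emsc_quadratic_only_is_degenerate(self):
        wl = np.linspace(1350, 2500, 60)
        lam = 2 * (wl - wl[0]) / (wl[-1] - wl[0]) - 1
        ref = np.exp(-0.5 * ((wl - 1900) / 120) ** 2)
        with pytest.raises(DegenerateSpectrumError):
            op_emsc(0.3 * lam**2 + 0.1, ref, wl)

    def test_norml_unit_norm(self):
        np.testing.assert_allclose(op_norml([3.0, 4.0]), [0.6, 0.8])
        with pytest.raises(DegenerateSpectrumError):
            op_norml([0.0, 0.0])


class TestBaselineOps:
    def test_detrend_kills_straight_line(self):
        wl = np.linspace(1350, 2500, 40)
        np.testing.assert_allclose(
            op_detrend(0.3 + 0.002 * wl, wl), np.zeros(40), atol=1e-9
        )

    def test_detrend_residual_orthogonal_to_line(self):
        wl = np.linspace(1350, 2500, 40)
        x = np.random.default_rng(2).normal(size=40)
        resid = op_detrend(x, wl)
        assert abs(resid.sum()) < 1e-8
        assert abs(resid @ wl) < 1e-4

    def test_baseline_centering_idempotent(self):
        x = np.array([1.0, 2.0, 6.0])
        out = op_baseline(x)
        assert abs(out.mean()) < 1e-12
        np.testing.assert_allclose(op_baseline(out), out)

    def test_clip_replaces_above_threshold(self):
        np.testing.assert_allclose(
            op_clip([1.0, 20000.0], threshold=10000.0), [1.0, 10000.0]
        )
        np.testing.assert_allclose(
            op_clip([1.0, 20000.0], threshold=10000.0, substitute=0.0), [1.0, 0.0]
        )
        np.testing.assert_allclose(op_clip([1.0, 2.0], threshold=10.0), [1.0, 2.0])


class TestSmoothingOps:
    def test_smooth_preserves_constant(self):
        np.testing.assert_allclose(op_smooth(np.full(30, 2.5), 5), np.full(30, 2.5))

    def test_smooth_impulse_response_sums_to_one(self):
        x = np.zeros(31)
        x[15] = 1.0
        out = op_smooth(x, 7)
        assert abs(out.sum() - 1.0) < 1e-10
        assert out.max() < 1.0

    def test_smooth_reduces_white_noise_variance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        assert op_smooth(x, 9).var() < x.var()

    def test_smooth_rejects_even_window(self):
        with pytest.raises(PipelineError):
            op_smooth(np.ones(10), 4)

    def test_savgol_polynomial_is_fixed_point(self):
        i = np.arange(41, dtype=float)
        x = 1 + 0.5 * i - 0.01 * i**2
        out = op_savgol(x, 7, 3, 0)
        np.testing.assert_allclose(out, x, atol=1e-8)

    def test_savgol_first_derivative_of_line(self):
        i = np.arange(41, dtype=float)
        out = op_savgol(2 + 0.25 * i, 7, 2, 1)
        np.testing.assert_allclose(out, np.full(41, 0.25), atol=1e-8)

    def test_savgol_second_derivative_of_line_is_zero(self):
        i = np.arange(41, dtype=float)
        out = op_savgol(2 + 0.25 * i, 7, 2, 2)
        np.testing.assert_allclose(out, np.zeros(41), atol=1e-8)

    @pytest.mark.parametrize("win,poly,deriv", [(4, 3, 1), (5, 5, 1), (5, 3, 4)])
    def test_savgol_rejects_bad_parameters(self, win, poly, deriv):
        with pytest.raises(PipelineError):
            op_savgol(np.ones(20), win, poly, deriv)


class TestResample:
    def test_point_count_rounds(self):
        out, _ = op_resample(np.random.default_rng(0).normal(size=136), 0.7)
        assert out.size == 95  # round(136 * 0.7)

    def test_ratio_one_is_identity_length(self, grid):
        x = np.sin(np.linspace(0, 5, 136))
        out, g = op_resample(x, 1.0, grid)
        assert out.size == 136
        assert len(g) == 136

    def test_constant_maps_to_constant(self):
        out, _ = op_resample(np.full(50, 3.0), 0.5)
        np.testing.assert_allclose(out, np.full(25, 3.0), atol=1e-10)

    def test_new_grid_spans_same_bounds(self, grid):
        _, g = op_resample(np.zeros(136), 0.7, grid)
        assert g.wavelengths[0] == grid.wavelengths[0]
        assert g.wavelengths[-1] == grid.wavelengths[-1]
        assert len(g) == 95


class TestPipeline:
    def test_empty_pipeline_is_identity(self, grid):
        X = np.random.default_rng(3).uniform(0.2, 1, (4, 136))
        out, _, fitted = fit_apply_pipeline(PipelineSpec(()), X, grid)
        np.testing.assert_array_equal(out, X)
        assert fitted.transform(X).shape == X.shape

    def test_pipeline_matches_manual_composition(self, grid):
        X = np.random.default_rng(4).uniform(0.2, 1, (3, 136))
        spec = PipelineSpec(
            (
                OperatorSpec("CLIP", {"threshold": 0.9, "substitute": None}),
                OperatorSpec("SNV"),
            )
        )
        out, _, _ = fit_apply_pipeline(spec, X, grid)
        manual = np.vstack([op_snv(op_clip(x, 0.9)) for x in X])
        np.testing.assert_allclose(out, manual)

    def test_canonical_order_is_imposed(self):
        spec = PipelineSpec((OperatorSpec("SNV"), OperatorSpec("CLIP")))
        assert spec.names() == ("CLIP", "SNV")

    def test_duplicate_operator_rejected(self):
        with pytest.raises(PipelineError):
            PipelineSpec((OperatorSpec("SNV"), OperatorSpec("SNV")))

    def test_msc_state_fitted_on_train_only(self, grid):
        rng = np.random.default_rng(5)
        train = rng.uniform(0.2, 1, (5, 136))
        test = rng.uniform(0.2, 1, (2, 136))
        spec = PipelineSpec((OperatorSpec("MSC"),))
        _, test_out, fitted = fit_apply_pipeline(spec, train, grid, test)
        np.testing.assert_allclose(fitted.reference["MSC"], train.mean(axis=0))
        manual = np.vstack([op_msc(x, train.mean(axis=0)) for x in test])
        np.testing.assert_allclose(test_out, manual)

    def test_snv_absorbs_baseline(self, grid):
        """Mean-centering before SNV changes nothing: SNV o BASELINE = SNV."""
        X = np.random.default_rng(6).uniform(0.2, 1, (3, 136))
        with_baseline = PipelineSpec((OperatorSpec("BASELINE"), OperatorSpec("SNV")))
        snv_only = PipelineSpec((OperatorSpec("SNV"),))
        a, _, _ = fit_apply_pipeline(with_baseline, X, grid)
        b, _, _ = fit_apply_pipeline(snv_only, X, grid)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_json_round_trip(self):
        spec = PipelineSpec(
            (
                OperatorSpec("CLIP", {"threshold": 10000.0, "substitute": None}),
                OperatorSpec("SAVGOL", {"filter_win": 5, "poly_order": 3, "deriv_order": 3}),
            )
        )
        assert PipelineSpec.from_json(spec.to_json()) == spec

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.data())
    def test_operators_preserve_finiteness_and_length(self, data):
        x = data.draw(
            hnp.arrays(np.float64, 30, elements=st.floats(0.015625, 2.0, width=32))
        )
        if np.percentile(x, 75) - np.percentile(x, 25) <= 1e-9:
            return
        wl = np.linspace(1350, 2500, 30)
        outputs = [
            op_snv(x),
            op_rnv(x),
            op_baseline(x),
            op_detrend(x, wl),
            op_clip(x, 1.5),
            op_smooth(x, 5),
            op_savgol(x, 5, 3, 1),
        ]
        for out in outputs:
            assert out.size == 30
            assert np.all(np.isfinite(out))


class TestEnumeration:
    def test_single_operator_gives_with_and_without(self):
        specs = enumerate_pipelines({"SNV": [{}]})
        assert len(specs) == 2  # empty pipeline + SNV

    def test_two_operators_subset_scheme(self):
        specs = enumerate_pipelines({"SNV": [{}], "BASELINE": [{}]})
        assert len(specs) == 4  # 2^2 subsets

    def test_parameter_grid_crossed_with_subsets(self):
        pools = {"RNV": [{"iqr": (75, 25)}, {"iqr": (90, 10)}], "SNV": [{}]}
        specs = enumerate_pipelines(pools)
        # {}, {SNV}, {RNV}x2, {SNV,RNV}x2
        assert len(specs) == 6

    def test_deterministic_and_deduplicated(self):
        pools = {"SNV": [{}, {}], "BASELINE": [{}]}
        specs = enumerate_pipelines(pools)
        assert len(specs) == len({s.to_json() for s in specs}) == 4

    def test_empty_pool_rejected(self):
        with pytest.raises(PipelineError):
            enumerate_pipelines({})


class TestSearch:
    def test_single_pipeline_returned_as_best(self):
        spec = PipelineSpec((OperatorSpec("SNV"),))
        results = search_best([spec], lambda s: 1.0)
        assert results[0].spec == spec and results[0].rank == 1

    def test_step_penalty_makes_empty_pipeline_win(self):
        specs = enumerate_pipelines({"SNV": [{}], "BASELINE": [{}], "NORML": [{}]})
        results = search_best(specs, lambda s: -len(s), direction="max")
        assert len(results[0].spec) == 0

    def test_planted_optimum_recovered_and_matches_brute_force(self):
        pools = {
            "SNV": [{}],
            "BASELINE": [{}],
            "SMOOTH": [{"filter_win": w, "window_type": "hamming"} for w in (5, 7)],
        }
        specs = enumerate_pipelines(pools)
        winner = PipelineSpec(
            (OperatorSpec("BASELINE"), OperatorSpec("SMOOTH", {"filter_win": 7, "window_type": "hamming"}))
        )

        def rigged(spec):
            return 100.0 if spec == winner else 50.0 - len(spec)

        results = search_best(specs, rigged, direction="max")
        assert results[0].spec == winner
        brute = max(specs, key=lambda s: (rigged(s), -len(s)))
        assert results[0].spec == brute

    def test_min_direction(self):
        specs = enumerate_pipelines({"SNV": [{}]})
        results = search_best(specs, lambda s: float(len(s)), direction="min")
        assert len(results[0].spec) == 0
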