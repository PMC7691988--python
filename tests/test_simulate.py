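"""Generator tests: geometry, photometry, determinism, FRAP model."""

import dataclasses
import math

import numpy as np
import pytest

from nucyto import (
    CellSimParams,
    FrapSimParams,
    MicropatternSpec,
    compartment_pearson,
    make_pattern_geometry,
    nc_ratio,
    read_frap_trace,
    read_tiff,
    shape_metrics,
    simulate_cell_image,
    simulate_cohort,
    simulate_frap_trace,
    write_cohort,
    write_frap_trace,
    zstack_project_sum,
)


class TestPatternGeometry:
    def test_square_1200_side_and_area(self, square_spec):
        geo = make_pattern_geometry(square_spec)
        assert geo.side_lengths_um[0] == pytest.approx(math.sqrt(1200), rel=1e-12)
        mask_area = geo.mask.sum() * square_spec.pixel_size**2
        assert mask_area == pytest.approx(1200, rel=0.02)

    @pytest.mark.parametrize("area", [500.0, 900.0, 1800.0])
    @pytest.mark.parametrize("aspect", [5.0, 8.0])
    def test_rectangle_sides_and_measured_aspect(self, area, aspect):
        spec = MicropatternSpec("rectangle", area, aspect_ratio=aspect)
        geo = make_pattern_geometry(spec)
        short, long = geo.side_lengths_um
        assert short == pytest.approx(math.sqrt(area / aspect), rel=1e-12)
        assert long == pytest.approx(aspect * short, rel=1e-12)
        measured = shape_metrics(geo.mask, spec.pixel_size)
        assert measured.aspect_ratio == pytest.approx(aspect, rel=0.05)
        assert measured.area == pytest.approx(area, rel=0.02)

    def test_degenerate_rectangle_equals_square(self):
        sq = make_pattern_geometry(MicropatternSpec("square", 900))
        rect = make_pattern_geometry(MicropatternSpec("rectangle", 900, aspect_ratio=1))
        assert np.array_equal(sq.mask, rect.mask)

    def test_pattern_too_large_for_frame_names_required_size(self, square_spec):
        with pytest.raises(ValueError, match=r"requires at least"):
            make_pattern_geometry(square_spec, frame_shape=(40, 40))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(shape="circle", area=100),
            dict(shape="square", area=-5),
            dict(shape="rectangle", area=100, aspect_ratio=0.5),
            dict(shape="square", area=100, aspect_ratio=2),
            dict(shape="square", area=100, image_margin=0),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MicropatternSpec(**kwargs)


class TestCellImage:
    def test_uniform_marker_for_free_diffusion(self, square_spec, noiseless_params):
        image, truth = simulate_cell_image(square_spec, noiseless_params)
        marker = image["marker"]
        assert marker[truth.masks.nucleus].mean() == marker[truth.masks.cytoplasm].mean()
        assert marker[~truth.masks.cell].max() == 0
        dna = image["dna"]
        assert dna[~truth.masks.nucleus].max() == 0

    def test_ground_truth_ratio_matches_rho(self, square_spec, noiseless_params):
        params = dataclasses.replace(noiseless_params, partition_coefficient=1.3)
        image, truth = simulate_cell_image(square_spec, params)
        meas = nc_ratio(image["marker"], truth.masks, background=0.0)
        assert meas.nc_ratio == pytest.approx(1.3, rel=0.01)

    def test_full_mixing_gives_affine_copy_and_unit_pearson(
        self, square_spec, noiseless_params
    ):
        params = dataclasses.replace(noiseless_params, coloc_mixing=1.0)
        image, truth = simulate_cell_image(square_spec, params)
        inside = truth.masks.cell
        ratio = image["marker2"][inside] / np.clip(image["marker"][inside], 1e-12, None)
        assert np.allclose(ratio, ratio[0])
        coloc = compartment_pearson(image["marker"], image["marker2"], truth.masks)
        assert coloc.pearson_nucleus == pytest.approx(1.0, abs=1e-9)
        assert coloc.pearson_cytoplasm == pytest.approx(1.0, abs=1e-9)

    def test_monotone_encoding_of_partition_coefficient(self, square_spec, noiseless_params):
        ratios = []
        for rho in (0.5, 0.8, 1.0, 1.3, 2.0, 4.0):
            params = dataclasses.replace(noiseless_params, partition_coefficient=rho)
            image, truth = simulate_cell_image(square_spec, params)
            marker = image["marker"]
            ratios.append(
                marker[truth.masks.nucleus].mean() / marker[truth.masks.cytoplasm].mean()
            )
        assert np.all(np.diff(ratios) > 0)

    def test_seed_determinism(self, square_spec):
        params = CellSimParams(seed=42, coloc_mixing=0.3)
        a, _ = simulate_cell_image(square_spec, params)
        b, _ = simulate_cell_image(square_spec, params)
        for name in a.channels:
            assert np.array_equal(a[name], b[name])

    def test_zstack_planes_sum_to_single_plane_expectation(
        self, square_spec, noiseless_params
    ):
        params = dataclasses.replace(
            noiseless_params, zstack=True, partition_coefficient=1.3
        )
        image, truth = simulate_cell_image(square_spec, params)
        assert image["marker"].ndim == 3 and image["marker"].shape[0] == 5
        projected = zstack_project_sum(image["marker"])
        single, _ = simulate_cell_image(
            square_spec, dataclasses.replace(params, zstack=False)
        )
        assert np.allclose(projected, single["marker"])
        meas = nc_ratio(projected, truth.masks, background=0.0)
        assert meas.nc_ratio == pytest.approx(1.3, rel=0.01)

    def test_blur_keeps_total_marker_intensity(self, square_spec, noiseless_params):
        sharp, _ = simulate_cell_image(square_spec, noiseless_params)
        blurred, _ = simulate_cell_image(
            square_spec, dataclasses.replace(noiseless_params, blur_sigma=0.8)
        )
        assert blurred["marker"].sum() == pytest.approx(sharp["marker"].sum(), rel=1e-6)


class TestCohort:
    def test_counts_and_distinct_seeds(self, square_spec, rect5_spec):
        cells = simulate_cohort(
            {"sq": square_spec, "re": rect5_spec}, 50, CellSimParams(), master_seed=5
        )
        assert len(cells) == 100
        assert len({c.seed for c in cells}) == 100
        assert sorted({c.geometry_label for c in cells}) == ["re", "sq"]

    def test_same_master_seed_is_bitwise_identical(self, square_spec):
        kwargs = dict(n_per_geometry=3, params=CellSimParams(), master_seed=9)
        a = simulate_cohort({"sq": square_spec}, **kwargs)
        b = simulate_cohort({"sq": square_spec}, **kwargs)
        for ca, cb in zip(a, b):
            assert ca.seed == cb.seed
            for name in ca.image.channels:
                assert np.array_equal(ca.image[name], cb.image[name])

    def test_rho_by_geometry_orders_recovered_medians(self, square_spec, rect5_spec):
        cells = simulate_cohort(
            {"sq": square_spec, "re": rect5_spec},
            15,
            CellSimParams(),
            rho_by_geometry={"sq": 1.3, "re": 1.0},
            master_seed=2,
        )
        ratios = {"sq": [], "re": []}
        for c in cells:
            meas = nc_ratio(c.image["marker"], c.truth.masks)
            ratios[c.geometry_label].append(meas.nc_ratio)
        assert np.median(ratios["sq"]) > np.median(ratios["re"])

    def test_empty_geometry_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort({}, 5, CellSimParams())

    def test_cohort_roundtrips_through_tiff(self, square_spec, tmp_path):
        cells = simulate_cohort({"sq": square_spec}, 2, CellSimParams(), master_seed=3)
        manifest = write_cohort(cells, tmp_path)
        assert manifest.exists()
        back = read_tiff(tmp_path / f"{cells[0].cell_id}.tiff")
        assert back.pixel_size == pytest.approx(square_spec.pixel_size)
        assert np.allclose(back["marker"], cells[0].image["marker"], atol=1e-4)


class TestFrapSimulation:
    def test_symmetric_rates_equalise_pools_at_long_times(self):
        trace = simulate_frap_trace(
            FrapSimParams(k_in=0.1, k_out=0.1, duration=300.0)
        )
        assert trace.nuclear_intensity[-1] == pytest.approx(
            trace.cytoplasmic_intensity[-1], rel=1e-6
        )

    def test_full_nuclear_bleach_matches_closed_form(self):
        p = FrapSimParams(k_in=0.03, k_out=0.07, bleach_residual=0.0)
        trace = simulate_frap_trace(p)
        post = trace.time >= 0
        t = trace.time[post]
        k = p.k_in + p.k_out
        total = p.k_out / k  # only the cytoplasmic pool survives the bleach
        expected = total * p.k_in / k * (1 - np.exp(-k * t))
        assert trace.nuclear_intensity[trace.bleach_index] == 0.0
        np.testing.assert_allclose(trace.nuclear_intensity[post], expected, rtol=1e-6, atol=1e-12)

    @pytest.mark.parametrize("target", ["nucleus", "cytoplasm"])
    def test_total_fluorescence_conserved_after_bleach(self, target):
        trace = simulate_frap_trace(
            FrapSimParams(k_in=0.04, k_out=0.09, bleach_target=target, bleach_residual=0.2)
        )
        post = trace.time >= 0
        total = trace.nuclear_intensity[post] + trace.cytoplasmic_intensity[post]
        np.testing.assert_allclose(total, total[0], rtol=1e-12)

    def test_no_exchange_warns_and_returns_flat_trace(self):
        with pytest.warns(UserWarning, match="no recovery"):
            trace = simulate_frap_trace(FrapSimParams(k_in=0.0, k_out=0.0))
        post = trace.time >= 0
        assert np.ptp(trace.nuclear_intensity[post]) == 0.0

    def test_noise_seed_determinism(self):
        p = FrapSimParams(k_in=0.05, k_out=0.05, trace_noise_sigma=0.02, seed=7)
        a, b = simulate_frap_trace(p), simulate_frap_trace(p)
        assert np.array_equal(a.nuclear_intensity, b.nuclear_intensity)

    def test_trace_roundtrips_through_csv(self, tmp_path):
        trace = simulate_frap_trace(
            FrapSimParams(k_in=0.05, k_out=0.02, trace_noise_sigma=0.01, seed=3)
        )
        path = write_frap_trace(trace, tmp_path / "trace.csv")
        back = read_frap_trace(path)
        np.testing.assert_array_equal(back.time, trace.time)
        np.testing.assert_array_equal(back.nuclear_intensity, trace.nuclear_intensity)
        assert back.bleach_index == trace.bleach_index
        assert back.bleach_target == trace.bleach_target
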