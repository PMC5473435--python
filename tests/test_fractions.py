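import numpy as np
import pytest

import specfrac as sf


def _two_maps(i1, i2, background=None):
    i1 = np.asarray(i1, dtype=float)
    i2 = np.asarray(i2, dtype=float)
    bg = np.zeros(i1.shape, dtype=bool) if background is None else background
    return sf.AbundanceMaps(np.stack([i1, i2]), ["apolar", "polar"],
                            bg, np.zeros(i1.shape, dtype=bool))


class TestFractionMap:
    def test_pointwise_examples(self):
        maps = _two_maps([[5.0, 3.0, 0.0]], [[5.0, 0.0, 0.0]])
        fmap = sf.fraction_map(maps)
        assert fmap.fraction[0, 0] == pytest.approx(0.5)
        assert fmap.fraction[0, 1] == pytest.approx(1.0)
        assert not fmap.defined[0, 2] and np.isnan(fmap.fraction[0, 2])

    def test_fractions_sum_to_one_everywhere_defined(self):
        rng = np.random.default_rng(0)
        i1 = rng.uniform(0, 100, (50, 50))
        i2 = rng.uniform(0, 100, (50, 50))
        i1[:5] = 0.0
        i2[:5] = 0.0
        maps = _two_maps(i1, i2)
        fmap = sf.fraction_map(maps)
        d = fmap.defined
        f2 = i2[d] / (i1[d] + i2[d])
        assert np.all(np.abs(fmap.fraction[d] + f2 - 1.0) <= 1e-12)

    def test_background_masked_pixels_undefined(self):
        bg = np.array([[True, False]])
        maps = _two_maps([[4.0, 4.0]], [[4.0, 4.0]], background=bg)
        fmap = sf.fraction_map(maps)
        assert not fmap.defined[0, 0]
        assert fmap.defined[0, 1]

    def test_requires_two_components(self, small_cell_scene, refs4, grid29):
        stack, _ = sf.make_two_dye_scene(grid29, refs4, seed=1, shape=(96, 96))
        maps = sf.unmix_fixed(stack, refs4, sf.UnmixParams(n_iterations=5))
        with pytest.raises(ValueError):
            sf.fraction_map(maps)
        # a two-component view of the same result is accepted
        assert sf.fraction_map(maps.pair(0, 1)).fraction.shape == (96, 96)


class TestGp:
    @pytest.mark.parametrize("frac,gp", [(0.5, 0.0), (1.0, 1.0), (0.0, -1.0),
                                         (0.75, 0.5)])
    def test_fraction_to_gp_values(self, frac, gp):
        assert sf.fraction_to_gp(frac) == pytest.approx(gp)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sf.fraction_to_gp(1.5)
        with pytest.raises(ValueError):
            sf.fraction_to_gp(np.array([0.2, -0.1]))

    def test_two_channel_gp_examples(self, grid17):
        counts = np.zeros((17, 1, 2))
        counts[2, 0, 0] = 3.0   # blue channel
        counts[7, 0, 0] = 1.0   # green channel
        counts[2, 0, 1] = 2.0
        counts[7, 0, 1] = 2.0
        stack = sf.LambdaStack(counts, grid17)
        gp = sf.gp_map_from_channels(stack, 2, 7)
        assert gp[0, 0] == pytest.approx(0.5)
        assert gp[0, 1] == pytest.approx(0.0)

    def test_identical_indices_rejected(self, uniform_stack):
        with pytest.raises(ValueError):
            sf.gp_map_from_channels(uniform_stack, 3, 3)

    def test_gp_equals_affine_fraction_route(self, grid17):
        # the two-channel GP and 2*fraction-1 on the same channels agree
        rng = np.random.default_rng(1)
        counts = np.zeros((17, 20, 20))
        counts[2] = rng.uniform(0, 50, (20, 20))
        counts[7] = rng.uniform(0, 50, (20, 20))
        stack = sf.LambdaStack(counts, grid17)
        gp = sf.gp_map_from_channels(stack, 2, 7)
        maps = _two_maps(counts[2], counts[7])
        frac = sf.fraction_map(maps)
        d = frac.defined
        assert np.all(np.abs(gp[d] - (2 * frac.fraction[d] - 1)) <= 1e-12)


class TestDiscreteLUT:
    def test_default_bin_edges(self):
        lut = sf.DiscreteLUT.six_colours_233332()
        assert np.allclose(lut.edges,
                           [0, 2 / 16, 5 / 16, 8 / 16, 11 / 16, 14 / 16, 1.0])

    def test_binning_is_exhaustive_and_exclusive(self):
        lut = sf.DiscreteLUT.six_colours_233332()
        f = np.linspace(0, 1, 1001)
        bins = lut.bin_index(f)
        assert bins.min() == 0 and bins.max() == 5
        # half-open bins: an edge value belongs to the upper bin ...
        assert lut.bin_index(2 / 16) == 1
        # ... except 1.0, which closes the last bin
        assert lut.bin_index(1.0) == 5
        assert lut.bin_index(np.nextafter(2 / 16, 0)) == 0

    def test_file_roundtrip(self, tmp_path):
        lut = sf.DiscreteLUT.six_colours_233332()
        p = tmp_path / "six.lut"
        lut.to_file(p)
        again = sf.DiscreteLUT.from_file(p)
        assert again == lut

    def test_invalid_lut_rejected(self):
        with pytest.raises(ValueError):
            sf.DiscreteLUT(colours=((0, 0, 0),), bin_widths=(1, 2))
        with pytest.raises(ValueError):
            sf.DiscreteLUT(colours=((0, 0, 300),), bin_widths=(1,))


class TestColorize:
    def test_zero_total_is_black_and_full_total_is_pure_colour(self):
        lut = sf.DiscreteLUT.six_colours_233332()
        maps = _two_maps([[0.0, 1.0]], [[0.0, 9.0]])  # fraction 0.1 -> first bin
        fmap = sf.fraction_map(maps)
        rgb = sf.colorize_fraction(fmap, lut, intensity_ceiling=10.0)
        assert tuple(rgb[0, 0]) == (0, 0, 0)
        assert tuple(rgb[0, 1]) == lut.colours[0]

    def test_intensity_scales_colour(self):
        lut = sf.DiscreteLUT.six_colours_233332()
        maps = _two_maps([[1.0]], [[9.0]])
        fmap = sf.fraction_map(maps)
        rgb = sf.colorize_fraction(fmap, lut, intensity_ceiling=20.0)
        assert tuple(rgb[0, 0]) == tuple(np.rint(np.array(lut.colours[0]) * 0.5)
                                         .astype(int))

    def test_all_undefined_warns(self):
        maps = _two_maps([[0.0]], [[0.0]])
        fmap = sf.fraction_map(maps)
        with pytest.warns(UserWarning):
            rgb = sf.colorize_fraction(fmap)
        assert np.all(rgb == 0)


class TestIntensityHistogram:
    def test_single_pixel(self):
        maps = _two_maps([[3.0]], [[4.0]])
        hist, *_ = sf.intensity_histogram_2d(maps, n_bins=8)
        assert hist.sum() == 1
        assert (hist == 1).sum() == 1

    def test_uniform_image_one_bin(self):
        maps = _two_maps(np.full((6, 6), 2.0), np.full((6, 6), 5.0))
        hist, *_ = sf.intensity_histogram_2d(maps, n_bins=4)
        assert hist.max() == 36 and hist.sum() == 36

    @pytest.mark.parametrize("scale", ["linear", "log"])
    def test_count_conservation_after_masking(self, scale):
        rng = np.random.default_rng(2)
        i1 = rng.uniform(0, 10, (30, 30))
        i2 = rng.uniform(0, 10, (30, 30))
        bg = rng.uniform(size=(30, 30)) < 0.3
        maps = _two_maps(i1, i2, background=bg)
        hist, *_ = sf.intensity_histogram_2d(maps, n_bins=16, scale=scale)
        assert hist.sum() == (~bg).sum()

    def test_invalid_bins(self):
        maps = _two_maps([[1.0]], [[1.0]])
        with pytest.raises(ValueError):
            sf.intensity_histogram_2d(maps, n_bins=1)


class TestGate:
    def _toy(self):
        i1 = np.array([[1.0, 5.0, 9.0]])
        i2 = np.array([[1.0, 5.0, 9.0]])
        return _two_maps(i1, i2)

    def test_bounding_rectangle_covers_everything(self):
        maps = self._toy()
        gate = sf.Gate(vertices=((1, 1), (9, 1), (9, 9), (1, 9)))
        fmap = sf.fraction_map(maps)
        _, mask = sf.gate_to_image(maps, gate, fmap)
        assert mask.all()  # boundary counts as inside

    def test_gate_far_from_data_is_empty(self):
        maps = self._toy()
        gate = sf.Gate(vertices=((100, 100), (200, 100), (200, 200)))
        fmap = sf.fraction_map(maps)
        rgb, mask = sf.gate_to_image(maps, gate, fmap)
        assert not mask.any()
        assert np.all(rgb == 0)

    def test_membership_matches_hand_point_in_polygon(self):
        # rectangle x in [0,6], y in [0,6]: pixels (1,1) and (5,5) inside,
        # (9,9) outside — by hand
        maps = self._toy()
        gate = sf.Gate(vertices=((0, 0), (6, 0), (6, 6), (0, 6)))
        fmap = sf.fraction_map(maps)
        _, mask = sf.gate_to_image(maps, gate, fmap)
        assert mask[0, 0] and mask[0, 1] and not mask[0, 2]

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            sf.Gate(vertices=((0, 0), (1, 1)))
        with pytest.raises(ValueError):
            sf.Gate(vertices=((0, 0), (1, 1), (2, 2)))  # zero area
        with pytest.raises(ValueError):
            sf.Gate(vertices=((0, 0), (1, 1), (1, 0), (0, 1)))  # self-crossing


class TestEndToEndPhantom:
    def test_noiseless_cell_phantom_fraction_recovery(self, small_cell_scene, refs2):
        stack, phantom = small_cell_scene
        maps = sf.unmix_fixed(stack, refs2, sf.UnmixParams(n_iterations=200))
        fmap = sf.fraction_map(maps)
        pm = phantom.compartment_mask("plasma_membrane")
        cyto = phantom.compartment_mask("cytoplasm")
        assert np.nanmedian(fmap.fraction[pm]) == pytest.approx(0.75, abs=0.01)
        assert np.nanmedian(fmap.fraction[cyto]) == pytest.approx(0.30, abs=0.01)
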