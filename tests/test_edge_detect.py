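import numpy as np
import pytest
from scipy import ndimage

from tubewidth.edge_detect import (
    NEIGHBOUR_OFFSETS,
    SOBEL_X,
    SOBEL_Y,
    EdgeComponent,
    extract_components,
    hysteresis_binarize,
    keep_longest_two,
    nonmax_suppress,
    quantize_orientation,
    sobel_gradients,
)
from tubewidth.errors import DimensionError, InsufficientEdgesError, ParameterError


class TestSobel:
    def test_kernels_as_specified(self):
        assert np.array_equal(SOBEL_X, [[-2, 0, 2], [-3, 0, 3], [-2, 0, 2]])
        assert np.array_equal(SOBEL_Y, SOBEL_X.T)

    def test_constant_image_zero_gradient(self):
        f = sobel_gradients(np.full((10, 10), 50, dtype=np.uint8))
        assert np.all(f.magnitude == 0)

    def test_horizontal_ramp(self):
        # I(r, c) = c: interior Ix = (2+3+2) * 2 = 14, Iy = 0
        img = np.tile(np.arange(20, dtype=np.uint8), (10, 1))
        f = sobel_gradients(img)
        assert np.allclose(f.ix[2:-2, 2:-2], 14)
        assert np.allclose(f.iy[2:-2, 2:-2], 0)
        # gradient along +x -> bearing 90 deg from the +y axis
        assert np.allclose(f.theta[2:-2, 2:-2], 90.0)

    def test_magnitude_is_euclidean(self, rng):
        img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        f = sobel_gradients(img)
        assert np.allclose(f.magnitude**2, f.ix**2 + f.iy**2, rtol=1e-6)

    def test_too_small_image_rejected(self):
        with pytest.raises(DimensionError):
            sobel_gradients(np.zeros((2, 5), dtype=np.uint8))


class TestQuantizeOrientation:
    @pytest.mark.parametrize("theta, bucket, triple", [
        (30.0, 45, ("P7", "P1", "P3")),
        (0.0, 0, ("P2", "P1", "P6")),
        (90.0, 90, ("P8", "P1", "P4")),
        (130.0, 135, ("P9", "P1", "P5")),
        (22.5, 45, ("P7", "P1", "P3")),    # boundary goes to the higher bucket
        (67.5, 90, ("P8", "P1", "P4")),
        (157.5, 0, ("P2", "P1", "P6")),
        (359.0, 0, ("P2", "P1", "P6")),
    ])
    def test_buckets(self, theta, bucket, triple):
        assert quantize_orientation(theta) == (bucket, triple)

    def test_periodic_mod_180(self):
        for theta in np.linspace(0, 179.9, 73):
            assert quantize_orientation(theta) == quantize_orientation((theta + 180) % 360)

    def test_triples_are_opposite_offsets(self):
        for _, (pa, centre, pb) in (quantize_orientation(t) for t in (0, 45, 90, 135)):
            assert centre == "P1"
            da, db = NEIGHBOUR_OFFSETS[pa], NEIGHBOUR_OFFSETS[pb]
            assert da[0] == -db[0] and da[1] == -db[1]

    def test_rejects_out_of_range(self):
        with pytest.raises(ParameterError):
            quantize_orientation(360.0)


def _field_from(mag, theta):
    from tubewidth.edge_detect import GradientField

    return GradientField(ix=np.zeros_like(mag), iy=np.zeros_like(mag),
                         magnitude=np.asarray(mag, dtype=float),
                         theta=np.full(np.shape(mag), float(theta)))


class TestNonmaxSuppress:
    def test_ideal_ridge_survives(self):
        mag = np.zeros((7, 7))
        mag[:, 3] = 5.0  # vertical ridge; gradient across it -> theta 90
        out = nonmax_suppress(_field_from(mag, 90.0))
        assert np.array_equal(out, mag)

    def test_three_pixel_ridge_keeps_centre(self):
        mag = np.zeros((7, 9))
        mag[:, 3], mag[:, 4], mag[:, 5] = 1.0, 2.0, 1.0
        out = nonmax_suppress(_field_from(mag, 90.0))
        assert np.all(out[:, 4] == 2.0)
        assert np.all(out[:, [3, 5]] == 0)

    def test_plateau_survives_on_ties(self):
        mag = np.full((6, 6), 3.0)
        out = nonmax_suppress(_field_from(mag, 90.0))
        assert np.array_equal(out, mag)

    def test_never_increases_and_zeroes_dominated(self, rng):
        mag = rng.random((20, 20)) * 10
        theta = rng.random((20, 20)) * 360
        from tubewidth.edge_detect import GradientField

        field = GradientField(ix=np.zeros_like(mag), iy=np.zeros_like(mag),
                              magnitude=mag, theta=theta)
        out = nonmax_suppress(field)
        assert np.all(out <= mag)
        assert np.all((out == mag) | (out == 0))


def _hysteresis_oracle(s, z1, z2):
    """Independent oracle: label non-zero pixels, keep components holding a
    strong pixel; output strong pixels plus reachable weak ones."""
    nonzero = s > 0
    labels, _ = ndimage.label(nonzero, structure=np.ones((3, 3), dtype=int))
    strong = s > z2
    good = set(np.unique(labels[strong])) - {0}
    reach = np.isin(labels, sorted(good))
    weak = (s >= z1) & ~strong & nonzero
    return (strong | (weak & reach)).astype(np.uint8)


class TestHysteresis:
    def test_isolated_strong_pixel_kept(self):
        s = np.zeros((5, 5))
        s[2, 2] = 11
        assert hysteresis_binarize(s, 5, 10)[2, 2] == 1

    def test_isolated_subweak_pixel_dropped(self):
        s = np.zeros((5, 5))
        s[2, 2] = 4
        assert hysteresis_binarize(s, 5, 10)[2, 2] == 0

    def test_weak_chain_promoted_only_with_strong_anchor(self):
        s = np.zeros((3, 10))
        s[1, 1:4] = [6, 7, 11]  # weak-weak-strong
        s[1, 6:9] = [6, 7, 8]   # isolated weak chain
        out = hysteresis_binarize(s, 5, 10)
        assert np.all(out[1, 1:4] == 1)
        assert np.all(out[1, 6:9] == 0)

    def test_rejects_bad_thresholds(self):
        with pytest.raises(ParameterError):
            hysteresis_binarize(np.zeros((3, 3)), 5, 5)

    def test_matches_connectivity_oracle_on_random_maps(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            s = rng.random((32, 32)) * 10
            s[rng.random((32, 32)) < 0.6] = 0.0
            z1, z2 = 3.0, 7.0
            assert np.array_equal(hysteresis_binarize(s, z1, z2),
                                  _hysteresis_oracle(s, z1, z2))


def _flood_fill_components(binary):
    """Independent flood-fill oracle for 8-connected components."""
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    h, w = binary.shape
    for r in range(h):
        for c in range(w):
            if binary[r, c] and not seen[r, c]:
                stack = [(r, c)]
                seen[r, c] = True
                comp = []
                while stack:
                    rr, cc = stack.pop()
                    comp.append((rr, cc))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            r2, c2 = rr + dr, cc + dc
                            if 0 <= r2 < h and 0 <= c2 < w and binary[r2, c2] and not seen[r2, c2]:
                                seen[r2, c2] = True
                                stack.append((r2, c2))
                comps.append(frozenset(comp))
    return set(comps)


class TestComponents:
    def test_two_segments_sorted_by_length(self):
        img = np.zeros((5, 20), dtype=np.uint8)
        img[1, 0:10] = 1
        img[3, 0:4] = 1
        comps = extract_components(img)
        assert [c.length for c in comps] == [10, 4]

    def test_single_pixel(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        img[2, 2] = 1
        comps = extract_components(img)
        assert len(comps) == 1 and comps[0].length == 1

    def test_empty_image(self):
        assert extract_components(np.zeros((4, 4), dtype=np.uint8)) == []

    def test_matches_flood_fill_oracle(self, rng):
        img = (rng.random((24, 24)) < 0.2).astype(np.uint8)
        comps = extract_components(img)
        got = {frozenset(map(tuple, c.pixels)) for c in comps}
        assert got == _flood_fill_components(img)


class TestKeepLongestTwo:
    # walls must sit farther apart than the ~6 px intra-wall gap bridging
    def _comps(self, *segments, shape=(40, 30)):
        img = np.zeros(shape, dtype=np.uint8)
        for row, c0, c1 in segments:
            img[row, c0:c1] = 1
        return extract_components(img), img

    def test_keeps_two_longest(self):
        comps, _ = self._comps((1, 0, 20), (15, 0, 15), (30, 0, 3))
        out = keep_longest_two(comps, (40, 30))
        assert out[1].sum() == 20 and out[15].sum() == 15 and out[30].sum() == 0

    def test_two_components_identity(self):
        comps, img = self._comps((2, 0, 9), (20, 0, 5))
        assert np.array_equal(keep_longest_two(comps, (40, 30)), img)

    def test_length_ties_broken_by_start_coordinate(self):
        comps, _ = self._comps((30, 0, 5), (1, 0, 5), (15, 0, 5))
        out = keep_longest_two(comps, (40, 30))
        assert out[1].sum() == 5 and out[15].sum() == 5 and out[30].sum() == 0

    def test_manual_override(self):
        comps, _ = self._comps((1, 0, 20), (15, 0, 15), (30, 0, 3))
        out = keep_longest_two(comps, (40, 30), manual_indices=(0, 2))
        assert out[1].sum() == 20 and out[30].sum() == 3 and out[15].sum() == 0

    def test_too_few_components_raises(self):
        comps, _ = self._comps((1, 0, 20))
        with pytest.raises(InsufficientEdgesError):
            keep_longest_two(comps, (40, 30))

    def test_intra_wall_break_not_counted_as_extra_edge(self):
        """A wall severed by a few missing pixels still counts as one wall:
        the kept pair is the broken wall (both pieces) plus the other wall,
        not the two pieces of one wall."""
        comps, img = self._comps((1, 0, 12), (1, 16, 30), (20, 0, 30))
        out = keep_longest_two(comps, (40, 30))
        assert np.array_equal(out, img)


def test_full_edge_stage_on_rectangle_yields_two_flanking_components():
    """A filled rectangle's long sides are the two longest edges."""
    from tubewidth.preprocess import equalize_histogram, gaussian_smooth

    img = np.zeros((120, 200), dtype=np.uint8)
    img[40:80, :] = 255  # band crossing the full frame
    sm = gaussian_smooth(equalize_histogram(img))
    f = sobel_gradients(sm)
    sup = nonmax_suppress(f)
    smax = sup.max()
    binary = hysteresis_binarize(sup, 0.08 * smax, 0.20 * smax)
    comps = extract_components(binary)
    assert len(comps) == 2
    rows0 = set(comps[0].pixels[:, 0].tolist())
    rows1 = set(comps[1].pixels[:, 0].tolist())
    assert (max(rows0) < 60) != (max(rows1) < 60)  # one above, one below
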