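"""Quantization, texture matrices and feature formulas.

Hand-computed values anchor the small cases; seeded random 4x4x4 grids are
checked against the brute-force enumeration oracles in conftest.
"""

import numpy as np
import pytest

from petradiomics.features import (FeatureConfig, code_similarity, extract_all,
                                   first_order_features, glcm_features, lilre,
                                   lilze, ngtdm_coarseness, run_percentage,
                                   suv_peak)
from petradiomics.matrices import (DIRECTIONS_13, glcm_build, glrlm_build,
                                   glszm_build, ngtdm_build, texture_codes)
from petradiomics.quantization import quantize
from petradiomics.segmentation import segment_isocontour
from petradiomics.synthetic import PhantomSpec, generate_phantom

from conftest import (line_voi, make_mask, make_volume, oracle_codes,
                      oracle_glcm, oracle_glrlm, oracle_ngtdm, oracle_zones)


class TestQuantize:
    def test_formula_values(self):
        # vmin=2, vmax=10, B=4: 2 -> 1, 6 -> 3, 10 -> 4
        vol = make_volume(np.array([2.0, 6.0, 10.0]).reshape(3, 1, 1))
        mask = make_mask(np.ones((3, 1, 1), bool))
        q = quantize(vol, mask, n_bins=4)
        assert q.voxel_levels.tolist() == [1, 3, 4]

    def test_constant_voi_maps_to_level_one(self):
        vol = make_volume(np.full((2, 2, 2), 7.0))
        q = quantize(vol, make_mask(np.ones((2, 2, 2), bool)), n_bins=64)
        assert (q.voxel_levels == 1).all()

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        data = rng.random((4, 4, 4)) * 10
        mask = make_mask(rng.random((4, 4, 4)) < 0.8)
        q1 = quantize(make_volume(data), mask)
        q2 = quantize(make_volume(3.7 * data + 1.2), mask)
        assert np.array_equal(q1.levels, q2.levels)

    def test_range_spans_bins(self):
        rng = np.random.default_rng(1)
        vol = make_volume(rng.random((5, 5, 5)))
        q = quantize(vol, make_mask(np.ones((5, 5, 5), bool)), n_bins=8)
        assert q.voxel_levels.min() == 1 and q.voxel_levels.max() == 8

    def test_too_few_bins_rejected(self):
        vol = make_volume(np.ones((2, 2, 2)))
        with pytest.raises(ValueError, match="bins"):
            quantize(vol, make_mask(np.ones((2, 2, 2), bool)), n_bins=1)


class TestFirstOrder:
    def test_symmetric_values(self):
        vol = make_volume(np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1))
        f = first_order_features(vol, make_mask(np.ones((3, 1, 1), bool)))
        assert f["SUVmean"] == 2.0 and f["SUVmax"] == 3.0
        assert f["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_moments(self):
        # {0,0,0,4}: m2=3, m3=6 => skewness = 6/3^1.5 = 2/sqrt(3)
        vol = make_volume(np.array([0.0, 0.0, 0.0, 4.0]).reshape(4, 1, 1))
        f = first_order_features(vol, make_mask(np.ones((4, 1, 1), bool)))
        assert f["skewness"] == pytest.approx(2 / np.sqrt(3))

    def test_constant_voi_undefined_shape_stats(self):
        vol = make_volume(np.full((3, 1, 1), 2.0))
        with pytest.warns(UserWarning, match="zero-variance"):
            f = first_order_features(vol, make_mask(np.ones((3, 1, 1), bool)))
        assert np.isnan(f["skewness"]) and np.isnan(f["kurtosis"])


class TestSUVPeak:
    def test_coarse_spacing_single_voxel_sphere(self):
        rng = np.random.default_rng(2)
        vol = make_volume(rng.random((4, 4, 4)), spacing=(15, 15, 15))
        mask = make_mask(np.ones((4, 4, 4), bool), spacing=(15, 15, 15))
        assert suv_peak(vol, mask) == vol.data.max()

    def test_uniform_voi(self):
        vol = make_volume(np.full((6, 6, 6), 4.2), spacing=(3, 3, 3))
        mask = make_mask(np.ones((6, 6, 6), bool), spacing=(3, 3, 3))
        assert suv_peak(vol, mask) == pytest.approx(4.2)

    def test_against_brute_force_sphere_placement(self):
        rng = np.random.default_rng(3)
        data = rng.random((5, 5, 5))
        data[:2, :2, :2] += 5.0  # hot corner
        spacing = (5.0, 5.0, 5.0)
        vol = make_volume(data, spacing=spacing)
        mask = make_mask(np.ones((5, 5, 5), bool), spacing=spacing)
        radius = 10.0 * (3.0 / (4 * np.pi)) ** (1 / 3)
        best = -np.inf
        for c in np.ndindex(data.shape):
            vals = []
            for v in np.ndindex(data.shape):
                d = np.sqrt(sum(((a - b) * s) ** 2 for a, b, s in zip(c, v, spacing)))
                if d <= radius:
                    vals.append(data[v])
            best = max(best, float(np.mean(vals)))
        assert suv_peak(vol, mask) == pytest.approx(best)


class TestRunLength:
    def test_hand_run_enumeration(self):
        q = line_voi([1, 1, 2, 2, 2, 1])
        m = glrlm_build(q, directions=((1, 0, 0),))
        assert m.counts[0, 0] == 1   # level 1, length 1
        assert m.counts[0, 1] == 1   # level 1, length 2
        assert m.counts[1, 2] == 1   # level 2, length 3
        assert m.n_runs == 3
        assert run_percentage(m) == 0.5
        assert lilre(m) == pytest.approx(7.25 / 3)

    def test_constant_segment_single_run(self):
        q = line_voi([2] * 7)
        m = glrlm_build(q, directions=((1, 0, 0),))
        assert m.counts[1, 6] == 1 and m.n_runs == 1
        assert run_percentage(m) == pytest.approx(1 / 7)

    def test_single_low_level_run_lilre_is_length_squared(self):
        q = line_voi([1] * 9)
        m = glrlm_build(q, directions=((1, 0, 0),))
        assert lilre(m) == pytest.approx(81.0)

    def test_all_distinct_levels_all_runs_length_one(self):
        # no two collinear neighbours share a level => every run has length 1
        lv = np.arange(1, 65, dtype=np.int64).reshape(4, 4, 4)
        from petradiomics.quantization import QuantizedVOI
        q = QuantizedVOI(levels=lv, mask=np.ones((4, 4, 4), bool),
                         n_bins=64, vmin=1, vmax=64)
        m = glrlm_build(q)
        assert run_percentage(m) == 1.0

    def test_intensity_flip_decreases_lilre_for_long_low_runs(self):
        # long run at the low level: flipping i -> B+1-i moves it high and
        # strictly shrinks the j^2/i^2 sum
        q = line_voi([1, 1, 1, 2], n_bins=2)
        flipped = line_voi([2, 2, 2, 1], n_bins=2)
        d = ((1, 0, 0),)
        assert lilre(glrlm_build(q, directions=d)) == pytest.approx((9.0 + 0.25) / 2)
        assert lilre(glrlm_build(flipped, directions=d)) < \
            lilre(glrlm_build(q, directions=d))

    def test_partition_identity(self, random_quantized_vois):
        for q in random_quantized_vois[:20]:
            m = glrlm_build(q)
            j = np.arange(1, m.counts.shape[1] + 1)
            assert (m.counts * j).sum() == 13 * q.n_voxels


class TestGLCM:
    def test_constant_voi(self):
        q = line_voi([1, 1, 1])
        P = glcm_build(q, directions=((1, 0, 0),))
        f = glcm_features(P)
        assert f["GLCM_homogeneity"] == pytest.approx(1.0)
        assert f["GLCM_contrast"] == pytest.approx(0.0)

    def test_alternating_line(self):
        # [1,2,1,2]: 3 ordered pairs each way => P(1,2)=P(2,1)=0.5
        q = line_voi([1, 2, 1, 2])
        P = glcm_build(q, directions=((1, 0, 0),))
        assert P[0, 1] == pytest.approx(0.5) and P[1, 0] == pytest.approx(0.5)
        f = glcm_features(P)
        assert f["GLCM_contrast"] == pytest.approx(1.0)
        assert f["GLCM_homogeneity"] == pytest.approx(0.5)

    def test_contrast_nonnegative_and_normalized(self, random_quantized_vois):
        for q in random_quantized_vois[:20]:
            P = glcm_build(q)
            if P.sum() > 0:
                assert P.sum() == pytest.approx(1.0)
                assert glcm_features(P)["GLCM_contrast"] >= 0


class TestNGTDM:
    def test_constant_voi_hits_eps_cap(self):
        q = line_voi([1, 1, 1, 1])
        m = ngtdm_build(q)
        assert ngtdm_coarseness(m) == pytest.approx(1e6)

    def test_three_voxel_line_hand_case(self):
        # [1,3,1]: voxel-wise neighbour means 3, 1, 3
        q = line_voi([1, 3, 1])
        m = ngtdm_build(q)
        assert m.n_valid == 3
        assert m.p[0] == pytest.approx(2 / 3) and m.p[2] == pytest.approx(1 / 3)
        assert m.s[0] == pytest.approx(4.0)  # |1-3| twice
        assert m.s[2] == pytest.approx(2.0)  # |3-1|

    def test_smoother_phantom_has_larger_coarseness(self):
        values = []
        for sigma in (1.0, 2.0, 4.0):
            spec = PhantomSpec(border_sigma_mm=sigma, noise_sd=0.0, seed=0)
            vol = generate_phantom(spec)
            mask = segment_isocontour(vol)
            values.append(ngtdm_coarseness(ngtdm_build(quantize(vol, mask))))
        assert values[0] < values[1] < values[2]


class TestGLSZM:
    def test_constant_voi_single_zone(self):
        q = line_voi([1] * 5)
        z = glszm_build(q)
        assert z[0, 4] == 1 and z.sum() == 1
        assert lilze(z) == pytest.approx(25.0)

    def test_two_isolated_level2_voxels(self):
        lv = np.zeros((5, 1, 1), dtype=np.int64)
        lv[0] = 2
        lv[4] = 2
        from petradiomics.quantization import QuantizedVOI
        q = QuantizedVOI(levels=lv, mask=lv > 0, n_bins=2, vmin=1, vmax=2)
        z = glszm_build(q)
        assert z[1, 0] == 2
        assert lilze(z) == pytest.approx(0.25)

    def test_partition_identity(self, random_quantized_vois):
        for q in random_quantized_vois[:20]:
            z = glszm_build(q)
            s = np.arange(1, z.shape[1] + 1)
            assert (z * s).sum() == q.n_voxels


class TestCodes:
    def test_constant_voi_similarity_one(self):
        q = line_voi([1, 1, 1, 1])
        assert code_similarity(texture_codes(q)) == 1.0

    def test_all_distinct_codes(self):
        assert code_similarity(np.array([1, 2, 3, 4])) == 0.0

    def test_pair_count_formula(self):
        assert code_similarity(np.array([5, 5, 9])) == pytest.approx(1 / 3)

    def test_single_voxel_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            code_similarity(np.array([1]))


class TestOracleEquivalence:
    """Every matrix builder equals exhaustive enumeration on random grids."""

    def test_glrlm(self, random_quantized_vois):
        for q in random_quantized_vois:
            m = glrlm_build(q)
            expected = oracle_glrlm(q.levels)
            got = {(i + 1, j + 1): int(c)
                   for (i, j), c in np.ndenumerate(m.counts) if c}
            assert got == expected

    def test_glcm(self, random_quantized_vois):
        for q in random_quantized_vois:
            P = glcm_build(q)
            counts = oracle_glcm(q.levels)
            if counts.sum() == 0:
                assert P.sum() == 0
                continue
            expected = np.zeros_like(P)
            expected[: counts.shape[0], : counts.shape[1]] = counts / counts.sum()
            np.testing.assert_allclose(P, expected, atol=1e-12)

    def test_ngtdm(self, random_quantized_vois):
        for q in random_quantized_vois:
            m = ngtdm_build(q)
            p, s, n_valid = oracle_ngtdm(q.levels)
            assert m.n_valid == n_valid
            np.testing.assert_allclose(m.p[: len(p)], p, atol=1e-12)
            np.testing.assert_allclose(m.s[: len(s)], s, atol=1e-9)
            assert not m.p[len(p):].any() and not m.s[len(s):].any()

    def test_glszm(self, random_quantized_vois):
        for q in random_quantized_vois:
            z = glszm_build(q)
            expected = oracle_zones(q.levels)
            got = {(i + 1, j + 1): int(c)
                   for (i, j), c in np.ndenumerate(z) if c}
            assert got == expected

    def test_codes(self, random_quantized_vois):
        for q in random_quantized_vois:
            got = texture_codes(q)
            expected = [sum(d * 3**k for k, d in enumerate(code))
                        for code in oracle_codes(q.levels)]
            assert sorted(got.tolist()) == sorted(expected)


class TestExtractAll:
    def test_deterministic(self):
        vol = generate_phantom(PhantomSpec(seed=3))
        mask = segment_isocontour(vol)
        a = extract_all(vol, mask)
        b = extract_all(vol, mask)
        assert a == b

    def test_peak_rescaling_leaves_quantized_features_unchanged(self):
        vol = generate_phantom(PhantomSpec(seed=4, noise_sd=0.0, border_sigma_mm=3.0))
        mask = segment_isocontour(vol)
        from petradiomics.volume import ImageVolume
        scaled = ImageVolume(vol.data * 2.5, vol.spacing_mm)
        a = extract_all(vol, mask)
        b = extract_all(scaled, mask)
        for name in ("run_percentage", "LILRE", "coarseness", "code_similarity",
                     "LILZE", "GLCM_homogeneity", "GLCM_contrast", "volume_ml"):
            assert a[name] == pytest.approx(b[name])
        assert b["SUVmax"] == pytest.approx(2.5 * a["SUVmax"])
        assert b["SUV_peak"] == pytest.approx(2.5 * a["SUV_peak"])

    def test_degenerate_voi_never_crashes(self):
        vol = make_volume(np.full((3, 3, 3), 5.0), spacing=(10, 10, 10))
        mask = make_mask(np.ones((3, 3, 3), bool), spacing=(10, 10, 10))
        f = extract_all(vol, mask)
        assert np.isnan(f["skewness"])
        assert f["coarseness"] == pytest.approx(1e6)
        assert f["code_similarity"] == 1.0

    def test_aggregation_modes_differ_but_agree_on_uniform(self):
        q_cfg = FeatureConfig(glrlm_aggregate=False)
        vol = generate_phantom(PhantomSpec(seed=5))
        mask = segment_isocontour(vol)
        summed = extract_all(vol, mask)
        averaged = extract_all(vol, mask, config=q_cfg)
        assert np.isfinite(averaged["LILRE"])
        # both conventions agree on the run-percentage of a direction-symmetric VOI
        assert averaged["run_percentage"] == pytest.approx(
            summed["run_percentage"], rel=0.1)
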