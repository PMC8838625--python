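"""Ground-truth and determinism contracts of the phantom generators."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from lipovoid.phantoms import (PhantomSpec, gen_bubbles, gen_cracks,
                               gen_sintered, generate, render_grayscale,
                               spec_from_dict)


def _sphere_voxel_count_oracle(center, r, dims):
    """Brute-force per-voxel centre-distance test."""
    zz, yy, xx = np.meshgrid(*[np.arange(d, dtype=float) for d in dims],
                             indexing="ij")
    return int(np.count_nonzero(
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
        <= r * r + 1e-12))


class TestBubbles:
    def test_zero_count_all_solid(self):
        spec = PhantomSpec("bubbles", (16, 16, 16), radius_params={"count": 0})
        truth = gen_bubbles(spec)
        assert truth.true_void_fraction == 0.0
        assert truth.feature_log == []

    def test_single_sphere_voxelization_matches_oracle(self):
        spec = PhantomSpec(
            "bubbles", (64, 64, 64), voxel_size_um=16.0,
            radius_params={"dist": "fixed", "radius_um": 8 * 16.0, "count": 1},
            seed=5,
        )
        truth = gen_bubbles(spec)
        (feat,) = truth.feature_log
        oracle = _sphere_voxel_count_oracle(feat["center_vox"], feat["radius_vox"],
                                            (64, 64, 64))
        assert truth.binary.void_voxel_count == oracle
        continuum = (4 / 3) * np.pi * 8**3 / 64**3
        assert truth.true_void_fraction == pytest.approx(continuum, rel=0.03)

    def test_true_void_fraction_is_recount(self, small_bubbles):
        m = small_bubbles.binary
        assert small_bubbles.true_void_fraction == m.void_voxel_count / m.mask.size

    def test_no_overlap_policy_keeps_bubbles_disconnected(self, small_bubbles):
        lab, n = ndi.label(small_bubbles.binary.mask, np.ones((3, 3, 3), int))
        assert n == len(small_bubbles.feature_log)

    def test_infeasible_packing_reports_achieved_fraction(self):
        spec = PhantomSpec(
            "bubbles", (20, 20, 20), voxel_size_um=16.0,
            target_void_fraction=0.5,
            radius_params={"dist": "fixed", "radius_um": 6 * 16.0},
        )
        with pytest.raises(RuntimeError, match="void fraction"):
            gen_bubbles(spec)


class TestCracks:
    def test_axis_aligned_slab_exact_fraction(self):
        spec = PhantomSpec(
            "cracks", (50, 50, 50),
            crack_params={"planes": [{"normal": [1, 0, 0], "point": [25, 25, 25],
                                      "thickness_vox": 3}]},
        )
        truth = gen_cracks(spec)
        assert truth.true_void_fraction == pytest.approx(3 / 50, abs=0)
        assert truth.binary.mask[24:27].all() and truth.binary.mask.sum() == 3 * 2500

    def test_orthogonal_slabs_union_subadditive(self):
        planes = [
            {"normal": [1, 0, 0], "point": [25, 25, 25], "thickness_vox": 3},
            {"normal": [0, 0, 1], "point": [25, 25, 25], "thickness_vox": 3},
        ]
        single = [
            gen_cracks(PhantomSpec("cracks", (50, 50, 50),
                                   crack_params={"planes": [p]})).true_void_fraction
            for p in planes
        ]
        union = gen_cracks(PhantomSpec("cracks", (50, 50, 50),
                                       crack_params={"planes": planes}))
        assert union.true_void_fraction < sum(single)
        # inclusion-exclusion: overlap is the 3x3 intersection column
        expect = sum(single) - 3 * 3 * 50 / 50**3
        assert union.true_void_fraction == pytest.approx(expect, rel=1e-12)

    def test_zero_planes_with_target_fraction_fails(self):
        spec = PhantomSpec("cracks", (20, 20, 20), target_void_fraction=0.05,
                           crack_params={"n_planes": 0})
        with pytest.raises(ValueError, match="zero planes"):
            gen_cracks(spec)


class TestSintered:
    def test_quantile_threshold_hits_target(self):
        spec = PhantomSpec("sintered", (40, 40, 40), target_void_fraction=0.12,
                           seed=2)
        truth = gen_sintered(spec)
        assert truth.true_void_fraction == pytest.approx(0.12, abs=0.005)

    def test_zero_quantile_all_solid(self):
        spec = PhantomSpec("sintered", (20, 20, 20), target_void_fraction=0.0)
        assert gen_sintered(spec).true_void_fraction == 0.0

    def test_target_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            gen_sintered(PhantomSpec("sintered", (10, 10, 10),
                                     target_void_fraction=1.2))

    def test_short_smoothing_gives_fragmented_voids(self):
        """sigma -> 0 yields salt-and-pepper; large sigma a spanning sheet."""
        shares = {}
        for corr in (0.0, 52.0):
            spec = PhantomSpec("sintered", (50, 50, 50), target_void_fraction=0.06,
                              blob_params={"corr_length_um": corr}, seed=3)
            mask = gen_sintered(spec).binary.mask
            lab, n = ndi.label(mask, np.ones((3, 3, 3), int))
            sizes = np.bincount(lab.ravel())[1:]
            shares[corr] = sizes.max() / sizes.sum()
        assert shares[0.0] < 0.05 < 0.5 < shares[52.0]


@pytest.mark.parametrize("morphology,kwargs", [
    ("bubbles", {"radius_params": {"dist": "fixed", "radius_um": 48.0, "count": 4}}),
    ("cracks", {"crack_params": {"n_planes": 2}}),
    ("sintered", {"target_void_fraction": 0.1}),
])
def test_seed_determinism(morphology, kwargs):
    spec = PhantomSpec(morphology, (24, 24, 24), seed=42, **kwargs)
    a = generate(spec)
    b = generate(spec_from_dict({"morphology": morphology, "dims": (24, 24, 24),
                                 "seed": 42, **kwargs}))
    np.testing.assert_array_equal(a.binary.mask, b.binary.mask)
    assert a.feature_log == b.feature_log


def test_wrong_parameter_block_rejected():
    with pytest.raises(ValueError, match="not a valid parameter block"):
        PhantomSpec("bubbles", (8, 8, 8), crack_params={"n_planes": 1},
                    radius_params={"count": 1})


class TestRender:
    def test_noiseless_unblurred_two_exact_intensities(self, small_bubbles):
        g = render_grayscale(small_bubbles, 180, 60, 0.0, 0.0)
        vals, counts = np.unique(g.data, return_counts=True)
        assert list(vals) == [60, 180]
        assert counts[0] == small_bubbles.binary.void_voxel_count

    def test_ideal_threshold_misclassification_below_1pct(self, small_bubbles):
        g = render_grayscale(small_bubbles, 180, 60, 10.0, 1.0, seed=7)
        truth = small_bubbles.binary.mask
        best = min(
            np.count_nonzero((g.data <= t) != truth) for t in range(60, 181)
        )
        assert best / truth.size < 0.01

    def test_render_determinism(self, small_bubbles):
        a = render_grayscale(small_bubbles, 180, 60, 10.0, 1.0, seed=9)
        b = render_grayscale(small_bubbles, 180, 60, 10.0, 1.0, seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_invalid_params(self, small_bubbles):
        with pytest.raises(ValueError):
            render_grayscale(small_bubbles, 100, 100)
        with pytest.raises(ValueError):
            render_grayscale(small_bubbles, 180, 60, noise_sd=-1.0)
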