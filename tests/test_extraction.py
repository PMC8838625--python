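"""Distance map, maximal balls and network construction against oracles."""

import itertools

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.segmentation import watershed

from lipovoid.extraction import (build_network, distance_map,
                                 extract_maximal_balls, extract_network,
                                 _find_seeds, _flood)
from lipovoid.phantoms import PhantomSpec, gen_bubbles
from lipovoid.volumes import BinaryVolume


def _brute_force_distance(mask):
    """Exhaustive nearest-solid-centre search (border counts as solid)."""
    padded = np.pad(mask, 1, constant_values=False)
    solid = np.argwhere(~padded)
    out = np.zeros(padded.shape)
    for v in np.argwhere(padded):
        out[tuple(v)] = np.sqrt(((solid - v) ** 2).sum(axis=1).min())
    return out[1:-1, 1:-1, 1:-1]


def _brute_force_maximal(dmap):
    """O(n^2) containment oracle over all candidate balls."""
    mask = dmap.values > 0
    cand = [(c.astype(float), dmap.values[tuple(c)]) for c in np.argwhere(mask)]
    out = []
    for i, (c2, r2) in enumerate(cand):
        contained = any(
            np.linalg.norm(c1 - c2) + r2 <= r1 + 1e-9
            for j, (c1, r1) in enumerate(cand) if j != i
        )
        if not contained:
            out.append((tuple(int(x) for x in c2), r2))
    return set(out)


class TestDistanceMap:
    def test_single_void_voxel(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        d = distance_map(BinaryVolume(mask, 16.0))
        assert d.values[1, 1, 1] == 1.0
        assert (d.values[~mask] == 0).all()

    def test_slab_center_distance(self):
        mask = np.zeros((9, 11, 11), bool)
        mask[2:7] = True  # 5 void layers bounded by solid above and below
        d = distance_map(BinaryVolume(mask, 16.0))
        # interior of the centre layer: nearest solid is 3 layers away
        assert (d.values[4, 3:8, 3:8] == 3.0).all()

    def test_border_counts_as_solid(self):
        mask = np.ones((5, 5, 5), bool)
        d = distance_map(BinaryVolume(mask, 16.0))
        assert d.values[2, 2, 2] == 3.0
        assert (d.values[0] == 1.0).all()

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((16, 16, 16)) < 0.5
        d = distance_map(BinaryVolume(mask, 16.0))
        np.testing.assert_allclose(d.values, _brute_force_distance(mask),
                                   atol=1e-12)

    def test_lipschitz_along_axes(self):
        rng = np.random.default_rng(3)
        mask = rng.random((12, 12, 12)) < 0.6
        d = distance_map(BinaryVolume(mask, 16.0)).values
        for ax in range(3):
            diff = np.abs(np.diff(d, axis=ax))
            assert diff.max() <= 1.0 + 1e-12


class TestMaximalBalls:
    def test_single_void_voxel_single_ball(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        balls = extract_maximal_balls(distance_map(BinaryVolume(mask, 16.0)))
        assert [(b.center, b.radius) for b in balls] == [((1, 1, 1), 1.0)]

    def test_two_disjoint_voxels_two_balls(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2, 2, 2] = mask[5, 5, 5] = True
        balls = extract_maximal_balls(distance_map(BinaryVolume(mask, 16.0)))
        assert len(balls) == 2

    def test_empty_void_empty_list(self):
        mask = np.zeros((4, 4, 4), bool)
        assert extract_maximal_balls(distance_map(BinaryVolume(mask, 16.0))) == []

    def test_sphere_retains_central_ball_no_containment(self):
        mask = np.zeros((24, 24, 24), bool)
        zz, yy, xx = np.meshgrid(*[np.arange(24.)] * 3, indexing="ij")
        mask |= ((zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2) <= 8**2
        dmap = distance_map(BinaryVolume(mask, 16.0))
        balls = extract_maximal_balls(dmap)
        assert max(b.radius for b in balls) >= 7.5
        for (c1, r1), (c2, r2) in itertools.permutations(
                [(np.array(b.center, float), b.radius) for b in balls], 2):
            assert np.linalg.norm(c1 - c2) + r2 > r1 + 1e-9

    @pytest.mark.parametrize("seed", [0, 7])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = ndi.binary_opening(rng.random((14, 14, 14)) < 0.6)
        dmap = distance_map(BinaryVolume(mask, 16.0))
        got = {(b.center, round(b.radius, 9)) for b in extract_maximal_balls(dmap)}
        exp = {(c, round(r, 9)) for c, r in _brute_force_maximal(dmap)}
        assert got == exp


class TestBuildNetwork:
    def test_single_cavity_one_pore_no_throats(self):
        mask = np.zeros((24, 24, 24), bool)
        zz, yy, xx = np.meshgrid(*[np.arange(24.)] * 3, indexing="ij")
        mask |= ((zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2) <= 8**2
        net = extract_network(BinaryVolume(mask, 16.0))
        assert net.pore_count == 1 and net.throat_count == 0
        assert net.pores[0].coordination == 0

    def test_dumbbell_two_pores_one_throat(self, dumbbell):
        net = extract_network(dumbbell.binary)
        assert net.pore_count == 2 and net.throat_count == 1
        (t,) = net.throats
        vox = net.voxel_size_um
        assert abs(t.radius_um / vox - 3.0) <= 1.0
        assert all(p.coordination == 1 for p in net.pores)
        assert t.radius_um <= min(p.radius_um for p in net.pores)

    def test_disjoint_bubbles_one_pore_each(self, small_bubbles):
        net = extract_network(small_bubbles.binary)
        assert net.pore_count == len(small_bubbles.feature_log)
        assert net.throat_count == 0

    def test_partition_and_degree_identities(self, small_bubbles, dumbbell):
        for truth in (small_bubbles, dumbbell):
            net = extract_network(truth.binary)
            vox = net.voxel_size_um
            assigned = sum(round(p.volume_um3 / vox**3) for p in net.pores)
            assert assigned == truth.binary.void_voxel_count == net.void_voxel_count
            assert sum(p.coordination for p in net.pores) == 2 * net.throat_count

    def test_throat_radius_bounded_by_pore_radii(self):
        spec = PhantomSpec("sintered", (40, 40, 40), target_void_fraction=0.12,
                          seed=9)
        from lipovoid.phantoms import gen_sintered
        net = extract_network(gen_sintered(spec).binary)
        lookup = {p.id: p.radius_um for p in net.pores}
        assert net.throat_count > 0
        for t in net.throats:
            assert t.radius_um <= min(lookup[t.pore_a], lookup[t.pore_b]) + 1e-9

    def test_balls_dmap_mismatch_rejected(self, small_bubbles, dumbbell):
        dmap_a = distance_map(small_bubbles.binary)
        balls_b = extract_maximal_balls(distance_map(dumbbell.binary))
        with pytest.raises(ValueError, match="do not match"):
            build_network(balls_b, dmap_a)

    def test_extraction_deterministic(self, dumbbell):
        a = extract_network(dumbbell.binary)
        b = extract_network(dumbbell.binary)
        assert [(p.id, p.center, p.radius_um) for p in a.pores] == \
            [(p.id, p.center, p.radius_um) for p in b.pores]
        assert [(t.pore_a, t.pore_b, t.radius_um) for t in a.throats] == \
            [(t.pore_a, t.pore_b, t.radius_um) for t in b.throats]

    def test_min_pore_radius_filter(self, small_bubbles):
        vox = small_bubbles.binary.voxel_size_um
        net = extract_network(small_bubbles.binary,
                              min_pore_radius_um=100 * vox)
        assert net.pore_count == 0

    @pytest.mark.parametrize("seed", [2, 6])
    def test_region_growth_agrees_with_watershed_oracle(self, seed):
        """Priority-flood assignment matches an independent watershed of -d.

        Overlapping bubbles give a gradient-rich radius field where the
        watershed is essentially unique; residual disagreement comes only
        from equal-d plateau tie-breaks at region boundaries.
        """
        spec = PhantomSpec(
            "bubbles", (48, 48, 48), voxel_size_um=16.0,
            radius_params={"dist": "fixed", "radius_um": 6 * 16.0,
                           "count": 10, "overlap": "allow"}, seed=seed)
        mask = gen_bubbles(spec).binary.mask
        d = distance_map(BinaryVolume(mask, 16.0)).values
        seeds = _find_seeds(d, mask)
        ours = _flood(d, mask, seeds)
        markers = np.zeros(mask.shape, np.int32)
        for i, s in enumerate(seeds, 1):
            markers[s] = i
        ref = watershed(-d, markers, mask=mask,
                        connectivity=np.ones((3, 3, 3), bool))
        agree = np.mean(ours[mask] == ref[mask])
        assert agree > 0.95
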