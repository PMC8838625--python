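"""Maximal-ball discretization of the void phase into a pore-throat network.

The void is described by the field of maximally inscribed spheres: at every
void voxel, the radius of the largest ball centred there that stays inside
the void equals the Euclidean distance from the voxel centre to the nearest
solid voxel centre.  Redundant balls (contained in a larger ball) are
removed, leaving balls along the void's medial axis.  Pores are local
maxima of the radius field (wide bodies, drawn as spheres); throats are the
saddles between adjacent pores (constrictions, drawn as cylinders).  Every
void voxel is assigned to exactly one pore by descending-radius region
growth, so pore voxel counts partition the void.

Conventions (all recorded in ``PoreNetwork.extraction_params``):

* ball radius = centre-to-centre distance to the nearest solid, with the
  volume border treated as a virtual solid shell;
* 26-connectivity for maxima, growth and throat interfaces;
* plateau maxima collapse to one seed (lexicographically smallest voxel);
* containment test ``|c1 - c2| + r2 <= r1 + eps`` with ``eps = 1e-9``;
* pore pairs whose saddle/peak ratio exceeds ``merge_ratio`` are merged
  (digitized spheres otherwise over-segment at spurious ridge maxima);
* dead-end interfaces (single-region contacts, e.g. at the border) are not
  throats — isolated pores have coordination 0.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .network import Pore, PoreNetwork, Throat
from .volumes import BinaryVolume

__all__ = [
    "DistanceMap",
    "MaximalBall",
    "distance_map",
    "extract_maximal_balls",
    "build_network",
    "extract_network",
]

EPS = 1e-9
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class DistanceMap:
    """Euclidean distance (voxel units) to the nearest solid voxel centre.

    Zero on solid voxels; the border is bounded by a virtual solid shell.
    """

    values: np.ndarray
    voxel_size_um: float


@dataclass(frozen=True)
class MaximalBall:
    center: tuple[int, int, int]  # (z, y, x)
    radius: float  # voxel units


def distance_map(binary: BinaryVolume) -> DistanceMap:
    """Exact Euclidean distance transform with the border treated as solid."""
    padded = np.pad(binary.mask, 1, constant_values=False)
    d = ndi.distance_transform_edt(padded)
    return DistanceMap(d[1:-1, 1:-1, 1:-1], binary.voxel_size_um)


def _padded_edt_with_indices(mask: np.ndarray):
    padded = np.pad(mask, 1, constant_values=False)
    d, idx = ndi.distance_transform_edt(padded, return_indices=True)
    return padded, d, idx


def extract_maximal_balls(dmap: DistanceMap) -> list[MaximalBall]:
    """Retain the maximal (non-redundant) inscribed balls.

    Every void voxel carries a candidate ball of radius ``d``.  A candidate
    at ``x`` is redundant iff some other candidate ``y`` contains it, which
    for an exact distance transform forces the collinear equality
    ``d(y) = d(x) + |x - y|`` with ``y`` on the lattice ray from ``x``'s
    nearest solid point through ``x`` (triangle inequality both ways).  If
    that equality holds for any such ``y``, it holds for the first lattice
    point ``x + p`` beyond ``x`` on the ray (``p`` the primitive step), and
    a candidate with two or more tied nearest solid points can never be
    contained (it cannot be collinear with both).  The containment test is
    therefore a single vectorized ray-neighbour check — exact, no pairwise
    search needed.
    """
    mask = dmap.values > 0
    if not mask.any():
        return []
    padded, d, idx = _padded_edt_with_indices(mask)
    vz, vy, vx = np.nonzero(padded)
    coords = np.stack([vz, vy, vx], axis=1)
    dv = d[vz, vy, vx]
    s = np.stack([idx[0][vz, vy, vx], idx[1][vz, vy, vx], idx[2][vz, vy, vx]], axis=1)
    v = coords - s
    g = np.gcd.reduce(np.abs(v), axis=1)
    g[g == 0] = 1
    p = v // g[:, None]
    pnorm = np.linalg.norm(p, axis=1)
    y = coords + p
    inb = np.all((y >= 0) & (y < np.array(padded.shape)), axis=1)
    redundant = np.zeros(len(coords), dtype=bool)
    yi = y[inb]
    dy = d[yi[:, 0], yi[:, 1], yi[:, 2]]
    redundant[inb] = dy >= dv[inb] + pnorm[inb] - EPS

    sv_coords = coords[~redundant]
    sv_r = dv[~redundant]
    out = [
        MaximalBall(center=(int(c[0] - 1), int(c[1] - 1), int(c[2] - 1)),
                    radius=float(r))
        for c, r in zip(sv_coords, sv_r)
    ]
    out.sort(key=lambda b: b.center)
    return out


# ---------------------------------------------------------------------------
# network construction


def _find_seeds(d: np.ndarray, mask: np.ndarray):
    """Local maxima of d over the 26-neighbourhood; one seed per plateau.

    Returns the seed voxels as a lexicographically sorted list of (z, y, x)
    tuples, one per connected plateau of maxima (its smallest voxel).
    """
    maxf = ndi.maximum_filter(d, size=3, mode="constant", cval=0.0)
    maxima = mask & (d >= maxf)
    lab, nlab = ndi.label(maxima, structure=_STRUCT26)
    seeds = []
    flat = lab.ravel()
    order = np.flatnonzero(flat)  # ascending flat index == lexicographic (z,y,x)
    seen = set()
    for fi in order:
        l = flat[fi]
        if l not in seen:
            seen.add(l)
            seeds.append(np.unravel_index(fi, d.shape))
    seeds.sort()
    return seeds


def _flood(d: np.ndarray, mask: np.ndarray, seeds) -> np.ndarray:
    """Priority-flood region growth: voxels claimed in decreasing d.

    Each popped voxel joins the region of its highest-d already-assigned
    26-neighbour (ties to the lower region id).  Equal-d ties pop in
    insertion (FIFO) order, so plateaus are split by front arrival as in a
    standard priority-flood watershed; the push order is itself
    deterministic, making the whole assignment reproducible.  Returns a
    label volume (0 = solid).
    """
    dp = np.pad(d, 1).astype(np.float64)
    mp = np.pad(mask, 1)
    labels = np.zeros(dp.shape, dtype=np.int32)
    sz, sy, sx = dp.shape
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz or dy or dx:
                    offs.append(dz * sy * sx + dy * sx + dx)
    dflat = dp.ravel()
    mflat = mp.ravel()
    lflat = labels.ravel()
    heap: list[tuple[float, int, int]] = []
    push = heapq.heappush
    pop = heapq.heappop
    age = 0
    for i, (z, y, x) in enumerate(seeds, start=1):
        fi = (z + 1) * sy * sx + (y + 1) * sx + (x + 1)
        lflat[fi] = i
    for z, y, x in seeds:
        fi = (z + 1) * sy * sx + (y + 1) * sx + (x + 1)
        for o in offs:
            n = fi + o
            if mflat[n] and lflat[n] == 0:
                age += 1
                push(heap, (-dflat[n], age, n))
    while heap:
        negd, _, fi = pop(heap)
        if lflat[fi]:
            continue
        best = 0
        bestd = -1.0
        for o in offs:
            n = fi + o
            l = lflat[n]
            if l:
                dn = dflat[n]
                if dn > bestd or (dn == bestd and (best == 0 or l < best)):
                    bestd = dn
                    best = l
        lflat[fi] = best
        for o in offs:
            n = fi + o
            if mflat[n] and lflat[n] == 0:
                age += 1
                push(heap, (-dflat[n], age, n))
    return labels[1:-1, 1:-1, 1:-1]


def _interface_saddles(labels: np.ndarray, d: np.ndarray) -> dict:
    """Saddle height per adjacent region pair.

    The interface between two regions is the set of 26-adjacent void voxel
    pairs spanning them; the throat radius is the maximum of d over the
    interface voxels (the minimal ball along the connecting path).
    """
    saddles: dict[tuple[int, int], float] = {}
    shifts = [
        (dz, dy, dx)
        for dz in (0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if (dz, dy, dx) > (0, 0, 0)
    ]
    nmax = int(labels.max())
    for off in shifts:
        a_sl, b_sl = [], []
        for n, o in zip(labels.shape, off):
            if o >= 0:
                a_sl.append(slice(0, n - o))
                b_sl.append(slice(o, n))
            else:
                a_sl.append(slice(-o, n))
                b_sl.append(slice(0, n + o))
        a_sl, b_sl = tuple(a_sl), tuple(b_sl)
        a = labels[a_sl]
        b = labels[b_sl]
        sel = (a > 0) & (b > 0) & (a != b)
        if not sel.any():
            continue
        pa = a[sel].astype(np.int64)
        pb = b[sel].astype(np.int64)
        height = np.maximum(d[a_sl][sel], d[b_sl][sel])
        lo = np.minimum(pa, pb)
        hi = np.maximum(pa, pb)
        keys = lo * (nmax + 1) + hi
        uniq, inv = np.unique(keys, return_inverse=True)
        maxes = np.full(len(uniq), -1.0)
        np.maximum.at(maxes, inv, height)
        for key, v in zip(uniq, maxes):
            pair = (int(key // (nmax + 1)), int(key % (nmax + 1)))
            if v > saddles.get(pair, -1.0):
                saddles[pair] = float(v)
    return saddles


def build_network(
    balls: list[MaximalBall],
    dmap: DistanceMap,
    merge_ratio: float = 0.7,
    min_pore_radius_um: float | None = None,
) -> PoreNetwork:
    """Assemble the pore-throat network from the maximal-ball radius field.

    ``balls`` must come from :func:`extract_maximal_balls` on the same
    distance map (checked).  Pore radii are the defining local-maximum ball
    radii; pore volumes are assigned-voxel volumes; throat radii are
    interface saddle heights; throat length is the centre distance minus
    the two pore radii (clamped to one voxel) and throat volume follows the
    cylinder model pi r^2 L.
    """
    d = dmap.values
    mask = d > 0
    vox = dmap.voxel_size_um
    void_count = int(np.count_nonzero(mask))
    for b in balls[: min(len(balls), 64)]:
        if abs(d[b.center] - b.radius) > 1e-6:
            raise ValueError("balls do not match the distance map")

    params = {
        "radius_convention": "center_to_center",
        "border": "solid",
        "connectivity": 26,
        "plateau_rule": "one seed per plateau, lexicographic",
        "containment_eps": EPS,
        "merge_ratio": merge_ratio,
        "min_pore_radius_um": min_pore_radius_um,
        "throat_radius": "interface saddle ball",
        "throats_per_pair": "one (post-merge)",
    }

    if void_count == 0:
        return PoreNetwork([], [], vox, 0, params)

    seeds = _find_seeds(d, mask)
    labels = _flood(d, mask, seeds)
    counts = np.bincount(labels.ravel())[1:]  # per label 1..P
    n = len(seeds)
    radii = np.array([d[s] for s in seeds])
    centers = list(seeds)
    saddles = _interface_saddles(labels, d)

    radii_l = list(map(float, radii))
    centers_l = centers[:]
    counts_l = list(map(int, counts))
    merged = _greedy_merge(radii_l, centers_l, counts_l, saddles, merge_ratio)
    g_radii, g_centers, g_counts, g_saddles = merged
    return _assemble(g_radii, g_centers, g_counts, g_saddles, vox, void_count,
                     params, min_pore_radius_um)


def _greedy_merge(radii, centers, counts, saddles, merge_ratio):
    """Sequentially merge the highest saddle/peak-ratio pair until none exceed
    ``merge_ratio``.

    Merging one pair at a time (largest ratio first, ties lexicographic on
    the pair) absorbs over-segmentation fragments — spurious ridge maxima
    of digitized bodies and constant-radius neck plateaus — into their
    dominant neighbour without chaining two genuinely distinct pores
    together through an intermediate fragment.  The surviving pore keeps
    the larger defining ball; interface saddles aggregate by maximum.
    """
    import heapq as _hq

    alive = {i + 1 for i in range(len(radii))}
    nbrs: dict[int, dict[int, float]] = {i + 1: {} for i in range(len(radii))}
    for (a, b), s in saddles.items():
        nbrs[a][b] = s
        nbrs[b][a] = s

    def ratio(a, b, s):
        rmin = min(radii[a - 1], radii[b - 1])
        return s / rmin if rmin > 0 else 0.0

    heap = []
    for (a, b), s in saddles.items():
        r = ratio(a, b, s)
        if r > merge_ratio:
            _hq.heappush(heap, (-r, a, b, s))
    while heap:
        negr, a, b, s = _hq.heappop(heap)
        if a not in alive or b not in alive:
            continue
        cur = nbrs[a].get(b)
        if cur is None or cur != s or -negr != ratio(a, b, cur):
            continue  # stale entry
        # survivor keeps the larger ball; ties -> lexicographically smaller center
        ia, ib = a - 1, b - 1
        if (radii[ib], ) > (radii[ia], ) or (
                radii[ib] == radii[ia] and centers[ib] < centers[ia]):
            a, b, ia, ib = b, a, ib, ia
        counts[ia] += counts[ib]
        alive.discard(b)
        del nbrs[a][b]
        for c, sc in nbrs[b].items():
            if c == a:
                continue
            del nbrs[c][b]
            snew = max(nbrs[a].get(c, -1.0), sc)
            nbrs[a][c] = snew
            nbrs[c][a] = snew
        nbrs[b] = {}
        for c, sc in list(nbrs[a].items()):
            r = ratio(a, c, sc)
            if r > merge_ratio:
                lo, hi = (a, c) if a < c else (c, a)
                _hq.heappush(heap, (-r, lo, hi, sc))

    labels = sorted(alive)
    remap = {old: i for i, old in enumerate(labels)}
    g_radii = [radii[l - 1] for l in labels]
    g_centers = [centers[l - 1] for l in labels]
    g_counts = [counts[l - 1] for l in labels]
    g_saddles: dict[tuple[int, int], float] = {}
    for l in labels:
        for c, s in nbrs[l].items():
            key = (min(remap[l], remap[c]) + 1, max(remap[l], remap[c]) + 1)
            g_saddles[key] = s
    return g_radii, g_centers, g_counts, g_saddles


def _assemble(radii, centers, counts, saddles, vox, void_count, params,
              min_pore_radius_um):
    n = len(radii)
    order = sorted(range(n), key=lambda i: centers[i])
    newid = {old + 1: rank + 1 for rank, old in enumerate(order)}
    pores = []
    for old in order:
        pores.append(Pore(
            id=newid[old + 1],
            center=tuple(int(c) for c in centers[old]),
            radius_um=float(radii[old]) * vox,
            volume_um3=float(counts[old]) * vox**3,
            coordination=0,
        ))
    pores.sort(key=lambda p: p.id)
    pore_by_id = {p.id: p for p in pores}
    throats = []
    items = sorted(
        ((min(newid[a], newid[b]), max(newid[a], newid[b]), s)
         for (a, b), s in saddles.items())
    )
    tid = 0
    centers_arr = {p.id: np.array(p.center, dtype=float) for p in pores}
    for a, b, s in items:
        tid += 1
        pa, pb = pore_by_id[a], pore_by_id[b]
        cdist = float(np.linalg.norm(centers_arr[a] - centers_arr[b]))
        length_vox = max(cdist - (pa.radius_um + pb.radius_um) / vox, 1.0)
        r_um = float(s) * vox
        length_um = length_vox * vox
        throats.append(Throat(
            id=tid, pore_a=a, pore_b=b, radius_um=r_um, length_um=length_um,
            volume_um3=float(np.pi * r_um**2 * length_um),
        ))
        pa.coordination += 1
        pb.coordination += 1

    if min_pore_radius_um is not None:
        small = {p.id for p in pores if p.radius_um < min_pore_radius_um}
        removed_voxels = sum(
            round(p.volume_um3 / vox**3) for p in pores if p.id in small)
        pores = [p for p in pores if p.id not in small]
        throats = [t for t in throats if t.pore_a not in small and t.pore_b not in small]
        void_count -= int(removed_voxels)
        inc: dict[int, int] = {p.id: 0 for p in pores}
        for t in throats:
            inc[t.pore_a] += 1
            inc[t.pore_b] += 1
        for p in pores:
            p.coordination = inc[p.id]

    net = PoreNetwork(pores, throats, vox, void_count, params)
    assigned = sum(round(p.volume_um3 / vox**3) for p in pores)
    if assigned != void_count:
        raise AssertionError(
            f"voxel partition violated: {assigned} assigned vs {void_count} void")
    return net


def extract_network(
    binary: BinaryVolume,
    merge_ratio: float = 0.7,
    min_pore_radius_um: float | None = None,
) -> PoreNetwork:
    """Convenience wrapper: distance map -> maximal balls -> network."""
    dmap = distance_map(binary)
    balls = extract_maximal_balls(dmap)
    return build_network(balls, dmap, merge_ratio=merge_ratio,
                         min_pore_radius_um=min_pore_radius_um)
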