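"""Seeded synthetic void phantoms for the three morphology regimes.

Shear-crystallized lipids show three characteristic void morphologies under
micro-CT: dilute disconnected spherical bubbles (air entrained during
crystallization), planar crack networks propagating through the solid, and
percolating irregular voids formed by sintering of crystal aggregates.
Each generator produces a ground-truth binary mask plus a feature log, so
segmentation, network extraction and the downstream metrics can all be
validated against known geometry.  Generators are pure functions of their
spec (seed included).

Digitization rule: a voxel is void iff its center lies inside the
continuous feature (closed surface).  The volume border counts as solid;
bubbles are placed fully interior so their count and radii are unambiguous
ground truth, while cracks and sintered fields are clipped at the border.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml
from scipy import ndimage as ndi

from .volumes import BinaryVolume, GrayscaleVolume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "gen_bubbles",
    "gen_cracks",
    "gen_sintered",
    "generate",
    "render_grayscale",
    "dumbbell_truth",
    "spec_from_dict",
    "spec_from_config",
]

MORPHOLOGIES = ("bubbles", "cracks", "sintered")

#: Default parameter blocks per morphology.  These emulate the regimes the
#: study reports: bubbles ~ spherical pores with volume-weighted radius
#: around 50 um at v ~ 0.11; cracks ~ sheet-like voids with varying aperture
#: at v ~ 0.05; sintered ~ a percolating correlated random field at v ~ 0.12.
DEFAULT_RADIUS_PARAMS = {
    "dist": "lognormal",
    "median_um": 48.0,
    "sigma": 0.35,
    "radius_um": None,  # used by dist == "fixed"
    "count": None,
    "overlap": "forbid",
    "surface_gap_vox": 2.0,
}
DEFAULT_CRACK_PARAMS = {
    "n_planes": 3,
    "thickness_um": 64.0,
    "extent": 1.0,
    "aperture_modulation": True,
    "aperture_corr_um": 96.0,
    "min_aperture_frac": 0.1,
    "planes": None,
}
DEFAULT_BLOB_PARAMS = {
    "corr_length_um": 46.0,
    "keep_largest": False,
}


@dataclass
class PhantomSpec:
    """Full description of one synthetic volume; the seed fixes the output."""

    morphology: str
    dims: tuple[int, int, int]
    voxel_size_um: float = 16.0
    target_void_fraction: float | None = None
    radius_params: dict | None = None
    crack_params: dict | None = None
    blob_params: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.morphology not in MORPHOLOGIES:
            raise ValueError(f"unknown morphology {self.morphology!r}")
        self.dims = tuple(int(d) for d in self.dims)
        if len(self.dims) != 3 or any(d <= 0 for d in self.dims):
            raise ValueError(f"dims must be three positive integers, got {self.dims}")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        blocks = {
            "bubbles": ("radius_params", DEFAULT_RADIUS_PARAMS),
            "cracks": ("crack_params", DEFAULT_CRACK_PARAMS),
            "sintered": ("blob_params", DEFAULT_BLOB_PARAMS),
        }
        wanted, defaults = blocks[self.morphology]
        for name, _ in blocks.values():
            val = getattr(self, name)
            if name == wanted:
                merged = dict(defaults)
                merged.update(val or {})
                unknown = set(merged) - set(defaults)
                if unknown:
                    raise ValueError(f"unknown {name} keys: {sorted(unknown)}")
                setattr(self, name, merged)
            elif val is not None:
                raise ValueError(
                    f"{name} is not a valid parameter block for morphology "
                    f"{self.morphology!r}"
                )


@dataclass
class PhantomTruth:
    """Ground truth for one phantom: mask, generator primitives, recount."""

    binary: BinaryVolume
    feature_log: list
    true_void_fraction: float
    spec: PhantomSpec


def _finish(mask: np.ndarray, spec: PhantomSpec, log: list) -> PhantomTruth:
    binary = BinaryVolume(mask, spec.voxel_size_um,
                          provenance=f"phantom:{spec.morphology}:seed={spec.seed}")
    frac = binary.void_voxel_count / mask.size
    return PhantomTruth(binary, log, frac, spec)


def generate(spec: PhantomSpec) -> PhantomTruth:
    """Dispatch to the generator for ``spec.morphology``."""
    return {"bubbles": gen_bubbles, "cracks": gen_cracks, "sintered": gen_sintered}[
        spec.morphology
    ](spec)


# ---------------------------------------------------------------------------
# bubbles


def _stamp_sphere(mask: np.ndarray, center: np.ndarray, r: float) -> int:
    """Set void voxels whose centers lie within the closed sphere; return count."""
    lo = np.maximum(np.floor(center - r).astype(int), 0)
    hi = np.minimum(np.ceil(center + r).astype(int) + 1, mask.shape)
    if np.any(lo >= hi):
        return 0
    zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    inside = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
              + (xx - center[2]) ** 2) <= r * r + 1e-12
    sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    added = int(np.count_nonzero(inside & ~sub))
    sub |= inside
    return added


def gen_bubbles(spec: PhantomSpec) -> PhantomTruth:
    """Place voxelized spheres with uniformly proposed interior centers.

    With the default ``overlap='forbid'`` policy, accepted spheres keep at
    least ``surface_gap_vox`` between surfaces, so every logged bubble is a
    distinct disconnected pore — the ground truth for count-recovery tests.
    Placement stops at the requested ``count`` or at
    ``target_void_fraction``, whichever is specified.
    """
    if spec.morphology != "bubbles":
        raise ValueError("spec morphology must be 'bubbles'")
    p = spec.radius_params
    count = p["count"]
    target = spec.target_void_fraction
    if count is None and target is None:
        raise ValueError("bubbles need radius_params['count'] or target_void_fraction")
    if count is not None and count < 0:
        raise ValueError("count must be nonnegative")
    rng = np.random.default_rng(spec.seed)
    dims = np.array(spec.dims)
    vox = spec.voxel_size_um
    mask = np.zeros(spec.dims, dtype=bool)
    log: list[dict] = []
    total = mask.size
    gap = float(p["surface_gap_vox"])
    forbid = p["overlap"] == "forbid"

    accepted_centers: list[np.ndarray] = []
    accepted_radii: list[float] = []
    void = 0
    budget = 20000 + 400 * (count or 1000)
    attempts = 0
    while True:
        if count is not None and len(log) >= count:
            break
        if count is None and void / total >= target:
            break
        if attempts >= budget:
            raise RuntimeError(
                "bubble packing rejection budget exhausted at void fraction "
                f"{void / total:.4f} ({len(log)} bubbles placed)"
            )
        attempts += 1
        if p["dist"] == "fixed":
            r_um = float(p["radius_um"])
        elif p["dist"] == "lognormal":
            r_um = float(rng.lognormal(np.log(p["median_um"]), p["sigma"]))
        else:
            raise ValueError(f"unknown radius dist {p['dist']!r}")
        r = r_um / vox
        if 2 * r + 2 > min(dims):
            if p["dist"] == "fixed":
                raise ValueError(f"radius {r_um} um does not fit inside dims {spec.dims}")
            continue
        lo, hi = r, dims - 1 - r
        c = lo + rng.random(3) * (hi - lo)
        if forbid and any(
            np.linalg.norm(c - c0) <= r + r0 + gap
            for c0, r0 in zip(accepted_centers, accepted_radii)
        ):
            continue
        added = _stamp_sphere(mask, c, r)
        void += added
        accepted_centers.append(c)
        accepted_radii.append(r)
        log.append({
            "center_vox": [float(v) for v in c],
            "radius_vox": r,
            "radius_um": r_um,
            "voxel_count": added,
        })
    return _finish(mask, spec, log)


# ---------------------------------------------------------------------------
# cracks


def _unit_normal(rng) -> np.ndarray:
    while True:
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
        if n > 1e-6:
            return v / n


def gen_cracks(spec: PhantomSpec) -> PhantomTruth:
    """Union of planar slabs with (optionally) spatially varying aperture.

    Real cracks are sheets of varying opening: wide pockets linked through
    narrow pinches.  With ``aperture_modulation`` on, each slab's aperture is
    modulated by a smoothed seeded random field rescaled to
    ``[min_aperture_frac, 1] * thickness_um``, which produces exactly that
    pocket/pinch structure; with it off, slabs have uniform thickness
    (useful for analytically exact fixtures).
    """
    if spec.morphology != "cracks":
        raise ValueError("spec morphology must be 'cracks'")
    p = spec.crack_params
    rng = np.random.default_rng(spec.seed)
    vox = spec.voxel_size_um
    nz, ny, nx = spec.dims
    explicit = p["planes"]
    n_planes = len(explicit) if explicit is not None else int(p["n_planes"])
    if n_planes == 0 and (spec.target_void_fraction or 0) > 0:
        raise ValueError("zero planes requested with nonzero target void fraction")

    zz, yy, xx = np.meshgrid(
        np.arange(nz, dtype=np.float64),
        np.arange(ny, dtype=np.float64),
        np.arange(nx, dtype=np.float64),
        indexing="ij",
    )
    mask = np.zeros(spec.dims, dtype=bool)
    log: list[dict] = []
    diag = float(np.linalg.norm(spec.dims))
    corr_vox = max(float(p["aperture_corr_um"]) / vox, 1.0)
    for i in range(n_planes):
        if explicit is not None:
            pl = explicit[i]
            n = np.asarray(pl["normal"], dtype=float)
            n = n / np.linalg.norm(n)
            point = np.asarray(pl["point"], dtype=float)
            t_vox = float(pl.get("thickness_vox", p["thickness_um"] / vox))
            modulate = bool(pl.get("aperture_modulation", False))
            extent = float(pl.get("extent", p["extent"]))
        else:
            n = _unit_normal(rng)
            point = rng.random(3) * (np.array(spec.dims) - 1)
            t_vox = float(p["thickness_um"]) / vox
            modulate = bool(p["aperture_modulation"])
            extent = float(p["extent"])
        signed = (zz - point[0]) * n[0] + (yy - point[1]) * n[1] + (xx - point[2]) * n[2]
        if modulate:
            g = rng.standard_normal(spec.dims)
            g = ndi.gaussian_filter(g, corr_vox, mode="wrap")
            # rank-normalize to uniform [0,1]: apertures spread evenly between
            # pinches and pockets instead of clustering at the field mean
            u = np.argsort(np.argsort(g.ravel())).reshape(spec.dims)
            u = u / max(u.size - 1, 1)
            frac = float(p["min_aperture_frac"])
            aperture = t_vox * (frac + (1.0 - frac) * u)
        else:
            aperture = t_vox
        slab = np.abs(signed) <= aperture / 2.0
        if extent < 1.0:
            in_plane2 = ((zz - point[0]) ** 2 + (yy - point[1]) ** 2
                         + (xx - point[2]) ** 2) - signed ** 2
            slab &= in_plane2 <= (extent * diag / 2.0) ** 2
        mask |= slab
        log.append({
            "normal_zyx": [float(v) for v in n],
            "point_vox": [float(v) for v in point],
            "thickness_vox": t_vox,
            "extent": extent,
            "aperture_modulation": modulate,
        })
    return _finish(mask, spec, log)


# ---------------------------------------------------------------------------
# sintered


def gen_sintered(spec: PhantomSpec) -> PhantomTruth:
    """Percolating sintered voids from a smoothed seeded random field.

    Sintering opens voids along the boundaries between crystal aggregates.
    The generator emulates that geometry by smoothing a seeded Gaussian
    white-noise field (domains of one sign play the role of aggregates) and
    taking the void to be the near-zero interface sheet ``|G| <= t``, with
    ``t`` set by quantile (order-statistic) thresholding so the realized
    void fraction hits ``target_void_fraction`` to within one voxel — no
    calibration loop.  The result is an irregular, highly connected
    labyrinth.  ``keep_largest`` optionally retains only the largest
    26-connected void component.
    """
    if spec.morphology != "sintered":
        raise ValueError("spec morphology must be 'sintered'")
    target = spec.target_void_fraction
    if target is None or target < 0 or target >= 1:
        raise ValueError(f"target_void_fraction must be in [0, 1), got {target}")
    p = spec.blob_params
    rng = np.random.default_rng(spec.seed)
    corr_vox = float(p["corr_length_um"]) / spec.voxel_size_um
    field_ = rng.standard_normal(spec.dims)
    if corr_vox > 0:
        field_ = ndi.gaussian_filter(field_, corr_vox, mode="wrap")
    field_ = np.abs(field_)
    n = field_.size
    k = int(round(target * n))
    if k == 0:
        mask = np.zeros(spec.dims, dtype=bool)
        threshold = float("-inf")
    else:
        flat = field_.ravel()
        threshold = float(np.partition(flat, k - 1)[k - 1])
        mask = field_ <= threshold
    if p["keep_largest"] and mask.any():
        lab, nlab = ndi.label(mask, structure=np.ones((3, 3, 3), dtype=int))
        sizes = np.bincount(lab.ravel())[1:]
        mask = lab == (int(np.argmax(sizes)) + 1)
    log = [{
        "field_seed": spec.seed,
        "corr_length_vox": corr_vox,
        "threshold": threshold,
        "keep_largest": bool(p["keep_largest"]),
    }]
    return _finish(mask, spec, log)


# ---------------------------------------------------------------------------
# rendering and fixtures


def render_grayscale(
    truth: PhantomTruth,
    solid_mode: float = 180.0,
    void_mode: float = 60.0,
    noise_sd: float = 10.0,
    blur_sigma_vox: float = 1.0,
    seed: int = 0,
) -> GrayscaleVolume:
    """Render a truth mask to a noisy 8-bit grayscale volume.

    Each phase gets its mode intensity, seeded Gaussian detector noise is
    added, and the noisy field is blurred isotropically — the point-spread/
    reconstruction smoothing acts on the noisy signal, as in a real scan,
    so the blur also suppresses part of the voxel-wise noise.  The result
    is clipped to [0, 255].  The histogram is bimodal whenever
    ``|solid_mode - void_mode| >= 4 * noise_sd``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if blur_sigma_vox < 0:
        raise ValueError("blur_sigma_vox must be nonnegative")
    if solid_mode == void_mode:
        raise ValueError("solid_mode and void_mode must differ")
    img = np.where(truth.binary.mask, float(void_mode), float(solid_mode))
    if noise_sd > 0:
        img = img + np.random.default_rng(seed).normal(0.0, noise_sd, img.shape)
    if blur_sigma_vox > 0:
        img = ndi.gaussian_filter(img, blur_sigma_vox)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return GrayscaleVolume(
        img, truth.binary.voxel_size_um,
        provenance=f"render:{truth.binary.provenance}",
    )


def dumbbell_truth(
    dims: tuple[int, int, int] = (48, 48, 96),
    sphere_radius_vox: float = 8.0,
    neck_radius_vox: float = 3.0,
    separation_vox: float = 40.0,
    voxel_size_um: float = 16.0,
) -> PhantomTruth:
    """Two spherical cavities bridged by a cylindrical neck along x.

    A calibration geometry with a known answer — two pores joined by one
    throat of the neck radius — used to exercise throat detection.
    """
    nz, ny, nx = dims
    c0 = np.array([nz / 2.0, ny / 2.0, nx / 2.0 - separation_vox / 2.0])
    c1 = np.array([nz / 2.0, ny / 2.0, nx / 2.0 + separation_vox / 2.0])
    mask = np.zeros(dims, dtype=bool)
    _stamp_sphere(mask, c0, sphere_radius_vox)
    _stamp_sphere(mask, c1, sphere_radius_vox)
    zz, yy, xx = np.meshgrid(
        np.arange(nz, dtype=float), np.arange(ny, dtype=float),
        np.arange(nx, dtype=float), indexing="ij",
    )
    axial = (xx >= c0[2]) & (xx <= c1[2])
    radial2 = (zz - c0[0]) ** 2 + (yy - c0[1]) ** 2
    mask |= axial & (radial2 <= neck_radius_vox**2 + 1e-12)
    spec = PhantomSpec(
        morphology="bubbles", dims=dims, voxel_size_um=voxel_size_um,
        radius_params={"count": 0}, seed=0,
    )
    log = [
        {"center_vox": list(map(float, c0)), "radius_vox": sphere_radius_vox},
        {"center_vox": list(map(float, c1)), "radius_vox": sphere_radius_vox},
        {"neck_radius_vox": neck_radius_vox},
    ]
    binary = BinaryVolume(mask, voxel_size_um, provenance="phantom:dumbbell")
    return PhantomTruth(binary, log, binary.void_voxel_count / mask.size, spec)


# ---------------------------------------------------------------------------
# config


def spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    if "dims" in d:
        d["dims"] = tuple(d["dims"])
    return PhantomSpec(**d)


def spec_from_config(path) -> PhantomSpec:
    """Load a phantom spec from a YAML key-value config file."""
    with open(path) as f:
        return spec_from_dict(yaml.safe_load(f))
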