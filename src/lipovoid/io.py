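"""Reading and writing volumes and pore-network tables.

Supported volume formats
------------------------
``tiff_stack``
    One multi-page TIFF, pages in z-ascending order.
``tiff_dir``
    A directory of single-slice TIFFs, ordered by the numeric part of the
    file name (``000.tif``, ``001.tif``, ...).
``raw_headered``
    A raw binary dump plus a small text sidecar (``<file>.hdr``) declaring
    dims, dtype and voxel size, so the file is self-describing.

Binary masks are serialized as 8-bit 0/255 for viewer compatibility; all
round trips are lossless (bit-exact for integer volumes).

Network tables
--------------
``tsv``
    ``nodes.tsv`` (pore_id, cx_um, cy_um, cz_um, radius_um, volume_um3,
    coordination) and ``links.tsv`` (throat_id, pore_a, pore_b, radius_um,
    length_um, volume_um3), with ``#``-prefixed header lines carrying the
    voxel size, void voxel count and extraction parameters.
``statoil_like``
    The conventional four-file node/link layout (``*_node1.dat``,
    ``*_node2.dat``, ``*_link1.dat``, ``*_link2.dat``) with the same fields,
    for interoperability with existing pore-network tools, plus a
    ``network_meta.txt`` sidecar.  Shape-factor/clay columns used by some
    consumers are emitted as zeros.
"""

from __future__ import annotations

import json
import os
import re
from pathlib import Path

import numpy as np
import tifffile

from .network import Pore, PoreNetwork, Throat
from .volumes import BinaryVolume, GrayscaleVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_network_tables",
    "read_network_tables",
]

VOLUME_FORMATS = ("tiff_stack", "tiff_dir", "raw_headered")
NETWORK_DIALECTS = ("tsv", "statoil_like")

_SUPPORTED_DTYPES = {"uint8", "int8", "uint16", "int16", "float32", "float64"}

# full repr precision so float round trips are exact
_F = "%.17g"


def _check_dtype(dtype: np.dtype, path) -> None:
    if dtype.name not in _SUPPORTED_DTYPES:
        raise ValueError(f"unsupported bit depth {dtype} in {path}")


def _numeric_key(name: str):
    m = re.search(r"(\d+)", Path(name).stem)
    return (int(m.group(1)) if m else -1, name)


def read_volume(path, voxel_size_um=None, format: str = "tiff_stack") -> GrayscaleVolume:
    """Load a 3D grayscale volume; no intensity rescaling is performed.

    ``voxel_size_um`` is required for the TIFF formats; for ``raw_headered``
    it is read from the sidecar (an explicit argument must then agree).
    """
    path = Path(path)
    if format not in VOLUME_FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {VOLUME_FORMATS}")
    if not path.exists():
        raise FileNotFoundError(str(path))

    if format == "tiff_stack":
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        _check_dtype(data.dtype, path)
    elif format == "tiff_dir":
        if not path.is_dir():
            raise NotADirectoryError(str(path))
        names = sorted(
            (n for n in os.listdir(path) if n.lower().endswith((".tif", ".tiff"))),
            key=_numeric_key,
        )
        if not names:
            raise FileNotFoundError(f"no TIFF slices in {path}")
        slices = []
        for n in names:
            s = tifffile.imread(path / n)
            if s.ndim != 2:
                raise ValueError(f"slice {n} is not 2D")
            if slices and s.shape != slices[0].shape:
                raise ValueError(
                    f"inconsistent slice shapes: {n} is {s.shape}, "
                    f"expected {slices[0].shape}"
                )
            slices.append(s)
        data = np.stack(slices)
        _check_dtype(data.dtype, path)
    else:  # raw_headered
        header = _read_raw_header(Path(str(path) + ".hdr"))
        dims = header["dims"]
        dtype = np.dtype(header["dtype"])
        _check_dtype(dtype, path)
        expected = int(np.prod(dims)) * dtype.itemsize
        actual = path.stat().st_size
        if actual != expected:
            raise ValueError(
                f"raw file size {actual} does not match header "
                f"dims {dims} x {dtype} = {expected} bytes"
            )
        data = np.fromfile(path, dtype=dtype).reshape(dims)
        hdr_voxel = header["voxel_size_um"]
        if voxel_size_um is not None and not np.isclose(voxel_size_um, hdr_voxel):
            raise ValueError(
                f"voxel_size_um argument {voxel_size_um} conflicts with "
                f"header value {hdr_voxel}"
            )
        voxel_size_um = hdr_voxel

    if voxel_size_um is None:
        raise ValueError("voxel_size_um is required for TIFF formats")
    return GrayscaleVolume(data, voxel_size_um, provenance=f"{format}:{path}")


def write_volume(volume, path, format: str = "tiff_stack") -> None:
    """Write a grayscale volume or binary mask (masks become 0/255 uint8)."""
    path = Path(path)
    if format not in VOLUME_FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {VOLUME_FORMATS}")
    if isinstance(volume, BinaryVolume):
        data = np.where(volume.mask, 255, 0).astype(np.uint8)
    elif isinstance(volume, GrayscaleVolume):
        data = volume.data
    else:
        raise TypeError(f"cannot write {type(volume).__name__}")
    _check_dtype(data.dtype, path)

    if format == "tiff_stack":
        tifffile.imwrite(path, data)
    elif format == "tiff_dir":
        path.mkdir(parents=True, exist_ok=True)
        width = max(3, len(str(data.shape[0] - 1)))
        for z in range(data.shape[0]):
            tifffile.imwrite(path / f"{z:0{width}d}.tif", data[z])
    else:  # raw_headered
        path.parent.mkdir(parents=True, exist_ok=True)
        data.tofile(path)
        _write_raw_header(
            Path(str(path) + ".hdr"), data.shape, data.dtype, volume.voxel_size_um
        )


def read_mask(path, voxel_size_um=None, format: str = "tiff_stack") -> BinaryVolume:
    """Read a serialized binary mask (nonzero = void)."""
    g = read_volume(path, voxel_size_um, format)
    return BinaryVolume(g.data > 0, g.voxel_size_um, provenance=g.provenance)


def _write_raw_header(hdr_path: Path, dims, dtype, voxel_size_um: float) -> None:
    hdr_path.write_text(
        "dims: %d %d %d\ndtype: %s\nvoxel_size_um: %s\n"
        % (dims[0], dims[1], dims[2], np.dtype(dtype).name, _F % voxel_size_um)
    )


def _read_raw_header(hdr_path: Path) -> dict:
    if not hdr_path.exists():
        raise FileNotFoundError(f"missing raw header sidecar {hdr_path}")
    out: dict = {}
    for line in hdr_path.read_text().splitlines():
        line = line.strip()
        if not line or ":" not in line:
            continue
        key, _, val = line.partition(":")
        key, val = key.strip(), val.strip()
        if key == "dims":
            out["dims"] = tuple(int(x) for x in val.split())
        elif key == "dtype":
            out["dtype"] = val
        elif key == "voxel_size_um":
            out["voxel_size_um"] = float(val)
    for req in ("dims", "dtype", "voxel_size_um"):
        if req not in out:
            raise ValueError(f"raw header {hdr_path} missing field {req!r}")
    return out


# ---------------------------------------------------------------------------
# network tables


def write_network_tables(network: PoreNetwork, dir_path, dialect: str = "tsv") -> None:
    if dialect not in NETWORK_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    network.validate()
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    if dialect == "tsv":
        _write_tsv(network, dir_path)
    else:
        _write_statoil_like(network, dir_path)


def read_network_tables(dir_path, dialect: str = "tsv") -> PoreNetwork:
    if dialect not in NETWORK_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    dir_path = Path(dir_path)
    if dialect == "tsv":
        return _read_tsv(dir_path)
    return _read_statoil_like(dir_path)


def _center_um(p: Pore, vox: float):
    # emitted as (x, y, z) columns; internal order is (z, y, x)
    z, y, x = ((c + 0.5) * vox for c in p.center)
    return x, y, z


def _center_from_um(cx: float, cy: float, cz: float, vox: float):
    idx = tuple(int(round(c / vox - 0.5)) for c in (cz, cy, cx))
    return idx


_META_KEYS = ("voxel_size_um", "void_voxel_count", "extraction_params")


def _meta_lines(network: PoreNetwork, prefix: str):
    yield f"{prefix}voxel_size_um\t{_F % network.voxel_size_um}"
    yield f"{prefix}void_voxel_count\t{network.void_voxel_count}"
    yield f"{prefix}extraction_params\t{json.dumps(network.extraction_params, sort_keys=True)}"


def _parse_meta(lines) -> dict:
    meta: dict = {}
    for line in lines:
        parts = line.split("\t", 1)
        if len(parts) != 2:
            continue
        key, val = parts[0].lstrip("# "), parts[1]
        if key == "voxel_size_um":
            meta[key] = float(val)
        elif key == "void_voxel_count":
            meta[key] = int(val)
        elif key == "extraction_params":
            meta[key] = json.loads(val)
    return meta


def _write_tsv(network: PoreNetwork, dir_path: Path) -> None:
    vox = network.voxel_size_um
    with open(dir_path / "nodes.tsv", "w") as f:
        for line in _meta_lines(network, "# "):
            f.write(line + "\n")
        f.write("pore_id\tcx_um\tcy_um\tcz_um\tradius_um\tvolume_um3\tcoordination\n")
        for p in sorted(network.pores, key=lambda p: p.id):
            cx, cy, cz = _center_um(p, vox)
            f.write(
                "%d\t%s\t%s\t%s\t%s\t%s\t%d\n"
                % (p.id, _F % cx, _F % cy, _F % cz, _F % p.radius_um,
                   _F % p.volume_um3, p.coordination)
            )
    with open(dir_path / "links.tsv", "w") as f:
        f.write("throat_id\tpore_a\tpore_b\tradius_um\tlength_um\tvolume_um3\n")
        for t in sorted(network.throats, key=lambda t: t.id):
            f.write(
                "%d\t%d\t%d\t%s\t%s\t%s\n"
                % (t.id, t.pore_a, t.pore_b, _F % t.radius_um, _F % t.length_um,
                   _F % t.volume_um3)
            )


def _read_tsv(dir_path: Path) -> PoreNetwork:
    nodes_path = dir_path / "nodes.tsv"
    links_path = dir_path / "links.tsv"
    for p in (nodes_path, links_path):
        if not p.exists():
            raise FileNotFoundError(str(p))
    meta_lines = []
    pores = []
    with open(nodes_path) as f:
        header = None
        for line in f:
            line = line.rstrip("\n")
            if line.startswith("#"):
                meta_lines.append(line)
                continue
            if header is None:
                header = line.split("\t")
                continue
            vals = line.split("\t")
            row = dict(zip(header, vals))
            pores.append(row)
    meta = _parse_meta(meta_lines)
    if "voxel_size_um" not in meta:
        raise ValueError(f"{nodes_path} is missing voxel_size_um metadata")
    vox = meta["voxel_size_um"]
    pore_objs = [
        Pore(
            id=int(r["pore_id"]),
            center=_center_from_um(
                float(r["cx_um"]), float(r["cy_um"]), float(r["cz_um"]), vox
            ),
            radius_um=float(r["radius_um"]),
            volume_um3=float(r["volume_um3"]),
            coordination=int(r["coordination"]),
        )
        for r in pores
    ]
    known = {p.id for p in pore_objs}
    throat_objs = []
    with open(links_path) as f:
        header = None
        for line in f:
            line = line.rstrip("\n")
            if line.startswith("#") or not line:
                continue
            if header is None:
                header = line.split("\t")
                continue
            r = dict(zip(header, line.split("\t")))
            a, b = int(r["pore_a"]), int(r["pore_b"])
            for pid in (a, b):
                if pid not in known:
                    raise ValueError(f"throat {r['throat_id']} references unknown pore id {pid}")
            throat_objs.append(
                Throat(
                    id=int(r["throat_id"]), pore_a=a, pore_b=b,
                    radius_um=float(r["radius_um"]),
                    length_um=float(r["length_um"]),
                    volume_um3=float(r["volume_um3"]),
                )
            )
    return PoreNetwork(
        pores=pore_objs,
        throats=throat_objs,
        voxel_size_um=vox,
        void_voxel_count=meta.get("void_voxel_count", 0),
        extraction_params=meta.get("extraction_params", {}),
    )


def _write_statoil_like(network: PoreNetwork, dir_path: Path, prefix: str = "network") -> None:
    vox = network.voxel_size_um
    nz = max((p.center[0] for p in network.pores), default=0) + 1
    ny = max((p.center[1] for p in network.pores), default=0) + 1
    nx = max((p.center[2] for p in network.pores), default=0) + 1
    incident: dict[int, list] = {p.id: [] for p in network.pores}
    for t in sorted(network.throats, key=lambda t: t.id):
        incident[t.pore_a].append((t.pore_b, t.id))
        incident[t.pore_b].append((t.pore_a, t.id))
    with open(dir_path / f"{prefix}_node1.dat", "w") as f:
        f.write("%d %s %s %s\n" % (len(network.pores), _F % (nx * vox),
                                   _F % (ny * vox), _F % (nz * vox)))
        for p in sorted(network.pores, key=lambda p: p.id):
            cx, cy, cz = _center_um(p, vox)
            fields = ["%d" % p.id, _F % cx, _F % cy, _F % cz, "%d" % p.coordination]
            fields += ["%d" % nb for nb, _ in incident[p.id]]
            fields += ["0", "0"]  # inlet/outlet flags, unused
            fields += ["%d" % tid for _, tid in incident[p.id]]
            f.write(" ".join(fields) + "\n")
    with open(dir_path / f"{prefix}_node2.dat", "w") as f:
        for p in sorted(network.pores, key=lambda p: p.id):
            f.write("%d %s %s 0 0\n" % (p.id, _F % p.volume_um3, _F % p.radius_um))
    with open(dir_path / f"{prefix}_link1.dat", "w") as f:
        f.write("%d\n" % len(network.throats))
        for t in sorted(network.throats, key=lambda t: t.id):
            f.write("%d %d %d %s 0 %s\n" % (t.id, t.pore_a, t.pore_b,
                                            _F % t.radius_um, _F % t.length_um))
    with open(dir_path / f"{prefix}_link2.dat", "w") as f:
        for t in sorted(network.throats, key=lambda t: t.id):
            f.write("%d %d %d 0 0 %s %s 0\n" % (t.id, t.pore_a, t.pore_b,
                                                _F % t.length_um, _F % t.volume_um3))
    with open(dir_path / "network_meta.txt", "w") as f:
        for line in _meta_lines(network, ""):
            f.write(line + "\n")


def _read_statoil_like(dir_path: Path, prefix: str = "network") -> PoreNetwork:
    paths = {k: dir_path / f"{prefix}_{k}.dat" for k in ("node1", "node2", "link1", "link2")}
    for p in paths.values():
        if not p.exists():
            raise FileNotFoundError(str(p))
    meta_path = dir_path / "network_meta.txt"
    meta = _parse_meta(meta_path.read_text().splitlines()) if meta_path.exists() else {}
    if "voxel_size_um" not in meta:
        raise ValueError(f"missing or incomplete {meta_path}")
    vox = meta["voxel_size_um"]

    node1 = paths["node1"].read_text().splitlines()
    n_pores = int(node1[0].split()[0])
    pores = {}
    for line in node1[1 : 1 + n_pores]:
        tok = line.split()
        pid = int(tok[0])
        cx, cy, cz = float(tok[1]), float(tok[2]), float(tok[3])
        coord = int(tok[4])
        pores[pid] = Pore(
            id=pid, center=_center_from_um(cx, cy, cz, vox),
            radius_um=0.0, volume_um3=0.0, coordination=coord,
        )
    for line in paths["node2"].read_text().splitlines():
        tok = line.split()
        pid = int(tok[0])
        if pid not in pores:
            raise ValueError(f"node2 row references unknown pore id {pid}")
        pores[pid].volume_um3 = float(tok[1])
        pores[pid].radius_um = float(tok[2])

    link1 = paths["link1"].read_text().splitlines()
    n_throats = int(link1[0].split()[0])
    throats = {}
    for line in link1[1 : 1 + n_throats]:
        tok = line.split()
        tid, a, b = int(tok[0]), int(tok[1]), int(tok[2])
        for pid in (a, b):
            if pid not in pores:
                raise ValueError(f"throat {tid} references unknown pore id {pid}")
        throats[tid] = Throat(
            id=tid, pore_a=a, pore_b=b, radius_um=float(tok[3]),
            length_um=float(tok[5]), volume_um3=0.0,
        )
    for line in paths["link2"].read_text().splitlines():
        tok = line.split()
        tid = int(tok[0])
        if tid not in throats:
            raise ValueError(f"link2 row references unknown throat id {tid}")
        throats[tid].volume_um3 = float(tok[6])

    return PoreNetwork(
        pores=[pores[k] for k in sorted(pores)],
        throats=[throats[k] for k in sorted(throats)],
        voxel_size_um=vox,
        void_voxel_count=meta.get("void_voxel_count", 0),
        extraction_params=meta.get("extraction_params", {}),
    )
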