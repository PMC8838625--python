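"""Round-trip and ordering contracts for volume and network-table IO."""

import numpy as np
import pytest
import tifffile

from lipovoid.io import (NETWORK_DIALECTS, read_mask, read_network_tables,
                         read_volume, write_network_tables, write_volume)
from lipovoid.network import Pore, PoreNetwork, Throat
from lipovoid.volumes import BinaryVolume, GrayscaleVolume


def test_zero_stack_identity(tmp_path):
    path = tmp_path / "zeros.tif"
    tifffile.imwrite(path, np.zeros((3, 4, 4), np.uint8))
    vol = read_volume(path, voxel_size_um=15.0, format="tiff_stack")
    assert vol.dims == (3, 4, 4)
    assert vol.voxel_size_um == 15.0
    assert not vol.data.any()


@pytest.mark.parametrize("fmt", ["tiff_stack", "tiff_dir", "raw_headered"])
def test_grayscale_roundtrip_bit_identical(tmp_path, rng, fmt):
    data = rng.integers(0, 2**16, (8, 8, 8), dtype=np.uint16)
    vol = GrayscaleVolume(data, 17.69)
    path = tmp_path / ("vol" if fmt == "tiff_dir" else "vol.bin")
    write_volume(vol, path, fmt)
    back = read_volume(path, None if fmt == "raw_headered" else 17.69, fmt)
    np.testing.assert_array_equal(back.data, data)
    assert back.voxel_size_um == pytest.approx(17.69)


@pytest.mark.parametrize("fmt", ["tiff_stack", "raw_headered"])
def test_binary_mask_roundtrip(tmp_path, rng, fmt):
    mask = rng.random((6, 5, 4)) < 0.3
    bv = BinaryVolume(mask, 14.66)
    path = tmp_path / "mask.bin"
    write_volume(bv, path, fmt)
    back = read_mask(path, None if fmt == "raw_headered" else 14.66, fmt)
    np.testing.assert_array_equal(back.mask, mask)


def test_all_true_mask_roundtrip(tmp_path):
    bv = BinaryVolume(np.ones((2, 2, 2), bool), 16.0)
    path = tmp_path / "m.tif"
    write_volume(bv, path, "tiff_stack")
    assert read_mask(path, 16.0).mask.all()


def test_tiff_dir_slice_order(tmp_path, rng):
    """Slices must load in numeric filename order, not lexicographic."""
    d = tmp_path / "slices"
    d.mkdir()
    slices = [rng.integers(0, 255, (4, 4), dtype=np.uint8) for _ in range(10)]
    # write with names whose lexicographic and numeric order differ
    for i, s in enumerate(slices):
        tifffile.imwrite(d / f"slice_{i}.tif", s)
    vol = read_volume(d, 16.0, "tiff_dir")
    assert vol.dims == (10, 4, 4)
    for i, s in enumerate(slices):
        np.testing.assert_array_equal(vol.data[i], s)


def test_missing_file_and_inconsistent_slices(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_volume(tmp_path / "nope.tif", 16.0)
    d = tmp_path / "bad"
    d.mkdir()
    tifffile.imwrite(d / "000.tif", np.zeros((4, 4), np.uint8))
    tifffile.imwrite(d / "001.tif", np.zeros((5, 4), np.uint8))
    with pytest.raises(ValueError, match="inconsistent slice shapes"):
        read_volume(d, 16.0, "tiff_dir")


def test_unsupported_bit_depth_rejected(tmp_path):
    path = tmp_path / "f64.tif"
    tifffile.imwrite(path, np.zeros((2, 4, 4), np.int32))
    with pytest.raises(ValueError, match="bit depth"):
        read_volume(path, 16.0)


def test_raw_header_size_mismatch(tmp_path):
    vol = GrayscaleVolume(np.zeros((4, 4, 4), np.uint8), 16.0)
    path = tmp_path / "v.raw"
    write_volume(vol, path, "raw_headered")
    path.write_bytes(path.read_bytes()[:-3])
    with pytest.raises(ValueError, match="does not match"):
        read_volume(path, format="raw_headered")


def test_anisotropic_voxels_rejected():
    with pytest.raises(ValueError, match="anisotropic"):
        GrayscaleVolume(np.zeros((2, 2, 2), np.uint8), (1.0, 2.0, 2.0))


# ---------------------------------------------------------------------------
# network tables


def _random_network(rng, n_pores=50, n_throats=40, vox=16.0):
    pores = [
        Pore(id=i + 1,
             center=(int(rng.integers(0, 40)), int(rng.integers(0, 40)),
                     int(rng.integers(0, 40))),
             radius_um=float(rng.uniform(5, 80)),
             volume_um3=float(rng.uniform(1e3, 1e6)),
             coordination=0)
        for i in range(n_pores)
    ]
    throats = []
    tid = 0
    seen = set()
    while len(throats) < n_throats:
        a, b = rng.choice(n_pores, 2, replace=False) + 1
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        tid += 1
        throats.append(Throat(id=tid, pore_a=int(a), pore_b=int(b),
                              radius_um=float(rng.uniform(2, 30)),
                              length_um=float(rng.uniform(16, 300)),
                              volume_um3=float(rng.uniform(1e2, 1e5))))
    inc = {p.id: 0 for p in pores}
    for t in throats:
        inc[t.pore_a] += 1
        inc[t.pore_b] += 1
    for p in pores:
        p.coordination = inc[p.id]
    return PoreNetwork(pores, throats, vox, void_voxel_count=12345,
                       extraction_params={"merge_ratio": 0.7})


@pytest.mark.parametrize("dialect", NETWORK_DIALECTS)
def test_network_roundtrip_full_precision(tmp_path, rng, dialect):
    net = _random_network(rng)
    write_network_tables(net, tmp_path, dialect)
    back = read_network_tables(tmp_path, dialect)
    assert back.voxel_size_um == net.voxel_size_um
    assert back.void_voxel_count == net.void_voxel_count
    assert back.extraction_params == net.extraction_params
    for p, q in zip(net.pores, back.pores):
        assert (p.id, p.center, p.coordination) == (q.id, q.center, q.coordination)
        assert p.radius_um == q.radius_um  # exact: %.17g round trip
        assert p.volume_um3 == q.volume_um3
    for t, u in zip(net.throats, back.throats):
        assert (t.id, t.pore_a, t.pore_b) == (u.id, u.pore_a, u.pore_b)
        assert (t.radius_um, t.length_um, t.volume_um3) == \
            (u.radius_um, u.length_um, u.volume_um3)


@pytest.mark.parametrize("dialect", NETWORK_DIALECTS)
def test_empty_network_tables(tmp_path, dialect):
    net = PoreNetwork([], [], 16.0, 0)
    write_network_tables(net, tmp_path, dialect)
    back = read_network_tables(tmp_path, dialect)
    assert back.pore_count == 0 and back.throat_count == 0


def test_two_pore_network_links_reference_both(tmp_path):
    pores = [Pore(1, (1, 1, 1), 16.0, 4096.0, 1), Pore(2, (1, 1, 5), 16.0, 4096.0, 1)]
    throats = [Throat(1, 1, 2, 8.0, 32.0, 6434.0)]
    net = PoreNetwork(pores, throats, 16.0, 2)
    write_network_tables(net, tmp_path, "tsv")
    text = (tmp_path / "links.tsv").read_text()
    rows = [l for l in text.splitlines() if not l.startswith(("#", "throat_id"))]
    assert len(rows) == 1 and rows[0].split("\t")[1:3] == ["1", "2"]
    back = read_network_tables(tmp_path, "tsv")
    assert back.pores[0].coordination == 1


def test_dangling_throat_reference_fails(tmp_path):
    net = _random_network(np.random.default_rng(0), n_pores=5, n_throats=3)
    write_network_tables(net, tmp_path, "tsv")
    links = (tmp_path / "links.tsv").read_text().replace("\t5\t", "\t99\t")
    (tmp_path / "links.tsv").write_text(links)
    if "\t99\t" in links:
        with pytest.raises(ValueError, match="99"):
            read_network_tables(tmp_path, "tsv")


def test_coordination_column_matches_recount(tmp_path, rng):
    """Emitted coordination equals the incident-throat count from links."""
    net = _random_network(rng, n_pores=20, n_throats=15)
    write_network_tables(net, tmp_path, "tsv")
    nodes = (tmp_path / "nodes.tsv").read_text().splitlines()
    links = (tmp_path / "links.tsv").read_text().splitlines()
    inc: dict[int, int] = {}
    for line in links[1:]:
        _, a, b, *_ = line.split("\t")
        inc[int(a)] = inc.get(int(a), 0) + 1
        inc[int(b)] = inc.get(int(b), 0) + 1
    header_rows = [l for l in nodes if not l.startswith("#")]
    for line in header_rows[1:]:
        f = line.split("\t")
        assert int(f[6]) == inc.get(int(f[0]), 0)


def test_inconsistent_coordination_rejected():
    pores = [Pore(1, (0, 0, 0), 1.0, 1.0, coordination=3)]
    with pytest.raises(ValueError, match="coordination"):
        PoreNetwork(pores, [], 16.0, 1)
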