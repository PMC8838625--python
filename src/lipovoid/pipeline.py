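"""End-to-end orchestration: simulate -> segment -> extract -> metrics -> stats.

A run is driven by a nested key-value config (YAML on disk).  Each stage
writes its outputs plus sidecar metadata into the run directory; the run
manifest lists every artifact with a content checksum, so two runs with
identical config and seed produce byte-identical manifests.  A single
global seed deterministically derives per-stage substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from . import metrics as vm
from . import phantoms, segmentation
from .extraction import extract_network
from .network import PoreNetwork
from .stats import GroupLabel, SampleGroup, compare_groups

__all__ = ["run_pipeline", "export_ball_and_stick", "PipelineError",
            "metrics_to_row", "compare_from_table"]

log = logging.getLogger("lipovoid")

STAGES = ("simulate", "segment", "extract", "metrics", "stats")
_F = "%.17g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def metrics_to_row(m: vm.VoidMetrics) -> dict:
    return {
        "v": m.v, "z": m.z, "r43_pore_um": m.r43_pore_um,
        "r43_throat_um": m.r43_throat_um,
        "micropore_fraction": m.micropore_fraction,
        "pore_count": m.pore_count, "throat_count": m.throat_count,
    }


def run_pipeline(config: dict, outdir=None) -> dict:
    """Execute the configured stages in order and return the run manifest.

    ``config`` keys: ``stages`` (ordered subset of simulate/segment/extract/
    metrics/stats), ``seed``, ``outdir`` (overridable by the argument), and
    one parameter block per stage.  Every referenced input must exist on
    disk or be produced by an earlier stage of the same run.
    """
    config = dict(config)
    outdir = Path(outdir or config.get("outdir", "lipovoid_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", []))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")
    order = [s for s in STAGES if s in stages]

    state: dict = {"voxel_size_um": None}
    artifacts: list[Path] = []
    timings: dict[str, float] = {}
    status = "ok"
    failed_stage = None
    # outdir is run-location metadata, not configuration: leaving it out keeps
    # resolved configs (and hence manifests) identical across run directories
    resolved = {"seed": seed, "stages": order}

    try:
        for stage in order:
            t0 = time.monotonic()
            log.info("stage %s: start", stage)
            block = dict(config.get(stage, {}) or {})
            runner = globals()[f"_stage_{stage}"]
            resolved[stage] = runner(block, state, outdir, artifacts, seed)
            timings[stage] = round(time.monotonic() - t0, 3)
            log.info("stage %s: done in %.2fs", stage, timings[stage])
    except Exception as exc:  # noqa: BLE001 - halt with the failing stage named
        status = "failed"
        failed_stage = stage
        manifest = _finish_manifest(outdir, artifacts, resolved, status,
                                    failed_stage, timings)
        raise PipelineError(stage, exc) from exc

    return _finish_manifest(outdir, artifacts, resolved, status, failed_stage,
                            timings)


def _finish_manifest(outdir, artifacts, resolved, status, failed_stage, timings):
    _write_json(outdir / "config_resolved.json", resolved)
    (outdir / "config_resolved.yaml").write_text(
        yaml.safe_dump(resolved, sort_keys=True))
    artifacts = artifacts + [outdir / "config_resolved.json",
                             outdir / "config_resolved.yaml"]
    manifest = {
        "status": status,
        "failed_stage": failed_stage,
        "artifacts": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(artifacts))
        },
    }
    _write_json(outdir / "manifest.json", manifest)
    manifest["timings_s"] = timings  # informational; excluded from the file
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(block, state, outdir, artifacts, seed):
    spec_dict = dict(block.get("phantom", {}))
    spec_dict.setdefault("seed", _stage_seed(seed, "simulate"))
    spec = phantoms.spec_from_dict(spec_dict)
    truth = phantoms.generate(spec)
    mask_path = outdir / "truth_mask.tif"
    vio.write_volume(truth.binary, mask_path, "tiff_stack")
    feat_path = outdir / "truth_features.json"
    _write_json(feat_path, {
        "morphology": spec.morphology,
        "true_void_fraction": truth.true_void_fraction,
        "features": truth.feature_log,
    })
    artifacts += [mask_path, feat_path]
    state["truth_mask"] = truth.binary
    state["voxel_size_um"] = spec.voxel_size_um
    resolved = {"phantom": spec_dict}
    render = block.get("render")
    if render is not None:
        render = dict(render)
        render.setdefault("seed", _stage_seed(seed, "render"))
        gray = phantoms.render_grayscale(truth, **render)
        gray_path = outdir / "grayscale.tif"
        vio.write_volume(gray, gray_path, "tiff_stack")
        artifacts.append(gray_path)
        state["grayscale"] = gray
        resolved["render"] = render
    return resolved


def _stage_segment(block, state, outdir, artifacts, seed):
    block = dict(block)
    inp = block.pop("input", None)
    if inp is not None:
        vol = vio.read_volume(inp, block.pop("voxel_size_um", None),
                              block.pop("format", "tiff_stack"))
    elif "grayscale" in state:
        vol = state["grayscale"]
    else:
        raise ValueError("segment stage needs an 'input' volume or a prior "
                         "simulate stage with rendering")
    method = block.pop("method", "valley")
    void_is = block.pop("void_is", "dark")
    bandwidth = int(block.pop("bandwidth", 5))
    if block:
        raise ValueError(f"unknown segment options {sorted(block)}")
    if method == "valley":
        res = segmentation.histogram_valley_threshold(vol, bandwidth, void_is)
    elif method == "consensus":
        res = segmentation.consensus_threshold(vol, void_is, bandwidth)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    mask_path = outdir / "segmented_mask.tif"
    vio.write_volume(res.binary, mask_path, "tiff_stack")
    diag_path = outdir / "segmentation.json"
    _write_json(diag_path, {
        "threshold": res.threshold, "method": res.method,
        "diagnostics": res.diagnostics,
    })
    artifacts += [mask_path, diag_path]
    state["mask"] = res.binary
    state["voxel_size_um"] = vol.voxel_size_um
    return {"method": method, "void_is": void_is, "bandwidth": bandwidth}


def _stage_extract(block, state, outdir, artifacts, seed):
    block = dict(block)
    inp = block.pop("input", None)
    if inp is not None:
        mask = vio.read_mask(inp, block.pop("voxel_size_um", None),
                             block.pop("format", "tiff_stack"))
    elif "mask" in state:
        mask = state["mask"]
    elif "truth_mask" in state:
        mask = state["truth_mask"]
    else:
        raise ValueError("extract stage needs an 'input' mask or a prior stage")
    merge_ratio = float(block.pop("merge_ratio", 0.7))
    min_r = block.pop("min_pore_radius_um", None)
    dialect = block.pop("dialect", "tsv")
    if block:
        raise ValueError(f"unknown extract options {sorted(block)}")
    net = extract_network(mask, merge_ratio=merge_ratio,
                          min_pore_radius_um=min_r)
    net_dir = outdir / "network"
    vio.write_network_tables(net, net_dir, dialect)
    params_path = outdir / "extraction_params.json"
    _write_json(params_path, net.extraction_params)
    artifacts += sorted(net_dir.iterdir()) + [params_path]
    state["network"] = net
    state["mask_for_metrics"] = mask
    return {"merge_ratio": merge_ratio, "min_pore_radius_um": min_r,
            "dialect": dialect}


def _stage_metrics(block, state, outdir, artifacts, seed):
    block = dict(block)
    net_dir = block.pop("network", None)
    mask_in = block.pop("mask", None)
    dialect = block.pop("dialect", "tsv")
    bin_um = float(block.pop("bin_um", 5.0))
    if net_dir is not None:
        net = vio.read_network_tables(net_dir, dialect)
    elif "network" in state:
        net = state["network"]
    else:
        raise ValueError("metrics stage needs a 'network' dir or a prior extract")
    if mask_in is not None:
        mask = vio.read_mask(mask_in, block.pop("voxel_size_um", None),
                             block.pop("format", "tiff_stack"))
    elif "mask_for_metrics" in state:
        mask = state["mask_for_metrics"]
    else:
        raise ValueError("metrics stage needs a 'mask' or a prior stage")
    if block:
        raise ValueError(f"unknown metrics options {sorted(block)}")
    m = vm.compute_metrics(net, mask, bin_um)
    row = metrics_to_row(m)
    tsv_path = outdir / "metrics.tsv"
    with open(tsv_path, "w") as f:
        f.write("\t".join(row) + "\n")
        f.write("\t".join(
            ("%d" % v) if isinstance(v, int) else (_F % v) for v in row.values()
        ) + "\n")
    artifacts.append(tsv_path)
    for name, dist in (
        ("coordination", m.coord_distribution),
        ("pore_radius", m.pore_radius_distribution),
        ("throat_radius", m.throat_radius_distribution),
    ):
        p = outdir / f"distribution_{name}.tsv"
        key_col = "coordination" if name == "coordination" else "bin_center_um"
        with open(p, "w") as f:
            f.write(f"{key_col}\trelative_frequency\n")
            for k in sorted(dist):
                f.write(f"{_F % k}\t{_F % dist[k]}\n")
        artifacts.append(p)
    state["metrics"] = m
    return {"bin_um": bin_um}


def compare_from_table(
    table: pd.DataFrame,
    metric: str,
    base_fat: str,
    alpha: float = 0.05,
):
    """Build SampleGroups from a replicate table and compare one metric.

    The table needs columns ``base_fat``, ``emulsifier``, ``shear_type``
    and the metric column; each row is one replicate.
    """
    sub = table[table["base_fat"] == base_fat]
    if sub.empty:
        raise ValueError(f"no rows with base_fat == {base_fat!r}")
    groups = []
    for (emu, shear), rows in sub.groupby(["emulsifier", "shear_type"], sort=True):
        label = GroupLabel(base_fat=base_fat, emulsifier=bool(emu),
                           shear_type=str(shear))
        groups.append(SampleGroup(label, rows[metric].tolist()))
    groups.sort(key=lambda g: str(g.label))
    return compare_groups(groups, metric_name=metric, alpha=alpha)


def _stage_stats(block, state, outdir, artifacts, seed):
    block = dict(block)
    table_path = block.pop("metrics_table", None)
    if table_path is None:
        raise ValueError("stats stage needs 'metrics_table' (replicate TSV)")
    base_fat = block.pop("base_fat")
    metric_cols = block.pop("metrics", ["v", "z", "r43_pore_um", "r43_throat_um"])
    alpha = float(block.pop("alpha", 0.05))
    if block:
        raise ValueError(f"unknown stats options {sorted(block)}")
    table = pd.read_csv(table_path, sep="\t")
    comp_path = outdir / "comparisons.tsv"
    diag = {}
    with open(comp_path, "w") as f:
        f.write("metric\tgroup\tmean\tsd\tletter\n")
        for metric in metric_cols:
            res = compare_from_table(table, metric, base_fat, alpha)
            for gname in sorted(res.letters):
                f.write("%s\t%s\t%s\t%s\t%s\n" % (
                    metric, gname, _F % res.means[gname], _F % res.sds[gname],
                    res.letters[gname]))
            diag[metric] = {
                "branch": res.branch,
                "factor_p_values": res.factor_p_values,
                "pairwise_p_values": {f"{a} vs {b}": p for (a, b), p
                                      in sorted(res.pairwise_p_values.items())},
                "homoscedasticity": res.homoscedasticity,
                "warnings": res.warnings,
            }
    diag_path = outdir / "stats_diagnostics.json"
    _write_json(diag_path, diag)
    artifacts += [comp_path, diag_path]
    return {"metrics_table": str(table_path), "base_fat": base_fat,
            "metrics": metric_cols, "alpha": alpha}


# ---------------------------------------------------------------------------
# visualization export


def export_ball_and_stick(network: PoreNetwork, path) -> None:
    """Write a renderer-neutral ball-and-stick scene description.

    One record per pore (sphere) and throat (cylinder between the two pore
    centres), each with a colour scalar equal to log10 of its radius in um,
    matching the conventional log-scale radius colouring.  Records are
    ordered by id.
    """
    path = Path(path)
    with open(path, "w") as f:
        f.write("# ball-and-stick scene; lengths in um; color = log10(radius_um)\n")
        f.write("kind\tid\tx_um\ty_um\tz_um\tx2_um\ty2_um\tz2_um\tradius_um\tcolor\n")
        centers = {}
        for p in sorted(network.pores, key=lambda p: p.id):
            z, y, x = network.pore_center_um(p)
            centers[p.id] = (x, y, z)
            f.write("sphere\t%d\t%s\t%s\t%s\t\t\t\t%s\t%s\n" % (
                p.id, _F % x, _F % y, _F % z, _F % p.radius_um,
                _F % np.log10(p.radius_um)))
        for t in sorted(network.throats, key=lambda t: t.id):
            x1, y1, z1 = centers[t.pore_a]
            x2, y2, z2 = centers[t.pore_b]
            f.write("cylinder\t%d\t%s\t%s\t%s\t%s\t%s\t%s\t%s\t%s\n" % (
                t.id, _F % x1, _F % y1, _F % z1, _F % x2, _F % y2, _F % z2,
                _F % t.radius_um, _F % np.log10(t.radius_um)))
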