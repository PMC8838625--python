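"""Quantitative void descriptors of a pore network and its mask.

The headline quantities for one replicate are the void fraction ``v``
(void voxels over total voxels), the connectivity ``z`` (mean pore
coordination number, identically ``2T/P``), and the volume-weighted mean
pore and throat radii ``R_43`` — each feature's radius weighted by its
occupied volume, which for spherical features (volume proportional to
``r^3``) reduces to the De Brouckere mean ``sum(r^4)/sum(r^3)``.  Radius
distributions are binned by volume into 5-um bins centred on multiples of
5 um; void features with radius >= 10 um are classified as micropores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import PoreNetwork
from .volumes import BinaryVolume

__all__ = [
    "VoidMetrics",
    "void_fraction",
    "connectivity",
    "coordination_distribution",
    "r43",
    "weighted_radius_distribution",
    "classify_micropores",
    "average_replicate_distributions",
    "summarize_replicates",
    "compute_metrics",
    "MICROPORE_RADIUS_UM",
]

#: Features with radius at or above this bound count as micropores
#: (boundary inclusive).
MICROPORE_RADIUS_UM = 10.0


def void_fraction(binary: BinaryVolume) -> float:
    """Void voxel count over total voxel count."""
    return binary.void_voxel_count / binary.mask.size


def connectivity(network: PoreNetwork) -> float:
    """Mean pore coordination number z; equals 2T/P by the degree identity."""
    if not network.pores:
        raise ValueError("connectivity is undefined for an empty network")
    return float(np.mean([p.coordination for p in network.pores]))


def coordination_distribution(network: PoreNetwork) -> dict[int, float]:
    """Relative frequency of each observed coordination number (sums to 1)."""
    if not network.pores:
        raise ValueError("empty network")
    vals, counts = np.unique([p.coordination for p in network.pores],
                             return_counts=True)
    n = counts.sum()
    return {int(v): float(c) / n for v, c in zip(vals, counts)}


def _features(features) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(list(features), dtype=float)
    if arr.size == 0:
        raise ValueError("empty feature list")
    radii, volumes = arr[:, 0], arr[:, 1]
    if np.any(volumes <= 0):
        raise ValueError("feature volumes must be positive")
    return radii, volumes


def r43(features) -> float:
    """Volume-weighted mean radius: sum(V_i r_i) / sum(V_i).

    ``features`` is an iterable of ``(radius_um, volume_um3)`` pairs.  With
    spherical volumes this is the D[4,3]-type mean sum(r^4)/sum(r^3).
    """
    radii, volumes = _features(features)
    return float(np.sum(volumes * radii) / np.sum(volumes))


def weighted_radius_distribution(
    features, bin_width_um: float = 5.0
) -> dict[float, float]:
    """Volume-weighted radius distribution on tick-centred bins.

    Each feature contributes its volume to the bin whose centre (a multiple
    of ``bin_width_um``) is nearest its radius; half-way ties go to the
    higher bin.  Masses are normalized to sum to 1.
    """
    radii, volumes = _features(features)
    idx = np.floor(radii / bin_width_um + 0.5).astype(int)
    total = volumes.sum()
    out: dict[float, float] = {}
    for i, v in zip(idx, volumes):
        c = float(i * bin_width_um)
        out[c] = out.get(c, 0.0) + float(v) / total
    return dict(sorted(out.items()))


def classify_micropores(features) -> float:
    """Fraction of features (by count) with radius >= 10 um."""
    radii, _ = _features(features)
    return float(np.mean(radii >= MICROPORE_RADIUS_UM))


def micropore_fraction_by_volume(features) -> float:
    """Volume-weighted variant of the micropore fraction."""
    radii, volumes = _features(features)
    return float(volumes[radii >= MICROPORE_RADIUS_UM].sum() / volumes.sum())


def average_replicate_distributions(distributions) -> dict:
    """Per-bin arithmetic mean of replicate relative distributions.

    Bins absent from a replicate contribute zero there.  All replicates
    must share the binning convention (checked via key compatibility:
    numeric keys must lie on a common grid).
    """
    distributions = list(distributions)
    if not distributions:
        raise ValueError("need at least one distribution")
    keys = sorted({k for d in distributions for k in d})
    numeric = [k for k in keys if isinstance(k, (int, float))]
    if len(numeric) > 1:
        diffs = np.diff(sorted(set(numeric)))
        step = np.min(diffs)
        if not np.allclose(diffs / step, np.round(diffs / step)):
            raise ValueError("inconsistent bin origin/width across replicates")
    n = len(distributions)
    return {k: sum(d.get(k, 0.0) for d in distributions) / n for k in keys}


def summarize_replicates(values) -> tuple[float, float]:
    """Replicate mean and sample (n-1) standard deviation.

    A single replicate yields ``(mean, nan)`` — the sd is flagged undefined
    rather than zero.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("no replicate values")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size >= 2 else float("nan")
    return mean, sd


@dataclass
class VoidMetrics:
    """All per-replicate descriptors in one record."""

    v: float
    z: float
    r43_pore_um: float
    r43_throat_um: float
    coord_distribution: dict[int, float]
    pore_radius_distribution: dict[float, float]
    throat_radius_distribution: dict[float, float]
    micropore_fraction: float
    pore_count: int
    throat_count: int


def compute_metrics(
    network: PoreNetwork,
    binary: BinaryVolume,
    bin_width_um: float = 5.0,
) -> VoidMetrics:
    """Compute the full metric set for one replicate.

    Pore weights are assigned-voxel volumes; throat weights are their
    cylinder-model volumes.  The micropore fraction pools pores and throats
    (all void features), by count.
    """
    pore_feats = [(p.radius_um, p.volume_um3) for p in network.pores]
    throat_feats = [(t.radius_um, t.volume_um3) for t in network.throats]
    all_feats = pore_feats + throat_feats
    empty = not network.pores
    return VoidMetrics(
        v=void_fraction(binary),
        z=connectivity(network) if not empty else float("nan"),
        r43_pore_um=r43(pore_feats) if pore_feats else float("nan"),
        r43_throat_um=r43(throat_feats) if throat_feats else float("nan"),
        coord_distribution=coordination_distribution(network) if not empty else {},
        pore_radius_distribution=(
            weighted_radius_distribution(pore_feats, bin_width_um)
            if pore_feats else {}),
        throat_radius_distribution=(
            weighted_radius_distribution(throat_feats, bin_width_um)
            if throat_feats else {}),
        micropore_fraction=classify_micropores(all_feats) if all_feats else float("nan"),
        pore_count=network.pore_count,
        throat_count=network.throat_count,
    )
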