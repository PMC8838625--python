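"""Histogram-valley binarization of grayscale volumes into void vs. solid.

Air attenuates X-rays far less than lipid, so a CT slice histogram shows
two modes — a dark void mode and a bright solid/liquid mode — separated by
a valley.  The primary method locates that valley on a smoothed histogram;
for low-contrast volumes (small voids, partial-volume mixing) a consensus
of the valley and a between-class-variance-maximizing (Otsu) threshold is
used instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu

from .volumes import BinaryVolume, GrayscaleVolume

__all__ = [
    "SegmentationResult",
    "NoValleyError",
    "histogram_valley_threshold",
    "consensus_threshold",
]


class NoValleyError(ValueError):
    """Raised when the smoothed histogram has no two-mode valley."""


@dataclass
class SegmentationResult:
    binary: BinaryVolume
    threshold: float
    method: str  # "valley" | "consensus"
    histogram: tuple[np.ndarray, np.ndarray]  # (bin centers, counts)
    diagnostics: dict = field(default_factory=dict)


def _histogram(volume: GrayscaleVolume):
    """Bin width 1 for integer volumes; 256 equal bins for real-valued."""
    data = volume.data
    if data.dtype.kind in "iu":
        lo, hi = int(data.min()), int(data.max())
        centers = np.arange(lo, hi + 1, dtype=float)
        counts = np.bincount((data.ravel() - lo).astype(np.int64),
                             minlength=hi - lo + 1).astype(float)
    else:
        lo, hi = float(data.min()), float(data.max())
        if hi == lo:
            return np.array([lo]), np.array([float(data.size)])
        counts, edges = np.histogram(data.ravel(), bins=256, range=(lo, hi))
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts = counts.astype(float)
    return centers, counts


def _smooth(counts: np.ndarray, bandwidth: int) -> np.ndarray:
    """Symmetric triangular kernel of half-width ``bandwidth`` bins."""
    if bandwidth <= 0:
        return counts.copy()
    j = np.arange(-bandwidth, bandwidth + 1)
    kernel = (bandwidth + 1 - np.abs(j)).astype(float)
    kernel /= kernel.sum()
    return np.convolve(counts, kernel, mode="same")


def _two_modes(smoothed: np.ndarray, total: float):
    """Indices of the two highest-prominence local maxima, or None."""
    floor = 1e-3 * total  # ignore noise spikes below 0.1% of voxel count
    # zero-pad so modes sitting on the histogram edges are detectable
    padded = np.concatenate([[0.0], smoothed, [0.0]])
    peaks, props = find_peaks(padded, prominence=floor)
    if len(peaks) < 2:
        return None
    order = np.argsort(props["prominences"])[::-1][:2]
    two = np.sort(peaks[order]) - 1
    return int(two[0]), int(two[1])


def _valley_between(smoothed: np.ndarray, centers: np.ndarray, lo: int, hi: int):
    """Argmin strictly between the modes; plateau ties -> midpoint."""
    inner = smoothed[lo + 1 : hi]
    if inner.size == 0:
        return None
    vmin = inner.min()
    idx = np.nonzero(inner == vmin)[0]
    # first contiguous run of minimal bins
    run_end = 0
    while run_end + 1 < idx.size and idx[run_end + 1] == idx[run_end] + 1:
        run_end += 1
    i0, i1 = idx[0] + lo + 1, idx[run_end] + lo + 1
    return 0.5 * (centers[i0] + centers[i1]), float(vmin)


def _apply(volume: GrayscaleVolume, threshold: float, void_is: str) -> np.ndarray:
    if void_is == "dark":
        return volume.data <= threshold
    if void_is == "bright":
        return volume.data >= threshold
    raise ValueError(f"void_is must be 'dark' or 'bright', got {void_is!r}")


def histogram_valley_threshold(
    volume: GrayscaleVolume,
    smoothing_bandwidth: int = 5,
    void_is: str = "dark",
) -> SegmentationResult:
    """Threshold at the smoothed-histogram minimum between the two phase modes.

    The intensity histogram is smoothed with a triangular kernel, the two
    most prominent modes are located, and the threshold is placed at the
    minimum of the smoothed counts strictly between them (midpoint of the
    minimal plateau on ties).  Voxels on the ``void_is`` side become void.

    Raises
    ------
    NoValleyError
        If the smoothed histogram is unimodal; ``consensus_threshold`` is
        the recommended fallback.
    """
    if volume.data.size == 0:
        raise ValueError("empty volume")
    centers, counts = _histogram(volume)
    smoothed = _smooth(counts, smoothing_bandwidth)
    modes = _two_modes(smoothed, float(volume.data.size))
    if modes is None:
        raise NoValleyError(
            "no valley: smoothed histogram is unimodal; "
            "try consensus_threshold for low-contrast volumes"
        )
    lo, hi = modes
    valley = _valley_between(smoothed, centers, lo, hi)
    if valley is None:
        raise NoValleyError("no interior bins between the two modes")
    threshold, depth = valley
    mask = _apply(volume, threshold, void_is)
    return SegmentationResult(
        binary=BinaryVolume(mask, volume.voxel_size_um,
                            provenance=f"valley:{volume.provenance}"),
        threshold=float(threshold),
        method="valley",
        histogram=(centers, counts),
        diagnostics={
            "peak_intensities": [float(centers[lo]), float(centers[hi])],
            "peak_counts": [float(smoothed[lo]), float(smoothed[hi])],
            "valley_depth": depth,
            "void_is": void_is,
            "smoothing_bandwidth": smoothing_bandwidth,
        },
    )


def consensus_threshold(
    volume: GrayscaleVolume,
    void_is: str = "dark",
    smoothing_bandwidth: int = 5,
) -> SegmentationResult:
    """Average of the valley and Otsu thresholds (whichever are defined).

    Intended for low-contrast volumes where the valley is shallow or
    absent.  If the valley is undefined the Otsu threshold is used alone;
    a constant volume (neither defined) is an error.
    """
    if volume.data.size == 0:
        raise ValueError("empty volume")
    if volume.data.min() == volume.data.max():
        raise ValueError("constant volume: no threshold is defined")
    estimates = {}
    try:
        valley_res = histogram_valley_threshold(volume, smoothing_bandwidth, void_is)
        estimates["valley"] = valley_res.threshold
    except NoValleyError:
        valley_res = None
    estimates["otsu"] = float(threshold_otsu(volume.data))
    threshold = float(np.mean(list(estimates.values())))
    mask = _apply(volume, threshold, void_is)
    centers, counts = (valley_res.histogram if valley_res is not None
                       else _histogram(volume))
    return SegmentationResult(
        binary=BinaryVolume(mask, volume.voxel_size_um,
                            provenance=f"consensus:{volume.provenance}"),
        threshold=threshold,
        method="consensus",
        histogram=(centers, counts),
        diagnostics={"estimates": estimates, "void_is": void_is},
    )
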