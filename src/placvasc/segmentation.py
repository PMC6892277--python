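"""Histogram-midpoint thresholding of tissue and contrast-filled vessels.

At both imaging scales the same rule applies: the tissue threshold is the
arithmetic midpoint between the air and tissue grey-level peaks, the
contrast (Microfil) threshold the midpoint between the tissue and contrast
peaks.  Peaks are found automatically on a smoothed intensity histogram;
a manual :class:`ThresholdPair` can always be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import ThresholdDetectionError
from .stackio import VolumeImage


@dataclass(frozen=True)
class ThresholdPair:
    """Tissue and contrast thresholds plus the peak locations that set them."""

    tissue_threshold: float
    microfil_threshold: float
    peaks: tuple[float, float, float] = (np.nan, np.nan, np.nan)

    def __post_init__(self) -> None:
        if not self.tissue_threshold < self.microfil_threshold:
            raise ThresholdDetectionError(
                "tissue threshold must be below the contrast threshold"
            )

    @classmethod
    def from_peaks(cls, air: float, tissue: float, contrast: float) -> "ThresholdPair":
        if not air < tissue < contrast:
            raise ThresholdDetectionError("peaks must satisfy air < tissue < contrast")
        return cls(
            tissue_threshold=(air + tissue) / 2.0,
            microfil_threshold=(tissue + contrast) / 2.0,
            peaks=(air, tissue, contrast),
        )


def _smooth(counts: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(counts.astype(float), kernel, mode="same")


def find_histogram_peaks(
    values: np.ndarray, counts: np.ndarray, n_peaks: int = 3
) -> np.ndarray:
    """The ``n_peaks`` most prominent local maxima of a smoothed histogram.

    The smoothing window is 1/64 of the intensity range (odd, >= 3).  On a
    plateau the lowest intensity is taken as the peak location.
    """
    span = float(values[-1] - values[0])
    width = max(3, int(round(span / 64.0)))
    if width % 2 == 0:
        width += 1
    smoothed = _smooth(counts, width)
    idx, props = find_peaks(smoothed, prominence=0.0, plateau_size=(1, None))
    locations = props["left_edges"]  # plateau tie-break: lowest intensity
    if len(idx) < n_peaks:
        raise ThresholdDetectionError(
            f"found {len(idx)} histogram peaks, need {n_peaks}; "
            "supply manual thresholds via config"
        )
    top = np.argsort(props["prominences"])[::-1][:n_peaks]
    return np.sort(values[locations[top]]).astype(float)


def find_thresholds(volume: VolumeImage | np.ndarray) -> ThresholdPair:
    """Locate the air/tissue/contrast peaks and return midpoint thresholds."""
    vox = volume.voxels if isinstance(volume, VolumeImage) else np.asarray(volume)
    lo, hi = int(vox.min()), int(vox.max())
    values = np.arange(lo, hi + 1)
    counts = np.bincount((vox.astype(np.int64) - lo).ravel(), minlength=values.size)
    air, tissue, contrast = find_histogram_peaks(values, counts)
    return ThresholdPair.from_peaks(air, tissue, contrast)


def segment(
    volume: VolumeImage | np.ndarray, thresholds: ThresholdPair
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean tissue and vessel masks; the vessel mask is a subset of the
    tissue mask by construction (contrast is brighter than tissue)."""
    vox = volume.voxels if isinstance(volume, VolumeImage) else np.asarray(volume)
    tissue_mask = vox >= thresholds.tissue_threshold
    vessel_mask = vox >= thresholds.microfil_threshold
    return tissue_mask, vessel_mask
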