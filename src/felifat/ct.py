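"""CT body-composition quantification from Hounsfield-unit histograms.

The measurement chain: mask excludable contents to the air sentinel
(-1024 HU), histogram the soft-tissue window [-250, 250] HU, locate the
fat and lean tissue peaks, split the window at their midpoint, count
bone as voxels >= 350 HU, and convert voxel counts to volumes:

    %BF  = 100 * fat / (fat + lean)
    VV   = pixel_width * pixel_length * slice_thickness   (cm^3)
    BFV  = fat_voxels * VV
    TBBV = bone_voxels * VV
    nBFV = BFV / TBBV

nBFV normalizes fat volume to skeletal size rather than lean mass, so it
is robust to muscle atrophy, and the voxel volume cancels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

AIR_HU = -1024
SOFT_TISSUE_WINDOW = (-250, 250)
BONE_THRESHOLD_HU = 350

# Exclusion-mask label semantics (0 = keep).
LABEL_EXTERNAL = 1  # CT table and external objects > -251 HU
LABEL_LUNG = 2  # non-aerated lung
LABEL_CONTENTS = 3  # GI/stomach contents, bladder urine
LABEL_NONSKELETAL = 4  # implants, microchips, mineralization, calculi

_SOFT_TISSUE_LABELS = (LABEL_EXTERNAL, LABEL_LUNG, LABEL_CONTENTS)
_BONE_LABELS = (LABEL_EXTERNAL, LABEL_LUNG, LABEL_CONTENTS, LABEL_NONSKELETAL)


class UndefinedFatPeakError(ValueError):
    """Fewer than two qualifying tissue peaks in the soft-tissue window.

    Mirrors the situation in very lean animals whose HU histogram lacks a
    defined fat peak; such subjects must be excluded from CT fat
    quantification rather than silently mis-segmented.
    """

    def __init__(self, n_peaks_found: int):
        self.n_peaks_found = n_peaks_found
        super().__init__(
            f"undefined fat peak: found {n_peaks_found} qualifying "
            "histogram peak(s), need 2 (fat and lean)"
        )


@dataclass(frozen=True)
class CTVolume:
    """3D CT grid in integer HU with voxel spacing in cm."""

    hu: np.ndarray
    spacing: tuple[float, float, float]  # (pixel_width, pixel_length, slice_thickness) cm
    cat_id: str = ""

    def __post_init__(self) -> None:
        if self.hu.ndim != 3:
            raise ValueError("hu grid must be 3-dimensional")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (cm)")
        if self.hu.size and int(self.hu.min()) < AIR_HU:
            raise ValueError(f"HU values below the air sentinel {AIR_HU}")

    @property
    def voxel_volume(self) -> float:
        """VV in cm^3."""
        w, l, t = self.spacing
        return w * l * t


@dataclass(frozen=True)
class ExclusionMasks:
    """Integer label grid aligned with a CTVolume (0 = keep)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise ValueError("label grid must be 3-dimensional")


@dataclass(frozen=True)
class HUHistogram:
    """Integer-binned voxel counts over an inclusive HU window."""

    bin_value: np.ndarray  # consecutive integer HU, lo..hi inclusive
    count: np.ndarray
    lo: int
    hi: int

    @property
    def total(self) -> int:
        return int(self.count.sum())


@dataclass(frozen=True)
class TissuePeaks:
    fat_peak_hu: int
    lean_peak_hu: int

    def __post_init__(self) -> None:
        lo, hi = SOFT_TISSUE_WINDOW
        if not (lo <= self.fat_peak_hu < self.lean_peak_hu <= hi):
            raise ValueError(
                "peaks must satisfy "
                f"{lo} <= fat_peak < lean_peak <= {hi}; got "
                f"({self.fat_peak_hu}, {self.lean_peak_hu})"
            )

    @property
    def midpoint_hu(self) -> float:
        """Fat/lean threshold; half-integer when the peak sum is odd."""
        return (self.fat_peak_hu + self.lean_peak_hu) / 2.0


@dataclass(frozen=True)
class BodyComposition:
    """Voxel counts and derived fat/bone metrics for one animal."""

    cat_id: str
    fat_voxels: int
    lean_voxels: int
    bone_voxels: int
    vv: float  # cm^3 per voxel

    @property
    def pbf(self) -> float:
        """Body fat percentage, in [0, 100]."""
        return 100.0 * self.fat_voxels / (self.fat_voxels + self.lean_voxels)

    @property
    def bfv(self) -> float:
        """Body fat volume, cm^3."""
        return self.fat_voxels * self.vv

    @property
    def tbbv(self) -> float:
        """Total body bone volume, cm^3."""
        return self.bone_voxels * self.vv

    @property
    def nbfv(self) -> float:
        """BFV / TBBV; voxel volume cancels exactly."""
        return self.fat_voxels / self.bone_voxels


def apply_exclusions(
    volume: CTVolume, masks: ExclusionMasks, purpose: str
) -> CTVolume:
    """Set excludable regions to the air sentinel -1024 HU.

    purpose="soft_tissue" removes external objects, lung, and GI/bladder
    contents (labels 1-3); purpose="bone" additionally removes
    non-skeletal dense structures such as implants (labels 1-4).
    Returns a new volume; the input is unchanged.
    """
    if purpose == "soft_tissue":
        labels = _SOFT_TISSUE_LABELS
    elif purpose == "bone":
        labels = _BONE_LABELS
    else:
        raise ValueError(f"unknown purpose {purpose!r}")
    if masks.labels.shape != volume.hu.shape:
        raise ValueError(
            f"mask shape {masks.labels.shape} does not match "
            f"volume shape {volume.hu.shape}"
        )
    hu = volume.hu.copy()
    hu[np.isin(masks.labels, labels)] = AIR_HU
    return CTVolume(hu=hu, spacing=volume.spacing, cat_id=volume.cat_id)


def build_histogram(volume: CTVolume, lo: int, hi: int) -> HUHistogram:
    """Integer-binned counts over [lo, hi], inclusive at both ends."""
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    flat = volume.hu.ravel()
    in_window = flat[(flat >= lo) & (flat <= hi)]
    counts = np.bincount(in_window - lo, minlength=hi - lo + 1)
    return HUHistogram(
        bin_value=np.arange(lo, hi + 1), count=counts, lo=lo, hi=hi
    )


def find_tissue_peaks(
    hist: HUHistogram,
    smooth_window: int = 11,
    prominence_fraction: float = 0.005,
    min_separation: int = 30,
) -> TissuePeaks:
    """Locate the fat and lean peaks of a soft-tissue-window histogram.

    Counts are smoothed with a moving average (default 11 HU wide), and
    local maxima with prominence >= ``prominence_fraction`` of the total
    count and mutual separation >= ``min_separation`` HU qualify.  The
    two largest are returned ordered as fat (lower HU) and lean (higher
    HU).

    Raises
    ------
    UndefinedFatPeakError
        When fewer than two maxima qualify, as in very lean subjects
        whose histogram is effectively unimodal.
    """
    counts = hist.count.astype(float)
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(counts, kernel, mode="same")
    total = counts.sum()
    idx, _ = find_peaks(
        smoothed, prominence=prominence_fraction * total, distance=min_separation
    )
    if len(idx) < 2:
        raise UndefinedFatPeakError(len(idx))
    top2 = idx[np.argsort(smoothed[idx])[-2:]]
    fat_i, lean_i = sorted(top2)
    return TissuePeaks(
        fat_peak_hu=int(hist.bin_value[fat_i]),
        lean_peak_hu=int(hist.bin_value[lean_i]),
    )


def classify_soft_tissue(
    hist: HUHistogram, peaks: TissuePeaks
) -> tuple[int, int]:
    """Split the window at the peak midpoint: fat <= midpoint < lean.

    The fat interval is closed at the midpoint; with a half-integer
    midpoint the integer bin just below it is the last fat bin.
    """
    mid = peaks.midpoint_hu
    fat = int(hist.count[hist.bin_value <= mid].sum())
    lean = int(hist.count[hist.bin_value > mid].sum())
    return fat, lean


def count_bone(volume: CTVolume) -> int:
    """Voxels >= 350 HU (bone-purpose exclusions already applied)."""
    return int((volume.hu >= BONE_THRESHOLD_HU).sum())


def compute_composition(
    fat_voxels: int,
    lean_voxels: int,
    bone_voxels: int,
    spacing: tuple[float, float, float],
    cat_id: str = "",
) -> BodyComposition:
    """Assemble the composition metrics from voxel counts and spacing.

    Zero soft tissue or zero bone is an explicit error rather than NaN.
    """
    if fat_voxels + lean_voxels <= 0:
        raise ValueError("no soft-tissue voxels: %BF undefined")
    if bone_voxels <= 0:
        raise ValueError("no bone voxels: TBBV and nBFV undefined")
    w, l, t = spacing
    return BodyComposition(
        cat_id=cat_id,
        fat_voxels=int(fat_voxels),
        lean_voxels=int(lean_voxels),
        bone_voxels=int(bone_voxels),
        vv=w * l * t,
    )


def analyze_volume(
    volume: CTVolume,
    masks: ExclusionMasks,
    smooth_window: int = 11,
    prominence_fraction: float = 0.005,
    min_separation: int = 30,
) -> BodyComposition:
    """Run the full measurement chain on one masked CT volume."""
    soft = apply_exclusions(volume, masks, "soft_tissue")
    hist = build_histogram(soft, *SOFT_TISSUE_WINDOW)
    peaks = find_tissue_peaks(
        hist,
        smooth_window=smooth_window,
        prominence_fraction=prominence_fraction,
        min_separation=min_separation,
    )
    fat, lean = classify_soft_tissue(hist, peaks)
    bone_vol = apply_exclusions(volume, masks, "bone")
    bone = count_bone(bone_vol)
    return compute_composition(fat, lean, bone, volume.spacing, volume.cat_id)
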