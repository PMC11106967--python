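"""Reading, writing and normalising X-ray CT volumes.

Volumes are 3-D scalar grids indexed ``(H, W, D)`` where ``H`` is the
slice/stack axis (slice index 0 = first reconstructed slice).  Three
intensity conventions are used throughout the package:

``raw16``
    Reconstructed 16-bit attenuation values as they come off the scanner.
``gray8``
    8-bit values produced by the peak-anchored rescale: the air histogram
    peak maps to 0 and the soil peak to 128, with clipping to [0, 255].
``unit``
    ``gray8`` divided by 255.0, the range fed to the networks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import imageio.v3 as iio
import nibabel as nib
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

__all__ = [
    "CTVolume",
    "LabelVolume",
    "HistogramPeaks",
    "PeakDetectionError",
    "read_volume",
    "write_volume",
    "find_histogram_peaks",
    "rescale_to_gray8",
    "to_unit",
    "crop_center",
]

_DTYPE_RANGES = {"raw16": (0, 65535), "gray8": (0, 255), "unit": (0.0, 1.0)}


class PeakDetectionError(ValueError):
    """Raised when the air/soil histogram peaks cannot be identified."""


@dataclass
class CTVolume:
    """A 3-D intensity grid with voxel-size and axis-order metadata.

    Parameters
    ----------
    data:
        Array of shape ``(H, W, D)``.
    dtype_tag:
        One of ``raw16``, ``gray8`` or ``unit``.
    voxel_size_mm:
        Isotropic voxel edge length in millimetres (scanner default 0.3).
    origin:
        0-based voxel index of the grid corner in the original scan frame.
    """

    data: np.ndarray
    dtype_tag: str
    voxel_size_mm: float = 0.3
    origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("all axis lengths must be >= 1")
        if self.dtype_tag not in _DTYPE_RANGES:
            raise ValueError(f"unknown dtype_tag {self.dtype_tag!r}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        lo, hi = _DTYPE_RANGES[self.dtype_tag]
        if self.data.size and (self.data.min() < lo or self.data.max() > hi):
            raise ValueError(
                f"{self.dtype_tag} values must lie in [{lo}, {hi}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    def with_data(self, data: np.ndarray, dtype_tag: str | None = None) -> "CTVolume":
        return CTVolume(
            data,
            dtype_tag or self.dtype_tag,
            voxel_size_mm=self.voxel_size_mm,
            origin=self.origin,
        )


@dataclass
class LabelVolume:
    """A Boolean grid congruent with its CT volume; True marks root voxels."""

    data: np.ndarray
    voxel_size_mm: float = 0.3

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3-D, got {self.data.shape}")
        if self.data.dtype != np.bool_:
            uniq = np.unique(self.data)
            if not np.isin(uniq, (0, 1, 255)).all():
                raise ValueError("label values must be Boolean (or 0/255 bytes)")
            self.data = self.data > 0

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]


@dataclass(frozen=True)
class HistogramPeaks:
    """Raw-intensity modes of the bimodal air/soil histogram."""

    air_peak: float
    soil_peak: float

    def __post_init__(self) -> None:
        if not self.air_peak < self.soil_peak:
            raise ValueError("air_peak must be strictly below soil_peak")


# ---------------------------------------------------------------------------
# I/O

_SLICE_EXTENSIONS = {".tif", ".tiff", ".png"}


def _infer_dtype_tag(data: np.ndarray) -> str:
    if data.dtype == np.uint16:
        return "raw16"
    if data.dtype == np.uint8:
        return "gray8"
    if np.issubdtype(data.dtype, np.floating):
        return "unit"
    raise ValueError(f"unsupported bit depth / dtype: {data.dtype}")


def read_volume(
    path: str | os.PathLike,
    format_hint: str | None = None,
    voxel_size_mm: float = 0.3,
) -> CTVolume:
    """Read a CT volume from a TIFF stack, a slice directory or a NIfTI file.

    Slices are stacked along the first (``H``) axis; for a directory the
    lexicographic file order defines the slice order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint or _guess_format(path)
    if fmt == "slice_dir":
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _SLICE_EXTENSIONS
        )
        if not files:
            raise ValueError(f"no slice images found in {path}")
        slices = [iio.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent slice shapes: {sorted(shapes)}")
        data = np.stack(slices, axis=0)
    elif fmt == "nifti":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    elif fmt == "tiff_stack":
        data = tifffile.imread(str(path))
        if data.ndim == 2:  # single-page stack
            data = data[None]
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return CTVolume(data, _infer_dtype_tag(data), voxel_size_mm=voxel_size_mm)


def _guess_format(path: Path) -> str:
    if path.is_dir():
        return "slice_dir"
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    return "tiff_stack"


def write_volume(
    vol: CTVolume | LabelVolume,
    path: str | os.PathLike,
    format: str = "tiff_stack",
) -> None:
    """Write a volume so that :func:`read_volume` recovers an identical grid.

    Label volumes are encoded as 8-bit 0/255 bytes.
    """
    path = Path(path)
    data = vol.data
    if isinstance(vol, LabelVolume):
        data = np.where(data, np.uint8(255), np.uint8(0))
    if format == "tiff_stack":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(str(path), data)
    elif format == "slice_dir":
        path.mkdir(parents=True, exist_ok=True)
        for h in range(data.shape[0]):
            tifffile.imwrite(str(path / f"slice_{h:04d}.tif"), data[h])
    elif format == "nifti":
        path.parent.mkdir(parents=True, exist_ok=True)
        affine = np.diag([vol.voxel_size_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(data, affine), str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_label(path: str | os.PathLike, format_hint: str | None = None) -> LabelVolume:
    """Read a 0/255-encoded label volume back as Boolean."""
    vol = read_volume(path, format_hint)
    return LabelVolume(vol.data > 0, voxel_size_mm=vol.voxel_size_mm)


# ---------------------------------------------------------------------------
# Intensity normalisation

#: number of histogram bins used for peak finding
_N_BINS = 256
#: Gaussian smoothing bandwidth, in bins
_SMOOTH_BINS = 2.0
#: minimum separation between the two modes, in bins
_MIN_SEPARATION = 10


def find_histogram_peaks(vol: CTVolume) -> HistogramPeaks:
    """Locate the air and soil modes of the raw-intensity histogram.

    A 256-bin histogram of the raw values is smoothed with a Gaussian of
    two bins bandwidth; the two tallest local maxima at least ten bins
    apart are taken as the air (lower) and soil (higher) peaks.  For
    integer data the reported peak is refined to the most frequent raw
    value within the winning bin.

    Raises
    ------
    PeakDetectionError
        If fewer than two separated maxima exist (e.g. a unimodal or
        constant volume).
    """
    data = vol.data.ravel()
    vmin, vmax = float(data.min()), float(data.max())
    if vmin == vmax:
        raise PeakDetectionError("constant volume has no bimodal histogram")
    counts, edges = np.histogram(data, bins=_N_BINS, range=(vmin, vmax))
    smoothed = gaussian_filter1d(counts.astype(float), _SMOOTH_BINS)
    # pad so that modes sitting on the first/last bin are still detected;
    # the prominence floor keeps sampling wiggle in a unimodal histogram
    # from masquerading as a second mode
    padded = np.concatenate(([0.0], smoothed, [0.0]))
    idx, _ = find_peaks(
        padded, distance=_MIN_SEPARATION, prominence=0.2 * smoothed.max()
    )
    idx -= 1
    if len(idx) < 2:
        raise PeakDetectionError(
            f"expected a bimodal histogram, found {len(idx)} separated maxima"
        )
    top2 = idx[np.argsort(smoothed[idx])[-2:]]
    lo_bin, hi_bin = int(top2.min()), int(top2.max())
    air = _refine_peak(data, edges, lo_bin)
    soil = _refine_peak(data, edges, hi_bin)
    return HistogramPeaks(air_peak=air, soil_peak=soil)


def _refine_peak(data: np.ndarray, edges: np.ndarray, bin_idx: int) -> float:
    center = 0.5 * (edges[bin_idx] + edges[bin_idx + 1])
    if not np.issubdtype(data.dtype, np.integer):
        return float(center)
    lo, hi = edges[bin_idx], edges[bin_idx + 1]
    in_bin = data[(data >= lo) & (data <= hi)]
    if in_bin.size == 0:
        return float(center)
    values, freq = np.unique(in_bin, return_counts=True)
    return float(values[np.argmax(freq)])


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def rescale_to_gray8(vol: CTVolume, peaks: HistogramPeaks) -> CTVolume:
    """Peak-anchored 16-to-8-bit rescale.

    The air peak maps to 0 and the soil peak to 128; values are rounded
    half-away-from-zero, then clipped to [0, 255].  Clipped values come
    from air or dense mineral contaminants and carry no root information.
    """
    if vol.dtype_tag != "raw16":
        raise ValueError("rescale_to_gray8 expects a raw16 volume")
    span = peaks.soil_peak - peaks.air_peak
    if span <= 0:
        raise ValueError("degenerate peaks: soil_peak must exceed air_peak")
    scaled = 128.0 * (vol.data.astype(np.float64) - peaks.air_peak) / span
    out = np.clip(_round_half_away(scaled), 0, 255).astype(np.uint8)
    return vol.with_data(out, "gray8")


def to_unit(vol: CTVolume) -> CTVolume:
    """Map gray8 values onto [0, 1] by dividing by 255.0."""
    if vol.dtype_tag != "gray8":
        raise ValueError("to_unit expects a gray8 volume")
    return vol.with_data(vol.data.astype(np.float32) / 255.0, "unit")


def crop_center(
    vol: CTVolume,
    radius_mm: float,
    circular_mask: bool = False,
) -> CTVolume:
    """Crop the centred square region of the pot in the W-D plane.

    The crop side is ``2*floor(radius_mm/voxel_size_mm) - 1`` voxels (odd,
    centred on a voxel); the full H extent is kept.  With
    ``circular_mask`` voxels farther than the radius from the plane
    centre are zeroed, otherwise the square prism is returned as-is.
    """
    r_vox = radius_mm / vol.voxel_size_mm
    side = 2 * int(np.floor(r_vox)) - 1
    H, W, D = vol.data.shape
    if side < 1:
        raise ValueError("radius smaller than one voxel")
    if side > min(W, D):
        raise ValueError(
            f"crop side {side} exceeds volume plane ({W}, {D})"
        )
    w0 = W // 2 - side // 2
    d0 = D // 2 - side // 2
    out = vol.data[:, w0 : w0 + side, d0 : d0 + side].copy()
    if circular_mask:
        c = side // 2
        w = np.arange(side) - c
        dist2 = w[:, None] ** 2 + w[None, :] ** 2
        out[:, dist2 > r_vox**2] = 0
    cropped = vol.with_data(out)
    cropped.origin = (vol.origin[0], vol.origin[1] + w0, vol.origin[2] + d0)
    return cropped
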