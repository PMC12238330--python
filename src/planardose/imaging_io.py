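"""Planar scintigraphy image I/O and view geometry.

Images are 2D count grids addressed by (row, col), row 0 at the top of the
detector field of view. MetaImage (.mhd/.raw) is the on-disk format;
``DimSize`` in the header is (cols, rows) as written by common MetaImage
tools, while in-memory grids are row-major numpy arrays of shape
(rows, cols).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import SimpleITK as sitk

__all__ = [
    "PlanarImage",
    "OrganMask",
    "ORGAN_LABELS",
    "VIEWS",
    "MetaImageFormatError",
    "read_metaimage",
    "write_metaimage",
    "read_mask",
    "write_mask",
    "flip_posterior",
    "geometric_mean_image",
]

VIEWS = ("anterior", "posterior", "posterior_flipped", "oblique45")

#: Organ labels used throughout the pipeline. The lung is split into thirds
#: so that effective attenuation can be assigned separately to each part
#: (rib-shadowed upper lung attenuates more than the lower lung).
ORGAN_LABELS = (
    "heart",
    "kidney_left",
    "kidney_right",
    "liver",
    "lung_upper",
    "lung_middle",
    "lung_lower",
    "spleen",
    "thyroid",
    "salivary_glands",
    "tumor",
    "background",
)

# MetaImage element types this package reads/writes: 8/16/32-bit integers
# and 32/64-bit floats. Anything else is refused by name.
_SUPPORTED_ELEMENT_TYPES = {
    "MET_CHAR",
    "MET_UCHAR",
    "MET_SHORT",
    "MET_USHORT",
    "MET_INT",
    "MET_UINT",
    "MET_FLOAT",
    "MET_DOUBLE",
}


class MetaImageFormatError(ValueError):
    """Raised for a MetaImage header the reader does not support."""


@dataclass
class PlanarImage:
    """A single planar projection: a non-negative count grid plus geometry.

    Parameters
    ----------
    pixels
        2D array of counts (or a count-derived quantity), shape (rows, cols).
    pixel_size_mm
        (row, col) pixel pitch in millimetres.
    view
        One of ``anterior``, ``posterior``, ``posterior_flipped``,
        ``oblique45``.
    time_post_admin_h
        Acquisition time after radionuclide administration, hours.
    duration_s
        Acquisition duration in seconds; counts / duration_s gives rates.
    """

    pixels: np.ndarray
    pixel_size_mm: tuple[float, float] = (2.3976, 2.3976)
    view: str = "anterior"
    time_post_admin_h: float = 0.0
    duration_s: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixel grid must be 2D, got ndim={self.pixels.ndim}")
        if np.any(self.pixels < 0):
            raise ValueError("pixel values must be non-negative")
        ps = tuple(float(v) for v in np.atleast_1d(self.pixel_size_mm))
        if len(ps) == 1:
            ps = (ps[0], ps[0])
        if any(v <= 0 for v in ps):
            raise ValueError(f"pixel_size_mm must be positive, got {ps}")
        self.pixel_size_mm = ps
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}; expected one of {VIEWS}")
        if self.time_post_admin_h < 0:
            raise ValueError("time_post_admin_h must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def count_rate(self) -> np.ndarray:
        """Per-pixel count rate in counts/s."""
        return self.pixels / self.duration_s


@dataclass
class OrganMask:
    """Binary organ region congruent with a planar image."""

    pixels: np.ndarray
    label: str = "tumor"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask grid must be 2D")
        if not self.pixels.any():
            raise ValueError(f"mask {self.label!r} has no pixels set")

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())


def _prescan_header(path: str) -> dict[str, str]:
    """Read the plain-text key = value block of an .mhd header."""
    fields: dict[str, str] = {}
    with open(path, "r", errors="replace") as fh:
        for line in fh:
            if "=" not in line:
                continue
            key, _, value = line.partition("=")
            fields[key.strip()] = value.strip()
            if key.strip() == "ElementDataFile":
                break
    return fields


def read_metaimage(path: str | os.PathLike, view: str | None = None) -> PlanarImage:
    """Read a 2D planar image from a MetaImage header.

    3D payloads with a singleton third dimension are squeezed to 2D.
    View, acquisition time and duration are taken from the custom header
    keys ``View``, ``TimePostAdminH`` and ``DurationS`` when present; the
    ``view`` argument overrides the header.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    header = _prescan_header(path)
    etype = header.get("ElementType", "MET_FLOAT")
    if etype not in _SUPPORTED_ELEMENT_TYPES:
        raise MetaImageFormatError(
            f"unsupported ElementType = {etype} in {path}; supported: "
            + ", ".join(sorted(_SUPPORTED_ELEMENT_TYPES))
        )
    datafile = header.get("ElementDataFile", "")
    if datafile and datafile not in ("LOCAL", "LIST"):
        rawpath = os.path.join(os.path.dirname(path) or ".", datafile)
        if not os.path.exists(rawpath):
            raise FileNotFoundError(f"raw payload {rawpath} for header {path}")
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # pragma: no cover - sitk wraps its own errors
        raise MetaImageFormatError(f"cannot read {path}: {exc}") from exc

    arr = sitk.GetArrayFromImage(img)
    if arr.ndim == 3:
        if 1 not in arr.shape:
            raise MetaImageFormatError(
                f"{path}: 3D image without a singleton dimension, shape {arr.shape}"
            )
        arr = arr.reshape([s for s in arr.shape if s != 1][:2] or (1, 1))
    spacing = img.GetSpacing()  # (col, row[, z]) order in sitk
    pixel_size = (float(spacing[1]), float(spacing[0]))

    keys = img.GetMetaDataKeys()
    meta_view = img.GetMetaData("View") if "View" in keys else "anterior"
    t_h = float(img.GetMetaData("TimePostAdminH")) if "TimePostAdminH" in keys else 0.0
    dur = float(img.GetMetaData("DurationS")) if "DurationS" in keys else 1.0
    return PlanarImage(
        pixels=arr.astype(float),
        pixel_size_mm=pixel_size,
        view=view or meta_view,
        time_post_admin_h=t_h,
        duration_s=dur,
    )


def write_metaimage(img: PlanarImage, path: str | os.PathLike) -> None:
    """Write a planar image as uncompressed MetaImage (.mhd + .raw)."""
    sitk_img = sitk.GetImageFromArray(img.pixels.astype(np.float64))
    sitk_img.SetSpacing((img.pixel_size_mm[1], img.pixel_size_mm[0]))
    sitk_img.SetMetaData("View", img.view)
    sitk_img.SetMetaData("TimePostAdminH", repr(img.time_post_admin_h))
    sitk_img.SetMetaData("DurationS", repr(img.duration_s))
    sitk.WriteImage(sitk_img, os.fspath(path), useCompression=False)


def read_mask(path: str | os.PathLike, label: str) -> OrganMask:
    """Read a 0/1 MetaImage payload as a binary organ mask."""
    img = read_metaimage(path)
    return OrganMask(pixels=img.pixels > 0.5, label=label)


def write_mask(mask: OrganMask, path: str | os.PathLike) -> None:
    sitk_img = sitk.GetImageFromArray(mask.pixels.astype(np.uint8))
    sitk_img.SetMetaData("Label", mask.label)
    sitk.WriteImage(sitk_img, os.fspath(path), useCompression=False)


def flip_posterior(img: PlanarImage) -> PlanarImage:
    """Rotate a posterior view 180 degrees in-plane.

    The posterior detector sees the patient mirrored relative to the
    anterior detector; a 180-degree in-plane rotation (flip along both
    axes) brings the two grids into register before the geometric mean.
    """
    if img.view not in ("posterior", "posterior_flipped"):
        raise ValueError(f"flip_posterior requires a posterior view, got {img.view!r}")
    new_view = "posterior_flipped" if img.view == "posterior" else "posterior"
    return replace(img, pixels=img.pixels[::-1, ::-1].copy(), view=new_view)


def geometric_mean_image(ant: PlanarImage, post_flipped: PlanarImage) -> PlanarImage:
    """Per-pixel geometric mean sqrt(anterior * flipped-posterior)."""
    if ant.shape != post_flipped.shape:
        raise ValueError(
            f"shape mismatch: anterior {ant.shape} vs posterior {post_flipped.shape}"
        )
    if not np.allclose(ant.pixel_size_mm, post_flipped.pixel_size_mm):
        raise ValueError("pixel size mismatch between views")
    gm = np.sqrt(ant.pixels * post_flipped.pixels)
    return replace(ant, pixels=gm, view="anterior")
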