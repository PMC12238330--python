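"""Dose-point-kernel (DPK) dosimetry.

A DPK is the absorbed-dose footprint of an isotropic point source in a
homogeneous medium, discretized on a small odd-sized square pixel grid in
Gy per MBq*s in the source pixel. The pixel dose map is the 2D convolution
of the cumulated-activity map with the kernel::

    D = A_cum (x) DPK

Organ mean doses average the map over the organ mask; the organ S-value is
the mean self-dose per unit total cumulated activity distributed uniformly
over the mask. The working assumption is that most organ energy deposition
is self-absorption, so each organ can use its own kernel.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve2d

from .imaging_io import OrganMask

__all__ = [
    "DoseKernel",
    "CumulatedActivityMap",
    "DoseMap",
    "KernelSummary",
    "KernelValidationError",
    "validate_kernel",
    "convolve_dose",
    "organ_mean_dose",
    "organ_s_value",
    "kernel_size_study",
    "read_kernel",
    "write_kernel",
]

DEFAULT_PIXEL_MM = 2.3976
DEFAULT_KERNEL_SIZE = 9


class KernelValidationError(ValueError):
    """A kernel grid violates a point-source kernel invariant."""


@dataclass
class DoseKernel:
    """Odd-sized square dose grid, Gy per (MBq*s) in the source pixel."""

    grid: np.ndarray
    pixel_size_mm: float = DEFAULT_PIXEL_MM
    organ_or_medium: str = "water"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise KernelValidationError(
                f"kernel must be square, got shape {self.grid.shape}"
            )
        if self.grid.shape[0] % 2 == 0:
            raise KernelValidationError(
                f"kernel size must be odd, got {self.grid.shape[0]}"
            )
        if self.pixel_size_mm <= 0:
            raise KernelValidationError("pixel_size_mm must be > 0")

    @property
    def size(self) -> int:
        return self.grid.shape[0]

    @property
    def center_value(self) -> float:
        c = self.size // 2
        return float(self.grid[c, c])


@dataclass
class CumulatedActivityMap:
    """2D grid of cumulated activity, MBq*s per pixel."""

    grid: np.ndarray
    pixel_size_mm: float = DEFAULT_PIXEL_MM

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("activity map must be 2D")
        if np.any(self.grid < 0):
            raise ValueError("cumulated activity must be >= 0")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be > 0")


@dataclass
class DoseMap:
    """2D absorbed-dose grid, Gy."""

    grid: np.ndarray
    pixel_size_mm: float = DEFAULT_PIXEL_MM

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("dose map must be 2D")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be > 0")


@dataclass
class KernelSummary:
    """Kernel diagnostics: center S-value and energy coverage by crop size."""

    s_value_center: float
    coverage_by_size: dict[int, float]


def _central_crop(grid: np.ndarray, n: int) -> np.ndarray:
    k = grid.shape[0]
    off = (k - n) // 2
    return grid[off:off + n, off:off + n]


def validate_kernel(
    k: DoseKernel,
    tol: float = 1e-6,
    coverage_threshold: float | None = None,
) -> KernelSummary:
    """Check point-source kernel invariants and summarize coverage.

    Invariants: odd square grid, non-negative entries, maximum at the
    center, symmetric under 90-degree rotation and mirroring within ``tol``
    (relative to the center value). When ``coverage_threshold`` is given,
    kernels whose outermost ring carries more than ``1 - coverage_threshold``
    of the total sum are rejected as truncated.
    """
    g = k.grid
    size = k.size
    if np.any(g < 0):
        raise KernelValidationError("kernel has negative entries")
    c = size // 2
    if g[c, c] < g.max() - tol * max(g[c, c], 1.0):
        raise KernelValidationError("kernel maximum is not at the center")
    scale = max(float(g[c, c]), np.finfo(float).tiny)
    for name, other in (
        ("90-degree rotation", np.rot90(g)),
        ("left-right mirror", g[:, ::-1]),
        ("up-down mirror", g[::-1, :]),
    ):
        if np.max(np.abs(g - other)) > tol * scale:
            raise KernelValidationError(f"kernel not symmetric under {name}")

    total = float(g.sum())
    coverage = {
        n: (float(_central_crop(g, n).sum()) / total if total > 0 else 1.0)
        for n in range(1, size + 1, 2)
    }
    if coverage_threshold is not None and size >= 3:
        inner = coverage[size - 2]
        if 1.0 - inner > 1.0 - coverage_threshold:
            raise KernelValidationError(
                f"outer ring holds {1 - inner:.3f} of the kernel sum "
                f"(> {1 - coverage_threshold:.3f}); enlarge the kernel"
            )
    if size > 1 and coverage[size - 2] < 0.95:
        warnings.warn(
            f"kernel coverage inside the {size - 2}x{size - 2} core is "
            f"{coverage[size - 2]:.3f} (< 0.95); dose may be truncated",
            stacklevel=2,
        )
    return KernelSummary(s_value_center=k.center_value, coverage_by_size=coverage)


def convolve_dose(
    a: CumulatedActivityMap, k: DoseKernel, edge: str = "zero_pad"
) -> DoseMap:
    """Dose map D = A_cum (x) DPK (true 2D convolution, zero-padded borders).

    Output has the same shape as the activity map. Activity outside the
    field of view contributes no dose (zero padding), so when the activity
    support stays at least half a kernel away from every border the total
    dose equals sum(A) * sum(kernel) exactly.
    """
    if edge != "zero_pad":
        raise ValueError(f"unsupported edge mode {edge!r}")
    if abs(a.pixel_size_mm - k.pixel_size_mm) > 1e-6:
        raise ValueError(
            f"pixel size mismatch: map {a.pixel_size_mm} mm vs kernel "
            f"{k.pixel_size_mm} mm"
        )
    dose = convolve2d(a.grid, k.grid, mode="same", boundary="fill", fillvalue=0.0)
    return DoseMap(grid=np.maximum(dose, 0.0), pixel_size_mm=a.pixel_size_mm)


def organ_mean_dose(d: DoseMap, mask: OrganMask) -> float:
    """Mean absorbed dose (Gy) over the organ mask."""
    if mask.pixels.shape != d.grid.shape:
        raise ValueError("mask and dose map shapes differ")
    return float(d.grid[mask.pixels].mean())


def organ_s_value(k: DoseKernel, mask: OrganMask) -> float:
    """Organ self-dose S-value: mean dose over the mask per unit total
    cumulated activity spread uniformly across the mask, Gy/(MBq*s)."""
    m = mask.n_pixels
    a = np.zeros(mask.pixels.shape, dtype=float)
    a[mask.pixels] = 1.0 / m
    dose = convolve_dose(CumulatedActivityMap(a, k.pixel_size_mm), k)
    return organ_mean_dose(dose, mask)


def _disc_phantom(shape: tuple[int, int], radius_px: float) -> np.ndarray:
    rr, cc = np.indices(shape)
    cr, cf = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    return ((rr - cr) ** 2 + (cc - cf) ** 2 <= radius_px ** 2).astype(float)


def kernel_size_study(
    k_full: DoseKernel,
    sizes,
    phantom_shape: tuple[int, int] = (41, 41),
    phantom_radius_px: float = 8.0,
) -> dict[int, dict[str, float]]:
    """Truncation analysis: for each odd crop size, the kernel coverage and
    the relative total-dose deficit on a uniform disc phantom versus the
    full kernel. The deficit is nonincreasing with crop size.
    """
    sizes = sorted(set(int(s) for s in sizes))
    for s in sizes:
        if s % 2 == 0:
            raise ValueError(f"kernel sizes must be odd, got {s}")
        if s > k_full.size:
            raise ValueError(f"requested size {s} exceeds kernel size {k_full.size}")
    phantom = CumulatedActivityMap(
        _disc_phantom(phantom_shape, phantom_radius_px), k_full.pixel_size_mm
    )
    full_total = float(convolve_dose(phantom, k_full).grid.sum())
    total_sum = float(k_full.grid.sum())
    out: dict[int, dict[str, float]] = {}
    for s in sizes:
        crop = DoseKernel(
            _central_crop(k_full.grid, s), k_full.pixel_size_mm,
            k_full.organ_or_medium,
        )
        cropped_total = float(convolve_dose(phantom, crop).grid.sum())
        out[s] = {
            "coverage": float(crop.grid.sum()) / total_sum if total_sum else 1.0,
            "dose_deficit": (full_total - cropped_total) / full_total
            if full_total else 0.0,
        }
    return out


# ---------------------------------------------------------------------------
# Kernel file formats: MetaImage grid, or whitespace text with a 3-line
# header (size, pixel size in mm, units).


def read_kernel(path, organ_or_medium: str = "water") -> DoseKernel:
    """Read a kernel from MetaImage (.mhd) or the 3-line-header text dialect."""
    path = os.fspath(path)
    if path.endswith(".mhd"):
        from .imaging_io import read_metaimage

        img = read_metaimage(path)
        return DoseKernel(img.pixels, img.pixel_size_mm[0], organ_or_medium)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 4:
        raise ValueError(f"kernel text file {path} too short")
    size = int(lines[0].split()[-1]) if not lines[0].isdigit() else int(lines[0])
    pixel = float(lines[1].split()[-1])
    # line 3 is the units string; kept for humans, not parsed further
    grid = np.loadtxt(lines[3:])
    grid = np.atleast_2d(grid)
    if grid.shape != (size, size):
        raise ValueError(
            f"kernel payload shape {grid.shape} disagrees with header size {size}"
        )
    return DoseKernel(grid, pixel, organ_or_medium)


def write_kernel(k: DoseKernel, path) -> None:
    path = os.fspath(path)
    if path.endswith(".mhd"):
        from .imaging_io import PlanarImage, write_metaimage

        write_metaimage(
            PlanarImage(k.grid, (k.pixel_size_mm, k.pixel_size_mm)), path
        )
        return
    with open(path, "w") as fh:
        fh.write(f"size {k.size}\n")
        fh.write(f"pixel_size_mm {k.pixel_size_mm!r}\n")
        fh.write("units Gy_per_MBq_s\n")
        np.savetxt(fh, k.grid)
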