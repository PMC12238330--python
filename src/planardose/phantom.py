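"""Synthetic phantoms: every input the dosimetry pipeline consumes.

The forward projector is a 2D slab model: each elliptical organ sits at a
single depth inside a body slab of known thickness, so the anterior and
posterior detectors see

    rate_ant  = C * A * exp(-mu * d)        (counts/s, summed over the organ)
    rate_post = C * A * exp(-mu * (T - d))

and the product of the two views satisfies I_A * I_B = C^2 A^2 exp(-mu T)
exactly in the noiseless case — the minimum physics that makes the
conjugate-view formula exactly invertible. The posterior image is stored as
the posterior detector records it (rotated 180 degrees), matching the
register-by-flipping step of the quantification chain.

Also generated: exponential radial dose kernels standing in for
Monte-Carlo-exported point-source kernels, noisy multi-time-point
time-activity curves, and ML cohorts whose target dose is a known function
of the features.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dpk import DoseKernel
from .imaging_io import OrganMask, PlanarImage
from .kinetics import ExpFit, TimeActivityCurve
from .planar_quant import I131_LAMBDA_PER_H

__all__ = [
    "OrganSpec",
    "PhantomConfig",
    "KernelModel",
    "project_phantom",
    "make_kernel",
    "make_tac",
    "make_cohort",
    "default_phantom",
]


@dataclass
class OrganSpec:
    """One elliptical organ in the slab phantom."""

    label: str
    center_rc: tuple[float, float]
    semiaxes_px: tuple[float, float]
    activity_MBq: float
    mu_cm1: float
    thickness_cm: float
    depth_cm: float | None = None  # anterior depth; default: mid-slab

    def __post_init__(self) -> None:
        if self.activity_MBq < 0:
            raise ValueError("activity must be >= 0")
        if self.mu_cm1 < 0 or self.thickness_cm <= 0:
            raise ValueError("mu must be >= 0 and thickness > 0")
        if self.depth_cm is None:
            self.depth_cm = self.thickness_cm / 2.0


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int] = (128, 128)
    pixel_size_mm: float = 2.3976
    organs: list[OrganSpec] = field(default_factory=list)
    background_activity_MBq: float = 0.0
    noise: str = "none"  # "none" | "poisson"
    seed: int | None = None
    calibration_cps_per_MBq: float = 1000.0
    duration_s: float = 600.0
    body_thickness_cm: float = 20.0
    time_post_admin_h: float = 24.0

    def __post_init__(self) -> None:
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.noise != "none" and self.seed is None:
            raise ValueError("a seed is mandatory when noise is enabled")
        rows, cols = self.grid_shape
        for o in self.organs:
            r, c = o.center_rc
            ar, ac = o.semiaxes_px
            if r - ar < 0 or r + ar >= rows or c - ac < 0 or c + ac >= cols:
                raise ValueError(f"organ {o.label!r} ellipse leaves the grid")


def _ellipse_mask(shape, center_rc, semiaxes_px) -> np.ndarray:
    rr, cc = np.indices(shape)
    r0, c0 = center_rc
    ar, ac = semiaxes_px
    return ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0


def default_phantom(
    noise: str = "none", seed: int | None = None, activity_scale: float = 1.0
) -> PhantomConfig:
    """A three-organ thorax-like slab phantom (liver, spleen, thyroid)."""
    return PhantomConfig(
        organs=[
            OrganSpec("liver", (70.0, 48.0), (18.0, 14.0), 120.0 * activity_scale,
                      0.11, 22.0),
            OrganSpec("spleen", (72.0, 88.0), (9.0, 7.0), 30.0 * activity_scale,
                      0.11, 20.0),
            OrganSpec("thyroid", (22.0, 64.0), (6.0, 8.0), 60.0 * activity_scale,
                      0.09, 12.0),
        ],
        background_activity_MBq=5.0 * activity_scale,
        noise=noise,
        seed=seed,
    )


def project_phantom(cfg: PhantomConfig):
    """Attenuated conjugate-view projections of a known activity phantom.

    Returns
    -------
    (anterior, posterior, oblique) : PlanarImage
        Count images; the posterior is in detector orientation (180-degree
        rotated with respect to the anterior).
    masks : dict[str, OrganMask]
        Organ masks in anterior register, plus a ``background`` mask.
    truth : dict
        Ground-truth activities and every generating parameter.
    """
    shape = tuple(cfg.grid_shape)
    C, dur = cfg.calibration_cps_per_MBq, cfg.duration_s
    ant = np.zeros(shape)
    post = np.zeros(shape)  # anterior register; rotated at the end
    masks: dict[str, OrganMask] = {}
    truth: dict = {
        "activities_MBq": {},
        "calibration_cps_per_MBq": C,
        "duration_s": dur,
        "mu_cm1": {},
        "thickness_cm": {},
        "depth_cm": {},
        "body_thickness_cm": cfg.body_thickness_cm,
    }

    organ_pixels = {}
    for o in cfg.organs:
        sel = _ellipse_mask(shape, o.center_rc, o.semiaxes_px)
        organ_pixels[o.label] = sel
        npix = int(sel.sum())
        rate_ant = C * o.activity_MBq * math.exp(-o.mu_cm1 * o.depth_cm)
        rate_post = C * o.activity_MBq * math.exp(
            -o.mu_cm1 * (o.thickness_cm - o.depth_cm)
        )
        ant[sel] += rate_ant * dur / npix
        post[sel] += rate_post * dur / npix
        masks[o.label] = OrganMask(sel, o.label)
        truth["activities_MBq"][o.label] = o.activity_MBq
        truth["mu_cm1"][o.label] = o.mu_cm1
        truth["thickness_cm"][o.label] = o.thickness_cm
        truth["depth_cm"][o.label] = o.depth_cm

    labels = list(organ_pixels)
    overlaps = [
        (a, b)
        for i, a in enumerate(labels)
        for b in labels[i + 1:]
        if (organ_pixels[a] & organ_pixels[b]).any()
    ]
    if overlaps:
        warnings.warn(f"overlapping organs: {overlaps}", stacklevel=2)
    truth["overlapping_pairs"] = overlaps

    if cfg.background_activity_MBq > 0:
        # Uniform background at mid-slab depth: identical per-pixel rate in
        # both views, so mean background subtraction removes it exactly.
        npix = ant.size
        mu_bg = cfg.organs[0].mu_cm1 if cfg.organs else 0.1
        rate = (
            C * cfg.background_activity_MBq
            * math.exp(-mu_bg * cfg.body_thickness_cm / 2.0)
        )
        ant += rate * dur / npix
        post += rate * dur / npix
        truth["background_activity_MBq"] = cfg.background_activity_MBq

    any_organ = np.zeros(shape, dtype=bool)
    for sel in organ_pixels.values():
        any_organ |= sel
    bg_sel = np.zeros(shape, dtype=bool)
    bg_sel[2:10, 2:10] = True
    bg_sel &= ~any_organ
    if bg_sel.any():
        masks["background"] = OrganMask(bg_sel, "background")

    # Oblique view: a bright chord whose length encodes the body thickness.
    obl = np.zeros(shape)
    chord_px = cfg.body_thickness_cm * 10.0 / cfg.pixel_size_mm
    r0 = shape[0] // 2
    c0 = max((shape[1] - int(round(chord_px))) // 2, 0)
    c1 = min(c0 + int(round(chord_px)), shape[1] - 1)
    obl[r0, c0:c1 + 1] = 1.0
    truth["oblique_chord"] = {"p1": [r0, c0], "p2": [r0, c0 + chord_px]}

    if cfg.noise == "poisson":
        rng = np.random.default_rng(cfg.seed)
        ant = rng.poisson(ant).astype(float)
        post = rng.poisson(post).astype(float)

    common = dict(
        pixel_size_mm=(cfg.pixel_size_mm, cfg.pixel_size_mm),
        time_post_admin_h=cfg.time_post_admin_h,
        duration_s=dur,
    )
    anterior = PlanarImage(ant, view="anterior", **common)
    posterior = PlanarImage(post[::-1, ::-1].copy(), view="posterior", **common)
    oblique = PlanarImage(obl, view="oblique45", **common)
    return (anterior, posterior, oblique), masks, truth


@dataclass
class KernelModel:
    """Exponential radial kernel k(r) = amplitude * exp(-r / range)."""

    amplitude: float = 1e-4
    range_mm: float = 3.0
    kernel_size: int = 9
    pixel_size_mm: float = 2.3976

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd")
        if self.amplitude <= 0 or self.range_mm <= 0 or self.pixel_size_mm <= 0:
            raise ValueError("amplitude, range and pixel size must be > 0")


def make_kernel(m: KernelModel, organ_or_medium: str = "water") -> DoseKernel:
    """Radially decreasing kernel evaluated at pixel-center distances."""
    k = m.kernel_size
    c = k // 2
    rr, cc = np.indices((k, k))
    r_mm = np.hypot(rr - c, cc - c) * m.pixel_size_mm
    grid = m.amplitude * np.exp(-r_mm / m.range_mm)
    return DoseKernel(grid, m.pixel_size_mm, organ_or_medium)


def make_tac(
    fit_truth: ExpFit,
    times_h=(24.0, 72.0, 168.0),
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> TimeActivityCurve:
    """Sample a decay model at given times with multiplicative lognormal
    noise of coefficient of variation ``noise_cv`` (mean-preserving)."""
    t = np.asarray(times_h, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    values = fit_truth(t)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + noise_cv ** 2))
        values = values * rng.lognormal(-sigma ** 2 / 2.0, sigma, size=t.size)
    return TimeActivityCurve(t, values, organ=fit_truth.organ)


_COHORT_ORGANS = ("liver", "spleen", "thyroid", "kidney_left", "kidney_right")

#: Organ factors for the nonlinear generator (relative self-dose geometry).
_ORGAN_FACTOR = {
    "liver": 1.0, "spleen": 1.3, "thyroid": 1.6,
    "kidney_left": 1.1, "kidney_right": 1.1,
}

#: Linear-generator coefficients (intercept + per-feature), Gy per unit.
_LINEAR_COEF = {
    "intercept": 0.5,
    "I_A_cps": 0.002,
    "I_B_cps": 0.001,
    "thickness_cm": 0.1,
    "s_value": 2.0e4,
    "mu_e_cm1": 5.0,
    "bmi_kg_m2": 0.05,
    "age_y": 0.02,
}


def make_cohort(
    n: int,
    generator: str = "linear",
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Synthetic ML cohort with a known dose-generating function.

    Features: age U(20, 80) y, BMI U(17, 40) kg/m^2, thickness U(15, 35) cm,
    mu_e U(0.09, 0.13) /cm, count rates lognormal (median 200 cps,
    sigma 0.35), S-value log-uniform in [2e-5, 8e-5] Gy/(MBq*s).

    generator="linear": dose is an affine function of the numeric features
    (coefficients in ``metadata['coefficients']``).
    generator="nonlinear": dose follows the quantification physics —
    conjugate-view activity, physical-decay residence time, S-value, an
    organ geometry factor and an inverse-BMI habitus factor.
    """
    from .dose_ml import CohortTable

    if n < 8:
        raise ValueError("cohort needs n >= 8")
    if generator not in ("linear", "nonlinear"):
        raise ValueError(f"unknown generator {generator!r}")
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "age_y": rng.uniform(20.0, 80.0, n),
            "bmi_kg_m2": rng.uniform(17.0, 40.0, n),
            "organ": rng.choice(_COHORT_ORGANS, n),
            "I_A_cps": rng.lognormal(math.log(200.0), 0.35, n),
            "I_B_cps": rng.lognormal(math.log(200.0), 0.35, n),
            "thickness_cm": rng.uniform(15.0, 35.0, n),
            "s_value": np.exp(rng.uniform(math.log(2e-5), math.log(8e-5), n)),
            "mu_e_cm1": rng.uniform(0.09, 0.13, n),
        }
    )
    meta: dict = {"generator": generator, "noise_sd": noise_sd, "seed": seed}
    if generator == "linear":
        coef = dict(_LINEAR_COEF)
        y = np.full(n, coef["intercept"])
        for col, b in coef.items():
            if col != "intercept":
                y = y + b * df[col].to_numpy()
        meta["coefficients"] = coef
    else:
        C = 1000.0
        activity = (
            np.sqrt(
                df["I_A_cps"] * df["I_B_cps"]
                * np.exp(df["mu_e_cm1"] * df["thickness_cm"])
            )
            / C
        )
        tia = activity / I131_LAMBDA_PER_H * 3600.0  # MBq*s, physical decay only
        organ_f = df["organ"].map(_ORGAN_FACTOR).to_numpy()
        habitus = np.sqrt(25.0 / df["bmi_kg_m2"].to_numpy())
        y = tia.to_numpy() * df["s_value"].to_numpy() * organ_f * habitus
        meta["calibration_cps_per_MBq"] = C
        meta["organ_factor"] = dict(_ORGAN_FACTOR)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n)
    df["target_dose_Gy"] = y
    return CohortTable(records=df, metadata=meta)


def truth_to_json(truth: dict, path) -> None:
    """Write a phantom truth record as JSON."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=float)
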