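"""Conjugate-view activity quantification.

The absolute activity A (MBq) in a region is recovered from the anterior
and posterior count rates I_A and I_B (counts/s) through the geometric-mean
formula with effective attenuation correction::

    A = sqrt(I_A * I_B * exp(mu_e * T)) / C

where mu_e (1/cm) is the effective linear attenuation coefficient of the
tissue column, T (cm) the body thickness along the projection measured on
a 45-degree oblique view, and C (counts/s per MBq) the system calibration
factor measured on a source of known activity. An optional recovery
coefficient divides out partial-volume losses for small structures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .imaging_io import OrganMask, PlanarImage

__all__ = [
    "I131_HALF_LIFE_H",
    "I131_LAMBDA_PER_H",
    "CalibrationFactor",
    "AttenuationSpec",
    "ThicknessMeasurement",
    "RecoveryCurve",
    "ActivityEstimate",
    "roi_counts",
    "effective_mu",
    "thickness_from_oblique",
    "conjugate_view_activity",
    "calibration_from_scan",
    "recovery_coefficient",
    "convert_activity",
    "convert_sensitivity",
    "decay_correct",
    "load_config",
    "quantify_organs",
]

#: Physical half-life of I-131 in hours (8.02 days).
I131_HALF_LIFE_H = 192.5
I131_LAMBDA_PER_H = math.log(2.0) / I131_HALF_LIFE_H

_CALIBRATION_METHODS = ("petri_dish", "point_source")


@dataclass
class CalibrationFactor:
    """System sensitivity: detector counts per second per MBq in the field."""

    value: float  # counts/s per MBq == counts per (MBq*s)
    method: str = "petri_dish"
    source_activity_MBq: float | None = None
    distance_cm: float | None = None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("calibration factor must be > 0")
        if self.method not in _CALIBRATION_METHODS:
            raise ValueError(
                f"unknown calibration method {self.method!r}; "
                f"expected one of {_CALIBRATION_METHODS}"
            )


@dataclass
class AttenuationSpec:
    """Per-organ effective linear attenuation coefficients (1/cm)."""

    per_organ_mu_e: dict[str, float]

    def __post_init__(self) -> None:
        for organ, mu in self.per_organ_mu_e.items():
            if mu < 0:
                raise ValueError(f"mu_e for {organ!r} must be >= 0, got {mu}")

    def mu_for(self, organ: str) -> float:
        try:
            return self.per_organ_mu_e[organ]
        except KeyError:
            raise KeyError(f"no effective attenuation coefficient for {organ!r}") from None


@dataclass
class ThicknessMeasurement:
    """Apparent body/organ thickness from two cursor points on the oblique view."""

    p1: tuple[float, float]
    p2: tuple[float, float]
    pixel_size_mm: tuple[float, float]
    obliquity_factor: float = 1.0
    thickness_cm: float = field(init=False)

    def __post_init__(self) -> None:
        ps = np.atleast_1d(np.asarray(self.pixel_size_mm, dtype=float))
        if ps.size == 1:
            ps = np.array([ps[0], ps[0]])
        if np.any(ps <= 0):
            raise ValueError("pixel_size_mm must be positive")
        self.pixel_size_mm = (float(ps[0]), float(ps[1]))
        if self.obliquity_factor <= 0:
            raise ValueError("obliquity_factor must be > 0")
        dr = (self.p2[0] - self.p1[0]) * self.pixel_size_mm[0]
        dc = (self.p2[1] - self.p1[1]) * self.pixel_size_mm[1]
        dist_mm = math.hypot(dr, dc)
        if dist_mm == 0:
            raise ValueError("degenerate thickness measurement: p1 == p2")
        self.thickness_cm = dist_mm * self.obliquity_factor / 10.0


@dataclass
class RecoveryCurve:
    """Recovery coefficient vs sphere diameter for one modality."""

    diameters_mm: list[float]
    rc: list[float]
    modality: str = "planar"

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters_mm, dtype=float)
        r = np.asarray(self.rc, dtype=float)
        if d.size == 0:
            raise ValueError("recovery curve must have at least one knot")
        if d.size != r.size:
            raise ValueError("diameters and rc lengths differ")
        if np.any(np.diff(d) <= 0):
            raise ValueError("diameters must be strictly increasing")
        if np.any(r <= 0):
            raise ValueError("recovery coefficients must be > 0")
        if self.modality not in ("planar", "spect"):
            raise ValueError(f"unknown modality {self.modality!r}")
        self.diameters_mm = d.tolist()
        self.rc = r.tolist()


@dataclass
class ActivityEstimate:
    """An organ activity with the ingredients that produced it."""

    activity_MBq: float
    organ: str = "tumor"
    components: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.activity_MBq < 0:
            raise ValueError("activity must be >= 0")


def roi_counts(
    img: PlanarImage,
    mask: OrganMask,
    background_mask: OrganMask | None = None,
) -> float:
    """Background-corrected ROI count rate (counts/s).

    The mean pixel value inside the ROI is reduced by the mean pixel value
    in the background ROI (floored at zero), multiplied back by the ROI
    pixel count, and divided by the acquisition duration.
    """
    if mask.pixels.shape != img.shape:
        raise ValueError(
            f"mask {mask.label!r} shape {mask.pixels.shape} != image shape {img.shape}"
        )
    roi_mean = float(img.pixels[mask.pixels].mean())
    bg_mean = 0.0
    if background_mask is not None:
        if background_mask.pixels.shape != img.shape:
            raise ValueError("background mask shape mismatch")
        bg_mean = float(img.pixels[background_mask.pixels].mean())
    net_mean = max(roi_mean - bg_mean, 0.0)
    return net_mean * mask.n_pixels / img.duration_s


def effective_mu(mu_values) -> float:
    """Effective attenuation coefficient: arithmetic mean of the tissue
    coefficients crossed by the projection line (1/cm).

    Lung thirds are handled as separate regions, each with its own call.
    """
    mu = np.asarray(list(mu_values), dtype=float)
    if mu.size == 0:
        raise ValueError("effective_mu needs at least one coefficient")
    if np.any(mu < 0):
        raise ValueError("attenuation coefficients must be >= 0")
    return float(mu.mean())


def thickness_from_oblique(
    p1: tuple[float, float],
    p2: tuple[float, float],
    pixel_size_mm,
    obliquity_factor: float = 1.0,
) -> ThicknessMeasurement:
    """Thickness (cm) from two cursor points on the 45-degree oblique view."""
    return ThicknessMeasurement(
        p1=tuple(p1), p2=tuple(p2), pixel_size_mm=pixel_size_mm,
        obliquity_factor=obliquity_factor,
    )


def conjugate_view_activity(
    I_A: float,
    I_B: float,
    mu_e: float,
    T_cm: float,
    C: CalibrationFactor,
    rc: float | None = None,
    organ: str = "tumor",
) -> ActivityEstimate:
    """Absolute activity from conjugate-view count rates.

    A = sqrt(I_A * I_B * exp(mu_e * T)) / C, divided by the recovery
    coefficient when one is supplied. Units are MBq when C is counts/s
    per MBq and I_A, I_B are counts/s.
    """
    if I_A < 0 or I_B < 0:
        raise ValueError("count rates must be >= 0")
    if mu_e < 0 or T_cm < 0:
        raise ValueError("mu_e and T must be >= 0")
    if rc is not None and rc <= 0:
        raise ValueError("recovery coefficient must be > 0")
    activity = math.sqrt(I_A * I_B * math.exp(mu_e * T_cm)) / C.value
    if rc is not None:
        activity /= rc
    return ActivityEstimate(
        activity_MBq=activity,
        organ=organ,
        components={
            "I_A_cps": I_A, "I_B_cps": I_B, "mu_e_cm1": mu_e, "T_cm": T_cm,
            "C": C.value, "RC": rc, "background": "subtracted upstream",
        },
    )


def calibration_from_scan(
    known_activity_MBq: float,
    total_counts: float,
    duration_s: float,
    method: str = "petri_dish",
    distance_cm: float | None = None,
) -> CalibrationFactor:
    """Calibration factor from a scan of a known source in air."""
    if known_activity_MBq <= 0 or total_counts <= 0 or duration_s <= 0:
        raise ValueError("activity, counts and duration must all be > 0")
    return CalibrationFactor(
        value=total_counts / (known_activity_MBq * duration_s),
        method=method,
        source_activity_MBq=known_activity_MBq,
        distance_cm=distance_cm,
    )


def recovery_coefficient(curve: RecoveryCurve, diameter_mm: float) -> float:
    """Piecewise-linear recovery coefficient at a given object diameter.

    Diameters outside the calibrated range are clamped to the nearest end
    knot with a warning (extrapolation could produce unphysical RC).
    """
    d = np.asarray(curve.diameters_mm)
    r = np.asarray(curve.rc)
    if diameter_mm < d[0] or diameter_mm > d[-1]:
        warnings.warn(
            f"diameter {diameter_mm} mm outside calibrated range "
            f"[{d[0]}, {d[-1]}] mm; clamping",
            stacklevel=2,
        )
        diameter_mm = min(max(diameter_mm, d[0]), d[-1])
    return float(np.interp(diameter_mm, d, r))


# ---------------------------------------------------------------------------
# Radioactivity unit conversions (exact; 1 mCi = 37 MBq by definition)

_BQ_PER_UNIT = {
    "Bq": 1.0,
    "kBq": 1e3,
    "MBq": 1e6,
    "uCi": 3.7e4,
    "mCi": 3.7e7,
    "Ci": 3.7e10,
}
_UNIT_ALIASES = {"μCi": "uCi", "µCi": "uCi"}


def _activity_unit(unit: str) -> tuple[float, bool]:
    """(Bq per unit, is-concentration) for an activity or activity/ml unit."""
    per_ml = unit.endswith("/ml")
    base = unit[:-3] if per_ml else unit
    base = _UNIT_ALIASES.get(base, base)
    if base not in _BQ_PER_UNIT:
        raise ValueError(f"unknown activity unit {unit!r}")
    return _BQ_PER_UNIT[base], per_ml


def convert_activity(value: float, from_unit: str, to_unit: str) -> float:
    """Exact radioactivity (or concentration, unit/ml) conversion."""
    f, f_conc = _activity_unit(from_unit)
    t, t_conc = _activity_unit(to_unit)
    if f_conc != t_conc:
        raise ValueError(
            f"cannot convert between activity and concentration: "
            f"{from_unit!r} -> {to_unit!r}"
        )
    return value * f / t


# denominator size in kBq: 1 uCi = 37 kBq exactly
_SENS_UNITS = {"cpm/uCi": 37.0, "cpm/kBq": 1.0}


def convert_sensitivity(
    value: float, from_unit: str, to_unit: str, ndigits: int | None = None
) -> float:
    """Detector sensitivity conversion between cpm/uCi and cpm/kBq."""
    from_u = _UNIT_ALIASES.get(from_unit.replace("μ", "u").replace("µ", "u"), from_unit)
    from_u = from_u.replace("μ", "u").replace("µ", "u")
    to_u = to_unit.replace("μ", "u").replace("µ", "u")
    if from_u not in _SENS_UNITS:
        raise ValueError(f"unknown sensitivity unit {from_unit!r}")
    if to_u not in _SENS_UNITS:
        raise ValueError(f"unknown sensitivity unit {to_unit!r}")
    out = value * _SENS_UNITS[to_u] / _SENS_UNITS[from_u]
    return round(out, ndigits) if ndigits is not None else out


def decay_correct(value: float, t_h: float, ref_t_h: float = 0.0) -> float:
    """Decay-correct an activity-like quantity from t_h to ref_t_h using the
    I-131 physical decay constant. Off by default in the pipeline; enable
    explicitly when counts from different sessions must share a time origin."""
    return value * math.exp(I131_LAMBDA_PER_H * (t_h - ref_t_h))


# ---------------------------------------------------------------------------
# Config + organ-level pipeline


def load_config(path) -> dict:
    """Load calibration, attenuation and RC curves from a YAML config.

    Expected keys: ``calibration`` (value, method), ``mu_e`` (organ -> 1/cm),
    ``recovery`` (modality -> {diameters_mm, rc}), optional
    ``thickness_cm`` (organ -> cm), ``obliquity_factor``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cal = raw.get("calibration", {})
    cfg = {
        "calibration": CalibrationFactor(
            value=float(cal.get("value", 1.0)),
            method=cal.get("method", "petri_dish"),
            source_activity_MBq=cal.get("source_activity_MBq"),
            distance_cm=cal.get("distance_cm"),
        ),
        "attenuation": AttenuationSpec(
            per_organ_mu_e={k: float(v) for k, v in raw.get("mu_e", {}).items()}
        ),
        "recovery": {
            mod: RecoveryCurve(
                diameters_mm=list(spec["diameters_mm"]),
                rc=list(spec["rc"]),
                modality=mod,
            )
            for mod, spec in raw.get("recovery", {}).items()
        },
        "thickness_cm": {k: float(v) for k, v in raw.get("thickness_cm", {}).items()},
        "obliquity_factor": float(raw.get("obliquity_factor", 1.0)),
    }
    return cfg


def quantify_organs(
    anterior: PlanarImage,
    posterior: PlanarImage,
    masks: dict[str, OrganMask],
    attenuation: AttenuationSpec,
    thickness_cm: dict[str, float],
    calibration: CalibrationFactor,
    background_mask: OrganMask | None = None,
    recovery: RecoveryCurve | None = None,
    organ_diameter_mm: dict[str, float] | None = None,
) -> list[ActivityEstimate]:
    """Conjugate-view activity for every organ mask.

    The posterior image is flipped into anterior register before ROI
    counting; each organ uses its own effective attenuation coefficient
    and thickness. Recovery-coefficient correction is applied only when a
    curve and a per-organ diameter are both given.
    """
    from .imaging_io import flip_posterior

    post = flip_posterior(posterior) if posterior.view == "posterior" else posterior
    estimates = []
    for organ, mask in masks.items():
        ia = roi_counts(anterior, mask, background_mask)
        ib = roi_counts(post, mask, background_mask)
        rc = None
        if recovery is not None and organ_diameter_mm and organ in organ_diameter_mm:
            rc = recovery_coefficient(recovery, organ_diameter_mm[organ])
        est = conjugate_view_activity(
            ia, ib,
            mu_e=attenuation.mu_for(organ),
            T_cm=thickness_cm[organ],
            C=calibration,
            rc=rc,
            organ=organ,
        )
        estimates.append(est)
    return estimates
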