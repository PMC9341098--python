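"""Littmann-Bennett transverse magnification correction.

Fundus-imaging instruments report on-retina dimensions assuming a fixed
axial length; eyes longer or shorter than that assumption are imaged with
a transverse magnification error.  The Littmann-Bennett relation recovers
the true linear dimension D_t from the measured one D_m:

    D_t = p * q * D_m,        q = 0.01306 * (AL - 1.82)

where q is the ocular magnification factor of the eye (AL in mm; 1.82 mm
is the distance from the corneal apex at which the relation is anchored)
and p is the instrument magnification factor.  Areas scale with the square
of the linear factor: A_t = (p*q)^2 * A_m.

The bundled profile is the Optovue RTVue XR Avanti OCTA system, p = 3.48,
designed around an assumed axial length of 23.95 mm, 3-mm scan field.
Note that with the published constants p * q(23.95) = 1.00578, not exactly
1; ``ratio_mode`` instead scales by q(AL)/q(reference_al), which is exactly
1 at the reference axial length.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigurationError, InvalidAxialLengthError

#: Slope of the Bennett ocular magnification relation, 1/mm.
Q_SLOPE = 0.01306
#: Corneal-apex offset of the relation, mm; q is undefined at or below it.
APEX_OFFSET_MM = 1.82


class ALSource(str, enum.Enum):
    """Provenance of the axial length used in a correction."""

    ACTUAL = "actual"
    ESTIMATED = "estimated"


@dataclass(frozen=True)
class DeviceProfile:
    """Optical profile of a fundus-imaging instrument.

    ``p_factor`` is the instrument magnification factor of the Littmann
    relation; ``reference_al`` is the axial length (mm) the instrument's
    nominal scaling assumes; ``scan_width`` is the nominal scan field (mm),
    needed only for pixel-scale computations.
    """

    name: str
    p_factor: float
    reference_al: float
    scan_width: Optional[float] = None

    def __post_init__(self) -> None:
        if self.p_factor <= 0:
            raise ConfigurationError(f"{self.name}: p_factor must be positive")
        if self.reference_al <= APEX_OFFSET_MM:
            raise ConfigurationError(
                f"{self.name}: reference_al must exceed {APEX_OFFSET_MM} mm"
            )


#: Optovue RTVue XR Avanti OCTA: p = 3.48, assumed AL 23.95 mm, 3-mm scan.
RTVUE_XR_AVANTI = DeviceProfile(
    name="RTVue XR Avanti", p_factor=3.48, reference_al=23.95, scan_width=3.0
)

DEFAULT_DEVICES = {"rtvue-xr-avanti": RTVUE_XR_AVANTI}


@dataclass(frozen=True)
class CorrectionResult:
    """Scale factors and corrected value for one eye/measurement."""

    q: float
    linear_scale: float
    area_scale: float
    corrected_value: float
    al_source: ALSource


def ocular_magnification_q(al, *, q_slope: float = Q_SLOPE,
                           apex_offset: float = APEX_OFFSET_MM):
    """Ocular magnification factor q = 0.01306 * (AL - 1.82).

    ``q_slope`` and ``apex_offset`` are fixed model constants, exposed only
    for expert re-parameterisation. Accepts scalars or arrays.
    """
    al_arr = np.asarray(al, dtype=float)
    if np.any(al_arr <= apex_offset):
        raise InvalidAxialLengthError(
            f"axial length must exceed the Littmann apex offset "
            f"{apex_offset} mm"
        )
    q = q_slope * (al_arr - apex_offset)
    return float(q) if np.isscalar(al) else q


def linear_scale(device: DeviceProfile, al, *, ratio_mode: bool = False):
    """Linear correction factor for measurements from ``device`` at ``al``.

    Default is the Littmann product p*q(AL).  In ``ratio_mode`` the factor
    is q(AL)/q(reference_al), exactly 1 at the device's reference axial
    length.
    """
    q = ocular_magnification_q(al)
    if ratio_mode:
        return q / ocular_magnification_q(device.reference_al)
    return device.p_factor * q


def true_linear_dimension(d_measured, device: DeviceProfile, al, *,
                          ratio_mode: bool = False):
    """True on-retina linear dimension D_t = p * q * D_m (mm)."""
    d = np.asarray(d_measured, dtype=float)
    if np.any(d < 0):
        raise ValueError("measured dimension must be >= 0")
    out = linear_scale(device, al, ratio_mode=ratio_mode) * d
    return float(out) if np.isscalar(d_measured) and np.isscalar(al) else out


def correct_area(area_measured, device: DeviceProfile, al, *,
                 ratio_mode: bool = False):
    """True area A_t = (p*q)^2 * A_m (mm^2).

    Areas scale with the square of the linear factor; the full product p*q
    is squared, not q alone.
    """
    a = np.asarray(area_measured, dtype=float)
    if np.any(a < 0):
        raise ValueError("measured area must be >= 0")
    out = linear_scale(device, al, ratio_mode=ratio_mode) ** 2 * a
    return float(out) if np.isscalar(area_measured) and np.isscalar(al) else out


def pixel_scale(device: DeviceProfile, al, pixels_across: int, *,
                ratio_mode: bool = False):
    """True on-retina sampling pitch, mm per pixel.

    (p*q * scan_width) / pixels_across; requires the device profile to
    declare its nominal scan width.
    """
    if device.scan_width is None:
        raise ConfigurationError(
            f"{device.name}: scan_width required for pixel-scale computation"
        )
    if pixels_across <= 0:
        raise ConfigurationError("pixels_across must be a positive count")
    return linear_scale(device, al, ratio_mode=ratio_mode) * device.scan_width / pixels_across


def correction(value, device: DeviceProfile, al, *, kind: str = "area",
               al_source: ALSource = ALSource.ACTUAL,
               ratio_mode: bool = False) -> CorrectionResult:
    """Correct one measurement and return the full scale breakdown."""
    q = ocular_magnification_q(al)
    lin = linear_scale(device, al, ratio_mode=ratio_mode)
    if kind == "area":
        corrected = lin ** 2 * value
    elif kind == "linear":
        corrected = lin * value
    else:
        raise ConfigurationError(f"unknown measurement kind: {kind!r}")
    return CorrectionResult(
        q=float(q),
        linear_scale=float(lin),
        area_scale=float(lin) ** 2,
        corrected_value=float(corrected),
        al_source=ALSource(al_source),
    )


_REGISTRY_KEYS = {"name", "p_factor", "reference_al_mm", "scan_width_mm"}
_REQUIRED_KEYS = {"name", "p_factor", "reference_al_mm"}


def load_device_registry(path) -> dict:
    """Load a JSON device registry: a list of profile objects.

    Each object must have ``name``, ``p_factor`` and ``reference_al_mm``,
    optionally ``scan_width_mm``; unknown keys are rejected so typos fail
    loudly rather than silently default.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise ConfigurationError("device registry must be a JSON list of objects")
    registry = dict(DEFAULT_DEVICES)
    for i, obj in enumerate(raw):
        if not isinstance(obj, dict):
            raise ConfigurationError(f"registry entry {i} is not an object")
        unknown = set(obj) - _REGISTRY_KEYS
        if unknown:
            raise ConfigurationError(
                f"registry entry {i}: unknown key(s) {sorted(unknown)}; "
                f"allowed: {sorted(_REGISTRY_KEYS)}"
            )
        missing = _REQUIRED_KEYS - set(obj)
        if missing:
            raise ConfigurationError(
                f"registry entry {i}: missing required key(s) {sorted(missing)}"
            )
        try:
            profile = DeviceProfile(
                name=str(obj["name"]),
                p_factor=float(obj["p_factor"]),
                reference_al=float(obj["reference_al_mm"]),
                scan_width=(
                    float(obj["scan_width_mm"])
                    if obj.get("scan_width_mm") is not None else None
                ),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"registry entry {i}: {exc}") from exc
        registry[_slug(profile.name)] = profile
    return registry


def _slug(name: str) -> str:
    return "-".join(name.lower().split())


def resolve_device(name: str, registry: Optional[dict] = None) -> DeviceProfile:
    """Look a device up by name or slug; raise ConfigurationError if absent."""
    reg = registry if registry is not None else DEFAULT_DEVICES
    key = _slug(name)
    if key in reg:
        return reg[key]
    for profile in reg.values():
        if profile.name == name:
            return profile
    raise ConfigurationError(
        f"unknown device {name!r}; known: {sorted(reg)}"
    )
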