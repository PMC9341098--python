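"""Per-eye ocular biometry and the axial-length estimation regression.

The central object is a linear model that predicts axial length (AL, mm)
from mean corneal radius of curvature (K, mm) and spherical equivalent
refraction (SE, D):

    AL_est = beta_k * K + beta_se * SE + intercept

The default model carries the published coefficients

    AL_est = 2.102 K - 0.4125 SE + 7.268        (R^2 = 0.794)

fitted on 650 young adults with post-cycloplegic refraction.  Longer eyes
are more myopic (beta_se < 0) and have flatter corneas (beta_k > 0), so
increasing myopia at fixed K strictly increases the estimate.

Units: the regression consumes K as a *radius in millimetres* (population
mean around 7.76 mm).  Keratometric power in dioptres is converted with the
standard keratometric index convention, r_mm = 337.5 / K_D.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .errors import FittingError, InvalidMeasurementError

logger = logging.getLogger("octamag.biometry")

#: Keratometric index constant: corneal radius (mm) = 337.5 / power (D).
KERATOMETRIC_CONSTANT = 337.5

#: Default plausibility bounds for axial length, mm.
AL_SANITY_BOUNDS = (15.0, 40.0)


class Eye(str, enum.Enum):
    """Eye laterality. Recorded and reported, never used in arithmetic."""

    RIGHT = "right"
    LEFT = "left"

    @classmethod
    def parse(cls, value: str) -> "Eye":
        v = str(value).strip().lower()
        if v in ("right", "r", "od"):
            return cls.RIGHT
        if v in ("left", "l", "os"):
            return cls.LEFT
        raise InvalidMeasurementError(f"unrecognised eye laterality: {value!r}")


def mean_keratometry(k_meridian_1: float, k_meridian_2: float) -> float:
    """Mean corneal radius (mm) of the two principal meridians."""
    if k_meridian_1 <= 0 or k_meridian_2 <= 0:
        raise InvalidMeasurementError(
            f"keratometry radii must be positive, got "
            f"({k_meridian_1}, {k_meridian_2})"
        )
    return (k_meridian_1 + k_meridian_2) / 2.0


def spherical_equivalent(sphere: float, cylinder: float) -> float:
    """Spherical equivalent SE = sphere + cylinder / 2, in dioptres.

    Agnostic to minus- vs plus-cylinder notation: the caller's convention
    propagates unchanged.
    """
    return sphere + cylinder / 2.0


def diopters_to_radius_mm(k_power: float) -> float:
    """Convert keratometric power (D) to corneal radius (mm).

    Uses the keratometric index convention r = 337.5 / K_D (refractive
    index 1.3375).
    """
    if k_power <= 0:
        raise InvalidMeasurementError(
            f"keratometric power must be positive, got {k_power}"
        )
    return KERATOMETRIC_CONSTANT / k_power


@dataclass(frozen=True)
class BiometryRecord:
    """One eye's biometry and (optionally) its OCTA FAZ-area measurement.

    Parameters
    ----------
    participant_id
        Free-form identifier; pairing across methods uses (id, eye).
    eye
        Laterality; metadata only.
    k_mean
        Mean corneal radius of curvature, mm. Must be positive.
    se
        Spherical equivalent, D. More negative = more myopic.
    cycloplegic
        Whether ``se`` was measured under cycloplegia. Metadata that is
        propagated into reports; the estimation formula is identical.
    sphere, cylinder
        Optional refraction components, D. If both are present together
        with ``se``, consistency se == sphere + cylinder/2 is enforced.
    al_act
        Measured (biometer) axial length, mm, if available.
    faza_measured
        Uncorrected foveal avascular zone area, mm^2, if available.
    sqi
        Scan quality index 0-10 of the OCTA acquisition, if available.
    al_bounds
        Plausibility bounds applied to ``al_act``.
    """

    participant_id: str
    eye: Eye
    k_mean: float
    se: float
    cycloplegic: bool = False
    sphere: Optional[float] = None
    cylinder: Optional[float] = None
    al_act: Optional[float] = None
    faza_measured: Optional[float] = None
    sqi: Optional[int] = None
    al_bounds: tuple = field(default=AL_SANITY_BOUNDS, repr=False)

    def __post_init__(self) -> None:
        if self.k_mean <= 0:
            raise InvalidMeasurementError(
                f"{self.participant_id}: k_mean must be positive, got {self.k_mean}"
            )
        if self.al_act is not None:
            lo, hi = self.al_bounds
            if not (lo <= self.al_act <= hi):
                raise InvalidMeasurementError(
                    f"{self.participant_id}: al_act {self.al_act} mm outside "
                    f"plausibility bounds [{lo}, {hi}]"
                )
        if self.faza_measured is not None and self.faza_measured < 0:
            raise InvalidMeasurementError(
                f"{self.participant_id}: faza_measured must be >= 0"
            )
        if self.sqi is not None and not (0 <= self.sqi <= 10):
            raise InvalidMeasurementError(
                f"{self.participant_id}: sqi must be in 0..10, got {self.sqi}"
            )
        if self.sphere is not None and self.cylinder is not None:
            implied = spherical_equivalent(self.sphere, self.cylinder)
            if abs(implied - self.se) > 1e-6:
                raise InvalidMeasurementError(
                    f"{self.participant_id}: se={self.se} inconsistent with "
                    f"sphere+cylinder/2={implied}"
                )


@dataclass(frozen=True)
class RegressionModel:
    """Linear axial-length model AL = beta_k*K + beta_se*SE + intercept.

    ``residual_sd`` is the standard deviation of the fit residuals in mm
    (denominator n-3).  ``coef_se`` optionally carries the analytic
    standard errors of a fitted model, keyed 'intercept', 'beta_k',
    'beta_se'.
    """

    beta_k: float
    beta_se: float
    intercept: float
    r_squared: float
    n: int
    residual_sd: float
    coef_se: Optional[dict] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError(f"r_squared must be in [0,1], got {self.r_squared}")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")

    def predict(self, k_mean, se):
        """Evaluate the model; accepts scalars or numpy arrays."""
        return self.beta_k * np.asarray(k_mean) + self.beta_se * np.asarray(se) + self.intercept

    def to_dict(self) -> dict:
        d = {
            "beta_k": self.beta_k,
            "beta_se": self.beta_se,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n": self.n,
            "residual_sd": self.residual_sd,
        }
        if self.coef_se is not None:
            d["coef_se"] = dict(self.coef_se)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionModel":
        return cls(
            beta_k=float(d["beta_k"]),
            beta_se=float(d["beta_se"]),
            intercept=float(d["intercept"]),
            r_squared=float(d["r_squared"]),
            n=int(d["n"]),
            residual_sd=float(d["residual_sd"]),
            coef_se=d.get("coef_se"),
        )

    def save_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load_json(cls, path) -> "RegressionModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


#: Published coefficients: AL_est = 2.102 K - 0.4125 SE + 7.268 (R^2 0.794),
#: fitted on n=650 post-cycloplegic eyes; residual_sd is the validation-set
#: SD of AL_est - AL_act differences (0.486 mm).
DEFAULT_AL_MODEL = RegressionModel(
    beta_k=2.102,
    beta_se=-0.4125,
    intercept=7.268,
    r_squared=0.794,
    n=650,
    residual_sd=0.486,
)


def estimate_axial_length(
    k_mean: float,
    se: float,
    model: RegressionModel = DEFAULT_AL_MODEL,
    bounds: tuple = AL_SANITY_BOUNDS,
):
    """Estimate axial length (mm) from corneal radius (mm) and SE (D).

    Out-of-range results are logged as warnings, not raised, so batch
    processing survives data-entry errors.  Accepts arrays.
    """
    k_arr = np.asarray(k_mean, dtype=float)
    if np.any(k_arr <= 0):
        raise InvalidMeasurementError("k_mean must be positive")
    al = model.predict(k_arr, se)
    lo, hi = bounds
    out = (al < lo) | (al > hi)
    if np.any(out):
        bad = np.atleast_1d(al)[np.atleast_1d(out)]
        logger.warning(
            "%d axial-length estimate(s) outside [%g, %g] mm (e.g. %.3f)",
            bad.size, lo, hi, float(bad.flat[0]),
        )
    if np.isscalar(k_mean) and np.isscalar(se):
        return float(al)
    return al


def _design(records: Iterable[BiometryRecord]):
    rows = [
        (r.k_mean, r.se, r.al_act)
        for r in records
        if r.al_act is not None and r.k_mean is not None and r.se is not None
    ]
    if len(rows) < 3:
        raise FittingError(
            f"need >= 3 records with k_mean, se and al_act; got {len(rows)}"
        )
    arr = np.asarray(rows, dtype=float)
    exog = sm.add_constant(arr[:, :2], has_constant="add")
    return exog, arr[:, 2]


def fit_al_model(records: Sequence[BiometryRecord]) -> RegressionModel:
    """Ordinary-least-squares fit of al_act on (k_mean, se) with intercept.

    Records lacking any of the three fields are excluded.  Raises
    :class:`FittingError` when fewer than three complete records remain or
    the design matrix is rank-deficient (e.g. all K identical).
    """
    exog, endog = _design(records)
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise FittingError("rank-deficient design matrix: K and SE lack variation")
    # df_resid is 0 for an exact 3-point interpolation; statsmodels'
    # internal scale divides by it, so suppress the benign warning
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sm.OLS(endog, exog).fit()
        n = int(res.nobs)
        resid_sd = math.sqrt(res.ssr / (n - 3)) if n > 3 else 0.0
        r2 = float(res.rsquared)
    # exact interpolation leaves r2 at 1 up to rounding noise
    r2 = min(max(r2, 0.0), 1.0)
    return RegressionModel(
        beta_k=float(res.params[1]),
        beta_se=float(res.params[2]),
        intercept=float(res.params[0]),
        r_squared=r2,
        n=n,
        residual_sd=resid_sd,
        coef_se={
            "intercept": float(res.bse[0]),
            "beta_k": float(res.bse[1]),
            "beta_se": float(res.bse[2]),
        },
    )
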