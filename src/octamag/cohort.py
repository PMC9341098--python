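"""Seeded synthetic biometry cohorts.

The generator emulates a young-adult population biometry cohort at the
measurement level: corneal radius K and post-cycloplegic spherical
equivalent SE are drawn from normal distributions matching the training
cohort (K ~ N(7.76, 0.26) mm, SE ~ N(-0.15, 1.62) D), and axial length is
generated *conditionally* through the estimation regression,

    AL_act = beta_k*K + beta_se*SE + intercept + N(0, residual_sd),

so that refitting the model is a well-posed parameter-recovery experiment.
Non-cycloplegic SE is the post-cycloplegic value plus an accommodation
shift (default N(-0.43, 0.30) D: eyes measure more myopic without
cycloplegia).  True FAZ areas are truncated-normal (default N(0.25, 0.10)
mm^2, floor 0.05); the uncorrected measurement is the exact inverse of the
area magnification correction at the eye's true axial length,

    FAZA_measured = FAZA_true / (p * q(AL_act))^2,

so correcting with the true axial length recovers FAZA_true to machine
precision (closure), and any discrepancy after correcting with an
*estimated* axial length is attributable to the estimate alone.

All randomness flows from the single integer seed in the spec; identical
spec + seed reproduce the cohort bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .agreement import BlandAltmanResult, PairedSample, bland_altman
from .biometry import DEFAULT_AL_MODEL, BiometryRecord, Eye, RegressionModel
from .errors import ConfigurationError
from .io import write_csv_atomic
from .magnification import RTVUE_XR_AVANTI, DeviceProfile, correct_area, linear_scale


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a synthetic cohort.

    Distribution tuples are (mean, sd).  Defaults reproduce the training
    cohort's biometry: K 7.76 (0.26) mm, post-cycloplegic SE -0.15 (1.62)
    D, regression residual SD 0.486 mm, accommodation shift -0.43 (0.30)
    D, true FAZ area 0.25 (0.10) mm^2 truncated at 0.05 mm^2.
    ``faza_noise_sd`` adds optional FAZ measurement noise (mm^2, applied to
    the uncorrected measurement); the default of 0 reflects the absence of
    replicate-scan data to pin it.
    """

    n: int
    k_mean_dist: Tuple[float, float] = (7.76, 0.26)
    se_post_dist: Tuple[float, float] = (-0.15, 1.62)
    residual_sd: float = 0.486
    accommodation_shift: Tuple[float, float] = (-0.43, 0.30)
    faza_true_dist: Tuple[float, float] = (0.25, 0.10)
    faza_truncation: float = 0.05
    faza_noise_sd: float = 0.0
    device: DeviceProfile = RTVUE_XR_AVANTI
    generating_model: RegressionModel = DEFAULT_AL_MODEL
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n < 1:
            problems.append(f"n must be >= 1, got {self.n}")
        for name in ("k_mean_dist", "se_post_dist", "accommodation_shift",
                     "faza_true_dist"):
            sd = getattr(self, name)[1]
            if sd < 0:
                problems.append(f"{name} sd must be >= 0, got {sd}")
        if self.residual_sd < 0:
            problems.append("residual_sd must be >= 0")
        if self.faza_noise_sd < 0:
            problems.append("faza_noise_sd must be >= 0")
        if self.faza_truncation <= 0:
            problems.append("faza_truncation must be > 0")
        if problems:
            raise ConfigurationError("invalid cohort spec: " + "; ".join(problems))

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "k_mean_dist": list(self.k_mean_dist),
            "se_post_dist": list(self.se_post_dist),
            "residual_sd": self.residual_sd,
            "accommodation_shift": list(self.accommodation_shift),
            "faza_true_dist": list(self.faza_true_dist),
            "faza_truncation": self.faza_truncation,
            "faza_noise_sd": self.faza_noise_sd,
            "device": {
                "name": self.device.name,
                "p_factor": self.device.p_factor,
                "reference_al_mm": self.device.reference_al,
                "scan_width_mm": self.device.scan_width,
            },
            "generating_model": self.generating_model.to_dict(),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        kwargs = dict(d)
        for name in ("k_mean_dist", "se_post_dist", "accommodation_shift",
                     "faza_true_dist"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        if "device" in kwargs:
            dev = kwargs["device"]
            kwargs["device"] = DeviceProfile(
                name=dev["name"], p_factor=dev["p_factor"],
                reference_al=dev["reference_al_mm"],
                scan_width=dev.get("scan_width_mm"),
            )
        if "generating_model" in kwargs:
            kwargs["generating_model"] = RegressionModel.from_dict(
                kwargs["generating_model"]
            )
        return cls(**kwargs)


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort with its ground truth and provenance."""

    records: Tuple[BiometryRecord, ...]
    se_noncyclo: np.ndarray
    faza_true: np.ndarray
    spec: CohortSpec = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view; faza_true_mm2 and se_noncyclo_d are synthetic-only
        ground-truth columns absent from real data."""
        df = pd.DataFrame({
            "participant_id": [r.participant_id for r in self.records],
            "eye": [r.eye.value for r in self.records],
            "k_mean_mm": [r.k_mean for r in self.records],
            "se_d": [r.se for r in self.records],
            "cycloplegic": [r.cycloplegic for r in self.records],
            "al_act_mm": [r.al_act for r in self.records],
            "faza_mm2": [r.faza_measured for r in self.records],
            "sqi": [r.sqi for r in self.records],
            "se_noncyclo_d": self.se_noncyclo,
            "faza_true_mm2": self.faza_true,
        })
        return df


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a cohort from the generative model described in the module
    docstring.  Deterministic for a given spec (including its seed)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    k = rng.normal(*spec.k_mean_dist, size=n)
    se_post = rng.normal(*spec.se_post_dist, size=n)
    al_act = spec.generating_model.predict(k, se_post) + rng.normal(
        0.0, spec.residual_sd, size=n
    )
    se_noncyclo = se_post + rng.normal(*spec.accommodation_shift, size=n)

    mu, sd = spec.faza_true_dist
    if sd > 0:
        a = (spec.faza_truncation - mu) / sd
        faza_true = stats.truncnorm.rvs(
            a, np.inf, loc=mu, scale=sd, size=n, random_state=rng
        )
    else:
        faza_true = np.full(n, max(mu, spec.faza_truncation))

    # exact inverse of the forward area correction at the true AL
    scale_sq = linear_scale(spec.device, al_act) ** 2
    faza_measured = faza_true / scale_sq
    if spec.faza_noise_sd > 0:
        faza_measured = np.clip(
            faza_measured + rng.normal(0.0, spec.faza_noise_sd, size=n), 0.0, None
        )
    sqi = rng.integers(7, 11, size=n)

    records = tuple(
        BiometryRecord(
            participant_id=f"SYN{i:04d}",
            eye=Eye.RIGHT,
            k_mean=float(k[i]),
            se=float(se_post[i]),
            cycloplegic=True,
            al_act=float(al_act[i]),
            faza_measured=float(faza_measured[i]),
            sqi=int(sqi[i]),
        )
        for i in range(n)
    )
    return SyntheticCohort(
        records=records,
        se_noncyclo=se_noncyclo,
        faza_true=faza_true,
        spec=spec,
    )


def emulate_ba_summaries(
    spec: CohortSpec,
    n_reps: int,
    seed: int,
    use_noncyclo: bool = False,
) -> List[BlandAltmanResult]:
    """Monte-Carlo harness: per replicate, generate a cohort, estimate AL
    from (K, SE), correct the measured FAZ area with both the estimated and
    the true axial length, and run Bland-Altman on (corrected-with-AL_est
    minus corrected-with-AL_act).

    ``use_noncyclo`` estimates from the accommodation-shifted SE, emulating
    a clinic without cycloplegia.
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2 ** 31)
    results: List[BlandAltmanResult] = []
    for s in child_seeds:
        rep_spec = dataclasses.replace(spec, seed=int(s))
        cohort = generate_cohort(rep_spec)
        k = np.array([r.k_mean for r in cohort.records])
        se = cohort.se_noncyclo if use_noncyclo else np.array(
            [r.se for r in cohort.records]
        )
        al_act = np.array([r.al_act for r in cohort.records])
        faza_m = np.array([r.faza_measured for r in cohort.records])
        al_est = rep_spec.generating_model.predict(k, se)
        faza_est = correct_area(faza_m, rep_spec.device, al_est)
        faza_act = correct_area(faza_m, rep_spec.device, al_act)
        labels = [r.participant_id for r in cohort.records]
        results.append(bland_altman(PairedSample(labels, faza_est, faza_act)))
    return results


def write_cohort(cohort: SyntheticCohort, csv_path, spec_path=None,
                 header_comment: Optional[str] = None) -> None:
    """Write the cohort CSV plus a sidecar JSON of the generating spec."""
    write_csv_atomic(cohort.to_frame(), csv_path, header_comment=header_comment)
    if spec_path is not None:
        with open(spec_path, "w", encoding="utf-8") as fh:
            json.dump(cohort.spec.to_dict(), fh, indent=2)
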