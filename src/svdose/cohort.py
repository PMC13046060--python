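"""Synthetic study cohorts for SV/WKP dosimetry precision analysis.

The real study design this emulates: 18 patients contribute both kidneys
(36 kidneys); each kidney's absorbed dose is estimated from the whole
kidney parenchyma and from 5 small spherical volumes at two SV volumes
(2 ml and 0.6 ml), on images post-filtered with Gaussian sigmas of
0, 3, 4, 5 and 6 mm — ten (volume, filter) conditions in all.

True doses are drawn once per kidney from a log-normal (doses are positive
and right-skewed) with median 3.76 Gy and log-sd 0.33, which puts the
central 95% of doses at roughly 2–7.2 Gy.  The same true dose is shared by
every condition of that kidney; measurement noise is drawn independently
per condition.

Default noise magnitudes are calibrated by inverting the first-order
precision formula: given the observed single-SV precision U(1) and the
asymptotic plateau U(inf), ``sigma_sv = sqrt(U1^2 - Uinf^2)`` (in
fractions) for any SV--WKP correlation rho, and sigma_wkp solves the
plateau equation.  rho defaults to 0 — the study argues the noise terms
are partially correlated but reports no value, and 0 is the conservative
(worst-precision) assumption with a closed-form calibration.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .noise_model import KidneyRecord, NoiseParams, simulate_measurements

__all__ = [
    "ConditionConfig",
    "CohortConfig",
    "calibrate_sigmas",
    "default_config",
    "generate_cohort",
]

# Observed per-filter single-SV precisions (percent), asymptotic plateaus
# (percent, the median across filters) and per-filter normalization factors
# for the two SV volumes; Gaussian filter sigmas in mm.
_FILTERS_MM = (0.0, 3.0, 4.0, 5.0, 6.0)
_SINGLE_SV_PRECISION = {
    2.0: (11.82, 11.41, 11.38, 11.29, 11.40),
    0.6: (13.13, 12.30, 12.11, 12.07, 12.24),
}
_PLATEAU = {2.0: 7.27, 0.6: 6.92}
_NF = {
    2.0: (1.12, 1.05, 1.01, 0.96, 0.91),
    0.6: (1.23, 1.14, 1.09, 1.02, 0.96),
}


class ConditionConfig(BaseModel):
    """Noise parameters of one (sv_volume_ml, filter_sigma_mm) condition."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    sv_volume_ml: float = Field(gt=0)
    filter_sigma_mm: float = Field(ge=0)
    sigma_sv: float = Field(ge=0)
    sigma_wkp: float = Field(ge=0)
    rho_sv_wkp: float = Field(default=0.0, ge=-1.0, le=1.0)
    rho_sv_sv: float = Field(default=0.0, ge=0.0, le=1.0)
    bias: float = Field(default=1.0, gt=0)

    @property
    def key(self) -> tuple[float, float]:
        return (self.sv_volume_ml, self.filter_sigma_mm)

    def noise_params(self) -> NoiseParams:
        return NoiseParams(
            sigma_sv=self.sigma_sv,
            sigma_wkp=self.sigma_wkp,
            rho_sv_wkp=self.rho_sv_wkp,
            rho_sv_sv=self.rho_sv_sv,
            bias=self.bias,
        )


class CohortConfig(BaseModel):
    """Full recipe for a synthetic cohort; JSON-serializable, unknown keys rejected."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_patients: int = Field(default=18, ge=1)
    kidneys_per_patient: int = Field(default=2, ge=1, le=2)
    svs_per_kidney: int = Field(default=5, ge=1)
    dose_median_gy: float = Field(default=3.76, gt=0)
    dose_log_sigma: float = Field(default=0.33, gt=0)
    conditions: tuple[ConditionConfig, ...]
    seed: int = 0

    @model_validator(mode="after")
    def _distinct_conditions(self) -> "CohortConfig":
        keys = [c.key for c in self.conditions]
        if not keys:
            raise ValueError("at least one condition required")
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (sv_volume_ml, filter_sigma_mm) conditions")
        for c in self.conditions:
            c.noise_params().validate_for(self.svs_per_kidney)
        return self

    @property
    def n_kidneys(self) -> int:
        return self.n_patients * self.kidneys_per_patient

    @property
    def filter_sigmas_mm(self) -> tuple[float, ...]:
        return tuple(sorted({c.filter_sigma_mm for c in self.conditions}))


def calibrate_sigmas(
    single_sv_precision: float, plateau: float, rho: float = 0.0
) -> tuple[float, float]:
    """Invert the first-order precision formula for (sigma_sv, sigma_wkp).

    Inputs are in percent: U(1), the single-SV precision, and U(inf), the
    plateau.  With rho_sv_sv = 0,

        U(1)^2   = sigma_sv^2 + sigma_wkp^2 - 2 rho sigma_sv sigma_wkp
        U(inf)^2 =              sigma_wkp^2 - 2 rho sigma_sv sigma_wkp

    so ``sigma_sv = sqrt(U1^2 - Uinf^2)`` for any rho, and sigma_wkp is the
    positive root of the plateau quadratic.  Raises if U(1) <= U(inf)
    (no real solution: averaging cannot worsen precision in this model).
    """
    u1, uinf = single_sv_precision / 100.0, plateau / 100.0
    if uinf < 0:
        raise ValueError("plateau must be non-negative")
    if u1 <= uinf:
        raise ValueError("single-SV precision must exceed the plateau")
    sigma_sv = math.sqrt(u1 * u1 - uinf * uinf)
    # sigma_wkp^2 - 2 rho sigma_sv sigma_wkp - uinf^2 = 0, positive root
    sigma_wkp = rho * sigma_sv + math.sqrt(rho * rho * sigma_sv * sigma_sv + uinf * uinf)
    if sigma_wkp < 0:
        raise ValueError("no non-negative sigma_wkp solves the plateau equation")
    return sigma_sv, sigma_wkp


def default_config(seed: int = 0) -> CohortConfig:
    """Cohort configuration calibrated to the observed study: per-filter
    sigma values from :func:`calibrate_sigmas` (rho = 0), per-filter
    normalization factors as the SV bias."""
    conditions = []
    for vol in (2.0, 0.6):
        for filt, u1, nf in zip(_FILTERS_MM, _SINGLE_SV_PRECISION[vol], _NF[vol]):
            sigma_sv, sigma_wkp = calibrate_sigmas(u1, _PLATEAU[vol], rho=0.0)
            conditions.append(
                ConditionConfig(
                    sv_volume_ml=vol,
                    filter_sigma_mm=filt,
                    sigma_sv=sigma_sv,
                    sigma_wkp=sigma_wkp,
                    rho_sv_wkp=0.0,
                    rho_sv_sv=0.0,
                    bias=nf,
                )
            )
    return CohortConfig(conditions=tuple(conditions), seed=seed)


def generate_cohort(config: CohortConfig) -> list[KidneyRecord]:
    """Simulate one cohort: one true dose per kidney (shared across all
    conditions), independent measurement noise per condition.

    Fully reproducible from ``config.seed``.  Record order: conditions in
    sorted (volume, filter) order, kidneys within each condition in
    patient/side order.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_kidneys
    mu = math.log(config.dose_median_gy)
    true_doses = np.exp(mu + config.dose_log_sigma * rng.standard_normal(n))

    width = len(str(config.n_patients))
    sides = ("left", "right")[: config.kidneys_per_patient]
    kidney_ids = [
        (f"P{p + 1:0{width}d}", side)
        for p in range(config.n_patients)
        for side in sides
    ]

    records: list[KidneyRecord] = []
    for cond in sorted(config.conditions, key=lambda c: c.key):
        sv, wkp, _ = simulate_measurements(
            true_doses, cond.noise_params(), config.svs_per_kidney, rng
        )
        for i, (pid, side) in enumerate(kidney_ids):
            records.append(
                KidneyRecord(
                    patient_id=pid,
                    kidney_side=side,
                    filter_sigma_mm=cond.filter_sigma_mm,
                    sv_volume_ml=cond.sv_volume_ml,
                    wkp_dose_gy=float(wkp[i]),
                    sv_doses_gy=tuple(sv[i]),
                    true_dose_gy=float(true_doses[i]),
                )
            )
    return records
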