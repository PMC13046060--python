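"""Generative measurement model for small-volume (SV) kidney dosimetry.

Each kidney carries an unknown true absorbed dose ``D`` (Gy).  The
whole-kidney-parenchyma (WKP) estimate and the ``m`` small-volume estimates
are modelled as multiplicative perturbations of that dose::

    D_WKP  = D * (1 + eps_wkp)
    D_SV_i = D * b * (1 + eps_i),     i = 1..m

where ``b`` is the systematic SV bias (the population quantity the
normalization factor estimates) and ``(eps_1 .. eps_m, eps_wkp)`` is a
jointly zero-mean Gaussian vector with

* ``Var(eps_i)   = sigma_sv**2``
* ``Var(eps_wkp) = sigma_wkp**2``
* ``Corr(eps_i, eps_wkp) = rho_sv_wkp``  (shared spatial origin of SV and WKP)
* ``Corr(eps_i, eps_j)   = rho_sv_sv``   (compound symmetry among SVs)

Because SVs sample the same spatially autocorrelated image as the WKP,
their noise terms are in general partially correlated; ``rho_sv_wkp = 1``
makes a single SV coincide with the reference and the relative difference
vanishes, ``rho_sv_wkp = 0`` is the independent (worst-precision) regime.

The module also provides closed-form delta-method oracles for the mean and
standard deviation of the relative difference RD = (SV_mean - WKP)/WKP.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "NoiseParams",
    "KidneyRecord",
    "KidneyMeasurement",
    "simulate_kidney_measurement",
    "simulate_measurements",
    "analytic_rd_sd",
    "analytic_rd_bias",
]

#: tolerance below which a covariance eigenvalue / radicand counts as zero
_PSD_TOL = 1e-10


@dataclass(frozen=True)
class NoiseParams:
    """Noise magnitudes, correlations and multiplicative bias of one
    measurement condition (one SV volume at one Gaussian post-filter).

    Parameters
    ----------
    sigma_sv : float
        Relative noise of a single SV dose estimate (dimensionless
        fraction, e.g. 0.12 for 12%).
    sigma_wkp : float
        Relative noise of the WKP dose estimate (fraction).
    rho_sv_wkp : float
        Correlation between each SV noise term and the WKP noise term,
        in [-1, 1].
    rho_sv_sv : float
        Pairwise correlation among distinct SV noise terms, in [0, 1].
        Default 0 (spatially independent SV placements).
    bias : float
        Multiplicative SV bias ``b > 0``; SV doses centre on ``b * D``.
    """

    sigma_sv: float
    sigma_wkp: float
    rho_sv_wkp: float = 0.0
    rho_sv_sv: float = 0.0
    bias: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_sv < 0 or self.sigma_wkp < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if abs(self.rho_sv_wkp) > 1:
            raise ValueError("rho_sv_wkp must lie in [-1, 1]")
        if not 0 <= self.rho_sv_sv <= 1:
            raise ValueError("rho_sv_sv must lie in [0, 1]")
        if self.bias <= 0:
            raise ValueError("bias must be positive")

    def covariance(self, m_sv: int) -> np.ndarray:
        """Joint covariance of ``(eps_1..eps_m, eps_wkp)`` for ``m_sv`` SVs."""
        if m_sv < 1:
            raise ValueError("m_sv must be >= 1")
        s, w = self.sigma_sv, self.sigma_wkp
        cov = np.empty((m_sv + 1, m_sv + 1))
        cov[:m_sv, :m_sv] = self.rho_sv_sv * s * s
        np.fill_diagonal(cov[:m_sv, :m_sv], s * s)
        cov[:m_sv, m_sv] = cov[m_sv, :m_sv] = self.rho_sv_wkp * s * w
        cov[m_sv, m_sv] = w * w
        return cov

    def validate_for(self, m_sv: int) -> None:
        """Reject parameter combinations whose joint covariance is not
        positive semi-definite for ``m_sv`` SVs.

        With compound symmetry the binding condition is
        ``m * rho_sv_wkp**2 <= 1 + (m - 1) * rho_sv_sv``: many SVs that are
        mutually independent cannot each be strongly correlated with the
        single WKP term.
        """
        if self.sigma_sv == 0 or self.sigma_wkp == 0:
            return  # degenerate covariance is always PSD
        lhs = m_sv * self.rho_sv_wkp**2
        rhs = 1.0 + (m_sv - 1) * self.rho_sv_sv
        if lhs > rhs + _PSD_TOL:
            raise ValueError(
                f"covariance not positive semi-definite for m={m_sv}: "
                f"m*rho_sv_wkp^2 = {lhs:.4g} > 1+(m-1)*rho_sv_sv = {rhs:.4g}"
            )


@dataclass(frozen=True)
class KidneyRecord:
    """One kidney's WKP dose and its SV doses under one condition."""

    patient_id: str
    kidney_side: str  # "left" | "right"
    filter_sigma_mm: float
    sv_volume_ml: float
    wkp_dose_gy: float
    sv_doses_gy: tuple[float, ...]
    true_dose_gy: float | None = None

    def __post_init__(self) -> None:
        if self.kidney_side not in ("left", "right"):
            raise ValueError(f"kidney_side must be 'left' or 'right', got {self.kidney_side!r}")
        object.__setattr__(self, "sv_doses_gy", tuple(float(x) for x in self.sv_doses_gy))
        if not self.sv_doses_gy:
            raise ValueError("sv_doses_gy must be non-empty")
        if self.wkp_dose_gy <= 0 or any(d <= 0 for d in self.sv_doses_gy):
            raise ValueError("all doses must be strictly positive")
        if self.true_dose_gy is not None and self.true_dose_gy <= 0:
            raise ValueError("true_dose_gy must be positive when given")

    @property
    def n_sv(self) -> int:
        return len(self.sv_doses_gy)

    @property
    def condition(self) -> tuple[float, float]:
        """(sv_volume_ml, filter_sigma_mm) stratum key."""
        return (self.sv_volume_ml, self.filter_sigma_mm)

    @property
    def kidney_key(self) -> tuple[str, str]:
        return (self.patient_id, self.kidney_side)


class KidneyMeasurement(NamedTuple):
    sv_doses_gy: tuple[float, ...]
    wkp_dose_gy: float
    n_redraws: int


def _noise_factor(params: NoiseParams, m_sv: int) -> np.ndarray:
    """Square-root factor F with F @ F.T = covariance, via eigendecomposition
    (the covariance may be singular, e.g. at rho = 1)."""
    cov = params.covariance(m_sv)
    vals, vecs = np.linalg.eigh(cov)
    if vals.min() < -_PSD_TOL * max(1.0, vals.max()):
        raise ValueError("covariance not positive semi-definite")
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def simulate_measurements(
    true_doses: np.ndarray | Sequence[float] | float,
    params: NoiseParams,
    m_sv: int,
    rng: np.random.Generator,
    max_redraws: int = 1000,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorised draw of SV and WKP dose estimates for many kidneys.

    Any kidney whose draw produces a non-positive dose factor ``1 + eps``
    has its *entire* noise vector redrawn (per-component truncation would
    distort the joint correlation structure).  At realistic noise levels
    (sigma <= 0.15) redraws are vanishingly rare (< 1e-6 per kidney).

    Returns
    -------
    sv : (n, m_sv) array, wkp : (n,) array, n_redraws : int
    """
    true = np.atleast_1d(np.asarray(true_doses, dtype=float))
    if np.any(true <= 0):
        raise ValueError("true doses must be positive")
    if m_sv < 1:
        raise ValueError("m_sv must be >= 1")
    params.validate_for(m_sv)
    factor = _noise_factor(params, m_sv)
    n = true.shape[0]

    eps = rng.standard_normal((n, m_sv + 1)) @ factor.T
    n_redraws = 0
    bad = np.any(eps <= -1.0, axis=1)
    rounds = 0
    while np.any(bad):
        rounds += 1
        n_redraws += int(bad.sum())
        if n_redraws > max_redraws or rounds > max_redraws:
            raise RuntimeError(
                f"rejection cap exceeded ({n_redraws} redraws): noise levels "
                "are incompatible with strictly positive doses"
            )
        eps[bad] = rng.standard_normal((int(bad.sum()), m_sv + 1)) @ factor.T
        bad = np.any(eps <= -1.0, axis=1)

    sv = true[:, None] * params.bias * (1.0 + eps[:, :m_sv])
    wkp = true * (1.0 + eps[:, m_sv])
    return sv, wkp, n_redraws


def simulate_kidney_measurement(
    true_dose: float,
    params: NoiseParams,
    m_sv: int,
    rng: np.random.Generator,
    max_redraws: int = 1000,
) -> KidneyMeasurement:
    """Draw one kidney's SV doses and WKP dose; see :func:`simulate_measurements`."""
    sv, wkp, n_redraws = simulate_measurements(float(true_dose), params, m_sv, rng, max_redraws)
    return KidneyMeasurement(tuple(sv[0]), float(wkp[0]), n_redraws)


def analytic_rd_sd(params: NoiseParams, k: int | float) -> float:
    """First-order (delta-method) standard deviation of RD(k), in percent.

    RD(k) = (mean of k SV doses - WKP)/WKP on bias-free doses; to first
    order its variance is the variance of ``eps_bar(k) - eps_wkp``::

        sigma_sv^2 * (1/k + (1 - 1/k) * rho_sv_sv)
          + sigma_wkp^2 - 2 * rho_sv_wkp * sigma_sv * sigma_wkp

    With independent noise and a noise-free reference this reduces to the
    central-limit ``sigma_sv / sqrt(k)`` scaling.  A negative radicand means
    the parameter combination has no valid joint distribution at this k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    s, w, rho = params.sigma_sv, params.sigma_wkp, params.rho_sv_wkp
    radicand = (
        s * s * (1.0 / k + (1.0 - 1.0 / k) * params.rho_sv_sv)
        + w * w
        - 2.0 * rho * s * w
    )
    if radicand < -_PSD_TOL:
        raise ValueError(f"negative RD variance ({radicand:.3g}): invalid parameters at k={k}")
    return 100.0 * math.sqrt(max(radicand, 0.0))


def analytic_rd_bias(params: NoiseParams) -> float:
    """Second-order mean of the un-normalized RD at any k, in percent.

    Expanding ``(eps_bar - eps_wkp)/(1 + eps_wkp)`` to second order gives
    ``sigma_wkp^2 - rho_sv_wkp * sigma_sv * sigma_wkp``: the noisy
    denominator induces a small positive bias even for zero-mean noise.
    After in-sample normalization-factor correction (see
    :mod:`svdose.precision_stats`) the empirical bias is zero by
    construction, which is why observed biases are negligible.

    Valid only for small WKP noise (guard: sigma_wkp < 0.3).
    """
    if params.sigma_wkp >= 0.3:
        raise ValueError("second-order expansion requires sigma_wkp < 0.3")
    s, w, rho = params.sigma_sv, params.sigma_wkp, params.rho_sv_wkp
    return 100.0 * (w * w - rho * s * w)
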