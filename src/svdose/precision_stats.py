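"""Estimators on SV/WKP dose tables.

* the normalization factor NF = mean of per-SV dose ratios D_SV/D_WKP over a
  stratum, with its standard error — the ratio estimator of the systematic
  SV bias;
* relative differences RD(k) = 100 * (SV_mean(k) - WKP)/WKP pooled over SV
  subsets of size k;
* the empirical precision curve U(k) = sd(RD(k));
* the empirical bias (mean RD) and a rank-sum comparison of two groups of
  precision estimates.

Subset convention: for k below the number of available SVs, *all* C(m, k)
subsets per kidney are enumerated (or a uniform sample of them), each
contributing one RD sample, and the standard deviation is taken over the
pooled samples.  Subset RDs within a kidney are pooled rather than first
averaged within the kidney — averaging all size-k subset means reproduces
the full-m mean and would erase the k-dependence.  Pooled samples from one
kidney are statistically dependent, so ``n_samples`` overstates the
effective sample size; U(k) remains a valid dispersion estimate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .noise_model import KidneyRecord

__all__ = [
    "RdSample",
    "PrecisionCurve",
    "NormalizationFactor",
    "relative_difference",
    "normalization_factor",
    "normalization_factors_by_stratum",
    "normalize_records",
    "rd_pool",
    "precision_curve",
    "bias",
    "compare_precision",
    "split_strata",
]


@dataclass(frozen=True)
class RdSample:
    """One relative-difference sample: one SV subset of one kidney."""

    kidney_key: tuple[str, str]
    k: int
    subset_index: tuple[int, ...]
    rd_percent: float


@dataclass(frozen=True)
class PrecisionCurve:
    """Empirical precision U(k) = sd(RD(k)) in percent over a grid of k."""

    k_values: tuple[int, ...]
    u_percent: tuple[float, ...]
    n_samples: tuple[int, ...]
    condition: tuple[float, float] | None = None  # (sv_volume_ml, filter_sigma_mm)

    def __post_init__(self) -> None:
        if not (len(self.k_values) == len(self.u_percent) == len(self.n_samples)):
            raise ValueError("k_values, u_percent and n_samples must have equal length")
        if any(k < 1 for k in self.k_values):
            raise ValueError("k values must be >= 1")
        if list(self.k_values) != sorted(set(self.k_values)):
            raise ValueError("k_values must be ascending and distinct")
        if any(u < 0 for u in self.u_percent):
            raise ValueError("u_percent must be non-negative")


class NormalizationFactor(NamedTuple):
    nf: float
    sem: float
    n: int


def relative_difference(sv_value: float, wkp_value: float) -> float:
    """RD in percent: ``100 * (sv_value - wkp_value) / wkp_value``."""
    if wkp_value <= 0:
        raise ValueError("reference (WKP) value must be positive")
    return 100.0 * (sv_value - wkp_value) / wkp_value


def split_strata(records: Iterable[KidneyRecord]) -> dict[tuple[float, float], list[KidneyRecord]]:
    """Group records by (sv_volume_ml, filter_sigma_mm) stratum, sorted keys."""
    out: dict[tuple[float, float], list[KidneyRecord]] = {}
    for rec in records:
        out.setdefault(rec.condition, []).append(rec)
    return dict(sorted(out.items()))


def _single_condition(records: Sequence[KidneyRecord]) -> tuple[float, float] | None:
    conditions = {rec.condition for rec in records}
    return conditions.pop() if len(conditions) == 1 else None


def normalization_factor(records: Sequence[KidneyRecord]) -> NormalizationFactor:
    """Mean and SEM of the pooled per-SV dose ratios D_SV_i / D_WKP.

    The caller controls stratification: pass one stratum's records for a
    per-condition NF (the usual case; see
    :func:`normalization_factors_by_stratum`) or all records for a pooled,
    all-strata estimate.  SEM uses the sample standard deviation (ddof=1)
    of the ratios divided by sqrt(n).
    """
    ratios = np.array([sv / rec.wkp_dose_gy for rec in records for sv in rec.sv_doses_gy])
    if ratios.size < 2:
        raise ValueError("need at least 2 SV/WKP ratios")
    nf = float(ratios.mean())
    sem = float(ratios.std(ddof=1) / math.sqrt(ratios.size))
    return NormalizationFactor(nf, sem, int(ratios.size))


def normalization_factors_by_stratum(
    records: Iterable[KidneyRecord],
) -> dict[tuple[float, float], NormalizationFactor]:
    return {cond: normalization_factor(recs) for cond, recs in split_strata(records).items()}


def normalize_records(records: Sequence[KidneyRecord], nf: float) -> list[KidneyRecord]:
    """Divide every SV dose by ``nf``; WKP doses are the reference and stay."""
    if nf <= 0:
        raise ValueError("normalization factor must be positive")
    return [
        KidneyRecord(
            patient_id=rec.patient_id,
            kidney_side=rec.kidney_side,
            filter_sigma_mm=rec.filter_sigma_mm,
            sv_volume_ml=rec.sv_volume_ml,
            wkp_dose_gy=rec.wkp_dose_gy,
            sv_doses_gy=tuple(d / nf for d in rec.sv_doses_gy),
            true_dose_gy=rec.true_dose_gy,
        )
        for rec in records
    ]


def _subsets_for(
    m: int, k: int, n_subsets: int | None, rng: np.random.Generator | None
) -> list[tuple[int, ...]]:
    all_subsets = list(itertools.combinations(range(m), k))
    if n_subsets is None:
        return all_subsets
    if n_subsets <= 0:
        raise ValueError("n_subsets must be positive")
    if n_subsets >= len(all_subsets):
        return all_subsets
    assert rng is not None
    idx = rng.choice(len(all_subsets), size=n_subsets, replace=False)
    return [all_subsets[i] for i in sorted(idx)]


def rd_pool(
    records: Sequence[KidneyRecord],
    k: int,
    n_subsets: int | None = None,
    seed: int | None = None,
) -> list[RdSample]:
    """Pooled RD(k) samples over all kidneys and SV subsets of size k.

    ``n_subsets=None`` enumerates all C(m, k) subsets per kidney in
    lexicographic order (deterministic); an integer draws that many subsets
    uniformly without replacement within each kidney, seeded by ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    short = [rec for rec in records if rec.n_sv < k]
    if short:
        raise ValueError(f"k={k} exceeds the SV count of {len(short)} record(s)")
    rng = np.random.default_rng(seed) if n_subsets is not None else None
    samples: list[RdSample] = []
    for rec in records:
        doses = np.asarray(rec.sv_doses_gy)
        for subset in _subsets_for(rec.n_sv, k, n_subsets, rng):
            sv_mean = float(doses[list(subset)].mean())
            samples.append(
                RdSample(
                    kidney_key=rec.kidney_key,
                    k=k,
                    subset_index=subset,
                    rd_percent=relative_difference(sv_mean, rec.wkp_dose_gy),
                )
            )
    return samples


def precision_curve(
    records: Sequence[KidneyRecord],
    k_values: Sequence[int],
    n_subsets: int | None = None,
    seed: int | None = None,
) -> PrecisionCurve:
    """U(k) = sample standard deviation (ddof=1) of pooled RD(k) samples."""
    if not len(k_values):
        raise ValueError("k_values must be non-empty")
    ks = sorted(set(int(k) for k in k_values))
    u, n = [], []
    for k in ks:
        rds = np.array([s.rd_percent for s in rd_pool(records, k, n_subsets, seed)])
        if rds.size < 2:
            raise ValueError(f"fewer than 2 RD samples at k={k}")
        u.append(float(rds.std(ddof=1)))
        n.append(int(rds.size))
    return PrecisionCurve(tuple(ks), tuple(u), tuple(n), condition=_single_condition(records))


def bias(
    records: Sequence[KidneyRecord],
    k: int = 1,
    n_subsets: int | None = None,
    seed: int | None = None,
) -> float:
    """Mean of the pooled RD(k) samples, percent.

    After dividing SV doses by the in-sample NF of the same stratum, the
    k=1 bias is zero up to floating-point roundoff by construction
    (mean ratio / NF = 1)."""
    rds = [s.rd_percent for s in rd_pool(records, k, n_subsets, seed)]
    return float(np.mean(rds))


def compare_precision(
    rd_dispersions_a: Sequence[float], rd_dispersions_b: Sequence[float]
) -> float:
    """Two-sided Wilcoxon rank-sum p-value comparing two groups of precision
    estimates (e.g. per-filter U values of two SV volumes).

    Exact null enumeration for tie-free groups below 20 observations each,
    otherwise the normal approximation with midranks for ties.
    """
    a = np.asarray(rd_dispersions_a, dtype=float)
    b = np.asarray(rd_dispersions_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    small = max(a.size, b.size) < 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)
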