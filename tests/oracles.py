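"""Independent oracles used by the test suite.

These deliberately avoid the code paths they are meant to check: the RD
moments are obtained by Gauss-Hermite quadrature over the reference (WKP)
noise with closed-form conditional Gaussian moments, not by the package's
first-order formula, and the RD pooling oracle is a direct nested-loop
enumeration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def exact_rd_moments(sigma_sv, sigma_wkp, rho_sv_wkp, rho_sv_sv, k, n_nodes=120):
    """Exact mean and sd (percent) of RD = 100*(eps_bar - w)/(1 + w).

    eps_bar is the mean of k jointly Gaussian SV noise terms; conditional on
    the WKP noise w, eps_bar is Gaussian with mean rho*sigma_sv*w/sigma_wkp
    and variance sbar^2 - rho^2*sigma_sv^2, so E[RD | w] and E[RD^2 | w] are
    closed-form and the outer integral over w ~ N(0, sigma_wkp^2) is done by
    Gauss-Hermite quadrature.
    """
    sbar2 = sigma_sv**2 * (1.0 / k + (1.0 - 1.0 / k) * rho_sv_sv)
    if sigma_wkp == 0.0:
        return 0.0, 100.0 * math.sqrt(sbar2)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = nodes * sigma_wkp
    weights = weights / math.sqrt(2.0 * math.pi)
    m_c = rho_sv_wkp * sigma_sv * w / sigma_wkp
    v_c = max(sbar2 - (rho_sv_wkp * sigma_sv) ** 2, 0.0)
    e1 = np.sum(weights * (m_c - w) / (1.0 + w))
    e2 = np.sum(weights * ((m_c - w) ** 2 + v_c) / (1.0 + w) ** 2)
    var = max(e2 - e1 * e1, 0.0)
    return 100.0 * e1, 100.0 * math.sqrt(var)


def first_order_truncation_bound(sigma_wkp):
    """A priori relative-error bound of the first-order sd formula.

    The noisy denominator inflates the true RD sd by approximately
    (3/2)*sigma_wkp^2 relative; 4*sigma_wkp^2 is a safe envelope for
    sigma_wkp <= 0.15.
    """
    return 4.0 * sigma_wkp**2


def brute_force_rd_sd(records, k):
    """RD pooling and dispersion by direct enumeration (no numpy vectorisation,
    no shared helpers): all size-k index subsets per kidney, pooled sd with
    denominator n-1."""
    rds = []
    for rec in records:
        for subset in itertools.combinations(range(len(rec.sv_doses_gy)), k):
            mean = sum(rec.sv_doses_gy[i] for i in subset) / k
            rds.append(100.0 * (mean - rec.wkp_dose_gy) / rec.wkp_dose_gy)
    n = len(rds)
    mu = sum(rds) / n
    return rds, math.sqrt(sum((x - mu) ** 2 for x in rds) / (n - 1))
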