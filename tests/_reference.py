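"""Independent oracle implementations used only by tests.

Everything here is written naively (plain loops, dense quadrature) and
directly from the published formulas, so the main package code is checked
against a second, independent path.
"""

from __future__ import annotations

import numpy as np


def chao2_reference(matrix, bias_corrected=True) -> float:
    """Bias-corrected Chao2 straight from a unit-by-taxon 0/1 matrix."""
    matrix = [list(row) for row in matrix]
    m = len(matrix)
    n_taxa = len(matrix[0]) if m else 0
    incidence = [sum(1 for row in matrix if row[j] > 0) for j in range(n_taxa)]
    s_obs = sum(1 for c in incidence if c > 0)
    if s_obs == 0:
        return 0.0
    if m == 1:
        return float(s_obs)
    q1 = sum(1 for c in incidence if c == 1)
    q2 = sum(1 for c in incidence if c == 2)
    if not bias_corrected and q2 > 0:
        return s_obs + (m - 1) / m * q1 * q1 / (2.0 * q2)
    return s_obs + (m - 1) / m * q1 * (q1 - 1) / (2.0 * (q2 + 1))


def ice_reference(matrix, cutoff=10) -> float:
    """ICE straight from a unit-by-taxon 0/1 matrix, loop by loop."""
    matrix = [list(row) for row in matrix]
    m = len(matrix)
    n_taxa = len(matrix[0]) if m else 0
    incidence = [sum(1 for row in matrix if row[j] > 0) for j in range(n_taxa)]
    s_obs = sum(1 for c in incidence if c > 0)
    if s_obs == 0:
        return 0.0
    if m == 1:
        return float(s_obs)
    infreq = [j for j in range(n_taxa) if 1 <= incidence[j] <= cutoff]
    s_infreq = len(infreq)
    if s_infreq == 0:
        return float(s_obs)
    s_freq = s_obs - s_infreq
    n_infreq = sum(incidence[j] for j in infreq)
    q1 = sum(1 for c in incidence if c == 1)
    coverage = 1.0 - q1 / n_infreq
    if coverage == 0.0:
        return chao2_reference(matrix)
    m_infreq = sum(
        1 for row in matrix if any(row[j] > 0 for j in infreq)
    )
    if m_infreq > 1:
        sum_jj1 = sum(incidence[j] * (incidence[j] - 1) for j in infreq)
        gamma2 = (
            (s_infreq / coverage)
            * (m_infreq / (m_infreq - 1.0))
            * sum_jj1
            / (n_infreq * n_infreq)
            - 1.0
        )
        gamma2 = max(gamma2, 0.0)
    else:
        gamma2 = 0.0
    return s_freq + s_infreq / coverage + (q1 / coverage) * gamma2


def lognormal_reference(N, Nmax, Nmin=1.0, npts=400_001):
    """Dense trapezoid quadrature + bisection solve of the lognormal model.

    Returns (S_total, a). Written before/independently of the closed-form
    error-function solver.
    """
    ymin, ymax = np.log(Nmin), np.log(Nmax)
    y0 = 0.5 * (ymin + ymax)
    h = 0.5 * (ymax - ymin)
    y = np.linspace(ymin, ymax, npts)

    def individuals(a):
        s0 = np.exp((a * h) ** 2)
        return np.trapezoid(s0 * np.exp(y - a * a * (y - y0) ** 2), y)

    lo, hi = 1e-8, 1.0
    while individuals(hi) < N:
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("no bracket")
    for _ in range(120):
        mid = 0.5 * (lo + hi)
        if individuals(mid) < N:
            lo = mid
        else:
            hi = mid
    a = 0.5 * (lo + hi)
    s0 = np.exp((a * h) ** 2)
    s_total = np.trapezoid(s0 * np.exp(-a * a * (y - y0) ** 2), y)
    return float(s_total), float(a)


def expected_realized_richness(probs, n) -> float:
    """Expected number of taxa with >= 1 read in a multinomial(n, probs) draw."""
    probs = np.asarray(probs, dtype=float)
    return float(np.sum(1.0 - (1.0 - probs) ** n))
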