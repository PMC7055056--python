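"""Incidence-based nonparametric richness estimators: Chao2 and ICE.

Both work from incidence frequency counts ``Q[j]`` — the number of taxa
present in exactly ``j`` of ``m`` sampling units. The Chao2 implementation
defaults to the bias-corrected form

    S_chao2 = S_obs + ((m - 1) / m) * Q1 * (Q1 - 1) / (2 * (Q2 + 1))

which is finite for Q2 = 0; the classic form (Q1^2 / (2 Q2)) is available
behind a flag. ICE follows the standard coverage-based definition with the
conventional infrequent cutoff of 10 units.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import sparse

from microcensus.corpus_io import IncidenceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "IncidenceFrequencies",
    "incidence_frequencies",
    "incidence_frequencies_from_counts",
    "chao2",
    "ice",
]


@dataclass
class IncidenceFrequencies:
    """Incidence frequency counts for a unit-by-taxon presence matrix.

    ``presence`` (optional) retains the source matrix; ICE needs it to count
    the units that contain at least one infrequent taxon.
    """

    m: int
    Q: Mapping[int, int]
    S_obs: int
    presence: sparse.csr_array | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if any(j < 1 or j > self.m for j in self.Q):
            raise ValueError("incidence classes must satisfy 1 <= j <= m")
        if any(q < 0 for q in self.Q.values()):
            raise ValueError("frequency counts must be non-negative")
        if sum(self.Q.values()) != self.S_obs:
            raise ValueError("sum of Q[j] must equal S_obs")

    def q(self, j: int) -> int:
        return int(self.Q.get(j, 0))


def incidence_frequencies(incidence: IncidenceMatrix) -> IncidenceFrequencies:
    """Compute Q[j] from an IncidenceMatrix (all-zero taxa excluded)."""
    counts = incidence.incidence_counts
    counts = counts[counts > 0]
    ks, qs = np.unique(counts, return_counts=True)
    return IncidenceFrequencies(
        m=incidence.m,
        Q={int(k): int(q) for k, q in zip(ks, qs)},
        S_obs=int(counts.size),
        presence=incidence.presence,
    )


def incidence_frequencies_from_counts(abundance: np.ndarray) -> IncidenceFrequencies:
    """Fast path: build frequencies straight from a unit-by-taxon count array."""
    abundance = np.asarray(abundance)
    presence = abundance > 0
    counts = presence.sum(axis=0)
    counts = counts[counts > 0]
    ks, qs = np.unique(counts, return_counts=True)
    return IncidenceFrequencies(
        m=int(abundance.shape[0]),
        Q={int(k): int(q) for k, q in zip(ks, qs)},
        S_obs=int(counts.size),
        presence=sparse.csr_array(presence.astype(np.int8)),
    )


def chao2(freqs: IncidenceFrequencies, bias_corrected: bool = True) -> float:
    """Chao2 incidence-based richness estimate.

    The bias-corrected default is always finite and >= S_obs; it equals
    S_obs exactly when Q1 <= 1. The classic variant falls back to the
    corrected form when Q2 = 0.
    """
    s_obs = freqs.S_obs
    if s_obs == 0:
        return 0.0
    m = freqs.m
    if m == 1:
        warnings.warn(
            "Chao2 is undefined for a single sampling unit; returning S_obs",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(s_obs)
    q1, q2 = freqs.q(1), freqs.q(2)
    k = (m - 1) / m
    if not bias_corrected and q2 > 0:
        return s_obs + k * q1 * q1 / (2.0 * q2)
    return s_obs + k * q1 * (q1 - 1) / (2.0 * (q2 + 1))


def ice(freqs: IncidenceFrequencies, infrequent_cutoff: int = 10) -> float:
    """Incidence-based coverage estimator (ICE).

    Taxa with incidence <= ``infrequent_cutoff`` form the infrequent group;
    sample coverage C = 1 - Q1 / N_infreq, and the squared CV of infrequent
    incidences (floored at 0) inflates the singleton term:

        S_ice = S_freq + S_infreq / C + (Q1 / C) * gamma^2

    Degenerate cases: no infrequent taxa -> S_obs; C = 0 (all infrequent
    taxa are singletons) -> bias-corrected Chao2 fallback (logged); fewer
    than two units holding infrequent taxa -> gamma^2 = 0.
    """
    if infrequent_cutoff < 1:
        raise ValueError("infrequent_cutoff must be >= 1")
    s_obs = freqs.S_obs
    if s_obs == 0:
        return 0.0
    m = freqs.m
    if m == 1:
        warnings.warn(
            "ICE is undefined for a single sampling unit; returning S_obs",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(s_obs)
    cutoff = infrequent_cutoff
    s_infreq = sum(q for j, q in freqs.Q.items() if j <= cutoff)
    if s_infreq == 0:
        return float(s_obs)
    s_freq = s_obs - s_infreq
    n_infreq = sum(j * q for j, q in freqs.Q.items() if j <= cutoff)
    q1 = freqs.q(1)
    coverage = 1.0 - q1 / n_infreq
    if coverage == 0.0:
        logger.info(
            "ICE coverage is zero (all infrequent taxa are singletons); "
            "falling back to bias-corrected Chao2"
        )
        return chao2(freqs)
    m_infreq = _units_with_infrequent_taxa(freqs, cutoff)
    if m_infreq > 1:
        sum_jj1 = sum(j * (j - 1) * q for j, q in freqs.Q.items() if j <= cutoff)
        gamma2 = max(
            (s_infreq / coverage)
            * (m_infreq / (m_infreq - 1.0))
            * sum_jj1
            / (n_infreq * n_infreq)
            - 1.0,
            0.0,
        )
    else:
        gamma2 = 0.0
    return s_freq + s_infreq / coverage + (q1 / coverage) * gamma2


def _units_with_infrequent_taxa(freqs: IncidenceFrequencies, cutoff: int) -> int:
    if freqs.presence is None:
        raise ValueError(
            "ICE needs the source presence matrix to count units holding "
            "infrequent taxa; build frequencies with incidence_frequencies()"
        )
    presence = freqs.presence
    col_incidence = np.asarray(presence.sum(axis=0)).ravel()
    infreq_cols = np.flatnonzero((col_incidence >= 1) & (col_incidence <= cutoff))
    if infreq_cols.size == 0:
        return 0
    per_unit = np.asarray(presence[:, infreq_cols].sum(axis=1)).ravel()
    return int(np.count_nonzero(per_unit))
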