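"""Per-assemblage species-abundance distribution (SAD) summaries.

For every sample the four scaling-law response variables are computed from
the vector of positive counts:

* ``N``        — total reads/individuals.
* ``S``        — observed richness.
* ``Nmax``     — dominance, the abundance of the most abundant taxon.
* ``evenness`` — Simpson evenness, (1 / sum p_i^2) / S, in (0, 1] and equal
  to 1 iff all abundances are equal.
* ``rarity``   — sample skewness (bias-corrected G1) of log10 abundances;
  defined as 0 when S < 3 or all abundances are equal. Skewness is
  location/scale invariant, so the log base is cosmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from microcensus.corpus_io import TaxonTable

__all__ = ["SADSummary", "summarize_sample", "summarize_corpus", "summaries_to_frame"]


@dataclass(frozen=True)
class SADSummary:
    sample_id: str
    N: int
    S: int
    Nmax: int
    evenness: float
    rarity: float

    def __post_init__(self) -> None:
        if not (1 <= self.Nmax <= self.N):
            raise ValueError("invariant violated: 1 <= Nmax <= N")
        if not (1 <= self.S <= self.N):
            raise ValueError("invariant violated: 1 <= S <= N")


def summarize_sample(counts, sample_id: str = "sample") -> SADSummary:
    """Summarize one assemblage's count vector (zeros ignored)."""
    counts = np.asarray(counts)
    if counts.size and np.issubdtype(counts.dtype, np.floating):
        if np.any(counts != np.rint(counts)):
            raise ValueError("counts must be integers")
        counts = counts.astype(np.int64)
    if counts.size and np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    positive = counts[counts > 0]
    if positive.size == 0:
        raise ValueError("assemblage has no positive counts")
    positive = np.sort(positive)[::-1]  # canonical order: permutation-invariant
    n = int(positive.sum())
    s = int(positive.size)
    nmax = int(positive.max())
    p = positive / n
    evenness = float((1.0 / np.sum(p * p)) / s)
    logs = np.log10(positive.astype(float))
    if s < 3 or np.ptp(logs) == 0.0:
        rarity = 0.0
    else:
        rarity = float(stats.skew(logs, bias=False))
    return SADSummary(
        sample_id=str(sample_id), N=n, S=s, Nmax=nmax, evenness=evenness, rarity=rarity
    )


def summarize_corpus(table: TaxonTable) -> list[SADSummary]:
    """One SADSummary per sample, in table order."""
    csr = table.counts
    out = []
    for i, sid in enumerate(table.sample_ids):
        row = csr.data[csr.indptr[i] : csr.indptr[i + 1]]
        out.append(summarize_sample(row, sample_id=sid))
    return out


def summaries_to_frame(summaries: Sequence[SADSummary]):
    """Tabulate summaries for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in summaries],
            "N": [s.N for s in summaries],
            "S": [s.S for s in summaries],
            "Nmax": [s.Nmax for s in summaries],
            "evenness": [s.evenness for s in summaries],
            "rarity": [s.rarity for s in summaries],
        }
    )
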