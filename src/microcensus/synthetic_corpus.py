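"""Ground-truthed synthetic corpora with known scaling structure.

Each corpus emulates a large 16S-style compilation: per-sample read totals
``N`` span several orders of magnitude (log-uniform), per-sample richness
and dominance follow power laws of N with known exponents

    S_target    = c_richness * N^z_richness * 10^eps,
    Nmax_target = N^z_dominance * 10^eps',      eps ~ Normal(0, noise_sigma)

and each sample carries a right-skewed (lognormal) relative-abundance
vector whose top entry is pinned to ``Nmax_target / N``. Counts are a
single multinomial draw of N reads, so realized richness can fall below the
target through thinning of rare taxa. Taxon identities are drawn from a
shared Dirichlet-weighted global pool so taxa recur across samples.

Targets are recorded as exact floats: on a noiseless spec, regressing
``log10(S_target)`` on ``log10(N)`` recovers ``z_richness`` exactly.

Seeding: the corpus seed feeds a ``SeedSequence`` whose first child governs
the pool weights and whose subsequent children each govern one sample, so
sub-streams are independently reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from microcensus.corpus_io import TaxonTable

logger = logging.getLogger(__name__)

__all__ = ["CorpusSpec", "SyntheticCorpus", "generate_corpus", "truth_report"]


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of a synthetic corpus with known scaling truth."""

    n_samples: int
    logN_range: tuple[float, float] = (3.0, 6.0)
    z_richness: float = 0.5
    c_richness: float = 1.0
    z_dominance: float = 0.9
    sad_sigma: float = 1.5
    noise_sigma: float = 0.1
    seed: int = 0
    pool_factor: float = 10.0
    pool_alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        lo, hi = self.logN_range
        if hi <= lo:
            raise ValueError("logN_range must be increasing")
        if hi - lo < 2.0:
            raise ValueError(
                "logN_range should span >= 2 orders of magnitude for "
                "meaningful scaling fits"
            )
        if not (0.0 < self.z_richness <= 1.0):
            raise ValueError("z_richness must be in (0, 1]")
        if not (0.0 < self.z_dominance <= 1.0):
            raise ValueError("z_dominance must be in (0, 1]")
        if self.sad_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        if self.c_richness <= 0:
            raise ValueError("c_richness must be positive")
        if self.pool_factor < 1.0:
            raise ValueError("pool_factor must be >= 1")

    @property
    def pool_size(self) -> int:
        """Global taxon pool size: pool_factor x a bound on per-sample S."""
        lo, hi = self.logN_range
        s_max = self.c_richness * (10.0 ** hi) ** self.z_richness
        s_max *= 10.0 ** (4.0 * self.noise_sigma)  # 4-sigma noise headroom
        return int(math.ceil(self.pool_factor * max(s_max, 1.0)))


@dataclass
class SyntheticCorpus:
    spec: CorpusSpec
    table: TaxonTable
    truth: pd.DataFrame
    probs: list[np.ndarray] | None = field(default=None, repr=False)


def generate_corpus(spec: CorpusSpec, store_probs: bool = False) -> SyntheticCorpus:
    """Generate a corpus plus its per-sample truth record.

    ``store_probs=True`` additionally retains each sample's multinomial
    probability vector (for oracle checks of expected realized richness).
    """
    ss = np.random.SeedSequence(spec.seed)
    pool_ss, *sample_ss = ss.spawn(spec.n_samples + 1)

    pool_size = spec.pool_size
    pool_rng = np.random.default_rng(pool_ss)
    pool_weights = pool_rng.dirichlet(np.full(pool_size, spec.pool_alpha))
    log_pool_weights = np.log(np.maximum(pool_weights, 1e-300))

    lo, hi = spec.logN_range
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    truth_rows = []
    probs_kept: list[np.ndarray] | None = [] if store_probs else None

    for i, child in enumerate(sample_ss):
        rng = np.random.default_rng(child)
        n = max(1, int(round(10.0 ** rng.uniform(lo, hi))))
        eps_s, eps_d = rng.normal(0.0, spec.noise_sigma, size=2)
        s_target = spec.c_richness * n ** spec.z_richness * 10.0 ** eps_s
        if s_target > n:
            logger.info(
                "sample %d: infeasible S target %.1f > N=%d; clipping", i, s_target, n
            )
            s_target = float(n)
        s = int(np.clip(round(s_target), 1, min(n, pool_size)))
        nmax_target = float(
            np.clip(n ** spec.z_dominance * 10.0 ** eps_d, n / s, n)
        )
        p = _sad_probs(rng, s, spec.sad_sigma, nmax_target / n)
        counts = rng.multinomial(n, p)
        taxa = _gumbel_top_k(rng, log_pool_weights, s)
        keep = counts > 0
        rows.append(np.full(int(keep.sum()), i, dtype=np.int64))
        cols.append(taxa[keep])
        vals.append(counts[keep].astype(np.int64))
        truth_rows.append(
            {
                "sample_id": f"s{i}",
                "N_target": n,
                "S_target": s_target,
                "Nmax_target": nmax_target,
                "N_realized": int(counts.sum()),
                "S_realized": int(keep.sum()),
                "Nmax_realized": int(counts.max()),
            }
        )
        if probs_kept is not None:
            probs_kept.append(p)

    sample_ids = [f"s{i}" for i in range(spec.n_samples)]
    taxon_ids = [f"t{j}" for j in range(pool_size)]
    mat = sparse.coo_array(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(spec.n_samples, pool_size),
    ).tocsr()
    table = TaxonTable(sample_ids, taxon_ids, mat)
    truth = pd.DataFrame(truth_rows)
    return SyntheticCorpus(spec=spec, table=table, truth=truth, probs=probs_kept)


def _sad_probs(
    rng: np.random.Generator, s: int, sad_sigma: float, p_max: float
) -> np.ndarray:
    """Lognormal relative abundances with the top entry pinned to p_max."""
    if s == 1:
        return np.ones(1)
    w = np.sort(rng.lognormal(0.0, sad_sigma, size=s))[::-1]
    tail = w[1:]
    p = np.empty(s)
    p[0] = p_max
    p[1:] = tail / tail.sum() * (1.0 - p_max)
    return p


def _gumbel_top_k(
    rng: np.random.Generator, log_weights: np.ndarray, k: int
) -> np.ndarray:
    """Weighted sampling of k pool indices without replacement (Gumbel trick)."""
    keys = log_weights + rng.gumbel(size=log_weights.size)
    return np.argpartition(keys, -k)[-k:]


def truth_report(corpus: SyntheticCorpus) -> pd.DataFrame:
    """Per-sample target vs realized (N, S, Nmax), with thinning losses.

    Realized N always equals the target N (multinomial total); realized S
    can only fall short of the target (rare taxa thinned to zero).
    """
    t = corpus.truth.copy()
    t["S_loss"] = t["S_target"].round().astype(int).clip(lower=1) - t["S_realized"]
    return t
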