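"""Spatially explicit landscape simulation of estimator bias.

``N`` individuals drawn from a pool of ``S`` species are placed on the unit
square, partitioned into a grid of sites (quadrats). Four scenarios cross
two abundance modes with two spatial modes:

* abundance ``even``   — all pool species share probability 1/S;
  ``uneven`` — probabilities drawn lognormal(0, sad_sigma), normalized.
* space ``uniform``    — every individual lands uniformly on [0, 1)^2;
  ``aggregated``       — each species gets a random center and an isotropic
  normal spread (drawn from ``aggregation_sd_range``); coordinates are
  reflected at the boundaries.

Realized species counts are a single multinomial draw of N, so rare pool
species may realize zero individuals — the root of estimator failure when
abundances are uneven. Increasing numbers of sites are then censused and
Chao2/ICE trajectories recorded against the true pool richness.

Placements are stored as a per-site-by-species count matrix (not individual
coordinates) to bound memory at N = 10^7.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from microcensus.corpus_io import IncidenceMatrix
from microcensus.estimators import (
    chao2,
    ice,
    incidence_frequencies_from_counts,
)

__all__ = [
    "Scenario",
    "SCENARIOS",
    "Landscape",
    "AccumulationRecord",
    "build_landscape",
    "census_sites",
    "accumulation_experiment",
    "records_to_frame",
]


@dataclass(frozen=True)
class Scenario:
    abundance_mode: Literal["even", "uneven"]
    spatial_mode: Literal["uniform", "aggregated"]

    def __post_init__(self) -> None:
        if self.abundance_mode not in ("even", "uneven"):
            raise ValueError(f"bad abundance_mode {self.abundance_mode!r}")
        if self.spatial_mode not in ("uniform", "aggregated"):
            raise ValueError(f"bad spatial_mode {self.spatial_mode!r}")

    @property
    def label(self) -> str:
        """Panel letters a-d: (even,uniform), (uneven,uniform),
        (even,aggregated), (uneven,aggregated)."""
        return {
            ("even", "uniform"): "a",
            ("uneven", "uniform"): "b",
            ("even", "aggregated"): "c",
            ("uneven", "aggregated"): "d",
        }[(self.abundance_mode, self.spatial_mode)]


SCENARIOS = {
    "a": Scenario("even", "uniform"),
    "b": Scenario("uneven", "uniform"),
    "c": Scenario("even", "aggregated"),
    "d": Scenario("uneven", "aggregated"),
}


@dataclass
class Landscape:
    scenario: Scenario
    n_individuals: int
    pool_richness: int
    grid: tuple[int, int]
    seed: int | None
    site_counts: np.ndarray          # (n_sites, pool_richness) int
    species_probs: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def n_sites(self) -> int:
        return self.grid[0] * self.grid[1]

    @property
    def species_totals(self) -> np.ndarray:
        return self.site_counts.sum(axis=0)

    @property
    def realized_richness(self) -> int:
        """Species that received at least one individual."""
        return int(np.count_nonzero(self.species_totals))


def _reflect_unit(v: np.ndarray) -> np.ndarray:
    """Reflect coordinates at 0 and 1, mapping into [0, 1)."""
    v = np.mod(v, 2.0)
    v = np.where(v >= 1.0, 2.0 - v, v)
    # the fold maps exactly-on-boundary values to 1.0; nudge them inside
    return np.minimum(v, np.nextafter(1.0, 0.0))


def build_landscape(
    scenario: Scenario,
    n_individuals: int,
    pool_richness: int,
    grid: tuple[int, int] = (10, 10),
    sad_sigma: float = 2.5,
    aggregation_sd_range: tuple[float, float] = (0.01, 0.3),
    seed: int | None = None,
) -> Landscape:
    """Place ``n_individuals`` of ``pool_richness`` species on the grid."""
    if sad_sigma < 0:
        raise ValueError("sad_sigma must be >= 0")
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise ValueError("grid must have at least one cell in each dimension")
    if pool_richness < 1:
        raise ValueError("pool_richness must be >= 1")
    if n_individuals < pool_richness:
        raise ValueError("need n_individuals >= pool_richness")
    lo, hi = aggregation_sd_range
    if not (0 < lo <= hi):
        raise ValueError("aggregation_sd_range must satisfy 0 < lo <= hi")

    rng = np.random.default_rng(seed)
    s = pool_richness
    if scenario.abundance_mode == "even":
        probs = np.full(s, 1.0 / s)
    else:
        w = rng.lognormal(mean=0.0, sigma=sad_sigma, size=s)
        probs = w / w.sum()
    species_counts = rng.multinomial(n_individuals, probs)
    sp = np.repeat(np.arange(s, dtype=np.int64), species_counts)

    if scenario.spatial_mode == "uniform":
        x = rng.random(n_individuals)
        y = rng.random(n_individuals)
    else:
        centers = rng.random((s, 2))
        spreads = rng.uniform(lo, hi, size=s)
        x = _reflect_unit(
            centers[sp, 0] + rng.standard_normal(n_individuals) * spreads[sp]
        )
        y = _reflect_unit(
            centers[sp, 1] + rng.standard_normal(n_individuals) * spreads[sp]
        )

    site = (y * rows).astype(np.int64) * cols + (x * cols).astype(np.int64)
    site_counts = np.bincount(site * s + sp, minlength=rows * cols * s).reshape(
        rows * cols, s
    )
    return Landscape(
        scenario=scenario,
        n_individuals=int(n_individuals),
        pool_richness=int(s),
        grid=(rows, cols),
        seed=seed,
        site_counts=site_counts.astype(np.int32),
        species_probs=probs,
    )


def census_sites(
    landscape: Landscape, site_ids: Sequence[int]
) -> tuple[IncidenceMatrix, np.ndarray]:
    """Exhaustively census a subset of sites.

    Returns the site-by-species incidence matrix (presence = abundance >= 1)
    and the corresponding abundance submatrix.
    """
    site_ids = np.asarray(site_ids, dtype=np.int64)
    if site_ids.size == 0:
        raise ValueError("site_ids must be non-empty")
    if np.unique(site_ids).size != site_ids.size:
        raise ValueError("site_ids must be unique")
    if site_ids.min() < 0 or site_ids.max() >= landscape.n_sites:
        raise ValueError(
            f"site ids must lie in [0, {landscape.n_sites - 1}]"
        )
    abundance = landscape.site_counts[site_ids]
    from scipy import sparse

    incidence = IncidenceMatrix(
        unit_ids=[f"site{i}" for i in site_ids],
        taxon_ids=[f"sp{j}" for j in range(landscape.pool_richness)],
        presence=sparse.csr_array((abundance > 0).astype(np.int8)),
    )
    return incidence, abundance


@dataclass(frozen=True)
class AccumulationRecord:
    n_sites_sampled: int
    observed_richness: int
    chao2_estimate: float
    ice_estimate: float
    replicate: int
    seed: int | None
    pool_richness: int
    realized_richness: int

    def __post_init__(self) -> None:
        if self.chao2_estimate < self.observed_richness - 1e-9:
            raise ValueError("bias-corrected Chao2 must be >= observed richness")


def accumulation_experiment(
    landscape: Landscape,
    site_counts: Sequence[int],
    n_replicates: int = 1,
    seed: int | None = None,
    nested: bool = False,
    ice_cutoff: int = 10,
) -> list[AccumulationRecord]:
    """Census increasing numbers of randomly drawn sites and run estimators.

    ``site_counts`` must be strictly increasing and end with the full site
    count. By default draws at different accumulation levels are independent
    (non-nested); ``nested=True`` takes prefixes of a single random site
    ordering per replicate instead.
    """
    counts = list(site_counts)
    total = landscape.n_sites
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not counts or any(b <= a for a, b in zip(counts, counts[1:])):
        raise ValueError("site_counts must be strictly increasing")
    if counts[0] < 1 or counts[-1] != total:
        raise ValueError(
            f"site_counts must lie in [1, {total}] and end at {total}"
        )

    realized = landscape.realized_richness
    child_seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    records: list[AccumulationRecord] = []
    for rep, child in enumerate(child_seeds):
        rng = np.random.default_rng(child)
        order = rng.permutation(total) if nested else None
        for k in counts:
            if nested:
                sites = order[:k]
            else:
                sites = rng.choice(total, size=k, replace=False)
            abundance = landscape.site_counts[sites]
            freqs = incidence_frequencies_from_counts(abundance)
            s_obs = freqs.S_obs
            if k == 1:
                est_chao2 = float(s_obs)
                est_ice = float(s_obs)
            else:
                est_chao2 = chao2(freqs)
                est_ice = ice(freqs, infrequent_cutoff=ice_cutoff)
            records.append(
                AccumulationRecord(
                    n_sites_sampled=k,
                    observed_richness=s_obs,
                    chao2_estimate=est_chao2,
                    ice_estimate=est_ice,
                    replicate=rep,
                    seed=seed,
                    pool_richness=landscape.pool_richness,
                    realized_richness=realized,
                )
            )
    return records


def records_to_frame(records: Sequence[AccumulationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "n_sites_sampled": [r.n_sites_sampled for r in records],
            "observed_richness": [r.observed_richness for r in records],
            "chao2_estimate": [r.chao2_estimate for r in records],
            "ice_estimate": [r.ice_estimate for r in records],
            "replicate": [r.replicate for r in records],
            "pool_richness": [r.pool_richness for r in records],
            "realized_richness": [r.realized_richness for r in records],
        }
    )
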