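"""Sample-by-taxon count tables: parsing, incidence conversion, pooling.

The :class:`TaxonTable` is the universal exchange object of the package: a
sparse, non-negative integer matrix of samples (rows) by taxa (columns).
Counts are deliberately restricted to integers — singleton/doubleton
frequency classes are meaningless on relative abundances.

Two delimited-text dialects are supported:

* ``wide``  — header row of taxon ids, first column the sample id, integer
  cells (dense).
* ``long``  — three columns ``sample``, ``taxon``, ``count``; zero rows may
  simply be absent.

A minimal reader for the BIOM 1.0 (JSON) sample-by-observation format is
provided as a convenience.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "TableFormatError",
    "TaxonTable",
    "IncidenceMatrix",
    "IncidenceTally",
    "read_taxon_table",
    "write_taxon_table",
    "read_biom_json",
    "to_incidence",
    "incidence_tally",
    "pool_corpus",
]


class TableFormatError(ValueError):
    """A delimited count table violates the format contract."""


def _to_int_csr(counts) -> sparse.csr_array:
    """Coerce to an int64 CSR array, rejecting negatives and fractions."""
    if sparse.issparse(counts):
        mat = sparse.csr_array(counts)
    else:
        arr = np.asarray(counts)
        if arr.ndim != 2:
            raise TableFormatError("counts must be a 2-D matrix")
        mat = sparse.csr_array(arr)
    data = mat.data
    if data.size and np.issubdtype(data.dtype, np.floating):
        if not np.all(np.isfinite(data)) or np.any(data != np.rint(data)):
            raise TableFormatError(
                "counts must be integers; fractional or non-finite values found"
            )
    elif data.size and not np.issubdtype(data.dtype, np.number):
        raise TableFormatError("counts must be numeric")
    if data.size and np.any(data < 0):
        raise TableFormatError("counts must be non-negative")
    out = mat.astype(np.int64)
    out.eliminate_zeros()
    out.sum_duplicates()
    return out


def _check_unique(ids: Sequence[str], kind: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise TableFormatError(f"duplicate {kind} identifier: {dup!r}")
    return ids


@dataclass
class TaxonTable:
    """Sparse sample-by-taxon count matrix.

    Invariants: counts >= 0 and integer; ids unique; every retained sample
    has a positive total (use :meth:`drop_empty_samples` after construction
    from raw data).
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: sparse.csr_array

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.taxon_ids = _check_unique(self.taxon_ids, "taxon")
        self.counts = _to_int_csr(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise TableFormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )

    # -- basic views -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def sample_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    @property
    def taxon_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def to_dense(self) -> np.ndarray:
        return self.counts.toarray()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.to_dense(), index=self.sample_ids, columns=self.taxon_ids
        )

    # -- construction helpers ---------------------------------------------
    @classmethod
    def from_dense(
        cls, counts, sample_ids=None, taxon_ids=None
    ) -> "TaxonTable":
        counts = np.asarray(counts)
        n, t = counts.shape
        if sample_ids is None:
            sample_ids = [f"s{i}" for i in range(n)]
        if taxon_ids is None:
            taxon_ids = [f"t{j}" for j in range(t)]
        return cls(list(sample_ids), list(taxon_ids), sparse.csr_array(counts))

    def drop_empty_samples(self) -> "TaxonTable":
        """Return a table without zero-total samples (logged if any dropped)."""
        totals = self.sample_totals
        keep = totals > 0
        if keep.all():
            return self
        dropped = [s for s, k in zip(self.sample_ids, keep) if not k]
        logger.warning(
            "dropping %d sample(s) with zero total counts: %s",
            len(dropped),
            ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
        return TaxonTable(
            [s for s, k in zip(self.sample_ids, keep) if k],
            list(self.taxon_ids),
            self.counts[np.flatnonzero(keep)],
        )

    def drop_empty_taxa(self) -> "TaxonTable":
        """Return a table without all-zero taxon columns."""
        totals = self.taxon_totals
        keep = totals > 0
        if keep.all():
            return self
        return TaxonTable(
            list(self.sample_ids),
            [t for t, k in zip(self.taxon_ids, keep) if k],
            self.counts[:, np.flatnonzero(keep)],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.taxon_ids == other.taxon_ids
            and (self.counts != other.counts).nnz == 0
        )


@dataclass
class IncidenceMatrix:
    """Binary unit-by-taxon presence matrix.

    The "unit" is a sample for corpus analyses and a landscape site (quadrat)
    for simulation analyses. ``empty_taxa`` flags retained all-zero columns.
    """

    unit_ids: list[str]
    taxon_ids: list[str]
    presence: sparse.csr_array
    empty_taxa: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.presence = sparse.csr_array(self.presence).astype(np.int8)
        if self.presence.data.size and not np.all(
            np.isin(self.presence.data, (0, 1))
        ):
            raise ValueError("presence entries must be 0/1")
        self.presence.eliminate_zeros()
        if self.presence.shape != (len(self.unit_ids), len(self.taxon_ids)):
            raise ValueError("presence shape does not match id lists")
        if self.empty_taxa is None:
            self.empty_taxa = self.incidence_counts == 0
        self.empty_taxa = np.asarray(self.empty_taxa, dtype=bool)

    @property
    def m(self) -> int:
        """Number of sampling units."""
        return len(self.unit_ids)

    @property
    def incidence_counts(self) -> np.ndarray:
        """Per-taxon number of units of occurrence (column sums)."""
        return np.asarray(self.presence.sum(axis=0)).ravel()


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_taxon_table(
    path, dialect: str = "long", sep: str | None = None
) -> TaxonTable:
    """Read a count table from delimited text.

    Parameters
    ----------
    path:
        File path. UTF-8; tab- or comma-delimited (sniffed from line 1
        unless ``sep`` is given).
    dialect:
        ``"long"`` (sample, taxon, count triplets; optional header) or
        ``"wide"`` (samples x taxa matrix with ids).

    Samples whose total count is zero are dropped with a logged warning.
    Malformed rows are rejected with their (1-based) row number.
    """
    path = Path(path)
    sep = _sniff_sep(path, sep)
    if dialect == "long":
        table = _read_long(path, sep)
    elif dialect == "wide":
        table = _read_wide(path, sep)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'wide' or 'long'")
    return table.drop_empty_samples()


def _read_long(path: Path, sep: str) -> TaxonTable:
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] != 3:
        raise TableFormatError(
            f"long dialect requires 3 columns, found {df.shape[1]}"
        )
    df.columns = ["sample", "taxon", "count"]
    offset = 1  # 1-based row numbers for messages
    first_count = str(df.iloc[0, 2])
    try:
        float(first_count)
    except ValueError:
        df = df.iloc[1:].reset_index(drop=True)
        offset = 2
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts != np.floor(counts)) | (counts < 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TableFormatError(
            f"row {row + offset}: count {df['count'].iloc[row]!r} is not a "
            "non-negative integer"
        )
    dup = df.duplicated(["sample", "taxon"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise TableFormatError(
            f"row {row + offset}: duplicate (sample, taxon) pair "
            f"({df['sample'].iloc[row]!r}, {df['taxon'].iloc[row]!r})"
        )
    samples = pd.Categorical(df["sample"], categories=df["sample"].unique())
    taxa = pd.Categorical(df["taxon"], categories=df["taxon"].unique())
    mat = sparse.coo_array(
        (counts.to_numpy(dtype=np.int64), (samples.codes, taxa.codes)),
        shape=(len(samples.categories), len(taxa.categories)),
    )
    return TaxonTable(
        list(samples.categories), list(taxa.categories), mat.tocsr()
    )


def _read_wide(path: Path, sep: str) -> TaxonTable:
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    if df.index.has_duplicates:
        raise TableFormatError("duplicate sample identifiers in first column")
    if df.columns.has_duplicates:
        raise TableFormatError("duplicate taxon identifiers in header")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(values) | (values != np.floor(values)) | (values < 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise TableFormatError(
            f"row {i + 2}: cell ({df.index[i]!r}, {df.columns[j]!r}) = "
            f"{df.iloc[i, j]!r} is not a non-negative integer"
        )
    return TaxonTable(
        [str(s) for s in df.index],
        [str(t) for t in df.columns],
        sparse.csr_array(values.astype(np.int64)),
    )


def write_taxon_table(
    table: TaxonTable, path, dialect: str = "long", sep: str = "\t"
) -> None:
    """Write a table as delimited text (UTF-8, header line included)."""
    path = Path(path)
    if dialect == "wide":
        frame = table.to_frame()
        frame.index.name = "sample"
        frame.to_csv(path, sep=sep)
    elif dialect == "long":
        coo = sparse.coo_array(table.counts)
        order = np.lexsort((coo.col, coo.row))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(sep.join(["sample", "taxon", "count"]) + "\n")
            samples = table.sample_ids
            taxa = table.taxon_ids
            for r, c, v in zip(
                coo.row[order], coo.col[order], coo.data[order]
            ):
                fh.write(f"{samples[r]}{sep}{taxa[c]}{sep}{v}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_biom_json(path) -> TaxonTable:
    """Read a BIOM 1.0 (JSON) file into a TaxonTable.

    Only the minimal fields are consumed: ``rows`` (observations = taxa),
    ``columns`` (samples), ``data`` and ``matrix_type``. The BIOM layout is
    observation-by-sample; the result is transposed to sample-by-taxon.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    shape = (len(taxa), len(samples))
    if doc.get("matrix_type") == "dense":
        mat = sparse.csr_array(np.asarray(doc["data"]))
    else:
        data = np.asarray(doc["data"])
        if data.size == 0:
            mat = sparse.csr_array(shape, dtype=np.int64)
        else:
            mat = sparse.coo_array(
                (data[:, 2], (data[:, 0].astype(int), data[:, 1].astype(int))),
                shape=shape,
            ).tocsr()
    return TaxonTable(samples, taxa, mat.T.tocsr()).drop_empty_samples()


# ---------------------------------------------------------------------------
# Derived structures
# ---------------------------------------------------------------------------

def to_incidence(table: TaxonTable, threshold: int = 1) -> IncidenceMatrix:
    """Threshold counts into presence/absence.

    A taxon is present in a sample when its count >= ``threshold`` (default
    1: a read is an occurrence). Taxa that vanish everywhere at the chosen
    threshold are retained as columns but flagged via ``empty_taxa``.
    """
    if threshold < 1:
        raise ValueError(f"threshold must be >= 1, got {threshold}")
    presence = (table.counts >= threshold).astype(np.int8)
    return IncidenceMatrix(
        list(table.sample_ids), list(table.taxon_ids), sparse.csr_array(presence)
    )


@dataclass(frozen=True)
class IncidenceTally:
    """Distribution of taxa over incidence classes.

    ``tally[k]`` is the number of taxa found in exactly ``k`` samples
    (k >= 1); ``fraction_rare`` is the share of observed taxa with k <= 2.
    """

    tally: Mapping[int, int]
    n_observed: int
    n_rare: int
    fraction_rare: float


def incidence_tally(
    table: TaxonTable, threshold: int = 1
) -> IncidenceTally:
    """Tally how many taxa occur in exactly k samples."""
    inc = to_incidence(table, threshold=threshold).incidence_counts
    inc = inc[inc > 0]
    ks, counts = np.unique(inc, return_counts=True)
    tally = {int(k): int(c) for k, c in zip(ks, counts)}
    n_obs = int(inc.size)
    n_rare = tally.get(1, 0) + tally.get(2, 0)
    frac = n_rare / n_obs if n_obs else 0.0
    return IncidenceTally(tally, n_obs, n_rare, frac)


def pool_corpus(table: TaxonTable) -> np.ndarray:
    """Pool all samples into one ranked abundance vector (the pooled SAD).

    Returns per-taxon grand totals, positive entries only, sorted
    descending; element 0 is the pooled N_max and the sum is the pooled N.
    """
    totals = table.taxon_totals
    totals = totals[totals > 0]
    if totals.size == 0:
        raise ValueError("cannot pool an empty table (no positive counts)")
    return np.sort(totals)[::-1]
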