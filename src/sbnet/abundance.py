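"""Abundance-matrix handling: parsing, normalisation, taxon filtering,
sampling-time augmentation and time-period partitioning.

The central container is :class:`AbundanceMatrix`, an ``n x p`` matrix of
non-negative values (raw read counts or relative abundances) over ``n``
samples and ``p`` taxa, optionally carrying one sampling time per sample.
All downstream stages (conditional-independence testing, structure
learning, co-occurrence networks) consume its ``values`` array directly.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Name of the appended pseudo-taxon column holding sampling times.
TIME_COLUMN = "__time"

#: Tolerance on row sums of a relative-abundance matrix.
ROW_SUM_TOL = 1e-9


class AbundanceError(ValueError):
    """Raised for malformed abundance inputs or invalid operations."""


@dataclass
class AbundanceMatrix:
    """Samples x taxa abundance matrix.

    Parameters
    ----------
    values
        ``(n, p)`` array of non-negative reals. If a ``__time`` pseudo-taxon
        column is present (see :func:`add_time_variable`) it is exempt from
        the non-negativity and row-sum checks.
    sample_ids
        ``n`` sample identifiers.
    taxon_names
        ``p`` unique taxon names (column labels).
    times
        Optional sampling time per sample.
    is_relative
        True once rows have been normalised to sum to 1.
    """

    values: np.ndarray
    sample_ids: list[str]
    taxon_names: list[str]
    times: np.ndarray | None = None
    is_relative: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise AbundanceError("values must be a 2-D samples x taxa array")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_names = [str(t) for t in self.taxon_names]
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise AbundanceError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(self.taxon_names) != p:
            raise AbundanceError(
                f"{len(self.taxon_names)} taxon names for {p} columns"
            )
        if len(set(self.taxon_names)) != p:
            dupes = sorted(
                t for t in set(self.taxon_names)
                if self.taxon_names.count(t) > 1
            )
            raise AbundanceError(f"duplicate taxon name(s): {dupes}")
        taxa_mask = np.array(
            [t != TIME_COLUMN for t in self.taxon_names], dtype=bool
        )
        taxa_vals = self.values[:, taxa_mask]
        if not np.all(np.isfinite(self.values)):
            raise AbundanceError("values contain non-finite entries")
        if taxa_vals.size and np.any(taxa_vals < 0):
            raise AbundanceError("abundance values must be non-negative")
        if self.is_relative and n > 0 and taxa_vals.shape[1] > 0:
            sums = taxa_vals.sum(axis=1)
            bad = np.nonzero(np.abs(sums - 1.0) > ROW_SUM_TOL)[0]
            if bad.size:
                raise AbundanceError(
                    f"relative-abundance row {self.sample_ids[bad[0]]} "
                    f"sums to {sums[bad[0]]!r}, not 1"
                )
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (n,):
                raise AbundanceError("times must have one entry per sample")
            if not np.all(np.isfinite(self.times)):
                raise AbundanceError("times contain missing/non-finite values")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    @property
    def has_time_column(self) -> bool:
        return TIME_COLUMN in self.taxon_names

    def column(self, taxon: str) -> np.ndarray:
        return self.values[:, self.taxon_names.index(taxon)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.taxon_names
        )


# ----------------------------------------------------------------------
# Reading

def read_abundance(path, format: str = "tsv") -> AbundanceMatrix:
    """Read an abundance table from ``path``.

    Two dialects are supported. ``tsv``: UTF-8 tab-separated text whose
    first row is ``sample_id`` followed by taxon names and whose first
    column holds sample identifiers. ``shared``: the mothur shared-file
    layout with leading ``label``/``Group``/``numOtus`` columns, where
    ``Group`` holds the sample identifier.

    Returns a raw-count matrix (``is_relative=False``); cell order is
    preserved exactly as on disk.
    """
    if format not in ("tsv", "shared"):
        raise AbundanceError(f"unknown format {format!r}")
    # sniff the raw header ourselves: pandas silently renames duplicates
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter="\t"), None)
    if header is None:
        raise AbundanceError("no samples: file is empty")
    try:
        df = pd.read_csv(path, sep="\t", header=None, skiprows=1, dtype=str)
    except pd.errors.EmptyDataError:
        raise AbundanceError("no samples: table has a header but no rows") from None
    if df.shape[1] != len(header):
        raise AbundanceError("malformed table: ragged rows")

    if format == "shared":
        expected = ["label", "Group", "numOtus"]
        if header[:3] != expected:
            raise AbundanceError(
                f"malformed shared header: expected leading columns "
                f"{expected}, got {header[:3]}"
            )
        first_taxon = 3
    else:
        first_taxon = 1
    sample_col = 1 if format == "shared" else 0
    sample_ids = df.iloc[:, sample_col].tolist()
    body = df.iloc[:, first_taxon:]
    taxa = [str(c) for c in header[first_taxon:]]

    if not taxa:
        raise AbundanceError("malformed header: no taxon columns found")
    if len(set(taxa)) != len(taxa):
        dupes = sorted(t for t in set(taxa) if taxa.count(t) > 1)
        raise AbundanceError(f"duplicate taxon column(s): {dupes}")

    values = np.empty(body.shape, dtype=float)
    for ci in range(body.shape[1]):
        col = body.iloc[:, ci]
        numeric = pd.to_numeric(col, errors="coerce")
        if numeric.isna().any():
            row = int(np.nonzero(numeric.isna().to_numpy())[0][0])
            raise AbundanceError(
                f"non-numeric cell at row {sample_ids[row]!r}, "
                f"column {taxa[ci]!r}: {col.iloc[row]!r}"
            )
        values[:, ci] = numeric
    return AbundanceMatrix(values, sample_ids, taxa, is_relative=False)


def write_abundance(m: AbundanceMatrix, path) -> None:
    """Write ``m`` in the plain TSV dialect :func:`read_abundance` consumes."""
    df = m.to_dataframe()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ----------------------------------------------------------------------
# Normalisation and filtering

def normalize_relative(m: AbundanceMatrix) -> AbundanceMatrix:
    """Convert raw counts to per-sample relative abundances.

    Each row ``b^(i)`` is divided by its total ``w^(i) = sum_j b_j^(i)``,
    so every output row sums to 1.
    """
    if m.is_relative:
        raise AbundanceError("matrix is already relative")
    totals = m.values.sum(axis=1)
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        raise AbundanceError(
            f"sample {m.sample_ids[zero[0]]!r} has zero total abundance"
        )
    return replace(m, values=m.values / totals[:, None], is_relative=True)


def filter_top_taxa(m: AbundanceMatrix, coverage: float = 0.99) -> AbundanceMatrix:
    """Keep the most abundant taxa jointly covering ``coverage`` of the mass.

    Taxa are ranked by mean relative abundance across samples (descending,
    ties broken by taxon name); the smallest prefix whose cumulative share
    reaches ``coverage`` is retained. The result is NOT renormalised: CI
    tests and correlations downstream run on the retained columns as-is.
    """
    if not m.is_relative:
        raise AbundanceError("filter_top_taxa requires a relative matrix")
    if m.has_time_column:
        raise AbundanceError("filter taxa before adding the time variable")
    if not (0 < coverage <= 1):
        raise AbundanceError(f"coverage must be in (0, 1], got {coverage}")
    shares = m.values.mean(axis=0)
    # descending share, ascending name on ties
    order = sorted(range(m.n_taxa), key=lambda j: (-shares[j], m.taxon_names[j]))
    cum = 0.0
    kept_rank: list[int] = []
    for j in order:
        if cum >= coverage - 1e-12:
            break
        if shares[j] == 0.0:
            break  # zero-share taxa can never contribute coverage
        kept_rank.append(j)
        cum += shares[j]
    kept = sorted(kept_rank)  # preserve original column order
    log.info("taxon filter: kept %d/%d taxa (coverage %.4f)",
             len(kept), m.n_taxa, cum)
    sub = m.values[:, kept]
    # rows are deliberately not renormalised; the flag only stays set when
    # dropping zero-share taxa left the rows closed to 1
    still_closed = bool(
        m.n_samples == 0 or np.all(np.abs(sub.sum(axis=1) - 1.0) <= ROW_SUM_TOL)
    )
    return AbundanceMatrix(
        sub,
        m.sample_ids,
        [m.taxon_names[j] for j in kept],
        times=m.times,
        is_relative=still_closed,
    )


def add_time_variable(m: AbundanceMatrix) -> AbundanceMatrix:
    """Append the sampling times as a pseudo-taxon column ``__time``.

    Downstream learners then treat sampling time as an ordinary continuous
    variable, letting edges anchored at the time node absorb shared
    temporal trends.
    """
    if m.times is None:
        raise AbundanceError("matrix has no sampling times")
    if m.has_time_column:
        raise AbundanceError("time variable already present")
    values = np.column_stack([m.values, m.times])
    return AbundanceMatrix(
        values,
        m.sample_ids,
        list(m.taxon_names) + [TIME_COLUMN],
        times=m.times,
        is_relative=m.is_relative,
    )


def partition_periods(m: AbundanceMatrix, k: int) -> list[AbundanceMatrix]:
    """Split samples into ``k`` equal-width periods along the time axis.

    The span ``[min(times), max(times)]`` is divided into ``k`` half-open
    intervals, the last closed on the right. Periods may be empty. When all
    times coincide, every sample lands in the last period.
    """
    if m.times is None:
        raise AbundanceError("matrix has no sampling times")
    if k < 1:
        raise AbundanceError(f"k must be >= 1, got {k}")
    t0, t1 = float(m.times.min()), float(m.times.max())
    if t1 == t0:
        idx = np.full(m.n_samples, k - 1, dtype=int)
    else:
        width = (t1 - t0) / k
        idx = np.minimum(((m.times - t0) / width).astype(int), k - 1)
    out = []
    for period in range(k):
        rows = np.nonzero(idx == period)[0]
        out.append(AbundanceMatrix(
            m.values[rows],
            [m.sample_ids[i] for i in rows],
            list(m.taxon_names),
            times=m.times[rows],
            is_relative=m.is_relative,
        ))
    return out
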