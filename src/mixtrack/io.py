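"""Community data containers and tabular I/O.

Count tables are plain TSV: first column taxon identifiers (header cell
``#TaxonID``), remaining columns one sample each, body non-negative
integers.  Role mappings follow the SourceTracker mapping convention: a TSV
with at least ``SampleID`` and ``SourceSink`` columns, the latter holding
``source`` or ``sink`` (matched case-insensitively; extra columns such as
``Env`` are ignored).  BIOM/HDF5 is deliberately unsupported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateSampleError, FormatError, RoleError

logger = logging.getLogger("mixtrack")

TAXON_HEADER = "#TaxonID"

__all__ = [
    "CommunitySet",
    "UnlabeledSampleSet",
    "SourceProfiles",
    "RoleMap",
    "read_counts_table",
    "write_counts_table",
    "read_role_mapping",
    "write_role_mapping",
    "assemble_community",
    "profiles_from_counts",
    "write_proportions",
]


def _check_counts(counts: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(counts)
    if not np.issubdtype(arr.dtype, np.integer):
        flo = np.asarray(arr, dtype=float)
        if not np.all(np.isfinite(flo)) or np.any(flo != np.floor(flo)):
            raise FormatError(f"{what}: counts must be integer-valued")
        arr = flo.astype(np.int64)
    if np.any(arr < 0):
        raise FormatError(f"{what}: counts must be non-negative")
    return arr.astype(np.int64, copy=False)


@dataclass
class CommunitySet:
    """One sink plus K sources over a shared taxon index.

    ``sink_counts`` is the observed sink vector x (total depth C);
    ``source_counts`` is the K x N matrix whose row i is y_i (depth C_i).
    """

    taxon_ids: list[str]
    sink_counts: np.ndarray
    source_counts: np.ndarray
    sink_id: str = "sink"
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sink_counts = _check_counts(self.sink_counts, "sink")
        self.source_counts = np.atleast_2d(
            _check_counts(self.source_counts, "sources")
        )
        n = len(self.taxon_ids)
        if self.sink_counts.shape != (n,):
            raise FormatError("sink counts length does not match taxa")
        if self.source_counts.shape[1] != n:
            raise FormatError("source counts width does not match taxa")
        if self.sink_counts.sum() <= 0:
            raise DegenerateSampleError(f"sink sample {self.sink_id!r} has zero total count")
        totals = self.source_counts.sum(axis=1)
        if np.any(totals <= 0):
            bad = int(np.flatnonzero(totals <= 0)[0])
            name = self.source_ids[bad] if self.source_ids else f"source {bad}"
            raise DegenerateSampleError(f"source sample {name!r} has zero total count")
        if not self.source_ids:
            self.source_ids = [f"source_{i + 1}" for i in range(self.n_sources)]

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_sources(self) -> int:
        return self.source_counts.shape[0]

    @property
    def sink_depth(self) -> int:
        return int(self.sink_counts.sum())

    @property
    def source_depths(self) -> np.ndarray:
        return self.source_counts.sum(axis=1)


@dataclass
class UnlabeledSampleSet:
    """K+1 samples over a shared taxon index, with no source/sink roles."""

    taxon_ids: list[str]
    counts: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(_check_counts(self.counts, "samples"))
        if self.counts.shape[0] < 2:
            raise FormatError("directionality inference needs at least 2 samples")
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise FormatError("counts shape does not match sample/taxon identifiers")
        totals = self.counts.sum(axis=1)
        if np.any(totals <= 0):
            bad = int(np.flatnonzero(totals <= 0)[0])
            raise DegenerateSampleError(
                f"sample {self.sample_ids[bad]!r} has zero total count"
            )

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    def as_community(self, sink_index: int) -> CommunitySet:
        """View sample ``sink_index`` as the sink and the rest as sources."""
        rest = [i for i in range(self.n_samples) if i != sink_index]
        return CommunitySet(
            taxon_ids=self.taxon_ids,
            sink_counts=self.counts[sink_index],
            source_counts=self.counts[rest],
            sink_id=self.sample_ids[sink_index],
            source_ids=[self.sample_ids[i] for i in rest],
        )


@dataclass
class SourceProfiles:
    """K x N matrix of source relative abundances; rows sum to 1."""

    profiles: np.ndarray

    def __post_init__(self) -> None:
        self.profiles = np.atleast_2d(np.asarray(self.profiles, dtype=float))
        if self.profiles.size == 0:
            raise ValueError("profiles matrix is empty")
        if np.any(self.profiles < 0) or np.any(self.profiles > 1):
            raise ValueError("profile entries must lie in [0, 1]")
        sums = self.profiles.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"profile row {bad} sums to {sums[bad]:.12g}, expected 1"
            )

    @property
    def n_sources(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.profiles.shape[1]


@dataclass
class RoleMap:
    """Assembly recipe produced by :func:`read_role_mapping`."""

    sink_id: str
    source_ids: list[str]


def read_counts_table(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Read a taxa-by-samples TSV into (taxon_ids, sample_ids, counts).

    File order is preserved; duplicate taxon or sample identifiers and any
    negative or non-integer cell are rejected with a :class:`FormatError`
    naming the offending row/column.
    """
    # pandas mangles duplicate header names, so validate the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: need a taxon column plus at least one sample column")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dupe = next(s for s in sample_ids if sample_ids.count(s) > 1)
        raise FormatError(f"{path}: duplicate sample identifier {dupe!r}")
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str, comment=None)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse counts table {path}: {exc}") from exc
    df.columns = header
    taxon_ids = [str(t) for t in df.iloc[:, 0]]
    if len(set(taxon_ids)) != len(taxon_ids):
        dupe = next(t for t in taxon_ids if taxon_ids.count(t) > 1)
        raise FormatError(f"{path}: duplicate taxon identifier {dupe!r}")
    counts = np.empty((len(taxon_ids), len(sample_ids)), dtype=np.int64)
    for j, col in enumerate(df.columns[1:]):
        for i, cell in enumerate(df[col]):
            try:
                value = int(str(cell))
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer count {cell!r} at taxon "
                    f"{taxon_ids[i]!r}, sample {sample_ids[j]!r}"
                ) from None
            if value < 0:
                raise FormatError(
                    f"{path}: negative count {value} at taxon "
                    f"{taxon_ids[i]!r}, sample {sample_ids[j]!r}"
                )
            counts[i, j] = value
    return taxon_ids, sample_ids, counts


def write_counts_table(
    path: str | Path,
    taxon_ids: Sequence[str],
    sample_ids: Sequence[str],
    counts: np.ndarray,
) -> None:
    """Write a taxa-by-samples integer matrix in the TSV dialect."""
    counts = _check_counts(counts, "counts")
    df = pd.DataFrame(counts, columns=list(sample_ids))
    df.insert(0, TAXON_HEADER, list(taxon_ids))
    df.to_csv(path, sep="\t", index=False)


def read_role_mapping(path: str | Path, sample_ids: Sequence[str]) -> RoleMap:
    """Read a SampleID/SourceSink mapping and validate it against sample ids.

    Exactly one sample must be labeled ``sink``; every mapped SampleID must
    be a column of the counts table. Counts columns absent from the mapping
    are ignored (logged).
    """
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except Exception as exc:  # pragma: no cover
        raise RoleError(f"cannot parse mapping {path}: {exc}") from exc
    cols = {c.lower(): c for c in df.columns}
    for needed in ("sampleid", "sourcesink"):
        if needed not in cols:
            raise RoleError(f"{path}: missing required column {needed!r}")
    ids = [str(s) for s in df[cols["sampleid"]]]
    roles = [str(r).strip().lower() for r in df[cols["sourcesink"]]]
    known = set(sample_ids)
    sinks, sources = [], []
    for sid, role in zip(ids, roles):
        if sid not in known:
            raise RoleError(f"{path}: SampleID {sid!r} not found in counts table")
        if role == "sink":
            sinks.append(sid)
        elif role == "source":
            sources.append(sid)
        else:
            raise RoleError(f"{path}: SourceSink value {role!r} for {sid!r} "
                            "(expected 'source' or 'sink')")
    if len(sinks) != 1:
        raise RoleError(f"{path}: expected exactly one sink, found {len(sinks)}")
    if not sources:
        raise RoleError(f"{path}: no source samples designated")
    unmapped = [s for s in sample_ids if s not in set(ids)]
    if unmapped:
        logger.info("ignoring %d unmapped sample(s): %s", len(unmapped), unmapped)
    return RoleMap(sink_id=sinks[0], source_ids=sources)


def assemble_community(
    taxon_ids: Sequence[str],
    sample_ids: Sequence[str],
    counts: np.ndarray,
    roles: RoleMap,
) -> CommunitySet:
    """Assemble a :class:`CommunitySet` from a counts matrix and roles.

    Taxa with zero counts in the sink AND every source are dropped (their
    regression rows carry no information); retained taxa keep file order
    and their counts are untouched.
    """
    counts = _check_counts(counts, "counts")
    index = {s: j for j, s in enumerate(sample_ids)}
    sink = counts[:, index[roles.sink_id]]
    src = counts[:, [index[s] for s in roles.source_ids]].T
    keep = (sink > 0) | (src.sum(axis=0) > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d taxa absent from sink and all sources", n_dropped)
    return CommunitySet(
        taxon_ids=[t for t, k in zip(taxon_ids, keep) if k],
        sink_counts=sink[keep],
        source_counts=src[:, keep],
        sink_id=roles.sink_id,
        source_ids=list(roles.source_ids),
    )


def profiles_from_counts(source_counts: np.ndarray) -> SourceProfiles:
    """Plug-in relative abundance profiles y_i / C_i for each source row."""
    counts = np.atleast_2d(_check_counts(source_counts, "sources"))
    totals = counts.sum(axis=1, dtype=float)
    if np.any(totals <= 0):
        bad = int(np.flatnonzero(totals <= 0)[0])
        raise DegenerateSampleError(f"source row {bad} has zero total count")
    return SourceProfiles(counts / totals[:, None])


def write_proportions(estimate, path: str | Path) -> None:
    """Write per-source estimated proportions plus an Unknown row.

    Columns: source id, post-processed proportion, raw GLS coefficient
    (alpha-tilde_i / C for sources, the intercept alpha-tilde_0 / C for
    Unknown). Proportions sum to 1.
    """
    source_ids = estimate.source_ids or [
        f"source_{i + 1}" for i in range(len(estimate.alpha_observed))
    ]
    rows = [
        (sid, estimate.alpha_observed[i], estimate.alpha_hat_raw[i + 1])
        for i, sid in enumerate(source_ids)
    ]
    rows.append(("Unknown", estimate.alpha_unknown, estimate.alpha_hat_raw[0]))
    df = pd.DataFrame(rows, columns=["SourceID", "Proportion", "RawCoefficient"])
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
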