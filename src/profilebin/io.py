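"""Read-count matrix construction and I/O.

The central data structure is the :class:`CountMatrix`: an ``N x P`` table of
non-negative integers whose entry ``(i, j)`` is the number of reads from
sample ``j`` whose primary alignment lands on contig ``i``.  Each row,
normalized, is the contig's *sample profile* — the feature on which all
downstream clustering operates.

Counts can be built directly from per-sample SAM/BAM files
(:func:`count_from_alignments`) or loaded from a TSV table
(:func:`read_count_table`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "ContigMeta",
    "CountMatrix",
    "count_from_alignments",
    "read_count_table",
    "write_count_table",
    "filter_contigs",
]


@dataclass(frozen=True)
class ContigMeta:
    """Identifier and length (bp) of one contig."""

    contig_id: str
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(
                f"contig {self.contig_id!r}: length must be >= 1, got {self.length}"
            )


@dataclass
class CountMatrix:
    """Contigs-by-samples read-count matrix with contig metadata.

    Parameters
    ----------
    counts : ndarray of shape (N, P)
        Non-negative integer read counts; ``counts[i, j]`` is the number of
        reads from sample ``j`` mapped to contig ``i``.
    contigs : sequence of ContigMeta, length N
        Row metadata, in row order.
    sample_ids : sequence of str, length P
        Column names, in column order.
    library_sizes : ndarray of shape (P,), optional
        Total reads sequenced per sample (``T_j``), used for abundance
        normalization.  Must dominate the corresponding column sums.
    """

    counts: np.ndarray
    contigs: list[ContigMeta]
    sample_ids: list[str]
    library_sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.array_equal(self.counts, np.floor(self.counts)):
                raise ValueError("counts must be integer-valued")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(f"negative count at contig row {i}, sample column {j}")
        self.contigs = list(self.contigs)
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, p = self.counts.shape
        if len(self.contigs) != n:
            raise ValueError(f"{len(self.contigs)} contigs for {n} count rows")
        if len(self.sample_ids) != p:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {p} columns")
        ids = [c.contig_id for c in self.contigs]
        if len(set(ids)) != len(ids):
            dup = next(x for x in ids if ids.count(x) > 1)
            raise ValueError(f"duplicate contig_id {dup!r}")
        if self.library_sizes is not None:
            self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
            if self.library_sizes.shape != (p,):
                raise ValueError("library_sizes must have one entry per sample")
            if (self.library_sizes < self.counts.sum(axis=0)).any():
                raise ValueError(
                    "library_sizes must be >= per-sample column sums"
                )

    # -- convenience accessors -------------------------------------------------
    @property
    def n_contigs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def contig_ids(self) -> list[str]:
        return [c.contig_id for c in self.contigs]

    @property
    def lengths(self) -> np.ndarray:
        """Contig lengths in bp, shape (N,)."""
        return np.array([c.length for c in self.contigs], dtype=np.int64)

    @property
    def row_totals(self) -> np.ndarray:
        """Total mapped reads per contig (n_i), shape (N,)."""
        return self.counts.sum(axis=1)

    def effective_library_sizes(self) -> np.ndarray:
        """T_j, falling back to column sums when library sizes are unknown."""
        if self.library_sizes is not None:
            return self.library_sizes
        return self.counts.sum(axis=0)


def count_from_alignments(
    alignment_paths: Sequence[str | Path],
    *,
    sample_ids: Sequence[str] | None = None,
    min_mapq: int = 0,
    primary_only: bool = True,
) -> CountMatrix:
    """Build a :class:`CountMatrix` from one SAM/BAM file per sample.

    Each read record counts once toward the contig its primary alignment maps
    to, provided its mapping quality is at least ``min_mapq``.  Secondary and
    supplementary records are never counted when ``primary_only`` is set (the
    default), so a multi-mapping read contributes to exactly one contig.
    Paired-end mates are counted as independent read records.

    Library sizes are the total number of read records per file, mapped or
    not, which makes them valid ``T_j`` denominators for abundance
    normalization.

    Raises
    ------
    ValueError
        If the files disagree on the reference contig namespace, or a file
        contains no records.
    """
    paths = [Path(p) for p in alignment_paths]
    if not paths:
        raise ValueError("no alignment files given")
    if sample_ids is None:
        sample_ids = [p.stem for p in paths]
    if len(sample_ids) != len(paths):
        raise ValueError("one sample_id per alignment file required")

    ref_names: list[str] | None = None
    ref_lengths: list[int] | None = None
    columns: list[np.ndarray] = []
    lib_sizes: list[int] = []

    for path in paths:
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            names, lens = list(fh.references), list(fh.lengths)
            if ref_names is None:
                ref_names, ref_lengths = names, lens
                if not ref_names:
                    raise ValueError(f"{path}: no reference contigs in header")
                index = {name: i for i, name in enumerate(ref_names)}
            elif names != ref_names or lens != ref_lengths:
                raise ValueError(
                    f"{path}: reference headers differ from {paths[0]}"
                )
            col = np.zeros(len(ref_names), dtype=np.int64)
            n_records = 0
            for rec in fh.fetch(until_eof=True):
                if rec.is_secondary or rec.is_supplementary:
                    if primary_only:
                        continue
                else:
                    n_records += 1
                if rec.is_unmapped or rec.mapping_quality < min_mapq:
                    continue
                col[index[rec.reference_name]] += 1
            if n_records == 0:
                raise ValueError(f"{path}: alignment file contains no reads")
            columns.append(col)
            lib_sizes.append(n_records)

    contigs = [ContigMeta(n, ln) for n, ln in zip(ref_names, ref_lengths)]
    return CountMatrix(
        counts=np.column_stack(columns),
        contigs=contigs,
        sample_ids=list(sample_ids),
        library_sizes=np.array(lib_sizes),
    )


def read_count_table(
    path: str | Path, *, library_sizes: Sequence[int] | None = None
) -> CountMatrix:
    """Load a CountMatrix from a TSV with columns contig_id, length, samples...

    Comment lines starting with ``#`` are skipped.  Unless ``library_sizes``
    is given, ``T_j`` defaults to the column sums — a bare count table cannot
    know how many reads went unmapped.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"contig_id": str})
    if df.columns[0] != "contig_id" or df.columns[1] != "length":
        raise ValueError(
            f"{path}: expected header starting 'contig_id\\tlength', "
            f"got {list(df.columns[:2])}"
        )
    sample_cols = list(df.columns[2:])
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns")
    for col in ["length"] + sample_cols:
        vals = df[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            frac = vals != np.floor(vals)
            if frac.any():
                row = int(np.flatnonzero(frac)[0])
                raise ValueError(
                    f"{path}: non-integer value in column {col!r}, "
                    f"contig {df['contig_id'].iloc[row]!r}"
                )
        neg = vals < 0
        if neg.any():
            row = int(np.flatnonzero(neg)[0])
            raise ValueError(
                f"{path}: negative value in column {col!r}, "
                f"contig {df['contig_id'].iloc[row]!r}"
            )
    counts = df[sample_cols].to_numpy(dtype=np.int64)
    contigs = [
        ContigMeta(cid, int(ln)) for cid, ln in zip(df["contig_id"], df["length"])
    ]
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    return CountMatrix(counts, contigs, sample_cols, np.asarray(library_sizes))


def write_count_table(cm: CountMatrix, path: str | Path, *, header_comment: str | None = None) -> None:
    """Write a CountMatrix as TSV (inverse of :func:`read_count_table`)."""
    df = pd.DataFrame(cm.counts, columns=cm.sample_ids)
    df.insert(0, "length", cm.lengths)
    df.insert(0, "contig_id", cm.contig_ids)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def filter_contigs(
    cm: CountMatrix, *, min_length: int = 1000, min_total_count: int = 0
) -> CountMatrix:
    """Drop short and low-coverage contigs.

    Retains contigs with ``length >= min_length`` and total mapped reads
    ``n_i >= min_total_count`` (both thresholds inclusive).  Very short
    contigs carry noisy sample profiles, and near-zero-coverage contigs carry
    almost no clustering signal; screening both out is the standard
    pre-processing step.  Library sizes describe the samples, not the retained
    rows, and pass through unchanged.
    """
    if min_length < 0 or min_total_count < 0:
        raise ValueError("thresholds must be non-negative")
    keep = (cm.lengths >= min_length) & (cm.row_totals >= min_total_count)
    if not keep.any():
        raise ValueError(
            f"filter (min_length={min_length}, min_total_count={min_total_count}) "
            "removed every contig"
        )
    return CountMatrix(
        counts=cm.counts[keep],
        contigs=[c for c, k in zip(cm.contigs, keep) if k],
        sample_ids=list(cm.sample_ids),
        library_sizes=cm.library_sizes,
    )
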