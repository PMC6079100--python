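"""Readers, writers and containers for pooled-screen inputs.

A screen is described by a guide library (guide → gene map with 20-nt
targeting sequences) and a guide × sample matrix of integer read counts,
typically one unsorted reference sample plus one or more FACS-sorted tail
populations.  Reads are assigned to guides by exact matching of the first
``trim_length`` bases against the library — the screen's amplicons carry
the guide at the 5' end, so trimming to the guide length and exact lookup
reproduce the counting step without an aligner.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Tuple, Union

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "GuideLibrary",
    "ScreenCounts",
    "read_guide_library",
    "write_guide_library",
    "count_reads",
    "read_count_table",
    "write_count_table",
]

#: gene id reserved for non-targeting / tag-targeting control guides
CONTROL_GENE = "CONTROL"

PathOrHandle = Union[str, IO]

_ACGT = frozenset("ACGT")


def _open_text(source: PathOrHandle, mode: str = "rt"):
    """Open ``source`` as a text handle; transparent gzip by filename."""
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    if str(source).endswith(".gz"):
        return gzip.open(source, mode), True
    return open(source, mode), True


@dataclass(frozen=True)
class GuideLibrary:
    """Validated guide library: unique guide ids, one gene per guide,
    equal-length ACGT sequences (the trim length)."""

    table: pd.DataFrame  # columns: guide_id, gene_id, sequence, is_control

    def __post_init__(self) -> None:
        t = self.table
        required = {"guide_id", "gene_id", "sequence"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"guide library missing columns: {sorted(missing)}")
        if t["guide_id"].duplicated().any():
            dup = t.loc[t["guide_id"].duplicated(), "guide_id"].iloc[0]
            raise ValueError(f"duplicate guide_id: {dup!r}")
        lengths = t["sequence"].str.len().unique()
        if len(lengths) != 1:
            raise ValueError(
                f"inconsistent guide sequence lengths: {sorted(lengths)}"
            )
        bad = ~t["sequence"].map(lambda s: set(s) <= _ACGT)
        if bad.any():
            raise ValueError(
                f"non-ACGT sequence for guide {t.loc[bad, 'guide_id'].iloc[0]!r}"
            )
        if "is_control" not in t.columns:
            object.__setattr__(
                self,
                "table",
                t.assign(is_control=t["gene_id"].eq(CONTROL_GENE)),
            )

    @property
    def guide_ids(self) -> pd.Index:
        return pd.Index(self.table["guide_id"])

    @property
    def sequence_length(self) -> int:
        return int(self.table["sequence"].str.len().iloc[0])

    @property
    def n_guides(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.table["gene_id"].unique())

    def guide_to_gene(self) -> pd.Series:
        """Series mapping guide_id -> gene_id."""
        return self.table.set_index("guide_id")["gene_id"]

    def sequence_index(self) -> dict:
        """Dict mapping sequence -> guide_id for exact-match counting."""
        return dict(zip(self.table["sequence"], self.table["guide_id"]))


@dataclass
class ScreenCounts:
    """Non-negative integer guide × sample count matrix."""

    counts: pd.DataFrame  # index: guide_id, columns: sample names

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            raise ValueError("duplicate guide ids in count matrix")
        if c.isna().any().any():
            raise ValueError("missing cells in count matrix")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("non-integer counts")
            self.counts = c.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def samples(self) -> list:
        return list(self.counts.columns)

    @property
    def totals(self) -> pd.Series:
        """Per-sample total of raw counts (the normalization denominator)."""
        return self.counts.sum(axis=0)


def read_guide_library(source: PathOrHandle) -> GuideLibrary:
    """Read a guide-library TSV with columns guide_id, gene_id, sequence
    and optionally is_control."""
    handle, close = _open_text(source)
    try:
        try:
            table = pd.read_csv(handle, sep="\t", dtype=str)
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed guide library table: {exc}") from exc
    finally:
        if close:
            handle.close()
    if "is_control" in table.columns:
        table["is_control"] = table["is_control"].map(
            {"True": True, "False": False, "1": True, "0": False}
        )
    return GuideLibrary(table)


def write_guide_library(library: GuideLibrary, target: PathOrHandle) -> None:
    handle, close = _open_text(target, "wt")
    try:
        library.table.to_csv(handle, sep="\t", index=False)
    finally:
        if close:
            handle.close()


def count_reads(
    fastq: PathOrHandle,
    library: GuideLibrary,
    trim_length: int = 20,
) -> Tuple[pd.Series, int]:
    """Count reads per guide by exact matching of the trimmed prefix.

    Each read is trimmed to its first ``trim_length`` bases and looked up
    against the library sequences; reads that do not match exactly (or are
    shorter than the trim length) are tallied as unassigned.

    Returns
    -------
    (counts, n_unassigned)
        ``counts`` is a Series indexed by guide_id (library order), and
        ``counts.sum() + n_unassigned`` equals the number of reads.
    """
    if trim_length != library.sequence_length:
        raise ValueError(
            f"trim_length {trim_length} != library sequence length "
            f"{library.sequence_length}"
        )
    index = library.sequence_index()
    tally = {gid: 0 for gid in library.guide_ids}
    unassigned = 0
    handle, close = _open_text(fastq)
    try:
        for _title, seq, _qual in FastqGeneralIterator(handle):
            if len(seq) < trim_length:
                unassigned += 1
                continue
            gid = index.get(seq[:trim_length].upper())
            if gid is None:
                unassigned += 1
            else:
                tally[gid] += 1
    except ValueError as exc:
        raise ValueError(f"truncated or malformed FASTQ record: {exc}") from exc
    finally:
        if close:
            handle.close()
    return pd.Series(tally, name="count"), unassigned


def read_count_table(source: PathOrHandle) -> ScreenCounts:
    """Read a guide × sample count TSV (first column guide_id)."""
    handle, close = _open_text(source)
    try:
        table = pd.read_csv(handle, sep="\t", index_col=0)
    finally:
        if close:
            handle.close()
    if table.isna().any().any():
        raise ValueError("missing cell in count table")
    return ScreenCounts(table)


def write_count_table(counts: ScreenCounts, target: PathOrHandle) -> None:
    handle, close = _open_text(target, "wt")
    try:
        counts.counts.to_csv(handle, sep="\t", index_label="guide_id")
    finally:
        if close:
            handle.close()
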