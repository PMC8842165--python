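"""Read-to-ORF assignment and count/CPM tables for pooled prey screens.

Reads from a pooled two-hybrid screen are PCR amplicons of prey ORFs,
sequenced after fluorescence sorting.  Interaction signal is taken to be
proportional to read counts per million (CPM).  Assignment here is exact
k-mer matching against the prey ORF reference: every k-mer unique to one
ORF votes for it, reads with conflicting or only-ambiguous k-mers are
discarded and tallied.  This keeps the stage deterministic and lets a
brute-force substring oracle verify it.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Sentinel for k-mers occurring in more than one reference ORF.
AMBIGUOUS = "__AMBIGUOUS__"

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class ORFReference:
    """Prey ORF library: unique ids, A/C/G/T sequences, k-mer length."""

    entries: tuple[tuple[str, str], ...]
    k: int = 31

    def __post_init__(self) -> None:
        ids = [oid for oid, _ in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate orf_id(s): {dupes}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for oid, seq in self.entries:
            if not set(seq) <= _VALID_BASES:
                raise ValueError(f"{oid}: sequence contains non-ACGT characters")
            if len(seq) < self.k:
                raise ValueError(f"{oid}: length {len(seq)} < k={self.k}")

    @property
    def orf_ids(self) -> list[str]:
        return [oid for oid, _ in self.entries]

    @classmethod
    def from_fasta(cls, path: str | Path, k: int = 31) -> "ORFReference":
        entries = tuple(
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
        )
        return cls(entries=entries, k=k)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for oid, seq in self.entries:
                fh.write(f">{oid}\n{seq}\n")


@dataclass
class CountTable:
    """Per-ORF read counts per replicate, with library sizes and CPM.

    ``counts`` is an (n_orfs, n_replicates) integer matrix; ``cpm`` is
    filled by :func:`counts_to_cpm` (counts x 1e6 / column library size).
    """

    orf_ids: list[str]
    counts: np.ndarray
    replicates: list[str]
    cpm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (ORF x replicate)")
        if self.counts.shape != (len(self.orf_ids), len(self.replicates)):
            raise ValueError("counts shape inconsistent with orf_ids/replicates")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.orf_ids, columns=self.replicates)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "orf_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="orf_id")
        return cls(
            orf_ids=list(df.index),
            counts=df.to_numpy(dtype=np.int64),
            replicates=list(df.columns),
        )


@dataclass
class AssignmentResult:
    """Per-ORF counts for one replicate plus the discard tallies."""

    counts: dict[str, int]
    n_assigned: int = 0
    n_ambiguous: int = 0
    n_conflicting: int = 0
    n_unmatched: int = 0
    n_short: int = 0

    @property
    def n_total(self) -> int:
        return (
            self.n_assigned
            + self.n_ambiguous
            + self.n_conflicting
            + self.n_unmatched
            + self.n_short
        )


def _kmers(seq: str, k: int) -> Iterator[str]:
    for i in range(len(seq) - k + 1):
        yield seq[i : i + k]


def index_reference(ref: ORFReference) -> dict[str, str]:
    """Build the k-mer -> orf_id index; shared k-mers map to AMBIGUOUS."""
    index: dict[str, str] = {}
    for oid, seq in ref.entries:
        for km in set(_kmers(seq, ref.k)):
            prev = index.get(km)
            if prev is None:
                index[km] = oid
            elif prev != oid:
                index[km] = AMBIGUOUS
    return index


def assign_reads(
    reads: Iterable[str],
    index: Mapping[str, str],
    k: int,
    orf_ids: Sequence[str] | None = None,
) -> AssignmentResult:
    """Assign reads to ORFs by exact k-mer voting.

    A read is counted for ORF X iff all its unambiguous k-mers map to X
    and at least one k-mer is unambiguous.  Reads shorter than k, reads
    whose k-mers are all ambiguous or all absent from the index, and
    reads with k-mers voting for different ORFs are discarded and
    tallied.  Counting is independent of read order.
    """
    result = AssignmentResult(counts={oid: 0 for oid in orf_ids} if orf_ids else {})
    for read in reads:
        read = read.upper()
        if len(read) < k:
            result.n_short += 1
            continue
        target: str | None = None
        saw_ambiguous = False
        conflict = False
        for km in _kmers(read, k):
            hit = index.get(km)
            if hit is None:
                continue
            if hit == AMBIGUOUS:
                saw_ambiguous = True
                continue
            if target is None:
                target = hit
            elif hit != target:
                conflict = True
                break
        if conflict:
            result.n_conflicting += 1
        elif target is not None:
            result.counts[target] = result.counts.get(target, 0) + 1
            result.n_assigned += 1
        elif saw_ambiguous:
            result.n_ambiguous += 1
        else:
            result.n_unmatched += 1
    return result


def build_count_table(
    ref: ORFReference,
    readsets: Sequence[Iterable[str]],
    replicate_labels: Sequence[str] | None = None,
) -> tuple[CountTable, list[AssignmentResult]]:
    """Assign each replicate's reads and stack the columns into a table."""
    if replicate_labels is None:
        replicate_labels = [f"rep{i + 1}" for i in range(len(readsets))]
    index = index_reference(ref)
    results = [assign_reads(rs, index, ref.k, orf_ids=ref.orf_ids) for rs in readsets]
    counts = np.column_stack(
        [[r.counts[oid] for oid in ref.orf_ids] for r in results]
    ).astype(np.int64)
    table = CountTable(
        orf_ids=list(ref.orf_ids), counts=counts, replicates=list(replicate_labels)
    )
    return table, results


def counts_to_cpm(table: CountTable) -> CountTable:
    """Fill ``cpm`` with counts x 1e6 / library size per replicate.

    Zero-library columns become all-zero CPM with a warning.
    """
    sizes = table.library_sizes.astype(float)
    cpm = np.zeros(table.counts.shape, dtype=float)
    for j, size in enumerate(sizes):
        if size > 0:
            cpm[:, j] = table.counts[:, j] * 1e6 / size
        else:
            warnings.warn(
                f"replicate {table.replicates[j]!r} has zero library size; "
                "CPM set to zero",
                stacklevel=2,
            )
    return CountTable(
        orf_ids=list(table.orf_ids),
        counts=table.counts,
        replicates=list(table.replicates),
        cpm=cpm,
    )


def read_fastq(path: str | Path) -> list[str]:
    """Read sequences from a FASTQ file (plain or gzip)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [str(rec.seq) for rec in SeqIO.parse(fh, "fastq")]


def write_fastq(path: str | Path, reads: Sequence[str], prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
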