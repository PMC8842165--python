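"""Candidate-interactor calling from per-replicate count tables.

A prey is a candidate interactor of a bait unless its read count is
below the minimum in *both* technical replicates: an ORF is removed iff
count < min_count in every replicate, i.e. kept when at least one
replicate reaches the threshold.  Per-replicate detection flags at the
same threshold feed the replicate-overlap report (e.g. 209 of 224
wild-type candidates seen in both replicates, ~93%).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .quant import CountTable
from .reporting import round_percent


@dataclass
class CandidateList:
    """Candidate interactors of one bait with per-replicate detection."""

    bait: str
    orf_ids: set[str]
    detected_in: dict[str, set[str]]
    min_count: int = 3
    replicates: tuple[str, ...] = ("rep1", "rep2")

    def __post_init__(self) -> None:
        for oid in self.orf_ids:
            if not self.detected_in.get(oid):
                raise ValueError(f"{oid}: candidate with empty detection set")

    def __len__(self) -> int:
        return len(self.orf_ids)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (oid, ";".join(sorted(self.detected_in[oid])))
            for oid in sorted(self.orf_ids)
        ]
        return pd.DataFrame(rows, columns=["orf_id", "detected_in"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def call_candidates(
    table: CountTable,
    bait: str,
    min_count: int = 3,
    allow_single_replicate: bool = False,
) -> CandidateList:
    """Apply the count filter: drop ORFs with count < min_count in all reps."""
    if len(table.replicates) < 2 and not allow_single_replicate:
        raise ValueError(
            "count table has a single replicate; pass allow_single_replicate=True "
            "to call candidates without replicate support"
        )
    detected: dict[str, set[str]] = {}
    for i, oid in enumerate(table.orf_ids):
        reps = {
            rep
            for j, rep in enumerate(table.replicates)
            if table.counts[i, j] >= min_count
        }
        if reps:
            detected[oid] = reps
    return CandidateList(
        bait=bait,
        orf_ids=set(detected),
        detected_in=detected,
        min_count=min_count,
        replicates=tuple(table.replicates),
    )


@dataclass(frozen=True)
class OverlapReport:
    n_total: int
    n_both: int
    percent_both: float
    empty: bool = False


def replicate_overlap(candidates: CandidateList) -> OverlapReport:
    """Fraction of candidates detected in both technical replicates."""
    if len(candidates.replicates) != 2:
        raise ValueError("replicate_overlap requires exactly 2 replicates")
    n_total = len(candidates.orf_ids)
    if n_total == 0:
        return OverlapReport(0, 0, 0.0, empty=True)
    n_both = sum(
        1 for oid in candidates.orf_ids if len(candidates.detected_in[oid]) == 2
    )
    return OverlapReport(n_total, n_both, round_percent(n_both, n_total))
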