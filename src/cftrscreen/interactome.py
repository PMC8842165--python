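"""Bait-versus-bait interactome bookkeeping and edge-list export.

After frequent-flier removal, the candidate lists of two baits (e.g.
wild-type and F508del CFTR) are compared by plain set algebra: shared
interactors, bait-unique interactors, and rounded percentages for
reporting.  The comparison exports as a deterministic TSV edge list with
one row per (bait, prey) and a category column (shared / a-only /
b-only), mirroring the usual blue/green/red network-figure semantics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .calling import CandidateList
from .reporting import round_percent


def remove_fliers(candidates: CandidateList, fliers: set[str]) -> CandidateList:
    """Drop flagged frequent fliers from a candidate list."""
    kept = candidates.orf_ids - set(fliers)
    return CandidateList(
        bait=candidates.bait,
        orf_ids=kept,
        detected_in={oid: candidates.detected_in[oid] for oid in kept},
        min_count=candidates.min_count,
        replicates=candidates.replicates,
    )


@dataclass(frozen=True)
class InteractomeComparison:
    """Set algebra between two baits' flier-filtered interactomes."""

    bait_a: str
    bait_b: str
    set_a: frozenset[str]
    set_b: frozenset[str]

    @property
    def shared(self) -> frozenset[str]:
        return self.set_a & self.set_b

    @property
    def unique_a(self) -> frozenset[str]:
        return self.set_a - self.set_b

    @property
    def unique_b(self) -> frozenset[str]:
        return self.set_b - self.set_a

    @property
    def union_size(self) -> int:
        return len(self.set_a | self.set_b)

    @property
    def percent_shared_of_union(self) -> float:
        return round_percent(len(self.shared), self.union_size, digits=1)

    def summary(self) -> dict:
        return {
            "bait_a": self.bait_a,
            "bait_b": self.bait_b,
            "n_a": len(self.set_a),
            "n_b": len(self.set_b),
            "n_shared": len(self.shared),
            "n_unique_a": len(self.unique_a),
            "n_unique_b": len(self.unique_b),
            "union_size": self.union_size,
            "percent_shared_of_union": self.percent_shared_of_union,
        }


def compare_baits(a: CandidateList, b: CandidateList) -> InteractomeComparison:
    """Compare two (flier-filtered) candidate lists."""
    return InteractomeComparison(
        bait_a=a.bait,
        bait_b=b.bait,
        set_a=frozenset(a.orf_ids),
        set_b=frozenset(b.orf_ids),
    )


def edges_frame(
    comparison: InteractomeComparison, annotations: pd.DataFrame | None = None
) -> pd.DataFrame:
    """One row per (bait, prey); shared preys appear under both baits.

    Categories: ``shared``, ``bait_a_only``, ``bait_b_only``.  Rows are
    ordered by (bait, orf_id) so re-export is byte-identical.  An
    optional annotation frame (indexed by orf_id) is left-joined.
    """
    rows: list[tuple[str, str, str]] = []
    for bait, members, uniq_cat in (
        (comparison.bait_a, comparison.set_a, "bait_a_only"),
        (comparison.bait_b, comparison.set_b, "bait_b_only"),
    ):
        for orf in sorted(members):
            cat = "shared" if orf in comparison.shared else uniq_cat
            rows.append((bait, orf, cat))
    rows.sort(key=lambda r: (r[0], r[1]))
    df = pd.DataFrame(rows, columns=["bait", "prey", "category"])
    if annotations is not None:
        df = df.join(annotations, on="prey")
    return df


def export_edges(
    comparison: InteractomeComparison,
    out_dir: str | Path,
    annotations: pd.DataFrame | None = None,
) -> tuple[Path, Path]:
    """Write the TSV edge list and a JSON count summary; return both paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edges_path = out_dir / "edges.tsv"
    edges_frame(comparison, annotations).to_csv(edges_path, sep="\t", index=False)
    summary_path = out_dir / "comparison.json"
    summary_path.write_text(json.dumps(comparison.summary(), indent=2) + "\n")
    return edges_path, summary_path
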