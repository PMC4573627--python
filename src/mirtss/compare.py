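"""Cross-method agreement of miRNA TSS call sets.

Two methods are considered to have found the same TSS for a miRNA when their
positions lie within ``tol`` bp of each other (default 100 bp).  For three
sets, a miRNA is consistent across all of them only when all three pairwise
agreements hold — the pairwise rule is not transitive near the tolerance, so
this is the strictest reading.  Interval-valued calls are reduced to their
midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations


import pandas as pd

from .annotation_io import TssCall

__all__ = ["TssSet", "match_pair", "overlap_counts", "read_tss_set"]


@dataclass
class TssSet:
    """One method's TSS calls: miRNA id -> (chrom, position)."""

    method: str
    positions: dict[str, tuple[str, float]] = field(default_factory=dict)

    @classmethod
    def from_calls(cls, method: str, calls: list[TssCall]) -> "TssSet":
        positions = {}
        for c in calls:
            if c.tss is None:
                continue
            positions[c.mirna_id] = (c.tss.chrom, c.tss.midpoint)
        return cls(method=method, positions=positions)

    def __len__(self) -> int:
        return len(self.positions)


def read_tss_set(path, method: str | None = None) -> TssSet:
    """Read a TSS set from TSV with columns mirna_id, chrom, position."""
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "chrom": str})
    required = {"mirna_id", "chrom", "position"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    positions = {
        str(r.mirna_id): (str(r.chrom), float(r.position)) for r in df.itertuples()
    }
    return TssSet(method=method or str(path), positions=positions)


def _agree(a: tuple[str, float], b: tuple[str, float], tol: float) -> bool:
    return a[0] == b[0] and abs(a[1] - b[1]) <= tol


def match_pair(a: TssSet, b: TssSet, tol: float = 100) -> set[str]:
    """miRNA ids present in both sets whose positions agree within ``tol`` bp."""
    return {
        mid
        for mid in a.positions.keys() & b.positions.keys()
        if _agree(a.positions[mid], b.positions[mid], tol)
    }


def overlap_counts(sets: list[TssSet], tol: float = 100) -> dict[str, int]:
    """Venn-partition counts of agreement across 2 or 3 TSS sets.

    A miRNA contributes to a region when it is present in exactly that group
    of methods *and* all pairwise agreements within the group hold; a miRNA
    present in all three sets with only partial pairwise agreement counts
    toward the largest fully-agreeing subgroup (ties broken by method order).
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("overlap_counts supports 2 or 3 sets")
    labels = [s.method for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("method labels must be unique")
    counts: dict[str, int] = {labels[0] + "_only": 0, labels[1] + "_only": 0}
    if len(sets) == 3:
        counts[labels[2] + "_only"] = 0
    for r in range(2, len(sets) + 1):
        for combo in combinations(range(len(sets)), r):
            counts["&".join(labels[i] for i in combo)] = 0

    all_ids = set()
    for s in sets:
        all_ids |= set(s.positions)
    for mid in sorted(all_ids):
        present = [i for i, s in enumerate(sets) if mid in s.positions]
        best: tuple[int, ...] = (present[0],)
        for r in range(len(present), 1, -1):
            found = None
            for combo in combinations(present, r):
                if all(
                    _agree(sets[i].positions[mid], sets[j].positions[mid], tol)
                    for i, j in combinations(combo, 2)
                ):
                    found = combo
                    break
            if found is not None:
                best = found
                break
        if len(best) == 1:
            counts[labels[best[0]] + "_only"] += 1
        else:
            counts["&".join(labels[i] for i in best)] += 1
    return counts
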