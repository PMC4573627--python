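"""Strand-oriented multi-mark profile extraction around anchor positions.

An anchor (a TSS, a random position, or a candidate bin during scanning) is
described by the binned RPM signal of each mark in ``k`` bins upstream and
``k`` bins downstream, oriented 5'->3' with respect to the anchor's strand.
The anchor's own bin is the first downstream bin (``d_1``); the per-mark
layout is ``u_k .. u_1, d_1 .. d_k`` and marks are concatenated in a fixed
configured order.  Bins falling off the chromosome contribute zero signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .annotation_io import GenomeTable
from .coverage import BinnedTrack

__all__ = [
    "Anchor",
    "ProfileMatrix",
    "MeanProfile",
    "extract_profile",
    "build_matrix",
    "sample_random_anchors",
    "mean_profile",
]


class Anchor(NamedTuple):
    id: str
    chrom: str
    position: int  # internal 0-based
    strand: str  # '+' or '-'


@dataclass
class ProfileMatrix:
    """Feature matrix of shape (#anchors, #marks * 2k) with optional labels."""

    anchors: list[Anchor]
    marks: list[str]
    k: int
    X: np.ndarray
    y: np.ndarray | None = None  # +1 / -1

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.anchors), len(self.marks) * 2 * self.k):
            raise ValueError(f"feature matrix shape {self.X.shape} inconsistent")
        if self.y is not None:
            self.y = np.asarray(self.y)
            if self.y.shape != (len(self.anchors),):
                raise ValueError("labels do not align with anchors")
            if not np.all(np.isin(self.y, [-1, 1])):
                raise ValueError("labels must be +1 / -1")

    @property
    def n(self) -> int:
        return len(self.anchors)

    def subset(self, idx) -> "ProfileMatrix":
        idx = np.asarray(idx)
        return ProfileMatrix(
            anchors=[self.anchors[i] for i in idx],
            marks=self.marks,
            k=self.k,
            X=self.X[idx],
            y=None if self.y is None else self.y[idx],
        )


@dataclass
class MeanProfile:
    """Average metagene profile of one mark over ±W bp around anchors."""

    mark: str
    bin_size: int
    W: int
    values: np.ndarray  # length 2*W/bin_size, upstream first

    @property
    def offsets(self) -> np.ndarray:
        """bp offset of each bin start relative to the anchor (5'->3')."""
        n_side = self.W // self.bin_size
        return (np.arange(-n_side, n_side)) * self.bin_size

    def to_tsv(self) -> str:
        lines = ["offset\tmean_rpm"]
        for off, v in zip(self.offsets, self.values):
            lines.append(f"{off}\t{v:.6g}")
        return "\n".join(lines) + "\n"


def _oriented_gather(track: BinnedTrack, anchors: Sequence[Anchor], k: int) -> np.ndarray:
    """Gather oriented 2k-bin windows for all anchors from one track."""
    out = np.zeros((len(anchors), 2 * k), dtype=np.float64)
    offsets = np.arange(-k, k)  # + strand: u_k..u_1, d_1..d_k
    by_chrom: dict[str, list[int]] = {}
    for i, a in enumerate(anchors):
        by_chrom.setdefault(a.chrom, []).append(i)
    for chrom, rows in by_chrom.items():
        if chrom not in track.values:
            raise KeyError(f"track {track.mark!r} has no chromosome {chrom!r}")
        vals = track.values[chrom]
        rows = np.asarray(rows)
        bins = np.array([anchors[i].position // track.bin_size for i in rows])
        sign = np.array([1 if anchors[i].strand != "-" else -1 for i in rows])
        idx = bins[:, None] + sign[:, None] * offsets[None, :]
        valid = (idx >= 0) & (idx < len(vals))
        out[rows] = np.where(valid, vals[np.clip(idx, 0, len(vals) - 1)], 0.0)
    return out


def extract_profile(
    tracks: dict[str, BinnedTrack], anchor: Anchor, k: int, marks: Sequence[str] | None = None
) -> np.ndarray:
    """Oriented feature vector of one anchor: 2k bins per mark, concatenated.

    ``marks`` fixes the concatenation order; default is the mapping order of
    ``tracks``.
    """
    marks = list(tracks) if marks is None else list(marks)
    for m in marks:
        if m not in tracks:
            raise KeyError(f"unknown mark {m!r}")
    return np.concatenate([_oriented_gather(tracks[m], [anchor], k)[0] for m in marks])


def build_matrix(
    tracks: dict[str, BinnedTrack],
    anchors: Sequence[Anchor],
    labels: Sequence[int] | None = None,
    k: int = 10,
    marks: Sequence[str] | None = None,
) -> ProfileMatrix:
    """Assemble the anchors-by-features matrix; row order follows anchor order."""
    marks = list(tracks) if marks is None else list(marks)
    ids = [a.id for a in anchors]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated anchor ids")
    if labels is not None and len(labels) != len(anchors):
        raise ValueError(f"{len(labels)} labels for {len(anchors)} anchors")
    if len(anchors) == 0:
        X = np.zeros((0, len(marks) * 2 * k))
    else:
        X = np.concatenate([_oriented_gather(tracks[m], anchors, k) for m in marks], axis=1)
    y = None if labels is None else np.asarray(labels, dtype=np.int64)
    return ProfileMatrix(anchors=list(anchors), marks=marks, k=k, X=X, y=y)


def sample_random_anchors(
    genome: GenomeTable,
    n: int,
    seed: int | np.random.Generator,
    exclusion: Sequence[tuple[str, int]] | None = None,
    exclusion_dist: int = 0,
    prefix: str = "rand",
) -> list[Anchor]:
    """Sample ``n`` uniform genomic positions with uniformly random strands.

    Chromosomes are chosen proportional to length.  With ``exclusion`` (a
    list of ``(chrom, position)`` TSSs) and ``exclusion_dist`` > 0, sampled
    positions closer than ``exclusion_dist`` bp to any excluded position are
    rejected and redrawn.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=np.float64)
    probs = lengths / lengths.sum()

    excl: dict[str, np.ndarray] = {}
    if exclusion is not None and exclusion_dist > 0:
        for chrom, pos in exclusion:
            excl.setdefault(chrom, [])
            excl[chrom].append(pos)
        excl = {c: np.sort(np.asarray(p)) for c, p in excl.items()}
        covered = sum(
            min(genome[c], len(p) * (2 * exclusion_dist + 1)) for c, p in excl.items()
        )
        if covered >= lengths.sum():
            raise ValueError("exclusion zone may cover the entire genome")

    anchors: list[Anchor] = []
    attempts = 0
    max_attempts = 200 * n + 1000
    while len(anchors) < n:
        if attempts >= max_attempts:
            raise ValueError("exclusion leaves too little sampleable space")
        attempts += 1
        ci = rng.choice(len(chroms), p=probs)
        chrom = chroms[ci]
        pos = int(rng.integers(0, genome[chrom]))
        if chrom in excl and len(excl[chrom]):
            j = np.searchsorted(excl[chrom], pos)
            near = [excl[chrom][m] for m in (j - 1, j) if 0 <= m < len(excl[chrom])]
            if near and min(abs(pos - q) for q in near) < exclusion_dist:
                continue
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        anchors.append(Anchor(f"{prefix}{len(anchors)}", chrom, pos, strand))
    return anchors


def mean_profile(
    tracks: dict[str, BinnedTrack], anchors: Sequence[Anchor], mark: str, W: int = 2000
) -> MeanProfile:
    """Arithmetic-mean oriented metagene profile of one mark over ±W bp."""
    if len(anchors) == 0:
        raise ValueError("mean_profile needs at least one anchor")
    track = tracks[mark] if isinstance(tracks, dict) else tracks
    if W % track.bin_size:
        raise ValueError("W must be a multiple of bin_size")
    k = W // track.bin_size
    windows = _oriented_gather(track, anchors, k)
    return MeanProfile(mark=mark, bin_size=track.bin_size, W=W, values=windows.mean(axis=0))
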