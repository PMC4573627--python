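"""Binned read coverage and reads-per-million (RPM) normalisation.

ChIP-Seq alignments are reduced to their 5'-most aligned base (strand-aware),
counted in fixed-width genomic bins (default 100 bp), and normalised to reads
per million per bin:

    RPM_i = R_i * 1e6 / N

where ``R_i`` is the read count in bin ``i`` and ``N`` the total mapped reads
of the library, so libraries of different depth become comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation_io import GenomeTable

__all__ = [
    "AlignedReadSet",
    "BinnedTrack",
    "read_bed_reads",
    "assign_bin",
    "bin_reads",
    "rpm_normalize",
    "track_from_reads",
    "write_bedgraph",
]


@dataclass
class AlignedReadSet:
    """5' positions of the aligned reads of one histone-mark library."""

    mark: str
    positions: dict[str, np.ndarray] = field(default_factory=dict)  # chrom -> int64

    @property
    def n_reads(self) -> int:
        return int(sum(len(v) for v in self.positions.values()))


@dataclass
class BinnedTrack:
    """Per-chromosome RPM values in fixed-width bins for one mark.

    The last bin of each chromosome may cover a shorter natural span; the RPM
    formula is unchanged for it.
    """

    mark: str
    bin_size: int
    values: dict[str, np.ndarray]  # chrom -> float64 RPM per bin
    N: int  # library size used for normalisation

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])


def read_bed_reads(path, mark: str) -> AlignedReadSet:
    """Load a BED6 file of alignments; the 5' end is inferred from the strand."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 5],
        names=["chrom", "start", "end", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
        comment="#",
    )
    five = np.where(df["strand"].to_numpy() == "-", df["end"].to_numpy() - 1, df["start"].to_numpy())
    positions: dict[str, np.ndarray] = {}
    for chrom, sub in df.assign(five=five).groupby("chrom", sort=True):
        positions[str(chrom)] = np.sort(sub["five"].to_numpy())
    return AlignedReadSet(mark=mark, positions=positions)


def assign_bin(position: int, bin_size: int) -> int:
    """Bin index of an internal position; bin ``i`` covers ``[i*b, (i+1)*b)``."""
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    if position < 0:
        raise ValueError(f"negative position {position}")
    return position // bin_size


def bin_reads(
    readset: AlignedReadSet,
    genome: GenomeTable,
    bin_size: int = 100,
    out_of_bounds: str = "error",
) -> dict[str, np.ndarray]:
    """Count read 5' ends per bin.

    ``out_of_bounds`` controls reads beyond the chromosome end (or on unknown
    chromosomes): ``"error"`` raises, ``"drop"`` discards them with a warning.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    if out_of_bounds not in {"error", "drop"}:
        raise ValueError(f"unknown out_of_bounds policy {out_of_bounds!r}")
    counts = {
        chrom: np.zeros(-(-length // bin_size), dtype=np.int64)
        for chrom, length in genome.items()
    }
    n_dropped = 0
    for chrom, pos in readset.positions.items():
        if chrom not in genome:
            if out_of_bounds == "error":
                raise ValueError(f"reads on unknown chromosome {chrom!r}")
            n_dropped += len(pos)
            continue
        bad = (pos < 0) | (pos >= genome[chrom])
        if bad.any():
            if out_of_bounds == "error":
                raise ValueError(
                    f"{int(bad.sum())} reads outside chromosome {chrom} "
                    f"(length {genome[chrom]})"
                )
            n_dropped += int(bad.sum())
            pos = pos[~bad]
        counts[chrom] += np.bincount(pos // bin_size, minlength=len(counts[chrom]))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} out-of-bounds reads", stacklevel=2)
    return counts


def rpm_normalize(
    counts: dict[str, np.ndarray], N: int, mark: str = "", bin_size: int = 100
) -> BinnedTrack:
    """Scale raw bin counts to reads per million per bin: ``R_i * 1e6 / N``."""
    if N <= 0:
        raise ValueError(f"library size N must be positive, got {N}")
    values = {chrom: c.astype(np.float64) * (1e6 / N) for chrom, c in counts.items()}
    return BinnedTrack(mark=mark, bin_size=bin_size, values=values, N=N)


def track_from_reads(
    readset: AlignedReadSet,
    genome: GenomeTable,
    bin_size: int = 100,
    N: int | None = None,
    out_of_bounds: str = "error",
) -> BinnedTrack:
    """Bin a read set and normalise it in one step.

    ``N`` defaults to the library's own mapped-read count and may be
    overridden when normalisation against an externally determined depth is
    wanted.
    """
    counts = bin_reads(readset, genome, bin_size=bin_size, out_of_bounds=out_of_bounds)
    if N is None:
        N = readset.n_reads
    return rpm_normalize(counts, N, mark=readset.mark, bin_size=bin_size)


def write_bedgraph(track: BinnedTrack, path) -> None:
    """Emit non-zero RPM bins as bedGraph."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.mark} RPM"\n')
        for chrom, vals in track.values.items():
            nz = np.flatnonzero(vals)
            for i in nz:
                start = int(i) * track.bin_size
                fh.write(f"{chrom}\t{start}\t{start + track.bin_size}\t{vals[i]:.6g}\n")
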