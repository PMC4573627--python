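"""Synthetic genomes, annotations and multi-mark ChIP-Seq reads with planted
promoter structure.

The generator lays the genome out as shuffled cassettes: 5 kb gene cassettes
(one protein-coding gene each, matching the dense one-gene-every-4-5-kb
architecture of a small plant genome) interleaved with 14 kb miRNA cassettes.
Each miRNA is planted in one of four categories:

* ``independent`` — its primary transcript has its own TSS 0.3–8 kb upstream
  of the miRNA locus, with promoter-like histone signal planted there;
* ``shared`` — the miRNA sits just downstream of a protein-coding gene and
  its planted TSS is that gene's TSS (co-transcription);
* ``intronic`` — the miRNA lies inside an intron of a host gene and shares
  the host TSS;
* ``null`` — no promoter signal anywhere in the miRNA's upstream window.

Reads are single-end 5' points.  Each mark's library is Poisson background
uniform over the genome plus, for marks with a TSS-proximal peak, reads drawn
from a strand-oriented Gaussian (default centre +200 bp downstream of each
planted TSS, sd 300 bp) with Poisson-distributed per-TSS counts, so that the
expected library size matches the configured depth.  Nine default marks
caricature the canonical promoter chromatin palette: one strongly peaked
(H3K4me3-like), five moderately peaked, two flat heterochromatic marks
(H3K9me2/H3K27me1-like) and one broad gene-body mark (H3K36me3-like).
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .annotation_io import GenomeTable, GenomicInterval, TranscriptAnnotation
from .coverage import AlignedReadSet, BinnedTrack, track_from_reads

__all__ = [
    "MarkSpec",
    "SimConfig",
    "SimTruth",
    "SimData",
    "DEFAULT_MARKS",
    "simulate_annotations",
    "simulate_reads",
    "simulate_dataset",
    "write_reads_bed",
    "make_fixture_table1",
]

GENE_SLOT = 5_000
MIRNA_SLOT = 14_000
CATEGORIES = ("independent", "shared", "intronic", "null")


@dataclass(frozen=True)
class MarkSpec:
    """Generative parameters of one histone-mark library.

    ``peak_amplitude`` is the expected number of TSS-proximal reads per
    planted TSS; ``peak_offset`` (bp, 5'->3') and ``peak_sd`` (bp) shape the
    Gaussian around it.  Amplitude 0 gives a background-only (flat) mark.
    """

    name: str
    peak_amplitude: float
    peak_offset: float = 200.0
    peak_sd: float = 300.0

    def __post_init__(self) -> None:
        if self.peak_amplitude < 0 or self.peak_sd <= 0:
            raise ValueError(f"invalid mark spec for {self.name}")


DEFAULT_MARKS: tuple[MarkSpec, ...] = (
    MarkSpec("H3K4me2", 15.0),
    MarkSpec("H3K4me3", 50.0),
    MarkSpec("H3K9Ac", 15.0),
    MarkSpec("H3K9me2", 0.0),
    MarkSpec("H3K18Ac", 15.0),
    MarkSpec("H3K27me1", 0.0),
    MarkSpec("H3K27me3", 15.0),
    MarkSpec("H3K36me2", 15.0),
    MarkSpec("H3K36me3", 12.0, peak_offset=800.0, peak_sd=600.0),
)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic genome."""

    genome: tuple[tuple[str, int], ...] = (("chr1", 6_000_000), ("chr2", 5_400_000))
    n_genes: int = 2000
    n_mirnas: int = 60
    category_fractions: tuple[float, float, float, float] = (0.15, 0.30, 0.10, 0.45)
    marks: tuple[MarkSpec, ...] = DEFAULT_MARKS
    library_size: int = 200_000
    bin_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.category_fractions) - 1.0) > 1e-9:
            raise ValueError("category fractions must sum to 1")
        if any(f < 0 for f in self.category_fractions):
            raise ValueError("category fractions must be non-negative")
        if self.library_size <= 0 or self.bin_size <= 0:
            raise ValueError("library_size and bin_size must be positive")
        needed = self.n_genes * GENE_SLOT + self.n_mirnas * MIRNA_SLOT
        total = sum(length for _, length in self.genome)
        if needed > total:
            raise ValueError(
                f"genome too small: need {needed} bp for "
                f"{self.n_genes} genes + {self.n_mirnas} miRNAs, have {total}"
            )

    @property
    def genome_table(self) -> GenomeTable:
        return GenomeTable(dict(self.genome))

    def category_counts(self) -> dict[str, int]:
        """Largest-remainder apportionment of miRNAs over categories."""
        raw = [f * self.n_mirnas for f in self.category_fractions]
        counts = [int(np.floor(r)) for r in raw]
        order = np.argsort([c - r for c, r in zip(counts, raw)])
        for i in range(self.n_mirnas - sum(counts)):
            counts[order[i]] += 1
        return dict(zip(CATEGORIES, counts))


@dataclass
class SimTruth:
    """Planted ground truth serialised alongside the synthetic outputs."""

    seed: int
    mirnas: list[dict] = field(default_factory=list)  # id, category, planted_tss, ...
    gene_tss: list[dict] = field(default_factory=list)  # chrom, position, strand
    mark_params: list[dict] = field(default_factory=list)
    background_rate: dict[str, float] = field(default_factory=dict)  # reads per bp

    def planted(self, category: str | None = None) -> list[dict]:
        return [
            m
            for m in self.mirnas
            if m["planted_tss"] is not None
            and (category is None or m["category"] == category)
        ]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        return cls(**json.loads(text))


def _flip(a: int, b: int, slot: int) -> tuple[int, int]:
    return slot - b, slot - a


def _make_exons(start: int, end: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """2-4 exons walking 5'->3' in genome coordinates, last exon pinned to end."""
    n_ex = int(rng.integers(2, 5))
    exons = []
    pos = start
    for _ in range(n_ex - 1):
        elen = int(rng.integers(200, 500))
        ilen = int(rng.integers(200, 800))
        if pos + elen + ilen + 200 > end:
            break
        exons.append((pos, pos + elen))
        pos = pos + elen + ilen
    exons.append((pos, end))
    return exons


def _gene_cassette(gid, chrom, base, strand, rng):
    glen = int(rng.integers(1500, 3001))
    s, e = 1000, 1000 + glen
    exons_local = _make_exons(s, e, rng)
    if strand == "-":
        s, e = _flip(s, e, GENE_SLOT)
        exons_local = sorted(_flip(a, b, GENE_SLOT) for a, b in exons_local)
    iv = GenomicInterval(chrom, base + s, base + e, strand)
    exons = [GenomicInterval(chrom, base + a, base + b, strand) for a, b in exons_local]
    tss = iv.start if strand == "+" else iv.end - 1
    return TranscriptAnnotation(gid, iv, "protein_coding", exons), tss


def _mirna_cassette(mid, chrom, base, strand, category, rng):
    """Local layout on the + strand, mirrored in-place for -; returns
    (mirna annotation, host gene annotation or None, planted TSS or None)."""
    mlen = int(rng.integers(80, 301))
    host = None
    if category in ("independent", "null"):
        m_s, m_e = 12000, 12000 + mlen
        planted_local = (m_s - int(rng.integers(300, 8001))) if category == "independent" else None
    elif category == "shared":
        glen = int(rng.integers(1500, 2501))
        g_s, g_e = 8000, 8000 + glen
        gap = int(rng.integers(200, 1500))
        m_s = g_e + gap
        m_e = m_s + mlen
        planted_local = g_s
        host = (g_s, g_e, _make_exons(g_s, g_e, rng))
    elif category == "intronic":
        g_s, g_e = 8000, 11000
        exons = [(8000, 8300), (10300, 11000)]
        m_s = 8300 + int(rng.integers(200, 1800))
        m_e = min(m_s + min(mlen, 200), 10300)
        planted_local = g_s
        host = (g_s, g_e, exons)
    else:
        raise ValueError(f"unknown category {category!r}")

    if strand == "-":
        m_s, m_e = _flip(m_s, m_e, MIRNA_SLOT)
        if planted_local is not None:
            planted_local = MIRNA_SLOT - 1 - planted_local
        if host is not None:
            g_s, g_e, exons = host
            g_s, g_e = _flip(g_s, g_e, MIRNA_SLOT)
            exons = sorted(_flip(a, b, MIRNA_SLOT) for a, b in exons)
            host = (g_s, g_e, exons)

    mirna = TranscriptAnnotation(
        mid, GenomicInterval(chrom, base + m_s, base + m_e, strand), "miRNA"
    )
    mirna.name = mid.replace("sim-mir", "sim-MIR")
    host_gene = None
    host_tss = None
    if host is not None:
        g_s, g_e, exons = host
        host_gene = TranscriptAnnotation(
            f"host_{mid}",
            GenomicInterval(chrom, base + g_s, base + g_e, strand),
            "protein_coding",
            [GenomicInterval(chrom, base + a, base + b, strand) for a, b in exons],
        )
        host_tss = host_gene.interval.start if strand == "+" else host_gene.interval.end - 1
    planted = None if planted_local is None else base + planted_local
    return mirna, host_gene, host_tss, planted


def simulate_annotations(
    config: SimConfig,
) -> tuple[list[TranscriptAnnotation], list[TranscriptAnnotation], SimTruth]:
    """Lay out genes and category-planted miRNAs on the configured genome."""
    rng = np.random.default_rng(config.seed)
    counts = config.category_counts()
    cassettes = ["gene"] * config.n_genes + [
        cat for cat in CATEGORIES for _ in range(counts[cat])
    ]
    order = rng.permutation(len(cassettes))
    cassettes = [cassettes[i] for i in order]

    genes: list[TranscriptAnnotation] = []
    mirnas: list[TranscriptAnnotation] = []
    truth = SimTruth(seed=config.seed, mark_params=[asdict(m) for m in config.marks])

    chrom_iter = iter(config.genome)
    chrom, length = next(chrom_iter)
    cursor = 0
    n_gene = n_mirna = 0
    for cat in cassettes:
        slot = GENE_SLOT if cat == "gene" else MIRNA_SLOT
        while cursor + slot > length:
            chrom, length = next(chrom_iter)  # capacity checked in SimConfig
            cursor = 0
        base = cursor
        cursor += slot
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        if cat == "gene":
            n_gene += 1
            gene, tss = _gene_cassette(f"gene{n_gene:05d}", chrom, base, strand, rng)
            genes.append(gene)
            truth.gene_tss.append({"chrom": chrom, "position": int(tss), "strand": strand})
        else:
            n_mirna += 1
            mid = f"sim-mir{n_mirna:04d}"
            mirna, host, host_tss, planted = _mirna_cassette(mid, chrom, base, strand, cat, rng)
            mirnas.append(mirna)
            if host is not None:
                genes.append(host)
                truth.gene_tss.append(
                    {"chrom": chrom, "position": int(host_tss), "strand": strand}
                )
            truth.mirnas.append(
                {
                    "id": mid,
                    "chrom": chrom,
                    "start": mirna.interval.start,
                    "end": mirna.interval.end,
                    "strand": strand,
                    "category": cat,
                    "planted_tss": None if planted is None else int(planted),
                }
            )
    genes.sort(key=lambda t: (t.interval.chrom, t.interval.start))
    mirnas.sort(key=lambda t: (t.interval.chrom, t.interval.start))
    return genes, mirnas, truth


def _peak_anchor_set(truth: SimTruth) -> list[tuple[str, int, str]]:
    """TSSs that receive promoter signal: every gene TSS plus every
    independent miRNA's planted TSS (shared/intronic reuse their gene's)."""
    anchors = [(g["chrom"], g["position"], g["strand"]) for g in truth.gene_tss]
    anchors += [
        (m["chrom"], m["planted_tss"], m["strand"])
        for m in truth.mirnas
        if m["category"] == "independent"
    ]
    return anchors


def simulate_reads(
    config: SimConfig, truth: SimTruth, seed: int | None = None
) -> dict[str, AlignedReadSet]:
    """Draw per-mark read 5' positions: Poisson background + Gaussian peaks."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genome = config.genome_table
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=np.float64)
    anchors = _peak_anchor_set(truth)
    total_len = lengths.sum()

    readsets: dict[str, AlignedReadSet] = {}
    for spec in config.marks:
        positions: dict[str, list[np.ndarray]] = {c: [] for c in chroms}
        expected_peak = spec.peak_amplitude * len(anchors)
        if spec.peak_amplitude > 0:
            counts = rng.poisson(spec.peak_amplitude, size=len(anchors))
            for (chrom, tss, strand), cnt in zip(anchors, counts):
                if cnt == 0:
                    continue
                direction = 1.0 if strand == "+" else -1.0
                offs = direction * (spec.peak_offset + spec.peak_sd * rng.normal(size=cnt))
                pos = np.clip(np.rint(tss + offs).astype(np.int64), 0, genome[chrom] - 1)
                positions[chrom].append(pos)
        expected_bg = max(0.0, config.library_size - expected_peak)
        n_bg = rng.poisson(expected_bg)
        per_chrom = rng.multinomial(n_bg, lengths / total_len)
        for chrom, cnt in zip(chroms, per_chrom):
            if cnt:
                positions[chrom].append(rng.integers(0, genome[chrom], size=cnt))
        merged = {
            c: np.sort(np.concatenate(v)) if v else np.empty(0, dtype=np.int64)
            for c, v in positions.items()
        }
        readsets[spec.name] = AlignedReadSet(mark=spec.name, positions=merged)
        truth.background_rate[spec.name] = expected_bg / total_len
    return readsets


def write_reads_bed(
    readset: AlignedReadSet,
    path,
    genome: GenomeTable,
    read_length: int = 35,
    seed: int = 0,
) -> None:
    """Write reads as BED6 with random read strands; the recorded span is the
    aligned read, whose strand-aware 5'-most base is the stored position."""
    rng = np.random.default_rng(seed)
    with open(path, "w") as fh:
        i = 0
        for chrom in readset.positions:
            L = genome[chrom]
            for p in readset.positions[chrom]:
                i += 1
                if rng.integers(0, 2) == 0:
                    start, end, strand = p, min(p + read_length, L), "+"
                else:
                    start, end, strand = max(p - read_length + 1, 0), p + 1, "-"
                fh.write(f"{chrom}\t{start}\t{end}\tread{i}\t0\t{strand}\n")


@dataclass
class SimData:
    """An in-memory synthetic dataset: annotations, truth, reads and tracks."""

    config: SimConfig
    genome: GenomeTable
    genes: list[TranscriptAnnotation]
    mirnas: list[TranscriptAnnotation]
    truth: SimTruth
    reads: dict[str, AlignedReadSet]
    tracks: dict[str, BinnedTrack]

    @property
    def mark_names(self) -> list[str]:
        return [m.name for m in self.config.marks]


def simulate_dataset(config: SimConfig | None = None, **overrides) -> SimData:
    """Generate annotations, reads and RPM tracks for one configuration."""
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    genes, mirnas, truth = simulate_annotations(config)
    reads = simulate_reads(config, truth)
    genome = config.genome_table
    tracks = {
        mark: track_from_reads(rs, genome, bin_size=config.bin_size)
        for mark, rs in reads.items()
    }
    return SimData(
        config=config,
        genome=genome,
        genes=genes,
        mirnas=mirnas,
        truth=truth,
        reads=reads,
        tracks=tracks,
    )


def make_fixture_table1() -> str:
    """The packaged machine-readable transcription of the published table of
    42 independent predicted miRNA TSSs (coordinates verbatim, en-dashes
    normalised to ASCII hyphens)."""
    return (
        importlib.resources.files("mirtss.data")
        .joinpath("independent_tss_fixture.tsv")
        .read_text()
    )
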