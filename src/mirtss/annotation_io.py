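"""Genomic annotation and table I/O, and the package's coordinate conventions.

All in-memory coordinates are 0-based half-open ``[start, end)``.  Printed and
parsed coordinates follow the conventions of the formats they travel in:

* GFF3 and ``chrom:start-end(strand)`` region strings are 1-based inclusive.
* Predicted-TSS intervals in prediction tables are 1-based *half-open* bin-edge
  pairs ``start-end`` with ``end - start`` equal to the bin width.  This is the
  convention under which every published 100 bp TSS bin has printed width 100
  and the printed distances between TSS bins and miRNA loci are plain
  subtractions of adjacent boundary coordinates.

En-dash separators (as they appear in typeset tables) are normalised to ASCII
hyphens on parse.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import gffutils

__all__ = [
    "GenomicInterval",
    "TranscriptAnnotation",
    "GenomeTable",
    "TssCall",
    "read_annotations",
    "write_annotations",
    "tss_of",
    "read_genome_table",
    "write_genome_table",
    "parse_region",
    "format_region",
    "read_prediction_table",
    "write_prediction_table",
    "calls_to_bed",
]

_STRANDS = {"+", "-", "."}

PREDICTION_COLUMNS = (
    "index",
    "mirna_id",
    "mirna_name",
    "mirna_coords",
    "strand",
    "tss_coords",
    "score",
    "qvalue",
    "category",
)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic span with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        """Centre of the covered bases, (start + end - 1) / 2.

        This convention maps exactly onto itself under genome reflection,
        which keeps proximity classifications strand-symmetric.
        """
        return (self.start + self.end - 1) / 2.0


@dataclass
class TranscriptAnnotation:
    """A gene or miRNA locus with optional exon structure.

    Exons are stored sorted in genome coordinates; introns are the gaps
    between consecutive exons.  miRNA loci are unspliced single intervals.
    """

    id: str
    interval: GenomicInterval
    kind: str = "protein_coding"  # or "miRNA"
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for e in self.exons:
            if e.chrom != self.interval.chrom:
                raise ValueError(f"{self.id}: exon on different chromosome")
            if e.start < self.interval.start or e.end > self.interval.end:
                raise ValueError(f"{self.id}: exon outside gene interval")
            if prev_end is not None and e.start < prev_end:
                raise ValueError(f"{self.id}: overlapping exons")
            prev_end = e.end

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(self.interval.chrom, a.end, b.start, self.interval.strand)
                )
        return out


class GenomeTable(dict):
    """Mapping chromosome name -> length in bp."""

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        for name, length in self.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    def contains(self, iv: GenomicInterval) -> bool:
        return iv.chrom in self and iv.end <= self[iv.chrom]


@dataclass
class TssCall:
    """One miRNA's predicted transcription start site (or the lack of one).

    ``category`` is one of ``independent`` (own promoter), ``shared_upstream``
    (coincides with the nearest upstream gene's TSS), or ``none`` (no candidate
    survived FDR control).  ``tss`` is the winning candidate bin, absent for
    ``none``.  Distances are measured between printed boundary coordinates
    (see module docstring), in bp.
    """

    mirna_id: str
    mirna_name: str = ""
    mirna: GenomicInterval | None = None
    category: str = "none"
    tss: GenomicInterval | None = None
    score: float | None = None
    qvalue: float | None = None
    distance_to_mirna: int | None = None
    distance_to_upstream_gene_tss: int | None = None
    intronic: bool = False

    def __post_init__(self) -> None:
        if (self.category == "none") != (self.tss is None):
            raise ValueError("category is 'none' iff no TSS interval is present")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_MIRNA_TYPES = {"miRNA", "miRNA_primary_transcript"}
_GENE_TYPES = {"gene", "protein_coding_gene"}


def read_annotations(gff3_path, kind_filter: str) -> list[TranscriptAnnotation]:
    """Parse a GFF3 file into :class:`TranscriptAnnotation` records.

    ``kind_filter`` selects ``"protein_coding"`` (``gene`` features, with
    ``exon`` children attached through their ``Parent`` attribute) or
    ``"miRNA"`` (miRBase-style ``miRNA``/``miRNA_primary_transcript``
    features, kept unspliced).  Coordinates convert from GFF3's 1-based
    inclusive convention to the internal 0-based half-open one.
    """
    if kind_filter not in {"protein_coding", "miRNA"}:
        raise ValueError(f"unknown kind_filter {kind_filter!r}")
    try:
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        if "empty file" in str(exc).lower() or "no lines parsed" in str(exc).lower():
            return []
        raise ValueError(f"malformed GFF3 {gff3_path}: {exc}") from exc

    def _iv(feat) -> GenomicInterval:
        strand = feat.strand if feat.strand in ("+", "-") else "."
        if feat.strand not in ("+", "-", ".", "?"):
            raise ValueError(f"unknown strand symbol {feat.strand!r} for {feat.id}")
        return GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand)

    out: list[TranscriptAnnotation] = []
    if kind_filter == "miRNA":
        wanted = sorted(_MIRNA_TYPES & set(db.featuretypes()))
        for ftype in wanted:
            for feat in db.features_of_type(ftype, order_by=("seqid", "start")):
                name = feat.attributes.get("Name", [feat.id])[0]
                out.append(TranscriptAnnotation(feat.id, _iv(feat), kind="miRNA"))
                out[-1].name = name  # convenience attr used by table writers
        return out

    wanted = sorted(_GENE_TYPES & set(db.featuretypes()))
    for ftype in wanted:
        for feat in db.features_of_type(ftype, order_by=("seqid", "start")):
            exons = [
                _iv(child)
                for child in db.children(feat, featuretype="exon", order_by="start")
            ]
            out.append(
                TranscriptAnnotation(feat.id, _iv(feat), kind="protein_coding", exons=exons)
            )
    return out


def write_annotations(annots: list[TranscriptAnnotation], path, source="mirtss") -> None:
    """Write records as GFF3; inverse of :func:`read_annotations`."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in annots:
            iv = t.interval
            ftype = "gene" if t.kind == "protein_coding" else "miRNA_primary_transcript"
            attrs = f"ID={t.id}"
            name = getattr(t, "name", None)
            if name:
                attrs += f";Name={name}"
            fh.write(
                f"{iv.chrom}\t{source}\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand if iv.strand != '.' else '.'}\t.\t{attrs}\n"
            )
            for j, e in enumerate(t.exons, 1):
                fh.write(
                    f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\tID={t.id}.exon{j};Parent={t.id}\n"
                )


def tss_of(t: TranscriptAnnotation) -> int:
    """5' end of a stranded annotation (internal 0-based position)."""
    iv = t.interval if isinstance(t, TranscriptAnnotation) else t
    if iv.strand == "+":
        return iv.start
    if iv.strand == "-":
        return iv.end - 1
    raise ValueError(f"record on {iv.chrom} has no strand; TSS undefined")


# ---------------------------------------------------------------------------
# chromosome sizes
# ---------------------------------------------------------------------------


def read_genome_table(path) -> GenomeTable:
    table = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            name, length = parts[0], int(parts[1])
            if name in table:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            table[name] = length
    return GenomeTable(table)


def write_genome_table(genome: GenomeTable, path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# region strings and prediction tables
# ---------------------------------------------------------------------------

_DASHES = re.compile("[‐‑‒–—−]")
_REGION = re.compile(
    r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)(?:\((?P<strand>[+-])\))?$"
)


def _normalize_dashes(s: str) -> str:
    return _DASHES.sub("-", s)


def parse_region(text: str, strand: str | None = None) -> GenomicInterval:
    """Parse ``chrom:start-end`` / ``chrom:start-end(strand)``, 1-based inclusive."""
    m = _REGION.match(_normalize_dashes(text.strip()))
    if not m:
        raise ValueError(f"unparseable genome coordinate string {text!r}")
    s = m.group("strand") or strand or "."
    return GenomicInterval(m.group("chrom"), int(m.group("start")) - 1, int(m.group("end")), s)


def format_region(iv: GenomicInterval, with_strand: bool = True) -> str:
    s = f"{iv.chrom}:{iv.start + 1}-{iv.end}"
    if with_strand and iv.strand != ".":
        s += f"({iv.strand})"
    return s


def _parse_tss_span(text: str, chrom: str, strand: str) -> GenomicInterval:
    """Parse a predicted-TSS span ``start-end`` (1-based half-open bin edges)."""
    m = re.match(r"^(\d+)-(\d+)$", _normalize_dashes(text.strip()))
    if not m:
        raise ValueError(f"unparseable TSS interval string {text!r}")
    s, e = int(m.group(1)), int(m.group(2))
    return GenomicInterval(chrom, s - 1, e - 1, strand)


def _format_tss_span(iv: GenomicInterval) -> str:
    return f"{iv.start + 1}-{iv.end + 1}"


def read_prediction_table(path) -> list[TssCall]:
    """Read a prediction table (published-table layout) into :class:`TssCall` records."""
    calls: list[TssCall] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header and header[0] and tuple(header) != PREDICTION_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(PREDICTION_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(PREDICTION_COLUMNS)} columns")
            (_, mid, name, mcoords, strand, tcoords, score, qvalue, category) = parts
            try:
                mirna = parse_region(mcoords, strand=strand)
                tss = _parse_tss_span(tcoords, mirna.chrom, mirna.strand)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno} ({mid}): {exc}") from exc
            calls.append(
                TssCall(
                    mirna_id=mid,
                    mirna_name=name,
                    mirna=mirna,
                    category=category or "independent",
                    tss=tss,
                    score=float(score) if score not in ("", "NA") else None,
                    qvalue=float(qvalue) if qvalue not in ("", "NA") else None,
                )
            )
    return calls


def _fmt_opt(x, digits=6) -> str:
    return "NA" if x is None else f"{x:.{digits}g}"


def write_prediction_table(calls: list[TssCall]) -> str:
    """Render calls as TSV text; inverse of :func:`read_prediction_table`.

    Calls without a predicted TSS (``category == 'none'``) are not rows of the
    published-table layout and are skipped.
    """
    lines = ["\t".join(PREDICTION_COLUMNS)]
    idx = 0
    for c in calls:
        if c.tss is None:
            continue
        idx += 1
        lines.append(
            "\t".join(
                [
                    str(idx),
                    c.mirna_id,
                    c.mirna_name,
                    format_region(c.mirna, with_strand=False),
                    c.mirna.strand,
                    _format_tss_span(c.tss),
                    _fmt_opt(c.score, 12),
                    _fmt_opt(c.qvalue, 12),
                    c.category,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def calls_to_bed(calls: list[TssCall]) -> str:
    """BED6 export of the called TSS bins."""
    rows = []
    for c in calls:
        if c.tss is None:
            continue
        score = 0 if c.score is None else c.score
        rows.append(
            f"{c.tss.chrom}\t{c.tss.start}\t{c.tss.end}\t{c.mirna_id}\t{score:.4f}\t{c.tss.strand}"
        )
    return "\n".join(rows) + ("\n" if rows else "")
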