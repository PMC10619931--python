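"""Readers and writers for the genomic formats the pipeline touches.

All coordinates are held 0-based half-open internally.  GTF is 1-based
closed on disk, so the reader/writer convert at the boundary; BED is
already 0-based half-open and passes through unchanged.  TE annotations
use the TEtranscripts attribute dialect (``gene_id`` = subfamily,
``transcript_id`` = element instance, ``family_id``, ``class_id``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import pysam

# SAM flag bits used throughout
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST_MATE = 0x40
FLAG_SECOND_MATE = 0x80
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


class FormatError(ValueError):
    """Malformed line in an annotation or alignment file."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A 0-based half-open interval on a contig, optionally stranded."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, slots=True)
class TEAnnotationRecord:
    """One annotated transposable-element copy."""

    interval: GenomicInterval
    element_id: str
    subfamily: str
    family: str = ""
    te_class: str = ""
    divergence: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.subfamily:
            raise ValueError("subfamily must be nonempty")

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(slots=True)
class AlignmentRecord:
    """One mapped read (or one reported hit of a multimapping read)."""

    read_id: str
    flag: int
    interval: GenomicInterval
    n_hits: int = 1
    mismatches: int = 0
    mapped_length: int = 0
    cell_barcode: Optional[str] = None
    umi: Optional[str] = None
    truth: Optional[object] = None

    def __post_init__(self) -> None:
        if self.n_hits < 1:
            raise ValueError("n_hits must be >= 1")
        if self.mapped_length and self.mismatches > self.mapped_length:
            raise ValueError("mismatches cannot exceed mapped length")
        if self.flag & FLAG_PAIRED:
            first = bool(self.flag & FLAG_FIRST_MATE)
            second = bool(self.flag & FLAG_SECOND_MATE)
            if first == second:
                raise ValueError(
                    "paired record must set exactly one of the mate bits"
                )

    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_first_mate(self) -> bool:
        return bool(self.flag & FLAG_FIRST_MATE)

    @property
    def is_second_mate(self) -> bool:
        return bool(self.flag & FLAG_SECOND_MATE)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    @property
    def is_primary(self) -> bool:
        return not (self.is_secondary or self.is_supplementary)


@dataclass(frozen=True, slots=True)
class TranscriptRecord:
    """An assembled transcript model; TSS is strand-dependent."""

    transcript_id: str
    interval: GenomicInterval
    exons: tuple = ()

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("transcript must be stranded")
        prev_end = None
        for exon in self.exons:
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ValueError("exon outside transcript span")
            if prev_end is not None and exon.start < prev_end:
                raise ValueError("exons must be ordered and non-overlapping")
            prev_end = exon.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Transcription start site: start on '+', end-1 on '-'."""
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True, slots=True)
class SequenceRecord:
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGTN"):
            raise ValueError("sequence must be uppercase over {A,C,G,T,N}")

    def __len__(self) -> int:
        return len(self.sequence)


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def _parse_gtf_attributes(text: str) -> dict:
    return dict(_GTF_ATTR.findall(text))


def read_te_annotation(path, dialect: str = "tetranscripts-gtf") -> list[TEAnnotationRecord]:
    """Read a TE annotation file into records.

    ``tetranscripts-gtf``: 1-based closed GTF with gene_id (subfamily),
    transcript_id (element instance), family_id, class_id attributes.
    ``repeatmasker-bed``: BED6 where the name column is the subfamily; the
    element_id is synthesised from name and coordinates.
    """
    if dialect not in ("tetranscripts-gtf", "repeatmasker-bed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[TEAnnotationRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "tetranscripts-gtf":
                    if len(fields) < 9:
                        raise FormatError("expected 9 tab-separated columns")
                    contig, _src, _feat, start, end, _score, strand, _frame, attrs = fields[:9]
                    attributes = _parse_gtf_attributes(attrs)
                    for required in ("gene_id", "transcript_id"):
                        if required not in attributes:
                            raise FormatError(f"missing required attribute {required}")
                    interval = GenomicInterval(
                        contig, int(start) - 1, int(end), strand if strand in "+-" else "."
                    )
                    div = attributes.get("divergence")
                    records.append(
                        TEAnnotationRecord(
                            interval=interval,
                            element_id=attributes["transcript_id"],
                            subfamily=attributes["gene_id"],
                            family=attributes.get("family_id", ""),
                            te_class=attributes.get("class_id", ""),
                            divergence=float(div) if div is not None else None,
                        )
                    )
                else:
                    if len(fields) < 6:
                        raise FormatError("expected at least 6 BED columns")
                    contig, start, end, name, _score, strand = fields[:6]
                    interval = GenomicInterval(
                        contig, int(start), int(end), strand if strand in "+-" else "."
                    )
                    records.append(
                        TEAnnotationRecord(
                            interval=interval,
                            element_id=f"{name}|{contig}:{start}-{end}",
                            subfamily=name,
                        )
                    )
            except (FormatError, ValueError) as exc:
                raise FormatError(f"{path}, line {lineno}: {exc}") from exc
    return records


def write_te_gtf(path, records: Iterable[TEAnnotationRecord]) -> None:
    """Write TE records as a TEtranscripts-dialect GTF (1-based closed)."""
    with open(path, "w") as fh:
        for rec in records:
            attrs = (
                f'gene_id "{rec.subfamily}"; transcript_id "{rec.element_id}"; '
                f'family_id "{rec.family}"; class_id "{rec.te_class}";'
            )
            if rec.divergence is not None:
                attrs += f' divergence "{rec.divergence:g}";'
            fh.write(
                "\t".join(
                    [
                        rec.interval.contig,
                        "l1locus",
                        "exon",
                        str(rec.interval.start + 1),
                        str(rec.interval.end),
                        ".",
                        rec.interval.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def filter_full_length(
    records: Sequence[TEAnnotationRecord],
    subfamilies: Optional[set] = None,
    min_len: int = 6000,
) -> list[TEAnnotationRecord]:
    """Keep elements of the given subfamilies strictly longer than min_len.

    Full-length L1s are defined as copies longer than 6 kbp: these retain
    the promoter-bearing 5'UTR.  The inequality is strict, so an element
    of exactly ``min_len`` bp is excluded.  Order is preserved.
    """
    if min_len <= 0:
        raise ValueError("min_len must be positive")
    return [
        rec
        for rec in records
        if rec.length > min_len
        and (subfamilies is None or rec.subfamily in subfamilies)
    ]


def read_transcript_gtf(path) -> list[TranscriptRecord]:
    """Read transcript models (``transcript`` + ``exon`` features) from GTF."""
    spans: dict[str, GenomicInterval] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}, line {lineno}: expected 9 columns")
            contig, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            attributes = _parse_gtf_attributes(attrs)
            tid = attributes.get("transcript_id")
            if tid is None:
                raise FormatError(f"{path}, line {lineno}: missing transcript_id")
            interval = GenomicInterval(contig, int(start) - 1, int(end), strand)
            if feature == "transcript":
                spans[tid] = interval
                order.append(tid)
            elif feature == "exon":
                exons.setdefault(tid, []).append(interval)
    out = []
    for tid in order:
        ex = tuple(sorted(exons.get(tid, [spans[tid]]), key=lambda iv: iv.start))
        out.append(TranscriptRecord(transcript_id=tid, interval=spans[tid], exons=ex))
    return out


def write_transcript_gtf(path, transcripts: Iterable[TranscriptRecord]) -> None:
    with open(path, "w") as fh:
        for tr in transcripts:
            attrs = f'transcript_id "{tr.transcript_id}";'
            base = [
                tr.interval.contig,
                "l1locus",
                "transcript",
                str(tr.interval.start + 1),
                str(tr.interval.end),
                ".",
                tr.strand,
                ".",
                attrs,
            ]
            fh.write("\t".join(base) + "\n")
            for exon in tr.exons or (tr.interval,):
                row = list(base)
                row[2] = "exon"
                row[3] = str(exon.start + 1)
                row[4] = str(exon.end)
                fh.write("\t".join(row) + "\n")


def read_fasta(path) -> dict[str, SequenceRecord]:
    from Bio import SeqIO

    return {
        rec.id: SequenceRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path, sequences: Iterable[SequenceRecord], width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in sequences:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _record_from_pysam(
    aln: pysam.AlignedSegment, cb_tag: str, ub_tag: str
) -> AlignmentRecord:
    end = aln.reference_end
    if end is None or end <= aln.reference_start:
        end = aln.reference_start + max(aln.query_length or 1, 1)
    mapped_length = aln.query_alignment_length or (end - aln.reference_start)
    return AlignmentRecord(
        read_id=aln.query_name,
        flag=aln.flag,
        interval=GenomicInterval(
            aln.reference_name,
            aln.reference_start,
            end,
            "-" if aln.is_reverse else "+",
        ),
        n_hits=aln.get_tag("NH") if aln.has_tag("NH") else 1,
        mismatches=aln.get_tag("NM") if aln.has_tag("NM") else 0,
        mapped_length=mapped_length,
        cell_barcode=aln.get_tag(cb_tag) if aln.has_tag(cb_tag) else None,
        umi=aln.get_tag(ub_tag) if aln.has_tag(ub_tag) else None,
    )


def read_alignments(
    path,
    region: Optional[GenomicInterval] = None,
    include_secondary: bool = False,
    cb_tag: str = "CB",
    ub_tag: str = "UB",
) -> Iterator[AlignmentRecord]:
    """Stream mapped records from SAM/BAM as AlignmentRecords.

    Secondary and supplementary records are excluded by default; pass
    ``include_secondary=True`` when multimapping hits are wanted (EM
    assignment).  CB/UB/NH/NM tags are surfaced when present; the tag
    names are configurable because upstream tools differ.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        if region is not None:
            if not fh.has_index():
                raise ValueError("region query requires an indexed file")
            if region.contig not in fh.references:
                raise ValueError(f"unknown contig {region.contig!r}")
            it = fh.fetch(region.contig, region.start, region.end)
        else:
            it = fh.fetch(until_eof=True)
        for aln in it:
            if aln.is_unmapped:
                continue
            if not include_secondary and (aln.is_secondary or aln.is_supplementary):
                continue
            yield _record_from_pysam(aln, cb_tag, ub_tag)


def write_alignments(
    path,
    records: Sequence[AlignmentRecord],
    contig_lengths: dict[str, int],
    cb_tag: str = "CB",
    ub_tag: str = "UB",
) -> None:
    """Write records as SAM (sequence-less; all fields used downstream kept)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": name, "LN": length} for name, length in contig_lengths.items()
        ],
    }
    contig_rank = {name: i for i, name in enumerate(contig_lengths)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for rec in sorted(
            records,
            key=lambda r: (contig_rank[r.interval.contig], r.interval.start, r.read_id, r.flag),
        ):
            aln = pysam.AlignedSegment(fh.header)
            aln.query_name = rec.read_id
            aln.flag = rec.flag
            aln.reference_name = rec.interval.contig
            aln.reference_start = rec.interval.start
            aln.mapping_quality = 255
            aln.cigarstring = f"{rec.interval.length}M"
            tags = [("NH", rec.n_hits), ("NM", rec.mismatches)]
            if rec.cell_barcode is not None:
                tags.append((cb_tag, rec.cell_barcode))
            if rec.umi is not None:
                tags.append((ub_tag, rec.umi))
            aln.set_tags(tags)
            fh.write(aln)
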