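"""L1-chimeric transcript detection and interval association.

A chimeric transcript is one whose transcription start site lies inside
(or within 100 bp of) a full-length L1 on the opposite strand — the
signature of the L1 antisense promoter driving transcription into
flanking sequence.  The calling chain is: collapse duplicate assembled
transcripts and drop short ones, build TSS windows, intersect them with
full-length elements requiring opposing strands, then keep candidates
whose normalized expression clears a threshold in at least one unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GenomicInterval, TEAnnotationRecord, TranscriptRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class ChimeraCall:
    transcript_id: str
    element_id: str
    subfamily: str
    transcript_strand: str
    element_strand: str
    tss_window: GenomicInterval
    expression: dict
    expressed_units: tuple
    expressed: bool


def dedup_and_filter_transcripts(
    transcripts: Sequence[TranscriptRecord],
    min_len: int = 1000,
) -> list[TranscriptRecord]:
    """Collapse identical transcript features and drop short ones.

    Transcripts sharing (contig, start, end, strand) are collapsed to
    the first occurrence; a transcript is retained only if its span is
    strictly longer than ``min_len`` (a 1000-bp transcript is excluded
    at the default).
    """
    seen: set = set()
    out: list[TranscriptRecord] = []
    for tr in transcripts:
        key = (tr.interval.contig, tr.interval.start, tr.interval.end, tr.strand)
        if key in seen:
            continue
        seen.add(key)
        if tr.length > min_len:
            out.append(tr)
    return out


def tss_windows(
    transcripts: Sequence[TranscriptRecord],
    flank: int = 100,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> dict[str, GenomicInterval]:
    """TSS +/- ``flank`` bp windows, half-open, clipped to contig bounds.

    The TSS is the interval start for '+' transcripts and end-1 for '-'
    transcripts; the window covers the TSS base plus ``flank`` bases on
    each side, i.e. [tss - flank, tss + flank + 1).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    windows: dict[str, GenomicInterval] = {}
    for tr in transcripts:
        start = max(0, tr.tss - flank)
        end = tr.tss + flank + 1
        if contig_lengths is not None and tr.interval.contig in contig_lengths:
            end = min(end, contig_lengths[tr.interval.contig])
        windows[tr.transcript_id] = GenomicInterval(
            tr.interval.contig, start, end, tr.strand
        )
    return windows


def intersect_antisense(
    windows: Mapping[str, GenomicInterval],
    full_length_l1s: Sequence[TEAnnotationRecord],
) -> list[tuple[str, str]]:
    """(transcript, element) pairs where a TSS window overlaps an
    opposite-strand full-length element by >= 1 bp.

    The element list is expected to be pre-filtered to full length.
    The result is sorted, hence independent of input ordering.
    """
    trees: dict[str, IntervalTree] = {}
    for rec in full_length_l1s:
        trees.setdefault(rec.interval.contig, IntervalTree()).addi(
            rec.interval.start, rec.interval.end, rec
        )
    pairs: list[tuple[str, str]] = []
    for tid, window in windows.items():
        tree = trees.get(window.contig)
        if tree is None:
            continue
        for iv in tree.overlap(window.start, window.end):
            element = iv.data
            if element.strand in ("+", "-") and element.strand != window.strand:
                pairs.append((tid, element.element_id))
    return sorted(pairs)


def call_expressed_chimeras(
    candidates: Sequence[tuple[str, str]],
    transcript_normalized_counts: pd.DataFrame,
    transcripts: Mapping[str, TranscriptRecord],
    elements: Mapping[str, TEAnnotationRecord],
    windows: Mapping[str, GenomicInterval],
    threshold: float = 20.0,
) -> list[ChimeraCall]:
    """Annotate candidate pairs with expression and call expressed chimeras.

    A transcript is considered expressed in a unit when its normalized
    count strictly exceeds ``threshold`` there; the chimera call is
    positive when this holds in at least one unit, and the per-unit
    table is carried along in the call.
    """
    calls: list[ChimeraCall] = []
    for tid, eid in candidates:
        if tid not in transcript_normalized_counts.index:
            raise ValueError(f"transcript {tid!r} absent from the count matrix")
        row = transcript_normalized_counts.loc[tid]
        expressed_units = tuple(u for u, v in row.items() if v > threshold)
        calls.append(
            ChimeraCall(
                transcript_id=tid,
                element_id=eid,
                subfamily=elements[eid].subfamily,
                transcript_strand=transcripts[tid].strand,
                element_strand=elements[eid].strand,
                tss_window=windows[tid],
                expression={u: float(v) for u, v in row.items()},
                expressed_units=expressed_units,
                expressed=len(expressed_units) > 0,
            )
        )
    return calls


def chimera_table(calls: Sequence[ChimeraCall]) -> pd.DataFrame:
    """Flat table of chimera calls (one row per transcript-element pair)."""
    rows = []
    for call in calls:
        row = {
            "transcript_id": call.transcript_id,
            "element_id": call.element_id,
            "subfamily": call.subfamily,
            "transcript_strand": call.transcript_strand,
            "element_strand": call.element_strand,
            "window": f"{call.tss_window.contig}:{call.tss_window.start}-{call.tss_window.end}",
            "expressed": call.expressed,
        }
        for unit, value in call.expression.items():
            row[f"norm_{unit}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def intersect_peaks_with_elements(
    peaks: Sequence[GenomicInterval],
    elements: Sequence[TEAnnotationRecord],
) -> list[tuple[int, str]]:
    """Any-overlap, strand-agnostic (peak index, element_id) pairs.

    Intervals are half-open, so abutting features do not overlap.  Each
    overlapping pair is listed exactly once.
    """
    trees: dict[str, IntervalTree] = {}
    for rec in elements:
        trees.setdefault(rec.interval.contig, IntervalTree()).addi(
            rec.interval.start, rec.interval.end, rec.element_id
        )
    pairs: list[tuple[int, str]] = []
    for i, peak in enumerate(peaks):
        tree = trees.get(peak.contig)
        if tree is None:
            continue
        for iv in tree.overlap(peak.start, peak.end):
            pairs.append((i, iv.data))
    return sorted(set(pairs))


def read_peaks_bed(path) -> list[GenomicInterval]:
    """Read peak intervals from BED (3+ columns)."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}, line {lineno}: expected >= 3 BED columns")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            peaks.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return peaks
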