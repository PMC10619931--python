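"""Promoter-sequence analyses and coverage meta-profiles.

The L1 5'UTR carries a bidirectional promoter.  Sense activity depends
on a YY1 binding site in the first 100 bp of the element; the antisense
promoter drives a small peptide (ORF0) whose start codon can be lost by
point mutation (the M1T change).  This module scans oriented element
prefixes for the exact YY1 motif, checks ORF0 start-codon intactness,
and builds strand-resolved binned coverage matrices over elements with
flanking regions for meta-profile heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .io_formats import (
    AlignmentRecord,
    GenomicInterval,
    SequenceRecord,
    TEAnnotationRecord,
)

YY1_MOTIF = "CAAGATGGCCG"

_CODON_TO_AA = {
    "ATG": "Met",
    "ACG": "Thr",
    "GTG": "Val",
}


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True, slots=True)
class MotifHit:
    element_id: str
    present: bool
    offset: Optional[int] = None


def extract_element_prefix(
    genome: Mapping[str, SequenceRecord],
    element: TEAnnotationRecord,
    n: int = 100,
) -> str:
    """The first ``n`` bases of an element in its own 5'->3' orientation.

    For '+' elements this is the genomic sequence at the element start;
    for '-' elements it is the reverse complement of the last ``n``
    genomic bases.  Elements shorter than ``n`` return their full
    oriented sequence.
    """
    contig = element.interval.contig
    if contig not in genome:
        raise KeyError(f"contig {contig!r} absent from genome")
    seq = genome[contig].sequence
    n = min(n, element.length)
    if element.strand == "-":
        return reverse_complement(seq[element.interval.end - n : element.interval.end])
    return seq[element.interval.start : element.interval.start + n]


def scan_yy1(
    prefixes: Mapping[str, str],
    motif: str = YY1_MOTIF,
) -> tuple[list[MotifHit], dict]:
    """Exact-match scan for the YY1 motif within element prefixes.

    A hit requires the motif to occur as an exact substring lying fully
    within the prefix (a match overhanging the prefix end does not
    count).  Returns per-element hits and summary counts.
    """
    if not motif or motif != motif.upper():
        raise ValueError("motif must be a nonempty uppercase string")
    hits: list[MotifHit] = []
    for element_id, prefix in prefixes.items():
        offset = prefix.find(motif)
        if offset >= 0:
            hits.append(MotifHit(element_id, True, offset))
        else:
            hits.append(MotifHit(element_id, False))
    n_present = sum(h.present for h in hits)
    summary = {"n_present": n_present, "n_absent": len(hits) - n_present}
    return hits, summary


def motif_table(
    hits: Sequence[MotifHit],
    annotation: Optional[Sequence[TEAnnotationRecord]] = None,
    detection: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Motif report, optionally stratified by a detection-call table."""
    df = pd.DataFrame(
        [{"element_id": h.element_id, "present": h.present, "offset": h.offset} for h in hits]
    )
    if annotation is not None:
        subfam = {rec.element_id: rec.subfamily for rec in annotation}
        df["subfamily"] = df["element_id"].map(subfam)
    if detection is not None:
        det = detection.groupby("element_id")["detected"].any()
        df["detected"] = df["element_id"].map(det).fillna(False)
    return df


def check_orf0_start(promoter_sequence: str, orf0_offset: int) -> tuple[str, str]:
    """Classify the ORF0 start codon in an antisense-promoter sequence.

    Returns (status, amino_acid): ``("intact", "Met")`` when the codon
    at ``orf0_offset`` is ATG, otherwise ``("disrupted", <aa>)`` with
    the amino acid the observed codon encodes (e.g. the M1T mutation
    yields ACG -> Thr).
    """
    if orf0_offset < 0 or orf0_offset + 3 > len(promoter_sequence):
        raise ValueError("ORF0 codon truncated or out of bounds")
    codon = promoter_sequence[orf0_offset : orf0_offset + 3]
    if codon == "ATG":
        return "intact", "Met"
    aa = _CODON_TO_AA.get(codon)
    if aa is None:
        aa = str(Seq(codon).translate())
    return "disrupted", aa


def count_reads_in_region(
    alignments: Iterable[AlignmentRecord],
    region: GenomicInterval,
) -> int:
    """Primary records overlapping the (half-open) region by >= 1 bp."""
    return sum(
        1
        for rec in alignments
        if rec.is_primary and rec.interval.overlaps(region)
    )


def _element_bin_edges(
    element: TEAnnotationRecord, flank: int, body_bins: int, flank_bin: int
) -> np.ndarray:
    """Absolute genomic bin edges: upstream flank, body, downstream flank.

    Flanks are binned at fixed ``flank_bin`` bp; the body is rescaled to
    ``body_bins`` bins.  Edges are in genomic orientation; rows of '-'
    elements are reversed afterwards so everything reads 5'->3'.
    """
    n_flank_bins = flank // flank_bin
    start, end = element.interval.start, element.interval.end
    left = start - flank + flank_bin * np.arange(n_flank_bins + 1)
    body = np.linspace(start, end, body_bins + 1)
    right = end + flank_bin * np.arange(n_flank_bins + 1)
    return np.concatenate([left[:-1], body, right[1:]]).astype(float)


def coverage_matrix(
    alignments: Sequence[AlignmentRecord],
    elements: Sequence[TEAnnotationRecord],
    contig_lengths: Mapping[str, int],
    flank: int = 6000,
    body_bins: int = 60,
    flank_bin: int = 100,
    normalization: str = "raw",
    total_mapped: Optional[int] = None,
) -> tuple[np.ndarray, list[str]]:
    """Binned read-count matrix over elements plus flanking regions.

    One row per element, oriented 5'->3' (rows of '-' elements are
    reversed); columns are upstream-flank bins, ``body_bins`` rescaled
    body bins, then downstream-flank bins.  A read contributes to every
    bin it overlaps.  Bins extending beyond contig bounds are missing
    (NaN), which is distinct from zero coverage.  ``normalization``:
    ``"raw"`` leaves read counts; ``"RPKM"`` divides by bin length in kb
    times total mapped reads in millions (``total_mapped`` defaults to
    the number of primary records supplied).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if body_bins < 1:
        raise ValueError("body_bins must be >= 1")
    if flank_bin <= 0:
        raise ValueError("flank_bin must be positive")
    if normalization not in ("raw", "RPKM"):
        raise ValueError(f"unknown normalization {normalization!r}")

    primaries = [rec for rec in alignments if rec.is_primary]
    if total_mapped is None:
        total_mapped = len(primaries)

    n_flank_bins = flank // flank_bin
    n_cols = 2 * n_flank_bins + body_bins
    matrix = np.zeros((len(elements), n_cols))

    # index reads by contig for the per-element span query
    read_tree: dict[str, IntervalTree] = {}
    for rec in primaries:
        read_tree.setdefault(rec.interval.contig, IntervalTree()).addi(
            rec.interval.start, rec.interval.end
        )

    for row, element in enumerate(elements):
        edges = _element_bin_edges(element, flank, body_bins, flank_bin)
        contig_len = contig_lengths[element.interval.contig]
        span_start, span_end = edges[0], edges[-1]
        tree = read_tree.get(element.interval.contig)
        if tree is not None:
            for iv in tree.overlap(span_start, span_end):
                # bins overlapped by [iv.begin, iv.end): half-open on both sides
                first = int(np.searchsorted(edges, iv.begin, side="right")) - 1
                last = int(np.searchsorted(edges, iv.end, side="left")) - 1
                first = max(first, 0)
                last = min(last, n_cols - 1)
                if first <= last:
                    matrix[row, first : last + 1] += 1
        if normalization == "RPKM":
            lengths_kb = np.diff(edges) / 1000.0
            denom = lengths_kb * (total_mapped / 1e6 if total_mapped else np.nan)
            with np.errstate(divide="ignore", invalid="ignore"):
                matrix[row] = np.where(denom > 0, matrix[row] / denom, np.nan)
        # bins not fully inside the contig are missing, not zero
        out_of_bounds = (edges[:-1] < 0) | (edges[1:] > contig_len)
        matrix[row, out_of_bounds] = np.nan
        if element.strand == "-":
            matrix[row] = matrix[row][::-1]

    return matrix, [el.element_id for el in elements]


def sense_antisense_profiles(
    forward_set: Sequence[AlignmentRecord],
    reverse_set: Sequence[AlignmentRecord],
    elements: Sequence[TEAnnotationRecord],
    contig_lengths: Mapping[str, int],
    **kwargs,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Sense and antisense coverage matrices over stranded elements.

    Four matrices are built — transcription strand x element strand —
    and concatenated so that each output matrix has one row per element
    in input order: the sense matrix takes forward transcription over
    '+' elements and reverse transcription over '-' elements; the
    antisense matrix takes the opposite combinations.
    """
    plus = [el for el in elements if el.strand == "+"]
    minus = [el for el in elements if el.strand == "-"]
    total = len(forward_set) + len(reverse_set)
    kwargs.setdefault("total_mapped", total)

    sense_plus, _ = coverage_matrix(forward_set, plus, contig_lengths, **kwargs)
    sense_minus, _ = coverage_matrix(reverse_set, minus, contig_lengths, **kwargs)
    anti_plus, _ = coverage_matrix(reverse_set, plus, contig_lengths, **kwargs)
    anti_minus, _ = coverage_matrix(forward_set, minus, contig_lengths, **kwargs)

    order = {el.element_id: i for i, el in enumerate(elements)}
    n_cols = sense_plus.shape[1] if len(plus) else sense_minus.shape[1]
    sense = np.zeros((len(elements), n_cols))
    antisense = np.zeros((len(elements), n_cols))
    for i, el in enumerate(plus):
        sense[order[el.element_id]] = sense_plus[i]
        antisense[order[el.element_id]] = anti_plus[i]
    for i, el in enumerate(minus):
        sense[order[el.element_id]] = sense_minus[i]
        antisense[order[el.element_id]] = anti_minus[i]
    return sense, antisense, [el.element_id for el in elements]
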