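"""Quantification core for TE expression.

Implements the unique-mapping element-level counting with the mismatch
filter, the SAM-flag partition of paired reads into forward/reverse
transcription, element-relative sense/antisense counting, and an EM
assignment of multimapping reads to TE subfamilies.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import (
    FLAG_FIRST_MATE,
    FLAG_REVERSE,
    FLAG_SECOND_MATE,
    AlignmentRecord,
    TEAnnotationRecord,
)

logger = logging.getLogger(__name__)


def build_feature_trees(
    annotation: Sequence[TEAnnotationRecord],
) -> dict[str, IntervalTree]:
    """Interval trees per contig, payload = annotation record."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for rec in annotation:
        trees[rec.interval.contig].addi(rec.interval.start, rec.interval.end, rec)
    return dict(trees)


def split_by_transcription_strand(
    alignments: Iterable[AlignmentRecord],
    single_end_rule: bool = False,
) -> tuple[list[AlignmentRecord], list[AlignmentRecord]]:
    """Partition records by the strand of the transcript they came from.

    For a reverse-stranded paired-end library the transcribed strand is
    recovered from the flag bits alone:

    * forward transcription: second mate mapped forward, or first mate
      mapped reverse (samtools ``-f 128 -F 16`` and ``-f 80``);
    * reverse transcription: second mate mapped reverse, or first mate
      mapped forward (``-f 144`` and ``-f 64 -F 16``).

    The two sets partition the input exactly.  Unpaired records are only
    accepted when ``single_end_rule`` is set, in which case the same
    chemistry is assumed (a reverse-strand alignment is forward
    transcription); otherwise an unpaired record raises.
    """
    forward: list[AlignmentRecord] = []
    reverse: list[AlignmentRecord] = []
    for rec in alignments:
        if not rec.is_paired:
            if not single_end_rule:
                raise ValueError(
                    f"unpaired record {rec.read_id!r}; enable single_end_rule "
                    "to route single-end data"
                )
            logger.warning("routing unpaired record %s by single-end rule", rec.read_id)
            (forward if rec.flag & FLAG_REVERSE else reverse).append(rec)
            continue
        second = bool(rec.flag & FLAG_SECOND_MATE)
        is_rev = bool(rec.flag & FLAG_REVERSE)
        first = bool(rec.flag & FLAG_FIRST_MATE)
        if (second and not is_rev) or (first and is_rev):
            forward.append(rec)
        else:
            reverse.append(rec)
    return forward, reverse


def count_unique_elements(
    alignments: Iterable[AlignmentRecord],
    annotation: Sequence[TEAnnotationRecord],
    strandness: str = "unstranded",
    max_mismatch_ratio: float = 0.03,
    transcription_strand: Optional[str] = None,
) -> tuple[pd.Series, dict]:
    """Count uniquely mapping reads per element.

    Only primary records with ``n_hits == 1`` and a mismatch-to-mapped-
    length ratio of at most ``max_mismatch_ratio`` are counted.  A record
    is assigned to a feature it overlaps by >= 1 bp; a record overlapping
    two or more distinct features is discarded as ambiguous.

    ``strandness="reverse-forced"`` restricts countable features to the
    strand matching ``transcription_strand`` — i.e. sense counting of a
    pre-split transcription-strand set.  ``"unstranded"`` counts against
    all features; directional sense/antisense tables are then assembled
    by :func:`count_sense_antisense` from two directional runs.

    Returns a counts Series indexed by element_id (full feature index,
    zeros included) and a report dict of filtered/dropped record counts.
    """
    if not (0.0 <= max_mismatch_ratio <= 1.0):
        raise ValueError("max_mismatch_ratio must be in [0, 1]")
    if strandness not in ("unstranded", "reverse-forced"):
        raise ValueError(f"unknown strandness {strandness!r}")
    if strandness == "reverse-forced" and transcription_strand not in ("+", "-"):
        raise ValueError("reverse-forced counting needs transcription_strand '+' or '-'")

    trees = build_feature_trees(annotation)
    counts = {rec.element_id: 0 for rec in annotation}
    report = {
        "counted": 0,
        "ambiguous": 0,
        "unassigned": 0,
        "filtered_multimap": 0,
        "filtered_mismatch": 0,
        "filtered_secondary": 0,
    }
    for rec in alignments:
        if not rec.is_primary:
            report["filtered_secondary"] += 1
            continue
        if rec.n_hits != 1:
            report["filtered_multimap"] += 1
            continue
        denom = rec.mapped_length or rec.interval.length
        if denom and rec.mismatches / denom > max_mismatch_ratio:
            report["filtered_mismatch"] += 1
            continue
        tree = trees.get(rec.interval.contig)
        hits = (
            {
                iv.data.element_id: iv.data
                for iv in tree.overlap(rec.interval.start, rec.interval.end)
            }
            if tree is not None
            else {}
        )
        if strandness == "reverse-forced":
            hits = {
                eid: feat
                for eid, feat in hits.items()
                if feat.strand == transcription_strand
            }
        if len(hits) == 0:
            report["unassigned"] += 1
        elif len(hits) == 1:
            counts[next(iter(hits))] += 1
            report["counted"] += 1
        else:
            report["ambiguous"] += 1
    series = pd.Series(counts, dtype=np.int64)
    series.index.name = "element_id"
    return series, report


def count_sense_antisense(
    forward_counts: pd.Series,
    reverse_counts: pd.Series,
    annotation: Sequence[TEAnnotationRecord],
) -> pd.DataFrame:
    """Element-relative sense/antisense counts from directional counts.

    Sense is forward-transcription counts on '+' features and reverse-
    transcription counts on '-' features; antisense is the converse.
    Unstranded ('.') features are excluded and logged.
    """
    rows = []
    for rec in annotation:
        if rec.strand == ".":
            logger.warning("excluding unstranded feature %s", rec.element_id)
            continue
        fwd = int(forward_counts.get(rec.element_id, 0))
        rev = int(reverse_counts.get(rec.element_id, 0))
        sense, antisense = (fwd, rev) if rec.strand == "+" else (rev, fwd)
        rows.append(
            {
                "element_id": rec.element_id,
                "subfamily": rec.subfamily,
                "strand": rec.strand,
                "sense": sense,
                "antisense": antisense,
            }
        )
    return pd.DataFrame(
        rows, columns=["element_id", "subfamily", "strand", "sense", "antisense"]
    ).set_index("element_id")


def aggregate_subfamily_strand(
    stranded: pd.DataFrame,
    subset: Optional[set] = None,
) -> pd.DataFrame:
    """Sum sense/antisense counts per subfamily.

    ``subset`` restricts the aggregation to the given element_ids (used
    to sum over full-length elements of the young subfamilies only).
    Sense is element-relative, so the sums do not depend on the strand
    composition of the subfamily.
    """
    df = stranded if subset is None else stranded.loc[stranded.index.isin(subset)]
    out = df.groupby("subfamily")[["sense", "antisense"]].sum()
    return out.rename(columns={"sense": "sense_sum", "antisense": "antisense_sum"})


def em_assign_multireads(
    alignments: Iterable[AlignmentRecord],
    annotation: Sequence[TEAnnotationRecord],
    max_iter: int = 100,
    tol: float = 1e-4,
    trace: Optional[list] = None,
) -> tuple[pd.Series, dict]:
    """EM assignment of multimapping reads to TE subfamilies.

    Records are grouped by read id (mates and secondary hits together);
    a read's candidate set is the set of subfamilies its reported hits
    overlap.  Uniquely assignable reads contribute unit mass to their
    subfamily; each ambiguous read's unit mass is split over its
    candidates proportionally to the current subfamily abundances
    (uniform initialisation).  Iteration stops when the largest absolute
    change in relative abundance drops below ``tol`` or after
    ``max_iter`` rounds.  Total assigned mass equals the number of reads
    with at least one TE-overlapping hit.

    ``trace``, if a list, receives the per-subfamily count vector after
    every iteration (mass is conserved at each one).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")

    trees = build_feature_trees(annotation)
    subfamilies = sorted({rec.subfamily for rec in annotation})
    sub_index = {name: i for i, name in enumerate(subfamilies)}
    k = len(subfamilies)

    candidates: dict[str, set[int]] = defaultdict(set)
    for rec in alignments:
        if rec.is_supplementary:
            continue
        cand = candidates[rec.read_id]  # register the read even without hits
        tree = trees.get(rec.interval.contig)
        if tree is None:
            continue
        for iv in tree.overlap(rec.interval.start, rec.interval.end):
            cand.add(sub_index[iv.data.subfamily])

    unique = np.zeros(k)
    # compress ambiguous reads by identical candidate sets
    multi: dict[frozenset, int] = defaultdict(int)
    n_assigned = 0
    n_no_candidate = 0
    for _read_id, cand in candidates.items():
        if not cand:
            n_no_candidate += 1
            continue
        n_assigned += 1
        if len(cand) == 1:
            unique[next(iter(cand))] += 1
        else:
            multi[frozenset(cand)] += 1

    counts = unique.copy()
    if multi:
        # uniform initialisation of the ambiguous mass
        for cand, m in multi.items():
            share = m / len(cand)
            for s in cand:
                counts[s] += share
    if trace is not None:
        trace.append(pd.Series(counts, index=subfamilies))

    n_iter = 0
    if multi and n_assigned > 0:
        abundance = counts / n_assigned
        multi_sets = [(np.fromiter(c, dtype=int), m) for c, m in multi.items()]
        for n_iter in range(1, max_iter + 1):
            counts = unique.copy()
            for cand, m in multi_sets:
                weights = abundance[cand]
                total = weights.sum()
                if total <= 0:
                    counts[cand] += m / len(cand)
                else:
                    counts[cand] += m * weights / total
            new_abundance = counts / n_assigned
            if trace is not None:
                trace.append(pd.Series(counts, index=subfamilies))
            delta = np.abs(new_abundance - abundance).max()
            abundance = new_abundance
            if delta < tol:
                break

    series = pd.Series(counts, index=subfamilies, dtype=float)
    series.index.name = "subfamily"
    report = {
        "n_reads_assigned": n_assigned,
        "n_reads_no_te_candidate": n_no_candidate,
        "n_ambiguous_reads": int(sum(multi.values())),
        "n_iterations": n_iter,
    }
    return series, report
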