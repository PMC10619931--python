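"""End-to-end drivers composing the pipeline stages.

These functions wire the stages together the way the analyses run them:
QC -> barcode back-tracing -> UMI dedup -> sample merge -> per-cluster
counting -> gene-factor normalization -> detection calling on the
single-nucleus side, and strand splitting -> element counting ->
sense/antisense tables -> chimera calling on the bulk side.  They are
shared by the numbered analysis scripts, the test suite and the
acceptance script so that every consumer exercises the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import chimera as chimera_mod
from . import normalize as norm_mod
from . import pseudobulk as pb
from . import te_quant as tq
from .io_formats import AlignmentRecord, TEAnnotationRecord, TranscriptRecord
from .synthetic_data import YOUNG_SUBFAMILIES, SimReads


def transcript_features(
    transcripts: Sequence[TranscriptRecord],
) -> list[TEAnnotationRecord]:
    """Transcript spans as countable features (ids = transcript ids)."""
    return [
        TEAnnotationRecord(interval=tr.interval, element_id=tr.transcript_id, subfamily=tr.transcript_id)
        for tr in transcripts
    ]


@dataclass
class PseudobulkResult:
    merged: dict[str, list[AlignmentRecord]]
    te_counts: pd.DataFrame  # elements x clusters, raw unique counts
    gene_counts: pd.DataFrame  # genes x clusters
    size_factors: pd.Series
    normalized: pd.DataFrame
    n_cells_kept: int
    reports: dict


def run_pseudobulk(sim: SimReads, qc_mode: str = "fetal") -> PseudobulkResult:
    """QC, back-trace, dedup and merge; count and normalize per cluster."""
    kept = pb.qc_filter_cells(sim.qc_metrics, mode=qc_mode)
    per_sample: dict[str, dict[str, list[AlignmentRecord]]] = {}
    reports: dict = {"assign": {}, "dedup": {}}
    for sample, records in sim.single_nucleus.items():
        kept_here = {bc for s, bc in kept if s == sample}
        cmap = sim.cluster_maps[sample].restrict(kept_here)
        primaries = [r for r in records if r.is_primary]
        collections, assign_report = pb.assign_reads_to_clusters(primaries, cmap)
        reports["assign"][sample] = assign_report
        deduped = {}
        for cluster, recs in collections.items():
            deduped[cluster], dd_report = pb.dedup_umis(recs)
            reports["dedup"][(sample, cluster)] = dd_report
        per_sample[sample] = deduped

    labels = [c.cluster_id for c in sim.genome.config.clusters]
    merged = pb.merge_samples(per_sample, labels=labels)

    te_cols, gene_cols = {}, {}
    gene_features = sim.genome.gene_features()
    for cluster, recs in merged.items():
        te_cols[cluster], _ = tq.count_unique_elements(recs, sim.genome.te_records)
        gene_cols[cluster], _ = tq.count_unique_elements(recs, gene_features)
    te_counts = pd.DataFrame(te_cols)
    gene_counts = pd.DataFrame(gene_cols)
    factors = norm_mod.size_factors_median_of_ratios(gene_counts)
    normalized = norm_mod.normalize_counts(te_counts, factors)
    return PseudobulkResult(
        merged=merged,
        te_counts=te_counts,
        gene_counts=gene_counts,
        size_factors=factors,
        normalized=normalized,
        n_cells_kept=len(kept),
        reports=reports,
    )


def detect_full_length_elements(
    result: PseudobulkResult,
    annotation: Sequence[TEAnnotationRecord],
    groups: Optional[Mapping[str, str]] = None,
    threshold: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detection calls over a full-length element universe, per cluster."""
    ids = [rec.element_id for rec in annotation]
    sub = result.normalized.loc[[i for i in ids if i in result.normalized.index]]
    if groups is None:
        groups = {unit: unit for unit in sub.columns}
    return norm_mod.call_detected_elements(sub, groups, annotation, threshold)


@dataclass
class BulkStrandResult:
    stranded: dict[str, pd.DataFrame]  # per sample: element sense/antisense
    subfamily: dict[str, pd.DataFrame]  # per sample: subfamily sums (full-length young)


def bulk_sense_antisense(
    sim: SimReads,
    full_length_subset: Optional[set] = None,
) -> BulkStrandResult:
    """Directional element counts and subfamily sense/antisense sums per sample."""
    if full_length_subset is None:
        full_length_subset = {rec.element_id for rec in sim.genome.full_length_young()}
    stranded, subfam = {}, {}
    for sample, records in sim.bulk.items():
        primaries = [r for r in records if r.is_primary]
        forward, reverse = tq.split_by_transcription_strand(primaries)
        fwd_counts, _ = tq.count_unique_elements(forward, sim.genome.te_records)
        rev_counts, _ = tq.count_unique_elements(reverse, sim.genome.te_records)
        stranded[sample] = tq.count_sense_antisense(
            fwd_counts, rev_counts, sim.genome.te_records
        )
        subfam[sample] = tq.aggregate_subfamily_strand(
            stranded[sample], subset=full_length_subset
        )
    return BulkStrandResult(stranded=stranded, subfamily=subfam)


@dataclass
class ChimeraResult:
    candidates: list
    calls: list
    normalized_tx: pd.DataFrame
    windows: dict


def run_chimera_analysis(sim: SimReads, threshold: float = 20.0) -> ChimeraResult:
    """Chimera calling from the assembled transcript set and bulk counts."""
    genome = sim.genome
    kept_tx = chimera_mod.dedup_and_filter_transcripts(genome.transcripts)
    windows = chimera_mod.tss_windows(kept_tx, contig_lengths=genome.contig_lengths)
    fl_young = genome.full_length_young()
    candidates = chimera_mod.intersect_antisense(windows, fl_young)

    tx_features = transcript_features(kept_tx)
    gene_features = genome.gene_features()
    tx_cols, gene_cols = {}, {}
    for sample, records in sim.bulk.items():
        primaries = [r for r in records if r.is_primary]
        forward, reverse = tq.split_by_transcription_strand(primaries)
        plus, _ = tq.count_unique_elements(
            forward, tx_features, strandness="reverse-forced", transcription_strand="+"
        )
        minus, _ = tq.count_unique_elements(
            reverse, tx_features, strandness="reverse-forced", transcription_strand="-"
        )
        tx_cols[sample] = plus + minus
        gene_cols[sample], _ = tq.count_unique_elements(primaries, gene_features)
    tx_counts = pd.DataFrame(tx_cols)
    factors = norm_mod.size_factors_median_of_ratios(pd.DataFrame(gene_cols))
    normalized_tx = norm_mod.normalize_counts(tx_counts, factors)

    calls = chimera_mod.call_expressed_chimeras(
        candidates,
        normalized_tx,
        transcripts={tr.transcript_id: tr for tr in kept_tx},
        elements={rec.element_id: rec for rec in genome.te_records},
        windows=windows,
        threshold=threshold,
    )
    return ChimeraResult(
        candidates=candidates, calls=calls, normalized_tx=normalized_tx, windows=windows
    )
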