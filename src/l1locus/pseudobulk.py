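"""Pseudo-bulk machinery for barcoded single-nucleus alignments.

Pooling the reads of all cells in a cluster into one bulk-like library
gives the depth needed to quantify individual repeat loci.  The stages
here mirror that workflow: QC-filter cells, back-trace each cluster's
barcodes to the alignment records, collapse PCR duplicates by UMI, and
merge samples clustered under a common label set.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io_formats import AlignmentRecord

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class ClusterMap:
    """Barcode -> cluster assignment for one sample."""

    sample_id: str
    mapping: dict[str, str] = field(default_factory=dict)

    @property
    def cluster_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for cluster in self.mapping.values():
            seen.setdefault(cluster)
        return list(seen)

    def restrict(self, barcodes: set[str]) -> "ClusterMap":
        """Keep only the given barcodes (e.g. the QC-passing set)."""
        kept = {bc: cl for bc, cl in self.mapping.items() if bc in barcodes}
        return ClusterMap(self.sample_id, kept)


def read_cluster_map(path, sample_id: str) -> ClusterMap:
    """Read a two-column barcode<TAB>cluster TSV (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["barcode", "cluster"], dtype=str)
    if df["barcode"].duplicated().any():
        dup = df.loc[df["barcode"].duplicated(), "barcode"].iloc[0]
        raise ValueError(f"barcode {dup!r} assigned to more than one cluster")
    return ClusterMap(sample_id, dict(zip(df["barcode"], df["cluster"])))


def write_cluster_map(path, cluster_map: ClusterMap) -> None:
    with open(path, "w") as fh:
        for barcode, cluster in cluster_map.mapping.items():
            fh.write(f"{barcode}\t{cluster}\n")


def qc_filter_cells(metrics: pd.DataFrame, mode: str) -> set[tuple[str, str]]:
    """Apply the per-sample cell QC rules; return kept (sample, barcode) pairs.

    Cells with mitochondrial content over 10% are removed in both modes.
    In ``adult`` mode, cells whose feature count exceeds the sample mean
    by more than two SDs (likely doublets) or falls more than one SD
    below it (low-quality nuclei) are removed.  In ``fetal`` mode the
    upper rule is the same but the lower rule is an absolute floor of
    2000 detected features.  Mean and SD (n-1 denominator) are computed
    per sample over all cells, before any other exclusion.
    """
    if mode not in ("adult", "fetal"):
        raise ValueError(f"mode must be 'adult' or 'fetal', got {mode!r}")
    required = {"barcode", "n_features", "mito_pct", "sample_id"}
    if not required <= set(metrics.columns):
        raise ValueError(f"metrics table needs columns {sorted(required)}")
    if ((metrics["mito_pct"] < 0) | (metrics["mito_pct"] > 100)).any():
        raise ValueError("mito_pct must lie in [0, 100]")

    kept: set[tuple[str, str]] = set()
    for sample_id, sub in metrics.groupby("sample_id", sort=False):
        if len(sub) < 2:
            raise ValueError(
                f"sample {sample_id!r} has fewer than 2 cells; SD thresholds undefined"
            )
        mean = sub["n_features"].mean()
        sd = sub["n_features"].std(ddof=1)
        upper = mean + 2.0 * sd
        lower = mean - 1.0 * sd if mode == "adult" else 2000.0
        ok = (
            (sub["mito_pct"] <= 10.0)
            & (sub["n_features"] <= upper)
            & (sub["n_features"] >= lower)
        )
        kept.update((sample_id, bc) for bc in sub.loc[ok, "barcode"])
    return kept


def assign_reads_to_clusters(
    alignments: Iterable[AlignmentRecord],
    clusters: ClusterMap,
) -> tuple[dict[str, list[AlignmentRecord]], dict]:
    """Back-trace cluster barcodes to their alignment records.

    Every record whose cell barcode is in the map goes to exactly one
    cluster collection; records without a barcode, or with a barcode
    absent from the map, are dropped and tallied.  Clusters present in
    the map but receiving no reads are emitted as empty collections.
    """
    collections: dict[str, list[AlignmentRecord]] = {
        cluster: [] for cluster in clusters.cluster_ids
    }
    report = {"n_assigned": 0, "n_dropped_no_barcode": 0, "n_dropped_unmapped_barcode": 0}
    for rec in alignments:
        if rec.cell_barcode is None:
            report["n_dropped_no_barcode"] += 1
            continue
        cluster = clusters.mapping.get(rec.cell_barcode)
        if cluster is None:
            report["n_dropped_unmapped_barcode"] += 1
            continue
        collections[cluster].append(rec)
        report["n_assigned"] += 1
    return collections, report


def dedup_umis(
    alignments: Sequence[AlignmentRecord],
    key: str = "position",
) -> tuple[list[AlignmentRecord], dict]:
    """Collapse PCR duplicates among barcoded, UMI-tagged records.

    With the default ``key="position"`` a duplicate is a record sharing
    (cell barcode, UMI, contig, alignment start) with an earlier record;
    including the position avoids collapsing distinct molecules that
    collide on a UMI.  ``key="cb-umi"`` is the stricter barcode+UMI-only
    key.  The first record in coordinate order is retained; records
    lacking a UMI are dropped.  The operation is idempotent.
    """
    if key not in ("position", "cb-umi"):
        raise ValueError(f"unknown duplicate key {key!r}")
    ordered = sorted(
        alignments,
        key=lambda r: (r.interval.contig, r.interval.start, r.read_id, r.flag),
    )
    seen: set = set()
    kept: list[AlignmentRecord] = []
    report = {"n_kept": 0, "n_duplicates": 0, "n_no_umi": 0}
    for rec in ordered:
        if rec.umi is None or rec.cell_barcode is None:
            report["n_no_umi"] += 1
            continue
        if key == "position":
            k = (rec.cell_barcode, rec.umi, rec.interval.contig, rec.interval.start)
        else:
            k = (rec.cell_barcode, rec.umi)
        if k in seen:
            report["n_duplicates"] += 1
            continue
        seen.add(k)
        kept.append(rec)
    report["n_kept"] = len(kept)
    return kept, report


def merge_samples(
    per_sample: Mapping[str, Mapping[str, Sequence[AlignmentRecord]]],
    labels: Optional[Sequence[str]] = None,
    regrouping: Optional[Mapping[str, str]] = None,
) -> dict[str, list[AlignmentRecord]]:
    """Concatenate same-labelled cluster collections across samples.

    ``labels`` fixes the shared label set (default: union over samples,
    in first-seen order); a label missing from a sample contributes an
    empty collection and is logged.  ``regrouping`` maps cluster labels
    onto coarser groups (e.g. pooling clusters into a cell type, or
    splitting by cell-cycle state upstream), in which case the merged
    collections are keyed by group.
    """
    if labels is None:
        seen: dict[str, None] = {}
        for collections in per_sample.values():
            for label in collections:
                seen.setdefault(label)
        labels = list(seen)
    if regrouping is not None:
        out_labels: dict[str, None] = {}
        for label in labels:
            out_labels.setdefault(regrouping.get(label, label))
        merged: dict[str, list[AlignmentRecord]] = {g: [] for g in out_labels}
    else:
        merged = {label: [] for label in labels}
    for sample_id, collections in per_sample.items():
        for label in labels:
            if label not in collections:
                logger.info("sample %s lacks cluster %s; treating as empty", sample_id, label)
                continue
            target = regrouping.get(label, label) if regrouping is not None else label
            merged[target].extend(collections[label])
    return merged
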