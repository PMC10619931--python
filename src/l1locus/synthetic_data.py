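"""Toy genome and read simulator with per-read ground truth.

Builds a small genome with planted L1 biology — several subfamilies of
full-length and 5'-truncated copies on both strands, genes with
embedded (intragenic) copies, a planted antisense-L1 chimeric
transcript plus decoy transcripts, YY1 promoter motifs and ORF0 start
codons — and simulates stranded alignments directly (no aligner is
run): paired-end bulk libraries and barcoded, UMI-tagged single-nucleus
libraries with PCR duplicates and multimapping hits.  Every read
carries ground truth (origin feature, promoter-driven vs readthrough,
transcribed strand, duplicate lineage, cluster), so each downstream
stage can be checked against what was planted.

Defaults describe the simulated study: two samples, four clusters of
which two express L1s, about 100 cells per sample at about 1000 reads
per cell, and 30k bulk read pairs per sample from 2x150 bp
reverse-stranded chemistry.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    FLAG_FIRST_MATE,
    FLAG_MATE_REVERSE,
    FLAG_PAIRED,
    FLAG_PROPER_PAIR,
    FLAG_REVERSE,
    FLAG_SECOND_MATE,
    FLAG_SECONDARY,
    AlignmentRecord,
    GenomicInterval,
    SequenceRecord,
    TEAnnotationRecord,
    TranscriptRecord,
    write_alignments,
    write_fasta,
    write_te_gtf,
    write_transcript_gtf,
)
from .motif_profiles import YY1_MOTIF
from .pseudobulk import ClusterMap, write_cluster_map

YOUNG_SUBFAMILIES = ("L1HS", "L1PA2", "L1PA3", "L1PA4")

# offsets within the oriented element (bp from the element 5' end)
YY1_PLANT_OFFSET = 6
ORF0_PROMOTER_WINDOW = 500  # antisense-promoter sequence = revcomp of first 500 bp
ORF0_OFFSET = 100  # ORF0 start codon offset within that antisense sequence

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {c: i for i, c in enumerate("ACGT")}
_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes][::-1]


@dataclass
class SubfamilySpec:
    """Planted copy-number and length structure of one L1 subfamily."""

    n_copies: int
    full_length_fraction: float
    truncated_length_range: tuple[int, int] = (600, 3000)
    full_length_range: tuple[int, int] = (6050, 6400)
    plus_strand_fraction: float = 0.5
    identity: float = 0.96  # within-subfamily pairwise identity
    consensus_divergence: float = 0.04  # from the shared family consensus


@dataclass
class ClusterSpec:
    cluster_id: str
    n_cells: int  # per sample
    l1_active: bool
    mean_reads_per_cell: float = 1000.0


def _default_subfamilies() -> dict[str, SubfamilySpec]:
    return {
        "L1HS": SubfamilySpec(6, 4 / 6, identity=0.985, consensus_divergence=0.01),
        "L1PA2": SubfamilySpec(6, 4 / 6, identity=0.97, consensus_divergence=0.03),
        "L1PA3": SubfamilySpec(5, 3 / 5, identity=0.95, consensus_divergence=0.05),
        "L1PA4": SubfamilySpec(5, 3 / 5, identity=0.93, consensus_divergence=0.07),
        "L1MA4": SubfamilySpec(8, 0.0, identity=0.80, consensus_divergence=0.20),
    }


def _default_clusters() -> list[ClusterSpec]:
    return [
        ClusterSpec("c0", 25, True),
        ClusterSpec("c1", 25, True),
        ClusterSpec("c2", 25, False),
        ClusterSpec("c3", 25, False),
    ]


@dataclass
class SimConfig:
    """All knobs of the simulated study; fixed seed means byte-identical output."""

    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 260_000
    subfamily_spec: dict[str, SubfamilySpec] = field(default_factory=_default_subfamilies)
    n_genes: int = 8
    gene_length_range: tuple[int, int] = (8000, 14000)
    intragenic_L1_fraction: float = 0.5  # of truncated copies, placed inside genes
    chimera_loci: int = 1
    promoter_driven_fraction: float = 0.8
    duplicate_rate: float = 0.15
    multimap_rate: float = 0.2
    clusters: list[ClusterSpec] = field(default_factory=_default_clusters)
    yy1_present_fraction: float = 0.6
    orf0_intact_fraction: float = 0.5
    n_samples: int = 2
    sample_ids: Optional[tuple[str, ...]] = None
    read_length: int = 150
    fragment_length_range: tuple[int, int] = (250, 450)
    bulk_reads_per_sample: int = 30_000
    expressed_fraction: float = 0.5  # of full-length young copies, sense-expressed
    # read-class mixtures (chimera/decoy transcript classes only exist in bulk)
    bulk_class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "gene": 0.60,
            "l1": 0.18,
            "chimera": 0.04,
            "decoy_same": 0.04,
            "decoy_short": 0.002,
            "intergenic": 0.138,
        }
    )
    decoy_lowexpr_reads: int = 6  # fixed, must stay below the expression threshold
    sn_active_class_probs: dict[str, float] = field(
        default_factory=lambda: {"gene": 0.80, "l1": 0.15, "intergenic": 0.05}
    )
    sn_inactive_class_probs: dict[str, float] = field(
        default_factory=lambda: {"gene": 0.95, "l1": 0.0, "intergenic": 0.05}
    )
    mismatch_fail_fraction: float = 0.04
    qc_fail_mito_fraction: float = 0.05
    n_features_mean: float = 3000.0
    n_features_sd: float = 300.0
    umi_length: int = 10
    barcode_length: int = 12

    def __post_init__(self) -> None:
        for name, value in [
            ("intragenic_L1_fraction", self.intragenic_L1_fraction),
            ("promoter_driven_fraction", self.promoter_driven_fraction),
            ("duplicate_rate", self.duplicate_rate),
            ("multimap_rate", self.multimap_rate),
            ("yy1_present_fraction", self.yy1_present_fraction),
            ("orf0_intact_fraction", self.orf0_intact_fraction),
            ("expressed_fraction", self.expressed_fraction),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.sample_ids is None:
            self.sample_ids = tuple(f"s{i}" for i in range(self.n_samples))


class ConfigError(ValueError):
    """The requested content does not fit the configured genome."""


@dataclass
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    embedded_elements: list[str] = field(default_factory=list)


@dataclass
class GenomeTruth:
    """Element- and transcript-level ground truth of the planted genome."""

    expressed_elements: set[str] = field(default_factory=set)
    yy1_elements: dict[str, bool] = field(default_factory=dict)
    orf0_intact: dict[str, bool] = field(default_factory=dict)
    orf0_offset: int = ORF0_OFFSET
    orf0_promoter_window: int = ORF0_PROMOTER_WINDOW
    chimera_transcripts: set[str] = field(default_factory=set)
    decoy_transcripts: dict[str, str] = field(default_factory=dict)
    chimera_hosts: dict[str, str] = field(default_factory=dict)  # transcript -> element
    intragenic_elements: dict[str, str] = field(default_factory=dict)  # element -> gene


@dataclass
class ToyGenome:
    config: SimConfig
    sequences: dict[str, SequenceRecord]
    contig_lengths: dict[str, int]
    te_records: list[TEAnnotationRecord]
    genes: list[GeneModel]
    transcripts: list[TranscriptRecord]
    truth: GenomeTruth

    def gene_features(self) -> list[TEAnnotationRecord]:
        """Gene intervals as countable features (for size-factor input)."""
        return [
            TEAnnotationRecord(
                interval=g.interval, element_id=g.gene_id, subfamily=g.gene_id
            )
            for g in self.genes
        ]

    def full_length_young(self, min_len: int = 6000) -> list[TEAnnotationRecord]:
        return [
            rec
            for rec in self.te_records
            if rec.subfamily in YOUNG_SUBFAMILIES and rec.length > min_len
        ]


def _oriented_write(arr: np.ndarray, element: TEAnnotationRecord, offset: int, codes: np.ndarray) -> None:
    """Write ``codes`` at an element-oriented offset into the genome array."""
    s, e = element.interval.start, element.interval.end
    if element.strand == "-":
        arr[e - offset - len(codes) : e - offset] = _revcomp_codes(codes)
    else:
        arr[s + offset : s + offset + len(codes)] = codes


def _oriented_read(arr: np.ndarray, element: TEAnnotationRecord, offset: int, length: int) -> np.ndarray:
    s, e = element.interval.start, element.interval.end
    if element.strand == "-":
        return _revcomp_codes(arr[e - offset - length : e - offset])
    return arr[s + offset : s + offset + length]


def build_toy_genome(config: SimConfig) -> ToyGenome:
    """Construct the planted toy genome, annotations and element truth."""
    rng = np.random.default_rng(config.seed)
    consensus_len = 6500
    family_consensus = rng.integers(0, 4, consensus_len, dtype=np.uint8)

    def mutate(codes: np.ndarray, rate: float) -> np.ndarray:
        out = codes.copy()
        n_mut = rng.binomial(len(codes), rate)
        if n_mut:
            pos = rng.choice(len(codes), size=n_mut, replace=False)
            out[pos] = (out[pos] + rng.integers(1, 4, n_mut, dtype=np.uint8)) % 4
        return out

    sub_consensus = {
        name: mutate(family_consensus, spec.consensus_divergence)
        for name, spec in config.subfamily_spec.items()
    }

    # ---- plan element copies -------------------------------------------------
    planned = []  # (element_id, subfamily, length, strand, full_length)
    for name, spec in config.subfamily_spec.items():
        n_fl = int(round(spec.n_copies * spec.full_length_fraction))
        for i in range(spec.n_copies):
            full = i < n_fl
            lo, hi = spec.full_length_range if full else spec.truncated_length_range
            length = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.random() < spec.plus_strand_fraction else "-"
            planned.append((f"{name}_{i}", name, length, strand, full))

    fl_ids = [eid for eid, _, _, _, full in planned if full]
    trunc_ids = [eid for eid, _, _, _, full in planned if not full]
    n_intragenic = int(round(len(trunc_ids) * config.intragenic_L1_fraction))
    intragenic_ids = set(
        map(str, rng.choice(trunc_ids, size=min(n_intragenic, len(trunc_ids)), replace=False))
    ) if trunc_ids else set()

    # chimera and decoy hosts: distinct full-length young copies, kept out of
    # the sense-expressed set so decoy expression is controlled exactly
    fl_young = [eid for eid, sub, _, _, full in planned if full and sub in YOUNG_SUBFAMILIES]
    n_hosts = config.chimera_loci + 3
    if len(fl_young) < n_hosts + 1:
        raise ConfigError("not enough full-length young copies for chimera/decoy hosts")
    hosts = [str(h) for h in rng.choice(fl_young, size=n_hosts, replace=False)]
    chimera_hosts = hosts[: config.chimera_loci]
    decoy_same_host, decoy_short_host, decoy_low_host = hosts[config.chimera_loci :][:3]

    # ---- lay out blocks across contigs --------------------------------------
    info = {eid: (sub, length, strand, full) for eid, sub, length, strand, full in planned}
    standalone = [eid for eid in info if eid not in intragenic_ids]
    host_set = set(hosts)

    gene_plans = []
    embed_pool = sorted(intragenic_ids)
    for i in range(config.n_genes):
        glen = int(rng.integers(*config.gene_length_range))
        gstrand = "+" if rng.random() < 0.5 else "-"
        embedded = []
        if embed_pool:
            embedded.append(embed_pool.pop(0))
        gene_plans.append((f"gene{i}", glen, gstrand, embedded))
    if embed_pool:
        raise ConfigError(
            "more intragenic copies requested than genes available to host them"
        )

    blocks = [("gene", plan) for plan in gene_plans] + [
        ("element", eid) for eid in standalone
    ]
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    contigs = [f"contig{i}" for i in range(config.n_contigs)]
    cursor = {c: 0 for c in contigs}
    te_records: list[TEAnnotationRecord] = []
    genes: list[GeneModel] = []
    truth = GenomeTruth()
    tx_len_chimera = 3000
    host_clearance = tx_len_chimera + 600

    placements = []  # deferred sequence pastes: (contig, element_id, start)
    ci = 0
    for kind, payload in blocks:
        contig = contigs[ci % len(contigs)]
        ci += 1
        gap = int(rng.integers(1500, 4000))
        if kind == "element" and payload in host_set:
            gap = max(gap, host_clearance)
        start = cursor[contig] + gap
        if kind == "gene":
            gene_id, glen, gstrand, embedded = payload
            interval = GenomicInterval(contig, start, start + glen, gstrand)
            gene = GeneModel(gene_id, interval)
            offset_lo = 500
            for eid in embedded:
                sub, length, strand, _full = info[eid]
                if offset_lo + length + 500 > glen:
                    raise ConfigError(f"gene {gene_id} too short for embedded {eid}")
                e_off = int(rng.integers(offset_lo, glen - length - 500 + 1))
                el_iv = GenomicInterval(contig, start + e_off, start + e_off + length, strand)
                te_records.append(
                    TEAnnotationRecord(
                        el_iv, eid, sub,
                        family="L1", te_class="LINE",
                        divergence=100 * (1 - config.subfamily_spec[sub].identity) / 2,
                    )
                )
                placements.append((contig, eid, start + e_off))
                truth.intragenic_elements[eid] = gene_id
                gene.embedded_elements.append(eid)
                offset_lo = e_off + length + 500
            genes.append(gene)
            cursor[contig] = start + glen
        else:
            eid = payload
            sub, length, strand, _full = info[eid]
            el_iv = GenomicInterval(contig, start, start + length, strand)
            te_records.append(
                TEAnnotationRecord(
                    el_iv, eid, sub,
                    family="L1", te_class="LINE",
                    divergence=100 * (1 - config.subfamily_spec[sub].identity) / 2,
                )
            )
            placements.append((contig, eid, start))
            cursor[contig] = start + length
            if eid in host_set:
                cursor[contig] += host_clearance
    for contig in contigs:
        if cursor[contig] + 1000 > config.contig_length:
            raise ConfigError(
                f"{contig} needs {cursor[contig] + 1000} bp but contig_length is "
                f"{config.contig_length}; increase contig_length or reduce content"
            )

    # ---- genome sequence -----------------------------------------------------
    arrays = {
        c: rng.integers(0, 4, config.contig_length, dtype=np.uint8) for c in contigs
    }
    by_id = {rec.element_id: rec for rec in te_records}
    for contig, eid, start in placements:
        rec = by_id[eid]
        spec = config.subfamily_spec[rec.subfamily]
        copy = mutate(sub_consensus[rec.subfamily], (1 - spec.identity) / 2)
        codes = copy[-rec.length :]  # 3'-anchored: L1s truncate from the 5' end
        if rec.strand == "-":
            codes = _revcomp_codes(codes)
        arrays[contig][start : start + rec.length] = codes

    # ---- promoter features on full-length elements ---------------------------
    motif_codes = _encode(YY1_MOTIF)
    fl_records = [by_id[eid] for eid in fl_ids]
    yy1_carriers = set(
        map(str, rng.choice(
            fl_ids,
            size=int(round(len(fl_ids) * config.yy1_present_fraction)),
            replace=False,
        ))
    ) if fl_ids else set()
    for rec in fl_records:
        arr = arrays[rec.interval.contig]
        if rec.element_id in yy1_carriers:
            _oriented_write(arr, rec, YY1_PLANT_OFFSET, motif_codes)
            truth.yy1_elements[rec.element_id] = True
        else:
            # scrub chance matches from the scanned prefix
            prefix = _oriented_read(arr, rec, 0, 100)
            text = _decode(prefix)
            pos = text.find(YY1_MOTIF)
            while pos >= 0:
                mid = pos + len(YY1_MOTIF) // 2
                prefix[mid] = (prefix[mid] + 1) % 4
                _oriented_write(arr, rec, 0, prefix)
                text = _decode(prefix)
                pos = text.find(YY1_MOTIF)
            truth.yy1_elements[rec.element_id] = False
        # ORF0 start codon, read on the antisense strand of the 5'UTR:
        # antisense position ORF0_OFFSET maps to oriented offset
        # window - offset - 3 with the codon reverse-complemented.
        intact = bool(rng.random() < config.orf0_intact_fraction)
        codon = "ATG" if intact else "ACG"  # ACG is the M1T (Met->Thr) variant
        _oriented_write(
            arr,
            rec,
            ORF0_PROMOTER_WINDOW - ORF0_OFFSET - 3,
            _revcomp_codes(_encode(codon)),
        )
        truth.orf0_intact[rec.element_id] = intact

    # ---- expressed set (sense promoter activity), stratified by subfamily ----
    for sub in YOUNG_SUBFAMILIES:
        pool = [
            eid
            for eid in fl_ids
            if info[eid][0] == sub and eid not in host_set
        ]
        spec = config.subfamily_spec.get(sub)
        if not pool or spec is None:
            continue
        n_fl_sub = sum(1 for eid in fl_ids if info[eid][0] == sub)
        n_expr = min(len(pool), max(1, int(round(n_fl_sub * config.expressed_fraction))))
        truth.expressed_elements.update(map(str, rng.choice(pool, size=n_expr, replace=False)))

    # ---- transcript models: gene transcripts, chimeras, decoys ---------------
    transcripts: list[TranscriptRecord] = []
    for gene in genes:
        transcripts.append(
            TranscriptRecord(
                f"{gene.gene_id}.t1", gene.interval, exons=(gene.interval,)
            )
        )

    def antisense_transcript(tid: str, host_id: str, length: int) -> TranscriptRecord:
        host = by_id[host_id]
        tss_oriented = 400  # inside the 5'UTR, where the antisense promoter sits
        if host.strand == "+":
            tss = host.interval.start + tss_oriented
            iv = GenomicInterval(host.interval.contig, tss - length + 1, tss + 1, "-")
        else:
            tss = host.interval.end - 1 - tss_oriented
            iv = GenomicInterval(host.interval.contig, tss, tss + length, "+")
        return TranscriptRecord(tid, iv, exons=(iv,))

    for i, host_id in enumerate(chimera_hosts):
        tr = antisense_transcript(f"chimera{i}", host_id, tx_len_chimera)
        transcripts.append(tr)
        truth.chimera_transcripts.add(tr.transcript_id)
        truth.chimera_hosts[tr.transcript_id] = host_id

    host = by_id[decoy_same_host]  # same-strand transcript starting inside the L1
    if host.strand == "+":
        iv = GenomicInterval(
            host.interval.contig, host.interval.start + 400, host.interval.start + 400 + 3000, "+"
        )
    else:
        iv = GenomicInterval(
            host.interval.contig, host.interval.end - 400 - 3000, host.interval.end - 400, "-"
        )
    transcripts.append(TranscriptRecord("decoy_same", iv, exons=(iv,)))
    truth.decoy_transcripts["decoy_same"] = "same_strand"
    truth.chimera_hosts["decoy_same"] = decoy_same_host

    tr = antisense_transcript("decoy_short", decoy_short_host, 900)
    transcripts.append(tr)
    truth.decoy_transcripts["decoy_short"] = "too_short"
    truth.chimera_hosts["decoy_short"] = decoy_short_host

    tr = antisense_transcript("decoy_lowexpr", decoy_low_host, 2500)
    transcripts.append(tr)
    truth.decoy_transcripts["decoy_lowexpr"] = "below_expression_threshold"
    truth.chimera_hosts["decoy_lowexpr"] = decoy_low_host

    sequences = {c: SequenceRecord(c, _decode(arrays[c])) for c in contigs}
    return ToyGenome(
        config=config,
        sequences=sequences,
        contig_lengths={c: config.contig_length for c in contigs},
        te_records=te_records,
        genes=genes,
        transcripts=transcripts,
        truth=truth,
    )


# --------------------------------------------------------------------------
# read simulation
# --------------------------------------------------------------------------


@dataclass
class SimReads:
    """Simulated alignments, cluster structure, QC metrics and read truth."""

    genome: ToyGenome
    bulk: dict[str, list[AlignmentRecord]]
    single_nucleus: dict[str, list[AlignmentRecord]]
    cluster_maps: dict[str, ClusterMap]
    qc_metrics: pd.DataFrame
    truth_reads: pd.DataFrame  # one row per read (not per hit record)


def _token(rng: np.random.Generator, length: int) -> str:
    return _decode(rng.integers(0, 4, length, dtype=np.uint8))


class _IntergenicSpace:
    """Gaps between annotated features, for placing background reads."""

    def __init__(self, genome: ToyGenome, margin: int):
        spans: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.contig_lengths}
        for rec in genome.te_records:
            spans[rec.interval.contig].append((rec.interval.start, rec.interval.end))
        for gene in genome.genes:
            spans[gene.interval.contig].append((gene.interval.start, gene.interval.end))
        for tr in genome.transcripts:
            spans[tr.interval.contig].append((tr.interval.start, tr.interval.end))
        self.gaps: list[tuple[str, int, int]] = []
        for contig, length in genome.contig_lengths.items():
            merged = []
            for s, e in sorted(spans[contig]):
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            prev = 0
            for s, e in merged + [(length, length)]:
                if s - prev >= margin + 200:  # leave a buffer on both sides
                    self.gaps.append((contig, prev + 100, s - 100 - margin))
                prev = max(prev, e)
        if not self.gaps:
            raise ConfigError("no intergenic space left for background reads")
        lengths = np.array([e - s for _, s, e in self.gaps], dtype=float)
        self.weights = lengths / lengths.sum()

    def draw(self, rng: np.random.Generator) -> tuple[str, int]:
        i = rng.choice(len(self.gaps), p=self.weights)
        contig, s, e = self.gaps[i]
        return contig, int(rng.integers(s, e))


def _fragment_in(
    rng: np.random.Generator, iv: GenomicInterval, frag_len: int
) -> tuple[int, int]:
    length = min(frag_len, iv.length)
    start = int(rng.integers(iv.start, iv.end - length + 1))
    return start, length


def _pair_records(
    read_id: str,
    contig: str,
    frag_start: int,
    frag_len: int,
    transcribed: str,
    read_length: int,
    n_hits: int,
    nm: tuple[int, int],
    secondary: bool = False,
) -> list[AlignmentRecord]:
    """Mate records of one fragment under reverse-stranded chemistry.

    The second mate aligns on the transcribed strand, the first mate on
    the opposite one, so the flag partition recovers the transcript
    strand exactly.
    """
    rl = min(read_length, frag_len)
    base = FLAG_PAIRED | FLAG_PROPER_PAIR | (FLAG_SECONDARY if secondary else 0)
    left = GenomicInterval(contig, frag_start, frag_start + rl, "+")
    right = GenomicInterval(contig, frag_start + frag_len - rl, frag_start + frag_len, "-")
    if transcribed == "+":
        r2 = AlignmentRecord(
            read_id, base | FLAG_SECOND_MATE | FLAG_MATE_REVERSE,
            left, n_hits, nm[1], rl,
        )
        r1 = AlignmentRecord(
            read_id, base | FLAG_FIRST_MATE | FLAG_REVERSE,
            dataclasses.replace(right), n_hits, nm[0], rl,
        )
    else:
        r1 = AlignmentRecord(
            read_id, base | FLAG_FIRST_MATE | FLAG_MATE_REVERSE,
            left, n_hits, nm[0], rl,
        )
        r2 = AlignmentRecord(
            read_id, base | FLAG_SECOND_MATE | FLAG_REVERSE,
            dataclasses.replace(right), n_hits, nm[1], rl,
        )
    return [r1, r2]


def _draw_nm(rng: np.random.Generator, config: SimConfig) -> int:
    # most reads pass the 0.03 mismatch-ratio filter at 150 bp (<= 4 mismatches)
    if rng.random() < config.mismatch_fail_fraction:
        return int(rng.integers(8, 13))
    return int(rng.integers(0, 5))


def simulate_reads(genome: ToyGenome, config: Optional[SimConfig] = None) -> SimReads:
    """Simulate bulk and single-nucleus alignments with ground truth."""
    config = config or genome.config
    rng = np.random.default_rng(config.seed + 1)
    by_id = {rec.element_id: rec for rec in genome.te_records}
    truth = genome.truth
    expressed = sorted(truth.expressed_elements)
    intragenic = sorted(truth.intragenic_elements)
    space = _IntergenicSpace(genome, margin=config.fragment_length_range[1])
    tx_by_id = {tr.transcript_id: tr for tr in genome.transcripts}

    # 3'-anchored homolog pool for multimapping: full-length young copies
    fl_young = genome.full_length_young()
    homologs: dict[str, list[str]] = {}
    for rec in fl_young:
        homologs[rec.element_id] = [
            other.element_id
            for other in fl_young
            if other.element_id != rec.element_id
        ]

    def element_fragment(eid: str, frag_len: int) -> tuple[str, int, int, str]:
        rec = by_id[eid]
        start, length = _fragment_in(rng, rec.interval, frag_len)
        return rec.interval.contig, start, length, rec.strand

    def homolog_placement(eid: str, frag_start: int, frag_len: int, hid: str):
        """Map a fragment to the same 3'-anchored offset in a homolog copy."""
        src, dst = by_id[eid], by_id[hid]
        if src.strand == "+":
            o5 = frag_start - src.interval.start
        else:
            o5 = src.interval.end - (frag_start + frag_len)
        o3 = src.length - (o5 + frag_len)  # distance from the element 3' end
        if o3 < 0 or o3 + frag_len > dst.length:
            return None
        d5 = dst.length - o3 - frag_len
        if dst.strand == "+":
            gstart = dst.interval.start + d5
        else:
            gstart = dst.interval.end - d5 - frag_len
        return dst.interval.contig, gstart, dst.strand

    truth_rows: list[dict] = []

    # ---------------- bulk: paired-end stranded libraries ----------------
    class_names = list(config.bulk_class_probs)
    class_p = np.array([config.bulk_class_probs[c] for c in class_names])
    class_p = class_p / class_p.sum()
    bulk: dict[str, list[AlignmentRecord]] = {}
    for sample in config.sample_ids:
        records: list[AlignmentRecord] = []
        n_total = config.bulk_reads_per_sample
        draws = rng.choice(len(class_names), size=n_total, p=class_p)
        lowexpr_ids = set(
            rng.choice(n_total, size=min(config.decoy_lowexpr_reads, n_total), replace=False)
        )
        for i in range(n_total):
            read_id = f"{sample}_b{i}"
            frag_len = int(rng.integers(*config.fragment_length_range))
            cls = class_names[draws[i]]
            origin_kind, origin = "gene", ""
            multimap_from = None
            if i in lowexpr_ids:
                cls = "transcript"
                tr = tx_by_id["decoy_lowexpr"]
                frag_start, frag_len = _fragment_in(rng, tr.interval, frag_len)
                contig, t = tr.interval.contig, tr.strand
                origin_kind, origin = "gene", tr.transcript_id
            elif cls == "gene":
                gene = genome.genes[int(rng.integers(len(genome.genes)))]
                frag_start, frag_len = _fragment_in(rng, gene.interval, frag_len)
                contig, t = gene.interval.contig, gene.interval.strand
                origin = gene.gene_id
                for eid in gene.embedded_elements:
                    el = by_id[eid]
                    if frag_start < el.interval.end and el.interval.start < frag_start + frag_len:
                        origin_kind, origin = "readthrough", eid
                        break
            elif cls == "l1":
                if expressed and rng.random() < config.promoter_driven_fraction:
                    eid = expressed[int(rng.integers(len(expressed)))]
                    contig, frag_start, frag_len, t = element_fragment(eid, frag_len)
                    origin_kind, origin = "L1-promoter", eid
                    if rng.random() < config.multimap_rate and homologs.get(eid):
                        multimap_from = eid
                elif intragenic:
                    eid = intragenic[int(rng.integers(len(intragenic)))]
                    el = by_id[eid]
                    gene = next(
                        g for g in genome.genes if g.gene_id == truth.intragenic_elements[eid]
                    )
                    lo = max(gene.interval.start, el.interval.start - frag_len + 1)
                    hi = min(el.interval.end, gene.interval.end - frag_len)
                    frag_start = int(rng.integers(lo, max(lo + 1, hi)))
                    contig, t = el.interval.contig, gene.interval.strand
                    origin_kind, origin = "readthrough", eid
                else:
                    contig, frag_start = space.draw(rng)
                    t = "+" if rng.random() < 0.5 else "-"
                    origin_kind, origin = "intergenic", ""
            elif cls in ("chimera", "decoy_same", "decoy_short"):
                if cls == "chimera":
                    if not truth.chimera_transcripts:
                        continue
                    tids = sorted(truth.chimera_transcripts)
                    tid = tids[int(rng.integers(len(tids)))]
                else:
                    tid = cls.replace("decoy_same", "decoy_same").replace(
                        "decoy_short", "decoy_short"
                    )
                tr = tx_by_id[tid]
                frag_start, frag_len = _fragment_in(rng, tr.interval, frag_len)
                contig, t = tr.interval.contig, tr.strand
                origin_kind, origin = "gene", tid
                cls = "transcript"
            else:  # intergenic background
                contig, frag_start = space.draw(rng)
                t = "+" if rng.random() < 0.5 else "-"
                origin_kind, origin = "intergenic", ""

            n_hits = 1
            secondary_placements = []
            if multimap_from is not None:
                pool = homologs[multimap_from]
                k = int(rng.integers(1, min(2, len(pool)) + 1))
                chosen = [str(h) for h in rng.choice(pool, size=k, replace=False)]
                for hid in chosen:
                    placement = homolog_placement(multimap_from, frag_start, frag_len, hid)
                    if placement is not None:
                        secondary_placements.append(placement)
                n_hits = 1 + len(secondary_placements)

            nm = (_draw_nm(rng, config), _draw_nm(rng, config))
            records.extend(
                _pair_records(
                    read_id, contig, frag_start, frag_len, t,
                    config.read_length, n_hits, nm,
                )
            )
            for hcontig, hstart, hstrand in secondary_placements:
                src_strand = by_id[multimap_from].strand
                ht = t if hstrand == src_strand else ("-" if t == "+" else "+")
                records.extend(
                    _pair_records(
                        read_id, hcontig, hstart, frag_len, ht,
                        config.read_length, n_hits, nm, secondary=True,
                    )
                )
            truth_rows.append(
                {
                    "read_id": read_id,
                    "sample": sample,
                    "source": "bulk",
                    "origin_kind": origin_kind,
                    "origin_feature_id": origin,
                    "read_class": cls,
                    "transcribed_strand": t,
                    "duplicate_of": "",
                    "true_cluster": "",
                    "cell_barcode": "",
                    "n_hits": n_hits,
                }
            )
        bulk[sample] = records

    # ---------------- single-nucleus: barcoded, UMI-tagged ----------------
    single_nucleus: dict[str, list[AlignmentRecord]] = {}
    cluster_maps: dict[str, ClusterMap] = {}
    qc_rows: list[dict] = []
    used_barcodes: set[str] = set()
    for sample in config.sample_ids:
        records = []
        cmap: dict[str, str] = {}
        for cluster in config.clusters:
            probs = (
                config.sn_active_class_probs
                if cluster.l1_active
                else config.sn_inactive_class_probs
            )
            names = list(probs)
            p = np.array([probs[c] for c in names])
            p = p / p.sum()
            for _cell in range(cluster.n_cells):
                while True:
                    barcode = _token(rng, config.barcode_length)
                    if barcode not in used_barcodes:
                        used_barcodes.add(barcode)
                        break
                cmap[barcode] = cluster.cluster_id
                mito = (
                    float(rng.uniform(10.5, 30.0))
                    if rng.random() < config.qc_fail_mito_fraction
                    else float(rng.uniform(0.0, 8.0))
                )
                qc_rows.append(
                    {
                        "barcode": barcode,
                        "n_features": int(
                            max(100, rng.normal(config.n_features_mean, config.n_features_sd))
                        ),
                        "mito_pct": round(mito, 3),
                        "sample_id": sample,
                    }
                )
                n_reads = int(rng.poisson(cluster.mean_reads_per_cell))
                molecules: list[dict] = []
                mol_keys: set[tuple] = set()
                cls_draws = rng.choice(len(names), size=max(n_reads, 1), p=p)
                dup_draws = rng.random(max(n_reads, 1))
                for j in range(n_reads):
                    read_id = f"{sample}_{barcode}_r{j}"
                    if molecules and dup_draws[j] < config.duplicate_rate:
                        mol = molecules[int(rng.integers(len(molecules)))]
                        dup_of = mol["read_id"]
                    else:
                        cls = names[cls_draws[j]]
                        frag = config.read_length
                        if cls == "l1" and expressed and rng.random() < config.promoter_driven_fraction:
                            eid = expressed[int(rng.integers(len(expressed)))]
                            contig, gstart, frag, t = element_fragment(eid, frag)
                            kind, origin = "L1-promoter", eid
                        elif cls == "l1" and intragenic:
                            eid = intragenic[int(rng.integers(len(intragenic)))]
                            el = by_id[eid]
                            gstart, frag = _fragment_in(rng, el.interval, frag)
                            contig = el.interval.contig
                            gene_id = truth.intragenic_elements[eid]
                            t = next(
                                g for g in genome.genes if g.gene_id == gene_id
                            ).interval.strand
                            kind, origin = "readthrough", eid
                        elif cls == "gene":
                            gene = genome.genes[int(rng.integers(len(genome.genes)))]
                            gstart, frag = _fragment_in(rng, gene.interval, frag)
                            contig, t = gene.interval.contig, gene.interval.strand
                            kind, origin = "gene", gene.gene_id
                            for eid in gene.embedded_elements:
                                el = by_id[eid]
                                if gstart < el.interval.end and el.interval.start < gstart + frag:
                                    kind, origin = "readthrough", eid
                                    break
                        else:
                            contig, gstart = space.draw(rng)
                            t = "+" if rng.random() < 0.5 else "-"
                            kind, origin = "intergenic", ""
                        while True:
                            umi = _token(rng, config.umi_length)
                            if (contig, gstart, umi) not in mol_keys:
                                mol_keys.add((contig, gstart, umi))
                                break
                        n_hits = 1
                        secondaries = []
                        if (
                            kind == "L1-promoter"
                            and rng.random() < config.multimap_rate
                            and homologs.get(origin)
                        ):
                            pool = homologs[origin]
                            hid = pool[int(rng.integers(len(pool)))]
                            placement = homolog_placement(origin, gstart, frag, hid)
                            if placement is not None:
                                secondaries.append(placement)
                                n_hits = 2
                        mol = {
                            "read_id": read_id,
                            "cls": cls,
                            "contig": contig,
                            "gstart": gstart,
                            "frag": frag,
                            "t": t,
                            "kind": kind,
                            "origin": origin,
                            "umi": umi,
                            "n_hits": n_hits,
                            "secondaries": secondaries,
                            "nm": _draw_nm(rng, config),
                        }
                        molecules.append(mol)
                        dup_of = ""
                    flag = FLAG_REVERSE if mol["t"] == "+" else 0  # reverse-stranded
                    records.append(
                        AlignmentRecord(
                            read_id,
                            flag,
                            GenomicInterval(
                                mol["contig"], mol["gstart"], mol["gstart"] + mol["frag"],
                                "-" if flag & FLAG_REVERSE else "+",
                            ),
                            n_hits=mol["n_hits"],
                            mismatches=mol["nm"],
                            mapped_length=mol["frag"],
                            cell_barcode=barcode,
                            umi=mol["umi"],
                        )
                    )
                    for hcontig, hstart, hstrand in mol["secondaries"]:
                        src_strand = by_id[mol["origin"]].strand
                        ht = mol["t"] if hstrand == src_strand else (
                            "-" if mol["t"] == "+" else "+"
                        )
                        hflag = (FLAG_REVERSE if ht == "+" else 0) | FLAG_SECONDARY
                        records.append(
                            AlignmentRecord(
                                read_id,
                                hflag,
                                GenomicInterval(
                                    hcontig, hstart, hstart + mol["frag"],
                                    "-" if hflag & FLAG_REVERSE else "+",
                                ),
                                n_hits=mol["n_hits"],
                                mismatches=mol["nm"],
                                mapped_length=mol["frag"],
                                cell_barcode=barcode,
                                umi=mol["umi"],
                            )
                        )
                    truth_rows.append(
                        {
                            "read_id": read_id,
                            "sample": sample,
                            "source": "sn",
                            "origin_kind": mol["kind"],
                            "origin_feature_id": mol["origin"],
                            "read_class": mol["cls"],
                            "transcribed_strand": mol["t"],
                            "duplicate_of": dup_of,
                            "true_cluster": cluster.cluster_id,
                            "cell_barcode": barcode,
                            "n_hits": mol["n_hits"],
                        }
                    )
        single_nucleus[sample] = records
        cluster_maps[sample] = ClusterMap(sample, cmap)

    truth_reads = pd.DataFrame(truth_rows)
    qc_metrics = pd.DataFrame(qc_rows, columns=["barcode", "n_features", "mito_pct", "sample_id"])
    return SimReads(
        genome=genome,
        bulk=bulk,
        single_nucleus=single_nucleus,
        cluster_maps=cluster_maps,
        qc_metrics=qc_metrics,
        truth_reads=truth_reads,
    )


def simulate_subfamily_mixture(
    n_reads: int = 5000,
    proportions: tuple[float, float] = (0.8, 0.2),
    ambiguous_fraction: float = 0.3,
    seed: int = 0,
    read_length: int = 150,
) -> tuple[list[AlignmentRecord], list[TEAnnotationRecord], dict[str, float]]:
    """Two-subfamily multimapping mixture for checking the EM assignment.

    Reads originate from subfamily A or B at the given proportions; an
    ``ambiguous_fraction`` of them report one hit in each subfamily
    (n_hits = 2), the rest map uniquely to their true subfamily.
    Returns (records, annotation, true proportions by subfamily).
    """
    rng = np.random.default_rng(seed)
    length = 7000
    annotation = [
        TEAnnotationRecord(GenomicInterval("mixA", 1000, 1000 + length, "+"), "A_0", "A"),
        TEAnnotationRecord(GenomicInterval("mixB", 1000, 1000 + length, "+"), "B_0", "B"),
    ]
    by_sub = {"A": annotation[0], "B": annotation[1]}
    records: list[AlignmentRecord] = []
    origins = rng.choice(["A", "B"], size=n_reads, p=np.array(proportions))
    ambiguous = rng.random(n_reads) < ambiguous_fraction
    for i in range(n_reads):
        offset = int(rng.integers(0, length - read_length))
        src = by_sub[origins[i]]
        iv = GenomicInterval(
            src.interval.contig, src.interval.start + offset,
            src.interval.start + offset + read_length, "+",
        )
        if ambiguous[i]:
            other = by_sub["B" if origins[i] == "A" else "A"]
            oiv = GenomicInterval(
                other.interval.contig, other.interval.start + offset,
                other.interval.start + offset + read_length, "+",
            )
            records.append(AlignmentRecord(f"m{i}", 0, iv, n_hits=2, mapped_length=read_length))
            records.append(
                AlignmentRecord(f"m{i}", FLAG_SECONDARY, oiv, n_hits=2, mapped_length=read_length)
            )
        else:
            records.append(AlignmentRecord(f"m{i}", 0, iv, n_hits=1, mapped_length=read_length))
    return records, annotation, {"A": proportions[0], "B": proportions[1]}


# --------------------------------------------------------------------------
# disk output
# --------------------------------------------------------------------------


def write_outputs(sim: SimReads, outdir) -> dict[str, Path]:
    """Write genome, annotations, alignments, cluster maps and truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = sim.genome
    paths: dict[str, Path] = {}

    paths["genome_fasta"] = outdir / "genome.fa"
    write_fasta(paths["genome_fasta"], genome.sequences.values())

    paths["te_gtf"] = outdir / "te_annotation.gtf"
    write_te_gtf(paths["te_gtf"], genome.te_records)

    paths["transcripts_gtf"] = outdir / "transcripts.gtf"
    write_transcript_gtf(paths["transcripts_gtf"], genome.transcripts)

    for sample, records in sim.bulk.items():
        p = outdir / f"bulk_{sample}.sam"
        write_alignments(p, records, genome.contig_lengths)
        paths[f"bulk_{sample}"] = p
    for sample, records in sim.single_nucleus.items():
        p = outdir / f"sn_{sample}.sam"
        write_alignments(p, records, genome.contig_lengths)
        paths[f"sn_{sample}"] = p
    for sample, cmap in sim.cluster_maps.items():
        p = outdir / f"clusters_{sample}.tsv"
        write_cluster_map(p, cmap)
        paths[f"clusters_{sample}"] = p

    paths["qc_metrics"] = outdir / "qc_metrics.tsv"
    sim.qc_metrics.to_csv(paths["qc_metrics"], sep="\t", index=False)
    paths["truth_reads"] = outdir / "truth_reads.tsv"
    sim.truth_reads.to_csv(paths["truth_reads"], sep="\t", index=False)

    config_dict = dataclasses.asdict(genome.config)
    paths["config"] = outdir / "sim_config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config_dict, fh, sort_keys=False)
    return paths
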