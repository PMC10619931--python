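"""Call L1-chimeric transcripts and associate promoter peaks with L1s.

Runs the chimera chain (dedup >1 kbp, TSS +/-100 bp windows, antisense
intersection with full-length L1s, normalized expression > 20) on the
assembled transcript set, then emulates promoter peak calling by
placing intervals over the 5' ends of the expressed elements and
intersecting them with full-length young L1s.
"""

import numpy as np

from _common import build_study, parse_args
from l1locus.chimera import chimera_table, intersect_peaks_with_elements
from l1locus.io_formats import GenomicInterval
from l1locus.pipeline import run_chimera_analysis


def main() -> None:
    args = parse_args(__doc__)
    sim = build_study(args.seed)
    genome = sim.genome

    result = run_chimera_analysis(sim)
    table = chimera_table(result.calls)
    table.to_csv(args.results / "chimera_calls.tsv", sep="\t", index=False)

    truth = genome.truth
    called = {c.transcript_id for c in result.calls if c.expressed}
    print(f"candidates: {result.candidates}")
    print(f"expressed chimera calls: {sorted(called)} "
          f"(planted: {sorted(truth.chimera_transcripts)})")
    print(f"decoys rejected: {sorted(truth.decoy_transcripts)}")

    # peaks over the 5' end of each expressed element, plus background peaks
    rng = np.random.default_rng(args.seed + 500)
    by_id = {r.element_id: r for r in genome.te_records}
    peaks = []
    for eid in sorted(truth.expressed_elements):
        rec = by_id[eid]
        anchor = rec.interval.start if rec.strand == "+" else rec.interval.end
        peaks.append(GenomicInterval(rec.interval.contig, max(0, anchor - 500), anchor + 500))
    for _ in range(10):
        contig = f"contig{int(rng.integers(len(genome.sequences)))}"
        start = int(rng.integers(0, genome.contig_lengths[contig] - 1000))
        peaks.append(GenomicInterval(contig, start, start + 1000))

    overlaps = intersect_peaks_with_elements(peaks, genome.full_length_young())
    with open(args.results / "peak_element_overlap.tsv", "w") as fh:
        fh.write("peak_index\tpeak\telement_id\n")
        for i, eid in overlaps:
            p = peaks[i]
            fh.write(f"{i}\t{p.contig}:{p.start}-{p.end}\t{eid}\n")
    n_promoter_peaks = len({i for i, _ in overlaps})
    print(f"{n_promoter_peaks}/{len(peaks)} peaks overlap a full-length young L1 "
          f"({len(overlaps)} peak-element pairs)")


if __name__ == "__main__":
    main()
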