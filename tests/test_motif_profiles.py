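import numpy as np
import pytest

from l1locus.io_formats import GenomicInterval, SequenceRecord
from l1locus.motif_profiles import (
    YY1_MOTIF,
    check_orf0_start,
    count_reads_in_region,
    coverage_matrix,
    extract_element_prefix,
    reverse_complement,
    scan_yy1,
    sense_antisense_profiles,
)

from conftest import make_element, make_read


def genome_of(seq, name="chr1"):
    return {name: SequenceRecord(name, seq)}


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestPrefixExtraction:
    def test_plus_strand_prefix_is_verbatim(self):
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 500)
        element = make_element("e", 50, 450, "+")
        assert extract_element_prefix(genome_of(seq), element, 100) == seq[50:150]

    def test_minus_strand_prefix_is_reverse_complement_of_tail(self):
        rng = np.random.default_rng(1)
        left = random_seq(rng, 200)
        oriented_prefix = YY1_MOTIF + random_seq(rng, 89)
        # place the reverse complement of the oriented prefix at the element's
        # genomic end so the oriented sequence starts with the motif
        seq = left + reverse_complement(oriented_prefix)
        element = make_element("e", 100, len(seq), "-")
        prefix = extract_element_prefix(genome_of(seq), element, 100)
        assert prefix == oriented_prefix
        assert prefix.startswith(YY1_MOTIF)

    def test_short_element_clipped(self):
        seq = "ACGT" * 50
        element = make_element("e", 10, 70, "+")
        assert len(extract_element_prefix(genome_of(seq), element, 100)) == 60

    def test_missing_contig_errors(self):
        element = make_element("e", 0, 100, "+", contig="chrX")
        with pytest.raises(KeyError):
            extract_element_prefix(genome_of("ACGT" * 100), element)


class TestYY1Scan:
    def test_match_with_offset(self):
        prefix = "ACGTAC" + YY1_MOTIF + "A" * 50
        (hit,), summary = scan_yy1({"e": prefix})
        assert hit.present and hit.offset == 6
        assert summary == {"n_present": 1, "n_absent": 0}

    def test_single_mismatch_not_a_hit(self):
        (hit,), _ = scan_yy1({"e": "CAAGATGGCCA" + "T" * 80})
        assert not hit.present

    def test_match_overhanging_prefix_end_not_counted(self):
        # motif starting at offset 95 of a 100-base prefix would end at 106
        prefix = "T" * 95 + YY1_MOTIF
        truncated = prefix[:100]
        (hit,), _ = scan_yy1({"e": truncated})
        assert not hit.present

    def test_agrees_with_brute_force_on_random_prefixes(self):
        rng = np.random.default_rng(42)
        prefixes = {}
        expected = {}
        for i in range(1000):
            seq = random_seq(rng, 100)
            if rng.random() < 0.5:
                pos = int(rng.integers(0, 90))
                seq = seq[:pos] + YY1_MOTIF + seq[pos + len(YY1_MOTIF):]
            prefixes[f"e{i}"] = seq
            # brute-force oracle: test every start position
            expected[f"e{i}"] = any(
                seq[j : j + len(YY1_MOTIF)] == YY1_MOTIF
                for j in range(len(seq) - len(YY1_MOTIF) + 1)
            )
        hits, _ = scan_yy1(prefixes)
        assert {h.element_id: h.present for h in hits} == expected

    def test_strand_symmetry_under_reverse_complement(self):
        rng = np.random.default_rng(3)
        body = YY1_MOTIF + random_seq(rng, 189)
        flank = random_seq(rng, 50)
        plus_seq = flank + body + flank
        plus_el = make_element("e", 50, 50 + len(body), "+")
        minus_seq = reverse_complement(plus_seq)
        minus_el = make_element("e", 50, 50 + len(body), "-")
        p_plus = extract_element_prefix(genome_of(plus_seq), plus_el, 100)
        p_minus = extract_element_prefix(genome_of(minus_seq), minus_el, 100)
        assert p_plus == p_minus
        (h1,), _ = scan_yy1({"e": p_plus})
        (h2,), _ = scan_yy1({"e": p_minus})
        assert h1.present == h2.present == True  # noqa: E712

    def test_simulated_truth_recovered_exactly(self, default_sim):
        genome = default_sim.genome
        fl = [r for r in genome.te_records if r.element_id in genome.truth.yy1_elements]
        prefixes = {
            r.element_id: extract_element_prefix(genome.sequences, r, 100) for r in fl
        }
        hits, summary = scan_yy1(prefixes)
        assert {h.element_id: h.present for h in hits} == genome.truth.yy1_elements
        assert summary["n_present"] == sum(genome.truth.yy1_elements.values())


class TestORF0:
    def test_atg_intact(self):
        assert check_orf0_start("AAATGCC", 2) == ("intact", "Met")

    def test_m1t_variant_reports_threonine(self):
        assert check_orf0_start("AAACGCC", 2) == ("disrupted", "Thr")

    def test_gtg_reports_valine(self):
        assert check_orf0_start("GTGAAA", 0) == ("disrupted", "Val")

    def test_truncated_codon_errors(self):
        with pytest.raises(ValueError):
            check_orf0_start("AT", 0)

    def test_simulated_orf0_truth_recovered(self, default_sim):
        genome = default_sim.genome
        truth = genome.truth
        for rec in genome.te_records:
            if rec.element_id not in truth.orf0_intact:
                continue
            oriented = extract_element_prefix(
                genome.sequences, rec, truth.orf0_promoter_window
            )
            promoter = reverse_complement(oriented)
            status, aa = check_orf0_start(promoter, truth.orf0_offset)
            assert (status == "intact") == truth.orf0_intact[rec.element_id]
            if status == "disrupted":
                assert aa == "Thr"  # the planted M1T variant


class TestReadCounting:
    def test_overlap_counting_and_half_open_boundary(self):
        region = GenomicInterval("chr1", 0, 900)
        reads = [
            make_read("in1", 0, 100),
            make_read("in2", 800, 150),  # overlaps [800, 900)
            make_read("in3", 899, 10),
            make_read("out1", 900, 100),  # abuts, half-open: no overlap
            make_read("out2", 2000, 100),
        ]
        assert count_reads_in_region(reads, region) == 3

    def test_empty_input(self):
        assert count_reads_in_region([], GenomicInterval("chr1", 0, 900)) == 0


class TestCoverageMatrix:
    def test_no_reads_zero_inside_missing_outside(self):
        element = make_element("e", 2000, 8000, "+")
        matrix, ids = coverage_matrix(
            [], [element], {"chr1": 10000}, flank=6000, body_bins=10, flank_bin=1000
        )
        assert ids == ["e"]
        row = matrix[0]
        assert row.shape == (6 + 10 + 6,)
        # upstream flank would start at -4000: first 4 bins out of bounds
        assert np.isnan(row[:4]).all() and not np.isnan(row[4:6]).any()
        # downstream flank runs 8000..14000: last 2 bins beyond the 10 kb contig
        assert np.isnan(row[-2:]).all()
        finite = row[~np.isnan(row)]
        assert (finite == 0).all()

    def test_flat_tiling_gives_constant_body_and_empty_flanks(self):
        # element body length 6000 rescaled to 60 bins of 100 bp; reads of
        # 100 bp tiled on bin boundaries put exactly one read in each bin
        element = make_element("e", 10000, 16000, "+")
        reads = [make_read(f"r{i}", 10000 + 100 * i, length=100) for i in range(60)]
        matrix, _ = coverage_matrix(
            reads, [element], {"chr1": 40000}, flank=2000, body_bins=60, flank_bin=100
        )
        row = matrix[0]
        assert (row[20:80] == 1).all()
        assert (row[:20] == 0).all() and (row[80:] == 0).all()

    def test_rpkm_arithmetic(self):
        element = make_element("e", 10000, 11000, "+")
        reads = [make_read(f"r{i}", 10100 + i, length=100) for i in range(10)]
        matrix, _ = coverage_matrix(
            reads, [element], {"chr1": 40000},
            flank=0, body_bins=1, flank_bin=100,
            normalization="RPKM", total_mapped=1_000_000,
        )
        # 10 reads in a 1 kb bin of a 1M-read library -> RPKM 10
        assert matrix[0, 0] == pytest.approx(10.0)

    def test_minus_strand_row_reversed(self):
        element = make_element("e", 10000, 16000, "-")
        # one read at the element's genomic start = its 3' end
        reads = [make_read("r", 10000, length=100)]
        matrix, _ = coverage_matrix(
            reads, [element], {"chr1": 40000}, flank=0, body_bins=60, flank_bin=100
        )
        row = matrix[0]
        assert row[-1] == 1 and row[0] == 0

    def test_sense_antisense_split_by_element_strand(self):
        plus = make_element("p", 10000, 16000, "+")
        minus = make_element("m", 20000, 26000, "-", contig="chr1")
        fwd = [make_read("f", 12000, length=100)]
        rev = [make_read("r", 22000, length=100, flag=16)]
        sense, antisense, ids = sense_antisense_profiles(
            fwd, rev, [plus, minus], {"chr1": 40000},
            flank=0, body_bins=10, flank_bin=100,
        )
        assert ids == ["p", "m"]
        assert sense[0].sum() == 1 and sense[1].sum() == 1
        assert antisense.sum() == 0

    def test_invalid_parameters(self):
        element = make_element("e", 0, 6000, "+")
        with pytest.raises(ValueError):
            coverage_matrix([], [element], {"chr1": 10000}, flank_bin=0)
        with pytest.raises(ValueError):
            coverage_matrix([], [element], {"chr1": 10000}, body_bins=0)
        with pytest.raises(ValueError):
            coverage_matrix([], [element], {"chr1": 10000}, normalization="cpm")
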