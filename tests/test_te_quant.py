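import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from l1locus.io_formats import AlignmentRecord, GenomicInterval
from l1locus.synthetic_data import simulate_subfamily_mixture
from l1locus.te_quant import (
    aggregate_subfamily_strand,
    count_sense_antisense,
    count_unique_elements,
    em_assign_multireads,
    split_by_transcription_strand,
)

from conftest import make_element, make_read


def paired_read(read_id, flag, start=1000):
    return make_read(read_id, start, flag=flag)


class TestStrandSplit:
    @pytest.mark.parametrize(
        "flag,expected",
        [
            (163, "forward"),  # paired, proper, second mate, forward
            (83, "forward"),  # paired, proper, first mate, reverse
            (99, "reverse"),  # paired, proper, first mate, forward
            (147, "reverse"),  # paired, proper, second mate, reverse
        ],
    )
    def test_flag_routing_matches_samtools_filters(self, flag, expected):
        forward, reverse = split_by_transcription_strand([paired_read("r", flag)])
        got = "forward" if forward else "reverse"
        assert got == expected

    def test_unpaired_record_rejected_unless_single_end_rule(self):
        rec = make_read("r", 0, flag=16)
        with pytest.raises(ValueError):
            split_by_transcription_strand([rec])
        forward, reverse = split_by_transcription_strand([rec], single_end_rule=True)
        assert forward == [rec] and reverse == []

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.sampled_from([83, 99, 147, 163, 339, 355]), max_size=30))
    def test_forward_and_reverse_partition_the_input(self, flags):
        reads = [paired_read(f"r{i}", f) for i, f in enumerate(flags)]
        forward, reverse = split_by_transcription_strand(reads)
        assert len(forward) + len(reverse) == len(reads)
        assert {id(r) for r in forward} | {id(r) for r in reverse} == {
            id(r) for r in reads
        }


def naive_unique_counts(reads, annotation, max_ratio=0.03):
    """Independent O(n*m) oracle for unique-mode element counting."""
    counts = {rec.element_id: 0 for rec in annotation}
    for read in reads:
        if not read.is_primary or read.n_hits != 1:
            continue
        denom = read.mapped_length or read.interval.length
        if denom and read.mismatches / denom > max_ratio:
            continue
        hits = [
            rec.element_id
            for rec in annotation
            if rec.interval.contig == read.interval.contig
            and read.interval.start < rec.interval.end
            and rec.interval.start < read.interval.end
        ]
        if len(set(hits)) == 1:
            counts[hits[0]] += 1
    return counts


class TestUniqueCounting:
    ANNOT = [make_element("A", 1000, 7000), make_element("B", 20000, 26000, "-")]

    def test_multimappers_excluded(self):
        reads = [make_read(f"r{i}", 2000) for i in range(3)] + [
            make_read("m", 2100, n_hits=2)
        ]
        counts, report = count_unique_elements(reads, self.ANNOT)
        assert counts["A"] == 3
        assert report["filtered_multimap"] == 1

    def test_mismatch_ratio_boundary(self):
        # 8/150 = 0.053 > 0.03 fails; 4/150 = 0.027 passes
        bad = make_read("bad", 2000, mismatches=8)
        good = make_read("good", 2000, mismatches=4)
        counts, report = count_unique_elements([bad, good], self.ANNOT)
        assert counts["A"] == 1
        assert report["filtered_mismatch"] == 1

    def test_empty_input_returns_full_zero_index(self):
        counts, _ = count_unique_elements([], self.ANNOT)
        assert list(counts.index) == ["A", "B"]
        assert (counts == 0).all()

    def test_ambiguous_overlap_discarded(self):
        annot = [make_element("A", 1000, 2000), make_element("B", 1900, 3000)]
        read = make_read("r", 1850, length=100)  # spans both
        counts, report = count_unique_elements([read], annot)
        assert counts.sum() == 0
        assert report["ambiguous"] == 1

    def test_invalid_mismatch_ratio_errors(self):
        with pytest.raises(ValueError):
            count_unique_elements([], self.ANNOT, max_mismatch_ratio=1.5)

    def test_reverse_forced_counts_only_matching_strand_features(self):
        annot = [make_element("P", 1000, 7000, "+"), make_element("M", 1000, 7000, "-", contig="chr2")]
        plus_read = make_read("r1", 2000)
        minus_read = make_read("r2", 2000, contig="chr2")
        counts, _ = count_unique_elements(
            [plus_read, minus_read], annot,
            strandness="reverse-forced", transcription_strand="+",
        )
        assert counts["P"] == 1 and counts["M"] == 0

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n_feat = int(rng.integers(1, 51))
            n_reads = int(rng.integers(0, 501))
            annotation = []
            for i in range(n_feat):
                start = int(rng.integers(0, 50000))
                length = int(rng.integers(100, 8000))
                annotation.append(
                    make_element(
                        f"e{i}", start, start + length,
                        strand=rng.choice(["+", "-"]),
                        contig=f"chr{int(rng.integers(1, 4))}",
                    )
                )
            reads = [
                make_read(
                    f"r{j}",
                    int(rng.integers(0, 55000)),
                    length=int(rng.integers(50, 300)),
                    contig=f"chr{int(rng.integers(1, 4))}",
                    n_hits=int(rng.integers(1, 4)),
                    mismatches=int(rng.integers(0, 12)),
                    flag=int(rng.choice([0, 0x100])),
                )
                for j in range(n_reads)
            ]
            counts, _ = count_unique_elements(reads, annotation)
            assert counts.to_dict() == naive_unique_counts(reads, annotation)


class TestSenseAntisense:
    def test_minus_feature_sense_is_reverse_transcription(self):
        annot = [make_element("M", 0, 7000, "-")]
        fwd = pd.Series({"M": 0})
        rev = pd.Series({"M": 5})
        out = count_sense_antisense(fwd, rev, annot)
        assert out.loc["M", "sense"] == 5 and out.loc["M", "antisense"] == 0

    def test_plus_feature_counts(self):
        annot = [make_element("P", 0, 7000, "+")]
        out = count_sense_antisense(pd.Series({"P": 2}), pd.Series({"P": 3}), annot)
        assert out.loc["P", "sense"] == 2 and out.loc["P", "antisense"] == 3

    def test_no_reads_gives_zero_zero(self):
        annot = [make_element("P", 0, 7000, "+")]
        out = count_sense_antisense(pd.Series(dtype=int), pd.Series(dtype=int), annot)
        assert (out[["sense", "antisense"]] == 0).all().all()

    def test_unstranded_feature_excluded(self):
        annot = [make_element("U", 0, 7000, ".")]
        out = count_sense_antisense(pd.Series({"U": 2}), pd.Series({"U": 3}), annot)
        assert out.empty

    def test_subfamily_sums_additive_and_strand_invariant(self):
        annot = [
            make_element("a", 0, 7000, "+", subfamily="L1HS"),
            make_element("b", 10000, 17000, "-", subfamily="L1HS"),
        ]
        out = count_sense_antisense(
            pd.Series({"a": 3, "b": 1}), pd.Series({"a": 0, "b": 4}), annot
        )
        agg = aggregate_subfamily_strand(out)
        assert agg.loc["L1HS", "sense_sum"] == 3 + 4
        assert agg.loc["L1HS", "antisense_sum"] == 0 + 1
        # flipping both element strands swaps directional counts but sums are
        # element-relative, so they are unchanged
        flipped = [
            make_element("a", 0, 7000, "-", subfamily="L1HS"),
            make_element("b", 10000, 17000, "+", subfamily="L1HS"),
        ]
        out2 = count_sense_antisense(
            pd.Series({"a": 0, "b": 4}), pd.Series({"a": 3, "b": 1}), flipped
        )
        agg2 = aggregate_subfamily_strand(out2)
        pd.testing.assert_frame_equal(agg, agg2)

    def test_subset_restriction_drops_other_subfamilies(self):
        annot = [
            make_element("a", 0, 7000, "+", subfamily="L1HS"),
            make_element("b", 10000, 11000, "+", subfamily="L1MA4"),
        ]
        out = count_sense_antisense(
            pd.Series({"a": 3, "b": 9}), pd.Series({"a": 0, "b": 0}), annot
        )
        agg = aggregate_subfamily_strand(out, subset={"a"})
        assert list(agg.index) == ["L1HS"]


def em_mixture(unique_a, unique_b, ambiguous):
    """Build alignment records: unique reads on A or B and A/B-ambiguous reads."""
    annot = [
        make_element("A0", 1000, 8000, subfamily="A", contig="cA"),
        make_element("B0", 1000, 8000, subfamily="B", contig="cB"),
    ]
    reads = []
    i = 0
    for n, contig in ((unique_a, "cA"), (unique_b, "cB")):
        for _ in range(n):
            reads.append(make_read(f"u{i}", 2000, contig=contig))
            i += 1
    for j in range(ambiguous):
        reads.append(make_read(f"m{j}", 2000, contig="cA", n_hits=2))
        reads.append(make_read(f"m{j}", 2000, contig="cB", n_hits=2, flag=0x100))
    return reads, annot


class TestEMAssignment:
    def test_all_unique_converges_immediately(self):
        reads, annot = em_mixture(12, 0, 0)
        counts, report = em_assign_multireads(reads, annot)
        assert counts["A"] == 12 and counts["B"] == 0
        assert report["n_iterations"] == 0

    def test_ambiguous_mass_follows_unique_evidence(self):
        # fixed point: a = (10 + 4a)/14  =>  a = 1, so A gets all 4
        reads, annot = em_mixture(10, 0, 4)
        counts, _ = em_assign_multireads(reads, annot)
        assert counts.sum() == pytest.approx(14.0, abs=1e-9)
        assert counts["A"] == pytest.approx(14.0, abs=1e-2)
        assert counts["A"] > 12.0

    def test_symmetric_case_splits_uniformly(self):
        reads, annot = em_mixture(0, 0, 6)
        counts, _ = em_assign_multireads(reads, annot)
        assert counts["A"] == pytest.approx(3.0, abs=1e-9)
        assert counts["B"] == pytest.approx(3.0, abs=1e-9)

    def test_mass_conserved_at_every_iteration(self):
        reads, annot = em_mixture(30, 10, 25)
        trace = []
        counts, report = em_assign_multireads(reads, annot, trace=trace)
        assert len(trace) >= 1
        for snapshot in trace:
            assert snapshot.sum() == pytest.approx(65.0, abs=1e-6)

    def test_read_without_te_candidate_reported(self):
        annot = [make_element("A0", 1000, 8000, subfamily="A")]
        reads = [make_read("r", 50000)]
        counts, report = em_assign_multireads(reads, annot)
        assert counts.sum() == 0
        assert report["n_reads_no_te_candidate"] == 1

    def test_invalid_parameters(self):
        reads, annot = em_mixture(1, 1, 0)
        with pytest.raises(ValueError):
            em_assign_multireads(reads, annot, tol=0)
        with pytest.raises(ValueError):
            em_assign_multireads(reads, annot, max_iter=0)

    def test_recovers_mixture_proportions(self):
        records, annot, truth = simulate_subfamily_mixture(
            n_reads=5000, proportions=(0.8, 0.2), ambiguous_fraction=0.3, seed=11
        )
        counts, report = em_assign_multireads(records, annot)
        assert counts.sum() == pytest.approx(5000, abs=1e-6)
        est = counts / counts.sum()
        assert est["A"] == pytest.approx(truth["A"], abs=0.03)
        assert est["B"] == pytest.approx(truth["B"], abs=0.03)
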