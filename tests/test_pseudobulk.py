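import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from l1locus.pseudobulk import (
    ClusterMap,
    assign_reads_to_clusters,
    dedup_umis,
    merge_samples,
    qc_filter_cells,
    read_cluster_map,
    write_cluster_map,
)

from conftest import make_read


def metrics(rows):
    return pd.DataFrame(rows, columns=["barcode", "n_features", "mito_pct", "sample_id"])


class TestQCFilter:
    def test_high_mito_removed_in_both_modes(self):
        table = metrics(
            [("b1", 3000, 12.0, "s"), ("b2", 3000, 5.0, "s"), ("b3", 3000, 9.9, "s")]
        )
        for mode in ("adult", "fetal"):
            kept = qc_filter_cells(table, mode)
            assert ("s", "b1") not in kept
            assert ("s", "b2") in kept and ("s", "b3") in kept

    def test_fetal_absolute_feature_floor(self):
        table = metrics(
            [("lo", 1500, 1.0, "s"), ("a", 2500, 1.0, "s"), ("b", 2600, 1.0, "s"),
             ("c", 2550, 1.0, "s")]
        )
        kept = qc_filter_cells(table, "fetal")
        assert ("s", "lo") not in kept
        assert {bc for _, bc in kept} == {"a", "b", "c"}

    def test_adult_two_sd_upper_and_one_sd_lower(self):
        features = [3000, 3050, 2950, 3000, 3000, 9000, 2000]
        table = metrics(
            [(f"b{i}", nf, 1.0, "s") for i, nf in enumerate(features)]
        )
        mean, sd = np.mean(features), np.std(features, ddof=1)
        kept = {bc for _, bc in qc_filter_cells(table, "adult")}
        for i, nf in enumerate(features):
            expected = (nf <= mean + 2 * sd) and (nf >= mean - sd)
            assert (f"b{i}" in kept) == expected

    def test_stats_are_per_sample(self):
        # same feature count is an outlier in one sample, typical in the other
        table = metrics(
            [("a1", 1000, 1.0, "s1"), ("a2", 1010, 1.0, "s1"), ("a3", 990, 1.0, "s1"),
             ("a5", 1005, 1.0, "s1"), ("a6", 995, 1.0, "s1"), ("a4", 5000, 1.0, "s1"),
             ("b1", 5000, 1.0, "s2"), ("b2", 5100, 1.0, "s2"), ("b3", 4900, 1.0, "s2")]
        )
        kept = qc_filter_cells(table, "fetal")
        assert ("s1", "a4") not in kept
        assert ("s2", "b1") in kept

    def test_single_cell_sample_errors(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            qc_filter_cells(metrics([("b", 3000, 1.0, "s")]), "adult")


class TestAssignReads:
    def test_mapped_unmapped_and_missing_barcodes(self):
        cmap = ClusterMap("s", {"b1": "c0", "b2": "c1"})
        reads = [
            make_read("r1", 0, cell_barcode="b1", umi="A"),
            make_read("r2", 10, cell_barcode="b1", umi="C"),
            make_read("r3", 20, cell_barcode="b2", umi="G"),
            make_read("r4", 30),
            make_read("r5", 40, cell_barcode="zz", umi="T"),
        ]
        collections, report = assign_reads_to_clusters(reads, cmap)
        assert len(collections["c0"]) == 2 and len(collections["c1"]) == 1
        assert report["n_dropped_no_barcode"] == 1
        assert report["n_dropped_unmapped_barcode"] == 1

    def test_empty_cluster_still_emitted(self):
        cmap = ClusterMap("s", {"b1": "c0", "b2": "c1"})
        collections, _ = assign_reads_to_clusters(
            [make_read("r", 0, cell_barcode="b1")], cmap
        )
        assert collections["c1"] == []

    def test_partition_invariant(self):
        cmap = ClusterMap("s", {"b1": "c0", "b2": "c1"})
        rng = np.random.default_rng(3)
        reads = [
            make_read(
                f"r{i}", int(rng.integers(0, 1000)),
                cell_barcode=str(rng.choice(["b1", "b2", "b3", None])) if rng.random() > 0.1 else None,
            )
            for i in range(200)
        ]
        collections, report = assign_reads_to_clusters(reads, cmap)
        total = sum(len(c) for c in collections.values())
        dropped = report["n_dropped_no_barcode"] + report["n_dropped_unmapped_barcode"]
        assert total + dropped == len(reads)


class TestDedupUMIs:
    def test_same_key_collapsed(self):
        reads = [
            make_read("r1", 100, cell_barcode="b", umi="U"),
            make_read("r2", 100, cell_barcode="b", umi="U"),
        ]
        kept, report = dedup_umis(reads)
        assert len(kept) == 1 and kept[0].read_id == "r1"
        assert report["n_duplicates"] == 1

    def test_same_umi_different_barcode_both_kept(self):
        reads = [
            make_read("r1", 100, cell_barcode="b1", umi="U"),
            make_read("r2", 100, cell_barcode="b2", umi="U"),
        ]
        kept, _ = dedup_umis(reads)
        assert len(kept) == 2

    def test_same_umi_different_position_kept_under_position_key_only(self):
        reads = [
            make_read("r1", 100, cell_barcode="b", umi="U"),
            make_read("r2", 500, cell_barcode="b", umi="U"),
        ]
        assert len(dedup_umis(reads)[0]) == 2
        assert len(dedup_umis(reads, key="cb-umi")[0]) == 1

    def test_unique_umis_pass_through(self):
        reads = [
            make_read(f"r{i}", 100 * i, cell_barcode="b", umi=f"U{i}") for i in range(5)
        ]
        kept, _ = dedup_umis(reads)
        assert {r.read_id for r in kept} == {r.read_id for r in reads}

    def test_records_without_umi_dropped(self):
        kept, report = dedup_umis([make_read("r", 0, cell_barcode="b")])
        assert kept == [] and report["n_no_umi"] == 1

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 5),  # position bucket
                st.sampled_from(["U1", "U2", "U3"]),
                st.sampled_from(["b1", "b2"]),
            ),
            max_size=40,
        )
    )
    def test_idempotent(self, triples):
        reads = [
            make_read(f"r{i}", 100 * pos, cell_barcode=bc, umi=umi)
            for i, (pos, umi, bc) in enumerate(triples)
        ]
        once, _ = dedup_umis(reads)
        twice, _ = dedup_umis(once)
        assert [r.read_id for r in twice] == [r.read_id for r in once]

    def test_retained_equals_distinct_lineages_on_simulation(self, default_sim):
        truth = default_sim.truth_reads
        sn_truth = truth[truth["source"] == "sn"]
        for sample, records in default_sim.single_nucleus.items():
            primaries = [r for r in records if r.is_primary]
            kept, _ = dedup_umis(primaries)
            sample_truth = sn_truth[sn_truth["sample"] == sample]
            n_lineages = (sample_truth["duplicate_of"].fillna("") == "").sum()
            assert len(kept) == n_lineages


class TestMergeSamples:
    def test_additivity(self):
        per_sample = {
            "s1": {"c0": [make_read(f"a{i}", i) for i in range(100)]},
            "s2": {"c0": [make_read(f"b{i}", i) for i in range(50)]},
        }
        merged = merge_samples(per_sample)
        assert len(merged["c0"]) == 150

    def test_regrouping_is_union(self):
        per_sample = {
            "s1": {
                "c0": [make_read("a", 0)],
                "c1": [make_read("b", 1)],
                "c2": [make_read("c", 2)],
            }
        }
        merged = merge_samples(per_sample, regrouping={"c0": "neurons", "c1": "neurons"})
        assert {r.read_id for r in merged["neurons"]} == {"a", "b"}
        assert [r.read_id for r in merged["c2"]] == ["c"]

    def test_missing_label_treated_as_empty(self):
        per_sample = {
            "s1": {"c0": [make_read("a", 0)], "c3": [make_read("d", 3)]},
            "s2": {"c0": [make_read("b", 0)]},
        }
        merged = merge_samples(per_sample, labels=["c0", "c3"])
        assert len(merged["c3"]) == 1


class TestClusterMapIO:
    def test_round_trip(self, tmp_path):
        cmap = ClusterMap("s", {"AAAC": "c0", "GGTT": "c1"})
        p = tmp_path / "clusters.tsv"
        write_cluster_map(p, cmap)
        back = read_cluster_map(p, "s")
        assert back.mapping == cmap.mapping

    def test_duplicate_barcode_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("AAAC\tc0\nAAAC\tc1\n")
        with pytest.raises(ValueError, match="more than one cluster"):
            read_cluster_map(p, "s")
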