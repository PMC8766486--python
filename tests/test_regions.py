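"""Region construction, assignment, burden, and reference matching tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarecnv.regions import (
    assign_calls_to_regions,
    build_regions,
    gene_burden_matrix,
    harmonise_arrays,
    match_reference_variants,
    merge_gene_regions,
)

POS = np.arange(10) * 1_000 + 500  # probe grid used by count-pattern tests


def probe_map(positions=POS, chrom="1", array="dense"):
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(len(positions))],
            "chromosome": chrom,
            "position": positions,
            "array": array,
        }
    )


def calls_for_counts(counts, chrom="1"):
    """Construct calls so the per-probe distinct-carrier counts equal
    ``counts``: one call per (level, run) for the required sample count."""
    counts = np.asarray(counts)
    rows = []
    sample = 0
    for level in range(1, counts.max() + 1):
        covered = counts >= level
        edges = np.flatnonzero(np.diff(np.r_[False, covered, False]))
        for a, b in zip(edges[::2], edges[1::2]):
            rows.append(
                {
                    "sample_id": f"c{level}_{a}",
                    "chromosome": chrom,
                    "start": POS[a] - 10,
                    "end": POS[b - 1] + 10,
                    "cnv_type": "deletion",
                    "filter_flags": "",
                    "n_probes": b - a,
                    "mean_z": -5.0,
                    "start_index": a,
                    "end_index": b,
                }
            )
            sample += 1
    # distinct samples per probe: for each level the covering samples differ
    out = pd.DataFrame(rows)
    out["sample_id"] = [f"s{i}" for i in range(len(out))]
    return out


class TestBuildRegions:
    def test_merge_within_gap(self):
        # counts [6,6,6,0,0,6,6,0,0,0]: runs 0-2 and 5-6, gap of 2 -> merged
        calls = calls_for_counts([6, 6, 6, 0, 0, 6, 6, 0, 0, 0])
        regions = build_regions(calls, probe_map(), "deletion")
        assert len(regions) == 1
        r = regions.iloc[0]
        assert (r["start_index"], r["end_index"]) == (0, 7)
        assert r["start"] == POS[0] and r["end"] == POS[6] + 1

    def test_gap_above_threshold_two_regions(self):
        # runs 0-2 and 9-10: six intervening probes > 5 -> stay separate
        calls = calls_for_counts([5, 5, 5, 0, 0, 0, 0, 0, 0, 5])
        regions = build_regions(calls, probe_map(), "deletion")
        assert len(regions) == 2

    def test_below_threshold_no_regions(self):
        calls = calls_for_counts([4] * 10)
        regions = build_regions(calls, probe_map(), "deletion")
        assert regions.empty

    def test_boundary_gap_exactly_five_merged(self):
        calls = calls_for_counts([5, 0, 0, 0, 0, 0, 5, 5, 0, 0])
        regions = build_regions(calls, probe_map(), "deletion", merge_gap_probes=5)
        assert len(regions) == 1

    def test_translation_invariance(self):
        calls = calls_for_counts([6, 6, 6, 0, 0, 6, 6, 0, 0, 0])
        r1 = build_regions(calls, probe_map(), "deletion")
        shifted_calls = calls.assign(start=calls["start"] + 7_777, end=calls["end"] + 7_777)
        r2 = build_regions(
            shifted_calls, probe_map(POS + 7_777), "deletion"
        )
        assert (r2["start"] - r1["start"] == 7_777).all()
        assert r1[["start_index", "end_index"]].equals(r2[["start_index", "end_index"]])

    def test_idempotence_via_assignment(self):
        calls = calls_for_counts([6, 6, 6, 0, 0, 6, 6, 0, 0, 0])
        regions = build_regions(calls, probe_map(), "deletion")
        _, table = assign_calls_to_regions(
            calls, regions, calls["sample_id"].unique()
        )
        assigned = calls[calls["sample_id"].isin(table["sample_id"])]
        rebuilt = build_regions(assigned, probe_map(), "deletion")
        pd.testing.assert_frame_equal(rebuilt, regions)


class TestMergeGeneRegions:
    anchors = pd.DataFrame(
        {"gene": ["BRCA1"], "chromosome": ["1"], "start": [1_000], "end": [6_000]}
    )

    def region(self, rid, start, end):
        return {
            "region_id": rid, "chromosome": "1", "start": start, "end": end,
            "start_index": 0, "end_index": 1, "n_probes": 1,
            "cnv_type": "deletion", "source_array": "dense",
        }

    def test_overlapping_regions_merged(self):
        regions = pd.DataFrame([self.region("a", 500, 2_000), self.region("b", 5_000, 8_000)])
        merged = merge_gene_regions(regions, self.anchors)
        assert len(merged) == 1
        assert merged.iloc[0]["start"] == 500 and merged.iloc[0]["end"] == 8_000

    def test_untouched_region_unchanged(self):
        regions = pd.DataFrame([self.region("a", 20_000, 30_000)])
        merged = merge_gene_regions(regions, self.anchors)
        pd.testing.assert_frame_equal(merged, regions)

    def test_three_regions_inside_anchor(self):
        regions = pd.DataFrame(
            [self.region("a", 1_100, 1_500), self.region("b", 2_000, 2_500),
             self.region("c", 3_000, 3_500)]
        )
        merged = merge_gene_regions(regions, self.anchors)
        assert len(merged) == 1


class TestAssignCalls:
    regions = pd.DataFrame(
        [{
            "region_id": "r1", "chromosome": "1", "start": 1_000, "end": 50_000,
            "start_index": 0, "end_index": 10, "n_probes": 10,
            "cnv_type": "deletion", "source_array": "dense",
        }]
    )

    def call(self, start, end, sample="a"):
        return pd.DataFrame(
            [{
                "sample_id": sample, "chromosome": "1", "start": start, "end": end,
                "cnv_type": "deletion", "filter_flags": "", "n_probes": 5,
                "mean_z": -5.0, "start_index": 0, "end_index": 5,
            }]
        )

    def test_high_fraction_assigned(self):
        # overlap 39000 of length 39100 = 99.7%
        cm, table = assign_calls_to_regions(self.call(900, 40_000), self.regions, ["a"])
        assert len(table) == 1
        assert table.iloc[0]["fraction"] == pytest.approx(39_000 / 39_100)
        assert cm.column("r1")[0] == 1

    def test_low_fraction_unassigned(self):
        cm, table = assign_calls_to_regions(self.call(0, 100_000), self.regions, ["a"])
        assert table.empty
        assert cm.column("r1")[0] == 0

    def test_binary_coding_two_calls_one_sample(self):
        calls = pd.concat([self.call(1_000, 10_000), self.call(20_000, 30_000)])
        cm, table = assign_calls_to_regions(calls, self.regions, ["a"])
        assert len(table) == 2
        assert cm.column("r1")[0] == 1  # still a 0/1 indicator

    def test_largest_fraction_wins(self):
        two = pd.concat(
            [self.regions.assign(region_id="r1"),
             self.regions.assign(region_id="r2", start=900, end=30_000)],
            ignore_index=True,
        )
        _, table = assign_calls_to_regions(self.call(1_000, 29_000), two, ["a"])
        assert table.iloc[0]["region_id"] == "r2"

    @settings(max_examples=50, deadline=None)
    @given(
        call_start=st.integers(0, 80_000),
        call_len=st.integers(1, 60_000),
        region_start=st.integers(0, 80_000),
        region_len=st.integers(1, 60_000),
    )
    def test_assigned_iff_fraction_reaches_threshold(
        self, call_start, call_len, region_start, region_len
    ):
        regions = self.regions.assign(start=region_start, end=region_start + region_len)
        call = self.call(call_start, call_start + call_len)
        _, table = assign_calls_to_regions(call, regions, ["a"])
        # brute-force overlap
        ov = max(
            0,
            min(call_start + call_len, region_start + region_len)
            - max(call_start, region_start),
        )
        frac = ov / call_len
        assert (len(table) == 1) == (frac >= 0.9)


class TestHarmoniseArrays:
    dense_regions = pd.DataFrame(
        [{
            "region_id": "d1", "chromosome": "1", "start": 1_000, "end": 50_000,
            "start_index": 0, "end_index": 10, "n_probes": 10,
            "cnv_type": "deletion", "source_array": "dense",
        }]
    )

    def sparse_calls(self, rows):
        return pd.DataFrame(
            [
                {
                    "sample_id": f"s{i}", "chromosome": "1", "start": s, "end": e,
                    "cnv_type": "deletion", "filter_flags": "", "n_probes": 4,
                    "mean_z": -5.0, "start_index": 0, "end_index": 4,
                }
                for i, (s, e) in enumerate(rows)
            ]
        )

    def test_sparse_call_into_dense_region(self):
        calls = self.sparse_calls([(2_000, 40_000)])
        combined, assignment = harmonise_arrays(
            calls, self.dense_regions, probe_map(POS * 100, array="sparse"), "deletion"
        )
        assert assignment.iloc[0]["region_id"] == "d1"
        assert combined.loc[combined["region_id"] == "d1", "provenance"].iloc[0] == "both"

    def test_leftover_builds_sparse_regions(self):
        pm = probe_map(np.arange(10) * 10_000 + 200_000, array="sparse")
        rows = [(200_000, 230_000)] * 6  # far from the dense region
        calls = self.sparse_calls(rows)
        combined, assignment = harmonise_arrays(calls, self.dense_regions, pm, "deletion")
        assert assignment.empty
        prov = combined["provenance"].value_counts().to_dict()
        assert prov.get("sparse_only", 0) == 1 and prov.get("dense", 0) == 1


class TestGeneBurden:
    genes = pd.DataFrame(
        {
            "gene": ["G1", "G1", "G2"],
            "chromosome": ["1", "1", "1"],
            "start": [10_000, 20_000, 500_000],
            "end": [11_000, 21_000, 501_000],
        }
    )

    def calls(self, intervals, sample_prefix="s"):
        return pd.DataFrame(
            [
                {
                    "sample_id": f"{sample_prefix}{i}", "chromosome": "1",
                    "start": s, "end": e, "cnv_type": "deletion",
                    "filter_flags": "", "n_probes": 3, "mean_z": -5.0,
                    "start_index": 0, "end_index": 3,
                }
                for i, (s, e) in enumerate(intervals)
            ]
        )

    def test_exon_overlap_is_carrier(self):
        calls = self.calls([(20_500, 22_000)])  # covers exon 2 of G1 only
        samples = calls["sample_id"].to_numpy()
        cm, summary = gene_burden_matrix(calls, self.genes, "deletion", samples, min_carriers=1)
        assert cm.column("G1")[0] == 1

    def test_intronic_call_not_carrier(self):
        calls = self.calls([(12_000, 19_000)])  # between the exons
        samples = calls["sample_id"].to_numpy()
        cm, summary = gene_burden_matrix(calls, self.genes, "deletion", samples, min_carriers=1)
        assert "G1" not in set(cm.unit_ids)
        assert summary.loc[summary["gene"] == "G1", "n_carriers"].iloc[0] == 0

    def test_min_carrier_threshold(self):
        calls23 = self.calls([(10_500, 10_600)] * 23)
        samples = calls23["sample_id"].to_numpy()
        cm, summary = gene_burden_matrix(calls23, self.genes, "deletion", samples)
        assert "G1" not in set(cm.unit_ids)  # 23 carriers < 24
        calls24 = self.calls([(10_500, 10_600)] * 24)
        samples = calls24["sample_id"].to_numpy()
        cm, _ = gene_burden_matrix(calls24, self.genes, "deletion", samples)
        assert cm.column("G1").sum() == 24

    def test_empty_exons_skipped_with_warning(self):
        genes = pd.concat(
            [self.genes, pd.DataFrame({"gene": ["BAD"], "chromosome": ["1"], "start": [5], "end": [5]})]
        )
        with pytest.warns(UserWarning, match="BAD"):
            _, summary = gene_burden_matrix(
                self.calls([(10_500, 10_600)]), genes, "deletion", ["s0"], min_carriers=1
            )
        assert "BAD" not in set(summary["gene"])

    def test_column_sums_match_counts(self):
        calls = self.calls([(10_500, 10_600)] * 30 + [(500_100, 500_200)] * 25)
        samples = calls["sample_id"].to_numpy()
        cm, summary = gene_burden_matrix(calls, self.genes, "deletion", samples)
        counts = cm.carrier_counts
        for gene in cm.unit_ids:
            assert counts[gene] == summary.loc[summary["gene"] == gene, "n_carriers"].iloc[0]


class TestMatchReference:
    reference = pd.DataFrame(
        {
            "variant_id": ["v1", "v2", "v3"],
            "chromosome": ["1", "1", "1"],
            "start": [10_000, 10_000, 90_000],
            "end": [20_000, 20_000, 95_000],
            "cnv_type": ["deletion", "duplication", "deletion"],
            "frequency": [0.005, 0.005, 0.05],  # v3 is common: excluded
        }
    )

    def call(self, start, end, cnv_type="deletion"):
        return pd.DataFrame(
            [{
                "sample_id": "a", "chromosome": "1", "start": start, "end": end,
                "cnv_type": cnv_type, "filter_flags": "", "n_probes": 3,
                "mean_z": -5.0, "start_index": 0, "end_index": 3,
            }]
        )

    def test_identical_call_matched(self):
        table, summary = match_reference_variants(self.call(10_000, 20_000), self.reference)
        assert table.iloc[0]["matched_variant"] == "v1"
        assert summary["fraction_calls_matched"] == 1.0

    def test_opposite_type_unmatched(self):
        # only the duplication v2 covers it, but the call is a deletion at 90% cut
        table, _ = match_reference_variants(
            self.call(10_000, 20_000, "duplication"), self.reference
        )
        assert table.iloc[0]["matched_variant"] == "v2"
        table2, _ = match_reference_variants(self.call(30_000, 40_000), self.reference)
        assert table2.iloc[0]["matched_variant"] is None

    def test_common_reference_excluded_from_denominator(self):
        _, summary = match_reference_variants(self.call(10_000, 20_000), self.reference)
        assert summary["n_reference"] == 2  # v3 dropped at frequency >= 1%
        assert summary["fraction_reference_hit"] == pytest.approx(0.5)


def test_region_recovery_on_called_cohort(called_cohort):
    """>=95% of planted variants with enough carriers yield exactly one
    region covering the planted midpoint."""
    truth = called_cohort["truth"]
    calls = called_cohort["result"].calls
    pm = called_cohort["probe_map"]
    recovered = 0
    eligible = 0
    for cnv_type in ("deletion", "duplication"):
        regions = build_regions(calls, pm, cnv_type, min_carriers=5)
        for t in truth:
            if t.cnv_type != cnv_type or len(t.carrier_samples) < 8:
                continue
            eligible += 1
            mid = (t.start + t.end) // 2
            cover = regions[
                (regions["chromosome"] == t.chromosome)
                & (regions["start"] <= mid)
                & (regions["end"] > mid)
            ]
            recovered += len(cover) == 1
    assert eligible >= 6
    assert recovered / eligible >= 0.95
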