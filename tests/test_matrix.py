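"""Strand merging, percentage formula, filters and environment calls."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smnmeth.matrix import (
    assign_environment,
    build_matrix,
    filter_depth,
    haplotype_matrix,
    mask_snv_cpgs,
    merge_strands,
    methylation_percent,
    restrict_to_regions,
)
from smnmeth.types import (
    ENV_MIXED,
    ENV_NONE,
    ENV_SMN1,
    ENV_SMN2,
    CpGSite,
    HaplotypeRecord,
    MethylationCall,
    Region,
    RegionSet,
    SnvTable,
)

from conftest import make_matrix


def snv_table(rows):
    return SnvTable(pd.DataFrame(rows, columns=list(SnvTable.REQUIRED)))


class TestMethylationPercent:
    @pytest.mark.parametrize("n_mod,n_can,expected", [
        (0, 100, 0.0), (50, 50, 50.0), (100, 0, 100.0), (1, 3, 25.0),
    ])
    def test_values(self, n_mod, n_can, expected):
        assert methylation_percent(n_mod, n_can) == expected

    def test_zero_depth_missing(self):
        assert np.isnan(methylation_percent(0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            methylation_percent(-1, 5)

    @settings(deadline=None)
    @given(st.integers(0, 10**6), st.integers(0, 10**6))
    def test_matches_rational_oracle(self, n_mod, n_can):
        if n_mod + n_can == 0:
            assert np.isnan(methylation_percent(n_mod, n_can))
        else:
            exact = Fraction(100 * n_mod, n_mod + n_can)
            assert abs(methylation_percent(n_mod, n_can) - float(exact)) < 1e-12


class TestMergeStrands:
    CPG = [CpGSite("chr5", 100)]

    def test_hand_summed_counts(self):
        calls = [MethylationCall("chr5", 100, "+", 10, 10),
                 MethylationCall("chr5", 101, "-", 30, 10)]
        res = merge_strands(calls, self.CPG)
        merged = res.merged[("chr5", 100)]
        assert (merged.n_mod, merged.n_can) == (40, 20)
        assert methylation_percent(merged.n_mod, merged.n_can) == pytest.approx(
            200 / 3
        )

    def test_single_strand(self):
        res = merge_strands([MethylationCall("chr5", 100, "+", 5, 5)], self.CPG)
        merged = res.merged[("chr5", 100)]
        assert (merged.n_mod, merged.n_can) == (5, 5)

    def test_off_target_reported_not_merged(self):
        res = merge_strands([MethylationCall("chr5", 200, "+", 5, 5)], self.CPG)
        assert res.merged == {}
        assert len(res.off_target) == 1

    def test_unknown_strand_assigned_by_position(self):
        calls = [MethylationCall("chr5", 100, ".", 3, 1),
                 MethylationCall("chr5", 101, ".", 1, 3)]
        res = merge_strands(calls, self.CPG)
        merged = res.merged[("chr5", 100)]
        assert (merged.n_mod, merged.n_can) == (4, 4)

    def test_duplicate_same_strand_error(self):
        calls = [MethylationCall("chr5", 100, "+", 1, 1),
                 MethylationCall("chr5", 100, "+", 2, 2)]
        with pytest.raises(ValueError, match="duplicate"):
            merge_strands(calls, self.CPG)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(
        st.tuples(st.integers(0, 9), st.booleans(), st.integers(0, 50),
                  st.integers(0, 50), st.integers(0, 10)),
        max_size=20, unique_by=lambda t: (t[0], t[1]),
    ))
    def test_count_conservation(self, spec):
        """Total modified/canonical/filtered counts survive merging."""
        cpgs = [CpGSite("chr5", 10 * i) for i in range(10)]
        calls = [
            MethylationCall("chr5", 10 * i + (1 if rev else 0),
                            "-" if rev else "+", m, c, f)
            for i, rev, m, c, f in spec
        ]
        res = merge_strands(calls, cpgs)
        for attr in ("n_mod", "n_can", "n_filt"):
            total_in = sum(getattr(c, attr) for c in calls)
            total_out = sum(getattr(c, attr) for c in res.merged.values())
            total_off = sum(getattr(c, attr) for c in res.off_target)
            assert total_in == total_out + total_off


class TestFilters:
    def test_depth_boundary(self):
        mat = make_matrix(np.array([[50.0, 50.0]]),
                          depth=np.array([[99, 100]]))
        out = filter_depth(mat, min_depth=100)
        assert np.isnan(out.percent.iloc[0, 0])
        assert out.percent.iloc[0, 1] == 50.0
        assert out.depth.iloc[0, 0] == 99  # depth retained for reporting

    def test_min_depth_one(self):
        mat = make_matrix(np.array([[50.0, 50.0]]), depth=np.array([[0, 1]]))
        out = filter_depth(mat, min_depth=1)
        assert np.isnan(out.percent.iloc[0, 0]) and out.percent.iloc[0, 1] == 50.0

    def test_region_restriction_half_open(self):
        mat = make_matrix(np.full((2, 1), 50.0), start=71_375_000,
                          spacing=50_000)  # sites at 71375000 and 71425000
        regions = RegionSet([Region("chr5", 71_375_000, 71_425_000, "ROI")])
        out = restrict_to_regions(mat, regions)
        assert list(out.sites["c_pos"]) == [71_375_000]
        assert out.sites["region"].tolist() == ["ROI"]

    def test_empty_region_set(self):
        mat = make_matrix(np.full((2, 1), 50.0))
        out = restrict_to_regions(mat, RegionSet([]))
        assert out.n_sites == 0

    def test_filters_never_add_values(self, rng):
        mat = make_matrix(rng.uniform(0, 100, (5, 3)),
                          depth=rng.integers(0, 300, (5, 3)))
        out = filter_depth(mat, 100)
        was_missing = mat.percent.isna()
        assert out.percent.isna()[was_missing].all().all()


class TestSnvMasking:
    def test_snv_at_g_removes_site(self):
        mat = make_matrix(np.full((2, 1), 50.0), start=100, spacing=50)
        snvs = snv_table([{"chrom": "chr5", "pos": 101, "ref": "G", "alt": "A",
                           "environment_marker": ENV_NONE}])
        out, report = mask_snv_cpgs(mat, snvs)
        assert out.n_sites == 1
        assert report["snv_role"].tolist() == ["G"]
        assert report["site_id"].tolist() == ["chr5:100"]

    def test_snv_before_c_keeps_site(self):
        mat = make_matrix(np.full((1, 1), 50.0), start=100)
        snvs = snv_table([{"chrom": "chr5", "pos": 99, "ref": "A", "alt": "T",
                           "environment_marker": ENV_NONE}])
        out, report = mask_snv_cpgs(mat, snvs)
        assert out.n_sites == 1 and report.empty

    def test_empty_snv_table_identity(self):
        mat = make_matrix(np.full((3, 2), 40.0))
        out, report = mask_snv_cpgs(mat, SnvTable.empty())
        pd.testing.assert_frame_equal(out.percent, mat.percent)
        assert report.empty


class TestBuildMatrix:
    def test_single_site_pipeline(self, cpg_sites):
        calls = {"S1": [MethylationCall("chr5", 71_375_100, "+", 60, 40)]}
        mat, _ = build_matrix(calls, cpg_sites[:1], min_depth=100)
        assert mat.percent.iloc[0, 0] == 60.0

    def test_depth_filter_applied(self, cpg_sites):
        calls = {"S1": [MethylationCall("chr5", 71_375_100, "+", 40, 40)]}
        mat, _ = build_matrix(calls, cpg_sites[:1], min_depth=100)
        assert np.isnan(mat.percent.iloc[0, 0])
        assert mat.depth.iloc[0, 0] == 80

    def test_call_rate_reported(self, cpg_sites):
        calls = {
            "S1": [MethylationCall("chr5", 71_375_100, "+", 60, 40)],
            "S2": [],
        }
        mat, _ = build_matrix(calls, cpg_sites[:1], min_depth=100)
        assert mat.sites["call_rate"].iloc[0] == 0.5

    def test_filter_order_logged(self, cpg_sites):
        calls = {"S1": [MethylationCall("chr5", 71_375_100, "+", 60, 40)]}
        regions = RegionSet([Region("chr5", 71_375_000, 71_425_000, "ROI")])
        mat, _ = build_matrix(calls, cpg_sites, regions, SnvTable.empty(), 100)
        kinds = [f.split("(")[0] for f in mat.filters_applied]
        assert kinds == ["on-target", "depth>=100", "snv-mask"]


class TestHaplotypeMatrix:
    def test_one_column_per_haplotype(self, cpg_sites):
        recs = [
            HaplotypeRecord("S1", h, [MethylationCall("chr5", 71_375_100, "+", h, 10)])
            for h in (1, 2, 3)
        ]
        mat, _ = haplotype_matrix(recs, cpg_sites[:1])
        assert mat.samples == ["S1|hap1", "S1|hap2", "S1|hap3"]

    def test_zero_coverage_missing(self, cpg_sites):
        recs = [HaplotypeRecord("S1", 1, []),
                HaplotypeRecord("S1", 2, [MethylationCall("chr5", 71_375_100, "+", 5, 5)])]
        mat, _ = haplotype_matrix(recs, cpg_sites[:1])
        assert np.isnan(mat.percent.loc["chr5:71375100", "S1|hap1"])
        assert mat.percent.loc["chr5:71375100", "S1|hap2"] == 50.0

    def test_haplotype_counts_sum_to_pooled(self):
        """Complete phasing: per-haplotype merged counts add up to the
        unphased sample's merged counts."""
        from smnmeth.simulate import (build_truth, scenario_config,
                                      simulate_cohort, simulate_haplotypes)

        config = scenario_config("environment-contrast")
        cohort = simulate_cohort(config, 5)
        truth = build_truth(config, cohort, 6)
        hap = simulate_haplotypes(config, cohort, truth, 7)
        cpgs = [CpGSite(r["chrom"], r["c_pos"]) for _, r in truth.sites.iterrows()]
        sample = cohort[0].sample_id
        hap_mat, _ = haplotype_matrix(
            [r for r in hap.records if r.sample_id == sample], cpgs)
        pooled_mat, _ = build_matrix({sample: hap.pooled[sample]}, cpgs, min_depth=1)
        hap_depth = hap_mat.depth.sum(axis=1)
        pd.testing.assert_series_equal(
            hap_depth, pooled_mat.depth[sample], check_names=False
        )


MARKERS = snv_table([
    {"chrom": "chr5", "pos": 100 + i, "ref": "T", "alt": "A",
     "environment_marker": ENV_SMN1}
    for i in range(5)
])


class TestAssignEnvironment:
    def test_unanimous_smn1(self):
        geno = {100 + i: "A" for i in range(5)}
        assert assign_environment(geno, MARKERS) == ENV_SMN1

    def test_unanimous_smn2_via_ref(self):
        geno = {100 + i: "T" for i in range(5)}
        assert assign_environment(geno, MARKERS) == ENV_SMN2

    def test_discordant_is_mixed(self):
        geno = {100: "A", 101: "A", 102: "A", 103: "T", 104: "T"}
        assert assign_environment(geno, MARKERS) == ENV_MIXED

    def test_no_markers_covered(self):
        assert assign_environment({}, MARKERS) == ENV_MIXED

    def test_partial_coverage_still_unanimous(self):
        assert assign_environment({102: "A"}, MARKERS) == ENV_SMN1


class TestSnvDilution:
    def test_destroyed_copies_dilute_pooled_methylation(self):
        """k of K copies destroyed and read as canonical: pooled apparent
        methylation approaches m*(K-k)/K at high depth."""
        from smnmeth.simulate import (build_truth, scenario_config,
                                      simulate_cohort, simulate_matrix)

        config = scenario_config("snv-artifact", depth_median=20000.0)
        cohort = simulate_cohort(config, 8)
        truth = build_truth(config, cohort, 9)
        mat = simulate_matrix(config, cohort, truth, 10)
        site = truth.sites.index[truth.artifacts[0].site]
        depth = mat.depth.loc[site].sum()
        n_mod = (mat.percent.loc[site] * mat.depth.loc[site] / 100).sum()
        pooled = 100 * n_mod / depth
        target = 80.0 * (2 - 1) / 2
        se = 100 * np.sqrt(0.4 * 0.6 / depth)
        assert abs(pooled - target) < 3 * se
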