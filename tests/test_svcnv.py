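"""SV/CNV cascade: interval kernels, flags, matching, oracle equivalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wgspanel.svcnv import (
    RegionSet,
    assign_max_af,
    associate_genes,
    build_footprints,
    frequency_flag,
    gene_footprint,
    match_cnv_calls,
    q0_flag,
    reciprocal_overlap,
    region_exclusion_flag,
    run_sv_cascade,
)


def sv_row(**overrides):
    row = {
        "id": "S1", "sv_type": "DEL", "chrom1": "pc1", "pos1": 0,
        "chrom2": "pc1", "pos2": 1000, "caller": "A",
        "q0": np.nan, "gtscore": np.nan,
    }
    row.update(overrides)
    return pd.Series(row)


class TestReciprocalOverlap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((100, 200), (100, 200), 1.0),
            ((0, 100), (20, 100), 0.8),
            ((0, 100), (200, 300), 0.0),
            ((1000, 2000), (1100, 2000), 0.9),
        ],
    )
    def test_examples(self, a, b, expected):
        assert reciprocal_overlap(a, b) == pytest.approx(expected)

    def test_zero_length_interval_rejected(self):
        with pytest.raises(ValueError):
            reciprocal_overlap((5, 5), (0, 10))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a0=st.integers(0, 1000), al=st.integers(1, 500),
        b0=st.integers(0, 1000), bl=st.integers(1, 500),
    )
    def test_symmetric_bounded_and_identity(self, a0, al, b0, bl):
        a, b = (a0, a0 + al), (b0, b0 + bl)
        ro = reciprocal_overlap(a, b)
        assert ro == reciprocal_overlap(b, a)
        assert 0.0 <= ro <= 1.0
        assert (ro == 1.0) == (a == b)


class TestQ0Flag:
    @pytest.mark.parametrize(
        "q0,gt,expected",
        [
            (0.6, 0.3, True),    # extreme q0, decent genotype score
            (0.6, 0.2, False),   # genotype score < 0.25 waives the flag
            (0.4, 0.9, False),   # q0 within [0, 0.5]
            (-1.0, 0.5, True),   # negative q0 is extreme
            (0.5, 0.9, False),   # boundary q0 = 0.5 not extreme
        ],
    )
    def test_rule(self, q0, gt, expected):
        assert q0_flag(sv_row(caller="B", q0=q0, gtscore=gt)) is expected

    def test_missing_q0_is_a_data_error(self):
        with pytest.raises(ValueError):
            q0_flag(sv_row(caller="B", q0=np.nan))


class TestMatchCnvCalls:
    def a(self, **kw):
        return pd.DataFrame([sv_row(caller="A", **kw)])

    def b(self, **kw):
        return pd.DataFrame([sv_row(caller="B", id="S2", **kw)])

    def test_concordant_pair(self):
        out = match_cnv_calls(
            self.a(pos1=1000, pos2=2000), self.b(pos1=1100, pos2=2000)
        )
        assert out["concordant"].all()
        assert out["reciprocal_overlap"].iloc[0] == pytest.approx(0.9)

    def test_type_mismatch_not_matched(self):
        out = match_cnv_calls(
            self.a(pos1=1000, pos2=2000, sv_type="DEL"),
            self.b(pos1=1000, pos2=2000, sv_type="DUP"),
        )
        assert not out["concordant"].any()
        assert (out["flags"].str.contains("SINGLE_CALLER")).all()

    def test_empty_other_caller_flags_everything(self):
        out = match_cnv_calls(self.a(), self.b().iloc[:0])
        assert not out["concordant"].any()
        assert out["flags"].str.contains("MANUAL_REVIEW").all()

    def test_overlap_below_threshold_not_concordant(self):
        out = match_cnv_calls(self.a(pos1=0, pos2=1000), self.b(pos1=500, pos2=1500))
        assert not out["concordant"].any()

    def test_non_cnv_types_rejected(self):
        with pytest.raises(ValueError):
            match_cnv_calls(self.a(sv_type="INV"), self.b())

    def test_one_to_one_matching(self, sv_bundle):
        from wgspanel.svcnv import CNV_TYPES

        cnv_a = sv_bundle.calls_a[sv_bundle.calls_a["sv_type"].isin(CNV_TYPES)]
        cnv_b = sv_bundle.calls_b[sv_bundle.calls_b["sv_type"].isin(CNV_TYPES)]
        out = match_cnv_calls(cnv_a, cnv_b)
        partners = out.loc[out["concordant"], "partner_id"]
        assert partners.is_unique
        assert out["concordant"].sum() // 2 <= min(len(cnv_a), len(cnv_b))


class TestRegionExclusion:
    def test_span_coverage_at_threshold(self):
        regions = RegionSet([("pc1", 0, 800)])
        assert region_exclusion_flag(sv_row(pos1=0, pos2=1000), regions)

    def test_span_coverage_below_threshold(self):
        regions = RegionSet([("pc1", 0, 799)])
        assert not region_exclusion_flag(sv_row(pos1=0, pos2=1000), regions)

    def test_union_coverage_across_disjoint_regions(self):
        regions = RegionSet([("pc1", 0, 400), ("pc1", 500, 900)])
        assert region_exclusion_flag(sv_row(pos1=0, pos2=1000), regions)

    def test_translocation_breakpoint_overlap(self):
        regions = RegionSet([("pc1", 400, 600)])
        v = sv_row(sv_type="TRA", pos1=500, chrom2="pc3", pos2=999_999)
        assert region_exclusion_flag(v, regions)

    def test_no_regions_no_flag(self):
        assert not region_exclusion_flag(sv_row(), RegionSet())

    def test_coverage_agrees_with_brute_force_scan(self):
        """Union-coverage kernel vs an O(n·m) per-base reference on random sets."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(1, 200))
            regs = []
            for _ in range(n):
                s = int(rng.integers(0, 5000))
                regs.append(("pc1", s, s + int(rng.integers(1, 400))))
            rs = RegionSet(regs)
            q0 = int(rng.integers(0, 5000))
            q1 = q0 + int(rng.integers(1, 1000))
            mask = np.zeros(q1 - q0, dtype=bool)
            for _, s, e in regs:
                lo, hi = max(s, q0), min(e, q1)
                if hi > lo:
                    mask[lo - q0:hi - q0] = True
            assert rs.coverage_fraction("pc1", q0, q1) == pytest.approx(mask.mean())


class TestFrequencyFlag:
    resource = pd.DataFrame(
        [
            {"sv_type": "DEL", "chrom1": "pc1", "pos1": 0, "chrom2": "pc1",
             "pos2": 1000, "af": 0.10},
            {"sv_type": "INS", "chrom1": "pc2", "pos1": 5000, "chrom2": "pc2",
             "pos2": 5000, "af": 0.40},
        ]
    )

    def test_matching_del_above_5pct_flags(self):
        v = sv_row(pos1=50, pos2=1000)  # reciprocal overlap 0.95
        assert frequency_flag(v, {"r": self.resource})

    def test_af_exactly_5pct_not_flagged(self):
        res = self.resource.copy()
        res.loc[0, "af"] = 0.05
        assert not frequency_flag(sv_row(), {"r": res})

    def test_ins_beyond_100bp_window_not_assigned(self):
        v = sv_row(sv_type="INS", chrom1="pc2", pos1=5150, chrom2="pc2", pos2=5150)
        assert assign_max_af(v, self.resource) == 0.0

    def test_ins_within_window_assigned(self):
        v = sv_row(sv_type="INS", chrom1="pc2", pos1=5080, chrom2="pc2", pos2=5080)
        assert assign_max_af(v, self.resource) == pytest.approx(0.40)

    def test_low_overlap_not_assigned(self):
        v = sv_row(pos1=700, pos2=1700)
        assert assign_max_af(v, self.resource) == 0.0


class TestGeneFootprint:
    def test_plus_strand_upstream_extension(self):
        fp = gene_footprint("G", "pc1", 10_000, 15_000, "+")
        assert (fp.start, fp.end) == (8_000, 15_000)

    def test_minus_strand_mirror(self):
        fp = gene_footprint("G", "pc1", 10_000, 15_000, "-")
        assert (fp.start, fp.end) == (10_000, 17_000)

    def test_clipping_at_chromosome_bounds(self):
        fp = gene_footprint("G", "pc1", 500, 900, "+")
        assert (fp.start, fp.end) == (0, 900)
        fp2 = gene_footprint("G", "pc1", 500, 900, "-", chrom_length=2_000)
        assert (fp2.start, fp2.end) == (500, 2_000)

    def test_strandless_mode(self):
        fp = gene_footprint("G", "pc1", 10_000, 15_000, "-", strand_aware=False)
        assert (fp.start, fp.end) == (8_000, 15_000)

    def test_invalid_strand(self):
        with pytest.raises(ValueError):
            gene_footprint("G", "pc1", 0, 10, ".")


class TestAssociateGenes:
    # footprint = [1000, 4000) after the 2000-bp upstream extension
    footprints = build_footprints(
        pd.DataFrame(
            [{"gene": "APC", "chrom": "pc1", "tx_start": 3000, "tx_end": 4000, "strand": "+"}]
        )
    )

    def test_cnv_any_overlap(self):
        # a single base of overlap with the footprint suffices for a CNV
        assert associate_genes(sv_row(pos1=0, pos2=1001), self.footprints) == ["APC"]
        assert associate_genes(sv_row(pos1=0, pos2=1000), self.footprints) == []

    def test_inversion_needs_breakpoint_inside(self):
        # spans the footprint entirely but both breakpoints outside
        v = sv_row(sv_type="INV", pos1=0, pos2=5000)
        assert associate_genes(v, self.footprints) == []
        v2 = sv_row(sv_type="INV", pos1=2000, pos2=5000)
        assert associate_genes(v2, self.footprints) == ["APC"]

    def test_no_footprints(self):
        assert associate_genes(sv_row(), []) == []


class TestCascade:
    def test_empty_inputs(self, sv_bundle):
        empty = sv_bundle.calls_a.iloc[:0]
        pri, audit = run_sv_cascade(
            empty, empty, sv_bundle.regions, sv_bundle.freq_resources, [], sv_bundle.panel
        )
        assert len(pri) == 0 and len(audit) == 0

    def test_matches_generator_ground_truth(self, sv_bundle):
        fps = build_footprints(sv_bundle.genes)
        pri, audit = run_sv_cascade(
            sv_bundle.calls_a, sv_bundle.calls_b, sv_bundle.regions,
            sv_bundle.freq_resources, fps, sv_bundle.panel,
        )
        truth = pd.concat([sv_bundle.calls_a, sv_bundle.calls_b], ignore_index=True)
        got = audit.set_index("id")["retained"]
        want = truth.set_index(truth["id"].astype(str))["truth_keep"]
        assert (got.loc[want.index] == want).all()

    def test_single_caller_records_kept_with_review_flag(self, sv_bundle):
        fps = build_footprints(sv_bundle.genes)
        pri, audit = run_sv_cascade(
            sv_bundle.calls_a, sv_bundle.calls_b, sv_bundle.regions,
            sv_bundle.freq_resources, fps, sv_bundle.panel,
        )
        single = pri[pri["flags"].str.contains("SINGLE_CALLER")]
        assert len(single) > 0
        assert single["flags"].str.contains("MANUAL_REVIEW").all()

    def test_multiple_flags_listed_in_audit(self, sv_bundle):
        regions = RegionSet([("pc1", 0, 2000)])
        call = pd.DataFrame([sv_row(pos1=0, pos2=1000)])
        res = {"r": pd.DataFrame([
            {"sv_type": "DEL", "chrom1": "pc1", "pos1": 0, "chrom2": "pc1",
             "pos2": 1000, "af": 0.5}
        ])}
        pri, audit = run_sv_cascade(
            call, call.iloc[:0], regions, res, [], sv_bundle.panel
        )
        assert len(pri) == 0
        assert "EXCLUDED_REGION" in audit.loc[0, "flags"]
        assert "COMMON" in audit.loc[0, "flags"]


def test_bed_round_trip(tmp_path, sv_bundle):
    from wgspanel.io import read_bed, write_bed

    path = tmp_path / "regions.bed"
    write_bed(sv_bundle.regions, path)
    back = read_bed(path)
    pd.testing.assert_frame_equal(sv_bundle.regions.to_frame(), back.to_frame())
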