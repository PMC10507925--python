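"""Generators: determinism, parameter validation, label consistency, fixture."""

import pandas as pd
import pytest

from wgspanel.smallvar import run_small_variant_cascade
from wgspanel.synth import (
    SUBPOPULATIONS,
    GeneratorParams,
    chromosome_lengths,
    gen_cohort_fixture,
    gen_econ_config,
    gen_region_resources,
    gen_small_variants,
    gen_sv_bundle,
    gen_sv_cnv,
    make_panel,
)


class TestParams:
    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            GeneratorParams(n_small_variants=-1)

    def test_proportion_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            GeneratorParams(fraction_common=1.5)


class TestSmallVariants:
    def test_zero_variants_gives_empty_table_with_header(self):
        df = gen_small_variants(GeneratorParams(seed=1, n_small_variants=0))
        assert len(df) == 0
        assert "truth_keep" in df.columns and "gnex_nfe" in df.columns

    def test_seed_determinism(self):
        p = GeneratorParams(seed=42, n_small_variants=150)
        a, b = gen_small_variants(p), gen_small_variants(p)
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv() == b.to_csv()

    def test_all_common_no_rescue_means_all_dropped(self):
        p = GeneratorParams(seed=7, n_small_variants=300, fraction_common=1.0,
                            fraction_clinvar_lp_p=0.0)
        df = gen_small_variants(p)
        assert not df["truth_keep"].any()

    def test_labels_match_independent_rule_application(self):
        # the cascade is the second, independent route to the same labels
        p = GeneratorParams(seed=7, n_small_variants=300, fraction_common=0.3)
        df = gen_small_variants(p)
        _, audit = run_small_variant_cascade(df, make_panel(p), SUBPOPULATIONS)
        assert (audit["keep"].values == df["truth_keep"].values).all()

    def test_value_ranges(self, small_table):
        assert small_table["vaf"].between(0, 1).all()
        af_cols = [c for c in small_table.columns if c.startswith(("gnex_", "gnge_"))]
        for c in af_cols + ["cohort_af", "inhouse_af"]:
            assert small_table[c].between(0, 1).all()
        assert small_table["pos"].ge(1).all()


class TestSvGenerators:
    def test_zero_svs(self):
        a, b = gen_sv_cnv(GeneratorParams(seed=1, n_sv_per_caller=0))
        assert len(a) == 0 and len(b) == 0

    def test_determinism(self):
        p = GeneratorParams(seed=9, n_sv_per_caller=40)
        a1, b1 = gen_sv_cnv(p)
        a2, b2 = gen_sv_cnv(p)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_caller_roles(self, sv_bundle):
        assert set(sv_bundle.calls_b["sv_type"]) <= {"DEL", "DUP"}
        assert sv_bundle.calls_b["q0"].notna().all()
        # non-CNV types exist and only in caller A
        assert (sv_bundle.calls_a["sv_type"].isin(["INV", "INS", "TRA"])).any()

    def test_overlap_mix_is_controllable(self, sv_bundle):
        """Some cross-caller DEL/DUP pairs sit above and some below 80% RO."""
        from wgspanel.svcnv import CNV_TYPES, reciprocal_overlap

        ros = []
        b_by_chrom = sv_bundle.calls_b.groupby("chrom1")
        for _, ra in sv_bundle.calls_a[sv_bundle.calls_a["sv_type"].isin(CNV_TYPES)].iterrows():
            if ra["chrom1"] not in b_by_chrom.groups:
                continue
            for _, rb in b_by_chrom.get_group(ra["chrom1"]).iterrows():
                if rb["sv_type"] != ra["sv_type"]:
                    continue
                ro = reciprocal_overlap((ra["pos1"], ra["pos2"]), (rb["pos1"], rb["pos2"]))
                if ro > 0:
                    ros.append(ro)
        assert any(r >= 0.8 for r in ros) and any(r < 0.8 for r in ros)


class TestRegions:
    def test_zero_regions(self):
        rs, _ = gen_region_resources(GeneratorParams(seed=1, n_exclusion_regions=0))
        assert len(rs) == 0

    def test_gene_count_and_intervals(self):
        p = GeneratorParams(seed=3, n_genes=101)
        _, genes = gen_region_resources(p)
        panel_genes = genes[~genes["gene"].str.startswith("NP")]
        assert len(panel_genes) == 101
        assert (genes["tx_end"] > genes["tx_start"]).all()

    def test_intervals_within_genome(self):
        p = GeneratorParams(seed=3)
        rs, genes = gen_region_resources(p)
        lengths = chromosome_lengths(p)
        for _, r in rs.to_frame().iterrows():
            assert 0 <= r["start"] < r["end"] <= lengths[r["chrom"]]
        for _, g in genes.iterrows():
            assert 0 <= g["tx_start"] < g["tx_end"] <= lengths[g["chrom"]]


class TestCohortFixture:
    def test_headline_tallies(self, cohort):
        cases, variants = cohort
        assert len(cases) == 195
        assert len(variants) == 119
        assert (variants["acmg_class"].isin(["LP", "P"])).sum() == 31
        assert (variants["acmg_class"] == "VUS").sum() == 88
        tiers = variants.loc[variants["acmg_class"] == "VUS", "vus_tier"].value_counts()
        assert tiers["A"] == 7 and tiers["B"] == 54 and tiers["C"] == 27

    def test_case_characteristics(self, cohort):
        cases, _ = cohort
        assert (cases["sex"] == "F").sum() == 141
        assert (cases["prior_testing"] == "uninformative").sum() == 140
        assert (cases["prior_testing"] == "none").sum() == 55
        assert [
            int(cases[c].sum())
            for c in ("elig_syndrome", "elig_two_primaries", "elig_three_primaries",
                      "elig_polyposis", "elig_multi_criteria")
        ] == [28, 83, 52, 29, 42]
        ages = cases["age_at_first_diagnosis"]
        assert (ages <= 18).sum() == 16
        assert ages.between(19, 49).sum() == 125
        assert (ages >= 50).sum() == 54
        assert cases["recruitment_site"].value_counts().to_dict() == {
            "VIC": 58, "QLD": 46, "NSW": 29, "WA": 27, "SA": 21, "TAS": 14
        }

    def test_phenotype_category_totals(self, cohort):
        from wgspanel.synth import PHENOTYPE_CATEGORIES

        cases, _ = cohort
        counts: dict[str, int] = {}
        for lst in cases["phenotypes"].str.split("|"):
            assert len(lst) >= 1
            assert len(set(lst)) == len(lst)
            for cat in lst:
                counts[cat] = counts.get(cat, 0) + 1
        assert counts == dict(PHENOTYPE_CATEGORIES)

    def test_flag_consistency(self, cohort):
        _, variants = cohort
        assert not (variants["causal_for_phenotype"] & variants["secondary_finding"]).any()
        vus = variants["acmg_class"] == "VUS"
        assert (variants.loc[vus, "vus_tier"].isin(["A", "B", "C"])).all()
        assert (variants.loc[~vus, "vus_tier"] == "").all()

    def test_fixture_is_deterministic(self, cohort):
        cases2, variants2 = gen_cohort_fixture()
        pd.testing.assert_frame_equal(cohort[0], cases2)
        pd.testing.assert_frame_equal(cohort[1], variants2)


def test_econ_config_carries_published_parameters():
    cfg = gen_econ_config()
    assert cfg.referred_national == 13230
    assert cfg.offered_targeted_proportion == pytest.approx(0.3504)
    assert cfg.wgs_uptake_s2 == pytest.approx(0.796)
    assert cfg.wgs_uptake_s3 == pytest.approx(0.968)
    assert cfg.wgs_yield_s3 == pytest.approx(0.384)
    assert cfg.cost_wgs == 1750
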