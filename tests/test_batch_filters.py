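"""GQ20Mx, differential-GQ and LD filters, the combined pipeline, summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wgsbatch as wb
from wgsbatch import FilterParams

from conftest import build_cohort, random_cohort


class TestPearsonChi2:
    def test_closed_form_example(self):
        # 200 x (90*50 - 10*50)^2 / (100*100*140*60) = 38.095...
        chi2, p = wb.pearson_chi2_2x2(90, 10, 50, 50)
        assert chi2 == pytest.approx(38.0952, abs=1e-3)
        assert p == pytest.approx(6.7e-10, rel=0.02)

    def test_moderate_table_not_significant(self):
        chi2, p = wb.pearson_chi2_2x2(60, 40, 50, 50)
        assert chi2 == pytest.approx(2.02, abs=0.01)
        assert p == pytest.approx(0.155, abs=0.01)

    def test_zero_margin_is_unset(self):
        chi2, p = wb.pearson_chi2_2x2(0, 0, 5, 5)
        assert np.isnan(chi2) and np.isnan(p)

    def test_yates_is_less_extreme(self):
        plain = wb.pearson_chi2_2x2(30, 10, 10, 30)[0]
        yates = wb.pearson_chi2_2x2(30, 10, 10, 30, yates=True)[0]
        assert yates < plain

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            wb.pearson_chi2_2x2(-1, 1, 1, 1)


class TestGqMissingnessFilter:
    def _cohort(self, low_gq_count, n=10):
        geno = np.ones((1, n), dtype=np.int8)
        gq = np.full((1, n), 90.0)
        gq[0, :low_gq_count] = 19.0
        return build_cohort(geno, gq=gq)

    def test_above_threshold_filtered(self):
        _, dec = wb.gq_missingness_filter(self._cohort(4))  # 40% > 30%
        assert bool(dec["filtered"].iloc[0])
        assert "GQ20M30" in dec["filter"].iloc[0]

    def test_exact_boundary_retained(self):
        _, dec = wb.gq_missingness_filter(self._cohort(3))  # exactly 30%
        assert not bool(dec["filtered"].iloc[0])

    def test_clean_site_identity(self):
        cohort = self._cohort(0)
        masked, dec = wb.gq_missingness_filter(cohort)
        assert not bool(dec["filtered"].iloc[0])
        np.testing.assert_array_equal(masked.genotype, cohort.genotype)

    def test_original_missing_stays_missing(self):
        geno = np.array([[1, -1, 1, 1]], dtype=np.int8)
        gq = np.array([[19.0, np.nan, 90.0, 90.0]])
        masked, dec = wb.gq_missingness_filter(build_cohort(geno, gq=gq))
        np.testing.assert_array_equal(masked.genotype[0], [-1, -1, 1, 1])
        assert dec["missing_rate_post_mask"].iloc[0] == pytest.approx(0.5)

    def test_absent_gq_treated_as_low_with_warning(self):
        geno = np.ones((1, 4), dtype=np.int8)
        gq = np.array([[np.nan, 90.0, 90.0, 90.0]])
        with pytest.warns(UserWarning, match="lack a GQ"):
            masked, _ = wb.gq_missingness_filter(build_cohort(geno, gq=gq))
        assert masked.genotype[0, 0] == -1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_monotone_nesting_of_presets(self, seed):
        cohort = random_cohort(np.random.default_rng(seed), n_sites=80, n_samples=30)
        removed = {}
        for name in ("GQ20M05", "GQ20M10", "GQ20M30"):
            _, dec = wb.gq_missingness_filter(cohort, FilterParams.preset(name))
            removed[name] = set(dec.loc[dec["filtered"], "pos"])
        assert removed["GQ20M30"] <= removed["GQ20M10"] <= removed["GQ20M05"]


def _diffgq_cohort(b1_hi, b1_lo, b2_hi, b2_lo, genotype_code=1):
    """One site whose `genotype_code` class has the given GQ60 table."""
    n1, n2 = b1_hi + b1_lo, b2_hi + b2_lo
    geno = np.full((1, n1 + n2), genotype_code, dtype=np.int8)
    gq = np.concatenate(
        [
            np.full(b1_hi, 80.0),
            np.full(b1_lo, 40.0),
            np.full(b2_hi, 80.0),
            np.full(b2_lo, 40.0),
        ]
    )[None, :]
    batch = ["g1"] * n1 + ["g2"] * n2
    return build_cohort(geno, gq=gq), batch


class TestDifferentialGqFilter:
    def test_strong_differential_filtered(self):
        cohort, batch = _diffgq_cohort(90, 10, 50, 50)
        dec = wb.differential_gq_filter(cohort, batch)
        assert bool(dec["filtered"].iloc[0])
        assert dec["p_het"].iloc[0] == pytest.approx(6.7e-10, rel=0.02)

    def test_moderate_differential_retained(self):
        cohort, batch = _diffgq_cohort(60, 40, 50, 50)
        dec = wb.differential_gq_filter(cohort, batch)
        assert not bool(dec["filtered"].iloc[0])
        assert dec["p_het"].iloc[0] == pytest.approx(0.155, abs=0.01)

    def test_identical_distributions_null(self):
        cohort, batch = _diffgq_cohort(50, 50, 50, 50)
        dec = wb.differential_gq_filter(cohort, batch)
        assert not bool(dec["filtered"].iloc[0])
        assert dec["p_het"].iloc[0] == pytest.approx(1.0)

    def test_class_with_zero_margin_skipped(self):
        # every genotype is het and every GQ >= 60: the GQ margin is zero
        cohort, batch = _diffgq_cohort(50, 0, 50, 0)
        dec = wb.differential_gq_filter(cohort, batch)
        assert not bool(dec["filtered"].iloc[0])
        assert np.isnan(dec["p_het"].iloc[0])

    def test_classes_tested_independently(self):
        # hom-alt carries the differential signal while het is balanced:
        # the site must be filtered on the hom-alt test alone
        geno = np.concatenate([np.full(200, 2), np.full(200, 1)])[None, :].astype(np.int8)
        gq = np.empty((1, 400))
        gq[0, 0:100] = 80.0  # g1 hom-alt: all high
        gq[0, 100:200] = 40.0  # g2 hom-alt: all low
        gq[0, 200:250] = 80.0  # g1 het: 50/50
        gq[0, 250:300] = 40.0
        gq[0, 300:350] = 80.0  # g2 het: 50/50
        gq[0, 350:400] = 40.0
        batch = ["g1"] * 100 + ["g2"] * 100 + ["g1"] * 100 + ["g2"] * 100
        cohort = build_cohort(geno, gq=gq)
        dec = wb.differential_gq_filter(cohort, batch)
        assert bool(dec["filtered"].iloc[0])
        assert dec["p_hom_alt"].iloc[0] < 1e-4
        assert dec["p_het"].iloc[0] == pytest.approx(1.0)

    def test_invariant_to_gq_shift_not_crossing_boundary(self):
        cohort, batch = _diffgq_cohort(70, 30, 40, 60)
        base = wb.differential_gq_filter(cohort, batch)
        shifted = build_cohort(
            cohort.genotype.copy(), gq=cohort.gq + 10.0
        )  # 40->50, 80->90: still straddle 60 identically
        after = wb.differential_gq_filter(shifted, batch)
        assert base["p_het"].iloc[0] == pytest.approx(after["p_het"].iloc[0])
        assert bool(base["filtered"].iloc[0]) == bool(after["filtered"].iloc[0])

    def test_requires_two_batches(self):
        cohort, batch = _diffgq_cohort(5, 5, 5, 5)
        with pytest.raises(ValueError, match="2 batch labels"):
            wb.differential_gq_filter(cohort, ["g1"] * len(batch))

    def test_null_rejection_rate_under_permuted_labels(self):
        # permuted labels break any batch link: per-class rejections ~ alpha
        rng = np.random.default_rng(11)
        cohort, infos, _ = wb.generate_cohort(
            wb.SyntheticSpec(n_samples_per_batch=(250, 250), n_sites=2000), seed=11
        )
        batch = rng.permutation([s.batch for s in infos])
        dec = wb.differential_gq_filter(cohort, batch)
        # expected site removals ~ 2000 * (up to 3 classes) * 1e-4 = 0.6
        assert int(dec["filtered"].sum()) <= 6


class TestLdConcordanceFilter:
    def _records(self, rows):
        frame = pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "alt", "variant_class", "p_value", "status"]
        )
        return frame

    def test_verdicts(self):
        orig = self._records(
            [
                ("1", 100, "A", "G", "SNP", 1e-9, "ok"),
                ("1", 200, "C", "T", "SNP", 1e-9, "ok"),
                ("1", 300, "A", "C", "SNP", 1e-5, "ok"),
                ("1", 400, "G", "T", "SNP", 1e-10, "ok"),
            ]
        )
        corr = self._records(
            [
                ("1", 100, "A", "G", "SNP", 1e-3, "ok"),  # lost significance
                ("1", 200, "C", "T", "SNP", 1e-9, "ok"),  # still GWS
                ("1", 300, "A", "C", "SNP", 1e-6, "ok"),  # not eligible
                # 400 absent from the corrected run
            ]
        )
        dec = wb.ld_concordance_filter(orig, corr)
        by_pos = dec.set_index("pos")
        assert bool(by_pos.loc[100, "filtered"])
        assert not bool(by_pos.loc[200, "filtered"])
        assert not bool(by_pos.loc[300, "filtered"])
        assert not bool(by_pos.loc[300, "applicable"])
        assert bool(by_pos.loc[400, "filtered"])
        assert "absent" in by_pos.loc[400, "reason"]

    def test_empty_join_raises(self):
        orig = self._records([("1", 100, "A", "G", "SNP", 1e-9, "ok")])
        corr = self._records([("2", 500, "C", "T", "SNP", 1e-9, "ok")])
        with pytest.raises(ValueError, match="no sites join"):
            wb.ld_concordance_filter(orig, corr)


class TestRegionMaskFilter:
    def test_coordinate_convention(self):
        sites = [wb.VariantSite("chr1", p, "A", "G") for p in (15, 20, 21)]
        mask = wb.RegionSet([("chr1", 10, 20)], "mask")
        dec = wb.region_mask_filter(sites, mask)
        assert list(dec["filtered"]) == [True, True, False]

    def test_empty_mask_filters_nothing(self):
        sites = [wb.VariantSite("chr1", 15, "A", "G")]
        dec = wb.region_mask_filter(sites, wb.RegionSet([], "empty"))
        assert not dec["filtered"].any()


@pytest.fixture(scope="module")
def synthetic_run():
    cohort, infos, truth = wb.generate_cohort(
        wb.SyntheticSpec(n_samples_per_batch=(250, 250), n_sites=400), seed=21
    )
    batch = [s.batch for s in infos]
    pheno = np.asarray([s.phenotype for s in infos], dtype=float)
    records = wb.logistic_assoc(cohort, pheno)
    corrected = wb.logistic_assoc(wb.make_ld_corrected(cohort, truth), pheno)
    return cohort, batch, truth, records, corrected


class TestRecommendedPipeline:
    def test_attribution_is_sequential_and_union_stable(self, synthetic_run):
        cohort, batch, truth, records, corrected = synthetic_run
        dec, summary = wb.recommended_pipeline(cohort, batch, records, corrected)
        removed = set(dec.loc[dec["filtered"], "pos"])
        # union equals the union of the three filters run independently
        params = FilterParams()
        gws = wb.genome_wide_significant(records, params.gws_threshold)
        keys = set(records.loc[gws, "pos"])
        sub = cohort.subset_sites(np.asarray([s.pos in keys for s in cohort.sites]))
        ld = wb.ld_concordance_filter(records, corrected, params)
        dgq = wb.differential_gq_filter(sub, batch, params)
        _, gq20 = wb.gq_missingness_filter(sub, params)
        union = (
            set(ld.loc[ld["filtered"], "pos"])
            | set(dgq.loc[dgq["filtered"], "pos"])
            | set(gq20.loc[gq20["filtered"], "pos"])
        ) & keys
        assert removed == union
        # attribution: anything LD removed is credited to LD
        ld_removed = set(ld.loc[ld["filtered"], "pos"]) & keys
        credited_ld = set(dec.loc[dec["filter"] == "LD", "pos"])
        assert ld_removed == credited_ld
        summary.table  # cumulative counts are monotone
        assert (summary.table["n_cumulative"].diff().fillna(0) >= 0).all()

    def test_skips_ld_stage_with_warning(self, synthetic_run):
        cohort, batch, _, records, _ = synthetic_run
        with pytest.warns(UserWarning, match="skipping the LD stage"):
            dec, _ = wb.recommended_pipeline(cohort, batch, records, None)
        assert (dec["filter"] != "LD").all()


class TestSummaries:
    def test_summarize_counts_and_universe_check(self):
        universe = [wb.VariantSite("1", p, "A", "G") for p in (100, 200)] + [
            wb.VariantSite("1", 300, "AT", "A")
        ]
        decisions = pd.DataFrame(
            {
                "chrom": ["1", "1", "1"],
                "pos": [100, 200, 300],
                "ref": ["A", "A", "AT"],
                "alt": ["G", "G", "A"],
                "filter": ["DiffGQ", "DiffGQ", "GQ20M30"],
                "filtered": [True, False, True],
            }
        )
        summary = wb.summarize(decisions, universe)
        table = summary.table.set_index("filter")
        assert table.loc["DiffGQ", "n_removed"] == 1
        assert table.loc["DiffGQ", "n_removed_snp"] == 1
        assert table.loc["GQ20M30", "n_removed_indel"] == 1
        assert summary.n_removed_total == 2
        with pytest.raises(ValueError, match="absent from the universe"):
            wb.summarize(decisions, universe[:1])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    a=st.integers(1, 40),
    b=st.integers(1, 40),
    c=st.integers(1, 40),
    d=st.integers(1, 40),
)
def test_chi2_matches_scipy_contingency(a, b, c, d):
    from scipy.stats import chi2_contingency

    chi2, p = wb.pearson_chi2_2x2(a, b, c, d)
    ref_chi2, ref_p, _, _ = chi2_contingency([[a, b], [c, d]], correction=False)
    assert chi2 == pytest.approx(ref_chi2, rel=1e-10)
    assert p == pytest.approx(ref_p, rel=1e-9)
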