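import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonarch.ccf import (
    annotate_mutations,
    call_cohort,
    ccf_grid,
    ccf_posterior,
    classify_clonality,
    expected_vaf,
    ks_uniformity,
)
from conftest import naive_ccf_posterior


class TestExpectedVaf:
    @pytest.mark.parametrize(
        "purity,ccf,cn,expected",
        [
            (1.0, 1.0, 2, 0.5),
            (0.5, 1.0, 2, 0.25),
            (0.6, 0.5, 3, 0.3 / 2.6),
        ],
    )
    def test_known_values(self, purity, ccf, cn, expected):
        assert expected_vaf(purity, ccf, cn) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_locus_errors(self):
        with pytest.raises(ValueError):
            expected_vaf(1.0, 0.5, 0)


class TestGrid:
    def test_grid_contract(self):
        g = ccf_grid()
        assert len(g) == 100
        assert g[0] == pytest.approx(0.01)
        assert g[-1] == pytest.approx(1.0)
        assert np.allclose(np.diff(g), 0.01)


class TestPosterior:
    def test_zero_alt_reads_force_minimal_ccf(self):
        post = ccf_posterior(0, 1000, 0.8, 2)
        assert post.map_ccf == pytest.approx(0.01)
        assert post.p_subclonal > 0.99

    def test_vaf_at_clonal_expectation_maps_to_one(self):
        # observed VAF 0.25 equals the CCF=1 expectation at purity 0.5, cn 2
        post = ccf_posterior(25, 100, 0.5, 2)
        assert post.map_ccf == pytest.approx(1.0)

    def test_subclonal_vaf_maps_near_truth(self):
        # expected VAF = 0.25 * CCF, observed 0.10 -> CCF 0.40
        post = ccf_posterior(10, 100, 0.5, 2)
        assert abs(post.map_ccf - 0.40) <= 0.01 + 1e-12
        assert classify_clonality(post) == "subclonal"

    def test_matches_naive_direct_probability_oracle(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(200):
            depth = int(rng.integers(10, 400))
            t = int(rng.integers(0, depth + 1))
            purity = float(rng.uniform(0.1, 1.0))
            cn = int(rng.integers(1, 5))
            naive = naive_ccf_posterior(t, depth, purity, cn)
            if naive is None:
                continue
            post = ccf_posterior(t, depth, purity, cn)
            worst = max(worst, 0.5 * np.abs(post.probs - naive).sum())
        assert worst <= 1e-9

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        depth=st.integers(1, 5000),
        frac=st.floats(0.0, 1.0),
        purity=st.floats(0.05, 1.0),
        cn=st.integers(1, 6),
    )
    def test_posterior_normalization_property(self, depth, frac, purity, cn):
        t = min(depth, int(round(frac * depth)))
        post = ccf_posterior(t, depth, purity, cn)
        assert post.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert post.ci_low <= post.map_ccf <= post.ci_high

    def test_map_monotone_in_alt_reads(self):
        maps = [ccf_posterior(t, 120, 0.6, 2).map_ccf for t in range(0, 121, 5)]
        assert all(b >= a for a, b in zip(maps, maps[1:]))


class TestClassification:
    def test_point_mass_at_one_is_clonal(self):
        post = ccf_posterior(500, 1000, 1.0, 2)  # VAF 0.5 = clonal expectation
        assert post.ci_high == pytest.approx(1.0)
        assert classify_clonality(post) == "clonal"

    def test_point_mass_below_threshold_is_subclonal(self):
        post = ccf_posterior(150, 1000, 1.0, 2)  # VAF 0.15 -> CCF 0.30
        assert post.map_ccf == pytest.approx(0.30)
        assert classify_clonality(post) == "subclonal"

    def test_label_invariant_from_stored_posterior(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            depth = int(rng.integers(30, 300))
            t = int(rng.integers(0, depth + 1))
            post = ccf_posterior(t, depth, float(rng.uniform(0.2, 1.0)), 2)
            label = classify_clonality(post)
            subclonal = post.ci_high < post.grid[-1] - 1e-12 and post.p_subclonal > 0.5
            assert (label == "subclonal") == subclonal


class TestAnnotate:
    def test_exclusion_reasons(self, toy_bundle):
        annotated, skip = annotate_mutations(toy_bundle)
        assert {a.mutation.gene for a in annotated} == {"TP53", "APC", "SIL"}
        reasons = dict(zip(skip["gene"], skip["reason"]))
        assert reasons == {
            "GX": "non-autosome",
            "DEL0": "homozygous-deletion",
            "NOSEG": "no-segment",
        }

    def test_local_cn_from_covering_segment(self, toy_bundle):
        annotated, _ = annotate_mutations(toy_bundle)
        by_gene = {a.mutation.gene: a for a in annotated}
        assert by_gene["APC"].local_cn == 3
        assert by_gene["TP53"].purity == 0.6


class TestCallCohort:
    def test_silent_mutations_excluded(self, toy_bundle):
        out = call_cohort(toy_bundle)
        assert "SIL" not in set(out.calls["gene"])
        assert (out.skip_report["reason"] == "silent").sum() == 1

    def test_counts_conserved_per_gene(self, small_cohort):
        _, bundle, _ = small_cohort
        out = call_cohort(bundle)
        for gene, summ in out.gene_summaries.items():
            assert summ.c1 + summ.s1 == (out.calls["gene"] == gene).sum()
            total = (
                summ.patients_clonal_only
                + summ.patients_subclonal_only
                + summ.patients_both
                + summ.patients_wt
            )
            assert total == len(bundle.clinical)

    def test_unmutated_patients_counted_wt(self, toy_bundle):
        out = call_cohort(toy_bundle)
        # 3 patients, TP53 mutated in 1 -> 2 WT
        assert out.gene_summaries["TP53"].patients_wt == 2

    def test_batch_calls_match_single_mutation_path(self, small_cohort):
        _, bundle, _ = small_cohort
        out = call_cohort(bundle)
        sample = out.calls.sample(20, random_state=0)
        for row in sample.itertuples():
            post = ccf_posterior(row.t_alt, row.t_depth, row.purity, row.local_cn)
            assert post.map_ccf == pytest.approx(row.map_ccf)
            assert post.ci_high == pytest.approx(row.ci_high)
            assert post.p_subclonal == pytest.approx(row.p_subclonal, abs=1e-9)
            assert classify_clonality(post) == row.label


class TestKsUniformity:
    def test_equally_spaced_values_small_statistic(self):
        # exact D for these 3 points is 0.25 (both one-sided deviations)
        stat, p, ok = ks_uniformity([0.25, 0.5, 0.75])
        assert ok and stat == pytest.approx(0.25, abs=1e-12)

    def test_point_mass_large_statistic(self):
        stat, p, ok = ks_uniformity([0.99] * 100)
        assert ok and stat >= 0.98 and p < 1e-3

    def test_too_few_values_not_evaluable(self):
        stat, p, ok = ks_uniformity([0.2, 0.8])
        assert not ok and stat is None and p is None
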