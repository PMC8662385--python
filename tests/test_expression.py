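"""Unit and property tests for TPM computation and enrichment filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from orthoverlap import (
    abundance_filter,
    compute_tpm,
    differential_test,
    select_enriched,
)
from orthoverlap.errors import (
    ConfigurationError,
    DegenerateInputError,
    ParameterError,
)
from orthoverlap.expression import _ttest
from orthoverlap.simulate import SyntheticConfig, generate

from conftest import make_study


class TestComputeTpm:
    def test_single_gene_single_sample_gets_the_whole_million(self):
        study = make_study({"g1": [7.0, 7.0]}, lengths={"g1": 500})
        tpm = compute_tpm(study)
        assert tpm.values.iloc[0, 0] == pytest.approx(1_000_000)

    def test_length_correction_splits_equal_counts_by_length(self):
        # equal counts, g2 half the length of g1 -> twice the rate
        study = make_study(
            {"g1": [10.0, 1.0], "g2": [10.0, 1.0]}, lengths={"g1": 1000, "g2": 500}
        )
        tpm = compute_tpm(study)
        assert tpm.values.loc["g1", "s1"] == pytest.approx(333_333.33, abs=0.01)
        assert tpm.values.loc["g2", "s1"] == pytest.approx(666_666.67, abs=0.01)

    def test_zero_count_gives_zero_tpm(self):
        study = make_study(
            {"g1": [0.0, 5.0], "g2": [3.0, 2.0]}, lengths={"g1": 100, "g2": 100}
        )
        tpm = compute_tpm(study)
        assert tpm.values.loc["g1", "s1"] == 0.0

    def test_missing_lengths_is_a_configuration_error(self):
        study = make_study({"g1": [1.0, 1.0]})
        with pytest.raises(ConfigurationError):
            compute_tpm(study)

    def test_all_zero_sample_is_degenerate_and_named(self):
        study = make_study({"g1": [0.0, 5.0], "g2": [0.0, 2.0]}, lengths={"g1": 100, "g2": 100})
        with pytest.raises(DegenerateInputError, match="s1"):
            compute_tpm(study)

    @given(seed=st.integers(0, 10_000))
    def test_every_sample_column_sums_to_one_million(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        counts = rng.integers(0, 1000, size=(n, 4)).astype(float)
        counts[rng.integers(0, n)] += 1  # keep columns non-degenerate
        study = make_study(
            {f"g{i}": counts[i] for i in range(n)},
            lengths={f"g{i}": int(rng.integers(200, 5000)) for i in range(n)},
        )
        tpm = compute_tpm(study)
        assert np.allclose(tpm.values.sum(axis=0), 1e6, atol=1e-3)


class TestAbundanceFilter:
    def test_below_threshold_gene_is_removed(self):
        study = make_study({"g1": [0.03, 0.02], "g2": [5.0, 5.0]}, kind="tpm")
        kept = abundance_filter(study, 0.1)
        assert "g1" not in kept and "g2" in kept

    def test_boundary_value_is_retained(self):
        study = make_study({"g1": [0.05, 0.05]}, kind="tpm")
        assert "g1" in abundance_filter(study, 0.1)

    def test_zero_threshold_retains_everything(self):
        study = make_study({"g1": [0.0, 0.0], "g2": [1.0, 2.0]}, kind="tpm")
        assert len(abundance_filter(study, 0.0)) == 2

    def test_planted_zero_genes_are_exactly_the_removed_ones(self):
        cfg = SyntheticConfig(
            n_single_copy=100, n_multi_copy=0, n_species_specific_a=0,
            n_species_specific_b=0, planted_enriched_size=0, planted_target_size=0,
            planted_overlap=0, planted_zero_size=10, seed=3,
        )
        bundle = generate(cfg)
        kept = abundance_filter(compute_tpm(bundle.study), 0.1)
        assert len(kept) == 90
        assert set(bundle.truth.zero_genes_a) == set(bundle.study.gene_ids) - kept.ids


class TestDifferentialTest:
    def test_identical_groups_give_fold_one_and_p_one(self):
        study = make_study({"g1": [4.0, 4.0, 4.0, 4.0, 4.0, 4.0]}, kind="tpm")
        de = differential_test(study, fc_pseudocount=0.0)
        assert de.loc["g1", "fold_change"] == pytest.approx(1.0)
        assert de.loc["g1", "p_value"] == pytest.approx(1.0)

    def test_fold_change_is_ratio_of_group_means(self):
        study = make_study({"g1": [8.0, 8.0, 8.0, 2.0, 2.0, 2.0]}, kind="tpm")
        de = differential_test(study, fc_pseudocount=0.0)
        assert de.loc["g1", "fold_change"] == pytest.approx(4.0)

    def test_single_replicate_in_both_groups_is_an_error(self):
        study = make_study({"g1": [1.0, 2.0]}, kind="tpm")
        with pytest.raises(DegenerateInputError):
            differential_test(study)

    def test_swapping_groups_inverts_fold_and_keeps_p(self):
        rng = np.random.default_rng(1)
        vals = rng.gamma(2.0, 50.0, size=(50, 6))
        study = make_study({f"g{i}": vals[i] for i in range(50)}, kind="tpm")
        flipped = make_study(
            {f"g{i}": vals[i] for i in range(50)},
            groups={f"s{i + 1}": ("B" if i < 3 else "A") for i in range(6)},
            kind="tpm",
        )
        de = differential_test(study, fc_pseudocount=0.0)
        de_f = differential_test(flipped, fc_pseudocount=0.0)
        assert np.allclose(de["fold_change"], 1.0 / de_f["fold_change"])
        assert np.allclose(de["p_value"], de_f["p_value"])

    def test_matches_scipy_on_generic_data(self, rng):
        """Cross-check both t variants against scipy.stats.ttest_ind."""
        a = rng.normal(5.0, 2.0, size=(200, 4))
        b = rng.normal(5.0, 1.0, size=(200, 3))
        for pooled in (True, False):
            t, p = _ttest(a, b, var_floor=1e-300, pooled=pooled)
            t_ref, p_ref = stats.ttest_ind(a, b, axis=1, equal_var=pooled)
            np.testing.assert_allclose(t, t_ref, rtol=1e-10)
            np.testing.assert_allclose(p, p_ref, rtol=1e-10)

    def test_type_one_error_is_nominal_on_null_data(self):
        """No planted effect, 3 vs 3, 2000 genes: share of p <= 0.05
        stays within 3 binomial standard deviations of 0.05."""
        cfg = SyntheticConfig(
            n_single_copy=2000, n_multi_copy=0, n_species_specific_a=0,
            n_species_specific_b=0, planted_enriched_size=0, planted_target_size=0,
            planted_overlap=0, planted_zero_size=0, seed=42,
        )
        de = differential_test(compute_tpm(generate(cfg).study))
        frac = float((de["p_value"] <= 0.05).mean())
        tol = 3 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(frac - 0.05) <= tol

    def test_bh_adjustment_is_monotone_and_larger(self):
        rng = np.random.default_rng(2)
        vals = rng.gamma(2.0, 50.0, size=(100, 6))
        study = make_study({f"g{i}": vals[i] for i in range(100)}, kind="tpm")
        raw = differential_test(study)["p_value"]
        adj = differential_test(study, adjust="bh")["p_value"]
        assert (adj >= raw - 1e-12).all()


class TestSelectEnriched:
    @staticmethod
    def de_frame(rows):
        return pd.DataFrame(
            rows,
            columns=["mean_tpm_A", "mean_tpm_B", "cumulative_tpm", "fold_change",
                     "p_value", "passed_abundance"],
            index=[f"g{i}" for i in range(len(rows))],
        )

    def test_boundary_values_are_inclusive(self):
        de = self.de_frame([[1, 1, 0.1, 5.0, 0.05, True]])
        assert "g0" in select_enriched(de, 5.0, 0.05, min_cumulative_tpm=0.1)

    def test_just_below_fold_threshold_is_excluded(self):
        de = self.de_frame([[9, 1, 50.0, 4.999, 0.01, True]])
        assert len(select_enriched(de, 5.0, 0.05)) == 0

    def test_abundance_failures_are_excluded_even_if_significant(self):
        de = self.de_frame([[1, 0.1, 0.05, 10.0, 0.001, False]])
        assert len(select_enriched(de, 5.0, 0.05)) == 0

    @given(seed=st.integers(0, 10_000))
    def test_monotone_in_both_thresholds(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        de = self.de_frame(
            np.column_stack([
                rng.gamma(2, 10, n), rng.gamma(2, 10, n), rng.gamma(2, 30, n),
                rng.gamma(2.0, 3.0, n), rng.uniform(0, 1, n), np.ones(n),
            ])
        )
        de["passed_abundance"] = True
        loose = select_enriched(de, 2.0, 0.05)
        assert select_enriched(de, 5.0, 0.05).ids <= loose.ids
        assert select_enriched(de, 2.0, 0.01).ids <= loose.ids

    def test_planted_enrichment_is_fully_recovered(self):
        """Strong planted signal among 2000 genes: every planted gene is
        selected and false inclusions stay below the nominal level."""
        cfg = SyntheticConfig(
            n_single_copy=2000, n_multi_copy=0, n_species_specific_a=0,
            n_species_specific_b=0, planted_enriched_size=40, planted_fold=10.0,
            planted_target_size=0, planted_overlap=0, planted_zero_size=0,
            nb_dispersion=0.01, seed=9,
        )
        bundle = generate(cfg)
        de = differential_test(compute_tpm(bundle.study))
        got = select_enriched(de, 5.0, 0.05)
        planted = set(bundle.truth.enriched_genes_a)
        assert planted <= got.ids
        assert len(got.ids - planted) <= 0.05 * 2000

    def test_bad_thresholds_are_rejected(self):
        de = self.de_frame([[1, 1, 1.0, 1.0, 0.5, True]])
        with pytest.raises(ParameterError):
            select_enriched(de, -1.0, 0.05)
        with pytest.raises(ParameterError):
            select_enriched(de, 5.0, 1.5)
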