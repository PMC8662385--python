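"""Generator ground truth, determinism, and feasibility guards."""

import hashlib

import numpy as np
import pytest

from orthoverlap import single_copy
from orthoverlap.errors import InfeasibleConfigError
from orthoverlap.simulate import SyntheticConfig, end_to_end_recovery, generate


def checksum_tree(paths):
    h = hashlib.sha256()
    for key in sorted(paths):
        if key == "config":
            continue
        h.update(paths[key].read_bytes())
    return h.hexdigest()


class TestComposition:
    def test_counts_match_config_exactly(self, default_bundle):
        cfg = default_bundle.config
        t = default_bundle.truth
        assert len(t.single_copy_orthogroups) == cfg.n_single_copy
        assert len(default_bundle.orthogroups) == (
            cfg.n_single_copy + cfg.n_multi_copy
            + cfg.n_species_specific_a + cfg.n_species_specific_b
        )
        assert len(t.enriched_genes_a) == cfg.planted_enriched_size
        assert len(t.target_genes_b) == cfg.planted_target_size
        assert len(t.overlap_orthogroups) == cfg.planted_overlap
        assert len(t.zero_genes_a) == cfg.planted_zero_size

    def test_planted_overlap_is_realised_in_orthogroup_space(self, default_bundle):
        sc = single_copy(default_bundle.orthogroups)
        cfg = default_bundle.config
        from orthoverlap import project

        enr = project(default_bundle.truth.enriched_genes_a, sc, cfg.species_a)
        tgt = project(default_bundle.target_genes, sc, cfg.species_b)
        assert len(enr.orthogroups & tgt.orthogroups) == cfg.planted_overlap
        assert sorted(enr.orthogroups & tgt.orthogroups) == (
            default_bundle.truth.overlap_orthogroups
        )

    def test_multi_copy_groups_have_expanded_side(self, default_bundle):
        sp_a, sp_b = default_bundle.orthogroups.species_labels
        multi = {
            og: by
            for og, by in default_bundle.orthogroups.membership.items()
            if og not in set(default_bundle.truth.single_copy_orthogroups)
            and by[sp_a] and by[sp_b]
        }
        assert len(multi) == default_bundle.config.n_multi_copy
        for by in multi.values():
            assert {len(by[sp_a]), len(by[sp_b])} & {2, 3, 4}


class TestCountModel:
    def test_nb_moments_match_configuration(self):
        """Empirical mean and dispersion of NB counts at fixed mean."""
        cfg = SyntheticConfig(
            n_single_copy=3000, n_multi_copy=0, n_species_specific_a=0,
            n_species_specific_b=0, planted_enriched_size=0, planted_target_size=0,
            planted_overlap=0, planted_zero_size=0,
            nb_mean_log10_range=(2.0, 2.0),  # all genes mean 100
            nb_dispersion=0.1, seed=23,
        )
        counts = generate(cfg).study.values.to_numpy()
        flat = counts.ravel().astype(float)
        mu, alpha, n = 100.0, 0.1, flat.size
        var = mu + alpha * mu**2
        assert abs(flat.mean() - mu) <= 3 * np.sqrt(var / n)
        # dispersion back-solved from the empirical variance
        alpha_hat = (flat.var(ddof=1) - flat.mean()) / flat.mean() ** 2
        assert alpha_hat == pytest.approx(alpha, rel=0.15)

    def test_zero_genes_are_all_zero(self, default_bundle):
        zeros = default_bundle.study.values.loc[default_bundle.truth.zero_genes_a]
        assert (zeros.to_numpy() == 0).all()

    def test_enriched_means_are_lifted_in_group_a(self, default_bundle):
        vals = default_bundle.study.values
        enr = default_bundle.truth.enriched_genes_a
        a_cols = default_bundle.study.samples_in_group("A")
        b_cols = default_bundle.study.samples_in_group("B")
        ratio = vals.loc[enr, a_cols].mean(axis=1) / vals.loc[enr, b_cols].mean(axis=1)
        # planted tenfold on counts; noisy per gene but unmistakable in bulk
        assert ratio.median() > 5


class TestDeterminismAndGuards:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SyntheticConfig(n_single_copy=120, n_multi_copy=10,
                              n_species_specific_a=5, n_species_specific_b=5,
                              planted_enriched_size=10, planted_target_size=8,
                              planted_overlap=4, planted_zero_size=5, seed=31)
        sum1 = checksum_tree(generate(cfg).write(tmp_path / "a"))
        sum2 = checksum_tree(generate(cfg).write(tmp_path / "b"))
        assert sum1 == sum2

    def test_different_seed_changes_outputs(self, tmp_path):
        base = dict(n_single_copy=120, n_multi_copy=0, n_species_specific_a=0,
                    n_species_specific_b=0, planted_enriched_size=10,
                    planted_target_size=8, planted_overlap=4, planted_zero_size=0)
        sum1 = checksum_tree(generate(SyntheticConfig(seed=1, **base)).write(tmp_path / "a"))
        sum2 = checksum_tree(generate(SyntheticConfig(seed=2, **base)).write(tmp_path / "b"))
        assert sum1 != sum2

    def test_infeasible_overlap_is_rejected_before_generation(self):
        cfg = SyntheticConfig(planted_target_size=10, planted_overlap=11)
        with pytest.raises(InfeasibleConfigError, match="planted_overlap"):
            generate(cfg)

    def test_zero_replicates_is_rejected(self):
        with pytest.raises(InfeasibleConfigError, match="replicates"):
            generate(SyntheticConfig(replicates=0))

    def test_overlarge_enriched_set_is_rejected(self):
        cfg = SyntheticConfig(n_single_copy=10, planted_enriched_size=50,
                              planted_target_size=5, planted_overlap=0,
                              n_multi_copy=0, n_species_specific_a=0,
                              n_species_specific_b=0)
        with pytest.raises(InfeasibleConfigError):
            generate(cfg)


class TestEndToEnd:
    def test_strong_signal_recovers_planted_overlap(self):
        rep = end_to_end_recovery(
            SyntheticConfig(nb_dispersion=0.01, seed=2), iterations=2000
        )
        assert rep.k_obs == rep.planted_overlap == 20
        assert rep.n_true_positive == rep.n_enriched_true
        assert rep.p_mc_corrected < 0.01

    def test_null_fold_gives_insignificant_overlap(self):
        """planted_fold = 1: no expression signal, so the enriched set is
        mostly empty and the overlap test cannot be significant."""
        cfg = SyntheticConfig(planted_fold=1.0, planted_overlap=20, seed=8)
        rep = end_to_end_recovery(cfg, iterations=2000)
        assert rep.n_enriched_recovered <= 0.05 * 1380
        assert rep.p_mc_corrected > 0.05
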