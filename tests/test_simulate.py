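"""Synthetic cohort generator: ground-truth fidelity and determinism."""

import numpy as np
import pytest
from scipy import stats

from fcrepro import (
    SimConfig,
    apply_effect_in_z,
    make_base_correlation,
    nearest_correlation,
    simulate_cohort,
    welch_contrast,
)
from fcrepro.connectivity import collection_fc
from fcrepro.pairs import PairIndex
from fcrepro.simulate import sample_timeseries


class TestBaseCorrelation:
    def test_two_region_bounds(self):
        c = make_base_correlation(2, 1, seed=0)
        assert c.shape == (2, 2)
        np.testing.assert_array_equal(np.diag(c), 1.0)
        assert abs(c[0, 1]) < 1

    @pytest.mark.parametrize("n_regions, rank, seed", [(5, 5, 1), (90, 10, 7), (30, 3, 2)])
    def test_symmetric_unit_diagonal_psd(self, n_regions, rank, seed):
        c = make_base_correlation(n_regions, rank, seed)
        assert np.linalg.norm(c - c.T) == 0.0
        np.testing.assert_allclose(np.diag(c), 1.0, atol=1e-12)
        assert np.linalg.eigvalsh(c)[0] >= -1e-12
        off = c[~np.eye(n_regions, dtype=bool)]
        assert np.all(np.abs(off) < 1)

    def test_deterministic_given_seed(self):
        np.testing.assert_array_equal(
            make_base_correlation(20, 4, seed=9), make_base_correlation(20, 4, seed=9)
        )

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            make_base_correlation(1, 1, 0)
        with pytest.raises(ValueError):
            make_base_correlation(5, 6, 0)


class TestNearestCorrelation:
    def test_valid_matrix_unchanged(self):
        c = make_base_correlation(8, 4, seed=3)
        np.testing.assert_array_equal(nearest_correlation(c), c)

    def test_indefinite_matrix_projected_psd(self):
        # 3x3 with an impossible correlation pattern (violates PSD)
        c = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(c)[0] < -1e-3
        out = nearest_correlation(c)
        w = np.linalg.eigvalsh(out)  # eigen-decomposition oracle
        assert w[0] >= -1e-12
        np.testing.assert_allclose(np.diag(out), 1.0, atol=1e-12)
        np.testing.assert_allclose(out, out.T, atol=1e-12)


class TestApplyEffect:
    def test_zero_delta_identity_on_valid_input(self):
        c = make_base_correlation(6, 3, seed=5)
        np.testing.assert_array_equal(apply_effect_in_z(c, [0, 4], 0.0), c)

    def test_closed_form_tanh_shift(self):
        c = np.eye(3)
        out = apply_effect_in_z(c, [0], 0.3)  # pair 0 = (0, 1), starts at 0
        assert out[0, 1] == pytest.approx(np.tanh(0.3), abs=1e-12)
        assert out[0, 1] == pytest.approx(0.2913, abs=1e-4)

    def test_invalid_push_gets_projected(self):
        c = np.array([[1.0, -0.8, 0.8], [-0.8, 1.0, 0.0], [0.8, 0.0, 1.0]])
        # push pair (1,2) strongly positive: incompatible with the other two
        out = apply_effect_in_z(c, [2], 3.0)
        assert np.linalg.eigvalsh(out)[0] >= -1e-12
        np.testing.assert_allclose(np.diag(out), 1.0, atol=1e-12)

    def test_degenerate_entry_rejected(self):
        c = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="z-shift undefined"):
            apply_effect_in_z(c, [0], 0.1)


class TestCohortStructure:
    def test_scan_counting_and_replicates(self):
        cfg = SimConfig(n_regions=6, n_timepoints=50, n_subjects_nc=4, n_subjects_pd=4)
        scans, _ = simulate_cohort(cfg)
        assert len(scans) == 16
        assert sum(s.group == "NC" for s in scans) == 8
        by_subject = {}
        for s in scans:
            by_subject.setdefault(s.subject_id, []).append(s.replicate_index)
        assert all(sorted(v) == [1, 2] for v in by_subject.values())

    def test_subtype_partition(self):
        cfg = SimConfig(
            n_regions=8,
            n_timepoints=50,
            n_subjects_nc=3,
            n_subjects_pd=10,
            effect_pairs=(((0, 1), 0.4), ((5, 6), 0.4)),
            subtype_proportions=(0.5, 0.5),
            seed=11,
        )
        _, truth = simulate_cohort(cfg)
        pd_subtypes = [v for v in truth.subtype_of_subject.values() if v >= 0]
        assert len(pd_subtypes) == 10
        assert set(pd_subtypes) <= {0, 1}

    def test_bit_identical_given_config(self):
        cfg = dict(
            n_regions=7, n_timepoints=40, n_subjects_nc=3, n_subjects_pd=3,
            effect_pairs=(((1, 2), 0.3),), sigma_subject=0.1, sigma_scan=0.05, seed=21,
        )
        scans1, _ = simulate_cohort(SimConfig(**cfg))
        scans2, _ = simulate_cohort(SimConfig(**cfg))
        for a, b in zip(scans1, scans2):
            assert a.scan_id == b.scan_id
            np.testing.assert_array_equal(a.timeseries.values, b.timeseries.values)

    def test_stratified_assignment_exact_counts(self):
        cfg = SimConfig(
            n_regions=8, n_timepoints=50, n_subjects_nc=3, n_subjects_pd=12,
            effect_pairs=(((0, 1), 0.4), ((5, 6), 0.4)),
            subtype_proportions=(0.5, 0.5), subtype_assignment="stratified", seed=31,
        )
        _, truth = simulate_cohort(cfg)
        counts = np.bincount([v for v in truth.subtype_of_subject.values() if v >= 0])
        np.testing.assert_array_equal(counts, [6, 6])

    def test_shared_base_seed_across_datasets(self):
        kw = dict(n_regions=7, n_timepoints=40, n_subjects_nc=2, n_subjects_pd=2)
        _, t1 = simulate_cohort(SimConfig(seed=1, base_seed=99, **kw))
        _, t2 = simulate_cohort(SimConfig(seed=2, base_seed=99, **kw))
        _, t3 = simulate_cohort(SimConfig(seed=3, **kw))
        np.testing.assert_array_equal(t1.base_correlation, t2.base_correlation)
        assert not np.array_equal(t1.base_correlation, t3.base_correlation)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(effect_pairs=(((0,), 0.3),), subtype_proportions=(0.9,))
        with pytest.raises(ValueError, match="out of range"):
            SimConfig(n_regions=4, base_structure_rank=2, effect_pairs=(((99,), 0.3),))


class TestGroundTruthFidelity:
    def test_large_t_zero_noise_recovers_target_z(self):
        cfg = SimConfig(
            n_regions=5, n_timepoints=50000, n_subjects_nc=1, n_subjects_pd=1,
            n_replicates=1, sigma_subject=0.0, sigma_scan=0.0, seed=4,
        )
        scans, truth = simulate_cohort(cfg)
        pidx = PairIndex(5)
        target_z = np.arctanh(pidx.condense(truth.base_correlation))
        for s in scans:
            emp = np.arctanh(pidx.condense(np.corrcoef(s.timeseries.values, rowvar=False)))
            assert np.max(np.abs(emp - target_z)) < 0.02

    def test_ar1_preserves_cross_region_correlation(self, rng):
        c = make_base_correlation(4, 2, seed=8)
        x = sample_timeseries(c, 40000, rng, ar1=0.5)
        emp = np.corrcoef(x, rowvar=False)
        # AR(1) inflates the effective sample error but not the target
        assert np.max(np.abs(emp - c)) < 0.05
        # temporal autocorrelation is actually present
        lag1 = np.mean([np.corrcoef(x[:-1, k], x[1:, k])[0, 1] for k in range(4)])
        assert lag1 == pytest.approx(0.5, abs=0.05)

    def test_effect_pairs_have_larger_t_than_null_pairs(self):
        cfg = SimConfig(
            n_regions=15, n_timepoints=150, n_subjects_nc=20, n_subjects_pd=20,
            n_replicates=1, effect_pairs=((tuple(range(20)), 0.5),),
            sigma_subject=0.05, sigma_scan=0.05, seed=13,
        )
        scans, truth = simulate_cohort(cfg)
        res = welch_contrast(scans)
        affected = sorted(truth.affected_pairs)
        others = np.setdiff1d(np.arange(res.pair_index.n_pairs), affected)
        stat = stats.mannwhitneyu(
            np.abs(res.t_values[affected]), np.abs(res.t_values[others]), alternative="greater"
        )
        assert stat.pvalue < 0.01

    def test_disjoint_subtypes_attenuate_pooled_t(self):
        pairs_a, pairs_b = tuple(range(10)), tuple(range(10, 20))
        common = dict(
            n_regions=15, n_timepoints=150, n_subjects_nc=20, n_subjects_pd=20,
            n_replicates=1, sigma_subject=0.05, sigma_scan=0.05, seed=17,
        )
        hom_scans, _ = simulate_cohort(
            SimConfig(effect_pairs=((pairs_a, 0.5),), **common)
        )
        het_scans, _ = simulate_cohort(
            SimConfig(
                effect_pairs=((pairs_a, 0.5), (pairs_b, 0.5)),
                subtype_proportions=(0.5, 0.5),
                **common,
            )
        )
        t_hom = np.abs(welch_contrast(hom_scans).t_values[list(pairs_a)]).mean()
        t_het = np.abs(welch_contrast(het_scans).t_values[list(pairs_a)]).mean()
        assert t_het < t_hom
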