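"""Cross-dataset min(max(p)) edge-consistency statistic."""

import itertools

import numpy as np
import pytest

from fcrepro import (
    SimConfig,
    consistency_permutation_test,
    max_p_table,
    min_max_p,
    simulate_cohort,
    welch_contrast,
)
from fcrepro.connectivity import collection_fc
from fcrepro.contrast import ContrastResult, welch_t_batch
from fcrepro.pairs import PairIndex


def _contrast(t, p, dataset_id="d"):
    t = np.asarray(t, dtype=float)
    n_regions = int(round((1 + np.sqrt(1 + 8 * t.size)) / 2))
    return ContrastResult(
        t_values=t,
        df_values=np.full(t.size, 10.0),
        p_values=np.asarray(p, dtype=float),
        n_nc=5,
        n_pd=5,
        pair_index=PairIndex(n_regions),
        dataset_id=dataset_id,
    )


class TestMaxPTable:
    def test_hand_case_sign_filter(self):
        # 3 pairs (R=3), 2 datasets; only pair 0 is positive in both
        con_a = _contrast([2.0, 1.5, -1.0], [0.01, 0.001, 0.3], "a")
        con_b = _contrast([1.8, -0.5, -2.0], [0.02, 0.5, 0.04], "b")
        table = max_p_table([con_a, con_b], "plus")
        assert list(table["pair_k"]) == [0]
        assert table["max_p"].iloc[0] == pytest.approx(0.02)

    def test_identical_contrasts_reduce_to_directional_p(self):
        t = np.array([2.0, -1.0, 0.5])
        p = np.array([0.01, 0.2, 0.4])
        con = _contrast(t, p)
        table = max_p_table([con, con, con], "plus")
        assert list(table["pair_k"]) == [0, 2]  # sorted by max_p
        np.testing.assert_allclose(table["max_p"], [0.01, 0.4])

    def test_matches_brute_force_double_loop(self, rng):
        contrasts = [
            _contrast(rng.normal(size=21), rng.uniform(size=21), f"d{k}") for k in range(3)
        ]
        for direction, sign in (("plus", 1), ("minus", -1)):
            table = max_p_table(contrasts, direction)
            expected = {}
            for k in range(21):
                if all(sign * c.t_values[k] > 0 for c in contrasts):
                    expected[k] = max(c.p_values[k] for c in contrasts)
            assert set(table["pair_k"]) == set(expected)
            for _, row in table.iterrows():
                assert row["max_p"] == pytest.approx(expected[row["pair_k"]], abs=1e-14)
            assert list(table["max_p"]) == sorted(table["max_p"])

    def test_adding_dataset_is_monotone(self, rng):
        contrasts = [
            _contrast(rng.normal(size=15), rng.uniform(size=15), f"d{k}") for k in range(3)
        ]
        t2 = max_p_table(contrasts[:2], "plus").set_index("pair_k")
        t3 = max_p_table(contrasts, "plus").set_index("pair_k")
        assert set(t3.index) <= set(t2.index)  # retained set can only shrink
        for k in t3.index:
            assert t3.loc[k, "max_p"] >= t2.loc[k, "max_p"] - 1e-14


class TestMinMaxP:
    def test_minimum_of_max_p_column(self):
        con_a = _contrast([1.0, 2.0, 1.5], [0.3, 0.012526, 0.9], "a")
        table_min = min_max_p([con_a, con_a], "plus")
        assert table_min == pytest.approx(0.012526)

    def test_empty_retained_set_is_one(self):
        con_a = _contrast([1.0], [0.1], "a")
        con_b = _contrast([-1.0], [0.1], "b")
        assert min_max_p([con_a, con_b], "plus") == 1.0
        assert min_max_p([con_a, con_b], "minus") == 1.0

    def test_equals_brute_force_min_over_pairs(self, rng):
        contrasts = [
            _contrast(rng.normal(size=10), rng.uniform(size=10), f"d{k}") for k in range(2)
        ]
        got = min_max_p(contrasts, "minus")
        vals = [
            max(c.p_values[k] for c in contrasts)
            for k in range(10)
            if all(c.t_values[k] < 0 for c in contrasts)
        ]
        assert got == pytest.approx(min(vals) if vals else 1.0, abs=1e-14)


def _tiny_collections(seed, effect=None):
    effect_pairs = ((effect, 0.8),) if effect else ()
    return [
        simulate_cohort(
            SimConfig(
                n_regions=6, n_timepoints=80, n_subjects_nc=3, n_subjects_pd=3,
                n_replicates=1, effect_pairs=effect_pairs,
                sigma_subject=0.05, sigma_scan=0.0, seed=seed + k, dataset_id=f"c{k}",
            )
        )[0]
        for k in range(2)
    ]


class TestPermutationTest:
    def test_direction_swap_on_sign_flip(self):
        from dataclasses import replace

        colls = _tiny_collections(seed=100)
        # swapping NC<->PD negates every t, so plus/minus results swap
        swapped = [
            [replace(s, group="PD" if s.group == "NC" else "NC") for s in coll]
            for coll in colls
        ]
        res_plus = consistency_permutation_test(colls, "plus", n_perm=150, seed=5)
        res_minus = consistency_permutation_test(swapped, "minus", n_perm=150, seed=5)
        assert res_minus.min_max_p == pytest.approx(res_plus.min_max_p, abs=1e-10)
        assert abs(res_minus.p_of_min_max_p - res_plus.p_of_min_max_p) <= 2 / 150

    def test_p_matches_exhaustive_enumeration(self):
        colls = _tiny_collections(seed=200)
        fcs = [collection_fc(c)[0] for c in colls]

        def stats_for(fc, nc_set):
            is_nc = np.zeros(6, dtype=bool)
            is_nc[list(nc_set)] = True
            t, _, p = welch_t_batch(fc, is_nc, with_p=True)
            return t, p

        per_coll = [
            [stats_for(fc, nc) for nc in itertools.combinations(range(6), 3)]
            for fc in fcs
        ]

        def mmp(stats_pair):
            (ta, pa), (tb, pb) = stats_pair
            keep = (ta > 0) & (tb > 0)
            if not keep.any():
                return 1.0
            return np.minimum.reduce(np.where(keep, np.maximum(pa, pb), np.inf)).item()

        obs_stats = [
            stats_for(fc, tuple(k for k, s in enumerate(coll) if s.group == "NC"))
            for fc, coll in zip(fcs, colls)
        ]
        observed = mmp(obs_stats)
        null = [mmp((sa, sb)) for sa in per_coll[0] for sb in per_coll[1]]
        p_exact = np.mean(np.asarray(null) <= observed)

        n_perm = 4000
        res = consistency_permutation_test(colls, "plus", n_perm=n_perm, seed=8)
        assert res.min_max_p == pytest.approx(observed, abs=1e-10)
        se = np.sqrt(max(p_exact * (1 - p_exact), 1e-6) / n_perm)
        assert abs(res.p_of_min_max_p - p_exact) <= 3 * se

    def test_planted_effect_beats_null(self):
        effect = (0, 1, 2)
        strong = [
            simulate_cohort(
                SimConfig(
                    n_regions=6, n_timepoints=200, n_subjects_nc=8, n_subjects_pd=8,
                    n_replicates=1, effect_pairs=((effect, 1.0),),
                    sigma_subject=0.02, sigma_scan=0.0, seed=300 + k, dataset_id=f"s{k}",
                )
            )[0]
            for k in range(3)
        ]
        res = consistency_permutation_test(strong, "plus", n_perm=200, seed=2)
        assert res.p_of_min_max_p <= 0.05
        assert set(res.ranked_pairs["pair_k"][:3]) & set(effect)
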