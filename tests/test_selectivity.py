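import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from dietsel.io import OtuTable, RelAbundanceTable
from dietsel.selectivity import (
    classify_electivity,
    differential_enrichment,
    dominance_index,
    electivity,
    electivity_frame,
    electivity_table,
    rank_sum_test,
)


class TestElectivity:
    def test_equal_shares_give_zero(self):
        assert electivity(0.3, 0.3) == 0.0

    def test_boundaries(self):
        assert electivity(0.2, 0.0) == 1.0
        assert electivity(0.0, 0.2) == -1.0

    def test_double_zero_convention(self):
        assert electivity(0.0, 0.0) == 0.0
        assert np.isnan(electivity(0.0, 0.0, zero_zero=None))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            electivity(-0.1, 0.5)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_antisymmetry_and_range(self, a, b):
        e = electivity(a, b)
        assert -1.0 <= e <= 1.0
        assert e == pytest.approx(-electivity(b, a))

    def test_monotone_in_diet_share(self):
        pi = 0.2
        es = [electivity(ri, pi) for ri in np.linspace(0.01, 1, 25)]
        assert (np.diff(es) > 0).all()


class TestClassification:
    @pytest.mark.parametrize(
        "E,expected",
        [
            (0.72, "preference"),
            (-0.47, "discrimination"),
            (0.06, "non-selective"),
            (0.25, "non-selective"),  # strict inequality at the threshold
            (-0.25, "non-selective"),
            (1.0, "preference"),
            (-1.0, "discrimination"),
        ],
    )
    def test_threshold_semantics(self, E, expected):
        assert classify_electivity(E) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_electivity(1.2)


def _pools_to_tables(gut_pool, water_pool):
    gut = OtuTable(pd.DataFrame([gut_pool, gut_pool],
                                index=["P1_Dec", "P2_Dec"]).astype(np.int64))
    water = OtuTable(pd.DataFrame([water_pool, water_pool],
                                  index=["A1_Dec", "A2_Dec"]).astype(np.int64))
    return gut, water


def _meta_for(sample_ids):
    rows = []
    for sid in sample_ids:
        comp = "gut" if sid.startswith("P") else "water"
        rows.append({"site": f"S{sid[1]}", "season": sid.split("_")[1],
                     "compartment": comp})
    from dietsel.io import SampleFrame
    return SampleFrame(pd.DataFrame(rows, index=sample_ids))


class TestElectivityTable:
    def test_equal_composition_gives_zero(self):
        gut, water = _pools_to_tables({"A": 25, "B": 25}, {"A": 250, "B": 250})
        meta = _meta_for(gut.sample_ids + water.sample_ids)
        recs = electivity_table(gut, water, meta)
        assert all(r.E == pytest.approx(0.0) for r in recs)

    def test_hand_computed_pools(self):
        # ri=(0.75,0.25) vs pi=(0.5,0.5): E_A=0.2, E_B=-1/3
        gut, water = _pools_to_tables({"A": 75, "B": 25}, {"A": 50, "B": 50})
        meta = _meta_for(gut.sample_ids + water.sample_ids)
        E = {r.taxon: r.E for r in electivity_table(gut, water, meta)}
        assert E["A"] == pytest.approx(0.2)
        assert E["B"] == pytest.approx(-1 / 3)

    def test_absent_from_gut_is_minus_one(self):
        gut, water = _pools_to_tables({"A": 50, "B": 0}, {"A": 50, "B": 50})
        meta = _meta_for(gut.sample_ids + water.sample_ids)
        recs = {r.taxon: r for r in electivity_table(gut, water, meta)}
        assert recs["B"].E == pytest.approx(-1.0)
        assert recs["B"].classification == "discrimination"

    def test_empty_gut_group_flagged_missing(self):
        gut, water = _pools_to_tables({"A": 0, "B": 0}, {"A": 50, "B": 50})
        meta = _meta_for(gut.sample_ids + water.sample_ids)
        recs = electivity_table(gut, water, meta)
        assert all(r.missing for r in recs)

    def test_recovers_truth_with_growing_depth(self):
        # mean signed error of E-hat against the generative E shrinks
        from dietsel.preprocess import remove_consumer_reads
        from dietsel.simulate import SimConfig, simulate_study

        errors = []
        weights = {"Chrysophyceae": 4.0}
        for depth in (600, 5_500, 55_000):
            cfg = SimConfig(seed=31, depth_gut=depth,
                            selectivity_weights=weights)
            study = simulate_study(cfg)
            gut = remove_consumer_reads(study.gut, study.taxonomy).table
            recs = electivity_table(gut, study.water, study.samples,
                                    grouping="season")
            errs = [
                r.E - study.truth.electivity(r.taxon, r.group)
                for r in recs
            ]
            errors.append(abs(float(np.mean(errs))))
        assert errors[2] < errors[0]
        assert errors[2] < 0.05

    def test_tidy_frame_columns(self, sim_study):
        from dietsel.preprocess import remove_consumer_reads

        gut = remove_consumer_reads(sim_study.gut, sim_study.taxonomy).table
        recs = electivity_table(gut, sim_study.water, sim_study.samples,
                                tax=sim_study.taxonomy, rank="class")
        frame = electivity_frame(recs)
        assert {"taxon", "group", "ri", "pi", "E", "classification"} <= set(frame.columns)
        assert set(frame["group"]) == {"Dec", "Mar", "Jun", "Sep"}


class TestDominance:
    def test_ubiquitous_taxon_equals_share(self):
        df = pd.DataFrame({"a": [0.268, 0.268], "b": [0.732, 0.732]},
                          index=["s1", "s2"])
        recs = {r.taxon: r.Y for r in dominance_index(RelAbundanceTable(df))}
        assert recs["a"] == pytest.approx(0.268)

    def test_half_occupancy_halves_share(self):
        df = pd.DataFrame({"a": [0.8, 0.0], "b": [0.2, 1.0]}, index=["s1", "s2"])
        recs = {r.taxon: r.Y for r in dominance_index(RelAbundanceTable(df))}
        assert recs["a"] == pytest.approx(0.4 * 0.5)

    def test_absent_taxon_is_zero(self):
        df = pd.DataFrame({"a": [1.0, 1.0], "b": [0.0, 0.0]}, index=["s1", "s2"])
        recs = {r.taxon: r.Y for r in dominance_index(RelAbundanceTable(df))}
        assert recs["b"] == 0.0

    def test_bounded_and_sorted(self, sim_study):
        from dietsel.preprocess import aggregate_by_rank, relative_abundance

        rel = relative_abundance(
            aggregate_by_rank(sim_study.water, sim_study.taxonomy, "class")
        )
        recs = dominance_index(rel)
        ys = [r.Y for r in recs]
        assert all(0 <= y <= 1 for y in ys)
        assert ys == sorted(ys, reverse=True)


def _enumeration_p(x, y):
    """Oracle: exact two-sided rank-sum p by enumerating every way the
    pooled ranks can be split between the groups."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w_obs = ranks[: len(x)].sum()
    ws = np.array([sum(c) for c in itertools.combinations(ranks, len(x))])
    return min(1.0, 2 * min((ws <= w_obs).sum(), (ws >= w_obs).sum()) / len(ws))


class TestRankSum:
    def test_perfect_separation_hand_value(self):
        _, p = rank_sum_test([0.9, 0.8, 0.85, 0.95], [0.1, 0.2, 0.15, 0.05])
        assert p == pytest.approx(2 / 70)

    def test_identical_groups_p_one(self):
        _, p = rank_sum_test([0.2, 0.2, 0.2], [0.2, 0.2, 0.2])
        assert p == 1.0

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 4), (5, 5), (4, 6)])
    def test_exact_agrees_with_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(25):
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            _, p = rank_sum_test(x, y)
            assert p == pytest.approx(_enumeration_p(x, y), abs=1e-12)


class TestEnrichment:
    def _rel(self, arrs, prefix):
        df = pd.DataFrame(arrs, index=[f"{prefix}{i}" for i in range(len(arrs))])
        return RelAbundanceTable(df.div(df.sum(axis=1), axis=0))

    def test_bh_hand_oracle(self):
        # step-up rule on p=(0.01, 0.02, 0.20): q=(0.03, 0.03, 0.20)
        _, q, _, _ = multipletests([0.01, 0.02, 0.20], method="fdr_bh")
        assert q == pytest.approx([0.03, 0.03, 0.20])

    def test_q_dominates_p_and_significance_consistent(self, sim_study):
        from dietsel.preprocess import (
            aggregate_by_rank,
            relative_abundance,
            remove_consumer_reads,
        )

        gut = remove_consumer_reads(sim_study.gut, sim_study.taxonomy).table
        gut_rel = relative_abundance(
            aggregate_by_rank(gut, sim_study.taxonomy, "class")
        )
        water_rel = relative_abundance(
            aggregate_by_rank(sim_study.water, sim_study.taxonomy, "class")
        )
        recs = differential_enrichment(gut_rel, water_rel)
        for r in recs:
            assert r.q_fdr >= r.p_raw - 1e-12
            assert r.significant == (r.q_fdr <= 0.05)
            assert r.significant_raw == (r.p_raw <= 0.05)
        qs = sorted((r.p_raw, r.q_fdr) for r in recs)
        for (p1, q1), (p2, q2) in zip(qs, qs[1:]):
            assert q2 >= q1 - 1e-12  # q monotone in sorted p

    def test_absent_taxon_p_one(self):
        gut = self._rel([[1.0, 0.0], [1.0, 0.0]], "g")
        water = self._rel([[1.0, 0.0], [1.0, 0.0]], "w")
        recs = {r.taxon: r for r in differential_enrichment(gut, water)}
        assert recs[1].p_raw == 1.0

    def test_type_i_error_calibrated_under_null(self):
        # same distribution in both compartments: raw-p rejections ~5%
        rng = np.random.default_rng(2024)
        hits, total = 0, 0
        for _ in range(300):
            x, y = rng.normal(size=6), rng.normal(size=6)
            _, p = rank_sum_test(x, y)
            hits += p <= 0.05
            total += 1
        assert 0.03 <= hits / total <= 0.07
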