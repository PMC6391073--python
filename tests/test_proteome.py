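"""Proteomics statistics: filtering, classification, clustering, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from cyanoecon import (IntensityMatrix, SyntheticSpec,
                       classify_growth_dependence, cluster_profiles,
                       enrich_go_slim, filter_protein_groups, map_go_slim,
                       simulate_proteomics)
from cyanoecon.proteome import (DependenceCall, calls_frame,
                                kruskal_wallis_pair, select_k_elbow)


def toy_matrix(values: dict[str, list[float]], groups=None,
               peptides=None, contaminant=(), reverse=()) -> IntensityMatrix:
    """Small matrix helper: 2 groups x 3 replicates unless specified."""
    samples = [f"g{g}_r{r}" for g in (1, 2) for r in (1, 2, 3)] \
        if groups is None else list(groups)
    groups_map = {s: s.split("_")[0] for s in samples}
    lfq = pd.DataFrame(values, index=samples).T
    return IntensityMatrix(
        lfq=lfq, ibaq=lfq.copy(),
        peptide_counts=pd.Series(peptides or {p: 5 for p in values}),
        contaminant=pd.Series({p: p in contaminant for p in values}),
        reverse=pd.Series({p: p in reverse for p in values}),
        groups=groups_map)


class TestFiltering:
    def test_flagged_and_low_evidence_removed(self):
        vals = {f"P{i}": [100.0] * 6 for i in range(4)}
        m = toy_matrix(vals, peptides={"P0": 5, "P1": 1, "P2": 5, "P3": 5},
                       contaminant={"P2"}, reverse={"P3"})
        filtered, report = filter_protein_groups(m)
        assert filtered.protein_ids == ["P0"]
        assert report["removed_flagged"] == 2
        assert report["removed_low_evidence"] == 1

    def test_missing_value_rule_both_readings(self):
        vals = {"complete": [1.0] * 6,
                "one_group_complete": [1.0, 1.0, 1.0, np.nan, 2.0, 2.0],
                "no_group_complete": [1.0, np.nan, 1.0, np.nan, 2.0, 2.0]}
        m = toy_matrix(vals)
        keep, _ = filter_protein_groups(m)
        assert set(keep.protein_ids) == {"complete", "one_group_complete"}
        drop, _ = filter_protein_groups(m, missing_rule="drop_complete_group")
        assert drop.protein_ids == ["no_group_complete"]

    def test_known_pass_set_count(self, rng):
        """Constructed table where exactly 120 of 200 proteins pass."""
        vals = {}
        peptides = {}
        for i in range(200):
            pid = f"P{i:03d}"
            row = list(rng.lognormal(10, 1, 6))
            if i >= 120:  # fail alternately by evidence or missingness
                if i % 2:
                    peptides[pid] = 1
                else:
                    row[0] = row[3] = np.nan
            if pid not in peptides:
                peptides[pid] = 4
            vals[pid] = row
        m = toy_matrix(vals, peptides=peptides)
        filtered, report = filter_protein_groups(m)
        assert report["retained"] == 120
        assert len(filtered) == 120


class TestClassification:
    def test_constant_values_are_independent(self):
        m = toy_matrix({"flat": [5.0] * 6})
        calls, summary = classify_growth_dependence(m, min_samples=3)
        assert not calls[0].dependent
        assert calls[0].min_pair_p == 1.0

    def test_planted_trend_detected(self, rng):
        """A 2-fold monotone trend across 6 groups (n=5, CV 10%)."""
        spec = SyntheticSpec(seed=11, n_proteins=40, dependent_fraction=1.0,
                             archetype_weights=(1, 0, 0, 0, 0, 0, 0),
                             noise_cv=0.10, missing_rate=0.0,
                             n_contaminants=0, n_reverse=0, n_low_evidence=0)
        m, truth = simulate_proteomics(spec)
        calls, summary = classify_growth_dependence(m)
        assert summary["dependent"] == summary["total"]

    def test_monotone_transform_invariance(self, rng):
        vals = {f"P{i}": list(rng.lognormal(8, 1, 6)) for i in range(15)}
        m = toy_matrix(vals)
        base = calls_frame(classify_growth_dependence(m, min_samples=3)[0])
        m_log = toy_matrix({k: list(np.log2(v)) for k, v in vals.items()})
        logged = calls_frame(classify_growth_dependence(m_log,
                                                        min_samples=3)[0])
        assert (base["dependent"] == logged["dependent"]).all()
        assert np.allclose(base["min_pair_p"], logged["min_pair_p"])

    def test_untestable_proteins_partition_totals(self):
        vals = {"ok": [1, 2, 1, 5, 6, 5],
                "sparse": [1.0, np.nan, np.nan, 2.0, np.nan, np.nan]}
        m = toy_matrix(vals)
        calls, summary = classify_growth_dependence(m, min_samples=3)
        assert summary["dependent"] + summary["independent"] \
            + summary["untestable"] == summary["total"]
        assert summary["untestable"] == 1

    def test_exact_small_sample_p_matches_enumeration(self, rng):
        """Exact-mode p-values reproduce a brute-force enumeration over all
        rank assignments (independent oracle, 3 vs 3)."""
        for _ in range(5):
            x = rng.normal(0.0, 1.0, 3)
            y = rng.normal(0.8, 1.0, 3)
            p_impl = kruskal_wallis_pair(x, y, method="exact")
            # oracle: enumerate group assignments, rank-sum statistic
            pooled = np.concatenate([x, y])
            ranks = stats.rankdata(pooled)
            def h_of(idx):
                r1 = ranks[list(idx)].sum()
                r2 = ranks.sum() - r1
                n = 6
                return (12 / (n * (n + 1))) * (r1 ** 2 / 3 + r2 ** 2 / 3) \
                    - 3 * (n + 1)
            h_obs = h_of(range(3))
            hs = [h_of(c) for c in itertools.combinations(range(6), 3)]
            p_oracle = np.mean([h >= h_obs - 1e-12 for h in hs])
            assert p_impl == pytest.approx(p_oracle, abs=1e-12)

    def test_null_flag_rate_equals_measured_familywise_rate(self):
        """Under a pure null (no dependent proteins) the per-protein flag
        rate is the empirical family-wise rate of the 15 correlated
        pairwise tests -- measured here on two disjoint simulations."""
        rates = []
        for seed in (21, 22):
            spec = SyntheticSpec(seed=seed, n_proteins=400,
                                 dependent_fraction=0.0, missing_rate=0.0,
                                 n_contaminants=0, n_reverse=0,
                                 n_low_evidence=0)
            m, _ = simulate_proteomics(spec)
            _, summary = classify_growth_dependence(m)
            rates.append(summary["dependent"] / summary["total"])
        # the two measurements agree within binomial sampling error
        se = math.sqrt(2 * rates[0] * (1 - rates[0]) / 400)
        assert abs(rates[0] - rates[1]) < 3 * se + 1e-9
        # and the rate is far above the single-test alpha but below the
        # 15-independent-test Bonferroni-style ceiling
        assert 0.05 < np.mean(rates) < 1 - 0.95 ** 15 + 0.05


class TestClustering:
    def test_identical_profiles_select_k1(self):
        vals = {f"P{i}": [3.0, 3.0, 3.0, 6.0, 6.0, 6.0] for i in range(20)}
        res = cluster_profiles(toy_matrix(vals))
        assert res.k == 1

    def test_three_archetypes_recovered_exactly(self):
        spec = SyntheticSpec(seed=5, n_proteins=300, dependent_fraction=1.0,
                             archetype_weights=(1, 1, 0, 0, 1, 0, 0),
                             missing_rate=0.0, n_contaminants=0,
                             n_reverse=0, n_low_evidence=0)
        m, truth = simulate_proteomics(spec)
        res = cluster_profiles(m)
        assert res.k == 3
        ari = adjusted_rand_score(
            truth.loc[res.assignments.index, "archetype"], res.assignments)
        assert ari == pytest.approx(1.0)

    def test_seven_archetypes_recovered(self, archetype_dataset):
        m, truth = archetype_dataset
        res = cluster_profiles(m)
        assert res.k == 7
        ari = adjusted_rand_score(
            truth.loc[res.assignments.index, "archetype"], res.assignments)
        assert ari > 0.9

    def test_centroids_are_member_means(self, archetype_dataset):
        m, _ = archetype_dataset
        res = cluster_profiles(m, k=4)
        for label, group in res.profile_matrix.groupby(res.assignments):
            assert np.allclose(res.centroids.loc[label], group.mean(axis=0))

    def test_elbow_helper_degenerate_inputs(self):
        assert select_k_elbow({1: 0.0, 2: 0.0, 3: 0.0}) == 1
        assert select_k_elbow({1: 5.0, 2: 1.0}) == 1


class TestGOSlim:
    SLIM = {"GO:1": {"Translation"}, "GO:2": {"Translation", "Transport"},
            "GO:3": {"unknown"}, "GO:4": {"Photosynthesis"}}

    def test_empty_and_trivial_annotations_are_unannotated(self):
        mapped, unknown = map_go_slim({"A": [], "B": ["GO:3"]}, self.SLIM)
        assert mapped["A"] == set() and mapped["B"] == set()

    def test_set_semantics_count_once(self):
        mapped, _ = map_go_slim({"A": ["GO:1", "GO:2"]}, self.SLIM)
        assert mapped["A"] == {"Translation", "Transport"}

    def test_unknown_terms_recorded(self):
        mapped, unknown = map_go_slim({"A": ["GO:999"]}, self.SLIM)
        assert unknown == ["GO:999"]
        assert mapped["A"] == set()

    def test_three_level_fixture_counts(self):
        # genes -> GO terms -> slim categories, counts checked by hand
        annotations = {"g1": ["GO:1"], "g2": ["GO:2"], "g3": ["GO:4"],
                       "g4": ["GO:1", "GO:4"], "g5": ["GO:3"]}
        mapped, _ = map_go_slim(annotations, self.SLIM)
        counts = {}
        for cats in mapped.values():
            for cat in cats:
                counts[cat] = counts.get(cat, 0) + 1
        assert counts == {"Translation": 3, "Transport": 1,
                          "Photosynthesis": 2}


class TestEnrichment:
    @staticmethod
    def _calls(n_dep, n_indep):
        dep = [DependenceCall(f"D{i}", True, 0.01, 15)
               for i in range(n_dep)]
        ind = [DependenceCall(f"I{i}", False, 0.5, 15)
               for i in range(n_indep)]
        return dep + ind

    def test_translation_category_imbalance(self):
        """The observed 40-vs-13 translation split over 779/577 proteins is
        a significant over-representation with odds ratio ~2.35."""
        calls = self._calls(779, 577)
        ann = {f"D{i}": {"Translation"} for i in range(40)}
        ann.update({f"I{i}": {"Translation"} for i in range(13)})
        rows = enrich_go_slim(calls, ann)
        row = rows[0]
        assert (row.a, row.b, row.c, row.d) == (40, 13, 739, 564)
        assert row.p < 0.05
        assert row.odds_ratio == pytest.approx((40 * 564) / (13 * 739),
                                               rel=1e-9)

    def test_balanced_table_not_significant(self):
        calls = self._calls(20, 20)
        ann = {f"D{i}": {"X"} for i in range(10)}
        ann.update({f"I{i}": {"X"} for i in range(10)})
        row = enrich_go_slim(calls, ann)[0]
        assert row.p == pytest.approx(1.0)

    def test_p_matches_hypergeometric_enumeration(self, rng):
        """Fisher p equals a direct hypergeometric tail enumeration on
        small tables (margins <= 30)."""
        for _ in range(10):
            a, b, c, d = rng.integers(0, 15, 4)
            n, K, N = a + b + c + d, a + b, a + c
            if n == 0 or K == 0 or K == n or N == 0 or N == n:
                continue
            calls = self._calls(int(a + c), int(b + d))
            ann = {f"D{i}": {"X"} for i in range(a)}
            ann.update({f"I{i}": {"X"} for i in range(b)})
            row = enrich_go_slim(calls, ann)[0]
            # oracle: sum hypergeometric pmf over tables as or less likely
            pmf_obs = stats.hypergeom.pmf(a, n, K, N)
            p_oracle = sum(
                stats.hypergeom.pmf(k, n, K, N)
                for k in range(max(0, K + N - n), min(K, N) + 1)
                if stats.hypergeom.pmf(k, n, K, N) <= pmf_obs * (1 + 1e-9))
            assert row.p == pytest.approx(p_oracle, rel=1e-6)

    def test_invariance_under_simultaneous_swap(self):
        """Swapping rows and columns of the 2x2 table together leaves the
        two-sided Fisher p unchanged."""
        a, b, c, d = 12, 3, 30, 25
        p1 = stats.fisher_exact([[a, b], [c, d]])[1]
        p2 = stats.fisher_exact([[d, c], [b, a]])[1]
        calls = self._calls(a + c, b + d)
        ann = {f"D{i}": {"X"} for i in range(a)}
        ann.update({f"I{i}": {"X"} for i in range(b)})
        assert enrich_go_slim(calls, ann)[0].p == pytest.approx(p1)
        assert p1 == pytest.approx(p2)
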