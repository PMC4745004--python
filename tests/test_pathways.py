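"""Hypergeometric enrichment, pathway overlap, restriction and recurrence."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import mirepress as mr


def exact_upper_tail(N, K, n, k):
    """Exhaustive hypergeometric P(X >= k) from the exact PMF."""
    denom = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j) / denom
        for j in range(k, min(K, n) + 1)
    )


def collection(**pathways):
    return mr.PathwayCollection({pid: (pid, frozenset(genes)) for pid, genes in pathways.items()})


class TestHypergeomEnrich:
    def test_full_overlap_worked_value(self):
        # choosing all 5 pathway genes among 5 hits from 20: 1 / C(20,5) = 1/15504
        universe = {f"g{i}" for i in range(20)}
        pw = collection(P1=[f"g{i}" for i in range(5)])
        result = mr.hypergeom_enrich({f"g{i}" for i in range(5)}, pw, universe)
        assert result.rows.loc["P1", "p_value"] == pytest.approx(1 / 15504, rel=1e-12)
        assert result.rows.loc["P1", "enriched"]

    def test_partial_overlap_worked_value(self):
        # N=10, K=4, n=5, k=3: (C(4,3)C(6,2)+C(4,4)C(6,1))/C(10,5) = 66/252
        universe = {f"g{i}" for i in range(10)}
        pw = collection(P1=["g0", "g1", "g2", "g3"])
        hits = {"g0", "g1", "g2", "g4", "g5"}
        result = mr.hypergeom_enrich(hits, pw, universe)
        assert result.rows.loc["P1", "p_value"] == pytest.approx(66 / 252, rel=1e-12)
        assert not result.rows.loc["P1", "enriched"]

    def test_pathway_equal_to_universe_certain(self):
        universe = {"g0", "g1", "g2"}
        result = mr.hypergeom_enrich({"g0"}, collection(P1=universe), universe)
        assert result.rows.loc["P1", "p_value"] == 1.0
        assert not result.rows.loc["P1", "enriched"]

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            mr.hypergeom_enrich({"x"}, collection(P1=["g0"]), {"g0"})

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            mr.hypergeom_enrich(set(), collection(P1=["g0"]), set())

    def test_matches_exact_tail_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            N = int(rng.integers(1, 61))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(0, N + 1))
            universe = {f"g{i}" for i in range(N)}
            pw = collection(P1=[f"g{i}" for i in range(K)])
            hits = set(rng.choice(sorted(universe), size=n, replace=False))
            k = len(hits & pw.genes_of("P1"))
            result = mr.hypergeom_enrich(hits, pw, universe)
            assert result.rows.loc["P1", "p_value"] == pytest.approx(
                exact_upper_tail(N, K, n, k), abs=1e-12
            )


def enrichment_with(enriched_ids, all_ids):
    rows = pd.DataFrame(
        {
            "overlap_count": 0,
            "pathway_size": 1,
            "hit_count": 0,
            "universe_size": 1,
            "p_value": [0.01 if p in enriched_ids else 0.9 for p in all_ids],
            "enriched": [p in enriched_ids for p in all_ids],
        },
        index=list(all_ids),
    )
    return mr.EnrichmentResult(rows)


class TestOverlappedPathways:
    def test_single_sample_identity(self):
        per_sample = {"s1": enrichment_with({"P1", "P3"}, ["P1", "P2", "P3"])}
        assert mr.overlapped_pathways(per_sample) == {"P1", "P3"}

    def test_two_sample_intersection(self):
        per_sample = {
            "s1": enrichment_with({"P1", "P2"}, ["P1", "P2", "P3"]),
            "s2": enrichment_with({"P2", "P3"}, ["P1", "P2", "P3"]),
        }
        assert mr.overlapped_pathways(per_sample) == {"P2"}

    def test_monotone_in_samples(self):
        rng = np.random.default_rng(4)
        ids = [f"P{i}" for i in range(8)]
        per_sample = {}
        previous = set(ids)
        for s in range(5):
            per_sample[f"s{s}"] = enrichment_with(
                {p for p in ids if rng.random() < 0.6}, ids
            )
            current = mr.overlapped_pathways(per_sample)
            assert current <= previous
            previous = current

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mr.overlapped_pathways({})


def diff_table(keys):
    df = pd.DataFrame(
        {c: 0.0 for c in mr.DifferentialTable.COLUMNS}, index=pd.Index(keys)
    )
    df["significant"] = False
    return mr.DifferentialTable(df)


class TestRestrictToPathways:
    def test_all_pathways_identity(self):
        pw = collection(P1=["g1", "g2"], P2=["g3"])
        table = diff_table(["g1", "g2", "g3"])
        out = mr.restrict_to_pathways(table, pw, {"P1", "P2"})
        assert list(out.rows.index) == ["g1", "g2", "g3"]

    def test_empty_selection_empty_table(self):
        pw = collection(P1=["g1"])
        assert len(mr.restrict_to_pathways(diff_table(["g1"]), pw, set())) == 0

    def test_membership_filter_preserves_order(self):
        pw = collection(P1=["g2", "g5", "g7"], P2=["g0"])
        keys = [f"g{i}" for i in range(10)]
        out = mr.restrict_to_pathways(diff_table(keys), pw, {"P1"})
        assert list(out.rows.index) == ["g2", "g5", "g7"]

    def test_interaction_keys_filtered_by_gene(self):
        pw = collection(P1=["g1"])
        idx = pd.MultiIndex.from_tuples([("m1", "g1"), ("m1", "g2"), ("m2", "g1")])
        table = mr.DifferentialTable(
            pd.DataFrame({c: 0.0 for c in mr.DifferentialTable.COLUMNS}, index=idx)
        )
        out = mr.restrict_to_pathways(table, pw, {"P1"})
        assert list(out.rows.index) == [("m1", "g1"), ("m2", "g1")]

    def test_unknown_pathway_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            mr.restrict_to_pathways(diff_table(["g1"]), collection(P1=["g1"]), {"P9"})


class TestRecurrentElements:
    def test_identical_sets(self):
        s = {"a", "b", "c"}
        out = mr.recurrent_elements({"s1": s, "s2": s, "s3": s, "s4": s})
        assert out.intersection == s
        assert out.region_counts == {("s1", "s2", "s3", "s4"): 3}

    def test_disjoint_sets(self):
        out = mr.recurrent_elements({"s1": {"a"}, "s2": {"b"}})
        assert out.intersection == frozenset()
        assert sum(out.region_counts.values()) == 2

    def test_four_set_enumeration(self):
        sets = {"s1": {"1", "2", "3"}, "s2": {"2", "3", "4"}, "s3": {"2", "3"}, "s4": {"2", "3", "5"}}
        out = mr.recurrent_elements(sets)
        assert out.intersection == {"2", "3"}
        assert sum(out.region_counts.values()) == 5
        assert out.region_counts[("s1",)] == 1  # element "1"
        assert out.region_counts[("s2",)] == 1  # element "4"
        assert out.region_counts[("s4",)] == 1  # element "5"

    def test_region_counts_satisfy_inclusion_exclusion(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            ids = [f"s{i}" for i in range(int(rng.integers(2, 5)))]
            universe = [f"e{i}" for i in range(15)]
            sets = {s: {e for e in universe if rng.random() < 0.5} for s in ids}
            out = mr.recurrent_elements(sets)
            # pairwise and triple intersections recomputed directly from regions
            for r in range(2, len(ids) + 1):
                for combo in itertools.combinations(ids, r):
                    direct = set.intersection(*(set(sets[s]) for s in combo))
                    from_regions = sum(
                        c for region, c in out.region_counts.items()
                        if set(combo) <= set(region)
                    )
                    assert from_regions == len(direct)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mr.recurrent_elements({})


class TestCountTargetsPerPathway:
    def test_no_targets_in_selected(self):
        inter = mr.InteractionTable.from_records([("a", "gX", 1.0)])
        pw = collection(P1=["g1"])
        out = mr.count_targets_per_pathway({"a"}, inter, pw, {"P1"})
        assert out == {"P1": {"a": 0}}

    def test_partial_overlap(self):
        inter = mr.InteractionTable.from_records(
            [("a", "g1", 1.0), ("a", "g2", 1.0), ("a", "g3", 1.0)]
        )
        pw = collection(P=["g2", "g3"])
        assert mr.count_targets_per_pathway({"a"}, inter, pw, {"P"})["P"]["a"] == 2

    def test_random_instance_matches_double_loop(self):
        rng = np.random.default_rng(33)
        genes = [f"g{i}" for i in range(60)]
        records = []
        for i in range(20):
            for g in rng.choice(genes, size=8, replace=False):
                records.append((f"m{i}", str(g), 1.0))
        inter = mr.InteractionTable.from_records(records)
        pw_sets = {f"P{j}": set(rng.choice(genes, size=15, replace=False)) for j in range(4)}
        pw = collection(**{k: list(v) for k, v in pw_sets.items()})
        mirnas = {f"m{i}" for i in range(20)}
        out = mr.count_targets_per_pathway(mirnas, inter, pw, set(pw_sets))
        for pid, gset in pw_sets.items():
            for m in mirnas:
                expected = sum(
                    1 for mm, g, _ in records if mm == m and g in gset
                )
                assert out[pid][m] == expected
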