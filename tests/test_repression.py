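"""Score-proportional apportionment of miRNA abundance and its invariants."""

import logging

import numpy as np
import pandas as pd
import pytest

import mirepress as mr
from conftest import make_tpm


def brute_force(tpm: dict, records: list) -> tuple[dict, dict]:
    """Independent O(|interactions|) oracle: per-miRNA score sums, then
    loop over every (miRNA, gene) record accumulating tpm·score/score_sum."""
    score_sum: dict = {}
    for m, g, s in records:
        score_sum[m] = score_sum.get(m, 0.0) + s
    repression: dict = {}
    contributions: dict = {}
    for m, g, s in records:
        if score_sum[m] <= 0:
            continue
        c = tpm.get(m, 0.0) * s / score_sum[m]
        repression[g] = repression.get(g, 0.0) + c
        contributions[(m, g)] = c
    return repression, contributions


class TestTargetWeights:
    def test_proportional_split(self):
        table = mr.InteractionTable.from_records([("a", "alpha", 60.0), ("a", "beta", 40.0)])
        w = mr.target_weights(table).weights.set_index(["mirna_id", "gene_id"])["weight"]
        assert w[("a", "alpha")] == pytest.approx(0.6, abs=1e-15)
        assert w[("a", "beta")] == pytest.approx(0.4, abs=1e-15)

    def test_single_target_weight_one(self):
        table = mr.InteractionTable.from_records([("a", "alpha", 77.0)])
        w = mr.target_weights(table).weights
        assert w["weight"].tolist() == [1.0]

    def test_zero_score_mirna_dropped_with_warning(self, caplog):
        table = mr.InteractionTable.from_records(
            [("a", "alpha", 0.0), ("a", "beta", 0.0), ("b", "alpha", 5.0)]
        )
        with caplog.at_level(logging.WARNING, logger="mirepress.repression"):
            w = mr.target_weights(table)
        assert set(w.weights["mirna_id"]) == {"b"}
        assert any("a" in rec.message for rec in caplog.records)


class TestRepressionScores:
    def test_single_mirna_split(self):
        weights = mr.target_weights(
            mr.InteractionTable.from_records([("a", "alpha", 60.0), ("a", "beta", 40.0)])
        )
        result = mr.repression_scores(make_tpm("s", {"a": 100.0}), weights)
        assert result.repression["alpha"] == pytest.approx(60.0)
        assert result.repression["beta"] == pytest.approx(40.0)
        assert result.total == pytest.approx(100.0)

    def test_two_mirna_accumulation_matches_oracle(self):
        records = [("a", "alpha", 50.0), ("a", "beta", 50.0), ("b", "alpha", 10.0)]
        tpm = {"a": 100.0, "b": 200.0}
        weights = mr.target_weights(mr.InteractionTable.from_records(records))
        result = mr.repression_scores(make_tpm("s", tpm), weights)
        expected, _ = brute_force(tpm, records)
        assert expected == {"alpha": 250.0, "beta": 50.0}
        for g, v in expected.items():
            assert result.repression[g] == pytest.approx(v, abs=1e-10)
        assert result.total == pytest.approx(300.0)

    def test_zero_tpm_on_all_targeting_mirnas(self):
        weights = mr.target_weights(mr.InteractionTable.from_records([("a", "alpha", 1.0)]))
        result = mr.repression_scores(make_tpm("s", {"a": 0.0}), weights)
        assert result.total == 0.0
        assert (result.repression == 0).all()

    def test_contributions_match_oracle_and_aggregate(self):
        records = [("a", "alpha", 50.0), ("a", "beta", 50.0), ("b", "alpha", 10.0)]
        tpm = {"a": 100.0, "b": 200.0}
        weights = mr.target_weights(mr.InteractionTable.from_records(records))
        profile = make_tpm("s", tpm)
        contrib = mr.interaction_contributions(profile, weights)
        _, expected = brute_force(tpm, records)
        assert expected == {("a", "alpha"): 50.0, ("a", "beta"): 50.0, ("b", "alpha"): 200.0}
        for pair, v in expected.items():
            assert contrib.contributions[pair] == pytest.approx(v, abs=1e-10)
        by_gene = contrib.by_gene()
        repression = mr.repression_scores(profile, weights).repression
        pd.testing.assert_series_equal(
            by_gene.sort_index(), repression.sort_index(), check_names=False
        )

    def test_empty_weights_empty_table(self):
        weights = mr.target_weights(mr.InteractionTable.from_records([]))
        contrib = mr.interaction_contributions(make_tpm("s", {"a": 10.0}), weights)
        assert contrib.contributions.empty


def random_instance(rng):
    n_mirnas = int(rng.integers(1, 12))
    n_genes = int(rng.integers(1, 15))
    records = []
    for i in range(n_mirnas):
        targets = rng.choice(n_genes, size=int(rng.integers(1, n_genes + 1)), replace=False)
        for g in targets:
            records.append((f"m{i}", f"g{g}", float(rng.uniform(0, 100))))
    expressed = [f"m{i}" for i in range(n_mirnas) if rng.random() < 0.8]
    raw = {m: float(rng.uniform(0, 1000)) for m in expressed}
    total = sum(raw.values())
    if total <= 0:
        raw = {"m0": 1.0}
        total = 1.0
    tpm = {m: v / total * 1e6 for m, v in raw.items()}
    return tpm, records


def test_agreement_with_naive_oracle_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(100):
        tpm, records = random_instance(rng)
        weights = mr.target_weights(mr.InteractionTable.from_records(records))
        result = mr.repression_scores(mr.NormalizedProfile("s", tpm), weights)
        contrib = mr.interaction_contributions(mr.NormalizedProfile("s", tpm), weights)
        exp_rep, exp_contrib = brute_force(tpm, records)
        # abs tolerance for small masses, rel for TPM-scale sums whose
        # summation order differs between the two routes
        for g in set(exp_rep) | set(result.repression.index):
            assert result.repression.get(g, 0.0) == pytest.approx(
                exp_rep.get(g, 0.0), rel=1e-12, abs=1e-10
            )
        for pair in set(exp_contrib) | set(contrib.contributions.index):
            assert contrib.contributions.get(pair, 0.0) == pytest.approx(
                exp_contrib.get(pair, 0.0), rel=1e-12, abs=1e-10
            )


def test_mass_conservation_on_random_instances():
    """Σ_α R(α) equals the total TPM of target-bearing miRNAs: mass is
    apportioned, never created."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        tpm, records = random_instance(rng)
        weights = mr.target_weights(mr.InteractionTable.from_records(records))
        result = mr.repression_scores(mr.NormalizedProfile("s", tpm), weights)
        retained = set(weights.weights["mirna_id"])
        expected_total = sum(v for m, v in tpm.items() if m in retained)
        assert result.total == pytest.approx(expected_total, rel=1e-9, abs=1e-9)


def test_linearity_via_mixture():
    """Repression of an average of profiles equals the average of repressions."""
    rng = np.random.default_rng(3)
    tpm_a, records = random_instance(rng)
    raw_b = {m: float(rng.uniform(1, 100)) for m in tpm_a}
    total_b = sum(raw_b.values())
    tpm_b = {m: v / total_b * 1e6 for m, v in raw_b.items()}
    weights = mr.target_weights(mr.InteractionTable.from_records(records))
    mix = mr.average_controls(
        [mr.NormalizedProfile("a", tpm_a), mr.NormalizedProfile("b", tpm_b)]
    )
    r_mix = mr.repression_scores(mix, weights).repression
    r_a = mr.repression_scores(mr.NormalizedProfile("a", tpm_a), weights).repression
    r_b = mr.repression_scores(mr.NormalizedProfile("b", tpm_b), weights).repression
    for g in r_mix.index:
        assert r_mix[g] == pytest.approx((r_a[g] + r_b[g]) / 2, rel=1e-9, abs=1e-9)
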