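import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from pollencast.magn import (
    magn_build,
    magn_predict,
    mine_patterns,
    mine_rules,
    mutual_information,
    normalized_mi,
    season_rules,
    tercile_bins,
)
from pollencast.metrics import scheme_for


def _rows(n=10, seed=0, values=4):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "a": rng.integers(0, values, n).astype(float),
            "b": rng.integers(0, 3, n).astype(float),
        }
    )
    df["target"] = rng.choice(["x", "y"], n)
    return df


class TestGraphBuild:
    def test_field_counters_sum_to_row_count(self):
        df = _rows(10, seed=1)
        g = magn_build(df)
        for f in g.fields.values():
            assert f.counters.sum() == 10
        assert g.object_counters.sum() == 10

    def test_distinct_values_become_sensory_neurons(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 2.0, 3.0, 4.0, 4.0, 4.0, 1.0, 2.0, 3.0]})
        df["target"] = "x"
        g = magn_build(df)
        assert len(g.fields["a"].values) == 4
        assert g.fields["a"].counters.sum() == 10

    def test_duplicate_row_aggregates_into_counter(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 2.0], "target": ["x", "x", "y"]})
        g = magn_build(df)
        assert g.n_objects == 2
        assert sorted(g.object_counters.tolist()) == [1, 2]

    def test_single_row_graph(self):
        df = pd.DataFrame({"a": [1.0], "b": [2.0], "target": ["x"]})
        g = magn_build(df)
        assert g.n_objects == 1
        assert all(len(f.values) == 1 and f.counters[0] == 1 for f in g.fields.values())

    def test_empty_and_missing_target_rejected(self):
        with pytest.raises(ValueError):
            magn_build(pd.DataFrame())
        with pytest.raises(ValueError):
            magn_build(pd.DataFrame({"a": [1.0]}), target="target")

    def test_neighbor_weights_follow_value_gaps(self):
        df = pd.DataFrame({"a": [0.0, 1.0, 3.0], "target": list("xyz")})
        g = magn_build(df, weight_fields=False)
        np.testing.assert_allclose(g.fields["a"].neighbor_weights(), [1 - 1 / 3, 1 - 2 / 3])

    def test_serializes_to_plain_dict(self):
        d = magn_build(_rows(8, seed=2)).to_dict()
        assert d["n_rows"] == 8
        assert set(d["fields"]) == {"a", "b"}


class TestSimilarityVoting:
    def test_single_voter_returns_its_target(self):
        g = magn_build(pd.DataFrame({"a": [1.0], "target": ["hit"]}))
        assert magn_predict(g, {"a": 99.0}, k=3) == "hit"

    def test_exact_match_of_unique_row_wins_top1(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        df["target"] = rng.choice(["x", "y", "z"], 40)
        g = magn_build(df)
        for i in (0, 13, 39):
            q = df.iloc[i][list("abc")].to_dict()
            assert magn_predict(g, q, k=1) == df.iloc[i]["target"]

    def test_unanimous_targets_vote_constant(self):
        df = _rows(12, seed=3)
        df["target"] = "only"
        g = magn_build(df)  # constant target: fields stay unweighted
        assert g.field_weights is None
        assert magn_predict(g, {"a": 0.0, "b": 1.0}) == "only"

    def test_regression_mode_weighted_mean(self):
        df = pd.DataFrame({"a": [0.0, 10.0], "target": [1.0, 3.0]})
        g = magn_build(df)
        pred = magn_predict(g, {"a": 0.0}, k=2, mode="regression")
        assert 1.0 <= pred < 2.0  # pulled toward the exact match

    def test_unseen_categorical_value_contributes_zero_not_error(self):
        df = pd.DataFrame({"a": ["u", "v", "u"], "b": [1.0, 2.0, 3.0], "target": ["x", "y", "x"]})
        assert magn_predict(magn_build(df), {"a": "w", "b": 1.0}, k=1) in {"x", "y"}

    def test_schema_violations_rejected(self):
        g = magn_build(_rows(5, seed=4))
        with pytest.raises(ValueError):
            magn_predict(g, {"zzz": 1.0})
        with pytest.raises(ValueError):
            magn_predict(g, {"a": 1.0}, k=0)

    def test_range_activation_variant_still_self_retrieves(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(20, 2)), columns=list("ab"))
        df["target"] = [f"t{i}" for i in range(20)]
        g = magn_build(df)
        q = df.iloc[7][list("ab")].to_dict()
        assert magn_predict(g, q, k=1, activation="range") == "t7"


class TestMutualInformation:
    def test_independent_joint_is_zero(self):
        joint = np.outer([0.2, 0.3, 0.5], [0.6, 0.4])
        assert abs(mutual_information(joint)) < 1e-12

    def test_identical_fair_binary_is_one_bit(self):
        assert mutual_information(np.array([[0.5, 0.0], [0.0, 0.5]])) == pytest.approx(1.0)

    def test_hand_computed_joint(self):
        mi = mutual_information(np.array([[0.4, 0.1], [0.1, 0.4]]))
        expected = 2 * 0.4 * np.log2(0.4 / 0.25) + 2 * 0.1 * np.log2(0.1 / 0.25)
        assert mi == pytest.approx(expected, abs=1e-12)
        assert mi == pytest.approx(0.278, abs=5e-4)

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(np.array([[0.5, 0.6]]))

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            j = rng.random((3, 4))
            j /= j.sum()
            assert mutual_information(j) >= -1e-15
            assert mutual_information(j) == pytest.approx(mutual_information(j.T), abs=1e-12)


class TestNormalizedMi:
    def test_deterministic_function_reaches_one(self):
        x = np.repeat(np.arange(9.0), 30)
        y = np.where(x < 3, "a", np.where(x < 6, "b", "c")).astype(object)
        assert normalized_mi(x, y) == pytest.approx(1.0)

    def test_independent_noise_is_near_zero(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=6000)
        y = rng.choice(["a", "b", "c"], 6000).astype(object)
        assert normalized_mi(x, y) < 0.01

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError):
            normalized_mi(np.arange(10.0), np.array(["a"] * 10, dtype=object))

    def test_repeated_call_is_deterministic(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=200), rng.choice(["a", "b"], 200).astype(object)
        assert normalized_mi(x, y) == normalized_mi(x, y)

    def test_coarsening_bins_never_increases_mi(self):
        from pollencast.magn import _joint_from_codes

        rng = np.random.default_rng(11)
        x = rng.normal(size=2000)
        y = (x + rng.normal(size=2000) > 0).astype(int)
        fine = tercile_bins(x, 4)
        # nested coarsening: merge fine quartile bins pairwise
        coarse = fine // 2
        mi_fine = mutual_information(_joint_from_codes(fine, y))
        mi_coarse = mutual_information(_joint_from_codes(coarse, y))
        assert mi_coarse <= mi_fine + 1e-12


def brute_force_patterns(rows: pd.DataFrame, min_support: Fraction):
    """Exhaustive itemset enumeration with exact rational supports."""
    n = len(rows)
    trans = [
        frozenset((c, v) for c, v in zip(rows.columns, rec))
        for rec in rows.itertuples(index=False, name=None)
    ]
    items = sorted(set().union(*trans), key=str)
    out = {}
    for r in range(1, len(rows.columns) + 1):
        for combo in itertools.combinations(items, r):
            s = frozenset(combo)
            if len({f for f, _ in s}) != len(s):
                continue
            c = sum(1 for t in trans if s <= t)
            if c and Fraction(c, n) >= min_support:
                out[s] = c
    return out


class TestMining:
    def test_support_definition(self):
        rows = pd.DataFrame({"f": ["a"] * 3 + ["b"] * 7})
        pats = {p.items: p.support for p in mine_patterns(rows, 0.3)}
        assert pats[frozenset({("f", "a")})] == Fraction(3, 10)

    def test_min_support_one_keeps_only_universal_patterns(self):
        rows = pd.DataFrame({"f": ["a"] * 5, "g": ["u", "u", "u", "u", "v"]})
        pats = mine_patterns(rows, 1.0)
        assert {p.items for p in pats} == {frozenset({("f", "a")})}

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(12)
        rows = pd.DataFrame({f"f{j}": rng.choice(list("abc"), 60) for j in range(3)})
        mined = {p.items: (p.count, p.support) for p in mine_patterns(rows, 0.1)}
        brute = brute_force_patterns(rows, Fraction(1, 10))
        assert {k: v[0] for k, v in mined.items()} == brute
        assert all(sup == Fraction(cnt, 60) for cnt, sup in mined.values())

    def test_rule_metrics_are_exact_rationals(self):
        rng = np.random.default_rng(13)
        rows = pd.DataFrame({f"f{j}": rng.choice(list("ab"), 40) for j in range(3)})
        pats = mine_patterns(rows, 0.1)
        rules = mine_rules(pats, rows, 0.2)
        assert rules, "fixture should produce rules"
        trans = [
            frozenset((c, v) for c, v in zip(rows.columns, rec))
            for rec in rows.itertuples(index=False, name=None)
        ]
        for r in rules:
            sa = Fraction(sum(1 for t in trans if r.antecedent <= t), 40)
            sb = Fraction(sum(1 for t in trans if r.consequent <= t), 40)
            sab = Fraction(sum(1 for t in trans if (r.antecedent | r.consequent) <= t), 40)
            assert r.support == sab
            assert r.confidence == sab / sa <= 1
            assert r.lift == (sab / sa) / sb

    def test_universal_consequent_has_unit_lift(self):
        rows = pd.DataFrame({"f": ["a", "a", "b", "b"], "g": ["u"] * 4})
        rules = mine_rules(mine_patterns(rows, 0.25), rows, 0.25)
        for r in rules:
            if r.consequent == frozenset({("g", "u")}):
                assert r.lift == 1

    def test_invalid_thresholds_rejected(self):
        rows = pd.DataFrame({"f": ["a"]})
        with pytest.raises(ValueError):
            mine_patterns(rows, 0.0)
        with pytest.raises(ValueError):
            mine_rules([], rows, 1.5)


class TestSeasonRules:
    @staticmethod
    def _planted_fixture():
        """90-day series where three hot days always precede a high-pollen
        day and cool days precede low days."""
        dates = pd.date_range("2022-04-01", periods=90, freq="D")
        rng = np.random.default_rng(14)
        blocks = rng.permutation(np.repeat([50, 150, 250], 30))  # tenths degC
        tg = np.repeat(blocks[:30], 3)
        meteo = pd.DataFrame({"date": dates})
        meteo["tg"] = pd.array(tg, dtype="Int64")
        for v, base in (("tn", 40), ("tx", 260), ("hu", 55), ("cc", 4), ("ss", 50),
                        ("fg", 25), ("pp", 10130), ("qq", 160), ("sd", 0)):
            meteo[v] = pd.array(rng.integers(base, base + 3, 90), dtype="Int64")
        trailing = pd.Series(tg, dtype=float).rolling(3).mean().shift(1)
        conc = np.where(trailing >= 200, 100.0, 2.0)
        conc[:3] = 2.0
        pollen = pd.DataFrame({"date": dates, "taxon": "Betula", "concentration": conc})
        from pollencast.io_ingest import extract_seasons

        return extract_seasons(pollen), meteo

    def test_planted_rule_recovered_with_high_confidence(self):
        seasons, meteo = self._planted_fixture()
        rules, table = season_rules(seasons, meteo, scheme_for("Betula"), 0.1, 0.5)
        hits = [
            r
            for r in rules
            if r.antecedent == frozenset({("tg_3d", "high")})
            and r.consequent == frozenset({("class", "high")})
        ]
        assert hits and hits[0].confidence > 0.8

    def test_min_support_above_class_frequency_gives_no_rules(self):
        seasons, meteo = self._planted_fixture()
        rules, _ = season_rules(seasons, meteo, scheme_for("Betula"), 0.95, 0.1)
        assert rules == []

    def test_consistent_with_generic_mining_on_same_table(self):
        seasons, meteo = self._planted_fixture()
        rules, table = season_rules(seasons, meteo, scheme_for("Betula"), 0.1, 0.5)
        generic = mine_rules(mine_patterns(table, 0.1), table, 0.5)
        generic = {
            (r.antecedent, r.consequent): (r.support, r.confidence, r.lift) for r in generic
        }
        for r in rules:
            assert generic[(r.antecedent, r.consequent)] == (r.support, r.confidence, r.lift)
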