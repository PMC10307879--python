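"""ORA, FPKM→TPM, bulk edge confirmation, and KM/log-rank survival."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import placenet as pn
from placenet.validation import SurvivalData, read_survival


class TestReadGMT:
    def test_members_deduplicated(self, tmp_path):
        f = tmp_path / "sets.gmt"
        f.write_text("SET1\tdesc\tA\tB\tA\n")
        assert pn.read_gmt(f) == {"SET1": {"A", "B"}}

    def test_short_line_errors_with_number(self, tmp_path):
        f = tmp_path / "bad.gmt"
        f.write_text("SET1\tdesc\tA\nSET2\tonly-desc\n")
        with pytest.raises(ValueError, match="line 2"):
            pn.read_gmt(f)

    def test_empty_file_warns(self, tmp_path, caplog):
        f = tmp_path / "empty.gmt"
        f.write_text("")
        with caplog.at_level("WARNING"):
            assert pn.read_gmt(f) == {}
        assert caplog.records

    def test_three_line_fixture_matches_hand_built(self, tmp_path):
        f = tmp_path / "sets.gmt"
        f.write_text("S1\td\tA\tB\nS2\td\tC\nS3\td\tA\tC\tD\n")
        assert pn.read_gmt(f) == {"S1": {"A", "B"}, "S2": {"C"}, "S3": {"A", "C", "D"}}


def hypergeom_upper_oracle(k, M, n, N):
    """P(X >= k) by direct combinatorial enumeration."""
    total = math.comb(M, N)
    return sum(
        math.comb(n, i) * math.comb(M - n, N - i) for i in range(k, min(n, N) + 1)
    ) / total


class TestORA:
    def test_three_in_five_of_ten(self):
        universe = [f"g{i}" for i in range(10)]
        collection = {"SET": set(universe[:5])}
        table = pn.ora(universe[:3], collection, universe)
        assert math.isclose(table["p"].iloc[0], 10 / 120)
        assert math.isclose(table["p"].iloc[0], hypergeom_upper_oracle(3, 10, 5, 3))

    def test_disjoint_query_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        table = pn.ora(universe[5:8], {"SET": set(universe[:3])}, universe)
        assert table["overlap"].iloc[0] == 0
        assert table["p"].iloc[0] == 1.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_enumeration_oracle_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(40)]
        collection = {
            f"S{j}": set(rng.choice(universe, size=rng.integers(3, 15), replace=False))
            for j in range(5)
        }
        query = list(rng.choice(universe, size=8, replace=False))
        table = pn.ora(query, collection, universe).set_index("set")
        for name, members in collection.items():
            k = len(set(query) & members)
            expected = hypergeom_upper_oracle(k, 40, len(members), 8) if k else 1.0
            assert math.isclose(table.loc[name, "p"], expected, rel_tol=1e-9)

    def test_relabeling_invariance(self):
        universe = [f"g{i}" for i in range(20)]
        collection = {"S": set(universe[:6])}
        q = universe[:4]
        p1 = pn.ora(q, collection, universe)["p"].iloc[0]
        ren = {g: f"x_{g}" for g in universe}
        p2 = pn.ora(
            [ren[g] for g in q],
            {"S": {ren[g] for g in collection["S"]}},
            [ren[g] for g in universe],
        )["p"].iloc[0]
        assert p1 == p2

    def test_query_outside_universe_dropped_and_empty_errors(self):
        universe = ["a", "b", "c", "d"]
        table = pn.ora(["a", "zzz"], {"S": {"a", "b"}}, universe)
        assert table["overlap"].iloc[0] == 1
        with pytest.raises(ValueError):
            pn.ora(["zzz"], {"S": {"a"}}, universe)
        with pytest.raises(ValueError):
            pn.ora(["a"], {"S": {"a"}}, [])


class TestFpkmToTpm:
    def test_single_gene_takes_the_million(self):
        out = pn.fpkm_to_tpm(pd.DataFrame({"s1": [7.0]}, index=["g"]))
        assert out.iloc[0, 0] == 1e6

    def test_proportional_share(self):
        out = pn.fpkm_to_tpm(pd.DataFrame({"s1": [1.0, 3.0]}, index=["a", "b"]))
        assert list(out["s1"]) == [250000.0, 750000.0]

    def test_matches_per_sample_loop_oracle(self):
        rng = np.random.default_rng(17)
        fpkm = pd.DataFrame(
            rng.gamma(2, 5, size=(50, 200)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{j}" for j in range(200)],
        )
        out = pn.fpkm_to_tpm(fpkm)
        for s in fpkm.columns[:20]:
            total = fpkm[s].sum()
            expected = [v / total * 1e6 for v in fpkm[s]]
            assert np.allclose(out[s], expected, atol=1e-9)
        assert np.allclose(out.sum(axis=0), 1e6, rtol=1e-6)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        fpkm = pd.DataFrame(rng.gamma(2, 5, size=(10, 4)))
        once = pn.fpkm_to_tpm(fpkm)
        assert np.allclose(pn.fpkm_to_tpm(once), once)

    def test_all_zero_sample_named(self):
        fpkm = pd.DataFrame({"ok": [1.0], "dead": [0.0]}, index=["g"])
        with pytest.raises(ValueError, match="dead"):
            pn.fpkm_to_tpm(fpkm)


class TestConfirmEdges:
    def make_bulk(self, rho_list, n=100, seed=0):
        rng = np.random.default_rng(seed)
        anchor = rng.normal(size=n)
        rows = {"ANCHOR": anchor}
        for i, rho in enumerate(rho_list):
            noise = rng.normal(size=n)
            rows[f"P{i}"] = rho * anchor + math.sqrt(1 - rho**2) * noise
        return pd.DataFrame(rows).T

    def test_empty_partner_list(self):
        bulk = self.make_bulk([0.9])
        _, summary = pn.confirm_edges("ANCHOR", [], bulk)
        assert summary.startswith("0 of 0")

    def test_two_of_three_confirmed(self):
        bulk = self.make_bulk([0.9, 0.9, 0.0], n=100, seed=1)
        records, summary = pn.confirm_edges("ANCHOR", ["P0", "P1", "P2"], bulk)
        # oracle: per-pair pearson + threshold
        for rec in records:
            r, p, _ = pn.pearson_with_p(bulk.loc["ANCHOR"], bulk.loc[rec.partner])
            assert rec.confirmed == (r > 0.5 and p < 0.05)
        assert summary.startswith("2 of 3")

    def test_exact_copy_confirmed_with_r_one(self):
        bulk = self.make_bulk([])
        bulk.loc["COPY"] = bulk.loc["ANCHOR"]
        records, _ = pn.confirm_edges("ANCHOR", ["COPY"], bulk)
        assert records[0].confirmed and records[0].r == 1.0

    def test_missing_partner_counts_as_unconfirmed_by_default(self):
        bulk = self.make_bulk([0.95], seed=3)
        records, summary = pn.confirm_edges("ANCHOR", ["P0", "GONE"], bulk)
        assert summary.startswith("1 of 2")
        _, summary_ex = pn.confirm_edges(
            "ANCHOR", ["P0", "GONE"], bulk, untestable="exclude"
        )
        assert summary_ex.startswith("1 of 1")

    def test_summary_fraction_equals_mean_of_flags(self):
        bulk = self.make_bulk([0.9, 0.4, 0.7, 0.0], seed=5)
        records, summary = pn.confirm_edges("ANCHOR", [f"P{i}" for i in range(4)], bulk)
        k = int(summary.split()[0])
        assert k == sum(r.confirmed for r in records)

    def test_too_few_samples_errors(self):
        bulk = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["ANCHOR"])
        with pytest.raises(ValueError, match="3 samples"):
            pn.confirm_edges("ANCHOR", [], bulk)


def logrank_oracle(times_a, events_a, times_b, events_b):
    """By-hand risk-set tabulation of the two-group log-rank chi-square."""
    data = [(t, e, 0) for t, e in zip(times_a, events_a)] + [
        (t, e, 1) for t, e in zip(times_b, events_b)
    ]
    event_times = sorted({t for t, e, _ in data if e == 1})
    O_a = E_a = V = 0.0
    for t in event_times:
        at_risk = [(tt, ee, g) for tt, ee, g in data if tt >= t]
        n = len(at_risk)
        n_a = sum(1 for _, _, g in at_risk if g == 0)
        d = sum(1 for tt, ee, _ in at_risk if tt == t and ee == 1)
        d_a = sum(1 for tt, ee, g in at_risk if tt == t and ee == 1 and g == 0)
        O_a += d_a
        E_a += d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return (O_a - E_a) ** 2 / V


class TestKMLogrank:
    def make_survival(self, times, events):
        idx = [f"s{i}" for i in range(len(times))]
        return SurvivalData(pd.Series(times, index=idx, dtype=float),
                            pd.Series(events, index=idx))

    def test_identical_groups_give_null_statistic(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [1, 1, 0, 1, 1, 0]
        surv = self.make_survival(times, events)
        values = pd.Series([10, 10, 10, 1, 1, 1], index=surv.samples, dtype=float)
        res = pn.km_logrank(values, surv)
        assert res["chi_square"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)
        assert res["n_high"] == 3 and res["n_low"] == 3

    def test_textbook_two_by_two_matches_hand_tabulation(self):
        surv = self.make_survival([1, 2, 3, 4], [1, 1, 1, 1])
        values = pd.Series([5, 5, 1, 1], index=surv.samples, dtype=float)
        res = pn.km_logrank(values, surv)
        expected = logrank_oracle([1, 2], [1, 1], [3, 4], [1, 1])
        assert res["chi_square"] == pytest.approx(expected, rel=1e-9)

    def test_invariant_to_flipping_expression_sign(self):
        rng = np.random.default_rng(6)
        n = 40
        surv = self.make_survival(rng.exponential(5, n), rng.integers(0, 2, n))
        v = pd.Series(rng.normal(size=n), index=surv.samples)
        r1 = pn.km_logrank(v, surv)
        r2 = pn.km_logrank(-v, surv)  # swaps the two groups
        assert r1["chi_square"] == pytest.approx(r2["chi_square"], rel=1e-9)

    def test_km_curves_are_monotone_steps(self):
        rng = np.random.default_rng(8)
        n = 30
        surv = self.make_survival(rng.exponential(5, n), np.ones(n, dtype=int))
        v = pd.Series(rng.normal(size=n), index=surv.samples)
        res = pn.km_logrank(v, surv)
        for curve in res["curves"].values():
            s = curve["survival"].to_numpy()
            assert (np.diff(s) <= 1e-12).all() and s[0] <= 1.0

    def test_degenerate_inputs_rejected(self):
        surv = self.make_survival([1, 2, 3, 4], [0, 0, 0, 0])
        v = pd.Series([1, 2, 3, 4], index=surv.samples, dtype=float)
        with pytest.raises(ValueError, match="no events"):
            pn.km_logrank(v, surv)
        surv2 = self.make_survival([1, 2, 3, 4], [1, 1, 0, 0])
        const = pd.Series([2, 2, 2, 2], index=surv2.samples, dtype=float)
        with pytest.raises(ValueError, match="< 2 samples"):
            pn.km_logrank(const, surv2)

    def test_read_survival_round_trip(self, tmp_path):
        f = tmp_path / "surv.tsv"
        f.write_text("sample\ttime\tevent\ns1\t3.5\t1\ns2\t7.0\t0\n")
        surv = read_survival(f)
        assert list(surv.time) == [3.5, 7.0]
        assert list(surv.event) == [1, 0]
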