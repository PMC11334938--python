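"""Profiles, Spearman networks, gated-vs-naive comparison, depth weights."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sphingolink import (
    AbundanceProfile,
    CoabundanceNetwork,
    SampleSeries,
    abundance_weight,
    compare_networks,
    gated_network,
    naive_network,
    normalize_per_read,
    spearman_matrix,
    spearman_rho,
)


def brute_force_spearman(x, y):
    """Oracle: average ranks by hand, then Pearson on the ranks."""
    def ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        pos = 1
        while i < len(v):
            jx = i
            while jx + 1 < len(v) and sorted_v[jx + 1] == sorted_v[i]:
                jx += 1
            mean_rank = (pos + pos + (jx - i)) / 2
            for k in range(i, jx + 1):
                r[order[k]] = mean_rank
            pos += jx - i + 1
            i = jx + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def series(t=5):
    return SampleSeries(tuple(f"S{i}" for i in range(t)),
                        tuple(50.0 + 10 * i for i in range(t)),
                        tuple([1_000_000] * t))


class TestNormalizePerRead:
    def test_division(self):
        s = SampleSeries(("a", "b"), (50.0, 60.0), (1_000_000, 2_000_000))
        prof = normalize_per_read([10.0, 20.0], s)
        np.testing.assert_allclose(prof.values, [1e-5, 1e-5])
        assert prof.normalization == "per_read"

    def test_all_zero_flagged(self):
        prof = normalize_per_read([0.0] * 5, series())
        assert prof.all_zero

    def test_linearity_in_reads(self):
        s1 = series()
        s2 = SampleSeries(s1.sample_ids, s1.depths_m,
                          tuple(2 * r for r in s1.reads_after_qc))
        d = [3.0, 1.0, 4.0, 1.0, 5.0]
        np.testing.assert_allclose(normalize_per_read(d, s2).values,
                                   normalize_per_read(d, s1).values / 2)

    def test_zero_reads_rejected(self):
        with pytest.raises(Exception):
            SampleSeries(("a", "b"), (50.0, 60.0), (0, 100))


class TestSpearman:
    def p(self, v):
        return AbundanceProfile(np.asarray(v, float))

    def test_monotone_is_one(self):
        x = self.p(np.arange(1, 16))
        y = self.p(np.arange(1, 16) ** 2)
        assert spearman_rho(x, y) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        x = self.p(np.arange(1, 16))
        y = self.p(np.arange(15, 0, -1) ** 2)
        assert spearman_rho(x, y) == pytest.approx(-1.0)

    def test_ties_match_brute_force_oracle(self, rng):
        for _ in range(50):
            x = rng.integers(0, 4, size=6).astype(float)  # many ties
            y = rng.integers(0, 4, size=6).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            assert spearman_rho(self.p(x), self.p(y)) == pytest.approx(
                brute_force_spearman(x, y), abs=1e-12)

    def test_constant_profile_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho(self.p([1, 1, 1]), self.p([1, 2, 3]))

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.integers(1, 10_000), min_size=4, max_size=12,
                    unique=True),
           st.floats(0.5, 3.0))
    def test_invariant_under_monotone_transform(self, vals, power):
        vals = np.asarray(vals, dtype=float)
        y = np.arange(len(vals), dtype=float)
        a = spearman_rho(self.p(vals), self.p(y))
        b = spearman_rho(self.p(np.asarray(vals) ** power), self.p(y))
        assert a == pytest.approx(b, abs=1e-12)

    def test_matrix_agrees_with_pairwise(self, rng):
        xs = rng.uniform(0, 10, size=(4, 8))
        ys = rng.uniform(0, 10, size=(3, 8))
        mat = spearman_matrix(xs, ys)
        for i in range(4):
            for k in range(3):
                want = brute_force_spearman(xs[i], ys[k])
                assert mat[i, k] == pytest.approx(want, abs=1e-12)


class TestGatedNetwork:
    def test_exact_boundary_inclusive(self):
        # ranks engineered so ρ = 0.9 exactly at t=5: swap one adjacent pair
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 4.0, 5.0])
        rho = brute_force_spearman(x, y)
        assert rho == pytest.approx(0.9)
        net = gated_network([("L", x)], [("s", y)], rho_min=0.9)
        assert net.n_edges == 1
        y_worse = np.array([3.0, 1.0, 2.0, 4.0, 5.0])
        assert brute_force_spearman(x, y_worse) < 0.9
        assert gated_network([("L", x)], [("s", y_worse)]).n_edges == 0

    def test_matches_brute_force_all_pairs(self, rng):
        lipids = [(f"L{i}", rng.uniform(0, 5, size=9)) for i in range(6)]
        scafs = [(f"s{k}", rng.uniform(0, 5, size=9)) for k in range(7)]
        net = gated_network(lipids, scafs, rho_min=0.3)
        expected = set()
        for lid, lv in lipids:
            for sid, sv in scafs:
                if brute_force_spearman(lv, sv) >= 0.3:
                    expected.add((lid, sid))
        assert net.lipid_target_pairs() == expected

    def test_empty_scaffold_set_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            net = gated_network([("L", np.arange(5.0))], [])
        assert net.n_edges == 0


class TestNaiveNetwork:
    def make_mag(self, n_corr, n_anti, base):
        scafs = [(f"s{k}", base + 0.01 * k) for k in range(n_corr)]
        scafs += [(f"a{k}", base[::-1] + 0.01 * k) for k in range(n_anti)]
        return scafs

    def test_min_scaffold_rule(self):
        base = np.arange(12, dtype=float) ** 1.5
        lip = [("L", base)]
        mag_ok = {"M1": self.make_mag(10, 2, base)}
        mag_short = {"M2": self.make_mag(9, 3, base)}
        assert naive_network(lip, mag_ok).n_edges == 1
        assert naive_network(lip, mag_short).n_edges == 0

    def test_small_mags_counted(self):
        lip = [("L", np.arange(12, dtype=float))]
        net = naive_network(lip, {"tiny": [("s0", np.arange(12.0))]})
        assert net.n_small_mags == 1
        assert net.n_edges == 0


class TestCompareNetworks:
    def net(self, kind, edges, lipids, targets):
        return CoabundanceNetwork(edges, kind, 0.9, lipid_ids=lipids,
                                  target_ids=targets)

    def test_candidate_pair_arithmetic(self):
        lipids = [f"L{i}" for i in range(229)]
        mags = [f"M{i}" for i in range(5069)]
        naive = self.net("mag", [], lipids, mags)
        gated = self.net("mag", [], lipids, [])
        out = compare_networks(naive, gated)
        assert out["n_candidate_pairs"] == 1_160_801

    def test_equal_networks_ratio_one(self):
        e = [("L1", "M1", 0.95)]
        out = compare_networks(self.net("mag", e, ["L1"], ["M1"]),
                               self.net("mag", e, ["L1"], ["M1"]))
        assert out["reduction_ratio"] == pytest.approx(1.0)
        assert not out["ratio_infinite"]

    def test_empty_gated_flags_infinite(self):
        out = compare_networks(self.net("mag", [("L1", "M1", 0.95)],
                                        ["L1"], ["M1"]),
                               self.net("mag", [], ["L1"], ["M1"]))
        assert out["ratio_infinite"] and out["reduction_ratio"] == float("inf")

    def test_mismatched_lipid_sets_rejected(self):
        with pytest.raises(ValueError, match="same lipid set"):
            compare_networks(self.net("mag", [], ["L1"], []),
                             self.net("mag", [], ["L2"], []))


class TestConfounders:
    def test_confounder_fools_naive_but_not_gated(self):
        # a non-producer cloned onto the producer's niche: its scaffolds
        # correlate with the lipid, but it owns no Spt-like scaffold
        rng = np.random.default_rng(5)
        bump = np.exp(-0.5 * ((np.arange(1, 16) - 8) / 1.2) ** 2)
        lipid = [("L", bump * 1e6)]
        producer_scafs = [(f"P_s{k}", bump * rng.lognormal(0, 0.05, 15))
                          for k in range(12)]
        confounder_scafs = [(f"C_s{k}", bump * rng.lognormal(0, 0.05, 15))
                            for k in range(12)]
        spt = [producer_scafs[0]]  # only the producer encodes Spt
        naive = naive_network(lipid, {"P": producer_scafs,
                                      "C": confounder_scafs})
        gated = gated_network(lipid, spt)
        assert {m for _l, m, _r in naive.edges} == {"P", "C"}
        assert {s for _l, s, _r in gated.edges} == {"P_s0"}


class TestAbundanceWeight:
    def indicator(self, j, t=15):
        v = np.zeros(t)
        v[j - 1] = 7.5
        return AbundanceProfile(v)

    def test_indicator_at_upper_euxinic_sample(self):
        assert abundance_weight(self.indicator(9)) == pytest.approx(9.0)

    def test_indicator_at_deepest_sample(self):
        assert abundance_weight(self.indicator(15)) == pytest.approx(15.0)

    def test_uniform_profile(self):
        assert abundance_weight(AbundanceProfile(np.full(15, 2.0))) == \
            pytest.approx(8.0)

    def test_bounds(self, rng):
        for _ in range(20):
            v = rng.uniform(0, 1, size=15)
            w = abundance_weight(AbundanceProfile(v))
            assert 1.0 <= w <= 15.0

    def test_cyclic_shift_equivariance(self):
        v = np.zeros(15)
        v[3] = 1.0
        w0 = abundance_weight(AbundanceProfile(v))
        w1 = abundance_weight(AbundanceProfile(np.roll(v, 4)))
        assert w1 - w0 == pytest.approx(4.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            abundance_weight(AbundanceProfile(np.zeros(15)))
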