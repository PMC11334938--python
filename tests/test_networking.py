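"""Modified cosine, mutual top-K network construction, class propagation."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from sphingolink import (
    NetworkParams,
    SimConfig,
    build_network,
    class_other_rule,
    generate_community,
    generate_lipids,
    modified_cosine,
    propagate_classes,
)
from sphingolink.networking import _candidate_pairs

from conftest import make_spectrum


def exhaustive_cosine(a, b, params=NetworkParams()):
    """Oracle: optimal (not greedy) one-to-one matching via the assignment
    problem over the same candidate-pair products."""
    pairs = _candidate_pairs(a, b, params.fragment_tol_da)
    if not pairs:
        return 0.0
    w = np.zeros((a.n_peaks, b.n_peaks))
    for i, j, prod, _pen in pairs:
        w[i, j] = prod
    ri, cj = linear_sum_assignment(-w)
    total = w[ri, cj].sum()
    norm = (np.linalg.norm(np.sqrt(a.intensity_array))
            * np.linalg.norm(np.sqrt(b.intensity_array)))
    return float(total / norm)


def random_spectrum(rng, feature_id, n_peaks):
    mz = np.sort(rng.uniform(100, 900, size=n_peaks))
    inten = rng.uniform(1, 100, size=n_peaks)
    prec = float(rng.uniform(400, 1000))
    return make_spectrum(feature_id, prec, list(zip(mz, inten)))


class TestModifiedCosine:
    def test_self_similarity_is_one(self, small_lipids):
        for sp in small_lipids[:5]:
            score, n = modified_cosine(sp, sp)
            assert score == pytest.approx(1.0, abs=1e-12)
            assert n == sp.n_peaks

    def test_disjoint_spectra_score_zero(self):
        a = make_spectrum("a", 500.0, [(100.0, 10.0), (200.0, 5.0)])
        b = make_spectrum("b", 500.0, [(130.0, 10.0), (170.0, 5.0)])
        assert modified_cosine(a, b) == (0.0, 0)

    def test_hand_computed_shared_peaks(self):
        # 6 shared fragments + 2 private each; equal precursors so only
        # direct matches exist; score = Σ√(Ia·Ib) / (‖√Ia‖·‖√Ib‖)
        shared = [(100.0 + 30 * k, 10.0 + k) for k in range(6)]
        a = make_spectrum("a", 700.0, shared + [(50.0, 3.0), (60.0, 4.0)])
        b_shared = [(m, i * 2) for m, i in shared]
        b = make_spectrum("b", 700.0, b_shared + [(55.0, 3.0), (65.0, 4.0)])
        num = sum(np.sqrt(i * 2 * i) for _m, i in shared)
        den = (np.sqrt(sum(p.intensity for p in a.peaks))
               * np.sqrt(sum(p.intensity for p in b.peaks)))
        score, n = modified_cosine(a, b)
        assert n == 6
        assert score == pytest.approx(num / den, abs=1e-9)

    def test_precursor_shifted_match(self):
        # all fragments offset by the precursor mass difference still match
        a = make_spectrum("a", 500.0, [(100.0, 10.0), (150.0, 20.0),
                                       (200.0, 30.0), (250.0, 5.0),
                                       (300.0, 8.0), (350.0, 12.0)])
        delta = 14.01565
        b = make_spectrum("b", 500.0 + delta,
                          [(p.mz + delta, p.intensity) for p in a.peaks])
        score, n = modified_cosine(a, b)
        assert score == pytest.approx(1.0, abs=1e-9)
        assert n == 6

    def test_empty_peak_list_rejected(self):
        a = make_spectrum("a", 500.0, [(100.0, 1.0)])
        b = make_spectrum("b", 500.0, [(100.0, 1.0)])
        b.peaks = []
        with pytest.raises(ValueError):
            modified_cosine(a, b)

    def test_symmetry_and_bounds_random(self, rng):
        for k in range(50):
            a = random_spectrum(rng, "a", int(rng.integers(2, 9)))
            b = random_spectrum(rng, "b", int(rng.integers(2, 9)))
            sab, nab = modified_cosine(a, b)
            sba, nba = modified_cosine(b, a)
            assert sab == pytest.approx(sba, abs=1e-12)
            assert nab == nba
            assert 0.0 <= sab <= 1.0

    def test_greedy_matches_optimal_on_small_spectra(self, rng):
        agree = 0
        trials = 300
        for k in range(trials):
            a = random_spectrum(rng, "a", int(rng.integers(2, 9)))
            b = random_spectrum(rng, "b", int(rng.integers(2, 9)))
            greedy, _ = modified_cosine(a, b)
            assert greedy <= exhaustive_cosine(a, b) + 1e-12
            if greedy == pytest.approx(exhaustive_cosine(a, b), abs=1e-9):
                agree += 1
        assert agree / trials >= 0.99


class TestBuildNetwork:
    def test_single_spectrum(self):
        sp = make_spectrum("only", 500.0, [(100.0, 1.0)])
        net = build_network([sp])
        assert net.nodes == ["only"]
        assert net.edges == []
        assert len(net.components) == 1

    def test_threshold_excludes_sub_cosine_pairs(self):
        shared = [(100.0 + 30 * k, 10.0) for k in range(6)]
        a = make_spectrum("a", 700.0, shared + [(400.0, 30.0)])
        b = make_spectrum("b", 700.0, shared + [(450.0, 30.0)])
        score, _ = modified_cosine(a, b)
        assert score < 1.0
        net = build_network([a, b], NetworkParams(cosine_min=score + 1e-6))
        assert net.edges == []
        net2 = build_network([a, b], NetworkParams(cosine_min=score - 1e-6))
        assert len(net2.edges) == 1

    def test_min_matched_peaks_excludes(self):
        shared = [(100.0 + 30 * k, 10.0) for k in range(6)]
        a = make_spectrum("a", 700.0, shared)
        b = make_spectrum("b", 700.0, shared)
        assert build_network([a, b], NetworkParams(min_matched_peaks=7)).edges == []

    def test_mutual_top_k_rule(self):
        # B is A's best match; C matches A above threshold but is not in
        # A's top-1, so the A–C edge must vanish at top_k=1
        base = [(100.0 + 30 * k, 10.0) for k in range(8)]
        a = make_spectrum("A", 700.0, base)
        b = make_spectrum("B", 700.0, base)  # identical → cosine 1
        c_peaks = base[:7] + [(950.0, 10.0)]
        c = make_spectrum("C", 700.0, c_peaks)
        s_ac, _ = modified_cosine(a, c)
        assert s_ac > 0.6
        net = build_network([a, b, c], NetworkParams(top_k=1))
        pairs = {frozenset((x, y)) for x, y, _s, _m in net.edges}
        assert frozenset(("A", "B")) in pairs
        assert frozenset(("A", "C")) not in pairs
        net_k2 = build_network([a, b, c], NetworkParams(top_k=2))
        assert frozenset(("A", "C")) in {
            frozenset((x, y)) for x, y, _s, _m in net_k2.edges}

    def test_tightening_filters_is_monotone(self, small_lipids):
        spectra = small_lipids[:14]
        loose = build_network(spectra, NetworkParams(cosine_min=0.5,
                                                     min_matched_peaks=4))
        tight = build_network(spectra, NetworkParams(cosine_min=0.8,
                                                     min_matched_peaks=8))
        loose_pairs = {frozenset((a, b)) for a, b, _s, _m in loose.edges}
        tight_pairs = {frozenset((a, b)) for a, b, _s, _m in tight.edges}
        assert tight_pairs <= loose_pairs


class TestPropagateClasses:
    def test_majority_and_tie_and_unknown(self):
        s1 = make_spectrum("A", 700.0, [(100.0 + 30 * k, 10.0) for k in range(6)])
        s2 = make_spectrum("B", 700.0, [(100.0 + 30 * k, 10.0) for k in range(6)])
        s3 = make_spectrum("C", 700.0, [(100.0 + 30 * k, 10.0) for k in range(6)])
        lone = make_spectrum("D", 900.0, [(500.0, 1.0)])
        net = build_network([s1, s2, s3, lone])
        labels = propagate_classes(net, {"A": "Cer"})
        assert labels["B"] == labels["C"] == "Cer"
        assert labels["D"] == "unknown"
        labels = propagate_classes(net, {"A": "Cer", "B": "Gly-Cer"})
        assert labels["C"] == "ambiguous"
        labels = propagate_classes(net, {"A": "Cer", "B": "Gly-Cer", "C": "Cer"})
        assert labels["A"] == "Cer"

    def test_unknown_seed_rejected(self):
        sp = make_spectrum("A", 700.0, [(100.0, 1.0)])
        net = build_network([sp])
        with pytest.raises(ValueError, match="absent"):
            propagate_classes(net, {"nope": "Cer"})

    def test_template_classes_recovered_on_synthetic_lipids(self):
        # one seed per subclass recovers ≥95% of node labels
        total = correct = 0
        for seed in range(5):
            cfg = SimConfig(seed=seed, n_mags=30, n_producer_mags=4,
                            n_lipids=28, scaffolds_per_mag=(12, 15))
            comm = generate_community(cfg)
            spectra = generate_lipids(cfg, comm.truth, comm.mags)
            net = build_network(spectra)
            seeds, seen = {}, set()
            for sp in spectra:
                cls = comm.truth.lipid_meta[sp.feature_id]["subclass"]
                if cls not in seen:
                    seeds[sp.feature_id] = cls
                    seen.add(cls)
            labels = propagate_classes(net, seeds)
            for sp in spectra:
                total += 1
                want = comm.truth.lipid_meta[sp.feature_id]["subclass"]
                correct += labels[sp.feature_id] == want
        assert correct / total >= 0.95


class TestClassOtherRule:
    def make_table(self, minor_profile):
        # two-class table; columns sum to 1 by construction
        minor = np.asarray(minor_profile)
        return pd.DataFrame({"minor": minor, "major": 1 - minor}).T

    def test_kept_when_above_threshold_in_multiple_samples(self):
        tab = self.make_table([0.02, 0.02, 0.02] + [0.001] * 12)
        kept, other = class_other_rule(tab)
        assert "minor" in kept and other == []

    def test_folded_when_only_one_sample(self):
        tab = self.make_table([0.02] + [0.001] * 14)
        kept, other = class_other_rule(tab)
        assert other == ["minor"]

    def test_exactly_one_percent_is_other(self):
        tab = self.make_table([0.01] * 15)
        _kept, other = class_other_rule(tab)
        assert other == ["minor"]  # strict >1%

    def test_non_normalized_columns_rejected(self):
        tab = pd.DataFrame({"a": [0.5, 0.5], "b": [0.6, 0.5]}).T
        with pytest.raises(ValueError, match="sum to 1"):
            class_other_rule(tab)
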