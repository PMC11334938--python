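"""Synthetic study generator: determinism, truth consistency, zonation."""

import hashlib
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from sphingolink import (
    SimConfig,
    classify_zone,
    generate_community,
    generate_function_table,
    generate_lipids,
    modified_cosine,
    write_dataset,
)
from sphingolink.simulate import generate_homolog_tables, generate_spt_tree
from sphingolink.screen import filter_spt_hits, gate_spt_like


def dir_digest(path):
    h = hashlib.sha256()
    for f in sorted(Path(path).rglob("*")):
        if f.is_file():
            h.update(f.name.encode())
            h.update(f.read_bytes())
    return h.hexdigest()


TINY = dict(n_mags=12, n_producer_mags=3, n_lipids=7,
            scaffolds_per_mag=(3, 5))


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(t=1),
        dict(n_producer_mags=300),
        dict(confounder_fraction=1.5),
        dict(scaffolds_per_mag=(5, 3)),
        dict(noise_cv=-0.1),
    ])
    def test_invalid_configs_rejected_before_generation(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestDeterminism:
    def test_identical_seed_gives_identical_dataset(self, tmp_path):
        cfg = SimConfig(seed=7, **TINY)
        write_dataset(cfg, tmp_path / "a")
        write_dataset(cfg, tmp_path / "b")
        assert dir_digest(tmp_path / "a") == dir_digest(tmp_path / "b")

    def test_different_seed_differs(self, tmp_path):
        write_dataset(SimConfig(seed=7, **TINY), tmp_path / "a")
        write_dataset(SimConfig(seed=8, **TINY), tmp_path / "b")
        assert dir_digest(tmp_path / "a") != dir_digest(tmp_path / "b")


class TestTruthConsistency:
    def test_each_producer_has_exactly_one_spt_scaffold(self, small_community):
        comm = small_community
        for mag in comm.mags:
            n_spt = sum(sid in comm.truth.spt_like_scaffolds
                        for sid in mag.scaffold_ids)
            assert n_spt == (1 if mag.mag_id in comm.truth.producer_mags else 0)

    def test_producer_map_subset_of_spt_carriers(self, small_community,
                                                 small_lipids):
        truth = small_community.truth
        mapped = set().union(*truth.producer_map.values())
        assert mapped <= truth.producer_mags

    def test_minimal_community(self):
        cfg = SimConfig(n_mags=1, n_producer_mags=1, n_lipids=1,
                        scaffolds_per_mag=(2, 3))
        comm = generate_community(cfg)
        assert len(comm.truth.spt_like_scaffolds) == 1

    def test_two_sample_series(self):
        comm = generate_community(SimConfig(t=2, **TINY))
        assert comm.samples.t == 2


class TestZonation:
    def test_euxinic_at_sulfide_onset(self):
        assert classify_zone(0.0, 0.85) == "euxinic"  # upper euxinic boundary

    def test_oxic_surface(self):
        assert classify_zone(78.0, 0.0) == "oxic"

    def test_suboxic_between(self):
        assert classify_zone(0.0, 0.1) == "suboxic"

    def test_exactly_threshold_not_euxinic(self):
        assert classify_zone(0.0, 0.2) == "suboxic"  # strict >0.2 µM

    def test_missing_both_rejected(self):
        with pytest.raises(ValueError):
            classify_zone(None, None)

    def test_default_series_zones(self, small_community):
        zones = small_community.truth.zone_labels
        assert zones[0] == "oxic" and zones[-1] == "euxinic"
        assert "suboxic" in zones
        # zones are ordered: oxic block, then suboxic, then euxinic
        order = {"oxic": 0, "suboxic": 1, "euxinic": 2}
        codes = [order[z] for z in zones]
        assert codes == sorted(codes)


class TestLipidGeneration:
    def test_same_subclass_neighbors_connect(self, small_community, small_lipids):
        meta = small_community.truth.lipid_meta
        by_template = {}
        for sp in small_lipids:
            by_template.setdefault(meta[sp.feature_id]["template"], []).append(sp)
        pairs_checked = 0
        for template, group in by_template.items():
            for a, b in zip(group, group[1:]):
                score, n = modified_cosine(a, b)
                assert score >= 0.6 and n >= 6
                pairs_checked += 1
        assert pairs_checked > 0

    def test_different_subclasses_do_not_connect(self, small_lipids,
                                                 small_community):
        meta = small_community.truth.lipid_meta
        for a in small_lipids[:7]:
            for b in small_lipids[:7]:
                if meta[a.feature_id]["template"] != meta[b.feature_id]["template"]:
                    score, _ = modified_cosine(a, b)
                    assert score < 0.6

    def test_zero_noise_lipid_tracks_spt_scaffold_exactly(self):
        cfg = SimConfig(seed=3, noise_cv=0.0, lipid_noise_frac=0.0, **TINY)
        comm = generate_community(cfg)
        spectra = generate_lipids(cfg, comm.truth, comm.mags)
        reads = np.array(comm.samples.reads_after_qc, float)
        for sp in spectra:
            producer = next(iter(comm.truth.producer_map[sp.feature_id]))
            sid = comm.truth.spt_scaffold_of_mag[producer]
            prof = comm.scaffolds[sid].raw_depths / reads
            rho = stats.spearmanr(sp.intensities.values, prof).statistic
            assert rho == pytest.approx(1.0)

    def test_zero_noise_disjoint_producers_uncorrelated(self):
        # lipids of one producer stay below ρ=0.9 with every other
        # producer's Spt scaffold when niches are disjoint
        cfg = SimConfig(seed=3, noise_cv=0.0, lipid_noise_frac=0.0,
                        confounder_fraction=0.0, **TINY)
        comm = generate_community(cfg)
        spectra = generate_lipids(cfg, comm.truth, comm.mags)
        reads = np.array(comm.samples.reads_after_qc, float)
        for sp in spectra:
            producer = next(iter(comm.truth.producer_map[sp.feature_id]))
            for other in comm.truth.producer_mags - {producer}:
                sid = comm.truth.spt_scaffold_of_mag[other]
                prof = comm.scaffolds[sid].raw_depths / reads
                rho = stats.spearmanr(sp.intensities.values, prof).statistic
                assert rho < 0.9


class TestFunctionTable:
    def test_zero_functions_empty_matrix(self, small_community):
        cfg = SimConfig(n_functions=0, **TINY)
        t = generate_function_table(cfg, small_community.truth,
                                    small_community.mags)
        assert t.matrix.shape[0] == 0

    def test_planted_enrichment_detectable_single_seed(self):
        cfg = SimConfig(seed=42, n_mags=200, n_producer_mags=100,
                        n_lipids=1, scaffolds_per_mag=(2, 3))
        comm = generate_community(cfg)
        t = generate_function_table(cfg, comm.truth, comm.mags)
        from sphingolink import run_association
        res = run_association(t)
        planted = {f"F{k:03d}" for k in range(cfg.n_enriched_functions)}
        sig = {r.function_id for r in res
               if r.test == "fisher" and r.p_bonferroni < 0.05}
        assert planted <= sig


class TestHomologTables:
    def test_decoys_split_by_filter_and_gate(self, small_config,
                                             small_community):
        comm = small_community
        spt_hits, acc_hits, decoys_passing = generate_homolog_tables(
            small_config, comm.truth, comm)
        kept = filter_spt_hits(spt_hits)
        kept_ids = {h.protein_id for h in kept}
        # every true producer Spt protein survives the filter
        true_prots = set(comm.truth.spt_protein_of_mag.values())
        assert true_prots <= kept_ids
        # passing decoys survive the filter but are gated out by the tree
        assert set(decoys_passing) <= kept_ids
        tree = generate_spt_tree(comm.truth, decoys_passing)
        res = gate_spt_like(tree)
        assert true_prots <= res.spt_like
        assert set(decoys_passing) <= res.divergent
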