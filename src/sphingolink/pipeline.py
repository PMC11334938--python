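"""End-to-end pipeline over an on-disk dataset.

Stages, in dependency order: read inputs → molecular network + class
propagation → response-factor quantification → genomic capacity screen
(hit filters, co-localization, clade gating, MAG quality) → gated and
naive co-abundance networks + comparison → pangenome association.  The
aggregated report is a plain dict (JSON-serializable); when a truth file
is present, gated/naive precision and recall against the planted
producer–lipid pairs are added.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import association as assoc
from . import coabundance as coab
from . import io as sio
from . import networking as netw
from . import quant as lq
from . import screen
from .simulate import QLEN
from .types import AbundanceProfile, Mag

__all__ = ["PipelineParams", "run_pipeline", "precision_recall"]


@dataclass(frozen=True)
class PipelineParams:
    """Every threshold the pipeline applies, defaulted to the study values."""

    cosine_min: float = 0.6
    min_matched_peaks: int = 6
    top_k: int = 10
    fragment_tol_da: float = 0.02
    spt_evalue_max: float = screen.SPT_EVALUE_MAX
    spt_qcov_min: float = screen.SPT_QCOV_MIN
    accessory_evalue_max: float = screen.ACCESSORY_EVALUE_MAX
    accessory_qcov_min: float = screen.ACCESSORY_QCOV_MIN
    coloc_window: int = screen.COLOC_WINDOW
    clade_min_support: float = screen.CLADE_MIN_SUPPORT
    rho_min: float = coab.RHO_MIN
    naive_min_scaffolds: int = coab.NAIVE_MIN_SCAFFOLDS
    prevalence_min: float = assoc.PHYLUM_PREVALENCE_MIN

    def as_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


def precision_recall(predicted: set, truth: set):
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else float("nan")
    recall = tp / len(truth) if truth else float("nan")
    return precision, recall


def run_pipeline(dataset_dir, params: PipelineParams = PipelineParams(),
                 outdir: Optional[Path] = None) -> dict:
    d = Path(dataset_dir)
    report: dict = {"params": params.as_dict()}

    # ---- inputs ------------------------------------------------------
    samples = sio.read_sample_table(d / "samples.tsv")
    mags = sio.read_mag_table(d / "mags.tsv")
    depths = sio.read_depth_table(d / "depths.tsv", samples)
    spectra = sio.read_mgf(d / "lipids.mgf")
    quant_tab = sio.read_quant_table(d / "quant.tsv", samples)
    sio.attach_intensities(spectra, quant_tab)
    orfs = sio.read_orf_table(d / "orfs.tsv")

    # ---- molecular network ------------------------------------------
    npar = netw.NetworkParams(params.cosine_min, params.min_matched_peaks,
                              params.top_k, params.fragment_tol_da)
    net = netw.build_network(spectra, npar)
    seeds = {}
    ann_path = d / "annotations.tsv"
    if ann_path.exists():
        ann = pd.read_csv(ann_path, sep="\t", dtype={"feature_id": str})
        # one seed per subclass: the first annotated feature
        for subclass, grp in ann.groupby("subclass"):
            seeds[str(grp.feature_id.iloc[0])] = subclass
    labels = netw.propagate_classes(net, seeds) if seeds else {}
    report["network"] = {
        "n_nodes": len(net.nodes), "n_edges": len(net.edges),
        "n_components": len(net.components),
        "n_classified": sum(1 for v in labels.values()
                            if v not in ("unknown", "ambiguous")),
    }

    # ---- quantification ---------------------------------------------
    conc_by_feature: Dict[str, np.ndarray] = {}
    std_path = d / "standards.tsv"
    if std_path.exists() and labels:
        std = pd.read_csv(std_path, sep="\t")
        factors = {}
        for cls, grp in std.groupby("lipid_class"):
            factors[cls] = lq.fit_response_factor(
                list(zip(grp.known_conc, grp.intensity)), cls,
                grp.standard_name.iloc[0])
        for sp in spectra:
            cls = labels.get(sp.feature_id, "unknown")
            if cls in ("unknown", "ambiguous") or sp.intensities is None:
                continue
            try:
                rf, _prov = lq.resolve_rf(cls, factors)
            except KeyError:
                continue
            conc_by_feature[sp.feature_id] = lq.quantify(
                sp.intensities.values, rf)
        report["quantified_features"] = len(conc_by_feature)

    # ---- capacity screen --------------------------------------------
    orf_by_protein = {o.protein_id: o for o in orfs}
    spt_hits = sio.read_blast_tab(d / "spt_hits.tsv", qlen_map=QLEN)
    kept_spt = screen.filter_spt_hits(spt_hits, params.spt_evalue_max,
                                      params.spt_qcov_min)
    acc_orfs: Dict[str, List] = {}
    for gene, fname in (("bCerS", "bcers_hits.tsv"), ("CerR", "cerr_hits.tsv")):
        hits = sio.read_blast_tab(d / fname, qlen_map=QLEN)
        kept = screen.filter_accessory_hits(hits, gene,
                                            params.accessory_evalue_max,
                                            params.accessory_qcov_min)
        acc_orfs[gene] = [orf_by_protein[h.protein_id] for h in kept
                          if h.protein_id in orf_by_protein]
    coloc_proteins = set()
    for h in kept_spt:
        spt_orf = orf_by_protein.get(h.protein_id)
        if spt_orf is None:
            continue
        for gene in ("bCerS", "CerR"):
            if any(screen.colocalized(spt_orf, a, params.coloc_window)
                   for a in acc_orfs[gene]):
                coloc_proteins.add(h.protein_id)
                break
    tree = sio.read_newick(d / "spt_tree.nwk")
    truth_path = d / "truth.json"
    refs = None
    if truth_path.exists():
        tjson = json.loads(truth_path.read_text())
        refs = [r for r in tjson.get("reference_spt_leaves", [])
                if r in set(tree.leaf_names())]
    if not refs:
        refs = [l for l in tree.leaf_names() if l.startswith("ref_spt")]
    tree.flag_leaves(reference_spt=refs, colocalized=coloc_proteins)
    gate = screen.gate_spt_like(tree, params.clade_min_support)
    kept_proteins = {h.protein_id for h in kept_spt} & gate.spt_like
    scaffold_of_protein = {o.protein_id: o.scaffold_id for o in orfs}
    spt_scaffolds = {scaffold_of_protein[p] for p in kept_proteins
                     if p in scaffold_of_protein}
    mag_of_scaffold = {sid: m.mag_id for m in mags for sid in m.scaffold_ids}
    quality = {m.mag_id: screen.mag_quality(m) for m in mags}
    mh_mags = {m.mag_id for m in mags if quality[m.mag_id][0] == "medium_high"}
    for m in mags:
        m.spt_like = any(sid in spt_scaffolds for sid in m.scaffold_ids)
    spt_mags = {m.mag_id for m in mags if m.spt_like and m.mag_id in mh_mags}
    report["screen"] = {
        "n_spt_hits_kept": len(kept_spt),
        "n_colocalized": len(coloc_proteins),
        "n_spt_like_leaves": len(gate.spt_like),
        "n_divergent_leaves": len(gate.divergent),
        "n_spt_scaffolds": len(spt_scaffolds),
        "n_spt_mags": len(spt_mags),
        "n_medium_high_mags": len(mh_mags),
    }

    # ---- co-abundance ------------------------------------------------
    per_read = {sid: coab.normalize_per_read(depths.loc[sid].to_numpy(), samples)
                for sid in depths.index}
    lipid_profiles = []
    for sp in spectra:
        vals = conc_by_feature.get(sp.feature_id)
        if vals is None and sp.intensities is not None:
            vals = sp.intensities.values
        if vals is not None and not np.all(vals == vals[0]):
            lipid_profiles.append((sp.feature_id, vals))
    binned_spt = [(sid, per_read[sid].values) for sid in sorted(spt_scaffolds)
                  if sid in per_read and mag_of_scaffold.get(sid) in mh_mags]
    gated = coab.gated_network(lipid_profiles, binned_spt, params.rho_min)
    mag_scafs = {m.mag_id: [(sid, per_read[sid].values)
                            for sid in m.scaffold_ids if sid in per_read]
                 for m in mags if m.mag_id in mh_mags}
    naive = coab.naive_network(lipid_profiles, mag_scafs, params.rho_min,
                               params.naive_min_scaffolds)
    comparison = coab.compare_networks(naive, gated, mags)
    report["coabundance"] = comparison
    weights = {}
    for lid, vals in lipid_profiles:
        prof = AbundanceProfile(np.asarray(vals, dtype=float), "raw")
        if not prof.all_zero:
            weights[lid] = coab.abundance_weight(prof)
    report["abundance_weights"] = {
        "min": min(weights.values()) if weights else None,
        "max": max(weights.values()) if weights else None,
    }

    # ---- association --------------------------------------------------
    func_path = d / "functions.tsv"
    if func_path.exists():
        fdf = sio.read_function_table(func_path)
        eligible = {m.mag_id for m in mags if quality[m.mag_id][1]}
        prods_eligible = spt_mags & eligible
        non_eligible = eligible - spt_mags
        if prods_eligible and non_eligible:
            cols = sorted(eligible)
            mat = (fdf.pivot_table(index="function_id", columns="mag_id",
                                   values="count", aggfunc="sum",
                                   fill_value=0)
                   .reindex(columns=cols, fill_value=0))
            table = assoc.FunctionTable(
                universe=str(fdf.universe.iloc[0]) if len(fdf) else "Pfam",
                matrix=mat.astype(int),
                mag_group={m: ("producer" if m in prods_eligible
                               else "non_producer") for m in cols},
                mag_phylum={m.mag_id: m.phylum or "unknown" for m in mags
                            if m.mag_id in eligible},
                sample_id="all")
            results = assoc.run_association(table, params.prevalence_min)
            n_sig = sum(1 for r in results if r.p_bonferroni < 0.05)
            n_shared = sum(1 for r in results
                           if r.p_bonferroni < 0.05
                           and r.phylum_prevalence >= params.prevalence_min)
            report["association"] = {
                "n_tests": len(results),
                "n_significant": n_sig,
                "n_significant_shared": n_shared,
                "n_eligible_mags": len(eligible),
            }

    # ---- truth comparison ---------------------------------------------
    if truth_path.exists():
        tjson = json.loads(truth_path.read_text())
        truth_pairs = {(lid, m) for lid, ms in tjson["producer_map"].items()
                       for m in ms}
        gated_pairs = {(l, mag_of_scaffold.get(s, s)) for l, s, _ in gated.edges}
        naive_pairs = naive.lipid_target_pairs()
        gp, gr = precision_recall(gated_pairs, truth_pairs)
        np_, nr = precision_recall(naive_pairs, truth_pairs)
        report["truth"] = {
            "gated_precision": gp, "gated_recall": gr,
            "naive_precision": np_, "naive_recall": nr,
        }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sio.write_network([(a, b, s) for a, b, s, _m in net.edges],
                          outdir / "molecular_network.tsv",
                          dialect="edge_tsv", weight_attr="cosine")
        sio.write_network(gated.edges, outdir / "gated_network.tsv")
        sio.write_network(naive.edges, outdir / "naive_network.tsv")
        (outdir / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True, default=float) + "\n")
    return report
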