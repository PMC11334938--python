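"""Synthetic stratified-water-column study with known ground truth.

Emulates the study design the pipeline targets: 15 depth-ordered samples
spanning an oxic / suboxic / euxinic redox zonation, a community of MAGs
whose true abundances are Gaussian niches over the sample index, scaffold
depth profiles with multiplicative lognormal noise, producer MAGs carrying
a serine-palmitoyltransferase-like (Spt) gene with bCerS and CerR
co-localized within 10 ORFs, confounder MAGs cloned onto producer niches,
producer-linked lipid intensity profiles, class-structured toy MS/MS
spectra built from seven sphingolipid-subclass templates, homolog hit
tables with decoy α-oxoamine synthases, an Spt phylogeny, and function
tables with planted enrichments.

All randomness flows through one seeded generator: identical config +
seed ⇒ byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import io as sio
from .association import FunctionTable
from .tree import Tree
from .types import (
    AbundanceProfile,
    HomologHit,
    Mag,
    Orf,
    Peak,
    SampleSeries,
    Scaffold,
    Spectrum,
)

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "Community",
    "classify_zone",
    "generate_community",
    "generate_lipids",
    "generate_function_table",
    "generate_homolog_tables",
    "generate_spt_tree",
    "write_dataset",
]

EUXINIC_SULFIDE_UM = 0.2

# Homologous-series mass shifts (Da): methylene unit and one unsaturation.
CH2 = 14.01565
H2 = 2.01565

SUBCLASS_TEMPLATES = (
    "Cer", "Gly-Cer", "Lys-Cer", "1-deoxyCer", "Sulfono-1-deoxyCer",
    "Acetylsulfono-1-deoxyCer", "Sulfate-1-deoxyCer",
)

PHYLA = (
    "Bacteroidota", "Desulfobacterota", "Chloroflexota", "Marinisomatota",
    "Planctomycetota", "Proteobacteria", "Cloacimonadota", "Verrucomicrobiota",
    "Myxococcota", "Actinobacteriota", "Acidobacteriota", "Spirochaetota",
)

# depth grid (mbsl) of the default 15-sample design
DEFAULT_DEPTHS_M = (50, 70, 80, 85, 90, 95, 100, 105, 110,
                    130, 170, 250, 500, 1000, 2000)


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study; defaults are the emulated conditions."""

    t: int = 15
    n_mags: int = 200
    n_producer_mags: int = 8
    scaffolds_per_mag: Tuple[int, int] = (12, 25)
    producer_niche_width: float = 0.9   # sample-index units
    niche_width_range: Tuple[float, float] = (0.8, 2.5)
    noise_cv: float = 0.2               # CV of multiplicative lognormal scaffold noise
    n_lipids: int = 50
    confounder_fraction: float = 0.3    # of non-producers cloned onto producer niches
    lipid_noise_frac: float = 0.002     # additive noise sd as fraction of peak intensity
    depth_floor: float = 1.0            # mapping depths below ~1x coverage are unobserved
    lod_sigma: float = 5.0              # lipid limit of detection, in noise sd units
    reads_range: Tuple[int, int] = (200_000_000, 400_000_000)
    orfs_per_scaffold: Tuple[int, int] = (20, 60)
    n_functions: int = 10
    n_enriched_functions: int = 3
    enriched_presence: Tuple[float, float] = (0.9, 0.1)  # producer, non-producer
    neutral_presence: float = 0.3
    quality_boundary_cases: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.t < 2:
            raise ValueError("t must be ≥ 2")
        if self.n_producer_mags > self.n_mags:
            raise ValueError("n_producer_mags cannot exceed n_mags")
        for name in ("n_mags", "n_producer_mags", "n_lipids"):
            if getattr(self, name) < 0 or (name != "n_producer_mags"
                                           and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.confounder_fraction <= 1.0):
            raise ValueError("confounder_fraction must be in [0, 1]")
        if self.scaffolds_per_mag[0] < 1 or \
                self.scaffolds_per_mag[0] > self.scaffolds_per_mag[1]:
            raise ValueError("invalid scaffolds_per_mag range")
        if self.noise_cv < 0 or self.lipid_noise_frac < 0:
            raise ValueError("noise levels must be non-negative")


@dataclass
class SyntheticTruth:
    """Planted ground truth the downstream stages are scored against."""

    producer_map: Dict[str, Set[str]] = field(default_factory=dict)
    spt_like_scaffolds: Set[str] = field(default_factory=set)
    zone_labels: Tuple[str, ...] = ()
    producer_mags: Set[str] = field(default_factory=set)
    confounder_mags: Set[str] = field(default_factory=set)
    mag_abundance: Dict[str, np.ndarray] = field(default_factory=dict)
    spt_scaffold_of_mag: Dict[str, str] = field(default_factory=dict)
    spt_protein_of_mag: Dict[str, str] = field(default_factory=dict)
    lipid_meta: Dict[str, dict] = field(default_factory=dict)


@dataclass
class Community:
    samples: SampleSeries
    mags: List[Mag]
    truth: SyntheticTruth
    scaffolds: Dict[str, Scaffold] = field(default_factory=dict)
    orfs: List[Orf] = field(default_factory=list)

    def __iter__(self):  # allows samples, mags, truth = generate_community(cfg)
        return iter((self.samples, self.mags, self.truth))


# ----------------------------------------------------------------------
# Redox zonation
# ----------------------------------------------------------------------

def classify_zone(oxygen_uM: Optional[float],
                  sulfide_uM: Optional[float]) -> str:
    """euxinic iff sulfide > 0.2 µM; oxic iff oxygen detected and not euxinic;
    suboxic otherwise."""
    if oxygen_uM is None and sulfide_uM is None:
        raise ValueError("cannot classify a zone with neither oxygen nor sulfide")
    if sulfide_uM is not None and sulfide_uM > EUXINIC_SULFIDE_UM:
        return "euxinic"
    if oxygen_uM is not None and oxygen_uM > 0:
        return "oxic"
    return "suboxic"


def _depth_grid(t: int) -> np.ndarray:
    if t == len(DEFAULT_DEPTHS_M):
        return np.array(DEFAULT_DEPTHS_M, dtype=float)
    return np.unique(np.round(np.geomspace(50, 2000, t), 1))


def _redox_profiles(depths: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Oxygen declining from ~78 µM at 50 mbsl to zero below 80 mbsl;
    sulfide appearing at 110 mbsl (0.85 µM) and rising toward depth."""
    oxygen = np.where(depths < 80, 78.0 * (80 - depths) / 30.0, 0.0)
    oxygen = np.clip(oxygen, 0.0, None)
    sulfide = np.where(
        depths >= 110, 0.85 + (depths - 110) / (2000 - 110) * 380.0, 0.0)
    return np.round(oxygen, 2), np.round(sulfide, 2)


# ----------------------------------------------------------------------
# Community
# ----------------------------------------------------------------------

def generate_community(config: SimConfig) -> Community:
    """Samples, niche-structured MAGs with scaffolds/ORFs, and ground truth."""
    rng = np.random.default_rng(config.seed)
    t = config.t
    depths = _depth_grid(t)
    oxygen, sulfide = _redox_profiles(depths)
    reads = rng.integers(config.reads_range[0], config.reads_range[1],
                         size=t)
    samples = SampleSeries(
        sample_ids=tuple(f"S{i:02d}" for i in range(1, t + 1)),
        depths_m=tuple(depths),
        reads_after_qc=tuple(int(r) for r in reads),
        oxygen_uM=tuple(oxygen),
        sulfide_uM=tuple(sulfide))
    zones = tuple(classify_zone(o, s) for o, s in zip(oxygen, sulfide))

    truth = SyntheticTruth(zone_labels=zones)
    comm = Community(samples=samples, mags=[], truth=truth)

    n_prod = config.n_producer_mags
    n_non = config.n_mags - n_prod
    # producers occupy evenly spaced, effectively disjoint niches; the 0.3
    # offset keeps centers off the integer sample grid so profiles carry no
    # exactly-tied symmetric values
    prod_centers = (np.linspace(2.0, t - 1.0, n_prod) + 0.3
                    if n_prod > 1 else np.array([t / 2.0 + 0.3]))
    non_centers = rng.uniform(1.0, t, size=n_non)
    non_widths = rng.uniform(*config.niche_width_range, size=n_non)
    # confounders clone a producer's niche exactly
    n_conf = int(round(config.confounder_fraction * n_non))
    conf_idx = rng.choice(n_non, size=n_conf, replace=False) if n_conf else []
    for k, idx in enumerate(sorted(conf_idx)):
        src = k % max(n_prod, 1)
        if n_prod:
            non_centers[idx] = prod_centers[src]
            non_widths[idx] = config.producer_niche_width

    j = np.arange(1, t + 1, dtype=float)
    sigma_ln = np.sqrt(np.log(1.0 + config.noise_cv ** 2))

    def lognormal_noise(size):
        if config.noise_cv == 0:
            return np.ones(size)
        return rng.lognormal(mean=-sigma_ln ** 2 / 2, sigma=sigma_ln, size=size)

    for m_idx in range(config.n_mags):
        is_prod = m_idx < n_prod
        mag_id = f"MAG{m_idx:04d}"
        if is_prod:
            center, width = prod_centers[m_idx], config.producer_niche_width
            phylum = PHYLA[m_idx % 6]
        else:
            k = m_idx - n_prod
            center, width = non_centers[k], non_widths[k]
            phylum = PHYLA[m_idx % len(PHYLA)]
            if k in set(np.atleast_1d(conf_idx)):
                truth.confounder_mags.add(mag_id)
        size_factor = rng.lognormal(mean=0.0, sigma=0.5)
        abundance = size_factor * np.exp(-0.5 * ((j - center) / width) ** 2)
        truth.mag_abundance[mag_id] = abundance

        completeness = float(rng.uniform(55, 99))
        contamination = float(rng.uniform(0, 8))
        if config.quality_boundary_cases and m_idx < 3:
            completeness, contamination = [(50.0, 5.0), (95.0, 6.0),
                                           (80.0, 2.0)][m_idx]
        mag = Mag(mag_id=mag_id, completeness=completeness,
                  contamination=contamination, phylum=phylum,
                  sample_id=samples.sample_ids[int(np.argmax(abundance))])

        n_scaf = int(rng.integers(config.scaffolds_per_mag[0],
                                  config.scaffolds_per_mag[1] + 1))
        spt_scaf_pos = int(rng.integers(0, n_scaf)) if is_prod else -1
        for s_idx in range(n_scaf):
            sid = f"{mag_id}_scaf{s_idx:03d}"
            profile = abundance * lognormal_noise(t)
            raw = profile * np.asarray(reads, dtype=float) * 1e-6
            if config.noise_cv > 0:
                # a scaffold whose expected coverage is below the floor gets
                # no mapped reads — real depth tables are zero there, they do
                # not carry vanishing-magnitude rank information
                raw = np.where(raw < config.depth_floor, 0.0, raw)
            scaf = Scaffold(scaffold_id=sid, mag_id=mag_id, raw_depths=raw)
            n_orfs = int(rng.integers(*config.orfs_per_scaffold))
            orfs = []
            for o in range(1, n_orfs + 1):
                start = (o - 1) * 900 + 1
                orfs.append(Orf(sid, o, start, start + 799,
                                "+" if rng.random() < 0.5 else "-",
                                f"{sid}_orf{o:03d}"))
            if s_idx == spt_scaf_pos:
                spt_orf = int(rng.integers(8, max(9, n_orfs - 8)))
                bcers_orf = spt_orf + int(rng.integers(1, 6))
                cerr_orf = max(1, spt_orf - int(rng.integers(1, 6)))
                truth.spt_like_scaffolds.add(sid)
                truth.spt_scaffold_of_mag[mag_id] = sid
                truth.spt_protein_of_mag[mag_id] = f"{sid}_orf{spt_orf:03d}"
                truth.producer_mags.add(mag_id)
                scaf.spt_orf_index = spt_orf
                scaf.bcers_orf_index = min(bcers_orf, n_orfs)
                scaf.cerr_orf_index = cerr_orf
            scaf.orfs = orfs
            mag.scaffold_ids.append(sid)
            comm.scaffolds[sid] = scaf
            comm.orfs.extend(orfs)
        comm.mags.append(mag)
    return comm


# ----------------------------------------------------------------------
# Lipids
# ----------------------------------------------------------------------

_TEMPLATE_INTENSITY = np.array(
    [100.0, 85.0, 70.0, 55.0, 40.0, 95.0, 80.0, 65.0, 50.0, 35.0])
_HEAD_OFFSETS = np.array([0.0, 17.02655, 35.06140, 59.01330, 77.05930])
_CHAIN_OFFSETS = np.array([0.0, 21.07100, 44.02600, 63.09100, 82.04900])


def _template_peaks(template: int, shift: float) -> np.ndarray:
    """10 fragment m/z values for a subclass template plus a chain shift.

    Five headgroup fragments are invariant within a subclass; five chain
    fragments move with the homologous-series shift, so same-subclass
    lipids match both directly and after the precursor-difference shift.
    """
    base = 200.0 + 180.0 * template
    # per-template stretch keeps fragment spacings template-specific, so
    # different subclasses do not align even after the precursor shift
    stretch = np.arange(5) * template
    head = base + _HEAD_OFFSETS + 3.17 * stretch
    chain = base + 95.0 + _CHAIN_OFFSETS + 5.13 * stretch + shift
    return np.concatenate([head, chain])


def generate_lipids(config: SimConfig, truth: SyntheticTruth,
                    mags: Sequence[Mag]) -> List[Spectrum]:
    """Producer-linked lipid features with class-structured toy spectra.

    Lipid per-sample intensity = Σ over producing MAGs of abundance × yield
    plus additive Gaussian noise truncated at zero; MS/MS peak lists come
    from one of seven subclass templates perturbed by CH₂ (14.01565 Da) and
    unsaturation (2.01565 Da) homologous-series shifts.
    """
    rng = np.random.default_rng(config.seed + 1)
    mag_ids = {m.mag_id for m in mags}
    producers = sorted(truth.producer_mags)
    if not producers:
        raise ValueError("community has no producer MAGs — nothing links lipids")
    spectra: List[Spectrum] = []
    for li in range(config.n_lipids):
        lid = f"L{li:04d}"
        producer = producers[li % len(producers)]
        if producer not in mag_ids:
            raise ValueError(f"lipid {lid} mapped to nonexistent MAG {producer}")
        template = li % len(SUBCLASS_TEMPLATES)
        n_ch2 = int(rng.integers(0, 6))
        n_db = int(rng.integers(0, 3))
        shift = n_ch2 * CH2 + n_db * H2
        yield_factor = rng.lognormal(0.0, 0.3)
        clean = truth.mag_abundance[producer] * yield_factor * 1e7
        if config.lipid_noise_frac > 0:
            sd = config.lipid_noise_frac * clean.max()
            noise = rng.normal(0.0, sd, size=clean.size)
            intensity = np.clip(clean + noise, 0.0, None)
            # features below the limit of detection are not reported
            intensity = np.where(intensity < config.lod_sigma * sd, 0.0,
                                 intensity)
        else:
            intensity = clean
        mz = _template_peaks(template, shift)
        peak_int = _TEMPLATE_INTENSITY * rng.uniform(0.95, 1.05, size=mz.size)
        precursor = 200.0 + 180.0 * template + 300.0 + shift
        sp = Spectrum(
            feature_id=lid, precursor_mz=precursor,
            peaks=[Peak(float(m), float(v)) for m, v in zip(mz, peak_int)],
            retention_time_s=float(60.0 + 10.0 * li),
            intensities=AbundanceProfile(intensity, "raw"))
        spectra.append(sp)
        truth.producer_map[lid] = {producer}
        base_c = 16 + template % 4 + 2 * n_db
        fa_c = 14 + 2 * (li % 8) + (li % 2)
        truth.lipid_meta[lid] = {
            "subclass": SUBCLASS_TEMPLATES[template],
            "template": template,
            "producer": producer,
            "base_c": base_c, "base_dbe": n_db,
            "fa_c": fa_c, "fa_dbe": max(0, n_db - 1),
        }
    return spectra


# ----------------------------------------------------------------------
# Function tables
# ----------------------------------------------------------------------

def generate_function_table(config: SimConfig, truth: SyntheticTruth,
                            mags: Sequence[Mag], universe: str = "Pfam",
                            sample_id: str = "all") -> FunctionTable:
    """Function × MAG counts with planted producer enrichments.

    The first ``n_enriched_functions`` functions are present with
    probability ``enriched_presence[0]`` in producers and
    ``enriched_presence[1]`` in non-producers (odds ratio 81 at the 0.9/0.1
    default); the rest are neutral at ``neutral_presence``.  Counts, given
    presence, are 1 + Poisson draws with a higher rate in producers for the
    enriched functions, so the quantitative test has signal too.
    """
    rng = np.random.default_rng(config.seed + 2)
    if config.n_functions == 0:
        return FunctionTable(universe=universe,
                             matrix=pd.DataFrame(
                                 np.zeros((0, len(mags)), dtype=int),
                                 columns=[m.mag_id for m in mags]),
                             mag_group={m.mag_id: ("producer"
                                                   if m.mag_id in truth.producer_mags
                                                   else "non_producer")
                                        for m in mags},
                             mag_phylum={m.mag_id: m.phylum or "unknown"
                                         for m in mags},
                             sample_id=sample_id)
    p_prod, p_non = config.enriched_presence
    rows = []
    fids = [f"F{k:03d}" for k in range(config.n_functions)]
    for k in range(config.n_functions):
        enriched = k < config.n_enriched_functions
        row = []
        for m in mags:
            is_prod = m.mag_id in truth.producer_mags
            if enriched:
                p = p_prod if is_prod else p_non
                lam = 4.0 if is_prod else 1.0
            else:
                p, lam = config.neutral_presence, 1.0
            present = rng.random() < p
            row.append(int(present) * (1 + int(rng.poisson(lam))))
        rows.append(row)
    matrix = pd.DataFrame(rows, index=fids,
                          columns=[m.mag_id for m in mags])
    return FunctionTable(
        universe=universe, matrix=matrix,
        mag_group={m.mag_id: ("producer" if m.mag_id in truth.producer_mags
                              else "non_producer") for m in mags},
        mag_phylum={m.mag_id: m.phylum or "unknown" for m in mags},
        sample_id=sample_id)


# ----------------------------------------------------------------------
# Homolog hit tables and Spt phylogeny
# ----------------------------------------------------------------------

SPT_QUERY = "spt_query_ref38"
ACC_QUERIES = {"bCerS": "bcers_query_ref38", "CerR": "cerr_query_ref38"}
QLEN = {SPT_QUERY: 400, ACC_QUERIES["bCerS"]: 350, ACC_QUERIES["CerR"]: 300}


def generate_homolog_tables(config: SimConfig, truth: SyntheticTruth,
                            comm: Community, n_decoys: int = 12):
    """BLAST-like hit tables: real Spt hits, decoy α-oxoamine synthases,
    and accessory (bCerS/CerR) hits on producer scaffolds.

    Half the decoys pass the Spt hit filter (they reach the tree and must
    be excluded by clade gating); the rest fail the e-value or coverage
    threshold outright.
    """
    rng = np.random.default_rng(config.seed + 3)
    qlen = QLEN[SPT_QUERY]
    spt_hits: List[HomologHit] = []
    acc_hits: Dict[str, List[HomologHit]] = {"bCerS": [], "CerR": []}
    for mag_id in sorted(truth.producer_mags):
        sid = truth.spt_scaffold_of_mag[mag_id]
        prot = truth.spt_protein_of_mag[mag_id]
        qcov = float(rng.uniform(0.75, 1.0))
        alen = int(qcov * qlen)
        spt_hits.append(HomologHit(
            query_id=SPT_QUERY, protein_id=prot,
            evalue=float(10.0 ** -rng.uniform(80, 150)),
            bitscore=float(rng.uniform(300, 600)), qcov=qcov,
            pident=float(rng.uniform(40, 80)), align_length=alen,
            hsp_span=(1, alen, 1, alen), scaffold_id=sid))
        scaf = comm.scaffolds[sid]
        for gene, orf_idx in (("bCerS", scaf.bcers_orf_index),
                              ("CerR", scaf.cerr_orf_index)):
            aq = QLEN[ACC_QUERIES[gene]]
            cov = float(rng.uniform(0.55, 0.95))
            al = int(cov * aq)
            acc_hits[gene].append(HomologHit(
                query_id=ACC_QUERIES[gene],
                protein_id=f"{sid}_orf{orf_idx:03d}",
                evalue=float(10.0 ** -rng.uniform(35, 80)),
                bitscore=float(rng.uniform(150, 400)), qcov=cov,
                pident=float(rng.uniform(30, 70)), align_length=al,
                hsp_span=(1, al, 1, al), scaffold_id=sid))

    non_prod_scafs = sorted(sid for sid, sc in comm.scaffolds.items()
                            if sc.mag_id not in truth.producer_mags)
    chosen = list(rng.choice(non_prod_scafs,
                             size=min(n_decoys, len(non_prod_scafs)),
                             replace=False))
    decoy_passing = []
    for d_idx, sid in enumerate(chosen):
        prot = f"{sid}_orf001"
        passes = d_idx % 2 == 0
        if passes:
            ev = float(10.0 ** -rng.uniform(75, 100))
            qcov = float(rng.uniform(0.72, 0.95))
            decoy_passing.append(prot)
        else:
            # fails either the e-value or the coverage threshold
            if d_idx % 4 == 1:
                ev, qcov = float(10.0 ** -rng.uniform(30, 60)), 0.9
            else:
                ev, qcov = float(10.0 ** -rng.uniform(75, 100)), 0.5
        alen = int(qcov * qlen)
        spt_hits.append(HomologHit(
            query_id=SPT_QUERY, protein_id=prot, evalue=ev,
            bitscore=float(rng.uniform(150, 400)), qcov=qcov,
            pident=float(rng.uniform(25, 50)), align_length=alen,
            hsp_span=(1, alen, 1, alen), scaffold_id=sid))
    return spt_hits, acc_hits, decoy_passing


def generate_spt_tree(truth: SyntheticTruth, decoy_leaves: Sequence[str],
                      n_references: int = 3) -> Tree:
    """Rooted toy phylogeny: reference Spt clade nested in a high-support
    clade with the producers' (co-localization-flagged) Spt proteins; decoy
    α-oxoamine synthases (Kbl/BioF/HemA analogs) attach outside."""
    refs = [f"ref_spt_{k}" for k in range(1, n_references + 1)]
    prods = [truth.spt_protein_of_mag[m] for m in sorted(truth.producer_mags)]
    ref_clade = "(" + ",".join(f"{r}:0.05" for r in refs) + ")99:0.05"
    if prods:
        prod_clade = "(" + ",".join(f"{p}:0.10" for p in prods) + ")98:0.05"
        clade_b = f"({ref_clade},{prod_clade})99:0.10"
    else:
        clade_b = ref_clade
    if decoy_leaves:
        decoys = "(" + ",".join(f"{d}:0.20" for d in decoy_leaves) + ")85:0.15"
        newick = f"({clade_b},{decoys});"
    else:
        newick = f"({clade_b},outgroup_kbl:0.4);"
    tree = Tree.from_newick(newick, force_rooted=True)
    tree.flag_leaves(reference_spt=refs, colocalized=prods)
    return tree


# ----------------------------------------------------------------------
# Disk round-trip: the dataset in exactly the dialects io reads
# ----------------------------------------------------------------------

def write_dataset(config: SimConfig, outdir) -> Path:
    """Generate the full synthetic study and write every pipeline input file.

    Layout: samples.tsv, mags.tsv, depths.tsv, orfs.tsv, lipids.mgf,
    quant.tsv, annotations.tsv, standards.tsv, spt_hits.tsv,
    bcers_hits.tsv, cerr_hits.tsv, spt_tree.nwk, functions.tsv, truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comm = generate_community(config)
    spectra = generate_lipids(config, comm.truth, comm.mags)
    ftable = generate_function_table(config, comm.truth, comm.mags)
    spt_hits, acc_hits, decoys = generate_homolog_tables(config, comm.truth, comm)
    tree = generate_spt_tree(comm.truth, decoys)

    sio.write_sample_table(comm.samples, outdir / "samples.tsv")
    sio.write_mag_table(comm.mags, outdir / "mags.tsv")
    depth_df = pd.DataFrame(
        {sid: comm.scaffolds[sid].raw_depths for sid in sorted(comm.scaffolds)},
        index=list(comm.samples.sample_ids)).T
    sio.write_depth_table(depth_df, outdir / "depths.tsv")
    sio.write_orf_table(comm.orfs, outdir / "orfs.tsv")
    sio.write_mgf(spectra, outdir / "lipids.mgf")
    quant = pd.DataFrame(
        {sp.feature_id: sp.intensities.values for sp in spectra},
        index=list(comm.samples.sample_ids)).T
    sio.write_quant_table(quant, outdir / "quant.tsv")
    ann = pd.DataFrame(
        [(lid, m["subclass"], m["base_c"], m["base_dbe"], m["fa_c"], m["fa_dbe"])
         for lid, m in sorted(comm.truth.lipid_meta.items())],
        columns=["feature_id", "subclass", "base_c", "base_dbe", "fa_c", "fa_dbe"])
    ann.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    # noiseless calibration curves: rf differs per subclass
    std_rows = []
    for k, cls in enumerate(SUBCLASS_TEMPLATES):
        rf = 5.0 + 2.0 * k
        for conc in (10.0, 20.0, 40.0):
            std_rows.append((cls, f"std_{cls}", conc, conc * rf))
    pd.DataFrame(std_rows, columns=["lipid_class", "standard_name",
                                    "known_conc", "intensity"]).to_csv(
        outdir / "standards.tsv", sep="\t", index=False)
    sio.write_blast_tab(spt_hits, outdir / "spt_hits.tsv", qlen_map=QLEN)
    sio.write_blast_tab(acc_hits["bCerS"], outdir / "bcers_hits.tsv", qlen_map=QLEN)
    sio.write_blast_tab(acc_hits["CerR"], outdir / "cerr_hits.tsv", qlen_map=QLEN)
    (outdir / "spt_tree.nwk").write_text(tree.as_newick() + "\n")
    long_rows = []
    for fid in ftable.matrix.index:
        for mag_id in ftable.matrix.columns:
            c = int(ftable.matrix.loc[fid, mag_id])
            if c > 0:
                long_rows.append((fid, ftable.universe, mag_id, c))
    sio.write_function_table(
        pd.DataFrame(long_rows,
                     columns=["function_id", "universe", "mag_id", "count"]),
        outdir / "functions.tsv")
    truth_json = {
        "producer_map": {k: sorted(v) for k, v in comm.truth.producer_map.items()},
        "spt_like_scaffolds": sorted(comm.truth.spt_like_scaffolds),
        "zone_labels": list(comm.truth.zone_labels),
        "producer_mags": sorted(comm.truth.producer_mags),
        "confounder_mags": sorted(comm.truth.confounder_mags),
        "spt_scaffold_of_mag": dict(sorted(comm.truth.spt_scaffold_of_mag.items())),
        "spt_protein_of_mag": dict(sorted(comm.truth.spt_protein_of_mag.items())),
        "reference_spt_leaves": [f"ref_spt_{k}" for k in range(1, 4)],
    }
    (outdir / "truth.json").write_text(json.dumps(truth_json, indent=1) + "\n")
    cfgd = asdict(config)
    (outdir / "config.json").write_text(json.dumps(cfgd, indent=1) + "\n")
    return outdir
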