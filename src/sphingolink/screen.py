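"""Genomic capacity screen for sphingolipid biosynthesis.

Identifies scaffolds and MAGs that can plausibly make sphingolipids:
filters serine palmitoyltransferase (Spt) and accessory (bacterial ceramide
synthase bCerS, ceramide reductase CerR) homolog hits, applies the
high-scoring-pair extraction rule, tests gene co-localization within a
10-ORF window, gates Spt homologs by phylogenetic clade (homology alone
cannot separate Spt from other α-oxoamine synthases such as Kbl, BioF and
HemA), and tiers MAG quality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .tree import Tree
from .types import HomologHit, Mag, Orf

__all__ = [
    "SPT_EVALUE_MAX",
    "SPT_QCOV_MIN",
    "ACCESSORY_EVALUE_MAX",
    "ACCESSORY_QCOV_MIN",
    "filter_spt_hits",
    "filter_accessory_hits",
    "extract_alignable_region",
    "colocalized",
    "gate_spt_like",
    "CladeGateResult",
    "mag_quality",
    "label_taxonomy",
]

SPT_EVALUE_MAX = 1e-70
SPT_QCOV_MIN = 0.70
ACCESSORY_EVALUE_MAX = 1e-30
ACCESSORY_QCOV_MIN = 0.50
HSP_SUBJECT_COV_MIN = 0.70
COLOC_WINDOW = 10
CLADE_MIN_SUPPORT = 98.0


def _best_hit_per_subject(hits: Iterable[HomologHit]) -> List[HomologHit]:
    """Keep, per subject protein, the best hit by e-value (bitscore tie-break)."""
    best: Dict[str, HomologHit] = {}
    for h in hits:
        cur = best.get(h.protein_id)
        if cur is None or (h.evalue, -h.bitscore) < (cur.evalue, -cur.bitscore):
            best[h.protein_id] = h
    return [best[k] for k in sorted(best)]


def filter_spt_hits(hits: Iterable[HomologHit],
                    evalue_max: float = SPT_EVALUE_MAX,
                    qcov_min: float = SPT_QCOV_MIN) -> List[HomologHit]:
    """Retain Spt homolog hits with e-value ≤ 1e-70 and query coverage ≥ 70%.

    Evaluated against the best-scoring query per subject protein (best hit
    by e-value); both boundaries inclusive.
    """
    return [h for h in _best_hit_per_subject(hits)
            if h.evalue <= evalue_max and h.qcov >= qcov_min]


def filter_accessory_hits(hits: Iterable[HomologHit], gene: str,
                          evalue_max: float = ACCESSORY_EVALUE_MAX,
                          qcov_min: float = ACCESSORY_QCOV_MIN) -> List[HomologHit]:
    """Retain bCerS/CerR hits with e-value ≤ 1e-30 and query coverage ≥ 50%."""
    if gene not in ("bCerS", "CerR"):
        raise ValueError(f"gene must be bCerS or CerR, got {gene!r}")
    return [h for h in _best_hit_per_subject(hits)
            if h.evalue <= evalue_max and h.qcov >= qcov_min]


def extract_alignable_region(hit: HomologHit,
                             full_protein_length: int) -> Tuple[int, int]:
    """Span of the subject protein to align downstream.

    Subject coverage below 70% → only the high-scoring pair (HSP) span is
    used, to avoid aligning possibly non-homologous flanks; otherwise the
    entire predicted protein.  Spans are 1-based inclusive.
    """
    _qs, _qe, sstart, send = hit.hsp_span
    lo, hi = min(sstart, send), max(sstart, send)
    if lo < 1 or hi > full_protein_length:
        raise ValueError(
            f"HSP span ({lo}, {hi}) outside protein of length {full_protein_length}")
    subject_cov = (hi - lo + 1) / full_protein_length
    if subject_cov < HSP_SUBJECT_COV_MIN:
        return (lo, hi)
    return (1, full_protein_length)


def colocalized(spt_orf: Orf, accessory_orf: Orf,
                window: int = COLOC_WINDOW) -> bool:
    """True iff both genes sit on the same scaffold within ``window`` ORFs.

    Distance is the difference in ordinal ORF index (strand-agnostic), not
    base pairs.
    """
    if spt_orf.scaffold_id != accessory_orf.scaffold_id:
        return False
    return abs(accessory_orf.orf_index - spt_orf.orf_index) <= window


@dataclass
class CladeGateResult:
    spt_like: Set[str]          # leaves inside clade B
    divergent: Set[str]         # leaves outside clade B (other α-oxoamine synthases)
    clade_a: Set[str]           # MRCA clade of reference Spt leaves
    degenerate: bool = False    # clade B reached the root


def gate_spt_like(tree: Tree, min_support: float = CLADE_MIN_SUPPORT,
                  ) -> CladeGateResult:
    """Gate Spt homologs by phylogenetic clade membership.

    Clade A is the smallest clade containing every reference Spt leaf.
    Clade B grows from clade A one ancestor at a time; an expansion step is
    accepted only if the new ancestor's bootstrap support is at least
    ``min_support`` (missing support fails) and every newly absorbed
    subtree contains at least one leaf whose gene has bCerS/CerR
    co-localized on its scaffold.  All clade-B leaves are called Spt-like;
    the rest are classified as divergent α-oxoamine synthases.
    """
    if not tree.reference_spt:
        raise ValueError("gating requires a non-empty reference Spt leaf set")
    node = tree.mrca(tree.reference_spt)
    clade_a = Tree.clade_leaves(node)
    while node is not tree.root:
        parent = node.parent_node
        # the root never carries bootstrap support, so expansion onto it
        # fails the support test like any other unsupported node
        support = Tree.node_support(parent) if parent is not tree.root else None
        if support is None or support < min_support:
            break
        siblings = [c for c in parent.child_nodes() if c is not node]
        absorbed_ok = all(
            Tree.clade_leaves(sib) & tree.colocalized for sib in siblings)
        if not absorbed_ok:
            break
        node = parent
    spt_like = Tree.clade_leaves(node)
    all_leaves = set(tree.leaf_names())
    degenerate = spt_like == all_leaves
    if degenerate:
        warnings.warn("clade B spans the whole tree — gating is degenerate")
    return CladeGateResult(spt_like=spt_like,
                           divergent=all_leaves - spt_like,
                           clade_a=clade_a,
                           degenerate=degenerate)


def mag_quality(mag: Mag) -> Tuple[str, bool]:
    """Quality tier and association eligibility of a MAG.

    ``medium_high`` requires completeness > 50 and contamination < 10
    (both strict); association eligibility requires
    completeness − 5×contamination ≥ 70.
    """
    tier = ("medium_high"
            if mag.completeness > 50 and mag.contamination < 10 else "low")
    assoc_eligible = (mag.completeness - 5 * mag.contamination) >= 70
    return tier, assoc_eligible


def label_taxonomy(scaffold_id: str,
                   mag_annotation: Optional[object] = None,
                   scaffold_annotation: Optional[str] = None) -> str:
    """Taxon label inheritance: MAG annotation wins, else scaffold, else unclassified.

    A MAG with multiple annotations contributes its majority classification
    (ties → unclassified).
    """
    if mag_annotation is not None:
        if isinstance(mag_annotation, str):
            return mag_annotation
        labels = list(mag_annotation)
        if labels:
            from collections import Counter
            counts = Counter(labels).most_common()
            if len(counts) == 1 or counts[0][1] > counts[1][1]:
                return counts[0][0]
            return "unclassified"
    if scaffold_annotation is not None:
        return scaffold_annotation
    return "unclassified"
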