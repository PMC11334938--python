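"""Feature-based molecular networking.

Pairs of MS/MS spectra are scored with a modified cosine: fragment peaks may
match either directly or after shifting by the precursor mass difference,
so that homologous lipids differing by e.g. a CH2 unit still align.  Edges
require a minimum cosine (default 0.6), a minimum number of matched
fragments (default 6) and mutual top-K membership (default K=10); connected
components of the surviving graph are the subnetworks, within which lipid
class labels propagate from annotated seed nodes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .types import Spectrum

__all__ = [
    "NetworkParams",
    "MolecularNetwork",
    "modified_cosine",
    "build_network",
    "propagate_classes",
    "class_other_rule",
]


@dataclass(frozen=True)
class NetworkParams:
    cosine_min: float = 0.6
    min_matched_peaks: int = 6
    top_k: int = 10
    fragment_tol_da: float = 0.02

    def __post_init__(self):
        if not (0.0 <= self.cosine_min <= 1.0):
            raise ValueError("cosine_min must be in [0, 1]")
        if self.min_matched_peaks < 1:
            raise ValueError("min_matched_peaks must be ≥ 1")
        if self.top_k < 1:
            raise ValueError("top_k must be ≥ 1")
        if self.fragment_tol_da <= 0:
            raise ValueError("fragment_tol_da must be positive")


@dataclass
class MolecularNetwork:
    nodes: List[str]
    edges: List[Tuple[str, str, float, int]]  # (a, b, cosine, n_matched)
    components: List[frozenset]
    class_labels: Dict[str, str] = field(default_factory=dict)
    params: Optional[NetworkParams] = None

    def component_of(self, node: str) -> frozenset:
        for comp in self.components:
            if node in comp:
                return comp
        raise KeyError(node)


def _candidate_pairs(a: Spectrum, b: Spectrum, tol: float):
    """All (i, j, product, penalty) pairs matching directly or precursor-shifted.

    Intensities are square-root transformed before products are formed.
    ``penalty`` orders ties: smaller residual |Δmz − shift| first, then lower m/z.
    """
    shift = b.precursor_mz - a.precursor_mz
    mza, mzb = a.mz_array, b.mz_array
    ia, ib = np.sqrt(a.intensity_array), np.sqrt(b.intensity_array)
    pairs = []
    for off in (0.0, shift):
        d = np.abs(mzb[None, :] - mza[:, None] - off)
        ii, jj = np.nonzero(d <= tol)
        for i, j in zip(ii, jj):
            pairs.append((int(i), int(j), ia[i] * ib[j],
                          (d[i, j], min(mza[i], mzb[j]))))
    # a pair may qualify both directly and via a ~zero shift; keep best residual
    best = {}
    for i, j, prod, pen in pairs:
        key = (i, j)
        if key not in best or pen < best[key][1]:
            best[key] = (prod, pen)
    return [(i, j, prod, pen) for (i, j), (prod, pen) in best.items()]


def _greedy_match(pairs) -> List[Tuple[int, int, float]]:
    """One-to-one matching, greedy by decreasing intensity product.

    Ties broken by smaller m/z residual, then lower m/z — deterministic.
    """
    order = sorted(pairs, key=lambda p: (-p[2], p[3]))
    used_a, used_b, out = set(), set(), []
    for i, j, prod, _pen in order:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append((i, j, prod))
    return out


def modified_cosine(a: Spectrum, b: Spectrum,
                    params: NetworkParams = NetworkParams()) -> Tuple[float, int]:
    """Modified cosine similarity between two spectra.

    Returns ``(score, n_matched)`` where score is the sum of matched
    square-root intensity products normalized by the product of the two
    spectra's Euclidean norms of square-root intensities, so a spectrum
    against itself scores exactly 1.
    """
    if a.n_peaks == 0 or b.n_peaks == 0:
        raise ValueError("modified_cosine requires non-empty peak lists")
    pairs = _candidate_pairs(a, b, params.fragment_tol_da)
    if not pairs:
        return 0.0, 0
    matched = _greedy_match(pairs)
    norm_a = float(np.linalg.norm(np.sqrt(a.intensity_array)))
    norm_b = float(np.linalg.norm(np.sqrt(b.intensity_array)))
    if norm_a == 0 or norm_b == 0:
        return 0.0, 0
    score = sum(prod for _i, _j, prod in matched) / (norm_a * norm_b)
    return min(1.0, float(score)), len(matched)


def build_network(spectra: Sequence[Spectrum],
                  params: NetworkParams = NetworkParams()) -> MolecularNetwork:
    """All-vs-all scoring, threshold + mutual top-K edge retention.

    A candidate edge must pass both the cosine threshold and the minimum
    matched-fragment count; it survives only if each endpoint ranks the
    other within its ``top_k`` best-scoring candidates.
    """
    if len(spectra) == 0:
        raise ValueError("build_network requires at least one spectrum")
    ids = [sp.feature_id for sp in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("feature_ids must be unique")
    n = len(spectra)
    candidates = []  # (i, j, score, n_matched)
    for i in range(n):
        for j in range(i + 1, n):
            score, m = modified_cosine(spectra[i], spectra[j], params)
            if score >= params.cosine_min and m >= params.min_matched_peaks:
                candidates.append((i, j, score, m))
    # per-node candidate ranking by score (desc), deterministic tie-break on id
    per_node: Dict[int, List[Tuple[float, int]]] = {i: [] for i in range(n)}
    for i, j, score, m in candidates:
        per_node[i].append((score, j))
        per_node[j].append((score, i))
    topk: Dict[int, set] = {}
    for i, lst in per_node.items():
        lst.sort(key=lambda p: (-p[0], ids[p[1]]))
        topk[i] = {j for _s, j in lst[: params.top_k]}
    edges = [(ids[i], ids[j], score, m)
             for i, j, score, m in candidates
             if j in topk[i] and i in topk[j]]

    g = nx.Graph()
    g.add_nodes_from(ids)
    g.add_edges_from((a, b) for a, b, _s, _m in edges)
    components = [frozenset(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: sorted(c)[0])
    return MolecularNetwork(nodes=ids, edges=edges, components=components,
                            params=params)


def propagate_classes(net: MolecularNetwork,
                      seed_annotations: Dict[str, str]) -> Dict[str, str]:
    """Propagate lipid-class labels from annotated seeds to whole subnetworks.

    Every node in a component with ≥1 seed inherits the majority seed class;
    tied majorities give ``ambiguous``; seedless components give ``unknown``.
    """
    node_set = set(net.nodes)
    for seed in seed_annotations:
        if seed not in node_set:
            raise ValueError(f"seed node {seed!r} absent from network")
    labels: Dict[str, str] = {}
    for comp in net.components:
        seeds = [seed_annotations[nd] for nd in comp if nd in seed_annotations]
        if not seeds:
            label = "unknown"
        else:
            counts = Counter(seeds).most_common()
            if len(counts) > 1 and counts[0][1] == counts[1][1]:
                label = "ambiguous"
            else:
                label = counts[0][0]
        for nd in comp:
            labels[nd] = label
    net.class_labels = labels
    return labels


def class_other_rule(class_abundance_by_sample, threshold: float = 0.01,
                     min_samples: int = 2) -> Tuple[List[str], List[str]]:
    """Fold minor classes into \"other\".

    ``class_abundance_by_sample`` is a class × sample DataFrame of relative
    abundances over the classified metalipidome (columns sum to 1).  A class
    is kept iff its relative abundance exceeds ``threshold`` (strict) in at
    least ``min_samples`` samples.  Returns (kept, folded_to_other).
    """
    import pandas as pd

    df = pd.DataFrame(class_abundance_by_sample)
    col_sums = df.sum(axis=0)
    bad = col_sums[(col_sums - 1.0).abs() > 1e-6]
    if len(bad):
        raise ValueError(
            f"per-sample relative abundances must sum to 1; offending "
            f"samples: {list(bad.index)}")
    n_over = (df > threshold).sum(axis=1)
    kept = sorted(df.index[n_over >= min_samples])
    other = sorted(df.index[n_over < min_samples])
    return kept, other
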