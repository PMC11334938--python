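"""Pangenome-wide association between genome functions and producer status.

Per water-column sample, functions annotated on association-eligible MAGs
(completeness − 5×contamination ≥ 70) are tested for qualitative
(presence/absence, Fisher's exact test) and quantitative (copy-count,
Mann–Whitney U) association with the potential-sphingolipid-producer group,
with Bonferroni correction within each sample × functional universe × test
family.  Cross-phylum prevalence keeps only functions shared by at least
75% of producer phyla, favouring general over taxon-specific associations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FunctionTable",
    "AssociationResult",
    "fisher_presence",
    "mwu_abundance",
    "bonferroni",
    "phylum_prevalence",
    "run_association",
    "PHYLUM_PREVALENCE_MIN",
    "MWU_EXACT_MAX_N",
]

PHYLUM_PREVALENCE_MIN = 0.75
MWU_EXACT_MAX_N = 12
UNIVERSES = ("CDD", "GO", "InterProScan", "NCBIfam", "pathways", "Pfam")


@dataclass
class FunctionTable:
    """Function × MAG count matrix plus MAG grouping metadata.

    ``matrix``: DataFrame, rows = function ids, columns = MAG ids, integer
    counts (presence = count > 0).  ``mag_group`` maps MAG id → "producer"
    (encodes an Spt-like protein) or "non_producer".  Every MAG is expected
    to be association-eligible.
    """

    universe: str
    matrix: pd.DataFrame
    mag_group: Dict[str, str]
    mag_phylum: Dict[str, str]
    sample_id: str = ""

    def __post_init__(self):
        if self.universe not in UNIVERSES:
            raise ValueError(f"unknown functional universe {self.universe!r}")
        if (self.matrix.values < 0).any():
            raise ValueError("function counts must be non-negative")
        unknown = set(self.matrix.columns) - set(self.mag_group)
        if unknown:
            raise ValueError(f"MAGs without group labels: {sorted(unknown)[:5]}")

    def producers(self) -> List[str]:
        return [m for m in self.matrix.columns if self.mag_group[m] == "producer"]

    def non_producers(self) -> List[str]:
        return [m for m in self.matrix.columns if self.mag_group[m] != "producer"]


@dataclass
class AssociationResult:
    function_id: str
    universe: str
    sample_id: str
    test: str           # "fisher" | "mwu"
    direction: str      # "enriched" | "depleted" | "neutral"
    p_raw: float
    p_bonferroni: float
    phylum_prevalence: float
    method: str = ""    # "exact" | "asymptotic" for mwu


def fisher_presence(present_prod: int, absent_prod: int,
                    present_non: int, absent_non: int) -> Tuple[float, str]:
    """Two-sided Fisher's exact test on a 2×2 presence table.

    Two-sided p is the sum of probabilities of tables (at fixed margins)
    no more probable than the observed one.  Direction compares presence
    odds between producers and non-producers.
    """
    for v in (present_prod, absent_prod, present_non, absent_non):
        if v < 0:
            raise ValueError("table counts must be non-negative")
    n_prod = present_prod + absent_prod
    n_non = present_non + absent_non
    if n_prod == 0 or n_non == 0:
        raise ValueError("both groups must be non-empty")
    table = [[present_prod, absent_prod], [present_non, absent_non]]
    p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    cross1 = present_prod * absent_non
    cross2 = absent_prod * present_non
    if cross1 > cross2:
        direction = "enriched"
    elif cross1 < cross2:
        direction = "depleted"
    else:
        direction = "neutral"
    return min(1.0, p), direction


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann–Whitney U of x vs y via rank sums (ties get mean rank)."""
    n1 = x.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    return r1 - n1 * (n1 + 1) / 2


def mwu_abundance(counts_producers: Sequence[float],
                  counts_non: Sequence[float]) -> Tuple[float, str, str]:
    """Two-sided Mann–Whitney U test of function counts between groups.

    Exact null distribution by enumeration of group assignments when
    n1 + n2 ≤ 12 (handles ties); tie-corrected normal approximation above.
    Returns (p, direction, method).
    """
    x = np.asarray(counts_producers, dtype=float)
    y = np.asarray(counts_non, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0, "neutral", "degenerate"
    u_obs = _u_statistic(x, y)
    mu = x.size * y.size / 2
    if x.size + y.size <= MWU_EXACT_MAX_N:
        n = pooled.size
        dev_obs = abs(u_obs - mu)
        hits = total = 0
        for idx in combinations(range(n), x.size):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        p = hits / total
        method = "exact"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
        p = float(res.pvalue)
        method = "asymptotic"
    if u_obs > mu:
        direction = "enriched"
    elif u_obs < mu:
        direction = "depleted"
    else:
        direction = "neutral"
    return min(1.0, p), direction, method


def bonferroni(p_values: Sequence[float],
               m: Optional[int] = None) -> List[float]:
    """p_adj = min(1, p × m); m defaults to the family size len(p_values)."""
    ps = list(p_values)
    if m is None:
        m = len(ps)
    for p in ps:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
    return [min(1.0, p * m) for p in ps]


def phylum_prevalence(table: FunctionTable, function_id: str) -> float:
    """Fraction of producer phyla with ≥1 member encoding the function."""
    producers = table.producers()
    if not producers:
        raise ValueError("no producer MAGs — prevalence undefined")
    phyla = {table.mag_phylum[m] for m in producers}
    present = {table.mag_phylum[m] for m in producers
               if table.matrix.loc[function_id, m] > 0}
    return len(present) / len(phyla)


def run_association(table: FunctionTable,
                    prevalence_min: float = PHYLUM_PREVALENCE_MIN,
                    ) -> List[AssociationResult]:
    """Run both tests over every function in one sample/universe family.

    Bonferroni m = number of functions tested within this
    sample × universe × test family.  Results carry phylum prevalence; the
    ≥75%-of-phyla shared-function filter is applied downstream by the
    caller (results below the cutoff are still reported).
    """
    producers = table.producers()
    non_producers = table.non_producers()
    if not producers or not non_producers:
        raise ValueError("association needs both producer and non-producer MAGs")
    functions = list(table.matrix.index)
    m = len(functions)
    results: List[AssociationResult] = []
    prod_counts = table.matrix[producers].to_numpy(dtype=float)
    non_counts = table.matrix[non_producers].to_numpy(dtype=float)
    for row, fid in enumerate(functions):
        prev = phylum_prevalence(table, fid)
        pp = int((prod_counts[row] > 0).sum())
        pn = int((non_counts[row] > 0).sum())
        p_f, dir_f = fisher_presence(pp, len(producers) - pp,
                                     pn, len(non_producers) - pn)
        results.append(AssociationResult(
            fid, table.universe, table.sample_id, "fisher", dir_f,
            p_f, min(1.0, p_f * m), prev, method="exact"))
        p_u, dir_u, method = mwu_abundance(prod_counts[row], non_counts[row])
        results.append(AssociationResult(
            fid, table.universe, table.sample_id, "mwu", dir_u,
            p_u, min(1.0, p_u * m), prev, method=method))
    return results


def results_to_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    rows = [(r.function_id, r.universe, r.sample_id, r.test, r.direction,
             r.p_raw, r.p_bonferroni, r.phylum_prevalence, r.method)
            for r in results]
    return pd.DataFrame(rows, columns=[
        "function_id", "universe", "sample_id", "test", "direction",
        "p_raw", "p_bonferroni", "phylum_prevalence", "method"])
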