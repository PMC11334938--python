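"""Response-factor calibration and lipid class summaries.

Ionization response differs strongly between lipid classes, so feature
intensities are converted to concentrations (ng L⁻¹) with per-class
response factors fitted from external standard curves; classes without a
standard fall back to a configured surrogate class.  Summaries cover
class-relative abundance per sample and odd/even chain parity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import AbundanceProfile

__all__ = [
    "ResponseFactor",
    "LipidSpecies",
    "SPHINGOLIPID_SUBCLASSES",
    "DEFAULT_SURROGATES",
    "fit_response_factor",
    "quantify",
    "resolve_rf",
    "chain_parity",
    "class_relative_abundance",
]

SPHINGOLIPID_SUBCLASSES = (
    "Cer", "Gly-Cer", "Lys-Cer", "1-deoxyCer", "Sulfono-1-deoxyCer",
    "Acetylsulfono-1-deoxyCer", "Sulfate-1-deoxyCer",
)

# class → surrogate class providing the standard when none is available:
# ornithine lipids borrow the DGTS amino-lipid standard; all
# 1-deoxyCer-derived classes share the 1-deoxyCer(d18:1/24:0) standard;
# Cer and Lys-Cer share the ceramide-mix average.
DEFAULT_SURROGATES: Dict[str, str] = {
    "OL": "DGTS",
    "Sulfono-1-deoxyCer": "1-deoxyCer",
    "Acetylsulfono-1-deoxyCer": "1-deoxyCer",
    "Sulfate-1-deoxyCer": "1-deoxyCer",
    "Lys-Cer": "Cer",
}


@dataclass(frozen=True)
class ResponseFactor:
    lipid_class: str
    rf: float  # intensity units per (ng L⁻¹)
    source_standard: str
    residual: float = 0.0

    def __post_init__(self):
        if self.rf <= 0:
            raise ValueError("response factor must be positive")


@dataclass
class LipidSpecies:
    feature_id: str
    subclass: str
    base_c: Optional[int] = None
    base_dbe: Optional[int] = None
    fa_c: Optional[int] = None
    fa_dbe: Optional[int] = None
    conc: Optional[AbundanceProfile] = None  # ng L⁻¹ per sample

    def __post_init__(self):
        for c in (self.base_c, self.fa_c):
            if c is not None and c <= 0:
                raise ValueError("carbon counts must be positive")
        for d in (self.base_dbe, self.fa_dbe):
            if d is not None and d < 0:
                raise ValueError("DBE must be non-negative")


def fit_response_factor(curve_points: Sequence[Tuple[float, float]],
                        lipid_class: str = "",
                        source_standard: str = "") -> ResponseFactor:
    """Least-squares slope through the origin of intensity vs concentration.

    rf = Σ(conc·intensity) / Σ(conc²).  A calibration line is forced through
    the origin because intensities are blank-subtracted.  Non-positive slope
    signals an unusable standard and raises.
    """
    pts = list(curve_points)
    if len(pts) < 2:
        raise ValueError("need ≥2 calibration points")
    conc = np.array([p[0] for p in pts], dtype=float)
    inten = np.array([p[1] for p in pts], dtype=float)
    if np.any(conc <= 0):
        raise ValueError("calibration concentrations must be positive")
    if len(np.unique(conc)) < 2:
        raise ValueError("calibration concentrations must be distinct")
    slope = float(np.sum(conc * inten) / np.sum(conc ** 2))
    if slope <= 0:
        raise ValueError(f"non-positive response factor ({slope}) — unusable standard")
    residual = float(np.sqrt(np.mean((inten - slope * conc) ** 2)))
    return ResponseFactor(lipid_class=lipid_class, rf=slope,
                          source_standard=source_standard, residual=residual)


def quantify(intensity, rf: ResponseFactor):
    """Concentration (ng L⁻¹) = intensity / rf, applied element-wise."""
    arr = np.asarray(intensity, dtype=float)
    if np.any(arr < 0):
        raise ValueError("intensity must be non-negative")
    out = arr / rf.rf
    return float(out) if np.isscalar(intensity) else out


def resolve_rf(lipid_class: str, factors: Dict[str, ResponseFactor],
               surrogates: Dict[str, str] = DEFAULT_SURROGATES,
               ) -> Tuple[ResponseFactor, str]:
    """Find the response factor for a class, falling back to its surrogate.

    Returns (rf, provenance) where provenance is ``direct`` or
    ``surrogate:<class>``.
    """
    if lipid_class in factors:
        return factors[lipid_class], "direct"
    surrogate = surrogates.get(lipid_class)
    if surrogate is not None and surrogate in factors:
        return factors[surrogate], f"surrogate:{surrogate}"
    raise KeyError(f"no response factor or surrogate for class {lipid_class!r}")


def chain_parity(species: LipidSpecies) -> str:
    """``odd`` iff the sphingoid base or the fatty acid has an odd carbon count."""
    if species.base_c is None or species.fa_c is None:
        raise ValueError(
            f"{species.feature_id}: chain information missing — species must "
            "be excluded from parity analysis")
    return "odd" if (species.base_c % 2 == 1 or species.fa_c % 2 == 1) else "even"


def class_relative_abundance(species_list: Iterable[LipidSpecies],
                             sample_ids: Sequence[str]) -> pd.DataFrame:
    """Class × sample matrix of concentration fractions.

    Fractions are over the classified species only; samples where all
    classified concentrations are zero get NaN columns (flagged undefined).
    """
    totals: Dict[str, np.ndarray] = {}
    n = len(sample_ids)
    for sp in species_list:
        if sp.conc is None:
            continue
        if sp.conc.t != n:
            raise ValueError(f"{sp.feature_id}: profile length mismatch")
        totals.setdefault(sp.subclass, np.zeros(n))
        totals[sp.subclass] = totals[sp.subclass] + sp.conc.values
    if not totals:
        raise ValueError("no classified species with concentrations")
    df = pd.DataFrame(totals, index=list(sample_ids)).T.sort_index()
    col_sums = df.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = df / col_sums
    frac[df.columns[col_sums == 0]] = np.nan
    return frac
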