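"""Shared domain types for the water-column lipid/producer inference pipeline.

The central convention, used by every module, is the 1-based sample index
``j`` defined by depth order: samples are sorted by increasing depth below
sea level, and ``j = 1 .. t`` indexes that order.  Abundance profiles,
depth-weight statistics and zone labels are all aligned to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "SampleSeries",
    "Peak",
    "Spectrum",
    "AbundanceProfile",
    "HomologHit",
    "Orf",
    "Scaffold",
    "Mag",
]


class ValidationError(ValueError):
    """Raised when a domain invariant is violated on construction."""


@dataclass(frozen=True)
class SampleSeries:
    """Depth-ordered series of water-column samples.

    ``depths_m`` must be strictly increasing; the resulting order defines the
    1-based sample index ``j`` used by the abundance-weight statistic and all
    profile alignment downstream.
    """

    sample_ids: tuple
    depths_m: tuple
    reads_after_qc: tuple
    oxygen_uM: Optional[tuple] = None
    sulfide_uM: Optional[tuple] = None

    def __post_init__(self):
        t = len(self.sample_ids)
        if t < 2:
            raise ValidationError("SampleSeries needs at least 2 samples")
        if len(self.depths_m) != t or len(self.reads_after_qc) != t:
            raise ValidationError("sample_ids, depths_m, reads_after_qc must align")
        d = np.asarray(self.depths_m, dtype=float)
        if not np.all(np.diff(d) > 0):
            raise ValidationError("depths_m must be strictly increasing")
        if any(r <= 0 for r in self.reads_after_qc):
            raise ValidationError("reads_after_qc must be positive")
        for conc in (self.oxygen_uM, self.sulfide_uM):
            if conc is not None:
                if len(conc) != t:
                    raise ValidationError("concentration vectors must align with samples")
                if any(c is not None and c < 0 for c in conc):
                    raise ValidationError("concentrations must be non-negative")

    @property
    def t(self) -> int:
        return len(self.sample_ids)

    @property
    def j(self) -> np.ndarray:
        """1-based sample indices in depth order."""
        return np.arange(1, self.t + 1)


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self):
        if self.mz <= 0:
            raise ValidationError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValidationError("peak intensity must be non-negative")


@dataclass
class AbundanceProfile:
    """Length-t non-negative vector aligned to a SampleSeries.

    ``normalization`` records provenance: ``raw`` (e.g. mapping depth or peak
    area), ``per_read`` (depth divided by reads after QC) or ``rel_freq``
    (sums to 1, or flagged all-zero).
    """

    values: np.ndarray
    normalization: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("profile must be 1-D")
        if np.any(self.values < 0):
            raise ValidationError("profile values must be non-negative")
        if self.normalization not in ("raw", "per_read", "rel_freq"):
            raise ValidationError(f"unknown normalization {self.normalization!r}")
        if self.normalization == "rel_freq" and not self.all_zero:
            s = float(self.values.sum())
            if abs(s - 1.0) > 1e-9:
                raise ValidationError(f"rel_freq profile sums to {s}, not 1")

    @property
    def t(self) -> int:
        return self.values.size

    @property
    def all_zero(self) -> bool:
        return bool(np.all(self.values == 0))

    def to_rel_freq(self) -> "AbundanceProfile":
        if self.all_zero:
            raise ValidationError("cannot normalize an all-zero profile to rel_freq")
        return AbundanceProfile(self.values / self.values.sum(), "rel_freq")


@dataclass
class Spectrum:
    """One MS/MS feature: precursor, fragment peak list, per-sample areas.

    Peaks are kept sorted by ascending m/z (enforced on construction).
    """

    feature_id: str
    precursor_mz: float
    peaks: list = field(default_factory=list)
    retention_time_s: Optional[float] = None
    intensities: Optional[AbundanceProfile] = None

    def __post_init__(self):
        if self.precursor_mz <= 0:
            raise ValidationError("precursor m/z must be positive")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


@dataclass
class HomologHit:
    """One tabular protein alignment hit (outfmt-6-like)."""

    query_id: str
    protein_id: str
    evalue: float
    bitscore: float
    qcov: float
    pident: float = 0.0
    align_length: int = 0
    hsp_span: tuple = (0, 0, 0, 0)  # qstart, qend, sstart, send
    scaffold_id: Optional[str] = None

    def __post_init__(self):
        if self.evalue < 0:
            raise ValidationError("e-value must be non-negative")
        if not (0.0 <= self.qcov <= 1.0 + 1e-9):
            raise ValidationError(f"query coverage {self.qcov} outside [0, 1]")


@dataclass(frozen=True)
class Orf:
    """One predicted gene on a scaffold; genomic coordinates 1-based inclusive."""

    scaffold_id: str
    orf_index: int  # ordinal position on the scaffold, 1-based
    start: int
    end: int
    strand: str
    protein_id: str


@dataclass
class Scaffold:
    scaffold_id: str
    mag_id: Optional[str] = None
    raw_depths: Optional[np.ndarray] = None  # aligned to SampleSeries
    orfs: list = field(default_factory=list)
    taxon: Optional[str] = None


@dataclass
class Mag:
    """A metagenome-assembled genome: binned scaffolds plus quality metadata."""

    mag_id: str
    scaffold_ids: list = field(default_factory=list)
    completeness: float = 0.0  # percent
    contamination: float = 0.0  # percent
    phylum: Optional[str] = None
    sample_id: Optional[str] = None
    spt_like: bool = False

    def __post_init__(self):
        if not (0 <= self.completeness <= 100):
            raise ValidationError("completeness must be in [0, 100]")
        if not (0 <= self.contamination <= 100):
            raise ValidationError("contamination must be in [0, 100]")
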