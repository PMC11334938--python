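"""Readers and writers for every external format the pipeline touches.

Dialects
--------
* MGF (Mascot generic format) for MS/MS spectra
* BLAST outfmt-6 TSV (optional 13th ``qlen`` column) for homology hits
* Newick for the Spt homolog phylogeny
* plain TSV for ORF tables, per-sample scaffold depths, MAG metadata,
  feature-quantification matrices, function tables and sample series
* GraphML / edge-TSV for networks

Every reader is total on its documented dialect and raises
:class:`ParseError` with location information for anything outside it;
nothing is silently coerced.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .tree import Tree, TreeParseError
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
    "ParseError",
    "read_mgf",
    "write_mgf",
    "read_blast_tab",
    "read_newick",
    "write_network",
    "read_network",
    "read_orf_table",
    "write_orf_table",
    "read_depth_table",
    "write_depth_table",
    "read_mag_table",
    "write_mag_table",
    "read_sample_table",
    "write_sample_table",
    "read_quant_table",
    "write_quant_table",
    "read_function_table",
    "write_function_table",
]


class ParseError(ValueError):
    """A file did not conform to its documented dialect."""


# ----------------------------------------------------------------------
# MGF
# ----------------------------------------------------------------------

def read_mgf(path) -> List[Spectrum]:
    """Parse an MGF file into Spectrum objects.

    Records are delimited by BEGIN IONS / END IONS and must carry PEPMASS;
    FEATURE_ID (or SCANS) names the feature.  Peaks are re-sorted by
    ascending m/z.  Per-sample intensities are left unset — they are joined
    later from the feature-quantification table.
    """
    spectra: List[Spectrum] = []
    in_record = False
    params: Dict[str, str] = {}
    peaks: List[Peak] = []
    record_start = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                if in_record:
                    raise ParseError(f"line {lineno}: nested BEGIN IONS")
                in_record, params, peaks, record_start = True, {}, [], lineno
                continue
            if line == "END IONS":
                if not in_record:
                    raise ParseError(f"line {lineno}: END IONS without BEGIN IONS")
                spectra.append(_finish_mgf_record(params, peaks, record_start))
                in_record = False
                continue
            if not in_record:
                continue  # headers between records are legal MGF
            if "=" in line:
                key, _, val = line.partition("=")
                params[key.upper()] = val
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"line {lineno}: expected 'mz intensity' peak line")
            try:
                mz, inten = float(fields[0]), float(fields[1])
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric peak line {line!r}")
            peaks.append(Peak(mz, inten))
    if in_record:
        raise ParseError(f"line {record_start}: BEGIN IONS never closed")
    return spectra


def _finish_mgf_record(params, peaks, record_start) -> Spectrum:
    if "PEPMASS" not in params:
        raise ParseError(f"line {record_start}: record missing PEPMASS")
    try:
        pepmass = float(params["PEPMASS"].split()[0])
    except ValueError:
        raise ParseError(f"line {record_start}: non-numeric PEPMASS")
    fid = params.get("FEATURE_ID") or params.get("SCANS")
    if fid is None:
        raise ParseError(f"line {record_start}: record missing FEATURE_ID/SCANS")
    rt = None
    if "RTINSECONDS" in params:
        rt = float(params["RTINSECONDS"])
    return Spectrum(feature_id=fid, precursor_mz=pepmass, peaks=peaks,
                    retention_time_s=rt)


def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    with open(path, "w") as fh:
        for sp in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"FEATURE_ID={sp.feature_id}\n")
            fh.write(f"PEPMASS={sp.precursor_mz:.5f}\n")
            if sp.retention_time_s is not None:
                fh.write(f"RTINSECONDS={sp.retention_time_s:.2f}\n")
            for p in sp.peaks:
                fh.write(f"{p.mz:.5f} {p.intensity:.4f}\n")
            fh.write("END IONS\n")


# ----------------------------------------------------------------------
# BLAST outfmt 6
# ----------------------------------------------------------------------

_BLAST_COLS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
               "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def read_blast_tab(path, qlen_map: Optional[Dict[str, int]] = None) -> List[HomologHit]:
    """Read a 12(+1)-column BLAST tabular file into HomologHit objects.

    Query coverage is computed as max(alignment length, qend−qstart+1)
    divided by the query length, which comes from an optional 13th ``qlen``
    column or from ``qlen_map``.  Queries with no length source raise
    :class:`ParseError` listing the offending query ids.
    """
    hits: List[HomologHit] = []
    missing = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"line {lineno}: expected ≥12 tab-separated columns")
            try:
                qseqid, sseqid = fields[0], fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
                qlen = int(fields[12]) if len(fields) > 12 else None
            except ValueError:
                raise ParseError(f"line {lineno}: malformed numeric field")
            if qlen is None and qlen_map is not None:
                qlen = qlen_map.get(qseqid)
            if qlen is None:
                missing.append(qseqid)
                continue
            span = abs(qend - qstart) + 1
            qcov = min(1.0, max(length, span) / qlen)
            hits.append(HomologHit(
                query_id=qseqid, protein_id=sseqid, evalue=evalue,
                bitscore=bitscore, qcov=qcov, pident=pident,
                align_length=length, hsp_span=(qstart, qend, sstart, send)))
    if missing:
        raise ParseError(
            "no query length available for queries: "
            + ", ".join(sorted(set(missing))))
    return hits


def write_blast_tab(hits: Iterable[HomologHit], path,
                    qlen_map: Optional[Dict[str, int]] = None) -> None:
    with open(path, "w") as fh:
        for h in hits:
            qs, qe, ss, se = h.hsp_span
            row = [h.query_id, h.protein_id, f"{h.pident:.1f}",
                   str(h.align_length), "0", "0", str(qs), str(qe),
                   str(ss), str(se), f"{h.evalue:.3g}", f"{h.bitscore:.1f}"]
            if qlen_map is not None:
                row.append(str(qlen_map[h.query_id]))
            fh.write("\t".join(row) + "\n")


# ----------------------------------------------------------------------
# Newick
# ----------------------------------------------------------------------

def read_newick(path) -> Tree:
    """Read one Newick tree; internal labels are bootstrap supports 0–100.

    Unrooted trees (root with >2 children) are midpoint-rooted; the result
    records this in ``Tree.midpoint_rooted``.
    """
    text = Path(path).read_text().strip()
    if text.count("(") != text.count(")"):
        raise TreeParseError("unbalanced parentheses in newick")
    return Tree.from_newick(text)


# ----------------------------------------------------------------------
# Networks
# ----------------------------------------------------------------------

def write_network(edges, path, dialect: str = "edge_tsv",
                  weight_attr: str = "rho") -> None:
    """Write (u, v, weight) edges; dialect ∈ {graphml, edge_tsv}.

    Weights round-trip to 6 decimals.
    """
    edges = list(edges)
    if dialect == "edge_tsv":
        with open(path, "w") as fh:
            fh.write(f"source\ttarget\t{weight_attr}\n")
            for u, v, w in edges:
                fh.write(f"{u}\t{v}\t{w:.6f}\n")
    elif dialect == "graphml":
        g = nx.Graph()
        for u, v, w in edges:
            g.add_edge(str(u), str(v), **{weight_attr: round(float(w), 6)})
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network dialect {dialect!r}")


def read_network(path, dialect: str = "edge_tsv", weight_attr: str = "rho"):
    if dialect == "edge_tsv":
        out = []
        with open(path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None or weight_attr not in reader.fieldnames:
                raise ParseError(f"edge TSV missing {weight_attr!r} column")
            for row in reader:
                out.append((row["source"], row["target"], float(row[weight_attr])))
        return out
    if dialect == "graphml":
        g = nx.read_graphml(path)
        return [(u, v, float(d[weight_attr])) for u, v, d in g.edges(data=True)]
    raise ValueError(f"unknown network dialect {dialect!r}")


# ----------------------------------------------------------------------
# Tabular helpers (ORF / depth / MAG / sample / quant / function tables)
# ----------------------------------------------------------------------

def read_orf_table(path) -> List[Orf]:
    df = pd.read_csv(path, sep="\t", dtype={"scaffold_id": str, "protein_id": str})
    req = {"scaffold_id", "orf_index", "start", "end", "strand", "protein_id"}
    if not req.issubset(df.columns):
        raise ParseError(f"ORF table missing columns {sorted(req - set(df.columns))}")
    return [Orf(r.scaffold_id, int(r.orf_index), int(r.start), int(r.end),
                r.strand, r.protein_id) for r in df.itertuples()]


def write_orf_table(orfs: Iterable[Orf], path) -> None:
    rows = [(o.scaffold_id, o.orf_index, o.start, o.end, o.strand, o.protein_id)
            for o in orfs]
    pd.DataFrame(rows, columns=["scaffold_id", "orf_index", "start", "end",
                                "strand", "protein_id"]).to_csv(
        path, sep="\t", index=False)


def read_depth_table(path, samples: Optional[SampleSeries] = None) -> pd.DataFrame:
    """Scaffold × sample raw mapping depths; sample columns in depth order."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if samples is not None:
        want = list(samples.sample_ids)
        if list(df.columns) != want:
            missing = set(want) - set(df.columns)
            if missing:
                raise ParseError(f"depth table missing sample columns {sorted(missing)}")
            df = df[want]
    return df


def write_depth_table(depths: pd.DataFrame, path) -> None:
    depths.to_csv(path, sep="\t", index_label="scaffold_id")


def read_mag_table(path) -> List[Mag]:
    df = pd.read_csv(path, sep="\t", dtype={"mag_id": str})
    req = {"mag_id", "scaffold_ids", "completeness", "contamination"}
    if not req.issubset(df.columns):
        raise ParseError(f"MAG table missing columns {sorted(req - set(df.columns))}")
    mags = []
    for r in df.itertuples():
        scafs = [] if pd.isna(r.scaffold_ids) or r.scaffold_ids == "" \
            else str(r.scaffold_ids).split(",")
        mags.append(Mag(
            mag_id=r.mag_id, scaffold_ids=scafs,
            completeness=float(r.completeness),
            contamination=float(r.contamination),
            phylum=getattr(r, "phylum", None) if not pd.isna(getattr(r, "phylum", np.nan)) else None,
            sample_id=getattr(r, "sample_id", None)))
    return mags


def write_mag_table(mags: Iterable[Mag], path) -> None:
    rows = [(m.mag_id, ",".join(m.scaffold_ids), m.completeness,
             m.contamination, m.phylum or "", m.sample_id or "")
            for m in mags]
    pd.DataFrame(rows, columns=["mag_id", "scaffold_ids", "completeness",
                                "contamination", "phylum", "sample_id"]).to_csv(
        path, sep="\t", index=False)


def read_sample_table(path) -> SampleSeries:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    req = {"sample_id", "depth_m", "reads_after_qc"}
    if not req.issubset(df.columns):
        raise ParseError(f"sample table missing columns {sorted(req - set(df.columns))}")
    df = df.sort_values("depth_m")

    def col(name):
        if name in df.columns:
            return tuple(None if pd.isna(v) else float(v) for v in df[name])
        return None

    return SampleSeries(
        sample_ids=tuple(df.sample_id),
        depths_m=tuple(float(d) for d in df.depth_m),
        reads_after_qc=tuple(int(r) for r in df.reads_after_qc),
        oxygen_uM=col("oxygen_uM"),
        sulfide_uM=col("sulfide_uM"))


def write_sample_table(samples: SampleSeries, path) -> None:
    data = {"sample_id": samples.sample_ids,
            "depth_m": samples.depths_m,
            "reads_after_qc": samples.reads_after_qc}
    if samples.oxygen_uM is not None:
        data["oxygen_uM"] = samples.oxygen_uM
    if samples.sulfide_uM is not None:
        data["sulfide_uM"] = samples.sulfide_uM
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_quant_table(path, samples: Optional[SampleSeries] = None) -> pd.DataFrame:
    """Feature × sample intensity (peak-area) matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if samples is not None:
        want = list(samples.sample_ids)
        missing = set(want) - set(df.columns)
        if missing:
            raise ParseError(f"quant table missing sample columns {sorted(missing)}")
        df = df[want]
    return df


def write_quant_table(quant: pd.DataFrame, path) -> None:
    quant.to_csv(path, sep="\t", index_label="feature_id")


def attach_intensities(spectra: List[Spectrum], quant: pd.DataFrame) -> List[Spectrum]:
    """Join per-sample areas from the quantification table onto spectra."""
    for sp in spectra:
        if sp.feature_id in quant.index:
            sp.intensities = AbundanceProfile(
                quant.loc[sp.feature_id].to_numpy(dtype=float), "raw")
    return spectra


def read_function_table(path) -> pd.DataFrame:
    """Long-format function annotations: function_id, universe, mag_id, count."""
    df = pd.read_csv(path, sep="\t", dtype={"function_id": str, "mag_id": str})
    req = {"function_id", "universe", "mag_id", "count"}
    if not req.issubset(df.columns):
        raise ParseError(
            f"function table missing columns {sorted(req - set(df.columns))}")
    return df


def write_function_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
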