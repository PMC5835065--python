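"""Readers and writers for the package's plain-text interchange formats.

Genomic tables are tab-separated, chemistry tables comma-separated; all
files are UTF-8 with mandatory header rows. Contigs travel as FASTA.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binning import BinAssignment
from .coverage import CoverageMatrix
from .kinetics import GrowthCurve
from .synthcom import ContigRecord, ContigSet, LinkGraph


# --- FASTA -----------------------------------------------------------------

def write_fasta(contigs: ContigSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(r.sequence), id=r.contig_id, description="")
        for r in contigs.records
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> ContigSet:
    records = [
        ContigRecord(rec.id, str(rec.seq).upper(), None)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return ContigSet(records=records)


# --- TSV genomic tables ----------------------------------------------------

def write_coverage(cov: CoverageMatrix, path: str | Path) -> None:
    cov.to_frame().to_csv(path, sep="\t")


def read_coverage(path: str | Path) -> CoverageMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return CoverageMatrix.from_frame(frame)


def write_links(links: LinkGraph, path: str | Path) -> None:
    pd.DataFrame(links.edges, columns=["contig_a", "contig_b", "n_pairs"]).to_csv(
        path, sep="\t", index=False
    )


def read_links(path: str | Path) -> LinkGraph:
    frame = pd.read_csv(path, sep="\t")
    return LinkGraph(edges=[
        (str(a), str(b), int(n))
        for a, b, n in frame[["contig_a", "contig_b", "n_pairs"]].itertuples(index=False)
    ])


def write_truth(truth: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(sorted(truth.items()), columns=["contig_id", "genome_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_truth(path: str | Path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t")
    return dict(zip(frame["contig_id"].astype(str), frame["genome_id"].astype(str)))


def write_markers(markers: Iterable[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(sorted(markers), columns=["contig_id", "marker_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_markers(path: str | Path) -> list[tuple[str, str]]:
    frame = pd.read_csv(path, sep="\t")
    return [(str(c), str(m)) for c, m in
            frame[["contig_id", "marker_id"]].itertuples(index=False)]


def write_bins(bins: BinAssignment, path: str | Path) -> None:
    rows = [
        (c, "UNBINNED" if b is None else b, bins.provenance.get(c, ""))
        for c, b in sorted(bins.assignment.items())
    ]
    pd.DataFrame(rows, columns=["contig_id", "bin_id", "provenance"]).to_csv(
        path, sep="\t", index=False
    )


def read_bins(path: str | Path) -> BinAssignment:
    frame = pd.read_csv(path, sep="\t", dtype={"bin_id": str})
    assignment: dict[str, int | None] = {}
    provenance: dict[str, str] = {}
    for c, b, p in frame[["contig_id", "bin_id", "provenance"]].itertuples(index=False):
        assignment[str(c)] = None if b == "UNBINNED" else int(b)
        provenance[str(c)] = "" if pd.isna(p) else str(p)
    return BinAssignment(assignment=assignment, provenance=provenance)


# --- CSV chemistry tables --------------------------------------------------

def write_curves(curves: Iterable[GrowthCurve], path: str | Path) -> None:
    frames = []
    for c in curves:
        nan = np.full(c.times.shape, np.nan)
        frames.append(pd.DataFrame({
            "time_h": c.times,
            "nh4_uM": c.nh4 if c.nh4 is not None else nan,
            "no2_uM": c.no2 if c.no2 is not None else nan,
            "no3_uM": c.no3 if c.no3 is not None else nan,
            "replicate": c.replicate_id,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_curves(path: str | Path) -> list[GrowthCurve]:
    frame = pd.read_csv(path)
    curves = []
    for rep, sub in frame.groupby("replicate", sort=True):
        sub = sub.sort_values("time_h")

        def col(name: str) -> np.ndarray | None:
            v = sub[name].to_numpy(dtype=float)
            return None if np.isnan(v).all() else v

        curves.append(GrowthCurve(
            times=sub["time_h"].to_numpy(dtype=float),
            nh4=col("nh4_uM"), no2=col("no2_uM"), no3=col("no3_uM"),
            replicate_id=str(rep),
        ))
    return curves


def read_qpcr_table(path: str | Path) -> tuple[list[tuple[float, float]], list[float]]:
    """Read a qPCR table with columns role(standard|unknown), log10_copies, ct."""
    frame = pd.read_csv(path)
    std = frame[frame["role"] == "standard"]
    unk = frame[frame["role"] == "unknown"]
    standards = [(float(l), float(c)) for l, c in
                 std[["log10_copies", "ct"]].itertuples(index=False)]
    unknowns = [float(c) for c in unk["ct"]]
    return standards, unknowns
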