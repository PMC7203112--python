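"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython, minimal SAM via pysam, BED/CSV via pandas. Interval
coordinates are 0-based half-open (BED convention); the optional GTF export
converts to 1-based inclusive.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif_grammar import ArrangementSpec, Layout, MotifPattern

__all__ = [
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "bed_to_gtf",
    "read_sam_intervals",
    "read_intervals",
    "read_motifs_config",
    "read_titration_csv",
    "write_titration_csv",
    "read_itc_csv",
    "write_itc_csv",
]

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class ParseError(ValueError):
    """Malformed input file."""


# --------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly wrapped) multi-record FASTA into name → sequence.

    Sequences are uppercased; duplicate record names are rejected.
    """
    path = Path(path)
    text = path.read_text()
    if not text.lstrip().startswith(">"):
        raise ParseError(f"{path}: not a FASTA file (line 1 does not start with '>')")
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"{path}: duplicate record name {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ParseError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# --------------------------------------------------------------------------
# BED / GTF / SAM intervals


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3 or BED6; BED3 is filled with name '.', score 0, strand '+'."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ParseError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, :6].copy()
    for i, (col, default) in enumerate(zip(BED6_COLUMNS, [None, None, None, ".", 0, "+"])):
        if i >= df.shape[1]:
            df[i] = default
    df.columns = BED6_COLUMNS[: df.shape[1]]
    for col, default in [("name", "."), ("score", 0), ("strand", "+")]:
        if col not in df.columns:
            df[col] = default
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] < 0).any():
        raise ParseError(f"{path}: negative coordinates")
    if (df["start"] >= df["end"]).any():
        raise ParseError(f"{path}: start >= end")
    return df[BED6_COLUMNS]


def write_bed(records: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED6_COLUMNS if c in records.columns]
    records[cols].to_csv(path, sep="\t", header=False, index=False)


def bed_to_gtf(
    records: pd.DataFrame,
    path: str | Path,
    source: str = "coopbind",
    feature: str = "region",
) -> None:
    """Export BED-convention intervals as GTF (1-based, inclusive)."""
    with open(path, "w") as fh:
        for _, r in records.iterrows():
            name = r.get("name", r.get("class_label", "."))
            attrs = f'gene_id "{name}"; transcript_id "{name}";'
            fh.write(
                "\t".join(
                    [
                        str(r["chrom"]),
                        source,
                        feature,
                        str(int(r["start"]) + 1),
                        str(int(r["end"])),
                        str(r.get("score", 0)),
                        str(r.get("strand", "+")),
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_sam_intervals(path: str | Path) -> pd.DataFrame:
    """Reference intervals of mapped reads from a (headered) SAM text file.

    Only chromosome, position and CIGAR reference length are used.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for read in fh.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            rows.append(
                (
                    read.reference_name,
                    read.reference_start,
                    read.reference_end,
                    read.query_name or ".",
                    0,
                    "-" if read.is_reverse else "+",
                )
            )
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def read_intervals(path: str | Path) -> pd.DataFrame:
    """Read aligned-read intervals from BED (default) or minimal SAM."""
    path = Path(path)
    if path.suffix.lower() == ".sam":
        return read_sam_intervals(path)
    return read_bed(path)


# --------------------------------------------------------------------------
# Configuration


def read_motifs_config(path: str | Path) -> list[ArrangementSpec]:
    """Motif/arrangement definitions from a YAML mapping.

    Format::

        motifs:
          - name: 2xTGAA
            core: TGAA
            layout: direct_repeat
            copies: 2
            spacer_nt: 0
            spacer_fill: C
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    entries = cfg.get("motifs") if isinstance(cfg, dict) else cfg
    if not entries:
        raise ParseError(f"{path}: no motif definitions found")
    specs = []
    for e in entries:
        motif = MotifPattern(e.get("motif_name", e["name"]), e["core"])
        layout = Layout(e.get("layout", "single"))
        default_copies = 1 if layout is Layout.SINGLE else 2
        specs.append(
            ArrangementSpec(
                motif=motif,
                layout=layout,
                copies=int(e.get("copies", default_copies)),
                spacer_nt=int(e.get("spacer_nt", 0)),
                spacer_fill=str(e.get("spacer_fill", "C")),
                name=e["name"],
            )
        )
    return specs


# --------------------------------------------------------------------------
# Titration / ITC tables


def write_titration_csv(series_list, path: str | Path) -> None:
    rows = []
    for s in series_list:
        for dt, y in zip(s.titrant_total, s.signal):
            rows.append((s.replicate_id, s.labeled_total, dt, y))
    pd.DataFrame(rows, columns=["replicate", "labeled_uM", "titrant_uM", "signal"]).to_csv(
        path, index=False
    )


def read_titration_csv(path: str | Path):
    from .binding_models import TitrationSeries

    df = pd.read_csv(path, float_precision="round_trip")
    required = {"replicate", "labeled_uM", "titrant_uM", "signal"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: titration CSV needs columns {sorted(required)}")
    series = []
    for rep, sub in df.groupby("replicate", sort=True):
        labeled = sub["labeled_uM"].unique()
        if len(labeled) != 1:
            raise ParseError(f"{path}: replicate {rep!r} mixes labeled concentrations")
        series.append(
            TitrationSeries(
                float(labeled[0]),
                sub["titrant_uM"].to_numpy(),
                sub["signal"].to_numpy(),
                replicate_id=str(rep),
            )
        )
    return series


def write_itc_csv(exp, path: str | Path) -> None:
    """ITC table: '#key=value' header block then injection rows."""
    with open(path, "w") as fh:
        fh.write(f"#cell_volume_uL={exp.cell_volume}\n")
        fh.write(f"#cell_DNA_uM={exp.cell_DNA}\n")
        fh.write(f"#syringe_protein_uM={exp.syringe_protein}\n")
        fh.write(f"#temperature_C={exp.temperature}\n")
        fh.write("injection_uL,heat_ucal\n")
        for v, q in zip(exp.injection_volumes, exp.heats):
            fh.write(f"{float(v)!r},{float(q)!r}\n")


def read_itc_csv(path: str | Path):
    from .binding_models import ITCExperiment

    header: dict[str, float] = {}
    body_lines = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                header[key.strip()] = float(val)
            else:
                body_lines.append(line)
    required = {"cell_volume_uL", "cell_DNA_uM", "syringe_protein_uM"}
    if not required.issubset(header):
        raise ParseError(f"{path}: ITC header block needs {sorted(required)}")
    df = pd.read_csv(_io.StringIO("\n".join(body_lines)), float_precision="round_trip")
    if not {"injection_uL", "heat_ucal"}.issubset(df.columns):
        raise ParseError(f"{path}: ITC table needs columns injection_uL, heat_ucal")
    return ITCExperiment(
        cell_volume=header["cell_volume_uL"],
        cell_DNA=header["cell_DNA_uM"],
        syringe_protein=header["syringe_protein_uM"],
        injection_volumes=df["injection_uL"].to_numpy(),
        heats=df["heat_ucal"].to_numpy(),
        temperature=header.get("temperature_C", 20.0),
    )
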