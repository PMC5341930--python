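"""Readers and writers for the pipeline's text formats.

All tabular data is TSV.  Writers emit '#'-prefixed metadata header lines
(``# key=value``) carrying the seed, package version and stage parameters,
and format floats at 6 significant digits so outputs are byte-stable across
runs and platforms.  Sequences are FASTA (via Biopython); amplicons and seed
sites use BED (0-based, half-open).  Malformed tabular input is reported with
the offending line number.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .seed_scan import Amplicon, MatureMiRNA, SeedSite, TranscriptRegion
from .synthetic_data import COHORT_COLUMNS, PLATE_COLUMNS, SPOT_COLUMNS

FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# TSV with metadata headers
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, meta: dict | None = None, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"arscreen_version": __version__, **(meta or {})}
    with open(path, "w", newline="\n") as fh:
        for key in sorted(meta):
            fh.write(f"# {key}={meta[key]}\n")
        df.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT, index=index, lineterminator="\n")


def read_tsv(path, required_columns=None) -> tuple[pd.DataFrame, dict]:
    """Read a TSV with '#' metadata headers; returns (frame, metadata)."""
    path = Path(path)
    meta: dict = {}
    lines: list[tuple[int, str]] = []  # (original line number, content)
    with open(path, newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
            else:
                lines.append((lineno, line))
    if not lines:
        raise ValueError(f"{path}: no header line found")
    ncols = len(lines[0][1].rstrip("\r\n").split("\t"))
    for lineno, line in lines[1:]:
        if line.strip() and line.rstrip("\r\n").count("\t") != ncols - 1:
            raise ValueError(f"{path}: line {lineno} has wrong field count")
    try:
        df = pd.read_csv(_io.StringIO("".join(l for _, l in lines)), sep="\t")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV ({exc})") from exc
    if required_columns is not None:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
    return df, meta


def read_spot_table(path) -> tuple[pd.DataFrame, dict]:
    return read_tsv(path, required_columns=SPOT_COLUMNS)


def read_plate_table(path) -> tuple[pd.DataFrame, dict]:
    return read_tsv(path, required_columns=PLATE_COLUMNS)


def read_cohort_table(path) -> tuple[pd.DataFrame, dict]:
    return read_tsv(path, required_columns=COHORT_COLUMNS)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(records: dict[str, str] | list, path) -> None:
    """Write id -> sequence pairs (or MatureMiRNA/TranscriptRegion lists)."""
    if not isinstance(records, dict):
        records = {r.id: r.sequence for r in records}
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ValueError(f"{path}: empty/truncated record {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def read_mirnas(path) -> list[MatureMiRNA]:
    return [MatureMiRNA(id=k, sequence=v) for k, v in read_fasta(path).items()]


def read_regions(path, role: str = "UTR3") -> list[TranscriptRegion]:
    return [
        TranscriptRegion(id=k, sequence=v, role=role)
        for k, v in read_fasta(path).items()
    ]


# ---------------------------------------------------------------------------
# BED (0-based half-open)
# ---------------------------------------------------------------------------

def write_amplicons_bed(amplicons: list[Amplicon], path, chrom: str) -> None:
    rows = [
        f"{chrom}\t{a.start - 1}\t{a.end}\t{a.name}" for a in amplicons
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("".join(r + "\n" for r in rows))


def read_amplicons_bed(path) -> list[Amplicon]:
    amps = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}: line {i}: need >= 4 BED fields")
        _, start, end, name = fields[:4]
        amps.append(Amplicon(name=name, start=int(start) + 1, end=int(end)))
    return amps


def write_sites_bed(sites: list[SeedSite], path) -> None:
    """Sites as BED6: chrom=region, name=mirna|type, score=0, strand=+."""
    rows = [
        f"{s.region_id}\t{s.start - 1}\t{s.end}\t{s.mirna_id}|{s.site_type}\t0\t+"
        for s in sites
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("".join(r + "\n" for r in rows))


def read_sites_bed(path) -> list[dict]:
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"{path}: line {i}: need 6 BED fields")
        chrom, start, end, name, _score, strand = fields[:6]
        mirna_id, site_type = name.rsplit("|", 1)
        out.append(
            {
                "region_id": chrom,
                "start": int(start) + 1,
                "end": int(end),
                "mirna_id": mirna_id,
                "site_type": site_type,
                "strand": strand,
            }
        )
    return out


# ---------------------------------------------------------------------------
# checksums / manifest
# ---------------------------------------------------------------------------

def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, files: list[str], params: dict, path_name="manifest.json") -> dict:
    outdir = Path(outdir)
    manifest = {
        "arscreen_version": __version__,
        "parameters": params,
        "files": {f: sha256_of(outdir / f) for f in sorted(files)},
    }
    (outdir / path_name).write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
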