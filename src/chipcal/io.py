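"""Readers and writers for the text formats the pipeline consumes.

Dialects
--------
peaks       BED3/BED5 (score in column 5) or ENCODE narrowPeak (score from
            column 7 ``signalValue`` by default, or column 8 ``-log10 p``).
gene models BED12, or a minimal GTF subset (gene/transcript/exon features).
tracks      bedGraph (chrom, start, end, value).
sequence    FASTA via Biopython.
tables      CSV with a header row, via pandas.

Chromosome names are matched exactly — no "chr" aliasing — so an input
mix-up fails loudly instead of silently producing empty overlaps.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GeneModel, GenomicInterval, SignalTrack


class FormatError(ValueError):
    """A malformed input line; the message names the file and line number."""


def _err(path, lineno: int, msg: str) -> FormatError:
    return FormatError(f"{path}, line {lineno}: {msg}")


# ---------------------------------------------------------------------------
# peaks


def read_peaks(
    path,
    dialect: Literal["bed", "narrowPeak"] = "bed",
    narrowpeak_score: Literal["signal", "neglog10p"] = "signal",
) -> list[GenomicInterval]:
    """Read peak calls from BED or narrowPeak.

    ``narrowpeak_score`` selects the score source for narrowPeak input:
    column 7 (signalValue, the default) or column 8 (−log10 p-value).
    """
    peaks: list[GenomicInterval] = []
    min_cols = 10 if dialect == "narrowPeak" else 3
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise _err(path, lineno, f"expected >= {min_cols} columns, got {len(fields)}")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError:
                raise _err(path, lineno, "non-integer coordinates") from None
            name = fields[3] if len(fields) > 3 else ""
            score: float | None = None
            strand = "."
            try:
                if dialect == "narrowPeak":
                    col = 6 if narrowpeak_score == "signal" else 7
                    score = float(fields[col])
                    strand = fields[5] if fields[5] in ("+", "-") else "."
                elif len(fields) > 4 and fields[4] not in (".", ""):
                    score = float(fields[4])
            except ValueError:
                raise _err(path, lineno, "non-numeric score") from None
            if len(fields) > 5 and dialect == "bed" and fields[5] in ("+", "-"):
                strand = fields[5]
            try:
                peaks.append(GenomicInterval(chrom, start, end, strand, score, name))
            except ValueError as exc:
                raise _err(path, lineno, str(exc)) from None
    return peaks


def write_peaks(path, peaks: Iterable[GenomicInterval]) -> None:
    """Write peaks as BED5 (name '.', score 0 when absent)."""
    with open(path, "w") as fh:
        for p in peaks:
            score = 0.0 if p.score is None else p.score
            name = p.name or "."
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{score:g}\n")


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(
    path, dialect: Literal["bed12", "gtf_min"] = "bed12"
) -> list[GeneModel]:
    if dialect == "bed12":
        return _read_bed12(path)
    if dialect == "gtf_min":
        return _read_gtf_min(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_bed12(path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise _err(path, lineno, f"BED12 requires 12 columns, got {len(f)}")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            if strand not in ("+", "-"):
                raise _err(path, lineno, f"missing or invalid strand {strand!r}")
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise _err(path, lineno, "blockCount does not match block lists")
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            gene_id = name.split("|")[0]
            tx_id = name.split("|")[1] if "|" in name else name
            try:
                gm = GeneModel(gene_id, tx_id, chrom, strand, exons)
            except ValueError as exc:
                raise _err(path, lineno, str(exc)) from None
            lo, hi = gm.span
            if lo != start or hi != end:
                raise _err(path, lineno, "blocks do not span chromStart..chromEnd")
            models.append(gm)
    return models


def _read_gtf_min(path) -> list[GeneModel]:
    """Minimal GTF: exon features grouped by transcript_id, strand required."""
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise _err(path, lineno, "GTF requires 9 columns")
            chrom, _, feature, start1, end1, _, strand, _, attrs = f[:9]
            if feature != "exon":
                continue
            if strand not in ("+", "-"):
                raise _err(path, lineno, f"missing or invalid strand {strand!r}")
            attr = _parse_gtf_attrs(attrs)
            tx = attr.get("transcript_id")
            if not tx:
                raise _err(path, lineno, "exon without transcript_id")
            rec = exons.setdefault(
                tx, {"chrom": chrom, "strand": strand,
                     "gene_id": attr.get("gene_id", tx), "exons": []}
            )
            # GTF is 1-based closed; convert at the boundary
            rec["exons"].append((int(start1) - 1, int(end1)))
    models = []
    for tx, rec in sorted(exons.items()):
        try:
            models.append(
                GeneModel(rec["gene_id"], tx, rec["chrom"], rec["strand"],
                          tuple(sorted(rec["exons"])))
            )
        except ValueError as exc:
            raise FormatError(f"{path}: transcript {tx}: {exc}") from None
    return models


def _parse_gtf_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def write_gene_models(path, models: Iterable[GeneModel]) -> None:
    """Write gene models as BED12 with name ``gene_id|transcript_id``."""
    with open(path, "w") as fh:
        for m in models:
            lo, hi = m.span
            sizes = ",".join(str(e - s) for s, e in m.exons)
            offsets = ",".join(str(s - lo) for s, _ in m.exons)
            fh.write(
                f"{m.chrom}\t{lo}\t{hi}\t{m.gene_id}|{m.transcript_id}\t0\t"
                f"{m.strand}\t{lo}\t{hi}\t0\t{len(m.exons)}\t{sizes}\t{offsets}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph tracks


def read_track(path) -> SignalTrack:
    track = SignalTrack()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise _err(path, lineno, "bedGraph requires 4 columns")
            try:
                track.add(f[0], int(f[1]), int(f[2]), float(f[3]), _validate=False)
            except ValueError as exc:
                raise _err(path, lineno, str(exc)) from None
    track._sort_and_validate()
    return track


def write_track(path, track: SignalTrack) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, v in track.iter_segments():
            fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, seqs: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# CSV tables

CT_COLUMNS = ["sample_id", "antibody", "amplicon", "replicate", "ct"]
TRACE_COLUMNS = ["time_s", "cell_id", "condition", "raw", "background"]


def read_ct_table(path) -> pd.DataFrame:
    """qPCR Ct table: sample_id, antibody, amplicon, replicate, ct."""
    df = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if not (df["ct"] > 0).all() or not df["ct"].apply(pd.api.types.is_number).all():
        raise FormatError(f"{path}: Ct values must be positive and finite")
    return df


def write_ct_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, columns=CT_COLUMNS, quoting=csv.QUOTE_MINIMAL)


def read_trace_table(path) -> pd.DataFrame:
    """Per-cell fluorescence table: time_s, cell_id, condition, raw, background."""
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def write_trace_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, columns=TRACE_COLUMNS)
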