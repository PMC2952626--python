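"""Sequence and annotation I/O.

Reads chromosome FASTA files, locates assembly gaps (N-runs) and splits
chromosomes into contigs at gaps whose length exceeds a fraction of the
chromosome; parses gene tables (TSV or GFF3) and RepeatMasker ``.out``
files; writes segment tables as TSV and BED.

Coordinate conventions: everything in memory is 0-based half-open.
User-facing TSV tables are 1-based inclusive (``length = stop - start + 1``);
BED exports are 0-based half-open per the BED standard.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from lhgr.errors import FormatError

# Any IUPAC code other than the four unambiguous bases collapses to N:
# ambiguity codes carry no composition information usable by the
# windowless statistics, and assembly gaps are already N.
_VALID = set(b"ACGTN")
_NORMALIZE = bytes(
    (c if c in _VALID else ord("N")) if chr(c).isalpha() else c
    for c in (bytes(range(256)).upper())
)


@dataclass(frozen=True)
class GenomeSequence:
    """A normalized chromosome sequence (uppercase A/C/G/T/N only)."""

    chrom_id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Contig:
    """A gap-delimited piece of a chromosome.

    ``offset`` is the 0-based start of the contig on its chromosome, so
    segment coordinates computed on the contig translate back to
    chromosomal coordinates by addition.
    """

    chrom_id: str
    offset: int
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def end(self) -> int:
        return self.offset + len(self.residues)


@dataclass
class GapTrack:
    """Maximal N-runs of a chromosome, 0-based half-open, sorted."""

    chrom_id: str
    gaps: list[tuple[int, int]] = field(default_factory=list)

    def lengths(self) -> list[int]:
        return [e - s for s, e in self.gaps]


def normalize_residues(residues: str) -> str:
    """Uppercase and map every non-ACGT letter to N."""
    return residues.encode("ascii").translate(_NORMALIZE).decode("ascii")


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into normalized :class:`GenomeSequence` records.

    Lowercase (soft-masked) residues are uppercased; IUPAC ambiguity
    codes other than A/C/G/T become N.  An empty sequence or a record
    with an empty identifier raises :class:`FormatError` naming the
    offending record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        seq = normalize_residues(str(rec.seq))
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(GenomeSequence(chrom_id=rec.id, residues=seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: Iterable[GenomeSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.chrom_id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def find_gaps(residues: str) -> list[tuple[int, int]]:
    """Locate maximal N-runs by a single linear scan (0-based half-open)."""
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    is_n = arr == ord("N")
    if not is_n.any():
        return []
    # run boundaries: transitions of the N mask
    d = np.diff(is_n.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if is_n[0]:
        starts = np.concatenate(([0], starts))
    if is_n[-1]:
        ends = np.concatenate((ends, [len(arr)]))
    return list(zip(starts.tolist(), ends.tolist()))


def split_into_contigs(
    seq: GenomeSequence, fraction_threshold: float = 0.01
) -> tuple[GapTrack, list[Contig]]:
    """Split a chromosome into contigs at large assembly gaps.

    A gap splits the sequence when its length is at least
    ``fraction_threshold`` times the chromosome length (default 1%).
    Shorter N-runs stay inside contigs: they keep their coordinates but
    are excluded later from all base-frequency computations.

    Returns the full gap track (all N-runs, large and small) and the
    list of contigs.  An all-N chromosome yields an empty contig list.
    """
    if not 0 < fraction_threshold <= 1:
        raise ValueError(f"fraction_threshold must be in (0, 1], got {fraction_threshold}")
    gaps = find_gaps(seq.residues)
    track = GapTrack(chrom_id=seq.chrom_id, gaps=gaps)
    cutoff = fraction_threshold * seq.length
    splitting = [(s, e) for s, e in gaps if (e - s) >= cutoff]
    contigs: list[Contig] = []
    pos = 0
    for s, e in splitting:
        if s > pos:
            contigs.append(Contig(seq.chrom_id, pos, seq.residues[pos:s]))
        pos = e
    if pos < seq.length:
        contigs.append(Contig(seq.chrom_id, pos, seq.residues[pos:]))
    # drop contigs that are pure N (can arise between adjacent large gaps)
    contigs = [c for c in contigs if c.residues.strip("N")]
    return track, contigs


# ---------------------------------------------------------------------------
# gene tables

_GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "cds"]


def read_gene_table(path: str | Path, fmt: str = "tsv") -> pd.DataFrame:
    """Read gene annotations.

    ``fmt='tsv'`` expects a tab-separated table with a header row and the
    columns ``gene_id, chrom, start, end, strand, cds`` (1-based inclusive
    coordinates, CDS concatenated in reading frame) — the dialect of a
    typical BioMart export.  ``fmt='gff3'`` accepts a GFF3 file and
    returns gene records without CDS sequences (CDS-dependent statistics
    such as GC3 are then unavailable).
    """
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        missing = [c for c in _GENE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: gene table missing columns {missing}")
        bad = df[df["start"] > df["end"]]
        if len(bad):
            raise FormatError(
                f"{path}: gene {bad.iloc[0]['gene_id']!r} has start > end"
            )
        return df[_GENE_COLUMNS].copy()
    if fmt == "gff3":
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 9:
                    raise FormatError(f"{path}: malformed GFF3 line: {line.strip()!r}")
                if parts[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                rows.append(
                    {
                        "gene_id": attrs.get("ID", f"{parts[0]}:{parts[3]}-{parts[4]}"),
                        "chrom": parts[0],
                        "start": int(parts[3]),
                        "end": int(parts[4]),
                        "strand": parts[6],
                        "cds": "",
                    }
                )
        return pd.DataFrame(rows, columns=_GENE_COLUMNS)
    raise ValueError(f"unknown gene table format: {fmt!r}")


def write_gene_table(genes: pd.DataFrame, path: str | Path) -> None:
    genes[_GENE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# RepeatMasker .out

_RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def read_repeatmasker_out(path: str | Path) -> pd.DataFrame:
    """Parse a RepeatMasker ``.out`` annotation file.

    The standard layout has two header lines plus a blank line, then one
    whitespace-delimited alignment row per repeat.  Coordinates are kept
    1-based inclusive as in the format.  Returns a DataFrame with columns
    ``chrom, start, end, repeat_name, repeat_class``; filtering (e.g. to
    LINE classes) is a separate downstream step.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3 or not line.strip():
                continue
            parts = line.split()
            if len(parts) < 11:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 11 whitespace-delimited "
                    f"columns, got {len(parts)}"
                )
            try:
                start, end = int(parts[5]), int(parts[6])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start > end:
                raise FormatError(f"{path}:{lineno}: start > end")
            rows.append(
                {
                    "chrom": parts[4],
                    "start": start,
                    "end": end,
                    "repeat_name": parts[9],
                    "repeat_class": parts[10],
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "repeat_name", "repeat_class"]
    )


def write_repeatmasker_out(repeats: pd.DataFrame, path: str | Path) -> None:
    """Write repeat records in the RepeatMasker ``.out`` dialect parsed above."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, row in enumerate(repeats.itertuples(index=False), start=1):
            fh.write(
                f"  239 12.5  0.0  0.0  {row.chrom} {row.start} {row.end} "
                f"(0) + {row.repeat_name} {row.repeat_class} 1 "
                f"{row.end - row.start + 1} (0) {i}\n"
            )


# ---------------------------------------------------------------------------
# segment tables

SEGMENT_COLUMNS = [
    "chrom",
    "start",
    "stop",
    "length",
    "gc",
    "family",
    "gc_type",
    "h",
    "klass",
    "delta_gc",
]


def write_segments_tsv(segments: pd.DataFrame, path: str | Path) -> None:
    """Write a classified segment table (1-based inclusive coordinates)."""
    segments.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def read_segments_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA", dtype={"chrom": str})


def write_segments_bed(segments: pd.DataFrame, path: str | Path) -> None:
    """Write segments as BED (0-based half-open); name = family, score = h*1000."""
    bed = pd.DataFrame(
        {
            "chrom": segments["chrom"],
            "start": segments["start"] - 1,
            "end": segments["stop"],
            "name": segments.get("family", pd.Series(["."] * len(segments))),
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 3+ column BED file (0-based half-open intervals)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        dtype={0: str},
    )
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED requires at least 3 columns")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "name"})
    return df
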