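"""Readers and writers for the text formats the pipeline touches.

BED3/BED6, ENCODE narrowPeak, bedGraph, FASTA and the MEME minimal
motif format. All coordinates are kept 0-based half-open.
"""
from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import Interval, PeakCall
from .tracks import CoverageTrack


class ParseError(ValueError):
    """Malformed input file; message names the file and line."""


def _fields(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


def read_bed(path: str | os.PathLike) -> list[Interval]:
    """Read BED3/BED6 into intervals; strand defaults to '+' when absent."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _fields(line)
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns, got {len(f)}")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start ({start}) >= end ({end})")
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 and f[4] not in (".", "") else 0.0
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "+"
            out.append(Interval(f[0], start, end, name=name, score=score, strand=strand))
    return out


def write_bed(intervals: Iterable[Interval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n")


def read_narrowpeak(path: str | os.PathLike) -> list[PeakCall]:
    """Read ENCODE narrowPeak (BED6+4); column 10 is the summit offset.

    A summit offset of -1 (MACS2 "no summit") falls back to the
    interval midpoint, rounded down.
    """
    peaks: list[PeakCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _fields(line)
            if len(f) != 10:
                raise ParseError(f"{path}:{lineno}: narrowPeak requires 10 columns, got {len(f)}")
            try:
                start, end, offset = int(f[1]), int(f[2]), int(f[9])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            if offset == -1:
                summit = start + (end - start) // 2
            else:
                if not (0 <= offset < end - start):
                    raise ParseError(
                        f"{path}:{lineno}: summit offset {offset} outside peak of "
                        f"length {end - start}"
                    )
                summit = start + offset
            score = float(f[6]) if f[6] not in (".", "") else 0.0
            peaks.append(PeakCall(f[0], start, end, summit=summit, score=score))
    return peaks


def read_coverage(
    path: str | os.PathLike,
    kind: str,
    name: str | None = None,
    library_size: int | None = None,
) -> CoverageTrack:
    """Read a coverage track from bedGraph or fragment-interval BED.

    For ``fragment_bed`` the library size is the fragment count; for
    ``bedgraph`` it cannot be inferred and must be supplied when RPM or
    RPKM normalization will be requested.
    """
    name = name or os.path.splitext(os.path.basename(os.fspath(path)))[0]
    if kind == "fragment_bed":
        frags: dict[str, list[tuple[int, int]]] = {}
        for iv in read_bed(path):
            frags.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return CoverageTrack.from_fragments(name, frags)
    if kind == "bedgraph":
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = _fields(line)
                if len(f) < 4:
                    raise ParseError(f"{path}:{lineno}: bedGraph requires 4 columns")
                try:
                    start, end, value = int(f[1]), int(f[2]), float(f[3])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: malformed bedGraph line") from exc
                if start >= end:
                    raise ParseError(f"{path}:{lineno}: start >= end")
                per_chrom.setdefault(f[0], []).append((start, end, value))
        arrays = {
            chrom: (
                np.array([r[0] for r in rows]),
                np.array([r[1] for r in rows]),
                np.array([r[2] for r in rows]),
            )
            for chrom, rows in per_chrom.items()
        }
        return CoverageTrack.from_bedgraph_arrays(name, arrays, library_size=library_size)
    raise ValueError(f"unknown coverage kind {kind!r}")


def write_bedgraph(track: CoverageTrack, path: str | os.PathLike) -> None:
    if track.kind != "bedgraph":
        raise TypeError("write_bedgraph requires a bedgraph track")
    with open(path, "w") as fh:
        for chrom in track.chromosomes:
            starts, ends, values = track.data[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:g}\n")


def write_fragment_bed(track: CoverageTrack, path: str | os.PathLike) -> None:
    if track.kind != "fragments":
        raise TypeError("write_fragment_bed requires a fragment track")
    with open(path, "w") as fh:
        for chrom in track.chromosomes:
            starts, ends = track.data[chrom]
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read FASTA into an id -> upper-case sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"{path}: duplicate sequence id {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq.upper()), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, os.fspath(path), "fasta")


def write_meme(pwms: Sequence, path: str | os.PathLike, alphabet: str = "ACGT") -> None:
    """Write position probability matrices in MEME minimal motif format v4.

    Each element of ``pwms`` must expose ``name``, ``matrix`` (w x 4,
    rows summing to 1 within 1e-9) and ``nsites``. Probabilities are
    printed with 6 decimals.
    """
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write(f"ALPHABET= {alphabet}\n\n")
        fh.write("strands: +\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pwm in pwms:
            mat = np.asarray(pwm.matrix, dtype=float)
            if mat.ndim != 2 or mat.shape[1] != 4:
                raise ValueError(f"motif {pwm.name}: matrix must be w x 4")
            sums = mat.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise ValueError(
                    f"motif {pwm.name}: row {bad} sums to {sums[bad]:.6g}, expected 1"
                )
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {mat.shape[0]} "
                f"nsites= {int(pwm.nsites)} E= 0\n"
            )
            for row in mat:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def write_tsv(df, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
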