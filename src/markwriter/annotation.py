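"""Gene annotation and peak-call containers.

All coordinates are 0-based half-open (BED convention). 1-based inputs
must be converted at the boundary before constructing these objects.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator


@dataclass(frozen=True)
class GeneModel:
    """A transcribed feature: coordinates, strand and biotype."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Base coordinate of the transcription start site (first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """Base coordinate of the transcription termination site (last transcribed base)."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class GenomeAnnotation:
    """A set of gene models plus chromosome sizes.

    Invariants checked at construction: unique gene ids, every gene
    within its chromosome bounds.
    """

    records: list[GeneModel]
    chromosome_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.records:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            if self.chromosome_sizes:
                size = self.chromosome_sizes.get(g.chrom)
                if size is None:
                    raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
                if g.start < 0 or g.end > size:
                    raise ValueError(
                        f"gene {g.gene_id} [{g.start},{g.end}) outside chromosome "
                        f"{g.chrom} of length {size}"
                    )

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self, gene_id: str) -> GeneModel:
        for g in self.records:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def chrom_length(self, chrom: str) -> int | None:
        return self.chromosome_sizes.get(chrom)


@dataclass(frozen=True)
class PeakCall:
    """A called peak with its summit (absolute 0-based coordinate)."""

    chrom: str
    start: int
    end: int
    summit: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"peak {self.chrom}:[{self.start},{self.end}): summit {self.summit} "
                "must satisfy start <= summit < end"
            )


@dataclass(frozen=True)
class Interval:
    """A plain BED interval."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"interval [{self.start},{self.end}) is empty or inverted")
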