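"""Coverage tracks: fragment-interval and piecewise-constant (bedGraph) signal.

A fragment track stores mapped fragments per chromosome and answers
"how many fragments overlap this interval by at least 1 bp"; a bedGraph
track stores a piecewise-constant signal and answers the signal area
over an interval. Both support RPM/RPKM through a library size, which
for bedGraph input cannot be inferred and must be supplied.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class CoverageTrack:
    name: str
    kind: str  # "fragments" | "bedgraph"
    # per chromosome: fragments -> (starts, ends) as parallel arrays;
    # bedgraph -> (starts, ends, values), sorted, non-overlapping
    data: dict[str, tuple[np.ndarray, ...]] = field(default_factory=dict)
    library_size: int | None = None
    # starts sorted / ends sorted independently, cached for counting
    _sorted: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("fragments", "bedgraph"):
            raise ValueError(f"unknown track kind {self.kind!r}")
        if self.kind == "fragments" and self.library_size is None:
            self.library_size = sum(len(s) for s, _ in self.data.values())
        for chrom, arrs in self.data.items():
            self.data[chrom] = tuple(np.asarray(a) for a in arrs)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_fragments(
        cls, name: str, fragments: dict[str, list[tuple[int, int]]] | dict[str, np.ndarray]
    ) -> "CoverageTrack":
        data = {}
        for chrom, frags in fragments.items():
            arr = np.asarray(list(frags), dtype=np.int64).reshape(-1, 2)
            data[chrom] = (arr[:, 0].copy(), arr[:, 1].copy())
        return cls(name=name, kind="fragments", data=data)

    @classmethod
    def from_bedgraph_arrays(
        cls,
        name: str,
        per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        library_size: int | None = None,
    ) -> "CoverageTrack":
        data = {}
        for chrom, (starts, ends, values) in per_chrom.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends[:-1] > starts[1:]):
                raise ValueError(f"overlapping bedGraph intervals on {chrom}")
            data[chrom] = (starts, ends, values)
        return cls(name=name, kind="bedgraph", data=data, library_size=library_size)

    # -- queries --------------------------------------------------------------

    def _warn_unknown(self, chrom: str) -> None:
        logger.warning("track %s: query on unknown chromosome %s returns 0", self.name, chrom)

    def count(self, chrom: str, start: int, end: int) -> int:
        """Number of fragments overlapping [start, end) by >= 1 bp."""
        if self.kind != "fragments":
            raise TypeError("count() requires a fragment track")
        if chrom not in self.data:
            self._warn_unknown(chrom)
            return 0
        if end <= start:
            return 0
        if chrom not in self._sorted:
            s, e = self.data[chrom]
            self._sorted[chrom] = (np.sort(s), np.sort(e))
        ss, es = self._sorted[chrom]
        n = len(ss)
        # a fragment [s,e) overlaps iff s < end and e > start; the two
        # excluded sets (s >= end) and (e <= start) are disjoint
        n_right = n - np.searchsorted(ss, end, side="left")
        n_left = np.searchsorted(es, start, side="right")
        return int(n - n_right - n_left)

    def area(self, chrom: str, start: int, end: int) -> float:
        """Signal integrated over [start, end) (bedGraph value x bp)."""
        if self.kind != "bedgraph":
            raise TypeError("area() requires a bedgraph track")
        if chrom not in self.data:
            self._warn_unknown(chrom)
            return 0.0
        starts, ends, values = self.data[chrom]
        ov = np.minimum(ends, end) - np.maximum(starts, start)
        ov = np.clip(ov, 0, None)
        return float(np.dot(ov, values))

    def signal(self, chrom: str, start: int, end: int) -> float:
        """Raw signal over a region: fragment count or bedGraph area."""
        if self.kind == "fragments":
            return float(self.count(chrom, start, end))
        return self.area(chrom, start, end)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.data)

    def n_fragments(self, chrom: str) -> int:
        if self.kind != "fragments" or chrom not in self.data:
            return 0
        return len(self.data[chrom][0])


def extend_reads(
    reads: list[tuple[str, int, int, str]],
    fragment_length: int = 250,
    chromosome_sizes: dict[str, int] | None = None,
) -> dict[str, list[tuple[int, int]]]:
    """Extend single-end reads to fragment length in the 3' direction.

    A + strand read [s, e) becomes [s, s+L); a - strand read becomes
    [e-L, e). Fragments are clipped to chromosome bounds when sizes are
    given, and to 0 on the left always.
    """
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, strand in reads:
        if strand == "+":
            s, e = start, start + fragment_length
        else:
            s, e = end - fragment_length, end
        s = max(s, 0)
        if chromosome_sizes is not None and chrom in chromosome_sizes:
            e = min(e, chromosome_sizes[chrom])
        out.setdefault(chrom, []).append((s, e))
    return out
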