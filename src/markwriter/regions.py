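"""Strand-aware anchor regions and peak-summit geometry.

An enzyme's canonical occupancy region is read off the distribution of
peak summits around gene anchors (TSS, TTS, or an enhancer midpoint):
the named region specs below (e.g. TSS region = 150 bp upstream to
300 bp downstream of the TSS) capture where each writer typically sits.

Coordinate conventions: regions are built from the gene-boundary
coordinate of the anchor (TSS -> start on +, end on -; TTS symmetric)
and extend upstream/downstream in the gene's reading direction, so a
spec of (up, down) always yields an up+down bp interval before
clipping. Summit distances are measured from the anchor *base*
(TSS base = end-1 on the - strand) and signed so that positive means
downstream in the reading direction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import GeneModel, GenomeAnnotation, PeakCall


@dataclass(frozen=True)
class RegionSpec:
    """A named, anchor-relative interval in reading-direction coordinates.

    ``upstream`` may be negative to describe a window that starts
    downstream of the anchor (e.g. the TSS2 region, +200..+600).
    """

    anchor: str  # "TSS" | "TTS" | "enhancer_center"
    upstream: int
    downstream: int
    name: str

    def __post_init__(self) -> None:
        if self.anchor not in ("TSS", "TTS", "enhancer_center"):
            raise ValueError(f"unknown anchor {self.anchor!r}")
        if self.upstream + self.downstream < 0:
            raise ValueError(f"spec {self.name}: upstream+downstream must be >= 0")


#: Region definitions for the occupancy regions of the H3K4 writers
#: studied here: TSS region (ATX1/2), TTS region (ATXR7), TSS region 2
#: (ATXR3) and the mouse enhancer region (MLL3/4).
DEFAULT_SPECS: dict[str, RegionSpec] = {
    "TSS_region": RegionSpec("TSS", 150, 300, "TSS_region"),
    "TTS_region": RegionSpec("TTS", 200, 200, "TTS_region"),
    "TSS_region2": RegionSpec("TSS", -200, 600, "TSS_region2"),
    "enhancer_region": RegionSpec("enhancer_center", 900, 900, "enhancer_region"),
}


@dataclass(frozen=True)
class AnchorRegion:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    spec_name: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _anchor_boundary(gene: GeneModel, anchor: str) -> int:
    """Half-open boundary coordinate of the anchor."""
    if anchor == "TSS":
        return gene.start if gene.strand == "+" else gene.end
    if anchor == "TTS":
        return gene.end if gene.strand == "+" else gene.start
    if anchor == "enhancer_center":
        return (gene.start + gene.end) // 2
    raise ValueError(anchor)


def anchor_base(gene: GeneModel, anchor: str) -> int:
    """Base coordinate of the anchor (used for summit distances)."""
    if anchor == "TSS":
        return gene.tss
    if anchor == "TTS":
        return gene.tts
    if anchor == "enhancer_center":
        return (gene.start + gene.end) // 2
    raise ValueError(anchor)


def make_anchor_region(
    gene: GeneModel,
    spec: RegionSpec,
    chromosome_sizes: dict[str, int] | None = None,
) -> AnchorRegion:
    """Build the strand-aware interval of ``spec`` around ``gene``'s anchor.

    Clipped to [0, chromosome length) when sizes are known; an unknown
    chromosome (when sizes are given) is an error.
    """
    if chromosome_sizes is not None and gene.chrom not in chromosome_sizes:
        raise KeyError(f"gene {gene.gene_id}: unknown chromosome {gene.chrom}")
    b = _anchor_boundary(gene, spec.anchor)
    if gene.strand == "+":
        start, end = b - spec.upstream, b + spec.downstream
    else:
        start, end = b - spec.downstream, b + spec.upstream
    start = max(start, 0)
    if chromosome_sizes is not None:
        end = min(end, chromosome_sizes[gene.chrom])
    end = max(end, start)
    return AnchorRegion(gene.gene_id, gene.chrom, start, end, gene.strand, spec.name)


def summit_distances(
    peaks: list[PeakCall], genes: GenomeAnnotation, anchor: str = "TSS"
) -> list[int]:
    """Signed distance of each peak summit to its nearest gene anchor.

    The nearest anchor is found regardless of strand; the distance is
    then signed by that gene's strand (positive = downstream of the
    anchor in the gene's reading direction).
    """
    if len(genes) == 0:
        raise ValueError("empty annotation")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, gs in by_chrom.items():
        pos = np.array([anchor_base(g, anchor) for g in gs])
        sign = np.array([1 if g.strand == "+" else -1 for g in gs])
        anchors[chrom] = (pos, sign)
    all_pos = np.concatenate([anchors[c][0] for c in anchors])
    all_sign = np.concatenate([anchors[c][1] for c in anchors])
    all_chrom = np.concatenate(
        [np.full(len(anchors[c][0]), c, dtype=object) for c in anchors]
    )
    out: list[int] = []
    for p in peaks:
        if p.chrom in anchors:
            pos, sign = anchors[p.chrom]
            i = int(np.argmin(np.abs(pos - p.summit)))
            out.append(int((p.summit - pos[i]) * sign[i]))
        else:
            # no gene on this chromosome: fall back to global nearest
            i = int(np.argmin(np.where(all_chrom == p.chrom, np.abs(all_pos - p.summit), np.inf)))
            if not np.isfinite(np.abs(all_pos[i] - p.summit)):
                continue
            out.append(int((p.summit - all_pos[i]) * all_sign[i]))
    return out


@dataclass
class SummitHistogram:
    bin_edges: np.ndarray  # signed bp offsets, len = n_bins + 1
    counts: np.ndarray
    anchor: str

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "offset_start": self.bin_edges[:-1].astype(int),
                "offset_end": self.bin_edges[1:].astype(int),
                "count": self.counts.astype(int),
            }
        )


def histogram_summits(
    distances: list[int], window: int, bin_width: int, anchor: str = "TSS"
) -> SummitHistogram:
    """Histogram of summit distances over [-window, +window) half-open bins.

    Distances at or beyond +window (or below -window) are discarded.
    """
    if window <= 0 or bin_width <= 0:
        raise ValueError("window and bin_width must be positive")
    if bin_width > 2 * window:
        raise ValueError("bin_width exceeds the full window")
    edges = np.arange(-window, window + bin_width, bin_width)
    edges = edges[edges <= window]
    if edges[-1] < window:
        edges = np.append(edges, window)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for d in distances:
        if -window <= d < window:
            i = int(np.searchsorted(edges, d, side="right")) - 1
            counts[i] += 1
    return SummitHistogram(bin_edges=edges, counts=counts, anchor=anchor)


def assign_peaks_to_genes(
    peaks: list[PeakCall], genes: GenomeAnnotation
) -> tuple[dict[int, set[str]], list[str]]:
    """Assign peaks to genes by >= 1 bp overlap.

    Returns (peak index -> set of overlapping gene ids, derived gene
    list). A peak over several genes keeps all of them; a gene hit by
    several peaks appears once in the derived list, which preserves
    annotation order.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    assignment: dict[int, set[str]] = {}
    hit: set[str] = set()
    for i, p in enumerate(peaks):
        ids = {
            g.gene_id
            for g in by_chrom.get(p.chrom, [])
            if p.start < g.end and g.start < p.end
        }
        assignment[i] = ids
        hit |= ids
    gene_list = [g.gene_id for g in genes if g.gene_id in hit]
    return assignment, gene_list
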