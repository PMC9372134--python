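"""Quantify coverage tracks over per-gene sub-regions into a feature table.

Each gene passing the length filter is split into its anchor regions
(TSS region, TTS region, and for the 4-region scheme the TSS2 region)
plus the gene body (transcribed interval minus the intra-genic parts of
the anchor regions). Anchor regions contribute one RPM column per
track; the gene body contributes both an RPM and a length-normalized
RPKM column, since body signal of gene-body marks scales with gene
length while 5'-biased marks do not. Expression (mean FPKM over
replicates) and gene length are appended as scalar predictors.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomeAnnotation
from .regions import DEFAULT_SPECS, AnchorRegion, RegionSpec, make_anchor_region
from .tracks import CoverageTrack

logger = logging.getLogger(__name__)

SCHEMES = {
    "3region": {"anchors": ["TSS_region", "TTS_region"], "body": "gene_body", "min_length": 500},
    "4region": {
        "anchors": ["TSS_region", "TSS_region2", "TTS_region"],
        "body": "gene_body2",
        "min_length": 800,
    },
}


def quantify(
    track: CoverageTrack,
    region: AnchorRegion,
    normalization: str = "raw",
    library_size: int | None = None,
) -> float:
    """Signal of ``track`` over ``region`` under the given normalization.

    raw = fragments overlapping the region by >= 1 bp (or bedGraph
    area); RPM = raw * 1e6 / library size; RPKM = RPM * 1e3 / length.
    """
    raw = track.signal(region.chrom, region.start, region.end)
    if normalization == "raw":
        return raw
    lib = library_size if library_size is not None else track.library_size
    if lib is None or lib <= 0:
        raise ValueError(f"track {track.name}: library size required for {normalization}")
    rpm = raw * 1e6 / lib
    if normalization == "RPM":
        return rpm
    if normalization == "RPKM":
        if region.length == 0:
            raise ValueError(f"RPKM undefined on empty region {region.spec_name}")
        return rpm * 1e3 / region.length
    raise ValueError(f"unknown normalization {normalization!r}")


def _subtract(interval: tuple[int, int], cuts: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Interval minus a union of intervals, as sorted disjoint pieces."""
    pieces = [interval]
    for cs, ce in cuts:
        nxt: list[tuple[int, int]] = []
        for s, e in pieces:
            a, b = max(s, cs), min(e, ce)
            if a >= b:
                nxt.append((s, e))
                continue
            if s < a:
                nxt.append((s, a))
            if b < e:
                nxt.append((b, e))
        pieces = nxt
    return sorted(pieces)


@dataclass
class GeneRegions:
    """The per-gene sub-regions of one splitting scheme."""

    gene: GeneModel
    anchors: dict[str, AnchorRegion]
    body_name: str
    body_pieces: list[tuple[int, int]]

    @property
    def body_length(self) -> int:
        return sum(e - s for s, e in self.body_pieces)


def split_gene(
    gene: GeneModel,
    scheme: str = "3region",
    specs: Mapping[str, RegionSpec] = DEFAULT_SPECS,
    chromosome_sizes: dict[str, int] | None = None,
    min_length: int | None = None,
) -> GeneRegions | None:
    """Split a gene into anchor regions + gene body; None if too short.

    The body is the transcribed interval minus the intra-genic parts of
    the anchor regions; an empty body is allowed.
    """
    cfg = SCHEMES[scheme]
    threshold = cfg["min_length"] if min_length is None else min_length
    if gene.length < threshold:
        return None
    anchors = {
        name: make_anchor_region(gene, specs[name], chromosome_sizes) for name in cfg["anchors"]
    }
    cuts = [
        (max(r.start, gene.start), min(r.end, gene.end))
        for r in anchors.values()
        if r.start < gene.end and r.end > gene.start
    ]
    body = _subtract((gene.start, gene.end), cuts)
    return GeneRegions(gene=gene, anchors=anchors, body_name=cfg["body"], body_pieces=body)


def _body_signal(track: CoverageTrack, gr: GeneRegions) -> float:
    return sum(track.signal(gr.gene.chrom, s, e) for s, e in gr.body_pieces)


@dataclass
class FeatureMatrix:
    """Genes x chromatin-feature table with gene chromosome lookup.

    Columns are named ``track:region:normalization`` plus the scalar
    columns ``expression`` and ``gene_length``.
    """

    df: pd.DataFrame
    chromosomes: pd.Series
    filtered_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.df.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if self.df.columns.duplicated().any():
            raise ValueError("duplicate feature descriptors")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.df.columns)

    def columns_for_track(self, track_name: str) -> list[str]:
        """All columns derived from one track (any region / normalization)."""
        return [c for c in self.df.columns if c.split(":")[0] == track_name]

    def zeroed(self, feature_names: Sequence[str]) -> "FeatureMatrix":
        """Copy with the named columns replaced by 0 (in-silico ablation input)."""
        unknown = [f for f in feature_names if f not in self.df.columns]
        if unknown:
            raise KeyError(f"unknown features: {unknown}")
        df = self.df.copy()
        df[list(feature_names)] = 0.0
        return FeatureMatrix(df=df, chromosomes=self.chromosomes, filtered_genes=self.filtered_genes)

    def to_tsv(self, path) -> None:
        """Two-line header: descriptor row then normalization row."""
        descriptors, norms = [], []
        for c in self.df.columns:
            parts = c.split(":")
            if len(parts) == 3:
                descriptors.append(f"{parts[0]}:{parts[1]}")
                norms.append(parts[2])
            else:
                descriptors.append(c)
                norms.append("-")
        with open(path, "w") as fh:
            fh.write("gene_id\tchrom\t" + "\t".join(descriptors) + "\n")
            fh.write("-\t-\t" + "\t".join(norms) + "\n")
            for gid in self.df.index:
                vals = "\t".join(repr(float(v)) for v in self.df.loc[gid])
                fh.write(f"{gid}\t{self.chromosomes[gid]}\t{vals}\n")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        with open(path) as fh:
            head = fh.readline().rstrip("\n").split("\t")
            norm = fh.readline().rstrip("\n").split("\t")
            cols = []
            for d, n in zip(head[2:], norm[2:]):
                cols.append(d if n == "-" else f"{d}:{n}")
            gene_ids, chroms, rows = [], [], []
            for line in fh:
                f = line.rstrip("\n").split("\t")
                gene_ids.append(f[0])
                chroms.append(f[1])
                rows.append([float(x) for x in f[2:]])
        df = pd.DataFrame(rows, index=gene_ids, columns=cols)
        return cls(df=df, chromosomes=pd.Series(chroms, index=gene_ids))


def build_matrix(
    tracks: Sequence[CoverageTrack],
    genes: GenomeAnnotation,
    scheme: str = "3region",
    expression: Mapping[str, float] | pd.DataFrame | None = None,
    specs: Mapping[str, RegionSpec] = DEFAULT_SPECS,
    min_length: int | None = None,
) -> FeatureMatrix:
    """Build the genes x features table consumed by both learners.

    ``expression`` may be a per-gene scalar mapping or a DataFrame of
    replicate FPKM columns (averaged). Genes below the scheme's length
    threshold are filtered out and reported on the result.
    """
    if len(tracks) == 0:
        raise ValueError("at least one track required")
    names = [t.name for t in tracks]
    if len(set(names)) != len(names):
        raise ValueError("duplicate track names")
    cfg = SCHEMES[scheme]

    if isinstance(expression, pd.DataFrame):
        expr = expression.mean(axis=1)
    elif expression is not None:
        expr = pd.Series(dict(expression), dtype=float)
    else:
        expr = None

    kept: list[GeneModel] = []
    splits: list[GeneRegions] = []
    filtered: list[str] = []
    for g in genes:
        gr = split_gene(g, scheme=scheme, specs=specs,
                        chromosome_sizes=genes.chromosome_sizes or None,
                        min_length=min_length)
        if gr is None:
            filtered.append(g.gene_id)
            continue
        kept.append(g)
        splits.append(gr)
    if filtered:
        logger.info("filtered %d genes below the %s length threshold", len(filtered), scheme)

    columns: list[str] = []
    for t in tracks:
        for a in cfg["anchors"]:
            columns.append(f"{t.name}:{a}:RPM")
        columns.append(f"{t.name}:{cfg['body']}:RPM")
        columns.append(f"{t.name}:{cfg['body']}:RPKM")
    columns += ["expression", "gene_length"]

    values = np.zeros((len(kept), len(columns)))
    col_index = {c: j for j, c in enumerate(columns)}
    for i, gr in enumerate(splits):
        for t in tracks:
            lib = t.library_size
            if lib is None or lib <= 0:
                raise ValueError(f"track {t.name}: library size required for RPM")
            for a, region in gr.anchors.items():
                raw = t.signal(region.chrom, region.start, region.end)
                values[i, col_index[f"{t.name}:{a}:RPM"]] = raw * 1e6 / lib
            braw = _body_signal(t, gr)
            brpm = braw * 1e6 / lib
            values[i, col_index[f"{t.name}:{gr.body_name}:RPM"]] = brpm
            blen = gr.body_length
            values[i, col_index[f"{t.name}:{gr.body_name}:RPKM"]] = (
                brpm * 1e3 / blen if blen > 0 else 0.0
            )
        gid = gr.gene.gene_id
        values[i, col_index["expression"]] = float(expr.get(gid, 0.0)) if expr is not None else 0.0
        values[i, col_index["gene_length"]] = gr.gene.length

    df = pd.DataFrame(values, index=[g.gene_id for g in kept], columns=columns)
    chroms = pd.Series({g.gene_id: g.chrom for g in kept})
    return FeatureMatrix(df=df, chromosomes=chroms.loc[df.index], filtered_genes=filtered)
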