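"""Mutant-effect analytics for writer loss-of-function lines.

Which genes lose the mark in each mutant, where along the gene body the
loss occurs (standardized 6-bin profiles, clustered across mutants),
whether the loss is global (spike-in read-ratio statistic R), and how
the mark-transcription coupling shifts when a writer is removed
(Spearman correlation per expression replicate, compared across
genotypes by Welch's t-test).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .annotation import GeneModel, GenomeAnnotation
from .regions import AnchorRegion
from .tracks import CoverageTrack

logger = logging.getLogger(__name__)


def _gene_region(gene: GeneModel) -> AnchorRegion:
    return AnchorRegion(gene.gene_id, gene.chrom, gene.start, gene.end, gene.strand, "gene")


def _gene_norm(track: CoverageTrack, gene: GeneModel, normalization: str) -> float:
    raw = track.signal(gene.chrom, gene.start, gene.end)
    if normalization == "raw":
        return raw
    if track.library_size is None or track.library_size <= 0:
        raise ValueError(f"track {track.name}: library size required")
    rpm = raw * 1e6 / track.library_size
    if normalization == "RPM":
        return rpm
    if normalization == "RPKM":
        return rpm * 1e3 / gene.length
    raise ValueError(f"unknown normalization {normalization!r}")


def marked_gene_set(
    wt_track: CoverageTrack,
    mut_track: CoverageTrack,
    genes: GenomeAnnotation,
    n: int = 3000,
    normalization: str = "RPKM",
) -> list[str]:
    """Top n genes by (WT - mutant) signal over TSS->TTS, descending.

    Ties break by gene id ascending. If every difference is zero the
    lexicographically first genes are returned with a warning.
    """
    if n > len(genes):
        raise ValueError(f"n ({n}) exceeds gene count ({len(genes)})")
    diffs = {
        g.gene_id: _gene_norm(wt_track, g, normalization) - _gene_norm(mut_track, g, normalization)
        for g in genes
    }
    if all(d == 0 for d in diffs.values()):
        logger.warning("marked_gene_set: no signal difference between WT and mutant")
    order = sorted(diffs, key=lambda gid: (-diffs[gid], gid))
    return order[:n]


@dataclass
class MutantBinMatrix:
    """Standardized per-gene 6-bin (WT - mutant) loss profiles."""

    mutant: str
    gene_ids: list[str]
    values: np.ndarray  # (n_genes, n_bins), row mean 0 / sample SD 1 or all-zero

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def vectorized(self) -> np.ndarray:
        return self.values.ravel()


def gene_bins(gene: GeneModel, n_bins: int = 6) -> list[tuple[int, int]]:
    """Equal sixths of TSS->TTS, 5'->3' in transcription direction.

    Boundaries at floor(i*L/n); the last bin absorbs the remainder.
    """
    L = gene.length
    edges = [gene.start + (i * L) // n_bins for i in range(n_bins)] + [gene.end]
    bins = [(edges[i], edges[i + 1]) for i in range(n_bins)]
    if gene.strand == "-":
        bins = bins[::-1]
    return bins


def bin_profile_matrix(
    wt_track: CoverageTrack,
    mut_track: CoverageTrack,
    genes: GenomeAnnotation,
    gene_set: list[str],
    n_bins: int = 6,
    mutant_name: str = "",
) -> MutantBinMatrix:
    """Per-gene standardized 6-bin RPM difference (WT - mutant).

    Genes shorter than ``n_bins`` bp are excluded and logged. Rows are
    standardized with sample SD (n-1); constant rows become all-zero.
    """
    by_id = {g.gene_id: g for g in genes}
    kept, rows = [], []
    wt_lib, mut_lib = wt_track.library_size, mut_track.library_size
    if not wt_lib or not mut_lib:
        raise ValueError("library sizes required for RPM bin profiles")
    for gid in gene_set:
        g = by_id[gid]
        if g.length < n_bins:
            logger.info("gene %s shorter than %d bp excluded from bin profile", gid, n_bins)
            continue
        bins = gene_bins(g, n_bins)
        wt = np.array([wt_track.signal(g.chrom, s, e) for s, e in bins]) * 1e6 / wt_lib
        mu = np.array([mut_track.signal(g.chrom, s, e) for s, e in bins]) * 1e6 / mut_lib
        diff = wt - mu
        sd = diff.std(ddof=1)
        rows.append(np.zeros(n_bins) if sd == 0 else (diff - diff.mean()) / sd)
        kept.append(gid)
    return MutantBinMatrix(mutant=mutant_name, gene_ids=kept, values=np.vstack(rows))


@dataclass
class MutantClustering:
    """Hierarchical clustering of mutants by vectorized loss profiles."""

    mutants: list[str]
    distances: pd.DataFrame  # symmetric Euclidean distance table
    linkage: np.ndarray  # scipy linkage matrix

    def cut(self, n_clusters: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return dict(zip(self.mutants, (int(x) for x in labels)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.mutants[node.id]
            left, right = rec(node.get_left()), rec(node.get_right())
            return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

        return rec(tree) + ";"


def cluster_mutants(
    matrices: list[MutantBinMatrix], linkage_method: str = "average"
) -> MutantClustering:
    """Euclidean distances between vectorized bin matrices, then
    agglomerative (default UPGMA) clustering."""
    ref = matrices[0]
    for m in matrices[1:]:
        if m.gene_ids != ref.gene_ids or m.n_bins != ref.n_bins:
            raise ValueError("bin matrices must share gene set, order and bin count")
    X = np.vstack([m.vectorized() for m in matrices])
    names = [m.mutant for m in matrices]
    from scipy.spatial.distance import pdist, squareform

    condensed = pdist(X, metric="euclidean")
    dist = pd.DataFrame(squareform(condensed), index=names, columns=names)
    Z = hierarchy.linkage(condensed, method=linkage_method)
    return MutantClustering(mutants=names, distances=dist, linkage=Z)


# ---------------------------------------------------------------------------
# spike-in normalization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpikeInSample:
    """Read counts for one ChIP sample with exogenous spike-in chromatin."""

    name: str
    genotype: str
    antibody: str
    ath_reads: int
    spike_reads: int

    def __post_init__(self) -> None:
        if self.spike_reads <= 0:
            raise ValueError(f"sample {self.name}: spike reads must be positive")
        if self.ath_reads <= 0:
            raise ValueError(f"sample {self.name}: target reads must be positive")

    @property
    def R(self) -> float:
        """Target-genome : spike-in mapped-read ratio."""
        return self.ath_reads / self.spike_reads


def spikein_expected_ratio(
    wt_h3: SpikeInSample,
    mut_h3: SpikeInSample,
    wt_mark: SpikeInSample,
    mut_mark: SpikeInSample,
) -> float:
    """Actual over expected R for the mutant mark sample.

    Under no global change, R_WT_H3 : R_mut_H3 = R_WT_mark :
    expected R_mut_mark; the returned ratio is the mutant's global
    mark level relative to WT.
    """
    expected = wt_mark.R * mut_h3.R / wt_h3.R
    return mut_mark.R / expected


# ---------------------------------------------------------------------------
# gene-set overlap and transcription-mark correlation
# ---------------------------------------------------------------------------


@dataclass
class OverlapResult:
    observed: int
    expected: float
    p_value: float
    tail: str


def overlap_test(
    set_a: set[str], set_b: set[str], universe: set[str], tail: str = "under"
) -> OverlapResult:
    """Hypergeometric tail test of the overlap of two gene sets.

    under: P(X <= observed); over: P(X >= observed). Expected overlap
    is |A||B|/N.
    """
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    N, a, b = len(universe), len(set_a), len(set_b)
    observed = len(set_a & set_b)
    hg = stats.hypergeom(N, a, b)
    if tail == "under":
        p = float(hg.cdf(observed))
    elif tail == "over":
        p = float(hg.sf(observed - 1))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return OverlapResult(observed=observed, expected=a * b / N, p_value=min(p, 1.0), tail=tail)


@dataclass
class CorrelationResult:
    """Spearman rho of a mark against each expression replicate."""

    genotype: str
    rhos: np.ndarray  # one per replicate
    plot_table: pd.DataFrame  # rank pairs, zero-expression genes excluded

    @property
    def mean_rho(self) -> float:
        return float(self.rhos.mean())

    @property
    def sd_rho(self) -> float:
        return float(self.rhos.std(ddof=1))

    @property
    def n_replicates(self) -> int:
        return len(self.rhos)


def correlation_landscape(
    mark_values: pd.Series,
    expression_replicates: pd.DataFrame,
    genotype: str = "",
) -> CorrelationResult:
    """Spearman rho between per-gene mark level and each expression
    replicate, over all genes.

    The correlation itself keeps zero-expression genes; the exported
    rank table for density plotting excludes them (two distinct
    filters, both intentional).
    """
    common = mark_values.index.intersection(expression_replicates.index)
    if len(common) < 2:
        raise ValueError("need at least 2 genes")
    mark = mark_values.loc[common]
    expr = expression_replicates.loc[common]
    if mark.nunique() <= 1:
        raise ValueError("mark values are all tied")
    rhos = []
    for col in expr.columns:
        if expr[col].nunique() <= 1:
            raise ValueError(f"expression replicate {col} is all tied")
        rho, _ = stats.spearmanr(mark.to_numpy(), expr[col].to_numpy())
        rhos.append(float(rho))
    expressed = expr.mean(axis=1) > 0
    plot = pd.DataFrame(
        {
            "gene_id": common[expressed],
            "mark_rank": stats.rankdata(mark[expressed]),
            "expression_rank": stats.rankdata(expr.mean(axis=1)[expressed]),
        }
    )
    return CorrelationResult(genotype=genotype, rhos=np.array(rhos), plot_table=plot)


def compare_correlations(res_a: CorrelationResult, res_b: CorrelationResult
                         ) -> tuple[float, float]:
    """Welch two-sample t-test on the replicate rho values.

    Returns (t statistic, two-sided p). Degenerate zero-variance
    inputs: equal means -> p = 1; unequal means -> p = 0 with warning.
    """
    a, b = res_a.rhos, res_b.rhos
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per genotype")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        logger.warning("compare_correlations: zero variance with unequal means")
        return float("inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
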