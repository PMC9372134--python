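"""Seeded synthetic-data generator for every pipeline stage.

Emulates the statistical structure the analysis assumes: per-gene
chromatin-feature levels with a planted "driver" feature causally
coupled to enzyme binding, an RNAP2-like track coupled to expression,
promoter sequences with a planted motif enriched in bound genes,
mutant tracks with sub-gene (per-bin) loss profiles, and spike-in read
counts under a planted global mark level. Every artifact is
deterministic given the config seed; per-stage generators derive their
streams by hashing the stage name, so stages can be re-run
independently without disturbing each other.
"""
from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomeAnnotation
from .binding_rf import BindingLabels
from .features import FeatureMatrix
from .mutants import SpikeInSample, gene_bins
from .tracks import CoverageTrack


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome.

    Desk-scale defaults (2000 genes, 300 bound, 5 chromosomes) keep the
    full pipeline fast; the full-study bound-gene count (3000) is a
    matter of raising ``n_genes``/``n_bound``.
    """

    seed: int = 0
    n_chromosomes: int = 5
    chromosome_length: int = 1_200_000
    n_genes: int = 2000
    gene_length_meanlog: float = math.log(1500.0)
    gene_length_sdlog: float = 0.4
    min_gene_length: int = 500
    n_bound: int = 300
    # binding model: logit = beta_driver * z(driver) + beta_motif * motif + noise
    beta_driver: float = 2.0
    beta_motif: float = 0.0
    logit_noise_sd: float = 1.0
    driver_modes: tuple[float, float] = (0.0, 2.5)  # bimodal driver, unit-SD components
    feature_noise_sd: float = 0.2  # measurement noise on feature values
    n_nuisance: int = 5
    # expression and the RNAP2-like feature
    gamma: float = 1.0  # RNAP2 ~ expression**gamma
    n_expression_replicates: int = 3
    expression_sdlog: float = 1.0
    replicate_noise_sdlog: float = 0.25
    zero_expression_fraction: float = 0.1
    # promoters
    promoter_length: int = 450
    motif: str = "GAGAGAGA"
    pi_bound: float = 0.6
    pi_unbound: float = 0.05
    # fragment-level tracks
    fragment_length: int = 50
    base_rate: float = 20.0  # mean fragments per gene for feature tracks
    tag_signal_rate: float = 40.0  # extra tag fragments in the occupancy region
    control_rate: float = 8.0
    # mutants
    mutant_profiles: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "mutA1": (1, 1, 1, 0.4, 0.4, 0.4),
            "mutA2": (1, 1, 1, 0.4, 0.4, 0.4),
            "mutA3": (1, 1, 1, 0.4, 0.4, 0.4),
            "mutB1": (0.5, 0.5, 0.5, 0.5, 0.5, 0.5),
            "mutB2": (0.5, 0.5, 0.5, 0.5, 0.5, 0.5),
            "mutB3": (0.5, 0.5, 0.5, 0.5, 0.5, 0.5),
        }
    )
    n_bins: int = 6
    mark_bin_rate_meanlog: float = math.log(40.0)
    mark_bin_rate_sdlog: float = 0.5
    # spike-in
    mark_level_mut: float = 0.5  # mutant's remaining global mark level (WT = 1)
    spike_fraction: float = 0.1  # spike-in : target chromatin ratio
    spike_total_reads: int = 100_000
    # correlation fixture
    cue_sdlog: float = 1.0
    mark_noise_sdlog: float = 0.2

    def __post_init__(self) -> None:
        for p in (self.pi_bound, self.pi_unbound, self.zero_expression_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_bound >= self.n_genes:
            raise ValueError("n_bound must be smaller than n_genes")
        for name, prof in self.mutant_profiles.items():
            if any(not 0 <= v <= 1.5 for v in prof):
                raise ValueError(f"mutant {name}: profile values must lie in [0, 1.5]")


@dataclass
class SimTruth:
    """Planted ground truth sufficient to score every recovery test."""

    bound: list[str] = field(default_factory=list)
    driver: dict[str, float] = field(default_factory=dict)
    logit: dict[str, float] = field(default_factory=dict)
    motif_latent: dict[str, int] = field(default_factory=dict)
    insertion_positions: dict[str, int] = field(default_factory=dict)
    affected: dict[str, list[str]] = field(default_factory=dict)
    profiles: dict[str, list[float]] = field(default_factory=dict)
    mark_level_mut: float = 1.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _rng(config: SimConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        [config.seed % (2**31), zlib.crc32(stage.encode()) % (2**31)]
    )


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def generate_annotation(config: SimConfig) -> GenomeAnnotation:
    """Non-overlapping genes with log-normal lengths, random strands."""
    rng = _rng(config, "annotation")
    chroms = [f"Chr{i + 1}" for i in range(config.n_chromosomes)]
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    records: list[GeneModel] = []
    gid = 0
    for chrom, n in zip(chroms, per_chrom):
        lengths = np.maximum(
            rng.lognormal(config.gene_length_meanlog, config.gene_length_sdlog, n).astype(int),
            config.min_gene_length,
        )
        free = config.chromosome_length - int(lengths.sum())
        if free < n + 1:
            raise ValueError(
                f"infeasible packing: {n} genes of total length {lengths.sum()} "
                f"do not fit on a {config.chromosome_length} bp chromosome"
            )
        gap_w = rng.random(n + 1)
        gaps = np.floor(gap_w / gap_w.sum() * free).astype(int)
        pos = 0
        for j in range(n):
            pos += int(gaps[j])
            start = pos
            end = start + int(lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(GeneModel(f"G{gid:05d}", chrom, start, end, strand))
            pos = end
            gid += 1
    sizes = {c: config.chromosome_length for c in chroms}
    return GenomeAnnotation(records=records, chromosome_sizes=sizes)


# ---------------------------------------------------------------------------
# binding truth and the analytic feature table
# ---------------------------------------------------------------------------


def generate_binding_truth(config: SimConfig, annotation: GenomeAnnotation) -> SimTruth:
    """Plant the causal structure: bimodal driver -> binding propensity.

    logit = beta_D * z(driver) + beta_M * motif_latent + Gaussian noise;
    the bound set is the top ``n_bound`` genes by propensity.
    """
    rng = _rng(config, "binding")
    ids = [g.gene_id for g in annotation]
    n = len(ids)
    comp = rng.random(n) < 0.5
    driver = np.where(comp, config.driver_modes[0], config.driver_modes[1]) + rng.normal(0, 1, n)
    z = (driver - driver.mean()) / driver.std(ddof=0)
    pi_prior = (
        config.pi_bound * config.n_bound + config.pi_unbound * (n - config.n_bound)
    ) / n
    motif_latent = (rng.random(n) < pi_prior).astype(int) if config.beta_motif != 0 else np.zeros(n, dtype=int)
    logit = (
        config.beta_driver * z
        + config.beta_motif * motif_latent
        + rng.normal(0, config.logit_noise_sd, n)
    )
    order = np.argsort(-logit, kind="stable")
    bound = sorted(ids[i] for i in order[: config.n_bound])
    return SimTruth(
        bound=bound,
        driver={g: float(v) for g, v in zip(ids, driver)},
        logit={g: float(v) for g, v in zip(ids, logit)},
        motif_latent={g: int(v) for g, v in zip(ids, motif_latent)},
    )


def generate_expression(config: SimConfig, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Log-normal expression, 3 replicates, a fraction exactly zero."""
    rng = _rng(config, "expression")
    ids = [g.gene_id for g in annotation]
    n = len(ids)
    base = rng.lognormal(1.0, config.expression_sdlog, n)
    zero = rng.random(n) < config.zero_expression_fraction
    base[zero] = 0.0
    reps = {}
    for r in range(config.n_expression_replicates):
        noise = rng.lognormal(0.0, config.replicate_noise_sdlog, n)
        reps[f"rep{r + 1}"] = base * noise
    return pd.DataFrame(reps, index=ids)


def simulate_binding_dataset(
    config: SimConfig,
) -> tuple[FeatureMatrix, BindingLabels, SimTruth]:
    """Analytic genes x features table with planted driver dependence.

    The driver column is the causal driver plus measurement noise;
    nuisance columns are independent noise; the RNAP2 column follows
    expression**gamma. This is the fixture for the random-forest
    recovery, null and ablation tests.
    """
    annotation = generate_annotation(config)
    truth = generate_binding_truth(config, annotation)
    expr = generate_expression(config, annotation)
    rng = _rng(config, "features")
    ids = [g.gene_id for g in annotation]
    n = len(ids)
    driver = np.array([truth.driver[g] for g in ids])
    cols = {
        "driver": driver + rng.normal(0, config.feature_noise_sd, n),
    }
    for i in range(config.n_nuisance):
        cols[f"nuisance_{i + 1}"] = rng.normal(0, 1, n)
    expr_mean = expr.mean(axis=1).to_numpy()
    cols["RNAP2"] = (expr_mean + 0.1) ** config.gamma * rng.lognormal(0, 0.3, n)
    cols["expression"] = expr_mean
    cols["gene_length"] = np.array([g.length for g in annotation], dtype=float)
    df = pd.DataFrame(cols, index=ids)
    chroms = pd.Series({g.gene_id: g.chrom for g in annotation})
    matrix = FeatureMatrix(df=df, chromosomes=chroms.loc[df.index])
    bound = set(truth.bound)
    labels = BindingLabels(
        labels=pd.Series({g: g in bound for g in ids}, dtype=bool).loc[ids],
        n_bound=config.n_bound,
        signal_descriptor="planted propensity",
    )
    return matrix, labels, truth


# ---------------------------------------------------------------------------
# fragment-level coverage tracks
# ---------------------------------------------------------------------------


def _fragments_for_rates(
    rng: np.random.Generator,
    annotation: GenomeAnnotation,
    rates: Mapping[str, float],
    fragment_length: int,
    within: Mapping[str, tuple[int, int]] | None = None,
) -> dict[str, list[tuple[int, int]]]:
    frags: dict[str, list[tuple[int, int]]] = {}
    for g in annotation:
        lam = rates.get(g.gene_id, 0.0)
        if lam <= 0:
            continue
        k = rng.poisson(lam)
        if k == 0:
            continue
        lo, hi = (within or {}).get(g.gene_id, (g.start, g.end))
        hi_start = max(hi - fragment_length, lo + 1)
        starts = rng.integers(lo, hi_start, size=k)
        size = annotation.chromosome_sizes.get(g.chrom)
        for s in starts:
            e = int(s) + fragment_length
            if size is not None:
                e = min(e, size)
            frags.setdefault(g.chrom, []).append((int(s), e))
    return frags


def generate_tracks(
    annotation: GenomeAnnotation,
    truth: SimTruth,
    config: SimConfig,
    expression: pd.DataFrame | None = None,
) -> dict[str, CoverageTrack]:
    """Fragment-level tracks: driver, nuisance x m, RNAP2-like, tag, control.

    Per-gene fragment counts are Poisson with rates tied to the planted
    per-gene values; tag = control background plus concentrated signal
    in the occupancy (TSS) region of bound genes.
    """
    from .regions import DEFAULT_SPECS, make_anchor_region

    rng = _rng(config, "tracks")
    if expression is None:
        expression = generate_expression(config, annotation)
    ids = [g.gene_id for g in annotation]
    driver = np.array([truth.driver[g] for g in ids])
    z = (driver - driver.mean()) / driver.std(ddof=0)
    tracks: dict[str, CoverageTrack] = {}

    def add(name: str, rates: Mapping[str, float], within=None) -> None:
        frags = _fragments_for_rates(rng, annotation, rates, config.fragment_length, within)
        tracks[name] = CoverageTrack.from_fragments(name, frags)

    add("driver", {g: config.base_rate * math.exp(0.5 * zz) for g, zz in zip(ids, z)})
    for i in range(config.n_nuisance):
        x = rng.normal(0, 1, len(ids))
        add(f"nuisance_{i + 1}", {g: config.base_rate * math.exp(0.5 * v) for g, v in zip(ids, x)})
    expr_mean = expression.mean(axis=1)
    add(
        "RNAP2",
        {g: config.base_rate * float(expr_mean[g] + 0.1) ** config.gamma / 3.0 for g in ids},
    )
    add("control", {g: config.control_rate for g in ids})
    tss_windows = {}
    for g in annotation:
        r = make_anchor_region(g, DEFAULT_SPECS["TSS_region"], annotation.chromosome_sizes)
        if r.length > 0:
            tss_windows[g.gene_id] = (r.start, r.end)
    bound = set(truth.bound)
    bg = _fragments_for_rates(
        rng, annotation, {g: config.control_rate for g in ids}, config.fragment_length
    )
    sig = _fragments_for_rates(
        rng,
        annotation,
        {g: config.tag_signal_rate for g in ids if g in bound and g in tss_windows},
        config.fragment_length,
        within=tss_windows,
    )
    merged = {c: list(v) for c, v in bg.items()}
    for c, v in sig.items():
        merged.setdefault(c, []).extend(v)
    tracks["tag"] = CoverageTrack.from_fragments("tag", merged)
    return tracks


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------


def generate_promoters(
    annotation: GenomeAnnotation,
    truth: SimTruth,
    config: SimConfig,
) -> dict[str, str]:
    """Uniform-ACGT promoter sequences with the planted motif.

    The motif is inserted at a uniform random offset with probability
    pi_bound for bound genes and pi_unbound otherwise; insertion
    positions are recorded in the truth object (-1 = no insertion).
    """
    if len(config.motif) > config.promoter_length:
        raise ValueError("motif longer than the promoter region")
    rng = _rng(config, "promoters")
    bound = set(truth.bound)
    bases = np.array(list("ACGT"))
    out: dict[str, str] = {}
    for g in annotation:
        seq = "".join(bases[rng.integers(0, 4, config.promoter_length)])
        pi = config.pi_bound if g.gene_id in bound else config.pi_unbound
        if rng.random() < pi:
            pos = int(rng.integers(0, config.promoter_length - len(config.motif) + 1))
            seq = seq[:pos] + config.motif + seq[pos + len(config.motif):]
            truth.insertion_positions[g.gene_id] = pos
        else:
            truth.insertion_positions[g.gene_id] = -1
        out[g.gene_id] = seq
    return out


def simulate_promoter_dataset(
    config: SimConfig,
) -> tuple[dict[str, str], BindingLabels, pd.Series, SimTruth]:
    """Promoter FASTA + labels + chromosome lookup for the SVM stage."""
    annotation = generate_annotation(config)
    truth = generate_binding_truth(config, annotation)
    seqs = generate_promoters(annotation, truth, config)
    ids = [g.gene_id for g in annotation]
    bound = set(truth.bound)
    labels = BindingLabels(
        labels=pd.Series({g: g in bound for g in ids}, dtype=bool).loc[ids],
        n_bound=config.n_bound,
        signal_descriptor="planted propensity",
    )
    chroms = pd.Series({g.gene_id: g.chrom for g in annotation})
    return seqs, labels, chroms, truth


# ---------------------------------------------------------------------------
# mutants and spike-in
# ---------------------------------------------------------------------------


def generate_mutants(
    annotation: GenomeAnnotation,
    truth: SimTruth,
    config: SimConfig,
    affected: Sequence[str] | None = None,
) -> tuple[CoverageTrack, dict[str, CoverageTrack]]:
    """WT mark track plus one mutant track per configured loss profile.

    A shared per-gene-per-bin rate field (log-normal) is sampled once;
    WT counts are Poisson at those rates and each mutant's counts are
    Poisson at rate x profile multiplier on its affected genes.
    Fragments are emitted as 1-bp points so per-bin counts partition
    exactly.
    """
    rng = _rng(config, "mutants")
    affected_set = set(affected if affected is not None else truth.bound)
    genes = [g for g in annotation if g.length >= config.n_bins]
    # shared per-gene-per-bin rate field and the WT realization; mutant
    # tracks are per-bin thinnings/augmentations of the same fragments,
    # so an identity profile reproduces the WT track exactly
    lam: dict[str, np.ndarray] = {}
    wt_pos: dict[str, list[np.ndarray]] = {}
    for g in genes:
        lam[g.gene_id] = rng.lognormal(
            config.mark_bin_rate_meanlog, config.mark_bin_rate_sdlog, config.n_bins
        )
        per_bin = []
        for (s, e), r in zip(gene_bins(g, config.n_bins), lam[g.gene_id]):
            k = rng.poisson(r)
            per_bin.append(rng.integers(s, e, size=k) if k else np.empty(0, dtype=np.int64))
        wt_pos[g.gene_id] = per_bin

    def as_track(name: str, positions: dict[str, list[np.ndarray]]) -> CoverageTrack:
        frags: dict[str, list[tuple[int, int]]] = {}
        for g in genes:
            for pos in positions[g.gene_id]:
                frags.setdefault(g.chrom, []).extend((int(p), int(p) + 1) for p in pos)
        return CoverageTrack.from_fragments(name, frags)

    wt = as_track("WT", wt_pos)
    muts = {}
    for name, profile in config.mutant_profiles.items():
        mpos: dict[str, list[np.ndarray]] = {}
        for g in genes:
            gid = g.gene_id
            if gid not in affected_set:
                mpos[gid] = wt_pos[gid]
                continue
            bins = gene_bins(g, config.n_bins)
            per_bin = []
            for b, (p, pos) in enumerate(zip(profile, wt_pos[gid])):
                if p == 1:
                    kept = pos
                elif p < 1:
                    kept = pos[rng.random(len(pos)) < p]
                else:
                    extra_n = rng.poisson((p - 1) * lam[gid][b])
                    s, e = bins[b]
                    extra = rng.integers(s, e, size=extra_n) if extra_n else np.empty(0, dtype=np.int64)
                    kept = np.concatenate([pos, extra])
                per_bin.append(kept)
            mpos[gid] = per_bin
        muts[name] = as_track(name, mpos)
        truth.affected[name] = sorted(affected_set)
        truth.profiles[name] = list(profile)
    return wt, muts


def generate_spikein(
    config: SimConfig, genotype: str = "mut"
) -> dict[str, SpikeInSample]:
    """Spike-in read counts for the WT/mutant x H3/mark quartet.

    The mutant's mark-ChIP sample pulls Arabidopsis chromatin in
    proportion to its remaining global mark level; the read split is
    binomial at fixed total depth.
    """
    rng = _rng(config, f"spikein:{genotype}")
    s = config.spike_fraction
    f = config.mark_level_mut
    truth_p = {
        "wt_h3": 1 / (1 + s),
        "mut_h3": 1 / (1 + s),
        "wt_mark": 1 / (1 + s),
        "mut_mark": f / (f + s),
    }
    out = {}
    for name, p in truth_p.items():
        ath = int(rng.binomial(config.spike_total_reads, p))
        ath = min(max(ath, 1), config.spike_total_reads - 1)
        gt = "WT" if name.startswith("wt") else genotype
        ab = "H3" if name.endswith("h3") else "mark"
        out[name] = SpikeInSample(
            name=name, genotype=gt, antibody=ab,
            ath_reads=ath, spike_reads=config.spike_total_reads - ath,
        )
    return out


# ---------------------------------------------------------------------------
# transcription-mark correlation fixture
# ---------------------------------------------------------------------------


def simulate_correlation(config: SimConfig) -> dict[str, object]:
    """Mark landscapes for a co-transcriptional and a cue-driven writer.

    WT mark = transcription-coupled deposition (proportional to
    expression**gamma) + chromatin-cue deposition (independent) +
    noise. Removing the co-transcriptional writer leaves only the cue
    component (correlation with expression drops); removing the
    cue writer leaves only the coupled component (correlation rises).
    """
    rng = _rng(config, "correlation")
    n = config.n_genes
    ids = [f"G{i:05d}" for i in range(n)]
    base = rng.lognormal(1.0, config.expression_sdlog, n)
    zero = rng.random(n) < config.zero_expression_fraction
    base[zero] = 0.0
    reps = {
        f"rep{r + 1}": base * rng.lognormal(0, config.replicate_noise_sdlog, n)
        for r in range(config.n_expression_replicates)
    }
    expression = pd.DataFrame(reps, index=ids)
    tx = (base + 0.1) ** config.gamma
    cue = rng.lognormal(1.0, config.cue_sdlog, n)
    # scale the two deposition pathways to equal mean contribution
    cue = cue * tx.mean() / cue.mean()

    def noisy(x: np.ndarray) -> pd.Series:
        return pd.Series(x * rng.lognormal(0, config.mark_noise_sdlog, n), index=ids)

    return {
        "expression": expression,
        "mark_wt": noisy(tx + cue),
        "mark_no_tx_writer": noisy(cue),
        "mark_no_cue_writer": noisy(tx),
    }


# ---------------------------------------------------------------------------
# full dataset to disk
# ---------------------------------------------------------------------------


def write_dataset(config: SimConfig, outdir) -> dict[str, str]:
    """Simulate and write every artifact; returns path manifest."""
    import os

    from . import io as mio

    os.makedirs(outdir, exist_ok=True)
    annotation = generate_annotation(config)
    truth = generate_binding_truth(config, annotation)
    expression = generate_expression(config, annotation)
    tracks = generate_tracks(annotation, truth, config, expression)
    promoters = generate_promoters(annotation, truth, config)
    wt, muts = generate_mutants(annotation, truth, config)
    truth.mark_level_mut = config.mark_level_mut
    spike = generate_spikein(config)

    paths: dict[str, str] = {}

    def p(name: str) -> str:
        path = os.path.join(outdir, name)
        paths[name] = path
        return path

    from .annotation import Interval

    mio.write_bed(
        [Interval(g.chrom, g.start, g.end, name=g.gene_id, strand=g.strand) for g in annotation],
        p("genes.bed"),
    )
    with open(p("chrom.sizes"), "w") as fh:
        for c, size in annotation.chromosome_sizes.items():
            fh.write(f"{c}\t{size}\n")
    for name, track in {**tracks, "mark_WT": wt, **{f"mark_{m}": t for m, t in muts.items()}}.items():
        mio.write_fragment_bed(track, p(f"track_{name}.bed"))
    mio.write_fasta(promoters, p("promoters.fa"))
    expression.rename_axis("gene_id").reset_index().to_csv(
        p("expression.tsv"), sep="\t", index=False
    )
    rows = [
        {"sample": s.name, "genotype": s.genotype, "antibody": s.antibody,
         "ath_reads": s.ath_reads, "spike_reads": s.spike_reads}
        for s in spike.values()
    ]
    pd.DataFrame(rows).to_csv(p("spikein_counts.tsv"), sep="\t", index=False)
    truth.to_json(p("truth.json"))
    return paths
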