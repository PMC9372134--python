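"""k-mer SVM mining of promoter sequence determinants of writer binding.

Anchor-region DNA (coding strand only) is converted to 4^k k-mer count
vectors, and balanced linear SVMs are trained to separate bound from
unbound promoters. The averaged per-k-mer weights over the repeat
models rank k-mers by predictive value; top k-mers are clustered by
sequence similarity (reverse complement > 1-nt offset > 1-nt offset on
the opposite strand), extended into 3+k+3 flanking-context probability
matrices for MEME export, annotated against exact 6-mer motif-family
catalogs, and profiled positionally along the anchor region.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.svm import LinearSVC

from .binding_rf import BindingLabels

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def all_kmers(k: int) -> list[str]:
    """All k-mers in lexicographic order (the feature index order)."""
    return ["".join(p) for p in itertools.product(_BASES, repeat=k)]


def kmer_index(kmer: str) -> int:
    idx = 0
    for c in kmer:
        idx = idx * 4 + _CODE[c]
    return idx


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def kmer_vectorize(sequence: str, k: int = 6) -> np.ndarray:
    """Count k-mers on the given strand; windows containing non-ACGT skip.

    Returns a length-4^k integer vector in lexicographic k-mer order.
    No reverse-complement collapsing: the biology here is directional
    (promoter architecture on the coding strand).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = np.zeros(4**k, dtype=np.int64)
    seq = sequence.upper()
    n = len(seq)
    if n < k:
        return counts
    codes = np.array([_CODE.get(c, -1) for c in seq], dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return counts
    powers = 4 ** np.arange(k - 1, -1, -1)
    idx = (windows[valid] * powers).sum(axis=1)
    np.add.at(counts, idx, 1)
    return counts


def vectorize_set(sequences: Mapping[str, str], k: int = 6) -> pd.DataFrame:
    """Vectorize a FASTA-like mapping into a sequences x 4^k frame."""
    kmers = all_kmers(k)
    mat = np.vstack([kmer_vectorize(s, k) for s in sequences.values()])
    return pd.DataFrame(mat, index=list(sequences), columns=kmers)


# ---------------------------------------------------------------------------
# linear SVM with balanced resampling and weight averaging
# ---------------------------------------------------------------------------


@dataclass
class KmerWeightTable:
    """Per-model and averaged linear-SVM weights over the k-mer space."""

    kmers: list[str]
    per_model: np.ndarray  # (n_models, 4^k), standardized-space weights
    means: np.ndarray  # per-model standardization means
    sds: np.ndarray
    best_C: float

    @property
    def averaged(self) -> pd.Series:
        return pd.Series(self.per_model.mean(axis=0), index=self.kmers)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.per_model.T, index=self.kmers,
            columns=[f"model_{i}" for i in range(self.per_model.shape[0])],
        )
        df.insert(0, "kmer", self.kmers)
        df["mean_weight"] = self.per_model.mean(axis=0)
        return df


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)  # zero-variance k-mers pass through
    return mu, sd


class KmerSVM:
    """Balanced linear-SVM promoter model over k-mer count features.

    Parameters
    ----------
    vectors:
        sequences x k-mer count frame (rows indexed by gene id), e.g.
        from :func:`vectorize_set`.
    labels:
        Bound/unbound labels over the same gene ids.
    chromosomes:
        gene id -> chromosome, for the chromosome holdout.
    kmer_subset:
        Optional restriction of the feature space (e.g. the 120 most
        predictive 6-mers).
    """

    def __init__(
        self,
        vectors: pd.DataFrame,
        labels: BindingLabels,
        chromosomes: Mapping[str, str] | pd.Series,
        holdout: str = "Chr5",
        n_models: int = 5,
        C_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0),
        kmer_subset: Sequence[str] | None = None,
    ):
        if kmer_subset is not None:
            if len(kmer_subset) == 0:
                raise ValueError("kmer subset must be non-empty")
            unknown = [m for m in kmer_subset if m not in vectors.columns]
            if unknown:
                raise KeyError(f"k-mers outside the feature space: {unknown[:5]}")
            vectors = vectors[list(kmer_subset)]
        self.vectors = vectors
        self.labels = labels
        self.chromosomes = pd.Series(dict(chromosomes)) if not isinstance(
            chromosomes, pd.Series) else chromosomes
        self.holdout = holdout
        self.n_models = n_models
        self.C_grid = list(C_grid)
        y = labels.labels
        self.pool_pos = sorted(g for g in y.index[y] if self.chromosomes[g] != holdout)
        self.pool_neg = sorted(g for g in y.index[~y] if self.chromosomes[g] != holdout)
        self.test_genes = sorted(g for g in y.index if self.chromosomes[g] == holdout)
        if not self.pool_pos or not self.pool_neg:
            raise ValueError("training pool lacks one of the classes")
        if 2 * min(len(self.pool_pos), len(self.pool_neg)) < self.n_models:
            raise ValueError("too few rows for the requested number of folds")

    def _trials(self, seed: int) -> list[dict]:
        """Five CV trials: fold t of the positives is validation, the
        rest train; negatives are sampled independently per trial
        (without replacement within a trial) to balance both sets."""
        rng = np.random.default_rng(seed % (2**31))
        pos = np.array(self.pool_pos)
        folds = np.array_split(rng.permutation(len(pos)), self.n_models)
        trials = []
        for t in range(self.n_models):
            trng = np.random.default_rng((seed + 1 + t) % (2**31))
            va_pos = sorted(pos[folds[t]])
            tr_pos = sorted(np.delete(pos, folds[t]))
            neg_pool = np.array(self.pool_neg)
            n_tr_neg = min(len(tr_pos), len(neg_pool) - 1)
            tr_neg = sorted(trng.choice(neg_pool, size=n_tr_neg, replace=False))
            remaining = np.array(sorted(set(self.pool_neg) - set(tr_neg)))
            n_va_neg = min(len(va_pos), len(remaining))
            if n_va_neg == 0:
                raise ValueError("no negatives left for the validation fold")
            va_neg = sorted(trng.choice(remaining, size=n_va_neg, replace=False))
            trials.append(
                {
                    "train": list(tr_pos) + list(tr_neg),
                    "y_train": np.array([True] * len(tr_pos) + [False] * len(tr_neg)),
                    "val": list(va_pos) + list(va_neg),
                    "y_val": np.array([True] * len(va_pos) + [False] * len(va_neg)),
                    "seed": (seed + 1 + t) % (2**31),
                }
            )
        return trials

    def fit(self, seed: int = 0) -> "KmerSVMResults":
        """Select C by mean CV accuracy, then keep the per-fold models.

        The final ensemble is the n_models fold models refit at the
        selected C on their balanced training sets; averaged weights
        over these independently trained models rank the k-mers.
        Standardization parameters are fit on each model's training
        rows only.
        """
        X_all = self.vectors
        trials = self._trials(seed)
        acc = {C: [] for C in self.C_grid}
        prepared = []
        for tr in trials:
            Xtr = X_all.loc[tr["train"]].to_numpy(dtype=float)
            Xva = X_all.loc[tr["val"]].to_numpy(dtype=float)
            mu, sd = _standardize_fit(Xtr)
            prepared.append(((Xtr - mu) / sd, (Xva - mu) / sd, mu, sd))
            for C in self.C_grid:
                clf = LinearSVC(C=C, random_state=tr["seed"])
                clf.fit(prepared[-1][0], tr["y_train"])
                acc[C].append(accuracy_score(tr["y_val"], clf.predict(prepared[-1][1])))
        mean_acc = {C: float(np.mean(v)) for C, v in acc.items()}
        best_C = max(self.C_grid, key=lambda C: (mean_acc[C], -C))
        logger.info("selected C=%g (CV accuracies %s)", best_C,
                    {C: round(a, 3) for C, a in mean_acc.items()})

        weights, mus, sds, models = [], [], [], []
        for tr, (Xtr, _, mu, sd) in zip(trials, prepared):
            clf = LinearSVC(C=best_C, random_state=tr["seed"])
            clf.fit(Xtr, tr["y_train"])
            weights.append(clf.coef_[0].copy())
            mus.append(mu)
            sds.append(sd)
            models.append(clf)
        table = KmerWeightTable(
            kmers=list(X_all.columns),
            per_model=np.vstack(weights),
            means=np.vstack(mus),
            sds=np.vstack(sds),
            best_C=float(best_C),
        )
        return KmerSVMResults(model_spec=self, table=table, models=models,
                              cv_accuracy=mean_acc, seed=seed)


@dataclass
class KmerSVMResults:
    """Fitted k-mer SVM ensemble: weight table, holdout ROC/AUC."""

    model_spec: KmerSVM
    table: KmerWeightTable
    models: list[LinearSVC]
    cv_accuracy: dict[float, float]
    seed: int

    def _holdout_scores(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        spec = self.model_spec
        X = spec.vectors.loc[spec.test_genes].to_numpy(dtype=float)
        X = (X - self.table.means[i]) / self.table.sds[i]
        y = spec.labels.labels.loc[spec.test_genes].to_numpy()
        return y, self.models[i].decision_function(X)

    @property
    def aucs(self) -> np.ndarray:
        return np.array([roc_auc_score(*self._holdout_scores(i))
                         for i in range(len(self.models))])

    @property
    def auc_mean(self) -> float:
        return float(self.aucs.mean())

    @property
    def auc_sd(self) -> float:
        return float(self.aucs.std(ddof=1))

    def summary(self) -> str:
        top = self.table.averaged.sort_values(ascending=False).head(10)
        lines = [
            "k-mer linear SVM",
            f"  models: {len(self.models)}  C: {self.table.best_C:g}",
            f"  holdout ({self.model_spec.holdout}) AUC: "
            f"{self.auc_mean:.3f} +/- {self.auc_sd:.3f}",
            "  top positive averaged weights:",
        ]
        for kmer, w in top.items():
            lines.append(f"    {kmer}  {w:+.4f}")
        return "\n".join(lines)


def retrain_on_subset(
    results: KmerSVMResults, kmer_subset: Sequence[str], seed: int | None = None
) -> KmerSVMResults:
    """Re-run the full protocol restricted to a k-mer subset."""
    spec = results.model_spec
    sub = KmerSVM(
        vectors=spec.vectors,
        labels=spec.labels,
        chromosomes=spec.chromosomes,
        holdout=spec.holdout,
        n_models=spec.n_models,
        C_grid=spec.C_grid,
        kmer_subset=kmer_subset,
    )
    return sub.fit(results.seed if seed is None else seed)


# ---------------------------------------------------------------------------
# k-mer selection, similarity clustering, annotation
# ---------------------------------------------------------------------------


def select_kmers(
    table: KmerWeightTable,
    n: int = 60,
    mode: str = "top_positive",
    seed: int = 0,
) -> pd.DataFrame:
    """Select n k-mers by averaged weight; rank labels by |weight| desc.

    Modes: top_positive (largest positive weights), top_negative
    (most negative), near_zero (smallest |weight|), random (uniform
    without replacement).
    """
    w = table.averaged
    if n > len(w):
        raise ValueError("n exceeds k-mer space")
    if mode == "top_positive":
        chosen = w.sort_values(ascending=False, kind="stable").head(n)
    elif mode == "top_negative":
        chosen = w.sort_values(ascending=True, kind="stable").head(n)
    elif mode == "near_zero":
        chosen = w.reindex(w.abs().sort_values(kind="stable").head(n).index)
    elif mode == "random":
        rng = np.random.default_rng(seed % (2**31))
        chosen = w.loc[sorted(rng.choice(w.index.to_numpy(), size=n, replace=False))]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    df = pd.DataFrame({"kmer": chosen.index, "weight": chosen.to_numpy()})
    df["rank"] = df["weight"].abs().rank(ascending=False, method="first").astype(int)
    return df.reset_index(drop=True)


SIMILARITY_LEVELS = ("revcomp", "offset", "offset_revcomp", "none")
#: display scores for graph export; the ordinal ordering is what matters
SIMILARITY_SCORES = {"revcomp": 1.0, "offset": 2 / 3, "offset_revcomp": 1 / 3, "none": 0.0}


def _is_offset(a: str, b: str) -> bool:
    return a[1:] == b[:-1] or b[1:] == a[:-1]


def kmer_similarity(a: str, b: str) -> str:
    """Similarity level of two distinct equal-length k-mers.

    reverse complement > 1-nt offset > 1-nt offset on the opposite
    strand > none; the highest applicable level wins.
    """
    if len(a) != len(b):
        raise ValueError("k-mers must have equal length")
    if b == reverse_complement(a):
        return "revcomp"
    if _is_offset(a, b):
        return "offset"
    if _is_offset(a, reverse_complement(b)):
        return "offset_revcomp"
    return "none"


@dataclass
class KmerSimilarityGraph:
    graph: nx.Graph
    ranks: dict[str, int]

    @property
    def edges(self) -> list[tuple[str, str, str]]:
        return [(a, b, d["level"]) for a, b, d in self.graph.edges(data=True)]

    @property
    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"kmer_a": a, "kmer_b": b, "level": lv, "score": SIMILARITY_SCORES[lv]}
            for a, b, lv in self.edges
        ]
        return pd.DataFrame(rows, columns=["kmer_a", "kmer_b", "level", "score"])


def build_similarity_graph(kmers: Sequence[str] | pd.DataFrame) -> KmerSimilarityGraph:
    """Score all pairs of a ranked k-mer list; edges for non-none levels.

    A self-reverse-complement k-mer forms no self edge.
    """
    if isinstance(kmers, pd.DataFrame):
        names = list(kmers["kmer"])
        ranks = dict(zip(kmers["kmer"], kmers["rank"])) if "rank" in kmers else {
            m: i + 1 for i, m in enumerate(names)}
    else:
        names = list(kmers)
        ranks = {m: i + 1 for i, m in enumerate(names)}
    if len(set(names)) != len(names):
        raise ValueError("k-mer list contains duplicates")
    g = nx.Graph()
    g.add_nodes_from(names)
    for a, b in itertools.combinations(names, 2):
        level = kmer_similarity(a, b)
        if level != "none":
            g.add_edge(a, b, level=level, score=SIMILARITY_SCORES[level])
    return KmerSimilarityGraph(graph=g, ranks=ranks)


# ---------------------------------------------------------------------------
# flanking-context PWMs, families, positional profiles, conservation
# ---------------------------------------------------------------------------


@dataclass
class FlankedPWM:
    """3 + k + 3 position probability matrix around one source k-mer."""

    source_kmer: str
    matrix: np.ndarray  # (k + 6) x 4, rows sum to 1
    n_occurrences: int
    flank: int = 3

    @property
    def name(self) -> str:
        return self.source_kmer

    @property
    def nsites(self) -> int:
        return self.n_occurrences

    def __post_init__(self) -> None:
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError(f"PWM rows for {self.source_kmer} do not sum to 1")


def _occurrences(sequence: str, kmer: str) -> list[int]:
    """All (possibly overlapping) start offsets of kmer in sequence."""
    out, start = [], 0
    while True:
        i = sequence.find(kmer, start)
        if i == -1:
            return out
        out.append(i)
        start = i + 1


def flanking_pwm(
    kmer: str, background_sequences: Iterable[str], flank: int = 3
) -> FlankedPWM:
    """Empirical base frequencies in the 3-bp flanks of every occurrence.

    Scanning is coding-strand only. Occurrences lacking a full flank,
    or with non-ACGT bases in a flank, are dropped. The inner k rows
    are one-hot for the k-mer itself.
    """
    k = len(kmer)
    counts = np.zeros((2 * flank, 4))
    n = 0
    for seq in background_sequences:
        seq = seq.upper()
        for p in _occurrences(seq, kmer):
            if p < flank or p + k + flank > len(seq):
                continue
            context = seq[p - flank:p] + seq[p + k:p + k + flank]
            if any(c not in _CODE for c in context):
                continue
            for j, c in enumerate(context):
                counts[j, _CODE[c]] += 1
            n += 1
    if n == 0:
        raise ValueError(f"no qualifying occurrence of {kmer} in the designated sequences")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    inner = np.zeros((k, 4))
    for i, c in enumerate(kmer):
        inner[i, _CODE[c]] = 1.0
    matrix = np.vstack([freqs[:flank], inner, freqs[flank:]])
    return FlankedPWM(source_kmer=kmer, matrix=matrix, n_occurrences=n, flank=flank)


#: Exact 6-mer sets operationalizing the promoter motif families.
MOTIF_FAMILIES: dict[str, frozenset[str]] = {
    "GAGA": frozenset(
        {"AAGAGA", "GAGAGA", "AAGAGG", "GAGAGG", "AGAGAA", "GGAGAA", "AGAGAG", "GGAGAG"}
    ),
    "TATA": frozenset(
        {"TATAAA", "TATATA", "ATATAA", "ATAAAT", "TAAATA", "ATATAT", "TTATAA", "TTATAT"}
    ),
    "telobox": frozenset({"AAACCC", "AACCCT", "ACCCAA", "ACCCTA"}),
    "ARGCCCAWT": frozenset(
        {"AAGCCC", "AGGCCC", "GGCCCA", "AGCCCA", "GCCCAA", "GCCCAT", "GGGCTT",
         "GGGCCT", "TGGGCC", "TGGGCT", "TTGGGC", "ATGGGC", "AATGGG", "CCCATT"}
    ),
}


def annotate_family(kmer: str, catalog: Mapping[str, frozenset[str]] = MOTIF_FAMILIES
                    ) -> str | None:
    """Exact membership lookup against the motif-family catalog."""
    for family, members in catalog.items():
        if kmer in members:
            return family
    return None


def positional_profile(
    sequences: Mapping[str, str] | Sequence[str], family_kmers: Iterable[str]
) -> np.ndarray:
    """Per-offset fraction of sequences with any family k-mer starting there.

    All sequences must share a common anchor and length.
    """
    seqs = list(sequences.values()) if isinstance(sequences, Mapping) else list(sequences)
    if not seqs:
        raise ValueError("no sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal length (shared anchor)")
    L = lengths.pop()
    family = [m.upper() for m in family_kmers]
    if not family:
        return np.zeros(L)
    k = len(family[0])
    profile = np.zeros(L - k + 1 if L >= k else 0)
    for seq in seqs:
        seq = seq.upper()
        hit = np.zeros(len(profile), dtype=bool)
        for m in family:
            for p in _occurrences(seq, m):
                hit[p] = True
        profile += hit
    return profile / len(seqs)


def conservation_per_kmer(
    kmer: str,
    sequences: Mapping[str, str],
    score_track: Mapping[str, np.ndarray],
) -> float:
    """Mean per-base conservation over every occurrence of the k-mer.

    ``score_track`` maps sequence id to a per-base score array aligned
    with the sequence; occurrences with any undefined (NaN) base are
    dropped and logged.
    """
    k = len(kmer)
    total, n_bases, dropped = 0.0, 0, 0
    for sid, seq in sequences.items():
        scores = np.asarray(score_track.get(sid, []), dtype=float)
        for p in _occurrences(seq.upper(), kmer):
            if p + k > len(scores):
                dropped += 1
                continue
            window = scores[p:p + k]
            if np.any(np.isnan(window)):
                dropped += 1
                continue
            total += float(window.sum())
            n_bases += k
    if dropped:
        logger.info("conservation_per_kmer(%s): dropped %d occurrences without scores",
                    kmer, dropped)
    if n_bases == 0:
        raise ValueError(f"no scored occurrence of {kmer}")
    return total / n_bases


def compare_weight_tables(t1: KmerWeightTable, t2: KmerWeightTable) -> float:
    """Pearson correlation of the averaged weights over the k-mer space."""
    if t1.kmers != t2.kmers:
        raise ValueError("weight tables cover different k-mer spaces")
    a, b = t1.averaged.to_numpy(), t2.averaged.to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance weight table")
    return float(np.corrcoef(a, b)[0, 1])
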