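"""Random-forest modelling of writer binding from chromatin features.

The question: can a writer's target genes be predicted from the
chromatin landscape alone, and which features carry the signal? Bound
genes are the top-n genes by tag-minus-control ChIP signal in the
writer's occupancy region. Each of the (default 5) repeats downsamples
the unbound class to the bound-class size, fits a random forest on the
non-held-out genes, and records Gini importance; ROC/AUC is measured on
the held-out chromosome (or held-out fraction). In-silico ablation
zeroes all columns of a feature and nominates "lost genes": genes
predicted bound by at least one original repeat and unbound by at least
one ablated repeat.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve

from .features import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class BindingLabels:
    """Bound/unbound gene labels derived from ranked ChIP signal."""

    labels: pd.Series  # gene_id -> bool (True = bound)
    n_bound: int
    signal_descriptor: str = ""

    def __post_init__(self) -> None:
        if int(self.labels.sum()) != self.n_bound:
            raise ValueError("label count inconsistent with n_bound")

    @property
    def bound(self) -> list[str]:
        return list(self.labels.index[self.labels])

    @property
    def unbound(self) -> list[str]:
        return list(self.labels.index[~self.labels])


def label_bound(
    signal: Mapping[str, float] | pd.Series, n_top: int, descriptor: str = ""
) -> BindingLabels:
    """Label the top ``n_top`` genes by signal as bound.

    Boundary ties are broken by gene id ascending so the labelling is
    deterministic. Negative signals (control exceeding tag) rank
    normally.
    """
    s = pd.Series(dict(signal)) if not isinstance(signal, pd.Series) else signal.copy()
    if n_top > len(s):
        raise ValueError(f"n_top ({n_top}) exceeds gene count ({len(s)})")
    order = sorted(s.index, key=lambda g: (-s[g], g))
    bound = set(order[:n_top])
    labels = pd.Series({g: g in bound for g in s.index}, dtype=bool).loc[s.index]
    return BindingLabels(labels=labels, n_bound=n_top, signal_descriptor=descriptor)


def _resolve_holdout(holdout) -> tuple[str, object]:
    if isinstance(holdout, str):
        return "chromosome", holdout
    if isinstance(holdout, dict) and len(holdout) == 1:
        ((k, v),) = holdout.items()
        if k in ("chromosome", "fraction"):
            return k, v
    raise ValueError("holdout must be a chromosome name or {'chromosome'|'fraction': value}")


@dataclass
class RepeatFit:
    model: RandomForestClassifier
    train_genes: list[str]
    test_genes: list[str]
    sampled_unbound: list[str]
    seed: int


class BindingForest:
    """Balanced random-forest binding model with repeat aggregation.

    Parameters
    ----------
    matrix, labels:
        Feature table and bound/unbound labels; every labelled gene
        must be a matrix row.
    holdout:
        Chromosome name (genes on it are never used for fitting) or
        ``{"fraction": p}`` for a seeded stratified split.
    features:
        Optional column subset (e.g. a single predictor).
    """

    def __init__(
        self,
        matrix: FeatureMatrix,
        labels: BindingLabels,
        holdout: str | dict = "Chr5",
        n_repeats: int = 5,
        n_estimators: int = 500,
        features: Sequence[str] | None = None,
    ):
        missing = [g for g in labels.labels.index if g not in matrix.df.index]
        if missing:
            raise ValueError(f"{len(missing)} labelled genes missing from matrix")
        self.matrix = matrix
        self.labels = labels
        self.holdout_kind, self.holdout_value = _resolve_holdout(holdout)
        self.n_repeats = n_repeats
        self.n_estimators = n_estimators
        if features is not None:
            unknown = [f for f in features if f not in matrix.df.columns]
            if unknown:
                raise KeyError(f"unknown features: {unknown}")
            self.features = list(features)
        else:
            self.features = list(matrix.df.columns)
        zero_var = [f for f in self.features if matrix.df[f].nunique() <= 1]
        if zero_var:
            logger.warning("zero-variance features kept (importance 0): %s", zero_var)

    # -- partitioning ---------------------------------------------------------

    def _test_genes(self, rng: np.random.Generator) -> set[str]:
        y = self.labels.labels
        if self.holdout_kind == "chromosome":
            chroms = self.matrix.chromosomes
            test = {g for g in y.index if chroms[g] == self.holdout_value}
        else:
            p = float(self.holdout_value)
            test = set()
            for cls in (True, False):
                ids = np.array(sorted(y.index[y == cls]))
                k = int(round(p * len(ids)))
                test |= set(rng.choice(ids, size=k, replace=False))
        if not test:
            raise ValueError("holdout partition is empty")
        if not any(y[g] for g in test) or all(y[g] for g in test):
            raise ValueError("holdout partition lacks one of the classes")
        return test

    def fit(self, seed: int = 0) -> "BindingForestResults":
        y = self.labels.labels
        bound = sorted(y.index[y])
        unbound = sorted(y.index[~y])
        repeats: list[RepeatFit] = []
        for r in range(self.n_repeats):
            rep_seed = (seed + r) % (2**31)
            rng = np.random.default_rng(rep_seed)
            test = self._test_genes(rng)
            # downsample negatives first (from all unbound genes), then
            # exclude the holdout from fitting
            sampled = sorted(rng.choice(np.array(unbound), size=self.labels.n_bound,
                                        replace=False))
            train = [g for g in bound + sampled if g not in test]
            y_train = y.loc[train]
            if y_train.all() or not y_train.any():
                raise ValueError("training partition lacks one of the classes")
            clf = RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_features="sqrt",
                random_state=rep_seed,
                n_jobs=1,
            )
            clf.fit(self.matrix.df.loc[train, self.features].to_numpy(), y_train.to_numpy())
            repeats.append(
                RepeatFit(model=clf, train_genes=train, test_genes=sorted(test),
                          sampled_unbound=sampled, seed=rep_seed)
            )
        return BindingForestResults(model_spec=self, repeats=repeats, seed=seed)


@dataclass
class AblationResult:
    """Outcome of zeroing one feature's columns in a trained ensemble."""

    ablated: list[str]
    original_predictions: pd.DataFrame  # genes x repeats, bool
    ablated_predictions: pd.DataFrame
    lost_genes: set[str]


@dataclass
class BindingForestResults:
    """Aggregated repeats: importance mean +/- SD, per-repeat ROC/AUC."""

    model_spec: BindingForest
    repeats: list[RepeatFit]
    seed: int
    _importance: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def features(self) -> list[str]:
        return self.model_spec.features

    def _importance_table(self) -> pd.DataFrame:
        if self._importance is None:
            imp = np.array([r.model.feature_importances_ for r in self.repeats])
            self._importance = pd.DataFrame(
                {"mean": imp.mean(axis=0), "sd": imp.std(axis=0, ddof=1)},
                index=self.features,
            )
        return self._importance

    @property
    def importance_mean(self) -> pd.Series:
        return self._importance_table()["mean"]

    @property
    def importance_sd(self) -> pd.Series:
        return self._importance_table()["sd"]

    def _test_scores(self, rep: RepeatFit) -> tuple[np.ndarray, np.ndarray]:
        X = self.model_spec.matrix.df.loc[rep.test_genes, self.features].to_numpy()
        proba = rep.model.predict_proba(X)
        pos = list(rep.model.classes_).index(True)
        y = self.model_spec.labels.labels.loc[rep.test_genes].to_numpy()
        return y, proba[:, pos]

    @property
    def aucs(self) -> np.ndarray:
        return np.array([roc_auc_score(*self._test_scores(r)) for r in self.repeats])

    @property
    def auc_mean(self) -> float:
        return float(self.aucs.mean())

    @property
    def auc_sd(self) -> float:
        return float(self.aucs.std(ddof=1))

    def roc_curves(self) -> list[pd.DataFrame]:
        out = []
        for rep in self.repeats:
            y, score = self._test_scores(rep)
            fpr, tpr, thr = roc_curve(y, score)
            out.append(pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}))
        return out

    def predictions(self, matrix: FeatureMatrix | None = None) -> pd.DataFrame:
        """Per-repeat majority-vote class predictions for every gene."""
        m = matrix if matrix is not None else self.model_spec.matrix
        X = m.df[self.features].to_numpy()
        cols = {}
        for i, rep in enumerate(self.repeats):
            cols[f"repeat_{i}"] = rep.model.predict(X).astype(bool)
        return pd.DataFrame(cols, index=m.df.index)

    def ablate(self, feature_names: Sequence[str] | None = None,
               track: str | None = None) -> AblationResult:
        """Zero the named columns (or all columns of ``track``) and
        re-predict; a gene is lost when at least one repeat flips it
        from bound to unbound under the ablation.

        The per-repeat pairing makes the rule null-safe: an ablation
        that leaves every repeat's predictions unchanged (e.g. zeroing
        an all-zero column) loses no genes, whereas an unpaired
        "bound >=1 original and unbound >=1 ablated" reading would
        nominate every gene the repeats merely disagree on.
        """
        if track is not None:
            feature_names = self.model_spec.matrix.columns_for_track(track)
            if not feature_names:
                raise KeyError(f"no columns for track {track!r}")
        if not feature_names:
            raise ValueError("no features to ablate")
        zeroed = self.model_spec.matrix.zeroed(feature_names)
        orig = self.predictions()
        abl = self.predictions(zeroed)
        lost = set(orig.index[(orig & ~abl).any(axis=1)])
        return AblationResult(
            ablated=list(feature_names),
            original_predictions=orig,
            ablated_predictions=abl,
            lost_genes=lost,
        )

    def importance_frame(self) -> pd.DataFrame:
        tab = self._importance_table().copy()
        tab.index.name = "feature"
        return tab.reset_index()

    def summary(self) -> str:
        tab = self._importance_table().sort_values("mean", ascending=False)
        lines = [
            "Binding random forest",
            f"  repeats: {len(self.repeats)}  trees/repeat: {self.model_spec.n_estimators}",
            f"  holdout: {self.model_spec.holdout_kind}={self.model_spec.holdout_value}",
            f"  holdout AUC: {self.auc_mean:.3f} +/- {self.auc_sd:.3f}",
            "  importance (mean decrease in Gini, mean +/- SD over repeats):",
        ]
        for feat, row in tab.iterrows():
            lines.append(f"    {feat:<40s} {row['mean']:.4f} +/- {row['sd']:.4f}")
        return "\n".join(lines)


def single_feature_model(
    matrix: FeatureMatrix,
    labels: BindingLabels,
    feature_name: str,
    holdout: str | dict = "Chr5",
    n_repeats: int = 5,
    seed: int = 0,
    n_estimators: int = 500,
) -> BindingForestResults:
    """Fit the repeat ensemble with a single predictor column."""
    model = BindingForest(
        matrix, labels, holdout=holdout, n_repeats=n_repeats,
        n_estimators=n_estimators, features=[feature_name],
    )
    return model.fit(seed)
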