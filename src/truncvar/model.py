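"""Model/Results facade over the dual balanced boosted-tree pair.

`TruncatingVariantModel` holds a design matrix of per-variant features and
their 0/1 class targets; :meth:`~TruncatingVariantModel.fit` trains the two
balanced ensembles and returns a :class:`TruncatingVariantResults` carrying
the fitted pair, training-set scores, diagnostics, and a text summary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .boosting import BoostedModelPair, Hyperparams, train_pair
from .datatypes import ProteinRecord, TruncatingVariant
from .evaluation import EvalReport, confusion, metrics, roc_points
from .features import FeatureSchema, featurize_dataset
from .significance import GumbelNullResults


class TruncatingVariantModel:
    """Pathogenicity scorer for truncating variants.

    Parameters
    ----------
    exog : array-like of shape (n, p)
        Feature matrix (one row per labeled variant).
    endog : array-like of shape (n,)
        Binary targets: 1 for pathogenic, 0 for neutral.
    feature_names : sequence of str, optional
        Column names of ``exog``.
    hyperparams : Hyperparams, optional
        Boosting hyperparameters; defaults to shrinkage 0.005, 2000 trees,
        depth 8.
    """

    def __init__(
        self,
        exog,
        endog,
        feature_names: Optional[Sequence[str]] = None,
        hyperparams: Hyperparams | None = None,
    ):
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        self.endog = np.asarray(endog, dtype=float)
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("exog and endog disagree on sample count")
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise ValueError("endog must be binary 0/1")
        self.feature_names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{i}" for i in range(self.exog.shape[1])]
        )
        if len(self.feature_names) != self.exog.shape[1]:
            raise ValueError("feature_names length does not match exog")
        self.hyperparams = hyperparams or Hyperparams()

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        label_col: str = "label",
        hyperparams: Hyperparams | None = None,
    ) -> "TruncatingVariantModel":
        """Build from a feature table as written by ``featurize``.

        Non-feature bookkeeping columns (``protein_id``, ``position``,
        ``type``) are dropped; the label column may hold 0/1 or the strings
        ``pathogenic``/``neutral``.
        """
        if label_col not in frame.columns:
            raise ValueError(f"no {label_col!r} column in frame")
        labels = frame[label_col]
        if labels.dtype == object:
            unknown = set(labels) - {"pathogenic", "neutral"}
            if unknown:
                raise ValueError(f"unlabeled rows present: {sorted(unknown)!r}")
            endog = (labels == "pathogenic").to_numpy(dtype=float)
        else:
            endog = labels.to_numpy(dtype=float)
        drop = [c for c in ("protein_id", "position", "type", label_col)
                if c in frame.columns]
        features = frame.drop(columns=drop)
        return cls(
            features.to_numpy(dtype=float),
            endog,
            feature_names=list(features.columns),
            hyperparams=hyperparams,
        )

    @classmethod
    def from_cohort(
        cls,
        proteins: dict[str, ProteinRecord],
        variants: list[TruncatingVariant],
        schema: FeatureSchema | None = None,
        hyperparams: Hyperparams | None = None,
    ) -> "TruncatingVariantModel":
        """Featurize labeled variants of a cohort and build the model."""
        schema = schema or FeatureSchema.final46()
        labeled = [v for v in variants if v.label in ("pathogenic", "neutral")]
        frame, failures = featurize_dataset(proteins, labeled, schema)
        if failures:
            raise ValueError(
                f"{len(failures)} variants not featurizable; first: {failures[0][1]}"
            )
        return cls.from_dataframe(frame, hyperparams=hyperparams)

    def fit(self, seed: int = 0) -> "TruncatingVariantResults":
        """Train the dual balanced pair; deterministic given ``seed``."""
        pathogenic = self.exog[self.endog == 1.0]
        neutral = self.exog[self.endog == 0.0]
        pair = train_pair(pathogenic, neutral, seed=seed,
                          hyperparams=self.hyperparams)
        return TruncatingVariantResults(self, pair)


class TruncatingVariantResults:
    """Fitted dual-ensemble scorer with diagnostics.

    Attributes
    ----------
    pair : BoostedModelPair
        The two trained ensembles.
    fittedvalues : ndarray
        Averaged, clipped scores of the training samples.
    """

    def __init__(self, model: TruncatingVariantModel, pair: BoostedModelPair):
        self.model = model
        self.pair = pair
        self.fittedvalues = pair.predict(model.exog)
        self.null: Optional[GumbelNullResults] = None

    def predict(self, exog) -> np.ndarray:
        """Score new variants (mean of the two ensembles, clipped to [0,1])."""
        if isinstance(exog, pd.DataFrame):
            exog = exog[self.model.feature_names].to_numpy(dtype=float)
        return self.pair.predict(np.atleast_2d(np.asarray(exog, dtype=float)))

    def pvalues(self, exog=None) -> np.ndarray:
        """Extreme-value null p-values of scores (requires an attached null)."""
        if self.null is None:
            raise ValueError("no null attached; use attach_null() first")
        scores = self.fittedvalues if exog is None else self.predict(exog)
        return np.asarray(self.null.pvalue(scores))

    def attach_null(self, null: GumbelNullResults) -> None:
        """Attach a fitted extreme-value null for p-value annotation."""
        self.null = null

    def evaluate(self, exog=None, labels=None, cutoff: float = 0.5) -> EvalReport:
        """Metrics at a cutoff; defaults to the training data (in-sample)."""
        if exog is None:
            scores = self.fittedvalues
            labels = [
                "pathogenic" if y == 1.0 else "neutral" for y in self.model.endog
            ]
        else:
            if labels is None:
                raise ValueError("labels required when evaluating new data")
            scores = self.predict(exog)
            labels = [
                l if isinstance(l, str) else ("pathogenic" if l else "neutral")
                for l in labels
            ]
        report = metrics(confusion(scores, labels, cutoff=cutoff))
        try:
            report.roc_points = roc_points(scores, labels)
        except ValueError:
            report.roc_points = None
        return report

    def summary(self, cutoff: float = 0.5) -> str:
        hp = self.model.hyperparams
        n = self.model.endog.size
        n_pos = int(self.model.endog.sum())
        report = self.evaluate(cutoff=cutoff)
        lines = [
            "Truncating-variant pathogenicity model (dual balanced boosted trees)",
            "=====================================================================",
            f"samples               {n} ({n_pos} pathogenic, {n - n_pos} neutral)",
            f"features              {len(self.model.feature_names)}",
            f"trees per model       {hp.n_trees}",
            f"shrinkage             {hp.shrinkage}",
            f"max depth             {hp.max_depth}",
            f"split seed            {self.pair.split_seed}",
            "",
            f"In-sample metrics at cutoff {cutoff}:",
            report.summary(),
        ]
        return "\n".join(lines)

    def plot_roc(self, ax=None, exog=None, labels=None):
        """ROC curve (training data by default)."""
        import matplotlib.pyplot as plt

        report = self.evaluate(exog=exog, labels=labels)
        if report.roc_points is None:
            raise ValueError("ROC undefined: single-class data")
        if ax is None:
            _, ax = plt.subplots()
        pts = np.asarray(report.roc_points)
        ax.plot(pts[:, 0], pts[:, 1], "-")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        return ax

    def save(self, path: str | Path) -> None:
        self.pair.save(path)
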