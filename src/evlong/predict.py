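"""Longevity prediction from EV peptides under three encodings.

The cohort is split, stratified by group, into a discovery set (2/3; 16+16
for the 24+24 design) and a holdout set (1/3; 8+8) that is never touched
during fitting or feature selection. Three feature encodings are supported:

``complete_continuous``
    peptides with zero missingness, raw quantitative values;
``missing_binary``
    peptides with at least one missing value, encoded 1 = observed,
    0 = missing — detection itself is the feature;
``all_zero_imputed``
    every peptide as a continuous value with missing imputed as zero.

The classifier is L1-penalized logistic regression; the penalty weight is
chosen by grid search inside repeated stratified k-fold cross-validation on
the discovery samples only, and the selected peptides are the features with
nonzero weight in the final refit on all discovery samples. The published
analysis defers its exact selection algorithm to an unavailable supplement;
this implementation makes no claim of algorithmic fidelity to it — it is a
transparent, fully seeded sparse stand-in with the same interface contract
(discovery-only selection, AUC evaluation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, RepeatedStratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .quantify import LONG, PeptideQuantTable, SampleAnnotation
from .stats_core import auc_rank

ENCODING_MODES = ("complete_continuous", "missing_binary", "all_zero_imputed")


class LeakageError(RuntimeError):
    """Holdout samples reached the discovery side."""


@dataclass(frozen=True)
class SplitSpec:
    """Stratified discovery/holdout partition of sample ids."""

    discovery_ids: tuple[str, ...]
    holdout_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.discovery_ids) & set(self.holdout_ids):
            raise LeakageError("discovery and holdout sets overlap")


@dataclass(frozen=True)
class CVConfig:
    folds: int = 5
    repeats: int = 10
    seed: int = 0
    c_grid: tuple[float, ...] = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0)


@dataclass
class ModelResult:
    mode: str
    selected_peptides: list[str]
    weights: dict[str, float]
    cv_auc: float
    cv_config: CVConfig
    estimator: Pipeline | None = None
    feature_names: list[str] = field(default_factory=list)
    holdout_auc: float | None = None
    holdout_scores: pd.Series | None = None


def encode(table: PeptideQuantTable, mode: str) -> pd.DataFrame:
    """Feature matrix (samples x features) for one encoding mode."""
    if mode not in ENCODING_MODES:
        raise ValueError(f"unknown encoding mode {mode!r}")
    q = table.quantities
    mask = q.isna()
    any_missing = mask.any(axis=0)
    if mode == "complete_continuous":
        return q.loc[:, ~any_missing].copy()
    if mode == "missing_binary":
        return (~mask.loc[:, any_missing]).astype(float)
    return q.fillna(0.0)


def split_cohort(annotation: SampleAnnotation, seed: int, holdout_fraction: float = 1 / 3) -> SplitSpec:
    """Stratified split; each group contributes round(n * holdout_fraction)
    holdout samples. For a 24+24 cohort this is 16+16 / 8+8."""
    rng = np.random.default_rng(seed)
    discovery, holdout = [], []
    for group in sorted(annotation.groups.unique()):
        members = np.array(annotation.group_samples(group))
        n_hold = int(round(len(members) * holdout_fraction))
        if n_hold == 0 or n_hold == len(members):
            raise ValueError(f"group {group!r} too small for a stratified split")
        perm = rng.permutation(len(members))
        holdout.extend(members[perm[:n_hold]])
        discovery.extend(members[perm[n_hold:]])
    return SplitSpec(tuple(sorted(discovery)), tuple(sorted(holdout)))


def _is_binary(values: np.ndarray) -> bool:
    return bool(np.isin(np.unique(values), (0.0, 1.0)).all())


def fit_longevity_model(
    features: pd.DataFrame,
    labels: pd.Series,
    cv_config: CVConfig | None = None,
    mode: str = "unspecified",
) -> ModelResult:
    """Fit the sparse longevity classifier on discovery data only.

    ``labels`` is 1 for long-lived. Continuous features are z-scored inside
    each CV fold; all-binary matrices are left on the 0/1 scale. cv_auc is
    the mean held-fold AUC of the selected penalty; selected peptides are
    the nonzero-weight features of the final discovery refit.
    """
    cv_config = cv_config or CVConfig()
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in discovery labels")
    if features.shape[1] == 0:
        raise ValueError("empty feature matrix")
    X = features.to_numpy(dtype=float)
    informative = X.std(axis=0) > 0
    names = list(features.columns[informative])
    if not names:
        # nothing to learn from: a constant scorer, AUC 0.5 by convention
        return ModelResult(mode, [], {}, 0.5, cv_config, None, [])
    X = X[:, informative]
    steps = []
    if not _is_binary(X):
        steps.append(("scale", StandardScaler()))
    steps.append(
        ("clf", LogisticRegression(l1_ratio=1.0, solver="liblinear", max_iter=2000,
                                   random_state=cv_config.seed))
    )
    cv = RepeatedStratifiedKFold(
        n_splits=cv_config.folds, n_repeats=cv_config.repeats, random_state=cv_config.seed
    )
    search = GridSearchCV(
        Pipeline(steps),
        param_grid={"clf__C": list(cv_config.c_grid)},
        scoring="roc_auc",
        cv=cv,
        n_jobs=1,
        refit=True,
    )
    search.fit(X, y)
    coef = search.best_estimator_.named_steps["clf"].coef_.ravel()
    selected = [n for n, w in zip(names, coef) if w != 0.0]
    weights = {n: float(w) for n, w in zip(names, coef) if w != 0.0}
    return ModelResult(
        mode=mode,
        selected_peptides=selected,
        weights=weights,
        cv_auc=float(search.best_score_),
        cv_config=cv_config,
        estimator=search.best_estimator_,
        feature_names=names,
    )


def evaluate_holdout(
    model: ModelResult,
    holdout_features: pd.DataFrame,
    holdout_labels: pd.Series,
    discovery_ids=None,
) -> float:
    """Score the untouched holdout set with the fitted model; rank AUC.

    When ``discovery_ids`` is given, any overlap with the holdout index is a
    :class:`LeakageError`.
    """
    if discovery_ids is not None:
        overlap = set(discovery_ids) & set(holdout_features.index)
        if overlap:
            raise LeakageError(f"holdout overlaps discovery: {sorted(overlap)[:5]}")
    y = np.asarray(holdout_labels).astype(int)
    if model.estimator is None:
        scores = np.zeros(len(holdout_features))
    else:
        X = holdout_features[model.feature_names].to_numpy(dtype=float)
        scores = model.estimator.decision_function(X)
    auc = auc_rank(scores, y) if len(np.unique(y)) == 2 else float("nan")
    model.holdout_auc = auc
    model.holdout_scores = pd.Series(scores, index=holdout_features.index)
    return auc


def run_prediction(
    table: PeptideQuantTable,
    annotation: SampleAnnotation,
    modes=ENCODING_MODES,
    split_seed: int = 0,
    cv_config: CVConfig | None = None,
) -> dict[str, ModelResult]:
    """Split once, then fit and evaluate every requested encoding."""
    split = split_cohort(annotation, seed=split_seed)
    labels = (annotation.groups == LONG).astype(int)
    results: dict[str, ModelResult] = {}
    for mode in modes:
        feats = encode(table, mode)
        model = fit_longevity_model(
            feats.loc[list(split.discovery_ids)],
            labels.loc[list(split.discovery_ids)],
            cv_config=cv_config,
            mode=mode,
        )
        evaluate_holdout(
            model,
            feats.loc[list(split.holdout_ids)],
            labels.loc[list(split.holdout_ids)],
            discovery_ids=split.discovery_ids,
        )
        results[mode] = model
    return results
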