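"""Class-balanced ensemble of feature-selection + random-forest submodels.

Each submodel draws a balanced undersample (90% of the minority class from
each class, without replacement), runs stability selection on the *weighted*
z-scored subset, then trains a random forest (default 50 trees) on the
*unweighted* z-scored values of the selected features.  Prediction pools hard
votes: the confidence score is the fraction of submodels voting positive and
the final label is positive only on a strict majority.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .config import RunConfig
from .selection import StabilityProfile, lambda_grid, stability_select
from .weighting import (LabeledMatrix, WeightSet, ZTransform, apply_weights,
                        assemble_weights, statistical_weights, z_normalize)

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleError",
    "Submodel",
    "EnsembleModel",
    "PredictionResult",
    "FittedPipeline",
    "undersample",
    "train_submodel",
    "train_ensemble",
    "predict",
    "fit_pipeline",
    "pipeline_predict",
    "model_complexity",
    "feature_usage",
]


class EnsembleError(ValueError):
    pass


@dataclass
class Submodel:
    sample_ids: list
    features: list
    forest: RandomForestClassifier
    seed: int
    fallback_used: bool = False
    profile: StabilityProfile | None = None


@dataclass
class EnsembleModel:
    submodels: list
    weights: WeightSet
    config: RunConfig

    def __post_init__(self) -> None:
        if not self.submodels:
            raise EnsembleError("ensemble needs at least one submodel")


@dataclass
class PredictionResult:
    """Per-sample confidence (positive-vote fraction) and hard label."""

    confidence: pd.Series
    labels: pd.Series


def undersample(y: pd.Series, rng: np.random.Generator,
                fraction: float = 0.9) -> list:
    """Balanced subset: floor(fraction * minority size) ids from each class."""
    pos = y.index[y == 1]
    neg = y.index[y == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise EnsembleError("each class needs >= 2 samples to undersample")
    n_each = int(np.floor(fraction * min(len(pos), len(neg))))
    if n_each < 1:
        raise EnsembleError("undersample size is zero")
    take_pos = rng.choice(np.asarray(pos), size=n_each, replace=False)
    take_neg = rng.choice(np.asarray(neg), size=n_each, replace=False)
    return list(take_pos) + list(take_neg)


def train_submodel(matrix: LabeledMatrix, weights: WeightSet,
                   subset_ids: list, config: RunConfig,
                   seed: np.random.SeedSequence) -> Submodel:
    """Select features on the weighted subset, fit a forest on unweighted ones."""
    sub = matrix.subset(subset_ids)
    Xw = apply_weights(sub, weights)

    sel_seed, forest_seed_seq = seed.spawn(2)
    y = sub.y.to_numpy()
    nonzero_cols = Xw.columns[(Xw.abs().sum(axis=0) > 0)]
    grid = lambda_grid(Xw[nonzero_cols].to_numpy(), y,
                       n_values=config.lambda_grid_size,
                       ratio=config.lambda_grid_ratio)
    profile = stability_select(
        Xw[nonzero_cols].to_numpy(), y, grid,
        n_bootstraps=config.n_inner_bootstraps,
        threshold=config.stability_threshold,
        seed=sel_seed,
        min_lambda_hits=config.min_lambda_hits,
        feature_ids=list(nonzero_cols),
        tol=config.solver_tol, max_iter=config.solver_max_iter)
    selected = profile.selected

    fallback = False
    if not selected:
        if config.empty_selection == "top_k":
            ranked = weights.reindex(matrix.feature_ids).W.sort_values(
                ascending=False)
            selected = list(ranked.index[:config.fallback_top_k])
            fallback = True
            logger.warning("empty selected set; falling back to top-%d by weight",
                           config.fallback_top_k)
        else:
            raise EnsembleError("empty selected set and fallback disabled")

    forest_seed = int(forest_seed_seq.generate_state(1)[0] % (2**31 - 1))
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features="sqrt",
        bootstrap=True,
        random_state=forest_seed,
        n_jobs=1,
    )
    forest.fit(sub.X[selected].to_numpy(), y)
    return Submodel(sample_ids=list(subset_ids), features=list(selected),
                    forest=forest, seed=forest_seed, fallback_used=fallback,
                    profile=profile)


def train_ensemble(matrix: LabeledMatrix, weights: WeightSet,
                   config: RunConfig, seed: int) -> EnsembleModel:
    """Train ``config.n_submodels`` submodels on independent balanced draws.

    Per-submodel randomness is derived from the master seed with spawned
    `numpy` seed sequences, so ensembles are bit-reproducible.
    """
    if not matrix.z_scored:
        raise EnsembleError("train_ensemble expects a z-scored matrix")
    master = np.random.SeedSequence(seed)
    children = master.spawn(config.n_submodels)
    submodels = []
    for child in children:
        draw_seq, fit_seq = child.spawn(2)
        rng = np.random.default_rng(draw_seq)
        subset = undersample(matrix.y, rng, fraction=config.undersample_fraction)
        submodels.append(train_submodel(matrix, weights, subset, config, fit_seq))
    return EnsembleModel(submodels=submodels, weights=weights, config=config)


def predict(model: EnsembleModel, Xz: pd.DataFrame,
            tie_positive: bool | None = None) -> PredictionResult:
    """Pool submodel votes into confidences and strict-majority labels.

    ``Xz`` must already carry the training z-transform.  A confidence of
    exactly 0.5 maps to the negative label unless ``tie_positive``.
    """
    if tie_positive is None:
        tie_positive = model.config.tie_positive
    needed = set()
    for sm in model.submodels:
        needed.update(sm.features)
    missing = sorted(needed - set(Xz.columns))
    if missing:
        raise EnsembleError(f"missing feature columns: {missing}")

    votes = np.zeros(len(Xz))
    for sm in model.submodels:
        votes += sm.forest.predict(Xz[sm.features].to_numpy())
    conf = votes / len(model.submodels)
    if tie_positive:
        labels = (conf >= 0.5).astype(int)
    else:
        labels = (conf > 0.5).astype(int)
    return PredictionResult(
        confidence=pd.Series(conf, index=Xz.index, name="confidence"),
        labels=pd.Series(labels, index=Xz.index, name="label"))


def model_complexity(model: EnsembleModel) -> float:
    """Mean number of selected features per submodel."""
    return float(np.mean([len(sm.features) for sm in model.submodels]))


def feature_usage(model: EnsembleModel) -> pd.Series:
    """Number of submodels in which each feature is included."""
    counts: dict = {}
    for sm in model.submodels:
        for f in sm.features:
            counts[f] = counts.get(f, 0) + 1
    return pd.Series(counts, name="n_submodels").sort_values(ascending=False)


# ---------------------------------------------------------------------------
# end-to-end pipeline: raw table -> z-transform -> weights -> ensemble


@dataclass
class FittedPipeline:
    """Everything needed to score held-out samples."""

    ztransform: ZTransform
    weights: WeightSet
    model: EnsembleModel
    mode: str


def fit_pipeline(matrix: LabeledMatrix, meta, conservation: pd.DataFrame,
                 config: RunConfig, *, mode: str = "es",
                 seed: int = 0) -> FittedPipeline:
    """Fit z-transform, statistical weights, and the ensemble on one cohort.

    All data-dependent parameters (feature means/sds, WS) are estimated on
    ``matrix`` only, so passing a training fold leaks nothing from test data.
    """
    mz, tf = z_normalize(matrix)
    ws = statistical_weights(mz, log_base=config.ws_log_base,
                             equal_var=not config.welch_t)
    weights = assemble_weights(conservation, meta, ws, mode=mode)
    weights = weights.reindex(mz.feature_ids)
    model = train_ensemble(mz, weights, config, seed)
    return FittedPipeline(ztransform=tf, weights=weights, model=model, mode=mode)


def pipeline_predict(fitted: FittedPipeline, X: pd.DataFrame) -> PredictionResult:
    """Score raw (unnormalized) samples with the stored training transform."""
    Xz = fitted.ztransform.apply(X)
    return predict(fitted.model, Xz)
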