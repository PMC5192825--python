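"""Composite feature weights: evolutionary conservation + outcome association.

Molecular features inherit the evolutionary weight ``WE = 1/R`` of their gene;
clinical covariates, which have no conservation score, receive the maximum
molecular ``WE`` in the dataset.  The statistical weight ``WS`` is the negative
log (base 10 by default) of a two-sample t-test p-value per feature.  The
composite weight ``W = WE + WS`` multiplies z-scored feature values before
sparse selection, which is equivalent to an adaptive per-feature l1 penalty.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # keeps WS finite under underflow

__all__ = [
    "WeightingError",
    "FeatureMeta",
    "LabeledMatrix",
    "ZTransform",
    "WeightSet",
    "statistical_weights",
    "assemble_weights",
    "z_normalize",
    "apply_weights",
]


class WeightingError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureMeta:
    """Kind and gene link for one feature.

    ``kind`` is "molecular" (gene-linked) or "clinical" (no gene link).
    """

    feature_id: str
    kind: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("molecular", "clinical"):
            raise WeightingError(
                f"feature {self.feature_id!r}: unknown kind {self.kind!r}")
        if self.kind == "clinical" and self.gene_id is not None:
            raise WeightingError(
                f"clinical feature {self.feature_id!r} must not link a gene")


@dataclass
class LabeledMatrix:
    """Sample-by-feature table with binary outcome labels.

    ``y == 1`` is the positive / poor-outcome class.  ``feature_means`` and
    ``feature_sds`` are populated by :func:`z_normalize` so held-out samples
    can be transformed with training-set parameters.
    """

    X: pd.DataFrame
    y: pd.Series
    z_scored: bool = False
    feature_means: pd.Series | None = None
    feature_sds: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise WeightingError("sample ids of X and y disagree")
        if self.y.isna().any():
            raise WeightingError("missing outcome labels")
        bad = set(self.y.unique()) - {0, 1}
        if bad:
            raise WeightingError(f"labels must be 0/1, found {sorted(bad)}")
        if self.X.index.has_duplicates:
            raise WeightingError("duplicate sample ids")

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, sample_ids) -> "LabeledMatrix":
        return LabeledMatrix(self.X.loc[sample_ids], self.y.loc[sample_ids],
                             z_scored=self.z_scored,
                             feature_means=self.feature_means,
                             feature_sds=self.feature_sds)


@dataclass(frozen=True)
class ZTransform:
    """Per-feature center/scale fitted on training samples (ddof=1 sd)."""

    means: pd.Series
    sds: pd.Series

    @property
    def feature_ids(self) -> list[str]:
        return list(self.means.index)

    def apply(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.means.index if c not in X.columns]
        if missing:
            raise WeightingError(f"missing feature columns: {missing}")
        Xs = X[self.means.index]
        return (Xs - self.means) / self.sds


@dataclass(frozen=True)
class WeightSet:
    """Per-feature evolutionary, statistical, and composite weights."""

    table: pd.DataFrame  # index: feature_id; columns: WE, WS, W

    def __post_init__(self) -> None:
        for col in ("WE", "WS", "W"):
            if col not in self.table.columns:
                raise WeightingError(f"weight table lacks column {col!r}")

    @property
    def W(self) -> pd.Series:
        return self.table["W"]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table.index)

    def reindex(self, feature_ids) -> "WeightSet":
        missing = [f for f in feature_ids if f not in self.table.index]
        if missing:
            raise WeightingError(f"weights missing for features: {missing}")
        return WeightSet(self.table.loc[list(feature_ids)])


def statistical_weights(matrix: LabeledMatrix, *, log_base: float = 10.0,
                        equal_var: bool = True) -> pd.Series:
    """Two-sided two-sample t-test per feature, ``WS = -log(p)``.

    Pooled-variance (classic Student's) by default; set ``equal_var=False``
    for Welch.  P-values are floored at 1e-300.  A feature with zero variance
    in both classes gets p=1 (no association) when the class means agree and
    the floor otherwise, with a logged warning.
    """
    y = matrix.y.to_numpy()
    pos = matrix.X.to_numpy()[y == 1]
    neg = matrix.X.to_numpy()[y == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise WeightingError("each class needs >= 2 samples for the t test")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(pos, neg, axis=0, equal_var=equal_var)
    p = np.asarray(p, dtype=float)

    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.warning("zero-variance features in t test: %s",
                       [matrix.feature_ids[i] for i in np.flatnonzero(degenerate)])
        same_mean = np.isclose(pos.mean(axis=0), neg.mean(axis=0))
        p[degenerate & same_mean] = 1.0
        p[degenerate & ~same_mean] = P_FLOOR

    p = np.clip(p, P_FLOOR, 1.0)
    ws = -np.log(p) / np.log(log_base)
    return pd.Series(ws, index=matrix.feature_ids, name="WS")


def assemble_weights(conservation: pd.DataFrame,
                     meta: dict[str, FeatureMeta] | pd.DataFrame,
                     WS: pd.Series, *,
                     mode: str = "es") -> WeightSet:
    """Combine per-gene WE and per-feature WS into composite weights.

    ``conservation`` is indexed by gene_id with a ``WE`` column (as written by
    the rates step).  ``mode`` selects the four comparison variants:

    - ``"es"``: W = WE + WS (the composite model)
    - ``"e"``:  W = WE (statistical weight zeroed)
    - ``"s"``:  W = WS (evolutionary weight zeroed; the clinical rule then
      assigns max(0) = 0, so clinical features carry WS only)
    - ``"0"``:  all weights equal 1 (unweighted)
    """
    if mode not in ("es", "e", "s", "0"):
        raise WeightingError(f"unknown weighting mode {mode!r}")
    metas = _as_meta_map(meta)

    we = pd.Series(0.0, index=WS.index, name="WE")
    if mode in ("es", "e"):
        gene_we = conservation["WE"]
        molecular = [f for f in WS.index if metas[f].kind == "molecular"]
        if not molecular:
            raise WeightingError(
                "no molecular features: clinical max-WE rule is undefined")
        for f in molecular:
            gid = metas[f].gene_id
            if gid is None or gid not in gene_we.index:
                raise WeightingError(
                    f"molecular feature {f!r} has no gene conservation entry")
            we[f] = gene_we[gid]
        clinical_we = we[molecular].max()
        for f in WS.index:
            if metas[f].kind == "clinical":
                we[f] = clinical_we

    ws = WS.astype(float).copy() if mode in ("es", "s") else pd.Series(
        0.0, index=WS.index, name="WS")
    if (ws < 0).any():
        raise WeightingError("negative WS values")

    w = we + ws
    if mode == "0":
        w = pd.Series(1.0, index=WS.index)
    table = pd.DataFrame({"WE": we, "WS": ws, "W": w})
    return WeightSet(table)


def _as_meta_map(meta) -> dict[str, FeatureMeta]:
    if isinstance(meta, dict):
        return meta
    out = {}
    for _, row in meta.iterrows():
        gid = row.get("gene_id")
        if gid is not None and (pd.isna(gid) or gid == ""):
            gid = None
        out[row["feature_id"]] = FeatureMeta(row["feature_id"], row["kind"], gid)
    return out


def z_normalize(matrix: LabeledMatrix) -> tuple[LabeledMatrix, ZTransform]:
    """Center and scale every feature to mean 0, sd 1 (sample sd, ddof=1).

    Zero-variance features are dropped with a warning.  The returned
    :class:`ZTransform` replays the training-set transform on held-out data.
    """
    if matrix.z_scored:
        raise WeightingError("matrix is already z-scored")
    means = matrix.X.mean(axis=0)
    sds = matrix.X.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.any():
        raise WeightingError("all features have zero variance")
    dropped = [c for c, k in keep.items() if not k]
    if dropped:
        logger.warning("dropping zero-variance features: %s", dropped)
    means, sds = means[keep], sds[keep]
    tf = ZTransform(means=means, sds=sds)
    Xz = tf.apply(matrix.X)
    out = LabeledMatrix(Xz, matrix.y.copy(), z_scored=True,
                        feature_means=means, feature_sds=sds)
    return out, tf


def apply_weights(matrix: LabeledMatrix, weights: WeightSet) -> pd.DataFrame:
    """Weighted feature matrix ``f^w_ij = W_i * f_ij`` (input untouched)."""
    if not matrix.z_scored:
        raise WeightingError("apply_weights expects a z-scored matrix")
    w = weights.reindex(matrix.feature_ids).W
    return matrix.X * w
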