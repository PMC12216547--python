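"""Stage-specific expression programs via self-organizing-map clustering.

Timepoint-mean profiles are z-scored per feature (population sd), grouped
on a small rectangular SOM grid trained online for a fixed number of
iterations, refined by dropping clusters whose members sit far from their
prototype (mean member distance at or above the 75th percentile of all
feature-to-prototype distances), and finally labeled with a developmental
stage when a cluster's median profile peaks inside one stage by a clear
margin.

The SOM here is deliberately simple and fully deterministic given a seed:
codebook initialization samples data rows, one randomly chosen feature
updates its best-matching unit (BMU) and grid neighbors per iteration,
learning rate decays linearly from 0.05 to 0.01 and the (bubble)
neighborhood radius from ceil(max(grid)/2) to 1. Distance ties resolve to
the lowest cell id.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from devodyn.omics_io import ExpressionMatrix, Scale

logger = logging.getLogger(__name__)


def zscore_profiles(means: ExpressionMatrix | pd.DataFrame) -> ExpressionMatrix:
    """Z-score each feature's profile across timepoints (population sd).

    Constant (zero-sd) features cannot be standardized and are dropped with
    a logged warning.
    """
    df = means.observed() if isinstance(means, ExpressionMatrix) else pd.DataFrame(means)
    x = df.to_numpy(dtype=float)
    mu = np.nanmean(x, axis=1, keepdims=True)
    sd = np.nanstd(x, axis=1, keepdims=True)
    flat = (sd == 0).ravel() | np.isnan(sd).ravel()
    if flat.any():
        logger.warning("dropping %d constant feature(s) before z-scoring", int(flat.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    out = pd.DataFrame(z, index=df.index, columns=df.columns).loc[~flat]
    return ExpressionMatrix(out, Scale.zscore)


class SOMClusterer(ClusterMixin, BaseEstimator):
    """Online self-organizing map on a rectangular grid.

    Parameters
    ----------
    grid_shape : (rows, cols) of the SOM grid; cells are numbered row-major.
    n_iter : number of single-feature online updates (default 1000).
    learning_rate : (initial, final), decaying linearly over iterations.
    radius : optional (initial, final) bubble-neighborhood radius in grid
        units; defaults to (ceil(max(grid_shape)/2), 1).
    random_state : seed controlling initialization and update order.

    Attributes
    ----------
    codebook_ : (n_cells, n_features) prototype matrix.
    labels_ : best-matching unit per input row (ties -> lowest cell id).
    distances_ : Euclidean distance of each row to its BMU.
    """

    def __init__(self, grid_shape=(4, 4), n_iter=1000,
                 learning_rate=(0.05, 0.01), radius=None, random_state=None):
        self.grid_shape = grid_shape
        self.n_iter = n_iter
        self.learning_rate = learning_rate
        self.radius = radius
        self.random_state = random_state

    def _grid_coords(self) -> np.ndarray:
        rows, cols = self.grid_shape
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a nonempty 2-d array")
        if not np.isfinite(X).all():
            raise ValueError("X must be finite (z-score profiles)")
        rows, cols = self.grid_shape
        n_cells = rows * cols
        if X.shape[0] < n_cells:
            raise ValueError(f"need >= {n_cells} features for a {rows}x{cols} grid")
        rng = np.random.default_rng(self.random_state)
        coords = self._grid_coords()
        codebook = X[rng.choice(X.shape[0], size=n_cells, replace=False)].copy()

        lr0, lr1 = self.learning_rate
        if self.radius is None:
            r0, r1 = float(math.ceil(max(self.grid_shape) / 2)), 1.0
        else:
            r0, r1 = map(float, self.radius)
        denom = max(self.n_iter - 1, 1)
        for t in range(self.n_iter):
            frac = t / denom
            lr = lr0 + (lr1 - lr0) * frac
            radius = r0 + (r1 - r0) * frac
            x = X[rng.integers(X.shape[0])]
            bmu = int(np.argmin(np.linalg.norm(codebook - x, axis=1)))
            nb = np.linalg.norm(coords - coords[bmu], axis=1) <= radius
            codebook[nb] += lr * (x - codebook[nb])

        d = np.linalg.norm(X[:, None, :] - codebook[None, :, :], axis=2)
        self.codebook_ = codebook
        self.labels_ = d.argmin(axis=1)  # argmin takes the lowest index on ties
        self.distances_ = d[np.arange(X.shape[0]), self.labels_]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "codebook_")
        X = np.asarray(X, dtype=float)
        d = np.linalg.norm(X[:, None, :] - self.codebook_[None, :, :], axis=2)
        return d.argmin(axis=1)


@dataclass
class ClusterModel:
    """Trained SOM with refinement and stage annotations.

    ``assignment`` maps each feature to its BMU cell, ``distance`` to the
    Euclidean distance from its prototype. ``kept`` flags clusters that
    survive refinement; ``stage_label`` holds a stage name for kept
    clusters with stage-specific dynamics, NaN otherwise. ``data`` retains
    the z-profiles the map was trained on (needed for median profiles).
    """

    codebook: pd.DataFrame  # cells x timepoints
    grid_shape: tuple[int, int]
    assignment: pd.Series  # feature -> cell id
    distance: pd.Series
    kept: pd.Series  # cell -> bool
    stage_label: pd.Series  # cell -> stage or NaN
    data: pd.DataFrame  # features x timepoints z-profiles
    params: dict = field(default_factory=dict)
    feature_kept: Optional[pd.Series] = None

    @property
    def n_cells(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def members(self, cell: int) -> pd.Index:
        return self.assignment.index[self.assignment == cell]

    def retained_features(self) -> pd.Index:
        """Features in kept clusters (post-refinement analysis set)."""
        if self.feature_kept is not None:
            return self.feature_kept.index[self.feature_kept]
        keep_cells = set(self.kept.index[self.kept])
        return self.assignment.index[self.assignment.isin(keep_cells)]

    def feature_stage(self) -> pd.Series:
        """Per retained feature, the stage label of its cluster ('none' if unlabeled)."""
        lab = self.stage_label.fillna("none")
        feats = self.retained_features()
        return self.assignment.loc[feats].map(lab)


def train_som(z: ExpressionMatrix | pd.DataFrame, grid_shape=(4, 4),
              iterations: int = 1000, seed: Optional[int] = None,
              learning_rate=(0.05, 0.01)) -> ClusterModel:
    """Train the online SOM on z-scored profiles and assign every feature."""
    df = z.values if isinstance(z, ExpressionMatrix) else pd.DataFrame(z)
    som = SOMClusterer(grid_shape=grid_shape, n_iter=iterations,
                       learning_rate=learning_rate, random_state=seed)
    som.fit(df.to_numpy(dtype=float))
    cells = pd.RangeIndex(som.codebook_.shape[0])
    return ClusterModel(
        codebook=pd.DataFrame(som.codebook_, index=cells, columns=df.columns),
        grid_shape=tuple(grid_shape),
        assignment=pd.Series(som.labels_, index=df.index),
        distance=pd.Series(som.distances_, index=df.index),
        kept=pd.Series(True, index=cells),
        stage_label=pd.Series(np.nan, index=cells, dtype=object),
        data=df.copy(),
        params={"iterations": iterations, "seed": seed,
                "learning_rate": tuple(learning_rate),
                "radius": (math.ceil(max(grid_shape) / 2), 1)},
    )


def refine_clusters(model: ClusterModel, percentile: float = 75.0,
                    member_level: bool = False) -> ClusterModel:
    """Drop incoherent clusters by mean member distance to the prototype.

    The threshold is the ``percentile``-th percentile of all pooled
    feature-to-BMU distances; a cluster is kept iff its mean member
    distance is strictly below it. Empty clusters are dropped. Features of
    dropped clusters leave the downstream analysis set (not reassigned).
    With ``member_level=True``, individual features at or above the
    threshold are additionally excluded even inside kept clusters.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    pooled = model.distance.to_numpy(dtype=float)
    threshold = float(np.percentile(pooled, percentile))
    kept = {}
    for cell in model.kept.index:
        members = model.members(cell)
        kept[cell] = bool(len(members)) and float(model.distance.loc[members].mean()) < threshold
    kept_s = pd.Series(kept)
    feature_kept = model.assignment.map(kept_s).astype(bool)
    if member_level:
        feature_kept &= model.distance < threshold
    out = ClusterModel(model.codebook, model.grid_shape, model.assignment,
                       model.distance, kept_s, model.stage_label.copy(),
                       model.data, dict(model.params), feature_kept)
    out.params.update({"refine_percentile": percentile,
                       "refine_threshold": threshold,
                       "member_level": member_level})
    return out


def assign_stage(model: ClusterModel, stage_of: dict[str, str],
                 margin: float = 1.0) -> ClusterModel:
    """Label kept clusters whose median profile is stage-specific.

    A kept cluster gets stage S iff the member-wise median z-profile
    reaches its maximum at a timepoint of S and the profile's mean over S
    exceeds its mean over every other single stage by more than ``margin``
    (z units). Comparing against the best competing stage rather than the
    pooled complement keeps a profile with two equally high stages
    unlabeled. Anything else stays unlabeled too.
    """
    stages = pd.Series([stage_of[t] for t in model.codebook.columns],
                       index=model.codebook.columns)
    labels = pd.Series(np.nan, index=model.kept.index, dtype=object)
    for cell in model.kept.index[model.kept]:
        members = model.members(cell)
        if model.feature_kept is not None:
            members = members.intersection(model.feature_kept.index[model.feature_kept])
        if len(members) == 0:
            continue
        profile = model.data.loc[members].median(axis=0)
        peak_stage = stages[profile.idxmax()]
        stage_means = profile.groupby(stages).mean()
        others = stage_means.drop(peak_stage)
        if stage_means[peak_stage] - others.max() > margin:
            labels[cell] = peak_stage
    out = ClusterModel(model.codebook, model.grid_shape, model.assignment,
                       model.distance, model.kept.copy(), labels, model.data,
                       dict(model.params), model.feature_kept)
    out.params["stage_margin"] = margin
    return out
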