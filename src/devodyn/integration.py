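"""Transcript-protein integration: correlations, index, cluster grouping.

Gene-wise agreement between the transcript and protein layers is measured
by the Pearson correlation of a gene's timepoint-mean profiles, with a
two-sided p-value from the exact t-transform (t = r * sqrt((n-2)/(1-r^2)),
n-2 degrees of freedom) and a three-way classification: positive (R > 0,
p < alpha), negative (R < 0, p < alpha), none otherwise or when R is
undefined (constant profile on either layer).

The transcript-protein index summarizes, per cluster of the joint SOM and
per stage, the mean difference between normalized transcript and protein
expression (z units): coherent clusters sit near 0, transcript-led
clusters are positive, protein-led negative. K-means over the cluster x
stage index matrix groups clusters with similar decoupling patterns.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from devodyn.omics_io import ExpressionMatrix, SampleSheet
from devodyn.stats_enrichment import bh_adjust, hypergeom_tail
from devodyn.stage_clustering import ClusterModel

logger = logging.getLogger(__name__)


def _as_frame(m) -> pd.DataFrame:
    return m.observed() if isinstance(m, ExpressionMatrix) else pd.DataFrame(m)


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson R and two-sided p (t-transform, n-2 df).

    Rows with a constant profile on either side yield NaN R and p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum(axis=1))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc).sum(axis=1) / denom
    r = np.where(denom == 0, np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, np.where(np.isinf(t), 0.0, p))
    return r, p


def classify_correlation(r: np.ndarray, p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """positive / negative (significant at alpha, by sign) or none."""
    out = np.full(r.shape, "none", dtype=object)
    sig = ~np.isnan(p) & (p < alpha)
    out[sig & (r > 0)] = "positive"
    out[sig & (r < 0)] = "negative"
    return out


def timepointwise_correlation(tx_means, prot_means, min_genes: int = 3) -> pd.DataFrame:
    """Timepoint x timepoint Pearson matrix across shared genes.

    Cell (i, j) correlates transcript expression at timepoint i with
    protein expression at timepoint j over all shared, complete genes.
    """
    tx = _as_frame(tx_means)
    prot = _as_frame(prot_means)
    genes = tx.index.intersection(prot.index)
    tx, prot = tx.loc[genes], prot.loc[genes]
    complete = ~(tx.isna().any(axis=1) | prot.isna().any(axis=1))
    tx, prot = tx.loc[complete], prot.loc[complete]
    if tx.shape[0] < min_genes:
        raise ValueError(f"fewer than {min_genes} shared complete genes")
    a = tx.to_numpy(dtype=float)
    b = prot.to_numpy(dtype=float)
    a = (a - a.mean(axis=0)) / a.std(axis=0)
    b = (b - b.mean(axis=0)) / b.std(axis=0)
    corr = a.T @ b / a.shape[0]
    return pd.DataFrame(corr, index=tx.columns, columns=prot.columns)


def genewise_correlation(tx_means, prot_means, genes: Optional[Iterable[str]] = None,
                         alpha: float = 0.05, min_timepoints: int = 3) -> pd.DataFrame:
    """Per-gene Pearson correlation between layers at matched timepoints.

    Both inputs must share the timepoint grid (identical columns). Returns
    a table of R, p and class per gene; genes with fewer than
    ``min_timepoints`` complete paired timepoints are skipped with a
    warning, constant profiles yield class "none".
    """
    tx = _as_frame(tx_means)
    prot = _as_frame(prot_means)
    if list(tx.columns) != list(prot.columns):
        raise ValueError("transcript and protein matrices must share timepoints")
    shared = tx.index.intersection(prot.index)
    if genes is not None:
        shared = shared.intersection(pd.Index(genes))
    tx, prot = tx.loc[shared], prot.loc[shared]
    complete = ~(tx.isna().any(axis=1) | prot.isna().any(axis=1))
    n_skipped = int((~complete).sum())  # incomplete profiles: would change n per gene
    paired_ok = complete & (tx.shape[1] >= min_timepoints)
    if tx.shape[1] < min_timepoints:
        raise ValueError("need >= 3 timepoints")
    if n_skipped:
        logger.warning("skipping %d gene(s) with incomplete paired profiles", n_skipped)
    tx, prot = tx.loc[paired_ok], prot.loc[paired_ok]
    r, p = pearson_with_p(tx.to_numpy(), prot.to_numpy())
    if np.isnan(r).any():
        logger.warning("%d gene(s) with constant profile -> class none",
                       int(np.isnan(r).sum()))
    return pd.DataFrame({"R": r, "p": p,
                         "class": classify_correlation(r, p, alpha)}, index=tx.index)


def detected_in_min_replicates(m: ExpressionMatrix, sheet: SampleSheet,
                               min_reps: int = 4) -> pd.Index:
    """Features observed in >= min_reps replicates of at least one timepoint."""
    observed = ~m.missing_mask
    hit = pd.Series(False, index=m.feature_ids)
    for tp in sheet.timepoints:
        samples = [s for s in sheet.samples_of_timepoint(tp) if s in m.sample_ids]
        if samples:
            hit |= observed[samples].sum(axis=1) >= min_reps
    return m.feature_ids[hit]


def cpm_expressed(tx: ExpressionMatrix, min_cpm: float = 10.0,
                  min_samples: int = 3) -> pd.Index:
    """Transcripts with CPM > min_cpm in at least min_samples samples."""
    obs = tx.observed()
    return tx.feature_ids[(obs > min_cpm).sum(axis=1) >= min_samples]


def tp_index(assignment: ClusterModel | pd.Series, tx_z, prot_z,
             stage_of: dict[str, str], agg: str = "mean") -> pd.DataFrame:
    """Transcript-protein index per (cluster, stage).

    Per gene and timepoint the difference tx_z - prot_z is taken, averaged
    over each stage's timepoints, then aggregated (mean by default, median
    with ``agg="median"``) over the member genes of each cluster. Genes
    missing one layer are excluded with a warning.
    """
    if isinstance(assignment, ClusterModel):
        feats = assignment.retained_features()
        assignment = assignment.assignment.loc[feats]
    tx = _as_frame(tx_z)
    prot = _as_frame(prot_z)
    if list(tx.columns) != list(prot.columns):
        raise ValueError("layers must share the timepoint grid")
    genes = assignment.index
    have_both = genes.isin(tx.index) & genes.isin(prot.index)
    if (~have_both).any():
        logger.warning("excluding %d gene(s) missing one layer", int((~have_both).sum()))
    genes = genes[have_both]
    assignment = assignment.loc[genes]
    diff = tx.loc[genes] - prot.loc[genes]
    stages = pd.Series([stage_of[t] for t in diff.columns], index=diff.columns)
    per_stage = diff.T.groupby(stages).mean().T  # gene x stage
    grouped = per_stage.groupby(assignment)
    table = grouped.median() if agg == "median" else grouped.mean()
    table.index.name = "cluster_id"
    if table.isna().to_numpy().any():
        raise ValueError("non-finite transcript-protein index")
    return table


def group_clusters_kmeans(tpindex: pd.DataFrame, k: int = 4,
                          seed: Optional[int] = None, n_init: int = 50) -> pd.Series:
    """Group clusters by similarity of their stage-wise index patterns.

    Euclidean k-means with k-means++ seeding, best of ``n_init`` restarts;
    deterministic given ``seed``. Returns one group label (0..k-1) per
    cluster row.
    """
    if k > len(tpindex):
        raise ValueError("k exceeds the number of clusters")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(tpindex.to_numpy(dtype=float))
    return pd.Series(labels, index=tpindex.index, name="group")


def cluster_overlap_test(tx_model: ClusterModel | pd.Series,
                         prot_model: ClusterModel | pd.Series) -> pd.DataFrame:
    """Fisher enrichment of overlap between transcript and protein clusters.

    For every (transcript cluster, protein cluster) pair, a one-tailed
    Fisher/hypergeometric test of membership overlap over the universe of
    genes present in both analyses, BH-adjusted across all pairs.
    """
    tx_assign = tx_model.assignment if isinstance(tx_model, ClusterModel) else tx_model
    prot_assign = prot_model.assignment if isinstance(prot_model, ClusterModel) else prot_model
    universe = tx_assign.index.intersection(prot_assign.index)
    if len(universe) == 0:
        raise ValueError("empty shared gene universe")
    tx_assign = tx_assign.loc[universe]
    prot_assign = prot_assign.loc[universe]
    N = len(universe)
    rows = []
    for tc in sorted(tx_assign.unique()):
        a = set(tx_assign.index[tx_assign == tc])
        for pc in sorted(prot_assign.unique()):
            b = set(prot_assign.index[prot_assign == pc])
            k = len(a & b)
            rows.append((tc, pc, k, len(a), len(b),
                         hypergeom_tail(k, len(a), len(b), N)))
    out = pd.DataFrame(rows, columns=["tx_cluster", "prot_cluster", "overlap",
                                      "tx_size", "prot_size", "p"])
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out
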