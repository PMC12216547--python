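"""Expression dynamicity: Gini ratio, variability filters, detection sets.

A gene's temporal dynamicity is scored with the Gini ratio of its
per-timepoint quantifications,

    G = sum_i sum_j |x_i - x_j| / (2 n^2 mu),

where n is the number of timepoints and mu the mean quantification. G is 0
for a perfectly stable gene and approaches 1 when expression concentrates
in a single timepoint; a threshold of 0.1 splits the proteome into stable
and dynamic fractions.

Variability filtering keeps the top P% most variable features by
interquartile range (IQR) across timepoint means; stage detection reports,
per feature, the stages in which it was observed at all, yielding
stage-exclusive sets and the core proteome quantified in every stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from devodyn.omics_io import ExpressionMatrix, SampleSheet, Scale, STAGES


def gini_ratio(x) -> float:
    """Gini ratio of a nonnegative per-timepoint quantification vector.

    Computed as the mean absolute pairwise difference normalized by twice
    the mean: ``sum_ij |x_i - x_j| / (2 n^2 mu)``. Scale-invariant and 0
    for constant vectors.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d vector with n >= 2 timepoints")
    if not np.isfinite(x).all():
        raise ValueError("non-finite quantification")
    if (x < 0).any():
        raise ValueError("quantifications must be nonnegative")
    mu = x.mean()
    if mu == 0:
        raise ValueError("mean quantification is zero; Gini undefined")
    # sum_ij |x_i - x_j| via the sorted-vector identity (O(n log n))
    s = np.sort(x)
    if s[0] == s[-1]:  # constant vector: exactly zero, no float residue
        return 0.0
    n = s.size
    ranks = np.arange(1, n + 1)
    total = 2.0 * np.sum((2 * ranks - n - 1) * s)
    return float(total / (2.0 * n * n * mu))


def gini_table(means: ExpressionMatrix, threshold: float = 0.1,
               min_timepoints: int = 2,
               on_linear: Optional[bool] = None) -> pd.DataFrame:
    """Per-feature Gini ratio over timepoint means, with stable/dynamic class.

    The Gini ratio is taken on linear quantifications: a log2-scale matrix
    is exponentiated first (``on_linear=True``, the default for log2
    scales), because on log-transformed intensities the normalized mean
    difference collapses toward zero and the stable/dynamic threshold
    loses meaning. ``mean_level`` reports the mean on the input scale
    (log2 for log2 inputs). Features with fewer than ``min_timepoints``
    observed timepoints or a zero mean are skipped. Columns: G, mu, n,
    mean_level, class.
    """
    if on_linear is None:
        on_linear = means.scale in (Scale.lfq_log2, Scale.cpm_log2)
    obs = means.observed()
    rows = {}
    for gene, row in obs.iterrows():
        x = row.dropna().to_numpy(dtype=float)
        if x.size < min_timepoints:
            continue
        q = np.power(2.0, x) if on_linear else x
        if q.mean() == 0:
            continue
        rows[gene] = (gini_ratio(q), q.mean(), q.size, x.mean())
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=["G", "mu", "n", "mean_level"])
    table.index.name = "feature_id"
    return classify_dynamicity(table, threshold)


def classify_dynamicity(table: pd.DataFrame, threshold: float = 0.1) -> pd.DataFrame:
    """Label each feature stable (G <= threshold, ties stable) or dynamic."""
    out = table.copy()
    out["class"] = np.where(out["G"] > threshold, "dynamic", "stable")
    return out


def variability_filter(means: ExpressionMatrix, top_percent: float) -> pd.Index:
    """Keep the top ``top_percent``% most temporally variable features.

    Variability is the IQR of a feature's timepoint means; the cutoff is
    the (100 - top_percent)th linear-interpolation quantile of all
    features' IQRs (zero-IQR features included), and features with
    IQR >= cutoff are kept — so exact ties at the cutoff survive.
    """
    if not 0 < top_percent <= 100:
        raise ValueError("top_percent must lie in (0, 100]")
    obs = means.observed()
    if obs.shape[1] < 2:
        raise ValueError("need >= 2 timepoints")
    q3 = obs.quantile(0.75, axis=1)
    q1 = obs.quantile(0.25, axis=1)
    iqr = (q3 - q1).fillna(0.0)
    cutoff = np.percentile(iqr.to_numpy(), 100.0 - top_percent)
    return iqr.index[iqr >= cutoff]


@dataclass
class StageDetection:
    """Per-feature stage detection flags, exclusive sets and Venn counts."""

    detected: pd.DataFrame  # features x stages, boolean

    @property
    def core(self) -> pd.Series:
        """Features quantified in every stage (AND over stages)."""
        return self.detected.all(axis=1)

    def exclusive(self, stage: str) -> pd.Index:
        others = [s for s in self.detected.columns if s != stage]
        mask = self.detected[stage] & ~self.detected[others].any(axis=1)
        return self.detected.index[mask]

    def venn_counts(self) -> dict[frozenset, int]:
        """Count features per detection pattern (nonempty stage subsets)."""
        counts: dict[frozenset, int] = {}
        stages = list(self.detected.columns)
        for _, row in self.detected.iterrows():
            key = frozenset(s for s in stages if row[s])
            if key:
                counts[key] = counts.get(key, 0) + 1
        return counts


def detection_and_core(prot: ExpressionMatrix, sheet: SampleSheet,
                       min_reps: int = 1) -> StageDetection:
    """Stage-wise detection from a non-imputed protein matrix.

    A feature counts as detected in a stage iff it is observed in at least
    ``min_reps`` replicates of at least one timepoint of that stage.
    Imputed matrices are rejected: imputation erases the missingness signal
    this analysis relies on.
    """
    if prot.is_imputed:
        raise ValueError("detection requires a non-imputed matrix")
    observed = ~prot.missing_mask
    stage_tps = sheet.stage_timepoints()
    cols = {}
    for stage in [s for s in STAGES if s in stage_tps]:
        hit = pd.Series(False, index=prot.feature_ids)
        for tp in stage_tps[stage]:
            samples = [s for s in sheet.samples_of_timepoint(tp) if s in prot.sample_ids]
            if samples:
                hit |= observed[samples].sum(axis=1) >= min_reps
        cols[stage] = hit
    return StageDetection(pd.DataFrame(cols))
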