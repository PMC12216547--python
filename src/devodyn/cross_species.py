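"""Cross-species ortholog comparison with timepoint-grid alignment.

Two species sampled on different developmental grids are compared by (i)
joining their matrices through a strict one-to-one ortholog map, (ii)
aligning each stage's timepoint series to a common length with a
normalized moving average (valid-mode convolution with a uniform kernel of
width w = m - k + 1, which maps 7 larval timepoints to 4 and 5 pupal
timepoints to 4), and (iii) correlating ortholog profiles over the
concatenated stage-ordered aligned series, overall and per stage.

A circular-convolution variant (which wraps the time axis) is available
for comparison but is not the default: a developmental trajectory has no
periodic boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from devodyn.omics_io import ExpressionMatrix, SampleSheet, STAGES
from devodyn.integration import classify_correlation, pearson_with_p
from devodyn.dynamicity import variability_filter

logger = logging.getLogger(__name__)


def load_ortholog_map(path: str | Path) -> pd.DataFrame:
    """Read a 2-column TSV of ortholog pairs and enforce one-to-one mapping.

    Any gene appearing in more than one pair — on either side — removes
    all of its pairs; removal counts are logged.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_a", "gene_b"],
                     dtype=str, comment="#")
    df = df.dropna()
    if df.empty:
        raise ValueError(f"{path}: empty ortholog map")
    return one_to_one(df)


def one_to_one(pairs: pd.DataFrame) -> pd.DataFrame:
    """Drop every pair involving a duplicated partner on either side."""
    dup_a = pairs["gene_a"].duplicated(keep=False)
    dup_b = pairs["gene_b"].duplicated(keep=False)
    keep = ~(dup_a | dup_b)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("removed %d many-to-many ortholog pair(s)", dropped)
    return pairs.loc[keep].reset_index(drop=True)


def align_series(series, k: int, circular: bool = False) -> np.ndarray:
    """Compress a length-m stage series to length k by moving average.

    Valid-mode convolution with a uniform kernel of width w = m - k + 1
    normalized to sum 1: ``out[t] = mean(series[t:t+w])``. ``k == m`` is
    the identity; constant series map to the same constant. The circular
    variant wraps the series before convolving (first k windows kept).
    """
    x = np.asarray(series, dtype=float)
    m = x.size
    if not 1 <= k <= m:
        raise ValueError(f"target length {k} outside [1, {m}]")
    w = m - k + 1
    kernel = np.full(w, 1.0 / w)
    if circular:
        wrapped = np.concatenate([x, x[: w - 1]])
        return np.convolve(wrapped, kernel, mode="valid")[:k]
    return np.convolve(x, kernel, mode="valid")


@dataclass
class AlignmentSpec:
    """Per-stage target lengths for aligning two timepoint grids.

    ``targets`` maps stage -> common length k (k <= both species' stage
    lengths; default: the minimum of the two). ``drop_timepoints`` lists
    timepoint labels excluded before alignment (e.g., a wandering-larva
    sample when a 8-long larval grid must enter a 7-to-4 alignment).
    """

    targets: dict[str, int] = field(default_factory=dict)
    drop_timepoints: tuple[str, ...] = ()
    circular: bool = False

    def target_for(self, stage: str, m_a: int, m_b: int) -> int:
        k = self.targets.get(stage, min(m_a, m_b))
        if k > min(m_a, m_b) or k < 1:
            raise ValueError(f"target length {k} invalid for stage {stage} "
                             f"({m_a} vs {m_b} timepoints)")
        return k


def _stage_blocks(means: pd.DataFrame, sheet: SampleSheet,
                  spec: AlignmentSpec) -> dict[str, pd.DataFrame]:
    blocks = {}
    for stage, tps in sheet.stage_timepoints().items():
        tps = [t for t in tps if t not in spec.drop_timepoints]
        blocks[stage] = means[tps]
    return blocks


def cross_correlate(m_a: ExpressionMatrix, sheet_a: SampleSheet,
                    m_b: ExpressionMatrix, sheet_b: SampleSheet,
                    ortholog_map: pd.DataFrame,
                    spec: Optional[AlignmentSpec] = None,
                    top_percent: float = 70.0,
                    alpha: float = 0.05):
    """Ortholog-wise and timepoint-wise correlation between two species.

    Both matrices must be timepoint means on a log scale. Orthologs pass
    the variability filter if they fall in the top ``top_percent``% of IQR
    variability in either species (union rule). Stage series are aligned
    per ``spec`` (moving average to the common length) and concatenated in
    canonical stage order for the per-ortholog correlation; per-stage
    correlations use each stage's aligned segment alone (skipped for
    stages shorter than 3 aligned points).

    Returns ``(records, tp_matrix, per_stage)``: per-ortholog R/p/class,
    the all-pairs timepoint correlation matrix on the unaligned grids, and
    a dict stage -> per-ortholog records.
    """
    spec = spec or AlignmentSpec()
    pairs = one_to_one(ortholog_map)
    pairs = pairs[pairs["gene_a"].isin(m_a.feature_ids)
                  & pairs["gene_b"].isin(m_b.feature_ids)].reset_index(drop=True)
    if pairs.empty:
        raise ValueError("no ortholog pair present in both matrices")

    keep_a = set(variability_filter(m_a, top_percent))
    keep_b = set(variability_filter(m_b, top_percent))
    pairs = pairs[pairs["gene_a"].isin(keep_a) | pairs["gene_b"].isin(keep_b)]
    pairs = pairs.reset_index(drop=True)

    a = m_a.observed().loc[pairs["gene_a"]]
    b = m_b.observed().loc[pairs["gene_b"]]
    complete = (~a.isna().any(axis=1).to_numpy()) & (~b.isna().any(axis=1).to_numpy())
    pairs = pairs.loc[complete].reset_index(drop=True)
    a, b = a.loc[a.index[complete]], b.loc[b.index[complete]]

    blocks_a = _stage_blocks(a, sheet_a, spec)
    blocks_b = _stage_blocks(b, sheet_b, spec)
    stages = [s for s in STAGES if s in blocks_a and s in blocks_b]

    aligned_a, aligned_b, seg_bounds = [], [], {}
    pos = 0
    for stage in stages:
        xa, xb = blocks_a[stage].to_numpy(), blocks_b[stage].to_numpy()
        k = spec.target_for(stage, xa.shape[1], xb.shape[1])
        ya = np.apply_along_axis(align_series, 1, xa, k, spec.circular) \
            if xa.shape[1] != k else xa
        yb = np.apply_along_axis(align_series, 1, xb, k, spec.circular) \
            if xb.shape[1] != k else xb
        aligned_a.append(ya)
        aligned_b.append(yb)
        seg_bounds[stage] = (pos, pos + k)
        pos += k
    full_a = np.hstack(aligned_a)
    full_b = np.hstack(aligned_b)
    if full_a.shape[1] < 3:
        raise ValueError("fewer than 3 aligned timepoints overall")

    r, p = pearson_with_p(full_a, full_b)
    records = pd.DataFrame({"gene_a": pairs["gene_a"], "gene_b": pairs["gene_b"],
                            "R": r, "p": p,
                            "class": classify_correlation(r, p, alpha)})

    # all-pairs timepoint matrix on the unaligned grids
    an = a.to_numpy(dtype=float)
    bn = b.to_numpy(dtype=float)
    an = (an - an.mean(axis=0)) / an.std(axis=0)
    bn = (bn - bn.mean(axis=0)) / bn.std(axis=0)
    tp_matrix = pd.DataFrame(an.T @ bn / an.shape[0], index=a.columns, columns=b.columns)

    per_stage = {}
    for stage in stages:
        lo, hi = seg_bounds[stage]
        if hi - lo < 3:
            logger.warning("stage %s has <3 aligned timepoints; skipped", stage)
            continue
        rs, ps = pearson_with_p(full_a[:, lo:hi], full_b[:, lo:hi])
        per_stage[stage] = pd.DataFrame(
            {"gene_a": pairs["gene_a"], "gene_b": pairs["gene_b"], "R": rs, "p": ps,
             "class": classify_correlation(rs, ps, alpha)})
    return records, tp_matrix, per_stage
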