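"""Differential abundance, Fisher enrichment, and BH multiple-testing control.

Covers the early-egg differential comparison (Welch t-test + fold-change
filter on two timepoints, typically the freshly-laid vs few-hours-old egg
samples that bracket the maternal-to-zygotic transition), generic
term-to-gene (GO/Pfam/KEGG-style) enrichment by one-tailed Fisher tests
with Benjamini-Hochberg correction, and the single maternal-gene
enrichment test against an ortholog-mapped reference set.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from devodyn.omics_io import ExpressionMatrix, SampleSheet, Scale

logger = logging.getLogger(__name__)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    Vectorized textbook step-up: sort, multiply by n/rank, enforce
    monotonicity from the largest p downward, cap at 1, unsort.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-d")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    out = np.empty(n)
    out[order] = ranked
    return out


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """One-tailed (enrichment) hypergeometric p: P(X >= k | N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("inconsistent 2x2 margins")
    if not (max(0, K + n - N) <= k <= min(K, n)):
        raise ValueError("k outside the support of the margins")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def differential_timepoints(tx: ExpressionMatrix, sheet: SampleSheet,
                            tp_a: str = "Ewhite", tp_b: str = "Ebrown",
                            min_cpm: float = 1.0, min_reps: int = 4,
                            adjust: bool = True, alpha: float = 0.05,
                            fc_threshold: float = 2.0,
                            equal_var: bool = True) -> pd.DataFrame:
    """Two-group differential expression between two timepoints.

    Input is a CPM matrix; genes enter the test only if they have CPM >=
    ``min_cpm`` in at least ``min_reps`` replicates of either group. The
    test is a two-sided unpaired t-test on log2(CPM+1) values — Student's
    pooled-variance test by default (``equal_var=False`` switches to
    Welch, whose degrees of freedom collapse at n = 5 when one group's
    sample variance happens to be small); fold change is the ratio of
    linear CPM group means. A gene is
    significant iff the (BH-adjusted when ``adjust``) p-value is <= alpha
    AND the fold change exceeds ``fc_threshold`` in either direction.

    Returns one row per tested gene: mean_a, mean_b (log2), log2_fc, p,
    fdr (NaN when unadjusted), significant, direction ("up_a"/"up_b"/"ns").
    """
    if tx.scale is not Scale.cpm:
        raise ValueError("differential test expects a linear CPM matrix")
    samples_a = [s for s in sheet.samples_of_timepoint(tp_a) if s in tx.sample_ids]
    samples_b = [s for s in sheet.samples_of_timepoint(tp_b) if s in tx.sample_ids]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    a_lin = tx.observed()[samples_a]
    b_lin = tx.observed()[samples_b]
    include = ((a_lin >= min_cpm).sum(axis=1) >= min_reps) | \
              ((b_lin >= min_cpm).sum(axis=1) >= min_reps)
    a = np.log2(a_lin.loc[include] + 1.0).to_numpy()
    b = np.log2(b_lin.loc[include] + 1.0).to_numpy()
    res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():  # zero variance in both groups
        logger.warning("%d gene(s) with degenerate t-test; p set to 1", degenerate.sum())
        p[degenerate] = 1.0
    lin_fc = (a_lin.loc[include].mean(axis=1) + 0.0) / b_lin.loc[include].mean(axis=1)
    out = pd.DataFrame({
        "mean_a": a.mean(axis=1), "mean_b": b.mean(axis=1),
        "log2_fc": np.log2(lin_fc.replace(0, np.nan)),
        "p": p,
    }, index=a_lin.loc[include].index)
    out["fdr"] = bh_adjust(p) if adjust else np.nan
    crit = out["fdr"] if adjust else out["p"]
    fc_ok = (lin_fc > fc_threshold) | (lin_fc < 1.0 / fc_threshold)
    out["significant"] = (crit <= alpha) & fc_ok.fillna(False)
    out["direction"] = np.where(~out["significant"], "ns",
                                np.where(lin_fc > 1, "up_a", "up_b"))
    out.index.name = "gene_id"
    return out


def fisher_enrichment(gene_set: Iterable[str], term_map: dict[str, set[str]],
                      background: Iterable[str], tail: str = "one") -> pd.DataFrame:
    """Term enrichment of ``gene_set`` against a background universe.

    One-tailed hypergeometric enrichment p per term (or two-sided Fisher
    with ``tail="two"``), BH-adjusted across terms, sorted by FDR. Terms
    are intersected with the background; the gene set must be a subset of
    the background.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    gene_set = set(gene_set) & background
    rows = []
    N = len(background)
    n = len(gene_set)
    for term, genes in term_map.items():
        tg = genes & background
        if not tg:
            continue
        k = len(gene_set & tg)
        K = len(tg)
        if tail == "one":
            p = hypergeom_tail(k, K, n, N)
        else:
            table = [[k, n - k], [K - k, N - K - (n - k)]]
            p = float(stats.fisher_exact(table).pvalue)
        denom = (n - k) * (K - k)
        odds = (k * (N - K - n + k)) / denom if denom > 0 else np.inf
        rows.append((term, k, n, K, N, odds, p))
    out = pd.DataFrame(rows, columns=["term_id", "k_in_set", "set_size",
                                      "K_in_background", "N_background",
                                      "odds_ratio", "p"]).set_index("term_id")
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("fdr", kind="stable")
    else:
        out["fdr"] = np.nan
    return out


def maternal_enrichment(up_genes: Iterable[str], maternal_ref: Iterable[str],
                        universe: Iterable[str]) -> pd.Series:
    """One-tailed Fisher test for maternal-gene enrichment in an up-set.

    ``maternal_ref`` is the reference maternal-gene set already mapped
    through one-to-one orthologs; both sets are intersected with the
    universe before building the 2x2 table.
    """
    universe = set(universe)
    up = set(up_genes) & universe
    ref = set(maternal_ref) & universe
    if not up or not ref:
        raise ValueError("empty gene set after intersecting with the universe")
    k = len(up & ref)
    p = hypergeom_tail(k, len(ref), len(up), len(universe))
    return pd.Series({"k_overlap": k, "set_size": len(up), "K_reference": len(ref),
                      "N_universe": len(universe), "p": p})
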