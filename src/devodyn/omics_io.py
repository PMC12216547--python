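"""Expression-matrix data model, file I/O, scale transforms, and LFQ imputation.

The central container is :class:`ExpressionMatrix`: a features-by-samples
table with an explicit measurement scale and an explicit missingness mask.
Proteome label-free quantification (LFQ) intensities are analyzed on the
log2 scale and carry missing-not-at-random holes below the detection limit;
transcript abundances arrive as counts-per-million (CPM) from 3'-end tag
counting and are transformed as log2(CPM + 1).

Missing proteome cells can be imputed by drawing from a beta distribution
shifted so that the upper edge of its support sits at the limit of
quantitation (LOQ) — a standard strategy for left-censored LFQ data, here
with explicit, seedable parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


class ParseError(ValueError):
    """Raised when a tabular input file cannot be parsed."""


class Scale(str, Enum):
    """Measurement scale of an expression matrix."""

    lfq_linear = "lfq_linear"
    lfq_log2 = "lfq_log2"
    cpm = "cpm"
    cpm_log2 = "cpm_log2"
    zscore = "zscore"


STAGES = ("egg", "larva", "pupa", "adult")

#: Smallest measured log2 LFQ intensity; used as the display/means fill for
#: timepoints with no measurement (limit of detection).
DEFAULT_LOD = 22.5


@dataclass
class ExpressionMatrix:
    """Features x samples numeric table with declared scale and missingness.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric matrix, rows indexed by feature id, columns by sample id.
        Cells flagged missing may hold NaN.
    scale : Scale
        Unit of ``values``.
    missing_mask : pandas.DataFrame, optional
        Boolean matrix, True where the cell was not measured. Defaults to
        ``values.isna()``.
    imputed_mask : pandas.DataFrame, optional
        True where a cell's value was filled in by imputation. Presence of
        any True marks the matrix as imputed; detection analyses reject such
        matrices.
    """

    values: pd.DataFrame
    scale: Scale
    missing_mask: Optional[pd.DataFrame] = None
    imputed_mask: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.values.index.name = "feature_id"
        self.values.columns.name = None
        if self.missing_mask is None:
            self.missing_mask = self.values.isna()
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape differs from values")
        self.missing_mask = self.missing_mask.astype(bool)
        self.missing_mask.index = self.values.index
        self.missing_mask.columns = self.values.columns
        observed = self.values.to_numpy(dtype=float)[~self.missing_mask.to_numpy()]
        if not np.isfinite(observed).all():
            raise ValueError("non-finite value in an observed (non-missing) cell")
        if self.scale is Scale.cpm and observed.size and observed.min() < 0:
            raise ValueError("CPM values must be nonnegative")

    # -- convenience -------------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def is_imputed(self) -> bool:
        return self.imputed_mask is not None and bool(self.imputed_mask.to_numpy().any())

    def observed(self) -> pd.DataFrame:
        """Values with missing cells replaced by NaN."""
        return self.values.where(~self.missing_mask)

    def subset(self, features=None, samples=None) -> "ExpressionMatrix":
        v = self.values
        mm = self.missing_mask
        im = self.imputed_mask
        if features is not None:
            v, mm = v.loc[features], mm.loc[features]
            im = im.loc[features] if im is not None else None
        if samples is not None:
            v, mm = v[samples], mm[samples]
            im = im[samples] if im is not None else None
        return ExpressionMatrix(v.copy(), self.scale, mm.copy(), None if im is None else im.copy())


@dataclass
class SampleSheet:
    """Per-sample metadata: timepoint, stage, replicate, species, optional sex.

    Timepoint order follows first appearance in the table; every timepoint
    must map to exactly one of the four holometabolous stages.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "timepoint", "stage", "replicate")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValueError(f"sample sheet missing column {col!r}")
        if "species" not in t.columns:
            t = t.assign(species="A")
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample sheet")
        bad_stage = set(t["stage"]) - set(STAGES)
        if bad_stage:
            raise ValueError(f"unknown stage labels: {sorted(bad_stage)}")
        if (t["replicate"].astype(int) < 1).any():
            raise ValueError("replicate indices must be positive")
        key = t[["timepoint", "replicate", "species"]]
        if key.duplicated().any():
            raise ValueError("(timepoint, replicate, species) not unique")
        n_stage = t.groupby("timepoint")["stage"].nunique()
        if (n_stage > 1).any():
            raise ValueError("a timepoint maps to more than one stage")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    @property
    def timepoints(self) -> list[str]:
        return list(dict.fromkeys(self.table["timepoint"]))

    def stage_of(self) -> dict[str, str]:
        """Map timepoint label -> stage."""
        return dict(zip(self.table["timepoint"], self.table["stage"]))

    def stage_timepoints(self) -> dict[str, list[str]]:
        """Map stage -> ordered timepoint labels, in sheet order."""
        out: dict[str, list[str]] = {}
        for tp in self.timepoints:
            out.setdefault(self.stage_of()[tp], []).append(tp)
        return out

    def samples_of_timepoint(self, tp: str) -> list[str]:
        t = self.table
        return list(t.loc[t["timepoint"] == tp, "sample_id"])


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix(path: str | Path, scale: Scale | str) -> ExpressionMatrix:
    """Read a features x samples TSV/CSV into an :class:`ExpressionMatrix`.

    The first column holds feature ids, the header row sample ids. Empty
    cells and the token ``NA`` denote missing measurements. Duplicate
    feature ids and non-numeric cells are rejected.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str,
                          keep_default_na=False)
    except Exception as exc:  # malformed file structure
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if raw.columns.size == 0:
        raise ParseError(f"{path}: header row has no sample columns")
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature ids {dups[:5]}")
    missing = (raw == "") | (raw == "NA")
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cell = raw[col].where(~missing[col], other="nan")
        try:
            values[col] = cell.astype(float)
        except ValueError:
            bad = cell[pd.to_numeric(cell, errors="coerce").isna() & ~missing[col]]
            row = bad.index[0] if len(bad) else "?"
            raise ParseError(
                f"{path}: non-numeric cell at feature {row!r}, sample {col!r}"
            ) from None
    values = values.where(~missing)
    return ExpressionMatrix(values, Scale(scale), missing)


def write_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV/CSV; missing cells become empty strings."""
    out = m.values.where(~m.missing_mask)
    out.to_csv(path, sep=_sep_for(path), na_rep="")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    t = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str, "timepoint": str})
    return SampleSheet(t)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep=_sep_for(path), index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT term-to-gene map: term, description, genes... per line."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            terms[parts[0]] = {g for g in parts[2:] if g}
    return terms


def write_gmt(terms: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, genes in terms.items():
            fh.write("\t".join([term, term] + sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform CPM (as log2(x+1)) or linear LFQ (as log2(x)) values.

    Observed linear LFQ intensities must be strictly positive.
    """
    if m.scale is Scale.cpm:
        vals = np.log2(m.values + 1.0)
        new_scale = Scale.cpm_log2
    elif m.scale is Scale.lfq_linear:
        obs = m.values.to_numpy(dtype=float)[~m.missing_mask.to_numpy()]
        if obs.size and obs.min() <= 0:
            raise ValueError("linear LFQ intensities must be > 0 to log-transform")
        vals = np.log2(m.values)
        new_scale = Scale.lfq_log2
    else:
        raise ValueError(f"cannot log-transform scale {m.scale.value}")
    return ExpressionMatrix(vals, new_scale, m.missing_mask.copy(),
                            None if m.imputed_mask is None else m.imputed_mask.copy())


@dataclass
class ImputationSpec:
    """Parameters of the shifted-beta imputation of left-censored LFQ cells.

    ``loq`` anchors the upper edge of the imputation interval (limit of
    quantitation, log2 intensity); draws fall in ``[loq - window_width,
    loq]``. Unset shape parameters are fitted by method of moments on
    min-max-rescaled observed intensities; unset ``loq`` defaults to the 1st
    percentile of observed values and unset ``window_width`` to 10% of the
    observed range.
    """

    loq: Optional[float] = None
    lod: float = DEFAULT_LOD
    beta_alpha: Optional[float] = None
    beta_beta: Optional[float] = None
    window_width: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta_alpha is not None and self.beta_alpha <= 0:
            raise ValueError("beta_alpha must be > 0")
        if self.beta_beta is not None and self.beta_beta <= 0:
            raise ValueError("beta_beta must be > 0")
        if self.window_width is not None and self.window_width <= 0:
            raise ValueError("window_width must be > 0")


class ShiftedBetaImputer(TransformerMixin, BaseEstimator):
    """Impute left-censored cells from a beta distribution shifted to the LOQ.

    Fitting learns, from the observed (finite) entries of ``X``:

    * ``loq_`` — the anchor intensity (default: 1st percentile of observed
      values), the upper edge of the imputation window;
    * ``window_width_`` — the span of the window (default: 10% of the
      observed range);
    * ``alpha_``, ``beta_`` — beta shape parameters, by method of moments on
      the observed values rescaled to [0, 1].

    ``transform`` replaces every NaN cell by ``loq_ - window_width_ * (1 - B)``
    with ``B ~ Beta(alpha_, beta_)``, so imputed intensities concentrate just
    below the limit of quantitation. Observed cells are never altered.
    """

    def __init__(self, loq=None, window_width=None, beta_alpha=None,
                 beta_beta=None, window_frac=0.1, loq_percentile=1.0,
                 random_state=None):
        self.loq = loq
        self.window_width = window_width
        self.beta_alpha = beta_alpha
        self.beta_beta = beta_beta
        self.window_frac = window_frac
        self.loq_percentile = loq_percentile
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        obs = X[np.isfinite(X)]
        need_fit = (self.loq is None or self.window_width is None
                    or self.beta_alpha is None or self.beta_beta is None)
        if obs.size == 0 and need_fit:
            raise ValueError("all cells missing and imputation parameters unset")
        self.loq_ = float(np.percentile(obs, self.loq_percentile)) if self.loq is None else float(self.loq)
        if self.window_width is None:
            span = float(obs.max() - obs.min())
            if span <= 0:
                raise ValueError("observed values constant; set window_width explicitly")
            self.window_width_ = self.window_frac * span
        else:
            self.window_width_ = float(self.window_width)
        if self.beta_alpha is None or self.beta_beta is None:
            lo, hi = float(obs.min()), float(obs.max())
            y01 = (obs - lo) / (hi - lo)
            mean, var = float(y01.mean()), float(y01.var())
            common = mean * (1.0 - mean) / var - 1.0 if var > 0 else 0.0
            if common <= 0:
                raise ValueError("method-of-moments beta fit failed; set shapes explicitly")
            self.alpha_ = mean * common
            self.beta_ = (1.0 - mean) * common
        else:
            self.alpha_ = float(self.beta_alpha)
            self.beta_ = float(self.beta_beta)
        return self

    def transform(self, X):
        check_is_fitted(self, "loq_")
        X = np.array(X, dtype=float, copy=True)
        hole = ~np.isfinite(X)
        rng = np.random.default_rng(self.random_state)
        draws = rng.beta(self.alpha_, self.beta_, size=int(hole.sum()))
        X[hole] = self.loq_ - self.window_width_ * (1.0 - draws)
        return X


def impute_shifted_beta(m: ExpressionMatrix, spec: ImputationSpec | None = None) -> ExpressionMatrix:
    """Fill missing log2-LFQ cells by shifted-beta imputation.

    Returns a new matrix whose ``imputed_mask`` records the filled cells;
    observed cells are unchanged and the missing mask is cleared.
    """
    if m.scale is not Scale.lfq_log2:
        raise ValueError("imputation operates on lfq_log2 matrices")
    spec = spec or ImputationSpec()
    imp = ShiftedBetaImputer(
        loq=spec.loq, window_width=spec.window_width,
        beta_alpha=spec.beta_alpha, beta_beta=spec.beta_beta,
        random_state=spec.seed,
    )
    holes = m.missing_mask.copy()
    if not holes.to_numpy().any():
        return ExpressionMatrix(m.values.copy(), m.scale, holes,
                                pd.DataFrame(False, index=m.feature_ids, columns=m.sample_ids))
    X = m.observed().to_numpy(dtype=float)
    filled = imp.fit(X).transform(X)
    vals = pd.DataFrame(filled, index=m.feature_ids, columns=m.sample_ids)
    clear = pd.DataFrame(False, index=m.feature_ids, columns=m.sample_ids)
    return ExpressionMatrix(vals, m.scale, clear, holes)


# ---------------------------------------------------------------------------
# aggregation & QC
# ---------------------------------------------------------------------------

def timepoint_means(m: ExpressionMatrix, sheet: SampleSheet,
                    lod_fill: Optional[float] = None) -> ExpressionMatrix:
    """Per-feature mean of observed replicate values per timepoint.

    A (feature, timepoint) cell with zero observed replicates is set to
    ``lod_fill`` when given (the limit-of-detection display convention),
    otherwise left missing.
    """
    absent = set(m.sample_ids) - set(sheet.sample_ids)
    if absent:
        raise ValueError(f"sample ids not in sample sheet: {sorted(absent)[:5]}")
    obs = m.observed()
    cols, masks = {}, {}
    for tp in sheet.timepoints:
        samples = [s for s in sheet.samples_of_timepoint(tp) if s in m.sample_ids]
        mu = obs[samples].mean(axis=1)  # skips NaN
        empty = mu.isna()
        if lod_fill is not None:
            mu = mu.fillna(lod_fill)
            empty = pd.Series(False, index=mu.index)
        cols[tp] = mu
        masks[tp] = empty
    vals = pd.DataFrame(cols)[sheet.timepoints]
    mask = pd.DataFrame(masks)[sheet.timepoints]
    return ExpressionMatrix(vals, m.scale, mask,
                            None if m.imputed_mask is None else
                            pd.DataFrame(False, index=vals.index, columns=vals.columns))


def replicate_correlation(m: ExpressionMatrix, sheet: Optional[SampleSheet] = None,
                          min_common: int = 3) -> pd.DataFrame:
    """Sample x sample Pearson matrix on pairwise-complete observed values.

    Pairs sharing fewer than ``min_common`` observed features get NaN.
    """
    if m.sample_ids.size < 2:
        raise ValueError("need at least 2 samples")
    if sheet is not None:
        absent = set(m.sample_ids) - set(sheet.sample_ids)
        if absent:
            raise ValueError(f"sample ids not in sample sheet: {sorted(absent)[:5]}")
    corr = m.observed().corr(method="pearson", min_periods=min_common)
    np.fill_diagonal(corr.values, 1.0)
    return corr
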