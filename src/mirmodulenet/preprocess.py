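"""Missing-data removal, count normalization, z-scoring and DE filtering.

The differential-expression stage is a distribution-free built-in
(two-sided Mann-Whitney U per feature, Benjamini-Hochberg adjustment,
log2 fold-change gate).  It replaces a negative-binomial count model: for
count data the results are broadly comparable but not identical; the
downstream grouping machinery only needs a candidate feature set and is
agnostic to which filter produced it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_expression import ExpressionDataset

logger = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass
class NormalizationParams:
    """Per-feature z-score parameters estimated on a training partition."""

    mean: pd.Series
    sd: pd.Series  # population (n-denominator) standard deviation, >= 0
    method: str = "none"  # count normalization applied before the fit

    def __post_init__(self) -> None:
        if (self.sd < 0).any():
            raise ValueError("negative standard deviation")
        n_const = int((self.sd == 0).sum())
        if n_const:
            logger.info("z-score fit: %d constant feature(s) flagged (sd=0)", n_const)


@dataclass
class DEFilterResult:
    """Outcome of the differential-expression filter.

    ``stats`` has one row per input feature with columns
    ``statistic, p_value, p_adjusted, log2_fc``; ``kept`` is the subset of
    feature IDs passing both thresholds.
    """

    kept: list[str]
    stats: pd.DataFrame
    alpha: float
    min_abs_log2fc: float


def drop_missing_features(ds: ExpressionDataset) -> ExpressionDataset:
    """Remove every feature that has at least one missing value."""
    mask = ds.values.notna().all(axis=1)
    removed = int((~mask).sum())
    if removed:
        logger.info("drop_missing_features: removed %d/%d features", removed, ds.n_features)
    if not mask.any():
        raise ValueError("all features contain missing values")
    return ExpressionDataset(ds.values.loc[mask], ds.omics_kind)


def normalize_counts(
    ds: ExpressionDataset,
    method: str,
    gene_lengths: Mapping[str, float] | None = None,
) -> ExpressionDataset:
    """Library-size normalization of raw read counts.

    RPM: value * 1e6 / library size.  RPKM: value * 1e9 / (library size *
    gene length in bp).  ``none`` passes pre-normalized data through.
    """
    if method == "none":
        return ds
    if method not in ("RPM", "RPKM"):
        raise ValueError(f"unknown normalization method: {method!r}")
    values = ds.values
    if (values.values < 0).any():
        raise ValueError(f"{method} normalization requires non-negative counts")
    libsize = values.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    if method == "RPM":
        out = values * 1e6 / libsize
    else:
        if gene_lengths is None:
            raise ValueError("RPKM requires gene lengths")
        missing = [f for f in ds.feature_ids if f not in gene_lengths]
        if missing:
            raise ValueError(f"no gene length for feature(s): {missing[:5]}")
        lengths = pd.Series({f: float(gene_lengths[f]) for f in ds.feature_ids})
        out = (values * 1e9 / libsize).div(lengths, axis=0)
    return ExpressionDataset(out, ds.omics_kind)


def fit_zscore(train: ExpressionDataset, method: str = "none") -> NormalizationParams:
    """Estimate per-feature mean/sd on the training partition only."""
    mean = train.values.mean(axis=1)
    sd = train.values.std(axis=1, ddof=0)
    return NormalizationParams(mean=mean, sd=sd, method=method)


def apply_zscore(ds: ExpressionDataset, params: NormalizationParams) -> ExpressionDataset:
    """Transform to (x - mean)/sd; constant (sd=0) features map to zeros."""
    missing = [f for f in ds.feature_ids if f not in params.mean.index]
    if missing:
        raise KeyError(f"no z-score parameters for feature(s): {missing[:5]}")
    mean = params.mean.loc[ds.feature_ids]
    sd = params.sd.loc[ds.feature_ids].replace(0.0, np.inf)  # sd=0 -> all-zero output
    out = ds.values.sub(mean, axis=0).div(sd, axis=0)
    return ExpressionDataset(out, ds.omics_kind)


def _log2_fold_change(mean_case: np.ndarray, mean_control: np.ndarray) -> np.ndarray:
    """log2((mean_case+eps)/(mean_control+eps)) with a degenerate-scale rule.

    The ratio is meaningful for non-negative expression units.  Where a
    shifted class mean is <= 0 (possible for already-standardized input) the
    fold change is reported as +/-inf so the gate defers to the p-value.
    """
    num = mean_case + _EPS
    den = mean_control + _EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.log2(num / den)
    bad = (num <= 0) | (den <= 0)
    fc[bad] = np.where(mean_case[bad] >= mean_control[bad], np.inf, -np.inf)
    return fc


def differential_filter(
    ds: ExpressionDataset,
    labels: pd.Series,
    alpha: float = 0.05,
    min_abs_log2fc: float = 1.0,
) -> DEFilterResult:
    """Distribution-free differential-expression filter.

    Per feature: two-sided Mann-Whitney U between case and control values,
    BH adjustment across features, then keep features with adjusted
    p <= alpha and |log2 fold change of class means| >= min_abs_log2fc.
    """
    y = labels.loc[ds.sample_ids].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("differential_filter needs both classes")
    if (y == 1).sum() < 3 or (y == 0).sum() < 3:
        raise ValueError("differential_filter needs >= 3 samples per class")
    X = ds.values.to_numpy(dtype=float)
    case, control = X[:, y == 1], X[:, y == 0]
    res = stats.mannwhitneyu(case, control, axis=1, alternative="two-sided", method="asymptotic")
    pvals = np.asarray(res.pvalue, dtype=float)
    # features constant across all samples give U at its null mean; force p=1
    constant = X.std(axis=1) == 0
    pvals[constant] = 1.0
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    fc = _log2_fold_change(case.mean(axis=1), control.mean(axis=1))
    keep = (p_adj <= alpha) & (np.abs(fc) >= min_abs_log2fc)
    table = pd.DataFrame(
        {
            "statistic": np.asarray(res.statistic, dtype=float),
            "p_value": pvals,
            "p_adjusted": p_adj,
            "log2_fc": fc,
        },
        index=ds.feature_ids,
    )
    kept = [f for f, k in zip(ds.feature_ids, keep) if k]
    logger.info(
        "differential_filter(%s): kept %d/%d features at alpha=%g, |log2FC|>=%g",
        ds.omics_kind, len(kept), ds.n_features, alpha, min_abs_log2fc,
    )
    return DEFilterResult(kept=kept, stats=table, alpha=alpha, min_abs_log2fc=min_abs_log2fc)


def top_features_by_p(result: DEFilterResult, n: int) -> list[str]:
    """The n smallest-adjusted-p features (candidate floor for low-signal data)."""
    order = result.stats.sort_values(["p_adjusted", "p_value"], kind="stable")
    return list(order.index[:n])
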