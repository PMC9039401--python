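"""Outer evaluation engine: Monte-Carlo cross-validation with
under-sampling, per-iteration module building/scoring, and cumulative
top-f random-forest models.

Each iteration i (seed = master_seed + i):

1. stratified 90/10 split of the samples,
2. 1:2 under-sampling of the training partition (all minority samples
   kept; majority sampled down to at most ratio x minority),
3. count normalization, z-scoring fitted on the training partition,
4. differential-expression filtering on training data (with a candidate
   floor so low-signal iterations still carry features forward),
5. miRNA-mRNA MI matrix and star-module construction on training data,
6. internal CV scoring and ranking of the modules,
7. cumulative evaluation: for f = 1..top_f, a random forest trained on the
   union of the top-f modules' genes and evaluated on the held-out test
   partition.

Every statistic that could leak label or distribution information is
estimated on the (under-sampled) training partition only; the test
partition is touched exclusively in step 7's evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .io_expression import ExpressionDataset, PairedOmicsDataset, StarModule
from . import preprocess
from .preprocess import DEFilterResult
from .scoring import (
    GroupScoreRecord,
    classification_metrics,
    forest_case_probability,
    score_all_groups,
)
from .star_modules import build_all_modules

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable parameters of one pipeline run."""

    iterations: int = 100
    test_fraction: float = 0.10
    top_f: int = 10
    undersample_ratio: float = 2.0  # majority allowed up to ratio x minority
    mi_threshold: float = 0.25
    mi_bins: int = 3
    inner_folds: int = 5
    n_trees: int = 50  # random-forest size
    master_seed: int = 0
    expansion: str = "center"  # star-module expansion criterion
    rank_by: str = "auc"
    de_alpha: float = 0.05
    de_min_abs_log2fc: float = 1.0
    min_candidate_mirnas: int = 10
    min_candidate_mrnas: int = 20
    normalization_mirna: str = "none"  # {"RPM", "none"}
    normalization_mrna: str = "none"  # {"RPKM", "none"}
    leaky_zscore: bool = False  # fit z-score on all samples (protocol-compat mode)
    gene_lengths: Mapping[str, float] | None = None

    def validate(self) -> None:
        if not (0 < self.test_fraction < 0.5):
            raise ValueError("test_fraction must be in (0, 0.5)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.top_f < 1:
            raise ValueError("top_f must be >= 1")
        if self.undersample_ratio < 1:
            raise ValueError("undersample_ratio must be >= 1")
        if self.mi_threshold < 0:
            raise ValueError("mi_threshold must be >= 0")
        if self.mi_bins < 2:
            raise ValueError("mi_bins must be >= 2")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("gene_lengths")
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        cfg = cls(**dict(d))
        cfg.validate()
        return cfg


@dataclass
class CumulativePerformanceRow:
    """Test-set performance of the model built on the top ``n_groups`` modules."""

    n_groups: int
    n_genes: int
    accuracy: float
    sensitivity: float
    specificity: float
    f_measure: float
    precision: float
    auc: float


@dataclass
class IterationResult:
    """Everything one MCCV iteration produced (training-side artifacts are
    kept so leakage audits can compare them across perturbed runs)."""

    seed: int
    train_samples: list[str]  # after under-sampling
    test_samples: list[str]
    candidate_mirnas: list[str]
    candidate_mrnas: list[str]
    de_mirna: DEFilterResult | None
    de_mrna: DEFilterResult | None
    modules: list[StarModule]
    records: list[GroupScoreRecord]
    rows: list[CumulativePerformanceRow]
    skipped: bool = False
    skip_reason: str = ""


@dataclass
class MCCVResult:
    performance: pd.DataFrame  # mean/sd per n_groups across iterations
    ranked_lists: list[list[str]]  # per-iteration center miRNAs, best first
    iteration_modules: list[list[StarModule]]
    candidate_universe: list[str]  # every miRNA that entered module construction
    iterations: list[IterationResult]
    n_skipped: int


class TooManySkippedError(RuntimeError):
    """More than half of the MCCV iterations produced zero modules.

    Carries the partial result so callers can still inspect what happened
    (typical cause: no signal in the data, or an MI threshold above every
    observed pair)."""

    def __init__(self, result: MCCVResult):
        self.result = result
        super().__init__(
            f"{result.n_skipped}/{len(result.iterations)} iterations produced no modules"
        )


def stratified_split(
    labels: pd.Series, test_fraction: float, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Per-class random split; at least one test sample per class."""
    if not (0 < test_fraction < 0.5):
        raise ValueError("test_fraction must be in (0, 0.5)")
    train: list[str] = []
    test: list[str] = []
    for cls in (0, 1):
        ids = np.array(labels.index[labels == cls])
        if len(ids) < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples")
        n_test = max(1, int(round(test_fraction * len(ids))))
        if n_test >= len(ids):
            raise ValueError(f"class {cls} too small for test_fraction={test_fraction}")
        picked = rng.choice(len(ids), size=n_test, replace=False)
        mask = np.zeros(len(ids), dtype=bool)
        mask[picked] = True
        test.extend(ids[mask])
        train.extend(ids[~mask])
    # canonical order within partitions: lexicographic
    return sorted(train), sorted(test)


def undersample(
    labels: pd.Series, ratio: float, rng: np.random.Generator
) -> list[str]:
    """Keep all minority samples; thin the majority to floor(ratio x minority)."""
    if ratio < 1:
        raise ValueError("undersample_ratio must be >= 1")
    counts = labels.value_counts()
    minority_cls = int(counts.idxmin())
    majority_cls = 1 - minority_cls
    minority = list(labels.index[labels == minority_cls])
    majority = np.array(labels.index[labels == majority_cls])
    cap = int(np.floor(ratio * len(minority)))
    if len(majority) > cap:
        picked = rng.choice(len(majority), size=cap, replace=False)
        majority = majority[np.sort(picked)]
    return sorted(minority + list(majority))


def _select_candidates(
    de: DEFilterResult, floor: int, n_features: int
) -> list[str]:
    """DE-kept features, padded to ``floor`` by smallest adjusted p."""
    if len(de.kept) >= floor:
        return de.kept
    return preprocess.top_features_by_p(de, min(floor, n_features))


def _prepare_layers(
    paired: PairedOmicsDataset,
    train_ids: list[str],
    test_ids: list[str],
    config: RunConfig,
) -> tuple[PairedOmicsDataset, PairedOmicsDataset, PairedOmicsDataset]:
    """Normalize counts, fit z-score on train, apply to train and test.

    Returns (train_normalized, train_z, test_z): the DE filter runs on the
    count-normalized scale (where fold changes are meaningful), MI and the
    classifiers on the z-scored scale.
    """
    norm: dict[str, ExpressionDataset] = {}
    for layer, method in (("mirna", config.normalization_mirna), ("mrna", config.normalization_mrna)):
        ds: ExpressionDataset = getattr(paired, layer)
        lengths = config.gene_lengths if method == "RPKM" else None
        norm[layer] = preprocess.normalize_counts(ds, method, gene_lengths=lengths)

    def _split(ds: ExpressionDataset, ids: list[str]) -> ExpressionDataset:
        return ds.subset_samples(ids)

    train_norm = {k: _split(v, train_ids) for k, v in norm.items()}
    test_norm = {k: _split(v, test_ids) for k, v in norm.items()}
    train_z, test_z = {}, {}
    for k in norm:
        fit_on = norm[k].subset_samples(sorted(train_ids + test_ids)) if config.leaky_zscore else train_norm[k]
        params = preprocess.fit_zscore(fit_on, method="none")
        train_z[k] = preprocess.apply_zscore(train_norm[k], params)
        test_z[k] = preprocess.apply_zscore(test_norm[k], params)
    lab = paired.labels
    return (
        PairedOmicsDataset(train_norm["mirna"], train_norm["mrna"], lab.loc[train_ids]),
        PairedOmicsDataset(train_z["mirna"], train_z["mrna"], lab.loc[train_ids]),
        PairedOmicsDataset(test_z["mirna"], test_z["mrna"], lab.loc[test_ids]),
    )


def cumulative_evaluate(
    ranked_modules: list[StarModule],
    train: PairedOmicsDataset,
    test: PairedOmicsDataset,
    top_f: int,
    rng_seed: int,
    n_trees: int = 50,
) -> list[CumulativePerformanceRow]:
    """For f = 1..top_f: train a random forest on the union of the top-f
    modules' genes and evaluate on the held-out test partition."""
    if not ranked_modules:
        raise ValueError("no ranked modules")
    if len(ranked_modules) < top_f:
        logger.warning(
            "only %d modules available; evaluating up to f=%d",
            len(ranked_modules), len(ranked_modules),
        )
    rows = []
    genes: set[str] = set()
    y_train = train.labels.to_numpy(int)
    y_test = test.labels.to_numpy(int)
    for f in range(1, min(top_f, len(ranked_modules)) + 1):
        genes |= set(ranked_modules[f - 1].members)
        cols = sorted(genes)
        X_train = train.mrna.subset_features(cols).values.T.to_numpy(float)
        X_test = test.mrna.subset_features(cols).values.T.to_numpy(float)
        score = forest_case_probability(X_train, y_train, X_test, rng_seed, n_trees)
        metrics = classification_metrics(y_test, (score > 0.5).astype(int), score)
        metrics.pop("cohens_kappa")
        rows.append(CumulativePerformanceRow(n_groups=f, n_genes=len(cols), **metrics))
    return rows


def run_single_iteration(
    paired: PairedOmicsDataset, config: RunConfig, seed: int
) -> IterationResult:
    """One complete MCCV iteration (split through cumulative evaluation)."""
    rng = np.random.default_rng(seed)
    train_all, test_ids = stratified_split(paired.labels, config.test_fraction, rng)
    train_ids = undersample(paired.labels.loc[train_all], config.undersample_ratio, rng)

    train_norm, train_z, test_z = _prepare_layers(paired, train_ids, test_ids, config)

    de_mirna = preprocess.differential_filter(
        train_norm.mirna, train_norm.labels, config.de_alpha, config.de_min_abs_log2fc
    )
    de_mrna = preprocess.differential_filter(
        train_norm.mrna, train_norm.labels, config.de_alpha, config.de_min_abs_log2fc
    )
    cand_mirnas = sorted(
        _select_candidates(de_mirna, config.min_candidate_mirnas, paired.mirna.n_features)
    )
    cand_mrnas = sorted(
        _select_candidates(de_mrna, config.min_candidate_mrnas, paired.mrna.n_features)
    )

    base = IterationResult(
        seed=seed,
        train_samples=train_ids,
        test_samples=test_ids,
        candidate_mirnas=cand_mirnas,
        candidate_mrnas=cand_mrnas,
        de_mirna=de_mirna,
        de_mrna=de_mrna,
        modules=[],
        records=[],
        rows=[],
    )
    try:
        modules = build_all_modules(
            train_z, cand_mirnas, cand_mrnas,
            tau=config.mi_threshold, bins=config.mi_bins, expansion=config.expansion,
        )
    except ValueError as exc:
        base.skipped = True
        base.skip_reason = str(exc)
        return base

    records = score_all_groups(
        train_z, modules, k=config.inner_folds, rng_seed=seed,
        rank_by=config.rank_by, n_trees=config.n_trees,
    )
    ranked_modules = [r.module for r in records]
    rows = cumulative_evaluate(
        ranked_modules, train_z, test_z, config.top_f, rng_seed=seed, n_trees=config.n_trees
    )
    base.modules = modules
    base.records = records
    base.rows = rows
    return base


def _aggregate_performance(iterations: list[IterationResult], top_f: int) -> pd.DataFrame:
    rows = []
    for it in iterations:
        for r in it.rows:
            rows.append(
                {
                    "n_groups": r.n_groups,
                    "n_genes": r.n_genes,
                    "accuracy": r.accuracy,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "f_measure": r.f_measure,
                    "precision": r.precision,
                    "auc": r.auc,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=[
                "n_groups", "mean_n_genes", "accuracy", "sensitivity", "specificity",
                "f_measure", "precision", "auc", "sd_auc",
            ]
        )
    df = pd.DataFrame(rows)
    grouped = df.groupby("n_groups")
    out = grouped.mean().rename(columns={"n_genes": "mean_n_genes"})
    out["sd_auc"] = grouped["auc"].std(ddof=0)
    out = out.reset_index()
    return out[out["n_groups"] <= top_f]


def run_mccv(paired: PairedOmicsDataset, config: RunConfig) -> MCCVResult:
    """Run the full Monte-Carlo cross-validation pipeline.

    Per-iteration seeds are master_seed + i, so iterations are independent
    and reproducible.  Iterations that produce no module are recorded as
    skipped; if more than half are skipped a TooManySkippedError is raised
    (carrying the partial result).
    """
    config.validate()
    paired = PairedOmicsDataset(
        preprocess.drop_missing_features(paired.mirna),
        preprocess.drop_missing_features(paired.mrna),
        paired.labels,
    )
    iterations = []
    for i in range(config.iterations):
        it = run_single_iteration(paired, config, seed=config.master_seed + i)
        if it.skipped:
            logger.warning("iteration %d skipped: %s", i, it.skip_reason)
        iterations.append(it)

    ok = [it for it in iterations if not it.skipped]
    universe = sorted({m for it in iterations for m in it.candidate_mirnas})
    result = MCCVResult(
        performance=_aggregate_performance(ok, config.top_f),
        ranked_lists=[[r.module.center_mirna for r in it.records] for it in ok],
        iteration_modules=[it.modules for it in ok],
        candidate_universe=universe,
        iterations=iterations,
        n_skipped=len(iterations) - len(ok),
    )
    if result.n_skipped * 2 > len(iterations):
        raise TooManySkippedError(result)
    return result
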