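"""Reading and writing of all tabular artifacts.

Expression matrices are held in canonical features x samples orientation
regardless of the on-disk layout.  The canonical on-disk layout written by
this package puts samples in rows and features in columns; a transposed
dialect is handled via an orientation flag on read.  Missing-value markers
accepted on read: empty cell, ``NA``, ``NaN``, ``null`` (any case).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_MARKERS = ["", "NA", "NaN", "nan", "null", "NULL", "Null", "na"]

#: floating-point precision used by every writer
FLOAT_FORMAT = "%.6f"


def _sep_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


@dataclass
class ExpressionDataset:
    """One omics layer: a feature-by-sample expression matrix.

    ``values`` is a pandas DataFrame with feature IDs on the index and
    sample IDs on the columns.  Both ID axes must be duplicate-free.
    """

    values: pd.DataFrame
    omics_kind: str  # "miRNA" | "mRNA"

    def __post_init__(self) -> None:
        if self.omics_kind not in ("miRNA", "mRNA"):
            raise ValueError(f"unknown omics kind: {self.omics_kind!r}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dupes}")
        if self.values.size == 0:
            raise ValueError("empty expression table")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionDataset":
        missing = [f for f in feature_ids if f not in self.values.index]
        if missing:
            raise KeyError(f"features not in dataset: {missing[:5]}")
        return ExpressionDataset(self.values.loc[list(feature_ids)], self.omics_kind)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionDataset":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in dataset: {missing[:5]}")
        return ExpressionDataset(self.values[list(sample_ids)], self.omics_kind)


@dataclass
class PairedOmicsDataset:
    """Aligned miRNA + mRNA layers over the same samples with binary labels.

    ``labels`` is a pandas Series indexed by sample ID with values in
    {0, 1}; 1 = case, 0 = control.  Sample order is identical across the
    three components.
    """

    mirna: ExpressionDataset
    mrna: ExpressionDataset
    labels: pd.Series

    def __post_init__(self) -> None:
        sm = self.mirna.sample_ids
        if self.mrna.sample_ids != sm or list(self.labels.index) != sm:
            raise ValueError("miRNA, mRNA and label sample orders differ")
        uniq = set(self.labels.unique().tolist())
        if not uniq <= {0, 1} or len(uniq) != 2:
            raise ValueError("labels must contain both classes coded 0/1")
        counts = self.labels.value_counts()
        if counts.min() < 2:
            raise ValueError("each class needs at least 2 samples")

    @property
    def sample_ids(self) -> list[str]:
        return self.mirna.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    def subset_samples(self, sample_ids: Sequence[str]) -> "PairedOmicsDataset":
        return PairedOmicsDataset(
            self.mirna.subset_samples(sample_ids),
            self.mrna.subset_samples(sample_ids),
            self.labels.loc[list(sample_ids)],
        )


@dataclass(frozen=True)
class StarModule:
    """One star-shaped regulatory module.

    A single center miRNA, the seed mRNA (its strongest MI partner) and the
    ordered set of member mRNAs; ``member_mi`` records, for each member, the
    mutual information (bits) that admitted it.
    """

    center_mirna: str
    seed_mrna: str
    members: tuple[str, ...]
    member_mi: Mapping[str, float] = field(hash=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("module has no members")
        if self.seed_mrna not in self.members:
            raise ValueError("seed mRNA must be a member of its module")
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate members in module")
        if self.member_mi and set(self.member_mi) != set(self.members):
            raise ValueError("member_mi must cover exactly the members")


def read_expression_table(
    path: str | Path,
    omics_kind: str,
    orientation: str = "features_in_columns",
    delimiter: str | None = None,
) -> ExpressionDataset:
    """Read a delimited expression table into canonical orientation.

    ``orientation`` names where features live on disk; the returned dataset
    is always features x samples.  Non-numeric cells become NaN.
    """
    if orientation not in ("features_in_rows", "features_in_columns"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    sep = _sep_for(Path(path), delimiter)
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=MISSING_MARKERS, keep_default_na=False
    )
    if df.size == 0:
        raise ValueError(f"empty expression table: {path}")
    df = df.apply(pd.to_numeric, errors="coerce")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    if orientation == "features_in_columns":
        df = df.T
    return ExpressionDataset(df, omics_kind)


def write_expression_table(
    ds: ExpressionDataset, path: str | Path, delimiter: str | None = None
) -> None:
    """Write in the canonical on-disk layout (samples in rows)."""
    sep = _sep_for(Path(path), delimiter)
    ds.values.T.to_csv(path, sep=sep, float_format=FLOAT_FORMAT, index_label="sample_id")


def read_labels(
    path: str | Path,
    case_label: str | None = None,
    delimiter: str | None = None,
) -> pd.Series:
    """Read a two-column (sample_id, class) file into a 0/1 label Series.

    ``case_label`` names the string coded as case (=1).  When omitted, the
    common conventions case/control, tumor/normal, 1/0 are recognised;
    anything else is an error asking for an explicit mapping.
    """
    sep = _sep_for(Path(path), delimiter)
    df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("label file needs two columns: sample_id, class")
    if df.shape[0] == 0:
        raise ValueError(f"empty label file: {path}")
    sample_ids = df.iloc[:, 0].astype(str)
    classes = df.iloc[:, 1].astype(str)
    if sample_ids.duplicated().any():
        raise ValueError(
            f"sample listed twice: {sample_ids[sample_ids.duplicated()].tolist()}"
        )
    distinct = sorted(classes.unique())
    if len(distinct) > 2:
        raise ValueError(f"more than two classes: {distinct}")
    if case_label is None:
        conventions = {"case", "tumor", "tumour", "cancer", "1", "positive", "disease"}
        inferred = [c for c in distinct if c.lower() in conventions]
        if len(inferred) != 1:
            raise ValueError(
                f"cannot infer which of {distinct} is the case class; "
                "pass case_label explicitly"
            )
        case_label = inferred[0]
    elif case_label not in distinct:
        raise ValueError(f"case label {case_label!r} absent from file classes {distinct}")
    labels = (classes == case_label).astype(np.int8)
    labels.index = sample_ids
    labels.name = "label"
    return labels


def write_labels(labels: pd.Series, path: str | Path, delimiter: str | None = None) -> None:
    sep = _sep_for(Path(path), delimiter)
    out = pd.DataFrame(
        {"sample_id": labels.index, "class": np.where(labels.values == 1, "case", "control")}
    )
    out.to_csv(path, sep=sep, index=False)


def align_samples(
    mirna: ExpressionDataset, mrna: ExpressionDataset, labels: pd.Series
) -> PairedOmicsDataset:
    """Restrict both layers and the labels to their shared samples.

    The intersection is taken over the two sample-ID sets and the labelled
    samples, ordered lexicographically (canonical order).  Dropped samples
    are logged.
    """
    shared = sorted(set(mirna.sample_ids) & set(mrna.sample_ids) & set(labels.index))
    if not shared:
        raise ValueError("no shared samples between miRNA, mRNA and labels")
    for name, ids in (
        ("miRNA", mirna.sample_ids),
        ("mRNA", mrna.sample_ids),
        ("labels", list(labels.index)),
    ):
        dropped = sorted(set(ids) - set(shared))
        if dropped:
            logger.info("align_samples: dropping %d %s-only samples", len(dropped), name)
    sub_labels = labels.loc[shared].astype(np.int8)
    if sub_labels.nunique() < 2:
        raise ValueError("shared samples cover a single class")
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared samples; need at least 4")
    return PairedOmicsDataset(
        mirna.subset_samples(shared), mrna.subset_samples(shared), sub_labels
    )


SCORING_COLUMNS = [
    "Group",
    "Accuracy",
    "Sensitivity",
    "Specificity",
    "FM",
    "Precision",
    "CohensKappa",
    "AUC",
]


def write_scoring_table(records: Iterable, path: str | Path) -> None:
    """Write ranked per-module scores (one row per module, ranking order)."""
    rows = [
        {
            "Group": r.module.center_mirna,
            "Accuracy": r.accuracy,
            "Sensitivity": r.sensitivity,
            "Specificity": r.specificity,
            "FM": r.f_measure,
            "Precision": r.precision,
            "CohensKappa": r.cohens_kappa,
            "AUC": r.auc,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=SCORING_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_scoring_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != SCORING_COLUMNS:
        raise ValueError(f"unexpected scoring table columns: {list(df.columns)}")
    return df


def write_module_file(modules: Iterable[StarModule], path: str | Path) -> None:
    """Write modules in a GMT-like format.

    One line per module: center miRNA, seed mRNA, then every member mRNA,
    tab-separated.  The seed is always a member, so no line has fewer than
    three fields.
    """
    with open(path, "w") as fh:
        for m in modules:
            fh.write("\t".join([m.center_mirna, m.seed_mrna, *m.members]) + "\n")


def read_module_file(path: str | Path) -> list[StarModule]:
    modules: list[StarModule] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: module line with <3 fields")
            modules.append(
                StarModule(center_mirna=fields[0], seed_mrna=fields[1], members=tuple(fields[2:]))
            )
    return modules


PERFORMANCE_COLUMNS = [
    "n_groups",
    "mean_n_genes",
    "accuracy",
    "sensitivity",
    "specificity",
    "f_measure",
    "precision",
    "auc",
    "sd_auc",
]


def write_performance_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT, columns=PERFORMANCE_COLUMNS)


def read_performance_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


RANKING_COLUMNS = ["miRNA", "rho", "p_value", "appearances", "rank"]


def write_ranking_table(ranking: Iterable, path: str | Path) -> None:
    rows = [
        {
            "miRNA": a.element_id,
            "rho": a.rho_score,
            "p_value": a.corrected_p,
            "appearances": a.appearance_count,
            "rank": a.final_rank,
        }
        for a in ranking
    ]
    pd.DataFrame(rows, columns=RANKING_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_ranking_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
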