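"""Plug-in mutual-information estimation between expression profiles.

Profiles are discretized by equal-frequency (quantile) binning, the joint
histogram is formed, and MI is the plug-in estimate

    I(X;Y) = H(X) + H(Y) - H(X,Y)        (bits by default)

Entropy terms are accumulated over *sorted* count vectors, which makes the
estimate bitwise symmetric in its two arguments.  Tiny negative values from
floating point are clipped at 0.  MI is always computed on training samples
only; quantile binning is invariant to monotone per-feature transforms, so
z-scoring upstream does not change the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_expression import ExpressionDataset, PairedOmicsDataset

__all__ = ["MIMatrix", "discretize", "mutual_information", "build_mi_matrix", "gene_gene_mi"]


@dataclass
class MIMatrix:
    """Mutual information for every (miRNA, mRNA) pair of the given subsets."""

    mirna_ids: list[str]
    mrna_ids: list[str]
    values: np.ndarray  # shape (n_mirna, n_mrna), bits
    bin_count: int

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.mirna_ids), len(self.mrna_ids)):
            raise ValueError("MI matrix shape does not match ID lists")
        if (self.values < 0).any():
            raise ValueError("negative MI entry")
        if (self.values > np.log2(self.bin_count) + 1e-9).any():
            raise ValueError("MI entry exceeds log2(bin_count)")

    def row(self, mirna_id: str) -> dict[str, float]:
        i = self.mirna_ids.index(mirna_id)
        return dict(zip(self.mrna_ids, self.values[i]))


def discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency binning into ``bins`` integer labels.

    Sorted positions are cut into ``bins`` contiguous chunks of (near-)equal
    size; ties are resolved by stable sort order of (value, original index).
    A constant vector maps entirely to bin 0.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if n < bins:
        raise ValueError(f"vector length {n} < bins {bins}")
    if np.ptp(x) == 0:
        return np.zeros(n, dtype=np.int64)
    order = np.argsort(x, kind="stable")
    labels = np.empty(n, dtype=np.int64)
    edges = np.round(np.arange(bins + 1) * n / bins).astype(int)
    for b in range(bins):
        labels[order[edges[b]: edges[b + 1]]] = b
    return labels


def _entropy_bits(counts: np.ndarray) -> float:
    """Shannon entropy of a count vector; summed over sorted counts so the
    result is independent of count ordering (exact symmetry downstream)."""
    counts = np.sort(counts[counts > 0])
    n = counts.sum()
    p = counts / n
    return float(-(p * np.log2(p)).sum())


def _mi_from_labels(lx: np.ndarray, ly: np.ndarray, bins: int, log_base: float) -> float:
    joint = np.bincount(lx * bins + ly, minlength=bins * bins)
    hx = _entropy_bits(np.bincount(lx, minlength=bins))
    hy = _entropy_bits(np.bincount(ly, minlength=bins))
    hxy = _entropy_bits(joint)
    mi = hx + hy - hxy
    if log_base != 2:
        mi /= np.log2(log_base)
    return max(mi, 0.0)


def mutual_information(
    x: np.ndarray, y: np.ndarray, bins: int = 3, log_base: float = 2
) -> float:
    """Plug-in MI (bits by default) between two real vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.shape[0] < 2 * bins:
        raise ValueError(f"need at least {2 * bins} samples for {bins} bins")
    return _mi_from_labels(discretize(x, bins), discretize(y, bins), bins, log_base)


def _discretize_matrix(values: np.ndarray, bins: int) -> np.ndarray:
    return np.vstack([discretize(row, bins) for row in values])


def build_mi_matrix(
    paired: PairedOmicsDataset,
    mirna_subset: Sequence[str],
    mrna_subset: Sequence[str],
    bins: int = 3,
    log_base: float = 2,
) -> MIMatrix:
    """MI over all (miRNA, mRNA) pairs of the given feature subsets.

    Each profile is discretized once; the joint histograms are then formed
    pairwise, so the cost is O(|miRNA| * |mRNA| * n).
    """
    if not len(mirna_subset) or not len(mrna_subset):
        raise ValueError("empty feature subset")
    lm = _discretize_matrix(
        paired.mirna.subset_features(mirna_subset).values.to_numpy(float), bins
    )
    lg = _discretize_matrix(
        paired.mrna.subset_features(mrna_subset).values.to_numpy(float), bins
    )
    out = np.empty((len(mirna_subset), len(mrna_subset)))
    for i in range(lm.shape[0]):
        for j in range(lg.shape[0]):
            out[i, j] = _mi_from_labels(lm[i], lg[j], bins, log_base)
    return MIMatrix(list(mirna_subset), list(mrna_subset), out, bins)


def gene_gene_mi(
    mrna: ExpressionDataset,
    seed_id: str,
    candidate_ids: Sequence[str],
    bins: int = 3,
    log_base: float = 2,
) -> np.ndarray:
    """MI of each candidate mRNA profile against the seed mRNA profile."""
    if seed_id not in mrna.values.index:
        raise KeyError(f"seed mRNA {seed_id!r} not in dataset")
    ls = discretize(mrna.values.loc[seed_id].to_numpy(float), bins)
    out = np.empty(len(candidate_ids))
    for j, cid in enumerate(candidate_ids):
        lc = discretize(mrna.values.loc[cid].to_numpy(float), bins)
        out[j] = _mi_from_labels(ls, lc, bins, log_base)
    return out
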