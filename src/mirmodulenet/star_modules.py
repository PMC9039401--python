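"""Construction of star-shaped miRNA-mRNA modules (the grouping component).

For a candidate center miRNA, the seed mRNA is its strongest MI partner
(ties broken lexicographically).  If even the strongest partner falls below
the threshold tau the miRNA forms no module.  Expansion adds further mRNAs
in exactly one hop from the seed, under one of three criteria:

``center``  (default)  I(gene, center miRNA) >= tau, read off the MI matrix
                       row.  The MI matrix the pipeline builds is the
                       miRNA-mRNA matrix, and on data with planted modules
                       this criterion recovers the regulated gene block;
                       gene-gene coupling between co-targets is typically
                       much weaker than the miRNA-target coupling itself.
``seed``               I(gene, seed mRNA) >= tau, from the gene-gene
                       provider (an alternative reading of module
                       expansion via the mRNA side).
``strict``             both of the above.
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np

from .io_expression import PairedOmicsDataset, StarModule
from .mi import MIMatrix, build_mi_matrix, gene_gene_mi
from .preprocess import DEFilterResult

logger = logging.getLogger(__name__)

EXPANSION_MODES = ("center", "seed", "strict")

#: gene_gene_provider signature: (seed_id, candidate_ids) -> MI vector
GeneGeneProvider = Callable[[str, Sequence[str]], np.ndarray]


def build_star_module(
    center: str,
    mi_matrix: MIMatrix,
    gene_gene_provider: GeneGeneProvider | None,
    tau: float,
    expansion: str = "center",
) -> StarModule | None:
    """Build one star module, or None if the center has no partner >= tau."""
    if expansion not in EXPANSION_MODES:
        raise ValueError(f"unknown expansion mode: {expansion!r}")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if center not in mi_matrix.mirna_ids:
        raise KeyError(f"unknown center miRNA: {center!r}")
    if expansion in ("seed", "strict") and gene_gene_provider is None:
        raise ValueError(f"expansion={expansion!r} needs a gene_gene_provider")

    row = mi_matrix.row(center)
    # argmax with lexicographic tie-break: sort by (-MI, ID)
    seed = min(row, key=lambda g: (-row[g], g))
    if row[seed] < tau:
        return None

    candidates = [g for g in mi_matrix.mrna_ids if g != seed]
    member_mi: dict[str, float] = {seed: row[seed]}
    if expansion == "center":
        for g in candidates:
            if row[g] >= tau:
                member_mi[g] = row[g]
    else:
        gg = gene_gene_provider(seed, candidates)
        for g, v in zip(candidates, gg):
            if v >= tau and (expansion == "seed" or row[g] >= tau):
                member_mi[g] = float(v)
    members = tuple(sorted(member_mi))
    return StarModule(center_mirna=center, seed_mrna=seed, members=members, member_mi=member_mi)


def build_all_modules(
    paired_train: PairedOmicsDataset,
    de_result_mirna: DEFilterResult | Sequence[str],
    de_result_mrna: DEFilterResult | Sequence[str],
    tau: float = 0.25,
    bins: int = 3,
    expansion: str = "center",
) -> list[StarModule]:
    """One star-module attempt per candidate miRNA; centers without a
    qualifying partner are dropped.  Output is ordered by center ID, so the
    result is independent of input order.  mRNAs may belong to several
    modules."""
    mirnas = sorted(
        de_result_mirna.kept if isinstance(de_result_mirna, DEFilterResult) else de_result_mirna
    )
    mrnas = sorted(
        de_result_mrna.kept if isinstance(de_result_mrna, DEFilterResult) else de_result_mrna
    )
    if not mirnas or not mrnas:
        raise ValueError("empty candidate feature set")
    matrix = build_mi_matrix(paired_train, mirnas, mrnas, bins=bins)
    provider: GeneGeneProvider = lambda seed, cands: gene_gene_mi(
        paired_train.mrna, seed, cands, bins=bins
    )
    modules = []
    for center in mirnas:
        m = build_star_module(center, matrix, provider, tau, expansion=expansion)
        if m is not None:
            modules.append(m)
    if not modules:
        raise ValueError(
            f"no module survived the MI threshold tau={tau}; consider lowering --mi-threshold"
        )
    logger.info("build_all_modules: %d/%d centers formed modules", len(modules), len(mirnas))
    return modules
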