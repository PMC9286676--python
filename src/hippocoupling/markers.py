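"""One-vs-rest marker detection over cell-type groups.

For every group, every gene passing light pre-filters (detected in a
minimal fraction of cells on either side and showing a minimal absolute
log2 fold change) is tested with the two-sided Wilcoxon rank-sum test
against all remaining cells; p-values are Benjamini-Hochberg adjusted
across all gene x group hypotheses tested in the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._stats import fold_change_log2, rank_sum_p
from .io import NormalizedMatrix
from .profiles import canonical_group_order

logger = logging.getLogger(__name__)

__all__ = ["MarkerResult", "bh_adjust", "find_all_markers"]


@dataclass
class MarkerResult:
    gene: str
    group: str
    log2fc: float
    pct_in: float
    pct_out: float
    p: float
    p_adj: float


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def find_all_markers(
    norm: NormalizedMatrix,
    annotation: pd.DataFrame,
    genes: list[str] | None = None,
    min_pct: float = 0.1,
    logfc_threshold: float = 0.25,
    group_key: str = "group",
    min_cells: int = 3,
    prefilter: bool = True,
    fc_mode: str = "expm1",
) -> pd.DataFrame:
    """Rank-sum one-vs-rest markers for every group.

    ``min_pct`` is the minimal detection fraction required in the group or
    in the rest; ``logfc_threshold`` the minimal absolute log2 fold change.
    Groups with fewer than ``min_cells`` cells are skipped with a warning.
    ``prefilter=False`` tests every gene, which is what the enumeration
    oracles exercise.  Returns a DataFrame with columns gene, group,
    log2fc, pct_in, pct_out, p, p_adj sorted by (group, p).
    """
    ann = annotation.set_index("cell_id").loc[norm.cell_ids]
    labels = ann[group_key].to_numpy()
    groups = canonical_group_order(labels)
    if len(groups) < 2:
        raise ValueError("find_all_markers needs at least two groups")
    if genes is None:
        genes = list(norm.gene_ids)
    dense = np.asarray(
        norm.values[[norm.gene_index(g) for g in genes]].todense()
    )
    rows: list[dict] = []
    for group in groups:
        mask = labels == group
        if mask.sum() < min_cells:
            logger.warning("group %r has <%d cells; skipped", group, min_cells)
            continue
        vin = dense[:, mask]
        vout = dense[:, ~mask]
        pct_in = 100.0 * (vin > 0).mean(axis=1)
        pct_out = 100.0 * (vout > 0).mean(axis=1)
        for gi, gene in enumerate(genes):
            lfc = fold_change_log2(vin[gi], vout[gi], fc_mode)
            if prefilter:
                if max(pct_in[gi], pct_out[gi]) < 100.0 * min_pct:
                    continue
                if abs(lfc) < logfc_threshold:
                    continue
            if np.all(vin[gi] == vin[gi][0]) and np.all(vout[gi] == vin[gi][0]):
                p = 1.0  # constant gene: no rank information
            else:
                p = rank_sum_p(vin[gi], vout[gi])
            rows.append(
                dict(gene=gene, group=group, log2fc=lfc,
                     pct_in=pct_in[gi], pct_out=pct_out[gi], p=p)
            )
    result = pd.DataFrame(rows, columns=["gene", "group", "log2fc", "pct_in", "pct_out", "p"])
    result["p_adj"] = bh_adjust(result["p"].to_numpy()) if len(result) else []
    return result.sort_values(["group", "p"], kind="stable").reset_index(drop=True)
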