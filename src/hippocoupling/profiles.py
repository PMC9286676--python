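"""Per-cell-type expression profiles and group contrasts.

``aggregate`` collapses the log-normalized matrix to a genes x groups table
of average expression x_it plus the percentage of positive cells;
``zscore`` row-standardizes it for dot-plot-style displays.  Contrast
helpers run the paired signed-rank test on per-group averages (gene vs gene
across cell types) and the rank-sum test within one group's cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import fold_change_log2, rank_sum_p, signed_rank_p
from .io import CANONICAL_GROUPS, NormalizedMatrix

__all__ = [
    "TypeProfile",
    "GroupContrast",
    "canonical_group_order",
    "aggregate",
    "zscore",
    "split_by",
    "paired_gene_contrast",
    "gene_within_group_contrast",
]


def canonical_group_order(groups) -> list[str]:
    """Order group labels canonically (hippocampal subclass display order
    when all labels belong to it, else lexicographic)."""
    groups = list(dict.fromkeys(groups))
    if set(groups) <= set(CANONICAL_GROUPS):
        return [g for g in CANONICAL_GROUPS if g in groups]
    return sorted(groups)


@dataclass
class TypeProfile:
    """Per-group expression summary.

    ``x``: genes x groups mean log-normalized expression (x_it);
    ``pct_pos``: percentage of the group's cells with nonzero raw count,
    0-100; ``n_cells``: cells per group; ``z``: optional row-standardized
    version of ``x``.
    """

    x: pd.DataFrame
    pct_pos: pd.DataFrame
    n_cells: pd.Series
    z: pd.DataFrame | None = None

    @property
    def groups(self) -> list[str]:
        return list(self.x.columns)

    def to_long(self) -> pd.DataFrame:
        """Long-format TSV-ready table (gene, group, x, pct_pos, n_cells[, z])."""
        long = self.x.stack().rename("x").reset_index()
        long.columns = ["gene", "group", "x"]
        long["pct_pos"] = self.pct_pos.stack().to_numpy()
        long["n_cells"] = long["group"].map(self.n_cells).astype(int)
        if self.z is not None:
            long["z"] = self.z.stack().to_numpy()
        return long


@dataclass
class GroupContrast:
    gene_a: str
    gene_b: str
    group: str  # "all" for profile-wide paired contrasts
    log2fc: float
    p: float
    p_adj: float
    test_name: str


def aggregate(
    norm: NormalizedMatrix,
    annotation: pd.DataFrame,
    group_key: str = "group",
    genes: list[str] | None = None,
) -> TypeProfile:
    """Average the normalized matrix within each group.

    x_it is the arithmetic mean of log-normalized values over the cells of
    group t; pct_pos the percentage of those cells with a nonzero raw count
    (the sparsity pattern is preserved by log-normalization, so nonzero
    normalized value is equivalent).  Groups with zero cells are simply
    absent; groups are ordered canonically.
    """
    ann = annotation.set_index("cell_id").loc[norm.cell_ids]
    if group_key not in ann.columns:
        raise KeyError(f"annotation lacks column {group_key!r}")
    labels = ann[group_key].to_numpy()
    order = canonical_group_order(labels)

    if genes is not None:
        missing = [g for g in genes if g not in set(norm.gene_ids)]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        rows = [norm.gene_index(g) for g in genes]
        values = norm.values[rows]
        gene_ids = np.asarray(genes, dtype=object)
    else:
        values = norm.values
        gene_ids = norm.gene_ids

    x = np.zeros((values.shape[0], len(order)))
    pct = np.zeros_like(x)
    n_cells = {}
    nz = values.copy()
    nz.data = np.ones_like(nz.data)
    for j, g in enumerate(order):
        mask = labels == g
        n = int(mask.sum())
        n_cells[g] = n
        x[:, j] = np.asarray(values[:, mask].mean(axis=1)).ravel()
        pct[:, j] = 100.0 * np.asarray(nz[:, mask].mean(axis=1)).ravel()
    return TypeProfile(
        x=pd.DataFrame(x, index=gene_ids, columns=order),
        pct_pos=pd.DataFrame(pct, index=gene_ids, columns=order),
        n_cells=pd.Series(n_cells, name="n_cells"),
    )


def zscore(profile: TypeProfile) -> TypeProfile:
    """Row-standardize the profile: z_it = (x_it - mean_t) / sd_t.

    Sample standard deviation (ddof=1); constant rows get all-zero z.
    Requires at least two groups.
    """
    if profile.x.shape[1] < 2:
        raise ValueError("zscore needs at least two groups")
    x = profile.x
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    z = x.sub(mu, axis=0).div(sd.where(sd > 0, np.inf), axis=0)
    return TypeProfile(x=profile.x, pct_pos=profile.pct_pos,
                       n_cells=profile.n_cells, z=z)


def split_by(annotation: pd.DataFrame, keys=("group", "sex")) -> pd.Series:
    """Composite group labels crossing annotation keys (e.g. group x sex).

    Returns a per-cell Series of "key1|key2" labels indexed by cell_id;
    combinations absent from the data simply do not occur.  Feeding the
    result back as a group column reproduces per-sex profiles.
    """
    for k in keys:
        if k not in annotation.columns:
            raise KeyError(f"annotation lacks column {k!r}")
    parts = [annotation[k].astype(str) for k in keys]
    label = parts[0]
    for p in parts[1:]:
        label = label + "|" + p
    return pd.Series(label.to_numpy(), index=annotation["cell_id"].to_numpy(),
                     name="|".join(keys))


def paired_gene_contrast(
    profile: TypeProfile,
    gene_a: str,
    gene_b: str,
    fc_mode: str = "expm1",
) -> GroupContrast:
    """Paired two-sided signed-rank test of two genes across cell types.

    Pairs the per-group average expression vectors (x_a,t, x_b,t) over the
    profile's groups — the "throughout cell types" comparison.  All-zero
    differences give p = 1.
    """
    for g in (gene_a, gene_b):
        if g not in profile.x.index:
            raise KeyError(f"gene {g!r} not in profile")
    if profile.x.shape[1] < 2:
        raise ValueError("paired contrast needs at least two groups")
    xa = profile.x.loc[gene_a].to_numpy()
    xb = profile.x.loc[gene_b].to_numpy()
    p = signed_rank_p(xa, xb)
    lfc = 0.0 if np.array_equal(xa, xb) else fold_change_log2(xa, xb, fc_mode)
    return GroupContrast(gene_a, gene_b, "all", lfc, p, p, "wilcoxon_signed_rank")


def gene_within_group_contrast(
    norm: NormalizedMatrix,
    annotation: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    group: str,
    group_key: str = "group",
    fc_mode: str = "expm1",
) -> GroupContrast:
    """Rank-sum test of two genes over the cells of one group."""
    ann = annotation.set_index("cell_id").loc[norm.cell_ids]
    mask = (ann[group_key] == group).to_numpy()
    if mask.sum() == 0:
        raise ValueError(f"group {group!r} not present")
    if mask.sum() < 2:
        raise ValueError(f"group {group!r} has fewer than 2 cells")
    va = norm.gene_values(gene_a)[mask]
    vb = norm.gene_values(gene_b)[mask]
    if np.array_equal(va, vb):
        return GroupContrast(gene_a, gene_b, group, 0.0, 1.0, 1.0, "wilcoxon_rank_sum")
    p = rank_sum_p(va, vb)
    lfc = fold_change_log2(va, vb, fc_mode)
    return GroupContrast(gene_a, gene_b, group, lfc, p, p, "wilcoxon_rank_sum")
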