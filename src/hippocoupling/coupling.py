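"""Receptor-gene coupling scores across cell types.

The coupling score of a receptor gene j (Nr3c1 or Nr3c2) with a gene of
interest i in cell type t is

    k_ijt = log10(x_it * x_jt)

where x are per-group average expression values, and the normalized score

    c_ijt = (k_ijt - min_S k) / (max_S k - min_S k)

min-max rescales k within a gene set S so the best co-expressed (gene,
cell type) combination scores 1 and the worst 0.  Averages are floored at
a small epsilon before the log so absent genes land at the block minimum
instead of -inf.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import TypeProfile

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "read_gene_set",
    "coupling_raw",
    "normalize_coupling",
    "couple",
    "shortlist",
    "coupling_heatmap_table",
]


@dataclass
class GeneSet:
    """A named, ordered set of gene symbols (steroid receptors,
    coregulators, neurotransmitter/neuropeptide receptors, target genes...)."""

    name: str
    members: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            dup = pd.Series(self.members).value_counts()
            raise ValueError(
                f"gene set {self.name!r} has duplicate member "
                f"{dup[dup > 1].index[0]!r}"
            )


def read_gene_set(path: str | Path) -> GeneSet:
    """Read a one-symbol-per-line TSV whose header names the set."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"{path}: need a header line and at least one member")
    return GeneSet(name=lines[0], members=lines[1:], provenance=str(path))


def coupling_raw(
    profile: TypeProfile,
    receptor: str,
    gene_set: GeneSet,
    epsilon: float = 1e-6,
) -> pd.DataFrame:
    """Raw coupling k_ijt for one receptor over a gene set, genes x groups.

    Gene-set members missing from the profile are reported and skipped;
    the receptor itself must be present.  Averages below ``epsilon`` are
    floored there, so k is finite everywhere.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if receptor not in profile.x.index:
        raise KeyError(f"receptor {receptor!r} not in profile")
    present = [g for g in gene_set.members if g in profile.x.index]
    missing = [g for g in gene_set.members if g not in profile.x.index]
    if missing:
        logger.warning(
            "gene set %s: %d member(s) missing from profile, skipped: %s",
            gene_set.name, len(missing), ", ".join(missing),
        )
    if not present:
        raise ValueError(f"no member of gene set {gene_set.name!r} is in the profile")
    xi = np.maximum(profile.x.loc[present].to_numpy(), epsilon)
    xj = np.maximum(profile.x.loc[receptor].to_numpy(), epsilon)
    k = np.log10(xi * xj[None, :])
    return pd.DataFrame(k, index=present, columns=profile.x.columns)


def normalize_coupling(k: pd.DataFrame, scope: str = "set_by_group_grid") -> pd.DataFrame:
    """Min-max normalize a raw coupling block to [0, 1].

    ``scope="set_by_group_grid"`` (default) rescales over the whole
    (gene in S) x (group) grid — one shared scale per receptor, matching a
    heatmap with a single color bar; ``scope="per_group"`` rescales each
    group's column separately.  A degenerate block (max = min) maps to all
    zeros.
    """
    if k.empty:
        raise ValueError("empty coupling block")
    if scope == "set_by_group_grid":
        lo, hi = k.to_numpy().min(), k.to_numpy().max()
        if hi == lo:
            return k * 0.0
        return (k - lo) / (hi - lo)
    if scope == "per_group":
        lo = k.min(axis=0)
        hi = k.max(axis=0)
        span = (hi - lo).replace(0, np.inf)
        return (k - lo).div(span, axis=1)
    raise ValueError(f"unknown normalization scope {scope!r}")


def couple(
    profile: TypeProfile,
    receptors: list[str],
    gene_set: GeneSet,
    epsilon: float = 1e-6,
    scope: str = "set_by_group_grid",
) -> pd.DataFrame:
    """Long-format coupling records for one gene set and several receptors.

    Columns: receptor, gene, group, k, c_norm, set.  Normalization is per
    (receptor, set) block.
    """
    records = []
    for j in receptors:
        k = coupling_raw(profile, j, gene_set, epsilon=epsilon)
        c = normalize_coupling(k, scope=scope)
        long_k = k.stack().rename("k").reset_index()
        long_k.columns = ["gene", "group", "k"]
        long_k.insert(0, "receptor", j)
        long_k["c_norm"] = c.stack().to_numpy()
        long_k["set"] = gene_set.name
        records.append(long_k)
    return pd.concat(records, ignore_index=True)


def shortlist(
    records: pd.DataFrame,
    threshold: float = 0.6,
    rule: str = "either",
) -> pd.DataFrame:
    """(gene, group) combinations whose c_norm strictly exceeds the threshold.

    ``rule="either"`` keeps combinations above threshold for at least one
    receptor and annotates which; ``rule="both"`` requires every receptor
    present in the records.  One row per (gene, group), with boolean
    columns per receptor and a ``receptors`` summary column.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    if rule not in ("either", "both"):
        raise ValueError(f"unknown shortlist rule {rule!r}")
    receptors = sorted(records["receptor"].unique())
    wide = records.pivot_table(
        index=["gene", "group"], columns="receptor", values="c_norm"
    )
    passed = wide > threshold
    if rule == "either":
        keep = passed.any(axis=1)
    else:
        keep = passed.all(axis=1)
    out = passed.loc[keep].reset_index()
    out.columns.name = None
    out["receptors"] = [
        ";".join(r for r in receptors if row[r])
        for _, row in out.iterrows()
    ]
    return out


def coupling_heatmap_table(
    records: pd.DataFrame,
    receptor: str,
    row_order: list[str] | None = None,
    col_order: list[str] | None = None,
    fill_value: float = np.nan,
) -> pd.DataFrame:
    """Wide genes x groups c_norm matrix for one receptor, heatmap-ready.

    Explicit row/column orders are honoured; grid cells absent from the
    records are filled with ``fill_value`` and warned about.
    """
    sub = records[records["receptor"] == receptor]
    if sub.empty:
        raise ValueError(f"no records for receptor {receptor!r}")
    wide = sub.pivot_table(index="gene", columns="group", values="c_norm")
    if row_order is not None:
        wide = wide.reindex(index=row_order)
    if col_order is not None:
        wide = wide.reindex(columns=col_order)
    if wide.isna().any().any():
        n = int(wide.isna().sum().sum())
        logger.warning("heatmap table for %s: %d missing grid cell(s) filled", receptor, n)
        wide = wide.fillna(fill_value)
    wide.index.name = "gene"
    wide.columns.name = None
    return wide
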