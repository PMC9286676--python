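"""Multi-evidence consensus calling of GR/MR target genes.

A gene is called a corticosteroid-receptor target when it satisfies all of:

1. regulated by glucocorticoids in at least one published transcriptomic
   study (the meta-analysis pool);
2. responsive in the in-house hippocampal RNA-seq experiment;
3. direction of regulation consistent across every reporting
   transcriptomic study;
4. associated with a GR and/or MR ChIP-seq binding site;

plus an enabled-by-default side rule requiring the gene to be reported by
at least ``min_reporting_studies`` distinct transcriptomic studies.
Evidence rows come from a TSV emulating a per-gene, per-study supplementary
compilation: (gene, source_type, study_id, direction, binding).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "EvidenceFormatError",
    "read_evidence",
    "validate_evidence",
    "classify_binding",
    "direction_consistent",
    "apply_consensus",
    "summarize_counts",
]

SOURCE_TYPES = {"meta_transcriptomic", "inhouse_rnaseq", "chipseq"}
DIRECTIONS = {"up", "down", "na"}
BINDINGS = {"GR", "MR", "both", "none"}
TRANSCRIPTOMIC = ("meta_transcriptomic", "inhouse_rnaseq")

CRITERIA = (
    "meta_reported",        # criterion 1
    "inhouse_responsive",   # criterion 2
    "direction_consistent", # criterion 3
    "receptor_binding",     # criterion 4
    "min_studies",          # >= min_reporting_studies side rule
)


class EvidenceFormatError(ValueError):
    pass


def validate_evidence(table: pd.DataFrame, source: str = "evidence") -> pd.DataFrame:
    """Validate schema, enumerations and uniqueness of an evidence table."""
    required = ["gene", "source_type", "study_id", "direction", "binding"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise EvidenceFormatError(f"{source}: missing column(s) {missing}")
    table = table[required].copy()
    table["gene"] = table["gene"].astype(str).str.strip()
    for row_no, row in enumerate(table.itertuples(index=False), start=1):
        if row.source_type not in SOURCE_TYPES:
            raise EvidenceFormatError(
                f"{source} row {row_no}: invalid source_type {row.source_type!r}"
            )
        if row.direction not in DIRECTIONS:
            raise EvidenceFormatError(
                f"{source} row {row_no}: invalid direction {row.direction!r}"
            )
        if row.binding not in BINDINGS:
            raise EvidenceFormatError(
                f"{source} row {row_no}: invalid binding {row.binding!r}"
            )
        if row.source_type == "chipseq":
            if row.binding == "none":
                raise EvidenceFormatError(
                    f"{source} row {row_no}: chipseq row must carry a binding annotation"
                )
            if row.direction != "na":
                raise EvidenceFormatError(
                    f"{source} row {row_no}: chipseq row must have direction 'na'"
                )
        else:
            if row.direction not in ("up", "down"):
                raise EvidenceFormatError(
                    f"{source} row {row_no}: transcriptomic row needs direction up/down"
                )
    dup = table.duplicated(subset=["gene", "study_id", "source_type"])
    if dup.any():
        row_no = int(dup.idxmax()) + 1
        rec = table.loc[dup.idxmax()]
        raise EvidenceFormatError(
            f"{source} row {row_no}: duplicate (gene={rec.gene!r}, "
            f"study={rec.study_id!r}, source={rec.source_type!r})"
        )
    return table


def read_evidence(path: str | Path) -> pd.DataFrame:
    """Read and validate an evidence TSV."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    return validate_evidence(table, source=str(path))


def classify_binding(gene: str, table: pd.DataFrame) -> str:
    """Union over a gene's ChIP-seq rows: GR, MR, both or none."""
    rows = table[(table["gene"] == gene) & (table["source_type"] == "chipseq")]
    if rows.empty:
        return "none"
    flags = set(rows["binding"])
    if "both" in flags or {"GR", "MR"} <= flags:
        return "both"
    return "GR" if "GR" in flags else "MR"


def direction_consistent(gene: str, table: pd.DataFrame) -> tuple[bool, str | None]:
    """Whether every transcriptomic row for the gene reports one direction.

    Returns (consistent, direction); a gene with no transcriptomic rows has
    an undefined direction and fails the criterion.
    """
    rows = table[
        (table["gene"] == gene) & table["source_type"].isin(TRANSCRIPTOMIC)
    ]
    if rows.empty:
        return False, None
    dirs = set(rows["direction"])
    if len(dirs) == 1:
        return True, dirs.pop()
    return False, None


def apply_consensus(
    table: pd.DataFrame,
    min_reporting_studies: int = 3,
    require_inhouse: bool = True,
) -> pd.DataFrame:
    """Evaluate every gene against the consensus criteria.

    Returns one row per *called* gene, sorted by symbol, with columns:
    gene, direction, binding_class, n_reporting_studies, one boolean per
    criterion, and a semicolon-joined provenance list of contributing
    transcriptomic study ids.  The result is invariant to evidence row
    order.
    """
    table = validate_evidence(table)
    calls = []
    for gene in sorted(table["gene"].unique()):
        rows = table[table["gene"] == gene]
        trans = rows[rows["source_type"].isin(TRANSCRIPTOMIC)]
        flags = {
            "meta_reported": (rows["source_type"] == "meta_transcriptomic").any(),
            "inhouse_responsive": (
                (rows["source_type"] == "inhouse_rnaseq").any()
                if require_inhouse else True
            ),
        }
        consistent, direction = direction_consistent(gene, table)
        flags["direction_consistent"] = consistent
        binding = classify_binding(gene, table)
        flags["receptor_binding"] = binding != "none"
        n_studies = trans["study_id"].nunique()
        flags["min_studies"] = n_studies >= min_reporting_studies
        if all(flags.values()):
            calls.append(
                {
                    "gene": gene,
                    "direction": direction,
                    "binding_class": binding,
                    "n_reporting_studies": int(n_studies),
                    **{f"crit_{k}": bool(v) for k, v in flags.items()},
                    "studies": ";".join(sorted(trans["study_id"].unique())),
                }
            )
    columns = (
        ["gene", "direction", "binding_class", "n_reporting_studies"]
        + [f"crit_{k}" for k in CRITERIA]
        + ["studies"]
    )
    return pd.DataFrame(calls, columns=columns)


def summarize_counts(table: pd.DataFrame, calls: pd.DataFrame) -> dict[str, int]:
    """Evidence-integration tallies mirroring the published funnel.

    Counts the union gene list, genes per exclusive ChIP-seq binding class,
    genes in the meta-analysis and the in-house experiment, the
    direction-consistent meta ∩ in-house subset, and the final calls by
    direction and binding class.
    """
    if table.empty:
        genes: list[str] = []
    else:
        table = validate_evidence(table)
        genes = sorted(table["gene"].unique())
    binding = {g: classify_binding(g, table) for g in genes}
    meta_genes = set(table.loc[table["source_type"] == "meta_transcriptomic", "gene"]) if genes else set()
    inhouse_genes = set(table.loc[table["source_type"] == "inhouse_rnaseq", "gene"]) if genes else set()
    consistent_overlap = {
        g for g in meta_genes & inhouse_genes if direction_consistent(g, table)[0]
    }
    summary = {
        "n_union_genes": len(genes),
        "n_binding_gr_only": sum(b == "GR" for b in binding.values()),
        "n_binding_mr_only": sum(b == "MR" for b in binding.values()),
        "n_binding_both": sum(b == "both" for b in binding.values()),
        "n_meta_reported": len(meta_genes),
        "n_inhouse_responsive": len(inhouse_genes),
        "n_consistent_overlap": len(consistent_overlap),
        "n_calls": len(calls),
        "n_calls_up": int((calls["direction"] == "up").sum()) if len(calls) else 0,
        "n_calls_down": int((calls["direction"] == "down").sum()) if len(calls) else 0,
        "n_calls_gr_only": int((calls["binding_class"] == "GR").sum()) if len(calls) else 0,
        "n_calls_mr_only": int((calls["binding_class"] == "MR").sum()) if len(calls) else 0,
        "n_calls_both": int((calls["binding_class"] == "both").sum()) if len(calls) else 0,
    }
    return summary
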