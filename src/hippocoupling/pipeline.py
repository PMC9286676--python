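"""End-to-end pipeline: preprocess -> profiles -> coupling -> consensus -> markers.

Configured from a YAML file or a :class:`PipelineConfig`; writes a run
directory with long/wide TSVs per stage, a manifest and a provenance log
(parameters and input digests; no wall-clock state, so identical inputs
reproduce byte-identical bundles).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import consensus as consensus_mod
from . import coupling as coupling_mod
from .io import log_normalize, qc_filter, read_annotation, read_counts, subset_cells
from .markers import find_all_markers
from .profiles import aggregate, zscore

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    mtx: str
    features: str
    barcodes: str
    annotation: str
    gene_sets: list[str] = field(default_factory=list)
    evidence: str | None = None
    out_dir: str = "run"
    keep_groups: list[str] | None = None
    min_cells: int = 1
    min_features: int = 100
    scale_factor: float = 10_000.0
    receptors: list[str] = field(default_factory=lambda: ["Nr3c1", "Nr3c2"])
    epsilon: float = 1e-6
    scope: str = "set_by_group_grid"
    shortlist_threshold: float = 0.6
    shortlist_rule: str = "either"
    min_reporting_studies: int = 3
    require_inhouse: bool = True
    marker_min_pct: float = 0.1
    marker_logfc_threshold: float = 0.25
    fc_mode: str = "expm1"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage and write the report bundle.

    Returns a manifest mapping artifact names to paths.  Any stage failure
    aborts with a stage-tagged error message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    def stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        stage("preprocess")
        matrix = read_counts(config.mtx, config.features, config.barcodes)
        annotation = read_annotation(config.annotation)
        if config.keep_groups:
            matrix, annotation = subset_cells(matrix, annotation, set(config.keep_groups))
        matrix, qc = qc_filter(matrix, config.min_cells, config.min_features)
        annotation = annotation[annotation["cell_id"].isin(set(matrix.cell_ids))]
        norm = log_normalize(matrix, config.scale_factor)
    except Exception as exc:
        raise RuntimeError(f"[preprocess] {exc}") from exc

    try:
        stage("profiles")
        profile = zscore(aggregate(norm, annotation))
        prof_path = out / "profile.tsv"
        profile.to_long().to_csv(prof_path, sep="\t", index=False, float_format="%.10g")
        manifest["profile"] = prof_path
    except Exception as exc:
        raise RuntimeError(f"[profiles] {exc}") from exc

    try:
        stage("coupling")
        shortlist_frames = []
        for gs_path in config.gene_sets:
            gene_set = coupling_mod.read_gene_set(gs_path)
            records = coupling_mod.couple(
                profile, config.receptors, gene_set,
                epsilon=config.epsilon, scope=config.scope,
            )
            rec_path = out / f"coupling_{gene_set.name}.tsv"
            records.to_csv(rec_path, sep="\t", index=False, float_format="%.10g")
            manifest[f"coupling_{gene_set.name}"] = rec_path
            for receptor in config.receptors:
                wide = coupling_mod.coupling_heatmap_table(records, receptor)
                wide_path = out / f"heatmap_{gene_set.name}_{receptor}.tsv"
                wide.to_csv(wide_path, sep="\t", float_format="%.10g")
                manifest[f"heatmap_{gene_set.name}_{receptor}"] = wide_path
            sl = coupling_mod.shortlist(
                records, threshold=config.shortlist_threshold, rule=config.shortlist_rule
            )
            sl.insert(0, "set", gene_set.name)
            shortlist_frames.append(sl)
        if shortlist_frames:
            sl_path = out / "shortlist.tsv"
            pd.concat(shortlist_frames, ignore_index=True).to_csv(
                sl_path, sep="\t", index=False
            )
            manifest["shortlist"] = sl_path
    except Exception as exc:
        raise RuntimeError(f"[coupling] {exc}") from exc

    try:
        stage("consensus")
        if config.evidence:
            table = consensus_mod.read_evidence(config.evidence)
            calls = consensus_mod.apply_consensus(
                table,
                min_reporting_studies=config.min_reporting_studies,
                require_inhouse=config.require_inhouse,
            )
            calls_path = out / "target_calls.tsv"
            calls.to_csv(calls_path, sep="\t", index=False)
            manifest["target_calls"] = calls_path
            summary = consensus_mod.summarize_counts(table, calls)
            summary_path = out / "consensus_summary.tsv"
            pd.Series(summary, name="count").rename_axis("quantity").to_csv(
                summary_path, sep="\t"
            )
            manifest["consensus_summary"] = summary_path
    except Exception as exc:
        raise RuntimeError(f"[consensus] {exc}") from exc

    try:
        stage("markers")
        markers = find_all_markers(
            norm, annotation,
            min_pct=config.marker_min_pct,
            logfc_threshold=config.marker_logfc_threshold,
            fc_mode=config.fc_mode,
        )
        markers_path = out / "markers.tsv"
        markers.to_csv(markers_path, sep="\t", index=False, float_format="%.10g")
        manifest["markers"] = markers_path
    except Exception as exc:
        raise RuntimeError(f"[markers] {exc}") from exc

    stage("report")
    provenance = {
        # out_dir identifies the bundle location, not the analysis; leaving it
        # out keeps reruns of one config byte-identical wherever they land
        "parameters": {
            k: v for k, v in vars(config).items() if k != "out_dir"
        },
        "qc": {"cells_removed": qc.cells_removed, "genes_removed": qc.genes_removed},
        "input_digests": {
            "mtx": _digest(config.mtx),
            "features": _digest(config.features),
            "barcodes": _digest(config.barcodes),
            "annotation": _digest(config.annotation),
            **{f"gene_set_{i}": _digest(p) for i, p in enumerate(config.gene_sets)},
            **({"evidence": _digest(config.evidence)} if config.evidence else {}),
        },
    }
    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2, sort_keys=True, default=str))
    manifest["provenance"] = prov_path
    man_path = out / "manifest.json"
    man_path.write_text(
        json.dumps({k: str(v) for k, v in sorted(manifest.items())}, indent=2)
    )
    manifest["manifest"] = man_path
    return manifest
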