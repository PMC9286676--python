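"""Synthetic labeled scRNA-seq counts and evidence tables with planted truth.

Counts follow the standard negative-binomial model for UMI data: gene ``g``
in cell ``c`` of group ``t`` is NB-distributed with mean
``mu_g * m_gt * f_c`` and variance ``mu + mu^2 / dispersion``, where
``mu_g`` is a gene-level base mean, ``m_gt`` an optional per-group
multiplier (receptor profiles, planted co-expression pairs) and ``f_c`` a
mean-one log-normal library-size factor.  Planted (gene_a, gene_b, group,
fold) pairs boost both genes' means in one group so the downstream coupling
score has a known argmax; the evidence simulator builds tables where every
gene carries a truth label against the four consensus criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CANONICAL_GROUPS, CountMatrix, write_counts

__all__ = [
    "SimulationConfig",
    "EvidenceSimConfig",
    "PlantedPair",
    "default_receptor_profile",
    "simulate_counts",
    "simulate_evidence",
    "write_fixture",
]

RECEPTOR_GENES = ("Nr3c1", "Nr3c2")

#: Glutamatergic + GABAergic subclasses vs non-neuronal, for the default
#: receptor emulation below.
_NEURONAL = {"Lamp5", "Vip", "Pvalb", "Sncg", "Sst", "DG", "CA1-ProS", "CA2", "CA3"}


@dataclass(frozen=True)
class PlantedPair:
    gene_a: str
    gene_b: str
    group: int
    fold: float


def default_receptor_profile(group_labels: tuple[str, ...]) -> dict[str, np.ndarray]:
    """Per-group mean multipliers for the two corticosteroid receptor genes.

    Emulates the hippocampal pattern: the MR transcript (Nr3c2) relatively
    high in neurons, the GR transcript (Nr3c1) relatively high in glia and
    other non-neuronal cells.
    """
    neuronal = np.array([g in _NEURONAL for g in group_labels])
    return {
        "Nr3c1": np.where(neuronal, 1.0, 4.0),
        "Nr3c2": np.where(neuronal, 6.0, 1.0),
    }


@dataclass
class SimulationConfig:
    """Parameters of the labeled count simulation.

    Defaults give the desk-scale stand-in for the real hippocampal matrix:
    13 subclasses x 200 cells x 2,000 genes.
    """

    n_groups: int = 13
    cells_per_group: int | list[int] = 200
    n_genes: int = 2000
    base_mean: float = 0.5
    dispersion: float = 2.0
    libsize_sigma: float = 0.3
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    receptor_profile: dict[str, np.ndarray] | None = None
    group_labels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.n_genes < 1:
            raise ValueError("n_groups and n_genes must be positive")
        if isinstance(self.cells_per_group, int):
            self.cells_per_group = [self.cells_per_group] * self.n_groups
        if len(self.cells_per_group) != self.n_groups:
            raise ValueError("cells_per_group length must equal n_groups")
        if any(c < 1 for c in self.cells_per_group):
            raise ValueError("cells_per_group entries must be positive")
        if self.base_mean <= 0 or self.dispersion <= 0:
            raise ValueError("base_mean and dispersion must be positive")
        if self.libsize_sigma < 0:
            raise ValueError("libsize_sigma must be non-negative")
        if self.group_labels is None:
            if self.n_groups == len(CANONICAL_GROUPS):
                self.group_labels = CANONICAL_GROUPS
            else:
                self.group_labels = tuple(f"group{i:02d}" for i in range(self.n_groups))
        if len(self.group_labels) != self.n_groups:
            raise ValueError("group_labels length must equal n_groups")
        for pair in self.planted_pairs:
            if not (0 <= pair.group < self.n_groups):
                raise ValueError(f"planted pair group {pair.group} out of range")
            if pair.fold <= 1:
                raise ValueError("planted fold must exceed 1")


def _gene_symbols(config: SimulationConfig) -> np.ndarray:
    """Gene names: the two receptor symbols first, then numbered genes."""
    n = config.n_genes
    names = [f"Gene{i:05d}" for i in range(n)]
    for i, r in enumerate(RECEPTOR_GENES[: min(2, n)]):
        names[i] = r
    return np.asarray(names, dtype=object)


def simulate_counts(
    config: SimulationConfig,
    return_truth: bool = False,
):
    """Draw a labeled count matrix (and annotation) from the NB model.

    Returns ``(CountMatrix, annotation DataFrame)``; with
    ``return_truth=True`` additionally returns the genes x groups matrix of
    true per-group NB means (library-size factor marginalized out, i.e. the
    expected count of an average-depth cell).
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_symbols(config)
    gene_index = {g: i for i, g in enumerate(genes)}

    # gene-level base means: log-normal spread around base_mean (mean-one factor)
    gene_means = config.base_mean * rng.lognormal(
        mean=-0.5, sigma=1.0, size=config.n_genes
    )

    # per-group multiplier matrix
    mult = np.ones((config.n_genes, config.n_groups))
    profile = config.receptor_profile
    if profile is None:
        profile = default_receptor_profile(config.group_labels)
    for gene, per_group in profile.items():
        if gene in gene_index:
            per_group = np.asarray(per_group, dtype=float)
            if per_group.shape != (config.n_groups,):
                raise ValueError(f"receptor_profile[{gene!r}] must have n_groups entries")
            mult[gene_index[gene]] *= per_group
    for pair in config.planted_pairs:
        for gene in (pair.gene_a, pair.gene_b):
            if gene not in gene_index:
                raise ValueError(f"planted gene {gene!r} not among simulated genes")
            mult[gene_index[gene], pair.group] *= pair.fold

    true_means = gene_means[:, None] * mult

    blocks = []
    cell_ids: list[str] = []
    rows = []
    sigma = config.libsize_sigma
    for t, (label, n_cells) in enumerate(
        zip(config.group_labels, config.cells_per_group)
    ):
        # mean-one log-normal library size factors
        lib = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_cells) if sigma else np.ones(n_cells)
        mu = true_means[:, [t]] * lib[None, :]
        r = config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
        blocks.append(sp.csr_matrix(counts))
        for c in range(n_cells):
            cid = f"{label}_c{c:04d}"
            cell_ids.append(cid)
            rows.append(
                {
                    "cell_id": cid,
                    "group": label,
                    "sex": "F" if rng.random() < 0.5 else "M",
                    "region": "HIP",
                    "subcluster": f"{label}_sub0",
                }
            )
    matrix = CountMatrix(sp.hstack(blocks).tocsr(), genes, np.asarray(cell_ids, dtype=object))
    annotation = pd.DataFrame(rows)
    if return_truth:
        truth = pd.DataFrame(true_means, index=genes, columns=list(config.group_labels))
        return matrix, annotation, truth
    return matrix, annotation


# ---------------------------------------------------------------------------
# evidence simulation

#: Decoy modes, one per consensus criterion.
FAILURE_MODES = ("no_meta", "no_inhouse", "inconsistent_direction", "no_binding")

INHOUSE_STUDY = "inhouse_rnaseq_2021"


@dataclass
class EvidenceSimConfig:
    """Parameters of the evidence-table simulation.

    ``n_true_targets`` genes satisfy all four consensus criteria (and are
    reported by at least three transcriptomic studies);
    ``decoys_per_failure_mode`` genes fail exactly one criterion each.
    ``n_studies_meta`` emulates the 17-study meta-analysis pool.
    """

    n_true_targets: int = 5
    decoys_per_failure_mode: int = 1
    n_studies_meta: int = 17
    direction_scheme: str = "random"  # "random" | "up" | "down"
    binding_probs: tuple[float, float, float] = (0.7, 0.1, 0.2)  # GR, MR, both
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_targets < 0 or self.decoys_per_failure_mode < 0:
            raise ValueError("counts must be non-negative")
        if self.n_studies_meta < 2:
            raise ValueError("need at least two meta-analysis studies")
        if self.direction_scheme not in ("random", "up", "down"):
            raise ValueError(f"unknown direction_scheme {self.direction_scheme!r}")


def _direction(rng: np.random.Generator, scheme: str) -> str:
    if scheme == "random":
        return "up" if rng.random() < 0.5 else "down"
    return scheme


def _binding_rows(gene: str, binding: str) -> list[dict]:
    rows = []
    if binding in ("GR", "both"):
        rows.append(
            dict(gene=gene, source_type="chipseq", study_id="chipseq_GR",
                 direction="na", binding="GR")
        )
    if binding in ("MR", "both"):
        rows.append(
            dict(gene=gene, source_type="chipseq", study_id="chipseq_MR",
                 direction="na", binding="MR")
        )
    return rows


def simulate_evidence(
    config: EvidenceSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build an evidence table plus per-gene truth labels.

    Returns ``(evidence, truth)``: evidence has columns (gene, source_type,
    study_id, direction, binding); truth has one row per gene with columns
    (gene, label, direction) where label is ``"pass"`` or
    ``"fail:<mode>"``.  True targets carry >= 2 meta-analysis studies plus
    the in-house study (so >= 3 reporting studies), consistent direction,
    and a GR/MR/both binding annotation; each decoy violates exactly its
    assigned criterion.
    """
    rng = np.random.default_rng(config.seed)
    meta_pool = [f"meta{i:02d}" for i in range(config.n_studies_meta)]
    binding_choices = ("GR", "MR", "both")
    rows: list[dict] = []
    truth: list[dict] = []

    def meta_rows(gene: str, n: int, direction: str) -> list[dict]:
        studies = rng.choice(meta_pool, size=n, replace=False)
        return [
            dict(gene=gene, source_type="meta_transcriptomic", study_id=s,
                 direction=direction, binding="none")
            for s in sorted(studies)
        ]

    def pick_binding() -> str:
        return str(rng.choice(binding_choices, p=config.binding_probs))

    for i in range(config.n_true_targets):
        gene = f"Target{i:03d}"
        d = _direction(rng, config.direction_scheme)
        n_meta = int(rng.integers(2, config.n_studies_meta + 1))
        rows += meta_rows(gene, n_meta, d)
        rows.append(dict(gene=gene, source_type="inhouse_rnaseq",
                         study_id=INHOUSE_STUDY, direction=d, binding="none"))
        rows += _binding_rows(gene, pick_binding())
        truth.append(dict(gene=gene, label="pass", direction=d))

    for mode in FAILURE_MODES:
        for i in range(config.decoys_per_failure_mode):
            gene = f"Decoy_{mode}_{i:03d}"
            d = _direction(rng, config.direction_scheme)
            if mode == "no_meta":
                rows.append(dict(gene=gene, source_type="inhouse_rnaseq",
                                 study_id=INHOUSE_STUDY, direction=d, binding="none"))
                rows += _binding_rows(gene, pick_binding())
            elif mode == "no_inhouse":
                rows += meta_rows(gene, int(rng.integers(3, config.n_studies_meta + 1)), d)
                rows += _binding_rows(gene, pick_binding())
            elif mode == "inconsistent_direction":
                other = "down" if d == "up" else "up"
                rows += meta_rows(gene, int(rng.integers(2, config.n_studies_meta + 1)), d)
                rows.append(dict(gene=gene, source_type="inhouse_rnaseq",
                                 study_id=INHOUSE_STUDY, direction=other, binding="none"))
                rows += _binding_rows(gene, pick_binding())
            else:  # no_binding
                rows += meta_rows(gene, int(rng.integers(2, config.n_studies_meta + 1)), d)
                rows.append(dict(gene=gene, source_type="inhouse_rnaseq",
                                 study_id=INHOUSE_STUDY, direction=d, binding="none"))
            truth.append(dict(gene=gene, label=f"fail:{mode}", direction=d))

    columns = ["gene", "source_type", "study_id", "direction", "binding"]
    evidence = pd.DataFrame(rows, columns=columns)
    truth_df = pd.DataFrame(truth, columns=["gene", "label", "direction"])
    return evidence, truth_df


def write_fixture(
    matrix: CountMatrix,
    annotation: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the simulated matrix and annotation as an on-disk fixture."""
    return write_counts(matrix, annotation, out_dir)
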