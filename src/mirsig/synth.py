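"""Synthetic PhenomiR-like record sets with planted, recoverable structure.

The generator emulates the record structure of curated miRNA-disease
fold-change databases: multiple studies per disease, dual- and single-valued
fold-changes, missing (study, miRNA) cells, and PubMed IDs shared across the
records of a study.  A planted module of miRNAs draws its fold-changes from
a shared latent factor within every disease, so that each scorer, the
consensus, and the class-level graph intersection have a known ground truth
to recover.

The latent-factor model: within a study, a module miRNA's fold-change is

    fc = loc + scale * (sqrt(rho) * z_study + sqrt(1 - rho) * eps)

with z_study shared by the whole study and eps private, giving pairwise
module correlation ~= rho; background miRNAs are pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np

from .networks import SignatureComponent
from .records import Dataset, ExpressionRecord, build_md_index

__all__ = ["SynthConfig", "GroundTruth", "RecoveryReport", "generate_dataset", "planted_truth"]


@dataclass
class SynthConfig:
    """Generator settings; defaults give a desk-scale recoverable instance.

    30 miRNAs across 3 diseases with 60 studies each and a 3-miRNA module at
    correlation 0.9 is strong planted structure that every scorer family can
    detect while keeping a full pipeline run to seconds.
    """

    n_mirnas: int = 30
    n_diseases: int = 3
    n_studies_per_disease: int = 60
    module_size: int = 3
    module_correlation: float = 0.9
    dual_value_fraction: float = 0.3
    missing_fraction: float = 0.1
    pmid_cocitation_rate: float = 0.5
    seed: int = 0
    fc_loc: float = 2.5
    fc_scale: float = 1.0

    def validate(self) -> None:
        if self.module_size > self.n_mirnas:
            raise ValueError("module_size cannot exceed n_mirnas")
        if not 0 < self.module_correlation < 1:
            raise ValueError("module_correlation must be in (0, 1)")
        for name in ("dual_value_fraction", "missing_fraction", "pmid_cocitation_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_mirnas", "n_diseases", "n_studies_per_disease", "module_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """Planted structure the pipeline is expected to recover."""

    module_members: set[str]
    planted_edges: dict[str, set[frozenset[str]]] = field(default_factory=dict)


@dataclass
class RecoveryReport:
    """Set overlap between planted and recovered signature edges."""

    n_planted: int
    n_recovered: int
    n_overlap: int

    @property
    def recall(self) -> float:
        return self.n_overlap / self.n_planted if self.n_planted else 1.0

    @property
    def precision(self) -> float:
        return self.n_overlap / self.n_recovered if self.n_recovered else 1.0


def generate_dataset(
    cfg: SynthConfig,
    class_layout: Mapping[str, list[str]] | None = None,
) -> tuple[Dataset, GroundTruth]:
    """Generate a record set plus the ground truth it plants.

    ``class_layout`` maps class names to disease-name lists; by default all
    generated diseases form one class.  Identical config and seed give an
    identical record list (and hence a byte-identical serialized file).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    mirnas = [f"mir-{i:03d}" for i in range(1, cfg.n_mirnas + 1)]
    diseases = [f"disease-{j:02d}" for j in range(1, cfg.n_diseases + 1)]
    module = set(mirnas[: cfg.module_size])
    if class_layout is None:
        class_layout = {"class-1": diseases}

    rho = cfg.module_correlation
    records: list[ExpressionRecord] = []
    pmid_counter = 0
    for disease in diseases:
        for s in range(1, cfg.n_studies_per_disease + 1):
            study_id = f"{disease}-study-{s:03d}"
            z = rng.standard_normal()
            cocited = rng.random() < cfg.pmid_cocitation_rate
            study_pmid = f"pmid-{disease}-{s:03d}"
            for mirna in mirnas:
                latent = (
                    np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.standard_normal()
                    if mirna in module
                    else rng.standard_normal()
                )
                fc_min = round(cfg.fc_loc + cfg.fc_scale * latent, 4)
                fc_max = None
                if rng.random() < cfg.dual_value_fraction:
                    fc_max = round(fc_min + 0.1 + abs(rng.normal(0.0, 0.5)), 4)
                missing = rng.random() < cfg.missing_fraction
                if cocited:
                    pmid = study_pmid
                else:
                    pmid_counter += 1
                    pmid = f"pmid-solo-{pmid_counter:06d}"
                if missing:
                    continue
                records.append(
                    ExpressionRecord(
                        study_id=study_id,
                        pmid=pmid,
                        disease=disease,
                        mirna=mirna,
                        fc_min=fc_min,
                        fc_max=fc_max,
                    )
                )

    pairs = {frozenset(p) for p in combinations(sorted(module), 2)}
    truth = GroundTruth(
        module_members=module,
        planted_edges={name: set(pairs) for name in class_layout},
    )
    return build_md_index(records), truth


def planted_truth(gt: GroundTruth, recovered: SignatureComponent) -> RecoveryReport:
    """Precision/recall of a recovered signature against the planted edges."""
    planted = gt.planted_edges.get(recovered.disease_class)
    if planted is None:
        # class name not in the layout: compare against the union
        planted = set().union(*gt.planted_edges.values()) if gt.planted_edges else set()
    found = set(recovered.edges)
    return RecoveryReport(
        n_planted=len(planted),
        n_recovered=len(found),
        n_overlap=len(planted & found),
    )
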