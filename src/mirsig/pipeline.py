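"""End-to-end orchestration: parse -> matrix -> infer -> consensus ->
validate -> disease networks -> signatures, as one reproducible run.

All randomness flows from the single run seed through per-stage derived
seeds, so a manifest plus the same seed reproduces the run bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import consensus as cns
from . import inference, matrices, networks, records, validation

logger = logging.getLogger("mirsig")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    Exactly one of ``min_confidence`` / ``top_fraction`` selects the
    high-confidence edge filter; the defaults mirror the method's standard
    settings (all six algorithms, 0.9 confidence cutoff).
    """

    input: str | Path
    outdir: str | Path
    matrix_method: str = "average"
    algorithms: tuple[str, ...] = inference.ALGORITHMS
    consensus_mode: str = "exact"
    min_confidence: float | None = 0.9
    top_fraction: float | None = None
    class_layout: Mapping[str, list[str]] | None = None
    seed: int = 0
    n_trees: int = 100
    mi_bins: int | None = None
    missing_policy: str = "pairwise_complete"  # for the correlation family
    dialect: Mapping[str, str] | None = None

    def validate(self) -> None:
        if not self.algorithms:
            raise ValueError("algorithm list must be non-empty")
        if (self.min_confidence is None) == (self.top_fraction is None):
            raise ValueError("set exactly one of min_confidence / top_fraction")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _type3_subset(result: cns.ConsensusResult) -> cns.ConsensusResult:
    kept = {
        e: s
        for e, s in result.final_rank.items()
        if networks.classify_edge_type(e) == 3
    }
    return cns.ConsensusResult(
        final_rank=kept,
        k_algorithms=result.k_algorithms,
        algorithms=list(result.algorithms),
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage, write all outputs under ``cfg.outdir``, and
    return (and write) a manifest of output paths, parameters and timings."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            "input": str(cfg.input),
            "matrix_method": cfg.matrix_method,
            "algorithms": list(cfg.algorithms),
            "consensus_mode": cfg.consensus_mode,
            "min_confidence": cfg.min_confidence,
            "top_fraction": cfg.top_fraction,
            "seed": cfg.seed,
            "n_trees": cfg.n_trees,
            "mi_bins": cfg.mi_bins,
            "missing_policy": cfg.missing_policy,
        },
        "outputs": {},
        "timings_s": {},
        "stats": {},
    }
    rng = np.random.default_rng(cfg.seed)
    stage_seeds = {alg: int(s) for alg, s in
                   zip(inference.ALGORITHMS, rng.integers(0, 2**31 - 1, len(inference.ALGORITHMS)))}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(name, exc) from exc
            manifest["timings_s"][name] = round(time.perf_counter() - t0, 4)
            logger.info("stage %s done in %.2fs", name, manifest["timings_s"][name])
            return out
        return deco

    dataset = stage("parse")(lambda: records.parse_records(cfg.input, dialect=cfg.dialect))
    manifest["stats"]["n_records"] = len(dataset.records)
    manifest["stats"]["n_nodes"] = dataset.n_nodes
    manifest["stats"]["n_studies"] = dataset.n_studies
    manifest["stats"]["dropped_rows"] = dataset.drop_report.dropped
    manifest["stats"]["interaction_space"] = cns.interaction_space(dataset.n_nodes)

    matrix = stage("matrix")(lambda: matrices.build_matrix(dataset, cfg.matrix_method))
    matrix_path = outdir / f"matrix_{cfg.matrix_method}.csv"
    matrix.to_csv(matrix_path)
    manifest["outputs"]["matrix"] = str(matrix_path)

    score_sets = stage("infer")(
        lambda: inference.score_all(
            matrix,
            algorithms=tuple(cfg.algorithms),
            seed=stage_seeds["genie3"],
            mi_cfg=inference.MIEstimatorConfig(bin_count=cfg.mi_bins),
            n_trees=cfg.n_trees,
            corr_missing_policy=cfg.missing_policy,
        )
    )
    manifest["outputs"]["scores"] = {}
    for alg, sm in score_sets.items():
        path = outdir / f"scores_{alg}.csv"
        sm.to_csv(path)
        manifest["outputs"]["scores"][alg] = str(path)

    result = stage("consensus")(
        lambda: cns.average_rank_consensus(
            [cns.rank_descending(score_sets[a]) for a in cfg.algorithms],
            mode=cfg.consensus_mode,
        )
    )
    consensus_path = outdir / "consensus.csv"
    result.to_csv(consensus_path)
    manifest["outputs"]["consensus"] = str(consensus_path)
    manifest["stats"]["k_algorithms"] = result.k_algorithms

    type3 = _type3_subset(result)

    def _validate():
        truth = validation.build_truth_network(dataset)
        labels = validation.label_edges(type3, truth)
        n_pos = sum(labels.values())
        if n_pos == 0 or n_pos == len(labels):
            logger.warning("degenerate labels (all %d); skipping curves", n_pos)
            return truth, None
        curve = validation.precision_recall_curve(type3.final_rank, labels)
        return truth, curve

    truth, curve = stage("validate")(_validate)
    manifest["stats"]["n_validated_triples"] = len(truth)
    if curve is not None:
        curve_path = outdir / "validation_curve.csv"
        curve.to_csv(curve_path)
        manifest["outputs"]["validation_curve"] = str(curve_path)
        manifest["stats"]["auroc"] = curve.auroc
        manifest["stats"]["aupr"] = curve.aupr

    min_conf = (
        cfg.min_confidence
        if cfg.min_confidence is not None
        else networks.top_fraction_threshold(result, cfg.top_fraction)
    )
    manifest["stats"]["confidence_cutoff"] = min_conf

    diseases = sorted({networks.split_label(n)[0] for n in
                       (node.label for node in dataset.nodes)})
    layout = (
        {k: list(v) for k, v in cfg.class_layout.items()}
        if cfg.class_layout is not None
        else {"class-1": diseases}
    )

    def _dmins():
        out = {}
        for disease in diseases:
            out[disease] = networks.build_dmin(type3, disease, min_conf)
        return out

    dmins = stage("dmin")(_dmins)
    manifest["outputs"]["dmin"] = {}
    for disease, dmin in dmins.items():
        path = outdir / f"dmin_{disease}.csv"
        networks.export_edgelist_csv(dmin, path)
        manifest["outputs"]["dmin"][disease] = str(path)

    def _signatures():
        out = {}
        for cls_name, members in layout.items():
            present = [d for d in members if d in dmins]
            if not present:
                logger.warning("class %s has no diseases in the data", cls_name)
                continue
            out[cls_name] = networks.intersect_class_signature(
                [dmins[d] for d in present], cls_name
            )
        return out

    signatures = stage("signature")(_signatures)
    manifest["outputs"]["signature"] = {}
    for cls_name, sig in signatures.items():
        path = outdir / f"signature_{cls_name}.csv"
        networks.export_edgelist_csv(sig, path)
        manifest["outputs"]["signature"][cls_name] = str(path)
        manifest["stats"][f"signature_{cls_name}_edges"] = len(sig)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
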