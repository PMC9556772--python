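"""End-to-end orchestration: preprocess -> association -> tree optimization."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import __version__
from .association import (
    AssociationRecord,
    WeightedAdjustment,
    classify_biomarker_effect,
    classify_drug_dependence,
    ihw_adjust,
    select_candidates,
    wilcoxon_association,
)
from .containers import LesionMatrix, NormalizedMatrix, ResponseMatrix
from .preprocess import (
    align_samples,
    filter_biomarkers,
    filter_drugs,
    knn_impute,
    normalize_ic50_star,
    read_drug_targets,
    read_lesion_matrix,
    read_response_matrix,
    write_normalized_matrix,
)
from .tree_opt import Assignment, TreatmentTree, assign_patients, solve_tree

__all__ = ["RunConfig", "PipelineResult", "fit_pipeline", "run_mom"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a full run; defaults are the reference analysis settings.

    Prevalence floor 0.01 ("more than 1% of patients"), drug coverage floor
    0.20, significance alpha 0.05 with effect floor delta 0.2 on IC50*, and
    a four-level tree (three biomarker levels plus the default).
    """

    response_path: str | None = None
    lesion_path: str | None = None
    lesion_format: str = "matrix"
    targets_path: str | None = None
    out_dir: str | None = None

    min_fraction: float = 0.01
    min_tested_fraction: float = 0.20
    clip_high: bool = False
    knn_k: int = 10
    min_group: int = 3
    alpha: float = 0.05
    delta_min: float = 0.2
    ihw_folds: int = 5
    K: int = 4
    n_min: int = 1
    time_limit: float = 3600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.min_fraction < 1:
            raise ValueError("min_fraction must be in [0, 1)")
        if not 0 <= self.min_tested_fraction <= 1:
            raise ValueError("min_tested_fraction must be in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.knn_k < 1 or self.ihw_folds < 2 or self.n_min < 0:
            raise ValueError("invalid knn_k / ihw_folds / n_min")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class PipelineResult:
    tree: TreatmentTree
    assignment: Assignment
    norm: NormalizedMatrix
    lesions: LesionMatrix
    records: list[AssociationRecord]
    adjustment: WeightedAdjustment
    candidates: list


def fit_pipeline(
    resp: ResponseMatrix,
    lesions: LesionMatrix,
    config: RunConfig | None = None,
    targets: dict[str, str] | None = None,
) -> PipelineResult:
    """Run the full in-memory pipeline on already-loaded matrices."""
    cfg = config or RunConfig()
    resp, lesions = align_samples(resp, lesions)
    lesions = filter_biomarkers(lesions, cfg.min_fraction)
    resp = filter_drugs(resp, cfg.min_tested_fraction, targets)
    resp = knn_impute(resp, cfg.knn_k)
    norm = normalize_ic50_star(resp)
    records = wilcoxon_association(norm, lesions, cfg.min_group)
    adj = ihw_adjust(records, cfg.alpha, cfg.ihw_folds, cfg.seed)
    cands = select_candidates(records, adj, cfg.alpha, cfg.delta_min)
    tree = solve_tree(
        norm,
        lesions,
        cands,
        K=cfg.K,
        n_min=cfg.n_min,
        time_limit=cfg.time_limit,
    )
    assignment = assign_patients(tree, lesions)
    return PipelineResult(
        tree=tree,
        assignment=assignment,
        norm=norm,
        lesions=lesions,
        records=records,
        adjustment=adj,
        candidates=cands,
    )


def _write_outputs(result: PipelineResult, cfg: RunConfig) -> None:
    out = cfg.out_dir or "."
    os.makedirs(out, exist_ok=True)
    with open(os.path.join(out, "tree.json"), "w") as fh:
        json.dump(result.tree.to_dict(), fh, indent=2)
    with open(os.path.join(out, "assignments.tsv"), "w") as fh:
        fh.write("patient_id\tlevel\tdrug_id\n")
        for p, (k, d) in result.assignment.assignments.items():
            fh.write(f"{p}\t{k}\t{d}\n")
    with open(os.path.join(out, "associations.tsv"), "w") as fh:
        fh.write(
            "drug_id\tlesion_id\tp_two_sided\tp_one_sided\tdelta\tweight\tp_adj\n"
        )
        for r in result.records:
            key = (r.drug_id, r.lesion_id)
            fh.write(
                f"{r.drug_id}\t{r.lesion_id}\t{r.p_two_sided:.6g}\t"
                f"{r.p_one_sided_sens:.6g}\t{r.delta:.6g}\t"
                f"{result.adjustment.weights.get(r.lesion_id, 0.0):.6g}\t"
                f"{result.adjustment.p_adj[key]:.6g}\n"
            )
    write_normalized_matrix(
        result.norm, os.path.join(out, "ic50_star.tsv")
    )
    by_lesion: dict[str, list[AssociationRecord]] = {}
    for r in result.records:
        by_lesion.setdefault(r.lesion_id, []).append(r)
    with open(os.path.join(out, "biomarker_effects.tsv"), "w") as fh:
        fh.write("lesion_id\teffect\n")
        for lesion in sorted(by_lesion):
            eff = classify_biomarker_effect(by_lesion[lesion])
            fh.write(f"{lesion}\t{eff.label}\n")
    with open(os.path.join(out, "drug_dependence.tsv"), "w") as fh:
        fh.write("drug_id\tdependence\n")
        labels = classify_drug_dependence(result.adjustment, cfg.alpha)
        for drug in sorted(labels):
            fh.write(f"{drug}\t{labels[drug]}\n")
    with open(os.path.join(out, "run_log.json"), "w") as fh:
        json.dump(
            {"momstrat_version": __version__, "config": cfg.to_dict()},
            fh,
            indent=2,
        )


def run_mom(config: RunConfig) -> PipelineResult:
    """File-based entry point: read inputs per config, fit, write outputs."""
    if not config.response_path or not config.lesion_path:
        raise ValueError("config must set response_path and lesion_path")
    try:
        resp = read_response_matrix(config.response_path, config.clip_high)
        lesions = read_lesion_matrix(config.lesion_path, config.lesion_format)
        targets = (
            read_drug_targets(config.targets_path)
            if config.targets_path
            else None
        )
    except Exception as exc:
        raise RuntimeError(f"[preprocess] input loading failed: {exc}") from exc
    result = fit_pipeline(resp, lesions, config, targets)
    if config.out_dir:
        _write_outputs(result, config)
    return result
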