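"""Model assessment: cross-validation stability and external-cohort checks.

Cross-validation refits the *entire* pipeline (association, weighting,
candidate selection and tree optimization) on each training split, so the
reported stability reflects the whole procedure rather than just the MILP.
External validation routes an independent cohort (typically cell lines
with CRISPR/RNAi essentiality scores or their own IC50 table) through a
fitted tree and asks, subgroup by subgroup, whether biomarker-positive
samples are more sensitive to the subgroup's drug than the not-yet-treated
rest; samples captured by an earlier subgroup are excluded from all later
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import LesionMatrix, ResponseMatrix
from .pipeline import RunConfig, fit_pipeline
from .tree_opt import TreatmentTree

__all__ = [
    "CVReport",
    "SubgroupComparison",
    "CohortValidation",
    "make_folds",
    "lesion_frequencies",
    "cross_validate",
    "validate_external",
]


@dataclass
class CVReport:
    n_folds: int
    seed: int
    fold_trees: list[TreatmentTree]
    full_tree: TreatmentTree
    biomarker_frequency: dict[str, float]  # lesion -> fraction of folds
    stability: float  # fraction of folds sharing >= m full-model lesions
    m: int
    folds: list[list[str]]  # held-out patients per fold


@dataclass
class SubgroupComparison:
    level: int
    lesion_id: str | None  # None for the default (biomarker-free) level
    drug_id: str
    positive_scores: list[float]
    comparison_scores: list[float]
    p_one_sided: float | None  # None when untestable

    @property
    def testable(self) -> bool:
        return self.p_one_sided is not None


@dataclass
class CohortValidation:
    subgroups: list[SubgroupComparison]
    pooled_p: float | None
    mode: str


# ---------------------------------------------------------------------------
# Cross-validation


def make_folds(
    patient_ids: list[str], n_folds: int, seed: int
) -> list[list[str]]:
    """Seeded partition of patients into n_folds held-out sets."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patient_ids))
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for pos, idx in enumerate(order):
        folds[pos % n_folds].append(patient_ids[idx])
    return folds


def lesion_frequencies(
    fold_lesion_sets: list[set[str]],
) -> dict[str, float]:
    """Fraction of folds in which each lesion appears in the fold's tree."""
    n = len(fold_lesion_sets)
    all_lesions = sorted(set().union(*fold_lesion_sets)) if n else []
    return {
        l: sum(l in s for s in fold_lesion_sets) / n for l in all_lesions
    }


def cross_validate(
    resp: ResponseMatrix,
    lesions: LesionMatrix,
    config: RunConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
    m: int | None = None,
) -> CVReport:
    """K-fold stability of the full pipeline.

    Each fold's tree is fit on the other folds' patients only.  A fold in
    which no candidate survives the filters yields a default-only tree
    (recorded, not fatal).  ``m`` is the number of full-model lesions a
    fold tree must share to count as stable; default: all of them.
    """
    cfg = config or RunConfig()
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    common = [p for p in resp.patient_ids if p in set(lesions.patient_ids)]
    if len(common) < n_folds:
        raise ValueError("need at least n_folds shared patients")
    full = fit_pipeline(resp, lesions, cfg)
    folds = make_folds(common, n_folds, seed)
    fold_trees: list[TreatmentTree] = []
    for held_out in folds:
        train = [p for p in common if p not in set(held_out)]
        sub_resp = ResponseMatrix(resp.values.loc[:, train])
        sub_les = LesionMatrix(lesions.status.loc[:, train])
        try:
            fold_trees.append(fit_pipeline(sub_resp, sub_les, cfg).tree)
        except ValueError:
            # no surviving candidates: the fold contributes a default-only tree
            from .preprocess import (
                align_samples,
                filter_drugs,
                knn_impute,
                normalize_ic50_star,
            )
            from .tree_opt import solve_tree

            r, l = align_samples(sub_resp, sub_les)
            norm = normalize_ic50_star(
                knn_impute(filter_drugs(r, cfg.min_tested_fraction), cfg.knn_k)
            )
            fold_trees.append(
                solve_tree(norm, l, [], K=1, time_limit=cfg.time_limit)
            )
    freq = lesion_frequencies([set(t.lesion_ids) for t in fold_trees])
    full_lesions = set(full.tree.lesion_ids)
    m_eff = len(full_lesions) if m is None else m
    stability = (
        sum(
            len(full_lesions & set(t.lesion_ids)) >= m_eff for t in fold_trees
        )
        / n_folds
    )
    return CVReport(
        n_folds=n_folds,
        seed=seed,
        fold_trees=fold_trees,
        full_tree=full.tree,
        biomarker_frequency=freq,
        stability=stability,
        m=m_eff,
        folds=folds,
    )


# ---------------------------------------------------------------------------
# External validation


def _one_sided_less(pos: np.ndarray, comp: np.ndarray) -> float:
    pooled = np.concatenate([pos, comp])
    exact = (
        pos.size <= 8 and comp.size <= 8 and np.unique(pooled).size == pooled.size
    )
    return float(
        stats.mannwhitneyu(
            pos, comp, alternative="less", method="exact" if exact else "asymptotic"
        ).pvalue
    )


def validate_external(
    tree: TreatmentTree,
    cohort_lesions: LesionMatrix,
    scores: pd.DataFrame,  # rows = cell lines, columns = drugs or genes
    drug_targets: dict[str, str] | None = None,
    mode: str = "drug_ic50",
) -> CohortValidation:
    """Validate a fitted tree on an independent cohort.

    ``mode="drug_ic50"`` reads each subgroup drug's own score column;
    ``mode="gene_essentiality"`` reads the column of the drug's target gene
    per ``drug_targets``.  Lower score = more sensitive in both modes.
    Cell lines are routed through the tree sequentially; each biomarker
    subgroup compares its not-yet-treated carriers against the
    not-yet-treated non-carriers, then removes the carriers from the pool.
    The biomarker-free default level compares the remaining pool against
    the previously captured lines on the default drug's column.  The pooled
    p-value concatenates per-subgroup observations after rank-normalizing
    each subgroup's pooled scores to (0, 1).
    """
    if mode not in ("drug_ic50", "gene_essentiality"):
        raise ValueError(f"unknown mode {mode!r}")

    def column_for(drug: str) -> str:
        if mode == "gene_essentiality":
            if not drug_targets or drug not in drug_targets:
                raise ValueError(
                    f"gene_essentiality mode needs a target gene for drug {drug!r}"
                )
            col = drug_targets[drug]
        else:
            col = drug
        if col not in scores.columns:
            raise ValueError(f"score table has no column {col!r}")
        return col

    lines = [p for p in cohort_lesions.patient_ids if p in set(scores.index)]
    pool = list(lines)
    treated: list[str] = []
    status = cohort_lesions.status
    subgroups: list[SubgroupComparison] = []
    pooled_pos: list[np.ndarray] = []
    pooled_comp: list[np.ndarray] = []

    def record(level, lesion, drug, pos_ids, comp_ids):
        col = column_for(drug)
        pos = scores.loc[pos_ids, col].dropna().to_numpy(dtype=float)
        comp = scores.loc[comp_ids, col].dropna().to_numpy(dtype=float)
        if pos.size == 0 or comp.size == 0:
            p = None
        else:
            p = _one_sided_less(pos, comp)
            combined = np.concatenate([pos, comp])
            ranks = stats.rankdata(combined) / (combined.size + 1)
            pooled_pos.append(ranks[: pos.size])
            pooled_comp.append(ranks[pos.size :])
        subgroups.append(
            SubgroupComparison(
                level=level,
                lesion_id=lesion,
                drug_id=drug,
                positive_scores=pos.tolist(),
                comparison_scores=comp.tolist(),
                p_one_sided=p,
            )
        )

    for k, (lesion, drug) in enumerate(tree.levels):
        if lesion not in set(cohort_lesions.lesion_ids):
            raise ValueError(f"lesion {lesion!r} absent from the cohort matrix")
        carriers = [p for p in pool if status.at[lesion, p] == 1]
        noncarriers = [p for p in pool if status.at[lesion, p] == 0]
        record(k, lesion, drug, carriers, noncarriers)
        treated.extend(carriers)
        pool = noncarriers

    record(len(tree.levels), None, tree.default_drug, pool, treated)

    if pooled_pos:
        pooled_p = _one_sided_less(
            np.concatenate(pooled_pos), np.concatenate(pooled_comp)
        )
    else:
        pooled_p = None
    return CohortValidation(subgroups=subgroups, pooled_p=pooled_p, mode=mode)
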