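"""Single biomarker–drug associations with covariate-weighted FDR control.

Every (drug, lesion) pair is scored with a Wilcoxon rank-sum test on the
IC50* values of carriers versus non-carriers.  The raw p-values are then
adjusted with a covariate-weighted Benjamini-Hochberg procedure in the
style of Independent Hypothesis Weighting (IHW): hypotheses are grouped by
lesion, nonnegative mean-1 weights are learned per group by cross-fitting
(so a hypothesis never influences its own weight), and BH is applied to
p_i / w_i.  A lesion weighted at zero is deemed irrelevant and all its
hypotheses receive an adjusted p-value of 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import LesionMatrix, NormalizedMatrix

__all__ = [
    "AssociationRecord",
    "WeightedAdjustment",
    "CandidateTreatment",
    "EffectClass",
    "wilcoxon_association",
    "weighted_bh_adjust",
    "ihw_adjust",
    "select_candidates",
    "classify_biomarker_effect",
    "classify_drug_dependence",
]

#: weights below this are treated as exactly zero (solver round-off guard)
WEIGHT_EPS = 1e-12


@dataclass(frozen=True)
class AssociationRecord:
    """One tested (drug, lesion) pair.

    ``delta`` is the signed effect size mean IC50*(non-carriers) minus mean
    IC50*(carriers) in log10 units: positive when carriers are more
    sensitive (lower IC50*).  ``p_one_sided_sens`` tests the alternative
    that carriers are more sensitive.
    """

    drug_id: str
    lesion_id: str
    p_two_sided: float
    p_one_sided_sens: float
    delta: float
    n_carrier: int
    n_noncarrier: int


@dataclass
class WeightedAdjustment:
    """Per-lesion IHW weights plus weighted-BH adjusted p-values."""

    weights: dict[str, float]  # lesion_id -> weight (mean 1 over hypotheses)
    p_adj: dict[tuple[str, str], float]  # (drug_id, lesion_id) -> adjusted p
    alpha: float
    n_folds: int
    seed: int


@dataclass(frozen=True)
class CandidateTreatment:
    """A (lesion, drug) pair that survives all candidacy filters."""

    lesion_id: str
    drug_id: str
    delta: float
    p_adj: float


@dataclass(frozen=True)
class EffectClass:
    lesion_id: str
    label: str  # "sensitising" | "resistant" | "neutral"


# ---------------------------------------------------------------------------
# Rank-sum testing


def _rank_sum(carrier: np.ndarray, noncarrier: np.ndarray) -> tuple[float, float]:
    """Two-sided and one-sided (carriers lower) rank-sum p-values.

    Exact null enumeration when both groups have <= 8 observations and the
    pooled sample is tie-free; otherwise the normal approximation with tie
    and continuity corrections.
    """
    pooled = np.concatenate([carrier, noncarrier])
    exact = (
        len(carrier) <= 8
        and len(noncarrier) <= 8
        and len(np.unique(pooled)) == len(pooled)
    )
    method = "exact" if exact else "asymptotic"
    p_two = stats.mannwhitneyu(
        carrier, noncarrier, alternative="two-sided", method=method
    ).pvalue
    p_less = stats.mannwhitneyu(
        carrier, noncarrier, alternative="less", method=method
    ).pvalue
    return float(p_two), float(p_less)


def wilcoxon_association(
    norm: NormalizedMatrix,
    lesions: LesionMatrix,
    min_group: int = 3,
) -> list[AssociationRecord]:
    """Test every (drug, lesion) pair with both groups of size >= min_group."""
    if min_group < 2:
        raise ValueError("min_group must be >= 2")
    if norm.patient_ids != lesions.patient_ids:
        raise ValueError("matrices are not patient-aligned; run align_samples")
    scores = norm.values.to_numpy(dtype=float)
    status = lesions.status.to_numpy()
    records: list[AssociationRecord] = []
    for li, lesion in enumerate(lesions.lesion_ids):
        mask = status[li] == 1
        n_car = int(mask.sum())
        n_non = int((~mask).sum())
        if n_car < min_group or n_non < min_group:
            continue
        for di, drug in enumerate(norm.drug_ids):
            car = scores[di, mask]
            non = scores[di, ~mask]
            p_two, p_less = _rank_sum(car, non)
            records.append(
                AssociationRecord(
                    drug_id=drug,
                    lesion_id=lesion,
                    p_two_sided=p_two,
                    p_one_sided_sens=p_less,
                    delta=float(non.mean() - car.mean()),
                    n_carrier=n_car,
                    n_noncarrier=n_non,
                )
            )
    if not records:
        warnings.warn("no (drug, lesion) pair satisfies the minimum group size")
    return records


# ---------------------------------------------------------------------------
# Weighted Benjamini-Hochberg


def weighted_bh_adjust(pvals: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """BH step-up adjusted values of p_i / w_i, capped at 1.

    ``weights`` must be nonnegative with mean 1.  A zero weight sends the
    hypothesis's adjusted p-value to 1.  With all weights 1 this is exactly
    textbook Benjamini-Hochberg.
    """
    p = np.asarray(pvals, dtype=float)
    w = np.asarray(weights, dtype=float)
    m = p.size
    if m == 0:
        return np.array([])
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if abs(w.mean() - 1.0) > 1e-9:
        raise ValueError("weights must average to 1")
    ptilde = np.full(m, np.inf)
    pos = w > WEIGHT_EPS
    ptilde[pos] = p[pos] / w[pos]
    order = np.argsort(ptilde, kind="stable")
    ranked = ptilde[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _stratified_folds(
    groups: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold label per hypothesis, stratified by covariate group."""
    fold = np.empty(groups.size, dtype=int)
    offset = 0
    for g in np.unique(groups):
        idx = np.where(groups == g)[0]
        idx = idx[rng.permutation(idx.size)]
        # rotate the starting fold across groups so small groups spread out
        fold[idx] = (np.arange(idx.size) + offset) % n_folds
        offset += idx.size
    return fold


def _learn_group_weights(
    p: np.ndarray, groups: np.ndarray, group_ids: np.ndarray, alpha: float
) -> np.ndarray:
    """Mean-1 group weights maximizing weighted-BH rejections on (p, groups).

    Deterministic iterative search: starting from uniform weights, each
    iteration re-allocates weight proportionally to the per-group rejection
    rate (with a small floor so silent groups can recover); the iterate
    with most rejections wins, then its weights are sharpened to be exactly
    proportional to per-group rejection rates so non-contributing groups
    land at 0.  Falls back to uniform when nothing is ever rejected.
    """
    m = p.size
    # groups can be absent from a training split; they then see 0 rejections
    n_g = np.maximum(
        np.array([(groups == g).sum() for g in group_ids], dtype=float), 1.0
    )

    def hyp_weights(group_w: np.ndarray) -> np.ndarray:
        w = group_w[np.searchsorted(group_ids, groups)]
        mean = w.mean()
        return w / mean if mean > 0 else np.ones(m)

    def rejections(group_w: np.ndarray) -> np.ndarray:
        w = hyp_weights(group_w)
        adj = weighted_bh_adjust(p, w)
        rej = adj < alpha
        return np.array([rej[groups == g].sum() for g in group_ids], dtype=float)

    best_w = np.ones(group_ids.size)
    best_rej = rejections(best_w)
    cur = best_w.copy()
    for _ in range(15):
        rej = rejections(cur)
        if rej.sum() > best_rej.sum():
            best_rej, best_w = rej, cur.copy()
        rate = rej / n_g
        if rate.sum() <= 0:
            break
        cur = rate / rate.sum() * group_ids.size + 0.05
        cur /= cur.mean()
    if best_rej.sum() <= 0:
        return np.ones(group_ids.size)
    # sharpen: weight exactly proportional to rejection rate at the best iterate
    rate = best_rej / n_g
    if rate.sum() <= 0:
        return best_w
    sharp = rate / rate.sum() * group_ids.size
    if rejections(sharp).sum() >= best_rej.sum():
        return sharp
    return best_w


def ihw_adjust(
    records: list[AssociationRecord],
    alpha: float = 0.05,
    n_folds: int = 5,
    seed: int = 0,
    weights: dict[str, float] | None = None,
    shrink: float = 0.25,
) -> WeightedAdjustment:
    """Covariate-weighted BH adjustment with the lesion as the covariate.

    Weights are learned by cross-fitting: hypotheses are split into
    ``n_folds`` folds stratified by lesion; each fold's weights are chosen
    on the remaining folds to maximize weighted-BH rejections at ``alpha``,
    then applied to the held-out fold.  ``shrink`` blends each fold's
    learned group weights with uniform ones — regularization that keeps a
    sparse signal (a lesion driving a single drug, whose only informative
    hypothesis sits in the held-out fold) from being zero-weighted away;
    ``shrink=0`` lets the search zero out silent covariate groups.  The
    assembled per-hypothesis weights are renormalized to mean 1 before the
    final weighted-BH pass.

    Passing ``weights`` (lesion -> weight) skips learning and applies those
    fixed weights; with all weights 1 the result is textbook BH.
    """
    if not 0 <= shrink <= 1:
        raise ValueError("shrink must be in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    keys = [(r.drug_id, r.lesion_id) for r in records]
    p = np.array([r.p_two_sided for r in records], dtype=float)
    groups = np.array([r.lesion_id for r in records])
    group_ids = np.unique(groups)
    m = p.size

    if weights is not None:
        w_hyp = np.array([weights[g] for g in groups], dtype=float)
        mean = w_hyp.mean()
        if mean <= 0:
            raise ValueError("fixed weights must have positive mean")
        w_hyp = w_hyp / mean
    elif group_ids.size < 2:
        warnings.warn(
            "fewer than 2 covariate groups; falling back to plain BH"
        )
        w_hyp = np.ones(m)
    else:
        rng = np.random.default_rng(seed)
        fold = _stratified_folds(groups, n_folds, rng)
        w_hyp = np.ones(m)
        for f in range(n_folds):
            held = fold == f
            if not held.any():
                continue
            train = ~held
            gw = _learn_group_weights(p[train], groups[train], group_ids, alpha)
            gw = (1.0 - shrink) * gw + shrink
            w_hyp[held] = gw[np.searchsorted(group_ids, groups[held])]
        mean = w_hyp.mean()
        w_hyp = w_hyp / mean if mean > 0 else np.ones(m)

    adj = weighted_bh_adjust(p, w_hyp)
    lesion_weight = {
        g: float(w_hyp[groups == g].mean()) for g in group_ids
    }
    return WeightedAdjustment(
        weights=lesion_weight,
        p_adj=dict(zip(keys, adj.tolist())),
        alpha=alpha,
        n_folds=n_folds,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Candidate selection and classification


def select_candidates(
    records: list[AssociationRecord],
    adj: WeightedAdjustment,
    alpha: float = 0.05,
    delta_min: float = 0.2,
) -> list[CandidateTreatment]:
    """Keep pairs with positive lesion weight, p_adj < alpha, delta > delta_min.

    ``delta > delta_min`` requires carriers to be the more *sensitive*
    group, since the treatment tree prescribes each level's drug to
    carriers of its biomarker.  Sorted by adjusted p, ties broken by
    (lesion_id, drug_id).
    """
    out = []
    for r in records:
        key = (r.drug_id, r.lesion_id)
        if key not in adj.p_adj:
            continue
        if adj.weights.get(r.lesion_id, 0.0) <= WEIGHT_EPS:
            continue
        p_adj = adj.p_adj[key]
        if p_adj < alpha and r.delta > delta_min:
            out.append(
                CandidateTreatment(
                    lesion_id=r.lesion_id,
                    drug_id=r.drug_id,
                    delta=r.delta,
                    p_adj=p_adj,
                )
            )
    out.sort(key=lambda c: (c.p_adj, c.lesion_id, c.drug_id))
    if not out:
        raise ValueError(
            "no candidate treatments at the current thresholds; relax "
            "alpha/delta_min or check the inputs (tree cannot be built)"
        )
    return out


def classify_biomarker_effect(records: list[AssociationRecord]) -> EffectClass:
    """Classify one lesion from its one-sided p-value histogram.

    Sensitising when #(p < 0.2) >= 2 x #(p > 0.2); else resistant when
    #(p > 0.8) >= 2 x #(p < 0.8); else neutral.  A p exactly at a boundary
    counts on neither side.
    """
    if not records:
        raise ValueError("need at least one association record")
    lesion_ids = {r.lesion_id for r in records}
    if len(lesion_ids) != 1:
        raise ValueError("records must all concern a single lesion")
    p = np.array([r.p_one_sided_sens for r in records])
    if (p < 0.2).sum() >= 2 * (p > 0.2).sum():
        label = "sensitising"
    elif (p > 0.8).sum() >= 2 * (p < 0.8).sum():
        label = "resistant"
    else:
        label = "neutral"
    return EffectClass(lesion_id=lesion_ids.pop(), label=label)


def classify_drug_dependence(
    adj: WeightedAdjustment, alpha: float = 0.05
) -> dict[str, str]:
    """Label each drug related/unrelated to genotype.

    A drug is *related* when its minimum adjusted p-value over lesions with
    positive weight is below ``alpha``.
    """
    best: dict[str, float] = {}
    for (drug, lesion), p_adj in adj.p_adj.items():
        if adj.weights.get(lesion, 0.0) <= WEIGHT_EPS:
            continue
        best[drug] = min(best.get(drug, np.inf), p_adj)
    labels = {}
    for drug in {d for d, _ in adj.p_adj}:
        if drug not in best:
            warnings.warn(f"drug {drug!r} has no weight-positive lesion tested")
        labels[drug] = "related" if best.get(drug, np.inf) < alpha else "unrelated"
    return labels
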