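"""Exact optimization of the biomarker-guided treatment tree.

The tree is a depth-K decision list: up to K-1 biomarker levels, each a
(lesion, drug) pair prescribing its drug to every not-yet-treated carrier
of its lesion, plus a final biomarker-free default drug for everyone left.
The objective is the total assigned IC50* (all scores <= 0; more negative
is better), minimized exactly with a mixed-integer linear program solved
by HiGHS branch-and-bound at zero gap, so the returned stratification is a
proven global optimum.  Among equally optimal trees the canonical one —
lexicographically smallest sequence of (lesion_id, drug_id) pairs, then
smallest default drug — is returned, which makes the output deterministic.

MILP formulation (levels k = 1..K-1, candidates j, patients p, default
drugs d; e_{p,j} = 1 iff p carries candidate j's lesion, s scores):

* z_{k,j} in {0,1}: candidate j sits at level k; sum_j z_{k,j} <= 1.
* each lesion is used at most once across levels; used levels are
  contiguous (symmetry break).
* r_{p,k} in [0,1]: p still untreated when reaching level k; r_{p,1} = 1
  and r_{p,k+1} = r_{p,k} - a_{p,k} with capture
  a_{p,k} = sum_j w_{p,k,j} over eligible j.
* w_{p,k,j} in [0,1] linearizes z_{k,j} AND r_{p,k}
  (w <= z, w <= r, w >= z + r - 1), defined only where e_{p,j} = 1.
* u_d in {0,1}: default drug, sum_d u_d = 1; v_{p,d} in [0,1] linearizes
  u_d AND r_{p,K} the same way.
* per-level floor: sum_p a_{p,k} >= n_min * sum_j z_{k,j}.
* minimize  sum w_{p,k,j} s_{d_j,p} + sum v_{p,d} s_{d,p}.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .association import CandidateTreatment
from .containers import LesionMatrix, NormalizedMatrix

__all__ = [
    "TreatmentTree",
    "Assignment",
    "SolverTimeoutError",
    "solve_tree",
    "brute_force_tree",
    "assign_patients",
    "evaluate_tree",
]

#: objective tolerance for tie detection and the recompute invariant
OBJ_TOL = 1e-6


class SolverTimeoutError(RuntimeError):
    """Raised when the solver hits its time limit before proving optimality."""

    def __init__(self, message: str, incumbent: float | None, bound: float | None):
        super().__init__(message)
        self.incumbent = incumbent
        self.bound = bound


@dataclass
class TreatmentTree:
    """An ordered stratification: biomarker levels plus a default drug."""

    levels: list[tuple[str, str]]  # (lesion_id, drug_id), first level first
    default_drug: str
    objective: float
    K: int
    n_per_level: list[int]  # per biomarker level, then the default level

    def __post_init__(self) -> None:
        lesions = [l for l, _ in self.levels]
        if len(set(lesions)) != len(lesions):
            raise ValueError("tree levels must use pairwise-distinct lesions")

    @property
    def lesion_ids(self) -> list[str]:
        return [l for l, _ in self.levels]

    def canonical_key(self) -> tuple:
        return (tuple(self.levels), self.default_drug)

    def to_dict(self) -> dict:
        return {
            "levels": [
                {"lesion": l, "drug": d, "n": n}
                for (l, d), n in zip(self.levels, self.n_per_level)
            ],
            "default_drug": self.default_drug,
            "default_n": self.n_per_level[-1],
            "objective": self.objective,
            "K": self.K,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "TreatmentTree":
        return cls(
            levels=[(lv["lesion"], lv["drug"]) for lv in payload["levels"]],
            default_drug=payload["default_drug"],
            objective=payload["objective"],
            K=payload["K"],
            n_per_level=[lv["n"] for lv in payload["levels"]]
            + [payload["default_n"]],
        )


@dataclass
class Assignment:
    """patient_id -> (level index, drug_id); the default level comes last."""

    assignments: dict[str, tuple[int, str]]

    def drug_for(self, patient_id: str) -> str:
        return self.assignments[patient_id][1]


# ---------------------------------------------------------------------------
# Direct evaluation of a fixed tree


def _route(
    levels: list[tuple[str, str]],
    default_drug: str,
    lesions: LesionMatrix,
) -> dict[str, tuple[int, str]]:
    status = lesions.status
    out: dict[str, tuple[int, str]] = {}
    for p in lesions.patient_ids:
        for k, (lesion, drug) in enumerate(levels):
            if status.at[lesion, p] == 1:
                out[p] = (k, drug)
                break
        else:
            out[p] = (len(levels), default_drug)
    return out


def evaluate_tree(
    levels: list[tuple[str, str]],
    default_drug: str,
    norm: NormalizedMatrix,
    lesions: LesionMatrix,
) -> tuple[float, list[int]]:
    """Objective and per-level patient counts of a fixed decision list."""
    routed = _route(levels, default_drug, lesions)
    counts = [0] * (len(levels) + 1)
    obj = 0.0
    for p, (k, drug) in routed.items():
        counts[k] += 1
        obj += float(norm.values.at[drug, p])
    return obj, counts


def assign_patients(tree: TreatmentTree, lesions: LesionMatrix) -> Assignment:
    """Route patients (or new samples) through a fitted tree."""
    missing = [l for l in tree.lesion_ids if l not in set(lesions.lesion_ids)]
    if missing:
        raise ValueError(f"lesions {missing} absent from the lesion matrix")
    return Assignment(_route(tree.levels, tree.default_drug, lesions))


# ---------------------------------------------------------------------------
# MILP


def _build_and_solve(
    S: np.ndarray,  # drugs x patients IC50*
    E: np.ndarray,  # candidates x patients eligibility
    cand_drug_idx: np.ndarray,  # candidate -> drug row in S
    cand_lesion_code: np.ndarray,  # candidate -> lesion code
    pool_idx: np.ndarray,  # default pool -> drug row in S
    L: int,  # number of biomarker levels (K - 1)
    n_min: int,
    time_limit: float,
    fix_z: dict[tuple[int, int], int] | None = None,
    fix_level_empty_from: int | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Solve the tree MILP, optionally with level choices pre-fixed.

    Returns (objective, z matrix L x J, u vector over pool).
    """
    T, P = S.shape
    J = E.shape[0]
    D = pool_idx.size

    # --- variable layout
    n_z = L * J
    n_u = D
    n_r = P * L  # r_{p,k} for k = 1..L (r at level index k uses column k-1)
    w_index: dict[tuple[int, int, int], int] = {}
    pos = n_z + n_u + n_r
    for k in range(L):
        for j in range(J):
            for p in np.where(E[j] == 1)[0]:
                w_index[(p, k, j)] = pos
                pos += 1
    n_v = P * D
    v0 = pos
    n_var = pos + n_v

    def zi(k: int, j: int) -> int:
        return k * J + j

    def ui(d: int) -> int:
        return n_z + d

    def ri(p: int, k: int) -> int:
        # r_{p,k} for k >= 1; k == 0 is the constant 1
        return n_z + n_u + (k - 1) * P + p

    def vi(p: int, d: int) -> int:
        return v0 + p * D + d

    c = np.zeros(n_var)
    for (p, k, j), col in w_index.items():
        c[col] = S[cand_drug_idx[j], p]
    for p in range(P):
        for d in range(D):
            c[vi(p, d)] = S[pool_idx[d], p]

    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    lo: list[float] = []
    hi: list[float] = []
    nrow = 0

    def add_row(entries: list[tuple[int, float]], lb: float, ub: float) -> None:
        nonlocal nrow
        for col, val in entries:
            rows.append(nrow)
            cols.append(col)
            data.append(val)
        lo.append(lb)
        hi.append(ub)
        nrow += 1

    inf = np.inf
    # one candidate per level
    for k in range(L):
        add_row([(zi(k, j), 1.0) for j in range(J)], -inf, 1.0)
    # each lesion at most once across levels
    for code in np.unique(cand_lesion_code):
        members = np.where(cand_lesion_code == code)[0]
        add_row(
            [(zi(k, j), 1.0) for k in range(L) for j in members], -inf, 1.0
        )
    # contiguity: level k+1 used only if level k used
    for k in range(L - 1):
        add_row(
            [(zi(k + 1, j), 1.0) for j in range(J)]
            + [(zi(k, j), -1.0) for j in range(J)],
            -inf,
            0.0,
        )
    # default drug
    add_row([(ui(d), 1.0) for d in range(D)], 1.0, 1.0)

    # capture linearization and reach recursion
    for k in range(L):
        for j in range(J):
            for p in np.where(E[j] == 1)[0]:
                wcol = w_index[(p, k, j)]
                add_row([(wcol, 1.0), (zi(k, j), -1.0)], -inf, 0.0)
                if k == 0:
                    # r_{p,1-th level} is the constant 1: w = z exactly
                    add_row([(wcol, 1.0), (zi(k, j), -1.0)], 0.0, inf)
                else:
                    add_row([(wcol, 1.0), (ri(p, k), -1.0)], -inf, 0.0)
                    add_row(
                        [(wcol, 1.0), (zi(k, j), -1.0), (ri(p, k), -1.0)],
                        -1.0,
                        inf,
                    )
    for k in range(L):
        for p in range(P):
            wcols = [
                w_index[(p, k, j)] for j in range(J) if E[j, p] == 1
            ]
            # r_{p,k+1} = r_{p,k} - sum_j w_{p,k,j}
            entries = [(ri(p, k + 1), 1.0)] + [(wc, 1.0) for wc in wcols]
            if k == 0:
                add_row(entries, 1.0, 1.0)
            else:
                add_row(entries + [(ri(p, k), -1.0)], 0.0, 0.0)
    # default linking
    for p in range(P):
        for d in range(D):
            add_row([(vi(p, d), 1.0), (ui(d), -1.0)], -inf, 0.0)
            add_row([(vi(p, d), 1.0), (ri(p, L), -1.0)], -inf, 0.0)
            add_row(
                [(vi(p, d), 1.0), (ui(d), -1.0), (ri(p, L), -1.0)], -1.0, inf
            )
    # minimum capture per used level
    if n_min > 0:
        for k in range(L):
            entries = [
                (w_index[(p, k, j)], 1.0)
                for j in range(J)
                for p in np.where(E[j] == 1)[0]
            ] + [(zi(k, j), -float(n_min)) for j in range(J)]
            add_row(entries, 0.0, inf)

    lb = np.zeros(n_var)
    ub = np.ones(n_var)
    integrality = np.zeros(n_var)
    integrality[: n_z + n_u] = 1

    if fix_z:
        for (k, j), val in fix_z.items():
            lb[zi(k, j)] = ub[zi(k, j)] = float(val)
    if fix_level_empty_from is not None:
        for k in range(fix_level_empty_from, L):
            for j in range(J):
                ub[zi(k, j)] = 0.0

    A = sparse.csr_matrix((data, (rows, cols)), shape=(nrow, n_var))
    res = milp(
        c=c,
        constraints=LinearConstraint(A, np.array(lo), np.array(hi)),
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options={"mip_rel_gap": 0.0, "time_limit": float(time_limit)},
    )
    if res.status == 1:  # iteration/time limit
        raise SolverTimeoutError(
            "MILP time limit reached before proving optimality",
            incumbent=getattr(res, "fun", None),
            bound=getattr(res, "mip_dual_bound", None),
        )
    if not res.success:
        raise ValueError(f"MILP infeasible or failed: {res.message}")
    x = res.x
    z = np.round(x[:n_z]).reshape(L, J).astype(int)
    u = np.round(x[n_z : n_z + n_u]).astype(int)
    return float(res.fun), z, u


def _prepare(
    norm: NormalizedMatrix,
    lesions: LesionMatrix,
    candidates: list[CandidateTreatment],
    default_pool: list[str] | None,
):
    if norm.patient_ids != lesions.patient_ids:
        raise ValueError("matrices are not patient-aligned")
    S = norm.values.to_numpy(dtype=float)
    drug_row = {d: i for i, d in enumerate(norm.drug_ids)}
    lesion_row = {l: i for i, l in enumerate(lesions.lesion_ids)}
    for cand in candidates:
        if cand.drug_id not in drug_row:
            raise ValueError(f"candidate drug {cand.drug_id!r} not in the screen")
        if cand.lesion_id not in lesion_row:
            raise ValueError(f"candidate lesion {cand.lesion_id!r} unknown")
    # canonical candidate order fixes all downstream tie-breaking
    cands = sorted(set((c.lesion_id, c.drug_id) for c in candidates))
    status = lesions.status.to_numpy()
    P = status.shape[1]
    E = np.array(
        [status[lesion_row[l]] for l, _ in cands], dtype=int
    ).reshape(len(cands), P)
    cand_drug_idx = np.array([drug_row[d] for _, d in cands], dtype=int)
    lesion_codes = sorted({l for l, _ in cands})
    code = {l: i for i, l in enumerate(lesion_codes)}
    cand_lesion_code = np.array([code[l] for l, _ in cands], dtype=int)
    pool = sorted(default_pool) if default_pool is not None else norm.drug_ids
    for d in pool:
        if d not in drug_row:
            raise ValueError(f"default-pool drug {d!r} not in the screen")
    pool_idx = np.array([drug_row[d] for d in pool], dtype=int)
    return S, cands, E, cand_drug_idx, cand_lesion_code, pool, pool_idx


def _finalize(
    levels: list[tuple[str, str]],
    default_drug: str,
    norm: NormalizedMatrix,
    lesions: LesionMatrix,
    K: int,
) -> TreatmentTree:
    obj, counts = evaluate_tree(levels, default_drug, norm, lesions)
    # drop levels that capture nobody (possible only when n_min == 0)
    kept = [(lv, n) for lv, n in zip(levels, counts[:-1]) if n > 0]
    levels = [lv for lv, _ in kept]
    counts = [n for _, n in kept] + [counts[-1]]
    return TreatmentTree(
        levels=levels,
        default_drug=default_drug,
        objective=obj,
        K=K,
        n_per_level=counts,
    )


def _best_default(
    S: np.ndarray, pool: list[str], pool_idx: np.ndarray, remaining: np.ndarray
) -> str:
    """Canonical best default drug for the given remaining-patient mask."""
    sums = S[pool_idx][:, remaining].sum(axis=1) if remaining.any() else np.zeros(
        pool_idx.size
    )
    best = sums.min()
    for d, s in zip(pool, sums):  # pool is sorted
        if s <= best + OBJ_TOL:
            return d
    raise AssertionError("unreachable")


def solve_tree(
    norm: NormalizedMatrix,
    lesions: LesionMatrix,
    candidates: list[CandidateTreatment],
    K: int = 4,
    default_pool: list[str] | None = None,
    n_min: int = 1,
    time_limit: float = 3600.0,
) -> TreatmentTree:
    """Exact optimal depth-K treatment tree by branch-and-bound MILP.

    A first solve proves the optimal objective at zero MIP gap; the
    canonical optimal tree is then extracted by greedy lexicographic
    fixing — at each level, "stop here" and then each candidate in sorted
    (lesion_id, drug_id) order are tried, keeping the first choice under
    which the fixed problem still attains the proven optimum — and the
    default drug is the alphabetically first minimizer over the remaining
    patients.  Two runs on identical input therefore return identical trees.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if n_min < 0:
        raise ValueError("n_min must be >= 0")
    S, cands, E, cand_drug_idx, cand_lesion_code, pool, pool_idx = _prepare(
        norm, lesions, candidates, default_pool
    )
    P = S.shape[1]
    L = min(K - 1, len(cands))

    if L == 0:
        default = _best_default(S, pool, pool_idx, np.ones(P, dtype=bool))
        return _finalize([], default, norm, lesions, K)

    args = dict(
        S=S,
        E=E,
        cand_drug_idx=cand_drug_idx,
        cand_lesion_code=cand_lesion_code,
        pool_idx=pool_idx,
        L=L,
        n_min=n_min,
        time_limit=time_limit,
    )
    best_obj, _, _ = _build_and_solve(**args)

    # greedy lexicographic extraction among provably optimal supports
    fixed: dict[tuple[int, int], int] = {}
    chosen: list[int] = []  # candidate index per fixed level
    used_lesions: set[int] = set()
    for k in range(L):
        # option 1 (lexicographically smallest): no further levels
        try:
            obj, _, _ = _build_and_solve(
                **args, fix_z=fixed, fix_level_empty_from=k
            )
            if obj <= best_obj + OBJ_TOL:
                break
        except ValueError:
            pass
        placed = False
        for j in range(len(cands)):  # cands sorted by (lesion_id, drug_id)
            if cand_lesion_code[j] in used_lesions:
                continue
            trial = dict(fixed)
            trial[(k, j)] = 1
            try:
                obj, _, _ = _build_and_solve(**args, fix_z=trial)
            except ValueError:
                continue
            if obj <= best_obj + OBJ_TOL:
                fixed = trial
                chosen.append(j)
                used_lesions.add(cand_lesion_code[j])
                placed = True
                break
        if not placed:
            break

    levels = [cands[j] for j in chosen]
    remaining = np.ones(P, dtype=bool)
    for j in chosen:
        remaining &= E[j] == 0
    default = _best_default(S, pool, pool_idx, remaining)
    tree = _finalize(levels, default, norm, lesions, K)
    if abs(tree.objective - best_obj) > OBJ_TOL:
        raise AssertionError(
            f"canonical extraction lost optimality: {tree.objective} vs {best_obj}"
        )
    return tree


# ---------------------------------------------------------------------------
# Exhaustive oracle


def brute_force_tree(
    norm: NormalizedMatrix,
    lesions: LesionMatrix,
    candidates: list[CandidateTreatment],
    K: int = 4,
    default_pool: list[str] | None = None,
    n_min: int = 1,
) -> TreatmentTree:
    """Exhaustive enumeration oracle returning the same canonical optimum.

    Guarded to small instances (<= 8 candidates, K <= 4, <= 12 patients).
    """
    S, cands, E, cand_drug_idx, cand_lesion_code, pool, pool_idx = _prepare(
        norm, lesions, candidates, default_pool
    )
    P = S.shape[1]
    if len(cands) > 8 or K > 4 or P > 12:
        raise ValueError("instance too large for exhaustive enumeration")
    L = min(K - 1, len(cands))

    best: tuple[float, tuple] | None = None
    best_tree: tuple[list[tuple[str, str]], str] | None = None
    floor = max(n_min, 1)
    for length in range(L + 1):
        for seq in permutations(range(len(cands)), length):
            codes = [cand_lesion_code[j] for j in seq]
            if len(set(codes)) != length:
                continue
            remaining = np.ones(P, dtype=bool)
            obj_levels = 0.0
            ok = True
            for j in seq:
                captured = remaining & (E[j] == 1)
                if captured.sum() < floor:
                    ok = False
                    break
                obj_levels += S[cand_drug_idx[j], captured].sum()
                remaining &= E[j] == 0
            if not ok:
                continue
            sums = (
                S[pool_idx][:, remaining].sum(axis=1)
                if remaining.any()
                else np.zeros(pool_idx.size)
            )
            for d, dsum in zip(pool, sums):
                obj = obj_levels + float(dsum)
                levels = [cands[j] for j in seq]
                key = (tuple(levels), d)
                if (
                    best is None
                    or obj < best[0] - OBJ_TOL
                    or (obj <= best[0] + OBJ_TOL and key < best[1])
                ):
                    best = (min(obj, best[0]) if best else obj, key)
                    best_tree = (levels, d)
    assert best_tree is not None
    levels, default = best_tree
    return _finalize(levels, default, norm, lesions, K)
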