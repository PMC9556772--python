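# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the test-bench demonstrates.

## The IC50* score

The screen provides ic50_{t,p} ∈ (0, 10] µM for drug t and patient p
(values above 10 µM are clipped to 10 under an explicit flag, otherwise
rejected; the assay range is part of the data contract). Per drug row,

    c_{t,p}    = (log10 ic50_{t,p} − 1) − mean_p (log10 ic50_{t,p} − 1)
    ic50*_{t,p} = c_{t,p} − max_p c_{t,p}

The "− 1" term is implemented verbatim but is algebraically inert: any
constant shift of log10 values cancels under centering. Two consequences
matter downstream:

* **Scale invariance.** Multiplying a drug's raw IC50s by any c > 0 leaves
  its IC50* row unchanged, so unit or potency rescaling cannot change the
  fitted tree.
* **Toxicity correction.** A drug that is uniformly potent has a flat
  centered row and contributes ≈ 0 everywhere; only *differential*
  (genotype-dependent) sensitivity produces large negative scores. The
  tree objective therefore cannot be won by indiscriminately toxic drugs.

The max is taken per drug over patients, giving row maximum exactly 0 and
all values ≤ 0. The `NormalizedMatrix` container enforces only the ≤ 0
half; the row-max-0 property is guaranteed by `normalize_ic50_star` and
asserted by property tests, but is deliberately not a container invariant
because patient sub-cohorts (cross-validation folds) and externally
normalized score matrices remain valid solver inputs.

## Filtering, imputation, ordering

Order of operations: align shared patients → prevalence-filter lesions →
coverage-filter drugs → impute → normalize. A lesion is a biomarker when
strictly more than `min_fraction` (default 1%) of patients carry it — the
strict inequality makes the floor 4 carriers in a 319-patient cohort. A
drug is kept when its non-missing fraction is ≥ 20% and, when a drug →
target-gene table is supplied, when it is annotated there.

Missing IC50s are filled by kNN over *drug rows* on the log10 scale:
distance between two rows is the root-mean-square difference over columns
observed in both (dividing by the shared-column count keeps rows with
different overlap comparable), the k = 10 nearest rows are averaged at the
missing column, neighbours themselves missing there are skipped, and the
row mean is the fallback. k and the orientation are configuration choices;
row-orientation reflects that drugs with similar response profiles predict
each other better than patients do in a screen with T ≪ P.

## Association testing and weighted FDR

Each (drug, lesion) pair with both groups ≥ 3 patients is tested by
Wilcoxon rank-sum on IC50*: exact null enumeration when both groups have
≤ 8 observations and the pooled sample is tie-free, otherwise the normal
approximation with tie and continuity corrections. The effect size is
Δ = mean IC50*(non-carriers) − mean IC50*(carriers), in log10 units and
*signed*: Δ > 0 means carriers are more sensitive, which is the direction
a (lesion → drug) rule can exploit, so candidacy requires Δ > 0.2 rather
than |Δ| > 0.2.

Multiple testing uses covariate-weighted Benjamini–Hochberg with the
lesion as the (categorical) covariate. Hypotheses are split into
`n_folds` = 5 folds stratified by lesion; for each fold, nonnegative
mean-1 group weights are chosen on the other folds to maximize the number
of weighted-BH rejections at α, then applied to the held-out fold, so no
p-value influences its own weight. The weight search is a deterministic
iterative re-allocation (weight ∝ per-group rejection rate, with a small
floor during iteration so silenced groups can recover; best iterate kept;
uniform fallback when nothing rejects). Learned fold weights are shrunk
toward uniform, w ← (1 − λ)·w + λ with λ = 0.25, before application:
without shrinkage, a lesion whose entire signal is a single hypothesis is
zero-weighted whenever that hypothesis is held out, which destroys exactly
the sparse-signal case the method exists for; λ = 0 restores hard zeros
for silent covariate groups. Assembled per-hypothesis weights are
renormalized to mean 1 and BH runs on p_i / w_i (w = 0 ⇒ adjusted p = 1).
With all weights fixed to 1 the procedure is textbook BH, element-wise.
The all-null false-discovery guarantee is checked by Monte-Carlo rather
than assumed.

Direction-of-effect summaries use the one-sided (carriers-more-sensitive)
p-value histogram per lesion: sensitising when #(p < 0.2) ≥ 2·#(p > 0.2),
else resistant when #(p > 0.8) ≥ 2·#(p < 0.8), else neutral; boundary
values count on neither side ("twice" is read as ≥ 2×). A drug is
genotype-related when its minimum adjusted p over positive-weight lesions
is < α.

## The tree MILP

A depth-K tree (default K = 4, counted as three biomarker levels plus the
biomarker-free default level, matching the published four-subgroup
guideline shape) is encoded with binaries z_{k,j} (candidate j at level
k), default binaries u_d, reach variables r_{p,k} (patient p still
untreated at level k; r_{p,1} = 1, r_{p,k+1} = r_{p,k} − capture), and
products w = z ∧ r, v = u ∧ r linearized with the standard three
inequalities. Lesions are pairwise distinct across levels (a repeated
lesion can only capture the empty set); used levels are contiguous (a pure
symmetry break); each used level must capture ≥ `n_min` patients (default
1 — the published subgroup sizes suggest no hard floor was needed). The
objective Σ w·s + Σ v·s sums assigned IC50*, hence is ≤ 0, and is
minimized by HiGHS branch-and-bound at `mip_rel_gap = 0`, so optimality is
proven, not approximated.

Among tied optima the canonical tree — lexicographically smallest sequence
of (lesion_id, drug_id) pairs, then smallest default drug — is extracted
by greedy fixing: at each level, "stop here" and then each candidate in
sorted order are tried, keeping the first choice under which the
prefix-fixed MILP still attains the proven optimum; the default stage is
closed-form (canonical argmin of remaining-patient column sums). Ties are
detected with an absolute objective tolerance of 1e-6, the same tolerance
the exhaustive enumeration oracle uses, so solver and oracle return
identical canonical trees; the recomputed-objective invariant uses the
same 1e-6. Degenerate inputs: no candidates (or K = 1) yields the
default-only tree; levels capturing zero patients (possible only with
n_min = 0) are dropped from the output, which the canonical rule already
prefers.

`brute_force_tree` enumerates every ordered distinct-lesion candidate
sequence × default drug and is guarded to ≤ 8 candidates, K ≤ 4, ≤ 12
patients; it exists purely as an independent correctness oracle.

## Cross-validation and external validation

`cross_validate` re-fits the *whole* pipeline (association, weighting,
selection, MILP) on each training split — re-using all-data candidates
would leak selection information into the folds. Reported: each lesion's
fold frequency (the natural "appears in 10 of 10 folds" statistic) and a
stability score, the fraction of folds whose tree shares ≥ m lesions with
the all-data tree; m defaults to all of the full tree's lesions (the
strictest reading) and is configurable. A fold with no surviving
candidates contributes a default-only tree and is recorded, not fatal.

`validate_external` routes an independent cohort (typically cell lines)
through a fitted tree sequentially. Each biomarker level compares its
not-yet-treated carriers against not-yet-treated non-carriers with a
one-sided rank-sum test (lower score = more sensitive), then removes the
carriers from the pool, so no line is counted in two subgroups. Scores
come from the drug's own column (`drug_ic50` mode) or from the drug's
target-gene essentiality column (`gene_essentiality` mode). The
biomarker-free default level has no published comparison recipe; here its
positives are the remaining pool and its comparison set the previously
captured lines, on the default drug's column — a documented design choice.
Subgroups with an empty side are untestable and excluded. The dataset-level
p-value pools per-subgroup observations after rank-normalizing each
subgroup's combined scores to (0, 1) (a rank-sum test is invariant to this
within a subgroup, so with a single testable subgroup the pooled p equals
that subgroup's p); pooling across subgroups of a common stratification is
itself a design choice, not a canonical statistic.

## Synthetic cohorts

`generate_cohort` draws lesion status Bernoulli(prevalence), log10 IC50 =
per-drug baseline (N(0, 0.5) log10 µM by default, i.e. median ≈ 1 µM) minus
Σ planted δ·status plus N(0, σ) noise, back-transforms to µM, clips to
(1e-3, 10], and masks cells missing completely at random. Reference
conditions used throughout the test-bench: P = 200 patients, T = 30 drugs,
B = 12 lesions, three planted pairs at δ = 2 log10 units with prevalences
0.30 / 0.15 / 0.20 (disjointly assignable as a depth-4 list), background
prevalence 0.10, σ = 0.4, 5% missingness. Optional forced mutual
exclusivity between lesion pairs mimics mutually exclusive driver
mutations; it is off by default. Effects are additive on the log10 scale —
the simplest structure consistent with the rank tests and the log-scale
normalization.

What the generator does *not* emulate: correlated drug responses (shared
mechanism), patient-level covariates and therapy stages, lesion
co-occurrence structure beyond the optional exclusivity, heavy-tailed or
censored dose-response fits, and informative (non-MCAR) missingness.
Passing the recovery tests therefore shows the pipeline is correct and
powerful under its own assumptions, not that it is robust to everything
real screens do.

## Problem sizes and runtime choices

The verification suite runs at desk scale by design: 200 random
MILP-vs-oracle instances (≤ 8 patients, ≤ 5 drugs, ≤ 4 lesions, K ≤ 3),
100 × 2000-hypothesis null replicates for FDR calibration, and 10
generator seeds of the 200 × 30 × 12 reference cohort for end-to-end
recovery. These sizes make every claim reproducible in minutes on one CPU
while still exercising each code path; the MILP itself scales to
cohort-scale inputs (hundreds of patients, ~100 drugs, dozens of
candidates) with the default one-hour solver budget.

## Known limitations

* Binary lesions only; continuous or multi-class markers would need a
  different capture encoding.
* The weight-learning heuristic maximizes rejections greedily; it honours
  the weighted-BH contract but will not bit-match any particular published
  weighting implementation.
* One drug per subgroup; combination therapy is out of scope.
* The canonical-tie extraction solves up to K·(J+1) additional MILPs; for
  very large candidate sets with many exact ties this is the dominant cost.
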