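# momstrat

Optimal biomarker-guided patient stratification from ex-vivo drug screens.

Given a drugs × patients IC50 matrix from an ex-vivo sensitivity screen and
a binary genetic-lesion matrix (SNVs, indels, fusions, inversions … ×
patients) for the same cohort, `momstrat` produces a depth-limited decision
tree of (biomarker → drug) rules: at each level, carriers of one lesion are
prescribed one drug, and everyone left over receives a biomarker-free
default drug. The tree is the *provably optimal* such decision list — it is
found by an exact mixed-integer linear program, so re-runs always return the
same, globally best stratification. The intended users are computational
groups analysing paired drug-screen + sequencing cohorts (AML ex-vivo panels
being the motivating case) who want an interpretable treatment guideline
rather than a black-box response predictor.

## Method

Three stages, each exposed as library functions:

1. **Preprocessing (`momstrat.preprocess`).** IC50s (µM, valid range
   (0, 10]) are filtered (lesions carried by > 1% of patients; drugs tested
   in ≥ 20% of patients and, optionally, with an annotated target gene),
   missing cells are filled by k-nearest-neighbour imputation over drug rows
   on the log10 scale, and each drug row is transformed to the IC50* score

   ic50\*_{t,p} = c_{t,p} − max_p c_{t,p},  with
   c_{t,p} = (log10 ic50_{t,p} − 1) − mean_p (log10 ic50_{t,p} − 1).

   Every IC50* is ≤ 0 with per-drug maximum 0. Centering removes each
   drug's absolute potency, so a uniformly toxic drug scores ≈ 0 everywhere
   while a drug with a genotype-dependent response keeps large negative
   scores exactly where it works — the optimization then favours
   *differential* efficacy over raw aggressiveness.

2. **Association (`momstrat.association`).** Every (lesion, drug) pair is
   tested with a Wilcoxon rank-sum test on IC50* (exact enumeration for
   tie-free groups ≤ 8, else normal approximation with tie and continuity
   corrections). P-values are adjusted by covariate-weighted
   Benjamini–Hochberg in the style of Independent Hypothesis Weighting: the
   lesion is the covariate, nonnegative mean-1 group weights are learned by
   cross-fitting to maximize rejections, and BH runs on p_i / w_i.
   Candidate treatments must have positive lesion weight, adjusted p < 0.05
   and effect size ΔIC50* = mean(non-carriers) − mean(carriers) > 0.2
   (carriers more sensitive). One-sided p-value histograms additionally
   classify each lesion as sensitising / resistant / neutral and each drug
   as genotype-related or not.

3. **Tree optimization (`momstrat.tree_opt`).** A MILP over level-candidate
   binaries, patient reach/capture indicators, and a default-drug choice
   minimizes the total assigned IC50* for trees of depth K (default 4 =
   three biomarker levels + default), with pairwise-distinct lesions across
   levels and an optional per-level minimum subgroup size. The solver is
   HiGHS branch-and-bound at zero MIP gap; among tied optima the
   lexicographically smallest tree is returned, and an exhaustive
   enumeration oracle (`brute_force_tree`) cross-checks the solver on small
   instances. `assign_patients` routes any cohort — including new patients —
   through a fitted tree.

`momstrat.evaluation` adds K-fold cross-validation of the whole pipeline
(per-lesion fold frequencies and a stability score) and external-cohort
validation (one-sided rank-sum tests per subgroup with sequential exclusion,
against drug IC50 or CRISPR/RNAi gene-essentiality tables).
`momstrat.synthetic_data` generates seeded cohorts with planted
(lesion, drug) sensitivity shifts for testing every stage offline.

## Worked example

```python
import momstrat as m

# 120 patients, 12 drugs, 6 lesions; two planted sensitising pairs:
# carriers of L00 respond to D00, carriers of L01 to D01 (shift 2.5 log10)
resp, lesions, truth = m.generate_cohort(
    P=120, T=12, B=6, planted=[(0, 0, 2.5), (1, 1, 2.5)],
    sigma=0.3, missing_rate=0.02, seed=21,
)
result = m.fit_pipeline(resp, lesions, m.RunConfig(seed=21))
print([(c.lesion_id, c.drug_id, round(c.delta, 2)) for c in result.candidates])
print(result.tree.to_dict())
```

prints the two surviving candidate treatments

```
[('L00', 'D00', 2.25), ('L01', 'D01', 2.45)]
```

(ΔIC50* ≈ 2.3–2.5 log10 units, adjusted p ≈ 1e-16 and 1e-9) and the optimal
tree

```
{'levels': [{'lesion': 'L01', 'drug': 'D01', 'n': 19},
            {'lesion': 'L00', 'drug': 'D00', 'n': 33}],
 'default_drug': 'D01', 'default_n': 68,
 'objective': -203.369, 'K': 4}
```

i.e. the 19 L01 carriers get D01, the 33 remaining L00 carriers get D00,
and the 68 left-over patients get the default drug; the objective is the
summed IC50* of every assignment (more negative = more total sensitivity),
and both planted rules were recovered exactly.

The same run is available from the shell:

```bash
momstrat simulate --patients 120 --drugs 12 --lesions 6 --seed 21 --out-prefix sim/cohort
momstrat run --response sim/cohort_response.tsv --lesions sim/cohort_lesions.tsv --out results/
momstrat predict --tree results/tree.json --lesions sim/cohort_lesions.tsv --out predicted.tsv
```

plus `momstrat cv` (fold-stability report) and `momstrat validate-external`
(independent-cohort subgroup tests).

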