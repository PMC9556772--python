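from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from momstrat import (
    AssociationRecord,
    LesionMatrix,
    NormalizedMatrix,
    classify_biomarker_effect,
    classify_drug_dependence,
    ihw_adjust,
    select_candidates,
    weighted_bh_adjust,
    wilcoxon_association,
)


def exact_ranksum_pvalues(carrier, noncarrier):
    """Independent oracle: enumerate all rank assignments of the pooled sample.

    Returns (two-sided p, one-sided p for 'carriers lower') for tie-free
    data, by counting how many carrier-index subsets give a rank sum at
    least as extreme as the observed one.
    """
    pooled = np.concatenate([carrier, noncarrier])
    ranks = {v: r for r, v in enumerate(np.sort(pooled), start=1)}
    n = len(carrier)
    observed = sum(ranks[v] for v in carrier)
    sums = [
        sum(ranks[pooled[i]] for i in idx)
        for idx in combinations(range(len(pooled)), n)
    ]
    mean = np.mean(sums)
    p_low = np.mean([s <= observed for s in sums])
    p_two = np.mean([abs(s - mean) >= abs(observed - mean) for s in sums])
    return p_two, p_low


def _single_lesion_setup(carrier_vals, noncarrier_vals):
    vals = np.array([list(carrier_vals) + list(noncarrier_vals)], dtype=float)
    vals = vals - vals.max()  # keep scores <= 0
    patients = [f"P{i}" for i in range(vals.shape[1])]
    norm = NormalizedMatrix(pd.DataFrame(vals, index=["D1"], columns=patients))
    status = [1] * len(carrier_vals) + [0] * len(noncarrier_vals)
    lesions = LesionMatrix(
        pd.DataFrame([status], index=["b"], columns=patients)
    )
    return norm, lesions


def _record(drug, lesion, p, p1=0.5, delta=0.0, n1=5, n2=5):
    return AssociationRecord(drug, lesion, p, p1, delta, n1, n2)


class TestWilcoxon:
    def test_separated_groups_exact_pvalues(self):
        norm, lesions = _single_lesion_setup([1, 2, 3], [4, 5, 6])
        (rec,) = wilcoxon_association(norm, lesions, min_group=3)
        assert rec.p_two_sided == pytest.approx(0.1)
        assert rec.p_one_sided_sens == pytest.approx(0.05)
        assert rec.n_carrier == 3 and rec.n_noncarrier == 3

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_path_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 9, size=2)
        pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
        car, non = pooled[:n1], pooled[n1:]
        norm, lesions = _single_lesion_setup(car, non)
        (rec,) = wilcoxon_association(norm, lesions, min_group=3)
        p_two, p_low = exact_ranksum_pvalues(
            norm.values.to_numpy()[0, :n1], norm.values.to_numpy()[0, n1:]
        )
        assert rec.p_two_sided == pytest.approx(p_two)
        assert rec.p_one_sided_sens == pytest.approx(p_low)

    def test_identical_groups_give_p_one(self):
        norm, lesions = _single_lesion_setup([1, 2, 3], [1, 2, 3])
        (rec,) = wilcoxon_association(norm, lesions, min_group=3)
        assert rec.p_two_sided == pytest.approx(1.0)
        assert rec.delta == pytest.approx(0.0)

    def test_label_swap_symmetry(self):
        # enumeration: carrier ranks {1,2,5} sum to 8; P(sum<=8) = 4/20,
        # and the swap gives 1 - 4/20 + P(sum=8) = 18/20 (discrete atom)
        norm, lesions = _single_lesion_setup([1, 2, 5], [3, 4, 6])
        (rec,) = wilcoxon_association(norm, lesions, min_group=3)
        flipped = LesionMatrix(1 - lesions.status)
        (swp,) = wilcoxon_association(norm, flipped, min_group=3)
        assert swp.p_two_sided == pytest.approx(rec.p_two_sided)
        assert swp.delta == pytest.approx(-rec.delta)
        assert rec.p_one_sided_sens == pytest.approx(0.2)
        assert swp.p_one_sided_sens == pytest.approx(0.9)

    def test_small_groups_skipped_with_warning(self):
        norm, lesions = _single_lesion_setup([1, 2], [3, 4, 5, 6])
        with pytest.warns(UserWarning):
            assert wilcoxon_association(norm, lesions, min_group=3) == []

    def test_delta_sign_convention(self):
        # carriers more sensitive (lower IC50*) -> positive delta
        norm, lesions = _single_lesion_setup([1, 2, 3], [4, 5, 6])
        (rec,) = wilcoxon_association(norm, lesions, min_group=3)
        assert rec.delta == pytest.approx(3.0)


class TestWeightedBH:
    def test_uniform_weights_reduce_to_textbook_bh(self):
        rng = np.random.default_rng(1)
        p = rng.random(200)
        ours = weighted_bh_adjust(p, np.ones_like(p))
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(ours, ref)

    def test_hand_computed_fixed_weights(self):
        p = np.array([0.01, 0.02, 0.90])
        w = np.array([2.0, 0.5, 0.5])
        np.testing.assert_allclose(
            weighted_bh_adjust(p, w), [0.015, 0.06, 1.0]
        )

    def test_zero_weight_sends_p_adj_to_one(self):
        adj = weighted_bh_adjust(np.array([1e-9, 0.5]), np.array([0.0, 2.0]))
        assert adj[0] == 1.0

    def test_monotone_in_raw_p_within_weight_group(self):
        rng = np.random.default_rng(2)
        p = np.sort(rng.random(50))
        adj = weighted_bh_adjust(p, np.ones(50))
        assert (np.diff(adj) >= -1e-12).all()


class TestIHW:
    def test_fixed_uniform_weights_match_bh(self):
        rng = np.random.default_rng(3)
        recs = [
            _record(f"D{i}", f"G{i % 4}", float(rng.random())) for i in range(40)
        ]
        adj = ihw_adjust(recs, weights={f"G{g}": 1.0 for g in range(4)})
        _, ref, _, _ = multipletests(
            [r.p_two_sided for r in recs], method="fdr_bh"
        )
        np.testing.assert_allclose(
            [adj.p_adj[(r.drug_id, r.lesion_id)] for r in recs], ref
        )

    def test_learned_weights_average_one(self):
        rng = np.random.default_rng(4)
        recs = [
            _record(f"D{i}", f"G{i % 5}", float(rng.random())) for i in range(100)
        ]
        adj = ihw_adjust(recs, seed=0)
        counts = {g: sum(r.lesion_id == g for r in recs) for g in adj.weights}
        mean_w = sum(adj.weights[g] * counts[g] for g in adj.weights) / 100
        assert mean_w == pytest.approx(1.0, abs=1e-9)

    def test_single_covariate_group_falls_back_to_bh(self):
        recs = [_record(f"D{i}", "G0", p) for i, p in enumerate([0.01, 0.5, 0.9])]
        with pytest.warns(UserWarning, match="plain BH"):
            adj = ihw_adjust(recs)
        _, ref, _, _ = multipletests([0.01, 0.5, 0.9], method="fdr_bh")
        np.testing.assert_allclose(
            [adj.p_adj[(r.drug_id, r.lesion_id)] for r in recs], ref
        )

    def test_seeded_determinism(self):
        rng = np.random.default_rng(6)
        recs = [
            _record(f"D{i}", f"G{i % 5}", float(rng.random())) for i in range(100)
        ]
        a = ihw_adjust(recs, seed=7)
        b = ihw_adjust(recs, seed=7)
        assert a.p_adj == b.p_adj and a.weights == b.weights

    def test_null_simulation_controls_fdr(self):
        # all-null hypotheses: mean false-discovery proportion stays near
        # alpha despite the data-driven weights (cross-fitting guarantee)
        rng = np.random.default_rng(42)
        fdps = []
        for rep in range(30):
            p = rng.random(1000)
            recs = [
                _record(f"D{i}", f"G{i % 10}", float(p[i])) for i in range(1000)
            ]
            adj = ihw_adjust(recs, alpha=0.05, seed=rep)
            any_rej = any(v < 0.05 for v in adj.p_adj.values())
            fdps.append(1.0 if any_rej else 0.0)
        assert np.mean(fdps) <= 0.1


class TestCandidateSelection:
    def _adj(self, weights, p_adj):
        from momstrat import WeightedAdjustment

        return WeightedAdjustment(weights, p_adj, 0.05, 5, 0)

    def test_zero_weight_excluded_despite_small_p(self):
        recs = [_record("D1", "G1", 0.001, delta=1.0)]
        adj = self._adj({"G1": 0.0}, {("D1", "G1"): 0.001})
        with pytest.raises(ValueError, match="relax"):
            select_candidates(recs, adj)

    def test_small_delta_excluded(self):
        recs = [
            _record("D1", "G1", 0.01, delta=0.15),
            _record("D2", "G1", 0.01, delta=0.5),
        ]
        adj = self._adj(
            {"G1": 1.0}, {("D1", "G1"): 0.04, ("D2", "G1"): 0.04}
        )
        cands = select_candidates(recs, adj)
        assert [(c.lesion_id, c.drug_id) for c in cands] == [("G1", "D2")]

    def test_order_invariance_and_sorting(self):
        recs = [
            _record("D2", "G1", 0.02, delta=0.5),
            _record("D1", "G2", 0.01, delta=0.5),
            _record("D3", "G1", 0.02, delta=0.5),
        ]
        p_adj = {("D2", "G1"): 0.03, ("D1", "G2"): 0.01, ("D3", "G1"): 0.03}
        adj = self._adj({"G1": 1.0, "G2": 1.0}, p_adj)
        fwd = select_candidates(recs, adj)
        rev = select_candidates(recs[::-1], adj)
        assert fwd == rev
        assert [(c.lesion_id, c.drug_id) for c in fwd] == [
            ("G2", "D1"), ("G1", "D2"), ("G1", "D3"),
        ]


class TestEffectClassification:
    @pytest.mark.parametrize(
        "pvals,label",
        [
            ([0.01, 0.05, 0.1, 0.15, 0.25], "sensitising"),  # 4 >= 2 x 1
            ([0.85, 0.9, 0.95, 0.3], "resistant"),  # 3 above 0.8 >= 2 x 1 below
            ([0.4, 0.5, 0.6], "neutral"),
        ],
    )
    def test_histogram_rule(self, pvals, label):
        recs = [_record(f"D{i}", "G1", 0.5, p1=p) for i, p in enumerate(pvals)]
        assert classify_biomarker_effect(recs).label == label

    def test_boundary_pvalue_counts_on_neither_side(self):
        recs = [
            _record(f"D{i}", "G1", 0.5, p1=p)
            for i, p in enumerate([0.1, 0.1, 0.2, 0.5])
        ]
        # below 0.2: 2, above 0.2: 1 -> sensitising; the exact 0.2 is ignored
        assert classify_biomarker_effect(recs).label == "sensitising"

    def test_invariant_to_drug_permutation(self):
        pvals = [0.05, 0.1, 0.9, 0.3, 0.15]
        recs = [_record(f"D{i}", "G1", 0.5, p1=p) for i, p in enumerate(pvals)]
        assert (
            classify_biomarker_effect(recs).label
            == classify_biomarker_effect(recs[::-1]).label
        )


class TestDrugDependence:
    def _adj(self, weights, p_adj):
        from momstrat import WeightedAdjustment

        return WeightedAdjustment(weights, p_adj, 0.05, 5, 0)

    def test_related_when_min_p_adj_below_alpha(self):
        adj = self._adj({"G1": 1.0}, {("D1", "G1"): 0.03})
        assert classify_drug_dependence(adj)["D1"] == "related"

    def test_unrelated_when_min_p_adj_large(self):
        adj = self._adj({"G1": 1.0}, {("D1", "G1"): 0.2})
        assert classify_drug_dependence(adj)["D1"] == "unrelated"

    def test_zero_weight_lesions_do_not_count(self):
        adj = self._adj({"G1": 0.0}, {("D1", "G1"): 0.001})
        with pytest.warns(UserWarning):
            assert classify_drug_dependence(adj)["D1"] == "unrelated"
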