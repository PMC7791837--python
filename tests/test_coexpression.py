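import itertools

import numpy as np
import pandas as pd
import pytest

from grnrewire.coexpression import (
    ModuleAssignment,
    alignment_occupancy_filter,
    ancestral_modules,
    assign_modules,
    correlation_band,
    hypergeom_enrich,
    motif_expr_correlation,
    state_changes,
    tau,
    variance_tails,
)
from grnrewire.io import read_tree
from grnrewire.simulate import SimulationConfig, simulate_expression


class TestTau:
    def test_closed_form_cases(self):
        t, cat = tau([2.0, 2.0, 2.0, 2.0])
        assert t == 0.0 and cat == "broad"
        t, cat = tau([3.0, 0.0, 0.0, 0.0])
        assert t == 1.0 and cat == "narrow"
        t, cat = tau([1.0, 0.5, 0.0])
        assert t == pytest.approx(0.75) and cat == "intermediate"

    def test_category_boundaries_inclusive(self):
        # tau == 0.5 is still broad, tau == 0.9 is already narrow
        assert tau([1.0, 0.5])[1] == "broad"
        assert tau([1.0, 0.1])[0] == pytest.approx(0.9)
        assert tau([1.0, 0.1])[1] == "narrow"

    def test_all_zero_flagged_not_zero(self):
        t, cat = tau([0.0, 0.0, 0.0])
        assert t is None and cat == "undefined"

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        profile = rng.random(6) + 0.1
        t1, _ = tau(profile)
        t2, _ = tau(profile * 37.5)
        assert t1 == pytest.approx(t2)

    def test_monotone_under_concentration(self):
        # progressively zeroing tissues concentrates expression
        profiles = [[1.0] * 6]
        for z in range(1, 6):
            profiles.append([1.0] * (6 - z) + [0.0] * z)
        taus = [tau(p)[0] for p in profiles]
        assert all(a < b for a, b in zip(taus, taus[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tau([1.0])
        with pytest.raises(ValueError):
            tau([1.0, -0.5])


class TestAssignModules:
    def test_noiseless_recovery_is_exact(self):
        from sklearn.metrics import adjusted_rand_score

        cfg = SimulationConfig(seed=4, n_genes=120, expression_noise_sd=0.0)
        sim = simulate_expression(cfg)
        assign = assign_modules(sim.tensor, sim.orthology, sim.tree, k=10, seed=0)
        for sp in sim.tree.leaf_names:
            ogs = sorted(sim.labels[sp])
            ari = adjusted_rand_score(
                [sim.labels[sp][og] for og in ogs],
                [assign.labels[sp][og] for og in ogs],
            )
            assert ari == pytest.approx(1.0)

    def test_noisy_recovery_ari(self):
        from sklearn.metrics import adjusted_rand_score

        cfg = SimulationConfig(seed=4, n_genes=200)  # default noise
        sim = simulate_expression(cfg)
        assign = assign_modules(sim.tensor, sim.orthology, sim.tree, k=10, seed=0)
        ogs = sorted(sim.labels["sp1"])
        ari = adjusted_rand_score(
            [sim.labels["sp1"][og] for og in ogs],
            [assign.labels["sp1"][og] for og in ogs],
        )
        assert ari >= 0.9

    def test_gene_order_invariance(self):
        cfg = SimulationConfig(seed=5, n_genes=60, expression_noise_sd=0.0)
        sim = simulate_expression(cfg)
        a = assign_modules(sim.tensor, sim.orthology, sim.tree, k=10, seed=0)
        shuffled = {
            sp: sim.tensor.raw[sp].sample(frac=1.0, random_state=1)
            for sp in sim.tensor.species
        }
        from grnrewire.core import ExpressionTensor

        tensor2 = ExpressionTensor(shuffled, sim.tensor.tissues)
        b = assign_modules(tensor2, sim.orthology, sim.tree, k=10, seed=0)
        assert a.labels == b.labels

    def test_k_exceeding_distinct_profiles_rejected(self):
        df = pd.DataFrame(np.ones((12, 3)), columns=list("abc"),
                          index=[f"sp1_og{i:04d}" for i in range(12)])
        from grnrewire.core import ExpressionTensor, OrthologyMap

        tensor = ExpressionTensor({"sp1": df}, list("abc"))
        orthology = OrthologyMap({f"og{i:04d}": {"sp1": [f"sp1_og{i:04d}"]} for i in range(12)})
        tree = read_tree("(sp1:1,sp2:1);")
        with pytest.raises(ValueError, match="distinct"):
            assign_modules(tensor, orthology, tree, k=10, seed=0)


def _assignment_from_leaf_labels(leaf_labels, k=10):
    return ModuleAssignment({sp: dict(d) for sp, d in leaf_labels.items()}, k)


def _sankoff_brute_force(tree, leaf_labels, k):
    """Exhaustive enumeration over all internal labelings; min total cost."""
    internal = [n.name for n in tree.root.postorder() if not n.is_leaf]
    best = None
    for combo in itertools.product(range(k), repeat=len(internal)):
        labels = dict(zip(internal, combo))
        labels.update(leaf_labels)
        cost = sum(
            labels[n.name] != labels[n.parent.name]
            for n in tree.root.postorder()
            if n.parent is not None
        )
        if best is None or cost < best:
            best = cost
    return best


class TestAncestralModules:
    def test_constant_labels_propagate(self, ladder_tree):
        leaves = {sp: {"og1": 3} for sp in ladder_tree.leaf_names}
        anc = ancestral_modules(_assignment_from_leaf_labels(leaves), ladder_tree)
        for node in ladder_tree.root.postorder():
            assert anc.of(node.name, "og1") == 3

    def test_single_deviant_leaf_changes_on_terminal_branch(self, ladder_tree):
        leaves = {sp: {"og1": 3} for sp in ladder_tree.leaf_names}
        leaves["sp3"]["og1"] = 5
        anc = ancestral_modules(_assignment_from_leaf_labels(leaves), ladder_tree)
        internal = [n.name for n in ladder_tree.root.postorder() if not n.is_leaf]
        assert all(anc.of(n, "og1") == 3 for n in internal)

    def test_sister_pair_change_placed_on_stem(self, ladder_tree):
        # sp1, sp2 are sisters under Anc1
        leaves = {sp: {"og1": 3} for sp in ladder_tree.leaf_names}
        leaves["sp1"]["og1"] = 5
        leaves["sp2"]["og1"] = 5
        anc = ancestral_modules(_assignment_from_leaf_labels(leaves), ladder_tree)
        assert anc.of("Anc1", "og1") == 5
        assert anc.of("Anc2", "og1") == 3

    def test_reconstruction_cost_matches_brute_force(self, ladder_tree):
        rng = np.random.default_rng(0)
        k = 4
        for _ in range(20):
            leaf_labels = {
                sp: {"og1": int(rng.integers(0, k))} for sp in ladder_tree.leaf_names
            }
            anc = ancestral_modules(
                _assignment_from_leaf_labels(leaf_labels, k), ladder_tree
            )
            cost = sum(
                anc.of(n.name, "og1") != anc.of(n.parent.name, "og1")
                for n in ladder_tree.root.postorder()
                if n.parent is not None
            )
            brute = _sankoff_brute_force(
                ladder_tree, {sp: d["og1"] for sp, d in leaf_labels.items()}, k
            )
            assert cost == brute

    def test_gene_absent_from_all_leaves_gets_no_ancestral_labels(self, ladder_tree):
        leaves = {sp: {} for sp in ladder_tree.leaf_names}
        anc = ancestral_modules(_assignment_from_leaf_labels(leaves), ladder_tree)
        assert anc.of(ladder_tree.root.name, "og1") is None


class TestStateChanges:
    def _full_assignment(self, ladder_tree, leaf_labels):
        assign = _assignment_from_leaf_labels(leaf_labels)
        return ancestral_modules(assign, ladder_tree)

    def test_constant_labels_no_changes(self, ladder_tree):
        leaves = {sp: {"og1": 2} for sp in ladder_tree.leaf_names}
        sc = state_changes(self._full_assignment(ladder_tree, leaves), ladder_tree)
        assert sc.per_node["changed_vs_root"].sum() == 0
        assert sc.per_node["changed_vs_lca"].sum() == 0
        assert all(len(v) == 0 for v in sc.focal_unique.values())

    def test_focal_only_difference(self, ladder_tree):
        leaves = {sp: {"og1": 3} for sp in ladder_tree.leaf_names}
        leaves["sp4"]["og1"] = 7
        sc = state_changes(self._full_assignment(ladder_tree, leaves), ladder_tree)
        assert sc.focal_unique["sp4"] == ["og1"]
        assert all(sc.focal_unique[sp] == [] for sp in ["sp1", "sp2", "sp3", "sp5"])
        assert sc.convergent["sp4"] == []

    def test_convergent_derived_label_in_non_sisters(self, ladder_tree):
        # sp1 and sp3 (non-sisters) share derived label 5; ancestors stay 3
        leaves = {sp: {"og1": 3} for sp in ladder_tree.leaf_names}
        leaves["sp1"]["og1"] = 5
        leaves["sp3"]["og1"] = 5
        sc = state_changes(self._full_assignment(ladder_tree, leaves), ladder_tree)
        assert "og1" in sc.convergent["sp1"]
        assert "og1" in sc.convergent["sp3"]
        assert sc.focal_unique["sp1"] == []


class TestHypergeomEnrich:
    def test_direct_combinatorial_case(self):
        bg = [f"g{i}" for i in range(10)]
        term = {"T": bg[:5]}
        res = hypergeom_enrich(bg[:4], term, bg)
        # all 4 candidates inside the 5-member term: C(5,4)C(5,0)/C(10,4)
        assert res.loc["T", "p"] == pytest.approx(5 / 210)
        assert res.loc["T", "k"] == 4

    def test_fold_one_when_proportional(self):
        bg = [f"g{i}" for i in range(20)]
        term = {"T": bg[:10]}  # K/N = 0.5
        res = hypergeom_enrich(bg[8:12], term, bg)  # k/n = 2/4 = 0.5
        assert res.loc["T", "fold"] == pytest.approx(1.0)

    def test_candidate_equals_background(self):
        bg = [f"g{i}" for i in range(8)]
        res = hypergeom_enrich(bg, {"T": bg[:3]}, bg)
        assert res.loc["T", "p"] == pytest.approx(1.0)

    def test_candidate_outside_background_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrich(["x"], {"T": ["a"]}, ["a", "b"])


class TestMotifExprCorrelation:
    def test_perfect_linear(self):
        expr = [1.0, 2.0, 3.0, 4.0, 5.0]
        enrich = [2 * e + 1 for e in expr]
        res = motif_expr_correlation(enrich, expr)
        assert res["r"] == pytest.approx(1.0)
        assert res["band"] == "large"

    def test_anti_linear(self):
        expr = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = motif_expr_correlation([-e for e in expr], expr)
        assert res["r"] == pytest.approx(-1.0)

    def test_hand_dataset_matches_textbook_formula(self):
        x = np.array([0.5, 1.2, 2.0, 3.1, 4.4])
        y = np.array([1.0, 0.7, 2.5, 2.9, 3.6])
        res = motif_expr_correlation(x, y)
        r_manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert res["r"] == pytest.approx(float(r_manual))

    def test_degenerate_zero_variance(self):
        res = motif_expr_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res["band"] == "degenerate"
        assert res["r"] is None

    def test_published_bands(self):
        assert correlation_band(0.005) == "none"
        assert correlation_band(0.2) == "small"
        assert correlation_band(0.4) == "medium"
        assert correlation_band(0.9) == "large"


class TestVarianceTails:
    def _frame(self):
        rng = np.random.default_rng(0)
        data = rng.random((20, 5)) + 1
        df = pd.DataFrame(data, index=[f"TF{i}" for i in range(20)])
        df.loc["TF0"] = 2.0  # identical across species: zero variance
        df.loc["TF1"] = [0.0, 0.0, 0.0, 0.0, 50.0]  # extreme outlier
        return df

    def test_tail_labels(self):
        labels = variance_tails(self._frame(), tail_frac=0.10)
        assert labels["TF0"] == "similar"
        assert labels["TF1"] == "dissimilar"

    def test_zero_tail_frac_all_middle(self):
        labels = variance_tails(self._frame(), tail_frac=0.0)
        assert (labels == "middle").all()

    def test_too_few_tfs_rejected(self):
        with pytest.raises(ValueError):
            variance_tails(self._frame().iloc[:5])


class TestAlignmentOccupancy:
    def test_row_below_100_nt_fails(self):
        msa = {"a": "A" * 1000, "b": "A" * 99 + "-" * 901}
        assert not alignment_occupancy_filter(msa)

    def test_boundary_10_percent_and_100_nt_passes(self):
        msa = {"a": "A" * 100 + "-" * 900, "b": "A" * 100 + "-" * 900}
        assert alignment_occupancy_filter(msa)

    def test_dense_row_passes(self):
        msa = {"a": "A" * 300 + "-" * 200, "b": "A" * 500}
        assert alignment_occupancy_filter(msa)

    def test_empty_alignment_fails(self):
        assert not alignment_occupancy_filter({})
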