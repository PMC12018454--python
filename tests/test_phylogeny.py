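import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_parsimony, enumerate_rooted_trees
from clonetime.genotypes import MISSING, GenotypeMatrix, build_genotype_matrix
from clonetime.phylogeny import (
    annotate_driver_clades,
    assign_mutations,
    build_parsimony_tree,
    colony_sensitivities,
    correct_branch_lengths,
    estimate_sensitivity,
    fitch_score,
    qc_colonies,
)
from clonetime.simdata import SimConfig, simulate_patient
from clonetime.trees import Tree


def balanced4():
    parent = np.array([4, 4, 5, 5, 6, 6, -1])
    return Tree(parent, ["a", "b", "c", "d"])


class TestFitch:
    def test_perfect_column_costs_one(self):
        assert fitch_score(balanced4(), [1, 1, 0, 0]) == 1

    def test_disjoint_carriers_cost_two(self):
        t = balanced4()
        col = [1, 0, 1, 0]
        assert fitch_score(t, col) == 2
        assert fitch_score(t, col) == brute_force_parsimony(col, t)

    def test_all_zero_and_all_missing(self):
        t = balanced4()
        assert fitch_score(t, [0, 0, 0, 0]) == 0
        assert fitch_score(t, [MISSING] * 4) == 0

    def test_matches_brute_force_on_random_columns(self):
        rng = np.random.default_rng(2)
        for tree in enumerate_rooted_trees(5)[::20]:
            for _ in range(6):
                col = rng.choice([0, 1, MISSING], size=5, p=[0.4, 0.4, 0.2])
                assert fitch_score(tree, col) == brute_force_parsimony(col, tree)


def _clean_genotypes(n_colonies=16, seed=4):
    cfg = SimConfig(colonies_per_patient=n_colonies, age_at_diagnosis=40.0,
                    depth_mean=60.0, seq_error=0.0, clonality=1.0, seed=seed)
    p = simulate_patient(cfg)
    sets = p.tree.tip_sets()
    truth = sets[p.provenance["branch"].to_numpy()].astype(np.int8)
    gm = GenotypeMatrix(states=pd.DataFrame(
        truth, index=p.mtr.index, columns=p.mtr.columns))
    return p, gm


class TestParsimonyBuilder:
    def test_recovers_true_topology_noise_free(self):
        p, gm = _clean_genotypes()
        tree = build_parsimony_tree(gm, seed=0, restarts=2)
        # perfect-phylogeny bound: score equals number of distinct mutated
        # column patterns
        from clonetime.phylogeny import fitch_scores

        cols, w = np.unique(gm.states.to_numpy(), axis=0, return_counts=True)
        # columns with both states need exactly one change on a perfect
        # phylogeny; all-carrier columns sit on the stem and cost zero
        informative = np.any(cols == 1, axis=1) & np.any(cols == 0, axis=1)
        score = int(fitch_scores(tree, cols) @ w)
        assert score == int(w[informative].sum())
        # every true clade with a mutation is recovered (RF distance 0 on
        # the shared splits)
        true_clades = {
            frozenset(np.flatnonzero(row))
            for row in cols[informative] == 1
            if 2 <= row.sum() < gm.states.shape[1]
        }
        name_idx = {n: i for i, n in enumerate(gm.states.columns)}
        rec = tree.tip_sets()
        rec_clades = {
            frozenset(name_idx[tree.tip_names[i]] for i in np.flatnonzero(row))
            for row in rec
            if 2 <= row.sum() < tree.n_tips
        }
        assert true_clades <= rec_clades

    def test_single_shared_clade(self):
        states = np.zeros((5, 6), dtype=np.int8)
        states[:, :3] = 1  # five mutations shared by colonies 0,1,2
        gm = GenotypeMatrix(states=pd.DataFrame(
            states, index=[f"m{i}" for i in range(5)],
            columns=[f"c{i}" for i in range(6)]))
        tree = build_parsimony_tree(gm, seed=0, restarts=1)
        sets = tree.tip_sets()
        names = tree.tip_names
        clades = [frozenset(names[i] for i in np.flatnonzero(r))
                  for r in sets if 2 <= r.sum() < 6]
        assert frozenset(["c0", "c1", "c2"]) in clades

    def test_score_not_worse_than_star(self):
        rng = np.random.default_rng(9)
        states = rng.choice([0, 1], size=(40, 8), p=[0.7, 0.3]).astype(np.int8)
        gm = GenotypeMatrix(states=pd.DataFrame(
            states, index=[f"m{i}" for i in range(40)],
            columns=[f"c{i}" for i in range(8)]))
        tree = build_parsimony_tree(gm, seed=1, restarts=2)
        from clonetime.phylogeny import fitch_scores

        star = Tree(np.array([8] * 8 + [-1]), [f"c{i}" for i in range(8)])
        assert fitch_scores(tree, states).sum() <= fitch_scores(star, states).sum()

    def test_too_few_colonies_rejected(self):
        gm = GenotypeMatrix(states=pd.DataFrame(
            np.zeros((3, 2), dtype=np.int8), columns=["a", "b"]))
        with pytest.raises(ValueError):
            build_parsimony_tree(gm)


class TestAssignment:
    def test_clean_clade_mutation_hits_stem(self):
        t = balanced4()
        mtr = pd.DataFrame([[15, 14, 0, 0]], index=["m0"],
                           columns=["a", "b", "c", "d"])
        dep = pd.DataFrame([[30, 30, 30, 30]], index=["m0"],
                           columns=["a", "b", "c", "d"])
        asn = assign_mutations(t, mtr, dep)
        assert asn.branch["m0"] == 4  # stem of (a, b)

    def test_tie_broken_rootmost(self):
        # no reads anywhere at positive depth: absent everywhere fits every
        # branch equally badly except the likelihood is identical across
        # nested candidates -> rootmost (largest carrier set) wins
        t = balanced4()
        mtr = pd.DataFrame([[0, 0, 0, 0]], index=["m0"],
                           columns=["a", "b", "c", "d"])
        dep = pd.DataFrame([[0, 0, 30, 30]], index=["m0"],
                           columns=["a", "b", "c", "d"])
        asn = assign_mutations(t, mtr, dep)
        # a and b give no evidence; among the tied branches the rootmost is 4
        assert asn.branch["m0"] == 4

    def test_zero_depth_everywhere_unassigned(self):
        t = balanced4()
        mtr = pd.DataFrame([[0, 0, 0, 0]], index=["m0"],
                           columns=["a", "b", "c", "d"])
        dep = pd.DataFrame([[0, 0, 0, 0]], index=["m0"],
                           columns=["a", "b", "c", "d"])
        asn = assign_mutations(t, mtr, dep)
        assert asn.unassigned == ["m0"]
        assert len(asn.branch) == 0

    def test_simulation_accuracy(self, small_patient):
        p = small_patient
        asn = assign_mutations(p.tree, p.mtr, p.dep, p_err=0.001)
        truth = p.provenance.set_index("mut_id")["branch"]
        agree = (asn.branch == truth.loc[asn.branch.index]).mean()
        assert agree >= 0.95

    def test_conservation(self, small_patient):
        p = small_patient
        asn = assign_mutations(p.tree, p.mtr, p.dep)
        counts = asn.branch_counts(p.tree.n_nodes)
        assert counts.sum() == len(asn.branch)
        assert len(asn.branch) + len(asn.unassigned) == len(p.mtr)


class TestSensitivity:
    @pytest.mark.parametrize(
        "det,tot,vaf,expected",
        [(90, 100, 0.5, 0.9), (90, 100, 0.4, 0.72), (100, 100, 0.5, 1.0)],
    )
    def test_formula(self, det, tot, vaf, expected):
        assert estimate_sensitivity(det, tot, vaf) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            estimate_sensitivity(1, 0, 0.5)

    def test_from_germline_matrices(self, small_patient):
        p = small_patient
        sens = colony_sensitivities(p.germline_mtr, p.germline_dep)
        assert ((sens > 0.9) & (sens <= 1.0)).all()


class TestQC:
    def _patient_tree(self, cfg_kwargs, seed=21):
        cfg = SimConfig(colonies_per_patient=20, age_at_diagnosis=40.0,
                        depth_mean=15.0, seed=seed, **cfg_kwargs)
        p = simulate_patient(cfg)
        gm = build_genotype_matrix(p.mtr, p.dep, p.sites)
        tree = build_parsimony_tree(gm, seed=0, restarts=1)
        asn = assign_mutations(tree, p.mtr, p.dep)
        sens = colony_sensitivities(p.germline_mtr, p.germline_dep)
        return p, tree, asn, sens

    def test_clean_colonies_kept(self, small_patient):
        p = small_patient
        asn = assign_mutations(p.tree, p.mtr, p.dep)
        sens = colony_sensitivities(p.germline_mtr, p.germline_dep)
        qc = qc_colonies(p.tree, p.mtr, p.dep, sens, asn)
        assert (qc.table["verdict"] == "keep").all()
        assert qc.n_retained == qc.n_total

    def test_low_sensitivity_dropped(self, small_patient):
        p = small_patient
        asn = assign_mutations(p.tree, p.mtr, p.dep)
        sens = pd.Series(1.0, index=p.colony_names)
        sens.iloc[0] = 0.59
        qc = qc_colonies(p.tree, p.mtr, p.dep, sens, asn)
        assert qc.table.iloc[0]["verdict"] == "drop_low_sensitivity"

    def test_low_clonality_flagged(self):
        # injected 50%-clonality colonies depress private-branch VAF
        p, tree, asn, sens = self._patient_tree(
            dict(contaminated_fraction=0.2, contaminated_clonality=0.5))
        qc = qc_colonies(tree, p.mtr, p.dep, sens, asn)
        bad = set(np.array(p.colony_names)[p.clonality < 1.0])
        verdicts = qc.table.set_index("colony_id")["verdict"]
        flagged = {c for c in bad
                   if verdicts[c] in ("drop_low_vaf", "drop_low_sensitivity")}
        assert len(flagged) >= 0.9 * len(bad)
        good = [c for c in p.colony_names if c not in bad]
        assert (verdicts[good] == "keep").mean() >= 0.9

    def test_retained_arithmetic(self, small_patient):
        p = small_patient
        asn = assign_mutations(p.tree, p.mtr, p.dep)
        sens = pd.Series(1.0, index=p.colony_names)
        sens.iloc[:3] = 0.5
        qc = qc_colonies(p.tree, p.mtr, p.dep, sens, asn)
        assert qc.n_retained == qc.n_total - qc.n_dropped == 17


class TestBranchCorrection:
    def test_identity_and_division(self):
        t = Tree(np.array([2, 2, -1]), ["a", "b"])
        raw = np.array([90.0, 90.0, 0.0])
        sens = pd.Series({"a": 1.0, "b": 0.9})
        out = correct_branch_lengths(t, raw, sens, 0.0)
        assert out[0] == pytest.approx(90.0)
        assert out[1] == pytest.approx(100.0)

    def test_cna_mask_rescaling(self):
        t = Tree(np.array([2, 2, -1]), ["a", "b"])
        raw = np.array([0.0, 90.0, 0.0])
        sens = pd.Series({"a": 0.9, "b": 0.9})
        out = correct_branch_lengths(t, raw, sens, 0.1)
        assert out[1] == pytest.approx(90.0 / 0.9 / 0.9)

    def test_shared_branch_uses_joint_sensitivity(self):
        t = Tree(np.array([2, 2, -1]), ["a", "b"])
        raw = np.array([0.0, 0.0, 100.0])
        sens = pd.Series({"a": 0.8, "b": 0.8})
        out = correct_branch_lengths(t, raw, sens, 0.0)
        assert out[2] == pytest.approx(100.0 / (1 - 0.2 ** 2))

    def test_full_mask_rejected(self):
        t = Tree(np.array([2, 2, -1]), ["a", "b"])
        with pytest.raises(ValueError):
            correct_branch_lengths(t, np.zeros(3), pd.Series({"a": 1, "b": 1}), 1.0)


class TestDriverClades:
    def test_all_positive_is_root(self):
        t = balanced4()
        assert annotate_driver_clades(t, dict.fromkeys("abcd", True)) == t.root

    def test_single_positive_is_terminal(self):
        t = balanced4()
        calls = dict.fromkeys("abcd", False)
        calls["c"] = True
        assert annotate_driver_clades(t, calls) == 2

    def test_simulated_clade_stem(self, small_patient):
        p = small_patient
        calls = {n: (i in set(p.mutant_tips))
                 for i, n in enumerate(p.colony_names)}
        assert annotate_driver_clades(p.tree, calls) == p.clade_node

    def test_non_monophyletic_rejected_with_offenders(self):
        t = balanced4()
        calls = {"a": True, "b": False, "c": True, "d": False}
        with pytest.raises(ValueError, match="intruding"):
            annotate_driver_clades(t, calls)
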