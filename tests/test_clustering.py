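import json

import numpy as np
import pytest

from micca import (
    Experiment,
    build_sensitivity_matrix,
    cluster_parameters,
    corr_with_rest,
    export_tree,
    random_input_profiles,
    screen_experiments,
)

from conftest import matrix_from_columns


@pytest.fixture(scope="module")
def gene_tree(gene_steady_S):
    return cluster_parameters(gene_steady_S, delta=0.95, zeta=1.0)


class TestClusterParameters:
    def test_gene_steady_state_merge_structure(self, gene_tree):
        """Production/degradation pairs join at zero height; the two pairs
        join later at positive height."""
        steps = gene_tree.merges
        assert len(steps) == 3
        first_two = [frozenset(m.left) | frozenset(m.right) for m in steps[:2]]
        assert frozenset({"k_r", "g_r"}) in first_two
        assert frozenset({"k_p", "g_p"}) in first_two
        assert steps[0].height == pytest.approx(0.0, abs=1e-9)
        assert steps[1].height == pytest.approx(0.0, abs=1e-9)
        assert steps[2].height > 0.01

    def test_gene_steady_state_pruning(self, gene_tree):
        """Each zero-height merge forces one member out (perfect pairwise
        compensation), so exactly two parameters are delta-pruned."""
        removed = gene_tree.removed_parameters()
        assert len(removed) == 2
        assert len({"k_r", "g_r"} & set(removed)) == 1
        assert len({"k_p", "g_p"} & set(removed)) == 1

    def test_partition_is_conserved(self, gene_tree):
        all_params = set(gene_tree.identifiable) | set(gene_tree.non_identifiable)
        assert all_params == set(gene_tree.leaves)
        assert not set(gene_tree.identifiable) & set(gene_tree.non_identifiable)

    def test_orthogonal_columns_cluster_without_pruning(self):
        S = matrix_from_columns(np.eye(4))
        tree = cluster_parameters(S, delta=0.95, zeta=0.5)
        assert all(m.height == pytest.approx(1.0, abs=1e-12) for m in tree.merges)
        assert not tree.removed_parameters()
        assert set(tree.identifiable) == {"p0", "p1", "p2", "p3"}

    def test_joint_compensation_prunes_exactly_one(self):
        """(1,0), (0,1) and their normalised sum: pairwise correlations are
        all moderate, yet the three together span only a plane, so the
        3-cluster contains a member fully compensated by the others."""
        S = matrix_from_columns([[1, 0], [0, 1], [1 / np.sqrt(2), 1 / np.sqrt(2)]])
        tree = cluster_parameters(S, delta=0.95, zeta=0.5)
        assert len(tree.removed_parameters()) == 1
        # removal happens at the step where the third column joins
        assert tree.merges[-1].removed == tree.removed_parameters()

    def test_determinism(self, gene_steady_S):
        t1 = cluster_parameters(gene_steady_S, 0.95, 1.0)
        t2 = cluster_parameters(gene_steady_S, 0.95, 1.0)
        assert export_tree(t1, "json") == export_tree(t2, "json")

    def test_permutation_changes_only_labels(self, gene_decay_S):
        rng = np.random.default_rng(5)
        perm = rng.permutation(gene_decay_S.n_params)
        shuffled = matrix_from_columns(
            gene_decay_S.values[:, perm].T,
            [gene_decay_S.param_names[i] for i in perm],
        )
        t_orig = cluster_parameters(gene_decay_S, 0.95, 1.0)
        t_perm = cluster_parameters(shuffled, 0.95, 1.0)
        orig_sets = [frozenset(m.left) | frozenset(m.right) for m in t_orig.merges]
        perm_sets = [frozenset(m.left) | frozenset(m.right) for m in t_perm.merges]
        assert sorted(orig_sets, key=sorted) == sorted(perm_sets, key=sorted)
        assert set(t_orig.identifiable) == set(t_perm.identifiable)

    def test_zero_height_merges_iff_all_ccs_one(self, gene_tree):
        for m in gene_tree.merges:
            if m.height < 1e-9:
                assert np.all(m.rhos > 1 - 1e-6)
            else:
                assert np.any(m.rhos < 1 - 1e-6)

    def test_pruned_members_had_rho_above_delta(self, gene_steady_S):
        """Post-hoc audit: at its pruning step, each removed parameter was
        correlated >= delta with the surviving members of its cluster."""
        tree = cluster_parameters(gene_steady_S, 0.95, 1.0)
        for m in tree.merges:
            if not m.removed:
                continue
            members = set(m.left) | set(m.right)
            for victim in m.removed:
                rest = sorted((members - {victim}) - set(m.removed))
                if rest:
                    assert corr_with_rest(gene_steady_S, victim, rest) >= 0.95 - 1e-9

    def test_zeta_failures_still_cluster_but_are_not_identifiable(self):
        S = matrix_from_columns([[1, 0], [0, 1], [0.007, 0.007]])
        tree = cluster_parameters(S, delta=0.95, zeta=0.5)
        assert "p2" in tree.zeta_failed
        assert any("p2" in (set(m.left) | set(m.right)) for m in tree.merges)
        assert "p2" not in tree.identifiable
        assert tree.non_identifiable["p2"].startswith("zeta")

    def test_single_parameter_matrix_rejected(self):
        S = matrix_from_columns([[1, 2, 3]])
        with pytest.raises(ValueError, match="two parameters"):
            cluster_parameters(S)


class TestExportTree:
    def test_two_leaf_newick(self):
        S = matrix_from_columns([[1, 0], [0, 1]], ["A", "B"])
        tree = cluster_parameters(S, 0.95, 0.5)
        assert export_tree(tree, "newick") == "(A:1,B:1);"

    def test_gene_tree_newick_has_all_leaves_and_removal_tags(self, gene_tree):
        nwk = export_tree(gene_tree, "newick")
        for p in gene_tree.leaves:
            assert p in nwk
        assert nwk.count("[&removed=") == 2

    def test_round_trip_preserves_merge_structure(self, gene_tree):
        import dendropy

        nwk = export_tree(gene_tree, "newick")
        parsed = dendropy.Tree.get(
            data=nwk,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        clades = {
            frozenset(leaf.taxon.label.split("[")[0] for leaf in node.leaf_iter())
            for node in parsed.preorder_node_iter()
            if not node.is_leaf()
        }
        assert _expected_clades(gene_tree) <= clades

    def test_json_export_is_valid_and_complete(self, gene_tree):
        doc = json.loads(export_tree(gene_tree, "json"))
        assert doc["schema"] == "micca-tree/1"
        assert len(doc["merges"]) == 3
        assert set(doc["identifiable"]) | set(doc["non_identifiable"]) == set(doc["leaves"])

    def test_unknown_format_rejected(self, gene_tree):
        with pytest.raises(ValueError, match="format"):
            export_tree(gene_tree, "nexus")


def _expected_clades(tree):
    """Full leaf set under each internal node, replayed from the merge
    history (merge records list only surviving members)."""
    clusters = [({p}, {p}) for p in tree.leaves]  # (surviving, full leaf set)
    clades = set()
    for m in tree.merges:
        left = next(c for c in clusters if c[0] == set(m.left))
        clusters.remove(left)
        right = next(c for c in clusters if c[0] == set(m.right))
        clusters.remove(right)
        full = left[1] | right[1]
        surviving = (set(m.left) | set(m.right)) - set(m.removed)
        clusters.append((surviving, full))
        clades.add(frozenset(full))
    return clades


class TestScreenExperiments:
    def test_decay_candidate_rescues_steady_state_design(self, gene_fx):
        ranking = screen_experiments(
            gene_fx.model,
            base=[gene_fx.experiment("steady_state")],
            candidates=[gene_fx.experiment("decay")],
        )
        (entry,) = ranking
        assert entry.n_identifiable == 4
        assert entry.gain == 4

    def test_duplicate_candidate_changes_nothing(self, gene_fx):
        base = [gene_fx.experiment("decay")]
        ranking = screen_experiments(
            gene_fx.model, base=base, candidates=[gene_fx.experiment("decay")]
        )
        (entry,) = ranking
        assert entry.gain == 0

    def test_ranking_is_sorted_and_deterministic(self, gene_fx):
        cands = [
            gene_fx.experiment("steady_state"),
            gene_fx.experiment("decay"),
            gene_fx.experiment("steady_state"),
        ]
        ranking = screen_experiments(gene_fx.model, base=[], candidates=cands)
        counts = [e.n_identifiable for e in ranking]
        assert counts == sorted(counts, reverse=True)
        # equal-count candidates keep their input order
        tied = [e.index for e in ranking if e.n_identifiable == counts[-1]]
        assert tied == sorted(tied)

    def test_failing_candidate_is_skipped_not_fatal(self, gene_fx):
        bad = Experiment(observed=["r"], times=[1e6], name="bad_horizon")
        # an unknown parameter override triggers a per-candidate error
        worse = Experiment(
            observed=["r"], times=[1.0], param_overrides={"nope": 1.0}, name="typo"
        )
        ranking = screen_experiments(
            gene_fx.model, base=[], candidates=[gene_fx.experiment("decay"), worse]
        )
        assert ranking[0].name == "decay"
        errs = [e for e in ranking if e.error is not None]
        assert len(errs) == 1 and errs[0].name == "typo"


class TestRandomInputProfiles:
    def test_seeded_profiles_are_reproducible_and_piecewise_constant(self):
        grid = [0.0, 2.0, 4.0, 8.0]
        p1 = random_input_profiles(42, 3, grid, (0.0, 2.0))
        p2 = random_input_profiles(42, 3, grid, (0.0, 2.0))
        ts = np.linspace(0, 10, 50)
        for a, b in zip(p1, p2):
            assert [a(t) for t in ts] == [b(t) for t in ts]
        vals = {p1[0](t) for t in np.linspace(0.1, 1.9, 10)}
        assert len(vals) == 1  # constant within a grid cell

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            random_input_profiles(1, 2, [0.0, 0.0, 1.0])
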