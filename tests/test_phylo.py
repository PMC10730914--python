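"""Dollo parsimony and marginal ancestral reconstruction, each checked
against exhaustive enumeration oracles written independently in this file."""

import itertools
import math
import random

import numpy as np
import pandas as pd
import pytest

from tropanevo.phylo import (SiteModel, dollo_losses, marginal_ancestral,
                             pathway_loss_report, read_tree, starred_newick,
                             AA_ORDER, AA_INDEX)


# ---------------------------------------------------------------------------
# Dollo

def random_tree(rng, n_leaves):
    """Random rooted binary topology as newick, unit branch lengths."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        nodes.append(f"({a}:1,{b}:1)")
    return nodes[0] + "R;"


def oracle_dollo(tree, traits):
    """Minimal 1->0 edge count over all labelings with no 0->1 edge and the
    root carrying the trait (single gain at the origin)."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = None
    for states in itertools.product((0, 1), repeat=len(internals)):
        lab = dict(zip((n.label for n in internals), states))
        lab.update(traits)
        if lab[tree.seed_node.label] != 1:
            continue
        losses = 0
        ok = True
        for node in tree.preorder_node_iter():
            for child in node.child_nodes():
                p, c = lab[node.label], lab[child.label]
                if p == 0 and c == 1:
                    ok = False
                    break
                if p == 1 and c == 0:
                    losses += 1
            if not ok:
                break
        if ok:
            best = losses if best is None else min(best, losses)
    return best


class TestDollo:
    def test_two_scattered_leaves_need_two_losses(self):
        tree = read_tree("((A:1,B:1)AB:1,(C:1,D:1)CD:1)R;")
        res = dollo_losses(tree, {"A": 1, "B": 0, "C": 1, "D": 0})
        assert res.loss_count == 2
        assert {c for _, c in res.loss_edges} == {"B", "D"}

    def test_all_present_no_losses(self):
        tree = read_tree("((A:1,B:1)AB:1,(C:1,D:1)CD:1)R;")
        assert dollo_losses(tree, dict.fromkeys("ABCD", 1)).loss_count == 0

    def test_matches_brute_force_on_random_instances(self):
        rng = random.Random(99)
        for _ in range(500):
            n = rng.randint(3, 10)
            tree = read_tree(random_tree(rng, n))
            leaves = [lf.label for lf in tree.leaf_node_iter()]
            traits = {lf: rng.randint(0, 1) for lf in leaves}
            if not any(traits.values()):
                traits[leaves[0]] = 1
            res = dollo_losses(tree, traits)
            assert res.loss_count == oracle_dollo(tree, traits)

    def test_single_flip_adds_at_most_one_loss(self):
        """Flipping one leaf off either opens one new loss edge or merges
        existing sibling losses into an ancestral one - never more than +1."""
        rng = random.Random(5)
        for _ in range(50):
            tree = read_tree(random_tree(rng, 8))
            leaves = [lf.label for lf in tree.leaf_node_iter()]
            traits = dict.fromkeys(leaves, 1)
            prev = 0
            for leaf in rng.sample(leaves, len(leaves) - 1):
                traits[leaf] = 0
                cur = dollo_losses(tree, traits).loss_count
                assert cur <= prev + 1
                assert cur >= 1
                prev = cur

    def test_missing_leaf_trait_rejected(self):
        tree = read_tree("((A:1,B:1):1,C:1)R;")
        with pytest.raises(ValueError):
            dollo_losses(tree, {"A": 1, "B": 0})


# ---------------------------------------------------------------------------
# Marginal ancestral reconstruction

def poisson_p(t):
    decay = math.exp(-t * 20 / 19)
    off = (1 - decay) / 20
    p = np.full((20, 20), off)
    np.fill_diagonal(p, off + decay)
    return p


def oracle_three_taxon(t, column):
    """Exhaustive summation over both internal states of ((A,B)X,C)R."""
    br = {n.label: n.edge.length for n in t.preorder_node_iter()
          if n.edge.length is not None}
    P = {lab: poisson_p(l) for lab, l in br.items()}
    pi = 1.0 / 20.0
    joint = np.zeros((20, 20))     # root state x internal state
    for sr in range(20):
        for sx in range(20):
            joint[sr, sx] = (
                pi
                * P["X"][sr, sx]
                * P["A"][sx, AA_INDEX[column["A"]]]
                * P["B"][sx, AA_INDEX[column["B"]]]
                * P["C"][sr, AA_INDEX[column["C"]]]
            )
    total = joint.sum()
    return {"R": joint.sum(axis=1) / total, "X": joint.sum(axis=0) / total}


class TestMarginalAncestral:
    def test_uniform_column_short_branches_certain(self):
        tree = read_tree("((A:1e-9,B:1e-9)X:1e-9,C:1e-9)R;")
        post = marginal_ancestral(tree, dict.fromkeys("ABC", "V"))
        for node in ("R", "X"):
            assert post.residue_probability(node, "V") > 0.999999

    def test_matches_exhaustive_summation_three_taxa(self):
        rng = random.Random(1)
        for _ in range(25):
            t1, t2, t3, t4 = (round(rng.uniform(0.01, 1.5), 3)
                              for _ in range(4))
            tree = read_tree(f"((A:{t1},B:{t2})X:{t3},C:{t4})R;")
            column = {lf: rng.choice(AA_ORDER) for lf in "ABC"}
            post = marginal_ancestral(tree, column)
            expected = oracle_three_taxon(tree, column)
            for node in ("R", "X"):
                assert np.allclose(post.posteriors[node], expected[node],
                                   atol=1e-12)

    def test_posteriors_normalized_everywhere(self):
        rng = random.Random(2)
        tree = read_tree(random_tree(rng, 9))
        column = {lf.label: rng.choice(AA_ORDER)
                  for lf in tree.leaf_node_iter()}
        post = marginal_ancestral(tree, column)
        for p in post.posteriors.values():
            assert abs(p.sum() - 1.0) < 1e-9

    def test_rerooting_leaves_likelihood_unchanged(self):
        rng = random.Random(3)
        newick = random_tree(rng, 7)
        tree = read_tree(newick)
        column = {lf.label: rng.choice(AA_ORDER)
                  for lf in tree.leaf_node_iter()}
        base = marginal_ancestral(tree, column).log_likelihood
        tree2 = read_tree(newick)
        internal = [n for n in tree2.preorder_node_iter()
                    if not n.is_leaf() and n is not tree2.seed_node][0]
        tree2.reroot_at_edge(internal.edge, update_bipartitions=False,
                             length1=internal.edge.length / 2,
                             length2=internal.edge.length / 2)
        from tropanevo.phylo import label_nodes
        label_nodes(tree2)
        again = marginal_ancestral(tree2, column).log_likelihood
        assert again == pytest.approx(base, abs=1e-9)

    def test_gap_treated_as_missing(self):
        tree = read_tree("((A:0.1,B:0.1)X:0.1,C:0.1)R;")
        post = marginal_ancestral(tree, {"A": "V", "B": "-", "C": "V"})
        assert post.map_state("R") == "V"

    def test_zero_length_conflict_is_error(self):
        tree = read_tree("((A:0,B:0)X:0,C:0)R;")
        with pytest.raises(ValueError):
            marginal_ancestral(tree, {"A": "V", "B": "L", "C": "V"})

    def test_site_set_reconstruction_over_alignment(self):
        from tropanevo.phylo import DEFAULT_KEY_SITES, reconstruct_sites
        assert DEFAULT_KEY_SITES == (109, 155, 167, 201, 243)
        tree = read_tree("((A:0.1,B:0.1)X:0.1,C:0.1)R;")
        aln = {"A": "VLV", "B": "VLV", "C": "VLL"}
        posts = reconstruct_sites(tree, aln, sites=(1, 3))
        assert set(posts) == {1, 3}
        assert posts[1].map_state("R") == "V"
        with pytest.raises(ValueError):
            reconstruct_sites(tree, aln, sites=(9,))

    def test_custom_rate_matrix_accepted(self):
        q = np.full((20, 20), 1 / 19)
        np.fill_diagonal(q, -1.0)
        tree = read_tree("((A:0.2,B:0.2)X:0.2,C:0.2)R;")
        column = {"A": "V", "B": "V", "C": "L"}
        default = marginal_ancestral(tree, column)
        custom = marginal_ancestral(tree, column,
                                    SiteModel(rate_matrix=q))
        # this Q *is* the Poisson generator, so posteriors agree
        for node in default.posteriors:
            assert np.allclose(default.posteriors[node],
                               custom.posteriors[node], atol=1e-9)


# ---------------------------------------------------------------------------
# Pathway-level report

def matrix_from(states: dict[str, dict[str, str]], enzymes) -> pd.DataFrame:
    return pd.DataFrame(states).reindex(index=enzymes)


class TestLossReport:
    TREE = "((Aaa:1,Bbb:1)AB:1,(Ccc:1,Ddd:1)CD:1)R;"
    HS = ["TRI", "LS", "CYP80F1", "HDH", "H6H"]

    def test_all_intact_matrix_has_no_stars(self, default_model):
        tree = read_tree(self.TREE)
        mat = matrix_from({sp: dict.fromkeys(default_model.enzymes, "intact")
                           for sp in ("Aaa", "Bbb", "Ccc", "Ddd")},
                          default_model.enzymes)
        report = pathway_loss_report(mat, tree, default_model)
        assert report.phenotype.loss_count == 0

    def test_clade_pseudogenized_segment_is_single_stem_star(self, default_model):
        tree = read_tree(self.TREE)
        states = {}
        for sp in ("Aaa", "Bbb", "Ccc", "Ddd"):
            cell = dict.fromkeys(default_model.enzymes, "intact")
            if sp in ("Ccc", "Ddd"):
                for e in self.HS:
                    cell[e] = "pseudogene"
            states[sp] = cell
        report = pathway_loss_report(
            matrix_from(states, default_model.enzymes), tree, default_model)
        assert {c for _, c in report.phenotype.loss_edges} == {"CD"}
        # locus-level view: pseudogenes still mark the locus as present
        for e in self.HS:
            assert report.locus_per_gene[e].loss_count == 0
            assert report.per_gene[e].loss_count == 1

    def test_gene_absent_across_ingroup_maps_to_its_stem(self, default_model):
        tree = read_tree("((Out1:1,Out2:1)OUT:1,"
                         "((Aaa:1,Bbb:1)AB:1,Ccc:2)ING:1)R;")
        states = {}
        for sp in ("Out1", "Out2", "Aaa", "Bbb", "Ccc"):
            cell = dict.fromkeys(default_model.enzymes, "intact")
            if sp not in ("Out1", "Out2"):
                cell["HDH"] = "absent"
            states[sp] = cell
        report = pathway_loss_report(
            matrix_from(states, default_model.enzymes), tree, default_model)
        assert {c for _, c in report.per_gene["HDH"].loss_edges} == {"ING"}

    def test_species_missing_from_tree_rejected(self, default_model):
        tree = read_tree(self.TREE)
        mat = matrix_from({sp: dict.fromkeys(default_model.enzymes, "intact")
                           for sp in ("Aaa", "Bbb", "Ccc", "Nope")},
                          default_model.enzymes)
        with pytest.raises(ValueError):
            pathway_loss_report(mat, tree, default_model)

    def test_starred_newick_marks_lost_branches(self, default_model):
        tree = read_tree(self.TREE)
        states = {}
        for sp in ("Aaa", "Bbb", "Ccc", "Ddd"):
            cell = dict.fromkeys(default_model.enzymes, "intact")
            if sp == "Ddd":
                for e in self.HS:
                    cell[e] = "absent"
            states[sp] = cell
        report = pathway_loss_report(
            matrix_from(states, default_model.enzymes), tree, default_model)
        nwk = starred_newick(tree, report.phenotype.loss_edges)
        assert "Ddd*" in nwk.replace("'", "")
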