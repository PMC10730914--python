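"""Dollo-parsimony loss inference and marginal ancestral state reconstruction.

A complex trait (here: a functional pathway gene, or the whole producer
phenotype) is assumed to arise once, at the root, and only be lost.  Under
that constraint the minimal labeling sets an internal node to 1 iff any
descendant leaf carries the trait; loss edges are the 1->0 edges.

Ancestral residues at single alignment columns are reconstructed by
Felsenstein's pruning algorithm with marginal posteriors from the standard
outside (re-rooting) pass.  The default substitution model is Poisson over
the 20 amino acids with equal stationary frequencies; a custom 20x20 rate
matrix may be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.linalg import expm

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


# ---------------------------------------------------------------------------
# Tree utilities

def read_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=False)
    label_nodes(tree)
    return tree


def label_nodes(tree: dendropy.Tree) -> None:
    """Ensure every node has a stable label (leaves: taxon; internals: given
    label or N<k> in preorder)."""
    k = 0
    for node in tree.preorder_node_iter():
        if node.taxon is not None and node.taxon.label:
            node.label = node.taxon.label.replace(" ", "_")
        elif not node.label:
            node.label = f"N{k}"
            k += 1


def write_newick(tree: dendropy.Tree) -> str:
    """Newick string with each internal label written exactly once.

    Internal labels parsed as taxa would otherwise be emitted twice (taxon +
    node label) after :func:`label_nodes` mirrors them onto ``node.label``.
    """
    return tree.as_string(
        schema="newick", suppress_rooting=True,
        suppress_internal_node_labels=True,
    ).strip() + "\n"


def node_by_label(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for node in tree.preorder_node_iter():
        if node.label == label:
            return node
    raise KeyError(f"no node labelled {label!r} in tree")


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.label for lf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Dollo parsimony

@dataclass
class DolloResult:
    origin: str
    states: dict[str, int]
    loss_edges: set[tuple[str, str]]

    @property
    def loss_count(self) -> int:
        return len(self.loss_edges)


def dollo_losses(tree: dendropy.Tree, traits: dict[str, int]) -> DolloResult:
    """Minimal single-gain (root-origin) labeling and its loss edges.

    ``traits`` maps every leaf label to 0/1 (1 = trait present/functional).
    Internal state is 1 iff any descendant leaf is 1; loss edges are the
    edges whose parent is 1 and child 0.  This labeling is the unique
    loss-minimal one among all labelings with no 0->1 edge.
    """
    if tree.seed_node is None or len(tree.seed_node.child_nodes()) == 0:
        raise ValueError("tree is empty")
    leaves = set(leaf_labels(tree))
    missing = leaves - set(traits)
    if missing:
        raise ValueError(f"traits missing for leaves: {sorted(missing)}")
    extra = set(traits) - leaves
    if extra:
        raise ValueError(f"traits for unknown leaves: {sorted(extra)}")

    states: dict[str, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            states[node.label] = int(traits[node.label])
        else:
            states[node.label] = int(
                any(states[c.label] for c in node.child_nodes())
            )
    losses = {
        (node.label, child.label)
        for node in tree.preorder_node_iter()
        for child in node.child_nodes()
        if states[node.label] == 1 and states[child.label] == 0
    }
    return DolloResult(tree.seed_node.label, states, losses)


# ---------------------------------------------------------------------------
# Marginal ancestral reconstruction

@dataclass
class SiteModel:
    """Substitution model + branch-length handling for one-column ASR.

    ``rate_matrix`` is a 20x20 generator (rows sum to zero) ordered by
    AA_ORDER; None selects the Poisson (equal-exchangeability, uniform
    frequency) model normalized to one expected substitution per unit branch
    length.  ``branch_scale`` multiplies input branch lengths, e.g. to map a
    time-calibrated tree (Mya) onto substitutions/site.
    """
    rate_matrix: np.ndarray | None = None
    frequencies: np.ndarray | None = None
    branch_scale: float = 1.0

    def __post_init__(self):
        if self.frequencies is None:
            self.frequencies = np.full(20, 1.0 / 20.0)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.rate_matrix is not None:
            q = np.asarray(self.rate_matrix, dtype=float)
            if q.shape != (20, 20):
                raise ValueError("rate matrix must be 20x20")
            self.rate_matrix = q

    def transition(self, t: float) -> np.ndarray:
        t = t * self.branch_scale
        if t < 0:
            raise ValueError("negative branch length")
        if self.rate_matrix is None:
            # Poisson closed form, normalized to 1 substitution/unit length:
            # P_ii(t) = 1/20 + 19/20 e^{-(20/19) t}
            return _poisson_p(t)
        return expm(self.rate_matrix * t)


def _poisson_p(t: float) -> np.ndarray:
    decay = np.exp(-t * 20.0 / 19.0)
    off = (1.0 - decay) / 20.0
    diag = off + decay
    p = np.full((20, 20), off)
    np.fill_diagonal(p, diag)
    return p


@dataclass
class AncestralPosterior:
    posteriors: dict[str, np.ndarray] = field(default_factory=dict)
    log_likelihood: float = 0.0

    def residue_probability(self, node: str, residue: str) -> float:
        return float(self.posteriors[node][AA_INDEX[residue]])

    def map_state(self, node: str) -> str:
        return AA_ORDER[int(np.argmax(self.posteriors[node]))]


def _leaf_vector(residue: str | None) -> np.ndarray:
    if residue is None or residue in ("-", "?", "X"):
        return np.ones(20)
    if residue not in AA_INDEX:
        raise ValueError(f"unknown residue {residue!r}")
    v = np.zeros(20)
    v[AA_INDEX[residue]] = 1.0
    return v


def marginal_ancestral(
    tree: dendropy.Tree,
    column: dict[str, str],
    model: SiteModel | None = None,
) -> AncestralPosterior:
    """Marginal posteriors over residues at every node for one column.

    ``column`` maps leaf labels to residues; gaps/unknowns ('-', '?', 'X' or
    a missing entry) contribute likelihood 1 for every state.  Zero-length
    branches use the identity transition P(0) = I; if hard-conflicting leaf
    states make the column likelihood exactly zero, a diagnostic error is
    raised.
    """
    model = model or SiteModel()
    leaves = set(leaf_labels(tree))
    extra = set(column) - leaves
    if extra:
        raise ValueError(f"column has residues for unknown leaves: {sorted(extra)}")

    inside: dict[str, np.ndarray] = {}
    pmat: dict[str, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node is not tree.seed_node:
            t = node.edge.length or 0.0
            pmat[node.label] = model.transition(t)
        if node.is_leaf():
            inside[node.label] = _leaf_vector(column.get(node.label))
        else:
            v = np.ones(20)
            for child in node.child_nodes():
                v = v * (pmat[child.label] @ inside[child.label])
            inside[node.label] = v

    root = tree.seed_node.label
    total = float(model.frequencies @ inside[root])
    if total <= 0.0:
        raise ValueError(
            "column likelihood is zero: conflicting hard leaf states on a "
            "zero-length tree"
        )

    outside: dict[str, np.ndarray] = {root: model.frequencies.copy()}
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        if not children:
            continue
        child_msgs = {
            c.label: pmat[c.label] @ inside[c.label] for c in children
        }
        for c in children:
            sib = np.ones(20)
            for other in children:
                if other is not c:
                    sib = sib * child_msgs[other.label]
            outside[c.label] = (outside[node.label] * sib) @ pmat[c.label]

    post = AncestralPosterior(log_likelihood=float(np.log(total)))
    for node in tree.preorder_node_iter():
        p = outside[node.label] * inside[node.label]
        post.posteriors[node.label] = p / p.sum()
    return post


# Variable TRI positions controlling tropinone binding/limitation, on the
# reference protein coordinate (1-based).
DEFAULT_KEY_SITES = (109, 155, 167, 201, 243)


def reconstruct_sites(
    tree: dendropy.Tree,
    alignment: dict[str, str],
    sites: tuple[int, ...] = DEFAULT_KEY_SITES,
    model: SiteModel | None = None,
) -> dict[int, AncestralPosterior]:
    """Marginal ancestral reconstruction at selected alignment columns.

    ``alignment`` maps leaf labels to equal-length protein sequences;
    ``sites`` are 1-based column indices on that alignment.  Returns one
    posterior table per site.
    """
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) > 1:
        raise ValueError("alignment sequences have unequal lengths")
    length = lengths.pop() if lengths else 0
    out = {}
    for site in sites:
        if not 1 <= site <= length:
            raise ValueError(f"site {site} outside alignment length {length}")
        column = {leaf: seq[site - 1] for leaf, seq in alignment.items()}
        out[site] = marginal_ancestral(tree, column, model)
    return out


# ---------------------------------------------------------------------------
# Pathway-level report

@dataclass
class LossReport:
    producer_traits: dict[str, int]
    phenotype: DolloResult
    per_gene: dict[str, DolloResult]
    locus_per_gene: dict[str, DolloResult]


def pathway_loss_report(matrix, tree: dendropy.Tree, model) -> LossReport:
    """Dollo analysis of a presence matrix (rows: enzymes, cols: species).

    Runs a per-gene Dollo on the functional states (intact = 1), a
    locus-level Dollo (intact or pseudogene = 1, i.e. the locus is still
    recognisable), and a Dollo on the producer phenotype derived from
    ``producer_phenotype``; the phenotype loss edges are the "starred"
    branches.
    """
    from .pathway import producer_phenotype

    leaves = set(leaf_labels(tree))
    missing = [sp for sp in matrix.columns if sp not in leaves]
    if missing:
        raise ValueError(f"matrix species not in tree: {missing}")

    traits = {}
    for sp in matrix.columns:
        states = {enzyme: matrix.loc[enzyme, sp] for enzyme in matrix.index}
        traits[sp] = int(producer_phenotype(model, states))
    for leaf in leaves - set(matrix.columns):
        raise ValueError(f"tree leaf {leaf!r} missing from matrix")

    phenotype = dollo_losses(tree, traits)
    per_gene = {}
    locus = {}
    for enzyme in matrix.index:
        fn = {sp: int(matrix.loc[enzyme, sp] == "intact") for sp in matrix.columns}
        lc = {sp: int(matrix.loc[enzyme, sp] in ("intact", "pseudogene"))
              for sp in matrix.columns}
        per_gene[enzyme] = dollo_losses(tree, fn)
        locus[enzyme] = dollo_losses(tree, lc)
    return LossReport(traits, phenotype, per_gene, locus)


def starred_newick(tree: dendropy.Tree, loss_edges: set[tuple[str, str]]) -> str:
    """Newick with '*' appended to labels of branches (child nodes) lost."""
    t = tree.clone(depth=1)
    lost_children = {c for _, c in loss_edges}
    for node in t.preorder_node_iter():
        if node.label in lost_children:
            star = node.label + "*"
            node.label = star
            if node.taxon is not None:
                node.taxon = dendropy.Taxon(label=star)
    return write_newick(t).strip()
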