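"""Synthetic clade generator with ground truth.

Builds an ancestral genome (background gene families plus the 12 pathway
genes at fixed loci), then evolves it along a rooted, time-calibrated
(million-year) species tree:

* coding sequences accumulate synonymous / nonsynonymous substitutions at
  per-site yearly rates r_s and r_n (class membership consistent with the
  NG86 counter used by the Ks estimator);
* whole-genome duplications (or triplications) on flagged branches copy
  every chromosome, then drop each duplicated gene with probability
  1 - retention;
* Poisson gene-level events along every branch: loss (locus removed),
  pseudogenization (5' exons truncated or a premature stop inserted; the
  disabled remnant stays at the locus and keeps drifting neutrally), and
  translocation (the gene moves; a translocated pathway gene additionally
  scatters its flanking orthologs, emulating the synteny erosion that makes
  such genes undetectable by collinearity);
* forced events: whole-pathway loss on designated branches (the five
  HS-exclusive genes become pseudogene-or-absent), tandem duplications, and
  forced translocations.

Everything is driven by a single seeded generator: identical tree + config +
seed give byte-identical outputs.  Ground truth (per-leaf functional states,
loss branches, paralog pairs with expected synonymous divergence, and a
replayable event log) is returned alongside the data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from ._codon import (
    NUCS, SENSE_CODONS, STOP_CODONS, single_changes, codon_sites, translate,
)
from .gffio import Gene, GenomeAnnotation, write_fasta, write_gff3
from .pathway import PathwayModel, hs_exclusive_steps, load_default_pathway
from .phylo import label_nodes, read_tree


class SimError(ValueError):
    pass


@dataclass
class WgdSpec:
    retention: float = 0.5
    multiplier: int = 2            # 2 = duplication, 3 = triplication

    def __post_init__(self):
        if not 0.0 < self.retention <= 1.0:
            raise SimError("retention fraction must be in (0, 1]")
        if self.multiplier not in (2, 3):
            raise SimError("multiplier must be 2 or 3")


@dataclass
class SimConfig:
    seed: int = 7
    n_chromosomes: int = 2
    n_background_genes_per_chrom: int = 40
    gene_length_bp: int = 450              # CDS incl. terminal stop codon
    intergenic_bp: int = 2000
    intron_bp: int = 100
    exon_fracs: tuple[float, ...] = (0.25, 0.25, 0.5)
    loss_rate: float = 2e-4                # events / gene / My
    pseudogenization_rate: float = 2e-4
    translocation_rate: float = 0.0
    tandem_dup_targets: list = field(default_factory=list)   # (branch, enzyme, extra)
    forced_translocations: list = field(default_factory=list)  # (branch, enzyme)
    wgd_branches: dict = field(default_factory=dict)  # branch -> WgdSpec|retention
    wgt_at_root: bool = False
    wgt_retention: float = 0.25
    r_s: float = 5.6e-9                    # subst / synonymous site / year
    # r_n is calibrated to the observed conservation of the pathway enzymes
    # (~82% protein identity across the family, ~90% to a reference):
    # 0.65e-9/site/yr * ~2.3 nonsyn sites/codon over a 130 My leaf-to-leaf
    # path gives ~20% residue divergence.
    r_n: float = 0.65e-9
    pathway_loss_branches: list = field(default_factory=list)
    pathway_loss_absent_prob: float = 0.5
    protect_pathway_background_events: bool = False
    pseudogenization_mode: str = "truncate-5prime-2-exons"
    translocation_erosion_halfwidth: int = 20

    def __post_init__(self):
        for rate in (self.loss_rate, self.pseudogenization_rate,
                     self.translocation_rate, self.r_s, self.r_n):
            if rate < 0:
                raise SimError("rates must be non-negative")
        if self.gene_length_bp % 3:
            raise SimError("gene_length_bp must be divisible by 3")
        if self.pseudogenization_mode not in (
                "truncate-5prime-2-exons", "premature-stop"):
            raise SimError(f"unknown pseudogenization mode "
                           f"{self.pseudogenization_mode!r}")
        self.wgd_branches = {
            br: spec if isinstance(spec, WgdSpec) else WgdSpec(retention=float(spec))
            for br, spec in self.wgd_branches.items()
        }


# ---------------------------------------------------------------------------
# Internal genome representation

@dataclass
class SimLocus:
    uid: int
    family: str                    # background family id or enzyme symbol
    enzyme: str | None             # pathway enzyme symbol, else None
    kind: str                      # "gene" | "remnant"
    seq: str                       # CDS (gene) or remnant nucleotides


SimGenome = dict[str, list[SimLocus]]   # chromosome -> ordered loci


@dataclass
class TruthTables:
    true_scenario: pd.DataFrame            # enzymes x leaves, states
    true_loss_edges: set[str]              # branch ids (child labels)
    true_wgd_pairs: list[tuple[str, str, str, float]]  # leaf, gene1, gene2, exp Ks
    event_log: list[tuple]                 # (branch, event, uid, family, extra)
    ancestral_uids: dict[int, str]         # uid -> family

    def replay_scenario(self, tree: dendropy.Tree,
                        enzymes: list[str]) -> pd.DataFrame:
        """Re-derive the per-leaf functional states from the event log alone."""
        by_branch: dict[str, list[tuple]] = {}
        for entry in self.event_log:
            by_branch.setdefault(entry[0], []).append(entry)
        out = {}
        for leaf in tree.leaf_node_iter():
            states = {
                uid: ("intact", fam)
                for uid, fam in self.ancestral_uids.items()
            }
            path = []
            node = leaf
            while node is not None:
                path.append(node.label)
                node = node.parent_node
            for branch in reversed(path):
                for entry in by_branch.get(branch, ()):
                    _, event, uid, fam, extra = entry
                    if event == "dup":
                        if uid in states:
                            states[extra] = states[uid]
                    elif event in ("loss", "remnant_loss"):
                        states.pop(uid, None)
                    elif event == "pseudogenize":
                        if uid in states:
                            states[uid] = ("pseudogene", states[uid][1])
            cells = {}
            for enzyme in enzymes:
                kinds = [st for st, fam in states.values() if fam == enzyme]
                if "intact" in kinds:
                    cells[enzyme] = "intact"
                elif "pseudogene" in kinds:
                    cells[enzyme] = "pseudogene"
                else:
                    cells[enzyme] = "absent"
            out[leaf.label] = cells
        frame = pd.DataFrame(out).reindex(index=enzymes)
        return frame[sorted(frame.columns)]


@dataclass
class SimResult:
    annotations: dict[str, GenomeAnnotation]
    truth: TruthTables
    tree: dendropy.Tree
    config: SimConfig
    reference_proteins: dict[str, str]     # enzyme -> ancestral protein
    pathway: PathwayModel


# ---------------------------------------------------------------------------
# Sequence evolution

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS),
                                                  size=n_codons - 2)]
    return "ATG" + "".join(body) + "TAA"


def evolve_cds(cds: str, branch_my: float, r_s: float, r_n: float,
               rng: np.random.Generator) -> str:
    """Evolve a coding sequence for ``branch_my`` million years.

    Substitution counts for each class are Poisson with mean
    rate x years x (NG86 site count of that class); each substitution picks a
    codon in proportion to its per-codon opportunity count and then one of
    its single-nucleotide changes of the class uniformly.  Changes that would
    create a stop codon are never sampled (rejected), so the sequence stays
    free of internal stops; a terminal stop codon is left untouched.
    """
    if len(cds) % 3:
        raise SimError("CDS length not divisible by 3")
    if branch_my < 0:
        raise SimError("negative branch length")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    tail = ""
    if codons and codons[-1] in STOP_CODONS:
        tail = codons.pop()
    if any(c in STOP_CODONS for c in codons):
        raise SimError("internal stop codon in input CDS")
    if branch_my == 0 or not codons:
        return cds

    def class_changes(codon, kind):
        return [ch for ch in single_changes(codon) if ch[3] == kind]

    syn_w = np.array([len(class_changes(c, "syn")) for c in codons], float)
    non_w = np.array([len(class_changes(c, "nonsyn")) for c in codons], float)
    S = sum(codon_sites(c)[0] for c in codons)
    N = sum(codon_sites(c)[1] for c in codons)
    years = branch_my * 1e6
    n_syn = int(rng.poisson(r_s * years * S))
    n_non = int(rng.poisson(r_n * years * N))

    events = ["syn"] * n_syn + ["non"] * n_non
    rng.shuffle(events)
    for kind in events:
        w = syn_w if kind == "syn" else non_w
        total = w.sum()
        if total == 0:
            continue
        i = int(rng.choice(len(codons), p=w / total))
        options = class_changes(codons[i], "syn" if kind == "syn" else "nonsyn")
        _, _, new, _ = options[int(rng.integers(0, len(options)))]
        codons[i] = new
        syn_w[i] = len(class_changes(new, "syn"))
        non_w[i] = len(class_changes(new, "nonsyn"))
    return "".join(codons) + tail


def _drift_nucleotides(seq: str, branch_my: float, rate: float,
                       rng: np.random.Generator) -> str:
    n = int(rng.poisson(rate * branch_my * 1e6 * len(seq)))
    if n == 0 or not seq:
        return seq
    chars = list(seq)
    for _ in range(n):
        i = int(rng.integers(0, len(chars)))
        chars[i] = NUCS[int(rng.integers(0, 4))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Generator

class _Sim:
    def __init__(self, tree: dendropy.Tree, config: SimConfig,
                 pathway: PathwayModel):
        self.tree = tree
        self.cfg = config
        self.pathway = pathway
        self.rng = np.random.default_rng(config.seed)
        self._uid = 0
        self.event_log: list[tuple] = []
        self.wgd_pair_reg: list[tuple[int, int, float]] = []  # uid1, uid2, age Mya
        self.leaf_genomes: dict[str, SimGenome] = {}
        self.node_age: dict[str, float] = {}

    def next_uid(self) -> int:
        self._uid += 1
        return self._uid

    # -- ancestral genome ---------------------------------------------------
    def build_ancestor(self) -> SimGenome:
        cfg = self.cfg
        n_codons = cfg.gene_length_bp // 3
        genome: SimGenome = {}
        enzymes = self.pathway.enzymes
        per_chrom = int(np.ceil(len(enzymes) / cfg.n_chromosomes))
        e_iter = iter(enzymes)
        self.reference_proteins = {}
        for c in range(cfg.n_chromosomes):
            chrom = f"chr{c + 1}"
            loci = []
            n_bg = cfg.n_background_genes_per_chrom
            # pathway genes interleaved at interior positions
            placed = [next(e_iter, None) for _ in range(per_chrom)]
            placed = [e for e in placed if e]
            step = max(1, n_bg // (len(placed) + 1)) if placed else n_bg + 1
            at = {step * (i + 1): e for i, e in enumerate(placed)}
            for i in range(n_bg):
                if i in at:
                    enzyme = at[i]
                    cds = _random_cds(self.rng, n_codons)
                    loci.append(SimLocus(self.next_uid(), enzyme, enzyme,
                                         "gene", cds))
                    self.reference_proteins[enzyme] = translate(cds)
                fam = f"fam{c:02d}_{i:04d}"
                loci.append(SimLocus(self.next_uid(), fam, None, "gene",
                                     _random_cds(self.rng, n_codons)))
            genome[chrom] = loci
        missing = [e for e in enzymes if e not in self.reference_proteins]
        if missing:
            raise SimError(f"could not place pathway genes: {missing} "
                           "(too few chromosomes/background genes)")
        self.ancestral_uids = {
            loc.uid: loc.family for loci in genome.values() for loc in loci
        }
        return genome

    # -- events -------------------------------------------------------------
    def wgd(self, genome: SimGenome, spec: WgdSpec, branch: str,
            age: float) -> SimGenome:
        out: SimGenome = {}
        for chrom, loci in genome.items():
            out[chrom] = loci
        for copy_i in range(spec.multiplier - 1):
            for chrom in list(genome):
                new_chrom = f"{chrom}_{branch}w{copy_i + 1}"
                new_loci = []
                for loc in genome[chrom]:
                    if self.rng.random() > spec.retention:
                        continue
                    uid = self.next_uid()
                    new_loci.append(SimLocus(uid, loc.family, loc.enzyme,
                                             loc.kind, loc.seq))
                    self.event_log.append((branch, "dup", loc.uid,
                                           loc.family, uid))
                    if loc.kind == "gene":
                        self.wgd_pair_reg.append((loc.uid, uid, age))
                if new_loci:
                    out[new_chrom] = new_loci
        return out

    def pseudogenize_seq(self, loc: SimLocus) -> str:
        cfg = self.cfg
        n_codons = len(loc.seq) // 3
        if cfg.pseudogenization_mode == "truncate-5prime-2-exons":
            keep_from = int(round(sum(cfg.exon_fracs[:-1]) * n_codons))
            return loc.seq[3 * keep_from:]
        # premature stop ~40% into the coding region
        pos = max(1, int(0.4 * n_codons))
        return loc.seq[:3 * pos] + "TAA" + loc.seq[3 * pos + 3:]

    def _eligible(self, genome: SimGenome) -> list[tuple[str, int]]:
        out = []
        for chrom in sorted(genome):
            for i, loc in enumerate(genome[chrom]):
                if loc.kind != "gene":
                    continue
                if self.cfg.protect_pathway_background_events and loc.enzyme:
                    continue
                out.append((chrom, i))
        return out

    def _insert_random(self, genome: SimGenome, loc: SimLocus,
                       exclude_chrom: str | None = None) -> None:
        chroms = sorted(genome)
        if exclude_chrom and len(chroms) > 1:
            chroms = [c for c in chroms if c != exclude_chrom]
        chrom = chroms[int(self.rng.integers(0, len(chroms)))]
        pos = int(self.rng.integers(0, len(genome[chrom]) + 1))
        genome[chrom].insert(pos, loc)

    def _remove(self, genome: SimGenome, chrom: str, uid: int) -> SimLocus:
        for i, loc in enumerate(genome[chrom]):
            if loc.uid == uid:
                return genome[chrom].pop(i)
        raise SimError(f"uid {uid} not on {chrom}")

    def translocate(self, genome: SimGenome, chrom: str, idx: int,
                    branch: str) -> None:
        """Move a gene to a random locus; for a pathway gene the surrounding
        background loci are lost as well (synteny erosion), so the moved gene
        ends up with no recognisable collinear context anywhere.  Scattering
        the flank instead would not erode anything: a few dozen relocated
        orthologs always contain a long increasing subsequence that re-chains
        into a block."""
        loc = genome[chrom][idx]
        erosion = loc.enzyme is not None
        flank = []
        if erosion:
            h = self.cfg.translocation_erosion_halfwidth
            lo, hi = max(0, idx - h), min(len(genome[chrom]), idx + h + 1)
            flank = [l for l in genome[chrom][lo:hi] if l.uid != loc.uid]
        moved = self._remove(genome, chrom, loc.uid)
        self._insert_random(genome, moved, exclude_chrom=chrom)
        self.event_log.append((branch, "translocate", moved.uid, moved.family,
                               None))
        for f in flank:
            src = next(c for c in sorted(genome)
                       if any(l.uid == f.uid for l in genome[c]))
            gone = self._remove(genome, src, f.uid)
            if gone.enzyme is not None:
                # another pathway gene in the flank keeps its truth state:
                # it is relocated, not lost
                self._insert_random(genome, gone, exclude_chrom=src)
                self.event_log.append((branch, "translocate", gone.uid,
                                       gone.family, "erosion"))
            else:
                event = "loss" if gone.kind == "gene" else "remnant_loss"
                self.event_log.append((branch, event, gone.uid, gone.family,
                                       "erosion"))

    def random_events(self, genome: SimGenome, branch: str,
                      branch_my: float) -> None:
        cfg = self.cfg
        for event, rate in (("loss", cfg.loss_rate),
                            ("pseudogenize", cfg.pseudogenization_rate),
                            ("translocate", cfg.translocation_rate)):
            eligible = self._eligible(genome)
            if not eligible or rate == 0:
                continue
            n = int(self.rng.poisson(rate * branch_my * len(eligible)))
            n = min(n, len(eligible))
            if n == 0:
                continue
            picks = self.rng.choice(len(eligible), size=n, replace=False)
            # resolve by uid: indices shift as loci are removed/moved
            uids = [(eligible[int(i)][0], genome[eligible[int(i)][0]]
                     [eligible[int(i)][1]].uid) for i in sorted(picks)]
            for chrom, uid in uids:
                idx = next(i for i, l in enumerate(genome[chrom])
                           if l.uid == uid)
                loc = genome[chrom][idx]
                if event == "loss":
                    genome[chrom].pop(idx)
                    self.event_log.append((branch, "loss", uid, loc.family,
                                           None))
                elif event == "pseudogenize":
                    loc.kind = "remnant"
                    loc.seq = self.pseudogenize_seq(loc)
                    self.event_log.append((branch, "pseudogenize", uid,
                                           loc.family, None))
                else:
                    self.translocate(genome, chrom, idx, branch)

    def forced_events(self, genome: SimGenome, branch: str) -> None:
        cfg = self.cfg
        for br, enzyme, extra in cfg.tandem_dup_targets:
            if br != branch:
                continue
            for chrom in sorted(genome):
                for i, loc in enumerate(list(genome[chrom])):
                    if loc.enzyme == enzyme and loc.kind == "gene":
                        for k in range(extra):
                            uid = self.next_uid()
                            genome[chrom].insert(
                                i + 1 + k,
                                SimLocus(uid, loc.family, loc.enzyme, "gene",
                                         loc.seq))
                            self.event_log.append((branch, "dup", loc.uid,
                                                   loc.family, uid))
                        break
                else:
                    continue
                break
        for br, enzyme in cfg.forced_translocations:
            if br != branch:
                continue
            found = [(chrom, i) for chrom in sorted(genome)
                     for i, loc in enumerate(genome[chrom])
                     if loc.enzyme == enzyme and loc.kind == "gene"]
            if found:
                self.translocate(genome, found[0][0], found[0][1], branch)
        if branch in cfg.pathway_loss_branches:
            hs = {s.enzyme_symbol for s in hs_exclusive_steps(self.pathway)}
            for chrom in sorted(genome):
                for idx in reversed(range(len(genome[chrom]))):
                    loc = genome[chrom][idx]
                    if loc.enzyme in hs and loc.kind == "gene":
                        if self.rng.random() < cfg.pathway_loss_absent_prob:
                            genome[chrom].pop(idx)
                            self.event_log.append((branch, "loss", loc.uid,
                                                   loc.family, "forced"))
                        else:
                            loc.kind = "remnant"
                            loc.seq = self.pseudogenize_seq(loc)
                            self.event_log.append((branch, "pseudogenize",
                                                   loc.uid, loc.family,
                                                   "forced"))

    # -- traversal ----------------------------------------------------------
    def evolve_branch(self, genome: SimGenome, node: dendropy.Node) -> SimGenome:
        branch = node.label
        branch_my = node.edge.length or 0.0
        if branch_my <= 0:
            raise SimError(f"branch to {branch} has non-positive length")
        genome = {c: [SimLocus(l.uid, l.family, l.enzyme, l.kind, l.seq)
                      for l in loci] for c, loci in genome.items()}
        if branch in self.cfg.wgd_branches:
            genome = self.wgd(genome, self.cfg.wgd_branches[branch], branch,
                              self.node_age[branch] + branch_my)
        for loci in genome.values():
            for loc in loci:
                if loc.kind == "gene":
                    loc.seq = evolve_cds(loc.seq, branch_my, self.cfg.r_s,
                                         self.cfg.r_n, self.rng)
                else:
                    loc.seq = _drift_nucleotides(loc.seq, branch_my,
                                                 self.cfg.r_s, self.rng)
        self.random_events(genome, branch, branch_my)
        self.forced_events(genome, branch)
        return genome

    def run(self) -> None:
        # node ages (My before present), assuming an ultrametric input tree
        depth: dict[str, float] = {self.tree.seed_node.label: 0.0}
        height = 0.0
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                continue
            depth[node.label] = depth[node.parent_node.label] + \
                (node.edge.length or 0.0)
            height = max(height, depth[node.label])
        self.node_age = {lab: height - d for lab, d in depth.items()}

        ancestor = self.build_ancestor()
        if self.cfg.wgt_at_root:
            ancestor = self.wgd(
                ancestor,
                WgdSpec(retention=self.cfg.wgt_retention, multiplier=3),
                self.tree.seed_node.label, height)
            self.ancestral_uids = {
                loc.uid: loc.family
                for loci in ancestor.values() for loc in loci
            }

        def descend(node: dendropy.Node, genome: SimGenome) -> None:
            for child in node.child_nodes():
                g = self.evolve_branch(genome, child)
                if child.is_leaf():
                    self.leaf_genomes[child.label] = g
                else:
                    descend(child, g)

        descend(self.tree.seed_node, ancestor)


def _layout_leaf(leaf: str, genome: SimGenome, cfg: SimConfig,
                 rng: np.random.Generator) -> GenomeAnnotation:
    """Lay a simulated genome onto coordinates and build the annotation."""
    ann = GenomeAnnotation(species=leaf)
    for chrom in sorted(genome):
        parts = []
        cursor = 0
        counter = 0
        for loc in genome[chrom]:
            spacer = "".join(NUCS[i] for i in rng.integers(0, 4,
                                                           cfg.intergenic_bp))
            parts.append(spacer)
            cursor += len(spacer)
            if loc.kind == "gene":
                counter += 1
                gid = f"{leaf}_{chrom}_g{counter:04d}"
                n_codons = len(loc.seq) // 3
                bounds = np.cumsum(
                    [0] + [int(round(f * n_codons)) for f in cfg.exon_fracs])
                bounds[-1] = n_codons
                exons = []
                start = cursor
                for k in range(len(cfg.exon_fracs)):
                    ex_seq = loc.seq[3 * bounds[k]:3 * bounds[k + 1]]
                    exons.append((cursor, cursor + len(ex_seq)))
                    parts.append(ex_seq)
                    cursor += len(ex_seq)
                    if k < len(cfg.exon_fracs) - 1:
                        intron = "".join(
                            NUCS[i] for i in rng.integers(0, 4, cfg.intron_bp))
                        parts.append(intron)
                        cursor += len(intron)
                ann.add(Gene(gene_id=gid, chrom=chrom, start=start,
                             end=cursor, strand="+", exons=exons,
                             cds=loc.seq, protein=translate(loc.seq)))
                ann.genes[gid].uid = loc.uid
                ann.genes[gid].enzyme = loc.enzyme
                ann.genes[gid].family_truth = loc.family
            else:
                parts.append(loc.seq)
                cursor += len(loc.seq)
        tail = "".join(NUCS[i] for i in rng.integers(0, 4, cfg.intergenic_bp))
        parts.append(tail)
        ann.chrom_seqs[chrom] = "".join(parts)
    return ann


def generate_dataset(
    tree: dendropy.Tree | str,
    config: SimConfig | None = None,
    pathway: PathwayModel | None = None,
) -> SimResult:
    """Simulate a clade and return annotations, sequences and ground truth."""
    config = config or SimConfig()
    pathway = pathway or load_default_pathway()
    if isinstance(tree, str):
        tree = read_tree(tree)
    else:
        label_nodes(tree)
    leaves = leaf_count = sum(1 for _ in tree.leaf_node_iter())
    if leaf_count < 3:
        raise SimError("tree must have at least 3 leaves")
    labels = {n.label for n in tree.preorder_node_iter()}
    for br in list(config.wgd_branches) + list(config.pathway_loss_branches) \
            + [b for b, _, _ in config.tandem_dup_targets] \
            + [b for b, _ in config.forced_translocations]:
        if br not in labels:
            raise SimError(f"branch id {br!r} not in tree")

    sim = _Sim(tree, config, pathway)
    sim.run()

    annotations = {}
    uid_to_gid: dict[str, dict[int, str]] = {}
    for leaf in sorted(sim.leaf_genomes):
        ann = _layout_leaf(leaf, sim.leaf_genomes[leaf], config, sim.rng)
        annotations[leaf] = ann
        uid_to_gid[leaf] = {
            g.uid: gid for gid, g in ann.genes.items()
        }

    # truth: per-leaf functional state per enzyme
    enzymes = pathway.enzymes
    cells = {}
    for leaf in sorted(sim.leaf_genomes):
        states = {}
        for enzyme in enzymes:
            kinds = [loc.kind for loci in sim.leaf_genomes[leaf].values()
                     for loc in loci if loc.family == enzyme]
            if "gene" in kinds:
                states[enzyme] = "intact"
            elif "remnant" in kinds:
                states[enzyme] = "pseudogene"
            else:
                states[enzyme] = "absent"
        cells[leaf] = states
    scenario = pd.DataFrame(cells).reindex(index=enzymes)

    pairs = []
    for leaf in sorted(sim.leaf_genomes):
        mapping = uid_to_gid[leaf]
        for u1, u2, age in sim.wgd_pair_reg:
            if u1 in mapping and u2 in mapping:
                pairs.append((leaf, mapping[u1], mapping[u2],
                              2.0 * config.r_s * age * 1e6))

    truth = TruthTables(
        true_scenario=scenario,
        true_loss_edges=set(config.pathway_loss_branches),
        true_wgd_pairs=pairs,
        event_log=sim.event_log,
        ancestral_uids=sim.ancestral_uids,
    )
    return SimResult(annotations, truth, tree, config,
                     sim.reference_proteins, pathway)


# ---------------------------------------------------------------------------
# On-disk dataset

def write_dataset(result: SimResult, out_dir: str | Path,
                  key_sites: dict[str, str] | None = None) -> Path:
    """Write the simulated clade as a standard-format workspace directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"species": {}, "tree": "tree.nwk",
                      "reference_proteins": "reference_proteins.faa"}
    for leaf, ann in sorted(result.annotations.items()):
        write_gff3(ann, out / f"{leaf}.gff3")
        write_fasta(ann.proteome(), out / f"{leaf}.protein.faa")
        write_fasta(ann.cds_store(), out / f"{leaf}.cds.fna")
        write_fasta(dict(sorted(ann.chrom_seqs.items())),
                    out / f"{leaf}.genomic.fna")
        manifest["species"][leaf] = {
            "gff": f"{leaf}.gff3",
            "protein": f"{leaf}.protein.faa",
            "cds": f"{leaf}.cds.fna",
            "genomic": f"{leaf}.genomic.fna",
        }
    from .phylo import write_newick
    (out / "tree.nwk").write_text(write_newick(result.tree))
    write_fasta(dict(sorted(result.reference_proteins.items())),
                out / "reference_proteins.faa")
    result.truth.true_scenario.to_csv(out / "truth_scenario.tsv", sep="\t")
    with open(out / "truth_loss_edges.tsv", "w") as fh:
        fh.write("branch\n")
        for br in sorted(result.truth.true_loss_edges):
            fh.write(br + "\n")
    with open(out / "truth_wgd_pairs.tsv", "w") as fh:
        fh.write("leaf\tgene_a\tgene_b\texpected_ks\n")
        for leaf, a, b, ks in result.truth.true_wgd_pairs:
            fh.write(f"{leaf}\t{a}\t{b}\t{ks:.5f}\n")
    with open(out / "event_log.tsv", "w") as fh:
        fh.write("branch\tevent\tuid\tfamily\textra\n")
        for branch, event, uid, fam, extra in result.truth.event_log:
            fh.write(f"{branch}\t{event}\t{uid}\t{fam}\t{extra}\n")
    cfg = asdict(result.config)
    cfg["wgd_branches"] = {
        br: {"retention": s.retention, "multiplier": s.multiplier}
        for br, s in result.config.wgd_branches.items()
    }
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    if key_sites:
        with open(out / "key_sites.tsv", "w") as fh:
            fh.write("leaf\tresidue\n")
            for leaf in sorted(key_sites):
                fh.write(f"{leaf}\t{key_sites[leaf]}\n")
        manifest["key_sites"] = "key_sites.tsv"
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest,
                                                      sort_keys=True))
    return out
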