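"""Workspace loading, validation, and end-to-end pipeline orchestration.

A workspace is a directory with a YAML manifest naming, per species, a GFF3
annotation plus protein/CDS/genomic FASTA files, a rooted Newick species
tree (branch lengths in My), reference pathway proteins, and optionally a
key-site residue column.  ``run_pipeline`` executes the analysis stages

    homology -> synteny -> scenarios -> ksdate -> infer

writing each stage's outputs into a run directory; stages are idempotent
and can resume from the serialized intermediates of earlier stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import yaml

from . import homology as hm
from . import ksdist, scenarios as sc, synteny as sy
from .gffio import (GenomeAnnotation, ValidationError, attach_sequences,
                    read_fasta, read_gff3)
from .pathway import PathwayModel, load_default_pathway, load_pathway
from .phylo import (SiteModel, leaf_labels, marginal_ancestral,
                    pathway_loss_report, read_tree, starred_newick)

log = logging.getLogger("tropanevo")

STAGES = ("homology", "synteny", "scenarios", "ksdate", "infer")
_DEPS = {
    "homology": (),
    "synteny": ("homology",),
    "scenarios": ("synteny",),
    "ksdate": ("synteny",),
    "infer": ("scenarios",),
}


@dataclass
class PipelineConfig:
    references: list[str] = field(default_factory=list)
    depth_pairs: list[tuple[str, str]] = field(default_factory=list)  # (target, query)
    ks_species: list[str] = field(default_factory=list)
    synonymous_rate: float = 5.6e-9       # substitutions/syn site/year
    branch_scale: float = 2e-3            # substitutions/site per My (ASR)
    depth_c_score: float = 0.9
    copy_cap: int = 20
    seed: int = 0
    align: hm.AlignParams = field(default_factory=lambda: hm.AlignParams(
        prefilter="edlib"))
    scenario: sc.ScenarioConfig = field(default_factory=sc.ScenarioConfig)
    min_block_size: int = 5
    max_gap: int = 25


@dataclass
class Workspace:
    root: Path
    species: dict[str, GenomeAnnotation]
    tree: dendropy.Tree
    pathway: PathwayModel
    reference_proteins: dict[str, str]
    key_sites: dict[str, str] | None = None
    config: PipelineConfig = field(default_factory=PipelineConfig)


def load_workspace(manifest: str | Path,
                   config: PipelineConfig | None = None) -> Workspace:
    """Load and cross-validate a workspace from its manifest."""
    manifest = Path(manifest)
    root = manifest.parent
    doc = yaml.safe_load(manifest.read_text())
    errors: list[str] = []

    tree = read_tree((root / doc["tree"]).read_text())
    leaves = set(leaf_labels(tree))

    pathway = (load_pathway(root / doc["pathway"]) if "pathway" in doc
               else load_default_pathway())

    species: dict[str, GenomeAnnotation] = {}
    seen_ids: dict[str, str] = {}
    for name in sorted(doc["species"]):
        files = doc["species"][name]
        if name not in leaves:
            errors.append(f"species {name!r} in manifest but not in tree")
        try:
            ann = read_gff3(root / files["gff"], species=name)
            attach_sequences(
                ann,
                proteins=read_fasta(root / files["protein"]),
                cds=read_fasta(root / files["cds"]),
                genomic=read_fasta(root / files["genomic"])
                if "genomic" in files else None,
            )
        except ValidationError as exc:
            errors.append(f"{name}: {exc}")
            continue
        for gid in ann.genes:
            if gid in seen_ids:
                errors.append(f"gene id {gid!r} in both {seen_ids[gid]} "
                              f"and {name}")
            seen_ids[gid] = name
        species[name] = ann

    refs = read_fasta(root / doc["reference_proteins"]) \
        if "reference_proteins" in doc else {}
    key_sites = None
    if "key_sites" in doc:
        key_sites = {}
        for ln in (root / doc["key_sites"]).read_text().splitlines()[1:]:
            leaf, residue = ln.split("\t")
            key_sites[leaf] = residue

    if errors:
        raise ValidationError("; ".join(errors))

    cfg = config or PipelineConfig()
    if not cfg.references:
        cfg.references = list(doc.get("references", [])) or sorted(species)[:1]
    return Workspace(root=root, species=species, tree=tree, pathway=pathway,
                     reference_proteins=refs, key_sites=key_sites, config=cfg)


# ---------------------------------------------------------------------------
# Stage implementations (each reads its inputs from memory or the run dir)

class PipelineRun:
    def __init__(self, workspace: Workspace, out_dir: str | Path):
        self.ws = workspace
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._cache: dict[str, object] = {}

    # -- intermediates ------------------------------------------------------
    def _hits_path(self) -> Path:
        return self.out / "hits.tsv"

    def hits(self) -> list[hm.HomologyHit]:
        if "hits" not in self._cache:
            path = self._hits_path()
            if not path.exists():
                raise FileNotFoundError(
                    "homology stage output missing; run stage 'homology' first")
            rows = path.read_text().splitlines()[1:]
            out = []
            for ln in rows:
                f = ln.split("\t")
                out.append(hm.HomologyHit(
                    query_gene=f[0], subject_gene=f[1],
                    identity_pct=float(f[2]), aln_len=int(f[3]),
                    mismatches=int(f[4]), gap_opens=int(f[5]),
                    qstart=int(f[6]) - 1, qend=int(f[7]),
                    sstart=int(f[8]) - 1, send=int(f[9]),
                    e_value=float(f[10]), bit_score=float(f[11]),
                    # raw score/coverage are not part of the 12-column
                    # format; reloaded hits only feed bit-score filters
                    raw_score=0.0, query_coverage=0.0,
                ))
            self._cache["hits"] = out
        return self._cache["hits"]

    def families(self) -> list[hm.GeneFamily]:
        if "families" not in self._cache:
            path = self.out / "families.tsv"
            if not path.exists():
                raise FileNotFoundError(
                    "homology stage output missing; run stage 'homology' first")
            fams: dict[str, set[str]] = {}
            for ln in path.read_text().splitlines()[1:]:
                fam, gid = ln.split("\t")
                fams.setdefault(fam, set()).add(gid)
            self._cache["families"] = [
                hm.GeneFamily(f, frozenset(m)) for f, m in sorted(fams.items())
            ]
        return self._cache["families"]

    def pathway_candidates(self) -> dict[tuple[str, str], list[str]]:
        if "candidates" not in self._cache:
            path = self.out / "pathway_genes.tsv"
            if not path.exists():
                raise FileNotFoundError(
                    "homology stage output missing; run stage 'homology' first")
            out: dict[tuple[str, str], list[str]] = {}
            for ln in path.read_text().splitlines()[1:]:
                sp, enzyme, gids = (ln.split("\t") + [""])[:3]
                out[(sp, enzyme)] = gids.split(",") if gids else []
            self._cache["candidates"] = out
        return self._cache["candidates"]

    def blocks(self, sp_a: str, sp_b: str) -> list[sy.SyntenyBlock]:
        key = f"blocks:{sp_a}:{sp_b}"
        if key not in self._cache:
            path = self.out / f"blocks.{sp_a}--{sp_b}.txt"
            if not path.exists():
                raise FileNotFoundError(
                    f"synteny output for {sp_a} vs {sp_b} missing; run stage "
                    "'synteny' first")
            self._cache[key] = sy.read_collinearity(path)
        return self._cache[key]

    def matrix(self) -> sc.PresenceMatrix:
        path = self.out / "presence_matrix.tsv"
        if not path.exists():
            raise FileNotFoundError(
                "scenarios stage output missing; run stage 'scenarios' first")
        return sc.PresenceMatrix.from_tsv(path)

    # -- stages -------------------------------------------------------------
    def stage_homology(self) -> None:
        ws = self.ws
        proteomes = {sp: ann.proteome() for sp, ann in sorted(ws.species.items())}
        hits = hm.build_hit_table(proteomes, ws.config.align)
        hm.write_hit_table(hits, self._hits_path())
        universe = {g for seqs in proteomes.values() for g in seqs}
        fams = hm.cluster_families(hits, universe=universe)
        with open(self.out / "families.tsv", "w") as fh:
            fh.write("family\tgene\n")
            for fam in fams:
                for gid in sorted(fam.member_gene_ids):
                    fh.write(f"{fam.family_id}\t{gid}\n")
        cands = hm.identify_pathway_genes(proteomes, ws.reference_proteins,
                                          ws.config.align)
        with open(self.out / "pathway_genes.tsv", "w") as fh:
            fh.write("species\tenzyme\tgenes\n")
            for (sp, enzyme), gids in sorted(cands.items()):
                fh.write(f"{sp}\t{enzyme}\t{','.join(gids)}\n")
        self._cache.update(hits=hits, families=fams, candidates=cands)

    def _pair_list(self) -> list[tuple[str, str]]:
        cfg = self.ws.config
        pairs = []
        for ref in cfg.references:
            for sp in sorted(self.ws.species):
                if sp != ref:
                    pairs.append((ref, sp))
        for target, query in cfg.depth_pairs:
            pairs.append((query, target))
        for sp in cfg.ks_species or cfg.references[:1]:
            pairs.append((sp, sp))
        seen = set()
        return [p for p in pairs if not (p in seen or seen.add(p))]

    def stage_synteny(self) -> None:
        ws = self.ws
        fams = self.families()
        hits = self.hits()
        cfg = ws.config
        depth_rev = {(q, t) for t, q in cfg.depth_pairs}
        for sp_a, sp_b in self._pair_list():
            c_score = cfg.depth_c_score if (sp_a, sp_b) in depth_rev else None
            anchors = sy.build_anchors(
                ws.species[sp_a], ws.species[sp_b], fams,
                copy_cap=cfg.copy_cap, c_score=c_score,
                hits=hits if c_score else None)
            if sp_a == sp_b:
                anchors = [a for a in anchors
                           if (a.chrom_a, a.rank_a) < (a.chrom_b, a.rank_b)]
            blocks = sy.chain_anchors(
                anchors, min_block_size=cfg.min_block_size,
                max_gap=cfg.max_gap, species_a=sp_a, species_b=sp_b)
            sy.write_collinearity(blocks,
                                  self.out / f"blocks.{sp_a}--{sp_b}.txt")
            sy.export_dotplot(blocks, self.out / f"dotplot.{sp_a}--{sp_b}.tsv")
            self._cache[f"blocks:{sp_a}:{sp_b}"] = blocks
        with open(self.out / "depth_ratios.tsv", "w") as fh:
            fh.write("target\tquery\tmodal_ratio\n")
            for target, query in cfg.depth_pairs:
                profile = sy.depth_ratio(self.blocks(query, target),
                                         ws.species[target], ws.species[query])
                fh.write(f"{target}\t{query}\t{profile.modal_ratio}\n")

    def stage_scenarios(self) -> None:
        ws = self.ws
        cfg = ws.config
        fam_of = hm.family_index(self.families())
        cands = self.pathway_candidates()
        species_order = [l for l in leaf_labels(ws.tree) if l in ws.species]
        all_calls: list[sc.ScenarioCall] = []
        calls_by_ref: dict[str, dict[tuple[str, str], sc.ScenarioCall]] = {}
        for ref in cfg.references:
            per_ref: dict[tuple[str, str], sc.ScenarioCall] = {}
            for enzyme in ws.pathway.enzymes:
                ref_genes = cands.get((ref, enzyme), [])
                if not ref_genes:
                    log.warning("reference %s lacks an identified %s gene",
                                ref, enzyme)
                    continue
                ref_gene = ref_genes[0]
                for sp in species_order:
                    blocks = [] if sp == ref else self.blocks(ref, sp)
                    c = sc.classify_gene(
                        ref_gene, enzyme, ws.species[ref], ws.species[sp],
                        blocks, fam_of, cfg.scenario, cfg.align)
                    per_ref[(enzyme, sp)] = c
                    all_calls.append(c)
            calls_by_ref[ref] = per_ref
        matrix = sc.build_matrix(calls_by_ref, ws.pathway.enzymes,
                                 species_order)
        matrix.to_tsv(self.out / "presence_matrix.tsv")
        sc.write_calls_jsonl(all_calls, self.out / "scenario_calls.jsonl")

    def stage_ksdate(self) -> None:
        ws = self.ws
        cfg = ws.config
        estimates = []
        block_medians = []
        for sp in cfg.ks_species or cfg.references[:1]:
            ann = ws.species[sp]
            cds = ann.cds_store()
            prot = ann.proteome()
            for b in self.blocks(sp, sp):
                vals = []
                for a in b.anchors:
                    ca, cb = ksdist.codon_align(prot[a.gene_a], prot[a.gene_b],
                                                cds[a.gene_a], cds[a.gene_b])
                    est = ksdist.estimate_ks(ca, cb, a.gene_a, a.gene_b)
                    estimates.append(est)
                    if est.valid:
                        vals.append(est.Ks)
                if vals:
                    import numpy as np
                    block_medians.append(float(np.median(vals)))
        ksdist.write_ks_table(estimates, self.out / "ks_pairs.tsv")
        peaks = ksdist.detect_peaks([e.Ks for e in estimates if e.valid])
        with open(self.out / "ks_peaks.tsv", "w") as fh:
            fh.write("mode\tcomponent_sd\tweight\tT_mya\tci_low\tci_high\n")
            for p in peaks:
                ev = ksdist.date_wgd(p.mode, p.component_sd,
                                     cfg.synonymous_rate)
                fh.write(f"{p.mode:.4f}\t{p.component_sd:.4f}\t{p.weight:.3f}"
                         f"\t{ev.T:.2f}\t{ev.ci95[0]:.2f}\t{ev.ci95[1]:.2f}\n")

    def stage_infer(self) -> None:
        ws = self.ws
        matrix = self.matrix()
        report = pathway_loss_report(matrix.states, ws.tree, ws.pathway)
        with open(self.out / "producer_traits.tsv", "w") as fh:
            fh.write("species\tproducer\n")
            for sp in sorted(report.producer_traits):
                fh.write(f"{sp}\t{report.producer_traits[sp]}\n")
        with open(self.out / "loss_edges.tsv", "w") as fh:
            fh.write("level\tname\tparent\tchild\n")
            for parent, child in sorted(report.phenotype.loss_edges):
                fh.write(f"phenotype\tHS-pathway\t{parent}\t{child}\n")
            for enzyme, res in report.per_gene.items():
                for parent, child in sorted(res.loss_edges):
                    fh.write(f"gene\t{enzyme}\t{parent}\t{child}\n")
            for enzyme, res in report.locus_per_gene.items():
                for parent, child in sorted(res.loss_edges):
                    fh.write(f"locus\t{enzyme}\t{parent}\t{child}\n")
        (self.out / "starred_tree.nwk").write_text(
            starred_newick(ws.tree, report.phenotype.loss_edges) + "\n")
        summary = {
            "producer_count": int(sum(report.producer_traits.values())),
            "phenotype_loss_count": report.phenotype.loss_count,
            "phenotype_loss_branches": sorted(
                child for _, child in report.phenotype.loss_edges),
        }
        if ws.key_sites:
            post = marginal_ancestral(
                ws.tree, ws.key_sites,
                SiteModel(branch_scale=ws.config.branch_scale))
            with open(self.out / "key_site_posteriors.tsv", "w") as fh:
                from .phylo import AA_ORDER
                fh.write("node\t" + "\t".join(AA_ORDER) + "\n")
                for node, p in sorted(post.posteriors.items()):
                    fh.write(node + "\t"
                             + "\t".join(f"{x:.6f}" for x in p) + "\n")
            root = ws.tree.seed_node.label
            summary["root_map_residue"] = post.map_state(root)
            summary["root_map_probability"] = float(
                post.posteriors[root].max())
        (self.out / "report.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")

    # -- driver -------------------------------------------------------------
    def run(self, stages: list[str] | None = None) -> None:
        stages = list(stages or STAGES)
        for s in stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        done = set()
        for s in stages:
            for dep in _DEPS[s]:
                if dep in done or dep in stages[:stages.index(s)]:
                    continue
                # accept pre-existing intermediates from an earlier run
                marker = {"homology": self._hits_path(),
                          "synteny": self.out / "depth_ratios.tsv",
                          "scenarios": self.out / "presence_matrix.tsv",
                          "ksdate": self.out / "ks_peaks.tsv",
                          "infer": self.out / "report.json"}[dep]
                if not marker.exists():
                    raise RuntimeError(
                        f"stage {s!r} requires stage {dep!r}; run it first")
            t0 = time.time()
            log.info("stage %s: start (seed=%s)", s, self.ws.config.seed)
            getattr(self, f"stage_{s}")()
            done.add(s)
            log.info("stage %s: done in %.1fs", s, time.time() - t0)
        self._write_runlog(stages)

    def _write_runlog(self, stages) -> None:
        cfg = self.ws.config
        params = {
            "stages": list(stages),
            "seed": cfg.seed,
            "references": cfg.references,
            "evalue_max": cfg.align.evalue_max,
            "min_block_size": cfg.min_block_size,
            "max_gap": cfg.max_gap,
            "window_genes": cfg.scenario.window_genes,
            "min_flank_anchors": cfg.scenario.min_flank_anchors,
            "synonymous_rate": cfg.synonymous_rate,
        }
        blob = json.dumps(params, sort_keys=True)
        params["parameter_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
        (self.out / "run_log.json").write_text(
            json.dumps(params, indent=2, sort_keys=True) + "\n")


def run_pipeline(workspace: Workspace, out_dir: str | Path,
                 stages: list[str] | None = None) -> PipelineRun:
    run = PipelineRun(workspace, out_dir)
    run.run(stages)
    return run


def bundle_hash(out_dir: str | Path) -> str:
    """SHA-256 over all report files (sorted) - determinism check."""
    h = hashlib.sha256()
    for path in sorted(Path(out_dir).glob("**/*")):
        if path.is_file() and path.name != "run_log.json":
            h.update(path.name.encode())
            h.update(path.read_bytes())
    return h.hexdigest()
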