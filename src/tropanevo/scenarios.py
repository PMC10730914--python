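"""Microsynteny scenario classification of pathway genes across genomes.

For each pathway gene in a reference genome and each query genome, the
cascade asks whether collinearity supports presence or absence:

* scenario 1 - a collinear block anchored by enough of the reference gene's
  flanking window contains a family ortholog: synteny supports presence.
* scenario 2 - such a region exists but holds no ortholog: synteny supports
  absence; a translated (six-frame) search of the region decides whether a
  disabled pseudogene remnant is still there, or the locus is gone.
* scenario 3 - no collinear region is found at all (synteny erosion, e.g.
  after translocation): fall back to a genome-wide family search (an intact
  but synteny-unsupported ortholog), then to a genome-wide translated
  search, else call the gene absent.

Calls from several reference genomes are combined into a presence matrix
with precedence intact > pseudogene > absent, synteny-supported presence
being the strongest evidence class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .gffio import GenomeAnnotation
from .homology import AlignParams, local_align
from .synteny import SyntenyBlock

STATE_SYMBOL = {"intact": "P", "pseudogene": "Ψ", "absent": "A"}
_PRECEDENCE = {"intact": 0, "pseudogene": 1, "absent": 2}


@dataclass
class ScenarioConfig:
    window_bp: int = 100_000
    window_genes: int = 20
    unit: str = "genes"               # "genes" | "bp"
    min_flank_anchors: int = 3
    both_sides: bool = False
    pseudo_identity_min: float = 40.0
    pseudo_cov_min: float = 0.3
    pseudo_cov_intact: float = 0.8
    scan_pad_bp: int = 4000
    min_segment_aa: int = 10
    min_segment_score: float = 30.0
    # per-segment E-value over the whole six-frame search space; keeps the
    # colinear merge from accumulating spurious short hits in large windows
    segment_evalue_max: float = 1e-3
    max_regions_scanned: int = 4

    def __post_init__(self):
        if self.window_bp <= 0 or self.window_genes <= 0:
            raise ValueError("window must be positive")
        if self.min_flank_anchors < 1:
            raise ValueError("min_flank_anchors must be >= 1")
        if self.unit not in ("genes", "bp"):
            raise ValueError(f"unknown window unit {self.unit!r}")


@dataclass
class PseudogeneEvidence:
    chrom: str
    start: int
    end: int
    identity_pct: float = 0.0
    coverage: float = 0.0
    premature_stop: bool = False
    frameshift_breaks: int = 0


@dataclass
class ScenarioCall:
    reference_species: str
    enzyme: str
    query_species: str
    scenario: int
    locus_state: str
    functional_state: str
    block_id: str | None = None
    query_gene: str | None = None
    synteny_unsupported: bool = False
    evidence: PseudogeneEvidence | None = None


# ---------------------------------------------------------------------------

def syntenic_window(gene_id: str, genome: GenomeAnnotation,
                    config: ScenarioConfig | None = None) -> list[str]:
    """Flanking genes within the window on each side of ``gene_id``.

    The window is +-window_genes gene ranks, or +-window_bp from the gene's
    span, depending on ``config.unit``; the focal gene is excluded and order
    is preserved.  Genes at chromosome ends get one-sided windows.
    """
    config = config or ScenarioConfig()
    chrom, rank = genome.rank_of(gene_id)
    order = genome.gene_order(chrom)
    if config.unit == "genes":
        lo = max(0, rank - config.window_genes)
        hi = min(len(order), rank + config.window_genes + 1)
        return [g for g in order[lo:hi] if g != gene_id]
    g = genome.genes[gene_id]
    lo_bp, hi_bp = g.start - config.window_bp, g.end + config.window_bp
    return [
        gid for gid in order
        if gid != gene_id
        and genome.genes[gid].end > lo_bp and genome.genes[gid].start < hi_bp
    ]


def _translate_frames(window: str) -> list[tuple[int, int, str]]:
    """Six-frame translations as (strand, frame_offset, aa_string)."""
    frames = []
    rc = str(Seq(window).reverse_complement())
    for strand, seq in ((1, window), (-1, rc)):
        for off in range(3):
            sub = seq[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            if sub:
                frames.append((strand, off, str(Seq(sub).translate())))
    return frames


def pseudogene_scan(
    reference_protein: str,
    window_nt: str,
    config: ScenarioConfig | None = None,
    params: AlignParams | None = None,
    chrom: str = "window",
    start: int = 0,
) -> tuple[PseudogeneEvidence, str]:
    """Translated search of a nucleotide window for a disabled gene remnant.

    All six reading frames are translated and split at stop codons; the
    reference protein is locally aligned to every segment, and the best
    non-overlapping hits are merged colinearly (in protein coordinates)
    across frames.  The locus is a pseudogene when the merged alignment is
    recognisable (identity >= pseudo_identity_min, coverage >=
    pseudo_cov_min) but disabled (coverage < pseudo_cov_intact, a premature
    stop, or a frameshift); with no qualifying alignment it is absent.  An
    intact state is never returned: annotated intact orthologs are the
    cascade's earlier scenarios.
    """
    config = config or ScenarioConfig()
    params = params or AlignParams()
    evidence = PseudogeneEvidence(chrom, start, start + len(window_nt))
    if len(window_nt) < 3:
        warnings.warn("pseudogene scan window shorter than one codon")
        return evidence, "absent"

    plen = len(reference_protein)
    frames = _translate_frames(window_nt)
    search_space = plen * sum(len(aa) for _, _, aa in frames)
    hits = []
    for frame_i, (strand, off, aa) in enumerate(frames):
        seg_start = 0
        for seg in aa.split("*"):
            if len(seg) >= config.min_segment_aa:
                h = local_align(reference_protein, seg, params)
                bit = (params.ka_lambda * h.raw_score
                       - math.log(params.ka_K)) / math.log(2.0)
                evalue = search_space * 2.0 ** (-bit)
                if (h.raw_score >= config.min_segment_score
                        and evalue <= config.segment_evalue_max):
                    ends_at_stop = seg_start + len(seg) < len(aa)
                    hits.append((h, frame_i, ends_at_stop, len(seg)))
            seg_start += len(seg) + 1

    hits.sort(key=lambda t: (-t[0].raw_score, t[1]))
    accepted: list[tuple] = []
    covered: set[int] = set()
    for h, frame_i, ends_at_stop, seg_len in hits:
        span = set(range(h.qstart, h.qend))
        if len(span & covered) > max(5, len(span) // 10):
            continue
        accepted.append((h, frame_i, ends_at_stop, seg_len))
        covered |= span

    if accepted:
        total_cols = sum(h.aln_len for h, *_ in accepted)
        ident = sum(h.identity_pct * h.aln_len for h, *_ in accepted)
        evidence.identity_pct = ident / total_cols if total_cols else 0.0
        evidence.coverage = len(covered) / plen
        evidence.frameshift_breaks = len(
            {frame_i for _, frame_i, _, _ in accepted}) - 1
        for h, frame_i, ends_at_stop, seg_len in accepted:
            # the aligned remnant runs into a stop before the protein ends
            if ends_at_stop and h.qend < 0.95 * plen and h.send >= seg_len - 2:
                evidence.premature_stop = True

    qualifying = (evidence.identity_pct >= config.pseudo_identity_min
                  and evidence.coverage >= config.pseudo_cov_min)
    disabled = (evidence.coverage < config.pseudo_cov_intact
                or evidence.premature_stop
                or evidence.frameshift_breaks >= 1)
    if qualifying and disabled:
        return evidence, "pseudogene"
    return evidence, "absent"


# ---------------------------------------------------------------------------

@dataclass
class _Region:
    block: SyntenyBlock
    chrom: str
    rank_lo: int
    rank_hi: int
    n_window_anchors: int
    window_anchors: list


def _find_regions(ref_gene: str, window: list[str], blocks: list[SyntenyBlock],
                  config: ScenarioConfig, ref_genome: GenomeAnnotation,
                  query_genome: GenomeAnnotation) -> list[_Region]:
    window_set = set(window)
    _, ref_rank = ref_genome.rank_of(ref_gene)
    regions = []
    for b in blocks:
        wa = [a for a in b.anchors if a.gene_a in window_set]
        if len(wa) < config.min_flank_anchors:
            continue
        if config.both_sides:
            up = sum(1 for a in wa if a.rank_a < ref_rank)
            down = sum(1 for a in wa if a.rank_a > ref_rank)
            if min(up, down) < config.min_flank_anchors:
                continue
        ranks_b = [a.rank_b for a in wa]
        pad = config.window_genes
        n_on_chrom = len(query_genome.gene_order(b.chrom_b))
        regions.append(_Region(
            block=b,
            chrom=b.chrom_b,
            rank_lo=max(0, min(ranks_b) - pad),
            rank_hi=min(n_on_chrom - 1, max(ranks_b) + pad),
            n_window_anchors=len(wa),
            window_anchors=wa,
        ))
    regions.sort(key=lambda r: (-r.n_window_anchors, r.block.block_id))
    return regions


def _region_scan_span(region: _Region, ref_rank: int,
                      query_genome: GenomeAnnotation,
                      config: ScenarioConfig) -> tuple[int, int]:
    """Base-pair span to scan: between the anchors bracketing the target."""
    below = [a for a in region.window_anchors if a.rank_a < ref_rank]
    above = [a for a in region.window_anchors if a.rank_a > ref_rank]
    genes = []
    if below:
        genes.append(max(below, key=lambda a: a.rank_a).gene_b)
    if above:
        genes.append(min(above, key=lambda a: a.rank_a).gene_b)
    if not genes:
        genes = [region.window_anchors[0].gene_b,
                 region.window_anchors[-1].gene_b]
    coords = [query_genome.genes[g] for g in genes]
    lo = min(g.start for g in coords) - config.scan_pad_bp
    hi = max(g.end for g in coords) + config.scan_pad_bp
    return max(0, lo), hi


def classify_gene(
    ref_gene: str,
    enzyme: str,
    ref_genome: GenomeAnnotation,
    query_genome: GenomeAnnotation,
    blocks: list[SyntenyBlock],
    fam_of: dict[str, str],
    config: ScenarioConfig | None = None,
    params: AlignParams | None = None,
) -> ScenarioCall:
    """One cascade classification of ``ref_gene`` in the query genome.

    ``blocks`` must carry the reference genome on side A and the query on
    side B; ``fam_of`` maps gene ids to family ids.
    """
    config = config or ScenarioConfig()
    params = params or AlignParams()
    ref_sp, query_sp = ref_genome.species, query_genome.species
    if not query_genome.genes:
        raise ValueError(f"query species {query_sp!r} has no annotation")

    def call(**kw):
        return ScenarioCall(reference_species=ref_sp, enzyme=enzyme,
                            query_species=query_sp, **kw)

    if query_sp == ref_sp:
        return call(scenario=1, locus_state="intact",
                    functional_state="intact", query_gene=ref_gene)

    fam = fam_of.get(ref_gene)
    orthologs = sorted(
        gid for gid, f in fam_of.items()
        if f == fam and gid in query_genome.genes
    ) if fam else []

    window = syntenic_window(ref_gene, ref_genome, config)
    _, ref_rank = ref_genome.rank_of(ref_gene)
    regions = _find_regions(ref_gene, window, blocks, config, ref_genome,
                            query_genome)

    # scenario 1: an ortholog inside any collinear region
    for region in regions:
        for gid in orthologs:
            chrom, rank = query_genome.rank_of(gid)
            if chrom == region.chrom and region.rank_lo <= rank <= region.rank_hi:
                return call(scenario=1, locus_state="intact",
                            functional_state="intact",
                            block_id=region.block.block_id, query_gene=gid)

    # scenario 2: region exists, ortholog does not -> translated search
    if regions:
        best_ev = None
        for region in regions[:config.max_regions_scanned]:
            lo, hi = _region_scan_span(region, ref_rank, query_genome, config)
            seq = query_genome.chrom_seqs.get(region.chrom, "")[lo:hi]
            ev, state = pseudogene_scan(
                ref_genome.genes[ref_gene].protein, seq, config, params,
                chrom=region.chrom, start=lo)
            if state == "pseudogene":
                return call(scenario=2, locus_state="pseudogene",
                            functional_state="pseudogene",
                            block_id=region.block.block_id, evidence=ev)
            if best_ev is None or ev.coverage > best_ev.coverage:
                best_ev = ev
        return call(scenario=2, locus_state="absent",
                    functional_state="absent",
                    block_id=regions[0].block.block_id, evidence=best_ev)

    # scenario 3: no collinear region at all
    if orthologs:
        return call(scenario=3, locus_state="intact",
                    functional_state="intact", query_gene=orthologs[0],
                    synteny_unsupported=True)
    best = None
    for chrom in query_genome.chromosomes:
        seq = query_genome.chrom_seqs.get(chrom, "")
        if not seq:
            continue
        ev, state = pseudogene_scan(ref_genome.genes[ref_gene].protein, seq,
                                    config, params, chrom=chrom)
        if state == "pseudogene" and (best is None or
                                      ev.coverage > best[0].coverage):
            best = (ev, state)
    if best:
        return call(scenario=3, locus_state="pseudogene",
                    functional_state="pseudogene", evidence=best[0])
    return call(scenario=3, locus_state="absent", functional_state="absent")


# ---------------------------------------------------------------------------

@dataclass
class PresenceMatrix:
    states: pd.DataFrame                  # enzymes x species, state words
    scenarios: pd.DataFrame               # enzymes x species, winning scenario
    calls: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        out = self.states.copy()
        for enzyme in out.index:
            for sp in out.columns:
                out.loc[enzyme, sp] = (
                    STATE_SYMBOL[self.states.loc[enzyme, sp]]
                    + str(self.scenarios.loc[enzyme, sp])
                )
        out.to_csv(path, sep="\t")

    @staticmethod
    def from_tsv(path: str | Path) -> "PresenceMatrix":
        raw = pd.read_csv(path, sep="\t", index_col=0)
        sym_to_state = {v: k for k, v in STATE_SYMBOL.items()}
        states = raw.map(lambda c: sym_to_state[c[:-1]])
        scen = raw.map(lambda c: int(c[-1]))
        return PresenceMatrix(states, scen)


def build_matrix(
    calls_by_ref: dict[str, dict[tuple[str, str], ScenarioCall]],
    enzymes: list[str],
    species_order: list[str],
) -> PresenceMatrix:
    """Consensus presence matrix over the reference genomes.

    Cell precedence is intact > pseudogene > absent; among calls with the
    winning state the lowest scenario number (strongest synteny support) is
    reported.  Conflicting intact calls naming different query loci keep the
    strongest-supported one and log the conflict.
    """
    states = pd.DataFrame("absent", index=enzymes, columns=species_order,
                          dtype=object)
    scen = pd.DataFrame(3, index=enzymes, columns=species_order, dtype=int)
    kept: dict[tuple[str, str], ScenarioCall] = {}
    for enzyme in enzymes:
        for sp in species_order:
            calls = [
                calls_by_ref[ref][(enzyme, sp)]
                for ref in sorted(calls_by_ref)
                if (enzyme, sp) in calls_by_ref[ref]
            ]
            if not calls:
                warnings.warn(f"no scenario call for ({enzyme}, {sp})")
                continue
            calls.sort(key=lambda c: (_PRECEDENCE[c.functional_state],
                                      c.scenario, c.reference_species))
            top = calls[0]
            winners = [c for c in calls
                       if c.functional_state == top.functional_state]
            loci = {c.query_gene for c in winners
                    if c.query_gene and c.functional_state == "intact"}
            if len(loci) > 1:
                warnings.warn(
                    f"conflicting intact loci for ({enzyme}, {sp}): "
                    f"{sorted(loci)}; keeping {top.query_gene}")
            states.loc[enzyme, sp] = top.functional_state
            scen.loc[enzyme, sp] = top.scenario
            kept[(enzyme, sp)] = top
    return PresenceMatrix(states, scen, kept)


def write_calls_jsonl(calls: list[ScenarioCall], path: str | Path) -> None:
    import json
    from dataclasses import asdict
    with open(path, "w") as fh:
        for c in calls:
            fh.write(json.dumps(asdict(c)) + "\n")
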