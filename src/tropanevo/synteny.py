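"""Collinear (synteny) block detection by anchor chaining, plus depth ratios.

Anchors are cross-genome gene pairs from the same homology family, addressed
by gene-order rank along their chromosomes.  Per chromosome pair and
orientation, maximum-score chains are found by dynamic programming over
anchors sorted by rank (MCScanX-style); chains are extracted greedily
best-first, anchors of an extracted chain are removed, and chains shorter
than ``min_block_size`` are discarded.  Rank gaps, not base pairs, drive the
gap constraint, which makes chaining robust to compressed intergenic scale.

The block-size threshold is >= 5 anchors: the tool settings the analysis
standardizes on ("-s 5") admit five-anchor blocks even where prose says
"more than five collinear genes".
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .gffio import GenomeAnnotation
from .homology import GeneFamily, HomologyHit


@dataclass(frozen=True)
class Anchor:
    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int
    family_id: str


@dataclass
class SyntenyBlock:
    block_id: str
    species_a: str
    species_b: str
    chrom_a: str
    chrom_b: str
    orientation: str                  # "same" | "inverted"
    anchors: list[Anchor]
    score: float

    @property
    def span_a(self) -> tuple[int, int]:
        ranks = [a.rank_a for a in self.anchors]
        return min(ranks), max(ranks)

    @property
    def span_b(self) -> tuple[int, int]:
        ranks = [a.rank_b for a in self.anchors]
        return min(ranks), max(ranks)


def build_anchors(
    genome_a: GenomeAnnotation,
    genome_b: GenomeAnnotation,
    families: list[GeneFamily],
    copy_cap: int = 20,
    c_score: float | None = None,
    hits: list[HomologyHit] | None = None,
) -> list[Anchor]:
    """One anchor per cross-genome gene pair sharing a family.

    Families with more than ``copy_cap`` members in either genome contribute
    no anchors (repeat suppression).  With ``c_score`` set, an anchor is kept
    only if its pair's bit score is at least ``c_score`` times the best bit
    score either gene has against the other genome (ortholog-only filtering
    for depth profiling); this requires ``hits``.
    """
    ids_a, ids_b = set(genome_a.genes), set(genome_b.genes)
    for gid in list(ids_a):
        if genome_a.genes[gid].start is None:
            raise ValueError(f"gene {gid} missing coordinates")

    bit: dict[tuple[str, str], float] = {}
    best_a: dict[str, float] = {}
    best_b: dict[str, float] = {}
    if c_score is not None:
        if hits is None:
            raise ValueError("c_score filtering requires the hit table")
        for h in hits:
            q, s = h.query_gene, h.subject_gene
            for x, y in ((q, s), (s, q)):
                if x in ids_a and y in ids_b:
                    bit[(x, y)] = max(bit.get((x, y), 0.0), h.bit_score)
                    best_a[x] = max(best_a.get(x, 0.0), h.bit_score)
                    best_b[y] = max(best_b.get(y, 0.0), h.bit_score)

    anchors = []
    for fam in sorted(families, key=lambda f: f.family_id):
        in_a = sorted(fam.member_gene_ids & ids_a)
        in_b = sorted(fam.member_gene_ids & ids_b)
        if not in_a or not in_b:
            continue
        if len(in_a) > copy_cap or len(in_b) > copy_cap:
            continue
        for ga in in_a:
            for gb in in_b:
                if ga == gb:
                    continue
                if c_score is not None:
                    b = bit.get((ga, gb), 0.0)
                    if b <= 0.0:
                        continue
                    if b < c_score * max(best_a.get(ga, 0.0), 1e-9) or \
                       b < c_score * max(best_b.get(gb, 0.0), 1e-9):
                        continue
                ca, ra = genome_a.rank_of(ga)
                cb, rb = genome_b.rank_of(gb)
                anchors.append(Anchor(ga, gb, ca, cb, ra, rb, fam.family_id))
    anchors.sort(key=lambda a: (a.chrom_a, a.chrom_b, a.rank_a, a.rank_b))
    return anchors


def _best_chain(
    anchors: list[Anchor],
    orientation: str,
    max_gap: int,
    gap_penalty: float,
    match_score: float,
    min_len: int,
) -> tuple[list[int], float]:
    """Highest-scoring chain of >= min_len anchors for one orientation.

    Anchors must be pre-sorted by (rank_a, rank_b).  A transition i->j needs
    strictly increasing rank_a, strictly increasing (same) or strictly
    decreasing (inverted) rank_b, and both rank gaps <= max_gap.  Chain score
    is len*match_score - gap_penalty * sum((da-1)+(db-1)); the DP carries the
    chain length (capped at min_len) as a second dimension so the optimum is
    taken over admissible chains only.  Ties prefer the chain ending at the
    smallest (rank_a, rank_b).
    """
    n = len(anchors)
    if n == 0 or min_len > n:
        return [], 0.0
    L = max(1, min_len)
    NEG = float("-inf")
    # score[j][k]: best chain ending at j whose length, capped at L, is k+1
    score = [[NEG] * L for _ in range(n)]
    prev: list[list[tuple[int, int] | None]] = [[None] * L for _ in range(n)]
    sign = 1 if orientation == "same" else -1
    for j in range(n):
        score[j][0] = match_score
        aj = anchors[j]
        for i in range(j):
            ai = anchors[i]
            da = aj.rank_a - ai.rank_a
            db = sign * (aj.rank_b - ai.rank_b)
            if da < 1 or db < 1 or da > max_gap or db > max_gap:
                continue
            if ai.gene_a == aj.gene_a or ai.gene_b == aj.gene_b:
                continue
            step = match_score - gap_penalty * ((da - 1) + (db - 1))
            for k in range(L):
                if score[i][k] == NEG:
                    continue
                k2 = min(k + 1, L - 1)
                cand = score[i][k] + step
                if cand > score[j][k2] + 1e-12:
                    score[j][k2] = cand
                    prev[j][k2] = (i, k)
    best = None
    for j in range(n):
        if score[j][L - 1] == NEG:
            continue
        key = (score[j][L - 1], -anchors[j].rank_a, -anchors[j].rank_b)
        if best is None or key > best[0]:
            best = (key, j)
    if best is None:
        return [], 0.0
    j, k = best[1], L - 1
    chain = []
    while j is not None:
        chain.append(j)
        nxt = prev[j][k]
        j, k = nxt if nxt is not None else (None, None)
    chain.reverse()
    return chain, score[best[1]][L - 1]


def chain_anchors(
    anchors: list[Anchor],
    min_block_size: int = 5,
    max_gap: int = 25,
    gap_penalty: float = 1.0,
    match_score: float = 10.0,
    species_a: str = "A",
    species_b: str = "B",
) -> list[SyntenyBlock]:
    """Chain anchors into collinear blocks, greedily best-first per pair."""
    groups: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.chrom_a, a.chrom_b), []).append(a)

    blocks = []
    for (ca, cb) in sorted(groups):
        pool = sorted(groups[(ca, cb)], key=lambda a: (a.rank_a, a.rank_b))
        while pool:
            candidates = []
            for orientation in ("same", "inverted"):
                idx, sc = _best_chain(pool, orientation, max_gap, gap_penalty,
                                      match_score, min_block_size)
                if len(idx) >= min_block_size:
                    candidates.append((sc, 0 if orientation == "same" else 1,
                                       pool[idx[0]].rank_a, orientation, idx))
            if not candidates:
                break
            candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
            sc, _, _, orientation, idx = candidates[0]
            chosen = [pool[i] for i in idx]
            blocks.append(
                SyntenyBlock(
                    block_id="",
                    species_a=species_a,
                    species_b=species_b,
                    chrom_a=ca,
                    chrom_b=cb,
                    orientation=orientation,
                    anchors=chosen,
                    score=sc,
                )
            )
            used = set(idx)
            pool = [a for i, a in enumerate(pool) if i not in used]
    blocks.sort(key=lambda b: (b.chrom_a, b.chrom_b, b.anchors[0].rank_a, b.orientation))
    for k, b in enumerate(blocks):
        b.block_id = f"{species_a}-{species_b}-b{k:04d}"
    return blocks


@dataclass
class DepthProfile:
    target_species: str
    query_species: str
    coverage: dict[str, int]          # target gene id -> covering block count
    reciprocal_coverage: dict[str, int]
    modal_ratio: str = "0:0"


def depth_ratio(
    blocks: list[SyntenyBlock],
    target_genome: GenomeAnnotation,
    query_genome: GenomeAnnotation,
) -> DepthProfile:
    """Syntenic depth: modal number of query blocks covering a target gene.

    Blocks may carry the target genome on either side.  A target gene is
    covered by a block when the block's anchor rank span on the target side
    contains the gene's rank on the matching chromosome.  The modal ratio is
    mode(nonzero target coverage):mode(nonzero query coverage).
    """
    tname, qname = target_genome.species, query_genome.species

    def coverage_of(genome: GenomeAnnotation, side_of_block) -> dict[str, int]:
        cov = {gid: 0 for gid in sorted(genome.genes)}
        for b in blocks:
            side = side_of_block(b)
            if side is None:
                continue
            chrom, (lo, hi) = side
            for gid in genome.gene_order(chrom):
                _, r = genome.rank_of(gid)
                if lo <= r <= hi:
                    cov[gid] += 1
        return cov

    def target_side(b: SyntenyBlock):
        if b.species_a == tname and b.species_b == qname:
            return b.chrom_a, b.span_a
        if b.species_b == tname and b.species_a == qname:
            return b.chrom_b, b.span_b
        return None

    def query_side(b: SyntenyBlock):
        if b.species_a == qname and b.species_b == tname:
            return b.chrom_a, b.span_a
        if b.species_b == qname and b.species_a == tname:
            return b.chrom_b, b.span_b
        return None

    cov_t = coverage_of(target_genome, target_side)
    cov_q = coverage_of(query_genome, query_side)

    def mode_nonzero(cov: dict[str, int]) -> int:
        nz = [v for v in cov.values() if v > 0]
        if not nz:
            return 0
        counts = Counter(nz)
        top = max(counts.values())
        return min(v for v, c in counts.items() if c == top)

    mt, mq = mode_nonzero(cov_t), mode_nonzero(cov_q)
    if mt == 0 and mq == 0:
        warnings.warn(f"no blocks between {tname} and {qname}; depth ratio 0:0")
    return DepthProfile(tname, qname, cov_t, cov_q, f"{mt}:{mq}")


# ---------------------------------------------------------------------------
# Serialization

def export_dotplot(blocks: list[SyntenyBlock], path: str | Path) -> None:
    """TSV of (rank_a, rank_b, block_id, orientation), sorted, lossless."""
    rows = [
        (a.rank_a, a.rank_b, b.block_id, b.orientation)
        for b in blocks
        for a in b.anchors
    ]
    rows.sort()
    with open(path, "w") as fh:
        fh.write("rank_a\trank_b\tblock_id\torientation\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


def write_collinearity(blocks: list[SyntenyBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(
                f"## block {b.block_id} species={b.species_a}|{b.species_b} "
                f"chroms={b.chrom_a}|{b.chrom_b} orientation={b.orientation} "
                f"score={b.score:g} n={len(b.anchors)}\n"
            )
            for a in b.anchors:
                fh.write(
                    f"{a.gene_a}\t{a.gene_b}\t{a.rank_a}\t{a.rank_b}\t{a.family_id}\n"
                )


def read_collinearity(path: str | Path) -> list[SyntenyBlock]:
    blocks: list[SyntenyBlock] = []
    cur: SyntenyBlock | None = None
    for ln in Path(path).read_text().splitlines():
        if ln.startswith("## block"):
            parts = dict(
                kv.split("=", 1) for kv in ln.split()[3:] if "=" in kv
            )
            bid = ln.split()[2]
            sa, sb = parts["species"].split("|")
            ca, cb = parts["chroms"].split("|")
            cur = SyntenyBlock(
                block_id=bid, species_a=sa, species_b=sb, chrom_a=ca,
                chrom_b=cb, orientation=parts["orientation"], anchors=[],
                score=float(parts["score"]),
            )
            blocks.append(cur)
        elif ln.strip():
            ga, gb, ra, rb, fam = ln.split("\t")
            cur.anchors.append(
                Anchor(ga, gb, cur.chrom_a, cur.chrom_b, int(ra), int(rb), fam)
            )
    return blocks
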