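"""All-vs-all protein similarity search, hit filtering, and family clustering.

Alignment is exact affine-gap Smith-Waterman (BLOSUM62 by default) scored
through the Karlin-Altschul statistics: bit = (lambda*raw - ln K)/ln 2 and
E = m*n*2^-bit with m, n the two sequence lengths.  The constants are fixed
gapped-BLOSUM62 defaults, so E-values are comparable to but not identical
with BLAST's; the filtering semantics (retain E <= 1e-5) are what matters.

For large all-vs-all jobs an optional edit-distance prescreen (edlib) skips
pairs whose normalized distance is far beyond anything that could reach the
E-value cut-off; exact DP is still the only scoring path for retained hits.

Family clustering is single-linkage over hits passing identity/coverage
thresholds - deterministic connected components, adequate for data dominated
by single-copy families.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

LN2 = math.log(2.0)


@dataclass
class AlignParams:
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    ka_lambda: float = 0.267          # gapped BLOSUM62 defaults
    ka_K: float = 0.041
    evalue_max: float = 1e-5
    prefilter: str | None = None      # None (exhaustive) or "edlib"
    prefilter_max_distance: float = 0.75

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")


@dataclass(frozen=True)
class HomologyHit:
    query_gene: str
    subject_gene: str
    raw_score: float
    bit_score: float
    e_value: float
    identity_pct: float
    query_coverage: float
    mismatches: int = 0
    gap_opens: int = 0
    aln_len: int = 0
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0


_AA = set("ACDEFGHIKLMNPQRSTVWYX")


def _make_aligner(params: AlignParams, mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    matrix = substitution_matrices.load(params.substitution_matrix)
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -(params.gap_open)
    aligner.extend_gap_score = -(params.gap_extend)
    aligner.mode = mode
    return aligner


def _check_seq(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"{name}: illegal residues {sorted(bad)}")


def local_align(
    a: str, b: str, params: AlignParams | None = None,
    query_id: str = "query", subject_id: str = "subject",
) -> HomologyHit:
    """Optimal local alignment of two protein sequences with hit statistics."""
    params = params or AlignParams()
    _check_seq(a, query_id)
    _check_seq(b, subject_id)
    aligner = _make_aligner(params)
    alignment = aligner.align(a, b)[0]
    raw = alignment.score
    bit = (params.ka_lambda * raw - math.log(params.ka_K)) / LN2
    evalue = len(a) * len(b) * 2.0 ** (-bit)

    qa, sa = alignment[0], alignment[1]
    ident = mism = gaps = 0
    in_gap = False
    for x, y in zip(qa, sa):
        if x == "-" or y == "-":
            if not in_gap:
                gaps += 1
            in_gap = True
        else:
            in_gap = False
            if x == y:
                ident += 1
            else:
                mism += 1
    ncols = len(qa)
    qblocks, sblocks = alignment.aligned
    if len(qblocks):
        qs, qe = int(qblocks[0][0]), int(qblocks[-1][1])
        ss, se = int(sblocks[0][0]), int(sblocks[-1][1])
    else:
        qs = qe = ss = se = 0
    aligned_cols = ident + mism
    return HomologyHit(
        query_gene=query_id,
        subject_gene=subject_id,
        raw_score=float(raw),
        bit_score=bit,
        e_value=evalue,
        identity_pct=100.0 * ident / aligned_cols if aligned_cols else 0.0,
        query_coverage=(qe - qs) / len(a),
        mismatches=mism,
        gap_opens=gaps,
        aln_len=ncols,
        qstart=int(qs),
        qend=int(qe),
        sstart=int(ss),
        send=int(se),
    )


def local_score(a: str, b: str, params: AlignParams | None = None) -> float:
    """Optimal local alignment raw score only (faster; no traceback)."""
    params = params or AlignParams()
    return float(_make_aligner(params).score(a, b))


def _prescreen_ok(a: str, b: str, params: AlignParams) -> bool:
    if params.prefilter != "edlib":
        return True
    res = edlib.align(a, b, task="distance")
    return res["editDistance"] / max(len(a), len(b)) <= params.prefilter_max_distance


def build_hit_table(
    proteomes: dict[str, dict[str, str]],
    params: AlignParams | None = None,
) -> list[HomologyHit]:
    """Align all cross- and within-species protein pairs, keep E <= cut-off.

    Symmetric pairs are computed once (the score is symmetric) and recorded
    with the lexicographically smaller gene id as query.  Output is sorted by
    (query id, subject id).
    """
    params = params or AlignParams()
    owner: dict[str, str] = {}
    for species, seqs in proteomes.items():
        if not seqs:
            warnings.warn(f"empty proteome for species {species!r}")
        for gid in seqs:
            if gid in owner:
                raise ValueError(
                    f"duplicate gene id {gid!r} in {owner[gid]} and {species}"
                )
            owner[gid] = species
    allseqs = {gid: seq for seqs in proteomes.values() for gid, seq in seqs.items()}
    ids = sorted(allseqs)
    hits = []
    for i, qid in enumerate(ids):
        qseq = allseqs[qid]
        for sid in ids[i + 1:]:
            sseq = allseqs[sid]
            if not _prescreen_ok(qseq, sseq, params):
                continue
            hit = local_align(qseq, sseq, params, qid, sid)
            if hit.e_value <= params.evalue_max:
                hits.append(hit)
    hits.sort(key=lambda h: (h.query_gene, h.subject_gene))
    return hits


@dataclass
class GeneFamily:
    family_id: str
    member_gene_ids: frozenset[str]


def cluster_families(
    hits: list[HomologyHit],
    identity_min: float = 30.0,
    coverage_min: float = 0.5,
    universe: set[str] | None = None,
) -> list[GeneFamily]:
    """Single-linkage connected components over threshold-passing hits.

    ``universe`` adds genes with no passing hit as singleton families.  The
    family id is the lexicographically smallest member.
    """
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(x: str, y: str) -> None:
        for n in (x, y):
            parent.setdefault(n, n)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for h in hits:
        parent.setdefault(h.query_gene, h.query_gene)
        parent.setdefault(h.subject_gene, h.subject_gene)
        if h.identity_pct >= identity_min and h.query_coverage >= coverage_min:
            union(h.query_gene, h.subject_gene)
    for gid in sorted(universe or ()):
        parent.setdefault(gid, gid)
    members: dict[str, set[str]] = {}
    for gid in parent:
        members.setdefault(find(gid), set()).add(gid)
    return [
        GeneFamily(family_id=root, member_gene_ids=frozenset(mem))
        for root, mem in sorted(members.items())
    ]


def family_index(families: list[GeneFamily]) -> dict[str, str]:
    return {
        gid: fam.family_id for fam in families for gid in fam.member_gene_ids
    }


def identify_pathway_genes(
    proteomes: dict[str, dict[str, str]],
    reference_seqs: dict[str, str],
    params: AlignParams | None = None,
    identity_min: float = 80.0,
) -> dict[tuple[str, str], list[str]]:
    """Reference-anchored identification of pathway gene candidates.

    For each (species, enzyme) returns the gene ids whose alignment to the
    enzyme's reference protein reaches ``identity_min`` percent identity and
    the E-value cut-off, ranked by bit score (tandem duplicates all appear).
    """
    params = params or AlignParams()
    if not reference_seqs:
        raise ValueError("no reference sequences supplied")
    for enzyme, seq in reference_seqs.items():
        if not seq:
            raise ValueError(f"enzyme {enzyme!r} has an empty reference sequence")
    out: dict[tuple[str, str], list[str]] = {}
    for species in sorted(proteomes):
        for enzyme in sorted(reference_seqs):
            ref = reference_seqs[enzyme]
            scored = []
            for gid in sorted(proteomes[species]):
                seq = proteomes[species][gid]
                if not _prescreen_ok(ref, seq, params):
                    continue
                hit = local_align(ref, seq, params, enzyme, gid)
                if hit.e_value <= params.evalue_max and hit.identity_pct >= identity_min:
                    scored.append((hit.bit_score, gid))
            scored.sort(key=lambda t: (-t[0], t[1]))
            out[(species, enzyme)] = [gid for _, gid in scored]
    return out


HIT_COLUMNS = [
    "query", "subject", "identity", "length", "mismatches", "gapopens",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def write_hit_table(hits: list[HomologyHit], path) -> None:
    """Write the 12-column tabular-search TSV (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.query_gene}\t{h.subject_gene}\t{h.identity_pct:.2f}\t"
                f"{h.aln_len}\t{h.mismatches}\t{h.gap_opens}\t"
                f"{h.qstart + 1}\t{h.qend}\t{h.sstart + 1}\t{h.send}\t"
                f"{h.e_value:.3e}\t{h.bit_score:.1f}\n"
            )
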