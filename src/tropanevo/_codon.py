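"""Shared codon machinery for NG86-style counting and coding-sequence simulation.

The standard genetic code only. Synonymous/nonsynonymous *site* counts follow
the classic convention in which a single-nucleotide change producing a stop
codon counts as nonsynonymous, so that S + N = 3 x (number of codons) exactly.
Difference counting between two codons averages over all minimal substitution
pathways, excluding pathways that pass through a stop codon (with
renormalization over the remaining pathways).
"""

from __future__ import annotations

import itertools
from functools import lru_cache

NUCS = "ACGT"

_BASES = [a + b + c for a in NUCS for b in NUCS for c in NUCS]

# Standard genetic code, written out to avoid any I/O at import time.
_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in _CODE.items() if aa == "*")
SENSE_CODONS = tuple(c for c in _BASES if c not in STOP_CODONS)


def translate_codon(codon: str) -> str:
    return _CODE[codon]


def translate(cds: str) -> str:
    """Translate an in-frame coding sequence; a terminal stop is dropped."""
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    aa = "".join(_CODE.get(cds[i:i + 3].upper(), "X") for i in range(0, len(cds), 3))
    return aa[:-1] if aa.endswith("*") else aa


def single_changes(codon: str):
    """All nine single-nucleotide neighbours as (pos, alt, new_codon, kind).

    kind is 'syn', 'nonsyn' or 'stop'.
    """
    out = []
    for pos in range(3):
        for alt in NUCS:
            if alt == codon[pos]:
                continue
            new = codon[:pos] + alt + codon[pos + 1:]
            if new in STOP_CODONS:
                kind = "stop"
            elif _CODE[new] == _CODE[codon]:
                kind = "syn"
            else:
                kind = "nonsyn"
            out.append((pos, alt, new, kind))
    return out


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """NG86 (synonymous, nonsynonymous) site counts for one sense codon.

    Stop-producing changes count toward the nonsynonymous class so the two
    counts always sum to 3.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    syn = sum(1 for *_, kind in single_changes(codon) if kind == "syn")
    s = syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """NG86 (synonymous, nonsynonymous) difference counts between two codons.

    Averages over all minimal substitution pathways between the codons; any
    pathway whose intermediate codon is a stop is excluded and the average is
    renormalized over the surviving pathways.  Both codons must be sense
    codons.  The two counts sum to the number of differing positions.
    """
    for c in (c1, c2):
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c} in difference counting")
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    nd = len(diff_pos)
    if nd == 0:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        path_syn = 0
        ok = True
        for pos in order:
            new = cur[:pos] + c2[pos] + cur[pos + 1:]
            if new in STOP_CODONS:
                ok = False
                break
            if _CODE[new] == _CODE[cur]:
                path_syn += 1
            cur = new
        if ok:
            totals.append(path_syn)
    if not totals:
        # Both endpoints are sense codons, so the single-step pathway at
        # nd == 1 can never be excluded; at nd >= 2 at least one ordering
        # avoids stops for all sense pairs under the standard code, but be
        # defensive and fall back to an all-nonsynonymous call.
        return 0.0, float(nd)
    sd = sum(totals) / len(totals)
    return sd, nd - sd


def random_sense_codon(rng) -> str:
    return SENSE_CODONS[rng.randrange(len(SENSE_CODONS))]
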