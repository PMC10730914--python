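"""Synonymous-divergence (Ks) estimation and Ks-distribution WGD dating.

Per-pair Ks/Ka uses Nei-Gojobori (1986) counting: synonymous and
nonsynonymous site fractions averaged over both sequences, multi-difference
codons averaged over all minimal substitution pathways (stop-passing pathways
excluded, renormalized), then the Jukes-Cantor multiple-hit correction
d = -(3/4) ln(1 - 4p/3).  Distribution modes are found by Gaussian kernel
density (Silverman bandwidth); a mode Ks dates a duplication at
T = Ks / (2 r) for synonymous rate r (substitutions/synonymous site/year).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde

from ._codon import STOP_CODONS, codon_sites, pair_differences
from .homology import AlignParams, _make_aligner

MIN_ALIGNED_CODONS = 30


@dataclass
class KsEstimate:
    gene_a: str
    gene_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ks: float
    Ka: float
    codons: int
    valid: bool


def _jc(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def estimate_ks(cds_a: str, cds_b: str, gene_a: str = "a", gene_b: str = "b") -> KsEstimate:
    """NG86 + Jukes-Cantor Ks/Ka for a gap-free aligned codon pair.

    Codon columns containing a stop codon in either sequence (terminal stops
    included) are skipped.  The estimate is flagged invalid when fewer than
    30 codons align or the synonymous proportion reaches the 3/4 ceiling
    where the correction is undefined.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("aligned CDS lengths differ")
    if len(cds_a) % 3:
        raise ValueError("aligned CDS length not divisible by 3")
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    S = N = Sd = Nd = 0.0
    ncod = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        if set(ca + cb) - set("ACGT"):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = pair_differences(ca, cb)
        Sd += sd
        Nd += nd
        ncod += 1
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0
    ks = _jc(ps)
    ka = _jc(pn)
    valid = ncod >= MIN_ALIGNED_CODONS and ps < 0.75
    return KsEstimate(gene_a, gene_b, S, N, Sd, Nd, ps, pn, ks, ka, ncod, valid)


def codon_align(prot_a: str, prot_b: str, cds_a: str, cds_b: str,
                params: AlignParams | None = None) -> tuple[str, str]:
    """Protein-guided codon alignment: align proteins globally, thread codons
    back, and drop columns gapped in either sequence.

    The CDS sequences may carry a terminal stop codon, which is ignored.
    """
    params = params or AlignParams()
    aligner = _make_aligner(params, mode="global")
    aln = aligner.align(prot_a, prot_b)[0]
    qa, sa = aln[0], aln[1]
    ia = ib = 0
    out_a, out_b = [], []
    for x, y in zip(qa, sa):
        if x != "-" and y != "-":
            out_a.append(cds_a[3 * ia:3 * ia + 3])
            out_b.append(cds_b[3 * ib:3 * ib + 3])
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    return "".join(out_a), "".join(out_b)


def block_ks(block, cds_store: dict[str, str],
             prot_store: dict[str, str] | None = None) -> float | None:
    """Median of valid per-anchor-pair Ks in one synteny block.

    Returns None (with a warning) when no pair yields a valid estimate.
    """
    values = []
    for a in block.anchors:
        ca, cb = cds_store.get(a.gene_a), cds_store.get(a.gene_b)
        if ca is None or cb is None:
            continue
        if prot_store and a.gene_a in prot_store and a.gene_b in prot_store:
            ca, cb = codon_align(prot_store[a.gene_a], prot_store[a.gene_b], ca, cb)
        est = estimate_ks(ca, cb, a.gene_a, a.gene_b)
        if est.valid and not math.isnan(est.Ks):
            values.append(est.Ks)
    if not values:
        warnings.warn(f"block {block.block_id}: no valid Ks estimate; excluded")
        return None
    return float(np.median(values))


@dataclass
class KsPeak:
    mode: float
    component_sd: float
    weight: float


@dataclass
class WgdEvent:
    ks_mode: float
    component_sd: float
    rate: float                    # substitutions/synonymous site/year
    T: float                       # Mya
    ci95: tuple[float, float]      # Mya


def detect_peaks(
    ks_values,
    lo: float = 0.005,
    hi: float = 2.0,
    bandwidth: str | float = "silverman",
    min_values: int = 50,
    grid: int = 512,
) -> list[KsPeak]:
    """KDE modes of the Ks distribution on (lo, hi], ordered by weight.

    The component sd of a peak is the standard deviation of the Ks values in
    the peak's basin (between the adjacent density minima); the weight is the
    fraction of values in the basin.
    """
    vals = np.asarray([v for v in ks_values if lo < v <= hi], dtype=float)
    if vals.size < min_values:
        if vals.size:
            warnings.warn(f"only {vals.size} Ks values in range; no peaks reported")
        return []
    kde = gaussian_kde(vals, bw_method=bandwidth)
    xs = np.linspace(lo, hi, grid)
    dens = kde(xs)
    maxima = argrelextrema(dens, np.greater)[0]
    minima = list(argrelextrema(dens, np.less)[0])
    peaks = []
    for m in maxima:
        left = max([i for i in minima if i < m], default=0)
        right = min([i for i in minima if i > m], default=grid - 1)
        basin = vals[(vals >= xs[left]) & (vals <= xs[right])]
        sd = float(basin.std(ddof=1)) if basin.size > 1 else 0.0
        peaks.append(KsPeak(float(xs[m]), sd, basin.size / vals.size))
    peaks.sort(key=lambda p: (-p.weight, p.mode))
    return peaks


def date_wgd(mode: float, component_sd: float, rate: float) -> WgdEvent:
    """Date a duplication peak: T = mode/(2r), CI from +-1.96 component sd."""
    if rate <= 0:
        raise ValueError("synonymous rate must be positive")
    if mode < 0:
        raise ValueError("Ks mode must be non-negative")
    t_my = mode / (2.0 * rate) / 1e6
    lo = max(0.0, (mode - 1.96 * component_sd)) / (2.0 * rate) / 1e6
    hi = (mode + 1.96 * component_sd) / (2.0 * rate) / 1e6
    return WgdEvent(mode, component_sd, rate, t_my, (lo, hi))


def write_ks_table(estimates: list[KsEstimate], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tS\tN\tSd\tNd\tps\tpn\tKa\tKs\tvalid\n")
        for e in estimates:
            fh.write(
                f"{e.gene_a}\t{e.gene_b}\t{e.S:.2f}\t{e.N:.2f}\t{e.Sd:.3f}\t"
                f"{e.Nd:.3f}\t{e.ps:.5f}\t{e.pn:.5f}\t{e.Ka:.5f}\t{e.Ks:.5f}\t"
                f"{int(e.valid)}\n"
            )
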