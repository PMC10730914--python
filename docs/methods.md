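# Methods

This note records the models, parameter choices, and numerical conventions
behind `tropanevo`, and what the synthetic validation does and does not
establish.

## The inference problem

A metabolic pathway present in scattered lineages of a plant family either
evolved convergently several times or arose once in the common ancestor and
was lost repeatedly. The two histories are distinguished genomically: under
single origin + loss, non-producing genomes retain collinear traces of the
pathway loci — intact orthologs in syntenic position, pseudogene fragments,
or conserved flanking blocks around an empty locus — and gene trees follow
the species tree rather than clustering producers together. The pipeline
formalises this argument: identify the pathway genes, locate their syntenic
context in every genome, classify each locus (present / pseudogene /
absent), and count losses on the species tree under Dollo parsimony.

## Pathway model

The 12-enzyme HS pathway is enzyme-indexed, not reaction-indexed: the
spontaneous cyclization between compounds 3 and 4 is not catalysed, so it is
folded into the surrounding enzymatic steps. Steps carry a segment tag —
tropane-ring formation (PMT, MPO, PYKS, CYP82M3), phenyllactylglucose
biosynthesis (ArAT4, PPAR, UGT1), and the HS-exclusive medicinal segment
(TRI, LS, CYP80F1, HDH, H6H). A species is a *producer* when every
non-dispensable enzyme has an intact copy. HDH is required by default; VIGS
evidence that HDH suppression does not reduce hyoscyamine leaves its
dispensability genuinely open, so it is a configuration switch
(`load_default_pathway(hdh_dispensable=True)`) rather than a guess.

## Homology search

Pairwise protein comparison is exact local alignment (affine-gap
Smith–Waterman, BLOSUM62, gap open 11 / extend 1) scored with fixed gapped
Karlin–Altschul constants (λ = 0.267, K = 0.041); E = m·n·2^(−bit) over the
pair's own search space. E-values are therefore comparable to, but not
identical with, BLAST's — only the ≤ 1e-5 retention semantics matter
downstream. For all-vs-all jobs the pipeline applies an edit-distance
prescreen (edlib, normalized distance ≤ 0.75) before the exact DP; at these
sequence lengths a pair above that distance cannot come near the E-value
cut-off, so the prescreen changes runtime, not results. Families are
single-linkage components over hits passing 30% identity and 0.5 query
coverage — simpler than Markov clustering and adequate when most families
are single-copy; the deviation is deliberate and documented here.
Pathway orthologs are identified against bundled reference proteins at
identity ≥ 80%, keeping all qualifying copies (tandem arrays) ranked by bit
score. Families with more than 20 members in one genome contribute no
synteny anchors (repeat suppression).

## Synteny chaining

Anchors are family-sharing gene pairs addressed by gene-order rank; rank
gaps, not base pairs, drive the chain constraints, which makes the chaining
independent of intergenic scale. Per chromosome pair and orientation, the
highest-scoring chain with strictly monotone ranks, both gaps ≤ 25, and at
least `min_block_size` anchors is found by DP (score = 10 per anchor − 1 per
skipped rank); the DP carries chain length as a capped second state so the
optimum is over admissible chains, not all chains. Chains are extracted
greedily best-first with used anchors removed. The block-size threshold is
≥ 5: the tool settings this reimplements ("-s 5") admit five-anchor blocks
even where prose says "more than five". No block-level E-value is computed;
`min_block_size` + `max_gap` substitute. Ties between equal-scoring chains
are broken toward the smaller starting rank, which makes extraction
deterministic but means exact invariance under joint order reversal holds
only when optima are unique (the test suite checks it on tie-free
instances).

Depth profiles count, for each target gene, the query blocks whose anchor
span covers its rank; the modal ratio is mode(nonzero target coverage) :
mode(nonzero reciprocal coverage). For depth profiling the anchors are
restricted to near-best hits (C-score 0.9, both directions), the standard
ortholog-only filtering for polyploidy depth; without it, anciently
triplicated chromosomes in the clean synthetic genomes chain perfectly and
inflate coverage beyond what eroded real paralog blocks show.

## Microsynteny scenarios

For each pathway gene in each of (by default) three reference genomes, the
flanking window is ±20 genes (or ±100 kb; genes are the default unit since
the simulator compresses intergenic DNA). A query region qualifies when a
collinear block contains ≥ 3 window anchors — the flank may match on either
side; requiring both sides is a config switch. Scenario 1: a family ortholog
inside a qualifying region. Scenario 2: regions exist but hold no ortholog;
the sub-region between the anchors bracketing the expected locus (± 4 kb
padding) is six-frame translated, segments split at stops are locally
aligned to the reference protein, and the best colinear, non-overlapping
segment hits are merged across frames. Each segment hit must clear a
per-segment E-value of 1e-3 over the whole translated search space —
without this gate, large windows accumulate spurious short hits whose merged
coverage mimics a pseudogene. The merged evidence calls a pseudogene when
identity ≥ 40% and coverage ≥ 0.3 but the gene is disabled (coverage < 0.8,
a premature stop, or a frameshift between merged segments); these
thresholds are pipeline choices (the original calls were manual and
structural) and all configurable. The scan never returns "intact": intact
loci are annotated and caught upstream. Scenario 3 (no qualifying region):
a genome-wide family ortholog yields an intact-but-synteny-unsupported
call; failing that, a genome-wide translated scan; failing that, absent.

Consensus across references uses precedence intact > pseudogene > absent —
synteny-supported presence is the strongest evidence class — with the
lowest scenario number among winning calls retained and conflicting intact
loci logged.

## Ks estimation and WGD dating

NG86 counting: per-codon synonymous site fractions are averaged over the two
sequences; multi-difference codons average the synonymous/nonsynonymous step
counts over all minimal substitution pathways, excluding pathways through
stop codons and renormalizing over the survivors. Site counting treats
stop-producing single-nucleotide changes as nonsynonymous so that S + N =
3 × codons exactly. Jukes–Cantor corrects multiple hits: Ks = −(3/4)·ln(1 −
4ps/3). Estimates are invalid below 30 aligned codons or at ps ≥ 3/4.
Codon alignments are protein-guided (global protein alignment, codons
threaded back, gap columns dropped). One consequence of pathway averaging
worth knowing: even a purely synonymous substitution history can yield
fractional nonsynonymous difference counts on multi-hit codons (the
estimator averages over orderings it cannot distinguish); Ka at low
divergence is therefore a slight overestimate, while Ks is unaffected.

Distribution modes come from a Gaussian KDE (Silverman bandwidth, 512-point
grid on (0.005, 2]); at least 50 in-range values are required. A peak's
component sd is the standard deviation of the values in its basin (between
adjacent density minima) and its weight the basin's share of values. Dating
uses T = mode/(2r) with r = 5.6×10⁻⁹ synonymous substitutions/site/year by
default; the 95% CI is a normal approximation, mode ± 1.96·sd mapped through
the same clock and floored at zero. Both the rate and the CI construction
are exposed as configuration: the quantities they reproduce were published
without stating either.

## Dollo parsimony and ancestral residues

With a single gain fixed at the root, the loss-minimal labeling sets a node
to 1 iff any descendant leaf is 1; loss edges are the 1→0 edges. This is
checked against brute-force minimization over all single-gain labelings.
Note that the loss count is *not* monotone as leaves flip off: turning one
more leaf off can consolidate several sibling-stem losses into one ancestral
loss; what does hold (and is tested) is that a single flip adds at most one
loss. Both a functional matrix (intact = 1) and a locus-level matrix
(intact-or-pseudogene = 1) are analysed: retained pseudogene loci are
precisely the evidence that distinguishes loss of an ancestral pathway from
never having had it.

Marginal ancestral reconstruction uses Felsenstein pruning with an outside
(re-rooting) pass for per-node posteriors. The default model is Poisson over
20 amino acids with equal frequencies, normalized to one expected
substitution per unit branch length (the closed form P_ii(t) = 1/20 +
(19/20)·e^(−20t/19) avoids matrix exponentials); a custom 20×20 generator is
accepted. Gaps and unknowns contribute likelihood 1. Time-calibrated trees
need a branch scale (substitutions/site per My); the pipeline default is
2×10⁻³, consistent with the ~18% protein divergence across a ~130 My
leaf-to-leaf path that the conserved pathway enzymes show.

## Synthetic clade generator

The generator is first-class, tested code: it builds an ancestral genome
(by default 2 chromosomes × 40 single-copy background genes, 450 bp CDS in
three exons of 25/25/50%, 2 kb intergenic — so a ±20-gene window spans
roughly the 100 kb the analysis assumes) with the 12 pathway genes at fixed
interior loci, then evolves it along a time-calibrated tree.

* **Sequence evolution**: per branch, synonymous and nonsynonymous
  substitution counts are Poisson with means r·t·(NG86 site count of the
  class); each substitution picks a codon proportional to its opportunity
  count and one of its class changes uniformly; stop-creating changes are
  never sampled. This makes the expected pairwise Ks of a duplication of
  age T exactly 2·r_s·T, the closed form the recovery tests check.
  Defaults: r_s = 5.6×10⁻⁹/site/year (the synonymous clock consistent with
  dating the recent duplication peak near 13 My — the published analysis
  does not state its rate, so this is a documented assumption);
  r_n = 0.65×10⁻⁹, calibrated to the observed conservation of the pathway
  enzymes (~82% protein identity across the family, ~90% to a reference,
  Ka/Ks ≈ 0.12 — strong purifying selection).
* **Polyploidy**: a flagged branch duplicates (or triplicates) every
  chromosome, then drops each duplicated gene with probability 1 −
  retention. The bundled preset retains 25% after the root triplication and
  50% after each lineage WGD — post-fractionation levels typical of these
  genomes.
* **Pseudogenization** (default mode `truncate-5prime-2-exons`): the first
  two exons (half the CDS) are deleted, the remnant stays at the locus and
  drifts neutrally at r_s per site; mode `premature-stop` inserts a stop 40%
  into the CDS instead.
* **Translocation with synteny erosion**: the gene moves to another
  chromosome and the surrounding ±20 background loci are lost. Scattering
  the flank instead of deleting it does not erode anything — a few dozen
  relocated orthologs always contain an increasing subsequence long enough
  to re-chain into a block (length ≈ 2√n) — so deletion is the model that
  actually produces the "no collinear block anywhere" state the cascade's
  scenario 3 describes. Pathway genes inside the eroded flank are relocated,
  never deleted, so one forced event cannot silently change another
  enzyme's truth state.
* **Forced pathway loss**: on designated branches every copy of the five
  HS-exclusive genes becomes a pseudogene or is deleted (fair coin per
  copy). In the bundled 17-leaf preset, three such branches mirror the
  repeated-loss topology; random loss/pseudogenization turnover is applied
  to background genes only (`protect_pathway_background_events`), so the
  pathway truth — and the exact set of loss branches the Dollo analysis
  must recover — is determined by the forced events while background
  turnover still exercises anchor filtering.

All randomness flows through one seeded generator; identical tree + config
+ seed give byte-identical outputs, which the determinism tests assert at
file level.

### What the synthetic data does not emulate

No repeats or transposons, no strand variation (all genes are forward), no
indel realism inside coding sequence, no intron evolution beyond exon
presence/absence, no annotation error, and background families are
single-copy before polyploidy. Passing the truth-recovery tests therefore
shows the pipeline's logic is correct under its own assumptions — clean
annotations and moderate divergence — not that it is robust to repeat-rich,
fragmentarily assembled real genomes, where anchor filtering and the
pseudogene thresholds would carry much more weight.

## Problem sizes and validation design

The bundled preset (17 leaves, ~130–210 genes per genome after polyploidy,
~2,400 proteins clade-wide) is sized so a full simulate-to-report run
completes in a few minutes on one CPU while still containing every
evolutionary structure the method must disentangle: nested triplication +
duplication, tandem arrays, eroded synteny, pseudogene remnants at three
ages, and three independent pathway losses. Oracle tests run exhaustive
enumeration at small n (≤ 8 anchors, ≤ 10 leaves, ≤ 12 residues, all 61²
codon pairs, 3-taxon 20-state summation); recovery tests use 500 replicate
pairs of 300 codons. The Ks-recovery tolerance (±0.02 on a 0.15 mode)
reflects KDE grid and bandwidth granularity, not estimator bias.

## Known limitations

* Scenario calls near a synteny-erosion event can misclassify *neighboring*
  genes whose windows are partially destroyed (observed as 4 of 204 cells
  in the preset); the consensus over three references does not always
  rescue them.
* E-values use pairwise search spaces and fixed Karlin–Altschul constants;
  absolute values differ from database-calibrated tools.
* The KDE peak picker reports grid-resolution modes; components closer than
  the bandwidth merge.
* Dollo assumes the root carries the trait whenever any leaf does; for a
  trait absent from the outgroup the "origin" is the tree root by
  definition, and placing the gain lower requires re-rooting the input
  tree.
* The ancestral-residue model ignores among-site rate variation and uses
  uniform frequencies unless a custom generator is supplied.
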