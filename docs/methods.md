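# Methods

This note documents the models, conventions and numerical choices behind
ringkit, and what the synthetic-data generators do and do not emulate.

## Domain scanning

A C3H2C3 RING domain is modelled as eight metal-ligand residues (C, C, C,
H, H, C, C, C) separated by seven spacers `g1..g7`. The default spacer
bounds are the family consensus g1=(2,2), g2=(9,39), g3=(1,3), g4=(2,3),
g5=(2,2), g6=(4,48), g7=(2,2); they are scan *constraints*, while the
narrower ranges observed in real families (g2 ≈ 11–24, g6 ≈ 8–14) are
census *outputs*. The scanner enumerates every position 8-tuple whose
residues and spacers satisfy the bounds, then selects non-overlapping hits
greedily: leftmost first ligand, then smallest span, then lexicographically
smallest tuple. The discarded co-valid assignments remain available
(`return_alternates=True`). All domains per protein are reported; nothing
is truncated to one hit per gene. `X` is accepted as spacer fill but never
as a ligand; scanning is case-insensitive; coordinates are 0-based in
memory and 1-based in written reports.

Under an i.i.d. residue model the expected number of valid assignments in a
random sequence is `(Σ over geometrically possible assignments) · fC^6 ·
fH^2`, computed exactly by convolving the seven spacer ranges
(`expected_random_assignments`); the false-positive property tests bound
observed counts by this expectation ± 3 standard errors.

## Physicochemistry

Molecular weight = Σ average residue masses + 18.0153 Da (one water);
unknown residue `X` contributes a configurable mean residue mass of
110.0 Da. The isoelectric point solves net charge = 0 by bisection to
1e-3 pH, where charge is the Henderson–Hasselbalch sum over the N-terminus,
H, K, R (positive) and the C-terminus, C, D, E, Y (negative). Two pKa
tables ship: EMBOSS (default) and Bjellqvist. Published pI values computed
with other tools typically agree only to a few tenths of a pH unit, so no
exact-match claim is made against any published table.

## Gene models

GFF3 is parsed through gffutils (in-memory database). One model per gene:
the transcript with the longest summed CDS, ties broken by lexicographic
transcript id. Introns are counted from exon features; when a transcript
carries only CDS features, those intervals stand in for exons (logged).
Family naming sorts chromosomes naturally (numeric suffixes numerically;
unanchored scaffolds after all numbered chromosomes) and genes by start
coordinate; the result is invariant to input order.

## Duplication and Ka/Ks

Candidate paralogs are all unordered pairs whose global CDS alignment
exceeds 75 % identity over more than 75 % of the shorter CDS (the
published screen's identity threshold; the e-value criterion of an
alignment-search tool is replaced by this deterministic desk-scale rule).
The affine-gap global alignment (match +2, mismatch −1, gap open −10,
extend −0.5; a length-k gap costs open + (k−1)·extend) is computed by a
dynamic program that maximizes the lexicographic objective
(score, matches, −aligned columns), making percent identity a well-defined
function of the two sequences rather than of an arbitrary co-optimal
traceback. The DP is numba-compiled with a pure-Python fallback.

Classification: a pair is *tandem* when both genes share a chromosome, at
most 5 other family members lie between them, and their nearest ends are at
most 100 kb apart; otherwise *segmental*. Both thresholds are
configurable; published family surveys rarely state their exact criterion,
and borderline pairs (roughly 100–200 kb apart) can be classified either
way depending on the convention chosen.

Ka/Ks uses Nei–Gojobori (1986) counting on a codon alignment built by
translating both CDS, aligning the proteins (BLOSUM62, −10/−0.5) and
back-threading codons; a direct nucleotide mode exists for gap-free pairs.
Per codon, each position contributes the fraction of its single-nucleotide
changes that are synonymous, with changes to stop codons excluded and the
fraction renormalized, so S + N = 3 × codon count exactly. Differences
between codons differing at several positions are averaged over all
substitution pathways, skipping pathways through stop codons (falling back
to all pathways if every one is blocked). Proportions pS = Sd/S and
pN = Nd/N are Jukes–Cantor corrected; when 4p/3 ≥ 1 the correction
saturates and the estimate is flagged undefined rather than raised, as is
the ratio when Ks = 0. Gap or `N`-containing codon columns are skipped.
Divergence-time dating is deliberately absent: no substitution-rate
constant is adopted.

## Promoters

The promoter is the 2-kb window immediately 5′ of the translation start:
for plus-strand genes the bases ending just before the gene start, for
minus-strand genes the reverse complement of the bases just after the gene
end; windows truncated at a contig edge are flagged. Elements are
IUPAC-degenerate patterns scanned on both strands with overlapping
occurrences all reported; minus-strand hits are mapped to
forward-orientation offsets (offset′ = L − offset − m), so a palindromic
pattern yields one hit per strand at the same offset. Summaries report
both occurrence counts (gene × element matrix) and prevalence (genes with
≥ 1 occurrence), because published censuses are ambiguous about which was
counted. The shipped dictionary carries literature-standard patterns for
the commonly reported plant elements in seven functional categories; motif
dictionaries differ between tools, so absolute counts are
dictionary-dependent and the dictionary is fully user-replaceable.

## Expression screen

Fold change is log2(WS/WW) per gene, genotype and timepoint, with replicate
cells averaged. Zeros follow a fixed convention instead of a pseudocount
(which would invent a magnitude): WS>0, WW=0 → +∞; WS=0, WW>0 → −∞; both
zero → undefined (NaN). A gene is *expressed* if any of its samples is
nonzero. A gene is differential at a timepoint when |log2(WS/WW)|
strictly exceeds the threshold (default 1); undefined cells are never
differential, infinite cells always are, and ties at exactly the threshold
are excluded. The multi-period intersection reports every Venn region
(gene regions partition the union) and the genes differential in ≥ k
timepoints. A `pseudocount` option is available for users who prefer
finite fold changes.

## Synthetic data

One master seed fans out to per-generator child streams through numpy's
`SeedSequence(seed, spawn_key=(k,))` with a fixed `k` per generator, so
adding a generator never perturbs existing outputs; every generator is
byte-reproducible from (parameters, seed) and emits a truth table consumed
directly by the tests.

* **Proteomes** — spacers sampled uniformly within bounds, spacer fill from
  non-ligand residues, domain inserted into an i.i.d. background;
  backgrounds are rejection-sampled until they contain no valid assignment,
  and domain proteins until the planted assignment is the only one, so
  recovery can be asserted exactly.
* **CDS pairs** — an ancestor of sense codons and a copy evolved by
  single-nucleotide proposals (transition:transversion ratio κ), accepting
  synonymous changes always, nonsynonymous with probability min(1, ω), and
  rejecting stop-creating changes, until the running NG86 Ks between
  ancestor and copy reaches the target (checked every 8 accepted changes;
  overshoot ≤ ~0.005). The parameter-recovery tests simulate with κ = 1,
  i.e. under the estimator's own model: with κ = 2 NG86 shows its known
  downward bias in ω (up to ≈ 0.2 at ω = 1), which is a property of the
  estimator, not an implementation error; a κ = 2 robustness check at
  moderate ω remains in the unit suite.
* **Promoters** — element-free background (scrubbed by local resampling
  until no dictionary pattern matches either strand) with one occurrence
  per chosen element planted at a recorded offset/strand. Planting is
  decided before any rejection retry, so retries cannot bias prevalence.
  The construction guarantees scanner hits equal the truth exactly, which
  requires the planted subset to be containment-free (one element's
  realizations must not be occurrences of another, e.g. G-box ⊃ ABRE, or
  CGTCA whose reverse complement is TGACG).
* **Expression** — well-watered baselines are lognormal; planted
  differential cells get WS = WW · 2^(±effect) exactly, everything else
  multiplicative lognormal noise 2^N(0, σ). Defaults: effect 3.0, σ = 0.2
  (false-call tail probability < 1e-6 per cell), 20 % of genes differential
  somewhere, of which up to 8 in ≥ 3 of 4 timepoints — mirroring the
  shape of a drought time-course screen.
* **Gene models** — genes laid out non-overlapping across several
  chromosomes plus an unanchored scaffold, intergenic gaps ≥ 4.5 kb so
  2-kb promoter windows never collide, exon counts drawn from a supplied
  intron-count distribution.
* The coherent bundle (`write_bundle`) shares gene identifiers across all
  files and re-plants promoter elements into the genome upstream of each
  gene, so the end-to-end pipeline can be checked against truth.

What the generators do **not** emulate: real codon-usage and GC landscapes,
repeats, alternative splicing, read-level noise, correlated expression, or
any real genome's gene spacing. Passing the recovery tests therefore
demonstrates algorithmic correctness on inputs satisfying the stated
models, not performance on a real genome, where domain-adjacent paralogy,
assembly gaps and annotation errors dominate.

## Problem sizes and defaults

The test and acceptance runs use sizes chosen to exercise the asymptotics
while staying desk-scale: 200 random proteins (≤ 400 aa) for
scanner/oracle equivalence, 1,000 proteins for planted recovery, 2,000
codons × 20 seeds for ω recovery (target Ks 0.5), 5,000 genes for the
noiseless DEG screen, 1,000 random promoters for the motif-scanner oracle,
and a 24-gene coherent bundle for end-to-end determinism. Published-table
statistics (the 143-member family table, the nine duplicate pairs) are
computed from the packaged TSVs and are seed-independent.

## Known limitations

* NG86 with Jukes–Cantor correction ignores transition/transversion bias
  and codon-frequency structure; for publication-grade selection inference
  a maximum-likelihood ω (codeml-style) is preferable.
* The tandem/segmental rule is a proximity heuristic, not a synteny
  analysis; collinearity-based classification is out of scope.
* Promoter censuses depend entirely on the motif dictionary; counts are not
  comparable across dictionaries.
* The pI calculation assumes independent ionizable groups (no local
  electrostatic corrections).
* The expression screen is a pure threshold rule without replicate-based
  statistical testing.
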