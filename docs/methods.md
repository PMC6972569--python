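# Methods

`mge-atlas` re-implements, as a tested pipeline, the comparative-genomics
workflow used to characterise a family of mid-sized archaeal plasmids that
integrate into host chromosomes at tRNA genes: boundary detection of
integrated elements from att-site direct repeats, reconstruction and typing
of the integrases that mediate integration, orthology and core-genome
analysis across family members, replication-origin prediction, CRISPR-spacer
host-range mapping, and distance-based tests of host–plasmid co-evolution.
Because no public analysis archive exists for such a family at desk scale,
the package ships a synthetic-data generator that emulates the study design
with known ground truth; every pipeline stage is validated as a round trip
against that truth.

## Element detection

**Model.** A circular element integrates by site-specific recombination
between a plasmid attachment site (attP) and an identical chromosomal site
(attB) that overlaps the 3′ end of a tRNA gene. Integration duplicates the
att sequence as a direct repeat (attL/attR) flanking the element and leaves
the tRNA gene intact. Detection therefore proceeds by (i) anchoring: ORFs
called on the genome (ATG/GTG starts, stops TAA/TAG/TGA, translation table
11) are scored by Smith–Waterman local alignment against a set of core
reference proteins; ORFs whose score exceeds 30% of the reference
self-alignment score become anchors; (ii) limit calling: a window (default
50 kb) around the anchor cluster is searched for direct-repeat pairs of
length ≥ 40 nt that bracket every anchor. Up to 3 mismatches are tolerated,
and only in the central third of the repeat — the recombination core decays
after integration while the flanking arms stay exact. Among bracketing
pairs the longest repeat wins, then the smallest span. No bracketing pair
means "no detectable limits" (remnant-like elements).

**Why central third?** The tolerance zone is not defined more precisely in
the source material; an explicit central-third rule (exact first and last
thirds) is testable and matches the intuition that strand exchange occurs
in the middle of the site. This choice is exposed as a parameter.

**Integrase reconstruction.** Type I integrases carry attP inside their
coding sequence, so integration splits the gene: the N-terminal CDS runs
from a start codon to the last codon before one att copy, the C-terminal
CDS from the first codon of the other att copy to a stop. Reconstruction
joins genome[n_start : attR.start) + genome[attL.start : stop) (both
orientations and strands are tried) and accepts a join only if it
translates cleanly to ≥ 100 aa. If no split join exists, an intact gene
strictly between the atts is looked up instead (type II). Classification:
type I when an att copy lies inside the integrase CDS, type II when an
intact integrase lies strictly between the atts, none when no integrase is
found.

**att–tRNA relations.** For each called element the report gives the
overlapped tRNA isotype (the att must cover the tRNA 3′ terminus), whether
the anticodon falls inside the att, the overlap length, and whether the att
contains a short imperfect palindrome (the tRNA T-arm stems, which the
integrase recognises). An att-exchange check compares the four att copies
of two co-integrated elements: when within-element identity fails but
attL(A)≈attL(B) and attR(A)≈attR(B), an inversion between the two elements
is called.

## Orthology and core-genome analysis

Pairwise protein comparison is optimal local alignment (BLOSUM62, gap open
11, extend 1 — the defaults of the search tool such surveys use). Raw
scores are normalized by the query self-alignment score; two proteins are
orthologs (a normalized BDBH pair) when each is the other's best raw-score
hit and **both** directed normalized scores exceed 30%. The "both" rule is
equivalent to thresholding the minimum of the two directions; an "either"
variant is exposed as a switch. Ties between equal best scores break by
higher alignment identity, then lexicographic subject id.

Pivot core analysis counts, for each protein of a chosen pivot element, how
many elements carry a BDBH ortholog (the pivot counts as carrying its own);
the core is the set present in ≥ 80% of elements. The conservation network
weights element pairs by their BDBH pair count; communities are found by
agglomerating short random walks (walktrap, via igraph) and cutting the
merge tree at maximal modularity. Families are single-transitive-link
clusters: an undirected link joins two proteins when their alignment
reaches the identity threshold (default 25%) and covers at least the
coverage threshold (default 60%) of **both** sequences; families are
connected components. Requiring coverage on both sides stands in for the
significance filter of a database search — without an E-value gate, short
high-identity local alignments between unrelated proteins would chain
everything into a few giant families. The source material uses 60%
coverage for its integrase analysis and mentions 40% for an all-protein
run, so the threshold is a parameter.

## Replication origins and Rep proteins

GC skew is (G−C)/(G+C) per window (default 500 nt, step 100 nt; windows
without G or C score 0). The cumulative-skew extremum (maximum or minimum,
whichever separates the two flanks by the larger mean-skew shift) is the
skew origin candidate; the call requires a shift ≥ 0.10 so flat profiles
return nothing. Repeat-rich regions are found by counting, per window,
positions whose k-mer (k = 10, canonicalised with its reverse complement)
occurs at least twice in the sequence; low-complexity k-mers (< 3 distinct
bases) are masked; the maximum z-score window is the repeat candidate when
z ≥ 3. The two methods merge into one origin when within 2 kb, yield two
origins when both fire apart, and "not found" when neither fires. Rep
proteins are classified by the best normalized-score hit (> 30%) against a
packaged exemplar set of the family's three Rep classes (MCM, MCM-like,
t26-22p-like). The exemplars are synthetic sequences generated once and
frozen (`data/rep_references_synthetic.faa`); the generator derives element
Rep genes from these same exemplars, so classification is a genuine round
trip rather than a lookup.

Window sizes and thresholds are not stated in the source material; the
defaults above were chosen once so that the generator's implanted signals
(a codon-bias skew switch plus an iterated 25-nt repeat cluster at one
locus) are detectable, and all are exposed as parameters.

## Host range and biogeography

Spacer matching is an ungapped Hamming scan at full spacer length on both
strands with ≤ 2 mismatches; N never matches. This is the standard
protospacer criterion and is exhaustively checkable. Prevalence summaries
count, per host order, genomes carrying an element, carrying a spacer
against the family, and both; the union uses inclusion–exclusion and
percentages are reported to one decimal. Note the printed union percentages
in the source survey (56%/55%) are not derivable from its own printed
counts (12+12−5 = 19 of 39 → 48.7%); the package reports computed unions.
Region summaries bucket isolates into six named sampling regions, with
anything else under "other".

## Co-evolution tests

Distances: optimal global alignment (same matrix/gaps), p = fraction of
differing residues over aligned non-gap columns, Poisson-corrected
d = −ln(1−p), capped at p = 0.95 with a saturation flag. Concatenation is
realised as the length-weighted mean of per-family distances over families
shared by both elements (identical to a concatenated alignment in the
low-divergence limit, without needing progressive MSA); a pair sharing no
family is an error. Trees are built by neighbor joining with a
deterministic lowest-index tie-break and exact recovery of additive
matrices (cross-checked against dendropy's NJ). Monophyly of a leaf set is
tested as the existence of an edge bipartitioning the leaves exactly into
set vs complement; congruence between the element tree and a host tree
(built the same way from host marker proteins) is quantified by the
Robinson–Foulds distance. Maximum-likelihood inference and bootstrap
supports are intentionally out of scope: the claims under test are
topological.

## Synthetic data generator

The generator encodes the study conditions:

- **Two host orders** (A ≈ Thermococcales-like, B ≈ Methanococcales-like),
  default 6 hosts each (60 kb backbones), plus one free (extrachromosomal,
  circular) element per order, and one remnant element (3 retained core
  genes, no att pair, hence no detectable limits).
- **Conserved module**: 12 gene slots named t26-4p…t26-15p of which 7
  (5p, 6p, 7p, 11p, 13p, 14p, 15p) are universal core; each non-core slot
  is carried by a fixed 60% of elements. Variable regions add
  Poisson-distributed (mean 3) random singleton genes. Slot proteins are
  generated by evolving random ancestral sequences down a two-order species
  tree, so the deep split is encoded in sequence divergence and the
  co-evolution claims are recoverable properties, not assumptions.
- **Divergence calibration**: root-to-order-ancestor branches are 0.08
  substitutions/site and within-order trees are rescaled to ≤ 0.08 depth.
  These values are bounded above by the family's defining property — core
  proteins must remain mutual best hits at > 30% normalized score *across*
  orders (as the real family's do) — while staying large enough that the
  two orders form well-separated clades. Raising the divergence breaks the
  cross-order orthology that defines the family, not just the tests.
- **Integration**: order A elements are type I (integrase written split,
  att inside its CDS, varied target tRNA isotypes), order B type II
  (intact integrase mid-element, tRNA-Ser targets with rare Leu,
  probability 0.1). att lengths are drawn from 44–129 nt; attB covers the
  tRNA 3′ end (anticodon included when the draw reaches it) and the tRNA
  T-arm contributes a perfect 5-nt hairpin, so att palindromes are real.
  Implant boundaries are kept crisp: a chance flanking base match that
  would extend the maximal repeat past the designed att is flipped, so the
  implanted att length is well-defined.
- **Codon level**: back-translation uses weighted synonymous codons — a
  GC-skew weight (exp(±1.5·(G−C))) around the origin locus, and one of two
  opposed codon-usage preferences per order. Order-specific usage mimics
  real between-order codon bias: protein identity is untouched while
  silent-site DNA identity drops, which keeps CRISPR spacers (35-nt
  verbatim copies from same-order elements) from matching the other
  order's elements through conserved coding runs. Intergenic gaps end with
  a 15-nt terminator carrying stop codons in all six frames (drawn per
  element, not a shared literal), so maximal ORFs coincide with real genes.
- **Origins**: each non-remnant element gets a skew switch plus an
  iterated-repeat cluster at one locus next to the Rep gene (classes
  assigned per order with probabilities mirroring the family's observed
  mix).
- **CRISPR arrays**: half the hosts (rate 0.5) receive a
  repeat–spacer–repeat array of 4 spacers copied verbatim from same-order
  free elements; provenance is recorded.
- **Transfer**: a within-order horizontal-transfer rate (default 0) makes
  an element lineage adopt another lineage's module proteins, degrading
  element/host tree congruence — used to test that the Robinson–Foulds
  statistic responds monotonically.

Everything is driven by one `numpy` Generator seeded from the config, and
re-runs are byte-identical. The truth set (JSON) records spans, att
coordinates and sequences, per-gene coordinates, family proteins,
integrase type and protein, target tRNA, Rep class, ori interval, host
order/region, and spacer provenance.

**What the generator does not emulate**: realistic archaeal codon usage or
genome composition, gene loss/pseudogenisation gradients, nested or
tandem co-integrates (available via explicit `implant_element` calls but
not in the default design), assembly artefacts, and sequencing error.
Passing the round-trip suites therefore shows the pipeline is correct on
clean signals at realistic divergence — not that it is robust to noisy
assemblies or atypical site architectures.

## Numerical and procedural choices

- Internal coordinates are 0-based half-open everywhere; 1-based inclusive
  only at file boundaries (GFF3, the packaged tables).
- Local/global alignments delegate to Biopython's `PairwiseAligner`
  (leftmost-optimal traceback, hence deterministic); an independent
  hand-written Gotoh DP serves as the test oracle.
- Direct-repeat search seeds on exact k-mers (k = max(12, min_len/3), so a
  valid repeat's exact first third always contains an anchor), extends
  with the mismatch budget, then trims to the longest window satisfying
  the middle-zone rule; hyper-repetitive seeds (> 25 occurrences) are
  skipped as low complexity.
- Proteome extraction suppresses ORFs that are mostly (> 60%) covered by a
  ≥ 1.25× longer ORF; near-equal-length opposite-strand overlaps are all
  kept, because without coding-potential scoring the choice would be
  arbitrary and spurious shadow proteins are not conserved across elements.
- NJ clamps negative branch lengths to zero; saturated distances are
  capped; DistanceMatrix validates symmetry, zero diagonal and finiteness.
- Problem sizes in the test suite: the default dataset (12 hosts + 2 free
  elements, ~10 kb elements) for round trips; 20-seed sweeps for the
  rate-style properties (ori recovery, two-clade recovery, RF
  monotonicity), with the ori sweep at 2 hosts per order since it only
  needs element sequences.

## Known limitations

- Anchoring requires core-protein homology detectable by local alignment;
  elements with no core-gene similarity to the references are invisible.
- The limit caller assumes one element per anchor cluster; two elements
  integrated back-to-back at the same tRNA would be merged or mis-bracketed
  (the att-exchange report flags the signature inversions produce).
- The walktrap community structure and family counts depend on thresholds
  carried over from the source workflow; they are reported, not asserted,
  on synthetic data.
- E-value statistics are not computed; all thresholds are score-ratio or
  identity/coverage based.
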