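# Methods

This note documents the models, estimators and design choices behind
`igevo`, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## Gene-class calling

The caller consumes GFF3 gene/mRNA/exon/CDS features and applies, in
order: (1) require at least one CDS line (genes without CDS are
excluded as `no_cds`); (2) deduplicate records describing the same
locus, keyed by (chromosome, span, strand), first record wins — the
format gives no better identity for "redundant records", so a stricter
key (e.g. identical exon structure) is deliberately not required;
(3) exclude genes on organellar contigs (case-insensitive name set,
default MT/PT and common aliases) — organellar genes are intronless for
reasons unrelated to the nuclear process under study; (4) exclude
unplaced scaffolds, either by a declared chromosome list or by a name
regex (`scaffold|contig|ctg|un` prefixes); (5) choose the
representative transcript as the one with the longest summed CDS,
breaking ties toward the lexicographically smallest transcript id for
determinism. Introns are counted on the representative transcript's
*coding* region (merged CDS blocks minus one): UTR-only exons would
otherwise misclassify genes whose coding sequence is a single block,
and the coding region is what the downstream Ka/Ks machinery sees. A
CDS segment not contained in any exon marks the gene `malformed`
(excluded, logged) rather than aborting the run.

## Homology

Candidate pairs share at least two 12-mers; retained pairs come from an
end-gap-free global alignment (match 2, mismatch −3, gap open −5,
extend −2). Identity is matches over columns where both sequences are
non-gap; coverage is the aligned (both-non-gap) column count over the
shorter sequence's length. Both must reach 0.7. The shorter-sequence
coverage convention keeps the map symmetric, so a truncated copy is
still recovered as a homolog of its full-length parent (an exact prefix
has coverage 1.0). Paralog families are single-linkage connected
components over retained within-genome pairs; the method deliberately
avoids a clustering granularity parameter because the downstream
family rule (below) is threshold-based anyway. Cross-genome orthology
uses the same alignment with reciprocal best hits scored by
identity × coverage.

## NG86 Ka/Ks

Synonymous sites per codon are the fraction of its nine single-base
mutants that preserve the amino acid; mutations to stop codons count as
nonsynonymous so that S + N = 3L holds exactly. Differences between
codons average over all minimal mutational pathways with equal weights;
pathways through stop codons are excluded, and a codon pair whose every
pathway crosses a stop is dropped and logged. The proportions
p = Sd/S and Nd/N receive the Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 flags saturation and yields NaN rather
than a number, and Ks = 0 with Ka > 0 flags an undefined ratio. Input
pairs of unequal length go through a codon-aware aligner (protein-level
global alignment, BLOSUM62, threaded back to nucleotides); gapped or
stop-containing codon columns are dropped in codon units. Divergence
times are T = Ks/(2r), r = 6.5 × 10⁻⁹/site/year, reported in My.
Group summaries report median, quartiles and a seeded 1,000-resample
bootstrap 95% CI of the median (the CI method is the package's choice;
only the level is conventional).

Comparisons between unpaired IG and MEG pair sets use the Mann–Whitney
rank-sum test rather than a paired signed-rank test: pairing is
undefined for unequal, unmatched sets, and the report records which
test was used.

## Duplication typing

Anchors are the homology map restricted to each gene's top five
partners. Chains are strictly monotone in both genomes' gene orders
(descending in one for inverted blocks), with inter-anchor gaps of at
most 25 genes and at least 5 anchors (the MCScanX-family defaults).
Two additional contract details are the package's own: in self
comparisons, near-diagonal hits (|Δorder| ≤ gap bound) are masked so
tandem/proximal arrays cannot chain into fake blocks; and an extracted
chain must be locally dense — median inter-anchor step ≤ gap/3 in both
orders — because at desk scale (hundreds of genes per chromosome) a
handful of scattered transposed copies can otherwise form a "block"
whose every step sits at the gap bound. Blocks failing the density
requirement are discarded, not emitted.

Classification precedence is WGD (pair is a block anchor) > tandem
(adjacent) > proximal (distance ≤ 10) > transposed (exactly one member
outgroup-anchored) > dispersed. Ancestral-locus evidence is membership
as an *interior* anchor in a genome-vs-outgroup block: a chain-terminal
anchor is constrained on one side only and can be a stray hit. Pairs
touching unplaced contigs fall to dispersed with a warning. Every
retained pair receives exactly one label.

Gene-conversion quartets hold two within-genome paralogs and their
reciprocal-best orthologs in a second genome. A quartet is converted
when Ks(a1,a2) < min(Ks(a1,b1), Ks(a2,b2)) and the inequality survives
in ≥ 95% of codon-resampled bootstrap replicates (codons, not
nucleotides, are the resampling unit, matching the estimator's unit;
replicates are drawn jointly across the three pairs when their
alignments share a codon grid, independently otherwise). Quartets with
any saturated Ks among the six distances are skipped and counted.
Conversion rates are reported as converted/total quartets per class
(IG–IG, IG–MEG, MEG–MEG) — the denominator is the package's decision,
recorded because the rate's denominator is otherwise ambiguous.

## Family dynamics

An IG family has a pooled intronless fraction in [0.50, 0.70] and
members in at least ⌈0.60 × n_species⌉ genomes. The upper bound
excludes families so uniformly intronless that they carry no signal
about the IG/MEG transition. The pooled fraction is the default; a
per-genome mode (rule holds in a majority of genomes where present) is
available. Raising the upper bound never removes a flag; raising the
presence requirement never adds one.

Ancestral family sizes minimize total |Δcount| over the tree (Sankoff
dynamic programming over states 0..max leaf count, branch lengths
deliberately ignored — the cost is per event, not per My). Ties resolve
to the smallest count. Per edge, families with child > parent count as
expanded, child < parent as contracted; summed gains and losses obey
parent + gains − losses = child exactly, which is what makes the Sankey
flow table bookkeeping-consistent. Fold change is the summed child
counts over summed parent counts; a zero parent total yields NaN with a
warning. A stochastic birth–death family-size model with significance
testing is intentionally out of scope; the tallies are descriptive.

## Intron gain/loss model

Intron sites evolve independently under a two-state CTMC with gain
rate g (0→1) and loss rate m (1→0), per site per My. The transition
matrix is closed-form; the likelihood is computed by pruning,
vectorized over sites, with unknown leaf states marginalized. Because a
site enters the matrix only if present in at least one leaf, the
default likelihood conditions on the pattern not being all-absent;
without this ascertainment correction the rates are biased by
construction of the data.

The root prior is a free presence probability estimated jointly with
(g, m) by Nelder–Mead on log/logit scales. This is a deliberate choice
over pinning the root at the stationary distribution: intron site
panels are typically far from equilibrium (ancestrally intron-rich and
decaying), and at stationarity the expected numbers of gains and
losses per branch balance exactly, so per-branch Loss% could never
dominate Gain% no matter how large m/g is. With the free root the
model recovers both the simulated rate ratio and the root state; the
stationary prior remains available (`root_prior="stationary"`). When
gains are very rare the gain rate is weakly identified and can run to
the boundary (g→0 with the root prior absorbing the signal) — at a few
hundred sites expect an unstable ratio; two thousand sites are
comfortable on a nine-leaf tree.

Branch histories come from joint maximum-likelihood ancestral states
(max-product over the tree). Loss% is losses over sites present at the
parent (explicitly "parental introns lost"); Gain% is gains over sites
present at the child — the gained-intron percentage needs a
denominator and the child's complement is the one that makes the two
percentages comparable per branch. For real annotations, cross-species
intron-site homology is simplified to rank-within-gene projection onto
families (site "family:i r" present in a genome iff some member there
has ≥ r introns); this is a known limitation — it cannot distinguish
positional homology from equal counts — and the simulator's TruthSet
supplies exact site identities for recovery tests instead.

## Retro density

Windows of 100 bp tile 4 kb upstream of the TSS and 4 kb downstream of
the TTS, laid out strand-aware (upstream means 5′ of the TSS in gene
orientation). A retro element increments every window it overlaps;
window sums per class are divided by the class gene count and averaged
into 500-bp bins (8 + 8). Windows truncated at contig edges keep their
reduced width and are logged. Per bin, IG and MEG densities are
compared by the exact paired signed-rank test over the five window
offsets; five pairs cannot reach two-sided p < 0.05 (the floor is
0.0625), so a pooled test over all 80 windows of both flanks is
reported alongside — the per-bin series shows *where* the enrichment
is, the pooled test *whether* it is there.

## Rank tests

The signed-rank null is built by dynamic programming over doubled
midranks (ties exact); enumeration applies up to 25 non-zero pairs,
beyond that a normal approximation with tie and continuity corrections.
The Mann–Whitney null uses the classic count recurrence, exact for
min(n) ≤ 10 without ties. Two-sided p-values are 2·min(lower, upper)
capped at 1. Zero differences are dropped and counted.

## Synthetic-data generator

The generator runs a forward simulation down a dated nine-leaf tree
with the PO (Pooideae+Oryzoideae) / CP (Chloridoideae+Panicoideae)
clade structure and 50 My root depth. Study conditions (defaults):
2 chromosomes × 500 genes, 5 kb intergenic gaps, codon lengths
100–250, root intron counts Poisson(3), a whole-genome duplication at
the root with 30% copy retention, per-gene per-My rates TD/PD/DSD
1.5 × 10⁻³, TRD 3 × 10⁻³, gene loss 1.5 × 10⁻³, intron gain
5 × 10⁻⁴ and loss 5 × 10⁻³ per site per My (loss-dominant, 10:1),
synonymous rate 6.5 × 10⁻³ per site per My per lineage (= r × 10⁶),
Ka/Ks target 0.3, TRD intron-removal probability 0.9, retro baseline
0.4/kb with ρ = 3 enrichment within ±4 kb of IG bodies. Decoys:
MT (3 genes) and PT (2) contigs, four unplaced scaffolds, and a 2%
redundant-record rate.

Codon evolution is an event-driven (Gillespie) process with uniform
per-option rates: every synonymous single-base change fires at one
rate, every nonsynonymous change at another, stop codons are never
offered. This matches the downstream estimator's assumptions (NG86 has
no rate structure), keeping recovery tests interpretable. One known
approximation: codons adjacent to stops offer fewer nonsynonymous
targets, so realized Ka runs ~4% below target — inside the recovery
tolerance and noted here rather than corrected. Transposed copies
enact the retroposition origin of IGs: the copy moves to a random
position and loses each intron with probability 0.9 (a free parameter,
not an empirical value). Dispersed events displace both copies, which
is the only planting consistent with "neither member at an ancestral
locus". Tandem copies insert adjacently, proximal copies 2–10 genes
away. WGD copies whole chromosomes followed by random fractional loss.
The TruthSet records duplication pairs with times, Markov intron
events per branch, family membership, ancestral family sizes per node,
realized substitution counts per duplicate pair, and the site × leaf
presence matrix.

Dedicated scenario builders keep the recovery experiments sharp: the
duplication scenario plants exactly 50 events per mode (the WGD as a
single-chromosome copy with exact retention so block anchors stay
dense under the fixed chaining defaults); the retro scenario lays 500
genes per class; the quartet simulator implements conversion as
overwriting one paralog with the other midway between speciation and
the present; and the site simulator draws root states present with
probability 0.95 (the intron-rich panel; pass the stationary value for
an equilibrium simulation).

What the generator does **not** emulate — and hence what green tests do
not certify on real data: alternative splicing and isoform choice, UTR
exons (exons equal CDS blocks, so the caller's UTR handling is
exercised only by construction), nucleotide-level retroelement
sequence models (intervals only), chromosomal rearrangements beyond
duplication placements, rate variation across sites or lineages, and
real intron positional homology.

## Problem sizes

Unit and recovery tests run the generator at 9 genomes × 30–120 genes,
400–2,000 intron sites, 200–600-codon quartets and 500 genes per class
for density profiles; the acceptance script uses 10,000-codon pairs
(20 replicates), 250 planted duplications, 2,000 sites and 60
calibration quartets. These sizes are chosen so every recovery
statistic is comfortably inside its tolerance while the whole suite
stays interactive; the estimators themselves are vectorized and run
unchanged at genome scale.
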