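# Methods

This note documents the models and procedures behind `panforge`, the
parameter choices that matter, what the synthetic generator does and does
not emulate, and the numerical conventions.

## Scope and scale

The pipeline targets panels of bacterial draft genomes of one species.
Real panels of this kind run to dozens of strains with ~3 Mb genomes and
~3,000 genes each; all-vs-all protein comparison at that scale is a
cluster job. `panforge` is built and validated at desk scale: the default
synthetic panel has 10 strains with 100 core + 50 accessory protein
families of ~250 residues (plus plasmid families), which keeps every stage
— including all-vs-all alignment — within seconds to a couple of minutes
on one CPU while preserving the structure of the full-scale analysis. All
sizes are configuration, not constants.

## Synthetic panels (`panforge.synth`)

**Protein families.** Each family has a random ancestor protein
(length ~ Normal(mean_gene_len, 15 %), min 80 aa, N-terminal Met). A
strain's copy substitutes each non-initiator residue independently with
probability `within_family_divergence` (default 0.10, giving ~81 % expected
pairwise identity between strain copies). Between-family identity is that
of unrelated random sequences (~6 %), far below the configured
`between_family_min_divergence` = 0.60 separation floor; configurations
where within-family divergence reaches the between-family floor are
rejected as unserviceable. Indels are deliberately excluded: substitution-
only evolution gives exact divergence control with minimal machinery, at
the cost of never exercising gap handling at scale (gaps are still covered
by unit tests of the aligner).

**Nucleotide sequences.** Each family's ancestor is back-translated once
(translation table 11) with synonymous-codon weights softmax(β·GC(codon)),
where β is solved by bisection so the expected GC over a uniform amino-acid
composition equals the target (background default 0.46). Strain copies
reuse the canonical codons and resample only the codons of substituted
residues, so within-family *nucleotide* identity stays high (used by the
known-plasmid criterion) while GC stays on target. Genes flagged as lying
in a phage region are fully re-encoded at `phage_gc` (default 0.40),
emulating the lower GC of prophages; intergenic spacers (60–200 bp) are
i.i.d. bases at the local GC target. Measured over whole planted phage
intervals, mean GC is within ±0.01 of the target (per-interval sampling
s.d. ≈ 0.005 at ~9 kb).

**Genome layout.** One shared gene order (the "reference layout") is drawn
per panel: shuffled core + free accessory families, with accessory islands
inserted as contiguous blocks at backbone boundaries (so islands never
interleave). Island presence is drawn per strain at the island level —
cassette genes co-occur, as real sugar-utilization cassettes do — while
free accessory families are independent Bernoulli draws; either way every
family's marginal presence probability is `accessory_presence_prob`. A
single circular reference genome carries the ancestor copy of every
chromosomal family in layout order; plasmid families never appear on it.

**Fragmentation.** Contig breakpoints are drawn uniformly inside
intergenic gaps only (never splitting genes, CRISPR arrays, or phage
regions), and contig identifiers are assigned in a shuffled order so that
names do not leak the true arrangement; the true order is recorded in the
TruthSet. Real draft assemblies do split genes and collapse repeats — that
failure mode is out of scope, so recovery tests certify the ordering
logic, not robustness to broken gene models.

**Plasmids.** Each planted plasmid is a separate contig carrying a
replication-initiator family, two cargo families, and an exact terminal
repeat of `plasmid_terminal_overlap` bp (default 150) — the signature an
assembler leaves on a circular molecule. The canonical (ancestor) plasmid
sequences are emitted as the "known plasmid" set, so criterion 3
(similarity to known plasmids) is exercised with realistic ~95 %
nucleotide identity.

**CRISPR arrays.** One direct-repeat sequence (default 36 nt, the typical
length for this system) is shared panel-wide; each CRISPR *type* is a
fixed ordered list of unique spacers (default 30 nt, n_repeats−1 of them).
Strains cycle deterministically through type 0 (no locus) and the
configured types, giving both shared and absent arrays for the typing
tests.

**Phenotypes and growth curves.** Each trait is tied to one island: a
strain is positive iff it carries every causal family, then the label is
flipped with probability `label_noise_rate`. OD curves are logistic
(plateau 0.95–1.20 blank-corrected for positives, 0.15–0.45 for
negatives, rate 0.5–0.9 h⁻¹, midpoint 4–10 h) sampled every 20 min over
24 h (73 points) plus a medium-only blank series, with small Gaussian
reading noise. The growth threshold (blank-corrected max OD strictly
above 0.8) therefore separates the classes by construction; what the
pipeline must recover is *which genes* explain the labels.

**Predictor error model.** Each simulated ORF-caller independently drops
true genes (miss rate), adds Poisson spurious ORFs (length 90–600 bp,
random placement), and jitters the *start* coordinate by a uniform
multiple of 3 within ±`boundary_jitter_bp` (stop fixed, frame preserved,
clamped to the contig and a 90 bp minimum). This matches how real
predictors disagree — starts are uncertain, stops are anchored by the stop
codon — and is what makes the stop-anchored vote the right identity
notion.

Everything derives from a single seeded NumPy generator; identical config
and seed reproduce the file tree byte for byte.

## Consensus gene calling (`panforge.genecall`)

ORFs from all predictors of one strain are grouped by (contig, strand,
stop coordinate); the candidate interval is the longest supporter's. A
candidate is accepted when its support strictly exceeds
`min_support_fraction × n_predictors` (default 0.5 — a strict majority,
i.e. ≥3 of 4 predictors). Overlaps are then resolved: while any accepted
pair overlaps by more than 100 bp (measured on nucleotide intervals,
strand-blind; exactly 100 bp is allowed), the pair with the largest
overlap is processed first and its shorter member discarded (equal
lengths: the later-starting ORF), which makes the output deterministic.
Internal coordinates are 0-based half-open; GFF3 conversion happens only
at I/O.

## Ortholog groups (`panforge.ortho`)

**Scoring.** Pairs sharing fewer than max(2, 2 % of the smaller k-mer
count) exact 4-mers are never aligned. The absolute floor of 2 governs
short proteins (two unrelated 100-aa sequences pass it in <1 % of draws);
the proportional term keeps the shared-k-mer null, which grows with the
product of sequence lengths, from flooding long pairs through. Surviving
pairs are scored by local alignment (BLOSUM62, gap open −11 / extend −1,
via Biopython's PairwiseAligner). An edge is kept when score ≥ 50, or when
identity ≥ 0.4 over an alignment covering ≥ 50 % of the shorter sequence
(this second route can only matter below ~60 residues, so longer pairs are
decided on score alone without a traceback). These cutoffs assume the
bimodal divergence regime the generator plants (~0.1 within families,
≥0.6 between); genuinely remote homology at 25–40 % identity would need a
lower prefilter fraction.

**Graph.** Inter-strain edges survive iff reciprocal-best (each endpoint
among the other's best-scoring hits in that strain; ties kept).
Within-strain edges survive iff the score reaches both endpoints' best
inter-strain score (recent in-paralogs); genes with no inter-strain hit
keep their within-strain edges. Weights are normalised by the global
maximum retained score — a simplification of per-species normalisation
that behaves identically on balanced panels.

**Markov clustering.** Per connected component (exact, since expansion
cannot cross components, and it keeps the matrices small): unit
self-loops, column normalisation, then expansion (matrix square) and
inflation (entrywise power 1.5, renormalise) with pruning below 1e-6,
until the maximum entry change is below 1e-8 or 200 iterations
(non-convergence warns and returns the partial result). Clusters are the
connected components of the limit matrix's nonzero pattern — by
construction the partition refines the input components. OG identifiers
are assigned over clusters sorted by member list, so fixed input order
gives identical output.

## Presence/absence analysis (`panforge.panmatrix`)

Presence is binary regardless of copy number; copy counts remain on the OG
records (single-copy core = count exactly 1 in every strain). Singleton
OGs (one gene in one genome) are excluded from the matrix by default, the
usual convention since such families are often gene fragments or
overpredictions. Accumulation curves use 100 seeded random genome
orderings (mean, s.d. and per-permutation values are all reported; a
single cumulative ordering is a special case). Variable regions are
maximal runs of ≥ `min_run` (default 10) consecutively ranked OGs each
present in ≤ `max_presence` (default 0.9) of strains; ranks come from the
pseudo-assembly projection. Cassette presence uses a completeness rule —
a named OG set is present in a strain when ≥ 80 % of its OGs are (there
is no canonical rule for partially assembled cassettes; config-exposed).

## Pseudo-assembly (`panforge.pseudoasm`)

Each query gene is matched to a reference gene by reciprocal best hit
(the same engine restricted to strain-vs-reference); "position" of a hit
is the midpoint (start+stop)/2, symmetric and strand-free. A contig's
coordinate is the mean of its anchors' midpoints; when the anchor spread
exceeds half the circular reference, the small coordinates are shifted up
one turn *only if that reduces the spread* (an unconditional shift
misplaces long contigs that genuinely span half the chromosome). Contigs
sort by mean coordinate, ties broken by length (longer first) then
identifier; anchorless contigs go to an unplaced bin in input order.
Contig orientation is not inferred — ordering only. The GC track is a
sliding window (default 5 kb window, 1 kb step) with ambiguous bases
excluded from numerator and denominator.

## Plasmid classification (`panforge.plasmids`)

Criteria per contig: (1) fraction of genes with a reference-chromosome
ortholog < 0.2 (a contig with no genes yields no evidence on this
criterion); (2) any gene annotation matching a plasmid-function keyword
(replication initiator, rep/mob/tra, relaxase, parA/parB, toxin-antitoxin,
"plasmid"); (3) windows totalling ≥ 50 % of the contig matching a known
plasmid at ≥ 80 % identity (semi-global edlib alignment per 1 kb window,
with an exact 16-mer prescreen); (4) an exact terminal repeat ≥ 50 bp
(found by scanning the tail for the prefix seed — equivalent to the
longest string border ≤ n/2 — so it is exact and fast on long contigs).
Two or more criteria give a confident `plasmid` call, exactly one gives
`putative_plasmid`; the confidence tiers are this package's convention on
top of the qualitative "one or preferably more" rule. The thresholds are
defaults chosen to be conservative at desk scale, all config-exposed.
Mismatched terminal repeats are not detected (assembler overlaps are exact
copies); OGs confined to plasmid-called contigs form the plasmid
pan-genome.

## Trees (`panforge.trees`)

The sequence tree uses per-OG distances 1 − fractional identity from
global alignment of each single-copy core OG, combined as a
length-weighted mean, then canonical neighbor joining (Q-criterion). NJ
recovers any additive matrix exactly (topology and branch lengths), which
is the central correctness property tested; negative branch lengths on
non-additive input are clamped to zero with a warning, and Q-ties break
toward the lexicographically smallest label pair for determinism. A
distance+NJ tree is a deliberate stand-in for concatenated-alignment
maximum likelihood: at within-species divergences the two agree on
relatedness structure, and it removes heavyweight alignment/ML machinery.
The content tree is average-linkage (configurable: complete/single)
agglomeration of Jaccard distances between strains' OG presence vectors,
with ultrametric branch lengths from merge heights and lexicographic
tie-breaking. Both trees are scikit-bio `TreeNode`s and serialise to
Newick round-trip-stably.

## CRISPR detection (`panforge.crispr`)

Exact 12-mers recurring at plausible periods (repeat 23–47 nt + spacer
20–50 nt → period 43–97 nt) nucleate candidates; the repeat window is
extended outward while each column agrees with its consensus up to one
mismatching copy, then boundary columns where copies disagree are trimmed
(majority extension can otherwise step one base into the spacers when
most spacer-edge bases coincide by chance). Arrays need ≥3 repeats, every
copy within `max_repeat_mismatch` (default 1) of the consensus, and all
spacers inside the length band; overlapping candidates resolve to the
highest repeat count. An array touching a contig end is flagged truncated
(draft assemblies frequently break inside repeat arrays). Spacers are
catalogued after reverse-complement canonicalisation (min of the two
orientations). Strain types are exact ordered spacer content — differing
in either number or identity of spacers separates types — with type 0 for
strains without a locus and ids in order of first appearance. A single
mismatch falling inside a seed window of every surviving k-mer chain can
still split a candidate; with ≤1 mismatch per copy and 36 nt repeats
there are always unaffected seed offsets in practice.

## Gene-trait matching (`panforge.gtm`)

Growth calls: blank-corrected maximum OD strictly above 0.8 (readings
subtracted pointwise against the medium-only series; curves with no valid
readings are `missing` and drop that strain for that trait only). Per
trait, a random forest (scikit-learn, 1000 trees, seeded,
`class_weight="balanced_subsample"` to rebalance classes per tree on
small panels) is trained on OG presence features; importance is the
normalised mean impurity decrease, which sums to 1 over features, and OGs
with importance strictly above 0.005 are reported in descending order.
Constant OGs can never be split on and get importance 0. The colouring
fraction is computed among positive-class strains by default (a
positive-vs-negative contrast is available via
`positive_only_fraction=False`): > 0.75 green, < 0.25 red, otherwise
black. Single-class traits are refused — there is no discriminative
signal. No multiple-testing correction is applied across traits.

One property worth stating explicitly: because impurity importances are
normalised per forest, planting a true association *concentrates*
importance mass and tends to reduce the number of OGs above a fixed
threshold, while permuting labels spreads mass and can push more noise
OGs over it. The meaningful permutation-null property — asserted in the
tests — is that the causal OG's importance collapses to the noise floor
and no OG under the null reaches the true association's importance, not
that fewer OGs are selected.

## Pipeline and reproducibility (`panforge.pipeline`)

Stages run in dependency order (gene calling → reference matching →
orthology → matrix/curves → pseudo-assembly → plasmids/trees/CRISPR →
GTM); a stage failure aborts with the stage name while earlier outputs
remain on disk, and a missing growth table skips GTM with a warning.
Annotation is transferred to consensus genes from their reciprocal-best
reference gene. The YAML run config rejects unknown keys by name and
echoes all defaults; the manifest records seed, parameters and a SHA-256
per output file, and a rerun with identical inputs and seed reproduces
every checksum.

## Known limitations

- Substitution-only evolution: no indels, rearrangements (beyond island
  presence/absence), or split genes; recovery results certify algorithmic
  correctness on clean structure, not robustness to assembly artefacts.
- Orthology cutoffs are tuned to the bimodal divergence regime; remote
  homologs and tree-aware orthology are out of scope.
- Pseudo-assembly orders contigs against a single reference and does not
  infer orientation.
- Plasmid circularity requires exact terminal repeats; coverage-based
  copy-number evidence is unavailable in this pipeline.
- cas-gene detection, PAM analysis and spacer–protospacer matching are out
  of scope for the CRISPR module.
- GTM reports association, not causation, and applies no multiple-testing
  calibration across traits.
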