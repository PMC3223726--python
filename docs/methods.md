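# Methods

This note records the models, parameter choices and numerical conventions
behind `regulonkit`, and what the simulator-based validation does and does
not demonstrate.

## Coordinate and sequence conventions

Internal coordinates are 0-based half-open on the forward strand; GFF3 on
disk is 1-based inclusive and BED is 0-based half-open, with conversion
only at the I/O boundary. Genome sequences may contain N; every
window-level operation (palindrome detection, PWM scoring, scanning) skips
windows containing N. Upstream sequences are oriented so that position 0
lies farthest from the start codon; minus-strand regions are reverse
complemented.

## Operons and upstream regions

The spacing model calls an operon as a maximal run of consecutive,
co-directional genes with intergenic gaps ≤ `max_gap_bp` (default 200 bp,
a standard prokaryotic operon-calling distance). The upstream region of an
operon is the intergenic segment 5' of its lead gene, truncated at 350 bp
or at the neighbouring gene body, whichever comes first; regions never
overlap an annotated gene body, but divergently transcribed operons may
share intergenic DNA and then both keep their (overlapping) upstream
regions — divergent TF–target arrangements are common and discarding
either promoter would lose real sites. Training sets use one region per
operon lead gene; a per-gene mode exists for annotations without reliable
operon structure.

## PWM model

Weights are pseudocounted log-odds against a uniform background,

    f(b,j) = (c(b,j) + 0.5) / (N + 2),   w(b,j) = log2(f(b,j) / 0.25),

a site scores the sum of its positional weights, and profile quality is
the information content `Σ f·log2(f/0.25)` in bits. Pseudocount 0.5 and
the uniform background are chosen jointly with the simulator's uniform
intergenic composition, which makes the weights exactly calibrated
log-odds in the recovery experiments. Consensus ties break alphabetically
(A<C<G<T, the `argmax` convention). Symmetrization adds the
reverse-complement-mirrored counts, after which a window and its reverse
complement score identically (|Δ| = 0 to 1e-9 in the property tests);
palindromic runs symmetrize by default.

## Iterative palindrome discovery

A *weak palindrome* is a length-L window (L even) with at most `m`
mismatched complementary pairs; the default `m = ⌈L/4⌉` admits roughly the
top quartile of pairing levels while keeping enumeration cheap. Each weak
palindrome seeds a profile built from itself plus its nearest neighbour
per region (Hamming distance; ties by region order then offset). The
fixed-point iteration scores all weak palindromes, keeps the best-scoring
window per region (first occurrence wins ties), drops the `d`
lowest-scoring regions (`d = ⌊n/5⌋` by default — the "allow a few
sequences to be ignored" behaviour for training sets of uncertain purity),
rebuilds counts and weights, and stops when a previously seen selection
recurs; `max_iter` (50) bounds pathological cycles, and an unconverged
profile competes with its flag set false. Among converged profiles the one
with the largest information content wins; ties break toward the
lexicographically smallest consensus so runs are reproducible.

Two engineering choices keep the all-seeds search tractable on pooled
multi-genome training sets (hundreds of regions, ~10⁴ windows): seed
candidates are ordered by palindromicity (fewest mismatched pairs first,
then region order/offset) and capped at `max_seeds` (500), which
guarantees that near-palindromic implanted sites always seed; and every
visited selection set memoizes the attractor it leads to, so later seeds
stop as soon as they enter known territory. Neither changes the result on
small inputs where all seeds run.

The discovery procedure deliberately models one box per target upstream
region and ungapped, fixed-width, palindromic motifs; gapped/bipartite
models, EM or Gibbs samplers, and automatic width search are out of scope.

## Scanning and the training-minimum threshold

The scan threshold is the lowest score observed among the training
windows, compared with `≥`, which forces self-detection of the entire
training set (verified as zero misses over 20 seeded runs). Symmetric
profiles are scanned on the forward strand only (the reverse strand is
redundant by construction); asymmetric profiles scan both strands. All
hits above threshold are reported without non-overlap pruning; consumers
deduplicate per operon by maximum score. The vectorized scanner is checked
bit-exactly (coordinates, strands, scores) against a plain-loop
sliding-window oracle on 50-kb genomes. No p-value calibration is
attempted: thresholds are training-set-relative by design.

## Orthology

Orthologs are reciprocal best local-alignment hits (Smith–Waterman via
scikit-bio `pair_align`, BLOSUM62, affine gap open 11 / extend 1 under the
`G(k) = o + e·k` convention) with identity = matches / aligned columns
(gap columns in the denominator) ≥ 0.30. Best-hit score ties break by
lexicographic locus tag. Because best-hit selection maximizes over many
alignments, proteins lacking a true counterpart in the partner genome can
pair up through short, high-identity chance alignments; two standard
significance guards screen these out: the alignment must cover ≥ 50% of
the shorter protein, and its Karlin–Altschul expect value
`K·m·n·exp(−λS)` (gapped BLOSUM62 constants λ = 0.267, K = 0.041) must be
≤ 1e-5. True orthologs at ≤ 10% divergence score two orders of magnitude
above this cutoff. Groups are connected components of the BBH graph;
unmatched proteins become strain-specific singletons. Conservation classes
follow the span rule (all / several / one genome) and summary percentages
round to the nearest integer percent. Tree-based refinement of dubious
orthologs is out of scope.

## Regulon reconstruction

The consistency check counts *genomes*: a candidate operon in genome g
survives if orthologs of its lead gene in ≥ 2 other genomes carry a hit
above the (pooled, per-regulon) threshold — presence, not positional
alignment, of the site is required, since site turnover within upstream
regions is common. Functionally linked candidates are retained only from
an explicit user-supplied list and flagged; no automatic inference.

Propagation projects a model-genome seed regulon through orthology,
re-derives the motif on the orthologous upstream regions, scans every
genome encoding the TF, filters, and — when the member repertoire grows —
repeats once from the projection step with the enlarged training set (a
single repeat bounds runtime; configurable). Propagation sets the
region-drop count `d = 0` by default: its training regions are
ortholog-derived and presumed signal-bearing, and dropping regions there
would lift the training-minimum threshold above the dropped true sites
and break self-recall. Ab initio inference keeps `d = ⌊n/5⌋` and flags a
"no confident regulon" warning when the discovered profile's mean column
information content falls below 0.8 bits: profiles overfit to signal-free
regions plateau near 0.5 bits/column, while recovered palindromic signal
stays above ~1 bit/column.

TF attribution scores TF-labelled ortholog groups on three boolean
evidences — a TF gene within two genes of a member operon, a site in the
TF's own upstream region, and exact genome-presence-pattern match — and
returns all groups tying for the most evidences (ties are reported, never
broken: the decision is the curator's). TF-less regulons are first-class
(`tf_group = None`), never silently dropped.

## Expression analytics

Pairwise Pearson correlation excludes constant-profile genes with a
warning instead of propagating NaN; the matrix is forced exactly
symmetric with unit diagonal and clipped to [−1, 1]. Subregulons are
single-linkage connected components of the gene graph with edges where
r ≥ 0.5 (configurable); single-linkage is the simplest rule consistent
with thresholded co-expression heatmaps, and labels are assigned by each
component's alphabetically first gene for determinism.

## The simulator

`SimConfig` defaults define the benchmark conditions: 16 genomes; 20 core,
6 variable and 2 strain-specific-per-genome gene families; ~100-aa
proteins derived from family ancestors by i.i.d. substitutions at rate
0.05 (no indels, keeping alignment identity analytically predictable);
intergenic DNA i.i.d. uniform over ACGT with gaps ≥ 230 bp so each gene
forms its own operon under the default gap; an 18-bp palindromic consensus
(`TTGACAATATATTGTCAA`) implanted once per target upstream in 12 core
families with ≤ 2 point mutations per site; 3 decoy sites carrying the
*same* consensus confined to one genome each (so only the consistency
filter, never the score, can remove them); and a two-block expression
design (6 + 6 target families, within-block Pearson target 0.8 achieved
with noise sd √(1/r − 1), 50 conditions). Ancestor residues are drawn from
Robinson–Robinson-style background frequencies: a uniform amino-acid
composition over-weights rare high-scoring residues (W, C) and makes
chance Smith–Waterman alignments between unrelated proteins far more
significant than in real proteomes. All genes default to the forward
strand; divergent pairs would share intergenic DNA and make a single
implanted site truthfully belong to two operons, blurring ground truth
(strand handling is exercised by hand-built fixtures instead, and a
`minus_strand_fraction` knob exists). Everything is a pure function of the
config including its seed.

What the simulator does **not** emulate — and what passing tests therefore
do not show about real data: phylogenetically structured sequence
evolution and codon structure, GC skew and compositional heterogeneity of
intergenic DNA, indels and domain rearrangements in proteins, multiple
boxes per promoter, operon rearrangement and horizontal transfer, and
condition-structured (non-block) expression covariance. Recovery at 100%
precision/recall on this generator demonstrates internal correctness of
the pipeline under its own model, not expected accuracy on biological
genomes, where thresholds, motif widths and training sets all require
curation.

## Validation problem sizes

The test suite and `scripts/acceptance.py` run: conservation arithmetic on
a 686-group summary (63/320/303 over 16 genomes); motif recovery on the
model genome's 12 implanted upstream regions for 10 seeds; scan–oracle
equivalence on one 50-kb genome; threshold self-consistency over 20 seeded
6-genome runs; consistency-filter discrimination on 10 seeded 16-genome
pangenomes; orthology recovery at 10% divergence (16 genomes, ~26 proteins
each); end-to-end propagation on 10 seeded 16-genome pangenomes; and
subregulon recovery on 10 seeded two-block designs. These sizes keep a
full run in the minutes range on a single CPU while preserving the default
study conditions (16 genomes, 12 target families, ≤ 2 mutations per site,
single-genome decoys).

## Known limitations

RNA-element regulons (riboswitches, attenuators), TF-family HMM
assignment, phylogenetic footprinting and tree construction, and
database-driven annotation are all outside this package's scope. The
iterative discovery is a local search: with pathological seeds it can
converge to background attractors, which the information-content selection
and the palindromicity-ordered seeding mitigate but do not eliminate. The
consistency filter assumes single-copy lead genes within an ortholog
group per genome; in-paralogs are clustered together and treated
interchangeably.
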