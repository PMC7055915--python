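# Methods

This note documents the models, defaults and design choices behind
`tyland`, in the order data flows through the package.

## Curation of raw repeat-annotation hits

Input is the standard 15-column RepeatMasker `.out` dialect (1-based
inclusive coordinates, `C` for the reverse strand, a per-element grouping
id in the last column) against a Ty query library whose entries distinguish
`<family>_LTR` and `<family>_I` records. Four operations are applied in
order:

1. **Divergence filter.** Hits with percent divergence strictly greater
   than 20 are removed; a hit at exactly 20.0% is retained. The filter is
   applied per fragment, before grouping.
2. **LTR relabelling.** Within a hit group containing an internal fragment,
   LTR fragments named for a different family are renamed to the internal
   fragment's family. Groups whose internal fragments disagree about the
   family are flagged and left unchanged.
3. **Tandem splitting.** A group whose fragments alternate
   LTR–I–LTR–I–…–LTR on one strand is split into component LTR–I–LTR
   copies, with each shared internal LTR represented in both neighbouring
   copies (so adjacent BED records overlap at the shared LTR). Groups that
   do not match the clean alternating pattern are left unsplit with a
   warning rather than guessed at.
4. **Fused-solo splitting.** Within a group, the element body is the
   internal fragment(s) plus at most one LTR on each side within
   `gap_tolerance` (default 100 bp) of it; any remaining LTR fragment —
   distal, or supernumerary beyond a complete structure — becomes its own
   solo-LTR record. The tolerance is not derivable from first principles
   and is exposed as a parameter.

**Structural classification.** An element with no internal fragment is a
solo LTR. Otherwise it is full-length iff its *total length* exceeds 95% of
the canonical element length (2×LTR + internal from the library), else
truncated. Total length is the **sum of aligned fragment lengths**, not the
genomic span: this measures sequence completeness and is insensitive to
nested insertions. (Span-based measurement is the other defensible reading;
the choice is documented here and isolated in `classify_structure`.)

Element ids are `<strain>_<f|t|s><serial>` with serials ascending in
(chromosome, start) order — deterministic and stable across runs. Ty1 and
Ty2 solo-LTR counts are pooled in the summary table because their LTRs are
too similar to assign unambiguously.

## K2P divergence and windows

The Kimura 2-parameter distance is computed from transition (P) and
transversion (Q) proportions over *usable* sites — both rows unambiguous
nucleotides — i.e. pairwise deletion of gap/N sites. Pairwise deletion (not
complete deletion) is chosen because the windowed analysis must stay
defined across partially gapped alignment regions. The estimate is NA, with
a recorded reason, when no usable sites remain or either log argument is
non-positive (saturation).

Sliding windows default to 50 bp with a 10 bp step over alignment columns;
a window needs at least `min_usable = 25` comparable sites (half the
window) for a defined distance. Both values are parameters; the window/step
pair matches the standard sliding-window setting for this analysis, the
minimum-sites rule is this package's own declared default.

## Distance clustering

NJ and BIONJ share the Q-criterion pair selection and limb-length formulas
and differ in the reduction step: NJ averages the two distances to the new
node; BIONJ weights them (λ) by a variance model with V initialised to the
distance matrix, clamping λ to [0, 1]. Ties in Q break toward the lowest
label-index pair, making both algorithms deterministic. Negative branch
lengths are retained in the output and logged, never clamped — the tree is
a faithful record of the algorithm's arithmetic. On exactly additive
matrices both methods recover the generating topology and branch lengths;
the suite verifies this exhaustively on random 8-taxon trees and
cross-checks NJ topologies against an independent implementation.

Bootstrap resamples alignment columns with replacement; each internal
bipartition of the point tree gets the percentage of replicate trees
containing it, stored as an integer internal-node label (the newick support
convention). Replicates whose resample yields an undefined K2P pair are
dropped and counted. A majority-rule consensus of the replicate trees is
returned alongside.

## Windowed subfamily assignment and breakpoints

A query aligned with two references is labelled per window by the nearer
reference under K2P; a window is *ambiguous* when either distance is
undefined or the margin |d_a − d_b| is below `margin_threshold` (default
0.02 substitutions/site — at the 0.08–0.12 between-subfamily divergences of
interest, roughly one substitution per 50 bp window, enough to suppress
single-window noise). Breakpoints are called between successive runs of
opposite labels with at least `min_run = 3` informative windows each;
ambiguous windows do not break runs. The reported position is the midpoint
between the bounding windows, mapped to reference coordinates through the
alignment's reference row; localisation accuracy is about half a window
plus one step (±35 bp at defaults).

Because overlapping windows smear a short foreign tract across
~(tract + window)/step windows, `min_run` bounds the *window* run length,
not the tract length; the suite documents this behaviour.

Per-region (*gag*, *pol*) types are the majority label of informative
windows in the region; a region with one or more internal breakpoints is
recombinant; fewer than 50% informative windows, or an exact 0.5 majority,
gives "undetermined" rather than a coin flip. *gag* and *pol* overlap on
the Ty1 frame, so a breakpoint within `edge_margin` (default window + step)
of a region edge is attributed to the boundary, not the interior — this is
what lets an exchange at the *gag*/*pol* boundary classify as a mosaic
(canonical *gag*, Ty1'-type *pol*) rather than flagging both ORFs. In
strain summaries, *gag*-recombinant elements count toward the subfamily
contributing the majority of their *gag*; truncated elements count only if
their retained sequence spans the whole p22 region.

## Reference frame and region coordinates

Region annotations live on the 5,918 bp Ty1-H3 frame (1-based inclusive)
in a packaged YAML: LTRs 1–334 and 5585–5918, *gag* 294–1616, *pol*
1578–5561, following the standard published organisation of the element.
The p22 region defaults to the C-terminal half of *gag* (p22 arises by
internal initiation there); the two alternative p22 start codons, the p18
start, the frameshift heptamer and the helix/antisense lists are
configurable placeholders chosen to be structurally consistent (both p22
starts in the *gag* frame, 72 nt apart) — suitable for synthetic analyses,
and meant to be overridden with curated coordinates for real elements.

Projection of truncated elements onto the reference uses affine-gap
alignment with free end gaps on the reference side only and a near-zero
gap-extension cost (−0.05), so large internal deletions behave like
spliced-alignment introns and the retained fragments appear as separate
blocks. Aligned blocks shorter than 30 bp or below 80% identity are
discarded; an unrelated query therefore projects to nothing. Both
thresholds are parameters with no counterpart stated in the source
analysis.

## Mobility statistics

Frequency = mean replicate revertant count / Ura+ titer (events per viable
cell). The SD is the sample standard deviation (n−1) of per-replicate
frequencies; the alternative reading — SD of raw counts rescaled — differs
only by the same 1/titer factor applied before vs after, and the choice is
flagged here as an interpretation. Detection-limit values ("<x") propagate
as bounds: a fold change over a bound is reported as a lower bound, and
bounded values are excluded from correlation unless explicitly substituted.

Spearman uses mid-ranks; the p-value is an exact enumeration over all rank
permutations when both vectors are tie-free with n ≤ 9, and otherwise the
two-sided t approximation t = ρ√((n−2)/(1−ρ²)) with n−2 df (the
approximation is what reproduces the printed headline p-value on the tied
genotype counts). Fisher's exact test is the standard two-sided
hypergeometric tail; the suite verifies it against full enumeration for
every 2×2 table with margins ≤ 12.

dN/dS is Nei–Gojobori (1986): per-codon mutation-fate enumeration for site
counts, equal-weight pathway averaging for differences, Jukes–Cantor
correction. Mutations to stop codons count as nonsynonymous so that
N + S = 3 × codons exactly. dS saturation (pS ≥ 0.75) and dS = 0 both give
an NA ratio. This is a deliberate counting analogue of maximum-likelihood
codon-model estimation, self-contained by design; its values are not
interchangeable with M0 estimates and are not asserted against them.

## The synthetic-data generator

`plant_genome` lays planted features left to right in i.i.d. uniform ACGT
background (no homology to the Ty library, hence no spurious hits by
construction), separated by 800 bp spacers. The synthetic canonical Ty1 is
334 + 5250 + 334 = 5,918 bp, the length of Ty1-H3; the Ty2-like family is
332 + 5296 bp. Subfamily references evolve from one ancestor: the
Ty1'-like internal at 0.10 substitutions/site (between-subfamily scale; the
true value is not printed anywhere and 0.10 is an explicit, configurable
default), the *S. paradoxus*-like internal at 0.04. Within-element drift
defaults to 0.01.

Substitutions are drawn per site from the closed-form K2P transition
matrix at the requested distance (β t = d/(κ+2), α t = κβt) — same marginal
law as event-by-event simulation, one vectorised draw. κ defaults to 2;
κ = ∞ is the transitions-only limit. Indels default off so synthetic MSAs
are column-aligned without an external aligner. Mosaic elements default to
a single breakpoint at internal coordinate 1282 (element coordinate 1616,
the *gag* ORF end).

Error modes mirror what the curation fixes: LTR mislabelling (only for
elements with an internal region — an isolated solo has nothing to correct
it from), tandem arrays merged under one hit id, nearby solos fused into an
element's group (planted 250 bp away, beyond the default gap tolerance),
and false positives at Poisson rate per 100 kb with divergence uniform in
(25, 45]%. Hit `pct_divergence` is the configured expected divergence, not
re-measured — only its position relative to the 20% threshold matters
downstream. Everything is driven by one integer seed; identical
(config, seed) gives byte-identical output.

Mobility assays are Poisson: replicate event counts ~
Poisson(frequency × cells/ml), titers reported alongside — the idealised
quadruplicate-culture design without plating losses or jackpot events.

**What passing the synthetic oracles does and does not show.** The
generator reproduces the *structure* the pipeline assumes (fragment
patterns, error modes, subfamily divergence, Poisson counting); it does not
model assembly error, nested or degenerate elements, inter-element gene
conversion, rate heterogeneity along the element, or non-Poisson assay
overdispersion. Exact round-trip on synthetic data therefore validates the
pipeline's logic, not its performance on every pathology of real
assemblies.

## Problem sizes

The test suite and the acceptance script use 100 random synthetic genomes
(4–8 elements each, ~30–60 kb), 100 planted-breakpoint simulations plus
100 pure-query controls at reference divergence 0.10, 50 random 8-taxon
trees for NJ/BIONJ recovery, exhaustive 2×2 tables with margins ≤ 12, and
10,000-replicate mobility simulations — sizes at which every stochastic
check is comfortably stable under reseeding.

## Known limitations

- Maximum-likelihood tree inference, ancestral-state reconstruction and
  phylogenetic networks are out of scope; the distance clustering covers
  the subfamily-resolution analyses only, and windowed assignment may not
  reproduce every recombinant call that network-based conflict analysis
  would make.
- The curation heuristics (gap tolerance, alternating-pattern tandem
  detection) resolve the error modes they were designed for; genuinely
  ambiguous fragment patterns are deliberately left unsplit with warnings.
- Region coordinates beyond the LTR/*gag*/*pol* bounds are placeholders
  until curated values are supplied.
- The Spearman exact-permutation branch enumerates n! permutations and is
  restricted to n ≤ 9.
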