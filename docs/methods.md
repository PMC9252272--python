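# Methods

This note documents the models and procedures implemented in `dollotrace`,
the assumptions behind them, the parameters that matter, and the choices
made where the design was genuinely open.

## Characters and their evolution

A TE insertion locus is treated as a binary character over samples:
1 = the insertion is present. The biological premises are:

1. **Homoplasy-free gains.** Two independent insertions at the same genomic
   position on the same strand are vanishingly unlikely, so each locus was
   gained exactly once in the history of the panel.
2. **Clonal inheritance.** Sublines propagate clonally; an insertion present
   in an ancestor is present in all descendants unless a segmental deletion
   removed the carrying haplotype, or the detector missed it (false
   negative).
3. **Polarized root.** The reference genome lacks all these insertions, so
   the natural outgroup is a hypothetical ancestor with state 0 at every
   locus. Trees here keep that ancestor implicit: the `root` node is the
   ingroup MRCA and the edge entering it (branch id `"root"`) is a
   reportable branch that collects characters present in every sample.

These premises are exactly Dollo parsimony: one 0→1 transition per
character, any number of 1→0 transitions. They also set the method's
limits — in regions of recurrent deletion, losses absorb detector noise and
deletions alike, and nothing here estimates *rates* (the number of passages
separating samples is generally unknown, so branch "lengths" are change
counts, not time).

## Locus clustering

Inputs are 6-column BED calls per sample (family encoded in the name column
before a configurable delimiter, default `|`). Processing order:

1. **Masking.** A call is kept only if its interval lies *entirely within* a
   normal-recombination region. Containment rather than mere overlap is
   deliberately conservative: a call straddling the euchromatin boundary is
   ambiguous. Region configs are written 1-based inclusive (the convention
   region boundaries are quoted in, e.g. `chrX:405967-20928973`) and
   converted once on load; everything in memory is 0-based half-open.
   The `INE-1` family is excluded by default (transpositionally dead for
   millions of years; calls on it are artifacts).
2. **Clustering.** Single-linkage on direct overlap (≥1 shared bp) within
   each (chromosome, strand) group; clusters are the transitive closure.
   Because overlap is an interval relation, a start-sorted sweep yields
   exactly the connected components of the pairwise overlap graph (the test
   suite checks this against an explicit union-find oracle). The all-pairs
   alternative (every pair in a cluster must overlap) was considered and
   rejected as stricter than any common detector-merging convention.
3. **Quality filter.** A cluster containing more than one TE family, or any
   sample contributing more than one call, is dropped whole — a locus-level
   retention criterion, not a per-call one.
4. **Matrix.** Rows follow the given sample order; columns are sorted by
   (chrom, start, end, strand, family) and named with canonical ids
   `chrom:start-end:strand:family`, so matrices diff cleanly across runs.
   All-absent columns are invalid by construction.

## Dollo cost and tree search

For a character with present-leaf set `P` on a rooted binary tree, the
minimal Dollo cost is `1 + |loss edges|`, where the gain sits on the edge
into `MRCA(P)` and loss edges leave the spanning subtree of `P` into
subtrees without carriers. The implementation encodes `P` and each node's
leaf set as 64-bit masks and evaluates all characters at once:
`cost(c) = E0(c) − T(c) + 2`, with `E0` the number of carrier→non-carrier
edges and `T` the number of nodes whose subtree contains all carriers (the
MRCA plus its strict ancestors, each of which sheds exactly one
carrier→non-carrier edge that is *not* a loss). A brute-force oracle that
enumerates every internal-state assignment (≤12 internal nodes) verifies
this formula across randomized tests.

**Heuristic search.** Each of 50 replicates draws a random taxon-addition
order, builds a starting tree by greedy stepwise insertion, and hill-climbs:
steepest-descent NNI until stuck, then a first-improvement scan of SPR
(subtree prune-and-regraft) rearrangements, returning to NNI after any SPR
improvement. NNI alone proved insufficient — on a small fraction of random
matrices it stalls one step short of the optimum — and the SPR escape
restores exact agreement with the exhaustive search on every tested 5–8
taxon instance. Ties keep the first tree found; all randomness flows from
one integer seed, and sample order is canonicalized internally so results do
not depend on matrix row order. A strict-consensus view of co-optimal trees
is available from the exhaustive search, but the pipeline reports a single
most-parsimonious tree.

**Exhaustive search** enumerates all `(2n−3)!!` rooted binary topologies for
n ≤ 8 taxa and returns every length-optimal tree. It exists as the
equivalence gate for the heuristic, and for tiny panels.

**Bootstrap.** Loci (columns) are resampled with replacement to the original
matrix size, 100 replicates by default; replicate `r` seeds both the
resampling and its search with `seed + r`. Support of each rooted clade of
the best tree is its frequency among replicate trees. Bootstrap replicates
use NNI-only hill climbing with 10 addition replicates — the customary
lighter setting for resampling analyses; support values are frequencies, not
optimality claims, and tolerate the cheaper search.

**Tree comparison** uses the rooted Robinson–Foulds distance (symmetric
difference of ingroup clade sets), since the hypothetical ancestor fixes
polarity.

## Ancestral events

Once the tree is fixed the minimal Dollo reconstruction is unique, so
per-branch event tables need no further search. Each matrix column
contributes exactly one gain (conservation: Σ gains = number of columns) and
its losses lie strictly inside the gained clade; Σ(gains + losses) equals
the tree length. Counts are reported raw; the `log10(count + 1)` transform
is applied only in the heatmap export, whose rows are sorted by total gains
per family (descending, ties alphabetical) and whose columns follow preorder
branch order.

## Copy-number profiling

Inputs are per-window tables (chrom, start, end, count, gc, mappability) —
deliberately not BAMs, to keep the package self-contained; producing such
tables from alignments is a documented extension point. Defaults follow
standard read-depth practice on fly genomes: 10 kb windows, windows with
mappability < 0.85 excluded (threshold inclusive at 0.85), expected count
modeled as a cubic polynomial of GC fitted on windows with GC in
[0.30, 0.45] (the degree drops automatically if the fit windows carry fewer
distinct GC values). Ratios are rescaled so the median over retained windows
is 1.0, which assumes the majority of the genome sits at baseline ploidy.
Copy number is `ratio × ploidy`; status compares `round(cn)` (half-up) with
the ploidy. Consecutive same-status windows merge into segments and
non-neutral runs shorter than 5 windows are relabelled neutral — simple
run-merging instead of full segmentation, which is sufficient for the
shared-CNV comparisons made here (per-window Poisson noise alone would
otherwise mislabel ~20% of neutral windows at typical depth). Exclusively
shared CNVs are windows where every sample in a set has the same non-neutral
status and every sample outside it is neutral.

Not implemented: allele-frequency (BAF) analysis, contamination and
subclonality estimation, LASSO-style segmentation.

## Occupancy spectra and model discrimination

The occupancy spectrum is the histogram of column sums of a (typically
region-restricted) matrix. Restriction keeps loci *fully inside* the region
and drops columns that become all-absent. The `burst_fraction` statistic —
the fraction of loci carried by every sample — is 1 under a pre-divergence
burst without deletions and 0 when all insertions are terminal.

The classifier formalizes a comparison the occupancy histogram otherwise
makes only qualitatively: simulate spectra under a **burst** config (all
insertion mass on the pre-root branch) and an **ongoing** config (the same
expected locus total spread evenly over ingroup branches), sharing tree and
sample count; compare the observed normalized spectrum to each model's mean
normalized spectrum by total-variation distance; return the closer label, or
`indeterminate` when the distances differ by less than a tolerance (default
0.02). TV distance was chosen as the simplest metric faithful to "which
histogram does this look like"; no likelihood-ratio machinery is implied.
Detection noise (false negatives) is simulated under *both* models so the
decision cannot reduce to "is occupancy N or N−1". Deletions are disabled in
these simulations, mirroring the analysis's restriction to regions without
shared copy-number losses; configs with deletion events are refused.

## The simulator

`simulate_evolution` draws, per branch and family, Poisson(λ) insertions
with uniform position inside normal-recombination regions, uniform strand,
and uniform haplotype in `1..ploidy` (default 4 — cultured fly cells are
typically tetraploid). Insertions are points; emitted calls get breakpoint
jitter of up to J bp (default 3) outward on each side, so same-locus calls
always contain the insertion point (hence always overlap directly) without
being identical. Same-(chrom, strand) insertions are kept ≥50 bp apart by
redrawing, which both enforces the homoplasy-free premise and prevents
distinct loci from merging under jitter. Segmental deletions remove loci on
the affected haplotype(s) inside the interval from all descendants of the
deletion branch; gains on the deletion branch itself are treated as
preceding the deletion, and insertions arising later in descendant lineages
are unaffected. Detector noise is i.i.d. per (sample, locus) false-negative
dropout plus Poisson-distributed private false positives; a copy-number-
dependent false-negative mode would be more realistic (dropout rises where
coverage falls) but is deliberately out of scope.

Window depth is Poisson(mean_count × cn/ploidy × bias(gc)) with GC drawn
from Normal(0.40, 0.025) clipped to [0.30, 0.48] — fly-euchromatin-like,
with the bulk inside the GC-correction's expected range — and a configurable
fraction of low-mappability windows.

Default study conditions, chosen once: genome = the five fly major arms with
their euchromatic normal-recombination regions; recovery simulations use 12
taxa and 30 expected gains per branch (enough signal per branch to make
topology recovery a property of the method, not of luck, while staying
desk-scale); model-discrimination simulations use 500 loci and a 5%
false-negative rate; depth simulations use mean 100 reads per 10 kb window.
Per-branch insertion rates are free parameters of the simulator — nothing
here claims to estimate real per-passage rates.

What the simulator does *not* emulate: read-level artifacts (mapping bias,
coverage waviness beyond GC), CN-dependent detection sensitivity, TE
sequence evolution, and cross-sample contamination. Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
stated model, not robustness to every failure mode of real detector output.

## Numerical and degenerate-input conventions

- Coordinates: 0-based half-open internally; 1-based inclusive in configs
  and region strings, converted exactly once on load.
- Ties in tree search keep the first candidate in a fixed deterministic
  order; ties in heatmap row sorting break alphabetically; `cn` rounds
  half-up.
- Characters present in all samples are retained (they cost 1 and land on
  the pre-root branch); all-absent characters are invalid in matrices and
  rejected by event reconstruction.
- Readers reject malformed records (wrong column count, inverted intervals,
  strand outside {+,-}) with the offending line number rather than skipping.
- Derived seeds are small fixed offsets from the user seed (`seed + r` for
  bootstrap replicate r; `seed + 1`/`seed + 2` separate the simulator's
  emission and depth streams from its evolution stream).

## Known limitations

- Dollo parsimony is conservative about terminal-branch counts: false
  positives inflate terminal gains and false negatives appear as terminal
  losses; internal-branch counts are robust to both.
- The heuristic search carries no optimality guarantee beyond the ≤8-taxon
  equivalence gate; panels far larger than a few dozen taxa would warrant a
  stronger swap (TBR) or dedicated software.
- The CNV caller assumes the dominant copy-number state is the baseline
  ploidy (median rescaling) and makes integer-CN calls only.
- Bootstrap support on rooted clades assumes the all-absent ancestor is the
  correct root; it cannot detect a mis-rooted ingroup.
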