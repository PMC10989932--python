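# Methods

## Trees

A tree is a rooted node structure with optional branch lengths in expected
substitutions per site. A basal node with exactly two children marks a
rooted tree; a basal multifurcation is the unrooted representation.
Branch lengths may be absent; every statistic that needs them raises a
`TreeError` naming the offending edge rather than assuming zero. Parsing
(Newick and NEXUS trees blocks, translate tables honored) is delegated to
dendropy with `preserve_underscores`, because extraction labels of the form
`Genus_species_ACC` must survive verbatim; square-bracket comments are
stripped and internal node labels are carried as support annotations that
play no role in any computation. The writer emits branch lengths with up to
10 significant digits, which bounds round-trip error at ~1e-10 relative.

Restructuring conventions, all deterministic:

- **Outgroup rooting** places the new root on the single edge separating
  the outgroup from the rest, splitting that edge into two *equal halves*.
  Root-to-tip lengths depend on this convention (an alternative would be to
  keep the full length on one side); patristic distances do not, and both
  facts are asserted by tests. An outgroup not separable by one edge is an
  error that reports the offending split.
- **Unrooting** merges the two root-incident edges (lengths summed) and
  attaches the merged edge under the first-listed root child, conserving
  total branch length and the patristic matrix.
- **Polytomy resolution** groups children left-to-right in input order —
  `(k1,k2,k3,k4)` becomes `(k1,(k2,(k3,k4)))` — inserting zero-length
  edges by default, which leaves the patristic matrix unchanged.

## Tree statistics

*Patristic distances* are computed by a single postorder sweep that merges
per-child leaf-distance lists (O(n²) overall), and are checked in tests
against two independent routes: a brute-force parent-chain oracle and
dendropy's phylogenetic distance matrix.

*LB scores* follow `LB_i = (PD̄_i / PD̄_all − 1) × 100`. Because the mean
of the `PD̄_i` equals `PD̄_all` algebraically, the scores sum to zero;
this identity is verified numerically to 1e-9 over 1000 random trees. The
"overall" summary reports mean, sample standard deviation (n−1), min and
max of the per-taxon scores — the standard deviation being the natural
single-number heterogeneity summary; the per-tree summary file is labeled
accordingly rather than asserted to match any particular external tool.

*Spurious species* uses the median over **all** edges (terminal and
internal; the root has no edge), and flags a tip when its terminal branch
is **≥** threshold × median — "at least" makes the boundary case a hit.
All-zero branch lengths are a degenerate-tree error.

*Treeness* counts an edge as internal when its child is not a leaf. With
the root stem absent this is exactly "internal branch length / total
branch length" and lies in [0, 1].

*Evolution rate* is total branch length divided by the number of tips.

## Composition, RCV, signal-to-noise

Character counts `c_ij` are **weighted counts, not proportions**: the RCV
formula divides by `n·t` itself, so feeding it raw counts matches the
formula literally. `t` is the full alignment length; gaps and '?' simply
contribute no counts. IUPAC degenerate symbols are spread evenly over
their constituent states (two-fold symbols ½ each, three-fold ⅓, N ¼;
protein B/Z/J ½ each, X 1/20 each). Per-taxon RCV is the additive
decomposition `RCV_j = Σ_i |c_ij − c̄_i| / (n·t)`, chosen so the species
values sum exactly to the overall value. Signal-to-noise is
treeness / RCV and errors on RCV = 0 (a perfectly homogeneous alignment
has no defined ratio).

Two different ambiguity conventions coexist deliberately: composition
weights degenerate symbols fractionally (that is what the RCV definition
prescribes), while pairwise difference/identity uses pairwise deletion —
only columns where *both* sequences carry an unambiguous state are
compared. Each convention matches the intent of its own formula.

## Saturation regression

x = patristic distance, y = observed pairwise difference, one point per
usable pair (pairs with zero comparable sites are excluded; fewer than
three usable pairs or zero variance in x is an error). The default fit is
ordinary least squares **with** intercept; a through-origin fit is
available and reported alongside, with the uncentered
r² = (Σxy)²/(Σx²·Σy²) so the value stays in [0, 1]. A constant-y input
returns slope 0 and r² 0 rather than NaN.

## Sequences, codes, extraction

Alignment I/O goes through Biopython (FASTA wrapped at 60; *relaxed*
sequential PHYLIP, since strict 10-character names would truncate
organism_accession labels; NEXUS data blocks with datatype, `missing=?`,
`gap=-`). Sequences are uppercased on read and RNA 'U' is normalized to
'T'; the alphabet is auto-detected (≥ 90 % of non-gap characters in
{A,C,G,T,U,N} ⇒ nucleotide) unless overridden.

Genetic codes wrap the NCBI tables bundled with Biopython, restricted to a
registry of tables 1, 2, 3, 4, 5, 9, 11, 13 and 14 (the common nuclear and
organellar codes, including the echinoderm/flatworm mitochondrial table 9);
the registry is extensible at run time. The test-suite compares every
bundled table against the published NCBI 64-codon strings frozen from an
independent source (Biostrings' `getGeneticCode`). Translation drops an
incomplete final codon with a warning, renders internal stops '*' with a
warning, optionally strips a terminal stop, and resolves degenerate codons
only when every IUPAC expansion agrees (GGN → G, ATN → X) — the
conservative choice.

GenBank extraction concatenates a feature's intervals in ascending order
and reverse-complements the whole on the minus strand, which implements
`complement(join(...))` semantics. Gene-name lookup normalizes to
lowercase alphanumerics and consults `/gene` then `/product`; unmatched
names are still extracted under their normalized form and tallied into
`name_for_unification.tsv`, so extraction is total and the report drives
the curate-and-reimport loop. CDS translation uses the feature's own
`/transl_table` when annotated, else the run-level code table.
Deduplication groups records by the full (case-insensitive) genome
sequence and keeps one per group, preferring accessions starting `NC_`
(the RefSeq copy), else the first encountered.

## Supermatrix

Missing whole genes are padded with '?', while gaps inside present genes
remain '-' — the two symbols mean different things downstream. Taxon
matching is exact string equality. Partitions are contiguous, 1-based
inclusive, in gene-map insertion order; codon-strided charsets are written
with `\3` stride notation. Back-translation verifies each protein row
against the translation of its coding sequence before emitting codons
(terminal stop tolerated; mismatches name the taxon and position); '-'
becomes '---' and '?'/'X' become '???' while still consuming a codon.
Frameshift sanitization replaces '!' everywhere and '*' only in nucleotide
data, where it is an aligner artifact; in protein data '*' is a real stop.

## Synthetic data

The simulator provides the study conditions for every stochastic test. A
pure-birth (Yule) topology with birth rate 1 and exponential waiting times
yields trees whose expected depth grows like log n; a scale factor
multiplies all branch lengths. Sequence evolution is Jukes–Cantor only: a
site changes along a branch of length b with probability
`¾(1 − e^(−4b/3))`, uniformly to one of the other three bases, so the
expected observed difference at patristic distance d has the closed form
`¾(1 − e^(−4d/3))` used as the oracle. "Low divergence" in the tests and
the acceptance script means scale 0.02 (pairwise distances ≲ 0.1
substitutions/site, where the difference–distance relation is still nearly
linear and slope recovery lands near 1); the saturated contrast uses 10×
that scale. Sequence length 10 000 keeps the Monte-Carlo standard error of
a pairwise difference below 0.005 so 3-SE bands are tight; tree sizes of
16 (statistics) and 4–64 (LB identity sweep) keep the full suite in
seconds. The generator is seed-deterministic (seed plus a per-purpose salt
feeds numpy's PCG64), and the GenBank emitter lays genes head-to-tail with
fixed spacers so coordinates are exactly derivable.

What the simulator does *not* emulate: indels (alignments are gap-free
until gaps are inserted synthetically), rate heterogeneity across sites,
compositional bias, unequal base frequencies, or realistic mitogenome
architecture. Passing tests therefore demonstrate correctness of the
computations and their invariants — not robustness of the diagnostics on
messy empirical data.

## Known limitations

- NeXML/PhyloXML input is not parsed (no reliable dialect to target).
- Only the JC model is simulated; saturation behaviour under richer models
  is monotone in the same direction but is not exercised.
- The per-species RCV decomposition and the content of the LB "overall"
  summary are this package's own documented choices where no single
  published convention exists.
- Rendered figures are out of scope; the regression emits `plot_data.tsv`
  for external plotting.
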