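# phylokit

Supermatrix construction and tree-based diagnostics for multilocus
phylogenetics, with a focus on organellar (mitogenome-style) datasets.

Multilocus phylogenies are built from many single-gene alignments that have
to be extracted from GenBank records, reconciled under one gene name,
concatenated into a supermatrix, and — once a tree exists — vetted for the
classic failure modes: long-branch attraction, substitution saturation,
compositional bias, and rogue taxa. `phylokit` implements that bespoke glue
and the diagnostic panel as a plain Python library with a thin CLI; the
heavy standard steps (alignment, trimming, model selection, tree inference)
belong to their own dedicated tools and are deliberately out of scope.

## What it computes

For a tree with branch lengths (substitutions/site):

- **Patristic distances** `d(i,j)`: sum of branch lengths on the path
  between tips *i* and *j*; and per-taxon **root-to-tip lengths**.
- **Long-branch scores**: `LB_i = (PD̄_i / PD̄_all − 1) × 100`, where
  `PD̄_i` is taxon *i*'s mean patristic distance to the other taxa and
  `PD̄_all` the mean over all pairs. The scores of a tree always average
  to zero; large positive values flag lineages prone to long-branch
  attraction, without depending on where the tree is rooted.
- **Spurious ("rogue") species**: tips whose terminal branch is at least
  *k* times the median branch length (default *k* = 20).
- **Treeness** (stemminess): internal branch length over total branch
  length, and **evolution rate**: total branch length over the number of
  tips.

For an alignment of *n* taxa and *t* sites:

- **RCV** (relative composition variability):
  `RCV = Σ_i Σ_j |c_ij − c̄_i| / (n·t)`, where `c_ij` is the weighted count
  of state *i* in taxon *j* (IUPAC degenerate symbols contribute fractional
  counts: Y = ½C + ½T, D = ⅓A + ⅓G + ⅓T, ...). **Signal-to-noise** is
  treeness / RCV.
- **Pairwise differences/identities** (p-distances under pairwise deletion)
  and the **saturation regression** of pairwise difference (y) on patristic
  distance (x): multiple hits depress the slope and r².

Around these sit GenBank gene extraction (alias-table name unification,
RefSeq-aware deduplication of identical genomes, strand-aware interval
assembly, translation under NCBI code tables incl. table 9), '?'-filled
concatenation with NEXUS/RAxML partition output, codon-position selection,
protein-to-codon back-translation, frameshift-mark sanitization, iTOL
simple-bar datasets, and a seed-deterministic Yule/Jukes–Cantor simulator
that generates every input the test-suite needs.

## Worked example

```python
from phylokit import parse_newick, lb_scores, treeness, spurious_species

tree = parse_newick("((A:1,B:2):1,(C:3,D:4):2);")
report = lb_scores(tree)
for taxon in report.taxa:
    print(taxon, round(report.lb[taxon], 4))
print("treeness", round(treeness(tree), 6))
print("flagged", spurious_species(tree, threshold=1.5)[0])
```

prints

```
A -14.2857
B -4.7619
C 4.7619
D 14.2857
treeness 0.230769
flagged ['C', 'D']
```

A and B sit closer than average to the rest of the tree (negative scores),
D is the most distant (+14.29 %); the scores sum to zero by construction.
Treeness 3/13 says less than a quarter of the evolutionary change happened
on internal branches. At a permissive 1.5× the median branch length, C and
D are flagged as potential rogue taxa; at the default 20× nothing is.

The same analyses run from the shell, writing the CSV/iTOL files:

```sh
phylokit treestats --analysis lb --tree mytree.nwk --out lb_results
phylokit extract mito.gb --code-table 9 --out extraction
phylokit concat extraction/genes_nt/*.fas --split-codon 12 --out concat
```

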