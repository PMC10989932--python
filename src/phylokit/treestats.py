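"""Tree-based diagnostics for phylogenetic datasets.

The statistics implemented here are the standard panel used to vet
multilocus datasets before (or after) tree inference:

* **patristic distances** -- tip-to-tip path sums over branch lengths;
* **long-branch (LB) scores** -- per-taxon percent deviation of the mean
  patristic distance from the tree-wide mean, ``LB_i = (PD_i / PD_all - 1)
  * 100``; a diagnostic for long-branch-attraction propensity that, unlike
  root-to-tip length, does not depend on the position of the root;
* **spurious-species detection** -- terminal branches at least ``k`` times
  the median branch length (default k = 20);
* **treeness** (stemminess) -- fraction of total branch length on internal
  branches;
* **RCV** (relative composition variability) -- mean absolute deviation of
  per-taxon character composition from the average composition, normalized
  by taxa x sites, with IUPAC degenerate symbols contributing fractional
  counts;
* **signal-to-noise** -- treeness divided by RCV;
* **pairwise sequence statistics** -- p-distances and identities under
  pairwise deletion of gaps and ambiguity codes;
* **saturation regression** -- observed pairwise difference (y) against
  patristic distance (x); multiple hits at the same site flatten the slope
  and erode r^2;
* **evolution rate** -- total branch length divided by the number of tips;
* **root-to-tip lengths** -- per-taxon path length to the root (rooted
  trees only; this one *does* depend on the rooting convention).
"""

from __future__ import annotations

import itertools
import statistics as _stats
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

from .seqio import AMINO_ACID, NUCLEOTIDE, AA_AMBIGUITY, AlignedMatrix, NT_AMBIGUITY
from .treeio import Node, PhyloTree, TreeError

__all__ = [
    "DistanceMatrix",
    "LBReport",
    "CompositionProfile",
    "SaturationResult",
    "patristic_matrix",
    "root_to_tip_lengths",
    "lb_scores",
    "spurious_species",
    "treeness",
    "composition_profile",
    "rcv",
    "signal_to_noise",
    "pairwise_sequence_stats",
    "saturation_regression",
    "evolution_rate",
]


@dataclass
class DistanceMatrix:
    """Symmetric taxon-by-taxon distances with a declared metric kind."""

    taxa: list[str]
    values: np.ndarray
    kind: str  # 'patristic' or 'p_distance'

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxon list")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])

    def pairs(self):
        for i, j in itertools.combinations(range(len(self.taxa)), 2):
            yield self.taxa[i], self.taxa[j], float(self.values[i, j])


@dataclass
class LBReport:
    taxa: list[str]
    lb: dict[str, float]          # LB_i, percent
    mean_pd: dict[str, float]     # PD_i: mean patristic distance to the others
    overall_mean_pd: float        # PD_all: mean over all pairs
    summary: dict[str, float] = field(default_factory=dict)


@dataclass
class CompositionProfile:
    states: list[str]
    counts: np.ndarray       # states x taxa, weighted counts
    taxa: list[str]
    t: int

    @property
    def n(self) -> int:
        return len(self.taxa)

    @property
    def mean_counts(self) -> np.ndarray:
        return self.counts.mean(axis=1)


@dataclass
class SaturationResult:
    records: list[dict]      # pair, patristic, difference, identity, compared
    slope: float
    intercept: float
    r_squared: float
    fit: str                 # 'ols_intercept' or 'through_origin'

    def plot_data_tsv(self) -> str:
        lines = ["taxon_1\ttaxon_2\tpatristic_distance\tpairwise_difference"]
        for rec in self.records:
            a, b = rec["pair"]
            lines.append(f"{a}\t{b}\t{rec['patristic']:.6g}\t{rec['difference']:.6g}")
        return "\n".join(lines) + "\n"


# -- tree metrics ---------------------------------------------------------


def patristic_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Tip-to-tip distances: the sum of branch lengths on each leaf pair's path.

    Invariant to where the tree is rooted.
    """
    tree.require_lengths()
    leaves = tree.leaves()
    taxa = [leaf.label for leaf in leaves]
    index = {id(leaf): i for i, leaf in enumerate(leaves)}
    n = len(taxa)
    dist = np.zeros((n, n))

    # postorder merge: at each internal node, combine child leaf sets
    below: dict[int, list[tuple[int, float]]] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            below[id(node)] = [(index[id(node)], 0.0)]
            continue
        groups = []
        for child in node.children:
            entries = [(i, d + child.length) for i, d in below.pop(id(child))]
            groups.append(entries)
        for g1, g2 in itertools.combinations(groups, 2):
            for i, di in g1:
                for j, dj in g2:
                    dist[i, j] = dist[j, i] = di + dj
        below[id(node)] = [entry for g in groups for entry in g]
    return DistanceMatrix(taxa=taxa, values=dist, kind="patristic")


def root_to_tip_lengths(tree: PhyloTree) -> dict[str, float]:
    """Path length from each leaf up to the root.

    Requires a rooted tree (root with exactly two children): on an unrooted
    representation the value would depend on an arbitrary basal node, so
    root with an outgroup first.
    """
    if not tree.is_rooted:
        raise TreeError(
            "tree is unrooted: root it first (e.g. with set_outgroup) before "
            "computing root-to-tip lengths"
        )
    tree.require_lengths()
    out: dict[str, float] = {}

    def _walk(node: Node, acc: float) -> None:
        if node.is_leaf:
            out[node.label] = acc
            return
        for child in node.children:
            _walk(child, acc + child.length)

    _walk(tree.root, 0.0)
    return out


def lb_scores(tree: PhyloTree) -> LBReport:
    """Long-branch scores: LB_i = (PD_i / PD_all - 1) * 100.

    PD_i is taxon i's mean patristic distance to the other n-1 taxa and
    PD_all the mean over all n(n-1)/2 pairs; consequently the LB scores of
    a tree always average to zero. The summary holds mean, sample standard
    deviation, min and max of the per-taxon scores.
    """
    if tree.n_leaves < 3:
        raise TreeError("LB scores need at least 3 leaves")
    dm = patristic_matrix(tree)
    n = len(dm.taxa)
    row_means = dm.values.sum(axis=1) / (n - 1)
    overall = float(dm.values.sum() / (n * (n - 1)))
    if overall == 0:
        raise TreeError("mean patristic distance is zero: LB scores undefined")
    lb_values = (row_means / overall - 1.0) * 100.0
    lb = {taxon: float(v) for taxon, v in zip(dm.taxa, lb_values)}
    scores = list(lb.values())
    summary = {
        "mean": float(np.mean(scores)),
        "sd": float(_stats.stdev(scores)) if n > 1 else 0.0,
        "min": float(min(scores)),
        "max": float(max(scores)),
    }
    return LBReport(
        taxa=dm.taxa,
        lb=lb,
        mean_pd={taxon: float(v) for taxon, v in zip(dm.taxa, row_means)},
        overall_mean_pd=overall,
        summary=summary,
    )


def spurious_species(tree: PhyloTree, threshold: float = 20.0):
    """Flag taxa whose terminal branch is >= threshold x median branch length.

    The median is taken over every edge of the tree (terminal and internal;
    the root carries no edge). The default multiplier of 20 is the
    conventional cutoff; 'at least' means the boundary case is flagged.
    Returns (flagged taxa, median, per-taxon terminal lengths).
    """
    if threshold <= 0:
        raise TreeError("threshold must be positive")
    tree.require_lengths()
    lengths = [node.length for node in tree.edges()]
    median = float(_stats.median(lengths))
    if median == 0 and all(v == 0 for v in lengths):
        raise TreeError("degenerate tree: all branch lengths are zero")
    terminal = {leaf.label: float(leaf.length) for leaf in tree.leaves()}
    flagged = [taxon for taxon, length in terminal.items() if length >= threshold * median]
    return flagged, median, terminal


def treeness(tree: PhyloTree) -> float:
    """Fraction of total branch length on internal branches (in [0, 1])."""
    tree.require_lengths()
    total = tree.total_branch_length()
    if total == 0:
        raise TreeError("total branch length is zero: treeness undefined")
    internal = sum(node.length for node in tree.edges() if not node.is_leaf)
    return internal / total


def evolution_rate(tree: PhyloTree) -> float:
    """Total branch length (internal + terminal) divided by the number of tips."""
    if tree.n_leaves < 1:
        raise TreeError("tree has no leaves")
    return tree.total_branch_length() / tree.n_leaves


# -- composition ----------------------------------------------------------

_NT_STATES = ["A", "C", "G", "T"]
_AA_STATES = list("ACDEFGHIKLMNPQRSTVWY")


def _weight_tables(alphabet: str):
    if alphabet == NUCLEOTIDE:
        states = _NT_STATES
        table: dict[str, dict[str, float]] = {}
        for sym, members in NT_AMBIGUITY.items():
            core = members & set(states)
            if not core or sym == "U":
                continue
            table[sym] = {m: 1.0 / len(core) for m in core}
        table["U"] = {"T": 1.0}
        return states, table
    states = _AA_STATES
    table = {s: {s: 1.0} for s in states}
    for sym, members in AA_AMBIGUITY.items():
        table[sym] = {m: 1.0 / len(members) for m in members}
    return states, table


def composition_profile(aln: AlignedMatrix) -> CompositionProfile:
    """Weighted per-taxon character counts with IUPAC degenerate expansion.

    A degenerate symbol is spread evenly over its constituent states (Y
    counts 1/2 C + 1/2 T; D counts 1/3 each of A, G, T; N 1/4 each; for
    proteins B, Z, J split in half and X spreads over all twenty). Gaps and
    '?' contribute nothing. ``t`` is the full alignment length including
    gap-containing columns.
    """
    states, table = _weight_tables(aln.alphabet)
    state_index = {s: i for i, s in enumerate(states)}
    counts = np.zeros((len(states), aln.n))
    for j, (_, seq) in enumerate(aln.rows):
        for ch in seq:
            weights = table.get(ch)
            if weights is None:
                continue
            for state, w in weights.items():
                counts[state_index[state], j] += w
    return CompositionProfile(states=states, counts=counts, taxa=aln.labels(), t=aln.t)


def rcv(aln: AlignedMatrix) -> tuple[float, dict[str, float]]:
    """Relative composition variability, overall and per taxon.

    RCV = sum_i sum_j |c_ij - mean_i(c)| / (n * t), where c_ij is the
    weighted count of state i in taxon j. The per-taxon terms
    RCV_j = sum_i |c_ij - mean_i(c)| / (n * t) add up to the overall value.
    Zero iff all taxa share the same weighted composition.
    """
    if aln.n < 2:
        raise ValueError("RCV needs at least 2 taxa")
    profile = composition_profile(aln)
    deviations = np.abs(profile.counts - profile.mean_counts[:, None])
    denom = profile.n * profile.t
    per_taxon_values = deviations.sum(axis=0) / denom
    per_taxon = {taxon: float(v) for taxon, v in zip(profile.taxa, per_taxon_values)}
    return float(deviations.sum() / denom), per_taxon


def signal_to_noise(tree: PhyloTree, aln: AlignedMatrix) -> dict[str, float]:
    """Treeness over RCV: phylogenetic signal relative to compositional noise."""
    missing = set(tree.leaf_labels()) - set(aln.labels())
    if missing:
        raise ValueError(f"tree leaves absent from the alignment: {sorted(missing)}")
    tness = treeness(tree)
    overall_rcv, _ = rcv(aln)
    if overall_rcv == 0:
        raise ZeroDivisionError("RCV is zero: signal-to-noise ratio undefined")
    return {"treeness": tness, "rcv": overall_rcv, "signal_to_noise": tness / overall_rcv}


# -- pairwise distances and saturation ------------------------------------


def _unambiguous_codes(alphabet: str) -> np.ndarray:
    chars = _NT_STATES if alphabet == NUCLEOTIDE else _AA_STATES
    lut = np.zeros(256, dtype=bool)
    for ch in chars:
        lut[ord(ch)] = True
    return lut


def pairwise_sequence_stats(aln: AlignedMatrix):
    """Uncorrected p-distances and identities under pairwise deletion.

    Only columns where both sequences carry an unambiguous state are
    compared; difference + identity = 1 on the compared sites. Pairs with
    no comparable site get NaN and are flagged.
    Returns (DistanceMatrix of p-distances, list of per-pair records).
    """
    if aln.n < 2:
        raise ValueError("pairwise statistics need at least 2 sequences")
    ok = _unambiguous_codes(aln.alphabet)
    arr = np.frombuffer("".join(seq for _, seq in aln.rows).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(aln.n, aln.t)
    usable = ok[arr]
    taxa = aln.labels()
    n = aln.n
    values = np.zeros((n, n))
    records = []
    for i, j in itertools.combinations(range(n), 2):
        both = usable[i] & usable[j]
        compared = int(both.sum())
        if compared == 0:
            diff = identity = float("nan")
        else:
            mismatches = int((arr[i, both] != arr[j, both]).sum())
            diff = mismatches / compared
            identity = 1.0 - diff
        values[i, j] = values[j, i] = diff
        records.append(
            {
                "pair": (taxa[i], taxa[j]),
                "difference": diff,
                "identity": identity,
                "compared": compared,
            }
        )
    return DistanceMatrix(taxa=taxa, values=values, kind="p_distance"), records


def saturation_regression(
    tree: PhyloTree,
    aln: AlignedMatrix,
    fit: str = "ols_intercept",
) -> SaturationResult:
    """Regress observed pairwise difference on patristic distance.

    Under little saturation the points fall near a straight line; multiple
    substitutions at the same site depress the observed differences for
    divergent pairs, lowering both the slope and r^2. The default fit is
    ordinary least squares with an intercept; ``through_origin`` constrains
    the line through (0, 0) and reports the uncentered r^2.
    """
    if fit not in ("ols_intercept", "through_origin"):
        raise ValueError(f"unknown fit mode: {fit!r}")
    missing = set(tree.leaf_labels()) - set(aln.labels())
    if missing:
        raise ValueError(f"tree leaves absent from the alignment: {sorted(missing)}")
    dm = patristic_matrix(tree)
    _, records = pairwise_sequence_stats(aln)
    by_pair = {frozenset(rec["pair"]): rec for rec in records}

    usable = []
    for a, b, d in dm.pairs():
        rec = by_pair[frozenset((a, b))]
        if rec["compared"] == 0:
            continue
        usable.append(
            {
                "pair": (a, b),
                "patristic": d,
                "difference": rec["difference"],
                "identity": rec["identity"],
                "compared": rec["compared"],
            }
        )
    if len(usable) < 3:
        raise ValueError("saturation regression needs at least 3 usable pairs")
    x = np.array([rec["patristic"] for rec in usable])
    y = np.array([rec["difference"] for rec in usable])
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in patristic distances: regression undefined")

    if fit == "ols_intercept":
        if np.allclose(y, y[0]):
            slope, intercept, r2 = 0.0, float(y[0]), 0.0
        else:
            res = sp_stats.linregress(x, y)
            slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    else:
        slope = float(x @ y / (x @ x))
        intercept = 0.0
        denom = float((x @ x) * (y @ y))
        r2 = float((x @ y) ** 2 / denom) if denom > 0 else 0.0
    return SaturationResult(records=usable, slope=slope, intercept=intercept, r_squared=r2, fit=fit)
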