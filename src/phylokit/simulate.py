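"""Deterministic synthetic data: Yule trees, Jukes-Cantor alignments, and
toy GenBank records.

Everything the package reads can also be generated here, so the full
pipeline -- extraction, concatenation, codon handling and the tree
statistics -- runs and tests without any download. The generator is
seed-driven: the same :class:`SimulationSpec` always yields byte-identical
output.

The sequence model is deliberately minimal: a pure-birth (Yule) topology
with exponential branch lengths, and Jukes-Cantor substitution, under which
a site changes along a branch of length ``b`` (expected substitutions/site)
with probability ``3/4 * (1 - exp(-4b/3))``, landing uniformly on one of
the other three bases. That closed form is what makes the saturation
diagnostics testable: the expected pairwise difference at patristic
distance ``d`` is ``3/4 * (1 - exp(-4d/3))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import NUCLEOTIDE, AlignedMatrix
from .treeio import Node, PhyloTree

__all__ = [
    "SimulationSpec",
    "simulate_yule_tree",
    "evolve_alignment",
    "jc_expected_difference",
    "genbank_fixture",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationSpec:
    """Parameters for one reproducible simulation."""

    n_taxa: int = 16
    birth_rate: float = 1.0
    length: int = 300
    model: str = "JC"
    scale: float = 1.0
    code_table: int = 9
    seed: int = 42

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def simulate_yule_tree(spec: SimulationSpec) -> PhyloTree:
    """Pure-birth tree with ``n_taxa`` leaves labeled T1..Tn.

    Waiting times between speciations are exponential with rate
    ``birth_rate * k`` (k = current number of lineages); a uniformly chosen
    lineage splits. Branch lengths are multiplied by ``scale``.
    """
    n = spec.n_taxa
    if n < 2:
        raise ValueError("a Yule tree needs at least 2 taxa")
    rng = spec.rng(salt=1)
    root = Node()
    active = [root.add_child(Node(length=0.0)), root.add_child(Node(length=0.0))]
    while len(active) < n:
        k = len(active)
        dt = rng.exponential(1.0 / (spec.birth_rate * k))
        for tip in active:
            tip.length += dt
        idx = rng.integers(k)
        parent = active.pop(idx)
        children = [parent.add_child(Node(length=0.0)), parent.add_child(Node(length=0.0))]
        active.extend(children)
    dt = rng.exponential(1.0 / (spec.birth_rate * n))
    for tip in active:
        tip.length += dt
    leaves = [node for node in root.preorder() if node.is_leaf]
    for i, leaf in enumerate(leaves, start=1):
        leaf.label = f"T{i}"
    if spec.scale != 1.0:
        for node in root.preorder():
            if node is not root:
                node.length *= spec.scale
    return PhyloTree(root)


def jc_expected_difference(d: float) -> float:
    """Expected observed pairwise difference at patristic distance ``d``."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def evolve_alignment(tree: PhyloTree, spec: SimulationSpec) -> AlignedMatrix:
    """Evolve a gap-free nucleotide alignment down the tree under Jukes-Cantor.

    The root sequence is uniform over {A, C, G, T}; along each edge every
    site independently substitutes with probability
    ``3/4 * (1 - exp(-4b/3))`` to one of the other three bases.
    """
    if spec.model != "JC":
        raise ValueError(f"only the JC model is implemented, not {spec.model!r}")
    tree.require_lengths()
    rng = spec.rng(salt=2)
    L = spec.length
    if L <= 0:
        raise ValueError("sequence length must be positive")

    root_seq = rng.integers(4, size=L)
    rows: list[tuple[str, str]] = []

    def _descend(node: Node, seq: np.ndarray) -> None:
        if node.is_leaf:
            rows.append((node.label, "".join(_BASES[seq])))
            return
        for child in node.children:
            p_change = 0.75 * (1.0 - np.exp(-4.0 * child.length / 3.0))
            change = rng.random(L) < p_change
            child_seq = seq.copy()
            if change.any():
                # uniform over the three other bases
                shift = rng.integers(1, 4, size=int(change.sum()))
                child_seq[change] = (child_seq[change] + shift) % 4
            _descend(child, child_seq)

    _descend(tree.root, root_seq)
    order = {leaf.label: i for i, leaf in enumerate(tree.leaves())}
    rows.sort(key=lambda row: order[row[0]])
    return AlignedMatrix(rows, NUCLEOTIDE)


# -- GenBank fixtures ------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def genbank_fixture(
    genes,
    organism: str = "Toyus exemplaris",
    accession: str = "NC_000001",
    lineage=("Eukaryota", "Toyophyta"),
    transl_table: int = 9,
    spacer: int = 10,
) -> str:
    """Emit a syntactically valid single-record GenBank flat file.

    ``genes`` is a list of ``(name, sequence, kind, strand)`` tuples; the
    gene sequences are laid head-to-tail (separated by random-free 'A'
    spacers) so coordinates are derivable. Minus-strand genes are stored
    reverse-complemented with a ``complement(...)`` location, so extraction
    recovers the forward sequence given here.
    """
    import io

    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    genome_parts: list[str] = []
    features = []
    cursor = 0
    for name, seq, kind, strand in genes:
        seq = seq.upper()
        stored = _revcomp(seq) if strand == "-" else seq
        start = cursor
        end = cursor + len(seq)
        location = FeatureLocation(start, end, strand=-1 if strand == "-" else 1)
        qualifiers = {"gene": [name]}
        if kind == "CDS":
            qualifiers["transl_table"] = [str(transl_table)]
        features.append(SeqFeature(location, type=kind, qualifiers=qualifiers))
        genome_parts.append(stored)
        genome_parts.append("A" * spacer)
        cursor = end + spacer
    genome = "".join(genome_parts)

    record = SeqRecord(
        Seq(genome),
        id=accession,
        name=accession,
        description=f"{organism} mitochondrion, synthetic fixture",
        annotations={
            "molecule_type": "DNA",
            "organism": organism,
            "taxonomy": list(lineage),
            "topology": "circular",
        },
        features=features,
    )
    buf = io.StringIO()
    SeqIO.write(record, buf, "genbank")
    return buf.getvalue()
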