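"""Supermatrix construction: codon-site selection, '?'-filled concatenation
with partition schemes, codon-aware back-translation, and sanitization of
frameshift marks left by codon-aware aligners.

Conventions: a taxon missing an entire gene is padded with '?' (gaps inside
a present gene remain '-'); partition coordinates are 1-based inclusive and
follow the insertion order of the gene map; taxon matching across genes is
exact string equality, because labels are produced by the extraction step
and must round-trip unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import AMINO_ACID, NUCLEOTIDE, AlignedMatrix, AlignmentError, GeneticCode, translate_cds

__all__ = [
    "Partition",
    "PartitionScheme",
    "ConcatResult",
    "split_codon_sites",
    "concatenate",
    "back_translate",
    "sanitize_frameshift_marks",
    "write_partition_scheme",
]


@dataclass(frozen=True)
class Partition:
    name: str
    start: int  # 1-based inclusive
    end: int
    codon_stride: int | None = None  # 1, 2 or 3: every 3rd column from start+stride-1


@dataclass
class PartitionScheme:
    partitions: list[Partition] = field(default_factory=list)

    def __post_init__(self):
        prev_end = 0
        for part in self.partitions:
            if part.start != prev_end + 1:
                raise AlignmentError(
                    f"partition {part.name!r} starts at {part.start}, expected {prev_end + 1}: "
                    "partitions must be contiguous and non-overlapping"
                )
            if part.end < part.start:
                raise AlignmentError(f"partition {part.name!r} has end < start")
            prev_end = part.end

    @property
    def total_columns(self) -> int:
        return self.partitions[-1].end if self.partitions else 0

    def __iter__(self):
        return iter(self.partitions)

    def __len__(self):
        return len(self.partitions)


@dataclass
class ConcatResult:
    matrix: AlignedMatrix
    scheme: PartitionScheme
    occupancy: dict[str, float]  # per taxon, fraction of non-'?' columns

    def __post_init__(self):
        if self.scheme.total_columns != self.matrix.t:
            raise AlignmentError("partition scheme does not cover the supermatrix")

    def gene_block(self, name: str) -> AlignedMatrix:
        """Slice one gene's columns back out of the supermatrix."""
        for part in self.scheme:
            if part.name == name:
                return self.matrix.columns(range(part.start - 1, part.end))
        raise KeyError(name)


def split_codon_sites(aln: AlignedMatrix, keep) -> AlignedMatrix:
    """Keep only the codon positions in ``keep`` (subset of {1, 2, 3}).

    Column p (1-based) belongs to codon position ((p-1) mod 3) + 1. Used to
    drop the fast-evolving third positions before concatenation.
    """
    keep = set(keep)
    if not keep or not keep <= {1, 2, 3}:
        raise AlignmentError("keep must be a nonempty subset of {1, 2, 3}")
    if aln.alphabet != NUCLEOTIDE:
        raise AlignmentError("codon-site selection applies to nucleotide alignments only")
    if aln.t % 3 != 0:
        raise AlignmentError(f"alignment length {aln.t} is not divisible by 3")
    indices = [i for i in range(aln.t) if (i % 3) + 1 in keep]
    return aln.columns(indices)


def concatenate(genes: dict[str, AlignedMatrix]) -> ConcatResult:
    """Concatenate per-gene alignments into a supermatrix.

    The taxon set is the union over genes; a taxon absent from a gene gets
    '?' across that gene's block. One partition per gene, in map order.
    """
    if not genes:
        raise AlignmentError("no gene alignments to concatenate")
    alphabets = {aln.alphabet for aln in genes.values()}
    if len(alphabets) > 1:
        raise AlignmentError("cannot concatenate nucleotide and amino-acid alignments together")
    alphabet = alphabets.pop()

    taxa: list[str] = []
    seen = set()
    for aln in genes.values():
        for label in aln.labels():
            if label not in seen:
                seen.add(label)
                taxa.append(label)

    parts = []
    pieces: dict[str, list[str]] = {taxon: [] for taxon in taxa}
    cursor = 0
    for name, aln in genes.items():
        t_gene = aln.t
        rows = dict(aln.rows)
        for taxon in taxa:
            pieces[taxon].append(rows.get(taxon, "?" * t_gene))
        parts.append(Partition(name=name, start=cursor + 1, end=cursor + t_gene))
        cursor += t_gene

    rows = [(taxon, "".join(pieces[taxon])) for taxon in taxa]
    matrix = AlignedMatrix(rows, alphabet)
    occupancy = {
        taxon: 1.0 - seq.count("?") / matrix.t for taxon, seq in matrix.rows
    }
    return ConcatResult(matrix=matrix, scheme=PartitionScheme(parts), occupancy=occupancy)


def back_translate(
    aa_aln: AlignedMatrix,
    cds: dict[str, str],
    code: GeneticCode,
) -> AlignedMatrix:
    """Map an aligned protein matrix back onto its source codons.

    Each amino-acid column becomes three nucleotide columns: '-' maps to
    '---', '?'/'X' to '???', and every residue consumes the next codon of
    the taxon's coding sequence. The coding sequences are verified against
    the protein rows first (a trailing stop codon is tolerated); a mismatch
    is reported with the taxon and the first discordant position.
    """
    if aa_aln.alphabet != AMINO_ACID:
        raise AlignmentError("back_translate expects an amino-acid alignment")
    out_rows = []
    for taxon, aa_row in aa_aln.rows:
        if taxon not in cds:
            raise AlignmentError(f"no coding sequence supplied for taxon {taxon!r}")
        nt = cds[taxon].upper().replace("U", "T")
        translated = translate_cds(nt, code, strip_terminal_stop=True)
        residues = aa_row.replace("-", "")
        for pos, (a, b) in enumerate(zip(residues, translated), start=1):
            if a in ("?", "X") or b == "X":
                continue
            if a != b:
                raise AlignmentError(
                    f"translation mismatch for taxon {taxon!r} at aa position {pos}: "
                    f"alignment has {a!r}, CDS translates to {b!r}"
                )
        if len(residues) > len(translated):
            raise AlignmentError(
                f"translation mismatch for taxon {taxon!r}: alignment row has "
                f"{len(residues)} residues but CDS translates to {len(translated)}"
            )
        codons = [nt[i : i + 3] for i in range(0, len(nt) - len(nt) % 3, 3)]
        out = []
        k = 0
        for ch in aa_row:
            if ch == "-":
                out.append("---")
            elif ch in ("?", "X"):
                out.append("???")
                k += 1
            else:
                out.append(codons[k])
                k += 1
        out_rows.append((taxon, "".join(out)))
    return AlignedMatrix(out_rows, NUCLEOTIDE)


def sanitize_frameshift_marks(aln: AlignedMatrix) -> AlignedMatrix:
    """Replace frameshift marks with '?' so downstream tools accept the file.

    Codon-aware aligners flag frameshifts with '!' (and, in nucleotide
    output, premature stops with '*'); both become '?'. In amino-acid data
    '*' is a legitimate stop character and is preserved.
    """
    rows = []
    for taxon, seq in aln.rows:
        seq = seq.replace("!", "?")
        if aln.alphabet == NUCLEOTIDE:
            seq = seq.replace("*", "?")
        rows.append((taxon, seq))
    return AlignedMatrix(rows, aln.alphabet)


def write_partition_scheme(
    scheme: PartitionScheme,
    dialect: str = "nexus_sets",
    explicit_codon_triples: bool = False,
    datatype: str = "DNA",
) -> str:
    """Serialize a partition scheme as a NEXUS sets block or RAxML lines.

    Codon strides are written ``start-end\\3`` (or, with
    ``explicit_codon_triples``, left to the caller to pre-expand).
    """
    if not len(scheme):
        raise AlignmentError("empty partition scheme")

    def _range(part: Partition) -> str:
        if part.codon_stride is None:
            return f"{part.start}-{part.end}"
        start = part.start + part.codon_stride - 1
        return f"{start}-{part.end}\\3"

    if dialect == "nexus_sets":
        lines = ["begin sets;"]
        for part in scheme:
            lines.append(f"    charset {part.name} = {_range(part)};")
        lines.append("end;")
        return "\n".join(lines) + "\n"
    if dialect == "raxml":
        return "".join(f"{datatype}, {part.name} = {_range(part)}\n" for part in scheme)
    raise AlignmentError(f"unknown partition dialect: {dialect!r}")
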