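"""Alignment I/O (FASTA / relaxed PHYLIP / NEXUS) and genetic-code handling.

The central container is :class:`AlignedMatrix`: equal-length, uniquely
labeled rows over a declared alphabet (nucleotide or amino acid). File
round-trips go through Biopython's AlignIO; genetic codes wrap the NCBI
translation tables bundled with Biopython, restricted to a registry of the
tables relevant for organellar work (1, 2, 3, 4, 5, 9, 11, 13, 14 -- the
flatworm/echinoderm mitochondrial code 9 among them).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Data import CodonTable, IUPACData
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentError",
    "AlignedMatrix",
    "GeneticCode",
    "genetic_code",
    "BUNDLED_CODE_TABLES",
    "read_alignment",
    "parse_alignment",
    "write_alignment",
    "translate_cds",
]

NUCLEOTIDE = "nucleotide"
AMINO_ACID = "amino_acid"

_NT_CORE = set("ACGTUN")  # U counts toward nucleotide so RNA is detected, then normalized
_GAPLIKE = set("-?")

# IUPAC ambiguity expansions used both for alphabet checks and translation
NT_AMBIGUITY = {k.upper(): set(v.upper()) for k, v in IUPACData.ambiguous_dna_values.items()}
AA_AMBIGUITY = {
    "B": set("DN"),
    "Z": set("EQ"),
    "J": set("IL"),
    "X": set("ACDEFGHIKLMNPQRSTVWY"),
}


class AlignmentError(ValueError):
    """Invalid alignment content or format."""


@dataclass
class AlignedMatrix:
    """Equal-length labeled sequence rows with a declared alphabet."""

    rows: list[tuple[str, str]]
    alphabet: str  # NUCLEOTIDE or AMINO_ACID

    def __post_init__(self):
        if not self.rows:
            raise AlignmentError("alignment has no rows")
        if self.alphabet not in (NUCLEOTIDE, AMINO_ACID):
            raise AlignmentError(f"unknown alphabet: {self.alphabet!r}")
        t = len(self.rows[0][1])
        if t == 0:
            raise AlignmentError("alignment has zero columns")
        for label, seq in self.rows:
            if len(seq) != t:
                raise AlignmentError(f"sequences not aligned: row {label!r} has length {len(seq)}, expected {t}")
        labels = [lab for lab, _ in self.rows]
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise AlignmentError(f"duplicate row labels: {sorted(dupes)}")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def t(self) -> int:
        return len(self.rows[0][1])

    def labels(self) -> list[str]:
        return [lab for lab, _ in self.rows]

    def sequence(self, label: str) -> str:
        for lab, seq in self.rows:
            if lab == label:
                return seq
        raise KeyError(label)

    def columns(self, indices) -> "AlignedMatrix":
        """New matrix keeping the given 0-based column indices, in order."""
        rows = [(lab, "".join(seq[i] for i in indices)) for lab, seq in self.rows]
        return AlignedMatrix(rows, self.alphabet)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AlignedMatrix)
            and self.rows == other.rows
            and self.alphabet == other.alphabet
        )


def detect_alphabet(rows) -> str:
    """Nucleotide when >= 90% of non-gap characters are in {A,C,G,T,N}."""
    total = core = 0
    for _, seq in rows:
        for ch in seq:
            if ch in _GAPLIKE:
                continue
            total += 1
            if ch in _NT_CORE:
                core += 1
    if total == 0:
        return NUCLEOTIDE
    return NUCLEOTIDE if core / total >= 0.9 else AMINO_ACID


_FORMAT_MAP = {"fasta": "fasta", "phylip": "phylip-relaxed", "nexus": "nexus"}


def parse_alignment(text: str, fmt: str = "fasta", alphabet: str | None = None) -> AlignedMatrix:
    """Parse alignment text; see :func:`read_alignment`."""
    if fmt not in _FORMAT_MAP:
        raise AlignmentError(f"unknown alignment format: {fmt!r}")
    try:
        msa = AlignIO.read(io.StringIO(text), _FORMAT_MAP[fmt])
    except ValueError as exc:
        msg = str(exc)
        if "same length" in msg or "length" in msg.lower():
            raise AlignmentError(f"sequences not aligned: {msg}") from exc
        raise AlignmentError(f"could not parse {fmt} alignment: {msg}") from exc
    rows = [(rec.id, str(rec.seq).upper()) for rec in msa]
    if alphabet is None:
        alphabet = detect_alphabet(rows)
    if alphabet == NUCLEOTIDE and any("U" in seq for _, seq in rows):
        logger.info("normalizing RNA 'U' to 'T' in nucleotide alignment")
        rows = [(lab, seq.replace("U", "T")) for lab, seq in rows]
    return AlignedMatrix(rows, alphabet)


def read_alignment(path, fmt: str | None = None, alphabet: str | None = None) -> AlignedMatrix:
    """Read a FASTA / relaxed-PHYLIP / NEXUS alignment from disk.

    Sequences are uppercased; for nucleotide data 'U' is normalized to 'T'.
    The alphabet is auto-detected (>= 90% of non-gap characters in
    {A,C,G,T,N} means nucleotide) unless ``alphabet`` overrides it. The
    format is inferred from the extension when ``fmt`` is None.
    """
    path = Path(path)
    if fmt is None:
        ext = path.suffix.lower()
        fmt = {
            ".fa": "fasta", ".fas": "fasta", ".fasta": "fasta",
            ".phy": "phylip", ".phylip": "phylip",
            ".nex": "nexus", ".nexus": "nexus", ".nxs": "nexus",
        }.get(ext, "fasta")
    return parse_alignment(path.read_text(), fmt, alphabet=alphabet)


def write_alignment(matrix: AlignedMatrix, fmt: str = "fasta") -> str:
    """Serialize an alignment; round-trips through :func:`parse_alignment`."""
    if fmt not in _FORMAT_MAP:
        raise AlignmentError(f"unknown alignment format: {fmt!r}")
    molecule = "DNA" if matrix.alphabet == NUCLEOTIDE else "protein"
    records = [
        SeqRecord(Seq(seq), id=lab, description="", annotations={"molecule_type": molecule})
        for lab, seq in matrix.rows
    ]
    msa = MultipleSeqAlignment(records)
    buf = io.StringIO()
    AlignIO.write(msa, buf, _FORMAT_MAP[fmt])
    return buf.getvalue()


def write_alignment_file(matrix: AlignedMatrix, path, fmt: str = "fasta") -> None:
    Path(path).write_text(write_alignment(matrix, fmt))


# -- genetic codes --------------------------------------------------------

BUNDLED_CODE_TABLES = (1, 2, 3, 4, 5, 9, 11, 13, 14)

_BASES = "TCAG"
_CODON_ORDER = [b1 + b2 + b3 for b1 in _BASES for b2 in _BASES for b3 in _BASES]


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table: 64 codons -> amino acids, stops as '*'."""

    table_id: int
    codon_map: dict = field(repr=False)
    stop_codons: frozenset = field(repr=False)
    name: str = ""

    def __post_init__(self):
        if len(self.codon_map) != 64:
            raise ValueError("a genetic code must map exactly 64 codons")
        for stop in self.stop_codons:
            if self.codon_map[stop] != "*":
                raise ValueError(f"stop codon {stop} must map to '*'")

    def aa(self, codon: str) -> str:
        return self.codon_map[codon.upper().replace("U", "T")]

    def table_string(self) -> str:
        """The 64 amino acids in NCBI order (TTT, TTC, ... GGG)."""
        return "".join(self.codon_map[c] for c in _CODON_ORDER)


_REGISTRY: dict[int, GeneticCode] = {}


def genetic_code(table_id: int = 1) -> GeneticCode:
    """Look up a bundled NCBI translation table by numeric id."""
    if table_id in _REGISTRY:
        return _REGISTRY[table_id]
    if table_id not in BUNDLED_CODE_TABLES:
        raise ValueError(
            f"code table {table_id} is not bundled (available: {BUNDLED_CODE_TABLES})"
        )
    ncbi = CodonTable.unambiguous_dna_by_id[table_id]
    codon_map = dict(ncbi.forward_table)
    for stop in ncbi.stop_codons:
        codon_map[stop] = "*"
    code = GeneticCode(
        table_id=table_id,
        codon_map=codon_map,
        stop_codons=frozenset(ncbi.stop_codons),
        name=ncbi.names[0] if ncbi.names else "",
    )
    _REGISTRY[table_id] = code
    return code


def register_genetic_code(code: GeneticCode) -> None:
    """Add or replace a table in the registry (extension hook)."""
    _REGISTRY[code.table_id] = code


def _translate_codon(codon: str, code: GeneticCode) -> str:
    """Translate one codon, resolving IUPAC ambiguity only when unanimous."""
    if codon in code.codon_map:
        return code.codon_map[codon]
    expansions = [NT_AMBIGUITY.get(ch) for ch in codon]
    if any(e is None for e in expansions):
        return "X"
    aas = {
        code.codon_map[b1 + b2 + b3]
        for b1 in expansions[0]
        for b2 in expansions[1]
        for b3 in expansions[2]
    }
    return aas.pop() if len(aas) == 1 else "X"


def translate_cds(seq: str, code: GeneticCode, strip_terminal_stop: bool = False) -> str:
    """Translate a gap-free coding sequence.

    An incomplete final codon is dropped with a warning; internal stops are
    rendered '*' with a warning; codons with ambiguity codes translate
    normally only when every expansion agrees, otherwise 'X'.
    """
    if not seq:
        raise AlignmentError("cannot translate an empty sequence")
    seq = seq.upper().replace("U", "T")
    if any(ch in _GAPLIKE for ch in seq):
        raise AlignmentError("translate_cds requires a gap-free sequence")
    if len(seq) < 3:
        raise AlignmentError("coding sequence shorter than one codon")
    remainder = len(seq) % 3
    if remainder:
        logger.warning("dropping incomplete final codon (%d trailing bases)", remainder)
        seq = seq[: len(seq) - remainder]
    aas = [_translate_codon(seq[i : i + 3], code) for i in range(0, len(seq), 3)]
    if "*" in aas[:-1]:
        logger.warning("internal stop codon(s) at aa position(s) %s",
                       [i + 1 for i, a in enumerate(aas[:-1]) if a == "*"])
    if strip_terminal_stop and aas and aas[-1] == "*":
        aas.pop()
    return "".join(aas)
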