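"""GenBank parsing, record deduplication, gene-name unification, extraction.

Mitogenome-style GenBank submissions name the same gene many different ways
("COX1", "COI", "COXI", "cytochrome c oxidase subunit I", ...). Extraction
therefore runs every raw feature name through a :class:`NameMap` whose
lookup key is normalized (lowercase, punctuation and whitespace stripped);
a curated default map covering the standard 13 protein-coding genes, the
two rRNAs and the 22 tRNAs ships with the package and can be replaced or
extended from a two-column TSV (old name TAB new name).

Records that passed RefSeq screening carry two accessions for the same
sequence; :func:`deduplicate_records` keeps one record per identical genome
sequence, preferring accessions that start with ``NC_``.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

from .seqio import GeneticCode, genetic_code, translate_cds

logger = logging.getLogger(__name__)

__all__ = [
    "GenBankError",
    "GeneFeature",
    "GenBankRecord",
    "NameMap",
    "ExtractionBundle",
    "read_genbank",
    "parse_genbank",
    "deduplicate_records",
    "unify_gene_name",
    "extract_genes",
    "make_taxon_label",
    "default_name_map",
]


class GenBankError(ValueError):
    """Malformed GenBank input or invalid extraction request."""


@dataclass
class GeneFeature:
    """One annotated feature: kind, raw name, 1-based inclusive intervals."""

    kind: str  # CDS, tRNA, rRNA, other
    raw_name: str
    intervals: list[tuple[int, int]]
    strand: str  # '+' or '-'
    transl_table: int | None = None

    def __post_init__(self):
        for start, end in self.intervals:
            if start < 1 or end < start:
                raise GenBankError(f"degenerate interval [{start}, {end}] on feature {self.raw_name!r}")


@dataclass
class GenBankRecord:
    accession: str
    organism: str
    lineage: list[str]
    features: list[GeneFeature]
    sequence: str

    def __post_init__(self):
        if not self.accession:
            raise GenBankError("record has no accession")
        for feat in self.features:
            for _, end in feat.intervals:
                if end > len(self.sequence):
                    raise GenBankError(
                        f"{self.accession}: feature {feat.raw_name!r} coordinate {end} "
                        f"beyond sequence end ({len(self.sequence)})"
                    )


_NORM_RE = re.compile(r"[^a-z0-9]+")


def normalize_name(raw: str) -> str:
    """Lowercase and strip punctuation/whitespace: the NameMap lookup key."""
    return _NORM_RE.sub("", raw.lower())


class NameMap:
    """Old-name -> new-name alias table with case/punctuation-insensitive keys."""

    def __init__(self, pairs=()):
        self._map: dict[str, str] = {}
        for old, new in pairs:
            self.add(old, new)

    def add(self, old: str, new: str) -> None:
        key = normalize_name(old)
        if key in self._map and self._map[key] != new:
            raise GenBankError(f"conflicting aliases for {old!r}: {self._map[key]!r} vs {new!r}")
        self._map[key] = new

    def lookup(self, raw: str) -> str | None:
        return self._map.get(normalize_name(raw))

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_tsv(cls, path) -> "NameMap":
        """Load a two-column TSV (Old Name TAB New Name); header tolerated."""
        nm = cls()
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise GenBankError(f"alias table line {lineno}: expected two tab-separated columns")
            old, new = parts[0].strip(), parts[1].strip()
            if lineno == 1 and normalize_name(old) in ("oldname", "rawname"):
                continue
            nm.add(old, new)
        return nm


_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C", "gln": "Q",
    "glu": "E", "gly": "G", "his": "H", "ile": "I", "leu": "L", "lys": "K",
    "met": "M", "phe": "F", "pro": "P", "ser": "S", "thr": "T", "trp": "W",
    "tyr": "Y", "val": "V",
}


def default_name_map() -> NameMap:
    """The bundled alias map for standard animal mitochondrial gene names."""
    nm = NameMap()
    aliases: dict[str, list[str]] = {
        "cox1": ["cox1", "coi", "coxi", "co1", "cox 1", "cytochrome c oxidase subunit I",
                 "cytochrome c oxidase subunit 1", "cytochrome oxidase subunit I"],
        "cox2": ["cox2", "coii", "coxii", "co2", "cytochrome c oxidase subunit II",
                 "cytochrome c oxidase subunit 2"],
        "cox3": ["cox3", "coiii", "coxiii", "co3", "cytochrome c oxidase subunit III",
                 "cytochrome c oxidase subunit 3"],
        "cob": ["cob", "cytb", "cyt b", "cytochrome b", "cytochrome-b", "apocytochrome b"],
        "nad1": ["nad1", "nd1", "nadh1", "NADH dehydrogenase subunit 1"],
        "nad2": ["nad2", "nd2", "nadh2", "NADH dehydrogenase subunit 2"],
        "nad3": ["nad3", "nd3", "nadh3", "NADH dehydrogenase subunit 3"],
        "nad4": ["nad4", "nd4", "nadh4", "NADH dehydrogenase subunit 4"],
        "nad4L": ["nad4l", "nd4l", "NADH dehydrogenase subunit 4L"],
        "nad5": ["nad5", "nd5", "nadh5", "NADH dehydrogenase subunit 5"],
        "nad6": ["nad6", "nd6", "nadh6", "NADH dehydrogenase subunit 6"],
        "atp6": ["atp6", "atpase6", "atpase 6", "ATP synthase F0 subunit 6"],
        "atp8": ["atp8", "atpase8", "atpase 8", "ATP synthase F0 subunit 8"],
        "rrnL": ["rrnl", "16s", "16s rrna", "16s ribosomal rna", "l-rrna", "lsu",
                 "large subunit ribosomal rna", "rrn16"],
        "rrnS": ["rrns", "12s", "12s rrna", "12s ribosomal rna", "s-rrna", "ssu",
                 "small subunit ribosomal rna", "rrn12"],
    }
    for canonical, raws in aliases.items():
        for raw in raws:
            nm.add(raw, canonical)
    for aa3, aa1 in _AA3_TO_1.items():
        nm.add(f"trna-{aa3}", f"trn{aa1}")
        nm.add(f"trn{aa1}", f"trn{aa1}")
        nm.add(f"trna {aa3}", f"trn{aa1}")
    # leucine/serine duplicates commonly annotated with codon families
    nm.add("trna-leu (uur)", "trnL2")
    nm.add("trna-leu (cun)", "trnL1")
    nm.add("trna-ser (ucn)", "trnS2")
    nm.add("trna-ser (agn)", "trnS1")
    return nm


def unify_gene_name(raw: str, name_map: NameMap) -> tuple[str, bool]:
    """Map a raw feature name onto its canonical gene name.

    Unmatched names pass through normalized, flagged False (these feed the
    name-unification report so the user can curate and re-import them).
    """
    if not raw:
        raise GenBankError("empty gene name")
    hit = name_map.lookup(raw)
    if hit is not None:
        return hit, True
    return normalize_name(raw), False


# -- parsing --------------------------------------------------------------

_KINDS = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def _feature_from_biopython(feat) -> GeneFeature | None:
    kind = _KINDS.get(feat.type, "other")
    quals = feat.qualifiers
    raw_name = (quals.get("gene") or quals.get("product") or [""])[0]
    if not raw_name:
        return None
    parts = sorted(feat.location.parts, key=lambda p: int(p.start))
    intervals = [(int(p.start) + 1, int(p.end)) for p in parts]
    strand = "-" if feat.location.strand == -1 else "+"
    table = quals.get("transl_table")
    return GeneFeature(
        kind=kind,
        raw_name=raw_name,
        intervals=intervals,
        strand=strand,
        transl_table=int(table[0]) if table else None,
    )


def parse_genbank(text: str) -> list[GenBankRecord]:
    """Parse GenBank flat-file text (one or more LOCUS...// records)."""
    import io

    records = []
    for rec in SeqIO.parse(io.StringIO(text), "genbank"):
        seq = str(rec.seq).upper()
        if not seq:
            raise GenBankError(f"{rec.name}: missing ORIGIN sequence")
        feats = []
        for feat in rec.features:
            if feat.type in ("CDS", "tRNA", "rRNA"):
                gf = _feature_from_biopython(feat)
                if gf is not None:
                    feats.append(gf)
        records.append(
            GenBankRecord(
                accession=rec.name or rec.id,
                organism=rec.annotations.get("organism", ""),
                lineage=list(rec.annotations.get("taxonomy", [])),
                features=feats,
                sequence=seq,
            )
        )
    if not records:
        raise GenBankError("no GenBank records found")
    return records


def read_genbank(path) -> list[GenBankRecord]:
    """Read all records from a GenBank flat file."""
    return parse_genbank(Path(path).read_text())


# -- deduplication --------------------------------------------------------


def deduplicate_records(records) -> tuple[list[GenBankRecord], list[GenBankRecord]]:
    """Collapse records with identical genome sequences.

    Within a group of identical sequences one record is kept: an accession
    starting with ``NC_`` (a RefSeq copy) when present, otherwise the first
    encountered. Output order follows input order.
    """
    groups: dict[str, list[GenBankRecord]] = {}
    for rec in records:
        groups.setdefault(rec.sequence.upper(), []).append(rec)
    keep_ids = set()
    for members in groups.values():
        chosen = next((r for r in members if r.accession.startswith("NC_")), members[0])
        keep_ids.add(id(chosen))
    kept = [r for r in records if id(r) in keep_ids]
    removed = [r for r in records if id(r) not in keep_ids]
    return kept, removed


# -- extraction -----------------------------------------------------------

DEFAULT_LABEL_TEMPLATE = "{organism}_{accession}"
_PLACEHOLDER_RE = re.compile(r"\{([a-z_]+)\}")


def make_taxon_label(record: GenBankRecord, template: str = DEFAULT_LABEL_TEMPLATE) -> str:
    """Build the row label used throughout downstream files.

    Supported placeholders: ``{organism}`` (spaces become underscores) and
    ``{accession}``.
    """
    values = {
        "organism": record.organism.replace(" ", "_"),
        "accession": record.accession,
    }
    unknown = [m for m in _PLACEHOLDER_RE.findall(template) if m not in values]
    if unknown:
        raise GenBankError(f"unknown placeholder(s) in label template: {unknown}")
    return template.format(**values)


@dataclass
class ExtractionBundle:
    """Per-gene sequence sets plus the name-unification report."""

    nucleotides: dict[str, dict[str, str]] = field(default_factory=dict)
    amino_acids: dict[str, dict[str, str]] = field(default_factory=dict)
    unmatched: Counter = field(default_factory=Counter)

    def genes(self) -> list[str]:
        return list(self.nucleotides)

    def name_report_tsv(self) -> str:
        """'name_for_unification.tsv': raw name, suggested name, count."""
        lines = ["raw_name\tsuggested_name\tcount"]
        for raw, count in sorted(self.unmatched.items()):
            lines.append(f"{raw}\t{normalize_name(raw)}\t{count}")
        return "\n".join(lines) + "\n"

    def write_fastas(self, outdir, which: str = "nt") -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table = self.nucleotides if which == "nt" else self.amino_acids
        suffix = ".fas" if which == "nt" else ".aa.fas"
        written = []
        for gene, seqs in table.items():
            path = outdir / f"{gene}{suffix}"
            with path.open("w") as fh:
                for taxon, seq in seqs.items():
                    fh.write(f">{taxon}\n")
                    for i in range(0, len(seq), 60):
                        fh.write(seq[i : i + 60] + "\n")
            written.append(path)
        return written


def _feature_sequence(record: GenBankRecord, feat: GeneFeature) -> str:
    pieces = [record.sequence[start - 1 : end] for start, end in feat.intervals]
    seq = "".join(pieces)
    if feat.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def extract_genes(
    records,
    name_map: NameMap | None = None,
    code: GeneticCode | None = None,
    kinds=("CDS", "tRNA", "rRNA"),
    label_template: str = DEFAULT_LABEL_TEMPLATE,
) -> ExtractionBundle:
    """Pull every selected feature out of the records, grouped by gene.

    Feature intervals are concatenated in order and reverse-complemented on
    the minus strand. CDS features are additionally translated, using the
    feature's own /transl_table when annotated, else ``code`` (default:
    the standard code, table 1). Names that the alias map does not know are
    tallied in the unmatched report but still extracted under their
    normalized name, so extraction is total.
    """
    if name_map is None:
        name_map = default_name_map()
    if code is None:
        code = genetic_code(1)
    kinds = set(kinds)
    bundle = ExtractionBundle()
    for record in records:
        taxon = make_taxon_label(record, label_template)
        for feat in record.features:
            if feat.kind not in kinds:
                continue
            gene, matched = unify_gene_name(feat.raw_name, name_map)
            if not matched:
                bundle.unmatched[feat.raw_name] += 1
            nt = _feature_sequence(record, feat)
            gene_nt = bundle.nucleotides.setdefault(gene, {})
            key = taxon
            if key in gene_nt:
                n = 2
                while f"{taxon}.{n}" in gene_nt:
                    n += 1
                key = f"{taxon}.{n}"
                logger.warning("duplicate (%s, %s): stored as %s", gene, taxon, key)
            gene_nt[key] = nt
            if feat.kind == "CDS":
                feat_code = genetic_code(feat.transl_table) if feat.transl_table else code
                aa = translate_cds(nt, feat_code, strip_terminal_stop=True)
                bundle.amino_acids.setdefault(gene, {})[key] = aa
    return bundle
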