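"""Sequence and metadata input/output.

Reads and writes protein/DNA FASTA files and taxon-assignment tables, and
applies the homolog-inclusion filter (global percent identity and query
coverage thresholds) used to assemble a group II PPTase family from a
candidate set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq as _BioSeq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

PROTEIN_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_LETTERS = frozenset("ACGTN")

#: Canonical taxon groups used throughout the package.
TAXA = ("archaea", "cyanobacteria", "bacteria", "fungi", "algae", "plant", "animal", "unknown")

# Singular/plural/common variants normalised case-insensitively.
_TAXON_ALIASES = {
    "archaea": "archaea",
    "archaeon": "archaea",
    "archaebacteria": "archaea",
    "archaebacterium": "archaea",
    "cyanobacteria": "cyanobacteria",
    "cyanobacterium": "cyanobacteria",
    "cyano-bacterium": "cyanobacteria",
    "bacteria": "bacteria",
    "bacterium": "bacteria",
    "fungi": "fungi",
    "fungus": "fungi",
    "fungal": "fungi",
    "algae": "algae",
    "alga": "algae",
    "algal": "algae",
    "plant": "plant",
    "plants": "plant",
    "animal": "animal",
    "animals": "animal",
    "metazoa": "animal",
    "unknown": "unknown",
}


class SequenceError(ValueError):
    """Raised on malformed sequence input (bad letters, duplicates, empties)."""


@dataclass(frozen=True)
class SeqRecord:
    """One protein or DNA sequence with its provenance metadata.

    ``residues`` is an upper-case, gap-free string over the declared
    alphabet (20 amino acids + X, or ACGTN).
    """

    id: str
    residues: str
    alphabet: str = "protein"
    description: str = ""
    taxon: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceError(f"invalid sequence id: {self.id!r}")
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        if self.alphabet not in ("protein", "dna"):
            raise SequenceError(f"record {self.id!r}: unknown alphabet {self.alphabet!r}")
        allowed = PROTEIN_LETTERS if self.alphabet == "protein" else DNA_LETTERS
        for pos, letter in enumerate(self.residues, start=1):
            if letter not in allowed:
                raise SequenceError(
                    f"record {self.id!r}: illegal {self.alphabet} letter "
                    f"{letter!r} at position {pos}"
                )
        if self.taxon not in TAXA:
            raise SequenceError(f"record {self.id!r}: unknown taxon {self.taxon!r}")

    def __len__(self) -> int:
        return len(self.residues)


def normalize_taxon(raw: str) -> str:
    """Map a free-form taxon string onto the canonical group name.

    Unrecognised strings normalise to ``"unknown"`` with a logged warning.
    """
    key = raw.strip().lower()
    if key in _TAXON_ALIASES:
        return _TAXON_ALIASES[key]
    logger.warning("unrecognised taxon %r mapped to 'unknown'", raw)
    return "unknown"


@dataclass
class TaxonTable:
    """Mapping from sequence id to taxon group; each id maps to one taxon."""

    assignments: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, seq_id: str) -> str:
        return self.assignments[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.assignments

    def __len__(self) -> int:
        return len(self.assignments)

    def add(self, seq_id: str, taxon: str) -> None:
        taxon = normalize_taxon(taxon)
        prior = self.assignments.get(seq_id)
        if prior is not None and prior != taxon:
            raise SequenceError(
                f"conflicting taxon for id {seq_id!r}: {prior!r} vs {taxon!r}"
            )
        self.assignments[seq_id] = taxon

    def get(self, seq_id: str, default: str = "unknown") -> str:
        return self.assignments.get(seq_id, default)


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[SeqRecord]:
    """Read a FASTA file into a list of validated :class:`SeqRecord`.

    The record id is the first whitespace-delimited header token; the full
    header is kept as ``description``. Letters are upper-cased. Raises
    :class:`SequenceError` on an empty file, an illegal letter (named with
    record and position), or a duplicate id.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for bio_rec in _BioSeqIO.parse(str(path), "fasta"):
        if bio_rec.id in seen:
            raise SequenceError(f"duplicate sequence id {bio_rec.id!r} in {path}")
        seen.add(bio_rec.id)
        records.append(
            SeqRecord(
                id=bio_rec.id,
                residues=str(bio_rec.seq).upper(),
                alphabet=alphabet,
                description=bio_rec.description,
            )
        )
    if not records:
        raise SequenceError(f"no sequences in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, line_width: int = 60) -> None:
    """Write records to FASTA. Round-trips with :func:`read_fasta` on id+residues."""
    records = list(records)
    if not records:
        raise SequenceError("refusing to write an empty FASTA file")
    bio_records = [
        _BioSeqRecord(_BioSeq(r.residues), id=r.id, description=r.description or "")
        for r in records
    ]
    writer = _BioSeqIO.FastaIO.FastaWriter(str(path), wrap=line_width)
    writer.write_file(bio_records)


def read_taxon_table(path: str | Path) -> TaxonTable:
    """Read a two-column TSV (``id<TAB>taxon``, header optional) into a TaxonTable.

    Taxon strings are normalised (case, singular/plural variants); an id
    listed twice with conflicting taxa is an error. An empty file yields an
    empty table.
    """
    table = TaxonTable()
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise SequenceError(f"{path}:{line_no}: expected 'id<TAB>taxon', got {line!r}")
            seq_id, taxon = parts[0].strip(), parts[1].strip()
            if line_no == 1 and seq_id.lower() == "id" and taxon.lower() == "taxon":
                continue  # header row
            table.add(seq_id, taxon)
    return table


def write_taxon_table(table: TaxonTable, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("id\ttaxon\n")
        for seq_id, taxon in table.assignments.items():
            handle.write(f"{seq_id}\t{taxon}\n")


def filter_homologs(
    query: SeqRecord,
    candidates: Iterable[SeqRecord],
    min_identity_pct: float = 35.0,
    min_coverage_pct: float = 70.0,
    scheme=None,
) -> list[SeqRecord]:
    """Retain candidates passing the homolog-inclusion rule.

    A candidate is kept when its global alignment to the query has percent
    identity strictly greater than ``min_identity_pct`` AND query coverage
    (percentage of query residues paired, gap-free, with candidate
    residues) strictly greater than ``min_coverage_pct``. The defaults are
    the >35% identity / >70% coverage thresholds used for family assembly.
    """
    from .align import default_scheme, global_align

    if query.alphabet != "protein":
        raise SequenceError("filter_homologs requires protein sequences")
    if scheme is None:
        scheme = default_scheme("protein")
    kept = []
    for cand in candidates:
        if cand.alphabet != "protein":
            raise SequenceError(f"candidate {cand.id!r} is not protein")
        aln = global_align(query, cand, scheme)
        if aln.identity_pct > min_identity_pct and aln.coverage_a_pct > min_coverage_pct:
            kept.append(cand)
    return kept
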