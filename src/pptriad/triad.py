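"""Magnesium-binding-triad detection and subgroup classification.

Group II phosphopantetheinyl transferases carry up to three carboxylate
Mg²⁺ ligands at alignment-homologous positions — the triad Asp-Xxx-Glu.
Enzymes with Glu at the second position ("three-Mg", e.g. Sfp, D107/E109/
E151) coordinate the ion with all three; enzymes with any other residue
there ("two-Mg", e.g. the human enzyme, D129/·/E181) use only the first
and third. This module transfers known triad coordinates from an anchor
sequence onto a query through global alignment, classifies the query into
the two-Mg or three-Mg subgroup from the second residue, and tabulates
taxon × second-residue distributions.

Coordinates are 1-based, inclusive, in the ungapped sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd

from .align import ScoringScheme, default_scheme, global_align
from .seqio import SeqRecord, TaxonTable

logger = logging.getLogger(__name__)

#: Second-residue states tracked as dedicated columns (any other amino
#: acid is pooled into "other"). Order follows the conventional report:
#: Glu first (three-Mg), then the two-Mg states by overall abundance.
SECOND_STATES = ("E", "M", "V", "A", "T", "Q", "S", "L", "C")

UNMAPPED = None  #: sentinel for a triad position aligned to a gap

SUBGROUP_THREE_MG = "three_mg"
SUBGROUP_TWO_MG = "two_mg"
SUBGROUP_UNCLASSIFIED = "unclassified"


class TriadError(ValueError):
    pass


@dataclass(frozen=True)
class TriadAnchor:
    """A reference sequence with known triad coordinates.

    ``positions`` are 1-based in the ungapped anchor; ``expected_residues``
    are the letters the anchor must carry there (validated on creation).
    """

    id: str
    record: SeqRecord
    positions: tuple[int, int, int]
    expected_residues: tuple[str, str, str]

    def __post_init__(self) -> None:
        p1, p2, p3 = self.positions
        if not (1 <= p1 < p2 < p3 <= len(self.record)):
            raise TriadError(
                f"anchor {self.id!r}: positions {self.positions} not strictly "
                f"increasing within sequence length {len(self.record)}"
            )
        for pos, expected in zip(self.positions, self.expected_residues):
            actual = self.record.residues[pos - 1]
            if actual != expected:
                raise TriadError(
                    f"anchor {self.id!r}: residue at {pos} is {actual!r}, "
                    f"expected {expected!r}"
                )


@dataclass(frozen=True)
class TriadCall:
    """Triad positions/residues mapped onto one query, plus its subgroup."""

    query_id: str
    anchor_id: str
    positions: tuple[Optional[int], Optional[int], Optional[int]]
    residues: tuple[str, str, str]  # '-' where unmapped
    subgroup: str = SUBGROUP_UNCLASSIFIED
    anchor_identity_pct: float = 0.0
    flags: frozenset[str] = frozenset()

    @property
    def second_state(self) -> str:
        """Second-residue state pooled onto the tracked alphabet."""
        res2 = self.residues[1]
        return res2 if res2 in SECOND_STATES else "other"


def _map_anchor_positions(row_anchor: str, row_query: str, positions: tuple[int, ...]):
    """Map 1-based anchor positions through an alignment onto the query."""
    targets = set(positions)
    found: dict[int, Optional[int]] = {}
    apos = 0
    qpos = 0
    for ac, qc in zip(row_anchor, row_query):
        if ac != "-":
            apos += 1
        if qc != "-":
            qpos += 1
        if ac != "-" and apos in targets:
            found[apos] = qpos if qc != "-" else UNMAPPED
    return tuple(found.get(p, UNMAPPED) for p in positions)


def detect_triad(
    query: SeqRecord,
    anchor: TriadAnchor,
    scheme: ScoringScheme | None = None,
    low_identity_threshold: float = 20.0,
) -> TriadCall:
    """Locate the query's triad by global alignment against the anchor.

    Each anchor triad column is transferred to the query; a column where
    the query has a gap yields an unmapped position. The call records the
    anchor–query percent identity and quality flags
    (``first_not_asp``, ``third_not_glu``, ``position_unmapped``,
    ``low_anchor_identity``) but does not yet assign a subgroup — see
    :func:`classify_subgroup`.
    """
    if query.alphabet != "protein":
        raise TriadError("triad detection requires a protein query")
    if scheme is None:
        scheme = default_scheme("protein")
    aln = global_align(anchor.record, query, scheme)
    positions = _map_anchor_positions(aln.row_a, aln.row_b, anchor.positions)
    residues = tuple(
        query.residues[p - 1] if p is not UNMAPPED else "-" for p in positions
    )
    flags = set()
    if positions[0] is UNMAPPED or positions[2] is UNMAPPED or positions[1] is UNMAPPED:
        flags.add("position_unmapped")
    if residues[0] != "D":
        flags.add("first_not_asp")
    if residues[2] != "E":
        flags.add("third_not_glu")
    if aln.identity_pct < low_identity_threshold:
        flags.add("low_anchor_identity")
    return TriadCall(
        query_id=query.id,
        anchor_id=anchor.id,
        positions=positions,
        residues=residues,
        anchor_identity_pct=aln.identity_pct,
        flags=frozenset(flags),
    )


def classify_subgroup(call: TriadCall, carboxylate_interchange: bool = False) -> TriadCall:
    """Assign the two-Mg / three-Mg subgroup from the triad residues.

    ``three_mg`` requires Glu at the second position (Asp also accepted
    when ``carboxylate_interchange`` is on); any other second residue —
    including a gap, as in the human enzyme which lacks the second ligand
    entirely — gives ``two_mg``. A call whose first position is not Asp or
    third not Glu (or either unmapped) is ``unclassified``.
    """
    res1, res2, res3 = call.residues
    first_ok = res1 == "D" or (carboxylate_interchange and res1 == "E")
    third_ok = res3 == "E" or (carboxylate_interchange and res3 == "D")
    if call.positions[0] is UNMAPPED or call.positions[2] is UNMAPPED or not first_ok or not third_ok:
        return replace(call, subgroup=SUBGROUP_UNCLASSIFIED)
    flags = set(call.flags)
    if res2 == "E" or (carboxylate_interchange and res2 == "D"):
        subgroup = SUBGROUP_THREE_MG
    else:
        subgroup = SUBGROUP_TWO_MG
        if res2 == "D":
            # carboxylate at position 2 but not Glu; flag rather than promote
            flags.add("second_is_asp")
    return replace(call, subgroup=subgroup, flags=frozenset(flags))


@dataclass
class DistributionTable:
    """Taxon × second-residue-state counts with recomputed margins."""

    counts: pd.DataFrame  # rows: taxa, columns: SECOND_STATES + other
    unclassified: list[str] = field(default_factory=list)

    @property
    def row_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out["sum"] = self.row_sums
        out.loc["sum"] = out.sum(axis=0)
        out.to_csv(path, sep="\t", index_label="taxon")


def tabulate_distribution(calls: Iterable[TriadCall], taxa: TaxonTable) -> DistributionTable:
    """Count classified calls by taxon and second-residue state.

    Unclassified calls are excluded from the matrix and listed separately.
    Every classified call's query id must be present in the taxon table.
    """
    states = list(SECOND_STATES) + ["other"]
    taxon_rows = [t for t in ("archaea", "cyanobacteria", "bacteria", "fungi",
                              "algae", "plant", "animal", "unknown")]
    counts = pd.DataFrame(0, index=taxon_rows, columns=states, dtype=int)
    unclassified = []
    for call in calls:
        if call.subgroup == SUBGROUP_UNCLASSIFIED:
            unclassified.append(call.query_id)
            continue
        if call.query_id not in taxa:
            raise TriadError(f"query {call.query_id!r} missing from taxon table")
        counts.loc[taxa[call.query_id], call.second_state] += 1
    return DistributionTable(counts=counts, unclassified=unclassified)


def write_triad_calls(calls: Iterable[TriadCall], path) -> None:
    """TSV report: one row per call with positions, residues, subgroup, flags."""
    rows = []
    for c in calls:
        rows.append(
            {
                "query_id": c.query_id,
                "anchor_id": c.anchor_id,
                "pos1": c.positions[0] if c.positions[0] is not UNMAPPED else "NA",
                "res1": c.residues[0],
                "pos2": c.positions[1] if c.positions[1] is not UNMAPPED else "NA",
                "res2": c.residues[1],
                "pos3": c.positions[2] if c.positions[2] is not UNMAPPED else "NA",
                "res3": c.residues[2],
                "subgroup": c.subgroup,
                "anchor_identity_pct": round(c.anchor_identity_pct, 2),
                "flags": ",".join(sorted(c.flags)) or "-",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
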