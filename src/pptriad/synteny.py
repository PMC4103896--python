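"""Gene-neighborhood conservation and duplication/HGT origin inference.

Two homologous loci that arose by recent gene duplication are expected to
share (i) the same triad configuration, (ii) high protein identity and
still-detectable DNA-level identity, and (iii) a conserved gene
neighborhood. Loci meeting all three are called ``duplication``; anything
else is called ``independent_origin``. A separate phylogenetic screen
flags a horizontal-gene-transfer signal when a focal set of leaves with a
shared subgroup nests inside a clade dominated by the other taxon domain
(e.g. plant three-Mg enzymes among prokaryotes).

Neighborhood conservation is quantified as the Jaccard index of the
orthogroup label sets within a fixed window up- and downstream of each
locus, strand-insensitive by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional

import dendropy

from .phylo import PhyloError, midpoint_root, mrca_leafset
from .seqio import TaxonTable
from .triad import SUBGROUP_UNCLASSIFIED, TriadCall

PROKARYOTE_TAXA = frozenset({"archaea", "cyanobacteria", "bacteria"})
EUKARYOTE_TAXA = frozenset({"fungi", "algae", "plant", "animal"})

VERDICT_DUPLICATION = "duplication"
VERDICT_INDEPENDENT = "independent_origin"


class SyntenyError(ValueError):
    pass


@dataclass(frozen=True)
class SyntenyNeighborhood:
    """Ordered, stranded orthogroup labels flanking one locus.

    ``upstream``/``downstream`` are tuples of ``(orthogroup_label, strand)``
    ordered outward from the locus, at most ``window`` genes each side.
    """

    locus_id: str
    upstream: tuple[tuple[str, str], ...]
    downstream: tuple[tuple[str, str], ...]
    window: int = 5

    def __post_init__(self) -> None:
        for side in (self.upstream, self.downstream):
            if len(side) > self.window:
                raise SyntenyError(
                    f"{self.locus_id}: neighborhood longer than window {self.window}"
                )
            for label, strand in side:
                if not label:
                    raise SyntenyError(f"{self.locus_id}: empty orthogroup label")
                if strand not in ("+", "-"):
                    raise SyntenyError(f"{self.locus_id}: bad strand {strand!r}")

    def labels(self, strand_aware: bool = False) -> frozenset:
        items = list(self.upstream) + list(self.downstream)
        if strand_aware:
            return frozenset(items)
        return frozenset(label for label, _ in items)


def synteny_score(
    a: SyntenyNeighborhood, b: SyntenyNeighborhood, strand_aware: bool = False
) -> float:
    """Jaccard index of the two windows' orthogroup label sets in [0, 1].

    Returns 0.0 when either window is empty. Strand is ignored unless
    ``strand_aware`` is set, in which case (label, strand) pairs must match.
    """
    if a.window != b.window:
        raise SyntenyError(f"window mismatch: {a.window} vs {b.window}")
    sa, sb = a.labels(strand_aware), b.labels(strand_aware)
    if not sa or not sb:
        return 0.0
    return len(sa & sb) / len(sa | sb)


@dataclass(frozen=True)
class OriginCall:
    """Duplication / independent-origin verdict with its evidence."""

    pair: tuple[str, str]
    verdict: str
    same_triad: bool
    protein_identity_pct: float
    dna_identity_detectable: Optional[bool]  # None = DNA unavailable
    synteny_score: float
    flags: frozenset[str] = frozenset()

    def to_json(self) -> str:
        return json.dumps(
            {
                "pair": list(self.pair),
                "verdict": self.verdict,
                "evidence": {
                    "same_triad": self.same_triad,
                    "protein_identity_pct": round(self.protein_identity_pct, 2),
                    "dna_identity_detectable": self.dna_identity_detectable,
                    "synteny_score": round(self.synteny_score, 4),
                },
                "flags": sorted(self.flags),
            }
        )


def classify_pair_origin(
    triad_a: TriadCall,
    triad_b: TriadCall,
    protein_identity_pct: float,
    dna_identity_detectable: Optional[bool],
    synteny: float,
    t_id: float = 50.0,
    t_syn: float = 0.3,
) -> OriginCall:
    """Apply the duplication decision rule to one locus pair.

    ``duplication`` requires ALL of: identical second triad residue and
    subgroup, protein identity ≥ ``t_id``, detectable DNA-level identity,
    and synteny score ≥ ``t_syn``; otherwise ``independent_origin``.
    When DNA sequence is unavailable (``dna_identity_detectable=None``)
    the DNA condition is waived and the call flagged ``protein_only``.
    The rule is symmetric in the pair.
    """
    for t in (triad_a, triad_b):
        if t.subgroup == SUBGROUP_UNCLASSIFIED:
            raise SyntenyError(f"triad call for {t.query_id!r} is unclassified")
    same_triad = (
        triad_a.residues[1] == triad_b.residues[1]
        and triad_a.subgroup == triad_b.subgroup
    )
    flags = set()
    if dna_identity_detectable is None:
        flags.add("protein_only")
        dna_ok = True
    else:
        dna_ok = dna_identity_detectable
    is_dup = (
        same_triad
        and protein_identity_pct >= t_id
        and dna_ok
        and synteny >= t_syn
    )
    return OriginCall(
        pair=(triad_a.query_id, triad_b.query_id),
        verdict=VERDICT_DUPLICATION if is_dup else VERDICT_INDEPENDENT,
        same_triad=same_triad,
        protein_identity_pct=protein_identity_pct,
        dna_identity_detectable=dna_identity_detectable,
        synteny_score=synteny,
        flags=frozenset(flags),
    )


def hgt_signal(
    tree: dendropy.Tree,
    taxa: TaxonTable,
    subgroups: Mapping[str, str],
    focal: set[str],
) -> bool:
    """Horizontal-transfer signal for a focal leaf set.

    True iff (i) every focal leaf carries the same subgroup, and (ii) on
    the midpoint-rooted tree, the smallest clade containing all focal
    leaves has a majority of its non-focal leaves from the opposite taxon
    domain (prokaryote vs eukaryote) to the focal leaves. Reported as a
    signal, not a proven event.
    """
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    unknown = set(focal) - leaves
    if unknown:
        raise PhyloError(f"unknown focal ids: {sorted(unknown)}")
    missing_taxa = [l for l in leaves if l not in taxa]
    if missing_taxa:
        raise PhyloError(f"leaves missing from taxon table: {sorted(missing_taxa)}")
    if not focal:
        return False
    focal_subgroups = {subgroups[l] for l in focal}
    if len(focal_subgroups) != 1:
        return False

    def domain(leaf: str) -> Optional[str]:
        t = taxa[leaf]
        if t in PROKARYOTE_TAXA:
            return "prokaryote"
        if t in EUKARYOTE_TAXA:
            return "eukaryote"
        return None

    focal_domains = {domain(l) for l in focal}
    if len(focal_domains) != 1 or None in focal_domains:
        return False
    focal_domain = focal_domains.pop()

    rooted = tree if tree.is_rooted else midpoint_root(tree)
    node = rooted.mrca(taxon_labels=list(focal))
    if node is None:
        raise PhyloError(f"no MRCA found for {sorted(focal)}")
    # smallest clade that actually places the focal leaves among neighbors:
    # ascend while the clade contains no non-focal leaf (singleton focal sets)
    clade = frozenset(l.taxon.label for l in node.leaf_iter())
    while clade <= set(focal) and node.parent_node is not None:
        node = node.parent_node
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
    others = clade - set(focal)
    if not others:
        return False
    foreign = sum(1 for l in others if domain(l) is not None and domain(l) != focal_domain)
    return foreign > len(others) / 2


def read_synteny_table(path, window: int = 5) -> dict[str, SyntenyNeighborhood]:
    """Read neighborhoods from TSV: locus_id, side (up/down), rank, orthogroup, strand."""
    raw: dict[str, dict[str, list]] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if line_no == 1 and parts[0].lower() == "locus_id":
                continue
            if len(parts) != 5:
                raise SyntenyError(f"{path}:{line_no}: expected 5 columns")
            locus, side, rank, og, strand = parts
            if side not in ("up", "down"):
                raise SyntenyError(f"{path}:{line_no}: bad side {side!r}")
            raw.setdefault(locus, {"up": [], "down": []})[side].append((int(rank), og, strand))
    out = {}
    for locus, sides in raw.items():
        up = tuple((og, st) for _, og, st in sorted(sides["up"]))
        down = tuple((og, st) for _, og, st in sorted(sides["down"]))
        out[locus] = SyntenyNeighborhood(locus, up, down, window=window)
    return out


def write_synteny_table(neighborhoods: Mapping[str, SyntenyNeighborhood], path) -> None:
    with open(path, "w") as handle:
        handle.write("locus_id\tside\trank\torthogroup\tstrand\n")
        for locus, nb in neighborhoods.items():
            for side, genes in (("up", nb.upstream), ("down", nb.downstream)):
                for rank, (og, strand) in enumerate(genes, start=1):
                    handle.write(f"{locus}\t{side}\t{rank}\t{og}\t{strand}\n")
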