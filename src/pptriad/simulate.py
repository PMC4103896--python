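"""Synthetic PPTase-family simulator with full ground truth.

Generates protein families that look like group II PPTase data sets —
a taxon-blocked gene tree, sequences with a conserved Asp-Xxx-Glu motif
amid divergent background, indels that never touch the motif, clade-fixed
second-residue states with planted change events, gene duplications,
horizontal transfers, and synteny neighborhoods conserved only where the
generating process says so. Every stochastic choice is logged in a
:class:`SimTruth` object so each pipeline stage can be scored against
known truth without any external data.

Default family composition mirrors a representative 56-member set:
4 archaea, 4 cyanobacteria, 14 bacteria, 11 fungi, 3 algae, 10 plants and
10 animals, with second-residue states Glu for prokaryotes, Met for
animals, Ala for algae and Val for fungi/plants.

Reproducibility: one integer seed drives four independent derived RNG
streams (tree = [seed, 0], sequences = [seed, 1], duplication/HGT events
= [seed, 2], synteny = [seed, 3]).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np

from .seqio import SeqRecord, TaxonTable, write_fasta, write_taxon_table
from .synteny import SyntenyNeighborhood, write_synteny_table
from .triad import TriadAnchor

_AA = "ACDEFGHIKLMNPQRSTVWY"

#: One fixed codon per amino acid (common E. coli usage) for back-translation.
CODON_TABLE = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGC", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
}

_SYNONYMS = {
    "A": ("GCG", "GCC", "GCA", "GCT"), "C": ("TGC", "TGT"),
    "D": ("GAT", "GAC"), "E": ("GAA", "GAG"), "F": ("TTT", "TTC"),
    "G": ("GGC", "GGT", "GGA", "GGG"), "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"), "K": ("AAA", "AAG"),
    "L": ("CTG", "TTA", "CTC", "CTT"), "M": ("ATG",),
    "N": ("AAC", "AAT"), "P": ("CCG", "CCA", "CCT", "CCC"),
    "Q": ("CAG", "CAA"), "R": ("CGT", "CGC", "AGA", "CGG"),
    "S": ("AGC", "TCT", "TCC", "AGT"), "T": ("ACC", "ACT", "ACA", "ACG"),
    "V": ("GTG", "GTT", "GTC", "GTA"), "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}

_GUARD = 2  # indel exclusion half-width around motif positions


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of one simulated family; defaults emulate the study scale."""

    taxon_blocks: dict[str, int] = field(
        default_factory=lambda: {
            "archaea": 4, "cyanobacteria": 4, "bacteria": 14,
            "fungi": 11, "algae": 3, "plant": 10, "animal": 10,
        }
    )
    seq_length: int = 240  # group II PPTases are >220 aa
    motif_positions: tuple[int, int, int] = (107, 109, 151)
    second_state_by_clade: dict[str, str] = field(
        default_factory=lambda: {
            "archaea": "E", "cyanobacteria": "E", "bacteria": "E",
            "fungi": "V", "algae": "A", "plant": "V", "animal": "M",
        }
    )
    root_second_state: str = "E"
    sub_rate: float = 0.3  # expected root-to-tip substitutions/site
    indel_rate: float = 1.0  # expected indel events per root-to-tip lineage
    indel_len_geometric_p: float = 0.5
    n_duplications: int = 1
    n_hgt: int = 1
    dup_divergence: float = 0.02
    hgt_divergence: float = 0.05
    hgt_donor_taxon: str = "bacteria"
    hgt_recipient_taxon: str = "plant"
    synteny_window: int = 5
    synteny_dropout: float = 0.25
    conserved_synteny_taxa: tuple[str, ...] = ("animal",)
    codon_wobble: float = 0.0
    min_internal_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        p1, p2, p3 = self.motif_positions
        if not (1 <= p1 < p2 < p3 <= self.seq_length):
            raise SimulationError("motif positions must be increasing and within seq_length")
        if min(self.sub_rate, self.indel_rate) < 0:
            raise SimulationError("rates must be non-negative")
        if not 0 < self.indel_len_geometric_p <= 1:
            raise SimulationError("indel_len_geometric_p must be in (0, 1]")

    @property
    def n_species(self) -> int:
        return sum(self.taxon_blocks.values())

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class IndelEvent:
    kind: str  # "ins" | "del"
    point: int  # 0-based: insertion point, or deletion start
    length: int


@dataclass
class SimTruth:
    """Ground-truth record of everything the simulator decided."""

    tree: dendropy.Tree
    leaf_motif: dict[str, dict] = field(default_factory=dict)
    state_changes: int = 0
    indel_events: dict[str, list[IndelEvent]] = field(default_factory=dict)
    duplications: list[tuple[str, str]] = field(default_factory=list)
    hgt_events: list[tuple[str, str]] = field(default_factory=list)
    conserved_synteny_groups: list[list[str]] = field(default_factory=list)

    def taxon_table(self) -> TaxonTable:
        table = TaxonTable()
        for leaf_id in self.leaf_motif:
            table.add(leaf_id, leaf_taxon(leaf_id))
        return table

    def make_anchor(self, leaf_id: str, records: list[SeqRecord]) -> TriadAnchor:
        """Turn one simulated family member into a coordinate anchor."""
        rec = next(r for r in records if r.id == leaf_id)
        info = self.leaf_motif[leaf_id]
        return TriadAnchor(
            id=leaf_id,
            record=rec,
            positions=tuple(info["positions"]),
            expected_residues=tuple(info["residues"]),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "tree_newick": self.tree.as_string(schema="newick").strip(),
                "leaf_motif": self.leaf_motif,
                "state_changes": self.state_changes,
                "indel_events": {
                    k: [asdict(e) for e in v] for k, v in self.indel_events.items()
                },
                "duplications": self.duplications,
                "hgt_events": self.hgt_events,
                "conserved_synteny_groups": self.conserved_synteny_groups,
            },
            indent=1,
        )


def leaf_taxon(leaf_id: str) -> str:
    """Taxon group encoded in a simulated leaf id (``taxon_NN`` or ``..._dup``)."""
    return leaf_id.split("_")[0]


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def _yule_subtree(rng: np.random.Generator, labels: list[str], height: float) -> dendropy.Node:
    """Ultrametric pure-birth subtree over the given labels, scaled to height.

    Forward simulation with unit birth rate and a uniformly chosen lineage
    at each split (equal-rates-Markov topology), then linearly rescaled so
    every leaf sits exactly at ``height``.
    """
    n = len(labels)
    root = dendropy.Node()
    if n == 1:
        leaf = dendropy.Node()
        leaf.sim_label = labels[0]
        leaf.edge.length = height
        root.add_child(leaf)
        return root

    # (node, birth_time) for each active lineage
    first = dendropy.Node()
    second = dendropy.Node()
    root.add_child(first)
    root.add_child(second)
    active = [(first, 0.0), (second, 0.0)]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        node, birth = active.pop(idx)
        node.edge.length = t - birth
        c1, c2 = dendropy.Node(), dendropy.Node()
        node.add_child(c1)
        node.add_child(c2)
        active.extend([(c1, t), (c2, t)])
    t += rng.exponential(1.0 / n)
    order = rng.permutation(n)
    for (node, birth), k in zip(active, order):
        node.edge.length = t - birth
        node.sim_label = labels[int(k)]
    # rescale to the requested height
    for node in root.preorder_iter():
        if node.edge.length is not None:
            node.edge.length *= height / t if t > 0 else 0.0
    return root


def _floor_internal_edges(tree: dendropy.Tree, frac: float) -> None:
    """Raise every internal edge to at least ``frac`` × tree height.

    Pure-birth trees routinely contain internal edges orders of magnitude
    shorter than the tree height; at realistic sequence lengths those edges
    carry no recoverable signal, which would make any topology-recovery
    statistic measure the data rather than the method. Flooring changes
    only branch lengths — the topology distribution stays equal-rates-
    Markov — and the tree is re-ultrametrized (leaf edges extended) and
    rescaled back to its original height.
    """

    def depth(node) -> float:
        d = 0.0
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        return d

    height = max(depth(l) for l in tree.leaf_node_iter())
    if height <= 0 or frac <= 0:
        return
    floor = frac * height
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and not node.is_leaf():
            node.edge.length = max(node.edge.length or 0.0, floor)
    parent_depth = {leaf: depth(leaf.parent_node) for leaf in tree.leaf_node_iter()}
    new_height = max(max(parent_depth.values()) + floor, height)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = new_height - parent_depth[leaf]
    scale = height / new_height
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length *= scale


def simulate_tree(cfg: SimConfig) -> dendropy.Tree:
    """Taxon-blocked ultrametric gene tree with root-to-tip length ``sub_rate``.

    Each taxon block is a pure-birth subtree (hence monophyletic); blocks
    are joined by a pure-birth backbone occupying the deepest 40% of the
    tree height. With a single block the topology is exactly Yule.
    Internal edges are floored at ``min_internal_frac`` of the height (see
    :func:`_floor_internal_edges`). Leaves are labelled ``{taxon}_{NN}``.
    """
    if cfg.n_species < 3:
        raise SimulationError("need at least 3 species")
    if any(c < 1 for c in cfg.taxon_blocks.values()):
        raise SimulationError("every taxon block needs at least one species")
    rng = cfg.rng(0)
    height = cfg.sub_rate if cfg.sub_rate > 0 else 1.0
    blocks = list(cfg.taxon_blocks.items())

    if len(blocks) == 1:
        taxon, count = blocks[0]
        labels = [f"{taxon}_{i:02d}" for i in range(1, count + 1)]
        top = _yule_subtree(rng, labels, height)
    else:
        backbone_height = 0.4 * height
        block_height = height - backbone_height
        top = _yule_subtree(rng, [name for name, _ in blocks], backbone_height)
        # replace each backbone tip with the block subtree
        for node in list(top.leaf_iter()):
            taxon = node.sim_label
            count = cfg.taxon_blocks[taxon]
            labels = [f"{taxon}_{i:02d}" for i in range(1, count + 1)]
            sub = _yule_subtree(rng, labels, block_height)
            stem = node.edge.length
            children = list(sub.child_nodes())
            if count == 1:
                child = children[0]
                node.sim_label = child.sim_label
                node.edge.length = stem + child.edge.length
            else:
                node.sim_label = None
                for child in children:
                    node.add_child(child)

    tree = dendropy.Tree()
    tree.seed_node = top
    tns = tree.taxon_namespace
    for leaf in tree.leaf_node_iter():
        leaf.taxon = tns.new_taxon(leaf.sim_label)
    tree.is_rooted = True
    if cfg.sub_rate == 0:
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length = 0.0
    else:
        _floor_internal_edges(tree, cfg.min_internal_frac)
    return tree


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _substitute(rng: np.random.Generator, seq: list[str], t: float, frozen: set[int]) -> None:
    """Per-site Poisson(t) substitution events, uniform among the other 19."""
    if t <= 0:
        return
    counts = rng.poisson(t, size=len(seq))
    for i in np.nonzero(counts)[0]:
        if int(i) in frozen:
            continue
        for _ in range(int(counts[i])):
            choices = [a for a in _AA if a != seq[i]]
            seq[int(i)] = str(choices[int(rng.integers(19))])


def _guard_zone(motif: tuple[int, int, int]) -> list[tuple[int, int]]:
    """Closed 0-based index intervals no indel may touch (motif ± guard)."""
    return [(m - 1 - _GUARD, m - 1 + _GUARD) for m in motif]


def _apply_indels(
    rng: np.random.Generator,
    seq: list[str],
    motif: list[int],
    n_events: int,
    geom_p: float,
    events_out: list[IndelEvent],
) -> None:
    for _ in range(n_events):
        placed = False
        for _attempt in range(200):
            kind = "ins" if rng.random() < 0.5 else "del"
            length = int(rng.geometric(geom_p))
            zones = _guard_zone(tuple(motif))
            if kind == "ins":
                point = int(rng.integers(0, len(seq) + 1))
                # an insertion at `point` splits residues point-1 | point
                if any(lo + 1 <= point <= hi for lo, hi in zones):
                    continue
                seq[point:point] = [str(a) for a in rng.choice(list(_AA), size=length)]
                for k in range(3):
                    if point <= motif[k] - 1:
                        motif[k] += length
                events_out.append(IndelEvent("ins", point, length))
            else:
                if length >= len(seq):
                    continue
                start = int(rng.integers(0, len(seq) - length + 1))
                end = start + length  # deletes [start, end)
                if any(start <= hi and end - 1 >= lo for lo, hi in zones):
                    continue
                del seq[start:end]
                for k in range(3):
                    if end - 1 < motif[k] - 1:
                        motif[k] -= length
                events_out.append(IndelEvent("del", start, length))
            placed = True
            break
        if not placed:
            raise SimulationError("could not place an indel outside the motif guard band")


def evolve_family(tree: dendropy.Tree, cfg: SimConfig) -> tuple[list[SeqRecord], SimTruth]:
    """Evolve sequences down the tree; returns leaf records plus truth.

    The first and third motif positions are frozen at Asp and Glu; the
    second is pinned to each taxon block's assigned state, switching on
    the block's stem edge (each switch is a planted state-change event).
    Indels never enter a ±2-residue guard band around motif positions, so
    true motif coordinates remain well-defined in every leaf.
    """
    rng = cfg.rng(1)
    truth = SimTruth(tree=tree)

    root_seq = [str(a) for a in rng.choice(list(_AA), size=cfg.seq_length)]
    p1, p2, p3 = cfg.motif_positions
    root_seq[p1 - 1] = "D"
    root_seq[p2 - 1] = cfg.root_second_state
    root_seq[p3 - 1] = "E"

    # block stem nodes (MRCA of each block; equals the leaf for blocks of 1)
    block_root: dict[int, str] = {}
    for taxon in cfg.taxon_blocks:
        labels = [l.taxon.label for l in tree.leaf_node_iter()
                  if leaf_taxon(l.taxon.label) == taxon]
        if not labels:
            continue
        if len(labels) == 1:
            node = next(l for l in tree.leaf_node_iter() if l.taxon.label == labels[0])
        else:
            node = tree.mrca(taxon_labels=labels)
        block_root[id(node)] = taxon

    heights = []
    for leaf in tree.leaf_node_iter():
        h, node = 0.0, leaf
        while node.parent_node is not None:
            h += node.edge.length or 0.0
            node = node.parent_node
        heights.append(h)
    height = max(heights) if heights else 0.0

    known_taxa = ("archaea", "cyanobacteria", "bacteria", "fungi",
                  "algae", "plant", "animal")
    records: list[SeqRecord] = []

    def descend(node, seq: list[str], motif: list[int], state: str,
                events: list[IndelEvent]) -> None:
        if id(node) in block_root:
            new_state = cfg.second_state_by_clade.get(block_root[id(node)], state)
            if new_state != state:
                truth.state_changes += 1
                state = new_state
            seq = list(seq)
            seq[motif[1] - 1] = state
        if node.is_leaf():
            label = node.taxon.label
            records.append(
                SeqRecord(
                    id=label,
                    residues="".join(seq),
                    alphabet="protein",
                    taxon=leaf_taxon(label) if leaf_taxon(label) in known_taxa else "unknown",
                )
            )
            truth.leaf_motif[label] = {
                "positions": list(motif),
                "residues": [seq[m - 1] for m in motif],
            }
            truth.indel_events[label] = events
            return
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            child_seq = list(seq)
            child_motif = list(motif)
            child_events = list(events)
            # the motif and its ±GUARD flanks are conserved columns: flank
            # conservation is what makes alignment-based coordinate
            # transfer well-posed in the real family, so the simulator
            # preserves it too
            frozen = {
                i
                for m in child_motif
                for i in range(m - 1 - _GUARD, m + _GUARD)
                if 0 <= i < len(child_seq)
            }
            _substitute(rng, child_seq, t, frozen)
            if cfg.indel_rate > 0 and height > 0:
                n_indels = int(rng.poisson(cfg.indel_rate * t / height))
                _apply_indels(rng, child_seq, child_motif, n_indels,
                              cfg.indel_len_geometric_p, child_events)
            # motif is invariant apart from the clade-pinned second state
            child_seq[child_motif[0] - 1] = "D"
            child_seq[child_motif[2] - 1] = "E"
            child_seq[child_motif[1] - 1] = state
            descend(child, child_seq, child_motif, state, child_events)

    descend(tree.seed_node, root_seq, list(cfg.motif_positions),
            cfg.root_second_state, [])
    return records, truth


# ---------------------------------------------------------------------------
# Duplication / HGT
# ---------------------------------------------------------------------------

def _diverge_copy(rng: np.random.Generator, rec: SeqRecord,
                  motif: tuple[int, int, int], rate: float) -> str:
    seq = list(rec.residues)
    frozen = {
        i
        for m in motif
        for i in range(m - 1 - _GUARD, m + _GUARD)
        if 0 <= i < len(seq)
    }
    _substitute(rng, seq, rate, frozen)
    return "".join(seq)


def simulate_duplication_hgt(
    records: list[SeqRecord], truth: SimTruth, cfg: SimConfig
) -> tuple[list[SeqRecord], SimTruth]:
    """Plant duplication and HGT events into an evolved family.

    Each duplication appends a slightly diverged copy of a random leaf
    (id ``<leaf>_dup``) whose synteny neighborhood will later be copied
    intact. Each HGT replaces a recipient-taxon leaf's sequence with a
    slightly diverged copy of a donor-taxon sequence — the recipient keeps
    its id and taxon, gains the donor's second-residue state, and does NOT
    inherit the donor's neighborhood. All events are logged in the truth.
    """
    rng = cfg.rng(2)
    records = list(records)
    by_id = {r.id: r for r in records}

    leaf_ids = sorted(truth.leaf_motif)
    if cfg.n_duplications > len(leaf_ids):
        raise SimulationError("more duplications requested than available leaves")

    for _ in range(cfg.n_duplications):
        source_id = str(rng.choice(leaf_ids))
        source = by_id[source_id]
        info = truth.leaf_motif[source_id]
        dup_id = f"{source_id}_dup"
        if dup_id in by_id:
            raise SimulationError(f"duplicate id collision: {dup_id}")
        residues = _diverge_copy(rng, source, tuple(info["positions"]), cfg.dup_divergence)
        dup = SeqRecord(id=dup_id, residues=residues, alphabet="protein", taxon=source.taxon)
        records.append(dup)
        by_id[dup_id] = dup
        truth.leaf_motif[dup_id] = {
            "positions": list(info["positions"]),
            "residues": list(info["residues"]),
        }
        truth.indel_events[dup_id] = list(truth.indel_events.get(source_id, []))
        truth.duplications.append((source_id, dup_id))

    donors = [l for l in leaf_ids if leaf_taxon(l) == cfg.hgt_donor_taxon]
    recipients = [l for l in leaf_ids if leaf_taxon(l) == cfg.hgt_recipient_taxon]
    if cfg.n_hgt > 0 and (not donors or cfg.n_hgt > len(recipients)):
        raise SimulationError("not enough donor/recipient leaves for requested HGT events")
    chosen_recipients = [str(x) for x in rng.choice(recipients, size=cfg.n_hgt, replace=False)] if cfg.n_hgt else []
    for recipient_id in chosen_recipients:
        donor_id = str(rng.choice(donors))
        donor = by_id[donor_id]
        donor_info = truth.leaf_motif[donor_id]
        residues = _diverge_copy(rng, donor, tuple(donor_info["positions"]), cfg.hgt_divergence)
        recipient_old = by_id[recipient_id]
        new_rec = SeqRecord(
            id=recipient_id, residues=residues,
            alphabet="protein", taxon=recipient_old.taxon,
        )
        records[records.index(recipient_old)] = new_rec
        by_id[recipient_id] = new_rec
        truth.leaf_motif[recipient_id] = {
            "positions": list(donor_info["positions"]),
            "residues": list(donor_info["residues"]),
        }
        truth.indel_events[recipient_id] = list(truth.indel_events.get(donor_id, []))
        truth.hgt_events.append((donor_id, recipient_id))
    return records, truth


# ---------------------------------------------------------------------------
# Synteny simulation
# ---------------------------------------------------------------------------

def _fresh_label(rng: np.random.Generator) -> str:
    return f"OG{int(rng.integers(10**8)):08d}"


def simulate_synteny(
    records: list[SeqRecord], truth: SimTruth, cfg: SimConfig
) -> dict[str, SyntenyNeighborhood]:
    """Assign a 2×window orthogroup neighborhood to every locus.

    Loci of the configured conserved taxa share a block-wide template with
    per-gene dropout (replaced by a fresh label); duplicated loci copy
    their source neighborhood intact; HGT recipients draw fresh labels
    (transfer moves the gene, not its neighborhood); everything else is
    independent random labels from a large space.
    """
    rng = cfg.rng(3)
    k = cfg.synteny_window
    dup_copies = {copy: src for src, copy in truth.duplications}
    neighborhoods: dict[str, SyntenyNeighborhood] = {}

    def fresh_side() -> tuple[tuple[str, str], ...]:
        return tuple(
            (_fresh_label(rng), "+" if rng.random() < 0.5 else "-") for _ in range(k)
        )

    templates: dict[str, tuple] = {}
    for taxon in cfg.conserved_synteny_taxa:
        templates[taxon] = (fresh_side(), fresh_side())

    conserved_groups: dict[str, list[str]] = {t: [] for t in cfg.conserved_synteny_taxa}

    for rec in records:
        if rec.id in dup_copies:
            continue  # copied after its source is placed
        taxon = leaf_taxon(rec.id)
        if taxon in templates:
            up_t, down_t = templates[taxon]
            def drop(side):
                return tuple(
                    (og if rng.random() >= cfg.synteny_dropout else _fresh_label(rng), st)
                    for og, st in side
                )
            neighborhoods[rec.id] = SyntenyNeighborhood(rec.id, drop(up_t), drop(down_t), window=k)
            conserved_groups[taxon].append(rec.id)
        else:
            neighborhoods[rec.id] = SyntenyNeighborhood(rec.id, fresh_side(), fresh_side(), window=k)

    for copy_id, src_id in dup_copies.items():
        src_nb = neighborhoods[src_id]
        neighborhoods[copy_id] = SyntenyNeighborhood(
            copy_id, src_nb.upstream, src_nb.downstream, window=k
        )

    truth.conserved_synteny_groups = [g for g in conserved_groups.values() if len(g) > 1]
    truth.conserved_synteny_groups += [[s, c] for s, c in truth.duplications]
    return neighborhoods


# ---------------------------------------------------------------------------
# Dataset emission
# ---------------------------------------------------------------------------

def back_translate(rec: SeqRecord, rng: Optional[np.random.Generator] = None,
                   wobble: float = 0.0) -> SeqRecord:
    """Protein → DNA via the fixed codon table, with optional synonymous noise."""
    codons = []
    for aa in rec.residues:
        codon = CODON_TABLE.get(aa, "NNN")
        if wobble > 0 and rng is not None and aa in _SYNONYMS and rng.random() < wobble:
            codon = str(rng.choice(_SYNONYMS[aa]))
        codons.append(codon)
    return SeqRecord(id=rec.id, residues="".join(codons), alphabet="dna", taxon=rec.taxon)


def simulate_family(cfg: SimConfig):
    """Run tree → sequences → duplication/HGT → synteny; return everything."""
    tree = simulate_tree(cfg)
    records, truth = evolve_family(tree, cfg)
    records, truth = simulate_duplication_hgt(records, truth, cfg)
    neighborhoods = simulate_synteny(records, truth, cfg)
    return records, neighborhoods, truth


def generate_dataset(cfg: SimConfig, outdir) -> dict[str, Path]:
    """Write a complete simulated data set to ``outdir``.

    Emits ``proteins.fasta``, ``dna.fasta`` (codon back-translation),
    ``taxa.tsv``, ``synteny.tsv`` and ``truth.json``; deterministic per
    seed. Returns the path of each artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, neighborhoods, truth = simulate_family(cfg)
    rng = cfg.rng(4)
    dna = [back_translate(r, rng, cfg.codon_wobble) for r in records]

    paths = {
        "proteins": outdir / "proteins.fasta",
        "dna": outdir / "dna.fasta",
        "taxa": outdir / "taxa.tsv",
        "synteny": outdir / "synteny.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(records, paths["proteins"])
    write_fasta(dna, paths["dna"])
    table = TaxonTable()
    for r in records:
        table.add(r.id, r.taxon)
    write_taxon_table(table, paths["taxa"])
    write_synteny_table(neighborhoods, paths["synteny"])
    paths["truth"].write_text(truth.to_json())
    return paths
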