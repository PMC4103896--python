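"""SYNTHETIC stand-in anchor sequences for triad detection.

The canonical coordinate anchors for this family are the Bacillus
subtilis enzyme Sfp (triad D107/E109/E151) and the human enzyme
(D129/·/E181, which lacks the second Mg ligand); SchPPT-type
(D105/E107/E151) and Sppt-type (Gln at the second position, Q112)
sequences exercise the two mutational backgrounds studied
experimentally. The real proteins live behind accessions a user can
fetch; this module instead constructs SYNTHETIC sequences that carry
exactly those triad coordinates and realistic mutual divergence, so that
coordinate transfer, classification and all downstream stages can run —
and be validated against known ground truth — without any network access.

Users with the real sequences can build :class:`~pptriad.triad.TriadAnchor`
objects from them directly; everything downstream is agnostic to where the
anchor came from.

Construction (fixed internal seed, hence bit-reproducible):

* ``sfp_like`` — 224 aa random protein, D/E/E planted at 107/109/151,
  ±5-residue conserved windows around each triad site.
* ``aashdppt_like`` — derived from ``sfp_like`` by 22 extra N-terminal
  residues, an 8-residue insertion between the second and third triad
  sites, ~30% substitutions outside the conserved windows, and Met at the
  second site → triad coordinates 129/131/181, reported subgroup two-Mg.
* ``schppt_like`` — 2-residue N-terminal deletion plus a compensating
  2-residue internal insertion and ~25% substitutions → 105/107/151, D-E-E.
* ``sppt_like`` — 3 extra N-terminal residues, Gln at the second site and
  ~25% substitutions → 110/112/154, D-Q-E.
"""

from __future__ import annotations

import numpy as np

from .seqio import SeqRecord
from .triad import TriadAnchor

_AA = "ACDEFGHIKLMNPQRSTVWY"
_SEED = 73902641  # fixed: anchors must be identical across runs/installs

SFP_TRIAD = (107, 109, 151)
AASHDPPT_TRIAD = (129, 131, 181)
SCHPPT_TRIAD = (105, 107, 151)
SPPT_TRIAD = (110, 112, 154)

_GUARD = 5  # conserved flank half-width around each triad site


def _random_protein(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(list(_AA), size=length))


def _protected(positions: tuple[int, int, int], length: int) -> set[int]:
    """0-based indices inside the conserved windows around triad sites."""
    keep: set[int] = set()
    for p in positions:
        for i in range(p - 1 - _GUARD, p + _GUARD):
            if 0 <= i < length:
                keep.add(i)
    return keep


def _mutate(rng: np.random.Generator, seq: list[str], frac: float, protected: set[int]) -> list[str]:
    out = list(seq)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < frac:
            choices = [a for a in _AA if a != out[i]]
            out[i] = str(rng.choice(choices))
    return out


def _build() -> dict[str, SeqRecord]:
    rng = np.random.default_rng(_SEED)

    base = _random_protein(rng, 224)
    base[106], base[108], base[150] = "D", "E", "E"
    protect = _protected(SFP_TRIAD, len(base))
    sfp = list(base)

    # human-enzyme-like: +22 N-terminal, +8 between sites 2 and 3, Met at site 2
    aas_core = _mutate(rng, sfp, 0.30, protect)
    aas_core[108] = "M"
    insert8 = _random_protein(rng, 8)
    aas = _random_protein(rng, 22) + aas_core[:130] + insert8 + aas_core[130:]

    # SchPPT-like: drop 2 near the N-terminus, insert 2 between sites 2 and 3
    sch_core = _mutate(rng, sfp, 0.25, protect)
    insert2 = _random_protein(rng, 2)
    sch = sch_core[:40] + sch_core[42:130] + insert2 + sch_core[130:]

    # Sppt-like: +3 N-terminal, Gln at site 2
    sppt_core = _mutate(rng, sfp, 0.25, protect)
    sppt_core[108] = "Q"
    sppt = _random_protein(rng, 3) + sppt_core

    def rec(name: str, taxon: str, chars: list[str]) -> SeqRecord:
        return SeqRecord(
            id=name,
            residues="".join(chars),
            alphabet="protein",
            description=f"{name} synthetic stand-in anchor sequence",
            taxon=taxon,
        )

    return {
        "sfp_like": rec("sfp_like", "bacteria", sfp),
        "aashdppt_like": rec("aashdppt_like", "animal", aas),
        "schppt_like": rec("schppt_like", "bacteria", sch),
        "sppt_like": rec("sppt_like", "cyanobacteria", sppt),
    }


_RECORDS = _build()


def reference_records() -> dict[str, SeqRecord]:
    """The four synthetic stand-in sequences, keyed by name."""
    return dict(_RECORDS)


def builtin_anchors() -> list[TriadAnchor]:
    """The two bundled coordinate anchors (three-Mg and two-Mg archetypes).

    Each anchor validates its residue-at-position invariant on
    construction, so a corrupted bundle fails loudly at import of the
    caller, not silently downstream.
    """
    return [
        TriadAnchor(
            id="sfp_like",
            record=_RECORDS["sfp_like"],
            positions=SFP_TRIAD,
            expected_residues=("D", "E", "E"),
        ),
        TriadAnchor(
            id="aashdppt_like",
            record=_RECORDS["aashdppt_like"],
            positions=AASHDPPT_TRIAD,
            expected_residues=("D", "M", "E"),
        ),
    ]
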