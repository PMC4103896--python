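# pptriad

Classification and evolutionary analysis of **group II phosphopantetheinyl
transferases** (Sfp-type PPTases) by their magnesium-binding triad.

PPTases attach the 4′-phosphopantetheine arm of coenzyme A to a conserved
serine of acyl/peptidyl carrier proteins, switching them from apo to holo
form. Group II enzymes (> 220 aa, monomeric, internally pseudosymmetric)
coordinate their catalytic Mg²⁺ through up to three carboxylates at
alignment-homologous positions — the triad **Asp-Xxx-Glu**. Enzymes with
Glu at the middle position (e.g. *Bacillus subtilis* Sfp: D107/E109/E151)
use all three ligands ("three-Mg"); enzymes with any other residue there
(e.g. the human enzyme: D129/·/E181) use only the first and third
("two-Mg"). The second residue is dispensable for catalysis but is
clade-fixed — Met in animals, Ala in algae, mostly Val in fungi and
plants, Glu in most prokaryotes — which makes it a useful phylogenetic
character and a window on duplication and horizontal-transfer history.

`pptriad` packages that analysis as a reusable pipeline:

| stage | module | what it does |
|---|---|---|
| IO + filtering | `pptriad.seqio` | FASTA/taxon tables; homolog filter (> 35 % identity, > 70 % query coverage) |
| alignment | `pptriad.align` | global/local affine-gap alignment (BLOSUM62, 10/0.5), identity/similarity %, center-star MSA |
| triad calling | `pptriad.triad` | anchor-based coordinate transfer, two-Mg/three-Mg classification, taxon × residue tables |
| phylogenetics | `pptriad.phylo` | Poisson/p-distances, neighbor joining, bootstrap, midpoint rooting, monophyly, Fitch parsimony |
| origin calls | `pptriad.synteny` | synteny Jaccard scores, duplication vs independent origin, HGT signal |
| simulation | `pptriad.simulate` | ground-truth PPTase-family generator (tree, motif-constrained sequences, indels, duplications, HGT, synteny) |

Every stage is validated against independent oracles (exhaustive alignment
enumeration, exhaustive parsimony, least-squares topology scoring,
brute-force midpoint search, and the simulator's truth logs).

## Worked example

Generate a synthetic 56-member family (4 archaea, 4 cyanobacteria, 14
bacteria, 11 fungi, 3 algae, 10 plants, 10 animals, plus one gene
duplication and one prokaryote→plant transfer), then classify it using
the first family member as the coordinate anchor:

```bash
$ pptriad simulate --out sim --seed 7
$ pptriad classify --fasta sim/proteins.fasta --taxa sim/taxa.tsv --out cls \
      --anchor-fasta sim/proteins.fasta --anchor-positions 107,109,151
INFO pptriad: classified 57 sequences: 24 three-Mg, 33 two-Mg, 0 unclassified, 0 flagged

$ head -3 cls/triads.tsv
query_id    anchor_id   pos1 res1 pos2 res2 pos3 res3 subgroup  anchor_identity_pct flags
archaea_03  archaea_03  107  D    109  E    151  E    three_mg  100.0               -
archaea_02  archaea_03  110  D    112  E    154  E    three_mg  80.66               -

$ cat cls/distribution.tsv
taxon          E   M   V   A  T  Q  S  L  C  other  sum
archaea        5   0   0   0  0  0  0  0  0  0      5
cyanobacteria  4   0   0   0  0  0  0  0  0  0      4
bacteria       14  0   0   0  0  0  0  0  0  0      14
fungi          0   0   11  0  0  0  0  0  0  0      11
algae          0   0   0   3  0  0  0  0  0  0      3
plant          1   0   9   0  0  0  0  0  0  0      10
animal         0   10  0   0  0  0  0  0  0  0      10
...
```

Each `triads.tsv` row gives the query's mapped triad coordinates (1-based)
and residues — e.g. `archaea_02` carries its triad at 110/112/154 because
of an indel upstream of the motif — and the distribution table counts the
second-residue states per taxon group. The single plant `E` is the planted
horizontal-transfer recipient: a plant gene carrying the prokaryotic
three-Mg triad. Downstream:

```bash
pptriad tree   --fasta sim/proteins.fasta --taxa sim/taxa.tsv --out tr --bootstrap 100 --seed 1
pptriad origin --fasta sim/proteins.fasta --dna-fasta sim/dna.fasta \
               --synteny sim/synteny.tsv --pairs "plant_01,plant_02" \
               --anchor-fasta sim/proteins.fasta --anchor-positions 107,109,151 \
               --out origin.jsonl
```

`tree` writes a midpoint-rooted NJ tree with bootstrap supports plus a
per-taxon monophyly report; `origin` emits JSON-lines duplication /
independent-origin verdicts with their full evidence (triad match, protein
identity, DNA-identity detectability, synteny score).

### Using real sequences

The bundled coordinate anchors are **synthetic stand-ins** (see
`pptriad/anchors_synthetic.py`) that carry the published triad coordinates
of the Sfp-type and human-type archetypes so the pipeline runs fully
offline. To anchor on real proteins, fetch them by accession (e.g. Sfp
CAA44858.1, human AASHDPPT Q9NRN7.2) and pass
`--anchor-fasta sfp.fasta --anchor-positions 107,109,151`; the library
equivalent is `TriadAnchor(id=..., record=..., positions=(107, 109, 151),
expected_residues=("D", "E", "E"))`.

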