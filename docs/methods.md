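# Methods

This note documents the models, conventions and design choices behind
`pptriad`, in the order the pipeline runs. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The triad model

Group II PPTases bind one catalytic Mg²⁺ through carboxylates at three
alignment-homologous positions, the triad Asp-Xxx-Glu. The package treats
the triad as a three-site coordinate system defined on an *anchor*
sequence with experimentally known positions (the Sfp-type archetype at
107/109/151, residues D-E-E; the human-type archetype at 129/·/181, which
lacks the second ligand). A query's triad is located by transferring the
anchor's coordinates through an optimal global alignment; the subgroup is
then read off the second residue:

- **three-Mg** — Glu at the second position;
- **two-Mg** — any other residue, including a gap (the second ligand may
  be absent entirely, as in the human enzyme);
- **unclassified** — first position not Asp, third not Glu, or either
  terminal position unmapped. These are reported with flags, never
  silently dropped or guessed.

Asp at the second position would also present a carboxylate; because the
family data motivating the rule names Glu specifically, the default
classifies second-Asp as two-Mg with a `second_is_asp` flag, and a
`carboxylate_interchange` switch treats D/E as equivalent at all three
sites. Coordinates are 1-based and inclusive throughout, matching how
point mutants (D105A, E107A, E151A, Q112E, …) are conventionally named.

### Bundled anchors are synthetic stand-ins

The two built-in anchors (`anchors_synthetic.py`) are constructed
sequences, not database proteins: a fixed internal seed generates a
224-residue Sfp-like sequence with D/E/E planted at 107/109/151, and
derives human-type (129/·/181, Met at the homologous second column),
SchPPT-type (105/107/151) and Sppt-type (Gln at 112) relatives from it by
substitutions and indels placed away from the motif. This keeps the whole
pipeline runnable and testable offline; the stand-ins carry the published
coordinates by construction, so anchoring tests verify the transfer
machinery, not database content. Users with accession-fetched sequences
build `TriadAnchor` objects from them directly.

### Anchor quality controls

`detect_triad` records the anchor–query percent identity and flags calls
below 20 % (alignment twilight zone). Coordinate transfer is exact under
self-anchoring and equivariant under terminal extensions (tested).
Near-motif alignment ambiguity — a compensating gap pair next to the
variable second site — can shift a mapped position by one or a few
columns; in practice such calls land outside the D…E frame and surface as
flagged/unclassified rather than as silent misassignments (tested on
simulated families).

## Alignment conventions

Pairwise alignment is delegated to Biopython's `PairwiseAligner`
(Needleman–Wunsch/Gotoh and Smith–Waterman with affine gaps) behind a
`ScoringScheme` that fixes the conventions:

- protein: BLOSUM62, gap open 10, gap extend 0.5; DNA: match +5,
  mismatch −4, same gap costs. A gap run of length L costs
  `open + (L−1)·extend`; terminal gaps are penalised in global mode.
- percent identity = identical columns / all alignment columns (gaps
  included); percent similarity = positively-scoring residue pairs / all
  columns, protein only. Full precision is kept internally; reports round
  to integers.
- ties between equally optimal traces follow the aligner's canonical
  enumeration order, so outputs are reproducible bit-for-bit.
- "detectable DNA identity" is operationalised as: the best local
  alignment is positive-scoring *and* covers ≥ 20 % of the shorter
  sequence — a BLAST-style hit/no-hit call. The threshold is an argument.

The multiple alignment is a center-star construction: every sequence is
globally aligned to a center (highest summed pairwise score by default),
and gaps are merged under once-a-gap-always-a-gap with insertion blocks
left-packed. This is deliberately simpler than progressive/iterative MSA;
it is fully deterministic, fast at family scale, and sufficient for
distance estimation on families whose homologous columns are largely
colinear. It will underperform curated MSAs on families with extensive
domain rearrangement — which is outside this package's scope.

The exhaustive-enumeration oracle in the test suite defines the scoring
semantics independently: all global alignments of toy sequences (length
≤ 6) are enumerated recursively and scored directly; the DP score must
match the maximum exactly, and local scores must match a brute-force
search over all substring pairs.

## Distances, trees, supports

- **Distances.** p-distance (share of differing sites) or its Poisson
  correction −ln(1−p), computed under pairwise deletion (columns gapped in
  either row are skipped for that pair). Pairwise deletion maximises
  usable signal on star-MSA output; a pair with no comparable columns (or
  p = 1 under Poisson) is an error, never an imputed value.
- **Neighbor joining** is implemented directly (Studier–Keppler Q
  criterion, lowest-index pair on ties, standard branch-length formulas,
  negative estimates clamped to zero and counted in a tree annotation).
  The implementation is cross-checked in tests against scikit-bio's NJ on
  random additive matrices and against the four-point/least-squares
  oracle on 5-leaf problems.
- **Bootstrap.** MSA columns are resampled with replacement; each internal
  edge of the point-estimate tree is annotated with the percentage of
  replicate trees containing the same bipartition. Replicates with
  degenerate distance matrices are skipped with a warning and removed
  from the denominator. A single integer seed drives all resampling.
- **Rooting and clade tests.** Midpoint rooting (via dendropy, verified
  against brute-force edge search) is the default presentation; monophyly
  queries and the HGT screen operate on the midpoint-rooted tree unless
  the caller provides a rooted tree.
- **Fitch parsimony** counts minimum unordered state changes of the
  second-residue character; at the trifurcating seed of an unrooted tree,
  child sets are folded left-to-right, equivalent to rooting along the
  first child edge (the count is rooting-invariant). Verified against
  exhaustive minimisation over all internal assignments for ≤ 6 leaves.

## Origin inference

Synteny conservation is quantified as the Jaccard index of orthogroup
label sets in a k-gene window (default 5) up- and downstream of each
locus, strand-insensitive by default with a strand-aware mode. The
underlying evidence in comparative-genomics practice is qualitative
(shared neighbors in genome-browser views); Jaccard over a fixed window
is the simplest score consistent with that reading, and the window size
is a parameter because browser-level synteny depth varies.

A locus pair is called a **duplication** only when *all* of the
following hold: identical second triad residue and subgroup; protein
identity ≥ 50 %; detectable DNA-level identity; synteny score ≥ 0.3.
Anything else is **independent origin**. The thresholds separate the
canonical positive pattern (≈ 94 % identity, conserved synteny, DNA-level
identity still detectable) from the canonical negatives (21–36 %
identity, no DNA hit, no shared neighbors) with wide margin on both
sides; both are configurable and echoed in the output. When DNA is
unavailable the DNA condition is waived and the call flagged
`protein_only`.

The **HGT screen** returns true for a focal leaf set when (i) all focal
leaves share one subgroup and (ii) the smallest clade containing them —
grown outward until it includes at least one non-focal leaf — has a
majority of non-focal leaves from the opposite taxon domain
(prokaryote/eukaryote). It is reported as a *signal*, mirroring the
tentative "may derive from" character of such inferences; it is not a
reconciliation-based transfer proof.

## The simulator and what it does (not) emulate

`pptriad.simulate` generates families with complete ground truth so every
stage can be scored without downloads. Defaults mirror a representative
56-member study set: blocks of 4 archaea, 4 cyanobacteria, 14 bacteria,
11 fungi, 3 algae, 10 plants, 10 animals; 240-residue proteins (group II
PPTases exceed 220 aa); triad at 107/109/151; second-residue states Glu
(prokaryotes), Met (animals), Ala (algae), Val (fungi, plants); expected
root-to-tip divergence 0.3 substitutions/site; one indel event per
root-to-tip lineage on average (geometric lengths, p = 0.5); one
duplication and one prokaryote→plant transfer per dataset.

Mechanics and deliberate simplifications:

- **Trees** are pure-birth (Yule): uniform lineage choice at each split
  (equal-rates-Markov topology), ultrametric, scaled so root-to-tip
  length equals `sub_rate`. Taxon blocks are simulated as separate
  subtrees joined by a pure-birth backbone (deepest 40 % of the height),
  which guarantees block monophyly; with a single block the topology is
  exactly Yule (the cherry-count test exploits this).
- **Internal-edge floor.** Pure-birth trees routinely contain internal
  edges of ~10⁻³ substitutions/site; no realistic alignment length can
  resolve them, so a topology-recovery statistic over raw Yule trees
  measures the data, not the method. `min_internal_frac` (default 0.1)
  floors internal edges at that fraction of tree height, re-extends leaf
  edges to restore ultrametricity and rescales to the target height. The
  topology distribution is untouched.
- **Sequences** evolve by per-site Poisson substitution events, uniform
  over the 19 alternative residues — not an empirical rate matrix. This
  keeps closed-form expectations for the tests; motif invariance, not
  substitution realism, is what downstream validation needs.
- **Motif constraint.** Triad positions 1 and 3 are frozen at D and E;
  position 2 is pinned to each block's state, switching on block stem
  edges (each switch is a logged, countable event). The ±2-residue guard
  band around each triad site is conserved against *both* indels and
  substitutions — the analogue of the invariant alignment columns
  flanking the real triad, and the property that makes coordinate
  transfer well-posed. Consequently true motif coordinates are always
  defined, and logged indel events reproduce every leaf's coordinate
  offsets exactly (tested by replay).
- **Duplications** append a slightly diverged copy of a leaf
  (default 0.02 subs/site, no indels) and copy its neighborhood intact.
  **HGT** replaces a recipient leaf's sequence with a diverged copy of a
  donor-lineage sequence; the recipient keeps its id and taxon, acquires
  the donor's second-residue state, and does not inherit the donor's
  neighborhood.
- **Synteny.** Conserved groups (default: the animal block, plus every
  duplication pair) share a label template with per-gene dropout (default
  0.25); all other loci draw fresh labels from a ~10⁸ space, so unrelated
  neighborhoods score ≈ 0. The dropout expectation is available in closed
  form (binomial sum over shared labels) and is verified empirically.
- **DNA** is emitted by a fixed codon table with optional synonymous
  wobble. It is intron-free CDS, so DNA-level identity is *less*
  discriminative here than in genomic comparisons that include introns;
  the duplication verdict therefore leans on the full evidence
  conjunction rather than DNA detectability alone.
- One seed drives four derived, documented RNG streams (tree, sequences,
  duplication/HGT, synteny), so datasets are bit-reproducible.

Passing tests on these families demonstrates correctness of the
machinery under motif-constrained divergence with indels — not
performance on real families with domain rearrangements, compositional
bias, or alignment-curation artifacts.

## Benchmark problem sizes

Chosen as the package's own regression conditions:

- Classification accuracy: five 56-leaf families at one indel event per
  lineage (≥ 95 % required; exact recovery required at indel rate 0).
- NJ topology recovery: 100 seeded 16-leaf families, divergence 0.3,
  indel rate 0.5, at 480 alignment columns (≥ 90 % required). A 16-leaf
  tree has 13 internal edges to recover simultaneously; at the floored
  edge lengths each edge needs a handful of expected substitutions, which
  240-column single-gene alignments cannot always supply — the 240-column
  figure is computed and reported by the acceptance script alongside the
  480-column benchmark rather than asserted.
- Duplication precision/recall: eight families with two duplications and
  one transfer each; negatives are sampled pairs whose neighborhoods the
  generator did not make co-syntenic (duplicate copies count as their
  source locus for this exclusion, since they inherit its neighborhood).
- Oracle suites run at toy sizes where enumeration is exact (alignment
  length ≤ 6, parsimony ≤ 6 leaves, topology scoring at 5 leaves).

## Numerical and degenerate-input policy

- Thresholds on the homolog filter are strict inequalities (> 35 %,
  > 70 %), matching their conventional statement.
- Negative NJ branch estimates are clamped to zero and counted, never
  hidden. Zero-length trees midpoint-root arbitrarily with a warning.
- Degenerate bootstrap replicates are skipped and the support denominator
  adjusted; they are never imputed.
- Unknown taxon strings normalise to `unknown` with a logged warning;
  conflicting duplicate assignments are errors.
- Empty FASTA input, alphabet mismatches, duplicate ids, unmapped anchor
  positions and unclassified triads in origin calls are all hard errors
  with named records.

## Known limitations

- The center-star MSA has no column-refinement step; distances inherit
  its gap placement.
- No maximum-likelihood or Bayesian inference; the NJ tree is the only
  estimator (by scope).
- The HGT screen is a composition test on one tree, not a
  species-tree/gene-tree reconciliation; incomplete lineage sorting or
  long-branch artifacts can mimic it.
- Orthogroup labels are taken as input truth; no ortholog inference is
  attempted.
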