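# Methods

## Model

The score estimates synthetic accessibility from two ingredients: a
fragment term measuring how familiar a molecule's substructures are to a
synthesis knowledge base, and a complexity penalty measuring global
structural difficulty. The knowledge base is split into what is
purchasable (building blocks) and what is formable (reaction centers of
recorded reactions), so the fragment term directly reflects the
capability of a concrete reagent catalog plus reaction corpus rather
than generic molecular popularity.

### Fragments

Fragments are unfolded Morgan (ECFP-style) circular environments
computed per atom, not folded fingerprint bits: the identifier space is
the full 32-bit invariant hash, so distinct environments essentially
never collide and counts refer to chemical environments rather than bit
positions. Hydrogens are implicit; only heavy atoms define centers.
Stereochemistry is deliberately excluded from the identifiers — it is
accounted for once, in the stereo complexity term.

Each heavy atom contributes exactly one retained fragment: its largest
realizable environment up to radius 2. For most atoms this is the full
radius-2 environment; for atoms whose whole reachable neighborhood fits
within a smaller radius (e.g. the central atom of neopentane) the
largest realizable environment fills the radius-2 slot. Environments of
radius 0 and 1 are otherwise excluded — they are so common that their
counts swamp the informative ones. Molecules with fewer than three
heavy atoms realize only radius-0/1 environments and therefore retain
no fragments; they receive a fragment term of 0 (with a warning) and
are effectively scored on complexity alone. The exclusion is applied
identically to both corpora; per-corpus configuration was considered
and rejected to keep a single fragment vocabulary.

### Building-block counts

Each block with m retained fragments contributes 1/m per fragment
occurrence, so a fragment buried in a large, specialized block counts
for less than the same fragment in a small versatile reagent. The
corpus total N_B is the *unnormalized* number of extracted occurrences;
"total number of fragments derived from the dataset" is read as an
occurrence count, and the per-molecule normalization affects only the
numerators. Normalization divides by retained (not pre-exclusion)
fragments, keeping numerator and denominator in the same vocabulary.

### Reaction-driven counts

Reactions must arrive atom-mapped (computing maps is out of scope).
Validation requires every product heavy atom to be mapped, map numbers
unique per side, and every product map present among the reactants.
The reaction center is the set of product atoms whose multiset of
(neighbor map number, bond order) pairs *or* attached-hydrogen count
differs from their mapped reactant counterpart; the hydrogen clause
catches centers such as reductions and deprotonations that a pure
bond-set diff misses. Unmapped reactant species (reagents) are ignored:
fragments are defined on the product side only.

Product atoms at shortest topological distance d from the nearest
center atom contribute their retained fragment with weight 2^−d for
d ∈ {0, 1, 2}; atoms further than two hops contribute nothing. The
weighted total accumulates into N_R, so numerator and denominator of
the log transform are weighted consistently. Identity reactions have an
empty center and contribute nothing (logged, never fatal); dirty corpus
records are skipped and counted, because real reaction sets are dirty.

### Score table

Counts ≤ 1 are excluded before scoring (with fractional and weighted
counts this also removes single-occurrence fragments). Raw scores are
natural logarithms of count / (0.001 · N); the base is immaterial
because each table is subsequently min–max rescaled onto [−3, 3]
(recorded in the file metadata for reproducibility). Min–max was chosen
over clipping because it uses the full declared range, and the two
tables are scaled independently so that each corpus's most popular
fragment anchors +3. A degenerate constant table maps to 0. A fragment
found in both tables takes the higher score; a fragment found in
neither takes the floor of −6, placing "completely unknown" well below
the worst known fragment.

### Final score

The fragment term averages the negative per-fragment scores over all n
retained fragments — n counts every fragment, not only the negative
ones, so a single odd fragment in a large familiar molecule is diluted.
The raw score (fragment term minus complexity penalty) is mapped
linearly onto [1, 10] between the anchors 0 (best) and −6 − PB (worst),
where the penalty buffer PB (default 1, exposed on the command line)
leaves room for complexity to differentiate molecules whose fragments
are all unknown. Raw scores below the worst anchor clip to 10; values
above 0 cannot occur by construction.

Per-atom attributions are the negative part of each atom's fragment
score; their sum equals n times the fragment term, and rendering atoms
darker for more-negative contributions localizes precisely which
substructures the knowledge base has never seen.

### Complexity penalty

Four non-negative terms: size (n_atoms^1.005 − n_atoms), stereo
(log₁₀ of assigned tetrahedral centers + 1 — unassigned potential
centers are not counted, so the score reflects the structure as drawn),
ring (log₁₀(bridgeheads + 1) + log₁₀(spiro atoms + 1)), and macrocycle
(log₁₀ of SSSR rings larger than 8 atoms + 1). Base-10 logarithms
follow the reference lineage of fragment-based SA scoring. Double-bond
stereo is intentionally not counted.

## Synthetic corpus generator

The generator emulates, at desk scale, the two corpora a synthesis
planner is built on: a reagent catalog of 60 small building blocks
drawn round-robin from five functional families (carboxylic acids,
alcohols, amines, alkyl/benzyl bromides, aldehydes over a shared set of
alkyl/aryl/ether R-groups), and 40 atom-mapped reactions produced by
applying four reliable transformations — esterification, amide
coupling, SN2 amination, reductive amination — to those reagents. Maps
are constructed by explicit bond surgery on the mapped reactants, so
correctness of the mapping is guaranteed by construction, and every
record is re-validated through the parser before writing. Query sets
are 20 "ES" molecules assembled from corpus reagents via the same
transformations and 20 "HS" molecules built around motifs absent from
the catalog (cage hydrocarbons, cumulenes and polyynes, dense
fluorination, spiro stacks, peroxides). All sampling flows from a
single required seed; identical parameters give byte-identical files.

What the generator does *not* emulate: the scale (millions of reactions,
hundreds of millions of blocks), the noise of automatically mapped
reaction data, route-search-derived labels, or chemistry outside four
reaction families. Passing tests therefore demonstrate the mechanics
and the analytic guarantees of the score, plus separability of
deliberately constructed easy/hard classes — not predictive accuracy on
real synthesis campaigns. In particular the near-perfect fixture AUC is
a property of the construction, not an accuracy claim.

## Numerical choices

* Unfolded identifiers: no folding, so no collision handling is needed.
* Exact equality is meaningful at the anchors: the best and worst cases
  produce exactly 1.0 and 10.0 (pure arithmetic, no rounding applied).
* The PR curve is integrated as an interpolation-free step function
  (average precision); ROC-AUC is the pairwise rank statistic with ties
  counted half. The PR sum is clamped at 1.0 against float drift.
* Score-table JSON is written with sorted keys and sorted entries,
  making table files byte-stable across runs.
* Ties and degenerate inputs: a constant raw-score table scales to 0;
  single-class evaluation inputs raise instead of returning NaN;
  molecules that retain no fragments warn and score on complexity only.

## Problem sizes

Defaults throughout — 60 building blocks, 40 reactions, 20 queries per
class — are the generator's study conditions and keep the full pipeline
(generate → index → build → score → evaluate) within seconds on one
CPU while producing a non-trivial table (tens of distinct scored
fragments per corpus).

## Known limitations

* Reaction knowledge is product-side only; stoichiometry, yields,
  conditions and protecting-group logic are invisible to the score.
* Fragment counts ≤ 1 are dropped, so a corpus of entirely unique
  fragments produces an empty (error) table — real catalogs always have
  redundancy, the toy generator is designed to.
* The per-molecule 1/m normalization makes building-block counts small;
  with tiny corpora relatively few BFrags clear the rarity threshold,
  and the reaction table carries more of the signal.
* Scores are relative to the supplied corpora: the same molecule scores
  differently against different catalogs. That is by design.
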