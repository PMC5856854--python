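# Methods

## Fingerprint definition and sign normalization

A PADIF is the N×8 matrix of per-atom score contributions exported by a
docking program for the N binding-site atoms, one column per ChemPLP term:
`ChemScore_PLP.Hbond`, `ChemScore_PLP.CHO`, `ChemScore_PLP.Metal`,
`PLP.S(hbond)`, `PLP.S(metal)`, `PLP.S(buried)`, `PLP.S(nonpolar)`,
`PLP.S(repulsive)`. Raw exports mix conventions — the three
ChemScore-derived terms report favourable interactions as positive, the
five PLP terms as negative — so fingerprint generation negates the first
three columns; afterwards a strictly negative element always means a
favourable interaction and a positive one a clash. Exact zero means "no
interaction" everywhere, and strict inequality (< 0) defines "favourable"
throughout; this three-way split (negative / zero / positive) is what the
scoring consumes.

## Atom identity and renumbering

Fingerprints from different crystal structures are only comparable row by
row if row m means the same physical atom in all of them. Serial atom
numbers differ between structures of the same protein, so identity here is
the tuple (chain, residue number, insertion code, atom name), and tables
from reference structures are renumbered onto the cavity-atom order of the
docking structure before merging. Reference atoms without a counterpart in
the docking cavity are dropped; cavity atoms that no reference atom maps
onto receive all-zero rows. Zero is the natural fill value — it encodes
"no interaction observed", contributes no weight, and never creates a
spurious favourable or repulsive element.

## Reference merging

Multiple reference fingerprints on a common atom order merge into a
consensus: per element, the median of the strictly negative values (an
even count of negatives takes the mean of the central pair), or 0 if no
reference is negative there; plus a weighting matrix holding the fraction
of references in which the element is favourable. Deliberate choices:

- The weight denominator is the full reference count, including references
  where the element is zero or positive — four favourable occurrences out
  of ten references give weight 0.4 regardless of what the other six show.
- Positive (repulsive) reference values contribute nothing, to the median
  or the weight: a clash in a reference complex carries no information
  about which interactions a binder should make.
- Mixed-sign elements take the median over the negatives only, even when
  positives are the majority.

The published score consumes only the weights and the sign pattern of the
consensus; the stored medians preserve interaction strengths for future
use (e.g. as features for learned rescoring) but do not modulate S_tot.

## Pose score

With R the number of favourable consensus elements and P the number of
favourable pose elements, each consensus element contributes +w, 0 or −w
according to whether the pose value there is negative, zero or positive;
O_max = min(P/R, 1), O_real = |P∩R|/R, O_rel = O_real/O_max, and
S_tot = ΣS − (1 − O_rel)·|ΣS|. The penalty shrinks the score toward zero
(or doubles a negative one) as the pose's favourable set strays outside
the consensus pattern, but a pose whose favourable elements are a subset
of the consensus has O_rel = 1 and keeps its raw ΣS — small ligands are
not punished for not filling the site. The score depends only on signs
and weights, never on pose magnitudes.

Degenerate cases, fixed here because the formulas leave them open:

- R = 0 (a consensus with no favourable element) makes the score
  undefined; fitting such a reference raises an error rather than
  returning a default.
- P = 0 makes O_rel formally 0/0. We set O_rel := 0, giving
  S_tot = 2·ΣS ≤ 0: an interaction-free pose ranks at the bottom, below
  any pose that matches at least something, which is consistent with the
  score's intent.

Ranking is by descending S_tot, ties broken lexicographically by pose id
for reproducibility. The combined ranking places the best ceil(0.03·K)
poses by conventional docking score first — ceiling, so "best three
percent" is never empty for small K — ordered by the conventional score
(the block is defined by that ranking), followed by the remaining poses in
S_tot order.

## Screening metrics

ROC AUC is the probability that a random active outscores a random decoy
(Mann–Whitney with mid-rank tie handling; computed via
`sklearn.metrics.roc_auc_score`, and cross-checked in the tests against an
O(n²) pairwise count). The enrichment factor at fraction x is the active
rate among the top ceil(x·K) entries divided by the overall active rate;
the ceiling matches the combined-ranking convention and keeps the top set
non-empty. Defaults report AUC, EF1% and EF3%. Both metrics depend only on
the ordering, hence are invariant under strictly monotone score
transforms.

## Synthetic data generator

The generator emulates the statistical situation of a screen with known
reference complexes, not its physics. A fixed "true pattern" of favourable
(atom, term) elements is planted; each reference realizes each true
element independently with `presence_prob`, so the expected merged weight
on a true element is exactly `presence_prob`. Actives realize each true
element with `active_overlap`; each decoy applies the same realization
probability to its own uniformly drawn same-sized pattern, which overlaps
the true pattern only by chance. All tables receive spurious repulsive
contacts with per-element probability `noise_prob`, and raw values are
emitted in the native mixed sign convention so normalization is exercised
end-to-end.

Defaults — chosen once to describe a well-behaved, data-rich target — are
20 cavity atoms, 10 references, a 12-element pattern, presence 0.7, unit
strength scale, noise 0.02, 50 actives at overlap 0.8 and 50 decoys.
Favourable magnitudes are half-normal times `strength_scale` (the score
ignores magnitudes, so this only exercises I/O and sign handling), and the
planted pattern avoids the `PLP.S(repulsive)` column, where a favourable
value would be contradictory; noise may land anywhere. All sampling runs
through `numpy.random.default_rng(seed)`, which is reproducible across
platforms.

What passing tests on this generator do **not** show: real per-atom
contributions are spatially correlated (one ligand atom touches several
protein atoms), reference sets are not independent draws from one pattern,
and real decoys are property-matched rather than pattern-randomized. The
simulations validate the algebra and the statistical behaviour of the
scoring scheme, not its enrichment on any experimental benchmark.

## Problem sizes and numerical choices

Property suites run on fingerprints of up to 5 atoms against brute-force
element-by-element oracles (1000 random instances at 1e-12 agreement);
statistical checks use 100–500 independent screens at the default sizes,
with three-standard-error bands around binomial/null expectations. The
weight-recovery check uses presence 0.4 over 500 seeds; the separation
check uses overlap 0.8 vs 0.0 over 100 and 40 seeds. File I/O is plain
TSV with a decimal point and no thousands separators; scores are written
with 10 significant digits, which round-trips the ranking exactly.

## Known limitations

- No importer for docking programs' native rescore/solution formats; the
  TSV dialect is canonical and native importers are future adapters.
- Atom mapping is exact-identity only; it does not resolve alternate
  locations, renamed atoms or gaps — those need structure superposition
  upstream.
- The consensus medians are stored but unused by the score (see above).
- Metrics beyond AUC/EF (BEDROC, RIE) and significance tests on AUC
  differences are out of scope.
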