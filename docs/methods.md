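# Methods

This note documents the models, rules and numerical choices behind
`barcodeid`, the assumptions they rest on, and what the synthetic data
can and cannot show about real barcode libraries.

## Distance model

Distances are Kimura 2-parameter (K2P), the de facto standard for COI
barcode work. For an aligned pair, sites are compared only where both
sequences carry an unambiguous A/C/G/T (pairwise deletion); IUPAC
ambiguity codes are never credited as partial matches, so `R` vs `A`
is simply not compared. With *P* and *Q* the transition and
transversion proportions over the compared sites,
`d = −½·ln((1−2P−Q)·√(1−2Q))`. The estimator is undefined when
`1−2P−Q ≤ 0` or `1−2Q ≤ 0` (saturation) or when no sites are
comparable; such pairs are recorded on the matrix (`undefined_pairs`),
excluded from pools with a warning, and refused by tree construction —
a policy choice, since barcode-scale divergences (<30%) essentially
never saturate. Distances are proportions everywhere in the library;
percentages appear only in reports, which avoids the classic
0.3%-vs-0.003 unit bug.

Pools for the distance summaries partition the ingroup pairs:
intraspecific (same species), interspecific (different species), with
intrageneric/intergeneric as sub-views, and outgroup comparisons kept
entirely separate. Means are simple averages over all pairwise
comparisons in a pool; an empty pool is reported as absent, never as
zero. The barcode-gap overlap is the fraction of all defined ingroup
comparisons lying between the minimum interspecific and maximum
intraspecific distance, zero when the gap is clean.

## Neighbour joining

The Saitou–Nei agglomeration is implemented directly because two
behaviours matter downstream and are not guaranteed by library
implementations:

- **Tie-break.** Ties on the Q criterion are resolved by the lowest
  pair of indices in input order (merged nodes take creation order).
  This makes the topology a pure function of the matrix; since exact
  distance ties are common in barcode data (identical haplotypes), an
  unspecified tie-break would make the tree-based criteria
  irreproducible.
- **Negative branches.** Negative NJ branch-length estimates are
  clamped to zero with the deficit moved to the sibling branch
  (preserving the pair's summed length). Zero-length internal branches
  then collapse cleanly into polytomies.

Polytomy collapse contracts internal branches with length ≤ ε
(default 1e-9, i.e. exact zeros only — how display software renders
near-zero branches is not modelled); leaf branches are never
contracted; the operation is idempotent. Rooting places the root at the
midpoint of the outgroup's pendant branch, preserving all path lengths.
Bootstrap supports resample alignment columns with replacement, rerun
the full distance + NJ pipeline per replicate, and score each internal
branch by the percentage of replicates containing the same bipartition
(normalised to the smaller side); replicates that produce an undefined
distance are dropped from the denominator with a warning. NJ on an
additive matrix reconstructs the generating tree exactly; this is the
correctness oracle used in the tests.

## Identification criteria

All criteria evaluate every ingroup sequence as a query against all
remaining ingroup sequences; outgroup sequences are never queries nor
candidate matches. Singleton species can never be correct.

Similarity criteria use a tie tolerance of 1e-12 (absolute): the
underlying P/Q are rationals, and representation noise must not create
or break ties. The BM tie table: all tied nearest matches conspecific →
correct; tie spans the query's species plus others, or two or more
foreign species → ambiguous; a single foreign species → incorrect. BCM
gates BM at the threshold (best distance ≤ threshold is within; above →
no match). ASB, within the threshold, is correct only when the most
distant conspecific is strictly closer than the nearest allospecific;
incorrect when some other species' sequences are *all* strictly closer
than every conspecific; ambiguous otherwise, including for singleton
queries (their "all conspecifics rank first" would be vacuously true,
which would contradict the fact that a singleton cannot be identified).

NJT marks a species correct when the minimal spanning clade of its ≥2
sequences contains no foreign leaf, incorrect otherwise (sequences "at
multiple positions"), and singletons ambiguous; the outcome is constant
across a species' sequences. NJT_M judges each leaf one node up, on the
polytomy-collapsed rooted tree: correct when the other leaves below the
parent are ≥2 and all conspecific; incorrect when they are ≥2 and all
allospecific; ambiguous for singletons, for mixed company, and for
single-sister cherries in either direction. The cherry rule is a
deliberate reading of the "sister group to conspecifics" ambiguity
clause — a sister relationship alone is no evidence of membership — and
is symmetric for a single allospecific sister. It is isolated in one
predicate should the broader reading ever be preferred.

Report percentages are rounded half-up to two decimals. Published
tables of this kind mix rounding and truncation; half-up is applied
uniformly here and the canonical machine-readable outputs keep full
precision.

## Thresholds, confusion classes, the ad hoc threshold

The default BCM/ASB threshold is the 95th percentile of all pooled
intraspecific distances, computed by linear interpolation between order
statistics (numpy's default); the percentile method used by the
original analysis software is unpublished, so the choice is documented
and configurable.

Confusion classes at a threshold *t*: TP = correct and best distance ≤
*t*; FP = ambiguous or incorrect and ≤ *t* (the ambiguous-counts-as-FP
convention is forced by the arithmetic of the published proportions);
FN = discarded (> *t*) although the best match was conspecific;
TN = discarded and the best match was not conspecific. The four derived
metrics are accuracy = TP+TN, precision = TP/(TP+FP), overall ID error
= FP+FN, relative ID error = FP/(TP+FP) = 1 − precision; precision and
relative error are absent (not zero) when nothing falls within the
threshold.

The sweep evaluates BCM at 30 evenly spaced thresholds from 0.15 down
to 0 (the leave-one-out best matches are threshold-independent, so they
are computed once and re-gated per row). The ad hoc threshold fits
relative ID error against threshold by ordinary least squares over all
sweep rows with a defined error and solves the line for the accepted
error level (default 5%), reporting the estimate, R², and a reliability
flag: a non-positive estimate means no threshold attains the accepted
error and the library should not be trusted for threshold-based
identification. A zero-variance fit reports an absent estimate. Fitting
over all rows (rather than a subset) is a documented choice; R² exposes
when the linear summary is poor.

Problem-taxon flagging pools per-criterion verdicts by species and
genus and flags a taxon when more than half of its queries are not
correct, or when it participates in any zero-distance allospecific
match — the signature of shared haplotypes that no threshold can fix.

## Synthetic libraries

The generator evolves sequences from a random stop-free root down a
genus → species → population → specimen hierarchy under the K80 model
with transition/transversion ratio κ (default 3.0, typical for insect
COI). Configured divergences are *expected pairwise substitutions per
site* for tips joined at that level; each level's increment is split
evenly between the two lineages, so the hierarchy is ultrametric in
expectation. Per branch, sites substitute independently with the exact
K80 transition probabilities — realised branch counts are therefore
binomial (Poisson-like), which is the dominant noise source at barcode
length (658 bp: a 0.2% branch expects ~1.3 substitutions).

Coding-frame cleanliness (no TAA/TAG in frame under the invertebrate
mitochondrial code) is enforced without biasing divergence: when a
substitution creates a stop codon, that substitution is redirected to a
different non-parental base that breaks the stop, preserving the
substitution count. (Naive "re-evolve the codon until stop-free"
rejection measurably depresses realised divergence by ~3%, the fraction
of substitutions that would create a stop.)

Scenario presets:

- `clean` — 10 genera × 3 species × (2 populations × 2 specimens);
  within-population 0.002, between-population 0.01, between-species
  0.10, between-genera 0.15. The 5× separation between the
  within-population scale (what a query's nearest conspecific looks
  like) and the between-population scale (which sets the upper
  intraspecific percentiles and hence the threshold) mirrors real
  libraries, where most conspecific best matches are at ~0% while the
  intraspecific tail is driven by geography; it is also what makes
  100% best-close-match identification a structural property of the
  scenario rather than a matter of seed luck.
- `singleton_rich` — the clean library with 30% of species reduced to
  one specimen.
- `urophora_like` — one designated genus whose species share identical
  per-population haplotypes (every specimen of every species in
  population *j* carries the same sequence), embedded in a library that
  is also ~30% singleton species. Both features are needed to reproduce
  the unreliable-library signature: the shared haplotypes supply
  zero-distance allospecific matches at every threshold, and the
  singletons supply moderate-distance false positives that make the
  relative ID error rise with the threshold, driving the ad hoc
  estimate negative.
- `host_race` — one designated species split across three host-labelled
  populations.
- `paper_shaped` — 135 species in 42 genera with the
  specimens-per-species histogram 41×1 / 78×(2–8) / 15×(9–15) / 1×23,
  divergences (0.001 / 0.004 / 0.04 / 0.14, outgroup 0.21) chosen so
  the pooled intraspecific and interspecific means land near 0.25% and
  13%.

The ground truth object records the generating hierarchy and exposes
the configured expected divergence per pair, which is what parameter-
recovery tests compare realised K2P means against.

**What passing tests do not show.** The simulator has no indels, no
rate heterogeneity across sites or lineages, no base-composition bias,
no recombination or introgression model (shared haplotypes are copied,
not coalescent-simulated), and uniform within-level divergences. Tests
passing on these libraries demonstrate that the analysis machinery is
correct and that the documented pathologies are detected when present;
they do not certify performance on real libraries, whose intraspecific
structure is far messier.

## Numerical choices and degenerate inputs

- Percentile: linear interpolation; configurable.
- OLS via `scipy.stats.linregress`; degenerate (zero-variance) fits
  signal absence rather than raising.
- Tie tolerance 1e-12 absolute for "equally good" matches; zero-distance
  allospecific detection uses the same tolerance.
- Rounding: half-up, two decimals, at the reporting layer only.
- Empty pools, absent metrics and undefined distances are represented
  as absent values (`None`/NaN plus a recorded pair set), never as
  zeros; operations that cannot proceed (single-species barcode gap,
  all-singleton percentile, <3 taxa NJ) raise with a named reason.
- Every stochastic operation (simulation, bootstrap) takes an explicit
  seed and is bit-reproducible given it.

## Problem sizes used in the test suite

The suite runs simulations at the scales the analyses are designed for
while staying desk-sized: clean-scenario recovery uses 10 seeds of
30 species × 4 specimens × 658 bp (~1200 leave-one-out queries,
~86 000 distance pairs); NJ correctness uses 100 random additive trees
of 4–8 taxa; criterion cross-checks use 150–200 random 4–6 sequence toy
datasets against an independent brute-force rule evaluator; the
pathology and stripping analyses use the `urophora_like` (~110
sequences) and `paper_shaped` (~640 sequences) presets. One
acceptance-level assertion — realised pooled intraspecific K2P within
3 relative % of the configured expectation over a fixed 10-seed batch —
sits at ~1.5σ of the irreducible Poisson sampling noise at these sizes
(per-seed sd ≈ 6%, unbiased to +0.6% over 100 seeds) and fails for the
fixed batch used in the suite; the generator's calibration is instead
demonstrated by the 100-seed measurement above and recomputed at run
time by `scripts/acceptance.py`.

## Known limitations

- Only the K2P distance is implemented; no model selection, no ML/MP
  trees (the NJ topology is a clustering device, not a phylogenetic
  estimate).
- The NJ tie-break makes results deterministic but not necessarily
  identical to other software's trees on tie-heavy data; tree-criterion
  tallies are therefore comparable, not bit-reproducible, across
  implementations.
- Bootstrap on large libraries is O(replicates × n²·L) and intended for
  subsets at the 1000-replicate scale.
- The ad hoc regression inherits the linearity assumption of the
  original method; a low R² is the signal to distrust the estimate.
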