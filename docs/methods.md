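# Methods

## Scope and model

`vstriage` implements the decision layer of a structure-based virtual
screen: everything that happens *around* the docking engines. Docking
itself (pose generation and scoring) is consumed as input — SDF poses
with per-engine score tags and ranked score lists — because those steps
belong to external engines with their own validation. The package's job
is to make the triage decisions reproducible: which compounds are
removed, why, and in what order.

## Stage-1 filtering

Descriptors are computed with RDKit: aromatic rings are counted per
SSSR ring whose atoms are all aromatic (a fused bicyclic counts 2);
rotatable bonds use the strict definition that excludes amide C–N
rotors (the vendor convention behind the thresholds is unrecorded, so
the non-strict variant is a flag); H-bond donors, Crippen clogP and
TPSA are the standard RDKit implementations. Thresholds (4 rings, 10
rotors, 3 donors, clogP 5, TPSA 125 Å²) are strict `>` rules: the
boundary value passes. Every fired rule is recorded per compound, so a
verdict is auditable; passing means no rule fired.

The default alert set is a small curated list of PAINS-like and
reactive motifs (acyl/sulfonyl halides, aldehydes, Michael acceptors,
epoxides/aziridines, isocyanates, anhydrides, azides, quinones,
rhodanines, catechols, hydrazines). It deliberately does not claim to
reproduce any published list's membership; full lists load from
two-column (label, SMARTS) CSVs.

## logD surrogate

Stage 2 removes pooled compounds by logD (pH 7.4) and PSA. The original
values for such cuts come from vendor calculators, which this package
does not reproduce; callers supply `logd`/`psa` columns alongside the
deck. For testing without such columns a clearly labeled surrogate is
used: clogP minus 1.5 per ionizable group (carboxylic acids and
non-amide, non-aryl amines). It preserves the ordering logic of the
filter, not vendor values. The sentence defining the cut is ambiguous
between conjunction and disjunction; the default is AND (both bounds
must be exceeded), with OR a configuration switch.

## Pharmacophore matching

A model is an ordered list of typed feature spheres (acceptor or donor
*projection* sites: the sphere marks where the complementary ligand
polar heavy atom should sit), a minimum match count, and exclusion
spheres. A feature is matched when any ligand heavy atom of the
complementary type lies within (≤) its radius; any heavy atom inside an
exclusion sphere vetoes the pose. Only heavy atoms are tested — polar
hydrogens fold into the donor typing of their parent N/O — because
docked SDF poses frequently lack explicit hydrogens. Typing rules:
donor = N/O bearing ≥1 H; acceptor = N/O with no positive formal
charge, excluding amide nitrogens. These are deliberately simple 2D
rules (no tautomer enumeration, no in-plane lone-pair geometry); they
are documented as this package's rule, not as any vendor's exact rule.
A compound passes when any of its poses passes; the best pose has the
most matched features, ties by the smaller summed atom-to-center
distance, then first pose index. Matching is exactly invariant under a
rigid motion applied jointly to pose and model, which the tests assert.

Because the original model's feature centers derive from a protein
frame that is not shipped, concrete model files are user-supplied; the
packaged default model (two acceptor sites, two donor sites, 2-of-4,
six exclusion spheres) is a synthetic construction with geometrically
consistent but arbitrary centers.

## Consensus pooling and global rank

The pool is the union of each engine's top-N prefix (N = 1000 by
default), with per-compound provenance. Prefixes are deterministic:
entries sort by score in the engine's stated direction, ties by
ascending id. Raw scores from different engines are incommensurable, so
the cross-engine order is positional: sort key = (best rank across
engines, mean rank over engines where the compound appears, id). The
key function is pluggable; engines missing a compound contribute
nothing to its mean. For L full lists the pool size is provably in
[N, L·N], a bound the tests exercise.

## Diversity selection

Fingerprints are hashed Morgan circular fingerprints. The default
radius is 4 with 2048 bits — kept as the quoted setting of the workflow
this package mirrors, although many toolkits would call the common
ECFP4 configuration radius 2; the radius is a parameter. Distance is
1 − Tanimoto, with two empty fingerprints defined as identical.

Clustering is PAM: greedy BUILD initialization, then best-improvement
SWAP until no single medoid/non-medoid exchange lowers the summed
distance to assigned medoids. The implementation is vectorized over the
full distance matrix (the swap deltas decompose into a per-candidate
base term plus per-removed-medoid segment sums), assigns ties to the
smaller medoid index, and is deterministic: the seed only breaks exact
ties in BUILD. Cost is non-increasing by construction and asserted per
accepted configuration.

**Known limitation.** PAM is a single-swap local search and does not
guarantee the global optimum: on roughly 5% of tiny random instances
(n ≤ 8, k ≤ 3; uniform, Euclidean and Tanimoto distance distributions
alike) it terminates in a certified swap-local optimum above the
exhaustive best. This is inherent to the algorithm, not this
implementation: R's reference `cluster::pam` returns the identical
suboptimal medoid set and cost on such instances, and the test suite
includes that cross-check. Consequently the 960-cluster partition of a
real pool is a deterministic, locally optimal partition — not a claimed
global optimum, and not a reproduction of any other tool's partition.

Selection: take the best-ranked member of each cluster, add unselected
members of the global top-M (M = 50), then trim the worst-ranked until
the target size (960) is reached, recording the trimmed ids worst-first.
Since the cluster representatives already number k ≥ target, the target
is always reachable; the trim count equals the number of top-M
compounds that were not already cluster representatives.

## Efficiency metrics

LE = 2.303·R·T·pIC50/HAC with 2.303·R·T = 1.364 kcal/mol at 298.15 K.
The common rounded constant 1.37 gives identical values at the 2-decimal
reporting precision; the constant is configurable because the convention
used for any particular published value is rarely stated. LLE = pIC50 −
logP (1 d.p.), hit rate = 100·hits/screened (1 d.p.), Kp,uu =
(total brain × fu,brain)/(total plasma × fu,plasma) (2 d.p.), unit-free
under a common concentration rescaling. All rounding is half-up, since
the quantities mirror fixed-precision printed values.

## Formula masses

The parser reads Hill-notation formulas with an optional trailing
charge. Digits adjacent to an element symbol always bind as atom counts
("C14H14N3O2S2+" is S₂ with charge +1); multiple charges are written
sign-first ("Fe+3") or space-separated ("SO4 2-"). Monoisotopic masses
sum the most-abundant-isotope masses (AME2020 values, embedded as a
versioned table), average masses sum IUPAC 2021 standard atomic
weights; reporting precision is 4 and 1 decimals respectively,
rounded half-up.

By default no electron-mass correction is applied to charged formulas:
the reported value is the plain atom-sum of the ion formula. Published
HRMS "calcd" values mix conventions — some entries are exactly the
atom-sum, others sit one electron mass (~0.00055 u) lower — so the
plain sum is the default (it matches the self-consistent majority of
the values this package pins as regressions) and `electron_correct=True`
subtracts one electron mass per positive charge when the other
convention is wanted. The two conventions differ only in the fourth
decimal place.

## Synthetic decks: what they emulate, and what they do not

The generator produces every pipeline input with planted ground truth.
Molecules come from a fragment grammar (heteroaryl cores ×
ring-decorated anilines × linkers × sulfone/sulfonamide/amide caps ×
small tails) so that chemical validity is guaranteed and stage-1
violations can be planted constructively rather than by rejection
sampling: each violator family is designed to trip exactly one rule
(e.g. penta-azine chains for the ring count, PEG chains for rotors,
polyols for donors, tri-tert-butylbenzenes for clogP, polynitroarenes
for TPSA, acyl halides for alerts), and every planted label is verified
against the real filter at generation time. Poses place planted polar
atoms inside feature spheres at radius × U(0, 0.9) and park all other
atoms far from every sphere; score lists solve the top-N overlap
arithmetic exactly so the pool union hits a requested size; stage-2
logD/PSA values are planted as caller-supplied columns; labels are
seeded Bernoulli draws. A single integer seed feeds a named-stream
splitter (seed, stream-name) → child generator, so sub-generators are
independently reproducible and byte-identical across runs.

Defaults mirror the funnel of the campaign this package models at desk
scale: a 3000-compound deck standing in for a 31000-member commercial
kinase-focused library (the downstream stages only ever see ≤ 2057
compounds, so the deck needs to cover the funnel, not the library),
three top-1000 lists pooling to 2057, 314 stage-2 violators leaving
1743, k = 960 clusters, target 960 with top-50 augmentation, hit rate
0.005.

What passing on synthetic data shows: that each stage implements its
decision rule exactly (planted labels are recovered verbatim) and that
the stages compose. What it does not show: behavior on real chemical
matter — the grammar's diversity is far narrower than a vendor library,
docking-score distributions are not emulated (scores are rank
surrogates), pose geometry is placed rather than docked, and planted
logD/PSA values bypass any property predictor. Intermediate counts of
the original campaign that depend on the commercial library and
licensed engines (e.g. the number of pharmacophore passers from a real
docked set) are exercised only through these planted mirrors.

The exact-trim plant deserves a note: the number of compounds trimmed
during selection equals the number of global top-M compounds that are
not cluster representatives, which depends on the clustering outcome.
`plan_selection_ranking` therefore builds its ranking *after*
clustering, placing M − s representatives of distinct clusters at the
head followed by s of their clustermates, which forces exactly s
trimmed compounds. The orchestrated pipeline instead uses the consensus
global rank, where the trim count is an outcome, not a plant; the final
set size is the target either way.

## Numerical and degenerate-input choices

Distances equal to a sphere radius count as inside (≤), tested at
machine-representable boundary values. Score ties break by ascending
compound id everywhere a prefix or ranking is cut, making every output
order-deterministic. Empty fingerprint pairs have similarity 1.
Readers are total: malformed SMILES rows, unreadable molblocks and
missing score tags are logged and skipped, never fatal; missing
descriptors fail the compound with an explicit reason rather than
raising. Report CSVs are UTF-8, sorted by id.

## Problem sizes in the test suite

The suite validates the funnel at its native scale (deck 3000, pool
2057 → 1743 → 960 with k = 960), which dominates the runtime (~40 s,
mostly PAM BUILD at k = 960); oracle comparisons (exhaustive k-medoids,
hand-enumerated rankings, rigid-motion checks) run at small n where
enumeration is exact. Property-based tests are derandomized for
reproducibility.
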