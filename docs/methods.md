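# Methods

## Scope and model

`dosecmap` implements the computational arm of a dose-stratified
connectivity-mapping screen for oligodendrogenesis-modulating compounds.
The object of study is the relationship between a *query signature* — two
disjoint gene sets describing the early→late oligodendrocyte-lineage
transition (late-lineage genes "up", early progenitor genes "down") — and a
catalogue of drug perturbation profiles, each a z-score vector over a fixed
landmark-gene universe, indexed by drug, dose, duration and replicate. All
quantitative claims the package makes are computed on synthetic data with
planted ground truth; nothing depends on external catalogues.

## Signature compilation

A differential-expression record passes iff `fdr < 0.05` and
`|log2FC| > log2(1.8)`, both strict. The fold-change cut is applied
two-sidedly: the screen needs both an up and a down half, so a
single-sided reading would be unusable. Passing genes are unioned across
datasets per direction; a gene that passes with opposite signs in
different datasets is removed from both halves. We interpret "commonly
expressed genes are removed" as exactly this cross-direction conflict rule:
it is the only reading that guarantees the Boolean up/down structure the
downstream scoring requires. Symbols are compared after uppercasing, which
makes mouse (`Mbp`) and human (`MBP`) conventions collide deliberately.

Ortholog mapping keeps only symbols with exactly one target; unmapped and
one-to-many symbols are dropped and counted in a mapping report rather
than expanded, because expansion would double-count genes in set-overlap
scores. Cross-direction collisions created by the mapping are removed from
both halves.

## Connectivity scoring

The default scorer discretises each profile into its `n_top = 50`
highest-z and lowest-z gene sets (ties broken by ascending symbol, up set
filled first, so results are deterministic) and computes the signed
Jaccard score — same-direction overlaps minus cross-direction overlaps,
halved, giving [−1, 1] with sign = direction of action. This emulates the
up/down-set scoring of L1000FWD-class query services, whose exact statistic
is not public; an unweighted KS enrichment scorer (`wks`) in the classic
CMap max-deviation form is provided as a cross-method check. The two
scorers are verified against brute-force oracles (exhaustive set
enumeration; a running-sum over all ranking positions).

Significance: `n_perm` random disjoint query pairs of the same sizes are
drawn uniformly from the universe per profile, seeded from
`(seed, profile_index)` so results are independent of iteration order.
The p-value is two-sided with add-one smoothing, so `p ∈ (0, 1]` and the
best achievable p is `1/(n_perm+1)`; a degenerate null (zero variance)
reports `p = 1, z = 0`. Profiles are ranked by `combined = z·(−log10 p)`,
which is monotone in both inputs and carries direction in its sign. For
the signed-Jaccard scorer the null is evaluated by a vectorised routine
that consumes the identical random stream and arithmetic as the generic
path (asserted equal in tests); this is purely a speed measure.

## Pooling, ranking, bipartite calls

Conditions are pooled per drug or per drug × dose band (a single boundary,
default 5 µM, separating the screen's 0.37–3.3 µM low regime from 10 µM
and above). Scores, z and combined are pooled by arithmetic mean;
p-values by Fisher's method (−2Σln p against χ² with 2k d.f.), treating
conditions as independent experiments. Pool-then-rank is the default
order; a rank-then-pool variant (restrict to top-N conditions per sign
before pooling) is exposed because the order is genuinely ambiguous in
this kind of screen. The pro table keeps the k_pro = 25 most positive
mean-combined rows, the anti table the k_anti = 15 most negative; rows of
the wrong sign never enter either table. A drug is *bipartite* iff one of
its dose bands is in the pro table and the other in the anti table; the
orientation (which band is pro) is recorded.

## Target genes and enrichment

Per condition, up-targets are genes with `z ≥ +2` and down-targets
`z ≤ −2` (the threshold for the "positive/negative ranges" is not
standardised anywhere; 2.0 ≈ two-sided 5% under a standard-normal null and
is exposed as a flag), optionally restricted to the query signature.
Conditions within a band are merged by per-direction union with the same
cross-direction conflict rule as the signature. Note the conflict rule
makes merging only commutative, not strictly associative, when a conflict
gene recurs after an inner merge; the pipeline always merges flat lists.

ORA uses the hypergeometric upper tail (survival function, evaluated in
log space by scipy) against a background universe that defaults to the
landmark universe — the measurement frame of the profiles — rather than
the union of library genes. BH step-up q-values are computed over the
terms with non-zero overlap (the tested family); including zero-overlap
terms is available via the library since they carry p = 1. The combined
score is `(−ln p) · zrank` with `zrank` the deviation of the term's
observed rank from its mean rank under 200 seeded random queries of the
same size, a rank-based correction in the spirit of the Enrichr webtool
(whose exact constants are unpublished; this is a declared emulation, not
a replica). Signed output is `+|combined|` for up-target runs and
`−|combined|` for down-target runs, so up- and down-derived pathways plot
strictly on opposite sides of zero.

## Similarity map

Distances between drug × band target sets are Jaccard distances over
*signed* elements — (gene, direction) pairs — so two conditions moving the
same genes in opposite directions are maximally distant. A plain-union
variant is available (`signed=False`), but it is direction-blind: a
dose-flip compound moves largely the same signature genes at both doses,
so only the signed form can reproduce the separation between its low- and
high-dose target sets, which is the property of interest. Embedding is
classical (Torgerson) metric MDS on the double-centred squared distances,
with axis signs fixed by convention — deterministic and seed-free, unlike
t-SNE, and adequate at the few-dozen-point scale of a top table.

## Synthetic study generator

The generator emulates the structure of the screened resource at desk
scale, and its defaults are the study conditions used by the tests and the
acceptance script:

- 978 landmark genes (L1000 scale); background z ~ iid Normal(0, 1) per
  gene per profile. Moderated z-scores of a null perturbation are
  approximately standard normal, which is all the scoring consumes.
- planted signature of 50 up + 50 down genes; DE tables (3 datasets) carry
  it with |log2FC| = log2(1.8) + LogNormal(−0.5, 0.5) and FDR in
  [1e-6, 0.04]; 200 noise genes fail at least one filter; 5 conflict genes
  alternate sign across datasets and must be removed by compilation.
- ortholog map: 90% one-to-one coverage, 5% one-to-two (dropped on
  conversion), the remainder unmapped — realistic losses for cross-species
  symbol translation.
- planted compounds in triplicate: a pro compound (+2 z-units on
  signature-up genes, −2 on signature-down, at 0.37, 3.3 and 10 µM), an
  anti compound (mirror image), and a dose-flip compound (pro at 0.37 and
  3.3 µM, anti at 10 µM), mirroring a low-{0.37, 3.3} µM / high-10 µM
  design with the band boundary at 5 µM.
- 300 null compounds, each in triplicate at two doses within a single
  band (alternating low {0.37, 3.3} µM and high {10, 20} µM across
  drugs). Screening libraries typically profile most compounds in one
  concentration regime; only the planted compounds span both. This also
  makes the bipartite call specific by construction: with hundreds of
  band-spanning null drugs, order statistics alone would place some null
  drug's two bands into the pro top-25 and anti top-15 with appreciable
  probability, and a screen of this design would not attribute bipartite
  behaviour to compounds never tested in both regimes.
- gene-set library: 100 random terms of 10–50 genes plus one planted term
  of 20 signature-up genes.

Every generator is a pure function of (config, seed); regenerated outputs
are byte-identical.

What the generator does *not* emulate — and therefore what passing tests
do not demonstrate about real catalogues: correlated gene-gene noise,
plate and batch effects, cell-line heterogeneity, dose–response curves
between the two bands, compound polypharmacology, and realistic
ortholog ambiguity structure. Recovery rates on this generator measure
internal correctness of the pipeline, not expected sensitivity on LINCS
data.

## Numerical choices and degenerate inputs

- Strict inequalities at both signature thresholds; boundary records are
  excluded.
- Score ties in the permutation null are counted in favour of the null
  (`|s_null| ≥ |s_obs|`), making p conservative under discreteness; on
  pure-noise profiles the observed type-I error at α = 0.05 is therefore
  at or slightly below nominal.
- `n_perm ≥ 99` is enforced as a p-value resolution floor.
- Empty-vs-empty set comparisons: Jaccard of two empty sets is 0 in
  scoring (no evidence) but distance 1 in the similarity map (nothing
  shared), each logged.
- An all-conflict signature, an empty post-mapping signature, and a query
  with either half absent from the universe are hard errors, not silent
  empties.
- MDS with fewer than two positive eigenvalues pads the missing axes with
  zeros and warns.

## Problem sizes

Default test and acceptance runs use the generator defaults above
(1,827 profiles × 978 genes per replicate, n_perm = 199, 20 replicates
for rate estimates), which keeps the full suite in the minutes range on a
single CPU while leaving every planted effect at the stated size.

## Known limitations

- The signed-Jaccard/permutation machinery emulates the class of resource
  scoring it stands in for; it is not a re-implementation of any specific
  service's statistic, and ranks from real services will differ.
- Fisher pooling assumes independence of conditions; replicates of the
  same condition are positively dependent, so pooled p-values for a drug
  are optimistic. They are used for ranking, not inference.
- The Enrichr-style rank correction uses 200 null queries; the zrank
  estimate carries Monte-Carlo noise of order 1/√200 that is immaterial
  for ranking but visible in the third significant digit.
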