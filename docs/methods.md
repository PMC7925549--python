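# Methods

## The Global Tree Difference

Two brains' count maps over the same rooted ontology are compared region by
region. For a region *r* with children *c₁ < c₂ < … < c_k* (sorted by id),
each brain contributes a composition vector of the children's cumulative
counts. Cells assigned to *r* directly (to the parent, not to any child)
are appended as one extra component whenever **either** brain of the pair
has any, so both vectors always share a dimension and every cell in the
comparison is conserved. Writing *f(r)* for the region's cumulative count
over the brain total,

- *M_r* = (f_a(r) + f_b(r)) / 2 — how much input the region carries, on
  average, in the pair;
- *D_r* = 1 − cos(**u**, **v**) — how differently that input is
  apportioned among the subregions;
- GTD = Σ M_r·D_r / Σ M_r over included regions.

A region is excluded from both sums when its composition vector has fewer
than two components (leaves; single-child regions without direct cells) or
when either brain's vector is all-zero: the cosine is undefined there, and
the presence/absence difference is already expressed one level up in the
parent's composition. This exclusion rule is what makes GTD = 1 exactly
attainable for maps with disjoint support.

**Cosine difference.** D is the bounded complement of cosine similarity,
the standard choice for non-negative compositional vectors (similarity 1
for identical direction, 0 for orthogonal). The similarity is evaluated as
√((u·v)² / (|u|²|v|²)) with an identical-vector shortcut. On integer count
vectors this form is invariant, bit for bit, under integer scaling of
either brain, so two analytic identities hold exactly in floating point
rather than approximately: GTD(a, a) = 0, and GTD is unchanged when every
count of one brain is multiplied by a positive integer. Cosine values are
clipped into [0, 1] against rounding overshoot.

**Pair sets.** The within-group set pools all same-group pairs across
*every* group — it estimates the GTD floor set by inter-animal
variability — while each between-group set contains all cross pairs of one
named comparison. Sets are summarized by median and IQR (Q3 − Q1, linear
interpolation; the quantile convention is fixed for reproducibility) and
compared with a two-sided Wilcoxon rank-sum test.

**Ablation.** `prune_region` removes a region and its whole subtree;
re-loading counts against the pruned tree drops rows in the removed
subtree with a logged warning. Off-path regions keep their D values
exactly; only the pruned region's ancestors (whose composition vectors
contained it) and the global fractions change.

## Rank tests

Whenever the two samples together hold ≤ 12 values, Mann–Whitney p-values
are computed by exhaustive enumeration of all C(n₁+n₂, n₁) group
assignments, with ties counted one half and never broken — so identical
samples give p = 1 exactly, complete separation of 3 vs 3 gives the exact
2/20 = 0.1 two-sided, and 2 vs 4 gives 1/15 one-tailed. Larger samples use
the tie-corrected normal approximation (scipy). Samples with no ordering
information at all (every value identical) return p = 1 by convention.

## Simplification and the gated tests

Retention criteria (per comparison pair, a child kept iff it passes in at
least one of the two groups): mean cumulative count ≥ `min_mean` (default
5) across the group's brains, and cumulative count ≥ `min_presence_count`
(default 1) in strictly more than `presence_fraction` (default 0.5) of
them — 3/5 brains passes, 2/4 does not. Criteria evaluate cumulative
counts: a region "has" the cells of its descendants; direct-only counting
would empty most internal regions. Children with zero cells in every brain
of both groups pooled are excluded up front and labelled `no-neurons`.
Non-retained children's cells plus the parent's direct cells form the
per-brain NOS count, so retained + NOS equals the parent's cumulative
count exactly (an integer identity asserted in tests).

The gate compares within- vs between-group cosine distances of the
per-brain composition vectors (retained children + NOS, normalized by the
region's cumulative count) with a one-tailed Mann–Whitney test in the
direction "between-group distances greater". Only the gate's significance
(p < `gate_alpha`, default 0.05) licenses the per-child t-tests; this is
the procedure's multiplicity control, by design — a single gate per region
replaces a correction over all its children. A Benjamini–Hochberg option
(`p_adjust="bh"`) exists for users who want adjusted child p-values as
well, but it is off by default: the gate *is* the intended control.
Traversal is breadth-first with id-sorted children and always descends,
whether or not a gate fires; the gate gates tests, not descent, since a
parent-level similarity does not preclude a localized child-level
difference.

Child t-tests compare parent-relative fractions (child cumulative / parent
cumulative), which decorrelates the hierarchy levels: permuting counts
among one region's children alters no other region's test inputs. The
default is Student's pooled-variance unpaired t-test, two-sided; Welch is
available via `equal_var=False`. Shapiro–Wilk p-values per group are
reported beside each test (NaN below n = 3 or for constant input) but
never switch the test — normality is reported, not enforced. Brains with
zero cells in a region are dropped from that region's vectors and
fractions with a warning rather than imputed; a region leaving fewer than
two brains in either group is reported untestable.

## Synthetic studies

The generator is the minimal compositional-count model with a dispersion
knob: a group's latent profile is a point on the leaf simplex; each brain
draws composition ~ Dirichlet(κ · profile), a total N log-uniform in
`total_range`, and leaf counts ~ Multinomial(N, composition). Direct
assignment is then applied top-down: each internal region claims
Binomial(n_under, `direct_fraction`) of the cells currently beneath it,
removed from its leaves by a multivariate hypergeometric draw, so N is
conserved as an integer identity. Effects are injected by multiplying a
subtree's leaf probabilities by a fold factor and renormalizing (a region
at mass m moves to fold·m / (1 + (fold−1)·m)).

Defaults, chosen once as the study conditions: five groups gadOn/parv/
gadOff/penk/ntsr1 of 5/5/3/3/4 brains; totals log-uniform in 420–16,944
(the reported per-line ranges span ~40-fold, so uniform-on-log); κ = 300,
giving ~10–20% CV on mid-sized fractions and a within-group GTD floor near
0.01; profiles drawn from symmetric Dirichlet(0.5) and then concentrated
20-fold onto one root-level subtree, emulating maps dominated by a
visual-cortex-like focus with long tails elsewhere; `direct_fraction` =
0.05. Each group draws its own profile by default; `shared_profile=True`
gives null (no-difference) datasets. The generator emulates compositional
structure, dispersion, and sparsity — not spatial positions, viral-spread
or starter-cell biology, hemispheres, or the real Allen ontology's shape —
so passing recovery tests demonstrate the statistical machinery, not
anatomical fidelity.

## Calibration and recovery bench

`experiments.py` fixes a reference scenario for characterising the
procedure: two groups of 5 brains, exactly 5,000 cells each, a complete
depth-2 branching-3 ontology, κ = 300, and — unlike the full-study
defaults — balanced profiles (symmetric Dirichlet(2), no focal
concentration) so each root-level subtree carries comparable,
non-negligible (~1/3) mass. This matters: under focally concentrated
profiles a fold-2 shift of a minor subtree moves so little mass that
neither the GTD nor the gate can see it (which mirrors how, in real data,
grossly similar maps can coexist with localized differences), and the
bench would then measure profile geometry rather than the procedure.
Measured on this bench: the null gate type-I rate sits near the nominal
0.05 (band 0.02–0.09 over 1,000 simulated pairs), a fold-2 effect on one
subtree is localized (parent gate + affected-child t-test, both p < 0.05)
in ≥ 80% of 200 runs, detection is monotone in fold, and between-group GTD
stochastically dominates within-group in ≥ 90% of 100 replicates.

## Numerical and interface choices

- Children are ordered by ascending region id everywhere; cosine values
  are order-invariant but audit ledgers must be reproducible.
- Counts CSVs carry direct counts only; cumulative counts are always
  derived by post-order traversal (single source of truth). Unlisted
  regions are zero, not missing. Duplicate (brain, region) rows sum.
- Input counts are assumed already restricted to a single hemisphere
  upstream; the loader does not split hemispheres.
- SEM = sample SD (n − 1 denominator) / √n; undefined (NaN) for n = 1.
- Percent-scale fractions are tested untransformed (no arcsine).
- Degenerate inputs: a chain ontology (no region with ≥ 2 composition
  components) raises a named error from the GTD; an empty brain is
  rejected at load; pruning the root is forbidden.

## Problem sizes

The test suite and the acceptance script run the property sweeps at 1,000
random fixtures (≤ 20 regions, counts ≤ 50), the oracle cross-check at 100
instances, and the bench at 1,000 null pairs / 200 effect runs / 100 GTD
replicates; the full sweep completes in well under a minute on one core.

## Known limitations

- The synthetic ontology is a complete tree; real atlas ontologies are
  ragged, with single-child chains that the GTD's exclusion rule simply
  skips. Behaviour on such chains is tested but not calibrated.
- The gate's distance sets are pairwise and therefore internally
  dependent; the Mann–Whitney null is an approximation whose actual
  type-I rate is verified empirically on the bench rather than derived.
- No multiplicity control beyond the gate; interpret child-level p-values
  within gated regions only.
- Group profiles and effects act on leaves; an effect confined to a
  parent's direct-assigned cells cannot currently be injected.
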