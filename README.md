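# braingtd

Statistical comparison of brain-wide, region-assigned cell-count maps across
hierarchical anatomical ontologies.

Brain-wide tracing experiments — for example monosynaptic rabies tracing of
presynaptic inputs onto a targeted cell population — end in a table of
labelled-cell counts per region of a hierarchical atlas ontology such as the
Allen CCFv3 structure graph. Comparing two such maps is awkward: regions are
nested, counts are compositional, totals vary ~40-fold between animals, and
testing every region invites false positives. `braingtd` implements a
three-part analysis for exactly this situation:

1. **Global Tree Difference (GTD)** — a single, [0, 1]-bounded pairwise
   dissimilarity between two maps that uses the entire hierarchy. For each
   region *r*, let **u**, **v** be the two brains' *subregion composition
   vectors* (cumulative counts of the id-sorted children, plus the region's
   own directly-assigned cells as an extra component when either brain has
   any), and let *f(r)* be the region's cumulative count as a fraction of
   the brain total. With the mean fraction *M_r = (f_a(r) + f_b(r))/2* and
   cosine difference *D_r = 1 − cos(**u**, **v**)*,

   ```
   GTD(a, b) = Σ_r M_r · D_r / Σ_r M_r
   ```

   summed over regions with ≥ 2 composition components and non-zero vectors
   in both brains. GTD(a, a) = 0 exactly; GTD = 1 requires orthogonal
   composition wherever mass sits, so values cluster near 0 unless
   differences are gross. Within-group and between-group pair sets are
   summarized by median/IQR and compared with the Wilcoxon rank-sum test.

2. **Ontology simplification with NOS amalgamation** — per comparison pair
   of groups, a child region is retained only if, in at least one group, it
   averages ≥ 5 cells across the group's brains *and* holds ≥ 1 cell in a
   strict majority of them. Cells in non-retained children, plus cells
   assigned directly to the parent, form a per-brain "not otherwise
   specified" (NOS) pseudo-subregion, so every cell is conserved.

3. **Gated hierarchical testing** — at each region with ≥ 2 retained
   children, each brain's composition over retained children + NOS is a
   vector on the simplex; cosine distances for all within-group and
   between-group brain pairs are compared by a one-tailed Mann–Whitney test
   (exact enumeration at small n). Only where this gate fires (p < 0.05)
   are the retained children tested individually with unpaired t-tests on
   *parent-relative* fractions (child cumulative / parent cumulative, which
   decorrelates hierarchy levels), with Shapiro–Wilk normality p-values
   reported alongside. NOS is never t-tested.

A Dirichlet-multinomial synthetic-study generator reproduces the layout and
statistical structure of a five-line rabies-tracing study (groups gadOn,
parv, gadOff, penk, ntsr1 of 5/5/3/3/4 brains; totals spanning 420–16,944
cells), so the whole pipeline is testable end-to-end with known ground
truth.

## Worked example

Simulate a study, compare two group pairs by GTD, then localize the
differences with the gated tests:

```bash
braingtd simulate --seed 7 --out study
braingtd gtd  --ontology study/ontology.json --counts study/counts.csv \
              --groups study/groups.csv --pair gadOff gadOn --pair gadOff ntsr1 \
              --out results
braingtd test --ontology study/ontology.json --counts study/counts.csv \
              --groups study/groups.csv --pair gadOff ntsr1 --out results
```

prints (abridged):

```
 group  n_brains   min   max      range        mean         sem
gadOff         3  1352  3067  1352-3067 2152.666667  498.329320
 gadOn         5  1602 12779 1602-12779 6322.200000 2559.167822
 ...
gadOff_vs_gadOn: within median 0.0114 (IQR 0.0051, n=32), between median
    0.1960 (IQR 0.0157, n=15), rank-sum p = 4.608e-08
gadOff_vs_ntsr1: within median 0.0114 (IQR 0.0051, n=32), between median
    0.0764 (IQR 0.0101, n=12), rank-sum p = 4.501e-07
gadOff_vs_ntsr1: 8 gated regions, 24 child tests, 17 significant
```

The within-group medians (~0.01) are the GTD floor set by inter-animal
variability; this synthetic study draws a different latent input profile
per line, so both between-group pair sets sit well above the floor and the
rank-sum test rejects. The `test` subcommand then reports, per gated
region, which subregions differ and by how much (mean ± SEM of
parent-relative fractions per line, t, p), in
`results/child_tests_gadOff_vs_ntsr1.csv`. Regions can be ablated from the
ontology with `--prune ACRONYM` to ask how much of a difference one subtree
carries. `braingtd run --config run.yaml` executes everything and writes a
manifest with input hashes for provenance.

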