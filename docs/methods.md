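# Methods

## The model

The pipeline treats disease-mapping prioritisation as a two-axis,
single-projection multi-criteria decision. Diseases are first partitioned
into *mapping clusters* — equivalence classes of the triple (agent type,
phylum subgroup, transmission mode), matched case-insensitively after
trimming. Clustering is purely attribute-driven: taxonomy and transmission
are inputs, never inferred from names. An empty subgroup is a legal key
component, because only the larger agent groups are split by phylum.

Each cluster is then summarised by two numbers:

* **Total burden** `D` — the sum of member DALY allocations over *all*
  members, including the data-poor Option 2/3 diseases, so that a cluster
  of many minor diseases still registers its collective weight.
* **Mean policy score** `P` — the arithmetic mean of per-disease policy
  scores over Option 4/5 members *only*. Averaging over the whole cluster
  would let low-scoring occurrence-mapping members mask the diseases the
  exercise exists to surface. A cluster with no Option 4/5 member gets
  `P = 0` and is flagged (`policy_defined = False`) rather than rejected.

Ranking projects each cluster onto the axis from the origin to a
*hypothetical ideal cluster* sitting at the observed maxima of both axes:

```
x = P / P_max          (linear policy axis)
y = log10(D) / log10(D_max)   (logarithmic burden axis)
score = (x + y) / sqrt(2)
```

Distance from the ideal and projection toward it along this axis order
clusters identically; the projection form is implemented because it is
defined at the origin. How the log burden axis and the linear policy axis
are made commensurable is a genuinely open design point; normalising each
by its observed maximum and projecting onto the diagonal is the package's
choice, adopted because applied to the fifteen printed cluster values it
reproduces the published order through position 11, whereas a linear burden
axis demonstrably reorders the published list earlier. Positions 12–15 of
the published table do not follow from the printed pairs under either
transform; the transform is therefore exposed as configuration
(`daly_transform: log10 | linear`) and only the leading positions are
asserted. Ties are broken by higher total DALYs (the less noisy axis) and
then label, making output order deterministic.

## Burden allocation

GBD-style cause categories map onto the registry three ways:

* `direct:<category>` — the category's DALY value belongs to one disease;
* `member_of:<category>` — an aggregated (ICD-10 style) category's value is
  split across its member diseases. The split is **equal per member**: the
  linkage says which diseases share a category but never with what weights,
  so the parameter-free choice is declared and an optional per-member
  weight vector is accepted for future use;
* `none` — unreconcilable diseases receive a nominal value
  (`nominal_daly`, default 100), small enough not to skew totals. A
  category that *reports* 0 DALYs keeps 0 with source `direct`: a measured
  zero is not the same as "could not be reconciled".

Allocation is total and exclusive: every registry disease gets exactly one
allocation, a disease claimed by two categories is an error naming both,
and the sum of allocations equals the sum of category values plus
`nominal × n_unlinked` to 1e-9 relative tolerance.

## Policy score

`P = S + N + H` per disease. `S` counts *distinct* stakeholders naming the
disease directly or via its cluster label (a disease named both ways by one
stakeholder scores one point); unresolvable portfolio names raise an error
rather than silently scoring 0, because silent misses would bias scores
downward invisibly. `N` defaults to the binary "notifiable anywhere"
reading; a `per_country` mode (one point per listing country) is provided
because the regional sampling design could support either. `H` bands the
h-index with both boundaries closed — h ≤ 50 → 1, 50 < h ≤ 100 → 1.5,
h > 100 → 2 — making the bands exhaustive. The h-index is computed from
supplied per-publication citation counts (largest h with at least h counts
≥ h) or taken precomputed; no live bibliometric querying.

The accumulation curve averages the running unique-disease count over
random stakeholder orderings (cluster names expanded before counting).
Monte-Carlo with a mandatory seed is the default (exactness is unneeded for
a plateau diagnostic; reproducibility is); exhaustive enumeration is
available for small surveys and is used as the test oracle. The terminal
value is pinned to the exact union size in both modes.

## Synthetic data

The generator emulates the study's input shape, not its content: disease
names are synthetic and no licensed listing is reproduced.

`study_scenario()` is deterministic and plants the published structural
marginals: 176 diseases in 33 clusters (7 singletons, largest 26); burden
links partitioned 34 direct / 131 aggregated / 11 nominal — the published
reconciliation counts sum to 177, one more than the registry size, so the
aggregated count absorbs the difference; the printed DALY totals and the
nearest representable policy sums for the 15 leading clusters (per-disease
scores live on a 0.5 grid, so a printed mean of 11.8 over three diseases is
realised as 35.5/3 = 11.83); 42 of 176 diseases (24%) named by at least one
of 20 stakeholders and 97 (55%) notifiable among 7 sampled countries. The
18 unprinted clusters carry small burdens (grand total ≈ 230.5M DALYs,
mirroring the published "over 230 million" with a top-10 share just above
92%) and policy means ≤ 4, keeping them below the leading clusters on the
projection axis.

`generate_scenario(plan, seed)` randomises everything under a
`SyntheticScenario` plan (default: the study-shaped cluster plan, 20
stakeholders with geometric-rank disease popularity so the accumulation
curve plateaus early, h-indices spread 64/19/17% over the three bands,
55% notifiable). Ground truth — census, allocations, scores, ranking — is
computed by construction inside the generator and written to a separate
file, so pipeline inputs can never contain it. What passing
parameter-recovery tests show is that the pipeline inverts its own
generative conventions exactly; they cannot show robustness to the
messiness of real registries (misspelled names, inconsistent taxonomy,
overlapping categories), which the validators are designed to reject
loudly rather than absorb.

`published_ranking_fixture()` carries the fifteen printed (total DALYs, mean policy,
n = priority/total) rows verbatim for direct testing of the ranking stage
against the published order.

## Numerical and formatting choices

* Policy totals are stored unrounded and displayed to 1 decimal; DALY
  totals are written as integers when integral, so integer inputs
  round-trip bit-exactly.
* `log10` requires positive totals and a maximum above 1; violations raise
  an error suggesting a floor or the linear transform. With the standard
  nominal value of 100 per unreconciled disease, totals are always ≥ 100.
* Cumulative shares pin their terminal value to exactly 100% against float
  drift; an all-zero burden vector is an error (shares undefined).
* Tables are comma-separated UTF-8 with a header; list-valued cells use
  ";" internally. Validation is total — every malformed row produces an
  error naming the table, row and field.
* The run manifest records config, input SHA-256 hashes and the package
  version but no timestamps, so identical runs are byte-identical.

## Problem sizes

Tests and the acceptance script run the full 176-disease / 33-cluster
bundle end-to-end, 20 random parameter-recovery scenarios, 100
planted-order ranking instances, 1000-case property sweeps for allocation
conservation, h-index and ranking invariants, exhaustive accumulation
orderings for up to 5 stakeholders and 999 Monte-Carlo permutations for
20 — the survey size actually used. The whole suite completes in a few
seconds.

## Known limitations

* Equal-split disaggregation is an assumption; if the original linkage used
  population- or evidence-weighted splits, per-disease allocations (not the
  category sums) would differ.
* Positions 12–15 of the published ranking are not reproducible from the
  printed values under any transform exposed here.
* Stakeholder weighting (state vs NGO vs private) and any hierarchy within
  a portfolio are deliberately out of scope: interest is binary.
* No geospatial modelling, no GBD re-estimation, no uncertainty intervals
  on burden or scores.
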