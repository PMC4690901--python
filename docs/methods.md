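# Methods

## Data model

The unit of evidence is a purchase report: store *s* acquires item *x* from
supplier *u*. Items are classified against a promoted-food catalog
(healthy, in three sub-classes: lower-calorie beverages, healthier
essentials, healthier snacks; or unhealthy) after canonicalization (trim,
collapse internal whitespace, lowercase), since survey free text varies.
Items not in the catalog are classified `unknown`: they contribute to
neither network and are surfaced in a report table rather than raised as
errors, because only catalogued foods have a defined class.

An edge (s, u) enters the healthy supplier network (HSN) iff at least one
healthy-classified purchase witnesses it, and the unhealthy supplier
network (UHSN) iff at least one unhealthy-classified purchase does; the two
memberships are independent. Purchase frequency is deliberately ignored for
edge existence — all downstream measures are on binary ties.

Store nodes always comprise the full store sample (isolates included);
supplier nodes are exactly the suppliers with ≥ 1 edge in that mode.

## Roster counting conventions

The packaged supplier roster uses two counting conventions, and both are
reported because the published tallies mix them: *entries* expands a
multiplicity annotation ("Name (2)" counts as two outlets), *distinct*
collapses by name. On the fixture, the healthy roster has 15 entries and 14
distinct identities, the unhealthy roster 41 distinct identities, and the
union 42 distinct suppliers over 7 categories (11/10/4/5/9/2/1). Per-category
published totals follow the distinct-name convention over the union of both
rosters; this was verified identity-by-identity before the counts were frozen
into tests. The store–supplier edge list behind those rosters was never
published, so the fixture witnesses membership through one pooled
pseudo-store; roster counts are exact on it, store-level statistics are not
meaningful there.

## Network measures

- **Degree centrality.** Raw degree per store, and 100 × degree / |suppliers
  in the same network|. The denominator is mode-specific (HSN and UHSN have
  different supplier counts). Zero realized suppliers ⇒ the normalized column
  is NaN and the table is flagged rather than erroring, so degenerate modes
  still report raw degrees.
- **Core.** "Possible connections" is read as the realized edge set:
  suppliers are ranked by degree descending with ties broken by id ascending
  (reproducibility), and the core is the shortest prefix whose summed degrees
  reach the threshold (default 0.80) times the edge count. Because each edge
  is incident to exactly one supplier, the prefix degree sum equals the
  number of edges covered; the rule is therefore exactly minimal among
  degree-ranked prefixes, and enumeration shows no smaller set of any
  composition can cover the threshold. A block-model core/periphery fit is
  deliberately not implemented.
- **Projection and density.** Two stores are adjacent iff they share ≥ 1
  supplier (weight = shared count, via the weighted bipartite projection).
  Density dichotomizes weights and keeps isolates in the denominator, so a
  network can simultaneously report isolates and a sub-100% density.

## Comparison statistics

- **Centrality t-test.** Default is *paired* across stores, since the same
  24 stores appear in both networks; pooled and Welch variants are
  available by flag. Zero-variance differences are split: all-zero
  differences return t = 0, p = 1 (exact null identity); constant nonzero
  differences return a degenerate-flagged result with no statistic, since
  the paired t is undefined there.
- **Bootstrap density test.** t = (d_A − d_B)/√(SE_A² + SE_B²) with each SE
  from B = 5000 bootstrap resamples and a t reference on n_A + n_B − 2
  degrees of freedom. The default resampling unit is the *dyad* (the
  n(n−1)/2 tie indicators). Node resampling — the scheme of the classic
  network-bootstrap literature — is provided as an option, but measurement on
  Erdős–Rényi graphs shows it inflates the SE roughly twofold when dyads are
  independent (empirical size ≈ 0 at nominal 5%), whereas the dyad scheme is
  close to nominal (empirical size 0.03–0.07 across densities). Since the
  generator draws ties independently, the calibrated scheme is the default.
  The test's degrees of freedom and the normal-like reference are an
  approximation; with both graphs complete or both empty the SE is zero and
  the result is flagged.
- **Bivariate OLS.** One covariate at a time against degree centrality;
  default outcome scale is raw degree, so slopes read as "connections per
  unit of covariate" (normalized percentage available by flag). Ethnicity is
  coded 1 = Asian/Hispanic with African American as the reference; binary
  slopes equal group-mean differences exactly. Perfect fits are flagged
  degenerate with a collapsed CI; zero-variance covariates raise a
  degenerate-design error (the full-report driver records such rows with a
  note instead of aborting). No multiple-testing correction is applied by
  default, mirroring the bivariate design; a Benjamini–Hochberg column is
  available by flag. Multivariate adjustment is out of scope at n = 24.

## Distances

Great-circle (haversine) kilometres on the IUGG mean Earth radius
(6371.0088 km), validated against an independent ellipsoidal geodesic
computation (agreement within 0.02% at city scale). Suppliers with several
distribution sites contribute their nearest site per store — the assumption
being that storeowners self-supply from the closest outlet. Per-store mean
distance is over the store's *connected* suppliers in the network under
analysis (its role as a regression covariate); road distance and travel time
are out of scope.

## Synthetic generator

The generator emulates the study conditions: 24 stores; 42 suppliers split
11/10/4/5/9/2/1 across the seven categories; store covariates drawn to match
the published sample summary (WIC 45.8%, SNAP 91.7%, Asian/Hispanic owners
79%, tenure 9.5 ± 7.7 and 15.6 ± 9.1 years — truncated at zero and ordered,
customers 165 ± 145, employees Poisson with means 0.75 and 1.96); store and
site coordinates uniform in a Baltimore-scale bounding box; 1–3 sites per
supplier; 40% of suppliers deliver.

Menus mirror the roster's structure: wholesale clubs, supermarkets and
discount stores carry both healthy and unhealthy items, snack suppliers
carry a healthier line 20% of the time, and beverage/specialty/meat vendors
are unhealthy-only. Every supplier can witness an unhealthy tie.

Ties are Bernoulli-independent given covariates (no dyadic dependence — this
keeps every oracle tractable and matches the absence of any asserted
dependence structure). Unhealthy ties use a flat p = 0.215, tuned so the
mean UHSN normalized centrality sits near 21.5%. Healthy ties toward the H
healthy-menu suppliers use

    p_i = p_base + (ethnicity_effect·1[AH] + snap_effect·1[SNAP] + wic_effect·1[WIC]) / H

with p_base = 0.117 (the reference-group normalized-centrality target), so
each effect shifts the store's *expected healthy raw degree* by the
configured number of connections (defaults −1.5 for Asian/Hispanic owners,
−1.9 for SNAP acceptance, 0 for WIC). Probabilities are clamped to [0, 1]
with a warning: under the default configuration the two negative effects
stack beyond the feasible range for most stores, so the default healthy
network is extremely sparse — a deliberate consequence of keeping the stated
effect sizes and baseline together, not a bug. Effect-recovery experiments
therefore isolate one effect at a time (others set to 0), which keeps every
store inside the feasible range and makes the configured effect the true
group-mean difference; at n = 24 with a 79/21 ethnicity split, an occasional
replicate draws a single-ethnicity sample in which the effect is
inestimable — such replicates are redrawn.

What the generator does **not** emulate: spatial clustering of stores,
dyadic/transitive dependence between ties, supplier-specific popularity
heterogeneity (hence synthetic cores are flatter and larger than a
skew-degree real network's), item-level assortment differences across sites
of one supplier, and purchase-frequency information. Tests passing on
generator output therefore validate the *pipeline's* correctness and the
calibration of its statistics under independence, not distributional realism
of any particular observed network.

## Determinism and problem sizes

A single configuration seed spawns independent substreams for the generator
and the bootstrap, so two `report` runs with the same config are
byte-identical. Default analysis sizes: bootstrap B = 5000; calibration
experiments in the test suite use 100–200 replicates with B = 1000 and
random bipartite oracles at ≤ 10 × 10 — sizes chosen to give Monte-Carlo
error well inside the asserted bands.

## Known limitations

- The coverage-rule core is one deterministic reading of "suppliers covering
  ≥ 80% of edges"; block-model core/periphery fits can select different sets.
- The bootstrap density test treats the two networks as independent, though
  they share the same stores; a paired scheme would need the joint tie
  structure that binary mode-wise edges do not retain.
- Haversine distance understates road travel, and per-store mean distance
  depends on which network's connected suppliers are averaged.
- The generator's independence assumptions make its null cases easier than
  real procurement networks with shared-wholesaler dependence.
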