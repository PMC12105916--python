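# Methods

This note documents the models and procedures implemented in `consunit`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate.

## Coordinate handling

All clustering, grid, perimeter, area and overlay math runs in a projected
metric CRS. The package implements the transverse-Mercator projection on
the GRS80 ellipsoid (Krüger series in Karney's form, exact to well under a
millimetre across a zone) and resolves GDA94/MGA (`EPSG:283zz`) and WGS84
UTM codes; when no CRS is given, the MGA zone containing the data's mean
longitude is used. The forward transform is verified in the test suite
against the published Flinders Peak GDA94→MGA55 control coordinate, and
round trips recover lon/lat to < 1e-6°. Longitudes more than 3.5° from the
central meridian are flagged as outside the zone's domain of validity
(warning, not rejection).

## Management-unit definition

**Grid method.** A sample at projected (x, y) falls in cell
(⌊x/s + 0.5⌋, ⌊y/s + 0.5⌋) for cell size s — nearest-integer binning with
half-up ties so binning is deterministic; floor binning is available via
`grid_binning: floor`. Default cell sizes: 50, 100, 250, 500 m.

**Density method.** DBSCAN with eps = 100 m and min_pts = 3 over all target
species pooled; a core point has ≥ min_pts neighbours within eps (itself
included), clusters are density-reachability closures, everything else is
noise. Defaults reflect on-ground practice: individuals more than 100 m
from a stand are not manageable with it, and stands under three plants are
not worth a dedicated site. Border points reachable from two clusters are
assigned by scikit-learn's deterministic order; the test oracle treats any
reachable cluster as correct, which is the inherent ambiguity of DBSCAN.

**Perimeter constraint.** The perimeter of a unit is the boundary length of
the convex hull of its member points. Degenerate sets are handled exactly:
two points or a collinear set count twice the maximum pairwise distance
(out-and-back walking distance) and are flagged; a single point has
perimeter 0. Clusters over the limit (default 700 m, the practical range of
fire-mitigation works) are split by 2-means on coordinates (10 restarts,
seeded; equidistant points tie-break to the first centroid), each side
re-examined recursively. Binary splitting is the minimal scheme that
guarantees termination, since every split strictly reduces membership.
Splitting may produce units below the DBSCAN minimum size; they are kept
and flagged rather than re-merged, because the size minimum is a clustering
parameter, not a property of the final units. Noise samples are reported
separately and never attached to a unit.

For overlay work, unit hulls are buffered by `hull_buffer_m` (default 10 m)
so degenerate units have positive area; overlap proportions are undefined
on zero-area geometry.

## SNP filtering and genetic metrics

Filters are applied in a fixed, logged order: reproducibility ≥ 0.96 → one
locus per sequencing tag (keeping the least-missing locus, ties to the
lowest locus id) → locus missingness ≤ 30% → fixed-locus removal → sample
missingness ≤ 30% → re-removal of loci made fixed by sample removal. The
order lets each rule see the most information; the per-step removal counts
make it auditable, and the whole cascade is idempotent.

Minor-allele frequencies are computed per species over all retained
samples (not per unit): an allele is classed once per species as common
(MAF > 5%) or rare (1% ≤ MAF ≤ 5%), then tabulated by group. Each biallelic
locus contributes up to two countable alleles; an allele is present in a
group when at least one copy appears among non-missing calls. Private
alleles are present in exactly one group. Counts are normalized by the
species-wide allele total of the class, so proportions are comparable
across species with very different locus counts.

Observed heterozygosity is the fraction of heterozygous calls over
non-missing common loci, per individual; group values are member means.
Individuals with no scored common locus are flagged undefined rather than
zeroed.

Pairwise genetic distance is Euclidean over loci scored in both
individuals, rescaled by √(L_total / L_shared) so pairs with different
completeness stay comparable (the unbiased pairwise-complete scaling).
Between-group distance is, per group, the unweighted mean over other groups
of the mean inter-individual distance; a pooled-pairs alternative is
available (`between_mode: pooled`). Within-group distance needs ≥ 2
members; undefined statistics are flagged, excluded from means, and
contribute zero to composite scores.

## Composite genetic value

`G_raw = Σ w_i v_i` with non-negative user weights, and
`G_final = G_raw / max(G_raw)` within each species, so `G_final ∈ [0, 1]`
and each species' best unit scores exactly 1. Because the metrics differ in
scale by orders of magnitude (allele proportions vs. genotype distances),
each variable is by default divided by its per-species maximum before
weighting; otherwise "equal weights" would de facto weight by scale. The
strict unnormalized sum is available (`normalize_variables: false`).
Weights need not sum to one — the final ratio cancels any scale. Member
count is wired in as an optional fifth variable with default weight 0.
A species whose raw scores are all zero gets G_final 0 with a warning
rather than a division error. Multispecies value is the per-unit sum of
per-species finals.

## Fire risk

For a severity class s, `expected(v, s) = share(v) × Σ_v observed(v, s)`
where share(v) is class v's fraction of the reference region, and
`ratio = observed / expected`. The reference region is the vegetation map
clipped to a buffer (default 100 m, mitre joins so rectangles stay
rectangular) around the burn footprint: the null model is "within the
fire-affected neighbourhood, every vegetation class burns alike", which
avoids diluting expectations with vegetation far from any fire. Burns can
enter as severity-labelled polygons (areas computed by overlay) or as a
printed area table with explicit reference areas. Expected areas conserve
the observed total per severity by construction; severities with zero
observed burn get flagged NaN ratios. Ratios are scale-invariant in area
units.

Unit risk multiplies each overlap proportion (unit∩class area / unit area)
by the class's *total*-severity ratio and sums; severity-specific risk is
available by argument. Unit area outside any mapped vegetation contributes
zero and is surfaced through a `coverage` diagnostic — whether that is the
right treatment of unmapped ground is a user decision, not asserted here.

A bundled area table for the Nightcap reserves (seven vegetation classes ×
four severities plus whole-reserve and fire-buffer reference areas, from
published 2019/20 fire accounting) provides a real fixed input; only areas
are stored, every ratio and percentage is recomputed at run time. Ratio
cells whose observed areas are a few hundredths of km² against a small
severity total (the high/extreme columns) are dominated by the 2-decimal
printing precision of the inputs; the tests bound those cells by interval
propagation of that precision rather than a fixed tolerance.

## Synthetic data

The generator emulates the study conditions end to end with known ground
truth. Occurrences are Gaussian stands: tight clusters (spreads 25–50 m)
separated by hundreds of metres to kilometres, three co-occurring species,
~100 samples total in the default scenario — the clumped, sympatric pattern
the clustering method is designed for. Genotypes follow the
Balding–Nichols model: ancestral frequencies Uniform(0.05, 0.95), group
frequencies Beta(p(1−θ)/θ, (1−p)(1−θ)/θ), genotypes Binomial(2, p_group);
defaults θ = 0.1 (moderate structure typical of fine-scale plant
populations), 200 loci, 5% missing calls, reproducibility 1.0 with unique
tags. The landscape is a Voronoi mosaic (40 cells over 5 × 5 km) with a
three-class flammability gradient and per-class burn probabilities
(0.2 / 0.5 / 0.8); burned cells draw severities from a fixed mixture
dominated by low severity. All draws derive from a single seed;
re-generation is bit-identical.

What passing tests show: the algorithms recover planted structure —
well-separated stands are recovered exactly, between-group distance rises
monotonically with θ, realized burn ratios match the analytic expectation
p_v/p̄ within sampling error, and the pipeline's top-ranked unit is the one
holding the most distinct alleles when richness alone is weighted. What
they do not show: robustness to real-data pathologies — spatial sampling
bias, linked loci, genotyping error structure, non-convex stand shapes, or
raster-derived severity noise. The generator deliberately makes no attempt
to mimic real geography or allele-frequency spectra.

## Problem sizes and determinism

Default test and acceptance runs use ~100-sample scenarios, 120–200 loci,
40-cell mosaics, 20-replicate recovery experiments, and 100 random
clustering scenarios — sizes at which every brute-force oracle (O(n²)
density closure, gift-wrapping hulls, exhaustive allele enumeration) is
exact and fast. All stochastic stages consume seeds derived from one
configured seed; a run manifest (config echo, version, per-stage counts)
suffices to reproduce a run bit-identically.

## Known limitations

- Unit boundaries are convex hulls; concave (alpha-shape) boundaries and
  interpolated diversity surfaces are out of scope.
- No kinship, F_IS, F_ST or effective-population-size estimation; the
  composite deliberately uses heterozygosity and distance metrics that are
  robust at small within-site sample sizes.
- Burn severity enters as polygons or area tables only; no raster
  ingestion, no fire-behaviour modelling.
- The between-group distance averages over groups, not pooled pairs, by
  default; both readings are defensible and the alternative is one flag
  away.
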