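# Methods

This note documents the models and numerical conventions behind sweepscan:
what each statistic estimates, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the design choices
made where more than one convention was defensible.

## Data model

Varieties are inbred lines, treated throughout as homozygous diploids: each
line contributes one haplotype, and observed heterozygosity is zero unless
real heterozygous calls are supplied. Alleles are coded 0/1 against the
*global* major allele — the most frequent allele over the union of both
populations of a pair (ties broken toward the lexicographically smaller
symbol). No ancestral/derived polarity is assumed or needed: Rsb and xpEHH
as used here are site statistics whose identity comparisons are symmetric
in allele labels. Positions are 1-based base pairs; all distances are in bp.

Panel-level filters mirror standard array practice: markers with more than
two observed alleles are rejected with an error record; markers mapping to
a duplicated position keep one representative (first by marker-id sort);
markers below 5% minor-allele frequency are removed (inclusive bound:
MAF = 0.05 is kept). On real data a marker's frequency uses non-missing
calls only, and a haplotype with a missing call inside an EHH interval
drops out of pair counting from that extension onward; imputation is out of
scope. The profile monotonicity guarantee below assumes complete data —
with missing-data dropout the denominator can shrink, so monotonicity is
only enforced on complete panels (synthetic data is always complete).

## Haplotype statistics

**EHH** at extension marker *t*, for a core allele at focal marker *s*, is
Σ_h C(n_h,2) / C(n_a,2): the probability that two of the n_a carrier
haplotypes, drawn without replacement, are identical at every marker of the
closed interval [s, t]. **EHHS** is the same quantity over all n haplotypes
(the focal allele participates in the identity comparison); the normalized
variant divides by focal-site homozygosity so the curve starts at 1.
Profiles are computed by partition refinement walking outward from the
focal marker; values are non-increasing because refinement never coarsens a
partition. Fewer than two (carrier) haplotypes, or a monomorphic focal
site, leaves the statistic undefined (missing).

**Integration.** iES and iNES are trapezoidal areas under the unnormalized
and normalized EHHS curves, left side plus right side, in bp. Two
numerical conventions matter:

* *Gap cap* (`scalegap_bp`, default 2,500,000): any intermarker gap wider
  than the cap contributes exactly the cap as width. Without it, a single
  multi-megabase gap bridged by chance identity would dominate the area.
* *Truncation* (`trunc`, default 0.05): on each side, integration stops
  at — and excludes — the first marker whose value falls below the
  threshold. The default matches the truncation conventionally used with
  these statistics; the value is a tail cutoff, below which the curve
  carries more noise than signal. Each curve variant is truncated on its
  own values (the normalized curve, being larger, integrates slightly
  further); this is this package's convention and is pinned by its tests.
  Integration simply ends at the terminal marker of a chromosome — no
  border discard, since sweeps at chromosome ends are legitimate calls.

**Cross-population statistics.** With per-marker areas for a target and a
reference population sharing one marker set, raw log-ratios
ln(iNES_t/iNES_r) and ln(iES_t/iES_r) are standardized genome-wide per
pair: Rsb subtracts the median, xpEHH the mean, and both divide by the
sample standard deviation (ddof = 1). Standardization is genome-wide, not
per chromosome or per frequency bin, because single ±2 thresholds are
applied genome-wide downstream. Markers where either area is missing or
zero are missing; a log-ratio track with zero spread raises a
degenerate-scan error rather than emitting infinities. A null diagnostic
reports mean, sd, the fraction beyond |2| (≈ 2Φ(−2) = 4.55% under
normality), and the maximum CDF discrepancy against a standard normal
truncated to [−2, 2].

## F_st and diversity

The Weir–Cockerham two-population estimator is implemented from its
variance components (a, b, c) with the heterozygosity terms retained, so
heterozygous calls on real data remain supported even though inbred panels
have h̄ = 0 (and hence c = 0). Monomorphic loci are missing, not zero;
negative estimates are reported unclamped — they are informative about
sampling noise and do not affect the 95th-percentile threshold materially.
The test suite pins the estimator to an independent sums-of-squares ANOVA
implementation at 1e-10. Whether lines are treated as haploid or
homozygous-diploid changes only the finite-sample correction; the
homozygous-diploid contract is adopted and pinned by that oracle test.

Gene diversity is PIC = 1 − Σ p_i²; ΔPIC = PIC_target − PIC_reference. For
the diversity-change summaries, a region "lost diversity" iff its mean
ΔPIC is strictly negative; ties count as gained.

## Population pairs

Four comparison categories are enumerated in a fixed order (over-time,
region, state, market class; labels sorted within category) so that region
serial numbers are stable. Over-time splits sort by (release year,
accession) — the accession tie-break makes year ties deterministic — and
give the older floor(n/2) varieties to the reference; an odd member joins
the newer target half, keeping the older half the baseline. State
comparisons exclude from the reference the target state, every state of
the target's region, and every bordering state, so that geographic
admixture does not dilute the contrast. Varieties of unknown market class
participate in panel/region/state populations but not in class
populations. Every emitted pair satisfies the ≥ 20 varieties-per-population
rule; smaller pairs are silently skipped. The packaged state→region table
and adjacency map cover a plausible subset of US wheat states under the
five-region scheme and are overridable.

## Candidate-region calling

Windows of `window_bp` = 5,000,000 are tiled, non-overlapping, from each
chromosome's first marker (the tiling origin is configurable in principle;
anchoring at the first marker keeps empty leading windows out). A window
qualifies with ≥ 5 markers and ≥ 90% of them at or above the threshold
("exceeding" is read as ≥). Only the positive tail of Rsb/xpEHH is scanned
by default — positive means selection in the target — with a config flag
for the mirrored scan. Candidate windows separated by < 1,000 kb merge
(strict inequality). Region coordinates are marker-delimited: the
positions of the first and last markers inside the merged span, *including*
markers whose statistic is undefined — inside a sweep the most extreme
markers are often fixed in the target, which makes the haplotype statistic
incalculable exactly where selection was strongest, and such markers still
belong to the swept segment. Marker counts and all statistic/PIC/frequency
summaries use only defined-statistic markers, so the count invariants match
the window rule. The F_st threshold is the pair's genome-wide 95th
percentile, computed with the linear-interpolation quantile.

## Synthetic data

The generator is a founder mosaic, not a coalescent: founder haplotypes are
drawn marker-by-marker from a U-shaped Beta(0.3, 0.3) spectrum truncated at
the MAF floor (an array-like, post-filter spectrum), and each inbred line
is a mosaic of founders with Poisson(recomb_rate × n_mixing_rounds)
crossover breakpoints per chromosome. This produces the long shared
haplotype tracts the EHH statistics measure, at a small fraction of the
cost of a forward or coalescent simulation, and is fully deterministic
under a seed. Marker maps have a low-density central zone
(`gap_model` = (0.25, 0.15): the middle 25% of each chromosome at 15%
relative density), which yields the multi-megabase gaps that motivate the
gap cap. Sweeps are planted as hard segment replacements: one founder's
segment over [focal − span/2, focal + span/2] is copied into a fraction
`sweep_freq` of target lines. The MAF filter and major/minor coding are
applied over the union of the pair, so both panels share one marker set.

Default neutral-pair conditions: 2 × 75 lines, 3 chromosomes × 600 Mb with
1,100 markers each (≈ 2,300 markers surviving the 5% MAF filter), 30
founders, 10 mixing rounds at 1 crossover per chromosome per round. Under
these conditions standardized xpEHH and Rsb sit within a fraction of a
percentage point of the 5% null tail.

What the generator does *not* emulate: demographic history (bottlenecks,
migration), genotyping error, low-diversity subgenomes, or gradual
hitchhiking decay at sweep edges (replacement boundaries are sharp).
Passing tests therefore demonstrate the pipeline's correctness and
calibration under idealized breeding-population structure, not performance
on any particular real panel.

**Recovery experiment design.** The planted-sweep recovery and null
false-positive tests run on a reduced genome chosen once: 2 chromosomes ×
150 Mb with 900 markers each (≈ 4 markers/Mb after filtering, so a 5-Mb
calling window holds ~20 markers and an 8-Mb sweep well over 10) and 20
founders, a founder base typical of a regional breeding program. The
founder count matters for detection geometry: background haplotype sharing
lets the elevated statistic reach slightly past the replaced segment, which
the fixed 5-Mb window needs in order to find a fully-extreme window at
every alignment of sweep to window grid. Focal positions are drawn in the
dense distal arm. With carrier frequency 0.95 and an 8-Mb span, the focal
position is covered by a called xpEHH region in 20/20 seeds, and neutral
genomes yield ≤ 2 haplotype-statistic regions in 20/20 seeds, at these
conditions.

## Known limitations

* EHH-family statistics are undefined once an allele is fixed in either
  population, so completed sweeps are visible only to F_st — the main
  reason the two families are complementary.
* The window rule's power depends on marker density relative to window
  size; sparse regions (e.g. the simulated centromeric zones) cannot
  produce calls because windows there hold fewer than five markers.
* Scan cost grows with haplotype sharing (long walks before truncation);
  panels with thousands of markers and ~100 lines scan in seconds, but
  very long, very homogeneous chromosomes will be slower.
* The 95th-percentile F_st threshold is relative per pair: it always flags
  the top tail, so F_st region counts are not comparable across pairs with
  very different differentiation levels without further calibration.
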