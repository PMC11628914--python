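# sweepscan

Genome-wide scans for **candidate selective sweeps (CSS)** in structured crop
populations genotyped with SNP arrays, aimed at breeders and population
geneticists working with panels of inbred varieties (each line contributes a
single haplotype, so no phasing is needed). The package builds
target/reference population pairs from variety metadata, computes
per-marker differentiation and haplotype-length statistics, calls candidate
regions with windowing rules, and quantifies the diversity change inside
each region.

## Statistics

For a biallelic marker with allele frequencies *p*ᵢ:

* **PIC / gene diversity**: PIC = 1 − Σᵢ *p*ᵢ²; ΔPIC = PIC(target) −
  PIC(reference) is negative where the target population lost diversity.
* **F_st** (Weir–Cockerham): the two-population variance-components
  estimator θ = a/(a+b+c), with a, b, c the among-population,
  among-individual and within-individual components. Inbred lines are
  homozygous diploids (observed heterozygosity 0); negative estimates are
  reported as computed. Each pair's CSS threshold is its genome-wide 95th
  percentile F_st.
* **EHH / EHHS**: the probability that two haplotypes drawn at random (from
  the carriers of a core allele, or from the whole sample) are identical
  over the closed interval from the focal marker to an extension marker.
  Integrating the EHHS decay curve over physical distance gives **iES**
  (unnormalized) and **iNES** (normalized by focal-site homozygosity).
  Intermarker gaps wider than 2,500 kb contribute only 2,500 kb of width
  (the gap cap), and each side of the curve is truncated at the first value
  below 0.05.
* **Rsb** = standardized ln(iNES_t / iNES_r) (median-centered) and
  **xpEHH** = standardized ln(iES_t / iES_r) (mean-centered), both scaled to
  unit variance genome-wide. Under neutrality both are approximately
  standard normal, so |value| > 2 marks the extreme ~5% of markers; positive
  values mean longer shared haplotypes — recent selection — in the target.
* **CSS calling**: 5,000-kb windows tiled from each chromosome's first
  marker; a window is a candidate when it holds ≥ 5 markers and ≥ 90% of
  them are at or above the threshold (+2 for Rsb/xpEHH, the 95th-percentile
  value for F_st). Candidate windows < 1,000 kb apart are merged, and each
  merged region is reported with marker-delimited coordinates, summary
  statistics, PIC/ΔPIC, and major-allele frequencies, under serial numbers
  css1, css2, ...

A founder-mosaic simulator generates inbred panels, marker maps with a
sparse centromeric zone, planted hard sweeps, and study-like variety
metadata, so the entire pipeline is testable without any external data.

## Worked example

```python
import sweepscan as ss

# neutral target/reference pair: 2 x 75 inbred lines, 3 chromosomes
config = ss.SimConfig(seed=1)
panel_t, panel_r = ss.simulate_pair(config)
scan = ss.scan_pair_panels(panel_t, panel_r)          # per-marker ScanTable

x = scan["xpEHH"].dropna()
print(len(x), round(x.mean(), 6), round(x.std(), 4),
      round((abs(x) > 2).mean(), 4))
# 2294 -0.0 1.0 0.0501
```

2,294 markers survive the 5% MAF filter; standardized xpEHH has mean 0 and
standard deviation 1 by construction, and 5.01% of markers fall beyond |2| —
matching the ~5% a standard-normal null predicts, so on this neutral pair
the scan flags nothing beyond the expected extreme tail. Planting a sweep
changes that:

```python
sweep = ss.SweepSpec("chr1", focal_bp=40_000_000, sweep_freq=0.95,
                     span_bp=8_000_000)
panel_t, panel_r = ss.simulate_pair(ss.SimConfig(
    n_chrom=2, chrom_length_bp=150_000_000, n_markers_per_chrom=900,
    n_founders=20, seed=2), sweep)
scan = ss.scan_pair_panels(panel_t, panel_r)
regions = ss.call_css({"demo": scan}, {"demo": {"category": "region"}})
for r in regions:
    print(r.serial, r.statistic, r.chromosome,
          f"{r.start_bp/1e6:.1f}-{r.end_bp/1e6:.1f} Mb",
          r.n_markers, round(r.delta_pic, 3))
# css1 Rsb chr1 35.3-44.9 Mb 27 -0.203
# css2 xpEHH chr1 35.3-44.9 Mb 27 -0.203
```

Both haplotype statistics recover the planted sweep: the called regions
cover the 36–44 Mb swept segment, and the negative ΔPIC shows the target
population lost diversity there, as a sweep predicts. (F_st calls no region
here — its threshold is the pair's own 95th percentile, and the sweep does
not push a 90%-extreme marker cluster past it in this simulation, an
illustration of why complementary statistics are scanned together.)

The same pipeline runs from the shell via the `sweepscan` CLI
(`simulate`, `pairs`, `scan`, `call`, `report` subcommands); pair
construction enumerates over-time splits (older half = reference, newer =
target), region-vs-others, state-vs-others (excluding co-regional and
bordering states), and market-class comparisons, keeping only pairs whose
populations both have ≥ 20 varieties.

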