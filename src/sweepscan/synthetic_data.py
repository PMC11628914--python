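"""Synthetic inbred SNP panels, marker maps, and variety metadata.

The generator emulates the statistical structure a crop SNP-array sweep scan
assumes, without any download:

* founder haplotypes drawn marker-by-marker from a U-shaped allele-frequency
  spectrum truncated at the MAF floor (a post-filter array spectrum, not a
  sequencing spectrum);
* inbred descendant lines built as recombinant mosaics of the founders, so
  long shared haplotype tracts exist for the EHH statistics to measure;
* uneven marker density with a low-density centromeric zone, producing the
  multi-megabase intermarker gaps that motivate the gap cap;
* optional hard sweeps planted by raising one founder's segment around a
  focal position to a chosen carrier frequency in the target population;
* variety metadata (year, state, region, market class, habit) whose default
  design reproduces the grouping structure of a nationwide wheat panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import HaplotypePanel, MarkerMap, default_geography, filter_maf


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the neutral founder-mosaic simulator.

    ``recomb_rate`` is the expected number of crossovers per chromosome per
    mixing round; ``n_mixing_rounds`` rounds accumulate, so a line's mosaic
    has on average ``recomb_rate * n_mixing_rounds`` breakpoints per
    chromosome.  ``gap_model`` is (center_fraction, density_ratio): the
    central ``center_fraction`` of each chromosome receives marker density
    reduced by ``density_ratio``, mimicking sparse centromeric coverage.
    """

    n_chrom: int = 3
    chrom_length_bp: int = 600_000_000
    n_markers_per_chrom: int = 1100
    gap_model: tuple[float, float] = (0.25, 0.15)
    n_founders: int = 30
    n_varieties_per_pop: int = 75
    recomb_rate: float = 1.0
    n_mixing_rounds: int = 10
    maf_floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chrom, self.chrom_length_bp, self.n_markers_per_chrom,
               self.n_founders, self.n_varieties_per_pop) <= 0:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in [0, 0.5)")
        if self.n_mixing_rounds < 0 or self.recomb_rate < 0:
            raise ValueError("mixing parameters must be non-negative")


@dataclass(frozen=True)
class SweepSpec:
    """A planted hard sweep: hitch-hiking identity around a favored site.

    In the target population, the segment ``[focal_bp - span_bp/2,
    focal_bp + span_bp/2]`` of one founder haplotype is copied into lines
    until its carrier frequency reaches ``sweep_freq``.
    """

    chromosome: str
    focal_bp: int
    sweep_freq: float = 0.95
    span_bp: int = 8_000_000

    def __post_init__(self) -> None:
        if not 0.5 < self.sweep_freq <= 1.0:
            raise ValueError("sweep_freq must be in (0.5, 1]")
        if self.span_bp <= 0:
            raise ValueError("span_bp must be positive")


def _chrom_names(n: int) -> list[str]:
    return [f"chr{i + 1}" for i in range(n)]


def _draw_positions(config: SimConfig, rng: np.random.Generator) -> MarkerMap:
    """Marker coordinates with a low-density central zone per chromosome."""
    center_frac, density_ratio = config.gap_model
    L = config.chrom_length_bp
    lo = 0.5 * (1.0 - center_frac) * L
    hi = 0.5 * (1.0 + center_frac) * L
    # expected marker share of the central zone under reduced density
    p_center = (center_frac * density_ratio) / (
        center_frac * density_ratio + (1.0 - center_frac)
    )
    marker_ids, chroms, positions = [], [], []
    for chrom in _chrom_names(config.n_chrom):
        m = config.n_markers_per_chrom
        n_center = rng.binomial(m, p_center)
        arm = rng.uniform(0, (1.0 - center_frac) * L, size=m - n_center)
        arm = np.where(arm < lo, arm, arm + center_frac * L)
        center = rng.uniform(lo, hi, size=n_center)
        pos = np.unique(np.concatenate([arm, center]).astype(np.int64) + 1)
        marker_ids += [f"{chrom}_m{p}" for p in pos]
        chroms += [chrom] * len(pos)
        positions += pos.tolist()
    return MarkerMap(
        np.array(marker_ids, dtype=object),
        np.array(chroms, dtype=object),
        np.array(positions, dtype=np.int64),
    )


def _draw_founders(
    n_markers: int, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Founder haplotypes under a truncated U-shaped frequency spectrum."""
    freq = rng.beta(0.3, 0.3, size=n_markers)
    freq = np.clip(freq, config.maf_floor, 1.0 - config.maf_floor)
    return (
        rng.random((config.n_founders, n_markers)) < freq[None, :]
    ).astype(np.int8)


def _mosaic_lines(
    founders: np.ndarray,
    marker_map: MarkerMap,
    n_lines: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inbred lines as founder mosaics with Poisson crossover breakpoints."""
    n_markers = founders.shape[1]
    lines = np.empty((n_lines, n_markers), dtype=np.int8)
    mean_breaks = config.recomb_rate * config.n_mixing_rounds
    chrom_arr = marker_map.chromosome
    pos_arr = marker_map.position_bp
    for chrom in marker_map.chromosomes:
        idx = np.flatnonzero(chrom_arr == chrom)
        pos = pos_arr[idx]
        for i in range(n_lines):
            n_breaks = rng.poisson(mean_breaks)
            cuts = np.sort(rng.uniform(0, config.chrom_length_bp, size=n_breaks))
            segment = np.searchsorted(cuts, pos)  # segment index per marker
            donors = rng.integers(0, config.n_founders, size=n_breaks + 1)
            lines[i, idx] = founders[donors[segment], idx]
    return lines


def _recode_major(alleles: np.ndarray) -> np.ndarray:
    """Flip columns so code 0 is the (global) major allele."""
    flip = alleles.mean(axis=0) > 0.5
    out = alleles.copy()
    out[:, flip] = 1 - out[:, flip]
    return out


def simulate_neutral_panel(config: SimConfig) -> HaplotypePanel:
    """One neutral population of inbred founder-mosaic lines.

    Deterministic under ``config.seed``.  Markers failing the MAF floor in
    the sampled lines are removed, so the returned panel satisfies
    MAF >= ``config.maf_floor`` exactly.
    """
    rng = np.random.default_rng(config.seed)
    marker_map = _draw_positions(config, rng)
    founders = _draw_founders(len(marker_map), config, rng)
    lines = _mosaic_lines(founders, marker_map, config.n_varieties_per_pop,
                          config, rng)
    panel = HaplotypePanel(
        [f"line{i + 1}" for i in range(config.n_varieties_per_pop)],
        _recode_major(lines),
        marker_map,
    )
    return filter_maf(panel, config.maf_floor)


def simulate_pair(
    config: SimConfig, sweep: SweepSpec | None = None
) -> tuple[HaplotypePanel, HaplotypePanel]:
    """A target/reference pair descending from one founder pool.

    Without a sweep the two populations are exchangeable neutral replicates.
    With a sweep, the target population receives one founder's segment
    around the focal site at carrier frequency ``sweep.sweep_freq``; the
    reference stays neutral.  Allele coding (major/minor) and the MAF filter
    are applied over the union of both populations so the panels share one
    marker set.
    """
    rng = np.random.default_rng(config.seed)
    marker_map = _draw_positions(config, rng)
    founders = _draw_founders(len(marker_map), config, rng)
    n = config.n_varieties_per_pop
    target = _mosaic_lines(founders, marker_map, n, config, rng)
    reference = _mosaic_lines(founders, marker_map, n, config, rng)

    if sweep is not None:
        if sweep.chromosome not in marker_map.chromosomes:
            raise ValueError(f"sweep chromosome {sweep.chromosome!r} not simulated")
        if not 1 <= sweep.focal_bp <= config.chrom_length_bp:
            raise ValueError("sweep focal position outside the chromosome")
        half = sweep.span_bp // 2
        in_span = (
            (marker_map.chromosome == sweep.chromosome)
            & (marker_map.position_bp >= sweep.focal_bp - half)
            & (marker_map.position_bp <= sweep.focal_bp + half)
        )
        donor = founders[int(rng.integers(0, config.n_founders))]
        n_carriers = int(round(sweep.sweep_freq * n))
        carriers = rng.choice(n, size=n_carriers, replace=False)
        target[np.ix_(carriers, np.flatnonzero(in_span))] = donor[in_span]

    both = _recode_major(np.vstack([target, reference]))
    union = HaplotypePanel(
        [f"t{i + 1}" for i in range(n)] + [f"r{i + 1}" for i in range(n)],
        both,
        marker_map,
    )
    union = filter_maf(union, config.maf_floor)
    panel_t = HaplotypePanel(
        [f"t{i + 1}" for i in range(n)], union.alleles[:n], union.map
    )
    panel_r = HaplotypePanel(
        [f"r{i + 1}" for i in range(n)], union.alleles[n:], union.map
    )
    return panel_t, panel_r


# ---------------------------------------------------------------------------
# metadata


@dataclass(frozen=True)
class GroupSpec:
    """One homogeneous block of varieties in a metadata design."""

    state: str
    habit: str
    market_class: str
    n: int


def study_design() -> list[GroupSpec]:
    """Default metadata design emulating a nationwide wheat variety panel.

    Group sizes are chosen so that, under the >= 20 per-population rule, the
    over-time enumeration yields exactly 19 pairs (panel, spring, winter,
    five regional both-habit, three regional spring, three regional winter,
    five market classes) and the across-population enumeration exactly 44
    (five regional both, four regional spring, four regional winter, twelve
    state both, five state spring, nine state winter, five market classes),
    mirroring the grouping structure of the US panel this package targets.
    """
    g = GroupSpec
    return [
        # Northern: strong spring (HRS), modest winter
        g("ND", "spring", "HRS", 50), g("ND", "winter", "HRW", 10),
        g("MN", "spring", "HRS", 19),
        g("MT", "spring", "HRS", 25),
        g("SD", "winter", "HRW", 15),
        # Pacific: spring-dominated
        g("CA", "spring", "HRS", 20), g("CA", "spring", "SWS", 20),
        g("CA", "winter", "HRW", 5),
        g("AZ", "spring", "HRS", 12), g("AZ", "winter", "HRW", 3),
        # Pacific Northwest: both habits strong
        g("WA", "spring", "SWS", 30), g("WA", "winter", "SWW", 40),
        g("OR", "spring", "SWS", 15), g("OR", "winter", "SWW", 25),
        g("ID", "spring", "SWS", 20), g("ID", "winter", "SWW", 25),
        g("UT", "winter", "SWW", 10),
        # Great Plains: winter (HRW) heartland
        g("KS", "spring", "HRS", 10), g("KS", "winter", "HRW", 60),
        g("NE", "spring", "HRS", 10), g("NE", "winter", "HRW", 30),
        g("TX", "spring", "HRS", 10), g("TX", "winter", "HRW", 25),
        g("OK", "winter", "HRW", 18),
        g("CO", "winter", "HRW", 18),
        # Eastern: soft red winter belt
        g("OH", "winter", "SRW", 30),
        g("IN", "winter", "SRW", 25),
        g("NY", "winter", "SRW", 18),
        g("SC", "winter", "SRW", 25),
        g("MO", "winter", "SRW", 15),
        g("VA", "winter", "SRW", 15),
        g("NC", "winter", "SRW", 15),
        g("GA", "winter", "SRW", 10),
        g("IL", "winter", "SRW", 12),
        g("MI", "spring", "unknown", 6),
    ]


def simulate_metadata(
    design: list[GroupSpec] | None = None,
    year_range: tuple[int, int] = (1858, 2014),
    seed: int = 0,
    state_region: dict[str, str] | None = None,
    adjacency: dict[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Variety metadata (plus adjacency map) for a grouping design.

    Years are drawn uniformly over ``year_range`` (ties allowed), accessions
    are unique, and group sizes are exactly as requested.  States in the
    design must exist in the state->region table.
    """
    if design is None:
        design = study_design()
    default_regions, default_adj = default_geography()
    if state_region is None:
        state_region = default_regions
    if adjacency is None:
        adjacency = default_adj
    unknown = {spec.state for spec in design} - set(state_region)
    if unknown:
        raise ValueError(f"design states missing from region table: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    rows = []
    counter = 0
    for spec in design:
        years = rng.integers(year_range[0], year_range[1] + 1, size=spec.n)
        for y in years:
            counter += 1
            rows.append(
                {
                    "variety_id": f"var{counter:04d}",
                    "accession": f"PI{600000 + counter}",
                    "year": int(y),
                    "state": spec.state,
                    "region": state_region[spec.state],
                    "market_class": spec.market_class,
                    "habit": spec.habit,
                }
            )
    return pd.DataFrame(rows), adjacency
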