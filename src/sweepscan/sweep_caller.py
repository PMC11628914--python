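"""Candidate selective sweep (CSS) calling from per-marker statistic tracks.

A chromosome is tiled with non-overlapping windows (default 5,000 kb)
anchored at its first marker.  A window is a candidate when it holds at
least ``min_markers`` markers and at least ``min_frac_extreme`` of them are
at or above the threshold — +2 for the standardized haplotype statistics
(one-sided, positive tail: selection in the target), and the pair-specific
95th-percentile value for Fst.  Candidate windows separated by less than
``merge_gap_bp`` are merged; the merged region is then reported with the
positions of its first and last markers and annotated with summary
statistics, diversity change, and major-allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EHH_STATS = ("Rsb", "xpEHH")
STATISTICS = ("Fst",) + EHH_STATS


@dataclass(frozen=True)
class RegionCallingConfig:
    """Window, threshold, and merge parameters for CSS calling."""

    window_bp: int = 5_000_000
    min_markers: int = 5
    min_frac_extreme: float = 0.9
    merge_gap_bp: int = 1_000_000
    ehh_threshold: float = 2.0
    fst_quantile: float = 0.95
    #: also scan the negative tail of Rsb/xpEHH (selection in the reference)
    call_negative_tail: bool = False

    def __post_init__(self) -> None:
        if min(self.window_bp, self.min_markers, self.merge_gap_bp) <= 0:
            raise ValueError("window_bp, min_markers, merge_gap_bp must be positive")
        if not 0.0 < self.min_frac_extreme <= 1.0:
            raise ValueError("min_frac_extreme must be in (0, 1]")
        if not 0.0 < self.fst_quantile < 1.0:
            raise ValueError("fst_quantile must be in (0, 1)")


@dataclass(frozen=True)
class CandidateRegion:
    """One called CSS with coordinates and marker-averaged annotations."""

    serial: str
    pair_label: str
    category: str
    statistic: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_markers: int
    n_extreme: int
    max_stat: float
    mean_stat: float
    pic_t: float
    pic_r: float
    delta_pic: float
    p_major_t: float
    p_major_r: float


def fst_threshold(fst_values, quantile: float = 0.95, min_values: int = 20) -> float:
    """Pair-specific Fst threshold: the genome-wide 95th percentile.

    Uses the linear-interpolation quantile between order statistics.
    """
    x = np.asarray(fst_values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < min_values:
        raise ValueError(f"need >= {min_values} non-missing Fst values, got {x.size}")
    return float(np.quantile(x, quantile, method="linear"))


def window_scan(
    positions,
    values,
    threshold: float,
    config: RegionCallingConfig,
) -> list[tuple[int, int]]:
    """Candidate windows on one chromosome.

    ``positions`` must be sorted; markers with missing values are ignored.
    Non-overlapping windows of ``config.window_bp`` are tiled from the first
    marker's position; a window qualifies when it holds >=
    ``config.min_markers`` markers of which >= ``config.min_frac_extreme``
    have value >= ``threshold``.  Returns (window_start, window_end) bp
    edges, end exclusive.
    """
    pos = np.asarray(positions, dtype=np.int64)
    val = np.asarray(values, dtype=float)
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    ok = ~np.isnan(val)
    pos, val = pos[ok], val[ok]
    if pos.size == 0:
        return []
    origin = int(pos[0])
    w = config.window_bp
    bins = (pos - origin) // w
    out = []
    for b in np.unique(bins):
        in_win = bins == b
        n = int(in_win.sum())
        if n < config.min_markers:
            continue
        n_extreme = int((val[in_win] >= threshold).sum())
        if n_extreme / n >= config.min_frac_extreme:
            start = origin + int(b) * w
            out.append((start, start + w))
    return out


def merge_windows(
    windows: list[tuple[int, int]], merge_gap_bp: int
) -> list[tuple[int, int]]:
    """Union windows whose gap (next.start - prev.end) is < ``merge_gap_bp``.

    Input must be sorted by start; the strict inequality means spans exactly
    ``merge_gap_bp`` apart stay separate.
    """
    merged: list[list[int]] = []
    for start, end in windows:
        if merged and start - merged[-1][1] < merge_gap_bp:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def annotate_region(
    span: tuple[int, int],
    chrom_scan: pd.DataFrame,
    statistic: str,
    threshold: float,
) -> dict:
    """Summaries over the markers falling inside a merged window span.

    Region coordinates are the positions of the first and last markers
    inside the span (marker-delimited, not window-edge), counting markers
    whose statistic is missing: inside a sweep the most extreme markers are
    often fixed in the target, which leaves the haplotype statistic
    undefined there, yet they belong to the swept segment.  Marker counts
    and the statistic, PIC, delta-PIC, and frequency summaries use only the
    markers with a defined statistic, matching the window rule.
    """
    start, end = span
    in_span = chrom_scan[(chrom_scan["pos"] >= start) & (chrom_scan["pos"] < end)]
    inside = in_span[in_span[statistic].notna()]
    if inside.empty:
        raise ValueError("span contains no markers")
    v = inside[statistic].to_numpy(dtype=float)
    return {
        "chromosome": str(inside["chrom"].iloc[0]),
        "start_bp": int(in_span["pos"].iloc[0]),
        "end_bp": int(in_span["pos"].iloc[-1]),
        "n_markers": int(len(inside)),
        "n_extreme": int((v >= threshold).sum()),
        "max_stat": float(v.max()),
        "mean_stat": float(v.mean()),
        "pic_t": float(inside["PIC_t"].mean()),
        "pic_r": float(inside["PIC_r"].mean()),
        "delta_pic": float(inside["dPIC"].mean()),
        "p_major_t": float(inside["p_major_t"].mean()),
        "p_major_r": float(inside["p_major_r"].mean()),
    }


def call_regions_for_scan(
    scan: pd.DataFrame,
    config: RegionCallingConfig = RegionCallingConfig(),
    statistics: tuple[str, ...] = STATISTICS,
) -> list[dict]:
    """Un-serialled candidate regions for one pair's ScanTable.

    Iterates statistic (Fst, Rsb, xpEHH) then chromosome (map order).  For
    the haplotype statistics only the positive tail is scanned unless
    ``config.call_negative_tail`` is set, in which case the mirrored scan on
    the negated track is appended (statistic suffix "-").
    """
    regions: list[dict] = []
    for statistic in statistics:
        if statistic == "Fst":
            threshold = fst_threshold(scan["Fst"], config.fst_quantile)
            tracks = [(statistic, scan, threshold)]
        else:
            tracks = [(statistic, scan, config.ehh_threshold)]
            if config.call_negative_tail:
                flipped = scan.copy()
                flipped[statistic] = -flipped[statistic]
                tracks.append((statistic + "-", flipped, config.ehh_threshold))
        for stat_name, table, thr in tracks:
            base = stat_name.rstrip("-")
            for chrom in pd.unique(table["chrom"]):
                chrom_scan = table[table["chrom"] == chrom]
                windows = window_scan(
                    chrom_scan["pos"], chrom_scan[base], thr, config
                )
                for span in merge_windows(windows, config.merge_gap_bp):
                    ann = annotate_region(span, chrom_scan, base, thr)
                    ann["statistic"] = stat_name
                    regions.append(ann)
    return regions


def call_css(
    scans: dict[str, pd.DataFrame],
    pair_meta: dict[str, dict],
    config: RegionCallingConfig = RegionCallingConfig(),
) -> list[CandidateRegion]:
    """Call and serialize CSS over many pairs.

    ``scans`` maps pair label -> ScanTable; ``pair_meta`` maps pair label ->
    {"category": ...}.  Serial numbers css1, css2, ... are assigned in the
    deterministic order (category order, pair label, statistic, chromosome,
    start position).  A CSS from the positive tail of Rsb/xpEHH belongs to
    the target population; an Fst CSS belongs to the pair.
    """
    from .population_builder import CATEGORY_ORDER

    cat_rank = {c.value: i for i, c in enumerate(CATEGORY_ORDER)}
    stat_rank = {s: i for i, s in enumerate(STATISTICS)}
    rows: list[tuple] = []
    for label, scan in scans.items():
        category = pair_meta[label]["category"]
        for ann in call_regions_for_scan(scan, config):
            base = ann["statistic"].rstrip("-")
            rows.append(
                (
                    cat_rank.get(category, len(cat_rank)),
                    label,
                    stat_rank.get(base, len(stat_rank)),
                    ann["statistic"],
                    ann["chromosome"],
                    ann["start_bp"],
                    category,
                    ann,
                )
            )
    rows.sort(key=lambda r: r[:6])
    out = []
    for i, (_, label, _, stat, chrom, start, category, ann) in enumerate(rows, 1):
        out.append(
            CandidateRegion(
                serial=f"css{i}",
                pair_label=label,
                category=category,
                statistic=stat,
                chromosome=chrom,
                start_bp=ann["start_bp"],
                end_bp=ann["end_bp"],
                n_markers=ann["n_markers"],
                n_extreme=ann["n_extreme"],
                max_stat=ann["max_stat"],
                mean_stat=ann["mean_stat"],
                pic_t=ann["pic_t"],
                pic_r=ann["pic_r"],
                delta_pic=ann["delta_pic"],
                p_major_t=ann["p_major_t"],
                p_major_r=ann["p_major_r"],
            )
        )
    return out


def css_table(regions: list[CandidateRegion]) -> pd.DataFrame:
    """Consolidated CSS table (one row per region), CSV-ready."""
    cols = [
        "serial", "pair_label", "category", "statistic", "chromosome",
        "start_bp", "end_bp", "n_markers", "n_extreme", "max_stat",
        "mean_stat", "pic_t", "pic_r", "delta_pic", "p_major_t", "p_major_r",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in regions],
                        columns=cols)


def css_marker_detail(
    region: CandidateRegion, scan: pd.DataFrame
) -> pd.DataFrame:
    """Per-marker detail for one CSS (SNP names, positions, PIC, freqs, stats)."""
    inside = scan[
        (scan["chrom"] == region.chromosome)
        & (scan["pos"] >= region.start_bp)
        & (scan["pos"] <= region.end_bp)
    ]
    cols = [
        "marker", "chrom", "pos", "p_major_t", "p_major_r", "PIC_t", "PIC_r",
        "dPIC", "Fst", "Rsb", "xpEHH",
    ]
    detail = inside[cols].copy()
    detail.insert(0, "serial", region.serial)
    return detail
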