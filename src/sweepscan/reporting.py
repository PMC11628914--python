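"""Result summaries: CSS count tables, Fst distribution summaries, and
known-locus overlap.

The count table mirrors the usual presentation of sweep-scan results — one
row per chromosome, one column per statistic plus a total — stratified by
comparison category.  The Fst summary provides boxplot-ready per-pair
distribution numbers (whiskers at 1.5 x IQR).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sweep_caller import STATISTICS, fst_threshold

#: strata of the count table and the categories each one covers
STRATA: dict[str, tuple[str, ...]] = {
    "all": ("over_time", "region", "state", "market_class"),
    "over_time": ("over_time",),
    "across": ("region", "state", "market_class"),
    "state_level": ("state",),
    "regional_level": ("region",),
    "market_class": ("market_class",),
}


def css_count_table(
    css: pd.DataFrame,
    strata: dict[str, tuple[str, ...]] | None = None,
    chromosomes: list[str] | None = None,
) -> pd.DataFrame:
    """CSS counts per chromosome x statistic within each stratum.

    ``css`` is the consolidated table from :func:`sweep_caller.css_table`.
    Returns long-form rows (stratum, chromosome) with columns Fst, Rsb,
    xpEHH, Total; a final "All" chromosome row per stratum carries the
    column sums.
    """
    if strata is None:
        strata = STRATA
    if chromosomes is None:
        chromosomes = sorted(css["chromosome"].unique()) if len(css) else []
    rows = []
    for stratum, categories in strata.items():
        sub = css[css["category"].isin(categories)] if len(css) else css
        for chrom in [*chromosomes, "All"]:
            at = sub if chrom == "All" else sub[sub["chromosome"] == chrom]
            row = {"stratum": stratum, "chromosome": chrom}
            total = 0
            for stat in STATISTICS:
                k = int((at["statistic"] == stat).sum()) if len(at) else 0
                row[stat] = k
                total += k
            row["Total"] = total
            rows.append(row)
    return pd.DataFrame(rows, columns=["stratum", "chromosome", *STATISTICS, "Total"])


def fst_distribution_summary(scans: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-pair Fst distribution numbers suitable for boxplot rendering.

    Median, mean, 95th percentile (the CSS threshold), quartiles, whisker
    bounds at 1.5 x IQR (clipped to the data), and the count of outliers
    beyond the whiskers.  Missing Fst values are ignored.
    """
    rows = []
    for label, scan in scans.items():
        x = scan["Fst"].to_numpy(dtype=float)
        x = x[~np.isnan(x)]
        q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = x[(x >= lo_fence) & (x <= hi_fence)]
        rows.append(
            {
                "pair_label": label,
                "n": int(x.size),
                "median": float(med),
                "mean": float(np.mean(x)),
                "p95": fst_threshold(x, 0.95),
                "q1": float(q1),
                "q3": float(q3),
                "whisker_low": float(inside.min()),
                "whisker_high": float(inside.max()),
                "n_outliers": int(x.size - inside.size),
            }
        )
    return pd.DataFrame(rows)


def delta_pic_summary(css: pd.DataFrame) -> pd.DataFrame:
    """Diversity-change accounting per statistic.

    A CSS "lost diversity" iff its mean delta-PIC is strictly negative
    (ties count as gained).  Reports counts and mean delta-PIC per statistic
    and overall.
    """
    rows = []
    groups = [("all", css)] + [
        (stat, css[css["statistic"] == stat]) for stat in STATISTICS
    ]
    for name, sub in groups:
        n = len(sub)
        lost = int((sub["delta_pic"] < 0).sum()) if n else 0
        rows.append(
            {
                "statistic": name,
                "n_css": n,
                "n_diversity_lost": lost,
                "n_diversity_gained": n - lost,
                "mean_delta_pic": float(sub["delta_pic"].mean()) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def known_locus_overlap(css: pd.DataFrame, loci: pd.DataFrame) -> pd.DataFrame:
    """Distance of each CSS to each known locus on the same chromosome.

    ``loci`` needs columns (name, chromosome, start_bp) and optionally
    end_bp (defaults to start_bp, a point locus).  Distance is 0 when the
    locus overlaps the CSS span, negative when the locus lies left of the
    span start, positive when right of the span end.
    """
    if loci.empty or css.empty:
        return pd.DataFrame(
            columns=["serial", "locus", "chromosome", "distance_bp", "overlaps"]
        )
    loci = loci.copy()
    if "end_bp" not in loci.columns:
        loci["end_bp"] = loci["start_bp"]
    rows = []
    for _, region in css.iterrows():
        for _, locus in loci[loci["chromosome"] == region["chromosome"]].iterrows():
            if locus["end_bp"] < region["start_bp"]:
                dist = int(locus["end_bp"] - region["start_bp"])
            elif locus["start_bp"] > region["end_bp"]:
                dist = int(locus["start_bp"] - region["end_bp"])
            else:
                dist = 0
            rows.append(
                {
                    "serial": region["serial"],
                    "locus": locus["name"],
                    "chromosome": region["chromosome"],
                    "distance_bp": dist,
                    "overlaps": dist == 0,
                }
            )
    return pd.DataFrame(rows)
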