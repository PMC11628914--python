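"""Extended haplotype homozygosity profiles and cross-population statistics.

EHH at extension marker t is the probability that two distinct haplotypes
drawn (without replacement) from the carriers of a core allele are identical
at every marker of the closed interval [focal, t].  EHHS is the same pair
probability over *all* haplotypes at the site, the focal allele included in
the identity comparison; its "normalized" variant divides by the focal-site
homozygosity so that the curve starts at 1.

Integrating the EHHS decay curve over physical distance gives iES
(unnormalized) and iNES (normalized), summaries of local shared-haplotype
length.  Because sparse marker coverage inflates these areas, any
intermarker gap wider than ``scalegap_bp`` contributes only ``scalegap_bp``
of width, and each side of the curve is truncated at the first marker whose
value falls below ``trunc``.

The cross-population statistics are log-ratios of these areas between a
target and a reference population, standardized genome-wide:

    Rsb   = (ln(iNES_t / iNES_r) - median) / sd
    xpEHH = (ln(iES_t  / iES_r)  - mean)   / sd

Positive values mean longer shared haplotypes — candidate recent selection —
in the target population.  Under neutrality both are close to standard
normal, so |value| > 2 marks the extreme ~5% of markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import HaplotypePanel

DEFAULT_SCALEGAP_BP = 2_500_000
DEFAULT_TRUNC = 0.05


class DegenerateScanError(ValueError):
    """Raised when a log-ratio track has zero spread and cannot be standardized."""


@dataclass(frozen=True)
class EHHProfile:
    """One side of a homozygosity decay curve.

    ``values[0]`` is at the focal marker itself; ``positions_bp`` runs
    outward (decreasing for the left side, increasing for the right).
    """

    focal_index: int
    side: str  # "left" | "right"
    values: np.ndarray
    positions_bp: np.ndarray


def _pair_identity_fraction(labels: np.ndarray) -> float:
    """Fraction of unordered haplotype pairs falling in the same identity class."""
    n = labels.size
    if n < 2:
        return float("nan")
    counts = np.bincount(labels)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _decay_walk(
    H: np.ndarray,
    positions: np.ndarray,
    focal_index: int,
    step: int,
    mask0: np.ndarray,
    stop_below: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Walk outward from the focal marker refining the identity partition.

    ``H`` is the haplotype matrix of one chromosome (n x m, int8, -1
    missing); ``mask0`` selects the haplotypes conditioned on at the focal
    site (all non-missing for EHHS, core-allele carriers for EHH).  The
    partition at each extension groups haplotypes identical over the closed
    interval walked so far; haplotypes hitting a missing call drop out from
    that extension onward.  The walk stops after the first value below
    ``stop_below`` (which is then not reported), at a zero value, or at the
    chromosome end.
    """
    active = np.flatnonzero(mask0)
    labels = np.zeros(active.size, dtype=np.int64)
    values = []
    kept_pos = []
    j = focal_index
    m = H.shape[1]
    while 0 <= j < m:
        col = H[active, j]
        called = col >= 0
        if not called.all():
            active = active[called]
            labels = labels[called]
            col = col[called]
        key = labels * 2 + col
        _, labels = np.unique(key, return_inverse=True)
        v = _pair_identity_fraction(labels)
        if np.isnan(v) or (j != focal_index and v < stop_below):
            break
        values.append(v)
        kept_pos.append(positions[j])
        if v == 0.0:
            break
        j += step
    return np.asarray(values, dtype=float), np.asarray(kept_pos, dtype=np.int64)


def _chromosome_block(panel: HaplotypePanel, focal_index: int):
    """Restrict the panel matrix to the focal marker's chromosome."""
    chrom = panel.map.chromosome[focal_index]
    in_chrom = np.flatnonzero(panel.map.chromosome == chrom)
    H = panel.alleles[:, in_chrom]
    positions = panel.map.position_bp[in_chrom]
    local_focal = int(np.searchsorted(in_chrom, focal_index))
    return H, positions, local_focal


def ehh_profile(
    panel: HaplotypePanel,
    focal_index: int,
    core_allele: int,
    trunc: float = 0.0,
) -> tuple[EHHProfile | None, EHHProfile | None]:
    """Allele-conditioned EHH decay curves (left, right) around a focal marker.

    Requires at least two carriers of ``core_allele``; returns ``(None,
    None)`` otherwise (the statistic is undefined).  With ``trunc`` > 0 each
    side is cut at the first sub-threshold marker, as done in scans.
    """
    H, positions, focal = _chromosome_block(panel, focal_index)
    carriers = H[:, focal] == core_allele
    if carriers.sum() < 2:
        return None, None
    sides = []
    for side, step in (("left", -1), ("right", 1)):
        values, pos = _decay_walk(H, positions, focal, step, carriers, trunc)
        sides.append(EHHProfile(focal_index, side, values, pos))
    return sides[0], sides[1]


def ehhs_profile(
    panel: HaplotypePanel,
    focal_index: int,
    normalized: bool = False,
    trunc: float = 0.0,
) -> tuple[EHHProfile | None, EHHProfile | None]:
    """Site EHHS decay curves (left, right) around a polymorphic focal marker.

    The unnormalized curve starts at the focal-site homozygosity; the
    normalized curve divides through by it and starts at 1.  A monomorphic
    (or <2 haplotype) focal site yields ``(None, None)``.
    """
    H, positions, focal = _chromosome_block(panel, focal_index)
    called = H[:, focal] >= 0
    focal_alleles = H[called, focal]
    if called.sum() < 2 or np.all(focal_alleles == focal_alleles[0]):
        return None, None
    hom_focal = _pair_identity_fraction(
        np.unique(focal_alleles, return_inverse=True)[1]
    )
    stop = trunc * hom_focal if normalized else trunc
    sides = []
    for side, step in (("left", -1), ("right", 1)):
        values, pos = _decay_walk(H, positions, focal, step, called, stop)
        if normalized and hom_focal > 0:
            values = values / hom_focal
        sides.append(EHHProfile(focal_index, side, values, pos))
    return sides[0], sides[1]


def integrate_profile(
    left: EHHProfile,
    right: EHHProfile,
    scalegap_bp: int = DEFAULT_SCALEGAP_BP,
    trunc: float = DEFAULT_TRUNC,
) -> float:
    """Trapezoidal area (bp) under a two-sided decay curve.

    Any intermarker gap wider than ``scalegap_bp`` contributes exactly
    ``scalegap_bp`` of width, so sparse regions cannot inflate the area.
    On each side integration stops at, and excludes, the first marker whose
    value is below ``trunc``.
    """
    if scalegap_bp <= 0:
        raise ValueError("scalegap_bp must be positive")
    if not 0.0 <= trunc < 1.0:
        raise ValueError("trunc must be in [0, 1)")
    area = 0.0
    for prof in (left, right):
        v = prof.values
        p = prof.positions_bp
        if v.size == 0 or v[0] < trunc:
            continue
        for i in range(1, v.size):
            if v[i] < trunc:
                break
            width = min(abs(int(p[i]) - int(p[i - 1])), scalegap_bp)
            area += 0.5 * (v[i] + v[i - 1]) * width
    return area


def scan_hh(
    panel: HaplotypePanel,
    scalegap_bp: int = DEFAULT_SCALEGAP_BP,
    trunc: float = DEFAULT_TRUNC,
) -> pd.DataFrame:
    """Per-marker integrated EHHS areas for one population.

    Returns a DataFrame (marker, chrom, pos, freq_minor, iES, iNES) in map
    order.  iES integrates the unnormalized EHHS curve, iNES the
    focal-homozygosity-normalized curve.  Markers monomorphic within the
    panel (or with fewer than two called haplotypes) carry NaN areas — the
    haplotype statistics are undefined once an allele is fixed.
    """
    n_markers = panel.n_markers
    ies = np.full(n_markers, np.nan)
    ines = np.full(n_markers, np.nan)
    chrom_arr = panel.map.chromosome
    pos_arr = panel.map.position_bp
    for chrom in panel.map.chromosomes:
        in_chrom = np.flatnonzero(chrom_arr == chrom)
        H = panel.alleles[:, in_chrom]
        positions = pos_arr[in_chrom]
        for local, global_idx in enumerate(in_chrom):
            col = H[:, local]
            called = col >= 0
            alleles = col[called]
            if alleles.size < 2 or np.all(alleles == alleles[0]):
                continue
            hom_focal = _pair_identity_fraction(
                np.unique(alleles, return_inverse=True)[1]
            )
            # normalized curve = unnormalized / hom_focal, so walking until
            # the unnormalized value < trunc * hom_focal covers both curves
            sides = []
            for step in (-1, 1):
                sides.append(
                    _decay_walk(H, positions, local, step, called, trunc * hom_focal)
                )
            (lv, lp), (rv, rp) = sides
            left_u = EHHProfile(global_idx, "left", lv, lp)
            right_u = EHHProfile(global_idx, "right", rv, rp)
            ies[global_idx] = integrate_profile(left_u, right_u, scalegap_bp, trunc)
            left_n = EHHProfile(global_idx, "left", lv / hom_focal, lp)
            right_n = EHHProfile(global_idx, "right", rv / hom_focal, rp)
            ines[global_idx] = integrate_profile(left_n, right_n, scalegap_bp, trunc)
    return pd.DataFrame(
        {
            "marker": panel.map.marker_id,
            "chrom": chrom_arr,
            "pos": pos_arr,
            "freq_minor": panel.minor_allele_freq(),
            "iES": ies,
            "iNES": ines,
        }
    )


def _log_ratio_stat(
    scan_target: pd.DataFrame,
    scan_ref: pd.DataFrame,
    column: str,
    center: str,
) -> pd.DataFrame:
    if not np.array_equal(
        scan_target["marker"].to_numpy(), scan_ref["marker"].to_numpy()
    ):
        raise ValueError("target and reference scans must share the marker set")
    a = scan_target[column].to_numpy(dtype=float)
    b = scan_ref[column].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where((a > 0) & (b > 0), np.log(a / b), np.nan)
    ok = ~np.isnan(raw)
    if ok.sum() < 2:
        raise DegenerateScanError("fewer than two markers with defined log-ratios")
    sd = float(np.std(raw[ok], ddof=1))
    if sd == 0.0:
        raise DegenerateScanError("log-ratio track has zero standard deviation")
    loc = float(np.median(raw[ok])) if center == "median" else float(np.mean(raw[ok]))
    standardized = (raw - loc) / sd
    return pd.DataFrame(
        {
            "marker": scan_target["marker"].to_numpy(),
            "raw_log_ratio": raw,
            "standardized": standardized,
        }
    )


def rsb(scan_target: pd.DataFrame, scan_ref: pd.DataFrame) -> pd.DataFrame:
    """Median-standardized log-ratio of iNES (target over reference)."""
    return _log_ratio_stat(scan_target, scan_ref, "iNES", "median")


def xpehh(scan_target: pd.DataFrame, scan_ref: pd.DataFrame) -> pd.DataFrame:
    """Mean-standardized log-ratio of iES (target over reference)."""
    return _log_ratio_stat(scan_target, scan_ref, "iES", "mean")


def null_diagnostic(standardized, min_values: int = 100) -> dict:
    """Compare a standardized statistic track with the standard-normal null.

    Returns mean, sd (ddof=1), the fraction of markers with |value| > 2, and
    the maximum absolute difference between the empirical CDF of the values
    falling in [-2, 2] and the CDF of a standard normal truncated to that
    interval.  Under neutrality the fraction should sit near 2 * Phi(-2) =
    4.55% and the discrepancy should be small.
    """
    x = np.asarray(standardized, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < min_values:
        raise ValueError(f"need >= {min_values} non-missing values, got {x.size}")
    sd = float(np.std(x, ddof=1))
    out = {
        "n": int(x.size),
        "mean": float(np.mean(x)),
        "sd": sd,
        "frac_beyond_2": float(np.mean(np.abs(x) > 2.0)),
        "degenerate": sd == 0.0,
    }
    inner = np.sort(x[(x >= -2.0) & (x <= 2.0)])
    if inner.size and not out["degenerate"]:
        lo, hi = stats.norm.cdf(-2.0), stats.norm.cdf(2.0)
        trunc_cdf = (stats.norm.cdf(inner) - lo) / (hi - lo)
        ecdf_hi = np.arange(1, inner.size + 1) / inner.size
        ecdf_lo = np.arange(0, inner.size) / inner.size
        out["normal_discrepancy"] = float(
            max(np.max(np.abs(ecdf_hi - trunc_cdf)), np.max(np.abs(trunc_cdf - ecdf_lo)))
        )
    else:
        out["normal_discrepancy"] = float("nan")
    return out
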