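"""Per-marker differentiation (Weir–Cockerham Fst) and diversity (PIC).

Inbred lines are treated as homozygous diploids: each variety contributes two
identical allele copies and an observed heterozygote proportion of zero.  The
Weir–Cockerham variance-component formulas keep their heterozygosity terms so
genuinely heterozygous calls remain supported on real array data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import HaplotypePanel


@dataclass(frozen=True)
class FstComponents:
    """Two-population Weir–Cockerham intermediates and variance components.

    ``fst = a / (a + b + c)``; NaN when the locus is monomorphic across both
    samples (a + b + c = 0).  ``a`` is the among-population component, ``b``
    among individuals within populations, ``c`` within individuals.
    """

    n1: int
    n2: int
    p1: float
    p2: float
    h1: float
    h2: float
    n_bar: float
    n_c: float
    p_bar: float
    s2: float
    h_bar: float
    a: float
    b: float
    c: float
    fst: float


def pic(freqs) -> float:
    """Polymorphic information content / gene diversity, 1 - sum(p_i^2).

    ``freqs`` is the full allele-frequency vector of the locus (it must sum
    to 1).  For a biallelic SNP the maximum is 0.5 at p = 0.5.
    """
    p = np.asarray(freqs, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("allele frequencies must sum to 1")
    return float(1.0 - np.sum(p**2))


def wc_fst(
    n1: int, p1: float, n2: int, p2: float, h1: float = 0.0, h2: float = 0.0
) -> FstComponents:
    """Weir–Cockerham theta for one biallelic locus and two populations.

    Parameters are per-population sample sizes (individuals), frequencies of
    one chosen allele, and observed heterozygote proportions.  With r = 2:

        n_bar = (n1 + n2) / 2
        n_c   = 2 n_bar - (n1^2 + n2^2) / (2 n_bar)
        p_bar = (n1 p1 + n2 p2) / (2 n_bar)
        s^2   = sum_i n_i (p_i - p_bar)^2 / n_bar          (r - 1 = 1)
        h_bar = (n1 h1 + n2 h2) / (2 n_bar)
        a = (n_bar / n_c) [s^2 - (p_bar(1-p_bar) - s^2/2 - h_bar/4)/(n_bar-1)]
        b = (n_bar/(n_bar-1)) [p_bar(1-p_bar) - s^2/2 - h_bar(2 n_bar - 1)/(4 n_bar)]
        c = h_bar / 2

    Negative estimates are reported as computed, never clamped.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    n_bar = (n1 + n2) / 2.0
    n_c = 2.0 * n_bar - (n1**2 + n2**2) / (2.0 * n_bar)
    p_bar = (n1 * p1 + n2 * p2) / (2.0 * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / n_bar
    h_bar = (n1 * h1 + n2 * h2) / (2.0 * n_bar)

    inner = p_bar * (1.0 - p_bar) - s2 / 2.0 - h_bar / 4.0
    a = (n_bar / n_c) * (s2 - inner / (n_bar - 1.0))
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1.0 - p_bar) - s2 / 2.0 - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
    )
    c = h_bar / 2.0
    denom = a + b + c
    fst = a / denom if denom != 0.0 else float("nan")
    return FstComponents(
        n1=n1, n2=n2, p1=p1, p2=p2, h1=h1, h2=h2,
        n_bar=n_bar, n_c=n_c, p_bar=p_bar, s2=s2, h_bar=h_bar,
        a=a, b=b, c=c, fst=fst,
    )


def wc_fst_track(panel_t: HaplotypePanel, panel_r: HaplotypePanel) -> np.ndarray:
    """Vectorized per-marker Weir–Cockerham Fst for two inbred panels.

    Uses non-missing calls per marker; heterozygote proportions are zero
    (inbred contract).  Returns NaN at markers monomorphic in both panels or
    with an empty sample.
    """
    out = np.full(panel_t.n_markers, np.nan)
    a_t, a_r = panel_t.alleles, panel_r.alleles
    n1 = (a_t >= 0).sum(axis=0).astype(float)
    n2 = (a_r >= 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(n1 > 0, (a_t == 1).sum(axis=0) / n1, np.nan)
        p2 = np.where(n2 > 0, (a_r == 1).sum(axis=0) / n2, np.nan)
        n_bar = (n1 + n2) / 2.0
        n_c = 2.0 * n_bar - (n1**2 + n2**2) / (2.0 * n_bar)
        p_bar = (n1 * p1 + n2 * p2) / (2.0 * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / n_bar
        inner = p_bar * (1.0 - p_bar) - s2 / 2.0
        a = (n_bar / n_c) * (s2 - inner / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * inner
        denom = a + b
        out = np.where(denom != 0.0, a / denom, np.nan)
    out[(n1 < 1) | (n2 < 1)] = np.nan
    return out


def pair_marker_stats(
    panel_t: HaplotypePanel, panel_r: HaplotypePanel
) -> pd.DataFrame:
    """Per-marker frequencies, PIC, delta-PIC and Fst for a population pair.

    Both panels must share the marker set (same map).  delta-PIC is
    PIC(target) - PIC(reference); it is negative where the target lost
    diversity, as under a sweep.
    """
    if not np.array_equal(panel_t.map.marker_id, panel_r.map.marker_id):
        raise ValueError("panels must share a common marker set")
    f1_t = panel_t.freq_code1()
    f1_r = panel_r.freq_code1()
    p_major_t = np.maximum(f1_t, 1.0 - f1_t)
    p_major_r = np.maximum(f1_r, 1.0 - f1_r)
    pic_t = 1.0 - f1_t**2 - (1.0 - f1_t) ** 2
    pic_r = 1.0 - f1_r**2 - (1.0 - f1_r) ** 2
    return pd.DataFrame(
        {
            "marker": panel_t.map.marker_id,
            "chrom": panel_t.map.chromosome,
            "pos": panel_t.map.position_bp,
            "p_major_t": p_major_t,
            "p_major_r": p_major_r,
            "PIC_t": pic_t,
            "PIC_r": pic_r,
            "dPIC": pic_t - pic_r,
            "Fst": wc_fst_track(panel_t, panel_r),
        }
    )
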