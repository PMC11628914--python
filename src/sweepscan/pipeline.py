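"""End-to-end glue: from a haplotype panel and a population pair to a
ScanTable, and from ScanTables to called candidate regions."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fst_diversity import pair_marker_stats
from .genotype_io import SCAN_COLUMNS, HaplotypePanel
from .haplotype_stats import (
    DEFAULT_SCALEGAP_BP,
    DEFAULT_TRUNC,
    rsb,
    scan_hh,
    xpehh,
)
from .population_builder import PopulationPair


def scan_pair_panels(
    panel_t: HaplotypePanel,
    panel_r: HaplotypePanel,
    scalegap_bp: int = DEFAULT_SCALEGAP_BP,
    trunc: float = DEFAULT_TRUNC,
) -> pd.DataFrame:
    """Full per-marker ScanTable for a target/reference panel pair.

    Columns: marker, chrom, pos, major-allele frequencies, PIC and
    delta-PIC, Weir–Cockerham Fst, integrated EHHS areas for both
    populations, and the standardized Rsb and xpEHH tracks.
    """
    stats = pair_marker_stats(panel_t, panel_r)
    hh_t = scan_hh(panel_t, scalegap_bp, trunc)
    hh_r = scan_hh(panel_r, scalegap_bp, trunc)
    table = stats.assign(
        iES_t=hh_t["iES"].to_numpy(),
        iES_r=hh_r["iES"].to_numpy(),
        iNES_t=hh_t["iNES"].to_numpy(),
        iNES_r=hh_r["iNES"].to_numpy(),
        Rsb=rsb(hh_t, hh_r)["standardized"].to_numpy(),
        xpEHH=xpehh(hh_t, hh_r)["standardized"].to_numpy(),
    )
    return table[SCAN_COLUMNS]


def scan_pair(
    pair: PopulationPair,
    panel: HaplotypePanel,
    scalegap_bp: int = DEFAULT_SCALEGAP_BP,
    trunc: float = DEFAULT_TRUNC,
) -> pd.DataFrame:
    """ScanTable for one labelled pair drawn from a combined panel."""
    panel_t = panel.take_varieties(pair.target_ids)
    panel_r = panel.take_varieties(pair.reference_ids)
    return scan_pair_panels(panel_t, panel_r, scalegap_bp, trunc)
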