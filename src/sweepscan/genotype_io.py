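"""Input/output and panel-level filters for inbred SNP haplotype data.

The in-memory containers are deliberately thin: a :class:`MarkerMap` wraps an
ordered per-chromosome coordinate table, and a :class:`HaplotypePanel` holds a
varieties x markers matrix of 0/1 allele codes (0 = global major allele,
1 = global minor allele, -1 = missing).  Inbred lines carry one haplotype
each, so no phasing information is needed.

File formats follow field conventions: haplotype tables are delimited text
with one row per variety and one column per marker; marker maps are
PLINK-MAP-like TSV (chromosome, marker id, bp position); variety metadata is
CSV; state adjacency is a JSON object mapping each state to its bordering
states.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

#: tokens treated as a missing call in haplotype tables
NA_TOKENS = {"NA", "N", "", "NaN", "nan", "-", "."}

REGIONS = ("Eastern", "GreatPlains", "Northern", "Pacific", "PacificNorthwest")
MARKET_CLASSES = ("HRS", "HRW", "HWS", "HWW", "SRW", "SWS", "SWW", "unknown")
HABITS = ("spring", "winter")

#: ScanTable column order used by write_scan_table / load_scan_table
SCAN_COLUMNS = [
    "marker",
    "chrom",
    "pos",
    "p_major_t",
    "p_major_r",
    "PIC_t",
    "PIC_r",
    "dPIC",
    "Fst",
    "iES_t",
    "iES_r",
    "iNES_t",
    "iNES_r",
    "Rsb",
    "xpEHH",
]


class GenotypeIOError(ValueError):
    """Malformed genotype, map, or metadata input."""


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker coordinates, 1-based bp, grouped by chromosome.

    Markers are stored sorted by (chromosome, position).  Positions must be
    strictly increasing within a chromosome (deduplicate first with
    :func:`dedupe_positions`) and marker ids unique.
    """

    marker_id: np.ndarray  # str array
    chromosome: np.ndarray  # str array
    position_bp: np.ndarray  # int64, 1-based

    def __post_init__(self) -> None:
        mid = np.asarray(self.marker_id, dtype=object)
        chrom = np.asarray(self.chromosome, dtype=object)
        pos = np.asarray(self.position_bp, dtype=np.int64)
        if not (len(mid) == len(chrom) == len(pos)):
            raise GenotypeIOError("marker map columns have unequal lengths")
        order = np.lexsort((pos, chrom))
        if not np.array_equal(order, np.arange(len(pos))):
            mid, chrom, pos = mid[order], chrom[order], pos[order]
        object.__setattr__(self, "marker_id", mid)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position_bp", pos)
        if len(set(mid)) != len(mid):
            raise GenotypeIOError("duplicate marker ids in map")
        for c in pd.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise GenotypeIOError(
                    f"positions not strictly increasing on chromosome {c}; "
                    "run dedupe_positions first"
                )

    def __len__(self) -> int:
        return len(self.marker_id)

    @property
    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.chromosome))

    def subset(self, keep: np.ndarray) -> "MarkerMap":
        """Positional boolean/index subset preserving order."""
        return MarkerMap(
            self.marker_id[keep], self.chromosome[keep], self.position_bp[keep]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chromosome,
                "marker_id": self.marker_id,
                "position_bp": self.position_bp,
            }
        )


@dataclass
class HaplotypePanel:
    """Varieties x markers allele matrix for one population of inbred lines.

    ``alleles[i, j]`` is 0 (major), 1 (minor) or -1 (missing) for variety
    ``variety_ids[i]`` at marker ``map.marker_id[j]``.  Column order matches
    the map order.
    """

    variety_ids: list[str]
    alleles: np.ndarray  # int8, shape (n_varieties, n_markers)
    map: MarkerMap
    rejected_markers: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise GenotypeIOError("allele matrix must be 2-D")
        if self.alleles.shape != (len(self.variety_ids), len(self.map)):
            raise GenotypeIOError(
                f"allele matrix shape {self.alleles.shape} does not match "
                f"{len(self.variety_ids)} varieties x {len(self.map)} markers"
            )

    @property
    def n_varieties(self) -> int:
        return len(self.variety_ids)

    @property
    def n_markers(self) -> int:
        return len(self.map)

    def minor_allele_freq(self) -> np.ndarray:
        """Per-marker minor-allele frequency over non-missing calls.

        The "minor" allele here is the panel's code-1 allele; the returned
        value is min(freq1, 1 - freq1) so it is a true MAF even if code 1
        drifted to majority within this subpopulation.
        """
        a = self.alleles
        called = a >= 0
        n_called = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            f1 = np.where(n_called > 0, (a == 1).sum(axis=0) / n_called, np.nan)
        return np.minimum(f1, 1.0 - f1)

    def freq_code1(self) -> np.ndarray:
        """Per-marker frequency of the code-1 (global minor) allele."""
        a = self.alleles
        called = a >= 0
        n_called = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_called > 0, (a == 1).sum(axis=0) / n_called, np.nan)

    def take_varieties(self, ids: Iterable[str]) -> "HaplotypePanel":
        """Subset rows to the given variety ids (in the given order)."""
        index = {v: i for i, v in enumerate(self.variety_ids)}
        missing = [v for v in ids if v not in index]
        if missing:
            raise GenotypeIOError(f"varieties not in panel: {missing[:5]}")
        rows = [index[v] for v in ids]
        return HaplotypePanel(list(ids), self.alleles[rows], self.map)

    def subset_markers(self, keep: np.ndarray) -> "HaplotypePanel":
        return HaplotypePanel(
            list(self.variety_ids), self.alleles[:, keep], self.map.subset(keep)
        )


# ---------------------------------------------------------------------------
# loading


def load_marker_map(path: str | Path, sep: str = "\t") -> MarkerMap:
    """Read a PLINK-MAP-like table (chromosome, marker_id, position_bp)."""
    df = pd.read_csv(path, sep=sep, dtype={0: str, 1: str})
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    required = {"chromosome", "marker_id", "position_bp"}
    if not required.issubset(cols):
        # headerless PLINK-style: chrom, id, pos in first three columns
        df = pd.read_csv(path, sep=sep, header=None, dtype={0: str, 1: str})
        df = df.iloc[:, :3]
        df.columns = ["chromosome", "marker_id", "position_bp"]
    return MarkerMap(
        df["marker_id"].to_numpy(dtype=object),
        df["chromosome"].to_numpy(dtype=object),
        df["position_bp"].to_numpy(dtype=np.int64),
    )


def _sniff_sep(path: str | Path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def load_haplotypes(path: str | Path, marker_map: MarkerMap) -> HaplotypePanel:
    """Read a haplotype table and recode alleles to global major/minor.

    The table has a variety-id column (first column, any name) and one column
    per marker with values in {A, C, G, T, 0, 1} plus missing tokens.  Per
    marker the most frequent non-missing allele over the whole table becomes
    code 0 (ties broken by symbol sort, so the lexicographically smaller
    allele is major).  Markers absent from ``marker_map`` are dropped with a
    warning; markers with more than two distinct non-missing alleles are
    rejected and recorded in ``panel.rejected_markers``.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    variety_ids = df.iloc[:, 0].astype(str).tolist()
    table_markers = list(df.columns[1:])

    in_map = set(marker_map.marker_id)
    dropped = [m for m in table_markers if m not in in_map]
    if dropped:
        warnings.warn(
            f"{len(dropped)} marker column(s) absent from map dropped "
            f"(e.g. {dropped[:3]})",
            stacklevel=2,
        )
    absent = [m for m in marker_map.marker_id if m not in set(table_markers)]
    if absent:
        raise GenotypeIOError(
            f"map markers missing from haplotype table: {absent[:5]}"
        )

    rejected: list[dict] = []
    cols: dict[str, np.ndarray] = {}
    for m in marker_map.marker_id:
        raw = df[m].astype(str).str.strip().to_numpy(dtype=object)
        is_na = np.isin(raw, list(NA_TOKENS)) | pd.isna(df[m]).to_numpy()
        observed = raw[~is_na]
        symbols, counts = np.unique(observed, return_counts=True)
        if len(symbols) > 2:
            rejected.append(
                {"marker_id": m, "alleles": sorted(symbols.tolist()),
                 "reason": "more than two alleles"}
            )
            continue
        col = np.full(len(raw), MISSING, dtype=np.int8)
        if len(symbols) > 0:
            # major = most frequent; tie -> lexicographically smaller symbol
            order = np.lexsort((symbols, -counts))
            major = symbols[order[0]]
            col[~is_na] = (observed != major).astype(np.int8)
        cols[m] = col

    keep = np.array([m in cols for m in marker_map.marker_id], dtype=bool)
    sub_map = marker_map.subset(keep)
    if len(sub_map):
        alleles = np.column_stack([cols[m] for m in sub_map.marker_id])
    else:
        alleles = np.empty((len(variety_ids), 0), dtype=np.int8)
    return HaplotypePanel(variety_ids, alleles, sub_map, rejected_markers=rejected)


def write_haplotypes(panel: HaplotypePanel, path: str | Path, sep: str = "\t") -> None:
    """Write the 0/1 coded haplotype table (missing as NA)."""
    df = pd.DataFrame(
        panel.alleles, index=pd.Index(panel.variety_ids, name="variety_id"),
        columns=panel.map.marker_id,
    ).astype(object)
    df = df.where(df != -1, "NA")
    df.to_csv(path, sep=sep)


def load_metadata(
    path: str | Path,
    state_region: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read variety metadata CSV and check region/state consistency.

    Expected columns: variety_id, accession, year, state, region,
    market_class, habit.  When ``state_region`` is given (or the packaged
    default is used), each row's region must match its state's region.
    """
    df = pd.read_csv(path, dtype={"variety_id": str, "accession": str, "state": str})
    required = {"variety_id", "accession", "year", "state", "region",
                "market_class", "habit"}
    missing = required - set(df.columns)
    if missing:
        raise GenotypeIOError(f"metadata missing columns: {sorted(missing)}")
    validate_metadata(df, state_region)
    return df


def validate_metadata(df: pd.DataFrame, state_region: dict[str, str] | None = None) -> None:
    bad_region = set(df["region"]) - set(REGIONS)
    if bad_region:
        raise GenotypeIOError(f"unknown regions: {sorted(bad_region)}")
    bad_class = set(df["market_class"]) - set(MARKET_CLASSES)
    if bad_class:
        raise GenotypeIOError(f"unknown market classes: {sorted(bad_class)}")
    bad_habit = set(df["habit"]) - set(HABITS)
    if bad_habit:
        raise GenotypeIOError(f"unknown habits: {sorted(bad_habit)}")
    if df["variety_id"].duplicated().any():
        raise GenotypeIOError("duplicate variety ids in metadata")
    if state_region is not None:
        mapped = df["state"].map(state_region)
        mismatch = df[mapped.notna() & (mapped != df["region"])]
        if len(mismatch):
            rows = mismatch[["variety_id", "state", "region"]].head()
            raise GenotypeIOError(
                f"region inconsistent with state->region table:\n{rows}"
            )


def load_adjacency(path: str | Path) -> dict[str, list[str]]:
    """Read a state-adjacency JSON map and check symmetry."""
    with open(path) as fh:
        adj = json.load(fh)
    check_adjacency_symmetric(adj)
    return adj


def check_adjacency_symmetric(adj: dict[str, list[str]]) -> None:
    for s, neighbors in adj.items():
        for t in neighbors:
            if t not in adj:
                raise GenotypeIOError(f"adjacency lists unknown state {t!r}")
            if s not in adj[t]:
                raise GenotypeIOError(f"adjacency not symmetric: {s}->{t}")


def default_geography() -> tuple[dict[str, str], dict[str, list[str]]]:
    """Packaged default (state -> region, state adjacency) maps."""
    text = (
        resources.files("sweepscan.data")
        .joinpath("us_wheat_geography.json")
        .read_text()
    )
    data = json.loads(text)
    check_adjacency_symmetric(data["adjacency"])
    return data["state_region"], data["adjacency"]


# ---------------------------------------------------------------------------
# panel-level filters


def filter_maf(panel: HaplotypePanel, min_maf: float) -> HaplotypePanel:
    """Keep markers with minor-allele frequency >= ``min_maf`` (inclusive)."""
    if not 0.0 <= min_maf <= 0.5:
        raise GenotypeIOError("min_maf must be in [0, 0.5]")
    if min_maf == 0:
        return panel.subset_markers(np.ones(panel.n_markers, dtype=bool))
    maf = panel.minor_allele_freq()
    # NaN (all-missing marker) fails the comparison and is dropped
    keep = np.nan_to_num(maf, nan=-1.0) >= min_maf
    return panel.subset_markers(keep)


def dedupe_positions(
    marker_map: MarkerMap, panel: HaplotypePanel | None = None
) -> tuple[MarkerMap, HaplotypePanel | None]:
    """Resolve duplicated (chromosome, position) pairs.

    For each duplicated position the first marker by marker-id sort is kept,
    the rest removed.  Accepts a map whose positions may repeat, hence builds
    from raw arrays rather than a validated MarkerMap.
    """
    df = pd.DataFrame(
        {
            "marker_id": marker_map.marker_id,
            "chromosome": marker_map.chromosome,
            "position_bp": marker_map.position_bp,
            "idx": np.arange(len(marker_map)),
        }
    )
    winners = (
        df.sort_values(["chromosome", "position_bp", "marker_id"])
        .groupby(["chromosome", "position_bp"], sort=True)
        .head(1)
    )
    keep = np.zeros(len(df), dtype=bool)
    keep[winners["idx"].to_numpy()] = True
    new_map = marker_map.subset(keep)
    if panel is None:
        return new_map, None
    return new_map, panel.subset_markers(keep)


def build_unvalidated_map(
    marker_id: Iterable[str], chromosome: Iterable[str], position_bp: Iterable[int]
) -> MarkerMap:
    """Construct a MarkerMap allowing duplicate positions (for dedupe input).

    Bypasses the strict-increase invariant by deduplicating immediately.
    """
    df = pd.DataFrame(
        {
            "marker_id": list(marker_id),
            "chromosome": list(chromosome),
            "position_bp": list(position_bp),
        }
    ).sort_values(["chromosome", "position_bp", "marker_id"])
    winners = df.groupby(["chromosome", "position_bp"]).head(1)
    return MarkerMap(
        winners["marker_id"].to_numpy(dtype=object),
        winners["chromosome"].to_numpy(dtype=object),
        winners["position_bp"].to_numpy(dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# scan tables


def write_scan_table(scan: pd.DataFrame, path: str | Path) -> None:
    """Write a per-marker ScanTable as TSV, missing values as NA."""
    missing = [c for c in SCAN_COLUMNS if c not in scan.columns]
    if missing:
        raise GenotypeIOError(f"scan table missing columns: {missing}")
    scan[SCAN_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def load_scan_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", na_values=["NA"], dtype={"marker": str, "chrom": str}
    )
    return df[SCAN_COLUMNS]


def write_marker_map(marker_map: MarkerMap, path: str | Path, sep: str = "\t") -> None:
    marker_map.to_frame().to_csv(path, sep=sep, index=False)
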