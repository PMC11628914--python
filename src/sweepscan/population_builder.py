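"""Construction of target/reference population pairs from variety metadata.

Four comparison categories are built:

* ``over_time`` — a population (the whole panel, a habit, a region, a
  region x habit, or a market class) is sorted by release year (ties broken
  by accession) and split into an older reference half and a newer target
  half.
* ``region`` — a region's varieties against all varieties of the other
  regions, within a habit scope.
* ``state`` — a state's varieties against varieties from other states,
  excluding the whole of the target state's region and every state sharing
  a border with the target state.
* ``market_class`` — one market class against all other known classes.

A pair is only emitted when both of its populations contain at least 20
varieties (``MIN_POP_SIZE``): smaller samples make the haplotype statistics
unstable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .genotype_io import MARKET_CLASSES, REGIONS, check_adjacency_symmetric

MIN_POP_SIZE = 20


class Category(str, Enum):
    over_time = "over_time"
    region = "region"
    state = "state"
    market_class = "market_class"


#: deterministic category ordering for serial-number stability
CATEGORY_ORDER = [
    Category.over_time,
    Category.region,
    Category.state,
    Category.market_class,
]

HABIT_SCOPES = ("both", "spring", "winter")
_HABIT_LETTER = {"both": "b", "spring": "s", "winter": "w"}


@dataclass(frozen=True)
class PopulationPair:
    """A labelled target/reference comparison.

    ``target_ids`` and ``reference_ids`` are disjoint tuples of variety ids,
    each of size >= ``MIN_POP_SIZE``.  For over-time pairs the reference is
    the older half and the target the newer half, following the convention
    that selection is assessed in the newer material.
    """

    label: str
    category: Category
    habit_scope: str
    target_ids: tuple[str, ...]
    reference_ids: tuple[str, ...]
    target_label: str = ""
    reference_label: str = ""

    def __post_init__(self) -> None:
        if set(self.target_ids) & set(self.reference_ids):
            raise ValueError(f"pair {self.label}: target and reference overlap")
        if len(self.target_ids) < MIN_POP_SIZE or len(self.reference_ids) < MIN_POP_SIZE:
            raise ValueError(
                f"pair {self.label}: both populations must have >= {MIN_POP_SIZE}"
            )


def _scope(meta: pd.DataFrame, habit_scope: str) -> pd.DataFrame:
    if habit_scope == "both":
        return meta
    return meta[meta["habit"] == habit_scope]


def split_over_time(
    members: pd.DataFrame, group_label: str, habit_scope: str = "both"
) -> PopulationPair | None:
    """Split a population into older (reference) and newer (target) halves.

    Members are ordered by (year ascending, accession ascending); the first
    floor(n/2) form the older half (label suffix 1) and the remainder the
    newer half (suffix 2), so an odd member goes to the newer half.  Returns
    None when either half is under the minimum size.
    """
    ordered = members.sort_values(
        ["year", "accession"], kind="mergesort"
    )["variety_id"].tolist()
    half = len(ordered) // 2
    older, newer = ordered[:half], ordered[half:]
    if len(older) < MIN_POP_SIZE or len(newer) < MIN_POP_SIZE:
        return None
    return PopulationPair(
        label=f"time:{_HABIT_LETTER[habit_scope]}:{group_label}",
        category=Category.over_time,
        habit_scope=habit_scope,
        target_ids=tuple(newer),
        reference_ids=tuple(older),
        target_label=f"{group_label}2",
        reference_label=f"{group_label}1",
    )


def build_over_time_pairs(meta: pd.DataFrame) -> list[PopulationPair]:
    """Over-time pairs for panel, habit, region(xhabit), and class groupings.

    Market-class populations exclude varieties of unknown class; the panel,
    habit, and regional populations include them.
    """
    pairs: list[PopulationPair] = []

    def try_add(members: pd.DataFrame, group_label: str, habit_scope: str) -> None:
        pair = split_over_time(members, group_label, habit_scope)
        if pair is not None:
            pairs.append(pair)

    try_add(meta, "all", "both")
    for habit in ("spring", "winter"):
        try_add(meta[meta["habit"] == habit], habit[:3], habit)
    for region in REGIONS:
        in_region = meta[meta["region"] == region]
        try_add(in_region, region, "both")
        for habit in ("spring", "winter"):
            try_add(in_region[in_region["habit"] == habit], region, habit)
    for mclass in MARKET_CLASSES:
        if mclass == "unknown":
            continue
        try_add(meta[meta["market_class"] == mclass], mclass, "both")
    return pairs


def build_region_pairs(meta: pd.DataFrame, habit_scope: str) -> list[PopulationPair]:
    """One pair per region: the region's varieties vs all other regions'."""
    scoped = _scope(meta, habit_scope)
    pairs = []
    for region in REGIONS:
        target = scoped[scoped["region"] == region]["variety_id"]
        reference = scoped[scoped["region"] != region]["variety_id"]
        if len(target) < MIN_POP_SIZE or len(reference) < MIN_POP_SIZE:
            continue
        pairs.append(
            PopulationPair(
                label=f"region:{_HABIT_LETTER[habit_scope]}:{region}",
                category=Category.region,
                habit_scope=habit_scope,
                target_ids=tuple(target),
                reference_ids=tuple(reference),
                target_label=region,
                reference_label="others",
            )
        )
    return pairs


def build_state_pairs(
    meta: pd.DataFrame,
    adjacency: dict[str, list[str]],
    region_table: dict[str, str],
    habit_scope: str,
) -> list[PopulationPair]:
    """One pair per state, excluding co-regional and bordering states.

    The reference holds varieties from states that are (a) not the target
    state, (b) not in the target state's region, and (c) not adjacent to the
    target state.  States present in the metadata must appear in both the
    adjacency map and the region table.
    """
    check_adjacency_symmetric(adjacency)
    scoped = _scope(meta, habit_scope)
    pairs = []
    for state in sorted(scoped["state"].unique()):
        if state not in adjacency:
            raise KeyError(f"state {state!r} missing from adjacency map")
        if state not in region_table:
            raise KeyError(f"state {state!r} missing from state->region table")
        target = scoped[scoped["state"] == state]["variety_id"]
        if len(target) < MIN_POP_SIZE:
            continue
        target_region = region_table[state]
        excluded = {state} | set(adjacency[state]) | {
            s for s, r in region_table.items() if r == target_region
        }
        reference = scoped[~scoped["state"].isin(excluded)]["variety_id"]
        if len(reference) < MIN_POP_SIZE:
            continue
        pairs.append(
            PopulationPair(
                label=f"state:{_HABIT_LETTER[habit_scope]}:{state}",
                category=Category.state,
                habit_scope=habit_scope,
                target_ids=tuple(target),
                reference_ids=tuple(reference),
                target_label=state,
                reference_label="others",
            )
        )
    return pairs


def build_market_class_pairs(meta: pd.DataFrame) -> list[PopulationPair]:
    """One pair per known market class vs all other known classes."""
    known = meta[meta["market_class"] != "unknown"]
    pairs = []
    for mclass in MARKET_CLASSES:
        if mclass == "unknown":
            continue
        target = known[known["market_class"] == mclass]["variety_id"]
        reference = known[known["market_class"] != mclass]["variety_id"]
        if len(target) < MIN_POP_SIZE or len(reference) < MIN_POP_SIZE:
            continue
        pairs.append(
            PopulationPair(
                label=f"class:{mclass}",
                category=Category.market_class,
                habit_scope="both",
                target_ids=tuple(target),
                reference_ids=tuple(reference),
                target_label=mclass,
                reference_label="others",
            )
        )
    return pairs


def enumerate_pairs(
    meta: pd.DataFrame,
    adjacency: dict[str, list[str]],
    region_table: dict[str, str],
) -> list[PopulationPair]:
    """All population pairs in deterministic order.

    Over-time pairs come first, then across-population pairs (regional,
    state, market class); within each category pairs are sorted by label.
    The ordering fixes the candidate-sweep serial numbers downstream.
    """
    if meta.empty:
        return []
    pairs: list[PopulationPair] = []
    pairs += sorted(build_over_time_pairs(meta), key=lambda p: p.label)
    across: list[PopulationPair] = []
    for habit_scope in HABIT_SCOPES:
        across += build_region_pairs(meta, habit_scope)
    region_pairs = sorted(
        (p for p in across if p.category == Category.region), key=lambda p: p.label
    )
    state_pairs: list[PopulationPair] = []
    for habit_scope in HABIT_SCOPES:
        state_pairs += build_state_pairs(meta, adjacency, region_table, habit_scope)
    state_pairs.sort(key=lambda p: p.label)
    class_pairs = sorted(build_market_class_pairs(meta), key=lambda p: p.label)
    return pairs + region_pairs + state_pairs + class_pairs


def pair_manifest(pairs: list[PopulationPair]) -> pd.DataFrame:
    """Tabular summary of a pair list (for the ``pairs`` CLI subcommand)."""
    import json

    return pd.DataFrame(
        {
            "label": [p.label for p in pairs],
            "category": [p.category.value for p in pairs],
            "habit_scope": [p.habit_scope for p in pairs],
            "n_target": [len(p.target_ids) for p in pairs],
            "n_reference": [len(p.reference_ids) for p in pairs],
            "target_ids": [json.dumps(list(p.target_ids)) for p in pairs],
            "reference_ids": [json.dumps(list(p.reference_ids)) for p in pairs],
        }
    )
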