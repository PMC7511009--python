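"""Stomach-content analysis: parsimonious prey enumeration and diet indices.

Prey individuals are counted from recovered hard parts with a parsimony rule
that seeks the smallest number of individuals able to explain the parts:
whole prey count as themselves, paired structures (otoliths, eyes, claws)
count as ``ceil(parts / 2)`` donors, and unquantifiable remains (muscle,
gills, bristles) attest a single individual — and only when no countable
part of the same taxon already does.

From the enumerated stomachs the module computes the vacuity rate %V
(fraction of empty stomachs, an inverse proxy of feeding intensity) and the
Hyslop indices per prey group: frequency of occurrence O_i = J_i / P over
non-empty stomachs, its rescaled percentage %O, and percentage numerical
abundance %N = N_i / ΣN_i.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .reference import CLASS_EDGES_MM, PREY_GROUPS, SIZE_CLASS_LABELS

PART_TYPES = ("whole", "paired_part", "uncountable_remains")


@dataclass(frozen=True)
class PreyItem:
    """One record of prey parts (or whole prey) found in a stomach."""

    stomach_id: str
    taxon: str
    group: str
    part_type: str
    raw_count: int = 1

    def __post_init__(self) -> None:
        if self.part_type not in PART_TYPES:
            raise ValueError(
                f"unknown part_type {self.part_type!r}; expected one of {PART_TYPES}"
            )
        if self.part_type != "uncountable_remains" and self.raw_count < 1:
            raise ValueError(
                f"raw_count must be >= 1 for part_type {self.part_type!r}"
            )


@dataclass
class StomachRecord:
    """All prey items of one stomach; an empty item list means an empty stomach."""

    stomach_id: str
    fish_id: str
    season: str
    size_class: str
    items: list[PreyItem] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return len(self.items) == 0


@dataclass
class VacuityResult:
    pct_V: float
    n_empty: int
    n_total: int


def assign_size_class(
    length_mm: float,
    class_edges: Sequence[float] = CLASS_EDGES_MM,
    labels: Sequence[str] = SIZE_CLASS_LABELS,
) -> str:
    """Map a total length (mm) to its 5-cm class label.

    Bins are left-closed right-open: a fish of exactly 150 mm belongs to
    15-20cm. The last class is open above.
    """
    if length_mm < class_edges[0]:
        raise ValueError(
            f"fish length {length_mm} mm below the class scheme (min {class_edges[0]})"
        )
    for edge, label in zip(reversed(class_edges), reversed(labels)):
        if length_mm >= edge:
            return label
    raise AssertionError("unreachable")


def enumerate_prey(items: Sequence[PreyItem]) -> int:
    """Minimal number of prey individuals explaining the parts of one taxon.

    All items must belong to the same stomach and taxon. Whole prey count
    one-for-one; ``n`` paired parts need at least ``ceil(n/2)`` donors;
    uncountable remains add one individual only if nothing countable of the
    taxon is present (countable parts already attest at least one donor that
    can have shed the remains).
    """
    if not items:
        return 0
    taxa = {it.taxon for it in items}
    if len(taxa) != 1:
        raise ValueError(f"enumerate_prey expects a single taxon, got {sorted(taxa)}")
    whole = sum(it.raw_count for it in items if it.part_type == "whole")
    paired = sum(it.raw_count for it in items if it.part_type == "paired_part")
    has_remains = any(it.part_type == "uncountable_remains" for it in items)
    count = whole + math.ceil(paired / 2)
    if has_remains and count == 0:
        count = 1
    return count


def stomach_prey_counts(stomach: StomachRecord) -> dict[str, int]:
    """Enumerated individuals per prey group for one stomach."""
    by_taxon: dict[tuple[str, str], list[PreyItem]] = defaultdict(list)
    for it in stomach.items:
        by_taxon[(it.group, it.taxon)].append(it)
    counts: dict[str, int] = defaultdict(int)
    for (group, _taxon), its in by_taxon.items():
        counts[group] += enumerate_prey(its)
    return dict(counts)


def vacuity(stomachs: Sequence[StomachRecord]) -> VacuityResult:
    """Vacuity rate %V = 100 × (empty stomachs) / (all stomachs)."""
    if not stomachs:
        raise ValueError("vacuity requires at least one stomach")
    n_total = len(stomachs)
    n_empty = sum(s.is_empty for s in stomachs)
    return VacuityResult(pct_V=100.0 * n_empty / n_total, n_empty=n_empty, n_total=n_total)


class NoNonEmptyStomachError(ValueError):
    """All stomachs in the cell are empty: occurrence indices are undefined."""


def occurrence_indices(
    stomachs: Sequence[StomachRecord], groups: Sequence[str] = PREY_GROUPS
) -> pd.DataFrame:
    """Frequency of occurrence O_i = J_i/P per group, with rescaled %O.

    O_i is computed over non-empty stomachs only. Because a stomach may
    contain several prey groups, Σ O_i can exceed 1; %O rescales the O_i to
    sum to 100. Items of groups outside ``groups`` still make a stomach
    non-empty (they count in P) but get no index row, so the indices can be
    restricted to focal prey groups.
    """
    if not stomachs:
        raise ValueError("occurrence_indices requires at least one stomach")
    non_empty = [s for s in stomachs if not s.is_empty]
    P = len(non_empty)
    if P == 0:
        raise NoNonEmptyStomachError(
            "no non-empty stomach in this set (P = 0); O_i is undefined"
        )
    J = {g: 0 for g in groups}
    for s in non_empty:
        for g in {it.group for it in s.items}:
            if g in J:
                J[g] += 1
    O = {g: J[g] / P for g in groups}
    total_O = sum(O.values())
    rows = [
        {
            "group": g,
            "J_i": J[g],
            "P": P,
            "O_i": O[g],
            "pct_O": (100.0 * O[g] / total_O) if total_O > 0 else 0.0,
        }
        for g in groups
    ]
    return pd.DataFrame(rows)


def abundance_indices(
    stomachs: Sequence[StomachRecord], groups: Sequence[str] = PREY_GROUPS
) -> pd.DataFrame:
    """Numerical abundance N_i per group (parsimonious enumeration) and %N."""
    if not stomachs:
        raise ValueError("abundance_indices requires at least one stomach")
    N = {g: 0 for g in groups}
    for s in stomachs:
        for g, n in stomach_prey_counts(s).items():
            if g in N:
                N[g] += n
    total = sum(N.values())
    if total == 0:
        raise ValueError("no enumerable prey in this set (ΣN_i = 0)")
    rows = [
        {"group": g, "N_i": N[g], "pct_N": 100.0 * N[g] / total} for g in groups
    ]
    return pd.DataFrame(rows)


def diet_table(
    stomachs: Sequence[StomachRecord],
    groups: Sequence[str] = PREY_GROUPS,
    seasons: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-(season, size class) diet indices plus a pooled block.

    Every cell with at least one non-empty stomach and at least one
    enumerable prey yields one row per prey group with O_i, %O, N_i, %N.
    The pooled block (season = size_class = "all") recomputes the indices on
    the concatenation of all stomachs, matching a diet averaged over seasons
    and size classes.
    """
    if not stomachs:
        raise ValueError("diet_table requires at least one stomach")
    cells: dict[tuple[str, str], list[StomachRecord]] = defaultdict(list)
    for s in stomachs:
        if seasons is not None and s.season not in seasons:
            raise ValueError(f"stomach {s.stomach_id} has unknown season {s.season!r}")
        cells[(s.season, s.size_class)].append(s)

    blocks: list[pd.DataFrame] = []

    def _block(season: str, size_class: str, ss: list[StomachRecord]) -> pd.DataFrame | None:
        try:
            occ = occurrence_indices(ss, groups)
            ab = abundance_indices(ss, groups)
        except (NoNonEmptyStomachError, ValueError):
            return None
        out = occ.merge(ab, on="group")
        out.insert(0, "size_class", size_class)
        out.insert(0, "season", season)
        return out

    for (season, size_class) in sorted(cells):
        b = _block(season, size_class, cells[(season, size_class)])
        if b is not None:
            blocks.append(b)
    pooled = _block("all", "all", list(stomachs))
    if pooled is not None:
        blocks.append(pooled)
    if not blocks:
        raise ValueError("no cell with enumerable prey")
    return pd.concat(blocks, ignore_index=True)


def vacuity_table(stomachs: Sequence[StomachRecord]) -> pd.DataFrame:
    """Vacuity per season and overall."""
    by_season: dict[str, list[StomachRecord]] = defaultdict(list)
    for s in stomachs:
        by_season[s.season].append(s)
    rows = []
    for season in sorted(by_season):
        v = vacuity(by_season[season])
        rows.append(
            {"season": season, "pct_V": v.pct_V, "n_empty": v.n_empty, "n_total": v.n_total}
        )
    v = vacuity(list(stomachs))
    rows.append({"season": "all", "pct_V": v.pct_V, "n_empty": v.n_empty, "n_total": v.n_total})
    return pd.DataFrame(rows)


def stomachs_from_frames(
    fish: pd.DataFrame, prey_items: pd.DataFrame, group_map: Mapping[str, str] | None = None
) -> list[StomachRecord]:
    """Assemble StomachRecords from fish and prey-item tables.

    ``fish`` needs columns fish_id, season, size_class (or length_mm, from
    which the class is derived); ``prey_items`` needs stomach_id, taxon,
    group (or a taxon→group mapping), part_type, raw_count. Fish without any
    prey row get an empty stomach.
    """
    fish = fish.copy()
    if "size_class" not in fish.columns:
        fish["size_class"] = [assign_size_class(l) for l in fish["length_mm"]]
    if "stomach_id" not in fish.columns:
        fish["stomach_id"] = fish["fish_id"]
    recs: dict[str, StomachRecord] = {}
    for row in fish.itertuples(index=False):
        recs[str(row.stomach_id)] = StomachRecord(
            stomach_id=str(row.stomach_id),
            fish_id=str(row.fish_id),
            season=str(row.season),
            size_class=str(row.size_class),
        )
    for row in prey_items.itertuples(index=False):
        sid = str(row.stomach_id)
        if sid not in recs:
            raise ValueError(f"prey item references unknown stomach {sid!r}")
        if group_map is not None:
            if row.taxon not in group_map:
                raise ValueError(f"taxon {row.taxon!r} missing from the prey-group mapping")
            group = group_map[row.taxon]
        else:
            group = str(row.group)
        recs[sid].items.append(
            PreyItem(
                stomach_id=sid,
                taxon=str(row.taxon),
                group=group,
                part_type=str(row.part_type),
                raw_count=int(row.raw_count),
            )
        )
    return list(recs.values())
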