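"""Assigning species to marine realms from gridded range occupancy.

A species' gridded range (presence/absence over ~50 km cells) is reduced to
the fraction of occupied cells falling in each realm; a realm is part of the
species' range when that fraction reaches a threshold of 1/9 — chosen so a
range spread perfectly evenly over all nine realms is counted in every one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .core import RangeState, RealmSet

__all__ = ["OccupancyGrid", "realm_fractions", "assign_realms", "realm_richness"]

DEFAULT_THRESHOLD = 1.0 / 9.0


@dataclass
class OccupancyGrid:
    """Grid cells with coordinates, a cell->realm map and per-species occupancy.

    ``cell_realm`` maps a cell id to a realm label or ``None`` for cells
    outside every realm (land / undefined).
    """

    cell_coords: dict[int, tuple[float, float]]  # cell id -> (lon, lat), WGS84
    cell_realm: dict[int, str | None]
    species_cells: dict[str, set[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.cell_realm) - set(self.cell_coords)
        if unknown:
            raise ValueError(f"cells with a realm but no coordinates: {sorted(unknown)[:5]}")
        for sp, cells in self.species_cells.items():
            if not cells:
                raise ValueError(f"species {sp} occupies no cells")


def realm_fractions(
    species_cells: Iterable[int],
    grid: OccupancyGrid,
    realms: RealmSet,
    count_unassigned_in_denominator: bool = True,
) -> dict[str, float]:
    """Fraction of a species' occupied cells falling in each realm.

    Cells outside every realm are excluded from every numerator; by default
    they stay in the denominator (the threshold applies to the whole range,
    not only its in-realm portion), switchable via
    ``count_unassigned_in_denominator``.
    """
    cells = set(species_cells)
    if not cells:
        raise ValueError("species occupies no cells")
    in_realm = {lab: 0 for lab in realms.labels}
    n_assigned = 0
    for cell in cells:
        lab = grid.cell_realm.get(cell)
        if lab is None:
            continue
        if lab not in in_realm:
            raise ValueError(f"cell {cell} labeled with unknown realm {lab!r}")
        in_realm[lab] += 1
        n_assigned += 1
    denom = len(cells) if count_unassigned_in_denominator else n_assigned
    if denom == 0:
        return {lab: 0.0 for lab in realms.labels}
    return {lab: n / denom for lab, n in in_realm.items()}


def assign_realms(
    fractions: Mapping[str, float],
    realms: RealmSet,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[RangeState, bool]:
    """Threshold realm fractions into a RangeState.

    A realm is included iff its fraction is >= ``threshold``.  If no realm
    reaches the threshold the species falls back to the single realm with the
    largest positive fraction (ties broken by canonical realm order) and the
    returned flag is True.  All-zero fractions raise: the species cannot be
    placed.
    """
    included = [lab for lab in realms.labels if fractions.get(lab, 0.0) >= threshold]
    if included:
        return RangeState.from_labels(included, realms), False
    best_lab, best_frac = None, 0.0
    for lab in realms.labels:  # canonical order breaks ties
        frac = fractions.get(lab, 0.0)
        if frac > best_frac:
            best_lab, best_frac = lab, frac
    if best_lab is None:
        raise ValueError("species has zero overlap with every realm: unassignable")
    return RangeState.from_labels([best_lab], realms), True


def realm_richness(
    assignments: Mapping[str, RangeState], realms: RealmSet
) -> dict[str, int]:
    """Number of species whose range includes each realm."""
    if not assignments:
        raise ValueError("empty assignment map")
    richness = {lab: 0 for lab in realms.labels}
    for state in assignments.values():
        for i in state.indices():
            richness[realms.labels[i]] += 1
    return richness
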