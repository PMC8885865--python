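"""Entity catalog and aggregation of calibrated series into groups.

The catalog maps knowledge-base entity identifiers (e.g. ``/m/09728`` for
"bread") to either a food category, or to a food-access mode classified on
two orthogonal axes: where the food is consumed (at home / outside) and
who prepares it (the household / a third party).  Because all series are
calibrated onto one multiplicative scale, the combined interest of a group
of entities is the week-wise sum of the members' volumes.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .series import InterestSeries

logger = logging.getLogger(__name__)

KIND_FOOD = "food"
KIND_ACCESS = "access_mode"
ACCESS_HOME_VALUES = ("home", "outside")
ACCESS_PREPARER_VALUES = ("household", "third_party")


@dataclass(frozen=True)
class CatalogEntry:
    entity_id: str
    display_name: str
    kind: str  # "food" or "access_mode"
    category: str | None = None  # food category, required for foods
    access_home: str | None = None  # "home" | "outside"
    access_preparer: str | None = None  # "household" | "third_party"

    def __post_init__(self) -> None:
        if self.kind not in (KIND_FOOD, KIND_ACCESS):
            raise ValueError(f"{self.entity_id}: unknown kind {self.kind!r}")
        if self.kind == KIND_FOOD:
            if not self.category:
                raise ValueError(f"food entity {self.entity_id} has no category")
        else:
            if self.access_home not in ACCESS_HOME_VALUES:
                raise ValueError(
                    f"access-mode entity {self.entity_id} needs access_home in "
                    f"{ACCESS_HOME_VALUES}"
                )
            if self.access_preparer not in ACCESS_PREPARER_VALUES:
                raise ValueError(
                    f"access-mode entity {self.entity_id} needs access_preparer in "
                    f"{ACCESS_PREPARER_VALUES}"
                )


@dataclass(frozen=True)
class EntityCatalog:
    """Validated set of catalog entries with unique entity ids."""

    entries: tuple[CatalogEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.entity_id for e in self.entries]
        dupes = [k for k, n in Counter(ids).items() if n > 1]
        if dupes:
            raise ValueError(f"duplicate entity_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def kind_counts(self) -> dict[str, int]:
        return dict(Counter(e.kind for e in self.entries))

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(
            sorted({e.category for e in self.entries if e.kind == KIND_FOOD})
        )

    def food_ids(self) -> tuple[str, ...]:
        return tuple(e.entity_id for e in self.entries if e.kind == KIND_FOOD)

    def category_members(self, category: str) -> tuple[str, ...]:
        ids = tuple(
            e.entity_id
            for e in self.entries
            if e.kind == KIND_FOOD and e.category == category
        )
        if not ids:
            raise ValueError(f"no entities in category {category!r}")
        return ids

    def access_mode_groups(self) -> dict[tuple[str, str], tuple[str, ...]]:
        """Members of the four (access_home, access_preparer) cells.

        Group membership is derived from the two orthogonal fields; only
        non-empty cells are returned.
        """
        groups: dict[tuple[str, str], list[str]] = {}
        for e in self.entries:
            if e.kind == KIND_ACCESS:
                groups.setdefault((e.access_home, e.access_preparer), []).append(
                    e.entity_id
                )
        return {k: tuple(v) for k, v in sorted(groups.items())}

    def access_mode_ids(self) -> tuple[str, ...]:
        return tuple(e.entity_id for e in self.entries if e.kind == KIND_ACCESS)


def load_catalog(path: str | Path) -> EntityCatalog:
    """Load and validate an entity catalog CSV.

    Expected columns: ``entity_id, display_name, kind, category,
    access_home, access_preparer`` (UTF-8, header row required).  Duplicate
    ids, food entries without a category, and access-mode entries missing
    either classification axis are hard errors.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"entity_id", "display_name", "kind"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalog {path}: missing columns {sorted(missing)}")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            CatalogEntry(
                entity_id=row["entity_id"],
                display_name=row["display_name"],
                kind=row["kind"],
                category=row.get("category", "") or None,
                access_home=row.get("access_home", "") or None,
                access_preparer=row.get("access_preparer", "") or None,
            )
        )
    catalog = EntityCatalog(tuple(entries))
    logger.info("loaded catalog %s: %s", path, catalog.kind_counts)
    return catalog


def write_catalog(catalog: EntityCatalog, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "entity_id": e.entity_id,
                "display_name": e.display_name,
                "kind": e.kind,
                "category": e.category or "",
                "access_home": e.access_home or "",
                "access_preparer": e.access_preparer or "",
            }
            for e in catalog.entries
        ]
    ).to_csv(path, index=False)


def aggregate_series(
    per_entity: list[InterestSeries],
    members: list[str] | tuple[str, ...],
    label: str | None = None,
) -> InterestSeries:
    """Week-wise sum of the member entities' calibrated volumes.

    All member series must share the country and the exact (year, week)
    grid.  Aggregation is associative and order-independent because it is
    a plain sum on a fixed grid.
    """
    members = list(members)
    if not members:
        raise ValueError("empty member list")
    by_label = {s.label: s for s in per_entity}
    missing = [m for m in members if m not in by_label]
    if missing:
        raise ValueError(f"member series not found: {missing}")
    selected = [by_label[m] for m in members]
    first = selected[0]
    total = first.data["volume"].to_numpy().copy()
    for s in selected[1:]:
        if s.country != first.country:
            raise ValueError(
                f"cannot aggregate across countries ({s.country} vs {first.country})"
            )
        if not s.same_grid(first):
            raise ValueError(
                f"mismatched week grids: {s.label!r} vs {first.label!r}"
            )
        total = total + s.data["volume"].to_numpy()
    return first.with_volumes(total, label=label or "+".join(members))
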