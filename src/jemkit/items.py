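"""Survey item definitions and occupation-to-JEM-group maps.

A job exposure matrix (JEM) is only as good as its item bookkeeping: which
ordinal survey items enter, which Karasek dimension each belongs to
(psychological demands vs. decision latitude / job control), what scale each
is measured on, and whether a *large* raw value means *adverse* exposure.
This module holds those definitions, validates them, and reads/writes the
human-editable YAML config and the occupation-code -> JEM-group CSV map.

Occupation codes (STYRK-style 4-digit classification codes) are identifiers,
not numbers: they are stored as fixed-width 4-character strings so that
leading zeros (e.g. ``"0110"``) survive every round trip.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import yaml

DEMAND = "demand"
CONTROL = "control"
DIMENSIONS = (DEMAND, CONTROL)

GENDERS = ("female", "male")


class ConfigError(ValueError):
    """Raised when an item set, group map, or crosswalk fails validation."""


def normalize_code(code: object) -> str:
    """Normalize an occupation code to a zero-padded 4-character string.

    Accepts strings or integers; ``110`` and ``"110"`` both become
    ``"0110"``. Anything that is not 1-4 digits after stripping whitespace
    is rejected.
    """
    text = str(code).strip()
    if text.endswith(".0"):  # float leakage from CSV readers
        text = text[:-2]
    if not text.isdigit() or not 1 <= len(text) <= 4:
        raise ConfigError(f"invalid occupation code {code!r}: need 1-4 digits")
    return text.zfill(4)


@dataclass(frozen=True)
class ItemDefinition:
    """One ordinal survey item.

    Parameters
    ----------
    item_id : str
        Short unique key, used as the survey column name.
    label : str
        Free-text description.
    dimension : {"demand", "control"}
        Karasek dimension the item measures.
    scale_min, scale_max : int
        Inclusive bounds of the ordinal response scale.
    adverse_high : bool
        True when larger raw values mean more adverse exposure. When False
        the raw value is aligned by reflection
        ``scale_min + scale_max - value`` before any median or cut-off.
    """

    item_id: str
    label: str = ""
    dimension: str = DEMAND
    scale_min: int = 1
    scale_max: int = 5
    adverse_high: bool = True

    def __post_init__(self) -> None:
        if not self.item_id:
            raise ConfigError("item_id must be non-empty")
        if self.dimension not in DIMENSIONS:
            raise ConfigError(
                f"item {self.item_id!r}: unknown dimension {self.dimension!r}"
            )
        if not self.scale_min < self.scale_max:
            raise ConfigError(
                f"item {self.item_id!r}: scale_min must be < scale_max "
                f"(got {self.scale_min} >= {self.scale_max})"
            )

    def align(self, value: float) -> float:
        """Return the adversity-aligned response value.

        Identity for ``adverse_high`` items, reflection about the scale
        midpoint otherwise, so that after alignment *larger always means
        more adverse* for every item.
        """
        if not self.scale_min <= value <= self.scale_max:
            raise ValueError(
                f"item {self.item_id!r}: value {value} outside scale "
                f"[{self.scale_min}, {self.scale_max}]"
            )
        if self.adverse_high:
            return value
        return self.scale_min + self.scale_max - value


@dataclass(frozen=True)
class ItemSet:
    """An ordered, validated collection of :class:`ItemDefinition`."""

    items: tuple[ItemDefinition, ...]
    name: str = "unnamed"

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if not ids:
            raise ConfigError("item set must contain at least one item")
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ConfigError(f"duplicate item_id(s): {sorted(dupes)}")

    def __iter__(self) -> Iterator[ItemDefinition]:
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, item_id: str) -> ItemDefinition:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def __contains__(self, item_id: object) -> bool:
        return any(it.item_id == item_id for it in self.items)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    @property
    def demand_items(self) -> tuple[ItemDefinition, ...]:
        return tuple(it for it in self.items if it.dimension == DEMAND)

    @property
    def control_items(self) -> tuple[ItemDefinition, ...]:
        return tuple(it for it in self.items if it.dimension == CONTROL)


def _item_from_mapping(raw: Mapping, index: int) -> ItemDefinition:
    if "item_id" not in raw:
        raise ConfigError(f"items[{index}]: missing item_id")
    known = {"item_id", "label", "dimension", "scale_min", "scale_max", "adverse_high"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"items[{index}]: unknown field(s) {sorted(unknown)}")
    dimension = raw.get("dimension", "")
    if dimension not in DIMENSIONS:
        raise ConfigError(
            f"items[{index}] ({raw['item_id']!r}): unknown dimension {dimension!r}"
        )
    # Demand items default to adverse_high=true (more frequent demands are
    # adverse almost by definition); control items vary in orientation, so
    # the config must state it explicitly rather than inherit a silent guess.
    if "adverse_high" not in raw:
        if dimension == CONTROL:
            raise ConfigError(
                f"items[{index}] ({raw['item_id']!r}): control items must state "
                "adverse_high explicitly"
            )
        adverse_high = True
    else:
        adverse_high = bool(raw["adverse_high"])
    return ItemDefinition(
        item_id=str(raw["item_id"]),
        label=str(raw.get("label", "")),
        dimension=dimension,
        scale_min=int(raw.get("scale_min", 1)),
        scale_max=int(raw.get("scale_max", 5)),
        adverse_high=adverse_high,
    )


def load_item_set(path: str | Path) -> ItemSet:
    """Load and validate an item-set YAML config.

    Raises :class:`ConfigError` on duplicate ids, malformed scales, unknown
    dimensions, or missing control-item orientations, and
    :class:`FileNotFoundError` when the file does not exist.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping) or "items" not in raw:
        raise ConfigError(f"{path}: config must be a mapping with an 'items' list")
    items = tuple(
        _item_from_mapping(entry, i) for i, entry in enumerate(raw["items"])
    )
    return ItemSet(items=items, name=str(raw.get("name", path.stem)))


def write_item_set(item_set: ItemSet, path: str | Path) -> None:
    """Write an item set back to YAML; inverse of :func:`load_item_set`."""
    payload = {
        "name": item_set.name,
        "items": [
            {
                "item_id": it.item_id,
                "label": it.label,
                "dimension": it.dimension,
                "scale_min": it.scale_min,
                "scale_max": it.scale_max,
                "adverse_high": it.adverse_high,
            }
            for it in item_set
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False, allow_unicode=True)


def default_item_set() -> ItemSet:
    """The packaged ten-item set: 4 demand + 6 control items on 1-5 scales."""
    ref = resources.files("jemkit.data").joinpath("default_items.yaml")
    with resources.as_file(ref) as path:
        return load_item_set(path)


@dataclass(frozen=True)
class JemGroupMap:
    """Mapping of 4-digit occupation codes to JEM group ids.

    Several detailed occupation codes may share one JEM group (the pooling
    that gives exposure cells enough respondents); every code belongs to
    exactly one group.
    """

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ConfigError("group map is empty")

    @property
    def code_count(self) -> int:
        return len(self.entries)

    @property
    def group_count(self) -> int:
        return len(set(self.entries.values()))

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.entries.values())))

    def group_of(self, code: str) -> str | None:
        return self.entries.get(code)

    def codes_in_group(self, group_id: str) -> tuple[str, ...]:
        return tuple(
            sorted(c for c, g in self.entries.items() if g == group_id)
        )

    def digest(self) -> str:
        """Stable content hash, recorded in matrix metadata for provenance."""
        h = hashlib.sha256()
        for code in sorted(self.entries):
            h.update(f"{code}\t{self.entries[code]}\n".encode())
        return h.hexdigest()[:12]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[object, str]]) -> "JemGroupMap":
        entries: dict[str, str] = {}
        for code, group in pairs:
            code = normalize_code(code)
            group = str(group).strip()
            if not group:
                raise ConfigError(f"code {code!r}: empty jem_group_id")
            if code in entries and entries[code] != group:
                raise ConfigError(
                    f"code {code!r} mapped to both {entries[code]!r} and {group!r}"
                )
            entries[code] = group
        return cls(entries=entries)


def load_group_map(path: str | Path) -> JemGroupMap:
    """Read an occupation_code,jem_group_id CSV into a validated map."""
    df = pd.read_csv(path, dtype=str)
    required = {"occupation_code", "jem_group_id"}
    if not required <= set(df.columns):
        raise ConfigError(
            f"{path}: group map needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    return JemGroupMap.from_pairs(
        zip(df["occupation_code"], df["jem_group_id"])
    )


def write_group_map(group_map: JemGroupMap, path: str | Path) -> None:
    pd.DataFrame(
        sorted(group_map.entries.items()),
        columns=["occupation_code", "jem_group_id"],
    ).to_csv(path, index=False)
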