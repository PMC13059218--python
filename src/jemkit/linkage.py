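"""Occupation-code crosswalks and register linkage.

Two operations connect an occupation-level exposure index to individual
register data: converting 4-digit occupation codes between classification
revisions (for which no official correspondence key may exist, so ambiguity
must be handled explicitly, never silently), and a left join of the index
onto register rows by (occupation_code, gender) that preserves every
register row and accounts for each one in a merge report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .items import ConfigError, normalize_code

POLICIES = ("strict", "first_match", "expand_rows")

_GENDER_ALIASES = {
    "female": "female", "f": "female", "k": "female", "kvinne": "female",
    "woman": "female", "w": "female", "2": "female",
    "male": "male", "m": "male", "mann": "male", "man": "male", "1": "male",
}


class AmbiguousCodeError(ConfigError):
    """Raised under the strict policy when a source code has >= 2 targets."""


def normalize_gender(
    values: pd.Series, mapping: dict[str, str] | None = None
) -> pd.Series:
    """Map assorted gender codings onto the two-level {female, male} enum.

    Register sources vary ("F"/"M", 1/2, Norwegian labels); anything not in
    the mapping raises rather than silently becoming a third stratum.
    """
    table = mapping or _GENDER_ALIASES
    out = values.astype(str).str.strip().str.lower().map(table)
    bad = values[out.isna() & values.notna()]
    if len(bad):
        raise ConfigError(f"unmappable gender value(s): {sorted(set(bad.astype(str)))[:5]}")
    return out


@dataclass(frozen=True)
class CrosswalkKey:
    """A 4-digit source -> target occupation-code key.

    ``pairs`` holds distinct (source, target) pairs; sources with two or
    more targets are genuinely ambiguous and enumerable via
    :attr:`ambiguous_sources`.
    """

    pairs: tuple[tuple[str, str], ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ConfigError("crosswalk key is empty")
        if len(set(self.pairs)) != len(self.pairs):
            raise ConfigError("crosswalk key contains duplicated (source, target) pairs")

    @property
    def mapping(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {}
        for s, t in self.pairs:
            out.setdefault(s, []).append(t)
        return {s: tuple(sorted(ts)) for s, ts in out.items()}

    @property
    def ambiguous_sources(self) -> tuple[str, ...]:
        return tuple(sorted(s for s, ts in self.mapping.items() if len(ts) > 1))

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[object, object]], provenance: str = ""
    ) -> "CrosswalkKey":
        normed = []
        seen = set()
        for s, t in pairs:
            pair = (normalize_code(s), normalize_code(t))
            if pair not in seen:
                seen.add(pair)
                normed.append(pair)
        return cls(pairs=tuple(normed), provenance=provenance)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CrosswalkKey":
        df = pd.read_csv(path, dtype=str)
        required = {"source_code", "target_code"}
        if not required <= set(df.columns):
            raise ConfigError(
                f"{path}: crosswalk needs columns {sorted(required)}, "
                f"found {list(df.columns)}"
            )
        return cls.from_pairs(
            zip(df["source_code"], df["target_code"]), provenance=str(path)
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.pairs, columns=["source_code", "target_code"]).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class ConversionReport:
    """Outcome accounting for one :func:`convert_codes` run."""

    n_input_rows: int
    n_converted: int
    n_unconverted: int
    n_output_rows: int
    ambiguous_sources_seen: tuple[str, ...]
    policy: str


def convert_codes(
    table: pd.DataFrame,
    key: CrosswalkKey,
    policy: str = "strict",
    code_col: str = "occupation_code",
) -> tuple[pd.DataFrame, ConversionReport]:
    """Convert a table's occupation codes through a crosswalk key.

    Policies for sources with several targets:

    - ``strict`` (default): raise :class:`AmbiguousCodeError` naming the
      offending source codes — unofficial keys can introduce errors, so
      silent resolution is opt-in;
    - ``first_match``: take the lexicographically first target and warn
      once per ambiguous source;
    - ``expand_rows``: emit one output row per candidate target, with the
      original code kept in a ``crosswalk_source`` provenance column.

    Codes absent from the key pass through unchanged and are counted as
    unconverted.
    """
    if policy not in POLICIES:
        raise ConfigError(f"unknown policy {policy!r}; choose from {POLICIES}")
    if code_col not in table.columns:
        raise ConfigError(f"table has no column {code_col!r}")
    mapping = key.mapping
    codes = table[code_col].map(normalize_code)

    seen_ambiguous = tuple(
        sorted(set(codes) & set(key.ambiguous_sources))
    )
    if policy == "strict" and seen_ambiguous:
        raise AmbiguousCodeError(
            "ambiguous source code(s) under strict policy: "
            + ", ".join(seen_ambiguous)
        )

    in_key = codes.isin(mapping.keys())
    n_converted = int(in_key.sum())
    n_unconverted = len(table) - n_converted

    if policy == "expand_rows":
        out = table.copy()
        out[code_col] = codes
        out["crosswalk_source"] = codes
        targets = codes.map(lambda c: mapping.get(c, (c,)))
        out = out.assign(**{code_col: targets}).explode(code_col, ignore_index=True)
        out.loc[~out["crosswalk_source"].isin(mapping.keys()), "crosswalk_source"] = pd.NA
        report = ConversionReport(
            n_input_rows=len(table),
            n_converted=n_converted,
            n_unconverted=n_unconverted,
            n_output_rows=len(out),
            ambiguous_sources_seen=seen_ambiguous,
            policy=policy,
        )
        return out, report

    if policy == "first_match":
        for src in seen_ambiguous:
            warnings.warn(
                f"source code {src} has targets {mapping[src]}; "
                f"taking {mapping[src][0]}",
                stacklevel=2,
            )
    out = table.copy()
    out[code_col] = codes.map(lambda c: mapping[c][0] if c in mapping else c)
    report = ConversionReport(
        n_input_rows=len(table),
        n_converted=n_converted,
        n_unconverted=n_unconverted,
        n_output_rows=len(out),
        ambiguous_sources_seen=seen_ambiguous,
        policy=policy,
    )
    return out, report


@dataclass(frozen=True)
class MergeReport:
    """Row accounting for one register merge.

    Invariant: ``n_matched + n_unmatched_code + n_unmatched_gender_cell ==
    n_input_rows`` — every register row is preserved and classified.
    """

    n_input_rows: int
    n_matched: int
    n_unmatched_code: int
    n_unmatched_gender_cell: int
    ambiguous_conversions: int = 0
    policy_used: str = "none"

    def __post_init__(self) -> None:
        total = self.n_matched + self.n_unmatched_code + self.n_unmatched_gender_cell
        if total != self.n_input_rows:
            raise ValueError(
                f"merge report does not balance: {total} != {self.n_input_rows}"
            )

    def __str__(self) -> str:
        return (
            "Merge report\n"
            f"  input rows:             {self.n_input_rows}\n"
            f"  matched:                {self.n_matched}\n"
            f"  unmatched (code):       {self.n_unmatched_code}\n"
            f"  unmatched (gender cell):{self.n_unmatched_gender_cell}\n"
            f"  ambiguous conversions:  {self.ambiguous_conversions}\n"
            f"  policy:                 {self.policy_used}\n"
        )


def merge_exposures(
    register: pd.DataFrame,
    index: pd.DataFrame,
    on: Sequence[str] = ("occupation_code", "gender"),
) -> tuple[pd.DataFrame, MergeReport]:
    """Left-join an occupation-level exposure index onto register rows.

    The register row count is preserved exactly; rows whose (code, gender)
    key has no index entry keep missing exposure columns and are flagged in
    ``jem_matched``. The index must be unique per key. Output is stably
    sorted by ``person_id`` when that column exists, making the join
    invariant to input row order.
    """
    on = list(on)
    for frame, label in ((register, "register"), (index, "index")):
        missing = [c for c in on if c not in frame.columns]
        if missing:
            raise ConfigError(f"{label} table lacks merge column(s) {missing}")
    if len(register) == 0:
        raise ConfigError("register table is empty")
    if index.duplicated(subset=on).any():
        dupes = index.loc[index.duplicated(subset=on), on].head(3)
        raise ConfigError(
            f"index table has duplicate keys on {on}: {dupes.to_dict('records')}"
        )

    reg = register.copy()
    if "occupation_code" in on:
        reg["occupation_code"] = reg["occupation_code"].map(normalize_code)
    merged = reg.merge(index, how="left", on=on, indicator="_merge_status")
    merged["jem_matched"] = merged["_merge_status"] == "both"

    index_codes = set(index["occupation_code"]) if "occupation_code" in on else set()
    unmatched = ~merged["jem_matched"]
    if "occupation_code" in on:
        code_known = merged["occupation_code"].isin(index_codes)
        n_unmatched_code = int((unmatched & ~code_known).sum())
        n_unmatched_gender = int((unmatched & code_known).sum())
    else:
        n_unmatched_code = int(unmatched.sum())
        n_unmatched_gender = 0
    merged = merged.drop(columns="_merge_status")
    if "person_id" in merged.columns:
        merged = merged.sort_values("person_id", kind="stable", ignore_index=True)

    report = MergeReport(
        n_input_rows=len(register),
        n_matched=int((~unmatched).sum()),
        n_unmatched_code=n_unmatched_code,
        n_unmatched_gender_cell=n_unmatched_gender,
        policy_used="left_join_exact",
    )
    return merged, report
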