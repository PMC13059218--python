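"""Median-split dichotomization and exposure-share aggregation.

The individual-level stage of a psychosocial job exposure matrix:

1. align each ordinal response so larger always means more adverse
   (reflection for protectively-oriented items);
2. per item, take the median of the aligned non-missing responses pooled
   over all waves and respondents as the cut-off;
3. a respondent is *exposed* on an item iff the aligned response is
   strictly greater than the cut-off (so respondents at the median count
   as non-exposed — e.g. a cut-off of 2 on a 1-5 frequency scale leaves
   exactly the responses 3, 4, 5 exposed);
4. aggregate to the share (%) of exposed among non-missing respondents
   within each (JEM group x gender) cell.

A share of 0 therefore means *no* non-missing respondent in the cell is
exposed, and 100 means *all* are; cells with fewer than ``n_min``
non-missing respondents are suppressed to missing rather than zero,
because "no data" must never masquerade as "0% exposed".

Even response counts can put the median midway between two admissible
scale values (e.g. 2.5): the strict-greater rule makes this equivalent to
cutting above the lower central value on integer scales, and keeps the
rule well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .items import ConfigError, ItemDefinition, ItemSet, JemGroupMap, normalize_code

ID_COLUMNS = ("respondent_id", "wave", "occupation_code", "gender")


def read_survey(path: str | Path, item_set: ItemSet) -> pd.DataFrame:
    """Read survey microdata CSV (codes as strings, blanks as missing).

    Stata ``.dta`` files with the same schema are accepted too.
    """
    path = Path(path)
    if path.suffix.lower() == ".dta":
        df = pd.read_stata(path)
    else:
        df = pd.read_csv(path, dtype={"occupation_code": str})
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    missing += [i for i in item_set.item_ids if i not in df.columns]
    if missing:
        raise ConfigError(f"{path}: survey lacks column(s) {missing}")
    df = df.copy()
    df["occupation_code"] = df["occupation_code"].map(normalize_code)
    for item in item_set.item_ids:
        df[item] = pd.to_numeric(df[item], errors="raise")
    return df


def align_response(value: float, item: ItemDefinition) -> float:
    """Adversity-align one response (identity or reflection); see ItemDefinition."""
    return item.align(value)


def _aligned_column(df: pd.DataFrame, item: ItemDefinition) -> pd.Series:
    col = df[item.item_id].astype(float)
    valid = col.dropna()
    out_of_range = valid[(valid < item.scale_min) | (valid > item.scale_max)]
    if len(out_of_range):
        raise ValueError(
            f"item {item.item_id!r}: {len(out_of_range)} response(s) outside "
            f"[{item.scale_min}, {item.scale_max}], e.g. {out_of_range.iloc[0]}"
        )
    if item.adverse_high:
        return col
    return item.scale_min + item.scale_max - col


@dataclass(frozen=True)
class CutoffTable:
    """Per-item median cut-offs on the aligned scale, with usage counts."""

    cutoffs: Mapping[str, float]
    n_used: Mapping[str, int]

    def __getitem__(self, item_id: str) -> float:
        return self.cutoffs[item_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": list(self.cutoffs),
                "cutoff": [self.cutoffs[i] for i in self.cutoffs],
                "n_used": [self.n_used[i] for i in self.cutoffs],
            }
        )


def compute_cutoffs(
    survey: pd.DataFrame, item_set: ItemSet, per_wave: bool = False
) -> CutoffTable | dict[int, CutoffTable]:
    """Median cut-off per item over aligned, non-missing responses.

    Pooled over all waves and both genders by default (one national median
    per item); ``per_wave=True`` instead returns ``{wave: CutoffTable}``.
    The median of an even count is the midpoint of the two central order
    statistics, which may be a half-integer.
    """
    if per_wave:
        return {
            int(wave): compute_cutoffs(chunk, item_set)
            for wave, chunk in survey.groupby("wave", sort=True)
        }
    cutoffs: dict[str, float] = {}
    n_used: dict[str, int] = {}
    for item in item_set:
        aligned = _aligned_column(survey, item).dropna()
        if aligned.empty:
            raise ConfigError(
                f"item {item.item_id!r}: no non-missing responses; cannot take a median"
            )
        cutoffs[item.item_id] = float(np.median(aligned))
        n_used[item.item_id] = int(len(aligned))
    return CutoffTable(cutoffs=cutoffs, n_used=n_used)


def dichotomize(
    survey: pd.DataFrame,
    cutoffs: CutoffTable | dict[int, CutoffTable],
    item_set: ItemSet,
    valid_codes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Flag each respondent exposed/non-exposed per item (strict-greater rule).

    Returns the survey's id columns plus one float column per item:
    1.0 = exposed (aligned value strictly above the cut-off), 0.0 =
    non-exposed, NaN = missing response. With a per-wave cut-off dict each
    respondent is cut at their own wave's table. Codes outside
    ``valid_codes`` (when given) trigger a warning, never an error.
    """
    if isinstance(cutoffs, dict):
        parts = [
            dichotomize(chunk, cutoffs[int(wave)], item_set, valid_codes=None)
            for wave, chunk in survey.groupby("wave", sort=True)
        ]
        flags = pd.concat(parts).loc[survey.index]
    else:
        missing_items = [i for i in item_set.item_ids if i not in cutoffs.cutoffs]
        if missing_items:
            raise ConfigError(f"cutoff table lacks item(s) {missing_items}")
        flags = survey.loc[:, [c for c in ID_COLUMNS if c in survey.columns]].copy()
        for item in item_set:
            aligned = _aligned_column(survey, item)
            cut = cutoffs[item.item_id]
            flags[item.item_id] = np.where(
                aligned.isna(), np.nan, (aligned > cut).astype(float)
            )
    if valid_codes is not None:
        unknown = sorted(set(flags["occupation_code"]) - set(valid_codes))
        if unknown:
            warnings.warn(
                f"{len(unknown)} occupation code(s) not in validation list, "
                f"e.g. {unknown[:5]}",
                stacklevel=2,
            )
    return flags


@dataclass(frozen=True)
class JemMatrix:
    """Exposure shares per (JEM group x gender) cell.

    ``table`` has one row per cell with, for each item, ``share_<item>``
    (percent exposed among non-missing, full precision; NaN when the cell
    holds fewer than ``n_min`` non-missing responses) and ``n_<item>``
    (the non-missing count). ``excluded`` lists survey rows whose
    occupation code the group map does not cover.
    """

    table: pd.DataFrame
    item_ids: tuple[str, ...]
    n_min: int
    stratify_by_gender: bool
    item_set_name: str = ""
    group_map_digest: str = ""
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["occupation_code", "n_rows"]
        )
    )

    @property
    def n_cells(self) -> int:
        return len(self.table)

    def cell_share(self, group: str, gender: str, item_id: str) -> float:
        row = self.table[
            (self.table["jem_group_id"] == group) & (self.table["gender"] == gender)
        ]
        if row.empty:
            raise KeyError((group, gender))
        return float(row[f"share_{item_id}"].iloc[0])

    def share_columns(self) -> list[str]:
        return [f"share_{i}" for i in self.item_ids]

    def to_csv(self, path: str | Path, decimals: int | None = 1) -> None:
        out = self.table.copy()
        if decimals is not None:
            out[self.share_columns()] = out[self.share_columns()].round(decimals)
        out.to_csv(path, index=False)

    def build_log(self) -> str:
        lines = [
            f"JEM build: {self.n_cells} cells "
            f"({'gender-stratified' if self.stratify_by_gender else 'pooled genders'}), "
            f"item set '{self.item_set_name}', group map {self.group_map_digest}",
            f"minimum cell size n_min = {self.n_min} (smaller cells suppressed to missing)",
        ]
        n_suppressed = int(self.table[self.share_columns()].isna().sum().sum())
        lines.append(f"suppressed cell x item shares: {n_suppressed}")
        if len(self.excluded):
            lines.append(
                f"excluded rows with unmapped codes: "
                f"{int(self.excluded['n_rows'].sum())} across "
                f"{len(self.excluded)} code(s): "
                + ", ".join(self.excluded["occupation_code"].head(10))
            )
        else:
            lines.append("excluded rows with unmapped codes: 0")
        return "\n".join(lines) + "\n"


def build_jem(
    flags: pd.DataFrame,
    group_map: JemGroupMap,
    item_set: ItemSet,
    stratify_by_gender: bool = True,
    n_min: int = 10,
) -> JemMatrix:
    """Aggregate exposure flags into per-(group, gender) exposure shares.

    ``share = 100 * exposed / (exposed + non-exposed)`` over non-missing
    flags; cells with a non-missing denominator below ``n_min`` carry NaN.
    Rows whose occupation code the group map does not cover are excluded
    and reported, not silently dropped.
    """
    if len(flags) == 0:
        raise ConfigError("no exposure flags to aggregate")
    items = list(item_set.item_ids)
    work = flags.copy()
    work["occupation_code"] = work["occupation_code"].map(normalize_code)
    work["jem_group_id"] = work["occupation_code"].map(group_map.entries)

    unmapped = work[work["jem_group_id"].isna()]
    excluded = (
        unmapped.groupby("occupation_code", sort=True)
        .size()
        .rename("n_rows")
        .reset_index()
    )
    work = work.dropna(subset=["jem_group_id"])
    if len(work) == 0:
        raise ConfigError("group map covers none of the observed occupation codes")

    keys = ["jem_group_id", "gender"] if stratify_by_gender else ["jem_group_id"]
    grouped = work.groupby(keys, sort=True)
    n = grouped[items].count()
    exposed = grouped[items].sum(min_count=1)
    share = 100.0 * exposed / n
    share = share.where(n >= n_min)

    table = pd.concat(
        {"share": share, "n": n.astype(int)}, axis=1
    )
    table.columns = [f"{stat}_{item}" for stat, item in table.columns]
    ordered = [f"share_{i}" for i in items] + [f"n_{i}" for i in items]
    table = table[ordered].reset_index()
    if not stratify_by_gender:
        table.insert(1, "gender", "all")
    return JemMatrix(
        table=table,
        item_ids=tuple(items),
        n_min=n_min,
        stratify_by_gender=stratify_by_gender,
        item_set_name=item_set.name,
        group_map_digest=group_map.digest(),
        excluded=excluded,
    )


def expand_to_codes(jem: JemMatrix, group_map: JemGroupMap) -> pd.DataFrame:
    """Expand group-level shares to one row per (occupation_code, gender).

    Every code inherits its JEM group's shares verbatim, so codes sharing
    a group carry identical exposure vectors by construction. Codes whose
    group has no cell in the matrix propagate missing shares.
    """
    code_frame = pd.DataFrame(
        sorted(group_map.entries.items()),
        columns=["occupation_code", "jem_group_id"],
    )
    genders = jem.table["gender"].drop_duplicates().sort_values()
    expanded = code_frame.merge(pd.DataFrame({"gender": genders}), how="cross")
    expanded = expanded.merge(jem.table, how="left", on=["jem_group_id", "gender"])
    cols = ["occupation_code", "gender", "jem_group_id"] + [
        c for c in jem.table.columns if c.startswith(("share_", "n_"))
    ]
    return expanded[cols].sort_values(
        ["occupation_code", "gender"], ignore_index=True
    )
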