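"""Occupation-level exposure assignment and the Karasek job strain index.

The second median split happens at the occupation level: for each item, the
cut-off is the unweighted median of exposure shares across (JEM group x
gender) cells, and an occupation is *exposed* on the item iff its cell's
share is strictly greater than that cut-off. Because cut-offs are defined
over group cells, the classification is invariant to whether shares are
expanded to detailed codes before or after the split.

Demand and control then combine per Karasek's Demand-Control model:

- ``demand_index``   = number of exposed demand items (0-4 with the
  default set);
- ``control_index``  = number of exposed control items, coded as
  *adversity* (exposed = low control), so "strictly greater than the
  median" means the same thing on both dimensions (0-6 default);
- ``high_demand`` / ``low_control`` split each count at its median across
  occupation rows (strict-greater, ties fall to the benign side);
- quadrants: high demand + low control = *high_strain* (job strain),
  high demand only = *active*, low control only = *passive*, neither =
  *low_strain*.

Rows with any missing constituent flag get missing indices and quadrant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .items import ConfigError, ItemSet, JemGroupMap
from .jem import JemMatrix, expand_to_codes

QUADRANTS = ("high_strain", "active", "passive", "low_strain")


@dataclass(frozen=True)
class OccupationExposureTable:
    """Binary occupation-level exposures with the share cut-offs that made them.

    ``table`` has one row per (occupation_code, gender) with
    ``share_<item>`` (inherited from the cell) and ``exp_<item>``
    (1.0 exposed / 0.0 non-exposed / NaN missing).
    """

    table: pd.DataFrame
    share_cutoffs: Mapping[str, float]
    item_ids: tuple[str, ...]
    median_over: str = "cells"

    def flags(self, code: str, gender: str) -> dict[str, float]:
        row = self.table[
            (self.table["occupation_code"] == code) & (self.table["gender"] == gender)
        ]
        if row.empty:
            raise KeyError((code, gender))
        return {i: float(row[f"exp_{i}"].iloc[0]) for i in self.item_ids}


def share_cutoffs(
    shares: pd.DataFrame, item_ids: tuple[str, ...]
) -> dict[str, float]:
    """Unweighted median of each item's share column (NaN shares ignored)."""
    cuts: dict[str, float] = {}
    for item in item_ids:
        col = shares[f"share_{item}"].dropna()
        if col.empty:
            raise ConfigError(f"item {item!r}: no non-missing shares to take a median")
        cuts[item] = float(np.median(col))
    return cuts


def assign_occupation_exposure(
    jem: JemMatrix,
    group_map: JemGroupMap,
    item_set: ItemSet,
    median_over: str = "cells",
) -> OccupationExposureTable:
    """Dichotomize cell shares at the median-of-shares, per item.

    ``median_over="cells"`` (default) takes each item's cut-off over the
    distinct (JEM group x gender) cells — the level at which shares are
    defined; ``"codes"`` instead takes it over the expanded per-code rows,
    which weights groups by how many detailed codes they contain. Exposed
    iff share strictly greater than the cut-off; missing (suppressed)
    shares propagate to missing flags.
    """
    if median_over not in ("cells", "codes"):
        raise ConfigError("median_over must be 'cells' or 'codes'")
    missing_cols = [
        i for i in item_set.item_ids if f"share_{i}" not in jem.table.columns
    ]
    if missing_cols:
        raise ConfigError(f"share table lacks item column(s) {missing_cols}")
    code_shares = expand_to_codes(jem, group_map)
    basis = jem.table if median_over == "cells" else code_shares
    cuts = share_cutoffs(basis, tuple(item_set.item_ids))

    out = code_shares.copy()
    for item in item_set.item_ids:
        s = out[f"share_{item}"]
        out[f"exp_{item}"] = np.where(s.isna(), np.nan, (s > cuts[item]).astype(float))
    return OccupationExposureTable(
        table=out,
        share_cutoffs=cuts,
        item_ids=tuple(item_set.item_ids),
        median_over=median_over,
    )


def compute_strain(
    occ_exposures: OccupationExposureTable, item_set: ItemSet
) -> pd.DataFrame:
    """Combine item flags into demand/control indices and strain quadrants.

    Returns one row per (occupation_code, gender) with nullable-integer
    ``demand_index`` and ``control_index``, boolean ``high_demand``,
    ``low_control`` and ``job_strain``, and a ``strain_quadrant`` label.
    Index medians are taken across fully observed rows.
    """
    missing_items = [
        i for i in item_set.item_ids if i not in occ_exposures.item_ids
    ]
    if missing_items:
        raise ConfigError(f"occupation exposures lack item(s) {missing_items}")
    table = occ_exposures.table
    if len(table) == 0:
        raise ConfigError("empty occupation exposure table")

    demand_cols = [f"exp_{it.item_id}" for it in item_set.demand_items]
    control_cols = [f"exp_{it.item_id}" for it in item_set.control_items]

    out = table[["occupation_code", "gender"]].copy()
    # sum() would treat NaN as 0; a row with any missing flag must be missing.
    d_raw = table[demand_cols].sum(axis=1)
    c_raw = table[control_cols].sum(axis=1)
    complete = table[demand_cols + control_cols].notna().all(axis=1)
    out["demand_index"] = d_raw.where(complete).astype("Int64")
    out["control_index"] = c_raw.where(complete).astype("Int64")

    if not complete.any():
        raise ConfigError("no fully observed occupation rows; cannot take index medians")
    med_d = float(np.median(d_raw[complete]))
    med_c = float(np.median(c_raw[complete]))

    high_demand = pd.Series(d_raw > med_d, dtype="boolean").mask(~complete)
    low_control = pd.Series(c_raw > med_c, dtype="boolean").mask(~complete)
    out["high_demand"] = high_demand
    out["low_control"] = low_control

    quadrant = np.select(
        [
            high_demand.fillna(False) & low_control.fillna(False),
            high_demand.fillna(False) & ~low_control.fillna(True),
            ~high_demand.fillna(True) & low_control.fillna(False),
            ~high_demand.fillna(True) & ~low_control.fillna(True),
        ],
        QUADRANTS,
        default=None,
    )
    out["strain_quadrant"] = pd.Series(quadrant, index=out.index, dtype="object").where(
        complete
    )
    out["job_strain"] = (high_demand & low_control).mask(~complete)
    out.attrs["median_demand_index"] = med_d
    out.attrs["median_control_index"] = med_c
    return out


def build_codebook(
    item_set: ItemSet,
    strain: pd.DataFrame,
    share_cutoffs: Mapping[str, float],
) -> str:
    """Generate a plain-text codebook for the exported index table."""
    lines = [
        "# Codebook: Psychosocial Job Exposure Matrix and Job Strain Index",
        "",
        "One row per (occupation_code, gender). Shares are percentages of",
        "survey respondents exposed per item within the occupation's JEM",
        "group; exp_* flags dichotomize each share at the median share",
        "across (JEM group x gender) cells (1 = strictly above the median).",
        "",
        "| variable | type | range | construction |",
        "|---|---|---|---|",
        "| occupation_code | string | 4-digit occupation code | key |",
        "| gender | string | female / male | key |",
    ]
    for it in item_set:
        orientation = "high raw = adverse" if it.adverse_high else "reflected (high raw = protective)"
        lines.append(
            f"| share_{it.item_id} | float | 0-100 or missing | % exposed, "
            f"{it.dimension} item '{it.label or it.item_id}', scale "
            f"{it.scale_min}-{it.scale_max}, {orientation} |"
        )
    for it in item_set:
        cut = share_cutoffs.get(it.item_id)
        cut_txt = f"{cut:.4g}" if cut is not None else "n/a"
        lines.append(
            f"| exp_{it.item_id} | 0/1/missing | binary | share strictly > "
            f"median share ({cut_txt}) |"
        )
    n_demand = len(item_set.demand_items)
    n_control = len(item_set.control_items)
    med_d = strain.attrs.get("median_demand_index", "n/a")
    med_c = strain.attrs.get("median_control_index", "n/a")
    lines += [
        f"| demand_index | integer | 0-{n_demand} | count of exposed demand items |",
        f"| control_index | integer | 0-{n_control} | count of exposed control items "
        "(adversity coding: exposed = low control) |",
        f"| high_demand | boolean | | demand_index strictly > median ({med_d}) |",
        f"| low_control | boolean | | control_index strictly > median ({med_c}) |",
        "| strain_quadrant | string | high_strain / active / passive / low_strain |"
        " Karasek quadrant from (high_demand, low_control) |",
        "| job_strain | boolean | | high_demand AND low_control |",
        "",
    ]
    return "\n".join(lines)


def export_strain_index(
    strain: pd.DataFrame,
    code_shares: pd.DataFrame,
    path: str | Path,
    *,
    item_set: ItemSet,
    share_cutoffs: Mapping[str, float] | None = None,
    codebook_path: str | Path | None = None,
    decimals: int | None = 1,
    stata: bool = False,
) -> pd.DataFrame:
    """Write the flat JEM + strain-index table, plus an optional codebook.

    One row per (occupation_code, gender): share and exposure-flag columns
    followed by the strain variables. Shares are rounded only here (full
    precision is kept in memory). ``stata=True`` additionally writes a
    ``.dta`` next to the CSV. The strain table and share table must cover
    identical keys.
    """
    if len(strain) == 0:
        raise ConfigError("empty strain table; nothing to export")
    keys = ["occupation_code", "gender"]
    left = set(map(tuple, strain[keys].itertuples(index=False)))
    right = set(map(tuple, code_shares[keys].itertuples(index=False)))
    if left != right:
        raise ConfigError(
            f"strain and share tables are keyed differently "
            f"({len(left ^ right)} mismatching key(s))"
        )
    share_cols = [f"share_{i}" for i in item_set.item_ids]
    exp_cols = [f"exp_{i}" for i in item_set.item_ids]
    merged = code_shares[keys + share_cols + exp_cols].merge(
        strain, on=keys, validate="one_to_one"
    )
    merged = merged.sort_values(keys, ignore_index=True)
    if decimals is not None:
        merged[share_cols] = merged[share_cols].round(decimals)

    path = Path(path)
    merged.to_csv(path, index=False)
    if stata:
        stata_frame = merged.copy()
        for col in ("high_demand", "low_control", "job_strain"):
            stata_frame[col] = stata_frame[col].astype("Int64").astype(float)
        for col in ("demand_index", "control_index"):
            stata_frame[col] = stata_frame[col].astype(float)
        stata_frame.to_stata(path.with_suffix(".dta"), write_index=False)
    if codebook_path is not None:
        cuts = share_cutoffs or {}
        Path(codebook_path).write_text(
            build_codebook(item_set, strain, cuts), encoding="utf-8"
        )
    return merged


def read_strain_index(path: str | Path) -> pd.DataFrame:
    """Re-read an exported index table with the key dtypes preserved."""
    df = pd.read_csv(path, dtype={"occupation_code": str})
    for col in ("demand_index", "control_index"):
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    for col in ("high_demand", "low_control", "job_strain"):
        if col in df.columns:
            df[col] = df[col].map({"True": True, "False": False, True: True, False: False}).astype("boolean")
    return df
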