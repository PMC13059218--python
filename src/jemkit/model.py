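"""Model/Results facade over the full JEM + job-strain pipeline.

`JobStrainModel` binds survey microdata to an item set and a group map;
``fit()`` runs the whole estimation chain — individual median cut-offs,
dichotomization, cell-share aggregation, occupation-level median split,
Karasek quadrant classification — and returns a `JobStrainResults` holding
every intermediate product, binomial standard errors for the cell shares,
and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .items import ItemSet, JemGroupMap, default_item_set, load_group_map, load_item_set
from .jem import (
    CutoffTable,
    JemMatrix,
    build_jem,
    compute_cutoffs,
    dichotomize,
    read_survey,
)
from .strain import (
    OccupationExposureTable,
    compute_strain,
    export_strain_index,
)


class JobStrainModel:
    """Occupation-level job-strain estimation from ordinal survey microdata.

    Parameters
    ----------
    survey : DataFrame
        One row per respondent: respondent_id, wave, occupation_code
        (4-char string), gender, one ordinal column per item.
    group_map : JemGroupMap
        occupation_code -> JEM group assignment.
    item_set : ItemSet, optional
        Defaults to the packaged ten-item demand/control set.
    n_min : int
        Minimum non-missing respondents per cell; smaller cells are
        suppressed to missing (default 10).
    stratify_by_gender : bool
        Build separate cells per gender (default True; the index is
        designed to merge on occupation code *and* gender).
    median_over : {"cells", "codes"}
        Level of the occupation median split (default "cells").
    per_wave : bool
        Compute individual cut-offs within each survey wave instead of
        pooled over all waves (default False).
    """

    def __init__(
        self,
        survey: pd.DataFrame,
        group_map: JemGroupMap,
        item_set: ItemSet | None = None,
        *,
        n_min: int = 10,
        stratify_by_gender: bool = True,
        median_over: str = "cells",
        per_wave: bool = False,
    ) -> None:
        self.survey = survey
        self.group_map = group_map
        self.item_set = item_set or default_item_set()
        self.n_min = n_min
        self.stratify_by_gender = stratify_by_gender
        self.median_over = median_over
        self.per_wave = per_wave

    @classmethod
    def from_csv(
        cls,
        survey_path: str | Path,
        group_map_path: str | Path,
        item_config_path: str | Path | None = None,
        **kwargs,
    ) -> "JobStrainModel":
        """Build the model straight from the CSV/YAML file formats."""
        item_set = (
            load_item_set(item_config_path) if item_config_path else default_item_set()
        )
        return cls(
            survey=read_survey(survey_path, item_set),
            group_map=load_group_map(group_map_path),
            item_set=item_set,
            **kwargs,
        )

    def fit(self) -> "JobStrainResults":
        """Run the full pipeline and return the results object."""
        cutoffs = compute_cutoffs(self.survey, self.item_set, per_wave=self.per_wave)
        flags = dichotomize(
            self.survey, cutoffs, self.item_set,
            valid_codes=self.group_map.entries.keys(),
        )
        jem = build_jem(
            flags,
            self.group_map,
            self.item_set,
            stratify_by_gender=self.stratify_by_gender,
            n_min=self.n_min,
        )
        from .strain import assign_occupation_exposure

        occ = assign_occupation_exposure(
            jem, self.group_map, self.item_set, median_over=self.median_over
        )
        strain = compute_strain(occ, self.item_set)
        return JobStrainResults(
            model=self,
            cutoffs=cutoffs,
            flags=flags,
            jem=jem,
            occupation_exposure=occ,
            strain=strain,
        )


@dataclass
class JobStrainResults:
    """Fitted JEM + job-strain index with uncertainties and export helpers."""

    model: JobStrainModel
    cutoffs: CutoffTable | dict[int, CutoffTable]
    flags: pd.DataFrame
    jem: JemMatrix
    occupation_exposure: OccupationExposureTable
    strain: pd.DataFrame

    @property
    def code_shares(self) -> pd.DataFrame:
        """Per-(occupation_code, gender) shares and binary exposure flags."""
        return self.occupation_exposure.table

    @property
    def index_table(self) -> pd.DataFrame:
        """The flat exportable JEM + JSI table, full precision."""
        keys = ["occupation_code", "gender"]
        items = self.model.item_set.item_ids
        cols = keys + [f"share_{i}" for i in items] + [f"exp_{i}" for i in items]
        return self.code_shares[cols].merge(self.strain, on=keys).sort_values(
            keys, ignore_index=True
        )

    def share_standard_errors(self) -> pd.DataFrame:
        """Binomial standard errors (percentage points) for each cell share.

        SE = 100 * sqrt(p_hat (1 - p_hat) / n) with p_hat the cell
        proportion exposed; suppressed cells stay missing.
        """
        out = self.jem.table[["jem_group_id", "gender"]].copy()
        for item in self.model.item_set.item_ids:
            p = self.jem.table[f"share_{item}"] / 100.0
            n = self.jem.table[f"n_{item}"]
            out[f"se_{item}"] = 100.0 * np.sqrt(p * (1 - p) / n)
        return out

    def summary(self) -> str:
        """Human-readable fit summary (statsmodels-style text block)."""
        model = self.model
        items = model.item_set
        n_resp = len(model.survey)
        lines = [
            "Occupational Job Strain Index",
            "=" * 66,
            f"Respondents:        {n_resp}",
            f"Waves:              {sorted(model.survey['wave'].unique().tolist())}",
            f"Items:              {len(items)} "
            f"({len(items.demand_items)} demand, {len(items.control_items)} control)",
            f"JEM groups:         {model.group_map.group_count} "
            f"over {model.group_map.code_count} occupation codes",
            f"Cells built:        {self.jem.n_cells} "
            f"(n_min = {model.n_min})",
            "",
            "Individual median cut-offs (aligned scale)",
            "-" * 66,
        ]
        if isinstance(self.cutoffs, dict):
            for wave, table in self.cutoffs.items():
                lines.append(f"  wave {wave}:")
                for item_id, cut in table.cutoffs.items():
                    lines.append(f"    {item_id:<24} {cut:>5.1f}  (n={table.n_used[item_id]})")
        else:
            for item_id, cut in self.cutoffs.cutoffs.items():
                lines.append(
                    f"  {item_id:<24} {cut:>5.1f}  (n={self.cutoffs.n_used[item_id]})"
                )
        lines += ["", "Occupation median-of-shares cut-offs (%)", "-" * 66]
        for item_id, cut in self.occupation_exposure.share_cutoffs.items():
            lines.append(f"  {item_id:<24} {cut:>6.2f}")
        counts = self.strain["strain_quadrant"].value_counts(dropna=True)
        n_rows = len(self.strain)
        lines += ["", "Karasek quadrants (occupation x gender rows)", "-" * 66]
        for quadrant in ("high_strain", "active", "passive", "low_strain"):
            k = int(counts.get(quadrant, 0))
            lines.append(f"  {quadrant:<14} {k:>6}  ({100.0 * k / n_rows:5.1f}%)")
        n_missing = int(self.strain["strain_quadrant"].isna().sum())
        lines.append(f"  {'(missing)':<14} {n_missing:>6}")
        return "\n".join(lines)

    def save(
        self,
        out_dir: str | Path,
        *,
        decimals: int | None = 1,
        stata: bool = False,
    ) -> dict[str, Path]:
        """Write index CSV, group-level matrix, codebook and build log."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "index": out_dir / "job_strain_index.csv",
            "matrix": out_dir / "jem_groups.csv",
            "codebook": out_dir / "codebook.md",
            "log": out_dir / "build_log.txt",
        }
        export_strain_index(
            self.strain,
            self.code_shares,
            paths["index"],
            item_set=self.model.item_set,
            share_cutoffs=self.occupation_exposure.share_cutoffs,
            codebook_path=paths["codebook"],
            decimals=decimals,
            stata=stata,
        )
        self.jem.to_csv(paths["matrix"], decimals=decimals)
        paths["log"].write_text(self.jem.build_log(), encoding="utf-8")
        return paths
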