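"""Synthetic survey, register, group-map and crosswalk generators.

The real microdata behind a national job exposure matrix sit behind
restricted-access agreements, so every downstream stage here is exercised on
synthetic tables with *known ground truth*. The survey generator controls
the exact probability that a respondent's aligned response exceeds the
intended median cut-off: responses are drawn two-sided around the cut-off
(a uniform draw from the admissible values above it when "exposed", from
the values at or below it otherwise), so the exceedance probability per
(JEM group, gender, item) cell equals ``true_exposure_prob`` by
construction, and recovered exposure shares can be compared to truth with
plain binomial error bounds.

Default scenario dimensions mirror a national five-wave survey programme:
333 occupation codes pooled into 268 JEM groups, waves 2006-2019, and 16
respondents per (group x gender x wave) cell for a total of ~43k
respondents. Per-cell true probabilities are drawn U(0.10, 0.45), which
keeps the pooled response median at the intended cut-off. Missingness is
injected completely at random (MCAR), so complete-case estimates stay
unbiased in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .items import (
    GENDERS,
    ConfigError,
    ItemSet,
    JemGroupMap,
    default_item_set,
    normalize_code,
    write_group_map,
    write_item_set,
)
from .linkage import CrosswalkKey

DEFAULT_WAVES = (2006, 2009, 2013, 2016, 2019)

ProbKey = tuple[str, str, str]  # (jem_group_id, gender, item_id)


@dataclass(frozen=True)
class SimulationScenario:
    """Complete specification of one synthetic survey world.

    ``true_exposure_prob`` maps (jem_group_id, gender, item_id) to the
    probability that an aligned response strictly exceeds
    ``intended_cutoff``; cells/items missing from the mapping default to
    ``default_prob``.
    """

    codes: tuple[str, ...]
    group_map: JemGroupMap
    waves: tuple[int, ...] = DEFAULT_WAVES
    n_per_cell: int = 16
    true_exposure_prob: Mapping[ProbKey, float] = field(default_factory=dict)
    default_prob: float = 0.25
    scale_min: int = 1
    scale_max: int = 5
    intended_cutoff: int = 2
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.codes:
            raise ConfigError("scenario needs at least one occupation code")
        if self.group_map.code_count < len(set(self.codes)):
            raise ConfigError("every scenario code must appear in the group map")
        if self.n_per_cell < 1:
            raise ConfigError("n_per_cell must be >= 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigError("missing_rate must lie in [0, 1]")
        if not 0.0 <= self.default_prob <= 1.0:
            raise ConfigError("default_prob must lie in [0, 1]")
        for key, p in self.true_exposure_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"true_exposure_prob{key} = {p} outside [0, 1]")
        if not self.scale_min <= self.intended_cutoff < self.scale_max:
            raise ConfigError(
                "intended_cutoff must satisfy scale_min <= cutoff < scale_max"
            )

    @property
    def n_codes(self) -> int:
        return len(set(self.codes))

    @property
    def n_groups(self) -> int:
        return self.group_map.group_count

    def prob(self, group: str, gender: str, item_id: str) -> float:
        return float(
            self.true_exposure_prob.get((group, gender, item_id), self.default_prob)
        )

    def with_probs(self, overrides: Mapping[ProbKey, float]) -> "SimulationScenario":
        merged = dict(self.true_exposure_prob)
        merged.update(overrides)
        return replace(self, true_exposure_prob=merged)


def make_codes(n_codes: int, rng: np.random.Generator) -> tuple[str, ...]:
    """Draw ``n_codes`` distinct 4-digit codes, leading zeros included."""
    if n_codes < 1 or n_codes > 10_000:
        raise ConfigError("n_codes must be in [1, 10000]")
    drawn = rng.choice(10_000, size=n_codes, replace=False)
    return tuple(sorted(normalize_code(int(c)) for c in drawn))


def make_group_map(
    codes: Sequence[str], n_groups: int, rng: np.random.Generator
) -> JemGroupMap:
    """Partition codes into ``n_groups`` non-empty JEM groups at random."""
    codes = [normalize_code(c) for c in codes]
    if not 1 <= n_groups <= len(codes):
        raise ConfigError("need 1 <= n_groups <= n_codes")
    width = len(str(n_groups))
    groups = [f"G{i + 1:0{width}d}" for i in range(n_groups)]
    # First one code per group (guarantees non-empty), rest assigned at random.
    shuffled = list(codes)
    rng.shuffle(shuffled)
    assignment = {code: groups[i] for i, code in enumerate(shuffled[:n_groups])}
    for code in shuffled[n_groups:]:
        assignment[code] = groups[rng.integers(n_groups)]
    return JemGroupMap.from_pairs(assignment.items())


def random_scenario(
    seed: int,
    *,
    n_codes: int = 333,
    n_groups: int = 268,
    waves: Sequence[int] = DEFAULT_WAVES,
    n_per_cell: int = 16,
    prob_range: tuple[float, float] = (0.10, 0.45),
    missing_rate: float = 0.05,
    scale_min: int = 1,
    scale_max: int = 5,
    intended_cutoff: int = 2,
    item_set: ItemSet | None = None,
) -> SimulationScenario:
    """Build a scenario with random codes, groups and cell probabilities.

    Defaults reproduce the paper-scale structure (333 codes, 268 groups,
    five waves, ~43k respondents).
    """
    item_set = item_set or default_item_set()
    rng = np.random.default_rng(seed)
    codes = make_codes(n_codes, rng)
    group_map = make_group_map(codes, n_groups, rng)
    lo, hi = prob_range
    probs: dict[ProbKey, float] = {}
    for group in group_map.groups:
        for gender in GENDERS:
            for item in item_set.item_ids:
                probs[(group, gender, item)] = float(rng.uniform(lo, hi))
    return SimulationScenario(
        codes=codes,
        group_map=group_map,
        waves=tuple(int(w) for w in waves),
        n_per_cell=n_per_cell,
        true_exposure_prob=probs,
        scale_min=scale_min,
        scale_max=scale_max,
        intended_cutoff=intended_cutoff,
        missing_rate=missing_rate,
        seed=seed,
    )


def generate_survey(
    scenario: SimulationScenario,
    item_set: ItemSet | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate survey microdata with exact per-cell exceedance probabilities.

    Returns one row per respondent: ``respondent_id``, ``wave``,
    ``occupation_code``, ``gender``, and one ordinal column per item
    (NaN = item nonresponse). Fully deterministic given scenario + seed.
    """
    item_set = item_set or default_item_set()
    for (_, _, item_id) in scenario.true_exposure_prob:
        if item_id not in item_set:
            raise ConfigError(f"true_exposure_prob references unknown item {item_id!r}")
    for it in item_set:
        if not (it.scale_min == scenario.scale_min and it.scale_max == scenario.scale_max):
            raise ConfigError(
                f"item {it.item_id!r} scale does not match the scenario scale"
            )
    rng = np.random.default_rng(scenario.seed if seed is None else seed)

    codes = sorted(set(scenario.codes))
    group_of = {c: scenario.group_map.group_of(c) for c in codes}

    rows_code: list[str] = []
    rows_group: list[str] = []
    rows_gender: list[str] = []
    rows_wave: list[int] = []
    for group in scenario.group_map.groups:
        group_codes = scenario.group_map.codes_in_group(group)
        group_codes = [c for c in group_codes if c in group_of]
        for gender in GENDERS:
            for wave in scenario.waves:
                picked = rng.choice(len(group_codes), size=scenario.n_per_cell)
                rows_code.extend(group_codes[i] for i in picked)
                rows_group.extend([group] * scenario.n_per_cell)
                rows_gender.extend([gender] * scenario.n_per_cell)
                rows_wave.extend([wave] * scenario.n_per_cell)

    n = len(rows_code)
    df = pd.DataFrame(
        {
            "respondent_id": [f"R{i:07d}" for i in range(n)],
            "wave": np.asarray(rows_wave, dtype=int),
            "occupation_code": rows_code,
            "gender": rows_gender,
        }
    )

    cut = scenario.intended_cutoff
    lo, hi = scenario.scale_min, scenario.scale_max
    group_arr = np.asarray(rows_group)
    gender_arr = np.asarray(rows_gender)
    for item in item_set:
        p = np.fromiter(
            (
                scenario.prob(g, s, item.item_id)
                for g, s in zip(group_arr, gender_arr)
            ),
            dtype=float,
            count=n,
        )
        exposed = rng.random(n) < p
        # Aligned response: uniform over values above the cut-off when
        # exposed, over values at/below it otherwise -- exceedance
        # probability is exactly p.
        aligned = np.where(
            exposed,
            rng.integers(cut + 1, hi + 1, size=n),
            rng.integers(lo, cut + 1, size=n),
        )
        raw = aligned if item.adverse_high else lo + hi - aligned
        values = raw.astype(float)
        if scenario.missing_rate > 0:
            values[rng.random(n) < scenario.missing_rate] = np.nan
        df[item.item_id] = values
    return df


def truth_table(
    scenario: SimulationScenario, item_set: ItemSet | None = None
) -> pd.DataFrame:
    """Ground-truth exposure probabilities, one row per (group, gender, item)."""
    item_set = item_set or default_item_set()
    rows = [
        (group, gender, item, scenario.prob(group, gender, item))
        for group in scenario.group_map.groups
        for gender in GENDERS
        for item in item_set.item_ids
    ]
    return pd.DataFrame(
        rows, columns=["jem_group_id", "gender", "item_id", "true_p"]
    )


def generate_register(
    n_persons: int,
    codes: Sequence[str],
    unmatched_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate register-style microdata (person_id, occupation_code, gender).

    A Bernoulli(``unmatched_fraction``) share of rows gets a code outside
    the supplied list, to exercise merge behaviour on codes the JEM does
    not cover.
    """
    if not codes:
        raise ConfigError("codes must be non-empty")
    if not 0.0 <= unmatched_fraction <= 1.0:
        raise ConfigError("unmatched_fraction must lie in [0, 1]")
    codes = sorted({normalize_code(c) for c in codes})
    known = set(codes)
    unknown_pool = sorted(
        normalize_code(i) for i in range(10_000) if normalize_code(i) not in known
    )
    if unmatched_fraction > 0 and not unknown_pool:
        raise ConfigError("code list covers the whole code space; cannot plant misses")
    rng = np.random.default_rng(seed)
    unmatched = rng.random(n_persons) < unmatched_fraction
    code_col = np.empty(n_persons, dtype=object)
    n_miss = int(unmatched.sum())
    if n_miss:
        code_col[unmatched] = rng.choice(unknown_pool, size=n_miss)
    n_hit = n_persons - n_miss
    if n_hit:
        code_col[~unmatched] = rng.choice(codes, size=n_hit)
    return pd.DataFrame(
        {
            "person_id": [f"P{i:07d}" for i in range(n_persons)],
            "occupation_code": code_col,
            "gender": rng.choice(GENDERS, size=n_persons),
        }
    )


def generate_crosswalk(
    codes_source: Sequence[str],
    codes_target: Sequence[str],
    ambiguous_fraction: float = 0.0,
    seed: int = 0,
) -> CrosswalkKey:
    """Generate a mostly one-to-one source->target code key.

    A Bernoulli(``ambiguous_fraction``) share of source codes maps to two
    targets, mimicking the genuinely ambiguous correspondences of real
    classification revisions, for which no official key exists.
    """
    if not codes_source or not codes_target:
        raise ConfigError("both code lists must be non-empty")
    if not 0.0 <= ambiguous_fraction <= 1.0:
        raise ConfigError("ambiguous_fraction must lie in [0, 1]")
    src = sorted({normalize_code(c) for c in codes_source})
    tgt = sorted({normalize_code(c) for c in codes_target})
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = []
    for s in src:
        primary = tgt[rng.integers(len(tgt))]
        pairs.append((s, primary))
        if len(tgt) > 1 and rng.random() < ambiguous_fraction:
            alternatives = [t for t in tgt if t != primary]
            pairs.append((s, alternatives[rng.integers(len(alternatives))]))
    return CrosswalkKey.from_pairs(pairs, provenance=f"synthetic key (seed={seed})")


def write_fixture_dir(
    out_dir: str | Path,
    scenario: SimulationScenario,
    item_set: ItemSet | None = None,
    *,
    n_register: int = 2000,
    unmatched_fraction: float = 0.10,
    ambiguous_fraction: float = 0.10,
) -> dict[str, Path]:
    """Write a complete fixture directory of plain CSV/YAML inputs.

    Emits survey.csv, register.csv, group_map.csv, crosswalk.csv, truth.csv
    and items.yaml -- the same dialects the builder consumes.
    """
    item_set = item_set or default_item_set()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(scenario.seed + 1)

    paths = {name: out_dir / f"{name}.csv" for name in
             ("survey", "register", "group_map", "crosswalk", "truth")}
    generate_survey(scenario, item_set).to_csv(paths["survey"], index=False)
    generate_register(
        n_register, scenario.codes, unmatched_fraction, seed=scenario.seed + 2
    ).to_csv(paths["register"], index=False)
    write_group_map(scenario.group_map, paths["group_map"])
    source_codes = make_codes(len(scenario.codes), rng)
    generate_crosswalk(
        source_codes, scenario.codes, ambiguous_fraction, seed=scenario.seed + 3
    ).to_csv(paths["crosswalk"])
    truth_table(scenario, item_set).to_csv(paths["truth"], index=False)
    items_path = out_dir / "items.yaml"
    write_item_set(item_set, items_path)
    paths["items"] = items_path
    return paths
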