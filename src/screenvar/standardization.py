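"""Indirect age standardisation of screening participation.

Australia's National Bowel Cancer Screening Program (NBCSP) mails iFOBT kits
to residents aged 50-74, but which single ages receive an invitation depends
on the calendar year: the program started with quinquennial ages in 2015 and
expanded to all even ages 50-74 by 2019.  Comparing areas therefore requires
expected counts that respect both the local age structure and the
year-varying eligibility.  This module provides:

* the eligibility schedule (calendar year -> eligible single ages),
* participation rates (screened / invitees, as a percentage),
* national age- and period-specific screening rates,
* indirectly standardised expected counts E_i and the standardised
  participation ratio SPR_i = observed_i / E_i,
* the inclusion filters (small populations, islands, suppressed records).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ELIGIBILITY_SCHEDULE",
    "PERIODS",
    "AGE_BANDS",
    "ScreeningCounts",
    "participation_rate",
    "round_half_up",
    "national_age_rates",
    "single_age_populations",
    "expected_counts",
    "compute_spr",
    "apply_exclusions",
    "load_national_margins",
]

#: Single ages invited to screen in each calendar year.  The program was
#: restricted to quinquennial ages in 2015 and expanded progressively until
#: all even ages 50-74 were invited from 2019 onward.
ELIGIBILITY_SCHEDULE: Mapping[int, tuple[int, ...]] = {
    2015: (50, 55, 60, 65, 70, 74),
    2016: (50, 55, 60, 64, 65, 70, 72, 74),
    2017: (50, 54, 55, 58, 60, 64, 68, 70, 72, 74),
    2018: (50, 54, 58, 60, 62, 64, 66, 68, 70, 72, 74),
    2019: (50, 52, 54, 56, 58, 60, 62, 64, 66, 68, 70, 72, 74),
    2020: (50, 52, 54, 56, 58, 60, 62, 64, 66, 68, 70, 72, 74),
}

#: Closed two-calendar-year reporting windows.
PERIODS: Mapping[str, tuple[int, int]] = {
    "2015-2016": (2015, 2016),
    "2017-2018": (2017, 2018),
    "2019-2020": (2019, 2020),
}

#: Five-year age bands covering the screening-eligible range.
AGE_BANDS: tuple[tuple[int, int], ...] = (
    (50, 54),
    (55, 59),
    (60, 64),
    (65, 69),
    (70, 74),
)


def band_column(lo: int, hi: int) -> str:
    return f"pop_{lo}_{hi}"


@dataclass
class ScreeningCounts:
    """Observed screening counts.

    ``area``: one row per area x period with columns ``area_id, period,
    invitees, screened`` (optionally a boolean ``suppressed``).
    ``national``: one row per single age x calendar year with columns
    ``age, year, invitees, screened``.
    """

    area: pd.DataFrame
    national: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, df, keys in (
            ("area", self.area, ["area_id", "period"]),
            ("national", self.national, ["age", "year"]),
        ):
            if df is None or len(df) == 0:
                continue
            missing = {*keys, "invitees", "screened"} - set(df.columns)
            if missing:
                raise ValueError(f"{name} counts missing columns {sorted(missing)}")
            if (df["invitees"] < 0).any() or (df["screened"] < 0).any():
                raise ValueError(f"{name} counts contain negative values")
            bad = df["screened"] > df["invitees"]
            if bad.any():
                rows = df.index[bad].tolist()[:5]
                raise ValueError(
                    f"{name} counts have screened > invitees at rows {rows}"
                )


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, as printed statistical tables do."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def participation_rate(invitees: int, screened: int) -> float:
    """Percentage of invitees who returned a completed kit.

    Returned at full precision; presentation rounding (one decimal,
    half-up) is left to :func:`round_half_up`.
    """
    if invitees <= 0:
        raise ValueError("participation rate undefined: zero invitees")
    if screened < 0 or screened > invitees:
        raise ValueError(f"invalid counts: screened={screened}, invitees={invitees}")
    return 100.0 * screened / invitees


def national_age_rates(counts: ScreeningCounts) -> pd.DataFrame:
    """National screening rate per single age and calendar year.

    Returns a DataFrame ``(age, year, rate)``; cells with zero invitees get
    ``rate = NaN`` (missing, not zero).
    """
    nat = counts.national
    if len(nat) == 0:
        raise ValueError("no national counts available")
    if (nat["invitees"] < 0).any() or (nat["screened"] < 0).any():
        raise ValueError("negative counts in national table")
    out = nat[["age", "year"]].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = nat["screened"].to_numpy(float) / nat["invitees"].to_numpy(float)
    rate[nat["invitees"].to_numpy() == 0] = np.nan
    out["rate"] = rate
    return out


def single_age_populations(areas: pd.DataFrame) -> pd.DataFrame:
    """Expand banded populations to single ages by uniform split.

    Eligibility operates on single ages while populations come in 5-year
    bands, so each band is spread evenly over its five ages.  Returns a
    DataFrame indexed by area_id with one column per age 50..74.
    """
    cols = {}
    for lo, hi in AGE_BANDS:
        col = band_column(lo, hi)
        if col not in areas.columns:
            raise ValueError(f"area table missing population band column {col!r}")
        per_age = areas[col].to_numpy(float) / (hi - lo + 1)
        for age in range(lo, hi + 1):
            cols[age] = per_age
    out = pd.DataFrame(cols, index=areas["area_id"].to_numpy())
    out.index.name = "area_id"
    return out


def expected_counts(
    areas: pd.DataFrame,
    schedule: Mapping[int, Sequence[int]],
    rates: pd.DataFrame,
    period: str,
    periods: Mapping[str, tuple[int, int]] = PERIODS,
) -> pd.DataFrame:
    """Indirectly standardised expected screens per area for one period.

    E_i = sum over the period's years, and over that year's eligible ages,
    of (area population at that age) x (national rate at that age/year).
    A missing national rate for an eligible cell is a hard error.
    """
    y0, y1 = periods[period]
    pops = single_age_populations(areas)
    rate_lookup = {(int(a), int(y)): r for a, y, r in rates[["age", "year", "rate"]].itertuples(index=False)}
    E = np.zeros(len(pops))
    for year in range(y0, y1 + 1):
        for age in schedule[year]:
            key = (int(age), int(year))
            if key not in rate_lookup or not np.isfinite(rate_lookup[key]):
                raise KeyError(f"no national rate for eligible cell age={age}, year={year}")
            E += pops[age].to_numpy() * rate_lookup[key]
    return pd.DataFrame({"area_id": pops.index, "period": period, "expected": E})


def compute_spr(observed: ScreeningCounts, expected: pd.DataFrame) -> pd.DataFrame:
    """Standardised participation ratio: observed / expected screens.

    E = 0 with no observed screens yields a missing SPR; E = 0 with
    observed screens is inconsistent and raises.
    """
    obs = observed.area[["area_id", "period", "screened"]]
    merged = obs.merge(expected, on=["area_id", "period"], how="outer", indicator=True)
    mismatched = merged.loc[merged["_merge"] != "both", "area_id"].tolist()
    if mismatched:
        raise ValueError(f"observed/expected key mismatch for areas {mismatched[:10]}")
    E = merged["expected"].to_numpy(float)
    y = merged["screened"].to_numpy(float)
    bad = (E == 0) & (y > 0)
    if bad.any():
        raise ValueError(
            f"zero expected count with positive observed screens for "
            f"{merged.loc[bad, 'area_id'].tolist()[:10]}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        spr = np.where(E > 0, y / np.where(E > 0, E, 1.0), np.nan)
    return pd.DataFrame(
        {"area_id": merged["area_id"], "period": merged["period"], "spr": spr}
    )


def apply_exclusions(
    areas: pd.DataFrame,
    counts: ScreeningCounts,
    min_mean_pop: float = 5.0,
    schedule: Mapping[int, Sequence[int]] = ELIGIBILITY_SCHEDULE,
    periods: Mapping[str, tuple[int, int]] = PERIODS,
) -> tuple[pd.DataFrame, ScreeningCounts, list[dict]]:
    """Apply the study's inclusion filters.

    Removes areas whose mean annual eligible population is below
    ``min_mean_pop``, areas flagged as islands (boolean ``island`` column),
    and count records flagged ``suppressed``.  Returns the filtered area
    table and counts plus a log of removals by reason.
    """
    log: list[dict] = []
    pops = single_age_populations(areas)
    used_periods = sorted(set(counts.area["period"])) or list(periods)
    years = sorted({y for p in used_periods for y in range(periods[p][0], periods[p][1] + 1)})
    elig = np.zeros(len(pops))
    for year in years:
        elig += pops[list(schedule[year])].sum(axis=1).to_numpy()
    mean_annual = elig / max(len(years), 1)

    small = set(pops.index[mean_annual < min_mean_pop])
    if small:
        log.append({"reason": "small_population", "n_areas": len(small),
                    "area_ids": sorted(small)})
    islands: set = set()
    if "island" in areas.columns:
        islands = set(areas.loc[areas["island"].astype(bool), "area_id"]) - small
        if islands:
            log.append({"reason": "island", "n_areas": len(islands),
                        "area_ids": sorted(islands)})
    drop = small | islands

    area_counts = counts.area
    n_suppressed = 0
    suppressed_screens = 0
    if "suppressed" in area_counts.columns:
        mask = area_counts["suppressed"].astype(bool)
        n_suppressed = int(mask.sum())
        suppressed_screens = int(area_counts.loc[mask, "screened"].sum())
        if n_suppressed:
            total_screens = int(area_counts["screened"].sum())
            log.append({
                "reason": "suppressed_record",
                "n_records": n_suppressed,
                "screened_excluded": suppressed_screens,
                "screened_fraction": suppressed_screens / max(total_screens, 1),
            })
        area_counts = area_counts.loc[~mask]

    kept_areas = areas.loc[~areas["area_id"].isin(drop)].reset_index(drop=True)
    kept_counts = area_counts.loc[~area_counts["area_id"].isin(drop)].reset_index(drop=True)
    unknown = set(kept_counts["area_id"]) - set(kept_areas["area_id"])
    if unknown:
        log.append({"reason": "unknown_area", "n_records":
                    int(kept_counts["area_id"].isin(unknown).sum()),
                    "area_ids": sorted(unknown)})
        kept_counts = kept_counts.loc[~kept_counts["area_id"].isin(unknown)].reset_index(drop=True)
    cols = [c for c in kept_counts.columns if c != "suppressed"]
    new_counts = ScreeningCounts(area=kept_counts[cols], national=counts.national)
    return kept_areas, new_counts, log


def load_national_margins() -> pd.DataFrame:
    """Published NBCSP participation margins, 2015-2020.

    Invitee and screened counts by state/territory, area-disadvantage
    quintile and remoteness category for the three two-year periods, with
    the participation rates as printed (one decimal).
    """
    with resources.files("screenvar.data").joinpath("nbcsp_table1.csv").open() as fh:
        return pd.read_csv(fh)
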