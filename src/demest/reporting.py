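"""Published-results tables: parsing, hierarchy aggregation and derived stats.

Ships transcriptions of the headline global and super-region results rows
(2019 population, fertility, livebirths, mortality, life expectancy, HALE
and deaths) plus the observed-versus-expected life expectancy summary by
SDI quintile, as CSVs with the original "value (lower to upper)" strings.
Parsing accepts middle-dot or period decimals, thin-space or plain-space
thousands separators, and "a (b to c)" / "a (b–c)" interval styles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResultsTableRow",
    "HierarchyNode",
    "gbd_hierarchy",
    "parse_value_ui",
    "read_results_table",
    "aggregate_check",
    "derived_indicators",
    "load_table",
    "SUPER_REGIONS",
    "GBD_REGIONS",
]

SUPER_REGIONS = (
    "Central Europe, eastern Europe, and central Asia",
    "High income",
    "Latin America and Caribbean",
    "North Africa and Middle East",
    "South Asia",
    "Southeast Asia, east Asia, and Oceania",
    "Sub-Saharan Africa",
)

GBD_REGIONS: dict[str, tuple[str, ...]] = {
    "Central Europe, eastern Europe, and central Asia": (
        "Central Asia", "Central Europe", "Eastern Europe",
    ),
    "High income": (
        "Australasia", "High-income Asia Pacific", "High-income North America",
        "Southern Latin America", "Western Europe",
    ),
    "Latin America and Caribbean": (
        "Andean Latin America", "Caribbean", "Central Latin America",
        "Tropical Latin America",
    ),
    "North Africa and Middle East": ("North Africa and Middle East",),
    "South Asia": ("South Asia",),
    "Southeast Asia, east Asia, and Oceania": ("East Asia", "Oceania", "Southeast Asia"),
    "Sub-Saharan Africa": (
        "Central sub-Saharan Africa", "Eastern sub-Saharan Africa",
        "Southern sub-Saharan Africa", "Western sub-Saharan Africa",
    ),
}


@dataclass
class HierarchyNode:
    name: str
    level: str
    parent: str | None
    children: list[str] = field(default_factory=list)


def gbd_hierarchy() -> dict[str, HierarchyNode]:
    """The global / super-region / region location tree (7 + 21 preset)."""
    nodes = {"Global": HierarchyNode("Global", "global", None)}
    for sr in SUPER_REGIONS:
        nodes[sr] = HierarchyNode(sr, "super-region", "Global")
        nodes["Global"].children.append(sr)
        for r in GBD_REGIONS[sr]:
            key = r if r not in nodes else f"{r} (region)"
            nodes[key] = HierarchyNode(key, "region", sr)
            nodes[sr].children.append(key)
    n_sr = sum(1 for n in nodes.values() if n.level == "super-region")
    n_r = sum(1 for n in nodes.values() if n.level == "region")
    assert n_sr == 7 and n_r == 21
    return nodes


@dataclass
class ResultsTableRow:
    location: str
    level: str
    parent: str | None
    metric: str
    year: int
    value: float
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None:
            if not (self.lower <= self.value <= self.upper):
                raise ValueError(
                    f"{self.location}/{self.metric}: value {self.value} outside "
                    f"UI [{self.lower}, {self.upper}]"
                )


_NUM_CLEAN = str.maketrans({"·": ".", " ": "", " ": "", " ": "", " ": "",
                            "−": "-", "–": "-"})


def _to_float(s: str) -> float:
    s = s.strip().translate(_NUM_CLEAN).replace("%", "")
    if s in ("", "-"):
        raise ValueError("empty numeric field")
    return float(s)


_UI_RE = re.compile(r"^(?P<v>[^()]+?)\s*\(\s*(?P<lo>.+?)\s*(?:to|–|—)\s*(?P<hi>.+?)\s*\)\s*$")


def parse_value_ui(s: str) -> tuple[float, float | None, float | None]:
    """Parse "73·5 (72·8–74·3)" or "1·1% (1·0 to 1·3)" into (value, lo, hi)."""
    s = str(s).strip()
    m = _UI_RE.match(s)
    if m is None:
        if "(" in s:
            raise ValueError(f"malformed UI string: {s!r}")
        return _to_float(s), None, None
    lo_raw = m.group("lo")
    # an en-dash may act as the range separator between negative numbers;
    # the regex above uses the first separator occurrence, which is correct
    # for the shipped tables (negative bounds always use the true minus sign)
    return _to_float(m.group("v")), _to_float(lo_raw), _to_float(m.group("hi"))


def read_results_table(path_or_buf, hierarchy: dict[str, HierarchyNode] | None = None) -> list[ResultsTableRow]:
    """Read a transcription CSV (location, level, metric, year, value_str).

    UI strings are parsed; locations are validated against the hierarchy
    preset when one is supplied.
    """
    df = pd.read_csv(path_or_buf)
    required = {"location", "level", "metric", "year", "value_str"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"table missing columns {sorted(missing)}")
    if hierarchy is not None:
        unknown = set(df["location"]) - set(hierarchy)
        if unknown:
            raise ValueError(f"unknown locations {sorted(unknown)}")
    rows = []
    for rec in df.itertuples(index=False):
        v, lo, hi = parse_value_ui(rec.value_str)
        parent = None
        if hierarchy is not None and rec.location in hierarchy:
            parent = hierarchy[rec.location].parent
        rows.append(
            ResultsTableRow(
                location=rec.location, level=rec.level, parent=parent,
                metric=rec.metric, year=int(rec.year), value=v, lower=lo, upper=hi,
            )
        )
    return rows


def write_results_table(rows: Sequence[ResultsTableRow], path) -> None:
    """Inverse of read_results_table (plain period decimals)."""
    recs = []
    for r in rows:
        if r.lower is not None:
            vs = f"{r.value} ({r.lower} to {r.upper})"
        else:
            vs = f"{r.value}"
        recs.append({"location": r.location, "level": r.level, "metric": r.metric,
                     "year": r.year, "value_str": vs})
    pd.DataFrame(recs).to_csv(path, index=False)


ADDITIVE_METRICS = {"population", "population_15_64", "population_under5",
                    "livebirths", "deaths", "under5_deaths"}


def aggregate_check(
    rows: Sequence[ResultsTableRow],
    hierarchy: dict[str, HierarchyNode],
    metric: str,
    year: int | None = None,
) -> pd.DataFrame:
    """Child sums per parent with absolute and relative discrepancies.

    Only declared-additive count metrics are accepted.
    """
    if metric not in ADDITIVE_METRICS:
        raise ValueError(f"{metric!r} is not declared additive")
    sel = [r for r in rows if r.metric == metric and (year is None or r.year == year)]
    by_loc = {(r.location, r.year): r.value for r in sel}
    out = []
    locs_present = {r.location for r in sel}
    # a parent is checked only when at least one of its children is present;
    # a partially transcribed sibling set is then an error
    parents = {
        loc for loc in locs_present
        if hierarchy[loc].children and any(k in locs_present for k in hierarchy[loc].children)
    }
    for p in sorted(parents):
        years = sorted({y for (l, y) in by_loc if l == p})
        for y in years:
            kids = hierarchy[p].children
            missing = [k for k in kids if (k, y) not in by_loc]
            if missing:
                raise ValueError(f"missing children of {p} for {metric}/{y}: {missing}")
            child_sum = sum(by_loc[(k, y)] for k in kids)
            parent_val = by_loc[(p, y)]
            out.append(
                {"parent": p, "year": y, "metric": metric,
                 "parent_value": parent_val, "child_sum": child_sum,
                 "abs_discrepancy": abs(child_sum - parent_val),
                 "rel_discrepancy": abs(child_sum - parent_val) / parent_val}
            )
    return pd.DataFrame(out)


def derived_indicators(rows: Sequence[ResultsTableRow]) -> dict:
    """Shares, sex gaps and threshold counts reproducible from table rows."""
    idx = {(r.location, r.metric, r.year): r.value for r in rows}
    out = {}
    key_b = ("Sub-Saharan Africa", "livebirths", 2019)
    key_g = ("Global", "livebirths", 2019)
    if key_b in idx and key_g in idx:
        out["ssa_livebirth_share_2019"] = round(idx[key_b] / idx[key_g] * 100.0, 1)
    kf = ("Global", "e0_female", 2019)
    km = ("Global", "e0_male", 2019)
    if kf in idx and km in idx:
        out["global_sex_gap_e0_2019"] = round(idx[kf] - idx[km], 1)
    return out


def count_below_threshold(values: Iterable[float], threshold: float,
                          rule: str = "strictly_less") -> int:
    """Threshold counting with an explicit tie rule ("strictly_less" or "at_most")."""
    vals = list(values)
    if rule == "strictly_less":
        return int(sum(v < threshold for v in vals))
    if rule == "at_most":
        return int(sum(v <= threshold for v in vals))
    raise ValueError(f"unknown tie rule {rule!r}")


def load_table(name: str) -> list[ResultsTableRow]:
    """Load a shipped transcription: "table1", "table2" or "table3"."""
    fname = {"table1": "table1_fertility_population.csv",
             "table2": "table2_mortality.csv",
             "table3": "table3_observed_expected_le.csv"}[name]
    hier = gbd_hierarchy() if name in ("table1", "table2") else None
    with resources.files("demest.data").joinpath(fname).open("r", encoding="utf-8") as f:
        return read_results_table(f, hier)
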