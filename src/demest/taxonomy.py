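"""Demographic-transition taxonomy: seven categories from crude-rate history.

A location-year is classified from the history of its crude birth rate
(CBR), crude death rate (CDR) and natural rate of increase
(NRI = CBR - CDR, per 1000), plus the sign of net migration:

* before: no sustained decline in CDR yet.
* early: CDR in sustained decline, but fertility decline has not begun
  and the historical maximum NRI has not reached 3.0% per year.
* mid: both CBR and CDR in sustained decline and max NRI has reached
  3.0%, with NRI not yet well past its peak.
* late_{emigration, immigration}: NRI declining from its historical
  peak (below the configured fraction of the peak) but still
  non-negative; split by net-migration sign.
* post_{emigration, immigration}: NRI negative (CBR/CDR crossover);
  split by net-migration sign.

"Sustained decline" is operationalised as a run of at least ``window``
consecutive years, each at least ``margin`` (relative) below the running
maximum of the series before the run started.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TransitionLabel",
    "RatesTrajectory",
    "TaxonomyConfig",
    "detect_sustained_decline",
    "classify_stage",
    "classify_trajectory",
]


class TransitionLabel(str, Enum):
    before = "before"
    early = "early"
    mid = "mid"
    late_emigration = "late_emigration"
    late_immigration = "late_immigration"
    post_emigration = "post_emigration"
    post_immigration = "post_immigration"


@dataclass
class RatesTrajectory:
    """Yearly CBR, CDR, NRI (per 1000) and net migration rate for one location."""

    years: np.ndarray
    cbr: np.ndarray
    cdr: np.ndarray
    net_migration_rate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.cbr = np.asarray(self.cbr, dtype=float)
        self.cdr = np.asarray(self.cdr, dtype=float)
        if np.any(np.diff(self.years) != 1):
            raise ValueError("years must be contiguous")
        if self.net_migration_rate is None:
            self.net_migration_rate = np.zeros_like(self.cbr)
        else:
            self.net_migration_rate = np.asarray(self.net_migration_rate, dtype=float)

    @property
    def nri(self) -> np.ndarray:
        return self.cbr - self.cdr


@dataclass
class TaxonomyConfig:
    window: int = 10  # years of sustained decline
    margin: float = 0.05  # relative drop below prior running max
    nri_threshold: float = 30.0  # 3.0% per year, in per-1000 units
    late_peak_fraction: float = 0.8  # NRI below this fraction of peak => late
    migration_mean_years: int = 5  # trailing mean for the migration sign


def detect_sustained_decline(
    series: Sequence[float], window: int = 10, margin: float = 0.05
) -> int | None:
    """Index of the first year beginning a sustained decline, or None.

    A sustained decline starting at index i requires ``window`` consecutive
    values (from i) each at least ``margin`` (relative) below the running
    maximum of the series before i.  Deterministic; an exhaustive scan.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    s = np.asarray(series, dtype=float)
    n = len(s)
    for i in range(1, n - window + 1):
        prior_max = s[:i].max()
        if prior_max <= 0:
            continue
        run = s[i : i + window]
        if np.all(run <= prior_max * (1.0 - margin)):
            return i
    return None


def _migration_sign(traj: RatesTrajectory, idx: int, cfg: TaxonomyConfig) -> tuple[str, bool]:
    lo = max(0, idx - cfg.migration_mean_years + 1)
    m = float(np.mean(traj.net_migration_rate[lo : idx + 1]))
    if m > 0:
        return "immigration", False
    if m < 0:
        return "emigration", False
    return "immigration", True  # exact zero: immigration branch, flagged


def classify_stage(
    traj: RatesTrajectory, year: int, config: TaxonomyConfig | None = None
) -> dict:
    """Classify one location-year; returns label plus onset diagnostics."""
    cfg = config or TaxonomyConfig()
    if year not in traj.years:
        raise ValueError(f"year {year} not in trajectory")
    idx = int(np.where(traj.years == year)[0][0])
    if idx + 1 < cfg.window:
        raise ValueError(f"insufficient history before {year} (need {cfg.window} years)")
    hist = slice(0, idx + 1)
    cdr_onset = detect_sustained_decline(traj.cdr[hist], cfg.window, cfg.margin)
    cbr_onset = detect_sustained_decline(traj.cbr[hist], cfg.window, cfg.margin)
    nri = traj.nri[hist]
    max_nri = float(nri.max())
    nri_now = float(nri[-1])
    diagnostics = {
        "cdr_decline_year": int(traj.years[cdr_onset]) if cdr_onset is not None else None,
        "cbr_decline_year": int(traj.years[cbr_onset]) if cbr_onset is not None else None,
        "max_nri": max_nri,
        "nri": nri_now,
    }
    mig, mig_flag = _migration_sign(traj, idx, cfg)
    diagnostics["migration_tie_flag"] = mig_flag

    if cdr_onset is None:
        label = TransitionLabel.before
    elif nri_now < 0:
        label = TransitionLabel[f"post_{mig}"]
        cross = np.where(nri < 0)[0]
        diagnostics["crossover_year"] = int(traj.years[cross[0]]) if len(cross) else None
    elif max_nri > 0 and nri_now < cfg.late_peak_fraction * max_nri and (
        cbr_onset is not None or max_nri >= cfg.nri_threshold
    ):
        label = TransitionLabel[f"late_{mig}"]
    elif cbr_onset is not None and max_nri >= cfg.nri_threshold:
        label = TransitionLabel.mid
    else:
        label = TransitionLabel.early
    diagnostics["label"] = label
    return diagnostics


def classify_trajectory(
    traj: RatesTrajectory, config: TaxonomyConfig | None = None
) -> pd.DataFrame:
    """Labels for every year with enough history; one label per year."""
    cfg = config or TaxonomyConfig()
    rows = []
    for i, y in enumerate(traj.years):
        if i + 1 < cfg.window:
            continue
        d = classify_stage(traj, int(y), cfg)
        rows.append({"year": int(y), "label": d["label"].value, **{
            k: v for k, v in d.items() if k != "label"
        }})
    return pd.DataFrame(rows)
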