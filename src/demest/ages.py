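"""Age grids used throughout the demographic pipeline.

The canonical grid is the 23-group GBD structure: early neonatal (0-6 days),
late neonatal (7-27 days), post-neonatal (28-364 days), 1-4 years, then
5-year groups up to 90-94, and an open 95+ interval.  Day-based widths are
expressed in years on a 365-day year so that person-year columns stay in
year units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["AgeGrid", "build_age_grid", "GBD23", "SINGLE_YEAR_0_110"]

#: Widths of the three under-1 intervals, in years (365-day year).
ENN_WIDTH = 7.0 / 365.0
LNN_WIDTH = 21.0 / 365.0
PNN_WIDTH = 337.0 / 365.0

GBD23 = "gbd23"
SINGLE_YEAR_0_110 = "single_year_0_110"


@dataclass(frozen=True)
class AgeGrid:
    """An ordered, contiguous partition of age starting at 0.

    ``starts[i]`` is the exact lower bound of interval *i* in years;
    ``widths[i]`` its width.  The terminal interval is open-ended and its
    width is ``nan``.
    """

    starts: tuple[float, ...]
    widths: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.starts) != len(self.widths) or len(self.starts) == 0:
            raise ValueError("starts and widths must be non-empty and equal length")
        if abs(self.starts[0]) > 1e-12:
            raise ValueError("age grid must start at 0")
        for i, w in enumerate(self.widths[:-1]):
            if not w > 0:
                raise ValueError(f"interval {i} has non-positive width {w}")
            nxt = self.starts[i] + w
            if abs(nxt - self.starts[i + 1]) > 1e-9:
                raise ValueError(
                    f"intervals {i} and {i + 1} are not contiguous "
                    f"({self.starts[i]}+{w} != {self.starts[i + 1]})"
                )
        if not np.isnan(self.widths[-1]):
            raise ValueError("terminal interval must be open (width = nan)")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def n(self) -> int:
        return len(self.starts)

    @property
    def closed_widths(self) -> np.ndarray:
        """Widths as an array; the open interval reported as nan."""
        return np.asarray(self.widths, dtype=float)

    @property
    def boundaries(self) -> np.ndarray:
        """All exact-age interval boundaries (excluding infinity)."""
        return np.asarray(self.starts, dtype=float)

    def index_of(self, age: float) -> int:
        """Index of the interval whose lower bound equals ``age``."""
        for i, s in enumerate(self.starts):
            if abs(s - age) < 1e-9:
                return i
        raise KeyError(f"age {age} is not an interval boundary of this grid")

    def contains_boundary(self, age: float) -> bool:
        return any(abs(s - age) < 1e-9 for s in self.starts)


def _gbd23() -> AgeGrid:
    starts = [0.0, ENN_WIDTH, ENN_WIDTH + LNN_WIDTH, 1.0]
    widths = [ENN_WIDTH, LNN_WIDTH, PNN_WIDTH, 4.0]
    a = 5.0
    while a < 95.0:
        starts.append(a)
        widths.append(5.0)
        a += 5.0
    starts.append(95.0)
    widths.append(float("nan"))
    return AgeGrid(tuple(starts), tuple(widths))


def _single_year(max_age: int = 110) -> AgeGrid:
    starts = [float(a) for a in range(max_age + 1)]
    widths = [1.0] * max_age + [float("nan")]
    return AgeGrid(tuple(starts), tuple(widths))


def build_age_grid(spec: str | Sequence[tuple[float, float | None]]) -> AgeGrid:
    """Build an :class:`AgeGrid` from a named preset or an explicit list.

    Parameters
    ----------
    spec
        ``"gbd23"``, ``"single_year_0_110"``, or an explicit sequence of
        ``(start, width)`` pairs; the last entry must be the open terminal
        interval, marked by a width of ``None`` (or nan).
    """
    if isinstance(spec, str):
        if spec == GBD23:
            return _gbd23()
        if spec == SINGLE_YEAR_0_110:
            return _single_year(110)
        raise ValueError(f"unknown grid name {spec!r}")
    starts = tuple(float(s) for s, _ in spec)
    widths = tuple(
        float("nan") if (w is None or (isinstance(w, float) and np.isnan(w))) else float(w)
        for _, w in spec
    )
    return AgeGrid(starts, widths)


def five_year_grid(max_start: float = 95.0) -> AgeGrid:
    """Plain 5-year grid 0-4, 5-9, ..., open at ``max_start``."""
    starts, widths = [], []
    a = 0.0
    while a < max_start:
        starts.append(a)
        widths.append(5.0)
        a += 5.0
    starts.append(max_start)
    widths.append(float("nan"))
    return AgeGrid(tuple(starts), tuple(widths))
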