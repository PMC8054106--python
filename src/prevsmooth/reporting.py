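"""Headline summaries: changes between anchor years, octile ranking and
coverage bands.

All inputs are on the 0-100 percent scale.  Change metrics are exact
arithmetic on point estimates; posterior intervals on changes are
computed draw-wise from paired posterior draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ChangeReport",
    "OctileTable",
    "change_metrics",
    "change_metrics_posterior",
    "octile_rank",
    "coverage_band",
]


@dataclass(frozen=True)
class ChangeReport:
    """Absolute and percentage change between two anchor years.

    ``absolute_change`` is in percentage points (end - start);
    ``percent_change`` is 100 * (end - start) / start, undefined (NaN,
    with ``percent_undefined`` set) when start is 0.  Interval fields
    are 2.5% / 97.5% draw quantiles when posterior draws were supplied.
    """

    factor_id: str
    start_year: int
    end_year: int
    start: float
    end: float
    absolute_change: float
    percent_change: float
    percent_undefined: bool = False
    absolute_lo95: float = float("nan")
    absolute_hi95: float = float("nan")
    percent_lo95: float = float("nan")
    percent_hi95: float = float("nan")

    def rounded(self) -> dict:
        """Display form: 1-decimal rounding, unrounded values retained
        on the dataclass itself."""
        return {
            "absolute_change": round(self.absolute_change, 1),
            "percent_change": round(self.percent_change, 1),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "factor_id": self.factor_id,
                    "start_year": self.start_year,
                    "end_year": self.end_year,
                    "start": self.start,
                    "end": self.end,
                    "absolute": self.absolute_change,
                    "absolute_lo95": self.absolute_lo95,
                    "absolute_hi95": self.absolute_hi95,
                    "pct": self.percent_change,
                    "pct_lo95": self.percent_lo95,
                    "pct_hi95": self.percent_hi95,
                }
            ]
        )


@dataclass(frozen=True)
class OctileTable:
    """Per-region octile classes (1-8) for one factor.

    Classes come from fixed 12.5-point-wide bins of the 0-100 scale, not
    from empirical quantiles; after an optional orientation flip, class
    1 always marks the unfavourable end.
    """

    factor_id: str
    region_ids: tuple
    classes: tuple
    higher_is_better: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region_id": self.region_ids, self.factor_id: self.classes}
        )


def change_metrics(start: float, end: float):
    """(absolute, percent) change between two percent-scale estimates.

    absolute = end - start (percentage points); percent = 100 *
    (end - start) / start, NaN when start is 0.
    """
    if not (np.isfinite(start) and np.isfinite(end)):
        raise ValueError("start and end must be finite")
    absolute = end - start
    percent = float("nan") if start == 0 else 100.0 * (end - start) / start
    return absolute, percent


def change_metrics_posterior(
    draws_start: np.ndarray,
    draws_end: np.ndarray,
    factor_id: str = "",
    start_year: int = 0,
    end_year: int = 0,
) -> ChangeReport:
    """Draw-wise change distribution with 95% intervals.

    Draws are paired by index (same posterior sample), so the interval
    on the change accounts for the posterior dependence between the two
    anchor years.  Point estimates are changes of the draw means: exact
    for the absolute change (linearity), a summary choice for the
    percent change, whose mean of ratios differs from the ratio of
    means.
    """
    s = np.asarray(draws_start, dtype=float)
    e = np.asarray(draws_end, dtype=float)
    if s.shape != e.shape:
        raise ValueError(
            f"draw counts differ: {s.shape} vs {e.shape}; draws must be paired"
        )
    if s.size == 0:
        raise ValueError("empty draw arrays")
    start, end = float(s.mean()), float(e.mean())
    absolute, percent = change_metrics(start, end)
    abs_draws = e - s
    undefined = bool(np.any(s == 0.0)) or start == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_draws = 100.0 * (e - s) / s
    a_lo, a_hi = np.quantile(abs_draws, [0.025, 0.975])
    if undefined:
        p_lo = p_hi = float("nan")
    else:
        p_lo, p_hi = np.quantile(pct_draws, [0.025, 0.975])
    return ChangeReport(
        factor_id=factor_id,
        start_year=start_year,
        end_year=end_year,
        start=start,
        end=end,
        absolute_change=absolute,
        percent_change=percent,
        percent_undefined=undefined,
        absolute_lo95=float(a_lo),
        absolute_hi95=float(a_hi),
        percent_lo95=float(p_lo),
        percent_hi95=float(p_hi),
    )


def _octile_class(value: float) -> int:
    # half-open bins [0,12.5), [12.5,25), ..., [87.5, 100]; boundary up
    return min(8, 1 + int(np.floor(value / 12.5)))


def octile_rank(
    values,
    factor_id: str = "",
    region_ids=None,
    higher_is_better: bool = True,
    natural_scale: bool = True,
) -> OctileTable:
    """Eight fixed-width classes of the 0-100 scale per region.

    Naturally 0-100 factors (coverage) are classed directly: class c =
    1 + floor(value / 12.5), capped at 8 (class 8 means ">= 87.5%").
    Factors without a natural 0-100 range are first min-max rescaled to
    0-100 across regions, then classed.  When high values are
    unfavourable (prevalence), classes flip to 9 - c so that class 1 is
    always the unfavourable end.
    """
    v = np.asarray(values, dtype=float)
    if region_ids is None:
        region_ids = tuple(range(len(v)))
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if natural_scale:
        if np.any((v < 0) | (v > 100)):
            raise ValueError(
                "natural-scale values must lie in [0, 100]; "
                "use natural_scale=False to min-max rescale first"
            )
        scaled = v
    else:
        lo, hi = v.min(), v.max()
        scaled = np.full_like(v, 50.0) if hi == lo else 100.0 * (v - lo) / (hi - lo)
    classes = np.array([_octile_class(x) for x in scaled])
    if not higher_is_better:
        classes = 9 - classes
    return OctileTable(
        factor_id=factor_id,
        region_ids=tuple(region_ids),
        classes=tuple(int(c) for c in classes),
        higher_is_better=higher_is_better,
    )


def coverage_band(value: float) -> str:
    """'low' (< 35), 'moderate' (35-65, closed), or 'high' (> 65)."""
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"coverage must be in [0, 100], got {value}")
    if value < 35.0:
        return "low"
    if value <= 65.0:
        return "moderate"
    return "high"
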