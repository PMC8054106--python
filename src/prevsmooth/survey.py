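"""Design-weighted prevalence estimation from survey microdata.

Household surveys record binary outcomes with design weights.  This
module harmonises recall windows across survey families, collapses
microdata to weighted proportions per (survey, region, year), attaches
the Kish effective sample size that drives the model's heteroscedastic
noise, and assembles the per-factor observation table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import RegionGraph

__all__ = [
    "SurveyObservation",
    "FactorDataset",
    "recall_window_filter",
    "weighted_proportion",
    "estimate_observations",
    "assemble_dataset",
    "read_microdata",
    "read_observations",
    "write_observations",
]

MICRO_COLUMNS = [
    "survey_id",
    "survey_family",
    "region_id",
    "event_year",
    "outcome",
    "weight",
    "cluster_id",
]

#: years of recall retained per survey family (survey_year - event_year < lag)
RECALL_LAG_YEARS = {"DHS-like": 3, "MICS-like": 2}
CENSUS_FAMILY = "census-like"
KNOWN_FAMILIES = set(RECALL_LAG_YEARS) | {CENSUS_FAMILY}


@dataclass(frozen=True)
class SurveyObservation:
    """One design-weighted proportion for a (survey, region, year) cell.

    ``y_logit`` is the empirical logit of ``q``; when ``q`` is exactly 0
    or 1 a continuity correction of half a pseudo-count on the effective
    sample-size scale keeps it finite and ``v_floor`` is set.
    """

    survey_id: str
    region_id: str
    year: int
    q: float
    n_eff: float
    y_logit: float
    v_floor: bool = False

    def __post_init__(self):
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q must be in [0, 1], got {self.q}")
        if self.n_eff <= 0:
            raise ValueError(f"n_eff must be positive, got {self.n_eff}")
        if not math.isfinite(self.y_logit):
            raise ValueError("y_logit must be finite")


def _check_micro(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MICRO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"microdata missing columns: {missing}")
    bad_fam = set(df["survey_family"].unique()) - KNOWN_FAMILIES
    if bad_fam:
        raise ValueError(
            f"unknown survey_family values {sorted(bad_fam)}; "
            f"expected one of {sorted(KNOWN_FAMILIES)}"
        )
    if (df["weight"] <= 0).any():
        raise ValueError("design weights must be positive")
    if not df["outcome"].isin([0, 1]).all():
        raise ValueError("outcome must be binary 0/1")
    return df


def recall_window_filter(records: pd.DataFrame, survey_year: int) -> pd.DataFrame:
    """Keep only events within each survey family's recall window.

    DHS-like surveys retain events with ``survey_year - event_year < 3``,
    MICS-like with ``survey_year - event_year < 2``; census-like records
    pass through unfiltered.  Harmonising the recall window keeps
    estimates comparable when survey programmes with different reference
    periods are combined.
    """
    if records.empty:
        return records
    records = _check_micro(records)
    if (records["event_year"] > survey_year).any():
        raise ValueError("event_year after survey_year")
    lag = survey_year - records["event_year"]
    max_lag = records["survey_family"].map(
        lambda f: RECALL_LAG_YEARS.get(f, np.inf)
    )
    return records.loc[lag < max_lag].reset_index(drop=True)


def weighted_proportion(records: pd.DataFrame) -> SurveyObservation:
    """Collapse one (survey, region, year) group of microdata.

    q      = sum(w * y) / sum(w)
    n_eff  = (sum w)^2 / sum(w^2)          (Kish effective sample size)
    y_logit = log(q* / (1 - q*)), q* = q except at the boundaries where
    q* = (q * n_eff + 0.5) / (n_eff + 1) and ``v_floor`` is set.
    """
    if len(records) == 0:
        raise ValueError("cannot estimate a proportion from zero records")
    records = _check_micro(records)
    for col in ("survey_id", "region_id", "event_year"):
        if records[col].nunique() != 1:
            raise ValueError(f"group is not homogeneous in {col}")
    w = records["weight"].to_numpy(dtype=float)
    y = records["outcome"].to_numpy(dtype=float)
    sw = w.sum()
    q = float((w * y).sum() / sw)
    n_eff = float(sw**2 / (w**2).sum())
    v_floor = q in (0.0, 1.0)
    q_star = (q * n_eff + 0.5) / (n_eff + 1.0) if v_floor else q
    return SurveyObservation(
        survey_id=str(records["survey_id"].iloc[0]),
        region_id=str(records["region_id"].iloc[0]),
        year=int(records["event_year"].iloc[0]),
        q=q,
        n_eff=n_eff,
        y_logit=float(np.log(q_star / (1.0 - q_star))),
        v_floor=v_floor,
    )


def estimate_observations(
    microdata: pd.DataFrame,
    survey_years: dict | None = None,
    min_n_eff: float = 1.5,
) -> pd.DataFrame:
    """Microdata -> observation table, applying the recall filter per survey.

    Parameters
    ----------
    microdata : DataFrame with :data:`MICRO_COLUMNS`.
    survey_years : optional mapping survey_id -> survey (interview) year.
        Defaults to each survey's latest event year, which is correct
        when fieldwork covers the final recall year.
    min_n_eff : float
        Groups whose Kish effective sample size falls below this are
        dropped with a warning: the noise model keys precision to
        log(n_eff), which is non-positive for near-singleton groups,
        and one or two respondents carry no usable design information.
    """
    microdata = _check_micro(microdata)
    out, dropped = [], 0
    for sid, sub in microdata.groupby("survey_id", sort=True):
        sy = (
            int(survey_years[sid])
            if survey_years and sid in survey_years
            else int(sub["event_year"].max())
        )
        kept = recall_window_filter(sub.reset_index(drop=True), sy)
        for (_, _, _), grp in kept.groupby(
            ["survey_id", "region_id", "event_year"], sort=True
        ):
            o = weighted_proportion(grp)
            if o.n_eff < min_n_eff:
                dropped += 1
            else:
                out.append(o)
    if dropped:
        warnings.warn(
            f"dropped {dropped} (survey, region, year) groups with "
            f"effective sample size below {min_n_eff}",
            RuntimeWarning,
            stacklevel=2,
        )
    return observations_frame(out)


def observations_frame(observations) -> pd.DataFrame:
    cols = ["survey_id", "region_id", "year", "q", "n_eff", "y_logit", "v_floor"]
    if not len(observations):
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([vars(o) for o in observations])[cols]


class FactorDataset:
    """Observations for one factor, indexed on a (region x year) lattice.

    Multiple observations may share a (region, year) cell — each survey
    contributes its own row — and many cells carry none; the model
    predicts those from the smoothing structure.
    """

    def __init__(self, observations: pd.DataFrame, graph: RegionGraph, years):
        years = range(int(min(years)), int(max(years)) + 1)
        self.graph = graph
        self.years = tuple(years)
        obs = observations.copy().reset_index(drop=True)
        if len(obs):
            unknown = sorted(set(obs["region_id"]) - set(graph.region_ids))
            if unknown:
                raise ValueError(f"observations reference unknown regions: {unknown}")
            out_of_window = sorted(
                set(obs["year"]) - set(self.years)
            )
            if out_of_window:
                raise ValueError(
                    f"observations outside year window "
                    f"{self.years[0]}-{self.years[-1]}: {out_of_window}"
                )
            obs["k"] = obs["region_id"].map(
                {r: i for i, r in enumerate(graph.region_ids)}
            )
            obs["t"] = obs["year"].map({y: i for i, y in enumerate(self.years)})
        else:
            obs["k"] = pd.Series(dtype=int)
            obs["t"] = pd.Series(dtype=int)
        self.observations = obs

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    @property
    def n_regions(self) -> int:
        return self.graph.n_regions

    @property
    def n_years(self) -> int:
        return len(self.years)

    def cell_multiplicity(self) -> np.ndarray:
        """K x T matrix of observation counts per cell."""
        m = np.zeros((self.n_regions, self.n_years), dtype=int)
        if self.n_obs:
            np.add.at(m, (self.observations["k"], self.observations["t"]), 1)
        return m

    def coverage(self) -> float:
        """Fraction of (region, year) cells with at least one observation."""
        return float((self.cell_multiplicity() > 0).mean())

    def subset(self, index) -> "FactorDataset":
        sub = self.observations.loc[index].drop(columns=["k", "t"])
        return FactorDataset(sub, self.graph, self.years)


def assemble_dataset(
    observations: pd.DataFrame, graph: RegionGraph, years
) -> FactorDataset:
    """Index an observation table on the model's (region, year) lattice."""
    return FactorDataset(observations, graph, years)


def read_microdata(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "survey_id": str,
            "survey_family": str,
            "region_id": str,
            "cluster_id": str,
        },
    )
    return _check_micro(df)


def read_observations(path) -> pd.DataFrame:
    """Read a pre-aggregated observation table (alternative entry point)."""
    df = pd.read_csv(path, dtype={"survey_id": str, "region_id": str})
    need = ["survey_id", "region_id", "year", "q", "n_eff"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"observation file missing columns: {missing}")
    if "y_logit" not in df.columns:
        obs = []
        for _, row in df.iterrows():
            q, n_eff = float(row["q"]), float(row["n_eff"])
            v_floor = q in (0.0, 1.0)
            q_star = (q * n_eff + 0.5) / (n_eff + 1.0) if v_floor else q
            obs.append((np.log(q_star / (1 - q_star)), v_floor))
        df["y_logit"] = [o[0] for o in obs]
        df["v_floor"] = [o[1] for o in obs]
    return df


def write_observations(observations: pd.DataFrame, path) -> None:
    observations.to_csv(path, index=False)
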