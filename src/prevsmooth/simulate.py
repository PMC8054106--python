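"""Synthetic survey data with the structure the analysis assumes.

Nothing here mimics real geography or factor levels; the generator
exists so every pipeline stage — estimation, smoothing, validation,
reporting — runs end-to-end with a known truth.  It emulates the shape
of a multi-country household-survey archive: a connected region graph,
a latent prevalence surface drawn from the model's own space-time
process, and a handful of irregularly timed surveys of two families
(DHS-like with a 3-year recall window, MICS-like with 2) plus censuses,
with cluster design weights, partial region coverage, and per-region
sample sizes spanning tens to hundreds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist
from scipy.special import expit

from .graph import RegionGraph, build_ar1_correlation, build_car_correlation
from .model import ModelParams, noise_variance
from .survey import RECALL_LAG_YEARS, CENSUS_FAMILY

__all__ = [
    "SurveySpec",
    "SimulationPlan",
    "ReferenceScenario",
    "generate_graph",
    "simulate_truth",
    "simulate_survey_microdata",
    "simulate_logit_observations",
    "make_reference_scenario",
]


@dataclass(frozen=True)
class SurveySpec:
    """One scheduled survey: which regions it visits and how hard."""

    survey_id: str
    family: str  # DHS-like / MICS-like / census-like
    year: int  # interview year
    regions: tuple  # region ids covered
    n_per_region: dict  # region id -> target respondent count


@dataclass(frozen=True)
class SimulationPlan:
    """Full recipe for one synthetic study."""

    K: int
    T: int
    truth: ModelParams
    survey_schedule: tuple
    weight_dispersion: float = 0.5  # CV of design weights
    cluster_size: int = 25
    seed: int = 0

    def __post_init__(self):
        if self.K < 2 or self.T < 2:
            raise ValueError("need K >= 2 regions and T >= 2 years")
        for spec in self.survey_schedule:
            if any(n < 5 for n in spec.n_per_region.values()):
                raise ValueError(
                    f"survey {spec.survey_id}: per-region n targets must be >= 5"
                )


@dataclass(frozen=True)
class ReferenceScenario:
    graph: RegionGraph
    years: tuple
    plan: SimulationPlan
    truth_field: np.ndarray  # K x T, logit scale
    truth_surface: np.ndarray  # K x T, probability scale
    microdata: pd.DataFrame
    survey_years: dict


def generate_graph(K: int, seed: int = 0) -> RegionGraph:
    """Connected planar-like region graph.

    Regions are random points on the unit square joined when closer
    than a radius scaled for an average degree near 4; the Euclidean
    minimum spanning tree is added so the graph is always connected.
    """
    if K < 2:
        raise ValueError(f"need K >= 2 regions, got {K}")
    rng = np.random.default_rng(seed)
    pos = rng.random((K, 2))
    labels = tuple(f"R{i:02d}" for i in range(K))
    radius = np.sqrt(2.0 / K)
    dist = squareform(pdist(pos))
    edges = set()
    for i in range(K):
        for j in range(i + 1, K):
            if dist[i, j] <= radius:
                edges.add(frozenset((labels[i], labels[j])))
    mst = minimum_spanning_tree(dist).tocoo()
    for i, j in zip(mst.row, mst.col):
        edges.add(frozenset((labels[i], labels[j])))
    return RegionGraph(labels, frozenset(edges))


def simulate_truth(
    graph: RegionGraph, T: int, truth: ModelParams, seed: int = 0
):
    """Draw the latent field and its probability surface.

    S ~ MVN(0, sigma2 * (R_S kron R_T)) via the Kronecker factor
    Cholesky roots; surface = expit(alpha + S).
    """
    rng = np.random.default_rng(seed)
    K = graph.n_regions
    Rs = build_car_correlation(graph, truth.rho_s).values
    Rt = build_ar1_correlation(T, truth.phi).values
    Ls = np.linalg.cholesky(Rs)
    Lt = np.linalg.cholesky(Rt)
    Z = rng.standard_normal((K, T))
    S = np.sqrt(truth.sigma2) * Ls @ Z @ Lt.T
    return S, expit(truth.alpha + S)


def _allowed_lags(family: str) -> range:
    if family == CENSUS_FAMILY:
        return range(0, 1)
    return range(0, RECALL_LAG_YEARS[family])


def simulate_survey_microdata(
    plan: SimulationPlan, surface: np.ndarray, years, seed: int = 0
) -> pd.DataFrame:
    """Draw respondent-level records for every scheduled survey.

    Within each (survey, region): respondents are grouped into clusters
    of ``plan.cluster_size``; each cluster gets a log-normal design
    weight with mean 1 and the plan's coefficient of variation (all
    members share it, the usual shape of cluster-sample weights); event
    years are spread uniformly over the survey's recall window
    (truncated to the analysis window) and outcomes are Bernoulli draws
    from the true surface at the event year.
    """
    years = tuple(years)
    K, T = surface.shape
    if K != plan.K or T != plan.T or len(years) != T:
        raise ValueError("plan, surface and years disagree on dimensions")
    year_to_t = {y: t for t, y in enumerate(years)}
    rng = np.random.default_rng(seed)
    cv = plan.weight_dispersion
    sig = np.sqrt(np.log1p(cv * cv))
    rows = []
    for spec in plan.survey_schedule:
        lags = [
            lag
            for lag in _allowed_lags(spec.family)
            if spec.year - lag in year_to_t
        ]
        if not lags:
            raise ValueError(
                f"survey {spec.survey_id} ({spec.year}) has no event years "
                f"inside the analysis window {years[0]}-{years[-1]}"
            )
        for region in spec.regions:
            if region not in spec.n_per_region:
                raise ValueError(
                    f"survey {spec.survey_id}: no n target for region {region}"
                )
            k = _region_index(region, K)
            n = int(spec.n_per_region[region])
            n_clusters = max(1, n // plan.cluster_size)
            cl = rng.integers(0, n_clusters, size=n)
            if cv > 0:
                cl_w = np.exp(rng.normal(-0.5 * sig * sig, sig, size=n_clusters))
            else:
                cl_w = np.ones(n_clusters)
            ev = spec.year - rng.choice(lags, size=n)
            p = surface[k, [year_to_t[e] for e in ev]]
            outc = (rng.random(n) < p).astype(int)
            for i in range(n):
                rows.append(
                    (
                        spec.survey_id,
                        spec.family,
                        region,
                        int(ev[i]),
                        int(outc[i]),
                        float(cl_w[cl[i]]),
                        f"{spec.survey_id}_{region}_c{cl[i]:03d}",
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "survey_id",
            "survey_family",
            "region_id",
            "event_year",
            "outcome",
            "weight",
            "cluster_id",
        ],
    )


def _region_index(region_id: str, K: int) -> int:
    # generator-internal labels are R00..R{K-1}
    idx = int(region_id[1:])
    if not 0 <= idx < K:
        raise ValueError(f"region {region_id} outside 0..{K - 1}")
    return idx


def simulate_logit_observations(
    graph: RegionGraph,
    years,
    truth: ModelParams,
    cell_coverage: float = 0.7,
    n_eff_range=(50, 500),
    seed: int = 0,
):
    """Well-specified observations drawn directly from the model.

    Skips the survey layer: each covered cell gets one observation with
    y_logit = alpha + S_kt + N(0, tau2/log(n_eff)) and q = expit(y_logit),
    n_eff uniform over ``n_eff_range``.  Used for calibration studies
    where the Gaussian noise model must hold exactly.

    Returns (observation DataFrame, truth field, truth surface).
    """
    years = tuple(years)
    rng = np.random.default_rng(seed)
    T = len(years)
    S, surface = simulate_truth(graph, T, truth, seed=rng.integers(2**31))
    rows = []
    for k, region in enumerate(graph.region_ids):
        for t, year in enumerate(years):
            if rng.random() > cell_coverage:
                continue
            n_eff = float(rng.uniform(*n_eff_range))
            sd = np.sqrt(noise_variance(n_eff, truth.tau2))
            yv = truth.alpha + S[k, t] + rng.normal(0.0, sd)
            rows.append(
                ("sim", region, year, float(expit(yv)), n_eff, float(yv), False)
            )
    obs = pd.DataFrame(
        rows,
        columns=["survey_id", "region_id", "year", "q", "n_eff", "y_logit", "v_floor"],
    )
    return obs, S, surface


def make_reference_scenario(seed: int = 0) -> ReferenceScenario:
    """The canonical test scenario: K=12 regions, T=10 years.

    Truth alpha=-0.5, sigma2=1.0, rho_s=0.9, phi=0.8, tau2=1.5; seven
    surveys of mixed families over the decade with per-region sample
    targets in [30, 800]; several surveys skip regions so that well
    over 10% of (region, year) cells carry no observation and the
    model must genuinely interpolate.
    """
    rng = np.random.default_rng(seed)
    K, T = 12, 10
    years = tuple(range(2005, 2015))
    truth = ModelParams(alpha=-0.5, sigma2=1.0, rho_s=0.9, phi=0.8, tau2=1.5)
    graph = generate_graph(K, seed=rng.integers(2**31))
    regions = graph.region_ids

    schedule = []
    plan_rows = [
        ("dhs_2006", "DHS-like", 2006, 10),
        ("mics_2008", "MICS-like", 2008, 8),
        ("dhs_2009", "DHS-like", 2009, 11),
        ("census_2010", "census-like", 2010, 12),
        ("mics_2011", "MICS-like", 2011, 8),
        ("dhs_2013", "DHS-like", 2013, 9),
        ("mics_2014", "MICS-like", 2014, 8),
    ]
    for sid, family, year, n_regions in plan_rows:
        covered = tuple(
            sorted(rng.choice(regions, size=n_regions, replace=False))
            if n_regions < K
            else regions
        )
        n_per = {
            r: int(rng.integers(30, 801))
            if family != "census-like"
            else int(rng.integers(400, 801))
            for r in covered
        }
        schedule.append(
            SurveySpec(
                survey_id=sid,
                family=family,
                year=year,
                regions=covered,
                n_per_region=n_per,
            )
        )

    plan = SimulationPlan(
        K=K,
        T=T,
        truth=truth,
        survey_schedule=tuple(schedule),
        weight_dispersion=0.5,
        seed=seed,
    )
    S, surface = simulate_truth(graph, T, truth, seed=rng.integers(2**31))
    micro = simulate_survey_microdata(
        plan, surface, years, seed=rng.integers(2**31)
    )
    survey_years = {sid: yr for sid, _, yr, _ in plan_rows}
    return ReferenceScenario(
        graph=graph,
        years=years,
        plan=plan,
        truth_field=S,
        truth_surface=surface,
        microdata=micro,
        survey_years=survey_years,
    )
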