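"""Hold-out validation of the smoothed surfaces.

A random fraction of observations (default 10%) is withheld, the model
is refit on the remainder, and the withheld weighted proportions are
scored against the posterior-mean prevalence at their (region, year)
cells with Pearson correlation, MAE and RMSE on the proportion scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import PosteriorSurface
from .survey import FactorDataset

__all__ = ["CvReport", "holdout_split", "cv_metrics"]


@dataclass(frozen=True)
class CvReport:
    """Predictive-performance summary on held-out observations.

    ``correlation`` is NaN (with a warning at computation time) when the
    predictions are constant, which leaves Pearson r undefined.
    """

    correlation: float
    mae: float
    rmse: float
    n_held_out: int

    def to_frame(self, **extra) -> pd.DataFrame:
        row = {
            "correlation": self.correlation,
            "mae": self.mae,
            "rmse": self.rmse,
            "n_held_out": self.n_held_out,
            **extra,
        }
        return pd.DataFrame([row])


def holdout_split(data: FactorDataset, fraction: float = 0.10, seed: int = 0):
    """Partition observations uniformly at random into (train, test).

    ``len(test) = round(fraction * N)`` with banker's rounding
    (round-half-even), so 1.5 expected hold-outs round to 2.  The split
    removes individual observations, not whole region-years: a cell
    observed by two surveys may keep one.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    n = data.n_obs
    if n < 2:
        raise ValueError(f"need at least 2 observations to split, got {n}")
    n_test = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return data.subset(train_idx), data.subset(test_idx)


def cv_metrics(test: FactorDataset, surface: PosteriorSurface) -> CvReport:
    """Score held-out weighted proportions against the posterior mean."""
    if test.n_obs < 2:
        raise ValueError(
            f"need at least 2 held-out observations for a correlation, "
            f"got {test.n_obs}"
        )
    obs = test.observations
    observed = obs["q"].to_numpy(dtype=float)
    predicted = np.array(
        [
            surface.at(r, int(yr))[0]
            for r, yr in zip(obs["region_id"], obs["year"])
        ]
    )
    err = observed - predicted
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err**2).mean()))
    if np.ptp(predicted) == 0.0 or np.ptp(observed) == 0.0:
        warnings.warn(
            "constant observed or predicted values: Pearson correlation "
            "is undefined; reporting NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        corr = float("nan")
    else:
        corr = float(stats.pearsonr(observed, predicted).statistic)
    return CvReport(correlation=corr, mae=mae, rmse=rmse, n_held_out=test.n_obs)
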