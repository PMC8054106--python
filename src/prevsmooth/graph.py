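"""Spatial units and the space-time correlation structure.

The latent field lives on a region graph crossed with a run of calendar
years.  Spatial dependence follows a proper conditionally autoregressive
(CAR) model on the graph; temporal dependence is a first-order
autoregression.  Their Kronecker product gives the separable space-time
covariance used throughout the package.

Vectorisation contract: a (region k, year t) cell maps to flat index
``k * T + t`` (region-major, year-minor).  Every module shares this
ordering; ``kron_covariance`` and the samplers rely on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "RegionGraph",
    "CorrelationMatrix",
    "build_car_correlation",
    "build_ar1_correlation",
    "kron_covariance",
    "read_adjacency",
    "write_adjacency",
]

_PD_TOL = 1e-10  # smallest admissible eigenvalue for a correlation matrix


@dataclass(frozen=True)
class RegionGraph:
    """An undirected, connected graph of spatial units.

    Parameters
    ----------
    region_ids : tuple of str
        Ordered region labels; the order fixes the row order of every
        spatial matrix built from this graph.
    edges : frozenset of frozenset
        Unordered region-id pairs.  No self-edges.

    Raises
    ------
    ValueError
        If there are fewer than two regions, an edge references an
        unknown region, an edge is a self-loop, or the graph is
        disconnected (a proper CAR correlation requires connectivity).
    """

    region_ids: tuple
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        ids = tuple(self.region_ids)
        object.__setattr__(self, "region_ids", ids)
        if len(ids) < 2:
            raise ValueError("a region graph needs at least 2 regions")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region ids")
        norm = set()
        known = set(ids)
        for e in self.edges:
            a, b = tuple(e) if len(e) == 2 else (None, None)
            if a is None or a == b:
                raise ValueError(f"self-edge or malformed edge: {set(e)}")
            if a not in known or b not in known:
                raise ValueError(f"edge references unknown region: {set(e)}")
            norm.add(frozenset((a, b)))
        object.__setattr__(self, "edges", frozenset(norm))
        if not nx.is_connected(self.to_networkx()):
            raise ValueError(
                "region graph is disconnected; a proper CAR correlation "
                "is only defined on a connected graph"
            )

    @classmethod
    def from_edge_list(cls, edges) -> "RegionGraph":
        """Build from an iterable of (region_a, region_b) pairs.

        Region order is first-appearance order over the edge list.
        """
        ids, seen = [], set()
        fs = set()
        for a, b in edges:
            for r in (a, b):
                if r not in seen:
                    seen.add(r)
                    ids.append(r)
            fs.add(frozenset((a, b)))
        return cls(tuple(ids), frozenset(fs))

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def index(self, region_id) -> int:
        return self.region_ids.index(region_id)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.region_ids)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g

    def adjacency_matrix(self) -> np.ndarray:
        """0/1 adjacency W in region order."""
        return nx.to_numpy_array(
            self.to_networkx(), nodelist=self.region_ids, dtype=float
        )


@dataclass(frozen=True)
class CorrelationMatrix:
    """A dense symmetric positive-definite matrix with unit diagonal."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("correlation matrix diagonal is not 1")
        if n and np.linalg.eigvalsh(v)[0] <= _PD_TOL:
            raise ValueError("correlation matrix is not positive definite")

    @property
    def n(self) -> int:
        return len(self.labels)


def build_car_correlation(graph: RegionGraph, rho_s: float) -> CorrelationMatrix:
    """Proper-CAR spatial correlation on a region graph.

    Inverts the proper-CAR precision ``D - rho_s * W`` (D the diagonal of
    neighbour counts, W the 0/1 adjacency) and rescales the resulting
    covariance to unit diagonal.  ``rho_s`` in (0, 1) controls spatial
    dependence; as ``rho_s -> 0`` regions decouple, as ``rho_s -> 1`` the
    model approaches the intrinsic CAR limit.
    """
    if not 0.0 < rho_s < 1.0:
        raise ValueError(f"rho_s must be in (0, 1), got {rho_s}")
    W = graph.adjacency_matrix()
    D = np.diag(W.sum(axis=1))
    prec = D - rho_s * W
    cov = np.linalg.inv(prec)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(graph.region_ids, corr)


def car_correlation_inverse(graph: RegionGraph, rho_s: float) -> np.ndarray:
    """Inverse of :func:`build_car_correlation` without a dense inversion
    of the correlation itself.

    With ``Sigma = (D - rho W)^{-1}`` and ``d = sqrt(diag(Sigma))``, the
    rescaled correlation is ``R = diag(1/d) Sigma diag(1/d)`` so
    ``R^{-1} = diag(d) (D - rho W) diag(d)``.  One K x K inversion is
    still needed for ``d``; K is the number of regions (tens), so this is
    cheap and exact.
    """
    if not 0.0 < rho_s < 1.0:
        raise ValueError(f"rho_s must be in (0, 1), got {rho_s}")
    W = graph.adjacency_matrix()
    D = np.diag(W.sum(axis=1))
    prec = D - rho_s * W
    d = np.sqrt(np.diag(np.linalg.inv(prec)))
    return prec * np.outer(d, d)


def build_ar1_correlation(n_years: int, phi: float) -> CorrelationMatrix:
    """AR(1) temporal correlation: entry (t, t') = phi ** |t - t'|."""
    if n_years < 1:
        raise ValueError(f"n_years must be >= 1, got {n_years}")
    if not -1.0 < phi < 1.0:
        raise ValueError(f"phi must be in (-1, 1), got {phi}")
    idx = np.arange(n_years)
    corr = phi ** np.abs(np.subtract.outer(idx, idx)).astype(float)
    return CorrelationMatrix(tuple(idx), corr)


def ar1_correlation_inverse(n_years: int, phi: float) -> np.ndarray:
    """Closed-form tridiagonal inverse of the AR(1) correlation matrix."""
    if not -1.0 < phi < 1.0:
        raise ValueError(f"phi must be in (-1, 1), got {phi}")
    T = n_years
    if T == 1:
        return np.array([[1.0]])
    q = np.zeros((T, T))
    one = 1.0 / (1.0 - phi**2)
    np.fill_diagonal(q, (1.0 + phi**2) * one)
    q[0, 0] = q[T - 1, T - 1] = one
    off = -phi * one
    i = np.arange(T - 1)
    q[i, i + 1] = off
    q[i + 1, i] = off
    return q


def kron_covariance(
    spatial: CorrelationMatrix, temporal: CorrelationMatrix, sigma2: float
) -> np.ndarray:
    """Separable space-time covariance ``sigma2 * (R_S kron R_T)``.

    Row/column index of the result is ``k * T + t`` (region-major,
    year-minor), matching the package-wide vectorisation contract.
    """
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    return sigma2 * np.kron(spatial.values, temporal.values)


def read_adjacency(path) -> RegionGraph:
    """Read a two-column delimited edge list (header ``region_a,region_b``)."""
    df = pd.read_csv(path, dtype=str)
    cols = [c.strip() for c in df.columns]
    if cols[:2] != ["region_a", "region_b"]:
        raise ValueError(
            f"adjacency file must have header 'region_a,region_b', got {cols[:2]}"
        )
    return RegionGraph.from_edge_list(
        df.iloc[:, :2].itertuples(index=False, name=None)
    )


def write_adjacency(graph: RegionGraph, path) -> None:
    rows = sorted(tuple(sorted(e)) for e in graph.edges)
    pd.DataFrame(rows, columns=["region_a", "region_b"]).to_csv(path, index=False)
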