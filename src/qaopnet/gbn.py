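"""Per-exposure static Gaussian Bayesian network on the pathway DAG.

Each exposure repetition gets its own linear-Gaussian network: every
biology node is regressed (OLS) on its pathway parents, with dose entering
as a continuous root feeding the MIEs.  Activation probabilities
P(node > Δ | dose ∈ [d ± ε]) are estimated by logic sampling (ancestral
forward simulation with the dose root drawn uniformly over the dose
range), and (Δ, dose) probability surfaces are summarized by their volume
under the surface (VUS, composite trapezoid rule).

All values are log fold changes (the natural-log scale the lognormal
replicate model is parameterized on); the default activation threshold is
the conventional Δ = log10 2 ≈ 0.301 in log fold-change units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyWindowError, GridError, RankError
from .graph import AOPGraph
from .resample import ReplicateDataset

DELTA_DEFAULT = float(np.log10(2.0))


@dataclass
class NodeParams:
    """Linear-Gaussian conditional: intercept-first β over parents, σ², R²."""

    node: str
    parents: list[str]
    beta: np.ndarray
    sigma2: float
    r2: float


@dataclass
class GBNModel:
    """One exposure repetition's fitted network."""

    exposure: int
    node_params: dict[str, NodeParams]
    dose_range: tuple[float, float]
    graph: AOPGraph = field(repr=False, default=None)

    @property
    def node_r2(self) -> dict[str, float]:
        return {v: p.r2 for v, p in self.node_params.items()}

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure,
            "dose_range": list(self.dose_range),
            "graph": self.graph.to_dict(),
            "nodes": {
                v: {
                    "parents": p.parents,
                    "beta": list(map(float, p.beta)),
                    "sigma2": p.sigma2,
                    "r2": p.r2,
                }
                for v, p in self.node_params.items()
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, payload: dict) -> "GBNModel":
        from .graph import AOPGraph

        graph = AOPGraph.from_dict(payload["graph"])
        params = {
            v: NodeParams(v, d["parents"], np.asarray(d["beta"], float),
                          float(d["sigma2"]), float(d["r2"]))
            for v, d in payload["nodes"].items()
        }
        return cls(int(payload["exposure"]), params,
                   tuple(payload["dose_range"]), graph)

    @classmethod
    def load(cls, path: str | Path) -> "GBNModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ActivationQuery:
    """One point query of the activation probability."""

    node: str
    delta: float = DELTA_DEFAULT
    dose: float = 0.0
    epsilon: float = 10.0


@dataclass
class ProbabilitySurface:
    """P(node > Δ | dose window) tabulated over (Δ, dose) grids."""

    node: str
    exposure: int
    delta_grid: np.ndarray
    dose_grid: np.ndarray
    prob: np.ndarray  # shape (len(delta_grid), len(dose_grid))
    vus: float

    def to_frame(self) -> pd.DataFrame:
        dd, gg = np.meshgrid(self.delta_grid, self.dose_grid, indexing="ij")
        return pd.DataFrame({
            "node": self.node,
            "exposure": self.exposure,
            "delta": dd.ravel(),
            "dose": gg.ravel(),
            "prob": self.prob.ravel(),
        })


def fit_gbn(
    data: ReplicateDataset,
    exposure: int,
    graph: AOPGraph | None = None,
) -> GBNModel:
    """Fit per-node OLS conditionals at one exposure, donors and doses pooled."""
    graph = graph if graph is not None else data.graph
    wide = data.means_matrix(exposure, log=True, with_dose=True)
    params: dict[str, NodeParams] = {}
    for v in graph.biology_nodes:
        pa = graph.parents(v)
        X = np.column_stack([np.ones(len(wide))] + [wide[p].to_numpy(float) for p in pa])
        y = wide[v].to_numpy(float)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise RankError(f"rank-deficient design for node {v} at e={exposure}")
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = max(len(y) - X.shape[1], 1)
        sigma2 = float(resid @ resid) / dof
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0
        params[v] = NodeParams(v, pa, beta, sigma2, r2)
    dr = (float(min(data.means.dose)), float(max(data.means.dose)))
    return GBNModel(exposure=exposure, node_params=params, dose_range=dr, graph=graph)


def logic_sample(
    model: GBNModel,
    n_samples: int,
    seed: int,
    dose_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Ancestral forward sampling of the fitted network.

    The dose root is drawn uniformly over the dose range; every node then
    follows its linear-Gaussian conditional in topological order.  Returns
    a frame of log fold-change draws with their dose values.
    """
    graph = model.graph
    lo, hi = dose_range if dose_range is not None else model.dose_range
    rng = np.random.default_rng(seed)
    cols = {graph.dose_node: rng.uniform(lo, hi, n_samples)}
    for v in graph.topological_order(include_dose=False):
        p = model.node_params[v]
        X = np.column_stack([np.ones(n_samples)] + [cols[q] for q in p.parents])
        mean = X @ p.beta
        cols[v] = mean + np.sqrt(max(p.sigma2, 0.0)) * rng.standard_normal(n_samples)
    return pd.DataFrame(cols)


def activation_probability(
    samples: pd.DataFrame,
    query: ActivationQuery,
    dose_node: str = "DOSE",
) -> tuple[float, int]:
    """Fraction of dose-window samples exceeding the threshold.

    Returns (probability, window count) so callers can attach a binomial
    Monte-Carlo standard error.
    """
    dose = samples[dose_node].to_numpy(float)
    mask = np.abs(dose - query.dose) <= query.epsilon
    n = int(mask.sum())
    if n == 0:
        raise EmptyWindowError(
            f"no samples with dose in [{query.dose - query.epsilon}, "
            f"{query.dose + query.epsilon}]"
        )
    prob = float((samples[query.node].to_numpy(float)[mask] > query.delta).mean())
    return prob, n


def default_grids(
    dose_range: tuple[float, float],
    design_doses: tuple[float, ...] | None = None,
    n_delta: int = 21,
    n_dose_extra: int = 17,
) -> tuple[np.ndarray, np.ndarray]:
    """Δ grid on [0, 1] and a dose grid interleaving the design doses."""
    delta_grid = np.linspace(0.0, 1.0, n_delta)
    lo, hi = dose_range
    dose_grid = np.linspace(lo, hi, n_dose_extra)
    if design_doses:
        dose_grid = np.union1d(dose_grid, np.asarray(design_doses, float))
    return delta_grid, dose_grid


def probability_surface(
    samples: pd.DataFrame,
    node: str,
    exposure: int,
    delta_grid: np.ndarray,
    dose_grid: np.ndarray,
    epsilon: float,
    dose_node: str = "DOSE",
) -> ProbabilitySurface:
    """Tabulate P(node > Δ | dose window) over the grids and integrate."""
    delta_grid = np.asarray(delta_grid, float)
    dose_grid = np.asarray(dose_grid, float)
    for g, name in ((delta_grid, "delta"), (dose_grid, "dose")):
        if len(g) < 2 or np.any(np.diff(g) <= 0):
            raise GridError(f"{name} grid must be ascending with >=2 points")
    dose = samples[dose_node].to_numpy(float)
    vals = samples[node].to_numpy(float)
    prob = np.zeros((len(delta_grid), len(dose_grid)))
    for j, d in enumerate(dose_grid):
        mask = np.abs(dose - d) <= epsilon
        n = int(mask.sum())
        if n == 0:
            raise EmptyWindowError(f"no samples near dose {d}")
        window = np.sort(vals[mask])
        # empirical exceedance via searchsorted: monotone in delta by construction
        prob[:, j] = 1.0 - np.searchsorted(window, delta_grid, side="right") / n
    surf = ProbabilitySurface(node, exposure, delta_grid, dose_grid, prob, 0.0)
    surf.vus = vus(surf)
    return surf


def vus(surface: ProbabilitySurface) -> float:
    """Composite 2-D trapezoid integral of the probability surface."""
    for g, name in ((surface.delta_grid, "delta"), (surface.dose_grid, "dose")):
        if len(g) < 2 or np.any(np.diff(g) <= 0):
            raise GridError(f"{name} grid must be ascending with >=2 points")
    inner = np.trapezoid(surface.prob, surface.dose_grid, axis=1)
    return float(np.trapezoid(inner, surface.delta_grid))
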