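"""Data-driven pruning of the pathway's dynamic network.

The wiring of an adverse outcome pathway need not be static under repeated
exposure: a lagged parent that is informative between exposures 4 and 5 may
carry no information between 2 and 3.  This module prunes the slice-wise
dynamic network edge by edge:

* nodes with several lagged parents — lasso regression with an
  LOOCV-selected penalty; parents whose coefficient is exactly zero at the
  selected penalty are dropped;
* nodes with a single lagged parent — ordinary regression; the edge is kept
  only if the slope's t-test p-value is below 0.05;
* reachability culling on the unrolled slice graph — any surviving edge
  whose child instance has no remaining directed path to the adverse
  outcome (at any later slice) is dropped as well;
* surviving parent sets are refit by OLS (relaxed-lasso style) and used to
  recompute the transition probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV
from sklearn.model_selection import LeaveOneOut

from .dbn import (
    DBNModel,
    PENALTY_GRID_DEFAULT,
    SliceParams,
    _aligned_slices,
    transition_catalog,
    transition_probability,
)
from .errors import EmptyConditioningError
from .gbn import DELTA_DEFAULT
from .graph import AOPGraph
from .resample import ReplicateDataset

REASON_LASSO = "lasso-zero"
REASON_PVALUE = "p>=0.05"
REASON_UNREACHABLE = "unreachable"


@dataclass(frozen=True)
class SliceEdge:
    """Lagged edge parent@(e−1) → child@e of the unrolled network."""

    exposure: int  # target slice e
    parent: str
    child: str


@dataclass
class PrunedDBN:
    """Pruning outcome: kept/dropped lagged edges and the refit slice models."""

    kept_edges: list[SliceEdge]
    dropped_edges: list[tuple[SliceEdge, str]]  # (edge, reason)
    base: DBNModel
    graph: AOPGraph = field(repr=False, default=None)

    def kept_at(self, exposure: int) -> list[SliceEdge]:
        return [e for e in self.kept_edges if e.exposure == exposure]

    def influences_ao(self, ke: str, tau: int, e: int) -> bool:
        """Does a kept lagged path run from ke@(e−τ) to AO@e?"""
        reach = _reachable_instances(self.kept_edges, self.graph.ao_node,
                                     targets={e})
        return (ke, e - tau) in reach

    def report(self) -> pd.DataFrame:
        rows = [
            {"slice_e": ed.exposure, "parent": ed.parent, "child": ed.child,
             "status": "kept", "reason": ""}
            for ed in self.kept_edges
        ] + [
            {"slice_e": ed.exposure, "parent": ed.parent, "child": ed.child,
             "status": "dropped", "reason": reason}
            for ed, reason in self.dropped_edges
        ]
        return (
            pd.DataFrame(rows)
            .sort_values(["slice_e", "child", "parent"])
            .reset_index(drop=True)
        )


def lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    penalty_grid: np.ndarray = PENALTY_GRID_DEFAULT,
    standardize: bool = True,
) -> tuple[np.ndarray, float]:
    """LOOCV lasso; returns coefficients (no intercept) and λ*.

    Predictors are standardized before the coordinate descent (penalties
    then act on comparable scales) and coefficients mapped back; an exact
    zero on the standardized scale is an exact zero on the original one.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    scale = X.std(axis=0, ddof=0) if standardize else np.ones(X.shape[1])
    scale = np.where(scale > 0, scale, 1.0)
    Xs = X / scale
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LassoCV(alphas=np.asarray(penalty_grid, float),
                        cv=LeaveOneOut(), max_iter=50_000)
        model.fit(Xs, y)
    return model.coef_ / scale, float(model.alpha_)


def slope_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided t-test p-value of a simple-regression slope."""
    if np.std(x) == 0 or len(x) < 3:
        return 1.0
    res = stats.linregress(x, y)
    return float(res.pvalue)


def _reachable_instances(
    kept: list[SliceEdge],
    ao: str,
    targets: set[int] | None = None,
) -> set[tuple[str, int]]:
    """Instances (node, exposure) with a kept directed path to AO.

    AO instances reach themselves by the empty path.  ``targets`` restricts
    which AO instances count as destinations.
    """
    children: dict[tuple[str, int], list[tuple[str, int]]] = {}
    instances: set[tuple[str, int]] = set()
    for ed in kept:
        a, b = (ed.parent, ed.exposure - 1), (ed.child, ed.exposure)
        children.setdefault(a, []).append(b)
        instances.update((a, b))
    good = {
        (v, e) for (v, e) in instances
        if v == ao and (targets is None or e in targets)
    }
    if targets is not None:
        good |= {(ao, e) for e in targets}
    # reverse reachability by fixed-point iteration (the slice graph is tiny)
    changed = True
    while changed:
        changed = False
        for a, kids in children.items():
            if a not in good and any(k in good for k in kids):
                good.add(a)
                changed = True
    return good


def lasso_prune(
    data: ReplicateDataset,
    graph: AOPGraph | None = None,
    penalty_grid: np.ndarray = PENALTY_GRID_DEFAULT,
    alpha: float = 0.05,
    dose: float | None = None,
) -> PrunedDBN:
    """Prune the slice-wise dynamic network and refit the kept edges."""
    graph = graph if graph is not None else data.graph
    exposures = sorted(data.means.exposure.unique())
    kept: list[SliceEdge] = []
    dropped: list[tuple[SliceEdge, str]] = []
    aligned = {}
    for e in exposures[1:]:
        e = int(e)
        prev, cur = _aligned_slices(data, e - 1, e, dose)
        aligned[e] = (prev, cur)
        for v in graph.biology_nodes:
            pa = graph.biology_parents(v)
            if not pa:
                continue
            y = cur[v].to_numpy(float)
            if len(pa) == 1:
                x = prev[pa[0]].to_numpy(float)
                if slope_pvalue(x, y) < alpha:
                    kept.append(SliceEdge(e, pa[0], v))
                else:
                    dropped.append((SliceEdge(e, pa[0], v), REASON_PVALUE))
            else:
                X = prev[pa].to_numpy(float)
                coef, _ = lasso_select(X, y, penalty_grid)
                for q, c in zip(pa, coef):
                    if c == 0.0:
                        dropped.append((SliceEdge(e, q, v), REASON_LASSO))
                    else:
                        kept.append(SliceEdge(e, q, v))

    # reachability culling on the unrolled slice graph (idempotent)
    reach = _reachable_instances(kept, graph.ao_node)
    still, culled = [], []
    for ed in kept:
        if (ed.child, ed.exposure) in reach:
            still.append(ed)
        else:
            culled.append((ed, REASON_UNREACHABLE))
    kept = still
    dropped.extend(culled)

    # relaxed-lasso refit of the surviving parent sets by OLS
    slices: dict[tuple[int, str], SliceParams] = {}
    for e in exposures[1:]:
        e = int(e)
        prev, cur = aligned[e]
        by_child: dict[str, list[str]] = {}
        for ed in kept:
            if ed.exposure == e:
                by_child.setdefault(ed.child, []).append(ed.parent)
        for v, pa in by_child.items():
            # preserve canonical parent order for determinism
            pa = [q for q in graph.biology_parents(v) if q in pa]
            X = np.column_stack([np.ones(len(prev))] +
                                [prev[q].to_numpy(float) for q in pa])
            y = cur[v].to_numpy(float)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            dof = max(len(y) - X.shape[1], 1)
            tss = float(((y - y.mean()) ** 2).sum())
            r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0
            slices[(e, v)] = SliceParams(v, pa, beta,
                                         float(resid @ resid) / dof, 0.0, r2)
    base = DBNModel(slices=slices, exposures=[int(e) for e in exposures[1:]],
                    dose_mode="pooled" if dose is None else str(dose),
                    graph=graph)
    return PrunedDBN(kept_edges=kept, dropped_edges=dropped, base=base,
                     graph=graph)


def pruned_transition_probability(
    pruned: PrunedDBN,
    data: ReplicateDataset,
    ke: str,
    tau: int,
    e: int,
    delta: float = DELTA_DEFAULT,
    n_sims: int = 100_000,
    seed: int = 0,
    init: str = "chain",
) -> dict:
    """One transition probability under the pruned, refit network.

    If no kept lagged path connects ke@(e−τ) to AO@e the pair is marked
    conditionally independent and no probability is simulated.
    """
    if not pruned.influences_ao(ke, tau, e):
        return {"ke": ke, "tau": tau, "e": e, "dose": pruned.base.dose_mode,
                "prob": np.nan, "n_conditioning": 0, "se": np.nan,
                "seed": seed, "delta": delta,
                "status": "conditionally independent"}
    # whole trajectories resampled from the pruned network (init="chain"),
    # or anchored at a bootstrap of the conditioning slice ("evidence").
    # Nodes lacking kept parents at a slice fall back to the empirical
    # bootstrap of that slice.
    graph = pruned.graph
    nodes = graph.biology_nodes
    idx = {v: i for i, v in enumerate(nodes)}
    rng = np.random.default_rng(seed)
    if init == "chain":
        e_start = 1
    else:
        emp_cond = data.means_matrix(e - tau, log=True)[nodes].to_numpy(float)
        e_start = e - tau
        if not (emp_cond[:, nodes.index(ke)] > delta).any():
            e_start = max(e - tau - 1, 1)
    emp0 = data.means_matrix(e_start, log=True)[nodes].to_numpy(float)
    state = emp0[rng.integers(0, len(emp0), n_sims)]
    cond = state if e_start == e - tau else None
    for step in range(e_start + 1, e + 1):
        emp = data.means_matrix(step, log=True)[nodes].to_numpy(float)
        new = np.empty_like(state)
        for v in nodes:
            p = pruned.base.slices.get((step, v))
            if p is None or not p.parents:
                # no kept incoming edge: the node's slice marginal, drawn
                # independently (the network has no within-slice edges)
                new[:, idx[v]] = emp[rng.integers(0, len(emp), n_sims), idx[v]]
                continue
            mean = p.beta[0] + state[:, [idx[q] for q in p.parents]] @ p.beta[1:]
            new[:, idx[v]] = mean + np.sqrt(max(p.sigma2, 0.0)) * \
                rng.standard_normal(n_sims)
        state = new
        if step == e - tau:
            cond = state
    ki, ai = idx[ke], idx[graph.ao_node]
    evidence = cond[:, ki] > delta
    n_cond = int(evidence.sum())
    if n_cond == 0:
        raise EmptyConditioningError(
            f"no trajectory satisfied {ke} > {delta:.4g} at e={e - tau}"
        )
    prob = float((state[evidence, ai] > delta).mean())
    return {"ke": ke, "tau": tau, "e": e, "dose": pruned.base.dose_mode,
            "prob": prob, "n_conditioning": n_cond,
            "se": float(np.sqrt(max(prob * (1 - prob), 0.0) / n_cond)),
            "seed": seed, "delta": delta, "status": "kept"}


def pruned_transitions(
    pruned: PrunedDBN,
    data: ReplicateDataset,
    delta: float = DELTA_DEFAULT,
    n_sims: int = 100_000,
    seed: int = 0,
    entries: list[tuple[str, int, int]] | None = None,
    init: str = "chain",
) -> pd.DataFrame:
    """Catalog transition probabilities on the pruned network."""
    E = max(pruned.base.exposures)
    entries = entries if entries is not None else transition_catalog(pruned.graph, E)
    rows = []
    for k, (ke, tau, e) in enumerate(entries):
        try:
            rows.append(
                pruned_transition_probability(pruned, data, ke, tau, e,
                                              delta, n_sims, seed + k, init)
            )
        except EmptyConditioningError:
            rows.append({"ke": ke, "tau": tau, "e": e,
                         "dose": pruned.base.dose_mode, "prob": np.nan,
                         "n_conditioning": 0, "se": np.nan, "seed": seed + k,
                         "delta": delta, "status": "empty conditioning"})
    return pd.DataFrame(rows)
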