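"""Replicate-level resampling of the primary dataset.

The primary dataset stores only per-cell means and SDs of fold changes.
Downstream network analyses need replicate-level data with realistic
cross-node correlation, so this module

1. converts each (donor, exposure, dose) cell to the parameters of a
   multivariate lognormal via exact moment matching on the natural-log
   scale:  μ_v = ln(f̄²/√(f̄² + s²)),  o_vv = ln(1 + s²/f̄²),  and
   o_vv' = ρ_vv' √(o_vv o_v'v') with a per-exposure empirical response–
   response correlation ρ;
2. learns per-node linear-Gaussian conditionals on the pathway parents by
   conjugate Bayesian updating across exposure repetitions — the posterior
   at exposure e−1 is the prior at e, the first exposure uses the OLS
   estimate, and the residual variance is plugged in as its OLS estimate;
3. draws a small number R of virtual replicates per cell from the
   posterior-predictive distribution — test rows for the parents come from
   the cell's moment-matched multivariate normal — and back-transforms to
   the fold-change scale.

Replicate-averaged fold changes from step 3 are the input to all
regression, static-network and dynamic-network analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateError, DomainError, SingularError
from .graph import AOPGraph
from .simulate import PrimaryDataset


# ---------------------------------------------------------------------------
# lognormal moment matching
# ---------------------------------------------------------------------------

@dataclass
class LogNormalParams:
    """Natural-log-scale mean vector and covariance for one cell."""

    nodes: list[str]
    mu: np.ndarray
    cov: np.ndarray
    rho: np.ndarray

    def marginal_sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def estimate_rho(
    primary: PrimaryDataset,
    exposure: int,
    nodes: list[str] | None = None,
    include_control: bool = True,
) -> pd.DataFrame:
    """Empirical node×node Pearson correlation at one exposure repetition.

    Mean fold-changes are pooled across all donor × dose cells of the
    exposure.  Control cells (identically 1 for every node) act as a
    common anchor; pass ``include_control=False`` to pool treatment doses
    only.  Nodes with zero pooled variance get zero off-diagonal
    correlation and unit diagonal.
    """
    nodes = nodes if nodes is not None else primary.graph.biology_nodes
    d = primary.data
    sub = d[d.exposure == exposure]
    if not include_control:
        sub = sub[sub.dose > 0]
    wide = sub.pivot_table(index=["donor", "dose"], columns="node", values="mean_fc")
    wide = wide[nodes]
    if len(wide) < 3:
        raise DegenerateError("need >=3 (donor, dose) cells to estimate rho")
    x = wide.to_numpy(float)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    rho = np.zeros((len(nodes), len(nodes)))
    if keep.any():
        sub_r = np.corrcoef(x[:, keep], rowvar=False)
        sub_r = np.atleast_2d(sub_r)
        idx = np.where(keep)[0]
        rho[np.ix_(idx, idx)] = sub_r
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    return pd.DataFrame(rho, index=nodes, columns=nodes)


def nearest_psd(cov: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Eigenvalue-clip repair that preserves the original diagonal."""
    diag = np.diag(cov).copy()
    w, q = np.linalg.eigh((cov + cov.T) / 2.0)
    if w.min() >= 0:
        return (cov + cov.T) / 2.0
    w = np.clip(w, floor, None)
    fixed = (q * w) @ q.T
    # rescale so the marginal variances are untouched
    d_fixed = np.diag(fixed)
    scale = np.sqrt(np.where(d_fixed > 0, diag / d_fixed, 1.0))
    fixed = fixed * np.outer(scale, scale)
    np.fill_diagonal(fixed, diag)
    return (fixed + fixed.T) / 2.0


def lognormal_params(
    mean_fc: np.ndarray,
    sd_fc: np.ndarray,
    rho: np.ndarray,
    nodes: list[str] | None = None,
) -> LogNormalParams:
    """Exact lognormal moment matching for one cell.

    ``mean_fc`` and ``sd_fc`` are fold-change scale; ``rho`` is the
    node×node correlation applied on the log scale.
    """
    f = np.asarray(mean_fc, float)
    s = np.asarray(sd_fc, float)
    if np.any(f <= 0):
        raise DomainError("mean fold-changes must be positive")
    if np.any(s < 0):
        raise DomainError("fold-change SDs must be non-negative")
    var_log = np.log1p((s / f) ** 2)
    mu = np.log(f**2 / np.sqrt(f**2 + s**2))
    sd_log = np.sqrt(var_log)
    cov = np.asarray(rho, float) * np.outer(sd_log, sd_log)
    np.fill_diagonal(cov, var_log)
    cov = nearest_psd(cov)
    if nodes is None:
        nodes = [f"v{i}" for i in range(len(f))]
    return LogNormalParams(nodes=list(nodes), mu=mu, cov=cov, rho=np.asarray(rho, float))


# ---------------------------------------------------------------------------
# conjugate Bayesian updating of linear-Gaussian conditionals
# ---------------------------------------------------------------------------

@dataclass
class PosteriorParams:
    """Linear-Gaussian conditional of one node given its pathway parents.

    The within-cell regression is through the origin on the log scale
    (control cells sit exactly at 0, so no intercept is needed):
    ``beta_pos`` holds one coefficient per parent, ``v_pos`` the posterior
    covariance of that vector, ``sigma2`` the plug-in residual variance.
    """

    node: str
    parents: list[str]
    beta_pos: np.ndarray
    v_pos: np.ndarray
    sigma2: float


def ols_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS coefficients and residual-variance estimate with denominator M−p."""
    M, p = X.shape
    if M <= p:
        raise SingularError("need more samples than predictors for the OLS plug-in")
    xtx = X.T @ X
    try:
        beta = np.linalg.solve(xtx, X.T @ y)
    except np.linalg.LinAlgError as err:
        raise SingularError("singular design in OLS") from err
    resid = y - X @ beta
    sigma2 = float(y @ resid) / (M - p)
    # numerical guard: y'(y - Xb) equals ||resid||^2 at the OLS solution but
    # can go slightly negative in floating point for near-perfect fits
    sigma2 = max(sigma2, float(resid @ resid) / (M - p), 0.0)
    return beta, sigma2


def bayes_update(
    beta_pr: np.ndarray,
    v_pr: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    sigma2: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Conjugate Gaussian update of regression coefficients, known σ².

    Returns (beta_pos, v_pos) with
    v_pos⁻¹ = v_pr⁻¹ + XᵀX/σ²  and  beta_pos = v_pos (v_pr⁻¹ β_pr + Xᵀy/σ²).
    """
    beta_pr = np.atleast_1d(np.asarray(beta_pr, float))
    v_pr = np.atleast_2d(np.asarray(v_pr, float))
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    if sigma2 <= 0:
        raise DomainError("sigma2 must be positive for the conjugate update")
    try:
        v_pr_inv = np.linalg.inv(v_pr)
    except np.linalg.LinAlgError as err:
        raise SingularError("prior covariance is singular") from err
    precision = v_pr_inv + (X.T @ X) / sigma2
    try:
        v_pos = np.linalg.inv(precision)
    except np.linalg.LinAlgError as err:
        raise SingularError("posterior precision is singular") from err
    beta_pos = v_pos @ (v_pr_inv @ beta_pr + (X.T @ y) / sigma2)
    v_pos = (v_pos + v_pos.T) / 2.0
    return beta_pos, v_pos


@dataclass
class TrainedCell:
    """Per-cell lognormal parameters plus per-node posteriors."""

    donor: int
    exposure: int
    dose: float
    lognormal: LogNormalParams
    posteriors: dict[str, PosteriorParams] = field(default_factory=dict)


@dataclass
class TrainedNetwork:
    """All trained cells of one study, keyed by (donor, exposure, dose)."""

    graph: AOPGraph
    kappa: int
    cells: dict[tuple[int, int, float], TrainedCell]

    def cell(self, donor: int, exposure: int, dose: float) -> TrainedCell:
        return self.cells[(donor, exposure, dose)]


def train_network(
    primary: PrimaryDataset,
    graph: AOPGraph | None = None,
    kappa: int | None = None,
    seed: int | None = None,
    rho_by_exposure: dict[int, pd.DataFrame] | None = None,
    prior: str = "flat",
) -> TrainedNetwork:
    """Learn per-cell linear-Gaussian conditionals by conjugate updating.

    κ log-scale draws from the moment-matched multivariate normal provide
    the within-cell samples; each node is regressed through the origin on
    its pathway parents.

    ``prior="flat"`` (default) applies the flat-prior limit of the
    conjugate update at every exposure: the posterior is the OLS estimate
    with covariance σ²(XᵀX)⁻¹ — the same treatment the first exposure
    always receives.  ``prior="chained"`` carries the previous exposure's
    posterior forward as the prior.  Chaining shrinks the conditional of a
    newly elicited chronic node toward its pre-onset (null) relationship by
    the fraction of pre-onset history, which visibly distorts the
    downstream node fits; the flat default keeps every cell anchored to its
    own moments.
    """
    if prior not in ("flat", "chained"):
        raise ValueError(f"unknown prior mode {prior!r}")
    graph = graph if graph is not None else primary.graph
    design = primary.design
    kappa = int(kappa if kappa is not None else design.kappa)
    seed = int(design.seed if seed is None else seed)
    nodes = graph.biology_nodes
    max_parents = max(len(graph.biology_parents(v)) for v in nodes)
    if kappa <= max_parents + 1:
        raise DomainError(f"kappa must exceed max |parents|+1 = {max_parents + 1}")
    # Eq.-style within-cell regression: through the origin on the log scale

    if rho_by_exposure is None:
        rho_by_exposure = {
            e: estimate_rho(primary, e, nodes)
            for e in range(1, design.n_exposures + 1)
        }

    rng = np.random.default_rng(seed)
    idx = {v: i for i, v in enumerate(nodes)}
    cells: dict[tuple[int, int, float], TrainedCell] = {}
    for dn in primary.donors:
        n = dn.donor_id
        for dose in design.doses:
            prev_post: dict[str, PosteriorParams] = {}
            for e in range(1, design.n_exposures + 1):
                f, s = primary.cell_vectors(n, e, dose, nodes)
                params = lognormal_params(f, s, rho_by_exposure[e].to_numpy(), nodes)
                # guard: control cells have zero covariance; draws are exact
                draws = rng.multivariate_normal(
                    params.mu, params.cov, size=kappa, method="eigh"
                )
                cell = TrainedCell(n, e, dose, params)
                for v in nodes:
                    pa = graph.biology_parents(v)
                    if not pa:
                        continue
                    X = np.column_stack([draws[:, idx[p]] for p in pa])
                    y = draws[:, idx[v]]
                    try:
                        beta_ols, sigma2 = ols_fit(X, y)
                    except SingularError:
                        # degenerate cell (control: all log draws are zero)
                        beta_ols = np.zeros(X.shape[1])
                        sigma2 = 0.0
                    if sigma2 <= 0 or prior == "flat" or v not in prev_post:
                        # flat-prior posterior (always used at the first
                        # exposure) or degenerate residual
                        if sigma2 > 0:
                            v_pos = sigma2 * np.linalg.inv(X.T @ X)
                            beta_pos = beta_ols
                        else:
                            v_pos = np.zeros((X.shape[1], X.shape[1]))
                            beta_pos = beta_ols
                    else:
                        pr = prev_post[v]
                        if np.all(np.linalg.eigvalsh(pr.v_pos) > 1e-12):
                            beta_pos, v_pos = bayes_update(
                                pr.beta_pos, pr.v_pos, X, y, sigma2
                            )
                        else:  # previous posterior degenerate: fall back to OLS
                            beta_pos = beta_ols
                            v_pos = sigma2 * np.linalg.inv(X.T @ X)
                    cell.posteriors[v] = PosteriorParams(
                        v, pa, beta_pos, v_pos, sigma2
                    )
                cells[(n, e, dose)] = cell
                prev_post = cell.posteriors
    return TrainedNetwork(graph=graph, kappa=kappa, cells=cells)


# ---------------------------------------------------------------------------
# posterior-predictive replicate resampling
# ---------------------------------------------------------------------------

@dataclass
class ReplicateDataset:
    """Virtual replicate-level fold changes and their replicate averages.

    ``replicates`` columns: donor, exposure, dose, replicate, node,
    fold_change.  ``means`` drops the replicate index and averages.
    """

    replicates: pd.DataFrame
    means: pd.DataFrame
    design: object
    graph: AOPGraph = field(repr=False, default=None)

    def means_matrix(
        self,
        exposure: int,
        dose: float | None = None,
        log: bool = True,
        with_dose: bool = False,
    ) -> pd.DataFrame:
        """Wide (donor, dose) × node matrix of replicate-mean fold changes.

        All analyses downstream of the resampler operate on log fold
        changes (the natural-log scale of the lognormal parameterization),
        so that is the default.
        """
        m = self.means[self.means.exposure == exposure]
        if dose is not None:
            m = m[m.dose == dose]
        wide = m.pivot_table(index=["donor", "dose"], columns="node",
                             values="fold_change")
        wide = wide[self.graph.biology_nodes]
        if log:
            wide = np.log(wide)
        if with_dose:
            wide.insert(0, self.graph.dose_node,
                        wide.index.get_level_values("dose").to_numpy(float))
        return wide


def resample_replicates(
    network: TrainedNetwork,
    n_replicates: int,
    seed: int,
) -> ReplicateDataset:
    """Posterior-predictive sampling of R replicates per cell.

    Each replicate row starts as a test draw from the cell's moment-matched
    multivariate normal; every node with pathway parents is then redrawn
    from its posterior predictive N(xβ̂_pos, σ² + x V_pos xᵀ) given the test
    values of its parents (one shared test row per replicate preserves
    cross-node coupling).  Nodes whose only parent is the dose root (the
    MIEs) keep their test draw — dose is constant within a cell so it
    cannot serve as a regressor there.  Values are back-transformed with
    exp().
    """
    graph = network.graph
    nodes = graph.biology_nodes
    idx = {v: i for i, v in enumerate(nodes)}
    rng = np.random.default_rng(seed)
    R = int(n_replicates)

    frames: list[pd.DataFrame] = []
    for (n, e, dose), cell in sorted(network.cells.items()):
        ln = cell.lognormal
        x_test = rng.multivariate_normal(ln.mu, ln.cov, size=R, method="eigh")
        x = x_test.copy()
        for v in nodes:
            post = cell.posteriors.get(v)
            if post is None:
                continue
            Xp = x_test[:, [idx[p] for p in post.parents]]
            mean = Xp @ post.beta_pos
            var = post.sigma2 + np.einsum("ij,jk,ik->i", Xp, post.v_pos, Xp)
            var = np.clip(var, 0.0, None)
            x[:, idx[v]] = mean + np.sqrt(var) * rng.standard_normal(R)
        fc = np.exp(x)
        frame = pd.DataFrame(fc, columns=nodes)
        frame.insert(0, "replicate", np.arange(1, R + 1))
        frame.insert(0, "dose", dose)
        frame.insert(0, "exposure", e)
        frame.insert(0, "donor", n)
        frames.append(frame)

    wide = pd.concat(frames, ignore_index=True)
    tidy = wide.melt(
        id_vars=["donor", "exposure", "dose", "replicate"],
        var_name="node",
        value_name="fold_change",
    )
    means = (
        tidy.groupby(["donor", "exposure", "dose", "node"], as_index=False)
        .fold_change.mean()
    )
    return ReplicateDataset(replicates=tidy, means=means, design=None, graph=graph)


def simulate_replicates(
    primary: PrimaryDataset,
    kappa: int | None = None,
    n_replicates: int | None = None,
    seed: int | None = None,
) -> ReplicateDataset:
    """Convenience: train the updating network and resample in one call."""
    design = primary.design
    seed = int(design.seed if seed is None else seed)
    network = train_network(primary, kappa=kappa, seed=seed)
    R = int(design.n_replicates if n_replicates is None else n_replicates)
    out = resample_replicates(network, R, seed=seed + 1)
    out.design = design
    return out
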