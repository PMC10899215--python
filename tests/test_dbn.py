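import numpy as np
import pandas as pd
import pytest
from scipy import stats

import qaopnet as q
from qaopnet import dbn
from qaopnet.errors import AlignmentError, DesignError
from conftest import make_linear_replicates


def _two_slice_data(mini, beta_lag, sigma, n_donors=100, seed=0):
    """Slice-1 states random; slice-2 states from a known lagged model."""
    rng = np.random.default_rng(seed)
    rows = []
    for n in range(1, n_donors + 1):
        for d in (0.0, 100.0):
            state = {v: rng.uniform(0.0, 1.0) for v in mini.biology_nodes}
            for v in mini.biology_nodes:
                rows.append((n, 1, d, v, float(np.exp(state[v]))))
            for v in mini.biology_nodes:
                pa = mini.biology_parents(v)
                if pa:
                    b0, b1 = beta_lag[v]
                    val = b0 + b1 * state[pa[0]] + sigma * rng.standard_normal()
                else:
                    val = rng.uniform(0.0, 1.0)
                rows.append((n, 2, d, v, float(np.exp(val))))
    means = pd.DataFrame(rows, columns=["donor", "exposure", "dose", "node",
                                        "fold_change"])
    return q.ReplicateDataset(replicates=means.assign(replicate=1),
                              means=means, design=None, graph=mini)


def test_ridge_at_zero_penalty_equals_ols():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 3))
    y = X @ [1.0, -2.0, 0.5] + 0.1 * rng.normal(size=40)
    beta, _, lam = dbn.ridge_loocv(X, y, penalty_grid=np.array([1e-12]))
    Xi = np.column_stack([np.ones(40), X])
    beta_ols = np.linalg.lstsq(Xi, y, rcond=None)[0]
    assert np.allclose(beta, beta_ols, atol=1e-8)


def test_ridge_at_huge_penalty_shrinks_to_zero():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(40, 3))
    y = X @ [1.0, -2.0, 0.5] + 0.1 * rng.normal(size=40)
    beta, _, _ = dbn.ridge_loocv(X, y, penalty_grid=np.array([1e12]))
    assert np.all(np.abs(beta[1:]) < 1e-6)


def test_loocv_selection_matches_brute_force_oracle():
    """The efficient leave-one-out penalty choice equals n refits."""
    rng = np.random.default_rng(2)
    n = 14
    X = rng.normal(size=(n, 2))
    y = X @ [1.0, 0.5] + 0.4 * rng.normal(size=n)
    grid = np.logspace(-3, 2, 8)
    press = []
    for lam in grid:
        errs = []
        for i in range(n):
            m = np.arange(n) != i
            Xc = X[m] - X[m].mean(0)
            yc = y[m] - y[m].mean()
            b = np.linalg.solve(Xc.T @ Xc + lam * np.eye(2), Xc.T @ yc)
            pred = (X[i] - X[m].mean(0)) @ b + y[m].mean()
            errs.append((y[i] - pred) ** 2)
        press.append(np.mean(errs))
    _, _, lam_star = dbn.ridge_loocv(X, y, penalty_grid=grid)
    assert lam_star == pytest.approx(grid[int(np.argmin(press))])


def test_lagged_parameter_recovery(mini):
    beta_lag = {"BM1": (0.1, 0.8), "KE1": (0.0, 1.2), "KE8": (0.2, 0.6),
                "AO": (0.0, 0.9)}
    data = _two_slice_data(mini, beta_lag, sigma=0.05, n_donors=100, seed=3)
    model = dbn.fit_dbn(data, mini)
    prev = data.means_matrix(1, log=True)
    for v, (b0, b1) in beta_lag.items():
        p = model.params(2, v)
        X = np.column_stack([np.ones(len(prev)), prev[p.parents[0]]])
        se = np.sqrt(np.diag(p.sigma2 * np.linalg.inv(X.T @ X)))
        assert abs(p.beta[0] - b0) < 3 * se[0] + p.lambda_
        assert abs(p.beta[1] - b1) < 3 * se[1] + p.lambda_


def test_slice_coefficients_are_non_stationary(study_replicates):
    """The AO conditional strengthens across exposure slices."""
    model = dbn.fit_dbn(study_replicates)
    b3 = model.params(3, "AO").beta[1]
    b6 = model.params(6, "AO").beta[1]
    assert b6 > b3


def test_alignment_error_on_disjoint_donors(mini):
    rows = []
    for v in mini.biology_nodes:
        rows.append((1, 1, 0.0, v, 1.0))
        rows.append((2, 2, 0.0, v, 1.0))
    means = pd.DataFrame(rows, columns=["donor", "exposure", "dose", "node",
                                        "fold_change"])
    data = q.ReplicateDataset(replicates=means.assign(replicate=1),
                              means=means, design=None, graph=mini)
    with pytest.raises(AlignmentError):
        dbn.fit_dbn(data, mini)


def test_per_dose_fit_warns_on_small_samples(study_replicates):
    with pytest.warns(dbn.SmallSampleWarning):
        dbn.fit_dbn(study_replicates, dose=200.0)


def test_deterministic_subthreshold_chain_gives_zero(mini):
    beta_lag = {"BM1": (0.9, 0.0), "KE1": (-1.0, 0.0), "KE8": (-1.0, 0.0),
                "AO": (-1.0, 0.0)}
    data = _two_slice_data(mini, beta_lag, sigma=1e-9, n_donors=30, seed=4)
    # raise slice-1 KE8 so the conditioning event has empirical support
    m = data.means
    m.loc[(m.exposure == 1) & (m.node == "KE8"), "fold_change"] = 3.0
    model = dbn.fit_dbn(data, mini)
    row = dbn.transition_probability(model, data, "KE8", 1, 2, n_sims=5000,
                                     seed=5, init="evidence")
    assert row["prob"] == 0.0
    assert row["n_conditioning"] == 5000


def test_vacuous_evidence_equals_unconditional(mini):
    beta_lag = {"BM1": (0.0, 0.9), "KE1": (0.0, 0.9), "KE8": (0.25, 0.2),
                "AO": (0.25, 0.2)}
    data = _two_slice_data(mini, beta_lag, sigma=0.08, n_donors=30, seed=6)
    m = data.means
    # every slice-1 KE8 value exceeds the threshold: evidence is vacuous
    m.loc[(m.exposure == 1) & (m.node == "KE8"), "fold_change"] = 5.0
    model = dbn.fit_dbn(data, mini)
    row = dbn.transition_probability(model, data, "KE8", 1, 2, n_sims=40_000,
                                     seed=7, init="evidence")
    assert row["n_conditioning"] == 40_000
    _, final = dbn.forward_simulate(model, data, 1, 2, 40_000, seed=7)
    uncond = (final[:, mini.biology_nodes.index("AO")] > 0.30103).mean()
    assert row["prob"] == pytest.approx(uncond, abs=1e-12)


def test_transition_matches_conditional_gaussian_oracle(mini):
    """One slice pair, evidence on the observed state: the estimate equals
    the average Gaussian tail probability over the conditioning rows."""
    beta_lag = {"BM1": (0.0, 0.9), "KE1": (0.0, 0.9), "KE8": (0.0, 0.9),
                "AO": (0.05, 0.7)}
    data = _two_slice_data(mini, beta_lag, sigma=0.1, n_donors=100, seed=8)
    model = dbn.fit_dbn(data, mini)
    row = dbn.transition_probability(model, data, "KE8", 1, 2, n_sims=200_000,
                                     seed=9, init="evidence")
    p = model.params(2, "AO")
    prev = data.means_matrix(1, log=True)
    x = prev["KE8"].to_numpy()
    x = x[x > 0.30103]
    exact = stats.norm.sf(
        0.30103, loc=p.beta[0] + p.beta[1] * x, scale=np.sqrt(p.sigma2)
    ).mean()
    assert abs(row["prob"] - exact) <= 3 * row["se"] + 0.01


def test_transition_table_is_deterministic(study_replicates):
    model = dbn.fit_dbn(study_replicates)
    entries = [("KE8", 1, 4), ("KE4", 2, 5)]
    a = dbn.transition_table(model, study_replicates, n_sims=5000, seed=1,
                             entries=entries)
    b = dbn.transition_table(model, study_replicates, n_sims=5000, seed=1,
                             entries=entries)
    pd.testing.assert_frame_equal(a, b)


def test_catalog_respects_lag_structure_and_horizon(graph):
    triples = dbn.transition_catalog(graph, 6)
    taus = {ke: tau for ke, tau, _ in triples}
    assert taus == {"KE8": 1, "KE4": 2, "KE5": 2, "KE6": 2, "KE7": 2,
                    "KE2": 3, "KE3": 3}
    assert [(k, t, e) for k, t, e in triples if k == "KE8"] == \
        [("KE8", 1, 3), ("KE8", 1, 4), ("KE8", 1, 5), ("KE8", 1, 6)]
    # a 3-exposure study leaves no room for lag-3 (or lag-2) queries
    short = dbn.transition_catalog(graph, 3)
    assert {t for _, t, _ in short} == {1}


def test_short_study_rejects_long_lag_queries(tiny_bundle):
    _, reps = tiny_bundle
    model = dbn.fit_dbn(reps)
    with pytest.raises(DesignError):
        dbn.transition_probability(model, reps, "KE8", 3, 6, n_sims=100)
    with pytest.raises(DesignError):
        dbn.transition_probability(model, reps, "KE8", 1, 1, n_sims=100)


def test_pooled_close_to_dose_average_when_doses_identical(mini):
    beta_lag = {"BM1": (0.0, 0.9), "KE1": (0.0, 0.9), "KE8": (0.0, 0.9),
                "AO": (0.05, 0.7)}
    data = _two_slice_data(mini, beta_lag, sigma=0.1, n_donors=60, seed=10)
    # duplicate the same rows across both dose groups
    m = data.means
    base = m[m.dose == 0.0].copy()
    other = base.copy()
    other["dose"] = 100.0
    data.means = pd.concat([base, other], ignore_index=True)
    data.replicates = data.means.assign(replicate=1)
    pooled = dbn.transition_probability(dbn.fit_dbn(data, mini), data, "KE8",
                                        1, 2, n_sims=50_000, seed=11)
    per = dbn.dose_specific_transitions(data, mini, n_sims=50_000, seed=11,
                                        entries=[("KE8", 1, 2)])
    assert abs(per.prob.mean() - pooled["prob"]) < 0.02


def test_model_round_trip(tmp_path, study_replicates):
    model = dbn.fit_dbn(study_replicates)
    path = tmp_path / "dbn.json"
    model.save(path)
    again = dbn.DBNModel.load(path)
    assert set(again.slices) == set(model.slices)
    p, p2 = model.params(5, "AO"), again.params(5, "AO")
    assert np.allclose(p.beta, p2.beta)
    assert p.lambda_ == p2.lambda_
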