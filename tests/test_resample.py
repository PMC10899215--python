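import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import qaopnet as q
from qaopnet import resample as rs
from qaopnet.errors import DomainError


# -- lognormal moment matching ------------------------------------------------

def test_lognormal_params_degenerate_and_worked_case():
    p = rs.lognormal_params([1.0], [0.0], np.eye(1))
    assert p.mu[0] == pytest.approx(0.0) and p.cov[0, 0] == pytest.approx(0.0)
    p = rs.lognormal_params([2.0], [1.0], np.eye(1))
    assert p.mu[0] == pytest.approx(np.log(4 / np.sqrt(5)))
    assert p.cov[0, 0] == pytest.approx(np.log(1.25))
    with pytest.raises(DomainError):
        rs.lognormal_params([0.0], [1.0], np.eye(1))


def test_zero_correlation_gives_diagonal_covariance():
    p = rs.lognormal_params([2.0, 3.0], [0.5, 0.4], np.eye(2))
    off = p.cov[0, 1]
    assert off == 0.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    f=st.floats(0.2, 10.0),
    s=st.floats(0.0, 3.0),
)
def test_moment_matching_is_exact_inversion(f, s):
    """exp-moments of the fitted normal reproduce (f, s) algebraically."""
    p = rs.lognormal_params([f], [s], np.eye(1))
    mu, o = p.mu[0], p.cov[0, 0]
    assert np.exp(mu + o / 2) == pytest.approx(f, rel=1e-10)
    var = (np.exp(o) - 1) * np.exp(2 * mu + o)
    assert var == pytest.approx(s**2, rel=1e-8, abs=1e-12)


def test_moment_recovery_by_simulation():
    """1e5 multivariate draws reproduce means and SDs within 2%."""
    f = np.array([1.5, 2.5, 4.0])
    s = np.array([0.3, 0.6, 1.0])
    rho = np.array([[1.0, 0.6, 0.3], [0.6, 1.0, 0.5], [0.3, 0.5, 1.0]])
    p = rs.lognormal_params(f, s, rho)
    rng = np.random.default_rng(1)
    draws = np.exp(rng.multivariate_normal(p.mu, p.cov, size=100_000))
    assert np.allclose(draws.mean(axis=0), f, rtol=0.02)
    assert np.allclose(draws.std(axis=0), s, rtol=0.02)


def test_psd_repair_preserves_diagonal():
    bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
    fixed = rs.nearest_psd(bad)
    assert np.all(np.linalg.eigvalsh(fixed) >= 0)
    assert np.allclose(np.diag(fixed), np.diag(bad))


# -- empirical correlation ----------------------------------------------------

def test_rho_identity_and_comonotone(study_bundle):
    primary, _ = study_bundle
    rho = q.estimate_rho(primary, 1)
    assert np.allclose(np.diag(rho), 1.0)
    assert rho.le(1.0).all().all() and rho.ge(-1.0).all().all()
    # two acute nodes share the dose-monotone trend: strongly correlated
    assert rho.loc["KE1", "BM5"] > 0.5


def test_acute_chronic_rho_small_before_onset():
    """With the control anchor excluded, pre-onset chronic noise is
    uncorrelated with the acute dose response at the first exposure."""
    vals = []
    for seed in range(6):
        primary = q.generate_primary(q.StudyDesign(seed=200 + seed))
        rho = q.estimate_rho(primary, 1, include_control=False)
        acute = [v for v in primary.graph.acute_nodes()]
        chronic = primary.graph.chronic_nodes()
        vals.append(rho.loc[acute, chronic].to_numpy().mean())
    assert abs(np.mean(vals)) < 0.15


# -- conjugate updating -------------------------------------------------------

def test_flat_prior_limit_recovers_ols():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(60, 2))
    y = X @ [1.5, -0.7] + 0.1 * rng.normal(size=60)
    beta_ols, _ = rs.ols_fit(X, y)
    beta_pos, _ = rs.bayes_update(np.zeros(2), 1e6 * np.eye(2), X, y, 0.01)
    assert np.allclose(beta_pos, beta_ols, atol=1e-4)


def test_uninformative_data_keeps_prior():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(30, 1))
    y = rng.normal(size=30)
    beta_pos, _ = rs.bayes_update([2.0], 1e-6 * np.eye(1), X, y, 1e6)
    assert beta_pos[0] == pytest.approx(2.0, abs=1e-3)


def test_single_predictor_update_matches_hand_arithmetic():
    """x=(1,2,3), y=(1,2,3), prior N(0,1), sigma2=1: scalar conjugate algebra
    gives V_pos = 1/(1 + 14) and beta_pos = (1/15)*(0 + 14) = 14/15."""
    X = np.array([[1.0], [2.0], [3.0]])
    y = np.array([1.0, 2.0, 3.0])
    sxx = float((X**2).sum())       # 14
    sxy = float((X[:, 0] * y).sum())  # 14
    v_expected = 1.0 / (1.0 / 1.0 + sxx / 1.0)
    b_expected = v_expected * (0.0 + sxy)
    beta_pos, v_pos = rs.bayes_update([0.0], np.eye(1), X, y, 1.0)
    assert beta_pos[0] == pytest.approx(b_expected, abs=1e-10)
    assert v_pos[0, 0] == pytest.approx(v_expected, abs=1e-10)
    assert b_expected == pytest.approx(14 / 15)


def test_sequential_updates_equal_single_batch():
    rng = np.random.default_rng(4)
    XA, XB = rng.normal(size=(20, 2)), rng.normal(size=(25, 2))
    yA, yB = rng.normal(size=20), rng.normal(size=25)
    prior_b, prior_v = np.array([0.5, -0.5]), np.diag([2.0, 3.0])
    s2 = 0.7
    b1, v1 = rs.bayes_update(prior_b, prior_v, XA, yA, s2)
    b2, v2 = rs.bayes_update(b1, v1, XB, yB, s2)
    b12, v12 = rs.bayes_update(prior_b, prior_v,
                               np.vstack([XA, XB]), np.r_[yA, yB], s2)
    assert np.allclose(b2, b12, atol=1e-10)
    assert np.allclose(v2, v12, atol=1e-10)


def test_information_never_decreases():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(40, 2))
    y = rng.normal(size=40)
    prior_v = np.diag([1.0, 2.0])
    _, v_pos = rs.bayes_update(np.zeros(2), prior_v, X, y, 1.0)
    gain = np.linalg.inv(v_pos) - np.linalg.inv(prior_v)
    assert np.all(np.linalg.eigvalsh(gain) >= -1e-10)


def test_posterior_covariance_trace_shrinks_with_kappa():
    rng = np.random.default_rng(6)
    traces = []
    for kappa in (20, 80, 320):
        X = rng.normal(size=(kappa, 2))
        y = X @ [1.0, 1.0] + rng.normal(size=kappa)
        _, v_pos = rs.bayes_update(np.zeros(2), np.eye(2), X, y, 1.0)
        traces.append(np.trace(v_pos))
    assert traces[0] > traces[1] > traces[2]


# -- replicate resampling -----------------------------------------------------

def test_resampling_is_deterministic(tiny_bundle):
    primary, _ = tiny_bundle
    a = q.simulate_replicates(primary, seed=9)
    b = q.simulate_replicates(primary, seed=9)
    pd.testing.assert_frame_equal(a.replicates, b.replicates)
    c = q.simulate_replicates(primary, seed=10)
    assert not c.replicates.equals(a.replicates)


def test_control_replicates_are_exactly_one(study_replicates):
    ctrl = study_replicates.replicates.query("dose == 0")
    assert np.allclose(ctrl.fold_change, 1.0)


def test_replicate_mean_recovers_lognormal_mean(tiny_bundle):
    """With many replicates the root node's average matches exp(mu + o/2)."""
    primary, _ = tiny_bundle
    net = rs.train_network(primary)
    reps = rs.resample_replicates(net, 10_000, seed=12)
    cell = net.cell(1, 3, 100.0)
    i = primary.graph.biology_nodes.index("MIE1")
    expected = np.exp(cell.lognormal.mu[i] + cell.lognormal.cov[i, i] / 2)
    m = reps.means.query("donor == 1 and exposure == 3 and dose == 100.0 "
                         "and node == 'MIE1'").fold_change.iloc[0]
    sd = np.exp(cell.lognormal.mu[i]) * np.sqrt(cell.lognormal.cov[i, i])
    assert abs(m - expected) < 3 * (sd / np.sqrt(10_000)) + 0.01 * expected


def test_chronic_elicitation_survives_resampling(study_bundle):
    """Post-onset chronic cells keep clearly elevated replicate means."""
    _, reps = study_bundle
    m = reps.means_matrix(5, log=True)
    elicited = m.loc[[(2, 200.0), (4, 200.0)]]
    assert (elicited[["KE4", "KE8", "AO"]] > 0.3).all().all()
    never = m.loc[[(7, 200.0), (8, 200.0)]]
    assert (never[["KE4", "KE8", "AO"]] < 0.3).all().all()


def test_chained_prior_shrinks_newly_elicited_conditionals():
    """The literal exposure-chained prior attenuates the acute-to-chronic
    junction at onset relative to the flat-prior default."""
    primary = q.generate_primary(q.StudyDesign(seed=3))
    flat = rs.train_network(primary, prior="flat")
    chained = rs.train_network(primary, prior="chained")
    b_flat = flat.cell(2, 4, 200.0).posteriors["KE2"].beta_pos[0]
    b_chain = chained.cell(2, 4, 200.0).posteriors["KE2"].beta_pos[0]
    assert b_chain < b_flat
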