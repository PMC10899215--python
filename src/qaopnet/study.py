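"""End-to-end reproduction of the repeated-exposure study's headline numbers.

One call to :func:`seed_metrics` regenerates the virtual study for a seed,
runs the static and dynamic network analyses and the pruning step, and
returns the quantities the study reports: AO transition probabilities by
upstream lag, chronic activation probabilities before and after onset,
chronic node-fit quality, and the pruned-network probabilities.
"""

from __future__ import annotations

import time

import numpy as np

from . import dbn, gbn, prune
from .errors import EmptyConditioningError
from .resample import simulate_replicates
from .simulate import StudyDesign, generate_primary

LAG2_KES = ("KE4", "KE5", "KE6", "KE7")
CHRONIC_R2_NODES = ("KE4", "KE5", "KE6", "KE8", "AO")


def _safe_prob(fn) -> float:
    try:
        return float(fn()["prob"])
    except EmptyConditioningError:
        return float("nan")


def seed_metrics(
    seed: int,
    n_sims: int = 100_000,
    n_logic: int = 100_000,
    include_pruned: bool = True,
) -> dict:
    """All headline quantities for one realization of the virtual study."""
    timings: dict[str, float] = {}
    t0 = time.time()
    primary = generate_primary(StudyDesign(seed=seed))
    reps = simulate_replicates(primary)
    graph = primary.graph
    timings["data"] = time.time() - t0

    # dynamic network: pooled-dose transition probabilities
    t0 = time.time()
    model = dbn.fit_dbn(reps, graph)
    tp = lambda ke, tau, e, k: _safe_prob(
        lambda: dbn.transition_probability(model, reps, ke, tau, e,
                                           n_sims=n_sims, seed=seed + k)
    )
    ke8_lag1 = {e: tp("KE8", 1, e, e) for e in (4, 5, 6)}
    lag2_e6 = {k: tp(k, 2, 6, 10 + i) for i, k in enumerate(LAG2_KES)}
    lag2_e5 = {k: tp(k, 2, 5, 20 + i) for i, k in enumerate(LAG2_KES)}
    timings["dbn"] = time.time() - t0

    # static networks: node fits and activation probabilities
    t0 = time.time()
    doses = [d for d in primary.design.doses if d > 0]
    eps = 0.05 * (max(primary.design.doses) - min(primary.design.doses))
    act_min_56, act_max_12, r2_min = 1.0, 0.0, 1.0
    chronic = graph.chronic_nodes()
    for e in range(1, primary.design.n_exposures + 1):
        g = gbn.fit_gbn(reps, e, graph)
        if e >= 3:
            r2_min = min(r2_min, *(g.node_r2[v] for v in CHRONIC_R2_NODES))
        if e in (1, 2, 5, 6):
            samples = gbn.logic_sample(g, n_logic, seed=seed * 10 + e)
            for v in chronic:
                for d in doses:
                    p, _ = gbn.activation_probability(
                        samples, gbn.ActivationQuery(v, dose=d, epsilon=eps)
                    )
                    if e in (5, 6):
                        act_min_56 = min(act_min_56, p)
                    else:
                        act_max_12 = max(act_max_12, p)
    timings["gbn"] = time.time() - t0

    out = {
        "seed": seed,
        "p_ao_given_ke8_lag1": ke8_lag1,
        "p_ao_given_lag2_at_e4": lag2_e6,
        "p_ao_given_lag2_at_e3": lag2_e5,
        "chronic_activation_min_e56": act_min_56,
        "chronic_activation_max_e12": act_max_12,
        "gbn_chronic_r2_min": r2_min,
        "timings": timings,
    }

    if include_pruned:
        t0 = time.time()
        pruned = prune.lasso_prune(reps, graph)
        kept = {(ed.parent, ed.child, ed.exposure) for ed in pruned.kept_edges}
        out["ke8_e2_ao_e3_dropped"] = ("KE8", "AO", 3) not in kept
        out["ke8_later_slices_kept"] = all(
            ("KE8", "AO", e) in kept for e in (4, 5, 6)
        )
        row = prune.pruned_transition_probability(
            pruned, reps, "KE4", 2, 5, n_sims=n_sims, seed=seed + 30
        )
        out["pruned_p_ao5_given_ke4_e3"] = float(row["prob"])
        row = prune.pruned_transition_probability(
            pruned, reps, "KE5", 2, 6, n_sims=n_sims, seed=seed + 31
        )
        out["pruned_p_ao6_given_ke5_e4"] = float(row["prob"])
        timings["prune"] = time.time() - t0

    return out


def aggregate_metrics(per_seed: list[dict]) -> dict:
    """Across-seed summaries on the scales the study reports."""
    m = per_seed

    def nanmean(vals):
        vals = [v for v in vals if v == v]
        return float(np.mean(vals)) if vals else float("nan")

    t1 = nanmean([nanmean(list(s["p_ao_given_ke8_lag1"].values())) for s in m])
    t2 = nanmean([nanmean(list(s["p_ao_given_lag2_at_e4"].values())) for s in m])
    t3 = nanmean([nanmean(list(s["p_ao_given_lag2_at_e3"].values())) for s in m])
    act = float(np.median([s["chronic_activation_min_e56"] for s in m]))
    r2 = float(np.median([s["gbn_chronic_r2_min"] for s in m]))
    out = {
        "ke8_lag1_transition": t1,
        "lag2_transition_at_e4": t2,
        "lag2_transition_at_e3": t3,
        "chronic_activation_min_pct": 100.0 * act,
        "chronic_r2_min": r2,
    }
    if "pruned_p_ao5_given_ke4_e3" in m[0]:
        out["pruned_ke4_transition"] = nanmean(
            [s["pruned_p_ao5_given_ke4_e3"] for s in m]
        )
        out["pruned_ke5_transition"] = nanmean(
            [s["pruned_p_ao6_given_ke5_e4"] for s in m]
        )
    return out
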