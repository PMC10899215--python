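import numpy as np
import pytest

import qaopnet as q


@pytest.fixture(scope="session")
def graph():
    return q.canonical_graph()


@pytest.fixture(scope="session")
def mini():
    return q.mini_graph()


@pytest.fixture(scope="session")
def tiny_bundle():
    """2 donors x 2 doses x 3 exposures on the 5-node chain."""
    return q.make_fixtures("tiny", seed=11)


@pytest.fixture(scope="session")
def study_bundle():
    """One paper-scale realization (8 donors, 4 doses, 6 exposures)."""
    primary = q.generate_primary(q.StudyDesign(seed=0))
    replicates = q.simulate_replicates(primary)
    return primary, replicates


@pytest.fixture(scope="session")
def study_replicates(study_bundle):
    return study_bundle[1]


def make_linear_replicates(graph, beta, sigma, n_donors=50,
                           doses=(0.0, 50.0, 100.0, 200.0), seed=0,
                           exposures=(1,)):
    """Synthetic replicate-mean data from a known linear-Gaussian network.

    ``beta`` maps node -> (intercept, coef per parent); values are on the
    log scale and exported as fold changes.  Used as ground truth for
    parameter-recovery tests.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    frames = []
    for e in exposures:
        rows = []
        for n in range(1, n_donors + 1):
            for d in doses:
                vals = {graph.dose_node: d}
                for v in graph.topological_order(include_dose=False):
                    b0, *bs = beta[v]
                    mean = b0 + sum(
                        b * vals[p] for b, p in zip(bs, graph.parents(v))
                    )
                    vals[v] = mean + sigma * rng.standard_normal()
                for v in graph.biology_nodes:
                    rows.append((n, e, d, v, float(np.exp(vals[v]))))
        frames.append(pd.DataFrame(
            rows, columns=["donor", "exposure", "dose", "node", "fold_change"]
        ))
    means = __import__("pandas").concat(frames, ignore_index=True)
    reps = means.assign(replicate=1)
    return q.ReplicateDataset(replicates=reps, means=means, design=None,
                              graph=graph)
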