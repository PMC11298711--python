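import numpy as np
import pandas as pd
import pytest

from tfnbs.harmonize import CohortDataset, build_dataset
from tfnbs.simulate import CohortSpec, make_parcellation, null_spec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """40-subject, 20-node cohort with planted effect and two batches."""
    spec = CohortSpec(
        n_group_a=20,
        n_group_b=20,
        n_nodes=20,
        edge_density=0.5,
        effect_size=1.0,
        planted_edge_fraction=0.1,
        batch_shift=(0.0, 0.5),
        batch_scale=(1.0, 1.3),
        seed=42,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return build_dataset(
        small_cohort.matrices, small_cohort.covariates, small_cohort.parcellation
    )


@pytest.fixture(scope="session")
def null_cohort():
    """Single-batch cohort with no group/covariate/batch effects."""
    spec = null_spec(n_group_a=25, n_group_b=25, n_nodes=15, edge_density=0.6, seed=7)
    return simulate_cohort(spec)


@pytest.fixture()
def one_edge_dataset():
    """A single edge over the printed toy groups {1,2,3} vs {3,4,5}."""
    parc = make_parcellation(2, "uniform")
    Y = np.array([[1.0, 2.0, 3.0, 3.0, 4.0, 5.0]])
    cov = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(6)],
            "group": ["A"] * 3 + ["B"] * 3,
            "age": [30.0, 40.0, 50.0, 35.0, 45.0, 55.0],
            "sex": [0, 1, 0, 1, 0, 1],
            "batch": ["b"] * 6,
        }
    )
    return CohortDataset(Y, np.array([[0, 1]]), cov, parc, log_scale=True)


def naive_tfce(t_matrix, E, H, K, h_max):
    """Independent threshold-loop TFCE oracle with BFS components.

    Deliberately avoids the package's union-find core: loops every rung of the
    ladder and re-derives components from scratch by breadth-first search.
    """
    t_matrix = np.asarray(t_matrix, dtype=float)
    n = t_matrix.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    tv = t_matrix[iu, ju]
    dh = h_max / K
    scores = np.zeros(len(tv))
    for k in range(1, K + 1):
        h = k * dh
        act = np.flatnonzero(tv > h)
        if len(act) == 0:
            continue
        adj = {}
        for e in act:
            adj.setdefault(iu[e], []).append((ju[e], e))
            adj.setdefault(ju[e], []).append((iu[e], e))
        comp_size = {}
        for e in act:
            if e in comp_size:
                continue
            stack = [iu[e], ju[e]]
            visited = set(stack)
            comp_edges = set()
            while stack:
                node = stack.pop()
                for nb, ee in adj.get(node, []):
                    comp_edges.add(ee)
                    if nb not in visited:
                        visited.add(nb)
                        stack.append(nb)
            for ee in comp_edges:
                comp_size[ee] = len(comp_edges)
        for e in act:
            scores[e] += comp_size[e] ** E * h**H * dh
    mat = np.zeros((n, n))
    mat[iu, ju] = scores
    mat[ju, iu] = scores
    return mat
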