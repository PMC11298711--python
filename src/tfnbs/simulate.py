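"""Synthetic structural-connectome cohorts.

Generates node parcellations and cohorts of sparse symmetric structural
connectivity matrices (SCMs) with the statistical structure the downstream
analysis assumes: log-normal edge weights on a support mask shared across
subjects, age and sex covariate effects, per-batch additive (location) and
multiplicative (noise scale) scanner effects, and a planted group-difference
subnetwork whose edges are known exactly (the ground truth for power and
calibration studies).

The generative model, per present edge ``e`` and subject ``i``::

    log w_ie = mu_e
               - effect_size * sigma_e * 1[i in group B] * 1[e planted]
               + beta_age * age_i + beta_sex * sex_i
               + batch_shift[b_i] + batch_scale[b_i] * eps_ie,
    eps_ie ~ Normal(0, sigma_e)

Weights are returned on the natural (exponentiated) scale; absent edges are
exactly zero in every subject. The planted effect is a *decrease* for group B
by default, the dominant directionality in patient-vs-control comparisons of
white-matter tract cross-sectional area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LOBES",
    "HEMISPHERES",
    "Parcellation",
    "CohortSpec",
    "SyntheticCohort",
    "make_parcellation",
    "simulate_cohort",
    "truth_mask",
]

LOBES = ("frontal", "occipital", "parietal", "temporal", "subcortical")
HEMISPHERES = ("left", "right")

# Cortical region counts per hemisphere echoing the Destrieux atlas proportions
# (74 cortical parcels + 7 subcortical structures = 81 per hemisphere). Region
# names are synthetic stand-ins, not atlas label strings.
_DESTRIEUX_LOBE_COUNTS = {
    "frontal": 26,
    "occipital": 14,
    "parietal": 16,
    "temporal": 18,
    "subcortical": 7,
}


@dataclass(frozen=True)
class Parcellation:
    """Node lookup: contiguous node ids with region name, lobe and hemisphere."""

    frame: pd.DataFrame  # columns: node_id, region_name, lobe, hemisphere

    def __post_init__(self) -> None:
        f = self.frame
        required = ["node_id", "region_name", "lobe", "hemisphere"]
        missing = [c for c in required if c not in f.columns]
        if missing:
            raise ValueError(f"parcellation missing columns {missing}")
        ids = f["node_id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(f))):
            raise ValueError("node ids must be the contiguous range 0..n-1")
        bad_lobe = set(f["lobe"]) - set(LOBES)
        if bad_lobe:
            raise ValueError(f"unknown lobe classes {sorted(bad_lobe)}")
        bad_hemi = set(f["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ValueError(f"unknown hemispheres {sorted(bad_hemi)}")

    @property
    def n_nodes(self) -> int:
        return len(self.frame)

    @property
    def lobes(self) -> np.ndarray:
        return self.frame["lobe"].to_numpy()

    @property
    def region_names(self) -> np.ndarray:
        return self.frame["region_name"].to_numpy()

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Parcellation":
        return cls(pd.read_csv(path, sep="\t"))


def make_parcellation(n_nodes: int, scheme: str = "uniform") -> Parcellation:
    """Build a node parcellation.

    ``destrieux162`` requires exactly 162 nodes and assigns 81 per hemisphere
    with Destrieux-like lobe proportions; ``uniform`` distributes any number of
    nodes round-robin over the five lobe classes and alternates hemispheres.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    rows = []
    if scheme == "destrieux162":
        if n_nodes != 162:
            raise ValueError("destrieux162 scheme requires n_nodes == 162")
        node = 0
        for hemi in HEMISPHERES:
            h = "lh" if hemi == "left" else "rh"
            for lobe in LOBES:
                for j in range(_DESTRIEUX_LOBE_COUNTS[lobe]):
                    rows.append((node, f"{h}_{lobe}_{j:02d}", lobe, hemi))
                    node += 1
    elif scheme == "uniform":
        for i in range(n_nodes):
            lobe = LOBES[i % len(LOBES)]
            hemi = HEMISPHERES[(i // len(LOBES)) % 2]
            h = "lh" if hemi == "left" else "rh"
            rows.append((i, f"{h}_{lobe}_{i:03d}", lobe, hemi))
    else:
        raise ValueError(f"unknown parcellation scheme {scheme!r}")
    frame = pd.DataFrame(rows, columns=["node_id", "region_name", "lobe", "hemisphere"])
    return Parcellation(frame)


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for a synthetic cohort.

    Defaults mirror a two-scanner-epoch patient/control design: 50 controls
    (group A) vs 92 patients (group B) on a 162-node parcellation, ages 18-60,
    a planted decrease of 0.8 within-edge SDs on 5% of present edges, mild age
    decline and sex offset on the log scale, and a second batch with a +0.2
    log-unit shift and 1.2x noise scale.
    """

    n_group_a: int = 50
    n_group_b: int = 92
    n_nodes: int = 162
    edge_density: float = 0.35
    effect_size: float = 0.8
    planted_edge_fraction: float = 0.05
    beta_age: float = -0.01
    beta_sex: float = 0.1
    batch_shift: tuple = (0.0, 0.2)
    batch_scale: tuple = (1.0, 1.2)
    age_range: tuple = (18.0, 60.0)
    planted_connected: bool = True
    group_labels: tuple = ("HC", "TLE")
    batch_labels: tuple = ("DV25", "DV26")
    subgroups: bool = True
    mu_mean: float = 4.0
    mu_sd: float = 0.75
    sigma_range: tuple = (0.3, 0.6)
    seed: int = 0

    def validate(self) -> None:
        if self.n_group_a <= 0 or self.n_group_b <= 0 or self.n_nodes < 2:
            raise ValueError("group sizes and n_nodes must be positive")
        if not (0.0 < self.edge_density <= 1.0):
            raise ValueError("edge_density must lie in (0, 1]")
        if not (0.0 <= self.planted_edge_fraction <= 1.0):
            raise ValueError("planted_edge_fraction must lie in [0, 1]")
        if len(self.batch_shift) != len(self.batch_scale):
            raise ValueError("batch_shift and batch_scale must have equal length")
        if len(self.batch_shift) != len(self.batch_labels):
            raise ValueError("batch_labels must match batch effect arrays")
        if any(s <= 0 for s in self.batch_scale):
            raise ValueError("batch_scale entries must be > 0")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        if self.sigma_range[0] <= 0:
            raise ValueError("sigma_range must be positive")


@dataclass
class SyntheticCohort:
    """One matrix per covariate row, plus the planted ground truth."""

    matrices: list  # list of (n, n) ndarrays, symmetric, zero diagonal
    covariates: pd.DataFrame
    truth: pd.DataFrame  # columns node_i, node_j, effect (signed, log scale)
    parcellation: Parcellation
    spec: CohortSpec = None

    @property
    def n_subjects(self) -> int:
        return len(self.matrices)


def _sample_support(rng: np.random.Generator, n: int, density: float) -> np.ndarray:
    """Choose a shared support mask: round(density * C(n,2)) upper-tri edges."""
    iu, ju = np.triu_indices(n, k=1)
    n_possible = len(iu)
    n_edges = int(round(density * n_possible))
    n_edges = max(n_edges, 1)
    chosen = rng.choice(n_possible, size=n_edges, replace=False)
    chosen.sort()
    return np.column_stack([iu[chosen], ju[chosen]])


def _plant_edges(
    rng: np.random.Generator, edges: np.ndarray, k: int, connected: bool
) -> np.ndarray:
    """Pick k planted edge indices, forming a connected subgraph if requested.

    Connected planting grows a snowball from a random seed edge, repeatedly
    adding a support edge incident to the nodes reached so far.
    """
    m = len(edges)
    if k == 0:
        return np.empty(0, dtype=int)
    if k > m:
        raise ValueError("planted_edge_fraction exceeds the available edge support")
    if not connected:
        idx = rng.choice(m, size=k, replace=False)
        idx.sort()
        return idx
    # adjacency over support edges
    incident: dict = {}
    for e, (i, j) in enumerate(edges):
        incident.setdefault(i, []).append(e)
        incident.setdefault(j, []).append(e)
    start = int(rng.integers(m))
    chosen = {start}
    nodes = {int(edges[start, 0]), int(edges[start, 1])}
    while len(chosen) < k:
        frontier = [
            e for v in nodes for e in incident[v] if e not in chosen
        ]
        if not frontier:
            raise ValueError(
                "support graph component too small for a connected planted "
                f"subnetwork of {k} edges"
            )
        e = int(rng.choice(frontier))
        chosen.add(e)
        nodes.update((int(edges[e, 0]), int(edges[e, 1])))
    return np.array(sorted(chosen), dtype=int)


def simulate_cohort(spec: CohortSpec, parcellation: Parcellation | None = None) -> SyntheticCohort:
    """Draw a cohort from the log-normal edge-weight model (see module docstring).

    Deterministic given ``spec.seed``: the same spec reproduces the cohort
    bit for bit.
    """
    spec.validate()
    if parcellation is None:
        scheme = "destrieux162" if spec.n_nodes == 162 else "uniform"
        parcellation = make_parcellation(spec.n_nodes, scheme)
    if parcellation.n_nodes != spec.n_nodes:
        raise ValueError("parcellation node count must equal spec.n_nodes")

    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    edges = _sample_support(rng, n, spec.edge_density)
    m = len(edges)
    n_planted = int(round(spec.planted_edge_fraction * m))
    planted_idx = _plant_edges(rng, edges, n_planted, spec.planted_connected)

    mu = rng.normal(spec.mu_mean, spec.mu_sd, size=m)
    sigma = rng.uniform(*spec.sigma_range, size=m)

    n_sub = spec.n_group_a + spec.n_group_b
    group = np.array(
        [spec.group_labels[0]] * spec.n_group_a + [spec.group_labels[1]] * spec.n_group_b
    )
    age = rng.uniform(*spec.age_range, size=n_sub)
    sex = rng.integers(0, 2, size=n_sub)
    n_batches = len(spec.batch_shift)
    batch_idx = rng.integers(0, n_batches, size=n_sub)

    is_b = (group == spec.group_labels[1]).astype(float)
    planted_mask_vec = np.zeros(m)
    planted_mask_vec[planted_idx] = 1.0

    # (m, n_sub) log-weights
    eps = rng.normal(0.0, 1.0, size=(m, n_sub)) * sigma[:, None]
    shift = np.asarray(spec.batch_shift, dtype=float)[batch_idx]
    scale = np.asarray(spec.batch_scale, dtype=float)[batch_idx]
    logw = (
        mu[:, None]
        - spec.effect_size * sigma[:, None] * planted_mask_vec[:, None] * is_b[None, :]
        + spec.beta_age * age[None, :]
        + spec.beta_sex * sex[None, :]
        + shift[None, :]
        + scale[None, :] * eps
    )
    weights = np.exp(logw)

    matrices = []
    for s in range(n_sub):
        mat = np.zeros((n, n))
        mat[edges[:, 0], edges[:, 1]] = weights[:, s]
        mat[edges[:, 1], edges[:, 0]] = weights[:, s]
        matrices.append(mat)

    covariates = pd.DataFrame(
        {
            "subject_id": [f"sub-{s:04d}" for s in range(n_sub)],
            "group": group,
            "age": age,
            "sex": sex,
            "batch": np.asarray(spec.batch_labels)[batch_idx],
        }
    )
    if spec.subgroups:
        covariates["fbtc"] = _subgroup_labels(
            rng, is_b.astype(bool), ("FBTC+", "FBTC-"), (0.75, 0.25)
        )
        covariates["impairment"] = _subgroup_labels(
            rng,
            is_b.astype(bool),
            ("none", "focal", "generalized"),
            (0.55, 0.33, 0.12),
        )

    truth = pd.DataFrame(
        {
            "node_i": edges[planted_idx, 0],
            "node_j": edges[planted_idx, 1],
            "effect": -spec.effect_size * sigma[planted_idx],
        }
    )
    return SyntheticCohort(matrices, covariates, truth, parcellation, spec)


def _subgroup_labels(rng, in_group_b, levels, probs):
    labels = np.full(len(in_group_b), "", dtype=object)
    nb = int(in_group_b.sum())
    labels[in_group_b] = rng.choice(levels, size=nb, p=probs)
    return labels


def truth_mask(cohort: SyntheticCohort) -> np.ndarray:
    """Symmetric boolean matrix of planted edges (zero diagonal)."""
    n = cohort.parcellation.n_nodes
    mask = np.zeros((n, n), dtype=bool)
    i = cohort.truth["node_i"].to_numpy()
    j = cohort.truth["node_j"].to_numpy()
    mask[i, j] = True
    mask[j, i] = True
    return mask


def null_spec(**overrides) -> CohortSpec:
    """A convenience spec with no group, covariate, or batch effects."""
    base = CohortSpec(
        effect_size=0.0,
        planted_edge_fraction=0.0,
        beta_age=0.0,
        beta_sex=0.0,
        batch_shift=(0.0,),
        batch_scale=(1.0,),
        batch_labels=("B1",),
        subgroups=False,
    )
    return replace(base, **overrides)
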