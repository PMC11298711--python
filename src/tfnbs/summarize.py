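"""Reporting artifacts: significant-edge masks, lobe-pair tables, top lists.

Significant connections at ``p <= alpha`` are organized by the unordered pair
of lobe classes their endpoints belong to (15 pairs over the five classes:
frontal, occipital, parietal, temporal, subcortical), separately per tested
direction (decrease / increase) and correction (corrected / uncorrected).
Percentages are relative to the total significant count in the stratum, so
each stratum's percentages sum to 100 whenever anything is significant.
"""

from __future__ import annotations

import logging
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

from .glm import DesignMatrix, StatGraph, residualize_adjusted
from .harmonize import CohortDataset
from .permutation import PValueGraphs
from .simulate import LOBES, Parcellation

__all__ = [
    "significant_edges",
    "lobe_pair_summary",
    "top_connections",
    "extract_adjusted",
]

logger = logging.getLogger(__name__)


def significant_edges(
    pgraphs: PValueGraphs, alpha: float = 0.05, correction: str = "corrected"
):
    """Symmetric mask of edges with ``p <= alpha`` plus the edge count."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if correction == "corrected":
        p = pgraphs.p_corrected
    elif correction == "uncorrected":
        p = pgraphs.p_uncorrected
    else:
        raise ValueError(f"correction must be 'corrected' or 'uncorrected', got {correction!r}")
    mask = p <= alpha
    np.fill_diagonal(mask, False)
    count = int(np.triu(mask, k=1).sum())
    return mask, count


def lobe_pair_summary(
    mask: np.ndarray,
    parcellation: Parcellation,
    direction: str = "decrease",
    correction: str = "corrected",
    denominator: str = "significant",
) -> pd.DataFrame:
    """Count significant edges per unordered lobe pair.

    ``denominator='significant'`` (default) expresses percentages relative to
    the total significant edges in the stratum; ``'possible'`` normalizes by
    the number of parcellation edge slots in each lobe pair instead.
    """
    mask = np.asarray(mask, dtype=bool)
    if not np.array_equal(mask, mask.T):
        raise ValueError("mask must be symmetric")
    n = parcellation.n_nodes
    if mask.shape != (n, n):
        raise ValueError("mask shape must match the parcellation")
    lobes = parcellation.lobes
    iu, ju = np.triu_indices(n, k=1)
    sel = mask[iu, ju]
    pairs = [tuple(sorted((lobes[a], lobes[b]))) for a, b in zip(iu[sel], ju[sel])]
    counts = pd.Series(pairs).value_counts() if pairs else pd.Series(dtype=int)

    all_pairs = list(combinations_with_replacement(sorted(set(LOBES)), 2))
    total = int(sel.sum())
    rows = []
    for pair in all_pairs:
        k = int(counts.get(pair, 0))
        if denominator == "significant":
            pct = 100.0 * k / total if total else 0.0
        elif denominator == "possible":
            n_a = int((lobes == pair[0]).sum())
            n_b = int((lobes == pair[1]).sum())
            slots = n_a * (n_a - 1) // 2 if pair[0] == pair[1] else n_a * n_b
            pct = 100.0 * k / slots if slots else 0.0
        else:
            raise ValueError("denominator must be 'significant' or 'possible'")
        rows.append(
            {
                "lobe_a": pair[0],
                "lobe_b": pair[1],
                "n_significant": k,
                "percent_of_significant": pct,
                "direction": direction,
                "correction": correction,
            }
        )
    return pd.DataFrame(rows)


def top_connections(
    pgraphs: PValueGraphs,
    stat_graph: StatGraph,
    parcellation: Parcellation,
    k: int = 16,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """The ``k`` most significant connections (corrected), with region names.

    Sorted ascending by corrected p; ties broken by ``|t|`` descending, then
    by lexicographic edge id. If fewer than ``k`` edges are significant at
    ``alpha``, all significant ones are returned (and the shortfall logged).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mask, count = significant_edges(pgraphs, alpha=alpha, correction="corrected")
    iu, ju = np.triu_indices(parcellation.n_nodes, k=1)
    sel = mask[iu, ju]
    ii, jj = iu[sel], ju[sel]
    p = pgraphs.p_corrected[ii, jj]
    t = stat_graph.t[ii, jj]
    frame = pd.DataFrame(
        {
            "node_i": ii,
            "node_j": jj,
            "region_i": parcellation.region_names[ii],
            "region_j": parcellation.region_names[jj],
            "t": t,
            "p_corrected": p,
            "abs_t": np.abs(t),
        }
    )
    frame = frame.sort_values(
        ["p_corrected", "abs_t", "node_i", "node_j"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).drop(columns="abs_t")
    if count < k:
        logger.info("top_connections: only %d significant edges (k=%d requested)", count, k)
    return frame.head(k).reset_index(drop=True)


def extract_adjusted(
    dataset: CohortDataset, edges, design: DesignMatrix
) -> pd.DataFrame:
    """Tidy per-subject nuisance-adjusted values for selected edges.

    ``edges`` is an iterable of ``(i, j)`` node pairs that must belong to the
    dataset's edge list; output columns: subject, group, edge, adjusted.
    """
    adjusted = residualize_adjusted(dataset, design)  # (m, n_kept)
    edge_index = {tuple(e): k for k, e in enumerate(map(tuple, dataset.edges))}
    cov = dataset.covariates.iloc[design.rows]
    out = []
    for i, j in edges:
        key = (min(i, j), max(i, j))
        if key not in edge_index:
            raise KeyError(f"edge {key} not in the dataset")
        row = adjusted[edge_index[key]]
        out.append(
            pd.DataFrame(
                {
                    "subject": cov["subject_id"].to_numpy()
                    if "subject_id" in cov
                    else cov.index.to_numpy(),
                    "group": cov.iloc[:, cov.columns.get_loc("group")].to_numpy()
                    if "group" in cov
                    else "",
                    "edge": f"{key[0]}-{key[1]}",
                    "adjusted": row,
                }
            )
        )
    return pd.concat(out, ignore_index=True)
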