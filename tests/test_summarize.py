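import numpy as np
import pandas as pd
import pytest

from tfnbs.glm import StatGraph, build_design
from tfnbs.permutation import PValueGraphs
from tfnbs.simulate import make_parcellation
from tfnbs.summarize import (
    extract_adjusted,
    lobe_pair_summary,
    significant_edges,
    top_connections,
)


def make_pgraphs(p_cor, p_unc=None):
    p_cor = np.asarray(p_cor, dtype=float)
    if p_unc is None:
        p_unc = p_cor
    return PValueGraphs(
        p_corrected=p_cor,
        p_uncorrected=np.asarray(p_unc, dtype=float),
        observed_score=np.zeros_like(p_cor),
        null_max=np.ones(1),
        null_edge=None,
        n_permutations=1,
        seed=0,
    )


def sym(n, entries, fill=1.0):
    m = np.full((n, n), fill)
    for i, j, v in entries:
        m[i, j] = m[j, i] = v
    np.fill_diagonal(m, 1.0)
    return m


class TestSignificantEdges:
    def test_all_ones_empty(self):
        pg = make_pgraphs(np.ones((5, 5)))
        mask, count = significant_edges(pg)
        assert count == 0 and not mask.any()

    def test_count_matches_entries(self):
        p = sym(6, [(0, 1, 0.01), (2, 3, 0.05), (4, 5, 0.049), (1, 2, 0.2)])
        _, count = significant_edges(make_pgraphs(p), alpha=0.05)
        assert count == 3  # p <= alpha is inclusive

    def test_corrected_subset_of_uncorrected(self, small_dataset):
        from tfnbs.permutation import permutation_pvalues

        design = build_design(small_dataset.covariates)
        pg = permutation_pvalues(
            small_dataset, design, n_permutations=100, seed=3, direction=-1
        )
        cor, _ = significant_edges(pg, 0.25, "corrected")
        unc, _ = significant_edges(pg, 0.25, "uncorrected")
        assert np.all(unc[cor])

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            significant_edges(make_pgraphs(np.ones((3, 3))), alpha=1.5)


class TestLobePairSummary:
    def test_single_lobe_gets_100_percent(self):
        parc = make_parcellation(25, "uniform")
        frontal = np.flatnonzero(parc.lobes == "frontal")
        mask = np.zeros((25, 25), dtype=bool)
        mask[frontal[0], frontal[1]] = mask[frontal[1], frontal[0]] = True
        table = lobe_pair_summary(mask, parc)
        row = table[(table.lobe_a == "frontal") & (table.lobe_b == "frontal")]
        assert row.percent_of_significant.iloc[0] == 100.0
        assert table.percent_of_significant.sum() == pytest.approx(100.0)

    def test_hand_computed_split(self):
        """2 subcortical-subcortical, 1 frontal-frontal, 1 parietal-temporal."""
        parc = make_parcellation(25, "uniform")
        idx = {lobe: np.flatnonzero(parc.lobes == lobe) for lobe in set(parc.lobes)}
        mask = np.zeros((25, 25), dtype=bool)
        pairs = [
            (idx["subcortical"][0], idx["subcortical"][1]),
            (idx["subcortical"][1], idx["subcortical"][2]),
            (idx["frontal"][0], idx["frontal"][1]),
            (idx["parietal"][0], idx["temporal"][0]),
        ]
        for i, j in pairs:
            mask[i, j] = mask[j, i] = True
        table = lobe_pair_summary(mask, parc).set_index(["lobe_a", "lobe_b"])
        assert table.loc[("subcortical", "subcortical"), "percent_of_significant"] == 50.0
        assert table.loc[("frontal", "frontal"), "percent_of_significant"] == 25.0
        assert table.loc[("parietal", "temporal"), "percent_of_significant"] == 25.0
        assert table.n_significant.sum() == 4

    def test_relabeling_invariance(self):
        """Consistently permuting node ids leaves the table unchanged."""
        rng = np.random.default_rng(4)
        parc = make_parcellation(20, "uniform")
        mask = np.zeros((20, 20), dtype=bool)
        iu, ju = np.triu_indices(20, k=1)
        pick = rng.choice(len(iu), size=12, replace=False)
        mask[iu[pick], ju[pick]] = mask[ju[pick], iu[pick]] = True
        table = lobe_pair_summary(mask, parc)

        perm = rng.permutation(20)
        mask_p = mask[np.ix_(perm, perm)]
        frame = parc.frame.iloc[perm].reset_index(drop=True)
        frame["node_id"] = np.arange(20)
        from tfnbs.simulate import Parcellation

        table_p = lobe_pair_summary(mask_p, Parcellation(frame))
        pd.testing.assert_frame_equal(table, table_p)

    def test_possible_denominator(self):
        parc = make_parcellation(10, "uniform")
        frontal = np.flatnonzero(parc.lobes == "frontal")  # 2 nodes -> 1 slot
        mask = np.zeros((10, 10), dtype=bool)
        mask[frontal[0], frontal[1]] = mask[frontal[1], frontal[0]] = True
        table = lobe_pair_summary(mask, parc, denominator="possible")
        row = table[(table.lobe_a == "frontal") & (table.lobe_b == "frontal")]
        assert row.percent_of_significant.iloc[0] == 100.0

    def test_asymmetric_mask_rejected(self):
        parc = make_parcellation(5, "uniform")
        bad = np.zeros((5, 5), dtype=bool)
        bad[0, 1] = True
        with pytest.raises(ValueError):
            lobe_pair_summary(bad, parc)


class TestTopConnections:
    def _setup(self):
        parc = make_parcellation(10, "uniform")
        p = sym(10, [(0, 1, 0.01), (2, 3, 0.01), (4, 5, 0.04), (6, 7, 0.2)])
        t = np.zeros((10, 10))
        for i, j, v in [(0, 1, -3.0), (2, 3, -5.0), (4, 5, -2.5), (6, 7, -1.0)]:
            t[i, j] = t[j, i] = v
        sg = StatGraph(t, dof=10, direction=-1)
        return parc, make_pgraphs(p), sg

    def test_ties_broken_by_abs_t(self):
        parc, pg, sg = self._setup()
        top = top_connections(pg, sg, parc, k=3)
        assert (top.node_i.iloc[0], top.node_j.iloc[0]) == (2, 3)  # |t|=5 first
        assert (top.node_i.iloc[1], top.node_j.iloc[1]) == (0, 1)
        assert len(top) == 3

    def test_k_exceeding_significant_returns_all(self):
        parc, pg, sg = self._setup()
        top = top_connections(pg, sg, parc, k=50)
        assert len(top) == 3  # only 3 significant at alpha 0.05

    def test_region_names_attached(self):
        parc, pg, sg = self._setup()
        top = top_connections(pg, sg, parc, k=1)
        assert top.region_i.iloc[0] == parc.region_names[2]

    def test_order_invariant_to_node_permutation_of_ranking(self):
        """Ranking depends on p and |t| only, not on matrix entry order."""
        parc, pg, sg = self._setup()
        top = top_connections(pg, sg, parc, k=3)
        ranked = list(zip(top.node_i, top.node_j))
        assert ranked == [(2, 3), (0, 1), (4, 5)]


class TestExtractAdjusted:
    def test_tidy_shape_and_groups(self, small_dataset):
        design = build_design(small_dataset.covariates)
        edges = [tuple(e) for e in small_dataset.edges[:3]]
        tidy = extract_adjusted(small_dataset, edges, design)
        assert set(tidy.columns) == {"subject", "group", "edge", "adjusted"}
        assert len(tidy) == 3 * design.n_subjects
        assert set(tidy.group) == {"HC", "TLE"}

    def test_unknown_edge_rejected(self, small_dataset):
        design = build_design(small_dataset.covariates)
        with pytest.raises(KeyError):
            extract_adjusted(small_dataset, [(0, 0)], design)
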