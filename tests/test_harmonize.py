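import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from tfnbs.harmonize import (
    ComBatConvergenceError,
    EmptyDatasetError,
    apply_combat,
    build_dataset,
    filter_edges,
    fit_combat,
    log_transform,
)
from tfnbs.simulate import CohortSpec, make_parcellation, simulate_cohort


def _two_batch_cohort(seed=11, n=60, shift=0.8, scale=1.4):
    spec = CohortSpec(
        n_group_a=n,
        n_group_b=n,
        n_nodes=10,
        edge_density=1.0,
        effect_size=1.0,
        planted_edge_fraction=0.2,
        batch_shift=(0.0, shift),
        batch_scale=(1.0, scale),
        batch_labels=("b1", "b2"),
        seed=seed,
    )
    c = simulate_cohort(spec)
    return build_dataset(c.matrices, c.covariates, c.parcellation)


class TestFilterEdges:
    def test_full_prevalence_retained(self, small_cohort):
        edges, support = filter_edges(small_cohort.matrices, 1.0)
        # shared support: everything present survives min_prevalence=1
        expected = int(np.triu(small_cohort.matrices[0] != 0, k=1).sum())
        assert len(edges) == expected
        assert np.all(edges[:, 0] < edges[:, 1])
        np.testing.assert_array_equal(support, support.T)

    def test_partial_prevalence_dropped(self):
        """Edge present in half the subjects is dropped at min_prevalence 0.9."""
        m_with = np.zeros((3, 3))
        m_with[0, 1] = m_with[1, 0] = 2.0
        m_with[1, 2] = m_with[2, 1] = 3.0
        m_without = np.zeros((3, 3))
        m_without[1, 2] = m_without[2, 1] = 4.0
        edges, _ = filter_edges([m_with, m_without], 0.9)
        assert edges.tolist() == [[1, 2]]
        edges_all, _ = filter_edges([m_with, m_without], 0.5)
        assert edges_all.tolist() == [[0, 1], [1, 2]]

    def test_hand_counted_toy(self):
        """4-node toy: hand-enumerated retained set at several thresholds."""
        def mat(pairs):
            m = np.zeros((4, 4))
            for i, j in pairs:
                m[i, j] = m[j, i] = 1.0
            return m

        mats = [
            mat([(0, 1), (1, 2), (2, 3)]),
            mat([(0, 1), (1, 2)]),
            mat([(0, 1), (0, 3)]),
        ]
        # prevalence: (0,1)=3/3, (1,2)=2/3, (2,3)=1/3, (0,3)=1/3
        assert len(filter_edges(mats, 1.0)[0]) == 1
        assert len(filter_edges(mats, 0.6)[0]) == 2
        assert len(filter_edges(mats, 0.3)[0]) == 4

    def test_empty_result_raises(self):
        with pytest.raises(EmptyDatasetError):
            filter_edges([np.zeros((3, 3))], 0.5)


class TestLogTransform:
    def test_known_values_and_round_trip(self):
        y = np.array([[1.0, np.e**2, 5.0]])
        out = log_transform(y)
        np.testing.assert_allclose(out[0, :2], [0.0, 2.0], atol=1e-12)
        np.testing.assert_allclose(np.exp(out), y)

    def test_zero_requires_offset(self):
        y = np.array([[1.0, 0.0]])
        with pytest.raises(ValueError):
            log_transform(y)
        out = log_transform(y, offset=0.5)
        assert out[0, 1] == np.log(0.5)
        assert out[0, 0] == 0.0  # offset applied only to exact zeros


class TestFitCombat:
    def test_single_batch_degenerate(self, null_cohort):
        ds = build_dataset(
            null_cohort.matrices, null_cohort.covariates, null_cohort.parcellation
        )
        model = fit_combat(ds)
        assert np.abs(model.gamma_star).max() < 1e-6
        assert np.abs(model.delta_star_sq - 1.0).max() < 1e-6
        out = apply_combat(model, ds)
        assert np.abs(out.Y - ds.Y).max() < 1e-8  # identity case

    def test_two_batch_shift_recovered(self):
        """gamma* contrast times the pooled SD recovers the planted shift of 1."""
        spec = CohortSpec(
            n_group_a=100,
            n_group_b=100,
            n_nodes=11,
            edge_density=1.0,
            effect_size=0.0,
            planted_edge_fraction=0.0,
            batch_shift=(0.0, 1.0),
            batch_scale=(1.0, 1.0),
            batch_labels=("b1", "b2"),
            seed=2,
        )
        c = simulate_cohort(spec)
        ds = build_dataset(c.matrices, c.covariates, c.parcellation)
        model = fit_combat(ds)
        recovered = np.mean(
            (model.gamma_star[1] - model.gamma_star[0]) * np.sqrt(model.pooled_var)
        )
        se = 0.6 * np.sqrt(2 / 100) / np.sqrt(ds.n_edges)
        assert abs(recovered - 1.0) < 3 * se + 0.05

    def test_zero_iterations_returns_naive(self):
        ds = _two_batch_cohort()
        model = fit_combat(ds, max_iter=0)
        np.testing.assert_array_equal(model.gamma_star, model.gamma_hat)
        np.testing.assert_array_equal(model.delta_star_sq, model.delta_hat_sq)

    def test_small_batch_rejected(self, one_edge_dataset):
        ds = one_edge_dataset
        labels = np.array(["a"] * 5 + ["b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_combat(ds, batch_labels=labels)

    def test_nonconvergence_carries_iterates(self):
        ds = _two_batch_cohort()
        with pytest.raises(ComBatConvergenceError) as err:
            fit_combat(ds, tol=0.0, max_iter=1)
        assert err.value.gamma_star.shape == (ds.n_edges,)


class TestApplyCombat:
    def test_batch_difference_shrinks(self):
        ds = _two_batch_cohort()
        model = fit_combat(ds)
        out = apply_combat(model, ds)
        b = ds.covariates["batch"].to_numpy()

        def batch_diff(Y):
            return np.abs(Y[:, b == "b2"].mean(axis=1) - Y[:, b == "b1"].mean(axis=1))

        assert batch_diff(out.Y).mean() <= 0.1 * batch_diff(ds.Y).mean()

    def test_group_effect_preserved(self):
        ds = _two_batch_cohort()
        model = fit_combat(ds)
        out = apply_combat(model, ds)
        g = ds.covariates["group"].to_numpy()

        def gdiff(Y):
            return Y[:, g == "TLE"].mean(axis=1) - Y[:, g == "HC"].mean(axis=1)

        r = np.corrcoef(gdiff(ds.Y), gdiff(out.Y))[0, 1]
        assert r >= 0.95

    def test_idempotent_refit(self):
        """Refitting on harmonized data finds ~no remaining batch effect."""
        ds = _two_batch_cohort()
        out = apply_combat(fit_combat(ds), ds)
        model2 = fit_combat(out)
        assert np.abs(model2.gamma_star[1] - model2.gamma_star[0]).mean() < 0.05
        assert np.abs(model2.delta_star_sq - 1.0).mean() < 0.1

    def test_quantile_alignment(self):
        """Per-batch quantiles of harmonized values agree on a null simulation."""
        ds = _two_batch_cohort(seed=23)
        out = apply_combat(fit_combat(ds), ds)
        b = ds.covariates["batch"].to_numpy()
        qs = np.linspace(0.1, 0.9, 9)
        q1 = np.quantile(out.Y[:, b == "b1"], qs)
        q2 = np.quantile(out.Y[:, b == "b2"], qs)
        assert np.abs(q1 - q2).max() < 0.12

    def test_unseen_batch_label(self):
        ds = _two_batch_cohort()
        model = fit_combat(ds)
        labels = ds.covariates["batch"].to_numpy().copy()
        labels[0] = "b3"
        with pytest.raises(ValueError, match="unseen"):
            apply_combat(model, ds, batch_labels=labels)


class TestAgainstSvaComBat:
    def test_matches_reference_implementation(self, tmp_path):
        """Harmonized values agree with sva::ComBat.

        The reference uses an n-1 denominator for naive batch variances where
        this implementation uses the MLE, so agreement is O(1/n_batch), not
        machine precision.
        """
        ds = _two_batch_cohort(seed=11)
        model = fit_combat(ds)
        out = apply_combat(model, ds)
        np.savetxt(tmp_path / "dat.csv", ds.Y, delimiter=",")
        ds.covariates[["group", "age", "sex", "batch"]].to_csv(
            tmp_path / "cov.csv", index=False
        )
        script = textwrap.dedent(
            """
            suppressMessages(library(sva))
            dat <- as.matrix(read.csv("dat.csv", header=FALSE))
            cov <- read.csv("cov.csv")
            mod <- model.matrix(~group+age+sex, data=cov)
            out <- ComBat(dat=dat, batch=cov$batch, mod=mod, par.prior=TRUE)
            write.table(out, "harm_R.csv", sep=",", row.names=FALSE, col.names=FALSE)
            """
        )
        (tmp_path / "ref.R").write_text(script)
        subprocess.run(
            ["Rscript", "ref.R"], cwd=tmp_path, check=True, capture_output=True
        )
        ref = np.loadtxt(tmp_path / "harm_R.csv", delimiter=",")
        assert np.abs(out.Y - ref).max() < 0.05
        assert np.corrcoef(out.Y.ravel(), ref.ravel())[0, 1] > 0.9999
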