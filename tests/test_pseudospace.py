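"""Trajectory construction, pseudocell generation, summaries, phase clustering."""

import numpy as np
import pandas as pd
import pytest

import pseudocell_tracer as pct
from pseudocell_tracer.pseudospace import PseudocellSet, TrajectorySummary

CH = list(pct.DEFAULT_CHANNELS)


class TestBuildTrajectory:
    def test_one_percent_steps_give_101_profiles(self):
        spec = pct.TrajectorySpec("Ighm", "Ighg1", CH, 0.01)
        traj = pct.build_trajectory(spec)
        assert traj.shape == (101, 8)
        assert np.allclose(traj.sum(axis=1), 1.0)

    def test_endpoints_are_pure_source_and_target(self):
        traj = pct.build_trajectory(pct.TrajectorySpec("Ighm", "Ighg1", CH, 0.01))
        assert np.array_equal(traj[0], np.eye(8)[0])   # 100% IgM
        assert np.array_equal(traj[-1], np.eye(8)[1])  # 100% IgG1

    def test_half_steps_closed_form(self):
        traj = pct.build_trajectory(pct.TrajectorySpec("Ighm", "Igha", CH, 0.5))
        s, t = CH.index("Ighm"), CH.index("Igha")
        assert traj.shape[0] == 3
        assert np.allclose(traj[:, s], [1.0, 0.5, 0.0])
        assert np.allclose(traj[:, t], [0.0, 0.5, 1.0])
        others = np.delete(traj, [s, t], axis=1)
        assert np.all(others == 0)

    def test_profiles_are_affine_in_t(self):
        spec = pct.TrajectorySpec("Ighm", "Ighg3", CH, 0.05)
        traj = pct.build_trajectory(spec)
        t = np.linspace(0, 1, spec.n_points)
        s_i, t_i = CH.index("Ighm"), CH.index("Ighg3")
        expected = np.outer(1 - t, np.eye(8)[s_i]) + np.outer(t, np.eye(8)[t_i])
        assert np.array_equal(traj, expected)

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            pct.TrajectorySpec("Ighm", "Ighg1", CH, 0.03)

    def test_same_source_target_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            pct.TrajectorySpec("Ighm", "Ighm", CH, 0.01)


class TestGeneratePseudocells:
    def test_replicates_axis_and_determinism(self, trained):
        spec = pct.TrajectorySpec("Ighm", "Ighg1", CH, 0.25)
        traj = pct.build_trajectory(spec)
        a = pct.generate_pseudocells(traj, trained.generator, trained.decoder,
                                     spec, replicates=7, seed=1)
        b = pct.generate_pseudocells(traj, trained.generator, trained.decoder,
                                     spec, replicates=7, seed=1)
        assert a.expression.shape == (5, 7, trained.data.expr.n_genes)
        assert a.n_pseudocells == 35
        assert np.array_equal(a.expression, b.expression)

    def test_single_replicate_shape(self, trained):
        spec = pct.TrajectorySpec("Ighm", "Ighg1", CH, 0.5)
        pc = pct.generate_pseudocells(pct.build_trajectory(spec), trained.generator,
                                      trained.decoder, spec, replicates=1, seed=2)
        assert pc.expression.shape[1] == 1

    def test_dimension_mismatch_rejected(self, trained):
        bad_gen = pct.GeneratorModel(
            pct.GeneratorSpec(condition_dim=8, output_dim=16), CH, seed=0)
        spec = pct.TrajectorySpec("Ighm", "Ighg1", CH, 0.5)
        with pytest.raises(ValueError, match="latent dim"):
            pct.generate_pseudocells(pct.build_trajectory(spec), bad_gen,
                                     trained.decoder, spec)


def _manual_pcs(expr, gene_ids, spec):
    p, r, g = expr.shape
    return PseudocellSet(np.zeros((p, len(CH))), np.zeros((p, r, 4)), expr,
                         gene_ids, CH, spec)


class TestSummarizeTrajectory:
    spec = pct.TrajectorySpec("Ighm", "Ighg1", CH, 0.5)

    def test_constant_output_gives_zero_width_ci(self):
        expr = np.full((3, 10, 2), 7.0)
        s = pct.summarize_trajectory(_manual_pcs(expr, ["a", "b"], self.spec))
        assert np.all(s.mean.to_numpy() == 7.0)
        assert np.all(s.upper.to_numpy() - s.lower.to_numpy() == 0.0)

    def test_percentile_band_matches_empirical_quantiles(self):
        reps = np.arange(1.0, 101.0)
        expr = np.zeros((1, 100, 1))
        expr[0, :, 0] = reps
        s = pct.summarize_trajectory(_manual_pcs(expr, ["g"], self.spec))
        assert s.mean.iloc[0, 0] == pytest.approx(50.5)
        assert s.lower.iloc[0, 0] == pytest.approx(np.percentile(reps, 2.5))
        assert s.upper.iloc[0, 0] == pytest.approx(np.percentile(reps, 97.5))

    def test_band_contains_mean_everywhere(self, trained):
        spec = pct.TrajectorySpec("Ighm", "Ighg1", CH, 0.1)
        pc = pct.generate_pseudocells(pct.build_trajectory(spec), trained.generator,
                                      trained.decoder, spec, replicates=100, seed=3)
        s = pct.summarize_trajectory(pc)
        assert np.all(s.lower.to_numpy() <= s.mean.to_numpy() + 1e-12)
        assert np.all(s.mean.to_numpy() <= s.upper.to_numpy() + 1e-12)

    def test_zscored_curves_are_standardized(self):
        rng = np.random.default_rng(0)
        expr = rng.random((11, 5, 3)) * 4
        s = pct.summarize_trajectory(_manual_pcs(expr, ["a", "b", "c"], self.spec),
                                     zscore=True)
        z = s.zscored.to_numpy()
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=0), 1.0, atol=1e-9)

    def test_unknown_gene_rejected(self):
        expr = np.zeros((2, 3, 2))
        with pytest.raises(KeyError, match="nope"):
            pct.summarize_trajectory(_manual_pcs(expr, ["a", "b"], self.spec),
                                     genes=["nope"])

    def test_single_replicate_cannot_form_ci(self):
        expr = np.zeros((2, 1, 2))
        with pytest.raises(ValueError, match="replicates"):
            pct.summarize_trajectory(_manual_pcs(expr, ["a", "b"], self.spec))


from helpers import planted_phase_summary as _planted_summary  # noqa: E402


class TestPhaseCluster:
    def test_planted_phases_recovered(self):
        summary, truth = _planted_summary()
        labels, order = pct.phase_cluster(summary, 3, seed=1)
        assert (labels == truth.loc[labels.index]).mean() >= 0.95

    def test_each_gene_its_own_cluster_when_k_equals_genes(self):
        summary, _ = _planted_summary(n_per_phase=1, noise=0.0)
        labels, _ = pct.phase_cluster(summary, 3, seed=2)
        assert labels.nunique() == 3

    def test_heatmap_order_groups_phases_contiguously(self):
        summary, _ = _planted_summary(n_per_phase=10)
        labels, order = pct.phase_cluster(summary, 3, seed=3)
        seq = [labels[g] for g in order]
        changes = sum(a != b for a, b in zip(seq, seq[1:]))
        assert changes == 2  # three contiguous blocks

    def test_all_constant_curves_rejected(self):
        axis = np.linspace(0, 1, 11)
        mean = pd.DataFrame(np.ones((11, 5)), columns=list("abcde"))
        s = TrajectorySummary(axis, mean, mean, mean)
        with pytest.raises(ValueError, match="non-constant"):
            pct.phase_cluster(s, 3)


class TestNearestRealCell:
    def _pcs_from_matrix(self, mat):
        p, g = mat.shape
        spec = pct.TrajectorySpec("Ighm", "Ighg1", CH, 1.0)
        return PseudocellSet(np.zeros((p, 8)), np.zeros((p, 1, 4)),
                             mat[:, None, :], [f"g{j}" for j in range(g)], CH, spec)

    def test_exact_copy_found_at_distance_zero(self, tiny_data):
        expr = tiny_data.expr
        pc = self._pcs_from_matrix(expr.values[[5]])
        pc.gene_ids[:] = expr.gene_ids
        out = pct.nearest_real_cell(pc, expr)
        assert out.nearest_cell.iloc[0] == expr.cell_ids[5]
        assert out.distance.iloc[0] == 0.0

    def test_matches_bruteforce_all_pairs_scan(self):
        rng = np.random.default_rng(4)
        ref_vals = rng.random((50, 6))
        ref = pct.ExpressionMatrix(ref_vals, [f"g{j}" for j in range(6)],
                                   [f"c{i}" for i in range(50)], "log2_tpm1")
        queries = rng.random((10, 6))
        pc = self._pcs_from_matrix(queries)
        out = pct.nearest_real_cell(pc, ref)
        for q in range(10):
            d = np.sqrt(((ref_vals - queries[q]) ** 2).sum(axis=1))
            assert out.nearest_cell.iloc[q] == f"c{d.argmin()}"
            assert out.distance.iloc[q] == pytest.approx(d.min())

    def test_cosine_distances_in_range(self):
        rng = np.random.default_rng(5)
        ref = pct.ExpressionMatrix(rng.random((20, 6)) + 0.01,
                                   [f"g{j}" for j in range(6)],
                                   [f"c{i}" for i in range(20)], "log2_tpm1")
        pc = self._pcs_from_matrix(rng.random((5, 6)) + 0.01)
        out = pct.nearest_real_cell(pc, ref, metric="cosine")
        assert np.all((out.distance >= 0) & (out.distance <= 2))


class TestMonotoneConditioningRecovery:
    def test_source_falls_and_target_rises_along_axis(self, trained):
        """Generated latents, read back through the supervised encoder head,
        show monotone source/target channel dynamics along the traced axis."""
        from scipy.stats import spearmanr

        spec = pct.TrajectorySpec("Ighm", "Ighg1", CH, 0.01)
        traj = pct.build_trajectory(spec)
        lat = pct.generate_latents(trained.generator, traj, 50, seed=6)
        pred = trained.encoder.predict_profiles_from_latent(lat.reshape(-1, 64))
        pred = pred.reshape(101, 50, 8).mean(axis=1)
        t = np.linspace(0, 1, 101)
        assert spearmanr(pred[:, 0], t).statistic <= -0.9
        assert spearmanr(pred[:, 1], t).statistic >= 0.9

    def test_planted_dynamics_recovered_for_monotone_genes(self, trained):
        """Median correlation between summarized pseudocell curves and the
        planted truth is >= 0.8 over genes with monotone response in t."""
        data = trained.data
        spec = pct.TrajectorySpec("Ighm", "Ighg1", CH, 0.01)
        pc = pct.generate_pseudocells(pct.build_trajectory(spec), trained.generator,
                                      trained.decoder, spec, replicates=100, seed=7)
        s = pct.summarize_trajectory(pc)
        t = pc.axis
        rs = []
        monotone = data.truth.genes[(data.truth.genes.module.isin(["early", "late"]))]
        for gid in monotone.index:
            if gid in s.mean.columns:
                rs.append(np.corrcoef(s.mean[gid], data.truth.true_curve(gid, t))[0, 1])
        # channel genes are exactly linear in t
        rs.append(np.corrcoef(s.mean["Ighm"], 1 - t)[0, 1])
        rs.append(np.corrcoef(s.mean["Ighg1"], t)[0, 1])
        assert np.median(rs) >= 0.8
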