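import numpy as np
import pytest
from scipy.stats import hypergeom

import mirfusion as mf
import mirfusion.evaluate
import mirfusion.predict
from .oracles import auc_rank_oracle


def assoc_from(MD):
    MD = np.asarray(MD, dtype=float)
    return mf.AssociationData(
        [f"m{i:03d}" for i in range(MD.shape[0])],
        [f"d{j:03d}" for j in range(MD.shape[1])],
        MD,
    )


@pytest.fixture(scope="module")
def loocv_report(small_dataset, small_config):
    assoc, kernels = small_dataset
    return mf.loocv(assoc, kernels, small_config)


class TestLoocv:
    def test_auc_equals_rank_statistic(self, loocv_report):
        want = auc_rank_oracle(loocv_report.positive_scores, loocv_report.negative_scores)
        assert loocv_report.auc == pytest.approx(want, abs=1e-12)

    def test_roc_curve_shape(self, loocv_report):
        pts = loocv_report.roc_points
        assert tuple(pts[0]) == (0.0, 0.0)
        assert tuple(pts[-1]) == (1.0, 1.0)
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()
        assert 0.0 <= loocv_report.auc <= 1.0

    def test_input_data_unchanged(self, small_dataset, small_config):
        assoc, kernels = small_dataset
        before = assoc.MD.copy()
        mf.loocv(assoc, kernels, small_config)
        np.testing.assert_array_equal(assoc.MD, before)

    def test_fold_count_equals_known_associations(self, small_dataset, loocv_report):
        assoc, _ = small_dataset
        assert len(loocv_report.fold_records) == assoc.n_associations

    def test_no_known_associations_is_error(self, small_dataset, small_config):
        _, kernels = small_dataset
        empty = assoc_from(np.zeros((20, 15)))
        with pytest.raises(mf.ValidationError, match="no known associations"):
            mf.loocv(empty, kernels, small_config)

    def test_noise_scores_give_chance_auc(self, small_dataset, small_config, monkeypatch):
        """With scores replaced by seeded uniform noise the pooled AUC must
        fall inside the permutation null band around 0.5."""
        assoc, kernels = small_dataset
        rng = np.random.default_rng(99)

        def noisy_predict(a, k, cfg=None, fused=None):
            real = mirfusion.predict.predict_full(a, k, cfg, fused=fused)
            real.Fpf = rng.random(real.Fpf.shape)
            return real

        monkeypatch.setattr(mirfusion.evaluate, "predict_full", noisy_predict)
        rep = mf.loocv(assoc, kernels, small_config)
        null = mf.permutation_null(rep, 200, seed=7)
        lo, hi = np.percentile(null, [2.5, 97.5])
        assert lo < rep.auc < hi

    def test_single_known_association_closed_form(self, small_config):
        """With one positive the ROC is a step function and the AUC is the
        tie-aware normalized rank of the held-out score among candidates."""
        rng = np.random.default_rng(12)
        MD = np.zeros((8, 6))
        MD[2, 3] = 1.0
        assoc = assoc_from(MD)
        ks = {}
        for key, n in (("mirna_functional", 8), ("mirna_sequence", 8),
                       ("disease_semantic", 6), ("disease_functional", 6)):
            A = rng.random((n, n))
            S = (A + A.T) / 2
            np.fill_diagonal(S, 1.0)
            names = [f"m{i:03d}" for i in range(8)] if n == 8 else [f"d{i:03d}" for i in range(6)]
            ks[key] = mf.KernelMatrix(names, S, "functional")
        rep = mf.loocv(assoc, ks, small_config)
        held = rep.positive_scores[0]
        cands = rep.negative_scores
        want = ((cands < held).sum() + 0.5 * (cands == held).sum()) / len(cands)
        assert rep.auc == pytest.approx(want, abs=1e-12)

    def test_fast_mode_matches_reference_under_constant_hamming(
        self, small_dataset, small_config, monkeypatch
    ):
        """When the Hamming kernels cannot react to masking (constant kernel),
        skipping per-fold fusion recomputation changes nothing."""
        assoc, kernels = small_dataset

        def constant_hamming(a, side):
            names = a.mirna_names if side == "mirna" else a.disease_names
            return mf.KernelMatrix(list(names), np.ones((len(names), len(names))), "hamming")

        monkeypatch.setattr(mirfusion.predict, "hamming_similarity", constant_hamming)
        slow = mf.loocv(assoc, kernels, small_config)
        fast_cfg = mf.ModelConfig(
            alpha=small_config.alpha, beta=small_config.beta, gamma=small_config.gamma,
            fusion=small_config.fusion, fast_loocv=True,
        )
        fast = mf.loocv(assoc, kernels, fast_cfg)
        assert fast.auc == pytest.approx(slow.auc, abs=1e-12)
        np.testing.assert_allclose(fast.positive_scores, slow.positive_scores, atol=1e-12)


class TestEntityProtocols:
    @pytest.mark.parametrize("protocol", ["new_mirna", "isolated_disease"])
    def test_auc_equals_rank_statistic_and_input_unchanged(
        self, small_dataset, small_config, protocol
    ):
        assoc, kernels = small_dataset
        before = assoc.MD.copy()
        rep = mf.loocv_entity(assoc, kernels, small_config, protocol)
        np.testing.assert_array_equal(assoc.MD, before)
        want = auc_rank_oracle(rep.positive_scores, rep.negative_scores)
        assert rep.auc == pytest.approx(want, abs=1e-12)

    def test_masked_column_scores_are_finite_at_gamma_one(self, small_dataset, small_config):
        assoc, kernels = small_dataset
        cfg = mf.ModelConfig(alpha=0.02, beta=0.02, gamma=1.0, fusion=small_config.fusion)
        rep = mf.loocv_entity(assoc, kernels, cfg, "new_mirna")
        assert np.isfinite(rep.positive_scores).all()
        assert np.isfinite(rep.negative_scores).all()

    def test_planted_signal_beats_noise_band(self, small_dataset, small_config):
        assoc, kernels = small_dataset
        rep = mf.loocv_entity(assoc, kernels, small_config, "new_mirna")
        null = mf.permutation_null(rep, 200, seed=5)
        assert rep.auc > np.percentile(null, 97.5)


class TestParameterSweep:
    def test_one_point_grid_equals_direct_loocv(self, small_dataset, small_config, loocv_report):
        assoc, kernels = small_dataset
        table, best = mf.parameter_sweep(
            assoc, kernels, [small_config.alpha], [small_config.gamma], small_config
        )
        assert len(table) == 1
        assert table["auc"].iloc[0] == pytest.approx(loocv_report.auc, abs=1e-12)

    def test_deterministic_and_argmax(self, small_dataset, small_config):
        assoc, kernels = small_dataset
        t1, best1 = mf.parameter_sweep(assoc, kernels, [0.0, 0.1], [0.5], small_config)
        t2, _ = mf.parameter_sweep(assoc, kernels, [0.0, 0.1], [0.5], small_config)
        assert t1.equals(t2)
        assert best1["auc"] >= t1["auc"].max() - 1e-15
        assert (t1["alpha"] == t1["beta"]).all()  # tied by default


class TestRanking:
    def test_excludes_known_and_caps_top_n(self, small_dataset, small_scores):
        assoc, _ = small_dataset
        disease = assoc.disease_names[0]
        known = {assoc.mirna_names[i] for i in np.flatnonzero(assoc.MD[:, 0] == 1)}
        ranked = mf.rank_candidates(small_scores, disease, top_n=10_000)
        names = [m for m, _ in ranked]
        assert not known & set(names)
        assert len(ranked) == assoc.n_mirna - len(known)
        scores = [s for _, s in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_all_ties_ranked_lexicographically(self):
        s = mf.ScoreMatrix(["m3", "m1", "m2"], ["dA", "dB"], None, None,
                           np.full((3, 2), 0.5), np.zeros((3, 2)))
        ranked = mf.rank_candidates(s, "dA", 3)
        assert [m for m, _ in ranked] == ["m1", "m2", "m3"]

    def test_planted_block_enriched_in_top_ranks(self, small_dataset, small_scores):
        assoc, _ = small_dataset
        # disease 0 sits in group 0 (round-robin assignment); so do miRNAs 0, 3, 6...
        disease = assoc.disease_names[0]
        same_group = {assoc.mirna_names[i] for i in range(assoc.n_mirna) if i % 3 == 0}
        ranked = mf.rank_candidates(small_scores, disease, top_n=5)
        hits = sum(1 for m, _ in ranked if m in same_group)
        n_cand = int((assoc.MD[:, 0] == 0).sum())
        n_same = sum(1 for i in range(assoc.n_mirna)
                     if i % 3 == 0 and assoc.MD[i, 0] == 0)
        expected = hypergeom(n_cand, n_same, 5).mean()
        assert hits > expected
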