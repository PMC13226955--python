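"""Confusion matrices, occupancy, fold changes and the exact Wilcoxon test."""

import itertools

import numpy as np
import pytest
from scipy import stats as sstats

import remloop as rl
from remloop.states import VigilanceState as V


def _hyp(codes):
    return rl.Hypnogram(labels=np.array(codes, dtype=np.int8))


class TestConfusionMatrix:
    def test_identity_prediction_is_diagonal(self, rng):
        codes = rng.integers(1, 4, size=300)
        cm = rl.confusion_matrix(_hyp(codes), _hyp(codes))
        assert np.all(cm.counts[~np.eye(3, dtype=bool)] == 0)
        assert np.allclose(np.diag(cm.row_pct), 100.0)

    def test_all_rem_predicted_all_wake(self):
        cm = rl.confusion_matrix(_hyp([1] * 10), _hyp([2] * 10))
        assert np.allclose(cm.row_pct[0], [0.0, 100.0, 0.0])

    def test_matches_pair_counting_oracle(self, rng):
        t = rng.integers(1, 4, size=500)
        p = rng.integers(1, 4, size=500)
        cm = rl.confusion_matrix(_hyp(t), _hyp(p))
        for i, st_t in enumerate(rl.STATE_ORDER):
            for j, st_p in enumerate(rl.STATE_ORDER):
                brute = sum(1 for a, b in zip(t, p) if a == int(st_t) and b == int(st_p))
                assert cm.counts[i, j] == brute

    def test_row_percentages_sum_to_100(self, rng):
        t = rng.integers(1, 4, size=200)
        p = rng.integers(1, 4, size=200)
        cm = rl.confusion_matrix(_hyp(t), _hyp(p))
        assert np.allclose(cm.row_pct.sum(axis=1), 100.0, atol=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rl.confusion_matrix(_hyp([1, 2]), _hyp([1, 2, 3]))


class TestRecallF1:
    def test_perfect_diagonal(self):
        cm = rl.confusion_matrix(_hyp([1, 2, 3] * 5), _hyp([1, 2, 3] * 5))
        scores = rl.recall_f1(cm)
        for st in rl.STATE_ORDER:
            assert scores[st] == {"recall": 1.0, "precision": 1.0, "f1": 1.0}

    def test_rem_recall_from_scaled_row(self):
        # REM row (886 correct of 1000) -> recall 0.886
        truth = [1] * 1000 + [2] * 10 + [3] * 10
        pred = [1] * 886 + [2] * 64 + [3] * 50 + [2] * 10 + [3] * 10
        scores = rl.recall_f1(rl.confusion_matrix(_hyp(truth), _hyp(pred)))
        assert scores[V.REM]["recall"] == pytest.approx(0.886)

    def test_matches_formula_oracle_on_random_matrices(self, rng):
        for _ in range(20):
            t = rng.integers(1, 4, size=300)
            p = rng.integers(1, 4, size=300)
            cm = rl.confusion_matrix(_hyp(t), _hyp(p))
            scores = rl.recall_f1(cm)
            c = cm.counts
            for i, st in enumerate(rl.STATE_ORDER):
                recall = c[i, i] / c[i].sum()
                precision = c[i, i] / c[:, i].sum()
                assert scores[st]["recall"] == pytest.approx(recall)
                assert scores[st]["precision"] == pytest.approx(precision)
                if recall + precision > 0:
                    f1 = 2 * recall * precision / (recall + precision)
                    assert scores[st]["f1"] == pytest.approx(f1)

    def test_absent_state_flags_nan_not_zero(self):
        cm = rl.confusion_matrix(_hyp([2, 3] * 5), _hyp([2, 3] * 5))
        scores = rl.recall_f1(cm)
        assert np.isnan(scores[V.REM]["recall"])


class TestOccupancy:
    def test_single_state(self):
        occ = rl.occupancy(_hyp([3] * 50))
        assert occ[V.NREM] == 100.0 and occ[V.REM] == 0.0 and occ[V.WAKE] == 0.0

    def test_mixed_proportions(self):
        occ = rl.occupancy(_hyp([1] * 7 + [2] * 45 + [3] * 48))
        assert occ[V.REM] == pytest.approx(7.0)
        assert occ[V.WAKE] == pytest.approx(45.0)
        assert occ[V.NREM] == pytest.approx(48.0)

    def test_conservation(self, rng):
        for _ in range(10):
            occ = rl.occupancy(_hyp(rng.integers(1, 4, size=rng.integers(1, 200))))
            assert sum(occ.values()) == pytest.approx(100.0, abs=1e-9)

    def test_baseline_cohort_near_stationary_target(self, model):
        occs = [
            rl.occupancy(rl.generate_hypnogram(model, 24 * 3600.0, seed=s))[V.REM]
            for s in range(8)
        ]
        pi_rem = 100 * rl.stationary_distribution(model.transition_matrix)[0]
        assert np.mean(occs) == pytest.approx(pi_rem, abs=2.0)


class TestFoldChange:
    def test_log_mean_of_two_ratios(self):
        fc = rl.fold_change([2.0, 8.0], [1.0, 1.0])
        assert fc.geometric_mean == pytest.approx(4.0)

    def test_no_change_gives_unit_gm_with_ci_containing_one(self):
        x = [7.0, 6.0, 8.0, 7.5]
        fc = rl.fold_change(x, x)
        assert fc.geometric_mean == pytest.approx(1.0)
        assert fc.ci95[0] <= 1.0 <= fc.ci95[1]

    def test_antisymmetry_under_swap(self):
        b, r = [7.0, 6.0, 8.0], [0.5, 0.7, 0.4]
        assert rl.fold_change(b, r).geometric_mean == pytest.approx(
            1.0 / rl.fold_change(r, b).geometric_mean
        )

    def test_zero_occupancy_requires_offset_and_reports_adjustment(self):
        with pytest.raises(ValueError, match="zero_offset"):
            rl.fold_change([7.0, 6.0], [0.0, 0.5])
        fc = rl.fold_change([7.0, 6.0], [0.0, 0.5], zero_offset=0.05)
        assert fc.zero_adjusted == (0,)
        assert np.isfinite(fc.geometric_mean)

    def test_ci_matches_plain_bootstrap_direction(self, rng):
        """Strong suppression: GM >> 1 with CI excluding 1, consistent with
        an independent percentile bootstrap on the log ratios."""
        base = rng.uniform(5, 9, size=8)
        rsd = base / rng.uniform(10, 25, size=8)
        fc = rl.fold_change(base, rsd, seed=1)
        assert fc.geometric_mean > 10
        assert fc.ci95[0] > 1.0
        logr = np.log(base / rsd)
        boots = np.exp(
            [np.mean(rng.choice(logr, size=8, replace=True)) for _ in range(4000)]
        )
        lo, hi = np.quantile(boots, [0.025, 0.975])
        # bias-corrected and plain percentile intervals agree loosely
        assert fc.ci95[0] == pytest.approx(lo, rel=0.2)
        assert fc.ci95[1] == pytest.approx(hi, rel=0.2)

    def test_unpaired_input_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            rl.fold_change([1.0, 2.0], [1.0])


class TestWilcoxonPaired:
    def test_extreme_rank_configuration_closed_form(self):
        base = [2, 3, 4, 5, 6, 7, 8, 9]
        rsd = [1, 2, 3, 4, 5, 6, 7, 8.5]
        res = rl.wilcoxon_paired(base, rsd)
        assert res["p_two_sided"] == pytest.approx(2 / 256)

    def test_sign_flip_symmetry(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        p1 = rl.wilcoxon_paired(x, y)["p_two_sided"]
        p2 = rl.wilcoxon_paired(y, x)["p_two_sided"]
        assert p1 == pytest.approx(p2)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(ValueError, match="zero"):
            rl.wilcoxon_paired([1.0, 2.0], [1.0, 2.0])

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_matches_exhaustive_sign_enumeration(self, n, rng):
        """Exact p agrees with brute-force enumeration of all 2^m sign
        assignments on the observed (midrank, Pratt) ranks."""
        for trial in range(3):
            x = rng.normal(size=n)
            y = x - rng.normal(size=n)
            if trial == 2:  # force ties and a zero difference
                y[0] = x[0]
                if n >= 3:
                    y[2] = x[2] - abs(x[1] - y[1])
            d = x - y
            if np.all(d == 0):
                continue
            res = rl.wilcoxon_paired(x, y)
            ranks = sstats.rankdata(np.abs(d))
            nz = d != 0
            r, s = ranks[nz], np.sign(d[nz])
            w_obs = float(np.sum(r[s > 0]))
            stats_all = [
                sum(ri for ri, si in zip(r, signs) if si > 0)
                for signs in itertools.product([-1, 1], repeat=int(nz.sum()))
            ]
            stats_all = np.array(stats_all)
            p_le = np.mean(stats_all <= w_obs + 1e-12)
            p_ge = np.mean(stats_all >= w_obs - 1e-12)
            expected = min(1.0, 2 * min(p_le, p_ge))
            assert res["p_two_sided"] == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_scipy_without_ties(self, rng):
        x = rng.normal(size=9)
        y = x + rng.normal(size=9) * 0.5
        ours = rl.wilcoxon_paired(x, y)["p_two_sided"]
        ref = sstats.wilcoxon(x, y, method="exact").pvalue
        assert ours == pytest.approx(ref)


class TestStateSpaceExport:
    def test_three_rows_with_correct_joins(self):
        df = rl.state_space_export([1.0, 2.0, 3.0], [0.1, 0.2, 0.3], _hyp([1, 2, 3]))
        assert len(df) == 3
        assert list(df.columns) == ["epoch", "r_theta_delta", "emg_rms", "state"]
        assert df.loc[0, "state"] == "REM" and df.loc[0, "r_theta_delta"] == 1.0

    def test_misalignment_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            rl.state_space_export([1.0], [0.1, 0.2], _hyp([1, 2]))

    def test_rem_rows_high_theta_delta_low_emg(self, baseline):
        td = [f.r_theta_delta for f in baseline.features]
        emg = rl.emg_epoch_rms(baseline.emg.samples, baseline.emg.fs)
        df = rl.state_space_export(td, emg, baseline.hypnogram)
        rem = df[df.state == "REM"]
        wake = df[df.state == "WAKE"]
        nrem = df[df.state == "NREM"]
        assert rem.r_theta_delta.median() > 5 * nrem.r_theta_delta.median()
        assert rem.emg_rms.median() < 0.5 * wake.emg_rms.median()
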