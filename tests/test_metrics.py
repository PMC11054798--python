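"""Phase-error metrics, heel-strike timing, cross-validation, statistics."""

import itertools

import numpy as np
import pytest
from scipy import stats

from gaitphase.labeling import encode_phase
from gaitphase.metrics import (
    compare_models,
    estimated_heel_strikes,
    phase_error,
    spatial_metrics,
    temporal_mae,
)


def _enc(phi):
    y1, y2 = encode_phase(np.asarray(phi))
    return np.stack([np.atleast_1d(y1), np.atleast_1d(y2)], axis=-1)


def wrap_oracle(phi, phi_hat):
    """Brute-force minimizer of |phi_hat - phi + k| over k in {-1, 0, 1}."""
    cands = np.stack([phi_hat - phi + k for k in (-1, 0, 1)])
    return cands[np.argmin(np.abs(cands), axis=0), np.arange(phi.size)]


class TestPhaseError:
    def test_wraparound(self):
        d = phase_error(_enc(0.99), _enc(0.01))
        assert abs(d[0]) == pytest.approx(0.02, abs=1e-12)

    def test_zero_for_equal_phases(self):
        assert phase_error(_enc(0.37), _enc(0.37))[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle_on_grid(self):
        phi = np.linspace(0, 1, 57, endpoint=False)
        phih = np.linspace(0, 1, 57, endpoint=False)
        pp, hh = [a.ravel() for a in np.meshgrid(phi, phih)]
        got = phase_error(_enc(pp), _enc(hh))
        expected = wrap_oracle(pp, hh)
        # at exactly 0.5 cycles apart the sign is arbitrary; compare magnitudes
        assert np.allclose(np.abs(got), np.abs(expected), atol=1e-9)
        off = np.abs(np.abs(hh - pp) - 0.5) > 1e-9
        assert np.allclose(got[off], expected[off], atol=1e-9)

    def test_scale_invariance(self):
        y = _enc(0.2)
        yh = _enc(0.6)
        assert phase_error(y, 7.3 * yh)[0] == pytest.approx(
            phase_error(y, yh)[0], abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            phase_error(np.zeros((1, 2)), _enc(0.1))


class TestSpatialMetrics:
    def test_all_zero(self):
        assert spatial_metrics(np.zeros(10)) == (0.0, 0.0)

    def test_constant_offset(self):
        srmse, smae = spatial_metrics(np.full(8, 0.05))
        assert srmse == pytest.approx(5.0)
        assert smae == pytest.approx(5.0)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(-0.5, 0.5, 1000)
        srmse, smae = spatial_metrics(d)
        assert srmse == pytest.approx(100 * np.sqrt(np.mean(d**2)), abs=1e-12)
        assert smae == pytest.approx(100 * np.mean(np.abs(d)), abs=1e-12)

    def test_rmse_dominates_mae(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            d = rng.uniform(-0.5, 0.5, 50)
            srmse, smae = spatial_metrics(d)
            assert srmse >= smae - 1e-12

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            spatial_metrics(np.empty(0))


class TestEstimatedHeelStrikes:
    def test_perfect_sawtooth(self):
        t = np.arange(0, 4, 0.01)
        phi = np.mod(t, 1.0)
        ev = estimated_heel_strikes(phi, t)
        assert np.allclose(ev, [1.0, 2.0, 3.0], atol=0.011)

    def test_monotone_without_wrap(self):
        t = np.arange(0, 2, 0.01)
        assert estimated_heel_strikes(t / 2.0, t).size == 0

    def test_noisy_sawtooth_one_event_per_wrap(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 6, 0.01)
        phi = np.mod(np.mod(t, 1.0) + rng.normal(0, 0.02, t.size), 1.0)
        ev = estimated_heel_strikes(phi, t)
        assert ev.size == 5
        for k in range(1, 6):
            assert np.min(np.abs(ev - k)) <= 0.02

    def test_subsample_refinement(self):
        t = np.arange(0, 3, 0.01)
        phi = np.mod((t + 0.005) / 1.0, 1.0)  # wraps midway between samples
        ev = estimated_heel_strikes(phi, t)
        assert np.allclose(ev, [0.995, 1.995], atol=1e-9)


class TestTemporalMae:
    def test_exact_match_zero(self):
        actual = np.array([1.0, 2.0, 3.0])
        tmae, n = temporal_mae(actual.copy(), actual)
        assert tmae == 0.0
        assert n == 2  # first actual event has no preceding stride

    def test_five_percent_example(self):
        """50 ms offset against a 1 s previous stride is a 5% step error."""
        actual = np.array([9.0, 10.0])
        tmae, n = temporal_mae(np.array([10.05]), actual)
        assert tmae == pytest.approx(5.0)
        assert n == 1

    def test_normalization_by_previous_stride(self):
        actual = np.array([0.0, 2.0])  # 2 s stride
        tmae, _ = temporal_mae(np.array([2.1]), actual)
        assert tmae == pytest.approx(5.0)

    def test_spurious_events_penalized(self):
        actual = np.array([0.0, 1.0, 2.0])
        clean, n_clean = temporal_mae(np.array([1.0, 2.0]), actual)
        noisy, n_noisy = temporal_mae(np.array([1.0, 1.4, 2.0]), actual)
        assert n_noisy == n_clean + 1
        assert noisy > clean

    def test_input_contracts(self):
        with pytest.raises(ValueError):
            temporal_mae(np.empty(0), np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            temporal_mae(np.array([1.0]), np.array([0.0]))


class TestCompareModels:
    def test_identical_errors_not_significant(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        out = compare_models({"a": v, "b": v.copy(), "c": v.copy()})
        assert not out["friedman"]["significant"]
        assert not any(p["significant"] for p in out["pairwise"].values())

    def test_three_models_three_pairs_bonferroni(self):
        rng = np.random.default_rng(0)
        errs = {k: rng.uniform(1, 10, 8) for k in "abc"}
        out = compare_models(errs)
        assert len(out["pairwise"]) == 3
        assert out["corrected_alpha"] == pytest.approx(0.05 / 3)

    def test_wilcoxon_exact_enumeration_oracle_n6(self):
        """Two-tailed signed-rank p at n=6 equals the exact tail
        probability from enumerating all 2^6 sign assignments."""
        a = np.array([2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        b = a - np.array([0.5, 0.6, 0.7, 0.8, 0.9, 1.0])  # all diffs positive
        out = compare_models({"a": a, "b": b})
        p_got = out["pairwise"]["a vs b"]["p"]

        diffs = a - b
        ranks = stats.rankdata(np.abs(diffs))
        w_obs = min(ranks[diffs > 0].sum(), ranks[diffs < 0].sum())
        count = 0
        for signs in itertools.product([1, -1], repeat=6):
            w_plus = sum(r for r, s in zip(ranks, signs) if s > 0)
            w = min(w_plus, ranks.sum() - w_plus)
            if w <= w_obs:
                count += 1
        p_exact = count / 2**6
        assert p_got == pytest.approx(p_exact, abs=1e-12)

    def test_ks_mode(self):
        rng = np.random.default_rng(1)
        errs = {"a": rng.normal(0, 1, 30), "b": rng.normal(3, 1, 30)}
        out = compare_models(errs, test="ks")
        assert out["pairwise"]["a vs b"]["significant"]

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_models({"a": np.ones(5), "b": np.ones(6)})


@pytest.fixture(scope="module")
def small_cv():
    """3 tiny subjects, minimal training, subject-out CV."""
    from gaitphase.metrics import cross_validate, prepare_subject
    from gaitphase.synthetic import default_calibrations, generate_dataset
    from gaitphase.training import TrainConfig

    ds = generate_dataset(3, "paper", 9, duration_scale=0.04)
    calibs = default_calibrations()
    subs = [prepare_subject(s, calibs, stride_step=8) for s in ds]
    cfg = TrainConfig(val_every=3, max_epochs=1, seed=0, batch_size=64)
    rep = cross_validate(subs, "dual_head_1", "subject_out", train_cfg=cfg)
    return subs, rep


class TestCrossValidationStructure:
    def test_fold_count_and_subjects(self, small_cv):
        subs, rep = small_cv
        assert len(rep.folds) == 3
        assert sorted(f.test_subject for f in rep.folds) == \
            sorted(s.subject_id for s in subs)

    def test_report_aggregation(self, small_cv):
        _, rep = small_cv
        mean, sd = rep.srmse_mean_sd
        v = rep.fold_vector("srmse")
        assert mean == pytest.approx(v.mean())
        assert sd == pytest.approx(v.std(ddof=1))
        assert (v >= 0).all()

    def test_too_few_subjects_rejected(self, small_cv):
        from gaitphase.metrics import cross_validate
        subs, _ = small_cv
        with pytest.raises(ValueError):
            cross_validate(subs[:2], "dual_head_1")

    def test_condition_out_excludes_held_out_windows(self, small_cv, monkeypatch):
        """In condition-out folds, no window of the held-out condition
        reaches the training or validation set, while the test subject
        keeps all conditions."""
        import gaitphase.metrics as metrics_mod
        from gaitphase.metrics import cross_validate
        from gaitphase.training import TrainConfig

        subs, _ = small_cv
        held = "speed_sweep"
        held_refs = {
            s.subject_id: set(np.round(s.windows.t_ref[
                np.array(s.condition_names)[s.condition_of_window] == held
            ], 4))
            for s in subs
        }
        seen_train_refs = []
        real_train = metrics_mod.train_network

        def spy_train(net, train_ws, val_ws, cfg):
            seen_train_refs.append(set(np.round(train_ws.t_ref, 4))
                                   | set(np.round(val_ws.t_ref, 4)))
            return real_train(net, train_ws, val_ws, cfg)

        monkeypatch.setattr(metrics_mod, "train_network", spy_train)
        cfg = TrainConfig(val_every=3, max_epochs=1, seed=0, batch_size=64)
        rep = cross_validate(subs, "dual_head_1", "condition_out",
                             train_cfg=cfg, conditions=[held])
        assert len(rep.folds) == len(subs)
        assert all(f.held_out_condition == held for f in rep.folds)
        assert held in rep.per_condition
        all_held = set().union(*held_refs.values())
        for refs in seen_train_refs:
            assert not (refs & all_held)
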