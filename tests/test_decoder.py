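"""CSP, log-variance features, LDA, run-wise CV and the competence gate."""

import numpy as np
import pytest

import mibci
from mibci.decoder import csp_eigen, csp_features, fit_csp, fit_lda
from mibci.recording import LabeledWindowSet


def make_ws(windows, labels, runs=None, sfreq=64.0,
            channel_names=("C3", "C4")):
    n = len(windows)
    return LabeledWindowSet(
        windows=np.asarray(windows), labels=np.asarray(labels, dtype=object),
        trial_id=np.arange(n),
        run_id=np.zeros(n, int) if runs is None else np.asarray(runs),
        window_length=1.0, step=1.0, sfreq=sfreq,
        channel_names=list(channel_names))


def gaussian_windows(rng, n, scales):
    """n windows of independent channels with given per-channel std."""
    return rng.standard_normal((n, len(scales), 256)) * \
        np.asarray(scales)[None, :, None]


class TestCsp:
    def test_axis_aligned_toy_eigenvalues(self):
        """diag(4,1) vs diag(1,4): generalized eigenvalues are {0.8, 0.2}
        (per-channel oracle var_A / (var_A + var_B))."""
        evals, evecs = csp_eigen(np.diag([4.0, 1.0]), np.diag([1.0, 4.0]))
        assert np.sort(evals) == pytest.approx([0.2, 0.8], abs=1e-12)
        # eigenvectors align with the coordinate axes
        for v in evecs.T:
            v = np.abs(v / np.linalg.norm(v))
            assert max(v) == pytest.approx(1.0, abs=1e-9)

    def test_identical_covariances_give_half(self, rng):
        cov = np.cov(rng.standard_normal((4, 500)))
        evals, _ = csp_eigen(cov, cov)
        assert evals == pytest.approx(np.full(4, 0.5), abs=1e-9)

    def test_fit_on_sampled_toy(self, rng):
        a = gaussian_windows(rng, 60, [2.0, 1.0])
        b = gaussian_windows(rng, 60, [1.0, 2.0])
        ws = make_ws(np.concatenate([a, b]), ["relax"] * 60 + ["left_hand"] * 60)
        bank = fit_csp(ws, n_components=2)
        assert bank.component_scores == pytest.approx([0.6, 0.6], abs=0.1)
        assert np.max(np.abs(bank.filters @ bank.patterns - np.eye(2))) < 1e-6

    def test_scale_equivariance(self, small_windows):
        bank = fit_csp(small_windows)
        scaled = small_windows.subset(slice(None))
        scaled.windows = scaled.windows * 3.7
        bank2 = fit_csp(scaled)
        cos = np.abs(np.sum(bank.filters * bank2.filters, axis=1)
                     / np.linalg.norm(bank.filters, axis=1)
                     / np.linalg.norm(bank2.filters, axis=1))
        assert cos == pytest.approx(np.ones(bank.n_components), abs=1e-6)

    def test_pattern_localizes_near_sensorimotor_sources(self, small_windows,
                                                         montage9):
        """The strongest pattern weight sits within 2 electrode neighbors of
        C3 or C4 (the generator's ground-truth sources)."""
        bank = fit_csp(small_windows)
        top = np.argmax(bank.component_scores)
        ch = bank.channel_names[int(np.argmax(np.abs(bank.patterns[:, top])))]
        near = {"C3", "C4"}
        near |= set(montage9.neighbors("C3", 2)) | set(montage9.neighbors("C4", 2))
        assert ch in near

    def test_single_class_rejected(self, rng):
        ws = make_ws(gaussian_windows(rng, 20, [1.0, 1.0]), ["relax"] * 20)
        with pytest.raises(ValueError, match="2 classes"):
            fit_csp(ws)


class TestCspFeatures:
    def test_unit_variance_noise_near_zero(self, rng):
        wins = rng.standard_normal((40, 2, 2048))
        bank = mibci.SpatialFilterBank(
            filters=np.eye(2), patterns=np.eye(2),
            component_scores=np.array([1.0, 1.0]),
            component_class=["relax", "relax"], channel_names=["C3", "C4"])
        feats = csp_features(wins, bank)
        assert np.abs(feats).max() < 0.2

    def test_amplitude_doubling_shifts_by_log4(self, small_windows):
        bank = fit_csp(small_windows)
        f1 = csp_features(small_windows.windows, bank)
        f2 = csp_features(2.0 * small_windows.windows, bank)
        assert f2 - f1 == pytest.approx(np.log(4.0), abs=1e-9)

    def test_zero_window_floored_not_crashing(self):
        bank = mibci.SpatialFilterBank(
            filters=np.eye(2), patterns=np.eye(2),
            component_scores=np.array([1.0, 1.0]),
            component_class=["relax", "relax"], channel_names=["C3", "C4"])
        with pytest.warns(UserWarning, match="floored"):
            feats = csp_features(np.zeros((1, 2, 64)), bank)
        assert np.all(feats == pytest.approx(np.log(1e-12)))


class TestLda:
    def test_separated_clouds_perfect_training_accuracy(self, rng):
        X = np.concatenate([rng.standard_normal((100, 2)) + [5.0, 0.0],
                            rng.standard_normal((100, 2)) - [5.0, 0.0]])
        y = ["left_hand"] * 100 + ["right_hand"] * 100
        lda = fit_lda(X, y)
        assert np.mean(lda.predict(X) == np.array(y, dtype=object)) == 1.0
        # oracle: distance-to-centroid agrees everywhere
        centroids = {c: X[np.array(y) == c].mean(axis=0) for c in set(y)}
        oracle = [min(centroids, key=lambda c: np.linalg.norm(x - centroids[c]))
                  for x in X]
        assert np.mean(lda.predict(X) == np.array(oracle, dtype=object)) == 1.0

    def test_boundary_normal_matches_closed_form(self, rng):
        cov = np.array([[2.0, 0.6], [0.6, 1.0]])
        L = np.linalg.cholesky(cov)
        mu1, mu2 = np.array([1.0, 0.0]), np.array([-1.0, 0.5])
        X = np.concatenate([rng.standard_normal((4000, 2)) @ L.T + mu1,
                            rng.standard_normal((4000, 2)) @ L.T + mu2])
        y = ["relax"] * 4000 + ["left_hand"] * 4000
        lda = fit_lda(X, y)
        w = lda.coef[-1] - lda.coef[0] if len(lda.coef) > 1 else lda.coef[0]
        expect = np.linalg.solve(cov, mu1 - mu2)
        cos = abs(w @ expect) / np.linalg.norm(w) / np.linalg.norm(expect)
        assert cos == pytest.approx(1.0, abs=1e-3)

    def test_equidistant_point_posterior_half(self):
        X = np.array([[1.0, 0.0], [1.1, 0.0], [0.9, 0.0],
                      [-1.0, 0.0], [-1.1, 0.0], [-0.9, 0.0]])
        y = ["relax"] * 3 + ["left_hand"] * 3
        lda = fit_lda(X, y)
        p = lda.posteriors(np.array([[0.0, 0.0]]))
        assert p[0] == pytest.approx([0.5, 0.5], abs=1e-9)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 2 samples"):
            fit_lda(np.array([[0.0], [1.0], [2.0]]), ["a", "a", "b"])


class TestCrossValidation:
    def test_runwise_folds(self, protocol_windows):
        cv = mibci.cross_validate(protocol_windows)
        assert cv.k == 9
        assert [len(f) for f in cv.fold_composition] == [1] * 9
        assert sorted(sum(cv.fold_composition, [])) == list(range(9))
        assert cv.mean_accuracy == pytest.approx(
            np.mean(cv.fold_accuracies), abs=1e-12)

    def test_near_separable_regime_is_ceiling(self, small_windows):
        """erd 0.6 / snr 6: at most one window decision off perfect."""
        cv = mibci.cross_validate(small_windows)
        assert cv.mean_accuracy >= 1.0 - 1.0 / (len(small_windows) / cv.k)

    def test_permuted_labels_fall_to_chance(self, small_windows, rng):
        shuffled = small_windows.subset(slice(None))
        shuffled.labels = rng.permutation(shuffled.labels)
        cv = mibci.cross_validate(shuffled)
        # band at the number of independent units (windows within a trial
        # overlap and share the trial's rhythm realization)
        n_eff = len(np.unique(shuffled.trial_id))
        band = 1.96 * np.sqrt((1 / 3) * (2 / 3) / n_eff)
        assert abs(cv.mean_accuracy - 1 / 3) <= band

    def test_joint_channel_shuffle_invariance(self, small_windows, rng):
        perm = rng.permutation(small_windows.windows.shape[1])
        shuffled = small_windows.subset(slice(None))
        shuffled.windows = shuffled.windows[:, perm, :]
        shuffled.channel_names = [small_windows.channel_names[i] for i in perm]
        a = mibci.cross_validate(small_windows)
        b = mibci.cross_validate(shuffled)
        assert a.mean_accuracy == pytest.approx(b.mean_accuracy, abs=1e-9)

    def test_accuracy_grows_with_erd_depth(self, montage9):
        """Expected accuracy is non-decreasing in effect size (10 seeds)."""
        means = []
        for depth in (0.1, 0.3, 0.5):
            accs = []
            for seed in range(10):
                cfg = mibci.SynthEegConfig(n_series=3, trials_per_task=2,
                                           erd_depth=depth, snr=4.0,
                                           seed=100 + seed)
                rec = mibci.generate_mi_session(cfg, montage9)
                ws = mibci.epoch_and_window(mibci.bandpass_fir(rec))
                accs.append(mibci.cross_validate(ws).mean_accuracy)
            means.append(np.mean(accs))
        assert means[0] <= means[1] + 0.02 <= means[2] + 0.04

    def test_run_missing_class_identified(self, small_windows):
        broken = small_windows.subset(
            ~((small_windows.run_id == 1) &
              (small_windows.labels == "relax")))
        with pytest.raises(ValueError, match="run 1"):
            mibci.cross_validate(broken)


class TestModelRoundTrip:
    def test_save_load_identical_predictions(self, small_model, small_windows,
                                             tmp_path):
        path = tmp_path / "model.json"
        small_model.save(path)
        loaded = mibci.DecoderModel.load(path)
        p1, l1 = small_model.decision(small_windows.windows)
        p2, l2 = loaded.decision(small_windows.windows)
        assert np.array_equal(l1, l2)
        assert np.array_equal(p1, p2)
        assert loaded.classes == small_model.classes


class TestCompetenceGate:
    @pytest.mark.parametrize("acc,passed", [(0.71, True), (0.70, True),
                                            (0.699, False)])
    def test_threshold_is_inclusive(self, acc, passed):
        report = mibci.CvReport(fold_accuracies=[acc] * 9, k=9,
                                fold_composition=[[i] for i in range(9)])
        assert mibci.competence_gate(report).passed is passed

    def test_fourth_attempt_refused(self):
        report = mibci.CvReport(fold_accuracies=[0.5] * 9, k=9,
                                fold_composition=[[i] for i in range(9)])
        for attempt in (1, 2, 3):
            decision = mibci.competence_gate(report, attempt=attempt)
            assert not decision.passed and decision.attempt == attempt
        with pytest.raises(ValueError, match="three"):
            mibci.competence_gate(report, attempt=4)


def test_mne_csp_agrees_on_two_classes(small_windows):
    """Independent cross-check: MNE's 2-class CSP spans the same extreme
    directions as the in-package eigendecomposition."""
    import mne

    two = small_windows.subset(np.isin(small_windows.labels,
                                       ["left_hand", "right_hand"]))
    y = (two.labels == "right_hand").astype(int)
    csp = mne.decoding.CSP(n_components=2, reg=None, log=True,
                           norm_trace=False)
    with np.errstate(all="ignore"):
        csp.fit(two.windows, y)
    bank = fit_csp(two, n_components=2)
    # each MNE filter is (anti)parallel to one of ours
    for f in csp.filters_[:2]:
        cos = np.abs(bank.filters @ f) / np.linalg.norm(f) \
            / np.linalg.norm(bank.filters, axis=1)
        assert cos.max() > 0.99
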