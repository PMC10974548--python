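import numpy as np
import pytest

from efnet.io import WG
from efnet.preprocess import preprocess_cohort
from efnet.synth import SyntheticConfig, generate_cohort, double_gamma_hrf


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        dict(n_subjects=0),
        dict(trials_per_session=5),
        dict(hrf_effect=-1.0),
        dict(noise_sigma=-0.1),
        dict(rest_s_range=(15.0, 13.0)),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            SyntheticConfig(**bad).validate()


class TestCohortStructure:
    def test_determinism_bit_identical(self):
        cfg = SyntheticConfig(n_subjects=2, n_sessions=1, seed=42)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for ra, rb in zip(a, b):
            assert ra == rb

    def test_different_seeds_differ(self):
        a = generate_cohort(SyntheticConfig(n_subjects=1, n_sessions=1, seed=1))[0]
        b = generate_cohort(SyntheticConfig(n_subjects=1, n_sessions=1, seed=2))[0]
        assert not np.array_equal(a.eeg, b.eeg)

    def test_label_balance_per_session(self, tiny_cohort):
        for rec in tiny_cohort:
            labels = rec.trial_labels
            assert sum(1 for l in labels if l == WG) == len(labels) // 2

    def test_onsets_monotone_with_rest_range(self, tiny_cohort):
        for rec in tiny_cohort:
            gaps = np.diff(rec.trial_onsets)
            # 2s cue + 10s task + rest in [13, 15]
            assert np.all(gaps >= 25.0 - 1e-9)
            assert np.all(gaps <= 27.0 + 1e-9)

    def test_signals_cover_every_trial(self, tiny_cohort):
        for rec in tiny_cohort:
            end = rec.trial_onsets[-1] + 12.0
            assert rec.eeg.shape[0] / rec.eeg_fs >= end
            assert rec.fnirs.shape[0] / rec.fnirs_fs >= end


class TestSignalModel:
    def test_hrf_peaks_near_six_seconds(self):
        h = double_gamma_hrf(fs=10.0)
        assert 5.0 <= np.argmax(h) / 10.0 <= 6.5
        assert h.min() < 0  # undershoot present

    def test_strong_effect_raises_wg_hbo_in_every_subject(self):
        cfg = SyntheticConfig(n_subjects=3, n_sessions=1, hrf_effect=5.0,
                              eeg_effect=0.0, noise_sigma=0.2,
                              subject_sigma=0.1, seed=9)
        for rec in generate_cohort(cfg):
            means = {"WG": [], "BL": []}
            for onset, lab in zip(rec.trial_onsets, rec.trial_labels):
                i0 = int((onset + 2.0) * rec.fnirs_fs)
                i1 = i0 + int(10.0 * rec.fnirs_fs)
                means[lab].append(rec.fnirs[i0:i1, :36].mean())
            assert np.mean(means["WG"]) > np.mean(means["BL"])

    def test_hbr_moves_opposite_to_hbo(self):
        cfg = SyntheticConfig(n_subjects=1, n_sessions=1, hrf_effect=5.0,
                              eeg_effect=0.0, noise_sigma=0.1,
                              subject_sigma=0.0, seed=3)
        rec = generate_cohort(cfg)[0]
        wg = [(o, l) for o, l in zip(rec.trial_onsets, rec.trial_labels) if l == WG]
        onset, _ = wg[0]
        i0 = int((onset + 2.0) * rec.fnirs_fs)
        i1 = i0 + 100
        base = np.array(rec.trial_onsets[:1])  # pre-cue baseline of the same trial
        b0 = int(base[0] * rec.fnirs_fs)
        hbo_rise = rec.fnirs[i0:i1, :36].mean() - rec.fnirs[b0:i0, :36].mean()
        hbr_fall = rec.fnirs[i0:i1, 36:].mean() - rec.fnirs[b0:i0, 36:].mean()
        assert hbo_rise > 0 > hbr_fall

    def test_null_effect_gives_chance_separability(self):
        """With zero effects the labels carry no signal information.

        Evaluated on a trial-grouped split (whole trials held out): a random
        window-level split would let a classifier memorize per-trial noise
        through overlapping windows and score far above chance even with no
        class effect at all — the leakage the split diagnostics quantify.
        """
        from sklearn.linear_model import LogisticRegression

        cfg = SyntheticConfig(n_subjects=4, n_sessions=1, hrf_effect=0.0,
                              eeg_effect=0.0, subject_sigma=0.2, seed=21)
        bundle = preprocess_cohort(generate_cohort(cfg))
        X = bundle.xf.mean(axis=1)
        te_mask = bundle.trial_indices >= 16  # last 4 trials of every subject
        clf = LogisticRegression(max_iter=1000).fit(X[~te_mask],
                                                    bundle.labels[~te_mask])
        acc = clf.score(X[te_mask], bundle.labels[te_mask])
        assert 0.3 <= acc <= 0.7

    def test_accuracy_monotone_in_effect_size(self):
        """Held-out accuracy of a fixed pipeline does not decrease as the
        hemodynamic effect grows (3-point grid, 2 seeds, sampling slack)."""
        from sklearn.linear_model import LogisticRegression

        def held_out_acc(effect, seed):
            cfg = SyntheticConfig(n_subjects=4, n_sessions=1, hrf_effect=effect,
                                  eeg_effect=0.0, subject_sigma=0.2, seed=seed)
            bundle = preprocess_cohort(generate_cohort(cfg))
            X = bundle.xf.mean(axis=1)
            te = bundle.trial_indices >= 16  # hold out whole trials
            clf = LogisticRegression(max_iter=1000).fit(X[~te], bundle.labels[~te])
            return clf.score(X[te], bundle.labels[te])

        grid = [0.0, 1.0, 3.0]
        accs = [np.mean([held_out_acc(e, s) for s in (1, 2)]) for e in grid]
        assert accs[1] >= accs[0] - 0.05
        assert accs[2] >= accs[1] - 0.05
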