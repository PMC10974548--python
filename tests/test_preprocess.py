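import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from efnet.io import SubjectRecording
from efnet.preprocess import (
    apply_normalizer,
    downsample_half,
    extract_task_segment,
    fit_normalizer,
    preprocess_cohort,
    segment_windows,
    windows_per_trial,
)


def _ramp_recording(onsets=(2.0,), labels=("WG",), dur=None):
    """EEG rows filled with their own row index, for timing checks."""
    dur = dur or (onsets[-1] + 15.0)
    n_e, n_f = int(dur * 200), int(dur * 10)
    eeg = np.tile(np.arange(n_e, dtype=float)[:, None], (1, 30))
    fnirs = np.tile(np.arange(n_f, dtype=float)[:, None], (1, 72))
    return SubjectRecording(
        subject_id="R", eeg=eeg, fnirs=fnirs,
        trial_onsets=list(onsets), trial_labels=list(labels),
    )


class TestExtractTaskSegment:
    def test_window_covers_t4_to_t14_for_onset_2(self):
        rec = _ramp_recording(onsets=(2.0,))
        eeg_seg, fnirs_seg = extract_task_segment(rec, 0)
        assert eeg_seg.shape == (2000, 30)
        assert fnirs_seg.shape == (100, 72)
        # rows correspond to t in [4.0, 14.0) s
        assert eeg_seg[0, 0] == 4.0 * 200
        assert eeg_seg[-1, 0] == 14.0 * 200 - 1
        assert fnirs_seg[0, 0] == 4.0 * 10

    def test_trial_index_out_of_range(self):
        rec = _ramp_recording()
        with pytest.raises(IndexError):
            extract_task_segment(rec, 5)

    def test_segment_past_signal_end(self):
        rec = _ramp_recording()
        rec.trial_onsets[0] = rec.eeg.shape[0] / 200 - 5.0  # too late
        with pytest.raises(ValueError):
            extract_task_segment(rec, 0)

    def test_constant_signal_extracts_constants(self):
        rec = _ramp_recording()
        rec.eeg = np.ones_like(rec.eeg)
        seg, _ = extract_task_segment(rec, 0)
        assert np.all(seg == 1.0)


class TestDownsample:
    def test_keeps_even_rows(self):
        x = np.arange(4, dtype=float)[:, None]
        assert np.array_equal(downsample_half(x)[:, 0], [0.0, 2.0])

    @pytest.mark.parametrize("shape,expected", [((2000, 30), (1000, 30)),
                                                ((100, 72), (50, 72))])
    def test_published_shapes(self, shape, expected):
        assert downsample_half(np.zeros(shape)).shape == expected

    def test_odd_rows_rejected(self):
        with pytest.raises(ValueError):
            downsample_half(np.zeros((101, 3)))


class TestSegmentWindows:
    def test_ten_second_signal_yields_six_windows(self):
        wins = segment_windows(np.zeros((1000, 30)), fs=100)
        assert len(wins) == 6
        assert all(w.shape == (500, 30) for w in wins)

    def test_exact_length_signal_yields_itself(self):
        x = np.arange(50, dtype=float)[:, None]
        wins = segment_windows(x, fs=10)
        assert len(wins) == 1
        assert np.array_equal(wins[0], x)

    def test_seven_second_signal_start_offsets(self):
        x = np.arange(70, dtype=float)[:, None]
        wins = segment_windows(x, fs=10)
        assert [int(w[0, 0]) for w in wins] == [0, 10, 20]

    def test_window_longer_than_signal(self):
        with pytest.raises(ValueError):
            segment_windows(np.zeros((40, 3)), fs=10)

    @settings(deadline=None, max_examples=60)
    @given(dur=st.integers(5, 40), fs=st.integers(2, 20),
           window=st.integers(1, 10), stride=st.integers(1, 5))
    def test_count_matches_start_offset_enumeration(self, dur, fs, window, stride):
        if window > dur:
            return
        x = np.zeros((dur * fs, 2))
        wins = segment_windows(x, fs=fs, window_s=window, stride_s=stride)
        # independent oracle: enumerate every valid start offset
        starts = [s for s in range(0, dur * fs, stride * fs)
                  if s + window * fs <= dur * fs]
        assert len(wins) == len(starts)
        assert len(wins) == windows_per_trial(dur, window, stride)


class TestNormalizer:
    def test_state_matches_pooled_brute_force(self):
        rng = np.random.default_rng(4)
        bundle = preprocess_cohort([_ramp_recording(onsets=(2.0, 28.0),
                                                    labels=("WG", "BL"))])
        bundle.xe[:] = rng.standard_normal(bundle.xe.shape)
        bundle.xf[:] = rng.standard_normal(bundle.xf.shape)
        state = fit_normalizer(bundle)
        for c in (0, 7, 29):
            # all time points of channel c, pooled by hand in float64
            pooled = bundle.xe[:, :, c].ravel().astype(np.float64)
            assert state.eeg_mean[c] == pytest.approx(pooled.mean())
            assert state.eeg_std[c] == pytest.approx(pooled.std())

    def test_apply_centers_and_scales(self, tiny_bundle):
        state = fit_normalizer(tiny_bundle)
        z = apply_normalizer(state, tiny_bundle)
        for c in (0, 29):
            pooled = z.xe[:, :, c].ravel()
            assert abs(pooled.mean()) < 1e-5
            assert abs(pooled.std() - 1.0) < 1e-4

    def test_constant_channel_maps_to_zero(self):
        bundle = preprocess_cohort([_ramp_recording()])
        bundle.xf[:, :, 3] = 7.0
        state = fit_normalizer(bundle)
        z = apply_normalizer(state, bundle)
        assert np.all(z.xf[:, :, 3] == 0.0)

    def test_empty_training_set_rejected(self, tiny_bundle):
        with pytest.raises(ValueError):
            fit_normalizer(tiny_bundle.subset(np.array([], dtype=int)))


class TestPreprocessCohort:
    def test_sample_count_and_shapes(self, tiny_cohort, tiny_bundle):
        expected = sum(rec.n_trials for rec in tiny_cohort) * 6
        assert len(tiny_bundle) == expected
        assert tiny_bundle.xe.shape[1:] == (500, 30)
        assert tiny_bundle.xf.shape[1:] == (25, 72)

    def test_labels_inherited_from_trials(self, tiny_cohort, tiny_bundle):
        rec = tiny_cohort[0]
        mask = tiny_bundle.subject_ids == rec.subject_id
        for trial in range(rec.n_trials):
            labs = tiny_bundle.labels[mask & (tiny_bundle.trial_indices == trial)]
            expect = 1 if rec.trial_labels[trial] == "WG" else 0
            assert np.all(labs == expect)

    def test_all_bl_cohort_all_zero_labels(self):
        rec = _ramp_recording(onsets=(2.0, 28.0), labels=("BL", "BL"))
        bundle = preprocess_cohort([rec])
        assert np.all(bundle.labels == 0)

    def test_provenance_is_bijective(self, tiny_bundle):
        keys = list(zip(tiny_bundle.subject_ids, tiny_bundle.trial_indices,
                        tiny_bundle.window_indices))
        assert len(set(keys)) == len(keys)

    def test_windows_within_trial_distinct(self, tiny_bundle):
        mask = ((tiny_bundle.subject_ids == tiny_bundle.subject_ids[0])
                & (tiny_bundle.trial_indices == 0))
        wins = tiny_bundle.xe[mask]
        for i in range(len(wins)):
            for j in range(i + 1, len(wins)):
                assert not np.array_equal(wins[i], wins[j])

    def test_global_normalize_mode(self):
        rec = _ramp_recording(onsets=(2.0, 28.0), labels=("WG", "BL"))
        bundle = preprocess_cohort([rec], normalize="global")
        assert bundle.normalizer_state is not None

    def test_bundle_round_trip(self, tiny_bundle, tmp_path):
        from efnet.preprocess import load_bundle, save_bundle

        path = tmp_path / "bundle.h5"
        save_bundle(tiny_bundle, path)
        back = load_bundle(path)
        assert np.array_equal(back.xe, tiny_bundle.xe)
        assert np.array_equal(back.labels, tiny_bundle.labels)
        assert list(back.subject_ids) == list(tiny_bundle.subject_ids)
        assert back.provenance == tiny_bundle.provenance
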