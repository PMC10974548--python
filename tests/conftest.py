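import numpy as np
import pytest

from efnet.preprocess import DatasetBundle, preprocess_cohort
from efnet.synth import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 subjects x 1 session x 20 trials, moderate effects."""
    cfg = SyntheticConfig(n_subjects=2, n_sessions=1, hrf_effect=2.0,
                          eeg_effect=2.0, subject_sigma=0.3, seed=5)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_cohort):
    return preprocess_cohort(tiny_cohort)


@pytest.fixture(scope="session")
def full_cohort_bundle():
    """The default-layout cohort (26 subjects x 60 trials), windowed.

    Raw recordings are released after windowing to bound memory; the shapes
    of one raw task segment are captured first.
    """
    from efnet.preprocess import downsample_half, extract_task_segment

    cfg = SyntheticConfig(seed=38)
    cohort = generate_cohort(cfg)
    eeg_seg, fnirs_seg = extract_task_segment(cohort[0], 0)
    meta = {
        "n_subjects": len(cohort),
        "segment_shapes": (eeg_seg.shape, fnirs_seg.shape),
        "decimated_shapes": (downsample_half(eeg_seg).shape,
                             downsample_half(fnirs_seg).shape),
        "trials_per_subject": [rec.n_trials for rec in cohort],
        "labels_per_subject": {rec.subject_id: list(rec.trial_labels) for rec in cohort},
    }
    bundle = preprocess_cohort(cohort)
    del cohort
    return bundle, meta


def skeleton_bundle(n_subjects=26, samples_per_subject=360, windows_per_trial=6,
                    seed=0):
    """A bundle with the right provenance columns but 1x1 signal stubs,
    for split-protocol tests where signal content is irrelevant."""
    rng = np.random.default_rng(seed)
    n = n_subjects * samples_per_subject
    trials_per_subject = samples_per_subject // windows_per_trial
    sids, trials, winds, labels = [], [], [], []
    for s in range(n_subjects):
        for t in range(trials_per_subject):
            lab = int(rng.random() < 0.5)
            for w in range(windows_per_trial):
                sids.append(f"S{s + 1:02d}")
                trials.append(t)
                winds.append(w)
                labels.append(lab)
    return DatasetBundle(
        xe=np.zeros((n, 1, 1), dtype=np.float32),
        xf=np.zeros((n, 1, 1), dtype=np.float32),
        labels=np.asarray(labels),
        subject_ids=np.asarray(sids),
        trial_indices=np.asarray(trials),
        window_indices=np.asarray(winds),
    )
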