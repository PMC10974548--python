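"""Windowing pipeline: continuous recordings -> fixed-shape paired samples.

For each trial the 2 s cue is discarded and the following 10 s task period
kept, giving 2000x30 EEG (200 Hz) and 100x72 fNIRS (10 Hz) segments.  Both
are decimated by 2 (1000x30 at 100 Hz, 50x72 at 5 Hz) and cut into 5 s
sliding windows with a 1 s shift, yielding 6 windows per trial: EEG windows
of 500x30 and fNIRS windows of 25x72.  A cohort with the published layout
(26 subjects x 60 trials) therefore yields 26*60*6 = 9360 paired samples,
360 per subject.

Per-channel z-score statistics are fit by pooling every time point of every
training sample of a channel; fitting on the training split only (the
default downstream) avoids leaking test statistics into training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from efnet.io import WG, SubjectRecording

#: label encoding
LABEL_CODE = {"BL": 0, "WG": 1}

EEG_WINDOW_SHAPE = (500, 30)
FNIRS_WINDOW_SHAPE = (25, 72)

#: guard for constant channels in z-scoring
EPS = 1e-8


@dataclass
class WindowSample:
    """One paired 5 s sample with provenance."""

    xe: np.ndarray          # (500, 30) EEG at 100 Hz
    xf: np.ndarray          # (25, 72) fNIRS at 5 Hz
    label: int              # WG=1, BL=0
    subject_id: str
    trial_index: int
    window_index: int


@dataclass
class NormalizerState:
    """Pooled per-channel mean/scale for both modalities."""

    eeg_mean: np.ndarray    # (30,)
    eeg_std: np.ndarray     # (30,)
    fnirs_mean: np.ndarray  # (72,)
    fnirs_std: np.ndarray   # (72,)


@dataclass
class DatasetBundle:
    """Windowed cohort stored as stacked arrays for efficiency.

    ``xe`` has shape (n, 500, 30), ``xf`` (n, 25, 72); ``labels`` is 0/1.
    Individual :class:`WindowSample` views are available by indexing.
    """

    xe: np.ndarray
    xf: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray     # (n,) str
    trial_indices: np.ndarray   # (n,) int
    window_indices: np.ndarray  # (n,) int
    normalizer_state: NormalizerState | None = None
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.xe.shape[0]

    def __getitem__(self, i: int) -> WindowSample:
        return WindowSample(
            xe=self.xe[i],
            xf=self.xf[i],
            label=int(self.labels[i]),
            subject_id=str(self.subject_ids[i]),
            trial_index=int(self.trial_indices[i]),
            window_index=int(self.window_indices[i]),
        )

    @property
    def samples(self) -> Iterator[WindowSample]:
        return (self[i] for i in range(len(self)))

    def subset(self, idx) -> "DatasetBundle":
        idx = np.asarray(idx)
        return DatasetBundle(
            xe=self.xe[idx],
            xf=self.xf[idx],
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
            trial_indices=self.trial_indices[idx],
            window_indices=self.window_indices[idx],
            normalizer_state=self.normalizer_state,
            provenance=dict(self.provenance),
        )


def extract_task_segment(rec: SubjectRecording, trial: int,
                         cue_s: float = 2.0, task_s: float = 10.0):
    """Return the task-period signals of one trial.

    Covers ``[onset + cue_s, onset + cue_s + task_s)``: at publisher rates a
    2000x30 EEG block and a 100x72 fNIRS block.  Rest-period data are never
    included.
    """
    if not 0 <= trial < rec.n_trials:
        raise IndexError(f"trial {trial} out of range (0..{rec.n_trials - 1})")
    onset = rec.trial_onsets[trial]
    start = onset + cue_s

    e0 = int(round(start * rec.eeg_fs))
    en = int(round(task_s * rec.eeg_fs))
    f0 = int(round(start * rec.fnirs_fs))
    fn = int(round(task_s * rec.fnirs_fs))
    if e0 + en > rec.eeg.shape[0] or f0 + fn > rec.fnirs.shape[0]:
        raise ValueError(
            f"trial {trial} at {onset:.2f}s: task segment exceeds signal end"
        )
    return rec.eeg[e0:e0 + en], rec.fnirs[f0:f0 + fn]


def downsample_half(x: np.ndarray) -> np.ndarray:
    """Keep every second row starting at row 0 (plain decimation by 2)."""
    x = np.asarray(x)
    if x.shape[0] % 2 != 0:
        raise ValueError(f"row count {x.shape[0]} is odd; trim before decimating")
    return x[::2]


def segment_windows(x: np.ndarray, fs: float, window_s: float = 5.0,
                    stride_s: float = 1.0) -> list[np.ndarray]:
    """Cut a time-major matrix into sliding windows.

    Windows are ``window_s * fs`` rows long and consecutive windows start
    ``stride_s * fs`` rows apart; a 10 s signal with a 5 s window and 1 s
    stride yields 6 windows.
    """
    x = np.asarray(x)
    wlen = int(round(window_s * fs))
    step = int(round(stride_s * fs))
    if wlen > x.shape[0]:
        raise ValueError(
            f"window of {wlen} rows longer than signal of {x.shape[0]} rows"
        )
    n_win = (x.shape[0] - wlen) // step + 1
    return [x[i * step:i * step + wlen] for i in range(n_win)]


def windows_per_trial(task_s: float = 10.0, window_s: float = 5.0,
                      stride_s: float = 1.0) -> int:
    return int((task_s - window_s) // stride_s) + 1


def fit_normalizer(samples) -> NormalizerState:
    """Pool all time points of all samples per channel; return mean/std.

    ``samples`` may be a DatasetBundle or a sequence of WindowSample.
    """
    xe, xf = _stacks(samples)
    if xe.shape[0] < 1:
        raise ValueError("cannot fit a normalizer on an empty training set")
    # accumulate in float64 regardless of storage dtype
    eeg_mean = xe.mean(axis=(0, 1), dtype=np.float64)
    eeg_std = xe.std(axis=(0, 1), dtype=np.float64)
    fnirs_mean = xf.mean(axis=(0, 1), dtype=np.float64)
    fnirs_std = xf.std(axis=(0, 1), dtype=np.float64)
    return NormalizerState(
        eeg_mean=eeg_mean,
        eeg_std=np.where(eeg_std < EPS, 1.0, eeg_std),
        fnirs_mean=fnirs_mean,
        fnirs_std=np.where(fnirs_std < EPS, 1.0, fnirs_std),
    )


def apply_normalizer(state: NormalizerState, samples):
    """Z-score per channel.  Returns the same container type as the input."""
    if isinstance(samples, DatasetBundle):
        out = DatasetBundle(
            xe=(samples.xe - state.eeg_mean) / state.eeg_std,
            xf=(samples.xf - state.fnirs_mean) / state.fnirs_std,
            labels=samples.labels,
            subject_ids=samples.subject_ids,
            trial_indices=samples.trial_indices,
            window_indices=samples.window_indices,
            normalizer_state=state,
            provenance=dict(samples.provenance),
        )
        return out
    return [
        WindowSample(
            xe=(s.xe - state.eeg_mean) / state.eeg_std,
            xf=(s.xf - state.fnirs_mean) / state.fnirs_std,
            label=s.label,
            subject_id=s.subject_id,
            trial_index=s.trial_index,
            window_index=s.window_index,
        )
        for s in samples
    ]


def _stacks(samples):
    if isinstance(samples, DatasetBundle):
        return samples.xe, samples.xf
    samples = list(samples)
    if not samples:
        return np.empty((0,) + EEG_WINDOW_SHAPE), np.empty((0,) + FNIRS_WINDOW_SHAPE)
    return np.stack([s.xe for s in samples]), np.stack([s.xf for s in samples])


def preprocess_cohort(cohort: Sequence[SubjectRecording], *,
                      cue_s: float = 2.0, task_s: float = 10.0,
                      window_s: float = 5.0, stride_s: float = 1.0,
                      normalize: str = "none",
                      dtype=np.float32) -> DatasetBundle:
    """Run the full pipeline over a cohort.

    Parameters
    ----------
    normalize : {"none", "global"}
        ``"none"`` (default) leaves samples raw so the trainer can fit the
        z-score statistics on its training split only; ``"global"`` fits on
        the whole cohort before splitting (the leakier dialect some studies
        use — provided for faithfulness comparisons, never the default).
    """
    if normalize not in ("none", "global"):
        raise ValueError("normalize must be 'none' or 'global'")
    xe_all, xf_all, labels, sids, trials, winds = [], [], [], [], [], []
    for rec in cohort:
        for trial in range(rec.n_trials):
            eeg_seg, fnirs_seg = extract_task_segment(rec, trial, cue_s, task_s)
            eeg_ds = downsample_half(eeg_seg)
            fnirs_ds = downsample_half(fnirs_seg)
            wins_e = segment_windows(eeg_ds, rec.eeg_fs / 2, window_s, stride_s)
            wins_f = segment_windows(fnirs_ds, rec.fnirs_fs / 2, window_s, stride_s)
            if len(wins_e) != len(wins_f):
                raise ValueError(
                    f"modality window-count mismatch ({len(wins_e)} EEG vs "
                    f"{len(wins_f)} fNIRS) for trial {trial} of {rec.subject_id}"
                )
            lab = LABEL_CODE[rec.trial_labels[trial]]
            for w, (we, wf) in enumerate(zip(wins_e, wins_f)):
                xe_all.append(np.asarray(we, dtype=dtype))
                xf_all.append(np.asarray(wf, dtype=dtype))
                labels.append(lab)
                sids.append(rec.subject_id)
                trials.append(trial)
                winds.append(w)
    bundle = DatasetBundle(
        xe=np.stack(xe_all) if xe_all else np.empty((0,) + EEG_WINDOW_SHAPE, dtype=dtype),
        xf=np.stack(xf_all) if xf_all else np.empty((0,) + FNIRS_WINDOW_SHAPE, dtype=dtype),
        labels=np.asarray(labels, dtype=np.int64),
        subject_ids=np.asarray(sids),
        trial_indices=np.asarray(trials, dtype=np.int64),
        window_indices=np.asarray(winds, dtype=np.int64),
        provenance={
            "cue_s": cue_s, "task_s": task_s,
            "window_s": window_s, "stride_s": stride_s,
            "normalize": normalize, "n_subjects": len(cohort),
        },
    )
    if normalize == "global":
        state = fit_normalizer(bundle)
        bundle = apply_normalizer(state, bundle)
    return bundle


def save_bundle(bundle: DatasetBundle, path) -> None:
    """Persist a windowed dataset to HDF5 (lossless)."""
    import json

    import h5py

    with h5py.File(str(path), "w") as f:
        f.create_dataset("xe", data=bundle.xe)
        f.create_dataset("xf", data=bundle.xf)
        f.create_dataset("labels", data=bundle.labels)
        f.create_dataset("subject_ids",
                         data=np.array([s.encode() for s in bundle.subject_ids]))
        f.create_dataset("trial_indices", data=bundle.trial_indices)
        f.create_dataset("window_indices", data=bundle.window_indices)
        f.attrs["provenance"] = json.dumps(bundle.provenance)
        if bundle.normalizer_state is not None:
            g = f.create_group("normalizer")
            ns = bundle.normalizer_state
            for k in ("eeg_mean", "eeg_std", "fnirs_mean", "fnirs_std"):
                g.create_dataset(k, data=getattr(ns, k))


def load_bundle(path) -> DatasetBundle:
    import json

    import h5py

    with h5py.File(str(path), "r") as f:
        ns = None
        if "normalizer" in f:
            g = f["normalizer"]
            ns = NormalizerState(
                eeg_mean=g["eeg_mean"][()], eeg_std=g["eeg_std"][()],
                fnirs_mean=g["fnirs_mean"][()], fnirs_std=g["fnirs_std"][()],
            )
        return DatasetBundle(
            xe=f["xe"][()],
            xf=f["xf"][()],
            labels=f["labels"][()],
            subject_ids=np.array([b.decode() for b in f["subject_ids"][()]]),
            trial_indices=f["trial_indices"][()],
            window_indices=f["window_indices"][()],
            normalizer_state=ns,
            provenance=json.loads(f.attrs["provenance"]),
        )
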