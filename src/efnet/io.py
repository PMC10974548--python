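"""Reading and writing paired EEG-fNIRS recordings.

Two on-disk dialects are supported:

* MATLAB v5 struct files, the format the open word-generation dataset ships
  in (read via :func:`scipy.io.loadmat`).  Field names vary between releases,
  so the reader takes a configurable field map.
* An HDF5 fixture container (one group per subject) used by this package for
  synthetic cohorts and intermediate artifacts.  Round trips through it are
  lossless and bit-exact.

All times are in seconds and all signal matrices are time-major
``[time x channels]``.  fNIRS channels are ordered HbO (columns 0..35) then
HbR (columns 36..71).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import scipy.io

WG = "WG"
BL = "BL"
VALID_LABELS = (WG, BL)

#: trial span that every recording must cover after each cue onset:
#: 2 s cue + 10 s task
TRIAL_SPAN_S = 12.0

DEFAULT_EEG_FS = 200.0
DEFAULT_FNIRS_FS = 10.0

#: default MAT struct field names; override via ``field_map`` for other
#: releases of the dataset
DEFAULT_FIELD_MAP = {
    "eeg": "eeg",
    "hbo": "hbo",
    "hbr": "hbr",
    "onsets": "onsets",
    "labels": "labels",
    "eeg_fs": "eeg_fs",
    "fnirs_fs": "fnirs_fs",
    "subject_id": "subject_id",
}


class FormatError(ValueError):
    """Container is readable but missing or mistyping a required field."""


class ConsistencyError(ValueError):
    """Fields are present but mutually inconsistent (e.g. onset past end)."""


@dataclass
class SubjectRecording:
    """One subject's continuous EEG + fNIRS streams with trial markers.

    Attributes
    ----------
    subject_id : str
        Stable identifier, e.g. ``"S01"``.
    eeg : ndarray, shape (time, 30)
        EEG in microvolts at ``eeg_fs`` Hz.
    fnirs : ndarray, shape (time, 72)
        Hemoglobin concentration changes at ``fnirs_fs`` Hz; columns 0..35
        are HbO, columns 36..71 HbR.
    eeg_fs, fnirs_fs : float
        Sampling rates in Hz (200 / 10 for the published data).
    trial_onsets : list of float
        Cue-onset times in seconds.
    trial_labels : list of str
        ``"WG"`` or ``"BL"``, one per onset.
    """

    subject_id: str
    eeg: np.ndarray
    fnirs: np.ndarray
    eeg_fs: float = DEFAULT_EEG_FS
    fnirs_fs: float = DEFAULT_FNIRS_FS
    trial_onsets: list = field(default_factory=list)
    trial_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg)
        self.fnirs = np.asarray(self.fnirs)
        self.trial_onsets = [float(t) for t in self.trial_onsets]
        self.trial_labels = list(self.trial_labels)
        self.validate()

    @property
    def n_trials(self) -> int:
        return len(self.trial_onsets)

    def validate(self) -> None:
        if self.eeg.ndim != 2 or self.fnirs.ndim != 2:
            raise FormatError("eeg and fnirs must be 2-D [time x channels]")
        if len(self.trial_onsets) != len(self.trial_labels):
            raise ConsistencyError(
                f"{len(self.trial_onsets)} onsets but "
                f"{len(self.trial_labels)} labels"
            )
        bad = set(self.trial_labels) - set(VALID_LABELS)
        if bad:
            raise FormatError(f"unknown trial labels: {sorted(bad)}")
        eeg_dur = self.eeg.shape[0] / self.eeg_fs
        fnirs_dur = self.fnirs.shape[0] / self.fnirs_fs
        for t in self.trial_onsets:
            if t < 0 or t + TRIAL_SPAN_S > min(eeg_dur, fnirs_dur):
                raise ConsistencyError(
                    f"trial at {t:.2f}s extends past signal end "
                    f"(eeg {eeg_dur:.2f}s, fnirs {fnirs_dur:.2f}s)"
                )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SubjectRecording):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.eeg_fs == other.eeg_fs
            and self.fnirs_fs == other.fnirs_fs
            and self.eeg.shape == other.eeg.shape
            and self.fnirs.shape == other.fnirs.shape
            and np.array_equal(self.eeg, other.eeg)
            and np.array_equal(self.fnirs, other.fnirs)
            and self.trial_onsets == other.trial_onsets
            and self.trial_labels == other.trial_labels
        )


def _mat_field(data: Mapping, key: str, name: str):
    if key not in data:
        raise FormatError(f"MAT file missing field '{key}' (expected for '{name}')")
    return data[key]


def read_matlab_recording(
    path: str | Path,
    field_map: Mapping[str, str] | None = None,
) -> SubjectRecording:
    """Read one subject from a MATLAB v5 struct file.

    Parameters
    ----------
    path : path
        ``.mat`` file with EEG array, HbO and HbR arrays (36 channels each),
        trial onsets in seconds and WG/BL labels.
    field_map : mapping, optional
        Maps logical names (``"eeg"``, ``"hbo"``, ``"hbr"``, ``"onsets"``,
        ``"labels"``, optionally ``"eeg_fs"``, ``"fnirs_fs"``,
        ``"subject_id"``) to the struct field names actually used in the
        file.  Defaults to :data:`DEFAULT_FIELD_MAP`.

    Returns
    -------
    SubjectRecording
        With HbO and HbR concatenated column-wise into the 72-channel
        ``fnirs`` matrix (HbO first) and sampling rates from the file or
        the publisher defaults 200 / 10 Hz.
    """
    fm = dict(DEFAULT_FIELD_MAP)
    if field_map:
        fm.update(field_map)
    data = scipy.io.loadmat(str(path), squeeze_me=True)

    eeg = np.atleast_2d(np.asarray(_mat_field(data, fm["eeg"], "eeg"), dtype=np.float64))
    hbo = np.atleast_2d(np.asarray(_mat_field(data, fm["hbo"], "hbo"), dtype=np.float64))
    hbr = np.atleast_2d(np.asarray(_mat_field(data, fm["hbr"], "hbr"), dtype=np.float64))
    if hbo.shape != hbr.shape:
        raise ConsistencyError(f"HbO shape {hbo.shape} != HbR shape {hbr.shape}")
    fnirs = np.concatenate([hbo, hbr], axis=1)

    onsets = np.atleast_1d(np.asarray(_mat_field(data, fm["onsets"], "onsets"), dtype=float))
    raw_labels = np.atleast_1d(_mat_field(data, fm["labels"], "labels"))
    labels = [_decode_label(x) for x in raw_labels]

    eeg_fs = float(data.get(fm["eeg_fs"], DEFAULT_EEG_FS))
    fnirs_fs = float(data.get(fm["fnirs_fs"], DEFAULT_FNIRS_FS))
    subject_id = str(data.get(fm["subject_id"], Path(path).stem))

    return SubjectRecording(
        subject_id=subject_id,
        eeg=eeg,
        fnirs=fnirs,
        eeg_fs=eeg_fs,
        fnirs_fs=fnirs_fs,
        trial_onsets=onsets.tolist(),
        trial_labels=labels,
    )


def _decode_label(x) -> str:
    if isinstance(x, bytes):
        x = x.decode()
    if isinstance(x, str):
        s = x.strip().upper()
        if s in VALID_LABELS:
            return s
        raise FormatError(f"unknown label string {x!r}")
    # numeric encoding: 1 = WG, 0 = BL
    v = int(x)
    if v in (0, 1):
        return WG if v == 1 else BL
    raise FormatError(f"unknown numeric label {x!r}")


def write_matlab_recording(
    rec: SubjectRecording,
    path: str | Path,
    field_map: Mapping[str, str] | None = None,
) -> None:
    """Write a recording in the MAT struct dialect (inverse of the reader)."""
    fm = dict(DEFAULT_FIELD_MAP)
    if field_map:
        fm.update(field_map)
    scipy.io.savemat(
        str(path),
        {
            fm["eeg"]: rec.eeg,
            fm["hbo"]: rec.fnirs[:, :36],
            fm["hbr"]: rec.fnirs[:, 36:],
            fm["onsets"]: np.asarray(rec.trial_onsets, dtype=float),
            fm["labels"]: np.asarray(rec.trial_labels),
            fm["eeg_fs"]: rec.eeg_fs,
            fm["fnirs_fs"]: rec.fnirs_fs,
            fm["subject_id"]: rec.subject_id,
        },
    )


def write_fixture(cohort: Sequence[SubjectRecording], path: str | Path) -> None:
    """Write a cohort to the HDF5 fixture container, one group per subject.

    The subject order is preserved and the round trip is bit-exact.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cannot write an empty cohort")
    with h5py.File(str(path), "w") as f:
        f.attrs["subject_order"] = [rec.subject_id for rec in cohort]
        grp = f.create_group("subjects")
        for rec in cohort:
            g = grp.create_group(rec.subject_id)
            g.create_dataset("eeg", data=rec.eeg)
            g.create_dataset("fnirs", data=rec.fnirs)
            g.create_dataset("trial_onsets", data=np.asarray(rec.trial_onsets, dtype=np.float64))
            g.create_dataset(
                "trial_labels",
                data=np.array([s.encode() for s in rec.trial_labels]),
            )
            g.attrs["eeg_fs"] = rec.eeg_fs
            g.attrs["fnirs_fs"] = rec.fnirs_fs


def read_fixture(path: str | Path) -> list[SubjectRecording]:
    """Read a cohort back from the HDF5 fixture container."""
    out: list[SubjectRecording] = []
    with h5py.File(str(path), "r") as f:
        if "subjects" not in f or "subject_order" not in f.attrs:
            raise FormatError("not an efnet fixture container")
        for sid in f.attrs["subject_order"]:
            sid = sid if isinstance(sid, str) else sid.decode()
            g = f["subjects"][sid]
            out.append(
                SubjectRecording(
                    subject_id=sid,
                    eeg=g["eeg"][()],
                    fnirs=g["fnirs"][()],
                    eeg_fs=float(g.attrs["eeg_fs"]),
                    fnirs_fs=float(g.attrs["fnirs_fs"]),
                    trial_onsets=g["trial_onsets"][()].tolist(),
                    trial_labels=[b.decode() for b in g["trial_labels"][()]],
                )
            )
    return out
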