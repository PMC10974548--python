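"""Train/test split protocols.

Three protocols are supported, mirroring how hybrid-BCI studies report
results:

* ``dependent`` — train and test within one subject's samples (personalized
  model).
* ``semidependent`` — one global shuffle of all samples from all subjects;
  any subject may appear on both sides.
* ``independent`` — subjects (not samples) are shuffled and partitioned, so
  no subject contributes to both sides; the honest measure of unseen-subject
  generalization.

The train share uses floor rounding (26 subjects -> 20 train + 6 test at
0.8).  Default seeds are (38, 43, 45).

Note that in the dependent and semidependent protocols, overlapping windows
cut from the same trial can land on opposite sides of the split; this is
part of the protocol, not a bug, and :func:`trial_leakage_report` quantifies
it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from efnet.preprocess import DatasetBundle

SETTINGS = ("dependent", "semidependent", "independent")
DEFAULT_SEEDS = (38, 43, 45)


@dataclass
class SplitSpec:
    """An assignment of samples (or subjects) to train/test.

    For ``dependent`` and ``semidependent`` settings, ``train_ids`` and
    ``test_ids`` are sample indices into the bundle; for ``independent``
    they are subject ids, and ``train_idx``/``test_idx`` carry the derived
    sample indices.
    """

    setting: str
    seed: int
    train_fraction: float
    train_ids: list
    test_ids: list
    train_idx: np.ndarray = field(default=None, repr=False)
    test_idx: np.ndarray = field(default=None, repr=False)

    def to_json(self) -> str:
        d = asdict(self)
        d["train_idx"] = None if self.train_idx is None else [int(i) for i in self.train_idx]
        d["test_idx"] = None if self.test_idx is None else [int(i) for i in self.test_idx]
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "SplitSpec":
        d = json.loads(s)
        for k in ("train_idx", "test_idx"):
            if d[k] is not None:
                d[k] = np.asarray(d[k], dtype=np.int64)
        return cls(**d)


def _shuffled_cut(n: int, frac: float, seed: int):
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(frac * n))
    return order[:n_train], order[n_train:]


def subject_dependent_split(bundle: DatasetBundle, subject_id: str,
                            frac: float = 0.8, seed: int = 38) -> SplitSpec:
    """Shuffle one subject's samples and cut 80/20."""
    mask = bundle.subject_ids == subject_id
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise KeyError(f"unknown subject {subject_id!r}")
    if idx.size < 5:
        raise ValueError(f"subject {subject_id!r} has only {idx.size} samples")
    tr, te = _shuffled_cut(idx.size, frac, seed)
    train_idx, test_idx = idx[tr], idx[te]
    return SplitSpec(
        setting="dependent", seed=seed, train_fraction=frac,
        train_ids=[int(i) for i in train_idx], test_ids=[int(i) for i in test_idx],
        train_idx=train_idx, test_idx=test_idx,
    )


def semidependent_split(bundle: DatasetBundle, frac: float = 0.8,
                        seed: int = 38) -> SplitSpec:
    """Shuffle the pooled samples of all subjects and cut 80/20."""
    n = len(bundle)
    if n == 0:
        raise ValueError("empty bundle")
    tr, te = _shuffled_cut(n, frac, seed)
    return SplitSpec(
        setting="semidependent", seed=seed, train_fraction=frac,
        train_ids=[int(i) for i in tr], test_ids=[int(i) for i in te],
        train_idx=np.asarray(tr), test_idx=np.asarray(te),
    )


def subject_independent_split(subject_ids, frac: float = 0.8, seed: int = 38,
                              bundle: DatasetBundle | None = None) -> SplitSpec:
    """Shuffle subjects and partition them; samples follow their subject.

    With 26 subjects and frac 0.8 this reserves 6 subjects for testing.
    Passing the bundle fills in the derived sample indices.
    """
    subject_ids = list(dict.fromkeys(subject_ids))  # unique, order-preserving
    if len(subject_ids) < 2:
        raise ValueError("subject-independent split needs at least 2 subjects")
    tr, te = _shuffled_cut(len(subject_ids), frac, seed)
    train_subjects = [subject_ids[i] for i in tr]
    test_subjects = [subject_ids[i] for i in te]
    spec = SplitSpec(
        setting="independent", seed=seed, train_fraction=frac,
        train_ids=train_subjects, test_ids=test_subjects,
    )
    if bundle is not None:
        attach_sample_indices(spec, bundle)
    return spec


def attach_sample_indices(spec: SplitSpec, bundle: DatasetBundle) -> SplitSpec:
    """Derive sample indices for a subject-level split from a bundle."""
    if spec.setting != "independent":
        return spec
    train_set = set(spec.train_ids)
    test_set = set(spec.test_ids)
    sids = bundle.subject_ids
    spec.train_idx = np.flatnonzero([s in train_set for s in sids])
    spec.test_idx = np.flatnonzero([s in test_set for s in sids])
    return spec


def audit_subject_leakage(spec: SplitSpec, bundle: DatasetBundle) -> int:
    """Number of test samples whose subject also contributes train samples.

    Always 0 for a correctly constructed independent split.
    """
    train_subjects = set(bundle.subject_ids[spec.train_idx])
    return int(np.sum([s in train_subjects for s in bundle.subject_ids[spec.test_idx]]))


def trial_leakage_report(spec: SplitSpec, bundle: DatasetBundle) -> dict:
    """Diagnostic: test windows sharing a (subject, trial) with a train window.

    Overlapping windows cut from one trial carry nearly identical signal, so
    when they straddle the split the protocol is easier than it looks.  This
    is inherent to the dependent/semidependent protocols; the count is
    reported for transparency, not corrected.
    """
    train_trials = set(zip(bundle.subject_ids[spec.train_idx],
                           bundle.trial_indices[spec.train_idx]))
    flags = [
        (s, t) in train_trials
        for s, t in zip(bundle.subject_ids[spec.test_idx],
                        bundle.trial_indices[spec.test_idx])
    ]
    n_test = len(flags)
    n_leaky = int(np.sum(flags))
    return {
        "setting": spec.setting,
        "seed": spec.seed,
        "n_test": n_test,
        "n_test_sharing_trial_with_train": n_leaky,
        "fraction": (n_leaky / n_test) if n_test else 0.0,
    }
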