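"""Synthetic paired EEG-fNIRS cohort generator.

Emulates the block design of the open word-generation dataset: 26 subjects,
3 sessions of 20 trials each (10 word-generation WG + 10 baseline BL in
random order), each trial a 2 s cue, a 10 s task period, and a 13-15 s rest.

The signal model is deliberately minimal — it carries exactly the structure
the classifier is built to exploit, and nothing else:

* EEG: 1/f-weighted ("pink") background noise per channel, plus, during the
  task period of WG trials only, a band-limited (8-12 Hz) sinusoidal burst
  with a Hann envelope, projected onto a fixed spatial channel pattern and
  scaled by ``eeg_effect``.
* fNIRS: slow sinusoidal drift plus white noise, plus, for WG trials only, a
  canonical double-gamma hemodynamic response (peak ~6 s, undershoot ~16 s,
  truncated at 25 s) convolved with the 10 s task boxcar — added positively
  to the 36 HbO channels and with opposite sign at half amplitude to the 36
  HbR channels, scaled by ``hrf_effect``.
* Subject heterogeneity: each subject draws a per-channel additive offset
  (scale ``subject_sigma``) and a multiplicative gain ``1 + subject_sigma*z``
  on the class effect; at large ``subject_sigma`` some subjects' effects are
  attenuated or sign-flipped, which is what makes unseen-subject
  generalization genuinely harder than within-subject evaluation.

Randomness uses counter-based substreams (one per subject, one per trial)
derived from the master seed, so cohorts are bit-reproducible regardless of
generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import gamma as gamma_dist

from efnet.io import BL, WG, SubjectRecording

#: silence before the first cue and after the last trial, seconds
_EDGE_PAD_S = 2.0


@dataclass
class SyntheticConfig:
    """Cohort layout and signal-model parameters.

    The layout defaults mirror the published dataset; the amplitude
    parameters are dimensionless scales on a unit-variance noise floor.
    """

    n_subjects: int = 26
    n_sessions: int = 3
    trials_per_session: int = 20  # half WG, half BL
    eeg_fs: float = 200.0
    fnirs_fs: float = 10.0
    cue_s: float = 2.0
    task_s: float = 10.0
    rest_s_range: tuple = (13.0, 15.0)
    eeg_effect: float = 1.0
    hrf_effect: float = 1.0
    subject_sigma: float = 0.5
    noise_sigma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_sessions < 1 or self.trials_per_session < 1:
            raise ValueError("all counts must be >= 1")
        if self.trials_per_session % 2 != 0:
            raise ValueError("trials_per_session must be even (half WG, half BL)")
        for name in ("eeg_effect", "hrf_effect", "subject_sigma", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.rest_s_range
        if not (0 < lo <= hi):
            raise ValueError("rest_s_range must satisfy 0 < lo <= hi")

    def asdict(self) -> dict:
        return asdict(self)


def double_gamma_hrf(fs: float, peak_s: float = 6.0, undershoot_s: float = 16.0,
                     length_s: float = 25.0, undershoot_ratio: float = 1 / 6) -> np.ndarray:
    """Canonical double-gamma hemodynamic impulse response, unit peak.

    The positive lobe peaks at ``peak_s`` and the negative undershoot at
    ``undershoot_s``; the kernel is truncated at ``length_s``.
    """
    t = np.arange(0, length_s, 1.0 / fs)
    # gamma pdf with shape a and scale 1 peaks at a-1 -> shape = peak+1
    pos = gamma_dist.pdf(t, peak_s + 1.0)
    neg = gamma_dist.pdf(t, undershoot_s + 1.0)
    h = pos - undershoot_ratio * neg
    return h / np.max(np.abs(h))


def _pink_noise(rng: np.random.Generator, n: int, n_ch: int, fs: float) -> np.ndarray:
    """1/f-amplitude-weighted Gaussian noise, unit variance per channel."""
    white = rng.standard_normal((n, n_ch))
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    w = np.ones_like(freqs)
    nz = freqs > 0
    w[nz] = 1.0 / np.sqrt(freqs[nz])
    w[0] = 0.0  # no DC drift from the noise term itself
    shaped = np.fft.irfft(spec * w[:, None], n=n, axis=0)
    sd = shaped.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def _session_labels(rng: np.random.Generator, n_trials: int) -> list:
    labels = [WG] * (n_trials // 2) + [BL] * (n_trials // 2)
    rng.shuffle(labels)
    return labels


def generate_cohort(cfg: SyntheticConfig) -> list[SubjectRecording]:
    """Generate a reproducible synthetic cohort.

    Returns one :class:`~efnet.io.SubjectRecording` per subject with subject
    ids ``S01..Snn``.  Deterministic given ``cfg.seed``: the same config
    yields bit-identical cohorts.
    """
    cfg.validate()
    root = np.random.SeedSequence([int(cfg.seed), 0x5EF_0E7])

    # cohort-level spatial patterns, shared by all subjects (the learnable,
    # subject-invariant structure)
    cohort_rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x5EF_0E7, 0]))
    eeg_pattern = 0.5 + cohort_rng.random(30)          # all-positive weights
    fnirs_pattern = 0.5 + cohort_rng.random(36)        # HbO spatial loading

    hrf = double_gamma_hrf(cfg.fnirs_fs)
    box = np.ones(int(round(cfg.task_s * cfg.fnirs_fs)))
    task_response = np.convolve(box, hrf)
    task_response /= task_response.max()               # unit peak

    out = []
    for s in range(cfg.n_subjects):
        out.append(_generate_subject(cfg, s, eeg_pattern, fnirs_pattern, task_response))
    return out


def _generate_subject(cfg: SyntheticConfig, s: int, eeg_pattern: np.ndarray,
                      fnirs_pattern: np.ndarray, task_response: np.ndarray) -> SubjectRecording:
    subj_rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x5EF_0E7, 1, s]))

    # per-subject nuisance: additive channel offsets and a gain on the effect
    eeg_offset = subj_rng.normal(0.0, cfg.subject_sigma, size=30)
    fnirs_offset = subj_rng.normal(0.0, cfg.subject_sigma, size=72)
    effect_gain = 1.0 + cfg.subject_sigma * subj_rng.standard_normal()

    # trial timeline for all sessions, concatenated into one continuous record
    onsets: list[float] = []
    labels: list[str] = []
    t = _EDGE_PAD_S
    trial_len = cfg.cue_s + cfg.task_s
    for sess in range(cfg.n_sessions):
        sess_rng = np.random.default_rng(
            np.random.SeedSequence([int(cfg.seed), 0x5EF_0E7, 2, s, sess])
        )
        for lab in _session_labels(sess_rng, cfg.trials_per_session):
            onsets.append(t)
            labels.append(lab)
            rest = sess_rng.uniform(*cfg.rest_s_range)
            t += trial_len + rest
    total_s = t + _EDGE_PAD_S

    n_e = int(np.ceil(total_s * cfg.eeg_fs))
    n_f = int(np.ceil(total_s * cfg.fnirs_fs))

    eeg = cfg.noise_sigma * _pink_noise(subj_rng, n_e, 30, cfg.eeg_fs)
    eeg += eeg_offset[None, :]

    fnirs = cfg.noise_sigma * subj_rng.standard_normal((n_f, 72))
    # slow physiological drift, ~0.01-0.05 Hz per channel
    tt = np.arange(n_f) / cfg.fnirs_fs
    drift_f = subj_rng.uniform(0.01, 0.05, size=72)
    drift_ph = subj_rng.uniform(0, 2 * np.pi, size=72)
    fnirs += 0.5 * cfg.noise_sigma * np.sin(2 * np.pi * drift_f[None, :] * tt[:, None] + drift_ph[None, :])
    fnirs += fnirs_offset[None, :]

    # class-dependent structure on WG trials only, during the task window
    for k, (onset, lab) in enumerate(zip(onsets, labels)):
        if lab != WG:
            continue
        trial_rng = np.random.default_rng(
            np.random.SeedSequence([int(cfg.seed), 0x5EF_0E7, 3, s, k])
        )
        _add_eeg_burst(eeg, cfg, onset, effect_gain, eeg_pattern, trial_rng)
        _add_hemodynamic_response(fnirs, cfg, onset, effect_gain, fnirs_pattern, task_response)

    return SubjectRecording(
        subject_id=f"S{s + 1:02d}",
        eeg=eeg.astype(np.float32),
        fnirs=fnirs.astype(np.float32),
        eeg_fs=cfg.eeg_fs,
        fnirs_fs=cfg.fnirs_fs,
        trial_onsets=onsets,
        trial_labels=labels,
    )


def _add_eeg_burst(eeg: np.ndarray, cfg: SyntheticConfig, onset: float,
                   gain: float, pattern: np.ndarray, rng: np.random.Generator) -> None:
    i0 = int(round((onset + cfg.cue_s) * cfg.eeg_fs))
    n = int(round(cfg.task_s * cfg.eeg_fs))
    i1 = min(i0 + n, eeg.shape[0])
    t = np.arange(i1 - i0) / cfg.eeg_fs
    f = rng.uniform(8.0, 12.0)           # alpha-band burst frequency
    phase = rng.uniform(0, 2 * np.pi)
    env = np.hanning(i1 - i0)
    burst = np.sin(2 * np.pi * f * t + phase) * env
    eeg[i0:i1, :] += cfg.eeg_effect * gain * burst[:, None] * pattern[None, :]


def _add_hemodynamic_response(fnirs: np.ndarray, cfg: SyntheticConfig, onset: float,
                              gain: float, pattern: np.ndarray,
                              task_response: np.ndarray) -> None:
    i0 = int(round((onset + cfg.cue_s) * cfg.fnirs_fs))
    n = min(len(task_response), fnirs.shape[0] - i0)
    resp = cfg.hrf_effect * gain * task_response[:n]
    fnirs[i0:i0 + n, :36] += resp[:, None] * pattern[None, :]
    fnirs[i0:i0 + n, 36:] += -0.5 * resp[:, None] * pattern[None, :]


def cohort_manifest(cohort) -> "pandas.DataFrame":  # noqa: F821
    """Ground-truth manifest: one row per trial (subject, trial, onset, label)."""
    import pandas as pd

    rows = [
        {"subject": rec.subject_id, "trial": k, "onset": onset, "label": lab}
        for rec in cohort
        for k, (onset, lab) in enumerate(zip(rec.trial_onsets, rec.trial_labels))
    ]
    return pd.DataFrame(rows)
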