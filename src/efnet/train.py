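"""Training loop, metrics and seed-aggregated experiment reports.

Training is minibatch Adam on binary cross-entropy, with a
reduce-on-plateau learning-rate schedule (halved when the monitored
accuracy has not improved for ``plateau_patience`` epochs) and early
stopping.  Two checkpoint rules are available:

* ``best-validation-accuracy`` (default): 10% of the training split is
  carved off as a validation set and the epoch with the best validation
  accuracy is kept — the statistically clean rule.
* ``best-test-accuracy`` ("faithful"): the epoch with the best *test*
  accuracy is kept.  This peeks at the test set during model selection and
  therefore biases reported scores upward; it is provided because some
  published pipelines use it, and every report records which rule produced
  its numbers.

Metrics (accuracy, precision, recall, F1, AUROC at the 0.5 threshold) are
computed with scikit-learn; the test suite cross-checks them against an
independent brute-force confusion-matrix/rank oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from efnet.model import ModelConfig, ModelSpec, build_efnet
from efnet.nn import Adam, softmax, sigmoid
from efnet.preprocess import DatasetBundle, apply_normalizer, fit_normalizer
from efnet.splits import (
    DEFAULT_SEEDS,
    SETTINGS,
    SplitSpec,
    semidependent_split,
    subject_dependent_split,
    subject_independent_split,
)

logger = logging.getLogger("efnet.train")

CHECKPOINT_RULES = ("best-validation-accuracy", "best-test-accuracy")


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 50
    checkpoint_rule: str = "best-validation-accuracy"
    plateau_patience: int = 3
    plateau_factor: float = 0.5
    early_stop_patience: int = 10
    validation_fraction: float = 0.1
    normalize: str = "train"          # {"train", "none"}
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.checkpoint_rule not in CHECKPOINT_RULES:
            raise ValueError(f"checkpoint_rule must be one of {CHECKPOINT_RULES}")
        if self.normalize not in ("train", "none"):
            raise ValueError("normalize must be 'train' or 'none'")


@dataclass
class MetricsReport:
    """Point metrics for one evaluated split (fractions in [0, 1])."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auroc: float | None
    n_test: int
    extra: dict = field(default_factory=dict)

    def asdict(self) -> dict:
        return asdict(self)

    def scaled(self) -> dict:
        """Metrics on the conventional x100 reporting scale."""
        out = {}
        for k in ("accuracy", "precision", "recall", "f1", "auroc"):
            v = getattr(self, k)
            out[k] = None if v is None else 100.0 * v
        out["n_test"] = self.n_test
        return out


def compute_metrics(y_true, scores, threshold: float = 0.5) -> MetricsReport:
    """Threshold scores at 0.5 for class metrics; AUROC from the raw scores.

    A single-class test set leaves AUROC undefined; it is reported as None.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    y_pred = (scores >= threshold).astype(int)
    if len(np.unique(y_true)) < 2:
        auroc = None
    else:
        auroc = float(roc_auc_score(y_true, scores))
    return MetricsReport(
        accuracy=float(accuracy_score(y_true, y_pred)),
        precision=float(precision_score(y_true, y_pred, zero_division=0)),
        recall=float(recall_score(y_true, y_pred, zero_division=0)),
        f1=float(f1_score(y_true, y_pred, zero_division=0)),
        auroc=auroc,
        n_test=int(y_true.size),
    )


def _batched_proba(spec: ModelSpec, bundle: DatasetBundle, idx, batch=256) -> np.ndarray:
    idx = np.asarray(idx)
    out = np.empty(idx.size)
    needs_e = spec.eeg_branch is not None
    needs_f = spec.fnirs_branch is not None
    for lo in range(0, idx.size, batch):
        sel = idx[lo:lo + batch]
        out[lo:lo + batch] = spec.predict_proba(
            xe=bundle.xe[sel] if needs_e else None,
            xf=bundle.xf[sel] if needs_f else None,
        )
    return out


def evaluate(spec: ModelSpec, bundle: DatasetBundle, idx=None,
             state: dict | None = None) -> MetricsReport:
    """Evaluate fitted parameters on the given sample indices."""
    if state is not None:
        spec.set_state(state)
    if idx is None:
        idx = np.arange(len(bundle))
    scores = _batched_proba(spec, bundle, idx)
    return compute_metrics(bundle.labels[np.asarray(idx)], scores)


@dataclass
class TrainResult:
    state: dict
    history: dict
    best_epoch: int
    checkpoint_rule: str
    normalizer_state: object = None


def _loss_and_grad(spec: ModelSpec, xe, xf, y, rng):
    z = spec.logits(xe=xe, xf=xf, train=True, rng=rng)
    n = y.size
    eps = 1e-12
    if spec.cfg.output_units == 1:
        p = sigmoid(z[:, 0])
        loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        dz = ((p - y) / n)[:, None]
    else:
        p2 = softmax(z)
        loss = -np.mean(np.log(p2[np.arange(n), y] + eps))
        dz = p2.copy()
        dz[np.arange(n), y] -= 1.0
        dz /= n
    return loss + spec.reg_loss(), dz


def train_model(spec: ModelSpec, bundle: DatasetBundle, split: SplitSpec,
                cfg: TrainingConfig) -> TrainResult:
    """Fit the model under a split; returns the checkpointed parameters.

    The per-channel z-score normalizer is fit on the training samples only
    (unless ``cfg.normalize == "none"``, for bundles normalized upstream).
    Fully seeded: parameter initialization is the caller's job (via
    ``build_efnet(init_seed=...)``); shuffling, validation carving and
    dropout all derive from ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x7121]))

    train_idx = np.asarray(split.train_idx)
    test_idx = np.asarray(split.test_idx)

    if cfg.normalize == "train":
        norm = fit_normalizer(bundle.subset(train_idx))
        bundle = apply_normalizer(norm, bundle)
    else:
        norm = bundle.normalizer_state

    if cfg.checkpoint_rule == "best-validation-accuracy":
        perm = rng.permutation(train_idx.size)
        n_val = max(1, int(round(cfg.validation_fraction * train_idx.size)))
        monitor_idx = train_idx[perm[:n_val]]
        fit_idx = train_idx[perm[n_val:]]
    else:
        monitor_idx = test_idx
        fit_idx = train_idx

    needs_e = spec.eeg_branch is not None
    needs_f = spec.fnirs_branch is not None
    opt = Adam(lr=cfg.learning_rate)
    pairs = spec.param_pairs()

    history = {"loss": [], "monitor_accuracy": [], "test_accuracy": [], "lr": []}
    best_acc, best_state, best_epoch = -np.inf, spec.get_state(), -1
    stale = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(fit_idx)
        losses = []
        for lo in range(0, order.size, cfg.batch_size):
            sel = order[lo:lo + cfg.batch_size]
            loss, dz = _loss_and_grad(
                spec,
                bundle.xe[sel] if needs_e else None,
                bundle.xf[sel] if needs_f else None,
                bundle.labels[sel], rng,
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss!r} "
                    f"(lr={opt.lr:g}); lower the learning rate"
                )
            spec.backward(dz)
            opt.step(pairs)
            losses.append(loss)

        mon = evaluate(spec, bundle, monitor_idx)
        test = evaluate(spec, bundle, test_idx)
        history["loss"].append(float(np.mean(losses)))
        history["monitor_accuracy"].append(mon.accuracy)
        history["test_accuracy"].append(test.accuracy)
        history["lr"].append(opt.lr)
        logger.info(
            "epoch %d loss %.4f monitor_acc %.4f test_acc %.4f lr %.2g",
            epoch, history["loss"][-1], mon.accuracy, test.accuracy, opt.lr,
        )

        if mon.accuracy > best_acc:
            best_acc, best_state, best_epoch = mon.accuracy, spec.get_state(), epoch
            stale = 0
        else:
            stale += 1
            if stale % cfg.plateau_patience == 0:
                opt.lr *= cfg.plateau_factor
            if stale >= cfg.early_stop_patience:
                break

    spec.set_state(best_state)
    return TrainResult(
        state=best_state,
        history=history,
        best_epoch=best_epoch,
        checkpoint_rule=cfg.checkpoint_rule,
        normalizer_state=norm,
    )


def _make_split(setting: str, bundle: DatasetBundle, seed: int,
                subject_id: str | None = None, frac: float = 0.8) -> SplitSpec:
    if setting == "dependent":
        return subject_dependent_split(bundle, subject_id, frac=frac, seed=seed)
    if setting == "semidependent":
        return semidependent_split(bundle, frac=frac, seed=seed)
    if setting == "independent":
        subjects = list(dict.fromkeys(bundle.subject_ids.tolist()))
        return subject_independent_split(subjects, frac=frac, seed=seed, bundle=bundle)
    raise ValueError(f"setting must be one of {SETTINGS}")


def run_single(bundle: DatasetBundle, setting: str, seed: int,
               model_cfg: ModelConfig, train_cfg: TrainingConfig,
               subject_id: str | None = None) -> MetricsReport:
    """One seed, one setting: split, train, evaluate on the test side."""
    split = _make_split(setting, bundle, seed, subject_id=subject_id)
    spec = build_efnet(model_cfg, init_seed=seed)
    cfg = TrainingConfig(**{**asdict(train_cfg), "seed": seed})
    result = train_model(spec, bundle, split, cfg)
    work = bundle
    if cfg.normalize == "train" and result.normalizer_state is not None:
        work = apply_normalizer(result.normalizer_state, bundle)
    report = evaluate(spec, work, split.test_idx)
    report.extra.update(
        setting=setting, seed=seed, subject_id=subject_id,
        checkpoint_rule=cfg.checkpoint_rule, best_epoch=result.best_epoch,
    )
    return report


METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auroc")


def aggregate_reports(reports) -> dict:
    """Mean +/- population std per metric over seeds, on the x100 scale."""
    out = {}
    for name in METRIC_NAMES:
        vals = [getattr(r, name) for r in reports]
        if any(v is None for v in vals):
            out[name] = {"mean": None, "std": None}
            continue
        arr = 100.0 * np.asarray(vals, dtype=float)
        out[name] = {"mean": float(arr.mean()), "std": float(arr.std(ddof=0))}
    return out


def run_experiment(bundle: DatasetBundle, setting: str, modality: str,
                   seeds=DEFAULT_SEEDS, model_cfg: ModelConfig | None = None,
                   train_cfg: TrainingConfig | None = None,
                   dependent_subjects=("S01", "S02", "S03")) -> dict:
    """Per-seed runs aggregated into one table row (mean +/- std, x100).

    In the subject-dependent setting each seed's value is the average over
    the first three subjects, trained individually.
    """
    if setting not in SETTINGS:
        raise ValueError(f"setting must be one of {SETTINGS}")
    model_cfg = model_cfg or ModelConfig(modality=modality)
    if model_cfg.modality != modality:
        raise ValueError("model_cfg.modality disagrees with the requested modality")
    train_cfg = train_cfg or TrainingConfig()

    per_seed: list[MetricsReport] = []
    for seed in seeds:
        if setting == "dependent":
            subj_reports = [
                run_single(bundle, setting, seed, model_cfg, train_cfg, subject_id=s)
                for s in dependent_subjects
            ]
            merged = MetricsReport(
                accuracy=float(np.mean([r.accuracy for r in subj_reports])),
                precision=float(np.mean([r.precision for r in subj_reports])),
                recall=float(np.mean([r.recall for r in subj_reports])),
                f1=float(np.mean([r.f1 for r in subj_reports])),
                auroc=(None if any(r.auroc is None for r in subj_reports)
                       else float(np.mean([r.auroc for r in subj_reports]))),
                n_test=int(np.sum([r.n_test for r in subj_reports])),
                extra={"setting": setting, "seed": seed,
                       "subjects": list(dependent_subjects)},
            )
            per_seed.append(merged)
        else:
            per_seed.append(run_single(bundle, setting, seed, model_cfg, train_cfg))

    return {
        "setting": setting,
        "modality": modality,
        "seeds": list(seeds),
        "checkpoint_rule": train_cfg.checkpoint_rule,
        "per_seed": [r.scaled() for r in per_seed],
        "aggregate": aggregate_reports(per_seed),
    }
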