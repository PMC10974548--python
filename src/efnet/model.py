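"""EF-Net: a two-branch convolutional classifier for paired EEG/fNIRS windows.

The EEG branch consumes a 500x30 window (reshaped to 500x30x1): three
Conv(7x1, 32) blocks scanning along time within a channel, MaxPool(7x1),
dropout, batch norm; three Conv(4x4, 64) blocks mixing time and neighboring
channels, MaxPool(4x4), dropout, batch norm; then a flatten (4480 features
under valid padding) and dense layers 256 -> 128.  The fNIRS branch consumes
a 25x72 window: two Conv(4x1, 32) blocks, MaxPool(4x1), dropout, batch norm;
two Conv(2x2, 64) blocks, MaxPool(2x2), dropout, batch norm; flatten and a
single dense layer to 128.  The two 128-dim representations are concatenated
and passed through a head of Dense(256) (+dropout, +L2), Dense(64), and a
2-unit softmax output whose second component is the probability of the
word-generation class.  All hidden activations are ReLU.  Dropout precedes
batch normalization in every block.

With valid padding and the default hyperparameters the full two-branch model
has exactly 1,757,314 trainable parameters (conv kernels and biases, batch
norm scale and shift, dense weights and biases; batch-norm running
statistics are not trainable).

Single-modality variants drop the other branch; the surviving 128-vector
feeds a head of identical layout (its first dense layer then takes 128
inputs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from efnet import nn
from efnet.nn import Sequential, ShapeError

EEG_INPUT_SHAPE = (500, 30, 1)
FNIRS_INPUT_SHAPE = (25, 72, 1)

MODALITIES = ("eeg", "fnirs", "both")


@dataclass
class ConvStack:
    """``repeats`` identical Conv2D blocks: kernel (kh, kw) with ``filters``."""

    kernel: tuple
    filters: int
    repeats: int


@dataclass
class ModelConfig:
    """Architecture hyperparameters; defaults reproduce the published model."""

    modality: str = "both"
    eeg_conv1: ConvStack = field(default_factory=lambda: ConvStack((7, 1), 32, 3))
    eeg_pool1: tuple = (7, 1)
    eeg_conv2: ConvStack = field(default_factory=lambda: ConvStack((4, 4), 64, 3))
    eeg_pool2: tuple = (4, 4)
    eeg_fc: tuple = (256, 128)
    fnirs_conv1: ConvStack = field(default_factory=lambda: ConvStack((4, 1), 32, 2))
    fnirs_pool1: tuple = (4, 1)
    fnirs_conv2: ConvStack = field(default_factory=lambda: ConvStack((2, 2), 64, 2))
    fnirs_pool2: tuple = (2, 2)
    fnirs_fc: tuple = (128,)
    head_fc: tuple = (256, 64)
    dropout: float = 0.5
    l2: float = 0.01
    padding: str = "valid"
    #: output layer width; 2 (softmax pair, WG probability = component 1) is
    #: the configuration whose trainable-parameter total matches the
    #: published 1,757,314; 1 gives a single-sigmoid variant.
    output_units: int = 2

    def validate(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        for stack in (self.eeg_conv1, self.eeg_conv2, self.fnirs_conv1, self.fnirs_conv2):
            if min(stack.kernel) < 1 or stack.filters < 1 or stack.repeats < 1:
                raise ValueError("conv kernel dims, filters and repeats must be >= 1")
        for pool in (self.eeg_pool1, self.eeg_pool2, self.fnirs_pool1, self.fnirs_pool2):
            if min(pool) < 1:
                raise ValueError("pool dims must be >= 1")
        if self.padding not in ("valid", "same"):
            raise ValueError("padding must be 'valid' or 'same'")
        if self.output_units not in (1, 2):
            raise ValueError("output_units must be 1 or 2")


def _branch(cfg: ModelConfig, in_shape, conv1: ConvStack, pool1, conv2: ConvStack,
            pool2, fc_dims, rng, tag) -> Sequential:
    layers = []
    c_in = in_shape[-1]
    for r in range(conv1.repeats):
        layers += [
            nn.Conv2D(conv1.kernel, c_in, conv1.filters, padding=cfg.padding,
                      rng=rng, name=f"{tag}_conv1_{r}"),
            nn.ReLU(),
        ]
        c_in = conv1.filters
    layers += [
        nn.MaxPool2D(pool1, name=f"{tag}_pool1"),
        nn.Dropout(cfg.dropout, name=f"{tag}_drop1"),
        nn.BatchNorm(c_in, name=f"{tag}_bn1"),
    ]
    for r in range(conv2.repeats):
        layers += [
            nn.Conv2D(conv2.kernel, c_in, conv2.filters, padding=cfg.padding,
                      rng=rng, name=f"{tag}_conv2_{r}"),
            nn.ReLU(),
        ]
        c_in = conv2.filters
    layers += [
        nn.MaxPool2D(pool2, name=f"{tag}_pool2"),
        nn.Dropout(cfg.dropout, name=f"{tag}_drop2"),
        nn.BatchNorm(c_in, name=f"{tag}_bn2"),
        nn.Flatten(),
    ]
    seq = Sequential(layers, in_shape)  # traces shapes; raises ShapeError early
    n_in = seq.out_shape[0]
    for d in fc_dims:
        seq.layers.append(nn.Dense(n_in, d, rng=rng, name=f"{tag}_fc{d}"))
        seq.shapes.append((d,))
        seq.layers.append(nn.ReLU())
        seq.shapes.append((d,))
        n_in = d
    return seq


def _head(cfg: ModelConfig, n_in: int, rng) -> Sequential:
    layers = []
    d0, d1 = cfg.head_fc
    layers += [
        nn.Dense(n_in, d0, l2=cfg.l2, rng=rng, name="head_fc0"),
        nn.ReLU(),
        nn.Dropout(cfg.dropout, name="head_drop"),
        nn.Dense(d0, d1, rng=rng, name="head_fc1"),
        nn.ReLU(),
        nn.Dense(d1, cfg.output_units, rng=rng, name="head_out"),
    ]
    return Sequential(layers, (n_in,))


class ModelSpec:
    """A built model: branch/head subgraphs, traced shapes, parameters."""

    def __init__(self, cfg: ModelConfig, init_seed: int = 0):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([int(init_seed), 0xEF]))
        self.eeg_branch = None
        self.fnirs_branch = None
        if cfg.modality in ("eeg", "both"):
            self.eeg_branch = _branch(cfg, EEG_INPUT_SHAPE, cfg.eeg_conv1,
                                      cfg.eeg_pool1, cfg.eeg_conv2, cfg.eeg_pool2,
                                      cfg.eeg_fc, rng, "eeg")
        if cfg.modality in ("fnirs", "both"):
            self.fnirs_branch = _branch(cfg, FNIRS_INPUT_SHAPE, cfg.fnirs_conv1,
                                        cfg.fnirs_pool1, cfg.fnirs_conv2,
                                        cfg.fnirs_pool2, cfg.fnirs_fc, rng, "fnirs")
        widths = []
        if self.eeg_branch is not None:
            widths.append(self.eeg_branch.out_shape[0])
        if self.fnirs_branch is not None:
            widths.append(self.fnirs_branch.out_shape[0])
        self._branch_widths = widths
        self.head = _head(cfg, sum(widths), rng)

    # -- introspection -----------------------------------------------------
    @property
    def eeg_flatten_width(self) -> int | None:
        """Width of the EEG branch's flatten layer (None for fNIRS-only)."""
        if self.eeg_branch is None:
            return None
        for layer, shape in zip(self.eeg_branch.layers, self.eeg_branch.shapes[1:]):
            if isinstance(layer, nn.Flatten):
                return shape[0]
        return None

    def branch_shapes(self, which="eeg"):
        branch = self.eeg_branch if which == "eeg" else self.fnirs_branch
        return list(branch.shapes)

    def subgraphs(self):
        out = []
        if self.eeg_branch is not None:
            out.append(("eeg", self.eeg_branch))
        if self.fnirs_branch is not None:
            out.append(("fnirs", self.fnirs_branch))
        out.append(("head", self.head))
        return out

    def n_params(self) -> int:
        return sum(seq.n_params() for _, seq in self.subgraphs())

    def named_params(self):
        for tag, seq in self.subgraphs():
            yield from seq.named_params(prefix=f"{tag}.")

    def param_pairs(self):
        return [(layer, key) for _, layer, key, _ in self.named_params()]

    def reg_loss(self) -> float:
        return sum(seq.reg_loss() for _, seq in self.subgraphs())

    # -- computation -------------------------------------------------------
    def _branch_inputs(self, xe, xf):
        feats = []
        if self.eeg_branch is not None:
            if xe is None:
                raise ValueError("model needs EEG input for its EEG branch")
            x = np.asarray(xe, dtype=np.float64)
            feats.append(x.reshape(x.shape[0], *EEG_INPUT_SHAPE))
        if self.fnirs_branch is not None:
            if xf is None:
                raise ValueError("model needs fNIRS input for its fNIRS branch")
            x = np.asarray(xf, dtype=np.float64)
            feats.append(x.reshape(x.shape[0], *FNIRS_INPUT_SHAPE))
        return feats

    def logits(self, xe=None, xf=None, train=False, rng=None):
        inputs = self._branch_inputs(xe, xf)
        reps = []
        i = 0
        if self.eeg_branch is not None:
            reps.append(self.eeg_branch.forward(inputs[i], train=train, rng=rng))
            i += 1
        if self.fnirs_branch is not None:
            reps.append(self.fnirs_branch.forward(inputs[i], train=train, rng=rng))
        joint = np.concatenate(reps, axis=1) if len(reps) > 1 else reps[0]
        return self.head.forward(joint, train=train, rng=rng)

    def predict_proba(self, xe=None, xf=None, train=False, rng=None) -> np.ndarray:
        """Probability of the word-generation (positive) class, one per sample."""
        z = self.logits(xe=xe, xf=xf, train=train, rng=rng)
        if self.cfg.output_units == 1:
            return nn.sigmoid(z[:, 0])
        return nn.softmax(z)[:, 1]

    def backward(self, dlogits) -> None:
        djoint = self.head.backward(dlogits)
        if self.eeg_branch is not None and self.fnirs_branch is not None:
            we = self._branch_widths[0]
            self.eeg_branch.backward(djoint[:, :we])
            self.fnirs_branch.backward(djoint[:, we:])
        elif self.eeg_branch is not None:
            self.eeg_branch.backward(djoint)
        else:
            self.fnirs_branch.backward(djoint)

    # -- (de)serialization -------------------------------------------------
    def get_state(self) -> dict:
        state = {name: val.copy() for name, _, _, val in self.named_params()}
        for tag, seq in self.subgraphs():
            for i, layer in enumerate(seq.layers):
                if isinstance(layer, nn.BatchNorm):
                    state[f"{tag}.{i}.{layer.name}.running_mean"] = layer.running_mean.copy()
                    state[f"{tag}.{i}.{layer.name}.running_var"] = layer.running_var.copy()
        return state

    def set_state(self, state: dict) -> None:
        for name, layer, key, _ in self.named_params():
            layer.params[key] = state[name].copy()
        for tag, seq in self.subgraphs():
            for i, layer in enumerate(seq.layers):
                if isinstance(layer, nn.BatchNorm):
                    layer.running_mean = state[f"{tag}.{i}.{layer.name}.running_mean"].copy()
                    layer.running_var = state[f"{tag}.{i}.{layer.name}.running_var"].copy()


def build_efnet(cfg: ModelConfig | None = None, init_seed: int = 0) -> ModelSpec:
    """Construct the model; raises :class:`~efnet.nn.ShapeError` naming the
    offending layer if a kernel or pool does not fit its input."""
    return ModelSpec(cfg or ModelConfig(), init_seed=init_seed)


def count_trainable_params(spec: ModelSpec) -> int:
    """Total element count over trainable tensors (conv kernels and biases,
    batch-norm scale/shift, dense weights and biases); running batch-norm
    statistics are excluded."""
    return spec.n_params()


def forward(spec: ModelSpec, xe=None, xf=None, train_mode: bool = False,
            rng=None) -> np.ndarray:
    """Class-probability forward pass; see :meth:`ModelSpec.predict_proba`."""
    return spec.predict_proba(xe=xe, xf=xf, train=train_mode, rng=rng)


def reduced_config(modality: str = "fnirs", width: int = 8) -> ModelConfig:
    """A narrow variant (same topology, ``width``/2*``width`` filters, small
    dense layers, lighter dropout to match the reduced capacity) for
    CPU-budget experiments and tests."""
    return ModelConfig(
        modality=modality,
        eeg_conv1=ConvStack((7, 1), width, 2),
        eeg_conv2=ConvStack((4, 4), 2 * width, 2),
        eeg_fc=(64, 32),
        fnirs_conv1=ConvStack((4, 1), width, 2),
        fnirs_conv2=ConvStack((2, 2), 2 * width, 2),
        fnirs_fc=(32,),
        head_fc=(64, 16),
        dropout=0.25,
    )
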