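"""Trainable fragment-intensity and retention-time models.

Both models are compact feed-forward networks implemented directly on
numpy with hand-written backpropagation, trained with the masked L1
objective: cells labeled shared or out-of-range contribute nothing to the
loss or its gradient. Optimization is Adam with a linear learning-rate
warmup over the configured number of epochs, then a constant rate.

The intensity model is a per-cleavage-site context network: one shared
network maps the local residue context of each backbone cleavage site,
together with global metadata (precursor charge, NCE, instrument), to the
intensities of all fragment columns at that site — weight sharing across
positions, as in a 1-D convolutional regressor. The RT model maps
amino-acid composition features of the peptidoform to a normalized
retention time in [0, 1].

Training is deterministic for a fixed seed on a single thread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .chem import CANONICAL_AA
from .errors import ConfigurationError, StateError, TrainingError, ValidationError
from .fragmentation import MASK_USE, parse_column
from .io_formats import Peptidoform
from .training_data import IntensityExample, RtExample

_AA_INDEX = {a: i for i, a in enumerate(CANONICAL_AA)}
_PAD = len(CANONICAL_AA)  # padding token for positions outside the peptide

MAX_PEPTIDE_LENGTH = 35
DEFAULT_INSTRUMENT_VOCAB = ("Lumos",)  # unseen instruments map to the surrogate


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass
class IntensityModelConfig:
    """Schedule defaults follow the fine-tuning regime (epoch 20, warmup
    10, lr 1e-4, batch 512); :meth:`desk_scale` returns a configuration
    suited to training the compact network from scratch on small
    simulated sets."""

    hidden_sizes: tuple[int, ...] = (64, 64)
    epochs: int = 20
    warmup_epochs: int = 10
    learning_rate: float = 1e-4
    batch_size: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.warmup_epochs > self.epochs:
            raise ConfigurationError("warmup epochs cannot exceed total epochs")
        if min(self.epochs, self.batch_size) <= 0 or self.learning_rate <= 0:
            raise ConfigurationError("epochs, batch size and learning rate must be positive")

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "IntensityModelConfig":
        return cls(hidden_sizes=(64, 64), epochs=200, warmup_epochs=10,
                   learning_rate=2e-3, batch_size=256, seed=seed)


@dataclass
class RtModelConfig:
    """Schedule defaults follow the fine-tuning regime (epoch 40, warmup
    10, lr 1e-4, batch 1024); see :meth:`desk_scale`."""

    hidden_sizes: tuple[int, ...] = (48, 48)
    epochs: int = 40
    warmup_epochs: int = 10
    learning_rate: float = 1e-4
    batch_size: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if self.warmup_epochs > self.epochs:
            raise ConfigurationError("warmup epochs cannot exceed total epochs")
        if min(self.epochs, self.batch_size) <= 0 or self.learning_rate <= 0:
            raise ConfigurationError("epochs, batch size and learning rate must be positive")

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "RtModelConfig":
        return cls(hidden_sizes=(48, 48), epochs=400, warmup_epochs=10,
                   learning_rate=5e-3, batch_size=128, seed=seed)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def masked_l1_loss(pred: np.ndarray, target: np.ndarray, mask: np.ndarray) -> float:
    """Mean absolute error over cells with ``mask == MASK_USE``; masked
    cells (shared, out-of-range) contribute nothing. Returns 0 when no
    cell is usable."""
    pred, target, mask = np.asarray(pred), np.asarray(target), np.asarray(mask)
    if not pred.shape == target.shape == mask.shape:
        raise ValidationError("pred/target/mask shapes differ")
    use = mask == MASK_USE
    if not use.any():
        return 0.0
    return float(np.abs(pred[use] - target[use]).mean())


# ---------------------------------------------------------------------------
# numpy MLP with Adam
# ---------------------------------------------------------------------------


class _Mlp:
    """Fully connected ReLU network with linear output."""

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 init_weights: list[tuple[np.ndarray, np.ndarray]] | None = None):
        self.sizes = list(sizes)
        if init_weights is not None:
            if len(init_weights) != len(sizes) - 1 or any(
                w.shape != (sizes[i], sizes[i + 1]) or b.shape != (sizes[i + 1],)
                for i, (w, b) in enumerate(init_weights)
            ):
                raise ConfigurationError("init_weights shapes do not match architecture")
            self.params = [(w.copy(), b.copy()) for w, b in init_weights]
        else:
            self.params = []
            for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
                w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
                self.params.append((w, np.zeros(fan_out)))
        self._adam_m = [(np.zeros_like(w), np.zeros_like(b)) for w, b in self.params]
        self._adam_v = [(np.zeros_like(w), np.zeros_like(b)) for w, b in self.params]
        self._adam_t = 0

    def forward(self, x: np.ndarray, keep: bool = False):
        acts = [x]
        h = x
        for i, (w, b) in enumerate(self.params):
            z = h @ w + b
            h = z if i == len(self.params) - 1 else np.maximum(z, 0.0)
            acts.append(h)
        return (h, acts) if keep else h

    def backward(self, acts: list[np.ndarray], grad_out: np.ndarray):
        grads = [None] * len(self.params)
        g = grad_out
        for i in range(len(self.params) - 1, -1, -1):
            h_in = acts[i]
            if i < len(self.params) - 1:
                g = g * (acts[i + 1] > 0)
            grads[i] = (h_in.T @ g, g.sum(axis=0))
            g = g @ self.params[i][0].T
        return grads

    def adam_step(self, grads, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for i, ((w, b), (gw, gb)) in enumerate(zip(self.params, grads)):
            mw, mb = self._adam_m[i]
            vw, vb = self._adam_v[i]
            mw[:] = beta1 * mw + (1 - beta1) * gw
            mb[:] = beta1 * mb + (1 - beta1) * gb
            vw[:] = beta2 * vw + (1 - beta2) * gw**2
            vb[:] = beta2 * vb + (1 - beta2) * gb**2
            corr1, corr2 = 1 - beta1**t, 1 - beta2**t
            w -= lr * (mw / corr1) / (np.sqrt(vw / corr2) + eps)
            b -= lr * (mb / corr1) / (np.sqrt(vb / corr2) + eps)


def _warmup_lr(epoch: int, config) -> float:
    if epoch < config.warmup_epochs:
        return config.learning_rate * (epoch + 1) / config.warmup_epochs
    return config.learning_rate


# ---------------------------------------------------------------------------
# feature encoders
# ---------------------------------------------------------------------------

_CONTEXT_OFFSETS = (-1, 0, 1, 2)  # 0-based residue indices around cleavage site r: r-1..r+2


def encode_intensity_rows(
    pf: Peptidoform, charge: int, nce: float, instrument: str,
    instrument_vocab: tuple[str, ...],
) -> np.ndarray:
    """Per-cleavage-site feature rows: local residue context one-hots and
    modification flags, relative position, length, charge, NCE, and the
    instrument category (unseen instruments fall back to the first vocab
    entry, the surrogate category)."""
    L = len(pf)
    if L > MAX_PEPTIDE_LENGTH:
        raise ValidationError(f"peptide length {L} exceeds cap {MAX_PEPTIDE_LENGTH}")
    seq_idx = np.array([_AA_INDEX[a] for a in pf.sequence])
    mod_delta = np.zeros(L)
    for pos, delta, _ in pf.mods:
        mod_delta[max(pos - 1, 0)] += delta

    n_ctx = len(_CONTEXT_OFFSETS)
    d_onehot = (_PAD + 1) * n_ctx
    inst = instrument if instrument in instrument_vocab else instrument_vocab[0]
    inst_onehot = np.array([1.0 if inst == v else 0.0 for v in instrument_vocab])

    rows = np.zeros((L - 1, d_onehot + n_ctx + 9 + len(instrument_vocab)))
    for r in range(L - 1):
        f = rows[r]
        for j, off in enumerate(_CONTEXT_OFFSETS):
            p = r + off
            tok = seq_idx[p] if 0 <= p < L else _PAD
            f[j * (_PAD + 1) + tok] = 1.0
            if 0 <= p < L:
                f[d_onehot + j] = mod_delta[p] / 100.0
        base = d_onehot + n_ctx
        f[base + 0] = (r + 1) / L  # relative cleavage position
        f[base + 1] = L / MAX_PEPTIDE_LENGTH
        f[base + 2] = charge / 4.0
        f[base + 3 : base + 7] = [1.0 if charge == z else 0.0 for z in (1, 2, 3, 4)]
        f[base + 7] = nce / 40.0
        f[base + 8] = (nce / 40.0) ** 2
        f[base + 9 :] = inst_onehot
    return rows


def encode_rt_features(pf: Peptidoform) -> np.ndarray:
    """Composition features: residue fractions, length, modification load."""
    L = len(pf)
    comp = np.zeros(len(CANONICAL_AA))
    for a in pf.sequence:
        comp[_AA_INDEX[a]] += 1.0
    comp /= L
    n_mods = len(pf.mods)
    n_phospho = sum(1 for _, _, name in pf.mods if name == "Phospho")
    return np.concatenate([comp, [L / MAX_PEPTIDE_LENGTH, n_mods / L, n_phospho / L]])


# ---------------------------------------------------------------------------
# trained model container
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    kind: str  # 'intensity' | 'rt'
    net: _Mlp | None
    config: IntensityModelConfig | RtModelConfig
    history: list[float] = field(default_factory=list)
    layout: tuple[str, ...] = ()
    instrument_vocab: tuple[str, ...] = DEFAULT_INSTRUMENT_VOCAB

    def require_trained(self) -> _Mlp:
        if self.net is None or not self.history:
            raise StateError(f"{self.kind} model has not been trained")
        return self.net


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _train_loop(net: _Mlp, X, Y, M, config, rng, kind: str) -> list[float]:
    """Minibatch Adam on the masked L1 objective; returns per-epoch loss."""
    n = X.shape[0]
    history = []
    for epoch in range(config.epochs):
        lr = _warmup_lr(epoch, config)
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            pred, acts = net.forward(X[idx], keep=True)
            use = M[idx]
            n_use = use.sum()
            if n_use == 0:
                continue
            grad = np.sign(pred - Y[idx]) * use / n_use
            net.adam_step(net.backward(acts, grad), lr)
        pred = net.forward(X)
        use = M.astype(bool)
        loss = float(np.abs(pred[use] - Y[use]).mean()) if use.any() else 0.0
        if not np.isfinite(loss):
            raise TrainingError(f"{kind} training loss became non-finite at epoch {epoch}")
        history.append(loss)
    return history


def train_intensity_model(
    examples: list[IntensityExample],
    config: IntensityModelConfig | None = None,
    init_weights=None,
) -> TrainedModel:
    """Train the fragment-intensity network with the masked L1 loss."""
    if not examples:
        raise ConfigurationError("no intensity training examples")
    config = config or IntensityModelConfig()
    layout = examples[0].layout
    vocab = tuple(dict.fromkeys(
        list(DEFAULT_INSTRUMENT_VOCAB) + [ex.instrument for ex in examples]
    ))
    rng = np.random.default_rng(config.seed)

    rows, targets, masks = [], [], []
    for ex in examples:
        if ex.layout != layout:
            raise ValidationError("mixed fragment layouts in one training set")
        rows.append(encode_intensity_rows(ex.peptidoform, ex.charge, ex.nce,
                                          ex.instrument, vocab))
        targets.append(ex.target)
        masks.append(ex.mask == MASK_USE)
    X = np.vstack(rows)
    Y = np.vstack(targets)
    M = np.vstack(masks).astype(float)

    sizes = [X.shape[1], *config.hidden_sizes, len(layout)]
    net = _Mlp(sizes, rng, init_weights)
    history = _train_loop(net, X, Y, M, config, rng, "intensity")
    return TrainedModel("intensity", net, config, history, layout, vocab)


def train_rt_model(
    rt_examples: list[RtExample],
    config: RtModelConfig | None = None,
    init_weights=None,
) -> TrainedModel:
    """Train the RT network with L1 loss on normalized retention times."""
    if not rt_examples:
        raise ConfigurationError("no RT training examples")
    config = config or RtModelConfig()
    rng = np.random.default_rng(config.seed)
    X = np.vstack([encode_rt_features(ex.peptidoform) for ex in rt_examples])
    Y = np.array([[ex.rt_normalized] for ex in rt_examples])
    M = np.ones_like(Y)
    sizes = [X.shape[1], *config.hidden_sizes, 1]
    net = _Mlp(sizes, rng, init_weights)
    history = _train_loop(net, X, Y, M, config, rng, "rt")
    return TrainedModel("rt", net, config, history)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def predict_intensity(
    model: TrainedModel, pf: Peptidoform, charge: int, nce: float, instrument: str
) -> np.ndarray:
    """Full-layout intensity matrix: negatives clipped to 0, inapplicable
    cells zeroed, renormalized to max 1. No peak masking at prediction."""
    net = model.require_trained()
    if model.kind != "intensity":
        raise StateError("predict_intensity requires an intensity model")
    X = encode_intensity_rows(pf, charge, nce, instrument, model.instrument_vocab)
    pred = np.maximum(net.forward(X), 0.0)
    for col, label in enumerate(model.layout):
        _, frag_charge, loss = parse_column(label)
        if charge == 1 and frag_charge > 1:
            pred[:, col] = 0.0
        if loss and not any(name == "Phospho" for _, _, name in pf.mods):
            pred[:, col] = 0.0
    peak = pred.max()
    if peak > 0:
        pred /= peak
    return pred


def predict_rt(model: TrainedModel, peptidoforms: list[Peptidoform]) -> np.ndarray:
    """Normalized RTs, clamped to be non-negative."""
    net = model.require_trained()
    if model.kind != "rt":
        raise StateError("predict_rt requires an RT model")
    X = np.vstack([encode_rt_features(pf) for pf in peptidoforms])
    return np.maximum(net.forward(X)[:, 0], 0.0)


# ---------------------------------------------------------------------------
# persistence (single JSON file with config embedded)
# ---------------------------------------------------------------------------


def save_model(model: TrainedModel, path) -> None:
    net = model.require_trained()
    payload = {
        "kind": model.kind,
        "config": asdict(model.config),
        "history": model.history,
        "layout": list(model.layout),
        "instrument_vocab": list(model.instrument_vocab),
        "sizes": net.sizes,
        "weights": [[w.tolist(), b.tolist()] for w, b in net.params],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path) -> TrainedModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    cfg_cls = IntensityModelConfig if payload["kind"] == "intensity" else RtModelConfig
    cfg_kwargs = payload["config"]
    cfg_kwargs["hidden_sizes"] = tuple(cfg_kwargs["hidden_sizes"])
    config = cfg_cls(**cfg_kwargs)
    weights = [
        (np.asarray(w, dtype=float), np.asarray(b, dtype=float))
        for w, b in payload["weights"]
    ]
    net = _Mlp(payload["sizes"], np.random.default_rng(0), init_weights=weights)
    return TrainedModel(
        kind=payload["kind"],
        net=net,
        config=config,
        history=list(payload["history"]),
        layout=tuple(payload["layout"]),
        instrument_vocab=tuple(payload["instrument_vocab"]),
    )
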