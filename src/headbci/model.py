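"""The per-participant three-class rotation classifier.

A dense multilayer perceptron maps one flattened 250-ms, 32-channel EEG window
(1024 features) to three probabilities (none, left, right). Architecture and
training follow the target protocol: hidden layers of 512, 256 and 6 ReLU units
with L2 regularisation, 10% dropout on the first two hidden layers, three
independent sigmoid output units, Adam (lr 0.001), 150 epochs, batches of 150.
The loss is categorical cross-entropy with the sigmoid activations normalised
inside the loss; inference reports the raw sigmoid activations, which need not
sum to one.

Batch "normalisation" of the inputs is per-feature standardisation using
training-set statistics, applied identically at training and inference so a
single streaming window is well-defined.

The public surface is statsmodels-shaped: :class:`HeadRotationClassifier` is
built from data and ``fit()`` returns a :class:`RotationFit` results object
carrying the weights, the training history, evaluation methods and
``summary()``.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import special, stats

from .epochs import CLASS_NAMES, EpochDataset
from .utils import substream

__all__ = ["ModelConfig", "HeadRotationClassifier", "RotationFit", "chance_threshold"]

N_CLASSES = 3


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimisation hyperparameters."""

    input_dim: int = 1024
    hidden: tuple[int, ...] = (512, 256, 6)
    dropout: float = 0.10          # on the first two hidden layers
    l2_penalty: float = 1e-4       # coefficient of sum of squared weights
    learning_rate: float = 0.001
    epochs: int = 150
    batch_size: int = 150
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden) or self.input_dim <= 0:
            raise ValueError("layer sizes must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @property
    def layer_dims(self) -> tuple[int, ...]:
        return (self.input_dim, *self.hidden, N_CLASSES)

    @property
    def n_parameters(self) -> int:
        dims = self.layer_dims
        weights = sum(a * b for a, b in zip(dims, dims[1:]))
        biases = sum(dims[1:])
        return weights + biases


def _init_params(cfg: ModelConfig, rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    """He-initialised weights, zero biases (float32 for BLAS speed)."""
    params = []
    dims = cfg.layer_dims
    for a, b in zip(dims, dims[1:]):
        w = rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b)).astype(np.float32)
        params.append((w, np.zeros(b, dtype=np.float32)))
    return params


def _forward(params, x, cfg: ModelConfig, rng: Optional[np.random.Generator] = None):
    """Forward pass; with ``rng`` set, applies inverted dropout (training mode).

    Returns (sigmoid activations, cache for backprop).
    """
    cache = []
    h = x
    for li, (w, b) in enumerate(params[:-1]):
        z = h @ w + b
        a = np.maximum(z, 0.0)
        mask = None
        if rng is not None and cfg.dropout > 0 and li < 2:
            mask = (rng.random(a.shape) >= cfg.dropout).astype(np.float32) / (1.0 - cfg.dropout)
            a = a * mask
        cache.append((h, z, mask))
        h = a
    w, b = params[-1]
    z_out = h @ w + b
    cache.append((h, z_out, None))
    a_out = special.expit(z_out)
    return a_out, cache


def _loss_and_output_grad(a_out: np.ndarray, y_onehot: np.ndarray):
    """Categorical cross-entropy on sigmoids normalised inside the loss.

    p_k = a_k / sum(a); L = -mean over samples of sum_k y_k log p_k.
    Returns (loss, dL/dz at the output, where a = sigmoid(z)).
    """
    eps = 1e-9
    a = np.clip(a_out, eps, 1.0 - eps)
    s = a.sum(axis=1, keepdims=True)
    p = a / s
    n = a.shape[0]
    loss = float(-np.sum(y_onehot * np.log(p)) / n)
    dl_da = (-y_onehot / a + 1.0 / s) / n
    dl_dz = dl_da * a * (1.0 - a)
    return loss, dl_dz.astype(np.float32)


def _backward(params, cache, dl_dz_out, cfg: ModelConfig):
    grads = [None] * len(params)
    delta = dl_dz_out
    for li in range(len(params) - 1, -1, -1):
        h_in, _z, _mask = cache[li]
        w, _b = params[li]
        gw = h_in.T @ delta + 2.0 * cfg.l2_penalty * w
        gb = delta.sum(axis=0)
        grads[li] = (gw, gb)
        if li > 0:
            delta = delta @ w.T
            prev_mask = cache[li - 1][2]
            if prev_mask is not None:
                delta = delta * prev_mask
            delta = delta * (cache[li - 1][1] > 0)
    return grads


@dataclass
class _Normalizer:
    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "_Normalizer":
        mean = x.mean(axis=0)
        scale = x.std(axis=0)
        scale[scale < 1e-8] = 1.0
        return cls(mean.astype(np.float32), scale.astype(np.float32))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float32) - self.mean) / self.scale


DataLike = Union[EpochDataset, tuple[np.ndarray, np.ndarray]]


def _as_xy(data: DataLike) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, EpochDataset):
        return data.features, data.labels.astype(int)
    x, y = data
    return np.asarray(x), np.asarray(y, dtype=int)


class HeadRotationClassifier:
    """Model object: built from a balanced training set and a validation set.

    Parameters
    ----------
    train, val : EpochDataset or (features, labels)
        Labels use the fixed convention 0=none, 1=left, 2=right. Training
        data should be class-balanced; validation must be disjoint from it.
    config : ModelConfig
    """

    def __init__(self, train: DataLike, val: Optional[DataLike] = None, config: ModelConfig = ModelConfig()):
        self.x_train, self.y_train = _as_xy(train)
        if self.x_train.shape[1] != config.input_dim:
            raise ValueError(
                f"feature length {self.x_train.shape[1]} does not match input_dim {config.input_dim}"
            )
        if val is not None:
            self.x_val, self.y_val = _as_xy(val)
            if self.x_val.shape[1] != config.input_dim:
                raise ValueError("validation feature length mismatch")
        else:
            self.x_val = self.y_val = None
        self.config = config

    def fit(self, seed: int = 0) -> "RotationFit":
        cfg = self.config
        rng = substream(seed, "model-init")
        drop_rng = substream(seed, "dropout")
        shuffle_rng = substream(seed, "shuffle")
        params = _init_params(cfg, rng)

        norm = _Normalizer.fit(self.x_train)
        x = norm(self.x_train)
        y = np.eye(N_CLASSES, dtype=np.float32)[self.y_train]
        xv = norm(self.x_val) if self.x_val is not None else None
        yv = np.eye(N_CLASSES, dtype=np.float32)[self.y_val] if self.y_val is not None else None

        m = [(np.zeros_like(w), np.zeros_like(b)) for w, b in params]
        v = [(np.zeros_like(w), np.zeros_like(b)) for w, b in params]
        step = 0
        history = {"train_loss": [], "val_loss": []}
        n = x.shape[0]
        for _epoch in range(cfg.epochs):
            order = shuffle_rng.permutation(n)
            epoch_loss = 0.0
            for lo in range(0, n, cfg.batch_size):
                idx = order[lo : lo + cfg.batch_size]
                xb, yb = x[idx], y[idx]
                a_out, cache = _forward(params, xb, cfg, rng=drop_rng)
                loss, dl_dz = _loss_and_output_grad(a_out, yb)
                epoch_loss += loss * len(idx)
                grads = _backward(params, cache, dl_dz, cfg)
                step += 1
                b1c = 1.0 - cfg.adam_beta1**step
                b2c = 1.0 - cfg.adam_beta2**step
                for li, ((w, b), (gw, gb)) in enumerate(zip(params, grads)):
                    mw, mb = m[li]
                    vw, vb = v[li]
                    mw[:] = cfg.adam_beta1 * mw + (1 - cfg.adam_beta1) * gw
                    mb[:] = cfg.adam_beta1 * mb + (1 - cfg.adam_beta1) * gb
                    vw[:] = cfg.adam_beta2 * vw + (1 - cfg.adam_beta2) * gw**2
                    vb[:] = cfg.adam_beta2 * vb + (1 - cfg.adam_beta2) * gb**2
                    w -= cfg.learning_rate * (mw / b1c) / (np.sqrt(vw / b2c) + cfg.adam_eps)
                    b -= cfg.learning_rate * (mb / b1c) / (np.sqrt(vb / b2c) + cfg.adam_eps)
            history["train_loss"].append(epoch_loss / n)
            if xv is not None and len(xv):
                av, _ = _forward(params, xv, cfg, rng=None)
                vloss, _ = _loss_and_output_grad(av, yv)
                history["val_loss"].append(vloss)
        return RotationFit(model=self, params=params, normalizer=norm, history=history, seed=seed)

    def fit_repetitions(self, n_repetitions: int = 3, seed: int = 0) -> list["RotationFit"]:
        """The repetition protocol: refit with fresh seeds."""
        return [self.fit(seed=seed + rep) for rep in range(n_repetitions)]


@dataclass
class RotationFit:
    """Fitted classifier: weights, normalisation statistics, history, metrics."""

    model: HeadRotationClassifier
    params: list
    normalizer: _Normalizer
    history: dict
    seed: int
    _val_accuracy: Optional[float] = field(default=None, repr=False)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Raw sigmoid activations (none, left, right); each in [0,1], need not sum to 1."""
        features = np.asarray(features)
        squeeze = features.ndim == 1
        if squeeze:
            features = features[None, :]
        if features.shape[1] != self.model.config.input_dim:
            raise ValueError(
                f"feature length {features.shape[1]} != input_dim {self.model.config.input_dim}"
            )
        a, _ = _forward(self.params, self.normalizer(features), self.model.config, rng=None)
        return a[0] if squeeze else a

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.argmax(np.atleast_2d(self.predict_proba(features)), axis=1)

    def evaluate(self, test: DataLike) -> "Evaluation":
        x, y = _as_xy(test)
        if len(y) == 0:
            raise ValueError("empty test set")
        pred = self.predict(x)
        confusion = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
        np.add.at(confusion, (y, pred), 1)
        return Evaluation(accuracy=float(np.mean(pred == y)), confusion=confusion, n=len(y))

    @property
    def val_accuracy(self) -> Optional[float]:
        if self._val_accuracy is None and self.model.x_val is not None and len(self.model.x_val):
            self._val_accuracy = self.evaluate((self.model.x_val, self.model.y_val)).accuracy
        return self._val_accuracy

    @property
    def n_parameters(self) -> int:
        return self.model.config.n_parameters

    def summary(self) -> str:
        cfg = self.model.config
        buf = io.StringIO()
        w = buf.write
        w("Head-rotation classifier fit\n")
        w("=" * 46 + "\n")
        w(f"architecture        {cfg.input_dim}-" + "-".join(map(str, cfg.hidden)) + f"-{N_CLASSES}\n")
        w(f"parameters          {cfg.n_parameters:,}\n")
        w(f"training epochs     {cfg.epochs}   batch {cfg.batch_size}   lr {cfg.learning_rate}\n")
        w(f"dropout / L2        {cfg.dropout} / {cfg.l2_penalty}\n")
        w(f"seed                {self.seed}\n")
        w(f"train samples       {self.model.x_train.shape[0]}\n")
        w(f"final train loss    {self.history['train_loss'][-1]:.4f}\n")
        if self.history["val_loss"]:
            w(f"final val loss      {self.history['val_loss'][-1]:.4f}\n")
        if self.val_accuracy is not None:
            w(f"validation accuracy {self.val_accuracy:.3f}\n")
        return buf.getvalue()


def save_fit(fit: RotationFit, path) -> None:
    """Single-file checkpoint: weights, config, normalisation stats, seed."""
    import json

    import h5py

    with h5py.File(path, "w") as f:
        for li, (w, b) in enumerate(fit.params):
            f.create_dataset(f"w{li}", data=w)
            f.create_dataset(f"b{li}", data=b)
        f.create_dataset("norm_mean", data=fit.normalizer.mean)
        f.create_dataset("norm_scale", data=fit.normalizer.scale)
        f.attrs["n_layers"] = len(fit.params)
        f.attrs["seed"] = fit.seed
        f.attrs["config"] = json.dumps(dataclasses.asdict(fit.model.config))
        f.attrs["history"] = json.dumps(fit.history)


def load_fit(path) -> RotationFit:
    """Restore a checkpoint for inference (no training data attached)."""
    import json

    import h5py

    with h5py.File(path, "r") as f:
        cfg_d = json.loads(f.attrs["config"])
        cfg_d["hidden"] = tuple(cfg_d["hidden"])
        cfg = ModelConfig(**cfg_d)
        params = [(f[f"w{li}"][()], f[f"b{li}"][()]) for li in range(int(f.attrs["n_layers"]))]
        norm = _Normalizer(f["norm_mean"][()], f["norm_scale"][()])
        history = json.loads(f.attrs["history"])
        seed = int(f.attrs["seed"])
    dummy = object.__new__(HeadRotationClassifier)
    dummy.x_train = np.zeros((0, cfg.input_dim), dtype=np.float32)
    dummy.y_train = np.zeros(0, dtype=int)
    dummy.x_val = dummy.y_val = None
    dummy.config = cfg
    return RotationFit(model=dummy, params=params, normalizer=norm, history=history, seed=seed)


@dataclass
class Evaluation:
    """Test-set metrics: overall accuracy and the 3x3 confusion matrix.

    Confusion rows are true classes, columns predicted, in (none, left, right)
    order; row sums equal the per-class test counts.
    """

    accuracy: float
    confusion: np.ndarray
    n: int

    def per_class_accuracy(self) -> dict[str, float]:
        rows = self.confusion.sum(axis=1)
        return {
            name: float(self.confusion[i, i] / rows[i]) if rows[i] else float("nan")
            for i, name in enumerate(CLASS_NAMES)
        }


def chance_threshold(n_trials: int, n_classes: int = 3, alpha: float = 0.05) -> float:
    """Upper bound of chance-level accuracy for a balanced test set.

    The smallest k with BinomialCDF(k; n_trials, 1/n_classes) >= 1 - alpha,
    returned as a fraction k/n_trials. A classifier guessing at random exceeds
    this accuracy with probability at most alpha.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    k = int(stats.binom.ppf(1.0 - alpha, n_trials, 1.0 / n_classes))
    # ppf returns the smallest k with cdf >= q; guard against edge rounding.
    while stats.binom.cdf(k, n_trials, 1.0 / n_classes) < 1.0 - alpha:
        k += 1
    while k > 0 and stats.binom.cdf(k - 1, n_trials, 1.0 / n_classes) >= 1.0 - alpha:
        k -= 1
    return k / n_trials
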