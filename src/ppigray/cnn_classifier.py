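"""The convolutional classifier and its training machinery.

The network consumes a 36 x 32 grayscale pair map and emits interaction /
non-interaction probabilities.  Architecture: three 6 x 6 stride-1
convolutions (all with the same channel count, each followed by ReLU) with
two overlapping 3 x 3 stride-1 max-pools interleaved, then a single fully
connected layer and softmax.  The spatial chain on a 36 x 32 input is
31x27 -> 26x22 -> 24x20 -> 19x15 -> 17x13, so the flattened vector has
length channels * 17 * 13 (14,144 at 64 channels).

Layers, backpropagation and the Adam optimizer are implemented directly on
NumPy arrays; convolutions use an im2col formulation, and the overlapping
max-pool scatters gradients back to per-window argmax positions.  Training
uses mini-batch softmax cross-entropy (mean per batch), early stopping on
validation loss with best-checkpoint restore, and per-run seeds for weight
initialization and batch shuffling.

Hyperparameter search covers the learning rate (log-uniform in
[1e-5, 1e-3]) and the shared channel count ({2, 4, ..., 64}); a seeded
random-search strategy proposes trials and the configuration with the best
validation ROC-AUC wins (first trial wins ties).  The production predictor
is an ensemble of five models trained on balanced undersampled training
sets; its probability is the arithmetic mean of the members'.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.metrics import roc_auc_score

CHANNEL_CHOICES = (2, 4, 8, 16, 32, 64)
LR_BOUNDS = (1e-5, 1e-3)

#: Class index of "interaction" in the 2-vector output.
INTERACTION_INDEX = 0


@dataclass(frozen=True)
class ModelConfig:
    channels: int = 64
    conv_kernel: int = 6
    pool_kernel: int = 3
    n_classes: int = 2

    def spatial_chain(self, height: int = 36, width: int = 32) -> list[tuple[int, int]]:
        """Spatial sizes after each conv/pool stage (stride 1, no padding)."""
        c, p = self.conv_kernel - 1, self.pool_kernel - 1
        chain = []
        h, w = height - c, width - c
        chain.append((h, w))          # conv1
        h, w = h - c, w - c
        chain.append((h, w))          # conv2
        h, w = h - p, w - p
        chain.append((h, w))          # pool1
        h, w = h - c, w - c
        chain.append((h, w))          # conv3
        h, w = h - p, w - p
        chain.append((h, w))          # pool2
        return chain

    def flat_dim(self, height: int = 36, width: int = 32) -> int:
        h, w = self.spatial_chain(height, width)[-1]
        return self.channels * h * w


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.max_epochs <= 0:
            raise ValueError("learning rate, batch size and epochs must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("early-stopping patience must be below max epochs")


# ---------------------------------------------------------------------------
# Layers


class _Conv2D:
    """6x6 stride-1 valid convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        fan_in = c_in * k * k
        bound = 1.0 / math.sqrt(fan_in)
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self.W = rng.uniform(-bound, bound, size=(fan_in, c_out)).astype(dtype)
        self.b = rng.uniform(-bound, bound, size=c_out).astype(dtype)
        self._cols = None
        self._in_shape = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, H, W = x.shape
        k = self.k
        win = sliding_window_view(x, (k, k), axis=(2, 3))  # B,C,H',W',k,k
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, H - k + 1, W - k + 1, C * k * k)
        out = cols @ self.W + self.b
        if train:
            self._cols = cols
            self._in_shape = x.shape
        return out.transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, Co, Hp, Wp = dy.shape
        k = self.k
        dy_cols = dy.transpose(0, 2, 3, 1)  # B,H',W',Co
        flat_cols = self._cols.reshape(-1, self._cols.shape[-1])
        flat_dy = dy_cols.reshape(-1, Co)
        self.dW = flat_cols.T @ flat_dy
        self.db = flat_dy.sum(axis=0)
        dcols = (flat_dy @ self.W.T).reshape(B, Hp, Wp, self.c_in, k, k)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dc = dcols.transpose(0, 3, 1, 2, 4, 5)  # B,Cin,H',W',k,k
        for di in range(k):
            for dj in range(k):
                dx[:, :, di:di + Hp, dj:dj + Wp] += dc[:, :, :, :, di, dj]
        self._cols = None
        return dx

    def params(self):
        return [("W", self), ("b", self)]


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class _MaxPool:
    """3x3 stride-1 overlapping max-pool with argmax gradient routing."""

    def __init__(self, k: int):
        self.k = k

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k = self.k
        win = sliding_window_view(x, (k, k), axis=(2, 3))  # B,C,H',W',k,k
        flat = win.reshape(*win.shape[:4], k * k)
        out = flat.max(axis=-1)
        if train:
            self._argmax = flat.argmax(axis=-1)
            self._in_shape = x.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k = self.k
        B, C, Hp, Wp = dy.shape
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        for off in range(k * k):
            mask = self._argmax == off
            if not mask.any():
                continue
            di, dj = divmod(off, k)
            dx[:, :, di:di + Hp, dj:dj + Wp] += dy * mask
        return dx


class _Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        bound = 1.0 / math.sqrt(d_in)
        self.W = rng.uniform(-bound, bound, size=(d_in, d_out)).astype(dtype)
        self.b = rng.uniform(-bound, bound, size=d_out).astype(dtype)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Model


class GrayMapCNN:
    """The map classifier: conv-ReLU, conv-ReLU, pool, conv-ReLU, pool,
    flatten, fully connected, softmax."""

    def __init__(self, config: ModelConfig, seed: int = 0,
                 input_shape: tuple[int, int] = (36, 32), dtype=np.float32):
        import warnings as _warnings
        if config.channels not in CHANNEL_CHOICES:
            _warnings.warn(
                f"channel count {config.channels} outside the usual search "
                f"set {CHANNEL_CHOICES}", stacklevel=2)
        self.config = config
        self.seed = seed
        self.input_shape = input_shape
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        c, k, pk = config.channels, config.conv_kernel, config.pool_kernel
        self.conv1 = _Conv2D(1, c, k, rng, dtype)
        self.conv2 = _Conv2D(c, c, k, rng, dtype)
        self.conv3 = _Conv2D(c, c, k, rng, dtype)
        self.relu1, self.relu2, self.relu3 = _ReLU(), _ReLU(), _ReLU()
        self.pool1, self.pool2 = _MaxPool(pk), _MaxPool(pk)
        self.fc = _Linear(config.flat_dim(*input_shape), config.n_classes, rng,
                          dtype)
        self._layers = [self.conv1, self.relu1, self.conv2, self.relu2,
                        self.pool1, self.conv3, self.relu3, self.pool2]
        self._param_layers = [self.conv1, self.conv2, self.conv3, self.fc]

    # -- forward / backward

    def forward(self, maps: np.ndarray, train: bool = False,
                return_intermediates: bool = False):
        """Logits for a batch of maps (B, 36, 32).  With
        ``return_intermediates``, also the list of post-stage tensors."""
        x = np.asarray(maps, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"expected input maps of shape {self.input_shape}, got {x.shape[1:]}")
        x = x[:, None]  # B,1,H,W
        inter = []
        for layer in self._layers:
            x = layer.forward(x, train)
            if isinstance(layer, (_Conv2D, _MaxPool)):
                inter.append(x)
        self._flat_shape = x.shape
        flat = x.reshape(x.shape[0], -1)
        logits = self.fc.forward(flat, train)
        if return_intermediates:
            return logits, inter
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        dflat = self.fc.backward(dlogits)
        dx = dflat.reshape(self._flat_shape)
        for layer in reversed(self._layers):
            dx = layer.backward(dx)

    def predict_proba(self, maps: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """P(interaction) per sample."""
        maps = np.asarray(maps, dtype=float)
        if maps.ndim == 2:
            maps = maps[None]
        probs = []
        for start in range(0, maps.shape[0], batch_size):
            logits = self.forward(maps[start:start + batch_size])
            probs.append(_softmax(logits)[:, INTERACTION_INDEX])
        return np.concatenate(probs)

    # -- parameter access

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self._param_layers:
            out += [layer.W, layer.b]
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self._param_layers:
            out += [layer.dW, layer.db]
        return out

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        idx = 0
        for layer in self._param_layers:
            layer.W = np.array(state[idx]); idx += 1
            layer.b = np.array(state[idx]); idx += 1


def build_model(config: ModelConfig, seed: int = 0,
                dtype=np.float32) -> GrayMapCNN:
    return GrayMapCNN(config, seed=seed, dtype=dtype)


# ---------------------------------------------------------------------------
# Loss and optimizer


def cross_entropy(logits: np.ndarray, classes: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy over the batch and its logit gradient."""
    probs = _softmax(np.asarray(logits, dtype=np.float64))
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), classes] + eps).mean()
    grad = probs.copy()
    grad[np.arange(n), classes] -= 1.0
    return float(loss), (grad / n).astype(logits.dtype)


class Adam:
    """Adaptive moment estimation with framework-default constants."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Training


def labels_to_classes(labels: np.ndarray) -> np.ndarray:
    """Map pair labels (1 = interacting) to class indices (0 = interaction)."""
    labels = np.asarray(labels)
    return np.where(labels == 1, INTERACTION_INDEX, 1 - INTERACTION_INDEX)


def evaluate_loss(model: GrayMapCNN, maps: np.ndarray, labels: np.ndarray,
                  batch_size: int = 256) -> float:
    classes = labels_to_classes(labels)
    total, n = 0.0, maps.shape[0]
    for start in range(0, n, batch_size):
        logits = model.forward(maps[start:start + batch_size])
        loss, _ = cross_entropy(logits, classes[start:start + batch_size])
        total += loss * logits.shape[0]
    return total / n


def train(model: GrayMapCNN, train_maps: np.ndarray, train_labels: np.ndarray,
          val_maps: np.ndarray, val_labels: np.ndarray,
          tc: TrainConfig) -> list[dict]:
    """Mini-batch Adam training with early stopping on validation loss.

    Stops when the validation loss has not strictly improved for
    ``tc.patience`` consecutive epochs, then restores the best-validation
    checkpoint.  Returns the per-epoch history
    (epoch, train_loss, val_loss).
    """
    if train_maps.shape[0] == 0 or val_maps.shape[0] == 0:
        raise ValueError("training and validation sets must be non-empty")
    classes = labels_to_classes(train_labels)
    rng = np.random.default_rng(tc.seed)
    optimizer = Adam(model.parameters(), lr=tc.learning_rate)
    best_loss = np.inf
    best_state = model.get_state()
    stall = 0
    history: list[dict] = []
    n = train_maps.shape[0]
    for epoch in range(1, tc.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for start in range(0, n, tc.batch_size):
            idx = order[start:start + tc.batch_size]
            logits = model.forward(train_maps[idx], train=True)
            loss, dlogits = cross_entropy(logits, classes[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={tc.learning_rate})")
            model.backward(dlogits)
            optimizer.step(model.parameters(), model.gradients())
            epoch_loss += loss * idx.size
            seen += idx.size
        val_loss = evaluate_loss(model, val_maps, val_labels)
        history.append({"epoch": epoch, "train_loss": epoch_loss / seen,
                        "val_loss": val_loss})
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.get_state()
            stall = 0
        else:
            stall += 1
            if stall >= tc.patience:
                break
    model.set_state(best_state)
    return history


def write_history(path, history: list[dict]) -> None:
    with open(path, "w") as fh:
        fh.write("epoch\ttrain_loss\tval_loss\n")
        for row in history:
            fh.write(f"{row['epoch']}\t{row['train_loss']:.6f}\t{row['val_loss']:.6f}\n")


# ---------------------------------------------------------------------------
# Hyperparameter search


@dataclass
class Trial:
    learning_rate: float
    channels: int
    auc: float = np.nan


def random_search_strategy(n_trials: int, seed: int,
                           lr_bounds: tuple[float, float] = LR_BOUNDS,
                           channel_choices: tuple[int, ...] = CHANNEL_CHOICES
                           ) -> list[Trial]:
    """Seeded random proposals: log-uniform learning rate, uniform channels."""
    rng = np.random.default_rng(seed)
    trials = []
    for _ in range(n_trials):
        lr = float(np.exp(rng.uniform(np.log(lr_bounds[0]), np.log(lr_bounds[1]))))
        ch = int(rng.choice(channel_choices))
        trials.append(Trial(learning_rate=lr, channels=ch))
    return trials


def select_best(trials: list[Trial]) -> Trial:
    """Argmax validation AUC; the earliest trial wins ties."""
    best = trials[0]
    for t in trials[1:]:
        if t.auc > best.auc:
            best = t
    return best


def tune(train_maps: np.ndarray, train_labels: np.ndarray,
         val_maps: np.ndarray, val_labels: np.ndarray,
         tc: TrainConfig, max_trials: int = 3, seed: int = 0,
         strategy=random_search_strategy,
         channel_choices: tuple[int, ...] = CHANNEL_CHOICES) -> Trial:
    """Run ``max_trials`` fresh trainings and keep the best-AUC configuration.

    The strategy is pluggable: any callable (n_trials, seed) -> proposals.
    """
    if max_trials < 1:
        raise ValueError("at least one tuning trial is required")
    trials = strategy(max_trials, seed, channel_choices=channel_choices) \
        if strategy is random_search_strategy else strategy(max_trials, seed)
    val_classes = labels_to_classes(val_labels)
    y_true = (val_classes == INTERACTION_INDEX).astype(int)
    for i, trial in enumerate(trials):
        model = build_model(ModelConfig(channels=trial.channels), seed=seed + 1000 + i)
        train(model, train_maps, train_labels, val_maps, val_labels,
              replace(tc, learning_rate=trial.learning_rate, seed=tc.seed + i))
        trial.auc = float(roc_auc_score(y_true, model.predict_proba(val_maps)))
    return select_best(trials)


# ---------------------------------------------------------------------------
# Ensemble


@dataclass
class TrainedEnsemble:
    """Five trained models; the prediction is the mean member probability."""

    models: list[GrayMapCNN]
    configs: list[ModelConfig] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)
    histories: list[list[dict]] = field(default_factory=list)
    chosen: list[Trial] = field(default_factory=list)

    def predict_proba(self, maps: np.ndarray) -> np.ndarray:
        return self.member_probabilities(maps).mean(axis=0)

    def member_probabilities(self, maps: np.ndarray) -> np.ndarray:
        """Per-member P(interaction), shape (n_members, n_samples)."""
        return np.stack([m.predict_proba(maps) for m in self.models])

    def classify(self, maps: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(maps) > threshold).astype(int)


def fit_ensemble(training_sets: list[tuple[np.ndarray, np.ndarray]],
                 val_maps: np.ndarray, val_labels: np.ndarray,
                 tc: TrainConfig, max_trials: int = 0, seed: int = 0,
                 channels: int = 8,
                 channel_choices: tuple[int, ...] = CHANNEL_CHOICES) -> TrainedEnsemble:
    """Train one model per balanced training set (usually five).

    With ``max_trials`` > 0, hyperparameters are tuned per set; otherwise
    the given ``channels`` and ``tc.learning_rate`` are used as-is.
    Member i trains with seed ``seed + i``.
    """
    ensemble = TrainedEnsemble(models=[])
    for i, (maps, labels) in enumerate(training_sets):
        member_seed = seed + i
        if max_trials > 0:
            choice = tune(maps, labels, val_maps, val_labels, tc,
                          max_trials=max_trials, seed=member_seed,
                          channel_choices=channel_choices)
        else:
            choice = Trial(learning_rate=tc.learning_rate, channels=channels)
        config = ModelConfig(channels=choice.channels)
        model = build_model(config, seed=member_seed)
        history = train(model, maps, labels, val_maps, val_labels,
                        replace(tc, learning_rate=choice.learning_rate,
                                seed=member_seed))
        ensemble.models.append(model)
        ensemble.configs.append(config)
        ensemble.seeds.append(member_seed)
        ensemble.histories.append(history)
        ensemble.chosen.append(choice)
    return ensemble


def predict(ensemble: TrainedEnsemble, maps: np.ndarray,
            threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble interaction probabilities and thresholded calls."""
    probs = ensemble.predict_proba(maps)
    return probs, (probs > threshold).astype(int)
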