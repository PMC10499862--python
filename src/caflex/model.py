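"""The encoder → bidirectional-LSTM → decoder B-factor regressor.

The model maps a protein's N×28 per-residue feature matrix to N predicted
B values: a feedforward encoder lifts each residue vector, a bidirectional
LSTM mixes information along the whole chain in both directions (so the
prediction at residue i can depend on every other residue, however distant
in sequence), and a feedforward decoder reads each recurrent state down to
a scalar.  Setting ``use_lstm=False`` removes the recurrent block entirely,
turning the model into a per-residue feedforward network — the ablation
used to measure what the recurrence itself contributes.

Training minimizes the per-protein mean squared error, averaged over the
proteins of a batch; variable-length batches are padded and padded
positions are excluded from the loss.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .features import FeatureMatrix

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainingHistory",
    "PredictionResult",
    "Predictor",
    "build_model",
    "count_parameters",
    "predict_protein",
    "train_model",
    "seed_robustness",
    "save_checkpoint",
    "load_checkpoint",
    "TrainingError",
]


class TrainingError(RuntimeError):
    pass


@dataclasses.dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``encoder_widths`` and ``decoder_widths`` list hidden widths in order;
    the decoder's final width must be 1 (the scalar B prediction) and its
    input width is inferred from the preceding block, so the decoder input
    automatically equals 2×``lstm_hidden`` when bidirectional, or
    ``lstm_hidden``, or the encoder output when ``use_lstm`` is false.
    """

    input_dim: int = 28
    encoder_widths: tuple[int, ...] = (64, 128)
    lstm_hidden: int = 256
    lstm_layers: int = 2
    bidirectional: bool = True
    decoder_widths: tuple[int, ...] = (128, 1)
    use_lstm: bool = True
    activation: str = "relu"

    def __post_init__(self) -> None:
        widths = (*self.encoder_widths, self.lstm_hidden, *self.decoder_widths)
        if any(w < 1 for w in widths):
            raise ValueError("all widths must be >= 1")
        if self.decoder_widths[-1] != 1:
            raise ValueError("decoder must end at width 1")
        if self.use_lstm and self.lstm_layers < 1:
            raise ValueError("use_lstm requires lstm_layers >= 1")


@dataclasses.dataclass
class TrainConfig:
    seeds: tuple[int, ...] = (0, 1, 2, 3)
    max_epochs: int = 300
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    early_stop_patience: int = 20
    b_mode: str = "normalized"

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("seeds must be nonempty")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")


@dataclasses.dataclass
class TrainingHistory:
    train_loss: list[float]
    val_loss: list[float]
    best_epoch: int  # 0-based index of the minimum validation loss


@dataclasses.dataclass
class PredictionResult:
    protein_id: str
    predicted: np.ndarray
    actual: np.ndarray | None = None


class Predictor:
    """A concrete, seeded instance of the regressor.

    The parameter count is independent of sequence length: the same
    weights are shared across all positions, so one instance accepts
    proteins of any size.
    """

    def __init__(self, config: ModelConfig, seed: int):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        act = config.activation
        self.encoder: list[nn.Dense] = []
        d = config.input_dim
        for w in config.encoder_widths:
            self.encoder.append(nn.Dense(d, w, act, rng))
            d = w
        if config.use_lstm:
            self.lstm = nn.BiLSTM(d, config.lstm_hidden, config.lstm_layers,
                                  config.bidirectional, rng)
            d = self.lstm.d_out
        else:
            self.lstm = None
        self.decoder: list[nn.Dense] = []
        for j, w in enumerate(config.decoder_widths):
            last = j == len(config.decoder_widths) - 1
            self.decoder.append(nn.Dense(d, w, "identity" if last else act, rng))
            d = w

    # ---- parameter bookkeeping -------------------------------------------------

    def _named_layers(self):
        for j, layer in enumerate(self.encoder):
            yield f"enc{j}", layer
        if self.lstm is not None:
            for name, layer in self.lstm.iter_layers():
                yield f"lstm_{name}", layer
        for j, layer in enumerate(self.decoder):
            yield f"dec{j}", layer

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            f"{name}_{p}": arr
            for name, layer in self._named_layers()
            for p, arr in layer.params().items()
        }

    def gradients(self) -> dict[str, np.ndarray]:
        return {
            f"{name}_{p}": arr
            for name, layer in self._named_layers()
            for p, arr in layer.grads().items()
        }

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        own = self.parameters()
        if set(own) != set(params):
            raise ValueError("parameter names do not match this architecture")
        for k, arr in own.items():
            if arr.shape != params[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            arr[...] = params[k]

    # ---- forward / backward ----------------------------------------------------

    def forward_batch(self, x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        """x: (B, T, input_dim), padded; returns (B, T) predictions."""
        if x.shape[-1] != self.config.input_dim:
            raise ValueError(
                f"expected feature width {self.config.input_dim}, got {x.shape[-1]}"
            )
        h = x
        for layer in self.encoder:
            h = layer.forward(h)
        if self.lstm is not None:
            h = self.lstm.forward(h, lengths)
        for layer in self.decoder:
            h = layer.forward(h)
        return h[..., 0]

    def backward_batch(self, dpred: np.ndarray) -> None:
        dh = dpred[..., None]
        for layer in reversed(self.decoder):
            dh = layer.backward(dh)
        if self.lstm is not None:
            dh = self.lstm.backward(dh)
        for layer in reversed(self.encoder):
            dh = layer.backward(dh)

    def predict(self, values: np.ndarray) -> np.ndarray:
        """Predict the B profile for one protein's N×28 matrix."""
        values = np.asarray(values, dtype=float)
        out = self.forward_batch(values[None], np.array([values.shape[0]]))
        return out[0]

    def predict_many(self, matrices: Sequence[np.ndarray]) -> list[np.ndarray]:
        """Batched prediction over proteins of different lengths."""
        lengths = np.array([m.shape[0] for m in matrices])
        T = int(lengths.max())
        x = np.zeros((len(matrices), T, self.config.input_dim))
        for i, m in enumerate(matrices):
            x[i, : m.shape[0]] = m
        out = self.forward_batch(x, lengths)
        return [out[i, :L] for i, L in enumerate(lengths)]


def build_model(config: ModelConfig, seed: int) -> Predictor:
    """Construct a predictor with deterministic, seeded initial weights."""
    return Predictor(config, seed)


def count_parameters(model: Predictor) -> int:
    """Total tunable scalar parameters (weights and biases, all gates,
    both directions)."""
    return int(sum(arr.size for arr in model.parameters().values()))


def predict_protein(
    model: Predictor, features: FeatureMatrix, actual: np.ndarray | None = None
) -> PredictionResult:
    pred = model.predict(features.values)
    return PredictionResult(features.protein_id, pred, actual)


# ---- training ------------------------------------------------------------------


def _pad_batch(items: list[tuple[np.ndarray, np.ndarray]], input_dim: int):
    lengths = np.array([v.shape[0] for v, _ in items])
    T = int(lengths.max())
    x = np.zeros((len(items), T, input_dim))
    y = np.zeros((len(items), T))
    for i, (v, t) in enumerate(items):
        x[i, : v.shape[0]] = v
        y[i, : v.shape[0]] = t
    return x, y, lengths


def _as_pairs(dataset) -> list[tuple[np.ndarray, np.ndarray]]:
    pairs = []
    for feats, target in dataset:
        v = feats.values if isinstance(feats, FeatureMatrix) else np.asarray(feats, float)
        pairs.append((v, np.asarray(target, float)))
    return pairs


def _eval_loss(model: Predictor, pairs, batch_size: int) -> float:
    total, count = 0.0, 0
    for k in range(0, len(pairs), batch_size):
        chunk = pairs[k : k + batch_size]
        x, y, lengths = _pad_batch(chunk, model.config.input_dim)
        pred = model.forward_batch(x, lengths)
        loss, _ = nn.masked_mse(pred, y, lengths)
        total += loss * len(chunk)
        count += len(chunk)
    return total / count


def train_model(
    config: ModelConfig,
    tc: TrainConfig,
    train_data,
    val_data,
    seed: int | None = None,
    verbose: bool = False,
) -> tuple[Predictor, TrainingHistory]:
    """Train one predictor with Adam on the masked per-protein MSE.

    ``train_data`` / ``val_data`` are sequences of ``(FeatureMatrix | N×28
    array, target)`` pairs, all encoded with the same feature mask.  The
    returned predictor carries the weights of the epoch with the lowest
    validation loss (earliest epoch on ties).
    """
    train_pairs = _as_pairs(train_data)
    val_pairs = _as_pairs(val_data)
    if not train_pairs or not val_pairs:
        raise TrainingError("training and validation sets must be nonempty")
    seed = tc.seeds[0] if seed is None else seed
    model = build_model(config, seed)
    opt = nn.Adam(model.parameters(), lr=tc.learning_rate)
    shuffle_rng = np.random.default_rng(seed + 10_000)

    train_hist: list[float] = []
    val_hist: list[float] = []
    best_val = np.inf
    best_epoch = 0
    best_params = {k: v.copy() for k, v in model.parameters().items()}

    for epoch in range(tc.max_epochs):
        order = shuffle_rng.permutation(len(train_pairs))
        epoch_loss, n_batches = 0.0, 0
        for k in range(0, len(order), tc.batch_size):
            batch = [train_pairs[j] for j in order[k : k + tc.batch_size]]
            x, y, lengths = _pad_batch(batch, config.input_dim)
            pred = model.forward_batch(x, lengths)
            loss, dpred = nn.masked_mse(pred, y, lengths)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}: {loss}; "
                    "reduce the learning rate or check the targets"
                )
            model.backward_batch(dpred)
            opt.step(model.gradients())
            epoch_loss += loss
            n_batches += 1
        train_hist.append(epoch_loss / n_batches)
        val_loss = _eval_loss(model, val_pairs, tc.batch_size)
        val_hist.append(val_loss)
        if verbose:
            print(f"epoch {epoch}: train {train_hist[-1]:.5f} val {val_loss:.5f}")
        if val_loss < best_val:  # strict: earliest epoch wins ties
            best_val = val_loss
            best_epoch = epoch
            best_params = {k: v.copy() for k, v in model.parameters().items()}
        elif epoch - best_epoch >= tc.early_stop_patience:
            break
    model.set_parameters(best_params)
    return model, TrainingHistory(train_hist, val_hist, best_epoch)


def seed_robustness(
    config: ModelConfig, tc: TrainConfig, train_data, val_data, test_data
) -> dict:
    """The multi-seed robustness protocol: train once per seed in
    ``tc.seeds`` and report each run's average test PCC plus the range."""
    from .evaluation import evaluate_dataset

    per_seed = {}
    for s in tc.seeds:
        model, _ = train_model(config, tc, train_data, val_data, seed=s)
        report = evaluate_dataset(model, test_data)
        per_seed[s] = report.average_pcc
    vals = list(per_seed.values())
    return {
        "per_seed_pcc": per_seed,
        "min_pcc": min(vals),
        "max_pcc": max(vals),
        "range": max(vals) - min(vals),
    }


# ---- checkpoints ---------------------------------------------------------------


def save_checkpoint(model: Predictor, directory: str | Path,
                    train_config: TrainConfig | None = None) -> None:
    """Write a checkpoint directory: plain-text config dump plus weights."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"model_config": dataclasses.asdict(model.config), "seed": model.seed}
    if train_config is not None:
        meta["train_config"] = dataclasses.asdict(train_config)
    (directory / "config.json").write_text(json.dumps(meta, indent=2))
    np.savez(directory / "weights.npz", **model.parameters())


def load_checkpoint(directory: str | Path) -> Predictor:
    """Load a checkpoint; fails loudly on any config/weight mismatch."""
    directory = Path(directory)
    meta = json.loads((directory / "config.json").read_text())
    cfg_dict = meta["model_config"]
    for key in ("encoder_widths", "decoder_widths", "seeds"):
        if key in cfg_dict and isinstance(cfg_dict[key], list):
            cfg_dict[key] = tuple(cfg_dict[key])
    config = ModelConfig(**cfg_dict)
    model = build_model(config, meta["seed"])
    with np.load(directory / "weights.npz") as npz:
        weights = {k: npz[k] for k in npz.files}
    model.set_parameters(weights)
    return model
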