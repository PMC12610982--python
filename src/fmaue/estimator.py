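"""Mixup-augmented LSTM autoencoder-regressor for FMA-UE sub-scores.

Architecture (per subject sample):

* input tensor [M motions, WL windows, 1530 features], z-scored;
* encoder: one LSTM (1530 -> 256 hidden) applied to each motion's window
  sequence, masked temporal mean pool over the WL steps, then a linear
  projection 256 -> 128, giving the latent [M, 128];
* predictor: one LSTM over the M-step latent sequence (hidden kept at 128),
  final-step hidden state -> dropout -> linear 128 -> 4 normalized sub-scores.

The encoder LSTM is shared across motions (the parameter-efficient reading of
"an LSTM layer"); motion order is part of the model contract because the
predictor consumes the latents as an ordered sequence.

Training minimizes MSE between predictions and (optionally mixup-blended)
normalized targets with Adam. Mixup forms convex combinations of sample pairs
via a random within-batch permutation:

    x~ = λ·x_i + (1-λ)·x_j,   y~ = λ·y_i + (1-λ)·y_j,   λ ~ Beta(α, α)

with α = 1 by default (λ uniform on [0, 1]). ``apply_prob = 0`` reduces the
loop exactly to plain MSE regression (the no-mixup ablation arm).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn
from .features import N_FEATURES, FeatureTensor, NormStats

__all__ = [
    "MixupConfig",
    "ModelConfig",
    "TrainedEstimator",
    "TrainingDivergedError",
    "mixup",
    "sample_lambda",
    "train",
]


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite loss at epoch {epoch}")


@dataclasses.dataclass
class MixupConfig:
    """Mixup strength α and per-batch application probability."""

    alpha: float = 1.0
    apply_prob: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not 0.0 <= self.apply_prob <= 1.0:
            raise ValueError("apply_prob must be in [0, 1]")


@dataclasses.dataclass
class ModelConfig:
    """Architecture and optimization hyperparameters.

    Defaults mirror the reference protocol: 1530 input features, encoder
    hidden 256, latent 128, one recurrent layer per stage, 4 outputs,
    dropout 0.3, Adam at lr 5e-5 for 100 epochs. ``batch_size`` = 8.
    """

    input_size: int = N_FEATURES
    encoder_hidden: int = 256
    latent: int = 128
    predictor_hidden: int = 128
    num_layers: int = 1
    output_size: int = 4
    dropout: float = 0.3
    lr: float = 5e-5
    epochs: int = 100
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("input_size", "encoder_hidden", "latent", "predictor_hidden",
                  "num_layers", "output_size", "epochs", "batch_size"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.num_layers != 1:
            raise ValueError("only single recurrent layers are supported")


def sample_lambda(cfg: MixupConfig, rng: np.random.Generator) -> float:
    """Draw the mixing weight λ ~ Beta(α, α); α = 1 gives Uniform(0, 1)."""
    return float(rng.beta(cfg.alpha, cfg.alpha))


def mixup(
    x_i: np.ndarray, x_j: np.ndarray,
    y_i: np.ndarray, y_j: np.ndarray,
    lam: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise convex combination of two (batched) samples and targets."""
    if np.shape(x_i) != np.shape(x_j) or np.shape(y_i) != np.shape(y_j):
        raise ValueError("mixup operands must have matching shapes")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    x_hat = lam * np.asarray(x_i) + (1.0 - lam) * np.asarray(x_j)
    y_hat = lam * np.asarray(y_i) + (1.0 - lam) * np.asarray(y_j)
    return x_hat, y_hat


class _Net:
    """Parameter container + forward/backward passes."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        self.cfg = cfg
        self.dtype = dtype
        self.enc_lstm = nn.LSTM(cfg.input_size, cfg.encoder_hidden, rng, dtype)
        self.enc_fc = nn.Linear(cfg.encoder_hidden, cfg.latent, rng, dtype)
        self.pred_lstm = nn.LSTM(cfg.latent, cfg.predictor_hidden, rng, dtype)
        self.dropout = nn.Dropout(cfg.dropout)
        self.out_fc = nn.Linear(cfg.predictor_hidden, cfg.output_size, rng,
                                dtype)
        self.modules = [self.enc_lstm, self.enc_fc, self.pred_lstm, self.out_fc]

    def encode(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """[B, M, WL, F] -> latent [B, M, latent] (masked mean pooling)."""
        b, m, wl, f = x.shape
        xb = x.reshape(b * m, wl, f).astype(self.dtype)
        hs = self.enc_lstm.forward(xb)  # (B*M, WL, H)
        mk = mask.reshape(b * m, wl, 1).astype(self.dtype)
        counts = mk.sum(axis=1)
        pooled = (hs * mk).sum(axis=1) / counts
        lat = self.enc_fc.forward(pooled)
        self._enc_shape = (b, m, wl, f)
        self._enc_mask = mk
        self._enc_counts = counts
        return lat.reshape(b, m, self.cfg.latent)

    def head(self, latent: np.ndarray, training: bool = False,
             rng: np.random.Generator | None = None) -> np.ndarray:
        """latent [B, M, latent] -> predictions [B, 4]."""
        hs = self.pred_lstm.forward(latent.astype(self.dtype))
        last = hs[:, -1]
        dropped = self.dropout.forward(last, training, rng)
        return self.out_fc.forward(dropped)

    def forward(self, x, mask, training=False, rng=None) -> np.ndarray:
        return self.head(self.encode(x, mask), training, rng)

    def backward(self, dy: np.ndarray) -> None:
        dlast = self.dropout.backward(self.out_fc.backward(dy))
        b, m, _, _ = self._enc_shape
        dhs2 = np.zeros((b, m, self.cfg.predictor_hidden), dtype=self.dtype)
        dhs2[:, -1] = dlast
        dlat = self.pred_lstm.backward(dhs2)
        dpooled = self.enc_fc.backward(
            dlat.reshape(b * m, self.cfg.latent))
        dhs = (dpooled[:, None, :] * self._enc_mask) / \
            self._enc_counts[:, None, :]
        self.enc_lstm.backward(dhs.astype(self.dtype))

    def zero_grad(self) -> None:
        for mod in self.modules:
            mod.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        names = ("enc_lstm", "enc_fc", "pred_lstm", "out_fc")
        for name, mod in zip(names, self.modules):
            for pname, p in mod.params.items():
                out[f"{name}.{pname}"] = p
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        names = ("enc_lstm", "enc_fc", "pred_lstm", "out_fc")
        for name, mod in zip(names, self.modules):
            for pname in mod.params:
                mod.params[pname][...] = state[f"{name}.{pname}"]


@dataclasses.dataclass
class TrainedEstimator:
    """A trained model plus its configs, normalization stats and history."""

    net: _Net
    model_config: ModelConfig
    mixup_config: MixupConfig
    norm: NormStats
    history: list[float] = dataclasses.field(default_factory=list)

    def encode(self, x: np.ndarray | FeatureTensor,
               mask: np.ndarray | None = None) -> np.ndarray:
        """Encode one normalized tensor [M, WL, 1530] -> latent [M, 128]."""
        if isinstance(x, FeatureTensor):
            x, mask = x.values, x.mask
        x = np.asarray(x)
        if mask is None:
            mask = np.ones(x.shape[:2], dtype=bool)
        return self.net.encode(x[None], mask[None])[0]

    def predict(self, latent: np.ndarray) -> np.ndarray:
        """Latent [M, 128] -> normalized scores [1, 4] (deterministic)."""
        return self.net.head(np.asarray(latent)[None], training=False)

    def predict_normalized(self, tensor: FeatureTensor) -> np.ndarray:
        """Normalized tensor -> normalized score 4-vector."""
        return self.predict(self.encode(tensor))[0]

    def predict_scores(self, tensor: FeatureTensor) -> np.ndarray:
        """Normalized tensor -> de-normalized, range-clipped sub-scores."""
        y = self.norm.denormalize_scores(self.predict_normalized(tensor))
        return np.clip(y, 0.0, self.norm.divisors)

    def save(self, path: str | Path) -> Path:
        """Self-describing single-file checkpoint (npz + embedded JSON)."""
        path = Path(path)
        meta = json.dumps({
            "model_config": dataclasses.asdict(self.model_config),
            "mixup_config": dataclasses.asdict(self.mixup_config),
            "registry_version": "fmaue-153x10-v1",
        })
        np.savez(
            path,
            __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
            norm_mean=self.norm.mean, norm_std=self.norm.std,
            norm_divisors=self.norm.divisors,
            history=np.asarray(self.history),
            **self.net.state_dict(),
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TrainedEstimator":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        mcfg = ModelConfig(**meta["model_config"])
        mixcfg = MixupConfig(**meta["mixup_config"])
        net = _Net(mcfg, np.random.default_rng(mcfg.seed))
        net.load_state_dict({k: data[k] for k in data.files
                             if "." in k})
        norm = NormStats(mean=data["norm_mean"], std=data["norm_std"],
                         divisors=data["norm_divisors"], fitted=True)
        return cls(net=net, model_config=mcfg, mixup_config=mixcfg,
                   norm=norm, history=list(data["history"]))


def train(
    tensors: list[FeatureTensor],
    scores_norm: np.ndarray,
    mcfg: ModelConfig,
    mixcfg: MixupConfig | None = None,
    norm: NormStats | None = None,
) -> TrainedEstimator:
    """Train the estimator on normalized tensors and normalized scores.

    ``tensors`` must already be z-scored with stats fitted on these training
    samples only; ``scores_norm`` is (n, 4) on the [0, 1] scale. Fully
    reproducible given the config seeds. Raises
    :class:`TrainingDivergedError` on a non-finite epoch loss.
    """
    if len(tensors) < 1:
        raise ValueError("need at least one training sample")
    mixcfg = mixcfg or MixupConfig()
    y = np.asarray(scores_norm, dtype=np.float32)
    if y.ndim != 2 or y.shape[0] != len(tensors):
        raise ValueError("scores_norm must be (n_samples, 4)")

    x = np.stack([t.values for t in tensors]).astype(np.float32)
    masks = np.stack([t.mask for t in tensors])
    n = len(tensors)

    init_rng = np.random.default_rng(mcfg.seed)
    net = _Net(mcfg, init_rng)
    opt = nn.Adam(net.modules, lr=mcfg.lr)
    train_rng = np.random.default_rng(
        np.random.SeedSequence([mcfg.seed, mixcfg.seed, 0xF17A]))

    history: list[float] = []
    for epoch in range(mcfg.epochs):
        order = train_rng.permutation(n)
        losses = []
        for start in range(0, n, mcfg.batch_size):
            idx = order[start:start + mcfg.batch_size]
            xb, yb = x[idx], y[idx]
            mb = masks[idx]
            if mixcfg.apply_prob > 0 and \
                    train_rng.random() < mixcfg.apply_prob and len(idx) > 1:
                lam = sample_lambda(mixcfg, train_rng)
                perm = train_rng.permutation(len(idx))
                xb, yb = mixup(xb, xb[perm], yb, yb[perm], lam)
                mb = mb | mb[perm]  # a slot is real if real in either parent
            pred = net.forward(xb.astype(np.float32), mb, training=True,
                               rng=train_rng)
            err = pred - yb.astype(np.float32)
            loss = float(np.mean(err**2))
            losses.append(loss)
            opt.zero_grad()
            net.backward(2.0 * err / err.size)
            opt.step()
        epoch_loss = float(np.mean(losses))
        if not np.isfinite(epoch_loss):
            raise TrainingDivergedError(epoch)
        history.append(epoch_loss)

    return TrainedEstimator(net=net, model_config=mcfg, mixup_config=mixcfg,
                            norm=norm or NormStats(), history=history)
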