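"""3D convolutional autoencoder for registered FA volumes.

The model maps a whole 3D volume through a stack of stride-2 convolutional
encoder blocks, a *linear* latent bottleneck (no activation on the latent
code), and a mirrored stack of transposed-convolution decoder blocks back
to the input grid, with no skip connections so the entire signal must pass
through the bottleneck.  Reconstruction is a voxel-wise regression: no
output activation, optimized with mean squared error computed only over
brain-mask voxels.

One latent coordinate per subject-and-dimension is an unsupervised deep
imaging phenotype (UDIP).  The full-size preset
(:func:`ukb_full_config`) is the full-scale reference configuration: 5+5
blocks, 128-dimensional latent space, 182x218x182 input, 138.12 million
trainable parameters.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import Adam, Conv3d, ConvTranspose3d, Dense, ReLU
from .volumes import BrainMask

__all__ = [
    "AEConfig",
    "AEModel",
    "TrainReport",
    "ukb_full_config",
    "build_model",
    "count_parameters",
    "masked_mse",
    "train",
    "encode",
    "decode",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class AEConfig:
    input_shape: tuple[int, int, int]
    channels: tuple[int, ...] = (8, 16, 32, 64, 64)
    latent_dim: int = 8
    kernel: int = 3
    stride: int = 2
    learning_rate: float = 1.4e-4
    epochs: int = 75
    batch_size: int = 16
    seed: int = 0

    @property
    def n_blocks(self) -> int:
        return len(self.channels)

    def __post_init__(self):
        if self.n_blocks < 1 or self.latent_dim < 1:
            raise ValueError("need at least one block and latent_dim >= 1")
        # ceil-halving must not collapse any axis to zero
        shape = self.input_shape
        for _ in range(self.n_blocks):
            shape = tuple(-(-d // self.stride) for d in shape)
            if any(d < 1 for d in shape):
                raise ValueError(f"input {self.input_shape} too small for {self.n_blocks} blocks")

    def spatial_shapes(self) -> list[tuple[int, int, int]]:
        """Spatial shape before each block plus the final bottleneck shape."""
        shapes = [tuple(self.input_shape)]
        for _ in range(self.n_blocks):
            shapes.append(tuple(-(-d // self.stride) for d in shapes[-1]))
        return shapes


def ukb_full_config() -> AEConfig:
    """Full-size configuration: 5+5 blocks, latent 128, input 182x218x182.

    Channel widths (64, 128, 256, 512, 1394) with 3^3 kernels give
    138,118,955 trainable parameters, i.e. 138.12 million.
    """
    return AEConfig(
        input_shape=(182, 218, 182),
        channels=(64, 128, 256, 512, 1394),
        latent_dim=128,
        learning_rate=1.4e-4,
        epochs=75,
    )


def count_parameters(cfg: AEConfig) -> int:
    """Closed-form trainable-parameter count for a configuration."""
    k3 = cfg.kernel**3
    chans = (1,) + tuple(cfg.channels)
    flat = int(np.prod(cfg.spatial_shapes()[-1])) * cfg.channels[-1]
    total = 0
    for cin, cout in zip(chans[:-1], chans[1:]):  # encoder convs
        total += cout * cin * k3 + cout
    total += flat * cfg.latent_dim + cfg.latent_dim  # encoder fc
    total += cfg.latent_dim * flat + flat  # decoder fc
    for cout, cin in zip(chans[:-1], chans[1:]):  # decoder transposed convs
        total += cin * cout * k3 + cout
    return total


class AEModel:
    """Encoder/decoder parameter store built from an :class:`AEConfig`."""

    def __init__(self, cfg: AEConfig):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xAE]))
        shapes = cfg.spatial_shapes()
        chans = (1,) + tuple(cfg.channels)
        pad = (cfg.kernel - 1) // 2

        self.encoder: list = []
        for i in range(cfg.n_blocks):
            try:
                conv = Conv3d(chans[i], chans[i + 1], shapes[i], cfg.kernel, cfg.stride, pad, rng)
            except ValueError as exc:
                raise ValueError(f"encoder block {i}: {exc}") from exc
            if conv.geom.out_shape != shapes[i + 1]:
                raise ValueError(f"encoder block {i} produced {conv.geom.out_shape}, expected {shapes[i + 1]}")
            self.encoder += [conv, ReLU()]
        self.flat_dim = int(np.prod(shapes[-1])) * chans[-1]
        self.bottleneck_shape = shapes[-1]
        self.enc_fc = Dense(self.flat_dim, cfg.latent_dim, rng)

        self.dec_fc = Dense(cfg.latent_dim, self.flat_dim, rng)
        self.decoder: list = [ReLU()]
        for i in range(cfg.n_blocks, 0, -1):
            convt = ConvTranspose3d(chans[i], chans[i - 1], shapes[i], shapes[i - 1], cfg.kernel, cfg.stride, pad, rng)
            self.decoder.append(convt)
            if i > 1:
                self.decoder.append(ReLU())
        self.mask_array: np.ndarray | None = None  # set by train()
        # training-set mean volume, subtracted before encoding and added back
        # after decoding; improves optimizer conditioning without changing the
        # encode/decode contract (differences and masked losses are unaffected)
        self.center: np.ndarray | None = None

    # ---- parameter plumbing -------------------------------------------------
    def _layers(self):
        return [*self.encoder, self.enc_fc, self.dec_fc, *self.decoder]

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self._layers()):
            for name, arr in layer.params().items():
                out[f"layer{i:02d}.{name}"] = arr
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self._layers()):
            for name, arr in layer.grads().items():
                out[f"layer{i:02d}.{name}"] = arr
        return out

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._layers()):
            for name in layer.params():
                layer.params()[name][...] = params[f"layer{i:02d}.{name}"]

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.parameters().values()))

    # ---- forward/backward ---------------------------------------------------
    def encode_array(self, x: np.ndarray) -> np.ndarray:
        """(B, nx, ny, nz) volumes -> (B, latent_dim) codes."""
        if self.center is not None:
            x = x - self.center
        h = x[:, None, :, :, :]
        for layer in self.encoder:
            h = layer.forward(h)
        return self.enc_fc.forward(h.reshape(h.shape[0], -1))

    def decode_array(self, z: np.ndarray) -> np.ndarray:
        """(B, latent_dim) codes -> (B, nx, ny, nz) reconstructions."""
        z = np.asarray(z, dtype=np.float64)
        if z.ndim != 2 or z.shape[1] != self.cfg.latent_dim:
            raise ValueError(f"latent width {z.shape} incompatible with latent_dim {self.cfg.latent_dim}")
        h = self.dec_fc.forward(z)
        h = h.reshape((z.shape[0], self.cfg.channels[-1]) + self.bottleneck_shape)
        for layer in self.decoder:
            h = layer.forward(h)
        out = h[:, 0]
        if self.center is not None:
            out = out + self.center
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.decode_array(self.encode_array(x))

    def backward(self, dout: np.ndarray) -> None:
        d = dout[:, None]
        for layer in reversed(self.decoder):
            d = layer.backward(d)
        d = self.dec_fc.backward(d.reshape(d.shape[0], -1))
        d = self.enc_fc.backward(d)
        d = d.reshape((d.shape[0], self.cfg.channels[-1]) + self.bottleneck_shape)
        for layer in reversed(self.encoder):
            d = layer.backward(d)


@dataclass
class TrainReport:
    train_loss: list[float]
    val_loss: list[float]
    best_epoch: int
    seed: int
    split_seed: int
    n_train: int
    n_val: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def masked_mse(x: np.ndarray, xhat: np.ndarray, mask: np.ndarray | BrainMask) -> float:
    """Mean squared error over brain-mask voxels, averaged over the batch."""
    m = mask.data if isinstance(mask, BrainMask) else np.asarray(mask)
    m = m.astype(bool)
    if not m.any():
        raise ValueError("empty mask")
    x = np.atleast_3d(np.asarray(x))
    if x.ndim == 3:
        x, xhat = x[None], np.asarray(xhat)[None]
    diff = (np.asarray(xhat) - x)[:, m]
    return float(np.mean(diff**2))


def build_model(cfg: AEConfig) -> AEModel:
    """Instantiate the autoencoder with seeded weights."""
    return AEModel(cfg)


def _as_array(volumes) -> np.ndarray:
    if hasattr(volumes, "data_array"):
        return volumes.data_array()
    if isinstance(volumes, np.ndarray):
        return volumes if volumes.ndim == 4 else volumes[None]
    return np.stack([getattr(v, "data", v) for v in volumes])


def train(
    model: AEModel,
    volumes,
    mask: BrainMask | np.ndarray,
    split: float = 0.75,
    epochs: int | None = None,
    verbose: bool = False,
) -> TrainReport:
    """Train with Adam on masked MSE; retain the best-validation checkpoint.

    ``split`` is the training fraction (default protocol: 75% train /
    25% validation, split at subject level).  Ties in validation loss are
    broken toward the earliest epoch.
    """
    cfg = model.cfg
    x = _as_array(volumes)
    m = (mask.data if isinstance(mask, BrainMask) else np.asarray(mask)).astype(bool)
    n = x.shape[0]
    n_train = int(round(split * n))
    if n_train < 2 or n - n_train < 1:
        raise ValueError(f"split {split} leaves too few subjects (n={n})")

    split_seed = cfg.seed + 1
    rng = np.random.default_rng(np.random.SeedSequence([split_seed, 0x5B17]))
    perm = rng.permutation(n)
    tr_idx, va_idx = perm[:n_train], perm[n_train:]
    x_tr = x[tr_idx] * m  # exterior voxels zeroed: part of the data contract
    x_va = x[va_idx] * m
    n_mask = int(m.sum())
    model.center = x_tr.mean(axis=0) * m

    params = model.parameters()
    opt = Adam(params, lr=cfg.learning_rate)
    n_epochs = cfg.epochs if epochs is None else epochs

    def evaluate(batch: np.ndarray) -> float:
        losses = []
        for s in range(0, batch.shape[0], cfg.batch_size):
            xb = batch[s : s + cfg.batch_size]
            losses.append(masked_mse(xb, model.forward(xb), m) * xb.shape[0])
        return float(sum(losses) / batch.shape[0])

    train_losses: list[float] = []
    val_losses: list[float] = []
    best_loss = np.inf
    best_epoch = -1
    best_params = copy.deepcopy(params)

    for epoch in range(n_epochs):
        order = rng.permutation(n_train)
        ep_loss = 0.0
        for s in range(0, n_train, cfg.batch_size):
            xb = x_tr[order[s : s + cfg.batch_size]]
            xhat = model.forward(xb)
            resid = (xhat - xb) * m  # masked loss: outside voxels contribute nothing
            loss = float(np.sum(resid**2) / (xb.shape[0] * n_mask))
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch}: loss={loss}")
            model.backward(2.0 * resid / (xb.shape[0] * n_mask))
            opt.step(model.gradients())
            ep_loss += loss * xb.shape[0]
        train_losses.append(ep_loss / n_train)
        val_losses.append(evaluate(x_va))
        if val_losses[-1] < best_loss:  # strict: ties keep the earlier epoch
            best_loss = val_losses[-1]
            best_epoch = epoch
            best_params = copy.deepcopy(params)
        if verbose:
            print(f"epoch {epoch:3d}  train {train_losses[-1]:.6f}  val {val_losses[-1]:.6f}")

    model.set_parameters(best_params)
    model.mask_array = m
    return TrainReport(
        train_loss=train_losses,
        val_loss=val_losses,
        best_epoch=best_epoch,
        seed=cfg.seed,
        split_seed=split_seed,
        n_train=n_train,
        n_val=n - n_train,
    )


def encode(model: AEModel, volumes, subject_ids=None, batch_size: int | None = None) -> pd.DataFrame:
    """Encode volumes to an n x latent_dim table of UDIP values.

    Volumes are multiplied by the training mask (if one was attached)
    before encoding, so voxels outside the brain cannot influence codes.
    """
    x = _as_array(volumes)
    if x.shape[1:] != tuple(model.cfg.input_shape):
        raise ValueError(f"volume shape {x.shape[1:]} != model input {model.cfg.input_shape}")
    if model.mask_array is not None:
        x = x * model.mask_array
    bs = batch_size or max(model.cfg.batch_size, 1)
    codes = np.vstack([model.encode_array(x[s : s + bs]) for s in range(0, x.shape[0], bs)])
    if subject_ids is None:
        if hasattr(volumes, "true_latents"):
            subject_ids = list(volumes.true_latents.index)
        else:
            subject_ids = [f"subj{i:04d}" for i in range(x.shape[0])]
    return pd.DataFrame(
        codes,
        index=pd.Index(subject_ids, name="subject"),
        columns=[f"dim_{j}" for j in range(model.cfg.latent_dim)],
    )


def decode(model: AEModel, latents, batch_size: int | None = None) -> np.ndarray:
    """Decode latent rows back to (n, nx, ny, nz) volumes."""
    z = latents.to_numpy() if isinstance(latents, pd.DataFrame) else np.asarray(latents)
    if z.ndim == 1:
        z = z[None]
    bs = batch_size or max(model.cfg.batch_size, 1)
    return np.concatenate([model.decode_array(z[s : s + bs]) for s in range(0, z.shape[0], bs)])


def save_model(model: AEModel, path: str | Path) -> Path:
    """Save parameters as .npz with a JSON config sidecar."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    extras = {}
    if model.mask_array is not None:
        extras["__mask__"] = model.mask_array.astype(np.uint8)
    if model.center is not None:
        extras["__center__"] = model.center
    np.savez_compressed(path, **model.parameters(), **extras)
    sidecar = path.with_suffix(path.suffix + ".json")
    cfg = asdict(model.cfg)
    cfg["input_shape"] = list(cfg["input_shape"])
    cfg["channels"] = list(cfg["channels"])
    sidecar.write_text(json.dumps(cfg, indent=2))
    return path


def load_model(path: str | Path) -> AEModel:
    path = Path(path)
    cfg_raw = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    cfg_raw["input_shape"] = tuple(cfg_raw["input_shape"])
    cfg_raw["channels"] = tuple(cfg_raw["channels"])
    model = AEModel(AEConfig(**cfg_raw))
    with np.load(path) as store:
        params = {k: store[k] for k in store.files if not k.startswith("__")}
        model.set_parameters(params)
        if "__mask__" in store.files:
            model.mask_array = store["__mask__"].astype(bool)
        if "__center__" in store.files:
            model.center = store["__center__"]
    return model
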