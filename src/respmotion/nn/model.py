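"""Hybrid multi-task motion network: dilated-conv trunk, BiLSTM, autoencoder heads.

The network consumes a normalized input window ``(B, T, C)`` and jointly
produces (i) a 4-way motion-range classification, (ii) future positions per
axis at each latency horizon, (iii) an autoencoder reconstruction of the clean
breathing window decoded from a low-dimensional latent code, and (iv) an
excessive-motion probability.  Training minimizes the weighted composite of
cross-entropy, mean-squared prediction error, reconstruction mean absolute
error, and binary cross-entropy.

Implemented on the package's NumPy layer core with explicit backpropagation;
training runs on a single CPU and is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .layers import (
    BiLSTM,
    CausalDilatedConv1d,
    Dense,
    LayerNorm,
    Param,
    ReLU,
    SpatialDropout,
    Tanh,
    sigmoid,
    softmax,
)

__all__ = [
    "NetConfig",
    "RespMotionNet",
    "composite_loss",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]

_EPS = 1e-12


@dataclass
class NetConfig:
    """Architecture and optimization settings for :class:`RespMotionNet`."""

    conv_channels: int = 32
    kernel_size: int = 3
    dilations: tuple[int, ...] = (1, 2, 4, 8)
    layer_norm: bool = True
    spatial_dropout: float = 0.2
    lstm_hidden: int = 64
    lstm_pool: int = 1      # average-pool factor on the time axis before the BiLSTM
    latent_dim: int = 16
    reg_hidden: int = 64
    reg_skip: int = 12      # recent raw samples fed directly to the regression head
    decoder_hidden: int = 64
    loss_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    learning_rate: float = 1e-3
    lr_schedule: str = "constant"  # or "cosine" (decay to ~0 over max_epochs)
    batch_size: int = 64
    max_epochs: int = 20
    patience: int = 5
    val_fraction: float = 0.1
    grad_clip: float = 5.0
    seed: int = 0
    dtype: str = "float32"

    def validate(self) -> None:
        if min(self.conv_channels, self.kernel_size, self.lstm_hidden,
               self.latent_dim, self.batch_size, self.max_epochs) < 1:
            raise ValueError("architecture sizes must be positive")
        if any(d < 1 for d in self.dilations) or not self.dilations:
            raise ValueError("dilations must be positive integers")
        if self.lstm_pool < 1:
            raise ValueError("lstm_pool must be >= 1")
        w = self.loss_weights
        if len(w) != 4 or any(x < 0 for x in w):
            raise ValueError("loss weights must be 4 non-negative reals")
        if not any(x > 0 for x in w):
            raise ValueError("at least one loss weight must be positive")
        if not 0.0 <= self.spatial_dropout < 1.0:
            raise ValueError("spatial_dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")


class _Adam:
    """Adaptive-moment gradient descent with bias correction."""

    def __init__(self, params: list[Param], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grad_clip: float = 0.0) -> None:
        if grad_clip > 0:
            total = np.sqrt(sum(float(np.sum(p.grad.astype(np.float64) ** 2))
                                for p in self.params))
            if total > grad_clip:
                scale = grad_clip / (total + _EPS)
                for p in self.params:
                    p.grad *= scale
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p in self.params:
            p.m = self.beta1 * p.m + (1.0 - self.beta1) * p.grad
            p.v = self.beta2 * p.v + (1.0 - self.beta2) * p.grad**2
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)


class RespMotionNet:
    """Multi-task respiratory-motion network (see module docstring).

    ``window_len`` and ``n_channels`` fix the input shape; ``n_horizons`` the
    number of latency horizons the regression head covers.  The latent code
    must be a genuine compression of the flattened signal window.
    """

    N_CLASSES = 4
    N_AXES = 3

    def __init__(self, config: NetConfig, window_len: int, n_channels: int,
                 n_horizons: int):
        config.validate()
        if config.latent_dim >= window_len * self.N_AXES:
            raise ValueError("latent dim must be smaller than the flattened window")
        if window_len % config.lstm_pool != 0:
            raise ValueError("window length must be divisible by lstm_pool")
        self.config = config
        self.window_len = window_len
        self.n_channels = n_channels
        self.n_horizons = n_horizons
        dtype = np.dtype(config.dtype).type
        self.dtype = dtype
        rng = np.random.default_rng(config.seed)
        self._rng = np.random.default_rng(config.seed + 1)

        # trunk summary: forward-end state, backward-start state, mean pool
        H2 = 4 * config.lstm_hidden
        self.reg_skip = min(config.reg_skip, window_len)
        self.conv_blocks = []
        c_in = n_channels
        for li, d in enumerate(config.dilations):
            block = {
                "conv": CausalDilatedConv1d(
                    c_in, config.conv_channels, config.kernel_size, d, rng,
                    dtype, name=f"conv{li}"),
                "ln": LayerNorm(config.conv_channels, dtype, name=f"ln{li}")
                if config.layer_norm else None,
                "relu": ReLU(),
                "drop": SpatialDropout(config.spatial_dropout),
            }
            self.conv_blocks.append(block)
            c_in = config.conv_channels
        self.bilstm = BiLSTM(c_in, config.lstm_hidden, rng, dtype)

        self.encoder = Dense(H2, config.latent_dim, rng, dtype, name="encoder")
        self.encoder_act = Tanh()
        if config.decoder_hidden > 0:
            self.decoder_hidden = Dense(config.latent_dim, config.decoder_hidden,
                                        rng, dtype, name="decoder_hidden")
            self.decoder_act = ReLU()
            dec_in = config.decoder_hidden
        else:
            self.decoder_hidden = None
            self.decoder_act = None
            dec_in = config.latent_dim
        self.decoder_out = Dense(dec_in, window_len * self.N_AXES, rng, dtype,
                                 name="decoder_out")

        self.class_head = Dense(H2, self.N_CLASSES, rng, dtype, name="class_head")
        self.exc_head = Dense(H2, 1, rng, dtype, name="exc_head")
        reg_in = H2 + self.reg_skip * self.N_AXES
        self.reg_hidden = Dense(reg_in, config.reg_hidden, rng, dtype, name="reg_hidden")
        self.reg_act = ReLU()
        self.reg_out = Dense(config.reg_hidden, self.N_AXES * n_horizons, rng,
                             dtype, name="reg_out")

    # ------------------------------------------------------------------ params
    def params(self) -> list[Param]:
        ps: list[Param] = []
        for blk in self.conv_blocks:
            ps += blk["conv"].params()
            if blk["ln"] is not None:
                ps += blk["ln"].params()
        ps += self.bilstm.params()
        ps += self.encoder.params()
        if self.decoder_hidden is not None:
            ps += self.decoder_hidden.params()
        ps += self.decoder_out.params()
        ps += self.class_head.params()
        ps += self.exc_head.params()
        ps += self.reg_hidden.params()
        ps += self.reg_out.params()
        return ps

    # ------------------------------------------------------------------ trunk
    def _trunk_forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = x
        for blk in self.conv_blocks:
            h = blk["conv"].forward(h)
            if blk["ln"] is not None:
                h = blk["ln"].forward(h)
            h = blk["relu"].forward(h)
            h = blk["drop"].forward(h, training=training, rng=self._rng)
        pool = self.config.lstm_pool
        if pool > 1:
            B, T, C = h.shape
            h = h.reshape(B, T // pool, pool, C).mean(axis=2)
        y = self.bilstm.forward(h)
        Hh = self.config.lstm_hidden
        # forward stream at the last step, backward stream at the first,
        # plus a mean-pooled readout over all steps
        feat = np.concatenate(
            [y[:, -1, :Hh], y[:, 0, Hh:], y.mean(axis=1)], axis=1
        )
        self._bilstm_out_shape = y.shape
        return feat

    def _trunk_backward(self, dfeat: np.ndarray) -> None:
        Hh = self.config.lstm_hidden
        B, T, _ = self._bilstm_out_shape
        dy = np.zeros(self._bilstm_out_shape, dtype=dfeat.dtype)
        dy[:, -1, :Hh] = dfeat[:, :Hh]
        dy[:, 0, Hh : 2 * Hh] = dfeat[:, Hh : 2 * Hh]
        dy += dfeat[:, None, 2 * Hh :] / T
        dh = self.bilstm.backward(dy)
        pool = self.config.lstm_pool
        if pool > 1:
            Bp, Tp, Cp = dh.shape
            dh = np.repeat(dh / pool, pool, axis=1)
        for blk in reversed(self.conv_blocks):
            dh = blk["drop"].backward(dh)
            dh = blk["relu"].backward(dh)
            if blk["ln"] is not None:
                dh = blk["ln"].backward(dh)
            dh = blk["conv"].backward(dh)

    # --------------------------------------------------------------- ae heads
    def encode(self, feat: np.ndarray) -> np.ndarray:
        """Latent code ``z = tanh(W feat + b)`` from trunk features."""
        return self.encoder_act.forward(self.encoder.forward(feat))

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Reconstruct the clean window ``(B, window_len, 3)`` from ``z``."""
        h = z
        if self.decoder_hidden is not None:
            h = self.decoder_act.forward(self.decoder_hidden.forward(h))
        flat = self.decoder_out.forward(h)
        return flat.reshape(z.shape[0], self.window_len, self.N_AXES)

    def _decode_backward(self, dxhat: np.ndarray) -> np.ndarray:
        dflat = dxhat.reshape(dxhat.shape[0], -1)
        dh = self.decoder_out.backward(dflat)
        if self.decoder_hidden is not None:
            dh = self.decoder_hidden.backward(self.decoder_act.backward(dh))
        return dh

    # ---------------------------------------------------------------- forward
    def forward(self, X: np.ndarray, training: bool = False) -> dict:
        """Run all four task heads on a batch of windows.

        Returns class probabilities (summing to 1), future positions per axis
        and horizon in normalized units, the reconstructed window, and the
        excessive-motion probability in [0, 1].
        """
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim != 3 or X.shape[1] != self.window_len or X.shape[2] != self.n_channels:
            raise ValueError(
                f"expected window batch of shape (B, {self.window_len}, "
                f"{self.n_channels}), got {X.shape}"
            )
        feat = self._trunk_forward(X, training)
        z = self.encode(feat)
        recon = self.decode(z)

        class_logits = self.class_head.forward(feat)
        class_probs = softmax(class_logits)
        exc_logit = self.exc_head.forward(feat)[:, 0]
        exc_prob = sigmoid(exc_logit)
        # regression head also sees the most recent raw samples (skip input)
        skip = X[:, -self.reg_skip :, : self.N_AXES].reshape(X.shape[0], -1)
        reg_in = np.concatenate([feat, skip], axis=1)
        delta = self.reg_out.forward(self.reg_act.forward(self.reg_hidden.forward(reg_in)))
        delta = delta.reshape(-1, self.N_AXES, self.n_horizons)
        last_obs = X[:, -1, : self.N_AXES]            # persistence anchor
        future = last_obs[:, :, None] + delta

        self._last_X = X
        return {
            "feat": feat,
            "z": z,
            "class_logits": class_logits,
            "class_probs": class_probs,
            "future": future,
            "recon": recon,
            "excessive_logit": exc_logit,
            "excessive_prob": exc_prob,
        }

    def predict(self, X: np.ndarray, batch_size: int = 256) -> dict:
        """Batched inference without dropout; concatenates head outputs."""
        outs: dict[str, list[np.ndarray]] = {}
        for i in range(0, len(X), batch_size):
            o = self.forward(X[i : i + batch_size], training=False)
            for k in ("class_probs", "future", "recon", "excessive_prob", "z"):
                outs.setdefault(k, []).append(o[k])
        return {k: np.concatenate(v) for k, v in outs.items()}

    # ------------------------------------------------------------- train step
    def train_step(self, X: np.ndarray, targets: dict, opt: _Adam) -> dict:
        """One forward/backward/update pass; returns the loss components."""
        out = self.forward(X, training=True)
        B = X.shape[0]
        w_cls, w_reg, w_rec, w_exc = self.config.loss_weights

        y_class = targets["class_index"]
        y_future = targets["future"].astype(self.dtype)
        y_recon = targets["recon"].astype(self.dtype)
        y_exc = targets["excessive"].astype(self.dtype)

        probs = out["class_probs"]
        ce = -np.mean(np.log(probs[np.arange(B), y_class] + _EPS))
        err = out["future"] - y_future
        mse = float(np.mean(err**2))
        rdiff = out["recon"] - y_recon
        mae = float(np.mean(np.abs(rdiff)))
        p_exc = out["excessive_prob"]
        bce = -float(np.mean(
            y_exc * np.log(p_exc + _EPS) + (1 - y_exc) * np.log(1 - p_exc + _EPS)
        ))
        loss = w_cls * ce + w_reg * mse + w_rec * mae + w_exc * bce
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite training loss (ce={ce}, mse={mse}, mae={mae}, bce={bce})"
            )

        for p in self.params():
            p.zero_grad()

        # head gradients
        dlogits = probs.copy()
        dlogits[np.arange(B), y_class] -= 1.0
        dlogits *= w_cls / B
        dfeat = self.class_head.backward(dlogits.astype(self.dtype))

        dexc = ((p_exc - y_exc) * (w_exc / B)).astype(self.dtype)[:, None]
        dfeat += self.exc_head.backward(dexc)

        dfuture = (2.0 * w_reg / err.size) * err
        ddelta = dfuture.reshape(B, -1).astype(self.dtype)
        dreg_in = self.reg_hidden.backward(
            self.reg_act.backward(self.reg_out.backward(ddelta))
        )
        dfeat += dreg_in[:, : dfeat.shape[1]]  # skip part needs no input grad

        dxhat = (w_rec / rdiff.size) * np.sign(rdiff)
        dz = self._decode_backward(dxhat.astype(self.dtype))
        dfeat += self.encoder.backward(self.encoder_act.backward(dz))

        self._trunk_backward(dfeat.astype(self.dtype))
        opt.step(self.config.grad_clip)
        return {"loss": float(loss), "ce": float(ce), "mse": mse,
                "mae": mae, "bce": bce}

    def eval_loss(self, X: np.ndarray, targets: dict, batch_size: int = 256) -> float:
        """Composite loss without dropout or updates (for validation)."""
        total, count = 0.0, 0
        for i in range(0, len(X), batch_size):
            sl = slice(i, i + batch_size)
            out = self.forward(X[sl], training=False)
            preds = {
                "class_probs": out["class_probs"],
                "future": out["future"],
                "recon": out["recon"],
                "excessive_prob": out["excessive_prob"],
            }
            tg = {k: targets[k][sl] for k in
                  ("class_index", "future", "recon", "excessive")}
            b = out["class_probs"].shape[0]
            total += composite_loss(preds, tg, self.config.loss_weights) * b
            count += b
        return total / max(count, 1)

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value for i, p in enumerate(self.params())}


def composite_loss(predictions: dict, targets: dict, weights) -> float:
    """Weighted multi-task loss.

    ``loss = w_cls * CE(class) + w_reg * MSE(future) + w_rec * MAE(recon)
    + w_exc * BCE(excessive)``.  Zero iff every head is exactly correct.
    """
    w = tuple(float(x) for x in weights)
    if len(w) != 4 or any(x < 0 for x in w):
        raise ValueError("weights must be 4 non-negative reals")
    probs = np.asarray(predictions["class_probs"], dtype=float)
    y_class = np.asarray(targets["class_index"], dtype=int)
    p_true = probs[np.arange(len(y_class)), y_class]
    ce = float(np.mean(-np.log(np.clip(p_true, _EPS, None))))
    mse = float(np.mean(
        (np.asarray(predictions["future"], dtype=float)
         - np.asarray(targets["future"], dtype=float)) ** 2))
    mae = float(np.mean(np.abs(
        np.asarray(predictions["recon"], dtype=float)
        - np.asarray(targets["recon"], dtype=float))))
    p_exc = np.asarray(predictions["excessive_prob"], dtype=float)
    y_exc = np.asarray(targets["excessive"], dtype=float)
    p_clip = np.clip(p_exc, _EPS, 1.0 - _EPS)
    bce_terms = -(y_exc * np.log(p_clip) + (1 - y_exc) * np.log(1 - p_clip))
    # an exactly correct hard probability contributes exactly zero
    bce_terms = np.where(p_exc == y_exc, 0.0, bce_terms)
    bce = float(np.mean(bce_terms))
    return w[0] * ce + w[1] * mse + w[2] * mae + w[3] * bce


def _patient_of(record_id: str) -> str:
    return record_id.rsplit("S", 1)[0]


def _dataset_targets(ds) -> dict:
    return {
        "class_index": ds.class_index,
        "future": ds.future,
        "recon": ds.recon,
        "excessive": ds.excessive,
    }


def train(dataset, config: NetConfig):
    """Train a :class:`RespMotionNet` on a :class:`WindowedDataset`.

    A patient-wise validation split (``config.val_fraction`` of training
    patients) drives early stopping; the best-validation parameters are
    restored at the end.  Identical ``(dataset, config)`` give identical
    histories and final parameters.

    Returns ``(model, history)`` where history is one dict per epoch with the
    train and validation composite losses.
    """
    config.validate()
    n = len(dataset)
    if n == 0:
        raise ValueError("empty dataset")

    rng = np.random.default_rng(config.seed + 17)
    patients = np.asarray([_patient_of(r) for r in dataset.record_ids])
    unique = np.unique(patients)
    if config.val_fraction > 0 and len(unique) >= 2:
        perm = rng.permutation(len(unique))
        n_val = max(1, int(round(config.val_fraction * len(unique))))
        n_val = min(n_val, len(unique) - 1)
        val_patients = set(unique[perm[:n_val]].tolist())
        val_mask = np.isin(patients, list(val_patients))
    else:
        # single patient (or no validation requested): hold out trailing windows
        val_mask = np.zeros(n, dtype=bool)
        if config.val_fraction > 0 and n >= 10:
            val_mask[int(n * (1 - config.val_fraction)):] = True
    train_idx = np.flatnonzero(~val_mask)
    val_idx = np.flatnonzero(val_mask)
    if len(train_idx) == 0:
        raise ValueError("validation split left no training windows")

    model = RespMotionNet(
        config,
        window_len=dataset.window_len,
        n_channels=dataset.n_channels,
        n_horizons=len(dataset.horizons),
    )
    opt = _Adam(model.params(), lr=config.learning_rate)
    targets = _dataset_targets(dataset)
    X = dataset.inputs

    def batch_targets(idx):
        return {k: v[idx] for k, v in targets.items()}

    history: list[dict] = []
    best_val = np.inf
    best_state: list[np.ndarray] | None = None
    wait = 0
    have_val = len(val_idx) > 0
    steps_per_epoch = int(np.ceil(len(train_idx) / config.batch_size))
    total_steps = max(1, steps_per_epoch * config.max_epochs)
    step = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(train_idx)
        losses = []
        for i in range(0, len(order), config.batch_size):
            if config.lr_schedule == "cosine":
                opt.lr = config.learning_rate * 0.5 * (
                    1.0 + np.cos(np.pi * step / total_steps)
                )
            idx = order[i : i + config.batch_size]
            stats = model.train_step(X[idx], batch_targets(idx), opt)
            losses.append(stats["loss"])
            step += 1
        train_loss = float(np.mean(losses))
        if have_val:
            val_loss = float(model.eval_loss(X[val_idx], batch_targets(val_idx)))
        else:
            val_loss = train_loss
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss})
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = [p.value.copy() for p in model.params()]
            wait = 0
        else:
            wait += 1
            if wait >= config.patience:
                break
    if best_state is not None:
        for p, v in zip(model.params(), best_state):
            p.value[...] = v
    return model, history


def save_checkpoint(model: RespMotionNet, path) -> None:
    """Single-file parameter archive with the embedded model configuration."""
    meta = {
        "config": asdict(model.config),
        "window_len": model.window_len,
        "n_channels": model.n_channels,
        "n_horizons": model.n_horizons,
    }
    arrays = model.state_arrays()
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> RespMotionNet:
    """Rebuild a model whose inference is bit-identical to the saved one."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode("utf-8"))
        cfg_d = dict(meta["config"])
        cfg_d["dilations"] = tuple(cfg_d["dilations"])
        cfg_d["loss_weights"] = tuple(cfg_d["loss_weights"])
        config = NetConfig(**cfg_d)
        model = RespMotionNet(
            config,
            window_len=meta["window_len"],
            n_channels=meta["n_channels"],
            n_horizons=meta["n_horizons"],
        )
        for i, p in enumerate(model.params()):
            p.value[...] = z[f"p{i}"]
    return model
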