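"""Binary CNN classifier of gene-expression class from flanking sequence.

The architecture follows the standard interpretable-genomics design: three
convolutional blocks (two valid-padding 1D convolutions, max pooling and
dropout each), a fully connected block of two hidden layers interspaced with
dropout, and a single sigmoid output unit giving the probability that the
gene is highly expressed.  Training minimises binary cross-entropy with Adam
(learning rate 0.001), early stopping (patience 10), learning-rate halving on
plateau (patience 5) and restoration of the best-validation-loss weights.

The classifier is exposed statsmodels-style: construct an
:class:`ExpressionClassifier` from arrays, call :meth:`fit`, and work with the
returned :class:`ClassifierResults` (history, metrics, ``summary()``,
``predict_proba``).

Classification rule at prediction time: probability <= 0.5 means *low*,
> 0.5 means *high*.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn

__all__ = ["ModelConfig", "ExpressionClassifier", "ClassifierResults",
           "build_model", "evaluate_predictions", "train_fold"]


@dataclass
class ModelConfig:
    n_conv_blocks: int = 3
    conv_layers_per_block: int = 2
    filters_per_block: tuple = (16, 32, 16)
    kernel_size: int = 8
    pool_size: int = 8
    dropout_rate: float = 0.25
    batch_norm: bool = True
    fc_sizes: tuple = (128, 64)
    learning_rate: float = 0.03
    weight_decay: float = 0.0
    max_epochs: int = 100
    min_epochs: int = 0  # early stopping / LR reduction start after this
    # restart training from a fresh seeded init when the validation loss is
    # still at the chance plateau at this epoch (0 disables); odd attempts
    # scale the learning rate by restart_lr_factor to diversify the search
    plateau_restart_epoch: int = 0
    max_restarts: int = 0
    plateau_loss: float = 0.67
    restart_lr_factor: float = 2.0
    # dropout applied while still on the chance plateau; the configured
    # dropout_rate takes over once learning is established (best validation
    # loss below ignition_exit_loss; None disables the two-phase scheme)
    ignition_dropout: float | None = 0.1
    ignition_exit_loss: float = 0.45
    early_stop_patience: int = 10
    lr_reduce_patience: int = 5
    lr_reduce_factor: float = 0.5
    min_lr: float = 1e-4
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        sizes = list(self.filters_per_block) + list(self.fc_sizes) + [
            self.kernel_size, self.pool_size, self.batch_size, self.max_epochs]
        if any(s <= 0 for s in sizes):
            raise ValueError("all sizes must be > 0")


def build_model(cfg: ModelConfig, input_len: int, n_channels: int = 4,
                seed: int | None = None) -> nn.Network:
    """Assemble the untrained network for a given fused-input length."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    layers = []
    L, C = input_len, n_channels
    for f in cfg.filters_per_block[: cfg.n_conv_blocks]:
        for _ in range(cfg.conv_layers_per_block):
            if L < cfg.kernel_size:
                raise ValueError("input too short for the convolutional stack")
            layers.append(nn.Conv1D(C, f, cfg.kernel_size, rng))
            if cfg.batch_norm:
                layers.append(nn.BatchNorm(f))
            layers.append(nn.ReLU())
            L, C = L - cfg.kernel_size + 1, f
        layers.append(nn.MaxPool1D(cfg.pool_size))
        L //= cfg.pool_size
        if L < 1:
            raise ValueError("input too short for the pooling stack")
        layers.append(nn.Dropout(cfg.dropout_rate))
    layers.append(nn.Flatten())
    D = L * C
    for h in cfg.fc_sizes:
        layers.append(nn.Dense(D, h, rng))
        if cfg.batch_norm:
            layers.append(nn.BatchNorm(h))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(cfg.dropout_rate))
        D = h
    layers.append(nn.Dense(D, 1, rng, he=False))
    layers.append(nn.Sigmoid())
    return nn.Network(layers)


def evaluate_predictions(probs, labels) -> dict:
    """Accuracy (threshold 0.5, ties -> low), auROC and F1 on the high class.

    auROC is absent (None) when the validation set is single-class.
    """
    from sklearn.metrics import f1_score, roc_auc_score

    probs = np.asarray(probs, dtype=float).ravel()
    labels = np.asarray(labels, dtype=int).ravel()
    pred = (probs > 0.5).astype(int)
    out = {
        "accuracy": float((pred == labels).mean()),
        "f1": float(f1_score(labels, pred, pos_label=1, zero_division=0)),
    }
    out["auroc"] = float(roc_auc_score(labels, probs)) if len(set(labels)) == 2 else None
    return out


@dataclass
class ClassifierResults:
    """Fitted-model container: best weights, history and validation metrics."""

    config: ModelConfig
    network: nn.Network
    history: dict
    metrics: dict
    best_epoch: int
    input_len: int

    def predict_proba(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != self.input_len:
            raise ValueError(f"input length {x.shape[1]} != trained length {self.input_len}")
        out = []
        for i in range(0, len(x), 256):
            out.append(self.network.forward(x[i : i + 256]).ravel())
        self.network.clear_caches()
        return np.concatenate(out).astype(float)

    def predict_class(self, x) -> np.ndarray:
        """1 = high for probability > 0.5; boundary 0.5 counts as low."""
        return (self.predict_proba(x) > 0.5).astype(int)

    def summary(self) -> str:
        lines = [
            "Expression CNN classifier",
            "=" * 40,
            f"parameters:        {self.network.n_params()}",
            f"input length:      {self.input_len}",
            f"epochs run:        {len(self.history['train_loss'])}",
            f"best epoch:        {self.best_epoch + 1}",
            f"best val loss:     {min(self.history['val_loss']):.4f}",
        ]
        for k in ("accuracy", "auroc", "f1"):
            v = self.metrics.get(k)
            lines.append(f"val {k:<14} {'--' if v is None else f'{v:.4f}'}")
        return "\n".join(lines)


class ExpressionClassifier:
    """Model object: training data in, :class:`ClassifierResults` out of fit()."""

    def __init__(self, x_train, y_train, x_val=None, y_val=None,
                 config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.x_train = np.asarray(x_train, dtype=np.float32)
        self.y_train = np.asarray(y_train, dtype=np.float32).ravel()
        if len(self.x_train) == 0:
            raise ValueError("empty training set")
        self.x_val = None if x_val is None else np.asarray(x_val, dtype=np.float32)
        self.y_val = None if y_val is None else np.asarray(y_val, dtype=np.float32).ravel()

    def fit(self, verbose: bool = False) -> ClassifierResults:
        """Train, restarting from a fresh seeded initialisation when the
        optimisation is still stuck at the chance plateau at the configured
        checkpoint epoch."""
        cfg = self.config
        last = None
        base = cfg.learning_rate
        f = cfg.restart_lr_factor
        # step-size regimes ignite on complementary initialisations, so the
        # restart ladder cycles three variants per initialisation seed before
        # advancing to a fresh seed: the base LR, the laddered LR, and a
        # two-level LR cycle straddling the base
        variants = [lambda e: base,
                    lambda e: base * f,
                    lambda e: base * (2 / 3) if (e // 4) % 2 == 0 else base * (5 / 3)]
        # an attempt counts as successful only when learning is established
        # (not merely below the chance plateau): weak partial solutions
        # otherwise evade the restart machinery
        success_loss = (cfg.ignition_exit_loss if cfg.ignition_dropout is not None
                        else cfg.plateau_loss)
        best_attempt = None
        for attempt in range(cfg.max_restarts + 1):
            plan = variants[attempt % len(variants)]
            last = self._fit_once(seed_offset=1000 * (attempt // len(variants)),
                                  verbose=verbose,
                                  allow_abandon=attempt < cfg.max_restarts,
                                  lr_plan=plan)
            if best_attempt is None or (min(last.history["val_loss"])
                                        < min(best_attempt.history["val_loss"])):
                best_attempt = last
            if min(last.history["val_loss"]) <= success_loss:
                break
            if verbose and attempt < cfg.max_restarts:
                print(f"restart {attempt + 1}: learning not established "
                      f"(best val loss "
                      f"{min(last.history['val_loss']):.3f})", flush=True)
        return best_attempt

    def _fit_once(self, seed_offset: int = 0, verbose: bool = False,
                  allow_abandon: bool = False, lr_plan=None) -> ClassifierResults:
        cfg = self.config
        net = build_model(cfg, self.x_train.shape[1], self.x_train.shape[2],
                          seed=cfg.seed + seed_offset)
        rng = np.random.default_rng(cfg.seed + seed_offset + 1)
        if lr_plan is None:
            lr_plan = lambda e: cfg.learning_rate
        opt = nn.Adam(net, lr=lr_plan(0), weight_decay=cfg.weight_decay)
        lr_scale = 1.0  # plateau reduction, multiplicative over the plan
        has_val = self.x_val is not None and len(self.x_val) > 0
        history = {"train_loss": [], "val_loss": [], "lr": []}
        best = {"loss": np.inf, "epoch": -1, "weights": net.get_weights()}
        stale = 0

        drop_layers = [l for l in net.layers if isinstance(l, nn.Dropout)]
        for epoch in range(cfg.max_epochs):
            opt.lr = max(lr_plan(epoch) * lr_scale, cfg.min_lr)
            if cfg.ignition_dropout is not None:
                ignited = best["loss"] <= cfg.ignition_exit_loss
                rate = cfg.dropout_rate if ignited else cfg.ignition_dropout
                for l in drop_layers:
                    l.rate = rate
            order = rng.permutation(len(self.x_train))
            losses = []
            for i in range(0, len(order), cfg.batch_size):
                idx = order[i : i + cfg.batch_size]
                xb, yb = self.x_train[idx], self.y_train[idx][:, None]
                p = net.forward(xb, train=True, rng=rng)
                loss, grad = nn.binary_cross_entropy(p, yb)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch + 1}; "
                        f"lr={opt.lr:.2e}, batch={i // cfg.batch_size}")
                net.backward(grad)
                opt.step()
                losses.append(loss)
            train_loss = float(np.mean(losses))
            if has_val:
                val_loss = self._loss(net, self.x_val, self.y_val)
            else:
                val_loss = train_loss
            history["train_loss"].append(train_loss)
            history["val_loss"].append(val_loss)
            history["lr"].append(opt.lr)
            if verbose:
                print(f"epoch {epoch + 1}: train {train_loss:.4f} val {val_loss:.4f}",
                      flush=True)

            if val_loss < best["loss"] - 1e-6:
                best = {"loss": val_loss, "epoch": epoch, "weights": net.get_weights()}
                stale = 0
            else:
                stale += 1
                if epoch + 1 >= cfg.min_epochs:
                    if stale >= cfg.early_stop_patience:
                        break
                    if stale and stale % cfg.lr_reduce_patience == 0:
                        lr_scale *= cfg.lr_reduce_factor
            if (allow_abandon and cfg.plateau_restart_epoch
                    and epoch + 1 == cfg.plateau_restart_epoch
                    and best["loss"] > cfg.plateau_loss):
                break  # still at the chance plateau; caller restarts

        net.set_weights(best["weights"])
        net.clear_caches()
        results = ClassifierResults(
            config=cfg, network=net, history=history,
            metrics={}, best_epoch=max(best["epoch"], 0),
            input_len=self.x_train.shape[1],
        )
        if has_val:
            probs = results.predict_proba(self.x_val)
            results.metrics = evaluate_predictions(probs, self.y_val.astype(int))
        return results

    @staticmethod
    def _loss(net, x, y):
        losses, n = 0.0, 0
        for i in range(0, len(x), 256):
            p = net.forward(x[i : i + 256])
            loss, _ = nn.binary_cross_entropy(p, y[i : i + 256][:, None])
            losses += loss * len(p)
            n += len(p)
        net.clear_caches()
        return losses / n


def train_fold(fold, encoded: dict, labels: dict, cfg: ModelConfig | None = None,
               verbose: bool = False) -> ClassifierResults:
    """Train on a CVFold given encodings and binary labels keyed by gene id."""
    cfg = cfg or ModelConfig()
    xt = np.stack([encoded[g] for g in fold.train_ids])
    yt = np.array([labels[g] for g in fold.train_ids])
    xv = np.stack([encoded[g] for g in fold.val_ids]) if fold.val_ids else None
    yv = np.array([labels[g] for g in fold.val_ids]) if fold.val_ids else None
    model = ExpressionClassifier(xt, yt, xv, yv, config=cfg)
    return model.fit(verbose=verbose)
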