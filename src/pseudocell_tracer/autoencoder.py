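"""Supervised autoencoder: expression -> latent -> (isotype profile, expression).

Two networks trained in sequence:

1. **Supervised encoder.** Maps log2(TPM+1) expression through ReLU layers
   (512, 256) to a 64-unit sigmoid latent, then through a 128-unit head to a
   softmax over the K condition channels. Trained with mean KL divergence
   between observed and predicted channel proportions plus an L2 weight
   penalty; the latent is thereby shaped so that cells with similar relative
   isotype expression receive similar encodings.
2. **Decoder.** Maps the (frozen) 64-d latent back to full expression through
   ReLU + batch-norm layers (256, 512) and a linear output, trained with MSE
   plus the same L2 penalty.

Both use Adam, dropout (encoder only), and patience-based early stopping on
the monitored loss *term* (KLD for the encoder, MSE for the decoder)
evaluated on a held-out validation split; after restoring the best weights,
training continues for a few epochs on the full data including the
validation split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .nn import Adam, BatchNorm, Dense, Dropout, EarlyStopper, Sequential
from .preprocess import AdjacentProfiles, ExpressionMatrix

__all__ = [
    "EncoderSpec", "DecoderSpec", "EarlyStopConfig",
    "EncoderModel", "DecoderModel", "CrossValResult",
    "kld", "encoder_loss", "decoder_loss",
    "train_supervised_encoder", "train_decoder", "encode",
    "crossvalidate_autoencoder",
]

PROB_FLOOR = 1e-12  # clip for predicted probabilities inside logs


@dataclass
class EncoderSpec:
    input_dim: int
    hidden_dims: tuple = (512, 256)
    latent_dim: int = 64
    head_hidden_dim: int = 128
    output_dim: int = 8
    dropout_rate: float = 0.3
    l2_weight: float = 1e-5
    learning_rate: float = 1e-4
    batch_size: int = 128

    def __post_init__(self):
        if not self.latent_dim < self.input_dim:
            raise ValueError("latent_dim must be smaller than input_dim")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class DecoderSpec:
    output_dim: int  # gene count
    latent_dim: int = 64
    hidden_dims: tuple = (256, 512)
    l2_weight: float = 1e-5
    learning_rate: float = 1e-4
    batch_size: int = 128


@dataclass
class EarlyStopConfig:
    validation_fraction: float = 0.10
    patience_epochs: int = 100
    post_restore_epochs: int = 5
    max_epochs: int = 10_000  # safety cap when patience never triggers

    def __post_init__(self):
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# losses (pure functions; these are also the training objectives)
# ---------------------------------------------------------------------------

def kld(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean KL divergence sum_k y_k log(y_k / yhat_k) over a batch.

    Zero-probability observed entries contribute 0; predictions are clipped
    to ``PROB_FLOOR`` before the log.
    """
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float))
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.shape[0] == 0:
        raise ValueError("empty batch")
    q = np.clip(y_pred, PROB_FLOOR, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(y_true > 0, y_true * (np.log(y_true) - np.log(q)), 0.0)
    value = float(terms.sum(axis=1).mean())
    if not np.isfinite(value):
        bad = int(np.flatnonzero(~np.isfinite(terms.sum(axis=1)))[0])
        raise FloatingPointError(f"non-finite KLD at batch index {bad}")
    return value


def l2_penalty(layer_weights, lam: float) -> float:
    return lam * sum(float(np.sum(np.asarray(W) ** 2)) for W in layer_weights)


def encoder_loss(y_true, y_pred, layer_weights=(), lam: float = 0.0) -> float:
    """Supervision loss: mean KLD(observed || predicted) + lam * sum ||W_l||^2."""
    return kld(y_true, y_pred) + l2_penalty(layer_weights, lam)


def decoder_loss(x_true, x_pred, layer_weights=(), lam: float = 0.0,
                 reduction: str = "mean_all") -> float:
    """Reconstruction loss: mean squared error + lam * sum ||W_l||^2.

    ``reduction="mean_all"`` averages squared errors over every (cell, gene)
    entry; ``"sum_genes"`` sums over genes before averaging over cells.
    """
    x_true = np.atleast_2d(np.asarray(x_true, dtype=float))
    x_pred = np.atleast_2d(np.asarray(x_pred, dtype=float))
    if x_true.shape != x_pred.shape:
        raise ValueError(f"shape mismatch: {x_true.shape} vs {x_pred.shape}")
    if x_true.shape[0] == 0:
        raise ValueError("empty batch")
    sq = (x_true - x_pred) ** 2
    mse = float(sq.mean()) if reduction == "mean_all" else float(sq.sum(axis=1).mean())
    return mse + l2_penalty(layer_weights, lam)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

class EncoderModel:
    """Trained supervised encoder: expression -> latent -> channel profile."""

    def __init__(self, spec: EncoderSpec, gene_ids, channel_ids, seed: int):
        self.spec = spec
        self.gene_ids = list(gene_ids)
        self.channel_ids = list(channel_ids)
        self.seed = seed
        rng = np.random.default_rng(seed)
        d = spec.dropout_rate
        trunk = []
        prev = spec.input_dim
        for h in spec.hidden_dims:
            trunk += [Dense(prev, h, "relu", rng), Dropout(d, rng)]
            prev = h
        trunk.append(Dense(prev, spec.latent_dim, "sigmoid", rng))
        self.trunk = Sequential(trunk)
        self.head = Sequential([
            Dense(spec.latent_dim, spec.head_hidden_dim, "relu", rng),
            Dropout(d, rng),
            Dense(spec.head_hidden_dim, spec.output_dim, "linear", rng),
        ])
        self.training_log: pd.DataFrame | None = None

    # -- inference ----------------------------------------------------------
    def _check_genes(self, expr: ExpressionMatrix) -> None:
        if list(expr.gene_ids) != self.gene_ids:
            missing = sorted(set(self.gene_ids) - set(expr.gene_ids))
            raise ValueError(
                f"gene set/order differs from training; {len(missing)} missing, "
                f"e.g. {missing[:5]}")

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Latent encodings in (0,1)^latent_dim; dropout disabled."""
        return self.trunk.forward(np.atleast_2d(x), training=False)

    def predict_profiles_from_latent(self, z: np.ndarray) -> np.ndarray:
        return _softmax(self.head.forward(np.atleast_2d(z), training=False))

    def predict_profiles(self, x: np.ndarray) -> np.ndarray:
        return self.predict_profiles_from_latent(self.encode(x))

    # -- training internals --------------------------------------------------
    @property
    def params(self):
        return self.trunk.params + self.head.params

    @property
    def grads(self):
        return self.trunk.grads + self.head.grads

    def get_state(self):
        return self.trunk.get_state() + self.head.get_state()

    def set_state(self, state):
        k = len(self.trunk.get_state())
        self.trunk.set_state(state[:k])
        self.head.set_state(state[k:])

    def weight_matrices(self):
        return self.trunk.weight_matrices() + self.head.weight_matrices()


class DecoderModel:
    """Trained decoder: latent -> full expression profile."""

    def __init__(self, spec: DecoderSpec, gene_ids, seed: int):
        self.spec = spec
        self.gene_ids = list(gene_ids)
        self.seed = seed
        rng = np.random.default_rng(seed)
        layers = []
        prev = spec.latent_dim
        for h in spec.hidden_dims:
            layers += [Dense(prev, h, "relu", rng), BatchNorm(h)]
            prev = h
        layers.append(Dense(prev, spec.output_dim, "linear", rng))
        self.net = Sequential(layers)
        self.training_log: pd.DataFrame | None = None

    def decode(self, z: np.ndarray) -> np.ndarray:
        return self.net.forward(np.atleast_2d(z), training=False)


def encode(model: EncoderModel, expr: ExpressionMatrix) -> np.ndarray:
    """Encode a matrix whose gene set/order matches the model's training data."""
    model._check_genes(expr)
    return model.encode(expr.values)


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

def _stratified_split(n: int, frac: float, labels, rng: np.random.Generator):
    """Seeded validation split, stratified by label when group sizes allow."""
    n_val = max(1, int(round(frac * n)))
    idx = np.arange(n)
    if labels is not None:
        labels = np.asarray(labels)
        val = []
        for lab in np.unique(labels):
            members = idx[labels == lab]
            members = members[rng.permutation(len(members))]
            take = max(1, int(round(frac * len(members)))) if len(members) > 1 else 0
            val.extend(members[:take])
        val = np.sort(np.array(val, dtype=int))
        if 0 < len(val) < n:
            train = np.setdiff1d(idx, val)
            return train, val
    perm = rng.permutation(n)
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


def train_supervised_encoder(expr: ExpressionMatrix, profiles: AdjacentProfiles,
                             spec: EncoderSpec | None = None,
                             stop: EarlyStopConfig | None = None,
                             seed: int = 0) -> EncoderModel:
    """Train the supervised encoder with early stopping on validation KLD."""
    if expr.n_cells != profiles.n_cells:
        raise ValueError("expression and profiles are not row-aligned")
    if expr.n_cells < 20:
        raise ValueError("need at least 20 cells to train")
    spec = spec or EncoderSpec(input_dim=expr.n_genes, output_dim=profiles.n_channels)
    stop = stop or EarlyStopConfig()
    if spec.input_dim != expr.n_genes or spec.output_dim != profiles.n_channels:
        raise ValueError("spec dimensions do not match the data")

    model = EncoderModel(spec, expr.gene_ids, profiles.channel_ids, seed)
    rng = np.random.default_rng(seed + 1)
    X, Y = expr.values, profiles.weights
    train_idx, val_idx = _stratified_split(
        expr.n_cells, stop.validation_fraction, profiles.dominant_channel(), rng)

    def forward_backward(xb, yb):
        z = model.trunk.forward(xb, training=True)
        logits = model.head.forward(z, training=True)
        probs = _softmax(logits)
        dlogits = (probs - yb) / xb.shape[0]  # fused softmax+KLD gradient
        model.trunk.backward(model.head.backward(dlogits))
        model.trunk.add_l2_grads(spec.l2_weight)
        model.head.add_l2_grads(spec.l2_weight)

    def monitored(idx):
        return kld(Y[idx], model.predict_profiles(X[idx]))

    opt = Adam(model.params, spec.learning_rate)
    stopper = EarlyStopper(stop.patience_epochs)
    log = _run_epochs(model, opt, forward_backward, monitored, train_idx, val_idx,
                      spec.batch_size, stop, stopper, rng, X, Y,
                      l2_value=lambda: l2_penalty(model.weight_matrices(), spec.l2_weight))
    model.training_log = log
    return model


def train_decoder(latents: np.ndarray, expr: ExpressionMatrix,
                  spec: DecoderSpec | None = None,
                  stop: EarlyStopConfig | None = None,
                  seed: int = 0,
                  stratify_labels=None) -> DecoderModel:
    """Train the decoder on (latent, expression) pairs; early stop on val MSE."""
    latents = np.asarray(latents, dtype=float)
    if latents.shape[0] != expr.n_cells:
        raise ValueError("latents and expression are not row-aligned")
    spec = spec or DecoderSpec(output_dim=expr.n_genes, latent_dim=latents.shape[1])
    stop = stop or EarlyStopConfig()
    if spec.latent_dim != latents.shape[1] or spec.output_dim != expr.n_genes:
        raise ValueError("spec dimensions do not match the data")

    model = DecoderModel(spec, expr.gene_ids, seed)
    rng = np.random.default_rng(seed + 1)
    X, Y = latents, expr.values  # input latent, target expression
    train_idx, val_idx = _stratified_split(
        expr.n_cells, stop.validation_fraction, stratify_labels, rng)

    def forward_backward(xb, yb):
        pred = model.net.forward(xb, training=True)
        dmse = 2.0 * (pred - yb) / pred.size  # mean over all entries
        model.net.backward(dmse)
        model.net.add_l2_grads(spec.l2_weight)

    def monitored(idx):
        return decoder_loss(Y[idx], model.decode(X[idx]))

    opt = Adam(model.net.params, spec.learning_rate)
    stopper = EarlyStopper(stop.patience_epochs)
    log = _run_epochs(model, opt, forward_backward, monitored, train_idx, val_idx,
                      spec.batch_size, stop, stopper, rng, X, Y,
                      l2_value=lambda: model.net.l2_penalty(spec.l2_weight))
    model.training_log = log
    return model


def _run_epochs(model, opt, forward_backward, monitored, train_idx, val_idx,
                batch_size, stop: EarlyStopConfig, stopper: EarlyStopper,
                rng: np.random.Generator, X, Y, l2_value):
    """Shared minibatch loop: early stop, weight restore, +N full-data epochs."""
    records = []
    n_train = len(train_idx)
    for epoch in range(stop.max_epochs):
        order = train_idx[rng.permutation(n_train)]
        for start in range(0, n_train, batch_size):
            batch = order[start:start + batch_size]
            forward_backward(X[batch], Y[batch])
            if not all(np.all(np.isfinite(g)) for g in _grads_of(model)):
                raise FloatingPointError(f"non-finite gradient at epoch {epoch}")
            opt.step(_grads_of(model))
        train_term = monitored(train_idx)
        val_term = monitored(val_idx)
        records.append({"epoch": epoch, "phase": "early_stop",
                        "train_term": train_term, "val_term": val_term,
                        "l2": l2_value()})
        if stopper.update(epoch, val_term, _state_of(model)):
            break
    if stopper.best_state is not None:
        _set_state_of(model, stopper.best_state)  # revert to best validation state
    all_idx = np.sort(np.concatenate([train_idx, val_idx]))
    for extra in range(stop.post_restore_epochs):
        order = all_idx[rng.permutation(len(all_idx))]
        for start in range(0, len(all_idx), batch_size):
            batch = order[start:start + batch_size]
            forward_backward(X[batch], Y[batch])
            opt.step(_grads_of(model))
        records.append({"epoch": stopper.best_epoch + 1 + extra, "phase": "full_data",
                        "train_term": monitored(all_idx),
                        "val_term": monitored(val_idx), "l2": l2_value()})
    log = pd.DataFrame(records)
    log.attrs["best_epoch"] = stopper.best_epoch
    log.attrs["best_val_term"] = stopper.best_value
    return log


def _grads_of(model):
    return model.grads if hasattr(model, "grads") else model.net.grads


def _state_of(model):
    return model.get_state() if hasattr(model, "get_state") else model.net.get_state()


def _set_state_of(model, state):
    if hasattr(model, "set_state"):
        model.set_state(state)
    else:
        model.net.set_state(state)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CrossValResult:
    """Pooled held-out predictions from k-fold cross-validation."""

    observed_expression: np.ndarray
    predicted_expression: np.ndarray
    observed_profiles: np.ndarray
    predicted_profiles: np.ndarray
    gene_ids: list
    channel_ids: list
    fold_of_cell: np.ndarray
    per_gene_r: pd.Series = field(init=False)
    per_channel_r: pd.Series = field(init=False)

    def __post_init__(self):
        self.per_gene_r = pd.Series(
            _columnwise_pearson(self.observed_expression, self.predicted_expression),
            index=self.gene_ids, name="pearson_r")
        self.per_channel_r = pd.Series(
            _columnwise_pearson(self.observed_profiles, self.predicted_profiles),
            index=self.channel_ids, name="pearson_r")


def _columnwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    denom = np.sqrt((a * a).sum(axis=0) * (b * b).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (a * b).sum(axis=0) / denom, np.nan)


def crossvalidate_autoencoder(expr: ExpressionMatrix, profiles: AdjacentProfiles,
                              folds: int = 10, seed: int = 0,
                              encoder_spec: EncoderSpec | None = None,
                              decoder_spec: DecoderSpec | None = None,
                              stop: EarlyStopConfig | None = None) -> CrossValResult:
    """k-fold cross-validation of the full two-step autoencoder.

    Every cell lands in exactly one test fold; per fold the encoder and
    decoder are trained from scratch on the remaining cells, then the held-out
    cells are encoded and decoded. Returns pooled (observed, predicted) pairs
    with per-gene and per-channel Pearson correlations.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > expr.n_cells:
        raise ValueError("more folds than cells")
    pred_x = np.full_like(expr.values, np.nan)
    pred_y = np.full_like(profiles.weights, np.nan)
    fold_of = np.full(expr.n_cells, -1, dtype=int)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for f, (train, test) in enumerate(kf.split(expr.values)):
        sub_expr = ExpressionMatrix(expr.values[train],
                                    expr.gene_ids,
                                    [expr.cell_ids[i] for i in train],
                                    expr.normalization_tag)
        sub_prof = AdjacentProfiles(profiles.weights[train], profiles.channel_ids,
                                    [profiles.cell_ids[i] for i in train]
                                    if profiles.cell_ids else [])
        enc = train_supervised_encoder(sub_expr, sub_prof, encoder_spec, stop,
                                       seed=seed * 1000 + f)
        z_train = enc.encode(sub_expr.values)
        dec = train_decoder(z_train, sub_expr, decoder_spec, stop,
                            seed=seed * 1000 + f,
                            stratify_labels=sub_prof.dominant_channel())
        z_test = enc.encode(expr.values[test])
        pred_x[test] = dec.decode(z_test)
        pred_y[test] = enc.predict_profiles_from_latent(z_test)
        fold_of[test] = f
    return CrossValResult(expr.values, pred_x, profiles.weights, pred_y,
                          list(expr.gene_ids), list(profiles.channel_ids), fold_of)
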