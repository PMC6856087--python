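"""Feedforward networks on Cholesky-encoded relationship features.

Instead of feeding raw markers to a network, the genotype design matrix is
post-multiplied by the transpose of the upper Cholesky factor of the
genomic relationship matrix, Z_G* = Z_G U^T, and the genotype x environment
block by the blockwise Kronecker analogue Z_GE* = Z_GE (I_I (x) U^T).  The
resulting features reproduce the GRM covariance exactly:
(Z_G U^T)(Z_G U^T)^T = Z_G G Z_G^T.  The full input is
X = [Z_E, Z_G*, Z_GE*] (the interaction block optional).

The networks are densely connected feedforward regressors with 1-3 hidden
layers of equal width, RELU activations (hidden and, by default, output —
the traits are positive), inverted dropout on hidden layers during
training, and mean-squared-error loss minimized by mini-batch gradient
descent with momentum.  The univariate model (UDL) has one output; the
multi-trait model (MTDL) one output per trait, sharing all hidden layers.

Hyper-parameters (units, epochs, layers) are tuned by grid search: one
training run per (units, layers) pair with the validation loss recorded at
every epoch, which evaluates every (units, epochs, layers) combination at a
fraction of the cost of retraining per epoch count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genotypes import CholeskyFactor

__all__ = [
    "NetworkSpec",
    "HyperGrid",
    "EncodedInputs",
    "TrainedNetwork",
    "encode_features",
    "network_depth",
    "network_size",
    "network_width",
    "train_network",
    "predict_network",
    "grid_search",
    "count_grid",
]


@dataclass
class NetworkSpec:
    """Architecture and training settings for one network."""

    n_hidden_layers: int = 2
    units_per_layer: int = 60
    n_outputs: int = 1
    dropout_rate: float = 0.30
    max_epochs: int = 200
    activation: str = "relu"
    output_activation: str = "relu"
    learning_rate: float = 0.002
    momentum: float = 0.9
    batch_size: int = 32
    max_grad_norm: float | None = 25.0  # global-norm clip; None disables
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_hidden_layers <= 3:
            raise ValueError("n_hidden_layers must be 1, 2 or 3")
        if self.units_per_layer < 1:
            raise ValueError("units_per_layer must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class HyperGrid:
    """Grid-search value lists for units, epochs and hidden-layer counts."""

    units_values: tuple[int, ...] = tuple(range(20, 201, 20))
    epoch_values: tuple[int, ...] = tuple(range(1, 201))
    layer_values: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self) -> None:
        for name in ("units_values", "epoch_values", "layer_values"):
            vals = getattr(self, name)
            if len(vals) == 0 or any(int(v) != v or v < 1 for v in vals):
                raise ValueError(f"{name} must be non-empty positive integers")


def count_grid(grid: HyperGrid) -> int:
    """Number of (units, epochs, layers) combinations the grid evaluates."""
    return len(grid.units_values) * len(grid.epoch_values) * len(grid.layer_values)


@dataclass
class EncodedInputs:
    """Feature matrix X = [Z_E, Z_G U^T (, Z_GE (I (x) U^T))] with block labels."""

    X: np.ndarray
    column_blocks: dict  # name -> (start, stop)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def encode_features(Z_E, Z_G, Z_GE, factor: CholeskyFactor,
                    include_interaction: bool = True) -> EncodedInputs:
    """Cholesky-encode the one-hot designs into network inputs.

    The Kronecker product I_I (x) U^T is never materialized: because each
    Z_GE row is the indicator of cell (i, j), its encoded row equals row j
    of U^T placed in environment block i, which is exactly the corresponding
    row of Z_G U^T.
    """
    J = factor.upper.shape[0]
    if Z_G.shape[1] != J:
        raise ValueError(
            f"Z_G has {Z_G.shape[1]} line columns but the factor is {J}x{J}"
        )
    n = Z_G.shape[0]
    I = Z_E.shape[1]
    Qt = factor.lower_t  # U^T, lower triangular
    Ze = np.asarray(Z_E.todense()) if sp.issparse(Z_E) else np.asarray(Z_E, dtype=float)
    Xg = (Z_G @ Qt) if sp.issparse(Z_G) else np.asarray(Z_G, dtype=float) @ Qt
    Xg = np.asarray(Xg)
    blocks = {"environment": (0, I), "genotype": (I, I + J)}
    parts = [Ze, Xg]
    if include_interaction:
        if Z_GE.shape[1] != I * J:
            raise ValueError("Z_GE column count must be n_envs * n_lines")
        Zge = Z_GE.tocsr() if sp.issparse(Z_GE) else sp.csr_matrix(Z_GE)
        Xge = np.zeros((n, I * J))
        cols = Zge.indices[Zge.indptr[:-1]]  # the single active cell per row
        env_of_row = cols // J
        for i in range(I):
            rows = np.flatnonzero(env_of_row == i)
            if rows.size:
                Xge[np.ix_(rows, range(i * J, (i + 1) * J))] = Xg[rows]
        parts.append(Xge)
        blocks["interaction"] = (I + J, I + J + I * J)
    return EncodedInputs(np.hstack(parts), blocks)


def network_depth(layer_sizes) -> int:
    """Layers excluding the input layer (the field's convention)."""
    if len(layer_sizes) < 2:
        raise ValueError("need at least input and output layers")
    return len(layer_sizes) - 1


def network_size(layer_sizes) -> int:
    """Total units counting one bias unit per non-output layer."""
    if len(layer_sizes) < 2:
        raise ValueError("need at least input and output layers")
    return sum(w + 1 for w in layer_sizes[:-1]) + layer_sizes[-1]


def network_width(layer_sizes) -> int:
    """Widest layer, bias units included (output has no bias unit)."""
    if len(layer_sizes) < 2:
        raise ValueError("need at least input and output layers")
    return max(max(w + 1 for w in layer_sizes[:-1]), layer_sizes[-1])


def _act(name: str, x: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(x, 0.0)
    if name == "linear":
        return x
    raise ValueError(f"unknown activation {name!r}")


def _act_grad(name: str, pre: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (pre > 0).astype(pre.dtype)
    if name == "linear":
        return np.ones_like(pre)
    raise ValueError(f"unknown activation {name!r}")


@dataclass
class TrainedNetwork:
    """Weights, feature standardization, and the loss history of one run."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    spec: NetworkSpec
    x_mean: np.ndarray
    x_scale: np.ndarray
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.weights[0].shape[0]


def _init_params(spec: NetworkSpec, d: int, target_means: np.ndarray, rng):
    sizes = [d] + [spec.units_per_layer] * spec.n_hidden_layers + [spec.n_outputs]
    weights, biases = [], []
    for a, b in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.standard_normal((a, b)) * np.sqrt(2.0 / a))  # He init
        biases.append(np.zeros(b))
    biases[-1][:] = target_means  # start the output near the trait means
    return weights, biases


def _forward(weights, biases, X, spec: NetworkSpec, rng=None, dropout: float = 0.0):
    """Returns per-layer pre-activations, activations and dropout masks."""
    pres, acts, masks = [], [X], []
    h = X
    L = len(weights)
    for l in range(L):
        pre = h @ weights[l] + biases[l]
        name = spec.activation if l < L - 1 else spec.output_activation
        h = _act(name, pre)
        if l < L - 1 and dropout > 0.0:
            mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)  # inverted dropout
            h = h * mask
        else:
            mask = None
        pres.append(pre)
        acts.append(h)
        masks.append(mask)
    return pres, acts, masks


def predict_network(model: TrainedNetwork, inputs: EncodedInputs | np.ndarray) -> np.ndarray:
    """Deterministic forward pass with dropout disabled."""
    X = inputs.X if isinstance(inputs, EncodedInputs) else np.asarray(inputs, dtype=float)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match training ({model.n_features})"
        )
    Xs = (X - model.x_mean) / model.x_scale
    _, acts, _ = _forward(model.weights, model.biases, Xs, model.spec, dropout=0.0)
    return acts[-1]


def train_network(
    inputs: EncodedInputs | np.ndarray,
    targets: np.ndarray,
    spec: NetworkSpec,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainedNetwork:
    """Train one network by mini-batch gradient descent with momentum.

    Features are standardized on the training set (constant columns are left
    unscaled); targets stay on their original positive scale so RELU outputs
    are feasible.  Rows with any missing target are dropped (listwise).
    With ``validation`` given, the validation MSE is recorded after every
    epoch; training always runs to ``spec.max_epochs``.
    """
    X = inputs.X if isinstance(inputs, EncodedInputs) else np.asarray(inputs, dtype=float)
    Y = np.asarray(targets, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[1] != spec.n_outputs:
        raise ValueError(f"targets have {Y.shape[1]} columns, spec expects {spec.n_outputs}")
    keep = ~np.isnan(Y).any(axis=1)
    X, Y = X[keep], Y[keep]
    if len(X) == 0:
        raise ValueError("no complete training rows")

    rng = np.random.default_rng(spec.seed)
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0)
    x_scale = np.where(x_sd > 1e-12, x_sd, 1.0)
    Xs = (X - x_mean) / x_scale
    if validation is not None:
        Xv = (np.asarray(validation[0], dtype=float) - x_mean) / x_scale
        Yv = np.asarray(validation[1], dtype=float)
        if Yv.ndim == 1:
            Yv = Yv[:, None]

    weights, biases = _init_params(spec, X.shape[1], Y.mean(axis=0), rng)
    vel_w = [np.zeros_like(w) for w in weights]
    vel_b = [np.zeros_like(b) for b in biases]
    n = len(Xs)
    bs = min(spec.batch_size, n)
    model = TrainedNetwork(weights, biases, spec, x_mean, x_scale)

    for epoch in range(spec.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            xb, yb = Xs[idx], Y[idx]
            pres, acts, masks = _forward(weights, biases, xb, spec, rng, spec.dropout_rate)
            pred = acts[-1]
            err = pred - yb
            loss = float(np.mean(err ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "lower the learning rate or standardize the targets"
                )
            epoch_loss += loss * len(idx)
            # backprop: MSE averaged over batch and summed equally over outputs
            L = len(weights)
            delta = (2.0 / (len(idx) * Y.shape[1])) * err * _act_grad(
                spec.output_activation, pres[-1]
            )
            grads_w, grads_b = [None] * L, [None] * L
            for l in range(L - 1, -1, -1):
                a_prev = acts[l]  # activation feeding layer l (acts[0] = input)
                grads_w[l] = a_prev.T @ delta
                grads_b[l] = delta.sum(axis=0)
                if l > 0:
                    delta = delta @ weights[l].T
                    if masks[l - 1] is not None:
                        delta = delta * masks[l - 1]
                    delta = delta * _act_grad(spec.activation, pres[l - 1])
            if spec.max_grad_norm is not None:
                gnorm = np.sqrt(sum(float((g ** 2).sum()) for g in grads_w)
                                + sum(float((g ** 2).sum()) for g in grads_b))
                if gnorm > spec.max_grad_norm:
                    scale = spec.max_grad_norm / gnorm
                    grads_w = [g * scale for g in grads_w]
                    grads_b = [g * scale for g in grads_b]
            for l in range(L):
                vel_w[l] = spec.momentum * vel_w[l] - spec.learning_rate * grads_w[l]
                vel_b[l] = spec.momentum * vel_b[l] - spec.learning_rate * grads_b[l]
                weights[l] += vel_w[l]
                biases[l] += vel_b[l]
        model.train_loss.append(epoch_loss / n)
        if validation is not None:
            _, acts_v, _ = _forward(weights, biases, Xv, spec, dropout=0.0)
            model.val_loss.append(float(np.mean((acts_v[-1] - Yv) ** 2)))
    return model


def grid_search(
    inputs: EncodedInputs | np.ndarray,
    targets: np.ndarray,
    grid: HyperGrid,
    spec_template: NetworkSpec,
    validation_fraction: float = 0.2,
) -> tuple[NetworkSpec, pd.DataFrame]:
    """Select (units, layers, epochs) by inner-validation MSE.

    Trains once per (units, layers) pair up to max(epoch_values) epochs,
    scoring the held-out inner-validation split after every epoch, which
    evaluates the full (units, epochs, layers) grid.  Ties are broken toward
    fewer layers, then fewer units, then fewer epochs.  Returns the winning
    spec (with ``max_epochs`` set to the best epoch) and the score table.
    """
    X = inputs.X if isinstance(inputs, EncodedInputs) else np.asarray(inputs, dtype=float)
    Y = np.asarray(targets, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    keep = ~np.isnan(Y).any(axis=1)
    X, Y = X[keep], Y[keep]
    n = len(X)
    n_val = int(round(validation_fraction * n))
    if n_val < 1 or n - n_val < 1:
        raise ValueError("validation split smaller than 1 record")
    rng = np.random.default_rng(spec_template.seed)
    order = rng.permutation(n)
    val_idx, trn_idx = order[:n_val], order[n_val:]
    max_ep = max(grid.epoch_values)

    records = []
    best = None  # (score, layers, units, epochs)
    for layers in sorted(grid.layer_values):
        for units in sorted(grid.units_values):
            spec = replace(spec_template, n_hidden_layers=int(layers),
                           units_per_layer=int(units), max_epochs=max_ep)
            model = train_network(X[trn_idx], Y[trn_idx], spec,
                                  validation=(X[val_idx], Y[val_idx]))
            for ep in grid.epoch_values:
                score = model.val_loss[ep - 1]
                records.append({"layers": layers, "units": units, "epochs": ep,
                                "val_mse": score})
                key = (score, layers, units, ep)
                if best is None or key < best:
                    best = key
    best_spec = replace(spec_template, n_hidden_layers=int(best[1]),
                        units_per_layer=int(best[2]), max_epochs=int(best[3]))
    return best_spec, pd.DataFrame.from_records(records)
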